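"""Delimited-text storage for voltage trace sets.

CSV layout: comment lines carrying the metadata (dt, stimulus amplitudes,
recorded segment), then a header row ``time_ms,sweep_0,...`` and one row per
sample.  Values are written with 9 significant digits, so a round trip
preserves voltages to well below 1e-6 mV.
"""

from __future__ import annotations

import numpy as np

from .simulation import TraceSet


class TraceFormatError(ValueError):
    pass


def write_traceset(ts: TraceSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("# neurosim traceset\n")
        fh.write(f"# dt_ms = {ts.dt:.9g}\n")
        fh.write(f"# record_segment = {ts.record_segment}\n")
        amps = ",".join(f"{a:.9g}" for a in np.atleast_1d(ts.amplitudes))
        fh.write(f"# amplitudes_nA = {amps}\n")
        cols = ["time_ms"] + [f"sweep_{k}" for k in range(ts.n_sweeps)]
        fh.write(",".join(cols) + "\n")
        if ts.n_sweeps == 0:
            return
        times = ts.times
        for j in range(ts.n_samples):
            row = [f"{times[j]:.9g}"] + [f"{ts.voltages[k, j]:.9g}"
                                         for k in range(ts.n_sweeps)]
            fh.write(",".join(row) + "\n")


def read_traceset(path) -> TraceSet:
    dt = None
    record_segment = 0
    amplitudes = np.empty(0)
    header = None
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = (s.strip() for s in body.partition("="))
                    if key == "dt_ms":
                        dt = float(val)
                    elif key == "record_segment":
                        record_segment = int(val)
                    elif key == "amplitudes_nA":
                        amplitudes = (np.fromstring(val, sep=",")
                                      if val else np.empty(0))
                continue
            if header is None:
                header = line.split(",")
                if header[0] != "time_ms":
                    raise TraceFormatError(f"{path}:{lineno}: missing time_ms header")
                continue
            cols = line.split(",")
            if len(cols) != len(header):
                raise TraceFormatError(
                    f"{path}:{lineno}: expected {len(header)} columns, got {len(cols)}")
            try:
                rows.append([float(c) for c in cols])
            except ValueError as exc:
                raise TraceFormatError(f"{path}:{lineno}: {exc}") from None
    if header is None:
        raise TraceFormatError(f"{path}: no header row found")
    n_sweeps = len(header) - 1
    if rows:
        data = np.asarray(rows)
        if dt is None:
            dt = float(data[1, 0] - data[0, 0]) if data.shape[0] > 1 else 1.0
        voltages = data[:, 1:].T.copy()
    else:
        voltages = np.empty((n_sweeps, 0))
        dt = dt if dt is not None else 1.0
    if amplitudes.size == 0 and n_sweeps:
        amplitudes = np.full(n_sweeps, np.nan)
    return TraceSet(voltages=voltages, dt=dt, amplitudes=amplitudes,
                    record_segment=record_segment)
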