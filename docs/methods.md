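# Methods

## Model and discretization

A morphology is a tree of cylindrical segments; one segment is one
compartment (no finer subdivision).  Segments are Hines-ordered
(`parent[i] < i`), so the backward-Euler current balance produces a
quasi-tridiagonal matrix: tridiagonal plus structurally symmetric entries
at branch points.  For physical inputs (Cm > 0, dt > 0, conductances ≥ 0)
the matrix is strictly diagonally dominant, hence the unpivoted two-sweep
elimination is stable and no solver ever needs pivoting.

Units are fixed package-wide: mV, ms, nA, µS, nF, MΩ, µm, Ω·cm, S/cm²,
µF/cm².  The only conversions are `µS = S/cm² · µm² · 1e−2` and
`nF = µF/cm² · µm² · 1e−5`, chosen so that µS·mV = nA and nF·mV/ms = nA
identically and published conductance densities can be used verbatim.
Axial coupling between adjacent segments is the series combination of each
segment's half-cylinder resistance, `0.01 · Ra · (L/2) / (π (d/2)²)` MΩ.

Each step performs, in order: exact-exponential gate relaxation at the
current voltage, membrane conductance/driving-term evaluation, matrix
assembly (the axial part is precomputed once; membrane terms change with
the gates), and the linear solve.  Backward Euler is first-order and
unconditionally stable; the test suite verifies the O(dt) error against
the analytic single-compartment charging curve and convergence to
`v∞ = e + I/G` at step sizes up to 10 ms.

## Membrane mechanisms

Passive segments contribute `g_pas (v − e_pas)`.  Hodgkin–Huxley segments
use the classic squid-axon rate functions (resting shift −65 mV), with
removable singularities evaluated by series expansion near the singular
voltages, and gates advanced by
`x ← x∞ + (x − x∞) exp(−dt·q·(α+β))`, the exact solution of the gate ODE at
frozen voltage (a semigroup: composing half-steps equals the full step to
1e−12).  `q = 3^((celsius−6.3)/10)`, default 6.3 °C so q = 1.  Rate
table-lookup is deliberately not implemented; rates are evaluated directly
each step.

Defaults not fixed by the benchmark definitions are the standard
conventions of the reference squid-axon mechanism: `gl = 0.0003 S/cm²`,
`el = −54.3 mV`, `ena = 50 mV`, `ek = −77 mV`, `Cm = 1 µF/cm²`,
`Ra = 100 Ω·cm`, `e_pas = −70 mV`, passive density 0.001 S/cm².  The
"hot-soma" configuration used in the excitability benchmarks puts
24 / 2.88 S/cm² (Na⁺/K⁺) on somatic segments and 0.12 / 0.036 S/cm² on
dendrites; printed negative signs on such densities in some sources are
typographic — conductance densities are nonnegative by construction here.

## Branches, levels, and the two parallel schedules

A branch is a maximal unbranched run of segments, or an explicitly
declared section: the binary-tree generator declares the soma and every
tree node as its own section (mirroring how such benchmarks are built in
section-based simulators), while the fork keeps the soma inside its trunk
branch.  Levels count branch distance from the root (soma branch = 1);
`depth` is the maximal level and `m` the maximal root-leaf distance in
segments.

*Branch-based schedule.*  Triangularization runs levels depth→1, all
branches of a level in one logical round, junction contributions
accumulated in ascending child order (fixed so runs are bit-reproducible);
back-substitution runs levels 1→depth.  Rounds = depth.  The cost model
charges, per level, the longest branch plus (for levels ≥ 2) the largest
branch degree; the analysis module evaluates this literally, attributing
junction work to the child level, and a cross-module test asserts the
formula equals the solver's own schedule accounting.

*Segment-based schedule.*  Back-substitution is the first-order recurrence
`x_i = c_i + e_i x_parent(i)` with `c = rhs/d`, `e = −a/d`.  A precomputed
2^j-ancestor table (root maps to itself) lets all segments substitute
their ancestor's recurrence simultaneously, squaring the jump distance
each round: after ceil(log₂ m) rounds every multiplier chain has absorbed
the root's zero and `x = c` exactly.  Rounds use strict read-before-write
semantics (all reads from the previous round's arrays).  The cost model
`(N/W) log₂ m` is evaluated with the true (non-integer) logarithm, while
the implemented round count is its ceiling; both are reported.

The L/U factors are never materialized; both sweeps modify copies in
place.  Pivots below 1e−300 (double) or the subnormal threshold (single)
raise a singular-system error.

## Precision switch

`precision="single"` keeps state, gate updates, assembly, and all solver
arithmetic in float32, including accumulations, so the rounding behavior
of a genuinely single-precision engine is reproduced rather than
simulated.  The validation harness compares matched spike trains between
single and double runs; the signature of accumulated rounding is a roughly
linear per-spike timing shift (a fraction of a µs per spike on the
benchmark fork), and passive responses agree to well under 0.01 mV² max
squared error.

## Synthetic morphologies and what they do / do not show

Generators produce unbranched cables, forks (trunk + two equal daughters;
`make_fork_total(n)` splits n into near-thirds with the remainder to the
trunk), full binary trees (soma + 2^depth − 1 single-segment nodes,
2^depth segments total, m = depth + 1), and random trees (biased toward
cable-like runs) for solver stress tests.  Default geometry is 10 µm × 3 µm
dendritic segments with a 20 µm × 20 µm soma; the benchmarks fix only
segment counts, and this geometry yields input resistances of tens of MΩ,
so nA-scale current clamp stays in the physiological voltage range
(−2 nA on the 320-segment fork bottoms out near −170 mV; thinner
dendrites would push past −200 mV, which we treat as unphysical for these
protocols).

These trees exercise the solver schedules and membrane kinetics, not the
full electrotonic richness of reconstructed cells: no tapering, spines, or
heterogeneous channel gradients.  SWC files provide realistic trees (one
sample = one compartment; root stub length 2·radius, sphere-as-cylinder),
but passing tests on synthetic trees demonstrates solver correctness and
scheduling, not biological fidelity of any particular cell model.

One behavioral caveat baked into the benchmarks: with a 24 S/cm² sodium
soma, release from a −1 nA hyperpolarizing step reliably triggers an
anodal-break spike (a genuine feature of this membrane model at 6.3 °C).
The "hyperpolarizing response is spike-free" check therefore holds the
stimulus to the end of the record and evaluates the response during the
current step.

## Protocols and batching

The default protocol mirrors the standard multi-sweep current clamp:
dt = 0.1 ms (0.01 ms for refinement studies), 5000 steps per sweep
(t_stop 500 ms — a conflicting description of sweep length elsewhere is
resolved in favor of the 5000-sample reading, and t_stop is configurable),
first amplitude −1 nA rising 0.3 nA per sweep, stimulus and recording at
the soma.  The stimulus is gated on each step's start time within
[delay, delay + duration).  Sweeps and cells are mutually independent by
construction; the batch tests assert bitwise equality with standalone
runs for 13-sweep protocols and 128-cell populations.  Benchmark problem
sizes in the tests and the acceptance script (40-segment fork and depth-5
tree for spiking runs at dt down to 0.001 ms; 4–8-segment cells with
10 ms sweeps for the 128-cell batch) are chosen to keep the full
validation runnable on one CPU in a couple of minutes while preserving
every asserted property.

## Workload ablation

`workload_breakdown` mirrors ablation-by-subtraction profiling: it times a
full sweep, a passive-membrane variant, a `skip_solve` variant (gates and
assembly run, voltage frozen), and both together, then reports
matrix-solve time as full − no-solve and mechanism time as full − passive,
as fractions of the full runtime.  Absolute fractions are
hardware-dependent; tests assert only the structure (fractions in [0, 1],
the passive variant does not spike where the full model does, the
no-solve variant's voltage stays frozen).

## Known limitations

Fixed time step only; no Crank–Nicolson weighting; no synapses, calcium,
or extracellular fields; no variable segment counts per section; no GPU
execution — the parallel schedules are validated by round counts and SIMD
read/write semantics on one CPU, not by hardware threads; wall-clock
speedups are out of scope.
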