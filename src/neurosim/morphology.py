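"""Branched neuron morphologies: trees of cylindrical compartments.

A morphology is a tree of segments numbered in *Hines order* — every
segment's parent has a smaller index — which makes the discretized cable
operator quasi-tridiagonal: tridiagonal except for structurally symmetric
off-diagonal entries at branch points, solvable by one bottom-up and one
top-down sweep.

Segments group into *branches* (maximal unbranched runs between junctions,
or explicitly declared sections, as in simulators that treat the soma as its
own section even when it has a single child).  Each branch carries a *level*:
its distance from the root branch, with the root/soma branch at level 1.
Levels drive the branch-parallel solver schedule; the maximal root-to-leaf
distance in segments (``m``) drives the pointer-jumping solver's round count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

ROOT = -1
MECHANISMS = ("pas", "hh")


class MorphologyError(ValueError):
    """Ill-formed tree, topology table, or SWC file."""


@dataclass
class Morphology:
    """A Hines-ordered branched tree of cylindrical segments.

    Parameters
    ----------
    parent
        Parent index per segment; the single root has parent ``-1`` and every
        non-root segment satisfies ``parent[i] < i``.
    length_um, diam_um
        Cylinder length and diameter per segment, in micrometers (> 0).
    mech_tag
        Membrane mechanism per segment, ``"pas"`` or ``"hh"``.
    is_soma
        Boolean mask of somatic segments (defaults to the root only).
    branch_of
        Optional explicit branch membership per segment (section semantics).
        When omitted, branches are inferred topologically: a segment starts a
        new branch iff it is the root or its parent has more than one child.
        Explicit membership may only *refine* the topological partition.
    """

    parent: np.ndarray
    length_um: np.ndarray
    diam_um: np.ndarray
    mech_tag: np.ndarray
    is_soma: np.ndarray | None = None
    branch_of: np.ndarray | None = None

    # derived annotations, computed on construction
    n_children: np.ndarray = field(init=False, repr=False)
    children: list = field(init=False, repr=False)
    branch_id: np.ndarray = field(init=False, repr=False)
    level: np.ndarray = field(init=False, repr=False)
    branch_level: np.ndarray = field(init=False, repr=False)
    root_distance: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.length_um = np.asarray(self.length_um, dtype=np.float64)
        self.diam_um = np.asarray(self.diam_um, dtype=np.float64)
        self.mech_tag = np.asarray(self.mech_tag, dtype="U8")
        n = self.parent.shape[0]
        for name in ("length_um", "diam_um", "mech_tag"):
            if getattr(self, name).shape != (n,):
                raise MorphologyError(f"{name} must have shape ({n},)")
        if n == 0:
            raise MorphologyError("empty morphology")
        if self.parent[0] != ROOT:
            raise MorphologyError("segment 0 must be the root (parent -1)")
        if n > 1:
            body = self.parent[1:]
            if np.any(body < 0) or np.any(body >= np.arange(1, n)):
                raise MorphologyError(
                    "not Hines-ordered: need 0 <= parent[i] < i for i >= 1 "
                    "(use hines_order on raw parent tables)"
                )
        if np.any(self.length_um <= 0) or np.any(self.diam_um <= 0):
            raise MorphologyError("segment lengths and diameters must be > 0")
        bad = set(self.mech_tag) - set(MECHANISMS)
        if bad:
            raise MorphologyError(f"unknown mech_tag values {sorted(bad)}; allowed: {MECHANISMS}")
        if self.is_soma is None:
            self.is_soma = self.parent == ROOT
        else:
            self.is_soma = np.asarray(self.is_soma, dtype=bool)
            if self.is_soma.shape != (n,):
                raise MorphologyError(f"is_soma must have shape ({n},)")
        self._annotate()

    def _annotate(self) -> None:
        n = self.n_segments
        par = self.parent
        self.n_children = np.zeros(n, dtype=np.int64)
        if n > 1:
            np.add.at(self.n_children, par[1:], 1)
        self.children = [[] for _ in range(n)]
        for i in range(1, n):
            self.children[par[i]].append(i)
        self.children = [np.asarray(c, dtype=np.int64) for c in self.children]

        # topological branch starts: root, or parent is a junction
        starts = np.zeros(n, dtype=bool)
        starts[0] = True
        for i in range(1, n):
            if self.n_children[par[i]] != 1:
                starts[i] = True
        if self.branch_of is not None:
            declared = np.asarray(self.branch_of, dtype=np.int64)
            if declared.shape != (n,):
                raise MorphologyError(f"branch_of must have shape ({n},)")
            for i in range(1, n):
                if declared[i] != declared[par[i]]:
                    starts[i] = True
                elif starts[i]:
                    raise MorphologyError(
                        f"branch_of merges across a junction at segment {i}"
                    )

        self.branch_id = np.empty(n, dtype=np.int64)
        self.level = np.empty(n, dtype=np.int64)
        nb = 0
        for i in range(n):
            if starts[i]:
                self.branch_id[i] = nb
                self.level[i] = 1 if par[i] == ROOT else self.level[par[i]] + 1
                nb += 1
            else:
                self.branch_id[i] = self.branch_id[par[i]]
                self.level[i] = self.level[par[i]]
        self.branch_level = np.empty(nb, dtype=np.int64)
        self.branch_level[self.branch_id] = self.level

        self.root_distance = np.empty(n, dtype=np.int64)
        self.root_distance[0] = 1
        for i in range(1, n):
            self.root_distance[i] = self.root_distance[par[i]] + 1

        # within an inferred or declared branch, segments must form a chain
        first = {}
        for i in range(n):
            b = self.branch_id[i]
            if b in first:
                if self.branch_id[par[i]] != b:
                    raise MorphologyError(f"branch {b} is not a connected run")
            else:
                first[b] = i

    # ------------------------------------------------------------------
    @property
    def n_segments(self) -> int:
        return self.parent.shape[0]

    @property
    def n_branches(self) -> int:
        return self.branch_level.shape[0]

    @property
    def depth(self) -> int:
        """Maximum branch level (root branch = 1)."""
        return int(self.branch_level.max())

    @property
    def max_root_leaf_distance(self) -> int:
        """Longest root-to-leaf path, counted in segments (root alone = 1)."""
        return int(self.root_distance.max())

    @property
    def area_um2(self) -> np.ndarray:
        """Lateral cylinder area per segment, pi * diam * length (um^2)."""
        return np.pi * self.diam_um * self.length_um

    def branch_segments(self) -> list[np.ndarray]:
        """Segment indices of each branch, proximal to distal."""
        out = [[] for _ in range(self.n_branches)]
        for i in range(self.n_segments):
            out[self.branch_id[i]].append(i)
        return [np.asarray(s, dtype=np.int64) for s in out]

    def branch_L(self) -> np.ndarray:
        """Number of segments per branch (symbol L)."""
        return np.bincount(self.branch_id, minlength=self.n_branches)

    def branch_D(self) -> np.ndarray:
        """Number of child branches per branch (symbol D, its degree)."""
        last = np.zeros(self.n_branches, dtype=np.int64)
        for i in range(self.n_segments):
            last[self.branch_id[i]] = i  # ascending scan: max index wins
        return self.n_children[last]

    def branches_at_level(self, lvl: int) -> np.ndarray:
        return np.flatnonzero(self.branch_level == lvl)

    def with_mech(self, tag: str) -> "Morphology":
        """Copy of this morphology with every segment set to `tag`."""
        return Morphology(
            parent=self.parent.copy(),
            length_um=self.length_um.copy(),
            diam_um=self.diam_um.copy(),
            mech_tag=np.full(self.n_segments, tag, dtype="U8"),
            is_soma=self.is_soma.copy(),
            branch_of=None if self.branch_of is None else np.asarray(self.branch_of).copy(),
        )


def segment_area(m: Morphology, i: int | None = None):
    """Lateral cylinder area (um^2) of segment ``i``, or all segments."""
    a = m.area_um2
    return a if i is None else float(a[i])


# ----------------------------------------------------------------------
# ordering
# ----------------------------------------------------------------------

def hines_order(raw_parent) -> tuple[np.ndarray, np.ndarray]:
    """Renumber a tree so that every parent index precedes its children.

    Parameters
    ----------
    raw_parent
        Parent index per node in arbitrary numbering; the root has parent -1.

    Returns
    -------
    perm, new_parent
        ``perm[old] = new`` index map, and the reordered parent array with
        ``new_parent[i] < i`` for every non-root ``i``.  Children are visited
        in ascending original index, so an already-ordered tree maps to the
        identity permutation.
    """
    raw = np.asarray(raw_parent, dtype=np.int64)
    n = raw.shape[0]
    if n == 0:
        raise MorphologyError("empty parent table")
    roots = np.flatnonzero(raw == ROOT)
    if roots.size == 0:
        raise MorphologyError("no root (parent -1) found")
    if roots.size > 1:
        raise MorphologyError(f"multiple roots at indices {roots.tolist()}")
    if np.any((raw < ROOT) | (raw >= n)):
        raise MorphologyError("parent index out of range")
    if np.any(raw == np.arange(n)):
        raise MorphologyError("segment listed as its own parent (cycle)")

    kids = [[] for _ in range(n)]
    for i in range(n):
        if raw[i] != ROOT:
            kids[raw[i]].append(i)

    order = np.empty(n, dtype=np.int64)
    stack = [int(roots[0])]
    k = 0
    while stack:
        node = stack.pop()
        order[k] = node
        k += 1
        stack.extend(reversed(kids[node]))  # ascending-index visit order
    if k != n:
        missing = sorted(set(range(n)) - set(order[:k].tolist()))
        raise MorphologyError(
            f"{n - k} segment(s) unreachable from the root "
            f"(cycle or disconnected components), e.g. index {missing[0]}"
        )

    perm = np.empty(n, dtype=np.int64)
    perm[order] = np.arange(n)
    new_parent = np.where(raw[order] == ROOT, ROOT, perm[np.clip(raw[order], 0, None)])
    return perm, new_parent


def from_unordered(raw_parent, length_um, diam_um, mech_tag, is_soma=None) -> Morphology:
    """Build a Morphology from an arbitrarily numbered parent table."""
    perm, new_parent = hines_order(raw_parent)
    n = len(new_parent)

    def permute(arr, dtype):
        out = np.empty(n, dtype=dtype)
        out[perm] = np.asarray(arr)
        return out

    return Morphology(
        parent=new_parent,
        length_um=permute(length_um, np.float64),
        diam_um=permute(diam_um, np.float64),
        mech_tag=permute(mech_tag, "U8"),
        is_soma=None if is_soma is None else permute(is_soma, bool),
    )


# ----------------------------------------------------------------------
# synthetic generators
# ----------------------------------------------------------------------
# Default geometry: 10 um x 3 um segments with a 20 um x 20 um soma.  The
# artificial-tree benchmarks are specified purely in segment counts; this
# geometry gives whole-cell input resistances in the tens of megaohms, i.e.
# physiological current-clamp responses for nA-scale stimuli (a few-nA step
# stays within the physically meaningful voltage range).
SEG_LENGTH_UM = 10.0
SEG_DIAM_UM = 3.0
SOMA_LENGTH_UM = 20.0
SOMA_DIAM_UM = 20.0


def _geometry(n, soma_length, soma_diam, seg_length, seg_diam):
    length = np.full(n, seg_length, dtype=np.float64)
    diam = np.full(n, seg_diam, dtype=np.float64)
    length[0] = soma_length
    diam[0] = soma_diam
    soma = np.zeros(n, dtype=bool)
    soma[0] = True
    return length, diam, soma


def make_cable(n_segments: int, *, mech: str = "hh",
               seg_length: float = SEG_LENGTH_UM, seg_diam: float = SEG_DIAM_UM,
               soma_length: float = SOMA_LENGTH_UM, soma_diam: float = SOMA_DIAM_UM) -> Morphology:
    """Unbranched cable of ``n_segments``; segment 0 is the soma."""
    if n_segments < 1:
        raise MorphologyError("n_segments must be >= 1")
    parent = np.arange(-1, n_segments - 1, dtype=np.int64)
    length, diam, soma = _geometry(n_segments, soma_length, soma_diam, seg_length, seg_diam)
    return Morphology(parent, length, diam, np.full(n_segments, mech, "U8"), is_soma=soma)


def make_fork(trunk_segments: int, branch_segments: int, *, mech: str = "hh",
              seg_length: float = SEG_LENGTH_UM, seg_diam: float = SEG_DIAM_UM,
              soma_length: float = SOMA_LENGTH_UM, soma_diam: float = SOMA_DIAM_UM) -> Morphology:
    """Fork: a trunk (soma first) whose last segment bears two equal branches."""
    if trunk_segments < 1 or branch_segments < 1:
        raise MorphologyError("trunk_segments and branch_segments must be >= 1")
    t, b = trunk_segments, branch_segments
    n = t + 2 * b
    parent = np.empty(n, dtype=np.int64)
    parent[:t] = np.arange(-1, t - 1)
    parent[t] = t - 1
    parent[t + 1:t + b] = np.arange(t, t + b - 1)
    parent[t + b] = t - 1
    parent[t + b + 1:] = np.arange(t + b, t + 2 * b - 1)
    length, diam, soma = _geometry(n, soma_length, soma_diam, seg_length, seg_diam)
    return Morphology(parent, length, diam, np.full(n, mech, "U8"), is_soma=soma)


def make_fork_total(n_total: int, **kwargs) -> Morphology:
    """Fork with ``n_total`` segments split as evenly as possible into thirds
    (remainder going to the trunk)."""
    if n_total < 3:
        raise MorphologyError("a fork needs at least 3 segments")
    branch = n_total // 3
    trunk = n_total - 2 * branch
    return make_fork(trunk, branch, **kwargs)


def make_binary_tree(depth: int, *, mech: str = "hh",
                     seg_length: float = SEG_LENGTH_UM, seg_diam: float = SEG_DIAM_UM,
                     soma_length: float = SOMA_LENGTH_UM, soma_diam: float = SOMA_DIAM_UM) -> Morphology:
    """Soma root plus a full binary tree of ``2**depth - 1`` one-segment
    branches, ``2**depth`` segments in total.

    Every node of the tree is declared as its own one-segment branch, and the
    soma as its own branch (section semantics), so the branch levels run
    1 (soma) through ``depth + 1`` (leaves) and the maximal root-leaf
    distance is ``depth + 1`` segments.
    """
    if depth < 1:
        raise MorphologyError("depth must be >= 1")
    parents = [ROOT]

    def add(p: int, levels_left: int) -> None:
        idx = len(parents)
        parents.append(p)
        if levels_left > 1:
            add(idx, levels_left - 1)
            add(idx, levels_left - 1)

    add(0, depth)
    n = len(parents)
    assert n == 2 ** depth
    parent = np.asarray(parents, dtype=np.int64)
    length, diam, soma = _geometry(n, soma_length, soma_diam, seg_length, seg_diam)
    branch_of = np.arange(n, dtype=np.int64)  # every segment its own section
    return Morphology(parent, length, diam, np.full(n, mech, "U8"),
                      is_soma=soma, branch_of=branch_of)


def make_random_tree(n_segments: int, rng, *, cable_bias: float = 0.7,
                     mech: str = "hh") -> Morphology:
    """Random Hines tree for solver stress tests.

    With probability ``cable_bias`` a new segment extends the previous one
    (cable-like runs); otherwise it attaches to a uniformly chosen earlier
    segment, creating junctions.  Geometry is drawn from physiological
    ranges (length 5-50 um, diameter 0.5-5 um); mechanism tags are drawn
    uniformly when ``mech`` is ``"mixed"``.
    """
    if n_segments < 1:
        raise MorphologyError("n_segments must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    parent = np.empty(n_segments, dtype=np.int64)
    parent[0] = ROOT
    for i in range(1, n_segments):
        if i == 1 or rng.random() < cable_bias:
            parent[i] = i - 1
        else:
            parent[i] = rng.integers(0, i)
    length = rng.uniform(5.0, 50.0, n_segments)
    diam = rng.uniform(0.5, 5.0, n_segments)
    if mech == "mixed":
        tags = rng.choice(MECHANISMS, n_segments)
    else:
        tags = np.full(n_segments, mech, "U8")
    soma = np.zeros(n_segments, dtype=bool)
    soma[0] = True
    return Morphology(parent, length, diam, tags, is_soma=soma)


# ----------------------------------------------------------------------
# file formats
# ----------------------------------------------------------------------

def read_swc(path, *, mech: str = "hh") -> Morphology:
    """Read a standard 7-column SWC file (id type x y z radius parent).

    One SWC sample becomes one compartment: diameter ``2 * radius``, length
    the 3-D distance to the parent sample.  The root sample (parent -1) has
    no parent edge and is given a stub compartment of length ``2 * radius``
    (sphere-as-cylinder convention).  Samples may reference parents that
    appear later in the file; the result is passed through Hines ordering.
    Somatic segments are those with SWC type 1 (or the root if none).
    """
    ids, types, xyz, radii, parents_raw, lines = [], [], [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            cols = text.split()
            if len(cols) != 7:
                raise MorphologyError(f"{path}:{lineno}: expected 7 columns, got {len(cols)}")
            try:
                sid = int(cols[0]); stype = int(cols[1])
                x, y, z, r = (float(c) for c in cols[2:6])
                pid = int(cols[6])
            except ValueError as exc:
                raise MorphologyError(f"{path}:{lineno}: malformed field ({exc})") from None
            if r <= 0:
                raise MorphologyError(f"{path}:{lineno}: radius must be > 0")
            ids.append(sid); types.append(stype); xyz.append((x, y, z))
            radii.append(r); parents_raw.append(pid); lines.append(lineno)
    if not ids:
        raise MorphologyError(f"{path}: no samples")
    if len(set(ids)) != len(ids):
        raise MorphologyError(f"{path}: duplicate sample ids")
    index = {sid: k for k, sid in enumerate(ids)}
    n = len(ids)
    parent = np.empty(n, dtype=np.int64)
    length = np.empty(n, dtype=np.float64)
    diam = 2.0 * np.asarray(radii)
    pts = np.asarray(xyz)
    for k in range(n):
        pid = parents_raw[k]
        if pid == -1:
            parent[k] = ROOT
            length[k] = 2.0 * radii[k]  # root stub
            continue
        if pid not in index:
            raise MorphologyError(f"{path}:{lines[k]}: unknown parent id {pid}")
        parent[k] = index[pid]
        length[k] = float(np.linalg.norm(pts[k] - pts[parent[k]]))
        if length[k] <= 0:
            raise MorphologyError(
                f"{path}:{lines[k]}: zero-length segment (coincident with parent)")
    roots = np.flatnonzero(parent == ROOT)
    if roots.size != 1:
        raise MorphologyError(f"{path}: need exactly one root sample, found {roots.size}")
    # reachability check so cycle errors can name a line
    reached = np.zeros(n, dtype=bool)
    stack = [int(roots[0])]
    kids = [[] for _ in range(n)]
    for k in range(n):
        if parent[k] != ROOT:
            kids[parent[k]].append(k)
    while stack:
        node = stack.pop()
        reached[node] = True
        stack.extend(kids[node])
    if not reached.all():
        bad = int(np.flatnonzero(~reached)[0])
        raise MorphologyError(
            f"{path}:{lines[bad]}: sample id {ids[bad]} lies on a cycle or "
            "disconnected subtree")
    soma = np.asarray(types) == 1
    if not soma.any():
        soma = parent == ROOT
    return from_unordered(parent, length, diam,
                          np.full(n, mech, "U8"), is_soma=soma)


TOPOLOGY_HEADER = "#index parent length_um diam_um mech"


def read_topology(path) -> Morphology:
    """Read the plain-text topology table dialect.

    Header line ``#index parent length_um diam_um mech``; whitespace-separated
    rows; 0-based indices; root parent ``-1``.
    """
    idx, par, length, diam, mech = [], [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            cols = text.split()
            if len(cols) != 5:
                raise MorphologyError(f"{path}:{lineno}: expected 5 columns, got {len(cols)}")
            try:
                idx.append(int(cols[0])); par.append(int(cols[1]))
                length.append(float(cols[2])); diam.append(float(cols[3]))
            except ValueError as exc:
                raise MorphologyError(f"{path}:{lineno}: malformed field ({exc})") from None
            mech.append(cols[4])
    if not idx:
        raise MorphologyError(f"{path}: empty topology table")
    n = len(idx)
    if sorted(idx) != list(range(n)):
        raise MorphologyError(f"{path}: indices must be 0..{n - 1} exactly")
    order = np.argsort(idx)
    return from_unordered(np.asarray(par)[order], np.asarray(length)[order],
                          np.asarray(diam)[order], np.asarray(mech)[order])


def write_topology(m: Morphology, path) -> None:
    with open(path, "w") as fh:
        fh.write(TOPOLOGY_HEADER + "\n")
        for i in range(m.n_segments):
            fh.write(f"{i} {m.parent[i]} {m.length_um[i]:.9g} "
                     f"{m.diam_um[i]:.9g} {m.mech_tag[i]}\n")
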