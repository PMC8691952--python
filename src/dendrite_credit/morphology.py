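"""Neuronal morphologies: SWC reading, repair, and compartmentalization.

A reconstructed morphology (SWC point list) is turned into a compartmental
:class:`Geometry`: the detailed axon is discarded, soma and axon hillock are
lumped into a single isopotential spherical compartment of radius 10 um, and
every dendritic branch (path between branch points / terminals) is split into
at least two equal-length cylinders no longer than 10 um.  Axial coupling
between compartments is summarized by the matrix ``G`` whose action on the
voltage vector gives the axial term of the cable equation in mV/ms (i.e. the
raw inter-compartment conductances are normalized by compartment capacitance).

Units: um for lengths/radii, Ohm*cm for axial resistivity, uF/cm^2 for
specific capacitance, cm^2 for areas, uS for conductances, nF for capacitance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

# SWC structure labels
SWC_SOMA, SWC_AXON, SWC_BASAL, SWC_APICAL = 1, 2, 3, 4

# Geometry domain codes
DOMAIN_SOMA, DOMAIN_BASAL, DOMAIN_APICAL = 0, 1, 2
DOMAIN_NAMES = {DOMAIN_SOMA: "soma", DOMAIN_BASAL: "basal", DOMAIN_APICAL: "apical"}

SOMA_RADIUS_UM = 10.0  # lumped axo-somatic compartment
MAX_COMP_LENGTH_UM = 10.0


class SWCParseError(ValueError):
    """Malformed SWC record."""


class StructureError(ValueError):
    """Morphology violates tree-structure requirements."""


@dataclass
class RawMorphology:
    """SWC point set: one sample per row, tree-structured via parent ids."""

    ids: np.ndarray        # (n,) int
    labels: np.ndarray     # (n,) int, SWC structure type
    xyz: np.ndarray        # (n, 3) float, um
    radius: np.ndarray     # (n,) float, um
    parent: np.ndarray     # (n,) int, SWC parent id (-1 for root)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.xyz = np.asarray(self.xyz, dtype=np.float64)
        self.radius = np.asarray(self.radius, dtype=np.float64)
        self.parent = np.asarray(self.parent, dtype=np.int64)

    @property
    def n_points(self) -> int:
        return len(self.ids)

    def index_of(self) -> dict[int, int]:
        """Map SWC id -> row index."""
        return {int(i): k for k, i in enumerate(self.ids)}

    def parent_index(self) -> np.ndarray:
        """Parent row index per point (-1 for the root)."""
        idx = self.index_of()
        out = np.empty(self.n_points, dtype=np.int64)
        for k, p in enumerate(self.parent):
            out[k] = -1 if p == -1 else idx[int(p)]
        return out

    def children(self) -> list[list[int]]:
        kids: list[list[int]] = [[] for _ in range(self.n_points)]
        for k, p in enumerate(self.parent_index()):
            if p >= 0:
                kids[p].append(k)
        return kids

    def validate(self) -> None:
        roots = np.flatnonzero(self.parent == -1)
        if len(roots) != 1:
            raise StructureError(f"expected exactly one root, found {len(roots)}")
        if np.any(self.radius <= 0):
            raise StructureError("all radii must be positive")
        # parent-before-child ordering guarantees acyclicity
        seen: set[int] = set()
        for k in range(self.n_points):
            p = int(self.parent[k])
            if p != -1 and p not in seen:
                raise SWCParseError(
                    f"point id {int(self.ids[k])}: parent {p} not declared before child"
                )
            seen.add(int(self.ids[k]))


def load_swc(path) -> RawMorphology:
    """Read a 7-column SWC file into a :class:`RawMorphology`.

    Dialect: '#' comments, whitespace-delimited records
    ``id label x y z radius parent``; a parent must be declared before its
    children (single forward pass), and exactly one point is the root
    (parent ``-1``).

    Raises
    ------
    SWCParseError
        On a malformed record (the error names the offending line) or a
        forward parent reference.
    StructureError
        If the point set is not a single tree.
    """
    ids, labels, xyz, radius, parent = [], [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            fields = text.split()
            if len(fields) != 7:
                raise SWCParseError(
                    f"line {lineno}: expected 7 fields, got {len(fields)}"
                )
            try:
                ids.append(int(fields[0]))
                labels.append(int(fields[1]))
                xyz.append([float(fields[2]), float(fields[3]), float(fields[4])])
                radius.append(float(fields[5]))
                parent.append(int(fields[6]))
            except ValueError as err:
                raise SWCParseError(f"line {lineno}: {err}") from None
    if not ids:
        raise SWCParseError(f"{path}: no records")
    raw = RawMorphology(
        ids=np.array(ids), labels=np.array(labels), xyz=np.array(xyz),
        radius=np.array(radius), parent=np.array(parent),
    )
    raw.validate()
    return raw


# ---------------------------------------------------------------------------
# branch decomposition over raw points

def _dendrite_branches(raw: RawMorphology) -> list[list[int]]:
    """Paths of dendritic point indices between branch points / terminals.

    Each branch is a list of point indices; the attachment point (soma point
    or the branch point terminating the parent branch) is *not* included but
    is recoverable via the first point's parent.
    """
    pidx = raw.parent_index()
    kids = raw.children()
    dendritic = np.isin(raw.labels, (SWC_BASAL, SWC_APICAL))

    def n_dendritic_children(k: int) -> int:
        return sum(1 for c in kids[k] if dendritic[c])

    starts = [
        k for k in range(raw.n_points)
        if dendritic[k] and (pidx[k] < 0 or not dendritic[pidx[k]]
                             or n_dendritic_children(pidx[k]) >= 2)
    ]
    branches = []
    for s in starts:
        path = [s]
        k = s
        while n_dendritic_children(k) == 1:
            k = next(c for c in kids[k] if dendritic[c])
            path.append(k)
        branches.append(path)
    return branches


def preprocess(raw: RawMorphology, smooth_window: int = 3,
               pinch_factor: float = 0.25) -> RawMorphology:
    """Repair pinched dendritic sections and smooth branch diameter profiles.

    A point whose radius falls below ``pinch_factor`` times the mean of its
    two flanking radii (within a branch) is treated as a reconstruction
    artifact and replaced by linear interpolation of the flanking radii.
    Each branch's radius profile is then smoothed with a replicate-padded
    moving average of ``smooth_window`` points.  Topology is unchanged.
    """
    if smooth_window < 1:
        raise ValueError("smooth_window must be >= 1")
    raw.validate()
    radius = raw.radius.copy()
    for path in _dendrite_branches(raw):
        r = radius[path].copy()
        # pinch repair (interior points only)
        for i in range(1, len(r) - 1):
            flank = 0.5 * (r[i - 1] + r[i + 1])
            if r[i] < pinch_factor * flank:
                r[i] = flank
        # replicate-padded moving average
        if smooth_window > 1 and len(r) > 1:
            half = smooth_window // 2
            padded = np.concatenate([np.full(half, r[0]), r, np.full(half, r[-1])])
            kernel = np.ones(smooth_window) / smooth_window
            r = np.convolve(padded, kernel, mode="valid")[: len(r)]
        radius[path] = r
    return RawMorphology(
        ids=raw.ids.copy(), labels=raw.labels.copy(), xyz=raw.xyz.copy(),
        radius=radius, parent=raw.parent.copy(),
    )


# ---------------------------------------------------------------------------
# compartmental geometry

@dataclass
class Geometry:
    """Compartmentalized tree.

    Compartment 0 is the lumped axo-somatic sphere; all others are dendritic
    cylinders ordered so that ``parent[i] < i``.  ``G`` is the axial coupling
    matrix normalized by compartment capacitance (units ms^-1: ``G @ v`` is
    the axial contribution to dv/dt in mV/ms); ``g_pair[i]`` is the raw axial
    conductance (uS) between compartment ``i`` and its parent.
    """

    length: np.ndarray      # um
    radius: np.ndarray      # um
    area: np.ndarray        # cm^2 (lateral for cylinders, full sphere for soma)
    parent: np.ndarray      # int, -1 for compartment 0
    branch_id: np.ndarray   # int, 0 for soma, 1..B for dendritic branches
    domain: np.ndarray      # int codes DOMAIN_*
    g_pair: np.ndarray      # uS, axial conductance to parent (0 for root)
    r_a: float = 150.0      # Ohm*cm
    c_m: float = 1.0        # uF/cm^2
    G: sp.csr_matrix = field(default=None, repr=False)
    soma_index: int = 0

    def __post_init__(self) -> None:
        if self.G is None:
            self.G = axial_matrix(self, self.r_a, self.c_m)

    @property
    def n_comp(self) -> int:
        return len(self.length)

    @property
    def capacitance(self) -> np.ndarray:
        """Per-compartment capacitance, nF."""
        return 1e3 * self.c_m * self.area

    def children(self) -> list[list[int]]:
        kids: list[list[int]] = [[] for _ in range(self.n_comp)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                kids[p].append(i)
        return kids

    def dendritic_mask(self) -> np.ndarray:
        return self.domain != DOMAIN_SOMA

    def branch_compartments(self) -> dict[int, np.ndarray]:
        """Compartment indices per dendritic branch id."""
        out: dict[int, np.ndarray] = {}
        for b in np.unique(self.branch_id):
            if b == 0:
                continue
            out[int(b)] = np.flatnonzero(self.branch_id == b)
        return out

    def root_branches(self, domain: int) -> list[int]:
        """Branch ids of the given domain whose first compartment attaches to the soma."""
        out = []
        for b, comps in self.branch_compartments().items():
            first = comps.min()
            if self.domain[first] == domain and self.parent[first] == self.soma_index:
                out.append(b)
        return sorted(out)

    def root_branch_of(self) -> np.ndarray:
        """For each compartment, the first-order branch id of its subtree (0 at soma)."""
        out = np.zeros(self.n_comp, dtype=np.int64)
        for i in range(1, self.n_comp):
            p = self.parent[i]
            out[i] = self.branch_id[i] if p == self.soma_index else out[p]
        return out

    def path_distance(self) -> np.ndarray:
        """Path distance (um) from the soma surface to each compartment midpoint."""
        dist = np.zeros(self.n_comp)
        for i in range(1, self.n_comp):
            p = self.parent[i]
            base = 0.0 if p == self.soma_index else dist[p] + self.length[p] / 2.0
            dist[i] = base + self.length[i] / 2.0
        return dist


def _half_resistance_mohm(length_um: float, radius_um: float, r_a: float) -> float:
    """Axial resistance of half a cylinder, MOhm."""
    return 0.01 * r_a * (length_um / 2.0) / (math.pi * radius_um**2)


def axial_matrix(geom: Geometry, r_a: float | None = None,
                 c_m: float | None = None) -> sp.csr_matrix:
    """Capacitance-normalized axial coupling matrix.

    Neighbor entries are built from half-compartment series resistances
    (standard compartmental coupling); the lumped somatic sphere contributes
    no internal series resistance.  Rows sum to zero, so a uniform voltage
    produces no axial current, and ``area_i * G_ij == area_j * G_ji`` for
    neighbor pairs (symmetric raw conductance).
    """
    r_a = geom.r_a if r_a is None else r_a
    c_m = geom.c_m if c_m is None else c_m
    if r_a <= 0 or c_m <= 0:
        raise ValueError("r_a and c_m must be positive")
    n = geom.n_comp
    cap = 1e3 * c_m * geom.area  # nF
    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for i in range(1, n):
        p = int(geom.parent[i])
        if p < 0:
            raise StructureError(f"compartment {i} is disconnected")
        g = geom.g_pair[i]
        rows += [i, p]
        cols += [p, i]
        vals += [g / cap[i], g / cap[p]]
        diag[i] -= g / cap[i]
        diag[p] -= g / cap[p]
    rows += list(range(n))
    cols += list(range(n))
    vals += list(diag)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def _compute_g_pair(length, radius, parent, r_a, soma_index=0,
                    soma_is_sphere=True) -> np.ndarray:
    n = len(length)
    g = np.zeros(n)
    for i in range(1, n):
        p = int(parent[i])
        r_half = _half_resistance_mohm(length[i], radius[i], r_a)
        if not (soma_is_sphere and p == soma_index):
            r_half += _half_resistance_mohm(length[p], radius[p], r_a)
        g[i] = 1.0 / r_half
    return g


def discretize(raw: RawMorphology, r_a: float = 150.0, c_m: float = 1.0) -> Geometry:
    """Compartmentalize a (preprocessed) morphology.

    The detailed axon is removed and soma + axon are replaced by a single
    isopotential sphere of radius 10 um (compartment 0).  Each dendritic
    branch of length L is split into ``max(2, ceil(L / 10 um))`` equal-length
    cylinders whose radii are read off the piecewise-linear radius profile at
    compartment midpoints.
    """
    raw.validate()
    pidx = raw.parent_index()
    branches = _dendrite_branches(raw)

    length = [2.0 * SOMA_RADIUS_UM]
    radius = [SOMA_RADIUS_UM]
    area = [4.0 * math.pi * (SOMA_RADIUS_UM * 1e-4) ** 2]
    parent = [-1]
    branch_id = [0]
    domain = [DOMAIN_SOMA]

    # map: raw point index -> compartment index of the compartment that
    # contains the branch's distal end (used to attach child branches)
    end_comp: dict[int, int] = {}
    soma_points = set(np.flatnonzero(raw.labels == SWC_SOMA))

    # process branches in an order where parents come first
    remaining = list(branches)
    b_id = 0
    progressed = True
    while remaining and progressed:
        progressed = False
        still = []
        for path in remaining:
            attach_pt = pidx[path[0]]
            if attach_pt < 0 or attach_pt in soma_points:
                parent_comp = 0
                start_xyz = raw.xyz[attach_pt] if attach_pt >= 0 else raw.xyz[path[0]]
                start_r = raw.radius[path[0]]
            elif attach_pt in end_comp:
                parent_comp = end_comp[attach_pt]
                start_xyz = raw.xyz[attach_pt]
                start_r = raw.radius[attach_pt]
            else:
                still.append(path)
                continue
            progressed = True
            b_id += 1
            dom = DOMAIN_BASAL if raw.labels[path[0]] == SWC_BASAL else DOMAIN_APICAL

            # arclength profile along attachment point + branch points
            pts = np.vstack([start_xyz, raw.xyz[path]])
            rads = np.concatenate([[start_r], raw.radius[path]])
            seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            arc = np.concatenate([[0.0], np.cumsum(seg)])
            total = arc[-1]
            if total <= 0:
                raise StructureError(
                    f"branch starting at point id {int(raw.ids[path[0]])} has zero length"
                )
            n_sub = max(2, math.ceil(total / MAX_COMP_LENGTH_UM))
            sub_len = total / n_sub
            mids = (np.arange(n_sub) + 0.5) * sub_len
            sub_rad = np.interp(mids, arc, rads)
            prev = parent_comp
            for k in range(n_sub):
                idx = len(length)
                length.append(sub_len)
                radius.append(float(sub_rad[k]))
                area.append(2.0 * math.pi * sub_rad[k] * sub_len * 1e-8)
                parent.append(prev)
                branch_id.append(b_id)
                domain.append(dom)
                prev = idx
            end_comp[path[-1]] = prev
        remaining = still
    if remaining:
        raise StructureError("could not order branches (disconnected dendrite?)")

    length = np.array(length)
    radius = np.array(radius)
    parent = np.array(parent, dtype=np.int64)
    g_pair = _compute_g_pair(length, radius, parent, r_a)
    return Geometry(
        length=length, radius=radius, area=np.array(area), parent=parent,
        branch_id=np.array(branch_id, dtype=np.int64),
        domain=np.array(domain, dtype=np.int64),
        g_pair=g_pair, r_a=r_a, c_m=c_m,
    )


# ---------------------------------------------------------------------------
# synthetic fixtures

def synthetic_tree(n_basal: int, n_apical: int, depth: int = 1, seed: int = 0,
                   r_a: float = 150.0, c_m: float = 1.0) -> Geometry:
    """Deterministic-by-seed branched fixture with basal and apical subtrees.

    ``n_basal``/``n_apical`` count *terminal* branches per domain; internal
    branches bifurcate so that terminals sit at the requested branching
    ``depth``.  Branch lengths are uniform in [40, 120] um and radii taper
    linearly from 1.0 um at the soma to 0.3 um at the tips.
    """
    if n_basal < 1 or n_apical < 1 or depth < 1:
        raise ValueError("counts and depth must be >= 1")
    rng = np.random.default_rng(seed)

    ids = [1]
    labels = [SWC_SOMA]
    xyz = [np.zeros(3)]
    radius = [SOMA_RADIUS_UM]
    parent = [-1]

    def add_point(label, pos, r, par_id):
        pid = len(ids) + 1
        ids.append(pid)
        labels.append(label)
        xyz.append(pos)
        radius.append(r)
        parent.append(par_id)
        return pid

    def taper(level: float) -> float:
        # linear taper from 1.0 um at the soma to 0.3 um at terminal tips
        return 1.0 + (0.3 - 1.0) * level / depth

    def grow(label, par_id, par_pos, direction, level, n_terminals):
        """Grow a subtree with the given number of terminal branches."""
        L = rng.uniform(40.0, 120.0)
        d = direction + rng.normal(scale=0.3, size=3)
        d /= np.linalg.norm(d)
        # two sample points per branch so the radius profile tapers within it
        prox = par_pos + 0.25 * L * d
        end = par_pos + L * d
        pid_prox = add_point(label, prox, taper(level - 1 + 0.25), par_id)
        pid = add_point(label, end, taper(level), pid_prox)
        if level >= depth or n_terminals <= 1:
            return
        left = n_terminals // 2
        grow(label, pid, end, d, level + 1, left)
        grow(label, pid, end, d, level + 1, n_terminals - left)

    def grow_domain(label, n_term, base_dir):
        n_roots = max(1, math.ceil(n_term / 2 ** (depth - 1)))
        per_root = [n_term // n_roots] * n_roots
        for k in range(n_term - sum(per_root)):
            per_root[k] += 1
        for k in range(n_roots):
            if per_root[k] == 0:
                continue
            angle = 2 * math.pi * k / n_roots
            direction = np.array([
                math.cos(angle), base_dir, math.sin(angle)
            ])
            direction /= np.linalg.norm(direction)
            grow(label, 1, np.zeros(3), direction, 1, per_root[k])

    grow_domain(SWC_BASAL, n_basal, -1.0)
    grow_domain(SWC_APICAL, n_apical, +1.0)

    raw = RawMorphology(
        ids=np.array(ids), labels=np.array(labels), xyz=np.array(xyz),
        radius=np.array(radius), parent=np.array(parent),
    )
    return discretize(raw, r_a=r_a, c_m=c_m)


def uniform_cable(n_comp: int, total_length: float, radius: float,
                  r_a: float = 150.0, c_m: float = 1.0) -> Geometry:
    """Sealed uniform unbranched cable (no somatic sphere).

    A test utility for comparison against closed-form cable theory; it
    deliberately has no lumped soma, so it does not satisfy the full-neuron
    geometry conventions (compartment 0 is simply the proximal cable end).
    """
    n = int(n_comp)
    length = np.full(n, total_length / n)
    rad = np.full(n, float(radius))
    area = 2.0 * math.pi * rad * length * 1e-8
    parent = np.arange(-1, n - 1, dtype=np.int64)
    g_pair = _compute_g_pair(length, rad, parent, r_a, soma_is_sphere=False)
    return Geometry(
        length=length, radius=rad, area=area, parent=parent,
        branch_id=np.ones(n, dtype=np.int64),
        domain=np.full(n, DOMAIN_BASAL, dtype=np.int64),
        g_pair=g_pair, r_a=r_a, c_m=c_m,
    )


# ---------------------------------------------------------------------------
# snapshots

def geometry_to_dict(geom: Geometry) -> dict:
    gcoo = geom.G.tocoo()
    return {
        "length": geom.length.tolist(),
        "radius": geom.radius.tolist(),
        "area": geom.area.tolist(),
        "parent": geom.parent.tolist(),
        "branch_id": geom.branch_id.tolist(),
        "domain": geom.domain.tolist(),
        "g_pair": geom.g_pair.tolist(),
        "r_a": geom.r_a,
        "c_m": geom.c_m,
        "G": {"row": gcoo.row.tolist(), "col": gcoo.col.tolist(),
              "data": gcoo.data.tolist(), "shape": list(gcoo.shape)},
    }


def geometry_from_dict(d: dict) -> Geometry:
    g = d["G"]
    G = sp.csr_matrix((g["data"], (g["row"], g["col"])), shape=tuple(g["shape"]))
    return Geometry(
        length=np.array(d["length"]), radius=np.array(d["radius"]),
        area=np.array(d["area"]), parent=np.array(d["parent"], dtype=np.int64),
        branch_id=np.array(d["branch_id"], dtype=np.int64),
        domain=np.array(d["domain"], dtype=np.int64),
        g_pair=np.array(d["g_pair"]), r_a=d["r_a"], c_m=d["c_m"], G=G,
    )


def save_geometry(geom: Geometry, path) -> None:
    import json
    with open(path, "w") as fh:
        json.dump(geometry_to_dict(geom), fh)


def load_geometry(path) -> Geometry:
    import json
    with open(path) as fh:
        return geometry_from_dict(json.load(fh))
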