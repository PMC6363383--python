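"""Neuron morphologies: SWC I/O, dendritic metrics and synthetic generators.

A :class:`Morphology` is a rooted tree of 3-D points with radii and region
labels (soma, axon initial segment, myelinated axon, basal/apical dendrite).
Morphologies are read and written as 7-column SWC (``id type x y z radius
parent``, 1-based ids, ``#`` comments).  SWC type code 2 is interpreted as
unmyelinated axon (AIS) and type 6 as myelinated axon so that the axonal
region split survives a round trip; types 1/3/4 carry their conventional
soma/basal/apical meaning.

The module also provides the two synthetic generators used throughout the
package: a single-cable "ball and stick" cell and a seeded random branched
tree calibrated to human temporal-cortex pyramidal cells (total dendritic
length ~14.7 mm, ~64 branch points).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import IntEnum

import numpy as np

__all__ = [
    "Region",
    "Morphology",
    "SyntheticTreeSpec",
    "SWCParseError",
    "MorphologyError",
    "GenerationError",
    "read_swc",
    "write_swc",
    "total_dendritic_length",
    "count_branch_points",
    "generate_ball_and_stick",
    "generate_branched_tree",
    "attach_axon",
]


class SWCParseError(ValueError):
    """Malformed SWC line (message carries the 1-based line number)."""


class MorphologyError(ValueError):
    """Structural problem: dangling parent, cycle, multiple roots, bad radii."""


class GenerationError(ValueError):
    """Synthetic-tree request that cannot be satisfied."""


class Region(IntEnum):
    """Region labels; values double as the on-disk SWC type codes."""

    SOMA = 1
    AXON_AIS = 2
    BASAL_DENDRITE = 3
    APICAL_DENDRITE = 4
    AXON_MYELIN = 6


DENDRITE_REGIONS = (Region.BASAL_DENDRITE, Region.APICAL_DENDRITE)
AXON_REGIONS = (Region.AXON_AIS, Region.AXON_MYELIN)


@dataclass
class Morphology:
    """Rooted tree of 3-D sample points.

    Nodes are stored in canonical order: the root (``parent == -1``) is node
    0 and every child index is greater than its parent index, so a single
    forward pass visits parents before children.

    Attributes
    ----------
    region : (n,) int array of :class:`Region` codes
    xyz : (n, 3) float array, µm
    radius : (n,) float array, µm
    parent : (n,) int array; -1 marks the root
    """

    region: np.ndarray
    xyz: np.ndarray
    radius: np.ndarray
    parent: np.ndarray

    def __post_init__(self) -> None:
        self.region = np.asarray(self.region, dtype=np.int64)
        self.xyz = np.asarray(self.xyz, dtype=np.float64)
        self.radius = np.asarray(self.radius, dtype=np.float64)
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.validate()

    @property
    def n_nodes(self) -> int:
        return len(self.radius)

    def validate(self) -> None:
        n = self.n_nodes
        if self.xyz.shape != (n, 3) or self.region.shape != (n,) or self.parent.shape != (n,):
            raise MorphologyError("inconsistent node-array shapes")
        roots = np.flatnonzero(self.parent == -1)
        if len(roots) != 1 or roots[0] != 0:
            raise MorphologyError(f"expected exactly one root at index 0, found roots {roots}")
        if np.any(self.parent[1:] >= np.arange(1, n)) or np.any(self.parent[1:] < 0):
            raise MorphologyError("nodes are not in canonical parent-before-child order")
        if np.any(self.radius <= 0):
            raise MorphologyError("all radii must be positive")
        if self.region[0] != Region.SOMA:
            raise MorphologyError("root node must be soma")
        # soma nodes must form a connected subtree containing the root
        soma = self.region == Region.SOMA
        bad = soma[1:] & ~soma[self.parent[1:]]
        if np.any(bad):
            raise MorphologyError("soma nodes must form a connected subtree at the root")
        for code in np.unique(self.region):
            if code not in Region._value2member_map_:
                raise MorphologyError(f"unknown region code {code}")

    def children(self) -> list[list[int]]:
        """Child index lists, parallel to the node arrays."""
        out: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in range(1, self.n_nodes):
            out[self.parent[i]].append(i)
        return out

    def edge_lengths(self) -> np.ndarray:
        """Euclidean length of the edge above each node (0 for the root)."""
        out = np.zeros(self.n_nodes)
        d = self.xyz[1:] - self.xyz[self.parent[1:]]
        out[1:] = np.linalg.norm(d, axis=1)
        return out

    def translated(self, offset) -> "Morphology":
        return replace(self, xyz=self.xyz + np.asarray(offset, dtype=float))

    def rotated(self, rotation_matrix) -> "Morphology":
        rm = np.asarray(rotation_matrix, dtype=float)
        return replace(self, xyz=self.xyz @ rm.T)


# ---------------------------------------------------------------------------
# SWC I/O


def read_swc(path) -> Morphology:
    """Read a 7-column SWC file.

    Raises
    ------
    SWCParseError
        for malformed records (message names the offending line).
    MorphologyError
        for dangling parent references, cycles or multiple roots.
    """
    records: dict[int, tuple[int, float, float, float, float, int]] = {}
    order: list[int] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SWCParseError(f"line {lineno}: expected 7 columns, got {len(parts)}")
            try:
                nid = int(parts[0])
                typ = int(parts[1])
                x, y, z, r = (float(p) for p in parts[2:6])
                par = int(parts[6])
            except ValueError as exc:
                raise SWCParseError(f"line {lineno}: {exc}") from None
            if nid in records:
                raise SWCParseError(f"line {lineno}: duplicate node id {nid}")
            records[nid] = (typ, x, y, z, r, par)
            order.append(nid)
    if not records:
        raise SWCParseError("empty SWC file")

    roots = [nid for nid in order if records[nid][5] == -1]
    if len(roots) != 1:
        raise MorphologyError(f"expected exactly one root, found {len(roots)}")
    for nid in order:
        par = records[nid][5]
        if par != -1 and par not in records:
            raise MorphologyError(f"node {nid} references undeclared parent {par}")

    # connectivity / cycle check by BFS from the root
    children: dict[int, list[int]] = {nid: [] for nid in order}
    for nid in order:
        par = records[nid][5]
        if par != -1:
            children[par].append(nid)
    reached = set()
    queue = [roots[0]]
    while queue:
        nid = queue.pop(0)
        reached.add(nid)
        queue.extend(children[nid])
    if len(reached) != len(records):
        raise MorphologyError("morphology is not a connected tree (cycle or orphan subtree)")

    # canonical renumbering: keep the file order when it already lists
    # parents before children (so write/read round-trips are lossless),
    # otherwise fall back to BFS order
    pos = {nid: i for i, nid in enumerate(order)}
    file_order_ok = order[0] == roots[0] and all(
        records[nid][5] == -1 or pos[records[nid][5]] < pos[nid] for nid in order
    )
    if file_order_ok:
        new_index = pos
    else:
        new_index = {}
        queue = [roots[0]]
        while queue:
            nid = queue.pop(0)
            new_index[nid] = len(new_index)
            queue.extend(children[nid])

    n = len(records)
    region = np.empty(n, dtype=np.int64)
    xyz = np.empty((n, 3))
    radius = np.empty(n)
    parent = np.empty(n, dtype=np.int64)
    for nid, idx in new_index.items():
        typ, x, y, z, r, par = records[nid]
        region[idx] = typ
        xyz[idx] = (x, y, z)
        radius[idx] = r
        parent[idx] = -1 if par == -1 else new_index[par]
    return Morphology(region=region, xyz=xyz, radius=radius, parent=parent)


def write_swc(m: Morphology, path) -> None:
    """Write ``m`` with 1-based sequential ids; full float precision."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# SWC written by dendrogain (id type x y z radius parent)\n")
        for i in range(m.n_nodes):
            par = -1 if m.parent[i] == -1 else m.parent[i] + 1
            x, y, z = m.xyz[i]
            fh.write(
                f"{i + 1} {int(m.region[i])} {x:.17g} {y:.17g} {z:.17g} "
                f"{m.radius[i]:.17g} {par}\n"
            )


# ---------------------------------------------------------------------------
# Metrics


def total_dendritic_length(m: Morphology) -> float:
    """Total dendritic length (TDL, µm): summed edge lengths over edges whose
    child node is basal or apical dendrite.  Axon and soma are excluded."""
    lengths = m.edge_lengths()
    dend = np.isin(m.region, DENDRITE_REGIONS)
    return float(lengths[dend].sum())


def count_branch_points(m: Morphology) -> int:
    """Number of dendritic nodes with at least two dendritic children."""
    dend = np.isin(m.region, DENDRITE_REGIONS)
    counts = np.zeros(m.n_nodes, dtype=int)
    child = np.arange(1, m.n_nodes)[dend[1:]]
    np.add.at(counts, m.parent[child], 1)
    return int(np.sum((counts >= 2) & dend))


# ---------------------------------------------------------------------------
# Generators


def generate_ball_and_stick(
    tdl: float, dendrite_diameter: float = 2.5, soma_diameter: float = 20.0
) -> Morphology:
    """Soma plus a single unbranched apical cable of total length ``tdl`` µm.

    The soma is a single sample point of radius ``soma_diameter / 2``
    (interpreted downstream as a cylinder with length equal to its
    diameter).  Cable nodes are spaced at most 250 µm apart so the
    piecewise-linear path length equals ``tdl`` to machine precision.
    """
    if tdl <= 0 or dendrite_diameter <= 0 or soma_diameter <= 0:
        raise GenerationError("tdl, dendrite_diameter and soma_diameter must be positive")
    n_seg = max(1, math.ceil(tdl / 250.0))
    ys = np.linspace(0.0, tdl, n_seg + 1)[1:]
    n = 1 + n_seg
    region = np.full(n, int(Region.APICAL_DENDRITE), dtype=np.int64)
    region[0] = int(Region.SOMA)
    xyz = np.zeros((n, 3))
    xyz[1:, 1] = ys
    radius = np.full(n, dendrite_diameter / 2.0)
    radius[0] = soma_diameter / 2.0
    parent = np.arange(-1, n - 1, dtype=np.int64)
    return Morphology(region=region, xyz=xyz, radius=radius, parent=parent)


@dataclass
class SyntheticTreeSpec:
    """Request for a random branched dendritic tree.

    ``target_tdl`` (µm) is met exactly (lengths are rescaled after the
    topology is drawn); ``target_branch_points`` bifurcations are produced
    exactly; ``stem_count`` primary dendrites leave the soma, the first one
    labelled apical, the rest basal.
    """

    target_tdl: float
    target_branch_points: int
    stem_count: int = 5
    diameter_taper: tuple[float, float] = (2.5, 0.8)  # (stem diameter µm, per-branch ratio)
    seed: int = 0
    soma_diameter: float = 20.0

    def __post_init__(self) -> None:
        if self.target_tdl <= 0:
            raise GenerationError("target_tdl must be positive")
        if self.target_branch_points < 0:
            raise GenerationError("target_branch_points must be >= 0")
        if self.stem_count < 1:
            raise GenerationError("stem_count must be >= 1")


def generate_branched_tree(spec: SyntheticTreeSpec) -> Morphology:
    """Grow a random binary-branching dendritic tree.

    Growth is by recursive bifurcation: starting from ``stem_count`` stems,
    a uniformly chosen terminal segment is bifurcated until exactly
    ``target_branch_points`` branch points exist.  Raw segment lengths are
    exponential draws rescaled so the measured TDL equals ``target_tdl``.
    Deterministic for a fixed seed.
    """
    n_segments = spec.stem_count + 2 * spec.target_branch_points
    mean_seg = spec.target_tdl / n_segments
    if mean_seg < 2.0:
        raise GenerationError(
            f"infeasible request: {spec.target_branch_points} branch points over "
            f"{spec.target_tdl:.0f} µm gives mean segment length {mean_seg:.2f} µm (< 2 µm)"
        )
    rng = np.random.default_rng(spec.seed)
    d0, taper = spec.diameter_taper
    if d0 <= 0 or not (0 < taper <= 1):
        raise GenerationError("diameter_taper must be (d0 > 0, 0 < ratio <= 1)")

    # topology first: segments as (parent_segment, region, raw_length, radius)
    parent_seg = [-1] * spec.stem_count
    seg_region = []
    raw_len = list(np.maximum(rng.exponential(1.0, size=n_segments), 0.05))
    seg_radius = [d0 / 2.0] * spec.stem_count
    for s in range(spec.stem_count):
        seg_region.append(Region.APICAL_DENDRITE if s == 0 else Region.BASAL_DENDRITE)
    terminals = list(range(spec.stem_count))
    for _ in range(spec.target_branch_points):
        k = int(rng.integers(len(terminals)))
        tseg = terminals.pop(k)
        for _child in range(2):
            parent_seg.append(tseg)
            seg_region.append(seg_region[tseg])
            seg_radius.append(max(seg_radius[tseg] * taper, 0.15))
            terminals.append(len(parent_seg) - 1)

    scale = spec.target_tdl / float(np.sum(raw_len[: len(parent_seg)]))
    lengths = [rl * scale for rl in raw_len[: len(parent_seg)]]

    # geometry: stems leave the soma in spread directions, the apical stem
    # along +y; children deviate from the parent direction
    stem_dirs = []
    for s in range(spec.stem_count):
        if s == 0:
            stem_dirs.append(np.array([0.0, 1.0, 0.0]))
        else:
            phi = 2 * np.pi * (s - 1) / max(spec.stem_count - 1, 1)
            v = np.array([np.cos(phi), -0.8, np.sin(phi)])
            stem_dirs.append(v / np.linalg.norm(v))

    region = [int(Region.SOMA)]
    xyz = [np.zeros(3)]
    radius = [spec.soma_diameter / 2.0]
    parent = [-1]
    seg_dir: list[np.ndarray] = [None] * len(parent_seg)  # type: ignore[list-item]
    seg_end_node: list[int] = [0] * len(parent_seg)
    for seg in range(len(parent_seg)):
        ps = parent_seg[seg]
        if ps == -1:
            direction = stem_dirs[seg]
            pnode = 0
        else:
            jitter = rng.standard_normal(3)
            jitter /= np.linalg.norm(jitter)
            direction = seg_dir[ps] + 0.9 * jitter
            direction = direction / np.linalg.norm(direction)
            pnode = seg_end_node[ps]
        seg_dir[seg] = direction
        end = xyz[pnode] + direction * lengths[seg]
        xyz.append(end)
        region.append(int(seg_region[seg]))
        radius.append(seg_radius[seg])
        parent.append(pnode)
        seg_end_node[seg] = len(xyz) - 1

    m = Morphology(
        region=np.array(region),
        xyz=np.array(xyz),
        radius=np.array(radius),
        parent=np.array(parent),
    )
    return m


def attach_axon(
    m: Morphology,
    ais_length: float = 50.0,
    myelin_length: float = 1000.0,
    diameter: float = 1.0,
) -> Morphology:
    """Append a cylindrical axon to the soma: an AIS (default 50 µm) followed
    by a myelinated section (default 1 mm), both 1 µm in diameter.

    Returns a new morphology; raises :class:`MorphologyError` if an axon is
    already present.
    """
    if np.any(np.isin(m.region, AXON_REGIONS)):
        raise MorphologyError("morphology already has an axon attached")
    root = m.xyz[0]
    ais_end = root + np.array([0.0, -ais_length, 0.0])
    myelin_end = ais_end + np.array([0.0, -myelin_length, 0.0])
    region = np.concatenate([m.region, [int(Region.AXON_AIS), int(Region.AXON_MYELIN)]])
    xyz = np.vstack([m.xyz, ais_end, myelin_end])
    radius = np.concatenate([m.radius, [diameter / 2.0, diameter / 2.0]])
    parent = np.concatenate([m.parent, [0, m.n_nodes]])
    return Morphology(region=region, xyz=xyz, radius=radius, parent=parent)
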