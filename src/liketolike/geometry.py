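"""Axon-dendrite proximity geometry.

Implements the anatomical-opportunity measurements used throughout the
analysis: skeletons are discretized so that no edge exceeds 1 um, proximal
vertex pairs are found within a 5 um closed ball, the co-travel distance Ld
is the summed length of dendritic edges touching the proximal set, and
synapses are assigned to a proximity when they fall within 3 um of any
proximal vertex.  Control cohorts (connected / ADP / same-region) are built
from the resulting pair table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "Skeleton",
    "Proximity",
    "discretize",
    "find_proximities",
    "compute_ld",
    "assign_synapses",
    "build_cohorts",
    "projection_type",
]

PROXIMITY_RADIUS_UM = 5.0
SYNAPSE_RADIUS_UM = 3.0
MAX_EDGE_UM = 1.0

#: mapping from release area labels to the coarse region used for projections
AREA_TO_REGION = {"V1": "V1", "AL": "HVA", "RL": "HVA", "HVA": "HVA"}


@dataclass
class Skeleton:
    """Piecewise-linear neuronal arbor.

    vertices are (n, 3) positions in um; edges are (m, 2) vertex indices.
    ``compartment`` is "axon" or "dendrite"; SWC type codes 2 and 3 map onto
    these on read.
    """

    vertices: np.ndarray
    edges: np.ndarray
    compartment: str = "dendrite"
    neuron_id: int | str | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        n = len(self.vertices)
        if self.edges.size:
            if self.edges.min() < 0 or self.edges.max() >= n:
                raise ValueError("edge references a vertex index out of range")
            if np.any(self.edges[:, 0] == self.edges[:, 1]):
                raise ValueError("skeleton contains a self-loop edge")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def edge_lengths(self) -> np.ndarray:
        if not self.edges.size:
            return np.zeros(0)
        d = self.vertices[self.edges[:, 0]] - self.vertices[self.edges[:, 1]]
        return np.linalg.norm(d, axis=1)

    def cable_length(self) -> float:
        return float(self.edge_lengths().sum())


@dataclass
class Proximity:
    """Merged proximity between one axon and one dendrite.

    Holds the union of proximal vertex pairs for the (pre, post) pair, the
    resulting co-travel distance Ld (um), and any assigned synapse ids.
    """

    pre_id: int | str
    post_id: int | str
    proximal_pairs: np.ndarray  # (k, 2) of (axon vertex, dendrite vertex)
    ld_um: float
    assigned_synapse_ids: set = field(default_factory=set)
    unassigned_synapse_ids: set = field(default_factory=set)

    @property
    def dendrite_vertices(self) -> np.ndarray:
        if self.proximal_pairs.size == 0:
            return np.zeros(0, dtype=int)
        return np.unique(self.proximal_pairs[:, 1])

    @property
    def axon_vertices(self) -> np.ndarray:
        if self.proximal_pairs.size == 0:
            return np.zeros(0, dtype=int)
        return np.unique(self.proximal_pairs[:, 0])


def discretize(skel: Skeleton, max_edge: float = MAX_EDGE_UM) -> Skeleton:
    """Subdivide edges so that none exceeds ``max_edge`` (um).

    Total cable length is preserved exactly up to floating point; new
    vertices lie on the original segments.  Zero-length edges are dropped
    with a warning.
    """
    if max_edge <= 0:
        raise ValueError("max_edge must be positive")
    lengths = skel.edge_lengths()
    if np.any(lengths == 0):
        warnings.warn("dropping zero-length edge(s) during discretization")
    keep = lengths > 0
    edges = skel.edges[keep]
    lengths = lengths[keep]
    if not edges.size:
        return replace(skel, edges=edges.reshape(-1, 2))
    if np.all(lengths <= max_edge):
        return replace(skel, edges=edges)

    new_vertices = [skel.vertices]
    new_edges = []
    next_idx = skel.n_vertices
    for (a, b), ln in zip(edges, lengths):
        n_seg = int(np.ceil(ln / max_edge))
        if n_seg == 1:
            new_edges.append((a, b))
            continue
        t = np.linspace(0.0, 1.0, n_seg + 1)[1:-1]
        pts = skel.vertices[a] + t[:, None] * (skel.vertices[b] - skel.vertices[a])
        idx = np.arange(next_idx, next_idx + len(pts))
        next_idx += len(pts)
        new_vertices.append(pts)
        chain = np.concatenate(([a], idx, [b]))
        new_edges.extend(zip(chain[:-1], chain[1:]))
    return replace(
        skel,
        vertices=np.vstack(new_vertices),
        edges=np.asarray(new_edges, dtype=int),
    )


def find_proximities(
    axon: Skeleton, dend: Skeleton, radius: float = PROXIMITY_RADIUS_UM
) -> np.ndarray:
    """All (axon vertex, dendrite vertex) pairs within ``radius`` (closed ball).

    Uses a KD-tree spatial query; results are identical to the brute-force
    all-pairs distance check.
    """
    if axon.n_vertices == 0 or dend.n_vertices == 0:
        return np.zeros((0, 2), dtype=int)
    tree_a = cKDTree(axon.vertices)
    tree_d = cKDTree(dend.vertices)
    pairs = []
    for ia, neigh in enumerate(tree_a.query_ball_tree(tree_d, r=radius)):
        pairs.extend((ia, jd) for jd in neigh)
    if not pairs:
        return np.zeros((0, 2), dtype=int)
    return np.asarray(sorted(pairs), dtype=int)


def compute_ld(
    axon: Skeleton, dend: Skeleton, radius: float = PROXIMITY_RADIUS_UM
) -> float:
    """Co-travel distance Ld: summed length of proximal dendritic edges.

    A dendritic edge counts (once) when at least one endpoint is a proximal
    vertex.  Skeletons are assumed already discretized.
    """
    pairs = find_proximities(axon, dend, radius=radius)
    return _ld_from_pairs(dend, pairs)


def _ld_from_pairs(dend: Skeleton, pairs: np.ndarray) -> float:
    if pairs.size == 0 or not dend.edges.size:
        return 0.0
    prox = np.zeros(dend.n_vertices, dtype=bool)
    prox[np.unique(pairs[:, 1])] = True
    touching = prox[dend.edges[:, 0]] | prox[dend.edges[:, 1]]
    return float(dend.edge_lengths()[touching].sum())


def make_proximity(
    pre_id, post_id, axon: Skeleton, dend: Skeleton, radius: float = PROXIMITY_RADIUS_UM
) -> Proximity:
    """Convenience constructor: proximal pairs plus Ld for one cell pair."""
    pairs = find_proximities(axon, dend, radius=radius)
    return Proximity(pre_id, post_id, pairs, _ld_from_pairs(dend, pairs))


def assign_synapses(
    synapses: pd.DataFrame,
    prox: Proximity,
    axon: Skeleton,
    dend: Skeleton,
    radius: float = SYNAPSE_RADIUS_UM,
) -> Proximity:
    """Assign synapses to a proximity when within ``radius`` of any proximal vertex.

    ``synapses`` needs columns synapse_id, pre_id, post_id, x_um, y_um, z_um.
    Synapses of the pair that fall farther away are flagged as unassigned.
    Rows whose pre/post ids do not match the proximity raise.
    """
    required = {"synapse_id", "pre_id", "post_id", "x_um", "y_um", "z_um"}
    missing = required - set(synapses.columns)
    if missing:
        raise ValueError(f"synapse table missing columns: {sorted(missing)}")
    mismatch = (synapses["pre_id"] != prox.pre_id) | (synapses["post_id"] != prox.post_id)
    if mismatch.any():
        raise ValueError("synapse rows do not match the proximity's pre/post ids")

    prox.assigned_synapse_ids = set()
    prox.unassigned_synapse_ids = set()
    if not len(synapses):
        return prox
    pts = synapses[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    if prox.proximal_pairs.size == 0:
        prox.unassigned_synapse_ids = set(synapses["synapse_id"])
        return prox
    cloud = np.vstack(
        [axon.vertices[prox.axon_vertices], dend.vertices[prox.dendrite_vertices]]
    )
    dist, _ = cKDTree(cloud).query(pts, k=1)
    ok = dist <= radius
    prox.assigned_synapse_ids = set(synapses["synapse_id"][ok])
    prox.unassigned_synapse_ids = set(synapses["synapse_id"][~ok])
    return prox


def projection_type(pre_area: str, post_area: str) -> str:
    """4-way projection label from release area labels (AL/RL fold into HVA)."""
    try:
        pre = AREA_TO_REGION[pre_area]
        post = AREA_TO_REGION[post_area]
    except KeyError as err:
        raise ValueError(f"unknown area label: {err.args[0]!r}") from None
    return f"{pre}->{post}"


def projection_area_layer(pre_area: str, pre_layer: str, post_area: str, post_layer: str) -> str:
    """Finer area-by-layer projection label for layer-resolved analyses."""
    return f"{AREA_TO_REGION[pre_area]}{pre_layer}->{AREA_TO_REGION[post_area]}{post_layer}"


def build_cohorts(
    presyn_id,
    neurons: pd.DataFrame,
    pairs: pd.DataFrame,
    target_region: str,
    cc_max_threshold: float = 0.4,
    cc_abs_threshold: float = 0.2,
) -> pd.DataFrame:
    """Assign each candidate neuron of one presyn to a control cohort.

    Candidates failing the functional inclusion thresholds (CCmax > 0.4 and
    CCabs > 0.2) are excluded outright.  Among the rest: connected when at
    least one synapse; ADP control when Ld > 0 with no synapse; same-region
    control when Ld = 0, no synapse, and located in ``target_region``.  A
    candidate qualifying for both controls lands in the ADP cohort (ADP
    precedence).

    ``neurons`` indexed by or carrying neuron_id with columns area, cc_max,
    cc_abs; ``pairs`` carries pre_id, post_id, ld_um, nsyn.
    """
    if "neuron_id" in neurons.columns:
        neurons = neurons.set_index("neuron_id")
    sub = pairs[pairs["pre_id"] == presyn_id]
    if not len(sub):
        raise KeyError(f"presyn {presyn_id!r} absent from pair table")
    rows = []
    for _, rec in sub.iterrows():
        cand = rec["post_id"]
        if cand not in neurons.index:
            raise KeyError(f"candidate {cand!r} absent from neuron table")
        meta = neurons.loc[cand]
        if not (meta["cc_max"] > cc_max_threshold and meta["cc_abs"] > cc_abs_threshold):
            cohort = "excluded"
        elif rec["nsyn"] >= 1:
            cohort = "connected"
        elif rec["ld_um"] > 0:
            cohort = "adp_control"
        elif AREA_TO_REGION.get(meta["area"]) == AREA_TO_REGION.get(target_region):
            cohort = "same_region_control"
        else:
            cohort = "excluded"
        rows.append({"pre_id": presyn_id, "post_id": cand, "cohort": cohort})
    return pd.DataFrame(rows)
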