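"""Unbound CDR conformational-space clustering.

Loops of one CDR type are partitioned into LRC ("Length and Residue
Configuration") groups by loop length and cis-proline positions, embedded
as 4L-dimensional vectors of (sin phi, cos phi, sin psi, cos psi) per
residue, and clustered by affinity propagation on negative squared
Euclidean distances with the preference set to the mean off-diagonal
similarity.  AP clusters whose exemplars are close in Cartesian space
(CA RMSD < 1.0 A, max CA displacement < 1.5 A, max CB displacement
< 1.9 A after fitting on loop CA atoms) are merged into canonical
clusters by connected components.

The message-passing implementation here adds no jitter to the similarity
matrix and breaks exemplar ties by lowest index, so results are exactly
reproducible for a fixed input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy.spatial.distance import squareform, pdist

from .structure import CDRLoop, CIS_OMEGA_THRESHOLD, is_cis
from .superpose import DegenerateFitError, kabsch_fit

__all__ = [
    "APCluster",
    "LRCSpace",
    "APConvergenceError",
    "CARTESIAN_THRESHOLDS",
    "assign_lrc",
    "vectorize",
    "torsion_distance",
    "similarity_matrix",
    "affinity_propagation",
    "cluster_radius",
    "cartesian_criteria",
    "merge_to_canonical",
    "cluster_lrc_group",
    "build_space",
]

#: (exemplar CA RMSD, max CA displacement, max CB displacement) in Angstrom.
CARTESIAN_THRESHOLDS = (1.0, 1.5, 1.9)


class APConvergenceError(RuntimeError):
    """Affinity propagation failed to reach a stable exemplar set."""

    def __init__(self, n_iter: int, n_points: int):
        self.n_iter = n_iter
        self.n_points = n_points
        super().__init__(
            f"affinity propagation did not converge after {n_iter} iterations "
            f"on {n_points} points"
        )


def assign_lrc(loop: CDRLoop, cis_threshold: float = CIS_OMEGA_THRESHOLD) -> str:
    """LRC group name, e.g. "L3-9-cis95" or "H2-10-allT".

    Partitions by CDR type, loop length, and the Martin positions of
    cis-proline residues (sorted ascending, comma-joined when multiple).
    """
    cis_positions = []
    for res, tor in zip(loop.residues, loop.torsions):
        if tor.omega is None:
            raise ValueError(
                f"omega undefined at {res.id} in {loop.loop_id}; "
                "loop incomplete or chain break"
            )
        if res.amino_acid == "P" and is_cis(tor.omega, cis_threshold):
            cis_positions.append(f"{res.id.number}{res.id.insertion}")
    tag = "cis" + ",".join(cis_positions) if cis_positions else "allT"
    return f"{loop.cdr}-{len(loop)}-{tag}"


def vectorize(loop: CDRLoop) -> np.ndarray:
    """Trig embedding: (sin phi, cos phi, sin psi, cos psi) per residue, 4L values."""
    out = np.empty(4 * len(loop))
    for i, tor in enumerate(loop.torsions):
        if tor.phi is None or tor.psi is None:
            raise ValueError(
                f"phi/psi undefined at position {i} of {loop.loop_id}; flanking "
                "residues must be present (run the completeness filter first)"
            )
        phi = np.radians(tor.phi)
        psi = np.radians(tor.psi)
        out[4 * i : 4 * i + 4] = (np.sin(phi), np.cos(phi), np.sin(psi), np.cos(psi))
    return out


def torsion_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Squared Euclidean distance between two trig vectors.

    Equals sum over residues of (sin a - sin b)^2 + (cos a - cos b)^2 for
    phi and psi; a single antipodal angle contributes exactly 4.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"vector length mismatch: {u.shape} vs {v.shape}")
    return float(np.sum((u - v) ** 2))


def similarity_matrix(vectors: np.ndarray) -> np.ndarray:
    """S(i,j) = -D(i,j); diagonal = mean similarity over unordered non-self pairs."""
    vectors = np.asarray(vectors, dtype=float)
    n = vectors.shape[0]
    if n < 2:
        raise ValueError("need at least 2 members for a similarity matrix")
    D = squareform(pdist(vectors, metric="sqeuclidean"))
    S = -D
    preference = float(np.mean(S[np.triu_indices(n, k=1)]))
    np.fill_diagonal(S, preference)
    return S


def affinity_propagation(
    S: np.ndarray,
    damping: float = 0.9,
    max_iter: int = 1000,
    convergence_iter: int = 50,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Frey-Dueck message passing on a similarity matrix with preferences.

    Returns (exemplar indices, labels, iterations).  Deterministic: no
    noise is added and argmax ties resolve to the lowest index.  Raises
    :class:`APConvergenceError` if the exemplar set does not stay stable
    for ``convergence_iter`` consecutive iterations within ``max_iter``.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if S.shape != (n, n):
        raise ValueError("similarity matrix must be square")
    if n == 1:
        return np.array([0]), np.array([0]), 0

    idx = np.arange(n)
    # Degenerate all-identical input: messages stay zero, no exemplar emerges.
    off = S[~np.eye(n, dtype=bool)]
    if np.all(np.abs(off - off[0]) < 1e-12) and abs(off[0]) < 1e-12:
        return np.array([0]), np.zeros(n, dtype=int), 0

    R = np.zeros((n, n))
    A = np.zeros((n, n))
    stable = 0
    last_exemplars: Optional[np.ndarray] = None
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        AS = A + S
        first_idx = AS.argmax(axis=1)
        first = AS[idx, first_idx]
        AS[idx, first_idx] = -np.inf
        second = AS.max(axis=1)
        Rnew = S - first[:, None]
        Rnew[idx, first_idx] = S[idx, first_idx] - second
        R = damping * R + (1 - damping) * Rnew

        Rp = np.maximum(R, 0)
        Rp[idx, idx] = R[idx, idx]
        colsum = Rp.sum(axis=0)
        Anew = np.minimum(0, colsum[None, :] - Rp)
        Anew[idx, idx] = colsum - R[idx, idx]
        A = damping * A + (1 - damping) * Anew

        exemplars = np.flatnonzero((A[idx, idx] + R[idx, idx]) > 0)
        if last_exemplars is not None and np.array_equal(exemplars, last_exemplars):
            stable += 1
        else:
            stable = 0
        last_exemplars = exemplars
        if stable >= convergence_iter and len(exemplars) > 0:
            break
    else:
        raise APConvergenceError(max_iter, n)

    K = last_exemplars
    labels = np.argmax(S[:, K], axis=1)
    labels[K] = np.arange(len(K))
    return K, labels, n_iter


@dataclass
class APCluster:
    """One affinity-propagation cluster with its exemplar and torsional radius."""

    id: int
    exemplar: int  # index into the LRC group's loop list
    members: list[int]
    radius: float = 0.0


def cluster_radius(cluster: APCluster, vectors: np.ndarray) -> float:
    """Max torsional distance from the exemplar to any member (0 for singletons)."""
    ex = vectors[cluster.exemplar]
    return max(torsion_distance(ex, vectors[m]) for m in cluster.members)


def cartesian_criteria(
    loop_a: CDRLoop,
    loop_b: CDRLoop,
    thresholds: Sequence[float] = CARTESIAN_THRESHOLDS,
) -> bool:
    """Cartesian-space similarity of two equal-length loops.

    After fitting on loop CA atoms, all three must hold strictly:
    CA RMSD < thresholds[0], max CA displacement < thresholds[1],
    max CB displacement < thresholds[2].  Positions lacking a CB in
    either loop (glycine) are skipped in the CB test.
    """
    if len(loop_a) != len(loop_b):
        raise ValueError(
            f"loop length mismatch: {len(loop_a)} vs {len(loop_b)} "
            f"({loop_a.loop_id} vs {loop_b.loop_id})"
        )
    rmsd_max, ca_max, cb_max = thresholds
    ca_a = loop_a.ca_coords()
    ca_b = loop_b.ca_coords()
    try:
        fit = kabsch_fit(ca_b, ca_a)
    except DegenerateFitError:
        return False
    if fit.rmsd >= rmsd_max:
        return False
    moved = fit.transform(ca_b)
    if np.max(np.linalg.norm(moved - ca_a, axis=1)) >= ca_max:
        return False
    cb_a = loop_a.cb_coords()
    cb_b = loop_b.cb_coords()
    for pa, pb in zip(cb_a, cb_b):
        if pa is None or pb is None:
            continue
        if np.linalg.norm(fit.rotation @ pb + fit.translation - pa) >= cb_max:
            return False
    return True


def merge_to_canonical(
    clusters: Sequence[APCluster],
    loops: Sequence[CDRLoop],
    thresholds: Sequence[float] = CARTESIAN_THRESHOLDS,
) -> dict[int, int]:
    """Map AP cluster id -> canonical cluster id via exemplar connectivity.

    Edges join AP clusters whose exemplar loops satisfy the Cartesian
    criteria; canonical clusters are the connected components (so chains
    a-b-c merge even if a-c fails directly).  Component ids are assigned
    in order of each component's smallest AP cluster id.
    """
    g = nx.Graph()
    g.add_nodes_from(c.id for c in clusters)
    for i, ca in enumerate(clusters):
        for cb in clusters[i + 1 :]:
            if cartesian_criteria(loops[ca.exemplar], loops[cb.exemplar], thresholds):
                g.add_edge(ca.id, cb.id)
    components = sorted(nx.connected_components(g), key=min)
    mapping: dict[int, int] = {}
    for can_id, comp in enumerate(components):
        for ap_id in comp:
            mapping[ap_id] = can_id
    return mapping


@dataclass
class LRCSpace:
    """Clustered conformational space of one LRC group."""

    name: str
    loops: list[CDRLoop]
    vectors: np.ndarray
    clusters: list[APCluster]
    canonical: dict[int, int]  # AP cluster id -> canonical cluster id
    ap_iterations: int = 0
    membership: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def exemplar_vectors(self) -> np.ndarray:
        return self.vectors[[c.exemplar for c in self.clusters]]

    def exemplar_loop(self, ap_id: int) -> CDRLoop:
        return self.loops[self.clusters[ap_id].exemplar]


def cluster_lrc_group(
    name: str,
    loops: Sequence[CDRLoop],
    damping: float = 0.9,
    max_iter: int = 1000,
    convergence_iter: int = 50,
    thresholds: Sequence[float] = CARTESIAN_THRESHOLDS,
) -> LRCSpace:
    """AP-cluster one LRC group and merge into canonical clusters.

    Groups with fewer than 2 members bypass message passing and form a
    single singleton cluster.
    """
    loops = list(loops)
    vectors = np.array([vectorize(lp) for lp in loops])
    if len(loops) < 2:
        clusters = [APCluster(0, 0, [0], 0.0)]
        labels = np.zeros(len(loops), dtype=int)
    else:
        S = similarity_matrix(vectors)
        exemplars, labels, n_iter = affinity_propagation(
            S, damping=damping, max_iter=max_iter, convergence_iter=convergence_iter
        )
        clusters = []
        for k, ex in enumerate(exemplars):
            members = list(np.flatnonzero(labels == k))
            clusters.append(APCluster(k, int(ex), members))
        for c in clusters:
            c.radius = cluster_radius(c, vectors)
    canonical = merge_to_canonical(clusters, loops, thresholds)
    space = LRCSpace(
        name, loops, vectors, clusters, canonical,
        ap_iterations=n_iter if len(loops) >= 2 else 0,
    )
    for c in clusters:
        for m in c.members:
            space.membership[loops[m].loop_id] = (c.id, canonical[c.id])
    return space


def build_space(
    loops: Sequence[CDRLoop],
    damping: float = 0.9,
    max_iter: int = 1000,
    convergence_iter: int = 50,
    thresholds: Sequence[float] = CARTESIAN_THRESHOLDS,
) -> dict[str, LRCSpace]:
    """Partition loops into LRC groups and cluster each one."""
    groups: dict[str, list[CDRLoop]] = {}
    for lp in loops:
        groups.setdefault(assign_lrc(lp), []).append(lp)
    return {
        name: cluster_lrc_group(
            name, members, damping, max_iter, convergence_iter, thresholds
        )
        for name, members in sorted(groups.items())
    }
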