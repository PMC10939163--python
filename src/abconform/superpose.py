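"""Rigid-body superposition and the local/global CDR C-alpha RMSD protocol.

Local RMSD superposes the CDR loop on itself and measures loop shape
change.  Global RMSD superposes only the supporting chain's framework
(V_H framework for heavy-chain CDRs, V_L for light) and then measures the
CDR without refitting, so it additionally captures rigid loop "flapping"
about the framework junction.  The flap statistic per unbound/bound pair
is |global - local|.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .structure import (
    CDR_NAMES,
    CDR_RANGES,
    DEFAULT_REGIONS,
    AntibodyEntry,
    RegionDefinition,
    StructureError,
    extract_cdr,
    extract_framework,
)

__all__ = [
    "FitResult",
    "MovementRecord",
    "DegenerateFitError",
    "kabsch_fit",
    "local_cdr_rmsd",
    "global_cdr_rmsd",
    "movement_survey",
    "bin_movements",
    "summary_fractions",
    "boxplot_stats",
    "compare_distributions",
    "length_correlation",
    "RMSD_BIN_EDGES",
    "FLAP_BIN_EDGES",
]

#: Right-closed bin edges for RMSD count tables (first bin is <= 0.5).
RMSD_BIN_EDGES = (0.5, 1.0, 2.0, 3.0, 4.0)
#: Edges for the flap (|global - local|) table.
FLAP_BIN_EDGES = (0.25, 0.5, 1.0, 2.0, 3.0)


class DegenerateFitError(ValueError):
    """Raised when the point sets cannot determine a unique rotation."""


@dataclass
class FitResult:
    """Proper rotation + translation minimizing RMSD of mobile onto reference."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_fit(mobile: np.ndarray, reference: np.ndarray) -> FitResult:
    """Least-squares rigid superposition (Kabsch/McLachlan), reflections excluded.

    Both inputs are (n, 3) arrays in position-wise correspondence, n >= 3.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(
            f"coordinate sets differ in shape: {mobile.shape} vs {reference.shape}"
        )
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("need at least 3 corresponding 3D points")
    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    P = mobile - mob_c
    Q = reference - ref_c
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    scale = max(S[0], np.linalg.norm(P), 1.0)
    if S[1] <= 1e-8 * scale:
        raise DegenerateFitError(
            "point set is (near-)collinear; rotation is underdetermined"
        )
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    moved = P @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    translation = ref_c - R @ mob_c
    return FitResult(R, translation, rmsd)


def _paired_cdr_ca(
    unbound: AntibodyEntry,
    bound: AntibodyEntry,
    cdr: str,
    region: RegionDefinition,
) -> tuple[np.ndarray, np.ndarray]:
    lu = extract_cdr(unbound, cdr, region)
    lb = extract_cdr(bound, cdr, region)
    if lu.residue_ids != lb.residue_ids:
        raise StructureError(
            f"CDR {cdr} residue mismatch between {unbound.entry_id} and "
            f"{bound.entry_id}: {lu.residue_ids} vs {lb.residue_ids}"
        )
    return lu.ca_coords(), lb.ca_coords()


def local_cdr_rmsd(
    unbound: AntibodyEntry,
    bound: AntibodyEntry,
    cdr: str,
    region: RegionDefinition = DEFAULT_REGIONS,
) -> float:
    """CA RMSD of the CDR after superposing the loop on itself."""
    ca_u, ca_b = _paired_cdr_ca(unbound, bound, cdr, region)
    return kabsch_fit(ca_b, ca_u).rmsd


def global_cdr_rmsd(
    unbound: AntibodyEntry,
    bound: AntibodyEntry,
    cdr: str,
    region: RegionDefinition = DEFAULT_REGIONS,
) -> float:
    """CA RMSD of the CDR after superposing the chain's framework only.

    The fit uses framework positions present in both entries; the RMSD is
    then evaluated over the CDR CA atoms without refitting.
    """
    chain = region.cdr_ranges[cdr][0]
    ids_u, fw_u = extract_framework(unbound, chain, region)
    ids_b, fw_b = extract_framework(bound, chain, region)
    common = sorted(set(ids_u) & set(ids_b))
    if len(common) < 3:
        raise StructureError(
            f"only {len(common)} common framework residues between "
            f"{unbound.entry_id} and {bound.entry_id} chain {chain}"
        )
    pos_u = {rid: i for i, rid in enumerate(ids_u)}
    pos_b = {rid: i for i, rid in enumerate(ids_b)}
    ref = fw_u[[pos_u[r] for r in common]]
    mob = fw_b[[pos_b[r] for r in common]]
    fit = kabsch_fit(mob, ref)
    ca_u, ca_b = _paired_cdr_ca(unbound, bound, cdr, region)
    moved = fit.transform(ca_b)
    return float(np.sqrt(np.mean(np.sum((moved - ca_u) ** 2, axis=1))))


def framework_rmsd(
    unbound: AntibodyEntry,
    bound: AntibodyEntry,
    chain: str,
    region: RegionDefinition = DEFAULT_REGIONS,
) -> float:
    """Framework-on-framework CA RMSD for one chain (used by the pair filter)."""
    ids_u, fw_u = extract_framework(unbound, chain, region)
    ids_b, fw_b = extract_framework(bound, chain, region)
    common = sorted(set(ids_u) & set(ids_b))
    if len(common) < 3:
        raise StructureError(
            f"only {len(common)} common framework residues between "
            f"{unbound.entry_id} and {bound.entry_id} chain {chain}"
        )
    pos_u = {rid: i for i, rid in enumerate(ids_u)}
    pos_b = {rid: i for i, rid in enumerate(ids_b)}
    ref = fw_u[[pos_u[r] for r in common]]
    mob = fw_b[[pos_b[r] for r in common]]
    return kabsch_fit(mob, ref).rmsd


@dataclass
class MovementRecord:
    """All pairwise local/global RMSDs of one antibody x CDR, with medians."""

    antibody_id: str
    cdr: str
    loop_length: int
    pairs: list[tuple[str, str, float, float, float]] = field(default_factory=list)

    @property
    def median_local(self) -> float:
        return float(np.median([p[2] for p in self.pairs]))

    @property
    def median_global(self) -> float:
        return float(np.median([p[3] for p in self.pairs]))

    @property
    def median_flap(self) -> float:
        return float(np.median([p[4] for p in self.pairs]))


def movement_survey(
    antibody_id: str,
    unbound: Sequence[AntibodyEntry],
    bound: Sequence[AntibodyEntry],
    cdrs: Sequence[str] = CDR_NAMES,
    pairs: Optional[Sequence[tuple[str, str]]] = None,
    region: RegionDefinition = DEFAULT_REGIONS,
) -> dict[str, MovementRecord]:
    """Evaluate every unbound x bound pair of an antibody for each CDR.

    ``pairs`` optionally restricts to (unbound_id, bound_id) combinations
    that survived the framework-RMSD filter.
    """
    allowed = set(pairs) if pairs is not None else None
    records: dict[str, MovementRecord] = {}
    for cdr in cdrs:
        rec = None
        for u in unbound:
            for b in bound:
                if allowed is not None and (u.entry_id, b.entry_id) not in allowed:
                    continue
                loc = local_cdr_rmsd(u, b, cdr, region)
                glo = global_cdr_rmsd(u, b, cdr, region)
                if rec is None:
                    rec = MovementRecord(
                        antibody_id, cdr, len(extract_cdr(u, cdr, region))
                    )
                rec.pairs.append(
                    (u.entry_id, b.entry_id, loc, glo, abs(glo - loc))
                )
        if rec is not None:
            records[cdr] = rec
    return records


def _bin_index(value: float, edges: Sequence[float]) -> int:
    """Right-closed binning: bin 0 is <= edges[0], last bin is > edges[-1]."""
    return int(np.searchsorted(edges, value, side="left"))


def _bin_labels(edges: Sequence[float]) -> list[str]:
    labels = [f"<={edges[0]:g}"]
    labels += [f"({a:g},{b:g}]" for a, b in zip(edges, edges[1:])]
    labels.append(f">{edges[-1]:g}")
    return labels


def bin_movements(
    records: Iterable[MovementRecord],
    edges: Sequence[float] = RMSD_BIN_EDGES,
    stat: str = "global",
) -> pd.DataFrame:
    """Antibody counts per CDR per RMSD range (median per antibody x CDR).

    ``stat`` selects the median used: "global", "local" or "flap".
    Bins are right-closed, e.g. 0.5 falls in the first (<=0.5) bin.
    """
    getter = {
        "global": lambda r: r.median_global,
        "local": lambda r: r.median_local,
        "flap": lambda r: r.median_flap,
    }[stat]
    labels = _bin_labels(edges)
    counts: dict[str, np.ndarray] = {}
    for rec in records:
        row = counts.setdefault(rec.cdr, np.zeros(len(labels), dtype=int))
        row[_bin_index(getter(rec), edges)] += 1
    cdr_order = [c for c in CDR_NAMES if c in counts] + sorted(
        set(counts) - set(CDR_NAMES)
    )
    return pd.DataFrame(
        [counts[c] for c in cdr_order], index=cdr_order, columns=labels
    )


def summary_fractions(
    records: Iterable[MovementRecord],
    thresholds: Sequence[float] = (1.0, 2.0),
    pooling: str = "pooled",
) -> pd.DataFrame:
    """Percentages of loops with median RMSD <= each threshold, H3 vs non-H3.

    ``pooling="pooled"`` counts antibody x CDR observations across the five
    non-H3 CDRs together; ``pooling="mean"`` averages the per-CDR
    percentages instead.
    """
    recs = list(records)
    rows = {}
    for stat, getter in (
        ("global", lambda r: r.median_global),
        ("local", lambda r: r.median_local),
    ):
        row = {}
        for thr in thresholds:
            for label, keep in (("non-H3", lambda r: r.cdr != "H3"),
                                ("H3", lambda r: r.cdr == "H3")):
                subset = [r for r in recs if keep(r)]
                if not subset:
                    row[(f"<={thr:g}", label)] = float("nan")
                    continue
                if pooling == "pooled" or label == "H3":
                    vals = np.array([getter(r) for r in subset])
                    pct = 100.0 * float(np.mean(vals <= thr))
                elif pooling == "mean":
                    per_cdr = []
                    for cdr in sorted({r.cdr for r in subset}):
                        vals = np.array([getter(r) for r in subset if r.cdr == cdr])
                        per_cdr.append(100.0 * float(np.mean(vals <= thr)))
                    pct = float(np.mean(per_cdr))
                else:
                    raise ValueError(f"unknown pooling {pooling!r}")
                row[(f"<={thr:g}", label)] = pct
        rows[stat] = row
    df = pd.DataFrame(rows).T
    df.columns = pd.MultiIndex.from_tuples(df.columns)
    return df


@dataclass
class BoxplotStats:
    q1: float
    median: float
    q3: float
    upper_fence: float


def boxplot_stats(values: Sequence[float]) -> BoxplotStats:
    """Quartiles (linear interpolation) and upper fence Q3 + 1.5*IQR."""
    arr = np.asarray(values, dtype=float)
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method="linear")
    return BoxplotStats(float(q1), float(med), float(q3), float(q3 + 1.5 * (q3 - q1)))


def compare_distributions(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided two-sample Mann-Whitney U test.

    Exact null distribution for small samples without ties; otherwise the
    normal approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    no_ties = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    method = "exact" if (len(a) <= 20 and len(b) <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def length_correlation(
    records: Iterable[MovementRecord], cdr: str = "H3"
) -> tuple[float, float]:
    """Spearman rank correlation between loop length and median global RMSD."""
    pts = [(r.loop_length, r.median_global) for r in records if r.cdr == cdr]
    if len(pts) < 3:
        raise ValueError(f"need at least 3 {cdr} records, got {len(pts)}")
    lengths, rmsds = zip(*pts)
    rho, p = stats.spearmanr(lengths, rmsds)
    return float(rho), float(p)
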