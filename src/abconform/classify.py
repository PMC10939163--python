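"""Classify bound CDR conformations against the unbound conformational space.

Each bound loop is compared with the AP/canonical clusters built from
unbound loops of its LRC group: the nearest AP cluster (by torsional
distance to exemplars) claims it if it falls within the cluster radius;
failing that, passing the Cartesian criteria against that exemplar grants
membership of the canonical cluster only; otherwise the conformation is
novel.  Comparing the bound assignment with the unbound loop's known
cluster yields one of four change types.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import (
    CARTESIAN_THRESHOLDS,
    LRCSpace,
    assign_lrc,
    cartesian_criteria,
    torsion_distance,
    vectorize,
)
from .structure import CDRLoop

__all__ = [
    "ChangeType",
    "Assignment",
    "ClassificationResult",
    "Chi2Result",
    "assign_to_space",
    "classify_pair",
    "aggregate_types",
    "chi_square_tests",
]


class ChangeType(enum.Enum):
    """Four-way conformational change on binding."""

    IDENTICAL_AP = "identical-AP"
    AP_SHIFT = "AP-cluster-shift"
    CANONICAL_SHIFT = "canonical-cluster-shift"
    NON_CANONICAL = "non-canonical"


#: Order used in summary tables; first three constitute Sum(NR).
NR_TYPES = (ChangeType.IDENTICAL_AP, ChangeType.AP_SHIFT, ChangeType.CANONICAL_SHIFT)


@dataclass
class Assignment:
    """Where a query loop lands in one LRC group's clustered space."""

    lrc: str
    ap: Optional[int]  # AP cluster id when a full member, else None
    canonical: Optional[int]  # canonical cluster id when assigned, else None
    nearest_ap: Optional[int] = None
    distance: Optional[float] = None
    radius: Optional[float] = None
    criteria_pass: Optional[bool] = None
    reason: str = ""


def assign_to_space(
    loop: CDRLoop,
    space: Optional[LRCSpace],
    preferred_canonical: Optional[int] = None,
    thresholds: Sequence[float] = CARTESIAN_THRESHOLDS,
) -> Assignment:
    """Locate a query loop in the clustered space of its LRC group.

    ``space`` is None when the LRC group has no unbound counterpart; the
    loop is then unassigned ("no matching LRC group").  Ties for the
    nearest exemplar prefer a cluster in ``preferred_canonical`` (the
    unbound loop's canonical cluster) and then the lowest cluster id.
    """
    lrc = assign_lrc(loop)
    if space is None:
        return Assignment(lrc, None, None, reason="no matching LRC group")
    x = vectorize(loop)
    dists = np.array(
        [torsion_distance(x, space.vectors[c.exemplar]) for c in space.clusters]
    )
    dmin = dists.min()
    tied = np.flatnonzero(np.isclose(dists, dmin, rtol=0.0, atol=1e-12))
    best = int(tied[0])
    if preferred_canonical is not None and len(tied) > 1:
        for t in tied:
            if space.canonical[space.clusters[int(t)].id] == preferred_canonical:
                best = int(t)
                break
    nearest = space.clusters[best]
    can = space.canonical[nearest.id]
    d = float(dists[best])
    if d <= nearest.radius:
        return Assignment(
            lrc, nearest.id, can, nearest.id, d, nearest.radius, None,
            reason="within radius",
        )
    ok = cartesian_criteria(loop, space.exemplar_loop(nearest.id), thresholds)
    if ok:
        return Assignment(
            lrc, None, can, nearest.id, d, nearest.radius, True,
            reason="outside radius, CartesianCriteria pass",
        )
    return Assignment(
        lrc, None, None, nearest.id, d, nearest.radius, False,
        reason="outside radius, CartesianCriteria fail",
    )


@dataclass
class ClassificationResult:
    antibody_id: str
    cdr: str
    unbound_id: str
    bound_id: str
    unbound_ap: int
    unbound_canonical: int
    unbound_lrc: str
    assignment: Assignment
    change_type: ChangeType


def classify_pair(
    antibody_id: str,
    unbound_loop: CDRLoop,
    bound_loop: CDRLoop,
    spaces: Mapping[str, LRCSpace],
    thresholds: Sequence[float] = CARTESIAN_THRESHOLDS,
) -> ClassificationResult:
    """Assign the bound loop and compare with the unbound loop's clusters.

    The unbound loop must have been part of the clustering input; a lookup
    failure is a pipeline-ordering error, not a data condition.
    """
    lrc_u = assign_lrc(unbound_loop)
    space_u = spaces.get(lrc_u)
    if space_u is None or unbound_loop.loop_id not in space_u.membership:
        raise KeyError(
            f"unbound loop {unbound_loop.loop_id} not found among clustered "
            "members; cluster the unbound space before classifying"
        )
    a_u, c_u = space_u.membership[unbound_loop.loop_id]

    lrc_b = assign_lrc(bound_loop)
    space_b = spaces.get(lrc_b)
    pref = c_u if lrc_b == lrc_u else None
    asg = assign_to_space(bound_loop, space_b, preferred_canonical=pref,
                          thresholds=thresholds)

    same_group = lrc_b == lrc_u
    if asg.ap is not None and same_group and asg.ap == a_u:
        ctype = ChangeType.IDENTICAL_AP
    elif asg.canonical is not None and same_group and asg.canonical == c_u:
        ctype = ChangeType.AP_SHIFT
    elif asg.canonical is not None:
        ctype = ChangeType.CANONICAL_SHIFT
    else:
        ctype = ChangeType.NON_CANONICAL
    return ClassificationResult(
        antibody_id, unbound_loop.cdr, unbound_loop.source_id,
        bound_loop.source_id, a_u, c_u, lrc_u, asg, ctype,
    )


def aggregate_types(
    results: Iterable[ClassificationResult],
    cdr_order: Sequence[str] = ("H1", "H2", "H3", "L1", "L2", "L3"),
) -> pd.DataFrame:
    """Distinct-antibody counts per CDR and change type, plus Sum(NR).

    An antibody with pairs of several types is counted once in each
    matching column, and once in Sum(NR) if any pair has one of the three
    not-novel types.
    """
    per_type: dict[tuple[str, ChangeType], set[str]] = {}
    nr: dict[str, set[str]] = {}
    seen_cdrs: set[str] = set()
    for r in results:
        seen_cdrs.add(r.cdr)
        per_type.setdefault((r.cdr, r.change_type), set()).add(r.antibody_id)
        if r.change_type in NR_TYPES:
            nr.setdefault(r.cdr, set()).add(r.antibody_id)
    rows = []
    index = [c for c in cdr_order if c in seen_cdrs] + sorted(
        seen_cdrs - set(cdr_order)
    )
    for cdr in index:
        rows.append(
            {
                "identical_ap": len(per_type.get((cdr, ChangeType.IDENTICAL_AP), ())),
                "ap_shift": len(per_type.get((cdr, ChangeType.AP_SHIFT), ())),
                "canonical_shift": len(
                    per_type.get((cdr, ChangeType.CANONICAL_SHIFT), ())
                ),
                "sum_nr": len(nr.get(cdr, ())),
                "non_canonical": len(
                    per_type.get((cdr, ChangeType.NON_CANONICAL), ())
                ),
            }
        )
    return pd.DataFrame(rows, index=index)


@dataclass
class Chi2Result:
    name: str
    statistic: float
    dof: int
    pvalue: float
    warning: str = ""


def _pearson_chi2(table: np.ndarray, name: str) -> Chi2Result:
    table = np.asarray(table, dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        dof = (table.shape[0] - 1) * (table.shape[1] - 1)
        return Chi2Result(
            name, float("nan"), dof, float("nan"),
            "degenerate table (zero marginal); test undefined",
        )
    stat, p, dof, expected = stats.chi2_contingency(table, correction=False)
    warning = ""
    if np.any(expected < 1):
        warning = "expected cell count below 1; chi-square approximation unreliable"
    return Chi2Result(name, float(stat), int(dof), float(p), warning)


def chi_square_tests(counts: pd.DataFrame) -> list[Chi2Result]:
    """Three Pearson chi-square tests on Sum(NR) vs non-canonical counts.

    (i) all CDRs x 2 outcomes; (ii) excluding CDR-H3; (iii) CDR-H3 vs
    pooled non-H3, 2 x 2.  ``counts`` is an aggregate_types frame indexed
    by CDR with columns sum_nr and non_canonical.
    """
    table = counts[["sum_nr", "non_canonical"]].to_numpy()
    results = [_pearson_chi2(table, "all CDRs x (Sum(NR), non-canonical)")]
    if "H3" in counts.index and len(counts.index) > 2:
        no_h3 = counts.drop(index="H3")[["sum_nr", "non_canonical"]].to_numpy()
        results.append(_pearson_chi2(no_h3, "non-H3 CDRs x (Sum(NR), non-canonical)"))
        h3 = counts.loc["H3", ["sum_nr", "non_canonical"]].to_numpy(dtype=float)
        pooled = no_h3.sum(axis=0)
        results.append(
            _pearson_chi2(
                np.vstack([h3, pooled]), "H3 vs pooled non-H3 (2x2)"
            )
        )
    return results
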