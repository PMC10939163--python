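"""Sequence-identity grouping and the stepwise structure quality filter.

Entries sharing identical heavy- and light-chain sequences form one
"antibody" (exact matching; equivalent to 100%-identity clustering).
The quality pipeline then eliminates, in order: poor/unknown resolution,
missing variable domains, CDRs with missing residues, zero or high CDR
CA B-factors, and cis non-proline residues in CDRs of unbound entries.
With pairing required it additionally keeps only antibodies with both
forms and drops unbound/bound pairs whose framework moves >= 1.0 A.

Every step records an audit row (entries in, rejections with reason
codes, entries out) so counts are conserved and exportable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .structure import (
    CDR_NAMES,
    CIS_OMEGA_THRESHOLD,
    DEFAULT_REGIONS,
    PEPTIDE_BOND_MAX,
    AntibodyEntry,
    RegionDefinition,
    ResidueID,
    is_cis,
)
from .superpose import framework_rmsd

__all__ = [
    "AntibodyGroup",
    "FilterStep",
    "FilterResult",
    "REASONS",
    "group_identical",
    "require_both_forms",
    "quality_filter",
    "framework_rmsd_filter",
]

#: Closed enumeration of rejection reason codes.
REASONS = (
    "resolution_missing",
    "resolution_above_threshold",
    "missing_heavy_domain",
    "missing_light_domain",
    "cdr_missing_residue",
    "cdr_incomplete_backbone",
    "cdr_bfactor_zero",
    "cdr_bfactor_high",
    "cdr_cis_nonproline",
    "no_unbound_form",
    "no_bound_form",
    "framework_rmsd_all_pairs",
)


@dataclass
class AntibodyGroup:
    """Entries with identical H+L sequences: one "antibody" in this analysis."""

    group_id: str
    members: list[AntibodyEntry] = field(default_factory=list)
    valid_pairs: Optional[list[tuple[str, str]]] = None

    @property
    def unbound(self) -> list[AntibodyEntry]:
        return [e for e in self.members if not e.is_bound]

    @property
    def bound(self) -> list[AntibodyEntry]:
        return [e for e in self.members if e.is_bound]


def _group_key(entry: AntibodyEntry) -> tuple[Optional[str], Optional[str]]:
    return entry.sequence("H"), entry.sequence("L")


def group_identical(entries: Sequence[AntibodyEntry]) -> list[AntibodyGroup]:
    """Group entries by exact (H, L) sequence identity; deterministic ids."""
    buckets: dict[tuple, list[AntibodyEntry]] = {}
    for e in entries:
        buckets.setdefault(_group_key(e), []).append(e)
    groups = []
    for key in sorted(buckets, key=lambda k: (k[0] or "", k[1] or "")):
        h, l = key
        digest = hashlib.sha1(f"{h or '-'}|{l or '-'}".encode()).hexdigest()[:10]
        members = sorted(buckets[key], key=lambda e: e.entry_id)
        groups.append(AntibodyGroup(f"ab_{digest}", members))
    return groups


def require_both_forms(groups: Sequence[AntibodyGroup]) -> list[AntibodyGroup]:
    """Keep only groups with at least one unbound and one bound member."""
    return [g for g in groups if g.unbound and g.bound]


@dataclass
class FilterStep:
    name: str
    n_in: int
    rejected: list[tuple[str, str]]  # (entry_id, reason code)
    n_out: int
    n_antibodies: int

    def check_conservation(self) -> bool:
        return self.n_in - len(self.rejected) == self.n_out


@dataclass
class FilterResult:
    steps: list[FilterStep]
    groups: list[AntibodyGroup]  # surviving groups (with surviving members only)

    @property
    def entries(self) -> list[AntibodyEntry]:
        return [e for g in self.groups for e in g.members]

    def audit_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "step": s.name,
                    "entries_in": s.n_in,
                    "rejected": len(s.rejected),
                    "entries_out": s.n_out,
                    "antibodies_out": s.n_antibodies,
                }
                for s in self.steps
            ]
        )

    def rejection_table(self) -> pd.DataFrame:
        rows = [
            {"step": s.name, "entry_id": eid, "reason": reason}
            for s in self.steps
            for eid, reason in s.rejected
        ]
        return pd.DataFrame(rows, columns=["step", "entry_id", "reason"])

    def write_audit(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.audit_table().to_csv(directory / "filter_audit.tsv", sep="\t", index=False)
        self.rejection_table().to_csv(
            directory / "filter_rejections.tsv", sep="\t", index=False
        )


def _expected_cdr_positions(
    group: list[AntibodyEntry], cdr: str, region: RegionDefinition
) -> set[ResidueID]:
    """Union of observed Martin positions in the CDR range across the group."""
    chain, start, end = region.cdr_ranges[cdr]
    expected: set[ResidueID] = set()
    for e in group:
        for r in e.chains.get(chain, []):
            if start <= r.id.number <= end:
                expected.add(r.id)
    return expected


def _check_cdr_completeness(
    entry: AntibodyEntry,
    expected: dict[str, set[ResidueID]],
    region: RegionDefinition,
) -> Optional[str]:
    for cdr in CDR_NAMES:
        chain, start, end = region.cdr_ranges[cdr]
        in_range = [
            r for r in entry.chains.get(chain, []) if start <= r.id.number <= end
        ]
        if expected[cdr] - {r.id for r in in_range}:
            return "cdr_missing_residue"
        for r in in_range:
            if not r.has_backbone:
                return "cdr_incomplete_backbone"
        # A chain break between consecutive CDR residues marks a residue
        # present in the sequence but not modelled in the coordinates.
        for prev, curr in zip(in_range, in_range[1:]):
            d = np.linalg.norm(prev.coord("C") - curr.coord("N"))
            if d > PEPTIDE_BOND_MAX:
                return "cdr_missing_residue"
    return None


def _check_cdr_bfactors(
    entry: AntibodyEntry, region: RegionDefinition, bfactor_max: float
) -> Optional[str]:
    for cdr in CDR_NAMES:
        chain, start, end = region.cdr_ranges[cdr]
        for r in entry.chains.get(chain, []):
            if not (start <= r.id.number <= end) or "CA" not in r.atoms:
                continue
            b = r.atoms["CA"].b
            if b == 0:
                return "cdr_bfactor_zero"
            if b > bfactor_max:
                return "cdr_bfactor_high"
    return None


def _check_cis_nonproline(
    entry: AntibodyEntry, region: RegionDefinition, cis_threshold: float
) -> Optional[str]:
    torsions = entry.torsions()
    for cdr in CDR_NAMES:
        chain, start, end = region.cdr_ranges[cdr]
        for r in entry.chains.get(chain, []):
            if not (start <= r.id.number <= end) or r.amino_acid == "P":
                continue
            omega = torsions[r.id].omega
            if omega is not None and is_cis(omega, cis_threshold):
                return "cdr_cis_nonproline"
    return None


def framework_rmsd_filter(
    group: AntibodyGroup,
    threshold: float = 1.0,
    region: RegionDefinition = DEFAULT_REGIONS,
) -> AntibodyGroup:
    """Drop unbound/bound pairs with framework CA RMSD >= threshold.

    The per-pair statistic is the maximum over the H- and L-chain
    framework fits.  Entries not participating in any surviving pair are
    removed; a group left without both forms is returned empty of
    members (caller drops it).
    """
    valid: list[tuple[str, str]] = []
    for u in group.unbound:
        for b in group.bound:
            r = max(
                framework_rmsd(u, b, "H", region),
                framework_rmsd(u, b, "L", region),
            )
            if r < threshold:
                valid.append((u.entry_id, b.entry_id))
    keep_ids = {eid for pair in valid for eid in pair}
    members = [e for e in group.members if e.entry_id in keep_ids]
    return AntibodyGroup(group.group_id, members, valid_pairs=valid)


def _n_antibodies(entries: Sequence[AntibodyEntry]) -> int:
    keys = {_group_key(e) for e in entries}
    return len(keys)


def quality_filter(
    entries: Sequence[AntibodyEntry],
    require_pairing: bool = True,
    resolution_max: float = 2.8,
    bfactor_max: float = 80.0,
    framework_rmsd_max: float = 1.0,
    cis_threshold: float = CIS_OMEGA_THRESHOLD,
    region: RegionDefinition = DEFAULT_REGIONS,
) -> FilterResult:
    """Run the sequential quality pipeline with a per-step audit trail.

    Entries with resolution exactly at the threshold are retained.  The
    cis non-proline check applies to unbound entries only.  When
    ``require_pairing`` is set, the both-forms retention, pairwise
    framework-RMSD filter, and both-forms recheck are appended.
    """
    steps: list[FilterStep] = []
    current = sorted(entries, key=lambda e: e.entry_id)

    def run_step(name: str, reject_fn) -> None:
        nonlocal current
        kept, rejected = [], []
        for e in current:
            reason = reject_fn(e)
            if reason is None:
                kept.append(e)
            else:
                rejected.append((e.entry_id, reason))
        steps.append(
            FilterStep(name, len(current), rejected, len(kept), _n_antibodies(kept))
        )
        current = kept

    run_step(
        "resolution",
        lambda e: (
            "resolution_missing"
            if e.resolution is None
            else ("resolution_above_threshold" if e.resolution > resolution_max else None)
        ),
    )
    run_step(
        "variable_domains",
        lambda e: (
            "missing_heavy_domain"
            if "H" not in e.chains
            else ("missing_light_domain" if "L" not in e.chains else None)
        ),
    )

    # Reference positions per CDR come from the entry's identical-sequence group.
    groups = group_identical(current)
    expected_by_group: dict[str, dict[str, set[ResidueID]]] = {}
    entry_group: dict[str, str] = {}
    for g in groups:
        expected_by_group[g.group_id] = {
            cdr: _expected_cdr_positions(g.members, cdr, region) for cdr in CDR_NAMES
        }
        for e in g.members:
            entry_group[e.entry_id] = g.group_id

    run_step(
        "cdr_completeness",
        lambda e: _check_cdr_completeness(
            e, expected_by_group[entry_group[e.entry_id]], region
        ),
    )
    run_step("cdr_bfactor", lambda e: _check_cdr_bfactors(e, region, bfactor_max))
    run_step(
        "cis_nonproline",
        lambda e: (
            None if e.is_bound else _check_cis_nonproline(e, region, cis_threshold)
        ),
    )

    groups = group_identical(current)
    if not require_pairing:
        return FilterResult(steps, groups)

    run_step(
        "both_forms",
        lambda e: _both_forms_reason(e, groups),
    )
    groups = [g for g in require_both_forms(group_identical(current))]

    filtered_groups: list[AntibodyGroup] = []
    rejected: list[tuple[str, str]] = []
    n_in = len(current)
    for g in groups:
        fg = framework_rmsd_filter(g, framework_rmsd_max, region)
        kept_ids = {e.entry_id for e in fg.members}
        for e in g.members:
            if e.entry_id not in kept_ids:
                rejected.append((e.entry_id, "framework_rmsd_all_pairs"))
        if fg.unbound and fg.bound:
            filtered_groups.append(fg)
    current = [e for g in filtered_groups for e in g.members]
    steps.append(
        FilterStep(
            "framework_rmsd", n_in, rejected, len(current), len(filtered_groups)
        )
    )
    return FilterResult(steps, filtered_groups)


def _both_forms_reason(
    entry: AntibodyEntry, groups: Sequence[AntibodyGroup]
) -> Optional[str]:
    for g in groups:
        if any(e.entry_id == entry.entry_id for e in g.members):
            if not g.unbound:
                return "no_unbound_form"
            if not g.bound:
                return "no_bound_form"
            return None
    return None
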