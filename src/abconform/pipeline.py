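"""End-to-end orchestration: filter -> pair -> RMSD survey -> cluster -> classify.

A run is a pure function of (input files, configuration): iteration
orders are sorted, clustering is jitter-free, and the configuration is
serialized alongside the outputs, so rerunning the same config on the
same inputs reproduces every table byte for byte.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import pandas as pd

from . import classify as _classify
from . import clustering as _clustering
from .filtering import FilterResult, quality_filter
from .structure import CDR_NAMES, AntibodyEntry, extract_cdr, read_entry
from .superpose import (
    FLAP_BIN_EDGES,
    RMSD_BIN_EDGES,
    MovementRecord,
    bin_movements,
    boxplot_stats,
    compare_distributions,
    length_correlation,
    movement_survey,
    summary_fractions,
)

logger = logging.getLogger("abconform")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "audit_counts"]


@dataclass
class RunConfig:
    """Every numeric threshold of the pipeline, serialized with each run."""

    input_dir: str
    output_dir: str
    resolution_max: float = 2.8
    bfactor_max: float = 80.0
    framework_rmsd_max: float = 1.0
    cartesian_thresholds: tuple[float, float, float] = (1.0, 1.5, 1.9)
    cis_threshold: float = 30.0
    ap_damping: float = 0.9
    ap_max_iter: int = 1000
    ap_convergence_iter: int = 50
    seed: int = 0

    def __post_init__(self):
        for name in (
            "resolution_max", "bfactor_max", "framework_rmsd_max", "cis_threshold"
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class PipelineResult:
    config: RunConfig
    paired_filter: FilterResult
    unbound_filter: FilterResult
    movements: list[MovementRecord]
    spaces: dict
    classifications: list
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def _read_input(input_dir: Path) -> list[AntibodyEntry]:
    files = sorted(input_dir.glob("*.pdb"))
    if not files:
        raise ValueError(f"no .pdb files found in {input_dir}")
    entries = []
    for f in files:
        entries.append(read_entry(f, require_both=False))
    return entries


def _movement_tables(movements: list[MovementRecord]) -> dict[str, pd.DataFrame]:
    tables = {}
    rows = [
        {
            "antibody": r.antibody_id, "cdr": r.cdr,
            "unbound_id": u, "bound_id": b,
            "local_rmsd": loc, "global_rmsd": glo, "flap": flap,
        }
        for r in movements
        for (u, b, loc, glo, flap) in r.pairs
    ]
    tables["movements"] = pd.DataFrame(rows)
    tables["rmsd_bins_global"] = bin_movements(movements, RMSD_BIN_EDGES, "global")
    tables["rmsd_bins_local"] = bin_movements(movements, RMSD_BIN_EDGES, "local")
    tables["rmsd_bins_flap"] = bin_movements(movements, FLAP_BIN_EDGES, "flap")
    tables["summary_fractions"] = summary_fractions(movements)

    stat_rows = []
    for cdr in CDR_NAMES:
        recs = [r for r in movements if r.cdr == cdr]
        if not recs:
            continue
        glo = [r.median_global for r in recs]
        loc = [r.median_local for r in recs]
        bs_g, bs_l = boxplot_stats(glo), boxplot_stats(loc)
        u_stat, p = compare_distributions(glo, loc)
        stat_rows.append(
            {
                "cdr": cdr, "n": len(recs),
                "global_q1": bs_g.q1, "global_median": bs_g.median,
                "global_q3": bs_g.q3, "global_upper_fence": bs_g.upper_fence,
                "local_q1": bs_l.q1, "local_median": bs_l.median,
                "local_q3": bs_l.q3, "local_upper_fence": bs_l.upper_fence,
                "mannwhitney_u": u_stat, "p_value": p,
            }
        )
    tables["boxplot_stats"] = pd.DataFrame(stat_rows)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant lengths -> undefined rho
            rho, p = length_correlation(movements, "H3")
        tables["h3_length_correlation"] = pd.DataFrame(
            [{"spearman_rho": rho, "p_value": p}]
        )
    except ValueError:
        pass
    return tables


def _cluster_tables(spaces: dict) -> dict[str, pd.DataFrame]:
    rows = []
    for name in sorted(spaces):
        sp = spaces[name]
        for c in sp.clusters:
            for m in c.members:
                rows.append(
                    {
                        "loop_id": sp.loops[m].loop_id,
                        "lrc_group": name,
                        "ap_cluster": c.id,
                        "canonical_cluster": sp.canonical[c.id],
                        "is_exemplar": m == c.exemplar,
                        "radius": c.radius,
                    }
                )
    return {"clusters": pd.DataFrame(rows)}


def _cluster_graph(spaces: dict) -> nx.Graph:
    g = nx.Graph()
    for name in sorted(spaces):
        sp = spaces[name]
        for c in sp.clusters:
            g.add_node(
                f"{name}/ap{c.id}",
                lrc=name, size=len(c.members),
                canonical=f"{name}/can{sp.canonical[c.id]}",
            )
        by_can: dict[int, list[int]] = {}
        for ap_id, can_id in sp.canonical.items():
            by_can.setdefault(can_id, []).append(ap_id)
        for can_id, ap_ids in by_can.items():
            ap_ids = sorted(ap_ids)
            for i, a in enumerate(ap_ids):
                for b in ap_ids[i + 1 :]:
                    if _clustering.cartesian_criteria(
                        sp.exemplar_loop(a), sp.exemplar_loop(b)
                    ):
                        g.add_edge(f"{name}/ap{a}", f"{name}/ap{b}")
    return g


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis and write the report bundle to output_dir."""
    input_dir = Path(config.input_dir)
    output_dir = Path(config.output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)

    entries = _read_input(input_dir)
    logger.info("read %d entries from %s", len(entries), input_dir)

    paired = quality_filter(
        entries,
        require_pairing=True,
        resolution_max=config.resolution_max,
        bfactor_max=config.bfactor_max,
        framework_rmsd_max=config.framework_rmsd_max,
        cis_threshold=config.cis_threshold,
    )
    paired.write_audit(output_dir)
    logger.info(
        "paired filter kept %d entries / %d antibodies",
        len(paired.entries), len(paired.groups),
    )

    unbound_only = [e for e in entries if not e.is_bound]
    unbound = quality_filter(
        unbound_only,
        require_pairing=False,
        resolution_max=config.resolution_max,
        bfactor_max=config.bfactor_max,
        cis_threshold=config.cis_threshold,
    )
    unbound.audit_table().to_csv(
        output_dir / "unbound_filter_audit.tsv", sep="\t", index=False
    )

    # RMSD survey over surviving pairs
    movements: list[MovementRecord] = []
    for g in paired.groups:
        recs = movement_survey(
            g.group_id, g.unbound, g.bound, pairs=g.valid_pairs
        )
        movements.extend(recs[c] for c in CDR_NAMES if c in recs)

    tables = _movement_tables(movements)

    # Unbound conformational space
    loops = []
    skipped = 0
    for e in unbound.entries:
        for cdr in CDR_NAMES:
            loop = extract_cdr(e, cdr)
            try:
                _clustering.vectorize(loop)
            except ValueError:
                skipped += 1
                continue
            loops.append(loop)
    if skipped:
        logger.warning("skipped %d loops with undefined torsions", skipped)
    spaces = _clustering.build_space(
        loops,
        damping=config.ap_damping,
        max_iter=config.ap_max_iter,
        convergence_iter=config.ap_convergence_iter,
        thresholds=config.cartesian_thresholds,
    )
    for name in sorted(spaces):
        sp = spaces[name]
        singles = sum(1 for c in sp.clusters if len(c.members) == 1)
        if singles:
            logger.info("LRC group %s: %d singleton AP clusters", name, singles)
    tables.update(_cluster_tables(spaces))

    # Classification of bound loops against the unbound space
    results = []
    class_rows = []
    for g in paired.groups:
        for u in g.unbound:
            for b in g.bound:
                if g.valid_pairs is not None and (
                    u.entry_id, b.entry_id
                ) not in g.valid_pairs:
                    continue
                for cdr in CDR_NAMES:
                    lu = extract_cdr(u, cdr)
                    lb = extract_cdr(b, cdr)
                    try:
                        res = _classify.classify_pair(
                            g.group_id, lu, lb, spaces,
                            thresholds=config.cartesian_thresholds,
                        )
                    except KeyError:
                        logger.warning(
                            "unbound loop %s absent from clustered space; "
                            "pair skipped", lu.loop_id,
                        )
                        continue
                    results.append(res)
                    class_rows.append(
                        {
                            "antibody": res.antibody_id, "cdr": res.cdr,
                            "unbound_id": res.unbound_id, "bound_id": res.bound_id,
                            "unbound_lrc": res.unbound_lrc,
                            "unbound_ap": res.unbound_ap,
                            "unbound_canonical": res.unbound_canonical,
                            "bound_ap": res.assignment.ap,
                            "bound_canonical": res.assignment.canonical,
                            "distance": res.assignment.distance,
                            "radius": res.assignment.radius,
                            "reason": res.assignment.reason,
                            "change_type": res.change_type.value,
                        }
                    )
    tables["classification"] = pd.DataFrame(class_rows)
    if results:
        type_counts = _classify.aggregate_types(results)
        tables["type_counts"] = type_counts
        chi2 = _classify.chi_square_tests(type_counts)
        tables["chi_square"] = pd.DataFrame(
            [
                {
                    "test": r.name, "statistic": r.statistic,
                    "dof": r.dof, "p_value": r.pvalue, "warning": r.warning,
                }
                for r in chi2
            ]
        )

    # Persist the bundle
    for name, df in tables.items():
        df.to_csv(
            output_dir / f"{name}.tsv", sep="\t",
            index=name in ("rmsd_bins_global", "rmsd_bins_local",
                           "rmsd_bins_flap", "summary_fractions", "type_counts"),
        )
    _write_dot(_cluster_graph(spaces), output_dir / "canonical_clusters.dot")
    (output_dir / "run_config.json").write_text(
        json.dumps(asdict(config), indent=2, sort_keys=True) + "\n"
    )

    return PipelineResult(
        config, paired, unbound, movements, spaces, results, tables
    )


def _write_dot(g: nx.Graph, path: Path) -> None:
    lines = ["graph canonical_clusters {"]
    for node, data in sorted(g.nodes(data=True)):
        attrs = ", ".join(f'{k}="{v}"' for k, v in sorted(data.items()))
        lines.append(f'  "{node}" [{attrs}];')
    for a, b in sorted(g.edges()):
        lines.append(f'  "{a}" -- "{b}";')
    lines.append("}")
    path.write_text("\n".join(lines) + "\n")


def audit_counts(result: PipelineResult) -> pd.DataFrame:
    """Stepwise entry/antibody counts with conservation check."""
    df = result.paired_filter.audit_table()
    if not all(s.check_conservation() for s in result.paired_filter.steps):
        raise AssertionError("audit conservation violated")
    return df
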