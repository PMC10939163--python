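"""Shared fixtures: synthetic entries, cohorts, and planted cluster spaces."""

from __future__ import annotations

import numpy as np
import pytest

from abconform.clustering import build_space
from abconform.structure import CDR_RANGES, extract_cdr
from abconform.synthetic import (
    ClusterSpec,
    CohortConfig,
    default_cluster_centers,
    generate_cohort,
    make_entry,
    sample_torsion_cluster,
)

ALL_DEFECTS = (
    "resolution",
    "missing_domain",
    "missing_residue",
    "bfactor",
    "cis_nonproline",
    "framework_shift",
)


def loop_length(cdr: str) -> int:
    _, start, end = CDR_RANGES[cdr]
    return end - start + 1


def sample_entry(ab_idx: int = 0, seed: int = 0, cluster: str = "c1", **kwargs):
    """One clean Fv entry with all six CDRs drawn from a planted cluster."""
    rng = np.random.default_rng(seed)
    torsions = {
        cdr: sample_torsion_cluster(
            ClusterSpec(default_cluster_centers(loop_length(cdr))[cluster], 2.0),
            rng, 1,
        )[0]
        for cdr in CDR_RANGES
    }
    kwargs.setdefault("pdb_code", f"{9900 + ab_idx % 100:04d}")
    kwargs.setdefault("index", 0)
    kwargs.setdefault("antigen_type", None)
    return make_entry(ab_idx=ab_idx, cdr_torsions=torsions, **kwargs)


@pytest.fixture(scope="session")
def defect_cohort():
    """Small cohort with exactly one planted defect per filter criterion."""
    config = CohortConfig(n_antibodies=9, seed=11, defects=ALL_DEFECTS)
    return config, generate_cohort(config)


@pytest.fixture(scope="session")
def clean_cohort():
    """Defect-free 24-antibody cohort with a 60/20/10/10 change-type mix."""
    config = CohortConfig(n_antibodies=24, seed=7)
    return config, generate_cohort(config)


@pytest.fixture(scope="session")
def planted_h3_space():
    """Clustered unbound H3 space: clusters c1 + c2 (one canonical) and c3.

    Returns (space, loops_by_cluster) for a single LRC group.
    """
    rng = np.random.default_rng(42)
    centers = default_cluster_centers(loop_length("H3"))
    loops, by_cluster = [], {}
    idx = 0
    for name in ("c1", "c2", "c3"):
        by_cluster[name] = []
        samples = sample_torsion_cluster(ClusterSpec(centers[name], 2.0), rng, 10)
        for s in samples:
            e = make_entry(f"{9700 + idx:04d}", 0, None, idx, {"H3": s})
            lp = extract_cdr(e, "H3")
            loops.append(lp)
            by_cluster[name].append(lp)
            idx += 1
    spaces = build_space(loops)
    assert len(spaces) == 1
    return next(iter(spaces.values())), by_cluster
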