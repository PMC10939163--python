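"""Superposition and the local/global RMSD protocol."""

import itertools

import numpy as np
import pytest
from scipy import stats
from scipy.spatial.transform import Rotation

from abconform.structure import CDR_RANGES
from abconform.superpose import (
    DegenerateFitError,
    MovementRecord,
    bin_movements,
    boxplot_stats,
    compare_distributions,
    global_cdr_rmsd,
    kabsch_fit,
    length_correlation,
    local_cdr_rmsd,
    movement_survey,
    summary_fractions,
)
from abconform.synthetic import CohortConfig, generate_cohort, generate_flap_pair

from conftest import sample_entry


def so3_grid_min_rmsd(mobile, reference, coarse_step=12.0, refinements=3):
    """Independent oracle: hierarchical Euler-angle grid search over SO(3)."""
    P = mobile - mobile.mean(axis=0)
    Q = reference - reference.mean(axis=0)

    def rmsd_for(angles):
        mats = Rotation.from_euler("zyx", angles, degrees=True).as_matrix()
        moved = np.einsum("mij,nj->mni", mats, P)
        return np.sqrt(np.mean(np.sum((moved - Q[None]) ** 2, axis=2), axis=1))

    grids = [
        np.arange(-180.0, 180.0, coarse_step),
        np.arange(-90.0, 90.0 + 1e-9, coarse_step),
        np.arange(-180.0, 180.0, coarse_step),
    ]
    angles = np.array(list(itertools.product(*grids)))
    vals = rmsd_for(angles)
    best = angles[np.argmin(vals)]
    best_val = vals.min()
    step = coarse_step
    for _ in range(refinements):
        step /= 4.0
        offsets = np.linspace(-2 * step, 2 * step, 9)
        local = np.array(
            [best + np.array(o) for o in itertools.product(offsets, repeat=3)]
        )
        vals = rmsd_for(local)
        if vals.min() < best_val:
            best_val = vals.min()
            best = local[np.argmin(vals)]
    return float(best_val)


class TestKabsch:
    def test_identity_on_identical_sets(self):
        pts = np.random.default_rng(0).normal(size=(6, 3))
        fit = kabsch_fit(pts, pts)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(fit.rotation, np.eye(3), atol=1e-12)

    def test_recovers_applied_rigid_transform(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(8, 3))
        R = Rotation.random(random_state=2).as_matrix()
        t = np.array([3.0, -1.0, 7.0])
        moved = pts @ R.T + t
        fit = kabsch_fit(moved, pts)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(fit.rotation @ R, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(fit.transform(moved), pts, atol=1e-9)

    def test_proper_rotation_only(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(5, 3))
        b = rng.normal(size=(5, 3))
        assert np.linalg.det(kabsch_fit(a, b).rotation) == pytest.approx(1.0)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(3):
            n = rng.integers(4, 9)
            a = rng.normal(size=(n, 3))
            b = rng.normal(size=(n, 3))
            fit = kabsch_fit(a, b)
            grid = so3_grid_min_rmsd(a, b)
            assert grid >= fit.rmsd - 1e-9
            assert grid - fit.rmsd < 1e-3

    def test_degenerate_and_mismatched_inputs(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(DegenerateFitError):
            kabsch_fit(line, line + 1.0)
        with pytest.raises(ValueError):
            kabsch_fit(np.zeros((4, 3)), np.zeros((5, 3)))
        with pytest.raises(ValueError):
            kabsch_fit(np.zeros((2, 3)), np.zeros((2, 3)))


class TestLocalGlobal:
    def test_identical_entries_give_zero(self):
        e = sample_entry(ab_idx=1, seed=2)
        assert local_cdr_rmsd(e, e, "H3") == pytest.approx(0.0, abs=1e-9)
        assert global_cdr_rmsd(e, e, "H3") == pytest.approx(0.0, abs=1e-9)

    def test_flap_has_no_local_signal_but_global_signal(self):
        unbound, bound = generate_flap_pair(0, "H3", 20.0, seed=0)
        assert local_cdr_rmsd(unbound, bound, "H3") == pytest.approx(0.0, abs=1e-9)
        assert global_cdr_rmsd(unbound, bound, "H3") > 0.5

    def test_local_equals_kabsch_on_cdr_atoms(self):
        from abconform.structure import extract_cdr

        u = sample_entry(ab_idx=2, seed=3, cluster="c1")
        b = sample_entry(ab_idx=2, seed=4, cluster="c2", index=1, antigen_type="P")
        direct = kabsch_fit(
            extract_cdr(b, "L1").ca_coords(), extract_cdr(u, "L1").ca_coords()
        ).rmsd
        assert local_cdr_rmsd(u, b, "L1") == pytest.approx(direct, abs=1e-12)

    def test_rmsd_symmetric_and_rigid_invariant(self):
        u = sample_entry(ab_idx=5, seed=5, cluster="c1")
        b = sample_entry(ab_idx=5, seed=6, cluster="c3", index=1, antigen_type="P")
        assert local_cdr_rmsd(u, b, "H2") == pytest.approx(
            local_cdr_rmsd(b, u, "H2"), abs=1e-9
        )
        assert global_cdr_rmsd(u, b, "H2") == pytest.approx(
            global_cdr_rmsd(b, u, "H2"), abs=1e-9
        )

    def test_local_le_global_across_modes(self, clean_cohort):
        _, cohort = clean_cohort
        by_code = {}
        for e in cohort.entries:
            by_code.setdefault(e.pdb_code, []).append(e)
        checked = 0
        for code, entries in sorted(by_code.items()):
            unbound = [e for e in entries if not e.is_bound]
            bound = [e for e in entries if e.is_bound]
            for u in unbound:
                for b in bound:
                    for cdr in CDR_RANGES:
                        loc = local_cdr_rmsd(u, b, cdr)
                        glo = global_cdr_rmsd(u, b, cdr)
                        assert loc <= glo + 1e-6
                        checked += 1
        assert checked >= 100


class TestSurveyTables:
    def _fake_record(self, cdr, values, length=10):
        rec = MovementRecord("ab", cdr, length)
        for i, (loc, glo) in enumerate(values):
            rec.pairs.append((f"u{i}", f"b{i}", loc, glo, abs(glo - loc)))
        return rec

    def test_movement_survey_pair_counts_and_medians(self):
        unbound = [sample_entry(ab_idx=6, seed=s, index=s) for s in range(3)]
        bound = [
            sample_entry(ab_idx=6, seed=10 + s, index=10 + s, antigen_type="P")
            for s in range(3)
        ]
        records = movement_survey("ab6", unbound, bound)
        assert set(records) == set(CDR_RANGES)
        for rec in records.values():
            assert len(rec.pairs) == 9
        single = movement_survey("ab6", unbound[:1], bound[:1])["H3"]
        assert single.median_local == pytest.approx(single.pairs[0][2])

    def test_bin_edges_are_right_closed(self):
        recs = [
            self._fake_record("H1", [(0.5, 0.5)]),
            self._fake_record("H1", [(0.51, 0.51)]),
            self._fake_record("H1", [(4.01, 4.01)]),
        ]
        table = bin_movements(recs, stat="global")
        assert table.loc["H1", "<=0.5"] == 1
        assert table.loc["H1", "(0.5,1]"] == 1
        assert table.loc["H1", ">4"] == 1

    def test_bin_counts_match_direct_counting(self):
        rng = np.random.default_rng(8)
        medians = rng.uniform(0.0, 5.0, 60)
        recs = [self._fake_record("L3", [(m, m)]) for m in medians]
        table = bin_movements(recs, stat="global")
        edges = [0.5, 1.0, 2.0, 3.0, 4.0]
        expect = [np.sum(medians <= 0.5)]
        expect += [
            np.sum((medians > a) & (medians <= b)) for a, b in zip(edges, edges[1:])
        ]
        expect.append(np.sum(medians > 4.0))
        assert list(table.loc["L3"]) == [int(x) for x in expect]

    def test_summary_fractions_half_split(self):
        recs = [self._fake_record("H3", [(0.4, 0.4)]) for _ in range(10)]
        recs += [self._fake_record("H3", [(3.0, 3.0)]) for _ in range(10)]
        recs += [self._fake_record("L2", [(0.2, 0.2)]) for _ in range(4)]
        df = summary_fractions(recs)
        assert df.loc["global", ("<=1", "H3")] == pytest.approx(50.0)
        assert df.loc["local", ("<=2", "non-H3")] == pytest.approx(100.0)

    def test_boxplot_stats(self):
        bs = boxplot_stats([1, 2, 3, 4, 5])
        assert bs.median == 3
        assert bs.upper_fence == pytest.approx(bs.q3 + 1.5 * (bs.q3 - bs.q1))
        const = boxplot_stats([2.0] * 7)
        assert const.q1 == const.q3 == const.upper_fence == 2.0
        rng = np.random.default_rng(9)
        vals = rng.normal(size=37)
        bs = boxplot_stats(vals)
        q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75], method="linear")
        assert (bs.q1, bs.median, bs.q3) == pytest.approx((q1, med, q3))


class TestStatistics:
    def test_identical_samples_not_significant(self):
        a = np.arange(10.0)
        _, p = compare_distributions(a, a.copy())
        assert p > 0.9

    def test_disjoint_support_is_extreme(self):
        a = np.arange(20.0)
        b = np.arange(100.0, 120.0)
        u, p = compare_distributions(a, b)
        assert u in (0.0, 400.0)
        assert p < 1e-4

    def test_exact_p_matches_enumeration(self):
        rng = np.random.default_rng(10)
        for _ in range(3):
            a = rng.normal(0, 1, 5)
            b = rng.normal(0.8, 1, 4)
            _, p = compare_distributions(a, b)
            pooled = np.concatenate([a, b])
            m = len(a)
            us = []
            for comb in itertools.combinations(range(len(pooled)), m):
                rest = [i for i in range(len(pooled)) if i not in comb]
                us.append(
                    sum(x > y for x in pooled[list(comb)] for y in pooled[rest])
                )
            us = np.array(us, dtype=float)
            u_obs = sum(x > y for x in a for y in b)
            p_enum = min(
                1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
            )
            assert p == pytest.approx(p_enum, abs=1e-12)

    def test_length_correlation_monotone(self):
        recs = []
        for i, length in enumerate(range(8, 16)):
            rec = MovementRecord("a%d" % i, "H3", length)
            rec.pairs.append(("u", "b", 0.1, 0.1 * (i + 1), 0.0))
            recs.append(rec)
        rho, _ = length_correlation(recs)
        assert rho == pytest.approx(1.0)
        for i, rec in enumerate(recs):
            rec.pairs[0] = ("u", "b", 0.1, 1.0 - 0.1 * i, 0.0)
        rho, _ = length_correlation(recs)
        assert rho == pytest.approx(-1.0)
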