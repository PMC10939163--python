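"""Torsion-space clustering: LRC groups, AP message passing, Cartesian merging."""

import numpy as np
import pytest

from abconform.clustering import (
    APCluster,
    affinity_propagation,
    assign_lrc,
    cartesian_criteria,
    cluster_lrc_group,
    cluster_radius,
    merge_to_canonical,
    similarity_matrix,
    torsion_distance,
    vectorize,
)
from abconform.structure import Atom, CDRLoop, Residue, ResidueID, Torsion, extract_cdr
from abconform.superpose import kabsch_fit
from abconform.synthetic import make_entry

from conftest import loop_length, sample_entry


def _loop_from_angles(angles, cdr="H3", start=95, tag="x"):
    """CDRLoop carrying torsions only (no coordinates needed)."""
    residues = [
        Residue(ResidueID("H", start + i), "A", {}) for i in range(len(angles))
    ]
    torsions = [Torsion(phi, psi, 180.0) for phi, psi in angles]
    return CDRLoop(cdr, residues, torsions, source_id=tag)


def _coord_loop(coords, tag):
    residues = [
        Residue(ResidueID("H", 95 + i), "A", {"CA": Atom(tuple(c))})
        for i, c in enumerate(coords)
    ]
    return CDRLoop("H3", residues, [Torsion(0.0, 0.0, 180.0)] * len(coords), tag)


class TestLRCNaming:
    def test_all_trans_names(self):
        entry = sample_entry()
        assert assign_lrc(extract_cdr(entry, "L2")) == "L2-7-allT"
        assert assign_lrc(extract_cdr(entry, "H2")) == "H2-9-allT"

    def test_cis_proline_position_in_name(self):
        # L3 spans L89-L97; a cis omega at loop index 6 is position L95
        omegas = np.full(9, 180.0)
        omegas[6] = 0.0
        torsions = {"L3": np.tile([-65.0, -40.0], (9, 1))}
        entry = make_entry("9abc", 0, None, 0, torsions, cdr_omegas={"L3": omegas})
        loop = extract_cdr(entry, "L3")
        assert loop.residues[6].amino_acid == "P"
        assert assign_lrc(loop) == "L3-9-cis95"

    def test_multiple_cis_positions_sorted(self):
        omegas = np.full(9, 180.0)
        omegas[6] = 0.0
        omegas[2] = 5.0
        entry = make_entry(
            "9abd", 0, None, 0,
            {"L3": np.tile([-65.0, -40.0], (9, 1))},
            cdr_omegas={"L3": omegas},
        )
        assert assign_lrc(extract_cdr(entry, "L3")) == "L3-9-cis91,95"

    def test_undefined_torsions_error(self):
        loop = _loop_from_angles([(-60.0, -40.0)] * 5)
        loop.torsions[2] = Torsion(-60.0, -40.0, None)
        with pytest.raises(ValueError, match="omega undefined"):
            assign_lrc(loop)


class TestVectorize:
    def test_blocks_and_length(self):
        loop = _loop_from_angles([(0.0, 0.0), (90.0, -90.0)] + [(30.0, 60.0)] * 7)
        v = vectorize(loop)
        assert v.shape == (36,)  # length-9 loop -> 36-dimensional vector
        np.testing.assert_allclose(v[:4], [0.0, 1.0, 0.0, 1.0], atol=1e-12)
        np.testing.assert_allclose(v[4:8], [1.0, 0.0, -1.0, 0.0], atol=1e-12)

    def test_sin_cos_pairs_on_unit_circle(self):
        rng = np.random.default_rng(0)
        loop = _loop_from_angles(rng.uniform(-180, 180, (8, 2)))
        v = vectorize(loop).reshape(-1, 2)
        np.testing.assert_allclose((v ** 2).sum(axis=1), 1.0, atol=1e-9)

    def test_undefined_phi_errors(self):
        loop = _loop_from_angles([(10.0, 20.0)] * 4)
        loop.torsions[0] = Torsion(None, 20.0, 180.0)
        with pytest.raises(ValueError, match="phi/psi undefined"):
            vectorize(loop)


class TestTorsionDistance:
    def test_identical_is_zero_and_antipodal_is_four(self):
        a = vectorize(_loop_from_angles([(30.0, -70.0)] * 6))
        assert torsion_distance(a, a) == 0.0
        angles = [(30.0, -70.0)] * 6
        angles[2] = (30.0 + 180.0, -70.0)  # single antipodal phi
        b = vectorize(_loop_from_angles(angles))
        assert torsion_distance(a, b) == pytest.approx(4.0, abs=1e-12)

    def test_closed_form_oracle(self):
        # independent closed form: f(a,b) = 2 - 2 cos(a-b) per angle
        rng = np.random.default_rng(1)
        for _ in range(20):
            ang_a = rng.uniform(-180, 180, (7, 2))
            ang_b = rng.uniform(-180, 180, (7, 2))
            d = torsion_distance(
                vectorize(_loop_from_angles(ang_a)),
                vectorize(_loop_from_angles(ang_b)),
            )
            closed = np.sum(2.0 - 2.0 * np.cos(np.radians(ang_a - ang_b)))
            assert d == pytest.approx(closed, abs=1e-10)

    def test_bounded_by_8L_and_symmetric(self):
        rng = np.random.default_rng(2)
        a = vectorize(_loop_from_angles(rng.uniform(-180, 180, (5, 2))))
        b = vectorize(_loop_from_angles(rng.uniform(-180, 180, (5, 2))))
        assert torsion_distance(a, b) == torsion_distance(b, a)
        assert 0.0 <= torsion_distance(a, b) <= 8 * 5

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            torsion_distance(np.zeros(8), np.zeros(12))


class TestSimilarity:
    def test_constructed_preference(self):
        # three points with pairwise squared distances exactly {2, 6, 4}
        pts = np.array([[0.0, 0.0], [np.sqrt(2.0), 0.0], [np.sqrt(2.0), 2.0]])
        S = similarity_matrix(pts)
        assert S[0, 1] == pytest.approx(-2.0)
        assert S[0, 2] == pytest.approx(-6.0)
        assert S[1, 2] == pytest.approx(-4.0)
        assert np.allclose(np.diag(S), -4.0)  # mean of -2, -4, -6

    def test_preference_matches_brute_force(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(17, 12))
        S = similarity_matrix(X)
        pairs = [
            -np.sum((X[i] - X[j]) ** 2)
            for i in range(17)
            for j in range(i + 1, 17)
        ]
        assert np.diag(S)[0] == pytest.approx(np.mean(pairs), abs=1e-12)


class TestAffinityPropagation:
    def _planted(self, rng, centers, n_per, scale=0.05):
        X, labels = [], []
        for k, c in enumerate(centers):
            X.append(c + rng.normal(0, scale, size=(n_per, len(c))))
            labels += [k] * n_per
        return np.vstack(X), np.array(labels)

    def test_recovers_two_planted_clusters(self):
        rng = np.random.default_rng(4)
        X, truth = self._planted(rng, [np.zeros(8), np.full(8, 3.0)], 15)
        S = similarity_matrix(X)
        exemplars, labels, _ = affinity_propagation(S)
        assert len(exemplars) == 2
        # same partition as planted
        assert len({(t, l) for t, l in zip(truth, labels)}) == 2

    def test_all_identical_points_one_cluster(self):
        X = np.ones((6, 4))
        S = similarity_matrix(X)
        exemplars, labels, _ = affinity_propagation(S)
        assert len(exemplars) == 1
        assert set(labels) == {0}

    def test_exemplars_near_centroids(self):
        rng = np.random.default_rng(5)
        centers = [np.zeros(6), np.full(6, 4.0), np.r_[np.full(3, -4.0), np.zeros(3)]]
        X, truth = self._planted(rng, centers, 12)
        S = similarity_matrix(X)
        exemplars, labels, _ = affinity_propagation(S)
        assert len(exemplars) == 3
        for ex in exemplars:
            k = truth[ex]
            members = np.flatnonzero(truth == k)
            centroid = X[members].mean(axis=0)
            dists = np.linalg.norm(X[members] - centroid, axis=1)
            assert np.linalg.norm(X[ex] - centroid) <= dists.min() + 1e-9

    def test_matches_sklearn_on_separated_data(self):
        sklearn = pytest.importorskip("sklearn")
        from sklearn.cluster import AffinityPropagation
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(6)
        X, truth = self._planted(rng, [np.zeros(10), np.full(10, 5.0)], 20)
        S = similarity_matrix(X)
        _, labels, _ = affinity_propagation(S)
        ref = AffinityPropagation(
            damping=0.9, preference=S[0, 0], random_state=0, max_iter=1000
        ).fit(X)
        assert adjusted_rand_score(ref.labels_, labels) == pytest.approx(1.0)

    def test_deterministic_for_fixed_input(self):
        rng = np.random.default_rng(7)
        X, _ = self._planted(rng, [np.zeros(5), np.full(5, 2.5)], 10)
        S = similarity_matrix(X)
        r1 = affinity_propagation(S)
        r2 = affinity_propagation(S)
        np.testing.assert_array_equal(r1[0], r2[0])
        np.testing.assert_array_equal(r1[1], r2[1])


class TestRadius:
    def test_singleton_and_pair(self):
        vecs = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 4.0]])
        assert cluster_radius(APCluster(0, 2, [2]), vecs) == 0.0
        pair = APCluster(0, 0, [0, 1])
        assert cluster_radius(pair, vecs) == pytest.approx(1.0)

    def test_matches_brute_force_max(self):
        rng = np.random.default_rng(8)
        vecs = rng.normal(size=(9, 6))
        c = APCluster(0, 3, list(range(9)))
        brute = max(np.sum((vecs[3] - vecs[m]) ** 2) for m in range(9))
        assert cluster_radius(c, vecs) == pytest.approx(brute, abs=1e-12)

    def test_members_within_radius_after_clustering(self, planted_h3_space):
        space, _ = planted_h3_space
        for c in space.clusters:
            for m in c.members:
                d = torsion_distance(space.vectors[c.exemplar], space.vectors[m])
                assert d <= c.radius + 1e-12


class TestCartesianCriteria:
    BASE = np.array(
        [[i * 3.8, (i % 2) * 0.8, 0.03 * i * i] for i in range(8)]
    )

    def test_identical_loops_pass(self):
        a = _coord_loop(self.BASE, "a")
        assert cartesian_criteria(a, _coord_loop(self.BASE.copy(), "b"))

    def test_large_single_residue_displacement_fails(self):
        moved = self.BASE.copy()
        moved[3] += np.array([0.0, 0.0, 5.0])
        assert not cartesian_criteria(_coord_loop(self.BASE, "a"), _coord_loop(moved, "b"))

    def test_each_threshold_is_binding(self):
        # measure the actual fitted quantities, then tighten one at a time
        moved = self.BASE.copy()
        moved[0, 2] += 1.2
        a, b = _coord_loop(self.BASE, "a"), _coord_loop(moved, "b")
        fit = kabsch_fit(b.ca_coords(), a.ca_coords())
        max_ca = np.max(
            np.linalg.norm(fit.transform(b.ca_coords()) - a.ca_coords(), axis=1)
        )
        assert cartesian_criteria(a, b, (fit.rmsd + 0.01, max_ca + 0.01, 1.9))
        assert not cartesian_criteria(a, b, (fit.rmsd - 0.01, max_ca + 0.01, 1.9))
        assert not cartesian_criteria(a, b, (fit.rmsd + 0.01, max_ca - 0.01, 1.9))

    def test_cb_threshold_binding_and_glycine_skipped(self):
        entry_a = sample_entry(ab_idx=11, seed=11, cluster="c1")
        entry_b = sample_entry(ab_idx=11, seed=12, cluster="c1", index=1)
        a = extract_cdr(entry_a, "H3")
        b = extract_cdr(entry_b, "H3")
        assert any(p is None for p in a.cb_coords())  # glycines present
        fit = kabsch_fit(b.ca_coords(), a.ca_coords())
        cb_d = [
            np.linalg.norm(fit.rotation @ pb + fit.translation - pa)
            for pa, pb in zip(a.cb_coords(), b.cb_coords())
            if pa is not None and pb is not None
        ]
        max_cb = max(cb_d)
        assert cartesian_criteria(a, b, (99.0, 99.0, max_cb + 0.01))
        assert not cartesian_criteria(a, b, (99.0, 99.0, max_cb - 0.01))

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="length mismatch"):
            cartesian_criteria(
                _coord_loop(self.BASE, "a"), _coord_loop(self.BASE[:5], "b")
            )


class TestCanonicalMerging:
    def test_chain_merges_by_connectivity(self):
        base = TestCartesianCriteria.BASE
        b = base.copy(); b[0, 2] += 1.6
        c = base.copy(); c[0, 2] += 3.2
        loops = [_coord_loop(base, "a"), _coord_loop(b, "b"), _coord_loop(c, "c")]
        # precondition of the fixture: a-b and b-c pass, a-c fails
        assert cartesian_criteria(loops[0], loops[1])
        assert cartesian_criteria(loops[1], loops[2])
        assert not cartesian_criteria(loops[0], loops[2])
        clusters = [APCluster(i, i, [i]) for i in range(3)]
        mapping = merge_to_canonical(clusters, loops)
        assert len(set(mapping.values())) == 1

    def test_no_passing_pairs_no_merge(self):
        base = TestCartesianCriteria.BASE
        b = base.copy(); b[0, 2] += 4.0
        c = base.copy(); c[4, 1] += 5.0
        loops = [_coord_loop(base, "a"), _coord_loop(b, "b"), _coord_loop(c, "c")]
        clusters = [APCluster(i, i, [i]) for i in range(3)]
        mapping = merge_to_canonical(clusters, loops)
        assert len(set(mapping.values())) == 3

    def test_planted_two_component_layout(self, planted_h3_space):
        space, by_cluster = planted_h3_space
        assert len(space.clusters) == 3
        assert len(set(space.canonical.values())) == 2
        # c1 and c2 share a canonical cluster; c3 stands alone
        can_of = {
            name: {space.membership[lp.loop_id][1] for lp in lps}
            for name, lps in by_cluster.items()
        }
        assert can_of["c1"] == can_of["c2"]
        assert can_of["c3"] != can_of["c1"]
        # merging never splits an AP cluster
        for c in space.clusters:
            cans = {space.membership[space.loops[m].loop_id][1] for m in c.members}
            assert len(cans) == 1

    def test_singleton_group_bypasses_ap(self):
        entry = sample_entry(ab_idx=13, seed=13)
        space = cluster_lrc_group("solo", [extract_cdr(entry, "L2")])
        assert len(space.clusters) == 1
        assert space.clusters[0].radius == 0.0
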