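"""The penalized joint SMACOF core: stress, updates, convergence and recovery."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from jointmds import (
    FixtureSpec,
    JointMDS,
    embedding_error,
    guttman_transform,
    joint_mds,
    kabsch,
    make_structure,
    pair_stress,
    penalized_update,
    relocalization_profile,
    select_similarity_weight,
    structure_to_contacts,
    prepare_pair,
)
from jointmds.datatypes import Structure

from conftest import exact_distmatrix


def two_point_setup():
    delta = np.array([[0.0, 1.0], [1.0, 0.0]])
    x = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
    return delta, x


class TestStress:
    def test_identical_configurations_have_zero_penalty(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(8, 3))
        delta = squareform(pdist(rng.normal(size=(8, 3))))
        s_free = pair_stress(x, x, delta, delta, 0.0)
        s_pen = pair_stress(x, x, delta, delta, 10.0)
        assert s_pen == pytest.approx(s_free)

    def test_perfect_fit_with_zero_weight_is_zero(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(6, 3))
        delta = squareform(pdist(x))
        assert pair_stress(x, x, delta, delta, 0.0) == pytest.approx(0.0, abs=1e-20)

    def test_hand_computed_two_point_value(self):
        delta, x1 = two_point_setup()
        assert pair_stress(x1, x1, delta, delta, 0.5) == pytest.approx(0.0)
        x2 = x1 + np.array([0.0, 0.0, 1.0])
        # fit terms stay perfect, penalty = 2 loci * 0.5 * 1^2
        assert pair_stress(x1, x2, delta, delta, 0.5) == pytest.approx(1.0)

    def test_missing_pairs_excluded_from_fit(self):
        x = np.array([[0.0, 0, 0], [1.0, 0, 0], [5.0, 0, 0]])
        delta = squareform(pdist(x))
        delta_missing = delta.copy()
        delta_missing[0, 2] = delta_missing[2, 0] = 0.0  # mark missing
        bad = x.copy()
        bad[2] = [9.0, 0, 0]  # ruins only the (0,2) and (1,2) distances
        full = pair_stress(bad, bad, delta, delta, 0.0)
        part = pair_stress(bad, bad, delta_missing, delta_missing, 0.0)
        assert part < full

    def test_shape_mismatch_rejected(self):
        delta, x = two_point_setup()
        with pytest.raises(ValueError):
            pair_stress(x, x[:1], delta, delta, 0.0)


class TestGuttmanTransform:
    def test_perfect_embedding_is_fixed_point(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=(10, 3))
        z -= z.mean(axis=0)
        delta = squareform(pdist(z))
        np.testing.assert_allclose(guttman_transform(z, delta), z, atol=1e-12)

    def test_two_points_contract_to_target_distance(self):
        delta, _ = two_point_setup()
        z = np.array([[-1.0, 0, 0], [1.0, 0, 0]])  # current distance 2, target 1
        out = guttman_transform(z, delta)
        assert np.linalg.norm(out[0] - out[1]) == pytest.approx(1.0)
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-15)

    def test_fully_missing_row_warns_and_pulls_to_origin(self):
        delta = np.array(
            [[0.0, 1, 0], [1, 0.0, 0], [0, 0, 0.0]]
        )  # locus 2 has no targets
        z = np.random.default_rng(3).normal(size=(3, 3))
        with pytest.warns(UserWarning, match="no usable target"):
            out = guttman_transform(z, delta)
        np.testing.assert_allclose(out[2], 0.0, atol=1e-15)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            guttman_transform(np.zeros((1, 3)), np.zeros((1, 1)))


class TestPenalizedUpdate:
    def test_zero_weight_equals_plain_guttman(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=(7, 3))
        other = rng.normal(size=(7, 3))
        delta = squareform(pdist(rng.normal(size=(7, 3))))
        np.testing.assert_allclose(
            penalized_update(other, z, delta, 0.0), guttman_transform(z, delta)
        )

    def test_infinite_weight_limit_snaps_to_other(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=(5, 3))
        other = rng.normal(size=(5, 3))
        delta = squareform(pdist(z))
        out = penalized_update(other, z, delta, 1e12)
        np.testing.assert_allclose(out, other, atol=1e-9)

    def test_unit_weight_blends_halfway(self):
        delta, _ = two_point_setup()
        z = np.array([[-0.5, 0, 0], [0.5, 0, 0]])  # perfect embedding: guttman = z
        other = np.array([[2.0, 0, 0], [3.0, 0, 0]])
        out = penalized_update(other, z, delta, 1.0)
        np.testing.assert_allclose(out, (other + z) / 2, atol=1e-12)

    def test_negative_weight_rejected(self):
        delta, x = two_point_setup()
        with pytest.raises(ValueError, match="non-negative"):
            penalized_update(x, x, delta, -0.1)


def aligned_rmsd_to_truth(coords, truth: Structure) -> float:
    """Best rigid-motion RMSD to the truth, allowing a global reflection."""
    est = Structure(truth.chrom, truth.bin_size, truth.bins.copy(), np.asarray(coords))
    best = np.inf
    for mirror in (1.0, -1.0):
        mirrored = est.copy()
        mirrored.coords = mirrored.coords * np.array([1.0, 1.0, mirror])
        _, aligned = kabsch(mirrored, truth)
        best = min(best, np.sqrt(np.mean(np.sum((aligned.coords - truth.coords) ** 2, axis=1))))
    return best


class TestJointMDS:
    def test_recovers_known_helix_and_aligns_pair(self, helix20, helix20_delta):
        fit = joint_mds(helix20_delta, helix20_delta, weight=0.05, seed=0)
        cross = np.linalg.norm(fit.pair.x1.coords - fit.pair.x2.coords, axis=1)
        assert cross.max() < 1e-6  # identical inputs, shared start: no split
        assert aligned_rmsd_to_truth(fit.pair.x1.coords, helix20) < 0.01  # 1% of radius 1

    def test_weight_zero_matches_classical_recovery(self, helix100, helix100_delta):
        fit = joint_mds(helix100_delta, helix100_delta, weight=0.0, seed=1)
        diameter = helix100_delta.delta.max()
        assert aligned_rmsd_to_truth(fit.pair.x1.coords, helix100) < 1e-3 * diameter

    def test_stress_trace_monotone_within_restart(self, helix20_delta):
        fit = joint_mds(helix20_delta, helix20_delta, weight=0.1, seed=2)
        tr = fit.stress_trace
        assert np.all(np.diff(tr) <= 1e-9 * np.maximum(tr[:-1], 1.0))

    def test_swapping_inputs_swaps_outputs_exactly(self):
        a = make_structure(FixtureSpec(n_loci=30, seed=6))
        b = make_structure(FixtureSpec(n_loci=30, seed=6, displacements={15: np.array([1.0, 0, 0])}))
        d1, d2 = prepare_pair(
            structure_to_contacts(a, noise_sd=0.2, seed=1),
            structure_to_contacts(b, noise_sd=0.2, seed=2),
        )
        f12 = joint_mds(d1, d2, weight=0.05, seed=3)
        f21 = joint_mds(d2, d1, weight=0.05, seed=3)
        np.testing.assert_array_equal(f12.pair.x1.coords, f21.pair.x2.coords)
        np.testing.assert_array_equal(f12.pair.x2.coords, f21.pair.x1.coords)

    def test_outputs_mean_centered(self, helix20_delta):
        fit = joint_mds(helix20_delta, helix20_delta, weight=0.05, seed=4)
        np.testing.assert_allclose(fit.pair.x1.coords.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(fit.pair.x2.coords.mean(axis=0), 0.0, atol=1e-9)

    def test_penalty_term_non_increasing_in_weight(self):
        a = make_structure(FixtureSpec(n_loci=40, seed=7))
        b = make_structure(FixtureSpec(n_loci=40, seed=7, displacements={20: np.array([0.8, 0.8, 0])}))
        d1, d2 = prepare_pair(
            structure_to_contacts(a, noise_sd=0.3, seed=11),
            structure_to_contacts(b, noise_sd=0.3, seed=12),
        )
        medians = []
        for w in (0.01, 0.05, 0.2):
            pens = []
            for seed in range(3):
                fit = joint_mds(d1, d2, weight=w, seed=seed)
                pens.append(
                    np.sum(np.linalg.norm(fit.pair.x1.coords - fit.pair.x2.coords, axis=1) ** 2)
                )
            medians.append(np.median(pens))
        assert medians[0] >= medians[1] >= medians[2]

    def test_planted_relocalization_found_in_most_seeds(self):
        base = make_structure(FixtureSpec(n_loci=50, seed=1))
        moved = make_structure(
            FixtureSpec(n_loci=50, seed=1, displacements={25: np.array([1.5, 0.0, 0.0])})
        )
        hits = 0
        for seed in range(10):
            d1, d2 = prepare_pair(
                structure_to_contacts(base, noise_sd=0.1, seed=100 + seed),
                structure_to_contacts(moved, noise_sd=0.1, seed=200 + seed),
            )
            fit = joint_mds(d1, d2, weight=0.05, seed=seed)
            prof = relocalization_profile(fit.pair)
            hits += int(prof.bins[np.argmax(prof.magnitude)]) == 25
        assert hits >= 9

    def test_nonconvergence_flagged(self, helix20_delta):
        with pytest.warns(UserWarning, match="no restart converged"):
            fit = joint_mds(helix20_delta, helix20_delta, weight=0.05, seed=0, max_iter=2)
        assert not fit.converged

    def test_mismatched_loci_rejected(self, helix20_delta, helix100_delta):
        with pytest.raises(ValueError, match="identical locus list"):
            joint_mds(helix20_delta, helix100_delta)


class TestSelectSimilarityWeight:
    def test_identical_inputs_choose_smallest_positive(self, helix20_delta):
        w, curve = select_similarity_weight(
            helix20_delta, helix20_delta, [0.01, 0.05], n_runs=2, seed=0
        )
        assert w == 0.01
        assert all(c == pytest.approx(1.0) for c in curve.values())

    def test_single_candidate_returned_with_curve(self, helix20_delta):
        w, curve = select_similarity_weight(helix20_delta, helix20_delta, [0.07], seed=0)
        assert w == 0.07 and set(curve) == {0.07}

    def test_empty_candidates_rejected(self, helix20_delta):
        with pytest.raises(ValueError, match="non-empty"):
            select_similarity_weight(helix20_delta, helix20_delta, [])


class TestEmbeddingError:
    def test_perfect_embedding_has_zero_error(self, helix20, helix20_delta):
        assert embedding_error(helix20, helix20_delta) == pytest.approx(0.0, abs=1e-12)

    def test_two_point_error_is_residual(self):
        from jointmds.datatypes import DistMatrix

        x = Structure("c", 10, np.arange(2), np.array([[0.0, 0, 0], [2.0, 0, 0]]))
        d = DistMatrix("c", 10, np.arange(2), np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert embedding_error(x, d) == pytest.approx(1.0)

    def test_similarity_weight_degrades_fit_only_slightly(self, helix100):
        # Noisy inputs, so the error floor is set by the data, not the optimizer.
        moved = make_structure(
            FixtureSpec(n_loci=100, seed=0, displacements={50: np.array([1.0, 1.0, 0])})
        )
        d1, d2 = prepare_pair(
            structure_to_contacts(helix100, noise_sd=0.2, seed=31),
            structure_to_contacts(moved, noise_sd=0.2, seed=32),
        )
        errs = {}
        for w in (0.0, 0.5):
            fit = joint_mds(d1, d2, weight=w, seed=0)
            errs[w] = embedding_error(fit.pair.x1, d1) + embedding_error(fit.pair.x2, d2)
        assert errs[0.5] <= 1.25 * errs[0.0]
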