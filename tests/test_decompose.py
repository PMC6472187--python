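"""The refitting core: flattening, PD correction, the QP and subset search."""

import itertools

import numpy as np
import pytest

from sigrefit import (
    ContextSpec,
    GenomeProfile,
    decompose_tumor,
    explained_variance,
    explained_variance_curve,
    flat_genome,
    flatten,
    nearest_positive_definite,
    random_signature_set,
    signature_matrix,
    solve_exposures,
)
from sigrefit.decompose import SimplexSolver
from sigrefit.sigmodel import ShiraishiSignature


def grid_search(g, S, step=1e-3):
    """Brute-force minimizer of ||g - S w||^2 over the simplex grid."""
    K = S.shape[1]
    if K == 1:
        return np.array([1.0])
    ticks = np.arange(0.0, 1.0 + step / 2, step)
    if K == 2:
        W = np.column_stack([ticks, 1.0 - ticks])
    else:
        assert K == 3
        w1, w2 = np.meshgrid(ticks, ticks, indexing="ij")
        w1, w2 = w1.ravel(), w2.ravel()
        keep = w1 + w2 <= 1.0 + step / 2
        W = np.column_stack([w1[keep], w2[keep], 1.0 - w1[keep] - w2[keep]])
    gram = S.T @ S
    d = S.T @ g
    vals = np.einsum("ij,jk,ik->i", W, gram, W) - 2.0 * W @ d
    return W[np.argmin(vals)]


class TestFlatten:
    def test_deamination_flattens_row_major(self, deamination):
        v = flatten(deamination)
        assert v.shape == (24,)
        np.testing.assert_array_equal(v[:6], [0.004, 0.006, 0.928, 0.009,
                                              0.038, 0.015])
        np.testing.assert_array_equal(v[-2:], [0.493, 0.507])

    def test_alexandrov_identity(self, rng):
        from sigrefit.sigmodel import AlexandrovSignature
        probs = rng.dirichlet(np.ones(96))
        assert flatten(AlexandrovSignature(probs)).shape == (96,)
        np.testing.assert_array_equal(
            flatten(AlexandrovSignature(probs)), probs)

    def test_mixed_specs_rejected(self, triplet_spec, quintet_strand_spec):
        a = random_signature_set(1, triplet_spec, seed=1)
        b = random_signature_set(1, quintet_strand_spec, seed=2)
        with pytest.raises(ValueError, match="mix"):
            signature_matrix(a + b)


class TestNearestPositiveDefinite:
    def test_identity_unchanged(self):
        eye = np.eye(4)
        assert nearest_positive_definite(eye) is eye

    def test_singular_diagonal_clipped_minimally(self):
        M = np.diag([1.0, 0.0])
        A = nearest_positive_definite(M)
        # eigenvalue-clipping oracle: eigvals -> (1, floor)
        assert np.all(np.linalg.eigvalsh(A) > 0)
        assert np.abs(A - M).max() <= 10 * 1e-8  # clipping floor eps*lambda_max
        np.linalg.cholesky(A)

    def test_full_rank_gram_untouched(self, quintet_strand_spec):
        sigs = random_signature_set(15, quintet_strand_spec, seed=7,
                                    min_separation=0.4)
        S = signature_matrix(sigs)
        gram = S.T @ S
        corrected = nearest_positive_definite(gram)
        rel = np.abs(corrected - gram) / np.abs(gram)
        assert rel.max() < 3e-15

    def test_rank_deficient_gram_becomes_pd(self, triplet_spec):
        sigs = random_signature_set(2, triplet_spec, seed=5)
        dup = ShiraishiSignature(sigs[0].matrix.copy(), triplet_spec, name="dup")
        S = signature_matrix(sigs + [dup])
        gram = S.T @ S
        assert np.linalg.eigvalsh(gram)[0] < 1e-12
        corrected = nearest_positive_definite(gram)
        np.linalg.cholesky(corrected)
        assert np.abs(corrected - gram).max() < 1e-6

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError):
            nearest_positive_definite(np.array([[1.0, 2.0], [0.0, 1.0]]))


class TestSolveExposures:
    def test_single_signature_forced_to_one(self, rng):
        S = rng.dirichlet(np.ones(5)).reshape(-1, 1)
        exposures, _ = solve_exposures(rng.dirichlet(np.ones(5)), S)
        assert exposures.weights[0] == 1.0

    def test_in_span_solution_exact(self):
        S = np.array([[1.0, 0.0], [0.0, 1.0]])
        exposures, rss = solve_exposures(np.array([0.3, 0.7]), S)
        np.testing.assert_allclose(exposures.weights, [0.3, 0.7], atol=1e-9)
        assert rss < 1e-18

    def test_vertex_solution(self):
        S = np.array([[0.8, 0.2], [0.2, 0.8]])
        exposures, rss = solve_exposures(np.array([0.9, 0.1]), S)
        np.testing.assert_allclose(exposures.weights, [1.0, 0.0], atol=1e-6)
        assert rss == pytest.approx(0.02, abs=1e-9)

    def test_matches_grid_oracle_on_random_instances(self, rng):
        """100 random (K<=3, P<=10) instances against brute-force simplex
        grid search at step 1e-3, agreement within 2e-3 per weight."""
        for i in range(100):
            K = int(rng.integers(1, 4))
            P = int(rng.integers(2, 11))
            S = rng.random((P, K))
            g = rng.random(P)
            exposures, _ = solve_exposures(g, S)
            w_grid = grid_search(g, S, step=1e-3)
            assert np.abs(exposures.weights - w_grid).max() < 2e-3, f"instance {i}"

    def test_exact_recovery_of_simplex_mixtures(self, rng):
        """g = S w_true with S full column rank recovers w_true to 1e-6."""
        for _ in range(20):
            K, P = 5, 24
            S = rng.random((P, K))
            w_true = rng.dirichlet(np.ones(K))
            exposures, rss = solve_exposures(S @ w_true, S)
            assert np.abs(exposures.weights - w_true).max() < 1e-6
            assert rss < 1e-16

    def test_permutation_equivariance(self, rng):
        S = rng.random((10, 4))
        g = rng.random(10)
        w, _ = solve_exposures(g, S)
        perm = rng.permutation(4)
        w_p, _ = solve_exposures(g, S[:, perm])
        np.testing.assert_allclose(w_p.weights, w.weights[perm], atol=1e-9)

    def test_weights_clamped_and_normalized(self, rng):
        S = rng.random((6, 3))
        exposures, _ = solve_exposures(rng.random(6), S)
        assert np.all(exposures.weights >= 0)
        assert exposures.weights.sum() == pytest.approx(1.0, abs=1e-12)


class TestExplainedVariance:
    def test_perfect_fit_is_one(self, deamination):
        g = flatten(deamination)
        assert explained_variance(g, spec=deamination.spec, g_hat=g) == 1.0

    def test_flat_prediction_is_zero(self, quintet_strand_spec, deamination):
        g = flatten(deamination)
        ref = flatten(flat_genome(quintet_strand_spec))
        assert explained_variance(g, spec=quintet_strand_spec,
                                  g_hat=ref) == pytest.approx(0.0, abs=1e-12)

    def test_direct_formula_agreement(self, triplet_set):
        """Two-signature fit of a toy profile: R^2 must equal the formula
        evaluated independently with numpy on the flat-genome baseline."""
        S = signature_matrix(triplet_set[:2])
        w = np.array([0.6, 0.4])
        g = S @ w + 0.01  # slight off-model shift, still row-normalized sums
        spec = triplet_set[0].spec
        ghat = S @ w
        expect = 1 - np.sum((g - ghat) ** 2) / np.sum(
            (g - flatten(flat_genome(spec))) ** 2)
        assert explained_variance(g, spec=spec, g_hat=ghat) == pytest.approx(
            expect, abs=1e-14)

    def test_alexandrov_uses_mean_baseline(self, rng):
        g = rng.dirichlet(np.ones(96))
        ghat = rng.dirichlet(np.ones(96))
        spec = ContextSpec(1, 1, False, "alexandrov")
        expect = 1 - np.sum((g - ghat) ** 2) / np.sum((g - g.mean()) ** 2)
        assert explained_variance(g, spec=spec, g_hat=ghat) == pytest.approx(
            expect, abs=1e-14)

    def test_flat_profile_degenerate(self, triplet_spec):
        flat = flat_genome(triplet_spec)
        with pytest.raises(ValueError, match="flat genome"):
            explained_variance(flat, g_hat=flatten(flat))


class TestDecomposeTumor:
    def _profile_from(self, sigs, w, spec):
        S = signature_matrix(sigs)
        g = S @ np.asarray(w)
        matrix = np.zeros((spec.n_rows, 6))
        widths = spec.row_widths()
        offset = 0
        for r, width in enumerate(widths):
            matrix[r, :width] = g[offset:offset + width]
            offset += width
        return GenomeProfile(matrix, spec, n_mutations=100)

    def test_full_set_equals_plain_solve(self, triplet_set, triplet_spec):
        profile = self._profile_from(triplet_set, [0.4, 0.3, 0.2, 0.1],
                                     triplet_spec)
        res = decompose_tumor(profile, triplet_set)
        exposures, rss = solve_exposures(profile, triplet_set)
        np.testing.assert_allclose(res.exposures.weights, exposures.weights,
                                   atol=1e-9)
        assert res.rss == pytest.approx(rss, abs=1e-12)
        assert res.subset == tuple(s.name for s in triplet_set)
        assert res.threshold_reached is None

    def test_threshold_zero_returns_smallest_k(self, triplet_set, triplet_spec):
        profile = self._profile_from(triplet_set, [0.4, 0.3, 0.2, 0.1],
                                     triplet_spec)
        res = decompose_tumor(profile, triplet_set, min_explained_variance=0.0)
        assert len(res.subset) == 2
        assert res.threshold_reached is True

    def test_generating_pair_recovered(self, triplet_spec):
        """A 2-of-4 mixture at (0.6, 0.4) must be identified exactly by the
        subset search with a 0.95 threshold."""
        sigs = random_signature_set(4, triplet_spec, seed=23,
                                    min_separation=0.5)
        profile = self._profile_from([sigs[1], sigs[3]], [0.6, 0.4],
                                     triplet_spec)
        res = decompose_tumor(profile, sigs, min_explained_variance=0.95)
        assert res.threshold_reached is True
        assert set(res.subset) == {sigs[1].name, sigs[3].name}
        w = res.exposures.as_dict()
        assert w[sigs[1].name] == pytest.approx(0.6, abs=0.02)
        assert w[sigs[3].name] == pytest.approx(0.4, abs=0.02)

    def test_unreachable_threshold_flagged(self, triplet_set, triplet_spec):
        profile = self._profile_from(triplet_set, [0.4, 0.3, 0.2, 0.1],
                                     triplet_spec)
        res = decompose_tumor(profile, triplet_set,
                              min_explained_variance=1.0 + 1e-9)
        assert res.threshold_reached is False

    def test_exhaustive_matches_brute_force_subsets(self, triplet_spec):
        sigs = random_signature_set(5, triplet_spec, seed=31)
        profile = self._profile_from([sigs[0], sigs[2]], [0.7, 0.3],
                                     triplet_spec)
        res = decompose_tumor(profile, sigs, min_num_signatures=2,
                              max_num_signatures=2)
        g = flatten(profile)
        S = signature_matrix(sigs)
        best_ev, best_subset = -np.inf, None
        for subset in itertools.combinations(range(5), 2):
            w, _ = SimplexSolver(S[:, subset]).solve(g)
            ev = explained_variance(g, spec=triplet_spec,
                                    g_hat=S[:, subset] @ w)
            if ev > best_ev:
                best_ev, best_subset = ev, subset
        assert res.subset == tuple(sigs[i].name for i in best_subset)
        assert res.explained_variance == pytest.approx(best_ev, abs=1e-12)

    def test_bad_arguments(self, triplet_set, triplet_spec):
        profile = self._profile_from(triplet_set, [0.25] * 4, triplet_spec)
        with pytest.raises(ValueError):
            decompose_tumor(profile, [])
        with pytest.raises(ValueError):
            decompose_tumor(profile, triplet_set, min_num_signatures=3,
                            max_num_signatures=2)
        with pytest.raises(ValueError):
            decompose_tumor(profile, triplet_set, min_explained_variance=0.9,
                            subset_cap=1)

    def test_greedy_fallback_under_cap(self, triplet_spec):
        sigs = random_signature_set(4, triplet_spec, seed=23,
                                    min_separation=0.5)
        profile = self._profile_from([sigs[1], sigs[3]], [0.6, 0.4],
                                     triplet_spec)
        res = decompose_tumor(profile, sigs, min_explained_variance=0.95,
                              subset_cap=1, greedy=True)
        assert res.threshold_reached is True
        assert set(res.subset) == {sigs[1].name, sigs[3].name}


class TestExplainedVarianceCurve:
    def test_curve_monotone_and_ends_at_full_fit(self, triplet_set,
                                                 triplet_spec):
        profile = TestDecomposeTumor()._profile_from(
            triplet_set, [0.4, 0.3, 0.2, 0.1], triplet_spec)
        curve = explained_variance_curve(profile, triplet_set)
        assert [k for k, _, _ in curve] == [1, 2, 3, 4]
        evs = [ev for _, ev, _ in curve]
        assert all(b >= a - 1e-9 for a, b in zip(evs, evs[1:]))
        full = decompose_tumor(profile, triplet_set)
        assert evs[-1] == pytest.approx(full.explained_variance, abs=1e-10)

    def test_duplicate_signature_plateaus(self, triplet_spec):
        sigs = random_signature_set(2, triplet_spec, seed=3, min_separation=0.3)
        dup = ShiraishiSignature(sigs[1].matrix.copy(), triplet_spec, name="dup")
        all_sigs = sigs + [dup]
        profile = TestDecomposeTumor()._profile_from(
            sigs, [0.5, 0.5], triplet_spec)
        curve = explained_variance_curve(profile, all_sigs)
        assert curve[1][1] == pytest.approx(curve[2][1], abs=1e-9)
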