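"""DSMs, representational models, correlations, ceiling, split-half."""

import numpy as np
import pytest
from scipy import stats as sps

from soundcat.rsa import (
    DSM,
    MODEL_NAMES,
    build_model_dsms,
    compute_brain_dsm,
    correlate_model,
    cross_roi_correlation,
    noise_ceiling_lower,
    partial_correlate_model,
    split_half_matrix,
    split_half_stability,
    subject_dsm,
)
from soundcat.stimuli import CATEGORIES


def _random_dsm(rng, n=8):
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return DSM(m)


class TestBrainDsm:
    def test_identical_patterns_zero_offdiagonal(self):
        P = np.tile(np.array([1.0, 2.0, 5.0, -1.0]), (8, 1))
        P += np.arange(8)[:, None]  # per-pattern offsets leave r = 1
        d = compute_brain_dsm(P)
        np.testing.assert_allclose(d.values, 0.0, atol=1e-12)

    def test_hand_computed_entry(self):
        """Patterns (1,0,0) and (0,1,0) have Pearson r = −0.5, distance 1.5."""
        P = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        d = compute_brain_dsm(P)
        assert d.values[0, 1] == pytest.approx(1.5)

    def test_per_pattern_affine_invariance(self, rng):
        P = rng.normal(size=(8, 30))
        d1 = compute_brain_dsm(P)
        Q = P.copy()
        Q[3] = 2.7 * Q[3] + 5.0  # positive affine map of one pattern
        d2 = compute_brain_dsm(Q)
        np.testing.assert_allclose(d1.values, d2.values, atol=1e-10)

    def test_zero_variance_names_condition(self):
        P = np.ones((8, 5))
        P[:7] += np.random.default_rng(0).normal(size=(7, 5))
        with pytest.raises(ValueError, match="7"):
            compute_brain_dsm(P)

    def test_dsm_invariants_enforced(self, rng):
        with pytest.raises(ValueError, match="symmetric"):
            DSM(rng.normal(size=(4, 4)))
        bad = np.eye(3)
        with pytest.raises(ValueError, match="diagonal"):
            DSM(bad)


class TestModelDsms:
    def test_seven_models_emitted(self, stimuli, rng):
        ratings = {f"s{i}": _random_dsm(rng).values for i in range(3)}
        models = build_model_dsms(stimuli, ratings)
        assert tuple(models) == MODEL_NAMES
        for m in models.values():
            assert m.n == 8

    def test_human_composite_entries(self, stimuli):
        m = build_model_dsms(stimuli)["human"]
        hv, hn = CATEGORIES.index("human_vocalization"), CATEGORIES.index("human_nonvocalization")
        others = [i for i in range(8) if i not in (hv, hn)]
        assert m.values[hv, hn] == 0.0
        for o in others:
            assert m.values[hv, o] == 1.0 and m.values[hn, o] == 1.0
        for i in others:
            for j in others:
                if i != j:
                    assert m.values[i, j] == 0.5

    def test_constant_pitch_gives_zero_model(self, stimuli):
        flat = stimuli.copy()
        flat["pitch"] = 440.0
        m = build_model_dsms(flat)["pitch"]
        np.testing.assert_array_equal(m.values, 0.0)


class TestCorrelations:
    def test_self_and_monotone_transform(self, rng):
        d = _random_dsm(rng)
        assert correlate_model(d, d) == pytest.approx(1.0)
        mono = DSM(np.exp(d.values) - 1.0)  # strictly increasing, zero-preserving
        assert correlate_model(d, mono) == pytest.approx(1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        for _ in range(200):
            a, b = _random_dsm(rng), _random_dsm(rng)
            rho = correlate_model(a, b)
            ra, rb = sps.rankdata(a.vec), sps.rankdata(b.vec)
            assert rho == pytest.approx(np.corrcoef(ra, rb)[0, 1], abs=1e-10)

    def test_constant_vector_flagged_nan(self, rng):
        const = DSM(np.ones((4, 4)) - np.eye(4))
        assert np.isnan(correlate_model(const, _random_dsm(rng, 4)))


class TestPartialCorrelation:
    def test_orthogonal_covariate_keeps_simple_rho(self, rng):
        a, b = _random_dsm(rng), _random_dsm(rng)
        cov = _random_dsm(rng)  # independent random covariate
        simple = correlate_model(a, b)
        partial = partial_correlate_model(a, b, [cov])
        assert abs(partial - simple) < 0.25

    def test_first_order_closed_form(self, rng):
        """Single covariate matches (r_xy − r_xz r_yz)/√((1−r_xz²)(1−r_yz²))
        on ranks."""
        for _ in range(100):
            x, y, z = (_random_dsm(rng) for _ in range(3))
            rx, ry, rz = (sps.rankdata(v.vec) for v in (x, y, z))
            rxy = np.corrcoef(rx, ry)[0, 1]
            rxz = np.corrcoef(rx, rz)[0, 1]
            ryz = np.corrcoef(ry, rz)[0, 1]
            expected = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
            got = partial_correlate_model(x, y, [z])
            assert got == pytest.approx(expected, abs=1e-10)

    def test_model_among_covariates_raises(self, rng):
        a, b = _random_dsm(rng), _random_dsm(rng)
        with pytest.raises(ValueError, match="covariate"):
            partial_correlate_model(a, b, [b])

    def test_collinear_covariates_raise(self, rng):
        a, b, z = (_random_dsm(rng) for _ in range(3))
        with pytest.raises(ValueError, match="collinear"):
            partial_correlate_model(a, b, [z, z])


class TestCrossRoi:
    def test_identical_dsms(self, rng):
        d = _random_dsm(rng)
        rho, p = cross_roi_correlation(d, d, n_perm=200, seed=0)
        assert rho == pytest.approx(1.0)
        assert p <= 0.05

    def test_permutation_preserves_entry_multiset(self, rng):
        d = _random_dsm(rng)
        perm = rng.permutation(8)
        assert sorted(d.permuted(perm).vec) == pytest.approx(sorted(d.vec))

    def test_p_uniform_under_independence(self, rng):
        """p-values over independent random DSM pairs are approximately
        uniform (calibration over 200 replicates)."""
        ps = [
            cross_roi_correlation(_random_dsm(rng), _random_dsm(rng),
                                  n_perm=200, seed=k)[1]
            for k in range(200)
        ]
        assert abs(np.mean(ps) - 0.5) < 2.5 / np.sqrt(12 * len(ps))
        assert sps.kstest(ps, "uniform").pvalue > 0.005


class TestNoiseCeiling:
    def test_identical_subjects_bound_one(self, rng):
        d = _random_dsm(rng)
        assert noise_ceiling_lower([d, d, d, d]) == pytest.approx(1.0)

    def test_independent_dsms_bound_near_zero(self, rng):
        bounds = [
            noise_ceiling_lower([_random_dsm(rng) for _ in range(5)])
            for _ in range(100)
        ]
        se = np.std(bounds, ddof=1) / np.sqrt(len(bounds))
        assert abs(np.mean(bounds)) < 3 * se + 0.02

    def test_monotone_in_shared_structure(self, rng):
        shared = _random_dsm(rng).values
        means = []
        for noise in (0.01, 0.3, 3.0):
            vals = []
            for _ in range(30):
                subs = []
                for _ in range(5):
                    m = shared + rng.normal(0, noise, shared.shape)
                    m = (m + m.T) / 2
                    np.fill_diagonal(m, 0)
                    subs.append(DSM(m))
                vals.append(noise_ceiling_lower(subs))
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_too_few_subjects_raises(self, rng):
        with pytest.raises(ValueError):
            noise_ceiling_lower([_random_dsm(rng), _random_dsm(rng)])


class TestSplitHalf:
    def test_orthogonal_identical_halves(self):
        """Identical halves with orthogonal equal-variance stimulus patterns
        give on-diagonal 1, off-diagonal ~0, stability ~1."""
        patterns = np.eye(24)  # 24 orthogonal patterns over 24 voxels
        patterns = patterns - patterns.mean(axis=1, keepdims=True)
        B = np.stack([patterns, patterns])  # 2 identical runs
        s = split_half_stability(B)
        assert s == pytest.approx(1.0 + 1.0 / 23.0, abs=1e-10)  # centred eye
        C = split_half_matrix(B)
        np.testing.assert_allclose(np.diag(C), 1.0, atol=1e-10)

    def test_pure_noise_stability_near_zero(self):
        vals = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            vals.append(split_half_stability(rng.normal(size=(4, 24, 30))))
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * se + 0.01

    def test_matrix_matches_double_loop(self, rng):
        B = rng.normal(size=(5, 24, 12))
        C = split_half_matrix(B)
        A = B[[0, 2, 4]].mean(axis=0)
        Bm = B[[1, 3]].mean(axis=0)
        for i in range(24):
            for j in range(24):
                assert C[i, j] == pytest.approx(
                    np.corrcoef(A[i], Bm[j])[0, 1], abs=1e-10
                )

    def test_single_run_raises(self, rng):
        with pytest.raises(ValueError):
            split_half_stability(rng.normal(size=(1, 24, 10)))


def test_subject_dsm_shape(signal_betas):
    d = subject_dsm(signal_betas["occipital"].subject("blind01"))
    assert d.n == 8 and len(d.vec) == 28
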