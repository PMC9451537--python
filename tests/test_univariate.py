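"""Contrasts, LOSO ROI definition, category β extraction, mixed ANOVA."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest

import soundcat as sc
from soundcat.stimuli import SUPERORDINATE_ORDER
from soundcat.synth import BetaArray
from soundcat.univariate import (
    ROIMask,
    define_roi_loso,
    extract_category_betas,
    mixed_anova,
    mixed_anova_2x4,
    sound_vs_baseline_contrast,
)


def _beta(vals, roi="occipital", sids=None):
    sids = sids or [f"s{i}" for i in range(vals.shape[0])]
    return BetaArray(values=vals, subject_ids=sids, roi=roi)


class TestContrast:
    def test_zero_and_constant(self):
        z = _beta(np.zeros((2, 5, 24, 7)))
        np.testing.assert_array_equal(sound_vs_baseline_contrast(z), 0.0)
        c = _beta(np.full((2, 5, 24, 7), 3.25))
        np.testing.assert_allclose(sound_vs_baseline_contrast(c), 3.25)

    def test_matches_brute_force_mean(self, rng):
        vals = rng.normal(size=(3, 5, 24, 6))
        got = sound_vs_baseline_contrast(_beta(vals))
        for s in range(3):
            for v in range(6):
                acc = [vals[s, r, c, v] for r in range(5) for c in range(24)]
                assert got[s, v] == pytest.approx(np.mean(acc), rel=1e-12)


class TestLosoRoi:
    def _planted(self, rng, planted):
        coh = sc.generate_cohort({"a": 5, "b": 5}, seed=0)
        maps = rng.normal(0, 0.1, size=(10, 100))
        amp = np.zeros(100)
        amp[planted] = 5.0
        maps[:5] += amp  # group a subjects boosted on the planted set
        return coh, maps

    def test_recovers_planted_set(self, rng):
        planted = [3, 17, 42, 77]
        coh, maps = self._planted(rng, planted)
        roi = define_roi_loso(maps, coh, "a01", "a", "b", k_voxels=4)
        assert sorted(roi.voxel_indices) == sorted(planted)
        assert roi.excluded_subject_id == "a01"

    def test_own_data_does_not_change_own_roi(self, rng):
        coh, maps = self._planted(rng, [1, 2])
        roi1 = define_roi_loso(maps, coh, "a01", "a", "b", k_voxels=10)
        maps2 = maps.copy()
        maps2[0] = rng.normal(size=100) * 100  # perturb only a01's map
        roi2 = define_roi_loso(maps2, coh, "a01", "a", "b", k_voxels=10)
        np.testing.assert_array_equal(roi1.voxel_indices, roi2.voxel_indices)

    def test_direction_swap_exchanges_rois(self, rng):
        coh = sc.generate_cohort({"a": 4, "b": 4}, seed=1)
        maps = rng.normal(0, 0.1, size=(8, 50))
        maps[:4, :5] += 4.0   # a-favoured voxels 0-4
        maps[4:, 45:] += 4.0  # b-favoured voxels 45-49
        roi_ab = define_roi_loso(maps, coh, "a01", "a", "b", k_voxels=5)
        roi_ba = define_roi_loso(maps, coh, "a01", "b", "a", k_voxels=5)
        assert sorted(roi_ab.voxel_indices) == [0, 1, 2, 3, 4]
        assert sorted(roi_ba.voxel_indices) == [45, 46, 47, 48, 49]

    def test_threshold_mode_empty_raises(self, rng):
        coh, maps = self._planted(rng, [0])
        with pytest.raises(ValueError, match="k_voxels"):
            define_roi_loso(maps, coh, "a01", "a", "b", threshold=1e9)


class TestExtractCategoryBetas:
    def test_constant_one(self, stimuli):
        b = _beta(np.ones((2, 5, 24, 10)))
        roi = ROIMask(np.arange(10), "r", n_voxels_total=10)
        out = extract_category_betas(b, roi, stimuli)
        assert list(out.columns) == SUPERORDINATE_ORDER
        np.testing.assert_allclose(out.to_numpy(), 1.0)

    def test_planted_human_signal(self, stimuli):
        vals = np.zeros((1, 5, 24, 10))
        human_rows = stimuli.index[stimuli["superordinate"] == "human"]
        vals[:, :, list(human_rows), :] = 2.0
        out = extract_category_betas(
            _beta(vals), ROIMask(np.arange(10), "r", n_voxels_total=10), stimuli
        )
        assert out.loc["s0", "human"] == pytest.approx(2.0)
        for other in ("animal", "manipulable", "big_place"):
            assert out.loc["s0", other] == pytest.approx(0.0)

    def test_matches_triple_loop(self, stimuli, rng):
        vals = rng.normal(size=(2, 3, 24, 8))
        roi = ROIMask(np.array([1, 4, 6]), "r", n_voxels_total=8)
        out = extract_category_betas(_beta(vals), roi, stimuli)
        sup = stimuli.sort_values("stimulus_id")["superordinate"].to_numpy()
        for s in range(2):
            for cat in SUPERORDINATE_ORDER:
                acc = [
                    vals[s, r, c, v]
                    for r in range(3)
                    for c in range(24)
                    if sup[c] == cat
                    for v in (1, 4, 6)
                ]
                assert out.iloc[s][cat] == pytest.approx(np.mean(acc), rel=1e-10)

    def test_grid_mismatch_raises(self, stimuli):
        b = _beta(np.ones((1, 2, 24, 5)))
        roi = ROIMask(np.array([0, 1]), "r", n_voxels_total=9)
        with pytest.raises(ValueError, match="grid"):
            extract_category_betas(b, roi, stimuli)


class TestMixedAnova:
    def test_identical_groups_zero_f(self, rng):
        block = rng.normal(size=(6, 4))
        data = np.vstack([block, block])
        groups = np.array(["a"] * 6 + ["b"] * 6)
        res = mixed_anova(data, groups)
        assert res.F("Group") == pytest.approx(0.0, abs=1e-20)
        assert res.F("Interaction") == pytest.approx(0.0, abs=1e-10)

    def test_ss_partition_additive(self, rng):
        for _ in range(20):
            n_a, n_b = rng.integers(3, 9, size=2)
            data = rng.normal(size=(n_a + n_b, 4))
            groups = np.array(["a"] * n_a + ["b"] * n_b)
            p = mixed_anova(data, groups).ss_partition
            parts = (
                p["group"] + p["subjects_within_groups"] + p["within"]
                + p["interaction"] + p["error_within"]
            )
            assert parts == pytest.approx(p["total"], rel=1e-8)

    def test_matches_pingouin(self, rng):
        """Independent cross-check of F statistics on balanced data."""
        data = rng.normal(size=(12, 4)) + np.arange(4) * 0.3
        data[:6] += 0.5
        groups = np.array(["a"] * 6 + ["b"] * 6)
        res = mixed_anova(data, groups, gg_correction=False)
        long = pd.DataFrame(
            {
                "y": data.reshape(-1),
                "subject": np.repeat(np.arange(12), 4),
                "cond": np.tile(np.arange(4), 12),
                "group": np.repeat(groups, 4),
            }
        )
        ref = pg.mixed_anova(
            long, dv="y", within="cond", subject="subject", between="group"
        ).set_index("Source")
        assert res.F("Group") == pytest.approx(ref.loc["group", "F"], rel=1e-6)
        assert res.F("Category") == pytest.approx(ref.loc["cond", "F"], rel=1e-6)
        assert res.F("Interaction") == pytest.approx(ref.loc["Interaction", "F"], rel=1e-6)
        assert res.p("Group") == pytest.approx(ref.loc["group", "p_unc"], rel=1e-6)

    def test_crossover_interaction_power(self, rng):
        """A 1-SD crossover Group×Category effect at n=16/group is detected
        (p < .05) in at least 80% of simulations."""
        pattern = np.array([0.5, -0.5, 0.5, -0.5])
        hits = 0
        n_sim = 200
        groups = np.array(["a"] * 16 + ["b"] * 16)
        for _ in range(n_sim):
            data = rng.normal(size=(32, 4))
            data[:16] += pattern
            data[16:] -= pattern
            if mixed_anova(data, groups).p("Interaction") < 0.05:
                hits += 1
        assert hits / n_sim >= 0.80

    def test_single_group_raises(self, rng):
        with pytest.raises(ValueError):
            mixed_anova(rng.normal(size=(5, 4)), np.array(["a"] * 5))
        with pytest.raises(ValueError):
            mixed_anova(rng.normal(size=(3, 4)), np.array(["a", "a", "b"]))

    def test_age_covariate_residualisation(self, rng):
        """When group differences are pure age effects, including age as a
        covariate removes the Group effect."""
        coh = sc.generate_cohort(
            {"a": 10, "b": 10},
            age_ranges={"a": (20.0, 30.0), "b": (50.0, 60.0)},
            seed=3,
        )
        age = np.asarray(coh.subjects["age"], dtype=float)
        data = rng.normal(0, 0.2, size=(20, 4)) + 0.2 * age[:, None]
        df = pd.DataFrame(data, columns=SUPERORDINATE_ORDER, index=coh.ids())
        f_raw = mixed_anova_2x4(df, coh, use_age_covariate=False).F("Group")
        f_adj = mixed_anova_2x4(df, coh, use_age_covariate=True).F("Group")
        assert f_adj < f_raw
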