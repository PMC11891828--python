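import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from orca.chunking import Chunk
from orca.profiling import (
    ResponseRecord,
    benjamini_hochberg,
    build_profile,
    dose_category,
    group_significance,
    scale_profile,
    significance,
)

DT = 1.0 / 1.66


def noise_chunk(noise_sd=0.01, seed=0):
    rng = np.random.default_rng(seed)
    t_rel = np.arange(-10.0, 40.0, DT)
    v = rng.normal(0.0, noise_sd, t_rel.size)
    return Chunk("SYNT", t_rel, v, np.zeros_like(v), -2, 0, 100.0)


def record(code, dilution, magnitude, animal=0):
    return ResponseRecord("orX", code, dilution, animal, magnitude, 0.01, True)


class TestSignificance:
    def test_three_sigma_magnitude_is_significant(self):
        ch = noise_chunk()
        sd = np.std(ch.pre_stimulus(), ddof=1)
        flag, _ = significance(ch, 3.0 * sd)
        assert flag

    def test_two_sigma_magnitude_is_not(self):
        ch = noise_chunk()
        sd = np.std(ch.pre_stimulus(), ddof=1)
        flag, _ = significance(ch, 2.0 * sd)
        assert not flag

    def test_negative_magnitude_uses_absolute_value(self):
        ch = noise_chunk()
        sd = np.std(ch.pre_stimulus(), ddof=1)
        flag, _ = significance(ch, -3.0 * sd)
        assert flag

    def test_too_few_noise_frames_raises(self):
        ch = noise_chunk()
        with pytest.raises(ValueError, match="noise frames"):
            significance(ch, 1.0, baseline_t=-9.5)

    def test_group_test_separates_clear_from_borderline(self):
        rng = np.random.default_rng(0)
        sds = np.full(10, 0.01)
        clearly_above = 2.5 * sds * 3 + rng.normal(0, 0.002, 10)
        assert group_significance(clearly_above, sds)
        at_threshold = 2.5 * sds + rng.normal(0, 0.005, 10)
        assert not group_significance(at_threshold, sds)

    def test_group_test_null_rate_controlled(self):
        # magnitudes fluctuating about the threshold reject at ~alpha
        rng = np.random.default_rng(1)
        rejections = 0
        for _ in range(200):
            sds = np.full(8, 0.01)
            mags = 2.5 * sds + rng.normal(0, 0.004, 8)
            rejections += group_significance(mags, sds)
        assert rejections <= 10  # ~alpha=0.01 of 200, with head room

    def test_group_converges_to_per_recording_flag_without_variance(self):
        sds = np.full(6, 0.01)
        assert group_significance(np.full(6, 0.026), sds)
        assert not group_significance(np.full(6, 0.024), sds)

    def test_benjamini_hochberg_rejects_small_pvalues_only(self):
        p = np.array([0.001, 0.002, 0.2, 0.8, 0.003])
        rejected = benjamini_hochberg(p, alpha=0.05)
        assert rejected.tolist() == [True, True, False, False, True]
        assert not benjamini_hochberg(np.array([0.2, 0.5, 0.9]), alpha=0.05).any()


class TestDoseCategory:
    @pytest.mark.parametrize(
        "flags, expected, non_mono",
        [
            ({-6: True, -4: True, -2: True}, 3, False),
            ({-6: False, -4: True, -2: True}, 2, False),
            ({-6: False, -4: False, -2: True}, 1, False),
            ({-6: False, -4: False, -2: False}, 0, False),
            ({-6: True, -4: False, -2: True}, 1, True),
            ({-6: True, -4: True, -2: False}, 0, True),
        ],
    )
    def test_contiguous_from_top_rule(self, flags, expected, non_mono):
        category, flag = dose_category(flags, (-6, -4, -2))
        assert category == expected
        assert flag == non_mono

    def test_missing_level_raises(self):
        with pytest.raises(ValueError, match="missing dilution"):
            dose_category({-6: True, -2: True}, (-6, -4, -2))

    @settings(derandomize=True, max_examples=40)
    @given(st.tuples(st.booleans(), st.booleans(), st.booleans()), st.integers(0, 2))
    def test_upgrading_a_flag_never_decreases_category(self, flags, i):
        dil = (-6, -4, -2)
        base = dict(zip(dil, flags))
        upgraded = dict(base)
        upgraded[dil[i]] = True
        c0, _ = dose_category(base, dil)
        c1, _ = dose_category(upgraded, dil)
        assert c1 >= c0


class TestProfile:
    def test_single_record_median_is_that_magnitude(self):
        table = build_profile([record("AAAA", -2, 0.37)])
        assert table.loc["AAAA", -2] == pytest.approx(0.37)

    def test_median_robust_to_outlier_animal(self):
        recs = [record("AAAA", -2, m, animal=i) for i, m in enumerate([1.0, 2.0, 100.0])]
        table = build_profile(recs)
        assert table.loc["AAAA", -2] == pytest.approx(2.0)

    def test_sorted_descending_with_negatives_last(self):
        recs = [
            record("POSB", -2, 0.5),
            record("POSA", -2, 0.9),
            record("NEGC", -2, -0.2),
        ]
        assert list(build_profile(recs).index) == ["POSA", "POSB", "NEGC"]

    def test_rank_order_follows_designed_potency(self):
        # ground-truth magnitudes from the generator keep their potency
        # ranking in the profile at a non-saturating dilution
        from orca.synthetic import example_mix, make_dataset

        mix = example_mix(seed=9)
        ds = make_dataset(mix)
        recs = [
            ResponseRecord("orX", code, d, a, gt.magnitude, 0.001, True)
            for (a, code, d), gt in ds.ground_truth.items()
            if not any(
                ev.code == code and ev.is_contaminant for ev in mix.odorants
            )
        ]
        table = build_profile(recs, reporting_dilution=-4)
        mags = {ev.code: ds.ground_truth[(0, ev.code, -4)].magnitude
                for ev in mix.odorants if not ev.is_contaminant}
        expected = sorted(mags, key=mags.get, reverse=True)
        assert list(table.sort_values(by=-4, ascending=False).index) == expected

    @settings(derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 1000))
    def test_median_invariant_to_order_and_duplication(self, seed):
        rng = np.random.default_rng(seed)
        mags = rng.normal(0, 1, 5)
        recs = [record("AAAA", -2, m, animal=i) for i, m in enumerate(mags)]
        base = build_profile(recs).loc["AAAA", -2]
        shuffled = build_profile(list(reversed(recs))).loc["AAAA", -2]
        duplicated = build_profile(recs + recs).loc["AAAA", -2]
        assert shuffled == pytest.approx(base)
        assert duplicated == pytest.approx(base)


class TestScaleProfile:
    def test_affine_map_of_three_values(self):
        scaled = scale_profile([10.0, 5.0, 0.0], top_k=3)
        assert sorted(scaled.to_list(), reverse=True) == pytest.approx([1.0, 0.5, 0.0])

    def test_top_k_larger_than_panel_warns_and_uses_all(self):
        with pytest.warns(UserWarning, match="whole panel"):
            scaled = scale_profile([3.0, 1.0], top_k=20)
        assert len(scaled) == 2

    def test_preserves_rank_order(self):
        rng = np.random.default_rng(3)
        values = rng.normal(0, 1, 30)
        scaled = scale_profile(values, top_k=20)
        original = [values[i] for i in scaled.index]
        assert np.array_equal(np.argsort(scaled.to_numpy()), np.argsort(original))

    def test_constant_values_raise(self):
        with pytest.raises(ValueError, match="undefined"):
            scale_profile([1.0, 1.0, 1.0], top_k=3)
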