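import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from orca.chunking import Chunk
from orca.ln_model import (
    FitResult,
    LNParams,
    bic_score,
    classify_polarity,
    fit,
    select_model,
    simulate,
    simulate_reference,
)
from orca.preprocessing import Trace

DT = 1.0 / 1.66


def step_trace(duration=200.0, dt=0.1):
    t = np.arange(0.0, duration, dt)
    return Trace(t, np.ones_like(t), "fid")


class TestSimulate:
    def test_zero_stimulus_gives_zero_response(self, chunk_grid):
        t_rel, _ = chunk_grid
        p = LNParams(k_a=0.5, k_af=0.4, k_f=0.12)
        r = simulate(p, Trace(t_rel, np.zeros_like(t_rel), "fid"))
        assert np.allclose(r.v, 0.0)

    def test_step_steady_state_is_gain_over_decay(self, one_comp_truth):
        r = simulate(one_comp_truth, step_trace())
        expected = one_comp_truth.k_af / one_comp_truth.k_f
        assert r.v[-1] == pytest.approx(expected, rel=1e-3)

    def test_step_response_matches_closed_form(self):
        # for s == 1: A = 1 - exp(-k_a t) and
        # CF = k_af/(k_f (k_a - k_f)) [(k_a - k_f) - k_a e^{-k_f t} + k_f e^{-k_a t}]
        k_a, k_af, k_f = 0.7, 0.3, 0.15
        st_ = step_trace(120.0, 0.05)
        r = simulate(LNParams(k_a=k_a, k_af=k_af, k_f=k_f), st_)
        t = st_.t
        exact = (
            k_af
            / (k_f * (k_a - k_f))
            * ((k_a - k_f) - k_a * np.exp(-k_f * t) + k_f * np.exp(-k_a * t))
        )
        assert np.abs(r.v - exact).max() < 1e-5 * exact.max()

    def test_matches_fine_step_reference(self, chunk_grid):
        t_rel, stim = chunk_grid
        st_ = Trace(t_rel, stim, "fid")
        p = LNParams(
            k_a=0.8, k_af=0.5, k_f=0.2, k_as=-0.1, k_s=0.07, d_as=3.0, n_components=2
        )
        r = simulate(p, st_).v
        ref = simulate_reference(p, st_, refine=100).v
        assert np.abs(r - ref).max() < 1e-4 * np.abs(ref).max()

    def test_negative_stimulus_rejected(self, chunk_grid):
        t_rel, _ = chunk_grid
        with pytest.raises(ValueError, match="non-negative"):
            simulate(LNParams(k_a=1, k_af=1, k_f=1), Trace(t_rel, -np.ones_like(t_rel)))

    def test_polarity_flips_sign(self, chunk_grid):
        t_rel, stim = chunk_grid
        st_ = Trace(t_rel, stim, "fid")
        pos = simulate(LNParams(k_a=0.5, k_af=0.4, k_f=0.12), st_).v
        neg = simulate(LNParams(k_a=0.5, k_af=0.4, k_f=0.12, polarity=-1), st_).v
        assert np.allclose(pos, -neg)

    @settings(derandomize=True, max_examples=15)
    @given(c=st.floats(0.1, 10.0))
    def test_linearity_in_gains(self, c, chunk_grid):
        t_rel, stim = chunk_grid
        st_ = Trace(t_rel, stim, "fid")
        base = LNParams(
            k_a=0.6, k_af=0.3, k_f=0.2, k_as=-0.05, k_s=0.1, d_as=2.0, n_components=2
        )
        scaled = dataclasses.replace(base, k_af=c * base.k_af, k_as=c * base.k_as)
        assert np.allclose(simulate(scaled, st_).v, c * simulate(base, st_).v, rtol=1e-9)

    @settings(derandomize=True, max_examples=15)
    @given(amp=st.floats(0.1, 5.0), bump=st.floats(0.0, 5.0))
    def test_peak_monotone_in_stimulus_amplitude(self, amp, bump, chunk_grid):
        t_rel, stim = chunk_grid
        p = LNParams(k_a=0.5, k_af=0.4, k_f=0.12)
        lo = simulate(p, Trace(t_rel, amp * stim, "fid")).v.max()
        hi = simulate(p, Trace(t_rel, (amp + bump) * stim, "fid")).v.max()
        assert hi >= lo - 1e-12

    def test_optional_saturation_compresses_peak(self, chunk_grid):
        t_rel, stim = chunk_grid
        st_ = Trace(t_rel, stim, "fid")
        p = LNParams(k_a=0.5, k_af=0.4, k_f=0.12)
        plain = simulate(p, st_).v.max()
        saturated = simulate(p, st_, saturation_rmax=0.5).v.max()
        assert saturated < plain


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"k_a": -1.0, "k_af": 1.0, "k_f": 1.0},
            {"k_a": 1.0, "k_af": -1.0, "k_f": 1.0},
            {"k_a": 1.0, "k_af": 1.0, "k_f": 0.0},
            {"k_a": 1.0, "k_af": 1.0, "k_f": 1.0, "d_as": -1.0},
            {"k_a": 1.0, "k_af": 1.0, "k_f": 1.0, "polarity": 2},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            LNParams(**kwargs)

    def test_one_component_forces_zero_slow_gain(self):
        p = LNParams(k_a=1.0, k_af=1.0, k_f=1.0, k_as=5.0, n_components=1)
        assert p.k_as == 0.0


class TestFit:
    def test_noiseless_one_component_recovered_within_one_percent(
        self, make_chunk, one_comp_truth
    ):
        res = fit(make_chunk(one_comp_truth), 1, seed=0)
        assert res.converged
        assert res.params.k_a == pytest.approx(one_comp_truth.k_a, rel=0.01)
        assert res.params.k_af == pytest.approx(one_comp_truth.k_af, rel=0.01)
        assert res.params.k_f == pytest.approx(one_comp_truth.k_f, rel=0.01)

    def test_flat_noise_chunk_fits_near_zero_gain(self, chunk_grid):
        t_rel, stim = chunk_grid
        rng = np.random.default_rng(0)
        noise_sd = 0.01
        ch = Chunk("NULL", t_rel, rng.normal(0, noise_sd, t_rel.size), stim, -2, 0, 100.0)
        res = fit(ch, 1, seed=0)
        assert res.fitted_trace.v.max() < 3 * noise_sd
        assert res.rss == pytest.approx(t_rel.size * noise_sd**2, rel=0.5)

    def test_two_component_never_worse_than_one(self, make_chunk, one_comp_truth):
        ch = make_chunk(one_comp_truth, noise_sd=0.02, seed=3)
        f1 = fit(ch, 1, seed=0)
        f2 = fit(
            ch,
            2,
            seed=1,
            extra_starts=(
                dataclasses.replace(f1.params, k_as=0.0, k_s=1.0, d_as=0.0, n_components=2),
            ),
        )
        assert f2.rss <= f1.rss + 1e-12

    def test_stimulus_scale_invariance_of_fitted_response(self, make_chunk, one_comp_truth):
        ch = make_chunk(one_comp_truth, noise_sd=0.01, seed=4)
        big = ch.copy()
        big.stimulus = 50.0 * big.stimulus
        f_small = fit(ch, 1, seed=0)
        f_big = fit(big, 1, seed=0)
        assert f_big.params.k_af == pytest.approx(f_small.params.k_af / 50.0, rel=0.05)
        assert f_big.fitted_trace.v.max() == pytest.approx(
            f_small.fitted_trace.v.max(), rel=0.05
        )


class TestModelSelection:
    def test_bic_formula_value(self):
        # independent arithmetic: 100 ln(0.01) + 3 ln(100)
        assert bic_score(1.0, 100, 3) == pytest.approx(-446.70150804084483)

    def test_identical_rss_prefers_fewer_parameters(self, make_chunk, one_comp_truth):
        ch = make_chunk(one_comp_truth)
        tr = Trace(ch.t_rel, ch.v, "dff")
        p2 = dataclasses.replace(one_comp_truth, n_components=2)
        f1 = FitResult(one_comp_truth, 1.0, ch.v.size, bic_score(1.0, ch.v.size, 3), True, tr)
        f2 = FitResult(p2, 1.0, ch.v.size, bic_score(1.0, ch.v.size, 6), True, tr)
        assert select_model(f1, f2) is f1

    def test_tie_breaks_to_one_component(self, make_chunk, one_comp_truth):
        ch = make_chunk(one_comp_truth)
        tr = Trace(ch.t_rel, ch.v, "dff")
        p2 = dataclasses.replace(one_comp_truth, n_components=2)
        f1 = FitResult(one_comp_truth, 1.0, 100, -50.0, True, tr)
        f2 = FitResult(p2, 1.0, 100, -50.0, True, tr)
        assert select_model(f2, f1) is f1

    def test_mismatched_n_obs_rejected(self, make_chunk, one_comp_truth):
        ch = make_chunk(one_comp_truth)
        tr = Trace(ch.t_rel, ch.v, "dff")
        f1 = FitResult(one_comp_truth, 1.0, 100, -50.0, True, tr)
        f2 = FitResult(one_comp_truth, 1.0, 99, -50.0, True, tr)
        with pytest.raises(ValueError, match="identical data"):
            select_model(f1, f2)


class TestPolarity:
    def test_positive_transient_unchanged(self, make_chunk, one_comp_truth):
        ch = make_chunk(one_comp_truth)
        pol, out = classify_polarity(ch)
        assert pol == 1
        assert np.allclose(out.v, ch.v)

    def test_negative_transient_inverted(self, make_chunk, one_comp_truth):
        neg = dataclasses.replace(one_comp_truth, polarity=-1)
        ch = make_chunk(neg)
        pol, out = classify_polarity(ch)
        assert pol == -1
        assert out.v.max() > 0
        assert np.allclose(out.v, -ch.v)

    def test_biphasic_keeps_dominant_positive_polarity(self, make_chunk):
        biphasic = LNParams(
            k_a=0.5, k_af=0.4, k_f=0.3, k_as=-0.08, k_s=0.08, d_as=4.0, n_components=2
        )
        ch = make_chunk(biphasic)
        pol, out = classify_polarity(ch)
        assert pol == 1
        f2 = fit(out, 2, seed=0)
        assert f2.params.k_as < 0  # undershoot carried by the signed slow gain

    def test_all_zero_chunk_flagged(self, chunk_grid):
        t_rel, stim = chunk_grid
        ch = Chunk("ZERO", t_rel, np.zeros_like(t_rel), stim, -2, 0, 100.0)
        pol, out = classify_polarity(ch)
        assert pol == 0
        assert out.flags["polarity_undefined"]
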