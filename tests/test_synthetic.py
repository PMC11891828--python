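import dataclasses

import numpy as np
import pytest
from scipy.integrate import quad

from orca.ln_model import simulate_reference
from orca.preprocessing import Trace
from orca.synthetic import (
    DEFAULT_KINETICS,
    MixConfig,
    OdorantEvent,
    emg_peak_value,
    emg_profile,
    example_mix,
    fid_amplitude,
    generate_calcium,
    generate_fid,
    make_dataset,
    noiseless_response,
    receptor_drive,
)


def small_mix(**overrides):
    defaults = dict(
        odorants=[
            OdorantEvent("AAAA", 100.0, potency=0.3, ec50=0.05),
            OdorantEvent("BBBB", 160.0, potency=0.1, ec50=0.05),
        ],
        dilutions=(-4, -2),
        n_animals=2,
        run_duration=240.0,
        seed=11,
    )
    defaults.update(overrides)
    return MixConfig(**defaults)


class TestMixConfig:
    def test_descending_dilutions_rejected(self):
        with pytest.raises(ValueError, match="ascending"):
            small_mix(dilutions=(-2, -4))

    def test_elution_beyond_run_rejected(self):
        with pytest.raises(ValueError, match="run duration"):
            small_mix(odorants=[OdorantEvent("AAAA", 500.0)])

    def test_minimum_spacing_enforced(self):
        with pytest.raises(ValueError, match="spacing"):
            small_mix(
                odorants=[
                    OdorantEvent("AAAA", 100.0),
                    OdorantEvent("BBBB", 110.0),
                ]
            )

    def test_unknown_dilution_rejected(self):
        with pytest.raises(ValueError, match="unknown dilution"):
            generate_fid(small_mix(), -3)


class TestFid:
    def test_empty_mix_is_flat_noise(self):
        mix = small_mix(odorants=[])
        tr = generate_fid(mix, -2)
        assert abs(np.mean(tr.v)) < 3 * mix.fid_noise_sd
        assert np.std(tr.v) == pytest.approx(mix.fid_noise_sd, rel=0.2)

    def test_dilution_step_scales_amplitude_hundredfold(self):
        mix = small_mix(odorants=[OdorantEvent("AAAA", 100.0)], fid_noise_sd=0.0)
        lo = generate_fid(mix, -4).v.max()
        hi = generate_fid(mix, -2).v.max()
        assert hi / lo == pytest.approx(100.0, rel=1e-6)

    def test_peak_area_matches_analytic_emg_area(self):
        # the elution profile is a unit-area density, so a peak of
        # amplitude A integrates to A (quadrature oracle)
        amp, sigma, tau = 7.3, 1.5, 3.0
        area, _ = quad(lambda x: amp * emg_profile(x, 50.0, sigma, tau), 0.0, 200.0)
        assert area == pytest.approx(amp, rel=1e-3)

    def test_amplitude_monotone_in_dilution(self):
        mix = example_mix()
        for ev in mix.odorants:
            amps = [fid_amplitude(mix, ev, d) for d in mix.dilutions]
            assert all(b >= a for a, b in zip(amps, amps[1:]))

    def test_hidden_contaminant_never_exceeds_detection_threshold(self):
        mix = example_mix(seed=5)
        hidden = [ev for ev in mix.odorants if ev.is_contaminant][0]
        for d in mix.dilutions:
            fid = generate_fid(mix, d)
            win = np.abs(fid.t - hidden.elution_time) <= 5.0
            assert fid.v[win].max() < mix.fid_detection_threshold


class TestCalcium:
    def test_zero_potency_mix_is_pure_bleach(self):
        mix = small_mix(
            odorants=[OdorantEvent("AAAA", 100.0, potency=0.0)], noise_sd=1.0
        )
        tr = generate_calcium(mix, -2, 0)
        amp, tau, offset = mix.bleach
        expected = amp * np.exp(-tr.t / tau) + offset
        assert np.abs(tr.v - expected).max() < 6 * mix.noise_sd

    def test_response_peak_time_matches_ode_oracle(self):
        mix = small_mix(noise_sd=0.0, bleach=(0.0, 180.0, 400.0))
        tr = generate_calcium(mix, -2, 0)
        dff = tr.v / 400.0 - 1.0
        ev = mix.odorants[0]
        params = dataclasses.replace(DEFAULT_KINETICS, polarity=1)
        center = ev.elution_time + mix.transfer_delay_s
        stim = (
            receptor_drive(mix, ev, -2)
            * emg_profile(tr.t, center, mix.emg_sigma, mix.emg_tau)
            / emg_peak_value(mix.emg_sigma, mix.emg_tau)
        )
        ref = simulate_reference(params, Trace(tr.t, stim, "fid"), refine=50)
        win = np.abs(tr.t - center) < 20.0
        t_obs = tr.t[win][np.argmax(dff[win])]
        t_ref = tr.t[win][np.argmax(ref.v[win])]
        assert abs(t_obs - t_ref) <= tr.dt + 1e-9

    def test_hidden_contaminant_drives_calcium_without_fid(self):
        mix = example_mix(seed=3)
        hidden = [ev for ev in mix.odorants if ev.is_contaminant][0]
        tr = generate_calcium(mix, -2, 0)
        _, _, offset = mix.bleach
        dff = (tr.v - offset) / offset
        win = np.abs(tr.t - (hidden.elution_time + mix.transfer_delay_s)) <= 5.0
        assert dff[win].max() > 0.2  # strong calcium response
        fid = generate_fid(mix, -2)
        fwin = np.abs(fid.t - hidden.elution_time) <= 5.0
        assert fid.v[fwin].max() < mix.fid_detection_threshold


class TestDataset:
    def test_factorial_counts(self):
        mix = small_mix(n_animals=3, dilutions=(-6, -4, -2))
        ds = make_dataset(mix)
        assert len(ds.raw_recordings) == 9
        assert len(ds.fid_traces) == 3
        assert len(ds.ground_truth) == 3 * 3 * len(mix.odorants)

    def test_same_seed_is_bit_identical(self):
        a = make_dataset(small_mix())
        b = make_dataset(small_mix())
        for key in a.raw_recordings:
            assert np.array_equal(a.raw_recordings[key].v, b.raw_recordings[key].v)
        for d in a.fid_traces:
            assert np.array_equal(a.fid_traces[d].v, b.fid_traces[d].v)

    def test_different_seed_same_truth_different_noise(self):
        a = make_dataset(small_mix(seed=1))
        b = make_dataset(small_mix(seed=2))
        key = (0, "AAAA", -2)
        assert a.ground_truth[key].magnitude == b.ground_truth[key].magnitude
        assert a.ground_truth[key].params == b.ground_truth[key].params
        # identical signal, different noise realization: the difference
        # between the raw traces is exactly the noise difference
        mix = small_mix(seed=1)
        t = a.raw_recordings[(0, -2)].t
        total, _ = noiseless_response(mix, -2, t)
        amp, tau, offset = mix.bleach
        clean = amp * np.exp(-t / tau) + offset + offset * total
        ra = a.raw_recordings[(0, -2)].v - clean
        rb = b.raw_recordings[(0, -2)].v - clean
        assert not np.allclose(ra, rb)
        assert np.std(ra) == pytest.approx(mix.noise_sd, rel=0.2)

    def test_noiseless_dataset_equals_forward_model(self):
        mix = small_mix(noise_sd=0.0, bleach=(0.0, 180.0, 500.0))
        ds = make_dataset(mix)
        tr = ds.raw_recordings[(0, -2)]
        total, _ = noiseless_response(mix, -2, tr.t)
        assert np.allclose(tr.v, 500.0 * (1.0 + total))

    def test_zero_animals_rejected(self):
        with pytest.raises(ValueError):
            small_mix(n_animals=0)
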