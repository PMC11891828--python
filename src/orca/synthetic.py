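"""Seeded synthetic GC-FID chromatograms and calcium recordings.

Emulates the statistical structure of GC-coupled antennal calcium
imaging so every downstream stage can be validated against ground truth:

* FID chromatograms as sums of exponentially modified Gaussian (EMG)
  elution peaks over a noisy baseline. Peak amplitude scales linearly
  with each odorant's relative headspace abundance (``vapor_weight``)
  and by a factor of 10 per liquid-dilution decade, so a 10⁻² run
  dwarfs a 10⁻⁶ run just as early/volatile eluates dwarf late ones.
* Raw calcium fluorescence as an additive photobleaching exponential
  plus the resting fluorescence times the summed forward LN-cascade
  responses of all odorants (long tails overlap into following peaks),
  plus Gaussian sensor noise, sampled at 1.66 Hz.
* Trace contaminants: odorants that drive a receptor response at their
  elution time while contributing no FID peak above the detection
  threshold (``contaminant_fid_visible=False`` hides the peak entirely).

The receptor drive for an odorant at liquid dilution d is
``|potency| · g(c)`` with ``c = 10^(d − d_ref)`` and the saturating
headspace/transduction law ``g(c) = c / (c + K)``; the stimulus waveform
itself is the noiseless unit-peak EMG concentration profile, so ground
truth is exact while the fitted pipeline sees only the noisy FID.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import exponnorm

from .preprocessing import Trace
from .ln_model import LNParams, simulate

#: one-component kinetics typical of a fast-rising, tens-of-seconds-decay
#: antennal calcium transient; per-odorant kinetics default to this.
DEFAULT_KINETICS = LNParams(k_a=0.5, k_af=0.4, k_f=0.12, n_components=1)

_FID_STREAM, _CA_STREAM = 101, 202


@dataclass
class OdorantEvent:
    """Registry entry for one eluting substance.

    ``vapor_weight`` is the dimensionless relative headspace abundance
    (≥ 0); ``potency`` the signed receptor-specific gain (negative =
    inhibitory, 0 = non-ligand). Hidden contaminants
    (``is_contaminant=True, contaminant_fid_visible=False``) never
    produce an FID peak above the detection threshold.
    """

    code: str
    elution_time: float
    vapor_weight: float = 1.0
    potency: float = 0.0
    is_contaminant: bool = False
    contaminant_fid_visible: bool = False
    kinetics: LNParams | None = None
    #: half-saturation of the receptor drive on the relative concentration
    #: scale (1.0 = the reference dilution); None falls back to the mix
    #: default. Small values -> the ligand saturates at high concentration,
    #: large values -> it stays in the linear (weak-ligand) regime.
    ec50: float | None = None

    def __post_init__(self):
        if not (4 <= len(self.code) <= 6):
            raise ValueError("odorant code must be 4-6 characters")
        if self.vapor_weight < 0:
            raise ValueError("vapor_weight must be >= 0")


@dataclass
class MixConfig:
    """Study conditions for one synthetic odorant mix.

    Defaults follow the recorded protocol where one exists (1.66 Hz
    calcium sampling, liquid dilutions 10⁻⁶/10⁻⁴/10⁻², ≥ 30 s between
    elutions); the remainder are documented instrument-realistic choices
    (10 Hz FID, EMG peak σ = 1.5 s / tail τ = 3 s, ~3 s transfer delay
    from the column splitter to the antenna).
    """

    odorants: list
    dilutions: tuple = (-6, -4, -2)
    n_animals: int = 4
    frame_rate: float = 1.66
    fid_rate: float = 10.0
    run_duration: float = 480.0
    noise_sd: float = 2.0  # raw-fluorescence units
    fid_noise_sd: float = 0.05
    bleach: tuple = (150.0, 180.0, 400.0)  # (amp, tau_s, offset)
    transfer_delay_s: float = 3.0
    seed: int = 0
    fid_gain: float = 100.0
    fid_detection_threshold: float = 1.0
    dilution_reference: float = -2.0
    half_saturation: float = 0.02
    emg_sigma: float = 1.5
    emg_tau: float = 3.0
    min_spacing_s: float = 30.0

    def __post_init__(self):
        if self.frame_rate <= 0 or self.fid_rate <= 0:
            raise ValueError("sampling rates must be positive")
        if len(self.dilutions) == 0:
            raise ValueError("at least one dilution required")
        if list(self.dilutions) != sorted(self.dilutions) or len(
            set(self.dilutions)
        ) != len(self.dilutions):
            raise ValueError("dilutions must be strictly ascending in concentration")
        if self.n_animals <= 0:
            raise ValueError("n_animals must be positive")
        times = sorted(ev.elution_time for ev in self.odorants)
        for t in times:
            if not (0.0 < t < self.run_duration):
                raise ValueError("elution_time outside run duration")
        if any(b - a < self.min_spacing_s - 1e-9 for a, b in zip(times, times[1:])):
            raise ValueError(f"inter-elution spacing below {self.min_spacing_s} s")

    def dilution_index(self, dilution) -> int:
        try:
            return list(self.dilutions).index(dilution)
        except ValueError:
            raise ValueError(f"unknown dilution {dilution!r}") from None


@dataclass
class GroundTruth:
    """True response parameters and peak for one odorant × dilution."""

    params: LNParams
    magnitude: float  # signed true peak ΔF/F
    drive: float  # |potency| · g(c), the stimulus scale fed to the cascade


@dataclass
class SyntheticDataset:
    fid_traces: dict  # dilution -> Trace
    raw_recordings: dict  # (animal, dilution) -> Trace
    ground_truth: dict  # (animal, code, dilution) -> GroundTruth
    registry: list
    mix: MixConfig


def emg_profile(t, center: float, sigma: float, tau: float) -> np.ndarray:
    """Unit-area exponentially modified Gaussian elution profile."""
    return exponnorm.pdf(np.asarray(t, float), K=tau / sigma, loc=center, scale=sigma)


def emg_peak_value(sigma: float, tau: float) -> float:
    """Maximum of the unit-area EMG, evaluated on a dense grid."""
    tt = np.linspace(-8.0 * sigma, 8.0 * (sigma + tau), 20001)
    return float(emg_profile(tt, 0.0, sigma, tau).max())


def fid_amplitude(mix: MixConfig, ev: OdorantEvent, dilution) -> float:
    """Integrated FID peak area for one odorant at one dilution.

    Linear in ``vapor_weight`` with a factor of 10 per dilution decade
    relative to ``dilution_reference``; hidden contaminants contribute
    nothing (their concentration sits below the FID detection limit).
    """
    if ev.is_contaminant and not ev.contaminant_fid_visible:
        return 0.0
    return mix.fid_gain * ev.vapor_weight * 10.0 ** (dilution - mix.dilution_reference)


def receptor_drive(mix: MixConfig, ev: OdorantEvent, dilution) -> float:
    """Effective stimulus scale |potency|·g(c), g(c) = c/(c + EC50)."""
    c = 10.0 ** (dilution - mix.dilution_reference)
    ec50 = mix.half_saturation if ev.ec50 is None else ev.ec50
    return abs(ev.potency) * c / (c + ec50)


def generate_fid(mix: MixConfig, dilution, seed=None) -> Trace:
    """One seeded FID chromatogram (10 Hz default) for one dilution."""
    d_idx = mix.dilution_index(dilution)
    entropy = mix.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([entropy, _FID_STREAM, d_idx]))
    t = np.arange(int(round(mix.run_duration * mix.fid_rate))) / mix.fid_rate
    v = np.zeros_like(t)
    for ev in mix.odorants:
        amp = fid_amplitude(mix, ev, dilution)
        if amp > 0:
            v += amp * emg_profile(t, ev.elution_time, mix.emg_sigma, mix.emg_tau)
    v += rng.normal(0.0, mix.fid_noise_sd, t.size)
    return Trace(t, v, "fid")


def _event_params(ev: OdorantEvent) -> LNParams:
    base = ev.kinetics if ev.kinetics is not None else DEFAULT_KINETICS
    return replace(base, polarity=-1 if ev.potency < 0 else 1)


def noiseless_response(mix: MixConfig, dilution, t: np.ndarray):
    """Summed ΔF/F response of all odorants plus per-odorant ground truth."""
    total = np.zeros_like(t)
    truth = {}
    peak = emg_peak_value(mix.emg_sigma, mix.emg_tau)
    for ev in mix.odorants:
        drive = receptor_drive(mix, ev, dilution)
        params = _event_params(ev)
        if drive == 0.0:
            truth[ev.code] = GroundTruth(params, 0.0, 0.0)
            continue
        center = ev.elution_time + mix.transfer_delay_s
        stim = drive * emg_profile(t, center, mix.emg_sigma, mix.emg_tau) / peak
        r = simulate(params, Trace(t, stim, "fid")).v
        total += r
        mag = params.polarity * float(np.max(np.abs(r)))
        truth[ev.code] = GroundTruth(params, mag, drive)
    return total, truth


def generate_calcium(mix: MixConfig, dilution, animal: int) -> Trace:
    """One seeded raw-fluorescence recording for (animal, dilution).

    raw(t) = bleach_amp·e^(−t/τ) + offset + offset·Σᵢ rᵢ(t) + ε(t) with
    each rᵢ the forward LN response to odorant i's noiseless concentration
    profile (delayed by the transfer time), ε ~ N(0, noise_sd).
    """
    if not (0 <= animal < mix.n_animals):
        raise ValueError("animal index out of range")
    d_idx = mix.dilution_index(dilution)
    rng = np.random.default_rng(
        np.random.SeedSequence([mix.seed, _CA_STREAM, animal, d_idx])
    )
    n = int(round(mix.run_duration * mix.frame_rate))
    t = np.arange(n) / mix.frame_rate
    amp, tau, offset = mix.bleach
    total, _ = noiseless_response(mix, dilution, t)
    v = amp * np.exp(-t / tau) + offset + offset * total
    v += rng.normal(0.0, mix.noise_sd, n)
    return Trace(t, v, "raw")


#: two-component kinetics of a biphasic response: positive fast phase with
#: a delayed negative slow phase (its peak ~30% of the fast peak)
BIPHASIC_KINETICS = LNParams(
    k_a=0.5, k_af=0.4, k_f=0.3, k_as=-0.07, k_s=0.08, d_as=4.0, n_components=2
)


def example_mix(seed: int = 0) -> MixConfig:
    """A six-odorant receptor panel spanning all dose-response categories.

    The declared odorants are designed, through their potency and EC50,
    to yield group-significant responses at all three dilutions (category
    3, a saturating best ligand), the top two only (category 2: one
    simple-positive, one biphasic, one inhibitory), the highest
    concentration only (category 1, a weak linear-regime ligand), or none
    (category 0). A seventh, undeclared odorant is a hidden component-borne
    contaminant: it drives the receptor concentration-dependently while
    its FID peak stays below the detection threshold.
    """
    odorants = [
        OdorantEvent("BEST", 100.0, vapor_weight=1.0, potency=0.41, ec50=1.6e-3),
        OdorantEvent("MEDP", 160.0, vapor_weight=0.9, potency=0.30, ec50=0.05),
        OdorantEvent(
            "BIPH", 220.0, vapor_weight=0.8, potency=0.45, ec50=0.05,
            kinetics=BIPHASIC_KINETICS,
        ),
        OdorantEvent("NEGA", 280.0, vapor_weight=0.7, potency=-0.20, ec50=0.05),
        OdorantEvent("WEAK", 340.0, vapor_weight=0.6, potency=0.25, ec50=10.0),
        OdorantEvent("NONE", 400.0, vapor_weight=0.5, potency=0.008, ec50=1.0),
        OdorantEvent(
            "CNTM", 460.0, vapor_weight=0.5, potency=0.35, ec50=0.05,
            is_contaminant=True, contaminant_fid_visible=False,
        ),
    ]
    return MixConfig(odorants=odorants, run_duration=560.0, seed=seed)


#: dose-response categories the example mix is designed to produce
EXAMPLE_MIX_CATEGORIES = {"BEST": 3, "MEDP": 2, "BIPH": 2, "NEGA": 2, "WEAK": 1, "NONE": 0}


def make_dataset(mix: MixConfig) -> SyntheticDataset:
    """Full factorial animals × dilutions dataset; pure function of the mix."""
    if mix.n_animals == 0 or len(mix.dilutions) == 0:
        raise ValueError("need at least one animal and one dilution")
    fid_traces = {d: generate_fid(mix, d) for d in mix.dilutions}
    raw, truth = {}, {}
    n = int(round(mix.run_duration * mix.frame_rate))
    t = np.arange(n) / mix.frame_rate
    per_dilution_truth = {d: noiseless_response(mix, d, t)[1] for d in mix.dilutions}
    for a in range(mix.n_animals):
        for d in mix.dilutions:
            raw[(a, d)] = generate_calcium(mix, d, a)
            for ev in mix.odorants:
                truth[(a, ev.code, d)] = per_dilution_truth[d][ev.code]
    return SyntheticDataset(
        fid_traces=fid_traces,
        raw_recordings=raw,
        ground_truth=truth,
        registry=list(mix.odorants),
        mix=mix,
    )
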