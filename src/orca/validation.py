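"""Seeded validation studies for every pipeline stage.

Each function generates its own synthetic inputs (via :mod:`orca.synthetic`
or direct construction), runs the stage under test, and returns measured
quantities — integrator deviation against a fine-step reference, parameter
recovery errors, model-order selection rates, synchronization error,
leakage-removal residuals, contamination detection/classification
performance, and end-to-end dose-response category reproduction. They are
what ``scripts/acceptance.py`` reports and what the acceptance test suite
asserts against.

All randomness is driven by the ``seed`` argument; problem sizes default
to what a desk-scale reproduction run uses.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import chunking, contamination, ln_model, pipeline, preprocessing
from .chunking import Chunk
from .ln_model import LNParams, simulate, simulate_reference
from .preprocessing import Trace
from .synthetic import (
    EXAMPLE_MIX_CATEGORIES,
    OdorantEvent,
    emg_profile,
    emg_peak_value,
    example_mix,
)

CALCIUM_DT = 1.0 / 1.66

#: canonical one-component response kinetics used across studies
ONE_COMP_TRUTH = LNParams(k_a=0.5, k_af=0.4, k_f=0.12, n_components=1)
#: biphasic truth: delayed slow phase of opposite sign, slow peak >= 30%
#: of the fast peak
BIPHASIC_TRUTH = LNParams(
    k_a=0.5, k_af=0.4, k_f=0.3, k_as=-0.08, k_s=0.08, d_as=4.0, n_components=2
)


def _emg_chunk_grid(pre_s: float = 10.0, post_s: float = 40.0):
    """Standard chunk grid with a unit-peak elution profile at t_rel = 0."""
    t_rel = np.arange(-pre_s, post_s, CALCIUM_DT)
    stim = emg_profile(t_rel, 0.0, 1.5, 3.0) / emg_peak_value(1.5, 3.0)
    return t_rel, stim


def _noisy_chunk(clean, t_rel, stim, snr, rng) -> Chunk:
    sd = float(np.abs(clean).max()) / snr
    v = clean + rng.normal(0.0, sd, clean.size)
    return Chunk("SYNT", t_rel, v, stim, -2, 0, 100.0)


# ---------------------------------------------------------------------------
# forward model


def ode_equivalence_study(seed: int = 0, n_sets: int = 20) -> dict:
    """Forward integrator vs a 100x-finer-step reference integration.

    Draws random parameter sets from the physiological range (rates
    0.03-3 s^-1, delays 0-10 s, half of them two-component) and reports
    the worst-case maximum absolute deviation as a fraction of the
    response peak.
    """
    rng = np.random.default_rng(seed)
    t_rel, stim = _emg_chunk_grid()
    st = Trace(t_rel, stim, "fid")
    worst = 0.0
    for i in range(n_sets):
        p = LNParams(
            k_a=10.0 ** rng.uniform(-1.5, 0.5),
            k_af=10.0 ** rng.uniform(-1.0, 0.5),
            k_f=10.0 ** rng.uniform(-1.5, 0.5),
        )
        if i % 2 == 1:
            p = dataclasses.replace(
                p,
                k_as=rng.uniform(-0.5, 0.5),
                k_s=10.0 ** rng.uniform(-1.5, 0.5),
                d_as=rng.uniform(0.0, 10.0),
                n_components=2,
            )
        r = simulate(p, st).v
        ref = simulate_reference(p, st, refine=100).v
        worst = max(worst, float(np.abs(r - ref).max() / np.abs(ref).max()))
    return {"max_rel_deviation": worst, "n": n_sets}


def steady_state_check() -> dict:
    """Step-stimulus steady state of the one-component model vs k_AF/k_F."""
    p = ONE_COMP_TRUTH
    duration = 12.0 / min(p.k_a, p.k_f)
    t = np.arange(0.0, duration, 0.1)
    r = simulate(p, Trace(t, np.ones_like(t), "fid")).v
    expected = p.k_af / p.k_f
    return {"rel_error": float(abs(r[-1] - expected) / expected), "n": t.size}


def recovery_study(seed: int = 0, n_repeats: int = 100, snr: float = 20.0) -> dict:
    """One-component parameter recovery at a given peak-to-noise SNR.

    Returns the median relative error of each rate over seeded repeats.
    """
    rng = np.random.default_rng(seed)
    t_rel, stim = _emg_chunk_grid()
    clean = simulate(ONE_COMP_TRUTH, Trace(t_rel, stim, "fid")).v
    truth = ONE_COMP_TRUTH
    errs = []
    for i in range(n_repeats):
        ch = _noisy_chunk(clean, t_rel, stim, snr, rng)
        p = ln_model.fit(ch, 1, seed=seed + i).params
        errs.append(
            [
                abs(p.k_a - truth.k_a) / truth.k_a,
                abs(p.k_af - truth.k_af) / truth.k_af,
                abs(p.k_f - truth.k_f) / truth.k_f,
            ]
        )
    med = np.median(np.asarray(errs), axis=0)
    return {
        "k_a_median_rel_error": float(med[0]),
        "k_af_median_rel_error": float(med[1]),
        "k_f_median_rel_error": float(med[2]),
        "n": n_repeats,
    }


def slow_fast_peak_ratio(params: LNParams) -> float:
    """|slow-component peak| / fast-component peak for a biphasic truth."""
    t_rel, stim = _emg_chunk_grid()
    st = Trace(t_rel, stim, "fid")
    full = simulate(params, st).v
    fast = simulate(
        dataclasses.replace(params, k_as=0.0, n_components=1), st
    ).v
    slow = full - fast
    return float(np.abs(slow).max() / fast.max())


def bic_selection_study(seed: int = 0, n_repeats: int = 100, snr: float = 20.0) -> dict:
    """BIC model-order selection rates for one-component and biphasic truths."""
    rng = np.random.default_rng(seed)
    t_rel, stim = _emg_chunk_grid()
    st = Trace(t_rel, stim, "fid")
    counts = {}
    for label, truth, want in (
        ("one_component", ONE_COMP_TRUTH, 1),
        ("two_component", BIPHASIC_TRUTH, 2),
    ):
        clean = simulate(truth, st).v
        correct = 0
        for i in range(n_repeats):
            ch = _noisy_chunk(clean, t_rel, stim, snr, rng)
            f1 = ln_model.fit(ch, 1, seed=seed + 2 * i)
            f2 = ln_model.fit(
                ch,
                2,
                seed=seed + 2 * i + 1,
                extra_starts=(
                    dataclasses.replace(
                        f1.params, k_as=0.0, k_s=1.0, d_as=0.0, n_components=2
                    ),
                ),
            )
            chosen = ln_model.select_model(f1, f2)
            correct += chosen.params.n_components == want
        counts[f"{label}_correct"] = correct
    counts["n"] = n_repeats
    return counts


# ---------------------------------------------------------------------------
# preprocessing


def bleach_recovery_study(seed: int = 0, n_repeats: int = 5) -> dict:
    """Photobleaching-fit recovery of (amp, tau, offset) on noisy traces."""
    rng = np.random.default_rng(seed)
    amp, tau, offset = 100.0, 200.0, 400.0
    t = np.arange(0.0, 480.0, CALCIUM_DT)
    worst = 0.0
    for _ in range(n_repeats):
        v = amp * np.exp(-t / tau) + offset + rng.normal(0.0, 1.0, t.size)
        f = preprocessing.fit_bleach(Trace(t, v, "raw"))
        worst = max(
            worst,
            abs(f.amp - amp) / amp,
            abs(f.tau - tau) / tau,
            abs(f.offset - offset) / offset,
        )
    return {"max_param_rel_error": float(worst), "n": n_repeats}


def mask_cardinality_check() -> dict:
    """60th-percentile mask on 100 distinct pixel values."""
    rng = np.random.default_rng(7)
    img = rng.permutation(np.arange(1.0, 101.0)).reshape(10, 10)
    movie = np.stack([np.zeros_like(img), img])
    mask = preprocessing.response_mask(movie, 1)
    return {
        "nonzero_weights": int(np.count_nonzero(mask.weights)),
        "max_weight": float(mask.weights.max()),
        "n": img.size,
    }


def sync_study(seed: int = 0, delay_s: float = 3.0) -> dict:
    """Recovery of an injected FID-to-calcium transfer delay.

    The calcium trace is the elution profile itself, delayed by exactly
    ``delay_s`` and resampled at 1.66 Hz with additive noise, so the peak
    shift is the delay by construction.
    """
    rng = np.random.default_rng(seed)
    t_fid = np.arange(0.0, 240.0, 0.1)
    peak = emg_profile(t_fid, 120.0, 1.5, 3.0) / emg_peak_value(1.5, 3.0)
    fid = Trace(t_fid, 10.0 * peak + rng.normal(0, 0.05, t_fid.size), "fid")
    t_ca = np.arange(0.0, 240.0, CALCIUM_DT)
    ca_v = np.interp(t_ca - delay_s, t_fid, peak) + rng.normal(0, 0.01, t_ca.size)
    ca = Trace(t_ca, ca_v, "dff")
    shift = preprocessing.synchronize(fid, ca, 120.0)
    return {"abs_error_s": float(abs(shift - delay_s)), "n": t_ca.size}


# ---------------------------------------------------------------------------
# chunking


def leakage_study(seed: int = 0) -> dict:
    """Chained leakage removal on overlapping long-tailed responses.

    Three responses, 40 s apart, with 20-s decay tails that ride well
    into the following windows; after model-based tail subtraction every
    pre-stimulus RMS is compared with its own response peak.
    """
    rng = np.random.default_rng(seed)
    slow_decay = LNParams(k_a=0.5, k_af=0.3, k_f=0.05, n_components=1)
    elutions = [60.0, 100.0, 140.0]
    scales = [1.0, 0.6, 0.8]
    t = np.arange(0.0, 240.0, CALCIUM_DT)
    peak = emg_peak_value(1.5, 3.0)
    dff_v = np.zeros_like(t)
    fid_t = np.arange(0.0, 240.0, 0.1)
    fid_v = np.zeros_like(fid_t)
    for te, sc in zip(elutions, scales):
        stim = sc * emg_profile(t, te, 1.5, 3.0) / peak
        dff_v += simulate(slow_decay, Trace(t, stim, "fid")).v
        fid_v += 10.0 * sc * emg_profile(fid_t, te, 1.5, 3.0) / peak
    dff_v += rng.normal(0.0, 0.005, t.size)
    dff = Trace(t, dff_v, "dff")
    fid = Trace(fid_t, fid_v, "fid")
    events = [OdorantEvent(f"OD{i:02d}", te) for i, te in enumerate(elutions)]

    chunks = chunking.extract_chunks(dff, fid, events, pre_s=10.0, post_s=40.0)
    prev_fit = None
    worst = 0.0
    for ch in chunks:
        clean = chunking.remove_leakage(ch, prev_fit)
        rms = float(np.sqrt(np.mean(clean.pre_stimulus() ** 2)))
        peak_v = float(clean.v[clean.t_rel >= -2].max())
        worst = max(worst, rms / peak_v)
        prev_fit = ln_model.fit(clean, 1, seed=seed)
    return {"max_prestim_rms_over_peak": worst, "n": len(chunks)}


# ---------------------------------------------------------------------------
# contamination


def contamination_classification_study(seed: int = 0, n_each: int = 50) -> dict:
    """Origin classification of synthetic contamination dose series.

    Component-borne events scale with concentration (pattern around
    0.05/0.20/0.60 across 10^-6/10^-4/10^-2); environmental events are
    flat. Four animals per dilution, small inter-animal noise.
    """
    rng = np.random.default_rng(seed)
    dil = (-6, -4, -2)
    correct = 0
    for _ in range(n_each):
        scale = rng.uniform(0.5, 1.5)
        means = scale * np.array([0.05, 0.20, 0.60])
        mags = {d: means[j] + rng.normal(0, 0.02, 4) for j, d in enumerate(dil)}
        correct += (
            contamination.concentration_dependence(mags)
            == contamination.COMPONENT_BORNE
        )
    for _ in range(n_each):
        base = rng.uniform(0.1, 0.4)
        mags = {
            d: base * (1 + rng.normal(0, 0.02)) + rng.normal(0, 0.02, 4) for d in dil
        }
        correct += (
            contamination.concentration_dependence(mags)
            == contamination.ENVIRONMENTAL
        )
    return {"classification_accuracy": correct / (2 * n_each), "n": 2 * n_each}


def _response_shape(center: float, t: np.ndarray, params: LNParams) -> np.ndarray:
    """Unit-peak forward response whose maximum sits exactly at ``center``."""
    stim = emg_profile(t, center, 1.5, 3.0) / emg_peak_value(1.5, 3.0)
    r = simulate(params, Trace(t, stim, "fid")).v
    lag = t[int(np.argmax(r))] - center
    stim = emg_profile(t, center - lag, 1.5, 3.0) / emg_peak_value(1.5, 3.0)
    r = simulate(params, Trace(t, stim, "fid")).v
    return r / r.max()


def contamination_detection_study(
    seed: int = 0,
    n_runs: int = 25,
    n_clean_runs: int = 200,
    contaminant_snr: float = 4.0,
) -> dict:
    """Hidden-contaminant detection recall and clean-run false positives.

    Each run is a median ΔF/F trace with one declared response and (for
    the recall arm) one undeclared response of peak ``contaminant_snr``
    times the noise SD, with no FID signal at its elution time. Clean
    runs contain the declared response only.
    """
    rng = np.random.default_rng(seed)
    noise_sd = 0.004
    t = np.arange(0.0, 300.0, CALCIUM_DT)
    fid_t = np.arange(0.0, 300.0, 0.1)
    declared = [OdorantEvent("KNWN", 60.0)]
    fid_v = 10.0 * emg_profile(fid_t, 60.0, 1.5, 3.0) / emg_peak_value(1.5, 3.0)
    base = 0.3 * _response_shape(65.0, t, ONE_COMP_TRUTH)
    contam_time = 200.0
    contam = _response_shape(contam_time, t, ONE_COMP_TRUTH)

    detected = 0
    for _ in range(n_runs):
        v = base + contaminant_snr * noise_sd * contam
        v = v + rng.normal(0.0, noise_sd, t.size)
        fid = Trace(fid_t, fid_v + rng.normal(0, 0.05, fid_t.size), "fid")
        found, _ = contamination.detect_unexpected(
            Trace(t, v, "dff"), fid, declared, fid_detection_threshold=1.0,
            declared_mask_post_s=45.0,
        )
        # a near-threshold response has a broad, flat top, so noise moves
        # the reported position by several seconds; a detection counts if
        # it lands anywhere on that top (+-10 s)
        detected += any(abs(e.elution_time - contam_time) <= 10.0 for e in found)

    false_events = 0
    for _ in range(n_clean_runs):
        v = base + rng.normal(0.0, noise_sd, t.size)
        fid = Trace(fid_t, fid_v + rng.normal(0, 0.05, fid_t.size), "fid")
        found, _ = contamination.detect_unexpected(
            Trace(t, v, "dff"), fid, declared, fid_detection_threshold=1.0,
            declared_mask_post_s=45.0,
        )
        false_events += len(found)
    return {
        "detection_recall": detected / n_runs,
        "false_positives_per_100_clean_runs": false_events * 100.0 / n_clean_runs,
        "n": n_runs,
    }


# ---------------------------------------------------------------------------
# end to end


def category_study(seed: int = 0, n_runs: int = 6) -> dict:
    """Full-pipeline reproduction of the designed dose-response categories.

    Runs the end-to-end pipeline on the example receptor panel with
    ``n_runs`` different seeds and reports the fraction of runs in which
    every odorant lands in its designed category, plus how often the
    hidden contaminant is detected and classified component-borne.
    """
    exact = 0
    contaminant_found = 0
    for i in range(n_runs):
        run_seed = int((seed + 1000 * i) % 2**31)
        cfg = pipeline.PipelineConfig(seed=run_seed, mix=example_mix(seed=run_seed))
        res = pipeline.run_pipeline(cfg)
        cats = res.categories.category.to_dict()
        exact += cats == EXAMPLE_MIX_CATEGORIES
        contaminant_found += any(
            e.matched_odorant == "CNTM" and e.origin == contamination.COMPONENT_BORNE
            for e in res.contaminations
        )
    return {
        "category_reproduction_rate": exact / n_runs,
        "contaminant_identified_rate": contaminant_found / n_runs,
        "n": n_runs,
    }
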