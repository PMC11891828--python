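"""Detection and classification of trace-contaminant responses.

A contamination is a consistent calcium response at an elution time where
no declared mix component elutes and no FID peak is detectable — the
substance is below the chemical detection limit but above the receptor's
threshold. Detected events are classified by their concentration
dependence across dilution series: responses that grow with the mix
concentration (monotone trend plus a fold-change gate) point to a
contaminant carried inside one of the mix components ("component-borne"),
flat responses point to solvent/air/syringe background ("environmental").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .preprocessing import Trace

DEFAULT_TOL_S = 5.0
TREND_ALPHA = 0.05
FOLD_CHANGE_GATE = 2.0
#: fraction of animals that must show the peak for it to count as consistent
CONSISTENCY_FRACTION = 0.6

COMPONENT_BORNE = "component_borne"
ENVIRONMENTAL = "environmental"
UNDETERMINED = "undetermined"


@dataclass
class ContaminationEvent:
    """An undeclared calcium response with no detectable FID signal."""

    elution_time: float
    magnitude: float
    fid_max_in_window: float
    matched_odorant: str | None = None
    origin: str = UNDETERMINED
    per_dilution_magnitude: dict = field(default_factory=dict)


@dataclass
class UnassignedOdorant:
    """An undeclared calcium response *with* a visible FID peak.

    Not a contamination in the trace-contaminant sense: some substance
    eluted in chemically detectable quantity but was never declared.
    """

    elution_time: float
    magnitude: float
    fid_max_in_window: float
    matched_odorant: str | None = None


def _noise_sd(trace: Trace, first_event_time: float, guard_s: float = 10.0) -> float:
    pre = trace.v[trace.t < first_event_time - guard_s]
    if pre.size < 8:
        pre = trace.v
    return float(np.std(pre, ddof=1)) + 1e-30


def detect_unexpected(
    median_trace: Trace,
    fid: Trace,
    events,
    fid_detection_threshold: float,
    registry=None,
    noise_multiple: float = 2.5,
    tol_s: float = DEFAULT_TOL_S,
    animal_traces=None,
    declared_mask_post_s: float | None = None,
):
    """Scan a (median) ΔF/F trace for responses with no declared odorant.

    Local maxima at least ``noise_multiple``·noise_sd above baseline and
    more than ``tol_s`` away from every declared elution become candidate
    events. Candidates whose FID maximum within ±``tol_s`` stays below the
    detection threshold are contamination events; candidates with a
    visible FID peak are reported separately as unassigned odorants.
    ``registry`` (iterable with ``code``/``elution_time``) proposes a
    matched odorant by elution time. When per-animal traces are supplied,
    a candidate must appear in at least 60% of animals to count.

    ``declared_mask_post_s`` extends the exclusion zone after each
    declared elution (a pipeline passes its response-window length here,
    since slow decay tails inside a declared window belong to that
    odorant, not to a contaminant); the same span masks the tail of an
    already-detected event. Default: symmetric ±``tol_s`` only.

    Returns ``(contaminations, unassigned)``.
    """
    declared = sorted(ev.elution_time for ev in events)
    if not declared:
        raise ValueError("declared event list is empty")
    sd = _noise_sd(median_trace, declared[0])

    # one candidate per contiguous suprathreshold region (its maximum);
    # this collapses the many local maxima a decaying response tail shows
    # and, with the minimum run length, suppresses single-frame noise
    # hits. A 3-frame median prefilter keeps single-frame dips from
    # splitting a genuine response region (the noise SD is still taken
    # from the unfiltered trace, which keeps the threshold conservative).
    v_f = signal.medfilt(median_trace.v, 3)
    above = v_f >= noise_multiple * sd
    min_run = 3
    idx = []
    i = 0
    n = above.size
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            if j - i >= min_run:
                seg = slice(i, j)
                idx.append(i + int(np.argmax(v_f[seg])))
            i = j
        else:
            i += 1

    mask_post = tol_s if declared_mask_post_s is None else declared_mask_post_s
    contaminations, unassigned = [], []
    kept_times = []
    for i in idx:
        t_peak = float(median_trace.t[i])
        if any(-tol_s <= t_peak - te <= mask_post for te in declared):
            # a declared odorant at this time masks detection; likewise a
            # contaminant smaller than the tail it rides on stays hidden,
            # because its region's maximum lies at the declared response
            continue
        if any(0.0 < t_peak - tk <= mask_post for tk in kept_times):
            continue  # decay tail of an event already reported
        if animal_traces is not None:
            n_show = 0
            for tr in animal_traces:
                win = (tr.t >= t_peak - tol_s) & (tr.t <= t_peak + tol_s)
                a_sd = _noise_sd(tr, declared[0])
                if win.any() and tr.v[win].max() >= noise_multiple * a_sd:
                    n_show += 1
            if n_show < CONSISTENCY_FRACTION * len(animal_traces):
                continue
        fwin = (fid.t >= t_peak - tol_s) & (fid.t <= t_peak + tol_s)
        fid_max = float(fid.v[fwin].max()) if fwin.any() else 0.0
        match = None
        if registry is not None:
            best = min(
                registry,
                key=lambda r: abs(r.elution_time - t_peak),
                default=None,
            )
            if best is not None and abs(best.elution_time - t_peak) <= tol_s:
                match = best.code
        mag = float(median_trace.v[i])
        kept_times.append(t_peak)
        if fid_max < fid_detection_threshold:
            contaminations.append(
                ContaminationEvent(t_peak, mag, fid_max, matched_odorant=match)
            )
        else:
            unassigned.append(UnassignedOdorant(t_peak, mag, fid_max, match))
    return contaminations, unassigned


def concentration_dependence(
    magnitudes_by_dilution: dict,
    alpha: float = TREND_ALPHA,
    fold_gate: float = FOLD_CHANGE_GATE,
) -> str:
    """Classify a contamination's origin from its dose dependence.

    ``magnitudes_by_dilution`` maps each dilution exponent (≥ 3 levels,
    ≥ 2 animals each) to per-animal response magnitudes. Component-borne:
    magnitudes increase with concentration (one-sided Spearman trend,
    p < ``alpha``) and the top/bottom dilution ratio is ≥ ``fold_gate``.
    Environmental: no trend (p ≥ alpha) and ratio < fold_gate. Anything
    mixed is undetermined.
    """
    levels = sorted(magnitudes_by_dilution)
    if len(levels) < 3:
        raise ValueError("need at least 3 dilution levels")
    x, y = [], []
    for d in levels:
        vals = np.atleast_1d(np.asarray(magnitudes_by_dilution[d], float))
        if vals.size < 2:
            raise ValueError("need at least 2 animals per dilution level")
        x.extend([d] * vals.size)
        y.extend(vals)
    rho, p_two = stats.spearmanr(x, y)
    if np.isnan(rho):
        rho, p_two = 0.0, 1.0
    p_one = p_two / 2.0 if rho > 0 else 1.0 - p_two / 2.0
    top = float(np.mean(magnitudes_by_dilution[levels[-1]]))
    bottom = float(np.mean(magnitudes_by_dilution[levels[0]]))
    ratio = abs(top) / max(abs(bottom), 1e-30)
    increasing = p_one < alpha and ratio >= fold_gate
    flat = p_one >= alpha and ratio < fold_gate
    if increasing:
        return COMPONENT_BORNE
    if flat:
        return ENVIRONMENTAL
    return UNDETERMINED
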