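"""Response-window ("chunk") extraction, leakage removal, and peak alignment.

Each odorant in a GC run has an elution time stamp; a chunk is the ΔF/F
window around that stamp (default −10 s to +40 s) together with the
matched FID stimulus segment resampled onto the calcium frame grid.
Because strong responses decay over tens of seconds, the modeled tail of
the preceding response is subtracted from the following chunk ("leakage
removal") before baseline removal and model fitting. Small elution-time
jitter is corrected by shifting each chunk so its peak sits at the
cross-animal median peak latency for that odorant.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field

import numpy as np

from .preprocessing import Trace
from . import ln_model

DEFAULT_PRE_S = 10.0
DEFAULT_POST_S = 40.0
#: pre-stimulus segment boundary used for baselines and noise estimates
DEFAULT_BASELINE_T = -2.0
DEFAULT_MAX_JITTER_S = 3.0


@dataclass
class Chunk:
    """One odorant's response window on the calcium frame grid.

    ``t_rel`` is time in seconds relative to the expected elution;
    ``stimulus`` is the FID segment resampled onto the same grid.
    Chunks own their arrays: mutating a chunk never mutates the source
    trace.
    """

    odorant_code: str
    t_rel: np.ndarray
    v: np.ndarray
    stimulus: np.ndarray
    dilution: float
    animal_id: object
    elution_time: float
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t_rel = np.asarray(self.t_rel, float)
        self.v = np.asarray(self.v, float)
        self.stimulus = np.asarray(self.stimulus, float)
        if not (self.t_rel.shape == self.v.shape == self.stimulus.shape):
            raise ValueError("t_rel, v and stimulus must share one grid")

    @property
    def dt(self) -> float:
        return (self.t_rel[-1] - self.t_rel[0]) / (self.t_rel.size - 1)

    def copy(self) -> "Chunk":
        return Chunk(
            self.odorant_code,
            self.t_rel.copy(),
            self.v.copy(),
            self.stimulus.copy(),
            self.dilution,
            self.animal_id,
            self.elution_time,
            _copy.deepcopy(self.flags),
        )

    def pre_stimulus(self, baseline_t: float = DEFAULT_BASELINE_T) -> np.ndarray:
        return self.v[self.t_rel < baseline_t]


def extract_chunks(
    trace: Trace,
    fid: Trace,
    events,
    pre_s: float = DEFAULT_PRE_S,
    post_s: float = DEFAULT_POST_S,
    dilution: float = np.nan,
    animal_id=None,
    stim_baseline: bool = True,
) -> list[Chunk]:
    """Cut one chunk per odorant event from a synchronized ΔF/F trace.

    ``events`` is an iterable with ``code`` and ``elution_time`` attributes,
    sorted by elution time. Windows are half-open ``[t_e − pre, t_e + post)``
    on the calcium grid; the FID is linearly resampled onto the same frames
    (baseline-subtracted and clipped at zero when ``stim_baseline``).
    """
    events = list(events)
    times = [ev.elution_time for ev in events]
    if times != sorted(times):
        raise ValueError("events must be sorted by elution_time")
    if len(set(times)) != len(times):
        raise ValueError("overlapping identical elution time stamps")

    chunks = []
    dt = trace.dt
    for ev in events:
        t0, t1 = ev.elution_time - pre_s, ev.elution_time + post_s
        if t0 < trace.t[0] - 0.5 * dt or t1 > trace.t[-1] + 0.5 * dt:
            raise ValueError(
                f"window for {ev.code} ({t0:.1f}-{t1:.1f} s) exceeds recording"
            )
        sel = (trace.t >= t0) & (trace.t < t1)
        t_sel = trace.t[sel]
        stim = np.interp(t_sel, fid.t, fid.v)
        if stim_baseline:
            pre = stim[t_sel - ev.elution_time < DEFAULT_BASELINE_T]
            base = np.median(pre) if pre.size else np.median(stim)
            stim = np.clip(stim - base, 0.0, None)
        chunks.append(
            Chunk(
                odorant_code=ev.code,
                t_rel=t_sel - ev.elution_time,
                v=trace.v[sel].copy(),
                stimulus=stim,
                dilution=dilution,
                animal_id=animal_id,
                elution_time=ev.elution_time,
                flags={},
            )
        )
    return chunks


def remove_leakage(
    chunk: Chunk,
    prev_fit: "ln_model.FitResult | None" = None,
    baseline_t: float = DEFAULT_BASELINE_T,
) -> Chunk:
    """Subtract the preceding response's modeled tail, then the baseline.

    ``prev_fit`` must be the fitted model of the immediately preceding
    chunk (carrying its chunk reference); its cascade is re-simulated with
    the stimulus zero-padded up to the end of this chunk, and the
    overlapping tail is subtracted. Baseline removal then subtracts the
    median of the pre-stimulus segment (t_rel < ``baseline_t``).
    """
    out = chunk.copy()
    if prev_fit is not None:
        prev = prev_fit.chunk
        if prev is None:
            raise ValueError("prev_fit carries no chunk to continue")
        dt = chunk.dt
        t_prev = prev.elution_time + prev.t_rel
        t_cur = chunk.elution_time + chunk.t_rel
        n_ext = int(round((t_cur[-1] - t_prev[0]) / dt)) + 1
        t_ext = t_prev[0] + dt * np.arange(n_ext)
        s_ext = np.zeros(n_ext)
        s_ext[: prev.stimulus.size] = np.clip(prev.stimulus, 0.0, None)
        # polarity of the previous response was handled by inverting its
        # data; restore the sign when simulating the physical tail
        pol = prev.flags.get("polarity", prev_fit.params.polarity)
        tail = ln_model.simulate(prev_fit.params, Trace(t_ext, s_ext, "fid")).v
        if pol == -1:
            tail = -tail
        if not np.all(np.isfinite(tail)):
            raise ValueError("simulated leakage tail is not finite")
        out.v = out.v - np.interp(t_cur, t_ext, tail)
        out.flags["leakage_removed"] = True
    pre = out.pre_stimulus(baseline_t)
    if pre.size:
        out.v = out.v - np.median(pre)
    out.flags["baseline_removed"] = True
    return out


def peak_latency(chunk: Chunk, response_from_s: float = DEFAULT_BASELINE_T) -> float:
    """Latency (t_rel, seconds) of the chunk's dominant extremum."""
    sel = chunk.t_rel >= response_from_s
    seg = chunk.v[sel]
    pol = chunk.flags.get("polarity") or (1 if seg.max() >= -seg.min() else -1)
    i = int(np.argmax(pol * seg))
    return float(chunk.t_rel[sel][i])


def median_peak_latency(chunks) -> float:
    """Cross-animal median peak latency for one odorant."""
    lat = [peak_latency(c) for c in chunks]
    if not lat:
        raise ValueError("no chunks")
    return float(np.median(lat))


def align_peak(
    chunk: Chunk,
    target_latency_s: float,
    max_jitter_s: float = DEFAULT_MAX_JITTER_S,
) -> Chunk:
    """Shift the chunk (whole frames) so its peak sits at the target latency.

    A shift whose magnitude exceeds ``max_jitter_s`` is not applied; the
    chunk comes back flagged ``aligned=False`` instead of silently moved.
    """
    out = chunk.copy()
    dt = chunk.dt
    shift = target_latency_s - peak_latency(chunk)
    n = int(round(shift / dt))
    applied = n * dt
    if abs(applied) > max_jitter_s + 1e-9:
        out.flags["aligned"] = False
        out.flags["shift_applied_s"] = 0.0
        return out
    if n > 0:  # move values later in time
        out.v = np.concatenate([np.full(n, chunk.v[0]), chunk.v[:-n]])
    elif n < 0:
        out.v = np.concatenate([chunk.v[-n:], np.full(-n, chunk.v[-1])])
    out.flags["aligned"] = True
    out.flags["shift_applied_s"] = float(applied)
    return out
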