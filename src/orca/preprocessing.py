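"""Raw-recording preprocessing.

Turns raw fluorescence recordings into bleach-corrected, synchronized
ΔF/F traces ready for response-window extraction:

* photobleaching correction by fitting an additive exponential decay
  ``A·exp(-x/B) + C`` to the response-free part of the trace,
* relative fluorescence change ΔF/F = (F_i - F_0)/F_0 with F_0 the mean
  of frames 10-100 (1-based, ~6-60 s after acquisition start at 1.66 Hz),
* a weighted spatial response mask (60th-percentile threshold of the
  peak-response frame, rescaled to [0, 1]) for movie inputs,
* FID/calcium clock synchronization from the reference-odorant peak.
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

# Relative jitter in the sample spacing still accepted as a uniform grid.
UNIFORM_GRID_RTOL = 1e-5

#: ΔF/F baseline frames, 1-based inclusive (frames 10-100 at 1.66 Hz span
#: roughly 6-60 s after measurement start).
DEFAULT_F0_FRAMES = (10, 100)

DEFAULT_MASK_PERCENTILE = 60.0


@dataclass
class Trace:
    """A uniformly sampled time series.

    Parameters
    ----------
    t : array of float
        Sample times in seconds, strictly increasing, uniform spacing.
    v : array of float
        Signal values (raw fluorescence, ΔF/F, or FID units).
    kind : {"raw", "dff", "fid"}
    """

    t: np.ndarray
    v: np.ndarray
    kind: str = "raw"

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.v.shape:
            raise ValueError("t and v must be 1-D arrays of equal length")
        if self.t.size == 0:
            raise ValueError("empty trace")
        if self.t.size >= 2:
            steps = np.diff(self.t)
            if np.any(steps <= 0):
                raise ValueError("time must be strictly increasing")
            dt = steps.mean()
            if (steps.max() - steps.min()) > UNIFORM_GRID_RTOL * dt:
                raise ValueError(
                    "non-uniform sampling grid; resample before constructing a Trace"
                )

    @property
    def dt(self) -> float:
        if self.t.size < 2:
            return np.nan
        return (self.t[-1] - self.t[0]) / (self.t.size - 1)

    @property
    def frame_rate(self) -> float:
        return 1.0 / self.dt

    def copy(self) -> "Trace":
        return Trace(self.t.copy(), self.v.copy(), self.kind)

    def shifted(self, shift_s: float) -> "Trace":
        """Return a copy with the time base shifted by ``-shift_s``.

        Used to apply a synchronization shift: subtracting the measured
        calcium-minus-FID lag aligns the calcium clock to the FID clock.
        """
        return Trace(self.t - shift_s, self.v.copy(), self.kind)


@dataclass
class BleachFit:
    """Result of the additive-exponential photobleaching fit A·e^(-x/B) + C.

    ``flagged`` marks degenerate fits (no decaying component identifiable:
    amplitude at/below zero, or decay time pinned at the search bound).
    """

    amp: float
    tau: float
    offset: float
    rss: float
    flagged: bool = False

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        return self.amp * np.exp(-np.asarray(x, float) / self.tau) + self.offset


def _exclude_mask(t: np.ndarray, exclude_windows) -> np.ndarray:
    keep = np.ones(t.size, dtype=bool)
    for t0, t1 in exclude_windows:
        keep &= ~((t >= t0) & (t < t1))
    return keep


def fit_bleach(raw: Trace, exclude_windows=()) -> BleachFit:
    """Fit the photobleaching decay A·exp(-x/B) + C on response-free samples.

    Parameters
    ----------
    raw : Trace
        Raw fluorescence recording.
    exclude_windows : iterable of (t0, t1)
        Absolute-time windows (seconds, half-open) excluded from the fit,
        typically around each expected odorant elution.

    Returns
    -------
    BleachFit
        Best of a multi-start bounded least-squares fit over decay-time
        initializations. A constant or rising trace yields ``amp ≈ 0`` /
        ``amp ≤ 0`` with ``flagged=True`` rather than an exception.
    """
    x_all = raw.t - raw.t[0]
    keep = _exclude_mask(raw.t, exclude_windows)
    if keep.sum() < 10:
        raise ValueError("fewer than 10 samples outside excluded windows")
    x, y = x_all[keep], raw.v[keep]

    span = max(x[-1] - x[0], 1.0)
    tau_min, tau_max = 1e-3, 50.0 * span
    offset0 = y[-max(1, y.size // 10):].mean()
    amp0 = y[: max(1, y.size // 10)].mean() - offset0

    best = None
    for tau0 in np.geomspace(span / 50.0, 5.0 * span, 6):
        p0 = [amp0, tau0, offset0]

        def resid(p):
            return p[0] * np.exp(-x / p[1]) + p[2] - y

        try:
            sol = optimize.least_squares(
                resid,
                p0,
                bounds=([-np.inf, tau_min, -np.inf], [np.inf, tau_max, np.inf]),
            )
        except Exception:
            continue
        rss = float(2.0 * sol.cost)
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    if best is None:
        raise RuntimeError("bleach fit failed to converge from any start")

    rss, (amp, tau, offset) = best
    scale = max(abs(offset), float(np.abs(y).max()), 1.0)
    flagged = bool(amp <= scale * 1e-6 or tau >= 0.98 * tau_max)
    return BleachFit(float(amp), float(tau), float(offset), rss, flagged)


def correct_bleach(raw: Trace, fit: BleachFit) -> Trace:
    """Subtract the fitted bleach curve; post-correction baseline = offset."""
    corrected = raw.v - fit.evaluate(raw.t - raw.t[0]) + fit.offset
    return Trace(raw.t.copy(), corrected, "raw")


def compute_dff(raw_corrected: Trace, f0_frames=DEFAULT_F0_FRAMES) -> Trace:
    """ΔF/F = (F_i - F_0)/F_0 with F_0 the mean over ``f0_frames``.

    ``f0_frames`` is a 1-based inclusive frame range (default 10-100).
    """
    i0, i1 = f0_frames
    if not (1 <= i0 <= i1):
        raise ValueError("invalid baseline frame range")
    if raw_corrected.v.size <= i1:
        raise ValueError(f"trace shorter than baseline window (needs > {i1} frames)")
    f0 = raw_corrected.v[i0 - 1 : i1].mean()
    if f0 <= 0:
        raise ValueError("non-physical baseline fluorescence F_0 <= 0")
    return Trace(raw_corrected.t.copy(), (raw_corrected.v - f0) / f0, "dff")


@dataclass
class ResponseMask:
    """Per-pixel response weights in [0, 1] from the peak-response frame.

    Pixels below the percentile threshold of the reference peak frame carry
    zero weight; the remainder is linearly rescaled so the maximum is 1.
    """

    weights: np.ndarray
    source_frame: int

    def apply(self, movie: np.ndarray) -> np.ndarray:
        """Weighted-mean trace Σ(w·pixel)/Σ(w) per frame of a (T, H, W) movie."""
        movie = np.asarray(movie, float)
        wsum = self.weights.sum()
        if wsum <= 0:
            raise ValueError("all-zero mask")
        return np.tensordot(movie, self.weights, axes=([1, 2], [0, 1])) / wsum


def response_mask(
    movie: np.ndarray, ref_peak_frame: int, percentile: float = DEFAULT_MASK_PERCENTILE
) -> ResponseMask:
    """Build the weighted response mask from a movie's peak-response frame.

    The peak-frame image is thresholded at its ``percentile`` (values below
    go to zero) and the remaining values are linearly rescaled to [0, 1].
    """
    movie = np.asarray(movie, float)
    if movie.ndim != 3:
        raise ValueError("movie must be a (T, H, W) frame stack")
    if not (0 <= ref_peak_frame < movie.shape[0]):
        raise ValueError("ref_peak_frame outside movie")
    img = movie[ref_peak_frame]
    if not np.any(img):
        raise ValueError("all-zero peak frame")
    thr = np.percentile(img, percentile)
    w = np.clip(img - thr, 0.0, None)
    top = w.max()
    if top <= 0:
        raise ValueError("no pixels above the percentile threshold")
    return ResponseMask(w / top, int(ref_peak_frame))


def _reference_peak_time(
    trace: Trace,
    t_expect: float,
    search_s: float,
    smooth_frames: int,
    noise_multiple: float,
    label: str,
) -> float:
    k = max(1, int(smooth_frames) | 1)  # medfilt needs an odd window
    v = signal.medfilt(trace.v, k) if k > 1 else trace.v
    sel = (trace.t >= t_expect - search_s) & (trace.t <= t_expect + search_s)
    if not sel.any():
        raise ValueError(f"search window outside {label} trace")
    med = np.median(trace.v)
    # noise from the unfiltered trace: the filtered extremum of pure
    # noise then stays safely below the acceptance gate
    noise = 1.4826 * np.median(np.abs(trace.v - med)) + 1e-30
    seg_t, seg_v = trace.t[sel], v[sel]
    i = int(np.argmax(seg_v))
    if seg_v[i] - med < noise_multiple * noise:
        raise ValueError(f"reference response missing in {label} trace")
    return float(seg_t[i])


def synchronize(
    fid: Trace,
    ca: Trace,
    ref_elution_time: float,
    search_s: float = 15.0,
    smooth_frames: int = 3,
    noise_multiple: float = 2.5,
) -> float:
    """Clock shift between calcium and FID from the reference-odorant peak.

    Returns ``shift = t(ca peak) - t(fid peak)`` within ``±search_s`` of the
    reference elution time; ``ca.shifted(shift)`` aligns the two peaks. The
    same shift applies to every recording of that animal.
    """
    t_fid = _reference_peak_time(
        fid, ref_elution_time, search_s, smooth_frames, noise_multiple, "fid"
    )
    t_ca = _reference_peak_time(
        ca, ref_elution_time, search_s, smooth_frames, noise_multiple, "calcium"
    )
    return t_ca - t_fid
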