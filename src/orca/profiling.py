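"""Response significance, odor-response profiles, and dose-response categories.

A modeled response is significant within a recording when its magnitude
is at least 2.5 times the noise, defined as the SD of the pre-stimulus
ΔF/F fluctuations; at the group level, per-animal magnitudes must exceed
2.5·noise_sd by a one-sided t-test at p < 0.01. Per receptor, the median
signed modeled magnitude per odorant and dilution forms the odor-response
profile, and each odorant gets a dose-response category: the number of
contiguous dilutions, counted down from the highest concentration, at
which its response is (group-)significant — 3, 2, 1, or 0 for the
standard 10⁻⁶/10⁻⁴/10⁻² series. For cross-dataset comparison the top-k
responses of a profile are affinely rescaled to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .chunking import Chunk, DEFAULT_BASELINE_T
from .ln_model import FitResult

NOISE_MULTIPLE = 2.5
GROUP_ALPHA = 0.01
MIN_NOISE_FRAMES = 8


@dataclass
class ResponseRecord:
    """Modeled response of one animal to one odorant at one dilution."""

    receptor: str
    odorant_code: str
    dilution: float
    animal_id: object
    magnitude: float  # signed modeled peak ΔF/F
    noise_sd: float
    significant: bool
    fit: Optional[FitResult] = None


def noise_sd_of(chunk: Chunk, baseline_t: float = DEFAULT_BASELINE_T) -> float:
    """SD of the pre-stimulus ΔF/F segment (the recording's noise floor)."""
    pre = chunk.pre_stimulus(baseline_t)
    if pre.size < MIN_NOISE_FRAMES:
        raise ValueError(f"fewer than {MIN_NOISE_FRAMES} pre-stimulus noise frames")
    return float(np.std(pre, ddof=1))


def significance(
    chunk: Chunk,
    magnitude: float,
    noise_multiple: float = NOISE_MULTIPLE,
    baseline_t: float = DEFAULT_BASELINE_T,
):
    """Per-recording significance flag: |magnitude| ≥ noise_multiple·noise_sd.

    Negative responses are tested with the same threshold on |magnitude|.
    Returns ``(flag, noise_sd)``.
    """
    sd = noise_sd_of(chunk, baseline_t)
    return bool(abs(magnitude) >= noise_multiple * sd), sd


def group_pvalue(
    magnitudes,
    noise_sds,
    noise_multiple: float = NOISE_MULTIPLE,
) -> float:
    """One-sided p-value that animal responses exceed the noise threshold.

    One-sample t-test of per-animal (|magnitude| − noise_multiple·noise_sd)
    against zero, alternative greater. Degenerate inputs (single animal,
    zero variance) collapse to p = 0 or 1 by the sign of the difference.
    """
    m = np.abs(np.asarray(magnitudes, float))
    s = np.asarray(noise_sds, float)
    if m.shape != s.shape or m.size == 0:
        raise ValueError("magnitudes and noise_sds must be equal-length, non-empty")
    diff = m - noise_multiple * s
    if m.size == 1 or np.allclose(diff, diff[0]):
        return 0.0 if diff[0] > 0 else 1.0
    return float(stats.ttest_1samp(diff, 0.0, alternative="greater").pvalue)


def group_significance(
    magnitudes,
    noise_sds,
    alpha: float = GROUP_ALPHA,
    noise_multiple: float = NOISE_MULTIPLE,
) -> bool:
    """Group-level significance flag at level ``alpha`` (see group_pvalue)."""
    return group_pvalue(magnitudes, noise_sds, noise_multiple) < alpha


def benjamini_hochberg(pvalues, alpha: float = GROUP_ALPHA) -> np.ndarray:
    """Benjamini-Hochberg FDR rejection flags for a family of p-values.

    Optional multiple-testing control across the odorant panel; the
    default workflow applies none.
    """
    p = np.asarray(pvalues, float)
    n = p.size
    order = np.argsort(p)
    thresholds = alpha * (np.arange(1, n + 1)) / n
    passed = p[order] <= thresholds
    k = np.max(np.nonzero(passed)[0]) + 1 if passed.any() else 0
    rejected = np.zeros(n, dtype=bool)
    rejected[order[:k]] = True
    return rejected


def dose_category(flags: dict, dilutions) -> tuple[int, bool]:
    """Dose-response category from per-dilution significance flags.

    ``dilutions`` ascending in concentration (e.g. (−6, −4, −2)); the
    category is the length of the maximal contiguous significant run
    ending at the highest concentration. Patterns that are significant at
    a low concentration but not at a higher one (e.g. 10⁻⁶ yes, 10⁻⁴ no)
    are categorized by the same contiguous-from-top rule and flagged
    non-monotone. Returns ``(category, non_monotone)``.
    """
    dilutions = list(dilutions)
    missing = [d for d in dilutions if d not in flags]
    if missing:
        raise ValueError(f"missing dilution level(s): {missing}")
    seq = [bool(flags[d]) for d in dilutions]
    category = 0
    for f in reversed(seq):
        if not f:
            break
        category += 1
    non_monotone = any(seq[: len(seq) - category])
    return category, non_monotone


def build_profile(records, reporting_dilution=None) -> pd.DataFrame:
    """Per-receptor odor-response table of median signed magnitudes.

    One row per odorant, one column per dilution (median across all
    records pooled over animals), sorted descending by the median at the
    reporting dilution (default: the highest concentration), so the
    strongest positive responses lead and negative responses trail.
    """
    rows = [
        {
            "receptor": r.receptor,
            "odorant_code": r.odorant_code,
            "dilution": r.dilution,
            "magnitude": r.magnitude,
        }
        for r in records
    ]
    if not rows:
        raise ValueError("no records")
    df = pd.DataFrame(rows)
    table = df.pivot_table(
        index="odorant_code", columns="dilution", values="magnitude", aggfunc="median"
    )
    if reporting_dilution is None:
        reporting_dilution = max(table.columns)
    return table.sort_values(by=reporting_dilution, ascending=False)


def scale_profile(values, top_k: int = 20) -> pd.Series:
    """Affinely rescale the top-k responses of a profile to [0, 1].

    Keeps the ``top_k`` largest values (whole panel with a warning when
    the panel is smaller) and maps max→1, min→0. Constant values make the
    scaling undefined and raise.
    """
    s = pd.Series(values, dtype=float)
    if top_k > s.size:
        warnings.warn(
            f"top_k={top_k} larger than panel of {s.size}; using whole panel",
            stacklevel=2,
        )
        top_k = s.size
    top = s.sort_values(ascending=False).iloc[:top_k]
    lo, hi = top.min(), top.max()
    if not (hi > lo):
        raise ValueError("constant top-k values: scaling undefined")
    return (top - lo) / (hi - lo)
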