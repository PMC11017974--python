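"""Size-caste designation from the colony's body-volume distribution.

The procedure has two branches.  A colony whose log volumes fail a
Shapiro-Wilk normality test is screened for bimodality on a default-binned
histogram of log10 volume; if two distinct peaks are found, the midpoint of
the emptiest bin between them (the trough) becomes the small/large cutoff
and every redia is either small or large.  Colonies that are not bimodal
fall back to comparing the smallest 25% of volumes against the largest 25%,
leaving the middle half as intermediates.

The histogram uses Sturges' class count with breakpoints snapped to "nice"
numbers (1, 2 or 5 times a power of ten), reproducing the default histogram
of the R environment in which such field data are conventionally analysed,
so the bimodality call depends only on the data and not on plotting choices.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .config import AnalysisConfig
from .datamodel import SizeClass
from .stats import quartiles

__all__ = [
    "NormalityResult",
    "BimodalityResult",
    "log_volume_normality",
    "default_histogram_breaks",
    "bin_counts",
    "detect_bimodality",
    "assign_size_classes",
    "volume_pattern_code",
]


@dataclass
class NormalityResult:
    W_statistic: float
    p_value: float
    n: int


@dataclass
class BimodalityResult:
    is_bimodal: bool
    method: str  # 'histogram_trough', 'quartile_fallback', 'manual_override'
    histogram_breaks: list[float] = field(default_factory=list)  # log10 um^3
    counts: list[int] = field(default_factory=list)
    peak_bins: list[int] = field(default_factory=list)
    trough_bin: int | None = None
    cutoff_volume_um3: float | None = None


def log_volume_normality(volumes: Sequence[float]) -> NormalityResult:
    """Shapiro-Wilk test on natural-log body volumes."""
    v = np.asarray(volumes, dtype=float)
    if v.size < 3:
        raise ValueError("normality test requires at least 3 volumes")
    if not np.all(np.isfinite(v) & (v > 0)):
        raise ValueError("volumes must be finite and positive")
    logv = np.log(v)
    if np.ptp(logv) == 0:
        raise ValueError("degenerate input: all volumes identical")
    w, p = sps.shapiro(logv)
    return NormalityResult(float(w), float(p), int(v.size))


def _nice_unit(cell: float) -> float:
    """Round a raw bin width to 1, 2, 5 or 10 times a power of ten.

    Implements the unit-selection rule of R's ``pretty()`` with its default
    biases (high.u.bias = 1.5, u5.bias = 2.75).
    """
    base = 10.0 ** math.floor(math.log10(cell))
    unit = base
    h, h5 = 1.5, 2.75
    if (2 * base) - cell < h * (cell - unit):
        unit = 2 * base
        if (5 * base) - cell < h5 * (cell - unit):
            unit = 5 * base
            if (10 * base) - cell < h * (cell - unit):
                unit = 10 * base
    return unit


def default_histogram_breaks(values: Sequence[float]) -> list[float]:
    """Sturges class count with breakpoints on nice numbers covering the data."""
    v = np.asarray(values, dtype=float)
    if v.size < 2 or np.unique(v).size < 2:
        raise ValueError("need at least 2 distinct values")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    n_classes = math.ceil(math.log2(v.size)) + 1
    lo, hi = float(v.min()), float(v.max())
    unit = _nice_unit((hi - lo) / n_classes)
    eps = 1e-10 * unit
    ns = math.floor(lo / unit + eps)
    nu = math.ceil(hi / unit - eps)
    return [round((ns + i) * unit, 12) for i in range(nu - ns + 1)]


def bin_counts(values: Sequence[float], breaks: Sequence[float]) -> list[int]:
    """Right-closed binning (a, b], lowest bin closed on both ends."""
    v = np.asarray(values, dtype=float)
    b = np.asarray(breaks, dtype=float)
    if np.any(v < b[0]) or np.any(v > b[-1]):
        raise ValueError("values fall outside the break range")
    idx = np.searchsorted(b, v, side="left") - 1
    idx = np.clip(idx, 0, b.size - 2)
    return np.bincount(idx, minlength=b.size - 1).astype(int).tolist()


def _local_maxima(counts: Sequence[int], min_peak_count: int) -> list[int]:
    """Indices of local-maximum bins, collapsing flat plateaus to their
    leftmost bin."""
    c = list(counts)
    k = len(c)
    peaks = []
    i = 0
    while i < k:
        j = i
        while j + 1 < k and c[j + 1] == c[i]:
            j += 1
        left_ok = i == 0 or c[i - 1] < c[i]
        right_ok = j == k - 1 or c[j + 1] < c[i]
        if left_ok and right_ok and c[i] >= min_peak_count and c[i] > 0:
            peaks.append(i)
        i = j + 1
    return peaks


def detect_bimodality(
    volumes: Sequence[float],
    config: AnalysisConfig | None = None,
    manual_cutoff_um3: float | None = None,
) -> BimodalityResult:
    """Histogram-trough bimodality screen on log10 body volumes.

    Returns ``method='quartile_fallback'`` (not an error) when the sample is
    too small or no qualifying peak pair exists.  A user-supplied cutoff
    bypasses the rule entirely (``method='manual_override'``).
    """
    cfg = config or AnalysisConfig()
    v = np.asarray(volumes, dtype=float)
    if manual_cutoff_um3 is not None:
        return BimodalityResult(
            True, "manual_override", cutoff_volume_um3=float(manual_cutoff_um3)
        )
    if v.size < cfg.min_n or np.unique(v).size < 2:
        return BimodalityResult(False, "quartile_fallback")
    logv = np.log10(v)
    breaks = default_histogram_breaks(logv)
    counts = bin_counts(logv, breaks)
    peaks = _local_maxima(counts, cfg.min_peak_count)
    if len(peaks) < 2:
        return BimodalityResult(False, "quartile_fallback", breaks, counts, peaks)
    # the two highest local maxima; count ties broken toward the lower index
    top2 = sorted(sorted(peaks, key=lambda i: (-counts[i], i))[:2])
    p1, p2 = top2
    if p2 - p1 < 2:
        return BimodalityResult(False, "quartile_fallback", breaks, counts, peaks)
    min_between = min(counts[i] for i in range(p1 + 1, p2))
    if min_between > cfg.trough_ratio * min(counts[p1], counts[p2]):
        return BimodalityResult(False, "quartile_fallback", breaks, counts, [p1, p2])
    between = list(range(p1 + 1, p2))
    min_count = min(counts[i] for i in between)
    mid = (p1 + p2) / 2.0
    trough_candidates = [i for i in between if counts[i] == min_count]
    trough = min(trough_candidates, key=lambda i: (abs(i - mid), i))
    cutoff_log10 = 0.5 * (breaks[trough] + breaks[trough + 1])
    return BimodalityResult(
        True,
        "histogram_trough",
        breaks,
        counts,
        [p1, p2],
        trough,
        10.0**cutoff_log10,
    )


def assign_size_classes(
    volumes: Sequence[float], bimodality: BimodalityResult
) -> list[SizeClass]:
    """Label every volume small/intermediate/large.

    Trough (or manual) cutoff: at or below the cutoff is small, above is
    large, with no intermediates.  Quartile fallback: the smallest 25% are
    small, the largest 25% large (boundaries inclusive), the rest
    intermediate.
    """
    v = np.asarray(volumes, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    if not np.all(np.isfinite(v) & (v > 0)):
        raise ValueError("volumes must be finite and positive")
    if np.unique(v).size == 1:
        warnings.warn("all volumes identical; labelling every redia small")
        return [SizeClass.SMALL] * v.size
    if bimodality.cutoff_volume_um3 is not None:
        c = bimodality.cutoff_volume_um3
        return [SizeClass.SMALL if x <= c else SizeClass.LARGE for x in v]
    q1, q3 = quartiles(v)
    out = []
    for x in v:
        if x <= q1:
            out.append(SizeClass.SMALL)
        elif x >= q3:
            out.append(SizeClass.LARGE)
        else:
            out.append(SizeClass.INTERMEDIATE)
    return out


def volume_pattern_code(
    normality: NormalityResult,
    bimodality: BimodalityResult,
    alpha: float = 0.05,
) -> str:
    """Y = bimodal; N* = non-normal but not bimodal; N = consistent with
    lognormal volumes."""
    if normality.p_value >= alpha:
        return "N"
    return "Y" if bimodality.is_bimodal else "N*"
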