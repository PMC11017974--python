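"""The per-colony battery of division-of-labor pattern tests.

Each test emits a :class:`PatternResult` whose ``code`` is drawn from a
closed, pattern-specific vocabulary (the same shorthand used in comparative
tables of redia DOL studies): for example the pharynx pattern is ``Y`` when
small rediae have a significantly larger *relative* pharynx volume than
large rediae, ``N`` when not, ``NA`` when a size class has no usable pharynx
measurement.  Significance is always ``p < alpha`` with no multiple-testing
correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .config import AnalysisConfig
from .datamodel import Colony, Extremum, PresenceScores, Section, SizeClass, SizeLabel
from .stats import ProportionCI, growth_trend, proportion_ci, quartiles, rank_sum

__all__ = [
    "PatternResult",
    "OutlierResult",
    "pharynx_pattern",
    "appendage_pattern",
    "reproduction_code",
    "percent_small",
    "spatial_distribution",
    "activity_comparison",
    "attack_summary",
    "pharynx_outliers",
    "large_pharynx_flag",
    "growth_trend",
]

#: pattern name -> allowed codes (NA = not assessable)
PATTERN_VOCABULARY = {
    "volume": ("Y", "N*", "N", "NA"),
    "reproduction": ("Y", "Y?", "U", "N", "NA"),
    "morphology": ("Y", "O", "N", "NA"),
    "pharynx": ("Y", "N", "NA"),
    "abs_pharynx": ("Y", "N", "NA"),
    "pct_small": None,  # integer percent string or NA
    "distribution": ("Y", "O", "N", "NA"),
    "activity": ("S", "NS", "NA"),
    "attacks": ("Y", "N", "NA"),
    "large_pharynx": ("Y", "N", "NA"),
}


@dataclass
class PatternResult:
    pattern: str
    code: str
    statistics: dict = field(default_factory=dict)
    notes: str = ""

    def __post_init__(self) -> None:
        vocab = PATTERN_VOCABULARY.get(self.pattern)
        if vocab is not None and self.code not in vocab:
            raise ValueError(
                f"code {self.code!r} not in vocabulary of pattern {self.pattern!r}"
            )


@dataclass
class OutlierResult:
    q1: float
    q3: float
    iqr: float
    upper_fence: float
    outlier_ids: list[str]
    outlier_fraction: float
    n: int


def _rel_pharynx_groups(colony: Colony) -> tuple[list[float], list[float]]:
    small, large = [], []
    for r in colony.included_records:
        if r.relative_pharynx is None:
            continue
        if r.size_class is SizeClass.SMALL:
            small.append(r.relative_pharynx)
        elif r.size_class is SizeClass.LARGE:
            large.append(r.relative_pharynx)
    return small, large


def pharynx_pattern(colony: Colony, config: AnalysisConfig | None = None) -> PatternResult:
    """Relative pharynx volume, small vs large rediae (one-tailed small > large)."""
    cfg = config or AnalysisConfig()
    small, large = _rel_pharynx_groups(colony)
    if not small or not large:
        return PatternResult(
            "pharynx", "NA",
            {"n_small": len(small), "n_large": len(large)},
            "at least one size class has no relative-pharynx measurement",
        )
    res = rank_sum(small, large, "greater", cfg.exact_n_max)
    code = "Y" if res.p_value < cfg.alpha else "N"
    return PatternResult(
        "pharynx", code,
        {
            "U": res.U_statistic, "p_value": res.p_value,
            "n_small": res.n1, "n_large": res.n2, "exact": res.exact,
            "median_small": float(np.median(small)),
            "median_large": float(np.median(large)),
        },
    )


def abs_pharynx_pattern(colony: Colony, config: AnalysisConfig | None = None) -> PatternResult:
    """Companion test on absolute pharynx volume (one-tailed large > small)."""
    cfg = config or AnalysisConfig()
    small, large = [], []
    for r in colony.included_records:
        if r.pharynx_volume_um3 is None:
            continue
        if r.size_class is SizeClass.SMALL:
            small.append(r.pharynx_volume_um3)
        elif r.size_class is SizeClass.LARGE:
            large.append(r.pharynx_volume_um3)
    if not small or not large:
        return PatternResult("abs_pharynx", "NA", {}, "insufficient pharynx data")
    res = rank_sum(large, small, "greater", cfg.exact_n_max)
    code = "Y" if res.p_value < cfg.alpha else "N"
    return PatternResult(
        "abs_pharynx", code,
        {"U": res.U_statistic, "p_value": res.p_value,
         "n_small": len(small), "n_large": len(large)},
    )


def appendage_pattern(
    scores: Sequence[PresenceScores], config: AnalysisConfig | None = None
) -> PatternResult:
    """Anterior and posterior appendage presence, smallest five vs largest five.

    Y = both appendages score significantly higher in the smallest rediae,
    O = exactly one does, N = neither does.
    """
    cfg = config or AnalysisConfig()
    sm = [s for s in scores if s.extremum is Extremum.SMALLEST5]
    lg = [s for s in scores if s.extremum is Extremum.LARGEST5]
    if not sm or not lg:
        return PatternResult("morphology", "NA", {}, "missing an extremum group")
    stats: dict = {}
    n_sig = 0
    for name in ("anterior_score", "posterior_score"):
        a = [getattr(s, name) for s in sm]
        b = [getattr(s, name) for s in lg]
        res = rank_sum(a, b, "greater", cfg.exact_n_max)
        stats[f"p_{name}"] = res.p_value
        stats[f"U_{name}"] = res.U_statistic
        if res.p_value < cfg.alpha:
            n_sig += 1
    code = {2: "Y", 1: "O", 0: "N"}[n_sig]
    return PatternResult("morphology", code, stats)


def reproduction_code(scores: Sequence[PresenceScores]) -> PatternResult:
    """Maximum embryo presence score among the smallest five rediae.

    4 -> Y (embryos clearly present), 3 -> Y?, 2 -> U, <=1 -> N (apparently
    embryo-free small rediae, the DOL-consistent outcome).
    """
    sm = [s.embryo_score for s in scores if s.extremum is Extremum.SMALLEST5]
    if not sm:
        return PatternResult("reproduction", "NA", {}, "no smallest-five scores")
    m = max(sm)
    code = {4: "Y", 3: "Y?", 2: "U"}.get(m, "N")
    return PatternResult("reproduction", code, {"max_embryo_score": m, "n": len(sm)})


def percent_small(colony: Colony, volume_code: str) -> PatternResult:
    """Percentage of classified rediae that are small; only meaningful for
    colonies with a bimodal volume distribution (others are NA)."""
    n_small = sum(
        1 for r in colony.included_records if r.size_class is SizeClass.SMALL
    )
    n_large = sum(
        1 for r in colony.included_records if r.size_class is SizeClass.LARGE
    )
    if volume_code != "Y":
        return PatternResult("pct_small", "NA", {}, "volume distribution not bimodal")
    if n_small + n_large == 0:
        raise ValueError("no classified rediae")
    pct = 100.0 * n_small / (n_small + n_large)
    notes = "no small rediae despite bimodal call" if n_small == 0 else ""
    return PatternResult(
        "pct_small", f"{round(pct)}%",
        {"pct_small": pct, "n_small": n_small, "n_large": n_large},
        notes,
    )


def spatial_distribution(
    colony: Colony, config: AnalysisConfig | None = None
) -> PatternResult:
    """Are small rediae over-represented at the snail's invasion front?

    Compares the proportion of small rediae (among small + large;
    intermediates excluded) in the head/foot (or mid section if the foot
    holds none) against the apical (gonad) section using exact binomial
    confidence intervals.  Y = anterior proportion higher and intervals
    disjoint; O = intervals overlap; N = apical proportion higher and
    intervals disjoint; NA = sections not recorded.
    """
    cfg = config or AnalysisConfig()
    by_section: dict[Section, list[SizeClass]] = {}
    for r in colony.included_records:
        if r.size_class in (SizeClass.SMALL, SizeClass.LARGE):
            by_section.setdefault(r.section, []).append(r.size_class)
    by_section.pop(Section.UNKNOWN, None)
    if Section.APICAL not in by_section or len(by_section) < 2:
        return PatternResult(
            "distribution", "NA", {}, "data from multiple body sections not available"
        )
    anterior = Section.FOOT if by_section.get(Section.FOOT) else Section.MID
    if not by_section.get(anterior):
        return PatternResult("distribution", "NA", {}, "no classified anterior rediae")

    def ci(section: Section) -> ProportionCI:
        classes = by_section[section]
        k = sum(1 for c in classes if c is SizeClass.SMALL)
        return proportion_ci(k, len(classes), cfg.ci_level, cfg.ci_method)

    ci_ant, ci_api = ci(anterior), ci(Section.APICAL)
    if ci_ant.overlaps(ci_api):
        code = "O"
    else:
        code = "Y" if ci_ant.point > ci_api.point else "N"
    return PatternResult(
        "distribution", code,
        {
            "anterior_section": anterior.value,
            "prop_small_anterior": ci_ant.point,
            "ci_anterior": (ci_ant.lo, ci_ant.hi),
            "prop_small_apical": ci_api.point,
            "ci_apical": (ci_api.lo, ci_api.hi),
            "ci_method": cfg.ci_method,
        },
    )


def activity_comparison(
    activity: Sequence, config: AnalysisConfig | None = None
) -> PatternResult:
    """Relative distance moved in 2 s (distance / body length), small vs large.

    The 0- and 15-minute measurements are averaged per redia (a single
    available timepoint is used as-is).  The comparison is two-tailed, with
    the direction reported; under DOL small rediae are predicted to be the
    more active class.  S = significant difference, NS = not.
    """
    cfg = config or AnalysisConfig()
    small = [a for a in activity if a.size_label is SizeLabel.SMALL]
    large = [a for a in activity if a.size_label is SizeLabel.LARGE]
    if len(small) < 2 or len(large) < 2:
        return PatternResult("activity", "NA", {}, "fewer than 2 rediae per size class")
    rel_s = [a.relative_distance for a in small]
    rel_l = [a.relative_distance for a in large]
    res = rank_sum(rel_s, rel_l, "two_sided", cfg.exact_n_max)
    abs_res = rank_sum(
        [a.mean_distance_um for a in small],
        [a.mean_distance_um for a in large],
        "two_sided",
        cfg.exact_n_max,
    )
    code = "S" if res.p_value < cfg.alpha else "NS"
    direction = "small" if np.median(rel_s) > np.median(rel_l) else "large"
    return PatternResult(
        "activity", code,
        {
            "p_relative": res.p_value, "U_relative": res.U_statistic,
            "p_absolute": abs_res.p_value, "U_absolute": abs_res.U_statistic,
            "n_small": len(small), "n_large": len(large),
            "more_active_class": direction,
        },
        "DOL predicts higher relative activity in small rediae",
    )


def attack_summary(attacks: Sequence) -> PatternResult:
    """Do observed attacks by small rediae outnumber those by large rediae?"""
    if not attacks:
        return PatternResult("attacks", "NA", {}, "no attack trials")
    totals = {SizeLabel.SMALL: 0, SizeLabel.LARGE: 0}
    by_target: dict[str, int] = {}
    for t in attacks:
        totals[t.attacker_size] += t.n_attacks_observed
        key = f"{t.attacker_size.value}:{t.target_type.value}"
        by_target[key] = by_target.get(key, 0) + t.n_attacks_observed
    code = "Y" if totals[SizeLabel.SMALL] > totals[SizeLabel.LARGE] else "N"
    return PatternResult(
        "attacks", code,
        {
            "attacks_small": totals[SizeLabel.SMALL],
            "attacks_large": totals[SizeLabel.LARGE],
            "by_target": by_target,
        },
    )


def pharynx_outliers(
    values: Sequence[float],
    k: float = 1.5,
    ids: Sequence[str] | None = None,
) -> OutlierResult:
    """Tukey upper-fence screen (> Q3 + k*IQR) on pharynx sizes."""
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("outlier screen requires at least 4 measurements")
    if ids is None:
        ids = [str(i) for i in range(v.size)]
    q1, q3 = quartiles(v)
    iqr = q3 - q1
    fence = q3 + k * iqr
    out_ids = [i for i, x in zip(ids, v) if x > fence]
    return OutlierResult(q1, q3, iqr, fence, out_ids, len(out_ids) / v.size, int(v.size))


def large_pharynx_flag(
    outliers: OutlierResult, min_fraction: float = 0.05
) -> PatternResult:
    """Flag a colony as containing a large-pharynx subpopulation when the
    outlier fraction reaches ``min_fraction`` (inclusive)."""
    flagged = outliers.outlier_fraction >= min_fraction
    return PatternResult(
        "large_pharynx",
        "Y" if flagged else "N",
        {
            "outlier_fraction": outliers.outlier_fraction,
            "upper_fence": outliers.upper_fence,
            "n_outliers": len(outliers.outlier_ids),
            "n": outliers.n,
        },
    )
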