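"""Self-validation experiments: oracle equivalences and parameter recovery.

Each function recomputes one operating characteristic of the pipeline from
scratch — exact-test agreement with independent oracles, type-I error of the
rank-sum primitive, recovery of simulated caste structure, pharynx
allometry, large-pharynx subpopulations and COI species — and returns plain
numbers.  The acceptance script and the acceptance tests both run these.
"""

from __future__ import annotations

import itertools
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

from .coi import cluster_species, identity_matrix
from .config import AnalysisConfig
from .datamodel import SizeClass
from .model import DivisionOfLaborAnalysis
from .patterns import pharynx_outliers
from .simulate import ColonySimConfig, simulate_coi, simulate_colony
from .sizeclasses import assign_size_classes, detect_bimodality
from .stats import proportion_ci, quartiles, rank_sum

__all__ = [
    "exact_rank_sum_max_error",
    "tukey_fence_example",
    "exact_ci_max_error",
    "rank_sum_type1_error",
    "pharynx_recovery_rate",
    "caste_agreement",
    "bimodality_detection_rate",
    "coi_recovery_rate",
    "large_pharynx_recovery_rate",
    "survey_total_colonies",
]


def exact_rank_sum_max_error(max_n: int = 8) -> float:
    """Worst absolute p-value disagreement between the exact rank-sum path
    and an independent exact implementation, over every two-group partition
    of the ranks 1..max_n and every alternative."""
    worst = 0.0
    pooled = list(range(1, max_n + 1))
    for n1 in range(1, max_n):
        for idx in itertools.combinations(range(max_n), n1):
            a = [pooled[i] for i in idx]
            b = [pooled[i] for i in range(max_n) if i not in idx]
            for alt, ref_alt in (
                ("greater", "greater"),
                ("less", "less"),
                ("two_sided", "two-sided"),
            ):
                p = rank_sum(a, b, alt).p_value
                ref = sps.mannwhitneyu(a, b, alternative=ref_alt, method="exact").pvalue
                worst = max(worst, abs(p - ref))
    return worst


def tukey_fence_example() -> dict:
    """Interpolated quartiles and the upper Tukey fence on the worked sample
    {5,5,6,6,7,7,8,30}, against a from-scratch interpolation oracle."""
    values = [5, 5, 6, 6, 7, 7, 8, 30]
    res = pharynx_outliers(values, k=1.5)
    v = np.sort(np.asarray(values, dtype=float))

    def interp(p):
        h = (len(v) - 1) * p
        lo = int(np.floor(h))
        return v[lo] + (h - lo) * (v[min(lo + 1, len(v) - 1)] - v[lo])

    oracle_fence = interp(0.75) + 1.5 * (interp(0.75) - interp(0.25))
    return {
        "q1": res.q1,
        "q3": res.q3,
        "upper_fence": res.upper_fence,
        "n_outliers": len(res.outlier_ids),
        "oracle_fence_abs_error": abs(res.upper_fence - oracle_fence),
    }


def exact_ci_max_error() -> float:
    """Worst bound disagreement between the exact binomial CI and the beta
    quantile oracle at 40/50 and 10/50 successes."""
    worst = 0.0
    for k, n in ((40, 50), (10, 50)):
        ci = proportion_ci(k, n)
        lo = sps.beta.ppf(0.025, k, n - k + 1)
        hi = sps.beta.ppf(0.975, k + 1, n - k)
        worst = max(worst, abs(ci.lo - lo), abs(ci.hi - hi))
    return worst


def rank_sum_type1_error(
    n_reps: int = 10_000, n_per_group: int = 25, alpha: float = 0.05, seed: int = 0
) -> float:
    """Rejection rate of the one-tailed rank-sum test when both groups are
    the same lognormal population."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        a = rng.lognormal(0.0, 1.0, n_per_group)
        b = rng.lognormal(0.0, 1.0, n_per_group)
        if rank_sum(a, b, "greater").p_value < alpha:
            rejections += 1
    return rejections / n_reps


def _recovery_config(seed: int, **overrides) -> ColonySimConfig:
    defaults = dict(n_rediae=100, seed=seed)
    defaults.update(overrides)
    return ColonySimConfig(**defaults)


def pharynx_recovery_rate(
    allometric_exponent: float, n_colonies: int = 200, seed: int = 0
) -> float:
    """Fraction of simulated colonies whose pharynx pattern is coded Y.

    With negative allometry (exponent 0.75) small rediae truly carry
    relatively larger pharynges, so this is the power of the pattern test;
    with isometry (exponent 1.0) it is its size."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_colonies):
        cfg = _recovery_config(
            int(rng.integers(2**31 - 1)),
            allometric_exponent=allometric_exponent,
            pharynx_noise_sd=0.1,
        )
        colony, _ = simulate_colony(cfg)
        res = DivisionOfLaborAnalysis(colony).fit()
        hits += res.patterns["pharynx"].code == "Y"
    return hits / n_colonies


def caste_agreement(
    n_colonies: int = 200, separation_sd: float = 3.0, seed: int = 0
) -> float:
    """Fraction of classified rediae (small/large; intermediates excluded)
    whose assigned caste matches the generating mixture component, at the
    given mode separation in units of mode_sd."""
    rng = np.random.default_rng(seed)
    agree = total = 0
    analysis_cfg = AnalysisConfig()
    for _ in range(n_colonies):
        cfg = _recovery_config(
            int(rng.integers(2**31 - 1)),
            log10_volume_modes=(6.0, 6.0 + separation_sd * 0.15),
        )
        colony, truth = simulate_colony(cfg)
        records = [r for r in colony.included_records if r.body_volume_um3 is not None]
        volumes = [r.body_volume_um3 for r in records]
        labels = assign_size_classes(
            volumes, detect_bimodality(volumes, analysis_cfg)
        )
        for r, lab in zip(records, labels):
            if lab in (SizeClass.SMALL, SizeClass.LARGE):
                total += 1
                agree += lab.value == truth.true_caste[r.redia_id]
    return agree / total


def bimodality_detection_rate(
    separation_sd: float, n_colonies: int = 200, n_rediae: int = 300, seed: int = 0
) -> float:
    """Fraction of simulated colonies called bimodal by the histogram-trough
    rule at the given mode separation (0 gives the false-positive rate)."""
    rng = np.random.default_rng(seed)
    analysis_cfg = AnalysisConfig()
    hits = 0
    for _ in range(n_colonies):
        cfg = _recovery_config(
            int(rng.integers(2**31 - 1)),
            n_rediae=n_rediae,
            log10_volume_modes=(6.0, 6.0 + separation_sd * 0.15),
        )
        colony, _ = simulate_colony(cfg)
        hits += detect_bimodality(colony.volumes(), analysis_cfg).is_bimodal
    return hits / n_colonies


def coi_recovery_rate(
    n_runs: int = 100,
    n_species: int = 20,
    n_per_species: int = 3,
    within_pct: float = 2.0,
    between_pct: float = 8.0,
    seq_length: int = 600,
    seed: int = 0,
) -> float:
    """Fraction of runs in which 95%-identity single-linkage clustering
    recovers exactly the true number of species."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_runs):
        records, _ = simulate_coi(
            n_species, n_per_species, within_pct, between_pct,
            seq_length=seq_length, seed=int(rng.integers(2**31 - 1)),
        )
        clusters = cluster_species(identity_matrix(records, aligned=True), 95.0)
        hits += len(clusters) == n_species
    return hits / n_runs


def large_pharynx_recovery_rate(
    n_colonies: int = 100, fraction: float = 0.10, multiplier: float = 2.0,
    seed: int = 0,
) -> float:
    """Fraction of colonies carrying a simulated large-pharynx subpopulation
    whose measured Tukey-fence outlier fraction falls in the reported
    5-15% range."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_colonies):
        cfg = _recovery_config(
            int(rng.integers(2**31 - 1)),
            n_rediae=300,
            large_pharynx_fraction=fraction,
            large_pharynx_multiplier=multiplier,
        )
        colony, _ = simulate_colony(cfg)
        sizes = [
            r.pharynx_um for r in colony.included_records if r.pharynx_um is not None
        ]
        res = pharynx_outliers(sizes, k=1.5)
        hits += 0.05 <= res.outlier_fraction <= 0.15
    return hits / n_colonies


def survey_total_colonies() -> int:
    """Total number of colonies in the bundled freshwater-survey species
    table (one row per COI species with its colony count)."""
    with resources.files("redialab.data").joinpath(
        "survey_species_counts.csv"
    ).open() as f:
        df = pd.read_csv(f)
    return int(df["n_colonies"].sum())
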