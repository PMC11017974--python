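"""Model/Results interface for the per-colony DOL pattern battery.

:class:`DivisionOfLaborAnalysis` is constructed from a :class:`Colony`
(or from raw data frames) and an :class:`AnalysisConfig`; :meth:`fit` runs
morphometric enrichment, size-caste designation and the full pattern
battery, returning a :class:`DivisionOfLaborResults` that carries every
pattern code with its supporting statistics and renders a one-line summary
row in the comparative-table vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import patterns as pt
from .config import AnalysisConfig
from .datamodel import Colony, Medium, SizeClass
from .morphometrics import enrich_colony
from .sizeclasses import (
    BimodalityResult,
    NormalityResult,
    assign_size_classes,
    detect_bimodality,
    log_volume_normality,
    volume_pattern_code,
)

#: column order of the comparative summary table
SUMMARY_COLUMNS = (
    "Volume",
    "Reproduction",
    "Morphology",
    "Pharynx",
    "%Small",
    "Distribution",
    "Activity",
    "Attacks",
)

_PATTERN_TO_COLUMN = {
    "volume": "Volume",
    "reproduction": "Reproduction",
    "morphology": "Morphology",
    "pharynx": "Pharynx",
    "pct_small": "%Small",
    "distribution": "Distribution",
    "activity": "Activity",
    "attacks": "Attacks",
}


class DivisionOfLaborAnalysis:
    """Pattern-battery model for a single redia colony."""

    def __init__(self, colony: Colony, config: AnalysisConfig | None = None):
        self.colony = colony
        self.config = config or AnalysisConfig()

    @classmethod
    def from_dataframes(
        cls,
        measurements: pd.DataFrame,
        scores: pd.DataFrame | None = None,
        activity: pd.DataFrame | None = None,
        attacks: pd.DataFrame | None = None,
        config: AnalysisConfig | None = None,
    ) -> list["DivisionOfLaborAnalysis"]:
        """One model per colony found in a measurement table."""
        from .io import colonies_from_frames

        return [
            cls(c, config)
            for c in colonies_from_frames(measurements, scores, activity, attacks)
        ]

    def fit(self) -> "DivisionOfLaborResults":
        cfg = self.config
        colony = enrich_colony(self.colony)
        volumes = colony.volumes()
        records = [r for r in colony.included_records if r.body_volume_um3 is not None]

        normality: NormalityResult | None = None
        bimodality = BimodalityResult(False, "quartile_fallback")
        manual = cfg.manual_cutoffs.get(colony.colony_id)
        if manual is not None:
            bimodality = detect_bimodality(volumes, cfg, manual_cutoff_um3=manual)
        if len(volumes) >= 3 and len(set(volumes)) > 1:
            normality = log_volume_normality(volumes)
            if manual is None and normality.p_value < cfg.alpha:
                # only colonies that fail the normality screen are examined
                # for two histogram peaks
                bimodality = detect_bimodality(volumes, cfg)
        if records:
            for r, cls_ in zip(records, assign_size_classes(
                [r.body_volume_um3 for r in records], bimodality
            )):
                r.size_class = cls_

        results: dict[str, pt.PatternResult] = {}
        if normality is None:
            results["volume"] = pt.PatternResult(
                "volume", "NA", {}, "fewer than 3 usable volumes"
            )
        else:
            code = volume_pattern_code(normality, bimodality, cfg.alpha)
            results["volume"] = pt.PatternResult(
                "volume", code,
                {
                    "shapiro_W": normality.W_statistic,
                    "shapiro_p": normality.p_value,
                    "n": normality.n,
                    "method": bimodality.method,
                    "cutoff_volume_um3": bimodality.cutoff_volume_um3,
                },
            )
        results["reproduction"] = pt.reproduction_code(colony.scores)
        results["morphology"] = pt.appendage_pattern(colony.scores, cfg)
        results["pharynx"] = pt.pharynx_pattern(colony, cfg)
        results["abs_pharynx"] = pt.abs_pharynx_pattern(colony, cfg)
        if results["volume"].code == "Y" and any(
            r.size_class in (SizeClass.SMALL, SizeClass.LARGE) for r in records
        ):
            results["pct_small"] = pt.percent_small(colony, "Y")
        else:
            results["pct_small"] = pt.PatternResult(
                "pct_small", "NA", {}, "volume distribution not bimodal"
            )
        results["distribution"] = pt.spatial_distribution(colony, cfg)

        behavior_ok = (
            colony.dissection_medium is Medium.SALINE or cfg.include_water_behavior
        )
        if behavior_ok:
            results["activity"] = pt.activity_comparison(colony.activity, cfg)
            results["attacks"] = pt.attack_summary(colony.attacks)
        else:
            note = "water-dissected colony; behavioural data not analysed"
            results["activity"] = pt.PatternResult("activity", "NA", {}, note)
            results["attacks"] = pt.PatternResult("attacks", "NA", {}, note)

        pharynx_sizes, pharynx_ids = [], []
        for r in colony.included_records:
            value = (
                r.pharynx_um if cfg.outlier_variable == "diameter"
                else r.pharynx_volume_um3
            )
            if value is not None:
                pharynx_sizes.append(value)
                pharynx_ids.append(r.redia_id)
        outliers = None
        if len(pharynx_sizes) >= 4:
            outliers = pt.pharynx_outliers(
                pharynx_sizes, cfg.outlier_fence_k, pharynx_ids
            )
            results["large_pharynx"] = pt.large_pharynx_flag(
                outliers, cfg.large_pharynx_min_fraction
            )
        else:
            results["large_pharynx"] = pt.PatternResult(
                "large_pharynx", "NA", {}, "fewer than 4 pharynx measurements"
            )

        return DivisionOfLaborResults(
            colony=colony,
            config=cfg,
            normality=normality,
            bimodality=bimodality,
            patterns=results,
            outliers=outliers,
        )


@dataclass
class DivisionOfLaborResults:
    """Fitted pattern battery for one colony."""

    colony: Colony
    config: AnalysisConfig
    normality: NormalityResult | None
    bimodality: BimodalityResult
    patterns: dict[str, pt.PatternResult]
    outliers: pt.OutlierResult | None = None

    @property
    def codes(self) -> dict[str, str]:
        """Summary-table codes keyed by column name."""
        return {
            col: self.patterns[name].code
            for name, col in _PATTERN_TO_COLUMN.items()
        }

    def summary(self) -> str:
        c = self.colony
        lines = [
            f"Colony {c.colony_id}"
            + (f" (COI species {c.coi_species})" if c.coi_species else ""),
            f"  dissection medium: {c.dissection_medium.value}; "
            f"n rediae measured: {len(c.included_records)}",
        ]
        if self.normality is not None:
            lines.append(
                f"  log-volume Shapiro-Wilk: W={self.normality.W_statistic:.4f}, "
                f"p={self.normality.p_value:.4g} "
                f"(size classes via {self.bimodality.method})"
            )
        width = max(len(col) for col in SUMMARY_COLUMNS)
        for col in SUMMARY_COLUMNS:
            res = self.patterns[_PATTERN_TO_COLUMN_INV[col]]
            p = res.statistics.get("p_value")
            extra = f"  (p={p:.4g})" if isinstance(p, float) else ""
            lines.append(f"  {col:<{width}} : {res.code}{extra}")
        lp = self.patterns["large_pharynx"]
        if lp.code == "Y":
            frac = lp.statistics["outlier_fraction"]
            lines.append(
                f"  large-pharynx subpopulation: {100 * frac:.0f}% of measured "
                "pharynges above the upper Tukey fence"
            )
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Per-pattern codes and p-values as a tidy frame."""
        rows = []
        for name, res in self.patterns.items():
            rows.append(
                {
                    "colony_id": self.colony.colony_id,
                    "pattern": name,
                    "code": res.code,
                    "p_value": res.statistics.get(
                        "p_value", res.statistics.get("p_relative")
                    ),
                    "notes": res.notes,
                }
            )
        return pd.DataFrame(rows)

    def plot_volume_histogram(self, ax=None):
        """Histogram of log10 body volume with the detected cutoff, if any."""
        import matplotlib.pyplot as plt
        import numpy as np

        if ax is None:
            _, ax = plt.subplots()
        logv = np.log10(self.colony.volumes())
        if self.bimodality.histogram_breaks:
            ax.hist(logv, bins=self.bimodality.histogram_breaks, edgecolor="black")
        else:
            ax.hist(logv, edgecolor="black")
        if self.bimodality.cutoff_volume_um3 is not None:
            ax.axvline(
                np.log10(self.bimodality.cutoff_volume_um3),
                color="red", linestyle="--", label="small/large cutoff",
            )
            ax.legend()
        ax.set_xlabel(r"$\log_{10}$ body volume ($\mu m^3$)")
        ax.set_ylabel("rediae")
        ax.set_title(f"Colony {self.colony.colony_id}")
        return ax


_PATTERN_TO_COLUMN_INV = {v: k for k, v in _PATTERN_TO_COLUMN.items()}
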