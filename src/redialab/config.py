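"""Analysis configuration with lossless JSON round-trip."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class AnalysisConfig:
    """Tunable thresholds for the pattern battery.

    alpha
        Significance level for every hypothesis test; no multiple-testing
        correction is applied anywhere (about 5% of significant calls are
        expected to be false positives by design).
    identity_threshold_pct
        COI percent identity at or above which two sequences are grouped
        into the same putative species.
    outlier_fence_k
        Multiplier on the interquartile range for the upper Tukey fence used
        to flag large-pharynx rediae.
    min_n, min_peak_count, trough_ratio
        Histogram-trough bimodality rule: a colony needs at least ``min_n``
        volumes, two local-maximum bins of at least ``min_peak_count``
        observations, and a between-peak minimum no deeper than
        ``trough_ratio`` times the smaller peak.
    exact_n_max
        Largest combined sample size for which rank-sum p-values are obtained
        by exhaustive enumeration rather than the normal approximation.
    large_pharynx_min_fraction
        Outlier fraction at or above which a colony is flagged as containing
        a large-pharynx subpopulation.
    include_water_behavior
        Behavioural patterns (activity, attacks) are only analysed for
        saline-dissected colonies unless this is set, because osmotic stress
        suppresses movement in water-dissected rediae.
    manual_cutoffs
        Optional per-colony volume cutoffs (um^3) overriding the histogram
        trough.
    """

    alpha: float = 0.05
    identity_threshold_pct: float = 95.0
    outlier_fence_k: float = 1.5
    min_n: int = 20
    min_peak_count: int = 5
    trough_ratio: float = 0.6
    exact_n_max: int = 12
    large_pharynx_min_fraction: float = 0.05
    ci_method: str = "clopper-pearson"
    ci_level: float = 0.95
    include_water_behavior: bool = False
    outlier_variable: str = "diameter"  # or "volume"
    manual_cutoffs: dict[str, float] = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.identity_threshold_pct <= 100:
            raise ValueError("identity_threshold_pct must be in (0, 100]")
        if self.outlier_fence_k <= 0:
            raise ValueError("outlier_fence_k must be positive")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if not 0 <= self.trough_ratio <= 1:
            raise ValueError("trough_ratio must be in [0, 1]")
        if self.min_n < 3:
            raise ValueError("min_n must be at least 3")
        if self.outlier_variable not in ("diameter", "volume"):
            raise ValueError("outlier_variable must be 'diameter' or 'volume'")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "AnalysisConfig":
        p = Path(source)
        text = p.read_text(encoding="utf-8") if p.exists() else str(source)
        data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
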