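"""Comparative summary rows: one per colony, aggregated per species and
overall.

Aggregate cells are count strings such as ``"4Y"`` or ``"1Y/2N*"``, with
codes listed in each pattern's fixed vocabulary order and zero-count codes
omitted.  Percent-small cells aggregate to a range (``"14-43%"``) over the
colonies with a bimodal volume distribution.  Because dissection medium
affects behaviour and size, species aggregates keep water- and
saline-dissected colonies on separate rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .model import SUMMARY_COLUMNS, DivisionOfLaborResults

__all__ = ["ColonySummary", "AggregateRow", "summarize_colony", "aggregate"]

#: vocabulary order used when formatting aggregate count strings
COLUMN_VOCAB_ORDER = {
    "Volume": ("Y", "N*", "N", "NA"),
    "Reproduction": ("Y", "Y?", "U", "N", "NA"),
    "Morphology": ("Y", "O", "N", "NA"),
    "Pharynx": ("Y", "N", "NA"),
    "Distribution": ("Y", "O", "N", "NA"),
    "Activity": ("S", "NS", "NA"),
    "Attacks": ("Y", "N", "NA"),
}


@dataclass
class ColonySummary:
    colony_id: str
    coi_species: str | None
    dissection_medium: str
    codes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in SUMMARY_COLUMNS if c not in self.codes]
        if missing:
            raise ValueError(f"summary missing column(s) {missing}")


@dataclass
class AggregateRow:
    group_label: str
    n_colonies: int
    counts: dict[str, str] = field(default_factory=dict)


def summarize_colony(results: DivisionOfLaborResults | dict) -> ColonySummary:
    """Collapse a fitted battery (or a pattern->result mapping) to one row."""
    if isinstance(results, DivisionOfLaborResults):
        codes = results.codes
        colony = results.colony
        return ColonySummary(
            colony.colony_id,
            colony.coi_species,
            colony.dissection_medium.value,
            codes,
        )
    from .model import _PATTERN_TO_COLUMN

    codes = {}
    for name, col in _PATTERN_TO_COLUMN.items():
        if name not in results:
            raise ValueError(f"missing pattern result: {name!r}")
        codes[col] = results[name].code
    meta = results.get("_meta", {})
    return ColonySummary(
        meta.get("colony_id", "?"),
        meta.get("coi_species"),
        meta.get("dissection_medium", "water"),
        codes,
    )


def _format_counts(codes: Sequence[str], column: str) -> str:
    vocab = COLUMN_VOCAB_ORDER[column]
    parts = []
    for code in vocab:
        k = sum(1 for c in codes if c == code)
        if k:
            parts.append(f"{k}{code}")
    return "/".join(parts) if parts else "NA"


def _format_pct_small(codes: Sequence[str]) -> str:
    values = []
    for c in codes:
        if c.endswith("%"):
            values.append(int(c[:-1]))
    if not values:
        return "NA"
    lo, hi = min(values), max(values)
    return f"{lo}%" if lo == hi else f"{lo}-{hi}%"


def _aggregate_group(label: str, members: list[ColonySummary]) -> AggregateRow:
    counts = {}
    for col in SUMMARY_COLUMNS:
        codes = [m.codes[col] for m in members]
        if col == "%Small":
            counts[col] = _format_pct_small(codes)
        else:
            counts[col] = _format_counts(codes, col)
    return AggregateRow(label, len(members), counts)


def aggregate(
    summaries: Sequence[ColonySummary], group_by: str = "species_medium"
) -> list[AggregateRow]:
    """Per-group count rows plus an overall ``All`` row.

    ``group_by='species_medium'`` groups by (COI species, dissection medium),
    labelled like ``"P113 (w)"``; ``group_by='species'`` ignores medium.
    The ``All`` row is always the true column-wise sum over every colony.
    """
    if not summaries:
        raise ValueError("no summaries to aggregate")
    groups: dict[str, list[ColonySummary]] = {}
    for s in summaries:
        species = s.coi_species or "Unknown"
        if group_by == "species_medium":
            label = f"{species} ({s.dissection_medium[0]})"
        elif group_by == "species":
            label = species
        else:
            raise ValueError(f"unknown group_by {group_by!r}")
        groups.setdefault(label, []).append(s)
    rows = [_aggregate_group(label, members) for label, members in sorted(groups.items())]
    rows.append(_aggregate_group("All", list(summaries)))
    return rows
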