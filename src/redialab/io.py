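"""Readers and writers for the package's external formats.

Measurement, score, activity and attack tables are comma-separated UTF-8
files with a header row; missing values are empty cells (never 0 or -1).
All lengths are micrometres and volumes cubic micrometres; there is no unit
auto-detection.  Reports are tab-separated.  Column names can be remapped
via ``column_map`` for tables exported from other measurement pipelines.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .datamodel import (
    SECTION_ALIASES,
    ActivityRecord,
    AttackTrial,
    Colony,
    Extremum,
    Medium,
    PresenceScores,
    RediaRecord,
    SizeLabel,
    SnailFamily,
    TargetType,
)

__all__ = [
    "read_measurements",
    "read_scores",
    "read_activity",
    "read_attacks",
    "read_fasta",
    "write_fasta",
    "write_report",
    "read_report",
    "colonies_from_frames",
    "write_colony_tables",
]

MEASUREMENT_COLUMNS = (
    "colony_id", "redia_id", "section", "length_um", "width_um", "pharynx_um",
)
SCORE_COLUMNS = (
    "colony_id", "redia_id", "extremum",
    "anterior_score", "posterior_score", "embryo_score",
)
ACTIVITY_COLUMNS = (
    "colony_id", "redia_id", "size_label",
    "distance_t0_um", "distance_t15_um", "body_length_um",
)
ATTACK_COLUMNS = (
    "colony_id", "trial_id", "attacker_size", "target_type",
    "n_attacks_observed", "n_rediae",
)


class SchemaError(ValueError):
    pass


def _read_csv(path: str | Path, required: Sequence[str], column_map=None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file") from None
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def _num(df_value: str, column: str, row: int, path) -> float | None:
    """Parse one numeric cell; empty means missing."""
    s = df_value.strip()
    if s == "":
        return None
    try:
        v = float(s)
    except ValueError:
        raise SchemaError(
            f"{path}: non-numeric value {s!r} in column {column!r}, row {row}"
        ) from None
    if not math.isfinite(v):
        raise SchemaError(f"{path}: non-finite value in column {column!r}, row {row}")
    return v


def _truthy(s: str) -> bool:
    return s.strip().lower() in ("1", "true", "yes", "y")


def read_measurements(
    path: str | Path, column_map: dict | None = None
) -> list[Colony]:
    """Load a per-redia measurement table into one Colony per colony_id.

    Optional columns: ``dissection_medium``, ``snail_family``,
    ``coi_species`` (colony-level, taken from the first row of the colony),
    ``excluded`` and ``exclude_reason`` (row-level reliability flags).
    Rows are never silently dropped: excluded rows are loaded with
    ``excluded=True``.
    """
    df = _read_csv(path, MEASUREMENT_COLUMNS, column_map)
    return _colonies_from_measurement_frame(df, path)


def _colonies_from_measurement_frame(df: pd.DataFrame, path) -> list[Colony]:
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    colonies: dict[str, Colony] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = row._asdict()
        cid = d["colony_id"].strip()
        if cid not in colonies:
            medium = Medium(d.get("dissection_medium", "").strip() or "water")
            fam = d.get("snail_family", "").strip()
            colonies[cid] = Colony(
                colony_id=cid,
                coi_species=d.get("coi_species", "").strip() or None,
                snail_family=SnailFamily(fam) if fam else None,
                dissection_medium=medium,
            )
        section_label = d["section"].strip().lower()
        if section_label not in SECTION_ALIASES:
            raise SchemaError(f"{path}: unknown section {section_label!r} in row {i}")
        rec = RediaRecord(
            redia_id=d["redia_id"].strip(),
            colony_id=cid,
            section=SECTION_ALIASES[section_label],
            length_um=_num(d["length_um"], "length_um", i, path),
            width_um=_num(d["width_um"], "width_um", i, path),
            pharynx_um=_num(d["pharynx_um"], "pharynx_um", i, path),
            excluded=_truthy(d.get("excluded", "")),
            exclude_reason=d.get("exclude_reason", "").strip(),
        )
        colonies[cid].records.append(rec)
    return list(colonies.values())


def read_scores(path: str | Path, column_map: dict | None = None) -> pd.DataFrame:
    df = _read_csv(path, SCORE_COLUMNS, column_map)
    return df


def read_activity(path: str | Path, column_map: dict | None = None) -> pd.DataFrame:
    return _read_csv(path, ACTIVITY_COLUMNS, column_map)


def read_attacks(path: str | Path, column_map: dict | None = None) -> pd.DataFrame:
    return _read_csv(path, ATTACK_COLUMNS, column_map)


def attach_scores(colonies: Iterable[Colony], df: pd.DataFrame, path="scores") -> None:
    by_id = {c.colony_id: c for c in colonies}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = row._asdict()
        cid = d["colony_id"].strip()
        if cid not in by_id:
            raise SchemaError(f"{path}: unknown colony_id {cid!r} in row {i}")
        by_id[cid].scores.append(
            PresenceScores(
                redia_id=d["redia_id"].strip(),
                extremum=Extremum(d["extremum"].strip()),
                anterior_score=int(d["anterior_score"]),
                posterior_score=int(d["posterior_score"]),
                embryo_score=int(d["embryo_score"]),
            )
        )


def attach_activity(colonies: Iterable[Colony], df: pd.DataFrame, path="activity") -> None:
    by_id = {c.colony_id: c for c in colonies}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = row._asdict()
        cid = d["colony_id"].strip()
        if cid not in by_id:
            raise SchemaError(f"{path}: unknown colony_id {cid!r} in row {i}")
        t15 = _num(d["distance_t15_um"], "distance_t15_um", i, path)
        by_id[cid].activity.append(
            ActivityRecord(
                redia_id=d["redia_id"].strip(),
                size_label=SizeLabel(d["size_label"].strip()),
                distance_t0_um=_num(d["distance_t0_um"], "distance_t0_um", i, path),
                distance_t15_um=t15,
                body_length_um=_num(d["body_length_um"], "body_length_um", i, path),
            )
        )


def attach_attacks(colonies: Iterable[Colony], df: pd.DataFrame, path="attacks") -> None:
    by_id = {c.colony_id: c for c in colonies}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = row._asdict()
        cid = d["colony_id"].strip()
        if cid not in by_id:
            raise SchemaError(f"{path}: unknown colony_id {cid!r} in row {i}")
        by_id[cid].attacks.append(
            AttackTrial(
                trial_id=d["trial_id"].strip(),
                attacker_size=SizeLabel(d["attacker_size"].strip()),
                target_type=TargetType(d["target_type"].strip()),
                n_attacks_observed=int(d["n_attacks_observed"]),
                n_rediae=int(d["n_rediae"]),
            )
        )


def colonies_from_frames(
    measurements: pd.DataFrame,
    scores: pd.DataFrame | None = None,
    activity: pd.DataFrame | None = None,
    attacks: pd.DataFrame | None = None,
) -> list[Colony]:
    """Build colonies from already-loaded data frames."""
    df = measurements.fillna("").astype(str)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"measurements frame missing column(s) {missing}")
    colonies = _colonies_from_measurement_frame(df, "<frame>")
    if scores is not None:
        attach_scores(colonies, scores.fillna("").astype(str))
    if activity is not None:
        attach_activity(colonies, activity.fillna("").astype(str))
    if attacks is not None:
        attach_attacks(colonies, attacks.fillna("").astype(str))
    return colonies


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Parse FASTA into (id, uppercased sequence) pairs in file order.

    Gap characters are retained so aligned FASTA round-trips.  Duplicate ids
    and sequence data before the first header are errors.
    """
    from Bio import SeqIO

    allowed = set("ACGTN-")
    text = Path(path).read_text(encoding="utf-8")
    for lineno, line in enumerate(text.splitlines(), 1):
        if line.strip() == "":
            continue
        if not line.startswith(">"):
            raise ValueError(
                f"{path}: sequence data before any '>' header (line {lineno})"
            )
        break
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        bad = set(seq) - allowed
        if bad:
            raise ValueError(
                f"{path}: invalid characters {sorted(bad)} in record {rec.id!r}"
            )
        records.append((rec.id, seq))
    return records


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w", encoding="utf-8") as f:
        for rid, seq in records:
            f.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                f.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# report TSV

REPORT_COLUMNS = (
    "group", "kind", "n_colonies",
    "Volume", "Reproduction", "Morphology", "Pharynx",
    "%Small", "Distribution", "Activity", "Attacks",
)


def write_report(
    colony_summaries: Sequence,
    path: str | Path,
    aggregates: Sequence | None = None,
) -> None:
    """Write per-colony rows plus aggregate rows as a TSV.

    ``colony_summaries`` are :class:`redialab.reporting.ColonySummary`;
    ``aggregates`` (per-species and overall rows) are computed with
    :func:`redialab.reporting.aggregate` when not supplied.
    """
    from .reporting import aggregate

    if aggregates is None:
        aggregates = aggregate(colony_summaries) if colony_summaries else []
    rows = []
    for s in colony_summaries:
        row = {
            "group": s.colony_id, "kind": "colony", "n_colonies": 1,
            **{c: s.codes[c] for c in REPORT_COLUMNS[3:]},
        }
        rows.append(row)
    for a in aggregates:
        rows.append(
            {"group": a.group_label, "kind": "aggregate", "n_colonies": a.n_colonies,
             **{c: a.counts[c] for c in REPORT_COLUMNS[3:]}}
        )
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    try:
        df.to_csv(path, sep="\t", index=False)
    except OSError as e:
        raise OSError(f"failed to write report to {path}: {e}") from e


def read_report(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: report missing column(s) {missing}")
    return df


# ---------------------------------------------------------------------------
# writing simulated colonies back out in the same schemas the readers consume

def write_colony_tables(colonies: Sequence[Colony], out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    m_rows, s_rows, a_rows, t_rows = [], [], [], []
    for c in colonies:
        for r in c.records:
            m_rows.append(
                {
                    "colony_id": c.colony_id,
                    "redia_id": r.redia_id,
                    "section": r.section.value,
                    "length_um": "" if r.length_um is None else repr(r.length_um),
                    "width_um": "" if r.width_um is None else repr(r.width_um),
                    "pharynx_um": "" if r.pharynx_um is None else repr(r.pharynx_um),
                    "dissection_medium": c.dissection_medium.value,
                    "snail_family": c.snail_family.value if c.snail_family else "",
                    "coi_species": c.coi_species or "",
                    "excluded": "true" if r.excluded else "",
                    "exclude_reason": r.exclude_reason,
                }
            )
        for s in c.scores:
            s_rows.append(
                {"colony_id": c.colony_id, "redia_id": s.redia_id,
                 "extremum": s.extremum.value, "anterior_score": s.anterior_score,
                 "posterior_score": s.posterior_score, "embryo_score": s.embryo_score}
            )
        for a in c.activity:
            a_rows.append(
                {"colony_id": c.colony_id, "redia_id": a.redia_id,
                 "size_label": a.size_label.value,
                 "distance_t0_um": repr(a.distance_t0_um),
                 "distance_t15_um": ""
                 if a.distance_t15_um is None else repr(a.distance_t15_um),
                 "body_length_um": repr(a.body_length_um)}
            )
        for t in c.attacks:
            t_rows.append(
                {"colony_id": c.colony_id, "trial_id": t.trial_id,
                 "attacker_size": t.attacker_size.value,
                 "target_type": t.target_type.value,
                 "n_attacks_observed": t.n_attacks_observed,
                 "n_rediae": t.n_rediae}
            )
    paths = {}
    specs = [
        ("measurements", m_rows, list(m_rows[0].keys()) if m_rows else MEASUREMENT_COLUMNS),
        ("scores", s_rows, SCORE_COLUMNS),
        ("activity", a_rows, ACTIVITY_COLUMNS),
        ("attacks", t_rows, ATTACK_COLUMNS),
    ]
    for name, rows, cols in specs:
        p = out / f"{name}.csv"
        pd.DataFrame(rows, columns=list(cols)).to_csv(p, index=False)
        paths[name] = p
    return paths
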