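"""Synthetic colony and COI-sequence generators with known ground truth.

The colony generator draws log10 body volumes from a two-component normal
mixture (the caste structure the size-designation procedure is meant to
recover), back-solves length and width through the cylinder formula at a
fixed aspect ratio, and attaches pharynx diameters through a noisy
allometry ``d = a * L^b``.  Negative allometry (``b < 1``) makes small
rediae carry relatively larger pharynges — the division-of-labor pharynx
signal — while ``b = 1`` with isometric volume scaling gives the null.
Ordinal presence scores come from thresholding a latent logistic variable;
activity distances are lognormal with a caste scale and a dissection-medium
multiplier; attack counts are binomial.  Every draw flows from a single
integer seed, so identical configurations reproduce byte-identical data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .datamodel import (
    ActivityRecord,
    AttackTrial,
    Colony,
    Extremum,
    Medium,
    PresenceScores,
    RediaRecord,
    Section,
    SizeLabel,
    TargetType,
)
from .morphometrics import enrich_colony

__all__ = [
    "ColonySimConfig",
    "SimTruth",
    "simulate_colony",
    "simulate_coi",
    "make_benchmark_suite",
]

_SECTIONS = (Section.APICAL, Section.MID, Section.FOOT)


@dataclass
class ColonySimConfig:
    """Generating parameters for one synthetic colony.

    Defaults describe a freshwater-like colony: a moderately separated
    volume mixture (modes 3 standard deviations apart on the log10 scale,
    about a 2.8-fold volume ratio — far from the 10s-to-100s-fold gaps of
    marine soldier-producing species), negative pharynx allometry, embryos
    visible in small rediae, appendages on both castes, and mild spatial
    bias of small rediae toward the head/foot.
    """

    colony_id: str = "SIM1"
    n_rediae: int = 120
    log10_volume_modes: tuple[float, float] = (6.0, 6.45)  # small, large (um^3)
    mode_sd: float = 0.15
    small_fraction: float = 0.5
    aspect_ratio: float = 4.0  # length / width
    allometric_exponent: float = 0.75  # pharynx diameter ~ length^b
    allometric_intercept: float = 0.43  # um^(1-b)
    pharynx_noise_sd: float = 0.1  # natural-log scale
    pharynx_measured_fraction: float = 0.9
    large_pharynx_fraction: float = 0.0  # of all rediae; drawn from large caste
    large_pharynx_multiplier: float = 2.0
    section_probs_small: tuple[float, float, float] = (0.25, 0.35, 0.40)
    section_probs_large: tuple[float, float, float] = (0.45, 0.35, 0.20)
    embryo_prob_small: float = 0.9
    embryo_prob_large: float = 1.0
    appendage_prob_small: float = 0.9
    appendage_prob_large: float = 0.9
    score_noise: float = 0.5  # latent logistic scale
    n_activity_per_class: int = 10
    activity_scale_small_um: float = 5.0  # water-dissection median, 2 s
    activity_scale_large_um: float = 7.5
    activity_log_sd: float = 0.5
    medium: Medium = Medium.SALINE
    saline_activity_multiplier: float = 2.5
    n_attack_rediae_per_well: int = 10
    attack_prob_small: float = 0.05
    attack_prob_large: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("section_probs_small", "section_probs_large"):
            p = getattr(self, name)
            if len(p) != 3 or any(x < 0 for x in p) or abs(sum(p) - 1) > 1e-9:
                raise ValueError(f"{name} must be 3 nonnegative numbers summing to 1")
        for name in (
            "small_fraction", "large_pharynx_fraction", "embryo_prob_small",
            "embryo_prob_large", "appendage_prob_small", "appendage_prob_large",
            "attack_prob_small", "attack_prob_large", "pharynx_measured_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in (
            "mode_sd", "aspect_ratio", "allometric_exponent",
            "allometric_intercept", "saline_activity_multiplier",
            "activity_scale_small_um", "activity_scale_large_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.large_pharynx_multiplier <= 1:
            raise ValueError("large_pharynx_multiplier must exceed 1")
        if self.n_rediae < 1:
            raise ValueError("n_rediae must be positive")
        if isinstance(self.medium, str):
            self.medium = Medium(self.medium)

    @property
    def mode_separation(self) -> float:
        return self.log10_volume_modes[1] - self.log10_volume_modes[0]


@dataclass
class SimTruth:
    """Ground truth attached to a synthetic colony."""

    colony_id: str
    true_caste: dict[str, str]  # redia_id -> 'small' | 'large'
    truly_bimodal: bool
    has_large_pharynx_subpop: bool
    large_pharynx_ids: list[str]
    config: ColonySimConfig


def _length_from_volume(volume_um3: float, aspect_ratio: float) -> float:
    # V = pi (L/(2*aspect))^2 L  =>  L = (4 aspect^2 V / pi)^(1/3)
    return (4.0 * aspect_ratio**2 * volume_um3 / math.pi) ** (1.0 / 3.0)


def _ordinal_score(rng: np.random.Generator, present: bool, noise: float) -> int:
    latent = (4.0 if present else 0.0) + rng.logistic(0.0, noise)
    return int(np.clip(round(latent), 0, 4))


def simulate_colony(config: ColonySimConfig) -> tuple[Colony, SimTruth]:
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_rediae
    is_small = rng.random(n) < cfg.small_fraction
    mu = np.where(is_small, cfg.log10_volume_modes[0], cfg.log10_volume_modes[1])
    log10_v = rng.normal(mu, cfg.mode_sd)
    volumes = 10.0**log10_v
    lengths = np.array([_length_from_volume(v, cfg.aspect_ratio) for v in volumes])
    widths = lengths / cfg.aspect_ratio
    noise = rng.normal(0.0, cfg.pharynx_noise_sd, n)
    pharynx = cfg.allometric_intercept * lengths**cfg.allometric_exponent * np.exp(noise)
    # the large-pharynx subpopulation is a fraction of the WHOLE colony,
    # drawn from the large caste (capped by its size)
    lp_mask = np.zeros(n, dtype=bool)
    if cfg.large_pharynx_fraction > 0:
        large_idx = np.flatnonzero(~is_small)
        n_lp = min(round(cfg.large_pharynx_fraction * n), large_idx.size)
        chosen = rng.choice(large_idx, size=n_lp, replace=False)
        lp_mask[chosen] = True
        pharynx = np.where(lp_mask, pharynx * cfg.large_pharynx_multiplier, pharynx)
    pharynx_measured = rng.random(n) < cfg.pharynx_measured_fraction

    colony = Colony(colony_id=cfg.colony_id, dissection_medium=cfg.medium)
    truth_caste: dict[str, str] = {}
    for i in range(n):
        probs = cfg.section_probs_small if is_small[i] else cfg.section_probs_large
        section = _SECTIONS[rng.choice(3, p=np.asarray(probs, dtype=float))]
        rid = f"{cfg.colony_id}-r{i + 1:04d}"
        colony.records.append(
            RediaRecord(
                redia_id=rid,
                colony_id=cfg.colony_id,
                section=section,
                length_um=float(lengths[i]),
                width_um=float(widths[i]),
                pharynx_um=float(pharynx[i]) if pharynx_measured[i] else None,
            )
        )
        truth_caste[rid] = "small" if is_small[i] else "large"

    # presence scores for the 5 smallest / 5 largest by true volume
    order = np.argsort(volumes)
    for extremum, idxs in (
        (Extremum.SMALLEST5, order[: min(5, n)]),
        (Extremum.LARGEST5, order[-min(5, n):]),
    ):
        for i in idxs:
            small = bool(is_small[i])
            embryo_p = cfg.embryo_prob_small if small else cfg.embryo_prob_large
            append_p = cfg.appendage_prob_small if small else cfg.appendage_prob_large
            colony.scores.append(
                PresenceScores(
                    redia_id=colony.records[i].redia_id,
                    extremum=extremum,
                    anterior_score=_ordinal_score(
                        rng, rng.random() < append_p, cfg.score_noise
                    ),
                    posterior_score=_ordinal_score(
                        rng, rng.random() < append_p, cfg.score_noise
                    ),
                    embryo_score=_ordinal_score(
                        rng, rng.random() < embryo_p, cfg.score_noise
                    ),
                )
            )

    # activity subsample: the extremes of each caste's length distribution
    medium_mult = (
        cfg.saline_activity_multiplier if cfg.medium is Medium.SALINE else 1.0
    )
    for label, scale in (
        (SizeLabel.SMALL, cfg.activity_scale_small_um),
        (SizeLabel.LARGE, cfg.activity_scale_large_um),
    ):
        caste_mu = (
            cfg.log10_volume_modes[0]
            if label is SizeLabel.SMALL
            else cfg.log10_volume_modes[1]
        )
        for j in range(cfg.n_activity_per_class):
            v = 10.0 ** rng.normal(caste_mu, cfg.mode_sd)
            body_len = _length_from_volume(v, cfg.aspect_ratio)
            d0, d15 = scale * medium_mult * np.exp(
                rng.normal(0.0, cfg.activity_log_sd, 2)
            )
            colony.activity.append(
                ActivityRecord(
                    redia_id=f"{cfg.colony_id}-act-{label.value}{j + 1}",
                    size_label=label,
                    distance_t0_um=float(d0),
                    distance_t15_um=float(d15),
                    body_length_um=float(body_len),
                )
            )

    # attack trials: one well per caste x target type
    for label, p in (
        (SizeLabel.SMALL, cfg.attack_prob_small),
        (SizeLabel.LARGE, cfg.attack_prob_large),
    ):
        for target in TargetType:
            k = cfg.n_attack_rediae_per_well
            colony.attacks.append(
                AttackTrial(
                    trial_id=f"{cfg.colony_id}-atk-{label.value}-{target.value}",
                    attacker_size=label,
                    target_type=target,
                    n_attacks_observed=int(rng.binomial(k, p)),
                    n_rediae=k,
                )
            )

    enrich_colony(colony)
    truly_bimodal = cfg.mode_separation > 0 and 0 < cfg.small_fraction < 1
    truth = SimTruth(
        colony_id=cfg.colony_id,
        true_caste=truth_caste,
        truly_bimodal=truly_bimodal,
        has_large_pharynx_subpop=cfg.large_pharynx_fraction > 0,
        large_pharynx_ids=[
            colony.records[i].redia_id for i in np.flatnonzero(lp_mask)
        ],
        config=cfg,
    )
    return colony, truth


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def simulate_coi(
    n_species: int,
    n_per_species: int,
    within_divergence_pct: float,
    between_divergence_pct: float,
    seq_length: int = 600,
    seed: int = 0,
    return_genealogy: bool = False,
):
    """COI-like sequence set with controlled divergence structure.

    One random ancestor is drawn and each species founder mutates it at
    ``between_divergence_pct`` expected per-site difference (so typical
    *observed* divergence between members of different species is roughly
    twice that, well clear of the clustering threshold).  Members mutate
    their founder at a per-site rate calibrated so that the expected
    *pairwise* divergence between two members of the same species equals
    ``within_divergence_pct``.  Substitutions are uniform over the three
    alternative bases.  Returns the FASTA-style records and the true
    sequence-id -> species map; with ``return_genealogy=True`` a third
    element carries the ancestor and founder sequences.
    """
    if between_divergence_pct <= 2 * within_divergence_pct:
        raise ValueError(
            "between-species divergence must exceed twice the within-species "
            "divergence for the clusters to be separable"
        )
    if seq_length < 100:
        raise ValueError("seq_length must be at least 100")
    rng = np.random.default_rng(seed)
    ancestor = rng.choice(_BASES, seq_length)

    # per-member rate r such that two members of one species differ at an
    # expected fraction q of sites: 2r(1-r) + (2/3)r^2 = q
    q = within_divergence_pct / 100.0
    member_rate = 0.75 - 0.375 * math.sqrt(4.0 - 16.0 * q / 3.0)

    def mutate(seq: np.ndarray, rate: float) -> np.ndarray:
        out = seq.copy()
        sites = np.flatnonzero(rng.random(seq.size) < rate)
        for s in sites:
            alternatives = _BASES[_BASES != out[s]]
            out[s] = rng.choice(alternatives)
        return out

    records: list[tuple[str, str]] = []
    truth: dict[str, str] = {}
    founders: dict[str, str] = {}
    for sp in range(1, n_species + 1):
        founder = mutate(ancestor, between_divergence_pct / 100.0)
        founders[f"sp{sp:02d}"] = founder.tobytes().decode()
        for k in range(1, n_per_species + 1):
            member = mutate(founder, member_rate)
            sid = f"sp{sp:02d}_m{k:02d}"
            records.append((sid, member.tobytes().decode()))
            truth[sid] = f"sp{sp:02d}"
    if return_genealogy:
        genealogy = {"ancestor": ancestor.tobytes().decode(), "founders": founders}
        return records, truth, genealogy
    return records, truth


#: archetype -> (config overrides, expected summary-table codes)
BENCHMARK_ARCHETYPES: dict[str, tuple[dict, dict]] = {
    # marine-style soldier colony: wide bimodality, embryo-free small caste,
    # appendages and relatively huge pharynges only on small rediae,
    # small rediae concentrated at the head/foot
    "dol_like": (
        dict(
            log10_volume_modes=(5.8, 6.7),
            small_fraction=0.25,
            allometric_exponent=0.6,
            embryo_prob_small=0.0,
            appendage_prob_small=0.95,
            appendage_prob_large=0.05,
            section_probs_small=(0.10, 0.25, 0.65),
            section_probs_large=(0.70, 0.20, 0.10),
        ),
        {"Volume": "Y", "Reproduction": "N", "Morphology": "Y", "Pharynx": "Y"},
    ),
    # what this package's field data mostly look like: modest bimodality,
    # reproducing small rediae, appendages on both castes, and a
    # large-pharynx subpopulation among the large rediae
    "freshwater_like": (
        dict(
            large_pharynx_fraction=0.10,
            large_pharynx_multiplier=2.0,
        ),
        {"Reproduction": "Y", "Morphology": "N", "Pharynx": "Y"},
    ),
    # no caste structure at all
    "null": (
        dict(
            log10_volume_modes=(6.2, 6.2),
            allometric_exponent=1.0,
            section_probs_small=(0.4, 0.35, 0.25),
            section_probs_large=(0.4, 0.35, 0.25),
        ),
        {"Volume": "N", "Reproduction": "Y", "Morphology": "N"},
    ),
}


def make_benchmark_suite(
    seed: int = 0,
    n_replicates: int = 10,
    out_dir: str | Path | None = None,
) -> dict:
    """Fixed battery of archetype colonies with a ground-truth manifest.

    Returns ``{"colonies": [(Colony, SimTruth), ...], "manifest": {...}}``;
    when ``out_dir`` is given the datasets are also written in the CSV
    schemas consumed by the readers, alongside ``manifest.json``.
    """
    rng = np.random.default_rng(seed)
    colonies: list[tuple[Colony, SimTruth]] = []
    manifest: dict = {"seed": int(seed), "n_replicates": n_replicates, "colonies": []}
    for name, (overrides, expected) in BENCHMARK_ARCHETYPES.items():
        for rep in range(1, n_replicates + 1):
            child_seed = int(rng.integers(0, 2**31 - 1))
            cfg = ColonySimConfig(
                colony_id=f"{name}-{rep:02d}", seed=child_seed, **overrides
            )
            colony, truth = simulate_colony(cfg)
            colonies.append((colony, truth))
            manifest["colonies"].append(
                {
                    "colony_id": cfg.colony_id,
                    "archetype": name,
                    "seed": child_seed,
                    "expected_codes": expected,
                    "truly_bimodal": truth.truly_bimodal,
                    "has_large_pharynx_subpop": truth.has_large_pharynx_subpop,
                }
            )
    if out_dir is not None:
        from .io import write_colony_tables

        out = Path(out_dir)
        write_colony_tables([c for c, _ in colonies], out)
        cfg_dump = {
            m["colony_id"]: m for m in manifest["colonies"]
        }
        (out / "manifest.json").write_text(
            json.dumps({**manifest, "colonies": list(cfg_dump.values())}, indent=2)
        )
    return {"colonies": colonies, "manifest": manifest}
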