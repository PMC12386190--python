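"""Synthetic cohort generation.

The original study's CT-derived landmarks and genotypes are not
publicly deposited, so this module generates cohorts with the same
statistical structure the analysis assumes: three populations with
their published two-SNP haplotype frequencies, study sex ratios,
Hardy-Weinberg genotypes from random haplotype pairing, a landmark
template calibrated to the Japanese cohort's measurement means, and a
planted additive genotype effect realized geometrically as an anterior
nasion displacement per rs7559271 derived allele (the direction the
nasal-root-flattening interpretation predicts).

Per-landmark Gaussian noise (default 0.7 mm per axis) models combined
biological and digitization variation and reproduces nasal-root angle
SDs of roughly 7-8 degrees; the mid-dacryon is recomputed from the
noisy dacryons, exactly as in the measurement pipeline.  Repeat
digitizations for Dahlberg error analysis add independent noise (default
0.3 mm) to both replicates of the same underlying anatomy.

Everything is driven by a single integer seed and regenerates
bit-exactly.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator
from scipy.optimize import brentq

from . import reference
from .geometry import LandmarkSet, measurement_table, three_point_angle
from .popgen import HAPLOTYPES, HAPLOTYPE_ALLELES

logger = logging.getLogger(__name__)


def load_template() -> dict:
    """Template landmark coordinates and calibration constants."""
    text = resources.files("craniogen.data").joinpath("template_landmarks.json").read_text()
    doc = json.loads(text)
    doc["landmarks"] = {k: np.asarray(v, dtype=float) for k, v in doc["landmarks"].items()}
    return doc


def template_landmark_set(subject_id: str = "template") -> LandmarkSet:
    return LandmarkSet(subject_id, load_template()["landmarks"])


class PopulationSpec(BaseModel):
    """One population's size, sex balance and haplotype frequencies."""

    name: str
    n: int = Field(ge=1)
    female_fraction: float = Field(ge=0.0, le=1.0)
    haplotype_freqs: dict[str, float]

    @field_validator("haplotype_freqs")
    @classmethod
    def _check_freqs(cls, v):
        if set(v) != set(HAPLOTYPES):
            raise ValueError(f"haplotype_freqs needs keys {HAPLOTYPES}")
        if any(f < 0 for f in v.values()) or abs(sum(v.values()) - 1.0) > 1e-6:
            raise ValueError("haplotype frequencies must be non-negative and sum to 1")
        return v


def default_populations() -> list[PopulationSpec]:
    """The three study populations at their published sizes, sex ratios
    and haplotype frequencies."""
    specs = []
    for pop in reference.POPULATIONS:
        males, females = reference.SEX_COUNTS[pop]
        specs.append(PopulationSpec(
            name=pop,
            n=reference.SAMPLE_SIZES[pop],
            female_fraction=females / (males + females),
            haplotype_freqs=dict(reference.HAPLOTYPE_FREQ[pop]),
        ))
    return specs


class SimulationConfig(BaseModel):
    """Full cohort simulation settings.

    ``effect_deg_per_allele`` is the target md-n-g slope per rs7559271
    derived allele; it is converted to an anterior nasion displacement
    by :func:`calibrate_nasion_shift` unless an explicit
    ``nasion_shift_per_allele_mm`` vector is given.  ``direct_effects``
    adds per-allele shifts straight onto named measurement columns
    (statistics-only mode, bypassing geometry).
    """

    populations: list[PopulationSpec] = Field(default_factory=default_populations)
    effect_deg_per_allele: float = -1.8
    nasion_shift_per_allele_mm: tuple[float, float, float] | None = None
    direct_effects: dict[str, float] = Field(default_factory=dict)
    landmark_noise_sd_mm: float | None = None
    seed: int = 0

    @field_validator("landmark_noise_sd_mm")
    @classmethod
    def _nonneg(cls, v):
        if v is not None and v < 0:
            raise ValueError("noise SD must be non-negative")
        return v


@dataclass
class SyntheticCohort:
    """Generated subjects: stacked landmarks, genotypes, and the truth.

    ``points`` maps landmark names to (N, 3) arrays; ``genotypes`` has
    columns subject/population/sex plus derived-allele counts; ``truth``
    records everything needed to audit the generator (seed, planted
    shift, per-population frequencies, true haplotype pairs).
    """

    points: dict[str, np.ndarray]
    genotypes: pd.DataFrame
    truth: dict

    @property
    def n(self) -> int:
        return len(self.genotypes)

    def landmark_sets(self) -> list[LandmarkSet]:
        sets = []
        for i, row in enumerate(self.genotypes.itertuples()):
            pts = {name: arr[i] for name, arr in self.points.items()}
            sets.append(LandmarkSet(row.subject, pts, row.population, row.sex))
        return sets

    def measurements(self) -> pd.DataFrame:
        """Measurement table (vectorized path) with subject metadata and
        any direct (non-geometric) planted effects applied."""
        table = measurement_table(self.points, self.genotypes["subject"].tolist())
        table = table.reset_index()
        table["population"] = self.genotypes["population"].to_numpy()
        table["sex"] = self.genotypes["sex"].to_numpy()
        counts2 = self.genotypes["rs7559271"].to_numpy(dtype=float)
        for var, per_allele in self.truth["direct_effects"].items():
            table[var] = table[var] + per_allele * counts2
        return table


def _mdng_slope_for_shift(delta_mm: float, landmarks: dict) -> float:
    """md-n-g change per allele when n moves delta_mm anteriorly per allele."""
    g, dr, dl = landmarks["g"], landmarks["dR"], landmarks["dL"]
    md = 0.5 * (dr + dl)

    def angle(count: int) -> float:
        n = landmarks["n"] + np.array([0.0, delta_mm * count, 0.0])
        return three_point_angle(md, n, g)

    return (angle(2) - angle(0)) / 2.0


def calibrate_nasion_shift(
    target_deg_per_allele: float = -1.8, landmarks: dict | None = None
) -> np.ndarray:
    """Anterior nasion displacement (mm/allele) whose noiseless md-n-g
    slope on the template equals the target (root-found to 1e-10 mm)."""
    if landmarks is None:
        landmarks = load_template()["landmarks"]
    if target_deg_per_allele == 0:
        return np.zeros(3)
    if target_deg_per_allele > 0:
        raise ValueError("anterior nasion displacement only flattens md-n-g; "
                         "target slope must be <= 0")
    delta = brentq(
        lambda d: _mdng_slope_for_shift(d, landmarks) - target_deg_per_allele,
        0.0, 5.0, xtol=1e-10,
    )
    return np.array([0.0, float(delta), 0.0])


def simulate_genotypes(
    freqs: dict[str, float], n: int, rng: np.random.Generator
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw n subjects' haplotype pairs under random mating.

    Returns derived-allele count columns for both SNPs and the true
    (n, 2) haplotype-index pairs for phasing validation.
    """
    probs = np.array([freqs[h] for h in HAPLOTYPES])
    pairs = rng.choice(len(HAPLOTYPES), size=(n, 2), p=probs / probs.sum())
    alleles = np.array([HAPLOTYPE_ALLELES[h] for h in HAPLOTYPES])
    counts = alleles[pairs[:, 0]] + alleles[pairs[:, 1]]
    table = pd.DataFrame({
        "rs9288572": counts[:, 0].astype(float),
        "rs7559271": counts[:, 1].astype(float),
    })
    return table, pairs


def simulate_cohort(cfg: SimulationConfig, seed: int | None = None) -> SyntheticCohort:
    """Generate a full multi-population cohort.

    Per subject: haplotype pair -> genotype; sex by Bernoulli at the
    population's female fraction; landmarks start from the population-
    and sex-adjusted template, the nasion is displaced by the planted
    vector times the rs7559271 derived count, i.i.d. Gaussian noise is
    added per landmark axis, and md is recomputed afterwards.
    """
    template = load_template()
    base = template["landmarks"]
    calib = template["calibration"]
    noise_sd = (cfg.landmark_noise_sd_mm if cfg.landmark_noise_sd_mm is not None
                else calib["landmark_noise_sd_mm"])
    if cfg.nasion_shift_per_allele_mm is not None:
        shift = np.asarray(cfg.nasion_shift_per_allele_mm, dtype=float)
    elif cfg.effect_deg_per_allele != 0:
        shift = calibrate_nasion_shift(cfg.effect_deg_per_allele, base)
    else:
        shift = np.zeros(3)

    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    names = [nm for nm in base]  # md not in template; derived downstream
    frames, hap_pairs = [], []
    blocks: dict[str, list[np.ndarray]] = {nm: [] for nm in names}
    for spec in cfg.populations:
        geno, pairs = simulate_genotypes(spec.haplotype_freqs, spec.n, rng)
        hap_pairs.append(pairs)
        female = rng.random(spec.n) < spec.female_fraction
        geno.insert(0, "subject", [f"{spec.name[:2].upper()}{i:04d}" for i in range(spec.n)])
        geno.insert(1, "population", spec.name)
        geno.insert(2, "sex", np.where(female, "female", "male"))
        frames.append(geno)

        pop_shift = np.array([0.0, calib["population_nasion_anterior_mm"].get(spec.name, 0.0), 0.0])
        counts2 = geno["rs7559271"].to_numpy(dtype=float)
        scale = np.where(female, calib["female_scale"], 1.0)[:, None]
        sex_shift = np.where(female, calib["female_nasion_anterior_mm"], 0.0)[:, None]
        for nm in names:
            block = np.broadcast_to(base[nm], (spec.n, 3)) * scale
            if nm == "n":
                block = block + pop_shift + counts2[:, None] * shift \
                    + sex_shift * np.array([0.0, 1.0, 0.0])
            block = block + rng.normal(0.0, noise_sd, size=(spec.n, 3))
            blocks[nm].append(block)

    genotypes = pd.concat(frames, ignore_index=True)
    points = {nm: np.concatenate(parts) for nm, parts in blocks.items()}
    truth = {
        "seed": cfg.seed if seed is None else seed,
        "nasion_shift_per_allele_mm": shift.tolist(),
        "effect_deg_per_allele": cfg.effect_deg_per_allele,
        "landmark_noise_sd_mm": noise_sd,
        "direct_effects": dict(cfg.direct_effects),
        "haplotype_freqs": {s.name: s.haplotype_freqs for s in cfg.populations},
        "haplotype_pairs": np.concatenate(hap_pairs),
    }
    return SyntheticCohort(points=points, genotypes=genotypes, truth=truth)


def simulate_repeat_measurements(
    cohort: SyntheticCohort,
    digitization_sd_mm: float | None = None,
    n_subjects: int = 30,
    seed: int = 0,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], np.ndarray]:
    """Two independent noisy digitizations of a random subject subset.

    Both replicates add i.i.d. Gaussian digitization noise to the
    cohort's landmarks, so the per-axis Dahlberg error estimates the
    digitization SD.  Returns (first, second, selected_indices) with
    stacked (n_subjects, 3) blocks per landmark.
    """
    if n_subjects > cohort.n:
        raise ValueError(f"n_subjects={n_subjects} exceeds cohort size {cohort.n}")
    sd = (digitization_sd_mm if digitization_sd_mm is not None
          else load_template()["calibration"]["digitization_sd_mm"])
    rng = np.random.default_rng(seed)
    idx = rng.choice(cohort.n, size=n_subjects, replace=False)
    first, second = {}, {}
    for nm, arr in cohort.points.items():
        anatomy = arr[idx]
        first[nm] = anatomy + rng.normal(0.0, sd, size=anatomy.shape)
        second[nm] = anatomy + rng.normal(0.0, sd, size=anatomy.shape)
    return first, second, idx
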