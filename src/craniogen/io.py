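"""Readers and writers for landmark and genotype files.

Landmark dialects
-----------------
``fcsv``
    3D Slicer Markups fiducial CSV.  The ``# CoordinateSystem`` header is
    respected: LPS coordinates are converted to RAS (x and y negated) so
    that every reader yields the same right-handed frame.
``markups_json``
    3D Slicer Markups JSON (``markups[*].controlPoints``), with the same
    LPS/RAS handling.
``long_csv``
    Plain long-format CSV with columns ``subject,landmark,x,y,z``.

Unrecognized landmark labels are reported (logged) but never fatal;
duplicate labels for the same subject are an error.  Sided rhinion
labels (rhiR/rhiL) are merged into the midline ``rhi`` as their
midpoint.
"""
from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geometry import (
    ALL_VARS,
    ANGLE_VARS,
    DISTANCE_VARS,
    RATIO_VAR,
    LandmarkSet,
    LandmarkValidationError,
    MeasurementRecord,
    canonical_name,
)
from .popgen import SnpDef, SNP_RS9288572, SNP_RS7559271

logger = logging.getLogger(__name__)


class LandmarkParseError(ValueError):
    """Malformed landmark file; message names the offending line/record."""


def _finalize_points(
    raw: dict[str, np.ndarray], subject_id: str
) -> dict[str, np.ndarray]:
    """Merge sided rhinion labels into the midline rhi."""
    points = dict(raw)
    rhi_r = points.pop("rhiR", None)
    rhi_l = points.pop("rhiL", None)
    if rhi_r is not None or rhi_l is not None:
        if "rhi" in points:
            logger.info(
                "subject %s: both midline and sided rhinion supplied; keeping midline",
                subject_id,
            )
        elif rhi_r is not None and rhi_l is not None:
            points["rhi"] = 0.5 * (rhi_r + rhi_l)
        else:
            points["rhi"] = rhi_r if rhi_r is not None else rhi_l
    return points


def _collect(
    labelled: Iterable[tuple[str, np.ndarray]], subject_id: str, source: str
) -> dict[str, np.ndarray]:
    raw: dict[str, np.ndarray] = {}
    unknown: list[str] = []
    for label, xyz in labelled:
        name = canonical_name(label)
        if name is None:
            unknown.append(label)
            continue
        if name in raw:
            raise LandmarkValidationError(
                f"{source}: duplicate landmark label {label!r} for subject {subject_id}"
            )
        raw[name] = xyz
    if unknown:
        logger.warning(
            "%s: ignoring %d unrecognized landmark label(s): %s",
            source, len(unknown), ", ".join(sorted(set(unknown))),
        )
    return _finalize_points(raw, subject_id)


def _read_fcsv(path: Path, subject_id: str) -> dict[str, np.ndarray]:
    coordinate_system = "LPS"  # Slicer default
    labelled: list[tuple[str, np.ndarray]] = []
    with open(path, newline="") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "CoordinateSystem" in line:
                    coordinate_system = line.split("=")[-1].strip()
                continue
            fields = next(csv.reader([line]))
            if len(fields) < 12:
                raise LandmarkParseError(
                    f"{path}:{lineno}: expected >=12 fcsv columns, got {len(fields)}"
                )
            try:
                xyz = np.array([float(fields[1]), float(fields[2]), float(fields[3])])
            except ValueError as exc:
                raise LandmarkParseError(f"{path}:{lineno}: bad coordinate ({exc})") from exc
            labelled.append((fields[11], xyz))
    if coordinate_system.upper().startswith("LPS"):
        labelled = [(lbl, xyz * np.array([-1.0, -1.0, 1.0])) for lbl, xyz in labelled]
    return _collect(labelled, subject_id, str(path))


def _read_markups_json(path: Path, subject_id: str) -> dict[str, np.ndarray]:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise LandmarkParseError(f"{path}: invalid JSON ({exc})") from exc
    labelled: list[tuple[str, np.ndarray]] = []
    for markup in doc.get("markups", []):
        system = markup.get("coordinateSystem", "LPS")
        flip = np.array([-1.0, -1.0, 1.0]) if system.upper().startswith("LPS") else np.ones(3)
        for i, cp in enumerate(markup.get("controlPoints", [])):
            if "label" not in cp or "position" not in cp:
                raise LandmarkParseError(
                    f"{path}: control point {i} lacks label/position"
                )
            labelled.append((cp["label"], np.asarray(cp["position"], dtype=float) * flip))
    return _collect(labelled, subject_id, str(path))


def _read_long_csv(path: Path) -> dict[str, dict[str, np.ndarray]]:
    try:
        frame = pd.read_csv(path)
    except Exception as exc:
        raise LandmarkParseError(f"{path}: unreadable CSV ({exc})") from exc
    required = {"subject", "landmark", "x", "y", "z"}
    if not required.issubset(frame.columns):
        raise LandmarkParseError(
            f"{path}: long CSV needs columns {sorted(required)}, got {list(frame.columns)}"
        )
    out: dict[str, dict[str, np.ndarray]] = {}
    for subject, group in frame.groupby("subject", sort=False):
        labelled = [
            (str(row.landmark), np.array([row.x, row.y, row.z], dtype=float))
            for row in group.itertuples()
        ]
        out[str(subject)] = _collect(labelled, str(subject), str(path))
    return out


def load_landmark_file(
    path,
    dialect: str | None = None,
    subject_id: str | None = None,
    population: str | None = None,
    sex: str | None = None,
) -> LandmarkSet:
    """Load one subject's landmarks from any supported dialect.

    ``dialect`` is one of ``fcsv``, ``markups_json``, ``long_csv``; when
    omitted it is inferred from the file suffix.  For a multi-subject
    long CSV, ``subject_id`` selects the subject (required unless the
    file holds exactly one).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = {
            ".fcsv": "fcsv",
            ".json": "markups_json",
            ".mrk.json": "markups_json",
            ".csv": "long_csv",
        }.get(path.suffix.lower(), "long_csv")
    if dialect == "fcsv":
        points = _read_fcsv(path, subject_id or path.stem)
        return LandmarkSet(subject_id or path.stem, points, population, sex)
    if dialect == "markups_json":
        points = _read_markups_json(path, subject_id or path.stem)
        return LandmarkSet(subject_id or path.stem, points, population, sex)
    if dialect == "long_csv":
        by_subject = _read_long_csv(path)
        if subject_id is None:
            if len(by_subject) != 1:
                raise LandmarkParseError(
                    f"{path}: holds {len(by_subject)} subjects; pass subject_id"
                )
            subject_id = next(iter(by_subject))
        if subject_id not in by_subject:
            raise LandmarkParseError(f"{path}: no subject {subject_id!r}")
        return LandmarkSet(subject_id, by_subject[subject_id], population, sex)
    raise ValueError(f"unknown dialect {dialect!r}")


def load_landmark_table(path, metadata: pd.DataFrame | None = None) -> list[LandmarkSet]:
    """Load every subject from a long-format landmark CSV.

    ``metadata`` (optional) is indexed by subject with ``population`` and
    ``sex`` columns to attach to each set.
    """
    by_subject = _read_long_csv(Path(path))
    sets = []
    for subject, points in by_subject.items():
        population = sex = None
        if metadata is not None and subject in metadata.index:
            population = metadata.loc[subject].get("population")
            sex = metadata.loc[subject].get("sex")
        sets.append(LandmarkSet(subject, points, population, sex))
    return sets


def write_landmarks_csv(sets: Sequence[LandmarkSet], path) -> None:
    """Write landmark sets as long-format CSV ``subject,landmark,x,y,z``."""
    rows = [
        {"subject": lm.subject_id, "landmark": name,
         "x": p[0], "y": p[1], "z": p[2]}
        for lm in sets
        for name, p in lm.points.items()
    ]
    pd.DataFrame(rows, columns=["subject", "landmark", "x", "y", "z"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# measurement table output

_DISPLAY_NAMES = (
    {v: f"{v} (mm)" for v in DISTANCE_VARS}
    | {v: f"{v} (°)" for v in ANGLE_VARS}
    | {RATIO_VAR: f"{RATIO_VAR} ratio"}
)


def write_measurement_tsv(records, path) -> None:
    """Write measurement records as TSV with the published variable names.

    Accepts a list of :class:`MeasurementRecord` or a DataFrame whose
    columns are the internal variable names.
    """
    if isinstance(records, pd.DataFrame):
        frame = records.copy()
    else:
        frame = pd.DataFrame(
            [
                {"subject": r.subject_id, "population": r.population,
                 "sex": r.sex, **r.values}
                for r in records
            ]
        ).set_index("subject")
    frame = frame.rename(columns=_DISPLAY_NAMES)
    frame.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# genotypes

GENOTYPE_COLUMNS = ("subject", "population", "sex", "rs9288572", "rs7559271")


def _parse_genotype_value(value, snp: SnpDef) -> float:
    """Parse 0/1/2 or an allele pair like 'AG' into a derived-allele count."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    text = str(value).strip()
    if text in ("", "NA", "nan", ".", "./."):
        return np.nan
    if text in ("0", "1", "2"):
        return float(text)
    alleles = text.replace("/", "").replace("|", "").upper()
    if len(alleles) == 2 and set(alleles) <= {snp.ancestral, snp.derived}:
        return float(sum(a == snp.derived for a in alleles))
    raise LandmarkValidationError(
        f"cannot parse genotype {value!r} for {snp.rs_id} "
        f"(alleles {snp.ancestral}/{snp.derived})"
    )


def read_genotype_csv(
    path, snps: Sequence[SnpDef] = (SNP_RS9288572, SNP_RS7559271)
) -> pd.DataFrame:
    """Read a genotype CSV into derived-allele counts.

    Expected columns: ``subject,population,sex`` plus one column per rs
    id holding 0/1/2 counts or unphased allele pairs ("AG", "A/G").
    """
    frame = pd.read_csv(path, dtype=str)
    missing = [c for c in ("subject",) + tuple(s.rs_id for s in snps) if c not in frame.columns]
    if missing:
        raise LandmarkParseError(f"{path}: genotype CSV missing column(s) {missing}")
    out = pd.DataFrame({"subject": frame["subject"].astype(str)})
    out["population"] = frame.get("population")
    out["sex"] = frame.get("sex")
    for snp in snps:
        out[snp.rs_id] = [
            _parse_genotype_value(v, snp) for v in frame[snp.rs_id]
        ]
    return out


def read_genotypes_vcf(
    path, snps: Sequence[SnpDef] = (SNP_RS9288572, SNP_RS7559271)
) -> pd.DataFrame:
    """Minimal VCF genotype reader (biallelic SNP records, GT field only).

    Records are matched by rs id; counts are oriented to the derived
    allele of each :class:`SnpDef` regardless of which of REF/ALT it is.
    Missing GT calls become NaN.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    wanted = {snp.rs_id: snp for snp in snps}
    data: dict[str, np.ndarray] = {}
    for variant in vcf:
        if variant.ID not in wanted:
            continue
        if len(variant.ALT) != 1 or not variant.is_snp:
            logger.warning("%s: skipping non-biallelic-SNP record %s", path, variant.ID)
            continue
        snp = wanted[variant.ID]
        alleles = {variant.REF.upper(), variant.ALT[0].upper()}
        if alleles != {snp.ancestral, snp.derived}:
            raise LandmarkValidationError(
                f"{path}: {variant.ID} alleles {sorted(alleles)} do not match "
                f"{snp.ancestral}/{snp.derived}"
            )
        alt_is_derived = variant.ALT[0].upper() == snp.derived
        counts = np.full(len(samples), np.nan)
        for i, gt in enumerate(variant.genotypes):
            calls = [g for g in gt[:2] if g >= 0]
            if len(calls) < 2:
                continue
            alt_count = sum(calls)
            counts[i] = alt_count if alt_is_derived else 2 - alt_count
        data[variant.ID] = counts
    vcf.close()
    out = pd.DataFrame({"subject": samples})
    for snp in snps:
        out[snp.rs_id] = data.get(snp.rs_id, np.nan)
    return out
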