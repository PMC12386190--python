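"""Landmark geometry for 3D craniofacial measurement.

This module defines the landmark catalogue, head-orientation
standardization, and the 21 scalar craniofacial variables (13
inter-landmark distances, 7 three-point angles, 1 ratio) used throughout
the package, plus Dahlberg's method-error statistic for repeated
digitizations.

Coordinates are millimetres.  After :func:`standardize_orientation` the
frame is right-handed with the nasion at the origin, +x toward the
subject's anatomical left, +y anterior and +z superior; the midsagittal
plane (nasion / anterior nasal spine / posterior nasal spine) is x = 0
and the Frankfurt horizontal plane (both porions and the left orbitale)
is horizontal.  All 21 variables are invariant under rigid motion, so
standardization affects axis labels only, never measured values.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical landmark names.  R/L suffixes denote the subject's right and
#: left sides; ``md`` (mid-dacryon) is derived, not digitized.
CATALOGUE = (
    "g", "n", "dR", "dL", "sorR", "sorL", "rhi", "orR", "orL",
    "fzsR", "fzsL", "ans", "pns", "poR", "poL", "s", "A", "B",
    "ba", "me", "md",
)

_CANONICAL = {name.lower(): name for name in CATALOGUE}

# Labels seen in the wild that are not verbatim catalogue names.  "a"/"b"
# are the cephalometric A and B points; sided rhinion labels are merged
# into the single midline rhi by the loaders (see craniogen.io).
_ALIASES = {
    "a": "A",
    "b": "B",
    "a point": "A",
    "b point": "B",
    "apoint": "A",
    "bpoint": "B",
    "point a": "A",
    "point b": "B",
    "nasion": "n",
    "glabella": "g",
    "sella": "s",
    "basion": "ba",
    "menton": "me",
    "rhinion": "rhi",
    "mid-dacryon": "md",
    "middacryon": "md",
}

#: Sided rhinion labels, resolved to the midline ``rhi`` at load time.
RHI_SIDED = {"rhir": "rhiR", "rhil": "rhiL"}

#: Tolerance (mm) above which a supplied mid-dacryon is considered
#: displaced from the dR/dL midpoint and triggers a warning on overwrite.
MD_WARN_TOL_MM = 0.5


class GeometryError(ValueError):
    """Degenerate geometry (collinear plane landmarks, zero-length ray)."""


class MissingLandmarkError(ValueError):
    """A required landmark is absent from a :class:`LandmarkSet`."""


class LandmarkValidationError(ValueError):
    """Landmark data violates catalogue or finiteness constraints."""


def canonical_name(label: str) -> str | None:
    """Map a raw landmark label to its catalogue name (case-insensitive).

    Returns ``None`` for labels that are neither catalogue names, known
    aliases, nor sided rhinion labels.  Sided rhinion labels are returned
    as ``rhiR``/``rhiL`` for the caller to merge.
    """
    key = label.strip().lower()
    if key in _ALIASES:
        return _ALIASES[key]
    if key in RHI_SIDED:
        return RHI_SIDED[key]
    return _CANONICAL.get(key)


def _as_point(value) -> np.ndarray:
    p = np.asarray(value, dtype=float).reshape(3)
    if not np.all(np.isfinite(p)):
        raise LandmarkValidationError(f"non-finite coordinate: {value!r}")
    return p


@dataclass
class LandmarkSet:
    """Named 3D landmarks (mm) for one subject.

    ``points`` maps catalogue names to length-3 float arrays.  Names
    outside the catalogue are rejected; use :func:`canonical_name` /
    the loaders in :mod:`craniogen.io` to normalize raw labels first.
    """

    subject_id: str
    points: dict[str, np.ndarray]
    population: str | None = None
    sex: str | None = None

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for name, value in self.points.items():
            if name not in CATALOGUE:
                raise LandmarkValidationError(
                    f"unknown landmark {name!r} (subject {self.subject_id})"
                )
            if name in clean:  # pragma: no cover - dict input dedupes
                raise LandmarkValidationError(f"duplicate landmark {name!r}")
            clean[name] = _as_point(value)
        self.points = clean
        if self.sex is not None and self.sex not in ("male", "female"):
            raise LandmarkValidationError(f"sex must be male/female, got {self.sex!r}")

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.points[name]
        except KeyError:
            raise MissingLandmarkError(
                f"landmark {name!r} missing for subject {self.subject_id}"
            ) from None

    def require(self, *names: str) -> None:
        missing = [nm for nm in names if nm not in self.points]
        if missing:
            raise MissingLandmarkError(
                f"subject {self.subject_id}: missing landmark(s) {', '.join(missing)}"
            )

    def replace_points(self, points: Mapping[str, np.ndarray]) -> "LandmarkSet":
        return LandmarkSet(
            subject_id=self.subject_id,
            points=dict(points),
            population=self.population,
            sex=self.sex,
        )

    def copy(self) -> "LandmarkSet":
        return self.replace_points({k: v.copy() for k, v in self.points.items()})


# ---------------------------------------------------------------------------
# elementary geometry


def interlandmark_distance(a, b) -> float:
    """Euclidean distance (mm) between two points."""
    return float(np.linalg.norm(_as_point(a) - _as_point(b)))


def three_point_angle(a, vertex, b) -> float:
    """Angle in degrees at ``vertex`` between rays vertex->a and vertex->b.

    The x-v-y measurement notation puts the vertex in the middle: md-n-g
    is the angle at the nasion.  Result lies in [0, 180]; the cosine is
    clamped to [-1, 1] before inversion.
    """
    a = _as_point(a)
    v = _as_point(vertex)
    b = _as_point(b)
    u1 = a - v
    u2 = b - v
    n1 = np.linalg.norm(u1)
    n2 = np.linalg.norm(u2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise GeometryError("zero-length ray in three_point_angle")
    c = float(np.dot(u1, u2) / (n1 * n2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def derive_mid_dacryon(lm: LandmarkSet) -> LandmarkSet:
    """Return a copy with md set to the componentwise dR/dL midpoint.

    The mid-dacryon corresponds to the soft-tissue midendocanthion and is
    always recomputed; a supplied md displaced more than
    :data:`MD_WARN_TOL_MM` from the midpoint is overwritten with a
    logged warning.
    """
    lm.require("dR", "dL")
    md = 0.5 * (lm["dR"] + lm["dL"])
    if "md" in lm:
        displacement = float(np.linalg.norm(lm["md"] - md))
        if displacement > MD_WARN_TOL_MM:
            logger.warning(
                "subject %s: supplied md displaced %.3f mm from dR/dL midpoint; overwritten",
                lm.subject_id, displacement,
            )
    points = {k: v.copy() for k, v in lm.points.items()}
    points["md"] = md
    return lm.replace_points(points)


# ---------------------------------------------------------------------------
# orientation standardization


def _plane_normal(p1, p2, p3) -> np.ndarray:
    normal = np.cross(p2 - p1, p3 - p1)
    norm = np.linalg.norm(normal)
    if norm < 1e-9:
        raise GeometryError("collinear landmarks cannot define a plane")
    return normal / norm


def standardize_orientation(lm: LandmarkSet) -> LandmarkSet:
    """Rigidly re-orient a landmark set into the standard head frame.

    The transform is a rotation plus translation (never scaling): the
    nasion maps to the origin, the midsagittal plane through n/ans/pns
    maps exactly to x = 0, and the Frankfurt plane normal (through poR,
    poL, orL) maps to the vertical axis up to the midsagittal
    constraint.  All inter-landmark distances are preserved.
    """
    lm.require("n", "ans", "pns", "poR", "poL", "orL")
    n = lm["n"]

    x_axis = _plane_normal(n, lm["ans"], lm["pns"])
    fh_normal = _plane_normal(lm["poR"], lm["poL"], lm["orL"])
    # superior orientation: the nasion lies above the Frankfurt plane
    if np.dot(fh_normal, n - lm["poR"]) < 0:
        fh_normal = -fh_normal

    z_axis = fh_normal - np.dot(fh_normal, x_axis) * x_axis
    z_norm = np.linalg.norm(z_axis)
    if z_norm < 1e-9:
        raise GeometryError("midsagittal and Frankfurt planes are parallel")
    z_axis = z_axis / z_norm
    y_axis = np.cross(z_axis, x_axis)

    # anterior = +y: the anterior nasal spine lies in front of the posterior
    if np.dot(y_axis, lm["ans"] - lm["pns"]) < 0:
        x_axis = -x_axis
        y_axis = -y_axis

    if np.dot(x_axis, lm["poL"] - lm["poR"]) < 0:
        logger.warning(
            "subject %s: +x does not point to the subject's left; "
            "input may be mirrored", lm.subject_id,
        )

    rotation = np.vstack([x_axis, y_axis, z_axis])
    points = {name: rotation @ (p - n) for name, p in lm.points.items()}
    return lm.replace_points(points)


# ---------------------------------------------------------------------------
# the 21 measurement variables

#: (variable, endpoint, endpoint) — 13 linear distances in mm.  "a-ba"
#: runs from the cephalometric A point to the basion.
DISTANCE_DEFS: tuple[tuple[str, str, str], ...] = (
    ("n-me", "n", "me"),
    ("n-ans", "n", "ans"),
    ("a-ba", "A", "ba"),
    ("n-ba", "n", "ba"),
    ("n-s", "n", "s"),
    ("poR-poL", "poR", "poL"),
    ("sorR-sorL", "sorR", "sorL"),
    ("fzsR-fzsL", "fzsR", "fzsL"),
    ("orR-orL", "orR", "orL"),
    ("dR-dL", "dR", "dL"),
    ("n-g", "n", "g"),
    ("n-rhi", "n", "rhi"),
    ("n-md", "n", "md"),
)

#: (variable, a, vertex, b) — 7 three-point angles in degrees.
ANGLE_DEFS: tuple[tuple[str, str, str, str], ...] = (
    ("g-n-rhi", "g", "n", "rhi"),
    ("md-n-g", "md", "n", "g"),
    ("s-n-g", "s", "n", "g"),
    ("s-n-rhi", "s", "n", "rhi"),
    ("s-n-md", "s", "n", "md"),
    ("dR-n-dL", "dR", "n", "dL"),
    ("dR-s-dL", "dR", "s", "dL"),
)

RATIO_VAR = "n-md/dR-dL"

DISTANCE_VARS = tuple(d[0] for d in DISTANCE_DEFS)
ANGLE_VARS = tuple(a[0] for a in ANGLE_DEFS)
ALL_VARS = DISTANCE_VARS + ANGLE_VARS + (RATIO_VAR,)

#: The eight variables characterizing nasal-root morphology, used as
#: association outcomes.
NASAL_ROOT_VARS = (
    "g-n-rhi", "md-n-g", "s-n-g", "s-n-rhi", "s-n-md",
    "dR-n-dL", "dR-s-dL", RATIO_VAR,
)


@dataclass
class MeasurementRecord:
    """The 21 scalar craniofacial variables for one subject."""

    subject_id: str
    values: dict[str, float]
    population: str | None = None
    sex: str | None = None

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def compute_measurement_record(lm: LandmarkSet) -> MeasurementRecord:
    """Compute all 21 variables; md is (re)derived from dR/dL first.

    Raises :class:`MissingLandmarkError` naming every variable affected
    by absent landmarks.
    """
    lm = derive_mid_dacryon(lm) if ("dR" in lm and "dL" in lm) else lm
    needed: dict[str, tuple[str, ...]] = {}
    for var, a, b in DISTANCE_DEFS:
        needed[var] = (a, b)
    for var, a, v, b in ANGLE_DEFS:
        needed[var] = (a, v, b)
    affected = {
        var: [nm for nm in lms if nm not in lm]
        for var, lms in needed.items()
    }
    bad = {var: miss for var, miss in affected.items() if miss}
    if bad:
        detail = "; ".join(f"{var} (missing {', '.join(m)})" for var, m in bad.items())
        raise MissingLandmarkError(
            f"subject {lm.subject_id}: cannot compute {detail}"
        )
    values: dict[str, float] = {}
    for var, a, b in DISTANCE_DEFS:
        values[var] = interlandmark_distance(lm[a], lm[b])
    for var, a, v, b in ANGLE_DEFS:
        values[var] = three_point_angle(lm[a], lm[v], lm[b])
    values[RATIO_VAR] = values["n-md"] / values["dR-dL"]
    return MeasurementRecord(
        subject_id=lm.subject_id, values=values,
        population=lm.population, sex=lm.sex,
    )


def measurement_table(
    points: Mapping[str, np.ndarray],
    subject_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Vectorized measurement computation for stacked landmark arrays.

    ``points`` maps each landmark name to an (N, 3) array.  Equivalent
    to :func:`compute_measurement_record` per subject (cross-checked in
    the test suite) but orders of magnitude faster for simulated
    cohorts.
    """
    arrays = {k: np.asarray(v, dtype=float) for k, v in points.items()}
    n_subj = next(iter(arrays.values())).shape[0]
    # md is always recomputed from dR/dL, overriding any supplied block
    arrays["md"] = 0.5 * (arrays["dR"] + arrays["dL"])

    def dist(a: str, b: str) -> np.ndarray:
        return np.linalg.norm(arrays[a] - arrays[b], axis=1)

    def angle(a: str, v: str, b: str) -> np.ndarray:
        u1 = arrays[a] - arrays[v]
        u2 = arrays[b] - arrays[v]
        c = np.einsum("ij,ij->i", u1, u2) / (
            np.linalg.norm(u1, axis=1) * np.linalg.norm(u2, axis=1)
        )
        return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))

    data: dict[str, np.ndarray] = {}
    for var, a, b in DISTANCE_DEFS:
        data[var] = dist(a, b)
    for var, a, v, b in ANGLE_DEFS:
        data[var] = angle(a, v, b)
    data[RATIO_VAR] = data["n-md"] / data["dR-dL"]
    index = subject_ids if subject_ids is not None else range(n_subj)
    return pd.DataFrame(data, index=pd.Index(index, name="subject"))


# ---------------------------------------------------------------------------
# Dahlberg method error

_AXES = {"X": 0, "Y": 1, "Z": 2}


def dahlberg_error(first, second, axis) -> float:
    """Dahlberg's method error sqrt(sum d_i^2 / 2N) on one axis (mm).

    ``first``/``second`` are equal-length paired point lists (first and
    repeat digitization of the same subjects).  When both replicates
    carry independent digitization noise of standard deviation s, the
    statistic estimates s itself: E[ME^2] = s^2.
    """
    a = np.atleast_2d(np.asarray(first, dtype=float))
    b = np.atleast_2d(np.asarray(second, dtype=float))
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise LandmarkValidationError(
            f"paired point lists must share an (N, 3) shape; got {a.shape} vs {b.shape}"
        )
    if a.shape[0] < 1:
        raise LandmarkValidationError("need at least one measurement pair")
    idx = _AXES[axis] if isinstance(axis, str) else int(axis)
    d = a[:, idx] - b[:, idx]
    return float(np.sqrt(np.sum(d * d) / (2 * len(d))))


def measurement_error_report(
    first: Mapping[str, np.ndarray], second: Mapping[str, np.ndarray]
) -> pd.DataFrame:
    """Per-landmark, per-axis Dahlberg errors for paired digitizations.

    Inputs map landmark names to (N, 3) stacked coordinates of the two
    digitization rounds.  Returns a DataFrame indexed by landmark with
    columns X, Y, Z (mm) and n_pairs.
    """
    rows = {}
    for name in first:
        if name not in second:
            continue
        a, b = np.asarray(first[name]), np.asarray(second[name])
        rows[name] = {
            ax: dahlberg_error(a, b, ax) for ax in ("X", "Y", "Z")
        } | {"n_pairs": len(a)}
    report = pd.DataFrame.from_dict(rows, orient="index")
    report.index.name = "landmark"
    return report
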