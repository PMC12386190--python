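"""Geometric morphometrics of the upper face.

Generalized Procrustes analysis (GPA) of the 13 upper-facial landmarks,
principal component analysis of the aligned (Procrustes shape)
coordinates, and wireframe export of per-PC shape deviations.

GPA iteratively removes translation (centering), size (unit centroid
size, optional) and orientation (orthogonal rotation without
reflection) from each configuration against an evolving consensus.  The
consensus is initialized from the mean of the centered/scaled
configurations, which makes the procedure invariant to subject order.
PCA is performed on the covariance of the flattened aligned
coordinates, the standard convention in geometric morphometrics.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import LandmarkSet, MissingLandmarkError, derive_mid_dacryon

logger = logging.getLogger(__name__)

#: The 13 upper-facial landmarks in fixed configuration order.
UPPER_FACE_LANDMARKS = (
    "g", "n", "dR", "dL", "sorR", "sorL", "fzsR", "fzsL",
    "rhi", "orR", "orL", "ans", "A",
)

#: Wireframe edge list over the 13 upper-face landmarks (index pairs).
WIREFRAME_EDGES = (
    ("g", "n"), ("n", "rhi"), ("rhi", "ans"), ("ans", "A"),
    ("n", "dR"), ("n", "dL"), ("dR", "orR"), ("dL", "orL"),
    ("orR", "fzsR"), ("orL", "fzsL"), ("fzsR", "sorR"), ("fzsL", "sorL"),
    ("sorR", "g"), ("sorL", "g"),
)


class MorphometricsError(ValueError):
    pass


@dataclass
class Configuration:
    """One subject's ordered 13x3 upper-face landmark block (mm)."""

    subject_id: str
    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(UPPER_FACE_LANDMARKS), 3):
            raise MorphometricsError(
                f"configuration must be {len(UPPER_FACE_LANDMARKS)}x3, "
                f"got {self.coords.shape}"
            )

    @classmethod
    def from_landmarks(cls, lm: LandmarkSet) -> "Configuration":
        lm = derive_mid_dacryon(lm) if ("dR" in lm and "dL" in lm) else lm
        lm.require(*UPPER_FACE_LANDMARKS)
        return cls(lm.subject_id, np.vstack([lm[nm] for nm in UPPER_FACE_LANDMARKS]))


@dataclass
class ProcrustesResult:
    aligned: np.ndarray          # (N, 13, 3), centroid 0, size 1 if scaled
    consensus: np.ndarray        # (13, 3)
    centroid_sizes: np.ndarray   # (N,) original sizes in mm
    subject_ids: list[str]
    iterations: int
    final_change: float
    converged: bool
    scaled: bool
    objective_trace: list[float] = field(default_factory=list, repr=False)


def centroid_size(coords: np.ndarray) -> float:
    """Square root of the summed squared deviations from the centroid."""
    c = np.asarray(coords, dtype=float)
    return float(np.linalg.norm(c - c.mean(axis=0)))


def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation R (det +1) minimizing ||source @ R - target||_F.

    Reflections are forbidden so anatomical chirality is preserved.
    """
    u, _, vt = np.linalg.svd(source.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d]) @ vt


def generalized_procrustes_align(
    configs: Sequence[Configuration],
    tol: float = 1e-10,
    max_iter: int = 100,
    scale: bool = True,
) -> ProcrustesResult:
    """Iterative GPA of two or more configurations.

    Each configuration is centered, scaled to unit centroid size (unless
    ``scale=False``), and rotated to the running consensus; the
    consensus is the mean of the rotated configurations.  Iteration
    stops when the RMS consensus change drops below ``tol``.  The
    summed squared distance of aligned configurations to the consensus
    (the GPA objective) is recorded per iteration and is non-increasing.
    """
    if len(configs) < 2:
        raise MorphometricsError("GPA needs at least two configurations")
    coords = np.stack([c.coords for c in configs])
    sizes = np.array([centroid_size(c.coords) for c in configs])
    if np.any(sizes < 1e-9):
        bad = [configs[i].subject_id for i in np.where(sizes < 1e-9)[0]]
        raise MorphometricsError(f"degenerate (zero-size) configuration(s): {bad}")
    centered = coords - coords.mean(axis=1, keepdims=True)
    aligned = centered / sizes[:, None, None] if scale else centered.copy()

    # order-invariant initialization: plain mean of unrotated configurations
    consensus = aligned.mean(axis=0)
    if np.linalg.norm(consensus) < 1e-9:  # pragma: no cover - pathological
        consensus = aligned[0]

    change = np.inf
    objective_trace: list[float] = []
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(len(aligned)):
            aligned[i] = aligned[i] @ _optimal_rotation(aligned[i], consensus)
        new_consensus = aligned.mean(axis=0)
        objective_trace.append(float(np.sum((aligned - new_consensus) ** 2)))
        change = float(np.sqrt(np.mean((new_consensus - consensus) ** 2)))
        consensus = new_consensus
        if change < tol:
            converged = True
            break
    if not converged:
        logger.warning("GPA did not converge in %d iterations (change %.2e)", max_iter, change)

    # canonical orientation: rotate everything onto the consensus'
    # principal axes with deterministic signs, so the result depends only
    # on shape content (invariant to the input orientations and to
    # subject order), while preserving chirality
    _, _, vt = np.linalg.svd(consensus, full_matrices=False)
    canon = vt.T
    rotated = consensus @ canon
    for j in range(2):
        if rotated[np.argmax(np.abs(rotated[:, j])), j] < 0:
            canon[:, j] = -canon[:, j]
    if np.linalg.det(canon) < 0:
        canon[:, 2] = -canon[:, 2]
    consensus = consensus @ canon
    aligned = aligned @ canon
    return ProcrustesResult(
        aligned=aligned,
        consensus=consensus,
        centroid_sizes=sizes,
        subject_ids=[c.subject_id for c in configs],
        iterations=iterations,
        final_change=change,
        converged=converged,
        scaled=scale,
        objective_trace=objective_trace,
    )


@dataclass
class PCModel:
    """PCA of flattened Procrustes coordinates.

    ``components`` rows are orthonormal eigenvectors ordered by
    decreasing variance, each with its largest-magnitude loading made
    positive so score signs are reproducible.
    """

    mean: np.ndarray                 # (39,)
    components: np.ndarray           # (k, 39)
    explained_variance: np.ndarray   # (k,) eigenvalues
    variance_fraction: np.ndarray    # (k,) of total variance (all PCs)
    scores: np.ndarray               # (N, k)
    subject_ids: list[str]
    total_variance: float

    def project(self, aligned: np.ndarray) -> np.ndarray:
        """Scores for (possibly new) aligned configurations."""
        flat = np.asarray(aligned).reshape(len(aligned), -1)
        return (flat - self.mean) @ self.components.T


def principal_components(result: ProcrustesResult, n_pcs: int | None = None) -> PCModel:
    """Eigen-decomposition of the aligned-coordinate covariance.

    Requires at least three subjects.  ``n_pcs`` beyond the matrix rank
    is truncated with a warning.
    """
    n_subjects = len(result.aligned)
    if n_subjects < 3:
        raise MorphometricsError("PCA needs at least three subjects")
    flat = result.aligned.reshape(n_subjects, -1)
    mean = flat.mean(axis=0)
    centered = flat - mean
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    eigvals = s**2 / (n_subjects - 1)
    rank = int(np.sum(s > max(centered.shape) * np.finfo(float).eps * (s[0] if s.size else 0)))
    k = rank if n_pcs is None else min(n_pcs, rank)
    if n_pcs is not None and n_pcs > rank:
        logger.warning("requested %d PCs but rank is %d; truncating", n_pcs, rank)
    components = vt[:k]
    scores = centered @ components.T
    # deterministic sign: largest-magnitude loading positive
    for i in range(k):
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] = -components[i]
            scores[:, i] = -scores[:, i]
    total = float(eigvals.sum())
    return PCModel(
        mean=mean,
        components=components,
        explained_variance=eigvals[:k],
        variance_fraction=eigvals[:k] / total if total > 0 else eigvals[:k],
        scores=scores,
        subject_ids=list(result.subject_ids),
        total_variance=total,
    )


@dataclass
class Wireframe:
    """Mean and ±k·SD displaced upper-face coordinates along one PC."""

    edges: tuple
    mean: np.ndarray    # (13, 3)
    plus: np.ndarray    # (13, 3) at mean + k*SD
    minus: np.ndarray   # (13, 3) at mean - k*SD
    k_sd: float
    pc_index: int


def wireframe_deviation(model: PCModel, pc_index: int, k_sd: float = 3.0) -> Wireframe:
    """Shape deviation of ±``k_sd`` standard deviations along one PC."""
    if not 0 <= pc_index < len(model.components):
        raise MorphometricsError(
            f"pc_index {pc_index} outside retained PCs (0..{len(model.components) - 1})"
        )
    sd = float(np.sqrt(model.explained_variance[pc_index]))
    direction = model.components[pc_index]
    shape = (len(UPPER_FACE_LANDMARKS), 3)
    return Wireframe(
        edges=WIREFRAME_EDGES,
        mean=model.mean.reshape(shape),
        plus=(model.mean + k_sd * sd * direction).reshape(shape),
        minus=(model.mean - k_sd * sd * direction).reshape(shape),
        k_sd=k_sd,
        pc_index=pc_index,
    )


def write_wireframe_csv(wf: Wireframe, path, edges_path=None) -> None:
    """Long CSV ``landmark,x,y,z,variant`` (+ optional edge-list CSV)."""
    rows = []
    for variant, block in (("mean", wf.mean), ("plus", wf.plus), ("minus", wf.minus)):
        for name, xyz in zip(UPPER_FACE_LANDMARKS, block):
            rows.append({"landmark": name, "x": xyz[0], "y": xyz[1],
                         "z": xyz[2], "variant": variant})
    pd.DataFrame(rows).to_csv(path, index=False)
    if edges_path is not None:
        pd.DataFrame(wf.edges, columns=["from", "to"]).to_csv(edges_path, index=False)
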