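"""Inverse-variance meta-analysis of per-population regression results.

The fixed-effect estimator weights each population's coefficient by the
reciprocal of its squared standard error:

    w_i = 1 / SE_i^2,  B = sum(w_i B_i) / sum(w_i),  SE = sum(w_i)^(-1/2)

with a two-sided normal p-value from z = B / SE.  A DerSimonian-Laird
random-effects option is provided for sensitivity analysis but the
fixed-effect model is the default.  Cochran's Q and I^2 are reported as
heterogeneity diagnostics.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


class MetaError(ValueError):
    pass


@dataclass
class MetaResult:
    B: float
    SE: float
    z: float
    p: float
    weights: np.ndarray
    k: int
    method: str
    Q: float
    I2: float
    tau2: float = 0.0


def inverse_variance_combine(
    estimates: Sequence[tuple[float, float]], method: str = "fixed"
) -> MetaResult:
    """Combine per-study (B, SE) pairs by inverse-variance weighting."""
    if len(estimates) < 1:
        raise MetaError("need at least one estimate")
    b = np.array([e[0] for e in estimates], dtype=float)
    se = np.array([e[1] for e in estimates], dtype=float)
    if np.any(se <= 0) or not np.all(np.isfinite(se)) or not np.all(np.isfinite(b)):
        raise MetaError("all standard errors must be finite and positive")
    w_fixed = 1.0 / se**2
    b_fixed = float(np.sum(w_fixed * b) / np.sum(w_fixed))
    q = float(np.sum(w_fixed * (b - b_fixed) ** 2))
    k = len(b)
    i2 = max(0.0, (q - (k - 1)) / q) if q > 0 and k > 1 else 0.0
    tau2 = 0.0
    if method == "fixed":
        w = w_fixed
    elif method == "dl":
        denom = np.sum(w_fixed) - np.sum(w_fixed**2) / np.sum(w_fixed)
        tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
        w = 1.0 / (se**2 + tau2)
    else:
        raise ValueError(f"unknown method {method!r}")
    b_comb = float(np.sum(w * b) / np.sum(w))
    se_comb = float(1.0 / np.sqrt(np.sum(w)))
    z = b_comb / se_comb
    return MetaResult(
        B=b_comb, SE=se_comb, z=float(z), p=float(2 * stats.norm.sf(abs(z))),
        weights=w, k=k, method=method, Q=q, I2=float(i2), tau2=float(tau2),
    )


def meta_p_value(m: MetaResult) -> float:
    """Two-sided normal p from the combined z = B/SE."""
    if m.SE <= 0:
        raise MetaError("SE must be positive")
    return float(2 * stats.norm.sf(abs(m.B / m.SE)))


def combine_table(
    results: pd.DataFrame,
    by: Sequence[str] = ("outcome", "term"),
    method: str = "fixed",
) -> pd.DataFrame:
    """Append combined rows to a per-population results table.

    ``results`` needs columns ``population, B, SE`` plus the grouping
    keys in ``by``.  Returns one row per group with the combined B, SE,
    z, p and heterogeneity diagnostics.
    """
    rows = []
    for keys, group in results.groupby(list(by), sort=False):
        keys = keys if isinstance(keys, tuple) else (keys,)
        usable = group.dropna(subset=["B", "SE"])
        usable = usable[usable["SE"] > 0]
        if usable.empty:
            continue
        m = inverse_variance_combine(list(zip(usable["B"], usable["SE"])), method=method)
        rows.append(dict(zip(by, keys)) | {
            "B": m.B, "SE": m.SE, "z": m.z, "p": m.p,
            "k": m.k, "Q": m.Q, "I2": m.I2,
        })
    return pd.DataFrame(rows)
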