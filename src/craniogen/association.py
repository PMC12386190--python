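"""Regression models and group comparisons for genotype-phenotype tests.

Three ordinary-least-squares model families relate a craniofacial
measurement (or PC score) to genotype, always with sex as a covariate
(coded male = 0, female = 1):

single-SNP
    outcome ~ 1 + derived_count + sex
multi-SNP
    outcome ~ 1 + count1 + count2 + count1*count2 + sex
haplotype
    outcome ~ 1 + copies(hAG) + copies(hAA) + copies(hGG) + sex, with the
    fully ancestral hGA absorbed by the intercept.

Inference is t-based with residual degrees of freedom.  Descriptive
group machinery covers genotype-group summaries and cross-population
comparisons (ANOVA + Tukey HSD when every group passes a Shapiro-Wilk
normality screen, otherwise Kruskal-Wallis + Dunn).
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

#: SE below this is treated as an exact fit; p is reported as a sentinel.
_SE_ZERO_TOL = 1e-10
P_SENTINEL = 1e-15


class AssociationError(ValueError):
    pass


@dataclass
class AssociationResult:
    """One fitted term: coefficient, its standard error, and t inference."""

    term: str
    B: float
    SE: float
    t: float
    df: int
    p: float
    n: int
    flagged: bool = False
    note: str = ""


def p_from_t(B: float, SE: float, df: int) -> float:
    """Two-sided p-value for B/SE against a t distribution with df.

    An SE of zero (exact fit) returns the sentinel ``P_SENTINEL``.
    """
    if df < 1:
        raise AssociationError("df must be >= 1")
    if SE < 0:
        raise AssociationError("SE must be non-negative")
    if SE <= _SE_ZERO_TOL * max(1.0, abs(B)):
        return P_SENTINEL
    return float(2 * stats.t.sf(abs(B / SE), df))


def bonferroni_threshold(alpha: float = 0.05, n_tests: int = 16) -> float:
    """Family-wise threshold alpha / n_tests.

    The default family size of 16 is the eight nasal-root variables
    tested against each of the two SNPs.
    """
    if n_tests < 1:
        raise AssociationError("n_tests must be >= 1")
    return alpha / n_tests


def _encode_sex(sex) -> np.ndarray:
    arr = np.asarray(sex)
    if arr.dtype.kind in "OUS":
        mapping = {"male": 0.0, "m": 0.0, "female": 1.0, "f": 1.0}
        try:
            return np.array([mapping[str(s).strip().lower()] for s in arr])
        except KeyError as exc:
            raise AssociationError(f"unknown sex label {exc.args[0]!r}") from None
    return arr.astype(float)


def _fit_ols(y, columns: dict[str, np.ndarray], report: list[str]) -> list[AssociationResult]:
    """OLS on [1, *columns]; returns results for the terms in ``report``.

    Listwise deletion of rows with any missing value; a rank-deficient
    design yields flagged results without p-values.
    """
    y = np.asarray(y, dtype=float)
    names = list(columns)
    design = np.column_stack([np.ones_like(y)] + [np.asarray(columns[nm], dtype=float) for nm in names])
    keep = np.isfinite(y) & np.all(np.isfinite(design), axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("OLS: listwise deletion dropped %d subject(s)", dropped)
    y, design = y[keep], design[keep]
    n, k = design.shape
    if n < k + 1:
        raise AssociationError(f"too few observations (n={n}) for {k} design columns")
    df = n - k
    if np.linalg.matrix_rank(design) < k:
        return [
            AssociationResult(term=nm, B=np.nan, SE=np.nan, t=np.nan, df=df,
                              p=np.nan, n=n, flagged=True, note="rank-deficient design")
            for nm in report
        ]
    fit = sm.OLS(y, design).fit()
    out = []
    for nm in report:
        idx = 1 + names.index(nm)
        b, se = float(fit.params[idx]), float(fit.bse[idx])
        p = p_from_t(b, se, df)
        t = b / se if se > 0 else np.inf * np.sign(b)
        out.append(AssociationResult(
            term=nm, B=b, SE=se, t=float(t), df=df, p=p, n=n,
            note="exact fit (SE = 0)" if p == P_SENTINEL else "",
        ))
    return out


def fit_single_snp_model(y, derived_counts, sex) -> AssociationResult:
    """Additive single-SNP model; returns the genotype term.

    ``derived_counts`` are derived-allele counts 0/1/2; df = n - 3.
    """
    (result,) = _fit_ols(
        y, {"count": derived_counts, "sex": _encode_sex(sex)}, ["count"]
    )
    return result


def fit_multi_snp_model(y, counts1, counts2, sex) -> list[AssociationResult]:
    """Two-SNP model with interaction; returns the three genetic terms."""
    c1 = np.asarray(counts1, dtype=float)
    c2 = np.asarray(counts2, dtype=float)
    return _fit_ols(
        y,
        {"count1": c1, "count2": c2, "interaction": c1 * c2, "sex": _encode_sex(sex)},
        ["count1", "count2", "interaction"],
    )


def fit_haplotype_model(y, copies: pd.DataFrame, sex) -> list[AssociationResult]:
    """Haplotype-copy model with hGA as the reference.

    ``copies`` holds columns hAG/hAA/hGG (per-subject copy numbers from
    :func:`craniogen.popgen.haplotype_copy_table`).  A haplotype absent
    from the cohort is dropped from the design with a warning.
    """
    terms = []
    cols: dict[str, np.ndarray] = {}
    for hap in ("hAG", "hAA", "hGG"):
        values = np.asarray(copies[hap], dtype=float)
        if np.nanmax(values, initial=0.0) <= 0:
            logger.warning("haplotype %s absent from cohort; term dropped", hap)
            continue
        cols[hap] = values
        terms.append(hap)
    if not terms:
        return []
    cols["sex"] = _encode_sex(sex)
    return _fit_ols(y, cols, terms)


# ---------------------------------------------------------------------------
# descriptive group comparisons


@dataclass
class GroupComparisonResult:
    variable: str
    groups: dict[str, dict[str, float]]   # label -> {n, mean, sd}
    omnibus_test: str
    omnibus_p: float | None
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)
    path_note: str = ""


def _summaries(values_by_group: dict[str, np.ndarray]) -> dict[str, dict[str, float]]:
    return {
        label: {
            "n": int(len(v)),
            "mean": float(np.mean(v)),
            "sd": float(np.std(v, ddof=1)) if len(v) > 1 else np.nan,
        }
        for label, v in values_by_group.items()
    }


def genotype_group_summary(
    y, genotypes, variable: str = "", test: str = "anova"
) -> GroupComparisonResult:
    """Per-genotype mean ± SD with an omnibus p across genotype groups.

    ``test`` chooses ANOVA or Kruskal-Wallis (both are defensible for
    genotype-group screening; the parametric path is the default).  A
    single non-empty group yields a summary without a p-value.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(genotypes, dtype=float)
    keep = np.isfinite(y) & np.isfinite(g)
    y, g = y[keep], g[keep]
    groups = {str(int(k)): y[g == k] for k in sorted(np.unique(g)) if np.sum(g == k) > 0}
    summaries = _summaries(groups)
    if len(groups) < 2:
        return GroupComparisonResult(variable, summaries, "none", None,
                                     path_note="single genotype group")
    samples = list(groups.values())
    if np.ptp(y) == 0:
        # completely constant outcome: no evidence against equality
        return GroupComparisonResult(variable, summaries, test, 1.0)
    if test == "anova":
        stat, p = stats.f_oneway(*samples)
    elif test == "kruskal":
        stat, p = stats.kruskal(*samples)
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparisonResult(variable, summaries, test, float(p))


def _dunn_pairwise(values_by_group: dict[str, np.ndarray], holm: bool = False) -> dict:
    """Dunn's z-tests on pooled ranks with tie-corrected variance."""
    labels = list(values_by_group)
    pooled = np.concatenate([values_by_group[k] for k in labels])
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    rank_by_group = {}
    start = 0
    for k in labels:
        size = len(values_by_group[k])
        rank_by_group[k] = ranks[start:start + size]
        start += size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12 * (n_total - 1))
    variance_base = n_total * (n_total + 1) / 12.0 - tie_term
    raw = {}
    for a, b in itertools.combinations(labels, 2):
        na, nb = len(rank_by_group[a]), len(rank_by_group[b])
        z = (rank_by_group[a].mean() - rank_by_group[b].mean()) / np.sqrt(
            variance_base * (1 / na + 1 / nb)
        )
        raw[(a, b)] = float(2 * stats.norm.sf(abs(z)))
    if not holm:
        return raw
    order = sorted(raw, key=raw.get)
    m = len(order)
    adjusted, running = {}, 0.0
    for i, key in enumerate(order):
        running = max(running, min(1.0, (m - i) * raw[key]))
        adjusted[key] = running
    return adjusted


def _tukey_pairwise(values_by_group: dict[str, np.ndarray]) -> dict:
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    labels = np.concatenate([[k] * len(v) for k, v in values_by_group.items()])
    pooled = np.concatenate(list(values_by_group.values()))
    res = pairwise_tukeyhsd(pooled, labels)
    out = {}
    for row in res.summary().data[1:]:
        out[(str(row[0]), str(row[1]))] = float(row[3])
    return out


def compare_populations(
    df: pd.DataFrame,
    variable: str,
    sex: str | None = None,
    group_col: str = "population",
    alpha_normality: float = 0.05,
    holm: bool = False,
    min_n: int = 3,
) -> GroupComparisonResult:
    """Cross-group comparison of one measurement, within a sex stratum.

    Every group is screened with Shapiro-Wilk at ``alpha_normality``;
    if all pass, one-way ANOVA with Tukey HSD pairwise tests is used,
    otherwise Kruskal-Wallis with Dunn's post hoc (pairwise p-values
    unadjusted unless ``holm``).  The chosen path is recorded on the
    result.  Groups with fewer than ``min_n`` observations are excluded
    with a warning.
    """
    data = df if sex is None else df[df["sex"] == sex]
    values_by_group: dict[str, np.ndarray] = {}
    for label, group in data.groupby(group_col, sort=False):
        v = np.asarray(group[variable].dropna(), dtype=float)
        if len(v) < min_n:
            logger.warning("group %s excluded from %s comparison (n=%d < %d)",
                           label, variable, len(v), min_n)
            continue
        values_by_group[str(label)] = v
    summaries = _summaries(values_by_group)
    if len(values_by_group) < 2:
        return GroupComparisonResult(variable, summaries, "none", None,
                                     path_note="fewer than two usable groups")
    normal = all(
        stats.shapiro(v).pvalue > alpha_normality for v in values_by_group.values()
    )
    samples = list(values_by_group.values())
    if normal:
        _, p = stats.f_oneway(*samples)
        pairwise = _tukey_pairwise(values_by_group)
        test, note = "ANOVA", "parametric path (all groups Shapiro-Wilk normal)"
    else:
        _, p = stats.kruskal(*samples)
        pairwise = _dunn_pairwise(values_by_group, holm=holm)
        test, note = "Kruskal-Wallis", "nonparametric path (Shapiro-Wilk rejected)"
    logger.info("compare_populations %s [%s]: %s", variable, sex, note)
    return GroupComparisonResult(variable, summaries, test, float(p), pairwise, note)
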