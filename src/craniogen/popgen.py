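"""Two-SNP population genetics: allele frequencies, EM haplotype
phasing, linkage disequilibrium, and per-subject haplotype copies.

The two PAX3 SNPs analysed throughout the package are rs9288572
(ancestral G, derived A) and rs7559271 (ancestral A, derived G).
Haplotypes are written hXY with the first letter the rs9288572 allele
and the second the rs7559271 allele, so hAG carries the derived allele
at both loci and hGA is the fully ancestral reference.

Phasing uses a maximum-likelihood EM under random mating.  For two
biallelic loci only double heterozygotes are phase-ambiguous, so the
E-step merely splits their mass between the cis (hAG/hGA) and trans
(hAA/hGG) resolutions in proportion to the current haplotype-frequency
products; the allele-frequency margins are preserved exactly at every
iteration.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Haplotype label order used everywhere (frequencies, copies, designs).
HAPLOTYPES = ("hAG", "hAA", "hGG", "hGA")

#: Derived-allele indicator pairs (locus 1 = rs9288572, locus 2 = rs7559271).
HAPLOTYPE_ALLELES = {"hAG": (1, 1), "hAA": (1, 0), "hGG": (0, 1), "hGA": (0, 0)}

_IDX = {h: i for i, h in enumerate(HAPLOTYPES)}


class GenotypeValidationError(ValueError):
    pass


@dataclass(frozen=True)
class SnpDef:
    """A biallelic SNP with an ancestral/derived allele orientation."""

    rs_id: str
    ancestral: str
    derived: str
    position: str = ""

    def __post_init__(self):
        if self.ancestral == self.derived:
            raise GenotypeValidationError("ancestral and derived alleles must differ")


SNP_RS9288572 = SnpDef("rs9288572", ancestral="G", derived="A", position="chr2:222097644")
SNP_RS7559271 = SnpDef("rs7559271", ancestral="A", derived="G", position="chr2:222203567")


def derived_allele_frequency(counts) -> float:
    """Derived-allele frequency from 0/1/2 counts (missing = NaN dropped)."""
    c = np.asarray(counts, dtype=float)
    c = c[~np.isnan(c)]
    if c.size == 0:
        raise GenotypeValidationError("no non-missing genotypes")
    if not np.all(np.isin(c, (0, 1, 2))):
        raise GenotypeValidationError("genotype counts must be 0, 1 or 2")
    return float(c.sum() / (2 * c.size))


@dataclass
class HaplotypeFrequencies:
    """Converged haplotype frequencies with the EM log-likelihood trace."""

    freqs: dict[str, float]
    loglik: float
    iterations: int
    converged: bool
    loglik_trace: list[float] = field(default_factory=list, repr=False)

    def __post_init__(self):
        total = sum(self.freqs.values())
        if abs(total - 1.0) > 1e-6 or any(f < -1e-12 for f in self.freqs.values()):
            raise GenotypeValidationError(f"invalid haplotype frequencies {self.freqs}")

    def __getitem__(self, name: str) -> float:
        return self.freqs[name]

    @property
    def derived_freq_rs9288572(self) -> float:
        return self.freqs["hAG"] + self.freqs["hAA"]

    @property
    def derived_freq_rs7559271(self) -> float:
        return self.freqs["hAG"] + self.freqs["hGG"]

    def as_array(self) -> np.ndarray:
        return np.array([self.freqs[h] for h in HAPLOTYPES])


def _genotype_counts(g1, g2) -> tuple[np.ndarray, int]:
    """3x3 genotype table from paired count vectors; missing pairs dropped."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape:
        raise GenotypeValidationError("genotype vectors differ in length")
    keep = ~(np.isnan(g1) | np.isnan(g2))
    dropped = int((~keep).sum())
    if dropped:
        logger.info("phasing: dropped %d subject(s) with missing genotypes", dropped)
    g1, g2 = g1[keep].astype(int), g2[keep].astype(int)
    if g1.size == 0:
        raise GenotypeValidationError("no complete two-locus genotypes")
    if not (np.all(np.isin(g1, (0, 1, 2))) and np.all(np.isin(g2, (0, 1, 2)))):
        raise GenotypeValidationError("genotype counts must be 0, 1 or 2")
    table = np.zeros((3, 3))
    np.add.at(table, (g1, g2), 1.0)
    return table, dropped


def _pair_resolutions(i: int, j: int) -> list[tuple[int, int]]:
    """Unordered haplotype-index pairs compatible with genotype (i, j)."""
    if i == 1 and j == 1:
        return [(_IDX["hAG"], _IDX["hGA"]), (_IDX["hAA"], _IDX["hGG"])]
    a_alleles = {0: (0, 0), 1: (1, 0), 2: (1, 1)}[i]
    b_alleles = {0: (0, 0), 1: (1, 0), 2: (1, 1)}[j]
    hap_of = {v: k for k, v in HAPLOTYPE_ALLELES.items()}
    # single-het genotypes pair the het locus' two alleles across haplotypes
    h1 = _IDX[hap_of[(a_alleles[0], b_alleles[0])]]
    h2 = _IDX[hap_of[(a_alleles[1], b_alleles[1])]]
    return [(min(h1, h2), max(h1, h2))]


def genotype_log_likelihood(freqs: np.ndarray, table: np.ndarray) -> float:
    """Multinomial log-likelihood of a 3x3 genotype table under HWE."""
    loglik = 0.0
    for i in range(3):
        for j in range(3):
            n_ij = table[i, j]
            if n_ij == 0:
                continue
            p = 0.0
            for h1, h2 in _pair_resolutions(i, j):
                term = freqs[h1] * freqs[h2]
                p += term if h1 == h2 else 2 * term
            if p <= 0:
                return -np.inf
            loglik += n_ij * np.log(p)
    return float(loglik)


def em_phase_two_loci(
    g1,
    g2,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    init=None,
    n_restarts: int = 1,
) -> HaplotypeFrequencies:
    """Maximum-likelihood two-locus haplotype frequencies by EM.

    ``g1``/``g2`` are derived-allele counts at rs9288572 and rs7559271.
    Convergence is declared when the largest frequency change falls
    below ``tol``.  ``init`` (length-4, HAPLOTYPES order) overrides the
    uniform start; ``n_restarts > 1`` adds jittered restarts and keeps
    the best likelihood (guards pathological inputs — the two-locus
    likelihood has a unique interior optimum in practice).
    """
    table, _ = _genotype_counts(g1, g2)
    n = table.sum()

    # fixed contributions from phase-unambiguous genotypes
    base = np.zeros(4)
    for i in range(3):
        for j in range(3):
            if i == 1 and j == 1:
                continue
            (h1, h2), = _pair_resolutions(i, j)
            base[h1] += table[i, j]
            base[h2] += table[i, j]
    n_dh = table[1, 1]

    def run(start: np.ndarray) -> HaplotypeFrequencies:
        f = start / start.sum()
        trace: list[float] = []
        converged = False
        iterations = 0
        for iterations in range(1, max_iter + 1):
            trace.append(genotype_log_likelihood(f, table))
            cis = f[_IDX["hAG"]] * f[_IDX["hGA"]]
            trans = f[_IDX["hAA"]] * f[_IDX["hGG"]]
            p_cis = 0.5 if cis + trans <= 0 else cis / (cis + trans)
            counts = base.copy()
            counts[_IDX["hAG"]] += n_dh * p_cis
            counts[_IDX["hGA"]] += n_dh * p_cis
            counts[_IDX["hAA"]] += n_dh * (1 - p_cis)
            counts[_IDX["hGG"]] += n_dh * (1 - p_cis)
            f_new = counts / (2 * n)
            change = float(np.max(np.abs(f_new - f)))
            f = f_new
            if change < tol:
                converged = True
                break
        loglik = genotype_log_likelihood(f, table)
        trace.append(loglik)
        if not converged:
            logger.warning("EM phasing did not converge in %d iterations", max_iter)
        return HaplotypeFrequencies(
            freqs={h: float(f[_IDX[h]]) for h in HAPLOTYPES},
            loglik=loglik,
            iterations=iterations,
            converged=converged,
            loglik_trace=trace,
        )

    starts = [np.asarray(init, dtype=float) if init is not None else np.full(4, 0.25)]
    rng = np.random.default_rng(0)
    for _ in range(n_restarts - 1):
        starts.append(rng.dirichlet(np.ones(4)))
    results = [run(s) for s in starts]
    return max(results, key=lambda r: r.loglik)


@dataclass
class LDResult:
    """Pairwise linkage-disequilibrium coefficients for two biallelic loci."""

    D: float
    D_prime: float
    r_squared: float
    defined: bool = True


def ld_coefficients(h: HaplotypeFrequencies) -> LDResult:
    """D, D' and r^2 from two-locus haplotype frequencies.

    With p the derived-allele frequency at rs9288572 and q at rs7559271:
    D = f(hAG) - p*q; D' = D / Dmax with the usual sign-dependent
    frequency bound; r^2 = D^2 / (p(1-p)q(1-q)).  A monomorphic locus
    leaves D'/r^2 undefined (``defined=False``).
    """
    p = h.derived_freq_rs9288572
    q = h.derived_freq_rs7559271
    d = h["hAG"] - p * q
    if p <= 0 or p >= 1 or q <= 0 or q >= 1:
        return LDResult(D=float(d), D_prime=np.nan, r_squared=np.nan, defined=False)
    if d > 0:
        d_max = min(p * (1 - q), (1 - p) * q)
    elif d < 0:
        d_max = min(p * q, (1 - p) * (1 - q))
    else:
        return LDResult(D=0.0, D_prime=0.0, r_squared=0.0)
    return LDResult(
        D=float(d),
        D_prime=float(d / d_max),
        r_squared=float(d * d / (p * (1 - p) * q * (1 - q))),
    )


@dataclass
class HaplotypeCopies:
    """Per-subject haplotype copy numbers (sum 2) for the regression design."""

    copies: dict[str, float]
    ambiguous: bool
    posterior: float

    def __post_init__(self):
        if abs(sum(self.copies.values()) - 2.0) > 1e-9:
            raise GenotypeValidationError("haplotype copies must sum to 2")


def assign_haplotype_copies(
    g1: int, g2: int, h: HaplotypeFrequencies, mode: str = "best"
) -> HaplotypeCopies:
    """Resolve one subject's genotype into haplotype copy numbers.

    Phase-unambiguous genotypes are resolved by counting.  Double
    heterozygotes take the cis/trans pair with the larger frequency
    product under ``mode='best'`` (the posterior probability of that
    pair is recorded), or fractional expected copies under
    ``mode='dosage'``.
    """
    if g1 is None or g2 is None or np.isnan(g1) or np.isnan(g2):
        raise GenotypeValidationError("cannot assign copies for missing genotypes")
    i, j = int(g1), int(g2)
    if i not in (0, 1, 2) or j not in (0, 1, 2):
        raise GenotypeValidationError(f"invalid genotype ({g1}, {g2})")
    copies = {hap: 0.0 for hap in HAPLOTYPES}
    if not (i == 1 and j == 1):
        (h1, h2), = _pair_resolutions(i, j)
        copies[HAPLOTYPES[h1]] += 1
        copies[HAPLOTYPES[h2]] += 1
        return HaplotypeCopies(copies=copies, ambiguous=False, posterior=1.0)
    cis = 2 * h["hAG"] * h["hGA"]
    trans = 2 * h["hAA"] * h["hGG"]
    total = cis + trans
    p_cis = 0.5 if total <= 0 else cis / total
    if mode == "dosage":
        copies["hAG"] = copies["hGA"] = p_cis
        copies["hAA"] = copies["hGG"] = 1 - p_cis
        return HaplotypeCopies(copies=copies, ambiguous=True, posterior=max(p_cis, 1 - p_cis))
    if mode != "best":
        raise ValueError(f"unknown mode {mode!r}")
    if p_cis >= 0.5:
        copies["hAG"] = copies["hGA"] = 1.0
    else:
        copies["hAA"] = copies["hGG"] = 1.0
    return HaplotypeCopies(copies=copies, ambiguous=True, posterior=max(p_cis, 1 - p_cis))


def haplotype_copy_table(
    genotypes: pd.DataFrame,
    h: HaplotypeFrequencies,
    mode: str = "best",
    snp1: str = "rs9288572",
    snp2: str = "rs7559271",
) -> pd.DataFrame:
    """Copy numbers for every subject with complete genotypes.

    Returns a DataFrame indexed like ``genotypes`` (rows with missing
    genotypes dropped) with one column per haplotype plus ``ambiguous``
    and ``posterior``.
    """
    keep = genotypes[[snp1, snp2]].notna().all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("haplotype copies: dropped %d subject(s) with missing genotypes", dropped)
    rows = {}
    for idx, row in genotypes.loc[keep].iterrows():
        hc = assign_haplotype_copies(row[snp1], row[snp2], h, mode=mode)
        rows[idx] = {**hc.copies, "ambiguous": hc.ambiguous, "posterior": hc.posterior}
    return pd.DataFrame.from_dict(rows, orient="index")


def hwe_chisq(counts) -> tuple[float, float]:
    """One-df chi-square HWE diagnostic (statistic, p) for one SNP."""
    from scipy import stats

    c = np.asarray(counts, dtype=float)
    c = c[~np.isnan(c)]
    n = c.size
    obs = np.array([(c == k).sum() for k in (0, 1, 2)], dtype=float)
    p = derived_allele_frequency(c)
    exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    if np.any(exp <= 0):
        return np.nan, np.nan
    stat = float(np.sum((obs - exp) ** 2 / exp))
    return stat, float(stats.chi2.sf(stat, df=1))
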