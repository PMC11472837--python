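"""Allele-frequency estimation, Hardy–Weinberg screening, and summary scans.

Allele frequencies come with 95% binomial confidence intervals — Wilson score
by default (bounded, well-behaved at small counts) or Wald for comparison
with older published tables. The Hardy–Weinberg test is the classical 1-df
chi-square against expected proportions (q², 2pq, p²) with the allele
frequency estimated from the same counts, no continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .io import CohortTable, GenotypeCounts, VariantFrequencyRecord

__all__ = [
    "AlleleFreqEstimate",
    "HweResult",
    "HetSummary",
    "NullGenotypeSummary",
    "allele_freq",
    "hwe_chisq",
    "heterozygosity_summary",
    "null_genotype_summary",
    "frequency_table",
]

_CI_METHODS = {"wilson": "wilson", "wald": "normal"}


@dataclass(frozen=True)
class AlleleFreqEstimate:
    p_alt: float
    ci_low: float
    ci_high: float
    ci_method: str
    n_alleles: int


@dataclass(frozen=True)
class HweResult:
    chi2: float
    df: int
    p_value: float
    expected: tuple[float, float, float]
    monomorphic: bool = False


@dataclass(frozen=True)
class HetSummary:
    min_het: float
    max_het: float
    min_locus: str
    max_locus: str


@dataclass(frozen=True)
class NullGenotypeSummary:
    f_null_A: float
    f_null_B: float
    f_concomitant: float


def allele_freq(
    counts: GenotypeCounts, ci_method: str = "wilson", alpha: float = 0.05
) -> AlleleFreqEstimate:
    """Alternative-allele frequency with a binomial CI on 2n allele draws.

    p_alt = (n_het + 2 n_alt_hom) / 2n. The Wilson interval always contains
    the point estimate and stays inside [0, 1]; the Wald interval can escape
    both near the boundaries, which is why it is not the default.
    """
    if counts.n == 0:
        raise ValueError("cannot estimate an allele frequency from zero individuals")
    if ci_method not in _CI_METHODS:
        raise ValueError(f"ci_method must be one of {sorted(_CI_METHODS)}")
    n_alleles = 2 * counts.n
    x = counts.n_alt_alleles
    p = x / n_alleles
    lo, hi = proportion_confint(x, n_alleles, alpha=alpha, method=_CI_METHODS[ci_method])
    if ci_method == "wilson":
        # guard float drift at the boundaries; Wilson brackets p by construction
        lo, hi = min(float(lo), p), max(float(hi), p)
    return AlleleFreqEstimate(
        p_alt=p,
        ci_low=float(lo),
        ci_high=float(hi),
        ci_method=ci_method,
        n_alleles=n_alleles,
    )


def hwe_chisq(counts: GenotypeCounts) -> HweResult:
    """1-df chi-square Hardy–Weinberg test (no continuity correction).

    Expected counts are n·(q², 2pq, p²) with p the alt-allele frequency
    estimated from the same counts. A monomorphic locus has no test; it is
    returned flagged with chi2 = 0 and p = 1 so whole-table scans never abort.
    """
    n = counts.n
    if n == 0:
        raise ValueError("cannot test HWE with zero individuals")
    p = counts.n_alt_alleles / (2 * n)
    q = 1.0 - p
    if p == 0.0 or p == 1.0:
        exp = (n * q**2, 2 * n * p * q, n * p**2)
        return HweResult(0.0, 1, 1.0, exp, monomorphic=True)
    expected = np.array([n * q**2, 2 * n * p * q, n * p**2])
    chi2 = float(((counts.as_array() - expected) ** 2 / expected).sum())
    return HweResult(chi2, 1, float(stats.chi2.sf(chi2, 1)), tuple(expected))


def _hwe_pvalues(obs: np.ndarray) -> np.ndarray:
    """Vectorized HWE chi-square p-values for an m × 3 matrix of counts.

    Monomorphic rows get p = 1 (no test), matching :func:`hwe_chisq`.
    """
    obs = np.asarray(obs, dtype=float)
    n = obs.sum(axis=1)
    p = (obs[:, 1] + 2 * obs[:, 2]) / (2 * n)
    q = 1.0 - p
    expected = np.column_stack([n * q**2, 2 * n * p * q, n * p**2])
    poly = (p > 0) & (p < 1)
    chi2 = np.zeros(len(obs))
    with np.errstate(invalid="ignore", divide="ignore"):
        contrib = (obs - expected) ** 2 / expected
    chi2[poly] = contrib[poly].sum(axis=1)
    pvals = np.ones(len(obs))
    pvals[poly] = stats.chi2.sf(chi2[poly], 1)
    return pvals


def heterozygosity_summary(records: list[VariantFrequencyRecord]) -> HetSummary:
    """Range of observed heterozygote frequencies across loci (ties → first row)."""
    if not records:
        raise ValueError("empty record list")
    hets = np.array([r.f_het for r in records])
    i, j = int(np.argmin(hets)), int(np.argmax(hets))
    return HetSummary(
        min_het=float(hets[i]),
        max_het=float(hets[j]),
        min_locus=records[i].variant.rsid,
        max_locus=records[j].variant.rsid,
    )


def null_genotype_summary(presence_calls) -> NullGenotypeSummary:
    """Frequencies of gene-deletion (null) genotypes from per-individual
    (gene A present?, gene B present?) call pairs — e.g. GSTM1*0 / GSTT1*0
    detected as absence of amplification."""
    calls = np.asarray(presence_calls, dtype=bool)
    if calls.size == 0:
        raise ValueError("empty presence-call input")
    if calls.ndim != 2 or calls.shape[1] != 2:
        raise ValueError("expected an n × 2 array of (A present, B present) booleans")
    a_null = ~calls[:, 0]
    b_null = ~calls[:, 1]
    m = len(calls)
    return NullGenotypeSummary(
        f_null_A=float(a_null.mean()),
        f_null_B=float(b_null.mean()),
        f_concomitant=float((a_null & b_null).sum() / m),
    )


def frequency_table(cohort: CohortTable, ci_method: str = "wilson") -> pd.DataFrame:
    """Per-locus genotype/allele frequency + HWE table from a genotype matrix.

    Missing calls are excluded per locus (per-locus effective n). Columns
    mirror the bundled survey-table schema, plus the effective n.
    """
    rows = []
    for j, v in enumerate(cohort.variants):
        counts = cohort.counts(j)
        if counts.n == 0:
            continue
        est = allele_freq(counts, ci_method=ci_method)
        hwe = hwe_chisq(counts)
        rows.append(
            {
                "rsid": v.rsid,
                "gene": v.gene,
                "ref": v.ref_allele,
                "alt": v.alt_allele,
                "n": counts.n,
                "f_ref_hom": counts.n_ref_hom / counts.n,
                "f_het": counts.n_het / counts.n,
                "f_alt_hom": counts.n_alt_hom / counts.n,
                "p_alt": est.p_alt,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "hwe_chi2": hwe.chi2,
                "hwe_p": hwe.p_value,
                "monomorphic": hwe.monomorphic,
            }
        )
    return pd.DataFrame(rows)
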