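"""Exact and asymptotic tests of genotype-by-stratum contingency tables.

The workhorse is the Fisher–Freeman–Halton exact test for r × c tables under
the fixed-margins (multivariate hypergeometric) null, with the conventional
two-sided definition: the p-value is the total conditional probability of all
margin-compatible tables whose probability does not exceed that of the
observed table. Small problems are solved by full enumeration; larger ones by
a seeded Monte Carlo estimate of the same tail (label-permutation sampling,
which draws exactly from the fixed-margins null), with the add-one correction
(x + 1)/(N + 1) so an estimated p is never zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .io import CohortTable

__all__ = [
    "ContingencyTable",
    "ExactTestResult",
    "ChisqResult",
    "LocusScan",
    "fisher_freeman_halton",
    "chisq_contingency",
    "scan_loci",
]

logger = logging.getLogger(__name__)

#: relative slack when comparing table probabilities for ties
TIE_RTOL = 1e-9
#: "auto" mode switches to Monte Carlo above this many margin-compatible tables
MAX_ENUMERATION = 1_000_000


@dataclass(frozen=True)
class ContingencyTable:
    counts: np.ndarray
    row_labels: tuple = ()
    col_labels: tuple = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=np.int64)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("contingency table must be at least 2 x 2")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if arr.sum() == 0:
            raise ValueError("contingency table is empty")
        object.__setattr__(self, "counts", arr)


@dataclass(frozen=True)
class ExactTestResult:
    p_value: float
    method: str  # "full_enumeration" | "monte_carlo"
    n_tables: int | None = None
    n_permutations: int | None = None
    seed: int | None = None


@dataclass(frozen=True)
class ChisqResult:
    chi2: float
    df: int
    p_value: float


def _as_counts(table) -> np.ndarray:
    if isinstance(table, ContingencyTable):
        return table.counts
    return ContingencyTable(np.asarray(table)).counts


def _compositions(total: int, bounds: tuple[int, ...]):
    """All non-negative integer vectors summing to ``total`` with per-slot bounds."""
    if total > sum(bounds):
        return
    if len(bounds) == 1:
        yield (total,)
        return
    head = bounds[0]
    tail = bounds[1:]
    tail_cap = sum(tail)
    for x in range(max(0, total - tail_cap), min(total, head) + 1):
        for rest in _compositions(total - x, tail):
            yield (x,) + rest


def _bounded_composition_count(total: int, bounds: tuple[int, ...]) -> int:
    """Number of non-negative integer vectors with the given sum and per-slot
    bounds, by inclusion-exclusion over bound violations."""
    c = len(bounds)
    count = 0
    for mask in range(1 << c):
        shift = total
        bits = 0
        for j in range(c):
            if mask >> j & 1:
                bits += 1
                shift -= bounds[j] + 1
        if shift < 0:
            continue
        count += (-1) ** bits * comb(shift + c - 1, c - 1)
    return count


def count_margin_tables(row_margins, col_margins, cap: int = MAX_ENUMERATION) -> int:
    """Number of tables with the given margins, truncated once it exceeds ``cap``.

    The last row is forced by the column margins and the penultimate row is
    counted in closed form, so the decision cost scales with the number of
    choices for the first r − 2 rows, not with the number of tables.
    """
    row_margins = tuple(int(r) for r in row_margins)
    n_rows = len(row_margins)
    if n_rows == 1:
        return 1

    @lru_cache(maxsize=None)
    def rec(i: int, rem: tuple[int, ...]) -> int:
        if i == n_rows - 2:
            return _bounded_composition_count(row_margins[i], rem)
        total = 0
        for comp in _compositions(row_margins[i], rem):
            total += rec(i + 1, tuple(a - b for a, b in zip(rem, comp)))
            if total > cap:
                return total
        return total

    return rec(0, tuple(int(c) for c in col_margins))


def _bounded_compositions_array(total: int, bounds: tuple[int, ...]) -> np.ndarray:
    """All bounded compositions as an (m, C) integer array (vectorized tail)."""
    c = len(bounds)
    empty = np.empty((0, c), dtype=np.int64)
    if total > sum(bounds) or total < 0:
        return empty
    if c == 1:
        return np.array([[total]], dtype=np.int64)
    if c == 2:
        lo, hi = max(0, total - bounds[1]), min(total, bounds[0])
        if hi < lo:
            return empty
        x0 = np.arange(lo, hi + 1, dtype=np.int64)
        return np.column_stack([x0, total - x0])
    parts = []
    lo, hi = max(0, total - sum(bounds[1:])), min(total, bounds[0])
    for x in range(lo, hi + 1):
        rest = _bounded_compositions_array(total - x, bounds[1:])
        if len(rest):
            parts.append(
                np.column_stack([np.full(len(rest), x, dtype=np.int64), rest])
            )
    return np.vstack(parts) if parts else empty


def _enumerate_pvalue(counts: np.ndarray) -> tuple[float, int]:
    """Exact two-sided tail by full enumeration; returns (p, number of tables).

    Rows before the last two are walked recursively; for each partial fill,
    every (penultimate row, forced last row) completion is evaluated in one
    vectorized sweep.
    """
    row_m = counts.sum(axis=1)
    col_m = counts.sum(axis=0)
    n = int(counts.sum())
    lgfact = gammaln(np.arange(n + 1) + 1.0)  # lgfact[x] = log(x!)
    const = float(lgfact[row_m].sum() + lgfact[col_m].sum() - lgfact[n])
    obs_stat = float(lgfact[counts].sum())  # log P(table) = const - stat
    thresh = obs_stat - np.log1p(TIE_RTOL)
    n_rows = len(row_m)
    tail = 0.0
    n_tables = 0

    def complete(rem: tuple[int, ...], acc: float) -> None:
        nonlocal tail, n_tables
        comps = _bounded_compositions_array(int(row_m[n_rows - 2]), rem)
        if not len(comps):
            return
        last = np.asarray(rem, dtype=np.int64)[None, :] - comps
        stat = acc + lgfact[comps].sum(axis=1) + lgfact[last].sum(axis=1)
        n_tables += len(comps)
        sel = stat >= thresh
        if sel.any():
            tail += float(np.exp(const - stat[sel]).sum())

    def rec(i: int, rem: tuple[int, ...], acc: float) -> None:
        if i == n_rows - 2:
            complete(rem, acc)
            return
        for comp in _compositions(int(row_m[i]), rem):
            rec(
                i + 1,
                tuple(a - b for a, b in zip(rem, comp)),
                acc + float(lgfact[list(comp)].sum()),
            )

    rec(0, tuple(int(c) for c in col_m), 0.0)
    return min(tail, 1.0), n_tables


def _mc_pvalue(counts: np.ndarray, n_permutations: int, seed: int) -> float:
    """Monte Carlo estimate of the same tail by column-label permutation."""
    n_r, n_c = counts.shape
    row_m = counts.sum(axis=1)
    col_m = counts.sum(axis=0)
    n = int(counts.sum())
    lgfact = gammaln(np.arange(n + 1) + 1.0)
    obs_stat = float(lgfact[counts].sum())
    thresh = obs_stat - np.log1p(TIE_RTOL)

    r_vec = np.repeat(np.arange(n_r, dtype=np.int64), row_m)
    c_vec = np.repeat(np.arange(n_c, dtype=np.int64), col_m)
    rng = np.random.default_rng(seed)
    hits = 0
    batch = 10_000
    done = 0
    cell_base = r_vec * n_c  # row part of the flat cell index, fixed
    while done < n_permutations:
        b = min(batch, n_permutations - done)
        mat = np.tile(c_vec, (b, 1))
        rng.permuted(mat, axis=1, out=mat)
        idx = cell_base[None, :] + mat
        flat = (idx + (n_r * n_c) * np.arange(b)[:, None]).ravel()
        tables = np.bincount(flat, minlength=b * n_r * n_c).reshape(b, n_r * n_c)
        perm_stats = lgfact[tables].sum(axis=1)
        hits += int((perm_stats >= thresh).sum())
        done += b
    return (hits + 1) / (n_permutations + 1)


def fisher_freeman_halton(
    table,
    mode: str = "auto",
    n_permutations: int = 100_000,
    seed: int | None = None,
) -> ExactTestResult:
    """Fisher–Freeman–Halton exact test on an r × c contingency table.

    ``mode`` is ``"auto"`` (full enumeration when at most
    :data:`MAX_ENUMERATION` margin-compatible tables exist, Monte Carlo
    otherwise), ``"enumerate"`` or ``"mc"``. Monte Carlo requires an explicit
    ``seed`` — estimated p-values must be reproducible.
    """
    counts = _as_counts(table)
    row_m = counts.sum(axis=1)
    col_m = counts.sum(axis=0)
    if (row_m == 0).any() or (col_m == 0).any():
        raise ValueError(
            "degenerate margin: drop empty rows/columns before testing"
        )
    if mode not in ("auto", "enumerate", "mc"):
        raise ValueError("mode must be 'auto', 'enumerate' or 'mc'")
    if mode == "auto":
        n_tab = count_margin_tables(row_m, col_m, cap=MAX_ENUMERATION)
        mode = "enumerate" if n_tab <= MAX_ENUMERATION else "mc"
    if mode == "enumerate":
        p, n_tables = _enumerate_pvalue(counts)
        return ExactTestResult(p, "full_enumeration", n_tables=n_tables)
    if seed is None:
        raise ValueError("Monte Carlo mode requires a seed (reproducibility contract)")
    p = _mc_pvalue(counts, n_permutations, seed)
    return ExactTestResult(
        p, "monte_carlo", n_permutations=n_permutations, seed=int(seed)
    )


def chisq_contingency(table) -> ChisqResult:
    """Pearson chi-square on an r × c table (no continuity correction).

    Asymptotic cross-check for the exact test; refuses tables with a zero
    expected cell, where the exact test should be used instead.
    """
    counts = _as_counts(table)
    expected = stats.contingency.expected_freq(counts)
    if (expected == 0).any():
        raise ValueError(
            "zero expected cell count: the asymptotic chi-square is undefined; "
            "use the exact test (fisher_freeman_halton) instead"
        )
    chi2, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return ChisqResult(float(chi2), int(df), float(p))


@dataclass
class LocusScan:
    stratum_variable: str
    alpha: float
    table: pd.DataFrame  # rsid, p_value, method, significant
    n_significant: int
    correction: str | None = None


def scan_loci(
    cohort: CohortTable,
    stratum_variable: str,
    alpha: float = 0.05,
    correction: str | None = None,
    mode: str = "auto",
    n_permutations: int = 100_000,
    seed: int | None = None,
) -> LocusScan:
    """One exact test per locus on the genotype × stratum table.

    Rows are the genotype classes {ref-hom, het, alt-hom} with zero-total rows
    dropped; columns are the stratum levels present. Raw p-values are compared
    to ``alpha`` by default (no multiple-testing correction); pass
    ``correction="bonferroni"`` or ``"bh"`` to adjust. Monte Carlo sub-seeds
    are derived per locus from ``seed`` so the scan is reproducible.
    """
    if stratum_variable not in cohort.strata.columns:
        raise ValueError(f"stratum variable {stratum_variable!r} not in strata table")
    labels = cohort.strata[stratum_variable].astype(str).to_numpy()
    levels = sorted(set(labels))
    if len(levels) < 2:
        raise ValueError(f"stratum variable {stratum_variable!r} has fewer than 2 levels")
    level_idx = {lev: k for k, lev in enumerate(levels)}
    col_of = np.array([level_idx[l] for l in labels])

    children = (
        np.random.SeedSequence(seed).spawn(cohort.n_loci) if seed is not None else None
    )
    rows = []
    for j, rsid in enumerate(cohort.rsids):
        doses = cohort.genotypes[:, j]
        ok = ~np.isnan(doses)
        if not ok.any():
            logger.info("scan_loci: %s skipped (all genotypes missing)", rsid)
            continue
        tab = np.zeros((3, len(levels)), dtype=np.int64)
        np.add.at(tab, (doses[ok].astype(int), col_of[ok]), 1)
        tab = tab[tab.sum(axis=1) > 0][:, tab.sum(axis=0) > 0]
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            rows.append({"rsid": rsid, "p_value": 1.0, "method": "degenerate"})
            continue
        locus_seed = (
            int(children[j].generate_state(1)[0] % (2**31)) if children is not None else None
        )
        res = fisher_freeman_halton(
            tab, mode=mode, n_permutations=n_permutations, seed=locus_seed
        )
        rows.append({"rsid": rsid, "p_value": res.p_value, "method": res.method})
    df = pd.DataFrame(rows)
    pvals = df["p_value"].to_numpy()
    if correction is not None:
        from statsmodels.stats.multitest import multipletests

        method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[correction]
        sig, p_adj, _, _ = multipletests(pvals, alpha=alpha, method=method)
        df["p_adjusted"] = p_adj
        df["significant"] = sig
        logger.info("scan_loci: applied %s correction at alpha=%g", correction, alpha)
    else:
        df["significant"] = pvals < alpha
    return LocusScan(
        stratum_variable=stratum_variable,
        alpha=alpha,
        table=df,
        n_significant=int(df["significant"].sum()),
        correction=correction,
    )
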