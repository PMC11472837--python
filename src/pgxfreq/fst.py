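"""Pairwise variant-specific F_ST and divergence classification.

For two equally weighted populations with alt-allele frequencies p1 and p2,

    F_ST = (p1 - p2)^2 / [(p1 + p2) (2 - p1 - p2)]

which is algebraically identical to the heterozygosity form (H_T - H_S)/H_T
with H_T = 2 p̄ (1 - p̄), p̄ = (p1 + p2)/2, and H_S the mean within-population
expected heterozygosity. Divergence classes follow the conventional cutoffs:
< 0.05 low, [0.05, 0.15) moderate, [0.15, 0.25] large, > 0.25 very large
(the interval endpoints are fixed half-open/closed-right so that every value
has exactly one class).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FstResult",
    "FstProfile",
    "pairwise_fst",
    "classify_fst",
    "fst_profile",
    "CATEGORIES",
]

logger = logging.getLogger(__name__)

CATEGORIES = ("low", "moderate", "large", "very_large")


@dataclass(frozen=True)
class FstResult:
    rsid: str
    p1: float
    p2: float
    fst: float
    category: str
    monomorphic: bool = False


@dataclass(frozen=True)
class FstProfile:
    comparison_label: str
    results: list[FstResult]
    mean_fst: float
    sd_fst: float
    n_per_category: dict[str, int]
    n_dropped: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "rsid": r.rsid,
                    "p1": r.p1,
                    "p2": r.p2,
                    "fst": r.fst,
                    "category": r.category,
                    "monomorphic": r.monomorphic,
                }
                for r in self.results
            ]
        )


def pairwise_fst(p1, p2):
    """Variant-specific F_ST between two populations; symmetric, in [0, 1].

    Both populations fixed for the same allele (0/0 denominator) is defined
    as 0. Accepts scalars or arrays.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if ((p1 < 0) | (p1 > 1)).any() or ((p2 < 0) | (p2 > 1)).any():
        raise ValueError("allele frequencies must lie in [0, 1]")
    s = p1 + p2  # computed once so the statistic is exactly symmetric
    denom = s * (2.0 - s)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (p1 - p2) ** 2 / np.where(denom > 0, denom, 1.0), 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def classify_fst(fst: float) -> str:
    """Divergence class: <0.05 low, [0.05,0.15) moderate, [0.15,0.25] large, >0.25 very large."""
    if not 0.0 <= fst <= 1.0:
        raise ValueError("F_ST must lie in [0, 1]")
    if fst < 0.05:
        return "low"
    if fst < 0.15:
        return "moderate"
    if fst <= 0.25:
        return "large"
    return "very_large"


def fst_profile(freqs_a, freqs_b, label: str = "") -> FstProfile:
    """Per-locus F_ST profile between two frequency tables.

    ``freqs_a``/``freqs_b`` are mappings or Series of per-locus alt-allele
    frequencies keyed by rsid. Loci missing (absent or NaN) from either side
    are dropped with a logged count; loci monomorphic for the same allele in
    both populations enter the profile as F_ST = 0 with a flag. Mean and
    sample SD (ddof = 1) are unweighted across the retained loci.
    """
    a = pd.Series(freqs_a, dtype=float)
    b = pd.Series(freqs_b, dtype=float)
    shared = a.index.intersection(b.index)
    joined = pd.DataFrame({"p1": a.reindex(shared), "p2": b.reindex(shared)}).dropna()
    n_dropped = len(a.index.union(b.index)) - len(joined)
    if joined.empty:
        raise ValueError("no shared loci with defined frequencies in both tables")
    if n_dropped:
        logger.info("fst_profile %s: dropped %d loci with missing frequencies", label, n_dropped)
    results = []
    for rsid, row in joined.iterrows():
        f = pairwise_fst(row["p1"], row["p2"])
        mono = row["p1"] == row["p2"] and row["p1"] in (0.0, 1.0)
        results.append(
            FstResult(
                rsid=str(rsid),
                p1=float(row["p1"]),
                p2=float(row["p2"]),
                fst=f,
                category=classify_fst(f),
                monomorphic=mono,
            )
        )
    values = np.array([r.fst for r in results])
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    counts = {c: sum(r.category == c for r in results) for c in CATEGORIES}
    return FstProfile(
        comparison_label=label,
        results=results,
        mean_fst=float(values.mean()),
        sd_fst=sd,
        n_per_category=counts,
        n_dropped=n_dropped,
    )
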