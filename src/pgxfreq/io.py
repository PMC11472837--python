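"""Genotype matrices, frequency tables, and count reconstruction.

This module owns the data model shared by the rest of the package:

* :class:`Variant` — a biallelic SNV with plus-strand ref/alt labels.
* :class:`GenotypeCounts` — the (ref-hom, het, alt-hom) integer triple that is
  the atom of every frequency and Hardy–Weinberg computation.
* :class:`VariantFrequencyRecord` — a published per-locus summary row
  (two-decimal genotype frequencies, alternative-allele frequency with 95% CI,
  HWE p-value), as found in population-survey tables.
* :class:`CohortTable` — an individuals × loci matrix of alt-allele doses
  (0/1/2, NaN for missing) plus per-individual stratum labels.

It also ships a bundled reference table: genotype and allele frequencies of 39
pharmacogene SNVs observed in a survey of 357 unrelated Cuban volunteers
(GRCh38, plus strand), loadable with :func:`load_cuban_snv_table`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Variant",
    "GenotypeCounts",
    "VariantFrequencyRecord",
    "CohortTable",
    "read_cohort_vcf",
    "write_cohort_vcf",
    "read_frequency_table",
    "load_cuban_snv_table",
    "reconstruct_counts",
    "write_results_tsv",
]

#: slack allowed on the sum of a published, 2-decimal genotype-frequency triple
ROUNDING_SLACK = 0.01
_EPS = 1e-9

MISSING = np.nan


@dataclass(frozen=True)
class Variant:
    """A biallelic SNV, annotated on the plus strand of the assembly."""

    rsid: str
    gene: str = ""
    ref_allele: str = "N"
    alt_allele: str = "N"
    assembly_note: str = ""

    def __post_init__(self) -> None:
        if not self.rsid:
            raise ValueError("variant rsid must be non-empty")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.rsid}: ref and alt alleles must differ")


@dataclass(frozen=True)
class GenotypeCounts:
    """Observed genotype class counts at one biallelic locus.

    ``n`` is derived, so the triple-sums-to-n invariant holds by construction.
    """

    n_ref_hom: int
    n_het: int
    n_alt_hom: int

    def __post_init__(self) -> None:
        for name in ("n_ref_hom", "n_het", "n_alt_hom"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.n_ref_hom + self.n_het + self.n_alt_hom

    @property
    def n_alt_alleles(self) -> int:
        return self.n_het + 2 * self.n_alt_hom

    def as_array(self) -> np.ndarray:
        return np.array([self.n_ref_hom, self.n_het, self.n_alt_hom], dtype=float)


@dataclass(frozen=True)
class VariantFrequencyRecord:
    """One published summary row: genotype freqs, alt-allele freq + CI, HWE p.

    Published triples are rounded to two decimals, so their sum may miss 1 by
    up to :data:`ROUNDING_SLACK`; larger discrepancies are rejected.
    """

    variant: Variant
    f_ref_hom: float
    f_het: float
    f_alt_hom: float
    p_alt: float
    ci_low: float
    ci_high: float
    hwe_p: float

    def __post_init__(self) -> None:
        for name in ("f_ref_hom", "f_het", "f_alt_hom", "p_alt", "ci_low", "ci_high", "hwe_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(
                    f"{self.variant.rsid}: {name} = {v} outside [0, 1]"
                )
        s = self.f_ref_hom + self.f_het + self.f_alt_hom
        if abs(s - 1.0) > ROUNDING_SLACK + _EPS:
            raise ValueError(
                f"{self.variant.rsid}: genotype frequencies sum to {s:.4f}, "
                f"deviating from 1 by more than the rounding slack {ROUNDING_SLACK}"
            )

    @property
    def genotype_freqs(self) -> tuple[float, float, float]:
        return (self.f_ref_hom, self.f_het, self.f_alt_hom)

    def ci_brackets_point(self) -> bool:
        return self.ci_low - _EPS <= self.p_alt <= self.ci_high + _EPS


@dataclass
class CohortTable:
    """Per-individual alt-allele doses for a panel of loci, with strata labels.

    ``genotypes`` is an ``n_individuals × n_loci`` float matrix taking values
    in {0, 1, 2} with ``NaN`` for missing calls. ``strata`` is indexed by
    sample id; its columns are categorical descriptors (e.g. skin-color
    category, birth region).
    """

    variants: list[Variant]
    genotypes: np.ndarray
    strata: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if self.genotypes.ndim != 2:
            raise ValueError("genotype matrix must be 2-dimensional")
        n, l = self.genotypes.shape
        if l != len(self.variants):
            raise ValueError(
                f"genotype matrix has {l} loci but {len(self.variants)} variants declared"
            )
        if len(self.strata) != n:
            raise ValueError(
                f"genotype matrix has {n} individuals but strata table has {len(self.strata)}"
            )
        rsids = [v.rsid for v in self.variants]
        if len(set(rsids)) != len(rsids):
            raise ValueError("duplicate rsids in variant list")
        observed = self.genotypes[~np.isnan(self.genotypes)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            raise ValueError("doses must be 0, 1, 2 or missing")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.strata.index]

    @property
    def rsids(self) -> list[str]:
        return [v.rsid for v in self.variants]

    def counts(self, locus: int | str) -> GenotypeCounts:
        """Genotype counts at one locus, excluding missing calls (per-locus n)."""
        j = self.rsids.index(locus) if isinstance(locus, str) else locus
        col = self.genotypes[:, j]
        col = col[~np.isnan(col)]
        return GenotypeCounts(
            int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
        )


# ---------------------------------------------------------------------------
# VCF + strata I/O


def _read_strata(strata_path) -> pd.DataFrame:
    strata = pd.read_csv(strata_path, sep="\t", dtype=str)
    if "sample_id" not in strata.columns:
        raise ValueError("strata file must have a 'sample_id' column")
    return strata.set_index("sample_id")


def read_cohort_vcf(path, strata_path) -> CohortTable:
    """Read a minimal biallelic GT-only VCF plus a tab-separated strata file.

    Doses are alt-allele counts; phased and unphased genotypes are treated
    identically; any missing allele makes the whole call missing. Multiallelic
    sites are a hard error. Samples absent from the strata file are kept with
    an ``unlabeled`` stratum and a warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: list[Variant] = []
    doses: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multiallelic site {rec.CHROM}:{rec.POS} ({rec.ID or 'no id'}): "
                "only biallelic sites are supported"
            )
        variants.append(
            Variant(
                rsid=rec.ID or f"{rec.CHROM}:{rec.POS}",
                ref_allele=rec.REF,
                alt_allele=rec.ALT[0],
            )
        )
        col = np.full(len(samples), MISSING)
        for i, gt in enumerate(rec.genotypes):
            alleles = [a for a in gt[:-1]]  # last entry is the phased flag
            if len(alleles) != 2 or any(a < 0 for a in alleles):
                continue
            col[i] = float(sum(1 for a in alleles if a > 0))
        doses.append(col)
    vcf.close()
    if not variants:
        raise ValueError(f"no variant records in {path}")

    strata = _read_strata(strata_path)
    missing_samples = [s for s in samples if s not in strata.index]
    if missing_samples:
        warnings.warn(
            f"{len(missing_samples)} VCF sample(s) absent from strata file "
            f"(e.g. {missing_samples[0]}); assigned stratum 'unlabeled'",
            stacklevel=2,
        )
    strata = strata.reindex(samples).fillna("unlabeled")
    return CohortTable(variants, np.column_stack(doses), strata)


_DOSE_TO_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_cohort_vcf(cohort: CohortTable, vcf_path, strata_path=None) -> None:
    """Write a cohort back out as a minimal VCF v4.2 (GT only) + strata TSV."""
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=1>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(cohort.sample_ids),
    ]
    for j, v in enumerate(cohort.variants):
        gts = [
            _DOSE_TO_GT.get(d, "./.") if not np.isnan(d) else "./."
            for d in cohort.genotypes[:, j]
        ]
        lines.append(
            f"1\t{j + 1}\t{v.rsid}\t{v.ref_allele}\t{v.alt_allele}\t.\t.\t.\tGT\t"
            + "\t".join(gts)
        )
    Path(vcf_path).write_text("\n".join(lines) + "\n")
    if strata_path is not None:
        out = cohort.strata.copy()
        out.index.name = "sample_id"
        out.to_csv(strata_path, sep="\t")


# ---------------------------------------------------------------------------
# Published frequency tables

FREQUENCY_COLUMNS = [
    "rsid", "gene", "ref", "alt",
    "f_ref_hom", "f_het", "f_alt_hom",
    "p_alt", "ci_low", "ci_high", "hwe_p",
]


def read_frequency_table(path) -> list[VariantFrequencyRecord]:
    """Read a per-locus summary TSV (columns as in :data:`FREQUENCY_COLUMNS`).

    Validates every row against the record invariants (0.01 rounding slack on
    the genotype triple) and warns — without rejecting — when a printed CI
    fails to bracket its point estimate, which happens in published tables
    when an interval was reported for the complementary allele.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in FREQUENCY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"frequency table {path} lacks columns: {missing}")
    records = []
    suspect_ci = []
    for _, row in df.iterrows():
        note = str(row["note"]) if "note" in df.columns and pd.notna(row.get("note")) else ""
        rec = VariantFrequencyRecord(
            variant=Variant(
                rsid=str(row["rsid"]),
                gene=str(row["gene"]),
                ref_allele=str(row["ref"]),
                alt_allele=str(row["alt"]),
                assembly_note=note,
            ),
            f_ref_hom=float(row["f_ref_hom"]),
            f_het=float(row["f_het"]),
            f_alt_hom=float(row["f_alt_hom"]),
            p_alt=float(row["p_alt"]),
            ci_low=float(row["ci_low"]),
            ci_high=float(row["ci_high"]),
            hwe_p=float(row["hwe_p"]),
        )
        if not rec.ci_brackets_point():
            suspect_ci.append(rec.variant.rsid)
        records.append(rec)
    rsids = [r.variant.rsid for r in records]
    if len(set(rsids)) != len(rsids):
        raise ValueError(f"duplicate rsids in frequency table {path}")
    if suspect_ci:
        warnings.warn(
            "printed 95% CI does not bracket the allele-frequency point estimate "
            f"for: {', '.join(suspect_ci)} (interval likely reported for the "
            "complementary allele); values kept as printed",
            stacklevel=2,
        )
    return records


def load_cuban_snv_table() -> list[VariantFrequencyRecord]:
    """Load the bundled 39-SNV pharmacogene summary (Cuban survey, n = 357)."""
    ref = resources.files("pgxfreq").joinpath("data/cuban_snv_table.tsv")
    with resources.as_file(ref) as p:
        with warnings.catch_warnings():
            # the rs2740574 CI is transcribed as printed and flagged at read
            # time; bundled loading should be quiet
            warnings.simplefilter("ignore")
            return read_frequency_table(p)


#: cohort size of the bundled survey
CUBAN_SURVEY_N = 357


# ---------------------------------------------------------------------------
# Count reconstruction


def reconstruct_counts(
    record: VariantFrequencyRecord | Sequence[float], n: int
) -> GenotypeCounts:
    """Invert two-decimal rounding: integer triple summing to ``n`` closest (L2)
    to the published genotype frequencies.

    Minimizes ``Σ (k_i/n − f_i)²`` over all triples ``(a, b, c)`` with
    ``a + b + c = n`` by exhaustive search; exact ties resolve to the
    lexicographically smallest triple (row-major argmin order).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if isinstance(record, VariantFrequencyRecord):
        f = np.array(record.genotype_freqs)
    else:
        f = np.asarray(record, dtype=float)
        if f.shape != (3,):
            raise ValueError("expected a triple of genotype frequencies")
    a = np.arange(n + 1)
    A, B = np.meshgrid(a, a, indexing="ij")
    C = n - A - B
    sse = (A / n - f[0]) ** 2 + (B / n - f[1]) ** 2 + (C / n - f[2]) ** 2
    sse = np.where(C >= 0, sse, np.inf)
    i, j = np.unravel_index(int(np.argmin(sse)), sse.shape)
    return GenotypeCounts(int(i), int(j), int(n - i - j))


# ---------------------------------------------------------------------------
# Generic results writer


def write_results_tsv(results, path) -> None:
    """Write records/results to TSV, round-trip stable at 6 decimals.

    Accepts a DataFrame, a list of dataclass instances, or an empty list
    (header cannot be inferred from an empty dataclass list, so an empty
    DataFrame writes its declared columns and an empty list writes nothing
    but an empty header line).
    """
    if isinstance(results, pd.DataFrame):
        df = results
    elif isinstance(results, Iterable):
        rows = []
        for r in results:
            if isinstance(r, VariantFrequencyRecord):
                d = {
                    "rsid": r.variant.rsid,
                    "gene": r.variant.gene,
                    "ref": r.variant.ref_allele,
                    "alt": r.variant.alt_allele,
                    "f_ref_hom": r.f_ref_hom,
                    "f_het": r.f_het,
                    "f_alt_hom": r.f_alt_hom,
                    "p_alt": r.p_alt,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "hwe_p": r.hwe_p,
                }
            elif hasattr(r, "__dataclass_fields__"):
                d = asdict(r)
            else:
                d = dict(r)
            rows.append(d)
        df = pd.DataFrame(rows, columns=FREQUENCY_COLUMNS if not rows else None)
    else:  # pragma: no cover - guarded by the Iterable branch
        raise TypeError(f"cannot serialize {type(results)!r}")
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
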