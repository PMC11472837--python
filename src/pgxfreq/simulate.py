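"""Synthetic admixed-cohort generator.

The generator reproduces the statistical structure the analysis pipeline
assumes for a 3-way admixed population (European / African / Amerindian):

* each individual i in stratum s draws an ancestry simplex
  q_i ~ Dirichlet(α_s), with α_s calibrated so that the stratum means match
  survey-reported ancestry proportions;
* a reference panel of AIM-like loci carries independent per-population
  alt-allele frequencies p_jk (Beta-distributed, U-shaped by default, so loci
  are frequently differentiated between populations);
* genotype doses are g_ij ~ Binomial(2, Σ_k q_ik p_jk) — the uncorrelated
  allele-frequencies admixture model, with loci simulated independently
  (no linkage);
* optionally, two whole-gene deletion ("null genotype") indicators are drawn
  independently per individual with stated deletion probabilities.

One master seed expands into fixed per-stage child seeds (panel, ancestry,
genotypes, deletions) via ``numpy.random.SeedSequence.spawn``, so any stage
can be re-run in isolation and identical configs give bit-identical cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .admixture import ReferencePanel
from .frequencies import frequency_table
from .io import CohortTable, Variant

__all__ = [
    "StratumSpec",
    "CohortConfig",
    "SimulatedCohort",
    "calibrate_alphas",
    "simulate_panel",
    "simulate_cohort",
    "cohort_report",
    "cuban_study_config",
]

logger = logging.getLogger(__name__)

ALPHA_FLOOR_FRACTION = 1e-3

#: survey-reported mean ancestry (European, African, Amerindian) by self-identified
#: skin-color category, with the stratum sizes of the surveyed cohort (n = 357)
SKIN_COLOR_ANCESTRY_MEANS = {
    "white": (0.859, 0.093, 0.048),
    "admixed": (0.577, 0.363, 0.060),
    "black": (0.312, 0.647, 0.041),
}
SKIN_COLOR_SIZES = {"white": 190, "admixed": 101, "black": 66}
ANCESTRY_LABELS = ("EUR", "AFR", "AMR")
#: survey-reported GSTM1*0 and GSTT1*0 deletion frequencies
NULL_GENE_PROBS = (0.39, 0.18)
DEFAULT_CONCENTRATION = 10.0


@dataclass(frozen=True)
class StratumSpec:
    label: str
    n: int
    alpha: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"stratum {self.label!r}: n must be positive")
        if any(a <= 0 for a in self.alpha):
            raise ValueError(f"stratum {self.label!r}: Dirichlet alphas must be positive")
        object.__setattr__(self, "alpha", tuple(float(a) for a in self.alpha))


@dataclass(frozen=True)
class CohortConfig:
    strata: tuple[StratumSpec, ...]
    L: int
    seed: int
    panel: ReferencePanel | None = None  # None -> simulate with beta_params
    beta_params: tuple[float, float] = (0.5, 0.5)
    ancestry_labels: tuple[str, ...] = ANCESTRY_LABELS
    null_gene_probs: tuple[float, float] | None = None
    stratum_variable: str = "stratum"

    def __post_init__(self) -> None:
        if not self.strata:
            raise ValueError("at least one stratum required")
        if self.seed is None:
            raise ValueError("a seed is mandatory: simulated cohorts must be reproducible")
        ks = {len(s.alpha) for s in self.strata}
        if len(ks) != 1:
            raise ValueError("all strata must share the same number of ancestry components")
        if self.panel is not None and self.panel.L != self.L:
            raise ValueError("panel width must equal L")
        if self.L < 1:
            raise ValueError("need at least one locus")

    @property
    def K(self) -> int:
        return len(self.strata[0].alpha)


@dataclass
class SimulatedCohort:
    cohort: CohortTable
    true_q: np.ndarray  # n x K
    panel: ReferencePanel
    config: CohortConfig
    null_calls: np.ndarray | None = None  # n x 2 booleans (gene present?)


def calibrate_alphas(target_means, concentration: float) -> np.ndarray:
    """Dirichlet α with the given mean: α = concentration × means.

    ``target_means`` is renormalized onto the simplex; zero components are
    floored at ``1e-3 × concentration`` (a Dirichlet needs strictly positive
    parameters) with a log entry.
    """
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    means = np.asarray(target_means, dtype=float)
    if (means < 0).any() or means.sum() <= 0:
        raise ValueError("target means must be non-negative and not all zero")
    means = means / means.sum()
    alpha = concentration * means
    floor = ALPHA_FLOOR_FRACTION * concentration
    if (alpha < floor).any():
        logger.info(
            "calibrate_alphas: %d component(s) floored at %g", (alpha < floor).sum(), floor
        )
        alpha = np.maximum(alpha, floor)
    return alpha


def simulate_panel(
    K: int,
    L: int,
    beta_params: tuple[float, float] = (0.5, 0.5),
    seed: int | None = 0,
    labels=None,
) -> ReferencePanel:
    """AIM-like reference panel: p_jk drawn i.i.d. Beta(a, b) per population.

    The default Beta(0.5, 0.5) is U-shaped, so draws for different
    populations frequently land on opposite sides of 0.5, giving the large
    between-population frequency contrasts that make a marker ancestry
    informative.
    """
    if L < 1:
        raise ValueError("need at least one locus")
    rng = np.random.default_rng(seed)
    freqs = rng.beta(beta_params[0], beta_params[1], size=(K, L))
    labels = tuple(labels) if labels is not None else tuple(f"pop{k}" for k in range(K))
    loci = tuple(f"snp{j:04d}" for j in range(L))
    return ReferencePanel(labels=labels, freqs=freqs, loci=loci)


def simulate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Draw an admixed cohort from a :class:`CohortConfig`; fully reproducible.

    Stage seeds: ``SeedSequence(seed).spawn(4)`` → (panel, ancestry,
    genotypes, deletions), in that fixed order.
    """
    ss_panel, ss_q, ss_geno, ss_null = np.random.SeedSequence(config.seed).spawn(4)
    if config.panel is not None:
        panel = config.panel
    else:
        panel = simulate_panel(
            config.K,
            config.L,
            beta_params=config.beta_params,
            seed=ss_panel,
            labels=config.ancestry_labels,
        )

    rng_q = np.random.default_rng(ss_q)
    q_blocks = []
    labels = []
    for spec in config.strata:
        q_blocks.append(rng_q.dirichlet(spec.alpha, size=spec.n))
        labels.extend([spec.label] * spec.n)
    true_q = np.vstack(q_blocks)

    rng_geno = np.random.default_rng(ss_geno)
    mixed = true_q @ panel.freqs  # n x L alt-allele frequencies
    doses = rng_geno.binomial(2, mixed).astype(float)

    null_calls = None
    if config.null_gene_probs is not None:
        rng_null = np.random.default_rng(ss_null)
        pa, pb = config.null_gene_probs
        n = len(true_q)
        null_calls = np.column_stack(
            [rng_null.random(n) >= pa, rng_null.random(n) >= pb]
        )

    loci = panel.loci or tuple(f"snp{j:04d}" for j in range(panel.L))
    variants = [Variant(rsid=r, ref_allele="A", alt_allele="G") for r in loci]
    strata = pd.DataFrame(
        {config.stratum_variable: labels},
        index=[f"S{i:05d}" for i in range(len(labels))],
    )
    strata.index.name = "sample_id"
    cohort = CohortTable(variants, doses, strata)
    return SimulatedCohort(cohort, true_q, panel, config, null_calls)


def cohort_report(simulated: SimulatedCohort, ci_method: str = "wilson") -> dict[str, pd.DataFrame]:
    """Survey-style frequency tables: pooled cohort plus one per stratum."""
    cohort = simulated.cohort
    out = {"overall": frequency_table(cohort, ci_method=ci_method)}
    var = simulated.config.stratum_variable
    for spec in simulated.config.strata:
        mask = (cohort.strata[var] == spec.label).to_numpy()
        sub = CohortTable(
            cohort.variants, cohort.genotypes[mask], cohort.strata.loc[mask]
        )
        out[spec.label] = frequency_table(sub, ci_method=ci_method)
    return out


def cuban_study_config(
    seed: int,
    L: int = 34,
    concentration: float = DEFAULT_CONCENTRATION,
    with_null_genes: bool = False,
) -> CohortConfig:
    """Study-condition defaults: skin-color strata with survey ancestry means.

    Three strata (white n=190, admixed n=101, black n=66; total 357) with
    Dirichlet concentration 10 around the reported mean ancestry vectors, and
    L ancestry-informative loci drawn Beta(0.5, 0.5) per population.
    """
    strata = tuple(
        StratumSpec(
            label=name,
            n=SKIN_COLOR_SIZES[name],
            alpha=tuple(calibrate_alphas(means, concentration)),
        )
        for name, means in SKIN_COLOR_ANCESTRY_MEANS.items()
    )
    return CohortConfig(
        strata=strata,
        L=L,
        seed=seed,
        null_gene_probs=NULL_GENE_PROBS if with_null_genes else None,
        stratum_variable="skin_color",
    )
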