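"""Supervised per-individual ancestry estimation and ancestry-group tests.

Given a fixed reference panel of alt-allele frequencies p_jk for K ancestral
populations, each individual's genotype dose g_j at locus j is modelled as
Binomial(2, m_j) with mixed allele frequency m_j = Σ_k q_k p_jk, where q is
the individual's ancestry simplex. The supervised log-likelihood

    ℓ(q) = Σ_j [ g_j log m_j + (2 − g_j) log(1 − m_j) ]

is maximized by an EM algorithm in which each allele copy carries a
responsibility over ancestral origins. This is the standard supervised
admixture model (the deterministic counterpart of model-based Bayesian
clustering with pre-assigned reference populations); it assumes unlinked loci
and known, fixed panel frequencies.

Group-level contrasts use Kruskal–Wallis with tie correction followed by
Dunn's post-hoc z-tests on mean ranks, judged at a pre-stated pairwise alpha
(Bonferroni-style 0.017 for three groups by default).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import CohortTable

__all__ = [
    "ReferencePanel",
    "AncestryEstimate",
    "GroupComparison",
    "supervised_admixture_em",
    "cohort_ancestry",
    "group_summary",
    "kruskal_dunn",
]

logger = logging.getLogger(__name__)

PANEL_CLAMP_EPS = 1e-6


@dataclass(frozen=True)
class ReferencePanel:
    """K ancestral populations × L loci of alt-allele frequencies.

    Frequencies are clamped to [ε, 1 − ε] at construction so that no locus is
    deterministically informative and the likelihood never hits log 0.
    """

    labels: tuple[str, ...]
    freqs: np.ndarray  # K × L
    loci: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        if freqs.ndim != 2:
            raise ValueError("panel frequencies must be a K x L matrix")
        if freqs.shape[0] != len(self.labels):
            raise ValueError("one label per ancestral population required")
        if freqs.shape[1] < 1:
            raise ValueError("panel needs at least one locus")
        if ((freqs < 0) | (freqs > 1)).any():
            raise ValueError("panel frequencies must lie in [0, 1]")
        object.__setattr__(
            self, "freqs", np.clip(freqs, PANEL_CLAMP_EPS, 1 - PANEL_CLAMP_EPS)
        )
        object.__setattr__(self, "labels", tuple(self.labels))
        if self.loci and len(self.loci) != freqs.shape[1]:
            raise ValueError("loci names must match panel width")

    @property
    def K(self) -> int:
        return self.freqs.shape[0]

    @property
    def L(self) -> int:
        return self.freqs.shape[1]

    @classmethod
    def from_tsv(cls, path) -> "ReferencePanel":
        """Read a panel TSV: ``rsid<TAB>pop1<TAB>pop2...`` of alt-allele freqs."""
        df = pd.read_csv(path, sep="\t")
        if df.columns[0] != "rsid":
            raise ValueError("panel TSV must start with an 'rsid' column")
        labels = tuple(df.columns[1:])
        return cls(
            labels=labels,
            freqs=df[list(labels)].to_numpy(float).T,
            loci=tuple(df["rsid"].astype(str)),
        )

    def to_tsv(self, path) -> None:
        loci = self.loci or tuple(f"locus{j:04d}" for j in range(self.L))
        df = pd.DataFrame({"rsid": loci})
        for k, lab in enumerate(self.labels):
            df[lab] = self.freqs[k]
        df.to_csv(path, sep="\t", index=False, float_format="%.6f")


@dataclass(frozen=True)
class AncestryEstimate:
    q: np.ndarray  # K-simplex
    loglik: float
    n_iter: int
    converged: bool
    loglik_path: np.ndarray = field(default_factory=lambda: np.array([]), repr=False)


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    kw_h: float
    kw_p: float
    alpha_pairwise: float
    pairwise: list[tuple]  # (group_i, group_j, z, dunn_p, significant)


def supervised_admixture_em(
    doses,
    panel: ReferencePanel,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> AncestryEstimate:
    """Maximize the supervised admixture likelihood for one individual by EM.

    ``doses`` is the individual's L-vector of alt-allele counts in
    {0, 1, 2}, NaN marking missing calls (dropped per locus). EM starts at
    the uniform simplex and stops when the relative log-likelihood change
    falls below ``tol``. The log-likelihood is non-decreasing at every step.
    """
    g = np.asarray(doses, dtype=float)
    if g.shape != (panel.L,):
        raise ValueError(f"expected {panel.L} doses, got shape {g.shape}")
    ok = ~np.isnan(g)
    if not ok.any():
        raise ValueError("all doses missing: ancestry is undefined")
    g = g[ok]
    P = panel.freqs[:, ok]  # K x L_obs
    K, L = P.shape
    if K == 1:
        m = P[0]
        ll = float(np.sum(g * np.log(m) + (2 - g) * np.log1p(-m)))
        return AncestryEstimate(np.array([1.0]), ll, 0, True, np.array([ll]))

    q = np.full(K, 1.0 / K)
    ll_prev = -np.inf
    path = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        m = q @ P  # mixed alt frequency per locus; in (0,1) by panel clamping
        ll = float(np.sum(g * np.log(m) + (2 - g) * np.log1p(-m)))
        path.append(ll)
        if np.isfinite(ll_prev) and abs(ll - ll_prev) <= tol * abs(ll_prev):
            converged = True
            break
        ll_prev = ll
        # E-step: per-allele-copy ancestry responsibilities; M-step: average
        resp_alt = q[:, None] * P / m  # K x L, columns sum to 1
        resp_ref = q[:, None] * (1.0 - P) / (1.0 - m)
        q = (resp_alt @ g + resp_ref @ (2.0 - g)) / (2.0 * L)
        q = q / q.sum()  # guard float drift; mathematically already 1
    return AncestryEstimate(q, path[-1], it, converged, np.asarray(path))


def cohort_ancestry(cohort: CohortTable, panel: ReferencePanel, **em_kwargs) -> list[AncestryEstimate | None]:
    """Supervised EM over every individual; deterministic given the inputs.

    Individuals whose estimate fails (e.g. all calls missing) are logged and
    returned as ``None`` so positions stay aligned with the cohort.
    """
    if cohort.n_loci != panel.L:
        raise ValueError(
            f"cohort has {cohort.n_loci} loci but panel has {panel.L}"
        )
    out: list[AncestryEstimate | None] = []
    for i in range(cohort.n_individuals):
        try:
            out.append(supervised_admixture_em(cohort.genotypes[i], panel, **em_kwargs))
        except ValueError as exc:
            logger.warning("individual %s skipped: %s", cohort.sample_ids[i], exc)
            out.append(None)
    return out


def ancestry_matrix(estimates) -> np.ndarray:
    """Stack per-individual q vectors (skipping failures) into an n × K matrix."""
    rows = [e.q for e in estimates if e is not None]
    if not rows:
        raise ValueError("no successful ancestry estimates")
    return np.vstack(rows)


def group_summary(estimates, labels, components=None) -> pd.DataFrame:
    """Per-group mean / min / max of each ancestry component.

    ``labels`` aligns with ``estimates``; individuals whose estimate failed
    are dropped together with their label. Empty groups are simply absent
    from the output (logged).
    """
    labels = [str(l) for l in labels]
    if len(labels) != len(estimates):
        raise ValueError("labels must align with estimates")
    pairs = [(l, e.q) for l, e in zip(labels, estimates) if e is not None]
    if not pairs:
        raise ValueError("no successful ancestry estimates")
    K = len(pairs[0][1])
    components = list(components) if components is not None else [f"q{k}" for k in range(K)]
    seen = sorted({l for l, _ in pairs})
    for lev in sorted(set(labels) - set(seen)):
        logger.info("group_summary: group %r has no estimates and is absent", lev)
    rows = []
    for lev in seen:
        Q = np.vstack([q for l, q in pairs if l == lev])
        for k, comp in enumerate(components):
            rows.append(
                {
                    "group": lev,
                    "component": comp,
                    "n": len(Q),
                    "mean": float(Q[:, k].mean()),
                    "min": float(Q[:, k].min()),
                    "max": float(Q[:, k].max()),
                }
            )
    return pd.DataFrame(rows)


def _dunn_pairwise(values: np.ndarray, groups: list[np.ndarray], names, alpha):
    """Dunn's z-tests on mean ranks with tie correction, two-sided p-values."""
    N = len(values)
    ranks = stats.rankdata(values)
    # tie correction term: sum(t^3 - t) over tied groups
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_factor = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))
    offsets = np.cumsum([0] + [len(g) for g in groups])
    mean_ranks = [
        float(ranks[offsets[i]: offsets[i + 1]].mean()) for i in range(len(groups))
    ]
    pairwise = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = np.sqrt(var_factor * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = float(2 * stats.norm.sf(abs(z)))
        pairwise.append((names[i], names[j], float(z), p, p < alpha))
    return pairwise


def kruskal_dunn(values, groups, alpha_pairwise: float = 0.017, variable: str = "") -> GroupComparison:
    """Kruskal–Wallis across groups, then Dunn's post-hoc pairwise z-tests.

    Dunn p-values are reported two-sided and compared to the pre-stated
    pairwise alpha (Bonferroni-corrected 0.05/3 ≈ 0.017 for three groups)
    rather than being adjusted themselves.
    """
    values = np.asarray(values, dtype=float)
    labels = [str(g) for g in groups]
    if len(labels) != len(values):
        raise ValueError("groups must align with values")
    names = sorted(set(labels))
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[np.array(labels) == g] for g in names]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group needs at least one observation")
    if np.ptp(values) == 0:
        # all observations identical: no evidence of any difference
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*samples)
    pooled = np.concatenate(samples)
    pairwise = _dunn_pairwise(pooled, samples, names, alpha_pairwise)
    return GroupComparison(
        variable=variable,
        kw_h=float(h),
        kw_p=float(p),
        alpha_pairwise=alpha_pairwise,
        pairwise=pairwise,
    )
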