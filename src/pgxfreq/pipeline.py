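"""End-to-end orchestration: frequencies → HWE → strata tests → ancestry → F_ST.

A single declarative config (YAML or dict) drives the whole analysis and
every source of randomness derives from its one seed, so re-running a config
reproduces the report byte for byte. The report directory holds plain TSVs,
a text summary, and a manifest listing every output with a checksum.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .admixture import ReferencePanel, cohort_ancestry, group_summary, kruskal_dunn
from .exact_tests import scan_loci
from .frequencies import frequency_table
from .fst import fst_profile
from .io import CohortTable, read_cohort_vcf, write_cohort_vcf
from .simulate import CohortConfig, StratumSpec, calibrate_alphas, simulate_cohort

__all__ = ["run_pipeline", "summarize_hwe_deviations", "load_config"]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6f"


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def summarize_hwe_deviations(hwe_table: pd.DataFrame, alpha: float = 0.05) -> list[str]:
    """rsids of loci deviating from HWE at ``alpha``, most significant first."""
    if len(hwe_table) == 0:
        return []
    col = "hwe_p" if "hwe_p" in hwe_table.columns else "p_value"
    hits = hwe_table[hwe_table[col] < alpha].sort_values(col)
    return [str(r) for r in hits["rsid"]]


def _cohort_config_from_dict(sim: dict, seed: int) -> CohortConfig:
    concentration = float(sim.get("concentration", 10.0))
    strata = tuple(
        StratumSpec(
            label=str(s["label"]),
            n=int(s["n"]),
            alpha=tuple(
                s["alpha"] if "alpha" in s else calibrate_alphas(s["means"], concentration)
            ),
        )
        for s in sim["strata"]
    )
    null_probs = sim.get("null_gene_probs")
    return CohortConfig(
        strata=strata,
        L=int(sim["L"]),
        seed=seed,
        beta_params=tuple(sim.get("beta_params", (0.5, 0.5))),
        ancestry_labels=tuple(sim.get("ancestry_labels", ("EUR", "AFR", "AMR"))[: len(strata[0].alpha)]),
        null_gene_probs=tuple(null_probs) if null_probs else None,
        stratum_variable=str(sim.get("stratum_variable", "stratum")),
    )


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config, output_dir=None) -> Path:
    """Run the full analysis described by ``config`` (path, or dict).

    Stages, in order: cohort acquisition (simulate or read VCF+strata),
    per-locus frequency/HWE table, HWE-deviation summary, per-locus exact
    stratification tests, supervised ancestry estimation with group
    comparisons, and pairwise per-stratum F_ST profiles. Any stage failure
    aborts with the stage name attached.
    """
    cfg = load_config(config) if not isinstance(config, dict) else dict(config)
    seed = int(cfg.get("seed", 0))
    out = Path(output_dir or cfg.get("output_dir", "pgxfreq_report"))
    out.mkdir(parents=True, exist_ok=True)
    alpha = float(cfg.get("alpha", 0.05))
    ci_method = str(cfg.get("ci_method", "wilson"))
    stratum_variable = cfg.get("stratum_variable")
    mc_permutations = int(cfg.get("mc_permutations", 2000))
    stage_seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ("strata_tests",), np.random.SeedSequence(seed).spawn(1)
        )
    }
    stages: list[str] = []
    panel: ReferencePanel | None = None

    def stage(name):
        stages.append(name)
        logger.info("pipeline stage: %s", name)

    try:
        stage("cohort")
        cohort_cfg = cfg["cohort"]
        true_q = None
        if "simulate" in cohort_cfg:
            sim_cfg = _cohort_config_from_dict(cohort_cfg["simulate"], seed)
            sim = simulate_cohort(sim_cfg)
            cohort, true_q, panel = sim.cohort, sim.true_q, sim.panel
            stratum_variable = stratum_variable or sim_cfg.stratum_variable
            write_cohort_vcf(cohort, out / "cohort.vcf", out / "strata.tsv")
            tq = pd.DataFrame(true_q, columns=list(panel.labels), index=cohort.sample_ids)
            tq.index.name = "sample_id"
            tq.to_csv(out / "true_q.tsv", sep="\t", float_format=_FLOAT_FMT)
        else:
            cohort = read_cohort_vcf(cohort_cfg["vcf"], cohort_cfg["strata_tsv"])
            if stratum_variable is None:
                stratum_variable = cohort.strata.columns[0]
        if "panel" in cfg:
            panel = ReferencePanel.from_tsv(cfg["panel"])
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'cohort' failed: {exc}") from exc

    results: dict[str, pd.DataFrame] = {}

    try:
        stage("frequencies")
        freq = frequency_table(cohort, ci_method=ci_method)
        _write_tsv(freq, out / "frequencies.tsv")
        results["frequencies"] = freq
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'frequencies' failed: {exc}") from exc

    try:
        stage("hwe")
        deviations = summarize_hwe_deviations(freq, alpha)
        hwe = freq[["rsid", "hwe_chi2", "hwe_p", "monomorphic"]].copy()
        hwe["deviates"] = hwe["rsid"].isin(deviations)
        _write_tsv(hwe, out / "hwe.tsv")
        results["hwe"] = hwe
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'hwe' failed: {exc}") from exc

    try:
        stage("strata_tests")
        scan = scan_loci(
            cohort,
            stratum_variable,
            alpha=alpha,
            n_permutations=mc_permutations,
            seed=stage_seeds["strata_tests"],
        )
        _write_tsv(scan.table, out / "strata_tests.tsv")
        results["strata_tests"] = scan.table
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'strata_tests' failed: {exc}") from exc

    try:
        stage("ancestry")
        comparisons = pd.DataFrame()
        if panel is not None:
            estimates = cohort_ancestry(cohort, panel)
            Q = np.vstack([e.q if e is not None else np.full(panel.K, np.nan) for e in estimates])
            anc = pd.DataFrame(Q, columns=list(panel.labels), index=cohort.sample_ids)
            anc.index.name = "sample_id"
            anc.insert(0, stratum_variable, cohort.strata[stratum_variable].to_numpy())
            anc.to_csv(out / "ancestry.tsv", sep="\t", float_format=_FLOAT_FMT)
            results["ancestry"] = anc
            summary = group_summary(
                estimates, cohort.strata[stratum_variable], components=panel.labels
            )
            _write_tsv(summary, out / "ancestry_groups.tsv")
            comp_rows = []
            for k, label in enumerate(panel.labels):
                ok = ~np.isnan(Q[:, k])
                comp = kruskal_dunn(
                    Q[ok, k],
                    cohort.strata[stratum_variable].to_numpy()[ok],
                    variable=label,
                )
                for g1, g2, z, p, sig in comp.pairwise:
                    comp_rows.append(
                        {
                            "component": label,
                            "kw_h": comp.kw_h,
                            "kw_p": comp.kw_p,
                            "group_1": g1,
                            "group_2": g2,
                            "dunn_z": z,
                            "dunn_p": p,
                            "significant": sig,
                        }
                    )
            comparisons = pd.DataFrame(comp_rows)
            _write_tsv(comparisons, out / "ancestry_comparisons.tsv")
            results["ancestry_comparisons"] = comparisons
        else:
            logger.info("no reference panel configured: ancestry stage skipped")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'ancestry' failed: {exc}") from exc

    try:
        stage("fst")
        labels = sorted(cohort.strata[stratum_variable].astype(str).unique())
        per_stratum = {}
        for lev in labels:
            mask = (cohort.strata[stratum_variable].astype(str) == lev).to_numpy()
            sub = CohortTable(cohort.variants, cohort.genotypes[mask], cohort.strata.loc[mask])
            tab = frequency_table(sub)
            per_stratum[lev] = pd.Series(tab["p_alt"].to_numpy(), index=tab["rsid"])
        fst_summaries = []
        for a, b in itertools.combinations(labels, 2):
            profile = fst_profile(per_stratum[a], per_stratum[b], label=f"{a}_vs_{b}")
            _write_tsv(profile.to_frame(), out / f"fst_{a}_vs_{b}.tsv")
            fst_summaries.append(
                {
                    "comparison": profile.comparison_label,
                    "n_loci": len(profile.results),
                    "mean_fst": profile.mean_fst,
                    "sd_fst": profile.sd_fst,
                    **{f"n_{c}": v for c, v in profile.n_per_category.items()},
                }
            )
        fst_df = pd.DataFrame(fst_summaries)
        _write_tsv(fst_df, out / "fst_summary.tsv")
        results["fst_summary"] = fst_df
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'fst' failed: {exc}") from exc

    lines = [
        f"pgxfreq {__version__} report",
        f"cohort: {cohort.n_individuals} individuals x {cohort.n_loci} loci",
        f"stratum variable: {stratum_variable}",
        f"HWE deviations (p < {alpha:g}): {', '.join(deviations) or 'none'}",
        f"strata-test significant loci (p < {alpha:g}): {int(scan.table['significant'].sum())}"
        f" of {len(scan.table)}",
    ]
    if not comparisons.empty:
        for _, row in comparisons.drop_duplicates("component").iterrows():
            lines.append(f"Kruskal-Wallis {row['component']}: H={row['kw_h']:.3f} p={row['kw_p']:.3g}")
    for s in fst_summaries:
        lines.append(
            f"F_ST {s['comparison']}: mean={s['mean_fst']:.4f} sd={s['sd_fst']:.4f}"
        )
    (out / "summary.txt").write_text("\n".join(lines) + "\n")

    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()
    files = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "pgxfreq_version": __version__,
        "config_sha256": cfg_hash,
        "seed": seed,
        "stage_seeds": stage_seeds,
        "stages": stages,
        "outputs": {name: _sha256(out / name) for name in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
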