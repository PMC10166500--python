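"""End-to-end pipeline: filter -> DE -> dynamics -> network -> F_ST -> bias.

Driven by a structured config (YAML/TOML-parsed dict) naming either input
TSVs or a ``simulate`` block.  Every stage writes TSV outputs whose header
comments record the package version, the seed and the governing
parameters, so a fixed config and seed reproduce byte-identical reports.
A single global seed fans out to per-stage seeds by fixed offsets, so
stages rerun in isolation reproduce their in-pipeline behaviour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import CountMatrix, read_counts, write_counts
from .de import bh_adjust, de_table, lrt_interaction, six_level_design, estimate_dispersion
from .dynamics import class_contribution_test, classify_de, tau_table, turnover_divergence
from .expression import filter_expressed, pca_expression, size_factors, tpm
from .fst import arm_cutoffs, fst_table, gene_region_enrichment, read_variants, write_variants
from .bias import bias_summary, bias_table
from .network import NetworkConfig, cluster_modules, eigengenes, module_trait_correlation
from .simulate import SimConfig, simulate_counts, simulate_dual_reference, simulate_snps

log = logging.getLogger("stagediv")

__all__ = ["PipelineConfig", "run_pipeline"]

SEED_OFFSETS = {"counts": 0, "snps": 1, "dual": 2, "kmeans": 3}

_THRESHOLD_DEFAULTS = {
    "min_mean": 15.0,
    "fdr": 0.05,
    "beta": 6.0,
    "min_module_size": 30,
    "merge_threshold": 0.95,
    "fst_quantile": 0.95,
    "min_snps": 20,
    "max_network_genes": 2000,
}

_SIM_EXTRA_KEYS = {"n_snps_per_arm", "n_hot_genes", "fst_base", "fst_hot",
                   "haploid_n", "dual_bias_fraction", "dual_bias_strength"}


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    Build from a plain dict (e.g. parsed YAML) with :meth:`from_dict`.
    Recognised top-level keys: ``seed``, ``output_dir``, ``simulate``,
    ``inputs``, ``thresholds``.  Unknown keys raise (fail-fast).
    """

    seed: int = 0
    output_dir: Path = Path("stagediv_out")
    simulate: dict | None = None
    inputs: dict | None = None
    thresholds: dict = field(default_factory=lambda: dict(_THRESHOLD_DEFAULTS))

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {"seed", "output_dir", "simulate", "inputs", "thresholds"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        thresholds = dict(_THRESHOLD_DEFAULTS)
        extra = set(raw.get("thresholds") or {}) - set(_THRESHOLD_DEFAULTS)
        if extra:
            raise ConfigError(f"unknown threshold key(s): {sorted(extra)}")
        thresholds.update(raw.get("thresholds") or {})
        if not 0 < thresholds["fdr"] < 1:
            raise ConfigError("fdr must be in (0, 1)")
        if not 0 < thresholds["fst_quantile"] < 1:
            raise ConfigError("fst_quantile must be in (0, 1)")
        sim = raw.get("simulate")
        inputs = raw.get("inputs")
        if sim is None and inputs is None:
            raise ConfigError("config needs either an 'inputs' or a 'simulate' block")
        if sim is not None:
            sim_known = {f.name for f in SimConfig.__dataclass_fields__.values()} | _SIM_EXTRA_KEYS
            unknown = set(sim) - sim_known
            if unknown:
                raise ConfigError(f"unknown simulate key(s): {sorted(unknown)}")
        if inputs is not None:
            in_known = {"counts", "samples", "genes", "snps", "dual_counts"}
            unknown = set(inputs) - in_known
            if unknown:
                raise ConfigError(f"unknown inputs key(s): {sorted(unknown)}")
            for key in ("counts", "samples", "genes"):
                if key not in inputs:
                    raise ConfigError(f"inputs block lacks '{key}'")
                if not Path(inputs[key]).exists():
                    raise ConfigError(f"input file missing: {inputs[key]}")
        return cls(
            seed=int(raw.get("seed", 0)),
            output_dir=Path(raw.get("output_dir", "stagediv_out")),
            simulate=sim, inputs=inputs, thresholds=thresholds,
        )


def _header(seed: int, **params) -> str:
    lines = [f"stagediv {__version__}", f"seed={seed}"]
    lines += [f"{k}={v}" for k, v in params.items()]
    return "\n".join(lines)


def _write(df: pd.DataFrame, path: Path, seed: int, index_label=None, **params) -> None:
    with open(path, "w") as fh:
        for line in _header(seed, **params).splitlines():
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index_label is not None,
                  index_label=index_label)


def run_pipeline(config: PipelineConfig, force: bool = False) -> dict:
    """Execute all pipeline stages; returns the in-memory result bundle.

    Stage order: simulate/load -> expression filter -> DE contrasts +
    interaction LRT -> dynamics (DE classes, turnover divergence, tau,
    lncRNA contribution chi-square) -> co-expression modules -> F_ST
    enrichment -> mapping bias (when dual counts are present).  Any stage
    failure raises :class:`StageError` naming the stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    seed = config.seed
    results: dict = {}
    snps = None
    dual = None
    hot_table = None
    sim_truth = None

    def stage(name):
        log.info("stage: %s", name)

    try:
        stage("load")
        if config.simulate is not None:
            sim_kwargs = {k: v for k, v in config.simulate.items()
                          if k in SimConfig.__dataclass_fields__}
            sim_kwargs["seed"] = seed + SEED_OFFSETS["counts"]
            if "n_genes" in sim_kwargs:
                sim_kwargs["n_genes"] = int(sim_kwargs["n_genes"])
            # tuples arrive as lists from YAML
            if "baseline_logmean_range" in sim_kwargs:
                sim_kwargs["baseline_logmean_range"] = tuple(sim_kwargs["baseline_logmean_range"])
            sim_cfg = SimConfig(**sim_kwargs)
            cm, sim_truth = simulate_counts(sim_cfg)
            write_counts(cm, out / "counts.tsv", out / "samples.tsv",
                         out / "genes.tsv",
                         header_comment=_header(seed, stage="simulate"))
            _write(sim_truth, out / "ground_truth.tsv", seed, index_label="gene")
            n_snps = int(config.simulate.get("n_snps_per_arm", 0))
            if n_snps:
                n_hot = int(config.simulate.get("n_hot_genes", 20))
                gm = cm.gene_meta
                hot_candidates = gm.iloc[:: max(1, len(gm) // max(n_hot, 1))].head(n_hot)
                hot = list(zip(hot_candidates.index, hot_candidates["arm"],
                               hot_candidates["start"], hot_candidates["end"]))
                arm_extent = int(gm["end"].max()) + 20_000
                snps, hot_table = simulate_snps(
                    n_snps_per_arm=n_snps,
                    arm_length=arm_extent,
                    n1=int(config.simulate.get("haploid_n", 20)),
                    n2=int(config.simulate.get("haploid_n", 20)),
                    hot_genes=hot,
                    fst_base=float(config.simulate.get("fst_base", 0.05)),
                    fst_hot=float(config.simulate.get("fst_hot", 0.40)),
                    seed=seed + SEED_OFFSETS["snps"],
                )
                write_variants(snps, out / "snps.tsv",
                               header_comment=_header(seed, stage="simulate_snps"))
            bias_frac = config.simulate.get("dual_bias_fraction")
            if bias_frac is not None:
                dual = simulate_dual_reference(
                    cm, bias_fraction=float(bias_frac),
                    bias_strength=float(config.simulate.get("dual_bias_strength", 0.5)),
                    seed=seed + SEED_OFFSETS["dual"],
                )[:2]
        else:
            cm = read_counts(config.inputs["counts"], config.inputs["samples"],
                             config.inputs["genes"])
            if config.inputs.get("snps"):
                snps = read_variants(config.inputs["snps"])
            if config.inputs.get("dual_counts"):
                p1, p2 = config.inputs["dual_counts"]
                dual = (pd.read_csv(p1, sep="\t", comment="#", index_col=0),
                        pd.read_csv(p2, sep="\t", comment="#", index_col=0))
        results["counts"] = cm
        results["ground_truth"] = sim_truth

        stage("filter")
        filtered, calls = filter_expressed(cm, th["min_mean"])
        _write(calls, out / "expression_calls.tsv", seed,
               index_label="gene", min_mean=th["min_mean"])
        results["filtered"] = filtered
        results["calls"] = calls

        stage("normalize")
        sf = size_factors(filtered)
        tpm_df = tpm(filtered) if "length" in filtered.gene_meta.columns else None
        scores, varfrac = pca_expression(filtered)
        _write(scores.assign(), out / "pca_scores.tsv", seed, index_label="sample")
        results["size_factors"] = sf
        results["tpm"] = tpm_df
        results["pca"] = (scores, varfrac)

        stage("de")
        design = six_level_design(filtered, contrasts="canonical")
        alpha = estimate_dispersion(filtered, design.groups, sf)["alpha"]
        de = de_table(filtered, design, fdr=th["fdr"], alpha=alpha,
                      size_factors_=sf)
        _write(de, out / "de_results.tsv", seed, fdr=th["fdr"])
        lrt = lrt_interaction(filtered, filtered.sample_meta["stage"],
                              filtered.sample_meta["population"], sf, alpha)
        lrt["padj"] = bh_adjust(lrt["pvalue"])
        _write(lrt, out / "interaction_lrt.tsv", seed, index_label="gene")
        results["de"] = de
        results["lrt"] = lrt

        stage("dynamics")
        results.update(_dynamics_stage(filtered, de, tpm_df, th, out, seed))

        stage("network")
        results["network"] = _network_stage(filtered, sf, th, out, seed)

        if snps is not None:
            stage("fst")
            ft = fst_table(snps)
            cuts = arm_cutoffs(ft, q=th["fst_quantile"], min_snps=th["min_snps"])
            gene_spans = filtered.gene_meta[["arm", "start", "end"]].dropna() \
                if {"arm", "start", "end"} <= set(filtered.gene_meta.columns) else None
            enr = None
            if gene_spans is not None and len(gene_spans):
                enr = gene_region_enrichment(gene_spans, ft, cuts,
                                             min_snps=th["min_snps"],
                                             top_fraction=1 - th["fst_quantile"],
                                             fdr=th["fdr"])
                _write(enr, out / "fst_enrichment.tsv", seed, index_label="gene",
                       min_snps=th["min_snps"], quantile=th["fst_quantile"])
            _write(cuts, out / "fst_cutoffs.tsv", seed, index_label="arm",
                   quantile=th["fst_quantile"])
            results["fst"] = {"table": ft, "cutoffs": cuts, "enrichment": enr,
                              "hot_genes": hot_table}
        else:
            log.info("no SNP input: popgen stage skipped")
            results["fst"] = None

        if dual is not None:
            stage("bias")
            bt = bias_table(dual[0].loc[filtered.genes], dual[1].loc[filtered.genes])
            summ = bias_summary(bt, filtered.sample_meta,
                                gene_class=filtered.gene_meta["biotype"])
            _write(summ["by_group"], out / "bias_summary.tsv", seed)
            results["bias"] = {"table": bt, "summary": summ}
        else:
            results["bias"] = None

        stage("report")
        _write_report(results, th, out, seed)
        return results
    except Exception as exc:
        raise StageError(f"pipeline failed: {exc}") from exc


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def _dynamics_stage(filtered, de, tpm_df, th, out, seed) -> dict:
    meta = filtered.sample_meta
    pops = sorted(meta["population"].unique())
    stages = list(dict.fromkeys(meta["stage"]))
    res: dict = {}

    # between-stage DE per population -> class table + divergence
    class_tables, divergences = {}, {}
    for s1, s2 in [(a, b) for i, a in enumerate(stages) for b in stages[i + 1:]]:
        per_pop = {}
        for p in pops:
            sub = de[de["contrast"] == f"{p}_{s2}_vs_{p}_{s1}"].set_index("gene")
            if len(sub):
                per_pop[p] = sub
        if len(per_pop) == 2:
            ct = classify_de(per_pop[pops[0]], per_pop[pops[1]],
                             label_pop1=pops[0], label_pop2=pops[1])
            class_tables[(s1, s2)] = ct
            try:
                divergences[(s1, s2)] = turnover_divergence(
                    ct[f"log2fc_{pops[0]}"], ct[f"log2fc_{pops[1]}"])
            except ValueError:
                divergences[(s1, s2)] = np.nan
    if class_tables:
        summary = pd.DataFrame({
            f"{s1}_vs_{s2}": ct["de_class"].value_counts()
            for (s1, s2), ct in class_tables.items()
        }).fillna(0).astype(int)
        summary.loc["divergence"] = [divergences[k] for k in class_tables]
        _write(summary, out / "dynamics_summary.tsv", seed, index_label="class")
        res["de_classes"] = class_tables
        res["divergence"] = divergences

    # tau per population
    if tpm_df is not None:
        taus = tau_table(tpm_df, meta)
        _write(taus, out / "tau.tsv", seed, index_label="gene")
        res["tau"] = taus

    # lncRNA contribution of per-stage up-regulated sets
    biotype = filtered.gene_meta["biotype"]
    bg_ln = int((biotype == "lncRNA").sum())
    bg_pc = int((biotype != "lncRNA").sum())
    rows = []
    if len(pops) == 2:
        for s in stages:
            sub = de[de["contrast"] == f"{pops[0]}_{s}_vs_{pops[1]}_{s}"]
            for pop, sign in ((pops[0], 1), (pops[1], -1)):
                up = sub[(sub["significant"]) & (sign * sub["log2fc"] > 0)]["gene"]
                n_ln = int((biotype.loc[up] == "lncRNA").sum())
                n_pc = len(up) - n_ln
                try:
                    r = class_contribution_test(n_ln, n_pc, bg_ln, bg_pc)
                    p, chi2 = r.pvalue, r.statistic
                except ValueError:
                    p, chi2 = np.nan, np.nan
                rows.append({"population": pop, "stage": s, "up_lncrna": n_ln,
                             "up_pc": n_pc, "chi2": chi2, "pvalue": p})
        contrib = pd.DataFrame(rows)
        _write(contrib, out / "lncrna_contribution.tsv", seed,
               bg_lncrna=bg_ln, bg_pc=bg_pc)
        res["lncrna_contribution"] = contrib
    return res


def _network_stage(filtered, sf, th, out, seed) -> dict:
    norm = np.log2(filtered.counts.to_numpy(dtype=float)
                   / sf.to_numpy()[None, :] + 1.0)
    norm = pd.DataFrame(norm, index=filtered.genes, columns=filtered.samples)
    max_genes = int(th["max_network_genes"])
    if len(norm) > max_genes:
        variances = norm.var(axis=1)
        norm = norm.loc[variances.sort_values(ascending=False).index[:max_genes]]
    cfg = NetworkConfig(beta=th["beta"], min_module_size=int(th["min_module_size"]),
                        merge_threshold=th["merge_threshold"])
    assignment = cluster_modules(norm, cfg)
    em, varexp = eigengenes(norm, assignment["module"])
    meta = filtered.sample_meta
    stages = list(dict.fromkeys(meta["stage"]))
    stage_code = meta["stage"].map({s: i for i, s in enumerate(stages)})
    pops = sorted(meta["population"].unique())
    traits = pd.DataFrame({
        "stage_age": stage_code.astype(float),
        "population": (meta["population"] == pops[0]).astype(float),
    }, index=meta.index)
    trait_corr = module_trait_correlation(em, traits) if len(em) else pd.DataFrame()
    _write(assignment, out / "modules.tsv", seed, index_label="gene",
           beta=cfg.beta, min_size=cfg.min_module_size, merge=cfg.merge_threshold)
    if len(em):
        _write(em, out / "eigengenes.tsv", seed, index_label="module")
        _write(trait_corr, out / "module_trait_correlation.tsv", seed)
    return {"assignment": assignment, "eigengenes": em,
            "variance_explained": varexp, "trait_correlation": trait_corr}


def _write_report(results, th, out, seed) -> None:
    rows = [
        ("n_genes_input", results["counts"].n_genes),
        ("n_genes_expressed", results["filtered"].n_genes),
        ("n_samples", results["filtered"].n_samples),
        ("fdr", th["fdr"]),
    ]
    de = results["de"]
    rows.append(("n_de_calls", int(de["significant"].sum())))
    rows.append(("n_de_genes_any_contrast",
                 int(de[de["significant"]]["gene"].nunique())))
    lrt = results["lrt"]
    rows.append(("n_interaction_genes", int((lrt["padj"] < th["fdr"]).sum())))
    net = results["network"]
    n_modules = int((net["assignment"]["module"] != "grey").sum() and
                    net["assignment"]["module"].nunique()
                    - int("grey" in set(net["assignment"]["module"])))
    rows.append(("n_modules", n_modules))
    if results.get("fst") is not None and results["fst"]["enrichment"] is not None:
        enr = results["fst"]["enrichment"]
        rows.append(("n_genes_fst_tested", int(enr["tested"].sum())))
        rows.append(("n_genes_fst_enriched", int(enr["enriched"].sum())))
    if results.get("divergence"):
        for (s1, s2), d in results["divergence"].items():
            rows.append((f"divergence_{s1}_vs_{s2}", d))
    formatted = [(k, v if isinstance(v, int) else f"{v:.6g}") for k, v in rows]
    report = pd.DataFrame(formatted, columns=["quantity", "value"])
    _write(report, out / "report.tsv", seed)
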