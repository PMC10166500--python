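"""Synthetic data generation with known ground truth.

Emulates the study design the package targets: bulk RNA-seq of two
populations (a derived European one, ``NL``, and an ancestral sub-Saharan
African one, ``ZI``) across three larval/prepupal developmental stages with
three biological replicates per population x stage cell — 18 samples over
~12,000 genes, ~6.6% of them lncRNAs.  Counts are negative-binomial with
variance mu + alpha*mu^2; developmental stage is made to explain several
times more expression variance than population, mirroring the structure of
real developmental series.

Three generators are provided:

* :func:`simulate_counts` — the expression matrix with planted stage-DE,
  population-DE, interaction and stage-specific genes;
* :func:`simulate_snps` — two-population SNP allele counts under a
  Balding–Nichols model with elevated differentiation inside "hot" gene
  spans;
* :func:`simulate_dual_reference` — paired count matrices from two
  reference annotations, with a planted mapping-bias subset.

Every generator is a pure function of its config and seed: identical inputs
give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import CountMatrix

__all__ = [
    "SimConfig",
    "simulate_counts",
    "simulate_snps",
    "simulate_dual_reference",
    "STAGES",
    "POPULATIONS",
]

STAGES = ("early", "late", "prepup")
POPULATIONS = ("NL", "ZI")
ARMS = ("2L", "2R", "3L", "3R", "X")


class SimulationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Configuration for :func:`simulate_counts`.

    Defaults reproduce the study conditions: 12,000 genes (6.6% lncRNA),
    2 populations x 3 stages x 3 replicates, NB dispersion alpha = 0.05,
    log2 effect size 2.0, and a 5x stage-over-population variance ratio.
    """

    n_genes: int = 12_000
    lncrna_fraction: float = 0.066
    n_replicates: int = 3
    baseline_logmean_range: tuple[float, float] = (3.0, 10.0)
    dispersion_alpha: float = 0.05
    frac_stage_de: float = 0.30
    frac_pop_de: float = 0.10
    frac_interaction: float = 0.05
    frac_stage_specific: float = 0.05
    effect_size_log2: float = 2.0
    stage_pop_variance_ratio: float = 5.0
    libsize_lognormal_sd: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        fracs = {
            "lncrna_fraction": self.lncrna_fraction,
            "frac_stage_de": self.frac_stage_de,
            "frac_pop_de": self.frac_pop_de,
            "frac_interaction": self.frac_interaction,
            "frac_stage_specific": self.frac_stage_specific,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name}={v} outside [0, 1]")
        total = (self.frac_stage_de + self.frac_pop_de + self.frac_interaction
                 + self.frac_stage_specific)
        if total > 1.0 + 1e-12:
            raise SimulationError(
                f"exclusive effect-class fractions sum to {total:.3f} > 1"
            )
        if self.n_genes < 1:
            raise SimulationError("n_genes must be >= 1")
        if self.n_replicates < 1:
            raise SimulationError("n_replicates must be >= 1")
        if self.dispersion_alpha < 0:
            raise SimulationError("dispersion_alpha must be >= 0")
        lo, hi = self.baseline_logmean_range
        if not lo <= hi:
            raise SimulationError("baseline_logmean_range must be (lo, hi) with lo <= hi")
        if self.libsize_lognormal_sd < 0:
            raise SimulationError("libsize_lognormal_sd must be >= 0")
        if self.stage_pop_variance_ratio <= 0:
            raise SimulationError("stage_pop_variance_ratio must be > 0")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB draws with variance mu + alpha*mu^2 (Poisson at alpha = 0)."""
    mu = np.asarray(mu, dtype=float)
    if alpha <= 0:
        return rng.poisson(mu)
    size_param = 1.0 / alpha
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    p = size_param / (size_param + mu[pos])
    out[pos] = rng.negative_binomial(size_param, p)
    return out


def _stage_effect_scale(cfg: SimConfig) -> float:
    """Scale stage offsets so stage variance ~= ratio x population variance.

    A stage-DE gene has one elevated stage (2 of 6 cells): per-gene variance
    over cells = (1/3)(2/3) * d_s^2.  A pop-DE gene has one elevated
    population (3 of 6 cells): (1/2)^2 * d_p^2.  Solving
    f_s * (2/9) d_s^2 = R * f_p * (1/4) d_p^2 for d_s gives the scale.
    """
    f_s = max(cfg.frac_stage_de, 1e-12)
    return cfg.effect_size_log2 * np.sqrt(
        cfg.stage_pop_variance_ratio * cfg.frac_pop_de * 0.25 / (f_s * 2.0 / 9.0)
    )


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate an 18-sample (by default) count matrix with planted effects.

    Returns the CountMatrix and a per-gene ground-truth table with columns:
    ``biotype``, ``is_stage_de``, ``is_pop_de``, ``is_interaction``,
    ``is_stage_specific``, ``pop_up`` (population carrying the planted
    up-regulation, or empty), ``true_pop_log2fc`` (NL minus ZI, log2),
    ``de_stage`` (elevated stage for stage-DE / stage-specific genes).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    n_cells = len(POPULATIONS) * len(STAGES)
    genes = [f"g{i:05d}" for i in range(G)]

    # disjoint effect-class blocks (order: stage-DE, pop-DE, interaction,
    # stage-specific, null) over a shuffled gene order
    order = rng.permutation(G)
    n_sde = int(round(config.frac_stage_de * G))
    n_pde = int(round(config.frac_pop_de * G))
    n_int = int(round(config.frac_interaction * G))
    n_spec = int(round(config.frac_stage_specific * G))
    splits = np.cumsum([n_sde, n_pde, n_int, n_spec])
    idx_sde, idx_pde, idx_int, idx_spec = (
        order[: splits[0]], order[splits[0]:splits[1]],
        order[splits[1]:splits[2]], order[splits[2]:splits[3]],
    )

    lo, hi = config.baseline_logmean_range
    baseline = rng.uniform(lo, hi, size=G)

    # log2 group means, genes x (pop, stage) cells
    log2q = np.repeat(baseline[:, None], n_cells, axis=1)
    cell_index = {(p, s): i * len(STAGES) + j
                  for i, p in enumerate(POPULATIONS) for j, s in enumerate(STAGES)}

    d_stage = _stage_effect_scale(config)
    d = config.effect_size_log2

    de_stage = np.array([""] * G, dtype=object)
    pop_up = np.array([""] * G, dtype=object)
    true_pop_lfc = np.zeros(G)

    # stage-DE: one stage elevated by d_stage in both populations
    up_stage = rng.integers(0, len(STAGES), size=idx_sde.size)
    for g, sj in zip(idx_sde, up_stage):
        for p in POPULATIONS:
            log2q[g, cell_index[(p, STAGES[sj])]] += d_stage
        de_stage[g] = STAGES[sj]

    # pop-DE: one population elevated by d across all stages
    up_pop = rng.integers(0, 2, size=idx_pde.size)
    for g, pj in zip(idx_pde, up_pop):
        for s in STAGES:
            log2q[g, cell_index[(POPULATIONS[pj], s)]] += d
        pop_up[g] = POPULATIONS[pj]
        true_pop_lfc[g] = d if pj == 0 else -d
    # interaction: one stage shifted +d in NL and -d in ZI
    int_stage = rng.integers(0, len(STAGES), size=idx_int.size)
    for g, sj in zip(idx_int, int_stage):
        log2q[g, cell_index[("NL", STAGES[sj])]] += d
        log2q[g, cell_index[("ZI", STAGES[sj])]] -= d
        de_stage[g] = STAGES[sj]

    # stage-specific: expressed in exactly one stage, zero mean elsewhere
    spec_stage = rng.integers(0, len(STAGES), size=idx_spec.size)
    q = np.exp2(log2q)
    for g, sj in zip(idx_spec, spec_stage):
        for p in POPULATIONS:
            for j, s in enumerate(STAGES):
                if j != sj:
                    q[g, cell_index[(p, s)]] = 0.0
        de_stage[g] = STAGES[sj]

    # samples and library sizes
    sample_ids, pops, stages, reps, cells = [], [], [], [], []
    for p in POPULATIONS:
        for s in STAGES:
            for r in range(1, config.n_replicates + 1):
                sample_ids.append(f"{p}_{s}_{r}")
                pops.append(p)
                stages.append(s)
                reps.append(r)
                cells.append(cell_index[(p, s)])
    n_samples = len(sample_ids)
    libsize = np.exp(rng.normal(0.0, config.libsize_lognormal_sd, size=n_samples))

    mu = q[:, cells] * libsize[None, :]
    counts = _nb_draw(rng, mu, config.dispersion_alpha)

    counts_df = pd.DataFrame(counts, index=genes, columns=sample_ids)
    sample_meta = pd.DataFrame(
        {"population": pops, "stage": stages, "replicate": reps}, index=sample_ids
    )
    sample_meta.index.name = "sample"

    # gene annotations: biotype, arm, span, effective length
    is_lnc = rng.random(G) < config.lncrna_fraction
    arm = rng.choice(ARMS, size=G)
    # whole-gene regions (UTRs + introns included): 2-15 kb, 20 kb spacing
    length = rng.integers(2000, 15_001, size=G)
    gene_meta = pd.DataFrame(index=pd.Index(genes, name="gene"))
    gene_meta["biotype"] = np.where(is_lnc, "lncRNA", "protein_coding")
    gene_meta["arm"] = arm
    start = np.zeros(G, dtype=np.int64)
    for a in ARMS:
        mask = arm == a
        start[mask] = 1 + 20_000 * np.arange(mask.sum())
    gene_meta["start"] = start
    gene_meta["end"] = start + length - 1
    gene_meta["length"] = length

    cm = CountMatrix(counts=counts_df, sample_meta=sample_meta, gene_meta=gene_meta)

    flags = np.zeros(G, dtype=bool)
    truth = pd.DataFrame(index=pd.Index(genes, name="gene"))
    truth["biotype"] = gene_meta["biotype"].to_numpy()
    for name, idx in (
        ("is_stage_de", idx_sde), ("is_pop_de", idx_pde),
        ("is_interaction", idx_int), ("is_stage_specific", idx_spec),
    ):
        col = flags.copy()
        col[idx] = True
        truth[name] = col
    truth["pop_up"] = pop_up
    truth["true_pop_log2fc"] = true_pop_lfc
    truth["de_stage"] = de_stage
    return cm, truth


# ---------------------------------------------------------------------------
# SNP simulation
# ---------------------------------------------------------------------------

def _check_spans(hot_genes: Sequence[tuple]) -> list[tuple[str, str, int, int]]:
    """Normalise hot-gene spans to (gene, arm, start, end); reject overlap."""
    spans = []
    for i, g in enumerate(hot_genes):
        if len(g) == 4:
            name, arm, start, end = g
        elif len(g) == 3:
            arm, start, end = g
            name = f"hot{i:03d}"
        else:
            raise SimulationError("hot gene spans must be (arm, start, end) or "
                                  "(name, arm, start, end)")
        start, end = int(start), int(end)
        if start > end:
            raise SimulationError(f"hot gene {name}: start > end")
        spans.append((str(name), str(arm), start, end))
    by_arm: dict[str, list] = {}
    for name, arm, start, end in spans:
        by_arm.setdefault(arm, []).append((start, end, name))
    for arm, lst in by_arm.items():
        lst.sort()
        for (s1, e1, n1), (s2, e2, n2) in zip(lst, lst[1:]):
            if s2 <= e1:
                raise SimulationError(
                    f"hot genes {n1} and {n2} overlap on arm {arm}"
                )
    return spans


def simulate_snps(
    n_snps_per_arm: int,
    arms: Sequence[str] = ARMS,
    n1: int = 20,
    n2: int = 20,
    hot_genes: Sequence[tuple] = (),
    fst_base: float = 0.05,
    fst_hot: float = 0.40,
    seed: int = 0,
    arm_length: int = 25_000_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-population SNP allele counts under a Balding–Nichols model.

    Ancestral allele frequencies are uniform on (0.05, 0.95); population
    frequencies are Beta-distributed around the ancestral value with
    divergence parameter ``fst_base`` genome-wide and ``fst_hot`` for SNPs
    inside ``hot_genes`` spans.  Allele counts are binomial at haploid
    sample sizes ``n1``/``n2``.

    Returns (snp_table, hot_gene_table).  ``snp_table`` columns: arm, pos,
    ref_count_pop1, alt_count_pop1, ref_count_pop2, alt_count_pop2, is_hot.
    """
    if not 0 <= fst_base < fst_hot < 1:
        raise SimulationError(
            f"require 0 <= fst_base < fst_hot < 1, got ({fst_base}, {fst_hot})"
        )
    if n1 < 2 or n2 < 2:
        raise SimulationError("haploid sample sizes must be >= 2")
    spans = _check_spans(hot_genes)
    rng = np.random.default_rng(seed)

    recs = []
    for arm in arms:
        pos = np.sort(rng.choice(arm_length, size=n_snps_per_arm, replace=False))
        hot = np.zeros(n_snps_per_arm, dtype=bool)
        for _, sp_arm, s, e in spans:
            if sp_arm == arm:
                hot |= (pos >= s) & (pos <= e)
        F = np.where(hot, fst_hot, fst_base)
        p_anc = rng.uniform(0.05, 0.95, size=n_snps_per_arm)
        p = np.empty((n_snps_per_arm, 2))
        for k in range(2):
            drift = F > 0
            a = p_anc * (1 - F) / np.maximum(F, 1e-12)
            b = (1 - p_anc) * (1 - F) / np.maximum(F, 1e-12)
            p[:, k] = np.where(drift, rng.beta(np.maximum(a, 1e-12),
                                               np.maximum(b, 1e-12)), p_anc)
        alt1 = rng.binomial(n1, p[:, 0])
        alt2 = rng.binomial(n2, p[:, 1])
        recs.append(pd.DataFrame({
            "arm": arm, "pos": pos,
            "ref_count_pop1": n1 - alt1, "alt_count_pop1": alt1,
            "ref_count_pop2": n2 - alt2, "alt_count_pop2": alt2,
            "is_hot": hot,
        }))
    snp_table = pd.concat(recs, ignore_index=True)
    hot_table = pd.DataFrame(spans, columns=["gene", "arm", "start", "end"])
    return snp_table, hot_table


# ---------------------------------------------------------------------------
# Dual-reference mapping-bias simulation
# ---------------------------------------------------------------------------

def simulate_dual_reference(
    cm: CountMatrix,
    bias_fraction: float = 0.0,
    bias_strength: float = 0.5,
    seed: int = 0,
    base_rate: float = 0.9,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Paired per-gene counts from two reference annotations.

    Each true read count is thinned twice: once at the population-reference
    mapping rate and once at the standard-reference rate.  Unbiased genes
    use ``base_rate`` for both; a ``bias_fraction`` subset has one rate
    reduced by the factor (1 - ``bias_strength``), with a random sign per
    gene.  At ``bias_strength = 1`` the disadvantaged reference maps no
    reads, driving the bias index to +/-1.

    Returns (counts_popref, counts_stdref, ground_truth); the count frames
    share ``cm``'s gene x sample layout.
    """
    if not 0.0 <= bias_fraction <= 1.0:
        raise SimulationError("bias_fraction must be in [0, 1]")
    if not 0.0 < bias_strength <= 1.0:
        raise SimulationError("bias_strength must be in (0, 1]")
    if not 0.0 < base_rate <= 1.0:
        raise SimulationError("base_rate must be in (0, 1]")
    rng = np.random.default_rng(seed)
    G = cm.n_genes
    biased = rng.random(G) < bias_fraction
    sign = np.where(rng.random(G) < 0.5, 1, -1)
    sign[~biased] = 0

    rate_pop = np.full(G, base_rate)
    rate_std = np.full(G, base_rate)
    rate_pop[sign == -1] *= (1.0 - bias_strength)
    rate_std[sign == 1] *= (1.0 - bias_strength)

    c = cm.counts.to_numpy().astype(np.int64)
    n_pop = rng.binomial(c, rate_pop[:, None])
    n_std = rng.binomial(c, rate_std[:, None])
    pop_df = pd.DataFrame(n_pop, index=cm.genes, columns=cm.samples)
    std_df = pd.DataFrame(n_std, index=cm.genes, columns=cm.samples)
    truth = pd.DataFrame(
        {"is_biased": biased, "bias_sign": sign},
        index=pd.Index(cm.genes, name="gene"),
    )
    return pop_df, std_df, truth
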