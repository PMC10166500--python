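"""Negative-binomial differential expression.

A spec-level NB test in the DESeq2 tradition, not a DESeq2 clone: per-gene
Cox–Reid-adjusted maximum-likelihood dispersion (no empirical-Bayes trend or
shrinkage), Wald contrasts between group means on the log scale, a
likelihood-ratio test for the stage x population interaction, and
Benjamini–Hochberg FDR control.  There is no fold-change shrinkage, no
Cook's-distance outlier handling and no independent filtering: calibration
and effect recovery on simulated counts are the behavioural contract.

The count model: y_gj ~ NB(mu_gj, alpha_g) with variance mu + alpha*mu^2 and
mu_gj = s_j * q_{g, group(j)}, where s_j are size factors and q the group
means on the count scale.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DesignSpec",
    "six_level_design",
    "estimate_dispersion",
    "wald_contrast",
    "lrt_interaction",
    "bh_adjust",
    "de_table",
    "upset_intersections",
    "compare_magnitudes",
    "strain_de",
]

ALPHA_MIN, ALPHA_MAX = 1e-8, 10.0
PSEUDOCOUNT = 0.5  # on the normalized-count scale, keeps log2FC defined


@dataclass
class DesignSpec:
    """Sample grouping plus the contrasts to test.

    ``groups`` assigns every sample to exactly one level; ``contrasts`` is a
    list of (numerator, denominator) group pairs — positive log2FC means the
    numerator group is up.
    """

    groups: pd.Series
    contrasts: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.groups.isna().any():
            raise ValueError("every sample needs a group label")
        levels = set(self.groups.unique())
        for a, b in self.contrasts:
            if a not in levels or b not in levels:
                raise ValueError(f"contrast ({a}, {b}) references unknown group")

    @property
    def levels(self) -> list[str]:
        return sorted(self.groups.unique())


def six_level_design(cm, contrasts: str = "all-pairs") -> DesignSpec:
    """One-factor design over the population x stage cells.

    ``contrasts``: "all-pairs" for every pairwise comparison (15 for six
    levels), or "canonical" for the comparisons the analysis actually uses —
    between populations within each stage and between stages within each
    population (3 + 6 = 9 for the 2 x 3 design).
    """
    groups = cm.groups()
    levels = sorted(groups.unique())
    if contrasts == "all-pairs":
        pairs = list(itertools.combinations(levels, 2))
    elif contrasts == "canonical":
        meta = cm.sample_meta
        pops = sorted(meta["population"].unique())
        stages = list(dict.fromkeys(meta["stage"]))  # keep sheet order
        pairs = []
        for s in stages:  # between populations, within stage
            pairs.append((f"{pops[0]}_{s}", f"{pops[1]}_{s}"))
        for p in pops:  # between stages, within population
            for s1, s2 in itertools.combinations(stages, 2):
                pairs.append((f"{p}_{s2}", f"{p}_{s1}"))
        pairs = [p for p in pairs if p[0] in levels and p[1] in levels]
    else:
        raise ValueError("contrasts must be 'all-pairs' or 'canonical'")
    return DesignSpec(groups=groups, contrasts=pairs)


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB log-likelihood with variance mu + alpha*mu^2 (alpha > 0)."""
    r = 1.0 / alpha
    mu = np.maximum(mu, 1e-10)
    return float(np.sum(
        special.gammaln(y + r) - special.gammaln(r) - special.gammaln(y + 1)
        + y * np.log(alpha * mu / (1.0 + alpha * mu))
        - r * np.log1p(alpha * mu)
    ))


def _cr_penalty(mu: np.ndarray, alpha: float, group_codes: np.ndarray,
                n_groups: int) -> float:
    """Cox–Reid adjustment: -0.5 * log det of the mean-parameter information.

    For a group-means model with log link the information matrix is diagonal
    with entries sum_j w_j per group, w_j = mu_j / (1 + alpha*mu_j).
    """
    w = mu / (1.0 + alpha * mu)
    sums = np.bincount(group_codes, weights=w, minlength=n_groups)
    sums = np.maximum(sums, 1e-300)
    return -0.5 * float(np.sum(np.log(sums)))


def estimate_dispersion(counts, groups: pd.Series, size_factors: pd.Series,
                        cox_reid: bool = True) -> pd.DataFrame:
    """Per-gene NB dispersion by (Cox–Reid adjusted) maximum likelihood.

    ``counts`` is a genes x samples DataFrame.  Group means are profiled as
    mean normalized counts per group; alpha is maximised on the log scale
    within [1e-8, 10] with a method-of-moments fallback if the optimiser
    fails.  All-zero genes are flagged untestable (alpha = NaN).

    Returns a DataFrame with columns ``alpha`` and ``untestable``.
    """
    counts = counts.counts if hasattr(counts, "counts") else counts
    groups = groups.loc[counts.columns]
    codes, levels = pd.factorize(groups)
    n_groups = len(levels)
    if n_groups < 2 or min(np.bincount(codes)) < 2:
        raise ValueError("need >= 2 groups with >= 2 samples each")
    s = size_factors.loc[counts.columns].to_numpy(dtype=float)
    Y = counts.to_numpy(dtype=float)
    norm = Y / s[None, :]

    # profiled group means, genes x groups
    qs = np.stack([norm[:, codes == g].mean(axis=1) for g in range(n_groups)], axis=1)
    mu_all = qs[:, codes] * s[None, :]

    alphas = np.full(Y.shape[0], np.nan)
    untestable = (Y.sum(axis=1) == 0)
    log_bounds = (np.log(ALPHA_MIN), np.log(ALPHA_MAX))

    for i in range(Y.shape[0]):
        if untestable[i]:
            continue
        y, mu = Y[i], mu_all[i]

        def neg_ll(log_a: float) -> float:
            a = np.exp(log_a)
            ll = _nb_loglik(y, mu, a)
            if cox_reid:
                ll += _cr_penalty(mu, a, codes, n_groups)
            return -ll

        try:
            res = optimize.minimize_scalar(
                neg_ll, bounds=log_bounds, method="bounded",
                options={"xatol": 1e-4},
            )
            alphas[i] = float(np.exp(res.x))
        except Exception:
            # method-of-moments fallback: alpha = (var - mean)/mean^2 pooled
            resid = y - mu
            denom = max(np.sum(mu**2), 1e-12)
            alphas[i] = float(np.clip((np.sum(resid**2 - mu)) / denom,
                                      ALPHA_MIN, ALPHA_MAX))
    alphas = np.clip(alphas, ALPHA_MIN, ALPHA_MAX)
    alphas[untestable] = np.nan
    return pd.DataFrame({"alpha": alphas, "untestable": untestable},
                        index=counts.index)


# ---------------------------------------------------------------------------
# Wald contrast
# ---------------------------------------------------------------------------

def wald_contrast(counts, groups: pd.Series, contrast: tuple[str, str],
                  size_factors: pd.Series, alpha: pd.Series) -> pd.DataFrame:
    """Wald test of one group-pair contrast, vectorised over genes.

    log2FC = log2((qA + 0.5) / (qB + 0.5)) on mean normalized counts; the
    Wald statistic uses the observed Fisher information of the log group
    means, SE = sqrt(1/I_A + 1/I_B) with I = sum_j mu_j/(1 + alpha*mu_j).
    Because the dispersion is estimated, the statistic is referred to a t
    distribution with the design's residual degrees of freedom
    (n_samples - n_groups) rather than to the normal — the usual
    small-sample correction; with many samples the two coincide.
    Genes that are all-zero in both groups get NaN P (excluded from BH).
    """
    counts = counts.counts if hasattr(counts, "counts") else counts
    groups = groups.loc[counts.columns]
    a_name, b_name = contrast
    in_a = (groups == a_name).to_numpy()
    in_b = (groups == b_name).to_numpy()
    if not in_a.any() or not in_b.any():
        raise ValueError(f"contrast ({a_name}, {b_name}) has an empty group")
    s = size_factors.loc[counts.columns].to_numpy(dtype=float)
    Y = counts.to_numpy(dtype=float)
    norm = Y / s[None, :]
    qa = norm[:, in_a].mean(axis=1)
    qb = norm[:, in_b].mean(axis=1)
    al = alpha.loc[counts.index].to_numpy(dtype=float)

    qa_t = qa + PSEUDOCOUNT
    qb_t = qb + PSEUDOCOUNT
    lfc = np.log2(qa_t / qb_t)

    with np.errstate(invalid="ignore"):
        mu_a = s[in_a][None, :] * qa_t[:, None]
        mu_b = s[in_b][None, :] * qb_t[:, None]
        info_a = np.sum(mu_a / (1.0 + al[:, None] * mu_a), axis=1)
        info_b = np.sum(mu_b / (1.0 + al[:, None] * mu_b), axis=1)
        se_ln = np.sqrt(1.0 / info_a + 1.0 / info_b)
        z = np.log(qa_t / qb_t) / se_ln
    df_resid = max(len(s) - groups.nunique(), 1)
    pval = 2.0 * stats.t.sf(np.abs(z), df_resid)

    both_zero = (Y[:, in_a].sum(axis=1) == 0) & (Y[:, in_b].sum(axis=1) == 0)
    undefined = both_zero | ~np.isfinite(al)
    pval = np.where(undefined, np.nan, pval)
    z = np.where(undefined, np.nan, z)

    direction = np.where(lfc > 0, a_name, np.where(lfc < 0, b_name, ""))
    return pd.DataFrame({
        "contrast": f"{a_name}_vs_{b_name}",
        "log2fc": lfc,
        "se": se_ln / np.log(2.0),
        "stat": z,
        "pvalue": pval,
        "direction": direction,
        "alpha": al,
    }, index=counts.index)


# ---------------------------------------------------------------------------
# interaction LRT
# ---------------------------------------------------------------------------

def lrt_interaction(counts, stage: pd.Series, population: pd.Series,
                    size_factors: pd.Series, alpha: pd.Series) -> pd.DataFrame:
    """Likelihood-ratio test for a stage x population interaction.

    Per gene, fits the full NB GLM (stage + population + stage:population,
    i.e. one mean per cell) and the reduced additive model
    (stage + population) with the gene's fixed dispersion, both via IRLS
    with a log link and log size-factor offsets.  The statistic
    LR = 2*(ll_full - ll_reduced) has df = (n_stages - 1)(n_pops - 1);
    because the dispersion is estimated, LR/df is referred to
    F(df, n_samples - p_full) rather than LR to chi-square — the
    quasi-likelihood-style small-sample correction.  The asymptotic
    chi-square P is also reported (``pvalue_chi2``).
    """
    import statsmodels.api as sm

    counts = counts.counts if hasattr(counts, "counts") else counts
    stage = stage.loc[counts.columns]
    population = population.loc[counts.columns]
    s = size_factors.loc[counts.columns].to_numpy(dtype=float)
    offset = np.log(s)

    stage_d = pd.get_dummies(stage, drop_first=True, dtype=float)
    pop_d = pd.get_dummies(population, drop_first=True, dtype=float)
    X_red = np.column_stack([np.ones(len(s)), stage_d.to_numpy(), pop_d.to_numpy()])
    inter = np.einsum("ij,ik->ijk", stage_d.to_numpy(), pop_d.to_numpy())
    X_full = np.column_stack([X_red, inter.reshape(len(s), -1)])
    df_diff = X_full.shape[1] - X_red.shape[1]

    Y = counts.to_numpy(dtype=float)
    al = alpha.loc[counts.index].to_numpy(dtype=float)
    n_genes = Y.shape[0]
    stat = np.full(n_genes, np.nan)
    df_resid = max(len(s) - X_full.shape[1], 1)

    if df_diff == 0:  # full and reduced designs coincide
        testable = (Y.sum(axis=1) > 0) & np.isfinite(al)
        stat[testable] = 0.0
        pval = np.where(testable, 1.0, np.nan)
        return pd.DataFrame({"stat": stat, "pvalue": pval,
                             "pvalue_chi2": pval, "df": 0},
                            index=counts.index)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_genes):
            y = Y[i]
            if y.sum() == 0 or not np.isfinite(al[i]):
                continue
            fam = sm.families.NegativeBinomial(alpha=max(al[i], 1e-8))
            try:
                full = sm.GLM(y, X_full, family=fam, offset=offset).fit(maxiter=100)
                red = sm.GLM(y, X_red, family=fam, offset=offset).fit(maxiter=100)
                lr = 2.0 * (full.llf - red.llf)
            except Exception:
                continue
            stat[i] = max(lr, 0.0)
    pval = stats.f.sf(stat / df_diff, df_diff, df_resid)
    pval_chi2 = stats.chi2.sf(stat, df_diff)
    return pd.DataFrame({"stat": stat, "pvalue": pval,
                         "pvalue_chi2": pval_chi2, "df": df_diff},
                        index=counts.index)


# ---------------------------------------------------------------------------
# multiplicity and result tables
# ---------------------------------------------------------------------------

def bh_adjust(pvalues) -> pd.Series | np.ndarray:
    """Benjamini–Hochberg step-up adjustment; NaNs pass through untouched.

    Missing values are excluded from the number of tests m.
    """
    p = np.asarray(pvalues, dtype=float)
    ok = np.isfinite(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    adj = np.full(p.shape, np.nan)
    if ok.any():
        adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
    if isinstance(pvalues, pd.Series):
        return pd.Series(adj, index=pvalues.index, name="padj")
    return adj


def de_table(cm, design: DesignSpec, fdr: float = 0.05,
             alpha: pd.Series | None = None,
             size_factors_: pd.Series | None = None) -> pd.DataFrame:
    """Full DE result table: one row per (gene, contrast).

    BH adjustment is applied within each contrast; ``significant`` is
    padj < fdr (strict).  Dispersions and size factors are estimated from
    the matrix unless supplied.
    """
    from .expression import size_factors as _sf

    sf = _sf(cm) if size_factors_ is None else size_factors_
    if alpha is None:
        alpha = estimate_dispersion(cm, design.groups, sf)["alpha"]
    tables = []
    for contrast in design.contrasts:
        t = wald_contrast(cm, design.groups, contrast, sf, alpha)
        t["padj"] = bh_adjust(t["pvalue"])
        t["significant"] = t["padj"] < fdr
        tables.append(t.reset_index(names="gene"))
    return pd.concat(tables, ignore_index=True)


def upset_intersections(up_sets: dict[str, set]) -> pd.DataFrame:
    """Upset-style intersection classes of named gene sets.

    Each gene in the union is assigned to exactly one intersection class:
    the combination of sets that contain it.  Returns one row per observed
    class with its member count, sorted by count.
    """
    universe = sorted(set().union(*up_sets.values())) if up_sets else []
    names = list(up_sets)
    rows: dict[tuple, int] = {}
    for g in universe:
        key = tuple(n for n in names if g in up_sets[n])
        rows[key] = rows.get(key, 0) + 1
    out = pd.DataFrame(
        [{"sets": "&".join(k), "degree": len(k), "count": v} for k, v in rows.items()]
    )
    return out.sort_values("count", ascending=False).reset_index(drop=True)


def compare_magnitudes(set_a, set_b, n_tests: int = 1) -> dict:
    """Welch t-test on |log2FC| magnitudes with Bonferroni correction."""
    a = np.asarray(set_a, dtype=float)
    b = np.asarray(set_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each set needs >= 2 values")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return {"t": float(t), "pvalue": float(p),
            "p_bonferroni": float(min(1.0, p * n_tests)), "n_tests": n_tests}


def strain_de(cm, group_col: str = "strain", mode: str = "pairwise",
              fdr: float = 0.05) -> pd.DataFrame:
    """Within-population DE across strains: all pairs, or one vs pooled rest.

    Strains with a single replicate are allowed (the dispersion is informed
    by the remaining strains) but reported in the table.  The union of
    significant genes over contrasts is the "variable within population"
    set used in overlap tests.
    """
    from .expression import size_factors as _sf

    if group_col not in cm.sample_meta.columns:
        raise ValueError(f"sample sheet lacks '{group_col}' column")
    groups = cm.sample_meta[group_col].astype(str)
    groups.name = "group"
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("need >= 2 strains")
    sf = _sf(cm)
    alpha = estimate_dispersion(cm, groups, sf)["alpha"]

    tables = []
    if mode == "pairwise":
        for a, b in itertools.combinations(levels, 2):
            t = wald_contrast(cm, groups, (a, b), sf, alpha)
            t["padj"] = bh_adjust(t["pvalue"])
            t["significant"] = t["padj"] < fdr
            tables.append(t.reset_index(names="gene"))
    elif mode == "one_vs_rest":
        for a in levels:
            collapsed = groups.where(groups == a, "rest")
            t = wald_contrast(cm, collapsed, (a, "rest"), sf, alpha)
            t["contrast"] = f"{a}_vs_rest"
            t["padj"] = bh_adjust(t["pvalue"])
            t["significant"] = t["padj"] < fdr
            tables.append(t.reset_index(names="gene"))
    else:
        raise ValueError("mode must be 'pairwise' or 'one_vs_rest'")
    out = pd.concat(tables, ignore_index=True)
    singles = {lv for lv in levels if (groups == lv).sum() < 2}
    out.attrs["single_replicate_strains"] = sorted(singles)
    return out
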