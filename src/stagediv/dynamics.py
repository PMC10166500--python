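"""Cross-population expression-dynamics statistics.

Given per-population differential-expression results between developmental
stages, this module classifies each gene's between-stage DE as conserved,
private to one population, or opposite in direction; quantifies the
divergence of transcriptional turnover between populations as
D = 1 - rho(log2FC_pop1, log2FC_pop2); computes the developmental
stage-specificity index tau from mean TPM per stage; and runs the
contingency-style chi-square tests for lncRNA contribution and gene-set
overlap, and the Welch t-tests on group TPM levels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "classify_de",
    "turnover_divergence",
    "private_de_correlation",
    "tau",
    "tau_table",
    "class_contribution_test",
    "overlap_test",
    "tpm_group_tests",
    "Chi2Result",
]

DE_CLASSES = ("conserved", "private_pop1", "private_pop2", "opposite", "none")


@dataclass(frozen=True)
class Chi2Result:
    """A 2x2 chi-square test: observed/expected tables, statistic, P."""

    observed: np.ndarray
    expected: np.ndarray
    statistic: float
    df: int
    pvalue: float


def classify_de(de_pop1: pd.DataFrame, de_pop2: pd.DataFrame,
                label_pop1: str = "NL", label_pop2: str = "ZI") -> pd.DataFrame:
    """Classify between-stage DE of each gene across two populations.

    Inputs are per-gene result frames for the *same* stage contrast in each
    population, indexed by gene with ``log2fc`` and ``significant`` columns
    (as produced by :func:`stagediv.de.de_table` rows for one contrast).

    Classes: ``conserved`` (significant in both, same log2FC sign),
    ``opposite`` (both, opposite sign), ``private_<pop>`` (exactly one),
    ``none``.  Genes present in only one table are treated as not-DE in the
    other and flagged in the ``missing_in`` column.
    """
    genes = de_pop1.index.union(de_pop2.index)
    t1 = de_pop1.reindex(genes)
    t2 = de_pop2.reindex(genes)
    sig1 = t1["significant"].eq(True)
    sig2 = t2["significant"].eq(True)
    s1 = np.sign(t1["log2fc"].fillna(0.0))
    s2 = np.sign(t2["log2fc"].fillna(0.0))

    cls = pd.Series("none", index=genes, name="de_class")
    cls[sig1 & ~sig2] = f"private_{label_pop1}"
    cls[~sig1 & sig2] = f"private_{label_pop2}"
    both = sig1 & sig2
    cls[both & (s1 * s2 > 0)] = "conserved"
    cls[both & (s1 * s2 < 0)] = "opposite"

    out = pd.DataFrame({
        "de_class": cls,
        f"sig_{label_pop1}": sig1,
        f"sig_{label_pop2}": sig2,
        f"log2fc_{label_pop1}": t1["log2fc"],
        f"log2fc_{label_pop2}": t2["log2fc"],
    })
    missing = pd.Series("", index=genes)
    missing[~genes.isin(de_pop1.index)] = label_pop1
    missing[~genes.isin(de_pop2.index)] = label_pop2
    out["missing_in"] = missing
    out.attrs["n_union_de"] = int((sig1 | sig2).sum())
    return out


def turnover_divergence(lfc_pop1, lfc_pop2, method: str = "pearson") -> float:
    """Divergence of transcriptional turnover: D = 1 - rho.

    ``rho`` is the correlation (Pearson by default, Spearman optionally) of
    the two populations' log2 fold-changes between a pair of stages over a
    common gene set.  D ranges over [0, 2]: 0 for identical turnover, 2 for
    exactly reversed turnover.
    """
    a = np.asarray(lfc_pop1, dtype=float)
    b = np.asarray(lfc_pop2, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 3:
        raise ValueError("need >= 3 paired finite fold-changes")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("divergence undefined for zero-variance fold-changes")
    if method == "pearson":
        rho = stats.pearsonr(a, b).statistic
    elif method == "spearman":
        rho = stats.spearmanr(a, b).statistic
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(1.0 - rho)


def private_de_correlation(lfc_pop1, lfc_pop2, n_tests: int = 1) -> dict:
    """Pearson correlation of privately-DE fold-changes across populations.

    Tests whether genes detected as DE in only one population nonetheless
    shift in the same direction in the other.  Returns r, the two-sided
    t-based P and its Bonferroni correction over ``n_tests`` comparisons.
    """
    a = np.asarray(lfc_pop1, dtype=float)
    b = np.asarray(lfc_pop2, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 3:
        raise ValueError("need >= 3 pairs")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined for constant vector")
    res = stats.pearsonr(a, b)
    return {"r": float(res.statistic), "pvalue": float(res.pvalue),
            "p_bonferroni": float(min(1.0, res.pvalue * n_tests)),
            "n": int(a.size), "n_tests": n_tests}


def tau(expression_by_stage) -> float:
    """Stage-specificity index tau = sum_i (1 - x_i/x_max) / (n - 1).

    1 when expression is confined to a single stage, 0 when uniform;
    undefined (raises) when all values are 0.
    """
    x = np.asarray(expression_by_stage, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("tau needs a 1-D vector of >= 2 stages")
    if (x < 0).any():
        raise ValueError("expression values must be >= 0")
    m = x.max()
    if m == 0:
        raise ValueError("tau undefined: all stages zero")
    return float(np.sum(1.0 - x / m) / (x.size - 1))


def tau_table(tpm_df: pd.DataFrame, sample_meta: pd.DataFrame) -> pd.DataFrame:
    """Per-gene, per-population tau from mean TPM per developmental stage.

    Genes with zero expression in every stage of a population get NaN; the
    number of such exclusions is stored in ``attrs['n_undefined']``.
    """
    out = {}
    n_undef = {}
    for pop, meta in sample_meta.groupby("population"):
        stage_means = []
        for stage, sm in meta.groupby("stage", sort=False):
            stage_means.append(tpm_df[sm.index].mean(axis=1))
        M = pd.concat(stage_means, axis=1).to_numpy()
        mx = M.max(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.sum(1.0 - M / mx[:, None], axis=1) / (M.shape[1] - 1)
        t[mx == 0] = np.nan
        out[pop] = t
        n_undef[pop] = int((mx == 0).sum())
    res = pd.DataFrame(out, index=tpm_df.index)
    res.attrs["n_undefined"] = n_undef
    return res


def _chi2_2x2(table: np.ndarray, correction: bool = True) -> Chi2Result:
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: zero margin")
    chi2, p, df, expected = stats.chi2_contingency(table, correction=correction)
    return Chi2Result(observed=table, expected=expected, statistic=float(chi2),
                      df=int(df), pvalue=float(p))


def class_contribution_test(up_lncrna: int, up_pc: int,
                            bg_lncrna: int, bg_pc: int) -> Chi2Result:
    """Does a gene set's lncRNA share differ from the dataset background?

    Yates-corrected 2x2 chi-square of [[up_lncrna, up_pc],
    [bg_lncrna, bg_pc]], where the background row is the whole analysed
    dataset (e.g. 816 lncRNA vs 11,615 protein-coding genes).
    """
    counts = np.array([[up_lncrna, up_pc], [bg_lncrna, bg_pc]], dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be >= 0")
    return _chi2_2x2(counts, correction=True)


def overlap_test(n_a_overlap: int, n_a_total: int,
                 n_b_overlap: int, n_b_total: int) -> Chi2Result:
    """Compare two overlap proportions with a Yates-corrected 2x2 chi-square.

    Rows are [[a_overlap, a_total - a_overlap],
    [b_overlap, b_total - b_overlap]].
    """
    if n_a_overlap > n_a_total or n_b_overlap > n_b_total:
        raise ValueError("overlap cannot exceed total")
    table = np.array([
        [n_a_overlap, n_a_total - n_a_overlap],
        [n_b_overlap, n_b_total - n_b_overlap],
    ], dtype=float)
    return _chi2_2x2(table, correction=True)


def tpm_group_tests(tpm_df: pd.DataFrame, sample_meta: pd.DataFrame,
                    gene_mask: pd.Series | None = None,
                    log_offset: float = 1.0) -> pd.DataFrame:
    """Welch t-tests on per-gene log2 mean TPM between sample groups.

    For every stage: between-population comparison at that stage; for every
    population: comparisons between consecutive stages.  The unit of
    observation is the gene (its log2 mean TPM over the group's samples);
    Bonferroni correction is over the whole comparison family, whose size
    is recorded in the ``family_size`` column.
    """
    if gene_mask is not None:
        tpm_df = tpm_df.loc[gene_mask.reindex(tpm_df.index).fillna(False)]
    stages = list(dict.fromkeys(sample_meta["stage"]))
    pops = sorted(sample_meta["population"].unique())

    def group_vals(pop, stage):
        cols = sample_meta.index[(sample_meta["population"] == pop)
                                 & (sample_meta["stage"] == stage)]
        return np.log2(tpm_df[cols].mean(axis=1).to_numpy() + log_offset)

    comparisons = []
    for s in stages:
        if len(pops) == 2:
            comparisons.append((f"{pops[0]}_vs_{pops[1]}@{s}",
                                group_vals(pops[0], s), group_vals(pops[1], s)))
    for p in pops:
        for s1, s2 in zip(stages, stages[1:]):
            comparisons.append((f"{s2}_vs_{s1}@{p}",
                                group_vals(p, s2), group_vals(p, s1)))
    k = len(comparisons)
    rows = []
    for name, a, b in comparisons:
        t, pv = stats.ttest_ind(a, b, equal_var=False)
        rows.append({"comparison": name, "t": float(t), "pvalue": float(pv),
                     "p_bonferroni": float(min(1.0, pv * k)), "family_size": k})
    return pd.DataFrame(rows)
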