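"""Dual-reference mapping-bias index and summaries.

When reads are mapped once against a population-matched reference and once
against the standard reference, per-gene count discrepancies reveal
reference (mapping) bias.  The index is

    b = (n_pop - n_std) / (n_pop + n_std)

with n_pop the reads mapped using the population reference and n_std the
reads mapped using the standard reference.  b lies in [-1, 1], is invariant
under scaling both counts by the same factor (hence robust to sequencing
depth) and antisymmetric in its arguments.  As written, positive values
mean more reads map with the population reference.  Gene/sample entries
with both counts zero are undefined and are excluded (and counted) rather
than imputed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["bias_index", "bias_table", "bias_summary", "HIST_EDGES"]

# fixed histogram bin edges: width 0.05 over [-1, 1]
HIST_EDGES = np.round(np.arange(-1.0, 1.0 + 0.05 / 2, 0.05), 10)


def bias_index(n_pop, n_std):
    """Mapping-bias index (n_pop - n_std) / (n_pop + n_std).

    Vectorised; entries where both counts are zero return NaN.
    """
    a = np.asarray(n_pop, dtype=float)
    b = np.asarray(n_std, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("counts must be >= 0")
    tot = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(tot > 0, (a - b) / np.where(tot > 0, tot, 1.0), np.nan)
    if np.isscalar(n_pop) and np.isscalar(n_std):
        return float(out)
    return out


def bias_table(counts_pop: pd.DataFrame, counts_std: pd.DataFrame) -> pd.DataFrame:
    """Per gene x sample bias index from two identically laid out count frames."""
    if not counts_pop.index.equals(counts_std.index) or \
       not counts_pop.columns.equals(counts_std.columns):
        raise ValueError("the two count tables must share gene and sample layout")
    vals = bias_index(counts_pop.to_numpy(), counts_std.to_numpy())
    return pd.DataFrame(vals, index=counts_pop.index, columns=counts_pop.columns)


def bias_summary(bt: pd.DataFrame, sample_meta: pd.DataFrame,
                 gene_class: pd.Series | None = None) -> dict:
    """Distributional summaries of the bias index.

    Returns a dict with:

    * ``by_group``: per population x stage — mean, median, quartiles, the
      number of defined entries and the number excluded (both counts 0);
    * ``histograms``: per group (and per gene class if ``gene_class`` maps
      gene -> class, e.g. biotype), counts over fixed 0.05-wide bins on
      [-1, 1].
    """
    if bt.empty:
        raise ValueError("empty bias table")
    groups = sample_meta.loc[bt.columns, ["population", "stage"]]
    rows, hists = [], {}
    classes = {"all": pd.Series(True, index=bt.index)}
    if gene_class is not None:
        for c in gene_class.unique():
            classes[str(c)] = gene_class == c
    for (pop, stage), meta in groups.groupby(["population", "stage"]):
        vals = bt[meta.index].to_numpy().ravel()
        defined = vals[np.isfinite(vals)]
        rows.append({
            "population": pop, "stage": stage,
            "mean": float(defined.mean()) if defined.size else np.nan,
            "median": float(np.median(defined)) if defined.size else np.nan,
            "q25": float(np.quantile(defined, 0.25)) if defined.size else np.nan,
            "q75": float(np.quantile(defined, 0.75)) if defined.size else np.nan,
            "n_defined": int(defined.size),
            "n_excluded": int(vals.size - defined.size),
        })
        for cname, mask in classes.items():
            sub = bt.loc[mask, meta.index].to_numpy().ravel()
            sub = sub[np.isfinite(sub)]
            # right-closed bins; values at exactly -1 fall in the first bin
            hist, _ = np.histogram(sub, bins=HIST_EDGES)
            hists[(pop, stage, cname)] = hist
    return {"by_group": pd.DataFrame(rows), "histograms": hists,
            "bin_edges": HIST_EDGES}
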