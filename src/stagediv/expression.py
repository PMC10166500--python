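"""Expression filtering, normalisation, binning, PCA and k-means summaries.

Implements the bookkeeping layer between raw counts and the statistical
analyses: the mean-reads-per-sample expression filter, DESeq-style
median-of-ratios size factors, TPM, the fixed TPM expression bins, PCA of
log-normalised counts, and k-means clustering of per-stage expression
profiles.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .containers import CountMatrix

__all__ = [
    "filter_expressed",
    "size_factors",
    "tpm",
    "bin_expression",
    "pca_expression",
    "kmeans_expression",
    "EXPRESSION_BINS",
]

# TPM bins with closed upper bounds: very low <= 1 < low <= 10 < moderate
# <= 25 < high <= 50 < very high
EXPRESSION_BINS = (
    ("very_low", 1.0),
    ("low", 10.0),
    ("moderate", 25.0),
    ("high", 50.0),
    ("very_high", np.inf),
)


def filter_expressed(
    cm: CountMatrix, min_mean_per_sample: float = 15
) -> tuple[CountMatrix, pd.DataFrame]:
    """Filter genes by mean mapped reads per sample; emit expression calls.

    A gene is *expressed* in the dataset when its mean count per sample over
    all samples is at least ``min_mean_per_sample`` (equivalently, total
    count >= threshold x n_samples: 270 for an 18-sample design, 165 for
    11 samples).  The same per-sample-mean rule, applied within each
    population x stage cell, yields the per-combination expressed calls.

    Returns the filtered CountMatrix and a per-gene call table with a
    global ``expressed`` column plus one boolean column per
    population x stage combination (named ``pop_stage``).
    """
    if min_mean_per_sample < 0:
        raise ValueError("min_mean_per_sample must be >= 0")
    totals = cm.counts.sum(axis=1)
    threshold = min_mean_per_sample * cm.n_samples
    keep = totals >= threshold

    calls = pd.DataFrame(index=cm.genes)
    calls["expressed"] = keep
    groups = cm.groups()
    for g in groups.unique():
        cols = groups.index[groups == g]
        calls[g] = cm.counts[cols].mean(axis=1) >= min_mean_per_sample

    if not keep.any():
        warnings.warn("no genes pass the expression filter", stacklevel=2)
    return cm.subset_genes(cm.genes[keep]), calls


def size_factors(cm: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (DESeq-style).

    factor_j = median over reference genes of count_gj / geomean_g, where
    reference genes are those with a positive count in every sample.  If no
    such gene exists, falls back to total-count ratios with a warning.
    """
    counts = cm.counts if isinstance(cm, CountMatrix) else cm
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if positive.any():
        logs = np.log(arr[positive])
        loggeo = logs.mean(axis=1, keepdims=True)
        factors = np.exp(np.median(logs - loggeo, axis=0))
    else:
        warnings.warn(
            "no gene has positive counts in all samples; "
            "falling back to total-count size factors", stacklevel=2
        )
        totals = arr.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("cannot compute size factors: a sample has zero total count")
        factors = totals / np.exp(np.mean(np.log(totals)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def tpm(cm: CountMatrix) -> pd.DataFrame:
    """Transcripts per million: (c_gj / L_g) / sum_h (c_hj / L_h) * 1e6."""
    lengths = cm.lengths().to_numpy()
    arr = cm.counts.to_numpy(dtype=float)
    rate = arr / lengths[:, None]
    denom = rate.sum(axis=0)
    zero = denom == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} sample(s) with zero total count: TPM column set to 0",
            stacklevel=2,
        )
        denom = np.where(zero, 1.0, denom)
    out = rate / denom[None, :] * 1e6
    out[:, zero] = 0.0
    return pd.DataFrame(out, index=cm.genes, columns=cm.samples)


def bin_expression(values: pd.Series | np.ndarray) -> pd.Series:
    """Assign TPM values to the fixed expression bins.

    Bins (closed upper bounds): very_low <= 1, low <= 10, moderate <= 25,
    high <= 50, very_high > 50.
    """
    v = pd.Series(values, dtype=float) if not isinstance(values, pd.Series) else values.astype(float)
    if (v < 0).any():
        raise ValueError("expression values must be >= 0")
    edges = [-np.inf] + [b for _, b in EXPRESSION_BINS[:-1]] + [np.inf]
    labels = [name for name, _ in EXPRESSION_BINS]
    return pd.cut(v, bins=edges, labels=labels, right=True).rename("bin")


def pca_expression(
    cm: CountMatrix, n_top_genes: int = 500, n_components: int = 5
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of log2(count / size_factor + 1) on the most variable genes.

    Returns per-sample scores (samples x components) and the per-component
    explained-variance fractions.
    """
    if cm.n_samples < 2:
        raise ValueError("PCA needs >= 2 samples")
    sf = size_factors(cm)
    norm = np.log2(cm.counts.to_numpy(dtype=float) / sf.to_numpy()[None, :] + 1.0)
    variances = norm.var(axis=1)
    k = min(n_top_genes, cm.n_genes)
    top = np.argsort(variances)[::-1][:k]
    X = norm[top].T  # samples x genes
    n_components = min(n_components, X.shape[0] - 1, X.shape[1])
    p = PCA(n_components=n_components, svd_solver="full")
    scores = p.fit_transform(X - X.mean(axis=0, keepdims=True))
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=cm.samples, columns=cols), p.explained_variance_ratio_


def kmeans_expression(
    profiles: pd.DataFrame, k: int = 5, seed: int = 0
) -> pd.Series:
    """k-means clustering of per-gene expression profiles (k-means++, 10 restarts).

    ``profiles`` is genes x conditions (e.g. mean log2 expression per
    stage).  Returns a per-gene integer cluster label, deterministic for a
    given seed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > profiles.shape[0]:
        raise ValueError(f"k={k} exceeds number of genes ({profiles.shape[0]})")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(profiles.to_numpy(dtype=float))
    return pd.Series(labels, index=profiles.index, name="cluster")
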