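"""Weighted co-expression network analysis.

Builds an unsigned soft-thresholded adjacency a_ij = |cor(x_i, x_j)|^beta,
derives the topological overlap matrix (TOM), clusters genes on 1 - TOM
with average-linkage hierarchical clustering, applies a size filter and an
eigengene-merge step, and reports module eigengenes, module-trait
correlations and connectivity (kTotal / kWithin, hub genes).

Tree cutting is a simplified static cut at a quantile of the dendrogram
merge heights followed by the minimum-size filter — not the published
dynamic hybrid algorithm.  The behavioural contract is module recovery on
block-correlated data, not replication of any particular module catalogue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "NetworkConfig",
    "adjacency",
    "tom",
    "cluster_modules",
    "eigengenes",
    "module_trait_correlation",
    "connectivity",
    "MODULE_COLORS",
]

# WGCNA-style color sequence for module labels, assigned by decreasing size
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
)
UNASSIGNED = "grey"


@dataclass(frozen=True)
class NetworkConfig:
    """Parameters of the co-expression network.

    ``beta``: soft-threshold power (6, the conventional unsigned default).
    ``min_module_size``: clusters smaller than this become unassigned.
    ``merge_threshold``: modules whose eigengenes correlate above this are
    merged (0.95 — high enough that well-separated modules never merge).
    ``cut_quantile``: static cut height as a quantile of dendrogram merge
    heights.
    """

    beta: float = 6.0
    min_module_size: int = 30
    merge_threshold: float = 0.95
    cut_quantile: float = 0.99

    def validate(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if not 0.0 < self.merge_threshold <= 1.0:
            raise ValueError("merge_threshold must be in (0, 1]")
        if not 0.0 < self.cut_quantile <= 1.0:
            raise ValueError("cut_quantile must be in (0, 1]")


def adjacency(expr: pd.DataFrame, beta: float = 6.0) -> pd.DataFrame:
    """Unsigned soft-thresholded adjacency |cor|^beta, genes x genes.

    ``expr`` is genes x samples (normalised log expression).  Constant
    genes have no defined correlation and are dropped with a warning.
    """
    if expr.shape[1] < 3:
        raise ValueError("need >= 3 samples for correlation networks")
    X = expr.to_numpy(dtype=float)
    sd = X.std(axis=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant gene(s) "
                      "from the network", stacklevel=2)
        X = X[keep]
    genes = expr.index[keep]
    r = np.corrcoef(X)
    a = np.abs(np.clip(r, -1.0, 1.0)) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=genes, columns=genes)


def tom(adj: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Topological overlap matrix.

    TOM_ij = (sum_{u != i,j} a_iu * a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    with k_i = sum_{u != i} a_iu and TOM_ii = 1.  Measures shared network
    neighbourhood in addition to direct adjacency.
    """
    A = adj.to_numpy(dtype=float) if isinstance(adj, pd.DataFrame) else np.asarray(adj, dtype=float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be square symmetric")
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    shared = A @ A  # sum_u a_iu a_uj; diagonal of A is 0 so u != i, j handled
    num = shared + A
    denom = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        T = num / denom
    T[~np.isfinite(T)] = 0.0
    np.fill_diagonal(T, 1.0)
    if isinstance(adj, pd.DataFrame):
        return pd.DataFrame(T, index=adj.index, columns=adj.columns)
    return T


def _eigengene(sub: np.ndarray) -> tuple[np.ndarray, float]:
    """First PC of a z-scored module submatrix (genes x samples).

    Returns the sample-length eigengene, sign-aligned with the module mean
    profile, and the fraction of variance it explains.
    """
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (sub - mu) / sd
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    eg = Vt[0]
    var_explained = float(S[0] ** 2 / np.sum(S ** 2)) if S.size else 0.0
    mean_profile = Z.mean(axis=0)
    if np.dot(eg, mean_profile) < 0:
        eg = -eg
    return eg, var_explained


def cluster_modules(expr: pd.DataFrame, config: NetworkConfig | None = None,
                    adj: pd.DataFrame | None = None) -> pd.DataFrame:
    """Detect co-expression modules from 1 - TOM dissimilarity.

    Average-linkage hierarchical clustering of the TOM dissimilarity, cut
    at the ``cut_quantile`` of merge heights; clusters below
    ``min_module_size`` go to the unassigned ``grey`` module.  Surviving
    modules are relabeled by decreasing size with the conventional color
    sequence, then modules whose eigengenes correlate above
    ``merge_threshold`` are merged iteratively (largest pair first).

    Returns a per-gene frame with ``module``, ``kTotal``, ``kWithin`` and
    ``hub`` columns (hub = top-5 kWithin within each non-grey module).
    """
    config = config or NetworkConfig()
    config.validate()
    if adj is None:
        adj = adjacency(expr, beta=config.beta)
    genes = adj.index
    expr = expr.loc[genes]
    T = tom(adj)
    D = 1.0 - T.to_numpy()
    np.fill_diagonal(D, 0.0)
    D = np.maximum(D, 0.0)
    condensed = squareform(D, checks=False)
    link = hierarchy.linkage(condensed, method="average")
    cut_h = float(np.quantile(link[:, 2], config.cut_quantile))
    raw = hierarchy.fcluster(link, t=cut_h, criterion="distance")

    sizes = pd.Series(raw).value_counts()
    keep_ids = [cid for cid in sizes.index if sizes[cid] >= config.min_module_size]
    # order by decreasing size, ties by cluster id for determinism
    keep_ids = sorted(keep_ids, key=lambda cid: (-sizes[cid], cid))
    labels = pd.Series(UNASSIGNED, index=genes, name="module")
    for rank, cid in enumerate(keep_ids):
        color = MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module{rank + 1}"
        labels[raw == cid] = color
    if (labels == UNASSIGNED).all():
        warnings.warn("all genes unassigned (grey); no module met the size "
                      "threshold", stacklevel=2)

    labels = _merge_by_eigengene(expr, labels, config.merge_threshold)

    conn = connectivity(adj, labels)
    conn.insert(0, "module", labels)
    return conn


def _merge_by_eigengene(expr: pd.DataFrame, labels: pd.Series,
                        threshold: float) -> pd.Series:
    """Iteratively merge the most correlated eigengene pair above threshold."""
    labels = labels.copy()
    while True:
        mods = [m for m in labels.unique() if m != UNASSIGNED]
        if len(mods) < 2:
            return labels
        egs = {m: _eigengene(expr.loc[labels[labels == m].index].to_numpy())[0]
               for m in mods}
        best, best_r = None, threshold
        for i, m1 in enumerate(mods):
            for m2 in mods[i + 1:]:
                r = float(np.corrcoef(egs[m1], egs[m2])[0, 1])
                if r > best_r:
                    best, best_r = (m1, m2), r
        if best is None:
            return labels
        m1, m2 = best
        # absorb the smaller module into the larger
        if (labels == m2).sum() > (labels == m1).sum():
            m1, m2 = m2, m1
        labels[labels == m2] = m1


def eigengenes(expr: pd.DataFrame, labels: pd.Series) -> tuple[pd.DataFrame, pd.Series]:
    """Module eigengenes (first PCs), modules x samples.

    Returns the eigengene matrix and the per-module variance-explained
    fractions.  The grey (unassigned) module gets no eigengene.
    """
    mods = [m for m in pd.unique(labels) if m != UNASSIGNED]
    rows, varexp = {}, {}
    for m in mods:
        sub = expr.loc[labels[labels == m].index]
        if sub.shape[0] < 2:
            warnings.warn(f"module {m} has < 2 genes; skipped", stacklevel=2)
            continue
        eg, ve = _eigengene(sub.to_numpy(dtype=float))
        rows[m] = eg
        varexp[m] = ve
    em = pd.DataFrame(rows, index=expr.columns).T
    return em, pd.Series(varexp, name="variance_explained")


def module_trait_correlation(eigengene_matrix: pd.DataFrame,
                             traits: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of each module eigengene with each trait.

    ``traits`` is samples x traits, numerically encoded (e.g. stage age and
    a 0/1 population indicator).  P-values are the student asymptotic
    t = r*sqrt(n-2)/sqrt(1-r^2) with df = n - 2.  Significance stars:
    * P < 0.05, ** P < 0.005, *** P < 1e-5.
    """
    n = eigengene_matrix.shape[1]
    if n < 3:
        raise ValueError("need >= 3 samples")
    traits = traits.loc[eigengene_matrix.columns]
    rows = []
    for m in eigengene_matrix.index:
        eg = eigengene_matrix.loc[m].to_numpy(dtype=float)
        for t in traits.columns:
            tv = traits[t].to_numpy(dtype=float)
            if np.std(tv) == 0:
                raise ValueError(f"trait '{t}' is constant")
            r = float(np.corrcoef(eg, tv)[0, 1])
            r = float(np.clip(r, -1.0, 1.0))
            if abs(r) == 1.0:
                p = 0.0
            else:
                tstat = r * np.sqrt(n - 2) / np.sqrt(1.0 - r ** 2)
                p = float(2.0 * stats.t.sf(abs(tstat), n - 2))
            stars = "***" if p < 1e-5 else "**" if p < 0.005 else "*" if p < 0.05 else ""
            rows.append({"module": m, "trait": t, "r": r, "pvalue": p,
                         "stars": stars})
    return pd.DataFrame(rows)


def connectivity(adj: pd.DataFrame, labels: pd.Series,
                 n_hubs: int = 5) -> pd.DataFrame:
    """Total and within-module connectivity plus hub flags.

    kTotal_i = sum of adjacency to all other genes; kWithin_i = the same
    restricted to the gene's module (0 for grey).  Hubs are the ``n_hubs``
    genes with highest kWithin in each non-grey module, ties broken by
    gene ID.
    """
    A = adj.to_numpy(dtype=float).copy()
    np.fill_diagonal(A, 0.0)
    genes = adj.index
    labels = labels.loc[genes]
    k_total = A.sum(axis=1)
    k_within = np.zeros_like(k_total)
    for m in labels.unique():
        idx = np.flatnonzero((labels == m).to_numpy())
        if m == UNASSIGNED:
            continue
        sub = A[np.ix_(idx, idx)]
        k_within[idx] = sub.sum(axis=1)
    out = pd.DataFrame({"kTotal": k_total, "kWithin": k_within}, index=genes)
    out["hub"] = False
    for m in labels.unique():
        if m == UNASSIGNED:
            continue
        members = out[labels == m].sort_values(
            ["kWithin"], ascending=False, kind="mergesort"
        )
        # stable sort + index tiebreak: sort by (-kWithin, gene id)
        members = members.iloc[
            np.lexsort((members.index.to_numpy(), -members["kWithin"].to_numpy()))
        ]
        out.loc[members.index[:n_hubs], "hub"] = True
    return out
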