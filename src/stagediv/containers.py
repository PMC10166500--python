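"""Core data containers and tabular I/O.

The central object is :class:`CountMatrix`: an integer gene x sample count
table together with per-sample metadata (population, developmental stage,
replicate) and per-gene metadata (biotype, chromosome arm, genomic span,
effective length).  All downstream stages — filtering, normalisation,
differential expression, co-expression networks — consume this object.

Tables are exchanged as plain TSV: a counts table (genes x samples, header
row of sample IDs), a sample sheet and a gene sheet.  Columns are documented
in :func:`read_counts`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CountMatrix", "read_counts", "write_counts"]

REQUIRED_SAMPLE_COLUMNS = ("sample", "population", "stage", "replicate")
REQUIRED_GENE_COLUMNS = ("gene", "biotype")
OPTIONAL_GENE_COLUMNS = ("arm", "start", "end", "length")

BIOTYPES = ("protein_coding", "lncRNA", "other_nc")


class CountMatrixError(ValueError):
    """Raised when count/metadata tables violate the container contract."""


@dataclass
class CountMatrix:
    """Gene x sample read counts with sample and gene annotations.

    Parameters
    ----------
    counts
        Non-negative integer DataFrame, index = gene IDs, columns = sample
        IDs.
    sample_meta
        One row per sample (index = sample ID) with at least ``population``
        and ``stage`` columns; ``replicate`` identifies the biological
        replicate or strain.
    gene_meta
        One row per gene (index = gene ID).  ``biotype`` is one of
        ``protein_coding`` / ``lncRNA`` / ``other_nc``; ``arm``, ``start``,
        ``end`` give the 1-based inclusive genomic span and ``length`` the
        effective length in bases used for TPM.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    gene_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- contract ----------------------------------------------------------
    def validate(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise CountMatrixError(f"duplicate gene IDs in counts: {dups[:5]}")
        if c.columns.has_duplicates:
            raise CountMatrixError("duplicate sample IDs in counts")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise CountMatrixError("counts must be numeric")
        if (arr < 0).any():
            raise CountMatrixError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise CountMatrixError("counts must be integers")

        missing = set(c.columns) - set(self.sample_meta.index)
        if missing:
            raise CountMatrixError(
                f"{len(missing)} sample(s) in counts absent from sample sheet: "
                f"{sorted(missing)[:5]}"
            )
        for col in ("population", "stage"):
            if col not in self.sample_meta.columns:
                raise CountMatrixError(f"sample sheet lacks '{col}' column")
            if self.sample_meta.loc[list(c.columns), col].isna().any():
                raise CountMatrixError(f"sample sheet has missing '{col}' labels")

        missing_g = set(c.index) - set(self.gene_meta.index)
        if missing_g:
            raise CountMatrixError(
                f"{len(missing_g)} gene(s) in counts absent from gene sheet: "
                f"{sorted(missing_g)[:5]}"
            )
        # align metadata to the count table order
        self.sample_meta = self.sample_meta.loc[list(c.columns)]
        self.gene_meta = self.gene_meta.loc[list(c.index)]

    # -- convenience -------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def groups(self, by: tuple[str, ...] = ("population", "stage")) -> pd.Series:
        """Per-sample group label built from sample-sheet columns.

        Default is the population x stage cell, the six-level grouping used
        for one-factor differential expression.
        """
        parts = [self.sample_meta[b].astype(str) for b in by]
        out = parts[0]
        for p in parts[1:]:
            out = out + "_" + p
        out.name = "group"
        return out

    def subset_genes(self, genes) -> "CountMatrix":
        genes = pd.Index(genes)
        return CountMatrix(
            counts=self.counts.loc[genes].copy(),
            sample_meta=self.sample_meta.copy(),
            gene_meta=self.gene_meta.loc[genes].copy(),
        )

    def subset_samples(self, samples) -> "CountMatrix":
        samples = pd.Index(samples)
        return CountMatrix(
            counts=self.counts[samples].copy(),
            sample_meta=self.sample_meta.loc[samples].copy(),
            gene_meta=self.gene_meta.copy(),
        )

    def lengths(self) -> pd.Series:
        """Effective gene lengths; raises if absent or non-positive."""
        if "length" not in self.gene_meta.columns:
            raise CountMatrixError("gene sheet has no 'length' column; TPM unavailable")
        ln = pd.to_numeric(self.gene_meta["length"], errors="coerce")
        if ln.isna().any() or (ln <= 0).any():
            raise CountMatrixError("gene lengths must be positive for TPM")
        return ln.astype(float)


def _read_tsv(path, required, what: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise CountMatrixError(f"cannot parse {what} table {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CountMatrixError(f"{what} table {path} lacks column(s): {missing}")
    return df


def read_counts(counts_path, sample_sheet, gene_sheet) -> CountMatrix:
    """Read a counts TSV plus sample and gene sheets into a CountMatrix.

    ``counts_path``: first column = gene ID, remaining columns = one per
    sample (header row of sample IDs).  ``sample_sheet`` columns: sample,
    population, stage, replicate.  ``gene_sheet`` columns: gene, biotype and
    optionally arm, start, end, length.  A missing ``length`` column is
    tolerated here; TPM computation refuses later.
    """
    counts = pd.read_csv(counts_path, sep="\t", comment="#", index_col=0)
    if counts.index.has_duplicates:
        raise CountMatrixError(f"duplicate gene IDs in {counts_path}")
    for col in counts.columns:
        vals = pd.to_numeric(counts[col], errors="coerce")
        if vals.isna().any():
            bad = counts.index[vals.isna()][0]
            raise CountMatrixError(
                f"non-numeric count in {counts_path}, sample {col}, gene {bad}"
            )
        counts[col] = vals

    smeta = _read_tsv(sample_sheet, REQUIRED_SAMPLE_COLUMNS[:3], "sample")
    smeta = smeta.set_index("sample")
    if smeta.index.has_duplicates:
        raise CountMatrixError(f"duplicate sample IDs in {sample_sheet}")

    gmeta = _read_tsv(gene_sheet, REQUIRED_GENE_COLUMNS, "gene")
    gmeta = gmeta.set_index("gene")
    if gmeta.index.has_duplicates:
        raise CountMatrixError(f"duplicate gene IDs in {gene_sheet}")

    return CountMatrix(counts=counts, sample_meta=smeta, gene_meta=gmeta)


def write_counts(cm: CountMatrix, counts_path, sample_sheet=None, gene_sheet=None,
                 header_comment: str | None = None) -> None:
    """Write a CountMatrix back to TSV (counts + optional sheets)."""
    counts_path = Path(counts_path)
    with open(counts_path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        cm.counts.to_csv(fh, sep="\t", index_label="gene")
    if sample_sheet is not None:
        cm.sample_meta.to_csv(sample_sheet, sep="\t", index_label="sample")
    if gene_sheet is not None:
        cm.gene_meta.to_csv(gene_sheet, sep="\t", index_label="gene")
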