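"""Multi-batch expression matrices: loading, merging, QC filtering, diagnostics.

The central container is :class:`ExpressionMatrix`, a genes x samples frame of
log-scale expression values (NaN marks missing cells) together with one batch
label per sample recording the experiment of origin.  Inputs are assumed to be
pre-normalized; this module never rescales values, it only inspects and
filters them.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "BatchDiagnostics",
    "load_expression",
    "merge_expression",
    "qc_filter",
    "batch_diagnostics",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples log-expression with per-sample batch labels.

    ``values`` is a float DataFrame indexed by gene ID with sample columns;
    missing cells are NaN.  ``batches`` maps every sample ID to a categorical
    batch label (experiment of origin).
    """

    values: pd.DataFrame
    batches: pd.Series

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.values.index.has_duplicates:
            dups = sorted(self.values.index[self.values.index.duplicated()].unique())
            raise ValueError(f"duplicate gene IDs: {dups}")
        if self.values.columns.has_duplicates:
            dups = sorted(self.values.columns[self.values.columns.duplicated()].unique())
            raise ValueError(f"duplicate sample IDs: {dups}")
        missing = [s for s in self.values.columns if s not in self.batches.index]
        if missing:
            raise ValueError(f"samples without batch label: {missing}")
        self.batches = self.batches.reindex(self.values.columns)
        finite = np.isfinite(self.values.to_numpy())
        if not (finite | self.mask).all():
            raise ValueError("non-missing values must be finite")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def mask(self) -> np.ndarray:
        """Boolean genes x samples array, True where a value is missing."""
        return self.values.isna().to_numpy()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_tsv(self, path: str | Path, manifest_path: str | Path | None = None) -> None:
        """Write the expression TSV (and optionally the sample manifest)."""
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", na_rep="NA")
        if manifest_path is not None:
            man = self.batches.rename("batch").rename_axis("sample_id")
            man.to_csv(manifest_path, sep="\t")


@dataclass
class BatchDiagnostics:
    """Per-batch five-number summaries plus a 2-D sample embedding."""

    summaries: pd.DataFrame  # index batch, columns min/q1/median/q3/max
    coordinates: pd.DataFrame  # index sample, columns coord1/coord2
    eigenvalues: np.ndarray  # non-increasing

    def write(self, summary_path: str | Path, coords_path: str | Path) -> None:
        self.summaries.rename_axis("batch").to_csv(summary_path, sep="\t")
        self.coordinates.rename_axis("sample").to_csv(coords_path, sep="\t")


def _check_rectangular(lines: list[str]) -> None:
    if not lines:
        raise ValueError("empty expression file")
    width = len(lines[0].rstrip("\n").split("\t"))
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        n = len(line.rstrip("\n").split("\t"))
        if n != width:
            raise ValueError(
                f"ragged row at line {lineno}: expected {width} fields, found {n}"
            )


def load_expression(path: str | Path, manifest_path: str | Path | None = None) -> ExpressionMatrix:
    """Read a tab-separated expression matrix (first column gene IDs).

    Empty cells and the token ``NA`` become missing values.  Samples with no
    manifest entry are assigned batch ``"unknown"``.
    """
    text = Path(path).read_text(encoding="utf-8")
    lines = text.splitlines(keepends=True)
    _check_rectangular(lines)
    df = pd.read_csv(io.StringIO(text), sep="\t", index_col=0, na_values=["NA", ""])
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicate gene IDs: {dups}")
    if manifest_path is not None:
        man = pd.read_csv(manifest_path, sep="\t", index_col=0)
        batch_col = man.columns[0]
        batches = man[batch_col].astype(str).reindex(df.columns).fillna("unknown")
    else:
        batches = pd.Series("unknown", index=df.columns)
    return ExpressionMatrix(values=df, batches=batches)


def merge_expression(matrices: Sequence[ExpressionMatrix], mode: str = "union") -> ExpressionMatrix:
    """Merge batches into one frame; sample IDs are prefixed with their batch.

    ``intersect`` keeps genes present in every input; ``union`` keeps all
    genes, masking cells where a gene is absent from a batch.  Column order
    follows input order.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    if mode not in ("intersect", "union"):
        raise ValueError(f"unknown merge mode: {mode!r}")
    frames, batch_parts = [], []
    seen: set[str] = set()
    for m in matrices:
        vals = m.values.copy()
        new_cols = [f"{m.batches[s]}:{s}" for s in vals.columns]
        clash = [c for c in new_cols if c in seen]
        if clash:
            raise ValueError(f"colliding sample IDs after batch prefixing: {clash}")
        seen.update(new_cols)
        vals.columns = new_cols
        frames.append(vals)
        batch_parts.append(pd.Series(list(m.batches.values), index=new_cols))
    if mode == "intersect":
        genes: pd.Index = frames[0].index
        for f in frames[1:]:
            genes = genes.intersection(f.index)
        genes = pd.Index(sorted(genes))
    else:
        all_genes: list[str] = []
        seen_g: set[str] = set()
        for f in frames:
            for g in f.index:
                if g not in seen_g:
                    seen_g.add(g)
                    all_genes.append(g)
        genes = pd.Index(all_genes)
    merged = pd.concat([f.reindex(genes) for f in frames], axis=1)
    return ExpressionMatrix(values=merged, batches=pd.concat(batch_parts))


def qc_filter(
    m: ExpressionMatrix,
    max_missing_frac: float = 0.5,
    impute: bool = True,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Drop genes with too much missing data or zero variance; optionally impute.

    Returns the filtered matrix and a removal report (gene_id, reason).
    Remaining missing cells are filled with the gene's median when ``impute``.
    """
    if not 0 <= max_missing_frac < 1:
        raise ValueError("max_missing_frac must be in [0, 1)")
    vals = m.values
    miss_frac = vals.isna().mean(axis=1)
    variance = vals.var(axis=1, ddof=0)
    removals: list[tuple[str, str]] = []
    keep: list[str] = []
    for g in vals.index:
        if miss_frac[g] > max_missing_frac:
            removals.append((g, f"missing fraction {miss_frac[g]:.3f} > {max_missing_frac}"))
        elif not variance[g] > 0:
            removals.append((g, "zero variance"))
        else:
            keep.append(g)
    if not keep:
        raise ValueError("qc_filter removed every gene")
    out = vals.loc[keep].copy()
    if impute:
        med = out.median(axis=1)
        out = out.apply(lambda row: row.fillna(med[row.name]), axis=1)
    report = pd.DataFrame(removals, columns=["gene_id", "reason"])
    return ExpressionMatrix(values=out, batches=m.batches.copy()), report


def _five_number(x: np.ndarray) -> tuple[float, float, float, float, float]:
    """Five-number summary with the midpoint (median-of-halves) quartiles.

    The data are split at the median, excluding the median itself for odd
    lengths; Q1/Q3 are the medians of the lower/upper halves.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    med = float(np.median(x))
    half = n // 2
    lower, upper = x[:half], x[n - half:]
    q1 = float(np.median(lower)) if lower.size else med
    q3 = float(np.median(upper)) if upper.size else med
    return float(x[0]), q1, med, q3, float(x[-1])


def classical_mds(distances: np.ndarray, n_components: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Classical (principal-coordinates) MDS of a distance matrix.

    Double-centers the squared distances, eigendecomposes, and returns
    coordinates scaled by the square roots of the top eigenvalues together
    with the full eigenvalue spectrum in non-increasing order.  Negative
    eigenvalues contribute zero coordinates.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    b = (b + b.T) / 2
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    coords = np.zeros((n, n_components))
    for k in range(min(n_components, n)):
        if eigval[k] > 0:
            coords[:, k] = eigvec[:, k] * np.sqrt(eigval[k])
    return coords, eigval


def batch_diagnostics(m: ExpressionMatrix) -> BatchDiagnostics:
    """Boxplot-style batch summaries and a 2-D principal-coordinate embedding.

    Requires complete data (run after :func:`qc_filter`) and at least three
    samples.  The embedding uses classical metric MDS of the Euclidean
    inter-sample distances.
    """
    if m.n_samples < 3:
        raise ValueError("batch_diagnostics needs at least 3 samples")
    if m.mask.any():
        raise ValueError("batch_diagnostics requires complete data; run qc_filter first")
    rows = {}
    for batch, samples in m.batches.groupby(m.batches).groups.items():
        pooled = m.values[list(samples)].to_numpy().ravel()
        rows[batch] = _five_number(pooled)
    summaries = pd.DataFrame.from_dict(
        rows, orient="index", columns=["min", "q1", "median", "q3", "max"]
    ).sort_index()
    x = m.values.to_numpy().T  # samples x genes
    dist = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
    coords, eigval = classical_mds(dist, n_components=2)
    coordinates = pd.DataFrame(coords, index=m.sample_ids, columns=["coord1", "coord2"])
    return BatchDiagnostics(summaries=summaries, coordinates=coordinates, eigenvalues=eigval)
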