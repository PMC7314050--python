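"""Biweight midcorrelation and the unsigned similarity matrix.

bicor is a robust alternative to Pearson correlation: each vector is centered
at its median and observations are down-weighted by Tukey's biweight as a
function of their distance from the median in MAD units, so isolated gross
outliers contribute almost nothing.  The co-expression similarity is the
absolute correlation, S_ij = |cor(i, j)|, which treats positively and
negatively co-regulated pairs alike (an unsigned network).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .expression import ExpressionMatrix

__all__ = ["bicor", "bicor_matrix", "similarity_matrix", "SimilarityMatrix"]

# Observations beyond 9 MADs from the median get zero weight; the standard
# tuning constant for the biweight midcorrelation.  MAD carries no
# consistency scaling here.
_MAD_TUNING = 9.0


def _biweight_transform(x: np.ndarray) -> tuple[np.ndarray, bool]:
    """Median-center and biweight-weight one vector.

    Returns the weighted centered vector and whether the MAD-zero fallback
    (mean/SD Pearson-style centering) was used.
    """
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        sd = x.std(ddof=0)
        if sd == 0:
            raise ValueError("undefined correlation: constant vector")
        return x - x.mean(), True
    u = (x - med) / (_MAD_TUNING * mad)
    w = (1 - u**2) ** 2 * (np.abs(u) < 1)
    return (x - med) * w, False


def bicor(x: np.ndarray, y: np.ndarray) -> float:
    """Biweight midcorrelation of two equal-length vectors, in [-1, 1].

    Vectors with zero MAD fall back to mean/SD (Pearson-style) centering;
    constant vectors raise ``ValueError``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 4:
        raise ValueError("bicor needs at least 4 observations")
    xt, _ = _biweight_transform(x)
    yt, _ = _biweight_transform(y)
    denom = np.sqrt((xt**2).sum() * (yt**2).sum())
    if denom == 0:
        raise ValueError("undefined correlation: all weights vanished")
    return float(np.clip((xt * yt).sum() / denom, -1.0, 1.0))


def bicor_matrix(x: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Row-wise biweight midcorrelation matrix of ``x`` (rows = variables).

    Each row is transformed exactly as in the scalar :func:`bicor`, then
    normalized to unit norm so the correlation matrix is a single symmetric
    cross-product.  Returns the matrix and the indices of rows that used the
    MAD-zero fallback.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    xt = np.empty_like(x)
    fallbacks: list[int] = []
    for i in range(n):
        xt[i], fb = _biweight_transform(x[i])
        if fb:
            fallbacks.append(i)
    norms = np.sqrt((xt**2).sum(axis=1))
    if (norms == 0).any():
        bad = list(np.where(norms == 0)[0])
        raise ValueError(f"undefined correlation for rows {bad}")
    xt /= norms[:, None]
    c = xt @ xt.T
    c = np.clip((c + c.T) / 2, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return c, fallbacks


def _pearson_matrix(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=1, ddof=0)
    if (sd == 0).any():
        bad = list(np.where(sd == 0)[0])
        raise ValueError(f"undefined correlation for rows {bad}")
    c = np.corrcoef(x)
    c = np.clip((c + c.T) / 2, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return c


@dataclass
class SimilarityMatrix:
    """Symmetric |correlation| matrix over genes, entries in [0, 1]."""

    gene_ids: list[str]
    values: np.ndarray
    method: str

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.gene_ids):
            raise ValueError("similarity matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if (v < 0).any() or (v > 1).any():
            raise ValueError("similarity entries must lie in [0, 1]")


def similarity_matrix(m: ExpressionMatrix, method: str = "bicor") -> SimilarityMatrix:
    """Unsigned similarity S_ij = |cor(gene_i, gene_j)| over all gene pairs.

    Requires complete data with at least 4 samples and no constant genes
    (``qc_filter`` guarantees both).  ``method`` selects bicor (default,
    robust) or pearson.
    """
    if m.n_samples < 4:
        raise ValueError("similarity_matrix needs at least 4 samples")
    if m.mask.any():
        raise ValueError("similarity_matrix requires complete data")
    x = m.values.to_numpy()
    constant = [g for g, sd in zip(m.gene_ids, x.std(axis=1, ddof=0)) if sd == 0]
    if constant:
        raise ValueError(f"constant genes present (run qc_filter): {constant}")
    if method == "bicor":
        c, _ = bicor_matrix(x)
    elif method == "pearson":
        c = _pearson_matrix(x)
    else:
        raise ValueError(f"unknown correlation method: {method!r}")
    s = np.abs(c)
    np.fill_diagonal(s, 1.0)
    return SimilarityMatrix(gene_ids=m.gene_ids, values=s, method=method)
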