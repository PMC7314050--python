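"""Adjacency, scale-free topology fit, soft-threshold choice, topological overlap.

The weighted network raises the unsigned similarity elementwise to a soft
threshold beta, AdjMat_ij = S_ij^beta, chosen as the smallest power at which
the degree distribution is approximately scale free (signed fit index
R^2 >= 0.9 by default).  The topological overlap matrix (TOM) then augments
direct adjacency with shared-neighbor agreement; 1 - TOM is the clustering
dissimilarity used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .correlation import SimilarityMatrix

__all__ = [
    "adjacency",
    "connectivity",
    "scale_free_fit",
    "scale_free_fit_from_degrees",
    "pick_soft_threshold",
    "topological_overlap",
    "SoftThresholdScan",
    "GeneNetwork",
    "build_network",
]


def adjacency(s: SimilarityMatrix | np.ndarray, beta: int) -> np.ndarray:
    """Soft-threshold adjacency: elementwise power of the similarity.

    Diagonal is fixed at 1 but excluded from all connectivity sums.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    vals = s.values if isinstance(s, SimilarityMatrix) else np.asarray(s, dtype=float)
    a = vals**beta
    np.fill_diagonal(a, 1.0)
    return a


def connectivity(adj: np.ndarray) -> np.ndarray:
    """Node degree k_i = sum of off-diagonal adjacency in row i."""
    return adj.sum(axis=1) - np.diag(adj)


def scale_free_fit(adj: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free topology fit index and log-log regression slope.

    Connectivities are binned into ``n_bins`` equal-width bins; per non-empty
    bin the mean connectivity and the fraction of genes are computed, and
    log10(fraction) is regressed on log10(mean k).  The signed index is
    -sign(slope) * R^2, so a decreasing (power-law-like) degree profile
    scores positively.
    """
    return scale_free_fit_from_degrees(connectivity(adj), n_bins=n_bins)


def scale_free_fit_from_degrees(degrees: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed fit index for an explicit connectivity vector (see
    :func:`scale_free_fit`)."""
    k = np.asarray(degrees, dtype=float)
    k = k[k > 0]
    if k.size < n_bins:
        raise ValueError("insufficient degree spread: too few positive connectivities")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    mean_k, frac = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            mean_k.append(k[sel].mean())
            frac.append(sel.mean())
    if len(mean_k) < 3:
        raise ValueError("insufficient degree spread: fewer than 3 non-empty bins")
    res = stats.linregress(np.log10(mean_k), np.log10(frac))
    r2 = res.rvalue**2
    signed = -np.sign(res.slope) * r2
    return float(signed), float(res.slope)


@dataclass
class SoftThresholdScan:
    """Per-beta scan table plus the selection outcome."""

    table: pd.DataFrame  # beta, r2_signed, slope, mean_k, median_k, max_k
    chosen_beta: int
    target_reached: bool  # False => argmax-R^2 fallback was used

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def pick_soft_threshold(
    s: SimilarityMatrix,
    beta_grid: list[int] | range = range(1, 21),
    r2_target: float = 0.9,
    n_bins: int = 10,
) -> SoftThresholdScan:
    """Choose the smallest beta whose signed fit index reaches ``r2_target``.

    If no beta on the grid qualifies, the beta maximizing the signed index is
    returned with ``target_reached`` False (a machine-readable warning).
    """
    betas = list(beta_grid)
    if not betas or sorted(betas) != betas:
        raise ValueError("beta_grid must be non-empty and ascending")
    rows = []
    for beta in betas:
        a = adjacency(s, beta)
        k = connectivity(a)
        try:
            r2, slope = scale_free_fit(a, n_bins=n_bins)
        except ValueError:
            r2, slope = np.nan, np.nan
        rows.append(
            {
                "beta": beta,
                "r2_signed": r2,
                "slope": slope,
                "mean_k": k.mean(),
                "median_k": float(np.median(k)),
                "max_k": k.max(),
            }
        )
    table = pd.DataFrame(rows)
    ok = table[table["r2_signed"] >= r2_target]
    if len(ok):
        chosen = int(ok.iloc[0]["beta"])
        reached = True
    else:
        r2s = table["r2_signed"]
        chosen = int(table.iloc[int(np.nanargmax(r2s)) if r2s.notna().any() else 0]["beta"])
        reached = False
    return SoftThresholdScan(table=table, chosen_beta=chosen, target_reached=reached)


def topological_overlap(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a symmetric adjacency in [0, 1].

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) where l_ij counts the
    shared weighted neighbors sum_{u != i,j} a_iu a_uj; the diagonal is 1.
    """
    a = np.asarray(adj, dtype=float)
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    l = a0 @ a0  # (A0^2)_ij = sum_{u != i,j} a_iu a_uj when a_ii = 0
    k = a0.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - a0
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + a0) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    tom = np.clip((tom + tom.T) / 2, 0.0, 1.0)
    np.fill_diagonal(tom, 1.0)
    return tom


@dataclass
class GeneNetwork:
    """Similarity, adjacency and TOM for one gene set at a chosen beta."""

    gene_ids: list[str]
    similarity: np.ndarray
    adjacency: np.ndarray
    tom: np.ndarray
    beta: int
    scan: SoftThresholdScan | None = None

    @property
    def dissimilarity(self) -> np.ndarray:
        d = 1.0 - self.tom
        np.fill_diagonal(d, 0.0)
        return d

    def tom_of(self, gene: str) -> pd.Series:
        if gene not in self.gene_ids:
            raise KeyError(f"unknown gene: {gene}")
        i = self.gene_ids.index(gene)
        return pd.Series(self.tom[i], index=self.gene_ids)


def build_network(
    s: SimilarityMatrix,
    beta: int | None = None,
    beta_grid: list[int] | range = range(1, 21),
    r2_target: float = 0.9,
) -> GeneNetwork:
    """Full network construction: soft-threshold scan (unless beta is fixed),
    adjacency and TOM."""
    scan = pick_soft_threshold(s, beta_grid=beta_grid, r2_target=r2_target)
    use_beta = beta if beta is not None else scan.chosen_beta
    a = adjacency(s, use_beta)
    tom = topological_overlap(a)
    return GeneNetwork(
        gene_ids=s.gene_ids, similarity=s.values, adjacency=a, tom=tom, beta=use_beta, scan=scan
    )
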