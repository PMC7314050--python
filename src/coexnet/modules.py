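"""Module detection: hierarchical clustering of the TOM dissimilarity,
dynamic hybrid tree cutting, module eigengenes, eigengene-based merging,
color naming and the inter-module graph.

A module is a dendrogram branch of genes with mutually high topological
overlap.  Its eigengene (ME) is the first principal component of the
module's standardized expression across samples, a per-sample summary
profile; modules whose eigengenes correlate above 1 - ``cut_height``
(0.8 at the default height of 0.2) are fused.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .expression import ExpressionMatrix

__all__ = [
    "Dendrogram",
    "ModulePartition",
    "ModuleEigengenes",
    "cluster_genes",
    "cut_dynamic",
    "module_eigengenes",
    "merge_modules",
    "assign_colors",
    "module_graph",
    "module_membership",
    "MODULE_COLORS",
]

# Canonical module color sequence, assigned to modules by decreasing size.
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
]

UNASSIGNED = 0  # the "grey" label


@dataclass
class Dendrogram:
    """Average-linkage merge tree over genes."""

    linkage: np.ndarray  # scipy linkage matrix, (n-1) x 4
    gene_ids: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> np.ndarray:
        return hierarchy.leaves_list(self.linkage)


@dataclass
class ModulePartition:
    """Gene -> module labels; label 0 is unassigned ("grey")."""

    gene_ids: list[str]
    labels: np.ndarray  # int per gene
    min_module_size: int
    colors: dict[int, str] = field(default_factory=dict)
    merge_history: list[tuple[tuple[int, ...], int]] = field(default_factory=list)

    def members(self, label: int) -> list[str]:
        return [g for g, l in zip(self.gene_ids, self.labels) if l == label]

    @property
    def module_labels(self) -> list[int]:
        return sorted(l for l in set(self.labels.tolist()) if l != UNASSIGNED)

    @property
    def module_sizes(self) -> dict[int, int]:
        return {l: int((self.labels == l).sum()) for l in self.module_labels}

    @property
    def n_modules(self) -> int:
        return len(self.module_labels)

    def color_of(self, label: int) -> str:
        if label == UNASSIGNED:
            return "grey"
        return self.colors.get(label, f"module_{label}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "label": self.labels,
                "color": [self.color_of(l) for l in self.labels],
            }
        )


def cluster_genes(dissimilarity: np.ndarray, gene_ids: list[str] | None = None) -> Dendrogram:
    """Average-linkage hierarchical clustering of a TOM dissimilarity matrix."""
    d = np.asarray(dissimilarity, dtype=float)
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("dissimilarity must be symmetric")
    if (np.diag(d) != 0).any():
        raise ValueError("dissimilarity must have zero diagonal")
    if (d < 0).any() or (d > 1).any():
        raise ValueError("dissimilarity entries must lie in [0, 1]")
    n = d.shape[0]
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n)]
    z = hierarchy.linkage(squareform(d, checks=False), method="average")
    return Dendrogram(linkage=z, gene_ids=list(gene_ids))


def _branch_split(
    node: hierarchy.ClusterNode,
    min_size: int,
    gap_min: float,
    clusters: list[list[int]],
    loose: list[int],
) -> None:
    """Recursively split a below-cut branch at merges with a large height gap.

    A node is split when its merge height exceeds the taller child by at
    least ``gap_min`` and the larger child can still form a module; leaves on
    a sub-minimum side are released as unassigned candidates for the PAM
    stage.  Without a qualifying gap the whole branch becomes one cluster.
    """
    if node.count < min_size:
        loose.extend(node.pre_order())
        return
    if node.is_leaf():
        loose.append(node.id)
        return
    left, right = node.get_left(), node.get_right()
    gap = node.dist - max(left.dist, right.dist)
    big, small = (left, right) if left.count >= right.count else (right, left)
    if gap > 0 and gap >= gap_min and big.count >= min_size:
        if small.count >= min_size:
            _branch_split(left, min_size, gap_min, clusters, loose)
            _branch_split(right, min_size, gap_min, clusters, loose)
        else:
            # trim stray leaves, keep descending into the main branch
            loose.extend(small.pre_order())
            _branch_split(big, min_size, gap_min, clusters, loose)
    else:
        clusters.append(node.pre_order())


def cut_dynamic(
    dendrogram: Dendrogram,
    dissimilarity: np.ndarray,
    min_cluster_size: int = 20,
    deep_split: int = 2,
    pam_stage: bool = True,
    max_cut_height: float = 0.99,
    method: str = "hybrid",
    cut_height: float | None = None,
) -> ModulePartition:
    """Cut the dendrogram into modules with a dynamic hybrid two-stage scheme.

    Stage 1 walks the merge tree below the cut height (``max_cut_height`` as
    a fraction of the dendrogram's height range; merges above it can never
    stay joined)
    and splits branches at merges whose height gap relative to their
    children is large; ``deep_split`` (0..4) controls how small a gap still
    splits, so larger values produce more, smaller modules.  Stage 2 (``pam_stage``) assigns each unlabeled gene to
    the cluster with the smallest average dissimilarity, provided that
    distance is below the cluster's internal dissimilarity radius (the most
    peripheral member's average distance to the rest of the cluster).

    ``method="height"`` is a plain fixed-height cut (at ``cut_height``,
    absolute units) followed by the minimum-size filter — a debugging
    fallback with no stage 2.
    """
    if min_cluster_size < 2:
        raise ValueError("min_cluster_size must be >= 2")
    if not 0 <= deep_split <= 4:
        raise ValueError("deep_split must be in 0..4")
    z = dendrogram.linkage
    n = len(dendrogram.gene_ids)
    d = np.asarray(dissimilarity, dtype=float)
    if d.shape != (n, n):
        raise ValueError("dissimilarity does not match the dendrogram's genes")
    heights = z[:, 2]
    hmin, hmax = float(heights.min()), float(heights.max())
    hrange = hmax - hmin

    labels = np.zeros(n, dtype=int)
    if method == "height":
        t = cut_height if cut_height is not None else hmin + max_cut_height * hrange
        flat = hierarchy.fcluster(z, t=t, criterion="distance")
        next_label = 1
        for c in np.unique(flat):
            members = np.where(flat == c)[0]
            if members.size >= min_cluster_size:
                labels[members] = next_label
                next_label += 1
        return ModulePartition(
            gene_ids=dendrogram.gene_ids, labels=labels, min_module_size=min_cluster_size
        )
    if method != "hybrid":
        raise ValueError(f"unknown cut method: {method!r}")

    # relative to the observed height range: high-beta TOM dissimilarities
    # concentrate near 1, so an absolute cut would be meaningless
    cut = hmin + max_cut_height * hrange
    # a merge is forcibly split only when it is both above the linear cut
    # and carries essentially no topological overlap relative to the
    # tightest pair: soft thresholding compresses weak-but-real branch
    # overlaps (~1e-4 of the maximum) and pure-noise overlaps (<1e-6 of it)
    # onto the same linear scale near height 1, where only this ratio
    # separates them
    min_rel_overlap = 1e-5
    overlap_floor = min_rel_overlap * (1.0 - hmin)
    # deep_split 0 (conservative) .. 4 (aggressive): minimum merge gap
    # (relative to the observed height range) required to split a branch.
    gap_min = (0.25 - 0.05 * deep_split) * hrange

    root = hierarchy.to_tree(z)
    clusters: list[list[int]] = []
    loose: list[int] = []

    def descend(node: hierarchy.ClusterNode) -> None:
        if node.is_leaf():
            loose.append(node.id)
            return
        if node.dist > cut and (1.0 - node.dist) < overlap_floor:
            # merges above the cut with negligible overlap can never stay
            # joined
            descend(node.get_left())
            descend(node.get_right())
        else:
            _branch_split(node, min_cluster_size, gap_min, clusters, loose)

    descend(root)
    # deterministic labels: clusters ordered by smallest member index
    clusters.sort(key=lambda c: min(c))
    for lab, members in enumerate(clusters, start=1):
        labels[members] = lab

    if pam_stage and clusters:
        radii = {}
        for lab, members in enumerate(clusters, start=1):
            idx = np.array(members)
            if idx.size < 2:
                radii[lab] = 0.0
                continue
            sub = d[np.ix_(idx, idx)]
            # the cluster's radius: the most peripheral member's average
            # dissimilarity to the rest of the cluster
            radii[lab] = float((sub.sum(axis=1) / (idx.size - 1)).max())
        for g in loose:
            best_lab, best_d = None, np.inf
            for lab, members in enumerate(clusters, start=1):
                avg = float(d[g, np.array(members)].mean())
                if avg < best_d:
                    best_lab, best_d = lab, avg
            if best_lab is None:
                continue
            # soft-thresholded overlaps compress multiplicatively toward
            # dissimilarity 1, so acceptance is relative in overlap (1 - d)
            # units: the gene's mean overlap with the cluster must reach a
            # fixed fraction of the cluster's own peripheral overlap level;
            # pure-noise genes fall short of it by orders of magnitude
            if (1.0 - best_d) > 0.01 * (1.0 - radii[best_lab]):
                labels[g] = best_lab
    return ModulePartition(
        gene_ids=dendrogram.gene_ids, labels=labels, min_module_size=min_cluster_size
    )


@dataclass
class ModuleEigengenes:
    """Module x sample eigengene matrix (unit-norm rows) with variance explained."""

    values: pd.DataFrame  # index module label, columns samples
    variance_explained: dict[int, float]

    @property
    def module_labels(self) -> list[int]:
        return list(self.values.index)

    def to_tsv(self, path) -> None:
        self.values.rename_axis("module").to_csv(path, sep="\t")


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def module_eigengenes(m: ExpressionMatrix, partition: ModulePartition) -> ModuleEigengenes:
    """First principal component of each module's standardized expression.

    Eigengenes are unit-norm over samples and sign-aligned so that each
    correlates non-negatively with its module's mean standardized profile.
    A single-gene module returns that gene's standardized profile (variance
    explained 1) with a warning.
    """
    if m.mask.any():
        raise ValueError("module_eigengenes requires complete data")
    x = m.values.to_numpy()
    mes, ve = {}, {}
    for lab in partition.module_labels:
        idx = np.where(partition.labels == lab)[0]
        sub = _zscore_rows(x[idx])
        if idx.size == 1:
            warnings.warn(f"module {lab} has a single gene; its profile is the eigengene")
            v = sub[0] / np.linalg.norm(sub[0])
            mes[lab], ve[lab] = v, 1.0
            continue
        u, s, vt = np.linalg.svd(sub, full_matrices=False)
        v = vt[0]
        ve[lab] = float(s[0] ** 2 / (s**2).sum())
        mean_profile = sub.mean(axis=0)
        if np.dot(v, mean_profile) < 0:
            v = -v
        mes[lab] = v
    values = pd.DataFrame.from_dict(mes, orient="index", columns=m.sample_ids)
    return ModuleEigengenes(values=values, variance_explained=ve)


def _me_dissimilarity(me: ModuleEigengenes) -> np.ndarray:
    c = np.corrcoef(me.values.to_numpy())
    c = np.clip((c + c.T) / 2, -1.0, 1.0)
    d = 1.0 - c
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, None)


def merge_modules(
    m: ExpressionMatrix,
    partition: ModulePartition,
    me: ModuleEigengenes | None = None,
    cut_height: float = 0.2,
) -> tuple[ModulePartition, ModuleEigengenes]:
    """Fuse modules whose eigengenes are highly correlated.

    Eigengenes are clustered by average linkage on 1 - cor(ME_i, ME_j) and
    every group below ``cut_height`` is fused (at the default 0.2 this merges
    modules with ME correlation above 0.8, the merging rule of the method).
    The merged module keeps the label of its largest constituent; eigengenes
    are recomputed and the step repeats until no pair remains below the
    height.
    """
    if not 0 < cut_height < 1:
        raise ValueError("cut_height must be in (0, 1)")
    part = ModulePartition(
        gene_ids=partition.gene_ids,
        labels=partition.labels.copy(),
        min_module_size=partition.min_module_size,
        merge_history=list(partition.merge_history),
    )
    me = me if me is not None else module_eigengenes(m, part)
    while part.n_modules > 1:
        labs = me.module_labels
        d = _me_dissimilarity(me)
        if (d[np.triu_indices(len(labs), k=1)] >= cut_height).all():
            break
        z = hierarchy.linkage(squareform(d, checks=False), method="average")
        flat = hierarchy.fcluster(z, t=cut_height, criterion="distance")
        sizes = part.module_sizes
        merged_any = False
        for grp in np.unique(flat):
            group = [labs[i] for i in np.where(flat == grp)[0]]
            if len(group) < 2:
                continue
            keep = max(group, key=lambda l: (sizes[l], -l))
            for l in group:
                if l != keep:
                    part.labels[part.labels == l] = keep
            part.merge_history.append((tuple(sorted(group)), keep))
            merged_any = True
        if not merged_any:
            break
        me = module_eigengenes(m, part)
    return part, me


def assign_colors(partition: ModulePartition) -> ModulePartition:
    """Name modules from the canonical color sequence by decreasing size.

    Ties are broken by the lexicographically smaller member gene-ID set;
    overflow beyond the palette becomes ``module_N``.  Unassigned genes are
    always grey.
    """
    order = sorted(
        partition.module_labels,
        key=lambda l: (-int((partition.labels == l).sum()), sorted(partition.members(l))),
    )
    colors = {}
    for rank, lab in enumerate(order):
        colors[lab] = MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module_{rank + 1}"
    partition.colors = colors
    return partition


def module_graph(me: ModuleEigengenes, edge_threshold: float = 0.0, sizes: dict[int, int] | None = None):
    """Inter-module graph: edge (i, j) iff |cor(ME_i, ME_j)| >= threshold.

    Returns a networkx Graph with edge weights |cor| and optional node sizes.
    """
    import networkx as nx

    labs = me.module_labels
    if len(labs) < 2:
        raise ValueError("module_graph needs at least 2 modules")
    c = np.abs(np.corrcoef(me.values.to_numpy()))
    g = nx.Graph()
    for lab in labs:
        g.add_node(lab, size=(sizes or {}).get(lab, 0))
    for i in range(len(labs)):
        for j in range(i + 1, len(labs)):
            w = float(np.clip(c[i, j], 0.0, 1.0))
            if w >= edge_threshold:
                g.add_edge(labs[i], labs[j], weight=w)
    return g


def module_membership(m: ExpressionMatrix, me: ModuleEigengenes) -> pd.DataFrame:
    """Signed kME table: correlation of every gene with every module eigengene."""
    x = _zscore_rows(m.values.to_numpy())
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    e = me.values.to_numpy()
    e = e - e.mean(axis=1, keepdims=True)
    e /= np.linalg.norm(e, axis=1, keepdims=True)
    kme = np.clip(x @ e.T, -1.0, 1.0)
    return pd.DataFrame(kme, index=m.gene_ids, columns=me.module_labels)
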