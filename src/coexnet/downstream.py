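"""Downstream analysis: hub genes, hypergeometric module/gene-list
association, term enrichment, TF ranking, and guilt-by-association
annotation of uncharacterized hubs.

Hubs are the most intramodularly connected genes of each module, subject to
a minimum module membership (kME > 0.8).  Module association against
externally derived gene lists (e.g. stress DEGs/DEPs) uses the exact
hypergeometric tail; transcription factors are ranked by their robust
correlation with their module's hub gene; a hypothetical hub inherits the
top enriched annotation of its high-TOM neighborhood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .correlation import bicor
from .expression import ExpressionMatrix
from .modules import ModuleEigengenes, ModulePartition, UNASSIGNED, module_membership
from .network import GeneNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "GeneList",
    "intramodular_connectivity",
    "select_hubs",
    "module_set_association",
    "term_enrichment",
    "rank_tfs",
    "annotate_hypothetical_hub",
    "first_neighbors",
    "load_gene_list",
    "load_annotation_map",
    "HubAnnotation",
]


@dataclass
class GeneList:
    """A labeled set of gene IDs (e.g. radiation-responsive DEGs)."""

    label: str
    members: list[str]
    directions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene list {self.label!r} contains duplicate IDs")


def load_gene_list(path: str | Path, label: str | None = None) -> GeneList:
    """Read a one-ID-per-line gene list; an optional second column is a
    direction tag."""
    members, directions = [], {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        members.append(parts[0].strip())
        if len(parts) > 1:
            directions[parts[0].strip()] = parts[1].strip()
    return GeneList(label=label or Path(path).stem, members=members, directions=directions)


def load_annotation_map(path: str | Path) -> dict[str, set[str]]:
    """Read gene_id<TAB>term_id[<TAB>term_name] rows into gene -> term sets."""
    ann: dict[str, set[str]] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            continue
        ann.setdefault(parts[0].strip(), set()).add(parts[1].strip())
    return ann


def intramodular_connectivity(
    network: GeneNetwork,
    partition: ModulePartition,
    expression: ExpressionMatrix | None = None,
    eigengenes: ModuleEigengenes | None = None,
) -> pd.DataFrame:
    """Per-gene kTotal, kWithin and own-module kME.

    kTotal is the node degree (sum of adjacency to all other genes);
    kWithin sums adjacency to same-module genes only.  kME (signed
    correlation with the own-module eigengene) is filled when expression and
    eigengenes are supplied, else NaN.  Unassigned genes get kWithin within
    the grey set and are flagged ``in_module`` False.
    """
    if network.gene_ids != partition.gene_ids:
        raise ValueError("network and partition gene sets differ")
    a = network.adjacency.copy()
    np.fill_diagonal(a, 0.0)
    k_total = a.sum(axis=1)
    labels = partition.labels
    k_within = np.zeros_like(k_total)
    for lab in set(labels.tolist()):
        idx = np.where(labels == lab)[0]
        k_within[idx] = a[np.ix_(idx, idx)].sum(axis=1)
    kme = np.full(len(labels), np.nan)
    if expression is not None and eigengenes is not None:
        kme_table = module_membership(expression, eigengenes)
        for i, lab in enumerate(labels):
            if lab in kme_table.columns:
                kme[i] = kme_table.iloc[i][lab]
    return pd.DataFrame(
        {
            "gene_id": partition.gene_ids,
            "module": labels,
            "in_module": labels != UNASSIGNED,
            "kTotal": k_total,
            "kWithin": k_within,
            "kME": kme,
        }
    ).set_index("gene_id")


def select_hubs(
    connectivity: pd.DataFrame,
    partition: ModulePartition,
    kme_min: float = 0.8,
) -> pd.DataFrame:
    """One hub per module: the max-kWithin gene among those with kME > kme_min.

    Ties break by higher kTotal, then lexicographically smaller gene ID.  A
    module with no gene above ``kme_min`` falls back to the plain
    argmax-kWithin gene and is flagged ``kme_fallback``.
    """
    rows = []
    for lab in partition.module_labels:
        sub = connectivity[connectivity["module"] == lab]
        if sub.empty:
            raise ValueError(f"module {lab} is empty")
        eligible = sub[sub["kME"] > kme_min]
        fallback = eligible.empty
        pool = sub if fallback else eligible
        # sort: kWithin desc, kTotal desc, gene_id asc
        pool = pool.sort_values(
            by=["kWithin", "kTotal"], ascending=[False, False], kind="mergesort"
        )
        top_kw = pool.iloc[0]["kWithin"]
        top_kt = pool.iloc[0]["kTotal"]
        tied = pool[(pool["kWithin"] == top_kw) & (pool["kTotal"] == top_kt)]
        hub = sorted(tied.index)[0]
        if fallback:
            logger.warning("module %s: no gene with kME > %.2f; argmax-kWithin hub", lab, kme_min)
        rows.append(
            {
                "module": lab,
                "color": partition.color_of(lab),
                "hub": hub,
                "kWithin": float(connectivity.loc[hub, "kWithin"]),
                "kTotal": float(connectivity.loc[hub, "kTotal"]),
                "kME": float(connectivity.loc[hub, "kME"]),
                "kme_fallback": fallback,
            }
        )
    return pd.DataFrame(rows).set_index("module")


def hypergeom_tails(N: int, K: int, n: int, k: int) -> tuple[float, float]:
    """Exact hypergeometric enrichment (upper) and depletion (lower) tails.

    Enrichment: P(X >= k); depletion: P(X <= k) for X ~ Hypergeom(N, K, n).
    """
    p_enrich = float(stats.hypergeom.sf(k - 1, N, K, n))
    p_deplete = float(stats.hypergeom.cdf(k, N, K, n))
    return min(p_enrich, 1.0), min(p_deplete, 1.0)


def module_set_association(
    partition: ModulePartition,
    gene_list: GeneList,
    universe: list[str] | set[str],
    alpha: float = 0.05,
    include_grey: bool = False,
) -> pd.DataFrame:
    """Hypergeometric association of every module with one gene list.

    List members outside the universe are discarded (and counted); per
    module the exact upper-tail (enrichment) and lower-tail (depletion)
    p-values are reported, with significance at ``alpha`` on enrichment.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    listed = [g for g in gene_list.members if g in universe]
    discarded = len(gene_list.members) - len(listed)
    if not listed:
        raise ValueError(f"gene list {gene_list.label!r} has no members in the universe")
    listed_set = set(listed)
    N, n = len(universe), len(listed)
    rows = []
    labels = partition.module_labels + ([UNASSIGNED] if include_grey else [])
    for lab in labels:
        members = [g for g in partition.members(lab) if g in universe]
        K = len(members)
        k = len(listed_set.intersection(members))
        p_enrich, p_deplete = hypergeom_tails(N, K, n, k)
        rows.append(
            {
                "module": lab,
                "color": partition.color_of(lab),
                "list": gene_list.label,
                "overlap": k,
                "module_size": K,
                "list_size": n,
                "universe_size": N,
                "discarded_ids": discarded,
                "p_enrich": p_enrich,
                "p_deplete": p_deplete,
                "significant": p_enrich <= alpha,
            }
        )
    return pd.DataFrame(rows)


def term_enrichment(
    gene_set: list[str] | set[str],
    annotation_map: dict[str, set[str]],
    universe: list[str] | set[str],
    alpha: float = 0.05,
    correction: str = "none",
) -> pd.DataFrame:
    """Two-sided (enrichment/depletion) hypergeometric test per annotation term.

    Terms annotating zero universe genes are skipped.  Benjamini-Hochberg
    adjusted enrichment p-values are always reported alongside the raw ones;
    ``correction`` selects which column drives the ``significant`` flag.
    Rows are ordered by raw enrichment p, ties by term ID.
    """
    if correction not in ("none", "BH"):
        raise ValueError(f"unknown correction: {correction!r}")
    universe = set(universe)
    gene_set = set(gene_set) & universe
    if not any(g in annotation_map for g in gene_set):
        raise ValueError("annotation map covers no gene of the set")
    term_universe: dict[str, set[str]] = {}
    for g in universe:
        for t in annotation_map.get(g, ()):
            term_universe.setdefault(t, set()).add(g)
    N, n = len(universe), len(gene_set)
    rows = []
    for term in sorted(term_universe):
        K = len(term_universe[term])
        if K == 0:
            logger.info("term %s annotates no universe gene; skipped", term)
            continue
        k = len(term_universe[term] & gene_set)
        p_enrich, p_deplete = hypergeom_tails(N, K, n, k)
        rows.append(
            {
                "term": term,
                "overlap": k,
                "term_size": K,
                "set_size": n,
                "universe_size": N,
                "p_enrich": p_enrich,
                "p_deplete": p_deplete,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["p_enrich_bh"] = multipletests(df["p_enrich"], method="fdr_bh")[1]
    col = "p_enrich" if correction == "none" else "p_enrich_bh"
    df["significant"] = df[col] <= alpha
    return df.sort_values(["p_enrich", "term"], kind="mergesort").reset_index(drop=True)


def rank_tfs(
    m: ExpressionMatrix,
    tf_ids: list[str] | set[str],
    partition: ModulePartition,
    hubs: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str]]:
    """Rank each module's transcription factors by bicor with the module hub.

    The score is the biweight midcorrelation between the TF's and the hub's
    expression profiles over all samples; TFs rank within their host module
    by descending |score| and carry a strength category (high >= 0.8,
    moderate 0.5-0.8, low < 0.5 on |score|).  TFs absent from the matrix or
    unassigned to a module are returned as unmapped.
    """
    gene_index = {g: i for i, g in enumerate(m.gene_ids)}
    labels = dict(zip(partition.gene_ids, partition.labels))
    x = m.values.to_numpy()
    rows, unmapped = [], []
    for tf in sorted(set(tf_ids)):
        lab = labels.get(tf)
        if tf not in gene_index or lab is None or lab == UNASSIGNED or lab not in hubs.index:
            unmapped.append(tf)
            continue
        hub = hubs.loc[lab, "hub"]
        score = 1.0 if tf == hub else bicor(x[gene_index[tf]], x[gene_index[hub]])
        a = abs(score)
        category = "high" if a >= 0.8 else ("moderate" if a >= 0.5 else "low")
        rows.append(
            {
                "tf": tf,
                "module": lab,
                "color": partition.color_of(lab),
                "hub": hub,
                "bicor_with_hub": score,
                "abs_bicor": a,
                "category": category,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["module", "abs_bicor", "tf"], ascending=[True, False, True], kind="mergesort")
        df["rank"] = df.groupby("module").cumcount() + 1
        df = df.reset_index(drop=True)
    return df, unmapped


def first_neighbors(
    gene: str,
    network: GeneNetwork,
    tom_min: float = 0.01,
    partition: ModulePartition | None = None,
) -> list[str]:
    """Genes whose topological overlap with ``gene`` exceeds ``tom_min``.

    The gene itself is excluded; supplying a partition restricts neighbors
    to the gene's own module.
    """
    tom_row = network.tom_of(gene)  # raises KeyError on unknown gene
    neighbors = [g for g in network.gene_ids if g != gene and tom_row[g] > tom_min]
    if partition is not None:
        labels = dict(zip(partition.gene_ids, partition.labels))
        neighbors = [g for g in neighbors if labels.get(g) == labels.get(gene)]
    return neighbors


@dataclass
class HubAnnotation:
    """Guilt-by-association annotation of one hub gene."""

    hub: str
    neighbors: list[str]
    enrichment: pd.DataFrame
    top_term: str  # "unassigned" when nothing is significant
    tie: bool = False


def annotate_hypothetical_hub(
    hub: str,
    network: GeneNetwork,
    annotation_map: dict[str, set[str]],
    universe: list[str] | set[str],
    tom_min: float = 0.01,
    alpha: float = 0.05,
) -> HubAnnotation:
    """Assign a function to a hub from its high-TOM neighborhood's enrichment.

    Neighbors are genes with TOM(hub, .) > tom_min; the most significantly
    enriched term of that set (smallest enrichment p, ties broken by term
    ID and logged) becomes the predicted function, or "unassigned" when no
    term is significant or the neighborhood is empty.
    """
    neighbors = first_neighbors(hub, network, tom_min=tom_min)
    if not neighbors:
        logger.warning("hub %s has no neighbors above TOM %.3g", hub, tom_min)
        return HubAnnotation(hub=hub, neighbors=[], enrichment=pd.DataFrame(), top_term="unassigned")
    try:
        enr = term_enrichment(neighbors, annotation_map, universe, alpha=alpha)
    except ValueError:
        return HubAnnotation(hub=hub, neighbors=neighbors, enrichment=pd.DataFrame(), top_term="unassigned")
    sig = enr[enr["significant"]]
    if sig.empty:
        return HubAnnotation(hub=hub, neighbors=neighbors, enrichment=enr, top_term="unassigned")
    best_p = sig["p_enrich"].min()
    best = sorted(sig[sig["p_enrich"] == best_p]["term"])
    tie = len(best) > 1
    if tie:
        logger.info("hub %s: %d terms tie at p=%.3g; lexicographic tie-break", hub, len(best), best_p)
    return HubAnnotation(hub=hub, neighbors=neighbors, enrichment=enr, top_term=best[0], tie=tie)
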