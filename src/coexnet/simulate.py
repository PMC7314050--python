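"""Synthetic expression data with planted module / hub / TF / trait structure.

The generator emulates the statistical shape of a merged multi-experiment
log-ratio compendium: each module is driven by a latent per-sample factor,
gene g in module m follows loading_g * factor_m + noise_sd * sqrt(1 -
loading_g^2) * eps, so at the default noise_sd = 1 the loading is the
gene's expected correlation with its factor; background genes are pure
noise, one gene per module carries a strictly larger loading
(the planted hub), optional designated TF genes track a module's factor, and
occasional gross multiplicative outliers stress the robust correlation.
Ground truth (labels, loadings, hubs, TFs, trait lists) is carried alongside
so every pipeline stage can be checked against what was planted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .downstream import GeneList
from .expression import ExpressionMatrix

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate_dataset", "generate_trait_lists"]


@dataclass
class SyntheticConfig:
    """Generator settings; defaults give 5 well-separated 40-gene modules,
    100 background genes and 60 samples."""

    n_modules: int = 5
    module_sizes: tuple[int, ...] = (40, 40, 40, 40, 40)
    n_background: int = 100
    n_samples: int = 60
    loading_range: tuple[float, float] = (0.8, 0.95)
    hub_loading: float = 0.98
    noise_sd: float = 1.0
    outlier_frac: float = 0.0
    outlier_scale: float = 10.0
    n_batches: int = 3
    tfs_per_module: int = 0
    tf_loading: float = 0.9
    factor_cor: tuple[tuple[int, int, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes length must equal n_modules")
        if any(s < 2 for s in self.module_sizes):
            raise ValueError("every module needs at least 2 genes")
        if self.n_samples < 8:
            raise ValueError("need at least 8 samples")
        if self.hub_loading <= self.loading_range[1]:
            raise ValueError("hub_loading must exceed the loading range maximum")
        if not 0 < self.loading_range[0] <= self.loading_range[1] <= 1:
            raise ValueError("loading_range must satisfy 0 < lo <= hi <= 1")


@dataclass
class SyntheticTruth:
    """What was planted: labels, loadings, factors, hubs, TFs, trait lists."""

    labels: dict[str, int]
    loadings: dict[str, float]
    factors: pd.DataFrame  # module x sample
    hubs: dict[int, str]
    tf_modules: dict[str, int]
    trait_lists: dict[str, dict] = field(default_factory=dict)
    noise_sd: float = 0.0
    outlier_frac: float = 0.0
    outlier_scale: float = 0.0
    seed: int = 0

    def module_members(self, label: int) -> list[str]:
        return [g for g, l in self.labels.items() if l == label]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "labels": self.labels,
            "loadings": self.loadings,
            "factors": {str(k): list(v) for k, v in self.factors.iterrows()},
            "hubs": {str(k): v for k, v in self.hubs.items()},
            "tf_modules": self.tf_modules,
            "trait_lists": self.trait_lists,
            "noise_sd": self.noise_sd,
            "outlier_frac": self.outlier_frac,
            "outlier_scale": self.outlier_scale,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def _factor_matrix(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-module factor profiles, optionally with planted inter-factor
    correlation (via the Cholesky factor of the requested correlation
    matrix)."""
    raw = rng.standard_normal((config.n_modules, config.n_samples))
    if not config.factor_cor:
        return raw
    corr = np.eye(config.n_modules)
    for i, j, rho in config.factor_cor:
        corr[i, j] = corr[j, i] = rho
    chol = np.linalg.cholesky(corr)
    return chol @ raw


def generate_dataset(config: SyntheticConfig | None = None, **overrides) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate an expression matrix plus its planted ground truth.

    Fully reproducible from ``config.seed``.  Gene IDs are ``M<m>_G<i>`` for
    module genes (the hub is ``M<m>_HUB``, planted TFs ``M<m>_TF<t>``) and
    ``BG_<i>`` for background noise genes.
    """
    if config is None:
        config = SyntheticConfig(**overrides)
    elif overrides:
        config = SyntheticConfig(**{**asdict(config), **overrides})
    rng = np.random.default_rng(config.seed)
    factors = _factor_matrix(config, rng)
    lo, hi = config.loading_range

    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    labels: dict[str, int] = {}
    loadings: dict[str, float] = {}
    hubs: dict[int, str] = {}
    tf_modules: dict[str, int] = {}

    for m in range(config.n_modules):
        lab = m + 1
        size = config.module_sizes[m]
        gene_loadings = rng.uniform(lo, hi, size=size)
        for i in range(size):
            if i == 0:
                gid, loading = f"M{lab}_HUB", config.hub_loading
                hubs[lab] = gid
            else:
                gid, loading = f"M{lab}_G{i}", float(gene_loadings[i])
            profile = loading * factors[m] + config.noise_sd * np.sqrt(
                max(0.0, 1 - loading**2)
            ) * rng.standard_normal(config.n_samples)
            gene_ids.append(gid)
            rows.append(profile)
            labels[gid] = lab
            loadings[gid] = loading
        for t in range(config.tfs_per_module):
            gid = f"M{lab}_TF{t + 1}"
            profile = config.tf_loading * factors[m] + config.noise_sd * np.sqrt(
                max(0.0, 1 - config.tf_loading**2)
            ) * rng.standard_normal(config.n_samples)
            gene_ids.append(gid)
            rows.append(profile)
            labels[gid] = lab
            loadings[gid] = config.tf_loading
            tf_modules[gid] = lab

    for i in range(config.n_background):
        gid = f"BG_{i + 1}"
        gene_ids.append(gid)
        rows.append(rng.standard_normal(config.n_samples))
        labels[gid] = 0
        loadings[gid] = 0.0

    x = np.vstack(rows)
    if config.outlier_frac > 0:
        mask = rng.random(x.shape) < config.outlier_frac
        x = np.where(mask, x * config.outlier_scale, x)

    sample_ids = [f"S{j + 1}" for j in range(config.n_samples)]
    batch_of = np.array_split(np.arange(config.n_samples), config.n_batches)
    batches = pd.Series(index=sample_ids, dtype=object)
    for b, cols in enumerate(batch_of):
        for j in cols:
            batches.iloc[j] = f"batch{b + 1}"

    matrix = ExpressionMatrix(
        values=pd.DataFrame(x, index=gene_ids, columns=sample_ids), batches=batches
    )
    truth = SyntheticTruth(
        labels=labels,
        loadings=loadings,
        factors=pd.DataFrame(factors, index=range(1, config.n_modules + 1), columns=sample_ids),
        hubs=hubs,
        tf_modules=tf_modules,
        noise_sd=config.noise_sd,
        outlier_frac=config.outlier_frac,
        outlier_scale=config.outlier_scale,
        seed=config.seed,
    )
    return matrix, truth


def generate_trait_lists(
    truth: SyntheticTruth,
    list_size: int,
    target_module: int,
    overlap_count: int,
    seed: int = 0,
    label: str | None = None,
) -> GeneList:
    """A gene list with an exact planted overlap with one module.

    Exactly ``overlap_count`` members come from ``target_module``; the rest
    are drawn uniformly from non-module genes.  Reproducible from ``seed``.
    """
    module_genes = sorted(truth.module_members(target_module))
    other_genes = sorted(g for g, l in truth.labels.items() if l != target_module)
    if overlap_count > min(list_size, len(module_genes)):
        raise ValueError("overlap_count exceeds list size or module size")
    if list_size - overlap_count > len(other_genes):
        raise ValueError("not enough non-module genes for the requested list")
    rng = np.random.default_rng(seed)
    inside = list(rng.choice(module_genes, size=overlap_count, replace=False))
    outside = list(rng.choice(other_genes, size=list_size - overlap_count, replace=False))
    members = sorted(inside + outside)
    name = label or f"trait_m{target_module}_k{overlap_count}"
    truth.trait_lists[name] = {
        "target_module": target_module,
        "overlap_count": overlap_count,
        "list_size": list_size,
        "members": members,
    }
    return GeneList(label=name, members=members)
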