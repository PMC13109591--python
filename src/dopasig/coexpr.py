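"""Signed-hybrid weighted co-expression networks and module eigengenes.

Adjacency is cor^beta for positive correlations and zero otherwise
(signed hybrid), with the soft power beta chosen as the smallest integer
in 1..20 whose degree distribution fits a scale-free law with R^2 >= 0.8
(falling back to 6).  Similarity for clustering is the topological
overlap measure; modules come from average-linkage hierarchical
clustering of 1 - TOM with a deterministic height scan, and each module
is summarized per sample by its eigengene (unit-norm first principal
component of the member genes' z-scored expression).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from ._stats import bh_adjust
from .normalize import ExpressionMatrix, design_matrix
from .ppi import ModulePartition

__all__ = [
    "CoexprNetwork",
    "EigengeneMatrix",
    "build_network",
    "detect_modules",
    "eigengenes",
    "module_trait",
    "module_correlations",
    "pick_soft_power",
    "tom_similarity",
]

GREY = "grey"


@dataclass
class CoexprNetwork:
    genes: list[str]
    method: str  # pearson | spearman
    beta: int
    adjacency: np.ndarray
    tom: np.ndarray
    expr: ExpressionMatrix = field(repr=False)


@dataclass
class EigengeneMatrix:
    values: pd.DataFrame  # samples x modules
    explained_variance: dict[str, float]


def _correlation(values: np.ndarray, method: str) -> np.ndarray:
    if method == "spearman":
        values = np.apply_along_axis(stats.rankdata, 1, values)
    elif method != "pearson":
        raise ValueError("method must be 'pearson' or 'spearman'")
    cor = np.corrcoef(values)
    return np.clip(cor, -1.0, 1.0)


def scale_free_fit(adjacency: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log-log regression of the binned degree distribution."""
    k = adjacency.sum(axis=1)
    k = k[k > 0]
    if k.size < n_bins:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.sum() / k.size))
    if len(xs) < 3:
        return 0.0
    slope, intercept, r, *_ = stats.linregress(xs, ys)
    return float(r**2)


def _signed_hybrid(cor: np.ndarray, beta: int) -> np.ndarray:
    a = np.where(cor > 0, cor, 0.0) ** beta
    np.fill_diagonal(a, 0.0)
    return a


def pick_soft_power(cor: np.ndarray, target_r2: float = 0.8, fallback: int = 6) -> int:
    """Smallest beta in 1..20 reaching the scale-free target, else 6."""
    for beta in range(1, 21):
        if scale_free_fit(_signed_hybrid(cor, beta)) >= target_r2:
            return beta
    return fallback


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap: (shared neighbors + direct link) / normalizer."""
    a = adjacency.copy()
    np.fill_diagonal(a, 0.0)
    l = a @ a
    k = a.sum(axis=1)
    kmin = np.minimum(k[:, None], k[None, :])
    denom = kmin + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def build_network(
    expr: ExpressionMatrix,
    method: str = "pearson",
    beta: int | None = None,
    top_n: int = 5000,
    *,
    allow_uncorrected: bool = False,
) -> CoexprNetwork:
    """Variance-filter genes, pick the soft power, build adjacency and TOM.

    Expects batch-corrected input (upstream removal of the site effect);
    pass ``allow_uncorrected=True`` to override deliberately.
    """
    if expr.provenance != "batch_corrected" and not allow_uncorrected:
        raise ValueError(
            "co-expression input should be batch corrected; "
            "pass allow_uncorrected=True to override"
        )
    if expr.values.shape[1] < 8:
        raise ValueError("need at least 8 samples for co-expression analysis")
    values = expr.values
    sd = values.std(axis=1)
    keep = sd > 0
    if (~keep).any():
        warnings.warn(f"dropped {int((~keep).sum())} constant genes")
    values = values[keep]
    genes = [g for g, k in zip(expr.genes, keep) if k]
    if len(genes) > top_n:
        mad = np.median(np.abs(values - np.median(values, axis=1, keepdims=True)), axis=1)
        order = np.argsort(-mad, kind="stable")[:top_n]
        order = np.sort(order)
        values = values[order]
        genes = [genes[i] for i in order]
    cor = _correlation(values, method)
    if beta is None:
        beta = pick_soft_power(cor)
    adjacency = _signed_hybrid(cor, beta)
    tom = tom_similarity(adjacency)
    sub = ExpressionMatrix(genes, list(expr.samples), values, expr.provenance)
    return CoexprNetwork(genes, method, beta, adjacency, tom, sub)


def _kme_filter(
    network: CoexprNetwork,
    raw: dict[str, list[str]],
    kme_threshold: float,
    min_size: int,
    grey: list[str],
) -> dict[str, list[str]]:
    """Drop weakly attached members (|cor with module eigengene| < threshold)."""
    part = ModulePartition(modules=raw)
    eg = eigengenes(network.expr, part)
    gene_index = {g: i for i, g in enumerate(network.expr.genes)}
    modules: dict[str, list[str]] = {}
    grey_out = list(grey)
    for k, (name, members) in enumerate(raw.items()):
        e = eg.values[name].to_numpy()
        kept = []
        for g in members:
            x = network.expr.values[gene_index[g]]
            if x.std() == 0:
                grey_out.append(g)
                continue
            kme = np.corrcoef(x, e)[0, 1]
            (kept if abs(kme) >= kme_threshold else grey_out).append(g)
        if len(kept) >= min_size:
            modules[name] = sorted(kept)
        else:
            grey_out.extend(kept)
    modules = {f"M{k + 1}": m for k, m in enumerate(modules.values())}
    if grey_out:
        modules[GREY] = sorted(grey_out)
    return modules


def detect_modules(
    network: CoexprNetwork, min_size: int = 30, kme_threshold: float = 0.5
) -> ModulePartition:
    """Average-linkage clustering of 1 - TOM with a deterministic height scan.

    Cut heights are scanned from 0.99 downward in steps of 0.01; the first
    height yielding at least two clusters of size >= min_size is used.
    Initial clusters are then cleaned by module membership: each gene must
    correlate with its module eigengene at |kME| >= ``kme_threshold`` or
    it is moved to the grey (unassigned) set, mirroring the usual
    eigengene-based membership filter.  If no height qualifies, all genes
    form a single module (with a warning).
    """
    genes = network.genes
    dist = 1.0 - network.tom
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    for height in np.arange(0.99, 0.0, -0.01):
        labels = hierarchy.fcluster(link, t=height, criterion="distance")
        sizes = pd.Series(labels).value_counts()
        big = sizes[sizes >= min_size]
        if len(big) >= 2:
            raw: dict[str, list[str]] = {}
            ordered = sorted(big.index, key=lambda lb: (-sizes[lb], lb))
            for k, lb in enumerate(ordered):
                raw[f"M{k + 1}"] = sorted(g for g, l in zip(genes, labels) if l == lb)
            grey = sorted(g for g, l in zip(genes, labels) if l not in set(big.index))
            modules = _kme_filter(network, raw, kme_threshold, min_size, grey)
            return ModulePartition(modules=modules, inflation=float("nan"), prune=float("nan"))
    warnings.warn("no cut height produced >=2 modules of the requested size")
    return ModulePartition(modules={"M1": sorted(genes)},
                           inflation=float("nan"), prune=float("nan"))


def eigengenes(expr: ExpressionMatrix, partition: ModulePartition) -> EigengeneMatrix:
    """Unit-norm PC1 of each module's z-scored expression, per sample.

    Sign is fixed so the eigengene correlates positively with the module's
    mean expression profile.  The grey (unassigned) module is skipped.
    """
    gene_index = {g: i for i, g in enumerate(expr.genes)}
    cols: dict[str, np.ndarray] = {}
    varfrac: dict[str, float] = {}
    for name, members in partition.modules.items():
        if name == GREY or not members:
            continue
        idx = [gene_index[g] for g in members if g in gene_index]
        if not idx:
            raise ValueError(f"module {name!r} has no genes in the expression matrix")
        block = expr.values[idx]
        sd = block.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = (block - block.mean(axis=1, keepdims=True)) / sd
        u, s, vt = np.linalg.svd(z.T, full_matrices=False)  # samples x genes
        pc1 = u[:, 0]
        total = float((s**2).sum())
        varfrac[name] = float(s[0] ** 2 / total) if total > 0 else 0.0
        mean_profile = z.mean(axis=0)
        # exactly balanced modules (e.g. an anticorrelated pair) have a
        # constant mean profile; keep the SVD sign then
        if mean_profile.std() > 0 and np.corrcoef(pc1, mean_profile)[0, 1] < 0:
            pc1 = -pc1
        cols[name] = pc1
    values = pd.DataFrame(cols, index=expr.samples)
    return EigengeneMatrix(values=values, explained_variance=varfrac)


def _one_hot_traits(metadata: pd.DataFrame, traits: list[str]) -> pd.DataFrame:
    out = {}
    for t in traits:
        for lv in sorted(metadata[t].astype(str).unique()):
            out[f"{t}={lv}"] = (metadata[t].astype(str) == lv).to_numpy(float)
    return pd.DataFrame(out, index=metadata["sample_id"])


def module_trait(
    eg: EigengeneMatrix,
    metadata: pd.DataFrame,
    traits: list[str],
    *,
    group_factor: str = "mutation",
) -> pd.DataFrame:
    """Module-trait correlations (Pearson and Spearman) plus a per-module GLM.

    Traits are one-hot indicators of the metadata factor levels.  The
    correlation grid is BH-adjusted per correlation method; the GLM tests
    eigengene ~ group with an overall F-test, BH-adjusted across modules.
    """
    trait_frame = _one_hot_traits(metadata, traits)
    trait_frame = trait_frame.loc[eg.values.index]
    rows = []
    for module in eg.values.columns:
        e = eg.values[module].to_numpy()
        for trait in trait_frame.columns:
            tv = trait_frame[trait].to_numpy()
            row = {"module": module, "trait": trait}
            if e.std() == 0 or tv.std() == 0:
                row.update({"pearson_r": np.nan, "pearson_p": np.nan,
                            "spearman_rho": np.nan, "spearman_p": np.nan})
            else:
                pr = stats.pearsonr(e, tv)
                sr = stats.spearmanr(e, tv)
                row.update({"pearson_r": float(pr.statistic), "pearson_p": float(pr.pvalue),
                            "spearman_rho": float(sr.statistic), "spearman_p": float(sr.pvalue)})
            rows.append(row)
    res = pd.DataFrame(rows)
    res["pearson_fdr"] = bh_adjust(res["pearson_p"].to_numpy())
    res["spearman_fdr"] = bh_adjust(res["spearman_p"].to_numpy())

    # per-module GLM: eigengene ~ group, overall F-test
    meta_idx = metadata.set_index("sample_id").loc[eg.values.index].reset_index()
    x, _ = design_matrix(meta_idx, [group_factor])
    n, p = x.shape
    glm_rows = []
    for module in eg.values.columns:
        y = eg.values[module].to_numpy()
        beta_hat, *_ = np.linalg.lstsq(x, y, rcond=None)
        rss1 = float(((y - x @ beta_hat) ** 2).sum())
        rss0 = float(((y - y.mean()) ** 2).sum())
        df1, df2 = p - 1, n - p
        if df2 < 1 or rss1 <= 0:
            glm_rows.append({"module": module, "glm_p": np.nan})
            continue
        f_stat = ((rss0 - rss1) / df1) / (rss1 / df2)
        glm_rows.append({"module": module, "glm_p": float(stats.f.sf(f_stat, df1, df2))})
    glm = pd.DataFrame(glm_rows)
    glm["glm_fdr"] = bh_adjust(glm["glm_p"].to_numpy())
    return res.merge(glm, on="module")


def module_correlations(eg: EigengeneMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman correlations between module eigengenes with BH FDR.

    Returns (correlation matrix, long table with p and fdr).  The
    correlation matrix of complete data is positive semidefinite.
    """
    mods = list(eg.values.columns)
    k = len(mods)
    cor = np.eye(k)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            sr = stats.spearmanr(eg.values[mods[i]], eg.values[mods[j]])
            cor[i, j] = cor[j, i] = float(sr.statistic)
            rows.append({"module_a": mods[i], "module_b": mods[j],
                         "rho": float(sr.statistic), "pvalue": float(sr.pvalue)})
    table = pd.DataFrame(rows, columns=["module_a", "module_b", "rho", "pvalue"])
    if len(table):
        table["fdr"] = bh_adjust(table["pvalue"].to_numpy())
    else:
        table["fdr"] = []
    return pd.DataFrame(cor, index=mods, columns=mods), table
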