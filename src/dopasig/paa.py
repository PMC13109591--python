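"""Pathway activity scoring and its association with study factors.

Two footprint scorers over a pathway x gene weight matrix: ``ulm``
regresses each sample's z-scored expression on the pathway's weight
vector (zero weight for non-members) and reports the slope t-statistic;
``wsum_perm`` computes the weighted sum of member-gene expression and
normalizes it to a z-score against gene-label permutations.  Activity is
then related to mutation, gender, reprogramming and differentiation site
with an ordinary least-squares model per pathway (treatment coding,
healthy / first level as reference), and to the co-expression structure
via Spearman correlation with module eigengenes and their first
principal component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .coexpr import EigengeneMatrix
from .normalize import ExpressionMatrix, design_matrix

__all__ = ["PathwayActivity", "score_pathways", "paa_glm", "modules_vs_paa"]


@dataclass
class PathwayActivity:
    values: pd.DataFrame  # pathways x samples
    method: str  # ulm | wsum_perm
    n_perm: int = 0
    seed: int = 0


def score_pathways(
    expr: ExpressionMatrix,
    weights: pd.DataFrame,
    method: str = "ulm",
    n_perm: int = 1000,
    seed: int = 0,
) -> PathwayActivity:
    """Per-sample pathway activity from a long (pathway, gene, weight) table.

    Pathways with no weighted gene present in the expression matrix are
    skipped with a warning; a pathway whose present weights are all zero
    raises.
    """
    if method not in ("ulm", "wsum_perm"):
        raise ValueError("method must be 'ulm' or 'wsum_perm'")
    gene_index = {g: i for i, g in enumerate(expr.genes)}
    n_genes, n_samples = expr.values.shape
    # z-score each sample's expression across genes
    x = expr.values
    mu = x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    rng = np.random.default_rng(seed)
    rows: dict[str, np.ndarray] = {}
    for pathway, sub in weights.groupby("pathway", sort=True):
        present = sub.loc[sub["gene"].isin(gene_index)]
        if present.empty:
            warnings.warn(f"pathway {pathway!r} has no gene in the expression matrix; skipped")
            continue
        w_full = np.zeros(n_genes)
        for _, r in present.iterrows():
            w_full[gene_index[r["gene"]]] = float(r["weight"])
        if not np.any(w_full):
            raise ValueError(f"pathway {pathway!r}: all weights zero")
        if method == "ulm":
            # slope t-statistic of z_sample ~ w, per sample
            wc = w_full - w_full.mean()
            ssw = float((wc**2).sum())
            yc = z - z.mean(axis=0, keepdims=True)
            slope = (wc @ yc) / ssw
            rss = (yc**2).sum(axis=0) - slope**2 * ssw
            df = n_genes - 2
            sigma2 = np.maximum(rss / df, 1e-300)
            tstat = slope / np.sqrt(sigma2 / ssw)
            rows[pathway] = tstat
        else:
            obs = w_full @ x
            members = np.where(w_full != 0)[0]
            w_m = w_full[members]
            null = np.empty((n_perm, n_samples))
            for b in range(n_perm):
                pick = rng.choice(n_genes, size=members.size, replace=False)
                null[b] = w_m @ x[pick]
            mu0 = null.mean(axis=0)
            sd0 = null.std(axis=0, ddof=1)
            sd0[sd0 == 0] = 1.0
            rows[pathway] = (obs - mu0) / sd0
    values = pd.DataFrame(rows, index=expr.samples).T
    return PathwayActivity(values=values, method=method,
                           n_perm=n_perm if method == "wsum_perm" else 0, seed=seed)


def _find_aliased(metadata: pd.DataFrame, factors: list[str]) -> tuple[str, str] | None:
    for a, b in combinations(factors, 2):
        xa, _ = design_matrix(metadata, [a], intercept=False)
        xb, _ = design_matrix(metadata, [b], intercept=False)
        joint = np.hstack([np.ones((len(metadata), 1)), xa, xb])
        if np.linalg.matrix_rank(joint) < joint.shape[1]:
            return a, b
    return None


def paa_glm(
    activity: PathwayActivity,
    metadata: pd.DataFrame,
    factors: list[str] = ("mutation", "gender", "reprogramming", "place"),
) -> pd.DataFrame:
    """OLS of activity ~ mutation + gender + reprogramming + place, per pathway.

    Treatment coding with healthy (or the alphabetically first level) as
    reference; two-sided t-test per coefficient; BH FDR across the whole
    pathway x coefficient grid (intercept excluded).
    """
    factors = list(factors)
    meta = metadata.set_index("sample_id").loc[activity.values.columns].reset_index()
    for f in factors:
        if meta[f].astype(str).nunique() < 2:
            raise ValueError(f"factor {f!r} has a single level")
    ref = {"mutation": "healthy"} if "mutation" in factors else None
    x, names = design_matrix(meta, factors, reference=ref)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        pair = _find_aliased(meta, factors)
        if pair:
            raise ValueError(f"confounded factors: {pair[0]!r} aliased with {pair[1]!r}")
        raise ValueError("model matrix rank deficient")
    n, p = x.shape
    if n - p < 1:
        raise ValueError("no residual degrees of freedom")
    xtx_inv = np.linalg.inv(x.T @ x)
    rows = []
    for pathway in activity.values.index:
        y = activity.values.loc[pathway].to_numpy()
        beta = xtx_inv @ x.T @ y
        resid = y - x @ beta
        sigma2 = float(resid @ resid) / (n - p)
        se = np.sqrt(np.maximum(np.diag(xtx_inv) * sigma2, 1e-300))
        tstat = beta / se
        pvals = 2.0 * stats.t.sf(np.abs(tstat), n - p)
        for i, name in enumerate(names):
            if name == "Intercept":
                continue
            rows.append({"pathway": pathway, "coefficient": name,
                         "estimate": float(beta[i]), "se": float(se[i]),
                         "pvalue": float(pvals[i])})
    res = pd.DataFrame(rows, columns=["pathway", "coefficient", "estimate", "se", "pvalue"])
    if len(res):
        res["fdr"] = bh_adjust(res["pvalue"].to_numpy())
    else:
        res["fdr"] = []
    return res


def modules_vs_paa(eg: EigengeneMatrix, activity: PathwayActivity) -> pd.DataFrame:
    """Spearman correlation of module eigengenes (and their PC1) with activity.

    PC1 summarizes the module-eigengene matrix; its explained-variance
    fraction is reported in the ``pc1_variance_fraction`` attribute row.
    """
    shared = [s for s in eg.values.index if s in activity.values.columns]
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared samples")
    e = eg.values.loc[shared]
    a = activity.values[shared]
    ec = e.to_numpy() - e.to_numpy().mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(ec, full_matrices=False)
    pc1 = u[:, 0] * s[0]
    total = float((s**2).sum())
    pc1_frac = float(s[0] ** 2 / total) if total > 0 else 0.0
    if np.corrcoef(pc1, e.to_numpy().mean(axis=1))[0, 1] < 0:
        pc1 = -pc1
    summaries = {"PC1": pc1, **{m: e[m].to_numpy() for m in e.columns}}
    rows = []
    for name, vec in summaries.items():
        for pathway in a.index:
            act = a.loc[pathway].to_numpy()
            sr = stats.spearmanr(vec, act)
            rows.append({"summary": name, "pathway": pathway,
                         "rho": float(sr.statistic), "pvalue": float(sr.pvalue)})
    res = pd.DataFrame(rows, columns=["summary", "pathway", "rho", "pvalue"])
    res["fdr"] = bh_adjust(res["pvalue"].to_numpy())
    res.attrs["pc1_variance_fraction"] = pc1_frac
    return res
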