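"""Exploratory structure: PCA, PERMANOVA, ANOVA batch screen, marker tests.

PERMANOVA partitions the Gower-centered Euclidean distance matrix with
sequential (Type-I) sums of squares in the user-given factor order;
pseudo-F per factor is referenced against free permutations of the sample
rows with the +1 convention, and p-values are BH-adjusted across factors.
The marker panel fits, per gene, a Gaussian random-intercept model
(expression ~ group + (1 | batch)) by REML with a one-dimensional profile
over the variance ratio, tests contrasts against the healthy group with a
normal approximation, and separately compares the two differentiation
sites with a Wilcoxon rank-sum test on pooled normalized expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._stats import bh_adjust
from .io import CountMatrix
from .normalize import ExpressionMatrix, design_matrix, normalized_counts

__all__ = [
    "PCAResult",
    "pca",
    "PermanovaResult",
    "permanova",
    "batch_screen",
    "marker_panel",
]


# --------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # genes x components
    explained_variance_ratio: np.ndarray


def pca(expr: ExpressionMatrix, n_components: int = 2) -> PCAResult:
    """SVD principal components of the per-gene-centered expression matrix.

    Sign convention: within each component the loading of largest absolute
    value is made positive, so results do not depend on LAPACK sign whims.
    """
    n_genes, n_samples = expr.values.shape
    if n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    if n_components > min(n_genes, n_samples):
        raise ValueError(
            f"n_components={n_components} exceeds min(genes, samples)="
            f"{min(n_genes, n_samples)}"
        )
    xc = (expr.values - expr.values.mean(axis=1, keepdims=True)).T  # samples x genes
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    total = float((s**2).sum())
    if total <= 1e-300:
        warnings.warn("degenerate PCA: all samples identical after centering")
        frac = np.zeros(n_components)
    else:
        frac = (s[:n_components] ** 2) / total
    scores = u[:, :n_components] * s[:n_components]
    loadings = vt[:n_components].T
    for k in range(n_components):
        imax = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[imax, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    comp_names = [f"PC{k + 1}" for k in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=expr.samples, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=expr.genes, columns=comp_names),
        explained_variance_ratio=frac,
    )


# --------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    table: pd.DataFrame  # factor, df, ss, r2, pseudo_f, pvalue, fdr
    n_perm: int
    seed: int
    total_ss: float = field(default=0.0)


def _gower_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    return -0.5 * j @ d2 @ j


def _hat(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x)


def permanova(
    expr: ExpressionMatrix,
    metadata: pd.DataFrame,
    factors: list[str],
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Sequential PERMANOVA on Euclidean distances between sample profiles.

    R-squared values of the factors plus the residual sum to one by the
    sequential decomposition; permutation p uses (1 + #{F* >= F}) /
    (1 + n_perm) so it is never exactly zero.
    """
    for f in factors:
        if metadata[f].astype(str).nunique() < 2:
            raise ValueError(f"factor {f!r} has a single level among these samples")
    xs = expr.values.T  # samples x genes
    n = xs.shape[0]
    d2 = ((xs[:, None, :] - xs[None, :, :]) ** 2).sum(axis=2)
    g = _gower_center(d2)
    total_ss = float(np.trace(g))

    hats, dfs = [], []
    prev_x = np.ones((n, 1))
    prev_rank = 1
    prev_h = _hat(prev_x)
    for f in factors:
        x_f, _ = design_matrix(metadata, [f], intercept=False)
        cur_x = np.hstack([prev_x, x_f])
        cur_rank = np.linalg.matrix_rank(cur_x)
        cur_h = _hat(cur_x)
        hats.append((prev_h, cur_h))
        dfs.append(cur_rank - prev_rank)
        prev_x, prev_rank, prev_h = cur_x, cur_rank, cur_h
    df_res = n - prev_rank
    h_full = prev_h

    def factor_stats(gm: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        ss = np.array([np.sum((ch - ph) * gm.T) for ph, ch in hats])
        ss_res = float(np.sum((np.eye(n) - h_full) * gm.T))
        f_stat = (ss / np.array(dfs)) / (ss_res / df_res)
        return ss, f_stat, ss_res

    ss_obs, f_obs, _ = factor_stats(g)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(factors))
    tie_tol = 1e-9 * np.maximum(1.0, np.abs(f_obs))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        _, f_p, _ = factor_stats(gp)
        exceed += f_p >= f_obs - tie_tol
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    table = pd.DataFrame(
        {
            "factor": factors,
            "df": dfs,
            "ss": ss_obs,
            "r2": ss_obs / total_ss if total_ss > 0 else np.zeros(len(factors)),
            "pseudo_f": f_obs,
            "pvalue": pvals,
            "fdr": bh_adjust(pvals),
        }
    )
    return PermanovaResult(table=table, n_perm=n_perm, seed=seed, total_ss=total_ss)


# --------------------------------------------------------------------------
# two-way ANOVA batch screen


def batch_screen(
    counts: CountMatrix,
    metadata: pd.DataFrame,
    factor_a: str = "place",
    factor_b: str = "condition",
) -> pd.DataFrame:
    """Per-gene two-factor fixed-effects ANOVA on log2(raw count + 1).

    Sequential (Type-I) sums of squares for factor_a, factor_b and their
    interaction; per-term p-values BH-adjusted across genes.
    """
    y = np.log2(counts.counts.astype(float) + 1.0).T  # samples x genes
    n = y.shape[0]
    xa, _ = design_matrix(metadata, [factor_a], intercept=False)
    xb, _ = design_matrix(metadata, [factor_b], intercept=False)
    inter = np.einsum("ni,nj->nij", xa, xb).reshape(n, -1)
    ones = np.ones((n, 1))
    models = [
        np.hstack([ones]),
        np.hstack([ones, xa]),
        np.hstack([ones, xa, xb]),
        np.hstack([ones, xa, xb, inter]),
    ]
    ranks = [np.linalg.matrix_rank(m) for m in models]
    rss = []
    for m in models:
        resid = y - m @ np.linalg.lstsq(m, y, rcond=None)[0]
        rss.append((resid**2).sum(axis=0))
    df_res = n - ranks[-1]
    if df_res < 1:
        raise ValueError("no residual degrees of freedom for the ANOVA screen")
    ms_res = rss[-1] / df_res
    out = {"gene": counts.genes}
    terms = [factor_a, factor_b, f"{factor_a}:{factor_b}"]
    for t, term in enumerate(terms):
        df_t = ranks[t + 1] - ranks[t]
        ss_t = rss[t] - rss[t + 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            f_stat = (ss_t / df_t) / ms_res
        p = stats.f.sf(f_stat, df_t, df_res)
        p = np.where(np.isfinite(f_stat), p, np.nan)
        out[f"p_{term}"] = p
        out[f"fdr_{term}"] = bh_adjust(p)
    return pd.DataFrame(out)


# --------------------------------------------------------------------------
# marker panel (LMM + Wilcoxon)


def _reml_random_intercept(y: np.ndarray, x: np.ndarray, groups: np.ndarray):
    """REML fit of y = X beta + b_group + eps via a 1-D profile over
    lambda = var_b / var_eps.  Returns (beta, cov_beta, var_b, var_e, llik)."""
    n, p = x.shape
    z = np.zeros((n, groups.max() + 1))
    z[np.arange(n), groups] = 1.0

    def neg2_reml(log_lam: float) -> float:
        lam = np.exp(log_lam)
        v = np.eye(n) + lam * (z @ z.T)
        try:
            l_chol = np.linalg.cholesky(v)
        except np.linalg.LinAlgError:
            return np.inf
        vi_x = np.linalg.solve(v, x)
        vi_y = np.linalg.solve(v, y)
        xtvx = x.T @ vi_x
        beta = np.linalg.solve(xtvx, x.T @ vi_y)
        r = y - x @ beta
        rvr = float(r @ np.linalg.solve(v, r))
        logdet_v = 2.0 * float(np.log(np.diag(l_chol)).sum())
        sign, logdet_x = np.linalg.slogdet(xtvx)
        return logdet_v + logdet_x + (n - p) * np.log(max(rvr, 1e-300))

    res = optimize.minimize_scalar(neg2_reml, bounds=(-15.0, 15.0), method="bounded")
    candidates = [(neg2_reml(-30.0), -30.0), (res.fun, float(res.x))]
    crit, log_lam = min(candidates)
    lam = np.exp(log_lam)
    v = np.eye(n) + lam * (z @ z.T)
    vi_x = np.linalg.solve(v, x)
    xtvx = x.T @ vi_x
    beta = np.linalg.solve(xtvx, x.T @ np.linalg.solve(v, y))
    r = y - x @ beta
    var_e = float(r @ np.linalg.solve(v, r)) / (n - p)
    var_b = lam * var_e if log_lam > -29.0 else 0.0
    cov_beta = var_e * np.linalg.inv(xtvx)
    return beta, cov_beta, var_b, var_e, -0.5 * crit


def marker_panel(
    counts: CountMatrix,
    sf: np.ndarray,
    metadata: pd.DataFrame,
    markers: list[str],
    *,
    group_factor: str = "mutation",
    batch_factor: str = "place",
    reference: str = "healthy",
) -> pd.DataFrame:
    """Random-intercept LMM contrasts vs the reference group, per marker.

    Expression is log2(normalized + 1).  Contrast p-values use a normal
    approximation to the Wald statistic.  The place comparison is a
    two-sided Wilcoxon rank-sum test on pooled normalized expression.
    Missing markers are reported and skipped.
    """
    if metadata[group_factor].astype(str).nunique() < 2:
        raise ValueError("marker panel needs at least two groups")
    norm = normalized_counts(counts, sf)
    logexpr = np.log2(norm.values + 1.0)
    gene_index = {g: i for i, g in enumerate(counts.genes)}
    x, names = design_matrix(metadata, [group_factor])
    groups = pd.factorize(metadata[batch_factor].astype(str))[0]
    levels = sorted(metadata[group_factor].astype(str).unique())
    contrasts = [lv for lv in levels if lv != reference]
    place_levels = sorted(metadata[batch_factor].astype(str).unique())

    rows = []
    for marker in markers:
        if marker not in gene_index:
            rows.append({"gene": marker, "found": False})
            continue
        y = logexpr[gene_index[marker]]
        beta, cov, var_b, var_e, llik = _reml_random_intercept(y, x, groups)
        row: dict = {
            "gene": marker,
            "found": True,
            "random_intercept_var": var_b,
            "residual_var": var_e,
            "reml_loglik": llik,
        }
        for lv in contrasts:
            c = np.zeros(len(names))
            ca = f"{group_factor}[{lv}]"
            cb = f"{group_factor}[{reference}]"
            for i, nm in enumerate(names):
                if nm == ca:
                    c[i] = 1.0
                elif nm == cb:
                    c[i] = -1.0
            est = float(c @ beta)
            se = float(np.sqrt(max(c @ cov @ c, 0.0)))
            zstat = est / se if se > 0 else 0.0
            row[f"estimate_{lv}_vs_{reference}"] = est
            row[f"p_{lv}_vs_{reference}"] = 2.0 * stats.norm.sf(abs(zstat))
        if len(place_levels) == 2:
            mask = metadata[batch_factor].astype(str) == place_levels[0]
            a = norm.values[gene_index[marker]][mask.to_numpy()]
            b = norm.values[gene_index[marker]][~mask.to_numpy()]
            if np.all(np.concatenate([a, b]) == np.concatenate([a, b])[0]):
                row["wilcoxon_stat"] = len(a) * len(b) / 2.0
                row["wilcoxon_p"] = 1.0
            else:
                w = stats.mannwhitneyu(a, b, alternative="two-sided")
                row["wilcoxon_stat"] = float(w.statistic)
                row["wilcoxon_p"] = float(w.pvalue)
        rows.append(row)
    return pd.DataFrame(rows)
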