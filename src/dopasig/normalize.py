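"""Size-factor normalization, variance-stabilizing transform, batch correction.

Size factors follow the median-of-ratios scheme: each sample's factor is
the median, over genes with a positive geometric mean across samples, of
that sample's count divided by the gene's geometric mean.  The variance
stabilizer is log2(count / size_factor + 1), a deliberately simple
monotone transform used only upstream of PCA, PERMANOVA and co-expression
(never for differential testing).  Batch correction fits, per gene, a
least-squares model on [design | batch] treatment codings and subtracts
only the fitted batch component, so design-attributable variation is
preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix

__all__ = ["ExpressionMatrix", "size_factors", "normalized_counts", "vst", "remove_batch"]


@dataclass
class ExpressionMatrix:
    """Real-valued gene x sample matrix with a provenance tag."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    provenance: str  # {normalized, vst, batch_corrected}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError("expression matrix dimensions inconsistent")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite expression values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)


def size_factors(counts: CountMatrix) -> np.ndarray:
    """Median-of-ratios size factors (one positive scalar per sample)."""
    c = counts.counts.astype(float)
    with np.errstate(divide="ignore"):
        logc = np.log(c)
    # geometric mean over samples; -inf marks genes with any zero
    loggeo = logc.mean(axis=1)
    ref = np.isfinite(loggeo)
    if not ref.any():
        raise ValueError("no gene with all-positive counts; size factors undefined")
    ratios = np.exp(logc[ref] - loggeo[ref, None])
    sf = np.median(ratios, axis=0)
    return sf


def normalized_counts(counts: CountMatrix, sf: np.ndarray | None = None) -> ExpressionMatrix:
    if sf is None:
        sf = size_factors(counts)
    vals = counts.counts / np.asarray(sf)[None, :]
    return ExpressionMatrix(list(counts.genes), list(counts.samples), vals, "normalized")


def vst(counts: CountMatrix, sf: np.ndarray | None = None) -> ExpressionMatrix:
    """log2(normalized count + 1): monotone per sample, finite everywhere."""
    if sf is None:
        sf = size_factors(counts)
    vals = np.log2(counts.counts / np.asarray(sf)[None, :] + 1.0)
    return ExpressionMatrix(list(counts.genes), list(counts.samples), vals, "vst")


def _treatment_coding(series: pd.Series, name: str, reference: str | None = None
                      ) -> tuple[np.ndarray, list[str]]:
    """Dummy columns for all but the reference (default: alphabetically first)."""
    levels = sorted(series.astype(str).unique())
    if reference is not None:
        if reference not in levels:
            raise ValueError(f"reference level {reference!r} not observed for {name!r}")
        levels = [reference] + [lv for lv in levels if lv != reference]
    cols = [(series.astype(str) == lv).to_numpy(float) for lv in levels[1:]]
    names = [f"{name}[{lv}]" for lv in levels[1:]]
    if cols:
        return np.column_stack(cols), names
    return np.empty((len(series), 0)), names


def design_matrix(metadata: pd.DataFrame, factors: list[str], *, intercept: bool = True,
                  reference: dict[str, str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded model matrix.

    The reference level of each factor is the alphabetically first one
    unless overridden via ``reference`` (factor -> level).
    """
    blocks, names = [], []
    if intercept:
        blocks.append(np.ones((len(metadata), 1)))
        names.append("Intercept")
    for f in factors:
        if f not in metadata.columns:
            raise ValueError(f"factor {f!r} not in metadata")
        x, n = _treatment_coding(metadata[f], f, (reference or {}).get(f))
        blocks.append(x)
        names.extend(n)
    return np.hstack(blocks), names


def remove_batch(
    expr: ExpressionMatrix,
    metadata: pd.DataFrame,
    batch_factor: str,
    design_factors: list[str],
) -> ExpressionMatrix:
    """Subtract the fitted batch component, gene-wise, keeping the design part.

    Least squares on [intercept | design | batch]; only the batch
    coefficients times the batch coding are removed.  Raises if the joint
    model matrix is rank-deficient (confounded factors).
    """
    x_design, names_d = design_matrix(metadata, design_factors, intercept=True)
    x_batch, names_b = design_matrix(metadata, [batch_factor], intercept=False)
    x = np.hstack([x_design, x_batch])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValueError(
            f"model matrix rank-deficient: batch {batch_factor!r} confounded "
            f"with design factors {design_factors}"
        )
    beta, *_ = np.linalg.lstsq(x, expr.values.T, rcond=None)
    n_d = x_design.shape[1]
    batch_part = x_batch @ beta[n_d:]
    corrected = expr.values - batch_part.T
    return ExpressionMatrix(list(expr.genes), list(expr.samples), corrected, "batch_corrected")
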