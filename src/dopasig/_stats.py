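"""Small shared statistical utilities."""

from __future__ import annotations

import numpy as np


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries are ignored (returned as NaN) and do not count toward the
    number of tests.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pm = p[mask]
    m = pm.size
    if m == 0:
        return out
    order = np.argsort(pm, kind="stable")
    ranked = pm[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[mask] = res
    return out


def benjamini_hochberg(pvals) -> np.ndarray:
    """Alias kept for readability at call sites."""
    return bh_adjust(np.asarray(pvals, dtype=float))
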