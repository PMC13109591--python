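"""Pre-ranked GSEA and hypergeometric over-representation analysis.

The ranking metric is sign(LFC) * -log10(p), capped at 300.  The GSEA
enrichment score is the extreme of the weighted Kolmogorov-Smirnov
running sum (hits increment by |score|^weight normalized over the set's
hits, misses decrement by 1/(N - n_set)).  The null is gene-set (tag)
permutation: random same-size sets drawn from the ranked universe.  NES
normalizes the observed ES by the mean |null ES| of matching sign, and
the nominal p comes from the matching-sign null tail with the +1
convention; FDR is BH across sets.  ORA reports the overlap k, the
enrichment ratio ER = (k/|hits|) / (|S|/|universe|) and the upper-tail
hypergeometric p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .io import GeneSetCollection

__all__ = ["RankedList", "make_ranked_list", "gsea_prerank", "ora", "es_score"]

_LOG10P_CAP = 300.0


@dataclass
class RankedList:
    """Genes in strictly decreasing score order (ties broken by name)."""

    genes: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores length mismatch")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in ranked list")
        if not np.isfinite(self.scores).all():
            raise ValueError("non-finite scores")

    def __len__(self) -> int:
        return len(self.genes)


def make_ranked_list(de: pd.DataFrame) -> RankedList:
    """Rank genes by sign(LFC) * min(-log10 p, 300), descending.

    Genes with NaN p (non-converged fits) are dropped; equal scores are
    ordered by gene identifier ascending so the list is deterministic.
    """
    ok = de["pvalue"].notna()
    sub = de.loc[ok, ["gene", "log2fc", "pvalue"]].copy()
    with np.errstate(divide="ignore"):
        mag = np.minimum(-np.log10(sub["pvalue"].to_numpy()), _LOG10P_CAP)
    score = np.sign(sub["log2fc"].to_numpy()) * mag
    sub["score"] = score
    sub = sub.sort_values(["score", "gene"], ascending=[False, True], kind="stable")
    return RankedList(list(sub["gene"]), sub["score"].to_numpy())


def es_score(
    scores: np.ndarray, hit_positions: np.ndarray, weight: float = 1.0
) -> tuple[float, int]:
    """Enrichment score of one gene set and the 0-based extremum position.

    ``scores`` are the full ranked scores; ``hit_positions`` the (sorted)
    ranks of the set members.  Runs in O(|S|) using the fact that the
    running sum is piecewise linear between hits.
    """
    n = len(scores)
    pos = np.sort(np.asarray(hit_positions))
    k = pos.size
    if k == 0:
        raise ValueError("empty gene set")
    if k >= n:
        raise ValueError("gene set spans the whole universe; miss step undefined")
    w = np.abs(scores[pos]) ** weight
    total = w.sum()
    if total <= 0:
        # all hit scores exactly zero: fall back to equal increments
        w = np.ones(k)
        total = float(k)
    cum_hit = np.cumsum(w) / total
    miss_step = 1.0 / (n - k)
    # value just after hit i (at position pos[i]) and just before it
    after = cum_hit - (pos + 1 - np.arange(1, k + 1)) * miss_step
    before = np.concatenate([[0.0], cum_hit[:-1]]) - (pos - np.arange(k)) * miss_step
    cand = np.concatenate([after, before])
    idx = int(np.argmax(np.abs(cand)))
    es = float(cand[idx])
    es_pos = int(pos[idx % k])
    return es, es_pos


def _null_es(
    scores: np.ndarray, set_size: int, n_perm: int, weight: float,
    rng: np.random.Generator,
) -> np.ndarray:
    n = len(scores)
    null = np.empty(n_perm)
    for b in range(n_perm):
        pos = rng.choice(n, size=set_size, replace=False)
        null[b], _ = es_score(scores, pos, weight)
    return null


def gsea_prerank(
    ranked: RankedList,
    sets: GeneSetCollection,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 5,
    max_size: int = 5000,
) -> pd.DataFrame:
    """Pre-ranked GSEA over a gene-set collection.

    Each set is intersected with the ranked universe and skipped (with a
    warning) if empty or outside [min_size, max_size] after intersection.
    """
    rank_of = {g: i for i, g in enumerate(ranked.genes)}
    n = len(ranked)
    rng = np.random.default_rng(seed)
    rows = []
    null_cache: dict[int, np.ndarray] = {}
    for name, genes in sets.items():
        pos = np.array(sorted(rank_of[g] for g in genes if g in rank_of), dtype=int)
        k = pos.size
        if k == 0:
            warnings.warn(f"gene set {name!r} empty after intersection; skipped")
            continue
        if k >= n:
            raise ValueError(f"gene set {name!r} equals the whole ranked universe")
        if not (min_size <= k <= max_size):
            warnings.warn(f"gene set {name!r} size {k} outside [{min_size}, {max_size}]; skipped")
            continue
        es, es_pos = es_score(ranked.scores, pos, weight)
        if k not in null_cache:
            null_cache[k] = _null_es(ranked.scores, k, n_perm, weight, rng)
        null = null_cache[k]
        same_sign = null >= 0 if es >= 0 else null < 0
        n_same = int(same_sign.sum())
        if n_same:
            tail = np.abs(null[same_sign]) >= abs(es)
            pval = (1.0 + tail.sum()) / (1.0 + n_same)
            denom = np.abs(null[same_sign]).mean()
            nes = es / denom if denom > 0 else 0.0
        else:
            pval = 1.0 / (1.0 + n_perm)
            nes = 0.0
        if es >= 0:
            leading = [ranked.genes[i] for i in pos if i <= es_pos]
        else:
            leading = [ranked.genes[i] for i in pos if i >= es_pos]
        rows.append(
            {
                "set": name,
                "size": k,
                "es": es,
                "nes": nes,
                "pvalue": pval,
                "leading_edge": ",".join(leading),
            }
        )
    res = pd.DataFrame(rows, columns=["set", "size", "es", "nes", "pvalue", "leading_edge"])
    if len(res):
        res["fdr"] = bh_adjust(res["pvalue"].to_numpy())
    else:
        res["fdr"] = []
    return res


def ora(
    hits: list[str],
    universe: list[str],
    sets: GeneSetCollection,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a hit list in each gene set."""
    uni = set(universe)
    hit_set = set(hits)
    if not hit_set or not uni:
        raise ValueError("hits and universe must be non-empty")
    if not hit_set <= uni:
        raise ValueError("hits must be a subset of the universe")
    n_uni, n_hits = len(uni), len(hit_set)
    rows = []
    for name, genes in sets.items():
        s = set(genes) & uni
        k = len(hit_set & s)
        if not s:
            continue
        er = (k / n_hits) / (len(s) / n_uni)
        pval = float(stats.hypergeom.sf(k - 1, n_uni, len(s), n_hits)) if k > 0 else 1.0
        rows.append({"set": name, "set_size": len(s), "overlap": k,
                     "enrichment_ratio": er, "pvalue": pval})
    res = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "enrichment_ratio", "pvalue"])
    if len(res):
        res["fdr"] = bh_adjust(res["pvalue"].to_numpy())
    else:
        res["fdr"] = []
    return res
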