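"""Signature derivation: differentiation markers and condition intersections.

Differentiation signatures come from the reference time course: genes
up-regulated (down-regulated) at every neuronal time point versus the
progenitor baseline form the "neurons" ("progenitors") set.  The six
condition-specific signatures apply a fixed intersection algebra over the
four cohort contrasts (PD vs healthy, LRRK2 vs healthy, Parkin vs
healthy, LRRK2 vs Parkin); genes admitted by more than one rule are then
removed from all of them, so the final signatures are pairwise disjoint
regardless of any removal order.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .diffexp import threshold_degs
from .io import GeneSetCollection

__all__ = [
    "GeneSignature",
    "derive_differentiation_signatures",
    "refine_condition_signatures",
    "signatures_to_gmt",
]

CONTRASTS = ("PD_vs_healthy", "LRRK2_vs_healthy", "Parkin_vs_healthy", "LRRK2_vs_Parkin")


@dataclass
class GeneSignature:
    name: str
    genes: list[str]
    direction: str  # up / down relative to the first-named group
    provenance: str = ""

    def __post_init__(self) -> None:
        self.genes = sorted(set(self.genes))

    def __len__(self) -> int:
        return len(self.genes)


def derive_differentiation_signatures(
    timepoint_results: dict[str, pd.DataFrame],
    fdr: float = 0.05,
    lfc: float = 1.0,
) -> tuple[GeneSignature, GeneSignature]:
    """Consistency intersections over the four day0-vs-week contrasts.

    ``timepoint_results`` maps time point label -> DE result frame of
    that time point versus the progenitor baseline (positive log2 fold
    change = higher in the neuronal time point).
    """
    if len(timepoint_results) < 4:
        raise ValueError(
            f"need all four neuronal time points, got {sorted(timepoint_results)}"
        )
    up_sets, down_sets = [], []
    for label in sorted(timepoint_results):
        up, down = threshold_degs(timepoint_results[label], fdr=fdr, lfc=lfc)
        up_sets.append(set(up))
        down_sets.append(set(down))
    neurons = set.intersection(*up_sets)
    progenitors = set.intersection(*down_sets)
    prov = f"intersection over {sorted(timepoint_results)} at FDR<{fdr}, |LFC|>{lfc}"
    return (
        GeneSignature("neurons", sorted(neurons), "up", prov),
        GeneSignature("progenitors", sorted(progenitors), "down", prov),
    )


@dataclass
class _Rule:
    name: str
    direction: str
    parts: list[tuple[str, str]]  # (contrast, up|down)

    def describe(self) -> str:
        return " & ".join(f"{d}({c})" for c, d in self.parts)


_RULES = [
    _Rule("PD_up", "up", [("PD_vs_healthy", "up"), ("LRRK2_vs_healthy", "up"), ("Parkin_vs_healthy", "up")]),
    _Rule("PD_down", "down", [("PD_vs_healthy", "down"), ("LRRK2_vs_healthy", "down"), ("Parkin_vs_healthy", "down")]),
    _Rule("LRRK2_up", "up", [("LRRK2_vs_healthy", "up"), ("LRRK2_vs_Parkin", "up")]),
    _Rule("LRRK2_down", "down", [("LRRK2_vs_healthy", "down"), ("LRRK2_vs_Parkin", "down")]),
    _Rule("Parkin_up", "up", [("Parkin_vs_healthy", "up"), ("LRRK2_vs_Parkin", "down")]),
    _Rule("Parkin_down", "down", [("Parkin_vs_healthy", "down"), ("LRRK2_vs_Parkin", "up")]),
]


def refine_condition_signatures(
    deg_lists: dict[str, dict[str, list[str]]],
) -> dict[str, GeneSignature]:
    """Six non-overlapping condition signatures from four contrast DEG lists.

    ``deg_lists`` maps contrast name -> {"up": [...], "down": [...]}.
    PD_up/PD_down require consistency across all three versus-healthy
    contrasts; mutation-specific sets combine the versus-healthy and the
    LRRK2-versus-Parkin contrast.  The PD_down set is the healthy-control
    signature (genes higher in healthy).  Any gene matching two or more
    rules is dropped from every signature.
    """
    missing = [c for c in CONTRASTS if c not in deg_lists]
    if missing:
        raise ValueError(f"missing contrast(s): {missing}")
    sets: dict[str, set[str]] = {}
    for rule in _RULES:
        parts = [set(deg_lists[c][d]) for c, d in rule.parts]
        sets[rule.name] = set.intersection(*parts)
    counts: dict[str, int] = {}
    for s in sets.values():
        for g in s:
            counts[g] = counts.get(g, 0) + 1
    dupes = {g for g, n in counts.items() if n > 1}
    out: dict[str, GeneSignature] = {}
    for rule in _RULES:
        genes = sorted(sets[rule.name] - dupes)
        out[rule.name] = GeneSignature(
            rule.name, genes, rule.direction,
            provenance=rule.describe() + ("; overlaps removed" if dupes else ""),
        )
    return out


def signatures_to_gmt(signatures: dict[str, GeneSignature] | list[GeneSignature]) -> GeneSetCollection:
    items = signatures.values() if isinstance(signatures, dict) else signatures
    return GeneSetCollection({s.name: list(s.genes) for s in items if len(s)})
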