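"""Readers and writers for the external formats the pipeline touches.

Counts and metadata travel as TSV, gene sets as GMT, protein-interaction
edges as a STRING-style three-column TSV, and pathway weights as a long
TSV.  Gene identifiers are opaque strings throughout; no identifier
mapping is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "CountMatrix",
    "GeneSetCollection",
    "METADATA_COLUMNS",
    "read_counts",
    "write_counts",
    "read_metadata",
    "write_metadata",
    "read_gmt",
    "write_gmt",
    "read_edges",
    "write_edges",
    "read_weights",
    "write_weights",
    "load_config",
    "save_config",
]


class FormatError(ValueError):
    """A file violated the expected dialect or an invariant."""


# --------------------------------------------------------------------------
# count matrix


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix.

    Invariants: unique gene and sample identifiers, non-negative integer
    counts, consistent dimensions.  Enforced at construction.
    """

    genes: list[str]
    samples: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        self.samples = [str(s) for s in self.samples]
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.genes), len(self.samples)):
            raise FormatError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        dup = _first_duplicate(self.genes)
        if dup is not None:
            raise FormatError(f"duplicate gene identifier: {dup}")
        dup = _first_duplicate(self.samples)
        if dup is not None:
            raise FormatError(f"duplicate sample identifier: {dup}")
        if not np.issubdtype(counts.dtype, np.integer):
            if np.isnan(counts.astype(float)).any():
                i, j = np.argwhere(np.isnan(counts.astype(float)))[0]
                raise FormatError(
                    f"NaN count at gene {self.genes[i]!r}, sample {self.samples[j]!r}"
                )
            rounded = np.rint(counts)
            if not np.allclose(counts, rounded, rtol=0, atol=1e-9):
                i, j = np.argwhere(counts != rounded)[0]
                raise FormatError(
                    f"non-integer count at gene {self.genes[i]!r}, "
                    f"sample {self.samples[j]!r}: {counts[i, j]}"
                )
            counts = rounded.astype(np.int64)
        if (counts < 0).any():
            i, j = np.argwhere(counts < 0)[0]
            raise FormatError(
                f"negative count at gene {self.genes[i]!r}, sample {self.samples[j]!r}"
            )
        self.counts = counts.astype(np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genes, columns=self.samples)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy())

    def subset_samples(self, samples: Iterable[str]) -> "CountMatrix":
        samples = list(samples)
        idx = [self.samples.index(s) for s in samples]
        return CountMatrix(list(self.genes), samples, self.counts[:, idx])


def _first_duplicate(items: list[str]) -> str | None:
    seen: set[str] = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return None


def read_counts(path: str | Path) -> CountMatrix:
    """Read a genes x samples TSV (header = sample ids, first column = gene ids)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(list(frame.index.astype(str)), list(frame.columns.astype(str)), frame.to_numpy())


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    df = cm.to_frame()
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


# --------------------------------------------------------------------------
# sample metadata

METADATA_COLUMNS = (
    "sample_id",
    "condition",
    "mutation",
    "place",
    "replicate",
    "gender",
    "reprogramming",
)

_MUTATION_CONDITION = {"healthy": "healthy", "LRRK2": "PD", "Parkin": "PD"}


def validate_metadata(meta: pd.DataFrame, counts: CountMatrix | None = None) -> pd.DataFrame:
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"metadata missing columns: {missing}")
    meta = meta.copy()
    meta["sample_id"] = meta["sample_id"].astype(str)
    dup = _first_duplicate(list(meta["sample_id"]))
    if dup is not None:
        raise FormatError(f"duplicate sample_id in metadata: {dup}")
    bad = meta.loc[~meta["mutation"].isin(_MUTATION_CONDITION), "mutation"]
    if len(bad):
        raise FormatError(f"unknown mutation level: {bad.iloc[0]!r}")
    expected = meta["mutation"].map(_MUTATION_CONDITION)
    if not (meta["condition"] == expected).all():
        sid = meta.loc[meta["condition"] != expected, "sample_id"].iloc[0]
        raise FormatError(f"condition inconsistent with mutation for sample {sid!r}")
    if counts is not None:
        meta_ids = set(meta["sample_id"])
        count_ids = set(counts.samples)
        if meta_ids != count_ids:
            raise FormatError(
                f"metadata/count sample mismatch: only in counts {sorted(count_ids - meta_ids)[:3]}, "
                f"only in metadata {sorted(meta_ids - count_ids)[:3]}"
            )
        meta = meta.set_index("sample_id").loc[counts.samples].reset_index()
    return meta


def read_metadata(path: str | Path, counts: CountMatrix | None = None) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"replicate": str})
    return validate_metadata(meta, counts)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# gene sets (GMT)


@dataclass
class GeneSetCollection:
    """Named gene sets: set name -> unique gene list."""

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(set(genes)) != len(genes):
                raise FormatError(f"duplicate genes within set {name!r}")
            if not genes:
                raise FormatError(f"empty gene set {name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def items(self):
        return self.sets.items()


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read the standard GMT dialect: name TAB description TAB gene..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno}: fewer than 3 fields")
            name = fields[0]
            genes = [g for g in fields[2:] if g]
            if not genes:
                logger.warning("GMT line %d: empty set %r dropped", lineno, name)
                continue
            # keep first occurrence of each gene
            uniq = list(dict.fromkeys(genes))
            sets[name] = uniq
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection | Mapping[str, list[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    items = collection.items() if hasattr(collection, "items") else collection
    with open(path, "w") as fh:
        for name, genes in items:
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# --------------------------------------------------------------------------
# PPI edges


def read_edges(path: str | Path, score_threshold: int = 400, *,
               unit_scale: bool = False) -> pd.DataFrame:
    """Read a STRING-style edge TSV (node1, node2, combined_score).

    Scores are kept on the integer 0-1000 STRING scale; pass
    ``unit_scale=True`` if the file stores them on 0-1 (they are then
    multiplied by 1000 before thresholding).  Self-loops are dropped with a
    logged count; duplicate undirected pairs keep the maximum score;
    edges with score < ``score_threshold`` are removed.
    """
    edges = pd.read_csv(path, sep="\t")
    return filter_edges(edges, score_threshold, unit_scale=unit_scale)


def filter_edges(edges: pd.DataFrame, score_threshold: int = 400, *,
                 unit_scale: bool = False) -> pd.DataFrame:
    required = {"node1", "node2", "combined_score"}
    missing = required - set(edges.columns)
    if missing:
        raise FormatError(f"edge table missing columns: {sorted(missing)}")
    edges = edges.copy()
    edges["node1"] = edges["node1"].astype(str)
    edges["node2"] = edges["node2"].astype(str)
    score = edges["combined_score"].astype(float)
    if unit_scale:
        score = score * 1000.0
    if ((score < 0) | (score > 1000)).any():
        raise FormatError("combined_score outside [0, 1000]")
    edges["combined_score"] = score
    loops = edges["node1"] == edges["node2"]
    if loops.any():
        logger.warning("dropped %d self-loop edges", int(loops.sum()))
        edges = edges.loc[~loops]
    # canonical undirected key, keep max score
    a = edges[["node1", "node2"]].min(axis=1)
    b = edges[["node1", "node2"]].max(axis=1)
    edges = edges.assign(node1=a, node2=b)
    edges = (
        edges.groupby(["node1", "node2"], as_index=False)["combined_score"].max()
    )
    edges = edges.loc[edges["combined_score"] >= score_threshold]
    return edges.reset_index(drop=True)


def write_edges(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# pathway weights


def read_weights(path: str | Path) -> pd.DataFrame:
    """Read a long-format weight TSV (pathway, gene, weight)."""
    w = pd.read_csv(path, sep="\t")
    required = {"pathway", "gene", "weight"}
    missing = required - set(w.columns)
    if missing:
        raise FormatError(f"weight table missing columns: {sorted(missing)}")
    if w.duplicated(["pathway", "gene"]).any():
        pair = w.loc[w.duplicated(["pathway", "gene"]), ["pathway", "gene"]].iloc[0]
        raise FormatError(f"duplicate (pathway, gene) pair: {tuple(pair)}")
    if not np.isfinite(w["weight"].astype(float)).all():
        raise FormatError("non-finite pathway weight")
    return w


def write_weights(weights: pd.DataFrame, path: str | Path) -> None:
    weights.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# configuration


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError("config must be a mapping")
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
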