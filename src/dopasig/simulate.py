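"""Synthetic data with planted ground truth.

Generates negative-binomial bulk RNA-seq count matrices shaped like the
two-laboratory iPSC-derived dopaminergic-neuron cohort (three mutation
groups, replicates, gender, reprogramming method), a progenitor-to-neuron
differentiation time course with monotone marker trajectories, planted
co-expression modules, stochastic-block-model protein-interaction graphs,
and toy pathway weight matrices.  Every generator is deterministic under a
fixed seed and returns the ground truth it planted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix, GeneSetCollection, validate_metadata

__all__ = [
    "SimulationDesign",
    "GroundTruth",
    "study_samples",
    "default_design",
    "simulate_counts",
    "simulate_timecourse",
    "simulate_ppi",
    "simulate_pathway_weights",
    "plant_pathway_shift",
]

TIMEPOINTS = ("day0", "wk2", "wk4", "wk6", "wk8")

# monotone fraction of the full marker effect reached at wk2..wk8
_TIME_RAMP = (0.5, 2.0 / 3.0, 5.0 / 6.0, 1.0)


@dataclass
class GroundTruth:
    """What the generator planted, keyed for downstream recovery checks."""

    degs: dict[str, dict[str, float]] = field(default_factory=dict)
    signatures: dict[str, list[str]] = field(default_factory=dict)
    modules: dict[str, list[str]] = field(default_factory=dict)
    pathway_shifts: dict[str, dict[str, float]] = field(default_factory=dict)
    batch_genes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "degs": self.degs,
            "signatures": self.signatures,
            "modules": self.modules,
            "pathway_shifts": self.pathway_shifts,
            "batch_genes": self.batch_genes,
        }


@dataclass
class SimulationDesign:
    """Full specification of one synthetic cohort.

    ``samples`` carries one row per sample with the seven metadata columns.
    ``effects`` is a long table (gene, factor, level, lfc): the NB mean of
    ``gene`` is multiplied by ``2**lfc`` in every sample whose metadata
    ``factor`` equals ``level``.  ``modules`` plants correlated blocks: for
    each named module a per-sample latent log2 factor ~ N(0, sd) scales all
    member genes, inducing co-expression.
    """

    n_genes: int
    samples: pd.DataFrame
    effects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene", "factor", "level", "lfc"])
    )
    modules: dict[str, tuple[list[str], float]] = field(default_factory=dict)
    baseline_log2_range: tuple[float, float] = (1.0, 12.0)
    dispersion_meanlog: float = float(np.log(0.1))
    dispersion_sdlog: float = 1.0
    libsize_log2_range: tuple[float, float] = (-0.5, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or len(self.samples) < 1:
            raise ValueError("design needs at least one gene and one sample")
        if len(self.effects) and not np.isfinite(self.effects["lfc"].astype(float)).all():
            raise ValueError("planted effects must be finite")

    @property
    def genes(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.n_genes)]


def study_samples() -> pd.DataFrame:
    """The 34-sample cohort layout: 12 healthy, 6 LRRK2, 16 Parkin across
    two differentiation sites (place A = 10 samples, place B = 24)."""
    lines = [
        # (line, mutation, gender, reprogramming, n_place_B, n_place_A)
        ("RG4S", "healthy", "M", "sendai", 4, 2),
        ("FF9S", "healthy", "F", "sendai", 4, 2),
        ("BL6S", "LRRK2", "M", "sendai", 4, 2),
        ("Tr5L", "Parkin", "M", "lentivirus", 4, 0),
        ("P12-1", "Parkin", "M", "lentivirus", 4, 2),
        ("Park14", "Parkin", "M", "sendai", 4, 2),
    ]
    rows = []
    for line, mut, gender, reprog, n_b, n_a in lines:
        for place, n in (("B", n_b), ("A", n_a)):
            for i in range(n):
                rows.append(
                    {
                        "sample_id": f"{line}_{place}{i + 1}",
                        "condition": "healthy" if mut == "healthy" else "PD",
                        "mutation": mut,
                        "place": place,
                        "replicate": str(i % 2 + 1),
                        "gender": gender,
                        "reprogramming": reprog,
                    }
                )
    return pd.DataFrame(rows)


def default_design(
    n_genes: int = 2000,
    *,
    samples: pd.DataFrame | None = None,
    n_lrrk2_deg: int = 60,
    n_parkin_deg: int = 60,
    n_shared_deg: int = 40,
    effect_lfc: float = 2.0,
    batch_frac: float = 0.1,
    batch_lfc: float = 1.0,
    seed: int = 0,
) -> SimulationDesign:
    """Study-shaped design: shared PD effects, mutation-specific effects,
    and an additive place (laboratory) batch shift on a random 10% of genes."""
    rng = np.random.default_rng(seed)
    if samples is None:
        samples = study_samples()
    genes = [f"G{i:05d}" for i in range(n_genes)]
    n_effect = n_lrrk2_deg + n_parkin_deg + n_shared_deg
    n_batch = int(round(batch_frac * n_genes))
    if n_effect + n_batch > n_genes:
        raise ValueError("more effect genes requested than genes in the universe")
    picked = rng.choice(n_genes, size=n_effect + n_batch, replace=False)
    lrrk2 = [genes[i] for i in picked[:n_lrrk2_deg]]
    parkin = [genes[i] for i in picked[n_lrrk2_deg : n_lrrk2_deg + n_parkin_deg]]
    shared = [genes[i] for i in picked[n_lrrk2_deg + n_parkin_deg : n_effect]]
    batch = [genes[i] for i in picked[n_effect:]]
    rows = []
    for gene_set, levels in ((lrrk2, ["LRRK2"]), (parkin, ["Parkin"]), (shared, ["LRRK2", "Parkin"])):
        for g in gene_set:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            for level in levels:
                rows.append({"gene": g, "factor": "mutation", "level": level, "lfc": sign * effect_lfc})
    for g in batch:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        rows.append({"gene": g, "factor": "place", "level": "B", "lfc": sign * batch_lfc})
    effects = pd.DataFrame(rows, columns=["gene", "factor", "level", "lfc"])
    return SimulationDesign(n_genes=n_genes, samples=samples, effects=effects, seed=seed)


def _effect_matrix(design: SimulationDesign, genes: list[str]) -> np.ndarray:
    """Per-gene, per-sample summed planted log2 effects."""
    log2fx = np.zeros((len(genes), len(design.samples)))
    gene_index = {g: i for i, g in enumerate(genes)}
    for _, row in design.effects.iterrows():
        g = str(row["gene"])
        if g not in gene_index:
            raise ValueError(f"effect gene {g!r} outside the simulated universe")
        active = (design.samples[row["factor"]].astype(str) == str(row["level"])).to_numpy()
        log2fx[gene_index[g], active] += float(row["lfc"])
    return log2fx


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB(mean mu, var mu + phi mu^2); phi == 0 degenerates to Poisson."""
    counts = np.empty(mu.shape, dtype=np.int64)
    poisson = phi <= 1e-12
    if poisson.any():
        counts[poisson] = rng.poisson(np.broadcast_to(mu, mu.shape)[poisson])
    nb = ~poisson
    if nb.any():
        r = 1.0 / phi[nb]
        p = r / (r + mu[nb])
        counts[nb] = rng.negative_binomial(r, p)
    return counts


def simulate_counts(design: SimulationDesign) -> tuple[CountMatrix, pd.DataFrame, GroundTruth]:
    """Draw a cohort count matrix from the planted negative-binomial model.

    mu_gs = s_s * q_g * 2**(sum of planted effects active in sample s
    + module latent factors), counts ~ NB(mu_gs, phi_g).
    """
    rng = np.random.default_rng(design.seed)
    genes = design.genes
    n_g, n_s = design.n_genes, len(design.samples)
    lo, hi = design.baseline_log2_range
    q = np.exp2(rng.uniform(lo, hi, size=n_g))
    phi = rng.lognormal(design.dispersion_meanlog, design.dispersion_sdlog, size=n_g)
    s = np.exp2(rng.uniform(*design.libsize_log2_range, size=n_s))
    log2fx = _effect_matrix(design, genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    truth_modules: dict[str, list[str]] = {}
    for mod_name, (members, sd) in design.modules.items():
        z = rng.normal(0.0, sd, size=n_s)
        for g in members:
            log2fx[gene_index[g]] += z
        truth_modules[mod_name] = list(members)
    mu = s[None, :] * q[:, None] * np.exp2(log2fx)
    counts = _nb_draw(rng, mu, np.repeat(phi[:, None], n_s, axis=1))
    meta = validate_metadata(design.samples.copy())
    cm = CountMatrix(genes, list(meta["sample_id"]), counts)

    truth = GroundTruth(modules=truth_modules)
    fx = design.effects
    mut_fx = fx[fx["factor"] == "mutation"]
    per_level: dict[str, dict[str, float]] = {"LRRK2": {}, "Parkin": {}}
    for _, row in mut_fx.iterrows():
        per_level.setdefault(str(row["level"]), {})[str(row["gene"])] = float(row["lfc"])
    lr, pk = per_level["LRRK2"], per_level["Parkin"]
    truth.degs["LRRK2_vs_healthy"] = dict(lr)
    truth.degs["Parkin_vs_healthy"] = dict(pk)
    truth.degs["LRRK2_vs_Parkin"] = {
        g: lr.get(g, 0.0) - pk.get(g, 0.0)
        for g in set(lr) | set(pk)
        if abs(lr.get(g, 0.0) - pk.get(g, 0.0)) > 0
    }
    # genes shifted the same way in both mutant groups drive the pooled PD contrast
    truth.degs["PD_vs_healthy"] = {
        g: lr[g] for g in set(lr) & set(pk) if np.sign(lr[g]) == np.sign(pk[g])
    }
    truth.batch_genes = sorted(set(fx.loc[fx["factor"] == "place", "gene"].astype(str)))
    return cm, meta, truth


def simulate_timecourse(
    n_genes: int,
    n_per_timepoint: int,
    n_neuron_markers: int,
    n_progenitor_markers: int,
    effect_size: float,
    seed: int,
    *,
    dispersion: float = 0.05,
) -> tuple[CountMatrix, pd.DataFrame, GroundTruth]:
    """Progenitor (day 0) to neuron (weeks 2-8) reference time course.

    Neuron markers rise monotonically with differentiation time, progenitor
    markers fall; all other genes are flat.  ``effect_size`` is the full
    log2 shift reached at week 8; week 2 already reaches half of it.
    """
    if n_neuron_markers + n_progenitor_markers > n_genes:
        raise ValueError("marker counts exceed the gene universe")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    picked = rng.choice(n_genes, size=n_neuron_markers + n_progenitor_markers, replace=False)
    neuron = [genes[i] for i in picked[:n_neuron_markers]]
    progenitor = [genes[i] for i in picked[n_neuron_markers:]]
    q = np.exp2(rng.uniform(3.0, 10.0, size=n_genes))
    time_labels = [t for t in TIMEPOINTS for _ in range(n_per_timepoint)]
    samples = [f"{t}_r{i + 1}" for t in TIMEPOINTS for i in range(n_per_timepoint)]
    log2fx = np.zeros((n_genes, len(samples)))
    gene_index = {g: i for i, g in enumerate(genes)}
    for j, t in enumerate(time_labels):
        if t == "day0":
            continue
        ramp = effect_size * _TIME_RAMP[TIMEPOINTS.index(t) - 1]
        for g in neuron:
            log2fx[gene_index[g], j] += ramp
        for g in progenitor:
            log2fx[gene_index[g], j] -= ramp
    mu = q[:, None] * np.exp2(log2fx)
    phi = np.full(mu.shape, dispersion)
    counts = _nb_draw(rng, mu, phi)
    cm = CountMatrix(genes, samples, counts)
    labels = pd.DataFrame({"sample_id": samples, "time": time_labels})
    truth = GroundTruth()
    if effect_size != 0:
        truth.signatures["neurons"] = sorted(neuron)
        truth.signatures["progenitors"] = sorted(progenitor)
    return cm, labels, truth


def simulate_ppi(
    n_nodes: int,
    n_communities: int,
    p_within: float,
    p_between: float,
    seed: int,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Planted-partition interaction graph with STRING-style scores.

    Within-community edges get scores in [600, 1000), between-community
    edges in [400, 600), so any threshold <= 400 keeps both kinds.
    """
    if p_within <= p_between:
        warnings.warn("p_within <= p_between: planted communities are unidentifiable")
    rng = np.random.default_rng(seed)
    nodes = [f"N{i:04d}" for i in range(n_nodes)]
    membership = np.sort(np.arange(n_nodes) % n_communities)
    rows = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            same = membership[i] == membership[j]
            p = p_within if same else p_between
            if rng.random() < p:
                lo, hi = (600, 1000) if same else (400, 600)
                rows.append({"node1": nodes[i], "node2": nodes[j],
                             "combined_score": float(rng.integers(lo, hi))})
    edges = pd.DataFrame(rows, columns=["node1", "node2", "combined_score"])
    truth = GroundTruth(
        modules={f"C{c}": [nodes[i] for i in range(n_nodes) if membership[i] == c]
                 for c in range(n_communities)}
    )
    return edges, truth


def simulate_pathway_weights(
    genes: list[str],
    n_pathways: int,
    genes_per_pathway: int,
    seed: int,
) -> pd.DataFrame:
    """Toy footprint weight matrix: disjoint member genes, signed weights."""
    if n_pathways * genes_per_pathway > len(genes):
        raise ValueError("not enough genes for disjoint pathways")
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(genes), size=n_pathways * genes_per_pathway, replace=False)
    rows = []
    for p in range(n_pathways):
        for k in range(genes_per_pathway):
            g = genes[picked[p * genes_per_pathway + k]]
            w = rng.normal(0.0, 1.0)
            rows.append({"pathway": f"P{p}", "gene": g, "weight": float(w)})
    return pd.DataFrame(rows)


def plant_pathway_shift(
    design: SimulationDesign,
    weights: pd.DataFrame,
    pathway: str,
    factor: str,
    level: str,
    scale: float,
) -> GroundTruth:
    """Shift a pathway's targets in one group, proportionally to their weights.

    Appends per-gene effects lfc = scale * w_g / max|w| for every member of
    ``pathway`` to the design (in place) and returns the planted truth.
    """
    w = weights.loc[weights["pathway"] == pathway]
    if w.empty:
        raise ValueError(f"pathway {pathway!r} not in the weight table")
    wmax = w["weight"].abs().max()
    rows = [
        {"gene": row["gene"], "factor": factor, "level": level,
         "lfc": scale * float(row["weight"]) / wmax}
        for _, row in w.iterrows()
    ]
    new = pd.DataFrame(rows, columns=["gene", "factor", "level", "lfc"])
    if design.effects.empty:
        design.effects = new
    else:
        design.effects = pd.concat([design.effects, new], ignore_index=True)
    truth = GroundTruth(pathway_shifts={pathway: {factor: scale, "level": level}})
    return truth


def signatures_to_collection(truth: GroundTruth) -> GeneSetCollection:
    return GeneSetCollection({k: list(v) for k, v in truth.signatures.items() if v})
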