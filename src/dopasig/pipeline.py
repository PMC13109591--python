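"""End-to-end study-shaped run on synthetic data with a run manifest.

One config drives: cohort simulation -> normalization -> exploratory
structure (PCA, PERMANOVA) -> differential expression for the four
contrasts -> signature algebra -> GSEA of the differentiation signatures
-> ORA -> PPI module construction with MCL -> co-expression eigengenes
-> pathway-activity GLM.  Every stage writes TSV outputs under the run
directory; the manifest records the config hash, seeds, per-stage
outputs with checksums, and headline summaries.  Identical config and
seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coexpr as cx
from . import diffexp, enrichment, explore, normalize, paa, ppi, signatures, simulate
from .io import GeneSetCollection, write_counts, write_gmt, write_metadata

__all__ = ["default_config", "run_all"]

CONTRAST_SPECS = {
    "PD_vs_healthy": ("condition", "PD", "healthy"),
    "LRRK2_vs_healthy": ("mutation", "LRRK2", "healthy"),
    "Parkin_vs_healthy": ("mutation", "Parkin", "healthy"),
    "LRRK2_vs_Parkin": ("mutation", "LRRK2", "Parkin"),
}


def default_config(seed: int = 0) -> dict:
    return {
        "seed": int(seed),
        "simulation": {
            "n_genes": 1500,
            "n_lrrk2_deg": 50,
            "n_parkin_deg": 50,
            "n_shared_deg": 40,
            "effect_lfc": 2.0,
            "batch_frac": 0.1,
            "batch_lfc": 1.0,
            "n_modules": 2,
            "module_size": 40,
            "module_sd": 0.6,
            "n_pathways": 4,
            "genes_per_pathway": 25,
            "pathway_shift": 1.5,
            "timecourse": {
                "n_genes": 600,
                "n_per_timepoint": 4,
                "n_neuron_markers": 25,
                "n_progenitor_markers": 25,
                "effect_size": 3.0,
            },
            "ppi": {"n_nodes": 120, "n_communities": 3,
                    "p_within": 0.35, "p_between": 0.02},
        },
        "thresholds": {"fdr": 0.05, "lfc": 1.0},
        "permutations": {"permanova": 999, "gsea": 1000, "wsum": 1000},
        "contrasts": list(CONTRAST_SPECS),
        "de_factors": ["place", "replicate"],
        "ppi": {"score_threshold": 400, "inflation": 2.0, "max_added": 50},
        "coexpr": {"top_n": 600, "min_size": 20, "method": "pearson"},
        "paa": {"method": "ulm"},
    }


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _validate(cfg: dict) -> None:
    for key in ("seed", "simulation", "thresholds", "permutations", "contrasts"):
        if key not in cfg:
            raise ValueError(f"config missing required key {key!r}")
    unknown = [c for c in cfg["contrasts"] if c not in CONTRAST_SPECS]
    if unknown:
        raise ValueError(f"unknown contrast(s) in config: {unknown}")


def run_all(config: dict, out_dir: str | Path) -> dict:
    """Execute every stage; return the manifest (also written as JSON)."""
    _validate(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    fdr_thr = float(config["thresholds"]["fdr"])
    lfc_thr = float(config["thresholds"]["lfc"])
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": seed,
        "stages": {},
        "summary": {},
        "warnings": [],
    }
    outputs: dict[str, Path] = {}

    def record(stage: str, name: str, path: Path) -> None:
        outputs[f"{stage}/{name}"] = path
        manifest["stages"].setdefault(stage, {})[name] = str(path.name)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # --- simulate -----------------------------------------------------
        sim = config["simulation"]
        design = simulate.default_design(
            sim["n_genes"],
            n_lrrk2_deg=sim["n_lrrk2_deg"],
            n_parkin_deg=sim["n_parkin_deg"],
            n_shared_deg=sim["n_shared_deg"],
            effect_lfc=sim["effect_lfc"],
            batch_frac=sim["batch_frac"],
            batch_lfc=sim["batch_lfc"],
            seed=seed,
        )
        rng = np.random.default_rng(seed + 101)
        genes = design.genes
        used = set(design.effects["gene"])
        free = [g for g in genes if g not in used]
        for m in range(sim["n_modules"]):
            members = free[m * sim["module_size"]:(m + 1) * sim["module_size"]]
            design.modules[f"planted_mod{m + 1}"] = (members, sim["module_sd"])
        pw_pool = free[sim["n_modules"] * sim["module_size"]:]
        weights = simulate.simulate_pathway_weights(
            pw_pool, sim["n_pathways"], sim["genes_per_pathway"], seed + 7
        )
        for level in ("LRRK2", "Parkin"):
            simulate.plant_pathway_shift(
                design, weights, "P0", "mutation", level, sim["pathway_shift"]
            )
        counts, meta, truth = simulate.simulate_counts(design)
        write_counts(counts, out / "counts.tsv")
        write_metadata(meta, out / "metadata.tsv")
        (out / "truth.json").write_text(json.dumps(truth.to_dict(), sort_keys=True, indent=1))
        record("simulate", "counts", out / "counts.tsv")
        record("simulate", "metadata", out / "metadata.tsv")
        record("simulate", "truth", out / "truth.json")

        # --- normalize ----------------------------------------------------
        sf = normalize.size_factors(counts)
        vst = normalize.vst(counts, sf)
        corrected = normalize.remove_batch(vst, meta, "place", ["mutation"])
        vst.to_frame().to_csv(out / "vst.tsv", sep="\t")
        corrected.to_frame().to_csv(out / "vst_batch_corrected.tsv", sep="\t")
        record("normalize", "vst", out / "vst.tsv")
        record("normalize", "vst_corrected", out / "vst_batch_corrected.tsv")

        # --- explore ------------------------------------------------------
        pca_res = explore.pca(vst, n_components=2)
        pca_res.scores.to_csv(out / "pca_scores.tsv", sep="\t")
        perm = explore.permanova(
            vst, meta, ["mutation", "place", "gender", "reprogramming"],
            n_perm=int(config["permutations"]["permanova"]), seed=seed + 11,
        )
        perm.table.to_csv(out / "permanova.tsv", sep="\t", index=False)
        perm_corr = explore.permanova(
            corrected, meta, ["mutation", "place"],
            n_perm=int(config["permutations"]["permanova"]), seed=seed + 12,
        )
        perm_corr.table.to_csv(out / "permanova_batch_corrected.tsv", sep="\t", index=False)
        record("explore", "pca", out / "pca_scores.tsv")
        record("explore", "permanova", out / "permanova.tsv")
        record("explore", "permanova_corrected", out / "permanova_batch_corrected.tsv")

        # --- differential expression ---------------------------------------
        de_results: dict[str, pd.DataFrame] = {}
        deg_lists: dict[str, dict[str, list[str]]] = {}
        for name in config["contrasts"]:
            factor, lv_a, lv_b = CONTRAST_SPECS[name]
            factors = list(config["de_factors"]) + [factor]
            res = diffexp.nb_wald(counts, meta, factors, (factor, lv_a, lv_b), sf=sf)
            res.to_csv(out / f"de_{name}.tsv", sep="\t", index=False)
            record("de", name, out / f"de_{name}.tsv")
            de_results[name] = res
            up, down = diffexp.threshold_degs(res, fdr=fdr_thr, lfc=lfc_thr)
            deg_lists[name] = {"up": up, "down": down}
        manifest["summary"]["deg_counts"] = {
            c: {"up": len(v["up"]), "down": len(v["down"])} for c, v in deg_lists.items()
        }

        # --- signatures ----------------------------------------------------
        tc_cfg = sim["timecourse"]
        tc_counts, tc_labels, tc_truth = simulate.simulate_timecourse(
            tc_cfg["n_genes"], tc_cfg["n_per_timepoint"],
            tc_cfg["n_neuron_markers"], tc_cfg["n_progenitor_markers"],
            tc_cfg["effect_size"], seed + 23,
        )
        tc_sf = normalize.size_factors(tc_counts)
        tc_results = {}
        for tp in simulate.TIMEPOINTS[1:]:
            keep = tc_labels["time"].isin(["day0", tp])
            sub_meta = tc_labels.loc[keep].reset_index(drop=True)
            sub_counts = tc_counts.subset_samples(sub_meta["sample_id"])
            res = diffexp.nb_wald(sub_counts, sub_meta, ["time"], ("time", tp, "day0"))
            tc_results[tp] = res
        neurons, progenitors = signatures.derive_differentiation_signatures(
            tc_results, fdr=fdr_thr, lfc=lfc_thr
        )
        condition_sigs = signatures.refine_condition_signatures(deg_lists)
        all_sigs = {s.name: s for s in (neurons, progenitors)} | condition_sigs
        gmt = signatures.signatures_to_gmt(all_sigs)
        write_gmt(gmt, out / "signatures.gmt")
        prov = pd.DataFrame(
            [{"name": s.name, "direction": s.direction, "n_genes": len(s),
              "provenance": s.provenance} for s in all_sigs.values()]
        )
        prov.to_csv(out / "signature_provenance.tsv", sep="\t", index=False)
        record("signatures", "gmt", out / "signatures.gmt")
        record("signatures", "provenance", out / "signature_provenance.tsv")
        manifest["summary"]["signature_sizes"] = {s.name: len(s) for s in all_sigs.values()}

        # --- GSEA + ORA ------------------------------------------------------
        n_perm_gsea = int(config["permutations"]["gsea"])
        diff_sets = GeneSetCollection(
            {k: v for k, v in {"neurons": neurons.genes,
                               "progenitors": progenitors.genes}.items() if v}
        )
        ranked_lists = {c: enrichment.make_ranked_list(r) for c, r in de_results.items()}
        gsea_frames = []
        if len(diff_sets):
            for c, rl in ranked_lists.items():
                g = enrichment.gsea_prerank(rl, diff_sets, n_perm=n_perm_gsea, seed=seed + 31)
                g.insert(0, "contrast", c)
                gsea_frames.append(g)
        gsea_all = (pd.concat(gsea_frames, ignore_index=True) if gsea_frames
                    else pd.DataFrame())
        gsea_all.to_csv(out / "gsea_differentiation.tsv", sep="\t", index=False)
        record("gsea", "differentiation", out / "gsea_differentiation.tsv")

        universe = list(de_results["PD_vs_healthy"]["gene"])
        ora_sets = GeneSetCollection(
            {p: list(g) for p, g in weights.groupby("pathway")["gene"].apply(list).items()}
        )
        pd_hits = deg_lists["PD_vs_healthy"]["up"] + deg_lists["PD_vs_healthy"]["down"]
        if pd_hits:
            ora_res = enrichment.ora(pd_hits, universe, ora_sets)
        else:
            ora_res = pd.DataFrame()
        ora_res.to_csv(out / "ora_pd.tsv", sep="\t", index=False)
        record("ora", "pd", out / "ora_pd.tsv")

        # --- PPI -------------------------------------------------------------
        ppi_cfg = sim["ppi"]
        seeds_deg = sorted(set(deg_lists["PD_vs_healthy"]["up"])
                           | set(deg_lists["PD_vs_healthy"]["down"]))
        n_nodes = int(ppi_cfg["n_nodes"])
        fill = [g for g in genes if g not in seeds_deg]
        node_genes = (seeds_deg + fill)[:n_nodes]
        edges, _ = simulate.simulate_ppi(
            n_nodes, int(ppi_cfg["n_communities"]),
            float(ppi_cfg["p_within"]), float(ppi_cfg["p_between"]), seed + 41,
        )
        rename = {f"N{i:04d}": node_genes[i] for i in range(n_nodes)}
        edges["node1"] = edges["node1"].map(rename)
        edges["node2"] = edges["node2"].map(rename)
        thr = int(config["ppi"]["score_threshold"])
        core = ppi.build_seeded_network(edges, [g for g in seeds_deg if g in set(node_genes)], thr)
        expanded = ppi.expand_network(core, edges, order=2,
                                      max_added=int(config["ppi"]["max_added"]), threshold=thr)
        partition = ppi.mcl(expanded, inflation=float(config["ppi"]["inflation"]))
        membership = pd.DataFrame(
            [{"node": n, "module": m} for m, ns in partition.modules.items() for n in ns]
        )
        membership.to_csv(out / "ppi_modules.tsv", sep="\t", index=False)
        record("ppi", "modules", out / "ppi_modules.tsv")
        module_gsea = ppi.validate_modules_gsea(
            partition, ranked_lists, n_perm=n_perm_gsea, seed=seed + 43
        )
        module_gsea.to_csv(out / "ppi_module_gsea.tsv", sep="\t", index=False)
        record("ppi", "module_gsea", out / "ppi_module_gsea.tsv")
        manifest["summary"]["ppi_module_count"] = len(partition)

        # --- co-expression ----------------------------------------------------
        cxc = config["coexpr"]
        network = cx.build_network(corrected, method=cxc["method"], top_n=int(cxc["top_n"]))
        modules = cx.detect_modules(network, min_size=int(cxc["min_size"]))
        eg = cx.eigengenes(network.expr, modules)
        eg.values.to_csv(out / "eigengenes.tsv", sep="\t")
        mt = cx.module_trait(eg, meta, ["condition", "mutation"])
        mt.to_csv(out / "module_trait.tsv", sep="\t", index=False)
        member = pd.DataFrame(
            [{"gene": g, "module": m} for m, gs in modules.modules.items() for g in gs]
        )
        member.to_csv(out / "coexpr_modules.tsv", sep="\t", index=False)
        record("coexpr", "modules", out / "coexpr_modules.tsv")
        record("coexpr", "eigengenes", out / "eigengenes.tsv")
        record("coexpr", "module_trait", out / "module_trait.tsv")
        manifest["summary"]["coexpr_module_count"] = sum(
            1 for m in modules.modules if m != cx.GREY
        )

        # --- pathway activity -------------------------------------------------
        activity = paa.score_pathways(
            corrected, weights, method=config["paa"]["method"],
            n_perm=int(config["permutations"]["wsum"]), seed=seed + 53,
        )
        activity.values.to_csv(out / "paa_scores.tsv", sep="\t")
        assoc = paa.paa_glm(activity, meta)
        assoc.to_csv(out / "paa_glm.tsv", sep="\t", index=False)
        mv = paa.modules_vs_paa(eg, activity)
        mv.to_csv(out / "paa_vs_modules.tsv", sep="\t", index=False)
        record("paa", "scores", out / "paa_scores.tsv")
        record("paa", "glm", out / "paa_glm.tsv")
        record("paa", "vs_modules", out / "paa_vs_modules.tsv")
        sig_paths = assoc.loc[assoc["fdr"] < fdr_thr, ["pathway", "coefficient"]]
        manifest["summary"]["significant_pathway_terms"] = [
            f"{r.pathway}:{r.coefficient}" for r in sig_paths.itertuples()
        ]

        manifest["warnings"] = sorted({str(w.message) for w in caught})

    manifest["checksums"] = {k: _checksum(p) for k, p in sorted(outputs.items())}
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest
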