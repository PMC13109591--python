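from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from dopasig.explore import batch_screen, marker_panel, pca, permanova
from dopasig.io import CountMatrix
from dopasig.normalize import ExpressionMatrix


def _expr(values, samples=None):
    genes = [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(genes, samples, np.asarray(values, float), "vst")


def exhaustive_permanova_one_factor(xs: np.ndarray, labels: np.ndarray):
    """Independent single-factor PERMANOVA via group sums over squared
    distances (Anderson's formulation) and full permutation enumeration."""
    n = len(labels)
    d2 = ((xs[:, None, :] - xs[None, :, :]) ** 2).sum(axis=2)
    def ss_parts(lab):
        ss_total = d2[np.triu_indices(n, 1)].sum() / n
        ss_within = 0.0
        for lv in np.unique(lab):
            idx = np.where(lab == lv)[0]
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        return ss_total, ss_total - ss_within
    ss_total, ss_a = ss_parts(labels)
    a = len(np.unique(labels))
    f_obs = (ss_a / (a - 1)) / ((ss_total - ss_a) / (n - a))
    count = 0
    total = 0
    for perm in permutations(range(n)):
        _, ss_p = ss_parts(labels[list(perm)])
        f_p = (ss_p / (a - 1)) / ((ss_total - ss_p) / (n - a))
        count += f_p >= f_obs - 1e-12
        total += 1
    return ss_a / ss_total, f_obs, count / total


class TestPca:
    def test_line_data_pc1_full_variance(self):
        t = np.linspace(0, 1, 6)
        values = np.outer([1.0, 2.0, -1.0], t)
        res = pca(_expr(values), 2)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_reconstruction_identity(self, rng):
        values = rng.normal(size=(15, 8))
        res = pca(_expr(values), 8)
        recon = (res.scores.to_numpy() @ res.loadings.to_numpy().T).T
        centered = values - values.mean(axis=1, keepdims=True)
        np.testing.assert_allclose(recon, centered, atol=1e-8)

    def test_identical_samples_degenerate_warns(self):
        values = np.tile([[1.0], [2.0]], (1, 2))
        with pytest.warns(UserWarning, match="degenerate"):
            res = pca(_expr(values), 1)
        assert res.explained_variance_ratio[0] == 0.0

    def test_too_many_components_errors(self, rng):
        with pytest.raises(ValueError, match="n_components"):
            pca(_expr(rng.normal(size=(5, 3))), 4)

    def test_sign_convention_deterministic(self, rng):
        values = rng.normal(size=(10, 6))
        r1 = pca(_expr(values), 2)
        r2 = pca(_expr(-(-values)), 2)
        pd.testing.assert_frame_equal(r1.scores, r2.scores)
        for k in ("PC1", "PC2"):
            col = r1.loadings[k]
            assert col[col.abs().idxmax()] > 0


class TestPermanova:
    def _meta(self, labels, factor="mutation"):
        n = len(labels)
        meta = pd.DataFrame({
            "sample_id": [f"s{j}" for j in range(n)],
            factor: labels,
        })
        return meta

    def test_matches_exhaustive_oracle_small_n(self, rng):
        xs = rng.normal(size=(6, 4))
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        expr = _expr(xs.T)
        meta = self._meta(labels)
        res = permanova(expr, meta, ["mutation"], n_perm=4999, seed=1)
        r2_oracle, f_oracle, p_oracle = exhaustive_permanova_one_factor(xs, labels)
        row = res.table.iloc[0]
        assert row["r2"] == pytest.approx(r2_oracle, abs=1e-10)
        assert row["pseudo_f"] == pytest.approx(f_oracle, abs=1e-10)
        # Monte-Carlo p within sampling error of the exhaustive tail
        assert abs(row["pvalue"] - p_oracle) < 0.05

    def test_separated_clusters_strong_signal(self, rng):
        xs = rng.normal(size=(12, 5))
        xs[:6] += 50.0
        labels = np.array(["a"] * 6 + ["b"] * 6)
        res = permanova(_expr(xs.T), self._meta(labels), ["mutation"],
                        n_perm=199, seed=2)
        row = res.table.iloc[0]
        assert row["r2"] > 0.5
        assert row["pvalue"] == pytest.approx(1 / 200)

    def test_sequential_total_invariant_to_order(self, rng):
        xs = rng.normal(size=(12, 6))
        meta = pd.DataFrame({
            "sample_id": [f"s{j}" for j in range(12)],
            "f1": ["a", "b"] * 6,
            "f2": ["x"] * 6 + ["y"] * 6,
        })
        r12 = permanova(_expr(xs.T), meta, ["f1", "f2"], n_perm=49, seed=3)
        r21 = permanova(_expr(xs.T), meta, ["f2", "f1"], n_perm=49, seed=3)
        assert r12.table["ss"].sum() == pytest.approx(r21.table["ss"].sum())

    def test_single_level_factor_errors(self, rng):
        xs = rng.normal(size=(6, 3))
        meta = self._meta(["a"] * 6)
        with pytest.raises(ValueError, match="single level"):
            permanova(_expr(xs.T), meta, ["mutation"], n_perm=9, seed=0)

    def test_pseudo_f_matches_scikit_bio(self, rng):
        """Single-factor pseudo-F agrees with the reference implementation."""
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova
        xs = rng.normal(size=(12, 5))
        labels = ["a", "b", "c"] * 4
        d = np.sqrt(((xs[:, None, :] - xs[None, :, :]) ** 2).sum(axis=2))
        dm = DistanceMatrix(d, ids=[f"s{j}" for j in range(12)])
        ref = skbio_permanova(dm, grouping=labels, permutations=99)
        res = permanova(_expr(xs.T), self._meta(labels), ["mutation"],
                        n_perm=99, seed=0)
        assert res.table["pseudo_f"].iloc[0] == pytest.approx(
            ref["test statistic"], abs=1e-8)

    def test_invariant_to_sample_ordering(self, rng):
        xs = rng.normal(size=(8, 4))
        labels = np.array(["a", "b"] * 4)
        res1 = permanova(_expr(xs.T), self._meta(labels), ["mutation"],
                         n_perm=999, seed=5)
        order = rng.permutation(8)
        meta2 = self._meta(labels[order])
        meta2["sample_id"] = [f"s{j}" for j in range(8)]
        res2 = permanova(_expr(xs[order].T), meta2, ["mutation"],
                         n_perm=999, seed=5)
        assert res1.table["r2"].iloc[0] == pytest.approx(res2.table["r2"].iloc[0])
        assert abs(res1.table["pvalue"].iloc[0] - res2.table["pvalue"].iloc[0]) < 0.05


class TestBatchScreen:
    def test_detects_planted_place_effect(self, two_group_meta, rng):
        base = rng.integers(50, 500, size=(40, 1))
        counts = np.tile(base, (1, 16))
        is_b = (two_group_meta["place"] == "B").to_numpy()
        counts[:10, is_b] *= 8
        counts = counts + rng.poisson(5, size=counts.shape)
        cm = CountMatrix([f"g{i}" for i in range(40)],
                         list(two_group_meta["sample_id"]), counts)
        res = batch_screen(cm, two_group_meta, "place", "condition")
        assert (res["fdr_place"][:10] < 0.05).all()
        assert (res["fdr_place"][10:] > 0.05).mean() > 0.8


class TestMarkerPanel:
    def test_zero_between_place_variance_matches_ols(self, two_group_meta, rng):
        counts = rng.poisson(100, size=(10, 16))
        # make place effect exactly zero by symmetrizing is unnecessary:
        # with a single-level variance the REML profile should land near 0
        cm = CountMatrix([f"g{i}" for i in range(10)],
                         list(two_group_meta["sample_id"]), counts)
        sf = np.ones(16)
        res = marker_panel(cm, sf, two_group_meta, ["g0", "g1"])
        # compare against OLS on log2(normalized + 1)
        from dopasig.normalize import design_matrix
        x, names = design_matrix(two_group_meta, ["mutation"])
        y = np.log2(counts[0] + 1.0)
        beta = np.linalg.lstsq(x, y, rcond=None)[0]
        ols_contrast = -beta[names.index("mutation[healthy]")]
        est = res.iloc[0]["estimate_LRRK2_vs_healthy"]
        assert est == pytest.approx(ols_contrast, abs=1e-4)

    def test_constant_gene_wilcoxon_p_one(self, two_group_meta):
        counts = np.full((2, 16), 7)
        cm = CountMatrix(["g0", "g1"], list(two_group_meta["sample_id"]), counts)
        res = marker_panel(cm, np.ones(16), two_group_meta, ["g0"])
        assert res.iloc[0]["wilcoxon_p"] == 1.0

    def test_missing_marker_reported(self, two_group_meta):
        counts = np.full((1, 16), 5)
        cm = CountMatrix(["g0"], list(two_group_meta["sample_id"]), counts)
        res = marker_panel(cm, np.ones(16), two_group_meta, ["g0", "ghost"])
        assert not res.set_index("gene").loc["ghost", "found"]

    def test_planted_shift_detected(self):
        """2-log2-unit mutation shift at study-like n: contrast significant
        in nearly all seeds."""
        from dopasig.simulate import SimulationDesign, simulate_counts, study_samples
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            meta = study_samples()
            effects = pd.DataFrame([{"gene": "G00000", "factor": "mutation",
                                     "level": "LRRK2", "lfc": 2.0}])
            design = SimulationDesign(n_genes=20, samples=meta, effects=effects,
                                      dispersion_meanlog=np.log(0.1),
                                      dispersion_sdlog=1e-9, seed=seed)
            counts, m, _ = simulate_counts(design)
            res = marker_panel(counts, np.ones(34), m, ["G00000"])
            hits += res.iloc[0]["p_LRRK2_vs_healthy"] < 0.05
        assert hits >= 0.9 * n_seeds

    def test_reml_at_least_ols_likelihood(self, two_group_meta, rng):
        counts = rng.poisson(200, size=(5, 16))
        cm = CountMatrix([f"g{i}" for i in range(5)],
                         list(two_group_meta["sample_id"]), counts)
        res = marker_panel(cm, np.ones(16), two_group_meta, [f"g{i}" for i in range(5)])
        assert (res["random_intercept_var"] >= 0).all()
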