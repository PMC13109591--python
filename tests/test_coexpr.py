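import numpy as np
import pandas as pd
import pytest

from dopasig.coexpr import (
    build_network,
    detect_modules,
    eigengenes,
    module_correlations,
    module_trait,
    tom_similarity,
)
from dopasig.normalize import ExpressionMatrix
from dopasig.ppi import ModulePartition


def _expr(values, provenance="batch_corrected", samples=None):
    genes = [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(genes, samples, np.asarray(values, float), provenance)


def brute_force_tom(a):
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


def _module_data(rng, n_samples=24, block=20, noise=0.3):
    """Two latent-factor blocks plus background noise genes."""
    z1 = rng.normal(size=n_samples)
    z2 = rng.normal(size=n_samples)
    rows = []
    for _ in range(block):
        rows.append(2.0 * z1 + noise * rng.normal(size=n_samples))
    for _ in range(block):
        rows.append(2.0 * z2 + noise * rng.normal(size=n_samples))
    for _ in range(40):
        rows.append(rng.normal(size=n_samples))
    return np.array(rows)


class TestBuildNetwork:
    def test_perfectly_correlated_pair_adjacency_one(self, rng):
        base = rng.normal(size=12)
        values = np.vstack([base, base * 2 + 1] + [rng.normal(size=12) for _ in range(10)])
        net = build_network(_expr(values), beta=6, top_n=50)
        assert net.adjacency[0, 1] == pytest.approx(1.0)

    def test_anticorrelated_pair_zeroed(self, rng):
        base = rng.normal(size=12)
        values = np.vstack([base, -base] + [rng.normal(size=12) for _ in range(10)])
        net = build_network(_expr(values), beta=6, top_n=50)
        assert net.adjacency[0, 1] == 0.0

    def test_tom_matches_triple_loop(self, rng):
        values = rng.normal(size=(40, 20))
        net = build_network(_expr(values), beta=6, top_n=50)
        np.testing.assert_allclose(net.tom, brute_force_tom(net.adjacency), atol=1e-10)

    def test_tom_symmetric_unit_diagonal(self, rng):
        a = np.abs(rng.normal(0, 0.3, size=(15, 15)))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        tom = tom_similarity(a)
        np.testing.assert_allclose(tom, tom.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(tom), 1.0)

    def test_beta_monotone_adjacency(self, rng):
        values = rng.normal(size=(20, 15))
        n1 = build_network(_expr(values), beta=2, top_n=30)
        n2 = build_network(_expr(values), beta=5, top_n=30)
        assert np.all(n2.adjacency <= n1.adjacency + 1e-12)

    def test_requires_batch_corrected(self, rng):
        values = rng.normal(size=(10, 10))
        with pytest.raises(ValueError, match="batch corrected"):
            build_network(_expr(values, provenance="vst"))
        build_network(_expr(values, provenance="vst"), beta=6, allow_uncorrected=True)

    def test_constant_genes_dropped_with_warning(self, rng):
        values = np.vstack([np.full(10, 3.0), rng.normal(size=(8, 10))])
        with pytest.warns(UserWarning, match="constant"):
            net = build_network(_expr(values), beta=6)
        assert len(net.genes) == 8


class TestDetectModules:
    def test_planted_blocks_recovered(self, rng):
        values = _module_data(rng)
        net = build_network(_expr(values), beta=6, top_n=100)
        part = detect_modules(net, min_size=10)
        truth1 = {f"g{i}" for i in range(20)}
        truth2 = {f"g{i}" for i in range(20, 40)}
        best1 = max(
            len(truth1 & set(m)) / len(truth1 | set(m))
            for m in part.modules.values()
        )
        best2 = max(
            len(truth2 & set(m)) / len(truth2 | set(m))
            for m in part.modules.values()
        )
        assert best1 >= 0.9 and best2 >= 0.9

    def test_pure_noise_mostly_grey(self, rng):
        grey_frac = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            values = r.normal(size=(60, 20))
            net = build_network(_expr(values), beta=6, top_n=100)
            part = detect_modules(net, min_size=10)
            grey = part.modules.get("grey", [])
            if len(part.modules) == 1 and "M1" in part.modules:
                grey_frac.append(0.0)  # degenerate single-module fallback
            else:
                grey_frac.append(len(grey) / 60)
        # noise should rarely produce well-formed modules
        assert np.median(grey_frac) > 0.5 or np.mean(np.array(grey_frac) == 0.0) > 0.5

    def test_min_size_too_large_single_module_warning(self, rng):
        values = rng.normal(size=(10, 10))
        net = build_network(_expr(values), beta=6)
        with pytest.warns(UserWarning, match="no cut height"):
            part = detect_modules(net, min_size=50)
        assert list(part.modules) == ["M1"]


class TestEigengenes:
    def test_identical_genes_full_variance(self):
        base = np.arange(10, dtype=float)
        values = np.vstack([base, base, base])
        expr = _expr(values)
        part = ModulePartition(modules={"M1": ["g0", "g1", "g2"]})
        eg = eigengenes(expr, part)
        assert eg.explained_variance["M1"] == pytest.approx(1.0)

    def test_anticorrelated_pair_full_variance(self):
        base = np.arange(8, dtype=float)
        values = np.vstack([base, -base])
        eg = eigengenes(_expr(values), ModulePartition(modules={"M1": ["g0", "g1"]}))
        assert eg.explained_variance["M1"] == pytest.approx(1.0)

    def test_matches_svd_oracle_up_to_sign(self, rng):
        values = rng.normal(size=(12, 16))
        expr = _expr(values)
        part = ModulePartition(modules={"M1": [f"g{i}" for i in range(12)]})
        eg = eigengenes(expr, part)
        z = (values - values.mean(axis=1, keepdims=True)) / values.std(axis=1, keepdims=True)
        u, s, vt = np.linalg.svd(z.T, full_matrices=False)
        oracle = u[:, 0]
        got = eg.values["M1"].to_numpy()
        assert abs(np.dot(oracle, got)) == pytest.approx(1.0, abs=1e-8)

    def test_sign_positive_with_mean_profile(self, rng):
        values = np.vstack([rng.normal(5, 1, 10) for _ in range(6)])
        eg = eigengenes(_expr(values),
                        ModulePartition(modules={"M1": [f"g{i}" for i in range(6)]}))
        z = (values - values.mean(axis=1, keepdims=True)) / values.std(axis=1, keepdims=True)
        assert np.corrcoef(eg.values["M1"], z.mean(axis=0))[0, 1] > 0


class TestModuleTrait:
    def _meta(self, n):
        return pd.DataFrame({
            "sample_id": [f"s{j}" for j in range(n)],
            "condition": ["PD" if j < n // 2 else "healthy" for j in range(n)],
            "mutation": ["LRRK2" if j < n // 2 else "healthy" for j in range(n)],
        })

    def test_indicator_eigengene_perfect_correlation(self):
        n = 12
        meta = self._meta(n)
        indicator = (meta["condition"] == "PD").to_numpy(float)
        eg_vals = pd.DataFrame({"M1": indicator}, index=meta["sample_id"])
        from dopasig.coexpr import EigengeneMatrix
        eg = EigengeneMatrix(values=eg_vals, explained_variance={"M1": 1.0})
        res = module_trait(eg, meta, ["condition"])
        row = res.set_index(["module", "trait"]).loc[("M1", "condition=PD")]
        assert row["pearson_r"] == pytest.approx(1.0)
        assert row["glm_p"] < 1e-6

    def test_module_correlations_psd(self, rng):
        from dopasig.coexpr import EigengeneMatrix
        vals = pd.DataFrame(rng.normal(size=(20, 4)),
                            columns=["M1", "M2", "M3", "M4"])
        eg = EigengeneMatrix(values=vals, explained_variance={})
        cor, table = module_correlations(eg)
        eigvals = np.linalg.eigvalsh(cor.to_numpy())
        assert eigvals.min() > -1e-8
        assert len(table) == 6
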