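import math

import numpy as np
import pandas as pd
import pytest

from nichetraits import life_history as lh


class TestMlhsAverage:
    def test_module_level_mean_not_strategy_mean(self):
        # four modules in strategy A (all 0.6), one module in B (0.1):
        # module-level mean = (4*0.6 + 0.1)/5 = 0.5; strategy-mean = 0.35
        row = pd.Series(
            {"M1": 0.6, "M2": 0.6, "M3": 0.6, "M4": 0.6, "M5": 0.1}
        )
        smap = {"M1": "growth", "M2": "growth", "M3": "growth",
                "M4": "growth", "M5": "dispersal"}
        avg, per = lh.mlhs_average(row, smap)
        assert avg == pytest.approx(0.5)
        assert per == {"growth": pytest.approx(0.6), "dispersal": pytest.approx(0.1)}

    def test_unmapped_modules_ignored(self):
        row = pd.Series({"M1": 0.2, "Mx": 0.9})
        avg, _ = lh.mlhs_average(row, {"M1": "growth"})
        assert avg == pytest.approx(0.2)

    def test_no_mapped_module_raises(self):
        with pytest.raises(ValueError):
            lh.mlhs_average(pd.Series({"M1": 0.2}), {"Mz": "growth"})


class TestMlhsEvenness:
    def test_uniform_means_give_one(self):
        assert lh.mlhs_evenness([0.3, 0.3, 0.3, 0.3]) == pytest.approx(1.0)

    def test_single_nonzero_strategy_gives_zero(self):
        assert lh.mlhs_evenness([0.7, 0.0, 0.0]) == pytest.approx(0.0)

    def test_worked_example(self):
        # means (0.5, 0.3, 0.2): H = -sum p ln p = 1.02965..., J = H/ln 3
        means = [0.5, 0.3, 0.2]
        p = np.array(means) / sum(means)
        h = -(p * np.log(p)).sum()
        assert lh.mlhs_evenness(means) == pytest.approx(h / math.log(3))
        assert lh.mlhs_evenness(means) == pytest.approx(0.93719, abs=1e-4)

    def test_k_includes_zero_strategies(self):
        # same nonzero means, but K=5 shrinks J via the larger denominator
        j3 = lh.mlhs_evenness([0.5, 0.3, 0.2])
        j5 = lh.mlhs_evenness([0.5, 0.3, 0.2, 0.0, 0.0])
        assert j5 == pytest.approx(j3 * math.log(3) / math.log(5))

    def test_zero_sum_is_nan(self):
        assert math.isnan(lh.mlhs_evenness([0.0, 0.0]))


class TestMlhsTable:
    def _setup(self):
        completeness = pd.DataFrame(
            {"M1": [1.0, 0.0], "M2": [0.5, 0.5], "M3": [0.0, 1.0]},
            index=["t1", "t2"],
        )
        smap = {"M1": "growth", "M2": "growth", "M3": "stress_tolerance"}
        return completeness, smap

    def test_columns_and_values(self):
        completeness, smap = self._setup()
        table = lh.mlhs_table(completeness, smap)
        assert table.loc["t1", "m_growth"] == pytest.approx(0.75)
        assert table.loc["t1", "m_stress_tolerance"] == pytest.approx(0.0)
        assert table.loc["t1", "average_mlhs"] == pytest.approx(0.5)
        assert table.loc["t1", "strategy_mean_mlhs"] == pytest.approx(0.375)
        assert table.loc["t1", "evenness_mlhs"] == pytest.approx(0.0)
        assert table.loc["t2", "evenness_mlhs"] == pytest.approx(
            lh.mlhs_evenness([0.25, 1.0])
        )

    def test_matches_scalar_function_row_by_row(self):
        rng = np.random.default_rng(6)
        completeness = pd.DataFrame(
            rng.uniform(size=(8, 6)),
            index=[f"t{i}" for i in range(8)],
            columns=[f"M{j}" for j in range(6)],
        )
        smap = {f"M{j}": s for j, s in enumerate(
            ["growth", "growth", "competition", "dispersal", "dispersal", "other"]
        )}
        table = lh.mlhs_table(completeness, smap)
        for t in completeness.index:
            avg, per = lh.mlhs_average(completeness.loc[t], smap)
            assert table.loc[t, "average_mlhs"] == pytest.approx(avg)
            for s, v in per.items():
                assert table.loc[t, f"m_{s}"] == pytest.approx(v)


class TestAssociation:
    def test_positive_planted_association_detected(self):
        rng = np.random.default_rng(10)
        breadth = pd.Series(rng.uniform(size=50), index=[f"t{i}" for i in range(50)])
        completeness = pd.DataFrame(
            np.clip(breadth.to_numpy()[:, None] + rng.normal(0, 0.1, size=(50, 4)), 0, 1),
            index=breadth.index, columns=["M1", "M2", "M3", "M4"],
        )
        smap = {"M1": "growth", "M2": "growth", "M3": "dispersal", "M4": "other"}
        table = lh.mlhs_table(completeness, smap)
        out = lh.mlhs_breadth_association(table, breadth)
        assert out.loc["average_mlhs", "r"] > 0.5
        assert out.loc["average_mlhs", "p"] < 1e-4

    def test_too_few_taxa_raises(self):
        table = pd.DataFrame(
            {"average_mlhs": [0.1, 0.2], "evenness_mlhs": [0.5, 0.6]},
            index=["t1", "t2"],
        )
        breadth = pd.Series([0.3, 0.4], index=["t1", "t2"])
        with pytest.raises(ValueError):
            lh.mlhs_breadth_association(table, breadth)


class TestTraitSpacePCA:
    def _random_completeness(self, n=30, m=6, seed=3):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.uniform(size=(n, m)),
            index=[f"t{i}" for i in range(n)],
            columns=[f"M{j}" for j in range(m)],
        )

    def test_matches_eigendecomposition_oracle(self):
        comp = self._random_completeness()
        res = lh.trait_space_pca(comp)
        x = comp.to_numpy()
        x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
        evals, evecs = np.linalg.eigh(np.cov(x.T))
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        assert np.allclose(
            res.explained_variance_ratio, evals / evals.sum(), atol=1e-10
        )
        for j in range(x.shape[1]):
            got = res.scores.iloc[:, j].to_numpy()
            want = x @ evecs[:, j]
            assert np.allclose(got, want, atol=1e-8) or np.allclose(
                got, -want, atol=1e-8
            )

    def test_pc1_loading_is_correlation_with_score(self):
        comp = self._random_completeness(seed=9)
        res = lh.trait_space_pca(comp)
        pc1 = res.scores["PC1"].to_numpy()
        for m in comp.columns:
            r = np.corrcoef(comp[m], pc1)[0, 1]
            assert res.pc1_loadings[m] == pytest.approx(r, abs=1e-10)

    def test_zero_variance_module_dropped_with_warning(self):
        comp = self._random_completeness()
        comp["Mflat"] = 0.5
        with pytest.warns(UserWarning, match="zero-variance"):
            res = lh.trait_space_pca(comp)
        assert res.dropped_modules == ["Mflat"]
        assert "Mflat" not in res.pc1_loadings.index

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            lh.trait_space_pca(self._random_completeness(n=2))


class TestModuleClusters:
    def _planted(self, n_blocks, modules_per_block, n_taxa=80, noise=0.3, seed=1):
        rng = np.random.default_rng(seed)
        cols = {}
        for b in range(n_blocks):
            latent = rng.uniform(size=n_taxa)
            for j in range(modules_per_block):
                cols[f"B{b}M{j}"] = np.clip(
                    latent + rng.normal(0, noise, n_taxa), 0, 1
                )
        return pd.DataFrame(cols, index=[f"t{i}" for i in range(n_taxa)])

    def test_recovers_two_planted_blocks(self):
        comp = self._planted(2, 4)
        res = lh.module_clusters(comp, k_max=6)
        assert res.k == 2
        blocks = pd.Series(
            [name[1] for name in res.labels.index], index=res.labels.index
        )
        # every planted block maps to exactly one cluster
        assert res.labels.groupby(blocks).nunique().max() == 1

    def test_recovers_four_planted_blocks(self):
        comp = self._planted(4, 4, seed=2)
        res = lh.module_clusters(comp, k_max=8)
        assert res.k == 4

    def test_constant_module_dropped_with_warning(self):
        comp = self._planted(2, 3)
        comp["Mflat"] = 0.7
        with pytest.warns(UserWarning, match="constant"):
            res = lh.module_clusters(comp)
        assert "Mflat" not in res.labels.index

    def test_low_confidence_flag_on_unstructured_data(self):
        rng = np.random.default_rng(4)
        comp = pd.DataFrame(
            rng.uniform(size=(60, 8)),
            index=[f"t{i}" for i in range(60)],
            columns=[f"M{j}" for j in range(8)],
        )
        res = lh.module_clusters(comp)
        assert res.low_confidence

    def test_too_few_modules_rejected(self):
        comp = self._planted(1, 2)
        with pytest.raises(ValueError, match="3 modules"):
            lh.module_clusters(comp)
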