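import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from nichetraits import trait_screen as ts


def newton_raphson_logistic(y, x, tol=1e-10, max_iter=200):
    """Independent textbook Newton-Raphson fit of a logit model."""
    X = np.column_stack([np.ones(len(x)), x])
    beta = np.zeros(2)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu)
        grad = X.T @ (y - mu)
        hess = X.T @ (X * W[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    cov = np.linalg.inv(X.T @ (X * (1.0 / (1.0 + np.exp(-(X @ beta)))
                                    * (1 - 1.0 / (1.0 + np.exp(-(X @ beta)))))[:, None]))
    return beta, np.sqrt(np.diag(cov))


class TestFitLogistic:
    def test_matches_independent_newton_raphson(self):
        rng = np.random.default_rng(11)
        for trial in range(10):
            x = rng.uniform(size=60)
            p = 1.0 / (1.0 + np.exp(-(-0.5 + 1.5 * x)))
            y = (rng.uniform(size=60) < p).astype(float)
            if y.min() == y.max():
                continue
            fit = ts.fit_logistic(y, x)
            if fit.separation:
                continue
            beta, se = newton_raphson_logistic(y, x)
            assert fit.intercept == pytest.approx(beta[0], abs=1e-6)
            assert fit.slope == pytest.approx(beta[1], abs=1e-6)
            assert fit.se == pytest.approx(se[1], rel=1e-4)

    def test_constant_x_raises(self):
        y = np.array([0, 1] * 10, dtype=float)
        with pytest.raises(ValueError, match="constant"):
            ts.fit_logistic(y, np.full(20, 0.3))

    def test_single_class_flagged_not_converged(self):
        fit = ts.fit_logistic(np.zeros(15), np.linspace(0, 1, 15))
        assert not fit.converged
        assert math.isnan(fit.p)

    def test_perfect_separation_flagged(self):
        x = np.linspace(0, 1, 30)
        y = (x > 0.5).astype(float)
        fit = ts.fit_logistic(y, x)
        assert fit.separation

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="10"):
            ts.fit_logistic(np.array([0.0, 1.0] * 4), np.linspace(0, 1, 8))

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(42)
        rejections = 0
        n_trials = 400
        for _ in range(n_trials):
            x = rng.uniform(size=200)
            y = (rng.uniform(size=200) < 0.5).astype(float)
            fit = ts.fit_logistic(y, x)
            if not fit.separation and fit.p < 0.05:
                rejections += 1
        assert 0.02 < rejections / n_trials < 0.08


class TestScreenFeatures:
    def _matrix(self, rows, taxa):
        return pd.DataFrame(
            rows, index=[f"M{i}" for i in range(len(rows))], columns=taxa
        )

    def test_monomorphic_features_skipped_with_reason(self):
        taxa = [f"t{i}" for i in range(20)]
        breadth = pd.Series(np.linspace(0.1, 0.9, 20), index=taxa)
        rows = [np.ones(20, dtype=int), np.zeros(20, dtype=int),
                (np.arange(20) % 2)]
        results, skipped = ts.screen_features(self._matrix(rows, taxa), breadth, "forest")
        assert set(skipped["feature_id"]) == {"M0", "M1"}
        assert (skipped["reason"] == "monomorphic").all()
        assert list(results["feature_id"]) == ["M2"]

    def test_bh_adjustment_matches_statsmodels_free_oracle(self):
        rng = np.random.default_rng(8)
        taxa = [f"t{i}" for i in range(60)]
        breadth = pd.Series(rng.uniform(size=60), index=taxa)
        rows = (rng.uniform(size=(12, 60)) < 0.5).astype(int)
        results, _ = ts.screen_features(self._matrix(list(rows), taxa), breadth, "forest")
        p = results["p"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        ranked = p[order] * m / (np.arange(m) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(ranked, 1.0)
        assert np.allclose(results["p_bh"].to_numpy(), expected, atol=1e-12)


class TestConsensusFilter:
    def _row(self, fid, eco, slope, p, sep=False, conv=True):
        return {
            "feature_id": fid, "feature_kind": "module", "ecosystem": eco,
            "slope": slope, "se": 0.1, "wald_z": slope / 0.1, "p": p,
            "direction": "+" if slope >= 0 else "-",
            "converged": conv, "separation": sep,
        }

    def test_quorum_and_sign_agreement(self):
        results = pd.DataFrame([
            self._row("A", "forest", 2.0, 0.001),
            self._row("A", "wetland", 1.5, 0.01),
            self._row("B", "forest", 2.0, 0.001),
            self._row("B", "wetland", -1.5, 0.01),  # sign flip
            self._row("C", "forest", 2.0, 0.001),
            self._row("C", "wetland", 1.5, 0.2),  # not significant twice
        ])
        out = ts.consensus_filter(results).set_index("feature_id")
        assert bool(out.loc["A", "retained"])
        assert out.loc["A", "shared_direction"] == "+"
        assert not bool(out.loc["B", "retained"])
        assert not bool(out.loc["C", "retained"])

    def test_separation_never_counts_toward_quorum(self):
        results = pd.DataFrame([
            self._row("A", "forest", 20.0, 1e-9, sep=True),
            self._row("A", "wetland", 1.5, 0.01),
        ])
        out = ts.consensus_filter(results)
        assert not bool(out.loc[0, "retained"])

    def test_min_ecosystems_three(self):
        results = pd.DataFrame([
            self._row("A", "forest", 2.0, 0.001),
            self._row("A", "wetland", 1.5, 0.01),
            self._row("A", "grassland", 1.1, 0.04),
        ])
        assert bool(ts.consensus_filter(results, min_ecosystems=3).loc[0, "retained"])
        results2 = results.iloc[:2]
        assert not bool(
            ts.consensus_filter(results2, min_ecosystems=3).loc[0, "retained"]
        )


class TestPearsonScreen:
    def test_matches_scipy(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=40)
        b = 0.4 * v + rng.normal(size=40)
        r, t, df, p = ts.pearson_screen(v, b)
        r_sp, p_sp = stats.pearsonr(v, b)
        assert r == pytest.approx(r_sp, abs=1e-12)
        assert p == pytest.approx(p_sp, rel=1e-9)
        assert df == 38

    def test_pairwise_missing_excluded(self):
        v = np.array([1.0, 2, np.nan, 4, 5, 6])
        b = np.array([1.1, 2.2, 3.0, np.nan, 5.2, 6.1])
        r, _, df, _ = ts.pearson_screen(v, b)
        assert df == 2  # four usable pairs
        assert r > 0.9

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ts.pearson_screen(np.ones(10), np.linspace(0, 1, 10))


def permanova_oracle(profiles, covariate, distance):
    """Independent PERMANOVA via explicit H and full matrix products."""
    X = profiles.to_numpy(dtype=float)
    d = pdist(X.astype(bool) if distance == "jaccard" else X, metric=distance)
    D2 = squareform(d) ** 2
    n = len(profiles)
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ D2 @ J
    Z = np.column_stack([np.ones(n), covariate])
    H = Z @ np.linalg.inv(Z.T @ Z) @ Z.T
    num = np.trace(H @ G @ H)
    den = np.trace((np.eye(n) - H) @ G @ (np.eye(n) - H))
    return num / np.trace(G), num / (den / (n - 2))


class TestPermanova:
    def _data(self, n=12, seed=2):
        rng = np.random.default_rng(seed)
        profiles = pd.DataFrame(
            (rng.uniform(size=(n, 15)) < 0.4).astype(int),
            index=[f"t{i}" for i in range(n)],
        )
        cov = pd.Series(rng.uniform(size=n), index=profiles.index)
        return profiles, cov

    @pytest.mark.parametrize("distance", ["jaccard", "braycurtis"])
    def test_statistics_match_explicit_hat_matrix_oracle(self, distance):
        profiles, cov = self._data()
        r2, f, _ = ts.permanova(profiles, cov, distance=distance, n_perm=99, seed=1)
        r2_o, f_o = permanova_oracle(profiles, cov, distance)
        assert r2 == pytest.approx(r2_o, abs=1e-10)
        assert f == pytest.approx(f_o, abs=1e-10)

    def test_exhaustive_p_matches_enumeration_oracle(self):
        profiles, cov = self._data(n=6, seed=3)
        _, f_obs, p = ts.permanova(profiles, cov, exhaustive=True, n_perm=99)
        covv = cov.to_numpy()
        count = 0
        total = 0
        for perm in itertools.permutations(range(6)):
            shuffled = pd.Series(covv[list(perm)], index=cov.index)
            _, f_perm = permanova_oracle(profiles, shuffled, "jaccard")
            count += f_perm >= f_obs - 1e-12
            total += 1
        assert p == pytest.approx(count / total, abs=1e-12)

    def test_strong_structure_detected(self):
        rng = np.random.default_rng(7)
        n = 40
        cov = pd.Series(np.linspace(0, 1, n), index=[f"t{i}" for i in range(n)])
        base = (rng.uniform(size=(n, 20)) < 0.2).astype(int)
        base[:, :10] = (cov.to_numpy()[:, None] > 0.5).astype(int)
        profiles = pd.DataFrame(base, index=cov.index)
        r2, _, p = ts.permanova(profiles, cov, n_perm=199, seed=4)
        assert p <= 0.01
        assert r2 > 0.1

    def test_too_few_taxa_rejected(self):
        profiles, cov = self._data(n=4)
        with pytest.raises(ValueError, match="5"):
            ts.permanova(profiles, cov)
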