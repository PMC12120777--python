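"""Cross-ecosystem genomic trait screen.

The core inference: for every trait (module presence or KO presence, 0/1)
a binomial GLM with logit link is fitted with niche breadth as the single
continuous covariate, per ecosystem. Significance is the Wald test of the
slope. A trait is *retained* when at least ``min_ecosystems`` ecosystems
show p < alpha with the same slope sign — the error control is consistency
across ecosystems, not a multiple-testing correction (an optional BH-FDR
column is emitted for users who want one).

Continuous traits (genome size, GC, KO richness, ...) are screened by
Pearson correlation; whole trait profiles by a distance-based PERMANOVA
with the continuous covariate (McArdle–Anderson linear model on the
Gower-centered distance matrix).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

__all__ = [
    "LogisticFit",
    "fit_logistic",
    "screen_features",
    "consensus_filter",
    "pearson_screen",
    "permanova",
]

#: |slope| beyond this (on the unit-breadth scale) is treated as separation.
SEPARATION_SLOPE = 15.0
MAX_IRLS_ITER = 50


@dataclass
class LogisticFit:
    """One binomial-GLM fit of trait presence on niche breadth."""

    slope: float
    intercept: float
    se: float
    wald_z: float
    p: float
    converged: bool
    separation: bool

    @property
    def direction(self) -> str:
        return "+" if self.slope >= 0 else "-"


def fit_logistic(y, x) -> LogisticFit:
    """Maximum-likelihood logistic fit of binary ``y`` on continuous ``x``.

    Fitted by iteratively reweighted least squares (binomial GLM, logit
    link); the two-sided p-value is the Wald test of the slope against the
    standard normal. Degenerate designs raise or are flagged:

    * constant ``x`` → ``ValueError`` (no identifiable slope);
    * single-class ``y`` → flagged not-converged, all statistics NaN;
    * complete separation (diverging slope or non-convergence) → the
      ``separation`` flag is set so the feature can be excluded downstream.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("y and x must be 1-D vectors of equal length")
    if len(y) < 10:
        raise ValueError("need at least 10 observations")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("y must be binary (0/1)")
    if np.ptp(x) == 0:
        raise ValueError("x is constant: no identifiable slope")
    if y.min() == y.max():
        return LogisticFit(
            slope=float("nan"), intercept=float("nan"), se=float("nan"),
            wald_z=float("nan"), p=float("nan"), converged=False, separation=False,
        )
    design = sm.add_constant(x)
    separation = False
    converged = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            model = sm.GLM(y, design, family=sm.families.Binomial())
            res = model.fit(maxiter=MAX_IRLS_ITER)
        converged = bool(res.converged)
    except (PerfectSeparationError, PerfectSeparationWarning):
        return LogisticFit(
            slope=float("nan"), intercept=float("nan"), se=float("nan"),
            wald_z=float("nan"), p=float("nan"), converged=False, separation=True,
        )
    intercept, slope = res.params
    se = float(res.bse[1])
    if abs(slope) > SEPARATION_SLOPE or not converged:
        separation = True
    wald_z = slope / se if se > 0 else float("nan")
    p = 2.0 * stats.norm.sf(abs(wald_z)) if np.isfinite(wald_z) else float("nan")
    return LogisticFit(
        slope=float(slope), intercept=float(intercept), se=se,
        wald_z=float(wald_z), p=float(p), converged=converged, separation=separation,
    )


def screen_features(
    trait_matrix: pd.DataFrame,
    breadth: pd.Series,
    ecosystem: str,
    feature_kind: str = "module",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit one presence-on-breadth GLM per feature within one ecosystem.

    ``trait_matrix`` is features (rows) × taxa (columns), binary; ``breadth``
    is indexed by taxon id. Only taxa present in both are used. Monomorphic
    features (all-0 or all-1 across the analysed taxa) are skipped with a
    reason rather than fitted.

    Returns ``(results, skipped)``; ``results`` has one row per fitted
    feature with a ``p_bh`` Benjamini–Hochberg column appended.
    """
    taxa = [t for t in trait_matrix.columns if t in breadth.index]
    if not taxa:
        raise ValueError("no taxa shared between trait matrix and breadth records")
    x = breadth.loc[taxa].to_numpy(dtype=float)
    rows, skipped = [], []
    for feature_id, trait_row in trait_matrix.loc[:, taxa].iterrows():
        y = trait_row.to_numpy(dtype=float)
        if y.min() == y.max():
            skipped.append(
                {"feature_id": feature_id, "ecosystem": ecosystem, "reason": "monomorphic"}
            )
            continue
        fit = fit_logistic(y, x)
        rows.append(
            {
                "feature_id": feature_id,
                "feature_kind": feature_kind,
                "ecosystem": ecosystem,
                "slope": fit.slope,
                "se": fit.se,
                "wald_z": fit.wald_z,
                "p": fit.p,
                "direction": fit.direction,
                "converged": fit.converged,
                "separation": fit.separation,
            }
        )
    results = pd.DataFrame(
        rows,
        columns=[
            "feature_id", "feature_kind", "ecosystem", "slope", "se",
            "wald_z", "p", "direction", "converged", "separation",
        ],
    )
    if len(results):
        ok = results["p"].notna()
        results["p_bh"] = np.nan
        if ok.any():
            results.loc[ok, "p_bh"] = multipletests(
                results.loc[ok, "p"].to_numpy(), method="fdr_bh"
            )[1]
    else:
        results["p_bh"] = pd.Series(dtype=float)
    return results, pd.DataFrame(skipped, columns=["feature_id", "ecosystem", "reason"])


def consensus_filter(
    results: pd.DataFrame, alpha: float = 0.05, min_ecosystems: int = 2
) -> pd.DataFrame:
    """Retain features significant with the same slope sign in enough ecosystems.

    ``results`` concatenates per-ecosystem screen outputs. A feature is
    retained iff at least ``min_ecosystems`` ecosystems show p < alpha with
    an identical slope sign; separation-flagged or non-converged fits never
    count toward the quorum. Features absent from an ecosystem simply do not
    count toward it.
    """
    records = []
    for feature_id, group in results.groupby("feature_id", sort=True):
        usable = group[
            group["p"].notna() & ~group["separation"].astype(bool)
            & group["converged"].astype(bool)
        ]
        sig = usable[usable["p"] < alpha]
        pos = sig[sig["slope"] > 0]
        neg = sig[sig["slope"] < 0]
        shared, ecosystems = "none", []
        if len(pos) >= min_ecosystems:
            shared, ecosystems = "+", sorted(pos["ecosystem"])
        elif len(neg) >= min_ecosystems:
            shared, ecosystems = "-", sorted(neg["ecosystem"])
        records.append(
            {
                "feature_id": feature_id,
                "ecosystems_significant": ",".join(ecosystems),
                "shared_direction": shared,
                "retained": shared != "none",
            }
        )
    return pd.DataFrame(
        records,
        columns=["feature_id", "ecosystems_significant", "shared_direction", "retained"],
    )


def pearson_screen(values, breadth) -> tuple[float, float, int, float]:
    """Pearson correlation of a continuous trait with niche breadth.

    Returns ``(r, t, df, p)`` with ``t = r * sqrt((n-2) / (1-r^2))`` and a
    two-sided p from the t distribution on n−2 degrees of freedom. Pairs
    with a missing value are excluded pairwise.
    """
    v = np.asarray(values, dtype=float)
    b = np.asarray(breadth, dtype=float)
    ok = ~(np.isnan(v) | np.isnan(b))
    v, b = v[ok], b[ok]
    n = len(v)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(v) == 0 or np.ptp(b) == 0:
        raise ValueError("constant vector: correlation undefined")
    r, _ = stats.pearsonr(v, b)
    df = n - 2
    if abs(r) >= 1.0:
        t = math.copysign(float("inf"), r)
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), df)
    return float(r), float(t), df, float(p)


def permanova(
    profiles: pd.DataFrame,
    covariate: pd.Series,
    distance: str = "jaccard",
    n_perm: int = 999,
    seed: int = 0,
    exhaustive: bool = False,
) -> tuple[float, float, float]:
    """Distance-based linear model of trait profiles on a continuous covariate.

    ``profiles`` is taxa × features (binary for Jaccard, counts for
    Bray–Curtis). The squared distance matrix is Gower-centered to G, the
    hat matrix H comes from the (intercept + covariate) design, and

    * R² = tr(HGH) / tr(G)
    * pseudo-F = [tr(HGH) / 1] / [tr((I−H)G(I−H)) / (n − 2)]
    * p = (1 + #{F_perm >= F_obs}) / (1 + n_perm), permuting taxa labels.

    With ``exhaustive=True`` all n! permutations are enumerated (n <= 8) and
    p = #{F_perm >= F_obs} / n! over the full group (identity included).

    Returns ``(R2, pseudo_F, p)``.
    """
    taxa = [t for t in profiles.index if t in covariate.index]
    if len(taxa) < 5:
        raise ValueError("need at least 5 taxa with covariate values")
    if n_perm < 99 and not exhaustive:
        raise ValueError("n_perm must be >= 99")
    X = profiles.loc[taxa].to_numpy(dtype=float)
    d = pdist(X.astype(bool) if distance == "jaccard" else X, metric=distance)
    if not np.isfinite(d).all():
        raise ValueError("undefined dissimilarities (empty profiles?)")
    if d.max() == 0:
        raise ValueError("zero total dissimilarity: all profiles identical")
    D2 = squareform(d) ** 2
    n = len(taxa)
    # Gower centering: G = -(1/2) J D2 J with J = I - 11'/n
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ D2 @ J
    tr_G = np.trace(G)
    cov = covariate.loc[taxa].to_numpy(dtype=float)
    if np.ptp(cov) == 0:
        raise ValueError("constant covariate")

    def _stat(order: np.ndarray) -> tuple[float, float]:
        design = np.column_stack([np.ones(n), cov[order]])
        # tr(HGH) = tr(GH) because H is symmetric idempotent
        coef = np.linalg.solve(design.T @ design, design.T @ G @ design)
        tr_hgh = np.trace(coef)
        r2 = tr_hgh / tr_G
        f = tr_hgh / ((tr_G - tr_hgh) / (n - 2))
        return r2, f

    identity = np.arange(n)
    r2_obs, f_obs = _stat(identity)
    if exhaustive:
        f_perm = np.array(
            [_stat(np.array(perm))[1] for perm in itertools.permutations(range(n))]
        )
        p = float(np.mean(f_perm >= f_obs))
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            order = rng.permutation(n)
            if _stat(order)[1] >= f_obs:
                count += 1
        p = (1.0 + count) / (1.0 + n_perm)
    return float(r2_obs), float(f_obs), float(p)
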