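"""Life-history-strategy aggregation and trait-space structure.

mLHS ("modules aggregated within Life-History Strategies") statistics:

* the *average mLHS* of a taxon is the mean completeness over all modules
  assigned to any strategy (a module-level mean, not a mean of strategy
  means — the two differ when strategies hold different numbers of modules);
* the *evenness mLHS* is the Pielou evenness of the strategy-level mean
  completenesses: J = H / ln(K) with H the Shannon entropy of the
  normalized strategy means and K the number of strategies in the map
  (strategies whose mean is zero still count toward K).

Trait-space structure: PCA of the (standardized) module-completeness matrix
with PC1 loadings reported as the Pearson correlation of each module with
the PC1 score, and module clustering by Ward agglomeration on
1 − Spearman ρ with the cluster count chosen by maximal mean silhouette.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score

from .trait_screen import pearson_screen

__all__ = [
    "mlhs_average",
    "mlhs_evenness",
    "mlhs_table",
    "mlhs_breadth_association",
    "TraitSpaceResult",
    "trait_space_pca",
    "ClusterResult",
    "module_clusters",
]


def mlhs_average(
    completeness_row: pd.Series, strategy_map: dict[str, str]
) -> tuple[float, dict[str, float]]:
    """Average mLHS of one taxon plus its per-strategy mean completenesses.

    The average is the mean over *modules* mapped to any strategy; the
    per-strategy means are means over the modules of each strategy.
    """
    mapped = [m for m in completeness_row.index if m in strategy_map]
    if not mapped:
        raise ValueError("no module of the completeness row is mapped to a strategy")
    values = completeness_row.loc[mapped].astype(float)
    average = float(values.mean())
    per_strategy: dict[str, float] = {}
    strategies = sorted(set(strategy_map[m] for m in mapped))
    for strategy in strategies:
        members = [m for m in mapped if strategy_map[m] == strategy]
        per_strategy[strategy] = float(values.loc[members].mean())
    return average, per_strategy


def mlhs_evenness(per_strategy_means, k: int | None = None) -> float:
    """Pielou evenness of the strategy-level mean completenesses.

    ``J = H / ln(K)`` where H is the Shannon entropy of the normalized means
    and K defaults to the number of strategies supplied (zero means still
    count toward K). Returns NaN when the means sum to zero or K < 2.
    """
    means = np.asarray(
        list(per_strategy_means.values())
        if isinstance(per_strategy_means, dict)
        else per_strategy_means,
        dtype=float,
    )
    if k is None:
        k = len(means)
    if k < 2:
        return float("nan")
    total = means.sum()
    if total <= 0:
        return float("nan")
    p = means / total
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    return h / np.log(k)


def mlhs_table(
    completeness: pd.DataFrame, strategy_map: dict[str, str]
) -> pd.DataFrame:
    """Per-taxon mLHS statistics over a taxa × modules completeness matrix.

    Columns: one ``m_<strategy>`` per mapped strategy, ``average_mlhs``
    (module-level mean), ``strategy_mean_mlhs`` (mean of strategy means,
    emitted for comparison) and ``evenness_mlhs``.
    """
    mapped = [m for m in completeness.columns if m in strategy_map]
    if not mapped:
        raise ValueError("strategy map covers no module of the completeness matrix")
    strategies = sorted(set(strategy_map[m] for m in mapped))
    out = pd.DataFrame(index=completeness.index)
    per_strategy = {}
    for strategy in strategies:
        members = [m for m in mapped if strategy_map[m] == strategy]
        per_strategy[strategy] = completeness[members].mean(axis=1)
        out[f"m_{strategy}"] = per_strategy[strategy]
    out["average_mlhs"] = completeness[mapped].mean(axis=1)
    out["strategy_mean_mlhs"] = out[[f"m_{s}" for s in strategies]].mean(axis=1)
    k = len(strategies)
    out["evenness_mlhs"] = [
        mlhs_evenness([per_strategy[s].loc[t] for s in strategies], k=k)
        for t in completeness.index
    ]
    return out


def mlhs_breadth_association(
    mlhs: pd.DataFrame, breadth: pd.Series
) -> pd.DataFrame:
    """Pearson association of average and evenness mLHS with niche breadth.

    Taxa with undefined evenness are excluded pairwise. Raises when fewer
    than three usable taxa remain for a statistic (an all-NaN evenness
    column surfaces as an error, never a silent NaN row).
    """
    taxa = [t for t in mlhs.index if t in breadth.index]
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa with both mLHS and breadth")
    rows = []
    for stat in ("average_mlhs", "evenness_mlhs"):
        r, t, df, p = pearson_screen(
            mlhs.loc[taxa, stat].to_numpy(), breadth.loc[taxa].to_numpy()
        )
        rows.append({"statistic": stat, "r": r, "t": t, "df": df, "p": p})
    return pd.DataFrame(rows).set_index("statistic")


# ---------------------------------------------------------------------------
# trait space
# ---------------------------------------------------------------------------


@dataclass
class TraitSpaceResult:
    scores: pd.DataFrame  # taxa × PCs
    pc1_loadings: pd.Series  # Pearson corr of each module with PC1
    explained_variance_ratio: np.ndarray
    dropped_modules: list[str]


def trait_space_pca(
    completeness: pd.DataFrame, standardize: bool = True
) -> TraitSpaceResult:
    """PCA of the module-completeness matrix.

    Modules are standardized by default (PCA on the correlation matrix) —
    completeness values share a scale but not a variance. Zero-variance
    modules are dropped with a warning. PC1 loadings are reported as the
    Pearson correlation of each retained module with the PC1 score.
    """
    if completeness.shape[1] < 2 or completeness.shape[0] < 3:
        raise ValueError("need at least 3 taxa and 2 modules")
    spans = completeness.max(axis=0) - completeness.min(axis=0)
    dropped = list(spans.index[spans == 0])
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance module(s)", stacklevel=2)
    kept = completeness.drop(columns=dropped)
    x = kept.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    if standardize:
        x = x / x.std(axis=0, ddof=1)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    n = x.shape[0]
    var = s**2 / (n - 1)
    ratio = var / var.sum()
    scores = u * s
    # orient each PC so its largest-magnitude coefficient is positive
    for j in range(vt.shape[0]):
        k = np.argmax(np.abs(vt[j]))
        if vt[j, k] < 0:
            vt[j] *= -1
            scores[:, j] *= -1
    pc_cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    scores_df = pd.DataFrame(scores, index=kept.index, columns=pc_cols)
    pc1 = scores[:, 0]
    loadings = pd.Series(
        [stats.pearsonr(kept[m].to_numpy(dtype=float), pc1)[0] for m in kept.columns],
        index=kept.columns,
        name="pc1_loading",
    )
    return TraitSpaceResult(scores_df, loadings, ratio, dropped)


@dataclass
class ClusterResult:
    spearman: pd.DataFrame  # modules × modules correlation
    linkage: np.ndarray
    k: int
    labels: pd.Series  # module -> cluster id (1..k)
    silhouette_by_k: dict[int, float]
    low_confidence: bool


def module_clusters(
    completeness: pd.DataFrame,
    k_max: int = 10,
    low_confidence_threshold: float = 0.25,
) -> ClusterResult:
    """Cluster modules by the similarity of their completeness profiles.

    Distance is 1 − pairwise Spearman ρ; agglomeration is Ward; the cluster
    count K is the argmax over 2..k_max of the mean silhouette width on the
    same distance, with ties broken toward smaller K. A ``low_confidence``
    flag marks weak structure (best silhouette below the threshold).
    """
    spans = completeness.max(axis=0) - completeness.min(axis=0)
    dropped = spans.index[spans == 0]
    if len(dropped):
        warnings.warn(
            f"dropping {len(dropped)} constant module(s) before clustering", stacklevel=2
        )
        completeness = completeness.drop(columns=dropped)
    if completeness.shape[1] < 3:
        raise ValueError("need at least 3 modules")
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    rho, _ = stats.spearmanr(completeness.to_numpy(dtype=float))
    rho = np.atleast_2d(rho)
    if np.isnan(rho).any():
        raise ValueError("Spearman correlation undefined (constant module?)")
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    condensed = dist[np.triu_indices_from(dist, k=1)]
    if condensed.max() == 0:
        raise ValueError("all modules identical: zero distance everywhere")
    z = linkage(condensed, method="ward")
    modules = list(completeness.columns)
    sil: dict[int, float] = {}
    for k in range(2, min(k_max, len(modules) - 1) + 1):
        labels = fcluster(z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        sil[k] = float(silhouette_score(dist, labels, metric="precomputed"))
    if not sil:
        raise ValueError("no valid cluster count in 2..k_max")
    best_k = min(sil, key=lambda k: (-sil[k], k))
    labels = pd.Series(
        fcluster(z, t=best_k, criterion="maxclust"), index=modules, name="cluster"
    )
    spearman_df = pd.DataFrame(rho, index=modules, columns=modules)
    return ClusterResult(
        spearman=spearman_df,
        linkage=z,
        k=best_k,
        labels=labels,
        silhouette_by_k=sil,
        low_confidence=sil[best_k] < low_confidence_threshold,
    )
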