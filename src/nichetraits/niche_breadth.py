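"""The multidimensional niche-breadth index and its taxonomic summaries.

Niche breadth of a taxon is computed from its presence/absence across
samples: each environmental variable is min-max standardized to [0, 1]
(per ecosystem by default), the per-variable *environmental range* is the
span (max − min) of the standardized variable over the samples the taxon
occupies, and the breadth index is the arithmetic mean of those ranges.
Taxa occurring in fewer than ``min_occupancy`` samples (default 2, i.e.
single-occurrence taxa) are excluded — a span is meaningless for one point.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import EnvironmentTable

__all__ = [
    "standardize_environment",
    "environmental_range",
    "niche_breadth_index",
    "niche_breadth",
    "breadth_by_group",
]


def standardize_environment(
    env: EnvironmentTable, scope: str = "per_ecosystem"
) -> EnvironmentTable:
    """Min-max standardize each variable to [0, 1] within ``scope``.

    ``scope`` is ``"per_ecosystem"`` (the default: min and max are taken
    within each ecosystem separately) or ``"global"``. Missing values stay
    missing. A variable constant within its scope has no defined scale and
    raises ``ValueError`` naming the variable.
    """
    if scope == "global":
        values = _minmax(env.values)
    elif scope == "per_ecosystem":
        pieces = []
        for eco in env.ecosystems:
            mask = env.ecosystem == eco
            pieces.append(_minmax(env.values.loc[mask], f" in ecosystem {eco!r}"))
        values = pd.concat(pieces).loc[env.samples]
    else:
        raise ValueError(f"unknown scope {scope!r} (per_ecosystem or global)")
    return EnvironmentTable(values, env.ecosystem.copy())


def _minmax(frame: pd.DataFrame, scope_note: str = "") -> pd.DataFrame:
    lo = frame.min(axis=0, skipna=True)
    hi = frame.max(axis=0, skipna=True)
    constant = hi <= lo
    if constant.any():
        var = constant.index[constant.to_numpy()][0]
        raise ValueError(f"variable {var!r} is constant{scope_note}; cannot standardize")
    return (frame - lo) / (hi - lo)


def environmental_range(
    occurrence_row: np.ndarray | pd.Series, standardized_variable: np.ndarray | pd.Series,
    quantile_trim: float | None = None,
) -> float:
    """Span of one standardized variable over the samples a taxon occupies.

    Returns NaN when fewer than two occupied samples have a non-missing
    value. With ``quantile_trim`` = q (e.g. 0.025) the span is the
    (1−q)−q interquantile distance instead of max − min.
    """
    occ = np.asarray(occurrence_row, dtype=bool)
    x = np.asarray(standardized_variable, dtype=float)
    vals = x[occ]
    vals = vals[~np.isnan(vals)]
    if len(vals) < 2:
        return float("nan")
    if quantile_trim:
        lo, hi = np.quantile(vals, [quantile_trim, 1.0 - quantile_trim])
        return float(hi - lo)
    return float(vals.max() - vals.min())


def niche_breadth_index(
    occurrence: pd.DataFrame,
    standardized_env: EnvironmentTable,
    min_occupancy: int = 2,
    quantile_trim: float | None = None,
    ecosystem_label: str | None = None,
) -> pd.DataFrame:
    """Per-taxon niche breadth over one (already standardized) sample set.

    Returns a DataFrame indexed by taxon id with ``n_occupied``, one
    ``range_<var>`` column per variable, and ``breadth`` (the mean of the
    defined per-variable ranges). Taxa occupying fewer than ``min_occupancy``
    samples are excluded.
    """
    common = [s for s in occurrence.columns if s in set(standardized_env.samples)]
    if not common:
        raise ValueError("occurrence and environment share no samples")
    occ = occurrence[common].to_numpy(dtype=bool)
    x = standardized_env.values.loc[common].to_numpy(dtype=float)
    variables = standardized_env.variables

    records = []
    for i, taxon in enumerate(occurrence.index):
        row = occ[i]
        n_occ = int(row.sum())
        if n_occ < min_occupancy:
            continue
        ranges = [environmental_range(row, x[:, v], quantile_trim) for v in range(len(variables))]
        ranges = np.asarray(ranges, dtype=float)
        defined = ~np.isnan(ranges)
        breadth = float(ranges[defined].mean()) if defined.any() else float("nan")
        rec = {"taxon_id": taxon, "n_occupied": n_occ}
        if ecosystem_label is not None:
            rec["ecosystem"] = ecosystem_label
        rec.update({f"range_{v}": r for v, r in zip(variables, ranges)})
        rec["breadth"] = breadth
        records.append(rec)
    if not records:
        warnings.warn("no taxa survive the occupancy filter", stacklevel=2)
        cols = ["taxon_id", "n_occupied"]
        if ecosystem_label is not None:
            cols.append("ecosystem")
        cols += [f"range_{v}" for v in variables] + ["breadth"]
        return pd.DataFrame(columns=cols).set_index("taxon_id")
    return pd.DataFrame.from_records(records).set_index("taxon_id")


def niche_breadth(
    occurrence: pd.DataFrame,
    env: EnvironmentTable,
    scope: str = "per_ecosystem",
    min_occupancy: int = 2,
    quantile_trim: float | None = None,
) -> pd.DataFrame:
    """Standardize the environment and compute breadth, per ecosystem or globally.

    With ``scope="per_ecosystem"`` each ecosystem is standardized and
    analysed separately (one record per taxon per ecosystem it occupies);
    with ``scope="global"`` a single record per taxon is produced.
    """
    if scope == "global":
        std = standardize_environment(env, "global")
        return niche_breadth_index(occurrence, std, min_occupancy, quantile_trim)
    if scope != "per_ecosystem":
        raise ValueError(f"unknown scope {scope!r}")
    pieces = []
    for eco in env.ecosystems:
        samples = list(env.samples[env.ecosystem == eco])
        sub_env = standardize_environment(env.subset(samples), "global")
        sub_occ = occurrence[[s for s in samples if s in occurrence.columns]]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            piece = niche_breadth_index(
                sub_occ, sub_env, min_occupancy, quantile_trim, ecosystem_label=eco
            )
        pieces.append(piece)
    out = pd.concat(pieces)
    if out.empty:
        warnings.warn("no taxa survive the occupancy filter in any ecosystem", stacklevel=2)
    return out


def breadth_by_group(
    breadth: pd.Series, groups: pd.Series, min_group_size: int = 2
) -> tuple[pd.DataFrame, float, int, int, float]:
    """Group summaries plus a classical one-way ANOVA of breadth across groups.

    Groups smaller than ``min_group_size`` are dropped with a warning.
    Returns ``(summary, F, df_between, df_within, p)``.
    """
    frame = pd.DataFrame({"breadth": breadth, "group": groups.loc[breadth.index]}).dropna()
    sizes = frame.groupby("group").size()
    small = sizes[sizes < min_group_size]
    if len(small):
        warnings.warn(
            f"dropping {len(small)} group(s) with fewer than {min_group_size} members",
            stacklevel=2,
        )
        frame = frame[~frame["group"].isin(small.index)]
    kept = frame.groupby("group")["breadth"]
    if kept.ngroups < 2:
        raise ValueError("need at least two groups with enough members for ANOVA")
    summary = kept.agg(["count", "mean", "median", "std"])
    samples = [vals.to_numpy() for _, vals in kept]
    f_stat, p = stats.f_oneway(*samples)
    df1 = kept.ngroups - 1
    df2 = len(frame) - kept.ngroups
    return summary, float(f_stat), df1, df2, float(p)
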