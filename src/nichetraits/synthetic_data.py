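"""Synthetic survey generator with planted generalist–specialist structure.

Every downstream stage of the pipeline has a parameter-recovery test because
the generator records its ground truth: each taxon occupies samples through a
hard tolerance window per environmental variable (present iff every variable
falls within the window, then detected with probability ``d``), and each
genome's gene content depends log-odds-linearly on the taxon's true niche
breadth. True breadth is the mean over variables of the tolerance-window
width ``2 w_v`` (clipped to [0, 1]).

Each generator operation draws from its own RNG stream, derived from the
master seed by a fixed label, so adding one generator call never perturbs
another's draws and identical master seeds give byte-identical output.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .io_formats import (
    STRATEGIES,
    EnvironmentTable,
    KOAnnotationTable,
    ModuleCatalog,
    ModuleDefinition,
)

__all__ = [
    "TaxonNicheParams",
    "SyntheticTruth",
    "stream_rng",
    "generate_environment",
    "sample_niche_params",
    "generate_occurrence",
    "generate_module_catalog",
    "generate_genomes",
    "generate_tree_and_trait",
    "simulate_dataset",
]

# Fixed labels for per-operation RNG streams.
_STREAMS = {
    "environment": 11,
    "niche_params": 13,
    "occurrence": 17,
    "catalog": 19,
    "genomes": 23,
    "tree": 29,
    "trait": 31,
    "meta": 37,
}

DEFAULT_ECOSYSTEMS = ("forest", "grassland", "wetland")

#: Default environmental variable names (standardized soil/climate axes).
DEFAULT_VARIABLES = ("MAT", "MAP", "pH", "SOM", "AP", "NO3", "NH4", "moisture")


def stream_rng(seed: int, label: str) -> np.random.Generator:
    """A generator-op RNG stream derived from the master seed by a fixed label."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, _STREAMS[label]])
    )


@dataclass
class TaxonNicheParams:
    """Tolerance window of one taxon on the standardized [0, 1] gradient."""

    taxon_id: str
    centers: np.ndarray  # c_v in [0, 1]
    half_widths: np.ndarray  # w_v in [0, 0.5]
    detection: float  # d in (0, 1]

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.half_widths = np.asarray(self.half_widths, dtype=float)
        if (self.half_widths < 0).any():
            raise ValueError("half-widths must be non-negative")
        if ((self.centers < 0) | (self.centers > 1)).any():
            raise ValueError("centers must lie in [0, 1]")
        if not 0 < self.detection <= 1:
            raise ValueError("detection probability must be in (0, 1]")

    @property
    def true_breadth(self) -> float:
        """Mean over variables of the window width 2 w_v, clipped to [0, 1]."""
        return float(np.mean(np.clip(2.0 * self.half_widths, 0.0, 1.0)))


@dataclass
class SyntheticTruth:
    """Record of every planted parameter and the master seed."""

    seed: int
    niche_params: dict[str, TaxonNicheParams] = field(default_factory=dict)
    true_breadth: dict[str, float] = field(default_factory=dict)
    zero_occupancy: list[str] = field(default_factory=list)
    gene_alpha: float | None = None
    gene_beta: dict[str, float] = field(default_factory=dict)  # module -> slope
    strategy_map: dict[str, str] = field(default_factory=dict)
    sigma2: float | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "true_breadth": self.true_breadth,
            "zero_occupancy": self.zero_occupancy,
            "gene_alpha": self.gene_alpha,
            "gene_beta": self.gene_beta,
            "strategy_map": self.strategy_map,
            "sigma2": self.sigma2,
            "niche_params": {
                t: {
                    "centers": p.centers.tolist(),
                    "half_widths": p.half_widths.tolist(),
                    "detection": p.detection,
                }
                for t, p in self.niche_params.items()
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------


def generate_environment(
    n_samples_per_ecosystem: int,
    ecosystems: Sequence[str] = DEFAULT_ECOSYSTEMS,
    n_vars: int = 8,
    seed: int = 0,
    rho: float | None = None,
    var_names: Sequence[str] | None = None,
) -> EnvironmentTable:
    """Draw per-sample environmental variables, uniform(0, 1) marginally.

    With ``rho`` set, variables share an equicorrelated Gaussian copula so
    every pair has (approximately) that Pearson correlation, mimicking the
    covariation of real climate/soil axes; by default variables are
    independent.
    """
    if n_vars < 1:
        raise ValueError("n_vars must be >= 1")
    if n_samples_per_ecosystem < 2:
        raise ValueError("n_samples_per_ecosystem must be >= 2")
    rng = stream_rng(seed, "environment")
    if var_names is None:
        if n_vars <= len(DEFAULT_VARIABLES):
            var_names = DEFAULT_VARIABLES[:n_vars]
        else:
            var_names = [f"var{i + 1}" for i in range(n_vars)]
    n_total = n_samples_per_ecosystem * len(ecosystems)
    if rho is None:
        values = rng.uniform(size=(n_total, n_vars))
    else:
        if not -1.0 / max(n_vars - 1, 1) < rho < 1:
            raise ValueError("rho outside the valid equicorrelation range")
        # Gaussian copula: shared factor + idiosyncratic noise, then Phi.
        from scipy.stats import norm

        shared = rng.standard_normal((n_total, 1))
        noise = rng.standard_normal((n_total, n_vars))
        z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * noise
        values = norm.cdf(z)
    sample_ids = []
    labels = []
    for eco in ecosystems:
        for i in range(n_samples_per_ecosystem):
            sample_ids.append(f"{eco}_s{i + 1:04d}")
            labels.append(eco)
    frame = pd.DataFrame(
        values, index=pd.Index(sample_ids, name="sample_id"), columns=list(var_names)
    )
    ecosystem = pd.Series(labels, index=frame.index, name="ecosystem")
    return EnvironmentTable(frame, ecosystem)


# ---------------------------------------------------------------------------
# niche parameters + occurrence
# ---------------------------------------------------------------------------


def sample_niche_params(
    n_taxa: int,
    n_vars: int = 8,
    seed: int = 0,
    detection: float = 0.9,
    breadth_range: tuple[float, float] = (0.02, 1.0),
    width_jitter: float = 0.05,
) -> list[TaxonNicheParams]:
    """Sample tolerance windows spanning the full generalist–specialist range.

    Each taxon gets a target breadth uniform over ``breadth_range``; its
    per-variable half-widths are the corresponding window ``b/2`` plus a small
    jitter, on the premise that tolerance is a property of the organism and
    therefore correlates strongly across environmental axes (a generalist is
    broadly tolerant on every axis). Centers are placed so the window lies
    inside the observed [0, 1] gradient.
    """
    rng = stream_rng(seed, "niche_params")
    params = []
    for i in range(n_taxa):
        b = rng.uniform(*breadth_range)
        w = np.clip(
            b / 2.0 + width_jitter * rng.uniform(-1, 1, size=n_vars), 0.0, 0.5
        )
        c = rng.uniform(w, 1.0 - w)
        params.append(
            TaxonNicheParams(
                taxon_id=f"t{i + 1:04d}",
                centers=c,
                half_widths=w,
                detection=detection,
            )
        )
    return params


def generate_occurrence(
    env: EnvironmentTable,
    niche_params: Sequence[TaxonNicheParams],
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Realise presence/absence from tolerance windows plus Bernoulli detection.

    A taxon is present in a sample iff every (min-max standardized) variable
    lies within its tolerance window, and the occurrence survives detection
    with probability ``d``. Taxa that end up occupying no sample are still
    emitted (all-zero rows) and flagged in the truth record.
    """
    rng = stream_rng(seed, "occurrence")
    x = env.values.to_numpy(dtype=float)
    # standardize to [0, 1] for the window test (identity for generated data)
    lo = np.nanmin(x, axis=0)
    hi = np.nanmax(x, axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    xs = (x - lo) / span
    truth = SyntheticTruth(seed=int(seed))
    rows = []
    taxa = []
    for p in niche_params:
        inside = np.abs(xs - p.centers) <= p.half_widths[None, :]
        in_window = np.nan_to_num(inside, nan=False).all(axis=1)
        detected = rng.uniform(size=len(in_window)) < p.detection
        present = (in_window & detected).astype(np.int8)
        rows.append(present)
        taxa.append(p.taxon_id)
        truth.niche_params[p.taxon_id] = p
        truth.true_breadth[p.taxon_id] = p.true_breadth
        if present.sum() == 0:
            truth.zero_occupancy.append(p.taxon_id)
    occurrence = pd.DataFrame(
        np.vstack(rows),
        index=pd.Index(taxa, name="taxon_id"),
        columns=env.samples,
    )
    return occurrence, truth


# ---------------------------------------------------------------------------
# module catalog
# ---------------------------------------------------------------------------


def generate_module_catalog(
    n_strategies: int = 5,
    modules_per_strategy: int = 11,
    steps_per_module: int = 4,
    kos_per_step: int = 1,
    seed: int = 0,
) -> tuple[ModuleCatalog, dict[str, str]]:
    """Build a catalog with disjoint KO universes per module.

    Mirrors the shape of a module set grouped into life-history strategies
    (e.g. 5 strategies × 11 modules). Steps randomly receive one or two
    alternatives so the full step/alternative/complex grammar is exercised.
    """
    if min(n_strategies, modules_per_strategy, steps_per_module, kos_per_step) < 1:
        raise ValueError("all counts must be >= 1")
    if n_strategies > len(STRATEGIES):
        raise ValueError(f"at most {len(STRATEGIES)} strategies available")
    rng = stream_rng(seed, "catalog")
    ko_counter = 0
    modules: list[ModuleDefinition] = []
    strategy_map: dict[str, str] = {}
    m_index = 0
    for s in range(n_strategies):
        strategy = STRATEGIES[s]
        for _ in range(modules_per_strategy):
            m_index += 1
            module_id = f"M{m_index:05d}"
            steps = []
            for _ in range(steps_per_module):
                n_alts = int(rng.integers(1, 3))
                alts = []
                for _ in range(n_alts):
                    kos = []
                    for _ in range(kos_per_step):
                        ko_counter += 1
                        kos.append(f"K{ko_counter:05d}")
                    alts.append(frozenset(kos))
                steps.append(tuple(alts))
            modules.append(ModuleDefinition(module_id, tuple(steps)))
            strategy_map[module_id] = strategy
    return ModuleCatalog(modules), strategy_map


# ---------------------------------------------------------------------------
# genomes
# ---------------------------------------------------------------------------


def generate_genomes(
    truth: SyntheticTruth,
    catalog: ModuleCatalog,
    alpha: float = -3.0,
    beta_map: Mapping[str, float] | None = None,
    seed: int = 0,
    copy_lambda: float | None = None,
    base_size: float = 2.0e6,
    size_per_gene: float = 1000.0,
) -> KOAnnotationTable:
    """Draw genomes whose gene content depends log-odds-linearly on breadth.

    For each taxon and module, every KO of the module is present
    independently with probability ``logistic(alpha + beta * NB_true)``.
    Copy counts are 1 when present, or ``1 + Poisson(copy_lambda)`` under the
    optional copy model. Genome size grows linearly with total gene count.
    """
    rng = stream_rng(seed, "genomes")
    beta_map = dict(beta_map or {})
    truth.gene_alpha = float(alpha)
    truth.gene_beta = {m.module_id: float(beta_map.get(m.module_id, 0.0)) for m in catalog}
    taxa = list(truth.true_breadth)
    all_kos = sorted({ko for m in catalog for ko in m.kos()})
    counts = np.zeros((len(taxa), len(all_kos)), dtype=int)
    col = {ko: j for j, ko in enumerate(all_kos)}
    for i, taxon in enumerate(taxa):
        b = truth.true_breadth[taxon]
        for module in catalog:
            beta = truth.gene_beta[module.module_id]
            p = 1.0 / (1.0 + np.exp(-(alpha + beta * b)))
            for ko in sorted(module.kos()):
                if rng.uniform() < p:
                    c = 1
                    if copy_lambda is not None:
                        c += int(rng.poisson(copy_lambda))
                    counts[i, col[ko]] = c
    totals = counts.sum(axis=1)
    gc = np.clip(rng.normal(0.55, 0.05, size=len(taxa)), 0.2, 0.8)
    genome_size = base_size + size_per_gene * totals
    # coding density of roughly one gene per kb, as in compact bacterial genomes
    cds = np.round(genome_size / 1000.0).astype(int)
    meta = pd.DataFrame(
        {"genome_size": genome_size, "gc": gc, "cds": cds},
        index=pd.Index(taxa, name="taxon_id"),
    )
    frame = pd.DataFrame(counts, index=meta.index, columns=all_kos)
    return KOAnnotationTable(frame, meta)


# ---------------------------------------------------------------------------
# trees + Brownian traits
# ---------------------------------------------------------------------------


def generate_tree_and_trait(
    n_tips: int,
    sigma2: float = 1.0,
    seed: int = 0,
    tip_labels: Sequence[str] | None = None,
) -> tuple[dendropy.Tree, pd.Series]:
    """Simulate a Yule tree and a Brownian-motion trait along its branches."""
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    tree_rng = random.Random(int(stream_rng(seed, "tree").integers(2**31)))
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=tree_rng,
    )
    leaves = list(tree.leaf_node_iter())
    if tip_labels is None:
        tip_labels = [f"t{i + 1:04d}" for i in range(len(leaves))]
    for leaf, label in zip(leaves, tip_labels):
        leaf.taxon.label = str(label)
    trait = simulate_brownian_trait(tree, sigma2, seed)
    return tree, trait


def simulate_brownian_trait(
    tree: dendropy.Tree, sigma2: float, seed: int = 0, root_value: float = 0.0
) -> pd.Series:
    """Brownian motion along branches: child = parent + N(0, sigma2 * length)."""
    rng = stream_rng(seed, "trait")
    values: dict[int, float] = {}
    tips: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = root_value
        else:
            length = node.edge.length or 0.0
            step = rng.normal(0.0, np.sqrt(sigma2 * length)) if sigma2 > 0 else 0.0
            values[id(node)] = values[id(node.parent_node)] + step
        if node.is_leaf():
            tips[node.taxon.label] = values[id(node)]
    return pd.Series(tips, name="trait")


# ---------------------------------------------------------------------------
# whole-survey convenience
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    env: EnvironmentTable
    occurrence: pd.DataFrame
    annotations: KOAnnotationTable
    catalog: ModuleCatalog
    strategy_map: dict[str, str]
    tree: dendropy.Tree
    truth: SyntheticTruth


def simulate_dataset(
    seed: int = 0,
    n_samples_per_ecosystem: int = 150,
    ecosystems: Sequence[str] = DEFAULT_ECOSYSTEMS,
    n_vars: int = 8,
    n_taxa: int = 300,
    detection: float = 0.9,
    n_strategies: int = 5,
    modules_per_strategy: int = 11,
    steps_per_module: int = 4,
    kos_per_step: int = 1,
    alpha: float = -3.0,
    beta_positive: float = 2.0,
    fraction_effect_modules: float = 0.6,
    fraction_negative: float = 0.2,
    sigma2: float = 1.0,
    rho: float | None = None,
) -> SyntheticDataset:
    """Generate a full survey under the study's default conditions.

    Defaults emulate the scale of a three-ecosystem soil survey (hundreds of
    samples per ecosystem, eight standardized environmental axes, a 55-module
    catalog over five life-history strategies). A fraction of modules carries
    a planted log-odds slope of gene content on true breadth, mostly positive
    with a minority negative, so the downstream screen has both signal and
    null features.
    """
    env = generate_environment(
        n_samples_per_ecosystem, ecosystems, n_vars, seed=seed, rho=rho
    )
    params = sample_niche_params(n_taxa, n_vars, seed=seed, detection=detection)
    occurrence, truth = generate_occurrence(env, params, seed=seed)
    catalog, strategy_map = generate_module_catalog(
        n_strategies, modules_per_strategy, steps_per_module, kos_per_step, seed=seed
    )
    truth.strategy_map = dict(strategy_map)
    rng = stream_rng(seed, "meta")
    beta_map: dict[str, float] = {}
    for module in catalog:
        u = rng.uniform()
        if u < fraction_effect_modules * (1.0 - fraction_negative):
            beta_map[module.module_id] = beta_positive
        elif u < fraction_effect_modules:
            beta_map[module.module_id] = -beta_positive
        else:
            beta_map[module.module_id] = 0.0
    annotations = generate_genomes(truth, catalog, alpha=alpha, beta_map=beta_map, seed=seed)
    tree, _ = generate_tree_and_trait(
        n_taxa, sigma2=sigma2, seed=seed, tip_labels=list(occurrence.index)
    )
    truth.sigma2 = float(sigma2)
    return SyntheticDataset(env, occurrence, annotations, catalog, strategy_map, tree, truth)
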