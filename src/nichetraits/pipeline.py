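"""One seeded, configured, logged run of the whole analysis.

Stages: simulate (or load) → niche breadth → module completeness → GLM
trait screen + consensus → mLHS / trait space → phylogenetic signal. Every
stage writes a TSV into the run directory and the manifest records the
config hash, master seed and per-output row counts, so a rerun with the
same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io_formats as iof
from . import life_history as lh
from . import phylo_signal as ps
from . import synthetic_data as sd
from . import trait_screen as tsc
from .niche_breadth import niche_breadth as _compute_breadth
from ._version import __version__

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("nichetraits.pipeline")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class RunConfig:
    """Declarative configuration of a pipeline run (YAML-loadable)."""

    seed: int = 0
    # --- simulation (used when simulate=True) ---
    simulate: bool = True
    n_samples_per_ecosystem: int = 150
    ecosystems: tuple[str, ...] = sd.DEFAULT_ECOSYSTEMS
    n_vars: int = 8
    n_taxa: int = 300
    detection: float = 0.9
    n_strategies: int = 5
    modules_per_strategy: int = 11
    steps_per_module: int = 4
    kos_per_step: int = 1
    gene_alpha: float = -3.0
    beta_positive: float = 2.0
    fraction_effect_modules: float = 0.6
    fraction_negative: float = 0.2
    sigma2: float = 1.0
    env_rho: float | None = None
    # --- real inputs (used when simulate=False) ---
    env_path: str | None = None
    occurrence_path: str | None = None
    annotations_path: str | None = None
    catalog_path: str | None = None
    tree_path: str | None = None
    # --- analysis parameters ---
    scope: str = "per_ecosystem"
    min_occupancy: int = 2
    binarization: str = "any_gene"  # or "any_step"
    alpha: float = 0.05
    min_ecosystems: int = 2
    distance: str = "jaccard"
    n_perm: int = 999
    k_max: int = 10

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config key(s): {sorted(unknown)}")
        if "ecosystems" in data:
            data = {**data, "ecosystems": tuple(data["ecosystems"])}
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["ecosystems"] = list(out["ecosystems"])
        return out


def _config_hash(config: RunConfig) -> str:
    canon = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(canon).hexdigest()


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute every stage into ``out_dir`` and return the manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    def _write(frame: pd.DataFrame, name: str, index: bool = True) -> None:
        iof.write_results(frame.reset_index() if index else frame, out / name)
        counts[name] = len(frame)
        logger.info("wrote %s (%d rows)", name, len(frame))

    # ---- stage: inputs ------------------------------------------------
    data = _load_or_simulate(config, out, counts)
    env, occurrence, annotations = data["env"], data["occurrence"], data["annotations"]
    catalog, strategy_map, tree = data["catalog"], data["strategy_map"], data["tree"]

    # ---- stage: breadth ------------------------------------------------
    breadth = _stage("breadth")(_compute_breadth)(
        occurrence, env, scope=config.scope, min_occupancy=config.min_occupancy
    )
    _write(breadth, "breadth.tsv")
    breadth_global = _stage("breadth")(_compute_breadth)(
        occurrence, env, scope="global", min_occupancy=config.min_occupancy
    )
    _write(breadth_global, "breadth_global.tsv")

    # ---- stage: genome traits ------------------------------------------
    from . import genome_traits as gt

    completeness, binary = _stage("annotate-traits")(gt.completeness_matrix)(
        annotations, catalog
    )
    _write(completeness, "completeness.tsv")
    _write(binary, "module_binary.tsv")
    summaries = _stage("annotate-traits")(gt.genome_summaries)(annotations)
    _write(summaries, "genome_summaries.tsv")

    # ---- stage: screen ---------------------------------------------------
    trait_source = binary if config.binarization == "any_gene" else (
        (completeness > 0).astype(int)
    )
    screens, skipped_all = [], []
    ecosystems_present = (
        list(breadth["ecosystem"].unique()) if "ecosystem" in breadth else ["all"]
    )
    for eco in ecosystems_present:
        sub = breadth[breadth["ecosystem"] == eco] if "ecosystem" in breadth else breadth
        taxa = [t for t in sub.index if t in trait_source.index]
        if len(taxa) < 10:
            logger.warning("ecosystem %s: too few taxa with genomes, skipped", eco)
            continue
        res, skipped = _stage("screen")(tsc.screen_features)(
            trait_source.loc[taxa].T, sub.loc[taxa, "breadth"], eco
        )
        screens.append(res)
        skipped_all.append(skipped)
    screen = pd.concat(screens, ignore_index=True) if screens else pd.DataFrame()
    _write(screen, "screen.tsv", index=False)
    skipped = (
        pd.concat(skipped_all, ignore_index=True) if skipped_all else pd.DataFrame()
    )
    _write(skipped, "screen_skipped.tsv", index=False)
    consensus = _stage("screen")(tsc.consensus_filter)(
        screen, alpha=config.alpha, min_ecosystems=config.min_ecosystems
    ) if len(screen) else pd.DataFrame()
    _write(consensus, "consensus.tsv", index=False)

    # ---- stage: permanova ------------------------------------------------
    permanova_rows = []
    for eco in ecosystems_present:
        sub = breadth[breadth["ecosystem"] == eco] if "ecosystem" in breadth else breadth
        taxa = [t for t in sub.index if t in binary.index]
        if len(taxa) < 5:
            continue
        r2, f, p = _stage("permanova")(tsc.permanova)(
            binary.loc[taxa],
            sub.loc[taxa, "breadth"],
            distance=config.distance,
            n_perm=config.n_perm,
            seed=config.seed,
        )
        permanova_rows.append(
            {"ecosystem": eco, "r2": r2, "pseudo_f": f, "p": p, "n_taxa": len(taxa)}
        )
    _write(pd.DataFrame(permanova_rows), "permanova.tsv", index=False)

    # ---- stage: life history --------------------------------------------
    if not strategy_map:
        raise PipelineError(
            "stage 'lifehistory' failed: no strategy map "
            f"(missing file: {config.catalog_path or 'catalog'})"
        )
    mlhs = _stage("lifehistory")(lh.mlhs_table)(completeness, strategy_map)
    _write(mlhs, "mlhs.tsv")
    assoc_rows = []
    for eco in ecosystems_present:
        sub = breadth[breadth["ecosystem"] == eco] if "ecosystem" in breadth else breadth
        taxa = [t for t in sub.index if t in mlhs.index]
        if len(taxa) < 3:
            continue
        try:
            assoc = lh.mlhs_breadth_association(mlhs.loc[taxa], sub.loc[taxa, "breadth"])
        except ValueError as exc:
            logger.warning("mLHS association in %s skipped: %s", eco, exc)
            continue
        assoc = assoc.reset_index()
        assoc.insert(0, "ecosystem", eco)
        assoc_rows.append(assoc)
    _write(
        pd.concat(assoc_rows, ignore_index=True) if assoc_rows else pd.DataFrame(),
        "mlhs_association.tsv",
        index=False,
    )
    pca = _stage("lifehistory")(lh.trait_space_pca)(completeness)
    _write(
        pca.pc1_loadings.to_frame().assign(
            pc1_variance_fraction=pca.explained_variance_ratio[0]
        ),
        "pca_loadings.tsv",
    )
    clusters = _stage("lifehistory")(lh.module_clusters)(completeness, k_max=config.k_max)
    _write(
        clusters.labels.to_frame().assign(selected_k=clusters.k),
        "module_clusters.tsv",
    )

    # ---- stage: phylosignal ----------------------------------------------
    phylo_rows = []
    trait = breadth_global["breadth"]
    trait = trait[[t in {l.taxon.label for l in tree.leaf_node_iter()} for t in trait.index]]
    if len(trait) >= 4 and np.ptp(trait.to_numpy()) > 0:
        sig = _stage("phylosignal")(ps.blomberg_k)(
            tree, trait, n_perm=config.n_perm, seed=config.seed
        )
        r_mantel, p_mantel = _stage("phylosignal")(ps.distance_breadth_correlation)(
            tree, trait, n_perm=config.n_perm, seed=config.seed
        )
        phylo_rows.append(
            {
                "trait": "breadth",
                "k": sig.k,
                "p_perm": sig.p_perm,
                "n_tips": sig.n_tips,
                "mantel_r": r_mantel,
                "mantel_p": p_mantel,
            }
        )
    _write(pd.DataFrame(phylo_rows), "phylosignal.tsv", index=False)

    # ---- manifest ---------------------------------------------------------
    manifest = {
        "config": config.to_dict(),
        "config_sha256": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "row_counts": dict(sorted(counts.items())),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(out / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return manifest


def _load_or_simulate(config: RunConfig, out: Path, counts: dict) -> dict:
    if config.simulate:
        dataset = _stage("simulate")(sd.simulate_dataset)(
            seed=config.seed,
            n_samples_per_ecosystem=config.n_samples_per_ecosystem,
            ecosystems=config.ecosystems,
            n_vars=config.n_vars,
            n_taxa=config.n_taxa,
            detection=config.detection,
            n_strategies=config.n_strategies,
            modules_per_strategy=config.modules_per_strategy,
            steps_per_module=config.steps_per_module,
            kos_per_step=config.kos_per_step,
            alpha=config.gene_alpha,
            beta_positive=config.beta_positive,
            fraction_effect_modules=config.fraction_effect_modules,
            fraction_negative=config.fraction_negative,
            sigma2=config.sigma2,
            rho=config.env_rho,
        )
        iof.write_environment_table(dataset.env, out / "env.tsv")
        iof.write_occurrence_matrix(dataset.occurrence, out / "occurrence.tsv")
        iof.write_ko_annotations(dataset.annotations, out / "ko_annotations.tsv")
        iof.write_module_catalog(dataset.catalog, dataset.strategy_map, out / "modules.tsv")
        iof.write_strategy_map(dataset.strategy_map, out / "strategy_map.tsv")
        iof.write_tree(dataset.tree, out / "tree.nwk")
        dataset.truth.to_json(out / "truth.json")
        counts["occurrence.tsv"] = len(dataset.occurrence)
        counts["env.tsv"] = len(dataset.env.samples)
        return {
            "env": dataset.env,
            "occurrence": dataset.occurrence,
            "annotations": dataset.annotations,
            "catalog": dataset.catalog,
            "strategy_map": dataset.strategy_map,
            "tree": dataset.tree,
        }
    for key in ("env_path", "occurrence_path", "annotations_path", "catalog_path", "tree_path"):
        value = getattr(config, key)
        if value is None:
            raise PipelineError(f"stage 'inputs' failed: missing {key} in config")
        if not Path(value).exists():
            raise PipelineError(f"stage 'inputs' failed: missing file {value}")
    env = _stage("inputs")(iof.read_environment_table)(config.env_path)
    occurrence = _stage("inputs")(iof.read_occurrence_matrix)(config.occurrence_path)
    annotations = _stage("inputs")(iof.read_ko_annotations)(config.annotations_path)
    catalog, strategy_map = _stage("inputs")(iof.parse_module_catalog)(config.catalog_path)
    tree = _stage("inputs")(iof.read_tree)(config.tree_path)
    counts["occurrence.tsv"] = len(occurrence)
    counts["env.tsv"] = len(env.samples)
    return {
        "env": env,
        "occurrence": occurrence,
        "annotations": annotations,
        "catalog": catalog,
        "strategy_map": strategy_map,
        "tree": tree,
    }
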