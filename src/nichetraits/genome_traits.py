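"""Genome-derived trait quantification: module completeness, KO richness,
and category-level gene-copy sums.

Module completeness is the fraction of a module's steps that are satisfied;
a step is satisfied iff at least one of its alternatives has *all* of its
KOs annotated in the genome (copy count >= 1). There is no partial credit
within a step: an AND-complex missing one KO contributes nothing.

Binary module presence is a weaker notion: 1 iff *any* KO appearing anywhere
in the module definition is annotated, so a genome can be "present" for a
module whose completeness is 0. Both columns are emitted because the
downstream screen can be configured to binarize either way.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .io_formats import KOAnnotationTable, ModuleCatalog, ModuleDefinition

__all__ = [
    "module_completeness",
    "module_binary_presence",
    "completeness_matrix",
    "genome_summaries",
]


def _as_ko_set(ko_counts) -> frozenset[str]:
    if isinstance(ko_counts, (set, frozenset)):
        return frozenset(ko_counts)
    if isinstance(ko_counts, Mapping):
        return frozenset(k for k, v in ko_counts.items() if v >= 1)
    if isinstance(ko_counts, pd.Series):
        return frozenset(ko_counts.index[ko_counts.to_numpy() >= 1])
    raise TypeError(f"cannot interpret {type(ko_counts).__name__} as a KO set")


def module_completeness(ko_counts, module: ModuleDefinition) -> float:
    """Fraction of the module's steps satisfied by the genome's KO set."""
    present = _as_ko_set(ko_counts)
    satisfied = sum(
        1 for step in module.steps if any(alt <= present for alt in step)
    )
    return satisfied / module.n_steps


def module_binary_presence(ko_counts, module: ModuleDefinition) -> int:
    """1 iff any KO of the module definition is annotated in the genome."""
    present = _as_ko_set(ko_counts)
    return int(bool(present & module.kos()))


def completeness_matrix(
    annotations: KOAnnotationTable, catalog: ModuleCatalog
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-genome completeness and binary presence for every catalog module.

    Returns ``(completeness, binary)``, both taxa × modules.
    """
    taxa = list(annotations.taxa)
    comp = np.zeros((len(taxa), len(catalog)))
    binary = np.zeros((len(taxa), len(catalog)), dtype=np.int8)
    counts = annotations.counts
    present_matrix = counts.to_numpy() >= 1
    col_of = {ko: j for j, ko in enumerate(counts.columns)}
    for j, module in enumerate(catalog):
        module_cols = [col_of[ko] for ko in module.kos() if ko in col_of]
        any_gene = (
            present_matrix[:, module_cols].any(axis=1)
            if module_cols
            else np.zeros(len(taxa), dtype=bool)
        )
        binary[:, j] = any_gene
        # step satisfaction, vectorized over genomes
        sat = np.zeros(len(taxa))
        for step in module.steps:
            step_ok = np.zeros(len(taxa), dtype=bool)
            for alt in step:
                cols = [col_of[ko] for ko in alt if ko in col_of]
                if len(cols) == len(alt):
                    step_ok |= present_matrix[:, cols].all(axis=1)
            sat += step_ok
        comp[:, j] = sat / module.n_steps
    index = pd.Index(taxa, name="taxon_id")
    columns = pd.Index(catalog.module_ids, name="module_id")
    return (
        pd.DataFrame(comp, index=index, columns=columns),
        pd.DataFrame(binary, index=index, columns=columns),
    )


def genome_summaries(
    annotations: KOAnnotationTable,
    category_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-genome KO richness (S.KO), structure fields, and category copy sums.

    ``category_map`` maps KO id → category label (e.g. a KEGG level-2
    grouping); the summary gains one ``copies_<category>`` column per label,
    the total copy count of that category's KOs. KOs in the map but absent
    from the annotation simply contribute zero.
    """
    counts = annotations.counts
    out = pd.DataFrame(index=counts.index)
    out["s_ko"] = (counts.to_numpy() >= 1).sum(axis=1)
    out["total_copies"] = counts.sum(axis=1)
    for col in annotations.meta.columns:
        out[col] = annotations.meta[col]
    if category_map:
        categories = sorted(set(category_map.values()))
        for cat in categories:
            kos = [k for k, c in category_map.items() if c == cat and k in counts.columns]
            out[f"copies_{cat}"] = counts[kos].sum(axis=1) if kos else 0
    return out
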