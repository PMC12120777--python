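"""Readers, writers and validation for every table and format the pipeline touches.

All tabular files are tab-separated UTF-8 with ``.`` as the decimal mark; there
is deliberately no CSV autodetection, which avoids locale ambiguity. Missing
environment values are written as ``NA`` and parsed back to NaN — they are
excluded per-variable downstream, never imputed.

Module definitions use a deliberately small grammar: steps joined by ``;``,
alternatives within a step by ``|``, AND-complexes within an alternative by
``+`` (e.g. ``K00001;K00002|K00003;K00004+K00005``). Nested parentheses and
optional terms found in full KEGG DEFINITION strings are out of scope.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "STRATEGIES",
    "FormatError",
    "EnvironmentTable",
    "ModuleDefinition",
    "ModuleCatalog",
    "KOAnnotationTable",
    "read_environment_table",
    "write_environment_table",
    "read_occurrence_matrix",
    "write_occurrence_matrix",
    "read_ko_annotations",
    "write_ko_annotations",
    "parse_module_definition",
    "parse_module_catalog",
    "write_module_catalog",
    "read_strategy_map",
    "write_strategy_map",
    "read_tree",
    "write_tree",
    "write_results",
    "read_results",
]

#: Fixed vocabulary of life-history strategies a module may be assigned to.
STRATEGIES = (
    "growth",
    "competition",
    "stress_tolerance",
    "resource_acquisition",
    "dispersal",
    "other",
)

#: Decimal places used when serialising floating-point results.
FLOAT_PRECISION = 12

_TOKEN_RE = re.compile(r"^[A-Za-z0-9_.:-]+$")


class FormatError(ValueError):
    """Raised when an input file violates its dialect or its invariants."""


# ---------------------------------------------------------------------------
# environment table
# ---------------------------------------------------------------------------


@dataclass
class EnvironmentTable:
    """Per-sample environmental measurements plus an ecosystem label.

    Parameters
    ----------
    values : pandas.DataFrame
        Samples (rows, indexed by sample id) by environmental variables
        (columns), in original units; NaN marks a missing measurement.
    ecosystem : pandas.Series
        Ecosystem label per sample, aligned with ``values``.
    """

    values: pd.DataFrame
    ecosystem: pd.Series

    def __post_init__(self) -> None:
        self.values.index = self.values.index.astype(str)
        self.ecosystem.index = self.ecosystem.index.astype(str)
        self.validate()

    @property
    def samples(self) -> pd.Index:
        return self.values.index

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)

    @property
    def ecosystems(self) -> list[str]:
        return list(pd.unique(self.ecosystem))

    def subset(self, samples: Sequence[str]) -> "EnvironmentTable":
        samples = list(samples)
        return EnvironmentTable(
            self.values.loc[samples].copy(), self.ecosystem.loc[samples].copy()
        )

    def validate(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        if not self.values.index.equals(self.ecosystem.index):
            raise FormatError("sample ids of values and ecosystem labels differ")
        if self.ecosystem.isna().any():
            missing = self.ecosystem.index[self.ecosystem.isna()][0]
            raise FormatError(f"sample {missing!r} has no ecosystem label")
        # no variable may be entirely missing within an ecosystem
        for eco, sub in self.values.groupby(self.ecosystem):
            all_na = sub.columns[sub.isna().all()]
            if len(all_na):
                raise FormatError(
                    f"variable {all_na[0]!r} entirely missing in ecosystem {eco!r}"
                )


def read_environment_table(path: str | Path) -> EnvironmentTable:
    """Read a TSV with columns ``sample_id``, ``ecosystem``, then variables.

    ``NA`` and empty cells are recorded as missing, not zero. Raises
    :class:`FormatError` on duplicate sample ids, non-numeric variable cells
    or an empty file.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty environment table: {path}") from exc
    if raw.empty or "sample_id" not in raw.columns or "ecosystem" not in raw.columns:
        raise FormatError(
            f"{path}: expected header starting with sample_id, ecosystem"
        )
    sample_ids = raw["sample_id"].astype(str)
    if sample_ids.duplicated().any():
        dup = sample_ids[sample_ids.duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate sample id {dup!r}")
    var_cols = [c for c in raw.columns if c not in ("sample_id", "ecosystem")]
    values = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    for col in var_cols:
        cell = raw[col].replace({"": "NA"})
        parsed = pd.to_numeric(cell.where(cell != "NA"), errors="coerce")
        bad = cell[(cell != "NA") & parsed.isna()]
        if len(bad):
            raise FormatError(
                f"{path}: non-numeric value {bad.iloc[0]!r} in variable {col!r}"
            )
        values[col] = parsed.to_numpy()
    ecosystem = pd.Series(
        raw["ecosystem"].astype(str).to_numpy(), index=values.index, name="ecosystem"
    )
    return EnvironmentTable(values, ecosystem)


def write_environment_table(table: EnvironmentTable, path: str | Path) -> None:
    out = table.values.copy()
    out.insert(0, "ecosystem", table.ecosystem)
    _write_frame(out.reset_index(), Path(path))


# ---------------------------------------------------------------------------
# occurrence matrix
# ---------------------------------------------------------------------------


def read_occurrence_matrix(path: str | Path) -> pd.DataFrame:
    """Read a taxa (rows) × samples (columns) presence/absence TSV."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty occurrence matrix: {path}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate taxon id {dup!r}")
    arr = df.to_numpy()
    if not np.isin(arr, (0, 1)).all():
        raise FormatError(f"{path}: occurrence entries must be 0 or 1")
    return df.astype(np.int8)


def write_occurrence_matrix(occurrence: pd.DataFrame, path: str | Path) -> None:
    out = occurrence.astype(int).copy()
    out.index.name = out.index.name or "taxon_id"
    _write_frame(out.reset_index(), Path(path))


# ---------------------------------------------------------------------------
# KO annotations
# ---------------------------------------------------------------------------


@dataclass
class KOAnnotationTable:
    """Per-genome KO copy counts plus genome structure descriptors.

    ``counts`` is taxa × KO identifiers (non-negative integers); ``meta``
    carries ``genome_size`` (bp), ``gc`` (fraction) and ``cds`` (count) where
    known (NaN otherwise).
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts.index = self.counts.index.astype(str)
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate taxon id: {dup!r}")
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("KO copy counts must be non-negative")
        if "genome_size" in self.meta.columns:
            gs = self.meta["genome_size"].dropna()
            if (gs <= 0).any():
                raise FormatError("genome_size must be positive where present")

    @property
    def taxa(self) -> pd.Index:
        return self.counts.index

    def ko_set(self, taxon_id: str) -> frozenset[str]:
        row = self.counts.loc[taxon_id]
        return frozenset(row.index[row.to_numpy() > 0])


_META_COLS = ("genome_size", "gc", "cds")


def read_ko_annotations(path: str | Path) -> KOAnnotationTable:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty KO annotation table: {path}") from exc
    df.index = df.index.astype(str)
    meta_cols = [c for c in _META_COLS if c in df.columns]
    meta = df[meta_cols].copy()
    counts = df.drop(columns=meta_cols)
    if not counts.map(lambda v: float(v).is_integer()).all().all():
        raise FormatError(f"{path}: KO copy counts must be integers")
    return KOAnnotationTable(counts.astype(int), meta)


def write_ko_annotations(table: KOAnnotationTable, path: str | Path) -> None:
    out = pd.concat([table.meta, table.counts], axis=1)
    out.index.name = "taxon_id"
    _write_frame(out.reset_index(), Path(path))


# ---------------------------------------------------------------------------
# module catalog + strategy map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModuleDefinition:
    """One metabolic module: ordered steps, each a set of alternatives.

    Each alternative is a frozenset of KO ids that must all be present
    (an AND-complex) for the alternative to satisfy its step.
    """

    module_id: str
    steps: tuple[tuple[frozenset[str], ...], ...]

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    def kos(self) -> frozenset[str]:
        """All KO ids appearing anywhere in the definition."""
        return frozenset(ko for step in self.steps for alt in step for ko in alt)

    def definition_string(self) -> str:
        return ";".join(
            "|".join("+".join(sorted(alt)) for alt in step) for step in self.steps
        )


@dataclass
class ModuleCatalog:
    modules: list[ModuleDefinition] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [m.module_id for m in self.modules]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise FormatError(f"duplicate module id: {dup!r}")
        self._by_id = {m.module_id: m for m in self.modules}

    def __iter__(self):
        return iter(self.modules)

    def __len__(self) -> int:
        return len(self.modules)

    def __getitem__(self, module_id: str) -> ModuleDefinition:
        return self._by_id[module_id]

    def __contains__(self, module_id: str) -> bool:
        return module_id in self._by_id

    @property
    def module_ids(self) -> list[str]:
        return [m.module_id for m in self.modules]


def parse_module_definition(module_id: str, definition: str) -> ModuleDefinition:
    """Parse a ``step;step|alt;ko+ko`` definition string."""
    steps: list[tuple[frozenset[str], ...]] = []
    for si, step_text in enumerate(definition.split(";"), start=1):
        if not step_text.strip():
            raise FormatError(f"module {module_id!r}: empty step at position {si}")
        alts: list[frozenset[str]] = []
        for alt_text in step_text.split("|"):
            if not alt_text.strip():
                raise FormatError(
                    f"module {module_id!r}: empty alternative in step {si}"
                )
            kos = []
            for token in alt_text.split("+"):
                token = token.strip()
                if not token or not _TOKEN_RE.match(token):
                    raise FormatError(
                        f"module {module_id!r}: malformed token {token!r} in step {si}"
                    )
                kos.append(token)
            alts.append(frozenset(kos))
        steps.append(tuple(alts))
    return ModuleDefinition(module_id, tuple(steps))


def parse_module_catalog(path: str | Path) -> tuple[ModuleCatalog, dict[str, str]]:
    """Parse a catalog file: ``module_id<TAB>strategy<TAB>definition`` per line.

    Returns the catalog and the module→strategy map carried on each line.
    """
    path = Path(path)
    modules: list[ModuleDefinition] = []
    strategy_map: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 tab-separated fields")
            module_id, strategy, definition = parts
            if strategy not in STRATEGIES:
                raise FormatError(
                    f"{path}:{lineno}: unknown strategy {strategy!r} "
                    f"(expected one of {', '.join(STRATEGIES)})"
                )
            modules.append(parse_module_definition(module_id, definition))
            strategy_map[module_id] = strategy
    if not modules:
        raise FormatError(f"{path}: no modules found")
    return ModuleCatalog(modules), strategy_map


def write_module_catalog(
    catalog: ModuleCatalog, strategy_map: Mapping[str, str], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for module in catalog:
            strategy = strategy_map.get(module.module_id, "other")
            fh.write(f"{module.module_id}\t{strategy}\t{module.definition_string()}\n")


def read_strategy_map(
    path: str | Path, catalog: ModuleCatalog | None = None
) -> dict[str, str]:
    """Read a two-column ``module_id<TAB>strategy`` TSV (with header)."""
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    if list(df.columns[:2]) != ["module_id", "strategy"]:
        raise FormatError(f"{path}: expected columns module_id, strategy")
    mapping: dict[str, str] = {}
    for module_id, strategy in zip(df["module_id"], df["strategy"]):
        if strategy not in STRATEGIES:
            raise FormatError(f"{path}: unknown strategy {strategy!r}")
        if catalog is not None and module_id not in catalog:
            raise FormatError(f"{path}: module {module_id!r} not in catalog")
        mapping[module_id] = strategy
    return mapping


def write_strategy_map(strategy_map: Mapping[str, str], path: str | Path) -> None:
    frame = pd.DataFrame(
        {"module_id": list(strategy_map), "strategy": list(strategy_map.values())}
    )
    _write_frame(frame, Path(path))


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------


def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a Newick tree, validating tip labels and branch lengths."""
    path = Path(path)
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"{path}: cannot parse Newick tree ({exc})") from exc
    return validate_tree(tree)


def validate_tree(tree: dendropy.Tree) -> dendropy.Tree:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        dup = next(l for l in labels if labels.count(l) > 1)
        raise FormatError(f"duplicate tip label: {dup!r}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise FormatError(f"negative branch length: {edge.length}")
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


# ---------------------------------------------------------------------------
# generic results
# ---------------------------------------------------------------------------


def write_results(
    records: pd.DataFrame | Iterable[Mapping],
    path: str | Path,
    format: str = "tsv",
) -> None:
    """Write result records with deterministic column order and fixed precision.

    ``format`` is ``tsv`` or ``json``; both round-trip through
    :func:`read_results` exactly for strings/integers and to within 1e-12
    for reals.
    """
    frame = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    path = Path(path)
    if format == "tsv":
        _write_frame(frame, path)
    elif format == "json":
        rounded = frame.copy()
        for col in rounded.columns:
            if pd.api.types.is_float_dtype(rounded[col]):
                rounded[col] = rounded[col].round(FLOAT_PRECISION)
        payload = rounded.to_dict(orient="records")
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True, allow_nan=True)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {format!r} (expected tsv or json)")


def read_results(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    path = Path(path)
    if format == "tsv":
        return pd.read_csv(path, sep="\t")
    if format == "json":
        with open(path, encoding="utf-8") as fh:
            return pd.DataFrame(json.load(fh))
    raise ValueError(f"unknown format {format!r} (expected tsv or json)")


def _write_frame(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(
        path,
        sep="\t",
        index=False,
        float_format=f"%.{FLOAT_PRECISION}g",
        na_rep="NA",
        lineterminator="\n",
    )
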