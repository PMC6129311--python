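"""Readers and writers for the external file dialects.

Three inputs are supported: an HPA-style long-format RNA expression table
(gene, tissue, FPKM-like value), an HPA-style IHC table (gene, tissue,
optional cell type, four-level detection call, optional reliability), and
a gene set collection in MSigDB GMT format.  Gene identifiers are opaque
strings matched by exact equality after whitespace trimming; an optional
two-column mapping file can translate between identifier spaces (e.g.
symbol to Ensembl).  All tables are UTF-8 tab-separated text.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Ordinal IHC detection scale, weakest to strongest.
IHC_LEVELS = ("Not detected", "Low", "Medium", "High")

_LEVEL_BY_LOWER = {lvl.lower(): lvl for lvl in IHC_LEVELS}


class ParseError(ValueError):
    """Malformed input file (bad line, bad column, bad value)."""


@dataclass
class ExpressionTable:
    """Gene x tissue expression matrix with explicit missingness.

    ``values`` is a float DataFrame (genes as index, tissues as columns);
    NaN marks a (gene, tissue) pair absent from the source file, which is
    distinct from an observed zero.  All observed values must be >= 0.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dupes = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dupes}")
        if v.columns.duplicated().any():
            raise ValueError("duplicate tissue names")
        arr = v.to_numpy(dtype=float)
        if np.nanmin(arr, initial=0.0) < 0:
            raise ValueError("expression values must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean gene x tissue frame, True where no measurement exists."""
        return self.values.isna()


@dataclass
class IHCTable:
    """Immunohistochemistry detection records.

    ``records`` has columns gene, tissue, cell_type, level, reliability;
    cell_type and reliability may be empty strings.  Levels are drawn from
    :data:`IHC_LEVELS` and (gene, tissue, cell_type) triples are unique.
    """

    records: pd.DataFrame

    COLUMNS = ("gene", "tissue", "cell_type", "level", "reliability")

    def __post_init__(self) -> None:
        r = self.records
        missing = set(self.COLUMNS) - set(r.columns)
        if missing:
            raise ValueError(f"IHC records missing columns: {sorted(missing)}")
        bad = set(r["level"]) - set(IHC_LEVELS)
        if bad:
            raise ValueError(
                f"IHC level(s) outside {IHC_LEVELS}: {sorted(bad)}"
            )
        key = r[["gene", "tissue", "cell_type"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].tolist()
            raise ValueError(f"duplicate IHC record for {tuple(dup)}")


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """Ordered collection of named gene sets over a shared universe.

    Equivalent to the g x p 0/1 indicator matrix used by competitive gene
    set tests: g sets (rows) annotated to the p genes of the universe.
    """

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            seen, dup = set(), None
            for n in names:
                if n in seen:
                    dup = n
                    break
                seen.add(n)
            raise ValueError(f"duplicate gene set name: {dup!r}")
        for s in self.sets:
            if len(set(s.genes)) != len(s.genes):
                raise ValueError(f"duplicate genes within set {s.name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    @property
    def universe(self) -> list[str]:
        """Union of all member genes, in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.sets:
            for g in s.genes:
                seen.setdefault(g, None)
        return list(seen)

    def to_indicator(self, universe: list[str] | None = None) -> pd.DataFrame:
        """g x p 0/1 membership matrix (sets as rows, genes as columns)."""
        if universe is None:
            universe = self.universe
        col = {g: j for j, g in enumerate(universe)}
        mat = np.zeros((len(self.sets), len(universe)), dtype=np.int8)
        for i, s in enumerate(self.sets):
            for g in s.genes:
                if g in col:
                    mat[i, col[g]] = 1
        return pd.DataFrame(mat, index=self.names, columns=list(universe))

    def map_genes(self, mapping: dict[str, str]) -> "GeneSetCollection":
        """Translate member identifiers; genes without a mapping are dropped."""
        out = []
        for s in self.sets:
            mapped: dict[str, None] = {}
            for g in s.genes:
                if g in mapping:
                    mapped.setdefault(mapping[g], None)
            out.append(GeneSet(s.name, s.description, tuple(mapped)))
        return GeneSetCollection(out)


def read_gmt(path) -> GeneSetCollection:
    """Read an MSigDB-dialect GMT file: name TAB description TAB gene...

    Duplicate genes within a line are removed with a warning; a line with
    fewer than three fields or a repeated set name raises :class:`ParseError`.
    """
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated "
                    f"fields (name, description, genes...), got {len(fields)}"
                )
            name = fields[0].strip()
            if name in seen:
                raise ParseError(f"{path}: line {lineno}: duplicate set name {name!r}")
            seen.add(name)
            genes: dict[str, None] = {}
            n_raw = 0
            for g in fields[2:]:
                g = g.strip()
                if g:
                    n_raw += 1
                    genes.setdefault(g, None)
            if len(genes) < n_raw:
                logger.warning(
                    "%s: line %d: set %r has %d duplicate gene(s); deduplicated",
                    path, lineno, name, n_raw - len(genes),
                )
            sets.append(GeneSet(name, fields[1], tuple(genes)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


def read_rna_table(
    path,
    gene_column: str = "Gene",
    tissue_column: str = "Sample",
    value_column: str = "Value",
) -> ExpressionTable:
    """Read a long-format HPA-style RNA table and pivot to gene x tissue.

    (gene, tissue) pairs absent from the file become missing cells (NaN),
    not zeros.  Duplicated pairs, negative values and unknown column names
    are errors.  Default column names follow the HPA v16 download but are
    overridable because HPA headers have changed across versions.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (gene_column, tissue_column, value_column):
        if col not in df.columns:
            raise ParseError(
                f"{path}: column {col!r} not found; available: {list(df.columns)}"
            )
    genes = df[gene_column].str.strip()
    tissues = df[tissue_column].str.strip()
    try:
        values = pd.to_numeric(df[value_column])
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: non-numeric expression value: {exc}") from exc
    if (values < 0).any():
        bad = values[values < 0].iloc[0]
        raise ParseError(f"{path}: negative expression value {bad}")
    long = pd.DataFrame({"gene": genes, "tissue": tissues, "value": values})
    if long.duplicated(["gene", "tissue"]).any():
        dup = long[long.duplicated(["gene", "tissue"])].iloc[0]
        raise ParseError(
            f"{path}: duplicated (gene, tissue) pair ({dup['gene']}, {dup['tissue']})"
        )
    wide = long.pivot(index="gene", columns="tissue", values="value")
    wide = wide.sort_index(axis=0).sort_index(axis=1)
    wide.index.name = None
    wide.columns.name = None
    return ExpressionTable(wide.astype(float))


def read_ihc_table(
    path,
    gene_column: str = "Gene",
    tissue_column: str = "Tissue",
    level_column: str = "Level",
    cell_type_column: str | None = "Cell type",
    reliability_column: str | None = "Reliability",
) -> IHCTable:
    """Read an HPA-style IHC table.

    Level strings are matched case-insensitively against the four-category
    scale; anything else is an error.  Cell-type and reliability columns
    are optional (silently treated as empty when the column is absent).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in (gene_column, tissue_column, level_column):
        if col not in df.columns:
            raise ParseError(
                f"{path}: column {col!r} not found; available: {list(df.columns)}"
            )

    def norm_level(s: str) -> str:
        key = s.strip().lower()
        if key not in _LEVEL_BY_LOWER:
            raise ParseError(
                f"{path}: unrecognized IHC level {s!r}; expected one of {IHC_LEVELS}"
            )
        return _LEVEL_BY_LOWER[key]

    records = pd.DataFrame(
        {
            "gene": df[gene_column].str.strip(),
            "tissue": df[tissue_column].str.strip(),
            "cell_type": (
                df[cell_type_column].str.strip()
                if cell_type_column and cell_type_column in df.columns
                else ""
            ),
            "level": df[level_column].map(norm_level) if len(df) else pd.Series([], dtype=str),
            "reliability": (
                df[reliability_column].str.strip()
                if reliability_column and reliability_column in df.columns
                else ""
            ),
        }
    )
    if len(df) == 0:
        records = pd.DataFrame(columns=IHCTable.COLUMNS).astype(str)
    return IHCTable(records)


def read_gene_mapping(path) -> dict[str, str]:
    """Two-column tab-separated identifier mapping (from -> to), no header."""
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 fields")
            src, dst = fields[0].strip(), fields[1].strip()
            if src in mapping and mapping[src] != dst:
                raise ParseError(f"{path}: line {lineno}: conflicting mapping for {src!r}")
            mapping[src] = dst
    return mapping


def write_weight_table(matrix: pd.DataFrame, path) -> None:
    """Write a weight matrix (rows = genes or sets, columns = tissues).

    Full float precision (repr round-trip) so that write-then-read is
    lossless; first column header is "name".
    """
    out = matrix.copy()
    out.index.name = "name"
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_weight_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="name", float_precision="round_trip")
    df.index.name = None
    df.columns.name = None
    return df.astype(float)


def read_pvalue_table(path, name_column: str = "set", p_column: str = "p_value") -> pd.Series:
    """Read a per-set p-value table (tab-separated; extra columns ignored)."""
    df = pd.read_csv(path, sep="\t")
    for col in (name_column, p_column):
        if col not in df.columns:
            raise ParseError(
                f"{path}: column {col!r} not found; available: {list(df.columns)}"
            )
    names = df[name_column].astype(str).str.strip()
    if names.duplicated().any():
        raise ParseError(f"{path}: duplicated set name in p-value table")
    p = pd.Series(pd.to_numeric(df[p_column]).to_numpy(), index=names.to_numpy())
    return p
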