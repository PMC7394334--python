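"""Reading and writing of expression tables, gene-set libraries and result files.

The screening data arrive as a long-format table (one row per
cell line / compound / dose / gene measurement).  For each cell line a complete
three-mode tensor ``x[dose, compound, gene]`` is assembled: replicate
measurements at the same (compound, dose, gene) are averaged, and any compound
that was not assayed at every dose level is dropped outright, because the
tensor decomposition admits no missing entries.

Gene-set libraries use the GMT dialect (one set per line:
name, description, members...).  Probe-to-symbol maps and known drug-target
references are plain two-column TSV files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyTensorError, FormatError, ParseError

logger = logging.getLogger(__name__)

LONG_TABLE_COLUMNS = ("cell_line", "compound", "dose", "gene", "expression")


@dataclass(frozen=True)
class ExpressionRecord:
    """A single expression measurement from the screen."""

    cell_line: str
    compound: str
    dose: float
    gene: str
    expression: float
    replicate: str | None = None

    def __post_init__(self) -> None:
        if not (self.dose > 0):
            raise ValueError(f"dose must be positive, got {self.dose}")
        if not np.isfinite(self.expression):
            raise ValueError("expression must be finite")


@dataclass
class ExpressionTensor:
    """Complete dose x compound x gene expression array with axis labels."""

    values: np.ndarray
    dose_levels: np.ndarray
    compound_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.dose_levels = np.asarray(self.dose_levels, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.values.ndim != 3:
            raise ValueError("tensor must have exactly three modes")
        d, j, l = self.values.shape
        if (len(self.dose_levels), len(self.compound_ids), len(self.gene_ids)) != (d, j, l):
            raise ValueError("axis label lengths do not match tensor shape")
        if not np.all(np.diff(self.dose_levels) > 0):
            raise ValueError("dose_levels must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("tensor contains non-finite entries")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class GeneSetLibrary:
    """Named gene sets, e.g. single-gene-perturbation signatures or hub-protein sets.

    Members are stored uppercased and deduplicated.  ``universe`` optionally
    pins an explicit background gene list; otherwise callers derive one.
    """

    name: str
    sets: dict[str, list[str]]
    universe: list[str] | None = None

    def __post_init__(self) -> None:
        cleaned: dict[str, list[str]] = {}
        for set_name, members in self.sets.items():
            uniq = list(dict.fromkeys(m.upper() for m in members if m))
            if not uniq:
                raise ValueError(f"gene set {set_name!r} has no members")
            cleaned[set_name] = uniq
        self.sets = cleaned
        if self.universe is not None:
            self.universe = list(dict.fromkeys(g.upper() for g in self.universe))

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out.update(members)
        return out

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class DrugTargetReference:
    """Known compound -> target-gene lists (e.g. from a curated drug-target database)."""

    targets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned = {}
        for compound, genes in self.targets.items():
            uniq = list(dict.fromkeys(g.upper() for g in genes if g))
            if uniq:
                cleaned[compound] = uniq
        self.targets = cleaned

    def get(self, compound: str) -> list[str] | None:
        return self.targets.get(compound)


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Read a two-column probe-ID -> gene-symbol TSV (no header required)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: probe map needs two tab-separated columns")
    return dict(zip(df.iloc[:, 0].str.strip(), df.iloc[:, 1].str.strip()))


def read_drug_targets(path: str | Path) -> DrugTargetReference:
    """Read a two-column compound -> target TSV; one target per row."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: drug-target reference needs two columns")
    targets: dict[str, list[str]] = {}
    for compound, gene in zip(df.iloc[:, 0], df.iloc[:, 1]):
        targets.setdefault(str(compound).strip(), []).append(str(gene).strip())
    return DrugTargetReference(targets)


def read_long_table(
    path: str | Path,
    mapping: Mapping[str, str] | str | Path | None = None,
    column_map: Mapping[str, str] | None = None,
) -> list[ExpressionRecord]:
    """Read a long-format expression TSV into records.

    Parameters
    ----------
    path
        Tab-separated file with header columns ``cell_line, compound, dose,
        gene, expression`` and optionally ``replicate``.  ``column_map``
        renames non-standard headers, e.g. ``{"conc": "dose"}``.
    mapping
        Optional probe-ID -> gene-symbol map (dict or two-column TSV path).
        Rows whose gene is absent from the map are dropped; the count is logged.
    """
    if isinstance(mapping, (str, Path)):
        mapping = read_probe_map(mapping)

    df = pd.read_csv(path, sep="\t", dtype=str)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in LONG_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    for col in ("dose", "expression"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            # +2: header line plus 1-based numbering
            line = int(bad.idxmax()) + 2
            raise ParseError(f"{path}: non-numeric {col!r} on line {line}")
        df[col] = parsed

    n_before = len(df)
    if mapping is not None:
        df = df[df["gene"].isin(mapping)].copy()
        dropped = n_before - len(df)
        if dropped:
            logger.info("dropped %d records with unmapped probe IDs", dropped)
        df["gene"] = df["gene"].map(dict(mapping))

    has_rep = "replicate" in df.columns
    records = [
        ExpressionRecord(
            cell_line=str(row.cell_line),
            compound=str(row.compound),
            dose=float(row.dose),
            gene=str(row.gene),
            expression=float(row.expression),
            replicate=str(row.replicate) if has_rep and pd.notna(row.replicate) else None,
        )
        for row in df.itertuples(index=False)
    ]
    return records


def build_tensor(records: Iterable[ExpressionRecord], cell_line: str) -> ExpressionTensor:
    """Assemble the complete dose x compound x gene tensor for one cell line.

    Replicates at the same (compound, dose, gene) are arithmetic-mean averaged.
    Compounds missing any (dose, gene) cell after averaging are dropped and
    logged, since the decomposition requires a complete array.
    """
    rows = [r for r in records if r.cell_line == cell_line]
    if not rows:
        raise EmptyTensorError(f"no records for cell line {cell_line!r}")

    df = pd.DataFrame(
        {
            "compound": [r.compound for r in rows],
            "dose": [r.dose for r in rows],
            "gene": [r.gene for r in rows],
            "expression": [r.expression for r in rows],
        }
    )
    averaged = (
        df.groupby(["compound", "dose", "gene"], sort=True)["expression"].mean().reset_index()
    )
    dose_levels = np.array(sorted(averaged["dose"].unique()))
    gene_ids = sorted(averaged["gene"].unique())

    wide = averaged.pivot_table(
        index="compound", columns=["dose", "gene"], values="expression", aggfunc="first"
    )
    full_cols = pd.MultiIndex.from_product([dose_levels, gene_ids], names=["dose", "gene"])
    wide = wide.reindex(columns=full_cols)
    complete = wide.dropna(axis=0)
    n_dropped = len(wide) - len(complete)
    if n_dropped:
        logger.info(
            "cell line %s: dropped %d incomplete compound(s)", cell_line, n_dropped
        )
    if complete.empty:
        raise EmptyTensorError(
            f"cell line {cell_line!r}: no compound measured at every dose level"
        )

    compound_ids = list(complete.index)
    values = (
        complete.to_numpy()
        .reshape(len(compound_ids), len(dose_levels), len(gene_ids))
        .transpose(1, 0, 2)
    )
    return ExpressionTensor(values, dose_levels, compound_ids, gene_ids)


def read_gmt(path: str | Path, name: str | None = None) -> GeneSetLibrary:
    """Read a GMT gene-set library (set name, description, members...)."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno} has fewer than 3 fields")
            sets[fields[0]] = [g for g in fields[2:] if g.strip()]
    if not sets:
        raise FormatError(f"{path}: empty gene-set library")
    return GeneSetLibrary(name=name or Path(path).stem, sets=sets)


def write_gmt(library: GeneSetLibrary, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for set_name, members in library.sets.items():
            fh.write("\t".join([set_name, "na", *members]) + "\n")
    return path


def write_long_table(
    tensor: ExpressionTensor, cell_line: str, path: str | Path
) -> Path:
    """Serialize a tensor back to the long-format TSV dialect read_long_table accepts."""
    d, j, l = tensor.shape
    di, ji, li = np.meshgrid(np.arange(d), np.arange(j), np.arange(l), indexing="ij")
    df = pd.DataFrame(
        {
            "cell_line": cell_line,
            "compound": np.asarray(tensor.compound_ids, dtype=object)[ji.ravel()],
            "dose": tensor.dose_levels[di.ravel()],
            "gene": np.asarray(tensor.gene_ids, dtype=object)[li.ravel()],
            "expression": tensor.values.ravel(),
        }
    )
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    summary: Mapping | None = None,
) -> dict[str, Path]:
    """Write named result tables as TSV plus a JSON run summary.

    Floats are written with Python's shortest round-trip repr, so re-reading
    preserves values exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, table in tables.items():
        p = out_dir / f"{name}.tsv"
        table.to_csv(p, sep="\t", index=False)
        paths[name] = p
    summary_path = out_dir / "run_summary.json"
    with open(summary_path, "w", encoding="utf-8") as fh:
        json.dump(dict(summary or {}), fh, indent=2, default=str)
    paths["run_summary"] = summary_path
    return paths
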