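"""Reading Iris colony-quantification files into a screen dataset.

Iris (the colony image-analysis tool) writes one tab-separated file per
photographed plate: a block of ``#``-prefixed comment lines, then a header
row, then one data row per colony position with 1-based ``row``/``column``
indices and one column per measured phenotype (``size``, ``colony integral
opacity``, ...).  This module parses those files, joins them with a plate
layout that names the strain pinned at every position, and assembles the
strain-position x (condition, replicate) measurement table the rest of the
pipeline consumes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Reserved strain label for wildtype positions in a plate layout.
WT_LABEL = "WT"
#: Reserved strain label for positions that carry no strain.
EMPTY_LABEL = "EMPTY"

#: Default filename convention: ``<condition>-<library_plate>_<replicate>.iris``
#: e.g. ``RIF2-6_C.iris`` -> condition "RIF2", library plate 6, replicate "C".
DEFAULT_FILENAME_PATTERN = (
    r"^(?P<condition>.+)-(?P<plate>\d+)_(?P<replicate>[^_.]+)\.iris$"
)

DEFAULT_MEASUREMENT = "size"

#: Provenance flags for dataset cells.
FLAG_RAW = "raw"
FLAG_ZERO_REMOVED = "zero-removed"
FLAG_QC_REMOVED = "qc-removed"


class IrisFormatError(ValueError):
    """Raised when an Iris file violates the expected tabular structure."""


class FilenameConventionError(ValueError):
    """Raised when a filename does not match the configured naming pattern."""


@dataclass
class PlateQuant:
    """One physical plate's colony measurements plus identity metadata.

    ``values`` is an ``(n_rows, n_cols)`` float array with NaN for missing
    positions; all finite entries must be non-negative.
    """

    condition: str
    library_plate: int
    replicate: str
    values: np.ndarray
    measurement: str = DEFAULT_MEASUREMENT
    batch: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("plate values must be a 2-D grid")
        if self.library_plate < 1:
            raise ValueError("library_plate must be a positive integer")
        finite = self.values[np.isfinite(self.values)]
        if (finite < 0).any():
            raise ValueError("colony measurements must be >= 0")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def key(self) -> tuple[str, int, str]:
        """(condition, library_plate, replicate) identity within a dataset."""
        return (self.condition, self.library_plate, self.replicate)

    def copy(self) -> "PlateQuant":
        return PlateQuant(
            condition=self.condition,
            library_plate=self.library_plate,
            replicate=self.replicate,
            values=self.values.copy(),
            measurement=self.measurement,
            batch=self.batch,
        )


@dataclass
class PlateLayout:
    """Mapping (library_plate, row, column) -> strain identifier.

    ``WT`` is reserved for wildtype positions and ``EMPTY`` marks positions
    carrying no strain (excluded from datasets).
    """

    table: pd.DataFrame  # columns: plate, row, column, gene

    def __post_init__(self) -> None:
        required = {"plate", "row", "column", "gene"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"layout missing columns: {sorted(missing)}")
        dup = self.table.duplicated(subset=["plate", "row", "column"])
        if dup.any():
            bad = self.table.loc[dup, ["plate", "row", "column"]]
            raise ValueError(f"duplicate layout positions:\n{bad}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PlateLayout":
        table = pd.read_csv(path, sep="\t")
        return cls(table=table)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def occupied(self) -> pd.DataFrame:
        """Layout rows whose position carries a strain (gene != EMPTY)."""
        return self.table[self.table["gene"] != EMPTY_LABEL]

    def gene_at(self, plate: int, row: int, column: int) -> str | None:
        hit = self.table[
            (self.table["plate"] == plate)
            & (self.table["row"] == row)
            & (self.table["column"] == column)
        ]
        if hit.empty:
            return None
        return str(hit["gene"].iloc[0])


ROW_INDEX_NAMES = ["plate", "row", "column", "gene"]
COL_INDEX_NAMES = ["condition", "replicate"]


@dataclass
class ScreenDataset:
    """Strain-position x (condition, replicate) colony-measurement table.

    Rows are indexed by ``(plate, row, column, gene)``, columns by
    ``(condition, replicate)``; cells are floats with NaN for missing.
    ``provenance`` mirrors ``values`` and records why a cell was altered
    (``raw``, ``zero-removed`` or ``qc-removed``).
    """

    values: pd.DataFrame
    n_rows: int
    n_cols: int
    provenance: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    measurement: str = DEFAULT_MEASUREMENT

    def __post_init__(self) -> None:
        if self.provenance is None:
            self.provenance = pd.DataFrame(
                FLAG_RAW, index=self.values.index, columns=self.values.columns
            )
        if not self.values.index.is_unique:
            raise ValueError("dataset row index is not unique")
        if not self.values.columns.is_unique:
            raise ValueError("dataset column index is not unique")
        arr = self.values.to_numpy(dtype=float)
        if (arr[np.isfinite(arr)] < 0).any():
            raise ValueError("dataset holds negative measurements")

    @property
    def conditions(self) -> list[str]:
        return list(self.values.columns.get_level_values("condition").unique())

    def replicates(self, condition: str) -> list[str]:
        cols = self.values.columns
        return list(cols[cols.get_level_values("condition") == condition]
                    .get_level_values("replicate"))

    @property
    def library_plates(self) -> list[int]:
        return list(self.values.index.get_level_values("plate").unique())

    def condition_block(self, condition: str) -> pd.DataFrame:
        """All replicate columns of one condition (positions x replicates)."""
        return self.values.xs(condition, axis=1, level="condition")

    def copy(self) -> "ScreenDataset":
        return ScreenDataset(
            values=self.values.copy(),
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            provenance=self.provenance.copy(),
            measurement=self.measurement,
        )

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.columns = [f"{c}::{r}" for c, r in out.columns]
        out.reset_index().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, n_rows: int, n_cols: int,
                 measurement: str = DEFAULT_MEASUREMENT) -> "ScreenDataset":
        table = pd.read_csv(path, sep="\t")
        table = table.set_index(ROW_INDEX_NAMES)
        table.columns = pd.MultiIndex.from_tuples(
            [tuple(c.split("::", 1)) for c in table.columns],
            names=COL_INDEX_NAMES,
        )
        return cls(values=table, n_rows=n_rows, n_cols=n_cols,
                   measurement=measurement)


def parse_plate_filename(
    name: str, pattern: str = DEFAULT_FILENAME_PATTERN
) -> tuple[str, int, str]:
    """Extract (condition, library_plate, replicate) from an Iris filename."""
    m = re.match(pattern, name)
    if m is None:
        raise FilenameConventionError(
            f"filename {name!r} does not match pattern {pattern!r}"
        )
    groups = m.groupdict()
    return groups["condition"], int(groups["plate"]), groups["replicate"]


def parse_iris_file(
    path: str | Path,
    measurement: str = DEFAULT_MEASUREMENT,
    pattern: str = DEFAULT_FILENAME_PATTERN,
) -> PlateQuant:
    """Parse one Iris quantification file into a :class:`PlateQuant`.

    Grid dimensions are inferred from the maximum row/column index in the
    file; positions absent from the file become missing (NaN).  Non-numeric
    measurement cells parse as missing with a logged warning so that a
    single corrupt cell does not abort a large run.
    """
    path = Path(path)
    condition, plate, replicate = parse_plate_filename(path.name, pattern)
    table = pd.read_csv(path, sep="\t", comment="#")
    for col in ("row", "column"):
        if col not in table.columns:
            raise IrisFormatError(f"{path.name}: missing required column {col!r}")
    if measurement not in table.columns:
        raise IrisFormatError(
            f"{path.name}: measurement column {measurement!r} not found; "
            f"available: {list(table.columns)}"
        )
    if table.duplicated(subset=["row", "column"]).any():
        raise IrisFormatError(f"{path.name}: duplicate (row, column) entries")

    rows = table["row"].astype(int).to_numpy()
    cols = table["column"].astype(int).to_numpy()
    if (rows < 1).any() or (cols < 1).any():
        raise IrisFormatError(f"{path.name}: row/column indices must be >= 1")
    vals = pd.to_numeric(table[measurement], errors="coerce").to_numpy(dtype=float)
    n_bad = int(np.isnan(vals).sum() - table[measurement].isna().sum())
    if n_bad > 0:
        logger.warning("%s: %d non-numeric %r cells parsed as missing",
                       path.name, n_bad, measurement)

    grid = np.full((rows.max(), cols.max()), np.nan)
    grid[rows - 1, cols - 1] = vals
    return PlateQuant(condition=condition, library_plate=plate,
                      replicate=replicate, values=grid, measurement=measurement)


def read_iris_directory(
    directory: str | Path,
    measurement: str = DEFAULT_MEASUREMENT,
    pattern: str = DEFAULT_FILENAME_PATTERN,
) -> list[PlateQuant]:
    """Parse every ``*.iris`` file in a directory (sorted for determinism)."""
    paths = sorted(Path(directory).glob("*.iris"))
    if not paths:
        raise FileNotFoundError(f"no .iris files in {directory}")
    return [parse_iris_file(p, measurement=measurement, pattern=pattern)
            for p in paths]


def build_dataset(
    plates: Iterable[PlateQuant], layout: PlateLayout
) -> ScreenDataset:
    """Assemble parsed plates into one screen dataset.

    One row per occupied layout position, one ``(condition, replicate)``
    column per distinct plate identity; cells are missing where the
    corresponding plate was not provided or did not report that position.
    """
    plates = list(plates)
    if not plates:
        raise ValueError("no plates supplied")
    shapes = {(p.n_rows, p.n_cols) for p in plates}
    if len(shapes) > 1:
        raise ValueError(f"plates disagree on grid dimensions: {sorted(shapes)}")
    n_rows, n_cols = shapes.pop()

    seen: dict[tuple[str, int, str], PlateQuant] = {}
    collisions = []
    for p in plates:
        if p.key in seen:
            collisions.append(p.key)
        seen[p.key] = p
    if collisions:
        raise ValueError(
            "conflicting duplicate plates for "
            f"(condition, plate, replicate): {sorted(set(collisions))}"
        )

    occ = layout.occupied().sort_values(["plate", "row", "column"])
    out_of_bounds = occ[(occ["row"] > n_rows) | (occ["column"] > n_cols)
                        | (occ["row"] < 1) | (occ["column"] < 1)]
    if not out_of_bounds.empty:
        raise ValueError(
            f"layout positions outside the {n_rows}x{n_cols} grid:\n{out_of_bounds}"
        )
    row_index = pd.MultiIndex.from_frame(
        occ[["plate", "row", "column", "gene"]], names=ROW_INDEX_NAMES
    )

    col_keys = sorted({(p.condition, p.replicate) for p in plates})
    col_index = pd.MultiIndex.from_tuples(col_keys, names=COL_INDEX_NAMES)

    data = np.full((len(row_index), len(col_index)), np.nan)
    plate_pos = {key: i for i, key in enumerate(col_keys)}
    lib = occ["plate"].to_numpy()
    r = occ["row"].to_numpy(dtype=int) - 1
    c = occ["column"].to_numpy(dtype=int) - 1
    for p in plates:
        j = plate_pos[(p.condition, p.replicate)]
        mask = lib == p.library_plate
        data[mask, j] = p.values[r[mask], c[mask]]

    values = pd.DataFrame(data, index=row_index, columns=col_index)
    return ScreenDataset(values=values, n_rows=n_rows, n_cols=n_cols,
                         measurement=plates[0].measurement)


def remove_stray_zeros(ds: ScreenDataset) -> ScreenDataset:
    """Convert likely mis-pinned colonies (stray zeros) to missing values.

    Within each (strain position, condition) replicate set: if every
    non-missing value is zero the zeros are kept — they record a genuine
    no-growth phenotype.  Otherwise each zero becomes missing, flagged
    ``zero-removed``, since a zero alongside grown replicates most likely
    reflects a pinning or detection failure rather than biology.
    """
    out = ds.copy()
    vals = out.values
    for condition in out.conditions:
        block = vals.xs(condition, axis=1, level="condition",
                        drop_level=False)
        arr = block.to_numpy(dtype=float)
        nonmissing = np.isfinite(arr)
        zero = nonmissing & (arr == 0)
        any_nonzero = (nonmissing & (arr != 0)).any(axis=1)
        strip = zero & any_nonzero[:, None]
        if strip.any():
            arr[strip] = np.nan
            vals.loc[:, block.columns] = arr
            prov = out.provenance.loc[:, block.columns].to_numpy(dtype=object)
            prov[strip] = FLAG_ZERO_REMOVED
            out.provenance.loc[:, block.columns] = prov
    return out


def layout_from_mapping(
    mapping: Mapping[tuple[int, int, int], str]
) -> PlateLayout:
    """Build a layout from ``{(plate, row, column): gene}``."""
    records = [
        {"plate": p, "row": r, "column": c, "gene": g}
        for (p, r, c), g in sorted(mapping.items())
    ]
    return PlateLayout(table=pd.DataFrame.from_records(records))
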