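"""Stem-census data model and I/O.

A census is a fully mapped inventory of woody stems inside a rectangular
plot: every stem carries a unique tag, the identifier of the individual
plant it belongs to (multi-stemmed shrubs and coppiced trees share one
individual id), a species code, plot-level metric coordinates, a diameter
at breast height (dbh, cm at 1.3 m), and a live/dead status.  The module
also reads and writes the two plain-text formats the pipeline consumes:
CSV stem tables and ESRI ASCII grid rasters for gridded covariates.

Conventions
-----------
* Coordinates are metres from the plot's southwest corner (origin).
* Live stems enter the census at dbh >= 1 cm; standing dead stems at
  dbh >= 5 cm.
* Quadrat and raster cells are half-open ``[a, a + s) x [b, b + s)``;
  the plot's maximal edges fold into the last cell so that cells
  partition the plot with no double counting.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import RasterFormatError, RowParseError, SchemaError, StandppError

__all__ = [
    "PlotWindow",
    "StemRecord",
    "Census",
    "QuadratGrid",
    "CovariateRaster",
    "ValidationReport",
    "read_stem_table",
    "write_stem_table",
    "validate_census",
    "read_ascii_raster",
    "write_ascii_raster",
    "assign_quadrats",
]

#: canonical stem-table columns, in storage order
STEM_COLUMNS = ("stem_tag", "individual_id", "species_code", "x", "y", "dbh", "status")

LIVE_MIN_DBH = 1.0  # cm, census inclusion threshold for live stems
DEAD_MIN_DBH = 5.0  # cm, threshold for standing dead stems
STATUS_VALUES = ("live", "dead")


@dataclass(frozen=True)
class PlotWindow:
    """Rectangular observation window in metres.

    The reference plot is 500 x 700 m = 35 ha; any positive rectangle is
    accepted.
    """

    width: float
    height: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if not (self.width > 0 and self.height > 0):
            raise ValueError("window sides must be positive")

    @property
    def area(self) -> float:
        """Window area in m^2."""
        return self.width * self.height

    @property
    def area_ha(self) -> float:
        """Window area in hectares."""
        return self.area / 10_000.0

    @property
    def xmax(self) -> float:
        return self.origin[0] + self.width

    @property
    def ymax(self) -> float:
        return self.origin[1] + self.height

    def contains(self, x, y) -> np.ndarray:
        """Vectorised inclusion test (boundary inclusive)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, y0 = self.origin
        return (x >= x0) & (x <= self.xmax) & (y >= y0) & (y <= self.ymax)


#: the 35-ha reference plot geometry
HF_WINDOW = PlotWindow(500.0, 700.0)


@dataclass(frozen=True)
class StemRecord:
    """One tagged stem."""

    stem_tag: str
    individual_id: str
    species_code: str
    x: float
    y: float
    dbh: float
    status: str


@dataclass
class Census:
    """A stem census: a table of stems plus plot geometry and a species list.

    ``table`` holds one row per stem with the canonical columns
    ``stem_tag, individual_id, species_code, x, y, dbh, status``.
    """

    window: PlotWindow
    table: pd.DataFrame
    species_table: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in STEM_COLUMNS if c not in self.table.columns]
        if missing:
            raise SchemaError(f"census table missing columns: {missing}")
        self.table = self.table.loc[:, list(STEM_COLUMNS)].reset_index(drop=True)

    @property
    def n_stems(self) -> int:
        return len(self.table)

    @property
    def n_individuals(self) -> int:
        return self.table["individual_id"].nunique()

    @property
    def species_codes(self) -> list[str]:
        return sorted(self.table["species_code"].unique())

    def stems(self) -> Iterator[StemRecord]:
        for row in self.table.itertuples(index=False):
            yield StemRecord(*row)

    def subset(self, species: str | Sequence[str] | None = None,
               status: str | None = None) -> "Census":
        """Return a census restricted to given species and/or status."""
        t = self.table
        if species is not None:
            if isinstance(species, str):
                species = [species]
            t = t[t["species_code"].isin(species)]
        if status is not None:
            t = t[t["status"] == status]
        return Census(self.window, t.copy(), dict(self.species_table))


@dataclass(frozen=True)
class QuadratGrid:
    """Regular census grid; the field standard is 20 x 20-m quadrats."""

    cell_size: float = 20.0
    n_cols: int = 25
    n_rows: int = 35

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one cell")

    @classmethod
    def for_window(cls, window: PlotWindow, cell_size: float = 20.0) -> "QuadratGrid":
        n_cols = int(np.ceil(window.width / cell_size - 1e-9))
        n_rows = int(np.ceil(window.height / cell_size - 1e-9))
        return cls(cell_size, n_cols, n_rows)


def _grid_index(coord, origin: float, cell: float, n_cells: int) -> np.ndarray:
    """Half-open cell index with the maximal edge folded into the last cell."""
    idx = np.floor((np.asarray(coord, dtype=float) - origin) / cell).astype(int)
    return np.minimum(idx, n_cells - 1)


def assign_quadrats(census: Census, grid: QuadratGrid | None = None) -> np.ndarray:
    """Assign each stem to a quadrat.

    Returns an integer array of shape (n, 2) holding (column, row) indices.
    Cells are half-open ``[a, a+s)``; points exactly on the plot's outer
    maximal edge fold into the last cell, so cells partition the plot.

    Raises :class:`StandppError` listing offending tags if any stem lies
    outside the window.
    """
    if grid is None:
        grid = QuadratGrid.for_window(census.window)
    w = census.window
    x = census.table["x"].to_numpy(float)
    y = census.table["y"].to_numpy(float)
    inside = w.contains(x, y)
    if not inside.all():
        bad = census.table.loc[~inside, "stem_tag"].tolist()
        raise StandppError(f"stems outside window: {bad}")
    ix = _grid_index(x, w.origin[0], grid.cell_size, grid.n_cols)
    iy = _grid_index(y, w.origin[1], grid.cell_size, grid.n_rows)
    return np.column_stack([ix, iy])


# ---------------------------------------------------------------------------
# stem-table I/O


def read_stem_table(path, column_map: Mapping[str, str] | None = None,
                    window: PlotWindow = HF_WINDOW,
                    species_table: Mapping[str, str] | None = None) -> Census:
    """Read a stem-census CSV into a :class:`Census`.

    ``column_map`` maps canonical names (``stem_tag`` ...) to the file's
    column headers; canonical headers are assumed where omitted.  Numeric
    columns are parsed with a locale-independent decimal point.

    Raises
    ------
    SchemaError
        if a required column cannot be resolved.
    RowParseError
        naming the 1-based file line of the first unparseable numeric.
    """
    column_map = dict(column_map or {})
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    rename = {}
    for canon in STEM_COLUMNS:
        src = column_map.get(canon, canon)
        if src not in raw.columns:
            raise SchemaError(f"required column {canon!r} (file column {src!r}) not found")
        rename[src] = canon
    tab = raw.rename(columns=rename).loc[:, list(STEM_COLUMNS)]
    for col in ("x", "y", "dbh"):
        parsed = pd.to_numeric(tab[col], errors="coerce")
        bad = parsed.isna() & tab[col].notna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            # +2: 1-based numbering plus the header line
            raise RowParseError(f"cannot parse {col}={tab[col].iloc[i]!r}", line=i + 2)
        if parsed.isna().any():
            i = int(np.flatnonzero(parsed.isna().to_numpy())[0])
            raise RowParseError(f"missing value in column {col}", line=i + 2)
        tab[col] = parsed.astype(float)
    for col in ("stem_tag", "individual_id", "species_code", "status"):
        tab[col] = tab[col].astype(str).str.strip()
    return Census(window, tab, dict(species_table or {}))


def write_stem_table(census: Census, path) -> None:
    """Write a census back to canonical CSV (inverse of :func:`read_stem_table`)."""
    census.table.to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# validation


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_census`: one entry per violated rule."""

    issues: list[tuple[str, list[str]]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def rules(self) -> list[str]:
        return [rule for rule, _ in self.issues]

    def __str__(self) -> str:
        if self.ok:
            return "census valid"
        lines = [f"{rule}: {len(tags)} stem(s), e.g. {tags[:5]}" for rule, tags in self.issues]
        return "\n".join(lines)


def validate_census(census: Census) -> ValidationReport:
    """Check every census invariant; violations are reported, never raised.

    Rules: unique tags; coordinates inside the window; dbh > 0; live stems
    >= 1 cm; dead stems >= 5 cm; status in {live, dead}; each individual is
    a single species; species codes resolve in the species table when one
    is present.
    """
    t = census.table
    report = ValidationReport()

    def flag(rule: str, mask) -> None:
        mask = np.asarray(mask)
        if mask.any():
            report.issues.append((rule, t.loc[mask, "stem_tag"].tolist()))

    dup = t["stem_tag"].duplicated(keep=False)
    flag("duplicate_stem_tag", dup.to_numpy())
    x, y = t["x"].to_numpy(float), t["y"].to_numpy(float)
    flag("outside_window", ~census.window.contains(x, y))
    dbh = t["dbh"].to_numpy(float)
    flag("nonpositive_dbh", ~(dbh > 0))
    live = t["status"] == "live"
    dead = t["status"] == "dead"
    flag("live_below_1cm", (live & (dbh < LIVE_MIN_DBH)).to_numpy())
    flag("dead_below_5cm", (dead & (dbh < DEAD_MIN_DBH)).to_numpy())
    flag("unknown_status", (~(live | dead)).to_numpy())
    nspp = t.groupby("individual_id")["species_code"].nunique()
    mixed = set(nspp.index[nspp > 1])
    flag("individual_mixed_species", t["individual_id"].isin(mixed).to_numpy())
    if census.species_table:
        flag("unknown_species_code",
             (~t["species_code"].isin(census.species_table)).to_numpy())
    return report


# ---------------------------------------------------------------------------
# covariate rasters (ESRI ASCII grid)


@dataclass
class CovariateRaster:
    """Gridded covariate over the plot.

    ``values[row, col]`` with row 0 the *southern* edge (row index grows
    with y, matching quadrat indices); the on-disk ESRI ASCII format lists
    the northern row first and is flipped on read/write.  ``kind`` is
    ``"continuous"`` or ``"categorical"``; categorical cell values are
    indices into ``classes``.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    kind: str = "continuous"
    nodata: float = -9999.0
    classes: list[str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown raster kind {self.kind!r}")
        if self.kind == "categorical" and self.classes is not None:
            valid = set(range(len(self.classes)))
            data = self.values[~self.nodata_mask]
            if not set(np.unique(data)).issubset(valid):
                raise ValueError("categorical values outside declared class list")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def nodata_mask(self) -> np.ndarray:
        return (self.values == self.nodata) | np.isnan(self.values)

    def cell_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """(col, row) of the containing cell; half-open with closed top edge."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        x0, y0 = self.origin
        xmax = x0 + self.n_cols * self.cell_size
        ymax = y0 + self.n_rows * self.cell_size
        outside = (x < x0) | (x > xmax) | (y < y0) | (y > ymax)
        if np.any(outside):
            raise StandppError("point(s) outside raster extent")
        col = _grid_index(x, x0, self.cell_size, self.n_cols)
        row = _grid_index(y, y0, self.cell_size, self.n_rows)
        return col, row

    def values_at(self, x, y) -> np.ndarray:
        """Nearest-cell sampling (no interpolation); nodata cells yield NaN."""
        col, row = self.cell_of(x, y)
        out = self.values[row, col].astype(float)
        nod = self.nodata_mask[row, col]
        out = np.where(nod, np.nan, out)
        return out

    def class_at(self, x, y) -> np.ndarray:
        """Class labels at points, for categorical rasters."""
        if self.kind != "categorical" or self.classes is None:
            raise StandppError("class_at requires a categorical raster with classes")
        vals = self.values_at(x, y)
        labels = np.array(self.classes, dtype=object)
        out = np.full(np.shape(vals), None, dtype=object)
        ok = ~np.isnan(vals)
        out[ok] = labels[vals[ok].astype(int)]
        return out


def read_ascii_raster(path, kind: str = "continuous",
                      classes: list[str] | None = None) -> CovariateRaster:
    """Read an ESRI ASCII grid (ncols/nrows/xllcorner/yllcorner/cellsize/NODATA)."""
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header: dict[str, float] = {}
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"):
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError as e:
                raise RasterFormatError(f"bad header value in {lines[i]!r}") from e
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise RasterFormatError(f"missing header field {key!r}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    nodata = header.get("nodata_value", -9999.0)
    body = lines[i:]
    if len(body) != nrows:
        raise RasterFormatError(f"expected {nrows} data rows, found {len(body)}")
    rows = []
    for ln in body:
        vals = ln.split()
        if len(vals) != ncols:
            raise RasterFormatError(
                f"row has {len(vals)} values, header declares ncols={ncols}")
        try:
            rows.append([float(v) for v in vals])
        except ValueError as e:
            raise RasterFormatError(f"unparseable raster value in row {ln!r}") from e
    values = np.asarray(rows, dtype=float)[::-1]  # file lists north row first
    return CovariateRaster(values, header["cellsize"],
                           (header["xllcorner"], header["yllcorner"]),
                           kind=kind, nodata=nodata, classes=classes)


def write_ascii_raster(raster: CovariateRaster, path) -> None:
    """Write an ESRI ASCII grid; inverse of :func:`read_ascii_raster`."""
    buf = io.StringIO()
    buf.write(f"ncols {raster.n_cols}\n")
    buf.write(f"nrows {raster.n_rows}\n")
    buf.write(f"xllcorner {raster.origin[0]:.10g}\n")
    buf.write(f"yllcorner {raster.origin[1]:.10g}\n")
    buf.write(f"cellsize {raster.cell_size:.10g}\n")
    buf.write(f"NODATA_value {raster.nodata:.10g}\n")
    vals = np.where(np.isnan(raster.values), raster.nodata, raster.values)
    for row in vals[::-1]:  # north row first on disk
        buf.write(" ".join(f"{v:.10g}" for v in row) + "\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")
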