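"""Raster grids, environmental stacks, occurrence tables, and project layout.

Grids are plain 2-D arrays with a nodata mask and a 6-number affine
geotransform ``(x_origin, x_cellsize, 0, y_origin, 0, -y_cellsize)`` in the
GDAL convention (origin = upper-left corner, north-up).  Two on-disk formats
are supported: ESRI ASCII grid (``.asc``) and single-band float GeoTIFF
(read/written through :mod:`tifffile` with the minimal GeoTIFF tag set).

Coordinates are treated as points assigned to the containing cell with
half-open cell semantics: ``col = floor((x - x_origin) / cellsize)``, so a
point exactly on a shared edge belongs to the cell to the east/south.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Grid",
    "EnvStack",
    "OccurrenceSet",
    "ProjectLayout",
    "GridFormatError",
    "read_grid",
    "write_grid",
    "read_occurrences",
    "write_occurrences",
    "read_env_dir",
    "extract_values",
]

OCC_ROLES = ("joint", "train", "test", "independent")

# GeoTIFF / GDAL tag codes used for round-tripping georeferencing.
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class GridFormatError(ValueError):
    """Raised for malformed raster headers or inconsistent grids."""


@dataclass
class Grid:
    """Single-band raster: values, nodata mask, and geotransform.

    Parameters
    ----------
    values : 2-D float array (masked cells may hold anything)
    nodata_mask : 2-D bool array, True where nodata
    transform : (x_origin, dx, 0, y_origin, 0, -dy) affine coefficients
    crs_label : free-text CRS note (no reprojection is performed)
    """

    values: np.ndarray
    nodata_mask: np.ndarray
    transform: tuple[float, float, float, float, float, float]
    crs_label: str = "unspecified"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.values.ndim != 2:
            raise GridFormatError("grid values must be 2-D")
        if self.values.shape != self.nodata_mask.shape:
            raise GridFormatError("values and nodata mask differ in shape")
        if self.transform[1] == 0 or self.transform[5] == 0:
            raise GridFormatError("cell size must be nonzero")
        if not np.all(np.isfinite(self.values[~self.nodata_mask])):
            raise GridFormatError("non-finite values outside the nodata mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cellsize(self) -> float:
        return abs(self.transform[1])

    def unmasked(self) -> np.ndarray:
        """Values of valid cells as a 1-D array (row-major order)."""
        return self.values[~self.nodata_mask]

    def copy_with(self, values: np.ndarray, mask: np.ndarray | None = None) -> "Grid":
        return Grid(
            values=np.asarray(values, dtype=float),
            nodata_mask=self.nodata_mask.copy() if mask is None else mask,
            transform=self.transform,
            crs_label=self.crs_label,
        )

    def rowcol(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cell containing each point (half-open cells)."""
        x0, dx, _, y0, _, dy = self.transform
        col = np.floor((np.asarray(lon, float) - x0) / dx).astype(int)
        row = np.floor((np.asarray(lat, float) - y0) / dy).astype(int)
        return row, col

    def cell_centers(self, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x0, dx, _, y0, _, dy = self.transform
        lon = x0 + (np.asarray(cols) + 0.5) * dx
        lat = y0 + (np.asarray(rows) + 0.5) * dy
        return lon, lat

    def same_geometry(self, other: "Grid", atol: float = 1e-9) -> bool:
        return self.shape == other.shape and np.allclose(
            self.transform, other.transform, atol=atol
        )


@dataclass
class EnvStack:
    """Ordered set of aligned environmental layers sharing one nodata mask.

    The combined mask is the union of the layer masks; ``ranges`` holds the
    per-layer (min, max) over unmasked cells, which later define the model's
    calibration ranges.
    """

    layers: list[Grid]
    names: list[str]
    ranges: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.layers:
            raise GridFormatError("empty environmental stack")
        if len(self.layers) != len(self.names):
            raise GridFormatError("layer/name count mismatch")
        if len(set(self.names)) != len(self.names):
            raise GridFormatError("layer names must be unique")
        ref = self.layers[0]
        for g, name in zip(self.layers, self.names):
            if not ref.same_geometry(g):
                raise GridFormatError(
                    f"layer {name!r} does not align with {self.names[0]!r}"
                )
        mask = np.zeros(ref.shape, dtype=bool)
        for g in self.layers:
            mask |= g.nodata_mask
        self.mask = mask
        for g in self.layers:
            g.nodata_mask = mask
        if not self.ranges:
            self.ranges = [
                (float(g.values[~mask].min()), float(g.values[~mask].max()))
                for g in self.layers
            ]

    @property
    def shape(self) -> tuple[int, int]:
        return self.layers[0].shape

    @property
    def transform(self):
        return self.layers[0].transform

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def values_matrix(self) -> np.ndarray:
        """(n_valid_cells, n_layers) matrix of unmasked cell values."""
        valid = ~self.mask
        return np.column_stack([g.values[valid] for g in self.layers])

    def full_matrix(self) -> np.ndarray:
        """(rows*cols, n_layers) matrix over all cells (masked rows included)."""
        return np.column_stack([g.values.ravel() for g in self.layers])

    def grid_like(self, flat_values: np.ndarray, mask: np.ndarray | None = None) -> Grid:
        """Build a Grid from a flat array over all cells."""
        vals = np.asarray(flat_values, float).reshape(self.shape)
        m = self.mask if mask is None else mask
        vals = np.where(m, 0.0, vals)
        return self.layers[0].copy_with(vals, m.copy())


@dataclass
class OccurrenceSet:
    """Species occurrence records with a role in the modeling workflow."""

    species: str
    records: np.ndarray  # (n, 2) lon, lat
    role: str

    def __post_init__(self) -> None:
        self.records = np.atleast_2d(np.asarray(self.records, dtype=float))
        if self.role not in OCC_ROLES:
            raise ValueError(f"role must be one of {OCC_ROLES}, got {self.role!r}")
        if self.records.size == 0:
            raise ValueError("no occurrences")
        if self.records.shape[1] != 2:
            raise ValueError("records must be (n, 2) lon/lat pairs")
        if not np.all(np.isfinite(self.records)):
            raise ValueError("non-finite coordinates")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def lon(self) -> np.ndarray:
        return self.records[:, 0]

    @property
    def lat(self) -> np.ndarray:
        return self.records[:, 1]


# ---------------------------------------------------------------------------
# Raster I/O
# ---------------------------------------------------------------------------

_ASC_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def _read_asc(path: Path) -> Grid:
    header: dict[str, float] = {}
    data_start = 0
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _ASC_KEYS + ("nodata_value",):
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError as exc:
                raise GridFormatError(f"bad header line in {path}: {line!r}") from exc
            data_start = i + 1
        else:
            break
    for key in _ASC_KEYS:
        if key not in header:
            raise GridFormatError(f"missing {key.upper()} in {path}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cellsize = header["cellsize"]
    if cellsize == 0:
        raise GridFormatError(f"cellsize 0 in {path}")
    nodata = header.get("nodata_value", -9999.0)
    try:
        values = np.loadtxt(lines[data_start:], dtype=float, ndmin=2)
    except ValueError as exc:
        raise GridFormatError(f"unparseable data section in {path}") from exc
    if values.shape != (nrows, ncols):
        raise GridFormatError(
            f"{path}: data shape {values.shape} != header ({nrows}, {ncols})"
        )
    mask = values == nodata
    # north-up transform: origin is upper-left corner
    y_origin = header["yllcorner"] + nrows * cellsize
    transform = (header["xllcorner"], cellsize, 0.0, y_origin, 0.0, -cellsize)
    values = np.where(mask, 0.0, values)
    return Grid(values=values, nodata_mask=mask, transform=transform)


def _write_asc(grid: Grid, path: Path, nodata: float = -9999.0) -> None:
    nrows, ncols = grid.shape
    x0, dx, _, y0, _, dy = grid.transform
    cellsize = abs(dx)
    yll = y0 - nrows * cellsize
    vals = np.where(grid.nodata_mask, nodata, grid.values)
    with open(path, "w") as fh:
        fh.write(f"NCOLS {ncols}\n")
        fh.write(f"NROWS {nrows}\n")
        fh.write(f"XLLCORNER {x0:.10g}\n")
        fh.write(f"YLLCORNER {yll:.10g}\n")
        fh.write(f"CELLSIZE {cellsize:.10g}\n")
        fh.write(f"NODATA_value {nodata:g}\n")
        np.savetxt(fh, vals, fmt="%.6g")


def _read_tif(path: Path) -> Grid:
    import tifffile

    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(float)
        tags = page.tags
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise GridFormatError(f"{path}: missing GeoTIFF georeferencing tags")
        scale = tags[_TAG_PIXEL_SCALE].value
        tie = tags[_TAG_TIEPOINT].value
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
    if values.ndim != 2:
        raise GridFormatError(f"{path}: only single-band rasters supported")
    dx, dy = float(scale[0]), float(scale[1])
    if dx == 0 or dy == 0:
        raise GridFormatError(f"{path}: zero pixel scale")
    # tiepoint: raster (i, j, k) -> model (x, y, z); assume (0,0) -> upper-left
    x0 = float(tie[3]) - float(tie[0]) * dx
    y0 = float(tie[4]) + float(tie[1]) * dy
    mask = ~np.isfinite(values)
    if nodata is not None:
        mask |= values == nodata
    values = np.where(mask, 0.0, values)
    return Grid(values=values, nodata_mask=mask, transform=(x0, dx, 0.0, y0, 0.0, -dy))


def _write_tif(grid: Grid, path: Path, nodata: float = -9999.0) -> None:
    import tifffile

    x0, dx, _, y0, _, dy = grid.transform
    vals = np.where(grid.nodata_mask, nodata, grid.values).astype(np.float32)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (abs(dx), abs(dy), 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, f"{nodata:g}"),
    ]
    tifffile.imwrite(str(path), vals, extratags=extratags)


def read_grid(path: str | os.PathLike) -> Grid:
    """Read a single-band raster (ESRI ASCII ``.asc`` or GeoTIFF)."""
    p = Path(path)
    if not p.exists():
        raise IOError(f"raster not found: {p}")
    suffix = p.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return _read_tif(p)
    if suffix == ".asc":
        return _read_asc(p)
    # fall back on magic: TIFF files start with II*\0 or MM\0*
    with open(p, "rb") as fh:
        magic = fh.read(4)
    if magic[:2] in (b"II", b"MM"):
        return _read_tif(p)
    return _read_asc(p)


def write_grid(grid: Grid, path: str | os.PathLike, nodata: float = -9999.0) -> None:
    """Write a grid as ESRI ASCII (6 significant digits) or float32 GeoTIFF."""
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    if p.suffix.lower() in (".tif", ".tiff"):
        _write_tif(grid, p, nodata)
    else:
        _write_asc(grid, p, nodata)


# ---------------------------------------------------------------------------
# Occurrences
# ---------------------------------------------------------------------------


def read_occurrences(path: str | os.PathLike, role: str) -> OccurrenceSet:
    """Read a ``species,longitude,latitude`` CSV into an OccurrenceSet."""
    p = Path(path)
    if not p.exists():
        raise IOError(f"occurrence file not found: {p}")
    df = pd.read_csv(p)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    for required in ("species", "longitude", "latitude"):
        if required not in cols:
            raise GridFormatError(f"{p}: missing column {required!r}")
    if len(df) == 0:
        raise ValueError(f"{p}: no occurrences")
    for col in ("longitude", "latitude"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.values)[0]) + 2  # 1-based incl. header
        elif coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna().values)[0]) + 2
        else:
            row = None
        if row is not None:
            raise GridFormatError(f"{p}: non-numeric {col} at line {row}")
        df[col] = coerced
    lon = df["longitude"].to_numpy(float)
    lat = df["latitude"].to_numpy(float)
    if np.any(np.abs(lon) > 180) or np.any(np.abs(lat) > 90):
        warnings.warn(
            f"{p}: coordinates outside [-180,180]x[-90,90]; accepted as-is",
            stacklevel=2,
        )
    species = str(df["species"].iloc[0])
    return OccurrenceSet(species=species, records=np.column_stack([lon, lat]), role=role)


def write_occurrences(occ: OccurrenceSet, path: str | os.PathLike) -> None:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"species": occ.species, "longitude": occ.lon, "latitude": occ.lat}
    ).to_csv(p, index=False)


def read_env_dir(directory: str | os.PathLike) -> EnvStack:
    """Load every ``.asc``/``.tif`` raster in a directory as an aligned stack."""
    d = Path(directory)
    if not d.is_dir():
        raise IOError(f"environmental directory not found: {d}")
    paths = sorted(
        [p for p in d.iterdir() if p.suffix.lower() in (".asc", ".tif", ".tiff")]
    )
    if not paths:
        raise IOError(f"no rasters in {d}")
    return EnvStack(layers=[read_grid(p) for p in paths], names=[p.stem for p in paths])


# ---------------------------------------------------------------------------
# Value extraction
# ---------------------------------------------------------------------------


def extract_values(
    stack: EnvStack | Grid, occ: OccurrenceSet, return_report: bool = False
):
    """Cell values at each occurrence (no interpolation).

    Records falling off-grid or on masked cells are dropped; the optional
    report gives their indices.  Returns an (n_kept, n_layers) matrix for a
    stack or an (n_kept,) vector for a single grid.
    """
    if isinstance(stack, Grid):
        ref, layers = stack, [stack]
    else:
        ref, layers = stack.layers[0], stack.layers
    row, col = ref.rowcol(occ.lon, occ.lat)
    nrows, ncols = ref.shape
    inside = (row >= 0) & (row < nrows) & (col >= 0) & (col < ncols)
    ok = inside.copy()
    ok[inside] &= ~ref.nodata_mask[row[inside], col[inside]]
    if not ok.any():
        raise ValueError("all occurrences fall off-grid or on masked cells")
    out = np.column_stack([g.values[row[ok], col[ok]] for g in layers])
    if isinstance(stack, Grid):
        out = out[:, 0]
    report = {
        "n_input": len(occ),
        "n_kept": int(ok.sum()),
        "dropped_indices": np.flatnonzero(~ok).tolist(),
    }
    if return_report:
        return out, report
    if report["dropped_indices"]:
        warnings.warn(
            f"{len(report['dropped_indices'])} occurrence(s) off-grid or masked; dropped",
            stacklevel=2,
        )
    return out


def occurrence_cells(
    stack: EnvStack | Grid, occ: OccurrenceSet, dedupe: bool = False
) -> np.ndarray:
    """Flat cell indices (row-major) of occurrences; optionally one per cell."""
    ref = stack if isinstance(stack, Grid) else stack.layers[0]
    row, col = ref.rowcol(occ.lon, occ.lat)
    nrows, ncols = ref.shape
    inside = (row >= 0) & (row < nrows) & (col >= 0) & (col < ncols)
    ok = inside.copy()
    ok[inside] &= ~ref.nodata_mask[row[inside], col[inside]]
    flat = row[ok] * ncols + col[ok]
    if dedupe:
        flat = np.unique(flat)
    return flat


# ---------------------------------------------------------------------------
# Project layout (directory conventions)
# ---------------------------------------------------------------------------


@dataclass
class ProjectLayout:
    """Single-species project directory convention.

    ::

        root/
          sp_joint.csv  sp_train.csv  sp_test.csv  [sp_ind.csv]
          M_variables/Set_1/ ... Set_k/      (calibration-region rasters)
          G_variables/Set_i/<scenario>/      (transfer rasters, optional)
    """

    root: Path

    def __post_init__(self) -> None:
        self.root = Path(self.root)

    @property
    def joint_csv(self) -> Path:
        return self.root / "sp_joint.csv"

    @property
    def train_csv(self) -> Path:
        return self.root / "sp_train.csv"

    @property
    def test_csv(self) -> Path:
        return self.root / "sp_test.csv"

    @property
    def independent_csv(self) -> Path:
        return self.root / "sp_ind.csv"

    @property
    def m_dir(self) -> Path:
        return self.root / "M_variables"

    @property
    def g_dir(self) -> Path:
        return self.root / "G_variables"

    def set_ids(self) -> list[str]:
        if not self.m_dir.is_dir():
            return []
        return sorted(p.name for p in self.m_dir.iterdir() if p.is_dir())

    def m_set_dir(self, set_id: str) -> Path:
        return self.m_dir / set_id

    def scenarios(self, set_id: str) -> list[str]:
        d = self.g_dir / set_id
        if not d.is_dir():
            return []
        return sorted(p.name for p in d.iterdir() if p.is_dir())

    def g_scenario_dir(self, set_id: str, scenario: str) -> Path:
        return self.g_dir / set_id / scenario

    def load_occurrences(self, role: str) -> OccurrenceSet:
        path = {
            "joint": self.joint_csv,
            "train": self.train_csv,
            "test": self.test_csv,
            "independent": self.independent_csv,
        }[role]
        return read_occurrences(path, role)

    def load_m_stack(self, set_id: str) -> EnvStack:
        return read_env_dir(self.m_set_dir(set_id))

    def load_g_stack(self, set_id: str, scenario: str) -> EnvStack:
        return read_env_dir(self.g_scenario_dir(set_id, scenario))

    def validate(self, require_g: bool = False) -> list[str]:
        """Return a list of problems (empty = valid layout)."""
        problems = []
        for path in (self.joint_csv, self.train_csv, self.test_csv):
            if not path.exists():
                problems.append(f"missing {path.name}")
        sets = self.set_ids()
        if not sets:
            problems.append("no predictor sets under M_variables/")
        for set_id in sets:
            m_names = {
                p.stem
                for p in self.m_set_dir(set_id).iterdir()
                if p.suffix.lower() in (".asc", ".tif", ".tiff")
            }
            if not m_names:
                problems.append(f"M_variables/{set_id} has no rasters")
            for scen in self.scenarios(set_id):
                g_names = {
                    p.stem
                    for p in self.g_scenario_dir(set_id, scen).iterdir()
                    if p.suffix.lower() in (".asc", ".tif", ".tiff")
                }
                if g_names != m_names:
                    problems.append(
                        f"G_variables/{set_id}/{scen} layers {sorted(g_names)} "
                        f"!= M layers {sorted(m_names)}"
                    )
        if require_g and not any(self.scenarios(s) for s in sets):
            problems.append("no transfer scenarios under G_variables/")
        return problems
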