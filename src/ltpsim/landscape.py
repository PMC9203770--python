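"""Raster landscapes: grids of cell types and elevation.

Everything downstream — movement costs, least-cost distances, the
reinforcement dynamics — sees the landscape only through a
:class:`LandscapeGrid`: a rectangular raster whose cells are land, ocean,
lake or river, with an elevation in metres on land.  Grids come from three
places: the flatland generator (uniform, optionally periodic), the synthetic
landscape generator (coastline carving + spectral fractal relief + rasterised
rivers, used to emulate realistic scenarios without external data), or ESRI
ASCII grid rasters on disk.

Grid convention: 0-based (row, col) with row 0 at the northern edge;
coordinates refer to cell centres.  East-west spacing may vary by row
(cos-latitude correction) for geographic rasters; synthetic grids use a
constant spacing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "LAND",
    "OCEAN",
    "LAKE",
    "RIVER",
    "CELL_TYPE_NAMES",
    "LandscapeGrid",
    "SyntheticLandscapeSpec",
    "generate_flatland",
    "generate_synthetic_landscape",
    "read_landscape",
    "write_landscape",
    "read_ascii_grid",
    "write_ascii_grid",
]

# Integer cell-type codes used throughout the package.
LAND, OCEAN, LAKE, RIVER = 0, 1, 2, 3
CELL_TYPE_NAMES = {LAND: "land", OCEAN: "ocean", LAKE: "lake", RIVER: "river"}

#: km per degree of latitude (spherical Earth, mean radius).
KM_PER_DEG = 111.32


@dataclass
class LandscapeGrid:
    """A raster landscape.

    Parameters
    ----------
    cell_type
        ``(nrows, ncols)`` int array with codes ``LAND``/``OCEAN``/``LAKE``/``RIVER``.
    elevation_m
        ``(nrows, ncols)`` float array, metres.  Defined (finite) on land;
        zero on water cells.
    cell_size_ew_km
        East-west centre-to-centre spacing, either a scalar or one value per
        row (geographic grids shrink with latitude).
    cell_size_ns_km
        North-south spacing (scalar).
    periodic
        Wrap-around topology (flatland only; requires all cells land).
    crs_note
        Free-text provenance, e.g. a bounding box or ``"synthetic"``.
    origin
        Optional ``(lon0, lat0, dlon, dlat)`` mapping cell (row, col) centres
        to geographic coordinates: ``lon = lon0 + (col + 0.5) * dlon``,
        ``lat = lat0 - (row + 0.5) * dlat`` (row 0 is the northern edge).
        ``None`` for synthetic grids, where lon ≡ col and lat ≡ row.
    """

    cell_type: np.ndarray
    elevation_m: np.ndarray
    cell_size_ew_km: np.ndarray | float
    cell_size_ns_km: float
    periodic: bool = False
    crs_note: str = "synthetic"
    origin: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        self.cell_type = np.asarray(self.cell_type, dtype=np.int8)
        self.elevation_m = np.asarray(self.elevation_m, dtype=float)
        if self.cell_type.ndim != 2 or self.cell_type.size == 0:
            raise ValueError("cell_type must be a non-empty 2-D array")
        if self.cell_type.shape != self.elevation_m.shape:
            raise ValueError("cell_type and elevation_m shapes differ")
        ew = np.atleast_1d(np.asarray(self.cell_size_ew_km, dtype=float))
        if ew.size == 1:
            ew = np.full(self.nrows, float(ew[0]))
        if ew.size != self.nrows:
            raise ValueError("cell_size_ew_km must be scalar or one per row")
        if np.any(ew <= 0) or self.cell_size_ns_km <= 0:
            raise ValueError("cell sizes must be positive")
        self.cell_size_ew_km = ew
        land = self.cell_type == LAND
        if not np.all(np.isfinite(self.elevation_m[land])):
            raise ValueError("elevation must be finite on land cells")
        if self.periodic and not land.all():
            raise ValueError("periodic grids must be all land")

    @property
    def nrows(self) -> int:
        return self.cell_type.shape[0]

    @property
    def ncols(self) -> int:
        return self.cell_type.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.cell_type.shape

    @property
    def is_land(self) -> np.ndarray:
        return self.cell_type == LAND

    @property
    def is_water(self) -> np.ndarray:
        return self.cell_type != LAND

    def land_fraction(self) -> float:
        return float(self.is_land.mean())

    def lonlat_to_cell(self, lon: float, lat: float) -> tuple[int, int]:
        """Map a (lon, lat) point to the containing (row, col) cell.

        Synthetic grids (no ``origin``) interpret lon as column index and lat
        as row index directly.
        """
        if self.origin is None:
            row, col = int(round(lat)), int(round(lon))
        else:
            lon0, lat0, dlon, dlat = self.origin
            col = int(np.floor((lon - lon0) / dlon))
            row = int(np.floor((lat0 - lat) / dlat))
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise ValueError(f"point ({lon}, {lat}) falls outside the grid")
        return row, col


@dataclass
class SyntheticLandscapeSpec:
    """Recipe for a seeded synthetic landscape.

    ``land_fraction`` controls coastline carving (1.0 = no ocean);
    ``roughness`` is the power-law exponent of the spectral elevation noise
    (larger = smoother); ``amplitude_m`` scales relief; ``rivers`` is a list
    of polylines, each a sequence of (row, col) vertices over land.
    """

    nrows: int
    ncols: int
    cell_size_km: float = 2.0
    land_fraction: float = 1.0
    roughness: float = 2.0
    amplitude_m: float = 0.0
    coast_smoothness: float = 3.0
    rivers: list[list[tuple[int, int]]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.land_fraction <= 1.0):
            raise ValueError("land_fraction must be in (0, 1]")
        if self.amplitude_m < 0:
            raise ValueError("amplitude_m must be non-negative")
        for poly in self.rivers:
            for r, c in poly:
                if not (0 <= r < self.nrows and 0 <= c < self.ncols):
                    raise ValueError(f"river vertex ({r}, {c}) outside grid bounds")


def generate_flatland(
    nrows: int, ncols: int, cell_size_km: float, periodic: bool = True
) -> LandscapeGrid:
    """Uniform all-land grid at elevation zero — the idealised isotropic case.

    With ``periodic=True`` the grid has wrap-around (toroidal) topology so
    that every cell has exactly eight neighbours and no boundary exists.
    """
    if nrows <= 0 or ncols <= 0:
        raise ValueError("grid dimensions must be positive")
    return LandscapeGrid(
        cell_type=np.full((nrows, ncols), LAND, dtype=np.int8),
        elevation_m=np.zeros((nrows, ncols)),
        cell_size_ew_km=cell_size_km,
        cell_size_ns_km=cell_size_km,
        periodic=periodic,
        crs_note="synthetic flatland",
    )


def _spectral_noise(rng: np.random.Generator, shape: tuple[int, int], exponent: float) -> np.ndarray:
    """Power-law (1/|k|^exponent) filtered Gaussian noise, unit variance."""
    nr, nc = shape
    white = rng.standard_normal(shape)
    ky = np.fft.fftfreq(nr)[:, None]
    kx = np.fft.fftfreq(nc)[None, :]
    k = np.hypot(ky, kx)
    k[0, 0] = np.inf  # zero-mean field
    spec = np.fft.fft2(white) / k**exponent
    out = np.real(np.fft.ifft2(spec))
    sd = out.std()
    return out / sd if sd > 0 else out


def _rasterize_polyline(vertices: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """8-connected Bresenham rasterisation of a polyline; de-duplicated, ordered."""
    cells: list[tuple[int, int]] = []
    for (r0, c0), (r1, c1) in zip(vertices[:-1], vertices[1:]):
        dr, dc = abs(r1 - r0), abs(c1 - c0)
        sr = 1 if r1 >= r0 else -1
        sc = 1 if c1 >= c0 else -1
        err = dr - dc
        r, c = r0, c0
        while True:
            if not cells or cells[-1] != (r, c):
                cells.append((r, c))
            if (r, c) == (r1, c1):
                break
            e2 = 2 * err
            if e2 > -dc:
                err -= dc
                r += sr
            if e2 < dr:
                err += dr
                c += sc
    if len(vertices) == 1:
        cells = [tuple(vertices[0])]
    return cells


def generate_synthetic_landscape(spec: SyntheticLandscapeSpec) -> LandscapeGrid:
    """Seeded synthetic landscape: coastline, fractal relief, rivers.

    The coastline is carved by thresholding a smooth spectral noise field at
    the quantile matching ``land_fraction``; water components touching the
    grid border become ocean, enclosed ones lakes.  Elevation is power-law
    spectral noise shifted to be non-negative over land and scaled to
    ``amplitude_m``; water sits at elevation zero.  Rivers are rasterised
    8-connected polylines over land.  Bit-reproducible for a fixed spec.
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.nrows, spec.ncols)
    cell_type = np.full(shape, LAND, dtype=np.int8)

    if spec.land_fraction < 1.0:
        coast_field = _spectral_noise(rng, shape, spec.coast_smoothness)
        thresh = np.quantile(coast_field, 1.0 - spec.land_fraction)
        water = coast_field < thresh
        # ocean = water touching the border; enclosed water = lake
        from scipy import ndimage

        labels, nlab = ndimage.label(water, structure=np.ones((3, 3)))
        border = np.zeros(shape, dtype=bool)
        border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
        ocean_labels = np.unique(labels[water & border])
        for lab in range(1, nlab + 1):
            cell_type[labels == lab] = OCEAN if lab in ocean_labels else LAKE
    else:
        # keep the stream position identical whether or not a coast is carved
        _ = rng.standard_normal(shape)

    if spec.amplitude_m > 0:
        relief = _spectral_noise(rng, shape, spec.roughness)
        relief = relief - relief.min()
        if relief.max() > 0:
            relief = relief / relief.max() * spec.amplitude_m
        elevation = relief
    else:
        _ = rng.standard_normal(shape)
        elevation = np.zeros(shape)

    for poly in spec.rivers:
        for r, c in _rasterize_polyline([tuple(v) for v in poly]):
            if cell_type[r, c] == LAND:
                cell_type[r, c] = RIVER

    elevation = np.where(cell_type == LAND, elevation, 0.0)
    return LandscapeGrid(
        cell_type=cell_type,
        elevation_m=elevation,
        cell_size_ew_km=spec.cell_size_km,
        cell_size_ns_km=spec.cell_size_km,
        periodic=False,
        crs_note="synthetic",
    )


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid; returns (array, header dict)."""
    path = Path(path)
    header: dict = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in ("ncols", "nrows"):
                header[key] = int(parts[1])
            elif key in ("xllcorner", "yllcorner", "cellsize", "nodata_value"):
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    data = np.array(
        [v for row in rows for v in row], dtype=float
    ).reshape(header["nrows"], header["ncols"])
    if "nodata_value" in header:
        data[data == header["nodata_value"]] = np.nan
    return data, header


def write_ascii_grid(
    path: str | Path,
    data: np.ndarray,
    xllcorner: float = 0.0,
    yllcorner: float = 0.0,
    cellsize: float = 1.0,
    nodata: float = -9999.0,
) -> None:
    data = np.asarray(data, dtype=float)
    out = np.where(np.isnan(data), nodata, data)
    with open(path, "w") as fh:
        fh.write(f"ncols {data.shape[1]}\n")
        fh.write(f"nrows {data.shape[0]}\n")
        fh.write(f"xllcorner {xllcorner!r}\n")
        fh.write(f"yllcorner {yllcorner!r}\n")
        fh.write(f"cellsize {cellsize!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def _block_median(data: np.ndarray, factor: int) -> np.ndarray:
    """Median over factor x factor blocks (truncating ragged edges)."""
    nr = (data.shape[0] // factor) * factor
    nc = (data.shape[1] // factor) * factor
    d = data[:nr, :nc].reshape(nr // factor, factor, nc // factor, factor)
    return np.nanmedian(d.transpose(0, 2, 1, 3).reshape(nr // factor, nc // factor, -1), axis=2)


def _block_mode(data: np.ndarray, factor: int) -> np.ndarray:
    """Most frequent integer code per block; ties go to the lower code."""
    nr = (data.shape[0] // factor) * factor
    nc = (data.shape[1] // factor) * factor
    d = data[:nr, :nc].astype(int)
    d = d.reshape(nr // factor, factor, nc // factor, factor).transpose(0, 2, 1, 3)
    d = d.reshape(nr // factor, nc // factor, -1)
    ncodes = int(d.max()) + 1
    counts = np.stack([(d == c).sum(axis=2) for c in range(ncodes)], axis=2)
    return counts.argmax(axis=2)


def read_landscape(
    elevation_path: str | Path,
    water_path: str | Path,
    min_river_class: int = 1,
    resample_factor: int = 1,
    river_class_path: str | Path | None = None,
    water_codes: dict[int, int] | None = None,
    geographic: bool = False,
    cell_size_km: float = 1.0,
) -> LandscapeGrid:
    """Build a LandscapeGrid from ESRI ASCII rasters.

    ``water_path`` holds integer cell-type codes (mapped through
    ``water_codes``, default identity on the package codes); an optional
    river-class raster keeps river cells only where class > ``min_river_class``
    (class-1 streams are dropped), matching how minor rivers are excluded from
    a GloRiC-style classification.  Elevation is median-resampled over
    ``resample_factor`` x ``resample_factor`` blocks to damp outliers; water
    codes are resampled by block majority.  With ``geographic=True`` the
    header is in degrees and per-row east-west spacing gets a cos-latitude
    correction; otherwise ``cell_size_km`` is the (input) cell size.
    """
    elev, eh = read_ascii_grid(elevation_path)
    water, wh = read_ascii_grid(water_path)
    if elev.shape != water.shape or eh.get("cellsize") != wh.get("cellsize"):
        raise ValueError("elevation and water rasters are misaligned")
    river_class = None
    if river_class_path is not None:
        river_class, rh = read_ascii_grid(river_class_path)
        if river_class.shape != elev.shape:
            raise ValueError("river-class raster misaligned with elevation")

    codes = water_codes or {LAND: LAND, OCEAN: OCEAN, LAKE: LAKE, RIVER: RIVER}
    water_int = np.where(np.isnan(water), OCEAN, water).astype(int)
    unknown = set(np.unique(water_int)) - set(codes)
    if unknown:
        raise ValueError(f"unknown water-raster codes: {sorted(unknown)}")
    cell_type = np.vectorize(codes.get, otypes=[np.int8])(water_int)

    if river_class is not None:
        drop = (cell_type == RIVER) & ~(np.nan_to_num(river_class) > min_river_class)
        cell_type[drop] = LAND

    if resample_factor > 1:
        elev = _block_median(elev, resample_factor)
        cell_type = _block_mode(cell_type, resample_factor).astype(np.int8)

    elev = np.where(cell_type == LAND, np.nan_to_num(elev), 0.0)

    cellsize = eh.get("cellsize", 1.0) * resample_factor
    if geographic:
        nrows = cell_type.shape[0]
        lat_top = eh["yllcorner"] + eh["nrows"] * eh["cellsize"]
        lats = lat_top - (np.arange(nrows) + 0.5) * cellsize
        ew = KM_PER_DEG * cellsize * np.cos(np.deg2rad(lats))
        ns = KM_PER_DEG * cellsize
        origin = (eh["xllcorner"], lat_top, cellsize, cellsize)
        note = f"geographic, cellsize {cellsize} deg"
    else:
        ew = cell_size_km * resample_factor
        ns = cell_size_km * resample_factor
        origin = None
        note = f"projected, cellsize {cellsize}"
    return LandscapeGrid(
        cell_type=cell_type,
        elevation_m=elev,
        cell_size_ew_km=ew,
        cell_size_ns_km=ns,
        periodic=False,
        crs_note=note,
        origin=origin,
    )


def write_landscape(grid: LandscapeGrid, directory: str | Path, stem: str = "landscape") -> dict:
    """Save a grid as elevation + cell-type ASCII rasters with a JSON sidecar.

    Returns the sidecar dict.  ``read_landscape`` on the written pair
    round-trips cell types and elevations exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if grid.origin is not None:
        lon0, lat0, dlon, dlat = grid.origin
        xll, yll, cs = lon0, lat0 - grid.nrows * dlat, dlon
    else:
        xll, yll, cs = 0.0, 0.0, 1.0
    write_ascii_grid(directory / f"{stem}_elevation.asc", grid.elevation_m, xll, yll, cs)
    write_ascii_grid(directory / f"{stem}_celltype.asc", grid.cell_type.astype(float), xll, yll, cs)
    meta = {
        "nrows": grid.nrows,
        "ncols": grid.ncols,
        "cell_size_ew_km": np.asarray(grid.cell_size_ew_km).tolist(),
        "cell_size_ns_km": grid.cell_size_ns_km,
        "periodic": grid.periodic,
        "crs_note": grid.crs_note,
        "origin": list(grid.origin) if grid.origin else None,
        "cell_type_codes": {str(k): v for k, v in CELL_TYPE_NAMES.items()},
    }
    with open(directory / f"{stem}_meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    return meta


def load_landscape(directory: str | Path, stem: str = "landscape") -> LandscapeGrid:
    """Inverse of :func:`write_landscape`."""
    directory = Path(directory)
    elev, _ = read_ascii_grid(directory / f"{stem}_elevation.asc")
    ctype, _ = read_ascii_grid(directory / f"{stem}_celltype.asc")
    with open(directory / f"{stem}_meta.json") as fh:
        meta = json.load(fh)
    ew = meta["cell_size_ew_km"]
    return LandscapeGrid(
        cell_type=ctype.astype(np.int8),
        elevation_m=np.nan_to_num(elev),
        cell_size_ew_km=np.asarray(ew, dtype=float) if isinstance(ew, list) else ew,
        cell_size_ns_km=meta["cell_size_ns_km"],
        periodic=meta["periodic"],
        crs_note=meta["crs_note"],
        origin=tuple(meta["origin"]) if meta["origin"] else None,
    )
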