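"""Raster data model and the spatial primitives every score layer builds on.

The landscape is a regular square grid in a projected (metre-unit) CRS.
Two primitives drive all downstream scoring:

* :func:`neighborhood_fraction` — the fraction of cells within a circular
  neighborhood that belong to a set of target landcover classes (a focal
  "density" statistic, e.g. native forest within a home range);
* :func:`distance_to_nearest` — Euclidean distance from each cell centre to
  the nearest cell of a target class (e.g. distance to intact forest).

Conventions (applied consistently across the package):

* a cell belongs to a circular neighborhood iff its CENTRE lies within the
  radius of the focal cell's CENTRE (boundary inclusive);
* neighborhoods are truncated at the raster edge and fractions use the
  in-bounds, non-NoData denominator, so coastal cells are not penalised for
  off-map area;
* NoData cells (code ``-1``) are excluded from numerators and denominators
  and can never be targets;
* row 0 is the northmost row; the origin is the top-left corner of the grid.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
import tifffile
from scipy import ndimage

NODATA_CODE = -1
NODATA_VALUE = -9999.0

#: Sentinel returned by :func:`distance_to_nearest` when the grid contains no
#: target cell at all.
INFINITE_DISTANCE = math.inf

# GeoTIFF tag ids used for georeferencing (pixel scale, tiepoint, GDAL nodata).
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

_GEOGRAPHIC_CRS_HINTS = ("4326", "crs84", "longlat", "degree", "wgs84(g", "epsg:4269")


class GridError(ValueError):
    """Raised for invalid grid construction or misaligned layers."""


def _ensure_metric_crs(crs_id: str) -> None:
    """Reject CRS identifiers that look geographic (degree units).

    Without a full CRS database this is a name-based check; projected CRS
    strings such as ``EPSG:32655`` pass through untouched.
    """
    low = (crs_id or "").lower()
    if any(h in low for h in _GEOGRAPHIC_CRS_HINTS):
        raise GridError(
            f"CRS {crs_id!r} appears to use degree units; reproject the "
            "landcover map to a metre-based projected CRS (e.g. a UTM zone) "
            "before gridding."
        )


@dataclass
class LandcoverGrid:
    """Categorical landcover raster with georeference metadata.

    Parameters
    ----------
    codes
        2-D integer array of landcover class codes; ``-1`` marks NoData.
    cell_size
        Side length of the square cells, metres.
    origin
        ``(x, y)`` of the grid's top-left corner in projected CRS units.
    crs_id
        Opaque CRS identifier (e.g. ``"EPSG:32655"``).
    class_names
        Mapping from class code to a human-readable label; every non-NoData
        code present in ``codes`` must be listed.
    """

    codes: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    crs_id: str = "local-metric"
    class_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int32)
        if self.codes.ndim != 2 or self.codes.size == 0:
            raise GridError("codes must be a non-empty 2-D array")
        if not self.cell_size > 0:
            raise GridError("cell_size must be > 0")
        _ensure_metric_crs(self.crs_id)
        present = set(np.unique(self.codes).tolist()) - {NODATA_CODE}
        missing = present - set(self.class_names)
        if missing:
            # Auto-label rather than fail: synthetic grids are built from bare
            # code arrays all the time.
            for c in sorted(missing):
                self.class_names[int(c)] = f"class_{int(c)}"

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return self.codes != NODATA_CODE

    def class_mask(self, classes) -> np.ndarray:
        """Boolean mask of cells whose code is in ``classes`` (NoData never)."""
        codes = list(classes)
        if not codes:
            return np.zeros(self.shape, dtype=bool)
        return np.isin(self.codes, codes) & self.valid_mask

    def cell_centre(self, row: int, col: int) -> tuple[float, float]:
        ox, oy = self.origin
        return (ox + (col + 0.5) * self.cell_size, oy - (row + 0.5) * self.cell_size)


@dataclass
class ScoreGrid:
    """Real-valued raster aligned to a :class:`LandcoverGrid`.

    ``values`` are float64; cells flagged in ``nodata_mask`` carry no score.
    Score layers live in [0, 1]; the internal distance layer is unnormalized
    metres (with ``inf`` when no target exists).
    """

    values: np.ndarray
    nodata_mask: np.ndarray
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    crs_id: str = "local-metric"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.values.shape != self.nodata_mask.shape:
            raise GridError("values and nodata_mask shapes differ")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def masked(self) -> np.ndarray:
        """Values with NoData replaced by NaN (convenient for reductions)."""
        out = self.values.copy()
        out[self.nodata_mask] = np.nan
        return out

    @classmethod
    def like(cls, grid: LandcoverGrid, values: np.ndarray, nodata_mask: np.ndarray) -> "ScoreGrid":
        if values.shape != grid.shape:
            raise GridError("layer shape does not match the landcover grid")
        return cls(values, nodata_mask, grid.cell_size, grid.origin, grid.crs_id)


@dataclass
class RasterizationReport:
    """Per-class area comparison between a vector map and its rasterization."""

    per_class_vector_area: dict[int, float]
    per_class_raster_area: dict[int, float]
    relative_error: dict[int, float]
    passed: bool
    missing_in_vector: set[int] = field(default_factory=set)


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def rasterize_landcover(polygons, cell_size: float, bounds, crs_id: str = "local-metric") -> LandcoverGrid:
    """Burn class polygons onto a grid by cell-centre containment.

    Parameters
    ----------
    polygons
        Iterable of ``(class_code, shapely geometry)`` pairs. Where polygons
        overlap, the first pair in iteration order wins (priority order).
    cell_size
        Cell side length, metres.
    bounds
        ``(minx, miny, maxx, maxy)`` rectangle covering all polygons.

    Cells whose centre falls in no polygon are NoData. Boundary points count
    as covered, so abutting polygons tile without gaps.
    """
    polys = list(polygons)
    if not polys:
        raise GridError("empty polygon set: nothing to rasterize")
    if not cell_size > 0:
        raise GridError("cell_size must be > 0")
    _ensure_metric_crs(crs_id)

    minx, miny, maxx, maxy = bounds
    if not (maxx > minx and maxy > miny):
        raise GridError("bounds rectangle is degenerate")
    ncols = max(1, int(math.ceil((maxx - minx) / cell_size - 1e-9)))
    nrows = max(1, int(math.ceil((maxy - miny) / cell_size - 1e-9)))

    cols = np.arange(ncols)
    rows = np.arange(nrows)
    cx = minx + (cols + 0.5) * cell_size
    cy = maxy - (rows + 0.5) * cell_size
    xx, yy = np.meshgrid(cx, cy)

    codes = np.full((nrows, ncols), NODATA_CODE, dtype=np.int32)
    unassigned = np.ones((nrows, ncols), dtype=bool)
    names: dict[int, str] = {}
    for code, geom in polys:
        if not unassigned.any():
            break
        # intersects is boundary-inclusive, unlike contains
        hit = shapely.intersects_xy(geom, xx[unassigned], yy[unassigned])
        idx = np.flatnonzero(unassigned.ravel())[hit]
        codes.ravel()[idx] = int(code)
        unassigned.ravel()[idx] = False
        names.setdefault(int(code), f"class_{int(code)}")
    return LandcoverGrid(codes, cell_size, origin=(minx, maxy), crs_id=crs_id, class_names=names)


def check_rasterization_fidelity(polygons, grid: LandcoverGrid, tolerance: float) -> RasterizationReport:
    """Compare per-class areas between source polygons and the raster.

    ``passed`` is true iff every class's relative area error is within
    ``tolerance`` and no raster class is missing from the vector map. Large
    errors signal that the cell size is too coarse for the map's patchiness.
    """
    vec: dict[int, float] = {}
    for code, geom in polygons:
        vec[int(code)] = vec.get(int(code), 0.0) + float(geom.area)

    ras: dict[int, float] = {}
    cell_area = grid.cell_size ** 2
    codes, counts = np.unique(grid.codes[grid.valid_mask], return_counts=True)
    for c, n in zip(codes.tolist(), counts.tolist()):
        ras[int(c)] = n * cell_area

    rel: dict[int, float] = {}
    passed = True
    for c, va in vec.items():
        if va > 0:
            rel[c] = abs(ras.get(c, 0.0) - va) / va
            if rel[c] > tolerance:
                passed = False
    missing = {c for c in ras if c not in vec}
    if missing:
        passed = False
    return RasterizationReport(vec, ras, rel, passed, missing)


def suggest_resolution(max_function_distance: float, candidate_sizes) -> float:
    """Pick the coarsest candidate cell size at most a tenth of the function scale.

    The grid must resolve the finest spatial scale at which the ecological
    function operates; a cell at least 10x smaller than the maximum function
    distance (e.g. the dispersal threshold) is the working rule. Advisory only.
    """
    if not max_function_distance > 0:
        raise GridError("max_function_distance must be > 0")
    cands = sorted(candidate_sizes)
    if not cands:
        raise GridError("no candidate sizes given")
    bound = max_function_distance / 10.0
    ok = [c for c in cands if c <= bound]
    if not ok:
        raise GridError(
            f"no candidate cell size satisfies the resolution bound "
            f"(need <= {bound:g} m, one tenth of {max_function_distance:g} m)"
        )
    return ok[-1]


# ---------------------------------------------------------------------------
# Spatial primitives
# ---------------------------------------------------------------------------

def disk_kernel(radius: float, cell_size: float) -> np.ndarray:
    """Boolean footprint of cells whose centres lie within ``radius`` metres.

    Centre-to-centre distances; the focal cell (distance 0) is always inside.
    """
    r_cells = int(math.floor(radius / cell_size + 1e-12))
    offs = np.arange(-r_cells, r_cells + 1)
    di, dj = np.meshgrid(offs, offs, indexing="ij")
    return np.hypot(di, dj) * cell_size <= radius


def linear_weight_kernel(radius: float, cell_size: float) -> np.ndarray:
    """Distance-decay footprint: weight ``1 - d/radius`` for d < radius, else 0."""
    r_cells = int(math.ceil(radius / cell_size))
    offs = np.arange(-r_cells, r_cells + 1)
    di, dj = np.meshgrid(offs, offs, indexing="ij")
    d = np.hypot(di, dj) * cell_size
    w = 1.0 - d / radius
    w[d >= radius] = 0.0
    return w


def neighborhood_fraction(grid: LandcoverGrid, target_classes, radius: float) -> ScoreGrid:
    """Fraction of a circular neighborhood occupied by the target classes.

    For each cell, counts the cells whose centres lie within ``radius`` of the
    focal centre (focal included); the fraction is target cells over in-bounds
    non-NoData cells. NoData focal cells stay NoData.
    """
    if not radius > 0:
        raise GridError("radius must be > 0")
    if radius < grid.cell_size:
        warnings.warn(
            "neighborhood radius is smaller than the cell size: the "
            "neighborhood degenerates to the focal cell alone",
            stacklevel=2,
        )
    valid = grid.valid_mask
    target = grid.class_mask(target_classes)
    kernel = disk_kernel(radius, grid.cell_size).astype(np.int64)
    # Integer convolution keeps both counts exact.
    num = ndimage.convolve(target.astype(np.int64), kernel, mode="constant", cval=0)
    den = ndimage.convolve(valid.astype(np.int64), kernel, mode="constant", cval=0)
    values = np.zeros(grid.shape, dtype=np.float64)
    ok = valid & (den > 0)
    values[ok] = num[ok] / den[ok]
    return ScoreGrid.like(grid, values, ~valid)


def distance_to_nearest(grid: LandcoverGrid, target_classes) -> ScoreGrid:
    """Euclidean centre-to-centre distance to the nearest target-class cell.

    0 on target cells; ``inf`` everywhere when the grid holds no target cell.
    Returned in metres, unnormalized.
    """
    target = grid.class_mask(target_classes)
    valid = grid.valid_mask
    if not target.any():
        values = np.full(grid.shape, INFINITE_DISTANCE)
    else:
        # EDT on the unit lattice, then scaled: both this and a brute-force
        # enumeration take sqrt of the same integer sum of squares.
        values = ndimage.distance_transform_edt(~target) * grid.cell_size
    return ScoreGrid.like(grid, values, ~valid)


# ---------------------------------------------------------------------------
# File I/O — GeoTIFF-tagged TIFF via tifffile, vector landcover via GeoJSON
# ---------------------------------------------------------------------------

def _geo_extratags(cell_size: float, origin, nodata, description: str):
    ox, oy = origin
    return [
        (_TAG_PIXEL_SCALE, "d", 3, (float(cell_size), float(cell_size), 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(ox), float(oy), 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata)),
    ]


def write_score_geotiff(path, layer: ScoreGrid) -> None:
    """Write a score layer as single-band float32 GeoTIFF, NoData = -9999."""
    data = layer.values.astype(np.float32)
    data[layer.nodata_mask] = np.float32(NODATA_VALUE)
    meta = {"cell_size": layer.cell_size, "origin": list(layer.origin), "crs_id": layer.crs_id}
    tifffile.imwrite(
        path,
        data,
        extratags=_geo_extratags(layer.cell_size, layer.origin, NODATA_VALUE, ""),
        description=json.dumps(meta),
    )


def write_landcover_geotiff(path, grid: LandcoverGrid) -> None:
    meta = {
        "cell_size": grid.cell_size,
        "origin": list(grid.origin),
        "crs_id": grid.crs_id,
        "class_names": {str(k): v for k, v in grid.class_names.items()},
    }
    tifffile.imwrite(
        path,
        grid.codes.astype(np.int32),
        extratags=_geo_extratags(grid.cell_size, grid.origin, NODATA_CODE, ""),
        description=json.dumps(meta),
    )


def _read_tiff(path):
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        data = page.asarray()
        tags = page.tags
        meta = {}
        desc = tags.get("ImageDescription")
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (TypeError, json.JSONDecodeError):
                meta = {}
        scale = tags.get(_TAG_PIXEL_SCALE)
        tie = tags.get(_TAG_TIEPOINT)
        cell = float(scale.value[0]) if scale is not None else float(meta.get("cell_size", 1.0))
        if tie is not None:
            origin = (float(tie.value[3]), float(tie.value[4]))
        else:
            origin = tuple(meta.get("origin", (0.0, 0.0)))
    return data, cell, origin, meta


def read_landcover_geotiff(path) -> LandcoverGrid:
    """Read an integer landcover raster (NoData tag -1 honoured)."""
    data, cell, origin, meta = _read_tiff(path)
    names = {int(k): v for k, v in meta.get("class_names", {}).items()}
    return LandcoverGrid(
        np.asarray(data, dtype=np.int32),
        cell,
        origin=origin,
        crs_id=meta.get("crs_id", "local-metric"),
        class_names=names,
    )


def read_score_geotiff(path) -> ScoreGrid:
    data, cell, origin, meta = _read_tiff(path)
    values = np.asarray(data, dtype=np.float64)
    mask = values == NODATA_VALUE
    values[mask] = 0.0
    return ScoreGrid(values, mask, cell, origin, meta.get("crs_id", "local-metric"))


def read_landcover_geojson(path, class_property: str = "class_code"):
    """Read ``(code, geometry)`` pairs from a GeoJSON FeatureCollection.

    Each feature must carry an integer class code in ``properties``; features
    are returned in file order (priority order for rasterization).
    """
    with open(path) as fh:
        doc = json.load(fh)
    feats = doc.get("features", [])
    if not feats:
        raise GridError(f"{path}: no features in GeoJSON")
    out = []
    for feat in feats:
        props = feat.get("properties") or {}
        if class_property not in props:
            raise GridError(f"{path}: feature missing property {class_property!r}")
        geom = shapely.geometry.shape(feat["geometry"])
        out.append((int(props[class_property]), geom))
    return out
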