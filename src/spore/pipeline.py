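"""Configuration, orchestration and file I/O for end-to-end runs.

A run executes the stages in fixed order — priority → suitability → function
→ rewilding → management units — writes each layer as GeoTIFF, the units as
GeoJSON plus a ranking CSV, and a JSON manifest recording the configuration,
the exact formula strings used, layer checksums and library versions, so a
run can be audited and reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import scipy
import shapely
import yaml

from . import grid as _grid
from .grid import (
    GridError,
    LandcoverGrid,
    check_rasterization_fidelity,
    rasterize_landcover,
    read_landcover_geojson,
    read_landcover_geotiff,
    write_landcover_geotiff,
    write_score_geotiff,
)
from .scoring import (
    NORMALIZATIONS,
    PROXIMITY_FORMS,
    FunctionWeights,
    PriorityTable,
    SpeciesProfile,
    function_score,
    habitat_suitability,
    priority_score,
    rewilding_score,
)
from .synth import guam_like_scenario
from .units import (
    AGGREGATORS,
    build_units,
    derive_attribute_grid,
    ranking_table,
    score_and_rank,
    units_to_geojson,
)

log = logging.getLogger("spore")


class ConfigError(ValueError):
    """Invalid configuration; ``errors`` lists every problem found."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {e}" for e in self.errors))


@dataclass
class SporeConfig:
    """Validated, fully-defaulted run configuration."""

    landcover: str  # path to .tif/.geojson, or "synthetic"
    cell_size: float
    priority_table: PriorityTable
    species: SpeciesProfile
    weights: FunctionWeights
    normalization: str
    attribute_rule: dict
    attribute_default: str
    connectivity: int
    min_cells: int
    aggregator: str
    output_dir: str
    seed: int = 0
    fidelity_tolerance: float = 0.05
    crs_id: str = "local-metric"
    synthetic_shape: tuple[int, int] = (300, 300)


@dataclass
class RunManifest:
    """Audit record written at the end of every successful run."""

    config: dict
    formulas: dict
    checksums: dict
    cell_counts: dict
    unit_count: int
    timestamp: str
    versions: dict

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


_KNOWN_KEYS = {
    "landcover",
    "cell_size",
    "crs_id",
    "priority_table",
    "species",
    "function",
    "rewilding",
    "units",
    "output_dir",
    "seed",
    "fidelity_tolerance",
    "synthetic_shape",
}


def validate_config(raw: dict) -> SporeConfig:
    """Normalize a parsed key-value document into a :class:`SporeConfig`.

    Collects every problem (unknown keys, out-of-range values, missing
    sections) into one itemized :class:`ConfigError` instead of failing on
    the first. Defaults applied: alpha 0.5, linear proximity,
    neighborhood-weight normalization, connectivity 8, min_cells 1,
    aggregator mean; each applied default is logged.
    """
    errors: list[str] = []
    if not isinstance(raw, dict):
        raise ConfigError(["configuration document must be a mapping"])
    for key in raw:
        if key not in _KNOWN_KEYS:
            errors.append(f"unknown key {key!r}")

    def _default(section, key, value):
        log.info("config default applied: %s.%s = %r", section, key, value)
        return value

    landcover = raw.get("landcover")
    if not landcover:
        errors.append("missing 'landcover' (path to GeoTIFF/GeoJSON, or 'synthetic')")
    cell_size = raw.get("cell_size", _default("root", "cell_size", 30.0))
    if not isinstance(cell_size, (int, float)) or cell_size <= 0:
        errors.append("cell_size must be a positive number of metres")

    table = None
    tbl = raw.get("priority_table")
    if not isinstance(tbl, dict) or not tbl:
        errors.append("missing or empty 'priority_table' (class code -> score in [0, 1])")
    else:
        try:
            table = PriorityTable(tbl)
        except ValueError as e:
            errors.append(str(e))

    species = None
    sp = raw.get("species")
    if not isinstance(sp, dict):
        errors.append("missing 'species' section (home_range_radius, dispersal_threshold, min_native_fraction, native_classes, unsuitable_classes)")
    else:
        try:
            species = SpeciesProfile(
                home_range_radius=float(sp.get("home_range_radius", 0)),
                dispersal_threshold=float(sp.get("dispersal_threshold", 0)),
                min_native_fraction=float(sp.get("min_native_fraction", 0)),
                native_classes=frozenset(sp.get("native_classes", ())),
                unsuitable_classes=frozenset(sp.get("unsuitable_classes", ())),
            )
        except (TypeError, ValueError) as e:
            errors.append(f"species: {e}")

    weights = None
    fn = raw.get("function") or {}
    try:
        weights = FunctionWeights(
            alpha=float(fn.get("alpha", _default("function", "alpha", 0.5))),
            proximity_form=fn.get("proximity", _default("function", "proximity", "linear")),
        )
    except (TypeError, ValueError) as e:
        errors.append(f"function: {e} (alpha must lie in [0, 1]; proximity one of {PROXIMITY_FORMS})")

    rw = raw.get("rewilding") or {}
    normalization = rw.get("normalization", _default("rewilding", "normalization", "neighborhood-weight"))
    if normalization not in NORMALIZATIONS:
        errors.append(f"rewilding.normalization must be one of {NORMALIZATIONS}")

    un = raw.get("units") or {}
    rule = dict(un.get("attribute_rule", _default("units", "attribute_rule", {})))
    attribute_default = str(rule.pop("default", "default"))
    connectivity = un.get("connectivity", _default("units", "connectivity", 8))
    if connectivity not in (4, 8):
        errors.append("units.connectivity must be 4 or 8")
    min_cells = un.get("min_cells", _default("units", "min_cells", 1))
    if not isinstance(min_cells, int) or min_cells < 1:
        errors.append("units.min_cells must be a positive integer")
    aggregator = un.get("aggregator", _default("units", "aggregator", "mean"))
    if aggregator not in AGGREGATORS:
        errors.append(f"units.aggregator must be one of {AGGREGATORS}")

    output_dir = raw.get("output_dir", _default("root", "output_dir", "spore_out"))
    seed = raw.get("seed", _default("root", "seed", 0))
    tol = raw.get("fidelity_tolerance", _default("root", "fidelity_tolerance", 0.05))
    crs_id = raw.get("crs_id", "local-metric")
    try:
        _grid._ensure_metric_crs(crs_id)
    except GridError as e:
        errors.append(str(e))
    shape = tuple(raw.get("synthetic_shape", (300, 300)))

    if errors:
        raise ConfigError(errors)
    return SporeConfig(
        landcover=str(landcover),
        cell_size=float(cell_size),
        priority_table=table,
        species=species,
        weights=weights,
        normalization=normalization,
        attribute_rule=rule,
        attribute_default=attribute_default,
        connectivity=int(connectivity),
        min_cells=int(min_cells),
        aggregator=aggregator,
        output_dir=str(output_dir),
        seed=int(seed),
        fidelity_tolerance=float(tol),
        crs_id=crs_id,
        synthetic_shape=shape,
    )


def load_config(path) -> SporeConfig:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh))


def _load_landcover(config: SporeConfig):
    """Returns (grid, fidelity_report_or_None)."""
    src = config.landcover
    if src == "synthetic":
        grid, _, _ = guam_like_scenario(config.seed, shape=config.synthetic_shape)
        return grid, None
    if src.endswith((".tif", ".tiff")):
        return read_landcover_geotiff(src), None
    if src.endswith((".geojson", ".json")):
        polys = read_landcover_geojson(src)
        xs, ys, xe, ye = zip(*(g.bounds for _, g in polys))
        bounds = (min(xs), min(ys), max(xe), max(ye))
        grid = rasterize_landcover(polys, config.cell_size, bounds, crs_id=config.crs_id)
        report = check_rasterization_fidelity(polys, grid, config.fidelity_tolerance)
        if not report.passed:
            log.warning(
                "rasterization fidelity check failed at tolerance %.3g; "
                "consider a finer cell size", config.fidelity_tolerance
            )
        return grid, report
    raise ConfigError([f"unrecognized landcover source {src!r} (use .tif, .geojson or 'synthetic')"])


def _formula_strings(config: SporeConfig) -> dict:
    w = config.weights
    prox = "(1 - dstar/T)" if w.proximity_form == "linear" else "1.0"
    return {
        "priority": "P = priority_table[landcover_class] (0 if unlisted)",
        "suitability": (
            "S = 0 if landcover_class in unsuitable_classes or "
            "native_fraction(home_range_radius) < min_native_fraction else 1"
        ),
        "function": (
            f"FS = P * (alpha*D + (1 - alpha)*{prox}) if dstar <= T and P > 0 else 0.0; "
            f"alpha = {w.alpha}; T = dispersal_threshold = {config.species.dispersal_threshold}; "
            "D = native_fraction(T); dstar = distance_to_nearest_native"
        ),
        "rewilding": (
            "RS = sum_k FS(k)*w(d) / "
            + ("sum_k w(d)" if config.normalization == "neighborhood-weight" else "max_over_suitable(sum_k FS(k)*w(d))")
            + f" over in-bounds non-NoData k with d < R; w(d) = 1 - d/R; R = home_range_radius = {config.species.home_range_radius}"
        ),
    }


def _checksum(layer) -> str:
    return hashlib.sha256(np.ascontiguousarray(layer.values).tobytes()
                          + np.ascontiguousarray(layer.nodata_mask).tobytes()).hexdigest()


def run_pipeline(config: SporeConfig) -> RunManifest:
    """Execute the full scoring pipeline and write all outputs.

    Stage order: priority → suitability → function → rewilding → units.
    Deterministic: identical config + inputs give bit-identical rasters, CSV
    and GeoJSON. Logs per-stage cell counts. A landscape with no suitable
    cells yields an all-NoData rewilding layer and an empty unit list, with a
    warning rather than an error.
    """
    grid, fidelity = _load_landcover(config)
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    valid_n = int(grid.valid_mask.sum())
    log.info("landscape: %dx%d cells at %g m, %d valid", *grid.shape, grid.cell_size, valid_n)

    prio = priority_score(grid, config.priority_table)
    log.info("priority: %d cells with positive priority", int((prio.values > 0).sum()))

    suit = habitat_suitability(grid, config.species)
    n_suit = int((suit.values > 0).sum())
    log.info("suitability: %d suitable cells", n_suit)
    if n_suit == 0:
        log.warning("no suitable cells: rewilding layer will be all NoData and no units built")

    fs = function_score(grid, config.priority_table, config.species, config.weights)
    log.info("function: %d cells with positive function score", int((fs.values > 0).sum()))

    rs = rewilding_score(fs, suit, config.species, grid, normalization=config.normalization)
    n_pos = int(((rs.values > 0) & ~rs.nodata_mask).sum())
    log.info("rewilding: %d suitable cells with positive score", n_pos)

    attrs = derive_attribute_grid(grid, config.attribute_rule, default=config.attribute_default)
    units = score_and_rank(
        build_units(rs, attrs, connectivity=config.connectivity, min_cells=config.min_cells),
        rs,
        aggregator=config.aggregator,
    )
    log.info("units: %d management units", len(units))

    write_landcover_geotiff(os.path.join(out, "landcover.tif"), grid)
    for name, layer in (("priority", prio), ("suitability", suit), ("function", fs), ("rewilding", rs)):
        write_score_geotiff(os.path.join(out, f"{name}.tif"), layer)
    units_to_geojson(units, grid, path=os.path.join(out, "units.geojson"))
    ranking_table(units, path=os.path.join(out, "units.csv"))
    if fidelity is not None:
        with open(os.path.join(out, "fidelity.json"), "w") as fh:
            json.dump(dataclasses.asdict(fidelity) | {"missing_in_vector": sorted(fidelity.missing_in_vector)}, fh, indent=1)

    cfg_echo = dataclasses.asdict(config)
    cfg_echo["priority_table"] = dict(config.priority_table.entries)
    cfg_echo["species"] = {
        "home_range_radius": config.species.home_range_radius,
        "dispersal_threshold": config.species.dispersal_threshold,
        "min_native_fraction": config.species.min_native_fraction,
        "native_classes": sorted(config.species.native_classes),
        "unsuitable_classes": sorted(config.species.unsuitable_classes),
    }
    cfg_echo["weights"] = {"alpha": config.weights.alpha, "proximity_form": config.weights.proximity_form}
    manifest = RunManifest(
        config=cfg_echo,
        formulas=_formula_strings(config),
        checksums={
            "priority": _checksum(prio),
            "suitability": _checksum(suit),
            "function": _checksum(fs),
            "rewilding": _checksum(rs),
        },
        cell_counts={
            "valid": valid_n,
            "positive_priority": int((prio.values > 0).sum()),
            "suitable": n_suit,
            "positive_function": int((fs.values > 0).sum()),
            "positive_rewilding": n_pos,
        },
        unit_count=len(units),
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        versions={
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "shapely": shapely.__version__,
        },
    )
    manifest.write(os.path.join(out, "manifest.json"))
    return manifest
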