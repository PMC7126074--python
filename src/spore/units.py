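"""Management units: connected clusters of positive-rewilding-score cells.

Cells with a positive rewilding score are clustered into connected components
that share a management-relevant attribute (on Guam: the snake-control method,
bait tubes in developed areas vs toxicant drops elsewhere). Units never span
an attribute boundary. Each unit gets an aggregate score from its member
cells' rewilding values and a deterministic rank.

Aggregator choice matters: ``mean`` favours small intense units, ``sum``
favours large ones — pick to match the management question.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage

from .grid import GridError, LandcoverGrid, ScoreGrid

AGGREGATORS = ("mean", "sum")

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


@dataclass
class AttributeGrid:
    """Per-cell categorical management attribute, aligned to the landcover grid."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise GridError("labels must be 2-D")


@dataclass
class ManagementUnit:
    """One connected, attribute-homogeneous cluster of positive-score cells."""

    cell_indices: frozenset
    attribute: str
    area: float
    score: float = float("nan")
    rank: int = 0

    @property
    def n_cells(self) -> int:
        return len(self.cell_indices)

    @property
    def anchor(self) -> tuple[int, int]:
        """Topmost-leftmost member cell (row-major minimum) — the tie-break key."""
        return min(self.cell_indices)


def derive_attribute_grid(grid: LandcoverGrid, rule: dict, default: str = "none") -> AttributeGrid:
    """Map landcover classes to management labels (unmapped classes → default)."""
    labels = np.full(grid.shape, default, dtype=object)
    for code, label in rule.items():
        labels[grid.codes == int(code)] = str(label)
    return AttributeGrid(labels)


def build_units(
    rewilding: ScoreGrid,
    attributes: AttributeGrid,
    connectivity: int = 8,
    min_cells: int = 1,
    cell_size: float | None = None,
) -> list[ManagementUnit]:
    """Connected components of positive-score cells within each attribute label.

    Components smaller than ``min_cells`` are discarded. The empty list is a
    legal result (no positive cells).
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    if rewilding.shape != attributes.labels.shape:
        raise GridError("rewilding layer and attribute grid are not aligned")
    cell_size = rewilding.cell_size if cell_size is None else cell_size
    positive = (rewilding.values > 0) & ~rewilding.nodata_mask

    units: list[ManagementUnit] = []
    for label in sorted(np.unique(attributes.labels[positive]).tolist()):
        mask = positive & (attributes.labels == label)
        comp, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
        for i in range(1, n + 1):
            rows, cols = np.nonzero(comp == i)
            if rows.size < min_cells:
                continue
            cells = frozenset(zip(rows.tolist(), cols.tolist()))
            units.append(
                ManagementUnit(cells, str(label), area=rows.size * cell_size ** 2)
            )
    return units


def score_and_rank(
    units: list[ManagementUnit],
    rewilding: ScoreGrid,
    aggregator: str = "mean",
) -> list[ManagementUnit]:
    """Aggregate member-cell rewilding values and rank units.

    Ranks run 1..n in descending score; ties break deterministically by larger
    area first, then by the topmost-leftmost member cell.
    """
    if aggregator not in AGGREGATORS:
        raise ValueError(f"unknown aggregator {aggregator!r}; use one of {AGGREGATORS}")
    scored = []
    for u in units:
        rows, cols = zip(*u.cell_indices)
        vals = rewilding.values[np.array(rows), np.array(cols)]
        score = float(vals.mean() if aggregator == "mean" else vals.sum())
        scored.append(ManagementUnit(u.cell_indices, u.attribute, u.area, score))
    scored.sort(key=lambda u: (-u.score, -u.n_cells, u.anchor))
    return [
        ManagementUnit(u.cell_indices, u.attribute, u.area, u.score, rank)
        for rank, u in enumerate(scored, start=1)
    ]


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def _unit_polygon(unit: ManagementUnit, grid_like) -> shapely.Geometry:
    """Dissolve the unit's cell squares into one (multi)polygon."""
    ox, oy = grid_like.origin
    cs = grid_like.cell_size
    boxes = [
        shapely.box(ox + c * cs, oy - (r + 1) * cs, ox + (c + 1) * cs, oy - r * cs)
        for r, c in sorted(unit.cell_indices)
    ]
    return shapely.unary_union(boxes)


def units_to_geojson(units: list[ManagementUnit], grid_like, path=None) -> dict:
    """Write ranked units as a GeoJSON FeatureCollection of dissolved polygons."""
    features = []
    for u in sorted(units, key=lambda u: u.rank):
        geom = _unit_polygon(u, grid_like)
        features.append(
            {
                "type": "Feature",
                "geometry": json.loads(shapely.to_geojson(geom)),
                "properties": {
                    "unit_id": u.rank,
                    "attribute": u.attribute,
                    "n_cells": u.n_cells,
                    "area_m2": u.area,
                    "score": u.score,
                    "rank": u.rank,
                },
            }
        )
    doc = {"type": "FeatureCollection", "features": features}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)
    return doc


def ranking_table(units: list[ManagementUnit], path=None) -> pd.DataFrame:
    """Ranking table: unit_id, attribute, n_cells, area_m2, score, rank."""
    rows = [
        {
            "unit_id": u.rank,
            "attribute": u.attribute,
            "n_cells": u.n_cells,
            "area_m2": u.area,
            "score": u.score,
            "rank": u.rank,
        }
        for u in sorted(units, key=lambda u: u.rank)
    ]
    df = pd.DataFrame(rows, columns=["unit_id", "attribute", "n_cells", "area_m2", "score", "rank"])
    if path is not None:
        df.to_csv(path, index=False)
    return df
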