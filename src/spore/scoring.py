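"""The four score layers: priority, habitat suitability, function, rewilding.

The layers are composed in a fixed order. A per-cell *priority* score (expert
lookup on landcover class) says where functional restoration is needed.
*Habitat suitability* (binary) says where the function provider could persist.
The *function* score combines priority with the provider's spatial
constraints — seed-source density within the dispersal range and proximity to
the nearest intact-forest cell, with a hard cutoff past the dispersal
threshold. The *rewilding* score, assigned only to suitable cells, is the
distance-weighted aggregate of function scores inside the provider's home
range: the landscape-level benefit of putting an animal there.

Exact combination rules used here (echoed verbatim into run manifests):

``FS(c) = P(c) * (alpha * D(c) + (1 - alpha) * (1 - d*(c)/T))`` for cells with
``P > 0`` and ``d* <= T``, else 0 — where ``D`` is the intact-forest fraction
within the dispersal threshold ``T`` and ``d*`` the distance to the nearest
intact-forest cell. ``alpha`` balances density against proximity (default
0.5); a ``step`` proximity form (1 inside the threshold) is available.

``RS(c) = sum_k FS(k) * w(d(c,k)) / sum_k w(d(c,k))`` over in-bounds non-NoData
cells ``k`` with ``d(c,k) < R`` (home-range radius), ``w(d) = 1 - d/R``.
Normalizing by the neighborhood's own total weight keeps RS in [0, 1] and
comparable across landscapes; landscape-max normalization is the alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import (
    GridError,
    LandcoverGrid,
    ScoreGrid,
    distance_to_nearest,
    linear_weight_kernel,
    neighborhood_fraction,
)

PROXIMITY_FORMS = ("linear", "step")
NORMALIZATIONS = ("neighborhood-weight", "landscape-max")


@dataclass
class PriorityTable:
    """Landcover class → restoration priority in [0, 1]; unlisted classes score 0."""

    entries: dict[int, float]

    def __post_init__(self) -> None:
        self.entries = {int(k): float(v) for k, v in self.entries.items()}
        bad = {k: v for k, v in self.entries.items() if not 0.0 <= v <= 1.0}
        if bad:
            raise ValueError(f"priority scores must lie in [0, 1]: {bad}")

    def score(self, code: int) -> float:
        return self.entries.get(int(code), 0.0)


@dataclass
class SpeciesProfile:
    """Function-provider parameters.

    ``home_range_radius`` (m) bounds the rewilding aggregation and the
    suitability food-resource check; ``dispersal_threshold`` (m) bounds the
    function score. Neither ordering between the two is required.
    ``native_classes`` are the seed-source landcovers; ``unsuitable_classes``
    can never host the provider (no nesting substrate).
    """

    home_range_radius: float
    dispersal_threshold: float
    min_native_fraction: float
    native_classes: frozenset = frozenset()
    unsuitable_classes: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not self.home_range_radius > 0 or not self.dispersal_threshold > 0:
            raise ValueError("home_range_radius and dispersal_threshold must be > 0")
        if not 0.0 <= self.min_native_fraction <= 1.0:
            raise ValueError("min_native_fraction must lie in [0, 1]")
        self.native_classes = frozenset(int(c) for c in self.native_classes)
        self.unsuitable_classes = frozenset(int(c) for c in self.unsuitable_classes)


@dataclass
class FunctionWeights:
    """Weight ``alpha`` on the seed-source density term versus proximity."""

    alpha: float = 0.5
    proximity_form: str = "linear"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.proximity_form not in PROXIMITY_FORMS:
            raise ValueError(f"proximity_form must be one of {PROXIMITY_FORMS}")


def priority_score(grid: LandcoverGrid, table: PriorityTable) -> ScoreGrid:
    """Per-cell priority lookup; NoData cells stay NoData."""
    values = np.zeros(grid.shape, dtype=np.float64)
    for code, p in table.entries.items():
        values[grid.codes == code] = p
    values[~grid.valid_mask] = 0.0
    return ScoreGrid.like(grid, values, ~grid.valid_mask)


def habitat_suitability(grid: LandcoverGrid, profile: SpeciesProfile) -> ScoreGrid:
    """Binary suitability: 1 unless the landcover is unsuitable or the
    native-forest fraction within the home range falls below the floor."""
    frac = neighborhood_fraction(grid, profile.native_classes, profile.home_range_radius)
    unsuitable = grid.class_mask(profile.unsuitable_classes)
    suitable = grid.valid_mask & ~unsuitable & (frac.values >= profile.min_native_fraction)
    return ScoreGrid.like(grid, suitable.astype(np.float64), ~grid.valid_mask)


def function_score(
    grid: LandcoverGrid,
    table: PriorityTable,
    profile: SpeciesProfile,
    weights: FunctionWeights | None = None,
) -> ScoreGrid:
    """Where restoration of the function is possible and beneficial.

    Zero wherever priority is 0 or the nearest seed source lies beyond the
    dispersal threshold; otherwise priority times the convex density/proximity
    combination. Values in [0, 1].
    """
    weights = weights or FunctionWeights()
    T = profile.dispersal_threshold
    prio = priority_score(grid, table)
    dens = neighborhood_fraction(grid, profile.native_classes, T)
    dist = distance_to_nearest(grid, profile.native_classes)

    reachable = dist.values <= T
    if weights.proximity_form == "linear":
        prox = np.where(reachable, 1.0 - np.minimum(dist.values, T) / T, 0.0)
    else:
        prox = reachable.astype(np.float64)
    values = prio.values * (weights.alpha * dens.values + (1.0 - weights.alpha) * prox)
    values[~reachable] = 0.0
    values[prio.values == 0.0] = 0.0
    values[~grid.valid_mask] = 0.0
    return ScoreGrid.like(grid, values, ~grid.valid_mask)


def distance_weight(d, home_range_radius: float):
    """Linear visitation decay: 1 at the scored cell, 0 at the home-range edge."""
    if not home_range_radius > 0:
        raise ValueError("home_range_radius must be > 0")
    return np.maximum(0.0, 1.0 - np.asarray(d, dtype=np.float64) / home_range_radius)


def rewilding_score(
    function_layer: ScoreGrid,
    suitability_layer: ScoreGrid,
    profile: SpeciesProfile,
    grid: LandcoverGrid,
    normalization: str = "neighborhood-weight",
) -> ScoreGrid:
    """Distance-weighted aggregate of function scores within the home range.

    Only suitable cells receive a score; unsuitable (and NoData) cells are
    NoData in the output. Membership is strict ``d < R``; the weight reaches 0
    exactly at R, so the boundary convention cannot change the sum.
    """
    if function_layer.shape != grid.shape or suitability_layer.shape != grid.shape:
        raise GridError("function/suitability layers are not aligned to the grid")
    if normalization not in NORMALIZATIONS:
        raise ValueError(f"normalization must be one of {NORMALIZATIONS}")

    valid = grid.valid_mask
    fs = np.where(function_layer.nodata_mask, 0.0, function_layer.values)
    kernel = linear_weight_kernel(profile.home_range_radius, grid.cell_size)
    raw = ndimage.convolve(fs, kernel, mode="constant", cval=0.0)
    suitable = valid & (suitability_layer.values > 0) & ~suitability_layer.nodata_mask

    values = np.zeros(grid.shape, dtype=np.float64)
    if normalization == "neighborhood-weight":
        wsum = ndimage.convolve(valid.astype(np.float64), kernel, mode="constant", cval=0.0)
        ok = suitable & (wsum > 0)
        values[ok] = raw[ok] / wsum[ok]
    else:
        top = raw[suitable].max(initial=0.0)
        if top > 0:
            values[suitable] = raw[suitable] / top
    return ScoreGrid.like(grid, values, ~suitable)
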