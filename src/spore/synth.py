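"""Seeded synthetic landscapes: patchy categorical rasters for desk-scale runs.

Patches are produced by multi-source region growing: each class places a few
seeds uniformly at random, then classes grow cell by cell from their
frontiers, with growth effort proportional to each class's remaining area
quota. The ``patch_cohesion`` parameter biases frontier selection toward
candidates with many same-class neighbours (high cohesion → compact blobs,
low cohesion → ragged dendritic patches). A class whose frontier gets walled
in re-seeds at a fresh unassigned cell, so area quotas are met exactly while
unassigned cells remain. Everything is driven by one seeded generator stream
per scenario, so results are bit-reproducible under a seed.

:func:`guam_like_scenario` assembles a small island in this style — water and
a sand margin around a vegetated interior with intact limestone-forest
patches, a degraded-forest matrix, Leucaena thicket, a developed block and
grassland — together with the matching priority table and species profile
for a frugivorous-bird seed-dispersal case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .grid import LandcoverGrid
from .scoring import PriorityTable, SpeciesProfile

# Class codes used by the island scenario.
WATER, INTACT, DEGRADED, THICKET, DEVELOPED, GRASSLAND, SAND = 0, 1, 2, 3, 4, 5, 6

GUAM_CLASS_NAMES = {
    WATER: "open_water",
    INTACT: "intact_limestone_forest",
    DEGRADED: "degraded_limestone_forest",
    THICKET: "leucaena_thicket",
    DEVELOPED: "developed",
    GRASSLAND: "grassland",
    SAND: "sand",
}

_NEIGHBORS4 = ((-1, 0), (1, 0), (0, -1), (0, 1))


@dataclass
class ScenarioSpec:
    """Recipe for one synthetic landscape.

    ``class_fractions`` are target cell fractions (sum ≤ 1; the remainder is
    filled with ``background_class``). With ``coastline`` set, the grid is
    wrapped in a water margin with a sand ring at the shore, and the fractions
    apply to the island interior.
    """

    shape: tuple[int, int]
    cell_size: float = 30.0
    class_fractions: dict[int, float] = field(default_factory=dict)
    patch_cohesion: float = 0.85
    seed: int = 0
    coastline: bool = False
    background_class: int = GRASSLAND
    origin: tuple[float, float] = (0.0, 0.0)
    crs_id: str = "local-metric"

    def __post_init__(self) -> None:
        if any(f < 0 for f in self.class_fractions.values()):
            raise ValueError("class fractions must be non-negative")
        if sum(self.class_fractions.values()) > 1.0 + 1e-9:
            raise ValueError("class fractions sum to more than 1")
        if not 0.0 <= self.patch_cohesion <= 1.0:
            raise ValueError("patch_cohesion must lie in [0, 1]")


def _island_mask(shape, rng) -> np.ndarray:
    """Ellipse with low-frequency radial noise: a plausible island outline."""
    rows, cols = shape
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    ry, rx = rows * 0.42, cols * 0.42
    phases = rng.uniform(0, 2 * math.pi, size=4)
    amps = rng.uniform(0.03, 0.08, size=4)
    yy, xx = np.mgrid[0:rows, 0:cols]
    theta = np.arctan2(yy - cy, xx - cx)
    wobble = sum(a * np.cos((k + 2) * theta + p) for k, (a, p) in enumerate(zip(amps, phases)))
    rad = np.hypot((yy - cy) / ry, (xx - cx) / rx)
    return rad <= 1.0 + wobble


def _grow_classes(assigned, quotas, cohesion, rng, mean_patch_cells=400):
    """Multi-source region growing over the unassigned (-2) cells of ``assigned``."""
    rows, cols = assigned.shape
    frontiers: dict[int, list] = {}
    remaining = {c: int(q) for c, q in quotas.items() if q > 0}

    def unassigned_cells():
        r, c = np.nonzero(assigned == -2)
        return list(zip(r.tolist(), c.tolist()))

    def seed_class(cls):
        pool = unassigned_cells()
        if not pool:
            return False
        r, c = pool[rng.integers(len(pool))]
        assigned[r, c] = cls
        remaining[cls] -= 1
        frontiers.setdefault(cls, [])
        _push_neighbors(cls, r, c)
        return True

    def _push_neighbors(cls, r, c):
        for dr, dc in _NEIGHBORS4:
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols and assigned[rr, cc] == -2:
                frontiers[cls].append((rr, cc))

    # initial seeds: one shared pool snapshot, sampled without replacement
    pool = unassigned_cells()
    if pool and remaining:
        want = {c: min(max(1, round(q / mean_patch_cells)), q) for c, q in remaining.items()}
        n_want = min(sum(want.values()), len(pool))
        picks = rng.choice(len(pool), size=n_want, replace=False)
        it = iter(picks.tolist())
        for cls in sorted(want):
            frontiers.setdefault(cls, [])
            for _ in range(want[cls]):
                i = next(it, None)
                if i is None:
                    break
                r, c = pool[i]
                if assigned[r, c] != -2:
                    continue
                assigned[r, c] = cls
                remaining[cls] -= 1
                _push_neighbors(cls, r, c)

    active = [c for c, q in remaining.items() if q > 0]
    while active:
        weights = np.array([remaining[c] for c in active], dtype=float)
        cls = active[rng.choice(len(active), p=weights / weights.sum())]
        placed = False
        frontier = frontiers.get(cls, [])
        while frontier:
            if rng.random() < cohesion and len(frontier) > 1:
                # pick, from a small random sample, the candidate hugging the
                # most same-class neighbours — compact growth
                sample = rng.choice(len(frontier), size=min(8, len(frontier)), replace=False)
                best, best_n = None, -1
                for si in sample:
                    r, c = frontier[si]
                    if assigned[r, c] != -2:
                        continue
                    n_same = sum(
                        1
                        for dr, dc in _NEIGHBORS4
                        if 0 <= r + dr < rows and 0 <= c + dc < cols and assigned[r + dr, c + dc] == cls
                    )
                    if n_same > best_n:
                        best, best_n = si, n_same
                idx = best if best is not None else len(frontier) - 1
            else:
                idx = int(rng.integers(len(frontier)))
            r, c = frontier[idx]
            frontier[idx] = frontier[-1]
            frontier.pop()
            if assigned[r, c] != -2:
                continue
            assigned[r, c] = cls
            remaining[cls] -= 1
            _push_neighbors(cls, r, c)
            placed = True
            break
        if not placed and not seed_class(cls):
            remaining[cls] = 0  # landscape full
        active = [c for c, q in remaining.items() if q > 0]
    return assigned


def generate_landscape(spec: ScenarioSpec) -> LandcoverGrid:
    """Generate one categorical landscape, deterministic under ``spec.seed``.

    Realized per-class fractions match the targets up to quota rounding (the
    grower re-seeds blocked classes), comfortably within ±20% relative for any
    class with a target fraction of at least 0.05.
    """
    rows, cols = spec.shape
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0x5B02E]))
    assigned = np.full((rows, cols), -2, dtype=np.int64)

    if spec.coastline:
        island = _island_mask(spec.shape, rng)
        assigned[~island] = WATER
        from scipy import ndimage as _ndi

        shore = island & ~_ndi.binary_erosion(island, iterations=2)
        assigned[shore] = SAND
    interior = int((assigned == -2).sum())

    quotas = {int(c): int(round(f * interior)) for c, f in spec.class_fractions.items()}
    total = sum(quotas.values())
    if total > interior:  # rounding pushed past capacity
        largest = max(quotas, key=quotas.get)
        quotas[largest] -= total - interior
    _grow_classes(assigned, quotas, spec.patch_cohesion, rng)
    assigned[assigned == -2] = spec.background_class
    return LandcoverGrid(
        assigned.astype(np.int32),
        spec.cell_size,
        origin=spec.origin,
        crs_id=spec.crs_id,
        class_names=dict(GUAM_CLASS_NAMES),
    )


def guam_like_scenario(seed: int, shape: tuple[int, int] = (300, 300)):
    """A small island scenario with the published parameter set.

    Returns ``(grid, priority_table, species_profile)``: a ~300×300 raster at
    30 m cells (water margin, sand shore, intact-forest patches, degraded
    matrix, thicket, a developed block, grassland), the priority table
    {intact 1.0, degraded 0.8, thicket 0.6}, and the frugivore profile
    (home range 1083 m, dispersal threshold 500 m, ≥10% native forest,
    water/sand unsuitable). At least one intact-forest patch of ≥50
    contiguous cells is always present.
    """
    spec = ScenarioSpec(
        shape=shape,
        cell_size=30.0,
        class_fractions={
            INTACT: 0.14,
            DEGRADED: 0.42,
            THICKET: 0.14,
            DEVELOPED: 0.06,
        },
        patch_cohesion=0.85,
        seed=seed,
        coastline=True,
        background_class=GRASSLAND,
    )
    grid = generate_landscape(spec)

    # Guarantee a compact intact-forest core patch (>= 50 contiguous cells):
    # stamp a disk of radius 4.5 cells at a seeded interior position.
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0DE]))
    rows, cols = grid.shape
    land = ~np.isin(grid.codes, [WATER, SAND])
    r0 = rows // 2 + int(rng.integers(-rows // 8, rows // 8 + 1))
    c0 = cols // 2 + int(rng.integers(-cols // 8, cols // 8 + 1))
    yy, xx = np.mgrid[0:rows, 0:cols]
    disk = (np.hypot(yy - r0, xx - c0) <= 4.5) & land
    grid.codes[disk] = INTACT

    table = PriorityTable({INTACT: 1.0, DEGRADED: 0.8, THICKET: 0.6})
    profile = SpeciesProfile(
        home_range_radius=1083.0,
        dispersal_threshold=500.0,
        min_native_fraction=0.10,
        native_classes=frozenset({INTACT}),
        unsuitable_classes=frozenset({WATER, SAND}),
    )
    return grid, table, profile
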