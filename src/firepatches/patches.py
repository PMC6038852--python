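"""Aggregate burned pixels into fire patches.

A fire patch is a set of burned pixels that is spatially connected under
queen (8-neighbour) adjacency and temporally coherent: two adjacent pixels
belong to the same patch when the absolute difference of their burn dates
is at most the cut-off (days). Patch membership is the transitive closure
of this pairwise rule — a patch may span a date range much longer than the
cut-off as long as every link in the chain respects it (single-linkage
clustering on the pixel adjacency graph).

``flood_fill_patches`` is the production implementation (vectorized
connected components on a sparse adjacency graph); ``brute_force_patches``
is an independent breadth-first-search reference used to cross-check it.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .raster_io import BurnDateRaster

DEFAULT_CUTOFFS = (3, 5, 9, 14)

# queen neighbourhood, forward half (each undirected edge built once)
_FORWARD_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))
_ALL_OFFSETS = tuple(
    (dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)
)


@dataclass
class FirePatch:
    """One reconstructed fire event.

    ``pixels`` is an (n, 3) integer array of (row, col, burn_date) records,
    sorted row-major. Pixel coordinates refer to the raster the patch was
    built from.
    """

    patch_id: str
    pixels: np.ndarray
    cutoff_days: int

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.int64).reshape(-1, 3)
        if len(self.pixels) == 0:
            raise ValueError("a patch must contain at least one pixel")

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)

    @property
    def rows(self) -> np.ndarray:
        return self.pixels[:, 0]

    @property
    def cols(self) -> np.ndarray:
        return self.pixels[:, 1]

    @property
    def dates(self) -> np.ndarray:
        return self.pixels[:, 2]

    def mask(self) -> tuple[np.ndarray, tuple[int, int]]:
        """Boolean footprint on the patch's bounding box.

        Returns (mask, (row_offset, col_offset)) so that raster pixel
        (r, c) maps to mask[r - row_offset, c - col_offset].
        """
        r0, c0 = self.rows.min(), self.cols.min()
        m = np.zeros(
            (self.rows.max() - r0 + 1, self.cols.max() - c0 + 1), dtype=bool
        )
        m[self.rows - r0, self.cols - c0] = True
        return m, (int(r0), int(c0))

    def key_pixel(self) -> tuple[int, int]:
        """Row-major first pixel; defines deterministic patch ordering."""
        order = np.lexsort((self.dates, self.cols, self.rows))
        first = self.pixels[order[0]]
        return int(first[0]), int(first[1])


def _as_values(raster) -> np.ndarray:
    values = raster.values if isinstance(raster, BurnDateRaster) else np.asarray(raster)
    if not np.issubdtype(values.dtype, np.integer):
        raise TypeError("burn dates must be integers")
    return values


def _make_id(survey: str, cutoff: int, tile: str, serial: int) -> str:
    return f"{survey}_co{cutoff}_{tile}_{serial:06d}"


def _patches_from_labels(values, labels_flat, burned_idx, cutoff_days,
                         survey, tile) -> list[FirePatch]:
    """Order components deterministically and wrap them as FirePatch."""
    ncols = values.shape[1]
    rows = burned_idx // ncols
    cols = burned_idx % ncols
    dates = values.ravel()[burned_idx]
    order = np.argsort(labels_flat, kind="stable")  # burned_idx is row-major
    bounds = np.flatnonzero(np.diff(labels_flat[order])) + 1
    groups = np.split(order, bounds)
    # components sorted by their first (row-major) pixel: since burned_idx is
    # already row-major sorted, the first element of each group is minimal
    groups.sort(key=lambda g: burned_idx[g[0]])
    patches = []
    for serial, g in enumerate(groups):
        pixels = np.column_stack((rows[g], cols[g], dates[g]))
        patches.append(
            FirePatch(_make_id(survey, cutoff_days, tile, serial), pixels, cutoff_days)
        )
    return patches


def flood_fill_patches(raster, cutoff_days: int, survey: str = "SYN",
                       tile: str = "t0") -> list[FirePatch]:
    """Partition burned pixels into fire patches.

    Patches are the connected components of the graph whose vertices are
    burned pixels (date > 0) and whose edges join queen-adjacent pixels
    with ``|date_a - date_b| <= cutoff_days``. Unburned and unmapped pixels
    break connectivity. Output order (and hence patch ids) is
    deterministic: patches sorted by their first pixel in row-major order.
    """
    if cutoff_days < 1:
        raise ValueError("cutoff_days must be >= 1")
    values = _as_values(raster)
    burned = values > 0
    n_burned = int(burned.sum())
    if n_burned == 0:
        return []
    node = np.full(values.shape, -1, dtype=np.int64)
    burned_idx = np.flatnonzero(burned.ravel())
    node.ravel()[burned_idx] = np.arange(n_burned)

    edges_i, edges_j = [], []
    for dr, dc in _FORWARD_OFFSETS:
        a = values[max(0, -dr):values.shape[0] - max(0, dr),
                   max(0, -dc):values.shape[1] - max(0, dc)]
        b = values[max(0, dr):values.shape[0] + min(0, dr) or None,
                   max(0, dc):values.shape[1] + min(0, dc) or None]
        ok = (a > 0) & (b > 0) & (np.abs(a.astype(np.int64) - b) <= cutoff_days)
        na = node[max(0, -dr):values.shape[0] - max(0, dr),
                  max(0, -dc):values.shape[1] - max(0, dc)][ok]
        nb = node[max(0, dr):values.shape[0] + min(0, dr) or None,
                  max(0, dc):values.shape[1] + min(0, dc) or None][ok]
        edges_i.append(na)
        edges_j.append(nb)
    i = np.concatenate(edges_i) if edges_i else np.empty(0, dtype=np.int64)
    j = np.concatenate(edges_j) if edges_j else np.empty(0, dtype=np.int64)
    graph = coo_matrix(
        (np.ones(len(i), dtype=np.int8), (i, j)), shape=(n_burned, n_burned)
    )
    _, labels = connected_components(graph, directed=False)
    return _patches_from_labels(values, labels, burned_idx, cutoff_days, survey, tile)


def brute_force_patches(raster, cutoff_days: int, survey: str = "SYN",
                        tile: str = "t0") -> list[FirePatch]:
    """Reference implementation: explicit BFS over the pixel graph.

    Independent of :func:`flood_fill_patches` (pure-Python adjacency walk);
    intended for small rasters and equivalence testing.
    """
    if cutoff_days < 1:
        raise ValueError("cutoff_days must be >= 1")
    values = _as_values(raster)
    nrows, ncols = values.shape
    burned = [(r, c) for r in range(nrows) for c in range(ncols) if values[r, c] > 0]
    seen = set()
    components = []
    for start in burned:  # row-major: components emerge in required order
        if start in seen:
            continue
        comp = []
        queue = [start]
        seen.add(start)
        while queue:
            r, c = queue.pop()
            comp.append((r, c, int(values[r, c])))
            for dr, dc in _ALL_OFFSETS:
                rr, cc = r + dr, c + dc
                if not (0 <= rr < nrows and 0 <= cc < ncols):
                    continue
                if (rr, cc) in seen or values[rr, cc] <= 0:
                    continue
                if abs(int(values[r, c]) - int(values[rr, cc])) <= cutoff_days:
                    seen.add((rr, cc))
                    queue.append((rr, cc))
        comp.sort()
        components.append(comp)
    return [
        FirePatch(_make_id(survey, cutoff_days, tile, serial), np.array(comp),
                  cutoff_days)
        for serial, comp in enumerate(components)
    ]


def filter_patches(patches: list[FirePatch], min_pixels: int = 5,
                   min_area_ha: float = 0.0,
                   raster: BurnDateRaster | None = None) -> list[FirePatch]:
    """Drop patches below the pixel-count and/or area thresholds.

    ``min_area_ha > 0`` requires ``raster`` for the georeferencing needed
    to evaluate pixel areas. Order is preserved.
    """
    if min_pixels < 1:
        raise ValueError("min_pixels must be >= 1")
    kept = [p for p in patches if p.n_pixels >= min_pixels]
    if min_area_ha > 0:
        if raster is None:
            raise ValueError("min_area_ha filtering requires the source raster")
        from .traits import areas  # local import avoids a cycle

        kept = [p for p in kept if areas(p, raster)[0] >= min_area_ha]
    return kept


def mean_burn_month(patch: FirePatch, year: int) -> int:
    """Calendar month containing the patch's mean burn date (day of year)."""
    mean_day = float(np.mean(patch.dates))
    day = min(max(int(np.ceil(mean_day)), 1), 366 if calendar.isleap(year) else 365)
    cum = 0
    for month in range(1, 13):
        cum += calendar.monthrange(year, month)[1]
        if day <= cum:
            return month
    return 12


def monthly_grouping(patches: list[FirePatch], year: int) -> list[tuple[FirePatch, int]]:
    """Annotate each patch with its output month.

    Patches are built on the full date axis first and then assigned to the
    calendar month of their mean burn date; a patch straddling a month
    boundary stays whole. Re-burns of the same cell at dates further apart
    than the cut-off are distinct patches and may land in distinct months.
    """
    return [(p, mean_burn_month(p, year)) for p in patches]
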