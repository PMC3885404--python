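"""Canopy-height segmentation into vegetation polygons.

The canopy-height model is partitioned into connected regions whose
internal height range stays within a scale parameter (metres).  Regions
are built by deterministic cheapest-first merging: starting from
single-cell regions, the adjacent pair whose union has the smallest
height range is merged first, and merging stops once the cheapest
remaining union would exceed the scale.  Executed merge costs are
nondecreasing, so the merge sequence at a smaller scale is a prefix of
the sequence at a larger one — increasing the scale can only coarsen the
partition.  Two scale levels are typically used: a "local" scale
resolving individual crowns and a larger "vegetation" scale for stands.

Each polygon is labelled with the structural class covering the largest
share of its cells; polygons without any above-ground returns are flagged
bare, and — where an RGB brightness raster and per-site thresholds are
available — bare polygons whose brightness relative to their enclosing
vegetation-scale polygon falls between the thresholds are flagged as
moss-mats (cryptogam mats on granite are darker than clean rock in the
wetter areas).
"""

from __future__ import annotations

import heapq
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import box, mapping
from shapely.ops import unary_union

from .grids import GridSpec, HeightRaster
from .classify import UNCLASSIFIED


@dataclass
class VegPolygon:
    """A segmented region of the canopy-height raster.

    ``cells`` is an (n, 2) array of (row, col) indices on ``grid``.
    Heights in metres, cover in percent, ``pds`` a probability.
    """

    polygon_id: int
    grid: GridSpec
    cells: np.ndarray
    mean_ch: float = 0.0
    mean_gc: float = 0.0
    class_id: int = UNCLASSIFIED
    bare: bool = False
    mossmat: bool = False
    pds: float = float("nan")
    rainfall: float = float("nan")
    elev_range: float = float("nan")
    _geometry: object = field(default=None, repr=False, compare=False)

    @property
    def area(self) -> float:
        return len(self.cells) * self.grid.cell_area

    @property
    def geometry(self):
        """Shapely polygon following cell boundaries (built lazily)."""
        if self._geometry is None:
            s = self.grid.cell_size
            boxes = [
                box(
                    self.grid.x0 + c * s,
                    self.grid.y0 + r * s,
                    self.grid.x0 + (c + 1) * s,
                    self.grid.y0 + (r + 1) * s,
                )
                for r, c in self.cells
            ]
            self._geometry = unary_union(boxes)
        return self._geometry


class _UnionFind:
    def __init__(self, n: int):
        self.parent = np.arange(n)

    def find(self, a: int) -> int:
        root = a
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[a] != root:
            self.parent[a], a = root, self.parent[a]
        return root

    def union(self, a: int, b: int) -> int:
        ra, rb = self.find(a), self.find(b)
        if ra > rb:
            ra, rb = rb, ra
        self.parent[rb] = ra
        return ra


def segment(chm: HeightRaster, scale: float) -> np.ndarray:
    """Partition a canopy-height raster into height-homogeneous regions.

    Returns an integer label raster shaped like ``chm.values``; every
    finite cell belongs to exactly one region and each region's height
    range (max - min) is at most ``scale``.
    """
    if scale < 0:
        raise ValueError("scale must be >= 0")
    values = np.asarray(chm.values, dtype=float)
    nrows, ncols = values.shape
    n = nrows * ncols
    flat = values.ravel()
    uf = _UnionFind(n)
    lo = flat.copy()
    hi = flat.copy()

    # 4-neighbour edges, cost = range of the union
    heap = []
    for r in range(nrows):
        base = r * ncols
        for c in range(ncols):
            a = base + c
            if c + 1 < ncols:
                b = a + 1
                cost = max(flat[a], flat[b]) - min(flat[a], flat[b])
                heap.append((cost, a, b))
            if r + 1 < nrows:
                b = a + ncols
                cost = max(flat[a], flat[b]) - min(flat[a], flat[b])
                heap.append((cost, a, b))
    heapq.heapify(heap)
    while heap:
        cost, a, b = heapq.heappop(heap)
        ra, rb = uf.find(a), uf.find(b)
        if ra == rb:
            continue
        true_cost = max(hi[ra], hi[rb]) - min(lo[ra], lo[rb])
        if true_cost > cost:  # stale entry: re-queue with the current cost
            if true_cost <= scale:
                heapq.heappush(heap, (true_cost, ra, rb))
            continue
        if cost > scale:
            break
        root = uf.union(ra, rb)
        lo[root] = min(lo[ra], lo[rb])
        hi[root] = max(hi[ra], hi[rb])

    labels = np.empty(n, dtype=np.int64)
    roots = {}
    for idx in range(n):
        r = uf.find(idx)
        labels[idx] = roots.setdefault(r, len(roots))
    return labels.reshape(nrows, ncols)


def polygons_from_labels(labels: np.ndarray, grid: GridSpec) -> list[VegPolygon]:
    """Materialize one VegPolygon per region label."""
    labels = np.asarray(labels)
    order = np.argsort(labels.ravel(), kind="stable")
    sorted_labels = labels.ravel()[order]
    boundaries = np.flatnonzero(np.diff(sorted_labels)) + 1
    groups = np.split(order, boundaries)
    ncols = labels.shape[1]
    polys = []
    for pid, flat_idx in enumerate(groups):
        rows = flat_idx // ncols
        cols = flat_idx % ncols
        polys.append(VegPolygon(polygon_id=pid, grid=grid, cells=np.c_[rows, cols]))
    return polys


def attach_polygon_stats(polys: list[VegPolygon], chm: HeightRaster, cover: np.ndarray) -> None:
    """Fill mean canopy height / ground cover and the bare flag.

    ``cover`` is a per-cell percent-cover raster co-registered with the
    canopy-height model; a polygon is bare when none of its cells has an
    above-ground return (cover 0 and height 0 everywhere).
    """
    for p in polys:
        r, c = p.cells[:, 0], p.cells[:, 1]
        heights = chm.values[r, c]
        covers = np.asarray(cover)[r, c]
        p.mean_ch = float(np.mean(heights))
        p.mean_gc = float(np.mean(covers))
        p.bare = bool((heights <= 0).all() and (covers <= 0).all())


def assign_polygon_class(
    poly: VegPolygon, class_raster: np.ndarray
) -> int:
    """Label a polygon with the modal class over its cells.

    Ties go to the smallest class id; a polygon whose cells are all
    unclassified gets the bare flag.
    """
    r, c = poly.cells[:, 0], poly.cells[:, 1]
    cls = np.asarray(class_raster)[r, c]
    cls = cls[cls != UNCLASSIFIED]
    if len(cls) == 0:
        poly.bare = True
        poly.class_id = UNCLASSIFIED
        return UNCLASSIFIED
    ids, counts = np.unique(cls, return_counts=True)  # unique sorts ids ascending
    poly.class_id = int(ids[np.argmax(counts)])  # argmax takes first max -> smallest id
    return poly.class_id


def mossmat_assign(
    bare_polys: list[VegPolygon],
    veg_polys: list[VegPolygon],
    brightness: np.ndarray | None,
    thresholds: tuple[float, float] | None,
) -> None:
    """Flag bare polygons as moss-mat by relative RGB brightness.

    A bare polygon's mean brightness is compared to the mean brightness of
    the enclosing vegetation-scale polygon (largest cell overlap); if the
    ratio lies within ``thresholds = (lo, hi)`` the polygon is flagged
    moss-mat, otherwise it stays bare rock.  With no brightness raster or
    no thresholds the step is skipped with a warning (the drier sites are
    left unresolved, mirroring summer imagery where mats do not contrast).
    """
    if brightness is None or thresholds is None:
        warnings.warn(
            "no brightness raster/thresholds configured; bare polygons left as bare rock",
            stacklevel=2,
        )
        return
    lo, hi = thresholds
    bright = np.asarray(brightness, dtype=float)
    # map each cell to its vegetation-scale polygon id
    shape = bright.shape
    owner = np.full(shape, -1, dtype=int)
    veg_mean = {}
    for vp in veg_polys:
        owner[vp.cells[:, 0], vp.cells[:, 1]] = vp.polygon_id
        veg_mean[vp.polygon_id] = float(bright[vp.cells[:, 0], vp.cells[:, 1]].mean())
    for p in bare_polys:
        if not p.bare:
            continue
        r, c = p.cells[:, 0], p.cells[:, 1]
        own = owner[r, c]
        own = own[own >= 0]
        if len(own) == 0:
            continue
        enclosing = np.bincount(own).argmax()
        ref = veg_mean[int(enclosing)]
        if ref <= 0:
            continue
        rel = float(bright[r, c].mean()) / ref
        p.mossmat = bool(lo <= rel <= hi)


def polygons_to_geojson(polys: list[VegPolygon], path: str | Path, extra: dict | None = None) -> None:
    """Write polygons as a GeoJSON FeatureCollection."""
    feats = []
    for p in polys:
        props = {
            "polygon_id": p.polygon_id,
            "class_id": int(p.class_id),
            "mean_ch": p.mean_ch,
            "mean_gc": p.mean_gc,
            "bare": p.bare,
            "mossmat": p.mossmat,
            "area_m2": p.area,
        }
        for key in ("pds", "rainfall", "elev_range"):
            val = getattr(p, key)
            if np.isfinite(val):
                props[key] = val
        if extra and p.polygon_id in extra:
            props.update(extra[p.polygon_id])
        feats.append(
            {"type": "Feature", "geometry": mapping(p.geometry), "properties": props}
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": feats})
    )
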