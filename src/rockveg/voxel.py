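"""Voxel occupancy, vertical PVF profiles and canopy-layer attributes.

Vegetation presence is recorded in voxels — one processing-grid cell
footprint (default 4x4 m) by 1 m height bin, bin ``h`` covering heights
``[h, h+1)`` m up to a configurable ceiling (80 m).  Presence/absence is
deliberately used instead of return fractions because it is insensitive
to point-density variation across a flight.  The percentage of filled
voxels (PVF) at each height bin is computed in a horizontal window
(default 3x3 cells, i.e. 12x12 m at 4 m cells), giving each cell a
vertical PVF profile.  Profiles are smoothed vertically with a small
Gaussian kernel (0.27, 0.46, 0.27); runs of bins at or above a 20%
threshold (2 of 9 window voxels) delimit vegetation layers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import convolve

from .grids import GridSpec

GAUSS_WEIGHTS = np.array([0.27, 0.46, 0.27])
DEFAULT_MAX_HEIGHT = 80
LAYER_THRESHOLD = 20.0

#: Default edges of the 18 sampling intervals covering 1–80 m; widths grow
#: from 1 m near the ground to 20 m at the top ([1,2), [2,3), ... [60,80]).
DEFAULT_INTERVAL_EDGES = np.array(
    [1, 2, 3, 4, 5, 6, 7, 8, 10, 12, 15, 18, 22, 26, 30, 36, 45, 60, 80]
)

#: Height bands for return-fraction cover: low, medium, high, top canopy.
BAND_EDGES = (0.0, 1.0, 3.0, 10.0, np.inf)
BAND_NAMES = ("low", "medium", "high", "top")


@dataclass
class CanopyLayer:
    """One detected vegetation layer in a PVF profile (heights in m)."""

    bottom: float
    top: float
    mean_coverage: float
    mean_intensity: float = float("nan")

    @property
    def thickness(self) -> float:
        return self.top - self.bottom


def voxelize(
    points: pd.DataFrame,
    grid: GridSpec,
    max_height: int = DEFAULT_MAX_HEIGHT,
) -> np.ndarray:
    """Boolean occupancy array shaped ``(max_height, nrows, ncols)``.

    A voxel is filled iff at least one non-ground return with normalized
    height in ``[h, h+1)`` falls in the cell.  Heights at or above the
    ceiling are clipped into the top bin with a warning.
    """
    occ = np.zeros((max_height, grid.nrows, grid.ncols), dtype=bool)
    veg = points.loc[~points["is_ground"] & (points["height"] > 0)]
    if len(veg) == 0:
        return occ
    i, j = grid.cell_index(veg["x"].to_numpy(), veg["y"].to_numpy())
    h = np.floor(veg["height"].to_numpy()).astype(int)
    n_clip = int((h >= max_height).sum())
    if n_clip:
        warnings.warn(
            f"clipped {n_clip} return(s) above {max_height} m into the top bin",
            stacklevel=2,
        )
        h = np.minimum(h, max_height - 1)
    ok = (i >= 0) & (i < grid.ncols) & (j >= 0) & (j < grid.nrows)
    occ[h[ok], j[ok], i[ok]] = True
    return occ


def compute_pvf(occupancy: np.ndarray, window: int = 3) -> np.ndarray:
    """Percent filled voxels per bin in a ``window x window`` cell window.

    ``pvf[h, j, i] = 100 * filled / available`` where *available* counts
    the window voxels actually inside the grid — edge and corner cells use
    their truncated sub-window with its own denominator.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    kernel = np.ones((1, window, window))
    filled = convolve(occupancy.astype(float), kernel, mode="constant", cval=0.0)
    avail = convolve(np.ones_like(occupancy, dtype=float), kernel, mode="constant", cval=0.0)
    return 100.0 * filled / avail


def smooth_profile(pvf: np.ndarray, axis: int = 0) -> np.ndarray:
    """Vertical Gaussian smoothing with weights (0.27, 0.46, 0.27).

    Boundary bins use the truncated kernel renormalized to sum 1, so a
    constant profile is preserved exactly.
    """
    from scipy.ndimage import convolve1d

    pvf = np.asarray(pvf, dtype=float)
    w = GAUSS_WEIGHTS
    num = convolve1d(pvf, w, axis=axis, mode="constant", cval=0.0)
    den = convolve1d(np.ones(pvf.shape[axis]), w, mode="constant", cval=0.0)
    if pvf.ndim > 1:
        shape = [1] * pvf.ndim
        shape[axis] = -1
        den = den.reshape(shape)
    return num / den


def detect_layers(
    profile: np.ndarray, threshold: float = LAYER_THRESHOLD
) -> list[CanopyLayer]:
    """Vegetation layers as maximal runs of bins with PVF >= threshold.

    Bin ``h`` spans heights ``[h, h+1)`` m, so a run over bins ``a..b``
    becomes a layer with ``bottom=a``, ``top=b+1``.  Layers are reported
    top-down: layer 1 is the uppermost, and its top is the cell's canopy
    height.
    """
    profile = np.asarray(profile, dtype=float)
    above = profile >= threshold
    if not above.any():
        return []
    edges = np.diff(np.concatenate(([0], above.astype(int), [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)  # exclusive
    layers = [
        CanopyLayer(
            bottom=float(a),
            top=float(b),
            mean_coverage=float(profile[a:b].mean()),
        )
        for a, b in zip(starts, ends)
    ]
    return layers[::-1]


def canopy_height(profile: np.ndarray, threshold: float = LAYER_THRESHOLD) -> float:
    """Top of the uppermost detected layer, or 0 with no vegetation."""
    layers = detect_layers(profile, threshold)
    return layers[0].top if layers else 0.0


def sample_profile(profile: np.ndarray, edges: np.ndarray = DEFAULT_INTERVAL_EDGES) -> np.ndarray:
    """Aggregate a 1 m-bin profile over the sampling intervals.

    Each entry is the arithmetic mean PVF over the interval's bins; the
    default table has 18 contiguous intervals covering [1, 80) m with
    widths nondecreasing from 1 to 20 m.
    """
    edges = np.asarray(edges)
    widths = np.diff(edges)
    if (widths <= 0).any() or (np.diff(widths) < 0).any():
        raise ValueError("interval edges must be increasing with nondecreasing widths")
    if edges[-1] > len(profile):
        raise ValueError("profile too short for the interval table")
    return np.array(
        [profile[a:b].mean() for a, b in zip(edges[:-1], edges[1:])]
    )


def band_cover(heights: np.ndarray) -> np.ndarray:
    """Fractions of above-ground returns in the four canopy bands.

    Bands are half-open lower-closed: low [0,1), medium [1,3), high
    [3,10), top [10, inf) m.  Returns all zeros when no above-ground
    returns are present.
    """
    heights = np.asarray(heights, dtype=float)
    heights = heights[heights > 0]
    if len(heights) == 0:
        return np.zeros(4)
    counts = np.histogram(heights, bins=BAND_EDGES)[0]
    return counts / len(heights)


def layer_mean_intensity(
    points: pd.DataFrame, grid: GridSpec, layers_by_cell: dict, max_height: int = DEFAULT_MAX_HEIGHT
) -> None:
    """Fill ``mean_intensity`` of each cell's layers in place.

    Uses only first and single returns (return_number == 1), because
    later returns carry systematically attenuated intensity.
    """
    first = points.loc[(points["return_number"] == 1) & ~points["is_ground"]]
    if len(first) == 0:
        return
    i, j = grid.cell_index(first["x"].to_numpy(), first["y"].to_numpy())
    h = first["height"].to_numpy()
    inten = first["intensity"].to_numpy()
    for (jj, ii), layers in layers_by_cell.items():
        mask = (i == ii) & (j == jj)
        if not mask.any():
            continue
        hc, ic = h[mask], inten[mask]
        for layer in layers:
            sel = (hc >= layer.bottom) & (hc < layer.top)
            if sel.any():
                layer.mean_intensity = float(ic[sel].mean())


def profile_features(
    points: pd.DataFrame,
    grid: GridSpec,
    window: int = 3,
    threshold: float = LAYER_THRESHOLD,
    edges: np.ndarray = DEFAULT_INTERVAL_EDGES,
    max_height: int = DEFAULT_MAX_HEIGHT,
    smooth: bool = True,
    with_intensity: bool = False,
) -> pd.DataFrame:
    """Per-cell feature table driving the structural classification.

    Columns: ``row, col, pvf_00..pvf_17`` (sampled profile), ``canopy_height``
    (m, top of the uppermost layer), ``cover`` (%, fraction of first/single
    pulses intercepted by vegetation), ``crown_thickness`` (m, thickness of
    the uppermost layer), ``n_layers``, the four band-cover fractions and,
    optionally, ``intensity`` (mean first-return intensity of the top layer).
    """
    occ = voxelize(points, grid, max_height)
    pvf = compute_pvf(occ, window)
    prof = smooth_profile(pvf, axis=0) if smooth else pvf

    # vegetation cover per cell from first/single returns
    first = points.loc[points["return_number"] == 1]
    i, j = grid.cell_index(first["x"].to_numpy(), first["y"].to_numpy())
    ok = (i >= 0) & (i < grid.ncols) & (j >= 0) & (j < grid.nrows)
    n_first = np.zeros((grid.nrows, grid.ncols))
    n_veg = np.zeros((grid.nrows, grid.ncols))
    np.add.at(n_first, (j[ok], i[ok]), 1.0)
    veg_mask = (first["height"].to_numpy() > 0) & ~first["is_ground"].to_numpy()
    np.add.at(n_veg, (j[ok & veg_mask], i[ok & veg_mask]), 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cover = np.where(n_first > 0, 100.0 * n_veg / np.maximum(n_first, 1), 0.0)

    # band cover per cell from all above-ground returns
    veg = points.loc[~points["is_ground"] & (points["height"] > 0)]
    iv, jv = grid.cell_index(veg["x"].to_numpy(), veg["y"].to_numpy())
    okv = (iv >= 0) & (iv < grid.ncols) & (jv >= 0) & (jv < grid.nrows)
    hv = veg["height"].to_numpy()[okv]
    band_idx = np.digitize(hv, BAND_EDGES[1:-1])
    band_counts = np.zeros((4, grid.nrows, grid.ncols))
    np.add.at(band_counts, (band_idx, jv[okv], iv[okv]), 1.0)
    tot = band_counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        band_frac = np.where(tot > 0, band_counts / np.maximum(tot, 1), 0.0)

    rows = []
    layers_by_cell = {}
    for jj in range(grid.nrows):
        for ii in range(grid.ncols):
            p = prof[:, jj, ii]
            layers = detect_layers(p, threshold)
            layers_by_cell[(jj, ii)] = layers
            ch = layers[0].top if layers else 0.0
            crown = layers[0].thickness if layers else 0.0
            sampled = sample_profile(p, edges)
            rec = {"row": jj, "col": ii, "canopy_height": ch, "cover": cover[jj, ii],
                   "crown_thickness": crown, "n_layers": len(layers)}
            rec.update({f"pvf_{k:02d}": sampled[k] for k in range(len(sampled))})
            rec.update({f"band_{name}": band_frac[b, jj, ii] for b, name in enumerate(BAND_NAMES)})
            rows.append(rec)
    feats = pd.DataFrame(rows)
    if with_intensity:
        layer_mean_intensity(points, grid, layers_by_cell)
        feats["intensity"] = [
            layers_by_cell[(r, c)][0].mean_intensity if layers_by_cell[(r, c)] else np.nan
            for r, c in zip(feats["row"], feats["col"])
        ]
    return feats


FEATURE_COLUMNS = tuple(
    [f"pvf_{k:02d}" for k in range(18)] + ["canopy_height", "cover", "crown_thickness"]
)
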