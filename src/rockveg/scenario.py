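"""Rainfall-reduction projection and restricted reclassification.

Space-for-time substitution: the fitted structure-rainfall-soil
relationships observed along the regional rainfall gradient are applied
to each polygon as if its site were relocated to a drier climate.  For
a rainfall multiplier m (default 0.8, the A1FI-style 20% reduction used
to illustrate 2070 conditions), each polygon's future canopy height and
ground cover are predicted from its estimated soil-depth probability and
reduced rainfall, and the polygon is reassigned to the structural class
whose mean (CH, GC) is nearest — restricted to classes whose mean canopy
height AND ground cover do not exceed the current class's means.  The
restriction prevents spurious upward jumps: classes are internally
heterogeneous, so an unrestricted nearest-mean match could move a
polygon into a taller/denser class under a drying scenario.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import habitat
from .classify import StructuralClassLibrary
from .segmentation import VegPolygon


@dataclass
class Scenario:
    """A rainfall-change projection scenario.

    mode "delta" (default) applies the *change* predicted by the
    equations to the polygon's current attributes, guaranteeing identity
    at multiplier 1; "absolute" replaces attributes with the raw equation
    outputs.
    """

    rainfall_multiplier: float = 0.8
    mode: str = "delta"  # or "absolute"
    distance_weights: tuple[float, float] | None = None  # (CH, GC) standardization

    def __post_init__(self) -> None:
        if self.rainfall_multiplier <= 0:
            raise ValueError("rainfall multiplier must be > 0")
        if self.mode not in ("delta", "absolute"):
            raise ValueError("mode must be 'delta' or 'absolute'")


def project_polygon(poly: VegPolygon, scenario: Scenario) -> tuple[float, float]:
    """Predicted (CH', GC') for a polygon under the scenario.

    The polygon's pDS is estimated from its present mean height, cover
    and rainfall if not already set.  In delta mode the equation-predicted
    change is added to the present values; results are floored at 0 (and
    cover capped at 100).
    """
    if not np.isfinite(poly.rainfall):
        raise ValueError(f"polygon {poly.polygon_id} has no rainfall value")
    pds = poly.pds
    if not np.isfinite(pds):
        pds = habitat.estimate_pds(poly.mean_ch, poly.mean_gc, poly.rainfall)
        poly.pds = pds
    r_new = scenario.rainfall_multiplier * poly.rainfall
    ch_eq = habitat.predict_canopy_height(pds, r_new)
    gc_eq = habitat.predict_ground_cover(pds, r_new)
    if scenario.mode == "absolute":
        return float(ch_eq), float(gc_eq)
    dch = ch_eq - habitat.predict_canopy_height(pds, poly.rainfall)
    dgc = gc_eq - habitat.predict_ground_cover(pds, poly.rainfall)
    ch = max(poly.mean_ch + dch, 0.0)
    gc = float(np.clip(poly.mean_gc + dgc, 0.0, 100.0))
    return float(ch), gc


def class_mean_scales(library: StructuralClassLibrary) -> tuple[float, float]:
    """Across-class standard deviations of mean CH and mean GC.

    Used to standardize the two axes of the reclassification distance;
    degenerate (zero) spreads fall back to 1.
    """
    means = library.class_means()
    s_ch = float(means["mean_ch"].std(ddof=0)) or 1.0
    s_gc = float(means["mean_gc"].std(ddof=0)) or 1.0
    return s_ch, s_gc


def reclassify_restricted(
    poly: VegPolygon,
    ch_future: float,
    gc_future: float,
    library: StructuralClassLibrary,
    scenario: Scenario | None = None,
) -> int:
    """Nearest admissible class for the projected (CH', GC').

    Candidates are the classes whose mean canopy height and mean ground
    cover are both <= the current class's means; the current class always
    qualifies, so the candidate set is never empty.  Distance is Euclidean
    in (CH, GC) standardized by across-class spreads (or the scenario's
    explicit weights); ties go to the smallest class id.
    """
    cur = library.get(poly.class_id)
    if scenario is not None and scenario.distance_weights is not None:
        s_ch, s_gc = scenario.distance_weights
    else:
        s_ch, s_gc = class_mean_scales(library)
    best_id, best_d = None, np.inf
    for cls in sorted(library.classes, key=lambda c: c.class_id):
        if cls.mean_ch <= cur.mean_ch and cls.mean_gc <= cur.mean_gc:
            d = np.hypot((ch_future - cls.mean_ch) / s_ch, (gc_future - cls.mean_gc) / s_gc)
            if d < best_d:  # strict: first (smallest id) wins ties
                best_id, best_d = cls.class_id, d
    return int(best_id)


def project_map(
    polys: list[VegPolygon],
    library: StructuralClassLibrary,
    scenario: Scenario,
) -> pd.DataFrame:
    """Project and reclassify every classified polygon.

    Returns a table with one row per polygon: current class, predicted
    CH'/GC', future class, and the class mean constraints used.  Bare and
    unclassified polygons pass through unchanged.
    """
    rows = []
    for p in polys:
        if p.class_id < 0:
            rows.append(
                {
                    "polygon_id": p.polygon_id,
                    "class_current": p.class_id,
                    "class_future": p.class_id,
                    "ch_future": p.mean_ch,
                    "gc_future": p.mean_gc,
                    "area_m2": p.area,
                }
            )
            continue
        ch_f, gc_f = project_polygon(p, scenario)
        if scenario.mode == "delta":
            # anchor the class search at the current class mean plus the
            # equation-predicted change: classes are internally heterogeneous,
            # so anchoring at the polygon's own (possibly off-mean) values
            # would reshuffle classes even under a no-change scenario
            cur = library.get(p.class_id)
            r_new = scenario.rainfall_multiplier * p.rainfall
            dch = habitat.predict_canopy_height(p.pds, r_new) - habitat.predict_canopy_height(p.pds, p.rainfall)
            dgc = habitat.predict_ground_cover(p.pds, r_new) - habitat.predict_ground_cover(p.pds, p.rainfall)
            target_ch = max(cur.mean_ch + dch, 0.0)
            target_gc = float(np.clip(cur.mean_gc + dgc, 0.0, 100.0))
        else:
            target_ch, target_gc = ch_f, gc_f
        new_id = reclassify_restricted(p, target_ch, target_gc, library, scenario)
        rows.append(
            {
                "polygon_id": p.polygon_id,
                "class_current": p.class_id,
                "class_future": new_id,
                "ch_future": ch_f,
                "gc_future": gc_f,
                "area_m2": p.area,
            }
        )
    return pd.DataFrame(rows)


def area_change_summary(
    projection: pd.DataFrame, mask_ids: set[int] | None = None
) -> pd.DataFrame:
    """Per-class area proportions now and under the scenario.

    ``projection`` is the output of :func:`project_map`; ``mask_ids``
    optionally restricts the reporting extent to a polygon subset (e.g.
    the near-outcrop zone).  Proportions are of the total area of the
    reported polygons and sum to 1 in both epochs.
    """
    df = projection
    if mask_ids is not None:
        df = df[df["polygon_id"].isin(mask_ids)]
    total = df["area_m2"].sum()
    if total <= 0:
        raise ValueError("empty reporting extent")
    current = df.groupby("class_current")["area_m2"].sum() / total
    future = df.groupby("class_future")["area_m2"].sum() / total
    out = pd.DataFrame({"current": current, "future": future}).fillna(0.0)
    out["change"] = out["future"] - out["current"]
    out.index.name = "class_id"
    return out
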