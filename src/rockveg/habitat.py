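"""Plot-level habitat statistics and structure–environment regression.

Field plots on and around the outcrops come in three habitat types with
type-specific footprints: off-flow herbfield plots (OF, 1x1 m), inter-
mediate plots (INT, 5x5 m) and on-flow plots at the outcrop base (ON,
20x20 m).  Soil depth is probed five times per plot; the probability of a
soil deeper than 0.5 m (pDS) is the fraction of probes strictly deeper
than the cutoff, so plot-level pDS is quantized to {0, 0.2, ..., 1}.

Structure statistics per plot are taken from the classified polygons
intersecting a 4 m buffer around the plot footprint (the buffer absorbs
hand-held GPS error).  Environment–structure relationships are fitted as
multivariate linear models with pairwise interactions and backward
elimination at alpha = 0.05, validated with leave-one-out Q².

The module also exposes the fitted region-wide closed forms relating
canopy height (CH, m) and ground cover (GC, %) to the product
``x = pDS * R`` of soil-depth probability and annual rainfall (mm), and
the inverse model estimating pDS from CH, GC and R:

    CH(x)  = 0.21 + 28.4e-4 x + 2.9e-5 x²
    GC(x)  = 25.5 + 69.6e-3 x
    pDS    = 0.55 + (10.89 CH + 8.93 GC - 0.73 R) / 1000   (clamped to [0,1])
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from shapely.geometry import box

PROBE_CUTOFF = 0.5  # m
PLOT_SIDE = {"OF": 1.0, "INT": 5.0, "ON": 20.0}  # m
DEFAULT_BUFFER = 4.0  # m
DEFAULT_MIN_COVER = 0.25  # fraction of the buffered plot

# fitted closed-form coefficients (region-wide, x = pDS * R)
HEIGHT_COEF = (0.21, 28.4e-4, 2.9e-5)
COVER_COEF = (25.5, 69.6e-3)
PDS_COEF = (0.55, 10.89, 8.93, -0.73)  # intercept + (CH, GC, R)/1000 terms


def pds_from_probes(depths, cutoff: float = PROBE_CUTOFF) -> float:
    """Fraction of soil probes strictly deeper than the cutoff.

    Five probes are expected; with fewer the fraction is computed over
    the available probes with a warning.
    """
    depths = np.asarray(depths, dtype=float)
    depths = depths[np.isfinite(depths)]
    if (depths < 0).any():
        raise ValueError("probe depths must be nonnegative")
    if len(depths) == 0:
        raise ValueError("no probe depths supplied")
    if len(depths) != 5:
        warnings.warn(
            f"expected 5 probes, got {len(depths)}; pDS computed over {len(depths)}",
            stacklevel=2,
        )
    return float((depths > cutoff).mean())


def predict_canopy_height(pds, rainfall) -> np.ndarray | float:
    """Canopy height (m) from the fitted quadratic in x = pDS*R, floored at 0."""
    x = np.asarray(pds, dtype=float) * np.asarray(rainfall, dtype=float)
    a, b, c = HEIGHT_COEF
    out = np.maximum(a + b * x + c * x**2, 0.0)
    return float(out) if out.ndim == 0 else out


def predict_ground_cover(pds, rainfall) -> np.ndarray | float:
    """Ground cover (%) from the fitted linear form in x = pDS*R, capped at 100."""
    x = np.asarray(pds, dtype=float) * np.asarray(rainfall, dtype=float)
    a, b = COVER_COEF
    out = np.clip(a + b * x, 0.0, 100.0)
    return float(out) if out.ndim == 0 else out


def estimate_pds(ch, gc, rainfall) -> np.ndarray | float:
    """Soil-depth probability from structure and rainfall, clamped to [0, 1]."""
    c0, c_ch, c_gc, c_r = PDS_COEF
    out = c0 + (
        c_ch * np.asarray(ch, dtype=float)
        + c_gc * np.asarray(gc, dtype=float)
        + c_r * np.asarray(rainfall, dtype=float)
    ) / 1000.0
    out = np.clip(out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def plot_buffer_stats(
    plot_x: float,
    plot_y: float,
    habitat: str,
    polygons,
    library=None,
    buffer: float = DEFAULT_BUFFER,
    min_cover: float = DEFAULT_MIN_COVER,
) -> dict:
    """Structure statistics over polygons intersecting a buffered plot.

    The plot footprint is a square of the habitat-type side length centred
    on the recorded location, dilated by ``buffer`` metres (Euclidean).
    Returns area-weighted mean ground cover and the maximum canopy height
    over intersecting polygons, plus class-weighted versions computed from
    library class means over polygons covering at least ``min_cover`` of
    the buffered plot.  All values are NaN (with a warning) when nothing
    intersects.
    """
    side = PLOT_SIDE[habitat]
    half = side / 2
    footprint = box(plot_x - half, plot_y - half, plot_x + half, plot_y + half).buffer(buffer)
    total = footprint.area
    weights, chs, gcs = [], [], []
    cw_weights, cw_ch, cw_gc = [], [], []
    for p in polygons:
        inter = footprint.intersection(p.geometry)
        if inter.is_empty or inter.area <= 0:
            continue
        weights.append(inter.area)
        chs.append(p.mean_ch)
        gcs.append(p.mean_gc)
        if library is not None and p.class_id >= 0 and inter.area >= min_cover * total:
            cls = library.get(p.class_id)
            cw_weights.append(inter.area)
            cw_ch.append(cls.mean_ch)
            cw_gc.append(cls.mean_gc)
    if not weights:
        warnings.warn("no polygon intersects the buffered plot", stacklevel=2)
        return {k: float("nan") for k in ("mean_gc", "max_ch", "class_ch", "class_gc")}
    w = np.asarray(weights)
    out = {
        "mean_gc": float(np.average(gcs, weights=w)),
        "max_ch": float(np.max(chs)),
        "class_ch": float("nan"),
        "class_gc": float("nan"),
    }
    if cw_weights:
        cw = np.asarray(cw_weights)
        out["class_ch"] = float(np.average(cw_ch, weights=cw))
        out["class_gc"] = float(np.average(cw_gc, weights=cw))
    return out


def loo_q2(results) -> float:
    """Leave-one-out predictive coefficient Q² = 1 - PRESS/TSS.

    Computed with the hat-matrix shortcut: the LOO residual of an OLS fit
    is ``e_i / (1 - h_ii)``, which equals the residual from explicitly
    refitting without observation i.  Undefined (raises) when the model
    has no residual degrees of freedom.
    """
    if results.df_resid < 1:
        raise ValueError("Q^2 undefined: no residual degrees of freedom")
    h = results.get_influence().hat_matrix_diag
    if np.any(1 - h <= 1e-12):
        raise ValueError("Q^2 undefined: leverage 1 observation")
    press = float(np.sum((results.resid / (1 - h)) ** 2))
    y = results.model.endog
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / tss


def fit_backward(y, X: pd.DataFrame, alpha: float = 0.05):
    """OLS with backward elimination of insignificant terms.

    Starting from all candidate columns of ``X`` (an intercept is always
    included and never dropped), the term with the largest p-value >= alpha
    is removed — one per refit, with no main-effect hierarchy, so an
    interaction may be retained without its mains.  Aliased
    (rank-deficient) terms are dropped first with a warning.  Returns the
    final statsmodels results and the list of retained term names.
    """
    y = np.asarray(y, dtype=float)
    work = X.copy()
    while True:
        design = sm.add_constant(work, has_constant="add")
        A = design.to_numpy(dtype=float)
        if np.linalg.matrix_rank(A) < A.shape[1]:
            # drop the first column linearly dependent on its predecessors
            _, R = np.linalg.qr(A)
            diag = np.abs(np.diag(R))
            dep = int(np.argmax(diag < 1e-8 * max(diag.max(), 1.0)))
            name = design.columns[dep]
            warnings.warn(f"dropping aliased term {name}", stacklevel=2)
            work = work.drop(columns=name)
            continue
        res = sm.OLS(y, design).fit()
        pvals = res.pvalues.drop("const", errors="ignore")
        if len(pvals) == 0 or pvals.max() < alpha:
            return res, list(work.columns)
        work = work.drop(columns=pvals.idxmax())


ENV_TERMS = ("R", "EV", "pDS")


def build_design(df: pd.DataFrame, terms=ENV_TERMS, interactions: bool = True) -> pd.DataFrame:
    """Candidate design: main environmental terms plus pairwise interactions."""
    X = pd.DataFrame({t: df[t].astype(float) for t in terms})
    if interactions:
        for a in range(len(terms)):
            for b in range(a + 1, len(terms)):
                X[f"{terms[a]}:{terms[b]}"] = X[terms[a]] * X[terms[b]]
    return X


@dataclass
class StructureEnvironmentResults:
    """Backward-eliminated OLS fit of a structure attribute on environment."""

    response: str
    terms: list[str]
    params: pd.Series
    pvalues: pd.Series
    rsquared: float
    q2: float
    nobs: int
    _sm_results: object = field(default=None, repr=False)

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        X = sm.add_constant(build_design(df)[self.terms], has_constant="add")
        return np.asarray(self._sm_results.predict(X))

    def summary(self) -> str:
        lines = [
            f"Structure-environment model: {self.response}",
            f"n = {self.nobs}   R^2 = {self.rsquared:.3f}   LOO Q^2 = {self.q2:.3f}",
            f"{'term':<12}{'coef':>12}{'p':>10}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:<12}{self.params[name]:>12.5g}{self.pvalues[name]:>10.3g}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "terms": self.terms,
            "params": {k: float(v) for k, v in self.params.items()},
            "pvalues": {k: float(v) for k, v in self.pvalues.items()},
            "rsquared": float(self.rsquared),
            "q2": float(self.q2),
            "n": int(self.nobs),
        }


class StructureEnvironmentModel:
    """Linear model of a plot attribute on rainfall, elevation range and pDS.

    Statsmodels-style: build from a plot table, ``fit()`` returns a
    results object carrying coefficients, p-values, R², LOO Q² and a
    ``summary()``.

    Parameters
    ----------
    df : DataFrame with columns ``R`` (annual rainfall, mm), ``EV``
        (site elevation range, m), ``pDS`` and the response column.
    response : name of the response column (e.g. ``max_ch`` or ``mean_gc``).
    interactions : include the three pairwise interaction candidates.
    """

    def __init__(self, endog: np.ndarray, exog: pd.DataFrame, response: str = "y"):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = exog
        self.response = response
        if len(self.endog) <= exog.shape[1] + 1:
            raise ValueError("need n > number of candidate terms + 1")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, response: str, terms=ENV_TERMS, interactions: bool = True
    ) -> "StructureEnvironmentModel":
        data = df.dropna(subset=[response, *terms])
        X = build_design(data, terms, interactions)
        return cls(data[response].to_numpy(), X, response)

    def fit(self, alpha: float = 0.05) -> StructureEnvironmentResults:
        res, kept = fit_backward(self.endog, self.exog, alpha)
        return StructureEnvironmentResults(
            response=self.response,
            terms=kept,
            params=res.params,
            pvalues=res.pvalues,
            rsquared=float(res.rsquared),
            q2=loo_q2(res),
            nobs=int(res.nobs),
            _sm_results=res,
        )


def save_models(results: list[StructureEnvironmentResults], path: str | Path) -> None:
    Path(path).write_text(json.dumps([r.to_dict() for r in results], indent=1))
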