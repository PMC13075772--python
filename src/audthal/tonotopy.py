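"""Tonotopic gradients: CF versus recording depth along probe penetrations.

Units are positioned along each penetration from their distance to the
probe tip; the insertion angle (default 60 degrees to the brain surface)
projects that distance to vertical depth.  Tonotopy is quantified per
penetration by regressing log2(CF) on distance from tip — half-octave
stimulus spacing makes the log2 scale natural — and penetrations are
classified by slope sign at alpha = 0.05.  The aggregate reports per-class
counts and a one-sample t-test of slopes against zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def locate_units(geometry: pd.DataFrame) -> pd.DataFrame:
    """Project along-shank distances to vertical depth via the insertion angle.

    Requires columns ``penetration_id, angle_deg, unit_id, dist_from_tip_um``;
    raises naming any unit without geometry.
    """
    required = {"penetration_id", "angle_deg", "unit_id", "dist_from_tip_um"}
    missing_cols = required - set(geometry.columns)
    if missing_cols:
        raise ValueError(f"geometry table lacks columns {sorted(missing_cols)}")
    bad = geometry[geometry[["angle_deg", "dist_from_tip_um"]].isna().any(axis=1)]
    if not bad.empty:
        raise ValueError("missing geometry for penetration(s) "
                         f"{sorted(bad['penetration_id'].unique().tolist())}")
    out = geometry.copy()
    out["depth_offset_um"] = (out["dist_from_tip_um"]
                              * np.sin(np.deg2rad(out["angle_deg"])))
    return out


@dataclass(frozen=True)
class TonotopyFit:
    penetration_id: int
    slope_log2_per_mm: float
    intercept: float
    p_value: float
    r_squared: float
    n_units: int
    classification: str     # negative-significant / positive-significant / non-significant
    zero_variance: bool = False


def tonotopy_regression(cf_hz: np.ndarray, dist_from_tip_um: np.ndarray,
                        penetration_id: int = -1, alpha: float = 0.05) -> TonotopyFit:
    """Least-squares regression of log2(CF) on distance from tip (mm)."""
    cf = np.asarray(cf_hz, float)
    dist_mm = np.asarray(dist_from_tip_um, float) / 1000.0
    if cf.size < 3:
        raise ValueError("tonotopy regression needs at least 3 CF-bearing units")
    if np.allclose(cf, cf[0]) or np.allclose(dist_mm, dist_mm[0]):
        return TonotopyFit(penetration_id, 0.0, float(np.log2(cf[0])), np.nan,
                           np.nan, cf.size, "non-significant", zero_variance=True)
    fit = stats.linregress(dist_mm, np.log2(cf))
    sig = fit.pvalue < alpha
    cls = ("negative-significant" if sig and fit.slope < 0
           else "positive-significant" if sig and fit.slope > 0
           else "non-significant")
    return TonotopyFit(penetration_id, float(fit.slope), float(fit.intercept),
                       float(fit.pvalue), float(fit.rvalue**2), int(cf.size), cls)


def fit_all_penetrations(tuning: pd.DataFrame, geometry: pd.DataFrame,
                         alpha: float = 0.05, min_units: int = 3) -> list[TonotopyFit]:
    """Run the regression for every penetration with enough CF-bearing units.

    ``tuning`` needs columns ``unit_id, cf_hz`` (NaN CF rows are dropped);
    ``geometry`` as for :func:`locate_units`.
    """
    merged = geometry.merge(tuning[["unit_id", "cf_hz"]], on="unit_id", how="inner")
    merged = merged.dropna(subset=["cf_hz"])
    fits = []
    for pid, g in merged.groupby("penetration_id"):
        if len(g) < min_units:
            continue
        fits.append(tonotopy_regression(g["cf_hz"].to_numpy(),
                                        g["dist_from_tip_um"].to_numpy(),
                                        penetration_id=int(pid), alpha=alpha))
    return fits


def aggregate_tonotopy(fits: list[TonotopyFit]) -> dict:
    """Class counts plus a one-sample t-test of slopes against zero."""
    slopes = np.array([f.slope_log2_per_mm for f in fits if not f.zero_variance])
    counts = {c: sum(1 for f in fits if f.classification == c)
              for c in ("negative-significant", "positive-significant", "non-significant")}
    if slopes.size >= 2:
        t, p = stats.ttest_1samp(slopes, 0.0)
    else:
        t, p = np.nan, np.nan
    return {"n_penetrations": len(fits), "counts": counts,
            "mean_slope_log2_per_mm": float(slopes.mean()) if slopes.size else np.nan,
            "t": float(t), "p": float(p)}
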