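"""Signal-detection scoring of lever-release sessions.

Each trial of the go/no-go task is segmented by target onset time into a
short-onset segment (onsets 1000-2250 ms after lever press) scored for
hits/misses and a long-onset segment (2250-3500 ms) scored for false
alarms/correct rejections inside a *virtual* response window that is
statistically identical to the hit window but contains no target.  From the
resulting 2x2 counts the module computes hit/false-alarm/miss rates,
percent-correct performance and behavioral sensitivity

    d' = Z(HR) - Z(FAR),

with a log-linear correction applied when a rate sits at 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

HIT, MISS, FA, CR, ABORT = "H", "M", "FA", "CR", "AB"

ONSET_MIN_MS = 1000.0
SEGMENT_BOUNDARY_MS = 2250.0
ONSET_MAX_MS = 3500.0
RESPONSE_WINDOW_MS = 700.0


def classify_trials(trials: pd.DataFrame, seed: int = 0,
                    response_window_ms: float = RESPONSE_WINDOW_MS) -> pd.DataFrame:
    """Assign each trial exactly one label in {H, M, FA, CR, AB}.

    Short-onset trials (onset <= 2250 ms): release within
    ``(onset, onset + 700]`` is a hit, any later release or none is a miss.
    Long-onset trials get a seeded virtual onset drawn uniformly over the
    hit-window onset range, truncated so the virtual window ends before the
    true target onset (which is what makes the false-alarm rate independent
    of target amplitude): release inside the virtual window is a false
    alarm, none is a correct rejection.  Releases before a trial's scoring
    window are aborts and are excluded from the rates.
    """
    onset = trials["onset_ms"].to_numpy(float)
    release = trials["release_ms"].to_numpy(float)
    press = trials["press_ms"].to_numpy(float) if "press_ms" in trials else np.zeros_like(onset)
    if np.any(onset < ONSET_MIN_MS) or np.any(onset > ONSET_MAX_MS):
        raise ValueError("target onsets outside the admissible 1000-3500 ms range")
    if np.any(release[np.isfinite(release)] <= press[np.isfinite(release)]):
        raise ValueError("release at or before lever press")

    rng = np.random.default_rng(seed)
    short = onset <= SEGMENT_BOUNDARY_MS
    v_hi = np.minimum(SEGMENT_BOUNDARY_MS, onset - response_window_ms)
    virtual = rng.uniform(ONSET_MIN_MS, np.maximum(v_hi, ONSET_MIN_MS + 1e-9))
    win_start = np.where(short, onset, virtual)
    win_end = win_start + response_window_ms

    has_release = np.isfinite(release)
    in_window = has_release & (release > win_start) & (release <= win_end)
    before_window = has_release & (release <= win_start)

    label = np.empty(len(trials), dtype=object)
    label[before_window] = ABORT
    label[short & in_window] = HIT
    label[short & ~in_window & ~before_window] = MISS
    label[~short & in_window] = FA
    label[~short & ~in_window & ~before_window] = CR

    out = trials.copy()
    out["label"] = label
    out["virtual_onset_ms"] = np.where(short, np.nan, virtual)
    out["window_start_ms"] = win_start
    out["window_end_ms"] = win_end
    return out


def _corrected_rates(ht: float, ms: float, fa: float, cr: float,
                     edge_correction: str = "loglinear") -> tuple[float, float]:
    hr = ht / (ht + ms) if ht + ms > 0 else np.nan
    far = fa / (fa + cr) if fa + cr > 0 else np.nan
    if edge_correction == "loglinear" and (hr in (0.0, 1.0) or far in (0.0, 1.0)):
        hr = (ht + 0.5) / (ht + ms + 1.0)
        far = (fa + 0.5) / (fa + cr + 1.0)
    return hr, far


def sdt_summary(outcomes: pd.DataFrame,
                group_cols: tuple[str, ...] = ("animal", "session", "kind", "spl_db"),
                edge_correction: str = "loglinear") -> pd.DataFrame:
    """Counts, rates, performance and d' per grouping cell.

    ``performance = (HT + CR) / (HT + CR + FA + MS)`` and
    ``d' = Z(HR_c) - Z(FAR_c)`` on edge-corrected rates.  Cells missing one
    of the scored trial types keep NaN rates (flagged, never silently zero).
    """
    scored = outcomes[outcomes["label"] != ABORT]
    rows = []
    for key, g in scored.groupby(list(group_cols)):
        counts = g["label"].value_counts()
        ht, ms = int(counts.get(HIT, 0)), int(counts.get(MISS, 0))
        fa, cr = int(counts.get(FA, 0)), int(counts.get(CR, 0))
        hr_c, far_c = _corrected_rates(ht, ms, fa, cr, edge_correction)
        hr = ht / (ht + ms) if ht + ms > 0 else np.nan
        far = fa / (fa + cr) if fa + cr > 0 else np.nan
        msr = 1.0 - hr if np.isfinite(hr) else np.nan
        total = ht + ms + fa + cr
        perf = (ht + cr) / total if total > 0 else np.nan
        dprime = (stats.norm.ppf(hr_c) - stats.norm.ppf(far_c)
                  if np.isfinite(hr_c) and np.isfinite(far_c) else np.nan)
        key = key if isinstance(key, tuple) else (key,)
        rows.append((*key, ht, ms, fa, cr, hr, far, msr, perf, dprime))
    cols = list(group_cols) + ["HT", "MS", "FA", "CR", "HR", "FAR", "MSR",
                               "performance", "d_prime"]
    return pd.DataFrame(rows, columns=cols)


def aggregate_dprime(summary: pd.DataFrame) -> pd.DataFrame:
    """Per-session cells -> per-animal means over sessions, per kind x SPL."""
    return (summary.groupby(["animal", "kind", "spl_db"], as_index=False)
            [["HR", "FAR", "MSR", "performance", "d_prime"]].mean())


def detection_thresholds(per_animal: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Lowest tested amplitude at which group d' exceeds zero.

    A one-sample t-test across animals (two-tailed, alpha) is run at each
    amplitude per stimulus kind; the threshold is the lowest amplitude with a
    significant, positive mean d'.  Returns per-kind thresholds and the
    PT - NBN difference.
    """
    res: dict = {"alpha": alpha, "per_amplitude": []}
    for kind, g in per_animal.groupby("kind"):
        threshold = np.nan
        for spl, cell in sorted(g.groupby("spl_db"), key=lambda kv: kv[0]):
            vals = cell["d_prime"].dropna().to_numpy()
            if len(vals) < 2:
                continue
            t, p = stats.ttest_1samp(vals, 0.0)
            sig = bool(p < alpha and np.mean(vals) > 0)
            res["per_amplitude"].append(
                {"kind": kind, "spl_db": float(spl), "mean_dprime": float(np.mean(vals)),
                 "t": float(t), "p": float(p), "significant": sig})
            if sig and not np.isfinite(threshold):
                threshold = float(spl)
        res[kind] = threshold
    if np.isfinite(res.get("PT", np.nan)) and np.isfinite(res.get("NBN", np.nan)):
        res["threshold_difference_db"] = res["PT"] - res["NBN"]
    else:
        res["threshold_difference_db"] = np.nan
    return res


@dataclass(frozen=True)
class StrategyRegression:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    degenerate: bool = False


def strategy_regression(msr: np.ndarray, far: np.ndarray) -> StrategyRegression:
    """OLS fit of per-animal FAR on miss rate (response-strategy axis).

    Animals trading misses against false alarms produce a negative slope;
    the p-value is the regression F-test (equal to the slope t-test for a
    single regressor).
    """
    msr = np.asarray(msr, float)
    far = np.asarray(far, float)
    if msr.size < 3:
        raise ValueError("strategy regression needs at least 3 animals")
    if np.allclose(msr, msr[0]):
        return StrategyRegression(np.nan, np.nan, np.nan, np.nan, msr.size, degenerate=True)
    fit = stats.linregress(msr, far)
    return StrategyRegression(slope=float(fit.slope), intercept=float(fit.intercept),
                              r_squared=float(fit.rvalue**2), p_value=float(fit.pvalue),
                              n=int(msr.size))
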