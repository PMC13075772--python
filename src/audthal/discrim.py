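"""Single-unit frequency discriminability (two-alternative d').

Each unit's capacity to discriminate its characteristic frequency (CF)
from an adjacent half-octave band is scored trial by trial: with evoked
spike counts in a 50 ms window starting 5 ms after onset and baseline
counts in the final 50 ms before onset,

    D = (evoked_CF - baseline_CF) - (evoked_adj - baseline_adj),

and the probability of correct discrimination with half credit for
uninformative (D = 0) trials and a +1-smoothed denominator is

    Pc = (n_{D>0} + 0.5 * (1 + n_{D=0})) / (n_total + 1),
    d'  = sqrt(2) * norminv(Pc).

The smoothing keeps Pc strictly inside (0, 1), so d' is always finite.
When the CF is interior to the grid, d' is averaged over the left and
right adjacent comparisons; at grid borders the single available side is
used.  Curves of d' against SPL are re-indexed by offset from each unit's
C50 to expose the peak just above response threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

EVOKED_WINDOW_MS = (5.0, 55.0)
BASELINE_WINDOW_MS = (-50.0, 0.0)


def pc_from_counts(n_pos: int, n_zero: int, n_total: int) -> float:
    """Probability correct with half credit for D = 0 trials."""
    if n_total < 0 or n_pos + n_zero > n_total:
        raise ValueError("inconsistent trial counts")
    return (n_pos + 0.5 * (1 + n_zero)) / (n_total + 1)


def dprime_from_pc(pc: float) -> float:
    return float(np.sqrt(2.0) * stats.norm.ppf(pc))


@dataclass(frozen=True)
class DiscriminabilityEntry:
    unit_id: int
    kind: str
    spl_db: float
    n_pos: int
    n_zero: int
    n_total: int
    pc: float
    d_prime: float
    n_sides: int


def _windowed_counts(spikes: pd.DataFrame, unit_id: int, kind: str, freq_hz: float,
                     spl_db: float, window: tuple[float, float], n_trials: int
                     ) -> np.ndarray:
    sub = spikes[(spikes["unit_id"] == unit_id) & (spikes["kind"] == kind)
                 & (np.isclose(spikes["freq_hz"], freq_hz))
                 & (np.isclose(spikes["spl_db"], spl_db))
                 & (spikes["spike_ms"] >= window[0]) & (spikes["spike_ms"] < window[1])]
    counts = np.zeros(n_trials)
    vc = sub.groupby("trial").size()
    for t, c in vc.items():
        if 0 <= t < n_trials:
            counts[int(t)] = c
    return counts


def trial_discriminability(spikes: pd.DataFrame, grid, tuning, spl_db: float,
                           evoked_window: tuple[float, float] = EVOKED_WINDOW_MS,
                           baseline_window: tuple[float, float] = BASELINE_WINDOW_MS
                           ) -> DiscriminabilityEntry:
    """CF-vs-adjacent discriminability at one SPL, trials paired by index."""
    if not tuning.has_cf:
        raise ValueError("unit has no defined CF")
    spls = np.asarray(grid.spl_levels)
    if not np.any(np.isclose(spls, spl_db)):
        raise ValueError(f"SPL {spl_db} dB not on the stimulus grid")
    freqs = np.asarray(grid.center_frequencies)
    n_t = grid.repetitions
    cfi = tuning.cf_index
    cf_ev = _windowed_counts(spikes, tuning.unit_id, tuning.kind, freqs[cfi],
                             spl_db, evoked_window, n_t)
    cf_ba = _windowed_counts(spikes, tuning.unit_id, tuning.kind, freqs[cfi],
                             spl_db, baseline_window, n_t)
    delta_cf = cf_ev - cf_ba

    dps, tot_pos = [], np.zeros(3, int)
    for side in (-1, 1):
        j = cfi + side
        if not (0 <= j < len(freqs)):
            continue
        adj_ev = _windowed_counts(spikes, tuning.unit_id, tuning.kind, freqs[j],
                                  spl_db, evoked_window, n_t)
        adj_ba = _windowed_counts(spikes, tuning.unit_id, tuning.kind, freqs[j],
                                  spl_db, baseline_window, n_t)
        d = delta_cf - (adj_ev - adj_ba)
        n_pos, n_zero = int(np.sum(d > 0)), int(np.sum(d == 0))
        pc = pc_from_counts(n_pos, n_zero, d.size)
        dps.append(dprime_from_pc(pc))
        tot_pos += (n_pos, n_zero, d.size)
    if not dps:
        raise ValueError("no adjacent frequency available")
    n_pos, n_zero, n_total = (int(v) for v in tot_pos)
    return DiscriminabilityEntry(
        unit_id=tuning.unit_id, kind=tuning.kind, spl_db=float(spl_db),
        n_pos=n_pos, n_zero=n_zero, n_total=n_total,
        pc=pc_from_counts(n_pos, n_zero, n_total),
        d_prime=float(np.mean(dps)), n_sides=len(dps))


def snap_offset(spl_db: float, c50_db: float, step_db: float = 5.0) -> float:
    """Offset from C50 snapped to the SPL grid step, ties toward lower SPL."""
    raw = (spl_db - c50_db) / step_db
    return float(np.ceil(raw - 0.5) * step_db)


def dprime_vs_level(spikes: pd.DataFrame, grid, tuning, c50_db: float
                    ) -> pd.DataFrame:
    """d' at every tested SPL, indexed by offset from the unit's C50."""
    rows = []
    for spl in grid.spl_levels:
        e = trial_discriminability(spikes, grid, tuning, spl)
        rows.append({"unit_id": e.unit_id, "kind": e.kind, "spl_db": e.spl_db,
                     "offset_db": snap_offset(e.spl_db, c50_db),
                     "n_pos": e.n_pos, "n_zero": e.n_zero, "n_tot": e.n_total,
                     "pc": e.pc, "dprime": e.d_prime})
    return pd.DataFrame(rows)


def dprime_vs_level_from_tensors(evoked: np.ndarray, baseline: np.ndarray,
                                 grid, tuning, c50_db: float) -> pd.DataFrame:
    """Vectorized d' vs SPL from precomputed count tensors.

    ``evoked`` and ``baseline`` are (n_freq, n_spl, n_trials) spike-count
    arrays for one unit and kind (evoked window 5-55 ms, baseline window the
    last 50 ms before onset).  Matches :func:`dprime_vs_level` exactly.
    """
    if not tuning.has_cf:
        raise ValueError("unit has no defined CF")
    delta = evoked - baseline                       # (n_f, n_s, n_t)
    cfi = tuning.cf_index
    n_f = delta.shape[0]
    rows = []
    for si, spl in enumerate(grid.spl_levels):
        dps = []
        tot = np.zeros(3, int)
        for side in (-1, 1):
            j = cfi + side
            if not (0 <= j < n_f):
                continue
            d = delta[cfi, si] - delta[j, si]
            n_pos, n_zero = int(np.sum(d > 0)), int(np.sum(d == 0))
            dps.append(dprime_from_pc(pc_from_counts(n_pos, n_zero, d.size)))
            tot += (n_pos, n_zero, d.size)
        n_pos, n_zero, n_total = (int(v) for v in tot)
        rows.append({"unit_id": tuning.unit_id, "kind": tuning.kind,
                     "spl_db": float(spl),
                     "offset_db": snap_offset(float(spl), c50_db),
                     "n_pos": n_pos, "n_zero": n_zero, "n_tot": n_total,
                     "pc": pc_from_counts(n_pos, n_zero, n_total),
                     "dprime": float(np.mean(dps))})
    return pd.DataFrame(rows)


def population_dprime_curve(per_unit: pd.DataFrame) -> pd.DataFrame:
    """Mean d' with SEM per (kind, offset from C50) across units."""
    g = per_unit.groupby(["kind", "offset_db"])["dprime"]
    out = g.agg(["mean", "sem", "count"]).reset_index()
    return out.rename(columns={"mean": "dprime_mean", "sem": "dprime_sem",
                               "count": "n_units"})
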