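"""Frequency response areas and log-normal rate-level fitting.

A unit's frequency response area (FRA) is the matrix of trial-averaged
firing rates over the frequency x SPL lattice, counted in a 5-95 ms window
after stimulus onset.  At each frequency the normalized rate-level function
is fitted with a scaled log-normal of SPL,

    f(x) = E / (x * sigma * sqrt(2 pi)) * exp(-(log x - mu)^2 / (2 sigma^2)) + B,

where x is SPL in dB, log is natural, and (E, mu, sigma, B) are constrained
positive with upper bounds [150, 20, 10, 0.4].  From the fitted curve the
module extracts C50 (SPL at 50% of the baseline-to-maximum range), the
half-width (SPL extent above half-maximum; infinite for monotonic units,
finite for O-shaped ones), selects the characteristic frequency (CF,
lowest C50 among criterion-passing frequencies) and measures tuning
bandwidth.

``RateLevelModel`` / ``RateLevelResult`` follow the model-object pattern:
construct from data, call :meth:`RateLevelModel.fit`, inspect the results
object (parameters, R^2, C50, half-width, ``summary()``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.stats import qmc

from .stimuli import StimulusGrid

RESPONSE_WINDOW_MS = (5.0, 95.0)
PARAM_UPPER_BOUNDS = (150.0, 20.0, 10.0, 0.4)
PARAM_LOWER_BOUND = 1e-6
EVAL_DOMAIN_DB = (1.0, 100.0)


def lognormal_rate(x: np.ndarray, E: float, mu: float, sigma: float, B: float) -> np.ndarray:
    """The scaled log-normal rate-level function of SPL (dB)."""
    x = np.asarray(x, float)
    out = np.full(x.shape, B, float)
    pos = x > 0
    xp = x[pos]
    out[pos] = (E / (xp * sigma * math.sqrt(2 * math.pi))
                * np.exp(-((np.log(xp) - mu) ** 2) / (2 * sigma**2)) + B)
    return out


def _lognormal_jac(x: np.ndarray, E: float, mu: float, sigma: float, B: float) -> np.ndarray:
    """Analytic Jacobian of :func:`lognormal_rate` wrt (E, mu, sigma, B)."""
    x = np.asarray(x, float)
    z = (np.log(x) - mu) / sigma
    core = np.exp(-0.5 * z**2) / (x * sigma * math.sqrt(2 * math.pi))
    dE = core
    dmu = E * core * z / sigma
    dsig = E * core * (z**2 - 1.0) / sigma
    dB = np.ones_like(x)
    return np.column_stack([dE, dmu, dsig, dB])


# ---------------------------------------------------------------------------
# FRA construction and responsiveness
# ---------------------------------------------------------------------------

@dataclass
class FRA:
    """Trial-averaged rate matrix (frequency x SPL) for one unit and kind."""

    unit_id: int
    kind: str
    frequencies: np.ndarray
    spls: np.ndarray
    rates: np.ndarray            # (n_freq, n_spl) sp/s
    counts: np.ndarray           # (n_freq, n_spl, n_trials) spikes in window
    window_ms: tuple[float, float] = RESPONSE_WINDOW_MS

    @property
    def max_rate(self) -> float:
        return float(self.rates.max())

    @property
    def degenerate(self) -> bool:
        return self.max_rate <= 0

    @property
    def normalized(self) -> np.ndarray:
        if self.degenerate:
            return np.zeros_like(self.rates)
        return self.rates / self.max_rate


def compute_fra(spikes: pd.DataFrame, grid: StimulusGrid, unit_id: int, kind: str,
                window_ms: tuple[float, float] = RESPONSE_WINDOW_MS) -> FRA:
    """Build the FRA from a long-format spike table.

    Rate per condition is the mean over repetitions of (spikes in window) /
    window length.  Missing conditions raise with the list of gaps.
    """
    freqs = np.asarray(grid.center_frequencies)
    spls = np.asarray(grid.spl_levels)
    n_t = grid.repetitions
    sub = spikes[(spikes["unit_id"] == unit_id) & (spikes["kind"] == kind)]
    lo, hi = window_ms
    win = sub[(sub["spike_ms"] >= lo) & (sub["spike_ms"] < hi)]
    grouped = win.groupby(["freq_hz", "spl_db", "trial"]).size()

    counts = np.zeros((len(freqs), len(spls), n_t))
    # a fully silent unit yields an all-zero, degenerate-flagged FRA; a grid
    # whose conditions are only partially covered by off-grid labels is the
    # error case
    off_grid = sub[~(sub["freq_hz"].isin(freqs) & sub["spl_db"].isin(spls))]
    if not off_grid.empty:
        gaps = off_grid[["freq_hz", "spl_db"]].drop_duplicates().to_numpy().tolist()
        raise ValueError(f"unit {unit_id}/{kind}: conditions off the grid: {gaps}")
    for (f, s, t), c in grouped.items():
        fi = int(np.argmin(np.abs(freqs - f)))
        si = int(np.argmin(np.abs(spls - s)))
        if t < n_t:
            counts[fi, si, int(t)] = c
    dur_s = (hi - lo) / 1000.0
    rates = counts.mean(axis=2) / dur_s
    return FRA(unit_id=unit_id, kind=kind, frequencies=freqs, spls=spls,
               rates=rates, counts=counts, window_ms=window_ms)


@dataclass(frozen=True)
class ResponsivenessResult:
    unit_id: int
    kind: str
    responsive: bool
    p_per_frequency: np.ndarray          # Bonferroni-corrected one-way p values
    p_omnibus_amplitude: float
    p_omnibus_frequency: float
    p_interaction: float
    zero_variance: bool = False


def detect_responsive(fra: FRA, alpha: float = 0.01, omnibus: bool = True
                      ) -> ResponsivenessResult:
    """Two-way ANOVA (frequency x amplitude) on trial spike counts, then
    per-frequency one-way amplitude tests Bonferroni-corrected across the
    frequency bands; responsive iff any corrected p < alpha."""
    n_f, n_s, n_t = fra.counts.shape
    if np.allclose(fra.counts, fra.counts.flat[0]):
        return ResponsivenessResult(fra.unit_id, fra.kind, False,
                                    np.ones(n_f), np.nan, np.nan, np.nan,
                                    zero_variance=True)
    p_freq = np.ones(n_f)
    for fi in range(n_f):
        groups = [fra.counts[fi, si] for si in range(n_s)]
        if np.allclose(np.concatenate(groups), groups[0][0]):
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = stats.f_oneway(*groups)
        if np.isfinite(p):
            p_freq[fi] = min(p * n_f, 1.0)  # Bonferroni across frequencies

    p_amp = p_f = p_int = np.nan
    if omnibus:
        p_amp, p_f, p_int = _twoway_anova(fra.counts)
    return ResponsivenessResult(fra.unit_id, fra.kind, bool((p_freq < alpha).any()),
                                p_freq, p_amp, p_f, p_int)


def _twoway_anova(counts: np.ndarray) -> tuple[float, float, float]:
    """Balanced two-way fixed-effects ANOVA with interaction on the
    (freq, spl, trial) count array; returns (p_amplitude, p_frequency,
    p_interaction)."""
    a, b, n = counts.shape
    grand = counts.mean()
    mean_ab = counts.mean(axis=2)
    mean_a = counts.mean(axis=(1, 2))
    mean_b = counts.mean(axis=(0, 2))
    ss_a = b * n * np.sum((mean_a - grand) ** 2)
    ss_b = a * n * np.sum((mean_b - grand) ** 2)
    ss_ab = n * np.sum((mean_ab - mean_a[:, None] - mean_b[None, :] + grand) ** 2)
    ss_e = np.sum((counts - mean_ab[:, :, None]) ** 2)
    df_a, df_b = a - 1, b - 1
    df_ab, df_e = df_a * df_b, a * b * (n - 1)
    if ss_e <= 0 or df_e <= 0:
        return np.nan, np.nan, np.nan
    mse = ss_e / df_e
    p = []
    for ss, df in ((ss_b, df_b), (ss_a, df_a), (ss_ab, df_ab)):
        f = (ss / df) / mse
        p.append(float(stats.f.sf(f, df, df_e)))
    return p[0], p[1], p[2]  # amplitude (b axis), frequency (a axis), interaction


# ---------------------------------------------------------------------------
# rate-level model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SensitivityMeasures:
    c50_db: float
    half_width_db: float          # np.inf for monotonic units
    monotonic: bool
    peak_db: float
    fitted_max: float


@dataclass
class RateLevelResult:
    """Fitted log-normal rate-level function for one frequency."""

    frequency_hz: float
    params: np.ndarray            # (E, mu, sigma, B)
    cov: np.ndarray | None
    r_squared: float
    converged: bool
    n_points: int
    sensitivity: SensitivityMeasures | None = None

    @property
    def E(self) -> float: return float(self.params[0])
    @property
    def mu(self) -> float: return float(self.params[1])
    @property
    def sigma(self) -> float: return float(self.params[2])
    @property
    def B(self) -> float: return float(self.params[3])

    @property
    def bse(self) -> np.ndarray:
        """Asymptotic standard errors of (E, mu, sigma, B)."""
        if self.cov is None:
            return np.full(4, np.nan)
        return np.sqrt(np.clip(np.diag(self.cov), 0, None))

    @property
    def rmax(self) -> float:
        """Fitted maximum response (including baseline) over the domain."""
        if self.sensitivity is None:
            return np.nan
        return self.sensitivity.fitted_max

    @property
    def c50(self) -> float:
        return np.nan if self.sensitivity is None else self.sensitivity.c50_db

    @property
    def half_width(self) -> float:
        return np.nan if self.sensitivity is None else self.sensitivity.half_width_db

    @property
    def monotonic(self) -> bool:
        return self.sensitivity is None or self.sensitivity.monotonic

    def predict(self, x: np.ndarray) -> np.ndarray:
        return lognormal_rate(x, *self.params)

    def summary(self) -> str:
        lines = [
            f"Log-normal rate-level fit @ {self.frequency_hz:.0f} Hz",
            "-" * 46,
            f"{'param':>8} {'estimate':>12} {'std err':>12}",
        ]
        for name, val, se in zip(("E", "mu", "sigma", "B"), self.params, self.bse):
            lines.append(f"{name:>8} {val:12.4f} {se:12.4f}")
        lines.append(f"R^2 = {self.r_squared:.4f}   n = {self.n_points}")
        if self.sensitivity is not None:
            hw = ("inf" if np.isinf(self.sensitivity.half_width_db)
                  else f"{self.sensitivity.half_width_db:.1f}")
            lines.append(f"C50 = {self.c50:.2f} dB   HW = {hw} dB   "
                         f"{'monotonic' if self.monotonic else 'O-shaped'}")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        xs = np.linspace(*EVAL_DOMAIN_DB, 400)
        ax.plot(xs, self.predict(xs), "k-")
        if np.isfinite(self.c50):
            ax.axvline(self.c50, color="C3", ls="--", label=f"C50 {self.c50:.1f} dB")
            ax.legend()
        ax.set_xlabel("SPL (dB)")
        ax.set_ylabel("normalized rate")
        return ax


class RateLevelModel:
    """Nonlinear least-squares log-normal fit of a normalized rate-level
    function at one frequency.

    Multi-start fitting: one data-driven start plus seeded Latin-hypercube
    starts over the bounded parameter box; the best-R^2 solution wins, ties
    broken by lowest E.
    """

    def __init__(self, spl_db: np.ndarray, response: np.ndarray,
                 frequency_hz: float = np.nan,
                 upper_bounds: tuple[float, ...] = PARAM_UPPER_BOUNDS):
        self.x = np.asarray(spl_db, float)
        self.y = np.asarray(response, float)
        if self.x.size < 4:
            raise ValueError("rate-level fit needs at least 4 SPL points")
        if np.any(self.x <= 0):
            raise ValueError("SPL values must be positive (log model)")
        self.frequency_hz = frequency_hz
        self.upper = np.asarray(upper_bounds, float)
        self.lower = np.full(4, PARAM_LOWER_BOUND)

    def _data_start(self) -> np.ndarray:
        b0 = max(float(self.y.min()), PARAM_LOWER_BOUND)
        i_pk = int(np.argmax(self.y))
        x_pk = self.x[i_pk]
        sig0 = 0.3
        mu0 = math.log(x_pk) + sig0**2
        amp = max(float(self.y.max() - b0), 1e-3)
        e0 = amp * x_pk * sig0 * math.sqrt(2 * math.pi)
        return np.clip([e0, mu0, sig0, b0], self.lower, self.upper)

    def fit(self, n_starts: int = 8, seed: int = 0,
            eval_domain: tuple[float, float] = EVAL_DOMAIN_DB,
            early_stop_r2: float = 0.995) -> RateLevelResult:
        starts = [self._data_start()]
        if n_starts > 1:
            sampler = qmc.LatinHypercube(d=4, seed=seed)
            box = sampler.random(n_starts - 1)
            # sample log-uniformly between lower and upper bounds
            lo = np.log(np.maximum(self.lower, 1e-6))
            hi = np.log(self.upper)
            starts.extend(np.exp(lo + box * (hi - lo)))

        ss_tot = float(np.sum((self.y - self.y.mean()) ** 2))
        best = None
        for p0 in starts:
            try:
                popt, pcov = optimize.curve_fit(
                    lognormal_rate, self.x, self.y, p0=p0, jac=_lognormal_jac,
                    bounds=(self.lower, self.upper), method="trf", maxfev=400)
            except (RuntimeError, ValueError):
                continue
            resid = self.y - lognormal_rate(self.x, *popt)
            r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
            cand = (r2, -popt[0], popt, pcov)
            if best is None or (cand[0], cand[1]) > (best[0], best[1]):
                best = cand
            if best[0] > early_stop_r2:
                break

        if best is None:
            return RateLevelResult(self.frequency_hz, np.full(4, np.nan), None,
                                   np.nan, False, self.x.size)
        r2, _, popt, pcov = best
        res = RateLevelResult(self.frequency_hz, popt, pcov, r2, True, self.x.size)
        res.sensitivity = derive_sensitivity(popt, eval_domain)
        return res


def fit_rate_level(spl_db: np.ndarray, response: np.ndarray,
                   frequency_hz: float = np.nan, n_starts: int = 8,
                   seed: int = 0) -> RateLevelResult:
    """Functional wrapper around :class:`RateLevelModel`."""
    return RateLevelModel(spl_db, response, frequency_hz).fit(n_starts=n_starts, seed=seed)


def derive_sensitivity(params: np.ndarray,
                       eval_domain: tuple[float, float] = EVAL_DOMAIN_DB
                       ) -> SensitivityMeasures | None:
    """C50, half-width and monotonicity of a fitted curve by root-finding.

    C50 is the rising-phase SPL where the curve reaches baseline + 50% of
    the baseline-to-maximum range.  The half-width is the SPL extent over
    which the curve exceeds 50% of its fitted maximum; if the curve has not
    fallen back below half-maximum by the domain's upper edge it is
    classified monotonic (infinite half-width).
    """
    E, mu, sigma, B = params
    if not np.all(np.isfinite(params)):
        return None
    lo, hi = eval_domain
    # analytic peak of the scaled log-normal
    x_peak = math.exp(mu - sigma**2)
    x_peak = min(max(x_peak, lo), hi)
    f = lambda x: lognormal_rate(np.asarray([x]), E, mu, sigma, B)[0]
    f_peak = f(x_peak)
    rng_half = B + 0.5 * (f_peak - B)
    if f_peak - B <= 1e-12:
        return SensitivityMeasures(np.nan, np.inf, True, x_peak, f_peak)

    # rising-phase C50
    if f(lo) >= rng_half:
        c50 = lo
    else:
        c50 = float(optimize.brentq(lambda x: f(x) - rng_half, lo, x_peak, xtol=1e-6))

    # half-maximum crossings for the half-width
    hw_level = 0.5 * f_peak
    if f(lo) >= hw_level:
        x1 = lo
    elif f_peak < hw_level:
        return SensitivityMeasures(c50, np.inf, True, x_peak, f_peak)
    else:
        x1 = float(optimize.brentq(lambda x: f(x) - hw_level, lo, x_peak, xtol=1e-6))
    if f(hi) >= hw_level or x_peak >= hi:
        return SensitivityMeasures(c50, np.inf, True, x_peak, f_peak)
    x2 = float(optimize.brentq(lambda x: f(x) - hw_level, x_peak, hi, xtol=1e-6))
    return SensitivityMeasures(c50, x2 - x1, False, x_peak, f_peak)


# ---------------------------------------------------------------------------
# characteristic frequency and bandwidth
# ---------------------------------------------------------------------------

@dataclass
class UnitTuning:
    """Per-unit criterion flags, CF and C50 at CF."""

    unit_id: int
    kind: str
    cf_hz: float                     # NaN when no frequency passes
    cf_index: int                    # -1 when undefined
    c50_at_cf_db: float
    o_shaped: bool
    passing: np.ndarray              # boolean per frequency
    criteria: pd.DataFrame           # per-frequency criterion table

    @property
    def has_cf(self) -> bool:
        return self.cf_index >= 0


@dataclass(frozen=True)
class CFCriteria:
    """The four selection criteria plus the automated atypical-fit filter."""

    min_r2: float = 0.7
    rmax_fraction: float = 0.5
    max_side_bands: int = 2          # selectivity: < 2 half-max bands per side
    alpha_anova: float = 0.01
    atypical_rmax_factor: float = 1.5
    c50_margin_db: float = 10.0
    selectivity_mode: str = "frequency"   # or "spl_halfwidth"
    max_halfwidth_db: float = 60.0        # used by the spl_halfwidth mode


def _selectivity_ok(fits: list[RateLevelResult | None], fra: FRA, fi: int,
                    crit: CFCriteria) -> bool:
    """Criterion (3): the response must be frequency-selective.

    Default interpretation: at the candidate's best SPL, fewer than
    ``max_side_bands`` contiguous neighboring bands on each side may respond
    above half of the candidate's fitted maximum.  The alternative SPL-domain
    reading (fitted half-width below a dB cutoff) is available via
    ``selectivity_mode='spl_halfwidth'``.
    """
    fit = fits[fi]
    if crit.selectivity_mode == "spl_halfwidth":
        return fit.half_width < crit.max_halfwidth_db
    spls = fra.spls
    x_best = float(np.clip(fit.sensitivity.peak_db, spls.min(), spls.max()))
    half = 0.5 * fit.rmax
    norm = fra.normalized

    def responds(j: int) -> bool:
        other = fits[j]
        if other is not None and other.converged and other.sensitivity is not None:
            return float(other.predict(np.asarray([x_best]))[0]) > half
        si = int(np.argmin(np.abs(spls - x_best)))
        return norm[j, si] > half

    for side in (-1, 1):
        run = 0
        j = fi + side
        while 0 <= j < len(fits) and responds(j):
            run += 1
            j += side
        if run >= crit.max_side_bands:
            return False
    return True


def select_characteristic_frequency(fits: list[RateLevelResult | None], fra: FRA,
                                    p_per_frequency: np.ndarray,
                                    criteria: CFCriteria = CFCriteria()) -> UnitTuning:
    """Apply the four selection criteria and pick CF = argmin C50.

    Criteria per frequency: R^2 > 0.7; fitted maximum >= 50% of the unit's
    observed maximum (on the normalized scale, >= 0.5); frequency
    selectivity; corrected ANOVA p < 0.01.  An automated atypical-fit filter
    replaces manual curation: fits whose maximum exceeds the observed
    maximum by more than 50%, or whose C50 lies outside the tested SPL range
    +/- 10 dB, are excluded.
    """
    n_f = len(fits)
    spl_lo, spl_hi = float(fra.spls.min()), float(fra.spls.max())
    rows = []
    passing = np.zeros(n_f, bool)
    for fi in range(n_f):
        fit = fits[fi]
        ok_fit = fit is not None and fit.converged and fit.sensitivity is not None
        r2 = fit.r_squared if ok_fit else np.nan
        rmax = fit.rmax if ok_fit else np.nan
        c50 = fit.c50 if ok_fit else np.nan
        c_r2 = bool(ok_fit and r2 > criteria.min_r2)
        c_rmax = bool(ok_fit and rmax >= criteria.rmax_fraction)
        c_anova = bool(p_per_frequency[fi] < criteria.alpha_anova)
        c_sel = bool(ok_fit and _selectivity_ok(fits, fra, fi, criteria)) if c_r2 else False
        atypical = bool(ok_fit and (
            rmax > criteria.atypical_rmax_factor * max(fra.normalized.max(), 1e-12)
            or not np.isfinite(c50)
            or c50 < spl_lo - criteria.c50_margin_db
            or c50 > spl_hi + criteria.c50_margin_db))
        ok = c_r2 and c_rmax and c_anova and c_sel and not atypical and np.isfinite(c50)
        passing[fi] = ok
        rows.append((fra.frequencies[fi], r2, rmax, c50, p_per_frequency[fi],
                     c_r2, c_rmax, c_sel, c_anova, atypical, ok))
    table = pd.DataFrame(rows, columns=["freq_hz", "r2", "rmax", "c50_db", "p_anova",
                                        "pass_r2", "pass_rmax", "pass_selectivity",
                                        "pass_anova", "atypical", "passes"])
    if not passing.any():
        return UnitTuning(fra.unit_id, fra.kind, np.nan, -1, np.nan, False,
                          passing, table)
    c50s = table["c50_db"].to_numpy()
    masked = np.where(passing, c50s, np.inf)
    cf_index = int(np.argmin(masked))
    fit = fits[cf_index]
    return UnitTuning(fra.unit_id, fra.kind, float(fra.frequencies[cf_index]),
                      cf_index, float(c50s[cf_index]),
                      o_shaped=not fit.monotonic, passing=passing, criteria=table)


def tuning_bandwidth(tuning: UnitTuning, fits: list[RateLevelResult | None],
                     fra: FRA, mode: str = "above_C50_10dB",
                     spl_db: float | None = None) -> int:
    """Tuning width in frequency bands.

    ``above_C50_10dB``: contiguous criterion-passing bands around CF whose
    C50 is below C50(CF) + 10 dB.  ``fixed_amplitude``: bands whose observed
    response at ``spl_db`` exceeds half of the row maximum at that SPL.
    """
    if mode == "fixed_amplitude":
        if spl_db is None:
            raise ValueError("fixed_amplitude mode needs spl_db")
        si = int(np.argmin(np.abs(fra.spls - spl_db)))
        row = fra.normalized[:, si]
        if row.max() <= 0:
            return 0
        return int(np.sum(row > 0.5 * row.max()))
    if not tuning.has_cf:
        raise ValueError("bandwidth requires a defined CF")
    cutoff = tuning.c50_at_cf_db + 10.0
    count = 1
    for side in (-1, 1):
        j = tuning.cf_index + side
        while 0 <= j < len(fits):
            if not tuning.passing[j]:
                break
            if not (fits[j].c50 < cutoff):
                break
            count += 1
            j += side
    return count
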