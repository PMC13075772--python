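"""Synthetic behavioral sessions and spike-sorted unit populations.

The generator emulates the statistical structure of a go/no-go auditory
detection experiment and of thalamic single-unit recordings:

* Behavior: an animal presses a lever, a target (pure tone or narrowband
  noise) plays at a random onset 1-3.5 s later at one of eight amplitudes,
  and the animal must release within 700 ms of onset.  Hits follow a
  cumulative-Gaussian psychometric function of amplitude; premature releases
  arise from a constant hazard, which makes the false-alarm rate independent
  of target amplitude by construction.
* Units: inhomogeneous-Poisson spike trains whose trial-averaged rate-level
  function at each frequency is a scaled log-normal of SPL (the same family
  the fitting module assumes), with condition-dependent offsets: narrowband
  noise lowers C50 (higher sensitivity at low level) while pure tones give
  shorter latencies and faster decay.

Every latent quantity is recorded in a ground-truth sidecar that analysis
code never reads; recovery tests compare pipeline estimates against it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .stimuli import PT, NBN, StimulusGrid, build_stimulus_grid

HALF_MAX_LOG_OFFSET = math.sqrt(2.0 * math.log(2.0))  # ~1.1774

#: Behavioral amplitude ladder (dB SPL), as presented in the detection task.
BEHAVIOR_AMPLITUDES = (28.0, 31.5, 35.0, 38.5, 42.5, 46.0, 49.5, 53.0)


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PsychometricParams:
    """Cumulative-Gaussian detection probability in dB.

    p_detect(a) = (1 - lapse) * asymptote * Phi((a - threshold) / slope_sd)
    """

    threshold_db: float
    slope_sd_db: float = 2.2
    lapse: float = 0.01
    asymptote: float = 0.99

    def p_detect(self, amplitude_db: np.ndarray) -> np.ndarray:
        from scipy.stats import norm

        p = (1.0 - self.lapse) * self.asymptote * norm.cdf(
            (np.asarray(amplitude_db, float) - self.threshold_db) / self.slope_sd_db
        )
        return p


@dataclass(frozen=True)
class BehaviorGenConfig:
    """Reference behavioral generator configuration.

    Psychometric midpoints sit one amplitude step apart (PT above NBN), so
    the pipeline's threshold rule recovers detection thresholds of 31.5 dB
    (PT) and 28 dB (NBN): a 3.5 dB difference.  The premature-release hazard
    sets the false-alarm rate (~0.068 per 700 ms window) and hence the
    high-amplitude d' plateau.
    """

    n_animals: int = 8
    n_sessions: int = 10
    trials_per_session: int = 400
    amplitudes: tuple[float, ...] = BEHAVIOR_AMPLITUDES
    onset_window_ms: tuple[float, float] = (1000.0, 3500.0)
    response_window_ms: float = 700.0
    pt_psychometric: PsychometricParams = PsychometricParams(threshold_db=34.5)
    nbn_psychometric: PsychometricParams = PsychometricParams(threshold_db=31.0)
    fa_hazard_per_s: float = 0.10
    abort_hazard_per_s: float = 0.02
    hazard_step_ms: float = 10.0
    #: per-animal strategy scalar in [-1, 1]: positive values trade misses for
    #: false alarms (hazard multiplied by exp(strategy_fa_scale * s), detection
    #: threshold shifted by -strategy_threshold_db * s).
    strategy_fa_scale: float = 1.3
    strategy_threshold_db: float = 1.5
    reaction_mean_ms: float = 350.0
    reaction_sd_ms: float = 110.0

    def __post_init__(self) -> None:
        for psy in (self.pt_psychometric, self.nbn_psychometric):
            if not (0 <= psy.lapse <= 1 and 0 < psy.asymptote <= 1):
                raise ValueError("psychometric probabilities must lie in [0, 1]")
        if self.fa_hazard_per_s < 0 or self.abort_hazard_per_s < 0:
            raise ValueError("hazards must be non-negative")
        if self.n_animals < 1 or self.n_sessions < 1 or self.trials_per_session < 1:
            raise ValueError("need at least one animal, session and trial")


def _first_hazard_event(rng: np.random.Generator, p_step: float, n_steps: np.ndarray,
                        step_ms: float) -> np.ndarray:
    """Time (ms) of the first per-step Bernoulli event, inf if none occurs
    within ``n_steps`` steps.  Vectorized geometric sampling."""
    out = np.full(n_steps.shape, np.inf)
    if p_step <= 0:
        return out
    k = rng.geometric(p_step, size=n_steps.shape)  # 1-based step of first event
    hit = k <= n_steps
    # event placed uniformly inside its 10 ms step
    out[hit] = (k[hit] - 1) * step_ms + rng.uniform(0, step_ms, size=int(hit.sum()))
    return out


def generate_behavior_sessions(config: BehaviorGenConfig, seed: int = 0
                               ) -> tuple[pd.DataFrame, dict]:
    """Simulate go/no-go sessions; returns a trial table and ground truth.

    One row per trial: ``trial_id, animal, session, press_ms, onset_ms, kind,
    spl_db, release_ms`` (NaN when the lever was held to the end).  Lever
    press defines time zero.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    step = config.hazard_step_ms
    lo, hi = config.onset_window_ms
    strategies = np.linspace(-1.0, 1.0, config.n_animals) if config.n_animals > 1 else np.zeros(1)

    rows = []
    truth_trials = []
    trial_counter = 0
    for animal in range(config.n_animals):
        s = strategies[animal]
        fa_hazard = config.fa_hazard_per_s * math.exp(config.strategy_fa_scale * s)
        thr_shift = -config.strategy_threshold_db * s
        p_fa_step = 1.0 - math.exp(-fa_hazard * step / 1000.0)
        p_ab_step = 1.0 - math.exp(-config.abort_hazard_per_s * step / 1000.0)
        for session in range(config.n_sessions):
            n = config.trials_per_session
            onset = rng.uniform(lo, hi, n)
            kind = np.where(rng.random(n) < 0.5, PT, NBN)
            spl = rng.choice(config.amplitudes, size=n)

            # premature releases: abort hazard before the first scoring window,
            # waiting (false-alarm) hazard from there until target onset
            n_ab_steps = np.full(n, int(lo / step))
            t_ab = _first_hazard_event(rng, p_ab_step, n_ab_steps, step)
            n_fa_steps = np.floor((onset - lo) / step).astype(int)
            t_fa = lo + _first_hazard_event(rng, p_fa_step, n_fa_steps, step)
            premature = np.minimum(t_ab, t_fa)

            # detection at target onset
            p_pt = PsychometricParams(
                threshold_db=config.pt_psychometric.threshold_db + thr_shift,
                slope_sd_db=config.pt_psychometric.slope_sd_db,
                lapse=config.pt_psychometric.lapse,
                asymptote=config.pt_psychometric.asymptote,
            ).p_detect(spl)
            p_nbn = PsychometricParams(
                threshold_db=config.nbn_psychometric.threshold_db + thr_shift,
                slope_sd_db=config.nbn_psychometric.slope_sd_db,
                lapse=config.nbn_psychometric.lapse,
                asymptote=config.nbn_psychometric.asymptote,
            ).p_detect(spl)
            p_det = np.where(kind == PT, p_pt, p_nbn)
            detected = rng.random(n) < p_det
            reaction = np.clip(
                rng.normal(config.reaction_mean_ms, config.reaction_sd_ms, n),
                100.0, config.response_window_ms - 10.0,
            )

            # undetected targets: the animal keeps waiting, hazard continues
            n_late_steps = np.full(n, int(1500.0 / step))
            t_late = onset + _first_hazard_event(rng, p_fa_step, n_late_steps, step)

            release = np.where(premature < onset, premature,
                               np.where(detected, onset + reaction, t_late))
            release = np.where(np.isinf(release), np.nan, release)

            for i in range(n):
                rows.append((trial_counter + i, animal, session, 0.0, onset[i],
                             kind[i], spl[i], release[i]))
                truth_trials.append(bool(detected[i] and premature[i] >= onset[i]))
            trial_counter += n

    df = pd.DataFrame(rows, columns=["trial_id", "animal", "session", "press_ms",
                                     "onset_ms", "kind", "spl_db", "release_ms"])
    truth = {
        "detected": truth_trials,
        "strategy": strategies.tolist(),
        "config": _config_dict(config),
    }
    return df, truth


# ---------------------------------------------------------------------------
# units
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitGenConfig:
    """Reference single-unit generator configuration.

    Per-kind offsets are calibrated to the recorded population: the
    narrowband-noise C50 sits 2.2 dB below the pure-tone C50 (PT median
    57.7 dB), NBN latency is 3 ms longer (PT median 23 ms), and NBN decay
    constants are ~35% slower.  CF assignment is sparse below 1 kHz.
    """

    n_units: int = 200
    trials_per_condition: int = 15
    #: sampling weights over the 11 grid frequencies, low to high
    cf_weights: tuple[float, ...] = (0.02, 0.04, 0.08, 0.10, 0.10, 0.10,
                                     0.12, 0.12, 0.12, 0.10, 0.10)
    baseline_median_sp_s: float = 2.0
    baseline_log_sd: float = 0.6
    rmax_median_sp_s: float = 48.0
    rmax_log_sd: float = 0.30
    c50_cf_mean_db: float = 57.7
    c50_cf_sd_db: float = 5.0
    c50_cf_range_db: tuple[float, float] = (46.0, 70.0)
    c50_growth_db_per_band: float = 6.0
    taper_sd_bands: float = 1.8
    sigma_shape_range: tuple[float, float] = (0.13, 0.19)
    o_shape_probability: float = 0.035
    o_sigma_shape_range: tuple[float, float] = (0.09, 0.13)
    latency_mean_ms: float = 23.0
    latency_sd_ms: float = 4.0
    tau_median_ms: float = 12.0
    tau_log_sd: float = 0.55
    nbn_c50_shift_db: float = -2.2
    nbn_latency_shift_ms: float = 3.0
    nbn_tau_factor: float = 1.6
    pt_peak_gain: float = 1.0
    epoch_ms: tuple[float, float] = (-150.0, 250.0)  # relative to stimulus onset
    n_penetrations: int = 22
    insertion_angle_deg: float = 60.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.o_shape_probability <= 1.0):
            raise ValueError("O-shape probability must lie in [0, 1]")
        if not (0.0 < self.tau_median_ms <= 1000.0):
            raise ValueError("tau must lie in (0, 1000] ms")


def lognormal_rate_curve(spl_db: np.ndarray, c50_db: float, sigma_shape: float) -> np.ndarray:
    """Normalized log-normal rate-level shape g(x) in [0, 1].

    In y = log(x) the scaled log-normal E/(x*sigma*sqrt(2pi)) *
    exp(-(log x - mu)^2 / (2 sigma^2)) is an exact Gaussian with peak at
    y* = mu - sigma^2 and standard deviation sigma, so the rising half-max
    point is x50 = exp(y* - sigma * sqrt(2 ln 2)).  The generator inverts
    that closed form: given the target C50 it places the peak at
    log(C50) + sigma * sqrt(2 ln 2).
    """
    x = np.asarray(spl_db, float)
    y_star = math.log(c50_db) + sigma_shape * HALF_MAX_LOG_OFFSET
    with np.errstate(divide="ignore"):
        y = np.where(x > 0, np.log(np.maximum(x, 1e-12)), -np.inf)
    return np.exp(-((y - y_star) ** 2) / (2.0 * sigma_shape**2))


def _draw_unit_params(config: UnitGenConfig, grid: StimulusGrid,
                      rng: np.random.Generator) -> dict:
    n = config.n_units
    freqs = np.asarray(grid.center_frequencies)
    w = np.asarray(config.cf_weights, float)[: len(freqs)]
    w = w / w.sum()
    cf_idx = rng.choice(len(freqs), size=n, p=w)
    baseline = np.exp(rng.normal(math.log(config.baseline_median_sp_s),
                                 config.baseline_log_sd, n))
    rmax = np.exp(rng.normal(math.log(config.rmax_median_sp_s),
                             config.rmax_log_sd, n))
    c50_pt = np.clip(rng.normal(config.c50_cf_mean_db, config.c50_cf_sd_db, n),
                     *config.c50_cf_range_db)
    o_shaped = rng.random(n) < config.o_shape_probability
    sigma_shape = np.where(
        o_shaped,
        rng.uniform(*config.o_sigma_shape_range, n),
        rng.uniform(*config.sigma_shape_range, n),
    )
    latency_pt = np.clip(rng.normal(config.latency_mean_ms, config.latency_sd_ms, n), 8.0, 60.0)
    tau_pt = np.clip(np.exp(rng.normal(math.log(config.tau_median_ms), config.tau_log_sd, n)),
                     3.0, 80.0)
    penetration = rng.integers(0, config.n_penetrations, size=n)
    return dict(cf_idx=cf_idx, baseline=baseline, rmax=rmax, c50_pt=c50_pt,
                o_shaped=o_shaped, sigma_shape=sigma_shape, latency_pt=latency_pt,
                tau_pt=tau_pt, penetration=penetration)


def generate_unit_population(config: UnitGenConfig, grid: StimulusGrid | None = None,
                             seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Simulate the spike-sorted unit population for both stimulus kinds.

    Returns a long-format spike table (one row per spike: ``unit_id,
    penetration_id, depth_um, trial, kind, freq_hz, spl_db, spike_ms`` with
    spike times relative to stimulus onset, epoch ``config.epoch_ms``) and a
    ground-truth sidecar dict.  Deterministic under ``seed``.
    """
    if grid is None:
        grid = build_stimulus_grid()
    rng = np.random.default_rng(seed)
    params = _draw_unit_params(config, grid, rng)
    freqs = np.asarray(grid.center_frequencies)
    spls = np.asarray(grid.spl_levels)
    n_f, n_s, n_t = len(freqs), len(spls), config.trials_per_condition
    epoch_lo, epoch_hi = config.epoch_ms
    epoch_s = (epoch_hi - epoch_lo) / 1000.0

    cols = {k: [] for k in ("unit_id", "penetration_id", "depth_um", "trial",
                            "kind", "freq_hz", "spl_db", "spike_ms")}
    truth_units = []

    band_idx = np.arange(n_f)
    for u in range(config.n_units):
        cfi = int(params["cf_idx"][u])
        dist = np.abs(band_idx - cfi)
        taper = np.exp(-(dist**2) / (2.0 * config.taper_sd_bands**2))
        depth_um = float(rng.uniform(200.0, 3800.0))
        unit_truth = {
            "unit_id": u,
            "cf_hz": float(freqs[cfi]),
            "baseline_sp_s": float(params["baseline"][u]),
            "rmax_sp_s": float(params["rmax"][u]),
            "o_shaped": bool(params["o_shaped"][u]),
            "sigma_shape": float(params["sigma_shape"][u]),
            "penetration_id": int(params["penetration"][u]),
            "depth_um": depth_um,
            "c50_db": {}, "latency_ms": {}, "tau_ms": {},
        }
        for kind in (PT, NBN):
            c50_cf = params["c50_pt"][u] + (config.nbn_c50_shift_db if kind == NBN else 0.0)
            latency = params["latency_pt"][u] + (config.nbn_latency_shift_ms if kind == NBN else 0.0)
            tau = params["tau_pt"][u] * (config.nbn_tau_factor if kind == NBN else 1.0)
            gain = config.pt_peak_gain if kind == PT else 1.0
            c50_per_f = c50_cf + config.c50_growth_db_per_band * dist
            # expected evoked spike count per trial, per condition
            shape = np.stack([lognormal_rate_curve(spls, c, params["sigma_shape"][u])
                              for c in c50_per_f])  # (n_f, n_s)
            n_ev = gain * params["rmax"][u] * 0.090 * taper[:, None] * shape

            unit_truth["c50_db"][kind] = [float(c) for c in c50_per_f]
            unit_truth["latency_ms"][kind] = float(latency)
            unit_truth["tau_ms"][kind] = float(tau)

            # vectorized Poisson spike generation over all conditions/trials
            fi_g, si_g, ti_g = np.meshgrid(np.arange(n_f), np.arange(n_s),
                                           np.arange(n_t), indexing="ij")
            fi_g, si_g, ti_g = fi_g.ravel(), si_g.ravel(), ti_g.ravel()
            lam_base = params["baseline"][u] * epoch_s
            n_base = rng.poisson(lam_base, size=fi_g.size)
            n_evk = rng.poisson(np.broadcast_to(n_ev[:, :, None], (n_f, n_s, n_t)).ravel())
            tot_b, tot_e = int(n_base.sum()), int(n_evk.sum())
            t_base = rng.uniform(epoch_lo, epoch_hi, tot_b)
            idx_b = np.repeat(np.arange(fi_g.size), n_base)
            t_evk = latency + rng.exponential(tau, tot_e)
            idx_e = np.repeat(np.arange(fi_g.size), n_evk)
            keep = t_evk < epoch_hi
            t_evk, idx_e = t_evk[keep], idx_e[keep]
            times = np.concatenate([t_base, t_evk])
            idx = np.concatenate([idx_b, idx_e])
            k = times.size
            if k:
                cols["unit_id"].append(np.full(k, u))
                cols["penetration_id"].append(np.full(k, params["penetration"][u]))
                cols["depth_um"].append(np.full(k, depth_um))
                cols["trial"].append(ti_g[idx])
                cols["kind"].append(np.full(k, kind, dtype=object))
                cols["freq_hz"].append(freqs[fi_g[idx]])
                cols["spl_db"].append(spls[si_g[idx]])
                cols["spike_ms"].append(times)
        truth_units.append(unit_truth)

    df = pd.DataFrame({k: np.concatenate(v) if v else np.array([]) for k, v in cols.items()})
    for c in ("unit_id", "trial", "penetration_id"):
        df[c] = df[c].astype(int)
    truth = {"units": truth_units, "config": _config_dict(config)}
    return df, truth


def generate_penetration_geometry(truth: dict, n_negative: int = 9, n_positive: int = 1,
                                  seed: int = 0, angle_deg: float = 60.0,
                                  gradient_log2_per_mm: float = 2.0,
                                  jitter_log2: float = 0.35) -> pd.DataFrame:
    """Assign along-shank distances so that a configured number of
    penetrations carry a tonotopic gradient.

    For gradient penetrations, units are re-ordered along the shank so that
    log2(CF) decreases (negative class) or increases (positive class) with
    distance from the probe tip; the rest are shuffled.  Returns a geometry
    table: ``penetration_id, angle_deg, unit_id, dist_from_tip_um``.
    """
    rng = np.random.default_rng(seed)
    units = truth["units"]
    pen_ids = sorted({u["penetration_id"] for u in units})
    classes = {}
    order = rng.permutation(pen_ids)
    for i, pid in enumerate(order):
        classes[pid] = "neg" if i < n_negative else ("pos" if i < n_negative + n_positive
                                                     else "none")
    rows = []
    for pid in pen_ids:
        members = [u for u in units if u["penetration_id"] == pid]
        if not members:
            continue
        log2cf = np.log2([u["cf_hz"] for u in members])
        n = len(members)
        span_um = 1000.0 * (log2cf.max() - log2cf.min() + 1.0) / gradient_log2_per_mm
        span_um = max(span_um, 400.0)
        if classes[pid] == "neg":
            rank = np.argsort(np.argsort(-(log2cf + rng.normal(0, jitter_log2, n))))
        elif classes[pid] == "pos":
            rank = np.argsort(np.argsort(log2cf + rng.normal(0, jitter_log2, n)))
        else:
            rank = rng.permutation(n)
        dist = 200.0 + rank / max(n - 1, 1) * span_um + rng.uniform(-40, 40, n)
        for u, d in zip(members, dist):
            rows.append((pid, angle_deg, u["unit_id"], float(max(d, 0.0)), classes[pid]))
    return pd.DataFrame(rows, columns=["penetration_id", "angle_deg", "unit_id",
                                       "dist_from_tip_um", "true_class"])


def _config_dict(cfg) -> dict:
    d = asdict(cfg)
    return json.loads(json.dumps(d, default=list))


def save_ground_truth(truth: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh)
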