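"""End-to-end orchestration: synthesize -> score -> fit -> discriminate ->
decode -> report.

The reference configuration encodes the calibrated group-level values in
one place (behavioral thresholds 31.5/28 dB for PT/NBN, plateau d' ~ 3.3,
NBN C50 offset -2.2 dB, PT/NBN latencies 23/26 ms, population C50 medians
near 57.7/55.5 dB); recovery analyses re-estimate them through the full
analysis chain with no access to ground truth.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, decoding, discrim, dynamics, fra, synth, tonotopy
from .stimuli import PT, NBN, StimulusGrid, build_stimulus_grid

log = logging.getLogger("audthal")


# ---------------------------------------------------------------------------
# behavioral arm
# ---------------------------------------------------------------------------

def run_behavior_arm(config: synth.BehaviorGenConfig | None = None, seed: int = 0
                     ) -> dict:
    """Generate sessions, score them, and recover detection thresholds."""
    config = config or synth.BehaviorGenConfig()
    trials, truth = synth.generate_behavior_sessions(config, seed=seed)
    outcomes = behavior.classify_trials(trials, seed=seed + 1)
    summary = behavior.sdt_summary(outcomes)
    per_animal = behavior.aggregate_dprime(summary)
    thresholds = behavior.detection_thresholds(per_animal)
    lowest = min(config.amplitudes)
    low = per_animal[per_animal["spl_db"] == lowest]
    strat = {}
    if config.n_animals >= 3:
        for kind, g in low.groupby("kind"):
            g = g.sort_values("animal")
            strat[kind] = behavior.strategy_regression(g["MSR"].to_numpy(),
                                                       g["FAR"].to_numpy())
    log.info("behavior arm: %d trials, %d scored",
             len(trials), int((outcomes["label"] != behavior.ABORT).sum()))
    return {"trials": trials, "outcomes": outcomes, "summary": summary,
            "per_animal": per_animal, "thresholds": thresholds,
            "strategy": strat, "truth": truth}


# ---------------------------------------------------------------------------
# neural arm
# ---------------------------------------------------------------------------

def analyze_units(spikes: pd.DataFrame, grid: StimulusGrid,
                  kinds: tuple[str, ...] = (PT, NBN), n_starts: int = 8,
                  seed: int = 0, criteria: fra.CFCriteria = fra.CFCriteria()
                  ) -> dict:
    """FRA -> responsiveness -> per-frequency log-normal fits -> CF selection
    for every unit and stimulus kind.

    Returns per-(unit, kind) FRAs, fit lists, responsiveness results and a
    tidy tuning table.
    """
    unit_ids = np.sort(spikes["unit_id"].unique())
    fras, fits, resp, tunings = {}, {}, {}, {}
    rows = []
    for u in unit_ids:
        for kind in kinds:
            f = fra.compute_fra(spikes, grid, int(u), kind)
            r = fra.detect_responsive(f)
            fras[(u, kind)], resp[(u, kind)] = f, r
            tun = None
            fit_list: list = [None] * len(grid.center_frequencies)
            if r.responsive and not f.degenerate:
                norm = f.normalized
                for fi in range(len(grid.center_frequencies)):
                    # frequencies failing the ANOVA criterion can never pass
                    # CF selection; a reduced start budget suffices there
                    k = n_starts if r.p_per_frequency[fi] < criteria.alpha_anova else 2
                    fit_list[fi] = fra.RateLevelModel(
                        f.spls, norm[fi], frequency_hz=f.frequencies[fi]
                    ).fit(n_starts=k, seed=seed + fi)
                tun = fra.select_characteristic_frequency(
                    fit_list, f, r.p_per_frequency, criteria)
            fits[(u, kind)] = fit_list
            tunings[(u, kind)] = tun
            rows.append({
                "unit_id": int(u), "kind": kind, "responsive": r.responsive,
                "has_cf": bool(tun is not None and tun.has_cf),
                "cf_hz": tun.cf_hz if tun is not None else np.nan,
                "c50_at_cf_db": tun.c50_at_cf_db if tun is not None else np.nan,
                "o_shaped": bool(tun.o_shaped) if tun is not None else False,
            })
    table = pd.DataFrame(rows)
    log.info("neural arm: %d units, %d responsive cells, %d with CF",
             len(unit_ids), int(table["responsive"].sum()), int(table["has_cf"].sum()))
    return {"fras": fras, "fits": fits, "responsiveness": resp,
            "tunings": tunings, "table": table}


def paired_c50_differences(analysis: dict) -> pd.DataFrame:
    """PT-minus-NBN C50 at CF for units with a consistent CF across kinds."""
    t = analysis["table"]
    pt = t[(t["kind"] == PT) & t["has_cf"]].set_index("unit_id")
    nbn = t[(t["kind"] == NBN) & t["has_cf"]].set_index("unit_id")
    common = pt.index.intersection(nbn.index)
    rows = []
    for u in common:
        if pt.loc[u, "cf_hz"] == nbn.loc[u, "cf_hz"]:
            rows.append({"unit_id": int(u), "cf_hz": float(pt.loc[u, "cf_hz"]),
                         "c50_pt": float(pt.loc[u, "c50_at_cf_db"]),
                         "c50_nbn": float(nbn.loc[u, "c50_at_cf_db"]),
                         "diff_db": float(pt.loc[u, "c50_at_cf_db"]
                                          - nbn.loc[u, "c50_at_cf_db"])})
    return pd.DataFrame(rows)


def timing_summaries(spikes: pd.DataFrame, grid: StimulusGrid, analysis: dict
                     ) -> pd.DataFrame:
    """Latency, peak rate and ISI decay constant at each unit's best stimulus."""
    rows = []
    for (u, kind), tun in analysis["tunings"].items():
        if tun is None or not tun.has_cf:
            continue
        f = analysis["fras"][(u, kind)]
        freq, spl = dynamics.best_stimulus_condition(f, tun)
        times, trials = dynamics.condition_spikes(spikes, int(u), kind, freq, spl)
        psth = dynamics.compute_psth(times, trials, grid.repetitions,
                                     unit_id=int(u), kind=kind)
        isi = dynamics.fit_isi_decay(times, trials, unit_id=int(u), kind=kind)
        rows.append({"unit_id": int(u), "kind": kind, "best_freq_hz": freq,
                     "best_spl_db": spl, "latency_ms": psth.time_to_peak_ms,
                     "peak_rate_sp_s": psth.peak_rate,
                     "tau_s": isi.tau_s if isi.converged else np.nan,
                     "tau_r2": isi.r_squared, "n_isi": isi.n_isi})
    return pd.DataFrame(rows)


def discriminability_curves(spikes: pd.DataFrame, grid: StimulusGrid,
                            analysis: dict) -> pd.DataFrame:
    """Per-unit d' vs SPL re-indexed by offset from C50, both kinds."""
    frames = []
    tensors: dict = {}
    for (u, kind), tun in analysis["tunings"].items():
        if tun is None or not tun.has_cf:
            continue
        if kind not in tensors:
            units = np.sort(spikes["unit_id"].unique())
            tensors[kind] = {
                "units": units,
                "ev": decoding.response_tensor(spikes, grid, units, kind,
                                               discrim.EVOKED_WINDOW_MS),
                "ba": decoding.response_tensor(spikes, grid, units, kind,
                                               discrim.BASELINE_WINDOW_MS),
            }
        row = int(np.searchsorted(tensors[kind]["units"], u))
        frames.append(discrim.dprime_vs_level_from_tensors(
            tensors[kind]["ev"][row], tensors[kind]["ba"][row],
            grid, tun, tun.c50_at_cf_db))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def run_decoding(spikes: pd.DataFrame, grid: StimulusGrid, analysis: dict,
                 kinds: tuple[str, ...] = (PT, NBN), n_pops: int = 10,
                 size: int = 50, seed: int = 0, shuffle: bool = False,
                 window_ms: tuple[float, float] = decoding.DEFAULT_WINDOW_MS,
                 tuning_budget: int = 20) -> pd.DataFrame:
    t = analysis["table"]
    rows = []
    for kind in kinds:
        pool = t[(t["kind"] == kind) & t["responsive"]]["unit_id"].to_numpy()
        tensor = decoding.response_tensor(spikes, grid, pool, kind, window_ms)
        pops = decoding.build_pseudopopulations({kind: tensor}, {kind: pool},
                                                size=size, n_pops=n_pops,
                                                seed=seed, window_ms=window_ms)
        for pop in pops:
            res = decoding.decode_frequency(pop, kind, shuffle=shuffle,
                                            seed=seed + 101 + pop.population_id,
                                            tuning_budget=tuning_budget)
            rows.append({"population_id": pop.population_id, "kind": kind,
                         "window_lo_ms": window_ms[0], "window_hi_ms": window_ms[1],
                         "shuffled": shuffle, "accuracy": res.accuracy,
                         "n_test": res.n_test, "C": res.C})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reference experiment
# ---------------------------------------------------------------------------

def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_reference_experiment(seed: int = 0, outdir: str | Path = "results",
                             behavior_config: synth.BehaviorGenConfig | None = None,
                             unit_config: synth.UnitGenConfig | None = None,
                             n_pops: int = 3, pop_size: int = 30,
                             n_starts: int = 4, decode_budget: int = 6) -> dict:
    """Single-command end-to-end run on synthetic data.

    Executes the behavioral and neural arms, writes summary tables and a
    JSON report plus a manifest of file digests.  Any stage failure raises
    with the stage name attached.  Identical seeds give identical outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = build_stimulus_grid()
    unit_config = unit_config or synth.UnitGenConfig(n_units=60)
    manifest: dict = {"seed": seed, "stages": {}}
    report: dict = {}

    stage = "behavior"
    try:
        beh = run_behavior_arm(behavior_config, seed=seed)
        beh["summary"].to_csv(outdir / "behavior_summary.csv", index=False)
        beh["per_animal"].to_csv(outdir / "behavior_per_animal.csv", index=False)
        report["thresholds"] = {k: v for k, v in beh["thresholds"].items()
                                if k != "per_amplitude"}
        report["strategy"] = {k: {"slope": v.slope, "r2": v.r_squared, "p": v.p_value}
                              for k, v in beh["strategy"].items()}

        stage = "synthesize-units"
        spikes, truth = synth.generate_unit_population(unit_config, grid, seed=seed + 7)
        synth.save_ground_truth(truth, str(outdir / "ground_truth.json"))

        stage = "fra-fitting"
        analysis = analyze_units(spikes, grid, n_starts=n_starts, seed=seed)
        analysis["table"].to_csv(outdir / "tuning.csv", index=False)
        paired = paired_c50_differences(analysis)
        paired.to_csv(outdir / "paired_c50.csv", index=False)
        report["median_paired_c50_diff_db"] = (float(paired["diff_db"].median())
                                               if len(paired) else np.nan)
        for kind in (PT, NBN):
            vals = analysis["table"].query("kind == @kind and has_cf")["c50_at_cf_db"]
            report[f"median_c50_{kind.lower()}_db"] = (float(vals.median())
                                                       if len(vals) else np.nan)

        stage = "temporal-dynamics"
        timing = timing_summaries(spikes, grid, analysis)
        timing.to_csv(outdir / "timing.csv", index=False)
        for kind in (PT, NBN):
            sub = timing[timing["kind"] == kind]
            report[f"median_latency_{kind.lower()}_ms"] = (
                float(sub["latency_ms"].median()) if len(sub) else np.nan)

        stage = "discriminability"
        curves = discriminability_curves(spikes, grid, analysis)
        curves.to_csv(outdir / "dprime.csv", index=False)
        if len(curves):
            pop_curve = discrim.population_dprime_curve(curves)
            pop_curve.to_csv(outdir / "dprime_population.csv", index=False)

        stage = "decoding"
        dec = run_decoding(spikes, grid, analysis, n_pops=n_pops, size=pop_size,
                           seed=seed, tuning_budget=decode_budget)
        dec.to_csv(outdir / "decoding.csv", index=False)
        report["decoding_accuracy"] = {
            kind: float(dec[dec["kind"] == kind]["accuracy"].mean())
            for kind in dec["kind"].unique()}

        stage = "tonotopy"
        geom = synth.generate_penetration_geometry(truth, seed=seed + 11,
                                                   n_negative=max(1, unit_config.n_penetrations * 9 // 22))
        fits = tonotopy.fit_all_penetrations(
            analysis["table"][analysis["table"]["kind"] == PT], geom)
        report["tonotopy"] = tonotopy.aggregate_tonotopy(fits)
    except Exception as exc:                     # noqa: BLE001
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    for p in sorted(outdir.glob("*.csv")) + [outdir / "report.json"]:
        manifest["stages"][p.name] = _digest(p)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return {"report": report, "manifest": manifest, "outdir": outdir}
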