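"""Stimulus condition grid, narrowband-noise band geometry and waveform synthesis.

The experimental protocol probes the auditory system with two parametric
stimulus sets matched in frequency, level and duration: pure tones (PT) and
half-octave narrowband noise (NBN).  Conditions form a lattice of 11
half-octave-spaced center frequencies x 8 sound pressure levels x 2 stimulus
kinds.  This module builds that lattice, computes the NBN band edges that tile
the frequency axis without gap or overlap, synthesizes the waveforms, and
provides the Fletcher critical-band conversion.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
import numpy as np
from scipy import signal

PT = "PT"
NBN = "NBN"

#: Nominal center frequencies (Hz) of the recording protocol.  These are the
#: rounded half-octave values actually presented, not exact sqrt(2) multiples.
CANONICAL_CENTERS = (560, 800, 1120, 1600, 2240, 3150, 4500, 6300, 9000, 12500, 18000)

#: Behavioral target band: NBN centered at 8.5 kHz with verbatim 7-10 kHz edges.
BEHAVIORAL_BAND = (8500.0, 7000.0, 10000.0)

#: Reference pressure in arbitrary amplitude units; only relative levels matter.
REFERENCE_PRESSURE = 20e-6


@dataclass(frozen=True)
class StimulusGrid:
    """The frequency x SPL x kind condition lattice.

    Parameters are the presentation parameters shared by every condition:
    stimulus duration and on/off ramp (ms), the inter-trial-interval range
    (ms) and the number of repetitions per condition.
    """

    center_frequencies: tuple[float, ...]
    spl_levels: tuple[float, ...]
    kinds: tuple[str, ...] = (PT, NBN)
    duration_ms: float = 100.0
    ramp_ms: float = 10.0
    iti_range_ms: tuple[float, float] = (200.0, 300.0)
    repetitions: int = 15

    def __post_init__(self) -> None:
        f = np.asarray(self.center_frequencies, float)
        s = np.asarray(self.spl_levels, float)
        if f.size == 0 or np.any(np.diff(f) <= 0):
            raise ValueError("center frequencies must be non-empty and strictly increasing")
        if s.size > 1:
            steps = np.diff(s)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
                raise ValueError("SPL levels must increase with a constant step")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.duration_ms <= 2 * self.ramp_ms:
            raise ValueError("duration must exceed twice the ramp")

    @property
    def n_conditions(self) -> int:
        return len(self.center_frequencies) * len(self.spl_levels) * len(self.kinds)

    @property
    def spl_step(self) -> float:
        s = self.spl_levels
        return float(s[1] - s[0]) if len(s) > 1 else 0.0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "StimulusGrid":
        d = json.loads(text)
        d["center_frequencies"] = tuple(d["center_frequencies"])
        d["spl_levels"] = tuple(d["spl_levels"])
        d["kinds"] = tuple(d["kinds"])
        d["iti_range_ms"] = tuple(d["iti_range_ms"])
        return cls(**d)


@dataclass(frozen=True)
class NBNBand:
    """Half-octave noise band geometry around one grid center."""

    center: float
    low_edge: float
    high_edge: float
    filter_order: int = 2

    def __post_init__(self) -> None:
        if not (self.low_edge < self.center < self.high_edge):
            raise ValueError("band edges must bracket the center")

    @property
    def width(self) -> float:
        return self.high_edge - self.low_edge


def build_stimulus_grid(
    low_bound: float = 500.0,
    high_bound: float = 22000.0,
    anchor: float = 560.0,
    spl_min: float = 40.0,
    spl_max: float = 75.0,
    spl_step: float = 5.0,
    exact: bool = False,
    **grid_kwargs,
) -> StimulusGrid:
    """Construct the condition lattice of half-octave bands and SPL levels.

    By default returns the protocol's canonical nominal centers (560 ... 18000
    Hz), which are rounded rather than exact sqrt(2) multiples.  With
    ``exact=True`` the centers are true ``anchor * 2**(k/2)`` values; in both
    modes only centers inside ``[low_bound, high_bound]`` are kept.
    """
    if not (low_bound < anchor <= high_bound):
        raise ValueError("anchor must lie inside (low_bound, high_bound]")
    if spl_step <= 0:
        raise ValueError("spl_step must be positive")

    if exact:
        centers = []
        k = 0
        while True:
            f = anchor * 2.0 ** (k / 2.0)
            if f > high_bound:
                break
            if f >= low_bound:
                centers.append(f)
            k += 1
        k = -1
        while True:
            f = anchor * 2.0 ** (k / 2.0)
            if f < low_bound:
                break
            centers.insert(0, f)
            k -= 1
    else:
        centers = [float(f) for f in CANONICAL_CENTERS if low_bound <= f <= high_bound]

    if not centers:
        raise ValueError("no center frequency fits inside the requested bounds")

    n_spl = int(math.floor((spl_max - spl_min) / spl_step + 1e-9)) + 1
    spls = tuple(spl_min + i * spl_step for i in range(n_spl))
    return StimulusGrid(center_frequencies=tuple(centers), spl_levels=spls, **grid_kwargs)


def nbn_band_edges(grid: StimulusGrid, center: float, behavioral_override: bool = True) -> NBNBand:
    """Edges of the half-octave noise band around ``center``.

    Grid bands get edges at the geometric midpoints to their neighbors so the
    11 bands tile the axis contiguously; the end bands are extended a quarter
    octave outward.  The behavioral band (center 8.5 kHz) is a verbatim
    override with 7-10 kHz edges, since the protocol defines it that way
    rather than geometrically.
    """
    if behavioral_override and math.isclose(center, BEHAVIORAL_BAND[0]):
        c, lo, hi = BEHAVIORAL_BAND
        return NBNBand(center=c, low_edge=lo, high_edge=hi)
    freqs = grid.center_frequencies
    matches = [i for i, f in enumerate(freqs) if math.isclose(f, center)]
    if not matches:
        raise ValueError(f"{center} Hz is not a grid center and no override applies")
    i = matches[0]
    low = math.sqrt(freqs[i - 1] * freqs[i]) if i > 0 else freqs[i] / 2.0 ** 0.25
    high = math.sqrt(freqs[i] * freqs[i + 1]) if i < len(freqs) - 1 else freqs[i] * 2.0 ** 0.25
    return NBNBand(center=float(center), low_edge=low, high_edge=high)


def _cosine_ramp(n_total: int, n_ramp: int) -> np.ndarray:
    """Raised-cosine on/off envelope."""
    env = np.ones(n_total)
    if n_ramp > 0:
        t = np.linspace(0.0, np.pi / 2.0, n_ramp, endpoint=False)
        env[:n_ramp] = np.sin(t) ** 2
        env[-n_ramp:] = env[:n_ramp][::-1]
    return env


def spl_to_rms(spl_db: float, reference: float = REFERENCE_PRESSURE) -> float:
    return reference * 10.0 ** (spl_db / 20.0)


def rms_to_spl(rms: float, reference: float = REFERENCE_PRESSURE) -> float:
    return 20.0 * math.log10(rms / reference)


def synthesize_stimulus(
    kind: str,
    band: NBNBand | float,
    duration_ms: float = 100.0,
    fs: float = 96000.0,
    target_spl: float = 60.0,
    ramp_ms: float = 10.0,
    seed: int = 0,
) -> np.ndarray:
    """Synthesize one PT or NBN stimulus waveform.

    PT is a sine at the tone frequency; NBN is white noise passed (forward
    only, i.e. causally) through a second-order Butterworth bandpass at the
    band edges.  Both receive 10 ms raised-cosine ramps and are RMS-scaled to
    ``target_spl`` re the configured reference pressure.
    """
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    if duration_ms <= 2 * ramp_ms:
        raise ValueError("duration must exceed twice the ramp")
    n = int(round(duration_ms / 1000.0 * fs))
    t = np.arange(n) / fs
    if kind == PT:
        freq = band.center if isinstance(band, NBNBand) else float(band)
        if fs <= 2 * freq:
            raise ValueError("sampling rate violates the Nyquist limit")
        x = np.sin(2 * np.pi * freq * t)
    elif kind == NBN:
        if not isinstance(band, NBNBand):
            raise TypeError("NBN synthesis requires an NBNBand")
        if fs <= 2 * band.high_edge:
            raise ValueError("sampling rate violates the Nyquist limit")
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(n)
        sos = signal.butter(band.filter_order, [band.low_edge, band.high_edge],
                            btype="bandpass", fs=fs, output="sos")
        x = signal.sosfilt(sos, noise)
    else:
        raise ValueError(f"unknown stimulus kind {kind!r}")
    x = x * _cosine_ramp(n, int(round(ramp_ms / 1000.0 * fs)))
    rms = float(np.sqrt(np.mean(x**2)))
    if rms == 0:
        raise ValueError("degenerate zero waveform")
    return x * (spl_to_rms(target_spl) / rms)


def butterworth_band_power_fraction(band: NBNBand, f_max: float) -> float:
    """Analytic fraction of white-noise power that a second-order Butterworth
    bandpass transmits inside its passband, by integrating |H(f)|^2.

    Serves as the transfer-function bound against which synthesized NBN
    spectra are checked.
    """
    f = np.linspace(1.0, f_max, 200001)
    w0 = 2 * np.pi * np.sqrt(band.low_edge * band.high_edge)
    bw = 2 * np.pi * (band.high_edge - band.low_edge)
    w = 2 * np.pi * f
    # |H|^2 of the order-2 bandpass prototype: (bw*w)^2 / ((w0^2-w^2)^2 + (bw*w)^2)
    h2 = (bw * w) ** 2 / ((w0**2 - w**2) ** 2 + (bw * w) ** 2)
    inside = (f >= band.low_edge) & (f <= band.high_edge)
    return float(np.trapezoid(h2[inside], f[inside]) / np.trapezoid(h2, f))


def critical_band(critical_ratio_db: float) -> float:
    """Fletcher's conversion from critical ratio (dB) to critical band (Hz):
    CB = 10**(CR/10)."""
    return 10.0 ** (critical_ratio_db / 10.0)


def write_wav(path: str, waveform: np.ndarray, fs: float) -> None:
    """Write a waveform as single-channel 16-bit WAV (inspection only)."""
    from scipy.io import wavfile

    peak = np.max(np.abs(waveform))
    scaled = (waveform / peak * 32000).astype(np.int16) if peak > 0 else waveform.astype(np.int16)
    wavfile.write(path, int(fs), scaled)
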