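"""Synthetic validation signals.

Three families:

* deterministic tones, chirps and their concatenations — used to check
  that the filter bank reports the amplitude of each component in the
  right band at the right time;
* a spiking-population local field potential (LFP) with a controllable
  neuronal *isolation fraction* — the fraction of scheduled action
  potentials suppressed per oscillation cycle, emulating the functional
  disconnection hypothesized under hypoxia.  The population's firing
  rate waxes and wanes slowly (rhythms are not metronomes); with no
  isolation the summed field's intensity envelope surges on that regular
  schedule, while suppression noise perturbs surge timing and makes the
  envelope chaotic;
* an amplitude-modulated tone whose burst *timing jitter* is the
  controlled quantity while the burst rate, and hence average band
  power, is held fixed — the construction used to compare peak-timing
  features against band-power features on equal footing.

All generators are deterministic given their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import chirp as _chirp
from scipy.signal import fftconvolve

__all__ = [
    "SegmentRecipe",
    "SpikePopulation",
    "LabeledSignal",
    "gen_tone",
    "gen_chirp",
    "gen_mixture",
    "reference_composite",
    "gen_lfp",
    "gen_jittered_bursts",
]


@dataclass(frozen=True)
class SegmentRecipe:
    """One segment of a concatenated test signal."""

    kind: str  # "tone" | "chirp" | "mixture"
    freqs: tuple[float, ...]
    amps: tuple[float, ...]
    duration: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if any(f < 0 for f in self.freqs):
            raise ValueError("frequencies must be non-negative")
        if self.kind == "chirp" and len(self.freqs) != 2:
            raise ValueError("chirp needs (start, end) frequency pair")


@dataclass(frozen=True)
class SpikePopulation:
    """Parameters of the rhythmic spiking population.

    Each cycle of the synchronizing rhythm, each neuron fires with
    probability (1 - isolation_frac) * s(t), where s(t) is a slow
    raised-cosine modulation of the population rate (the waxing-waning
    of the rhythm), at the cycle time plus Gaussian jitter.  Suppression
    is per-cycle stochastic by default; per-neuron mode permanently
    silences a fixed random subset instead.
    """

    n_neurons: int = 200
    osc_freq: float = 10.0
    jitter_sd: float = 0.005
    isolation_frac: float = 0.0
    spike_duration: float = 0.002
    duration: float = 60.0
    mod_freq: float = 0.25
    mod_depth: float = 0.6
    noise_sd: float = 0.0
    isolation_mode: str = "per_cycle"  # "per_cycle" | "per_neuron"

    def __post_init__(self) -> None:
        if not 0.0 <= self.isolation_frac <= 1.0:
            raise ValueError("isolation_frac must lie in [0, 1]")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")
        if not 0.0 <= self.mod_depth < 1.0 + 1e-12:
            raise ValueError("mod_depth must lie in [0, 1]")
        if self.n_neurons < 1:
            raise ValueError("need at least one neuron")


@dataclass
class LabeledSignal:
    """A generated signal plus its ground truth.

    ``annotations`` is a list of dicts with at least ``t0``/``t1`` span
    keys; spike generators also return a ``raster`` of (neuron, time)
    pairs.
    """

    samples: np.ndarray
    fs: float
    annotations: list[dict] = field(default_factory=list)
    raster: np.ndarray | None = None  # (n_spikes, 2): neuron id, time (s)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs


def _aliasing_guard(freq: float, fs: float) -> None:
    if freq >= fs / 2.0:
        raise ValueError(f"frequency {freq} Hz at or above Nyquist ({fs / 2} Hz)")


def gen_tone(freq: float, amp: float, duration: float, fs: float) -> LabeledSignal:
    """Stationary sinusoid amp*sin(2*pi*f*t)."""
    _aliasing_guard(freq, fs)
    t = np.arange(int(round(duration * fs))) / fs
    return LabeledSignal(
        samples=amp * np.sin(2 * np.pi * freq * t),
        fs=fs,
        annotations=[{"kind": "tone", "t0": 0.0, "t1": duration, "freq": freq, "amp": amp}],
    )


def gen_chirp(f0: float, f1: float, amp: float, duration: float, fs: float) -> LabeledSignal:
    """Linear chirp from f0 to f1 Hz; annotation stores the sweep."""
    _aliasing_guard(max(f0, f1), fs)
    t = np.arange(int(round(duration * fs))) / fs
    samples = amp * _chirp(t, f0=f0, t1=duration, f1=f1, method="linear", phi=-90)
    return LabeledSignal(
        samples=samples,
        fs=fs,
        annotations=[
            {"kind": "chirp", "t0": 0.0, "t1": duration, "f0": f0, "f1": f1, "amp": amp}
        ],
    )


def gen_mixture(
    freqs: tuple[float, ...], amps: tuple[float, ...], duration: float, fs: float
) -> LabeledSignal:
    """Sum of stationary sinusoids."""
    for f in freqs:
        _aliasing_guard(f, fs)
    t = np.arange(int(round(duration * fs))) / fs
    samples = sum(a * np.sin(2 * np.pi * f * t) for f, a in zip(freqs, amps))
    return LabeledSignal(
        samples=np.asarray(samples),
        fs=fs,
        annotations=[
            {"kind": "mixture", "t0": 0.0, "t1": duration, "freqs": list(freqs), "amps": list(amps)}
        ],
    )


def reference_composite(fs: float = 256.0, tone_duration: float = 5.0) -> LabeledSignal:
    """The standard validation composite: four tones, a chirp, a two-tone mix.

    Stationary tones at 2.3/5.6/8.75/11.4 Hz with amplitudes 7.5/4/5.5/8
    (``tone_duration`` seconds each, filling 0-20 s at the default),
    then a 0-to-15 Hz chirp of amplitude 6 over 10 s (the 20-30 s span),
    then 10 s of 2.3 Hz (amp 2.3) + 16.6 Hz (amp 6.5).  Junctions are
    abrupt — no cross-fading — so irrelevant filters show brief
    perturbations at the seams.
    """
    if fs < 80:
        raise ValueError("fs must be at least 80 Hz for the 16.6 Hz mixture component")
    parts = [
        gen_tone(2.3, 7.5, tone_duration, fs),
        gen_tone(5.6, 4.0, tone_duration, fs),
        gen_tone(8.75, 5.5, tone_duration, fs),
        gen_tone(11.4, 8.0, tone_duration, fs),
        gen_chirp(0.0, 15.0, 6.0, 10.0, fs),
        gen_mixture((2.3, 16.6), (2.3, 6.5), 10.0, fs),
    ]
    samples = np.concatenate([p.samples for p in parts])
    annotations = []
    t0 = 0.0
    for p in parts:
        for ann in p.annotations:
            a = dict(ann)
            a["t0"] += t0
            a["t1"] += t0
            annotations.append(a)
        t0 += p.duration
    return LabeledSignal(samples=samples, fs=fs, annotations=annotations)


def spike_waveform(fs: float, duration: float = 0.002) -> np.ndarray:
    """Biphasic action-potential waveform: one sine cycle over ``duration``.

    Sampled at bin centers over at least two samples so the waveform
    never degenerates to zero when ``duration`` is below one sample
    period.
    """
    nk = max(2, int(round(duration * fs)))
    tk = (np.arange(nk) + 0.5) / nk
    return np.sin(2 * np.pi * tk)


def gen_lfp(pop: SpikePopulation, fs: float, seed: int = 0) -> LabeledSignal:
    """Summed field potential of the rhythmic population.

    Returns the trace plus the spike raster.  Fully reproducible from
    (pop, fs, seed).
    """
    rng = np.random.default_rng(seed)
    n = int(round(pop.duration * fs))
    cycle_times = np.arange(0.0, pop.duration, 1.0 / pop.osc_freq)
    mod = (1.0 + pop.mod_depth * np.cos(2 * np.pi * pop.mod_freq * cycle_times)) / (
        1.0 + pop.mod_depth
    )
    p_fire = mod[None, :].repeat(pop.n_neurons, axis=0)
    if pop.isolation_mode == "per_cycle":
        p_fire = (1.0 - pop.isolation_frac) * p_fire
    elif pop.isolation_mode == "per_neuron":
        silenced = rng.random(pop.n_neurons) < pop.isolation_frac
        p_fire = p_fire * (~silenced[:, None])
    else:
        raise ValueError(f"unknown isolation_mode {pop.isolation_mode!r}")
    fire = rng.random((pop.n_neurons, len(cycle_times))) < p_fire
    times = cycle_times[None, :] + rng.normal(
        0.0, pop.jitter_sd, size=(pop.n_neurons, len(cycle_times))
    )
    idx = np.round(times * fs).astype(int)
    ok = fire & (idx >= 0) & (idx < n)

    trace = np.zeros(n)
    np.add.at(trace, idx[ok], 1.0)
    trace = fftconvolve(trace, spike_waveform(fs, pop.spike_duration), mode="same")
    if pop.noise_sd > 0:
        trace = trace + pop.noise_sd * rng.standard_normal(n)

    neuron_ids = np.broadcast_to(
        np.arange(pop.n_neurons)[:, None], times.shape
    )
    raster = np.column_stack([neuron_ids[ok], times[ok]])
    return LabeledSignal(
        samples=trace,
        fs=fs,
        annotations=[
            {
                "kind": "lfp",
                "t0": 0.0,
                "t1": pop.duration,
                "osc_freq": pop.osc_freq,
                "isolation_frac": pop.isolation_frac,
                "n_spikes": int(ok.sum()),
            }
        ],
        raster=raster,
    )


def gen_jittered_bursts(
    *,
    carrier_freq: float = 9.2,
    burst_period: float = 2.5,
    jitter_frac: float = 0.0,
    duration: float = 300.0,
    fs: float = 128.0,
    burst_width: float = 0.3,
    burst_depth: float = 1.5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> LabeledSignal:
    """Amplitude-modulated tone with jittered burst timing.

    Gaussian amplitude bursts (width ``burst_width`` s, relative height
    ``burst_depth`` above a unit baseline) are scheduled every
    ``burst_period`` seconds and displaced by N(0, (jitter_frac *
    burst_period)^2).  The burst *rate* — and with it the average band
    power — does not depend on the jitter; only the regularity of peak
    timing does.
    """
    _aliasing_guard(carrier_freq, fs)
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    centers = np.arange(burst_period, duration - burst_period, burst_period)
    centers = centers + rng.normal(0.0, jitter_frac * burst_period, size=len(centers))
    env = np.ones(n)
    # support wide enough that the truncation step (exp(-32) ~ 1e-14) is
    # below double-precision noise; narrower cuts leave envelope
    # discontinuities whose broadband splatter is measurable in far bands
    half = int(round(8 * burst_width * fs))
    for tc in centers:
        c = int(round(tc * fs))
        lo, hi = max(c - half, 0), min(c + half + 1, n)
        if lo < hi:
            env[lo:hi] += burst_depth * np.exp(
                -0.5 * ((t[lo:hi] - tc) / burst_width) ** 2
            )
    x = env * np.sin(2 * np.pi * carrier_freq * t)
    if noise_sd > 0:
        x = x + noise_sd * rng.standard_normal(n)
    return LabeledSignal(
        samples=x,
        fs=fs,
        annotations=[
            {
                "kind": "jittered_bursts",
                "t0": 0.0,
                "t1": duration,
                "carrier_freq": carrier_freq,
                "burst_period": burst_period,
                "jitter_frac": jitter_frac,
                "burst_times": centers.tolist(),
            }
        ],
    )
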