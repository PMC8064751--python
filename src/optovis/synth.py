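"""Synthetic recording sessions with known ground truth.

The generator emulates the statistical structure of awake head-fixed
recordings in mouse visual thalamocortical circuits under optogenetic
perturbation, so that every analysis stage can be exercised — and its
parameters recovered — without real recordings:

* a drifting-grating schedule (``n_directions × n_repeats`` per laser
  condition, randomly interleaved, gray gaps between trials);
* orientation-tuned units (von Mises in direction with a 180°-periodic
  component) emitting inhomogeneous-Poisson spikes; laser trials scale
  rates by class- and state-specific opto factors and *flatten* tuning
  curves toward their mean by ``pattern_degradation`` — a response-pattern
  change at fixed mean rate;
* narrow- (NS) and broad-spiking (BS) waveform templates whose summary
  features fall near the empirical class centroids;
* LFP per channel = 1/f^α background + narrow-band gamma whose power is
  state-dependent (running gain, laser suppression) + stimulus-evoked
  broadband noise;
* a two-state (still/running) Markov locomotion process driving both the
  speed trace and the state-dependent rates.

Everything is deterministic for a fixed ``GeneratorConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
from scipy import signal as sps
from scipy.ndimage import gaussian_filter

from .session import (
    LaserEvent,
    LocomotionConfig,
    Session,
    SpeedTrace,
    StimulusEvent,
    Unit,
)

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "NoiseMovieResult",
    "generate_session",
    "generate_gray_block",
    "generate_noise_movie",
    "waveform_template",
]


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic session.

    Defaults encode the study conditions the analyses assume: 8 grating
    directions × 20 repetitions × 2 s with 2 s gray gaps per laser
    condition; laser-on/off firing-rate ratios of 0.79 (BS, still), 0.67
    (BS, running) and 0.65 (NS); a gamma-band power running gain of ~1.5
    and laser suppression to ~0.5; a 1/f^2.5 LFP background. Gamma gains
    are *power* ratios (the measured band-power contrasts), so the
    synthesized amplitude scales with their square root.
    """

    # units
    n_units_bs: int = 14
    n_units_ns: int = 6
    base_rate_bs: float = 10.0        # Hz, mean evoked rate, still & laser-off
    base_rate_ns: float = 16.0        # Hz
    spont_rate_factor: float = 0.3    # gray-screen rate as fraction of base
    tuning_concentration: float = 3.0  # von Mises kappa
    locomotion_gain: float = 1.5      # rate multiplier while running
    opto_rate_factor_bs_still: float = 0.79
    opto_rate_factor_bs_run: float = 0.67
    opto_rate_factor_ns_still: float = 0.65
    opto_rate_factor_ns_run: float = 0.65
    pattern_degradation: float = 0.5  # tuning flattening under laser, in [0, 1]

    # stimulus / laser schedule
    n_directions: int = 8
    n_repeats: int = 20
    stim_duration: float = 2.0        # s
    gap_duration: float = 2.0         # s
    spatial_freq: float = 0.04        # cycles/degree
    temporal_freq: float = 1.0        # Hz
    laser_duration: float = 2.0       # s, coupled to stimulus onset
    lead_in: float = 5.0              # s of gray before the first trial

    # LFP
    lfp_rate: float = 1000.0          # Hz
    n_channels: int = 8
    channel_spacing: float = 100.0    # µm
    top_channel_depth: float = 100.0  # µm below pia
    one_over_f_alpha: float = 2.5
    one_over_f_amp: float = 30.0      # µV RMS of the background
    gamma_center: float = 55.0        # Hz
    gamma_halfwidth: float = 12.5     # Hz
    gamma_amp_still: float = 10.0     # µV RMS, still & laser-off
    gamma_run_gain: float = 1.5       # power ratio running / still
    gamma_opto_factor: float = 0.5    # power ratio laser-on / laser-off
    evoked_broadband_amp: float = 3.0  # µV RMS added during stimuli

    # locomotion
    speed_bin_length: float = 0.1     # s
    p_still_to_run: float = 0.01      # per speed bin
    p_run_to_still: float = 0.02
    run_speed_range: tuple = (5.0, 15.0)   # cm/s
    still_speed_range: tuple = (0.0, 0.5)  # cm/s
    locomotion_threshold: float = 2.0  # cm/s, used for state-dependent rates

    # waveforms
    waveform_rate: float = 30000.0    # Hz
    bs_trough_to_peak: float = 0.73   # ms
    ns_trough_to_peak: float = 0.32   # ms
    bs_peak_height: float = 0.20      # fraction of |trough|
    ns_peak_height: float = 0.34
    waveform_jitter: float = 0.04     # relative sd applied to ttp and height

    # misc
    subject_id: str = "synthetic"
    region: str = "V1"
    opsin: str = "ChR2"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_directions % 2 != 0:
            raise ValueError("n_directions must be even for 180-degree grouping")
        if not 0.0 <= self.pattern_degradation <= 1.0:
            raise ValueError("pattern_degradation must lie in [0, 1]")
        for name in (
            "base_rate_bs", "base_rate_ns", "spont_rate_factor",
            "locomotion_gain", "opto_rate_factor_bs_still",
            "opto_rate_factor_bs_run", "opto_rate_factor_ns_still",
            "opto_rate_factor_ns_run", "gamma_run_gain", "gamma_opto_factor",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("stim_duration", "gap_duration", "laser_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.tuning_concentration < 0:
            raise ValueError("tuning_concentration must be >= 0")

    @property
    def n_units(self) -> int:
        return self.n_units_bs + self.n_units_ns

    @property
    def directions(self) -> np.ndarray:
        return np.arange(self.n_directions) * (360.0 / self.n_directions)


@dataclass
class GroundTruth:
    """What the generator actually used — the recovery target for tests."""

    unit_ids: list
    is_ns: np.ndarray                       # bool per unit
    pref_direction: np.ndarray              # degrees per unit
    directions: np.ndarray                  # the direction grid
    # (locomotion, laser_on) -> units × directions mean evoked rate, Hz
    tuning: dict
    # (locomotion, laser_on) -> gamma-band signal power, µV²
    gamma_power: dict
    # (locomotion, laser_on) -> gray-screen (spontaneous) rate per unit, Hz
    spont_rate: dict
    kernels: list | None = None             # noise-movie receptive fields


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def waveform_template(
    trough_to_peak_ms: float,
    peak_height: float,
    waveform_rate: float,
    trough_width_ms: float | None = None,
) -> np.ndarray:
    """Stereotyped extracellular waveform: narrow negative trough at t=0
    followed by a positive peak ``trough_to_peak_ms`` later, amplitudes
    normalized so the trough is −1."""
    if trough_width_ms is None:
        trough_width_ms = 0.12 + 0.06 * trough_to_peak_ms
    t = np.arange(-1.0, 2.0, 1000.0 / waveform_rate)  # ms
    sigma_pk = 0.4 * trough_to_peak_ms
    w = -np.exp(-(t ** 2) / (2 * trough_width_ms ** 2))
    w = w + peak_height * np.exp(-((t - trough_to_peak_ms) ** 2) / (2 * sigma_pk ** 2))
    return w / np.abs(w.min())


def _tuning_curves(cfg: GeneratorConfig, rng: np.random.Generator) -> tuple:
    """Base (still, laser-off) tuning curves, units × directions, mean-rate
    normalized so that the average over the direction grid equals the class
    base rate regardless of concentration."""
    dirs = np.deg2rad(cfg.directions)
    is_ns = np.zeros(cfg.n_units, dtype=bool)
    is_ns[cfg.n_units_bs:] = True
    # preferred directions tile the grid evenly, with a small random offset
    pref_idx = np.arange(cfg.n_units) % cfg.n_directions
    pref = cfg.directions[pref_idx]
    kappa = cfg.tuning_concentration
    curves = np.empty((cfg.n_units, cfg.n_directions))
    for u in range(cfg.n_units):
        mu = np.deg2rad(pref[u])
        g = np.exp(kappa * (np.cos(dirs - mu) - 1.0)) + 0.5 * np.exp(
            kappa * (np.cos(dirs - mu - np.pi) - 1.0)
        )
        base = cfg.base_rate_ns if is_ns[u] else cfg.base_rate_bs
        curves[u] = base * g / g.mean()
    return curves, is_ns, pref


def _condition_tuning(cfg: GeneratorConfig, base_curves, is_ns) -> dict:
    """Tuning per (locomotion, laser) condition.

    Running multiplies rates by ``locomotion_gain``. Laser first flattens
    each curve toward its own mean by ``pattern_degradation`` (a pattern
    change at fixed mean rate), then scales it by the class/state opto
    factor — so the laser-on/off mean-rate ratio equals the factor exactly.
    """
    out = {}
    for state in ("still", "running"):
        gain = cfg.locomotion_gain if state == "running" else 1.0
        off = base_curves * gain
        factors = np.where(
            is_ns,
            cfg.opto_rate_factor_ns_run if state == "running"
            else cfg.opto_rate_factor_ns_still,
            cfg.opto_rate_factor_bs_run if state == "running"
            else cfg.opto_rate_factor_bs_still,
        )[:, None]
        mean = off.mean(axis=1, keepdims=True)
        flattened = mean + (1.0 - cfg.pattern_degradation) * (off - mean)
        out[(state, False)] = off
        out[(state, True)] = factors * flattened
    return out


def _markov_speed(
    cfg: GeneratorConfig, duration: float, rng: np.random.Generator
) -> SpeedTrace:
    n_bins = int(np.ceil(duration / cfg.speed_bin_length))
    running = np.empty(n_bins, dtype=bool)
    state = rng.random() < 0.5
    u = rng.random(n_bins)
    for i in range(n_bins):
        p = cfg.p_run_to_still if state else cfg.p_still_to_run
        if u[i] < p:
            state = not state
        running[i] = state
    v = np.where(
        running,
        rng.uniform(*cfg.run_speed_range, size=n_bins),
        rng.uniform(*cfg.still_speed_range, size=n_bins),
    )
    t = (np.arange(n_bins) + 0.5) * cfg.speed_bin_length
    return SpeedTrace(t=t, v=v)


def _segment_state(speed: SpeedTrace, t0: float, t1: float, threshold: float) -> str:
    sel = (speed.t >= t0) & (speed.t < t1)
    if not np.any(sel):
        sel = np.argmin(np.abs(speed.t - 0.5 * (t0 + t1)))
    return "running" if float(np.mean(speed.v[sel])) > threshold else "still"


def _poisson_times(
    rate: float, t0: float, t1: float, rng: np.random.Generator
) -> np.ndarray:
    n = rng.poisson(max(rate, 0.0) * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, size=n))


def _one_over_f_noise(
    n: int, fs: float, alpha: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance noise with a one-sided PSD ∝ f^(−alpha) above 1 Hz."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.maximum(f, 1.0) ** (-alpha / 2.0)
    shape[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shape, n=n)
    return x / x.std()


def _gamma_noise(
    n: int, fs: float, center: float, halfwidth: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance band-limited noise centered on the gamma peak."""
    sos = sps.butter(
        4, [center - halfwidth, center + halfwidth], btype="bandpass", fs=fs,
        output="sos",
    )
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _synthesize_lfp(
    cfg: GeneratorConfig,
    duration: float,
    speed: SpeedTrace,
    laser_events: list[LaserEvent],
    stim_spans: list[tuple[float, float]],
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-channel LFP: shaped background + state-modulated gamma (+ evoked
    broadband during stimuli). Gamma gains are power ratios, so amplitude
    envelopes use their square roots."""
    n = int(round(duration * cfg.lfp_rate))
    # amplitude envelope at the LFP rate
    run_bins = speed.v > cfg.locomotion_threshold
    samples_per_bin = int(round(cfg.speed_bin_length * cfg.lfp_rate))
    running = np.repeat(run_bins, samples_per_bin)[:n]
    if running.size < n:
        running = np.pad(running, (0, n - running.size), constant_values=False)
    env = np.full(n, cfg.gamma_amp_still)
    env[running] *= np.sqrt(cfg.gamma_run_gain)
    laser_mask = np.zeros(n, dtype=bool)
    for ev in laser_events:
        a, b = int(ev.onset * cfg.lfp_rate), int(ev.offset * cfg.lfp_rate)
        laser_mask[a:b] = True
    env[laser_mask] *= np.sqrt(cfg.gamma_opto_factor)
    stim_mask = np.zeros(n, dtype=bool)
    for t0, t1 in stim_spans:
        stim_mask[int(t0 * cfg.lfp_rate): int(t1 * cfg.lfp_rate)] = True

    lfp = np.empty((cfg.n_channels, n))
    for ch in range(cfg.n_channels):
        bg = cfg.one_over_f_amp * _one_over_f_noise(
            n, cfg.lfp_rate, cfg.one_over_f_alpha, rng
        )
        gam = env * _gamma_noise(
            n, cfg.lfp_rate, cfg.gamma_center, cfg.gamma_halfwidth, rng
        )
        x = bg + gam
        if np.any(stim_mask):
            x = x + np.where(
                stim_mask, cfg.evoked_broadband_amp * rng.standard_normal(n), 0.0
            )
        lfp[ch] = x
    return lfp


def _make_units(
    cfg: GeneratorConfig,
    is_ns: np.ndarray,
    spike_trains: list[np.ndarray],
    rng: np.random.Generator,
) -> list[Unit]:
    units = []
    for u in range(cfg.n_units):
        if is_ns[u]:
            ttp, h = cfg.ns_trough_to_peak, cfg.ns_peak_height
        else:
            ttp, h = cfg.bs_trough_to_peak, cfg.bs_peak_height
        ttp = ttp * (1.0 + cfg.waveform_jitter * rng.standard_normal())
        h = h * (1.0 + cfg.waveform_jitter * rng.standard_normal())
        wf = waveform_template(max(ttp, 0.1), max(h, 0.02), cfg.waveform_rate)
        units.append(
            Unit(
                unit_id=f"u{u:03d}",
                spike_times=spike_trains[u],
                mean_waveform=wf,
                waveform_rate=cfg.waveform_rate,
                channel_index=int(u % cfg.n_channels),
                sort_class="SU",
            )
        )
    return units


def _gamma_power_truth(cfg: GeneratorConfig) -> dict:
    base = cfg.gamma_amp_still ** 2
    return {
        ("still", False): base,
        ("still", True): base * cfg.gamma_opto_factor,
        ("running", False): base * cfg.gamma_run_gain,
        ("running", True): base * cfg.gamma_run_gain * cfg.gamma_opto_factor,
    }


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_session(cfg: GeneratorConfig) -> tuple[Session, GroundTruth]:
    """Generate a full drifting-grating session with interleaved laser trials.

    The schedule is exact: ``n_directions × n_repeats`` gratings per laser
    condition in a randomly interleaved order, each ``stim_duration`` long
    and followed by ``gap_duration`` of gray; laser pulses start at the
    onset of laser-on gratings. Spike counts, locomotion and LFP all follow
    the condition structure described in the module docstring.
    """
    rng = np.random.default_rng(cfg.seed)
    base_curves, is_ns, pref = _tuning_curves(cfg, rng)
    tuning = _condition_tuning(cfg, base_curves, is_ns)

    # --- schedule ---------------------------------------------------------
    trial_dirs = np.tile(np.repeat(cfg.directions, cfg.n_repeats), 2)
    trial_laser = np.repeat([False, True], cfg.n_directions * cfg.n_repeats)
    order = rng.permutation(trial_dirs.size)
    trial_dirs, trial_laser = trial_dirs[order], trial_laser[order]
    period = cfg.stim_duration + cfg.gap_duration
    onsets = cfg.lead_in + np.arange(trial_dirs.size) * period
    duration = float(onsets[-1] + period + cfg.lead_in)

    stimulus_events = [
        StimulusEvent(
            onset=float(t), duration=cfg.stim_duration, kind="grating",
            direction=float(d), spatial_freq=cfg.spatial_freq,
            temporal_freq=cfg.temporal_freq,
        )
        for t, d in zip(onsets, trial_dirs)
    ]
    laser_events = [
        LaserEvent(onset=float(t), duration=cfg.laser_duration)
        for t, on in zip(onsets, trial_laser)
        if on
    ]

    # --- locomotion -------------------------------------------------------
    speed = _markov_speed(cfg, duration, rng)

    # --- spikes -----------------------------------------------------------
    dir_index = {d: i for i, d in enumerate(cfg.directions)}
    spont = {
        ("still", False): np.where(is_ns, cfg.base_rate_ns, cfg.base_rate_bs)
        * cfg.spont_rate_factor,
        ("running", False): np.where(is_ns, cfg.base_rate_ns, cfg.base_rate_bs)
        * cfg.spont_rate_factor * cfg.locomotion_gain,
    }
    spont[("still", True)] = spont[("still", False)]
    spont[("running", True)] = spont[("running", False)]

    # piecewise-constant rate segments: lead-in, then (stimulus, gap) pairs
    segments = [(0.0, cfg.lead_in, None, False)]
    for t, d, on in zip(onsets, trial_dirs, trial_laser):
        segments.append((float(t), float(t) + cfg.stim_duration, float(d), bool(on)))
        segments.append(
            (float(t) + cfg.stim_duration, float(t) + period, None, False)
        )
    segments.append((duration - cfg.lead_in, duration, None, False))

    spike_trains: list[list[np.ndarray]] = [[] for _ in range(cfg.n_units)]
    for t0, t1, d, laser in segments:
        state = _segment_state(speed, t0, t1, cfg.locomotion_threshold)
        if d is None:
            rates = spont[(state, laser)]
        else:
            rates = tuning[(state, laser)][:, dir_index[d]]
        for u in range(cfg.n_units):
            spike_trains[u].append(_poisson_times(float(rates[u]), t0, t1, rng))
    trains = [np.concatenate(s) for s in spike_trains]

    units = _make_units(cfg, is_ns, trains, rng)

    # --- LFP --------------------------------------------------------------
    lfp = _synthesize_lfp(
        cfg, duration, speed, laser_events,
        [(e.onset, e.offset) for e in stimulus_events], rng,
    )

    depths = cfg.top_channel_depth + cfg.channel_spacing * np.arange(cfg.n_channels)
    sess = Session(
        subject_id=cfg.subject_id,
        region=cfg.region,
        opsin=cfg.opsin,
        lfp=lfp,
        lfp_rate=cfg.lfp_rate,
        channel_depths=depths,
        channel_shanks=np.zeros(cfg.n_channels, dtype=int),
        units=units,
        speed=speed,
        stimulus_events=stimulus_events,
        laser_events=laser_events,
    )
    truth = GroundTruth(
        unit_ids=[u.unit_id for u in units],
        is_ns=is_ns,
        pref_direction=pref,
        directions=cfg.directions,
        tuning=tuning,
        gamma_power=_gamma_power_truth(cfg),
        spont_rate=spont,
    )
    return sess, truth


def generate_gray_block(
    cfg: GeneratorConfig,
    block_duration: float = 200.0,
    laser_period: float = 20.0,
    laser_pulse: float = 4.0,
) -> tuple[Session, GroundTruth]:
    """Gray-screen block: no gratings, a 4 s laser pulse every 20 s.

    Pulses are centered on the period (first onset at ``laser_period/2``),
    so a 200 s block carries exactly 10 pulses and the last offset stays
    inside the block. Units fire at their spontaneous rates, scaled by the
    opto factor during pulses; LFP gamma follows the same state logic as in
    :func:`generate_session`.
    """
    rng = np.random.default_rng(cfg.seed)
    base_curves, is_ns, pref = _tuning_curves(cfg, rng)
    tuning = _condition_tuning(cfg, base_curves, is_ns)

    onsets = []
    t = laser_period / 2.0
    while t + laser_pulse <= block_duration + 1e-9:
        onsets.append(t)
        t += laser_period
    laser_events = [LaserEvent(onset=o, duration=laser_pulse) for o in onsets]

    speed = _markov_speed(cfg, block_duration, rng)

    base = np.where(is_ns, cfg.base_rate_ns, cfg.base_rate_bs)
    factors = {
        "still": np.where(
            is_ns, cfg.opto_rate_factor_ns_still, cfg.opto_rate_factor_bs_still
        ),
        "running": np.where(
            is_ns, cfg.opto_rate_factor_ns_run, cfg.opto_rate_factor_bs_run
        ),
    }
    spont = {
        ("still", False): base * cfg.spont_rate_factor,
        ("running", False): base * cfg.spont_rate_factor * cfg.locomotion_gain,
    }
    spont[("still", True)] = spont[("still", False)] * factors["still"]
    spont[("running", True)] = spont[("running", False)] * factors["running"]

    # segment the block at laser edges
    edges = [0.0]
    for ev in laser_events:
        edges += [ev.onset, ev.offset]
    edges.append(block_duration)
    spike_trains: list[list[np.ndarray]] = [[] for _ in range(cfg.n_units)]
    for t0, t1 in zip(edges[:-1], edges[1:]):
        if t1 <= t0:
            continue
        laser = any(ev.onset <= t0 < ev.offset for ev in laser_events)
        state = _segment_state(speed, t0, t1, cfg.locomotion_threshold)
        rates = spont[(state, laser)]
        for u in range(cfg.n_units):
            spike_trains[u].append(_poisson_times(float(rates[u]), t0, t1, rng))
    trains = [np.concatenate(s) for s in spike_trains]
    units = _make_units(cfg, is_ns, trains, rng)

    lfp = _synthesize_lfp(cfg, block_duration, speed, laser_events, [], rng)
    depths = cfg.top_channel_depth + cfg.channel_spacing * np.arange(cfg.n_channels)
    sess = Session(
        subject_id=cfg.subject_id,
        region=cfg.region,
        opsin=cfg.opsin,
        lfp=lfp,
        lfp_rate=cfg.lfp_rate,
        channel_depths=depths,
        channel_shanks=np.zeros(cfg.n_channels, dtype=int),
        units=units,
        speed=speed,
        stimulus_events=[],
        laser_events=laser_events,
    )
    truth = GroundTruth(
        unit_ids=[u.unit_id for u in units],
        is_ns=is_ns,
        pref_direction=pref,
        directions=cfg.directions,
        tuning=tuning,
        gamma_power=_gamma_power_truth(cfg),
        spont_rate=spont,
    )
    return sess, truth


@dataclass
class NoiseMovieResult:
    """Low-pass-filtered noise movie plus LN-model units driven by it."""

    movie: np.ndarray          # frames × h × w, zero-mean
    frame_rate: float          # Hz
    spike_trains: list         # one spike-time array per unit
    kernels: list              # one h × w linear receptive field per unit
    base_rates: np.ndarray     # Hz per unit

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.movie.shape[0]) / self.frame_rate


def _dog_kernel(size: int, center: tuple, sigma_c: float, sigma_s: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    r2 = (yy - center[0]) ** 2 + (xx - center[1]) ** 2
    k = np.exp(-r2 / (2 * sigma_c ** 2)) - 0.5 * np.exp(-r2 / (2 * sigma_s ** 2))
    return k / np.linalg.norm(k)


def generate_noise_movie(
    cfg: GeneratorConfig,
    n_frames: int = 3000,
    frame_rate: float = 30.0,
    size: int = 12,
    smooth_sigma: float = 0.5,
    n_units: int = 4,
    base_rate: float = 15.0,
    ln_gain: float = 1.5,
) -> NoiseMovieResult:
    """Spatially low-pass-filtered white-noise movie and LN-model units.

    Each unit's rate is ``base_rate · exp(g·(k·s) − g²·var/2)`` for a
    difference-of-Gaussians (center-surround) kernel ``k`` — the classic
    linear-nonlinear Poisson model, so its spike-triggered average
    converges on (a smoothed copy of) ``k``.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    movie = rng.standard_normal((n_frames, size, size))
    movie = gaussian_filter(movie, sigma=(0.0, smooth_sigma, smooth_sigma))
    movie -= movie.mean()
    movie /= movie.std()

    kernels, trains, bases = [], [], []
    for u in range(n_units):
        center = rng.integers(size // 4, 3 * size // 4, size=2)
        k = _dog_kernel(size, tuple(center), sigma_c=1.5, sigma_s=3.0)
        drive = np.tensordot(movie, k, axes=([1, 2], [0, 1]))
        rate = base_rate * np.exp(ln_gain * drive - 0.5 * (ln_gain * drive.std()) ** 2)
        n_spk = rng.poisson(rate / frame_rate)
        times = np.concatenate(
            [
                (i + rng.random(c)) / frame_rate
                for i, c in enumerate(n_spk)
                if c > 0
            ]
        )
        kernels.append(k)
        trains.append(np.sort(times))
        bases.append(base_rate)
    return NoiseMovieResult(
        movie=movie,
        frame_rate=frame_rate,
        spike_trains=trains,
        kernels=kernels,
        base_rates=np.asarray(bases),
    )
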