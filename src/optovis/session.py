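"""Core data model for extracellular recording sessions.

A :class:`Session` bundles everything one recording produces: multichannel
LFP with electrode depths, sorted units (spike times + mean waveforms), the
animal's running-speed trace, and the stimulus / laser event schedules.
Trial assembly (:func:`build_trials`) converts the event schedule into a
trials × units spike-count matrix with per-trial stimulus, optogenetic and
locomotion labels — the common input of the rate, information and decoding
analyses.

Conventions: all times are seconds from recording start; electrode depths
are µm below the pia, positive downward; speed is cm/s on a uniform grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "Unit",
    "StimulusEvent",
    "LaserEvent",
    "SpeedTrace",
    "Session",
    "LocomotionConfig",
    "TrialTable",
    "integrate_speed",
    "classify_locomotion",
    "build_trials",
    "read_session",
    "write_session",
]

REGIONS = ("V1", "dLGN")
OPSINS = ("ChR2", "eNpHR", "eYFP")
SORT_CLASSES = ("SU", "MU", "unknown")
STIMULUS_KINDS = ("grating", "gray", "checkerboard", "noise")


class SchemaError(ValueError):
    """A session container is missing a required group or field."""


@dataclass
class Unit:
    """One sorted unit: spike times, mean waveform and provenance."""

    unit_id: str
    spike_times: np.ndarray          # s, sorted ascending
    mean_waveform: np.ndarray        # µV, sampled at waveform_rate
    waveform_rate: float             # Hz
    channel_index: int
    sort_class: str = "unknown"

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        self.mean_waveform = np.asarray(self.mean_waveform, dtype=float)
        if self.spike_times.ndim != 1:
            raise ValueError(f"unit {self.unit_id}: spike_times must be 1-D")
        if self.spike_times.size and (
            np.any(np.diff(self.spike_times) < 0) or self.spike_times[0] < 0
        ):
            raise ValueError(
                f"unit {self.unit_id}: spike_times must be sorted and >= 0"
            )
        if self.sort_class not in SORT_CLASSES:
            raise ValueError(f"unit {self.unit_id}: bad sort_class {self.sort_class!r}")


@dataclass
class StimulusEvent:
    """A single visual stimulus presentation.

    ``direction`` (degrees, [0, 360)) is defined iff ``kind == "grating"``.
    """

    onset: float
    duration: float
    kind: str
    direction: float | None = None
    spatial_freq: float | None = None
    temporal_freq: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in STIMULUS_KINDS:
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("stimulus duration must be > 0")
        if (self.kind == "grating") != (self.direction is not None):
            raise ValueError("direction must be given iff kind == 'grating'")
        if self.direction is not None and not 0 <= self.direction < 360:
            raise ValueError("direction must lie in [0, 360)")

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass
class LaserEvent:
    """One optogenetic light pulse."""

    onset: float
    duration: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("laser duration must be > 0")

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass
class SpeedTrace:
    """Running speed (cm/s) on a uniform grid; ``t`` holds bin centers."""

    t: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.shape != self.v.shape or self.t.ndim != 1:
            raise ValueError("speed trace t and v must be equal-length 1-D arrays")
        if self.v.size and np.any(self.v < 0):
            raise ValueError("speed values must be >= 0")

    @property
    def bin_length(self) -> float:
        if self.t.size < 2:
            return float("nan")
        return float(self.t[1] - self.t[0])

    @property
    def span(self) -> tuple[float, float]:
        """Start/end of the time range covered by the bins (bin edges)."""
        half = self.bin_length / 2.0
        return float(self.t[0] - half), float(self.t[-1] + half)


@dataclass
class LocomotionConfig:
    """Locomotion-state segmentation parameters.

    ``speed_threshold`` defaults to 2 cm/s, the midpoint of the 1–3 cm/s
    per-experiment range used with ball-tracking noise; it is meant to be
    overridden per session when the tracker noise floor differs.
    """

    bin_length: float = 0.1       # s
    speed_threshold: float = 2.0  # cm/s

    def __post_init__(self) -> None:
        if self.bin_length <= 0:
            raise ValueError("bin_length must be > 0")
        if self.speed_threshold <= 0:
            raise ValueError("speed_threshold must be > 0")


@dataclass
class Session:
    """Full recording container. See module docstring for conventions."""

    subject_id: str
    region: str
    opsin: str
    lfp: np.ndarray                  # channels × samples, µV
    lfp_rate: float                  # Hz
    channel_depths: np.ndarray       # µm below pia, one per channel
    channel_shanks: np.ndarray       # shank id per channel
    units: list[Unit]
    speed: SpeedTrace
    stimulus_events: list[StimulusEvent]
    laser_events: list[LaserEvent]

    # highest analysis frequency used anywhere downstream (bandpass upper edge)
    MAX_ANALYSIS_FREQ = 300.0

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.opsin not in OPSINS:
            raise ValueError(f"unknown opsin {self.opsin!r}")
        self.lfp = np.asarray(self.lfp)
        if self.lfp.ndim != 2:
            raise ValueError("lfp must be channels × samples")
        self.channel_depths = np.asarray(self.channel_depths, dtype=float)
        self.channel_shanks = np.asarray(self.channel_shanks, dtype=int)
        if self.channel_depths.shape[0] != self.lfp.shape[0]:
            raise ValueError("one depth per LFP channel required")
        if self.channel_shanks.shape != self.channel_depths.shape:
            raise ValueError("one shank id per channel required")
        if self.lfp_rate <= 2 * self.MAX_ANALYSIS_FREQ:
            raise ValueError(
                f"lfp_rate must exceed {2 * self.MAX_ANALYSIS_FREQ} Hz "
                "(twice the highest analysis frequency)"
            )
        for shank in np.unique(self.channel_shanks):
            d = self.channel_depths[self.channel_shanks == shank]
            if d.size > 1 and not (np.all(np.diff(d) > 0) or np.all(np.diff(d) < 0)):
                raise ValueError(f"channel depths not monotone within shank {shank}")
        span = self.duration
        for ev in self.stimulus_events:
            if ev.onset < 0 or ev.offset > span + 1e-9:
                raise ValueError(f"stimulus event at {ev.onset} s outside recording span")
        for ev in self.laser_events:
            if ev.onset < 0 or ev.offset > span + 1e-9:
                raise ValueError(f"laser event at {ev.onset} s outside recording span")
        on = sorted(self.laser_events, key=lambda e: e.onset)
        for a, b in zip(on, on[1:]):
            if b.onset < a.offset:
                raise ValueError("laser events must not overlap")

    @property
    def n_channels(self) -> int:
        return self.lfp.shape[0]

    @property
    def duration(self) -> float:
        """Recording span in seconds (from the LFP, the longest stream)."""
        return self.lfp.shape[1] / self.lfp_rate

    def grating_events(self) -> list[StimulusEvent]:
        return [e for e in self.stimulus_events if e.kind == "grating"]


@dataclass
class TrialTable:
    """Trials × units spike counts with stimulus / laser / locomotion labels."""

    counts: np.ndarray               # trials × units, non-negative ints
    unit_ids: list[str]
    stimulus_direction: np.ndarray   # degrees per trial
    laser_on: np.ndarray             # bool per trial
    locomotion: np.ndarray           # "still" | "running" per trial
    mean_speed: np.ndarray           # cm/s per trial
    window_start_offset: float       # s after stimulus onset
    window_length: float             # s

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be trials × units")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")
        self.stimulus_direction = np.asarray(self.stimulus_direction, dtype=float)
        self.laser_on = np.asarray(self.laser_on, dtype=bool)
        self.locomotion = np.asarray(self.locomotion, dtype=object)
        self.mean_speed = np.asarray(self.mean_speed, dtype=float)
        n = self.counts.shape[0]
        for name in ("stimulus_direction", "laser_on", "locomotion", "mean_speed"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"{name} must have one entry per trial")
        if len(self.unit_ids) != self.counts.shape[1]:
            raise ValueError("one unit_id per counts column required")

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_units(self) -> int:
        return self.counts.shape[1]

    def select(
        self, laser: bool | None = None, locomotion: str | None = None
    ) -> np.ndarray:
        """Boolean trial mask for a laser × locomotion condition selector."""
        mask = np.ones(self.n_trials, dtype=bool)
        if laser is not None:
            mask &= self.laser_on == laser
        if locomotion is not None:
            if locomotion not in ("still", "running"):
                raise ValueError(f"unknown locomotion state {locomotion!r}")
            mask &= self.locomotion == locomotion
        return mask

    def rates(self) -> np.ndarray:
        """Per-trial firing rates (Hz), counts / window_length."""
        return self.counts / self.window_length

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "trial_idx": np.arange(self.n_trials),
                "direction_deg": self.stimulus_direction,
                "laser_on": self.laser_on,
                "locomotion": self.locomotion.astype(str),
                "mean_speed": self.mean_speed,
            }
        )
        for j, uid in enumerate(self.unit_ids):
            df[uid] = self.counts[:, j]
        return df

    def to_csv(self, path, window_in_header: bool = True) -> None:
        df = self.to_dataframe()
        with open(path, "w") as fh:
            if window_in_header:
                fh.write(
                    f"# window_start_offset={self.window_start_offset}"
                    f" window_length={self.window_length}\n"
                )
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrialTable":
        window_start, window_len = 0.5, 1.0
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                for tok in first[1:].split():
                    k, _, v = tok.partition("=")
                    if k == "window_start_offset":
                        window_start = float(v)
                    elif k == "window_length":
                        window_len = float(v)
                df = pd.read_csv(fh)
            else:
                fh.seek(0)
                df = pd.read_csv(fh)
        meta = ["trial_idx", "direction_deg", "laser_on", "locomotion", "mean_speed"]
        unit_ids = [c for c in df.columns if c not in meta]
        return cls(
            counts=df[unit_ids].to_numpy(dtype=np.int64),
            unit_ids=unit_ids,
            stimulus_direction=df["direction_deg"].to_numpy(),
            laser_on=df["laser_on"].to_numpy(dtype=bool),
            locomotion=df["locomotion"].to_numpy(dtype=object),
            mean_speed=df["mean_speed"].to_numpy(),
            window_start_offset=window_start,
            window_length=window_len,
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def integrate_speed(
    event_times: Sequence[float],
    displacements: Sequence[float],
    bin_length: float = 0.1,
    duration: float | None = None,
) -> SpeedTrace:
    """Integrate timestamped ball displacements into a uniform speed trace.

    Tracker events arrive event-driven; displacement (cm) accumulated inside
    each ``bin_length`` interval divided by the interval gives cm/s. Bins with
    no events read 0. An empty event stream yields an all-zero trace over
    ``duration`` (which is then required).
    """
    if bin_length <= 0:
        raise ValueError("bin_length must be > 0")
    t = np.asarray(event_times, dtype=float)
    d = np.asarray(displacements, dtype=float)
    if t.shape != d.shape:
        raise ValueError("event_times and displacements must match in length")
    if t.size and np.any(np.diff(t) < 0):
        raise ValueError("event timestamps must be sorted")
    if duration is None:
        if t.size == 0:
            raise ValueError("duration required for an empty event stream")
        duration = float(t[-1])
    n_bins = max(1, int(np.ceil(duration / bin_length - 1e-9)))
    edges = np.arange(n_bins + 1) * bin_length
    total, _ = np.histogram(t, bins=edges, weights=d)
    centers = edges[:-1] + bin_length / 2.0
    return SpeedTrace(t=centers, v=total / bin_length)


def classify_locomotion(
    trial_span: tuple[float, float],
    speed: SpeedTrace,
    cfg: LocomotionConfig | None = None,
) -> str:
    """Label a trial ``"running"`` iff its mean speed is strictly above threshold.

    The tie goes to ``"still"``: a mean exactly at threshold did not fall
    *above* it.
    """
    cfg = cfg or LocomotionConfig()
    state, _ = _locomotion_state(trial_span, speed, cfg)
    return state


def _locomotion_state(
    trial_span: tuple[float, float], speed: SpeedTrace, cfg: LocomotionConfig
) -> tuple[str, float]:
    t0, t1 = trial_span
    if t1 <= t0:
        raise ValueError("trial span must have positive length")
    lo, hi = speed.span
    if t0 < lo - 1e-9 or t1 > hi + 1e-9:
        raise ValueError(
            f"trial span [{t0}, {t1}] outside speed trace [{lo}, {hi}]: "
            "events and speed trace appear misaligned"
        )
    sel = (speed.t >= t0) & (speed.t < t1)
    if not np.any(sel):
        # span narrower than a bin: use the bin containing its midpoint
        mid = 0.5 * (t0 + t1)
        sel = np.argmin(np.abs(speed.t - mid))
    mean_speed = float(np.mean(speed.v[sel]))
    state = "running" if mean_speed > cfg.speed_threshold else "still"
    return state, mean_speed


def build_trials(
    session: Session,
    window_start_offset: float = 0.5,
    window_length: float = 1.0,
    cfg: LocomotionConfig | None = None,
) -> TrialTable:
    """Assemble the per-grating spike-count table.

    Counts fall in the half-open window ``[onset + offset, onset + offset +
    length)`` — 1000 ms beginning 500 ms after stimulus onset by default,
    skipping the transient. A trial is laser-on iff any laser pulse overlaps
    the stimulus span; locomotion is thresholded on the mean speed over the
    stimulus span.
    """
    cfg = cfg or LocomotionConfig()
    gratings = session.grating_events()
    if not gratings:
        raise ValueError("session has no grating events")
    for ev in gratings:
        if window_start_offset + window_length > ev.duration + 1e-9:
            raise ValueError(
                f"counting window [{window_start_offset}, "
                f"{window_start_offset + window_length}] s extends past the end "
                f"of the grating at onset {ev.onset} s (duration {ev.duration} s)"
            )
    n_trials, n_units = len(gratings), len(session.units)
    counts = np.zeros((n_trials, n_units), dtype=np.int64)
    for j, unit in enumerate(session.units):
        st = unit.spike_times
        for i, ev in enumerate(gratings):
            a = ev.onset + window_start_offset
            counts[i, j] = np.searchsorted(st, a + window_length, "left") - np.searchsorted(
                st, a, "left"
            )
    laser_on = np.array(
        [
            any(l.onset < ev.offset and l.offset > ev.onset for l in session.laser_events)
            for ev in gratings
        ],
        dtype=bool,
    )
    loco = np.empty(n_trials, dtype=object)
    mean_speed = np.empty(n_trials)
    for i, ev in enumerate(gratings):
        loco[i], mean_speed[i] = _locomotion_state(
            (ev.onset, ev.offset), session.speed, cfg
        )
    return TrialTable(
        counts=counts,
        unit_ids=[u.unit_id for u in session.units],
        stimulus_direction=np.array([e.direction for e in gratings], dtype=float),
        laser_on=laser_on,
        locomotion=loco,
        mean_speed=mean_speed,
        window_start_offset=window_start_offset,
        window_length=window_length,
    )


# ---------------------------------------------------------------------------
# HDF5 container I/O
# ---------------------------------------------------------------------------

_STIM_FIELDS = ("onset", "duration", "kind", "direction", "spatial_freq", "temporal_freq")


def write_session(session: Session, path) -> None:
    """Write a session to the fixed HDF5 layout (see docs/methods.md)."""
    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        meta.attrs["subject_id"] = session.subject_id
        meta.attrs["region"] = session.region
        meta.attrs["opsin"] = session.opsin
        lfp = f.create_group("lfp")
        lfp.create_dataset("data", data=session.lfp)
        lfp.create_dataset("rate", data=float(session.lfp_rate))
        lfp.create_dataset("depths", data=session.channel_depths)
        lfp.create_dataset("shanks", data=session.channel_shanks)
        units = f.create_group("units")
        for u in session.units:
            g = units.create_group(u.unit_id)
            g.create_dataset("spike_times", data=u.spike_times)
            g.create_dataset("mean_waveform", data=u.mean_waveform)
            g.create_dataset("waveform_rate", data=float(u.waveform_rate))
            g.create_dataset("channel_index", data=int(u.channel_index))
            g.attrs["sort_class"] = u.sort_class
        sp = f.create_group("speed")
        sp.create_dataset("t", data=session.speed.t)
        sp.create_dataset("v", data=session.speed.v)
        ev = f.create_group("events")
        stim = ev.create_group("stimulus")
        stim.create_dataset(
            "onset", data=np.array([e.onset for e in session.stimulus_events])
        )
        stim.create_dataset(
            "duration", data=np.array([e.duration for e in session.stimulus_events])
        )
        stim.create_dataset(
            "kind",
            data=np.array([e.kind for e in session.stimulus_events], dtype="S16"),
        )
        stim.create_dataset(
            "direction",
            data=np.array(
                [np.nan if e.direction is None else e.direction
                 for e in session.stimulus_events]
            ),
        )
        stim.create_dataset(
            "spatial_freq",
            data=np.array(
                [np.nan if e.spatial_freq is None else e.spatial_freq
                 for e in session.stimulus_events]
            ),
        )
        stim.create_dataset(
            "temporal_freq",
            data=np.array(
                [np.nan if e.temporal_freq is None else e.temporal_freq
                 for e in session.stimulus_events]
            ),
        )
        laser = ev.create_group("laser")
        laser.create_dataset(
            "onset", data=np.array([e.onset for e in session.laser_events])
        )
        laser.create_dataset(
            "duration", data=np.array([e.duration for e in session.laser_events])
        )


def _require(node, key: str):
    if key not in node:
        raise SchemaError(f"session file missing required field {node.name}/{key}")
    return node[key]


def read_session(path) -> Session:
    """Read a session written by :func:`write_session`.

    Raises :class:`SchemaError` naming the first missing group/field.
    """
    with h5py.File(path, "r") as f:
        meta = _require(f, "meta")
        for attr in ("subject_id", "region", "opsin"):
            if attr not in meta.attrs:
                raise SchemaError(f"session file missing required field /meta@{attr}")
        lfp = _require(f, "lfp")
        data = _require(lfp, "data")[...]
        rate = float(_require(lfp, "rate")[()])
        depths = _require(lfp, "depths")[...]
        shanks = (
            lfp["shanks"][...] if "shanks" in lfp else np.zeros(len(depths), dtype=int)
        )
        units_grp = _require(f, "units")
        units = []
        for uid in sorted(units_grp):
            g = units_grp[uid]
            units.append(
                Unit(
                    unit_id=uid,
                    spike_times=_require(g, "spike_times")[...],
                    mean_waveform=_require(g, "mean_waveform")[...],
                    waveform_rate=float(_require(g, "waveform_rate")[()]),
                    channel_index=int(_require(g, "channel_index")[()]),
                    sort_class=g.attrs.get("sort_class", "unknown"),
                )
            )
        sp = _require(f, "speed")
        speed = SpeedTrace(t=_require(sp, "t")[...], v=_require(sp, "v")[...])
        ev = _require(f, "events")
        stim_grp = _require(ev, "stimulus")
        onsets = _require(stim_grp, "onset")[...]
        durations = _require(stim_grp, "duration")[...]
        kinds = [k.decode() for k in _require(stim_grp, "kind")[...]]
        direction = _require(stim_grp, "direction")[...]
        sf = _require(stim_grp, "spatial_freq")[...]
        tf = _require(stim_grp, "temporal_freq")[...]
        stimulus_events = [
            StimulusEvent(
                onset=float(onsets[i]),
                duration=float(durations[i]),
                kind=kinds[i],
                direction=None if np.isnan(direction[i]) else float(direction[i]),
                spatial_freq=None if np.isnan(sf[i]) else float(sf[i]),
                temporal_freq=None if np.isnan(tf[i]) else float(tf[i]),
            )
            for i in range(len(onsets))
        ]
        laser_grp = _require(ev, "laser")
        l_on = _require(laser_grp, "onset")[...]
        l_dur = _require(laser_grp, "duration")[...]
        laser_events = [
            LaserEvent(onset=float(a), duration=float(d)) for a, d in zip(l_on, l_dur)
        ]
        return Session(
            subject_id=str(meta.attrs["subject_id"]),
            region=str(meta.attrs["region"]),
            opsin=str(meta.attrs["opsin"]),
            lfp=data,
            lfp_rate=rate,
            channel_depths=depths,
            channel_shanks=shanks,
            units=units,
            speed=speed,
            stimulus_events=stimulus_events,
            laser_events=laser_events,
        )
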