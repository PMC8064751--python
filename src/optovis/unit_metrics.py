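"""Single-unit metrics: waveform classification, rate statistics and STAs.

Waveform shape separates putative fast-spiking interneurons (narrow-spiking,
NS) from the mostly excitatory broad-spiking (BS) population. Three summary
features are taken from the mean waveform after normalizing so the trough is
−1: the positive-peak height relative to the trough, the trough-to-peak time
(ms), and the waveform slope 0.5 ms after the trough. A deterministic
2-means clustering of the z-scored features splits the population; the
cluster with the longer trough-to-peak time is BS.

Rate statistics (condition rates, laser-on/off ratios, evoked/baseline
ratios, coefficient of variation) operate on the trial table; spike-
triggered averages (STA) against a noise movie estimate linear receptive
fields and back an SNR-based single-unit/multi-unit call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .session import Session, StimulusEvent, TrialTable, Unit

__all__ = [
    "WaveformFeatures",
    "CellClassResult",
    "waveform_features",
    "classify_ns_bs",
    "condition_rate",
    "laser_rate_ratio",
    "evoked_baseline_ratio",
    "coefficient_of_variation",
    "spike_triggered_average",
    "sta_snr_score",
    "classify_su_mu",
]


@dataclass
class WaveformFeatures:
    """Three shape features of a trough-normalized mean waveform.

    ``peak_trough_height`` is stored as the (positive) peak amplitude in
    units of |trough|; reports following the field's sign convention
    display it negated.
    """

    peak_trough_height: float
    trough_to_peak: float       # ms
    post_trough_slope: float    # normalized amplitude per ms, at +0.5 ms

    def __post_init__(self) -> None:
        if not np.isfinite(
            [self.peak_trough_height, self.trough_to_peak, self.post_trough_slope]
        ).all():
            raise ValueError("waveform features must be finite")
        if self.trough_to_peak <= 0:
            raise ValueError("trough_to_peak must be > 0")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.peak_trough_height, self.trough_to_peak, self.post_trough_slope]
        )


@dataclass
class CellClassResult:
    labels: np.ndarray           # "NS" | "BS" per unit
    cluster_centroids: dict      # label -> WaveformFeatures (feature-space means)


def waveform_features(
    mean_waveform: np.ndarray, waveform_rate: float
) -> WaveformFeatures:
    """Extract the three classification features from a mean waveform.

    The waveform is normalized by |global minimum| so the trough is −1; the
    peak is the maximum after the trough; the slope is a central difference
    evaluated 0.5 ms after the trough.
    """
    w = np.asarray(mean_waveform, dtype=float)
    if w.ndim != 1 or w.size < 3:
        raise ValueError("mean_waveform must be a 1-D array")
    trough = int(np.argmin(w))
    if trough >= w.size - 1:
        raise ValueError("waveform trough at the last sample: no post-trough segment")
    depth = abs(w[trough])
    if depth == 0:
        raise ValueError("degenerate waveform: zero trough amplitude")
    w = w / depth
    dt_ms = 1000.0 / waveform_rate
    post = w[trough + 1:]
    peak_rel = int(np.argmax(post)) + 1
    height = float(w[trough + peak_rel])
    ttp = peak_rel * dt_ms
    half_ms = int(round(0.5 / dt_ms))
    i = trough + half_ms
    if i + 1 >= w.size:
        raise ValueError("waveform must span at least 0.5 ms past the trough")
    slope = float((w[i + 1] - w[i - 1]) / (2 * dt_ms))
    return WaveformFeatures(
        peak_trough_height=height, trough_to_peak=ttp, post_trough_slope=slope
    )


def _two_means(Z: np.ndarray, max_iter: int = 100) -> np.ndarray:
    """Deterministic 2-means: centers start at the two mutually farthest
    points (farthest-point initialization), then Lloyd iterations."""
    n = Z.shape[0]
    d0 = np.linalg.norm(Z - Z.mean(axis=0), axis=1)
    a = int(np.argmax(d0))
    b = int(np.argmax(np.linalg.norm(Z - Z[a], axis=1)))
    centers = np.stack([Z[a], Z[b]])
    assign = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        dists = np.linalg.norm(Z[:, None, :] - centers[None], axis=2)
        new = np.argmin(dists, axis=1)
        if np.array_equal(new, assign) and _ > 0:
            break
        assign = new
        for k in (0, 1):
            if np.any(assign == k):
                centers[k] = Z[assign == k].mean(axis=0)
    return assign


def classify_ns_bs(features: list[WaveformFeatures]) -> CellClassResult:
    """Split units into narrow- and broad-spiking by 2-means clustering of
    the z-scored feature triples; the cluster with the larger mean
    trough-to-peak time is labeled BS."""
    if len(features) < 2:
        raise ValueError("need at least two units to classify")
    F = np.stack([f.as_array() for f in features])
    sd = F.std(axis=0)
    if np.all(sd == 0):
        raise ValueError("degenerate clustering: all feature vectors identical")
    sd = np.where(sd == 0, 1.0, sd)
    Z = (F - F.mean(axis=0)) / sd
    assign = _two_means(Z)
    ttp_means = [F[assign == k, 1].mean() if np.any(assign == k) else -np.inf
                 for k in (0, 1)]
    bs_cluster = int(np.argmax(ttp_means))
    labels = np.where(assign == bs_cluster, "BS", "NS").astype(object)
    centroids = {}
    for lab in ("BS", "NS"):
        sel = labels == lab
        if np.any(sel):
            m = F[sel].mean(axis=0)
            centroids[lab] = WaveformFeatures(*m)
    return CellClassResult(labels=labels, cluster_centroids=centroids)


# ---------------------------------------------------------------------------
# rate statistics
# ---------------------------------------------------------------------------

def condition_rate(
    table: TrialTable,
    unit: int | str,
    laser: bool | None = None,
    locomotion: str | None = None,
) -> float:
    """Mean firing rate (Hz) of one unit over trials matching the selector."""
    j = table.unit_ids.index(unit) if isinstance(unit, str) else int(unit)
    mask = table.select(laser=laser, locomotion=locomotion)
    if not np.any(mask):
        raise ValueError(
            f"no trials match selector laser={laser}, locomotion={locomotion}"
        )
    return float(table.counts[mask, j].mean() / table.window_length)


def laser_rate_ratio(
    table: TrialTable, unit: int | str, locomotion: str | None = None
) -> float:
    """Laser-on / laser-off firing-rate ratio at fixed locomotion state.

    Returns NaN (with a warning) for units silent in the laser-off
    condition, for which the ratio is undefined.
    """
    off = condition_rate(table, unit, laser=False, locomotion=locomotion)
    on = condition_rate(table, unit, laser=True, locomotion=locomotion)
    if off == 0:
        warnings.warn(
            f"unit {unit!r}: zero laser-off rate, ratio undefined", stacklevel=2
        )
        return float("nan")
    return on / off


def evoked_baseline_ratio(
    unit: Unit,
    stimulus_events: list[StimulusEvent],
    pre_window: float = 0.5,
    window_start_offset: float = 0.5,
    window_length: float = 1.0,
) -> float:
    """Visually evoked rate at the optimal grating over the pre-onset rate.

    The optimal grating is the direction with the highest mean evoked rate
    (ties to the lowest direction); the baseline is the mean rate in the
    ``pre_window`` seconds immediately before onset, over the same trials.
    Returns NaN (with a warning) when the baseline is silent.
    """
    gratings = [e for e in stimulus_events if e.kind == "grating"]
    if not gratings:
        raise ValueError("no grating events supplied")
    st = unit.spike_times
    dirs = sorted({e.direction for e in gratings})
    evoked = {}
    base_counts = {}
    for d in dirs:
        evs = [e for e in gratings if e.direction == d]
        n_ev = sum(
            np.searchsorted(st, e.onset + window_start_offset + window_length)
            - np.searchsorted(st, e.onset + window_start_offset)
            for e in evs
        )
        n_pre = sum(
            np.searchsorted(st, e.onset) - np.searchsorted(st, e.onset - pre_window)
            for e in evs
        )
        evoked[d] = n_ev / (len(evs) * window_length)
        base_counts[d] = n_pre / (len(evs) * pre_window)
    best = max(dirs, key=lambda d: (evoked[d], -d))  # ties -> lowest direction
    baseline = base_counts[best]
    if baseline == 0:
        warnings.warn(
            f"unit {unit.unit_id}: zero baseline rate, ratio undefined",
            stacklevel=2,
        )
        return float("nan")
    return evoked[best] / baseline


def coefficient_of_variation(rates: np.ndarray) -> float:
    """Sample SD (n−1 denominator) over mean of per-trial firing rates.

    NaN (with a warning) for a zero mean, where CV is undefined.
    """
    r = np.asarray(rates, dtype=float)
    if r.size < 2:
        raise ValueError("CV requires at least two trials")
    m = r.mean()
    if m == 0:
        warnings.warn("zero mean rate, CV undefined", stacklevel=2)
        return float("nan")
    return float(r.std(ddof=1) / m)


# ---------------------------------------------------------------------------
# spike-triggered averages
# ---------------------------------------------------------------------------

def spike_triggered_average(
    spike_times: np.ndarray,
    movie: np.ndarray,
    frame_rate: float,
    n_lags: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean stimulus frame at fixed lags preceding each spike.

    ``movie`` is frames × h × w shown at ``frame_rate``; lag ``l`` averages
    the frame ``l`` steps before the frame containing each spike (lag 0 is
    the concurrent frame). Returns (sta: n_lags × h × w, n_spikes_per_lag).
    """
    st = np.asarray(spike_times, dtype=float)
    movie = np.asarray(movie, dtype=float)
    n_frames = movie.shape[0]
    idx = np.floor(st * frame_rate).astype(int)
    idx = idx[(idx >= 0) & (idx < n_frames)]
    if idx.size == 0:
        raise ValueError("no spikes within the movie span")
    sta = np.empty((n_lags,) + movie.shape[1:])
    counts = np.empty(n_lags, dtype=int)
    for lag in range(n_lags):
        valid = idx - lag
        valid = valid[valid >= 0]
        counts[lag] = valid.size
        sta[lag] = movie[valid].mean(axis=0) if valid.size else 0.0
    return sta, counts


def sta_snr_score(
    sta: np.ndarray, pixel_variance: float, n_spikes: int
) -> float:
    """Peak |STA| in z-units of the pixel noise floor.

    For a stimulus-independent unit the STA of ``n`` spikes has per-pixel
    variance ``pixel_variance / n``; the score is the largest absolute STA
    value divided by that SD.
    """
    if pixel_variance <= 0 or n_spikes < 1:
        raise ValueError("need positive pixel variance and >= 1 spike")
    noise_sd = np.sqrt(pixel_variance / n_spikes)
    return float(np.max(np.abs(sta)) / noise_sd)


def classify_su_mu(scores: np.ndarray, threshold: float = 5.0) -> np.ndarray:
    """Label units SU iff their STA SNR score reaches ``threshold``."""
    s = np.asarray(scores, dtype=float)
    return np.where(s >= threshold, "SU", "MU").astype(object)
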