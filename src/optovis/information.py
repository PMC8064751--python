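"""Shannon information carried by single-neuron spike counts about stimuli.

Plug-in estimation throughout: joint probabilities are empirical frequencies
from a response-symbol × stimulus-class contingency table, substituted
directly into H(S), H(S|R) and I(R,S) = H(S) − H(S|R) in bits. Response
symbols are raw integer spike counts (no binning) by default, with an
optional tail cap for small samples; Miller–Madow bias correction is
available behind a flag and off by default.

The plug-in estimator is biased upward on finite data — on a table of
independent margins with T trials the expected estimate is roughly
(|R|−1)(|S|−1) / (2 T ln 2) bits — so "zero information" reads as a small
positive number at realistic trial counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .session import TrialTable

__all__ = [
    "JointCountTable",
    "MIResult",
    "entropy",
    "mutual_information",
    "mi_per_unit",
]


@dataclass
class JointCountTable:
    """Response-symbol × stimulus-class contingency counts."""

    counts: np.ndarray            # |R| × |S| non-negative integers
    response_symbols: np.ndarray  # ordered spike-count values
    class_labels: np.ndarray      # stimulus classes

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (responses × classes)")
        if np.any(self.counts < 0) or np.any(self.counts != np.round(self.counts)):
            raise ValueError("counts must be non-negative integers")
        self.counts = self.counts.astype(np.int64)
        self.response_symbols = np.asarray(self.response_symbols)
        self.class_labels = np.asarray(self.class_labels)
        if self.response_symbols.size != self.counts.shape[0]:
            raise ValueError("one response symbol per row required")
        if self.class_labels.size != self.counts.shape[1]:
            raise ValueError("one class label per column required")
        if self.counts.sum() < 1:
            raise ValueError("table must contain at least one observation")

    @classmethod
    def from_observations(
        cls,
        responses: np.ndarray,
        classes: np.ndarray,
        max_count: int | None = None,
    ) -> "JointCountTable":
        """Tabulate per-trial spike counts against stimulus classes.

        ``max_count`` pools the tail: counts above it are merged into one
        symbol, a small-sample stabilization of the plug-in estimate.
        """
        responses = np.asarray(responses)
        classes = np.asarray(classes)
        if responses.shape != classes.shape or responses.ndim != 1:
            raise ValueError("responses and classes must be equal-length 1-D")
        if responses.size == 0:
            raise ValueError("no observations")
        if max_count is not None:
            responses = np.minimum(responses, max_count)
        symbols, r_idx = np.unique(responses, return_inverse=True)
        labels, s_idx = np.unique(classes, return_inverse=True)
        counts = np.zeros((symbols.size, labels.size), dtype=np.int64)
        np.add.at(counts, (r_idx, s_idx), 1)
        return cls(counts=counts, response_symbols=symbols, class_labels=labels)

    def transpose(self) -> "JointCountTable":
        return JointCountTable(
            counts=self.counts.T,
            response_symbols=self.class_labels,
            class_labels=self.response_symbols,
        )


@dataclass
class MIResult:
    mi: float            # bits
    h_s: float           # stimulus entropy, bits
    h_s_given_r: float   # residual stimulus entropy after observing R, bits
    n_trials: int

    def __post_init__(self) -> None:
        if not np.isclose(self.mi, self.h_s - self.h_s_given_r, atol=1e-9):
            raise ValueError("MI identity violated: mi != h_s - h_s_given_r")


def entropy(p: np.ndarray, axis: int | None = None) -> float | np.ndarray:
    """Shannon entropy in bits, −Σ p log₂ p with 0·log 0 ≡ 0.

    ``p`` must be a probability vector (non-negative, summing to 1 within
    1e−9 along ``axis``).
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be >= 0")
    total = p.sum(axis=axis)
    if not np.allclose(total, 1.0, atol=1e-9):
        raise ValueError("probabilities must sum to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    out = -terms.sum(axis=axis)
    return float(out) if axis is None else out


def mutual_information(
    table: JointCountTable, miller_madow: bool = False
) -> MIResult:
    """Plug-in mutual information between responses and stimulus classes.

    Computed as H(S) − H(S|R) from empirical frequencies; algebraically
    identical to the double sum Σ p(r,s) log₂[p(r,s)/(p(r)p(s))], with
    zero-probability cells contributing nothing. ``miller_madow`` adds the
    first-order bias correction −(|R*|−1)(|S*|−1)/(2 T ln 2) over occupied
    symbols/classes.
    """
    n = int(table.counts.sum())
    p_rs = table.counts / n
    p_r = p_rs.sum(axis=1)
    p_s = p_rs.sum(axis=0)
    h_s = entropy(p_s)
    # H(S|R) = Σ_r p(r) H(S | R = r)
    h_s_given_r = 0.0
    for r in range(p_rs.shape[0]):
        if p_r[r] > 0:
            h_s_given_r += p_r[r] * entropy(p_rs[r] / p_r[r])
    mi = h_s - h_s_given_r
    if miller_madow:
        r_occ = int(np.count_nonzero(p_r))
        s_occ = int(np.count_nonzero(p_s))
        mi -= (r_occ - 1) * (s_occ - 1) / (2.0 * n * np.log(2.0))
    # numerical guard: the plug-in estimate is non-negative analytically
    mi = max(mi, 0.0) if not miller_madow else mi
    return MIResult(mi=mi, h_s=h_s, h_s_given_r=h_s - mi, n_trials=n)


def mi_per_unit(
    table: TrialTable,
    unit: int | str,
    laser: bool | None = None,
    locomotion: str | None = None,
    class_map=None,
    max_count: int | None = None,
    miller_madow: bool = False,
) -> MIResult:
    """Mutual information of one unit's spike counts about the stimulus.

    Trials are restricted to the laser × locomotion selector; stimulus
    classes default to the grating movement directions, or are produced by
    ``class_map(directions)`` (e.g. orientation grouping from the decoding
    module). At least two stimulus classes must be present.
    """
    j = table.unit_ids.index(unit) if isinstance(unit, str) else int(unit)
    mask = table.select(laser=laser, locomotion=locomotion)
    if not np.any(mask):
        raise ValueError(
            f"no trials match selector laser={laser}, locomotion={locomotion}"
        )
    responses = table.counts[mask, j]
    dirs = table.stimulus_direction[mask]
    classes = np.asarray(class_map(dirs)) if class_map is not None else dirs
    if np.unique(classes).size < 2:
        raise ValueError("need at least two stimulus classes under the selector")
    joint = JointCountTable.from_observations(responses, classes, max_count=max_count)
    return mutual_information(joint, miller_madow=miller_madow)
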