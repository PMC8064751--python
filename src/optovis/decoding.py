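"""Population decoding of the visual stimulus from spike counts.

The decoder is a Gaussian linear discriminant with a *diagonal* covariance
matrix — neurons are treated as independent, with one pooled within-class
variance per neuron shared across classes. Accuracy is evaluated by
leave-one-out cross-validation (LOOXV): the model is refit with each trial
held out in turn and that trial's class predicted from the refit model.

Two higher-level procedures build on this:

* :func:`subsampled_error_distribution` — repeated stratified subsampling of
  trials, yielding a distribution of LOOXV accuracies;
* :func:`count_matched_decoding` — the rate-versus-pattern dissociation:
  accuracy is measured as a function of the *population spike count* (the
  summed count over a sampled neuron subset), separately for laser-off and
  laser-on trials, so the two optogenetic conditions can be compared at
  matched firing levels. Larger neuron subsets in the suppressed condition
  reach the same population counts as smaller subsets in the control
  condition, which is exactly what makes the comparison possible.

Orientation grouping (directions 180° apart share a class) is the default
class map for accuracy reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .session import TrialTable

__all__ = [
    "DiagLdaModel",
    "DecodingResult",
    "CountMatchedCurve",
    "group_orientations",
    "fit_diag_lda",
    "predict",
    "looxv_accuracy",
    "subsampled_error_distribution",
    "count_matched_decoding",
]

_REL_FLOOR = 1e-6
_ABS_FLOOR = 1e-9


def group_orientations(directions: np.ndarray) -> np.ndarray:
    """Map movement directions (degrees) to orientation class indices.

    Directions 180° apart fall in the same class; classes are numbered
    0, 1, ... in ascending order of ``direction mod 180``.
    """
    d = np.mod(np.asarray(directions, dtype=float), 360.0)
    ori = np.mod(d, 180.0)
    _, labels = np.unique(np.round(ori, 9), return_inverse=True)
    return labels


@dataclass
class DiagLdaModel:
    """Diagonal-covariance LDA: class means, shared per-unit variances."""

    classes: np.ndarray
    class_means: np.ndarray       # K × U
    pooled_variances: np.ndarray  # U (floored)
    class_log_priors: np.ndarray  # K

    def __post_init__(self) -> None:
        if np.any(self.pooled_variances <= 0):
            raise ValueError("pooled variances must be positive after flooring")
        if not np.isclose(np.exp(self.class_log_priors).sum(), 1.0, atol=1e-9):
            raise ValueError("priors must sum to 1")


@dataclass
class DecodingResult:
    accuracy: float
    predictions: np.ndarray
    labels: np.ndarray
    condition: dict = field(default_factory=dict)
    subsample_accuracies: np.ndarray | None = None
    bootstrap_se: float | None = None

    def __post_init__(self) -> None:
        if not np.isclose(self.accuracy, np.mean(self.predictions == self.labels)):
            raise ValueError("accuracy must equal mean(prediction == label)")


@dataclass
class CountMatchedCurve:
    """Accuracy vs population spike count, per optogenetic condition."""

    bin_edges: np.ndarray             # B+1 edges on population spike count
    conditions: tuple                 # ("laser_off", "laser_on")
    accuracy: np.ndarray              # 2 × B (NaN where a bin is empty)
    bootstrap_se: np.ndarray          # 2 × B
    n_samples: np.ndarray             # 2 × B ints
    config: dict = field(default_factory=dict)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def _floored(var: np.ndarray) -> np.ndarray:
    floor = max(_REL_FLOOR * float(np.mean(var)), _ABS_FLOOR)
    return np.maximum(var, floor)


def fit_diag_lda(
    X: np.ndarray, y: np.ndarray, min_per_class: int = 2
) -> DiagLdaModel:
    """Fit class means, pooled per-unit variances (n−K denominator) and
    empirical priors. Every class must contribute at least two trials."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ValueError("X must be trials × units with one label per trial")
    classes, y_idx = np.unique(y, return_inverse=True)
    n_c = np.bincount(y_idx, minlength=classes.size)
    for k, cnt in zip(classes, n_c):
        if cnt < min_per_class:
            raise ValueError(
                f"class {k!r} has {cnt} trial(s); at least {min_per_class} required"
            )
    n, K = X.shape[0], classes.size
    if n - K < 1:
        raise ValueError("not enough trials to estimate pooled variances")
    means = np.empty((K, X.shape[1]))
    ssw = np.zeros(X.shape[1])
    for k in range(K):
        Xi = X[y_idx == k]
        means[k] = Xi.mean(axis=0)
        ssw += ((Xi - means[k]) ** 2).sum(axis=0)
    var = _floored(ssw / (n - K))
    return DiagLdaModel(
        classes=classes,
        class_means=means,
        pooled_variances=var,
        class_log_priors=np.log(n_c / n),
    )


def predict(model: DiagLdaModel, x: np.ndarray):
    """Most probable class under the diagonal-Gaussian model.

    Score_k = log prior_k − ½ Σ_u (x_u − mean_{k,u})² / var_u; ties resolve
    to the lowest class index. Accepts a single trial (1-D) or trials ×
    units (2-D).
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != model.class_means.shape[1]:
        raise ValueError(
            f"input has {X.shape[1]} units, model expects "
            f"{model.class_means.shape[1]}"
        )
    d = X[:, None, :] - model.class_means[None, :, :]
    scores = model.class_log_priors[None, :] - 0.5 * np.sum(
        d * d / model.pooled_variances[None, None, :], axis=2
    )
    idx = np.argmax(scores, axis=1)  # first max -> lowest class index on ties
    out = model.classes[idx]
    return out[0] if single else out


def _loo_predictions(X: np.ndarray, y_idx: np.ndarray, K: int) -> np.ndarray:
    """Vectorized leave-one-out predictions (class indices 0..K−1).

    Per-class sums/sums-of-squares are downdated for the held-out trial
    instead of refitting from scratch; identical results to naive refits.
    """
    n, U = X.shape
    n_c = np.bincount(y_idx, minlength=K).astype(float)
    sum_c = np.zeros((K, U))
    ss_c = np.zeros((K, U))
    np.add.at(sum_c, y_idx, X)
    np.add.at(ss_c, y_idx, X * X)
    ssw_c = ss_c - sum_c ** 2 / n_c[:, None]          # K × U within-class SS
    ssw_tot = ssw_c.sum(axis=0)                        # U

    c = y_idx
    n_own = n_c[c]                                     # N
    sum_own = sum_c[c]                                 # N × U
    ss_own = ss_c[c]
    # own-class SS with trial i removed
    adj_mean = (sum_own - X) / (n_own[:, None] - 1.0)  # N × U
    ssw_own_excl = ss_own - X * X - (sum_own - X) ** 2 / (n_own[:, None] - 1.0)
    var = (ssw_tot[None, :] - ssw_c[c] + ssw_own_excl) / (n - 1 - K)
    floor = np.maximum(_REL_FLOOR * var.mean(axis=1, keepdims=True), _ABS_FLOOR)
    var = np.maximum(var, floor)

    means = sum_c / n_c[:, None]                       # K × U
    d = X[:, None, :] - means[None, :, :]              # N × K × U
    d[np.arange(n), c, :] = X - adj_mean               # own class uses downdated mean
    log_priors = np.log(
        (n_c[None, :] - (np.arange(K)[None, :] == c[:, None])) / (n - 1.0)
    )
    scores = log_priors - 0.5 * np.einsum("nku,nu->nk", d * d, 1.0 / var)
    return np.argmax(scores, axis=1)


def looxv_accuracy(
    X: np.ndarray, y: np.ndarray, condition: dict | None = None
) -> DecodingResult:
    """Leave-one-out cross-validated accuracy of the diagonal LDA.

    Deterministic; every class needs at least two trials so each held-out
    fit still sees all classes.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, y_idx = np.unique(y, return_inverse=True)
    n_c = np.bincount(y_idx)
    for k, cnt in zip(classes, n_c):
        if cnt < 2:
            raise ValueError(
                f"class {k!r} has {cnt} trial(s); leave-one-out needs >= 2"
            )
    if X.shape[0] - 1 - classes.size < 1:
        raise ValueError("not enough trials for held-out variance estimation")
    pred_idx = _loo_predictions(X, y_idx, classes.size)
    predictions = classes[pred_idx]
    return DecodingResult(
        accuracy=float(np.mean(predictions == y)),
        predictions=predictions,
        labels=y,
        condition=condition or {},
    )


def subsampled_error_distribution(
    X: np.ndarray,
    y: np.ndarray,
    fraction: float,
    n_reps: int = 50,
    seed: int | None = None,
) -> np.ndarray:
    """LOOXV accuracies over repeated stratified trial subsamples.

    Each repetition keeps ``round(fraction · n_k)`` trials per class,
    sampled without replacement; infeasible fractions (fewer than two
    trials in some class) raise.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    classes = np.unique(y)
    per_class_idx = [np.flatnonzero(y == k) for k in classes]
    keep = [int(round(fraction * idx.size)) for idx in per_class_idx]
    for k, m in zip(classes, keep):
        if m < 2:
            raise ValueError(
                f"fraction {fraction} keeps {m} trial(s) of class {k!r}; "
                "at least 2 required"
            )
    accs = np.empty(n_reps)
    for r in range(n_reps):
        sel = np.concatenate(
            [
                rng.choice(idx, size=m, replace=False)
                for idx, m in zip(per_class_idx, keep)
            ]
        )
        accs[r] = looxv_accuracy(X[sel], y[sel]).accuracy
    return accs


def _merge_count_bins(
    counts_by_cond: list[np.ndarray], min_samples: int
) -> np.ndarray:
    """Integer-width bins over the pooled counts, merged left-to-right until
    each bin holds at least ``min_samples`` in every condition."""
    pooled = np.concatenate(counts_by_cond)
    lo, hi = int(pooled.min()), int(pooled.max())
    edges = [lo]
    next_edge = lo + 1
    while next_edge <= hi + 1:
        ok = all(
            np.count_nonzero((c >= edges[-1]) & (c < next_edge)) >= min_samples
            for c in counts_by_cond
        )
        if ok:
            edges.append(next_edge)
        next_edge += 1
    if len(edges) == 1 or edges[-1] <= hi:
        edges.append(hi + 1)
    return np.asarray(edges, dtype=float)


def count_matched_decoding(
    table: TrialTable,
    class_map=group_orientations,
    n_neuron_grid: np.ndarray | None = None,
    n_combos: int = 100,
    count_bins: np.ndarray | None = None,
    min_bin_samples: int = 20,
    replace: bool = False,
    n_boot: int = 1000,
    locomotion: str | None = None,
    seed: int | None = None,
) -> CountMatchedCurve:
    """Decoding accuracy as a function of population spike count, per laser
    condition.

    For every neuron-subset size in ``n_neuron_grid`` (default: a geometric
    ladder from 1 to the population size), ``n_combos`` subsets are drawn
    (without replacement by default — a physical neuron cannot appear
    twice — the with-replacement variant is available via ``replace``).
    Each subset yields per-trial (population count, LOOXV-correct) pairs
    within each laser condition; pairs are pooled over subsets and binned
    by population count. Per-bin accuracy comes with a bootstrap SE
    (``n_boot`` resamples). Empty bins report ``n_samples`` 0 and NaN
    accuracy.
    """
    rng = np.random.default_rng(seed)
    n_units = table.n_units
    if n_neuron_grid is None:
        grid = np.unique(
            np.round(np.geomspace(1, n_units, num=min(8, n_units))).astype(int)
        )
    else:
        grid = np.unique(np.asarray(n_neuron_grid, dtype=int))
        if grid.min() < 1:
            raise ValueError("neuron-subset sizes must be >= 1")
        if not replace and grid.max() > n_units:
            raise ValueError(
                "subset size exceeds the population; use replace=True to allow it"
            )

    conds = (False, True)
    masks = [table.select(laser=c, locomotion=locomotion) for c in conds]
    for c, m in zip(conds, masks):
        if not np.any(m):
            raise ValueError(f"no trials with laser_on={c} under the selector")
    pooled_counts: list[np.ndarray] = []
    pooled_correct: list[np.ndarray] = []
    for mask in masks:
        X_all = table.counts[mask].astype(float)
        y = np.asarray(class_map(table.stimulus_direction[mask]))
        classes, y_idx = np.unique(y, return_inverse=True)
        if classes.size < 2:
            raise ValueError("need at least two stimulus classes per condition")
        if np.bincount(y_idx).min() < 2:
            raise ValueError("every class needs >= 2 trials per condition")
        counts_acc, correct_acc = [], []
        for n in grid:
            for _ in range(n_combos):
                subset = rng.choice(n_units, size=int(n), replace=replace)
                Xs = X_all[:, subset]
                pred = _loo_predictions(Xs, y_idx, classes.size)
                counts_acc.append(Xs.sum(axis=1))
                correct_acc.append(pred == y_idx)
        pooled_counts.append(np.concatenate(counts_acc))
        pooled_correct.append(np.concatenate(correct_acc))

    if count_bins is None:
        edges = _merge_count_bins(pooled_counts, min_bin_samples)
    else:
        edges = np.asarray(count_bins, dtype=float)
        if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("count_bins must be increasing bin edges")
    B = edges.size - 1
    acc = np.full((2, B), np.nan)
    se = np.full((2, B), np.nan)
    n_samp = np.zeros((2, B), dtype=int)
    for ci in range(2):
        which = np.digitize(pooled_counts[ci], edges) - 1
        for b in range(B):
            flags = pooled_correct[ci][which == b]
            n_samp[ci, b] = flags.size
            if flags.size:
                p = float(np.mean(flags))
                acc[ci, b] = p
                # bootstrap over binary flags == binomial resampling
                boot = rng.binomial(flags.size, p, size=n_boot) / flags.size
                se[ci, b] = float(np.std(boot))
    return CountMatchedCurve(
        bin_edges=edges,
        conditions=("laser_off", "laser_on"),
        accuracy=acc,
        bootstrap_se=se,
        n_samples=n_samp,
        config={
            "n_neuron_grid": grid.tolist(),
            "n_combos": n_combos,
            "replace": replace,
            "min_bin_samples": min_bin_samples,
            "n_boot": n_boot,
            "locomotion": locomotion,
        },
    )
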