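"""Group-level inference for measurements nested within subjects.

Channels and cells are not independent across a mouse, so pooling them into
one big sample pseudo-replicates. Besides the usual rank tests and Spearman
correlation with Bonferroni control, this module provides a subject-
stratified permutation test: the statistic is the difference of condition
means computed *per subject* and then averaged with equal subject weight,
and the null distribution is built by permuting condition labels within
subject (paired design) or subject-to-condition assignments (unpaired).
That targets the same question as a nested/multilevel model comparison —
is there a condition effect robust to the nesting — with fewer
distributional assumptions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as scs

__all__ = [
    "NestedSample",
    "rank_tests",
    "spearman_bonferroni",
    "hierarchical_permutation_test",
    "subject_mean_t_test",
]


@dataclass
class NestedSample:
    """Scalar measurements tagged with the subject they came from."""

    values: np.ndarray
    subject_id: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.subject_id = np.asarray(self.subject_id)
        if self.values.shape != self.subject_id.shape or self.values.ndim != 1:
            raise ValueError("values and subject_id must be equal-length 1-D")
        if self.values.size < 2:
            raise ValueError("need at least two measurements")

    def subject_means(self) -> dict:
        return {
            s: float(self.values[self.subject_id == s].mean())
            for s in np.unique(self.subject_id)
        }


def rank_tests(
    x: np.ndarray, y: np.ndarray, paired: bool = False
) -> tuple[float, float]:
    """Two-sided Wilcoxon tests: signed-rank when ``paired``, rank-sum
    otherwise. Exact p-values for small samples without ties, normal
    approximation with tie correction otherwise; zero differences in the
    paired test are discarded (an all-zero difference vector gives p = 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least two values")
    if paired:
        if x.size != y.size:
            raise ValueError("paired samples must have equal length")
        d = x - y
        if np.all(d == 0):
            return 0.0, 1.0
        res = scs.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided")
    else:
        res = scs.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def spearman_bonferroni(
    pairs: list[tuple[np.ndarray, np.ndarray]], m: int | None = None
) -> list[dict]:
    """Spearman rank correlation per dataset with Bonferroni adjustment.

    ``m`` defaults to the number of datasets; each entry reports rho, the
    raw p and ``min(1, m · p)``. Constant inputs leave rho undefined
    (NaN, flagged).
    """
    if not pairs:
        raise ValueError("no datasets supplied")
    m = len(pairs) if m is None else int(m)
    if m < 1:
        raise ValueError("number of tests m must be >= 1")
    out = []
    for x, y in pairs:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size != y.size or x.size < 3:
            raise ValueError("each dataset needs n >= 3 paired values")
        if np.all(x == x[0]) or np.all(y == y[0]):
            out.append(
                {"rho": float("nan"), "p_raw": float("nan"),
                 "p_adjusted": float("nan"), "constant_input": True}
            )
            continue
        rho, p = scs.spearmanr(x, y)
        out.append(
            {"rho": float(rho), "p_raw": float(p),
             "p_adjusted": float(min(1.0, m * p)), "constant_input": False}
        )
    return out


def _paired_null(
    vals: list[tuple[np.ndarray, np.ndarray]],
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null statistics for the paired design: within each subject, the
    pooled observations are reshuffled between the two condition groups
    (sizes preserved); each permutation's statistic averages the per-subject
    mean differences with equal weight."""
    n_sub = len(vals)
    per_subj = np.empty((n_sub, n_perm))
    for i, (a, b) in enumerate(vals):
        pooled = np.concatenate([a, b])
        n_a, n_tot = a.size, pooled.size
        tiled = np.broadcast_to(pooled, (n_perm, n_tot))
        perm = rng.permuted(tiled, axis=1)
        per_subj[i] = perm[:, :n_a].mean(axis=1) - perm[:, n_a:].mean(axis=1)
    return per_subj.mean(axis=0)


def hierarchical_permutation_test(
    a: NestedSample,
    b: NestedSample,
    n_perm: int = 10000,
    seed: int | None = None,
) -> dict:
    """Subject-stratified permutation test of a condition effect.

    The observed statistic is the equal-weight average over subjects of the
    per-subject mean difference (condition a − condition b), which
    neutralizes pseudo-replication from subjects contributing many
    measurements. If both samples share the same subjects the design is
    paired and condition labels are permuted within subject; with disjoint
    subject sets, whole subjects are reassigned between conditions. The
    two-sided p-value is ``(1 + #{|perm| >= |obs|}) / (1 + n_perm)``.
    """
    rng = np.random.default_rng(seed)
    subj_a = set(np.unique(a.subject_id).tolist())
    subj_b = set(np.unique(b.subject_id).tolist())
    if len(subj_a | subj_b) < 2:
        raise ValueError(
            "a single subject cannot support a nested comparison; use a "
            "within-subject test instead"
        )
    if subj_a == subj_b:
        subjects = sorted(subj_a)
        vals = [
            (a.values[a.subject_id == s], b.values[b.subject_id == s])
            for s in subjects
        ]
        diffs = {s: float(va.mean() - vb.mean()) for s, (va, vb) in zip(subjects, vals)}
        observed = float(np.mean(list(diffs.values())))
        null = _paired_null(vals, n_perm, rng)
        design = "paired"
    elif subj_a.isdisjoint(subj_b):
        means_a = a.subject_means()
        means_b = b.subject_means()
        all_means = np.array(
            [means_a[s] for s in sorted(subj_a)] + [means_b[s] for s in sorted(subj_b)]
        )
        n_a = len(subj_a)
        observed = float(all_means[:n_a].mean() - all_means[n_a:].mean())
        null = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(all_means)
            null[i] = perm[:n_a].mean() - perm[n_a:].mean()
        diffs = {**{s: means_a[s] for s in sorted(subj_a)},
                 **{s: means_b[s] for s in sorted(subj_b)}}
        design = "unpaired"
    else:
        raise ValueError(
            "subject sets must be identical (paired) or disjoint (unpaired)"
        )
    p = (1.0 + np.count_nonzero(np.abs(null) >= abs(observed))) / (1.0 + n_perm)
    return {
        "p": float(p),
        "observed": observed,
        "design": design,
        "n_perm": n_perm,
        "subject_summary": diffs,
    }


def subject_mean_t_test(a: NestedSample, b: NestedSample) -> tuple[float, float]:
    """Summary-statistic cross-check: paired t-test on per-subject means
    (identical subject sets required)."""
    ma, mb = a.subject_means(), b.subject_means()
    if set(ma) != set(mb):
        raise ValueError("paired t-test on subject means needs identical subjects")
    keys = sorted(ma)
    res = scs.ttest_rel([ma[k] for k in keys], [mb[k] for k in keys])
    return float(res.statistic), float(res.pvalue)
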