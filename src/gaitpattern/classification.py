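"""Pairwise two-group leave-one-out classification with a maximal-margin
linear separator, binomial significance, and discriminant back-projection.

For every comparison, each trial row is held out in turn, a linear-kernel
support-vector machine is trained on the remaining rows, and the held-out
row is predicted; the classification rate r_class is the fraction of rows
predicted correctly.  Chance performance is 0.5, so significance is judged
against a one-sided binomial test: the comparison is significant when the
number of correct predictions reaches the smallest count c with
P(X >= c | Binomial(n, 0.5)) <= alpha.

Three comparison schemes mirror a splint-condition gait study design:

* every pair of subjects, pooling all their trials (is movement
  subject-specific?),
* each splint condition against the reference condition pooled across all
  subjects (is there a subject-independent condition effect?), and
* each splint condition against the reference within every subject
  (does the condition shift an individual's pattern?).

When a comparison is significant, the separator's weight vector (the
discriminant) marks which columns drive the separation; columns whose
|weight| exceeds twice the SD of all weights are the selected variables,
and group means are mapped back to degrees through the stored
standardization parameters.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.svm import SVC

from .errors import DegenerateDataError, ParameterError
from .waveform_prep import FeatureMatrix, NormalizationParams, inverse_standardize


@dataclass
class ComparisonResult:
    """Leave-one-out outcome of one two-group comparison."""

    group_a: str
    group_b: str
    n_trials: int
    n_correct: int
    r_class: float
    significant: bool
    alpha: float
    critical_count: int | None

    def __post_init__(self) -> None:
        assert abs(self.r_class - self.n_correct / self.n_trials) < 1e-12


def binomial_critical_count(n: int, p: float = 0.5, alpha: float = 0.05) -> int | None:
    """Smallest c with P(X >= c) <= alpha for X ~ Binomial(n, p); None if no c <= n works."""
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    if not (0 < p < 1) or not (0 < alpha < 1):
        raise ParameterError("p and alpha must lie strictly in (0, 1)")
    # P(X >= c) = sf(c - 1); scan upward, the tail is decreasing in c
    for c in range(n + 1):
        if binom.sf(c - 1, n, p) <= alpha:
            return c
    return None


def train_separator(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> SVC:
    """Fit the maximal-margin linear separator (hard margin approached as C grows)."""
    clf = SVC(kernel="linear", C=C)
    clf.fit(X, y)
    return clf


def loo_classify(
    X: np.ndarray,
    labels: np.ndarray,
    group_a: str,
    group_b: str,
    C: float = 1.0,
    alpha: float = 0.05,
) -> ComparisonResult:
    """Leave-one-out classification rate of group_a vs group_b rows.

    Deterministic given the data: zero decision values predict group_a.
    """
    labels = np.asarray(labels)
    X = np.asarray(X, dtype=float)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ParameterError(f"need exactly 2 classes, got {classes.size}")
    if {group_a, group_b} != set(classes):
        raise ParameterError("group_a/group_b must match the provided labels")
    for g in (group_a, group_b):
        if (labels == g).sum() < 2:
            raise ParameterError(f"group {g!r} needs at least 2 rows")
    y = (labels == group_b).astype(int)  # decision > 0 -> group_b
    n = X.shape[0]
    n_correct = 0
    idx = np.arange(n)
    # the linear kernel is computed once; each fold solves the same
    # maximal-margin problem on the cached Gram submatrix
    gram = X @ X.T
    for i in range(n):
        mask = idx != i
        if len(np.unique(y[mask])) < 2:  # pragma: no cover - guarded by >=2/group
            continue
        clf = SVC(kernel="precomputed", C=C)
        clf.fit(gram[np.ix_(mask, mask)], y[mask])
        d = float(clf.decision_function(gram[i : i + 1, mask])[0])
        pred = 1 if d > 0 else 0  # ties go to group_a
        n_correct += int(pred == y[i])
    cc = binomial_critical_count(n, 0.5, alpha)
    return ComparisonResult(
        group_a=group_a,
        group_b=group_b,
        n_trials=n,
        n_correct=n_correct,
        r_class=n_correct / n,
        significant=cc is not None and n_correct >= cc,
        alpha=alpha,
        critical_count=cc,
    )


def pairwise_subject_comparisons(
    matrix: FeatureMatrix, C: float = 1.0, alpha: float = 0.05
) -> list[ComparisonResult]:
    """All unordered subject pairs, pooling each subject's trials of all
    conditions and sides; subjects with fewer than 2 rows are excluded."""
    subjects = list(dict.fromkeys(matrix.row_labels["subject"]))
    counts = matrix.row_labels["subject"].value_counts()
    usable = [s for s in subjects if counts[s] >= 2]
    dropped = sorted(set(subjects) - set(usable))
    if dropped:
        warnings.warn(f"excluding subject(s) with < 2 trials: {dropped}", stacklevel=2)
    if len(usable) < 2:
        raise ParameterError("need at least 2 subjects with >= 2 trials")
    results = []
    subj = matrix.row_labels["subject"].to_numpy()
    for a, b in itertools.combinations(usable, 2):
        mask = (subj == a) | (subj == b)
        results.append(
            loo_classify(matrix.values[mask], subj[mask], a, b, C=C, alpha=alpha)
        )
    return results


def condition_comparisons_across(
    matrix: FeatureMatrix,
    reference: str = "Neutral",
    C: float = 1.0,
    alpha: float = 0.05,
) -> list[ComparisonResult]:
    """Reference condition vs each other condition, all subjects pooled."""
    conditions = list(dict.fromkeys(matrix.row_labels["condition"]))
    if reference not in conditions:
        raise ParameterError(f"reference condition {reference!r} not present")
    others = [c for c in conditions if c != reference]
    if not others:
        raise ParameterError("need at least one non-reference condition")
    cond = matrix.row_labels["condition"].to_numpy()
    results = []
    for other in others:
        mask = (cond == reference) | (cond == other)
        results.append(
            loo_classify(matrix.values[mask], cond[mask], reference, other, C=C, alpha=alpha)
        )
    return results


def condition_comparisons_within(
    matrix: FeatureMatrix,
    reference: str = "Neutral",
    C: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-subject reference-vs-splint comparisons (one row per comparison).

    Returns a tidy table with columns subject, comparison, n_trials,
    n_correct, r_class, significant; cells with too few trials on either
    side are marked missing (NaN rate) with a warning.  Use
    :func:`within_table` to pivot it into the subjects-as-columns layout.
    """
    conditions = list(dict.fromkeys(matrix.row_labels["condition"]))
    if reference not in conditions:
        raise ParameterError(f"reference condition {reference!r} not present")
    others = [c for c in conditions if c != reference]
    subjects = list(dict.fromkeys(matrix.row_labels["subject"]))
    subj = matrix.row_labels["subject"].to_numpy()
    cond = matrix.row_labels["condition"].to_numpy()
    rows = []
    for s in subjects:
        for other in others:
            mask = (subj == s) & ((cond == reference) | (cond == other))
            sub_cond = cond[mask]
            if (sub_cond == reference).sum() < 2 or (sub_cond == other).sum() < 2:
                warnings.warn(
                    f"subject {s}: insufficient trials for {reference} vs {other}",
                    stacklevel=2,
                )
                rows.append((s, f"{reference} vs {other}", 0, 0, np.nan, False))
                continue
            res = loo_classify(
                matrix.values[mask], sub_cond, reference, other, C=C, alpha=alpha
            )
            rows.append(
                (s, f"{reference} vs {other}", res.n_trials, res.n_correct, res.r_class, res.significant)
            )
    return pd.DataFrame(
        rows,
        columns=["subject", "comparison", "n_trials", "n_correct", "r_class", "significant"],
    )


def within_table(within: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Pivot the within-subject results: comparisons as rows, subjects as
    columns; returns (rates, significance flags, mean rate per comparison)."""
    rates = within.pivot(index="comparison", columns="subject", values="r_class")
    flags = within.pivot(index="comparison", columns="subject", values="significant")
    return rates, flags, rates.mean(axis=1, skipna=True)


@dataclass
class DiscriminantProfile:
    """Unit-norm discriminant with the 2xSD variable selection and
    back-projected angle-space profiles (degrees)."""

    weights: np.ndarray
    threshold: float
    selected_columns: np.ndarray
    angle_names: tuple[str, ...]
    n_time: int
    group_means_deg: dict[str, np.ndarray] = field(default_factory=dict)

    def weights_by_angle(self) -> dict[str, np.ndarray]:
        return {
            a: self.weights[i * self.n_time : (i + 1) * self.n_time]
            for i, a in enumerate(self.angle_names)
        }

    def selected_mask_by_angle(self) -> dict[str, np.ndarray]:
        mask = np.zeros(self.weights.size, dtype=bool)
        mask[self.selected_columns] = True
        return {
            a: mask[i * self.n_time : (i + 1) * self.n_time]
            for i, a in enumerate(self.angle_names)
        }


def extract_discriminant(
    separator: SVC,
    params: NormalizationParams,
    X: np.ndarray | None = None,
    labels: np.ndarray | None = None,
) -> DiscriminantProfile:
    """Discriminant weights of a trained linear separator.

    The weight vector is normalized to unit length; columns with
    |w_i| > 2 * SD(w) are the selected variables.  If the training rows and
    labels are supplied, each group's mean row is mapped back to degrees via
    the standardization parameters (the pipeline is bijective, so actual
    movement values are recoverable).
    """
    if not hasattr(separator, "coef_"):
        raise ParameterError("separator must be a fitted linear-kernel SVM")
    w = np.asarray(separator.coef_, dtype=float).ravel()
    norm = np.linalg.norm(w)
    if norm <= 0:
        raise DegenerateDataError("degenerate separator: zero weight vector")
    w = w / norm
    threshold = 2.0 * float(np.std(w))
    selected = np.flatnonzero(np.abs(w) > threshold)
    group_means: dict[str, np.ndarray] = {}
    if X is not None and labels is not None:
        labels = np.asarray(labels)
        for g in np.unique(labels):
            mean_std = np.asarray(X, dtype=float)[labels == g].mean(axis=0)
            group_means[str(g)] = inverse_standardize(mean_std, params)
    return DiscriminantProfile(
        weights=w,
        threshold=threshold,
        selected_columns=selected,
        angle_names=params.angle_names,
        n_time=params.n_time,
        group_means_deg=group_means,
    )
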