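"""Time-resolved decoding of the two stimulus conditions.

For every timepoint a linear support-vector machine is trained on the
channel vector and evaluated with stratified 8-group cross-validation
(leave-one-group-out), repeated with random regroupings (100 repetitions by
default) and averaged.  On top of the accuracy time series the module
provides the per-timepoint confusion series, temporal generalization
(train at one timepoint, test at all), Haufe activation patterns
(covariance x weights, the interpretable counterpart of classifier weights),
and group-level inference by sign permutation against chance with
Benjamini-Hochberg FDR across timepoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn import config_context
from sklearn.svm import LinearSVC
from statsmodels.stats.multitest import multipletests

from .synth import EpochSet


def fold_assignments(rng: np.random.Generator, y: np.ndarray,
                     n_folds: int) -> np.ndarray:
    """Stratified random grouping: each fold receives an equal (+/-1) number
    of trials of each class."""
    fold = np.empty(y.shape[0], dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if idx.size < n_folds:
            raise ValueError(
                f"class {cls!r} has {idx.size} trials, fewer than "
                f"{n_folds} folds"
            )
        perm = rng.permutation(idx)
        fold[perm] = np.arange(perm.size) % n_folds
    return fold


@dataclass
class DecodingResult:
    """Repetition-averaged decoding output for one participant."""

    times: np.ndarray
    accuracy: np.ndarray            # (T,) proportion correct, chance 0.5
    confusion: dict[str, np.ndarray]  # four (T,) series, rows sum to 1
    weights: np.ndarray             # (channels, T) mean SVM weights
    labels: tuple[str, str]
    chance: float = 0.5
    n_folds: int = 8
    n_repetitions: int = 100
    epochs: EpochSet | None = field(default=None, repr=False)


@dataclass
class TGMatrix:
    """Temporal-generalization accuracy: train time x test time."""

    times: np.ndarray
    matrix: np.ndarray  # (T_train, T_test)
    labels: tuple[str, str]
    chance: float = 0.5

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.matrix)


def _prepare(epochs: EpochSet, decim: int, correct_only: bool):
    trials = epochs.trials
    keep = np.ones(len(trials), dtype=bool)
    if correct_only:
        keep &= trials["correct"].to_numpy()
    labels = tuple(sorted(trials.loc[keep, "condition"].unique()))
    if len(labels) != 2:
        raise ValueError(
            f"decoding needs exactly two conditions, got {labels}"
        )
    y = (trials.loc[keep, "condition"].to_numpy() == labels[1]).astype(int)
    X = np.ascontiguousarray(
        epochs.data[keep][:, :, ::decim].transpose(2, 0, 1)
    )  # (T, trials, channels)
    times = epochs.times[::decim]
    return X, y, times, labels


def _run_cv(
    X: np.ndarray,  # (T, trials, channels)
    y: np.ndarray,
    n_folds: int,
    n_repetitions: int,
    seed: int,
    tg: bool,
    C: float,
):
    n_time, n_trials, _ = X.shape
    rng = np.random.default_rng(seed)
    acc = np.zeros((n_time, n_time) if tg else n_time)
    # predicted-as-class counts per true class, per timepoint
    conf = np.zeros((2, 2, n_time))
    wsum = np.zeros((X.shape[2], n_time))
    n_per_class = np.array([(y == 0).sum(), (y == 1).sum()])

    with config_context(assume_finite=True):
        _cv_loop(X, y, n_folds, n_repetitions, rng, tg, C, acc, conf, wsum)

    denom = n_trials * n_repetitions
    acc = acc / denom
    conf = conf / (n_per_class[:, None, None] * n_repetitions)
    wmean = wsum / (n_folds * n_repetitions)
    return acc, conf, wmean


def _cv_loop(X, y, n_folds, n_repetitions, rng, tg, C, acc, conf, wsum):
    n_time = X.shape[0]
    for _ in range(n_repetitions):
        fold = fold_assignments(rng, y, n_folds)
        for f in range(n_folds):
            test = fold == f
            train = ~test
            ytr, yte = y[train], y[test]
            for t in range(n_time):
                Xtr = X[t, train]
                mu = Xtr.mean(axis=0)
                sd = Xtr.std(axis=0)
                sd[sd == 0] = 1.0
                clf = LinearSVC(C=C, dual=True, tol=1e-3, max_iter=2000,
                                random_state=0)
                clf.fit((Xtr - mu) / sd, ytr)
                w = clf.coef_[0] / sd
                b = clf.intercept_[0] - (clf.coef_[0] * mu / sd).sum()
                wsum[:, t] += clf.coef_[0]
                if tg:
                    # scores for the test trials at every test timepoint
                    scores = X[:, test] @ w + b  # (T_test, n_test)
                    pred = scores > 0  # decision 0 -> first label
                    acc[t] += (pred == yte[None, :]).sum(axis=1)
                else:
                    scores = X[t, test] @ w + b
                    pred = scores > 0
                    acc[t] += (pred == yte).sum()
                    for cls in (0, 1):
                        m = yte == cls
                        conf[cls, 1, t] += pred[m].sum()
                        conf[cls, 0, t] += (~pred[m]).sum()


def decode_time_series(
    epochs: EpochSet,
    n_folds: int = 8,
    n_repetitions: int = 100,
    seed: int = 0,
    decim: int = 1,
    C: float = 1.0,
    correct_only: bool = False,
) -> DecodingResult:
    """Per-timepoint linear-SVM decoding with repeated stratified CV.

    ``decim`` keeps every ``decim``-th sample, trading temporal resolution for
    runtime.  Channel-wise z-scoring is fitted on the training folds only.
    """
    X, y, times, labels = _prepare(epochs, decim, correct_only)
    acc, conf, wmean = _run_cv(X, y, n_folds, n_repetitions, seed,
                               tg=False, C=C)
    confusion = {
        f"{labels[0]}_as_{labels[0]}": conf[0, 0],
        f"{labels[0]}_as_{labels[1]}": conf[0, 1],
        f"{labels[1]}_as_{labels[1]}": conf[1, 1],
        f"{labels[1]}_as_{labels[0]}": conf[1, 0],
    }
    return DecodingResult(times, acc, confusion, wmean, labels,
                          n_folds=n_folds, n_repetitions=n_repetitions,
                          epochs=epochs)


def temporal_generalization(
    epochs: EpochSet,
    n_folds: int = 8,
    n_repetitions: int = 100,
    seed: int = 0,
    decim: int = 1,
    C: float = 1.0,
    correct_only: bool = False,
) -> TGMatrix:
    """Train at each timepoint, test at all timepoints.

    Under the same seed the diagonal equals :func:`decode_time_series`
    exactly (identical fold draws and classifier fits).
    """
    X, y, times, labels = _prepare(epochs, decim, correct_only)
    acc, _, _ = _run_cv(X, y, n_folds, n_repetitions, seed, tg=True, C=C)
    return TGMatrix(times, acc, labels)


def confusion_series(result: DecodingResult) -> dict[str, np.ndarray]:
    """The four per-class proportion series; each class's pair sums to 1."""
    return result.confusion


def haufe_patterns(weights: np.ndarray, covariance: np.ndarray,
                   ridge: float = 0.0) -> np.ndarray:
    """Activation patterns from classifier weights: ``A = Cov @ W``.

    ``weights`` is (channels, T); ``covariance`` either one (channels,
    channels) matrix used for all timepoints or a (T, channels, channels)
    stack.  Patterns are rescaled to unit norm per timepoint.  ``ridge`` adds
    ``ridge * mean(diag) * I`` to a (near-)singular covariance.
    """
    weights = np.asarray(weights, dtype=float)
    covariance = np.asarray(covariance, dtype=float)
    n_chan, n_time = weights.shape

    def reg(c: np.ndarray) -> np.ndarray:
        if ridge > 0:
            return c + ridge * np.mean(np.diag(c)) * np.eye(n_chan)
        return c

    if covariance.ndim == 2:
        patterns = reg(covariance) @ weights
    else:
        patterns = np.stack(
            [reg(covariance[t]) @ weights[:, t] for t in range(n_time)], axis=1
        )
    norms = np.linalg.norm(patterns, axis=0, keepdims=True)
    norms[norms == 0] = 1.0
    return patterns / norms


def compute_patterns(result: DecodingResult, decim: int = 1,
                     correct_only: bool = False) -> np.ndarray:
    """Haufe patterns for a decoding result, using the per-timepoint channel
    covariance of the (z-scored) data the classifier saw."""
    if result.epochs is None:
        raise ValueError("decoding result does not retain its epochs")
    X, _, _, _ = _prepare(result.epochs, decim, correct_only)
    n_time = X.shape[0]
    patterns = np.empty_like(result.weights)
    for t in range(n_time):
        Xt = X[t]
        mu = Xt.mean(axis=0)
        sd = Xt.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (Xt - mu) / sd
        cov = np.cov(Z, rowvar=False)
        patterns[:, t] = cov @ result.weights[:, t]
    norms = np.linalg.norm(patterns, axis=0, keepdims=True)
    norms[norms == 0] = 1.0
    return patterns / norms


@dataclass
class SignPermResult:
    observed_mean: np.ndarray
    pvalues: np.ndarray
    qvalues: np.ndarray
    mask: np.ndarray
    alpha: float


def signperm_fdr(
    values: np.ndarray,
    chance: float = 0.5,
    alpha: float = 0.05,
    n_perms: int = 1000,
    seed: int = 0,
    tail: str = "greater",
) -> SignPermResult:
    """Group-level sign-permutation test against chance with BH-FDR.

    ``values`` is (participants, ...) — an accuracy time series stack or a
    stack of temporal-generalization matrices.  Per cell, the participant
    deviations from chance are randomly sign-flipped ``n_perms`` times; the
    empirical p compares the observed mean deviation with the flipped-mean
    null ((1 + exceedances) / (1 + n_perms)).  BH correction runs across all
    cells jointly.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim < 2 or values.shape[0] < 2:
        raise ValueError("need at least 2 participants on the first axis")
    if n_perms < 100:
        warnings.warn(f"n_perms={n_perms} is low for permutation inference")
    shape = values.shape[1:]
    d = (values - chance).reshape(values.shape[0], -1)
    n_p = d.shape[0]
    obs = d.mean(axis=0)
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perms, n_p))
    null = signs @ d / n_p  # (n_perms, cells)
    if tail == "greater":
        exceed = (null >= obs[None, :]).sum(axis=0)
    elif tail == "two-sided":
        exceed = (np.abs(null) >= np.abs(obs)[None, :]).sum(axis=0)
    else:
        raise ValueError("tail must be 'greater' or 'two-sided'")
    p = (1.0 + exceed) / (1.0 + n_perms)
    mask, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return SignPermResult(
        obs.reshape(shape), p.reshape(shape), q.reshape(shape),
        mask.reshape(shape), alpha,
    )
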