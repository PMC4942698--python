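"""Per-state lasso logistic classifiers and state-probability decoding.

One binary (one-vs-rest) lasso logistic regression model is trained per state
on the single localizer sample recorded ``train_latency_ms`` after stimulus
onset (default 200 ms). A trained model for state ``k`` is a weight vector of
length ``n_sensors + 1``: one slope per sensor plus an unpenalized intercept.
Applied to unlabeled data, each time point is treated independently:
``X[t, k] = sigmoid(intercept_k + slopes_k . data[t])``. The six models are
independent, so rows of ``X`` need not sum to 1.

The lasso penalty ``lam`` follows the glmnet convention
``(1/n) * sum(logloss) + lam * ||slopes||_1`` (mapped internally onto
scikit-learn's ``C``).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from .seqness import sequenceness_curve

DEFAULT_TRAIN_LATENCY_MS = 200.0
#: default penalty grid: 10 log-spaced points bracketing typical group modes
DEFAULT_LAMBDA_GRID = tuple(np.logspace(-4, -1, 10))


@dataclasses.dataclass
class StateClassifier:
    """Trained one-vs-rest model for a single state."""

    state: int
    slopes: np.ndarray      # (n_sensors,)
    intercept: float
    lam: float

    def __post_init__(self):
        self.slopes = np.asarray(self.slopes, dtype=float)
        if not (np.all(np.isfinite(self.slopes)) and np.isfinite(self.intercept)):
            raise ValueError("non-finite classifier weights")

    @property
    def beta(self) -> np.ndarray:
        """Full weight vector (slopes followed by the intercept)."""
        return np.concatenate([self.slopes, [self.intercept]])


@dataclasses.dataclass
class StateProbabilityMatrix:
    """Decoded time x state probability matrix for one trial."""

    data: np.ndarray
    bin_ms: float = 10.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("X must be 2-D (time x state)")
        if np.any(self.data <= 0) or np.any(self.data >= 1):
            raise ValueError("probabilities must lie strictly in (0, 1)")


@dataclasses.dataclass
class CrossValReport:
    """Cross-validated model outputs plus label-shuffle thresholds."""

    times_ms: np.ndarray
    mean_prob: np.ndarray          # (true state, model, time)
    accuracy: np.ndarray           # (time,)
    shuffle_max_probs: np.ndarray  # one maximal statistic per shuffle
    shuffle_max_accs: np.ndarray
    prob_threshold: float          # 95th percentile of shuffle_max_probs
    accuracy_threshold: float

    @property
    def chance_accuracy(self) -> float:
        return 1.0 / self.mean_prob.shape[0]


# ---------------------------------------------------------------------------
# Partitions
# ---------------------------------------------------------------------------

def balanced_partition(labels: Sequence[int], rng: np.random.Generator
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Random train/test split with balanced left-in classes.

    The split satisfies, exactly: (1) every class has at least one left-out
    trial; (2) every class has the same number of left-in trials; (3) the
    number of left-out trials is minimal given (1) and (2). These constraints
    force the per-class left-in count to ``min(class counts) - 1``; which
    trials are left out is random.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 trials")
    n_in = counts.min() - 1
    left_in, left_out = [], []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        idx = rng.permutation(idx)
        left_in.extend(idx[:n_in])
        left_out.extend(idx[n_in:])
    return np.sort(np.asarray(left_in)), np.sort(np.asarray(left_out))


# ---------------------------------------------------------------------------
# Training and prediction
# ---------------------------------------------------------------------------

def _latency_index(times_ms: np.ndarray, latency_ms: float) -> int:
    i = int(np.argmin(np.abs(times_ms - latency_ms)))
    if abs(times_ms[i] - latency_ms) > 1e-6:
        raise ValueError(f"latency {latency_ms} ms not on the epoch time grid")
    return i


def train_state_classifiers(epochs: np.ndarray, labels: Sequence[int],
                            lam: float,
                            times_ms: np.ndarray,
                            train_latency_ms: float = DEFAULT_TRAIN_LATENCY_MS,
                            max_iter: int = 2000,
                            tol: float = 1e-6) -> list[StateClassifier]:
    """Fit one lasso logistic model per state at a single epoch sample.

    ``epochs`` is (n_trials, n_times, n_sensors) with time 0 at stimulus
    onset; features are the sensor vector at ``train_latency_ms``. The L1
    penalty applies to slopes only; the intercept is unpenalized, so in the
    large-``lam`` limit all slopes are exactly 0 and the model predicts the
    class base rate.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    epochs = np.asarray(epochs, dtype=float)
    labels = np.asarray(labels)
    feats = epochs[:, _latency_index(np.asarray(times_ms), train_latency_ms), :]
    if np.allclose(feats.std(axis=0), 0):
        raise ValueError("degenerate features: zero variance in all sensors")
    n = feats.shape[0]
    C = 1.0 / (lam * n) if lam > 0 else 1e10
    out = []
    for state in np.unique(labels):
        y = (labels == state).astype(int)
        # liblinear with a large intercept_scaling leaves the intercept
        # effectively unpenalized (its L1 weight is intercept / scaling)
        clf = LogisticRegression(penalty="l1", C=C, solver="liblinear",
                                 fit_intercept=True, intercept_scaling=1e4,
                                 max_iter=max_iter, tol=tol, random_state=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(feats, y)
        slopes = clf.coef_[0].copy()
        intercept = _refit_intercept(feats @ slopes, y,
                                     float(clf.intercept_[0]))
        out.append(StateClassifier(state=int(state), slopes=slopes,
                                   intercept=intercept, lam=float(lam)))
    return out


def _refit_intercept(margins: np.ndarray, y: np.ndarray, b0: float,
                     n_iter: int = 50) -> float:
    """1-D Newton refit of the unpenalized intercept with slopes fixed.

    liblinear applies a (tiny but nonzero) L1 cost to the intercept via the
    augmented-feature trick; re-solving ``mean(sigmoid(m + b)) = mean(y)``
    removes that bias exactly -- in particular, with all slopes zero the
    intercept becomes the exact base-rate logit.
    """
    b = b0
    for _ in range(n_iter):
        p = expit(margins + b)
        grad = float(np.mean(p - y))
        hess = float(np.mean(p * (1 - p)))
        if hess < 1e-12 or abs(grad) < 1e-12:
            break
        b -= grad / hess
    return float(b)


def predict_state_probabilities(classifiers: Sequence[StateClassifier],
                                data: np.ndarray,
                                bin_ms: float = 10.0) -> StateProbabilityMatrix:
    """Decode a (time x sensor) array into per-state probabilities.

    Each time point is treated independently; column ``k`` holds
    ``sigmoid(intercept_k + slopes_k . data[t])``. Values are clipped away
    from exact 0/1 to keep entries strictly inside (0, 1).
    """
    data = np.asarray(data, dtype=float)
    if data.shape[1] != classifiers[0].slopes.shape[0]:
        raise ValueError("sensor count mismatch between data and classifiers")
    W = np.column_stack([c.slopes for c in classifiers])
    b = np.array([c.intercept for c in classifiers])
    X = expit(data @ W + b)
    eps = 1e-12
    return StateProbabilityMatrix(np.clip(X, eps, 1 - eps), bin_ms=bin_ms)


# ---------------------------------------------------------------------------
# Cross-validation report with label-shuffle null
# ---------------------------------------------------------------------------

def _crossval_once(epochs, labels, lam, times_ms, latency, n_partitions, rng,
                   max_iter):
    """Mean left-out probabilities and per-time accuracy over partitions."""
    classes = np.unique(labels)
    n_states, n_times = len(classes), epochs.shape[1]
    prob_sum = np.zeros((n_states, n_states, n_times))
    prob_cnt = np.zeros(n_states)
    correct = np.zeros(n_times)
    total = 0
    for _ in range(n_partitions):
        tr, te = balanced_partition(labels, rng)
        clfs = train_state_classifiers(epochs[tr], labels[tr], lam, times_ms,
                                       latency, max_iter=max_iter)
        for i in te:
            X = predict_state_probabilities(clfs, epochs[i]).data  # time x state
            true_idx = int(np.flatnonzero(classes == labels[i])[0])
            prob_sum[true_idx] += X.T
            prob_cnt[true_idx] += 1
            correct += (np.argmax(X, axis=1) == true_idx)
            total += 1
    mean_prob = prob_sum / prob_cnt[:, None, None]
    return mean_prob, correct / total


def crossval_report(epochs: np.ndarray, labels: Sequence[int], lam: float,
                    times_ms: np.ndarray,
                    rng: np.random.Generator,
                    train_latency_ms: float = DEFAULT_TRAIN_LATENCY_MS,
                    n_partitions: int = 50, n_shuffles: int = 100,
                    shuffle_partitions: int | None = None,
                    max_iter: int = 2000) -> CrossValReport:
    """Repeated balanced cross-validation plus a label-shuffle null.

    Accuracy at each peristimulus time is the fraction of left-out trials for
    which the argmax over the six model outputs equals the true state. The
    shuffle null permutes the labels and re-runs the full procedure; each
    shuffle contributes two maximal statistics -- max mean probability over
    (state, time) and max accuracy over time -- whose 95th percentiles are
    the significance thresholds.
    """
    if n_shuffles < 20:
        warnings.warn("n_shuffles < 20: shuffle threshold unstable",
                      stacklevel=2)
    epochs = np.asarray(epochs, dtype=float)
    labels = np.asarray(labels)
    times_ms = np.asarray(times_ms)
    mean_prob, accuracy = _crossval_once(
        epochs, labels, lam, times_ms, train_latency_ms, n_partitions, rng,
        max_iter)
    if shuffle_partitions is None:
        shuffle_partitions = n_partitions
    max_probs, max_accs = [], []
    for _ in range(n_shuffles):
        perm_labels = rng.permutation(labels)
        mp, acc = _crossval_once(epochs, perm_labels, lam, times_ms,
                                 train_latency_ms, shuffle_partitions, rng,
                                 max_iter)
        # on-diagonal mean probability: model k output on true-k data
        diag = np.array([mp[k, k] for k in range(mp.shape[0])])
        max_probs.append(diag.max())
        max_accs.append(acc.max())
    max_probs = np.asarray(max_probs)
    max_accs = np.asarray(max_accs)
    return CrossValReport(
        times_ms=times_ms, mean_prob=mean_prob, accuracy=accuracy,
        shuffle_max_probs=max_probs, shuffle_max_accs=max_accs,
        prob_threshold=float(np.percentile(max_probs, 95)),
        accuracy_threshold=float(np.percentile(max_accs, 95)))


# ---------------------------------------------------------------------------
# Penalty selection by leave-one-subject-out sequenceness
# ---------------------------------------------------------------------------

def select_penalty(subjects: Sequence[dict], lambdas: Sequence[float],
                   T: np.ndarray, lags_ms: Sequence[float],
                   rng: np.random.Generator,
                   train_latency_ms: float = DEFAULT_TRAIN_LATENCY_MS,
                   max_iter: int = 2000
                   ) -> tuple[dict[int, float], dict[float, int]]:
    """Choose a lasso penalty per subject by leave-one-subject-out.

    Each element of ``subjects`` is a dict with keys ``epochs`` (trials x
    times x sensors), ``labels``, ``times_ms`` and ``planning`` (list of
    time x sensor arrays). For every held-out subject the selected penalty is
    the candidate maximizing the absolute group-mean sequenceness difference,
    at its extremal lag, over the *other* subjects.

    Returns ``(per_subject_lambda, histogram)`` where the histogram counts
    one selection per subject.
    """
    lambdas = list(lambdas)
    if not lambdas:
        raise ValueError("candidate penalty grid is empty")
    if len(subjects) < 2:
        raise ValueError("need at least two subjects")
    # mean diff curve per (subject, lambda)
    curves = np.zeros((len(subjects), len(lambdas), len(lags_ms)))
    for si, sub in enumerate(subjects):
        for li, lam in enumerate(lambdas):
            clfs = train_state_classifiers(
                sub["epochs"], sub["labels"], lam, sub["times_ms"],
                train_latency_ms, max_iter=max_iter)
            diffs = []
            for planning in sub["planning"]:
                X = predict_state_probabilities(clfs, planning).data
                diffs.append(sequenceness_curve(X, T, lags_ms).diff)
            curves[si, li] = np.mean(diffs, axis=0)
    choice: dict[int, float] = {}
    for si in range(len(subjects)):
        others = np.delete(curves, si, axis=0).mean(axis=0)  # lambda x lag
        scores = np.abs(others).max(axis=1)
        choice[si] = float(lambdas[int(np.argmax(scores))])
    hist = {lam: sum(1 for v in choice.values() if v == lam) for lam in lambdas}
    return choice, hist
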