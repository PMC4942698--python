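"""Lagged sequenceness statistics and state-identity permutation nulls.

Given a decoded probability matrix ``X`` (time x state, 0-based columns) and
the task transition matrix ``T``, forward sequenceness at lag ``d`` is the
mean over states ``j`` of the Pearson correlation between column ``j`` of
``X @ T`` at time ``t`` and column ``j`` of ``X`` at time ``t + d`` --
i.e. how strongly evidence for the *predecessors* of ``j`` predicts evidence
for ``j`` a lag later. Reverse sequenceness uses ``X @ T.T``; the reported
statistic is forward minus reverse.

Sign convention (pinned by unit test): data containing an explicit forward
chain -- state ``a`` at ``t`` and a successor of ``a`` at ``t + d`` --
produce *positive* forward sequenceness at lag ``d``.

Correlations are taken over the truncated overlap (no padding); a
zero-variance column contributes correlation 0.

The null distribution permutes *state identities*: relabelings of the
transition matrix, grouped into equivalence classes of relabelings that
induce the same permuted matrix, excluding the identity class and the
reverse-order class (the relabeling mapping ``T`` onto ``T.T``). A
sample-order shuffle null is also provided; on autocorrelated data it is
anticonservative and is included for exactly that demonstration.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Sequence

import numpy as np

DEFAULT_LAGS_MS = tuple(range(10, 210, 10))
DEFAULT_BIN_MS = 10.0

_EPS = 1e-12


# ---------------------------------------------------------------------------
# Curves
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SequencenessCurve:
    """Forward, reverse, and difference sequenceness per lag."""

    lags_ms: np.ndarray
    forward: np.ndarray
    reverse: np.ndarray

    @property
    def diff(self) -> np.ndarray:
        return self.forward - self.reverse

    def extremal_lag(self) -> float:
        """Lag (ms) at which |forward - reverse| is largest."""
        return float(self.lags_ms[int(np.argmax(np.abs(self.diff)))])


def _lags_to_bins(lags_ms, bin_ms: float, n_samples: int, min_overlap: int = 3
                  ) -> np.ndarray:
    lags_ms = np.asarray(lags_ms, dtype=float)
    bins = lags_ms / bin_ms
    if np.any(np.abs(bins - np.round(bins)) > 1e-9) or np.any(bins < 1):
        raise ValueError("lags must be positive multiples of the bin size")
    bins = np.round(bins).astype(int)
    if bins.max() > n_samples - min_overlap:
        raise ValueError("max lag too long for this trial")
    return bins


def _lagged_moments(X: np.ndarray, d: int):
    """Second moments for lag ``d`` over the truncated overlap.

    Returns ``(C, S, L)`` where ``C[i, j] = cov(X_i(t), X_j(t+d))``,
    ``S = cov`` of the early window with itself, and ``L[j] = var`` of the
    late window of column ``j``. All covariances use the window means.
    """
    A = X[:X.shape[0] - d]
    B = X[d:]
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    m = A.shape[0]
    C = Ac.T @ Bc / m
    S = Ac.T @ Ac / m
    L = np.einsum("ij,ij->j", Bc, Bc) / m
    return C, S, L


def _mean_lagged_corr(moments, M: np.ndarray) -> float:
    """Mean over columns j of corr((X @ M)_j early, X_j late)."""
    C, S, L = moments
    num = np.einsum("ij,ij->j", M, C)
    var1 = np.einsum("ij,ik,kj->j", M, S, M)
    denom = np.sqrt(np.clip(var1, 0.0, None) * np.clip(L, 0.0, None))
    corr = np.where(denom > _EPS, num / np.where(denom > _EPS, denom, 1.0), 0.0)
    return float(corr.mean())


def transition_transform(X: np.ndarray, T: np.ndarray, steps: int = 1,
                         reverse: bool = False) -> np.ndarray:
    """Project ``X`` through ``steps`` applications of the transition matrix.

    Forward: ``X @ T**steps`` -- column ``j`` aggregates evidence for the
    depth-``steps`` predecessors of state ``j``. Reverse uses ``T.T``.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    X = np.asarray(X, dtype=float)
    T = np.asarray(T, dtype=float)
    if X.shape[1] != T.shape[0] or T.shape[0] != T.shape[1]:
        raise ValueError("shape mismatch between X and T")
    M = np.linalg.matrix_power(T.T if reverse else T, steps)
    return X @ M


def sequenceness_curve(X: np.ndarray, T: np.ndarray,
                       lags_ms: Sequence[float] = DEFAULT_LAGS_MS,
                       bin_ms: float = DEFAULT_BIN_MS) -> SequencenessCurve:
    """Forward/reverse sequenceness of one trial at each requested lag."""
    X = np.asarray(X, dtype=float)
    T = np.asarray(T, dtype=float)
    bins = _lags_to_bins(lags_ms, bin_ms, X.shape[0])
    fwd = np.empty(len(bins))
    rev = np.empty(len(bins))
    for i, d in enumerate(bins):
        moments = _lagged_moments(X, int(d))
        fwd[i] = _mean_lagged_corr(moments, T)
        rev[i] = _mean_lagged_corr(moments, T.T)
    return SequencenessCurve(lags_ms=np.asarray(lags_ms, dtype=float),
                             forward=fwd, reverse=rev)


def brute_force_sequenceness(X, T, lag_ms: float,
                             bin_ms: float = DEFAULT_BIN_MS) -> float:
    """Explicit-loop oracle for the forward-minus-reverse statistic.

    Recomputes the same quantity as :func:`sequenceness_curve` at a single
    lag using plain Python loops over states and time samples -- no matrix
    algebra. Intended for small inputs (<= ~500 bins).
    """
    X = [list(map(float, row)) for row in np.asarray(X)]
    T = [list(map(float, row)) for row in np.asarray(T)]
    n_time = len(X)
    n_states = len(T)
    d = int(round(lag_ms / bin_ms))

    def col_corr(early_col, late_col):
        m = len(early_col)
        me = sum(early_col) / m
        ml = sum(late_col) / m
        cov = var_e = var_l = 0.0
        for t in range(m):
            cov += (early_col[t] - me) * (late_col[t] - ml)
            var_e += (early_col[t] - me) ** 2
            var_l += (late_col[t] - ml) ** 2
        if var_e <= _EPS * m or var_l <= _EPS * m:
            return 0.0
        return cov / (var_e * var_l) ** 0.5

    def mean_corr(transposed):
        total = 0.0
        for j in range(n_states):
            proj = []
            for t in range(n_time - d):
                acc = 0.0
                for i in range(n_states):
                    acc += X[t][i] * (T[j][i] if transposed else T[i][j])
                proj.append(acc)
            late = [X[t + d][j] for t in range(n_time - d)]
            total += col_corr(proj, late)
        return total / n_states

    return mean_corr(False) - mean_corr(True)


def length_n_curve(X: np.ndarray, T: np.ndarray, n: int,
                   lags_ms: Sequence[float] = DEFAULT_LAGS_MS,
                   bin_ms: float = DEFAULT_BIN_MS) -> SequencenessCurve:
    """Length-``n`` sequence statistic (un-normalized products) per lag.

    For each state ``j`` and lag ``d``, multiplies element-wise the
    mean-centred columns
    ``(X @ T^(n-1))_j(t), (X @ T^(n-2))_j(t + d), ..., X_j(t + (n-1) d)`` and
    averages the product over the valid window, so a planted forward chain
    ending at ``j`` yields a positive forward value. The reverse statistic
    uses powers of ``T.T``. Columns are centred (cross-correlation style) but
    the products are *not* variance-normalized, so values are per-time
    densities that are not comparable across different ``n``; compare
    reliabilities instead. Centring matters: with raw probabilities a
    length-``n`` chain would masquerade as a length-``n+1`` chain via the
    positive probability baseline.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    X = np.asarray(X, dtype=float)
    T = np.asarray(T, dtype=float)
    lags_ms = np.asarray(lags_ms, dtype=float)
    bins = np.round(lags_ms / bin_ms).astype(int)
    if np.any((n - 1) * bins >= X.shape[0]):
        raise ValueError("trial too short for these lags at this n")
    X = X - X.mean(axis=0)

    def stat(M):
        mats = [X]
        for _ in range(n - 1):
            mats.append(mats[-1] @ M)
        out = np.empty(len(bins))
        for i, d in enumerate(bins):
            w = X.shape[0] - (n - 1) * d
            prod = np.ones((w, X.shape[1]))
            for m in range(n):
                prod *= mats[n - 1 - m][m * d:m * d + w]
            out[i] = prod.sum(axis=0).mean() / w
        return out

    return SequencenessCurve(lags_ms=lags_ms, forward=stat(T), reverse=stat(T.T))


def pairwise_sequenceness(X: np.ndarray, pair: tuple[int, int], lag_ms: float,
                          bin_ms: float = DEFAULT_BIN_MS) -> float:
    """Forward-minus-reverse cross-correlation for one ordered state pair.

    ``pair = (i, j)`` with 0-based column indices: returns
    ``corr(X_i(t), X_j(t+d)) - corr(X_j(t), X_i(t+d))``; antisymmetric in
    pair order by construction. Zero-variance columns contribute 0.
    """
    i, j = pair
    if i == j:
        raise ValueError("pair must be two distinct states")
    return float(pairwise_matrix(X, lag_ms, bin_ms)[i, j])


def pairwise_matrix(X: np.ndarray, lag_ms: float,
                    bin_ms: float = DEFAULT_BIN_MS) -> np.ndarray:
    """All ordered-pair sequenceness scores at one lag (antisymmetric)."""
    X = np.asarray(X, dtype=float)
    d = int(_lags_to_bins([lag_ms], bin_ms, X.shape[0])[0])
    C, S, L = _lagged_moments(X, d)
    sd_e = np.sqrt(np.clip(np.diag(S), 0.0, None))
    sd_l = np.sqrt(np.clip(L, 0.0, None))
    denom = np.outer(sd_e, sd_l)
    corr = np.where(denom > _EPS, C / np.where(denom > _EPS, denom, 1.0), 0.0)
    out = corr - corr.T
    np.fill_diagonal(out, 0.0)
    return out


# ---------------------------------------------------------------------------
# State-identity permutation classes
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class LabelClassSet:
    """Equivalence classes of state relabelings of a transition matrix.

    Two relabelings are equivalent iff they induce the same permuted matrix
    ``T[p][:, p]``. ``representatives`` holds one permutation array per
    class; ``identity_index`` / ``reversal_index`` locate the class whose
    matrix equals ``T`` / ``T.T`` (None if absent).
    """

    representatives: list[np.ndarray]
    class_sizes: list[int]
    identity_index: int | None
    reversal_index: int | None

    @property
    def n_classes(self) -> int:
        return len(self.representatives)

    def shuffle_representatives(self) -> list[np.ndarray]:
        """Class representatives excluding the identity and reversal classes."""
        skip = {self.identity_index, self.reversal_index}
        return [p for k, p in enumerate(self.representatives) if k not in skip]


def permute_matrix(T: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Relabeled transition matrix ``M[a, b] = T[perm[a], perm[b]]``."""
    perm = np.asarray(perm)
    return T[np.ix_(perm, perm)]


def enumerate_label_classes(T: np.ndarray) -> LabelClassSet:
    """Group all ``n!`` relabelings by the permuted matrix they induce."""
    T = np.asarray(T, dtype=float)
    n = T.shape[0]
    key_id = np.round(T, 12).tobytes()
    key_rev = np.round(T.T, 12).tobytes()
    classes: dict[bytes, list] = {}
    for p in itertools.permutations(range(n)):
        M = permute_matrix(T, np.array(p))
        key = np.round(M, 12).tobytes()
        if key in classes:
            classes[key][1] += 1
        else:
            classes[key] = [np.array(p), 1]
    reps, sizes = [], []
    identity_index = reversal_index = None
    for key, (p, size) in classes.items():
        if key == key_id:
            identity_index = len(reps)
        elif key == key_rev:
            reversal_index = len(reps)
        reps.append(p)
        sizes.append(size)
    return LabelClassSet(representatives=reps, class_sizes=sizes,
                         identity_index=identity_index,
                         reversal_index=reversal_index)


# ---------------------------------------------------------------------------
# Permutation thresholds
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ShuffleNull:
    """Permutation-null summary for a mean sequenceness-difference curve."""

    lags_ms: np.ndarray
    observed: np.ndarray           # mean diff curve over trials
    shuffle_curves: np.ndarray     # (n_shuffles, n_lags)
    permutations: list[np.ndarray]
    per_lag_threshold: np.ndarray  # max over shuffles of |diff| at each lag
    global_threshold: float        # max over shuffles and lags
    exceeds_global: bool
    p_value: float
    nominal_level: float           # two-tailed level, 1 / n_shuffles

    @property
    def n_shuffles(self) -> int:
        return self.shuffle_curves.shape[0]


def _trial_moment_cache(X_trials, bins):
    cache = []
    for X in X_trials:
        X = np.asarray(X, dtype=float)
        cache.append({int(d): _lagged_moments(X, int(d)) for d in bins})
    return cache


def _mean_diff_from_cache(cache, M, bins) -> np.ndarray:
    out = np.zeros(len(bins))
    for i, d in enumerate(bins):
        vals = [_mean_lagged_corr(c[int(d)], M) - _mean_lagged_corr(c[int(d)], M.T)
                for c in cache]
        out[i] = np.mean(vals)
    return out


def mean_diff_curve(X_trials: Sequence[np.ndarray], T: np.ndarray,
                    lags_ms: Sequence[float] = DEFAULT_LAGS_MS,
                    bin_ms: float = DEFAULT_BIN_MS) -> np.ndarray:
    """Unweighted mean over trials of the per-trial diff curve."""
    return np.mean([sequenceness_curve(np.asarray(X), T, lags_ms, bin_ms).diff
                    for X in X_trials], axis=0)


def empirical_two_tailed_level(n_shuffles: int) -> float:
    """Nominal two-tailed level of the maximal-statistic permutation test:
    exceeding the peak of ``n`` exchangeable shuffles has level ``1/n``."""
    if n_shuffles < 1:
        raise ValueError("need at least one shuffle")
    return 1.0 / n_shuffles


def permutation_thresholds(X_trials: Sequence[np.ndarray], T: np.ndarray,
                           lags_ms: Sequence[float] = DEFAULT_LAGS_MS,
                           bin_ms: float = DEFAULT_BIN_MS,
                           max_shuffles: int | None = None,
                           rng: np.random.Generator | None = None
                           ) -> ShuffleNull:
    """State-identity permutation null with maximal-statistic thresholds.

    For every non-identity, non-reversal relabeling class the mean diff curve
    is recomputed under the permuted transition matrix. The per-lag threshold
    is the max over shuffles of |diff| at that lag; the global threshold is
    the max over shuffles *and* lags (family-wise control over lags). The
    empirical two-tailed p of the observed curve is
    ``(1 + #shuffle peaks >= observed peak) / n_shuffles`` capped at 1, so an
    observed peak exceeding every shuffle has p = 1/n_shuffles.

    ``max_shuffles`` randomly subsamples the shuffle classes (seeded by
    ``rng``) to bound cost.
    """
    if len(X_trials) < 1:
        raise ValueError("need at least one trial")
    T = np.asarray(T, dtype=float)
    lags_ms = np.asarray(lags_ms, dtype=float)
    min_len = min(np.asarray(X).shape[0] for X in X_trials)
    bins = _lags_to_bins(lags_ms, bin_ms, min_len)
    reps = enumerate_label_classes(T).shuffle_representatives()
    if max_shuffles is not None and len(reps) > max_shuffles:
        if rng is None:
            raise ValueError("rng required when subsampling shuffles")
        idx = rng.choice(len(reps), size=max_shuffles, replace=False)
        reps = [reps[i] for i in sorted(idx)]
    if len(reps) < 10:
        warnings.warn("fewer than 10 shuffle classes: threshold is coarse",
                      stacklevel=2)
    cache = _trial_moment_cache(X_trials, bins)
    observed = _mean_diff_from_cache(cache, T, bins)
    curves = np.array([_mean_diff_from_cache(cache, permute_matrix(T, p), bins)
                       for p in reps])
    per_lag = np.abs(curves).max(axis=0)
    global_thr = float(per_lag.max())
    obs_peak = float(np.abs(observed).max())
    n_exceeding = int(np.sum(np.abs(curves).max(axis=1) >= obs_peak))
    p = min(1.0, (1 + n_exceeding) / len(reps))
    return ShuffleNull(lags_ms=lags_ms, observed=observed,
                       shuffle_curves=curves, permutations=reps,
                       per_lag_threshold=per_lag, global_threshold=global_thr,
                       exceeds_global=obs_peak > global_thr, p_value=p,
                       nominal_level=empirical_two_tailed_level(len(reps)))


def sample_order_thresholds(X_trials: Sequence[np.ndarray], T: np.ndarray,
                            lags_ms: Sequence[float] = DEFAULT_LAGS_MS,
                            bin_ms: float = DEFAULT_BIN_MS,
                            n_shuffles: int = 28,
                            rng: np.random.Generator | None = None
                            ) -> ShuffleNull:
    """Sample-order shuffle null: permute time bins within each trial.

    Provided as a comparison baseline only -- destroying temporal
    autocorrelation makes this null far too tight on realistic data, so it
    yields inflated false-positive rates. Use
    :func:`permutation_thresholds` for inference.
    """
    if rng is None:
        raise ValueError("rng is required")
    T = np.asarray(T, dtype=float)
    lags_ms = np.asarray(lags_ms, dtype=float)
    X_trials = [np.asarray(X, dtype=float) for X in X_trials]
    min_len = min(X.shape[0] for X in X_trials)
    bins = _lags_to_bins(lags_ms, bin_ms, min_len)
    cache = _trial_moment_cache(X_trials, bins)
    observed = _mean_diff_from_cache(cache, T, bins)
    curves = np.empty((n_shuffles, len(bins)))
    for s in range(n_shuffles):
        shuffled = [X[rng.permutation(X.shape[0])] for X in X_trials]
        sc = _trial_moment_cache(shuffled, bins)
        curves[s] = _mean_diff_from_cache(sc, T, bins)
    per_lag = np.abs(curves).max(axis=0)
    global_thr = float(per_lag.max())
    obs_peak = float(np.abs(observed).max())
    n_exceeding = int(np.sum(np.abs(curves).max(axis=1) >= obs_peak))
    return ShuffleNull(lags_ms=lags_ms, observed=observed,
                       shuffle_curves=curves, permutations=[],
                       per_lag_threshold=per_lag, global_threshold=global_thr,
                       exceeds_global=obs_peak > global_thr,
                       p_value=min(1.0, (1 + n_exceeding) / n_shuffles),
                       nominal_level=empirical_two_tailed_level(n_shuffles))
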