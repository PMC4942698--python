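"""Group-level inference for trial-wise sequenceness values.

The workhorse is a random-intercept model ``y_i = beta + b_k + e_i`` with
``b_k ~ N(0, sigma_b^2)`` per subject and ``e_i ~ N(0, sigma_e^2)``, fit by
maximum likelihood (profiling the variance ratio) with a Wald two-tailed p
for the fixed intercept. A single fixed-slope covariate can be added, which
serves the trial-wise regressions of sequenceness on earnings or planning
time. Also provided: the chosen-vs-unchosen tuple contrast, subject-mean
OLS regression, and a one-way ANOVA across directed task-edge pairs.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps
from scipy.optimize import minimize_scalar

from .task import TaskGraph


@dataclasses.dataclass
class MixedModelFit:
    """ML fit of the random-intercept model."""

    beta: float
    se: float
    z: float
    p: float
    sigma_b: float
    sigma_e: float
    loglik: float
    loglik_no_random: float   # loglik at sigma_b = 0 (OLS submodel)
    n_obs: int
    n_groups: int
    slope: float | None = None
    slope_se: float | None = None
    slope_p: float | None = None

    def __post_init__(self):
        if self.sigma_b < 0 or self.sigma_e < 0:
            raise ValueError("variance components must be >= 0")
        if not (0 < self.p <= 1):
            raise ValueError("p must lie in (0, 1]")


def _profile_loglik(theta: float, y_groups, X_groups):
    """Profiled ML log-likelihood at variance ratio theta = sigma_b^2/sigma_e^2.

    Uses the Woodbury identity per group: V_k^{-1} = I - w_k J with
    w_k = theta / (1 + theta * n_k). Returns (loglik, beta_hat, cov_unscaled,
    sigma_e^2) where SE(beta) = sqrt(sigma_e^2 * cov_unscaled).
    """
    p = X_groups[0].shape[1]
    XtViX = np.zeros((p, p))
    XtViy = np.zeros(p)
    N = 0
    logdet = 0.0
    for y, X in zip(y_groups, X_groups):
        nk = len(y)
        w = theta / (1.0 + theta * nk)
        Xs, ys = X.sum(axis=0), y.sum()
        XtViX += X.T @ X - w * np.outer(Xs, Xs)
        XtViy += X.T @ y - w * Xs * ys
        logdet += np.log1p(theta * nk)
        N += nk
    beta = np.linalg.solve(XtViX, XtViy)
    quad = 0.0
    for y, X in zip(y_groups, X_groups):
        r = y - X @ beta
        w = theta / (1.0 + theta * len(y))
        quad += r @ r - w * r.sum() ** 2
    sigma_e2 = quad / N
    ll = -0.5 * (N * np.log(2 * np.pi * sigma_e2) + logdet + N)
    return ll, beta, np.linalg.inv(XtViX), sigma_e2


def mixed_intercept_fit(y: Sequence[float], subject_ids: Sequence,
                        x: Sequence[float] | None = None) -> MixedModelFit:
    """Fit the random-intercept model by maximum likelihood.

    Parameters
    ----------
    y : array-like
        Trial-level values.
    subject_ids : array-like
        Group label per observation.
    x : array-like, optional
        A single fixed-slope covariate; when given, ``slope``/``slope_p``
        report a Wald test of the covariate effect.

    With a single subject the model is degenerate; a one-sample t-test (or
    OLS, with a covariate) is substituted with a warning.
    """
    y = np.asarray(y, dtype=float)
    subject_ids = np.asarray(subject_ids)
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    groups = np.unique(subject_ids)
    if x is None:
        X = np.ones((y.size, 1))
    else:
        X = np.column_stack([np.ones(y.size), np.asarray(x, dtype=float)])

    if len(groups) < 2:
        warnings.warn("single subject: falling back to a fixed-effects test",
                      stacklevel=2)
        if x is None:
            t, p = sps.ttest_1samp(y, 0.0)
            se = y.std(ddof=1) / np.sqrt(y.size)
            return MixedModelFit(beta=float(y.mean()), se=float(se),
                                 z=float(t), p=float(p), sigma_b=0.0,
                                 sigma_e=float(y.std(ddof=1)),
                                 loglik=np.nan, loglik_no_random=np.nan,
                                 n_obs=y.size, n_groups=1)
        res = sps.linregress(np.asarray(x, float), y)
        return MixedModelFit(beta=float(res.intercept),
                             se=float(res.intercept_stderr),
                             z=float(res.intercept / res.intercept_stderr),
                             p=float(2 * sps.norm.sf(
                                 abs(res.intercept / res.intercept_stderr))),
                             sigma_b=0.0, sigma_e=float(np.std(y, ddof=1)),
                             loglik=np.nan, loglik_no_random=np.nan,
                             n_obs=y.size, n_groups=1,
                             slope=float(res.slope),
                             slope_se=float(res.stderr),
                             slope_p=float(res.pvalue))

    y_groups = [y[subject_ids == g] for g in groups]
    X_groups = [X[subject_ids == g] for g in groups]

    def nll_log(log_theta):
        return -_profile_loglik(np.exp(log_theta), y_groups, X_groups)[0]

    grid = np.concatenate([[-np.inf], np.linspace(-12, 8, 41)])
    vals = [(-_profile_loglik(0.0, y_groups, X_groups)[0] if g == -np.inf
             else nll_log(g)) for g in grid]
    best = int(np.argmin(vals))
    if best == 0:
        theta = 0.0
    else:
        lo = grid[max(best - 1, 1)]
        hi = grid[min(best + 1, len(grid) - 1)]
        res = minimize_scalar(nll_log, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-8})
        theta = float(np.exp(res.x))
        if -res.fun < _profile_loglik(0.0, y_groups, X_groups)[0]:
            theta = 0.0

    ll, beta, cov_u, sigma_e2 = _profile_loglik(theta, y_groups, X_groups)
    ll0 = _profile_loglik(0.0, y_groups, X_groups)[0]
    se = float(np.sqrt(sigma_e2 * cov_u[0, 0]))
    z = float(beta[0] / se)
    fit = MixedModelFit(
        beta=float(beta[0]), se=se, z=z,
        p=float(max(2 * sps.norm.sf(abs(z)), np.finfo(float).tiny)),
        sigma_b=float(np.sqrt(theta * sigma_e2)),
        sigma_e=float(np.sqrt(sigma_e2)),
        loglik=float(ll), loglik_no_random=float(ll0),
        n_obs=y.size, n_groups=len(groups))
    if x is not None:
        sse = float(np.sqrt(sigma_e2 * cov_u[1, 1]))
        zs = float(beta[1] / sse)
        fit.slope = float(beta[1])
        fit.slope_se = sse
        fit.slope_p = float(max(2 * sps.norm.sf(abs(zs)), np.finfo(float).tiny))
    return fit


# ---------------------------------------------------------------------------
# Chosen-vs-unchosen tuple contrast
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TupleContrast:
    """Per-trial chosen-minus-unchosen pair-sequenceness contrast."""

    contrasts: np.ndarray
    subject_ids: np.ndarray
    n_chosen: np.ndarray     # chosen tuples per trial (4, or 1 in first-move mode)
    fit: MixedModelFit
    mode: str


def tuple_contrast(pair_mats: Sequence[np.ndarray],
                   starts: Sequence[int],
                   plans: Sequence[Sequence[str]],
                   subject_ids: Sequence,
                   graph: TaskGraph,
                   mode: str = "all_moves") -> TupleContrast:
    """Compare pair sequenceness of chosen vs unchosen transitions.

    ``pair_mats[t]`` is the antisymmetric ordered-pair score matrix for trial
    ``t`` (0-based state indices, e.g. from
    :func:`seqmeg.seqness.pairwise_matrix`); ``starts``/``plans`` give the
    trial's start state and four chosen actions. Chosen tuples are the
    ``(state, next state)`` edges actually traversed (all four, or only the
    first with ``mode="first_move"``); unchosen tuples are the remaining
    directed task edges. The per-trial contrast (mean chosen score - mean
    unchosen score) is fed to :func:`mixed_intercept_fit`.

    Trials whose moves do not resolve to valid graph edges are skipped with
    a warning.
    """
    if mode not in ("all_moves", "first_move"):
        raise ValueError("mode must be 'all_moves' or 'first_move'")
    all_edges = set(graph.edges())
    contrasts, subjects, n_chosen = [], [], []
    n_skipped = 0
    for mat, start, plan, sid in zip(pair_mats, starts, plans, subject_ids):
        try:
            seq = [int(start)]
            for a in plan:
                seq.append(graph.successor(seq[-1], a))
        except KeyError:
            n_skipped += 1
            continue
        edges = [(seq[m], seq[m + 1]) for m in range(len(plan))]
        if mode == "first_move":
            edges = edges[:1]
        if any(e not in all_edges for e in edges):
            n_skipped += 1
            continue
        chosen = [mat[i - 1, j - 1] for i, j in edges]
        unchosen = [mat[i - 1, j - 1] for i, j in all_edges
                    if (i, j) not in set(edges)]
        contrasts.append(np.mean(chosen) - np.mean(unchosen))
        subjects.append(sid)
        n_chosen.append(len(edges))
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} trial(s) with invalid choices",
                      stacklevel=2)
    contrasts = np.asarray(contrasts)
    fit = mixed_intercept_fit(contrasts, np.asarray(subjects))
    return TupleContrast(contrasts=contrasts,
                         subject_ids=np.asarray(subjects),
                         n_chosen=np.asarray(n_chosen), fit=fit, mode=mode)


# ---------------------------------------------------------------------------
# Simple group tests
# ---------------------------------------------------------------------------

def subject_mean_regression(x: Sequence[float], y: Sequence[float]
                            ) -> tuple[float, float]:
    """OLS slope of subject means and its two-tailed p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 subjects")
    if np.isclose(x.std(), 0):
        raise ValueError("zero variance in x")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.pvalue)


@dataclasses.dataclass
class PairAnovaResult:
    F: float
    df: tuple[int, int]
    p: float


def pair_anova(groups: Sequence[Sequence[float]] | Mapping) -> PairAnovaResult:
    """One-way ANOVA across groups of pair-sequenceness scores.

    Textbook between/within decomposition; with 12 directed task-edge pairs
    observed in 12 sessions the degrees of freedom are (11, 132).
    """
    if isinstance(groups, Mapping):
        groups = list(groups.values())
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(a.size < 2 for a in arrs):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    all_vals = np.concatenate(arrs)
    gm = all_vals.mean()
    ssb = sum(a.size * (a.mean() - gm) ** 2 for a in arrs)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    df1 = len(arrs) - 1
    df2 = all_vals.size - len(arrs)
    F = (ssb / df1) / (ssw / df2)
    return PairAnovaResult(F=float(F), df=(df1, df2),
                           p=float(sps.f.sf(F, df1, df2)))
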