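"""Six-state maze task: transition graph, trial generation, and behavioral choice models.

States are labelled 1..n everywhere in this module. Each state offers two
deterministic actions ("up" and "down") leading to two distinct other states.
Each state carries an integer reward in pence (clamped to [-5, +5]); on every
trial two distinct states are flagged "neg": entering a neg state first adds
its reward to the running total and then flips the sign of the running total.

Four choice models are provided for fitting participants' (or simulated
agents') four-move plans:

* ``Plan``   -- full-depth tree search; softmax over the earnings of all 16
  four-move plans (one inverse-temperature parameter).
* ``Greedy`` -- per-move softmax over the one-step change in running total
  (including the neg flip), using knowledge of the graph.
* ``Qfirst`` -- model-free; Q-values over the 12 (state, action) pairs updated
  only from the first move of each trial; later moves are modelled as coin
  flips (learning rate + inverse temperature).
* ``Qall``   -- Q-values over the 12 (state, action) pairs, evaluated and
  updated for all four moves using knowledge of the graph.

A 0-parameter ``Uniform`` baseline is included in model comparison.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

ACTIONS: tuple[str, str] = ("up", "down")
REWARD_MIN, REWARD_MAX = -5, 5
PLAN_DEPTH = 4

#: Trial timing constants (milliseconds). Metadata only -- nothing in the
#: analysis enforces them, but the visual cross-fade duration is used as the
#: behavioural benchmark against which neural lags are compared.
TIMING_MS = {
    "planning_max": 60_000,
    "crossfade": 350,
    "post_fade_pause": 500,
    "reward_display": 1_000,
    "total_display": 1_000,
}

MODEL_NAMES = ("Plan", "Qfirst", "Qall", "Greedy")


# ---------------------------------------------------------------------------
# Graph
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class TaskGraph:
    """Deterministic two-action transition structure over ``n_states`` states.

    Attributes
    ----------
    n_states : int
        Number of states (default task: 6).
    successors : dict
        ``successors[s][a]`` is the state reached from ``s`` (1-based) under
        action ``a`` in :data:`ACTIONS`.
    transition_matrix : numpy.ndarray
        Row-stochastic ``n x n`` matrix ``T`` with 0.5 on each of the two
        out-edges of every row (equal action probabilities). ``T[i-1, j-1]``
        is the probability of moving from state ``i`` to state ``j`` under a
        uniform random policy.
    state_names : tuple of str
        Labels, default ``("S1", ..., "Sn")``.
    """

    n_states: int
    successors: Mapping[int, Mapping[str, int]]
    transition_matrix: np.ndarray
    state_names: tuple[str, ...]

    def successor(self, state: int, action: str) -> int:
        return self.successors[state][action]

    def edges(self) -> list[tuple[int, int]]:
        """All directed edges (i, j), 1-based, in deterministic order."""
        out = []
        for s in range(1, self.n_states + 1):
            for a in ACTIONS:
                out.append((s, self.successors[s][a]))
        return out

    @property
    def n_actions(self) -> int:
        return len(ACTIONS)

    def q_table_size(self) -> int:
        """Number of (state, action) pairs maintained by the Q models."""
        return self.n_states * self.n_actions


def default_edge_spec(n_states: int = 6) -> dict[int, dict[str, int]]:
    """Circulant layout: 'up' -> +1, 'down' -> +4 (mod n, 1-based).

    For the six-state task this satisfies every published textual constraint
    (S1 -> {S2, S5}; S4 -> S5; S5 -> S6) and the relabelling i -> -i maps the
    transition matrix onto its transpose, so a reverse-order relabelling
    exists. The true layout of the original experiment is not recoverable
    from text; pass an explicit ``edge_spec`` to override.
    """
    if n_states != 6:
        raise ValueError("default edge layout is defined for 6 states only; "
                         "supply edge_spec for other sizes")
    return {
        s: {"up": (s - 1 + 1) % n_states + 1, "down": (s - 1 + 4) % n_states + 1}
        for s in range(1, n_states + 1)
    }


def build_task_graph(edge_spec: Mapping[int, Mapping[str, int]] | None = None,
                     n_states: int = 6,
                     state_names: Sequence[str] | None = None) -> TaskGraph:
    """Construct a :class:`TaskGraph`, validating the edge specification.

    Parameters
    ----------
    edge_spec : mapping, optional
        ``{state: {"up": succ, "down": succ}}`` with exactly two distinct,
        non-self successors per state. Defaults to :func:`default_edge_spec`.

    Raises
    ------
    ValueError
        On self-loops, duplicate successors, missing actions, or
        out-of-range states.
    """
    if edge_spec is None:
        edge_spec = default_edge_spec(n_states)
    states = range(1, n_states + 1)
    succ: dict[int, dict[str, int]] = {}
    for s in states:
        if s not in edge_spec:
            raise ValueError(f"edge_spec missing state {s}")
        row = dict(edge_spec[s])
        if set(row) != set(ACTIONS):
            raise ValueError(f"state {s}: actions must be exactly {ACTIONS}")
        up, down = row["up"], row["down"]
        for t in (up, down):
            if not (1 <= int(t) <= n_states):
                raise ValueError(f"state {s}: successor {t} out of range")
            if int(t) == s:
                raise ValueError(f"state {s}: self-loop not allowed")
        if up == down:
            raise ValueError(f"state {s}: up and down successors must differ")
        succ[s] = {"up": int(up), "down": int(down)}
    T = np.zeros((n_states, n_states))
    for s in states:
        for a in ACTIONS:
            T[s - 1, succ[s][a] - 1] += 0.5
    if state_names is None:
        state_names = tuple(f"S{s}" for s in states)
    return TaskGraph(n_states=n_states, successors=succ,
                     transition_matrix=T, state_names=tuple(state_names))


# ---------------------------------------------------------------------------
# Trials and plan evaluation
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class TrialSpec:
    """One trial: start state, two neg states, per-state rewards (pence)."""

    start_state: int
    neg_states: frozenset[int]
    rewards: tuple[int, ...]

    def __post_init__(self):
        if len(self.neg_states) != 2:
            raise ValueError("exactly two distinct neg states required")
        if any(r < REWARD_MIN or r > REWARD_MAX for r in self.rewards):
            raise ValueError(f"rewards must lie in [{REWARD_MIN}, {REWARD_MAX}]")


@dataclasses.dataclass(frozen=True)
class PlanOutcome:
    """Result of walking a plan: visited states, running totals, earnings."""

    plan: tuple[str, ...]
    path: tuple[int, ...]          # the states *entered*, start excluded
    running_totals: tuple[int, ...]  # running total after each move
    earnings: int


def enumerate_plans(depth: int = PLAN_DEPTH) -> list[tuple[str, ...]]:
    """All ``2**depth`` action sequences, lexicographic ('down' < 'up')."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    return sorted(itertools.product(ACTIONS, repeat=depth))


def evaluate_plan(graph: TaskGraph, trial: TrialSpec,
                  plan: Sequence[str]) -> PlanOutcome:
    """Walk ``plan`` from the trial's start state and accumulate earnings.

    Entering a state adds its current reward to the running total; if the
    state is a neg state the running total is then multiplied by -1. The
    start state's own reward is never collected.
    """
    state = trial.start_state
    total = 0
    path: list[int] = []
    totals: list[int] = []
    for action in plan:
        if action not in ACTIONS:
            raise ValueError(f"invalid action {action!r}")
        state = graph.successor(state, action)
        total += trial.rewards[state - 1]
        if state in trial.neg_states:
            total = -total
        path.append(state)
        totals.append(total)
    return PlanOutcome(plan=tuple(plan), path=tuple(path),
                       running_totals=tuple(totals), earnings=total)


def plan_values(graph: TaskGraph, trial: TrialSpec,
                depth: int = PLAN_DEPTH) -> np.ndarray:
    """Earnings of every plan from :func:`enumerate_plans`, in order."""
    return np.array([evaluate_plan(graph, trial, p).earnings
                     for p in enumerate_plans(depth)], dtype=float)


def best_plan(graph: TaskGraph, trial: TrialSpec) -> tuple[tuple[str, ...], int]:
    """Earnings-maximizing plan (first in lexicographic order on ties)."""
    plans = enumerate_plans()
    values = plan_values(graph, trial)
    idx = int(np.argmax(values))
    return plans[idx], int(values[idx])


def greedy_plan(graph: TaskGraph, trial: TrialSpec) -> tuple[tuple[str, ...], int]:
    """Deterministic greedy walk: each move maximizes the resulting running
    total one step ahead (neg flip of the accumulated total included).
    Ties resolve in :data:`ACTIONS` order."""
    state = trial.start_state
    total = 0
    plan: list[str] = []
    for _ in range(PLAN_DEPTH):
        candidates = []
        for a in ACTIONS:
            nxt = graph.successor(state, a)
            v = total + trial.rewards[nxt - 1]
            if nxt in trial.neg_states:
                v = -v
            candidates.append(v)
        k = int(np.argmax(candidates))
        plan.append(ACTIONS[k])
        state = graph.successor(state, ACTIONS[k])
        total = candidates[k]
    return tuple(plan), int(total)


def drift_rewards(rewards: Sequence[int], rng: np.random.Generator) -> tuple[int, ...]:
    """Each reward moves by -1/0/+1 with equal probability, clamped to bounds."""
    r = np.asarray(rewards, dtype=int) + rng.integers(-1, 2, size=len(rewards))
    return tuple(int(v) for v in np.clip(r, REWARD_MIN, REWARD_MAX))


def generate_session(graph: TaskGraph, n_trials: int, rng: np.random.Generator,
                     adversarial_filter: bool = False, margin: int = 2,
                     initial_rewards: Sequence[int] | None = None,
                     max_resamples: int = 1000) -> list[TrialSpec]:
    """Generate a session of trials with drifting rewards.

    Start states are uniform; neg states are a uniform pair. With
    ``adversarial_filter`` on, the (start, neg) assignment of each trial is
    resampled until the best plan beats the deterministic greedy walk by at
    least ``margin`` pence, discouraging simple local strategies.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if initial_rewards is None:
        rewards = tuple(int(v) for v in
                        rng.integers(REWARD_MIN, REWARD_MAX + 1, size=graph.n_states))
    else:
        rewards = tuple(int(v) for v in initial_rewards)
    trials: list[TrialSpec] = []
    for _ in range(n_trials):
        for attempt in range(max_resamples):
            start = int(rng.integers(1, graph.n_states + 1))
            negs = rng.choice(graph.n_states, size=2, replace=False) + 1
            trial = TrialSpec(start_state=start,
                              neg_states=frozenset(int(v) for v in negs),
                              rewards=rewards)
            if not adversarial_filter:
                break
            _, vbest = best_plan(graph, trial)
            _, vgreedy = greedy_plan(graph, trial)
            if vbest - vgreedy >= margin:
                break
        else:
            raise RuntimeError(
                f"adversarial filter failed after {max_resamples} resamples")
        trials.append(trial)
        rewards = drift_rewards(rewards, rng)
    return trials


# ---------------------------------------------------------------------------
# Choice models
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class BehaviorModelFit:
    """Maximum-likelihood fit of one choice model."""

    model_name: str
    params: dict[str, float]
    log_likelihood: float
    bic: float
    n_obs: int

    def __post_init__(self):
        if self.log_likelihood > 1e-9:
            raise ValueError("log-likelihood must be <= 0")
        if not np.isfinite(self.bic):
            raise ValueError("BIC must be finite")


def _softmax(values: np.ndarray, beta: float) -> np.ndarray:
    z = beta * np.asarray(values, dtype=float)
    z = z - z.max()
    # exact argmax limit: at large beta only maximal entries survive
    p = np.exp(z)
    return p / p.sum()


def choice_model_probs(model_name: str, params: Mapping[str, float],
                       graph: TaskGraph, trial: TrialSpec,
                       q_values: np.ndarray | None = None,
                       chosen_plan: Sequence[str] | None = None):
    """Choice probabilities of a model on one trial.

    For ``Plan`` the return value is a length-16 distribution over
    :func:`enumerate_plans`. For ``Greedy``/``Qall``/``Qfirst`` the return
    value is a ``(4, 2)`` array of per-move action probabilities along the
    *chosen* path (``chosen_plan`` required for Greedy/Qall because later
    moves depend on the states actually visited).
    """
    beta = float(params["beta"])
    if not np.isfinite(beta):
        raise ValueError("non-finite inverse temperature")
    if model_name == "Plan":
        return _softmax(plan_values(graph, trial), beta)
    if model_name == "Greedy":
        if chosen_plan is None:
            raise ValueError("Greedy needs the chosen plan to condition on")
        probs = np.empty((PLAN_DEPTH, 2))
        state, total = trial.start_state, 0
        for m, action in enumerate(chosen_plan):
            vals = []
            for a in ACTIONS:
                nxt = graph.successor(state, a)
                v = total + trial.rewards[nxt - 1]
                if nxt in trial.neg_states:
                    v = -v
                vals.append(v)
            probs[m] = _softmax(np.array(vals, float), beta)
            k = ACTIONS.index(action)
            state = graph.successor(state, action)
            total = vals[k]
        return probs
    if model_name == "Qfirst":
        if q_values is None:
            raise ValueError("Qfirst needs a Q table")
        probs = np.full((PLAN_DEPTH, 2), 0.5)
        probs[0] = _softmax(q_values[trial.start_state - 1], beta)
        return probs
    if model_name == "Qall":
        if q_values is None or chosen_plan is None:
            raise ValueError("Qall needs a Q table and the chosen plan")
        probs = np.empty((PLAN_DEPTH, 2))
        state = trial.start_state
        for m, action in enumerate(chosen_plan):
            probs[m] = _softmax(q_values[state - 1], beta)
            state = graph.successor(state, action)
        return probs
    raise ValueError(f"unknown model {model_name!r}")


def _new_q(graph: TaskGraph) -> np.ndarray:
    return np.zeros((graph.n_states, graph.n_actions))


def _q_update_first(q, trial, plan, earnings, alpha):
    s, a = trial.start_state - 1, ACTIONS.index(plan[0])
    q[s, a] += alpha * (earnings - q[s, a])


def _q_update_all(q, graph, trial, plan, earnings, alpha):
    state = trial.start_state
    for action in plan:
        s, a = state - 1, ACTIONS.index(action)
        q[s, a] += alpha * (earnings - q[s, a])
        state = graph.successor(state, action)


def simulate_choices(graph: TaskGraph, trials: Sequence[TrialSpec],
                     model_name: str, params: Mapping[str, float],
                     rng: np.random.Generator) -> list[tuple[str, ...]]:
    """Sample a plan per trial from a choice model (with Q learning where
    applicable). Returns one 4-action tuple per trial."""
    beta = float(params["beta"])
    alpha = float(params.get("alpha", 0.0))
    q = _new_q(graph)
    plans: list[tuple[str, ...]] = []
    all_plans = enumerate_plans()
    for trial in trials:
        if model_name == "Plan":
            p = _softmax(plan_values(graph, trial), beta)
            plan = all_plans[int(rng.choice(len(all_plans), p=p))]
        elif model_name == "Uniform":
            plan = all_plans[int(rng.integers(len(all_plans)))]
        elif model_name == "Greedy":
            state, total, acts = trial.start_state, 0, []
            for _ in range(PLAN_DEPTH):
                vals = []
                for a in ACTIONS:
                    nxt = graph.successor(state, a)
                    v = total + trial.rewards[nxt - 1]
                    if nxt in trial.neg_states:
                        v = -v
                    vals.append(v)
                k = int(rng.choice(2, p=_softmax(np.array(vals, float), beta)))
                acts.append(ACTIONS[k])
                state = graph.successor(state, ACTIONS[k])
                total = vals[k]
            plan = tuple(acts)
        elif model_name == "Qfirst":
            k = int(rng.choice(2, p=_softmax(q[trial.start_state - 1], beta)))
            rest = [ACTIONS[int(rng.integers(2))] for _ in range(PLAN_DEPTH - 1)]
            plan = (ACTIONS[k], *rest)
        elif model_name == "Qall":
            state, acts = trial.start_state, []
            for _ in range(PLAN_DEPTH):
                k = int(rng.choice(2, p=_softmax(q[state - 1], beta)))
                acts.append(ACTIONS[k])
                state = graph.successor(state, ACTIONS[k])
            plan = tuple(acts)
        else:
            raise ValueError(f"unknown model {model_name!r}")
        earnings = evaluate_plan(graph, trial, plan).earnings
        if model_name == "Qfirst":
            _q_update_first(q, trial, plan, earnings, alpha)
        elif model_name == "Qall":
            _q_update_all(q, graph, trial, plan, earnings, alpha)
        plans.append(plan)
    return plans


# -- likelihoods -------------------------------------------------------------

class _FitCache:
    """Parameter-independent per-trial quantities, computed once per fit."""

    def __init__(self, graph: TaskGraph, trials: Sequence[TrialSpec],
                 plans: Sequence[Sequence[str]]):
        self.graph = graph
        plan_index = {p: i for i, p in enumerate(enumerate_plans())}
        self.n_trials = len(trials)
        self.plan_vals = np.array([plan_values(graph, t) for t in trials])
        self.chosen_idx = np.array([plan_index[tuple(p)] for p in plans])
        self.action_idx = np.array([[ACTIONS.index(a) for a in p]
                                    for p in plans])
        # greedy: candidate resulting totals at each step along the chosen path
        self.greedy_vals = np.empty((len(trials), PLAN_DEPTH, 2))
        for t, (trial, plan) in enumerate(zip(trials, plans)):
            state, total = trial.start_state, 0
            for m, action in enumerate(plan):
                for k, a in enumerate(ACTIONS):
                    nxt = graph.successor(state, a)
                    v = total + trial.rewards[nxt - 1]
                    if nxt in trial.neg_states:
                        v = -v
                    self.greedy_vals[t, m, k] = v
                total = self.greedy_vals[t, m, ACTIONS.index(action)]
                state = graph.successor(state, action)
        self.earnings = np.array([
            evaluate_plan(graph, trial, plan).earnings
            for trial, plan in zip(trials, plans)], dtype=float)
        self.visited = []  # per trial: list of (state-1, action index)
        for trial, plan in zip(trials, plans):
            state, vis = trial.start_state, []
            for action in plan:
                vis.append((state - 1, ACTIONS.index(action)))
                state = graph.successor(state, action)
            self.visited.append(vis)
        self.starts = np.array([t.start_state - 1 for t in trials])

    def loglik(self, model_name: str, params: Mapping[str, float]) -> float:
        beta = float(params.get("beta", 0.0))
        alpha = float(params.get("alpha", 0.0))
        if not (np.isfinite(beta) and np.isfinite(alpha)):
            return -np.inf
        if model_name == "Uniform":
            return float(PLAN_DEPTH * self.n_trials * np.log(0.5))
        if model_name == "Plan":
            z = beta * self.plan_vals
            z -= z.max(axis=1, keepdims=True)
            logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
            return float(logp[np.arange(self.n_trials), self.chosen_idx].sum())
        if model_name == "Greedy":
            z = beta * self.greedy_vals
            z -= z.max(axis=2, keepdims=True)
            logp = z - np.log(np.exp(z).sum(axis=2, keepdims=True))
            rows = np.arange(self.n_trials)[:, None]
            cols = np.arange(PLAN_DEPTH)[None, :]
            return float(logp[rows, cols, self.action_idx].sum())
        q = _new_q(self.graph)
        ll = 0.0
        if model_name == "Qfirst":
            for t in range(self.n_trials):
                s, a = self.starts[t], self.action_idx[t, 0]
                z = beta * q[s]
                z = z - z.max()
                ll += z[a] - np.log(np.exp(z).sum())
                ll += (PLAN_DEPTH - 1) * np.log(0.5)
                q[s, a] += alpha * (self.earnings[t] - q[s, a])
            return float(ll)
        if model_name == "Qall":
            for t in range(self.n_trials):
                for s, a in self.visited[t]:
                    z = beta * q[s]
                    z = z - z.max()
                    ll += z[a] - np.log(np.exp(z).sum())
                for s, a in self.visited[t]:
                    q[s, a] += alpha * (self.earnings[t] - q[s, a])
            return float(ll)
        raise ValueError(f"unknown model {model_name!r}")


def _loglik(model_name: str, params: Mapping[str, float], graph: TaskGraph,
            trials: Sequence[TrialSpec], plans: Sequence[Sequence[str]]) -> float:
    """Total log-likelihood of observed plans under a model."""
    return _FitCache(graph, trials, plans).loglik(model_name, params)


_N_PARAMS = {"Plan": 1, "Greedy": 1, "Qfirst": 2, "Qall": 2, "Uniform": 0}


def fit_model(model_name: str, graph: TaskGraph, trials: Sequence[TrialSpec],
              plans: Sequence[Sequence[str]],
              cache: _FitCache | None = None) -> BehaviorModelFit:
    """Maximum-likelihood fit of one model (coarse grid + Nelder-Mead)."""
    n_obs = PLAN_DEPTH * len(trials)
    if cache is None:
        cache = _FitCache(graph, trials, plans)
    if model_name == "Uniform":
        ll = cache.loglik("Uniform", {})
        return BehaviorModelFit("Uniform", {}, ll, -2 * ll, n_obs)

    has_alpha = _N_PARAMS[model_name] == 2
    beta_grid = np.log(np.array([0.03, 0.1, 0.3, 1.0, 3.0]))
    alpha_grid = np.array([-2.0, 0.0, 2.0]) if has_alpha else np.array([0.0])

    def unpack(x):
        p = {"beta": float(np.exp(x[0]))}
        if has_alpha:
            p["alpha"] = float(expit(x[1]))
        return p

    def neg(x):
        return -cache.loglik(model_name, unpack(x))

    best_x, best_v = None, np.inf
    for lb in beta_grid:
        for la in alpha_grid:
            x = np.array([lb, la])[: 1 + has_alpha]
            v = neg(x)
            if v < best_v:
                best_x, best_v = x, v
    res = minimize(neg, best_x, method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400})
    x = res.x if res.fun <= best_v else best_x
    ll = -min(res.fun, best_v)
    k = _N_PARAMS[model_name]
    bic = k * np.log(n_obs) - 2 * ll
    return BehaviorModelFit(model_name, unpack(x), float(ll), float(bic), n_obs)


def fit_and_compare(plans: Sequence[Sequence[str]], graph: TaskGraph,
                    trials: Sequence[TrialSpec],
                    model_names: Iterable[str] = (*MODEL_NAMES, "Uniform"),
                    ) -> list[BehaviorModelFit]:
    """Fit each model and rank by BIC (best first)."""
    if len(trials) < 1:
        raise ValueError("need at least one trial")
    if len(set(tuple(p) for p in plans)) == 1 and len(plans) > 1:
        warnings.warn("degenerate choice data: all plans identical",
                      stacklevel=2)
    cache = _FitCache(graph, trials, plans)
    fits = [fit_model(m, graph, trials, plans, cache=cache)
            for m in model_names]
    return sorted(fits, key=lambda f: f.bic)


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

def session_to_frame(graph: TaskGraph, trials: Sequence[TrialSpec],
                     plans: Sequence[Sequence[str]]) -> pd.DataFrame:
    """Tabulate a session: one row per trial (1-indexed states)."""
    rows = []
    for t, (trial, plan) in enumerate(zip(trials, plans), start=1):
        neg1, neg2 = sorted(trial.neg_states)
        row = {"trial": t, "start": trial.start_state, "neg1": neg1, "neg2": neg2}
        for s in range(1, graph.n_states + 1):
            row[f"reward_S{s}"] = trial.rewards[s - 1]
        for m, a in enumerate(plan, start=1):
            row[f"move{m}"] = a
        row["earnings"] = evaluate_plan(graph, trial, plan).earnings
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_session(frame: pd.DataFrame, graph: TaskGraph
                     ) -> tuple[list[TrialSpec], list[tuple[str, ...]]]:
    """Inverse of :func:`session_to_frame`."""
    trials, plans = [], []
    reward_cols = [f"reward_S{s}" for s in range(1, graph.n_states + 1)]
    move_cols = [f"move{m}" for m in range(1, PLAN_DEPTH + 1)]
    for _, row in frame.iterrows():
        trials.append(TrialSpec(
            start_state=int(row["start"]),
            neg_states=frozenset({int(row["neg1"]), int(row["neg2"])}),
            rewards=tuple(int(row[c]) for c in reward_cols)))
        plans.append(tuple(str(row[c]) for c in move_cols))
    return trials, plans
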