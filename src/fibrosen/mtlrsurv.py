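"""Multi-task logistic regression (MTLR) survival model with DE feature
selection and concordance evaluation.

The time axis is discretized into ``m`` intervals at event-time quantiles
(``m = ceil(sqrt(#events))``, clamped to [2, 30]). Each sample's outcome is
one of ``m + 1`` monotone binary sequences ``s_j`` (death in interval
``j + 1``; ``s_m`` survives past the last boundary) with score
``f(s_j | x) = sum_{k > j} (theta_k . x + b_k)``. The likelihood is the
softmax over sequences; a censored subject contributes the summed
probability of every sequence consistent with death at or after its
censoring interval. The objective adds a ridge penalty on the weights and a
temporal-smoothness penalty on adjacent weight differences, and is
minimized by quasi-Newton iteration (L-BFGS) from zero initialization, so
the fit is deterministic.

With a single boundary and no censoring the model reduces exactly to a
ridge-penalized logistic regression of ``I(T <= t_1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp


@dataclass(frozen=True)
class TimeGrid:
    """Strictly increasing interval boundaries ``t_1 < ... < t_m`` (days)."""

    boundaries: tuple[float, ...]

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if b.size < 1:
            raise ValueError("time grid needs at least one boundary")
        if b[0] <= 0:
            raise ValueError("first boundary must be positive")
        if np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must be strictly increasing")

    @property
    def m(self) -> int:
        return len(self.boundaries)

    def interval_of(self, times: np.ndarray) -> np.ndarray:
        """1-based interval index; ``m + 1`` is the open interval beyond t_m."""
        return np.searchsorted(np.asarray(self.boundaries), times, side="left") + 1


def select_de_features(
    expr: pd.DataFrame,
    times: pd.Series | np.ndarray,
    events: pd.Series | np.ndarray,
    n_features: int = 10,
) -> list[str]:
    """Differential-expression feature selection around the median survival.

    Poor outcome: died before the median observed time; good outcome:
    observed (event or censoring) at or beyond the median. Samples censored
    before the median are uninformative and excluded. Per-gene two-sided
    Wilcoxon rank-sum p-values (BH-adjusted for reporting) rank the genes;
    the ``n_features`` smallest-p genes are returned, ties broken by larger
    absolute median difference and then by gene id.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n = len(times)
    if n < 20:
        raise ValueError("need at least 20 samples with outcome")
    med = np.median(times)
    poor = (times < med) & (events == 1)
    good = times >= med
    if poor.sum() < 5 or good.sum() < 5:
        raise ValueError(
            f"outcome groups too small (poor={int(poor.sum())}, good={int(good.sum())})"
        )
    x_poor = expr.loc[expr.index[poor]].to_numpy()
    x_good = expr.loc[expr.index[good]].to_numpy()
    res = stats.mannwhitneyu(
        x_poor, x_good, axis=0, alternative="two-sided", method="asymptotic"
    )
    p = np.atleast_1d(res.pvalue)
    med_diff = np.abs(np.median(x_poor, axis=0) - np.median(x_good, axis=0))
    order = sorted(
        range(expr.shape[1]), key=lambda i: (p[i], -med_diff[i], expr.columns[i])
    )
    return [expr.columns[i] for i in order[:n_features]]


def make_time_grid(times: np.ndarray, events: np.ndarray) -> TimeGrid:
    """Boundaries at evenly spaced event-time quantiles, m = ceil(sqrt(#events))."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    event_times = times[events == 1]
    if np.unique(event_times).size < 2:
        raise ValueError("need at least 2 distinct event times to build a grid")
    m = int(np.clip(np.ceil(np.sqrt(event_times.size)), 2, 30))
    qs = (np.arange(1, m + 1)) / (m + 1)
    bounds = np.unique(np.quantile(event_times, qs))
    bounds = bounds[bounds > 0]
    return TimeGrid(boundaries=tuple(bounds))


@dataclass
class MtlrParameters:
    """Fitted MTLR weights with the regularization and convergence record."""

    theta: np.ndarray  # m x d
    bias: np.ndarray  # m
    grid: TimeGrid
    c1: float
    c2: float
    n_iter: int
    grad_norm: float
    converged: bool
    features: list[str] | None = None


def _sequence_scores(theta: np.ndarray, bias: np.ndarray, X: np.ndarray) -> np.ndarray:
    """n x (m+1) matrix of sequence scores f(s_j | x), j = 0..m."""
    a = X @ theta.T + bias  # n x m, a[:, k] = theta_k . x + b_k
    rev = np.cumsum(a[:, ::-1], axis=1)[:, ::-1]  # suffix sums over k > j
    return np.concatenate([rev, np.zeros((X.shape[0], 1))], axis=1)


def fit_mtlr(
    X: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    grid: TimeGrid,
    c1: float = 1.0,
    c2: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> MtlrParameters:
    """Fit MTLR by penalized maximum likelihood (deterministic L-BFGS)."""
    X = np.asarray(X, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n, d = X.shape
    m = grid.m
    if events.sum() == 0:
        raise ValueError("no events: MTLR likelihood is uninformative")
    interval = grid.interval_of(times)  # in 1..m+1
    # allowed sequence indices: uncensored -> {i-1}; censored -> {i-1, .., m}
    start = interval - 1
    uncensored = events == 1

    def unpack(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return w[: m * d].reshape(m, d), w[m * d :]

    diff = np.diff(np.eye(m), axis=0)  # (m-1) x m first-difference operator

    def objective(w: np.ndarray) -> tuple[float, np.ndarray]:
        theta, bias = unpack(w)
        G = _sequence_scores(theta, bias, X)  # n x (m+1)
        logZ = logsumexp(G, axis=1)
        # restricted log-sum over allowed sequences (suffix logsumexp)
        suffix = np.full_like(G, -np.inf)
        suffix[:, m] = G[:, m]
        for j in range(m - 1, -1, -1):
            suffix[:, j] = np.logaddexp(G[:, j], suffix[:, j + 1])
        lognum = np.where(uncensored, G[np.arange(n), start], suffix[np.arange(n), start])
        nll = float(np.sum(logZ - lognum))

        P_full = np.exp(G - logZ[:, None])
        P_allowed = np.zeros_like(G)
        rows = np.arange(n)
        P_allowed[rows[uncensored], start[uncensored]] = 1.0
        cens = ~uncensored
        if cens.any():
            Gc = G[cens]
            lnc = suffix[cens, start[cens]]
            Pc = np.exp(Gc - lnc[:, None])
            cols = np.arange(m + 1)[None, :]
            Pc[cols < start[cens][:, None]] = 0.0
            P_allowed[cens] = Pc
        # dNLL/da_k = q_k(full) - q_k(allowed), q_k = P(sequence index < k)
        q_full = np.cumsum(P_full, axis=1)[:, :m]
        q_allow = np.cumsum(P_allowed, axis=1)[:, :m]
        dA = q_full - q_allow  # n x m
        g_theta = dA.T @ X
        g_bias = dA.sum(axis=0)

        pen = 0.5 * c1 * float(np.sum(theta**2))
        g_theta += c1 * theta
        if m > 1 and c2 > 0:
            delta = np.diff(theta, axis=0)
            pen += 0.5 * c2 * float(np.sum(delta**2))
            g_theta += c2 * (diff.T @ diff) @ theta
        value = nll + pen
        if not np.isfinite(value):
            raise FloatingPointError("non-finite MTLR objective; check feature scaling")
        return value, np.concatenate([g_theta.ravel(), g_bias])

    w0 = np.zeros(m * d + m)
    res = optimize.minimize(
        objective,
        w0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": tol, "ftol": 1e-14},
    )
    theta, bias = unpack(res.x)
    grad_norm = float(np.max(np.abs(res.jac)))
    if not res.success and grad_norm > 10 * tol:
        import warnings

        warnings.warn(f"MTLR did not fully converge: {res.message} (|grad|={grad_norm:.2e})")
    return MtlrParameters(
        theta=theta,
        bias=bias,
        grid=grid,
        c1=c1,
        c2=c2,
        n_iter=int(res.nit),
        grad_norm=grad_norm,
        converged=bool(res.success),
    )


@dataclass
class SurvivalPrediction:
    """Per-sample survival curve on the grid plus a scalar risk score."""

    survival: np.ndarray  # n x m, S(t_k | x)
    sequence_probs: np.ndarray  # n x (m+1)
    risk: np.ndarray  # n, sum_k (1 - S(t_k))


def predict_survival(params: MtlrParameters, X: np.ndarray) -> SurvivalPrediction:
    """Survival probabilities ``S(t_k | x)`` and risk ``sum_k (1 - S(t_k))``."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != params.theta.shape[1]:
        raise ValueError(
            f"feature mismatch: model has {params.theta.shape[1]} features, "
            f"input has {X.shape[1]}"
        )
    G = _sequence_scores(params.theta, params.bias, X)
    logZ = logsumexp(G, axis=1)
    P = np.exp(G - logZ[:, None])  # n x (m+1)
    # S(t_k) = P(sequence index >= k): alive at t_k
    m = params.grid.m
    cum = np.cumsum(P, axis=1)
    survival = 1.0 - cum[:, :m]
    risk = np.sum(1.0 - survival, axis=1)
    return SurvivalPrediction(survival=survival, sequence_probs=P, risk=risk)


def concordance(
    times: np.ndarray,
    events: np.ndarray,
    risks: np.ndarray,
    method: str = "harrell",
    tau: float | None = None,
) -> float:
    """Concordance index between predicted risk and observed survival.

    Harrell: over usable pairs (t_i < t_j, event_i = 1), the fraction with
    risk_i > risk_j, ties counted one half. Uno: the same pairs weighted by
    the inverse squared Kaplan-Meier estimate of the censoring survival at
    t_i, restricted to t_i < tau (default: 90th percentile of observed
    times).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    risks = np.asarray(risks, dtype=float)
    n = len(times)
    lt = times[:, None] < times[None, :]
    usable = lt & (events[:, None] == 1)
    if method == "harrell":
        weights = usable.astype(float)
    elif method == "uno":
        if tau is None:
            tau = float(np.quantile(times, 0.9))
        kmf = KaplanMeierFitter_censoring(times, events)
        G = np.maximum(kmf(times), 1e-8)
        weights = usable.astype(float) / (G[:, None] ** 2)
        weights[times >= tau] = 0.0
    else:
        raise ValueError(f"unknown method {method!r}")
    if weights.sum() == 0:
        raise ValueError("no comparable pairs")
    gt = risks[:, None] > risks[None, :]
    eq = risks[:, None] == risks[None, :]
    return float(np.sum(weights * (gt + 0.5 * eq)) / weights.sum())


def KaplanMeierFitter_censoring(times: np.ndarray, events: np.ndarray):
    """Left-limit KM estimate of the censoring survival function G(t-)."""
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(times, 1 - np.asarray(events))

    def G_minus(t: np.ndarray) -> np.ndarray:
        return kmf.survival_function_at_times(np.asarray(t) - 1e-9).to_numpy()

    return G_minus
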