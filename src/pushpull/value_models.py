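"""Forgetting-Q value model fitting and choice-history analyses.

The behavioral model is a two-parameter Q-learner with nondifferential
forgetting: after each completed choice the chosen action's value moves
toward the reward, Q <- Q + alpha (r - Q), and the unchosen action's
value decays toward zero at the same rate, Q <- (1 - alpha) Q.  Choices
are softmax in the value difference, P(push) = logistic(beta (Q_push -
Q_pull)).  Maximum-likelihood fitting runs a coarse (alpha, beta) grid
followed by Nelder-Mead refinement and is fully deterministic for a
given choice/reward series.

|dQ| = |Q_push - Q_pull| is the model's trial-by-trial read of choice
(un)certainty: small |dQ| means the two actions look equally valuable,
i.e. high uncertainty.  Companion analyses: win-stay/lose-switch rates,
logistic regression of choice repetition on outcome history, and
rank-based trend tests of movement vigor against reward volume and
uncertainty class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

from .agents import PULL, PUSH
from .bouts_vigor import TrialKinematics

__all__ = [
    "ChoiceSeries",
    "QFitResult",
    "UncertaintySplit",
    "WslsStats",
    "LagRegressionResult",
    "q_trajectory_nll",
    "fit_q_model",
    "uncertainty_split",
    "wsls_stats",
    "repeat_choice_regression",
    "vigor_by_value_summary",
    "series_from_session",
]

ALPHA_GRID = np.arange(0.025, 0.9751, 0.025)
BETA_GRID = np.arange(0.0, 20.001, 0.25)


@dataclass
class ChoiceSeries:
    """Completed-choice trials only: choices, rewards and optional extras.

    Omission and premature trials carry no choice and are excluded before
    model fitting; :func:`series_from_session` does that filtering.
    """

    choices: list[str]
    rewards: list[int]
    block_ids: list[int] | None = None
    volumes_ul: list[float] | None = None
    kinematics: list[TrialKinematics] | None = None

    def __post_init__(self) -> None:
        n = len(self.choices)
        if len(self.rewards) != n:
            raise ValueError("choices and rewards must have equal length")
        for name in ("block_ids", "volumes_ul", "kinematics"):
            v = getattr(self, name)
            if v is not None and len(v) != n:
                raise ValueError(f"{name} length mismatch")
        if any(c not in (PUSH, PULL) for c in self.choices):
            raise ValueError("series may contain only completed choices")

    def __len__(self) -> int:
        return len(self.choices)


def series_from_session(log, attach_kinematics: Sequence | None = None) -> ChoiceSeries:
    """Extract the completed-choice series from a simulated session log."""
    choices, rewards, blocks, vols, kins = [], [], [], [], []
    for i, tr in enumerate(log.trials):
        if tr.outcome not in ("rewarded", "unrewarded"):
            continue
        choices.append(tr.choice)
        rewards.append(int(tr.outcome == "rewarded"))
        blocks.append(tr.block_id)
        vols.append(tr.volume_ul)
        if attach_kinematics is not None:
            kins.append(attach_kinematics[i])
    return ChoiceSeries(
        choices=choices,
        rewards=rewards,
        block_ids=blocks,
        volumes_ul=vols,
        kinematics=kins if attach_kinematics is not None else None,
    )


@dataclass
class QFitResult:
    alpha_hat: float
    beta_hat: float
    neg_log_likelihood: float
    q_push: np.ndarray
    q_pull: np.ndarray
    boundary_warning: bool = False

    @property
    def delta_q(self) -> np.ndarray:
        return self.q_push - self.q_pull


def _encode(series: ChoiceSeries) -> tuple[np.ndarray, np.ndarray]:
    c = np.array([1.0 if ch == PUSH else -1.0 for ch in series.choices])
    r = np.asarray(series.rewards, dtype=float)
    return c, r


def _q_forward(c: np.ndarray, r: np.ndarray, alpha: float, q_init: float = 0.0):
    """Pre-choice Q trajectories for one alpha (push, pull)."""
    n = len(c)
    qp = np.empty(n)
    ql = np.empty(n)
    q_push, q_pull = q_init, q_init
    a = alpha
    for t in range(n):
        qp[t] = q_push
        ql[t] = q_pull
        if c[t] > 0:
            q_push += a * (r[t] - q_push)
            q_pull *= 1 - a
        else:
            q_pull += a * (r[t] - q_pull)
            q_push *= 1 - a
    return qp, ql


def q_trajectory_nll(
    series: ChoiceSeries, alpha: float, beta: float, q_init: float = 0.0
) -> tuple[float, np.ndarray, np.ndarray]:
    """Negative log-likelihood plus the pre-choice Q trajectories.

    The forward pass applies the same update and choice rules as the
    simulated agents (the equivalence is pinned by a test); the
    log-likelihood uses logaddexp so extreme beta values cannot underflow.
    """
    if len(series) == 0:
        raise ValueError("empty series")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    c, r = _encode(series)
    qp, ql = _q_forward(c, r, alpha, q_init)
    z = beta * c * (qp - ql)  # log-odds of the chosen action
    nll = float(np.logaddexp(0.0, -z).sum())
    return nll, qp, ql


def fit_q_model(series: ChoiceSeries, q_init: float = 0.0) -> QFitResult:
    """Maximum-likelihood (alpha, beta) by grid search plus refinement.

    Coarse grid: alpha 0.025..0.975 step 0.025, beta 0..20 step 0.25;
    Nelder-Mead polishes the grid optimum.  The returned NLL never
    exceeds the best grid NLL, and the whole procedure is deterministic.
    """
    if len(series) < 100:
        warnings.warn(
            f"only {len(series)} completed trials; fits below ~100 are noisy",
            stacklevel=2,
        )
    c, r = _encode(series)
    degenerate = len(set(series.choices)) < 2
    if degenerate:
        warnings.warn("all choices identical; fit will sit on a boundary",
                      stacklevel=2)

    best = (np.inf, ALPHA_GRID[0], 0.0)
    for a in ALPHA_GRID:
        qp, ql = _q_forward(c, r, a, q_init)
        dz = c * (qp - ql)
        # vectorized over the beta grid
        nlls = np.logaddexp(0.0, -np.outer(BETA_GRID, dz)).sum(axis=1)
        k = int(np.argmin(nlls))
        if nlls[k] < best[0]:
            best = (float(nlls[k]), float(a), float(BETA_GRID[k]))

    def objective(theta: np.ndarray) -> float:
        a, b = theta
        if not (0 < a <= 1) or b < 0:
            return np.inf
        qp, ql = _q_forward(c, r, a, q_init)
        return float(np.logaddexp(0.0, -b * c * (qp - ql)).sum())

    res = optimize.minimize(
        objective,
        x0=[best[1], best[2]],
        method="Nelder-Mead",
        options={"xatol": 1e-5, "fatol": 1e-9, "maxiter": 400},
    )
    if np.isfinite(res.fun) and res.fun <= best[0]:
        nll, alpha_hat, beta_hat = float(res.fun), float(res.x[0]), float(res.x[1])
    else:
        nll, alpha_hat, beta_hat = best
    qp, ql = _q_forward(c, r, alpha_hat, q_init)
    return QFitResult(
        alpha_hat=alpha_hat,
        beta_hat=beta_hat,
        neg_log_likelihood=nll,
        q_push=qp,
        q_pull=ql,
        boundary_warning=degenerate,
    )


@dataclass
class UncertaintySplit:
    abs_delta_q: np.ndarray
    low_uncertainty: np.ndarray  # high |dQ|
    high_uncertainty: np.ndarray  # low |dQ|
    threshold: float


def uncertainty_split(fit: QFitResult, quantile: float = 0.5) -> UncertaintySplit:
    """Split trials into high-|dQ| (low uncertainty) and low-|dQ| classes.

    Trials with |dQ| strictly below the given quantile form the
    high-uncertainty mask; trials at or above it the low-uncertainty mask.
    """
    adq = np.abs(fit.delta_q)
    thr = float(np.quantile(adq, quantile))
    if np.allclose(adq, adq[0]):
        warnings.warn("constant |dQ|; all trials fall in the low-uncertainty class",
                      stacklevel=2)
    high = adq < thr
    return UncertaintySplit(
        abs_delta_q=adq, low_uncertainty=~high, high_uncertainty=high, threshold=thr
    )


@dataclass
class WslsStats:
    p_stay_given_win: float | None
    p_switch_given_lose: float | None
    n_win: int
    n_lose: int


def wsls_stats(series: ChoiceSeries) -> WslsStats:
    """Win-stay and lose-switch rates over consecutive completed trials."""
    if len(series) < 2:
        raise ValueError("need at least 2 trials")
    c = np.array(series.choices)
    r = np.asarray(series.rewards)
    stay = c[1:] == c[:-1]
    win = r[:-1] == 1
    lose = ~win
    n_win, n_lose = int(win.sum()), int(lose.sum())
    p_stay = float(stay[win].mean()) if n_win else None
    p_switch = float((~stay[lose]).mean()) if n_lose else None
    return WslsStats(p_stay, p_switch, n_win, n_lose)


@dataclass
class LagRegressionResult:
    intercept: float
    rewarded_weights: np.ndarray  # one per lag
    unrewarded_weights: np.ndarray
    converged: bool
    ridged: bool = False


def _ridge_irls(X: np.ndarray, y: np.ndarray, penalty: float = 1e-4,
                tol: float = 1e-8, maxiter: int = 100):
    """Ridge-stabilized IRLS for the logistic likelihood (separation fallback)."""
    w = np.zeros(X.shape[1])
    prev_nll = np.inf
    converged = False
    for _ in range(maxiter):
        z = X @ w
        p = 1.0 / (1.0 + np.exp(-np.clip(z, -35, 35)))
        W = np.maximum(p * (1 - p), 1e-10)
        H = X.T @ (X * W[:, None]) + penalty * np.eye(X.shape[1])
        g = X.T @ (y - p) - penalty * w
        w = w + np.linalg.solve(H, g)
        nll = float(
            np.logaddexp(0, -np.where(y > 0, 1, -1) * (X @ w)).sum()
            + 0.5 * penalty * (w @ w)
        )
        if abs(prev_nll - nll) < tol * max(abs(prev_nll), 1.0):
            converged = True
            break
        prev_nll = nll
    return w, converged


def repeat_choice_regression(
    series: ChoiceSeries,
    n_lags: int = 1,
    include_intercept: bool = False,
) -> LagRegressionResult:
    """Logistic regression of choice repetition on outcome history.

    The outcome is repeat_t = [choice_t == choice_{t-1}].  For each lag k
    the predictor pair is the rewarded / unrewarded indicator of trial
    t-k, signed for k > 1 by whether that trial's choice agrees with the
    choice being repeated.  Because the pair sums to one on every
    completed trial, no intercept is fit by default (the weights then map
    directly to P(repeat | win) and P(repeat | lose)); with an intercept
    the ridge path handles the collinearity.

    Fit by iteratively reweighted least squares (tol 1e-8, max 100
    iterations); perfect separation falls back to ridge-IRLS (1e-4).
    """
    if n_lags < 1:
        raise ValueError("n_lags must be >= 1")
    n = len(series)
    if n <= 10 * (2 * n_lags + 1):
        raise ValueError("series too short for the requested lags")
    c = np.array(series.choices)
    r = np.asarray(series.rewards)
    start = n_lags
    repeat = (c[start:] == c[start - 1 : -1]).astype(float)
    cols = []
    for k in range(1, n_lags + 1):
        rew_k = r[start - k : n - k].astype(float)
        agree = np.where(c[start - k : n - k] == c[start - 1 : -1], 1.0, -1.0)
        sign = agree if k > 1 else 1.0
        cols.append(rew_k * sign)
        cols.append((1.0 - rew_k) * sign)
    X = np.column_stack(cols)
    if include_intercept:
        X = np.column_stack([np.ones(len(repeat)), X])

    ridged = False
    converged = True
    if include_intercept:
        w, converged = _ridge_irls(X, repeat)
        ridged = True
    else:
        import statsmodels.api as sm

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.GLM(repeat, X, family=sm.families.Binomial())
                fit = model.fit(maxiter=100, tol=1e-8)
            w = np.asarray(fit.params)
            if not np.all(np.isfinite(w)) or np.abs(w).max() > 30:
                raise ValueError("separation")
            converged = bool(fit.converged)
        except Exception:
            w, converged = _ridge_irls(X, repeat)
            ridged = True

    off = 1 if include_intercept else 0
    return LagRegressionResult(
        intercept=float(w[0]) if include_intercept else 0.0,
        rewarded_weights=w[off::2][:n_lags].astype(float),
        unrewarded_weights=w[off + 1 :: 2][:n_lags].astype(float),
        converged=converged,
        ridged=ridged,
    )


# ---------------------------------------------------------------------------
# Vigor vs value summaries
# ---------------------------------------------------------------------------

def _rank_trend_stat(groups: list[np.ndarray]) -> float:
    """Jonckheere-style ordered-alternative statistic by explicit rank sums.

    Sum over ordered group pairs (i < j) of the Mann-Whitney count
    #(x_i < x_j) + 0.5 #(x_i == x_j), centered at its null mean so that
    positive values indicate an increasing trend.
    """
    stat = 0.0
    null_mean = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a, b = groups[i], groups[j]
            less = (a[:, None] < b[None, :]).sum()
            ties = (a[:, None] == b[None, :]).sum()
            stat += less + 0.5 * ties
            null_mean += len(a) * len(b) / 2.0
    return stat - null_mean


def _permutation_p(
    values: np.ndarray, labels: np.ndarray, observed: float,
    stat_fn, reps: int, rng: np.random.Generator,
) -> float:
    count = 0
    for _ in range(reps):
        perm = rng.permutation(labels)
        groups = [values[perm == g] for g in np.unique(labels)]
        if abs(stat_fn(groups)) >= abs(observed) - 1e-12:
            count += 1
    return (count + 1) / (reps + 1)


def _rank_sum_stat(groups: list[np.ndarray]) -> float:
    # two-group Mann-Whitney count, centered
    a, b = groups
    return float(
        (a[:, None] < b[None, :]).sum()
        + 0.5 * (a[:, None] == b[None, :]).sum()
        - len(a) * len(b) / 2.0
    )


def vigor_by_value_summary(
    series: ChoiceSeries,
    fit: QFitResult | None = None,
    permutation_reps: int = 1000,
    rng: np.random.Generator | int | None = None,
    min_group: int = 3,
) -> dict:
    """Vigor readouts versus reward volume and versus uncertainty class.

    Volume part: per-volume medians of peak displacement and choice
    latency plus an ordered rank trend statistic across the 2/4/8 ul
    blocks (positive = increases with volume), with permutation p-values
    when ``permutation_reps`` > 0.  Uncertainty part (needs a Q fit):
    low- vs high-|dQ| medians and rank-sum contrasts of the five per-trial
    readouts.  Groups with fewer than ``min_group`` trials are excluded
    and named in the output.
    """
    if series.kinematics is None:
        raise ValueError("series has no attached kinematics")
    rng = np.random.default_rng(rng)
    kin = series.kinematics
    out: dict = {"excluded_groups": []}

    def metric(name):
        return np.array(
            [getattr(k, name) if getattr(k, name) is not None else np.nan for k in kin]
        )

    vols = np.asarray(series.volumes_ul, dtype=float)
    vol_levels = sorted(set(vols))
    volume_section: dict = {"levels": vol_levels, "medians": {}, "trend": {}}
    for name in ("peak_displacement", "choice_latency"):
        vals = metric(name)
        ok = ~np.isnan(vals)
        groups, labels_v, vals_v = [], [], []
        for lv in vol_levels:
            g = vals[ok & (vols == lv)]
            if len(g) < min_group:
                out["excluded_groups"].append((name, lv, len(g)))
                continue
            groups.append(g)
            labels_v.append(np.full(len(g), lv))
            vals_v.append(g)
            volume_section["medians"].setdefault(name, {})[lv] = float(np.median(g))
        if len(groups) >= 2:
            stat = _rank_trend_stat(groups)
            entry = {"stat": stat}
            if permutation_reps > 0:
                entry["p"] = _permutation_p(
                    np.concatenate(vals_v), np.concatenate(labels_v),
                    stat, _rank_trend_stat, permutation_reps, rng,
                )
            volume_section["trend"][name] = entry
    out["volume"] = volume_section

    if fit is not None:
        split = uncertainty_split(fit)
        unc_section: dict = {"threshold": split.threshold, "contrasts": {}}
        readouts = (
            "peak_displacement",
            "n_bouts",
            "directional_consistency",
            "decisive_mean_velocity",
            "path_length",
        )
        for name in readouts:
            vals = metric(name)
            ok = ~np.isnan(vals)
            lo = vals[ok & split.low_uncertainty]
            hi = vals[ok & split.high_uncertainty]
            if len(lo) < min_group or len(hi) < min_group:
                out["excluded_groups"].append((name, "uncertainty", min(len(lo), len(hi))))
                continue
            stat = _rank_sum_stat([lo, hi])
            entry = {
                "median_low_uncertainty": float(np.median(lo)),
                "median_high_uncertainty": float(np.median(hi)),
                "stat": stat,  # positive: larger under high uncertainty
            }
            if permutation_reps > 0:
                vals2 = np.concatenate([lo, hi])
                labels2 = np.concatenate([np.zeros(len(lo)), np.ones(len(hi))])
                entry["p"] = _permutation_p(
                    vals2, labels2, stat, _rank_sum_stat, permutation_reps, rng
                )
            unc_section["contrasts"][name] = entry
        out["uncertainty"] = unc_section
    return out
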