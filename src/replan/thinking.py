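"""Bayesian decomposition of response times into thinking time and delay.

Each response time is modeled as t_r = t_t + t_d, the sum of a latent
thinking time t_t (uniform prior on [0, 7 s], the maximum response allowed
by the task) and a perception-action delay t_d with a shifted log-normal
prior p_d(t_d; mu, sigma, delta).  The delay prior is fitted per participant
on *guided* actions, where the optimal path is shown and t_t = 0 by design,
so t_d is observed directly.  A separate prior is fitted for the first
action of each trial (which carries an extra perceptual load after the
teleport) and for all other actions.

Given a fitted prior, the posterior-mean thinking time has the closed form

    t_hat = t_r - delta - E[x | x < t_r - delta]

with E[x | x < k] = exp(mu + sigma^2/2) * Phi((log k - mu - sigma^2)/sigma)
                                        / Phi((log k - mu)/sigma)

for an (unshifted) log-normal x.  Because t_r never exceeds the uniform
prior's 7-s bound, the upper truncation of p(t_t) never binds and is omitted
from the closed form.  Response times below the fitted delta are assigned a
thinking time of zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import log_ndtr

FIRST_OF_TRIAL = "first_of_trial"
OTHER = "other"


@dataclass(frozen=True)
class DelayPrior:
    """Shifted log-normal delay prior: log(t_d - delta) ~ N(mu, sigma^2)."""

    mu: float          # log-ms location
    sigma: float       # log-ms scale
    delta_ms: float    # shift (minimum possible delay), ms
    action_class: str = OTHER

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.delta_ms < 0:
            raise ValueError("delta must be non-negative")

    def mean_delay(self) -> float:
        return self.delta_ms + float(np.exp(self.mu + 0.5 * self.sigma ** 2))

    def to_dict(self) -> dict:
        return {"mu": self.mu, "sigma": self.sigma,
                "delta_ms": self.delta_ms, "action_class": self.action_class}


def fit_delay_prior(guided_rts: np.ndarray, action_class: str = OTHER
                    ) -> DelayPrior:
    """Maximum-likelihood shifted log-normal fit to guided response times.

    For each candidate shift delta on a 1-ms grid over
    [0, min(guided_rts) - 1], the optimal (mu, sigma) are the mean and s.d.
    of log(t - delta); the delta with the largest profiled likelihood wins.
    The grid stops 1 ms below the smallest observation so every data point
    keeps strictly positive density.
    """
    t = np.asarray(guided_rts, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 guided response times")
    if np.any(t <= 0):
        raise ValueError("response times must be positive")
    deltas = np.arange(0.0, max(np.floor(t.min() - 1.0), 0.0) + 1.0)
    shifted = t[None, :] - deltas[:, None]           # (D, n), all > 0
    logs = np.log(shifted)
    mu = logs.mean(axis=1)
    sigma = logs.std(axis=1)
    ok = sigma > 1e-12
    if not ok.any():
        raise ValueError("degenerate guided response times (zero variance)")
    n = t.size
    # profiled log-likelihood: sum of squares term collapses to n/2
    ll = np.where(ok,
                  -logs.sum(axis=1) - n * np.log(np.where(ok, sigma, 1.0))
                  - 0.5 * n * np.log(2 * np.pi) - 0.5 * n,
                  -np.inf)
    best = int(np.argmax(ll))
    return DelayPrior(mu=float(mu[best]), sigma=float(sigma[best]),
                      delta_ms=float(deltas[best]), action_class=action_class)


def truncated_lognormal_mean(k, mu: float, sigma: float):
    """E[x | x < k] for log-normal x (no shift), stable in log space."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    k = np.asarray(k, dtype=float)
    if np.any(k <= 0):
        raise ValueError("truncation point must be positive")
    logk = np.log(k)
    log_ratio = (log_ndtr((logk - mu - sigma ** 2) / sigma)
                 - log_ndtr((logk - mu) / sigma))
    out = np.exp(mu + 0.5 * sigma ** 2 + log_ratio)
    # guard against roundoff: the conditional mean is below the cutoff
    out = np.minimum(out, k)
    return out if out.ndim else float(out)


def posterior_mean_thinking_time(t_r, prior: DelayPrior,
                                 strategy: str = "posterior_mean"):
    """Point estimate of the thinking time for response time(s) `t_r` (ms).

    strategy:
      - "posterior_mean" (default): closed-form posterior mean.
      - "posterior_mode": mode of p(t_t | t_r).
      - "constant_delay": t_r minus the prior's mean delay, clipped at 0.
    Response times at or below the prior's delta map to 0.
    """
    t_r = np.asarray(t_r, dtype=float)
    k = t_r - prior.delta_ms
    if strategy == "posterior_mean":
        with np.errstate(divide="ignore"):
            est = np.where(k > 0,
                           k - truncated_lognormal_mean(np.maximum(k, 1e-12),
                                                        prior.mu, prior.sigma),
                           0.0)
    elif strategy == "posterior_mode":
        mode_delay = np.exp(prior.mu - prior.sigma ** 2)
        est = np.clip(k - mode_delay, 0.0, np.maximum(k, 0.0))
    elif strategy == "constant_delay":
        est = np.maximum(t_r - prior.mean_delay(), 0.0)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    est = np.maximum(est, 0.0)
    return est if est.ndim else float(est)


def fit_priors(rt_table: pd.DataFrame) -> dict:
    """Fit per-participant, per-action-class priors from the guided rows.

    Expects columns (participant, response_time_ms, guided, first_action).
    Returns {(participant, action_class): DelayPrior}.
    """
    priors = {}
    guided = rt_table[rt_table["guided"].astype(bool)]
    for pid, sub in guided.groupby("participant"):
        for cls, m in ((FIRST_OF_TRIAL, sub["first_action"].astype(bool)),
                       (OTHER, ~sub["first_action"].astype(bool))):
            vals = sub.loc[m, "response_time_ms"].to_numpy()
            if vals.size >= 2:
                priors[(pid, cls)] = fit_delay_prior(vals, cls)
    return priors


def estimate_thinking_times(rt_table: pd.DataFrame, priors: dict,
                            strategy: str = "posterior_mean") -> pd.DataFrame:
    """Posterior-mean thinking time for every nonguided action.

    `priors` maps (participant, action_class) to a DelayPrior; a missing
    prior for a needed class raises KeyError.  Returns the nonguided rows
    with an added `thinking_time_ms` column.
    """
    out = rt_table[~rt_table["guided"].astype(bool)].copy()
    est = np.empty(len(out))
    for i, (_, row) in enumerate(out.iterrows()):
        cls = FIRST_OF_TRIAL if row["first_action"] else OTHER
        key = (row["participant"], cls)
        if key not in priors:
            raise KeyError(f"no delay prior fitted for {key}")
        est[i] = posterior_mean_thinking_time(row["response_time_ms"],
                                              priors[key], strategy=strategy)
    out["thinking_time_ms"] = est
    return out
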