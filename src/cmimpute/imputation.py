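"""Marginal imputation distributions and conditional mean completion.

For each subject the chosen imputation method defines a marginal
multivariate-normal distribution ``N(mu_tilde_i, sigma_tilde_i)`` over the
J scheduled outcomes:

* MAR: ``mu_tilde = X_i beta_hat`` (the subject's own fitted trajectory);
* CR (copy reference): the fitted control trajectory ``X_i,ref beta_hat``;
* J2R (jump to reference): own trajectory up to the ICE visit, control
  trajectory afterwards;
* CIR (copy increments in reference): own trajectory up to the ICE visit,
  then the control trajectory's increments added onto the value reached.

Control-arm subjects always use the MAR distribution.  With a common
covariance across arms, ``sigma_tilde = sigma_hat`` for every method.
Missing entries are replaced deterministically by the conditional mean given
all observed outcomes (including observed post-ICE values).  Random
conditional draws are provided for validation: averaging many random
single-imputation estimates converges to the conditional-mean estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .mmrm import MmrmFit
from .trial_data import ModelFrame, REFERENCE_METHODS, METHODS

__all__ = [
    "MarginalImputationDistribution",
    "CompletedDataset",
    "marginal_distribution",
    "marginal_means",
    "conditional_mean",
    "complete_frame",
    "random_conditional_draws",
]

_COND_MAX = 1e12  # condition-number guard for "singular" observed blocks


@dataclass
class MarginalImputationDistribution:
    """Per-subject marginal imputation distribution (mu_tilde, sigma_tilde)."""

    mu_tilde: np.ndarray
    sigma_tilde: np.ndarray
    method: str
    subject_id: object = None


@dataclass
class CompletedDataset:
    """Outcome matrix with missing entries replaced by conditional means."""

    completed: np.ndarray  # (n, J)
    imputed_mask: np.ndarray  # (n, J) True where the value was imputed
    frame: ModelFrame = None
    subjects: pd.DataFrame = None  # subject-level fields for the analysis step
    method: str = ""

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format completed outcomes with an ``imputed`` flag column."""
        n, J = self.completed.shape
        return pd.DataFrame(
            {
                "subject_id": np.repeat(self.frame.subject_ids, J),
                "visit": np.tile(np.arange(1, J + 1), n),
                "outcome": self.completed.ravel(),
                "imputed": self.imputed_mask.ravel(),
            }
        )


def resolve_strategies(frame: ModelFrame, method: str | None) -> np.ndarray:
    """Per-subject imputation strategy after applying a method override.

    ``method`` (if given) replaces the recorded strategy of every subject
    with an ICE; subjects without an ICE are MAR by construction.  Control
    subjects keep their label but are imputed under their MAR distribution.
    """
    if method is not None and method not in METHODS:
        raise ValueError(f"unknown imputation method {method!r}; expected one of {METHODS}")
    strategies = frame.strategy.astype(object).copy()
    if method is not None:
        strategies[frame.ice_visit >= 0] = method
    return strategies


def marginal_means(frame: ModelFrame, fit: MmrmFit, method: str | None = None) -> np.ndarray:
    """(n, J) matrix of marginal imputation means for all subjects."""
    mu = frame.X @ fit.beta
    mu_ref = frame.X_ref @ fit.beta
    strategies = resolve_strategies(frame, method)
    out = mu.copy()
    for i in range(frame.n_subjects):
        strat = strategies[i]
        if strat not in REFERENCE_METHODS or frame.arm[i] == 0:
            continue
        tv = int(frame.ice_visit[i])
        if tv < 0:
            raise ValueError(
                f"reference-based method {strat!r} requires an ICE visit for subject "
                f"{frame.subject_ids[i]!r}"
            )
        out[i] = _reference_mean(mu[i], mu_ref[i], tv, strat)
    return out


def _reference_mean(mu_i: np.ndarray, mu_ref_i: np.ndarray, tv: int, method: str) -> np.ndarray:
    J = len(mu_i)
    out = mu_i.copy()
    if method == "CR":
        return mu_ref_i.copy()
    if method == "J2R":
        out[tv:] = mu_ref_i[tv:]  # visits tv+1..J are indices tv..J-1
        return out
    if method == "CIR":
        if tv == 0:
            # ICE before the first follow-up: the anchor is the (shared)
            # baseline, so copying increments coincides with copy reference
            return mu_ref_i.copy()
        out[tv:] = mu_i[tv - 1] + (mu_ref_i[tv:] - mu_ref_i[tv - 1])
        return out
    raise ValueError(f"unknown reference-based method {method!r}")


def marginal_distribution(
    subject_index: int,
    frame: ModelFrame,
    fit: MmrmFit,
    method: str | None = None,
) -> MarginalImputationDistribution:
    """Marginal imputation distribution for one subject."""
    mu = marginal_means(frame, fit, method)[subject_index]
    strategies = resolve_strategies(frame, method)
    return MarginalImputationDistribution(
        mu_tilde=mu,
        sigma_tilde=fit.sigma.copy(),
        method=str(strategies[subject_index]),
        subject_id=frame.subject_ids[subject_index],
    )


# ---------------------------------------------------------------------------
# conditional completion
# ---------------------------------------------------------------------------


def _conditional_blocks(sigma: np.ndarray, obs: np.ndarray, mis: np.ndarray):
    """K = Sigma_mo Sigma_oo^-1 and the conditional covariance (Schur)."""
    S_oo = sigma[np.ix_(obs, obs)]
    if obs.size:
        cf = linalg.cho_factor(S_oo, lower=True, check_finite=False)
        d = np.diag(cf[0]) ** 2
        if d.max() / d.min() > _COND_MAX:
            raise np.linalg.LinAlgError(
                "observed-block covariance is numerically singular"
            )
        K = linalg.cho_solve(cf, sigma[np.ix_(obs, mis)], check_finite=False).T
    else:
        K = np.zeros((mis.size, 0))
    S_cond = sigma[np.ix_(mis, mis)] - K @ sigma[np.ix_(obs, mis)]
    return K, S_cond


def conditional_mean(
    marg: MarginalImputationDistribution,
    y: np.ndarray,
    observed: np.ndarray | None = None,
) -> np.ndarray:
    """Complete one outcome vector by its conditional expectation.

    ``y`` is the length-J outcome vector with NaN for missing entries (or
    pass an explicit boolean ``observed`` mask).  Observed entries are
    returned untouched; missing entries are replaced by
    ``mu_m + Sigma_mo Sigma_oo^-1 (y_o - mu_o)``.
    """
    y = np.asarray(y, dtype=float)
    obs_mask = ~np.isnan(y) if observed is None else np.asarray(observed, bool)
    obs = np.flatnonzero(obs_mask)
    mis = np.flatnonzero(~obs_mask)
    out = y.copy()
    if mis.size == 0:
        return out
    K, _ = _conditional_blocks(marg.sigma_tilde, obs, mis)
    out[mis] = marg.mu_tilde[mis] + K @ (y[obs] - marg.mu_tilde[obs])
    return out


def complete_frame(
    frame: ModelFrame,
    fit: MmrmFit,
    method: str | None = None,
    subjects: pd.DataFrame | None = None,
) -> CompletedDataset:
    """Conditional-mean completion of every subject in the frame.

    Subjects sharing an observation pattern share the conditional-mean
    weights, so the completion is one small solve per pattern.
    """
    mu = marginal_means(frame, fit, method)
    Y = frame.Y
    mask = frame.obs_mask
    completed = np.where(mask, Y, 0.0)
    n, J = Y.shape
    keys = mask @ (1 << np.arange(J))
    for key in np.unique(keys):
        idx = np.flatnonzero(keys == key)
        row = mask[idx[0]]
        mis = np.flatnonzero(~row)
        if mis.size == 0:
            continue
        obs = np.flatnonzero(row)
        K, _ = _conditional_blocks(fit.sigma, obs, mis)
        resid = Y[np.ix_(idx, obs)] - mu[np.ix_(idx, obs)]
        completed[np.ix_(idx, mis)] = mu[np.ix_(idx, mis)] + resid @ K.T
    return CompletedDataset(
        completed=completed,
        imputed_mask=~mask,
        frame=frame,
        subjects=subjects,
        method=method or "per-subject",
    )


def random_conditional_draws(
    marg: MarginalImputationDistribution,
    y: np.ndarray,
    M: int,
    seed=None,
    observed: np.ndarray | None = None,
) -> np.ndarray:
    """M random single imputations from the conditional distribution.

    Returns an (M, J) array of completed vectors whose missing entries are
    drawn from ``N(E[Y_mis | Y_obs], Schur complement)``.  The empirical
    mean converges to :func:`conditional_mean` as M grows; used to validate
    the deterministic shortcut.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    y = np.asarray(y, dtype=float)
    obs_mask = ~np.isnan(y) if observed is None else np.asarray(observed, bool)
    obs = np.flatnonzero(obs_mask)
    mis = np.flatnonzero(~obs_mask)
    rng = np.random.default_rng(seed)
    out = np.tile(np.where(obs_mask, y, 0.0), (M, 1))
    if mis.size == 0:
        return out
    K, S_cond = _conditional_blocks(marg.sigma_tilde, obs, mis)
    center = marg.mu_tilde[mis] + K @ (y[obs] - marg.mu_tilde[obs])
    # guard against a numerically semi-definite Schur complement
    w, V = np.linalg.eigh((S_cond + S_cond.T) / 2.0)
    root = V * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((M, mis.size))
    out[:, mis] = center + z @ root.T
    return out
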