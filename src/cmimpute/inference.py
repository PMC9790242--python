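"""Resampling-based frequentist inference for the CMI treatment effect.

The whole imputation pipeline (model fit, conditional mean imputation,
ANCOVA) is re-run on each leave-one-subject-out dataset (jackknife) or
subject-level resample (bootstrap, stratified by treatment arm).  Tests and
confidence intervals use the Z-score ``(theta_hat - theta0) / se`` with a
normal approximation.  Rubin's rules do not apply here: the imputations are
generated conditional on the REML estimate, and the jackknife/bootstrap
target the frequentist repeated-sampling variance instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .mmrm import ConvergenceError

__all__ = [
    "TreatmentEffectResult",
    "jackknife_se",
    "bootstrap_se",
    "wald_summary",
    "jackknife_se_from_estimates",
]


@dataclass
class TreatmentEffectResult:
    """Treatment effect with resampling standard error and Wald test."""

    theta_hat: float
    se: float
    z: float
    p_two_sided: float
    ci: tuple[float, float]
    alpha: float = 0.05
    theta0: float = 0.0
    resampling: str = "none"
    n_resamples: int = 0
    n_replaced: int = 0  # bootstrap redraws after non-convergence
    seed: int | None = None  # None for deterministic (jackknife) results


def wald_summary(
    theta_hat: float,
    se: float,
    theta0: float = 0.0,
    alpha: float = 0.05,
    resampling: str = "none",
    n_resamples: int = 0,
    n_replaced: int = 0,
    seed=None,
) -> TreatmentEffectResult:
    """Normal-approximation two-sided test and confidence interval."""
    if se < 0:
        raise ValueError("standard error must be non-negative")
    if se == 0:
        z = 0.0 if theta_hat == theta0 else math.copysign(math.inf, theta_hat - theta0)
    else:
        z = (theta_hat - theta0) / se
    p = 2.0 * stats.norm.sf(abs(z))
    q = stats.norm.ppf(1.0 - alpha / 2.0)
    return TreatmentEffectResult(
        theta_hat=float(theta_hat),
        se=float(se),
        z=float(z),
        p_two_sided=float(p),
        ci=(float(theta_hat - q * se), float(theta_hat + q * se)),
        alpha=alpha,
        theta0=theta0,
        resampling=resampling,
        n_resamples=n_resamples,
        n_replaced=n_replaced,
        seed=seed,
    )


def jackknife_se_from_estimates(loo: np.ndarray) -> float:
    """se = sqrt((n-1)/n * sum((theta_-i - mean)^2)) from leave-one-out fits."""
    loo = np.asarray(loo, dtype=float)
    n = len(loo)
    return float(np.sqrt((n - 1) / n * np.sum((loo - loo.mean()) ** 2)))


def _run_indexed(tasks, n_jobs):
    if n_jobs != 1:
        from joblib import Parallel, delayed

        return Parallel(n_jobs=n_jobs)(delayed(f)() for f in tasks)
    return [f() for f in tasks]


def jackknife_se(
    engine,
    theta_hat: float,
    theta0: float = 0.0,
    alpha: float = 0.05,
    start_sigma=None,
    n_jobs: int = 1,
) -> TreatmentEffectResult:
    """Leave-one-subject-out jackknife standard error and Wald inference.

    Re-runs the full pipeline n times.  A non-convergent leave-one-out fit
    is a hard error (there is no redraw analogue for the jackknife).
    Deterministic: results are independent of subject ordering and worker
    count.
    """
    n = engine.frame.n_subjects
    if min((engine.frame.arm == 0).sum(), (engine.frame.arm == 1).sum()) < 2:
        raise ValueError("jackknife requires at least 2 subjects per arm")
    all_idx = np.arange(n)

    def task(i):
        def run():
            idx = np.delete(all_idx, i)
            try:
                res, _ = engine.estimate(idx, start_sigma=start_sigma)
            except ConvergenceError as e:
                raise ConvergenceError(
                    f"leave-one-out fit failed for subject index {i} "
                    f"(id {engine.frame.subject_ids[i]!r}): {e}"
                ) from None
            return res.theta_hat
        return run

    loo = np.array(_run_indexed([task(i) for i in range(n)], n_jobs), dtype=float)
    se = jackknife_se_from_estimates(loo)
    return wald_summary(
        theta_hat, se, theta0=theta0, alpha=alpha,
        resampling="jackknife", n_resamples=n, seed=None,
    )


def bootstrap_se(
    engine,
    theta_hat: float,
    B: int = 999,
    seed=None,
    theta0: float = 0.0,
    alpha: float = 0.05,
    start_sigma=None,
    max_redraws: int | None = None,
    n_jobs: int = 1,
) -> TreatmentEffectResult:
    """Subject-level bootstrap standard error, stratified by treatment arm.

    Each resample redraws subjects with replacement within each arm
    (preserving the allocation) and re-runs the full pipeline.  Resamples
    whose imputation model does not converge are replaced by fresh resamples
    and counted in ``n_replaced``; more than ``max_redraws`` (default 10*B)
    total replacements is an error.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if seed is None:
        raise ValueError("bootstrap requires a seed for reproducibility")
    if max_redraws is None:
        max_redraws = 10 * B
    arm = engine.frame.arm
    idx_c = np.flatnonzero(arm == 0)
    idx_t = np.flatnonzero(arm == 1)
    ss = np.random.SeedSequence(seed)
    # one independent stream per resample slot: estimates do not depend on
    # execution order, and a replacement only reseeds its own slot
    streams = [np.random.default_rng(s) for s in ss.spawn(B)]

    n_replaced = 0

    def task(b):
        def run():
            rng = streams[b]
            replaced = 0
            while True:
                idx = np.concatenate(
                    [rng.choice(idx_c, size=len(idx_c), replace=True),
                     rng.choice(idx_t, size=len(idx_t), replace=True)]
                )
                try:
                    res, _ = engine.estimate(idx, start_sigma=start_sigma)
                    return res.theta_hat, replaced
                except ConvergenceError:
                    replaced += 1
                    if replaced > max_redraws:
                        raise ConvergenceError(
                            f"more than {max_redraws} consecutive non-convergent "
                            f"bootstrap resamples"
                        ) from None
        return run

    out = _run_indexed([task(b) for b in range(B)], n_jobs)
    thetas = np.array([t for t, _ in out], dtype=float)
    n_replaced = int(sum(r for _, r in out))
    se = float(np.std(thetas, ddof=1)) if B > 1 else 0.0
    return wald_summary(
        theta_hat, se, theta0=theta0, alpha=alpha,
        resampling="bootstrap", n_resamples=B, n_replaced=n_replaced,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )
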