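"""ANCOVA analysis of completed data and the end-to-end CMI estimator.

The pipeline is: build the model frame, fit the MMRM imputation model by
REML, complete the data by conditional mean imputation under the chosen
method, then regress the completed outcome at the analysis visit on the
treatment indicator and baseline covariates by ordinary least squares.  The
treatment effect ``theta`` is the treatment-indicator coefficient.  Because
every step after the model fit is deterministic, two runs on identical
input give bit-identical results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import imputation, mmrm
from .imputation import CompletedDataset, complete_frame
from .trial_data import DEFAULT_FORMULA, ModelFrame, TrialDataset, build_model_frame

__all__ = ["AncovaResult", "run_ancova", "cmi_estimate", "CmiEstimator", "MmrmImputer"]

DEFAULT_ANALYSIS_COVARIATES = ("baseline",)


@dataclass
class AncovaResult:
    """OLS fit of the completed outcome at one visit."""

    theta_hat: float  # treatment-indicator coefficient
    coefficients: np.ndarray
    column_names: list[str]
    visit_analyzed: int
    n: int


def _ancova_design(subjects: pd.DataFrame, arm: np.ndarray, covariates) -> tuple[np.ndarray, list]:
    """Intercept + treatment indicator + covariate columns, one row/subject."""
    cols = [np.ones(len(arm)), arm.astype(float)]
    names = ["Intercept", "arm[T.intervention]"]
    for c in covariates:
        if c not in subjects.columns:
            raise ValueError(f"analysis covariate {c!r} not found in the data")
        v = subjects[c]
        if pd.api.types.is_numeric_dtype(v):
            cols.append(v.to_numpy(dtype=float))
            names.append(c)
        else:
            dummies = pd.get_dummies(v, prefix=c, drop_first=True)
            for dc in dummies.columns:
                cols.append(dummies[dc].to_numpy(dtype=float))
                names.append(dc)
    return np.column_stack(cols), names


def _ancova_solve(A: np.ndarray, z: np.ndarray, names, visit: int) -> AncovaResult:
    coef, _, rank, _ = np.linalg.lstsq(A, z, rcond=None)
    if rank < A.shape[1]:
        raise np.linalg.LinAlgError(
            f"collinear analysis covariates (rank {rank} < {A.shape[1]}): columns {names}"
        )
    return AncovaResult(
        theta_hat=float(coef[1]),
        coefficients=coef,
        column_names=list(names),
        visit_analyzed=visit,
        n=len(z),
    )


def run_ancova(
    completed: CompletedDataset,
    visit: int | None = None,
    covariates=DEFAULT_ANALYSIS_COVARIATES,
) -> AncovaResult:
    """ANCOVA of the completed outcome at ``visit`` (default: final visit).

    One row per subject; the dependent variable is the observed-or-imputed
    outcome at the visit, the primary covariate is the treatment group.
    """
    frame = completed.frame
    J = completed.completed.shape[1]
    j = J if visit is None else int(visit)
    if not 1 <= j <= J:
        raise ValueError(f"visit must be in 1..{J}")
    subjects = completed.subjects if completed.subjects is not None else pd.DataFrame(
        index=range(completed.completed.shape[0])
    )
    A, names = _ancova_design(subjects, frame.arm, covariates)
    return _ancova_solve(A, completed.completed[:, j - 1], names, j)


class _CmiEngine:
    """Precomputed arrays for fast repeated estimation on subject subsets.

    Used by the resampling inference: ``estimate(idx)`` re-runs model fit,
    conditional mean imputation and ANCOVA on the subjects selected by
    ``idx`` (which may repeat for bootstrap resamples), warm-starting the
    covariance optimisation at the full-data estimate.
    """

    def __init__(
        self,
        frame: ModelFrame,
        ancova_X: np.ndarray,
        ancova_names: list,
        visit: int,
        method: str | None,
        objective: str = "REML",
    ):
        self.frame = frame
        self.ancova_X = ancova_X
        self.ancova_names = ancova_names
        self.visit = visit
        self.method = method
        self.objective = objective

    def estimate(self, idx=None, start_sigma=None):
        frame = self.frame if idx is None else self.frame.subset(idx)
        A = self.ancova_X if idx is None else self.ancova_X[idx]
        # warm-started resampling re-fits tolerate a looser gradient norm:
        # the effect on the resulting theta is far below the resampling SE
        gtol = 1e-3 if (idx is not None and start_sigma is not None) else 1e-5
        fit = mmrm.fit_mmrm(
            frame, objective=self.objective, start_sigma=start_sigma,
            check_rank=(idx is None), gtol=gtol,
        )
        comp = complete_frame(frame, fit, method=self.method)
        res = _ancova_solve(A, comp.completed[:, self.visit - 1], self.ancova_names, self.visit)
        return res, fit

    def estimate_multi(self, methods):
        """One model fit shared across several imputation methods.

        Valid because the post-ICE masking (and hence the fitted model) is
        identical for every method; only the marginal imputation means
        differ.  Returns ({method: AncovaResult}, fit).
        """
        fit = mmrm.fit_mmrm(self.frame, objective=self.objective)
        out = {}
        for m in methods:
            comp = complete_frame(self.frame, fit, method=m)
            out[m] = _ancova_solve(
                self.ancova_X, comp.completed[:, self.visit - 1],
                self.ancova_names, self.visit,
            )
        return out, fit


class CmiEstimator(BaseEstimator):
    """Treatment-effect estimator by conditional mean imputation.

    Parameters
    ----------
    method : {None, "MAR", "CR", "J2R", "CIR"}
        Imputation method applied to every subject with an ICE; ``None``
        uses the per-subject strategies recorded in the data.
    formula : str
        Mean model of the MMRM imputation step (patsy right-hand side).
    analysis_covariates : sequence of str
        Baseline covariates of the ANCOVA analysis model.
    visit : int or None
        Analysis visit; ``None`` means the final visit J.
    objective : {"REML", "ML"}
    drop_post_ice : bool
        Also remove observed post-ICE data of MAR/control subjects from the
        imputation model (post-ICE data of intervention-arm reference-based
        subjects is always removed).  All observed values re-enter the
        imputation conditioning and the analysis regardless.
    inference : {None, "jackknife", "bootstrap"}
    B : int
        Bootstrap resamples.
    alpha, theta0 : float
        Test level and null value of the Wald test.
    seed : int, optional
        Bootstrap seed (required for bootstrap; the jackknife is
        deterministic).
    n_jobs : int
        Parallel workers for the resampling loop; results are reduced by
        stable index and invariant to worker count.

    Attributes (after :meth:`fit`)
    ------------------------------
    theta_, se_, z_, pvalue_, ci_ : float / tuple
    mmrm_fit_ : MmrmFit
    ancova_result_ : AncovaResult
    result_ : TreatmentEffectResult (when inference was requested)
    """

    def __init__(
        self,
        method: str | None = None,
        formula: str = DEFAULT_FORMULA,
        analysis_covariates=DEFAULT_ANALYSIS_COVARIATES,
        visit: int | None = None,
        objective: str = "REML",
        drop_post_ice: bool = True,
        inference: str | None = None,
        B: int = 999,
        alpha: float = 0.05,
        theta0: float = 0.0,
        seed=None,
        n_jobs: int = 1,
    ):
        self.method = method
        self.formula = formula
        self.analysis_covariates = analysis_covariates
        self.visit = visit
        self.objective = objective
        self.drop_post_ice = drop_post_ice
        self.inference = inference
        self.B = B
        self.alpha = alpha
        self.theta0 = theta0
        self.seed = seed
        self.n_jobs = n_jobs

    def _engine(self, data: TrialDataset) -> _CmiEngine:
        frame = build_model_frame(
            data, formula=self.formula, drop_post_ice_control=self.drop_post_ice
        )
        subjects = data.subjects
        A, names = _ancova_design(subjects, frame.arm, tuple(self.analysis_covariates))
        visit = data.n_visits if self.visit is None else int(self.visit)
        return _CmiEngine(frame, A, names, visit, self.method, self.objective)

    def fit(self, data: TrialDataset, y=None):
        from . import inference as inf

        engine = self._engine(data)
        if self.inference == "jackknife":
            counts = np.bincount(engine.frame.arm, minlength=2)
            if counts.min() < 2:
                raise ValueError(
                    "jackknife requires at least 2 subjects per arm "
                    f"(got control={counts[0]}, intervention={counts[1]})"
                )
        res, fit = engine.estimate()
        self.engine_ = engine
        self.mmrm_fit_ = fit
        self.ancova_result_ = res
        self.theta_ = res.theta_hat
        if self.inference is None:
            return self
        if self.inference == "jackknife":
            result = inf.jackknife_se(
                engine, theta_hat=self.theta_, theta0=self.theta0,
                alpha=self.alpha, start_sigma=fit.sigma, n_jobs=self.n_jobs,
            )
        elif self.inference == "bootstrap":
            if self.seed is None:
                raise ValueError("bootstrap inference requires a seed for reproducibility")
            result = inf.bootstrap_se(
                engine, theta_hat=self.theta_, B=self.B, seed=self.seed,
                theta0=self.theta0, alpha=self.alpha, start_sigma=fit.sigma,
                n_jobs=self.n_jobs,
            )
        else:
            raise ValueError(f"unknown inference {self.inference!r}")
        self.result_ = result
        self.se_ = result.se
        self.z_ = result.z
        self.pvalue_ = result.p_two_sided
        self.ci_ = result.ci
        return self


def cmi_estimate(
    data: TrialDataset,
    method: str | None = None,
    formula: str = DEFAULT_FORMULA,
    visit: int | None = None,
    analysis_covariates=DEFAULT_ANALYSIS_COVARIATES,
    objective: str = "REML",
    drop_post_ice: bool = True,
) -> AncovaResult:
    """Point estimate of the treatment effect by conditional mean imputation."""
    est = CmiEstimator(
        method=method,
        formula=formula,
        analysis_covariates=analysis_covariates,
        visit=visit,
        objective=objective,
        drop_post_ice=drop_post_ice,
    )
    est.fit(data)
    return est.ancova_result_


class MmrmImputer(BaseEstimator):
    """Transformer-style interface: fit the imputation model, return
    conditional-mean-completed data.

    ``fit(data)`` fits the MMRM on the masked fitting rows;
    ``transform(data)`` returns the long-format completed outcomes with an
    ``imputed`` flag.  ``fit_transform`` chains the two on one dataset.
    """

    def __init__(
        self,
        method: str | None = None,
        formula: str = DEFAULT_FORMULA,
        objective: str = "REML",
        drop_post_ice: bool = True,
    ):
        self.method = method
        self.formula = formula
        self.objective = objective
        self.drop_post_ice = drop_post_ice

    def fit(self, data: TrialDataset, y=None):
        self.frame_ = build_model_frame(
            data, formula=self.formula, drop_post_ice_control=self.drop_post_ice
        )
        self.mmrm_fit_ = mmrm.fit_mmrm(self.frame_, objective=self.objective)
        self.beta_ = self.mmrm_fit_.beta
        self.sigma_ = self.mmrm_fit_.sigma
        return self

    def transform(self, data: TrialDataset | None = None) -> pd.DataFrame:
        frame = self.frame_
        if data is not None:
            frame = build_model_frame(
                data, formula=self.formula, drop_post_ice_control=self.drop_post_ice
            )
        comp = complete_frame(frame, self.mmrm_fit_, method=self.method)
        return comp.to_dataframe()

    def fit_transform(self, data: TrialDataset, y=None) -> pd.DataFrame:
        return self.fit(data).transform()
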