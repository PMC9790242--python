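"""Clinical-trial simulator for longitudinal outcomes with treatment discontinuation.

Generates two-arm trials with bi-monthly visits, outcomes driven by a
random-intercept/random-slope Gaussian model, outcome-dependent logistic
study-drug discontinuation, a copy-increments-in-reference (CIR) type change
of trajectory after discontinuation in the active arm, and study drop-out at
the discontinuation visit.  A harness computes operating characteristics
(mean/SD of the treatment-effect estimate, mean standard error, rejection
rate) of the conditional-mean-imputation pipeline over simulated replicates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .trial_data import TrialDataset

__all__ = [
    "SimulationScenario",
    "OperatingCharacteristics",
    "simulate_trial",
    "true_effect",
    "run_operating_characteristics",
]


def _logit(p: float) -> float:
    if p <= 0.0:
        return -np.inf  # hazard switched off
    if p >= 1.0:
        return np.inf
    return math.log(p / (1.0 - p))


@dataclass
class SimulationScenario:
    """Generative parameters of the simulated trial.

    Outcomes are measured at ``visit_months`` (month 0 is baseline).  The
    control-arm mean rises linearly from ``baseline_mean`` by
    ``control_slope`` points/year.  Under the alternative hypothesis the
    active-arm slope drops to ``active_slope`` points/year from
    ``active_kink_month`` onward; under the null both arms share the control
    trajectory.  Subject-level deviations come from a bivariate normal
    random intercept and slope plus independent residual noise.

    Study-drug discontinuation is drawn after each visit listed in
    ``disc_draw_visits`` (indices into ``visit_months``) from a logistic
    model in the observed outcome at that visit:
    ``expit(logit(base) + log(disc_odds_factor)/10 * (y - disc_outcome_ref))``
    where ``base = 1 - (1 - p_month)**disc_interval_months`` compounds the
    per-arm monthly hazard ``disc_base_prob`` over the between-visit
    interval, and the odds multiply by ``disc_odds_factor`` per 10 outcome
    points above the reference.  With ``disc_floor_at_ref`` the outcome
    term is floored at the reference (outcomes below it do not reduce the
    odds); the default logistic is linear in ``y`` throughout.
    Discontinuation is absorbing.  In the active arm under the alternative,
    the subject's mean trajectory follows the control slope from the
    discontinuation visit onward.  With probability ``dropout_prob_at_disc``
    all outcomes after the discontinuation visit are missing.
    """

    n_per_arm: int = 100
    visit_months: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0)
    hypothesis: str = "null"  # "null" | "alternative"
    baseline_mean: float = 50.0
    control_slope: float = 10.0  # points per year
    active_slope: float = 5.0  # points per year after the kink (alternative)
    active_kink_month: float = 4.0
    sd_intercept: float = 5.0
    sd_slope: float = 5.0  # per year
    cor_intercept_slope: float = 0.25
    sd_residual: float = 2.5
    disc_base_prob: tuple[float, float] = (0.015, 0.025)  # monthly (control, active)
    disc_interval_months: float = 2.0  # between-visit interval the hazard acts over
    disc_odds_factor: float = 1.5  # odds ratio per 10 points above reference
    disc_outcome_ref: float = 50.0
    disc_floor_at_ref: bool = False
    disc_draw_visits: tuple[int, ...] | None = None  # default: every visit
    dropout_prob_at_disc: float = 0.75

    def __post_init__(self) -> None:
        if self.hypothesis not in ("null", "alternative"):
            raise ValueError(f"hypothesis must be 'null' or 'alternative', got {self.hypothesis!r}")
        if not 0.0 <= self.dropout_prob_at_disc <= 1.0:
            raise ValueError("dropout_prob_at_disc must be in [0, 1]")
        for p in self.disc_base_prob:
            if not 0.0 <= p < 1.0:
                raise ValueError("disc_base_prob entries must be probabilities")
        if self.disc_draw_visits is None:
            self.disc_draw_visits = tuple(range(len(self.visit_months)))

    # -- derived quantities ------------------------------------------------

    @property
    def times(self) -> np.ndarray:
        """Visit times in years."""
        return np.asarray(self.visit_months, dtype=float) / 12.0

    @property
    def n_followup(self) -> int:
        """Number of post-baseline visits J."""
        return len(self.visit_months) - 1

    def mean_trajectory(self, arm: int) -> np.ndarray:
        """Pre-discontinuation mean outcome at each visit for arm 0/1."""
        t = self.times
        control = self.baseline_mean + self.control_slope * t
        if arm == 0 or self.hypothesis == "null":
            return control
        tk = self.active_kink_month / 12.0
        active = np.where(
            t <= tk,
            control,
            self.baseline_mean + self.control_slope * tk + self.active_slope * (t - tk),
        )
        return active

    def marginal_variance(self, t: float) -> float:
        """Marginal outcome variance at time ``t`` (years)."""
        return (
            self.sd_intercept**2
            + 2.0 * self.cor_intercept_slope * self.sd_intercept * self.sd_slope * t
            + (self.sd_slope * t) ** 2
            + self.sd_residual**2
        )

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        for key, value in d.items():
            if isinstance(value, tuple):
                d[key] = list(value)  # JSON/YAML friendly
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationScenario":
        d = dict(d)
        for key in ("visit_months", "disc_base_prob", "disc_draw_visits"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "SimulationScenario":
        """Load a scenario from a YAML or JSON file."""
        text = open(path).read()
        try:
            d = json.loads(text)
        except json.JSONDecodeError:
            import yaml

            d = yaml.safe_load(text)
        return cls.from_dict(d)


@dataclass
class OperatingCharacteristics:
    """Aggregate repeated-sampling summaries over simulated replicates."""

    mean_theta: float
    sd_theta: float
    mean_se: float
    rejection_rate: float
    rejection_rate_mcse: float
    n_sims: int
    n_nonconverged_dropped: int
    method: str = ""
    inference: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# raw simulation
# ---------------------------------------------------------------------------


def _simulate_raw(scenario: SimulationScenario, rng: np.random.Generator,
                  n_per_arm: int | None = None):
    """Vectorised draw of one trial; returns raw arrays.

    Returns (y, arm, disc_idx, dropout) where ``y`` is the (n, V) outcome
    matrix *including* post-discontinuation trajectory changes, ``disc_idx``
    the visit index of discontinuation (-1 if none) and ``dropout`` a bool
    flag for subjects whose post-discontinuation outcomes are missing.
    """
    sc = scenario
    n_arm = sc.n_per_arm if n_per_arm is None else n_per_arm
    n = 2 * n_arm
    t = sc.times
    V = len(t)
    arm = np.repeat(np.array([0, 1]), n_arm)

    means = np.vstack([sc.mean_trajectory(0), sc.mean_trajectory(1)])  # (2, V)

    z = rng.standard_normal((n, 2))
    b0 = sc.sd_intercept * z[:, 0]
    rho = sc.cor_intercept_slope
    b1 = sc.sd_slope * (rho * z[:, 0] + math.sqrt(1.0 - rho**2) * z[:, 1])
    resid = sc.sd_residual * rng.standard_normal((n, V))

    y = means[arm] + b0[:, None] + b1[:, None] * t[None, :] + resid

    # outcome-dependent absorbing discontinuation process
    logit_base = np.array(
        [_logit(1.0 - (1.0 - p) ** sc.disc_interval_months) for p in sc.disc_base_prob]
    )
    slope = math.log(sc.disc_odds_factor) / 10.0
    disc_idx = np.full(n, -1, dtype=np.int64)
    active_alt = (arm == 1) & (sc.hypothesis == "alternative")
    for j in sorted(sc.disc_draw_visits):
        at_risk = disc_idx < 0
        x = y[:, j] - sc.disc_outcome_ref
        if sc.disc_floor_at_ref:
            x = np.maximum(x, 0.0)
        eta = logit_base[arm] + slope * x
        p = 1.0 / (1.0 + np.exp(-eta))
        u = rng.random(n)
        new = at_risk & (u < p)
        disc_idx[new] = j
        # active arm switches to the control slope from the visit onward
        later = t > t[j]
        if sc.hypothesis == "alternative" and later.any():
            idx = np.flatnonzero(new & active_alt)
            if idx.size:
                post_mean = means[1, j] + sc.control_slope * (t[later] - t[j])
                y[np.ix_(idx, np.flatnonzero(later))] += post_mean - means[1, later]

    dropout = (disc_idx >= 0) & (rng.random(n) < sc.dropout_prob_at_disc)
    return y, arm, disc_idx, dropout


def simulate_trial(scenario: SimulationScenario, seed=None,
                   ice_strategy: str = "MAR") -> TrialDataset:
    """Simulate one trial and package it as a :class:`TrialDataset`.

    The modelled outcome is the change from baseline at the J follow-up
    visits; the baseline measurement enters as a covariate.  Discontinuers
    with at least one post-discontinuation follow-up get ``ice_visit`` set to
    the discontinuation visit (0 = before the first follow-up) and the given
    ``ice_strategy``; discontinuation at the final visit has no downstream
    visit and leaves the ICE fields unset.  With probability
    ``dropout_prob_at_disc`` all post-discontinuation outcomes are missing.
    """
    rng = np.random.default_rng(seed)
    sc = scenario
    y, arm, disc_idx, dropout = _simulate_raw(sc, rng)
    n = y.shape[0]
    J = sc.n_followup
    change = y[:, 1:] - y[:, [0]]
    observed = np.ones((n, J), dtype=bool)
    has_post = (disc_idx >= 0) & (disc_idx < J)
    rows_missing = dropout & has_post
    for i in np.flatnonzero(rows_missing):
        observed[i, disc_idx[i]:] = False  # follow-up k has visit index k+1

    subj = np.arange(1, n + 1)
    df = pd.DataFrame(
        {
            "subject_id": np.repeat(subj, J),
            "arm": np.repeat(np.where(arm == 1, "intervention", "control"), J),
            "visit": np.tile(np.arange(1, J + 1), n),
            "outcome": np.where(observed.ravel(), change.ravel(), np.nan),
            "baseline": np.repeat(y[:, 0], J),
            "ice_visit": np.repeat(np.where(has_post, disc_idx, -1), J).astype(float),
            "ice_strategy": np.repeat(
                np.where(has_post, ice_strategy, "MAR"), J
            ),
        }
    )
    df.loc[df["ice_visit"] < 0, "ice_visit"] = np.nan
    return TrialDataset(df)


def true_effect(scenario: SimulationScenario, n_large: int = 1_000_000,
                seed=None, return_arms: bool = False):
    """Treatment-policy estimand implied by the generative model.

    Simulates ``n_large`` subjects per arm, applies the discontinuation
    process and the post-discontinuation trajectory change but no missing
    data, and returns the active-minus-control difference in mean change
    from baseline at the final visit.  With ``return_arms`` the per-arm mean
    changes are also returned.
    """
    rng = np.random.default_rng(seed)
    total = np.zeros(2)
    count = np.zeros(2)
    chunk = 200_000
    done = 0
    while done < n_large:
        m = min(chunk, n_large - done)
        y, arm, _, _ = _simulate_raw(scenario, rng, n_per_arm=m)
        change = y[:, -1] - y[:, 0]
        for a in (0, 1):
            total[a] += change[arm == a].sum()
            count[a] += (arm == a).sum()
        done += m
    mean_change = total / count
    effect = mean_change[1] - mean_change[0]
    if return_arms:
        return effect, mean_change[0], mean_change[1]
    return effect


def discontinuation_rates(scenario: SimulationScenario, n_large: int = 100_000,
                          seed=None) -> tuple[float, float]:
    """Empirical probability of ever discontinuing study drug, per arm."""
    rng = np.random.default_rng(seed)
    disc = np.zeros(2)
    count = np.zeros(2)
    chunk = 200_000
    done = 0
    while done < n_large:
        m = min(chunk, n_large - done)
        _, arm, disc_idx, _ = _simulate_raw(scenario, rng, n_per_arm=m)
        for a in (0, 1):
            disc[a] += (disc_idx[arm == a] >= 0).sum()
            count[a] += (arm == a).sum()
        done += m
    return disc[0] / count[0], disc[1] / count[1]


# ---------------------------------------------------------------------------
# operating-characteristics harness
# ---------------------------------------------------------------------------


def run_point_estimates(
    scenario: SimulationScenario,
    methods: Sequence[str] = ("MAR", "CR", "J2R", "CIR"),
    n_sims: int = 100,
    seed=None,
) -> pd.DataFrame:
    """Per-replicate point estimates for several imputation methods at once.

    The imputation-model fit is shared across methods within a replicate
    (the post-ICE masking is method-independent), so this is the efficient
    way to tabulate mean/SD of the point estimator per method.  Replicates
    with a non-convergent fit are dropped for all methods.
    """
    from .estimation import CmiEstimator
    from .mmrm import ConvergenceError

    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rows = []
    for rs in ss.spawn(n_sims):
        data = simulate_trial(scenario, seed=rs, ice_strategy="MAR")
        engine = CmiEstimator(method=None, drop_post_ice=True)._engine(data)
        try:
            res, _ = engine.estimate_multi(methods)
        except ConvergenceError:
            continue
        rows.append({m: res[m].theta_hat for m in methods})
    return pd.DataFrame(rows)


def run_operating_characteristics(
    scenario: SimulationScenario,
    method: str = "MAR",
    inference: str | None = None,
    n_sims: int = 100,
    seed=None,
    alpha: float = 0.05,
    B: int = 999,
    n_jobs: int = 1,
    return_replicates: bool = False,
):
    """Monte-Carlo operating characteristics of the CMI pipeline.

    Per replicate: simulate a trial, exclude observed post-discontinuation
    data from the imputation model (but keep it in the analysis), estimate
    the treatment effect at the final visit by conditional mean imputation
    under ``method``, and optionally compute a jackknife or bootstrap
    standard error with a two-sided Wald test at level ``alpha``.
    Replicates whose imputation model fails to converge are dropped and
    counted.  With ``inference=None`` only point estimates are collected
    (sd_theta is still reported; mean_se and rejection_rate are NaN).
    """
    from .estimation import CmiEstimator
    from .mmrm import ConvergenceError

    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rep_seeds = ss.spawn(n_sims)

    def one(rs):
        data = simulate_trial(scenario, seed=rs, ice_strategy=method)
        est = CmiEstimator(
            method=method,
            inference=inference,
            alpha=alpha,
            B=B,
            drop_post_ice=True,
            seed=rs.spawn(1)[0] if inference == "bootstrap" else None,
        )
        try:
            est.fit(data)
        except ConvergenceError:
            return None
        if inference is None:
            return (est.theta_, np.nan, np.nan)
        return (est.theta_, est.se_, est.pvalue_)

    if n_jobs != 1:
        from joblib import Parallel, delayed

        rows = Parallel(n_jobs=n_jobs)(delayed(one)(rs) for rs in rep_seeds)
    else:
        rows = [one(rs) for rs in rep_seeds]

    dropped = sum(r is None for r in rows)
    arr = np.array([r for r in rows if r is not None], dtype=float)
    theta, se, pval = arr[:, 0], arr[:, 1], arr[:, 2]
    m = len(theta)
    if inference is None:
        rej, mean_se = np.nan, np.nan
    else:
        rej = float(np.mean(pval < alpha))
        mean_se = float(np.mean(se))
    oc = OperatingCharacteristics(
        mean_theta=float(np.mean(theta)),
        sd_theta=float(np.std(theta, ddof=1)) if m > 1 else float("nan"),
        mean_se=mean_se,
        rejection_rate=rej,
        rejection_rate_mcse=float(np.sqrt(rej * (1 - rej) / m)) if np.isfinite(rej) else float("nan"),
        n_sims=m,
        n_nonconverged_dropped=dropped,
        method=method,
        inference=inference or "none",
    )
    if return_replicates:
        rep = pd.DataFrame({"theta": theta, "se": se, "p": pval})
        return oc, rep
    return oc
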