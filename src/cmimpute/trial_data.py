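"""Long-format trial data with intercurrent-event annotations.

A :class:`TrialDataset` holds one row per subject and scheduled follow-up
visit (1..J) with a continuous outcome that may be missing, a baseline
outcome and optional extra covariates, plus per-subject intercurrent-event
(ICE) information: the visit after which the ICE occurred and the imputation
strategy chosen for post-ICE missing data (MAR or one of the reference-based
strategies CR / J2R / CIR).

:func:`build_model_frame` turns a dataset into the numeric arrays consumed
by model fitting and imputation: per-subject design matrices for the
subject's own arm and for the counterfactual assignment to control, the
outcome matrix, and the two masks that distinguish "observed" (available to
the analysis) from "used for fitting" (observed and not removed as
incompatible post-ICE data).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TrialDataset",
    "ModelFrame",
    "read_trial_csv",
    "write_trial_csv",
    "build_model_frame",
    "ValidationError",
    "REFERENCE_METHODS",
    "METHODS",
    "DEFAULT_FORMULA",
]

REFERENCE_METHODS = ("CR", "J2R", "CIR")
METHODS = ("MAR",) + REFERENCE_METHODS

#: treatment group, categorical visit, treatment-by-visit interaction and
#: baseline with baseline-by-visit interaction -- the default mean model.
DEFAULT_FORMULA = "arm * C(visit) + baseline + baseline:C(visit)"

REQUIRED_COLUMNS = (
    "subject_id",
    "arm",
    "visit",
    "outcome",
    "baseline",
    "ice_visit",
    "ice_strategy",
)

ARMS = ("control", "intervention")


class ValidationError(ValueError):
    """Raised when input data violate the trial-data contract."""


class TrialDataset:
    """Validated long-format longitudinal trial data.

    Parameters
    ----------
    df : DataFrame
        One row per subject-visit with columns ``subject_id``, ``arm``
        (``control`` / ``intervention``), ``visit`` (1..J), ``outcome``
        (NaN for missing), ``baseline``, ``ice_visit`` (NaN for no ICE; 0
        means the ICE occurred before the first follow-up), ``ice_strategy``
        and any extra covariate columns.  Missing outcomes must be explicit
        rows, never absent rows.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        df = df.copy()
        missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing_cols:
            raise ValidationError(f"missing required columns: {missing_cols}")
        df["visit"] = df["visit"].astype(int)
        df["outcome"] = pd.to_numeric(df["outcome"], errors="coerce")
        df["ice_visit"] = pd.to_numeric(df["ice_visit"], errors="coerce")
        strat = df["ice_strategy"].astype("string").str.upper()
        strat = strat.fillna("MAR").replace("", "MAR")
        df["ice_strategy"] = strat
        # stable ordering: subjects in first-appearance order, visits ascending
        order = {s: k for k, s in enumerate(df["subject_id"].drop_duplicates())}
        df = df.sort_values(
            ["subject_id", "visit"],
            key=lambda s: s.map(order) if s.name == "subject_id" else s,
            kind="stable",
        ).reset_index(drop=True)
        self.df = df
        self.covariates = [c for c in df.columns if c not in REQUIRED_COLUMNS]
        if validate:
            self._validate()

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        df = self.df
        J = int(df["visit"].max())
        if df["visit"].min() < 1:
            raise ValidationError("visits must be numbered 1..J")
        bad_arm = set(df["arm"].unique()) - set(ARMS)
        if bad_arm:
            raise ValidationError(f"unknown arm labels {sorted(bad_arm)}; expected {ARMS}")
        counts = df.groupby("subject_id", sort=False)["visit"].agg(["size", "nunique"])
        dup = counts[counts["size"] != counts["nunique"]]
        if len(dup):
            raise ValidationError(f"duplicate subject-visit rows for subjects {list(dup.index)}")
        incomplete = counts[counts["size"] != J]
        if len(incomplete):
            missing = []
            for sid in incomplete.index:
                have = set(df.loc[df["subject_id"] == sid, "visit"])
                for v in range(1, J + 1):
                    if v not in have:
                        missing.append(f"{sid}, visit {v}")
            raise ValidationError("missing scheduled-visit rows: " + "; ".join(missing))
        for col in ["baseline"] + self.covariates:
            bad = df[df[col].isna()]
            if len(bad):
                where = [f"{r.subject_id}, visit {r.visit}" for r in bad.itertuples()][:5]
                raise ValidationError(
                    f"missing covariate values are not allowed: column {col!r} at " + "; ".join(where)
                )
        per = df.groupby("subject_id", sort=False)
        for col in ("arm", "ice_strategy"):
            if (per[col].nunique() > 1).any():
                raise ValidationError(f"column {col!r} must be constant within subject")
        if (per["ice_visit"].nunique(dropna=False) > 1).any():
            raise ValidationError("column 'ice_visit' must be constant within subject")
        sub = self.subjects
        bad_strat = set(sub["ice_strategy"]) - set(METHODS)
        if bad_strat:
            raise ValidationError(f"unknown ice_strategy values {sorted(bad_strat)}")
        tv = sub["ice_visit"]
        if ((tv.dropna() % 1) != 0).any():
            raise ValidationError("ice_visit must be an integer visit index")
        if (tv >= J).any():
            off = sub.loc[tv >= J, "subject_id"].tolist()
            raise ValidationError(
                f"ice_visit must be < J={J} (the ICE visit needs a later scheduled visit); "
                f"violating subjects: {off}"
            )
        if (tv < 0).any():
            raise ValidationError("ice_visit must be >= 0")
        ref = sub["ice_strategy"].isin(REFERENCE_METHODS)
        if (ref & tv.isna()).any():
            off = sub.loc[ref & tv.isna(), "subject_id"].tolist()
            raise ValidationError(
                f"reference-based ice_strategy requires ice_visit; missing for subjects: {off}"
            )

    # -- accessors ---------------------------------------------------------

    @property
    def n_visits(self) -> int:
        """Number of scheduled follow-up visits J."""
        return int(self.df["visit"].max())

    @property
    def subject_ids(self) -> np.ndarray:
        return self.df["subject_id"].to_numpy()[:: self.n_visits]

    @property
    def n_subjects(self) -> int:
        return len(self.df) // self.n_visits

    @property
    def subjects(self) -> pd.DataFrame:
        """One row per subject with subject-level fields (visit-1 values)."""
        return self.df.iloc[:: self.n_visits].reset_index(drop=True)

    def outcome_matrix(self) -> np.ndarray:
        """(n, J) outcome matrix with NaN for missing values."""
        return self.df["outcome"].to_numpy(dtype=float).reshape(self.n_subjects, self.n_visits)

    def copy(self) -> "TrialDataset":
        return TrialDataset(self.df.copy(), validate=False)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<TrialDataset n={self.n_subjects} J={self.n_visits} "
            f"missing={int(self.df['outcome'].isna().sum())}>"
        )


def read_trial_csv(path, schema: dict | None = None) -> TrialDataset:
    """Read and validate a long-format trial CSV.

    ``schema`` maps the canonical column names (``subject_id``, ``arm``, ...)
    to the names used in the file.  Empty fields and the usual NA spellings
    are normalised to a single missing marker.
    """
    df = pd.read_csv(path, na_values=["NA", "NaN", ""], keep_default_na=True)
    if schema:
        unknown = [v for v in schema.values() if v not in df.columns]
        if unknown:
            raise ValidationError(f"schema refers to columns absent from the file: {unknown}")
        df = df.rename(columns={v: k for k, v in schema.items()})
    return TrialDataset(df)


def write_trial_csv(data: TrialDataset, path) -> None:
    """Write a dataset back to CSV (inverse of :func:`read_trial_csv`)."""
    data.df.to_csv(path, index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# model frame
# ---------------------------------------------------------------------------


@dataclass
class ModelFrame:
    """Numeric arrays for fitting, imputation and analysis.

    ``X`` and ``X_ref`` are (n, J, p) stacked per-subject design matrices for
    the subject's actual arm and for the counterfactual control assignment.
    ``Y`` holds every originally observed outcome (NaN where missing);
    ``obs_mask`` marks those entries and is what the analysis step sees,
    while ``fit_mask`` additionally removes observed post-ICE values that
    are incompatible with the imputation model.
    """

    X: np.ndarray
    X_ref: np.ndarray
    Y: np.ndarray
    obs_mask: np.ndarray
    fit_mask: np.ndarray
    arm: np.ndarray  # 0 control / 1 intervention
    ice_visit: np.ndarray  # -1 if none
    strategy: np.ndarray  # per-subject method labels
    subject_ids: np.ndarray
    column_names: list[str] = field(default_factory=list)
    formula: str = ""

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_visits(self) -> int:
        return self.X.shape[1]

    @property
    def n_params(self) -> int:
        return self.X.shape[2]

    def subset(self, idx) -> "ModelFrame":
        """Row-subset (or resample, indices may repeat) of the frame."""
        idx = np.asarray(idx)
        return ModelFrame(
            X=self.X[idx],
            X_ref=self.X_ref[idx],
            Y=self.Y[idx],
            obs_mask=self.obs_mask[idx],
            fit_mask=self.fit_mask[idx],
            arm=self.arm[idx],
            ice_visit=self.ice_visit[idx],
            strategy=self.strategy[idx],
            subject_ids=self.subject_ids[idx],
            column_names=self.column_names,
            formula=self.formula,
        )


def build_model_frame(
    data: TrialDataset,
    formula: str = DEFAULT_FORMULA,
    drop_post_ice_control: bool = True,
) -> ModelFrame:
    """Construct design matrices and fitting/analysis masks.

    The mean-model ``formula`` (right-hand side, patsy syntax) must include
    at minimum the treatment group, the categorical visit and their
    interaction.  Observed outcomes after the ICE visit are always removed
    from the fitting data for intervention-arm subjects with a
    reference-based strategy; for all other subjects with an ICE (control
    arm, or MAR strategy in either arm) they are removed iff
    ``drop_post_ice_control``.  Removed values remain in ``Y`` / ``obs_mask``
    and are used as observed data by the imputation and analysis steps.
    """
    import patsy

    df = data.df.copy()
    df["arm"] = pd.Categorical(df["arm"], categories=list(ARMS))
    for name in ("arm", "visit"):
        if name not in formula:
            raise ValidationError(
                f"imputation-model formula must include treatment group, visit and "
                f"their interaction; {name!r} not found in {formula!r}"
            )
    try:
        dm = patsy.dmatrix(formula, df, return_type="dataframe", NA_action="raise")
    except patsy.PatsyError as e:
        raise ValidationError(f"invalid model formula {formula!r}: {e}") from None
    design_info = dm.design_info
    n, J = data.n_subjects, data.n_visits
    p = dm.shape[1]
    X = dm.to_numpy().reshape(n, J, p)

    df_ref = df.copy()
    df_ref["arm"] = pd.Categorical(["control"] * len(df_ref), categories=list(ARMS))
    (dm_ref,) = patsy.build_design_matrices([design_info], df_ref)
    X_ref = np.asarray(dm_ref).reshape(n, J, p)

    Y = data.outcome_matrix()
    obs_mask = ~np.isnan(Y)

    sub = data.subjects
    arm = (sub["arm"].to_numpy() == "intervention").astype(np.int64)
    tv = sub["ice_visit"].to_numpy(dtype=float)
    ice_visit = np.where(np.isnan(tv), -1, tv).astype(np.int64)
    strategy = sub["ice_strategy"].to_numpy(dtype=object)

    fit_mask = obs_mask.copy()
    visits = np.arange(1, J + 1)
    is_ref = np.isin(strategy.astype(str), REFERENCE_METHODS) & (arm == 1)
    has_ice = ice_visit >= 0
    always = is_ref & has_ice
    optional = has_ice & ~always
    post = visits[None, :] > ice_visit[:, None]
    fit_mask[always] &= ~post[always]
    if drop_post_ice_control:
        fit_mask[optional] &= ~post[optional]

    return ModelFrame(
        X=X,
        X_ref=X_ref,
        Y=Y,
        obs_mask=obs_mask,
        fit_mask=fit_mask,
        arm=arm,
        ice_visit=ice_visit,
        strategy=strategy,
        subject_ids=data.subject_ids.copy(),
        column_names=list(design_info.column_names),
        formula=formula,
    )
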