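"""Cluster-robust inference for the four pharmacogenetic outcomes.

Binary early-nonpersistence records are analysed with population-averaged
logistic regression (GEE, exchangeable working correlation, sandwich
standard errors clustered on person).  Survival outcomes (discontinuation,
switch, mania) use Cox proportional-hazards regression with robust standard
errors clustered on person and Efron tie handling — registry dates are
day-resolved, so ties are common.

Exposure codings
----------------
* ``categorical6`` — the six metabolic phenotypes with EM (normal) as the
  reference category;
* ``collapsed3`` — PM/IM/IM+ vs EM vs EM+/UM, used when events are sparse;
* ``activity_score`` — the inverted activity score (UM=1 … PM=6) as a single
  continuous trend term, so HR > 1 means slower metabolism increases hazard;
* ``cyp2c_rank`` — the expanded 10-level CYP2C diplotype rank as a trend;
* ``cyp2c_collapse3`` — the expanded scheme collapsed to lower-exposure /
  reference / higher-exposure groups.

A nested Wald test compares models with and without a monotherapy ×
exposure interaction block, using the robust covariance of the full model.

The module also provides the Schoenfeld events formula for two-group Cox
sample-size planning, and Kaplan–Meier median follow-up times.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter

from .phenotypes import PHENOTYPE_LEVELS

__all__ = [
    "ModelSpec",
    "ModelResult",
    "build_design",
    "fit_gee_logistic",
    "fit_cox_clustered",
    "trend_cox",
    "fit_model",
    "wald_interaction_test",
    "km_median",
    "schoenfeld_events",
    "cox_sample_size",
]


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one analysis cell."""
    outcome: str = "mania"
    coding: str = "categorical6"
    covariates: tuple[str, ...] = ("sex", "wave", "age_at_start")
    adjust_mood_stabilizer: bool = False
    interaction_monotherapy: bool = False
    reference: str = "EM"
    cluster: str = "person_id"
    drug_group: str | None = None
    variant: str = "main"

    def label(self) -> str:
        bits = [self.outcome, self.coding, self.variant]
        if self.drug_group:
            bits.insert(0, self.drug_group)
        if self.interaction_monotherapy:
            bits.append("x-monotherapy")
        return "/".join(bits)


@dataclass
class ModelResult:
    """Fitted estimates on the ratio scale plus the robust covariance."""
    scale: str                  # "OR" or "HR"
    summary: pd.DataFrame       # term-indexed: estimate, se, ci_low, ci_high, p
    params: pd.Series           # log scale, term-indexed
    cov: pd.DataFrame           # robust covariance of params
    n: int
    n_persons: int
    n_events: int
    converged: bool = True
    notes: tuple[str, ...] = ()
    spec: ModelSpec | None = None


_CATEGORICAL = {
    "categorical6": ("phenotype", tuple(PHENOTYPE_LEVELS)),
    "collapsed3": ("phenotype3", ("PM/IM/IM+", "EM", "EM+/UM")),
    "cyp2c_collapse3": ("cyp2c_collapse3",
                        ("lower-exposure", "reference", "higher-exposure")),
}
_CONTINUOUS = {"activity_score": "activity_score", "cyp2c_rank": "cyp2c_rank"}
_CAT_REFERENCE = {"categorical6": "EM", "collapsed3": "EM",
                  "cyp2c_collapse3": "reference"}


def _exposure_columns(records: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    if spec.coding in _CONTINUOUS:
        col = _CONTINUOUS[spec.coding]
        x = records[col].astype(float)
        if x.nunique() < 2:
            raise ValueError(f"no variation in exposure {col!r}; trend is undefined")
        return x.to_frame(col)
    if spec.coding in _CATEGORICAL:
        col, levels = _CATEGORICAL[spec.coding]
        ref = spec.reference if spec.coding == "categorical6" else _CAT_REFERENCE[spec.coding]
        present = [lv for lv in levels if (records[col] == lv).any()]
        if ref not in present:
            raise ValueError(f"reference level {ref!r} absent from {col!r}")
        X = pd.DataFrame(index=records.index)
        for lv in present:
            if lv != ref:
                X[f"{col}[{lv}]"] = (records[col] == lv).astype(float)
        return X
    raise ValueError(f"unknown exposure coding {spec.coding!r}")


def build_design(records: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, list[str]]:
    """Design matrix (no intercept column) and the exposure column names."""
    X = _exposure_columns(records, spec)
    exposure_terms = list(X.columns)
    for cov in spec.covariates:
        if cov == "sex":
            X["sex[female]"] = (records["sex"] == "female").astype(float)
        elif cov == "wave":
            for w in sorted(records["wave"].unique()):
                if w != records["wave"].min():
                    X[f"wave[{w}]"] = (records["wave"] == w).astype(float)
        else:
            X[cov] = records[cov].astype(float)
    if spec.adjust_mood_stabilizer:
        X["mood_stabilizer_flag"] = records["mood_stabilizer_flag"].astype(float)
    if spec.interaction_monotherapy:
        mono = records["monotherapy_flag"].astype(float)
        X["monotherapy_flag"] = mono
        for term in exposure_terms:
            X[f"monotherapy:{term}"] = mono * X[term]
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant design column(s) {constant}; "
                         "the coefficient is not identifiable")
    return X, exposure_terms


def _drop_empty_wave(records: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, ModelSpec, list[str]]:
    """Drop the wave covariate when some wave has no events (inestimable)."""
    notes: list[str] = []
    if "wave" in spec.covariates and "event" in records:
        by_wave = records.groupby("wave")["event"].sum()
        if (by_wave == 0).any():
            empty = by_wave.index[by_wave == 0].tolist()
            notes.append(f"wave covariate dropped: no events in wave(s) {empty}")
            warnings.warn(notes[-1], stacklevel=3)
            spec = replace(spec, covariates=tuple(c for c in spec.covariates if c != "wave"))
    return records, spec, notes


def _required_columns(spec: ModelSpec) -> list[str]:
    cols = ["event", spec.cluster]
    if spec.coding in _CONTINUOUS:
        cols.append(_CONTINUOUS[spec.coding])
    else:
        cols.append(_CATEGORICAL[spec.coding][0])
    cols += [c for c in spec.covariates if c != "wave"] + \
            (["wave"] if "wave" in spec.covariates else [])
    if spec.adjust_mood_stabilizer:
        cols.append("mood_stabilizer_flag")
    if spec.interaction_monotherapy:
        cols.append("monotherapy_flag")
    return cols


def _summarise(params: pd.Series, cov: pd.DataFrame, scale: str) -> pd.DataFrame:
    se = pd.Series(np.sqrt(np.diag(cov.to_numpy())), index=params.index)
    z = params / se
    p = 2 * stats.norm.sf(np.abs(z))
    with np.errstate(over="ignore"):  # a degenerate cell may have an inf CI bound
        return pd.DataFrame({
            "estimate": np.exp(params),
            "se": se,
            "ci_low": np.exp(params - 1.959963984540054 * se),
            "ci_high": np.exp(params + 1.959963984540054 * se),
            "p": p,
        }, index=params.index)


class _BoundedExchangeable(sm.cov_struct.Exchangeable):
    """Exchangeable working correlation constrained to [0, 0.95].

    The moment estimate of the common correlation can drift negative; below
    −1/(k−1) the working covariance of a size-k cluster is no longer positive
    definite and the IRLS update diverges.  Clipping keeps the fit stable;
    the sandwich covariance remains valid under a misspecified working
    structure, which is the point of GEE.
    """

    def update(self, params):
        super().update(params)
        self.dep_params = float(np.clip(self.dep_params, 0.0, 0.95))


def fit_gee_logistic(records: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """Population-averaged logistic regression via GEE.

    Exchangeable working correlation over each person's records; sandwich
    (robust) covariance.  Raises on outcomes without both classes and flags
    apparent separation (diverging coefficients) as an error.
    """
    df = records.dropna(subset=_required_columns(spec)).reset_index(drop=True)
    if df["event"].nunique() < 2:
        raise ValueError("binary outcome requires at least one event and one non-event")
    df, spec, notes = _drop_empty_wave(df, spec)
    X, _ = build_design(df, spec)
    exog = sm.add_constant(X, has_constant="add")
    model = sm.GEE(df["event"].astype(float), exog, groups=df[spec.cluster],
                   family=sm.families.Binomial(),
                   cov_struct=_BoundedExchangeable())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=200)
    params = pd.Series(res.params, index=exog.columns)
    if not np.isfinite(params).all():
        raise ValueError("GEE estimation failed to converge (non-finite coefficients)")
    if params.abs().max() > 15:
        raise ValueError("apparent separation: diverging GEE coefficients")
    cov = pd.DataFrame(res.cov_params(), index=exog.columns, columns=exog.columns)
    return ModelResult(
        scale="OR",
        summary=_summarise(params.drop("const"), cov.drop("const").drop(columns="const"), "OR"),
        params=params, cov=cov,
        n=len(df), n_persons=df[spec.cluster].nunique(),
        n_events=int(df["event"].sum()),
        converged=bool(getattr(res, "converged", True)),
        notes=tuple(notes), spec=spec,
    )


def fit_cox_clustered(records: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """Cox regression with robust (cluster) standard errors and Efron ties."""
    needed = _required_columns(spec) + ["time_days"]
    df = records.dropna(subset=[c for c in needed if c in records.columns])
    df = df.reset_index(drop=True)
    if int(df["event"].sum()) == 0:
        raise ValueError("no events; the Cox partial likelihood is undefined")
    df, spec, notes = _drop_empty_wave(df, spec)
    X, _ = build_design(df, spec)
    fit_df = X.copy()
    fit_df["time_days"] = df["time_days"].astype(float)
    fit_df["event"] = df["event"].astype(int)
    fit_df["_cluster"] = df[spec.cluster].to_numpy()

    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(fit_df, duration_col="time_days", event_col="event",
                cluster_col="_cluster", robust=True, show_progress=False)
    params = cph.params_.copy()
    cov = cph.variance_matrix_.copy()
    if not (np.isfinite(params).all() and np.isfinite(cov.to_numpy()).all()):
        raise ValueError("Cox estimation failed to converge (non-finite estimates)")
    return ModelResult(
        scale="HR",
        summary=_summarise(params, cov, "HR"),
        params=params, cov=cov,
        n=len(df), n_persons=df[spec.cluster].nunique(),
        n_events=int(df["event"].sum()),
        converged=True, notes=tuple(notes), spec=spec,
    )


def trend_cox(records: pd.DataFrame, spec: ModelSpec | None = None) -> ModelResult:
    """Cox trend model on the continuous activity score (one HR per step)."""
    if spec is None:
        spec = ModelSpec(coding="activity_score")
    elif spec.coding not in _CONTINUOUS:
        spec = replace(spec, coding="activity_score")
    return fit_cox_clustered(records, spec)


def fit_model(records: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """Dispatch: GEE for the binary nonpersistence outcome, Cox otherwise."""
    if spec.outcome == "nonpersistence":
        return fit_gee_logistic(records, spec)
    return fit_cox_clustered(records, spec)


def wald_interaction_test(full: ModelResult, reduced: ModelResult) -> float:
    """Joint Wald chi-square p-value for the terms present only in ``full``.

    Uses the full model's robust covariance; degrees of freedom equal the
    number of extra terms.  Identical term sets yield p = 1 (nothing to
    test); non-nested models are an error.
    """
    full_terms = list(full.params.index)
    red_terms = set(reduced.params.index)
    if not red_terms <= set(full_terms):
        raise ValueError("models are not nested: reduced has terms absent from full")
    block = [t for t in full_terms if t not in red_terms]
    if not block:
        return 1.0
    b = full.params[block].to_numpy()
    V = full.cov.loc[block, block].to_numpy()
    stat = float(b @ np.linalg.solve(V, b))
    return float(stats.chi2.sf(stat, df=len(block)))


def km_median(durations, events=None) -> float | None:
    """Kaplan–Meier median time-to-event in days (None if never reached)."""
    durations = np.asarray(durations, dtype=float)
    if events is None:
        events = np.ones_like(durations)
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=np.asarray(events, dtype=int))
    med = kmf.median_survival_time_
    return None if np.isinf(med) else float(med)


def schoenfeld_events(hazard_ratio: float, exposed_proportion: float,
                      power: float = 0.8, alpha: float = 0.05) -> float:
    """Schoenfeld's required number of events for a two-group Cox comparison.

    E = (z_{1-α/2} + z_{power})² / (p (1-p) (ln HR)²), where p is the exposed
    proportion.  Symmetric in p ↔ 1-p and decreasing in |ln HR|.
    """
    if hazard_ratio <= 0:
        raise ValueError("hazard ratio must be positive")
    if hazard_ratio == 1:
        raise ValueError("hazard ratio 1 implies no effect: infinite sample size")
    if not 0 < exposed_proportion < 1:
        raise ValueError("exposed proportion must be in (0, 1)")
    if not 0 < power < 1 or not 0 < alpha < 1:
        raise ValueError("power and alpha must be in (0, 1)")
    z = stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)
    p = exposed_proportion
    return z * z / (p * (1 - p) * np.log(hazard_ratio) ** 2)


def cox_sample_size(hazard_ratio: float, exposed_proportion: float,
                    event_rate: float, power: float = 0.8,
                    alpha: float = 0.05) -> int:
    """Total sample size for a two-group Cox comparison (Schoenfeld formula).

    The required event count is inflated by the overall event rate:
    n = ceil(E / event_rate).
    """
    if not 0 < event_rate <= 1:
        raise ValueError("event rate must be in (0, 1]")
    e = schoenfeld_events(hazard_ratio, exposed_proportion, power, alpha)
    return int(np.ceil(e / event_rate))
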