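"""The five regression models of the economic evaluation.

Every model uses the same baseline covariate set — arm, mean-adjusted age,
sex, number of ulcers, ulcer area and ulcer duration — so that corrected
group prognosis (CGP) standardisation and probabilistic sensitivity
analysis can operate on a common design:

* survival: lognormal accelerated-failure-time model (family chosen by
  AIC among exponential, Weibull, lognormal and log-logistic);
* EQ-5D utility: linear mixed model with a patient random intercept and
  categorical visit-week effects interacting with arm;
* other NHS cost per inter-visit period: the same mixed-model structure;
* hospitalisation: proportional-odds ordinal logit on the 4-level scale
  none < other admission < minor amputation/revascularisation < major
  amputation, per follow-up period;
* antibiotic prescription: plain logistic regression per period (random
  effects deliberately omitted).

Design matrices are built by explicit column construction (no formula
layer), so a `ModelFit` is fully described by its named coefficient vector
and variance-covariance matrix and can be serialised to JSON and re-used
for prediction and PSA without refitting.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import lifelines
import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel

COVARIATE_COLS = [
    "arm",
    "mean_adjusted_age",
    "sex_male",
    "n_ulcers",
    "ulcer_area",
    "ulcer_duration",
]

HOSP_CATEGORIES = ["none", "other", "minor_amp_or_revasc", "major_amp"]

_AFT_FITTERS = {
    "weibull": lifelines.WeibullAFTFitter,
    "lognormal": lifelines.LogNormalAFTFitter,
    "loglogistic": lifelines.LogLogisticAFTFitter,
}


class ConvergenceError(RuntimeError):
    pass


def make_covariates(
    patients: pd.DataFrame, age_center: float | None = None
) -> tuple[pd.DataFrame, float]:
    """Common covariate design from a baseline table.

    Expects columns arm ('swab'/'tissue' or 0/1), age, sex ('male'/'female'
    or 0/1), n_ulcers, ulcer_area, ulcer_duration. Age is centred at the
    sample mean (or a supplied constant, e.g. when predicting from a stored
    fit). Returns the design indexed by patient_id and the centring constant.
    """
    df = patients.set_index("patient_id") if "patient_id" in patients.columns else patients
    arm = df["arm"]
    if arm.dtype == object:
        arm = arm.map({"swab": 0, "tissue": 1})
        if arm.isna().any():
            raise ValueError("arm must be 'swab' or 'tissue'")
    sex = df["sex"]
    if sex.dtype == object:
        sex = sex.map({"female": 0, "male": 1})
        if sex.isna().any():
            raise ValueError("sex must be 'male' or 'female'")
    if age_center is None:
        age_center = float(df["age"].mean())
    X = pd.DataFrame(
        {
            "arm": arm.astype(float),
            "mean_adjusted_age": df["age"].astype(float) - age_center,
            "sex_male": sex.astype(float),
            "n_ulcers": df["n_ulcers"].astype(float),
            "ulcer_area": df["ulcer_area"].astype(float),
            "ulcer_duration": df["ulcer_duration"].astype(float),
        },
        index=df.index,
    )
    return X, age_center


def longitudinal_design(
    X_rows: pd.DataFrame, weeks: np.ndarray, visit_weeks: list[int]
) -> pd.DataFrame:
    """Fixed-effects design for the mixed models.

    One row per observation: intercept, baseline covariates, visit-week
    dummies (reference = first visit) and arm-by-week interactions, so a
    per-week arm contrast exists at every follow-up visit.
    """
    weeks = np.asarray(weeks)
    out = pd.DataFrame(index=X_rows.index)
    out["const"] = 1.0
    for c in COVARIATE_COLS:
        out[c] = X_rows[c].to_numpy()
    for w in visit_weeks[1:]:
        dummy = (weeks == w).astype(float)
        out[f"week_{w}"] = dummy
        out[f"arm_x_week_{w}"] = dummy * X_rows["arm"].to_numpy()
    return out


@dataclass
class ModelFit:
    """One fitted regression: named coefficients, vcov and fit metadata.

    ``params`` and ``vcov`` cover every parameter sampled in PSA; scale
    parameters kept on an unconstrained scale (e.g. the AFT log-sigma) are
    noted in ``extras`` so draws remain in the valid region.
    """

    family: str  # lognormal_aft | weibull_aft | loglogistic_aft | exponential_aft
    #              | linear_mixed | ordinal_logit | logit
    params: pd.Series
    vcov: pd.DataFrame
    n_obs: int
    loglik: float
    aic: float
    bic: float
    age_center: float
    covariate_cols: list[str] = field(default_factory=lambda: list(COVARIATE_COLS))
    extras: dict = field(default_factory=dict)
    re_estimates: pd.Series | None = None

    def __post_init__(self) -> None:
        v = self.vcov.to_numpy()
        scale = max(1.0, float(np.abs(v).max()))
        if np.abs(v - v.T).max() > 1e-6 * scale:
            raise ValueError("vcov must be symmetric")
        if np.abs(v - v.T).max() > 0:  # symmetrise numerical noise
            v = (v + v.T) / 2.0
            self.vcov = pd.DataFrame(v, index=self.vcov.index, columns=self.vcov.columns)
        if np.linalg.eigvalsh(v).min() < -1e-8 * scale:
            raise ValueError(
                "vcov not positive semi-definite; consider projecting to the "
                "nearest PSD matrix before use"
            )
        if self.family == "ordinal_logit":
            th = ordinal_thresholds(self)
            if not np.all(np.diff(th) > 0):
                raise ValueError("ordinal thresholds must be strictly increasing")
        if self.family.endswith("_aft") and "log_scale_param" in self.extras:
            if not np.isfinite(self.params[self.extras["log_scale_param"]]):
                raise ValueError("AFT scale parameter not finite")

    @property
    def n_params(self) -> int:
        return len(self.params)

    def to_json(self) -> str:
        payload = {
            "family": self.family,
            "params": {k: float(v) for k, v in self.params.items()},
            "param_order": list(self.params.index),
            "vcov": self.vcov.to_numpy().tolist(),
            "n_obs": self.n_obs,
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "age_center": self.age_center,
            "covariate_cols": self.covariate_cols,
            "extras": _jsonable(self.extras),
            "re_estimates": (
                None
                if self.re_estimates is None
                else {str(k): float(v) for k, v in self.re_estimates.items()}
            ),
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ModelFit":
        d = json.loads(text)
        order = d["param_order"]
        params = pd.Series({k: d["params"][k] for k in order}, name="coef")
        vcov = pd.DataFrame(np.array(d["vcov"]), index=order, columns=order)
        re = d.get("re_estimates")
        return cls(
            family=d["family"],
            params=params,
            vcov=vcov,
            n_obs=d["n_obs"],
            loglik=d["loglik"],
            aic=d["aic"],
            bic=d["bic"],
            age_center=d["age_center"],
            covariate_cols=d["covariate_cols"],
            extras=d["extras"],
            re_estimates=None if re is None else pd.Series(re),
        )

    def draw_params(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        """Sample parameter vectors from MVN(theta-hat, vcov); shape (n, k)."""
        v = self.vcov.to_numpy()
        # clip tiny negative eigenvalues from numerical noise
        w, q = np.linalg.eigh(v)
        w = np.clip(w, 0.0, None)
        root = q * np.sqrt(w)
        z = rng.standard_normal((n, len(self.params)))
        return self.params.to_numpy()[None, :] + z @ root.T


def _jsonable(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, (np.integer,)):
            v = int(v)
        elif isinstance(v, (np.floating,)):
            v = float(v)
        elif isinstance(v, (list, tuple)):
            v = [int(x) if isinstance(x, np.integer) else x for x in v]
        out[k] = v
    return out


def information_criteria(loglik: float, k: int, n: int) -> tuple[float, float]:
    """AIC = -2l + 2k; BIC = -2l + k log n."""
    return -2.0 * loglik + 2.0 * k, -2.0 * loglik + k * np.log(n)


# ---------------------------------------------------------------------------
# survival


def _check_survival_inputs(time: np.ndarray, event: np.ndarray) -> None:
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")
    if event.sum() == 0:
        raise ValueError("no deaths observed; survival model cannot be fitted")


def fit_survival(
    patients: pd.DataFrame,
    time: pd.Series,
    event: pd.Series,
    family: str = "lognormal",
    age_center: float | None = None,
    covariates: list[str] | None = None,
) -> ModelFit:
    """Maximum-likelihood AFT fit with right censoring.

    ``time`` is follow-up in weeks, ``event`` 1 for death and 0 for
    censoring, indexed like ``patients``. The scale parameter is estimated
    on the log scale so PSA draws keep sigma positive. ``covariates=[]``
    fits an intercept-only model.
    """
    X, age_center = make_covariates(patients, age_center)
    if covariates is not None:
        X = X[covariates]
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=float)
    _check_survival_inputs(t, e)
    if family == "exponential":
        return _fit_exponential_aft(X, t, e, age_center)
    if family not in _AFT_FITTERS:
        raise ValueError(f"unknown AFT family {family!r}")
    df = X.copy()
    df["time"], df["event"] = t, e
    fitter = _AFT_FITTERS[family]()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fitter.fit(df, duration_col="time", event_col="event")
    flat = {f"{p}:{c}": v for (p, c), v in fitter.params_.items()}
    params = pd.Series(flat, name="coef")
    names = list(params.index)
    vcov = pd.DataFrame(
        fitter.variance_matrix_.to_numpy(), index=names, columns=names
    )
    ll = float(fitter.log_likelihood_)
    k = len(params)
    aic, bic = information_criteria(ll, k, len(t))
    primary = fitter._primary_parameter_name  # mu_ / lambda_ / alpha_
    ancillary = fitter._ancillary_parameter_name  # sigma_ / rho_ / beta_
    return ModelFit(
        family=f"{family}_aft",
        params=params,
        vcov=vcov,
        n_obs=len(t),
        loglik=ll,
        aic=aic,
        bic=bic,
        age_center=age_center,
        covariate_cols=list(X.columns),
        extras={
            "location_prefix": f"{primary}:",
            "log_scale_param": f"{ancillary}:Intercept",
            "n_events": int(e.sum()),
        },
    )


def _fit_exponential_aft(
    X: pd.DataFrame, t: np.ndarray, e: np.ndarray, age_center: float
) -> ModelFit:
    """Exponential AFT (log T mean = x'b): censored ML via Newton steps."""
    Xc = np.column_stack([X.to_numpy(), np.ones(len(t))])
    names = [f"mu_:{c}" for c in X.columns] + ["mu_:Intercept"]

    def loglik(b):
        eta = Xc @ b
        return np.sum(-e * eta - t * np.exp(-eta))

    # concave in b: damped Newton with analytic gradient/Hessian
    b = np.zeros(Xc.shape[1])
    b[-1] = np.log(t.sum() / max(e.sum(), 1.0))
    for _ in range(500):
        eta = Xc @ b
        w = t * np.exp(-eta)
        g = Xc.T @ (-e + w)
        if np.max(np.abs(g)) < 1e-8:
            break
        hess = Xc.T @ (Xc * w[:, None])
        step = np.linalg.solve(hess, g)
        ll0, scale_ = loglik(b), 1.0
        while scale_ > 1e-10 and loglik(b + scale_ * step) < ll0:
            scale_ /= 2.0
        b = b + scale_ * step
    else:
        raise ConvergenceError("exponential AFT did not converge")
    eta = Xc @ b
    w = t * np.exp(-eta)
    hess = Xc.T @ (Xc * w[:, None])  # observed information
    vcov = np.linalg.inv(hess)
    ll = loglik(b)
    k = Xc.shape[1]
    aic, bic = information_criteria(ll, k, len(t))
    params = pd.Series(b, index=names, name="coef")
    return ModelFit(
        family="exponential_aft",
        params=params,
        vcov=pd.DataFrame(vcov, index=names, columns=names),
        n_obs=len(t),
        loglik=ll,
        aic=aic,
        bic=bic,
        age_center=age_center,
        extras={"location_prefix": "mu_:", "n_events": int(e.sum())},
    )


def select_survival_family(
    patients: pd.DataFrame, time: pd.Series, event: pd.Series
) -> tuple[str, pd.DataFrame]:
    """AIC-based choice among exponential/Weibull/lognormal/log-logistic.

    Returns the AIC-minimising family name and the comparison table; a
    warning is emitted if BIC prefers a different family.
    """
    rows = []
    for fam in ["exponential", "weibull", "lognormal", "loglogistic"]:
        fit = fit_survival(patients, time, event, family=fam)
        rows.append({"family": fam, "aic": fit.aic, "bic": fit.bic,
                     "loglik": fit.loglik, "k": fit.n_params})
    table = pd.DataFrame(rows).set_index("family")
    best_aic = table["aic"].idxmin()
    best_bic = table["bic"].idxmin()
    if best_aic != best_bic:
        warnings.warn(
            f"AIC prefers {best_aic} but BIC prefers {best_bic}; returning "
            f"the AIC choice",
            stacklevel=2,
        )
    return best_aic, table


def survival_location_scale(
    fit: ModelFit, X: pd.DataFrame
) -> tuple[np.ndarray, float]:
    """Linear predictor (location) per patient and the scale sigma."""
    return _location_scale_from_params(fit, fit.params.to_numpy(), X)


def _location_scale_from_params(
    fit: ModelFit, theta: np.ndarray, X: pd.DataFrame
) -> tuple[np.ndarray, float]:
    prefix = fit.extras["location_prefix"]
    names = list(fit.params.index)
    beta = {n[len(prefix):]: theta[i] for i, n in enumerate(names) if n.startswith(prefix)}
    mu = np.full(len(X), beta["Intercept"])
    for c in X.columns:
        if c in beta:
            mu = mu + beta[c] * X[c].to_numpy()
    if "log_scale_param" in fit.extras:
        sigma = float(np.exp(theta[names.index(fit.extras["log_scale_param"])]))
    else:
        sigma = 1.0
    return mu, sigma


# ---------------------------------------------------------------------------
# linear mixed models (utility / other cost)


def fit_lmm(
    long_df: pd.DataFrame,
    patients: pd.DataFrame,
    outcome: str,
    time_col: str,
    visit_weeks: list[int],
    age_center: float | None = None,
) -> ModelFit:
    """REML linear mixed model with a patient random intercept.

    ``long_df`` must carry patient_id, ``time_col`` and the outcome; rows
    with a missing outcome are dropped (available-case behaviour is decided
    upstream). Returns empirical-Bayes random-intercept predictions per
    patient in ``re_estimates``.
    """
    X, age_center = make_covariates(patients, age_center)
    df = long_df.dropna(subset=[outcome])
    if df.empty:
        raise ValueError(f"all {outcome!r} observations missing")
    if df["patient_id"].nunique() < 2:
        raise ValueError("mixed model needs at least 2 patients")
    Xrows = X.loc[df["patient_id"]]
    exog = longitudinal_design(Xrows, df[time_col].to_numpy(), visit_weeks)
    exog.index = df.index
    endog = df[outcome].astype(float)
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(endog, exog, groups=df["patient_id"].to_numpy())
        for method in (None, "lbfgs", "powell"):
            try:
                kw = {} if method is None else {"method": method, "maxiter": 500}
                cand = model.fit(reml=True, **kw)
            except np.linalg.LinAlgError:
                continue
            if cand.converged:
                res = cand
                break
    if res is None:
        raise ConvergenceError("mixed model did not converge")
    fe = res.fe_params
    vcov = pd.DataFrame(
        np.asarray(res.cov_params())[: len(fe), : len(fe)],
        index=fe.index,
        columns=fe.index,
    )
    re = pd.Series({k: float(v.iloc[0]) for k, v in res.random_effects.items()})
    ll = float(res.llf)
    k = len(fe) + 2  # + random-intercept variance + residual variance
    aic, bic = information_criteria(ll, k, len(df))
    return ModelFit(
        family="linear_mixed",
        params=pd.Series(fe, name="coef"),
        vcov=vcov,
        n_obs=len(df),
        loglik=ll,
        aic=aic,
        bic=bic,
        age_center=age_center,
        extras={
            "outcome": outcome,
            "visit_weeks": list(visit_weeks),
            "re_var": float(res.cov_re.iloc[0, 0]),
            "resid_var": float(res.scale),
        },
        re_estimates=re,
    )


def predict_lmm(
    fit: ModelFit,
    X_rows: pd.DataFrame,
    weeks: np.ndarray,
    theta: np.ndarray | None = None,
    include_random_effect: bool = True,
) -> np.ndarray:
    """Fixed-effect prediction (+ empirical-Bayes intercept when available).

    ``X_rows`` is the covariate design (one row per prediction, indexed by
    patient_id) and ``weeks`` the matching visit weeks.
    """
    exog = longitudinal_design(X_rows, np.asarray(weeks), fit.extras["visit_weeks"])
    exog = exog[list(fit.params.index)]
    beta = fit.params.to_numpy() if theta is None else np.asarray(theta)
    pred = exog.to_numpy() @ beta
    if include_random_effect and fit.re_estimates is not None:
        re = fit.re_estimates.reindex(X_rows.index).fillna(0.0).to_numpy()
        pred = pred + re
    return pred


# ---------------------------------------------------------------------------
# ordinal hospitalisation model


def collapse_empty_categories(
    cats: pd.Series, order: list[str] = HOSP_CATEGORIES
) -> tuple[pd.Series, list[str]]:
    """Merge categories unobserved in the data upward into the next-severe one.

    Preserves the ordering; emits a warning naming the merge.
    """
    present = [c for c in order if (cats == c).any()]
    unknown = set(cats) - set(order)
    if unknown:
        raise ValueError(f"unknown hospitalisation categories: {sorted(unknown)}")
    if len(present) == len(order):
        return cats, list(order)
    mapping = {}
    for i, c in enumerate(order):
        if c in present:
            mapping[c] = c
        else:
            more_severe = [s for s in order[i + 1:] if s in present]
            target = more_severe[0] if more_severe else present[-1]
            mapping[c] = target
            warnings.warn(
                f"hospitalisation category {c!r} unobserved; merged into {target!r}",
                stacklevel=2,
            )
    return cats.map(mapping), present


def fit_hospitalisation_ordinal(
    period_df: pd.DataFrame,
    patients: pd.DataFrame,
    age_center: float | None = None,
) -> ModelFit:
    """Proportional-odds logit for the per-period admission severity scale.

    ``period_df`` needs patient_id and ``category`` (one row per patient per
    follow-up period). Thresholds are kept in the fitted unconstrained
    parametrisation (first cut point, then log-increments) so PSA draws
    always yield strictly increasing cut points.
    """
    X, age_center = make_covariates(patients, age_center)
    cats, present = collapse_empty_categories(period_df["category"])
    if len(present) < 2:
        raise ValueError("hospitalisation outcome has a single observed category")
    codes = cats.map({c: i for i, c in enumerate(present)}).to_numpy()
    exog = X.loc[period_df["patient_id"]].reset_index(drop=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = OrderedModel(codes, exog, distr="logit")
        res = model.fit(method="bfgs", disp=False, gtol=1e-8, maxiter=500)
    if not res.mle_retvals.get("converged", True):
        raise ConvergenceError("ordinal model did not converge")
    params = pd.Series(res.params, name="coef")
    params.index = [str(i) for i in params.index]
    vcov = pd.DataFrame(
        np.asarray(res.cov_params()), index=params.index, columns=params.index
    )
    ll = float(res.llf)
    aic, bic = information_criteria(ll, len(params), len(codes))
    return ModelFit(
        family="ordinal_logit",
        params=params,
        vcov=vcov,
        n_obs=len(codes),
        loglik=ll,
        aic=aic,
        bic=bic,
        age_center=age_center,
        extras={"categories": present, "n_covariates": exog.shape[1]},
    )


def ordinal_thresholds(fit: ModelFit, theta: np.ndarray | None = None) -> np.ndarray:
    """Strictly increasing cut points from the unconstrained parametrisation."""
    theta = fit.params.to_numpy() if theta is None else np.asarray(theta)
    p = fit.extras["n_covariates"]
    raw = theta[p:]
    th = np.empty(len(raw))
    th[0] = raw[0]
    th[1:] = raw[0] + np.cumsum(np.exp(raw[1:]))
    return th


def predict_ordinal_probs(
    fit: ModelFit, X: pd.DataFrame, theta: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-category probabilities (columns ordered none -> most severe)."""
    theta = fit.params.to_numpy() if theta is None else np.asarray(theta)
    p = fit.extras["n_covariates"]
    eta = X.to_numpy() @ theta[:p]
    th = ordinal_thresholds(fit, theta)
    cum = stats.logistic.cdf(th[None, :] - eta[:, None])  # P(Y<=j), j=0..k-2
    bounds = np.hstack([np.zeros((len(eta), 1)), cum, np.ones((len(eta), 1))])
    probs = np.diff(bounds, axis=1)
    return pd.DataFrame(probs, index=X.index, columns=fit.extras["categories"])


# ---------------------------------------------------------------------------
# antibiotic logit


def _find_separating_covariate(X: pd.DataFrame, y: np.ndarray) -> str | None:
    for c in X.columns:
        x = X[c].to_numpy()
        if y.sum() in (0, len(y)):
            return None
        if x[y == 1].min() > x[y == 0].max() or x[y == 1].max() < x[y == 0].min():
            return c
    return None


def fit_antibiotic_logit(
    period_df: pd.DataFrame,
    patients: pd.DataFrame,
    age_center: float | None = None,
    covariates: list[str] | None = None,
) -> ModelFit:
    """Plain logistic regression for per-period prescription probability.

    A random-effects version is deliberately not offered: with sparse
    per-period binary outcomes the RE logit routinely fails to converge, so
    the population-average logit is the supported model. exp(arm coefficient)
    is the arm odds ratio.
    """
    X, age_center = make_covariates(patients, age_center)
    if covariates is not None:
        X = X[covariates]
    y = period_df["prescribed"].astype(float).to_numpy()
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("prescribed must be binary")
    exog = X.loc[period_df["patient_id"]].reset_index(drop=True)
    exog.insert(0, "const", 1.0)
    sep = _find_separating_covariate(exog.drop(columns="const"), y)
    if sep is not None:
        raise ValueError(f"perfect separation on covariate {sep!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, exog).fit(disp=False, maxiter=500, tol=1e-8)
    if not res.mle_retvals.get("converged", True):
        raise ConvergenceError("logistic model did not converge")
    params = pd.Series(res.params, name="coef")
    vcov = pd.DataFrame(
        np.asarray(res.cov_params()), index=params.index, columns=params.index
    )
    ll = float(res.llf)
    aic, bic = information_criteria(ll, len(params), len(y))
    return ModelFit(
        family="logit",
        params=params,
        vcov=vcov,
        n_obs=len(y),
        loglik=ll,
        aic=aic,
        bic=bic,
        age_center=age_center,
        covariate_cols=list(X.columns),
        extras={"outcome": "prescribed"},
    )


def predict_logit_prob(
    fit: ModelFit, X: pd.DataFrame, theta: np.ndarray | None = None
) -> np.ndarray:
    theta = fit.params.to_numpy() if theta is None else np.asarray(theta)
    exog = X.copy()
    exog.insert(0, "const", 1.0)
    exog = exog[list(fit.params.index)]
    return stats.logistic.cdf(exog.to_numpy() @ theta)


def assert_common_design(fits: list[ModelFit]) -> None:
    """All models must share the covariate set and age-centring constant."""
    base = fits[0]
    for f in fits[1:]:
        if f.covariate_cols != base.covariate_cols:
            raise AssertionError("covariate sets differ across models")
        if abs(f.age_center - base.age_center) > 1e-9:
            raise AssertionError("age centring constants differ across models")
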