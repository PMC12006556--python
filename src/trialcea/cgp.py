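"""Corrected group prognosis: counterfactual standardisation of outcomes.

Because several of the outcome regressions are non-linear, arm effects
cannot be read off coefficients.  CGP instead predicts every patient's
outcome under *both* sampling policies using their own covariates (and
their empirical-Bayes random intercept for the mixed models), then averages
over the full population.  The difference of these standardised averages is
the incremental effect.

Expected QALYs follow the survival-times-utility construction: the fitted
lognormal survival function S(t) = 1 - Phi((log t - x'b)/sigma) is
multiplied by the conditional expectation of utility u(t) (linear
interpolation between visit weeks) and the area under S(t)u(t) is taken up
to the horizon, divided by 52 weeks/year.  Utility after death contributes
nothing via the S(t) weighting.

Expected event costs are built per inter-visit period: each period
contributes (category probabilities x expected category costs) for
hospitalisation, (prescription probability x expected course cost) for
antibiotics, and the mixed-model prediction for other NHS costs; each
period is weighted by the probability of being alive at its start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from . import cea as cea_mod
from . import regression_engine as reg
from .costing import CostTables

DEFAULT_VISIT_WEEKS = [0, 4, 12, 26, 39, 52, 104]
DEFAULT_GRID_STEP = 0.1  # weeks; refinement of the AUC integration grid


@dataclass
class SurvivalCurve:
    """Survival probabilities for one patient under one counterfactual arm."""

    patient_id: object
    arm: int
    times: np.ndarray
    surv: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.surv = np.asarray(self.surv, dtype=float)
        if self.times[0] != 0 or abs(self.surv[0] - 1.0) > 1e-12:
            raise ValueError("curve must start at S(0) = 1")
        if np.any(np.diff(self.surv) > 1e-12):
            raise ValueError("survival must be non-increasing")
        if self.surv.min() < -1e-12 or self.surv.max() > 1 + 1e-12:
            raise ValueError("survival probabilities must lie in [0, 1]")


@dataclass
class FittedModels:
    """The five fitted regressions driving the standardisation."""

    survival: reg.ModelFit
    utility: reg.ModelFit
    hospitalisation: reg.ModelFit
    antibiotics: reg.ModelFit
    other_cost: reg.ModelFit

    def as_list(self) -> list[reg.ModelFit]:
        return [self.survival, self.utility, self.hospitalisation,
                self.antibiotics, self.other_cost]

    def validate(self) -> None:
        reg.assert_common_design(self.as_list())


@dataclass
class ExpectedOutcome:
    """Per-arm expected outcomes at a horizon, averaged over the population."""

    arm: int
    horizon_weeks: int
    qaly: float
    cost_antibiotics: float
    cost_hospitalisation: float
    cost_other: float

    @property
    def total_cost(self) -> float:
        return self.cost_antibiotics + self.cost_hospitalisation + self.cost_other


def lognormal_survival(
    mu: np.ndarray, sigma: float, times: np.ndarray
) -> np.ndarray:
    """S(t) matrix (patients x times); S(0) = 1 by convention."""
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("grid times must be non-negative")
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    out = np.ones((len(mu), len(times)))
    pos = times > 0
    if sigma <= 0:
        # degenerate limit: step function at exp(mu)
        out[:, pos] = (np.log(times[pos])[None, :] < mu[:, None]).astype(float)
        return out
    z = (np.log(times[pos])[None, :] - mu[:, None]) / sigma
    out[:, pos] = 1.0 - ndtr(z)
    return out


def predict_survival_curve(
    fit: reg.ModelFit,
    patient: pd.Series | pd.DataFrame,
    arm: int,
    grid: np.ndarray,
) -> SurvivalCurve:
    """Counterfactual lognormal survival curve for one patient."""
    if not fit.family.startswith("lognormal"):
        raise ValueError("survival curves are produced from the lognormal AFT fit")
    row = patient.to_frame().T if isinstance(patient, pd.Series) else patient
    X = row[reg.COVARIATE_COLS].copy()
    X["arm"] = float(arm)
    mu, sigma = reg.survival_location_scale(fit, X)
    surv = lognormal_survival(mu, sigma, grid)[0]
    return SurvivalCurve(patient_id=row.index[0], arm=arm, times=np.asarray(grid, float), surv=surv)


def _refined_grid(visit_weeks: np.ndarray, horizon: float, step: float) -> np.ndarray:
    fine = np.arange(0.0, horizon + step / 2, step)
    grid = np.union1d(fine, np.asarray(visit_weeks, float))
    return grid[grid <= horizon + 1e-9]


def expected_qaly(
    survival_curve: SurvivalCurve,
    visit_weeks: np.ndarray,
    utilities: np.ndarray,
    horizon: float,
    discount_rate: float | None = None,
) -> float:
    """Area under S(t) u(t) up to the horizon, in QALY-years.

    ``utilities`` are the conditional (on being alive) utility expectations
    at the visit weeks; they are linearly interpolated between visits, the
    survival curve is linearly interpolated onto the same refined grid, and
    the product is integrated by trapezoid.  With discounting on, the
    portion accruing after week 52 is multiplied by 1/(1+rate).
    """
    visit_weeks = np.asarray(visit_weeks, dtype=float)
    if horizon > visit_weeks.max() + 1e-9:
        raise ValueError("horizon beyond the last visit week; no utility extrapolation")
    grid = _refined_grid(visit_weeks, horizon, DEFAULT_GRID_STEP)
    grid = np.union1d(grid, survival_curve.times[survival_curve.times <= horizon + 1e-9])
    u = np.interp(grid, visit_weeks, utilities)
    s = np.interp(grid, survival_curve.times, survival_curve.surv)
    return _auc_qaly(grid, s * u, discount_rate)


def _auc_qaly(
    grid: np.ndarray, integrand: np.ndarray, discount_rate: float | None
) -> float:
    seg = np.diff(grid) * (integrand[:-1] + integrand[1:]) / 2.0
    if discount_rate is not None:
        mid = (grid[:-1] + grid[1:]) / 2.0
        seg = np.where(mid > cea_mod.WEEKS_PER_YEAR, seg / (1.0 + discount_rate), seg)
    return float(seg.sum()) / cea_mod.WEEKS_PER_YEAR


_GRID_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _grid_and_weights(
    visit_weeks: tuple[float, ...], horizon: float, step: float
) -> tuple[np.ndarray, np.ndarray]:
    """Refined grid plus the (n_visits x n_grid) linear-interpolation matrix."""
    key = (visit_weeks, horizon, step)
    if key not in _GRID_CACHE:
        vw = np.asarray(visit_weeks, dtype=float)
        grid = _refined_grid(vw, horizon, step)
        W = np.empty((len(vw), len(grid)))
        for j in range(len(vw)):
            basis = np.zeros(len(vw))
            basis[j] = 1.0
            W[j] = np.interp(grid, vw, basis)
        _GRID_CACHE[key] = (grid, W)
    return _GRID_CACHE[key]


def _qaly_matrix(
    mu: np.ndarray,
    sigma: float,
    util_at_visits: np.ndarray,  # (n, n_visits)
    visit_weeks: np.ndarray,
    horizon: float,
    discount_rate: float | None,
    step: float = DEFAULT_GRID_STEP,
) -> np.ndarray:
    """Vectorised expected QALY per patient (exact lognormal S on the grid)."""
    grid, W = _grid_and_weights(tuple(np.asarray(visit_weeks, float)), float(horizon), step)
    S = lognormal_survival(mu, sigma, grid)
    U = util_at_visits @ W  # linear interpolation of utilities onto the grid
    f = S * U
    w = np.diff(grid)
    seg = (f[:, :-1] + f[:, 1:]) / 2.0 * w[None, :]
    if discount_rate is not None:
        mid = (grid[:-1] + grid[1:]) / 2.0
        seg = np.where(mid[None, :] > cea_mod.WEEKS_PER_YEAR,
                       seg / (1.0 + discount_rate), seg)
    return seg.sum(axis=1) / cea_mod.WEEKS_PER_YEAR


@dataclass
class CostAssumptions:
    """Expected event costs entering the probability-times-cost products.

    ``hosp_category_costs`` maps the ordinal severity categories (above
    'none') to the expected cost of one admission of that severity;
    ``expected_course_cost`` is the expected cost of one antibiotic course.
    Defaults derive from the admission cost schedule at average stay
    lengths; the pipeline replaces them with observed within-trial means.
    """

    hosp_category_costs: dict[str, float] = field(default_factory=dict)
    expected_course_cost: float = 25.0

    @classmethod
    def from_tables(cls, tables: CostTables) -> "CostAssumptions":
        minor = tables.expected_admission_cost("minor_amputation")
        revasc = tables.expected_admission_cost("revascularisation")
        return cls(
            hosp_category_costs={
                "other": tables.expected_admission_cost("other"),
                "minor_amp_or_revasc": (minor + revasc) / 2.0,
                "major_amp": tables.expected_admission_cost("major_amputation"),
            }
        )


def expected_event_costs(
    fits: FittedModels,
    X_arm: pd.DataFrame,
    visit_weeks: list[int],
    horizon: int,
    assumptions: CostAssumptions,
    discount_rate: float | None = None,
    thetas: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Per-patient expected cost components up to the horizon.

    ``X_arm`` is the covariate design with the arm column already set to the
    counterfactual arm.  Period contributions are weighted by the predicted
    probability of being alive at the period start.  Returns a frame indexed
    like ``X_arm`` with columns antibiotics / hospitalisation / other.
    """
    visit_weeks = list(visit_weeks)
    if horizon not in visit_weeks:
        raise ValueError(f"horizon {horizon} is not a period boundary {visit_weeks}")
    thetas = thetas or {}
    starts = np.array([w for w in visit_weeks if w < horizon], dtype=float)
    ends = np.array([w for w in visit_weeks[1:] if w <= horizon], dtype=float)

    mu, sigma = reg._location_scale_from_params(
        fits.survival, thetas.get("survival", fits.survival.params.to_numpy()), X_arm
    )
    alive_at_start = lognormal_survival(mu, sigma, starts)  # (n, n_periods)

    hosp_probs = reg.predict_ordinal_probs(
        fits.hospitalisation, X_arm, thetas.get("hospitalisation")
    )
    per_period_hosp = np.zeros(len(X_arm))
    for cat, cost in assumptions.hosp_category_costs.items():
        if cat in hosp_probs.columns:
            per_period_hosp += hosp_probs[cat].to_numpy() * cost

    p_rx = reg.predict_logit_prob(fits.antibiotics, X_arm, thetas.get("antibiotics"))
    per_period_abx = p_rx * assumptions.expected_course_cost

    n, k = len(X_arm), len(ends)
    other_pred = np.empty((n, k))
    for j, w in enumerate(ends):
        other_pred[:, j] = reg.predict_lmm(
            fits.other_cost, X_arm, np.full(n, w), theta=thetas.get("other_cost")
        )

    disc = np.ones(k)
    if discount_rate is not None:
        disc = np.where(ends > cea_mod.WEEKS_PER_YEAR, 1.0 / (1.0 + discount_rate), 1.0)

    hosp = (alive_at_start * per_period_hosp[:, None] * disc[None, :]).sum(axis=1)
    abx = (alive_at_start * per_period_abx[:, None] * disc[None, :]).sum(axis=1)
    other = (alive_at_start * other_pred * disc[None, :]).sum(axis=1)
    return pd.DataFrame(
        {"antibiotics": abx, "hospitalisation": hosp, "other": other},
        index=X_arm.index,
    )


class CgpEvaluator:
    """Precomputed counterfactual design matrices for fast repeated CGP.

    Building the per-arm design matrices once makes a PSA draw a handful of
    matrix products; the deterministic result is the evaluation at the
    fitted parameter vectors.
    """

    def __init__(
        self,
        fits: FittedModels,
        patients: pd.DataFrame,
        assumptions: CostAssumptions,
        visit_weeks: list[int] = DEFAULT_VISIT_WEEKS,
    ):
        self.fits = fits
        self.assumptions = assumptions
        self.visit_weeks = list(visit_weeks)
        X, _ = reg.make_covariates(patients, age_center=fits.survival.age_center)
        self.n = len(X)
        vw = np.asarray(self.visit_weeks, dtype=float)
        self.vw = vw
        self.period_ends = vw[1:]
        self.period_starts = vw[:-1]
        self._arm_design: dict[int, dict[str, np.ndarray]] = {}
        for arm in (0, 1):
            X_arm = X.copy()
            X_arm["arm"] = float(arm)
            d: dict[str, np.ndarray] = {}
            # survival location design aligned to the location parameters
            loc_prefix = fits.survival.extras["location_prefix"]
            names = list(fits.survival.params.index)
            self._surv_loc_idx = [
                i for i, nm in enumerate(names) if nm.startswith(loc_prefix)
            ]
            cols = [names[i][len(loc_prefix):] for i in self._surv_loc_idx]
            d["surv"] = np.column_stack(
                [
                    np.ones(self.n) if c == "Intercept" else X_arm[c].to_numpy()
                    for c in cols
                ]
            )
            # utility design stacked over visit weeks: (n_visits * n, k)
            rep = X_arm.loc[np.tile(X_arm.index, len(vw))]
            weeks = np.repeat(vw, self.n)
            ut = reg.longitudinal_design(rep, weeks, fits.utility.extras["visit_weeks"])
            d["util"] = ut[list(fits.utility.params.index)].to_numpy()
            # other-cost design stacked over period ends
            rep2 = X_arm.loc[np.tile(X_arm.index, len(self.period_ends))]
            weeks2 = np.repeat(self.period_ends, self.n)
            ot = reg.longitudinal_design(
                rep2, weeks2, fits.other_cost.extras["visit_weeks"]
            )
            d["other"] = ot[list(fits.other_cost.params.index)].to_numpy()
            # ordinal & logit covariate designs
            d["ord"] = X_arm.to_numpy()
            lg = X_arm.copy()
            lg.insert(0, "const", 1.0)
            d["logit"] = lg[list(fits.antibiotics.params.index)].to_numpy()
            self._arm_design[arm] = d
        self._scale_idx = names.index(fits.survival.extras["log_scale_param"]) \
            if "log_scale_param" in fits.survival.extras else None
        re_u = fits.utility.re_estimates
        self._re = (
            re_u.reindex(X.index).fillna(0.0).to_numpy()
            if re_u is not None
            else np.zeros(self.n)
        )
        # hospitalisation expected per-period cost vector over categories
        self._hosp_cost = np.array(
            [
                assumptions.hosp_category_costs.get(c, 0.0)
                for c in fits.hospitalisation.extras["categories"]
            ]
        )

    def _mu_sigma(self, arm: int, theta: np.ndarray) -> tuple[np.ndarray, float]:
        mu = self._arm_design[arm]["surv"] @ theta[self._surv_loc_idx]
        sigma = (
            float(np.exp(theta[self._scale_idx])) if self._scale_idx is not None else 1.0
        )
        return mu, sigma

    def outcome(
        self,
        arm: int,
        horizon: int,
        thetas: dict[str, np.ndarray] | None = None,
        discount_rate: float | None = None,
        include_random_effect: bool = True,
    ) -> ExpectedOutcome:
        thetas = thetas or {}
        fits = self.fits
        d = self._arm_design[arm]
        th_surv = thetas.get("survival", fits.survival.params.to_numpy())
        mu, sigma = self._mu_sigma(arm, th_surv)

        vis = self.vw[self.vw <= horizon]
        n_vis = len(vis)
        th_u = thetas.get("utility", fits.utility.params.to_numpy())
        util_all = (d["util"] @ th_u).reshape(len(self.vw), self.n).T
        if include_random_effect:
            util_all = util_all + self._re[:, None]
        qalys = _qaly_matrix(
            mu, sigma, util_all[:, :n_vis], vis, float(horizon), discount_rate
        )

        ends = self.period_ends[self.period_ends <= horizon]
        starts = self.period_starts[: len(ends)]
        alive = lognormal_survival(mu, sigma, starts)
        probs = reg.predict_ordinal_probs(
            fits.hospitalisation,
            pd.DataFrame(d["ord"], columns=reg.COVARIATE_COLS),
            thetas.get("hospitalisation"),
        ).to_numpy()
        per_hosp = probs @ self._hosp_cost
        th_l = thetas.get("antibiotics", fits.antibiotics.params.to_numpy())
        from scipy.stats import logistic

        p_rx = logistic.cdf(d["logit"] @ th_l)
        per_abx = p_rx * self.assumptions.expected_course_cost
        th_o = thetas.get("other_cost", fits.other_cost.params.to_numpy())
        other_all = (d["other"] @ th_o).reshape(len(self.period_ends), self.n).T
        other_all = other_all[:, : len(ends)]
        disc = np.ones(len(ends))
        if discount_rate is not None:
            disc = np.where(
                ends > cea_mod.WEEKS_PER_YEAR, 1.0 / (1.0 + discount_rate), 1.0
            )
        hosp = (alive * per_hosp[:, None] * disc[None, :]).sum(axis=1)
        abx = (alive * per_abx[:, None] * disc[None, :]).sum(axis=1)
        other = (alive * other_all * disc[None, :]).sum(axis=1)
        return ExpectedOutcome(
            arm=arm,
            horizon_weeks=horizon,
            qaly=float(qalys.mean()),
            cost_antibiotics=float(abx.mean()),
            cost_hospitalisation=float(hosp.mean()),
            cost_other=float(other.mean()),
        )

    def contrast(
        self,
        horizon: int,
        thetas: dict[str, np.ndarray] | None = None,
        discount_rate: float | None = None,
    ) -> tuple[ExpectedOutcome, ExpectedOutcome]:
        return (
            self.outcome(1, horizon, thetas, discount_rate),
            self.outcome(0, horizon, thetas, discount_rate),
        )


def cgp_average(
    fits: FittedModels,
    patients: pd.DataFrame,
    arm: int,
    horizon: int,
    assumptions: CostAssumptions,
    visit_weeks: list[int] = DEFAULT_VISIT_WEEKS,
    discount_rate: float | None = None,
    thetas: dict[str, np.ndarray] | None = None,
    include_random_effect: bool = True,
) -> ExpectedOutcome:
    """Population-average expected outcomes under one counterfactual arm.

    Every patient — regardless of actual assignment — is predicted under the
    given arm with their own covariates and empirical-Bayes random effects,
    and the predictions are averaged.
    """
    if float(max(visit_weeks)) < horizon:
        raise ValueError("horizon beyond the visit schedule")
    ev = CgpEvaluator(fits, patients, assumptions, visit_weeks)
    return ev.outcome(arm, horizon, thetas, discount_rate, include_random_effect)


def cgp_contrast(
    fits: FittedModels,
    patients: pd.DataFrame,
    horizon: int,
    assumptions: CostAssumptions,
    visit_weeks: list[int] = DEFAULT_VISIT_WEEKS,
    discount_rate: float | None = None,
    thetas: dict[str, np.ndarray] | None = None,
) -> tuple[ExpectedOutcome, ExpectedOutcome]:
    """Standardised outcomes under swab (arm 0) and tissue (arm 1)."""
    ev = CgpEvaluator(fits, patients, assumptions, visit_weeks)
    return ev.contrast(horizon, thetas, discount_rate)
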