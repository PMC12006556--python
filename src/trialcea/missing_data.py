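"""Missing-data handling: available cases, chained-equation MI, pooling.

Self-reported outcomes (EQ-5D utilities, the 4-week-recall cost
questionnaire) suffer attrition — in this design largely administrative,
which makes missing-at-random plausible — and are handled two ways:

* available-case analysis (ACA): rows with a missing self-reported value
  are simply dropped from the model that uses them;
* multiple imputation (MI) by fully conditional specification: each
  incomplete variable is imputed in turn from a regression on patient
  characteristics and all other outcomes, cycling until the chain has
  burnt in, and the whole procedure repeated to give m completed datasets
  whose analyses are pooled by Rubin's rules.

Researcher-collected streams (deaths, admissions, antibiotic diaries) are
treated as complete and are never imputed.

Linear imputation models use proper posterior-predictive draws
(sigma^2 from the scaled inverse-chi-square, beta from its conditional
normal, plus residual noise); binary variables use a logistic model with
parameters drawn from the asymptotic normal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ImputationConfig:
    """FCS settings: m completed datasets, each after ``burn_in`` sweeps."""

    n_imputations: int = 100
    burn_in: int = 10
    seed: int = 0
    families: dict[str, str] = field(default_factory=dict)  # col -> linear|logistic

    def __post_init__(self) -> None:
        if self.n_imputations < 2:
            raise ValueError("need at least 2 imputations")
        if self.burn_in < 1:
            raise ValueError("need at least 1 burn-in sweep")


def aca_filter(df: pd.DataFrame, self_reported_cols: list[str]) -> pd.DataFrame:
    """Drop rows with missing self-reported values (available-case analysis)."""
    present = [c for c in self_reported_cols if c in df.columns]
    out = df.dropna(subset=present)
    if out.empty:
        raise ValueError("no available cases after dropping missing rows")
    return out


def _design(df: pd.DataFrame, cols: list[str]) -> np.ndarray:
    X = df[cols].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(df)), X])


def _draw_linear(
    X_obs: np.ndarray, y_obs: np.ndarray, X_mis: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Posterior-predictive draw for a normal linear imputation model."""
    n, p = X_obs.shape
    # standardise columns for conditioning; intercept/constant columns keep scale 1
    scale = X_obs.std(axis=0)
    scale[scale < 1e-12] = 1.0
    Xs = X_obs / scale
    xtx = Xs.T @ Xs
    ridge = 1e-6 * max(np.trace(xtx) / p, 1.0)  # guards collinear / sparse columns
    xtx_inv = np.linalg.inv(xtx + ridge * np.eye(p))
    beta_hat = xtx_inv @ (Xs.T @ y_obs)
    resid = y_obs - Xs @ beta_hat
    dof = max(n - p, 1)
    sigma2 = resid @ resid / rng.chisquare(dof)
    cov = sigma2 * (xtx_inv + xtx_inv.T) / 2.0
    w, q = np.linalg.eigh(cov)
    root = q * np.sqrt(np.clip(w, 0.0, None))
    beta = beta_hat + root @ rng.standard_normal(p)
    mean_mis = (X_mis / scale) @ beta
    return mean_mis + np.sqrt(sigma2) * rng.standard_normal(len(X_mis))


def _draw_logistic(
    X_obs: np.ndarray, y_obs: np.ndarray, X_mis: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y_obs, X_obs).fit(disp=False, maxiter=200)
    cov = np.asarray(res.cov_params())
    w, q = np.linalg.eigh(cov)
    root = q * np.sqrt(np.clip(w, 0, None))
    beta = np.asarray(res.params) + root @ rng.standard_normal(len(res.params))
    p = stats.logistic.cdf(X_mis @ beta)
    return (rng.random(len(X_mis)) < p).astype(float)


def mi_fcs(
    df: pd.DataFrame,
    impute_cols: list[str],
    predictor_cols: list[str],
    config: ImputationConfig,
) -> list[pd.DataFrame]:
    """Fully conditional specification: m completed copies of ``df``.

    Each incomplete column is imputed from an intercept + the predictor
    columns + every *other* imputable column (current working values), in a
    fixed sweep order, with ``burn_in`` full sweeps per chain.  Observed
    values are never altered; the output is deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    for c in impute_cols:
        if df[c].isna().all():
            raise ValueError(f"column {c!r} is 100% missing; cannot impute")
    if set(impute_cols) & set(predictor_cols):
        raise ValueError("a variable cannot predict its own imputation")
    masks = {c: df[c].isna().to_numpy() for c in impute_cols}
    incomplete = [c for c in impute_cols if masks[c].any()]
    completed: list[pd.DataFrame] = []
    for _ in range(config.n_imputations):
        work = df.copy()
        for c in incomplete:  # chain init: bootstrap from observed margins
            obs = work.loc[~masks[c], c].to_numpy()
            work.loc[masks[c], c] = rng.choice(obs, size=masks[c].sum(), replace=True)
        for _sweep in range(config.burn_in):
            for c in incomplete:
                others = [o for o in impute_cols if o != c]
                cols = predictor_cols + others
                X_all = _design(work, cols)
                y_obs = df.loc[~masks[c], c].to_numpy(dtype=float)
                X_obs, X_mis = X_all[~masks[c]], X_all[masks[c]]
                fam = config.families.get(c, "linear")
                if fam == "linear":
                    vals = _draw_linear(X_obs, y_obs, X_mis, rng)
                elif fam == "logistic":
                    vals = _draw_logistic(X_obs, y_obs, X_mis, rng)
                else:
                    raise ValueError(f"unknown imputation family {fam!r}")
                work.loc[masks[c], c] = vals
        completed.append(work)
    return completed


@dataclass
class PooledEstimate:
    estimate: float
    within_variance: float
    between_variance: float
    total_variance: float
    df: float
    m: int

    @property
    def std_error(self) -> float:
        return float(np.sqrt(self.total_variance))

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        half = stats.t.ppf(0.5 + level / 2, self.df) * self.std_error
        return self.estimate - half, self.estimate + half


def pool_rubin(estimates, variances) -> PooledEstimate:
    """Rubin's rules: pooled point estimate and total variance.

    total = within-mean + (1 + 1/m) x between;
    df = (m - 1) (1 + within / ((1 + 1/m) between))^2, infinite when the
    between-imputation variance is zero.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    m = len(q)
    if m < 2:
        raise ValueError("Rubin pooling needs at least 2 imputations")
    if len(u) != m:
        raise ValueError("estimates and variances must have equal length")
    qbar = q.mean()
    ubar = u.mean()
    b = q.var(ddof=1)
    total = ubar + (1 + 1 / m) * b
    if b > 0:
        df = (m - 1) * (1 + ubar / ((1 + 1 / m) * b)) ** 2
    else:
        df = np.inf
    return PooledEstimate(
        estimate=float(qbar),
        within_variance=float(ubar),
        between_variance=float(b),
        total_variance=float(total),
        df=float(df),
        m=m,
    )
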