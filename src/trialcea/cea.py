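"""Decision layer: discounting, ICER, net benefit, PSA and CEAC.

Conventions used throughout:

* increments are always intervention minus comparator (tissue minus swab);
* INMB(lambda) = lambda * dQ - dC (pounds); INHB(lambda) = dQ - dC / lambda
  (QALYs), so INHB = INMB / lambda identically;
* the ICER dC/dQ is only reported in the trade-off quadrants; a strategy
  that costs more and yields less is "dominated", one that costs less and
  yields more is "dominant";
* costs and utilities accruing in the second year (weeks 53-104) are
  discounted by a single annual factor 1/(1+rate); the first year is
  undiscounted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_DISCOUNT_RATE = 0.035
DEFAULT_LAMBDAS = (20_000.0, 30_000.0)
WEEKS_PER_YEAR = 52


def discount(amount: float, week: float, rate: float = DEFAULT_DISCOUNT_RATE):
    """Present value of an amount accruing at a given follow-up week.

    Two-year horizon convention: weeks 0-52 undiscounted, weeks 53-104 (and
    beyond) discounted one year at ``rate``. Applies identically to costs
    and utilities.
    """
    if rate < 0:
        raise ValueError("discount rate must be non-negative")
    week = np.asarray(week, dtype=float)
    factor = np.where(week > WEEKS_PER_YEAR, 1.0 / (1.0 + rate), 1.0)
    out = np.asarray(amount, dtype=float) * factor
    return float(out) if out.ndim == 0 else out


def inmb(delta_q: float, delta_c: float, lam: float) -> float:
    """Incremental net monetary benefit lambda*dQ - dC (pounds)."""
    if lam <= 0:
        raise ValueError("willingness-to-pay threshold must be positive")
    return lam * delta_q - delta_c


def inhb(delta_q: float, delta_c: float, lam: float) -> float:
    """Incremental net health benefit dQ - dC/lambda (QALYs)."""
    if lam <= 0:
        raise ValueError("willingness-to-pay threshold must be positive")
    return delta_q - delta_c / lam


def icer(delta_c: float, delta_q: float) -> tuple[float | None, str]:
    """ICER with dominance classification.

    Returns ``(ratio, label)``: label is ``"dominated"`` (costlier, less
    effective), ``"dominant"`` (cheaper, more effective), or the trade-off
    quadrant labels ``"icer_ne"`` / ``"icer_sw"`` with the ratio dC/dQ.
    dQ = 0 yields no ratio and a label by the sign of dC.
    """
    if delta_q == 0:
        if delta_c == 0:
            return None, "indifferent"
        return None, "dominated" if delta_c > 0 else "dominant"
    if delta_c >= 0 and delta_q < 0:
        return None, "dominated"
    if delta_c < 0 and delta_q > 0:
        return None, "dominant"
    ratio = delta_c / delta_q
    return ratio, "icer_ne" if delta_q > 0 else "icer_sw"


@dataclass
class CeResult:
    """Per-horizon cost-effectiveness summary for tissue vs swab sampling."""

    horizon_weeks: int
    cost_tissue: float
    cost_swab: float
    qaly_tissue: float
    qaly_swab: float
    missing_data_mode: str = "ACA"  # ACA | MI
    evaluation_mode: str = "deterministic"  # deterministic | PSA
    cost_components: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def delta_cost(self) -> float:
        return self.cost_tissue - self.cost_swab

    @property
    def delta_qaly(self) -> float:
        return self.qaly_tissue - self.qaly_swab

    def inmb(self, lam: float) -> float:
        return inmb(self.delta_qaly, self.delta_cost, lam)

    def inhb(self, lam: float) -> float:
        return inhb(self.delta_qaly, self.delta_cost, lam)

    @property
    def icer(self) -> tuple[float | None, str]:
        return icer(self.delta_cost, self.delta_qaly)

    def row(self, lambdas=DEFAULT_LAMBDAS) -> dict[str, object]:
        ratio, label = self.icer
        out: dict[str, object] = {
            "horizon_weeks": self.horizon_weeks,
            "missing_data": self.missing_data_mode,
            "evaluation": self.evaluation_mode,
            "qaly_tissue": self.qaly_tissue,
            "qaly_swab": self.qaly_swab,
            "delta_qaly": self.delta_qaly,
            "cost_tissue": self.cost_tissue,
            "cost_swab": self.cost_swab,
            "delta_cost": self.delta_cost,
        }
        for lam in lambdas:
            tag = f"{int(lam/1000)}k"
            out[f"inhb_{tag}"] = self.inhb(lam)
            out[f"inmb_{tag}"] = self.inmb(lam)
        out["icer"] = ratio if ratio is not None else np.nan
        out["icer_label"] = label
        return out


@dataclass
class PsaDraws:
    """Per-draw incremental outcomes from probabilistic sensitivity analysis."""

    draws: pd.DataFrame  # columns: cost_tissue cost_swab qaly_tissue qaly_swab

    def __post_init__(self) -> None:
        need = {"cost_tissue", "cost_swab", "qaly_tissue", "qaly_swab"}
        if not need <= set(self.draws.columns):
            raise ValueError(f"draws must have columns {sorted(need)}")
        if not np.isfinite(self.draws[list(need)].to_numpy()).all():
            raise ValueError("non-finite PSA draw encountered")

    @property
    def n_draws(self) -> int:
        return len(self.draws)

    @property
    def delta_cost(self) -> np.ndarray:
        return (self.draws["cost_tissue"] - self.draws["cost_swab"]).to_numpy()

    @property
    def delta_qaly(self) -> np.ndarray:
        return (self.draws["qaly_tissue"] - self.draws["qaly_swab"]).to_numpy()

    def mean_result(self, horizon_weeks: int, missing_data_mode: str = "ACA") -> CeResult:
        m = self.draws.mean()
        return CeResult(
            horizon_weeks=horizon_weeks,
            cost_tissue=float(m["cost_tissue"]),
            cost_swab=float(m["cost_swab"]),
            qaly_tissue=float(m["qaly_tissue"]),
            qaly_swab=float(m["qaly_swab"]),
            missing_data_mode=missing_data_mode,
            evaluation_mode="PSA",
        )


def psa_run(
    fits,
    patients: pd.DataFrame,
    horizon: int,
    assumptions,
    n_draws: int = 1000,
    seed: int | np.random.Generator = 0,
    visit_weeks=None,
    discount_rate: float | None = None,
) -> PsaDraws:
    """Probabilistic sensitivity analysis by parametric resampling.

    Each draw samples every model's full parameter vector from
    MVN(theta-hat, vcov) — preserving within-model correlation; draws are
    independent across the separately fitted models — and re-runs the CGP
    standardisation under both arms. Deterministic given the seed; with all
    vcov matrices zero every draw reproduces the deterministic result.
    """
    from . import cgp as cgp_mod  # deferred: cgp imports this module's constants

    if n_draws < 1:
        raise ValueError("n_draws must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if visit_weeks is None:
        visit_weeks = cgp_mod.DEFAULT_VISIT_WEEKS
    model_names = ["survival", "utility", "hospitalisation", "antibiotics", "other_cost"]
    samples = {
        name: getattr(fits, name).draw_params(rng, n_draws) for name in model_names
    }
    evaluator = cgp_mod.CgpEvaluator(fits, patients, assumptions, visit_weeks)
    rows = []
    for d in range(n_draws):
        thetas = {name: samples[name][d] for name in model_names}
        tissue, swab = evaluator.contrast(horizon, thetas, discount_rate)
        rows.append(
            {
                "cost_tissue": tissue.total_cost,
                "cost_swab": swab.total_cost,
                "qaly_tissue": tissue.qaly,
                "qaly_swab": swab.qaly,
            }
        )
    return PsaDraws(draws=pd.DataFrame(rows))


def ceac(draws: PsaDraws, lambda_grid: np.ndarray | None = None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve for tissue vs swab.

    CEAC(lambda) is the fraction of PSA draws with strictly positive INMB at
    that threshold (ties count against adoption).
    """
    if draws.n_draws == 0:
        raise ValueError("no PSA draws")
    if lambda_grid is None:
        lambda_grid = np.arange(0.0, 50_001.0, 1_000.0)
    lam = np.asarray(lambda_grid, dtype=float)
    dq, dc = draws.delta_qaly[None, :], draws.delta_cost[None, :]
    nb = lam[:, None] * dq - dc
    prob = (nb > 0).mean(axis=1)
    return pd.DataFrame({"lambda": lam, "p_cost_effective": prob})


def ce_plane(draws: PsaDraws) -> pd.DataFrame:
    """Incremental (dQ, dC) pairs for the cost-effectiveness plane."""
    return pd.DataFrame(
        {"delta_qaly": draws.delta_qaly, "delta_cost": draws.delta_cost}
    )
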