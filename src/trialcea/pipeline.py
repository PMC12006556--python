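"""End-to-end orchestration: data -> costing -> fits -> CGP -> decision outputs.

`prepare_analysis` turns the raw trial tables into model-ready inputs
(scored utilities, per-period admission severity and antibiotic
indicators, extrapolated other-NHS costs) plus the observed expected event
costs that enter the probability-times-cost products.  `run_pipeline`
executes every requested combination of missing-data handling (ACA / MI)
and evaluation mode (deterministic / PSA) at every horizon, and writes the
result tables and a reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cea as cea_mod
from . import cgp as cgp_mod
from . import missing_data as md
from . import regression_engine as reg
from .costing import (
    CostTables,
    cost_antibiotic_course,
    cost_contacts_window,
    extrapolate_window,
    resolve_overlapping_admissions,
)
from .eq5d_utility import load_tariff, score_frame
from .trial_synth import DEFAULT_VISIT_WEEKS, TrialData

SEVERITY_OF_CATEGORY = {
    "major_amputation": "major_amp",
    "minor_amputation": "minor_amp_or_revasc",
    "revascularisation": "minor_amp_or_revasc",
}  # anything else -> "other"


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    horizons: tuple[int, ...] = (26, 52, 104)
    missing_modes: tuple[str, ...] = ("ACA", "MI")
    evaluation_modes: tuple[str, ...] = ("deterministic", "PSA")
    visit_weeks: list[int] = field(default_factory=lambda: list(DEFAULT_VISIT_WEEKS))
    lambdas: tuple[float, ...] = (20_000.0, 30_000.0)
    ceac_step: float = 1_000.0
    ceac_max: float = 50_000.0
    discount: bool = False
    discount_rate: float = cea_mod.DEFAULT_DISCOUNT_RATE
    n_psa_draws: int = 1000
    n_imputations: int = 100
    mi_burn_in: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        bad = [h for h in self.horizons if h not in self.visit_weeks]
        if bad:
            raise ValueError(f"horizons {bad} are not scheduled visit weeks")

    @property
    def rate(self) -> float | None:
        return self.discount_rate if self.discount else None


@dataclass
class AnalysisInputs:
    """Model-ready tables derived from one (possibly imputed) dataset."""

    patients: pd.DataFrame
    utilities: pd.DataFrame      # patient_id, week, utility (NaN = missing), status
    hosp_periods: pd.DataFrame   # patient_id, period_end, category
    abx_periods: pd.DataFrame    # patient_id, period_end, prescribed
    other_costs: pd.DataFrame    # patient_id, period_end, other_cost (NaN = missing)
    assumptions: cgp_mod.CostAssumptions
    visit_weeks: list[int]


def prepare_analysis(
    data: TrialData,
    tables: CostTables | None = None,
    visit_weeks: list[int] | None = None,
) -> AnalysisInputs:
    """Score, cost and periodise the raw trial tables."""
    tables = tables if tables is not None else CostTables()
    vw = list(visit_weeks) if visit_weeks is not None else list(DEFAULT_VISIT_WEEKS)
    patients = data.patients
    periods = list(zip(vw[:-1], vw[1:]))

    # --- utilities -------------------------------------------------------
    tariff = load_tariff()
    utilities = data.eq5d[["patient_id", "week"]].copy()
    utilities["utility"] = score_frame(data.eq5d, tariff)
    if "status" in data.eq5d.columns:
        utilities["status"] = data.eq5d["status"]

    # --- admissions: overlap resolution, costing, severity scale ---------
    adm = data.admissions
    if len(adm):
        adm = resolve_overlapping_admissions(adm, tables.admission)
        adm = adm.assign(
            cost=[
                float(cost_admission_row(tables, c, l))
                for c, l in zip(adm["category"], adm["los_days"])
            ],
            severity=[
                SEVERITY_OF_CATEGORY.get(c, "other") for c in adm["category"]
            ],
        )
    sev_rank = {s: i for i, s in enumerate(reg.HOSP_CATEGORIES)}
    hosp_rows, abx_rows, other_rows = [], [], []

    abx = data.antibiotics
    abx_costs = (
        pd.Series(
            [
                cost_antibiotic_course(d, f, u, t, tables.antibiotics)
                for d, f, u, t in zip(
                    abx["drug"], abx["form"], abx["units_per_day"], abx["duration_days"]
                )
            ],
            index=abx.index,
        )
        if len(abx)
        else pd.Series(dtype=float)
    )

    contact_cols = [
        c for c in data.contacts.columns if c in tables.unit.contacts
    ]
    contacts = data.contacts.set_index(["patient_id", "week"])
    samples = data.samples
    sample_cost = (
        samples["sample_type"].map(tables.unit.samples) if len(samples) else None
    )

    followup = patients.set_index("patient_id")["followup_week"]
    for pid in patients["patient_id"]:
        fu = float(followup[pid])
        for start, end in periods:
            if fu <= start:
                continue  # dead or censored before the period begins
            # hospitalisation severity: worst admission starting in period
            if len(adm):
                in_p = adm[
                    (adm["patient_id"] == pid)
                    & (adm["start_week"] >= start)
                    & (adm["start_week"] < end)
                ]
            else:
                in_p = adm
            if len(in_p):
                worst = max(in_p["severity"], key=lambda s: sev_rank[s])
            else:
                worst = "none"
            hosp_rows.append(
                {"patient_id": pid, "period_end": end, "category": worst}
            )
            if len(abx):
                hit = (
                    (abx["patient_id"] == pid)
                    & (abx["week"] >= start)
                    & (abx["week"] < end)
                )
            else:
                hit = np.zeros(0, dtype=bool)
            abx_rows.append(
                {"patient_id": pid, "period_end": end, "prescribed": int(hit.any())}
            )
            # other NHS cost: extrapolated contact window + sampling costs
            key = (pid, end)
            if key in contacts.index:
                row = contacts.loc[key]
                if row[contact_cols].isna().any():
                    window = np.nan
                else:
                    window = cost_contacts_window(
                        {c: float(row[c]) for c in contact_cols}, tables.unit
                    )
            else:
                window = np.nan
            if np.isnan(window):
                other = np.nan
            else:
                other = extrapolate_window(window, end - start)
                if len(samples):
                    # baseline (week 0) samples fall inside the first period
                    in_s = (
                        (samples["patient_id"] == pid)
                        & (samples["week"] >= start)
                        & (samples["week"] < end)
                    )
                    other += float(sample_cost[in_s].sum())
            other_rows.append(
                {"patient_id": pid, "period_end": end, "other_cost": other}
            )

    hosp_periods = pd.DataFrame(hosp_rows)
    abx_periods = pd.DataFrame(abx_rows)
    other_costs = pd.DataFrame(other_rows)

    # --- observed expected event costs ----------------------------------
    assumptions = cgp_mod.CostAssumptions.from_tables(tables)
    if len(adm):
        observed = adm.groupby("severity")["cost"].mean()
        for sev, cost in observed.items():
            assumptions.hosp_category_costs[sev] = float(cost)
    if len(abx_costs):
        assumptions.expected_course_cost = float(abx_costs.mean())

    return AnalysisInputs(
        patients=patients,
        utilities=utilities,
        hosp_periods=hosp_periods,
        abx_periods=abx_periods,
        other_costs=other_costs,
        assumptions=assumptions,
        visit_weeks=vw,
    )


def cost_admission_row(tables: CostTables, category: str, los_days: float) -> float:
    from .costing import cost_admission

    return cost_admission(category, los_days, tables.admission)


def fit_models(
    inputs: AnalysisInputs,
    utilities: pd.DataFrame | None = None,
    other_costs: pd.DataFrame | None = None,
) -> cgp_mod.FittedModels:
    """Fit the five regressions (optionally on imputed outcome tables)."""
    patients = inputs.patients
    vw = inputs.visit_weeks
    util = utilities if utilities is not None else inputs.utilities
    other = other_costs if other_costs is not None else inputs.other_costs

    survival = reg.fit_survival(
        patients, patients["followup_week"], patients["died"], family="lognormal"
    )
    center = survival.age_center
    utility = reg.fit_lmm(
        util.rename(columns={"week": "time"}),
        patients,
        outcome="utility",
        time_col="time",
        visit_weeks=vw,
        age_center=center,
    )
    other_fit = reg.fit_lmm(
        other.rename(columns={"period_end": "time"}),
        patients,
        outcome="other_cost",
        time_col="time",
        visit_weeks=vw[1:],
        age_center=center,
    )
    hosp = reg.fit_hospitalisation_ordinal(inputs.hosp_periods, patients, age_center=center)
    abx = reg.fit_antibiotic_logit(inputs.abx_periods, patients, age_center=center)
    fits = cgp_mod.FittedModels(
        survival=survival,
        utility=utility,
        hospitalisation=hosp,
        antibiotics=abx,
        other_cost=other_fit,
    )
    fits.validate()
    return fits


# ---------------------------------------------------------------------------
# multiple imputation plumbing


def _wide_outcomes(inputs: AnalysisInputs) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Patient-wide table of outcomes + predictors for FCS imputation."""
    vw = inputs.visit_weeks
    pat = inputs.patients.set_index("patient_id")
    wide = pd.DataFrame(index=pat.index)
    wide["arm"] = (pat["arm"] == "tissue").astype(float)
    wide["age"] = pat["age"]
    wide["sex_male"] = (pat["sex"] == "male").astype(float)
    for c in ("n_ulcers", "ulcer_area", "ulcer_duration"):
        wide[c] = pat[c].astype(float)
    wide["died"] = pat["died"].astype(float)
    wide["followup_week"] = pat["followup_week"].astype(float)
    total_hosp = inputs.hosp_periods.assign(
        any_adm=lambda d: (d["category"] != "none").astype(float)
    ).groupby("patient_id")["any_adm"].sum()
    wide["n_admission_periods"] = total_hosp.reindex(wide.index).fillna(0.0)
    total_abx = inputs.abx_periods.groupby("patient_id")["prescribed"].sum()
    wide["n_abx_periods"] = total_abx.reindex(wide.index).fillna(0.0)

    util_cols, cost_cols = [], []
    u = inputs.utilities.pivot_table(
        index="patient_id", columns="week", values="utility", dropna=False
    )
    for w in vw:
        col = f"utility_w{w}"
        wide[col] = u[w].reindex(wide.index) if w in u.columns else np.nan
        util_cols.append(col)
    oc = inputs.other_costs.pivot_table(
        index="patient_id", columns="period_end", values="other_cost", dropna=False
    )
    for w in vw[1:]:
        col = f"othercost_w{w}"
        wide[col] = oc[w].reindex(wide.index) if w in oc.columns else np.nan
        cost_cols.append(col)
    predictors = [
        "arm", "age", "sex_male", "n_ulcers", "ulcer_area", "ulcer_duration",
        "died", "followup_week", "n_admission_periods", "n_abx_periods",
    ]
    return wide, util_cols + cost_cols, predictors


def _long_from_wide(
    inputs: AnalysisInputs, wide: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rebuild long utility/other-cost tables from an imputed wide table.

    Visits at which the patient was already dead are excluded (death is
    observed, not missing); everything else is complete after imputation.
    """
    vw = inputs.visit_weeks
    pat = inputs.patients.set_index("patient_id")
    death_known = pat["died"].astype(bool)
    fu = pat["followup_week"]
    util_rows, cost_rows = [], []
    for pid in wide.index:
        dead_after = fu[pid] if death_known[pid] else np.inf
        for w in vw:
            if w >= dead_after:
                continue
            util_rows.append(
                {"patient_id": pid, "week": w, "utility": wide.loc[pid, f"utility_w{w}"]}
            )
        for w in vw[1:]:
            if w >= dead_after:
                continue
            cost_rows.append(
                {
                    "patient_id": pid,
                    "period_end": w,
                    "other_cost": wide.loc[pid, f"othercost_w{w}"],
                }
            )
    return pd.DataFrame(util_rows), pd.DataFrame(cost_rows)


def mi_fit_sets(
    inputs: AnalysisInputs, m: int, burn_in: int, seed: int
) -> list[cgp_mod.FittedModels]:
    """One FittedModels per imputed dataset (self-reported outcomes refitted)."""
    wide, impute_cols, predictors = _wide_outcomes(inputs)
    cfg = md.ImputationConfig(n_imputations=m, burn_in=burn_in, seed=seed)
    completed = md.mi_fcs(wide, impute_cols, predictors, cfg)
    out = []
    for w in completed:
        util_long, cost_long = _long_from_wide(inputs, w)
        out.append(fit_models(inputs, utilities=util_long, other_costs=cost_long))
    return out


# ---------------------------------------------------------------------------
# analysis execution


def _deterministic_result(
    fits: cgp_mod.FittedModels,
    inputs: AnalysisInputs,
    horizon: int,
    rate: float | None,
    tag: str,
) -> cea_mod.CeResult:
    tissue, swab = cgp_mod.cgp_contrast(
        fits, inputs.patients, horizon, inputs.assumptions, inputs.visit_weeks, rate
    )
    return cea_mod.CeResult(
        horizon_weeks=horizon,
        cost_tissue=tissue.total_cost,
        cost_swab=swab.total_cost,
        qaly_tissue=tissue.qaly,
        qaly_swab=swab.qaly,
        missing_data_mode=tag,
        evaluation_mode="deterministic",
        cost_components={
            "tissue": {
                "antibiotics": tissue.cost_antibiotics,
                "hospitalisation": tissue.cost_hospitalisation,
                "other": tissue.cost_other,
            },
            "swab": {
                "antibiotics": swab.cost_antibiotics,
                "hospitalisation": swab.cost_hospitalisation,
                "other": swab.cost_other,
            },
        },
    )


def _pool_deterministic(
    results: list[cea_mod.CeResult], horizon: int
) -> cea_mod.CeResult:
    """Point-estimate pooling of per-imputation deterministic results."""
    def mean(attr):
        return float(np.mean([getattr(r, attr) for r in results]))

    comp = {}
    for armname in ("tissue", "swab"):
        comp[armname] = {
            k: float(np.mean([r.cost_components[armname][k] for r in results]))
            for k in ("antibiotics", "hospitalisation", "other")
        }
    return cea_mod.CeResult(
        horizon_weeks=horizon,
        cost_tissue=mean("cost_tissue"),
        cost_swab=mean("cost_swab"),
        qaly_tissue=mean("qaly_tissue"),
        qaly_swab=mean("qaly_swab"),
        missing_data_mode="MI",
        evaluation_mode="deterministic",
        cost_components=comp,
    )


def _psa_over_imputations(
    fit_sets: list[cgp_mod.FittedModels],
    inputs: AnalysisInputs,
    horizon: int,
    n_draws: int,
    rate: float | None,
    rng: np.random.Generator,
) -> cea_mod.PsaDraws:
    """PSA draws cycled over the imputed datasets (parameter uncertainty
    within imputations, between-imputation variability across the cycle)."""
    m = len(fit_sets)
    per = [n_draws // m + (1 if i < n_draws % m else 0) for i in range(m)]
    frames = []
    for fits, k in zip(fit_sets, per):
        if k == 0:
            continue
        draws = cea_mod.psa_run(
            fits, inputs.patients, horizon, inputs.assumptions,
            n_draws=k, seed=rng, visit_weeks=inputs.visit_weeks, discount_rate=rate,
        )
        frames.append(draws.draws)
    return cea_mod.PsaDraws(draws=pd.concat(frames, ignore_index=True))


@dataclass
class ReportBundle:
    results: list[cea_mod.CeResult]
    psa_draws: dict[tuple[int, str], cea_mod.PsaDraws]
    manifest: dict

    def summary_table(self, lambdas=(20_000.0, 30_000.0)) -> pd.DataFrame:
        return pd.DataFrame([r.row(lambdas) for r in self.results])

    def components_table(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            if not r.cost_components:
                continue
            for armname, comp in r.cost_components.items():
                rows.append(
                    {
                        "horizon_weeks": r.horizon_weeks,
                        "missing_data": r.missing_data_mode,
                        "evaluation": r.evaluation_mode,
                        "arm": armname,
                        **comp,
                        "total": sum(comp.values()),
                        "qaly": r.qaly_tissue if armname == "tissue" else r.qaly_swab,
                    }
                )
        return pd.DataFrame(rows)


def run_pipeline(
    data: TrialData,
    config: RunConfig,
    tables: CostTables | None = None,
) -> ReportBundle:
    """Execute every requested ACA/MI x deterministic/PSA combination."""
    t0 = time.time()
    inputs = prepare_analysis(data, tables, config.visit_weeks)
    rng = np.random.default_rng(config.seed)
    warnings_log: list[str] = []

    fits_aca = fit_models(inputs)
    fit_sets_mi: list[cgp_mod.FittedModels] | None = None
    if "MI" in config.missing_modes:
        fit_sets_mi = mi_fit_sets(
            inputs, config.n_imputations, config.mi_burn_in, seed=config.seed + 1
        )

    results: list[cea_mod.CeResult] = []
    psa_draws: dict[tuple[int, str], cea_mod.PsaDraws] = {}
    for horizon in config.horizons:
        rate = config.rate
        for mode in config.missing_modes:
            if "deterministic" in config.evaluation_modes:
                if mode == "ACA":
                    results.append(
                        _deterministic_result(fits_aca, inputs, horizon, rate, "ACA")
                    )
                else:
                    per_imp = [
                        _deterministic_result(f, inputs, horizon, rate, "MI")
                        for f in fit_sets_mi
                    ]
                    results.append(_pool_deterministic(per_imp, horizon))
            if "PSA" in config.evaluation_modes:
                if mode == "ACA":
                    draws = cea_mod.psa_run(
                        fits_aca, inputs.patients, horizon, inputs.assumptions,
                        n_draws=config.n_psa_draws, seed=rng,
                        visit_weeks=inputs.visit_weeks, discount_rate=rate,
                    )
                else:
                    draws = _psa_over_imputations(
                        fit_sets_mi, inputs, horizon, config.n_psa_draws, rate, rng
                    )
                psa_draws[(horizon, mode)] = draws
                results.append(draws.mean_result(horizon, missing_data_mode=mode))

    manifest = {
        "config": asdict(config),
        "n_patients": int(len(inputs.patients)),
        "survival_family": fits_aca.survival.family,
        "elapsed_seconds": round(time.time() - t0, 2),
        "warnings": warnings_log,
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
    }
    return ReportBundle(results=results, psa_draws=psa_draws, manifest=manifest)


def write_report(bundle: ReportBundle, outdir: str | Path, config: RunConfig) -> None:
    """Write the result tables, CEAC/plane data and the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.summary_table(config.lambdas).to_csv(outdir / "ce_results.csv", index=False)
    comp = bundle.components_table()
    if len(comp):
        comp.to_csv(outdir / "cost_components.csv", index=False)
    grid = np.arange(0.0, config.ceac_max + config.ceac_step / 2, config.ceac_step)
    ceac_frames, plane_frames = [], []
    for (horizon, mode), draws in bundle.psa_draws.items():
        c = cea_mod.ceac(draws, grid)
        c.insert(0, "horizon_weeks", horizon)
        c.insert(1, "missing_data", mode)
        ceac_frames.append(c)
        p = cea_mod.ce_plane(draws)
        p.insert(0, "horizon_weeks", horizon)
        p.insert(1, "missing_data", mode)
        plane_frames.append(p)
    if ceac_frames:
        pd.concat(ceac_frames, ignore_index=True).to_csv(
            outdir / "ceac.csv", index=False
        )
        pd.concat(plane_frames, ignore_index=True).to_csv(
            outdir / "ce_plane.csv", index=False
        )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2)
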