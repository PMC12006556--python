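"""Synthetic two-arm wound-sampling trial generator.

The analysis pipeline was designed for patient-level data that are not
publicly deposited, so this module generates datasets with the same
statistical structure: a two-arm randomised trial (swab vs tissue sampling
of infected diabetic foot ulcers) with staggered recruitment, a fixed
administrative stop date, scheduled visits at weeks 0/4/12/26/39/52/104,
and the outcome streams the economic evaluation consumes:

* baseline covariates calibrated to the published arm-specific moments
  (age, sex, ulcer count/area/duration);
* death times from a lognormal accelerated-failure-time model;
* EQ-5D-3L profiles: a latent utility from a linear mixed model (patient
  random intercept) mapped to the profile whose UK-TTO score is nearest;
* per-period hospital admissions from a proportional-odds model on the
  severity scale none < other < minor amputation/revascularisation <
  major amputation, expanded to concrete costed admission events;
* antibiotic courses from a per-period logistic model with a realistic
  drug mix;
* healthcare-contact counts per 4-week recall window from Poisson rates;
* wound-sample events (baseline + follow-up sampling).

The generative families deliberately match the analysis models, so the
regression engine is well-specified on these data and parameter-recovery
tests are meaningful.  Missingness is applied in two layers that mirror
the trial's attrition: administrative censoring from the staggered
recruitment against a fixed stop week, and missing-at-random dropout of
the self-reported streams whose hazard depends only on observed baseline
covariates and the previous utility.  Researcher-collected streams
(deaths, admissions, antibiotics) are never made missing.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .eq5d_utility import DIMENSIONS, _NearestScorer, load_tariff

DEFAULT_VISIT_WEEKS = [0, 4, 12, 26, 39, 52, 104]

# population age centring used by the generator's linear predictors
GENERATOR_AGE_CENTER = 62.7

_DEFAULT_BASELINE = {
    # arm-specific marginals matched to the published baseline table
    "age_mean": {"swab": 65.7, "tissue": 59.7},
    "age_sd": {"swab": 11.39, "tissue": 12.98},
    "age_bounds": [18.0, 100.0],
    "p_male": {"swab": 0.867, "tissue": 0.784},
    # lognormal parameters matched to published medians / IQRs
    "ulcer_area_mu": {"swab": 0.7885, "tissue": 0.0953},
    "ulcer_area_sigma": {"swab": 1.412, "tissue": 1.352},
    "ulcer_duration_mu": {"swab": 0.0, "tissue": 0.6931},
    "ulcer_duration_sigma": {"swab": 1.328, "tissue": 1.541},
    "extra_ulcer_rate": 0.32,  # n_ulcers = 1 + Poisson(rate)
}

_DEFAULT_SURVIVAL = {
    # log T = intercept + arm + covariate terms + sigma * N(0,1), weeks
    "intercept": 5.64,
    "arm": 0.60,
    "age": -0.02,
    "sex_male": 0.05,
    "n_ulcers": -0.05,
    "ulcer_area": -0.01,
    "ulcer_duration": 0.0,
    "sigma": 1.3,
}

_DEFAULT_UTILITY = {
    "intercept": 0.52,
    "week_effects": {4: 0.03, 12: 0.08, 26: 0.01, 39: -0.11, 52: -0.05, 104: -0.25},
    "arm_week_effects": {4: 0.05, 12: -0.05, 26: 0.0, 39: -0.05, 52: -0.15, 104: 0.10},
    "arm": 0.0,  # no arm effect at baseline (randomisation)
    "age": -0.004,
    "sex_male": 0.02,
    "n_ulcers": -0.02,
    "ulcer_area": -0.005,
    "ulcer_duration": -0.002,
    "re_sd": 0.25,
    "resid_sd": 0.18,
}

_DEFAULT_HOSPITALISATION = {
    # proportional odds: P(Y <= j) = expit(threshold_j - eta)
    "thresholds": [0.847, 2.31, 3.66],
    "arm": 0.25,
    "age": 0.01,
    "sex_male": 0.0,
    "n_ulcers": 0.1,
    "ulcer_area": 0.02,
    "ulcer_duration": 0.0,
    # expansion of severity categories into concrete admission categories
    "other_mix": {"cellulitis": 0.35, "osteomyelitis": 0.2,
                  "surgical_debridement": 0.25, "other": 0.2},
    "minor_mix": {"minor_amputation": 0.55, "revascularisation": 0.45},
}

_DEFAULT_ANTIBIOTICS = {
    "intercept": -0.2,
    "arm": 0.60,
    "age": 0.0,
    "sex_male": 0.0,
    "n_ulcers": 0.05,
    "ulcer_area": 0.01,
    "ulcer_duration": 0.0,
    # (drug, form, units/day, duration days, weight)
    "drug_mix": [
        ["flucloxacillin", "500 mg capsule", 4, 7, 0.30],
        ["co-amoxiclav", "500 mg/125 mg tablet", 3, 7, 0.25],
        ["clindamycin", "300 mg capsule", 4, 7, 0.15],
        ["ceftriaxone", "2 g vial", 1, 7, 0.12],
        ["ertapenem", "1 g vial", 1, 14, 0.12],
        ["linezolid", "600 mg capsule", 2, 10, 0.06],
    ],
}

_DEFAULT_CONTACTS = {
    # Poisson rates per 4-week recall window
    "rates": {"gp": 0.8, "practice_nurse": 0.7, "district_nurse": 2.0,
              "foot_clinic": 1.2, "outpatient": 0.4, "a_and_e": 0.1},
    # tissue-arm rate multiplier up to week 52; reverts to parity afterwards
    "arm_multiplier": 1.25,
    "arm_multiplier_after_52": 1.0,
    "resample_prob": 0.25,  # follow-up wound sampling per visit
    "bone_sample_prob": 0.03,
}

_DEFAULT_MISSINGNESS = {
    # marginal per-visit dropout probability of the self-reported
    # questionnaire among patients alive and inside the admin window,
    # calibrated to the published attrition pattern
    "visit_rates": [0.055, 0.19, 0.33, 0.43, 0.52, 0.50, 0.78],
    "age_logit": 0.01,       # per year above the population mean
    "prev_utility_logit": -0.8,  # lower previous utility -> more dropout
}


@dataclass
class TrialConfig:
    """Generative parameters for one synthetic trial."""

    n_per_arm: int = 75
    recruitment_window_weeks: int = 155
    admin_stop_week: int = 207  # last follow-up a year after recruitment closed
    visit_weeks: list[int] = field(default_factory=lambda: list(DEFAULT_VISIT_WEEKS))
    seed: int = 2019
    age_center: float = GENERATOR_AGE_CENTER
    baseline: dict = field(default_factory=lambda: copy.deepcopy(_DEFAULT_BASELINE))
    survival: dict = field(default_factory=lambda: copy.deepcopy(_DEFAULT_SURVIVAL))
    utility: dict = field(default_factory=lambda: copy.deepcopy(_DEFAULT_UTILITY))
    hospitalisation: dict = field(
        default_factory=lambda: copy.deepcopy(_DEFAULT_HOSPITALISATION)
    )
    antibiotics: dict = field(default_factory=lambda: copy.deepcopy(_DEFAULT_ANTIBIOTICS))
    contacts: dict = field(default_factory=lambda: copy.deepcopy(_DEFAULT_CONTACTS))
    missingness: dict = field(default_factory=lambda: copy.deepcopy(_DEFAULT_MISSINGNESS))

    def __post_init__(self) -> None:
        if self.n_per_arm < 2:
            raise ValueError("n_per_arm must be at least 2")
        vw = self.visit_weeks
        if vw[0] != 0 or any(b <= a for a, b in zip(vw, vw[1:])):
            raise ValueError("visit_weeks must be strictly increasing and start at 0")
        for p in self.baseline["p_male"].values():
            if not 0 <= p <= 1:
                raise ValueError("p_male must lie in [0, 1]")
        for r in self.missingness["visit_rates"]:
            if not 0 <= r <= 1:
                raise ValueError("missingness rates must lie in [0, 1]")
        if len(self.missingness["visit_rates"]) != len(vw):
            raise ValueError("one missingness rate per scheduled visit required")

    @classmethod
    def null_effects(cls, **kwargs) -> "TrialConfig":
        """Config with identical arms: common baseline moments, zero arm effects."""
        cfg = cls(**kwargs)
        for key in ("age_mean", "age_sd", "p_male", "ulcer_area_mu",
                    "ulcer_area_sigma", "ulcer_duration_mu", "ulcer_duration_sigma"):
            pooled = float(np.mean(list(cfg.baseline[key].values())))
            cfg.baseline[key] = {"swab": pooled, "tissue": pooled}
        cfg.survival["arm"] = 0.0
        cfg.utility["arm"] = 0.0
        cfg.utility["arm_week_effects"] = {
            w: 0.0 for w in cfg.utility["arm_week_effects"]
        }
        cfg.hospitalisation["arm"] = 0.0
        cfg.antibiotics["arm"] = 0.0
        cfg.contacts["arm_multiplier"] = 1.0
        cfg.contacts["arm_multiplier_after_52"] = 1.0
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrialConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


@dataclass
class TrialData:
    """The generated tables, pre- or post-missingness."""

    patients: pd.DataFrame
    eq5d: pd.DataFrame
    admissions: pd.DataFrame
    antibiotics: pd.DataFrame
    contacts: pd.DataFrame
    samples: pd.DataFrame

    _TABLES = ("patients", "eq5d", "admissions", "antibiotics", "contacts", "samples")

    def write_csv(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in self._TABLES:
            getattr(self, name).to_csv(outdir / f"{name}.csv", index=False, na_rep="NA")

    @classmethod
    def read_csv(cls, indir: str | Path) -> "TrialData":
        indir = Path(indir)
        frames = {
            name: pd.read_csv(indir / f"{name}.csv", na_values=["NA"])
            for name in cls._TABLES
        }
        return cls(**frames)


def _linear_predictor(patients: pd.DataFrame, coefs: dict, age_center: float) -> np.ndarray:
    arm = (patients["arm"] == "tissue").astype(float).to_numpy()
    male = (patients["sex"] == "male").astype(float).to_numpy()
    return (
        coefs.get("intercept", 0.0)
        + coefs.get("arm", 0.0) * arm
        + coefs.get("age", 0.0) * (patients["age"].to_numpy() - age_center)
        + coefs.get("sex_male", 0.0) * male
        + coefs.get("n_ulcers", 0.0) * patients["n_ulcers"].to_numpy()
        + coefs.get("ulcer_area", 0.0) * patients["ulcer_area"].to_numpy()
        + coefs.get("ulcer_duration", 0.0) * patients["ulcer_duration"].to_numpy()
    )


def generate_baseline(config: TrialConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Baseline covariates and recruitment calendar for both arms."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    b = config.baseline
    lo, hi = b["age_bounds"]
    rows = []
    for arm in ("swab", "tissue"):
        n = config.n_per_arm
        m, s = b["age_mean"][arm], b["age_sd"][arm]
        if s == 0:
            age = np.full(n, m)
        else:
            a, z = (lo - m) / s, (hi - m) / s
            age = stats.truncnorm.rvs(a, z, loc=m, scale=s, size=n, random_state=rng)
        rows.append(
            pd.DataFrame(
                {
                    "arm": arm,
                    "age": age,
                    "sex": np.where(rng.random(n) < b["p_male"][arm], "male", "female"),
                    "n_ulcers": 1 + rng.poisson(b["extra_ulcer_rate"], n),
                    "ulcer_area": rng.lognormal(
                        b["ulcer_area_mu"][arm], b["ulcer_area_sigma"][arm], n
                    ),
                    "ulcer_duration": rng.lognormal(
                        b["ulcer_duration_mu"][arm], b["ulcer_duration_sigma"][arm], n
                    ),
                    "recruitment_week": rng.integers(
                        0, config.recruitment_window_weeks, n
                    ),
                }
            )
        )
    out = pd.concat(rows, ignore_index=True)
    out.insert(0, "patient_id", [f"P{i:04d}" for i in range(len(out))])
    return out


def simulate_outcomes(
    patients: pd.DataFrame,
    config: TrialConfig,
    rng: np.random.Generator | None = None,
) -> TrialData:
    """Complete (pre-missingness) outcome streams for every patient.

    No stream carries any observation after the patient's death week.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    n = len(patients)
    vw = config.visit_weeks
    scorer = _NearestScorer(load_tariff())

    # --- survival -------------------------------------------------------
    sv = config.survival
    mu = _linear_predictor(patients, sv, config.age_center)
    death_week = np.exp(mu + sv["sigma"] * rng.standard_normal(n))
    patients = patients.copy()
    patients["death_week"] = death_week

    # --- EQ-5D latent utilities -> profiles ------------------------------
    uc = config.utility
    base_lp = _linear_predictor(patients, uc, config.age_center)
    b_i = rng.normal(0.0, uc["re_sd"], n)
    arm_ind = (patients["arm"] == "tissue").astype(float).to_numpy()
    eq_rows = []
    for w in vw:
        lat = (
            base_lp
            + uc["week_effects"].get(w, 0.0)
            + uc["arm_week_effects"].get(w, 0.0) * arm_ind
            + b_i
            + rng.normal(0.0, uc["resid_sd"], n)
        )
        labels, _ = scorer.map(lat)
        alive = death_week > w
        frame = pd.DataFrame(
            {
                "patient_id": patients["patient_id"],
                "week": w,
                **{
                    dim: [int(lab[k]) for lab in labels]
                    for k, dim in enumerate(DIMENSIONS)
                },
            }
        )
        eq_rows.append(frame.loc[alive])
    eq5d = pd.concat(eq_rows, ignore_index=True)

    # --- hospital admissions per inter-visit period ----------------------
    hc = config.hospitalisation
    eta = _linear_predictor(patients, hc, config.age_center)
    th = np.asarray(hc["thresholds"], dtype=float)
    adm_rows = []
    from .costing import load_admission_costs

    adm_table = load_admission_costs()
    for start, end in zip(vw[:-1], vw[1:]):
        cum = stats.logistic.cdf(th[None, :] - eta[:, None])
        u = rng.random(n)
        sev = (u[:, None] > cum).sum(axis=1)  # 0=none .. 3=major
        for i in np.flatnonzero(sev > 0):
            if death_week[i] <= start:
                continue
            if sev[i] == 3:
                category = "major_amputation"
            elif sev[i] == 2:
                mix = hc["minor_mix"]
                category = rng.choice(list(mix), p=_norm(list(mix.values())))
            else:
                mix = hc["other_mix"]
                category = rng.choice(list(mix), p=_norm(list(mix.values())))
            start_week = float(rng.uniform(start, min(end, max(death_week[i], start + 1e-6))))
            los = int(rng.poisson(adm_table.categories[category].average_length_of_stay))
            adm_rows.append(
                {
                    "patient_id": patients["patient_id"].iloc[i],
                    "category": category,
                    "start_week": round(start_week, 2),
                    "end_week": round(start_week + max(los, 1) / 7.0, 2),
                    "los_days": los,
                }
            )
    admissions = pd.DataFrame(
        adm_rows,
        columns=["patient_id", "category", "start_week", "end_week", "los_days"],
    )

    # --- antibiotic prescriptions ---------------------------------------
    ac = config.antibiotics
    p_rx = stats.logistic.cdf(_linear_predictor(patients, ac, config.age_center))
    mix = ac["drug_mix"]
    weights = _norm([row[4] for row in mix])
    abx_rows = []
    for start, end in zip(vw[:-1], vw[1:]):
        hit = rng.random(n) < p_rx
        for i in np.flatnonzero(hit):
            if death_week[i] <= start:
                continue
            drug, form, upd, dur, _w = mix[rng.choice(len(mix), p=weights)]
            week = float(rng.uniform(start, min(end, max(death_week[i], start + 1e-6))))
            abx_rows.append(
                {
                    "patient_id": patients["patient_id"].iloc[i],
                    "week": round(week, 2),
                    "drug": drug,
                    "form": form,
                    "units_per_day": upd,
                    "duration_days": dur,
                }
            )
    antibiotics = pd.DataFrame(
        abx_rows,
        columns=["patient_id", "week", "drug", "form", "units_per_day", "duration_days"],
    )

    # --- healthcare contacts (4-week recall windows) ---------------------
    cc = config.contacts
    contact_rows = []
    for w in vw[1:]:
        mult = np.where(
            arm_ind > 0,
            cc["arm_multiplier"] if w <= 52 else cc["arm_multiplier_after_52"],
            1.0,
        )
        alive = death_week > w
        counts = {
            kind: rng.poisson(rate * mult) for kind, rate in cc["rates"].items()
        }
        frame = pd.DataFrame(
            {"patient_id": patients["patient_id"], "week": w, **counts}
        )
        contact_rows.append(frame.loc[alive])
    contacts = pd.concat(contact_rows, ignore_index=True)

    # --- wound samples ---------------------------------------------------
    sample_rows = [
        pd.DataFrame(
            {
                "patient_id": patients["patient_id"],
                "week": 0,
                "sample_type": patients["arm"],
            }
        )
    ]
    for w in vw[1:]:
        alive = death_week > w
        resample = (rng.random(n) < cc["resample_prob"]) & alive
        bone = (rng.random(n) < cc["bone_sample_prob"]) & alive
        sample_rows.append(
            pd.DataFrame(
                {
                    "patient_id": patients["patient_id"][resample],
                    "week": w,
                    "sample_type": patients["arm"][resample],
                }
            )
        )
        sample_rows.append(
            pd.DataFrame(
                {
                    "patient_id": patients["patient_id"][bone],
                    "week": w,
                    "sample_type": "bone",
                }
            )
        )
    samples = pd.concat(sample_rows, ignore_index=True)

    return TrialData(
        patients=patients,
        eq5d=eq5d,
        admissions=admissions,
        antibiotics=antibiotics,
        contacts=contacts,
        samples=samples,
    )


def _norm(w) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    return w / w.sum()


def apply_missingness(
    data: TrialData,
    config: TrialConfig,
    rng: np.random.Generator | None = None,
) -> TrialData:
    """Administrative censoring plus MAR dropout of self-reported streams.

    Administrative censoring removes every visit whose calendar week
    (recruitment + follow-up) falls after the trial stop week — hence it is
    monotone in follow-up time.  MAR dropout hits the patient questionnaire
    (EQ-5D and contact counts jointly) with a per-visit probability
    depending on age and the previous observed utility.  The returned eq5d
    table is a full patient-by-visit lattice with a ``status`` column
    (observed / missing_dropout / missing_admin / dead) so attrition
    accounting stays possible; researcher-collected streams are truncated
    at the admin stop but never made missing.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    vw = config.visit_weeks
    mc = config.missingness
    patients = data.patients
    n = len(patients)
    death = patients["death_week"].to_numpy()
    recruit = patients["recruitment_week"].to_numpy()
    age = patients["age"].to_numpy()

    from .eq5d_utility import load_tariff, score_frame

    utilities = score_frame(data.eq5d, load_tariff())
    eq_obs = data.eq5d.assign(_util=utilities).set_index(["patient_id", "week"])

    prev_util = np.full(n, 0.55)  # population-level prior before any observation
    lattice_rows = []
    dropped: dict[tuple, str] = {}
    for j, w in enumerate(vw):
        base = mc["visit_rates"][j]
        base_logit = np.log(base / (1 - base)) if 0 < base < 1 else None
        for i in range(n):
            pid = patients["patient_id"].iloc[i]
            if death[i] <= w:
                status = "dead"
            elif recruit[i] + w > config.admin_stop_week:
                status = "missing_admin"
            elif base is not None and base_logit is not None:
                lp = (
                    base_logit
                    + mc["age_logit"] * (age[i] - config.age_center)
                    + mc["prev_utility_logit"] * (prev_util[i] - 0.55)
                )
                status = "missing_dropout" if rng.random() < stats.logistic.cdf(lp) else "observed"
            elif base == 1:
                status = "missing_dropout"
            else:
                status = "observed"
            lattice_rows.append({"patient_id": pid, "week": w, "status": status})
            if status == "observed":
                key = (pid, w)
                if key in eq_obs.index:
                    prev_util[i] = float(eq_obs.loc[key, "_util"])
            else:
                dropped[(pid, w)] = status

    lattice = pd.DataFrame(lattice_rows)
    eq5d = lattice.merge(
        data.eq5d, on=["patient_id", "week"], how="left"
    )
    mask = eq5d["status"] != "observed"
    eq5d.loc[mask, list(DIMENSIONS)] = np.nan

    contacts = lattice.merge(data.contacts, on=["patient_id", "week"], how="inner")
    count_cols = [c for c in data.contacts.columns if c not in ("patient_id", "week")]
    contacts.loc[contacts["status"] != "observed", count_cols] = np.nan

    # researcher-collected streams: truncate at the admin stop, keep complete
    def _trunc(df: pd.DataFrame, week_col: str) -> pd.DataFrame:
        cal_limit = pd.Series(
            config.admin_stop_week - recruit, index=patients["patient_id"]
        )
        lim = df["patient_id"].map(cal_limit)
        return df.loc[df[week_col] <= lim].reset_index(drop=True)

    admissions = _trunc(data.admissions, "start_week")
    antibiotics = _trunc(data.antibiotics, "week")
    samples = _trunc(data.samples, "week")

    # observed survival: censored at admin stop and the final scheduled visit
    censor = np.minimum(config.admin_stop_week - recruit, float(vw[-1]))
    observed_time = np.minimum(death, censor)
    patients = patients.copy()
    patients["followup_week"] = np.maximum(observed_time, 1e-6)
    patients["died"] = (death <= censor).astype(int)

    return TrialData(
        patients=patients,
        eq5d=eq5d,
        admissions=admissions,
        antibiotics=antibiotics,
        contacts=contacts,
        samples=samples,
    )


def generate_trial(config: TrialConfig) -> TrialData:
    """Baseline -> outcomes -> missingness, all from the config seed."""
    rng = np.random.default_rng(config.seed)
    patients = generate_baseline(config, rng)
    complete = simulate_outcomes(patients, config, rng)
    return apply_missingness(complete, config, rng)
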