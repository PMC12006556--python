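"""EQ-5D-3L utility scoring with the UK general-population TTO tariff.

An EQ-5D-3L health state is a profile of five dimensions (mobility,
self-care, usual activities, pain/discomfort, anxiety/depression), each at
level 1 (no problems), 2 (some problems) or 3 (extreme problems).  The UK
time-trade-off tariff maps each of the 243 profiles to a utility on a scale
where 1 is full health and 0 is death; states worse than death score below
zero (the all-3s state scores -0.594 under the default tariff).

Scoring is additive-decrement:

    U = 1 - c * [any level > 1] - sum(dimension decrements) - n3 * [any level = 3]
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

DIMENSIONS = (
    "mobility",
    "self_care",
    "usual_activities",
    "pain_discomfort",
    "anxiety_depression",
)


@dataclass(frozen=True)
class Eq5dProfile:
    """One EQ-5D-3L health state; each dimension at level 1, 2 or 3."""

    mobility: int
    self_care: int
    usual_activities: int
    pain_discomfort: int
    anxiety_depression: int

    def __post_init__(self) -> None:
        for dim in DIMENSIONS:
            level = getattr(self, dim)
            if level not in (1, 2, 3):
                raise ValueError(
                    f"EQ-5D-3L level for {dim!r} must be 1, 2 or 3; got {level!r}"
                )

    @property
    def levels(self) -> tuple[int, int, int, int, int]:
        return tuple(getattr(self, d) for d in DIMENSIONS)

    @classmethod
    def from_string(cls, state: str) -> "Eq5dProfile":
        """Parse a 5-digit state label such as ``"21123"``."""
        if len(state) != 5 or not state.isdigit():
            raise ValueError(f"expected a 5-digit EQ-5D-3L state, got {state!r}")
        return cls(*(int(ch) for ch in state))

    def __str__(self) -> str:
        return "".join(str(v) for v in self.levels)


@dataclass(frozen=True)
class UtilityTariff:
    """Additive-decrement EQ-5D-3L value set.

    ``decrements[dim]`` holds the level-2 and level-3 decrements for each
    dimension; ``any_problem_decrement`` is subtracted once if any dimension
    is above level 1 and ``n3_decrement`` once if any dimension is at
    level 3.  All decrements are non-negative.
    """

    name: str
    any_problem_decrement: float
    n3_decrement: float
    decrements: dict[str, tuple[float, float]]  # dim -> (level2, level3)
    full_health_constant: float = 1.0

    def __post_init__(self) -> None:
        if self.any_problem_decrement < 0 or self.n3_decrement < 0:
            raise ValueError("tariff decrements must be non-negative")
        for dim in DIMENSIONS:
            if dim not in self.decrements:
                raise ValueError(f"tariff missing dimension {dim!r}")
            l2, l3 = self.decrements[dim]
            if l2 < 0 or l3 < 0:
                raise ValueError(f"negative decrement for {dim!r}")

    @property
    def floor(self) -> float:
        """Score of the all-3s state, the minimum attainable utility."""
        return score_profile(Eq5dProfile(3, 3, 3, 3, 3), self)


def load_tariff(path: str | None = None) -> UtilityTariff:
    """Load a tariff from YAML; default is the bundled UK TTO value set."""
    if path is None:
        text = (
            resources.files("trialcea.data").joinpath("uk_tto_tariff.yaml").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    decrements = {
        dim: (float(v["level2"]), float(v["level3"]))
        for dim, v in raw["dimensions"].items()
    }
    return UtilityTariff(
        name=raw.get("name", "custom"),
        any_problem_decrement=float(raw["any_problem_decrement"]),
        n3_decrement=float(raw["n3_decrement"]),
        decrements=decrements,
        full_health_constant=float(raw.get("full_health_constant", 1.0)),
    )


def score_profile(profile: Eq5dProfile, tariff: UtilityTariff | None = None) -> float:
    """Utility of a single profile under the tariff (<= 1, may be negative)."""
    tariff = tariff if tariff is not None else load_tariff()
    levels = profile.levels
    score = tariff.full_health_constant
    if any(l > 1 for l in levels):
        score -= tariff.any_problem_decrement
    for dim, level in zip(DIMENSIONS, levels):
        l2, l3 = tariff.decrements[dim]
        if level == 2:
            score -= l2
        elif level == 3:
            score -= l3
    if any(l == 3 for l in levels):
        score -= tariff.n3_decrement
    return score


def all_profiles() -> list[Eq5dProfile]:
    """All 243 EQ-5D-3L states in lexicographic order."""
    return [Eq5dProfile(*lv) for lv in itertools.product((1, 2, 3), repeat=5)]


def tariff_table(tariff: UtilityTariff | None = None) -> pd.DataFrame:
    """Scores for all 243 states, indexed by the 5-digit label."""
    tariff = tariff if tariff is not None else load_tariff()
    rows = {str(p): score_profile(p, tariff) for p in all_profiles()}
    return pd.DataFrame({"utility": pd.Series(rows)})


def score_frame(
    eq5d: pd.DataFrame, tariff: UtilityTariff | None = None
) -> pd.Series:
    """Score a long table with the five dimension columns.

    Rows with any dimension missing are treated as wholly missing (NaN);
    no partial scoring is attempted.
    """
    tariff = tariff if tariff is not None else load_tariff()
    missing = [c for c in DIMENSIONS if c not in eq5d.columns]
    if missing:
        raise ValueError(f"eq5d table missing columns: {missing}")
    levels = eq5d[list(DIMENSIONS)]
    complete = levels.notna().all(axis=1)
    out = pd.Series(np.nan, index=eq5d.index, name="utility")
    if complete.any():
        lut = tariff_table(tariff)["utility"]
        keys = (
            levels.loc[complete]
            .astype(int)
            .astype(str)
            .agg("".join, axis=1)
        )
        bad = ~keys.isin(lut.index)
        if bad.any():
            raise ValueError(
                f"invalid EQ-5D-3L levels in rows {list(keys.index[bad][:5])}"
            )
        out.loc[complete] = lut.reindex(keys).to_numpy()
    return out


def nearest_profile(
    latent: float, tariff: UtilityTariff | None = None
) -> Eq5dProfile:
    """Profile whose tariff score is closest to a latent utility.

    Ties break to the lexicographically smallest 5-digit label, so the
    mapping is deterministic and round-trips exactly with `score_profile`.
    """
    tariff = tariff if tariff is not None else load_tariff()
    best: Eq5dProfile | None = None
    best_dist = np.inf
    for p in all_profiles():  # lexicographic order => first win is the tie-break
        d = abs(score_profile(p, tariff) - latent)
        if d < best_dist - 1e-12:
            best, best_dist = p, d
    assert best is not None
    return best


class _NearestScorer:
    """Vectorised latent-utility -> (profile, score) mapper with caching."""

    def __init__(self, tariff: UtilityTariff | None = None):
        self.tariff = tariff if tariff is not None else load_tariff()
        tbl = tariff_table(self.tariff)
        self.labels = np.array(tbl.index)
        self.scores = tbl["utility"].to_numpy()

    def map(self, latent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        latent = np.asarray(latent, dtype=float)
        # distance matrix latent x 243; argmin takes the first (lexicographically
        # smallest) label on ties because labels are sorted
        dist = np.abs(latent[:, None] - self.scores[None, :])
        idx = dist.argmin(axis=1)
        return self.labels[idx], self.scores[idx]
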