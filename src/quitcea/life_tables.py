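"""Disease-specific and all-cause mortality schedules for the cohort model.

The engine consumes annual death probabilities for lung cancer, COPD and
cardiovascular disease, stratified by gender, single year of age (15-110)
and smoking status (never smoker, current smoker, or former smoker by
completed years since cessation).  Former-smoker risk is expressed through
relative risks versus never smokers over duration-of-cessation bands, so
that risk decays from near the current-smoker level toward the never-smoker
floor as abstinence lengthens.

Two routes produce the schedules:

* the adjustment pipeline (:func:`apply_adjustment_ratios`,
  :func:`derive_former_smoker_rates`, :func:`derive_female_rates`,
  :func:`residual_other_cause_mortality`) for transcribed external life
  tables, mirroring how British cohort mortality is re-based to a French
  setting via spatial and temporal mortality ratios, CPS-I-style relative
  risks and a male/female lung-cancer death ratio; and

* :func:`generate_synthetic_tables`, a calibrated generator producing
  epidemiologically plausible stand-in tables (Gompertz all-cause baseline,
  proportional disease shares, excess-risk multipliers for smokers and a
  decaying former-smoker relative risk) when transcribed tables are
  unavailable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ConfigurationError, DataConsistencyError

log = logging.getLogger(__name__)

GENDERS = ("male", "female")
DISEASES = ("lung_cancer", "copd", "cvd")
AGE_MIN = 15
AGE_MAX = 110
N_AGES = AGE_MAX - AGE_MIN + 1
AGES = np.arange(AGE_MIN, AGE_MAX + 1)

#: duration-of-cessation bands (half-open, years) for former-smoker relative risk
DEFAULT_RR_BANDS = ((1.0, 3.0), (3.0, 6.0), (6.0, 11.0), (11.0, 16.0), (16.0, math.inf))

# status axis layout: 0 = never, 1 = current, 2 + band_index = former(band)
STATUS_NEVER = 0
STATUS_CURRENT = 1


def _gender_index(gender: str) -> int:
    try:
        return GENDERS.index(gender)
    except ValueError:
        raise ConfigurationError(f"unknown gender {gender!r}; expected one of {GENDERS}")


def _disease_index(disease: str) -> int:
    try:
        return DISEASES.index(disease)
    except ValueError:
        raise ConfigurationError(f"unknown disease {disease!r}; expected one of {DISEASES}")


def _age_index(age) -> int:
    if not AGE_MIN <= age <= AGE_MAX:
        raise ConfigurationError(f"age {age} outside table range [{AGE_MIN}, {AGE_MAX}]")
    return int(age) - AGE_MIN


@dataclass(frozen=True)
class RelativeRiskSchedule:
    """Former- vs never-smoker relative risk by duration-of-cessation band.

    ``rr[disease]`` holds one value per band; bands are half-open year
    intervals partitioning [1, inf).  Durations below the first band use the
    first band; durations beyond the last use the last band (the asymptotic
    floor).
    """

    bands: tuple = DEFAULT_RR_BANDS
    rr: dict = field(default_factory=dict)  # disease -> tuple of RR per band

    def __post_init__(self):
        if not self.bands:
            raise ConfigurationError("relative-risk schedule needs at least one band")
        for dis, values in self.rr.items():
            _disease_index(dis)
            if len(values) != len(self.bands):
                raise ConfigurationError(
                    f"relative risks for {dis} must have one value per band "
                    f"({len(self.bands)} bands, got {len(values)})"
                )
            arr = np.asarray(values, dtype=float)
            if np.any(arr < 1.0):
                raise ConfigurationError(f"relative risks for {dis} must be >= 1")
            if np.any(np.diff(arr) > 1e-12):
                raise ConfigurationError(f"relative risks for {dis} must be non-increasing across bands")

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    def band_index(self, years_since_quit: float) -> int:
        """Band containing the given completed cessation duration."""
        d = years_since_quit
        if d < self.bands[0][0]:
            return 0  # durations under one year fall back to the first band
        for k, (lo, hi) in enumerate(self.bands):
            if lo <= d < hi:
                return k
        return self.n_bands - 1

    def relative_risk(self, disease: str, years_since_quit: float) -> float:
        return float(self.rr[disease][self.band_index(years_since_quit)])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for dis in DISEASES:
            for (lo, hi), v in zip(self.bands, self.rr[dis]):
                rows.append({"disease": dis, "band_lo": lo, "band_hi": hi, "rr": v})
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RelativeRiskSchedule":
        bands = None
        rr = {}
        for dis, grp in df.groupby("disease", sort=False):
            grp = grp.sort_values("band_lo")
            b = tuple((float(lo), float(hi)) for lo, hi in zip(grp["band_lo"], grp["band_hi"]))
            if bands is None:
                bands = b
            elif b != bands:
                raise DataConsistencyError(f"band layout for {dis} differs from other diseases")
            rr[dis] = tuple(float(v) for v in grp["rr"])
        return cls(bands=bands, rr=rr)


@dataclass
class DiseaseMortalitySchedule:
    """Annual disease-specific death probabilities.

    ``probs`` has shape ``(gender, age, status, disease)`` with the status
    axis laid out as never, current, then one former slot per RR band.
    """

    bands: tuple = DEFAULT_RR_BANDS
    probs: np.ndarray | None = None

    def __post_init__(self):
        n_status = 2 + len(self.bands)
        if self.probs is None:
            self.probs = np.zeros((len(GENDERS), N_AGES, n_status, len(DISEASES)))
        self.probs = np.asarray(self.probs, dtype=float)
        expected = (len(GENDERS), N_AGES, n_status, len(DISEASES))
        if self.probs.shape != expected:
            raise ConfigurationError(
                f"disease schedule array must have shape {expected}, got {self.probs.shape}"
            )

    @property
    def n_status(self) -> int:
        return self.probs.shape[2]

    def status_index(self, status: str, years_since_quit: float | None = None) -> int:
        if status == "never":
            return STATUS_NEVER
        if status == "current":
            return STATUS_CURRENT
        if status == "former":
            if years_since_quit is None:
                raise ConfigurationError("former status requires years_since_quit")
            return 2 + RelativeRiskSchedule(bands=self.bands).band_index(years_since_quit)
        raise ConfigurationError(f"unknown smoking status {status!r}")

    def get(self, gender: str, age: int, status: str, disease: str,
            years_since_quit: float | None = None) -> float:
        return float(
            self.probs[
                _gender_index(gender), _age_index(age),
                self.status_index(status, years_since_quit), _disease_index(disease),
            ]
        )

    def copy(self) -> "DiseaseMortalitySchedule":
        return DiseaseMortalitySchedule(bands=self.bands, probs=self.probs.copy())

    def validate(self) -> None:
        """Raise if any type invariant is violated."""
        p = self.probs
        if np.any(p < 0) or np.any(p > 1):
            raise DataConsistencyError("disease probabilities must lie in [0, 1]")
        if np.any(p.sum(axis=3) > 1 + 1e-12):
            raise DataConsistencyError("disease probabilities sum above 1 at some key")
        never = p[:, :, STATUS_NEVER, :]
        current = p[:, :, STATUS_CURRENT, :]
        former = p[:, :, 2:, :]
        if np.any(former < never[:, :, None, :] - 1e-12):
            raise DataConsistencyError("former-smoker probability below never-smoker level")
        if np.any(former > current[:, :, None, :] + 1e-12):
            raise DataConsistencyError("former-smoker probability above current-smoker level")
        if former.shape[2] > 1 and np.any(np.diff(former, axis=2) > 1e-12):
            raise DataConsistencyError("former-smoker probability increases with cessation duration")

    # -- CSV round trip ----------------------------------------------------

    def _band_label(self, k: int) -> str:
        lo, hi = self.bands[k]
        return f"{lo:g}+" if math.isinf(hi) else f"{lo:g}-{hi:g}"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gi, gender in enumerate(GENDERS):
            for ai, age in enumerate(AGES):
                for si in range(self.n_status):
                    if si == STATUS_NEVER:
                        status, band = "never", ""
                    elif si == STATUS_CURRENT:
                        status, band = "current", ""
                    else:
                        status, band = "former", self._band_label(si - 2)
                    rows.append({
                        "gender": gender, "age": int(age), "status": status,
                        "years_since_quit_band": band,
                        "p_lung": self.probs[gi, ai, si, 0],
                        "p_copd": self.probs[gi, ai, si, 1],
                        "p_cvd": self.probs[gi, ai, si, 2],
                    })
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, bands: tuple = DEFAULT_RR_BANDS) -> "DiseaseMortalitySchedule":
        sched = cls(bands=bands)
        labels = {sched._band_label(k): k for k in range(len(bands))}
        for row in df.itertuples(index=False):
            gi = _gender_index(row.gender)
            ai = _age_index(row.age)
            if row.status == "never":
                si = STATUS_NEVER
            elif row.status == "current":
                si = STATUS_CURRENT
            else:
                band = str(row.years_since_quit_band)
                if band not in labels:
                    raise DataConsistencyError(f"unknown cessation band label {band!r}")
                si = 2 + labels[band]
            sched.probs[gi, ai, si, :] = (row.p_lung, row.p_copd, row.p_cvd)
        return sched


@dataclass
class AllCauseMortalitySchedule:
    """Annual all-cause death probability by gender and age: shape (2, n_ages)."""

    probs: np.ndarray | None = None

    def __post_init__(self):
        if self.probs is None:
            self.probs = np.zeros((len(GENDERS), N_AGES))
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (len(GENDERS), N_AGES):
            raise ConfigurationError(
                f"all-cause array must have shape {(len(GENDERS), N_AGES)}, got {self.probs.shape}"
            )

    def get(self, gender: str, age: int) -> float:
        return float(self.probs[_gender_index(gender), _age_index(age)])

    def validate(self, disease: DiseaseMortalitySchedule | None = None) -> None:
        """The all-cause table is the never-smoker (background) life table, so
        it must dominate the never-smoker disease burden; smokers' implied
        all-cause mortality (background residual plus their own disease rates)
        may legitimately exceed it."""
        if np.any(self.probs < 0) or np.any(self.probs > 1):
            raise DataConsistencyError("all-cause probabilities must lie in [0, 1]")
        if disease is not None:
            never = disease.probs[:, :, STATUS_NEVER, :].sum(axis=2)
            if np.any(never > self.probs + 1e-12):
                raise DataConsistencyError(
                    "never-smoker disease mortality exceeds all-cause mortality at some key"
                )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gi, gender in enumerate(GENDERS):
            for ai, age in enumerate(AGES):
                rows.append({"gender": gender, "age": int(age), "p_allcause": self.probs[gi, ai]})
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AllCauseMortalitySchedule":
        sched = cls()
        for row in df.itertuples(index=False):
            sched.probs[_gender_index(row.gender), _age_index(row.age)] = row.p_allcause
        return sched


@dataclass(frozen=True)
class AdjustmentRatios:
    """Spatial (France/UK 1995) and temporal (France 2000/1995) mortality ratios.

    ``female_male_lung_ratio`` converts male lung-cancer mortality into the
    female schedule; the other diseases default to a ratio of 1 unless
    configured.
    """

    spatial: dict = field(default_factory=lambda: {d: 1.0 for d in DISEASES})
    temporal: dict = field(default_factory=lambda: {d: 1.0 for d in DISEASES})
    female_male_lung_ratio: float = 1.0
    female_male_other: dict = field(default_factory=dict)  # optional copd/cvd ratios

    def __post_init__(self):
        for name, mapping in (("spatial", self.spatial), ("temporal", self.temporal)):
            for dis in DISEASES:
                if dis not in mapping:
                    raise ConfigurationError(f"missing {name} ratio for disease {dis!r}")
                if mapping[dis] <= 0:
                    raise ConfigurationError(f"{name} ratio for {dis!r} must be > 0")
        if self.female_male_lung_ratio <= 0:
            raise ConfigurationError("female/male lung-cancer ratio must be > 0")
        for dis, v in self.female_male_other.items():
            if v <= 0:
                raise ConfigurationError(f"female/male ratio for {dis!r} must be > 0")

    def gender_ratio(self, disease: str) -> float:
        if disease == "lung_cancer":
            return self.female_male_lung_ratio
        return float(self.female_male_other.get(disease, 1.0))


# ---------------------------------------------------------------------------
# adjustment pipeline
# ---------------------------------------------------------------------------

def apply_adjustment_ratios(base: DiseaseMortalitySchedule,
                            ratios: AdjustmentRatios) -> DiseaseMortalitySchedule:
    """Multiply every entry by its disease's spatial then temporal ratio.

    Probabilities pushed above 1 are clipped (with a logged warning); the key
    set is unchanged.
    """
    factors = np.array([ratios.spatial[d] * ratios.temporal[d] for d in DISEASES])
    out = base.copy()
    out.probs = base.probs * factors
    if np.any(out.probs > 1.0):
        n = int(np.count_nonzero(out.probs > 1.0))
        log.warning("adjustment pushed %d probabilities above 1; clipping", n)
        np.clip(out.probs, 0.0, 1.0, out=out.probs)
    return out


def derive_former_smoker_rates(schedule: DiseaseMortalitySchedule,
                               rr: RelativeRiskSchedule) -> DiseaseMortalitySchedule:
    """Fill former-smoker entries as never-smoker rate x band relative risk.

    The result is capped at the current-smoker rate at the same key, so the
    former level always lies between never and current.
    """
    if not rr.rr:
        raise ConfigurationError("relative-risk schedule has no diseases configured")
    if rr.bands != schedule.bands:
        raise ConfigurationError("relative-risk bands do not match the schedule's band layout")
    out = schedule.copy()
    never = schedule.probs[:, :, STATUS_NEVER, :]
    current = schedule.probs[:, :, STATUS_CURRENT, :]
    rr_arr = np.array([rr.rr[d] for d in DISEASES]).T  # (n_bands, n_diseases)
    former = never[:, :, None, :] * rr_arr[None, None, :, :]
    out.probs[:, :, 2:, :] = np.minimum(former, current[:, :, None, :])
    return out


def derive_female_rates(schedule: DiseaseMortalitySchedule,
                        ratios: AdjustmentRatios) -> DiseaseMortalitySchedule:
    """Derive the female plane from the male one via per-disease gender ratios."""
    out = schedule.copy()
    male = schedule.probs[_gender_index("male")]
    g = np.array([ratios.gender_ratio(d) for d in DISEASES])
    female = np.clip(male * g, 0.0, 1.0)
    out.probs[_gender_index("female")] = female
    return out


def residual_other_cause_mortality(all_cause: AllCauseMortalitySchedule,
                                   disease: DiseaseMortalitySchedule,
                                   status: str,
                                   years_since_quit: float | None = None) -> np.ndarray:
    """All-cause minus the three disease-specific probabilities for a status.

    Returns an array of shape ``(gender, age)``.  A negative residual means
    the inputs are inconsistent and raises :class:`DataConsistencyError`
    naming the offending key.
    """
    si = disease.status_index(status, years_since_quit)
    residual = all_cause.probs - disease.probs[:, :, si, :].sum(axis=2)
    if np.any(residual < -1e-12):
        gi, ai = np.argwhere(residual < -1e-12)[0]
        raise DataConsistencyError(
            "negative other-cause residual at "
            f"gender={GENDERS[gi]}, age={AGES[ai]}, status={status}"
        )
    return np.clip(residual, 0.0, None)


def residual_matrix(all_cause: AllCauseMortalitySchedule,
                    disease: DiseaseMortalitySchedule) -> np.ndarray:
    """Other-cause residual for every status at once: shape (gender, age, status)."""
    residual = all_cause.probs[:, :, None] - disease.probs.sum(axis=3)
    if np.any(residual < -1e-12):
        gi, ai, si = np.argwhere(residual < -1e-12)[0]
        raise DataConsistencyError(
            "negative other-cause residual at "
            f"gender={GENDERS[gi]}, age={AGES[ai]}, status_index={si}"
        )
    return np.clip(residual, 0.0, None)


# ---------------------------------------------------------------------------
# synthetic tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticTableParams:
    """Parameters of the synthetic life-table generator.

    All-cause mortality follows a Gompertz curve per gender,
    ``q(a) = intercept * exp(slope * (a - 20))`` capped at
    ``max_annual_prob`` (late-life mortality deceleration).  When the
    intercept is not given it is calibrated so that general-population life
    expectancy at age 20 matches ``target_le_at_20``.

    Disease-specific never-smoker mortality is a share of all-cause
    mortality, ramping linearly from zero at ``onset_age`` up to the full
    ``disease_shares`` value at ``reference_age``.  Current smokers carry
    ``current_multipliers`` times the never-smoker rate; former-smoker
    relative risk decays geometrically with a half-life of
    ``rr_decay_halflife_years`` toward the never-smoker floor.

    ``jitter`` perturbs shares and multipliers by a seeded uniform relative
    factor — used to draw families of random but invariant-satisfying tables.
    """

    seed: int = 0
    slope: float = 0.085
    target_le_at_20: tuple = (60.6, 64.0)  # never-smoker LE at 20 (male, female)
    intercept: tuple | None = None          # overrides calibration when given
    max_annual_prob: float = 0.28
    disease_shares: tuple = (0.025, 0.015, 0.150)       # lung, copd, cvd at reference age
    current_multipliers: tuple = (32.0, 18.0, 5.0)
    onset_age: float = 20.0
    reference_age: float = 40.0
    rr_decay_halflife_years: float = 5.0
    bands: tuple = DEFAULT_RR_BANDS
    jitter: float = 0.0

    def __post_init__(self):
        shares = np.asarray(self.disease_shares, float)
        mults = np.asarray(self.current_multipliers, float)
        if shares.shape != (3,) or mults.shape != (3,):
            raise ConfigurationError("need one share and one multiplier per disease")
        if np.any(shares < 0) or shares.sum() >= 1:
            raise ConfigurationError("disease shares must be non-negative and sum to < 1")
        if np.any(mults < 1):
            raise ConfigurationError("current-smoker multipliers must be >= 1")
        # row feasibility at the capped (oldest) ages: background other-cause
        # mortality plus current-smoker disease mortality, plus headroom for a
        # cessation exit, must stay below 1
        excess = float(shares @ mults) - float(shares.sum())
        if self.max_annual_prob * (1.0 + excess) > 0.75 + 1e-12:
            raise ConfigurationError(
                "current-smoker total exit probability would exceed 0.75 at the "
                "capped ages; lower max_annual_prob or the shares/multipliers"
            )
        if self.slope <= 0 or not 0 < self.max_annual_prob <= 1:
            raise ConfigurationError("slope must be > 0 and max_annual_prob in (0, 1]")
        if self.onset_age >= self.reference_age:
            raise ConfigurationError("onset_age must be below reference_age")


@lru_cache(maxsize=128)
def _calibrated_intercept(slope: float, target_le: float, cap: float) -> float:
    """Gompertz intercept whose life table reproduces the target LE at age 20."""

    def le_at_20(log10_a: float) -> float:
        q = np.minimum(10.0 ** log10_a * np.exp(slope * (np.arange(20, AGE_MAX) - 20)), cap)
        surv = np.concatenate([[1.0], np.cumprod(1.0 - q)])
        return float(surv.sum())  # forced death at AGE_MAX truncates the sum

    root = brentq(lambda x: le_at_20(x) - target_le, -9.0, -1.0, xtol=1e-12)
    return 10.0 ** root


def gompertz_all_cause(params: SyntheticTableParams) -> AllCauseMortalitySchedule:
    """All-cause schedule for both genders from the (possibly calibrated) Gompertz."""
    probs = np.empty((len(GENDERS), N_AGES))
    for gi in range(len(GENDERS)):
        if params.intercept is not None:
            a = params.intercept[gi]
        else:
            a = _calibrated_intercept(params.slope, params.target_le_at_20[gi],
                                      params.max_annual_prob)
        probs[gi] = np.minimum(a * np.exp(params.slope * (AGES - 20)), params.max_annual_prob)
    return AllCauseMortalitySchedule(probs=probs)


def generate_synthetic_tables(params: SyntheticTableParams):
    """Build (disease schedule, all-cause schedule, RR schedule) from parameters.

    Deterministic given the seed; every output satisfies the schedule
    invariants by construction.
    """
    rng = np.random.default_rng(params.seed)
    shares = np.asarray(params.disease_shares, float)
    mults = np.asarray(params.current_multipliers, float)
    if params.jitter > 0:
        shares = shares * (1.0 + params.jitter * rng.uniform(-1, 1, 3))
        mults = np.maximum(1.0, mults * (1.0 + params.jitter * rng.uniform(-1, 1, 3)))
        excess = float(shares @ mults) - float(shares.sum())
        # looser bound than the base-case check: jittered draws are used for
        # property sweeps at the base cessation rate, not for PSA tail draws
        if shares.sum() >= 1 or params.max_annual_prob * (1.0 + excess) > 0.90:
            raise ConfigurationError("jittered shares/multipliers leave no feasible row")

    all_cause = gompertz_all_cause(params)

    ramp = np.clip((AGES - params.onset_age) / (params.reference_age - params.onset_age), 0.0, 1.0)
    never = all_cause.probs[:, :, None] * ramp[None, :, None] * shares[None, None, :]
    current = never * mults[None, None, :]

    # former-smoker RR per band: geometric decay from the current multiplier toward 1
    lo_edges = np.array([lo for lo, _ in params.bands])
    decay = 2.0 ** (-lo_edges / params.rr_decay_halflife_years)
    rr_values = {
        dis: tuple(1.0 + (mults[di] - 1.0) * decay) for di, dis in enumerate(DISEASES)
    }
    rr_sched = RelativeRiskSchedule(bands=params.bands, rr=rr_values)

    disease = DiseaseMortalitySchedule(bands=params.bands)
    disease.probs[:, :, STATUS_NEVER, :] = never
    disease.probs[:, :, STATUS_CURRENT, :] = current
    disease = derive_former_smoker_rates(disease, rr_sched)
    disease.validate()
    all_cause.validate(disease)
    return disease, all_cause, rr_sched


# ---------------------------------------------------------------------------
# CSV I/O helpers
# ---------------------------------------------------------------------------

def save_tables(disease: DiseaseMortalitySchedule, all_cause: AllCauseMortalitySchedule,
                rr: RelativeRiskSchedule, disease_path, allcause_path, rr_path) -> None:
    disease.to_frame().to_csv(disease_path, index=False)
    all_cause.to_frame().to_csv(allcause_path, index=False)
    rr.to_frame().to_csv(rr_path, index=False)


def load_tables(disease_path, allcause_path, rr_path):
    rr = RelativeRiskSchedule.from_frame(pd.read_csv(rr_path))
    disease = DiseaseMortalitySchedule.from_frame(
        pd.read_csv(disease_path, keep_default_na=False), bands=rr.bands)
    all_cause = AllCauseMortalitySchedule.from_frame(pd.read_csv(allcause_path))
    disease.validate()
    all_cause.validate(disease)
    return disease, all_cause, rr


__all__ = [
    "GENDERS", "DISEASES", "AGE_MIN", "AGE_MAX", "AGES", "DEFAULT_RR_BANDS",
    "STATUS_NEVER", "STATUS_CURRENT",
    "RelativeRiskSchedule", "DiseaseMortalitySchedule", "AllCauseMortalitySchedule",
    "AdjustmentRatios", "SyntheticTableParams",
    "apply_adjustment_ratios", "derive_former_smoker_rates", "derive_female_rates",
    "residual_other_cause_mortality", "residual_matrix",
    "generate_synthetic_tables", "gompertz_all_cause", "save_tables", "load_tables",
]
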