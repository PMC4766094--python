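"""Six-state Markov cohort engine with cessation tunnel states.

States: smoker (S), former smoker (F, tunnelled by completed years since
cessation so former-smoker risk can decay with abstinence), diagnosed lung
cancer (C), COPD (O), cardiovascular disease (V), and dead (D, absorbing).
One-year cycles; everyone starts as a smoker; the run ends when the whole
cohort is dead or reaches the maximum age.

Incidence of the three diseases is proxied by disease-specific mortality at
the person's current smoking status; death from S/F uses the other-cause
residual (all-cause minus the three disease-specific rates), so the three
disease exits and the residual exit together reproduce all-cause mortality.
Diagnosed persons move to a terminal disease track whose annual death
probability is fixed by post-diagnosis life expectancy (age band and
smoking status at diagnosis).

Relapse is folded into the definitive cessation probability, so the F -> S
transition probability is zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, ModelConsistencyError
from .life_tables import (
    AGE_MAX, AGE_MIN, DISEASES, GENDERS, STATUS_CURRENT, STATUS_NEVER,
    AllCauseMortalitySchedule, DiseaseMortalitySchedule, RelativeRiskSchedule,
)

log = logging.getLogger(__name__)

DEATH_CAUSES = DISEASES + ("other",)
SURVIVAL_MODES = ("reciprocal", "exponential", "fixed")

# status-at-diagnosis codes used on the disease track
DIAG_NEVER, DIAG_CURRENT, DIAG_FORMER = 0, 1, 2
_DIAG_LABELS = ("never", "current", "former")


def definitive_cessation_probability(natural: float = 0.026,
                                     odds_ratios=(1.95, 1.39),
                                     scale: str = "multiplicative") -> float:
    """Per-attempt definitive cessation probability under supported treatment.

    The base-case construction multiplies the natural (unassisted) annual
    cessation probability by the treatment odds ratios, 0.026 x 1.95 x 1.39
    = 7.05%.  ``scale="odds"`` applies the odds ratios on the odds scale
    instead, which yields a slightly lower probability.
    """
    if scale == "multiplicative":
        p = natural
        for o in odds_ratios:
            p *= o
        return p
    if scale == "odds":
        odds = natural / (1.0 - natural)
        for o in odds_ratios:
            odds *= o
        return odds / (1.0 + odds)
    raise ConfigurationError(f"unknown odds-ratio scale {scale!r}")


def participation_rate(want_to_quit: float = 0.73, truly_motivated: float = 0.10) -> float:
    """Programme participation: the truly motivated fraction of would-be quitters."""
    return want_to_quit * truly_motivated


def annual_death_probability_from_life_expectancy(le: float, method: str = "reciprocal") -> float:
    """Constant annual death probability matching a post-diagnosis life expectancy.

    ``reciprocal`` returns 1/LE (a geometric lifetime with mean LE in whole
    cycles); ``exponential`` returns 1 - exp(-1/LE) (constant hazard 1/LE).
    """
    if le < 1:
        raise ConfigurationError(f"life expectancy after diagnosis must be >= 1 year, got {le}")
    if method == "reciprocal":
        return 1.0 / le
    if method == "exponential":
        return 1.0 - np.exp(-1.0 / le)
    raise ConfigurationError(f"unknown conversion method {method!r}")


@dataclass(frozen=True)
class StrategySpec:
    """One coverage arm: who participates, how attempts work, and what they cost.

    A covered attempt exposes participating smokers to the per-attempt
    cessation probability at cycles 0, f, 2f, ... for ``n_attempts`` attempts
    (f = ``attempt_frequency_years``); in all other cycles, and for
    non-participants always, the natural cessation probability applies.
    Each attempt made while still a smoker costs one consultation plus one
    drug course (2009 euros, inflated by cycle).
    """

    participation: float = 0.073
    attempt_cessation_prob: float = 0.0704
    natural_cessation_prob: float = 0.026
    n_attempts: int = 4
    attempt_frequency_years: int = 2
    consult_cost: float = 132.0
    drug_cost: float = 201.0
    name: str = "strategy"

    def __post_init__(self):
        for f in ("participation", "attempt_cessation_prob", "natural_cessation_prob"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{f} must be a probability in [0, 1], got {v}")
        if self.n_attempts < 0:
            raise ConfigurationError("n_attempts must be >= 0")
        if self.attempt_frequency_years < 1:
            raise ConfigurationError("attempt_frequency_years must be >= 1")
        if self.consult_cost < 0 or self.drug_cost < 0:
            raise ConfigurationError("attempt costs must be >= 0")

    def is_attempt_cycle(self, cycle: int) -> bool:
        f = self.attempt_frequency_years
        return cycle % f == 0 and cycle // f < self.n_attempts

    def cessation_prob(self, cycle: int, participant: bool) -> float:
        if participant and self.is_attempt_cycle(cycle):
            return self.attempt_cessation_prob
        return self.natural_cessation_prob


def full_coverage_strategy(**overrides) -> StrategySpec:
    """Base-case full-coverage arm: 7.3% participation, 7.04% per-attempt
    cessation, four biennial covered attempts at 132 + 201 euros each."""
    return replace(StrategySpec(name="full_coverage"), **overrides)


def fifty_euro_strategy(**overrides) -> StrategySpec:
    """Existing lump-sum arm: 3.75% cost-only participation (one 14.4 + 50
    euro claim at entry); everyone quits at the natural rate."""
    base = StrategySpec(participation=0.0375, attempt_cessation_prob=0.026,
                        n_attempts=1, attempt_frequency_years=1,
                        consult_cost=14.4, drug_cost=50.0, name="fifty_euro")
    return replace(base, **overrides)


def no_coverage_strategy(**overrides) -> StrategySpec:
    """No-coverage comparator: natural cessation only, no payer spending."""
    base = StrategySpec(participation=0.0, attempt_cessation_prob=0.026,
                        n_attempts=0, consult_cost=0.0, drug_cost=0.0, name="no_coverage")
    return replace(base, **overrides)


@dataclass(frozen=True)
class Stratum:
    gender: str
    entry_age: int
    weight: float

    def __post_init__(self):
        if self.gender not in GENDERS:
            raise ConfigurationError(f"unknown gender {self.gender!r}")
        if not 15 <= self.entry_age <= 75:
            raise ConfigurationError(f"entry age {self.entry_age} outside [15, 75]")
        if self.weight < 0:
            raise ConfigurationError("stratum weight must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Age/gender strata of the smoker cohort; weights are persons."""

    strata: tuple

    def __post_init__(self):
        if not self.strata:
            raise ConfigurationError("cohort needs at least one stratum")

    @property
    def size(self) -> float:
        return float(sum(s.weight for s in self.strata))

    def scaled(self, factor: float) -> "CohortSpec":
        return CohortSpec(tuple(replace(s, weight=s.weight * factor) for s in self.strata))


# age-band weights emulating the age/gender profile of French daily smokers
# aged 15-75 (smoking prevalence concentrated under 55, more men than women)
_DEFAULT_AGE_WEIGHTS = ((20, 0.20), (30, 0.22), (40, 0.20), (50, 0.18), (60, 0.13), (70, 0.07))
_DEFAULT_MALE_SHARE = 0.55


def default_french_smoker_cohort(size: float = 1000.0) -> CohortSpec:
    """Default 1,000-smoker cohort: six age bands (midpoints) by gender."""
    strata = []
    for gender, gshare in (("male", _DEFAULT_MALE_SHARE), ("female", 1 - _DEFAULT_MALE_SHARE)):
        for age, ashare in _DEFAULT_AGE_WEIGHTS:
            strata.append(Stratum(gender, age, size * gshare * ashare))
    return CohortSpec(tuple(strata))


def _band_lookup(bands, age):
    for hi, value in bands:
        if age < hi:
            return value
    raise ConfigurationError(f"age {age} not covered by survival bands {bands}")


@dataclass(frozen=True)
class DiseaseSurvivalSpec:
    """Post-diagnosis life expectancy (years) by disease, age band and
    smoking status at diagnosis.

    Lung cancer: 2 years regardless of age and status.  COPD varies by both
    age band and status; CVD by age band only.  Bands are closed-open
    ((hi, LE) means age < hi).
    """

    lung_cancer: float = 2.0
    copd_current: tuple = ((70, 18.0), (80, 10.0), (np.inf, 3.0))
    copd_former: tuple = ((70, 20.0), (80, 15.0), (np.inf, 5.0))
    copd_never: tuple = ((80, 20.0), (np.inf, 5.0))
    cvd: tuple = ((65, 15.0), (75, 6.0), (85, 3.0), (np.inf, 1.0))

    def life_expectancy(self, disease: str, age: float, status: str) -> float:
        if disease == "lung_cancer":
            return self.lung_cancer
        if disease == "copd":
            bands = {"current": self.copd_current, "former": self.copd_former,
                     "never": self.copd_never}[status]
            return _band_lookup(bands, age)
        if disease == "cvd":
            return _band_lookup(self.cvd, age)
        raise ConfigurationError(f"unknown disease {disease!r}")


@dataclass
class MortalityTables:
    """Bundle of the three schedules plus arrays precomputed for the engine.

    The all-cause schedule is read as the never-smoker (background) life
    table.  Other-cause mortality — all-cause minus the never-smoker burden
    of the three diseases — is treated as independent of smoking status:
    smoking's excess mortality operates entirely through the modelled
    diseases, which is the premise of attributing its burden to them.  A
    current or former smoker therefore faces the background other-cause
    rate plus their own (elevated) disease-specific rates, and a never
    smoker reproduces the all-cause table exactly.
    """

    disease: DiseaseMortalitySchedule
    all_cause: AllCauseMortalitySchedule
    rr: RelativeRiskSchedule
    residual: np.ndarray = field(init=False)
    duration_status: np.ndarray = field(init=False)  # tunnel year d (1-based) -> status index

    def __post_init__(self):
        from .life_tables import residual_other_cause_mortality
        background = residual_other_cause_mortality(self.all_cause, self.disease, "never")
        self.residual = np.repeat(background[:, :, None], self.disease.n_status, axis=2)
        d_max = self.tunnel_length
        self.duration_status = np.array(
            [2 + self.rr.band_index(d) for d in range(1, d_max + 1)], dtype=int)

    @property
    def tunnel_length(self) -> int:
        """Years tracked in the former-smoker tunnel (the last band's lower edge)."""
        return int(self.rr.bands[-1][0])


@dataclass
class CohortTrace:
    """Full run record: start-of-cycle occupancies plus within-cycle events.

    Arrays are indexed ``[stratum, cycle, ...]``; occupancies are persons
    (stratum weights), events (diagnoses, deaths, covered attempts) are
    person-weighted counts occurring during the cycle.
    """

    cohort: CohortSpec
    strategy: StrategySpec
    occ_s_part: np.ndarray
    occ_s_non: np.ndarray
    occ_f: np.ndarray          # (n, T+1, tunnel_length)
    occ_dis: np.ndarray        # (n, T+1, 3)
    occ_d: np.ndarray
    inc: np.ndarray            # (n, T+1, 3) incident diagnoses during cycle
    deaths: np.ndarray         # (n, T+1, 4) per DEATH_CAUSES
    attempts: np.ndarray       # (n, T+1) covered-attempt events
    snapshots: dict            # cycle -> disease occupancy by (disease, diag cycle, diag status)

    @property
    def n_cycles(self) -> int:
        return self.occ_d.shape[1] - 1

    def alive(self) -> np.ndarray:
        """Persons alive at the start of each cycle, per stratum."""
        return (self.occ_s_part + self.occ_s_non
                + self.occ_f.sum(axis=2) + self.occ_dis.sum(axis=2))

    def occupancy(self) -> np.ndarray:
        """Occupancy of the six model states: (n, T+1, 6) ordered S,F,C,O,V,D."""
        return np.stack(
            [self.occ_s_part + self.occ_s_non, self.occ_f.sum(axis=2),
             self.occ_dis[:, :, 0], self.occ_dis[:, :, 1], self.occ_dis[:, :, 2],
             self.occ_d], axis=2)

    def cumulative_deaths_by_cause(self) -> dict:
        totals = self.deaths.sum(axis=(0, 1))
        return dict(zip(DEATH_CAUSES, totals))

    def disease_person_years(self) -> np.ndarray:
        """Person-cycles spent in each disease state, counting the diagnosis
        cycle: (n, T+1, 3)."""
        return self.occ_dis + self.inc


def build_transition_row(origin: str, gender: str, age: int, cycle: int,
                         strategy: StrategySpec, tables: MortalityTables,
                         survival: DiseaseSurvivalSpec,
                         years_since_quit: int | None = None,
                         age_at_diagnosis: float | None = None,
                         status_at_diagnosis: str | None = None,
                         participant: bool = False,
                         survival_mode: str = "reciprocal",
                         smoker_status: str = "current") -> dict:
    """One-cycle transition probabilities out of a single origin state.

    Returns a dict over destination labels (``S``, ``F1`` ... ``F<dmax>``,
    ``C``, ``O``, ``V``, ``D``) summing to 1.  Disease origins need the age
    and smoking status at diagnosis, which pin the death probability.
    """
    gi = GENDERS.index(gender)
    ai = int(age) - AGE_MIN
    d_max = tables.tunnel_length
    row = {}

    if origin == "D":
        return {"D": 1.0}

    if origin in ("C", "O", "V"):
        if age_at_diagnosis is None or status_at_diagnosis is None:
            raise ConfigurationError("disease origins need age and status at diagnosis")
        disease = DISEASES[("C", "O", "V").index(origin)]
        le = survival.life_expectancy(disease, age_at_diagnosis, status_at_diagnosis)
        if survival_mode == "fixed":
            raise ConfigurationError(
                "fixed-duration survival is not a per-cycle probability; "
                "use the reciprocal or exponential mode for transition rows")
        p = annual_death_probability_from_life_expectancy(
            le, "reciprocal" if survival_mode == "reciprocal" else "exponential")
        return {"D": p, origin: 1.0 - p}

    if origin == "S":
        si = STATUS_NEVER if smoker_status == "never" else STATUS_CURRENT
        p_dis = tables.disease.probs[gi, ai, si, :]
        p_other = tables.residual[gi, ai, si]
        cess = strategy.cessation_prob(cycle, participant)
        total = p_dis.sum() + p_other + cess
        if total > 1.0 + 1e-12:
            raise ModelConsistencyError(
                f"smoker row over-allocated at gender={gender}, age={age}: sum={total:.6f}")
        row["C"], row["O"], row["V"] = (float(v) for v in p_dis)
        row["D"] = float(p_other)
        row["F1"] = float(cess)
        row["S"] = 1.0 - row["C"] - row["O"] - row["V"] - row["D"] - row["F1"]
        return row

    if origin == "F":
        if years_since_quit is None:
            raise ConfigurationError("former-smoker origin needs years_since_quit")
        d = int(years_since_quit)
        si = int(tables.duration_status[min(d, d_max) - 1])
        p_dis = tables.disease.probs[gi, ai, si, :]
        p_other = tables.residual[gi, ai, si]
        total = p_dis.sum() + p_other
        if total > 1.0 + 1e-12:
            raise ModelConsistencyError(
                f"former-smoker row over-allocated at gender={gender}, age={age}, d={d}")
        row["C"], row["O"], row["V"] = (float(v) for v in p_dis)
        row["D"] = float(p_other)
        nxt = min(d + 1, d_max)
        row[f"F{nxt}"] = 1.0 - p_dis.sum() - p_other  # P_FS = 0: cessation is definitive
        return row

    raise ConfigurationError(f"unknown origin state {origin!r}")


_death_path_cache: dict = {}


def _disease_death_prob_paths(strata, survival, T, mode):
    key = (strata, survival, T, mode)
    cached = _death_path_cache.get(key)
    if cached is None:
        cached = _death_path_cache[key] = _build_death_prob_paths(strata, survival, T, mode)
        if len(_death_path_cache) > 64:
            _death_path_cache.pop(next(iter(_death_path_cache)))
    return cached


def _build_death_prob_paths(strata, survival, T, mode):
    """Per-stratum death probability (or fixed duration) on the disease track.

    Returns an array (n, 3 diseases, T+1 diagnosis cycles, 3 diag statuses)
    of annual probabilities, or of integer survival durations in fixed mode.
    """
    n = len(strata)
    out = np.empty((n, len(DISEASES), T + 1, 3))
    for i, s in enumerate(strata):
        for di, disease in enumerate(DISEASES):
            for t0 in range(T + 1):
                age = min(s.entry_age + t0, AGE_MAX)
                for si, status in enumerate(_DIAG_LABELS):
                    le = survival.life_expectancy(disease, age, status)
                    if mode == "fixed":
                        out[i, di, t0, si] = round(le)
                    else:
                        out[i, di, t0, si] = annual_death_probability_from_life_expectancy(
                            le, "reciprocal" if mode == "reciprocal" else "exponential")
    return out


def run_cohort(cohort: CohortSpec, strategy: StrategySpec, tables: MortalityTables,
               survival: DiseaseSurvivalSpec | None = None,
               horizon="lifetime", survival_mode: str = "reciprocal",
               initial_status: str = "current", initial_state: str = "smoker",
               snapshot_cycles=()) -> CohortTrace:
    """Deterministic cohort run; everyone starts in S at cycle 0.

    ``horizon`` is an integer number of cycles or ``"lifetime"`` (run until
    the cohort is dead or capped at age 110, where survivors are moved to D).
    ``initial_status="never"`` runs a lifelong never-smoker counterfactual:
    the S compartment uses never-smoker incidence and residual mortality and
    diagnoses carry never-smoker life expectancy (used for validation).
    ``initial_state="former"`` starts the whole cohort as fresh quitters in
    the first tunnel year instead of smokers (accomplished-quitter scenarios).
    ``snapshot_cycles`` asks for the disease-track occupancy broken down by
    diagnosis cycle and status at those cycles (taken after that cycle's
    incident diagnoses, before its disease deaths).
    """
    if survival is None:
        survival = DiseaseSurvivalSpec()
    if survival_mode not in SURVIVAL_MODES:
        raise ConfigurationError(f"unknown survival mode {survival_mode!r}")
    if initial_status not in ("current", "never"):
        raise ConfigurationError("initial_status must be 'current' or 'never'")

    strata = cohort.strata
    n = len(strata)
    entry = np.array([s.entry_age for s in strata])
    weights = np.array([s.weight for s in strata])
    gi = np.array([GENDERS.index(s.gender) for s in strata])
    d_max = tables.tunnel_length

    max_cycles = int(AGE_MAX - entry.min())
    T = max_cycles if horizon == "lifetime" else int(horizon)
    if T < 1:
        raise ConfigurationError("horizon must be >= 1 cycle")
    T = min(T, max_cycles)

    ages = np.minimum(entry[:, None] + np.arange(T + 1)[None, :], AGE_MAX)  # (n, T+1)
    age_idx = ages - AGE_MIN
    # per-stratum probability paths: disease (n, T+1, status, 3) and residual (n, T+1, status)
    p_dis_path = tables.disease.probs[gi[:, None], age_idx, :, :]
    resid_path = tables.residual[gi[:, None], age_idx, :]
    dstat = tables.duration_status  # (d_max,) tunnel year -> status column
    smoker_si = STATUS_NEVER if initial_status == "never" else STATUS_CURRENT
    diag_status_smoker = DIAG_NEVER if initial_status == "never" else DIAG_CURRENT

    p_death = _disease_death_prob_paths(strata, survival, T, survival_mode)

    if initial_state not in ("smoker", "former"):
        raise ConfigurationError("initial_state must be 'smoker' or 'former'")
    f_occ = np.zeros((n, d_max))
    if initial_state == "former":
        s_part = np.zeros(n)
        s_non = np.zeros(n)
        f_occ[:, 0] = weights
    else:
        s_part = weights * strategy.participation
        s_non = weights - s_part
    dis = np.zeros((n, len(DISEASES), T + 1, 3))  # by (diag cycle, diag status)
    dead = np.zeros(n)

    trace = CohortTrace(
        cohort=cohort, strategy=strategy,
        occ_s_part=np.zeros((n, T + 1)), occ_s_non=np.zeros((n, T + 1)),
        occ_f=np.zeros((n, T + 1, d_max)), occ_dis=np.zeros((n, T + 1, len(DISEASES))),
        occ_d=np.zeros((n, T + 1)), inc=np.zeros((n, T + 1, len(DISEASES))),
        deaths=np.zeros((n, T + 1, len(DEATH_CAUSES))), attempts=np.zeros((n, T + 1)),
        snapshots={},
    )

    tsd_grid = -np.arange(T + 1)  # + t gives time since diagnosis per diag-cycle column

    for t in range(T + 1):
        trace.occ_s_part[:, t] = s_part
        trace.occ_s_non[:, t] = s_non
        trace.occ_f[:, t, :] = f_occ
        trace.occ_dis[:, t, :] = dis.sum(axis=(2, 3))
        trace.occ_d[:, t] = dead
        if t == T:
            break

        at_cap = ages[:, t + 1] >= AGE_MAX  # strata reaching the age cap after this cycle

        # --- smokers -----------------------------------------------------
        cess_p = strategy.cessation_prob(t, participant=True)
        cess_n = strategy.cessation_prob(t, participant=False)
        if strategy.is_attempt_cycle(t):
            trace.attempts[:, t] = s_part
        pd_s = p_dis_path[:, t, smoker_si, :]           # (n, 3)
        po_s = resid_path[:, t, smoker_si]
        over = pd_s.sum(axis=1) + po_s + max(cess_p, cess_n) - 1.0
        if np.any(over > 1e-12):
            i = int(np.argmax(over))
            raise ModelConsistencyError(
                f"smoker row over-allocated for stratum {strata[i].gender}/{strata[i].entry_age} "
                f"at cycle {t} (excess {over[i]:.3g})")
        s_tot = s_part + s_non
        new_dis_s = s_tot[:, None] * pd_s               # diagnoses from S
        dis[:, :, t, diag_status_smoker] += new_dis_s
        trace.inc[:, t, :] += new_dis_s
        trace.deaths[:, t, 3] += s_tot * po_s
        to_f1 = s_part * cess_p + s_non * cess_n
        s_part = s_part * (1.0 - pd_s.sum(axis=1) - po_s - cess_p)
        s_non = s_non * (1.0 - pd_s.sum(axis=1) - po_s - cess_n)

        # --- former smokers (tunnel) ------------------------------------
        pd_f = p_dis_path[:, t, dstat, :]               # (n, d_max, 3)
        po_f = resid_path[:, t, dstat]                  # (n, d_max)
        new_dis_f = (f_occ[:, :, None] * pd_f).sum(axis=1)
        dis[:, :, t, DIAG_FORMER] += new_dis_f
        trace.inc[:, t, :] += new_dis_f
        trace.deaths[:, t, 3] += (f_occ * po_f).sum(axis=1)
        survivors = f_occ * (1.0 - pd_f.sum(axis=2) - po_f)
        f_next = np.zeros_like(f_occ)
        f_next[:, 1:] = survivors[:, :-1]
        f_next[:, -1] += survivors[:, -1]               # last band is absorbing in d
        f_next[:, 0] = to_f1
        f_occ = f_next

        # --- disease track (snapshot before deaths, after incidence) ----
        if t in snapshot_cycles:
            trace.snapshots[t] = dis.copy()
        if survival_mode == "fixed":
            tsd = tsd_grid + t                           # (T+1,) per diag-cycle column
            dying_mask = (tsd[None, None, :, None] == p_death - 1.0)
            d_deaths = np.where(dying_mask, dis, 0.0)
        else:
            d_deaths = dis * p_death
        dis = dis - d_deaths
        per_disease = d_deaths.sum(axis=(2, 3))
        trace.deaths[:, t, :3] += per_disease

        dead = trace.occ_d[:, t] + trace.deaths[:, t, :].sum(axis=1)

        # --- age-110 cap: survivors are moved to D ----------------------
        if np.any(at_cap):
            cap = at_cap
            trace.deaths[cap, t, :3] += dis[cap].sum(axis=(2, 3))
            trace.deaths[cap, t, 3] += s_part[cap] + s_non[cap] + f_occ[cap].sum(axis=1)
            dead[cap] = weights[cap]
            s_part[cap] = 0.0
            s_non[cap] = 0.0
            f_occ[cap] = 0.0
            dis[cap] = 0.0
            log.debug("cycle %d: moved age-capped strata to death state", t)

        if horizon == "lifetime" and dead.sum() >= cohort.size - 1e-9:
            trace = _truncate_trace(trace, t + 1)
            trace.occ_d[:, t + 1] = dead
            return trace

    return trace


def _truncate_trace(trace: CohortTrace, T: int) -> CohortTrace:
    return CohortTrace(
        cohort=trace.cohort, strategy=trace.strategy,
        occ_s_part=trace.occ_s_part[:, :T + 1], occ_s_non=trace.occ_s_non[:, :T + 1],
        occ_f=trace.occ_f[:, :T + 1], occ_dis=trace.occ_dis[:, :T + 1],
        occ_d=trace.occ_d[:, :T + 1], inc=trace.inc[:, :T + 1],
        deaths=trace.deaths[:, :T + 1], attempts=trace.attempts[:, :T + 1],
        snapshots=trace.snapshots,
    )


def life_years(trace: CohortTrace, rate: float = 0.03, per_stratum: bool = False):
    """Discounted life-years: persons alive at each cycle start, discounted.

    One full year is credited per executed cycle to persons alive at that
    cycle's start (no half-cycle correction); the occupancy recorded at the
    final horizon boundary is not an executed cycle and earns nothing.
    """
    if rate < 0:
        raise ConfigurationError("discount rate must be >= 0")
    alive = trace.alive()[:, :-1]
    df = (1.0 + rate) ** (-np.arange(alive.shape[1]))
    ly = alive @ df
    return ly if per_stratum else float(ly.sum())


def cause_specific_deaths(trace_a: CohortTrace, trace_b: CohortTrace, per: float = 1000.0) -> dict:
    """Deaths avoided per cause: cumulative tallies of arm A minus arm B,
    normalized per ``per`` cohort members."""
    if trace_a.cohort != trace_b.cohort:
        raise ConfigurationError("traces come from different cohorts")
    size = trace_a.cohort.size
    a = trace_a.cumulative_deaths_by_cause()
    b = trace_b.cumulative_deaths_by_cause()
    return {c: (a[c] - b[c]) * per / size for c in DEATH_CAUSES}


__all__ = [
    "DEATH_CAUSES", "SURVIVAL_MODES",
    "definitive_cessation_probability", "participation_rate",
    "annual_death_probability_from_life_expectancy",
    "StrategySpec", "full_coverage_strategy", "fifty_euro_strategy", "no_coverage_strategy",
    "Stratum", "CohortSpec", "default_french_smoker_cohort",
    "DiseaseSurvivalSpec", "MortalityTables", "CohortTrace",
    "build_transition_row", "run_cohort", "life_years", "cause_specific_deaths",
]
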