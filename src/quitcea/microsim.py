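"""Individual-level microsimulation used as an independent check.

Simulates each smoker as a random walker through the same six-state
structure as the cohort engine.  In expectation the two agree exactly, so
the microsimulated state occupancies provide a Monte Carlo oracle for the
deterministic cohort trace (per-cycle agreement within sampling error).
"""

from __future__ import annotations

import numpy as np

from .life_tables import AGE_MAX, AGE_MIN, GENDERS, STATUS_CURRENT, STATUS_NEVER
from .markov import (
    CohortSpec, DiseaseSurvivalSpec, MortalityTables, StrategySpec,
    _disease_death_prob_paths,
)

# walker state codes
_S = 0          # smoker
_F_BASE = 1     # former smoker with duration d -> code _F_BASE + d - 1
_DIS_BASE = 100  # disease code _DIS_BASE + disease index
_D = 999


def simulate_individuals(cohort: CohortSpec, strategy: StrategySpec,
                         tables: MortalityTables,
                         survival: DiseaseSurvivalSpec | None = None,
                         n_walkers: int = 200_000, seed: int = 0,
                         horizon: int | None = None,
                         survival_mode: str = "reciprocal",
                         initial_status: str = "current") -> dict:
    """Monte Carlo walk of ``n_walkers`` individuals through the model.

    Walkers are allocated to strata proportionally to weights.  Returns a
    dict with per-stratum occupancy *fractions* of the six aggregate states
    (S, F, C, O, V, D) at each cycle start, the walker counts per stratum,
    and matching expected fractions are obtainable from a cohort trace via
    ``CohortTrace.occupancy()``.
    """
    if survival is None:
        survival = DiseaseSurvivalSpec()
    strata = cohort.strata
    n_strata = len(strata)
    weights = np.array([s.weight for s in strata])
    alloc = np.maximum(1, np.round(weights / weights.sum() * n_walkers).astype(int))
    entry = np.array([s.entry_age for s in strata])
    max_cycles = int(AGE_MAX - entry.min())
    T = max_cycles if horizon is None else min(int(horizon), max_cycles)
    d_max = tables.tunnel_length
    smoker_si = STATUS_NEVER if initial_status == "never" else STATUS_CURRENT
    diag_si = 0 if initial_status == "never" else 1  # never/current/former at diagnosis

    rng = np.random.default_rng(seed)
    p_death = _disease_death_prob_paths(strata, survival, T, survival_mode)

    occ = np.zeros((n_strata, T + 1, 6))
    for i, s in enumerate(strata):
        N = int(alloc[i])
        gi = GENDERS.index(s.gender)
        state = np.full(N, _S, dtype=np.int32)
        participant = rng.random(N) < strategy.participation
        dis_p = np.zeros(N)        # annual death probability once diagnosed
        dis_left = np.zeros(N, dtype=np.int32)  # remaining years in fixed mode

        for t in range(T + 1):
            is_s = state == _S
            is_f = (state >= _F_BASE) & (state < _F_BASE + d_max)
            is_dis = (state >= _DIS_BASE) & (state < _DIS_BASE + 3)
            occ[i, t, 0] = is_s.sum()
            occ[i, t, 1] = is_f.sum()
            for di in range(3):
                occ[i, t, 2 + di] = (state == _DIS_BASE + di).sum()
            occ[i, t, 5] = (state == _D).sum()
            if t == T:
                break
            age = min(s.entry_age + t, AGE_MAX)
            ai = age - AGE_MIN

            u = rng.random(N)
            new_state = state.copy()

            # smokers: diseases, other-cause death, cessation, stay
            if is_s.any():
                pd_s = tables.disease.probs[gi, ai, smoker_si, :]
                po = tables.residual[gi, ai, smoker_si]
                cess = np.where(participant,
                                strategy.cessation_prob(t, True),
                                strategy.cessation_prob(t, False))
                cum = np.cumsum(np.concatenate([pd_s, [po]]))
                us = u[is_s]
                cs = cess[is_s]
                dest = np.full(us.shape, _S, dtype=np.int32)
                dest[us < cum[3]] = _D
                for di in (2, 1, 0):
                    dest[us < cum[di]] = _DIS_BASE + di
                quit_mask = (us >= cum[3]) & (us < cum[3] + cs)
                dest[quit_mask] = _F_BASE  # duration 1
                new_state[is_s] = dest

            # former smokers by tunnel year
            if is_f.any():
                for d in range(1, d_max + 1):
                    sel = state == _F_BASE + d - 1
                    if not sel.any():
                        continue
                    si = int(tables.duration_status[d - 1])
                    pd_f = tables.disease.probs[gi, ai, si, :]
                    po = tables.residual[gi, ai, si]
                    cum = np.cumsum(np.concatenate([pd_f, [po]]))
                    uf = u[sel]
                    nxt = _F_BASE + min(d + 1, d_max) - 1
                    dest = np.full(uf.shape, nxt, dtype=np.int32)
                    dest[uf < cum[3]] = _D
                    for di in (2, 1, 0):
                        dest[uf < cum[di]] = _DIS_BASE + di
                    new_state[sel] = dest

            # configure the disease track for fresh diagnoses
            fresh = (new_state >= _DIS_BASE) & (new_state < _DIS_BASE + 3) & ~is_dis
            if fresh.any():
                was_f = is_f & fresh
                for di in range(3):
                    sel = fresh & (new_state == _DIS_BASE + di)
                    if not sel.any():
                        continue
                    for former, si in ((False, diag_si), (True, 2)):
                        ss = sel & (was_f if former else ~was_f)
                        if not ss.any():
                            continue
                        val = p_death[i, di, t, si]
                        if survival_mode == "fixed":
                            dis_left[ss] = int(val)
                        else:
                            dis_p[ss] = val

            # established disease-track deaths (fresh cases are at risk this
            # same cycle, matching the cohort engine's ordering)
            on_track = (new_state >= _DIS_BASE) & (new_state < _DIS_BASE + 3)
            if on_track.any():
                if survival_mode == "fixed":
                    dis_left[on_track] -= 1
                    new_state[on_track & (dis_left <= 0)] = _D
                else:
                    dies = on_track & (rng.random(N) < dis_p)
                    new_state[dies] = _D

            if min(s.entry_age + t + 1, AGE_MAX) >= AGE_MAX:
                new_state[:] = _D  # age cap
            state = new_state

    fractions = occ / alloc[:, None, None]
    return {"fractions": fractions, "counts": alloc, "n_cycles": T}


def compare_with_cohort(trace, microsim: dict, n_se: float = 3.0) -> dict:
    """Largest |microsim - cohort| occupancy gap in units of binomial SE.

    Returns the worst z-score and the fraction of (stratum, cycle, state)
    cells within ``n_se`` standard errors.  Cells where the cohort
    probability is 0 or 1 have zero sampling variance and must match
    exactly (to a 1e-12 slack).
    """
    T = microsim["n_cycles"]
    expected = trace.occupancy()[:, :T + 1, :] / np.array(
        [s.weight for s in trace.cohort.strata])[:, None, None]
    observed = microsim["fractions"]
    counts = microsim["counts"][:, None, None]
    se = np.sqrt(np.clip(expected * (1 - expected), 0.0, None) / counts)
    diff = np.abs(observed - expected)
    z = np.where(se > 0, diff / np.where(se > 0, se, 1.0), np.where(diff > 1e-12, np.inf, 0.0))
    return {"max_z": float(z.max()), "fraction_within": float((z <= n_se).mean())}


__all__ = ["simulate_individuals", "compare_with_cohort"]
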