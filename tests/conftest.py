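import numpy as np
import pytest

from quitcea.life_tables import (AllCauseMortalitySchedule, DiseaseMortalitySchedule,
                                 RelativeRiskSchedule, SyntheticTableParams,
                                 generate_synthetic_tables, DEFAULT_RR_BANDS, DISEASES)
from quitcea.markov import CohortSpec, MortalityTables, Stratum
from quitcea.pipeline import ModelInputs


@pytest.fixture(scope="session")
def synthetic_tables():
    """Calibrated default synthetic life tables (deterministic, seed 0)."""
    disease, all_cause, rr = generate_synthetic_tables(SyntheticTableParams())
    return MortalityTables(disease=disease, all_cause=all_cause, rr=rr)


@pytest.fixture(scope="session")
def base_inputs(synthetic_tables):
    """Base-case model inputs on the default synthetic tables."""
    return ModelInputs(tables=synthetic_tables)


@pytest.fixture(scope="session")
def small_cohort():
    return CohortSpec((Stratum("male", 40, 600.0), Stratum("female", 50, 400.0)))


@pytest.fixture
def zero_mortality_tables():
    """Tables where nobody ever dies or falls ill."""
    disease = DiseaseMortalitySchedule(bands=DEFAULT_RR_BANDS)
    all_cause = AllCauseMortalitySchedule()
    rr = RelativeRiskSchedule(bands=DEFAULT_RR_BANDS,
                              rr={d: (1.0,) * len(DEFAULT_RR_BANDS) for d in DISEASES})
    return MortalityTables(disease=disease, all_cause=all_cause, rr=rr)


def random_consistent_tables(rng, bands=DEFAULT_RR_BANDS):
    """Random schedules satisfying every type invariant (for property tests)."""
    n_bands = len(bands)
    never = rng.uniform(0.0, 0.01, size=(2, 96, 3))
    mult = rng.uniform(1.0, 5.0, size=3)
    current = never * mult
    disease = DiseaseMortalitySchedule(bands=bands)
    disease.probs[:, :, 0, :] = never
    disease.probs[:, :, 1, :] = current
    rr_decay = np.sort(rng.uniform(1.0, mult.min(), size=(3, n_bands)), axis=1)[:, ::-1]
    rr = RelativeRiskSchedule(bands=bands,
                              rr={d: tuple(rr_decay[i]) for i, d in enumerate(DISEASES)})
    for k in range(n_bands):
        former = never * rr_decay.T[k][None, None, :]
        disease.probs[:, :, 2 + k, :] = np.minimum(former, current)
    margin = rng.uniform(0.0, 0.05, size=(2, 96))
    all_cause = AllCauseMortalitySchedule(
        probs=np.clip(disease.probs.sum(axis=3).max(axis=2) + margin, 0, 1))
    return disease, all_cause, rr
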