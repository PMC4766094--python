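"""Budget impact: national first-year cost and disease cost offsets.

Budget-impact figures follow payer convention: undiscounted, inflation-
adjusted, scaled from the modelled cohort to the national smoker count.
The first-year figure is gross intervention spending at implementation;
offsets are the chronic-illness spending the comparator arm incurs but the
full-coverage arm avoids, accumulated over 5/10/20-year horizons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .economics import CostParameters, chronic_cost_stream
from .errors import ConfigurationError
from .life_tables import DISEASES
from .markov import CohortTrace, StrategySpec
from .pipeline import ModelInputs, run_arm
from .psa import ParameterDistributions, apply_parameter_set, sample_parameter_set

Z975 = 1.959964


@dataclass(frozen=True)
class PopulationScale:
    """Scaling from the modelled cohort to the national smoker population."""

    national_smokers: float = 10_000_000.0  # smokers aged 15-75
    cohort_size: float = 1000.0

    def __post_init__(self):
        if self.national_smokers <= 0 or self.cohort_size <= 0:
            raise ConfigurationError("population counts must be > 0")

    @property
    def factor(self) -> float:
        return self.national_smokers / self.cohort_size


def first_year_budget(trace: CohortTrace, strategy: StrategySpec,
                      scale: PopulationScale) -> float:
    """Gross intervention spending in the implementation year, undiscounted."""
    per_cohort = float(trace.attempts[:, 0].sum()) * (strategy.consult_cost + strategy.drug_cost)
    return per_cohort * scale.factor


def horizon_cost_offsets(trace_full: CohortTrace, trace_comparator: CohortTrace,
                         costs: CostParameters, scale: PopulationScale,
                         horizon: int) -> dict:
    """Per-disease avoided chronic spending over the first ``horizon`` cycles.

    Positive values mean the comparator spends more than full coverage.
    """
    for trace in (trace_full, trace_comparator):
        if horizon > trace.n_cycles:
            raise ConfigurationError(
                f"horizon {horizon} exceeds trace length {trace.n_cycles}")
    full = chronic_cost_stream(trace_full, costs, per_disease=True)
    comp = chronic_cost_stream(trace_comparator, costs, per_disease=True)
    diff = (comp[:, :horizon, :] - full[:, :horizon, :]).sum(axis=(0, 1)) * scale.factor
    out = {d: float(v) for d, v in zip(DISEASES, diff)}
    out["combined"] = float(diff.sum())
    return out


@dataclass
class BIAResult:
    deterministic: dict
    iterations: pd.DataFrame | None = None

    def summary(self) -> dict:
        out = {"deterministic": self.deterministic}
        if self.iterations is not None:
            probs = {}
            for col in self.iterations.columns:
                if col == "iteration":
                    continue
                x = self.iterations[col].to_numpy(dtype=float)
                n = len(x)
                mean = float(np.mean(x))
                sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
                half = Z975 * sd / np.sqrt(n) if n > 1 else 0.0
                probs[col] = {
                    "mean": mean, "sd": sd,
                    # interval for the Monte Carlo mean vs interval of the draws:
                    # both are reported because either reading is defensible
                    "ci95_mean": [mean - half, mean + half],
                    "interval95_sample": [float(np.percentile(x, 2.5)),
                                          float(np.percentile(x, 97.5))],
                    "p95": float(np.percentile(x, 95)),
                }
            out["probabilistic"] = probs
        return out


def deterministic_budget_impact(inputs: ModelInputs, scale: PopulationScale,
                                horizons=(5, 10, 20)) -> dict:
    trace_full = run_arm(inputs, inputs.full)
    trace_comp = run_arm(inputs, inputs.comparator)
    out = {
        "first_year_cost_full": first_year_budget(trace_full, inputs.full, scale),
        "first_year_cost_comparator": first_year_budget(trace_comp, inputs.comparator, scale),
    }
    for h in horizons:
        out[f"offsets_{h}y"] = horizon_cost_offsets(
            trace_full, trace_comp, inputs.costs, scale, h)
    return out


def probabilistic_budget_impact(inputs: ModelInputs, dists: ParameterDistributions | None,
                                n_iterations: int, seed: int, scale: PopulationScale,
                                offset_horizon: int = 5) -> BIAResult:
    """Monte Carlo budget impact reusing the sensitivity-analysis sampler."""
    if n_iterations < 1:
        raise ConfigurationError("n_iterations must be >= 1")
    dists = dists if dists is not None else ParameterDistributions()
    rng = np.random.default_rng(seed)
    rows = []
    for it in range(n_iterations):
        params = sample_parameter_set(dists, rng)
        drawn = apply_parameter_set(inputs, params)
        trace_full = run_arm(drawn, drawn.full)
        trace_comp = run_arm(drawn, drawn.comparator)
        offsets = horizon_cost_offsets(trace_full, trace_comp, drawn.costs, scale,
                                       offset_horizon)
        rows.append({
            "iteration": it,
            "first_year_cost": first_year_budget(trace_full, drawn.full, scale),
            **{f"offset_{d}": offsets[d] for d in DISEASES},
            "offset_combined": offsets["combined"],
        })
    return BIAResult(deterministic=deterministic_budget_impact(inputs, scale),
                     iterations=pd.DataFrame(rows))


__all__ = [
    "PopulationScale", "BIAResult",
    "first_year_budget", "horizon_cost_offsets",
    "deterministic_budget_impact", "probabilistic_budget_impact",
]
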