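"""Costing and incremental cost-effectiveness from cohort traces.

All prices are 2009 euros from the statutory-health-insurance perspective.
Intervention spending prices each covered attempt (consultation plus drug
course, inflated on separate price indexes); disease spending applies the
annual chronic-illness cost of the long-term-illness (ALD) scheme to every
person-cycle spent in a disease state, including the diagnosis cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .life_tables import DISEASES
from .markov import CohortTrace, StrategySpec

#: annual chronic-illness cost per person, 2009 euros
DEFAULT_CHRONIC_COSTS = {"lung_cancer": 13872.0, "copd": 6562.0, "cvd": 7976.0}
#: annual price inflation per cost stream (2004-2008 health price indexes)
DEFAULT_INFLATION = {"gp_visits": 0.0023, "drugs": 0.0219, "chronic": -0.015}


@dataclass(frozen=True)
class CostParameters:
    chronic_costs: dict = field(default_factory=lambda: dict(DEFAULT_CHRONIC_COSTS))
    inflation: dict = field(default_factory=lambda: dict(DEFAULT_INFLATION))

    def __post_init__(self):
        for dis in DISEASES:
            if dis not in self.chronic_costs:
                raise ConfigurationError(f"missing chronic cost for disease {dis!r}")
            if self.chronic_costs[dis] < 0:
                raise ConfigurationError(f"chronic cost for {dis!r} must be >= 0")
        for stream in ("gp_visits", "drugs", "chronic"):
            if stream not in self.inflation:
                raise ConfigurationError(f"missing inflation rate for stream {stream!r}")


@dataclass(frozen=True)
class DiscountSpec:
    """Annual discount rate with independent switches for each stream,
    so the 'benefits undiscounted' sensitivity can be reproduced."""

    rate: float = 0.03
    discount_costs: bool = True
    discount_benefits: bool = True

    def __post_init__(self):
        if self.rate < 0:
            raise ConfigurationError("discount rate must be >= 0")

    @property
    def cost_rate(self) -> float:
        return self.rate if self.discount_costs else 0.0

    @property
    def benefit_rate(self) -> float:
        return self.rate if self.discount_benefits else 0.0


def inflate_cost(base: float, annual_rate: float, years: float) -> float:
    """Compound a 2009 price forward: base x (1 + rate)^years."""
    if years < 0:
        raise ConfigurationError("years elapsed must be >= 0")
    return base * (1.0 + annual_rate) ** years


def discount_factor(rate: float, cycle) -> float:
    """Present-value factor (1 + rate)^(-cycle)."""
    if np.any(np.asarray(cycle) < 0):
        raise ConfigurationError("cycle must be >= 0")
    return (1.0 + rate) ** (-np.asarray(cycle, dtype=float))


def attempt_cost_stream(trace: CohortTrace, strategy: StrategySpec,
                        costs: CostParameters) -> np.ndarray:
    """Undiscounted intervention spending per stratum and cycle (inflated)."""
    t = np.arange(trace.n_cycles + 1)
    unit = (strategy.consult_cost * (1.0 + costs.inflation["gp_visits"]) ** t
            + strategy.drug_cost * (1.0 + costs.inflation["drugs"]) ** t)
    return trace.attempts * unit[None, :]


def chronic_cost_stream(trace: CohortTrace, costs: CostParameters,
                        per_disease: bool = False) -> np.ndarray:
    """Undiscounted chronic-illness spending per stratum and cycle (inflated).

    With ``per_disease=True`` the disease axis is kept: (n, T+1, 3).
    """
    t = np.arange(trace.n_cycles + 1)
    infl = (1.0 + costs.inflation["chronic"]) ** t
    unit = np.array([costs.chronic_costs[d] for d in DISEASES])
    stream = trace.disease_person_years() * unit[None, None, :] * infl[None, :, None]
    return stream if per_disease else stream.sum(axis=2)


def strategy_cost(trace: CohortTrace, strategy: StrategySpec, costs: CostParameters,
                  discount: DiscountSpec, per_stratum: bool = False):
    """Total discounted cost of one arm: covered attempts plus chronic illness.

    Only executed cycles accrue cost; the final horizon boundary does not.
    """
    T = trace.n_cycles
    df = discount_factor(discount.cost_rate, np.arange(T))
    stream = (attempt_cost_stream(trace, strategy, costs)
              + chronic_cost_stream(trace, costs))[:, :T]
    total = stream @ df
    return total if per_stratum else float(total.sum())


@dataclass(frozen=True)
class CEAResult:
    """Paired costs and effects with the incremental ratio or a dominance label."""

    cost_a: float
    cost_b: float
    ly_a: float
    ly_b: float
    label_a: str = "intervention"
    label_b: str = "comparator"

    @property
    def delta_cost(self) -> float:
        return self.cost_a - self.cost_b

    @property
    def delta_ly(self) -> float:
        return self.ly_a - self.ly_b

    @property
    def icer(self) -> float | None:
        if self.delta_ly == 0:
            return None
        return self.delta_cost / self.delta_ly

    @property
    def dominance(self) -> str:
        if self.delta_ly > 0:
            return "cost-saving" if self.delta_cost < 0 else "icer"
        if self.delta_ly == 0:
            return "indeterminate"
        return "dominated" if self.delta_cost > 0 else "indeterminate"

    def as_dict(self) -> dict:
        return {
            "arms": {self.label_a: {"cost": self.cost_a, "life_years": self.ly_a},
                     self.label_b: {"cost": self.cost_b, "life_years": self.ly_b}},
            "delta_cost": self.delta_cost,
            "delta_life_years": self.delta_ly,
            "icer_eur_per_lyg": self.icer,
            "dominance": self.dominance,
        }


def compute_icer(cost_a: float, cost_b: float, ly_a: float, ly_b: float,
                 label_a: str = "intervention", label_b: str = "comparator") -> CEAResult:
    for v in (cost_a, cost_b, ly_a, ly_b):
        if not np.isfinite(v):
            raise ConfigurationError("costs and effects must be finite")
    return CEAResult(cost_a, cost_b, ly_a, ly_b, label_a, label_b)


__all__ = [
    "DEFAULT_CHRONIC_COSTS", "DEFAULT_INFLATION",
    "CostParameters", "DiscountSpec", "CEAResult",
    "inflate_cost", "discount_factor",
    "attempt_cost_stream", "chronic_cost_stream", "strategy_cost", "compute_icer",
]
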