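"""Probabilistic and deterministic sensitivity analysis.

The probabilistic analysis redraws the uncertain parameters — per-attempt
cessation probability (log-normal anchored at the base-case value as the
median, spread fitted from the reported 95% CI), participation and drug
cost (triangular), and the number/frequency of covered attempts, discount
rate and inflation alternates (discrete) — and re-evaluates both arms with
the same draw (common random numbers), yielding the distribution of the
incremental cost-effectiveness ratio.  The deterministic sweep varies only
the number of covered attempts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .markov import life_years
from .pipeline import ModelInputs, run_cea

Z975 = 1.959964  # two-sided 95% normal quantile


def fit_lognormal_from_ci(point: float, ci_low: float, ci_high: float) -> tuple:
    """(mu, sigma) of a log-normal with median ``point`` and log-scale spread
    matching the CI width: sigma = ln(high/low) / (2 x 1.959964).

    The point estimate is treated as the median (exp(mu) == point), so if the
    printed CI is not symmetric about the point on the log scale the fitted
    interval deviates slightly from the printed one.
    """
    if not 0 < ci_low < point < ci_high:
        raise ConfigurationError(
            f"need 0 < ci_low < point < ci_high, got ({ci_low}, {point}, {ci_high})")
    sigma = math.log(ci_high / ci_low) / (2.0 * Z975)
    return math.log(point), sigma


def sample_triangular(lo: float, mode: float, hi: float, u) -> float | np.ndarray:
    """Inverse-CDF draw from a triangular distribution at uniform quantile u."""
    if not lo <= mode <= hi:
        raise ConfigurationError(f"need min <= mode <= max, got ({lo}, {mode}, {hi})")
    u = np.asarray(u, dtype=float)
    if np.any(u < 0) or np.any(u > 1):
        raise ConfigurationError("u must lie in [0, 1]")
    if lo == hi:
        return lo if u.ndim == 0 else np.full_like(u, lo)
    fc = (mode - lo) / (hi - lo)
    left = lo + np.sqrt(u * (hi - lo) * (mode - lo))
    right = hi - np.sqrt((1.0 - u) * (hi - lo) * (hi - mode))
    out = np.where(u < fc, left, right)
    # guard the degenerate edges (mode == lo or mode == hi)
    out = np.where(u == 0, lo, np.where(u == 1, hi, out))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class Triangular:
    lo: float
    mode: float
    hi: float

    def __post_init__(self):
        if not self.lo <= self.mode <= self.hi:
            raise ConfigurationError("triangular needs min <= mode <= max")

    def sample(self, rng) -> float:
        return float(sample_triangular(self.lo, self.mode, self.hi, rng.uniform()))

    @property
    def mean(self) -> float:
        return (self.lo + self.mode + self.hi) / 3.0


@dataclass(frozen=True)
class LogNormal:
    mu: float
    sigma: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ConfigurationError("log-normal sigma must be > 0")

    @classmethod
    def from_ci(cls, point, ci_low, ci_high):
        return cls(*fit_lognormal_from_ci(point, ci_low, ci_high))

    def sample(self, rng) -> float:
        return float(rng.lognormal(self.mu, self.sigma))

    @property
    def median(self) -> float:
        return math.exp(self.mu)


@dataclass(frozen=True)
class Discrete:
    support: tuple

    def __post_init__(self):
        if not self.support:
            raise ConfigurationError("discrete support must be non-empty")

    def sample(self, rng):
        return self.support[int(rng.integers(len(self.support)))]


@dataclass(frozen=True)
class Degenerate:
    value: float

    def sample(self, rng):
        return self.value


@dataclass(frozen=True)
class ParameterDistributions:
    """Sampling specification of the probabilistic analysis.

    The comparator's natural cessation rate is deliberately not sampled;
    there is no evidence base for its variation.
    """

    cessation: LogNormal = field(
        default_factory=lambda: LogNormal.from_ci(0.0704, 0.0564, 0.0947))
    participation: Triangular = field(default_factory=lambda: Triangular(0.05, 0.073, 0.73))
    drug_cost: Triangular = field(default_factory=lambda: Triangular(120.0, 201.0, 220.0))
    attempts: Discrete = field(default_factory=lambda: Discrete((2, 4, 6)))
    frequency: Discrete = field(default_factory=lambda: Discrete((1, 2, 4)))
    discount: Discrete = field(default_factory=lambda: Discrete((0.0, 0.03, 0.06)))
    inflation_gp: Discrete = field(default_factory=lambda: Discrete((0.0023, 0.0132)))
    inflation_drugs: Discrete = field(default_factory=lambda: Discrete((0.0219, -0.0538)))
    inflation_chronic: Discrete = field(default_factory=lambda: Discrete((-0.015, 0.015)))

    _FIELDS = ("cessation", "participation", "drug_cost", "attempts", "frequency",
               "discount", "inflation_gp", "inflation_drugs", "inflation_chronic")

    @classmethod
    def degenerate(cls, inputs: ModelInputs) -> "ParameterDistributions":
        """Collapse every distribution onto the base-case value of ``inputs``."""
        return cls(
            cessation=Degenerate(inputs.full.attempt_cessation_prob),
            participation=Degenerate(inputs.full.participation),
            drug_cost=Degenerate(inputs.full.drug_cost),
            attempts=Discrete((inputs.full.n_attempts,)),
            frequency=Discrete((inputs.full.attempt_frequency_years,)),
            discount=Discrete((inputs.discount.rate,)),
            inflation_gp=Discrete((inputs.costs.inflation["gp_visits"],)),
            inflation_drugs=Discrete((inputs.costs.inflation["drugs"],)),
            inflation_chronic=Discrete((inputs.costs.inflation["chronic"],)),
        )


def sample_parameter_set(dists: ParameterDistributions, rng) -> dict:
    """One independent draw per parameter; reproducible under a seeded rng."""
    return {name: getattr(dists, name).sample(rng) for name in dists._FIELDS}


def apply_parameter_set(inputs: ModelInputs, params: dict) -> ModelInputs:
    """Return inputs with one sampled parameter set substituted in."""
    full = replace(inputs.full,
                   attempt_cessation_prob=min(1.0, float(params["cessation"])),
                   participation=float(params["participation"]),
                   drug_cost=float(params["drug_cost"]),
                   n_attempts=int(params["attempts"]),
                   attempt_frequency_years=int(params["frequency"]))
    discount = replace(inputs.discount, rate=float(params["discount"]))
    costs = replace(inputs.costs, inflation={
        "gp_visits": float(params["inflation_gp"]),
        "drugs": float(params["inflation_drugs"]),
        "chronic": float(params["inflation_chronic"]),
    })
    return inputs.with_(full=full, discount=discount, costs=costs)


@dataclass
class PSAResult:
    iterations: pd.DataFrame
    seed: int

    def summary(self) -> dict:
        icer = self.iterations["icer"].to_numpy(dtype=float)  # None -> NaN
        return {
            "n": int(len(icer)),
            "mean": float(np.nanmean(icer)),
            "sd": float(np.nanstd(icer, ddof=1)) if len(icer) > 1 else 0.0,
            "median": float(np.nanmedian(icer)),
            "q25": float(np.nanpercentile(icer, 25)),
            "q75": float(np.nanpercentile(icer, 75)),
            "p95": float(np.nanpercentile(icer, 95)),
            "p99": float(np.nanpercentile(icer, 99)),
            "min": float(np.nanmin(icer)),
            "max": float(np.nanmax(icer)),
            "fraction_cost_saving": float(np.mean(
                self.iterations["dominance"].to_numpy() == "cost-saving")),
        }

    def cumulative_frequency(self) -> pd.DataFrame:
        """Empirical cumulative distribution of the ICER (for re-plotting)."""
        icer = np.sort(self.iterations["icer"].to_numpy(dtype=float))
        return pd.DataFrame({
            "icer": icer,
            "cumulative_frequency": np.arange(1, len(icer) + 1) / len(icer),
        })


def run_psa(inputs: ModelInputs, dists: ParameterDistributions | None = None,
            n_iterations: int = 1000, seed: int = 0) -> PSAResult:
    """Monte Carlo over parameter draws; each draw evaluates both arms.

    Parameter draws are independent across parameters; the same draw feeds
    both arms of an iteration (common random numbers), so arm differences
    reflect the strategy, not sampling noise.
    """
    if n_iterations < 1:
        raise ConfigurationError("n_iterations must be >= 1")
    dists = dists if dists is not None else ParameterDistributions()
    rng = np.random.default_rng(seed)
    rows = []
    for it in range(n_iterations):
        params = sample_parameter_set(dists, rng)
        out = run_cea(apply_parameter_set(inputs, params))
        res = out.result
        rows.append({"iteration": it, **params,
                     "cost_full": res.cost_a, "cost_comparator": res.cost_b,
                     "ly_full": res.ly_a, "ly_comparator": res.ly_b,
                     "delta_cost": res.delta_cost, "delta_ly": res.delta_ly,
                     "icer": res.icer, "dominance": res.dominance})
    return PSAResult(iterations=pd.DataFrame(rows), seed=seed)


def attempts_sweep(inputs: ModelInputs, attempts=(2, 4, 6)) -> pd.DataFrame:
    """Deterministic sweep of the number of covered attempts.

    Reports the (discounted) ICER and the life-year gain per cohort with the
    discount applied to costs only (the benefit-undiscounted convention the
    deterministic sensitivity uses).
    """
    rows = []
    for n in attempts:
        swept = inputs.with_(full=replace(inputs.full, n_attempts=int(n)))
        out = run_cea(swept)
        ly_gain_undisc = (life_years(out.trace_full, 0.0)
                          - life_years(out.trace_comparator, 0.0))
        rows.append({"attempts": int(n),
                     "icer": out.result.icer,
                     "dominance": out.result.dominance,
                     "delta_cost": out.result.delta_cost,
                     "delta_ly_discounted": out.result.delta_ly,
                     "ly_gain_undiscounted": ly_gain_undisc})
    return pd.DataFrame(rows)


__all__ = [
    "Z975", "fit_lognormal_from_ci", "sample_triangular",
    "Triangular", "LogNormal", "Discrete", "Degenerate",
    "ParameterDistributions", "sample_parameter_set", "apply_parameter_set",
    "PSAResult", "run_psa", "attempts_sweep",
]
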