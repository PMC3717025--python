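"""Probabilistic sensitivity analysis and value-of-information measures.

Second-order Monte Carlo: each iteration draws one realization of every
model input and evaluates both strategies on that shared draw (common
random numbers), yielding paired (cost, QALY) outcomes.  From the sample
this module derives cost-effectiveness plane quadrant proportions, net
monetary benefit NB = lambda * QALYs - cost, the per-patient expected
value of perfect information

    EVPI(lambda) = E[max_s NB_s] - max_s E[NB_s],

the effective population (discounted future incidence over the
technology's lifetime), and the population EVPI, their product.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from hemovoi.cohort_model import (
    DEFAULT_CONFIG,
    ModelConfig,
    default_strategies,
    evaluate_strategy,
)
from hemovoi.parameters import ClipCounter, ParameterTable, sample_draw

__all__ = [
    "PSASample",
    "EVPIResult",
    "run_psa",
    "ce_plane_quadrants",
    "net_benefit",
    "evpi_per_patient",
    "effective_population",
    "evpi_curve",
]

STRATEGY_NAMES = ("routine", "gdht")


@dataclass(frozen=True)
class PSASample:
    """Paired Monte Carlo outcomes for the two strategies.

    ``cost`` and ``qalys`` are (N, 2) arrays with columns ordered as
    :data:`STRATEGY_NAMES`; increments are GDHT minus routine.
    """

    cost: np.ndarray
    qalys: np.ndarray
    seed: int
    table_fingerprint: str
    n_clipped: int = 0

    def __post_init__(self) -> None:
        if self.cost.shape != self.qalys.shape or self.cost.ndim != 2:
            raise ValueError("cost and qalys must be matching (N, 2) arrays")
        if self.cost.shape[0] < 1 or self.cost.shape[1] != 2:
            raise ValueError(f"need an (N>=1, 2) sample, got {self.cost.shape}")
        if not (np.isfinite(self.cost).all() and np.isfinite(self.qalys).all()):
            raise ValueError("non-finite outcomes in PSA sample")

    @property
    def n_iterations(self) -> int:
        return self.cost.shape[0]

    @property
    def delta_cost(self) -> np.ndarray:
        """Incremental cost, GDHT minus routine."""
        return self.cost[:, 1] - self.cost[:, 0]

    @property
    def delta_qalys(self) -> np.ndarray:
        """Incremental effect (QALYs), GDHT minus routine."""
        return self.qalys[:, 1] - self.qalys[:, 0]

    def to_frame(self) -> pd.DataFrame:
        """Long-format per-iteration outcomes plus increments."""
        n = self.n_iterations
        frames = []
        for j, name in enumerate(STRATEGY_NAMES):
            frames.append(
                pd.DataFrame(
                    {
                        "iteration": np.arange(n),
                        "strategy": name,
                        "cost": self.cost[:, j],
                        "qalys": self.qalys[:, j],
                        "delta_cost": self.delta_cost,
                        "delta_qalys": self.delta_qalys,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class EVPIResult:
    """EVPI across a willingness-to-pay grid, per patient and population."""

    lambdas: np.ndarray
    evpi_per_patient: np.ndarray
    effective_population: int
    population_evpi: np.ndarray
    annual_incidence: float
    lifetime: int
    discount: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lambda": self.lambdas,
                "evpi_per_patient": self.evpi_per_patient,
                "population_evpi": self.population_evpi,
            }
        )


def run_psa(
    table: ParameterTable,
    n_iterations: int = 1000,
    seed: int = 0,
    horizon: int = 5,
    discount: float = 0.03,
    config: ModelConfig = DEFAULT_CONFIG,
) -> PSASample:
    """Second-order Monte Carlo over the parameter table.

    Each iteration draws one parameter set and evaluates both strategies
    on it (common random numbers across strategies within an iteration).
    Reproducible bit-for-bit given the same seed and table.
    """
    if n_iterations < 1:
        raise ValueError(f"n_iterations must be >= 1, got {n_iterations}")
    rng = np.random.default_rng(seed)
    strategies = default_strategies(table)
    clip = ClipCounter()
    cost = np.empty((n_iterations, 2))
    qalys = np.empty((n_iterations, 2))
    for i in range(n_iterations):
        draw = sample_draw(table, rng)
        for j, strategy in enumerate(strategies):
            outcome = evaluate_strategy(
                draw, strategy, horizon, discount, config, clip_counter=clip
            )
            cost[i, j] = outcome.cost
            qalys[i, j] = outcome.qalys
    return PSASample(
        cost=cost,
        qalys=qalys,
        seed=seed,
        table_fingerprint=table.fingerprint(),
        n_clipped=clip.count,
    )


def ce_plane_quadrants(sample: PSASample) -> dict[str, float]:
    """Proportions of iterations per cost-effectiveness plane quadrant.

    Keys name the GDHT-versus-routine verdict.  Exact zeros (measure-zero
    events) count as "more effective" / "less costly".
    """
    de = sample.delta_qalys
    dc = sample.delta_cost
    more_eff = de >= 0
    less_costly = dc <= 0
    n = sample.n_iterations
    return {
        "less_costly_more_effective": float((less_costly & more_eff).sum() / n),
        "more_costly_more_effective": float((~less_costly & more_eff).sum() / n),
        "more_costly_less_effective": float((~less_costly & ~more_eff).sum() / n),
        "less_costly_less_effective": float((less_costly & ~more_eff).sum() / n),
    }


def net_benefit(sample: PSASample, lam: float) -> np.ndarray:
    """Net monetary benefit per iteration per strategy at threshold lam.

    NB = lam * QALYs - cost; columns follow :data:`STRATEGY_NAMES`.
    """
    if lam < 0:
        raise ValueError(f"willingness-to-pay must be non-negative, got {lam}")
    return lam * sample.qalys - sample.cost


def evpi_per_patient(nb: np.ndarray) -> float:
    """Per-patient EVPI from a net-benefit matrix (iterations x strategies).

    The expectation of the best-attainable net benefit under perfect
    information minus the best expected net benefit under current
    information; non-negative by Jensen's inequality (tiny negative
    floating-point residue is clamped to 0).
    """
    nb = np.asarray(nb, dtype=float)
    if nb.ndim != 2 or nb.shape[0] < 1:
        raise ValueError(f"need an (N>=1, S) net-benefit matrix, got {nb.shape}")
    value = float(nb.max(axis=1).mean() - nb.mean(axis=0).max())
    return max(value, 0.0)


def effective_population(
    annual_incidence: float, lifetime: int, discount: float
) -> int:
    """Discounted number of future patients facing the decision.

    Sum over the technology's lifetime of the annual incidence discounted
    to present value with the first year undiscounted, rounded down:

        floor( sum_{k=1..L} incidence * (1+r)^-(k-1) )
    """
    if lifetime < 1:
        raise ValueError(f"lifetime must be >= 1, got {lifetime}")
    if discount < 0:
        raise ValueError(f"discount must be non-negative, got {discount}")
    if annual_incidence < 0:
        raise ValueError("annual_incidence must be non-negative")
    total = sum(
        annual_incidence * (1 + discount) ** -(k - 1) for k in range(1, lifetime + 1)
    )
    return math.floor(total)


def evpi_curve(
    sample: PSASample,
    lambdas,
    annual_incidence: float,
    lifetime: int,
    discount: float,
) -> EVPIResult:
    """Per-patient and population EVPI across a willingness-to-pay grid."""
    grid = np.asarray(lambdas, dtype=float)
    if grid.size == 0:
        raise ValueError("lambda grid must be non-empty")
    if grid.min() < 0:
        raise ValueError("lambda grid must be non-negative")
    if not np.all(np.diff(grid) >= 0):
        raise ValueError("lambda grid must be sorted ascending")
    per_patient = np.array(
        [evpi_per_patient(net_benefit(sample, lam)) for lam in grid]
    )
    pop = effective_population(annual_incidence, lifetime, discount)
    return EVPIResult(
        lambdas=grid,
        evpi_per_patient=per_patient,
        effective_population=pop,
        population_evpi=per_patient * pop,
        annual_incidence=annual_incidence,
        lifetime=lifetime,
        discount=discount,
    )
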