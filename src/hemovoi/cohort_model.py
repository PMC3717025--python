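"""Short-term decision tree feeding a five-year Markov cohort model.

One strategy under one parameter draw is evaluated in two stages.  The
decision tree covers the hospital episode: the cohort splits over five
mutually exclusive outcomes (uncomplicated recovery, cardiovascular
complications, stroke, other complications, death), each with a sampled
episode cost; delivery costs of the chosen fluid strategy are added.  The
resulting outcome mix seeds a six-state annual Markov cohort —

    well, post-cardiovascular, post-stroke, post-other,
    recovered-other, dead

— run for a fixed horizon (default 5 annual cycles).  Recovery is possible
only from the other-complications state; cardiovascular and stroke states
are lifelong; dead is absorbing.  Per cycle, costs and quality-adjusted
life-years accrue on the start-of-cycle occupancies and are discounted by
(1+r)^-(k-1), i.e. the first year is undiscounted and no half-cycle
correction is applied.

Cost conventions: the first cycle uses the first-year follow-up cost
schedule and charges the one-off death cost to the fraction that died in
hospital; later cycles use the years-2+ schedule, in which the well and
recovered states carry no cost.  Deaths in later cycles accrue no extra
cost by default (``ModelConfig.death_cost_every_cycle`` switches this).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from hemovoi.parameters import (
    ClipCounter,
    ParameterDraw,
    ParameterTable,
    gdht_probabilities,
)

__all__ = [
    "STATES",
    "StrategySpec",
    "ModelConfig",
    "OutcomePair",
    "CohortTrace",
    "default_strategies",
    "run_decision_tree",
    "transition_matrix",
    "run_markov",
    "evaluate_strategy",
]

#: Markov state order used throughout.
STATES = ("well", "post_cv", "post_stroke", "post_other", "recovered", "dead")
_WELL, _CV, _STROKE, _OTHER, _REC, _DEAD = range(6)

#: Episode-cost names averaged into the cardiovascular branch.
CV_EPISODE_COSTS = ("cost_episode_mi", "cost_episode_hf")
#: Episode-cost names averaged into the other-complications branch.
OTHER_EPISODE_COSTS = (
    "cost_episode_pneumonia",
    "cost_episode_renal",
    "cost_episode_wound",
    "cost_episode_dvt",
    "cost_episode_pe",
    "cost_episode_gi",
    "cost_episode_confusion",
)


@dataclass(frozen=True)
class StrategySpec:
    """A fluid-management strategy and its per-patient delivery costs (EUR).

    ``name`` must be ``"routine"`` or ``"gdht"``; for ``"gdht"`` the
    sampled relative risks are applied to the routine outcome mix.
    """

    name: str
    device_cost: float
    preop_cost: float
    anesthesia_cost: float

    def __post_init__(self) -> None:
        if self.name not in ("routine", "gdht"):
            raise ValueError(f"unknown strategy name {self.name!r}")
        if min(self.device_cost, self.preop_cost, self.anesthesia_cost) < 0:
            raise ValueError("delivery costs must be non-negative")

    @property
    def delivery_cost(self) -> float:
        return self.device_cost + self.preop_cost + self.anesthesia_cost


def default_strategies(table: ParameterTable) -> tuple[StrategySpec, StrategySpec]:
    """(routine, gdht) strategies with delivery costs from the table."""
    routine = StrategySpec(
        "routine",
        float(table["cost_routine_device"].point_estimate),
        float(table["cost_routine_preop"].point_estimate),
        float(table["cost_routine_anesthesia"].point_estimate),
    )
    gdht = StrategySpec(
        "gdht",
        float(table["cost_gdht_device"].point_estimate),
        float(table["cost_gdht_preop"].point_estimate),
        float(table["cost_gdht_anesthesia"].point_estimate),
    )
    return routine, gdht


@dataclass(frozen=True)
class ModelConfig:
    """Structural assumptions that the published model leaves open.

    Attributes
    ----------
    standard_annual_mortality
        Annual death probability in the well state, standing in for the
        age-adjusted standard mortality of the >80-year-old source
        population (implementer assumption, default 0.10).
    stroke_annual_mortality
        Annual post-stroke death probability for cycles 2+.  ``None``
        (default) follows the cardiovascular schedule.
    death_cost_every_cycle
        If True, the one-off death cost is charged to the newly dead in
        every cycle, not only to in-hospital deaths in cycle 1.
    cv_episode_weights / other_episode_weights
        Mixing weights for the component episode costs of the grouped
        cardiovascular / other branches (default: unweighted means).
    """

    standard_annual_mortality: float = 0.10
    stroke_annual_mortality: float | None = None
    death_cost_every_cycle: bool = False
    cv_episode_weights: tuple[float, ...] = (0.5, 0.5)
    other_episode_weights: tuple[float, ...] = tuple([1.0 / 7] * 7)

    def __post_init__(self) -> None:
        if not 0 <= self.standard_annual_mortality <= 1:
            raise ValueError("standard_annual_mortality must be in [0, 1]")
        if self.stroke_annual_mortality is not None and not (
            0 <= self.stroke_annual_mortality <= 1
        ):
            raise ValueError("stroke_annual_mortality must be in [0, 1]")
        for w, k in ((self.cv_episode_weights, 2), (self.other_episode_weights, 7)):
            if len(w) != k or abs(sum(w) - 1.0) > 1e-9 or min(w) < 0:
                raise ValueError(f"episode weights must be {k} non-negatives summing to 1")


DEFAULT_CONFIG = ModelConfig()


@dataclass(frozen=True)
class OutcomePair:
    """Total discounted cost (EUR) and discounted QALYs for one strategy."""

    cost: float
    qalys: float


@dataclass(frozen=True)
class CohortTrace:
    """State occupancies and discounted flows per cycle.

    ``occupancy[k]`` is the distribution at the *start* of cycle k+1 (row 0
    is the post-hospital mix seeding the Markov model); ``cost`` and
    ``qalys`` are the discounted increments accrued during each cycle.
    """

    occupancy: np.ndarray  # (horizon+1, 6); row 0 = initial distribution
    cost: np.ndarray  # (horizon,)
    qalys: np.ndarray  # (horizon,)


def run_decision_tree(
    draw: ParameterDraw,
    strategy: StrategySpec,
    config: ModelConfig = DEFAULT_CONFIG,
    clip_counter: ClipCounter | None = None,
) -> tuple[float, np.ndarray]:
    """Hospital-episode cost and initial Markov distribution for a strategy.

    The routine outcome mix comes from the draw; for GDHT, death is scaled
    by the sampled mortality relative risk and the three complication
    branches by the complications relative risk.  The episode cost of the
    grouped cardiovascular and other branches is a weighted mean of their
    sampled component costs.  No QALYs accrue in the tree.
    """
    probs = draw.outcome_vector
    if strategy.name == "gdht":
        probs = gdht_probabilities(
            probs,
            rr_complications=float(draw["rr_complications"]),
            rr_mortality=float(draw["rr_mortality"]),
            clip_counter=clip_counter,
        )
    cost_cv = float(
        np.dot(config.cv_episode_weights, [draw[n] for n in CV_EPISODE_COSTS])
    )
    cost_other = float(
        np.dot(config.other_episode_weights, [draw[n] for n in OTHER_EPISODE_COSTS])
    )
    episode_costs = np.array(
        [
            draw["cost_episode_death"],
            cost_cv,
            draw["cost_episode_stroke"],
            cost_other,
            draw["cost_episode_uncomplicated"],
        ],
        dtype=float,
    )
    short_cost = strategy.delivery_cost + float(probs @ episode_costs)
    death, cv, stroke, other, uncomplicated = probs
    initial = np.array([uncomplicated, cv, stroke, other, 0.0, death])
    return short_cost, initial


def transition_matrix(
    draw: ParameterDraw,
    cycle: int,
    config: ModelConfig = DEFAULT_CONFIG,
) -> np.ndarray:
    """Row-stochastic transition matrix for a 1-based annual cycle.

    Post-cardiovascular mortality follows the tabulated first/second/third
    year values with the third-year value carried forward; post-stroke
    mortality is the tabulated 3-month value in cycle 1, then the
    cardiovascular schedule (or ``config.stroke_annual_mortality``).  The
    other-complications state can recover; its death and recovery draws
    are renormalized in the (practically impossible) case they exceed 1.
    """
    if cycle < 1:
        raise ValueError(f"cycle must be >= 1, got {cycle}")
    cv_schedule = (
        float(draw["mort_cv_year1"]),
        float(draw["mort_cv_year2"]),
        float(draw["mort_cv_year3"]),
    )
    mort_cv = cv_schedule[min(cycle, 3) - 1]
    if cycle == 1:
        mort_stroke = float(draw["mort_stroke_first"])
    elif config.stroke_annual_mortality is not None:
        mort_stroke = config.stroke_annual_mortality
    else:
        mort_stroke = cv_schedule[min(cycle, 3) - 1]
    mort_other = float(draw["mort_other"])
    rec_other = float(draw["recovery_other"])
    if mort_other + rec_other > 1.0:
        total = mort_other + rec_other
        mort_other, rec_other = mort_other / total, rec_other / total
    mort_rec = float(draw["mort_after_recovery_other"])
    mort_well = config.standard_annual_mortality

    m = np.zeros((6, 6))
    m[_WELL, _WELL] = 1 - mort_well
    m[_WELL, _DEAD] = mort_well
    m[_CV, _CV] = 1 - mort_cv
    m[_CV, _DEAD] = mort_cv
    m[_STROKE, _STROKE] = 1 - mort_stroke
    m[_STROKE, _DEAD] = mort_stroke
    m[_OTHER, _OTHER] = 1 - mort_other - rec_other
    m[_OTHER, _REC] = rec_other
    m[_OTHER, _DEAD] = mort_other
    m[_REC, _REC] = 1 - mort_rec
    m[_REC, _DEAD] = mort_rec
    m[_DEAD, _DEAD] = 1.0

    rowsums = m.sum(axis=1)
    if not np.allclose(rowsums, 1.0, atol=1e-9):
        raise RuntimeError(f"transition rows do not sum to 1: {rowsums}")
    return m


def _state_utilities(draw: ParameterDraw) -> np.ndarray:
    u_well = float(draw["utility_well"])
    utils = np.array(
        [
            u_well,
            u_well - float(draw["decrement_cv"]),
            u_well - float(draw["decrement_stroke"]),
            u_well - float(draw["decrement_other"]),
            float(draw["utility_recovered"]),
            0.0,
        ]
    )
    return np.maximum(utils, 0.0)


def run_markov(
    initial: Sequence[float],
    draw: ParameterDraw,
    horizon: int = 5,
    discount: float = 0.03,
    config: ModelConfig = DEFAULT_CONFIG,
) -> tuple[CohortTrace, OutcomePair]:
    """Propagate a cohort through the Markov model and accrue flows.

    Cycle k (k = 1..horizon) accrues cost and QALYs on the start-of-cycle
    occupancies, discounted by (1+discount)^-(k-1), then applies that
    cycle's transition matrix.  Cycle 1 uses the first-year cost schedule
    plus the one-off death cost for the initially dead fraction; later
    cycles use the years-2+ schedule.
    """
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    if discount < 0:
        raise ValueError(f"discount must be non-negative, got {discount}")
    state = np.asarray(initial, dtype=float)
    if state.shape != (6,) or abs(state.sum() - 1.0) > 1e-6 or state.min() < -1e-12:
        raise ValueError("initial distribution must be a 6-state simplex point")

    utils = _state_utilities(draw)
    cost_year1 = np.array(
        [
            draw["cost_year1_well"],
            draw["cost_year1_cv"],
            draw["cost_year1_stroke"],
            draw["cost_year1_other"],
            draw["cost_year1_recovered"],
            0.0,
        ],
        dtype=float,
    )
    cost_later = np.array(
        [0.0, draw["cost_later_cv"], draw["cost_later_stroke"],
         draw["cost_later_other"], 0.0, 0.0]
    )
    death_cost = float(draw["cost_year1_death"])

    occ = np.empty((horizon + 1, 6))
    occ[0] = state
    costs = np.empty(horizon)
    qalys = np.empty(horizon)
    for k in range(1, horizon + 1):
        df = (1 + discount) ** -(k - 1)
        schedule = cost_year1 if k == 1 else cost_later
        cost_k = float(state @ schedule)
        if k == 1:
            cost_k += state[_DEAD] * death_cost
        qalys[k - 1] = df * float(state @ utils)
        m = transition_matrix(draw, k, config)
        new_state = state @ m
        if config.death_cost_every_cycle and k > 1:
            cost_k += (new_state[_DEAD] - state[_DEAD]) * death_cost
        costs[k - 1] = df * cost_k
        state = new_state
        occ[k] = state
    trace = CohortTrace(occupancy=occ, cost=costs, qalys=qalys)
    return trace, OutcomePair(cost=float(costs.sum()), qalys=float(qalys.sum()))


def evaluate_strategy(
    draw: ParameterDraw,
    strategy: StrategySpec,
    horizon: int = 5,
    discount: float = 0.03,
    config: ModelConfig = DEFAULT_CONFIG,
    clip_counter: ClipCounter | None = None,
) -> OutcomePair:
    """Discounted total cost and QALYs of one strategy under one draw.

    The hospital-episode (decision-tree) cost is undiscounted; Markov
    flows are discounted from cycle 1 with the first year undiscounted.
    """
    short_cost, initial = run_decision_tree(draw, strategy, config, clip_counter)
    _, long_outcome = run_markov(initial, draw, horizon, discount, config)
    return OutcomePair(
        cost=short_cost + long_outcome.cost,
        qalys=long_outcome.qalys,
    )
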