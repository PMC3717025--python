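"""Synthetic trial outcomes and toy EVPI scenarios with known ground truth.

``simulate_trial`` emulates a 1:1 randomized two-arm trial with a binary
complication outcome: independent Bernoulli draws per arm with control
risk ``p_control`` and treatment risk ``true_rr * p_control``.  Defaults
mirror the studied interim design: 50 patients per arm, a 0.38 control
complication risk and a true relative risk of about 0.8.

``make_toy_evpi_scenario`` builds tiny discrete decision problems —
equally weighted parameter states with a known net benefit per strategy —
whose EVPI is computed by exhaustive enumeration and stored alongside the
states, serving as an exact oracle for the EVPI engine.  The scenarios
ship as a versioned JSON fixture.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from hemovoi.interim_stats import TrialCounts

__all__ = [
    "TrialSimSpec",
    "ToyEVPIScenario",
    "simulate_trial",
    "make_toy_evpi_scenario",
    "TOY_SCENARIO_KINDS",
]


@dataclass(frozen=True)
class TrialSimSpec:
    """Design of a simulated two-arm binary-outcome trial.

    ``p_control`` is the complication probability in the control arm and
    ``true_rr`` the true treatment-versus-control relative risk, so the
    treatment-arm probability is ``true_rr * p_control``.
    """

    n_per_arm: int
    p_control: float
    true_rr: float
    seed: int

    def __post_init__(self) -> None:
        if self.n_per_arm < 1:
            raise ValueError(f"n_per_arm must be >= 1, got {self.n_per_arm}")
        if not 0 < self.p_control < 1:
            raise ValueError(f"p_control must be in (0, 1), got {self.p_control}")
        if self.true_rr < 0:
            raise ValueError(f"true_rr must be non-negative, got {self.true_rr}")
        if self.true_rr * self.p_control > 1:
            raise ValueError(
                "true_rr * p_control must not exceed 1, got "
                f"{self.true_rr * self.p_control}"
            )


def simulate_trial(spec: TrialSimSpec) -> TrialCounts:
    """Draw event counts for both arms of a randomized trial.

    Outcomes are independent Bernoulli indicators per patient; the control
    arm is drawn first, then the treatment arm (documented draw order).
    Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    events_control = int(rng.binomial(spec.n_per_arm, spec.p_control))
    events_treatment = int(
        rng.binomial(spec.n_per_arm, spec.true_rr * spec.p_control)
    )
    return TrialCounts(
        events_treatment=events_treatment,
        n_treatment=spec.n_per_arm,
        events_control=events_control,
        n_control=spec.n_per_arm,
    )


@dataclass(frozen=True)
class ToyEVPIScenario:
    """A finite decision problem with an analytically known EVPI.

    ``nb_matrix`` holds the net benefit (EUR) of each strategy (columns)
    in each equally weighted parameter state (rows).  ``analytic_evpi`` is
    computed by exhaustive enumeration: the mean over states of the
    per-state best net benefit, minus the best strategy's mean.
    """

    kind: str
    strategies: tuple[str, ...]
    nb_matrix: np.ndarray
    analytic_evpi: float

    def __post_init__(self) -> None:
        if self.nb_matrix.ndim != 2 or self.nb_matrix.shape[1] != len(self.strategies):
            raise ValueError("nb_matrix must be (states, strategies)")
        if self.analytic_evpi < 0:
            raise ValueError("EVPI cannot be negative")


def _enumerate_evpi(nb: np.ndarray) -> float:
    """Exhaustive-enumeration EVPI over equally weighted states."""
    return float(np.mean(np.max(nb, axis=1)) - np.max(np.mean(nb, axis=0)))


def _load_scenarios() -> dict:
    text = (
        resources.files("hemovoi").joinpath("data/toy_scenarios.json").read_text()
    )
    return json.loads(text)["scenarios"]


TOY_SCENARIO_KINDS = ("two_point", "dominated", "single_state")


def make_toy_evpi_scenario(kind: str) -> ToyEVPIScenario:
    """Build one of the documented toy scenarios.

    * ``"two_point"`` — strategy A yields 0 in both states, strategy B
      +10 / -10; perfect information is worth 5.
    * ``"dominated"`` — one strategy is better in every state; no decision
      uncertainty, EVPI 0.
    * ``"single_state"`` — one state only; information is already perfect,
      EVPI 0.
    """
    scenarios = _load_scenarios()
    if kind not in scenarios:
        raise ValueError(
            f"unknown scenario kind {kind!r}; known kinds: {sorted(scenarios)}"
        )
    entry = scenarios[kind]
    nb = np.asarray(entry["nb_matrix"], dtype=float)
    return ToyEVPIScenario(
        kind=kind,
        strategies=tuple(entry["strategies"]),
        nb_matrix=nb,
        analytic_evpi=_enumerate_evpi(nb),
    )
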