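"""Interim efficacy statistics for a two-arm binary-outcome trial.

Provides the relative risk with a Wald confidence interval on the log
scale, and a generic normal-approximation sample-size calculator for
comparing two proportions, with an explicit "dilution" factor that scales
the realizable fraction of the anticipated risk reduction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

__all__ = [
    "TrialCounts",
    "RelativeRiskEstimate",
    "relative_risk",
    "sample_size_two_proportions",
]


@dataclass(frozen=True)
class TrialCounts:
    """Events and totals for the two arms of a binary-outcome trial.

    Attributes
    ----------
    events_treatment, n_treatment
        Number of patients with the outcome and number allocated in the
        treatment (GDHT) arm.
    events_control, n_control
        Same for the control (routine fluid therapy) arm.
    """

    events_treatment: int
    n_treatment: int
    events_control: int
    n_control: int

    def __post_init__(self) -> None:
        for arm in ("treatment", "control"):
            e = getattr(self, f"events_{arm}")
            n = getattr(self, f"n_{arm}")
            if n <= 0:
                raise ValueError(f"n_{arm} must be positive, got {n}")
            if not 0 <= e <= n:
                raise ValueError(
                    f"events_{arm} must be in [0, n_{arm}={n}], got {e}"
                )

    def swapped(self) -> "TrialCounts":
        """Counts with the two arms exchanged."""
        return TrialCounts(
            events_treatment=self.events_control,
            n_treatment=self.n_control,
            events_control=self.events_treatment,
            n_control=self.n_treatment,
        )


@dataclass(frozen=True)
class RelativeRiskEstimate:
    """Relative risk with a log-scale Wald confidence interval."""

    rr: float
    log_rr: float
    se_log_rr: float
    ci_low: float
    ci_high: float
    level: float


def relative_risk(counts: TrialCounts, level: float = 0.95) -> RelativeRiskEstimate:
    """Relative risk of treatment versus control with a Wald CI.

    The point estimate is the ratio of the two event proportions.  The
    standard error of log(RR) is

        se = sqrt(1/e_t - 1/n_t + 1/e_c - 1/n_c)

    and the interval is exp(log RR +/- z * se), with z the standard-normal
    quantile for the requested two-sided confidence ``level``.  No
    continuity correction is applied; zero events in either arm raise an
    error rather than being silently corrected.
    """
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    if counts.events_treatment == 0 or counts.events_control == 0:
        raise ValueError(
            "relative risk undefined with zero events in an arm "
            f"(treatment={counts.events_treatment}, control={counts.events_control})"
        )
    p_t = counts.events_treatment / counts.n_treatment
    p_c = counts.events_control / counts.n_control
    rr = p_t / p_c
    log_rr = math.log(rr)
    se = math.sqrt(
        1 / counts.events_treatment
        - 1 / counts.n_treatment
        + 1 / counts.events_control
        - 1 / counts.n_control
    )
    z = stats.norm.ppf(0.5 + level / 2)
    return RelativeRiskEstimate(
        rr=rr,
        log_rr=log_rr,
        se_log_rr=se,
        ci_low=math.exp(log_rr - z * se),
        ci_high=math.exp(log_rr + z * se),
        level=level,
    )


def sample_size_two_proportions(
    p_control: float,
    rr: float,
    power: float = 0.8,
    alpha: float = 0.05,
    dilution: float = 1.0,
) -> int:
    """Total sample size (both groups) to detect a relative risk.

    Uses the classical normal-approximation formula with pooled variance
    under the null:

        n_per_group = (z_{1-a/2} sqrt(2 pbar qbar)
                       + z_{power} sqrt(p1 q1 + p2 q2))^2 / (p1 - p2)^2

    ``dilution`` is the fraction of the anticipated risk reduction assumed
    realizable in the trial population: the effective relative risk is
    RR' = 1 - dilution * (1 - rr), so dilution = 1 uses ``rr`` as given and
    smaller values shrink the detectable effect (inflating n).  This models
    attenuation of the treatment effect by age and comorbidity.
    """
    if not 0 < p_control < 1:
        raise ValueError(f"p_control must be in (0, 1), got {p_control}")
    if not 0 < rr < 1:
        raise ValueError(f"rr must be in (0, 1) for a superiority design, got {rr}")
    if not 0 < power < 1:
        raise ValueError(f"power must be in (0, 1), got {power}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if not 0 < dilution <= 1:
        raise ValueError(f"dilution must be in (0, 1], got {dilution}")

    rr_eff = 1.0 - dilution * (1.0 - rr)
    p_treat = p_control * rr_eff
    diff = p_control - p_treat
    if diff <= 0 or p_treat >= 1:
        raise ValueError("effective risk difference is degenerate (infinite n)")

    z_a = stats.norm.ppf(1 - alpha / 2)
    z_b = stats.norm.ppf(power)
    p_bar = (p_control + p_treat) / 2
    numer = (
        z_a * math.sqrt(2 * p_bar * (1 - p_bar))
        + z_b * math.sqrt(p_control * (1 - p_control) + p_treat * (1 - p_treat))
    ) ** 2
    n_per_group = math.ceil(numer / diff**2)
    return 2 * n_per_group
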