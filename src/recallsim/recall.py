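"""Recall outcomes per risk category and their routing.

A screening mammogram may be read as potentially abnormal (BI-RADS 0) and the
patient recommended for diagnostic workup — a "recall".  The per-category
recall probability is a scenario input; two named profiles are studied, both
with an overall recall rate of about 11% at the 44/28/28 category mix:

* ``uniform``    — 6% / 12% / 18%: recall risk grows in step with cancer risk.
* ``nonuniform`` — 1% / 1% / 37%: category 3 drives almost all recalls.

In the AI-triaged workflow a recalled patient proceeds to same-day diagnostic
imaging; in the baseline workflow a follow-up diagnostic visit is booked about
20 days later.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import ClinicConfig, ConfigurationError
from .templates import DEFAULT_PROPORTIONS, RssCategory

SAME_DAY_WORKUP = "same_day_workup"
FOLLOWUP_BOOKING = "followup_booking"
NONE = "none"

#: same-day workup sub-types, aligned with ClinicConfig.same_day_mix
SAME_DAY_SUBTYPES = ("mammo_us", "mammo", "us")


@dataclass(frozen=True)
class RecallProfile:
    """Per-category recall probabilities."""

    rates: tuple[float, float, float]
    name: str = "custom"

    def __post_init__(self) -> None:
        if not all(0.0 <= r <= 1.0 for r in self.rates):
            raise ConfigurationError(f"recall rates must be in [0, 1], got {self.rates}")

    def rate(self, category: RssCategory | int) -> float:
        return self.rates[int(category) - 1]

    def overall_rate(self, proportions: Sequence[float] = DEFAULT_PROPORTIONS) -> float:
        """Population recall rate under the given category proportions."""
        return float(sum(p * r for p, r in zip(proportions, self.rates)))

    def recall_shares(self, proportions: Sequence[float] = DEFAULT_PROPORTIONS) -> tuple[float, ...]:
        """Fraction of all recalls contributed by each category."""
        contrib = [p * r for p, r in zip(proportions, self.rates)]
        total = sum(contrib)
        if total == 0:
            return (0.0, 0.0, 0.0)
        return tuple(c / total for c in contrib)

    def scaled_to(
        self,
        target_overall: float,
        proportions: Sequence[float] = DEFAULT_PROPORTIONS,
    ) -> "RecallProfile":
        """Proportionally rescale all three rates to hit a target overall rate.

        Used by the sensitivity analysis that raises the overall recall rate
        from ~11% to 15%.
        """
        current = self.overall_rate(proportions)
        if current == 0:
            raise ConfigurationError("cannot scale an all-zero profile")
        factor = target_overall / current
        new = tuple(r * factor for r in self.rates)
        if any(r > 1.0 for r in new):
            raise ConfigurationError("scaling pushes a category rate above 1")
        return RecallProfile(rates=new, name=f"{self.name}_scaled_{target_overall:g}")


def uniform_profile() -> RecallProfile:
    return RecallProfile(rates=(0.06, 0.12, 0.18), name="uniform")


def nonuniform_profile() -> RecallProfile:
    return RecallProfile(rates=(0.01, 0.01, 0.37), name="nonuniform")


NAMED_PROFILES = {"uniform": uniform_profile, "nonuniform": nonuniform_profile}


def draw_recall(
    category: RssCategory | int,
    profile: RecallProfile,
    rng: np.random.Generator,
) -> bool:
    """Bernoulli recall draw for one screening patient."""
    return bool(rng.random() < profile.rate(category))


@dataclass(frozen=True)
class FollowupBooking:
    """A future-day diagnostic visit created by a baseline-workflow recall."""

    origin_day: int
    target_day: int
    slot: int

    def __post_init__(self) -> None:
        if self.target_day <= self.origin_day:
            raise ValueError("follow-up must land on a later day")
        if self.slot < 1:
            raise ValueError("slot index starts at 1")


def book_followup(
    origin_day: int,
    config: ClinicConfig,
    rng: np.random.Generator,
) -> FollowupBooking:
    """Book a follow-up diagnostic visit.

    The delay is Normal(20 d, 4 d) rounded to the nearest positive integer
    day (non-positive roundings are redrawn); the slot is discrete-uniform on
    {1, ..., round(0.67 x expected daily volume)} and only orders the booking
    within the target day's diagnostic stream.
    """
    for _ in range(1000):
        delay = int(round(rng.normal(config.followup_delay_mean_days, config.followup_delay_sd_days)))
        if delay >= 1:
            break
    else:  # pragma: no cover
        raise RuntimeError("follow-up delay redraw cap exceeded")
    slot = int(rng.integers(1, config.followup_slot_count + 1))
    return FollowupBooking(origin_day=origin_day, target_day=origin_day + delay, slot=slot)


def sample_same_day_subtype(config: ClinicConfig, u: float) -> str:
    """Map a uniform draw to a same-day workup sub-type via the 70/15/15 mix."""
    cum = 0.0
    for share, subtype in zip(config.same_day_mix, SAME_DAY_SUBTYPES):
        cum += share
        if u < cum:
            return subtype
    return SAME_DAY_SUBTYPES[-1]


def route_recall(
    recalled: bool,
    same_day_enabled: bool,
    origin_day: int,
    config: ClinicConfig,
    rng: np.random.Generator,
) -> tuple[str, object]:
    """Route one screening patient's recall outcome.

    Returns ``(NONE, None)`` when not recalled; ``(SAME_DAY_WORKUP, subtype)``
    in the AI workflow; ``(FOLLOWUP_BOOKING, FollowupBooking)`` in the
    baseline workflow.
    """
    if not recalled:
        return (NONE, None)
    if same_day_enabled:
        return (SAME_DAY_WORKUP, sample_same_day_subtype(config, rng.random()))
    return (FOLLOWUP_BOOKING, book_followup(origin_day, config, rng))
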