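"""Daily screening-mammography rosters under conventional and risk-stratified templates.

Patients due for screening are banded into three risk categories from their
5-year breast-cancer risk: category 1 (<2%), category 2 (2 to <4%) and
category 3 (>=4% or elevated recall risk by history, e.g. no prior mammogram
within 5 years).  Two scheduling templates are modelled:

* ``non_rss`` — conventional scheduling: every screening slot is open to any
  patient, so the daily count of each category is a Poisson-thinned share of
  the screening volume (44% / 28% / 28%).
* ``rss`` — risk-stratified scheduling: the template reserves a fixed number
  of slots (seven, plus one extra with probability 0.1, giving mean 7.1 and
  SD 0.3) for each of categories 2 and 3, schedules category 3 first in the
  day, then category 2, then category 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Optional, Sequence

import numpy as np

from .config import (
    BIOPSY_MR,
    BIOPSY_STEREO,
    BIOPSY_US,
    DIAGNOSTIC,
    SCREENING_MAMMO,
    SCREENING_US,
    ClinicConfig,
    ConfigurationError,
)


class SchedulingError(RuntimeError):
    """Raised when a roster cannot be laid out in the check-in window."""


class RssCategory(IntEnum):
    """Risk band used by the risk-stratified schedule (1 = lowest)."""

    LOW = 1        # 5-year risk < 2%
    MODERATE = 2   # 2% <= risk < 4%
    ELEVATED = 3   # risk >= 4%, or elevated recall risk by screening history


#: half-open 5-year risk bands [low, high) per category
RISK_BANDS = {
    RssCategory.LOW: (0.0, 0.02),
    RssCategory.MODERATE: (0.02, 0.04),
    RssCategory.ELEVATED: (0.04, float("inf")),
}

#: population share of each category among screening patients
DEFAULT_PROPORTIONS = (0.44, 0.28, 0.28)


def assign_rss_category(
    tc_5yr_risk: float,
    dl_high_risk: bool = False,
    has_prior_mammo_within_5y: bool = True,
) -> RssCategory:
    """Band a patient into a risk category.

    A patient without a baseline screening mammogram (or none within 5 years)
    is placed in the elevated-recall-risk category regardless of risk score.
    ``dl_high_risk`` escalates the risk band by one category; this escalation
    rule is a user-overridable placeholder for the full decision logic that
    combines the risk-calculator score with the deep-learning flag.
    """
    if not 0.0 <= tc_5yr_risk <= 1.0:
        raise ValueError(f"5-year risk must be in [0, 1], got {tc_5yr_risk}")
    if not has_prior_mammo_within_5y:
        return RssCategory.ELEVATED
    for cat, (lo, hi) in RISK_BANDS.items():
        if lo <= tc_5yr_risk < hi:
            break
    else:  # pragma: no cover - bands partition [0, inf)
        cat = RssCategory.ELEVATED
    if dl_high_risk and cat < RssCategory.ELEVATED:
        cat = RssCategory(cat + 1)
    return cat


@dataclass(frozen=True)
class TemplateSpec:
    """Parameters of a daily screening template."""

    kind: str = "non_rss"  # "non_rss" | "rss"
    category_proportions: tuple[float, float, float] = DEFAULT_PROPORTIONS
    fixed_count_base: int = 7
    fixed_count_extra_prob: float = 0.1
    ordering: tuple[int, int, int] = (3, 2, 1)

    def __post_init__(self) -> None:
        if self.kind not in ("non_rss", "rss"):
            raise ConfigurationError(f"unknown template kind {self.kind!r}")
        if abs(sum(self.category_proportions) - 1.0) > 1e-9:
            raise ConfigurationError("category_proportions must sum to 1")
        if not 0.0 <= self.fixed_count_extra_prob <= 1.0:
            raise ConfigurationError("fixed_count_extra_prob must be in [0, 1]")
        if sorted(self.ordering) != [1, 2, 3]:
            raise ConfigurationError("ordering must be a permutation of (1, 2, 3)")

    @property
    def fixed_count_mean(self) -> float:
        return self.fixed_count_base + self.fixed_count_extra_prob

    @property
    def guaranteed_categories(self) -> tuple[int, ...]:
        """Categories whose daily counts the template fixes (waitlist-backfilled)."""
        return (2, 3) if self.kind == "rss" else ()


def non_rss_template(**kw) -> TemplateSpec:
    return TemplateSpec(kind="non_rss", **kw)


def rss_template(**kw) -> TemplateSpec:
    return TemplateSpec(kind="rss", **kw)


def sample_category_counts(
    template: TemplateSpec,
    expected_screening_per_day: float,
    rng: np.random.Generator,
    no_show_rate: float = 0.0,
) -> tuple[int, int, int]:
    """Draw one day's scheduled screening counts per risk category.

    ``expected_screening_per_day`` is the target mean of screening patients
    who *arrive*.  Poisson streams are inflated by 1/(1 - no_show_rate) at
    scheduling so that, after independent no-shows, arrivals keep a Poisson
    law with the target mean.  Under the ``rss`` template the category-2 and
    -3 counts are fixed template slots (``fixed_count_base`` plus a Bernoulli
    extra) kept filled from a waitlist, hence not subject to no-show; the
    category-1 slots absorb the remaining mean so that the overall expected
    arrivals equal ``expected_screening_per_day``.

    With ``no_show_rate=0`` this is the bare count construction: non-RSS
    counts are independent Poisson draws with means proportion x volume
    (e.g. 11.1 / 7.06 / 7.06 at 25.2/day); RSS category-2/3 counts lie in
    {7, 8} with mean 7.1 and SD 0.3.
    """
    if expected_screening_per_day <= 0:
        raise ConfigurationError("expected_screening_per_day must be > 0")
    if not 0.0 <= no_show_rate < 1.0:
        raise ConfigurationError("no_show_rate must be in [0, 1)")
    inflate = 1.0 / (1.0 - no_show_rate)
    if template.kind == "non_rss":
        p = template.category_proportions
        lam = [p[i] * expected_screening_per_day * inflate for i in range(3)]
        return tuple(int(rng.poisson(l)) for l in lam)  # type: ignore[return-value]
    # rss: fixed counts for categories 2 and 3, Poisson remainder for 1
    c2 = template.fixed_count_base + int(rng.random() < template.fixed_count_extra_prob)
    c3 = template.fixed_count_base + int(rng.random() < template.fixed_count_extra_prob)
    remaining = expected_screening_per_day - 2 * template.fixed_count_mean
    if remaining < 0:
        raise ConfigurationError(
            "fixed RSS counts exceed the expected daily screening volume"
        )
    c1 = int(rng.poisson(remaining * inflate))
    return (c1, c2, c3)


@dataclass(frozen=True)
class RosterSlot:
    """One scheduled appointment."""

    time_h: float
    patient_type: str
    rss_category: Optional[RssCategory] = None
    backfilled: bool = False  # fixed template slot, kept filled despite no-shows


@dataclass
class DailyRoster:
    day_index: int
    slots: list[RosterSlot] = field(default_factory=list)

    @property
    def counts_by_category(self) -> tuple[int, int, int]:
        counts = [0, 0, 0]
        for s in self.slots:
            if s.patient_type == SCREENING_MAMMO and s.rss_category is not None:
                counts[s.rss_category - 1] += 1
        return tuple(counts)  # type: ignore[return-value]

    @property
    def n_screening(self) -> int:
        return sum(1 for s in self.slots if s.patient_type == SCREENING_MAMMO)

    def to_records(self) -> list[dict]:
        return [
            {
                "day": self.day_index,
                "slot_time_h": s.time_h,
                "patient_type": s.patient_type,
                "rss_category": int(s.rss_category) if s.rss_category else None,
            }
            for s in self.slots
        ]


@dataclass(frozen=True)
class ArrivalProfile:
    """Piecewise-constant hourly arrival-rate weights over the check-in window.

    The default (no weights) is uniform over the window — the minimal
    assumption when the true hourly profile is unknown.
    """

    window: float = 9.5
    hourly_weights: Optional[tuple[float, ...]] = None

    def sample_times(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if n == 0:
            return np.empty(0)
        if self.hourly_weights is None:
            return rng.uniform(0.0, self.window, size=n)
        w = np.asarray(self.hourly_weights, dtype=float)
        n_bins = len(w)
        edges = np.linspace(0.0, self.window, n_bins + 1)
        bins = rng.choice(n_bins, size=n, p=w / w.sum())
        return edges[bins] + rng.uniform(0.0, self.window / n_bins, size=n)


# at most one scheduled appointment per minute of the check-in window
_SLOTS_PER_HOUR = 60


def build_daily_roster(
    counts: Sequence[int],
    template: TemplateSpec,
    profile: ArrivalProfile,
    rng: np.random.Generator,
    day_index: int = 0,
    other_counts: Optional[dict[str, int]] = None,
    extra_diagnostic_times: Optional[Sequence[float]] = None,
) -> DailyRoster:
    """Lay out one day's appointments.

    Screening-mammography slots get risk categories per the template: the RSS
    template blocks category 3 earliest, then 2, then 1; the conventional
    template shuffles categories uniformly over the screening slots.  Other
    patient types (``other_counts``: type -> count) are interleaved at times
    drawn from the same arrival profile.  ``extra_diagnostic_times`` appends
    follow-up diagnostic visits booked on earlier days.
    """
    counts = tuple(int(c) for c in counts)
    if any(c < 0 for c in counts):
        raise SchedulingError("category counts must be non-negative")
    other_counts = dict(other_counts or {})
    n_screen = sum(counts)
    n_total = n_screen + sum(other_counts.values()) + len(extra_diagnostic_times or ())
    if n_total > profile.window * _SLOTS_PER_HOUR:
        raise SchedulingError(
            f"{n_total} appointments exceed the {profile.window} h check-in window"
        )

    slots: list[RosterSlot] = []
    times = np.sort(profile.sample_times(n_screen, rng))
    if template.kind == "rss":
        categories: list[int] = []
        for cat in template.ordering:
            categories.extend([cat] * counts[cat - 1])
    else:
        categories = [1] * counts[0] + [2] * counts[1] + [3] * counts[2]
        rng.shuffle(categories)
    guaranteed = set(template.guaranteed_categories)
    for t, cat in zip(times, categories):
        slots.append(
            RosterSlot(
                time_h=float(t),
                patient_type=SCREENING_MAMMO,
                rss_category=RssCategory(cat),
                backfilled=cat in guaranteed,
            )
        )

    for ptype, n in other_counts.items():
        for t in profile.sample_times(n, rng):
            slots.append(RosterSlot(time_h=float(t), patient_type=ptype))
    for t in extra_diagnostic_times or ():
        slots.append(RosterSlot(time_h=float(t), patient_type=DIAGNOSTIC))

    slots.sort(key=lambda s: s.time_h)
    return DailyRoster(day_index=day_index, slots=slots)


def sample_other_counts(
    config: ClinicConfig,
    rng: np.random.Generator,
    expected_followups_per_day: float = 0.0,
) -> dict[str, int]:
    """Draw one day's scheduled non-screening visit counts.

    Counts are Poisson with means set so that arrivals (after no-shows) match
    the configured type mix of the checked-in volume.  The external diagnostic
    stream is reduced by ``expected_followups_per_day`` (recall follow-ups
    booked by the simulation itself) so total checked-in volume stays at its
    calibrated mean when the baseline workflow feeds recalls back as visits.
    """
    inflate = 1.0 / (1.0 - config.no_show_rate)
    total = config.expected_checked_in_per_day
    diag_mean = max(config.type_mix[DIAGNOSTIC] * total - expected_followups_per_day, 0.0)
    means = {
        SCREENING_US: config.type_mix[SCREENING_US] * total,
        DIAGNOSTIC: diag_mean,
        BIOPSY_STEREO: config.biopsy_subtype_mix[0] * config.type_mix["biopsy"] * total,
        BIOPSY_US: config.biopsy_subtype_mix[1] * config.type_mix["biopsy"] * total,
        BIOPSY_MR: config.biopsy_subtype_mix[2] * config.type_mix["biopsy"] * total,
    }
    return {k: int(rng.poisson(m * inflate)) for k, m in means.items()}
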