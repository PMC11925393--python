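"""Scenario orchestration: the 8-scenario matrix and its summary tables.

The full experiment crosses scheduling template (conventional vs
risk-stratified) x same-day diagnostic workup (off vs on) x recall-rate
profile (uniform vs nonuniform), runs each scenario for 365 weekdays with 10
replication seeds (3,650 pooled weekdays), and compares each template pair
with Levene's, Wilcoxon signed-rank and rank-sum tests.  Template pairs share
replication seeds, hence common random numbers.

``analytic_oracle`` is the closed-form companion: with independent category
counts n_i and per-category recall rates r_i, the daily recall count R has

    E[R]   = sum_i E[n_i] r_i
    Var[R] = sum_i E[n_i] r_i (1 - r_i)  +  sum_i r_i^2 Var[n_i]

by the law of total variance, which the simulated variance must match for
every scenario (the same-day toggle adds no recall-count mechanism).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .clinic import DayStreams, run_day
from .config import ClinicConfig
from .outcomes import (
    ScenarioResult,
    mean_operating_hours,
    mean_wait,
    pooled_waits,
    served_within_close,
)
from .recall import RecallProfile, nonuniform_profile, uniform_profile
from .stats import ComparisonReport, levene, rank_sum, signed_rank
from .templates import (
    ArrivalProfile,
    TemplateSpec,
    build_daily_roster,
    non_rss_template,
    rss_template,
    sample_category_counts,
    sample_other_counts,
)

DEFAULT_DAYS = 365
DEFAULT_N_SEEDS = 10


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation scenario."""

    template: TemplateSpec
    profile: RecallProfile
    same_day: bool = False
    days: int = DEFAULT_DAYS
    seeds: tuple[int, ...] = tuple(range(DEFAULT_N_SEEDS))
    clinic: ClinicConfig = field(default_factory=ClinicConfig)

    def __post_init__(self) -> None:
        if self.days < 1:
            raise ValueError("days must be >= 1")
        if not self.seeds:
            raise ValueError("at least one replication seed required")

    @property
    def label(self) -> str:
        wd = "same_day" if self.same_day else "baseline"
        return f"{self.profile.name}|{self.template.kind}|{wd}"


def count_moments(
    template: TemplateSpec,
    expected_screening_per_day: float,
) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
    """(means, variances) of the *arrived* daily category counts.

    Poisson-thinned streams stay Poisson after no-shows with the target mean,
    and the fixed template slots are backfilled, so arrived moments do not
    depend on the no-show rate.
    """
    if template.kind == "non_rss":
        p = template.category_proportions
        means = tuple(pi * expected_screening_per_day for pi in p)
        return means, means  # Poisson: variance = mean
    q = template.fixed_count_extra_prob
    fixed_mean = template.fixed_count_mean
    fixed_var = q * (1 - q)
    c1_mean = expected_screening_per_day - 2 * fixed_mean
    return (c1_mean, fixed_mean, fixed_mean), (c1_mean, fixed_var, fixed_var)


def analytic_oracle(
    count_means: Sequence[float],
    count_vars: Sequence[float],
    rates: Sequence[float],
) -> tuple[float, float]:
    """Closed-form (mean, variance) of the daily recall count."""
    mean = sum(m * r for m, r in zip(count_means, rates))
    var = sum(m * r * (1 - r) for m, r in zip(count_means, rates)) + sum(
        r * r * v for r, v in zip(rates, count_vars)
    )
    return float(mean), float(var)


def scenario_analytic_moments(spec: ScenarioSpec) -> tuple[float, float]:
    means, variances = count_moments(spec.template, spec.clinic.expected_screening_per_day)
    return analytic_oracle(means, variances, spec.profile.rates)


def _followup_slot_time(slot: int, config: ClinicConfig) -> float:
    frac = (slot - 0.5) / config.followup_slot_count
    return min(frac, 1.0) * config.checkin_cutoff


def run_scenario(spec: ScenarioSpec, record_stages: bool = False) -> ScenarioResult:
    """Run one scenario: ``days`` weekdays per replication seed, pooled.

    Deterministic for a fixed (spec, seeds): all randomness flows through
    per-(seed, day) named substreams.  Follow-up bookings feed diagnostic
    load back into later days of the same replication; bookings past the
    horizon are recorded on the result but not simulated.
    """
    clinic = spec.clinic
    arrival = ArrivalProfile(window=clinic.checkin_cutoff)
    # hold total diagnostic volume constant across workflows: the external
    # stream makes room for the follow-up inflow the baseline workflow creates
    # (booked follow-ups face the same no-show risk as any appointment, so
    # the expected *arrived* inflow is bookings x (1 - no-show rate))
    exp_followups = (
        scenario_analytic_moments(spec)[0] * (1.0 - clinic.no_show_rate)
        if not spec.same_day
        else 0.0
    )

    result = ScenarioResult(label=spec.label)
    unsimulated_bookings = 0
    for rep, seed in enumerate(spec.seeds):
        pending: dict[int, list[int]] = {}
        for day in range(spec.days):
            streams = DayStreams.for_day(seed, day)
            counts = sample_category_counts(
                spec.template,
                clinic.expected_screening_per_day,
                streams.counts,
                no_show_rate=clinic.no_show_rate,
            )
            other = sample_other_counts(clinic, streams.counts, exp_followups)
            extra = [
                _followup_slot_time(s, clinic) for s in sorted(pending.pop(day, []))
            ]
            roster = build_daily_roster(
                counts,
                spec.template,
                arrival,
                streams.times,
                day_index=day,
                other_counts=other,
                extra_diagnostic_times=extra,
            )
            outcome, _, bookings = run_day(
                clinic, roster, spec.profile, streams, spec.same_day,
                record_stages=record_stages,
            )
            outcome.day_index = rep * spec.days + day
            result.daily.append(outcome)
            for b in bookings:
                if b.target_day < spec.days:
                    pending.setdefault(b.target_day, []).append(b.slot)
                else:
                    unsimulated_bookings += 1
    return result


@dataclass
class MatrixResult:
    """All scenario results plus the recall and operations summary tables."""

    results: dict[str, ScenarioResult]
    specs: dict[str, ScenarioSpec]
    table_recalls: pd.DataFrame
    table_operations: pd.DataFrame
    comparisons: list[ComparisonReport]

    def comparisons_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(c) for c in self.comparisons])

    def save(self, outdir: str | Path, fmt: str = "csv") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tables = {
            "table_recalls": self.table_recalls,
            "table_operations": self.table_operations,
            "comparisons": self.comparisons_frame(),
        }
        for name, frame in tables.items():
            if fmt == "csv":
                frame.to_csv(outdir / f"{name}.csv", index=False)
            else:
                frame.to_json(outdir / f"{name}.json", orient="records", indent=2)
        daily = pd.concat(
            [r.daily_frame().assign(scenario=label) for label, r in self.results.items()],
            ignore_index=True,
        )
        daily.to_csv(outdir / "daily_outcomes.csv", index=False)


def matrix_specs(
    clinic: Optional[ClinicConfig] = None,
    days: int = DEFAULT_DAYS,
    seeds: Optional[Sequence[int]] = None,
    recall_scale_to: Optional[float] = None,
) -> dict[str, ScenarioSpec]:
    """The 8-scenario default matrix, optionally rescaled to a target overall recall rate."""
    clinic = clinic or ClinicConfig()
    seeds = tuple(seeds) if seeds is not None else tuple(range(DEFAULT_N_SEEDS))
    profiles = [uniform_profile(), nonuniform_profile()]
    if recall_scale_to is not None:
        profiles = [p.scaled_to(recall_scale_to) for p in profiles]
    specs: dict[str, ScenarioSpec] = {}
    for profile in profiles:
        for same_day in (False, True):
            for template in (non_rss_template(), rss_template()):
                spec = ScenarioSpec(
                    template=template,
                    profile=profile,
                    same_day=same_day,
                    days=days,
                    seeds=seeds,
                    clinic=clinic,
                )
                specs[spec.label] = spec
    return specs


def run_matrix(
    clinic: Optional[ClinicConfig] = None,
    days: int = DEFAULT_DAYS,
    seeds: Optional[Sequence[int]] = None,
    recall_scale_to: Optional[float] = None,
) -> MatrixResult:
    """Run every scenario of the matrix and build the summary tables."""
    specs = matrix_specs(clinic, days, seeds, recall_scale_to)
    results = {label: run_scenario(spec) for label, spec in specs.items()}
    return summarize_matrix(specs, results)


def _pair_key(label: str) -> tuple[str, str]:
    profile, _, workflow = label.split("|")
    return profile, workflow


def summarize_matrix(
    specs: dict[str, ScenarioSpec],
    results: dict[str, ScenarioResult],
) -> MatrixResult:
    comparisons: list[ComparisonReport] = []
    rows_recall = []
    rows_ops = []
    # group scenarios into (non_rss, rss) pairs holding profile and workflow fixed
    pairs: dict[tuple[str, str], dict[str, str]] = {}
    for label, spec in specs.items():
        pairs.setdefault(_pair_key(label), {})[spec.template.kind] = label

    for (profile, workflow), members in pairs.items():
        base_label = members.get("non_rss")
        rss_label = members.get("rss")
        for kind in ("non_rss", "rss"):
            label = members.get(kind)
            if label is None:
                continue
            res = results[label]
            s = res.summary()
            counts = res.recall_counts
            levene_p = np.nan
            if kind == "rss" and base_label is not None:
                _, levene_p = levene(results[base_label].recall_counts, counts)
                comparisons.append(
                    ComparisonReport(
                        "recall_variance", base_label, label, "levene",
                        *levene(results[base_label].recall_counts, counts),
                    )
                )
            rows_recall.append(
                {
                    "profile": profile,
                    "schedule": kind,
                    "same_day": workflow == "same_day",
                    "mean_recalls_per_day": s["mean_recalls"],
                    "sd_recalls_per_day": s["sd_recalls"],
                    "recall_variance": s["recall_variance"],
                    "levene_p": levene_p,
                    "high_recall_days": s["high_recall_days"],
                    "high_recall_days_pct": 100.0 * s["high_recall_days"] / len(res.daily),
                }
            )
            served_series = [d.n_served_within_close for d in res.daily]
            hours_series = [d.operating_hours for d in res.daily]
            waits = pooled_waits(res.daily)
            p_served = p_hours = p_wait = np.nan
            if kind == "rss" and base_label is not None:
                base = results[base_label]
                base_served = [d.n_served_within_close for d in base.daily]
                base_hours = [d.operating_hours for d in base.daily]
                _, p_served = signed_rank(served_series, base_served)
                _, p_hours = signed_rank(hours_series, base_hours)
                _, p_wait = rank_sum(waits, pooled_waits(base.daily))
                comparisons.extend(
                    [
                        ComparisonReport(
                            "served_within_close", base_label, label, "signed_rank",
                            *signed_rank(served_series, base_served),
                        ),
                        ComparisonReport(
                            "operating_hours", base_label, label, "signed_rank",
                            *signed_rank(hours_series, base_hours),
                        ),
                        ComparisonReport(
                            "mean_wait", base_label, label, "rank_sum",
                            *rank_sum(waits, pooled_waits(base.daily)),
                        ),
                    ]
                )
            rows_ops.append(
                {
                    "profile": profile,
                    "schedule": kind,
                    "same_day": workflow == "same_day",
                    "served_within_close": float(np.mean(served_series)),
                    "served_within_close_sd": float(np.std(served_series, ddof=1)),
                    "signed_rank_p_served": p_served,
                    "operating_hours": float(np.mean(hours_series)),
                    "operating_hours_sd": float(np.std(hours_series, ddof=1)),
                    "signed_rank_p_hours": p_hours,
                    "mean_wait": float(waits.mean()) if waits.size else 0.0,
                    "mean_wait_sd": float(waits.std(ddof=1)) if waits.size > 1 else 0.0,
                    "rank_sum_p_wait": p_wait,
                }
            )

    return MatrixResult(
        results=results,
        specs=specs,
        table_recalls=pd.DataFrame(rows_recall),
        table_operations=pd.DataFrame(rows_ops),
        comparisons=comparisons,
    )


def variance_reduction(matrix: MatrixResult) -> pd.DataFrame:
    """Relative recall-variance reduction of each RSS scenario vs its partner."""
    rows = []
    t = matrix.table_recalls
    for (profile, same_day), grp in t.groupby(["profile", "same_day"]):
        by_kind = grp.set_index("schedule")["recall_variance"]
        if {"rss", "non_rss"} <= set(by_kind.index) and by_kind["non_rss"] > 0:
            rows.append(
                {
                    "profile": profile,
                    "same_day": same_day,
                    "non_rss_variance": by_kind["non_rss"],
                    "rss_variance": by_kind["rss"],
                    "reduction_pct": 100.0 * (1.0 - by_kind["rss"] / by_kind["non_rss"]),
                }
            )
    return pd.DataFrame(rows)
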