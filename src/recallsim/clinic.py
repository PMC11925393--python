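"""One clinic day as a discrete event simulation.

Every checked-in patient flows check-in -> public waiting -> consent ->
dressing -> gowned waiting -> examination, seizing capacity-limited staff,
rooms, technologists and radiologists along the way.  In the AI-triaged
workflow a completed screening mammogram is assessed immediately (AI score
plus radiologist confirmation, modelled as one radiologist activity) and
recalled patients continue to same-day diagnostic imaging and a radiologist
review; in the baseline workflow recalled patients leave and a follow-up
diagnostic visit is booked on a later day.  Check-in stops at the cutoff;
service continues past the nominal close until everyone checked in completes.

Waiting time is congestion delay only: the time between requesting a stage's
resource and seizing it, summed over stages.  The waiting rooms' own dwell
distributions are service, not waiting, so in an uncongested clinic the
waiting time is exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import (
    BIOPSY_MR,
    BIOPSY_STEREO,
    BIOPSY_US,
    CONSENT,
    DIAGNOSTIC,
    DRESSING,
    GOWNED_WAIT,
    MAMMO_TECH,
    PUBLIC_WAIT,
    RADIOLOGIST,
    SCREENING_MAMMO,
    SCREENING_US,
    STAFF,
    US_TECH,
    ClinicConfig,
    ServiceTimeSpec,
)
from .engine import Acquire, Release, Resource, Simulation, Timeout
from .outcomes import DailyOutcome
from .recall import (
    FollowupBooking,
    RecallProfile,
    book_followup,
    sample_same_day_subtype,
)
from .templates import DailyRoster, RssCategory

_RESAMPLE_CAP = 1000


def sample_service_time(spec: ServiceTimeSpec, rng: np.random.Generator) -> float:
    """Draw a non-negative duration from Normal(mean, sd), resampling below 0."""
    if spec.sd == 0.0:
        return spec.mean
    for _ in range(_RESAMPLE_CAP):
        d = rng.normal(spec.mean, spec.sd)
        if d >= 0.0:
            return float(d)
    raise RuntimeError(f"truncated-normal resampling cap hit for {spec}")


@dataclass
class PatientVisit:
    """One patient's trajectory through the clinic day."""

    id: int
    patient_type: str
    rss_category: Optional[RssCategory]
    scheduled_time: float
    no_show: bool = False
    checkin_time: Optional[float] = None
    recall: bool = False
    same_day: bool = False
    same_day_subtype: Optional[str] = None
    completion_time: Optional[float] = None
    waiting_time: float = 0.0
    stage_log: list[tuple[str, float, float]] = field(default_factory=list)

    def validate(self) -> None:
        if self.same_day and not self.recall:
            raise ValueError("same-day workup without a recall")
        if self.waiting_time < 0:
            raise ValueError("negative waiting time")


# columns of the per-patient pre-drawn standard-normal matrix
_ST_CHECKIN, _ST_PUBLIC, _ST_CONSENT, _ST_DRESSING, _ST_GOWNED = range(5)
_ST_EXAM1, _ST_EXAM2, _ST_AI, _ST_REVIEW, _ST_SD_EXAM = range(5, 10)
_N_STAGE_DRAWS = 10


@dataclass
class DayStreams:
    """Named random substreams for one simulated day.

    Separating the streams lets paired scenarios (risk-stratified vs
    conventional template, same-day workflow on vs off) share arrival,
    no-show, recall and service randomness — common random numbers — so that
    outcome differences are attributable to the design change alone.
    """

    counts: np.random.Generator
    times: np.random.Generator
    noshow: np.random.Generator
    recall: np.random.Generator
    service: np.random.Generator
    routing: np.random.Generator

    @classmethod
    def for_day(cls, replication_seed: int, day: int) -> "DayStreams":
        names = ("counts", "times", "noshow", "recall", "service", "routing")
        gens = {
            name: np.random.Generator(
                np.random.Philox(key=np.random.SeedSequence(
                    entropy=replication_seed, spawn_key=(day, k)
                ).generate_state(2, np.uint64))
            )
            for k, name in enumerate(names)
        }
        return cls(**gens)


def _duration(spec: ServiceTimeSpec, z: float, fallback: np.random.Generator) -> float:
    d = spec.mean + spec.sd * z
    if d >= 0.0:
        return d
    return sample_service_time(spec, fallback)  # rare with small SDs


def _stage(sim, pool, duration, visit, name, log):
    req = sim.now
    grant = yield Acquire(pool)
    visit.waiting_time += grant - req
    yield Timeout(duration)
    if log is not None:
        log.append((name, grant, sim.now))
    yield Release(pool)


def _dual_stage(sim, pool_a, pool_b, duration, visit, name, log):
    # seize two resources for one activity; consistent ordering avoids deadlock
    req = sim.now
    grant = yield Acquire(pool_a)
    visit.waiting_time += grant - req
    req = sim.now
    grant = yield Acquire(pool_b)
    visit.waiting_time += grant - req
    yield Timeout(duration)
    if log is not None:
        log.append((name, grant, sim.now))
    yield Release(pool_b)
    yield Release(pool_a)


def _patient_process(
    sim: Simulation,
    pools: dict[str, Resource],
    cfg: ClinicConfig,
    visit: PatientVisit,
    z: np.ndarray,
    same_day_enabled: bool,
    diag_subtype: Optional[str],
    fallback_rng: np.random.Generator,
    record_stages: bool,
):
    st = cfg.service_times
    log = visit.stage_log if record_stages else None
    visit.checkin_time = sim.now

    ptype = visit.patient_type
    yield from _stage(sim, pools[STAFF], _duration(st["checkin"], z[_ST_CHECKIN], fallback_rng), visit, "checkin", log)
    yield from _stage(sim, pools[PUBLIC_WAIT], _duration(st["public_wait_dwell"], z[_ST_PUBLIC], fallback_rng), visit, "public_wait", log)
    if ptype in (BIOPSY_STEREO, BIOPSY_US, BIOPSY_MR):
        # procedure consent only: the one consent room (0.17 h per patient)
        # cannot physically serve all 60 daily patients inside the window
        yield from _stage(sim, pools[CONSENT], _duration(st["consent"], z[_ST_CONSENT], fallback_rng), visit, "consent", log)
    yield from _stage(sim, pools[DRESSING], _duration(st["dressing"], z[_ST_DRESSING], fallback_rng), visit, "dressing", log)
    yield from _stage(sim, pools[GOWNED_WAIT], _duration(st["gowned_wait_dwell"], z[_ST_GOWNED], fallback_rng), visit, "gowned_wait", log)

    if ptype == SCREENING_MAMMO:
        yield from _stage(sim, pools[MAMMO_TECH], _duration(st["screening_mammo"], z[_ST_EXAM1], fallback_rng), visit, "screening_mammo", log)
        if same_day_enabled:
            yield from _stage(sim, pools[RADIOLOGIST], _duration(st["ai_assessment"], z[_ST_AI], fallback_rng), visit, "ai_assessment", log)
            if visit.recall:
                visit.same_day = True
                sub = visit.same_day_subtype
                if sub in ("mammo_us", "mammo"):
                    yield from _stage(sim, pools[MAMMO_TECH], _duration(st["diagnostic_mammo"], z[_ST_SD_EXAM], fallback_rng), visit, "diagnostic_mammo", log)
                if sub in ("mammo_us", "us"):
                    yield from _stage(sim, pools[US_TECH], _duration(st["diagnostic_us"], z[_ST_EXAM2], fallback_rng), visit, "diagnostic_us", log)
                yield from _stage(sim, pools[RADIOLOGIST], _duration(st["diagnostic_review"], z[_ST_REVIEW], fallback_rng), visit, "diagnostic_review", log)
    elif ptype == SCREENING_US:
        yield from _stage(sim, pools[US_TECH], _duration(st["screening_us"], z[_ST_EXAM1], fallback_rng), visit, "screening_us", log)
    elif ptype == DIAGNOSTIC:
        if diag_subtype in ("mammo_us", "mammo"):
            yield from _stage(sim, pools[MAMMO_TECH], _duration(st["diagnostic_mammo"], z[_ST_EXAM1], fallback_rng), visit, "diagnostic_mammo", log)
        if diag_subtype in ("mammo_us", "us"):
            yield from _stage(sim, pools[US_TECH], _duration(st["diagnostic_us"], z[_ST_EXAM2], fallback_rng), visit, "diagnostic_us", log)
        yield from _stage(sim, pools[RADIOLOGIST], _duration(st["diagnostic_review"], z[_ST_REVIEW], fallback_rng), visit, "diagnostic_review", log)
    elif ptype == BIOPSY_STEREO:
        yield from _dual_stage(sim, pools[MAMMO_TECH], pools[RADIOLOGIST], _duration(st["biopsy_stereo"], z[_ST_EXAM1], fallback_rng), visit, "biopsy_stereo", log)
    elif ptype == BIOPSY_US:
        yield from _dual_stage(sim, pools[US_TECH], pools[RADIOLOGIST], _duration(st["biopsy_us"], z[_ST_EXAM1], fallback_rng), visit, "biopsy_us", log)
    elif ptype == BIOPSY_MR:
        # MR technologist is out of scope (MRI shares no resources); only the
        # radiologist is seized for the procedure duration
        yield from _stage(sim, pools[RADIOLOGIST], _duration(st["biopsy_mr"], z[_ST_EXAM1], fallback_rng), visit, "biopsy_mr", log)
    else:  # pragma: no cover
        raise ValueError(f"unknown patient type {ptype!r}")

    visit.completion_time = sim.now


def run_day(
    config: ClinicConfig,
    roster: DailyRoster,
    profile: RecallProfile,
    streams: DayStreams,
    same_day_enabled: bool,
    record_stages: bool = False,
) -> tuple[DailyOutcome, list[PatientVisit], list[FollowupBooking]]:
    """Simulate one clinic day.

    Returns the day's outcome aggregates, every patient visit (including
    no-shows, flagged), and the follow-up bookings generated by baseline-
    workflow recalls.
    """
    slots = roster.slots
    n = len(slots)
    for s in slots:
        if not 0.0 <= s.time_h <= config.checkin_cutoff:
            raise ValueError("roster slot outside the check-in window")

    # pre-draw the full randomness bundle per patient so that toggling the
    # template or the same-day workflow changes only which draws are consumed
    z = streams.service.standard_normal((n, _N_STAGE_DRAWS)) if n else np.empty((0, _N_STAGE_DRAWS))
    # no-show and recall draws are indexed by screening-visit order (not
    # global slot position) so both workflows consume those streams
    # identically: the same screening patient gets the same draws when only
    # the same-day toggle or the surrounding non-screening load changes
    scr_rank = np.full(n, -1, dtype=int)
    k = 0
    for i, s in enumerate(slots):
        if s.patient_type == SCREENING_MAMMO:
            scr_rank[i] = k
            k += 1
    u_noshow_scr = streams.noshow.random(k)
    u_noshow_other = streams.noshow.random(n)
    other = 0
    u_noshow = np.empty(n)
    for i in range(n):
        if scr_rank[i] >= 0:
            u_noshow[i] = u_noshow_scr[scr_rank[i]]
        else:
            u_noshow[i] = u_noshow_other[other]
            other += 1
    u_recall = streams.recall.random(k)
    u_route = streams.routing.random(n)
    z_delay = streams.routing.standard_normal(n)
    u_slot = streams.routing.random(n)

    sim = Simulation()
    pools = {name: Resource(name, cap) for name, cap in config.resources.items()}
    visits: list[PatientVisit] = []
    bookings: list[FollowupBooking] = []

    for i, slot in enumerate(slots):
        visit = PatientVisit(
            id=i,
            patient_type=slot.patient_type,
            rss_category=slot.rss_category,
            scheduled_time=slot.time_h,
        )
        visits.append(visit)
        if (not slot.backfilled) and u_noshow[i] < config.no_show_rate:
            visit.no_show = True
            continue

        diag_subtype = None
        if slot.patient_type == SCREENING_MAMMO:
            visit.recall = u_recall[scr_rank[i]] < profile.rate(slot.rss_category)
            if visit.recall:
                if same_day_enabled:
                    visit.same_day_subtype = sample_same_day_subtype(config, u_route[i])
                else:
                    bookings.append(
                        _booking_from_draws(
                            roster.day_index, config, z_delay[i], u_slot[i], streams.routing
                        )
                    )
        elif slot.patient_type == DIAGNOSTIC:
            diag_subtype = sample_same_day_subtype(config, u_route[i])  # same 70/15/15 mix

        sim.schedule(
            _patient_process(
                sim, pools, config, visit, z[i],
                same_day_enabled, diag_subtype, streams.service, record_stages,
            ),
            at=slot.time_h,
        )

    sim.run()

    arrived = [v for v in visits if not v.no_show]
    for v in arrived:
        if v.completion_time is None:
            raise RuntimeError("checked-in patient never completed (deadlock?)")
        v.validate()
    served = [v for v in arrived if v.completion_time <= config.close]
    outcome = DailyOutcome(
        day_index=roster.day_index,
        n_scheduled=n,
        n_checked_in=len(arrived),
        n_screening=sum(v.patient_type == SCREENING_MAMMO for v in arrived),
        n_recalls=sum(v.recall for v in arrived),
        n_served_within_close=len(served),
        operating_hours=required_operating_hours(arrived, config.close),
        waits_served=np.array([v.waiting_time for v in served]),
        waits_all=np.array([v.waiting_time for v in arrived]),
    )
    return outcome, visits, bookings


def _booking_from_draws(
    origin_day: int,
    config: ClinicConfig,
    z_delay: float,
    u_slot: float,
    fallback_rng: np.random.Generator,
) -> FollowupBooking:
    delay = int(round(config.followup_delay_mean_days + config.followup_delay_sd_days * z_delay))
    if delay < 1:  # rare; redraw per the booking contract
        return book_followup(origin_day, config, fallback_rng)
    slot = 1 + int(u_slot * config.followup_slot_count)
    return FollowupBooking(origin_day=origin_day, target_day=origin_day + delay, slot=min(slot, config.followup_slot_count))


def required_operating_hours(visits: list[PatientVisit], close: float) -> float:
    """Hours needed to serve every checked-in patient: latest completion, floored at close."""
    completions = [v.completion_time for v in visits if not v.no_show]
    if any(c is None for c in completions):
        raise ValueError("all visits must be completed")
    if not completions:
        return close
    return max(close, max(completions))


def visits_to_records(visits: list[PatientVisit], day_index: int) -> list[dict]:
    """Flatten stage logs into event-log records (for CSV export / Gantt views)."""
    records = []
    for v in visits:
        for stage, start, end in v.stage_log:
            records.append(
                {
                    "day": day_index,
                    "id": v.id,
                    "type": v.patient_type,
                    "category": int(v.rss_category) if v.rss_category else None,
                    "stage": stage,
                    "start": start,
                    "end": end,
                }
            )
    return records
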