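"""The clinic-day simulation: service sampling, patient flow, day outcomes."""

import numpy as np
import pytest

from recallsim.clinic import (
    DayStreams,
    required_operating_hours,
    run_day,
    sample_service_time,
)
from recallsim.config import ClinicConfig, ServiceTimeSpec
from recallsim.experiments import ScenarioSpec, run_scenario
from recallsim.recall import RecallProfile, nonuniform_profile
from recallsim.templates import (
    ArrivalProfile,
    build_daily_roster,
    non_rss_template,
    rss_template,
)

ALWAYS = RecallProfile(rates=(1.0, 1.0, 1.0))
NEVER = RecallProfile(rates=(0.0, 0.0, 0.0))


class TestSampleServiceTime:
    def test_mean_preserved_under_truncation(self, rng):
        spec = ServiceTimeSpec(0.05, 0.01)
        n = 100_000
        draws = np.array([sample_service_time(spec, rng) for _ in range(n)])
        se = 0.01 / np.sqrt(n)
        assert draws.mean() == pytest.approx(0.05, abs=3 * se)

    def test_degenerate_sd_returns_mean_exactly(self, rng):
        spec = ServiceTimeSpec(0.3, 0.0)
        assert all(sample_service_time(spec, rng) == 0.3 for _ in range(100))

    def test_draws_never_negative_even_with_large_sd(self, rng):
        spec = ServiceTimeSpec(0.05, 0.2)  # heavy truncation regime
        draws = [sample_service_time(spec, rng) for _ in range(20_000)]
        assert min(draws) >= 0.0


def _single_patient_day(config, profile, same_day, template=None, counts=(0, 0, 1)):
    template = template or rss_template()
    streams = DayStreams.for_day(0, 0)
    roster = build_daily_roster(
        counts, template, ArrivalProfile(), streams.times, day_index=0
    )
    return run_day(config, roster, profile, streams, same_day)


class TestDeterministicPathOracle:
    """With all SDs at zero and one patient there is no queueing, so the
    end-to-end time must equal the sum of the stage means exactly."""

    SCREEN_PATH = 0.05 + 0.17 + 0.03 + 0.017 + 0.17  # check-in .. exam

    def test_screening_baseline_path_length(self, deterministic_config):
        outcome, visits, _ = _single_patient_day(deterministic_config, NEVER, False)
        v = [x for x in visits if not x.no_show][0]
        assert v.completion_time == pytest.approx(v.scheduled_time + self.SCREEN_PATH)
        assert v.waiting_time == 0.0

    def test_screening_same_day_recall_path_length(self, deterministic_config):
        cfg = deterministic_config
        cfg.same_day_mix = (1.0, 0.0, 0.0)  # force mammo + US workup
        outcome, visits, _ = _single_patient_day(cfg, ALWAYS, True)
        v = [x for x in visits if not x.no_show][0]
        extra = 0.25 + 0.417 + 0.417 + 0.083  # AI check, both workups, review
        assert v.completion_time == pytest.approx(
            v.scheduled_time + self.SCREEN_PATH + extra
        )
        assert v.same_day and v.recall
        assert v.waiting_time == 0.0

    def test_baseline_recall_books_followup_and_exits(self, deterministic_config):
        outcome, visits, bookings = _single_patient_day(
            deterministic_config, ALWAYS, False
        )
        v = [x for x in visits if not x.no_show][0]
        assert v.recall and not v.same_day
        assert v.completion_time == pytest.approx(v.scheduled_time + self.SCREEN_PATH)
        assert len(bookings) == 1
        assert bookings[0].target_day > 0


class TestRequiredOperatingHours:
    def test_floor_at_close_when_day_ends_early(self, deterministic_config):
        outcome, visits, _ = _single_patient_day(deterministic_config, NEVER, False)
        assert outcome.operating_hours == 10.0

    def test_latest_completion_governs_when_past_close(self):
        class V:
            no_show = False

            def __init__(self, t):
                self.completion_time = t

        assert required_operating_hours([V(9.1), V(10.4)], close=10.0) == 10.4

    def test_empty_day_is_close_time(self):
        assert required_operating_hours([], close=10.0) == 10.0

    def test_incomplete_visit_rejected(self):
        class V:
            no_show = False
            completion_time = None

        with pytest.raises(ValueError):
            required_operating_hours([V()], close=10.0)


class TestDayInvariants:
    def test_flow_conservation_and_no_show_rate(self):
        spec = ScenarioSpec(
            template=non_rss_template(),
            profile=nonuniform_profile(),
            same_day=False,
            days=150,
            seeds=(0,),
        )
        result = run_scenario(spec)
        for d in result.daily:
            assert d.n_served_within_close <= d.n_checked_in
            assert d.operating_hours >= 10.0
            assert d.waits_all.min() >= 0.0 if d.waits_all.size else True
        scheduled = np.array([d.n_scheduled for d in result.daily])
        checked = np.array([d.n_checked_in for d in result.daily])
        # RSS-free scenario: every slot faces the 10% no-show risk
        frac = checked.sum() / scheduled.sum()
        se = np.sqrt(0.9 * 0.1 / scheduled.sum())
        assert frac == pytest.approx(0.9, abs=4 * se)

    def test_same_day_workup_never_shortens_a_visit(self):
        """Under common random numbers, adding the same-day pathway can delay
        but never accelerate any individual patient."""
        cfg = ClinicConfig()
        completions = {}
        for same_day in (False, True):
            streams = DayStreams.for_day(11, 0)
            roster = build_daily_roster(
                (11, 7, 7),
                rss_template(),
                ArrivalProfile(),
                streams.times,
                other_counts={"diagnostic": 20, "screening_us": 6},
            )
            _, visits, _ = run_day(cfg, roster, nonuniform_profile(), streams, same_day)
            completions[same_day] = {
                v.id: v.completion_time for v in visits if not v.no_show
            }
        assert completions[True].keys() == completions[False].keys()
        for vid, t_on in completions[True].items():
            assert t_on >= completions[False][vid] - 1e-9

    def test_roster_outside_checkin_window_rejected(self):
        cfg = ClinicConfig()
        streams = DayStreams.for_day(0, 0)
        roster = build_daily_roster(
            (1, 0, 0), non_rss_template(), ArrivalProfile(window=12.0), streams.times
        )
        roster.slots[0] = type(roster.slots[0])(
            time_h=11.0, patient_type=roster.slots[0].patient_type,
            rss_category=roster.slots[0].rss_category,
        )
        with pytest.raises(ValueError):
            run_day(cfg, roster, NEVER, streams, False)


class TestCalibration:
    def test_checked_in_volume_and_screening_share(self):
        spec = ScenarioSpec(
            template=rss_template(),
            profile=nonuniform_profile(),
            same_day=False,
            days=200,
            seeds=(1,),
        )
        result = run_scenario(spec)
        s = result.summary()
        assert s["mean_checked_in"] == pytest.approx(60.0, abs=1.5)
        assert s["screening_share"] == pytest.approx(0.42, abs=0.02)
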