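"""Schedule templates: category counts, roster construction, risk banding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from recallsim.config import ConfigurationError, SCREENING_MAMMO
from recallsim.templates import (
    ArrivalProfile,
    RssCategory,
    SchedulingError,
    assign_rss_category,
    build_daily_roster,
    non_rss_template,
    rss_template,
    sample_category_counts,
)

EXPECTED_SCREENING = 25.2  # 42% of 60 checked-in patients


class TestSampleCategoryCounts:
    def test_rss_fixed_counts_stay_in_two_point_support(self, rng):
        t = rss_template()
        counts = np.array(
            [sample_category_counts(t, EXPECTED_SCREENING, rng) for _ in range(20_000)]
        )
        assert set(np.unique(counts[:, 1])) <= {7, 8}
        assert set(np.unique(counts[:, 2])) <= {7, 8}

    def test_rss_fixed_count_moments(self, rng):
        # base 7 + Bernoulli(0.1) has mean 7.1 and SD 0.3 exactly
        t = rss_template()
        n = 100_000
        counts = np.array(
            [sample_category_counts(t, EXPECTED_SCREENING, rng) for _ in range(n)]
        )
        se_mean = 0.3 / np.sqrt(n)
        for col in (1, 2):
            assert counts[:, col].mean() == pytest.approx(7.1, abs=3 * se_mean)
            assert counts[:, col].std() == pytest.approx(0.3, abs=0.01)
        # category 1 takes the remaining mean: Poisson(25.2 - 14.2) = Poisson(11)
        assert counts[:, 0].mean() == pytest.approx(11.0, abs=3 * np.sqrt(11 / n))

    def test_non_rss_poisson_thinning_moments(self, rng):
        t = non_rss_template()
        n = 100_000
        counts = np.array(
            [sample_category_counts(t, EXPECTED_SCREENING, rng) for _ in range(n)]
        )
        expected = np.array([0.44, 0.28, 0.28]) * EXPECTED_SCREENING
        for col, mu in enumerate(expected):
            se = np.sqrt(mu / n)
            assert counts[:, col].mean() == pytest.approx(mu, abs=3 * se)
            # Poisson: SD = sqrt(mean)
            assert counts[:, col].std() == pytest.approx(np.sqrt(mu), rel=0.03)

    def test_no_show_inflation_targets_arrived_mean(self, rng):
        # scheduled counts are inflated so 10% no-shows thin back to target
        t = non_rss_template()
        n = 50_000
        counts = np.array(
            [
                sample_category_counts(t, EXPECTED_SCREENING, rng, no_show_rate=0.1)
                for _ in range(n)
            ]
        )
        target = 0.44 * EXPECTED_SCREENING / 0.9
        assert counts[:, 0].mean() == pytest.approx(target, abs=3 * np.sqrt(target / n))

    def test_vanishing_volume_gives_zero_counts(self, rng):
        t = non_rss_template()
        counts = [sample_category_counts(t, 1e-9, rng) for _ in range(100)]
        assert all(c == (0, 0, 0) for c in counts)

    @pytest.mark.parametrize("volume", [0.0, -1.0])
    def test_nonpositive_volume_rejected(self, rng, volume):
        with pytest.raises(ConfigurationError):
            sample_category_counts(non_rss_template(), volume, rng)

    def test_rss_volume_below_fixed_counts_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            sample_category_counts(rss_template(), 10.0, rng)


class TestBuildDailyRoster:
    @given(
        c1=st.integers(0, 20),
        c2=st.integers(0, 12),
        c3=st.integers(0, 12),
        seed=st.integers(0, 1000),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_rss_ordering_blocks_categories_3_2_1(self, c1, c2, c3, seed):
        rng = np.random.default_rng(seed)
        roster = build_daily_roster(
            (c1, c2, c3), rss_template(), ArrivalProfile(), rng
        )
        times = {cat: [] for cat in (1, 2, 3)}
        for s in roster.slots:
            if s.patient_type == SCREENING_MAMMO:
                times[int(s.rss_category)].append(s.time_h)
        if times[3] and times[2]:
            assert max(times[3]) <= min(times[2])
        if times[2] and times[1]:
            assert max(times[2]) <= min(times[1])
        assert roster.counts_by_category == (c1, c2, c3)

    def test_non_rss_first_slot_is_exchangeable(self):
        # with counts (11, 7, 7) the first screening slot is category 3
        # with probability 7/25 under a uniform shuffle
        rng = np.random.default_rng(7)
        n = 10_000
        hits = 0
        for _ in range(n):
            roster = build_daily_roster(
                (11, 7, 7), non_rss_template(), ArrivalProfile(), rng
            )
            first = min(
                (s for s in roster.slots if s.patient_type == SCREENING_MAMMO),
                key=lambda s: s.time_h,
            )
            hits += first.rss_category == RssCategory.ELEVATED
        p = 7 / 25
        se = np.sqrt(p * (1 - p) / n)
        assert hits / n == pytest.approx(p, abs=3 * se)

    def test_empty_counts_leave_other_types_untouched(self, rng):
        roster = build_daily_roster(
            (0, 0, 0),
            non_rss_template(),
            ArrivalProfile(),
            rng,
            other_counts={"diagnostic": 5},
        )
        assert roster.n_screening == 0
        assert len(roster.slots) == 5

    def test_backfill_flags_mark_fixed_rss_slots(self, rng):
        roster = build_daily_roster((3, 2, 2), rss_template(), ArrivalProfile(), rng)
        for s in roster.slots:
            assert s.backfilled == (int(s.rss_category) in (2, 3))

    def test_overfull_window_rejected(self, rng):
        with pytest.raises(SchedulingError):
            build_daily_roster((600, 0, 0), non_rss_template(), ArrivalProfile(), rng)

    def test_slot_times_inside_checkin_window(self, rng):
        roster = build_daily_roster((11, 7, 7), rss_template(), ArrivalProfile(), rng)
        assert all(0 <= s.time_h <= 9.5 for s in roster.slots)


class TestAssignRssCategory:
    @pytest.mark.parametrize(
        "risk, dl_high, has_prior, expected",
        [
            (0.01, False, True, RssCategory.LOW),
            (0.03, False, True, RssCategory.MODERATE),
            (0.05, False, True, RssCategory.ELEVATED),
            (0.01, False, False, RssCategory.ELEVATED),  # no prior mammogram
            (0.01, True, True, RssCategory.MODERATE),  # DL flag escalates one band
            (0.05, True, True, RssCategory.ELEVATED),
            (0.0, False, True, RssCategory.LOW),
        ],
    )
    def test_banding(self, risk, dl_high, has_prior, expected):
        assert assign_rss_category(risk, dl_high, has_prior) == expected

    @pytest.mark.parametrize("risk", [-0.1, 1.5])
    def test_risk_outside_unit_interval_rejected(self, risk):
        with pytest.raises(ValueError):
            assign_rss_category(risk)
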