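import numpy as np
import pytest

from timeusecox.accelerometer import (
    DailySummary,
    MinuteSeries,
    build_exposures,
    classify_minute,
    detect_nonwear,
    read_minute_streams,
    summarize_day,
)


def brute_force_nonwear(counts, window=90, allowance_max=2, flank=30):
    """Independent reference: enumerate all candidate zero-bounded segments.

    A segment [i, j] is a non-wear period iff it starts and ends on zero
    counts, is at least ``window`` minutes long, contains no count >= 100, has
    at most ``allowance_max`` nonzero minutes, and every maximal nonzero gap
    inside it is flanked by >= ``flank`` consecutive zero minutes on each side
    (a flank truncated by the recording boundary passes).
    """
    counts = np.asarray(counts)
    n = len(counts)
    wear = np.ones(n, dtype=bool)
    # candidate segments start at a zero-run start and end at a zero-run end:
    # any other zero-bounded segment is a sub-segment of one of these, and a
    # valid sub-segment implies the enclosing run-bounded one is valid too
    zero = counts == 0
    edges = np.flatnonzero(np.diff(np.concatenate(([0], zero.view(np.int8), [0]))))
    run_starts, run_stops = edges[::2], edges[1::2]

    def gap_flanked(g0, g1):
        """The maximal nonzero gap counts[g0:g1] as a unit has zero flanks."""
        left = 0
        p = g0 - 1
        while p >= 0 and counts[p] == 0:
            left += 1
            p -= 1
        right = 0
        p = g1
        while p < n and counts[p] == 0:
            right += 1
            p += 1
        ok_left = left >= flank or (g0 - 1 - left) < 0
        ok_right = right >= flank or (g1 + right) > n - 1
        return ok_left and ok_right

    for i in run_starts:
        for j in run_stops[run_stops > i] - 1:
            if j - i + 1 < window:
                continue
            seg = counts[i : j + 1]
            nz = np.flatnonzero(seg > 0)
            if len(nz) > allowance_max or np.any(seg >= 100):
                continue
            gaps = []
            for k in nz:
                if gaps and k == gaps[-1][1]:
                    gaps[-1] = (gaps[-1][0], k + 1)
                else:
                    gaps.append((k, k + 1))
            if all(gap_flanked(i + g0, i + g1) for g0, g1 in gaps):
                wear[i : j + 1] = False
    return wear


def random_day(rng):
    """A day built from blocks of zeros / low counts / active counts."""
    pieces = []
    total = 0
    n_target = int(rng.integers(200, 1441))
    while total < n_target:
        kind = rng.choice(["zero", "low", "active"], p=[0.45, 0.2, 0.35])
        length = int(rng.integers(1, 140))
        length = min(length, n_target - total)
        if kind == "zero":
            pieces.append(np.zeros(length, dtype=np.int64))
        elif kind == "low":
            pieces.append(rng.integers(1, 100, size=length))
        else:
            pieces.append(rng.integers(100, 4000, size=length))
        total += length
    return np.concatenate(pieces)


class TestDetectNonwear:
    def test_all_zero_day_is_fully_nonwear(self):
        s = MinuteSeries("a", 1, np.zeros(1440, dtype=int))
        assert not detect_nonwear(s).any()

    def test_short_zero_runs_stay_wear(self):
        counts = np.concatenate([np.zeros(60), np.full(60, 500), np.zeros(60)])
        s = MinuteSeries("a", 1, counts.astype(int))
        assert detect_nonwear(s).all()

    def test_allowance_absorbs_low_count_interruption(self):
        # 45 zeros + one minute of 50 cpm + 45 zeros inside an active day:
        # the 91-minute span counts as a single non-wear period
        counts = np.concatenate(
            [np.full(100, 500), np.zeros(45), [50], np.zeros(45), np.full(100, 500)]
        ).astype(int)
        s = MinuteSeries("a", 1, counts)
        wear = detect_nonwear(s)
        assert not wear[100:191].any()
        assert wear[:100].all() and wear[191:].all()
        np.testing.assert_array_equal(wear, brute_force_nonwear(counts))

    def test_high_count_interruption_breaks_run(self):
        counts = np.concatenate(
            [np.zeros(45), [150], np.zeros(45), np.full(100, 500)]
        ).astype(int)
        wear = detect_nonwear(MinuteSeries("a", 1, counts))
        assert wear.all()  # neither zero run reaches 90 on its own

    def test_unflanked_interruption_not_absorbed(self):
        # 20-zero flank on the right is below the 30-minute requirement
        counts = np.concatenate(
            [np.zeros(80), [50], np.zeros(20), np.full(200, 500), np.zeros(100)]
        ).astype(int)
        wear = detect_nonwear(MinuteSeries("a", 1, counts))
        np.testing.assert_array_equal(wear, brute_force_nonwear(counts))
        assert wear[80]  # the interruption minute stays wear

    def test_boundary_run_needs_no_flank(self):
        # interruption near the start: left flank truncated by the recording edge
        counts = np.concatenate([np.zeros(5), [50], np.zeros(90), np.full(60, 500)])
        wear = detect_nonwear(MinuteSeries("a", 1, counts.astype(int)))
        np.testing.assert_array_equal(wear, brute_force_nonwear(counts))
        assert not wear[:96].any()

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            MinuteSeries("a", 1, np.array([], dtype=int))

    def test_matches_brute_force_on_random_days(self):
        rng = np.random.default_rng(2024)
        for _ in range(150):
            counts = random_day(rng)
            s = MinuteSeries("r", 1, counts)
            np.testing.assert_array_equal(
                detect_nonwear(s),
                brute_force_nonwear(counts),
                err_msg=f"mismatch for seed-derived day of length {len(counts)}",
            )


class TestClassifyMinute:
    @pytest.mark.parametrize(
        "count,label",
        [
            (0, "SB"),
            (100, "SB"),
            (101, "LLPA"),
            (760, "LLPA"),
            (761, "HLPA"),
            (1951, "HLPA"),
            (1952, "MVPA"),
            (10000, "MVPA"),
        ],
    )
    def test_cut_point_boundaries(self, count, label):
        assert classify_minute(count) == label

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_minute(-1)

    def test_monotone_with_three_breakpoints(self):
        order = ["SB", "LLPA", "HLPA", "MVPA"]
        labels = [order.index(classify_minute(c)) for c in range(0, 3000)]
        diffs = np.diff(labels)
        assert (diffs >= 0).all() and (diffs == 1).sum() == 3


class TestSummarizeDay:
    def test_sedentary_wear_day(self):
        s = MinuteSeries("a", 1, np.zeros(600, dtype=int))
        d = summarize_day(s, np.ones(600, dtype=bool))
        assert d.sb_min == 600 and d.wear_minutes == 600
        assert d.mvpa_min == d.hlpa_min == d.llpa_min == 0

    def test_fully_nonwear_mask(self):
        s = MinuteSeries("a", 1, np.zeros(600, dtype=int))
        d = summarize_day(s, np.zeros(600, dtype=bool))
        assert d.wear_minutes == 0 and d.sb_min == 0

    def test_mixed_band_counting(self):
        counts = np.concatenate([np.full(300, 2000), np.full(300, 50)]).astype(int)
        d = summarize_day(MinuteSeries("a", 1, counts), np.ones(600, dtype=bool))
        assert (d.mvpa_min, d.sb_min) == (300, 300)

    def test_partition_property_on_random_days(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            counts = random_day(rng)
            d = summarize_day(MinuteSeries("a", 1, counts))
            assert d.mvpa_min + d.hlpa_min + d.llpa_min + d.sb_min == d.wear_minutes

    def test_length_mismatch_rejected(self):
        s = MinuteSeries("a", 1, np.zeros(600, dtype=int))
        with pytest.raises(ValueError):
            summarize_day(s, np.ones(10, dtype=bool))


def _day(sid, day, wear, sb=None):
    sb = wear if sb is None else sb
    return DailySummary(sid, day, wear, 0, 0, wear - sb, sb)


class TestBuildExposures:
    def test_compliant_subject_included(self):
        days = [_day("s1", d, 900) for d in range(1, 8)]
        exposures, log = build_exposures(days)
        assert len(exposures) == 1 and exposures[0].n_valid_days == 7
        assert log.empty

    def test_three_valid_days_excluded(self):
        days = [_day("s1", d, 900) for d in range(1, 4)]
        exposures, log = build_exposures(days)
        assert not exposures and list(log["subject_id"]) == ["s1"]

    def test_ten_hour_day_threshold(self):
        days = [_day("s1", 1, 590), _day("s1", 2, 610)] + [
            _day("s1", d, 800) for d in range(3, 7)
        ]
        exposures, _ = build_exposures(days)
        assert exposures[0].n_valid_days == 5  # the 590-min day is dropped
        assert exposures[0].wear_minutes == pytest.approx((610 + 4 * 800) / 5)

    def test_means_sum_to_wear(self):
        days = [_day("s1", d, 700 + 10 * d, sb=500) for d in range(1, 6)]
        exposures, _ = build_exposures(days)
        e = exposures[0]
        total = e.mvpa_min + e.hlpa_min + e.llpa_min + e.sb_min
        assert total == pytest.approx(e.wear_minutes, abs=1e-9)


class TestMinuteStreamIO:
    def test_long_and_wide_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 3000, size=120)
        long = tmp_path / "long.csv"
        with open(long, "w") as fh:
            fh.write("subject_id,day_index,minute_index,count\n")
            for m, c in enumerate(counts):
                fh.write(f"s1,1,{m},{c}\n")
        wide = tmp_path / "wide.csv"
        with open(wide, "w") as fh:
            fh.write("subject_id,day_index," + ",".join(f"m{i}" for i in range(120)))
            fh.write("\ns1,1," + ",".join(str(c) for c in counts) + "\n")
        for path in (long, wide):
            series = read_minute_streams(path)
            assert len(series) == 1
            np.testing.assert_array_equal(series[0].counts, counts)

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("foo,bar\n1,2\n")
        with pytest.raises(ValueError, match="subject_id"):
            read_minute_streams(p)
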