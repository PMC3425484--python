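import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirscreen.errors import ValidationError
from mirscreen.screen_stats import (
    NORMAL_MAD,
    BScoreTable,
    PrimaryHitCriteria,
    bscore_plate,
    fdr_curve,
    intraplate_bias_report,
    mad,
    null_tail_probability,
    select_primary_hits,
)

from conftest import build_plate


def brute_median(values):
    s = sorted(values)
    n = len(s)
    return s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2


def brute_mad(values):
    m = brute_median(values)
    return brute_median([abs(v - m) for v in values])


class TestMad:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([1, 2, 3, 4, 5], 1.0),
            ([7, 7, 7, 7], 0.0),
            ([1, 1, 1, 9], 0.0),
        ],
    )
    def test_known_values(self, values, expected):
        assert mad(values) == expected

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            mad([])

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(120):
            values = rng.normal(size=rng.integers(1, 25)).tolist()
            assert mad(values) == pytest.approx(brute_mad(values), abs=1e-12)


class TestBscorePlate:
    def test_known_plate(self):
        plate = build_plate([10, 12, 14, 16, 18])
        scores = bscore_plate(plate)
        assert scores["c001"] == pytest.approx(-2.0)
        assert scores["c003"] == 0.0  # well at the plate median

    def test_matches_brute_force_on_random_plates(self, rng):
        for _ in range(100):
            values = rng.lognormal(0, 0.3, size=int(rng.integers(5, 40)))
            plate = build_plate(values)
            scores = bscore_plate(plate)
            m, s = brute_median(values.tolist()), brute_mad(values.tolist())
            for i, v in enumerate(values):
                assert scores[f"c{i + 1:03d}"] == pytest.approx((v - m) / s, rel=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        a=st.floats(min_value=0.1, max_value=50),
        b=st.floats(min_value=0, max_value=100),
        seed=st.integers(0, 10_000),
    )
    def test_affine_invariance(self, a, b, seed):
        values = np.random.default_rng(seed).lognormal(0, 0.4, size=20)
        base = bscore_plate(build_plate(values))
        scaled = bscore_plate(build_plate(a * values + b))
        for cid in base:
            assert scaled[cid] == pytest.approx(base[cid], rel=1e-9, abs=1e-9)

    def test_mad_zero_plate_flagged_not_infinite(self):
        plate = build_plate([5.0] * 10)
        with pytest.warns(UserWarning, match="MAD is 0"):
            scores = bscore_plate(plate)
        assert all(math.isnan(v) for v in scores.values())

    def test_too_few_usable_wells_rejected(self):
        with pytest.raises(ValidationError):
            bscore_plate(build_plate([1.0]))

    def test_excluded_wells_do_not_shift_scores(self):
        values = [10, 12, 14, 16, 18]
        plate = build_plate(values)
        # pack huge values into excluded-edge wells: scores must not move
        loud = build_plate(values)
        for w in loud.wells.values():
            if w.role == "excluded_edge":
                w.value = 1e6
        assert bscore_plate(plate) == bscore_plate(loud)


class TestIntraplateBias:
    def test_identical_rows_have_zero_deviation(self):
        # 6 usable rows x 10 cols, each row identical
        values = np.tile(np.arange(10, dtype=float), 6)
        report = intraplate_bias_report(build_plate(values))
        rows = report[report["kind"] == "row"]
        assert np.allclose(rows["deviation_mad"], 0.0)

    def test_shifted_row_detected_in_mad_units(self, rng):
        values = rng.normal(100, 5, size=60)
        plate = build_plate(values)
        scale = mad(values)
        # shift all wells of usable row C by +3 plate-MADs
        for w in plate.wells.values():
            if w.row == "C" and w.usable:
                w.value += 3 * scale
        report = intraplate_bias_report(plate)
        dev = report[(report["kind"] == "row") & (report["label"] == "C")][
            "deviation_mad"
        ].iloc[0]
        # brute-force the same definition on the shifted data: the shift
        # contaminates the plate median/MAD, so the expected deviation is
        # computed directly, not assumed to stay at exactly +3
        shifted = [w.value for w in plate.usable_wells()]
        row_c = [w.value for w in plate.usable_wells() if w.row == "C"]
        expected = (brute_median(row_c) - brute_median(shifted)) / brute_mad(shifted)
        assert dev == pytest.approx(expected, rel=1e-12)
        assert dev > 1.5  # clearly flagged as the outlying row
        others = report[(report["kind"] == "row") & (report["label"] != "C")]
        assert (others["deviation_mad"].abs() < 1.0).all()

    def test_needs_two_rows_and_columns(self):
        plate = build_plate(np.arange(10.0))  # a single usable row
        with pytest.raises(ValidationError):
            intraplate_bias_report(plate)


def make_table(mean_pairs, assay="viability"):
    """Build a BScoreTable whose construct means equal the given values."""
    table = BScoreTable()
    for i, m in enumerate(mean_pairs):
        table.add_replicate(f"c{i:04d}", assay, m)
        table.add_replicate(f"c{i:04d}", assay, m)
    return table


class TestFdrCurve:
    def test_normal_mad_constant_matches_simulation(self, rng):
        # the MAD of a large standard-normal sample converges to 0.67449
        sample = rng.standard_normal(400_000)
        assert mad(sample) == pytest.approx(NORMAL_MAD, abs=5e-3)

    def test_null_probability_at_zero_is_half(self):
        assert null_tail_probability(0.0, k=1) == pytest.approx(0.5)
        assert null_tail_probability(0.0, k=2) == pytest.approx(0.5)

    def test_expected_count_single_replicate(self):
        # 1072 tested constructs, one replicate, cutoff -3
        table = BScoreTable()
        for i in range(1072):
            table.add_replicate(f"c{i}", "viability", 0.0)
        curve = fdr_curve(table, "viability", [-3.0], k=1)
        assert curve.expected[0] == pytest.approx(23.0, abs=0.1)

    def test_fdr_capped_at_one_and_nan_when_no_hits(self):
        table = make_table([0.0] * 100 + [-4.0])
        curve = fdr_curve(table, "viability", [-0.1, -5.0])
        assert curve.fdr[0] == 1.0  # expected ~47 >> observed 1
        assert math.isnan(curve.fdr[1])  # nothing observed at -5

    def test_observed_counts_non_increasing(self, rng):
        table = make_table(rng.normal(0, 1.5, size=300))
        curve = fdr_curve(table, "viability", [-0.5, -1.0, -2.0, -3.0])
        assert np.all(np.diff(curve.observed) <= 0)

    def test_non_monotone_thresholds_rejected(self):
        table = make_table([-1.0, -2.0])
        with pytest.raises(ValidationError):
            fdr_curve(table, "viability", [-3.0, -1.0])
        with pytest.raises(ValidationError):
            fdr_curve(table, "viability", [-1.0, 1.0])

    def test_k_defaults_to_modal_replicate_count(self):
        table = make_table([0.0] * 50)  # two replicates each
        curve = fdr_curve(table, "viability", [-2.0])
        assert curve.k == 2


class TestPrimaryHitSelection:
    @pytest.mark.parametrize(
        "viab, count, low_titer, expected_rules",
        [
            (-3.5, -1.0, False, ("A",)),
            (-3.0, -1.0, False, ("A",)),  # reaching the cutoff counts for A
            (-2.5, -3.5, False, ("B",)),
            (-2.5, -1.0, True, ("C",)),
            (-2.5, -2.5, False, ()),
            (-2.0, -3.5, False, ()),  # B is strict at -2
            (-1.0, -5.0, True, ()),
            (-3.5, -3.5, True, ("A", "B", "C")),
        ],
    )
    def test_rule_branches(self, viab, count, low_titer, expected_rules):
        viability = BScoreTable()
        counts = BScoreTable()
        viability.add_replicate("x", "viability", viab)
        counts.add_replicate("x", "cell_count", count)
        titer = {"x"} if low_titer else set()
        calls = select_primary_hits(viability, counts, titer)
        if expected_rules:
            assert calls.hits["x"] == expected_rules
        else:
            assert "x" not in calls.hits

    def test_construct_missing_from_viability_skipped_with_warning(self):
        viability = BScoreTable()
        counts = BScoreTable()
        viability.add_replicate("a", "viability", -5.0)
        counts.add_replicate("a", "cell_count", -1.0)
        counts.add_replicate("orphan", "cell_count", -9.0)
        with pytest.warns(UserWarning, match="orphan"):
            calls = select_primary_hits(viability, counts)
        assert set(calls.hits) == {"a"}

    def test_hit_set_monotone_under_cutoff_relaxation(self, rng):
        viability = BScoreTable()
        counts = BScoreTable()
        n = 200
        for i in range(n):
            viability.add_replicate(f"c{i}", "viability", rng.normal(-1.5, 1.5))
            counts.add_replicate(f"c{i}", "cell_count", rng.normal(-1.5, 1.5))
        titer = {f"c{i}" for i in range(0, n, 7)}
        strict = select_primary_hits(viability, counts, titer)
        relaxed = select_primary_hits(
            viability,
            counts,
            titer,
            PrimaryHitCriteria(-2.5, -1.5, -2.5, -1.5),
        )
        assert set(strict.hits) <= set(relaxed.hits)

    def test_criteria_must_be_negative(self):
        with pytest.raises(ValidationError):
            PrimaryHitCriteria(rule_a_viability_mean=1.0)
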