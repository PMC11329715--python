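"""Thermoregulation indices: deviations, bootstrap CIs, E/I/E_x, report assembly."""

import numpy as np
import pandas as pd
import pytest

from vipertherm import indices
from vipertherm.errors import (
    InsufficientDataError,
    InvalidBoundsError,
    UndefinedIndexError,
)
from vipertherm.indices import BootstrapSpec
from vipertherm.tset import TsetEstimate

TSET = TsetEstimate(30.0, 25.0, 35.0, "population", 100)


def spots_frame(t_b, times=None, pop="P"):
    t_b = list(t_b)
    if times is None:
        times = [f"2019-08-01 12:{i % 60:02d}:00" for i in range(len(t_b))]
    return pd.DataFrame(
        {
            "individual_id": [f"i{i}" for i in range(len(t_b))],
            "population": pop,
            "datetime": times,
            "t_b": t_b,
            "microhabitat": "sun",
        }
    )


def otm_frame(t_e, times=None, micro="sun", pop="P"):
    t_e = list(t_e)
    if times is None:
        start = pd.Timestamp("2019-08-01 12:00:00")
        times = [
            (start + pd.Timedelta(minutes=5 * i)).strftime("%Y-%m-%d %H:%M:%S")
            for i in range(len(t_e))
        ]
    return pd.DataFrame(
        {"population": pop, "microhabitat": micro, "datetime": times, "t_e": t_e}
    )


class TestDeviation:
    @pytest.mark.parametrize(
        "t, expected", [(30.0, 0.0), (40.0, 5.0), (20.0, 5.0), (25.0, 0.0), (35.0, 0.0)]
    )
    def test_piecewise_values(self, t, expected):
        assert indices.deviation(t, 25.0, 35.0) == expected

    def test_vectorized_matches_scalar(self, rng):
        t = rng.uniform(10, 50, size=40)
        vec = indices.deviation(t, 25.0, 35.0)
        assert np.array_equal(vec, [indices.deviation(x, 25.0, 35.0) for x in t])

    def test_invalid_bounds(self):
        with pytest.raises(InvalidBoundsError):
            indices.deviation(30.0, 35.0, 25.0)


class TestAccuracyDb:
    def test_all_inside_range_is_exact_zero(self):
        mean, lo, hi, n = indices.accuracy_db(
            spots_frame([26, 28, 30, 34]), TSET, BootstrapSpec(1000, 0)
        )
        assert (mean, lo, hi) == (0.0, 0.0, 0.0)
        assert n == 4

    def test_mean_of_two_exceedances(self):
        tset = TsetEstimate(30.0, 25.0, 34.0, "population", 10)
        mean, *_ = indices.accuracy_db(spots_frame([36, 38]), tset, BootstrapSpec(100, 0))
        assert mean == 3.0

    def test_empty_input_rejected(self):
        with pytest.raises(InsufficientDataError):
            indices.accuracy_db(spots_frame([]), TSET)

    def test_per_individual_averaging_flag(self):
        tset = TsetEstimate(30.0, 25.0, 35.0, "population", 10)
        spots = spots_frame([39.0, 35.0, 36.0])  # deviations 4, 0, 1
        spots["individual_id"] = ["a", "a", "b"]
        pooled, *_ = indices.accuracy_db(spots, tset, BootstrapSpec(100, 0))
        per_ind, *_ = indices.accuracy_db(
            spots, tset, BootstrapSpec(100, 0), per_individual=True
        )
        assert pooled == pytest.approx(5 / 3)
        assert per_ind == pytest.approx((2.0 + 1.0) / 2)

    def test_ci_brackets_point_estimate(self, rng):
        mean, lo, hi, _ = indices.accuracy_db(
            spots_frame(rng.uniform(20, 40, 30)), TSET, BootstrapSpec(2000, 3)
        )
        assert lo <= mean <= hi


class TestHabitatQualityDe:
    def test_diurnal_window_inclusive_start_exclusive_end(self):
        times = [
            "2019-08-01 05:55:00",
            "2019-08-01 06:00:00",
            "2019-08-01 19:55:00",
            "2019-08-01 20:00:00",
            "2019-08-01 20:05:00",
        ]
        # deviations: excluded, 5, 0, excluded, excluded
        otm = otm_frame([10.0, 40.0, 30.0, 10.0, 10.0], times=times)
        mean, _, _, n = indices.habitat_quality_de(otm, TSET, BootstrapSpec(100, 0))
        assert n == 2
        assert mean == 2.5

    def test_hand_enumerated_mean(self):
        otm = otm_frame([30.0, 37.0, 39.0])  # deviations 0, 2, 4
        mean, *_ = indices.habitat_quality_de(otm, TSET, BootstrapSpec(100, 0))
        assert mean == 2.0

    def test_no_diurnal_readings_rejected(self):
        otm = otm_frame([30.0], times=["2019-08-01 03:00:00"])
        with pytest.raises(InsufficientDataError):
            indices.habitat_quality_de(otm, TSET)


class TestEffectiveness:
    def test_hertz_printed_arithmetic(self):
        assert round(indices.effectiveness_hertz(1.42, 5.89), 2) == 0.76
        assert indices.effectiveness_hertz(0.0, 5.51) == 1.0
        assert indices.effectiveness_hertz(3.0, 3.0) == 0.0

    def test_hertz_undefined_for_ideal_habitat(self):
        with pytest.raises(UndefinedIndexError):
            indices.effectiveness_hertz(0.0, 0.0)

    def test_bdw_difference(self):
        assert round(indices.effectiveness_bdw(1.42, 5.89), 2) == 4.47
        assert indices.effectiveness_bdw(0.0, 5.51) == 5.51
        assert indices.effectiveness_bdw(3.0, 3.0) == 0.0


class TestExploitationEx:
    def _fixture(self):
        """10 spots; 6 with t_b inside T_set; matched T_e inside for only 2."""
        start = pd.Timestamp("2019-08-01 12:00:00")
        times = [
            (start + pd.Timedelta(minutes=5 * i)).strftime("%Y-%m-%d %H:%M:%S")
            for i in range(10)
        ]
        t_b = [26, 27, 28, 29, 30, 31, 20, 21, 22, 23]  # 6 inside [25, 35]
        spots = spots_frame(t_b, times=times)
        te_sun = [30.0, 30.0] + [40.0] * 8  # first two spots overlap T_set
        te_shade = [40.0] * 10
        otm = pd.concat(
            [otm_frame(te_sun, times=times), otm_frame(te_shade, times=times, micro="shade")],
            ignore_index=True,
        )
        return spots, otm

    def test_hand_enumerated_ratio_exceeds_one(self):
        spots, otm = self._fixture()
        assert indices.exploitation_ex(spots, otm, TSET) == 3.0

    def test_all_inside_gives_one(self):
        spots = spots_frame([26, 28, 30])
        otm = otm_frame([30.0, 30.0, 30.0], times=list(spots["datetime"]))
        assert indices.exploitation_ex(spots, otm, TSET) == 1.0

    def test_no_tb_inside_gives_zero(self):
        spots = spots_frame([20, 21, 22])
        otm = otm_frame([30.0, 30.0, 30.0], times=list(spots["datetime"]))
        assert indices.exploitation_ex(spots, otm, TSET) == 0.0

    def test_no_overlap_undefined(self):
        spots = spots_frame([26.0])
        otm = otm_frame([40.0], times=list(spots["datetime"]))
        with pytest.raises(UndefinedIndexError):
            indices.exploitation_ex(spots, otm, TSET)


class TestBootstrapCI:
    def test_identical_deviations_zero_width(self):
        spots = spots_frame([38.0] * 12)  # every deviation exactly 3
        mean, lo, hi, _ = indices.accuracy_db(spots, TSET, BootstrapSpec(500, 0))
        assert mean == lo == hi == 3.0

    def test_ci_seed_deterministic(self, rng):
        spots = spots_frame(rng.uniform(20, 42, 25))
        a = indices.accuracy_db(spots, TSET, BootstrapSpec(1000, 9))
        b = indices.accuracy_db(spots, TSET, BootstrapSpec(1000, 9))
        assert a == b


class TestTranslationInvariance:
    def test_db_de_invariant_under_common_shift(self, rng):
        t_b = rng.uniform(20, 40, 20)
        t_e = rng.uniform(15, 45, 30)
        for c in (-3.0, 2.5):
            shifted = TsetEstimate(30.0 + c, 25.0 + c, 35.0 + c, "population", 1)
            a, *_ = indices.accuracy_db(spots_frame(t_b), TSET, BootstrapSpec(100, 0))
            b, *_ = indices.accuracy_db(
                spots_frame(t_b + c), shifted, BootstrapSpec(100, 0)
            )
            assert a == pytest.approx(b, abs=1e-12)
            d1, *_ = indices.habitat_quality_de(otm_frame(t_e), TSET, BootstrapSpec(100, 0))
            d2, *_ = indices.habitat_quality_de(
                otm_frame(t_e + c), shifted, BootstrapSpec(100, 0)
            )
            assert d1 == pytest.approx(d2, abs=1e-12)


def brute_force_indices(spots, otm, tset, tol_min=2.5):
    """Explicit-loop oracle for d_b, d_e, E, I, E_x on tiny inputs."""

    def dev(t):
        if t > tset.t_set_upper:
            return t - tset.t_set_upper
        if t < tset.t_set_lower:
            return tset.t_set_lower - t
        return 0.0

    d_b = sum(dev(t) for t in spots["t_b"]) / len(spots)
    day = []
    for _, row in otm.iterrows():
        ts = pd.Timestamp(row["datetime"])
        frac = ts.hour + ts.minute / 60 + ts.second / 3600
        if 6 <= frac < 20:
            day.append(row["t_e"])
    d_e = sum(dev(t) for t in day) / len(day)
    numer = sum(
        1 for t in spots["t_b"] if tset.t_set_lower <= t <= tset.t_set_upper
    )
    denom = 0
    for _, srow in spots.iterrows():
        st = pd.Timestamp(srow["datetime"])
        overlap = False
        for micro in otm["microhabitat"].unique():
            grp = otm[otm["microhabitat"] == micro]
            best, best_d = None, None
            for _, orow in grp.iterrows():
                d = abs((pd.Timestamp(orow["datetime"]) - st).total_seconds())
                if best_d is None or d < best_d:
                    best_d, best = d, orow["t_e"]
            if best_d is not None and best_d <= tol_min * 60:
                if tset.t_set_lower <= best <= tset.t_set_upper:
                    overlap = True
        if overlap:
            denom += 1
    e_x = numer / denom if denom else None
    e = 1 - d_b / d_e if d_e > 0 else None
    return d_b, d_e, e, d_e - d_b, e_x


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_fixtures(self):
        """Vectorized indices equal an explicit-loop recount on 20 small fixtures."""
        rng = np.random.default_rng(42)
        for rep in range(20):
            n_spots = int(rng.integers(3, 20))
            n_otm = int(rng.integers(5, 25))
            start = pd.Timestamp("2019-08-01 10:00:00")
            otimes = [
                (start + pd.Timedelta(minutes=5 * i)).strftime("%Y-%m-%d %H:%M:%S")
                for i in range(n_otm)
            ]
            stimes = [
                otimes[int(rng.integers(0, n_otm))] for _ in range(n_spots)
            ]
            spots = spots_frame(np.round(rng.uniform(18, 42, n_spots), 1), times=stimes)
            otm = pd.concat(
                [
                    otm_frame(np.round(rng.uniform(15, 45, n_otm), 1), times=otimes),
                    otm_frame(
                        np.round(rng.uniform(15, 45, n_otm), 1),
                        times=otimes,
                        micro="shade",
                    ),
                ],
                ignore_index=True,
            )
            exp_db, exp_de, exp_e, exp_i, exp_ex = brute_force_indices(spots, otm, TSET)
            d_b, *_ = indices.accuracy_db(spots, TSET, BootstrapSpec(100, 0))
            d_e, *_ = indices.habitat_quality_de(otm, TSET, BootstrapSpec(100, 0))
            assert d_b == pytest.approx(exp_db, abs=1e-12)
            assert d_e == pytest.approx(exp_de, abs=1e-12)
            assert indices.effectiveness_hertz(d_b, d_e) == pytest.approx(exp_e, abs=1e-12)
            assert indices.effectiveness_bdw(d_b, d_e) == pytest.approx(exp_i, abs=1e-12)
            if exp_ex is not None:
                assert indices.exploitation_ex(spots, otm, TSET) == pytest.approx(
                    exp_ex, abs=1e-12
                )


class TestIndexReport:
    def test_missing_tb_flags_db_e_i_missing(self):
        otm = otm_frame([30.0, 38.0, 40.0])
        rep = indices.build_index_report("VA", TSET, None, otm, BootstrapSpec(200, 0))
        assert rep.d_e is not None
        assert rep.d_b is None and rep.e_hertz is None and rep.i_bdw is None
        assert rep.e_x is None

    def test_full_inputs_internally_consistent(self):
        spots = spots_frame([26, 28, 37])
        otm = otm_frame([30.0, 38.0, 40.0], times=list(spots["datetime"]))
        rep = indices.build_index_report("P", TSET, spots, otm, BootstrapSpec(200, 0))
        assert rep.e_hertz == pytest.approx(1 - rep.d_b / rep.d_e, abs=1e-12)
        assert rep.i_bdw == pytest.approx(rep.d_e - rep.d_b, abs=1e-12)
        assert rep.e_x is not None

    def test_report_frame_columns(self):
        otm = otm_frame([30.0, 38.0])
        rep = indices.build_index_report("VA", TSET, None, otm, BootstrapSpec(100, 0))
        frame = indices.report_frame([rep])
        assert list(frame["population"]) == ["VA"]
        assert np.isnan(frame["d_b"].iloc[0])
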