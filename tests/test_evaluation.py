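"""Metrics, rank statistics and report builders, checked against
brute-force oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from nirscart.evaluation import (
    aggregate_location_prediction,
    build_report,
    evaluate_set,
    group_comparison,
    group_summary,
    iqr,
    is_reliable,
    mann_whitney_u,
    nrmse,
    read_report_csv,
    rmse,
    rpiq,
    shapiro_wilk_gate,
    spearman,
    write_report_csv,
)


def _rank_average(values):
    """Brute-force average ranks with ties."""
    values = list(values)
    ranks = []
    for v in values:
        less = sum(1 for u in values if u < v)
        equal = sum(1 for u in values if u == v)
        ranks.append(less + (equal + 1) / 2.0)
    return ranks


class TestRmseNrmse:
    def test_identical_zero(self):
        assert rmse([1, 2, 3], [1, 2, 3]) == 0.0

    def test_constant_offset(self):
        assert rmse(np.zeros(5), np.full(5, 0.3)) == pytest.approx(0.3)

    def test_matches_loop_oracle(self, rng):
        a, b = rng.normal(size=20), rng.normal(size=20)
        acc = 0.0
        for x, y in zip(a, b):
            acc += (x - y) ** 2
        assert rmse(a, b) == pytest.approx(math.sqrt(acc / 20))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse([1, 2], [1, 2, 3])

    @pytest.mark.parametrize(
        "err,rng_,expected",
        [(4.0, 4.0, 100.0), (0.0, 4.0, 0.0), (0.5, 4.0, 12.5)],
    )
    def test_nrmse_arithmetic(self, err, rng_, expected):
        y = np.array([0.0, 1.0])
        assert nrmse(y, y + err, rng_) == pytest.approx(expected)

    def test_nrmse_zero_range_rejected(self):
        with pytest.raises(ValueError):
            nrmse([1, 2], [1, 2], 0.0)


class TestRpiq:
    def test_iqr_equals_rmse_gives_one(self):
        y = np.array([0.0, 25.0, 75.0, 100.0])
        assert rpiq(y, iqr(y)) == pytest.approx(1.0)

    def test_threshold_case_flagged_reliable(self):
        """IQR twice the RMSE sits exactly on the reliability threshold."""
        y = np.array([0.0, 1.0, 3.0, 4.0])
        value = rpiq(y, iqr(y) / 2.0)
        assert value == pytest.approx(2.0)
        assert is_reliable(value)
        assert not is_reliable(1.99)

    def test_iqr_matches_sorting_oracle(self):
        """Type-7 quantiles of 1..100 by the textbook interpolation
        formula: q = x[floor(h)] + (h - floor(h)) * (x[h+1] - x[h]),
        h = (n - 1) * p."""
        vals = np.arange(1.0, 101.0)

        def quantile_oracle(x, p):
            x = sorted(x)
            h = (len(x) - 1) * p
            lo = math.floor(h)
            return x[lo] + (h - lo) * (x[min(lo + 1, len(x) - 1)] - x[lo])

        oracle = quantile_oracle(vals, 0.75) - quantile_oracle(vals, 0.25)
        assert rpiq(vals, 10.0) == pytest.approx(oracle / 10.0)

    def test_scale_invariance(self, rng):
        y = rng.normal(size=30)
        err = 0.7
        assert rpiq(5 * y, 5 * err) == pytest.approx(rpiq(y, err))

    def test_zero_rmse_reports_infinity(self):
        assert rpiq(np.arange(10.0), 0.0) == math.inf

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            rpiq([1.0, 2.0, 3.0], 1.0)


class TestAggregate:
    def test_negative_predictions_excluded(self):
        assert aggregate_location_prediction([2.0, -1.0, 4.0]) == pytest.approx(3.0)

    def test_single_prediction_passthrough(self):
        assert aggregate_location_prediction([5.0]) == 5.0

    def test_all_negative_missing(self):
        assert math.isnan(aggregate_location_prediction([-1.0, -2.0]))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_location_prediction([])

    def test_constant_predictions_aggregate_to_value(self):
        assert aggregate_location_prediction([7.0] * 8) == 7.0


class TestSpearman:
    def test_monotone_pairs(self):
        x = np.arange(10.0)
        assert spearman(x, x**3)[0] == pytest.approx(1.0)
        assert spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_tied_data_matches_rank_formula_oracle(self):
        x = [1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 7.0]
        y = [2.0, 1.0, 4.0, 4.0, 6.0, 8.0, 8.0]
        rho, _ = spearman(x, y)
        rx, ry = _rank_average(x), _rank_average(y)
        assert rho == pytest.approx(np.corrcoef(rx, ry)[0, 1])

    def test_exact_small_sample_p_by_enumeration(self):
        """n = 4 tie-free data: p equals the fraction of the 24 rank
        permutations with |rho| at least as extreme."""
        x = [1.0, 2.0, 3.0, 4.0]
        y = [1.0, 3.0, 2.0, 4.0]
        rho, p = spearman(x, y)
        count = 0
        for perm in itertools.permutations([1, 2, 3, 4]):
            r = np.corrcoef([1, 2, 3, 4], perm)[0, 1]
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        assert p == pytest.approx(count / 24)

    def test_constant_input_flagged(self):
        with pytest.warns(UserWarning):
            rho, p = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert math.isnan(rho)


class TestMannWhitney:
    def test_identical_samples_null(self):
        a = np.array([1.0, 2.0, 3.0, 4.0] * 5)
        _, p = mann_whitney_u(a, a.copy())
        assert p > 0.9

    def test_separated_samples_u_zero_and_enumeration(self):
        """{1,2,3} vs {4,5,6}: U = 0 for the first sample, and the exact p
        equals the enumeration over all C(6,3) = 20 rank arrangements."""
        u, p = mann_whitney_u([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert u == 0.0
        stats = []
        pool = [1, 2, 3, 4, 5, 6]
        for combo in itertools.combinations(range(6), 3):
            a = [pool[i] for i in combo]
            ua = sum(1 for x in a for v in pool if v not in a and x > v)
            stats.append(ua)
        mid = 9 / 2  # n_a * n_b / 2
        extreme = sum(1 for s in stats if abs(s - mid) >= abs(0 - mid))
        assert p == pytest.approx(extreme / 20)

    def test_u_conservation_identity(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(size=9)
        ua, _ = mann_whitney_u(a, b)
        ub, _ = mann_whitney_u(b, a)
        assert ua + ub == pytest.approx(len(a) * len(b))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestShapiroGate:
    def test_normal_samples_mostly_parametric(self):
        rng = np.random.default_rng(1)
        results = [
            shapiro_wilk_gate(rng.standard_normal(500)) for _ in range(50)
        ]
        assert results.count("parametric") >= 45

    def test_exponential_samples_nonparametric(self):
        rng = np.random.default_rng(2)
        results = [
            shapiro_wilk_gate(rng.exponential(size=500)) for _ in range(20)
        ]
        assert results.count("nonparametric") == 20

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk_gate([1.0, 2.0])


class TestReportBuilders:
    def _rows(self, n_params=2):
        rows = []
        rng = np.random.default_rng(0)
        for p in range(n_params):
            for variant in ("Model1", "Model2"):
                for s in ("cal+val", "test"):
                    y = rng.normal(size=20)
                    rows.append(
                        {
                            "parameter": f"p{p}",
                            "variant": variant,
                            "region_um": "0.75-1.90",
                            "n_variables": 5,
                            "set": s,
                            **evaluate_set(y, y + rng.normal(0, 0.3, 20), 4.0),
                        }
                    )
        return rows

    def test_row_counting(self):
        report = build_report(self._rows())
        assert len(report) == 2 * 2 * 2
        assert list(report.columns)[:5] == [
            "parameter", "variant", "region_um", "n_variables", "set",
        ]

    def test_empty_report(self):
        assert build_report([]).empty

    def test_csv_roundtrip(self, tmp_path):
        report = build_report(self._rows(1))
        path = tmp_path / "report.csv"
        write_report_csv(report, path)
        back = read_report_csv(path)
        assert list(back.columns) == list(report.columns)
        assert np.allclose(back["nrmse_pct"], report["nrmse_pct"], rtol=1e-5)

    def test_group_summary_quartile_ordering(self):
        rng = np.random.default_rng(3)
        refs = pd.DataFrame(
            {
                "group": ["repair"] * 30 + ["control"] * 20,
                "distance_class": list(np.tile([1, 2], 25)),
                "E_eq": rng.normal(500, 100, 50),
            }
        )
        summary = group_summary(refs, ["E_eq"])
        assert (summary["q25"] <= summary["median"]).all()
        assert (summary["median"] <= summary["q75"]).all()
        assert summary["n"].sum() == 50

    def test_group_comparison_detects_separation(self):
        rng = np.random.default_rng(4)
        refs = pd.DataFrame(
            {
                "group": ["repair"] * 40 + ["control"] * 30,
                "distance_class": 1,
                "E_eq": np.concatenate(
                    [rng.normal(300, 50, 40), rng.normal(600, 50, 30)]
                ),
            }
        )
        out = group_comparison(refs, ["E_eq"])
        assert bool(out.loc[0, "significant"])
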