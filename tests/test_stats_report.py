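import numpy as np
import pandas as pd
import pytest

from rotometry import errors
from rotometry.outcome_metrics import build_records
from rotometry.rotation_measure import AngleMeasurement
from rotometry.stats_report import (
    accuracy_regression,
    build_report,
    dahlberg_error,
    icc_agreement,
    method_error,
    paired_compare,
    paired_t_power,
    paired_t_sample_size,
)


class TestDahlberg:
    def test_identical_series_zero(self):
        x = np.arange(10.0)
        assert dahlberg_error(x, x) == 0.0

    def test_unit_differences_closed_form(self):
        a = np.arange(8.0)
        assert dahlberg_error(a + 1.0, a) == pytest.approx(np.sqrt(8 / 16))

    def test_matches_direct_arithmetic(self, rng):
        a, b = rng.normal(size=30), rng.normal(size=30)
        d = a - b
        assert dahlberg_error(a, b) == pytest.approx(
            np.sqrt(np.sum(d**2) / (2 * len(d)))
        )

    def test_symmetric(self, rng):
        a, b = rng.normal(size=12), rng.normal(size=12)
        assert dahlberg_error(a, b) == pytest.approx(dahlberg_error(b, a))

    def test_length_mismatch(self):
        with pytest.raises(errors.InvalidInputError):
            dahlberg_error([1, 2, 3], [1, 2])


class TestICC:
    def test_perfect_agreement(self, rng):
        x = rng.normal(size=20)
        assert icc_agreement(np.column_stack([x, x])) == pytest.approx(1.0)

    def test_matches_pingouin(self, rng):
        import pingouin as pg

        a = rng.normal(size=25) * 3
        b = a + rng.normal(size=25) * 0.7 + 0.2
        ours = icc_agreement(np.column_stack([a, b]))
        df = pd.DataFrame(
            {
                "targets": np.tile(np.arange(25), 2),
                "raters": np.repeat(["r1", "r2"], 25),
                "scores": np.concatenate([a, b]),
            }
        )
        icc2 = pg.intraclass_corr(df, "targets", "raters", "scores")
        # ICC(A,1): two-way, absolute agreement, single measures.
        ref = float(icc2.loc[icc2["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert ours == pytest.approx(ref, abs=1e-9)

    def test_dominant_noise_near_zero(self):
        rng = np.random.default_rng(7)
        vals = []
        for _ in range(20):
            items = rng.normal(size=50) * 0.5
            vals.append(
                icc_agreement(
                    np.column_stack(
                        [items + rng.normal(size=50) * 5, items + rng.normal(size=50) * 5]
                    )
                )
            )
        assert np.mean(vals) < 0.2

    def test_variance_components_oracle(self):
        # item variance : error variance = 9 : 1 -> ICC ~ 0.9
        rng = np.random.default_rng(42)
        items = rng.normal(size=1000) * 3.0
        x = np.column_stack(
            [items + rng.normal(size=1000), items + rng.normal(size=1000)]
        )
        assert icc_agreement(x) == pytest.approx(0.9, abs=0.03)

    def test_zero_variance_undefined(self):
        with pytest.raises(errors.UndefinedStatisticError):
            icc_agreement(np.ones((10, 2)))

    def test_shift_invariance(self, rng):
        a = rng.normal(size=15)
        b = a + rng.normal(size=15) * 0.3
        x = np.column_stack([a, b])
        assert icc_agreement(x + 100.0) == pytest.approx(icc_agreement(x), abs=1e-9)

    def test_method_error_bundle(self, rng):
        a = rng.normal(size=20) * 2 + 8
        b = a + rng.normal(size=20) * 0.1
        res = method_error(a, b)
        assert res.icc > 0.99
        assert res.dahlberg_deg < 0.2
        assert 0 <= res.paired_t_p <= 1


class TestPairedCompare:
    def test_degenerate_identical(self):
        x = np.arange(10.0)
        res = paired_compare(x, x)
        assert res.degenerate
        assert res.p_value == 1.0

    def test_gaussian_null_selects_t_mostly(self):
        rng = np.random.default_rng(5)
        picks = []
        for _ in range(300):
            d = rng.normal(size=30)
            base = rng.normal(size=30) * 2 + 10
            picks.append(paired_compare(base + d, base).test_used)
        frac_t = np.mean([p == "paired_t" for p in picks])
        assert 0.90 < frac_t <= 1.0  # Shapiro rejects ~5% of true normals

    def test_skewed_selects_wilcoxon_mostly(self):
        rng = np.random.default_rng(6)
        picks = []
        for _ in range(200):
            d = rng.lognormal(mean=0.0, sigma=1.2, size=30)
            base = rng.normal(size=30) + 15
            picks.append(paired_compare(base + d, base).test_used)
        assert np.mean([p == "wilcoxon" for p in picks]) > 0.5

    def test_both_branches_always_reported(self, rng):
        res = paired_compare(rng.normal(size=20) + 10, rng.normal(size=20) + 9)
        assert np.isfinite(res.paired_t_p)
        assert np.isfinite(res.wilcoxon_p)

    def test_too_short_rejected(self):
        with pytest.raises(errors.InvalidInputError):
            paired_compare([1, 2, 3], [1, 2, 4])


class TestAccuracyRegression:
    @staticmethod
    def records_with(accuracy_fn, prescribed, ttype="canine"):
        ms = [
            AngleMeasurement(33, p, accuracy_fn(p) / 100.0 * p, ttype, "mandibular", "c")
            for p in prescribed
        ]
        return build_records(ms)

    def test_flat_response(self):
        recs = self.records_with(lambda p: 80.0, np.linspace(3, 20, 15))
        res = accuracy_regression(recs)
        assert res.beta == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.9

    def test_two_point_design_exact_slope(self):
        prescribed = [5.0] * 6 + [15.0] * 6
        recs = self.records_with(lambda p: 90.0 - 1.5 * p, prescribed)
        res = accuracy_regression(recs)
        assert res.beta == pytest.approx(-1.5, abs=1e-9)
        # exact fit: the CI degenerates onto the estimate but must contain it
        assert res.ci_low - 1e-9 <= res.beta <= res.ci_high + 1e-9

    def test_coverage_simulation(self):
        rng = np.random.default_rng(11)
        prescribed = np.linspace(2.5, 20, 40)
        covered = 0
        reps = 400
        for _ in range(reps):
            noise = rng.normal(0, 8, size=len(prescribed))
            recs = self.records_with(lambda p: 90.0 - 1.5 * p, prescribed)
            # add noise on top of the deterministic accuracy
            for r, e in zip(recs, noise):
                r.accuracy += e
            res = accuracy_regression(recs)
            covered += res.ci_low <= -1.5 <= res.ci_high
        assert covered / reps == pytest.approx(0.95, abs=0.025)

    def test_degenerate_design(self):
        recs = self.records_with(lambda p: 80.0, [10.0] * 12)
        with pytest.raises(errors.UndefinedStatisticError):
            accuracy_regression(recs)


class TestPairedTSampleSize:
    def test_monotone_in_d_and_power(self):
        n1 = paired_t_sample_size(0.4)
        n2 = paired_t_sample_size(0.6)
        n3 = paired_t_sample_size(0.8)
        assert n1 >= n2 >= n3
        assert paired_t_sample_size(0.6, power=0.9) >= paired_t_sample_size(0.6, power=0.8)

    def test_large_effect_small_n(self):
        assert 2 <= paired_t_sample_size(3.0) <= 5

    def test_invalid_inputs(self):
        with pytest.raises(errors.InvalidInputError):
            paired_t_sample_size(0.0)
        with pytest.raises(errors.InvalidInputError):
            paired_t_sample_size(0.6, alpha=1.5)

    def test_bracketing_and_monte_carlo(self):
        n = paired_t_sample_size(0.6, 0.05, 0.80)
        assert paired_t_power(n, 0.6) >= 0.80
        assert paired_t_power(n - 1, 0.6) < 0.80
        # Monte-Carlo check of the analytic power at the returned n.
        rng = np.random.default_rng(3)
        reps = 100_000
        x = rng.normal(0.6, 1.0, size=(reps, n))
        t = x.mean(axis=1) / (x.std(axis=1, ddof=1) / np.sqrt(n))
        from scipy import stats as sps

        tcrit = sps.t.ppf(0.975, n - 1)
        mc_power = np.mean(np.abs(t) > tcrit)
        assert mc_power == pytest.approx(paired_t_power(n, 0.6), abs=0.01)


class TestBuildReport:
    @staticmethod
    def synthetic_records(seed=0, n=40):
        rng = np.random.default_rng(seed)
        ms = []
        for arch in ("mandibular", "maxillary"):
            for i in range(n):
                p = float(rng.uniform(2.5, 20))
                a = p * 0.8 + rng.normal(0, 1.5)
                ms.append(
                    AngleMeasurement(33, p, a, "canine", arch, f"case-{i}")
                )
        return build_records(ms)

    def test_structural(self, tmp_path):
        paths = build_report(self.synthetic_records(), tmp_path / "report")
        assert len(paths) == 5
        t1 = pd.read_csv(tmp_path / "report" / "table1_prescription_vs_achieved.csv")
        assert set(t1["group"]) == {"canine", "total"}
        t4 = pd.read_csv(tmp_path / "report" / "table4_regression.csv")
        assert len(t4) == 2  # one regression row per arch group

    def test_deterministic_rerun(self, tmp_path):
        for sub in ("r1", "r2"):
            build_report(self.synthetic_records(), tmp_path / sub, seed=5)
        for name in (
            "table1_prescription_vs_achieved.csv",
            "table2_accuracy.csv",
            "table3_fope_direction.csv",
            "table4_regression.csv",
        ):
            assert (tmp_path / "r1" / name).read_bytes() == (
                tmp_path / "r2" / name
            ).read_bytes()

    def test_empty_records_stage_error(self, tmp_path):
        with pytest.raises(errors.StageError):
            build_report([], tmp_path)
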