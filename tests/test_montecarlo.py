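"""Monte-Carlo protocol: report shape, statistics, determinism, summaries."""

import numpy as np
import pandas as pd
import pytest

from floquetbias import (
    BIAS_REPORT_COLUMNS,
    ExperimentConfig,
    IncompleteReportError,
    NoiseSpec,
    ParameterError,
    compare_stitched,
    min_unbiased_n,
    run_experiment,
    test_unbiasedness,
)


def small_config(**kwargs):
    defaults = dict(
        lambdas=(0.75,),
        n_grid=(10,),
        noises=(NoiseSpec("normal", 1.0),),
        replicates=100,
        estimators=("regression", "yule_walker"),
        master_seed=42,
    )
    defaults.update(kwargs)
    return ExperimentConfig(**defaults)


class TestUnbiasednessTest:
    def test_zero_variance_exact_mean_accepted(self):
        res = test_unbiasedness([0.75] * 10, 0.75)
        assert res.h0_accepted and res.ttest_p == 1.0

    def test_zero_variance_wrong_mean_rejected(self):
        res = test_unbiasedness([0.7] * 10, 0.75)
        assert not res.h0_accepted and res.ttest_p == 0.0

    def test_large_shift_rejected(self):
        rng = np.random.default_rng(42)
        est = 1.25 + 0.01 * rng.standard_normal(1000)  # 50 sigma from 0.75
        res = test_unbiasedness(est, 0.75)
        assert not res.h0_accepted
        assert res.ttest_p < 1e-100

    def test_type_one_error_rate(self):
        """Under its null the t-test accepts ~95% of the time at alpha 5%."""
        rng = np.random.default_rng(42)
        accepted = sum(
            test_unbiasedness(0.75 + 0.1 * rng.standard_normal(500), 0.75).h0_accepted
            for _ in range(400)
        )
        assert 0.92 < accepted / 400 < 0.98

    def test_too_few_estimates(self):
        with pytest.raises(ParameterError):
            test_unbiasedness([0.75], 0.75)


class TestRunExperiment:
    def test_report_shape_and_columns(self):
        report = run_experiment(small_config())
        assert list(report.columns) == BIAS_REPORT_COLUMNS
        assert len(report) == 2  # one row per estimator in the single cell
        assert set(report["estimator"]) == {"regression", "yule_walker"}
        assert (report["n_replicates"] == 100).all()
        assert (report["sd_hat"] >= 0).all()

    def test_h0_flag_consistent_with_pvalue(self):
        report = run_experiment(small_config(replicates=200))
        assert (report["h0_accepted"] == (report["ttest_p"] >= 0.05)).all()

    def test_deterministic_given_master_seed(self):
        a = run_experiment(small_config())
        b = run_experiment(small_config())
        pd.testing.assert_frame_equal(a, b)
        c = run_experiment(small_config(master_seed=43))
        assert not a["mean_hat"].equals(c["mean_hat"])

    def test_baselines_underestimate_stability_magnitude(self):
        """Regression, Yule-Walker and Burg all have clearly negative bias
        for 0 < lambda < 1 (stability is overestimated)."""
        report = run_experiment(
            small_config(
                n_grid=(20,),
                replicates=500,
                estimators=("regression", "yule_walker", "burg"),
            )
        )
        se = report["sd_hat"] / np.sqrt(report["n_replicates"])
        assert (report["bias"] < -3.0 * se).all()

    def test_bias_shrinks_with_series_length(self):
        """|bias| of the regression estimator decreases along the default
        length grid (one adjacent inversion tolerated at large n where the
        bias is within Monte-Carlo noise)."""
        report = run_experiment(
            small_config(
                n_grid=(10, 20, 50, 100, 200, 500, 1000),
                replicates=1000,
                estimators=("regression",),
            )
        )
        mags = report.sort_values("n")["bias"].abs().to_numpy()
        inversions = int(np.sum(np.diff(mags) >= 0))
        assert inversions <= 1

    def test_relative_bias_roughly_distribution_free(self):
        """At n = 10 the regression bias agrees across the three noise
        families to first order (within 8 percentage points of relative
        bias); the residual difference is a real second-order effect of the
        lognormal family's skewness."""
        report = run_experiment(
            small_config(
                noises=tuple(NoiseSpec(f, 1.0) for f in ("normal", "uniform", "lognormal")),
                replicates=4000,
                estimators=("regression",),
            )
        )
        rel = report.set_index("noise_family")["rel_bias_pct"]
        assert rel.max() - rel.min() < 8.0

    def test_estimator_bias_ordering(self):
        """|bias|: corrected < Yule-Walker < regression, at lambda = 0.75
        under normal noise for short-to-moderate records."""
        report = run_experiment(
            small_config(
                n_grid=(10, 20, 50, 100),
                replicates=1000,
                estimators=("regression", "yule_walker", "corrected"),
            )
        )
        by = report.pivot(index="n", columns="estimator", values="bias").abs()
        assert (by["corrected"] < by["yule_walker"]).all()
        assert (by["yule_walker"] < by["regression"]).all()

    def test_degenerate_noise_aborts(self):
        """An all-degenerate cell (sigma = 0) trips the 1% failure cap."""
        cfg = small_config(noises=(NoiseSpec("normal", 0.0),), replicates=100)
        with pytest.raises(RuntimeError):
            run_experiment(cfg)

    def test_invalid_configs(self):
        with pytest.raises(ParameterError):
            small_config(replicates=1)
        with pytest.raises(ParameterError):
            small_config(lambdas=(1.5,))
        with pytest.raises(ParameterError):
            small_config(estimators=("magic",))
        with pytest.raises(ParameterError):
            small_config(alpha=0.0)
        with pytest.raises(ParameterError):
            small_config(n_grid=(2,))


class TestMinUnbiasedN:
    @staticmethod
    def fake_report(accept_flags):
        ns = [10, 20, 50, 100]
        return pd.DataFrame(
            {
                "estimator": "corrected",
                "lam": 0.75,
                "n": ns,
                "noise_family": "normal",
                "h0_accepted": accept_flags,
            }
        )

    def test_all_accepted_gives_smallest(self):
        rep = self.fake_report([True, True, True, True])
        assert min_unbiased_n(rep, "corrected", 0.75, "normal") == 10

    def test_none_accepted_gives_none(self):
        rep = self.fake_report([False, False, False, False])
        assert min_unbiased_n(rep, "corrected", 0.75, "normal") is None

    def test_requires_acceptance_for_all_larger_n(self):
        rep = self.fake_report([True, False, True, True])
        assert min_unbiased_n(rep, "corrected", 0.75, "normal") == 50

    def test_last_rejection_gives_none(self):
        rep = self.fake_report([True, True, True, False])
        assert min_unbiased_n(rep, "corrected", 0.75, "normal") is None

    def test_missing_cells_raise(self):
        rep = self.fake_report([True] * 4)
        with pytest.raises(IncompleteReportError):
            min_unbiased_n(rep, "regression", 0.75, "normal")
        with pytest.raises(IncompleteReportError):
            min_unbiased_n(rep, "corrected", 0.75, "normal", n_grid=[10, 20, 500])


class TestCompareStitched:
    def test_single_segment_statistically_indistinguishable(self):
        """With one segment the two arms run the same generator, so the
        two-sample test sees only sampling noise."""
        out = compare_stitched(
            0.75, 100, 1, NoiseSpec("normal", 1.0), replicates=300, seed=42
        )
        assert out.attrs["two_sample_p"] > 0.01

    def test_stitching_inflates_bias(self):
        out = compare_stitched(
            0.75, 10, 20, NoiseSpec("normal", 1.0), replicates=400, seed=42
        )
        rows = out.set_index("series_type")
        assert abs(rows.loc["stitched", "bias"]) > abs(rows.loc["single", "bias"])
        assert out.attrs["abs_bias_diff"] > 0
        assert out.attrs["two_sample_p"] < 1e-6

    def test_boundary_exclusion_mode(self):
        """Identical seeds generate identical series in both modes, so the
        comparison is paired: dropping the uncorrelated boundary-spanning
        pairs removes part of the whitening and shrinks the bias."""
        naive = compare_stitched(
            0.75, 5, 40, NoiseSpec("normal", 1.0), replicates=400, seed=42
        )
        strict = compare_stitched(
            0.75,
            5,
            40,
            NoiseSpec("normal", 1.0),
            replicates=400,
            seed=42,
            include_boundary_pairs=False,
        )
        naive_rows = naive.set_index("series_type")
        strict_rows = strict.set_index("series_type")
        # the single-series arm is untouched by the mode switch
        assert strict_rows.loc["single", "mean_hat"] == naive_rows.loc["single", "mean_hat"]
        assert abs(strict_rows.loc["stitched", "bias"]) < abs(
            naive_rows.loc["stitched", "bias"]
        )

    def test_exclusion_only_for_regression(self):
        with pytest.raises(ParameterError):
            compare_stitched(
                0.75,
                10,
                5,
                NoiseSpec("normal", 1.0),
                replicates=10,
                seed=0,
                estimator="burg",
                include_boundary_pairs=False,
            )
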