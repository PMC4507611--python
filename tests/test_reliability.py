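"""Agreement statistics: one-way ICC, Cronbach's alpha, Bland-Altman.

The frozen expected values for the bundled validation dataset were computed
with an independent hand-rolled ANOVA decomposition (sums of squares over
the 10 x 2 duration matrix) before the implementation existed; pingouin
serves as a second, external oracle.
"""

import numpy as np
import pytest

from trunklab.reliability import (DegenerateDataError, PairedMeasurements,
                                  bland_altman, cronbach_alpha, icc_ci,
                                  icc_oneway, reliability_table,
                                  round_half_up)

# hand-ANOVA oracle values for the validation dataset (full precision)
EXPECTED = {
    "STEET": dict(icc_avg=0.9160, icc_single=0.8451, alpha=0.9160,
                  ci=(0.6827, 0.9788), ba_mean=-5.4),
    "TCSET": dict(icc_avg=0.8901, icc_single=0.8020, alpha=0.8798,
                  ci=(0.5848, 0.9723), ba_mean=2.4),
    "SBET right": dict(icc_avg=0.8385, icc_single=0.7218, alpha=0.8302,
                       ci=(0.3895, 0.9592), ba_mean=-2.5),
    "SBET left": dict(icc_avg=0.7512, icc_single=0.6016, alpha=0.7784,
                      ci=(0.0599, 0.9372), ba_mean=-5.3),
}


@pytest.fixture
def identical_columns():
    x = np.array([10.0, 20, 30, 40, 55])
    return PairedMeasurements.from_arrays(x, x.copy())


class TestIcc:
    @pytest.mark.parametrize("test", sorted(EXPECTED))
    def test_average_measures_against_anova_oracle(self, validation_study, test):
        assert icc_oneway(validation_study[test], "average") == pytest.approx(
            EXPECTED[test]["icc_avg"], abs=5e-4)

    @pytest.mark.parametrize("test", sorted(EXPECTED))
    def test_single_measures_against_anova_oracle(self, validation_study, test):
        assert icc_oneway(validation_study[test], "single") == pytest.approx(
            EXPECTED[test]["icc_single"], abs=5e-4)

    def test_identical_columns_give_unity(self, identical_columns):
        assert icc_oneway(identical_columns, "average") == 1.0
        assert icc_oneway(identical_columns, "single") == 1.0
        assert icc_ci(identical_columns, "average") == (1.0, 1.0)

    def test_constant_data_degenerate(self):
        pm = PairedMeasurements.from_arrays([5.0, 5, 5], [5.0, 5, 5])
        with pytest.raises(DegenerateDataError):
            icc_oneway(pm)

    @pytest.mark.parametrize("test", sorted(EXPECTED))
    def test_ci_bounds_against_exact_f_oracle(self, validation_study, test):
        lo, hi = icc_ci(validation_study[test], "average")
        exp_lo, exp_hi = EXPECTED[test]["ci"]
        assert lo == pytest.approx(exp_lo, abs=5e-4)
        assert hi == pytest.approx(exp_hi, abs=5e-4)

    def test_ci_brackets_estimate(self, validation_study):
        for pm in validation_study.values():
            for form in ("average", "single"):
                lo, hi = icc_ci(pm, form)
                assert lo <= icc_oneway(pm, form) <= hi <= 1.0

    def test_average_dominates_single_when_positive(self, rng):
        for _ in range(50):
            a = rng.normal(50, 15, 12)
            b = a + rng.normal(0, 8, 12)
            pm = PairedMeasurements.from_arrays(a, b)
            single = icc_oneway(pm, "single")
            if single > 0:
                assert icc_oneway(pm, "average") >= single

    def test_shift_and_scale_invariance(self, validation_study):
        pm = validation_study["STEET"]
        shifted = PairedMeasurements.from_arrays(pm.method_a + 100,
                                                 pm.method_b + 100)
        scaled = PairedMeasurements.from_arrays(pm.method_a * 3.5,
                                                pm.method_b * 3.5)
        for other in (shifted, scaled):
            assert icc_oneway(other) == pytest.approx(icc_oneway(pm), abs=1e-12)
            assert cronbach_alpha(other) == pytest.approx(cronbach_alpha(pm),
                                                          abs=1e-12)

    def test_against_pingouin(self, validation_study):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd
        pm = validation_study["STEET"]
        df = pd.DataFrame({
            "subject": list(pm.subjects) * 2,
            "rater": ["a"] * pm.n + ["b"] * pm.n,
            "y": np.concatenate([pm.method_a, pm.method_b]),
        })
        res = pingouin.intraclass_corr(df, targets="subject", raters="rater",
                                       ratings="y").set_index("Type")
        assert icc_oneway(pm, "single") == pytest.approx(
            res.loc["ICC(1,1)", "ICC"], abs=1e-9)
        assert icc_oneway(pm, "average") == pytest.approx(
            res.loc["ICC(1,k)", "ICC"], abs=1e-9)
        lo, hi = icc_ci(pm, "average")
        # pingouin reports the interval rounded to 2 dp
        assert [round_half_up(lo), round_half_up(hi)] == pytest.approx(
            list(res.loc["ICC(1,k)", "CI95"]))


class TestCronbachAlpha:
    @pytest.mark.parametrize("test", sorted(EXPECTED))
    def test_against_variance_oracle(self, validation_study, test):
        assert cronbach_alpha(validation_study[test]) == pytest.approx(
            EXPECTED[test]["alpha"], abs=5e-4)

    def test_identical_columns_give_unity(self, identical_columns):
        assert cronbach_alpha(identical_columns) == pytest.approx(1.0)

    def test_degenerate_sum_variance(self):
        pm = PairedMeasurements.from_arrays([1.0, 2, 3], [3.0, 2, 1])
        with pytest.raises(DegenerateDataError):
            cronbach_alpha(pm)


class TestBlandAltman:
    def test_identical_columns_zero_limits(self, identical_columns):
        r = bland_altman(identical_columns)
        assert r.mean_diff == r.loa_low == r.loa_high == 0.0

    def test_mean_difference_of_sorensen_durations(self, validation_study):
        r = bland_altman(validation_study["STEET"])
        assert r.mean_diff == pytest.approx(-5.4)
        assert r.loa_low <= r.mean_diff <= r.loa_high

    def test_coverage_of_simulated_normal_differences(self, rng):
        n = 10_000
        a = rng.normal(100, 1e-9, n)
        b = a - rng.normal(0, 7, n)  # differences ~ Normal(0, 7)
        r = bland_altman(PairedMeasurements.from_arrays(a, b))
        inside = np.mean((r.differences >= r.loa_low)
                         & (r.differences <= r.loa_high))
        assert inside == pytest.approx(0.95, abs=0.01)


class TestReliabilityTable:
    def test_validation_dataset_rounds_to_published_values(self, validation_study):
        table = reliability_table(validation_study)
        assert list(table["icc"]) == [0.92, 0.89, 0.84, 0.75]
        assert list(table["alpha"]) == [0.92, 0.88, 0.83, 0.78]
        assert list(table["icc_quality"]) == ["excellent"] * 4

    def test_permutation_invariance(self, validation_study, rng):
        pm = validation_study["TCSET"]
        perm = rng.permutation(pm.n)
        shuffled = PairedMeasurements.from_arrays(pm.method_a[perm],
                                                  pm.method_b[perm])
        assert icc_oneway(shuffled) == pytest.approx(icc_oneway(pm), abs=1e-12)
        assert cronbach_alpha(shuffled) == pytest.approx(cronbach_alpha(pm),
                                                         abs=1e-12)

    def test_method_swap_symmetry(self, validation_study):
        pm = validation_study["SBET right"]
        swapped = PairedMeasurements.from_arrays(pm.method_b, pm.method_a)
        assert icc_oneway(swapped) == pytest.approx(icc_oneway(pm), abs=1e-12)
        assert cronbach_alpha(swapped) == pytest.approx(cronbach_alpha(pm),
                                                        abs=1e-12)
        assert bland_altman(swapped).mean_diff == pytest.approx(
            -bland_altman(pm).mean_diff)


def test_round_half_up_at_boundary():
    assert round_half_up(0.845) == 0.85
    assert round_half_up(0.5848, 3) == 0.585
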