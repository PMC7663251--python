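"""Agreement, diagnostic and error-distribution statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pelviscreen import (
    ContingencyTable,
    PairedMeasures,
    bland_altman,
    bland_altman_from_summary,
    build_contingency,
    correlation,
    diagnostic_metrics,
    error_distribution,
)


def pairs_of(device, reference, position="flexed_seated"):
    device = np.asarray(device, float)
    return PairedMeasures(device, np.asarray(reference, float),
                          np.full(device.size, position, dtype=object))


class TestBlandAltman:
    def test_identical_vectors(self):
        ba = bland_altman(pairs_of([1, 2, 3], [1, 2, 3]))
        assert ba.bias_deg == 0 and ba.sd_deg == 0
        assert ba.upper_loa_deg == 0 and ba.lower_loa_deg == 0

    def test_published_step_up_worked_example(self):
        # bias 0.06, SD 2.74 -> upper limit of agreement 5.43 at k=1.96
        ba = bland_altman_from_summary(0.06, 2.74, k=1.96)
        assert round(ba.upper_loa_deg, 2) == 5.43

    def test_matches_direct_formula(self, rng):
        dev = rng.normal(0, 10, 40)
        ref = dev + rng.normal(1.5, 3, 40)
        ba = bland_altman(pairs_of(dev, ref))
        diff = dev - ref
        assert ba.bias_deg == pytest.approx(diff.mean())
        assert ba.sd_deg == pytest.approx(diff.std(ddof=1))
        assert ba.upper_loa_deg == pytest.approx(diff.mean() + 1.96 * diff.std(ddof=1))
        np.testing.assert_allclose(ba.differences, diff)
        np.testing.assert_allclose(ba.means, (dev + ref) / 2)

    def test_loa_span_is_2k_sd(self, rng):
        dev, ref = rng.normal(0, 5, 20), rng.normal(0, 5, 20)
        for k in (1.0, 1.96, 2.5):
            ba = bland_altman(pairs_of(dev, ref), k=k)
            assert ba.upper_loa_deg - ba.lower_loa_deg == pytest.approx(2 * k * ba.sd_deg)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            bland_altman(pairs_of([1.0], [2.0]))


class TestDiagnosticMetrics:
    def test_published_contingency_table(self):
        m = diagnostic_metrics(ContingencyTable(tp=11, fn=2, fp=1, tn=19))
        assert round(100 * m["sensitivity"], 1) == 84.6
        assert round(100 * m["specificity"], 1) == 95.0
        assert round(100 * m["accuracy"], 1) == 90.9

    def test_perfect_classifier(self):
        m = diagnostic_metrics(ContingencyTable(tp=1, fn=0, fp=0, tn=1))
        assert m == {"sensitivity": 1.0, "specificity": 1.0, "accuracy": 1.0}

    @settings(deadline=None, derandomize=True)
    @given(
        tp=st.integers(0, 30), fn=st.integers(0, 30),
        fp=st.integers(0, 30), tn=st.integers(0, 30),
        scale=st.integers(1, 9),
    )
    def test_matches_count_arithmetic_and_scale_invariance(self, tp, fn, fp, tn, scale):
        if tp + fn + fp + tn == 0:
            return
        m = diagnostic_metrics(ContingencyTable(tp, fn, fp, tn))
        ms = diagnostic_metrics(ContingencyTable(scale * tp, scale * fn, scale * fp, scale * tn))
        for key, num, den in (
            ("sensitivity", tp, tp + fn),
            ("specificity", tn, tn + fp),
            ("accuracy", tp + tn, tp + tn + fp + fn),
        ):
            if den == 0:
                assert math.isnan(m[key]) and math.isnan(ms[key])
            else:
                assert m[key] == pytest.approx(num / den)
                assert ms[key] == pytest.approx(m[key])

    def test_zero_denominator_is_undefined_not_zero(self):
        m = diagnostic_metrics(ContingencyTable(tp=3, fn=1, fp=0, tn=0))
        assert math.isnan(m["specificity"])
        assert m["sensitivity"] == pytest.approx(0.75)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            ContingencyTable(tp=-1, fn=0, fp=0, tn=0)


class TestBuildContingency:
    def test_perfect_agreement_has_no_errors(self):
        deltas = [-20.0, -5.0, 0.0, 14.0, 30.0]
        table = build_contingency(pairs_of(deltas, deltas))
        assert table.fp == 0 and table.fn == 0
        assert table.tp == 3 and table.tn == 2  # |−20|,|14|,|30| ≥ 13

    def test_boundary_bookkeeping(self):
        table = build_contingency(pairs_of([12.0], [14.0]))
        assert (table.tp, table.fn, table.fp, table.tn) == (0, 1, 0, 0)

    def test_posterior_changes_count_in_absolute_mode(self):
        table = build_contingency(pairs_of([-14.0], [-15.0]))
        assert table.tp == 1
        signed = build_contingency(pairs_of([-14.0], [-15.0]), signed=True)
        assert signed.tn == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no paired"):
            build_contingency(pairs_of([], []))


class TestCorrelation:
    def test_perfect_linear_agreement(self):
        p = pairs_of([1, 2, 3, 4], [10, 20, 30, 40])
        for method in ("spearman", "pearson"):
            res = correlation(p, method)
            assert res["coefficient"] == pytest.approx(1.0)
            assert res["r_squared"] == pytest.approx(1.0)

    def test_reversed_ranks(self):
        res = correlation(pairs_of([1, 2, 3, 4], [8, 6, 4, 2]), "spearman")
        assert res["coefficient"] == pytest.approx(-1.0)

    def test_matches_rank_formula(self):
        # hand-built vector, no ties: rho = 1 - 6*sum(d^2)/(n(n^2-1))
        dev = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0])
        ref = np.array([2.0, 0.5, 7.0, 1.0, 3.0, 8.0])
        from scipy.stats import rankdata
        d = rankdata(dev) - rankdata(ref)
        rho = 1 - 6 * np.sum(d**2) / (len(dev) * (len(dev) ** 2 - 1))
        assert correlation(pairs_of(dev, ref))["coefficient"] == pytest.approx(rho)

    def test_spearman_invariant_under_monotone_transform(self, rng):
        dev = rng.normal(0, 10, 25)
        ref = dev + rng.normal(0, 5, 25)
        base = correlation(pairs_of(dev, ref))["coefficient"]
        warped = correlation(pairs_of(np.exp(dev / 10), ref**3))["coefficient"]
        assert warped == pytest.approx(base)

    def test_constant_vector_flagged_undefined(self):
        res = correlation(pairs_of([1, 1, 1], [1, 2, 3]))
        assert math.isnan(res["coefficient"])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            correlation(pairs_of([1, 2], [1, 2]))


class TestErrorDistribution:
    def test_all_zero_errors(self):
        d = error_distribution(pairs_of([1, 2, 3], [1, 2, 3]))
        assert d["median"] == 0 and d["q3"] == 0
        assert d["poisson_lambda_mle"] == 0

    def test_hand_computed_quantiles(self):
        # |errors| = {1,1,2,4}: median 1.5; Q3 under linear interpolation
        # = 2 + 0.25*(4-2) = 2.5; Poisson MLE = mean = 2.0
        d = error_distribution(pairs_of([1, 1, 2, 4], [0, 0, 0, 0]))
        assert d["median"] == pytest.approx(1.5)
        assert d["q3"] == pytest.approx(2.5)
        assert d["poisson_lambda_mle"] == pytest.approx(2.0)
        assert d["histogram_counts"] == [0, 2, 1, 0, 1]

    def test_pools_positions_and_uses_absolute_errors(self):
        p = PairedMeasures(
            np.array([5.0, -5.0]), np.array([3.0, -1.0]),
            np.array(["flexed_seated", "step_up"], object),
        )
        d = error_distribution(p)
        assert d["n"] == 2
        assert d["median"] == pytest.approx(3.0)  # errors {2, 4}


class TestPairedMeasures:
    def test_missing_pairs_dropped(self):
        p = PairedMeasures(
            np.array([1.0, np.nan, 3.0]), np.array([1.0, 2.0, np.nan]),
            np.array(["flexed_seated"] * 3, object),
        )
        assert len(p) == 1

    def test_frame_round_trip(self):
        p = pairs_of([1.5, -2.0], [1.0, -2.5])
        back = PairedMeasures.from_frame(p.to_frame())
        np.testing.assert_allclose(back.device_delta_deg, p.device_delta_deg)

    def test_missing_columns_named(self):
        import pandas as pd
        with pytest.raises(ValueError, match="reference_delta_deg"):
            PairedMeasures.from_frame(pd.DataFrame({"device_delta_deg": [1.0]}))
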