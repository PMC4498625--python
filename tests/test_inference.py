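"""Bootstrap p-value, percentile CI, bin assignment, per-gene/dataset drivers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phaseboot import (
    UNASSIGNED,
    DegenerateSeriesError,
    ExpressionSeries,
    MebootParams,
    analyze_dataset,
    analyze_gene,
    assign_phase,
    bootstrap_pvalue,
    percentile_ci,
    phase_bins,
)
from phaseboot.inference import _percentile_indices


def tau_vector(n_exceed, R, tau_hat=0.5):
    """Replicate statistics with exactly ``n_exceed`` strictly above tau_hat."""
    return np.concatenate([np.full(n_exceed, tau_hat + 0.2),
                           np.full(R - n_exceed, tau_hat - 0.2)])


class TestBootstrapPvalue:
    def test_worked_example_73_of_999(self):
        assert bootstrap_pvalue(0.5, tau_vector(73, 999)) == 0.074

    def test_bounds(self):
        assert bootstrap_pvalue(0.5, tau_vector(0, 999)) == 0.001
        assert bootstrap_pvalue(0.5, tau_vector(999, 999)) == 1.0

    def test_ties_do_not_count(self):
        # strict inequality as printed: equal values are not exceedances
        assert bootstrap_pvalue(0.5, np.full(9, 0.5)) == 0.1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_pvalue(0.5, np.array([]))

    @given(st.integers(0, 99))
    def test_monotone_in_exceedances(self, e):
        assert bootstrap_pvalue(0.5, tau_vector(e, 100)) <= bootstrap_pvalue(
            0.5, tau_vector(min(e + 1, 100), 100))

    @given(st.lists(st.floats(-1, 1), min_size=1, max_size=200),
           st.floats(-1, 1))
    def test_always_in_unit_interval(self, taus, tau_hat):
        p = bootstrap_pvalue(tau_hat, np.array(taus))
        R = len(taus)
        assert 1 / (R + 1) <= p <= 1.0


def naive_percentile_ci(theta_star, alpha):
    """Brute-force sort-and-index oracle implementing the stated rule."""
    s = sorted(theta_star)
    R = len(s)
    r_alpha = R * alpha
    if abs(r_alpha - round(r_alpha)) < 1e-9:
        lo, hi = int(round(r_alpha)), int(round(R * (1 - alpha)))
    else:
        lo = int((R + 1) * alpha + 1e-9)
        hi = R + 1 - lo
    return s[lo - 1], s[hi - 1]


class TestPercentileCI:
    def test_999_at_2p5_percent_picks_25th_and_975th(self):
        assert _percentile_indices(999, 0.025) == (25, 975)
        theta = np.arange(1.0, 1000.0)  # value v is the v-th order statistic
        assert percentile_ci(theta, 0.025) == (25.0, 975.0)

    def test_integer_branch(self):
        # R*alpha integer: 1000 * 0.025 = 25 exactly
        assert _percentile_indices(1000, 0.025) == (25, 975)

    def test_degenerate_distribution(self):
        assert percentile_ci(np.full(999, 8.0), 0.025) == (8.0, 8.0)

    def test_small_R_against_enumeration(self):
        # R = 9, alpha = 0.1: k = floor(10 * 0.1) = 1 -> (1st, 9th)
        theta = np.array([5.0, 1.0, 3.0, 9.0, 7.0, 2.0, 8.0, 4.0, 6.0])
        assert percentile_ci(theta, 0.1) == (1.0, 9.0)
        assert percentile_ci(theta, 0.1) == naive_percentile_ci(theta, 0.1)

    def test_alpha_validation(self):
        for bad in (0.0, 0.5, -0.1, 0.7):
            with pytest.raises(ValueError):
                percentile_ci(np.arange(100.0), bad)
        with pytest.raises(ValueError, match="too small"):
            percentile_ci(np.arange(5.0), 0.01)

    @given(st.integers(0, 2**31 - 1), st.sampled_from([99, 199, 500, 999]),
           st.sampled_from([0.01, 0.025, 0.05, 0.1]))
    def test_matches_naive_oracle(self, seed, R, alpha):
        rng = np.random.default_rng(seed)
        theta = rng.normal(size=R)
        assert percentile_ci(theta, alpha) == naive_percentile_ci(theta, alpha)

    @given(st.integers(0, 2**31 - 1))
    def test_widening_alpha_narrows_ci(self, seed):
        rng = np.random.default_rng(seed)
        theta = rng.normal(size=999)
        lo1, hi1 = percentile_ci(theta, 0.01)
        lo2, hi2 = percentile_ci(theta, 0.05)
        assert lo1 <= lo2 and hi2 <= hi1


class TestAssignPhase:
    @pytest.fixture(scope="class")
    @staticmethod
    def bins():
        return phase_bins(24.0, 3)

    @pytest.mark.parametrize("ci,theta,expected", [
        ((8, 8), 8, "G2"),       # point CI at bin center, G2 = [6, 10]
        ((0, 0), 0, "G0"),       # bin straddling zero
        ((4, 8), 8, UNASSIGNED),  # spans G1/G2 boundary
        ((7, 9), 8, "G2"),
        ((18, 22), 20, "G5"),
        ((-2, 2), 0, "G0"),
        ((0, 8), 4, UNASSIGNED),
    ])
    def test_containment_rule(self, bins, ci, theta, expected):
        assert assign_phase(ci, bins, theta) == expected

    def test_circular_wrap_of_first_bin(self):
        """With a fine template grid a CI like [23.6, 0.4] wraps into G0."""
        fine_bins = phase_bins(24.0, 15)  # width 0.8, G0 = [-0.4, 0.4]
        assert assign_phase((23.8, 24.2), fine_bins, 0.0) == "G0"
        assert assign_phase((23.9, 23.95), fine_bins, 23.9) == "G0"
        # wide wrapped interval does not sneak in
        assert assign_phase((12.0, 20.0), fine_bins, 16.0) == UNASSIGNED
        # documented limitation: a linear CI spanning the whole day from a
        # wrapped bootstrap sample stays unassigned
        assert assign_phase((0.0, 23.6), fine_bins, 0.0) == UNASSIGNED

    def test_shared_boundary_tiebreak_uses_theta_hat(self, bins):
        # [6, 6] sits on the G1|G2 boundary: theta_hat decides
        assert assign_phase((6, 6), bins, 8.0) == "G2"
        assert assign_phase((6, 6), bins, 4.0) == "G1"
        # theta_hat itself ambiguous -> lowest bin index
        assert assign_phase((6, 6), bins, 6.0) == "G1"

    def test_invalid_interval(self, bins):
        with pytest.raises(ValueError):
            assign_phase((5, 3), bins, 4.0)


class TestAnalyzeGene:
    def test_noise_free_cosine_assigned_G2(self, cosine_series):
        """End-to-end: 2 + cos(2*pi*t/24 - 2*pi/3) peaks at 8 h -> G2."""
        result = analyze_gene(cosine_series(peak_hour=8.0),
                              params=MebootParams(n_replicates=99, seed=1),
                              alpha=0.05)
        assert result.estimate.theta_hat == 8.0
        assert result.is_circadian
        assert result.assigned_bin == "G2"
        assert result.p_value == pytest.approx(1 / 100)

    def test_reproducible_given_seed(self, cosine_series):
        series = cosine_series(peak_hour=4.0, amplitude=0.5)
        kwargs = dict(params=MebootParams(n_replicates=199, seed=11), alpha=0.05)
        r1, r2 = analyze_gene(series, **kwargs), analyze_gene(series, **kwargs)
        assert r1.to_record() == r2.to_record()

    def test_ci_endpoints_lie_on_peak_grid(self, cosine_series, timepoints):
        rng = np.random.default_rng(8)
        series = ExpressionSeries("g", cosine_series(12.0).values
                                  + rng.normal(0, 0.5, 12), timepoints)
        result = analyze_gene(series, params=MebootParams(n_replicates=199, seed=8))
        grid = {0.0, 4.0, 8.0, 12.0, 16.0, 20.0}
        assert result.ci_lower in grid and result.ci_upper in grid
        assert result.ci_lower <= result.ci_upper

    def test_pvalue_bounds_invariant(self, cosine_series):
        result = analyze_gene(cosine_series(), params=MebootParams(99, seed=2))
        assert 1 / 100 <= result.p_value <= 1.0

    def test_degenerate_series_raises(self, timepoints):
        series = ExpressionSeries("flat", np.full(12, 2.0), timepoints)
        with pytest.raises(DegenerateSeriesError):
            analyze_gene(series, params=MebootParams(9, seed=0))

    def test_not_circadian_still_reports_ci(self, timepoints):
        rng = np.random.default_rng(14)
        # pure noise: CI computed and reported, bin withheld unless circadian
        series = ExpressionSeries("n", rng.normal(size=12), timepoints)
        result = analyze_gene(series, params=MebootParams(n_replicates=199, seed=3))
        assert np.isfinite(result.ci_lower) and np.isfinite(result.ci_upper)
        if not result.is_circadian:
            assert result.assigned_bin == UNASSIGNED


class TestAnalyzeDataset:
    @pytest.fixture(scope="class")
    @staticmethod
    def small_matrix():
        from phaseboot import SyntheticSpec, generate_matrix

        spec = SyntheticSpec(n_genes=20, fraction_rhythmic=0.5, amplitude=3.0,
                             noise_sd=0.05, peak_hours=(8.0,), seed=21)
        return generate_matrix(spec)

    def test_high_snr_cosines_bin_to_G2(self, small_matrix):
        matrix, truth = small_matrix
        results, summary = analyze_dataset(matrix, n_replicates=199, seed=21)
        rhythmic = results[results.gene_id.str.startswith("cos")]
        assert (rhythmic.assigned_bin == "G2").mean() >= 0.9
        assert summary.bin_counts["G2"] >= 9

    def test_row_order_invariance(self, small_matrix):
        matrix, _ = small_matrix
        shuffled = matrix.sample(frac=1.0, random_state=0)
        r1, s1 = analyze_dataset(matrix, n_replicates=99, seed=5)
        r2, s2 = analyze_dataset(shuffled, n_replicates=99, seed=5)
        assert s1.bin_counts == s2.bin_counts
        merged = r1.merge(r2, on="gene_id", suffixes=("_a", "_b"))
        assert (merged.p_value_a == merged.p_value_b).all()
        assert (merged.assigned_bin_a == merged.assigned_bin_b).all()

    def test_subset_matches_full_run(self, small_matrix):
        matrix, _ = small_matrix
        full, _ = analyze_dataset(matrix, n_replicates=99, seed=5)
        sub, _ = analyze_dataset(matrix, n_replicates=99, seed=5,
                                 genes=["cos_0003", "noise_0015"])
        merged = sub.merge(full, on="gene_id", suffixes=("_s", "_f"))
        assert len(merged) == 2
        assert (merged.p_value_s == merged.p_value_f).all()

    def test_degenerate_row_excluded_and_logged(self, small_matrix, caplog):
        matrix, _ = small_matrix
        matrix = pd.concat([matrix, pd.DataFrame(
            [np.zeros(12)], index=pd.Index(["flatgene"], name="gene_id"),
            columns=matrix.columns)])
        with caplog.at_level("WARNING"):
            results, summary = analyze_dataset(matrix, n_replicates=49, seed=5)
        assert summary.n_skipped == 1
        row = results[results.gene_id == "flatgene"].iloc[0]
        assert row.status.startswith("failed") and not row.is_circadian
        assert "flatgene" in caplog.text
        # totals unaffected by the degenerate row
        assert summary.total_circadian == int(results.is_circadian.sum())

    def test_percentages_recompute_from_counts(self):
        from phaseboot.inference import DatasetSummary

        # the reported convention: share of the circadian total, e.g. a bin
        # holding 223 of 646 circadian genes is 34.52%
        summary = DatasetSummary(
            bin_counts={"G0": 28, "G1": 47, "G2": 223, "G3": 128, "G4": 117,
                        "G5": 103},
            total_circadian=646, n_genes=22000, n_skipped=0, alpha=0.05,
            ci_alpha=0.025, n_replicates=999, k=3, period_T=24.0, seed=0)
        assert summary.percentages["G2"] == pytest.approx(34.52, abs=0.005)
        assert summary.total_assigned == 646
        frame = summary.to_frame()
        assert list(frame.phase) == [f"G{i}" for i in range(6)] + ["Total"]
        assert frame.n_genes.iloc[-1] == 646

    def test_bh_flag_adds_qvalues(self, small_matrix):
        matrix, _ = small_matrix
        results, _ = analyze_dataset(matrix, n_replicates=99, seed=5, bh=True)
        assert "q_value" in results.columns
        ok = results.status == "ok"
        assert (results.loc[ok, "q_value"] >= results.loc[ok, "p_value"] - 1e-12).all()

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            analyze_dataset(pd.DataFrame(np.empty((0, 12))))
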