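"""Ratio histogram, Gaussian fit, QC and score normalization."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import precisionif as pf
from precisionif.scoring import QCStatus, _gauss


def _meas(pairs):
    return [
        pf.TileMeasurement(tile_id=(i, 0), ck_mean=ck, her2_mean=h,
                           roi_area=100, valid=True)
        for i, (h, ck) in enumerate(pairs)
    ]


class TestRatioPerTile:
    def test_elementwise_ratio(self):
        ratios = pf.ratio_per_tile(_meas([(0.3, 0.6), (0.5, 0.5), (0.2, 0.8)]))
        np.testing.assert_allclose(ratios, [0.5, 1.0, 0.25])

    def test_common_staining_factor_cancels(self):
        base = [(0.3, 0.6), (0.4, 0.5), (0.2, 0.8)]
        scaled = [(2.0 * h, 2.0 * ck) for h, ck in base]
        np.testing.assert_array_equal(
            pf.ratio_per_tile(_meas(base)), pf.ratio_per_tile(_meas(scaled)))

    def test_nonpositive_ck_is_a_contract_violation(self):
        with pytest.raises(pf.PrecisionIFError):
            pf.ratio_per_tile(_meas([(0.3, 0.0)]))


class TestBuildHistogram:
    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(0)
        hist = pf.build_histogram(rng.normal(0.6, 0.1, 500))
        assert hist.frequencies.sum() == pytest.approx(1.0)

    def test_identical_ratios_single_occupied_bin(self):
        hist = pf.build_histogram([0.5] * 100)
        assert np.count_nonzero(hist.frequencies) == 1
        assert hist.frequencies.max() == pytest.approx(1.0)

    def test_mode_near_true_mean_for_normal_sample(self):
        rng = np.random.default_rng(1)
        hist = pf.build_histogram(rng.normal(0.6, 0.1, 5000))
        width = hist.bin_edges[1] - hist.bin_edges[0]
        mode = hist.bin_centers[np.argmax(hist.frequencies)]
        assert abs(mode - 0.6) <= max(width, 0.02)

    def test_too_few_ratios_unscorable(self):
        with pytest.raises(pf.UnscorableCaseError):
            pf.build_histogram([0.5] * 5)

    @given(st.integers(0, 2**31 - 1))
    def test_batch_upper_bound_preserves_normalization(self, seed):
        rng = np.random.default_rng(seed)
        ratios = rng.gamma(4.0, 0.2, 80)
        hist = pf.build_histogram(ratios, upper=float(ratios.max()) * 2)
        assert hist.frequencies.sum() == pytest.approx(1.0)


class TestFitGaussian:
    def test_recovers_sample_moments_of_large_normal_sample(self):
        rng = np.random.default_rng(2)
        draws = rng.normal(0.6, 0.1, 10_000)
        hist = pf.build_histogram(draws)
        fit = pf.fit_gaussian(hist)
        assert fit.converged
        assert fit.mu == pytest.approx(draws.mean(), abs=0.01)
        assert fit.sigma == pytest.approx(draws.std(), abs=0.01)

    def test_perfectly_gaussian_frequencies_fit_tightly(self):
        edges = np.linspace(0.0, 1.2, 61)
        centers = 0.5 * (edges[:-1] + edges[1:])
        freq = _gauss(centers, 1.0, 0.6, 0.1)
        freq /= freq.sum()
        hist = pf.RatioHistogram(bin_edges=edges, frequencies=freq, n_tiles=1000)
        fit = pf.fit_gaussian(hist)
        assert fit.adj_r2 > 0.99
        assert fit.mu == pytest.approx(0.6, abs=1e-3)
        assert fit.sigma == pytest.approx(0.1, abs=1e-3)

    def test_flat_histogram_fails_r2_qc(self):
        rng = np.random.default_rng(3)
        hist = pf.build_histogram(rng.uniform(0.0, 1.0, 500))
        fit = pf.fit_gaussian(hist)
        assert fit.adj_r2 < 0.5
        assert pf.qc_case(fit) == QCStatus.EXCLUDED_LOW_R2

    def test_mu_tracks_sample_mean_for_unimodal_case(self):
        rng = np.random.default_rng(4)
        ratios = rng.normal(0.8, 0.12, 200)
        fit = pf.fit_gaussian(pf.build_histogram(ratios))
        assert fit.mu == pytest.approx(ratios.mean(), rel=0.02)

    def test_too_few_occupied_bins_unscorable(self):
        edges = np.linspace(0.0, 1.0, 51)
        freq = np.zeros(50)
        freq[10] = 0.5
        freq[11] = 0.5
        hist = pf.RatioHistogram(bin_edges=edges, frequencies=freq, n_tiles=100)
        with pytest.raises(pf.UnscorableCaseError):
            pf.fit_gaussian(hist)


class TestScores:
    def test_control_scored_against_itself_is_unity(self):
        fit = pf.GaussianFit(mu=0.9, sigma=0.2, amplitude=0.1,
                             adj_r2=0.95, converged=True)
        s = pf.score_case(fit, fit)
        assert (s.m_score, s.sigma_score, s.mtp_score) == (1.0, 1.0, 1.0)

    def test_product_definition(self):
        pos = pf.GaussianFit(mu=1.0, sigma=0.5, amplitude=0.1,
                             adj_r2=0.95, converged=True)
        case = pf.GaussianFit(mu=0.9, sigma=0.6, amplitude=0.1,
                              adj_r2=0.95, converged=True)
        s = pf.score_case(case, pos)
        assert s.m_score == pytest.approx(0.9)
        assert s.sigma_score == pytest.approx(1.2)
        assert s.mtp_score == pytest.approx(1.08)

    @given(st.floats(0.01, 10.0), st.floats(0.01, 5.0),
           st.floats(0.1, 10.0), st.floats(0.01, 5.0))
    def test_mtp_is_exactly_the_product(self, mu, sigma, mu_pos, sigma_pos):
        pos = pf.GaussianFit(mu=mu_pos, sigma=sigma_pos, amplitude=0.1,
                             adj_r2=0.9, converged=True)
        case = pf.GaussianFit(mu=mu, sigma=sigma, amplitude=0.1,
                              adj_r2=0.9, converged=True)
        s = pf.score_case(case, pos)
        assert s.mtp_score == s.m_score * s.sigma_score

    def test_failed_control_fit_rejected(self):
        bad = pf.GaussianFit(mu=float("nan"), sigma=float("nan"),
                             amplitude=float("nan"), adj_r2=float("nan"),
                             converged=False)
        good = pf.GaussianFit(mu=1.0, sigma=0.2, amplitude=0.1,
                              adj_r2=0.9, converged=True)
        with pytest.raises(pf.PrecisionIFError):
            pf.score_case(good, bad)


class TestQC:
    @pytest.mark.parametrize("adj_r2,expected", [
        (0.4837, QCStatus.EXCLUDED_LOW_R2),
        (0.4806, QCStatus.EXCLUDED_LOW_R2),
        (0.95, QCStatus.PASS),
        (0.5, QCStatus.PASS),
    ])
    def test_r2_cutoff(self, adj_r2, expected):
        fit = pf.GaussianFit(mu=0.6, sigma=0.1, amplitude=0.1,
                             adj_r2=adj_r2, converged=True)
        assert pf.qc_case(fit) == expected

    def test_non_convergence_status(self):
        fit = pf.GaussianFit(mu=float("nan"), sigma=float("nan"),
                             amplitude=float("nan"), adj_r2=float("nan"),
                             converged=False)
        assert pf.qc_case(fit) == QCStatus.EXCLUDED_NO_CONVERGENCE
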