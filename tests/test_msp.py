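import numpy as np
import pytest

from pymsp import msp, templates
from pymsp.exceptions import (
    DegenerateSpectrumError,
    DomainError,
    FormatError,
    InsufficientLimbError,
)

from conftest import (
    MERGED_GRID, OUTWARD_GRID, RETURN_GRID,
    merged_template, template_record, template_scans,
)


class TestSpectralScan:
    def test_direction_grid_validation(self):
        with pytest.raises(FormatError):
            msp.SpectralScan(RETURN_GRID, np.zeros(len(RETURN_GRID)), "outward")
        with pytest.raises(FormatError):
            msp.SpectralScan(np.array([350.0, 353.0]), np.zeros(2), "return")

    def test_length_mismatch(self):
        with pytest.raises(FormatError):
            msp.SpectralScan(RETURN_GRID, np.zeros(3), "return")


class TestMergeScans:
    def test_constant_scans_merge_to_constant(self):
        out = msp.SpectralScan(OUTWARD_GRID, np.full(len(OUTWARD_GRID), 0.02), "outward")
        ret = msp.SpectralScan(RETURN_GRID, np.full(len(RETURN_GRID), 0.02), "return")
        merged = msp.merge_scans(out, ret)
        assert np.allclose(merged.mean_absorbance, 0.02)

    def test_linear_function_merges_to_midpoint_values(self):
        f = lambda w: 1e-4 * w + 0.003
        out = msp.SpectralScan(OUTWARD_GRID, f(OUTWARD_GRID), "outward")
        ret = msp.SpectralScan(RETURN_GRID, f(RETURN_GRID), "return")
        merged = msp.merge_scans(out, ret)
        assert np.allclose(merged.mean_absorbance, f(merged.wavelengths),
                           atol=1e-12)

    def test_pair_count_201_plus_200_gives_200(self):
        # oracle: enumerate the two grids and count adjacent (w-1, w) pairs
        outward_set = set(OUTWARD_GRID.tolist())
        expected = sum(1 for w in RETURN_GRID if (w - 1.0) in outward_set)
        assert expected == 200
        out = msp.SpectralScan(OUTWARD_GRID, np.zeros(201), "outward")
        ret = msp.SpectralScan(RETURN_GRID, np.zeros(200), "return")
        merged = msp.merge_scans(out, ret)
        assert len(merged.wavelengths) == 200
        assert np.allclose(merged.wavelengths, MERGED_GRID)

    def test_non_interleaving_grids_rejected_with_wavelengths(self):
        out = msp.SpectralScan(OUTWARD_GRID + 0.5, np.zeros(201), "outward")
        ret = msp.SpectralScan(RETURN_GRID, np.zeros(200), "return")
        with pytest.raises(FormatError, match="interleave"):
            msp.merge_scans(out, ret)


class TestNormalize:
    def test_affine_template_construction(self):
        merged = merged_template(500.0, density=0.02, baseline=0.005)
        assert merged.transverse_density == pytest.approx(0.02, rel=1e-3)
        assert merged.fractional.max() == pytest.approx(1.0, abs=1e-3)
        assert merged.baseline == pytest.approx(0.005, abs=1e-6)

    def test_flat_spectrum_is_degenerate(self):
        out = msp.SpectralScan(OUTWARD_GRID, np.full(201, 0.01), "outward")
        ret = msp.SpectralScan(RETURN_GRID, np.full(200, 0.01), "return")
        with pytest.raises(DegenerateSpectrumError):
            msp.normalize(msp.merge_scans(out, ret))

    def test_fractional_reproduces_template_noise_free(self):
        # built directly on the merged grid (pair-averaging real scans adds
        # an O(h^2) curvature error ~6e-5, so the exact round trip is a
        # property of normalize itself); lambda_max on-grid so the sampled
        # peak is exactly 1
        lm = 500.5
        expected = templates.pigment_absorbance(lm, MERGED_GRID)
        raw = msp.MergedSpectrum(MERGED_GRID, 0.02 * expected + 0.005)
        merged = msp.normalize(raw, peak_smoothing=None)
        assert np.allclose(merged.fractional, expected, atol=1e-6)
        assert merged.fractional.max() == pytest.approx(1.0, abs=1e-9)

    def test_baseline_window_outside_coverage(self):
        merged = merged_template(500.0)
        raw = msp.MergedSpectrum(merged.wavelengths, merged.mean_absorbance)
        with pytest.raises(DomainError):
            msp.normalize(raw, baseline_window=(900.0, 950.0))


class TestEstimatePrimary:
    def test_noise_free_recovery(self):
        merged = merged_template(563.2)
        lam, sd, n = msp.estimate_primary(merged)
        assert lam == pytest.approx(563.2, abs=0.05)
        assert sd < 0.05
        assert n == 20

    def test_truncated_limb_errors(self):
        # spectrum cut just long of the peak: no usable limb
        merged = merged_template(563.2)
        cut = merged.wavelengths < 575.0
        trunc = msp.MergedSpectrum(
            merged.wavelengths[cut], merged.mean_absorbance[cut],
            merged.baseline, merged.fractional[cut],
            merged.transverse_density, merged.smoothed_fractional[cut])
        with pytest.raises(InsufficientLimbError):
            msp.estimate_primary(trunc)

    def test_requires_normalization(self):
        raw = msp.MergedSpectrum(MERGED_GRID, np.zeros(len(MERGED_GRID)))
        with pytest.raises(DomainError):
            msp.estimate_primary(raw)


class TestEstimateSecondary:
    def test_noise_free_recovery(self):
        merged = merged_template(563.2)
        lam, n = msp.estimate_secondary(merged)
        assert lam == pytest.approx(563.2, abs=0.5)
        assert n == 50

    def test_primary_secondary_agree_noise_free(self):
        merged = merged_template(505.0)
        p, _, _ = msp.estimate_primary(merged)
        s, _ = msp.estimate_secondary(merged)
        assert abs(p - s) < 0.5

    def test_secondary_sampling_distribution(self, rng):
        # Monte-Carlo comparison with the primary estimator.  Despite using
        # more points, the peak-centred estimate is measurably NOISIER than
        # the limb estimate (points at/near the peak amplify absorbance
        # noise); both must stay unbiased and the variance ratio bounded.
        prim, sec = [], []
        for _ in range(60):
            merged = merged_template(505.0, noise_sd=0.002, rng=rng)
            merged = msp.refine_normalization(
                merged, msp.estimate_primary(merged)[0])
            prim.append(msp.estimate_primary(merged)[0])
            sec.append(msp.estimate_secondary(merged)[0])
        assert abs(np.mean(prim) - 505.0) < 0.6
        assert abs(np.mean(sec) - 505.0) < 0.8
        assert np.var(sec) <= 4.0 * np.var(prim)


class TestCheckBleach:
    def _pre(self):
        return merged_template(505.0)

    def _post_scan(self, values):
        return msp.SpectralScan(RETURN_GRID, values, "return")

    def test_proper_bleach_is_true(self):
        pre = self._pre()
        bump = 0.006 * np.exp(-(((RETURN_GRID - 380.0) / 30.0) ** 2))
        post = self._post_scan(0.005 + 0.1 * 0.02 *
                               templates.pigment_absorbance(505.0, RETURN_GRID)
                               + bump)
        assert msp.check_bleach(pre, post) is True

    def test_unchanged_spectrum_is_false(self):
        pre = self._pre()
        post = self._post_scan(
            0.005 + 0.02 * templates.pigment_absorbance(505.0, RETURN_GRID))
        assert msp.check_bleach(pre, post) is False

    def test_peak_halved_flat_elsewhere_is_true(self):
        # walk the rule's two clauses: 50% drop at the peak (non-strict)
        # and unchanged short-wave signal
        pre = self._pre()
        curve = 0.02 * templates.pigment_absorbance(505.0, RETURN_GRID)
        halved = np.where(np.abs(RETURN_GRID - 505.0) <= 40.0, 0.5, 1.0)
        post = self._post_scan(0.005 + curve * halved)
        assert msp.check_bleach(pre, post) is True

    def test_missing_scan_is_unverified(self):
        assert msp.check_bleach(self._pre(), None) is None


class TestApplyQC:
    def _estimate(self, density, sd, diff, bleach=None):
        return msp.LambdaMaxEstimate(
            transverse_density=density, sd_right_limb=sd,
            method_difference=diff, bleach_confirmed=bleach,
            lambda_max_primary=500.0, lambda_max_secondary=500.0 + diff)

    def test_strict_pass(self):
        v = msp.apply_qc(self._estimate(0.02, 5.0, 2.0), "MWS")
        assert v.passed and v.regime == "strict"

    def test_density_threshold_is_strictly_greater(self):
        v = msp.apply_qc(self._estimate(0.01, 5.0, 2.0), "MWS")
        assert not v.passed
        assert v.failed_criteria == ["transverse_density"]

    def test_relaxed_regime_retains_on_bleach_alone(self):
        v = msp.apply_qc(self._estimate(0.005, 20.0, 8.0, bleach=True), "UVS")
        assert v.passed and v.regime == "relaxed"

    def test_relaxed_regime_fails_without_bleach(self):
        for bleach in (False, None):
            v = msp.apply_qc(self._estimate(0.02, 1.0, 1.0, bleach=bleach), "SWS")
            assert not v.passed
            assert v.failed_criteria == ["bleach_confirmed"]

    def test_sd_and_diff_thresholds_strict(self):
        assert not msp.apply_qc(self._estimate(0.02, 12.0, 2.0), "rod").passed
        assert not msp.apply_qc(self._estimate(0.02, 5.0, 6.0), "rod").passed
        assert msp.apply_qc(self._estimate(0.02, 11.99, 5.99), "rod").passed

    def test_verdict_enumerates_every_failure(self):
        v = msp.apply_qc(self._estimate(0.005, 20.0, 8.0), "LWS")
        assert set(v.failed_criteria) == {
            "transverse_density", "sd_right_limb", "method_difference"}


class TestClassifyPigment:
    def test_table_values(self):
        assert msp.classify_pigment(359.3) == "UVS"
        assert msp.classify_pigment(563.2) == "LWS"
        assert msp.classify_pigment(450.3) == "SWS"

    def test_rod_mws_morphology_tiebreak(self):
        assert msp.classify_pigment(503.0, "rod") == "rod"
        assert msp.classify_pigment(503.0, "single cone") == "MWS"

    def test_no_rule_gives_unknown(self):
        assert msp.classify_pigment(503.0, "") == "unknown"

    def test_out_of_range_is_domain_error(self):
        with pytest.raises(DomainError):
            msp.classify_pigment(700.0)


class TestProcessRecord:
    def test_noise_free_full_pipeline(self):
        est = msp.process_record(template_record(563.2))
        assert est.lambda_max_primary == pytest.approx(563.2, abs=0.05)
        assert est.method_difference < 0.5
        assert est.qc.passed
        assert est.pigment_class == "LWS"

    def test_degenerate_record_fails_qc_not_crash(self):
        out = msp.SpectralScan(OUTWARD_GRID, np.full(201, 0.01), "outward")
        ret = msp.SpectralScan(RETURN_GRID, np.full(200, 0.01), "return")
        rec = msp.MSPRecord("flat", "b", "p", "LWS", out, ret)
        est = msp.process_record(rec)
        assert not est.qc.passed
        assert "DegenerateSpectrumError" in est.error

    def test_blind_to_population_label(self, rng):
        a = template_record(505.0, noise_sd=0.002, rng=np.random.default_rng(7),
                            population="popA")
        b = template_record(505.0, noise_sd=0.002, rng=np.random.default_rng(7),
                            population="masked")
        ea, eb = msp.process_record(a), msp.process_record(b)
        assert ea.lambda_max_primary == eb.lambda_max_primary
        assert ea.lambda_max_secondary == eb.lambda_max_secondary

    def test_determinism(self, rng):
        rec = template_record(505.0, noise_sd=0.002,
                              rng=np.random.default_rng(3))
        e1 = msp.process_record(rec)
        e2 = msp.process_record(rec)
        assert e1.lambda_max_primary == e2.lambda_max_primary
        assert e1.sd_right_limb == e2.sd_right_limb


class TestEstimatorBias:
    """Desk-scale unbiasedness (heavier versions live in test_acceptance)."""

    @pytest.mark.parametrize("lm,cls", [(365.0, "UVS"), (450.0, "SWS"),
                                        (505.0, "MWS"), (565.0, "LWS")])
    def test_mean_bias_small(self, lm, cls):
        rng = np.random.default_rng(int(lm))
        ests = []
        for _ in range(60):
            noise = rng.uniform(0.05, 0.15) * 0.02
            rec = template_record(lm, putative_class=cls, noise_sd=noise,
                                  rng=rng)
            est = msp.process_record(rec)
            if np.isfinite(est.lambda_max_primary):
                ests.append(est.lambda_max_primary)
        assert len(ests) >= 50
        assert abs(np.mean(ests) - lm) < 1.0

    def test_qc_monotone_in_noise(self):
        # shrinking the same noise realization never flips pass -> fail
        rng = np.random.default_rng(11)
        noise = rng.normal(0.0, 1.0, size=(len(OUTWARD_GRID) + len(RETURN_GRID)))
        for scale_hi, scale_lo in [(0.002, 0.0005), (0.003, 0.001)]:
            verdicts = []
            for scale in (scale_hi, scale_lo):
                no, nr = noise[:len(OUTWARD_GRID)], noise[len(OUTWARD_GRID):]
                out_clean, ret_clean = template_scans(505.0)
                out = msp.SpectralScan(OUTWARD_GRID,
                                       out_clean.absorbance + scale * no,
                                       "outward")
                ret = msp.SpectralScan(RETURN_GRID,
                                       ret_clean.absorbance + scale * nr,
                                       "return")
                rec = msp.MSPRecord("c", "b", "p", "MWS", out, ret,
                                    morphology="single cone")
                verdicts.append(msp.process_record(rec).qc.passed)
            if verdicts[0]:
                assert verdicts[1]
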