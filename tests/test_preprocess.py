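"""Preprocessing chain: QC gate, baseline, alignment, grid, averaging."""

import dataclasses

import numpy as np
import pytest

from salivaraman import SyntheticCohortConfig, generate_cohort
from salivaraman.exceptions import (
    AlignmentError,
    CoverageError,
    GridMismatchError,
    NormalizationError,
    StageError,
)
from salivaraman.preprocess import (
    PreprocessConfig,
    align_spectrum,
    average_subject,
    group_summary,
    normalize_spectrum,
    preprocess_cohort,
    qc_gate,
    resample_to_grid,
    subtract_baseline,
    subtraction_spectrum,
)
from salivaraman.spectra_io import RamanSpectrum

from conftest import make_spectrum

CFG = PreprocessConfig()
AXIS = np.arange(900.0, 1100.0, 1.21)


def _noise_spectrum(rng, peak_amp=0.0, center=1003.0):
    y = rng.normal(0.0, 1.0, AXIS.size)
    if peak_amp:
        y = y + peak_amp * np.exp(-0.5 * ((AXIS - center) / 4.0) ** 2)
    return make_spectrum(AXIS, y)


class TestQCGate:
    def test_visible_peak_passes_with_expected_snr(self):
        rng = np.random.default_rng(0)
        qc = qc_gate(_noise_spectrum(rng, peak_amp=10.0), CFG)
        assert qc.passed
        # amplitude 10 over unit noise: SNR should sit near 10
        assert 5.0 < qc.snr < 20.0

    def test_pure_noise_rarely_passes(self):
        rng = np.random.default_rng(1)
        passes = sum(
            qc_gate(_noise_spectrum(rng), CFG).passed for _ in range(200)
        )
        assert passes / 200 < 0.05

    def test_all_zero_fails_with_zero_snr(self):
        qc = qc_gate(make_spectrum(AXIS, np.zeros(AXIS.size)), CFG)
        assert not qc.passed and qc.snr == 0.0

    def test_window_outside_axis_raises(self):
        s = make_spectrum([400.0, 500.0], [1.0, 1.0])
        with pytest.raises(CoverageError):
            qc_gate(s, CFG)


class TestBaseline:
    def test_cubic_polynomial_annihilated(self):
        x = np.linspace(400, 1600, 500)
        y = 5 + 0.01 * x - 2e-5 * x**2 + 1e-8 * x**3
        out = subtract_baseline(make_spectrum(x, y), CFG)
        assert np.max(np.abs(out.intensities)) < 1e-8 * np.max(np.abs(y))
        assert out.stage == "baseline_corrected"

    def test_degree_zero_on_constant_gives_zeros(self):
        cfg = dataclasses.replace(CFG, baseline_degree=0)
        out = subtract_baseline(make_spectrum([1.0, 2, 3, 4], [7.0, 7, 7, 7]), cfg)
        assert np.allclose(out.intensities, 0.0, atol=1e-12)

    def test_gaussian_peak_area_survives_masked_fit(self):
        # cubic background + Gaussian(amp 100, sigma 5) at 920: the masked
        # iterative fit must return the peak with its analytic area
        x = np.arange(400.0, 1600.0, 1.21)
        amp, sigma = 100.0, 5.0
        peak = amp * np.exp(-0.5 * ((x - 920.0) / sigma) ** 2)
        cubic = 30 + 0.02 * x - 1e-5 * x**2 + 2e-9 * x**3
        out = subtract_baseline(make_spectrum(x, cubic + peak), CFG)
        area = np.trapezoid(out.intensities, x)
        analytic = amp * sigma * np.sqrt(2 * np.pi)
        assert abs(area - analytic) / analytic < 0.05

    def test_plain_ls_biases_baseline_into_peak(self):
        # sanity for the design choice: plain LS removes part of the peak
        x = np.arange(400.0, 1600.0, 1.21)
        peak = 100.0 * np.exp(-0.5 * ((x - 920.0) / 5.0) ** 2)
        cfg = dataclasses.replace(CFG, baseline_mode="plain_ls")
        masked = subtract_baseline(make_spectrum(x, peak), CFG)
        plain = subtract_baseline(make_spectrum(x, peak), cfg)
        analytic = 100.0 * 5.0 * np.sqrt(2 * np.pi)
        err_masked = abs(np.trapezoid(masked.intensities, x) - analytic)
        err_plain = abs(np.trapezoid(plain.intensities, x) - analytic)
        assert err_masked < err_plain

    def test_requires_raw_stage(self):
        s = make_spectrum([1.0, 2, 3, 4, 5], np.ones(5), stage="aligned")
        with pytest.raises(StageError):
            subtract_baseline(s, CFG)


def _corrected(peak_center, amp=5.0):
    # grid laid out so `peak_center` is exactly a grid point
    x = peak_center + 1.21 * np.arange(-500, 500)
    y = amp * np.exp(-0.5 * ((x - peak_center) / 4.0) ** 2)
    return make_spectrum(x, y, stage="baseline_corrected")


class TestAlignment:
    def test_apex_at_reference_is_fixed_point(self):
        s = _corrected(CFG.align_reference)
        out = align_spectrum(s, CFG)
        assert np.allclose(out.wavenumbers, s.wavenumbers, atol=1e-6)

    def test_planted_shift_recovered(self):
        shifted = _corrected(CFG.align_reference + 2.42)
        out = align_spectrum(shifted, CFG)
        applied = out.wavenumbers[0] - shifted.wavenumbers[0]
        assert abs(applied - (-2.42)) < 0.05

    def test_implausible_shift_raises(self):
        cfg = dataclasses.replace(CFG, align_reference=1000.0)
        s = _corrected(1011.5)  # would need a -11.5 cm^-1 shift
        with pytest.raises(AlignmentError):
            align_spectrum(s, cfg)


class TestResample:
    def test_identity_on_target_grid(self):
        grid = CFG.grid
        s = make_spectrum(grid, np.sin(grid / 100), stage="aligned")
        out = resample_to_grid(s, CFG)
        assert np.array_equal(out.wavenumbers, grid)
        assert np.allclose(out.intensities, s.intensities, atol=1e-12)

    def test_exact_on_affine_intensity(self):
        x = np.linspace(395, 1605, 731)
        s = make_spectrum(x, 3.0 * x - 7.0, stage="aligned")
        out = resample_to_grid(s, CFG)
        assert np.allclose(out.intensities, 3.0 * out.wavenumbers - 7.0, rtol=1e-12)

    def test_default_grid_has_967_points(self):
        x = np.linspace(395, 1605, 2000)
        out = resample_to_grid(make_spectrum(x, np.ones_like(x), stage="aligned"), CFG)
        assert len(out) == 967

    def test_uncovered_grid_raises(self):
        x = np.linspace(500, 1605, 1000)
        with pytest.raises(CoverageError, match="start"):
            resample_to_grid(make_spectrum(x, np.ones_like(x), stage="aligned"), CFG)


class TestNormalize:
    def _resampled(self, y):
        return make_spectrum(CFG.grid, y, stage="resampled")

    def test_l2_norm_is_one(self):
        out = normalize_spectrum(self._resampled(np.sin(CFG.grid)), CFG)
        assert abs(np.linalg.norm(out.intensities) - 1.0) < 1e-12

    def test_scale_invariance(self):
        y = np.cos(CFG.grid / 50) + 2
        a = normalize_spectrum(self._resampled(y), CFG)
        b = normalize_spectrum(self._resampled(7.0 * y), CFG)
        assert np.allclose(a.intensities, b.intensities, atol=1e-12)

    def test_area_mode_unit_integral(self):
        cfg = dataclasses.replace(CFG, normalization="area")
        out = normalize_spectrum(self._resampled(np.abs(np.sin(CFG.grid)) + 0.1), cfg)
        assert abs(np.trapezoid(np.abs(out.intensities), out.wavenumbers) - 1) < 1e-9

    def test_zero_vector_raises(self):
        with pytest.raises(NormalizationError):
            normalize_spectrum(self._resampled(np.zeros(967)), CFG)


class TestAveraging:
    def _rep(self, value, sid="S"):
        return make_spectrum([1.0, 2, 3], np.full(3, float(value)),
                             subject_id=sid, stage="normalized")

    def test_idempotent_on_identical_replicates(self):
        out = average_subject([self._rep(4)] * 10)
        assert np.allclose(out.intensities, 4.0)
        assert out.stage == "averaged"

    def test_mean_of_zero_and_two_is_one(self):
        out = average_subject([self._rep(0), self._rep(2)])
        assert np.allclose(out.intensities, 1.0)

    def test_balanced_batch_associativity(self):
        rng = np.random.default_rng(3)
        reps = [
            make_spectrum([1.0, 2, 3], rng.normal(size=3), subject_id="S",
                          stage="normalized")
            for _ in range(4)
        ]
        direct = average_subject(reps).intensities
        batched = 0.5 * (
            average_subject(reps[:2]).intensities
            + average_subject(reps[2:]).intensities
        )
        assert np.allclose(direct, batched, atol=1e-15)

    def test_mixed_grids_rejected(self):
        a = self._rep(1)
        b = make_spectrum([1.0, 2, 4], np.ones(3), subject_id="S", stage="normalized")
        with pytest.raises(GridMismatchError):
            average_subject([a, b])

    def test_mixed_subjects_rejected(self):
        with pytest.raises(GridMismatchError):
            average_subject([self._rep(1, "A"), self._rep(1, "B")])


class TestGroupSummary:
    def test_constant_spectra_mean_and_sample_sd(self):
        from salivaraman.spectra_io import ClinicalRecord, Cohort, SubjectRecord

        def subj(sid, value):
            rec = SubjectRecord(clinical=ClinicalRecord(sid, "CTR"))
            rec.averaged = make_spectrum([1.0, 2, 3], np.full(3, value),
                                         subject_id=sid, stage="averaged")
            return rec

        cohort = Cohort(subjects=[subj("a", 0.0), subj("b", 2.0)])
        summ = group_summary(cohort, "CTR")
        assert np.allclose(summ.mean_spectrum, 1.0)
        assert np.allclose(summ.sd_spectrum, np.sqrt(2.0))

    def test_subtraction_antisymmetry_and_zero(self):
        from salivaraman.spectra_io import ClinicalRecord, Cohort, SubjectRecord

        rng = np.random.default_rng(5)

        def subj(sid, group):
            rec = SubjectRecord(clinical=ClinicalRecord(
                sid, group, ahi=20 if group == "OSAS" else None))
            rec.averaged = make_spectrum([1.0, 2, 3], rng.normal(size=3),
                                         subject_id=sid, stage="averaged")
            return rec

        cohort = Cohort(subjects=[subj("a", "CTR"), subj("b", "CTR"),
                                  subj("c", "OSAS"), subj("d", "OSAS")])
        sa = group_summary(cohort, "OSAS")
        sb = group_summary(cohort, "CTR")
        assert np.allclose(subtraction_spectrum(sa, sb),
                           -subtraction_spectrum(sb, sa))
        assert np.allclose(subtraction_spectrum(sa, sa), 0.0)


class TestCohortPipeline:
    def test_deterministic_bit_identical(self):
        cfg = SyntheticCohortConfig(n_osas=4, n_ctr=4,
                                    replicates_per_subject=2, seed=21)
        a = preprocess_cohort(generate_cohort(cfg))
        b = preprocess_cohort(generate_cohort(cfg))
        assert a.matrix.equals(b.matrix)
        assert a.qc_table.equals(b.qc_table)

    def test_noise_free_correction_recovers_peak_component(self):
        # with no noise and no jitter, the corrected spectrum must track the
        # pure peak-sum component almost perfectly
        cfg = SyntheticCohortConfig(
            n_osas=2, n_ctr=2, replicates_per_subject=1,
            replicate_noise_sd=0.0, wavenumber_jitter_sd=0.0,
            subject_scale_cv=1e-9, peak_amplitude_cv=1e-9,
            severity_effect_sd=0.0, seed=2,
        )
        cohort = generate_cohort(cfg)
        pre = preprocess_cohort(
            cohort, PreprocessConfig(normalization="none"))
        from salivaraman.synthetic_cohort import default_peak_library
        grid = pre.config.grid
        pure = np.sum(
            [p.base_amplitude * p.profile(grid) for p in default_peak_library()],
            axis=0,
        )
        ctr_row = pre.matrix.loc["C003"].to_numpy()
        r = np.corrcoef(ctr_row, pure)[0, 1]
        assert r > 0.99

    def test_group_difference_directions_match_planted_effects(self, default_analysis):
        # OSAS-minus-CTR must be negative at the control-elevated bands
        # (saccharides 477, phosphate 589, glycerol 630, carotene 1517) and
        # positive at the disease-elevated bands (920, 957, 1030, 1444)
        diff = default_analysis.subtraction
        grid = default_analysis.preprocess.config.grid
        for center in (477, 589, 630, 1517):
            assert diff[np.argmin(np.abs(grid - center))] < 0
        for center in (920, 957, 1030, 1444):
            assert diff[np.argmin(np.abs(grid - center))] > 0

    def test_qc_discards_are_counted(self):
        cfg = SyntheticCohortConfig(n_osas=3, n_ctr=3,
                                    replicates_per_subject=2, seed=5)
        cohort = generate_cohort(cfg)
        # sabotage one replicate: flat noise, no reference peak
        rep = cohort.subjects[0].replicates[0]
        rep.intensities = np.random.default_rng(0).normal(0, 0.1, rep.intensities.size)
        pre = preprocess_cohort(cohort)
        assert pre.n_discarded == 1
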