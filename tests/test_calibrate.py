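"""Calibration fitting, external-standard quantification, validation stats."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import qamskit as qk
from qamskit.calibrate import esm_quantify, fit_calibration, recovery, rsd, validation_stats
from qamskit.peaks import detect_peaks
from qamskit.qams import assign_peaks


def _series_areas(noise_sd=0.0, seed=1):
    """Per-analyte (concentration, detected area) pairs over a dilution series."""
    panel = qk.default_panel()
    runs = qk.simulate_standard_series(
        concentration_levels=(0.25, 0.5, 0.75, 1.0, 1.25, 1.5),
        injection_volumes=(2.0,),
        seed=seed,
        noise_sd=noise_sd,
        baseline_drift=1.0 if noise_sd else 0.0,
    )
    pts = {a: [] for a in panel.analytes}
    for run in runs:
        res = assign_peaks(detect_peaks(qk.correct_baseline(run.chromatogram)), panel)
        for a in panel.analytes:
            p = res.peak(a)
            if p is not None:
                pts[a].append((run.concentrations[a], p.area))
    return pts


def test_exact_line_recovered():
    curve = fit_calibration([(c, 200.0 * c) for c in (0.1, 0.2, 0.4, 0.8)], "x")
    assert curve.slope == pytest.approx(200.0, rel=1e-12)
    assert curve.intercept == pytest.approx(0.0, abs=1e-10)
    assert curve.r == pytest.approx(1.0, abs=1e-12)
    assert curve.lod <= curve.loq


def test_noise_free_series_r_at_least_0p9990():
    for analyte, pts in _series_areas(noise_sd=0.0).items():
        curve = fit_calibration(pts, analyte)
        assert curve.r >= 0.9990, analyte


def test_noisy_slope_within_three_standard_errors_of_configured_response():
    """1% multiplicative area noise on a manifest-derived series leaves the
    fitted slope within 3 SE of the configured response x injection volume."""
    from qamskit.simulate import DEFAULT_RESPONSE_FACTORS
    from scipy.stats import linregress

    rng = np.random.default_rng(5)
    runs = qk.simulate_standard_series(
        concentration_levels=(0.25, 0.5, 0.75, 1.0, 1.25, 1.5),
        injection_volumes=(2.0,),
        seed=5,
    )
    for analyte in qk.ANALYTES:
        pts = [
            (run.concentrations[analyte], run.manifest.area(analyte) * (1 + rng.normal(0, 0.01)))
            for run in runs
        ]
        conc, area = np.array(pts).T
        fit = linregress(conc, area)
        expected = DEFAULT_RESPONSE_FACTORS[analyte] * 2.0  # x 2 uL injection
        assert abs(fit.slope - expected) <= 3 * fit.stderr, analyte


def test_too_few_levels_rejected():
    with pytest.raises(ValueError, match="distinct concentration"):
        fit_calibration([(1.0, 10.0), (2.0, 20.0)])
    with pytest.raises(ValueError):
        fit_calibration([(1.0, 10.0), (1.0, 11.0), (1.0, 12.0)])


class TestEsmQuantify:
    curve = qk.CalibrationCurve("x", slope=100.0, intercept=5.0, r=0.9999,
                                conc_range=(0.0, 1.0), lod=0.001, loq=0.003)

    def test_area_equal_to_intercept_gives_zero_content(self):
        q = esm_quantify(self.curve, 5.0, sample_mass_g=0.5)
        assert q.content == pytest.approx(0.0, abs=1e-12)

    def test_doubling_sample_mass_halves_content(self):
        q1 = esm_quantify(self.curve, 55.0, sample_mass_g=0.5)
        q2 = esm_quantify(self.curve, 55.0, sample_mass_g=1.0)
        assert q1.content == pytest.approx(2.0 * q2.content, rel=1e-12)

    def test_below_lod_flagged_but_quantified(self):
        q = esm_quantify(self.curve, 5.01, sample_mass_g=0.5)
        assert q.below_lod and q.flag == "below LOD" and float(q) > 0

    def test_area_far_above_range_rejected(self):
        with pytest.raises(ValueError, match="outside the calibrated response"):
            esm_quantify(self.curve, 1000.0, sample_mass_g=0.5)


def test_quantification_inverts_simulation_noise_free():
    """ESM content from a simulated extract returns the configured content within 0.5%."""
    from qamskit.simulate import contents_to_concentrations, SimulationConfig

    true_contents = {a: w for a, w in
                     zip(qk.ANALYTES, (3.2, 1.1, 3.7, 19.0, 2.4, 36.0, 5.0, 2.5, 1.0, 0.8))}
    conc = contents_to_concentrations(true_contents, 0.5, 45.0)
    chrom, _ = qk.simulate_chromatogram(
        SimulationConfig(concentrations=conc, noise_sd=0.0, baseline_drift=0.0)
    )
    panel = qk.default_panel()
    res = assign_peaks(detect_peaks(qk.correct_baseline(chrom)), panel)
    curves = {a: fit_calibration(pts, a) for a, pts in _series_areas().items()}
    for a in panel.analytes:
        q = esm_quantify(curves[a], res.peak(a).area, sample_mass_g=0.5, extract_volume_ml=45.0)
        assert q.content == pytest.approx(true_contents[a], rel=0.005), a


class TestValidationStats:
    def test_identical_replicates_have_zero_rsd(self):
        assert rsd([10.0, 10.0, 10.0]) == 0.0

    def test_nominal_spike_recovers_100_percent(self):
        assert recovery(2.5, 2.5) == pytest.approx(100.0)

    def test_rsd_of_published_rcf_replicates(self):
        # five per-volume f values of the least reproducible panel analyte
        assert rsd([0.327, 0.330, 0.321, 0.343, 0.343]) == pytest.approx(2.96, abs=0.005)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        values=st.lists(st.floats(min_value=0.1, max_value=100.0), min_size=2, max_size=8),
        scale=st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_rsd_scale_invariance(self, values, scale):
        assert rsd([v * scale for v in values]) == pytest.approx(rsd(values), rel=1e-9, abs=1e-9)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError, match="zero-mean"):
            rsd([-1.0, 1.0])

    def test_combined_report(self):
        out = validation_stats([1.0, 1.02, 0.98], [(0.99, 1.0), (1.05, 1.0)])
        assert set(out) == {"rsd_pct", "recovery_pct", "recovery_rsd_pct"}
        assert out["recovery_pct"] == pytest.approx(102.0)
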