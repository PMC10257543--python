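"""Relative correction factors, peak assignment, single-marker quantification, SMD."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import qamskit as qk
from qamskit.calibrate import fit_calibration
from qamskit.datasets import RCF_VOLUME_COLUMNS, load_rcf_reference
from qamskit.peaks import Peak, detect_peaks
from qamskit.qams import (
    AmbiguousAssignmentError,
    AnalytePanel,
    MarkerNotFoundError,
    RCFTable,
    assign_peaks,
    compute_rcf,
    qams_quantify,
    rcf_table,
    relative_retention,
    robustness_report,
    smd,
)

positive = st.floats(min_value=1e-3, max_value=1e3)


class TestComputeRcf:
    def test_marker_against_itself_is_one(self):
        assert compute_rcf(2.0, 300.0, 2.0, 300.0) == 1.0

    def test_direct_arithmetic(self):
        assert compute_rcf(2.0, 100.0, 1.0, 25.0) == pytest.approx(0.5)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_non_positive_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            compute_rcf(bad, 1.0, 1.0, 1.0)

    def test_noise_free_standard_gives_response_factor_ratio(self):
        """f_{k/m} from a clean run equals rf_analyte / rf_marker by Eq-level algebra."""
        from qamskit.simulate import DEFAULT_RESPONSE_FACTORS, STANDARD_CONCENTRATIONS

        runs = qk.simulate_standard_series(
            concentration_levels=(1.0,), injection_volumes=(1.0, 2.0), seed=0
        )
        run = runs[0]
        wk = STANDARD_CONCENTRATIONS["naringin"]
        ak = run.manifest.area("naringin")
        for a in qk.ANALYTES:
            f = compute_rcf(wk, ak, STANDARD_CONCENTRATIONS[a], run.manifest.area(a))
            expected = DEFAULT_RESPONSE_FACTORS[a] / DEFAULT_RESPONSE_FACTORS["naringin"]
            assert f == pytest.approx(expected, rel=1e-12)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(wk=positive, ak=positive, wm=positive, am=positive, wn=positive, an=positive)
    def test_reciprocity_and_transitivity(self, wk, ak, wm, am, wn, an):
        f_km = compute_rcf(wk, ak, wm, am)
        f_mk = compute_rcf(wm, am, wk, ak)
        f_mn = compute_rcf(wm, am, wn, an)
        f_kn = compute_rcf(wk, ak, wn, an)
        assert f_km * f_mk == pytest.approx(1.0, rel=1e-9)
        assert f_km * f_mn == pytest.approx(f_kn, rel=1e-9)


class TestRcfTable:
    def test_reference_f_values_reproduce_published_means(self):
        ref = load_rcf_reference()
        table = RCFTable.from_f_values(ref[RCF_VOLUME_COLUMNS], marker="naringin")
        # two analytes round the other way from unrounded source data
        skip = {"narirutin", "hesperetin"}
        for a in ref.index:
            if a in skip:
                continue
            assert round(float(table.mean_f[a]), 3) == pytest.approx(
                ref.loc[a, "mean_printed"]
            ), a

    def test_marker_row_exactly_one_with_zero_rsd(self):
        ref = load_rcf_reference()
        table = RCFTable.from_f_values(ref[RCF_VOLUME_COLUMNS], marker="naringin")
        assert table.mean_f["naringin"] == 1.0
        assert table.rsd_pct["naringin"] == 0.0

    def test_constant_f_across_volumes_has_zero_rsd(self):
        table = RCFTable.from_f_values({"a": [0.5, 0.5, 0.5], "m": [1, 1, 1]}, marker="m")
        assert table.rsd_pct["a"] == 0.0

    def test_from_runs_flags_missing_analyte(self):
        runs = {
            "1 uL": {"m": (1.0, 100.0), "a": (1.0, 50.0)},
            "2 uL": {"m": (1.0, 200.0)},
        }
        table = rcf_table(runs, "m")
        assert "a" in table.incomplete
        assert table.mean_f["a"] == pytest.approx(0.5)

    def test_single_run_rejected(self):
        with pytest.raises(ValueError, match="two standard runs"):
            rcf_table({"1 uL": {"m": (1.0, 1.0)}}, "m")


class TestRelativeRetention:
    def test_marker_maps_to_one(self):
        assert relative_retention(10.0, 10.0) == 1.0

    def test_direct_ratio(self):
        assert relative_retention(10.0, 15.0) == pytest.approx(1.5)

    def test_non_positive_marker_time_rejected(self):
        with pytest.raises(ValueError):
            relative_retention(0.0, 5.0)

    def test_rrt_rsd_below_3pct_across_rescaled_instruments(self, panel):
        """Two 'instruments' = uniformly rescaled time axes; RRTs agree to <3% RSD."""
        chrom, _ = qk.simulate_chromatogram(qk.example_ffa_config(seed=3))
        rrts = {a: [] for a in panel.analytes}
        for stretch in (1.0, 1.07, 0.95):
            res = assign_peaks(
                detect_peaks(qk.correct_baseline(chrom.scaled_time(stretch))), panel
            )
            tk = res.marker_peak.apex_time
            for a, p in res.assigned.items():
                rrts[a].append(relative_retention(tk, p.apex_time))
        for a, vals in rrts.items():
            assert len(vals) == 3
            assert 100 * np.std(vals, ddof=1) / np.mean(vals) < 3.0, a


def _fake_peak(t, area=10.0):
    return Peak(apex_time=t, area=area, height=area, left_bound=t - 0.2, right_bound=t + 0.2)


class TestAssignPeaks:
    def test_full_panel_assigned_in_order(self, ffa_default_noise, panel):
        chrom, _ = ffa_default_noise
        res = assign_peaks(detect_peaks(qk.correct_baseline(chrom)), panel)
        assert list(res.assigned) == list(panel.analytes)
        assert res.absent == []
        assert res.assigned["naringin"] is not None

    def test_rfa_reports_three_absent(self, rfa_default_noise, panel):
        chrom, _ = rfa_default_noise
        res = assign_peaks(detect_peaks(qk.correct_baseline(chrom)), panel)
        assert len(res.assigned) == 7
        assert set(res.absent) == {"hesperidin-7-O-glucoside", "naringenin", "hesperetin"}

    def test_uniform_time_stretch_preserves_assignment(self, ffa_default_noise, panel):
        chrom, _ = ffa_default_noise
        base = assign_peaks(detect_peaks(qk.correct_baseline(chrom)), panel)
        stretched = assign_peaks(
            detect_peaks(qk.correct_baseline(chrom.scaled_time(1.1))), panel
        )
        assert list(stretched.assigned) == list(base.assigned)
        for a in base.assigned:
            assert stretched.assigned[a].apex_time == pytest.approx(
                1.1 * base.assigned[a].apex_time, rel=1e-6
            )

    def test_missing_marker_is_hard_failure(self, panel):
        with pytest.raises(MarkerNotFoundError):
            assign_peaks([_fake_peak(25.0)], panel)

    def test_two_candidates_in_one_window_is_ambiguity_error(self, panel):
        peaks = [_fake_peak(10.4, area=100.0), _fake_peak(12.55), _fake_peak(12.7)]
        with pytest.raises(AmbiguousAssignmentError, match="hesperidin"):
            assign_peaks(peaks, panel)


def _rcf_from_pairs(pairs, marker):
    runs = {"v1": dict(pairs), "v2": dict(pairs)}
    return rcf_table(runs, marker)


class TestQamsQuantify:
    def test_direct_arithmetic(self):
        # marker content 1.0 mg/g from its own curve, analyte f = 0.5, area ratio 0.5
        curve = fit_calibration([(0.5, 50.0), (1.0, 100.0), (2.0, 200.0)], "m")
        rcf = _rcf_from_pairs({"m": (1.0, 100.0), "a": (1.0, 50.0)}, "m")
        peaks = {"m": _fake_peak(10.0, 100.0), "a": _fake_peak(12.0, 50.0)}
        contents, flags = qams_quantify(
            curve, peaks, rcf, sample_mass_g=1.0, extract_volume_ml=1.0
        )
        assert contents["m"] == pytest.approx(1.0, rel=1e-12)
        assert contents["a"] == pytest.approx(1.0, rel=1e-12)
        assert flags == {}

    def test_absent_analyte_reported_not_detected(self):
        curve = fit_calibration([(0.5, 50.0), (1.0, 100.0), (2.0, 200.0)], "m")
        rcf = _rcf_from_pairs({"m": (1.0, 100.0), "a": (1.0, 50.0)}, "m")
        contents, flags = qams_quantify(
            curve, {"m": _fake_peak(10.0, 100.0)}, rcf, sample_mass_g=1.0, extract_volume_ml=1.0
        )
        assert contents["a"] == 0.0
        assert flags["a"] == "not detected"

    def test_identity_with_esm_when_sharing_one_run(self):
        """QAMS equals ESM cell-for-cell when RCFs come from the ESM response data."""
        rng = np.random.default_rng(11)
        analytes = list(qk.ANALYTES)
        std_conc = {a: float(c) for a, c in zip(analytes, rng.uniform(0.05, 0.6, 10))}
        rf = {a: float(v) for a, v in zip(analytes, rng.uniform(100, 900, 10))}
        std_area = {a: rf[a] * std_conc[a] for a in analytes}
        curves = {
            a: fit_calibration(
                [(s * std_conc[a], s * std_area[a]) for s in (0.5, 1.0, 1.5)], a
            )
            for a in analytes
        }
        rcf = _rcf_from_pairs({a: (std_conc[a], std_area[a]) for a in analytes}, "naringin")
        for _ in range(5):  # five synthetic samples, within each calibrated range
            scale = rng.uniform(0.1, 1.1, 10)
            sample_area = {a: float(s) * std_area[a] for a, s in zip(analytes, scale)}
            peaks = {a: _fake_peak(10.0, sample_area[a]) for a in analytes}
            esm_row = {
                a: qk.esm_quantify(
                    curves[a], sample_area[a], sample_mass_g=0.5, extract_volume_ml=45.0
                ).content
                for a in analytes
            }
            qams_row, _ = qams_quantify(
                curves["naringin"], peaks, rcf, sample_mass_g=0.5, extract_volume_ml=45.0
            )
            for a in analytes:
                assert qams_row[a] == pytest.approx(esm_row[a], rel=1e-10), a


class TestSmd:
    def test_worked_example(self):
        esm = pd.DataFrame({"eriocitrin": [4.04]}, index=["F1"])
        qams = pd.DataFrame({"eriocitrin": [4.11]}, index=["F1"])
        rep = smd(esm, qams)
        assert rep.per_cell.iloc[0, 0] == pytest.approx(1.70, abs=0.005)

    def test_equal_tables_give_zero(self):
        df = pd.DataFrame(np.ones((3, 2)), columns=["a", "b"])
        rep = smd(df, df.copy())
        assert (rep.per_cell == 0).all().all()
        assert rep.summary["max_abs"] == 0.0

    def test_both_zero_cells_defined_as_zero(self):
        df0 = pd.DataFrame({"a": [0.0, 1.0]})
        df1 = pd.DataFrame({"a": [0.0, 1.25]})
        rep = smd(df0, df1)
        assert rep.per_cell.iloc[0, 0] == 0.0
        assert rep.per_cell.iloc[1, 0] == pytest.approx(20.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="identical rows"):
            smd(pd.DataFrame({"a": [1.0]}), pd.DataFrame({"b": [1.0]}))


class TestRobustness:
    def _table(self, f_a=0.5):
        return RCFTable.from_f_values({"m": [1.0, 1.0], "a": [f_a, f_a], "b": [0.3, 0.3]}, "m")

    def test_identical_conditions_zero_rsd_no_flags(self):
        rep = robustness_report({"instrument A": self._table(), "instrument B": self._table()})
        assert (rep["rsd_pct"] == 0).all()
        assert not rep["flagged"].any()

    def test_small_perturbation_stays_below_threshold(self):
        rep = robustness_report({"A": self._table(0.5), "B": self._table(0.505)})
        assert (rep["rsd_pct"] < 3.0).all()

    def test_ten_percent_perturbation_flags_exactly_that_analyte(self):
        with pytest.warns(UserWarning, match="a"):
            rep = robustness_report({"A": self._table(0.5), "B": self._table(0.55)})
        assert rep.loc["a", "flagged"]
        assert not rep.drop(index="a")["flagged"].any()

    def test_single_condition_rejected(self):
        with pytest.raises(ValueError):
            robustness_report({"A": self._table()})
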