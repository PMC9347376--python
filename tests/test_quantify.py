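"""Calibration, concentration, and empty/full ratio arithmetic and recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vpquant import (
    InstrumentSpec,
    MixtureSpec,
    SampleSpec,
    accuracy_percent,
    assign_peaks,
    capsid_concentration,
    capsids_per_injection,
    detect_peaks,
    dilutional_linearity,
    empty_fraction,
    empty_full_ratio,
    fit_standard_curve,
    process_flag,
    quantify_sample,
    simulate_chromatogram,
    simulate_standard_series,
    theoretical_mixture,
)
from vpquant.models import StandardCurve
from vpquant.synthetic import expected_standard_slope

from validation_data import AREA_INJECTIONS, AREA_VP_ORDER

LEVELS = list(np.geomspace(2.78e9, 1.04e11, 6))


def _areas(row):
    return dict(zip(AREA_VP_ORDER, row[:5]))


class TestStandardCurve:
    def test_exact_line(self):
        pts = [(x, 2.0 * x + 10.0) for x in (1.0, 2.0, 5.0, 9.0)]
        curve = fit_standard_curve(pts)
        assert curve.slope == pytest.approx(2.0)
        assert curve.intercept == pytest.approx(10.0)
        assert curve.r2 == pytest.approx(1.0)

    def test_noiseless_simulated_slope_matches_closed_form(self, vps, capsid, quiet_inst):
        series = simulate_standard_series(LEVELS, vps, capsid, quiet_inst)
        pts = [(t.injected_capsids, t.total_area) for _, t in series]
        curve = fit_standard_curve(pts)
        assert curve.slope == pytest.approx(
            expected_standard_slope(vps, capsid, quiet_inst), rel=1e-9
        )

    def test_one_percent_noise_keeps_good_linearity(self, vps, capsid):
        inst = InstrumentSpec(seed=42)
        series = simulate_standard_series(
            LEVELS, vps, capsid, inst, area_cv=0.01
        )
        pts = []
        for trace, truth in series:
            peaks = detect_peaks(trace)
            pts.append((truth.injected_capsids, sum(p.area for p in peaks)))
        assert fit_standard_curve(pts).r2 > 0.999

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_standard_curve([(1.0, 1.0), (2.0, 2.0)])


CURVE = StandardCurve(slope=2.0, intercept=10.0, r2=1.0, range=(5.0, 100.0))


class TestCapsidsPerInjection:
    def test_area_at_intercept_gives_zero(self):
        assert capsids_per_injection(10.0, CURVE).value == 0.0

    def test_direct_arithmetic(self):
        assert capsids_per_injection(30.0, CURVE).value == pytest.approx(10.0)

    def test_out_of_range_flagged_not_rejected(self):
        # 10% below the validated range minimum -> value + extrapolation flag.
        n = 0.9 * CURVE.range[0]
        res = capsids_per_injection(CURVE.intercept + CURVE.slope * n, CURVE)
        assert res.value == pytest.approx(n)
        assert res.extrapolated

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError, match="negative capsid count"):
            capsids_per_injection(5.0, CURVE)


class TestCapsidConcentration:
    def test_arithmetic(self):
        assert capsid_concentration(1.0e10, 0.01, 1.0) == pytest.approx(1.0e12)

    def test_dilution_scales_result(self):
        base = capsid_concentration(1.0e10, 0.01, 1.0)
        assert capsid_concentration(1.0e10, 0.01, 6.0) == pytest.approx(6.0 * base)

    def test_zero_count_gives_zero(self):
        assert capsid_concentration(0.0, 0.01) == 0.0

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError, match="volume"):
            capsid_concentration(1.0, 0.0)


class TestEmptyFullRatio:
    def test_first_injection_ratio(self):
        areas = _areas(AREA_INJECTIONS[0])
        # 11,698,177 / (21,890,324 + 193,564) -> 0.53
        assert round(empty_full_ratio(areas), 2) == 0.53

    def test_triplicate_average_ratio(self):
        ratios = [empty_full_ratio(_areas(r)) for r in AREA_INJECTIONS[:3]]
        assert round(float(np.mean(ratios)), 3) == 0.523

    def test_missing_vp0_means_pure_full(self):
        assert empty_full_ratio({"VP2": 100.0, "VP4": 1.0}) == 0.0

    def test_simplified_uses_vp2_only(self):
        areas = {"VP0": 10.0, "VP2": 40.0, "VP4": 10.0}
        assert empty_full_ratio(areas, simplified=True) == pytest.approx(0.25)
        assert empty_full_ratio(areas) == pytest.approx(0.2)

    def test_no_full_capsids_rejected(self):
        with pytest.raises(ValueError, match="no full capsids"):
            empty_full_ratio({"VP0": 5.0, "VP2": 0.0, "VP4": 0.0})


class TestEmptyFraction:
    @pytest.mark.parametrize(
        "ratio,expected", [(0.0, 0.0), (1.0, 0.5), (0.522, 0.343)]
    )
    def test_known_values(self, ratio, expected):
        assert round(empty_fraction(ratio), 3) == expected

    @settings(deadline=None, max_examples=50)
    @given(f=st.floats(min_value=0.0, max_value=0.99))
    def test_exact_inverse_of_f_to_ratio(self, f):
        assert empty_fraction(f / (1.0 - f)) == pytest.approx(f, abs=1e-12)


class TestDilutionalLinearity:
    DILUTIONS = [1.0, 1.5, 3.0, 6.0, 15.0]

    def _measure(self, vps, capsid, inst, area_cv=0.0):
        series_inst = inst
        curve_series = simulate_standard_series(
            LEVELS, vps, capsid, InstrumentSpec(noise_sd=0.0)
        )
        curve = fit_standard_curve(
            [(t.injected_capsids, t.total_area) for _, t in curve_series]
        )
        rng = np.random.default_rng(inst.seed)
        rows = []
        for d in self.DILUTIONS:
            s = SampleSpec(capsid_conc=3.0e12, empty_fraction=0.05, dilution_factor=d)
            _, truth = simulate_chromatogram(s, vps, capsid, series_inst, rng=rng)
            total = truth.total_area
            if area_cv:
                total *= rng.normal(1.0, area_cv)
            n = capsids_per_injection(total, curve).value
            rows.append((d, n, capsid_concentration(n, s.injection_volume, d)))
        return rows

    def test_noiseless_is_perfectly_linear(self, vps, capsid, quiet_inst):
        rep = dilutional_linearity(self._measure(vps, capsid, quiet_inst))
        assert rep.r2 == pytest.approx(1.0, abs=1e-9)
        assert rep.conc_rsd == pytest.approx(0.0, abs=1e-6)

    def test_one_percent_noise_within_limits(self, vps, capsid):
        rep = dilutional_linearity(
            self._measure(vps, capsid, InstrumentSpec(seed=7), area_cv=0.01)
        )
        assert rep.conc_rsd < 5.0
        assert rep.r2 >= 0.999

    def test_duplicate_levels_collapse_with_warning(self):
        rows = [(1.0, 10.0, 1e12), (1.0, 10.1, 1.01e12), (3.0, 3.3, 1e12), (6.0, 1.7, 1e12)]
        with pytest.warns(UserWarning, match="duplicate"):
            rep = dilutional_linearity(rows)
        assert rep.n_levels == 3


class TestTheoreticalMixture:
    def test_self_mixture_is_identity(self):
        s = SampleSpec(capsid_conc=2e12, empty_fraction=0.2)
        mix = MixtureSpec(components=((s, 0.4), (s, 0.6)))
        res = theoretical_mixture(mix)
        assert res.capsid_conc == pytest.approx(2e12)
        assert res.ef_ratio == pytest.approx(0.25)

    def test_fifty_fifty_closed_form(self):
        a = SampleSpec(capsid_conc=1e12, empty_fraction=0.0)
        b = SampleSpec(capsid_conc=1e12, empty_fraction=0.5)
        res = theoretical_mixture(MixtureSpec(components=((a, 0.5), (b, 0.5))))
        assert res.capsid_conc == pytest.approx(1e12)
        assert res.empty_fraction == pytest.approx(0.25)
        assert res.ef_ratio == pytest.approx(1.0 / 3.0)

    @settings(deadline=None, max_examples=30)
    @given(
        c1=st.integers(min_value=1, max_value=500),
        c2=st.integers(min_value=1, max_value=500),
        e1=st.integers(min_value=0, max_value=500),
        e2=st.integers(min_value=0, max_value=500),
        v=st.floats(min_value=0.05, max_value=0.95),
    )
    def test_particle_bookkeeping_oracle(self, c1, c2, e1, e2, v):
        # Brute-force discrete particles: component i contributes v_i * C_i
        # particles of which a fraction f_i is empty; the mixture fraction
        # must equal (total empty)/(total particles).
        e1 = min(e1, c1)
        e2 = min(e2, c2)
        s1 = SampleSpec(capsid_conc=float(c1), empty_fraction=e1 / c1)
        s2 = SampleSpec(capsid_conc=float(c2), empty_fraction=e2 / c2)
        res = theoretical_mixture(MixtureSpec(components=((s1, v), (s2, 1.0 - v))))
        total = v * c1 + (1 - v) * c2
        empty = v * e1 + (1 - v) * e2
        assert res.capsid_conc == pytest.approx(total, rel=1e-12)
        assert res.empty_fraction == pytest.approx(empty / total, rel=1e-9, abs=1e-12)

    def test_all_zero_concentration_rejected(self):
        z = SampleSpec(capsid_conc=0.0, empty_fraction=0.0)
        with pytest.raises(ValueError, match="no capsids"):
            theoretical_mixture(MixtureSpec(components=((z, 1.0),)))


class TestAccuracyPercent:
    @pytest.mark.parametrize(
        "measured,theoretical,expected",
        [(2.58e12, 2.52e12, 102), (0.0715, 0.0793, 90), (5.0, 5.0, 100)],
    )
    def test_spike_recovery(self, measured, theoretical, expected):
        assert accuracy_percent(measured, theoretical) == expected

    def test_zero_theoretical_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            accuracy_percent(1.0, 0.0)


class TestProcessFlag:
    @pytest.mark.parametrize(
        "ratio,threshold,expected",
        [(0.25, 0.20, "flag"), (0.035, 0.04, "pass"), (0.0, 0.01, "pass")],
    )
    def test_thresholding(self, ratio, threshold, expected):
        assert process_flag(ratio, threshold) == expected


class TestEndToEndRecovery:
    def _curve(self, vps, capsid):
        series = simulate_standard_series(
            LEVELS, vps, capsid, InstrumentSpec(noise_sd=0.0)
        )
        return fit_standard_curve(
            [(t.injected_capsids, t.total_area) for _, t in series]
        )

    @pytest.mark.parametrize("true_f", [0.05, 0.343, 0.7])
    def test_conc_and_empty_fraction_recovered(self, vps, capsid, true_f):
        curve = self._curve(vps, capsid)
        inst = InstrumentSpec(seed=11)  # SNR >> 100 for all real peaks
        s = SampleSpec(capsid_conc=3.66e12, empty_fraction=true_f)
        trace, _ = simulate_chromatogram(s, vps, capsid, inst)
        peaks = detect_peaks(trace)
        refs = {n: vp.ref_rt for n, vp in vps.items()}
        q = quantify_sample(assign_peaks(peaks, refs, tol=0.3), curve)
        assert q.capsid_conc == pytest.approx(3.66e12, rel=0.05)
        assert q.empty_fraction == pytest.approx(true_f, abs=0.02)

    def test_measured_conc_invariant_to_empty_fraction(self, vps, capsid):
        # The assay's central structural claim: total area (hence measured
        # concentration) does not depend on the empty/full composition.
        curve = self._curve(vps, capsid)
        concs = []
        for f in (0.0, 0.25, 0.5, 0.9):
            s = SampleSpec(capsid_conc=2.5e12, empty_fraction=f)
            trace, _ = simulate_chromatogram(s, vps, capsid, InstrumentSpec(seed=5))
            total = sum(p.area for p in detect_peaks(trace))
            n = capsids_per_injection(total, curve).value
            concs.append(capsid_concentration(n, s.injection_volume))
        assert max(concs) / min(concs) - 1.0 < 0.02

    def test_measured_ratio_monotone_in_true_fraction(self, vps, capsid):
        curve = self._curve(vps, capsid)
        refs = {n: vp.ref_rt for n, vp in vps.items()}
        measured = []
        for f in (0.1, 0.3, 0.5, 0.7):
            s = SampleSpec(capsid_conc=3e12, empty_fraction=f)
            trace, _ = simulate_chromatogram(s, vps, capsid, InstrumentSpec(seed=13))
            q = quantify_sample(assign_peaks(detect_peaks(trace), refs), curve)
            measured.append(q.ef_ratio)
        assert measured == sorted(measured)

    def test_sensitivity_to_small_ratio_changes(self, vps, capsid):
        # Two samples whose true ratios differ by 0.012 keep their ordering
        # in measured ratios across seeded replicates.
        curve = self._curve(vps, capsid)
        refs = {n: vp.ref_rt for n, vp in vps.items()}
        f_lo = empty_fraction(0.024)
        f_hi = empty_fraction(0.036)
        ordered = 0
        n_rep = 20
        for seed in range(n_rep):
            out = []
            for k, f in enumerate((f_lo, f_hi)):
                s = SampleSpec(capsid_conc=1.5e12, empty_fraction=f)
                trace, _ = simulate_chromatogram(
                    s, vps, capsid, InstrumentSpec(seed=1000 + 2 * seed + k)
                )
                q = quantify_sample(assign_peaks(detect_peaks(trace), refs), curve)
                out.append(q.ef_ratio)
            ordered += out[0] < out[1]
        assert ordered >= 0.95 * n_rep
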