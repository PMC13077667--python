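"""The six QA analyses against simulator ground truth and closed forms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epidqa import (AnalysisError, BeamGeometry, EpidImage, ErrorSpec,
                    FieldModel, central_axis_dose, focal_spot_epid,
                    focal_spot_twofield, make_focal_spot_set, make_open_field,
                    make_vmat_pair, make_wedge_field, symmetry, vmat_analysis,
                    wedge_factor, wedge_factor_true)
from epidqa.geometry import GeometryError
from epidqa.qa import VmatBandResult


@pytest.fixture(scope="module")
def open_field(geom):
    return make_open_field(FieldModel(noise_sd=0.0), geom=geom)


class TestWedgeFactor:
    def test_identical_images_give_unity(self, open_field):
        assert wedge_factor(open_field, open_field).wf == pytest.approx(1.0,
                                                                        abs=1e-12)

    def test_linearity(self, open_field):
        assert (wedge_factor(open_field.scaled(0.5), open_field).wf
                == pytest.approx(0.5, rel=1e-12))

    def test_simulated_wedge_recovers_ground_truth(self, quiet_fm, geom,
                                                   open_field):
        """Noise-free 30-degree wedge: the band reading ratio equals the
        closed-form band average of the exponential wedge,
        WF_true * sinh(a*w/2)/(a*w/2), and WF_true itself to ~1e-4."""
        wedged = make_wedge_field(quiet_fm, 30.0, geom=geom)
        wf = wedge_factor(wedged, open_field, wedge_angle_deg=30.0).wf
        a = 0.002 * math.tan(math.radians(30.0))
        band_avg = wedge_factor_true(30.0) * math.sinh(a * 2.5) / (a * 2.5)
        assert wf == pytest.approx(band_avg, abs=1e-6)
        assert wf == pytest.approx(wedge_factor_true(30.0), rel=1e-4)

    def test_geometry_mismatch_rejected(self, open_field):
        other = EpidImage(open_field.pixels[:-1, :], open_field.pixel_pitch,
                          open_field.sid)
        with pytest.raises(AnalysisError):
            wedge_factor(other, open_field)


class TestCentralAxisDose:
    def test_identical_image_zero_change(self, open_field):
        base = central_axis_dose(open_field)
        res = central_axis_dose(open_field, baseline=base)
        assert res.percent_change_from_baseline == pytest.approx(0.0, abs=1e-12)

    def test_mu_change_54_over_50_reads_8_percent(self, quiet_fm, geom,
                                                  open_field):
        """Delivering 54 MU against a 50 MU baseline is a +8.00% change."""
        base = central_axis_dose(open_field)
        hot = make_open_field(quiet_fm, ErrorSpec(output_scale=54.0 / 50.0),
                              geom)
        res = central_axis_dose(hot, baseline=base)
        assert res.percent_change_from_baseline == pytest.approx(8.0, abs=1e-6)

    def test_constant_image_reads_the_constant(self):
        img = EpidImage(np.full((64, 64), 1.37), pixel_pitch=1.0)
        assert central_axis_dose(img).cu_mean == pytest.approx(1.37, abs=1e-12)

    def test_bad_baseline_rejected(self, open_field):
        with pytest.raises(AnalysisError):
            central_axis_dose(open_field, baseline=0.0)


class TestSymmetry:
    def test_symmetric_image_reads_zero(self, open_field):
        res = symmetry(open_field)
        assert res.axial == pytest.approx(0.0, abs=1e-9)
        assert res.transverse == pytest.approx(0.0, abs=1e-9)

    def test_equations_consistent_with_roi_means(self, quiet_fm, geom):
        img = make_open_field(quiet_fm, ErrorSpec(tilt_x=0.03, tilt_y=-0.02),
                              geom)
        res = symmetry(img)
        m = res.roi_means
        assert res.axial == pytest.approx(
            100.0 * (m["top"] - m["bottom"]) / m["bottom"], abs=1e-12)
        assert res.transverse == pytest.approx(
            100.0 * (m["right"] - m["left"]) / m["left"], abs=1e-12)

    @pytest.mark.parametrize("tilt", [0.01, 0.04, 0.08])
    def test_injected_tilt_matches_closed_form(self, quiet_fm, geom, tilt):
        """Transverse symmetry of a tilted beam equals the disk-averaged
        profile-model closed form (horn-tilt cross terms included)."""
        img = make_open_field(quiet_fm, ErrorSpec(tilt_x=tilt), geom)
        hc, rf, a = quiet_fm.horn_coeff, 90.0, 2.5

        def disk_mean(cx):
            return (1 + hc * (cx ** 2 + a ** 2 / 2) / rf ** 2 + tilt * cx / 100
                    + tilt * hc / (100 * rf ** 2) * (cx ** 3 + cx * a ** 2))

        expected = 100.0 * (disk_mean(75.0) - disk_mean(-75.0)) / disk_mean(-75.0)
        # agreement limited by pixel-center quadrature of the ROI mean
        assert symmetry(img).transverse == pytest.approx(expected, abs=5e-4)

    def test_vertical_flip_reverses_sign_relation(self, quiet_fm, geom):
        """Flipping the image in y swaps top/bottom: axial becomes
        (b - t)/t, numerically the stated relation, not an exact negation."""
        img = make_open_field(quiet_fm, ErrorSpec(tilt_y=0.03), geom)
        flipped = EpidImage(img.pixels[::-1, :], img.pixel_pitch, img.sid,
                            img.origin)
        t = symmetry(img).roi_means["top"]
        b = symmetry(img).roi_means["bottom"]
        assert symmetry(flipped).axial == pytest.approx(100 * (b - t) / t,
                                                        abs=1e-6)

    def test_scale_invariance(self, quiet_fm, geom):
        img = make_open_field(quiet_fm, ErrorSpec(tilt_x=0.05), geom)
        res, scaled = symmetry(img), symmetry(img.scaled(7.0))
        assert scaled.transverse == pytest.approx(res.transverse, rel=1e-12)
        assert scaled.axial == pytest.approx(res.axial, abs=1e-12)


class TestFocalSpotTwoField:
    def test_equal_offsets_give_zero(self):
        assert focal_spot_twofield(0.2, 0.2) == pytest.approx(0.0)

    def test_direct_formula(self):
        assert focal_spot_twofield(0.1, 0.3) == pytest.approx(0.1)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(a=st.floats(-2, 2), b=st.floats(-2, 2))
    def test_antisymmetry_under_input_swap(self, a, b):
        assert focal_spot_twofield(a, b) == pytest.approx(
            -focal_spot_twofield(b, a), abs=1e-12)

    def test_vectorized_per_axis(self):
        out = focal_spot_twofield((0.1, -0.4), (0.3, 0.0))
        assert np.allclose(out, [0.1, 0.2])


class TestFocalSpotEpid:
    def test_aligned_source_reads_zero(self, quiet_fm, geom):
        res = focal_spot_epid(make_focal_spot_set(quiet_fm, (0, 0), geom), geom)
        assert res.sx == pytest.approx(0.0, abs=1e-6)
        assert res.sy == pytest.approx(0.0, abs=1e-6)

    def test_recovers_injected_shift(self, quiet_fm, geom):
        res = focal_spot_epid(make_focal_spot_set(quiet_fm, (0.4, -0.2), geom),
                              geom)
        assert res.sx == pytest.approx(0.4, abs=0.01)
        assert res.sy == pytest.approx(-0.2, abs=0.01)
        assert res.total == pytest.approx(math.hypot(0.4, 0.2), abs=0.02)

    def test_device_miscentering_cancels(self, quiet_fm, geom):
        """Opposing-collimator averaging removes a pure device offset."""
        images = make_focal_spot_set(quiet_fm, (0.0, 0.0), geom,
                                     device_offset=1.5)
        res = focal_spot_epid(images, geom)
        assert res.sx == pytest.approx(0.0, abs=0.01)
        assert res.sy == pytest.approx(0.0, abs=0.01)

    def test_recovery_linear_over_steering_range(self, quiet_fm, geom):
        """Shift sweep 0-0.6 mm: recovered-vs-true slope is 1.000 +/- 0.01."""
        true = np.arange(0.0, 0.61, 0.1)
        rec = [focal_spot_epid(make_focal_spot_set(quiet_fm, (s, s), geom),
                               geom).sx for s in true]
        slope = np.polyfit(true, rec, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.01)

    def test_degenerate_heights_rejected(self, quiet_fm):
        geom = BeamGeometry(h_jaw_x=509.0, h_jaw_y=509.0)
        images = make_focal_spot_set(quiet_fm, (0, 0), geom)
        with pytest.raises(GeometryError):
            focal_spot_epid(images, geom)


class TestVmatAnalysis:
    def test_modified_leafspeed_fractions_oracle(self, quiet_fm, geom):
        """16/21/29/34% segments under the unscaled Rcorr convention give
        Diff = (-9, -4, +4, +9); a 2% tolerance flags all four bands."""
        fr = (0.16, 0.21, 0.29, 0.34)
        dyn, open_ = make_vmat_pair("leafspeed", fr, quiet_fm, geom,
                                    normalize=False)
        res = vmat_analysis(dyn, open_, "leafspeed")
        assert np.allclose(res.diff, [-9.0, -4.0, 4.0, 9.0], atol=1e-9)
        assert not res.passed.any()

    def test_equal_fractions_all_pass(self, quiet_fm, geom):
        dyn, open_ = make_vmat_pair("drgs", None, quiet_fm, geom)
        res = vmat_analysis(dyn, open_, "drgs")
        assert np.allclose(res.diff, 0.0, atol=1e-9)
        assert res.all_passed

    @settings(derandomize=True, max_examples=10, deadline=None)
    @given(raw=st.lists(st.floats(0.5, 2.0), min_size=4, max_size=4))
    def test_diff_sums_to_zero(self, geom, raw):
        fr = np.array(raw) / np.sum(raw)
        dyn, open_ = make_vmat_pair("leafspeed", fr,
                                    FieldModel(noise_sd=0.0), geom)
        res = vmat_analysis(dyn, open_, "leafspeed")
        assert abs(res.diff.sum()) < 1e-9

    def test_pass_flag_flips_exactly_at_tolerance(self, quiet_fm, geom):
        """pass iff |Diff| <= tolerance, tested astride the boundary."""
        fr = (0.16, 0.21, 0.29, 0.34)   # |Diff| = 9, 4, 4, 9
        dyn, open_ = make_vmat_pair("leafspeed", fr, quiet_fm, geom,
                                    normalize=False)
        at = vmat_analysis(dyn, open_, "leafspeed", tolerance=4.0 + 1e-9)
        assert at.passed.tolist() == [False, True, True, False]
        below = vmat_analysis(dyn, open_, "leafspeed", tolerance=4.0 - 1e-9)
        assert not below.passed.any()
        above = vmat_analysis(dyn, open_, "leafspeed", tolerance=9.0 + 1e-9)
        assert above.all_passed

    def test_rcorr_scale_invariance(self, quiet_fm, geom):
        fr = (0.2, 0.2, 0.25, 0.35)
        dyn, open_ = make_vmat_pair("leafspeed", fr, quiet_fm, geom)
        a = vmat_analysis(dyn, open_, "leafspeed")
        b = vmat_analysis(dyn.scaled(3.0), open_.scaled(3.0), "leafspeed")
        assert np.allclose(a.rcorr, b.rcorr, rtol=1e-12)

    def test_result_invariant_enforced(self):
        bad = np.array([1.0, 2.0])
        with pytest.raises(AnalysisError):
            VmatBandResult(r_ls=bad, r_open=bad, rcorr=bad, diff=bad,
                           passed=bad > 0, tolerance=2.0,
                           centers_cm=(0.0, 1.0))
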