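"""Frame reduction: q mapping, cake integration, peak fitting, segmentation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cuticleflex import phantom, waxd


class TestPixelToQ:
    def test_beam_center_is_q_zero(self, mini_geo):
        assert waxd.pixel_to_q(mini_geo, mini_geo.beam_center_px) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_hand_evaluated_geometry(self):
        # distance 200 mm, radius 30 mm, 14 keV -> q = 10.554 nm^-1
        geo = waxd.DetectorGeometry(200.0, 172.0, (0.0, 0.0), 14.0, (64, 64))
        q = waxd.pixel_to_q(geo, (30.0 / 0.172, 0.0))
        assert q == pytest.approx(10.554, abs=1e-3)

    def test_monotone_in_radius(self, mini_geo):
        r = np.linspace(0, 400, 50)
        q = waxd.pixel_to_q(mini_geo, np.c_[r + mini_geo.beam_center_px[0],
                                            np.full_like(r, mini_geo.beam_center_px[1])])
        assert np.all(np.diff(q) > 0)

    def test_wavelength_energy_relation(self, mini_geo):
        assert mini_geo.wavelength_nm == pytest.approx(1.23984 / 14.0, rel=1e-6)


def _brute_force_cake(frame, geometry, q_window, az0, half_width, n_bins):
    """Per-pixel loop oracle for the cake integration."""
    edges = np.linspace(q_window[0], q_window[1], n_bins + 1)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    rows, cols = geometry.shape
    for iy in range(rows):
        for ix in range(cols):
            q = waxd.pixel_to_q(geometry, (ix, iy))
            if not (q_window[0] <= q <= q_window[1]):
                continue
            dx = (ix - geometry.beam_center_px[0])
            dy = (iy - geometry.beam_center_px[1])
            az = math.degrees(math.atan2(dy, dx)) % 360.0
            d1 = abs((az - az0 + 180.0) % 360.0 - 180.0)
            d2 = abs((az - az0) % 360.0 - 180.0)
            if d1 > half_width and d2 > half_width:
                continue
            b = min(int((q - q_window[0]) / (edges[1] - edges[0])), n_bins - 1)
            sums[b] += frame.data[iy, ix]
            counts[b] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return mean, counts


class TestCakeIntegrate:
    def test_uniform_frame_gives_constant_bins(self, mini_geo):
        frame = waxd.DetectorFrame(np.full(mini_geo.shape, 7.0))
        prof = waxd.cake_integrate(frame, mini_geo, azimuth_deg=0.0)
        assert np.allclose(prof.intensity[prof.nonempty], 7.0)

    def test_matches_per_pixel_brute_force(self, mini_geo):
        frame = phantom.render_frame(0.5150, mini_geo, phantom.NoiseModel(), 5)
        prof = waxd.cake_integrate(frame, mini_geo, azimuth_deg=0.0,
                                   half_width_deg=10.0, n_bins=60)
        mean, counts = _brute_force_cake(frame, mini_geo, (11.0, 20.0), 0.0, 10.0, 60)
        assert np.array_equal(prof.counts, counts)
        nz = counts > 0
        assert np.allclose(prof.intensity[nz], mean[nz], rtol=1e-12)

    def test_noiseless_ring_peaks_at_true_q(self, mini_geo):
        frame = phantom.render_frame(
            0.5150, mini_geo, phantom.NoiseModel(poisson=False, read_sigma=0.0), 0
        )
        prof = waxd.cake_integrate(frame, mini_geo)
        q_max = prof.q[np.nanargmax(np.where(prof.nonempty, prof.intensity, -1))]
        assert q_max == pytest.approx(2 * math.pi / 0.5150, abs=0.05)

    def test_empty_window_rejected(self, mini_geo):
        frame = waxd.DetectorFrame(np.ones(mini_geo.shape))
        with pytest.raises(ValueError):
            waxd.cake_integrate(frame, mini_geo, q_window=(50.0, 60.0))


class TestPeakFit:
    def test_synthetic_gaussian_recovered_exactly(self):
        q = np.linspace(11.0, 20.0, 400)
        y = 50.0 * np.exp(-((q - 12.20) ** 2) / (2 * 0.05**2)) + 3.0 + 0.2 * q
        prof = waxd.RadialProfile(q=q, intensity=y, counts=np.ones_like(q, dtype=int))
        fit = waxd.fit_peak_002(prof)
        assert fit.converged
        assert fit.q0 == pytest.approx(12.20, rel=1e-6)
        assert fit.D_nm == pytest.approx(0.51501, abs=1e-5)

    def test_d_spacing_identity(self):
        q = np.linspace(11.0, 20.0, 400)
        y = 20.0 * np.exp(-((q - 12.0) ** 2) / (2 * 0.08**2)) + 1.0
        fit = waxd.fit_peak_002(
            waxd.RadialProfile(q=q, intensity=y, counts=np.ones_like(q, dtype=int))
        )
        assert fit.D_nm * fit.q0 == pytest.approx(2 * math.pi, rel=1e-12)

    def test_flat_profile_flagged_unconverged(self):
        q = np.linspace(11.0, 20.0, 400)
        prof = waxd.RadialProfile(q=q, intensity=np.full_like(q, 4.0),
                                  counts=np.ones_like(q, dtype=int))
        fit = waxd.fit_peak_002(prof)
        assert not fit.converged

    def test_too_few_bins_unconverged_not_raising(self):
        q = np.linspace(11.9, 12.1, 5)
        prof = waxd.RadialProfile(q=q, intensity=np.ones_like(q),
                                  counts=np.ones_like(q, dtype=int))
        assert not waxd.fit_peak_002(prof).converged


class TestFibrilStrain:
    def _fit(self, q0, ok=True):
        return waxd.PeakFit(q0=q0, sigma=0.05, amplitude=1.0, c0=0.0, c1=0.0,
                            residual_norm=0.0, converged=ok)

    def test_closed_form_shift(self):
        # q 12.20 -> 12.1393 is a +0.50% strain
        strain = waxd.fibril_strain(self._fit(12.1393), self._fit(12.20))
        assert strain == pytest.approx(0.50, abs=1e-3)

    def test_no_shift_no_strain(self):
        assert waxd.fibril_strain(self._fit(12.2), self._fit(12.2)) == 0.0

    @given(st.sampled_from([-1.0, -0.5, 0.5, 1.0]))
    @settings(max_examples=4, deadline=None)
    def test_round_trip_applied_strain(self, eps):
        d_ref = 0.5150
        d = d_ref * (1 + eps / 100.0)
        strain = waxd.fibril_strain(
            self._fit(2 * math.pi / d), self._fit(2 * math.pi / d_ref)
        )
        assert strain == pytest.approx(eps, rel=1e-9)

    def test_unconverged_propagates_nan(self):
        assert math.isnan(
            waxd.fibril_strain(self._fit(12.2, ok=False), self._fit(12.2))
        )


class TestSegmentScan:
    def test_phantom_extent_matches_truth(self, phantom_dataset):
        truth = phantom_dataset["truth"].table
        scan = phantom_dataset["scans"][0.0]
        t0 = truth[truth.step_pct == 0].reset_index(drop=True)
        true_in = t0.in_sample.to_numpy()
        got_in = (scan.points["label"] != "outside").to_numpy()
        # labelled extent within one scan point of the rendered extent
        assert abs(got_in.sum() - true_in.sum()) <= 2
        assert np.mean(got_in == true_in) >= 0.9

    def test_depth_endpoints_are_zero_and_one(self, phantom_dataset):
        scan = phantom_dataset["scans"][0.0]
        depth = scan.cuticle()["depth_norm"]
        assert depth.min() == 0.0 and depth.max() == 1.0
        assert np.all(np.diff(scan.cuticle()["depth_norm"]) >= 0)

    def test_all_background_raises_no_sample(self):
        inten = np.full(20, 5.0)
        with pytest.raises(ValueError, match="no sample"):
            waxd.segment_scan(inten + np.random.default_rng(0).normal(0, 0.1, 20),
                              t1_fraction=0.35)

    def test_exo_side_end_reverses_depth(self):
        inten = np.array([1, 1, 10, 10, 10, 10, 1, 1], dtype=float)
        _, depth_fwd = waxd.segment_scan(inten, 0.35, exo_side="start")
        _, depth_rev = waxd.segment_scan(inten, 0.35, exo_side="end")
        valid = ~np.isnan(depth_fwd)
        assert np.allclose(depth_fwd[valid] + depth_rev[valid], 1.0)


class TestPrestrain:
    def test_phantom_gradient_recovered(self, phantom_dataset):
        prof = waxd.prestrain_profile(phantom_dataset["scans"][0.0])
        assert prof.endo_minus_exo_pct == pytest.approx(0.15, abs=0.03)

    def test_surface_point_is_reference(self, phantom_dataset):
        prof = waxd.prestrain_profile(phantom_dataset["scans"][0.0])
        assert prof.delta_pct[0] == 0.0

    def test_flat_phantom_profile_is_null(self, mini_geo, tmp_path):
        spec = phantom.PhantomSpec(
            seed=4,
            prestrain_exo_pct=0.0,
            prestrain_endo_pct=0.0,
            strain_steps_pct=(0.0,),
            noise=phantom.NoiseModel(poisson=False, read_sigma=0.0),
        )
        paths = phantom.write_dataset(spec, tmp_path)
        scans = waxd.reduce_manifest(paths["manifest"], spec.geometry,
                                     t1_fraction=0.35)
        prof = waxd.prestrain_profile(scans[0.0])
        assert np.allclose(prof.delta_pct, 0.0, atol=1e-3)

    def test_prestress_conversion(self):
        assert waxd.prestress_equivalent(0.15, 120.0) == pytest.approx(180.0)
        assert waxd.prestress_equivalent(0.0, 37.0) == 0.0
        assert waxd.prestress_equivalent(1.0, 100.0) == pytest.approx(1000.0)


class TestRoundTrip:
    def test_noiseless_phantom_self_consistency(self, noiseless_spec, tmp_path):
        # reducing a noiseless phantom returns the ground-truth lattice
        # spacing to <= 1e-4 relative at every scan point
        paths = phantom.write_dataset(noiseless_spec, tmp_path)
        truth, _ = phantom.make_phantom(noiseless_spec)
        scans = waxd.reduce_manifest(
            paths["manifest"],
            noiseless_spec.geometry,
            t1_fraction=noiseless_spec.arc.t1_mm / noiseless_spec.arc.h_mm,
        )
        for step, scan in scans.items():
            tt = truth.table[
                (truth.table.step_pct == step) & truth.table.in_sample
            ].set_index("position_um")
            pts = scan.cuticle().set_index("position_um")
            common = pts.index.intersection(tt.index)
            rel = np.abs(
                pts.loc[common, "D_nm"] - tt.loc[common, "D_nm"]
            ) / tt.loc[common, "D_nm"]
            assert np.nanmax(rel) <= 1e-4

    def test_default_noise_strain_error_small(self, phantom_dataset):
        truth = phantom_dataset["truth"].table
        scan = phantom_dataset["scans"][2.0]
        tt = truth[(truth.step_pct == 2.0) & truth.in_sample].set_index("position_um")
        pts = scan.cuticle()
        pts = pts[pts.converged].set_index("position_um")
        common = pts.index.intersection(tt.index)
        err = pts.loc[common, "strain_pct"] - tt.loc[common, "fibril_strain_pct"]
        assert np.nanmax(np.abs(err)) <= 0.02
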