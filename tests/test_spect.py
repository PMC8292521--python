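"""Quantitative SPECT chain tests: OS-EM behaviour, scatter-window
attenuation maps, sensitivity calibration, VOI extraction, and fractions."""

import numpy as np
import pytest

import dmsapk as d
from dmsapk.projector import LN2
from dmsapk.spect import ActivityImage, MuMap


@pytest.fixture(scope="module")
def noisefree_projections(small_phantom, small_geometry, sensitivity, response):
    return d.simulate_acquisition(
        small_phantom, small_geometry, sensitivity, time_post_injection_h=3.0,
        noise=False, response=response, photopeak_scatter_fraction=0.2,
    )


class TestOsem:
    def test_zero_projections_give_zero_image(self, small_phantom, small_geometry,
                                              sensitivity, response):
        proj = d.ProjectionSet(
            counts={"photopeak": np.zeros((24, 32, 32))},
            geometry=small_geometry, voxel_size_cm=0.875,
        )
        img = d.reconstruct_osem(proj, MuMap(small_phantom.mu_grid), response,
                                 sensitivity, n_iterations=1, n_subsets=4,
                                 scatter_estimate=None)
        assert not img.values_mbq.any()

    def test_mlem_converges_to_truth(self, small_phantom, sensitivity, response):
        """Noise-free data, true mu map, matched PSF, 1 subset x 200
        iterations: kidney-mask activity within 2% of the decayed truth."""
        geom = d.AcquisitionGeometry(n_views=24, orbit_radius_cm=15.0)
        proj = d.simulate_acquisition(small_phantom, geom, sensitivity, 3.0,
                                      noise=False, response=response)
        img = d.reconstruct_osem(proj, MuMap(small_phantom.mu_grid), response,
                                 sensitivity, n_iterations=200, n_subsets=1)
        truth = small_phantom.kidney_activity_mbq * d.decay_factor(3.0)
        got = img.values_mbq[small_phantom.kidney_mask].sum()
        assert got == pytest.approx(truth, rel=0.02)

    def test_osem_subsets_near_truth(self, small_phantom, noisefree_projections,
                                     sensitivity, response):
        img = d.reconstruct_osem(noisefree_projections, MuMap(small_phantom.mu_grid),
                                 response, sensitivity, n_iterations=5, n_subsets=8)
        truth = small_phantom.kidney_activity_mbq * d.decay_factor(3.0)
        got = img.values_mbq[small_phantom.kidney_mask].sum()
        assert got == pytest.approx(truth, rel=0.05)

    def test_nonnegativity_and_scale_equivariance(self, small_phantom,
                                                  noisefree_projections,
                                                  sensitivity, response):
        proj = noisefree_projections
        c = 3.7
        scaled = d.ProjectionSet(
            counts={k: c * v for k, v in proj.counts.items()},
            geometry=proj.geometry, voxel_size_cm=proj.voxel_size_cm,
            scatter_expectation=c * proj.scatter_expectation,
        )
        i1 = d.reconstruct_osem(proj, MuMap(small_phantom.mu_grid), response,
                                sensitivity, 2, 4)
        i2 = d.reconstruct_osem(scaled, MuMap(small_phantom.mu_grid), response,
                                sensitivity, 2, 4)
        assert (i1.values_mbq >= 0).all()
        assert np.allclose(i2.values_mbq, c * i1.values_mbq,
                           atol=1e-8 * c * i1.values_mbq.max())

    def test_mlem_likelihood_nondecreasing(self, small_phantom, sensitivity):
        """With one subset on noise-free data the Poisson log-likelihood is
        non-decreasing across iterations."""
        geom = d.AcquisitionGeometry(n_views=8, orbit_radius_cm=15.0)
        proj = d.simulate_acquisition(small_phantom, geom, sensitivity, 3.0,
                                      noise=False, response=None)
        y = proj.counts["photopeak"]
        scale = sensitivity.cps_per_mbq * geom.seconds_per_view
        from dmsapk.projector import SystemModel

        sm = SystemModel(small_phantom.mu_grid, geom, None, 0.875)

        def loglik(x):
            lam = sm.forward(x) * scale
            sel = lam > 0
            return float((y[sel] * np.log(lam[sel]) - lam[sel]).sum())

        lls = []
        for n_it in (1, 2, 4, 8):
            img = d.reconstruct_osem(proj, MuMap(small_phantom.mu_grid), None,
                                     sensitivity, n_iterations=n_it, n_subsets=1)
            lls.append(loglik(img.values_mbq))
        assert all(b >= a - 1e-6 * abs(a) for a, b in zip(lls, lls[1:]))

    def test_subset_balance(self):
        from dmsapk.spect import make_subsets

        subs = make_subsets(120, 16)
        sizes = sorted(len(s) for s in subs)
        assert sum(sizes) == 120
        assert sizes[-1] - sizes[0] <= 1
        assert sorted(v for s in subs for v in s) == list(range(120))


class TestAttenuationMap:
    def test_scatter_window_contour(self, sensitivity, response):
        """Noiseless scatter projections of the elliptical body: derived
        contour area within 10% of the true cross-section; interior mu_soft,
        exterior 0; constant axially."""
        ph = d.make_phantom()  # full-resolution grid for an accurate contour
        geom = d.AcquisitionGeometry(n_views=24, orbit_radius_cm=15.0)
        proj = d.simulate_acquisition(ph, geom, sensitivity, 3.0, noise=False,
                                      response=response,
                                      photopeak_scatter_fraction=0.2)
        zs = np.where(ph.kidney_mask.any(axis=(0, 1)))[0]
        mu_map = d.attenuation_map_from_scatter_window(
            proj, (int(zs.min()), int(zs.max()) + 1)
        )
        assert mu_map.provenance == "scatter_window_derived"
        mid = ph.body_mask.shape[2] // 2
        contour = mu_map.mu_grid[:, :, mid] > 0
        true_area = ph.body_mask[:, :, mid].sum()
        assert contour.sum() == pytest.approx(true_area, rel=0.10)
        vals = np.unique(mu_map.mu_grid)
        assert set(np.round(vals, 10)) <= {0.0, 0.15}
        # replication: identical in every axial slice over the kidney range
        for z in range(int(zs.min()), int(zs.max()) + 1):
            assert np.array_equal(mu_map.mu_grid[:, :, z], mu_map.mu_grid[:, :, mid])

    def test_empty_contour_raises(self, small_geometry):
        proj = d.ProjectionSet(
            counts={"photopeak": np.zeros((24, 32, 32)),
                    "scatter": np.zeros((24, 32, 32))},
            geometry=small_geometry, voxel_size_cm=0.875,
        )
        with pytest.raises(ValueError, match="contour"):
            d.attenuation_map_from_scatter_window(proj, (10, 20))


class TestSensitivity:
    def test_flask_ratio(self):
        s = d.sensitivity_from_flask(200000, 1.0, 39.96, 0.0)
        assert s.cpm_per_mbq == pytest.approx(5005.0, abs=0.1)

    def test_decay_correction_direction(self):
        base = d.sensitivity_from_flask(200000, 1.0, 39.96, 0.0)
        later = d.sensitivity_from_flask(200000, 1.0, 39.96, 6.0)
        assert later.cpm_per_mbq == pytest.approx(2 * base.cpm_per_mbq)

    def test_duration_invariance_in_expectation(self):
        """Doubling the duration at fixed true sensitivity leaves the
        estimate unchanged in expectation (Poisson replicates)."""
        rng = np.random.default_rng(3)
        true_cpm = 5000.0
        activity = 40.0
        est1 = [d.sensitivity_from_flask(rng.poisson(true_cpm * activity * 1.0),
                                         1.0, activity).cpm_per_mbq
                for _ in range(200)]
        est2 = [d.sensitivity_from_flask(rng.poisson(true_cpm * activity * 2.0),
                                         2.0, activity).cpm_per_mbq
                for _ in range(200)]
        assert np.mean(est1) == pytest.approx(np.mean(est2), rel=0.005)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            d.sensitivity_from_flask(1000, 0.0, 40.0)
        with pytest.raises(ValueError):
            d.sensitivity_from_flask(1000, 1.0, -1.0)


class TestVoiAndFraction:
    def test_clean_kidneys_recovered_exactly(self, small_phantom):
        """An image that is exactly the phantom's kidneys on a zero
        background: any threshold recovers the full kidney activity (plain
        threshold mode)."""
        ph = small_phantom
        vals = np.where(ph.kidney_mask, ph.activity_grid, 0.0)
        img = ActivityImage(vals, ph.voxel_size_cm)
        for thr in (0.1, 0.5, 0.9):
            act, voi = d.kidney_activity_from_image(img, thr, smooth_sigma_vox=0,
                                                    dilate_vox=0)
            assert act == pytest.approx(ph.kidney_activity_mbq, rel=1e-12)

    def test_threshold_one_single_voxel(self):
        vals = np.zeros((8, 8, 8))
        vals[4, 4, 4] = 2.0
        vals[2, 2, 2] = 1.0
        act, voi = d.kidney_activity_from_image(
            ActivityImage(vals, 1.0), 1.0, smooth_sigma_vox=0, dilate_vox=0
        )
        assert voi.sum() == 1 and act == 2.0

    def test_fraction_injected_closed_forms(self):
        a0 = 100.0
        assert d.fraction_injected(a0 * d.decay_factor(3.0), a0, 3.0) == pytest.approx(1.0)
        assert d.fraction_injected(0.0, a0, 2.0) == 0.0
        act = 0.3 * a0 * 2 ** (-3.0 / 6.0)
        assert d.fraction_injected(act, a0, 3.0) == pytest.approx(0.3)
        assert d.fraction_injected(act, a0, 3.0, decay_correct=False) == pytest.approx(
            0.3 * 2 ** -0.5
        )

    def test_unphysical_fraction_warns(self):
        with pytest.warns(UserWarning, match="unphysical"):
            d.fraction_injected(200.0, 100.0, 0.0)
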