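"""Phantom generator: schedule arithmetic, kinetics, blur, noise, rendering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from flucipet import phantom as ph
from tests.conftest import make_noiseless_spec


class TestFrameSchedule:
    @pytest.mark.parametrize(
        "groups, n, total",
        [
            ([(6, 30.0), (4, 180.0), (5, 600.0)], 15, 3900.0),
            ([(1, 60.0)], 1, 60.0),
            ([(3, 10.0), (2, 20.0)], 5, 70.0),
        ],
    )
    def test_expansion(self, groups, n, total):
        s = ph.make_frame_schedule(groups)
        assert s.n_frames == n
        assert s.total_duration_s == total
        assert s.frame_starts[0] == 0.0

    def test_cumulative_starts_and_midtimes(self):
        s = ph.make_frame_schedule([(3, 10.0), (2, 20.0)])
        assert np.array_equal(s.frame_starts, [0, 10, 20, 30, 50])
        single = ph.make_frame_schedule([(1, 60.0)])
        assert single.frame_mid_times_min[0] == 0.5

    def test_default_equilibrium_midtimes(self, schedule):
        assert np.allclose(schedule.frame_mid_times_min[-4:], [30, 40, 50, 60])
        assert np.array_equal(schedule.equilibrium_frames(30.0), [11, 12, 13, 14])

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ph.make_frame_schedule([])
        with pytest.raises(ValueError):
            ph.make_frame_schedule([(0, 30.0)])
        with pytest.raises(ValueError):
            ph.make_frame_schedule([(2, -1.0)])
        with pytest.raises(ValueError):
            ph.FrameSchedule(np.array([0.0, 40.0]), np.array([30.0, 30.0]))

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(1, 5), st.floats(1.0, 600.0)), min_size=1, max_size=5))
    def test_contiguity_invariant(self, groups):
        s = ph.make_frame_schedule(groups)
        assert np.allclose(s.frame_starts[1:], s.frame_starts[:-1] + s.frame_durations[:-1])
        assert np.all(np.diff(s.frame_mid_times_min) > 0)


class TestTissueKinetics:
    def test_starts_at_zero_and_saturates(self):
        kin = ph.TissueKinetics(plateau_suv=3.0, uptake_rate=5.0, infusion_duration=1.0)
        assert ph.tissue_tac(kin, 0.0) == 0.0
        assert ph.tissue_tac(kin, 60.0) == pytest.approx(3.0, abs=1e-6)

    def test_closed_form_matches_quadrature(self):
        # independent oracle: numerically integrate the infusion convolution
        kin = ph.TissueKinetics(plateau_suv=1.0, uptake_rate=0.2, infusion_duration=4.0)
        for t in (0.5, 2.0, 4.0, 10.0, 40.0):
            expected = quad(
                lambda u: (1 - np.exp(-kin.uptake_rate * (t - u))) / kin.infusion_duration,
                0.0, min(t, kin.infusion_duration),
            )[0]
            assert ph.tissue_tac(kin, t) == pytest.approx(expected, abs=1e-8)

    def test_bolus_limit(self):
        kin = ph.TissueKinetics(plateau_suv=2.0, uptake_rate=0.3, infusion_duration=0.0)
        t = np.array([0.0, 1.0, 10.0])
        assert np.allclose(ph.tissue_tac(kin, t), 2.0 * (1 - np.exp(-0.3 * t)))

    def test_drift_term(self):
        kin = ph.TissueKinetics(plateau_suv=0.0, uptake_rate=1.0, drift_slope=0.1, drift_onset=30.0)
        assert ph.tissue_tac(kin, 29.0) == 0.0
        assert ph.tissue_tac(kin, 40.0) == pytest.approx(1.0)

    def test_negative_time_rejected(self):
        kin = ph.TissueKinetics(plateau_suv=1.0)
        with pytest.raises(ValueError):
            ph.tissue_tac(kin, -0.1)

    def test_driftfree_tac_is_monotone_with_shrinking_steps(self, schedule):
        kin = ph.TissueKinetics(plateau_suv=4.0, uptake_rate=0.25, infusion_duration=4.0)
        vals = ph.frame_average_tac(kin, schedule)
        diffs = np.diff(vals)
        assert np.all(diffs >= -1e-12)
        # plateau: late inter-frame increments shrink toward zero
        late = diffs[-4:]
        assert np.all(np.diff(late) <= 1e-12)

    def test_frame_average_matches_quadrature(self, schedule):
        kin = ph.TissueKinetics(plateau_suv=2.5, uptake_rate=0.22, infusion_duration=4.0,
                                drift_slope=0.01, drift_onset=30.0)
        vals = ph.frame_average_tac(kin, schedule)
        for i in (0, 5, 9, 14):
            a = schedule.frame_starts[i] / 60.0
            b = schedule.frame_ends[i] / 60.0
            expected = quad(lambda t: ph.tissue_tac(kin, t), a, b, limit=200)[0] / (b - a)
            assert vals[i] == pytest.approx(expected, abs=1e-8)


class TestApplyPsf:
    def _delta_image(self, shape=(33, 33, 33), vox=1.2):
        v = np.zeros(shape + (1,))
        v[shape[0] // 2, shape[1] // 2, shape[2] // 2, 0] = 1.0
        sched = ph.make_frame_schedule([(1, 60.0)])
        return ph.DynamicImage(v, vox, sched)

    def test_zero_fwhm_is_identity(self, noiseless_phantom):
        img, _ = noiseless_phantom
        out = ph.apply_psf(img, 0.0)
        assert out.voxels is img.voxels

    def test_impulse_fwhm_recovered(self):
        img = self._delta_image()
        out = ph.apply_psf(img, 4.6)
        prof = out.voxels[:, 16, 16, 0]
        half = prof.max() / 2.0
        above = np.nonzero(prof >= half)[0]
        # linear interpolation at the half-maximum crossings
        lo, hi = above[0], above[-1]
        f_lo = lo - (prof[lo] - half) / (prof[lo] - prof[lo - 1])
        f_hi = hi + (prof[hi] - half) / (prof[hi] - prof[hi + 1])
        measured = (f_hi - f_lo) * 1.2
        assert measured == pytest.approx(4.6, abs=0.6)  # half a voxel

    def test_total_activity_conserved(self):
        img = self._delta_image()
        out = ph.apply_psf(img, 4.6)
        assert out.voxels.sum() == pytest.approx(img.voxels.sum(), rel=1e-3)

    def test_uniform_volume_unchanged(self):
        sched = ph.make_frame_schedule([(1, 60.0)])
        img = ph.DynamicImage(np.full((12, 12, 12, 1), 2.5), 2.0, sched)
        out = ph.apply_psf(img, 5.0)
        assert np.allclose(out.voxels, 2.5)

    def test_negative_fwhm_rejected(self, noiseless_phantom):
        with pytest.raises(ValueError):
            ph.apply_psf(noiseless_phantom[0], -1.0)


class TestAddNoise:
    def test_sigma_zero_is_identity_and_seed_reproducible(self, noiseless_phantom):
        img, _ = noiseless_phantom
        assert ph.add_noise(img, 0.0, 1).voxels is img.voxels
        a = ph.add_noise(img, 0.1, 42)
        b = ph.add_noise(img, 0.1, 42)
        assert np.array_equal(a.voxels, b.voxels)
        c = ph.add_noise(img, 0.1, 43)
        assert not np.array_equal(a.voxels, c.voxels)

    def test_mean_shift_within_clt_bound(self, noiseless_phantom):
        img, truth = noiseless_phantom
        noisy = ph.add_noise(img, 0.2, 7)
        region = truth.label_volume == 1
        n = region.sum() * img.schedule.n_frames
        shift = (noisy.voxels - img.voxels)[region].mean()
        assert abs(shift) <= 3 * 0.2 / np.sqrt(n)


class TestRenderPhantom:
    def test_noiseless_voxels_equal_frame_averaged_tacs(self, noiseless_phantom, noiseless_spec):
        img, truth = noiseless_phantom
        lesion = truth.label_volume == truth.lesion_labels["les1"]
        expected = truth.lesion_tacs["les1"]
        assert np.allclose(img.voxels[lesion, :], expected[None, :])
        brain = truth.label_volume == ph.LABEL_BRAIN
        assert np.allclose(img.voxels[brain, :], truth.brain_tac[None, :])

    def test_determinism_and_seed_sensitivity(self):
        spec = make_noiseless_spec(noise_sigma=0.1, psf_fwhm_mm=4.6, seed=5)
        a, _ = ph.render_phantom(spec)
        b, _ = ph.render_phantom(spec)
        assert np.array_equal(a.voxels, b.voxels)
        c, _ = ph.render_phantom(make_noiseless_spec(noise_sigma=0.1, psf_fwhm_mm=4.6, seed=6))
        assert not np.array_equal(a.voxels, c.voxels)

    def test_noise_sd_calibrated(self):
        img, truth = ph.render_phantom(make_noiseless_spec())
        noisy, _ = ph.render_phantom(make_noiseless_spec(noise_sigma=0.1, seed=3))
        region = truth.label_volume == ph.LABEL_BRAIN  # uniform tissue, >1000 voxels
        assert region.sum() >= 1000
        resid = (noisy.voxels - img.voxels)[region, -1]
        assert np.std(resid) == pytest.approx(0.1, rel=0.1)

    def test_ground_truth_tb_ratio(self, noiseless_phantom):
        _, truth = noiseless_phantom
        assert truth.lesion_tb_ratio["les1"] == pytest.approx(3.0)

    def test_truth_labels_partition_grid(self, noiseless_phantom, noiseless_spec):
        _, truth = noiseless_phantom
        labels = set(np.unique(truth.label_volume))
        assert ph.LABEL_BRAIN in labels and ph.LABEL_VENOUS in labels
        assert set(truth.lesion_labels.values()) <= labels

    def test_overlapping_lesions_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            make_noiseless_spec(
                lesions=(
                    ph.LesionSpec("a", (48.5, 34.5, 28.5), 7.0,
                                  ph.TissueKinetics(plateau_suv=3.0)),
                    ph.LesionSpec("b", (44.5, 34.5, 28.5), 7.0,
                                  ph.TissueKinetics(plateau_suv=2.0)),
                )
            )

    def test_lesion_outside_brain_rejected(self):
        with pytest.raises(ValueError, match="inside brain"):
            make_noiseless_spec(
                lesions=(
                    ph.LesionSpec("a", (68.0, 34.5, 28.5), 7.0,
                                  ph.TissueKinetics(plateau_suv=3.0)),
                )
            )


class TestSynthesizeCohort:
    def test_composition_and_reproducibility(self):
        a = ph.synthesize_cohort(12, 6, seed=9)
        b = ph.synthesize_cohort(12, 6, seed=9)
        assert a == b
        assert sum(l.grade_class == "HGG" for l in a) == 12
        assert sum(l.who_grade == "III" for l in a) == 1
        assert all(l.who_grade == "II" for l in a if l.grade_class == "LGG")
        assert all(
            l.kinetics.plateau_suv > ph.BRAIN_PLATEAU_SUV for l in a
        )  # every lesion is hotter than parenchyma
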