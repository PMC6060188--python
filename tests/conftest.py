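import numpy as np
import pytest

from flucipet import phantom as ph


@pytest.fixture(scope="session")
def schedule():
    return ph.default_frame_schedule()


def make_noiseless_spec(**overrides) -> ph.PhantomSpec:
    """Small ideal phantom: one 7-mm lesion (plateau 3) in brain (plateau 1),
    no blur, no noise, so every measurement has an exact ground truth."""
    grid = (24, 24, 20)
    vox = 3.0
    center = tuple(vox * (np.array(grid) - 1) / 2.0)
    kwargs = dict(
        grid_shape=grid,
        voxel_size_mm=vox,
        brain_center_mm=center,
        brain_semiaxes_mm=(33.0, 33.0, 27.0),
        lesions=(
            ph.LesionSpec(
                lesion_id="les1",
                center_mm=(center[0] + 14.0, center[1], center[2]),
                radius_mm=7.0,
                kinetics=ph.TissueKinetics(plateau_suv=3.0, uptake_rate=0.3),
                grade_label="HGG",
            ),
        ),
        normal_brain_kinetics=ph.TissueKinetics(plateau_suv=1.0, uptake_rate=0.35),
        venous_center_mm=(center[0], center[1] - 18.0, center[2] - 6.0),
        venous_radius_mm=4.0,
        venous_kinetics=ph.TissueKinetics(plateau_suv=1.1, uptake_rate=0.9),
        psf_fwhm_mm=0.0,
        noise_sigma=0.0,
        seed=0,
    )
    kwargs.update(overrides)
    return ph.PhantomSpec(**kwargs)


@pytest.fixture(scope="session")
def noiseless_spec():
    return make_noiseless_spec()


@pytest.fixture(scope="session")
def noiseless_phantom(noiseless_spec):
    return ph.render_phantom(noiseless_spec)
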