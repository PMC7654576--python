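import numpy as np
import pytest

import retispec as rs


@pytest.fixture(scope="session")
def camera():
    return rs.CameraModel()


@pytest.fixture(scope="session")
def cohort():
    return rs.generate_cohort(rs.CohortSpec(seed=1))


@pytest.fixture(scope="session")
def phantom_bundle(camera, cohort):
    """One full-scale subject imaged through the whole front end."""
    subject = cohort[0]
    phantom = rs.generate_phantom(subject, camera, seed=100)
    raw = rs.render_raw_mosaic(phantom, camera, rng=np.random.default_rng(7))
    cube = rs.to_relative_reflectance(rs.demosaic(raw, camera), camera,
                                      subject_ref=subject.subject_id)
    return subject, phantom, raw, cube


@pytest.fixture(scope="session")
def uniform_cube(camera):
    values = np.full((64, 96, 16), 0.4)
    return rs.HyperspectralCube(values=values, band_centers=camera.band_centers)
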