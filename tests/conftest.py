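"""Shared fixtures: phantoms, mask sets and reconstructions reused across tests.

Session scope keeps the expensive pieces (phantom rendering, iterative
reconstructions, the retrospective experiment) to a single run each.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cstpm import (
    PhantomSpec,
    ReconConfig,
    cs_reconstruct,
    make_mask_set,
    render_kspace,
    retrospective_experiment,
    retrospective_undersample,
)
from cstpm.evaluation import kinematics_from_images

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

MATRIX = 64
N_FRAMES = 16
N_COILS = 4
TUNED_LAM = 0.01
US_FACTORS = (2, 4, 8, 16)


@pytest.fixture(scope="session")
def phantom_small():
    """Tiny noiseless phantom for cheap reconstruction/decoding tests."""
    return render_kspace(
        PhantomSpec(matrix=32, n_frames=8, n_coils=2, noise_sigma=0.0, seed=3)
    )


@pytest.fixture(scope="session")
def phantom64():
    """Default noisy phantom at the analysis problem size."""
    return render_kspace(PhantomSpec(matrix=MATRIX, n_frames=N_FRAMES, seed=1))


@pytest.fixture(scope="session")
def phantom64_clean():
    return render_kspace(
        PhantomSpec(matrix=MATRIX, n_frames=N_FRAMES, noise_sigma=0.0, seed=1)
    )


@pytest.fixture(scope="session")
def seg64(phantom64):
    return phantom64.segmentation()


@pytest.fixture(scope="session")
def mask_sets64(phantom64):
    k = phantom64.kspace
    return {
        us: make_mask_set(k.n_ky, us, k.n_frames, k.n_encodings, seed=100 + us)
        for us in (1,) + US_FACTORS
    }


@pytest.fixture(scope="session")
def cs4_64(phantom64, mask_sets64):
    """4x undersampled k-space, its CS reconstruction and report."""
    und = retrospective_undersample(phantom64.kspace, mask_sets64[4])
    images, report = cs_reconstruct(und, mask_sets64[4], ReconConfig(lam=TUNED_LAM))
    return und, images, report


@pytest.fixture(scope="session")
def agreement_table(phantom64, seg64, mask_sets64):
    return retrospective_experiment(
        phantom64.kspace,
        mask_sets64,
        seg64,
        phantom64.contour_seeds,
        phantom64.spec.scheme,
        ReconConfig(lam=TUNED_LAM),
    )


@pytest.fixture(scope="session")
def kinematics_pair64(phantom64, seg64, cs4_64):
    """(fully sampled, CS4) kinematic results under the same segmentation."""
    ref, _ = kinematics_from_images(
        phantom64.kspace.to_images(),
        phantom64.spec.scheme,
        seg64,
        phantom64.contour_seeds,
    )
    cs, _ = kinematics_from_images(
        cs4_64[1], phantom64.spec.scheme, seg64, phantom64.contour_seeds
    )
    return ref, cs
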