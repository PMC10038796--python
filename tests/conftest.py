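import numpy as np
import pytest

from crossisc import BoldGroup, SimSpec, generate_bold_groups


def make_group(n_subjects=4, n_voxels=6, n_timepoints=48, run_lengths=(24, 24),
               seed=0, condition="A") -> BoldGroup:
    """Small random group for unit tests."""
    rng = np.random.default_rng(seed)
    return BoldGroup(
        subject_ids=[f"s{i}" for i in range(n_subjects)],
        data=rng.standard_normal((n_subjects, n_voxels, n_timepoints)),
        tr_seconds=2.0,
        run_lengths=run_lengths,
        condition=condition,
    )


@pytest.fixture
def small_group():
    return make_group()


@pytest.fixture
def null_pair():
    """Two groups with no shared signal (pure AR(1) noise)."""
    spec = SimSpec(n_subjects_per_group=4, n_voxels=20, n_timepoints=120,
                   run_lengths=(60, 60), voxel_timescale_s=np.zeros(20),
                   shared_amplitude=0.0, seed=11)
    ga, gv, truth = generate_bold_groups(spec)
    return ga, gv, truth


@pytest.fixture
def shared_pair():
    """Two groups sharing band-limited latents at half the voxels."""
    ts = np.zeros(20)
    ts[:10] = 20.0
    spec = SimSpec(n_subjects_per_group=5, n_voxels=20, n_timepoints=300,
                   run_lengths=(150, 150), voxel_timescale_s=ts,
                   shared_amplitude=1.0, noise_ar1=0.0, seed=7)
    ga, gv, truth = generate_bold_groups(spec)
    return ga, gv, truth
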