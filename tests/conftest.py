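import numpy as np
import pytest

from mrar import AcquisitionConfig, CoagulationTrajectory, simulate_run


@pytest.fixture
def clean_config():
    """Small noiseless single-channel acquisition for exact comparisons."""
    return AcquisitionConfig(
        total_duration=12.0, n_channels=1, noise_snr_db=np.inf, amplitude_jitter=0.0
    )


@pytest.fixture
def dho_config():
    """One-measurement acquisition for damped-oscillator tracking checks."""
    return AcquisitionConfig(
        total_duration=0.0, n_channels=1, noise_snr_db=np.inf, amplitude_jitter=0.0
    )


def dho_trajectory(f=300.0, amp=20e-6, decay=20e-3):
    """Trajectory that oscillates at a single fixed frequency everywhere."""
    # t_start far beyond any run: the liquid plateau (frequency exactly f) holds throughout
    return CoagulationTrajectory(
        f_liquid=f,
        f_solid=f * 1.001,
        t_start=1e9,
        t_end=2e9,
        amp_liquid=amp,
        amp_solid=amp,
        decay_liquid=decay,
        decay_solid=decay,
    )


@pytest.fixture(scope="session")
def clotting_run():
    """One simulated 15-min clotting run at 30 dB SNR, with ground truth."""
    cfg = AcquisitionConfig(total_duration=900.0, n_channels=1, noise_snr_db=30.0, seed=42)
    traj = CoagulationTrajectory(t_start=120.0, t_end=240.0)
    archive, truth = simulate_run(cfg, [traj])
    return cfg, traj, archive, truth
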