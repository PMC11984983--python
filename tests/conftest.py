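import numpy as np
import pytest

from chromodyn import AcquisitionParams, KineticTruth, simulate_tracks


@pytest.fixture(scope="session")
def slow_acq_no_axial() -> AcquisitionParams:
    """200 ms dwell-time acquisition with axial loss disabled, so that the
    only detection-loss process is photobleaching (the assumption behind
    the count-decay bleach-rate estimator)."""
    return AcquisitionParams(
        frame_interval_s=0.2, n_frames=200, axial_range_nm=0.0, localization_error_um=0.035
    )


@pytest.fixture(scope="session")
def dwell_trackset(slow_acq_no_axial):
    """End-to-end dwell fixture: two bound populations (T_s = 5 s,
    T_ns = 0.5 s, 60% non-specific), 20 s photobleach lifetime."""
    truth = KineticTruth(
        frac_bound=0.5,
        frac_ns_of_bound=0.6,
        k_ns=2.0,
        k_s=0.2,
        D_bound=0.005,
        D_free=2.0,
        bleach_lifetime_s=20.0,
        interconvert=True,
    )
    return simulate_tracks(truth, slow_acq_no_axial, 2000, seed=7)


@pytest.fixture(scope="session")
def fast_acq_no_axial() -> AcquisitionParams:
    """15 ms jump-length acquisition, axial loss disabled so the empirical
    bound/free jump mixture keeps the simulated weights."""
    return AcquisitionParams(
        frame_interval_s=0.015, n_frames=12, axial_range_nm=0.0, localization_error_um=0.035
    )


@pytest.fixture(scope="session")
def jump_trackset(fast_acq_no_axial):
    """Two-state jump fixture: F_bound = 0.5, D_bound = 0.005,
    D_free = 2.0 um^2/s, sigma = 35 nm, no state switching."""
    truth = KineticTruth(
        frac_bound=0.5,
        D_bound=0.005,
        D_free=2.0,
        k_ns=2.0,
        k_s=0.2,
        bleach_lifetime_s=1e6,
        interconvert=False,
    )
    return simulate_tracks(truth, fast_acq_no_axial, 2600, seed=11)
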