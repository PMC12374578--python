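import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import segscan as ss


def beta_floquet_oracle(q: float) -> float:
    """Independent beta oracle: integrate the Mathieu equation u'' = 2q cos(2x) u
    over one period and extract the Floquet exponent from the monodromy trace,
    cos(pi beta) = tr(M)/2."""

    def rhs(x, y):
        u1, du1, u2, du2 = y
        c = 2.0 * q * math.cos(2.0 * x)
        return [du1, c * u1, du2, c * u2]

    sol = solve_ivp(rhs, [0.0, math.pi], [1.0, 0.0, 0.0, 1.0],
                    rtol=1e-11, atol=1e-12, method="DOP853")
    trace = sol.y[0, -1] + sol.y[3, -1]
    return math.acos(trace / 2.0) / math.pi


@pytest.fixture(scope="session")
def trap_cfg():
    return ss.TrapConfig()


@pytest.fixture(scope="session")
def profile():
    return ss.reference_profile()


@pytest.fixture(scope="session")
def sc_model(profile):
    return ss.SpaceChargeModel.calibrated(profile)


@pytest.fixture(scope="session")
def schedule():
    return ss.plan_segments(50.0, 500.0, 20.0, 5.0)


@pytest.fixture(scope="session")
def full_scan_60(profile, sc_model):
    return ss.simulate_scan(
        profile, ss.AcquisitionSettings(injection_time=60.0), sc=sc_model
    )


@pytest.fixture(scope="session")
def full_scan_35(profile, sc_model):
    return ss.simulate_scan(
        profile, ss.AcquisitionSettings(injection_time=35.0), sc=sc_model
    )


@pytest.fixture(scope="session")
def merged_segment_60(profile, schedule, sc_model):
    spectra = ss.simulate_segment_run(
        profile, schedule,
        ss.AcquisitionSettings(injection_time=60.0, scan_mode="segment"),
        sc=sc_model,
    )
    return ss.merge_segments(spectra, schedule)


def gaussian_spectrum(centers, heights, sigma=0.17, lo=50.0, hi=100.0,
                      spacing=0.05, baseline=0.0):
    """Analytic multi-Gaussian fixture on an aligned grid."""
    mz = np.arange(math.ceil(lo / spacing), math.floor(hi / spacing) + 1) * spacing
    intensity = np.full_like(mz, baseline, dtype=float)
    for c, h in zip(centers, heights):
        intensity += h * np.exp(-0.5 * ((mz - c) / sigma) ** 2)
    return ss.Spectrum(mz, intensity, {"polarity": "negative"})
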