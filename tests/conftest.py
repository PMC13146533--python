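import numpy as np
import pytest

from photothermics import LaserProtocol, ThermalSystem, icg_demo_scenario


@pytest.fixture(scope="session")
def demo():
    """Single-cycle demo scenario: 600 s on at 2.5 W, 600 s off."""
    return icg_demo_scenario()


@pytest.fixture
def generic_system():
    return ThermalSystem(
        heat_capacity_total=4.2,
        hA=0.014,
        eta=0.5,
        absorbance=1.0,
        solvent_heat=0.01,
        ambient_temp=25.0,
    )


@pytest.fixture
def single_on_protocol():
    return LaserProtocol([(0.0, 600.0, 1.0)])


def steady_state_pair(eta_true=0.76, tau_s=120.0, ambient=26.3, power=2.5,
                      absorbance=0.45, solvent_heat=0.0174, heat_capacity=4.18,
                      n_tau_heating=8.0, dt=60.0):
    """Sample/water trace pair whose heating window reaches true steady state.

    Returns (sample_trace, water_trace, laser_off_s, kwargs-for-estimation).
    """
    from photothermics import simulate_trace

    hA = heat_capacity / tau_s
    on_s = np.ceil(n_tau_heating * tau_s / dt) * dt
    off_s = on_s
    common = dict(heat_capacity_total=heat_capacity, hA=hA,
                  solvent_heat=solvent_heat, ambient_temp=ambient)
    sample_sys = ThermalSystem(eta=eta_true, absorbance=absorbance, **common)
    water_sys = ThermalSystem(eta=0.0, absorbance=absorbance, **common)
    protocol = LaserProtocol([(0.0, on_s, power), (on_s, on_s + off_s, 0.0)])
    times = np.arange(0.0, on_s + off_s + 1e-9, dt)
    sample = simulate_trace(sample_sys, protocol, times)
    water = simulate_trace(water_sys, protocol, times)
    est_kwargs = dict(laser_off_s=on_s, heat_capacity_total=heat_capacity,
                      laser_power=power, absorbance=absorbance, ambient_temp=ambient)
    return sample, water, sample_sys, est_kwargs
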