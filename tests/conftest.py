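import numpy as np
import pytest

from tkreceptor import (
    GPULEX_BINDING,
    GPULEX_THIACLOPRID,
    ExposureScenario,
    TKParameters,
)


@pytest.fixture
def ref_params() -> TKParameters:
    """Best-fit TK-receptor parameters (thiacloprid / G. pulex)."""
    return GPULEX_THIACLOPRID


@pytest.fixture
def ref_binding():
    """Best-fit one-site binding parameters (thiacloprid on G. pulex MP)."""
    return GPULEX_BINDING


@pytest.fixture
def pulse_scenario() -> ExposureScenario:
    """2 d at 0.2 µM (50 µg/L) followed by 2 d of clean water."""
    return ExposureScenario.uptake_elimination(0.2, 2.0, 2.0)


def small_design(cv, seed, replicates=2):
    """Compact three-treatment calibration design for fast fitting.

    One kinetic arm (2 d + 8 d at 50 µg/L), one long low-concentration
    arm (20 d + 5 d at 0.5 µg/L) and one short high-concentration arm
    (2 d + 2 d at 1500 µg/L): together they identify k_u, k_e and B_max.
    """
    from tkreceptor import DesignTemplate, generate_tk_dataset
    from tkreceptor.synthetic import standard_templates

    t50 = standard_templates(cv=cv, seed=seed)["I"]
    t_low = DesignTemplate(
        experiment="II", concentrations_ug_l=(0.5,),
        exposure_d=20.0, elimination_d=5.0,
        sampling_times=(5.0, 10.0, 15.0, 20.0, 25.0),
        replicates=replicates, cv=cv,
        seed=None if seed is None else seed + 1,
    )
    t_high = DesignTemplate(
        experiment="III", concentrations_ug_l=(1500.0,),
        exposure_d=2.0, elimination_d=2.0,
        sampling_times=(1.0, 2.0, 3.0, 4.0),
        replicates=replicates, cv=cv,
        seed=None if seed is None else seed + 2,
    )
    params = TKParameters(k_u=10.6, k_e=5.2, k_on=200.0, B_max=25.0)
    ds = generate_tk_dataset(params, t50)
    ds = ds.concat(generate_tk_dataset(params, t_low))
    return ds.concat(generate_tk_dataset(params, t_high))


def euler_simulate(params, scenario, times, initial_state=(0.0, 0.0), dt=1e-5):
    """Fixed-step explicit-Euler integration of the TK-receptor system.

    Deliberately naive reference implementation: no adaptivity, no
    stiffness handling, just small steps.  Used as an independent oracle
    for the adaptive solver.
    """
    times = np.asarray(times, dtype=float)
    out = np.empty((len(times), 2))
    c_s, c_mp = float(initial_state[0]), float(initial_state[1])
    k_u, k_e, k_on, k_off = params.k_u, params.k_e, params.k_on, params.k_off
    b_max, fms = params.B_max, params.fms
    t = 0.0
    i = 0
    while i < len(times) and times[i] <= t:
        out[i] = (c_s, c_mp)
        i += 1
    for a, b, c_w in scenario.intervals:
        while t < b - 1e-15:
            h = min(dt, b - t)
            d_mp = k_on * c_s * (b_max - c_mp) - k_off * c_mp
            d_s = k_u * c_w - k_e * c_s - fms * d_mp
            c_s += h * d_s
            c_mp += h * d_mp
            t += h
            while i < len(times) and times[i] <= t + 1e-12:
                out[i] = (c_s, c_mp)
                i += 1
        if i >= len(times):
            break
    c_total = out[:, 0] + fms * out[:, 1]
    return out[:, 0], out[:, 1], c_total
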