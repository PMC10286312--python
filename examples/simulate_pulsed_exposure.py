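"""Simulate a pulsed-exposure experiment and show elimination resistance.

Three cycles of 2 d exposure at 50 µg/L followed by 3 d of clean water.
After every depuration phase the whole-body residue returns to the same
plateau, fms * B_max = 0.25 µmol/kg: the receptor pool saturates during
the first pulse and, with k_off = 0, never releases its ligand.
"""

import numpy as np

from tkreceptor import ExposureScenario, GPULEX_THIACLOPRID, simulate

scenario = ExposureScenario.pulses(
    c_w_um=0.2,        # 50 µg/L at 250 g/mol
    exposure_d=2.0,
    elimination_d=3.0,
    n_pulses=3,
)
times = np.linspace(0.0, scenario.t_end, 301)
traj = simulate(GPULEX_THIACLOPRID, scenario, times)

print("pulsed exposure, 3 x (2 d at 0.2 uM + 3 d clean water)")
print(f"{'day':>5} {'C_structure':>12} {'C_MP':>8} {'C_total':>9}")
for day in (1, 2, 5, 7, 10, 12, 15):
    i = np.searchsorted(times, day)
    print(
        f"{times[i]:5.1f} {traj.c_structure[i]:12.4f} "
        f"{traj.c_mp[i]:8.2f} {traj.c_total[i]:9.4f}"
    )

plateau = traj.c_total[np.searchsorted(times, [5.0, 10.0, 15.0])]
print(
    "\nend-of-depuration residues:",
    np.round(plateau, 4),
    "umol/kg  (fms*B_max =",
    GPULEX_THIACLOPRID.fms * GPULEX_THIACLOPRID.B_max,
    ")",
)
print(
    "The identical plateaus show the elimination-resistant, receptor-bound\n"
    "fraction: repeated pulses do not increase the residual body burden."
)
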