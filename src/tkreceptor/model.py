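"""Two-compartment toxicokinetic model with irreversible receptor binding.

The organism is split into a bulk *structure* compartment that exchanges
ligand reversibly with the surrounding water (uptake rate ``k_u``,
first-order elimination ``k_e``) and a small *membrane-protein* (MP)
compartment holding the receptor pool (nAChRs), a mass fraction ``fms``
of the structure compartment.  Ligand in the structure compartment binds
free receptors by second-order mass action (rate ``k_on``); the reverse
dissociation rate ``k_off`` is zero for an irreversibly binding ligand,
which is what makes the receptor-bound residue resistant to depuration.

With ``C_structure`` (µmol/kg_structure) and ``C_MP`` (µmol/kg_MP) as
state variables and ``C_W(t)`` (µM) the piecewise-constant water
concentration, the dynamics are::

    dC_MP/dt        = k_on * C_structure * (B_max - C_MP) - k_off * C_MP
    dC_structure/dt = k_u * C_W(t) - k_e * C_structure - fms * dC_MP/dt

and the whole-body (total) concentration is approximated additively as
``C_total = C_structure + fms * C_MP``.

The free-receptor concentration is a derived quantity,
``N_R = B_max - C_MP``; the bound-receptor concentration is ``C_MP``
itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import ODEintWarning, odeint

from .units import DEFAULT_MOLAR_MASS, ug_per_l_to_um

__all__ = [
    "TKParameters",
    "ExposureScenario",
    "Trajectory",
    "simulate",
    "steady_state",
    "GPULEX_THIACLOPRID",
]


@dataclass(frozen=True)
class TKParameters:
    """Rate constants and binding capacity of the TK-receptor model.

    Parameters
    ----------
    k_u : float
        Uptake rate from water into the structure compartment,
        L kg_structure⁻¹ d⁻¹.
    k_e : float
        First-order elimination rate from the structure compartment, d⁻¹.
    k_on : float
        Second-order association rate of the ligand–receptor complex,
        kg_structure µmol⁻¹ d⁻¹.
    B_max : float
        Maximal receptor binding capacity, µmol kg_MP⁻¹.  Proxy for the
        receptor density of the membrane-protein fraction.
    k_off : float
        First-order dissociation rate of the complex, d⁻¹.  Zero for an
        irreversibly binding ligand (the default); a nonzero value is
        accepted but flagged with a warning because depuration from the
        MP compartment then becomes possible.
    fms : float
        Membrane-protein mass fraction of the organism,
        kg_MP kg_structure⁻¹ (default 0.01, i.e. 1 % MP content).
    """

    k_u: float
    k_e: float
    k_on: float
    B_max: float
    k_off: float = 0.0
    fms: float = 0.01

    def __post_init__(self) -> None:
        for name in ("k_u", "k_e", "k_on", "B_max", "k_off", "fms"):
            value = getattr(self, name)
            if not np.isfinite(value):
                raise ValueError(f"{name} must be finite, got {value}")
            if value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")
        if not 0.0 < self.fms < 1.0:
            raise ValueError(f"fms must lie in (0, 1), got {self.fms}")
        if self.k_off > 0:
            warnings.warn(
                "k_off > 0: the receptor-bound pool is no longer "
                "elimination-resistant; steady-state formulas assuming "
                "irreversible binding do not apply.",
                UserWarning,
                stacklevel=2,
            )

    @property
    def irreversible(self) -> bool:
        """True when binding is irreversible (``k_off == 0``)."""
        return self.k_off == 0.0

    @property
    def c_bmax(self) -> float:
        """Receptor capacity scaled to the whole organism, µmol/kg."""
        return self.B_max * self.fms

    def replace(self, **changes) -> "TKParameters":
        return replace(self, **changes)


#: Best-fit TK-receptor parameters for thiacloprid in *Gammarus pulex*
#: (irreversible binding; the association rate sits at the upper bound of
#: the calibration search space because in vivo binding is effectively
#: instantaneous relative to uptake).
GPULEX_THIACLOPRID = TKParameters(k_u=10.6, k_e=5.2, k_on=200.0, B_max=25.0)


@dataclass(frozen=True)
class ExposureScenario:
    """Piecewise-constant water-concentration schedule.

    ``intervals`` is an ordered tuple of ``(t_start, t_end, c_w)`` with
    times in days and concentrations in µM.  Intervals must be
    contiguous, non-overlapping, and start at ``t = 0``.
    """

    intervals: tuple[tuple[float, float, float], ...]
    molar_mass: float = DEFAULT_MOLAR_MASS

    def __post_init__(self) -> None:
        ivs = tuple((float(a), float(b), float(c)) for a, b, c in self.intervals)
        object.__setattr__(self, "intervals", ivs)
        if not ivs:
            raise ValueError("scenario needs at least one interval")
        if ivs[0][0] != 0.0:
            raise ValueError(f"first interval must start at t=0, got {ivs[0][0]}")
        for a, b, c in ivs:
            if not (np.isfinite(a) and np.isfinite(b) and np.isfinite(c)):
                raise ValueError("intervals must be finite")
            if a >= b:
                raise ValueError(f"interval ({a}, {b}) must have t_start < t_end")
            if c < 0:
                raise ValueError(f"water concentration must be >= 0, got {c}")
        for (a0, b0, _), (a1, _, _) in zip(ivs, ivs[1:]):
            if b0 != a1:
                raise ValueError(
                    f"intervals must be contiguous: gap/overlap between t={b0} and t={a1}"
                )
        if self.molar_mass <= 0:
            raise ValueError("molar_mass must be positive")

    # -- constructors -------------------------------------------------
    @classmethod
    def constant(
        cls, c_w_um: float, duration: float, molar_mass: float = DEFAULT_MOLAR_MASS
    ) -> "ExposureScenario":
        """Constant exposure at ``c_w_um`` µM for ``duration`` days."""
        return cls(((0.0, float(duration), float(c_w_um)),), molar_mass)

    @classmethod
    def uptake_elimination(
        cls,
        c_w_um: float,
        exposure_d: float,
        elimination_d: float,
        molar_mass: float = DEFAULT_MOLAR_MASS,
    ) -> "ExposureScenario":
        """Single uptake phase followed by clean-water elimination."""
        return cls.pulses(c_w_um, exposure_d, elimination_d, 1, molar_mass)

    @classmethod
    def pulses(
        cls,
        c_w_um: float,
        exposure_d: float,
        elimination_d: float,
        n_pulses: int,
        molar_mass: float = DEFAULT_MOLAR_MASS,
    ) -> "ExposureScenario":
        """``n_pulses`` cycles of exposure followed by clean water.

        The elimination medium is treated as exactly ligand-free
        (measured depuration media are below the limit of quantification).
        """
        if n_pulses < 1:
            raise ValueError(f"n_pulses must be >= 1, got {n_pulses}")
        if exposure_d <= 0 or elimination_d < 0:
            raise ValueError("phase durations must be positive")
        intervals = []
        t = 0.0
        for _ in range(int(n_pulses)):
            intervals.append((t, t + exposure_d, float(c_w_um)))
            t += exposure_d
            if elimination_d > 0:
                intervals.append((t, t + elimination_d, 0.0))
                t += elimination_d
        return cls(tuple(intervals), molar_mass)

    @classmethod
    def from_ug_per_l(
        cls,
        intervals_ug_l: Sequence[tuple[float, float, float]],
        molar_mass: float = DEFAULT_MOLAR_MASS,
    ) -> "ExposureScenario":
        """Build a scenario from intervals with concentrations in µg/L."""
        return cls(
            tuple((a, b, ug_per_l_to_um(c, molar_mass)) for a, b, c in intervals_ug_l),
            molar_mass,
        )

    # -- queries ------------------------------------------------------
    @property
    def t_end(self) -> float:
        return self.intervals[-1][1]

    @property
    def breakpoints(self) -> np.ndarray:
        return np.array([iv[0] for iv in self.intervals] + [self.t_end])

    def c_w(self, t: float) -> float:
        """Water concentration at time ``t`` (right-continuous in t)."""
        if t < 0 or t > self.t_end:
            raise ValueError(f"t={t} outside scenario span [0, {self.t_end}]")
        for a, b, c in self.intervals:
            if a <= t < b:
                return c
        return self.intervals[-1][2]


@dataclass
class Trajectory:
    """Time-resolved compartment concentrations from a simulation.

    Attributes
    ----------
    times : ndarray
        Sampling times, days.
    c_structure : ndarray
        Structure-compartment concentration, µmol/kg_structure.
    c_mp : ndarray
        Membrane-protein compartment concentration, µmol/kg_MP.
    c_total : ndarray
        Whole-body concentration ``c_structure + fms * c_mp``, µmol/kg.
    params : TKParameters
        Parameter set used to generate the trajectory.
    """

    times: np.ndarray
    c_structure: np.ndarray
    c_mp: np.ndarray
    c_total: np.ndarray
    params: TKParameters = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_d": self.times,
                "c_structure_umol_kg": self.c_structure,
                "c_mp_umol_kgMP": self.c_mp,
                "c_total_umol_kg": self.c_total,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _rhs(y, t, k_u, k_e, k_on, k_off, b_max, fms, c_w):
    c_s, c_mp = y
    d_mp = k_on * c_s * (b_max - c_mp) - k_off * c_mp
    d_s = k_u * c_w - k_e * c_s - fms * d_mp
    return (d_s, d_mp)


def _jac(y, t, k_u, k_e, k_on, k_off, b_max, fms, c_w):
    c_s, c_mp = y
    d_mp_d_s = k_on * (b_max - c_mp)
    d_mp_d_mp = -k_on * c_s - k_off
    return (
        (-k_e - fms * d_mp_d_s, -fms * d_mp_d_mp),
        (d_mp_d_s, d_mp_d_mp),
    )


def simulate(
    params: TKParameters,
    scenario: ExposureScenario,
    times: Sequence[float],
    initial_state: tuple[float, float] = (0.0, 0.0),
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the TK-receptor ODE system over an exposure scenario.

    The water forcing is discontinuous at scenario breakpoints, so the
    stiffness-switching LSODA integrator is restarted at every interval
    boundary rather than stepping across the discontinuity.

    Parameters
    ----------
    params, scenario
        Model parameters and piecewise-constant exposure schedule.
    times
        Strictly non-negative sampling grid (days) within the scenario
        span; need not include the breakpoints.
    initial_state
        ``(C_structure, C_MP)`` at ``t = 0``; both non-negative and
        ``C_MP <= B_max``.
    rtol, atol
        Relative / absolute solver tolerances.

    Returns
    -------
    Trajectory
        Concentrations at the requested times.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted ascending")
    if times[0] < 0 or times[-1] > scenario.t_end + 1e-12:
        raise ValueError(
            f"times must lie within the scenario span [0, {scenario.t_end}]"
        )
    c_s0, c_mp0 = float(initial_state[0]), float(initial_state[1])
    if not (np.isfinite(c_s0) and np.isfinite(c_mp0)):
        raise ValueError("initial state must be finite")
    if c_s0 < 0 or c_mp0 < 0:
        raise ValueError("initial state must be non-negative")
    if c_mp0 > params.B_max * (1 + 1e-12):
        raise ValueError(
            f"initial C_MP={c_mp0} exceeds the binding capacity B_max={params.B_max}"
        )

    out_s = np.empty_like(times)
    out_mp = np.empty_like(times)
    state = np.array([c_s0, min(c_mp0, params.B_max)])
    done = times <= 0.0
    out_s[done] = state[0]
    out_mp[done] = state[1]

    args = (
        params.k_u,
        params.k_e,
        params.k_on,
        params.k_off,
        params.B_max,
        params.fms,
        0.0,
    )
    for a, b, c_w in scenario.intervals:
        sel = (times > a) & (times <= b)
        if b < times[-1] or np.any(sel):
            t_pts = np.unique(np.concatenate(([a], times[sel], [b])))
            seg_args = args[:-1] + (c_w,)
            with warnings.catch_warnings():
                # solver failures are re-raised below with diagnostics;
                # the raw ODEintWarning would only duplicate them
                warnings.simplefilter("ignore", ODEintWarning)
                y, info = odeint(
                    _rhs,
                    state,
                    t_pts,
                    args=seg_args,
                    Dfun=_jac,
                    rtol=rtol,
                    atol=atol,
                    full_output=True,
                    mxstep=50_000,
                )
            if info["message"] != "Integration successful.":
                raise RuntimeError(
                    f"ODE solver failed on interval ({a}, {b}) at C_W={c_w}: "
                    f"{info['message']} (params={params})"
                )
            if np.any(sel):
                idx = np.searchsorted(t_pts, times[sel])
                out_s[sel] = y[idx, 0]
                out_mp[sel] = y[idx, 1]
            state = y[-1]
        if b >= times[-1]:
            break

    # LSODA respects the dynamics to within tolerance; clip the tiny
    # numerical overshoot of the saturation bound it can leave behind.
    tol = max(atol, rtol * params.B_max) * 10
    if np.any(out_mp > params.B_max + tol) or np.any(out_s < -tol):
        raise RuntimeError("solver output violates physical bounds beyond tolerance")
    out_mp = np.clip(out_mp, 0.0, params.B_max if params.B_max > 0 else 0.0)
    out_s = np.clip(out_s, 0.0, None)

    return Trajectory(
        times=times,
        c_structure=out_s,
        c_mp=out_mp,
        c_total=out_s + params.fms * out_mp,
        params=params,
    )


def steady_state(params: TKParameters, c_w_um: float) -> tuple[float, float]:
    """Asymptotic state under indefinite constant exposure (irreversible case).

    With ``k_off = 0`` the structure compartment relaxes to
    ``k_u / k_e * C_W`` and the receptor pool fills completely, so the MP
    compartment tends to ``B_max`` — regardless of how small ``C_W`` is,
    only the time to saturation changes.

    Raises
    ------
    ValueError
        If ``c_w_um <= 0`` (the MP steady state is then determined by the
        initial condition, not the exposure) or ``k_off != 0`` (the
        reversible steady state is not implemented).
    """
    if c_w_um <= 0:
        raise ValueError("steady state requires C_W > 0")
    if params.k_off != 0:
        raise ValueError("steady_state assumes irreversible binding (k_off = 0)")
    if params.k_e <= 0:
        raise ValueError("steady state requires k_e > 0")
    return params.k_u / params.k_e * c_w_um, params.B_max
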