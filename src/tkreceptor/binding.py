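"""In vitro receptor-binding assay: one-site saturation model and fitting.

A membrane-protein (MP) extract is incubated with the ligand at a series
of free concentrations ``C_free`` (nM) and the specifically bound amount
``C_bound`` (µmol/kg_MP) is measured.  Under equilibrium, one-site
specific binding follows the saturation isotherm::

    C_bound = B_max * C_free / (K_d + C_free)            (specific)
    C_bound = B_max * C_free / (K_d + C_free) + NS*C_free (+ unspecific)

``B_max`` (µmol/kg_MP) measures the receptor density of the MP fraction
(one specific binding site per receptor assumed) and ``K_d`` (nM) the
free-ligand concentration at half-maximal occupancy.  The fitted
``B_max`` can be scaled to a whole-organism receptor capacity via the MP
content of the organism and the MP recovery of the assay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import lmfit
import numpy as np
import pandas as pd

__all__ = [
    "BindingParameters",
    "BindingDataset",
    "specific_binding",
    "fit_binding",
    "scale_to_organism",
    "scatchard_transform",
    "GPULEX_BINDING",
    "ASSAY_LEVELS_NM",
    "SPECIFIC_FIT_WINDOW_NM",
    "MP_RECOVERY",
]

#: Assay concentration series (nM) used for the in vitro nAChR assay.
ASSAY_LEVELS_NM = (0.0, 2.5, 5.0, 10.0, 25.0, 50.0)

#: Upper free-concentration limit (nM) of the specific-only fit window;
#: above it unspecific membrane binding is no longer negligible.
SPECIFIC_FIT_WINDOW_NM = 25.0

#: MP recovery fraction across the in vitro assay work-up.
MP_RECOVERY = 0.24


@dataclass
class BindingParameters:
    """Fitted (or assumed) saturation-binding parameters.

    Attributes
    ----------
    b_max : float
        Maximal binding capacity, µmol/kg_MP.
    k_d : float
        Equilibrium dissociation constant, nM.
    ns : float
        Unspecific-binding slope, µmol kg_MP⁻¹ nM⁻¹ (0 = specific only).
    ci_95 : dict
        Per-parameter 95 % confidence intervals ``{name: (lo, hi)}``.
    r_squared : float or None
        Coefficient of determination of the fit.
    stderr : dict
        Per-parameter asymptotic standard errors.
    """

    b_max: float
    k_d: float
    ns: float = 0.0
    ci_95: dict = field(default_factory=dict)
    r_squared: float | None = None
    stderr: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.b_max <= 0:
            raise ValueError(f"b_max must be > 0, got {self.b_max}")
        if self.k_d <= 0:
            raise ValueError(f"k_d must be > 0, got {self.k_d}")
        if self.ns < 0:
            raise ValueError(f"ns must be >= 0, got {self.ns}")


#: One-site specific-binding parameters of thiacloprid on G. pulex
#: membrane protein.
GPULEX_BINDING = BindingParameters(b_max=5.7, k_d=0.41)


@dataclass
class BindingDataset:
    """In vitro assay observations.

    ``observations`` is a DataFrame with columns ``c_free_nM``,
    ``c_bound_umol_kgMP`` and ``replicate``.
    """

    observations: pd.DataFrame

    REQUIRED = ("c_free_nM", "c_bound_umol_kgMP", "replicate")

    def __post_init__(self) -> None:
        df = self.observations
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if (df["c_free_nM"] < 0).any():
            raise ValueError("c_free_nM must be >= 0")
        if (df["c_bound_umol_kgMP"] < 0).any():
            n = int((df["c_bound_umol_kgMP"] < 0).sum())
            warnings.warn(
                f"clamping {n} blank-corrected bound value(s) below 0 to 0",
                UserWarning,
                stacklevel=2,
            )
            df = df.copy()
            df.loc[df["c_bound_umol_kgMP"] < 0, "c_bound_umol_kgMP"] = 0.0
            self.observations = df

    @classmethod
    def from_arrays(
        cls,
        c_free_nm: Sequence[float],
        c_bound: Sequence[float],
        replicate: Sequence[int] | None = None,
    ) -> "BindingDataset":
        c_free_nm = np.asarray(c_free_nm, dtype=float)
        if replicate is None:
            replicate = np.zeros(len(c_free_nm), dtype=int)
        return cls(
            pd.DataFrame(
                {
                    "c_free_nM": c_free_nm,
                    "c_bound_umol_kgMP": np.asarray(c_bound, dtype=float),
                    "replicate": np.asarray(replicate),
                }
            )
        )

    @classmethod
    def from_csv(cls, path) -> "BindingDataset":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.observations.to_csv(path, index=False)

    @property
    def n_levels(self) -> int:
        return self.observations["c_free_nM"].nunique()


def specific_binding(c_free_nm, params: BindingParameters):
    """Bound concentration (µmol/kg_MP) at free concentration(s) in nM.

    Evaluates the one-site isotherm, plus the linear unspecific term when
    ``params.ns > 0``.  Accepts scalars or arrays.
    """
    c = np.asarray(c_free_nm, dtype=float)
    if np.any(c < 0):
        raise ValueError("C_free must be >= 0")
    out = params.b_max * c / (params.k_d + c) + params.ns * c
    return float(out) if np.isscalar(c_free_nm) else out


def _isotherm(c_free, b_max, k_d, ns):
    return b_max * c_free / (k_d + c_free) + ns * c_free


def fit_binding(
    data: BindingDataset,
    model: Literal["specific", "specific+unspecific"] = "specific",
    fit_window_nm: float | None = SPECIFIC_FIT_WINDOW_NM,
    weights: Sequence[float] | None = None,
) -> BindingParameters:
    """Least-squares fit of the saturation-binding model.

    Ordinary (unweighted) least squares on the natural concentration
    scale, the standard choice for saturation-binding isotherms; per-point
    ``weights`` can be supplied for variance weighting.  For the
    specific-only model the fit is restricted to free concentrations
    ``<= fit_window_nm`` (pass ``None`` to use all levels), because at
    higher concentrations the unspecific contribution is no longer
    negligible.  95 % confidence intervals are asymptotic
    (covariance-based, ±1.96 SE).

    Raises
    ------
    ValueError
        Degenerate design: fewer distinct concentration levels than free
        parameters + 1.
    RuntimeError
        Optimizer failure.
    """
    df = data.observations
    if model not in ("specific", "specific+unspecific"):
        raise ValueError(f"unknown model {model!r}")
    if model == "specific" and fit_window_nm is not None:
        df = df[df["c_free_nM"] <= fit_window_nm]
    c_free = df["c_free_nM"].to_numpy(dtype=float)
    c_bound = df["c_bound_umol_kgMP"].to_numpy(dtype=float)
    n_free_params = 2 if model == "specific" else 3
    n_levels = np.unique(c_free).size
    if n_levels < n_free_params + 1:
        raise ValueError(
            f"degenerate design: {n_levels} distinct concentration level(s), "
            f"need at least {n_free_params + 1}"
        )

    mod = lmfit.Model(_isotherm, independent_vars=["c_free"])
    pars = mod.make_params(
        b_max=dict(value=max(c_bound.max(), 1e-6), min=1e-9),
        k_d=dict(value=max(np.median(c_free[c_free > 0]), 1e-3), min=1e-9),
        ns=dict(value=0.0, min=0.0, vary=model == "specific+unspecific"),
    )
    w = None if weights is None else np.asarray(weights, dtype=float)
    result = mod.fit(c_bound, pars, c_free=c_free, weights=w)
    if not result.success:
        raise RuntimeError(f"binding fit did not converge: {result.message}")

    ss_res = float(np.sum((c_bound - result.best_fit) ** 2))
    ss_tot = float(np.sum((c_bound - c_bound.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    ci, se = {}, {}
    for name in ("b_max", "k_d", "ns"):
        p = result.params[name]
        if p.vary and p.stderr is not None:
            se[name] = float(p.stderr)
            ci[name] = (
                float(p.value - 1.96 * p.stderr),
                float(p.value + 1.96 * p.stderr),
            )
    return BindingParameters(
        b_max=float(result.params["b_max"].value),
        k_d=float(result.params["k_d"].value),
        ns=float(result.params["ns"].value),
        ci_95=ci,
        r_squared=r2,
        stderr=se,
    )


def scale_to_organism(b_max: float, fms: float, recovery: float = 1.0) -> float:
    """Scale an MP-normalized binding capacity to the whole organism.

    ``C_Bmax = B_max * fms / recovery`` (µmol/kg wet weight), where
    ``fms`` is the organism's MP mass fraction and ``recovery`` the MP
    recovery fraction of the assay work-up (1.0 when the capacity is
    already corrected for losses, e.g. a model-calibrated B_max).
    """
    if not 0 < fms < 1:
        raise ValueError(f"fms must lie in (0, 1), got {fms}")
    if not 0 < recovery <= 1:
        raise ValueError(f"recovery must lie in (0, 1], got {recovery}")
    if b_max < 0:
        raise ValueError("b_max must be >= 0")
    return b_max * fms / recovery


def scatchard_transform(data: BindingDataset) -> np.ndarray:
    """Scatchard linearization: points ``(C_bound, C_bound / C_free)``.

    For ideal one-site data the transformed points fall on a line of
    slope ``-1/K_d`` with x-intercept ``B_max`` — a quick visual check of
    whether the assay design covers the isotherm around ``K_d``.  Points
    with ``C_free = 0`` are dropped (with a warning) because the ratio is
    undefined there.
    """
    df = data.observations
    zero = df["c_free_nM"] == 0
    if zero.any():
        warnings.warn(
            f"dropping {int(zero.sum())} point(s) at C_free = 0 from the "
            "Scatchard transform",
            UserWarning,
            stacklevel=2,
        )
    df = df[~zero]
    if df.empty:
        return np.empty((0, 2))
    bound = df["c_bound_umol_kgMP"].to_numpy(dtype=float)
    free = df["c_free_nM"].to_numpy(dtype=float)
    return np.column_stack([bound, bound / free])
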