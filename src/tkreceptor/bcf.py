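"""Bioconcentration factors and regulatory-threshold extrapolation.

Three flavours of BCF are distinguished for a two-compartment organism
with an elimination-resistant, receptor-bound pool:

* ``bcf_ss_total``      — whole-body tissue / water ratio at the end of
  the uptake phase (apparent steady state).
* ``bcf_ss_structure``  — same ratio after subtracting the
  elimination-resistant residue measured at the end of depuration,
  i.e. the BCF of the reversibly exchanging structure compartment.
* ``bcf_kin_structure`` — kinetic structure BCF, the rate ratio
  ``k_u / k_e``.

Because the receptor pool saturates at ``fms * B_max`` independently of
the exposure level, the asymptotic whole-body BCF,
``k_u/k_e + fms * B_max / C_W``, grows without bound as the water
concentration decreases — which is what pushes the modelled BCF past
regulatory bioaccumulation thresholds at environmentally realistic
(ng/L) concentrations.
"""

from __future__ import annotations

import math
import warnings

from .model import TKParameters

__all__ = [
    "bcf_ss_total",
    "bcf_ss_structure",
    "bcf_kin_structure",
    "bcf_ss_total_model",
    "threshold_crossing_concentration",
    "propagate_ratio_sd",
]

#: Regulatory bioaccumulation thresholds (L/kg): the "bioaccumulative"
#: B criterion and the "very bioaccumulative" vB criterion.
B_CRITERION = 2000.0
VB_CRITERION = 5000.0


def bcf_ss_total(c_tissue_u: float, c_water_um: float) -> float:
    """Whole-body steady-state BCF, L/kg.

    Ratio of the measured total tissue concentration at the end of the
    uptake phase (µmol/kg) to the water concentration (µM).
    """
    if c_water_um <= 0:
        raise ValueError(f"water concentration must be > 0, got {c_water_um}")
    if c_tissue_u < 0:
        raise ValueError(f"tissue concentration must be >= 0, got {c_tissue_u}")
    return c_tissue_u / c_water_um


def bcf_ss_structure(
    c_tissue_u: float, c_tissue_e: float, c_water_um: float
) -> float:
    """Steady-state BCF of the structure compartment, L/kg.

    The elimination-resistant residue ``c_tissue_e`` (end of the
    depuration phase) is subtracted from the end-of-uptake concentration
    before taking the ratio to water.  If the residue exceeds the uptake
    concentration the (negative) value is still returned, with a warning,
    so that noisy replicate data do not silently disappear.
    """
    if c_water_um <= 0:
        raise ValueError(f"water concentration must be > 0, got {c_water_um}")
    if c_tissue_e < 0 or c_tissue_u < 0:
        raise ValueError("tissue concentrations must be >= 0")
    if c_tissue_e > c_tissue_u:
        warnings.warn(
            f"elimination-resistant residue ({c_tissue_e}) exceeds the "
            f"end-of-uptake concentration ({c_tissue_u}); returning a "
            "negative structure BCF",
            UserWarning,
            stacklevel=2,
        )
    return (c_tissue_u - c_tissue_e) / c_water_um


def bcf_kin_structure(params: TKParameters) -> float:
    """Kinetic BCF of the structure compartment, ``k_u / k_e`` (L/kg)."""
    if params.k_e <= 0:
        raise ValueError("kinetic BCF requires k_e > 0")
    return params.k_u / params.k_e


def bcf_ss_total_model(params: TKParameters, c_w_um: float) -> float:
    """Asymptotic whole-body BCF under indefinite constant exposure, L/kg.

    At true steady state the structure compartment contributes
    ``k_u/k_e`` and the saturated receptor pool contributes a fixed
    tissue concentration ``fms * B_max``, so::

        BCF(C_W) = k_u/k_e + fms * B_max / C_W

    which is concentration-dependent whenever ``B_max > 0``.
    """
    if c_w_um <= 0:
        raise ValueError(f"water concentration must be > 0, got {c_w_um}")
    if params.k_e <= 0:
        raise ValueError("requires k_e > 0")
    return params.k_u / params.k_e + params.fms * params.B_max / c_w_um


def threshold_crossing_concentration(
    params: TKParameters, threshold: float
) -> float | None:
    """Water concentration (µM) below which the model BCF exceeds ``threshold``.

    Solves ``k_u/k_e + fms * B_max / C_W = threshold`` for ``C_W``.
    Returns ``None`` when the BCF can never reach the threshold
    (``B_max = 0`` and ``k_u/k_e < threshold``) or always exceeds it
    (``k_u/k_e >= threshold``, where the formal crossing is infinite).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    kin = bcf_kin_structure(params)
    if kin >= threshold:
        return None  # above the threshold at every concentration
    if params.B_max == 0 or params.fms == 0:
        return None  # concentration-independent BCF below the threshold
    return params.fms * params.B_max / (threshold - kin)


def propagate_ratio_sd(
    num: float, num_sd: float, den: float, den_sd: float
) -> tuple[float, float]:
    """First-order error propagation for a ratio ``num / den``.

    Returns ``(ratio, sd)`` with
    ``sd = |ratio| * sqrt((num_sd/num)^2 + (den_sd/den)^2)``.
    """
    if den == 0:
        raise ValueError("denominator must be nonzero")
    if num_sd < 0 or den_sd < 0:
        raise ValueError("standard deviations must be >= 0")
    ratio = num / den
    if num == 0:
        # relative error of the numerator is undefined at 0; the ratio's
        # absolute error is then num_sd/den
        return ratio, num_sd / abs(den)
    sd = abs(ratio) * math.sqrt((num_sd / num) ** 2 + (den_sd / den) ** 2)
    return ratio, sd
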