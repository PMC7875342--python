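"""Model parameters.

All model constants of the five-species invasion-front system live here.
Units: lengths are domain units (1 domain unit = 100 cell diameters by the
default calibration, i.e. ``cell_diameter = 0.01``), times are hours,
densities are scaled to the respective carrying capacities.

The shipped defaults are this package's own calibration: they are chosen so
that (i) the tumor front traverses an O(1) fraction of the unit domain over
15 h, (ii) the microtube band spans about 6 cell diameters ahead of the
support edge, and (iii) the baseline run displays the characteristic front
pattern (protease halo ahead of the front, active-integrin plateau on the
microtube band).  They are a versioned default configuration, not a fit to
any particular experiment.
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["ModelParams", "PorosityMap"]


class PorosityMap(BaseModel):
    """Optional porosity-dependent tumor propagation speed.

    ECM density is mapped to porosity eps(x) = eps_min + (eps_max - eps_min)
    * (1 - E/E0) (clipped to the band), and the tumor saturation speed ramps
    smoothly from ``v_min`` at ``eps_min`` to ``v_max`` at ``eps_max``.  The
    default band [0.50, 0.66] places the minimum speed at 50% porosity and
    the maximum near 66%.
    """

    model_config = ConfigDict(extra="forbid")

    E0: float = Field(1.0, gt=0, description="reference (healthy) ECM density")
    eps_min: float = Field(0.50, ge=0)
    eps_max: float = Field(0.66, le=1)
    v_min: float = Field(0.02, gt=0)
    v_max: float = Field(0.032, gt=0)

    @model_validator(mode="after")
    def _check_band(self) -> "PorosityMap":
        if not self.eps_min < self.eps_max:
            raise ValueError("eps_min must be strictly below eps_max")
        if self.v_max < self.v_min:
            raise ValueError("v_max must be >= v_min")
        return self


class ModelParams(BaseModel):
    """Every constant of the coupled tumor / MMP1 / ECM / integrin system."""

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    # tumor flux saturation: J = nu_N * N * N_x / sqrt(m_N^2 + (nu_N/v_N)^2 N_x^2)
    nu_N: float = Field(0.008, ge=0, description="tumor viscosity-like coefficient")
    m_N: float = Field(1.0, gt=0, description="tumor flux-saturation constant")
    v_N: float = Field(0.02, gt=0, description="maximum tumor propagation speed [1/h]")
    # taxis and growth
    a1: float = Field(0.0005, ge=0, description="chemotactic sensitivity to MMP1 gradient")
    a2: float = Field(0.0005, ge=0, description="haptotactic sensitivity to active-integrin gradient")
    a3: float = Field(0.01, ge=0, description="logistic growth rate [1/h]")
    K_N: float = Field(1.0, gt=0, description="tumor carrying capacity")
    # protease flux saturation
    nu_P: float = Field(0.02, ge=0)
    m_P: float = Field(1.0, gt=0)
    v_P: float = Field(0.04, gt=0, description="maximum MMP1 propagation speed [1/h]")
    a4: float = Field(0.5, ge=0, description="MMP1 production rate on the TM band")
    a5: float = Field(0.4, ge=0, description="MMP1 degradation rate by tumor cells")
    # ECM
    a6: float = Field(0.5, ge=0, description="ECM degradation rate by MMP1")
    E0: float = Field(1.0, gt=0, description="healthy-tissue ECM density")
    E_basal: float = Field(0.1, ge=0, description="residual ECM level inside the tumor bulk")
    # integrins
    a7: float = Field(3.0, ge=0, description="integrin activation rate (ECM- and activity-dependent)")
    a8: float = Field(1.0, ge=0, description="integrin inactivation rate inside the support")
    a9: float = Field(3.0, ge=0, description="integrin exocytosis rate")
    K_I: float = Field(1.0, gt=0, description="integrin saturation level")
    v_Int: float = Field(0.02, ge=0, description="integrin transport speed [1/h]")
    transport_orientation: Literal["toward_front", "as_printed"] = "toward_front"
    # microtube band and activity functional
    h_p: float = Field(0.06, gt=0, description="maximum microtube length")
    eps_F: float = Field(0.3, gt=0, description="activity-functional regularisation")
    alpha_F: float = Field(1.0, ge=0, description="activity-functional exponent")
    # numerics-facing model constants
    delta_N: float = Field(1e-3, gt=0, description="support-detection threshold")
    # basal levels (imposed through initial conditions)
    A_basal: float = Field(0.2, ge=0, description="basal active integrins in the tumor bulk")
    I_basal: float = Field(0.4, ge=0, description="basal inactive integrins on the TM band")
    # scenario variants
    porosity: Optional[PorosityMap] = Field(
        None, description="enable the porosity-dependent tumor speed v_N(eps)"
    )
    reduced_model: bool = Field(
        False, description="tumor equation reduced to the flux-saturated term only"
    )

    @model_validator(mode="after")
    def _check(self) -> "ModelParams":
        if self.delta_N >= self.K_N:
            raise ValueError("delta_N must be below the carrying capacity K_N")
        return self
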