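"""Langevin force interpretation of drift-velocity profiles.

In the overdamped Langevin picture the viscous drag balances the applied
force, so the ensemble-averaged velocity obeys <xdot> = F/gamma: the drift
velocity is proportional to the mean force biasing the locus.  The drag
coefficient is estimated from the effective diffusion constant through the
Einstein relation gamma = k_B T / D — an order-of-magnitude assumption in
the active, viscoelastic cytoplasm, where fluctuations need not be purely
thermal; the resulting forces are therefore rough estimates, useful mainly
for comparison against reference scales such as the ~piconewton forces of
canonical cytoskeletal motors.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import constants

from .drift import DriftProfile

#: reference force scale of canonical molecular motors, N
MOTOR_REFERENCE_N = 1e-12

_UM2_PER_MIN_TO_M2_PER_S = 1e-12 / 60.0
_UM_PER_MIN_TO_M_PER_S = 1e-6 / 60.0


@dataclass(frozen=True)
class PhysicalContext:
    """Physical constants for relative-to-SI conversion.

    Temperature defaults to the 30 C growth temperature (303 K); the cell
    length (um) converts relative positions and velocities to physical
    units.  k_B T is computed from scipy's CODATA Boltzmann constant.
    """

    temperature_K: float = 303.0
    cell_length_um: float = 2.5
    dt_min: float = 1.0

    def __post_init__(self) -> None:
        if self.temperature_K <= 0:
            raise ValueError("temperature must be > 0 K")
        if self.cell_length_um <= 0:
            raise ValueError("cell length must be > 0 um")

    @property
    def kBT_J(self) -> float:
        return constants.k * self.temperature_K


@dataclass
class ForceProfile:
    """Force versus relative position, F(x) = gamma * v_phys(x)."""

    x: np.ndarray  # relative units (populated bins only)
    force_N: np.ndarray
    force_se_N: np.ndarray
    gamma_kg_s: float
    d_eff_m2_s: float
    peak_force_N: float
    interval: str | None
    annotation: str


def estimate_drag(d_phys_m2_s: float, context: PhysicalContext) -> float:
    """Viscous drag from the Einstein relation, gamma = k_B T / D (kg/s)."""
    if d_phys_m2_s <= 0:
        raise ValueError("effective diffusion constant must be > 0")
    return context.kBT_J / d_phys_m2_s


def force_profile(
    profile: DriftProfile,
    d_eff: float,
    context: PhysicalContext | None = None,
    cell_length_um: float | None = None,
) -> ForceProfile:
    """Convert a drift profile and effective diffusion constant to forces.

    ``d_eff`` is in (relative units)^2/min, as produced by the step
    summary for the same interval as ``profile``.  Conversion uses a
    single representative cell length L: v_phys = v * L, D_phys = D * L^2.
    ``cell_length_um`` overrides the context length (e.g. with the mean
    observed length from the track table).
    """
    context = context or PhysicalContext()
    L = cell_length_um if cell_length_um is not None else context.cell_length_um
    if L is None or not np.isfinite(L) or L <= 0:
        raise ValueError("physical conversion requires a positive cell length")
    d_phys = d_eff * L**2 * _UM2_PER_MIN_TO_M2_PER_S
    gamma = estimate_drag(d_phys, context)
    ok = profile.populated
    v_phys = profile.v[ok] * L * _UM_PER_MIN_TO_M_PER_S
    se_phys = profile.se[ok] * L * _UM_PER_MIN_TO_M_PER_S
    force = gamma * v_phys
    peak = float(np.max(np.abs(force))) if force.size else float("nan")
    annotation = (
        f"peak |F| = {peak:.3g} N = {peak / MOTOR_REFERENCE_N:.3g} pN "
        f"(reference: canonical molecular motors exert ~1 pN); assumes the "
        f"Einstein relation gamma = kBT/D with fluctuations not "
        f"significantly larger than thermal, gamma constant in space and "
        f"time, and a representative cell length L = {L:g} um"
    )
    return ForceProfile(
        x=profile.x_mean[ok],
        force_N=force,
        force_se_N=gamma * se_phys,
        gamma_kg_s=gamma,
        d_eff_m2_s=d_phys,
        peak_force_N=peak,
        interval=profile.interval,
        annotation=annotation,
    )
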