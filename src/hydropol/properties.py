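"""Property estimators from observable series.

These reconstruct, with standard textbook definitions, the measurements a
simulation study reads off equilibrium trajectories: integral heat of
adsorption from potential energies, thermal expansion from box length vs
temperature, heat capacity from enthalpy vs temperature, elastic moduli
from stress–strain slopes and Poisson's ratio from transverse vs axial
strain.  All slopes are ordinary least squares over the supplied window;
choosing the window (e.g. a small-strain regime) is the caller's job.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.stats import linregress

from .geometry import WATER_MOLAR_MASS

__all__ = [
    "SeriesKind",
    "ObservableSeries",
    "heat_of_adsorption",
    "thermal_expansion_coefficient",
    "heat_capacity",
    "modulus_from_stress_strain",
    "poissons_ratio",
]


class SeriesKind(str, enum.Enum):
    LENGTH_VS_TEMPERATURE = "length_vs_temperature"
    ENTHALPY_VS_TEMPERATURE = "enthalpy_vs_temperature"
    STRESS_VS_STRAIN = "stress_vs_strain"
    STRAIN_VS_STRAIN = "strain_vs_strain"
    ENERGY_VS_COUNT = "energy_vs_count"


@dataclass
class ObservableSeries:
    """A monotone-x observable series (T/strain/pressure vs H/L/stress/...)."""

    x: np.ndarray
    y: np.ndarray
    kind: SeriesKind | str = SeriesKind.STRESS_VS_STRAIN

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.x) != len(self.y):
            raise ValueError("x and y must have equal lengths")
        if len(self.x) < 3:
            raise ValueError("an observable series needs at least 3 points")
        dx = np.diff(self.x)
        if not (np.all(dx > 0) or np.all(dx < 0)):
            raise ValueError("x must be strictly monotone")
        self.kind = SeriesKind(self.kind)

    def slope(self) -> float:
        return float(linregress(self.x, self.y).slope)


def heat_of_adsorption(
    U_dry: float,
    U_hydrated: float,
    n_water: int,
    u_ref_vapor: float,
) -> float:
    """Integral heat of adsorption, kJ per kg of adsorbed water.

    Q = [U_dry + n_water·u_ref_vapor − U_hydrated] / (n_water · M_w)

    referenced to isolated vapor-phase water (``u_ref_vapor``, kJ/mol per
    molecule), so at large uptake Q tends to the bulk-water latent-heat
    scale.  The reference energy is a required input: its choice sets the
    absolute scale and must not be defaulted silently.
    """
    if n_water < 1:
        raise ValueError("n_water must be at least 1")
    released = U_dry + n_water * u_ref_vapor - U_hydrated  # kJ/mol basis
    return released / (n_water * WATER_MOLAR_MASS * 1e-3)


def thermal_expansion_coefficient(series: ObservableSeries, T0: float = 300.0) -> float:
    """Uniaxial thermal expansion α_X = (1/L(T0)) · dL/dT, 1/K.

    dL/dT is the least-squares slope of box length vs temperature and
    L(T0) the fitted length at the reference temperature, which must lie
    inside the fitted range.
    """
    if series.kind is not SeriesKind.LENGTH_VS_TEMPERATURE:
        raise ValueError("series must be box length vs temperature")
    if not (min(series.x) <= T0 <= max(series.x)):
        raise ValueError(f"T0={T0} lies outside the fitted temperature range")
    fit = linregress(series.x, series.y)
    L0 = fit.intercept + fit.slope * T0
    if L0 <= 0:
        raise ValueError("fitted length at T0 is non-positive")
    return float(fit.slope / L0)


def heat_capacity(series: ObservableSeries, mass: float) -> float:
    """Isobaric heat capacity C_p = (dH/dT)/mass, kJ/(kg K)."""
    if series.kind is not SeriesKind.ENTHALPY_VS_TEMPERATURE:
        raise ValueError("series must be enthalpy vs temperature")
    if mass <= 0:
        raise ValueError("mass must be positive")
    return series.slope() / mass


def modulus_from_stress_strain(
    series: ObservableSeries,
    max_strain: float,
    stress_unit: str = "GPa",
) -> float:
    """Elastic modulus (GPa) as the stress–strain slope for |ε| ≤ max_strain.

    The same estimator serves uniaxial (Young's), volumetric (bulk, with
    ε = ΔV/V and σ = −ΔP) and shear loadings; the loading protocol decides
    the interpretation.  ``stress_unit`` ("GPa" or "MPa") sets the input
    scale of σ.
    """
    if series.kind is not SeriesKind.STRESS_VS_STRAIN:
        raise ValueError("series must be stress vs strain")
    mask = np.abs(series.x) <= max_strain
    if int(mask.sum()) < 3:
        raise ValueError(
            f"strain window |eps| <= {max_strain} contains fewer than 3 points"
        )
    slope = float(linregress(series.x[mask], series.y[mask]).slope)
    scale = {"GPA": 1.0, "MPA": 1e-3}.get(stress_unit.upper())
    if scale is None:
        raise ValueError("stress_unit must be 'GPa' or 'MPa'")
    return slope * scale


def poissons_ratio(axial: ObservableSeries, transverse: ObservableSeries) -> float:
    """ν = −(slope of transverse vs axial strain), dimensionless."""
    if len(axial.x) != len(transverse.x) or not np.allclose(axial.x, transverse.x):
        raise ValueError("axial and transverse series must share the same grid")
    return -float(linregress(axial.y, transverse.y).slope)
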