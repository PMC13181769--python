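"""Permittivity -> composition -> excess interfacial mass density.

The chain quantifies interfacial solute enrichment from SPR-fitted
permittivities:

1. The Clausius-Mossotti (Lorentz-Lorenz) relation links the relative
   permittivity of a glycine solution to a density-weighted sum of the
   specific refractions of its components,

       (eps - 1) / (eps + 2) = rho(x) * [x * r_gly + (1 - x) * r_water],

   where ``x`` is the glycine mass fraction and ``rho(x)`` the solution
   mass density in g/cm^3.
2. ``rho(x)`` interpolates a packaged literature-derived property table
   up to the last tabulated composition and, beyond it (interfacial
   compositions can exceed saturation), extrapolates the apparent
   specific volume of glycine linearly toward the crystal density
   1.607 g/cm^3 at x = 1.
3. The excess interfacial mass density of an assumed layer of thickness
   ``t`` over a bulk of permittivity ``eps_bulk`` is

       Gamma = t * [rho(x_i) * x_i - rho(x_b) * x_b],

   reported in ng/cm^2.  Because the optical fit trades layer
   permittivity against assumed thickness, Gamma is approximately
   invariant to the choice of ``t``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.constants import Avogadro
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .errors import CalibrationError, DomainError, InversionError

__all__ = [
    "MOLAR_MASS_GLYCINE",
    "MOLAR_MASS_WATER",
    "RHO_WATER",
    "EPS_WATER",
    "RHO_GLYCINE_CRYSTAL",
    "SolutionComposition",
    "RefractionCalibration",
    "ExcessDensity",
    "cm_fraction",
    "load_property_table",
    "density_of_solution",
    "calibrate_refractions",
    "default_calibration",
    "eps_to_massfraction",
    "gamma_excess",
    "mass_to_number_density",
    "convert_gamma_units",
]

#: Glycine molar mass, g/mol.
MOLAR_MASS_GLYCINE = 75.07
#: Water molar mass, g/mol.
MOLAR_MASS_WATER = 18.015
#: Pure water mass density at 22 degC, g/cm^3.
RHO_WATER = 0.99777
#: Pure water relative permittivity at 632.8 nm.
EPS_WATER = 1.7770
#: alpha-glycine crystal mass density, g/cm^3.
RHO_GLYCINE_CRYSTAL = 1.607

_TABLE_NAME = "glycine_solution_properties.csv"


@dataclass(frozen=True)
class SolutionComposition:
    """Composition of an aqueous glycine solution.

    ``concentration`` follows the grams-solute-per-kilogram-of-water
    convention, so 250 g/kg corresponds to ``x_gly = 0.2``.
    """

    x_gly: float
    rho: float
    below_solvent: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.x_gly <= 1.0:
            raise DomainError("mass fraction must lie in [0, 1]")

    @property
    def concentration_g_per_kg(self) -> float:
        if self.x_gly >= 1.0:
            return float("inf")
        return 1000.0 * self.x_gly / (1.0 - self.x_gly)


@dataclass(frozen=True)
class RefractionCalibration:
    """Specific refractions (cm^3/g) of water and glycine plus provenance."""

    r_water: float
    r_gly: float
    eps_water: float
    rho_water: float
    source_points: tuple = ()

    def __post_init__(self) -> None:
        if self.r_water <= 0 or self.r_gly <= 0:
            raise CalibrationError("specific refractions must be positive")

    def cm_forward(self, x: float, rho: float) -> float:
        """Clausius-Mossotti fraction predicted for composition (x, rho)."""
        return rho * (x * self.r_gly + (1.0 - x) * self.r_water)


@dataclass(frozen=True)
class ExcessDensity:
    """Excess interfacial solute mass per unit area and derived quantities."""

    gamma_ng_cm2: float
    layer_thickness_nm: float
    x_interf: float
    x_bulk: float

    @property
    def gamma_ng_nm2(self) -> float:
        return convert_gamma_units(self.gamma_ng_cm2)

    @property
    def excess_molecules_per_nm3(self) -> float:
        """Excess glycine number density within the assumed layer."""
        rho_excess = self.gamma_ng_cm2 * 1e-9 / (self.layer_thickness_nm * 1e-7)
        return mass_to_number_density(rho_excess)


def cm_fraction(eps: float) -> float:
    """Clausius-Mossotti fraction ``(eps - 1) / (eps + 2)``.

    Strictly increasing in ``eps``; 0 for vacuum, -> 1 as eps -> inf.
    """
    eps = np.asarray(eps, dtype=float)
    if np.any(eps <= 0.0):
        raise DomainError("permittivity must be positive")
    out = (eps - 1.0) / (eps + 2.0)
    return float(out) if out.ndim == 0 else out


def load_property_table() -> pd.DataFrame:
    """Packaged (x_gly, rho, eps) table for aqueous glycine at 22 degC."""
    ref = importlib.resources.files("sprgamma.data").joinpath(_TABLE_NAME)
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, comment="#")


class _DensityModel:
    """Monotone interpolant of the table with crystal-anchored extension."""

    def __init__(self, table: pd.DataFrame | None = None):
        table = load_property_table() if table is None else table
        x = table["x_gly"].to_numpy(float)
        rho = table["rho_g_cm3"].to_numpy(float)
        self._interp = PchipInterpolator(x, rho)
        self.x_max = float(x[-1])
        rho_max = float(rho[-1])
        # apparent specific volume of glycine at the last tabulated point
        self._v_water = 1.0 / float(rho[0])
        self._v_app_max = (
            1.0 / rho_max - (1.0 - self.x_max) * self._v_water
        ) / self.x_max
        self._v_app_crystal = 1.0 / RHO_GLYCINE_CRYSTAL

    def __call__(self, x: float) -> float:
        if not 0.0 <= x <= 1.0:
            raise DomainError(f"mass fraction {x!r} outside [0, 1]")
        if x <= self.x_max:
            return float(self._interp(x))
        frac = (x - self.x_max) / (1.0 - self.x_max)
        v_app = self._v_app_max + frac * (self._v_app_crystal - self._v_app_max)
        return 1.0 / ((1.0 - x) * self._v_water + x * v_app)


_DENSITY_MODEL: _DensityModel | None = None


def _density_model() -> _DensityModel:
    global _DENSITY_MODEL
    if _DENSITY_MODEL is None:
        _DENSITY_MODEL = _DensityModel()
    return _DENSITY_MODEL


def density_of_solution(x_gly: float) -> float:
    """Solution mass density rho(x) in g/cm^3 at 22 degC.

    Interpolates the packaged table for tabulated compositions and
    extrapolates linearly in apparent specific volume to the glycine
    crystal density at x = 1.
    """
    return _density_model()(float(x_gly))


def calibrate_refractions(
    water_point: tuple[float, float],
    solution_points=(),
) -> RefractionCalibration:
    """Solve the Clausius-Mossotti system for the two specific refractions.

    ``water_point`` is ``(eps, rho)`` of pure water and fixes ``r_water``
    exactly; ``solution_points`` is an iterable of ``(eps, x_gly, rho)``
    rows and fixes ``r_gly`` by linear least squares.
    """
    eps_w, rho_w = water_point
    r_water = cm_fraction(eps_w) / rho_w
    pts = [tuple(map(float, p)) for p in solution_points]
    useful = [p for p in pts if p[1] > 0.0]
    if not useful:
        raise CalibrationError(
            "need at least one solution point with x_gly > 0"
        )
    a = np.array([rho * x for _, x, rho in useful])
    b = np.array(
        [cm_fraction(eps) - rho * (1.0 - x) * r_water for eps, x, rho in useful]
    )
    r_gly = float(a @ b / (a @ a))
    return RefractionCalibration(
        r_water=float(r_water),
        r_gly=r_gly,
        eps_water=float(eps_w),
        rho_water=float(rho_w),
        source_points=tuple(pts),
    )


_DEFAULT_CALIBRATION: RefractionCalibration | None = None


def default_calibration() -> RefractionCalibration:
    """Calibration built from the packaged property table."""
    global _DEFAULT_CALIBRATION
    if _DEFAULT_CALIBRATION is None:
        table = load_property_table()
        water = table.iloc[0]
        rest = table.iloc[1:]
        _DEFAULT_CALIBRATION = calibrate_refractions(
            (float(water["eps"]), float(water["rho_g_cm3"])),
            list(
                zip(rest["eps"], rest["x_gly"], rest["rho_g_cm3"], strict=True)
            ),
        )
    return _DEFAULT_CALIBRATION


def eps_to_massfraction(
    eps: float,
    calib: RefractionCalibration | None = None,
    xtol: float = 1e-12,
) -> SolutionComposition:
    """Invert permittivity to glycine mass fraction by bracketed root find.

    Solves ``cm_fraction(eps) == rho(x) * [x r_gly + (1-x) r_water]`` on
    [0, 1].  A permittivity below the calibration's pure-water value maps
    to x = 0 with the ``below_solvent`` flag set.
    """
    calib = default_calibration() if calib is None else calib
    target = cm_fraction(eps)
    model = _density_model()

    def g(x: float) -> float:
        return calib.cm_forward(x, model(x)) - target

    if g(0.0) >= 0.0:  # eps at or below the pure-solvent value
        return SolutionComposition(0.0, model(0.0), below_solvent=g(0.0) > 0)
    if g(1.0) < 0.0:
        raise InversionError(
            f"eps={eps:g} exceeds the pure-glycine limit; no root in [0, 1]"
        )
    x = brentq(g, 0.0, 1.0, xtol=xtol)
    return SolutionComposition(float(x), model(float(x)))


def gamma_excess(
    eps_interf: float,
    eps_bulk: float,
    t_nm: float = 1.0,
    calib: RefractionCalibration | None = None,
) -> ExcessDensity:
    """Excess interfacial mass density for an assumed layer thickness.

    ``Gamma = t * [rho(x_i) x_i - rho(x_b) x_b]`` in ng/cm^2.  Negative
    values (interfacial depletion) are reported as negative Gamma.
    """
    if not t_nm > 0:
        raise DomainError("layer thickness must be positive")
    comp_i = eps_to_massfraction(eps_interf, calib)
    comp_b = eps_to_massfraction(eps_bulk, calib)
    delta = comp_i.rho * comp_i.x_gly - comp_b.rho * comp_b.x_gly  # g/cm^3
    gamma = delta * (t_nm * 1e-7) * 1e9  # -> ng/cm^2
    return ExcessDensity(
        gamma_ng_cm2=float(gamma),
        layer_thickness_nm=float(t_nm),
        x_interf=comp_i.x_gly,
        x_bulk=comp_b.x_gly,
    )


def mass_to_number_density(
    mass_density_g_cm3: float, molar_mass: float = MOLAR_MASS_GLYCINE
) -> float:
    """Convert a mass density in g/cm^3 to molecules per nm^3."""
    if molar_mass <= 0:
        raise DomainError("molar mass must be positive")
    if mass_density_g_cm3 < 0:
        raise DomainError("mass density must be non-negative")
    return mass_density_g_cm3 * Avogadro / molar_mass * 1e-21


def convert_gamma_units(gamma_ng_cm2: float) -> float:
    """ng/cm^2 -> ng/nm^2 (1 cm^2 = 1e14 nm^2)."""
    return gamma_ng_cm2 * 1e-14
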