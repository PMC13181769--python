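"""Transfer-matrix reflectivity of a planar multilayer in the Kretschmann
configuration.

The model is the standard characteristic-matrix (Abelès) formulation for
p-polarized (transverse-magnetic) light incident from a semi-infinite
high-index prism onto a stack of homogeneous layers terminated by a
semi-infinite bulk liquid.  All angles are internal incidence angles at
the prism base, in degrees; all lengths are in nanometres.

Conventions
-----------
* Time dependence ``exp(-i omega t)``: absorbing media have a *positive*
  imaginary permittivity.
* The normal wavevector in each layer is the principal complex square
  root, sign-fixed so evanescent fields decay away from the prism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, DomainError, NoTIRError

__all__ = [
    "OpticalLayer",
    "LayerStack",
    "AngleScan",
    "reflectivity_tm",
    "transmissivity_tm",
    "simulate_scan",
    "tir_angle_analytic",
    "DEFAULT_WAVELENGTH_NM",
]

#: Default source wavelength (HeNe laser line), nm.
DEFAULT_WAVELENGTH_NM = 632.8


@dataclass(frozen=True)
class OpticalLayer:
    """One homogeneous layer of the stack.

    Parameters
    ----------
    label:
        Free-text name ("prism", "gold", "interfacial", "bulk", ...).
    eps:
        Complex relative permittivity at the working wavelength
        (``eps = n**2``).  The imaginary part must be >= 0.
    thickness_nm:
        Layer thickness in nm; ``None`` for the two semi-infinite
        terminal media.
    interfacial:
        Marks the (at most one) thin layer adjacent to the bulk whose
        permittivity the inversion stage fits.
    """

    label: str
    eps: complex
    thickness_nm: float | None = None
    interfacial: bool = False

    def __post_init__(self) -> None:
        eps = complex(self.eps)
        if eps.imag < 0:
            raise ConfigurationError(
                f"layer {self.label!r}: negative imaginary permittivity "
                f"({eps.imag:g}) violates the absorbing-medium convention"
            )
        if self.thickness_nm is not None and not self.thickness_nm > 0:
            raise ConfigurationError(
                f"layer {self.label!r}: internal layer thickness must be > 0"
            )


@dataclass(frozen=True)
class LayerStack:
    """Ordered multilayer from prism (first) to bulk liquid (last)."""

    layers: tuple[OpticalLayer, ...]
    wavelength_nm: float = DEFAULT_WAVELENGTH_NM

    def __post_init__(self) -> None:
        layers = tuple(self.layers)
        object.__setattr__(self, "layers", layers)
        if len(layers) < 2:
            raise ConfigurationError("a stack needs at least two media")
        if not self.wavelength_nm > 0:
            raise ConfigurationError("wavelength must be positive")
        for terminal in (layers[0], layers[-1]):
            if terminal.thickness_nm is not None:
                raise ConfigurationError(
                    f"terminal medium {terminal.label!r} must be semi-infinite"
                )
        for internal in layers[1:-1]:
            if internal.thickness_nm is None:
                raise ConfigurationError(
                    f"internal layer {internal.label!r} needs a thickness"
                )
        if sum(1 for l in layers if l.interfacial) > 1:
            raise ConfigurationError("at most one layer may be interfacial")

    @property
    def prism(self) -> OpticalLayer:
        return self.layers[0]

    @property
    def bulk(self) -> OpticalLayer:
        return self.layers[-1]

    def with_bulk(self, eps_bulk: complex) -> "LayerStack":
        """Return a copy whose bulk permittivity is replaced."""
        new = self.layers[:-1] + (replace(self.layers[-1], eps=eps_bulk),)
        return LayerStack(new, self.wavelength_nm)

    def with_interfacial_layer(
        self, eps: complex, thickness_nm: float, label: str = "interfacial"
    ) -> "LayerStack":
        """Return a copy with a thin layer inserted next to the bulk.

        If the stack already carries an interfacial layer it is replaced.
        """
        layers = tuple(l for l in self.layers if not l.interfacial)
        new_layer = OpticalLayer(label, eps, thickness_nm, interfacial=True)
        return LayerStack(
            layers[:-1] + (new_layer, layers[-1]), self.wavelength_nm
        )

    def without_interfacial_layer(self) -> "LayerStack":
        layers = tuple(l for l in self.layers if not l.interfacial)
        return LayerStack(layers, self.wavelength_nm)


@dataclass
class AngleScan:
    """Reflectivity versus internal incidence angle.

    ``angles_deg`` must be strictly increasing; reflectivity is
    dimensionless and, after normalization, confined to [0, 1].
    """

    angles_deg: np.ndarray
    reflectivity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.reflectivity = np.asarray(self.reflectivity, dtype=float)
        if self.angles_deg.shape != self.reflectivity.shape:
            raise ConfigurationError("angle and reflectivity lengths differ")
        if self.angles_deg.size < 10:
            raise ConfigurationError("an angle scan needs at least 10 points")
        if not np.all(np.diff(self.angles_deg) > 0):
            raise ConfigurationError("angles must be strictly increasing")

    def restricted(self, lo: float, hi: float) -> "AngleScan":
        """Sub-scan over ``lo <= angle <= hi`` (metadata shared)."""
        mask = (self.angles_deg >= lo) & (self.angles_deg <= hi)
        return AngleScan(
            self.angles_deg[mask], self.reflectivity[mask], dict(self.metadata)
        )


def _kz_and_q(stack: LayerStack, angles_deg: np.ndarray):
    """Normal wavevectors and TM admittances for each layer x angle."""
    theta = np.deg2rad(angles_deg)
    eps = np.array([complex(l.eps) for l in stack.layers])
    if abs(eps[0].imag) > 1e-12:
        raise ConfigurationError("the prism must be lossless")
    k0 = 2.0 * np.pi / stack.wavelength_nm
    kx = k0 * np.sqrt(eps[0].real) * np.sin(theta)
    kz = np.sqrt(eps[:, None] * k0**2 - kx[None, :] ** 2)
    # principal branch gives Im(kz) >= 0 for Im(eps) >= 0; enforce the
    # decaying-field sign on the branch cut (lossless evanescent case)
    kz = np.where(kz.imag < 0.0, -kz, kz)
    q = kz / eps[:, None]
    return kz, q


def _amplitudes(stack: LayerStack, angles_deg: np.ndarray):
    """Complex reflection and transmission amplitudes r_p, t_p."""
    kz, q = _kz_and_q(stack, angles_deg)
    n_angles = angles_deg.size
    m11 = np.ones(n_angles, dtype=complex)
    m12 = np.zeros(n_angles, dtype=complex)
    m21 = np.zeros(n_angles, dtype=complex)
    m22 = np.ones(n_angles, dtype=complex)
    for j, layer in enumerate(stack.layers[1:-1], start=1):
        delta = kz[j] * layer.thickness_nm
        c, s = np.cos(delta), np.sin(delta)
        a11, a12 = c, -1j * s / q[j]
        a21, a22 = -1j * q[j] * s, c
        m11, m12, m21, m22 = (
            m11 * a11 + m12 * a21,
            m11 * a12 + m12 * a22,
            m21 * a11 + m22 * a21,
            m21 * a12 + m22 * a22,
        )
    q0, qn = q[0], q[-1]
    num_r = q0 * (m11 + m12 * qn) - (m21 + m22 * qn)
    den = q0 * (m11 + m12 * qn) + (m21 + m22 * qn)
    r = num_r / den
    t = 2.0 * q0 / den
    return r, t, q0, qn


def _check_angles(angles_deg: np.ndarray) -> np.ndarray:
    angles_deg = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    if np.any(angles_deg <= 0.0) or np.any(angles_deg >= 90.0):
        raise DomainError("incidence angles must lie strictly in (0, 90) deg")
    return angles_deg


def reflectivity_tm(stack: LayerStack, angle_deg) -> np.ndarray | float:
    """p-polarized power reflectivity ``|r_p|**2``.

    ``angle_deg`` may be a scalar or an array; the return matches.
    """
    scalar = np.isscalar(angle_deg)
    angles = _check_angles(angle_deg)
    r, _, _, _ = _amplitudes(stack, angles)
    R = np.abs(r) ** 2
    return float(R[0]) if scalar else R


def transmissivity_tm(stack: LayerStack, angle_deg) -> np.ndarray | float:
    """p-polarized power transmissivity into the bulk medium.

    For a lossless stack below the critical angle, ``R + T == 1``.
    """
    scalar = np.isscalar(angle_deg)
    angles = _check_angles(angle_deg)
    _, t, q0, qn = _amplitudes(stack, angles)
    T = np.real(qn) / np.real(q0) * np.abs(t) ** 2
    return float(T[0]) if scalar else T


def simulate_scan(
    stack: LayerStack,
    angle_grid: Sequence[float] | np.ndarray,
    metadata: dict | None = None,
) -> AngleScan:
    """Noise-free synthetic angle scan over a strictly increasing grid."""
    grid = np.asarray(angle_grid, dtype=float)
    if not np.all(np.diff(grid) > 0):
        raise ConfigurationError("angle grid must be strictly increasing")
    refl = reflectivity_tm(stack, grid)
    meta = {"source": "synthetic", "wavelength_nm": stack.wavelength_nm}
    if metadata:
        meta.update(metadata)
    return AngleScan(grid, np.asarray(refl), meta)


def tir_angle_analytic(eps_prism: float, eps_bulk: float) -> float:
    """Critical angle ``arcsin(sqrt(eps_bulk / eps_prism))`` in degrees.

    Depends only on the two terminal media — the bulk refractive index is
    the sole liquid property it encodes.
    """
    if eps_prism <= 0 or eps_bulk <= 0:
        raise DomainError("permittivities must be positive")
    if eps_bulk >= eps_prism:
        raise NoTIRError(
            f"no total internal reflection: eps_bulk={eps_bulk:g} >= "
            f"eps_prism={eps_prism:g}"
        )
    return float(np.degrees(np.arcsin(np.sqrt(eps_bulk / eps_prism))))
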