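"""Invert angle scans into bulk and interfacial permittivities.

The default protocol is two-stage, mirroring how index-matched SPR pairs
are analyzed in practice:

* stage 1 fixes the bulk permittivity from the TIR edge (of the sample
  scan itself or, preferably, of its index-matched partner), because the
  edge depends only on the bulk index;
* stage 2 frees a single parameter — the permittivity of a thin
  interfacial layer of *assumed* thickness (default 1 nm) — and fits the
  plasmon-minimum region.

Because a thin layer's optical effect is governed approximately by the
product (eps_interf - eps_bulk) * t, the assumed thickness is not
identifiable from a single scan; downstream surface-excess estimates are
insensitive to it (see :mod:`sprgamma.thermo`).

``fit_full_curve`` generalizes to any small set of free stack parameters
via bounded least squares; jointly freeing the layer's permittivity and
thickness is refused as unidentifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .errors import (
    ConfigurationError,
    FitNonConvergedError,
    IdentifiabilityError,
)
from .features import (
    DEFAULT_SPR_WINDOW,
    DEFAULT_TIR_WINDOW,
    find_spr_minimum,
    find_tir_edge,
)
from .optics import AngleScan, LayerStack, OpticalLayer, reflectivity_tm

__all__ = [
    "InterfacialFit",
    "fit_bulk_eps",
    "fit_interfacial_eps",
    "fit_full_curve",
    "normalize_scan",
]

_EPS_TOL = 1e-6
_MAX_ITER = 200


@dataclass
class InterfacialFit:
    """Result of an interfacial-permittivity inversion."""

    eps_bulk: float
    eps_interf: float
    assumed_thickness_nm: float
    residual: float
    converged: bool
    mode: str = "curve"
    window: tuple[float, float] = DEFAULT_SPR_WINDOW
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.assumed_thickness_nm <= 0:
            raise ConfigurationError("assumed thickness must be positive")
        if self.residual < 0:
            raise ConfigurationError("residual must be non-negative")

    def to_record(self) -> dict:
        return {
            "eps_bulk": self.eps_bulk,
            "eps_interf": self.eps_interf,
            "assumed_thickness_nm": self.assumed_thickness_nm,
            "residual": self.residual,
            "converged": self.converged,
            "mode": self.mode,
            "window_deg": list(self.window),
        }


def normalize_scan(scan: AngleScan, plateau: tuple[float, float]) -> AngleScan:
    """Rescale reflectivity so the pre-edge plateau has unit mean.

    Raw SPR intensities are in arbitrary units; the plateau below the
    TIR edge is the natural normalization reference.
    """
    sub = scan.restricted(*plateau)
    if sub.reflectivity.size == 0:
        raise ConfigurationError("normalization plateau outside the scan")
    mean = float(sub.reflectivity.mean())
    if mean <= 0:
        raise ConfigurationError("non-positive plateau mean")
    return AngleScan(
        scan.angles_deg, scan.reflectivity / mean, dict(scan.metadata)
    )


def fit_bulk_eps(
    scan: AngleScan,
    eps_prism: float,
    window: tuple[float, float] = DEFAULT_TIR_WINDOW,
) -> float:
    """Stage 1: bulk permittivity from the TIR edge.

    ``eps_bulk = eps_prism * sin^2(theta_TIR)`` — the critical-angle
    relation inverted with a prism permittivity calibrated on the same
    chip, so edge-locator bias cancels.
    """
    theta = find_tir_edge(scan, window)
    return float(eps_prism * np.sin(np.radians(theta)) ** 2)


def _layered_stack(
    stack_without_layer: LayerStack,
    eps_bulk: float,
    eps_interf: float,
    t_nm: float,
) -> LayerStack:
    return stack_without_layer.with_bulk(eps_bulk).with_interfacial_layer(
        eps_interf, t_nm
    )


def fit_interfacial_eps(
    scan: AngleScan,
    stack_without_layer: LayerStack,
    eps_bulk: float,
    t_nm: float = 1.0,
    mode: str = "curve",
    window: tuple[float, float] = DEFAULT_SPR_WINDOW,
    bounds: tuple[float, float] = (1.0, 3.5),
) -> InterfacialFit:
    """Stage 2: single-parameter fit of the interfacial permittivity.

    Parameters
    ----------
    mode:
        ``"curve"`` minimizes the squared reflectivity mismatch over the
        SPR window; ``"feature"`` matches the extracted minimum angle
        only.  Both are bracketed scalar minimizations (tolerance 1e-6
        in permittivity, 200-iteration budget).
    """
    if t_nm <= 0:
        raise ConfigurationError("assumed thickness must be positive")
    if mode not in ("curve", "feature"):
        raise ConfigurationError(f"unknown fit mode {mode!r}")
    sub = scan.restricted(*window)
    if sub.angles_deg.size < 5:
        raise ConfigurationError("SPR window spans fewer than 5 scan points")

    if mode == "curve":

        def objective(eps_i: float) -> float:
            stack = _layered_stack(stack_without_layer, eps_bulk, eps_i, t_nm)
            model = reflectivity_tm(stack, sub.angles_deg)
            return float(np.mean((model - sub.reflectivity) ** 2))

    else:
        theta_obs = find_spr_minimum(scan, window)
        grid = np.arange(window[0], window[1] + 1e-9, 0.005)

        def objective(eps_i: float) -> float:
            stack = _layered_stack(stack_without_layer, eps_bulk, eps_i, t_nm)
            model = AngleScan(grid, reflectivity_tm(stack, grid))
            return (find_spr_minimum(model, window) - theta_obs) ** 2

    res = minimize_scalar(
        objective,
        bounds=bounds,
        method="bounded",
        options={"xatol": _EPS_TOL, "maxiter": _MAX_ITER},
    )
    converged = bool(res.success)
    if not converged:
        raise FitNonConvergedError(
            f"interfacial fit did not converge within {_MAX_ITER} iterations"
        )
    rms = float(np.sqrt(res.fun)) if mode == "curve" else float(np.sqrt(res.fun))
    return InterfacialFit(
        eps_bulk=float(eps_bulk),
        eps_interf=float(res.x),
        assumed_thickness_nm=float(t_nm),
        residual=rms,
        converged=converged,
        mode=mode,
        window=window,
        details={"iterations": int(res.nfev)},
    )


# --- full-curve fitting -------------------------------------------------

#: Free parameters fit_full_curve understands.
_FREE_PARAMS = (
    "metal_thickness",
    "metal_eps_real",
    "metal_eps_imag",
    "bulk_eps",
    "layer_eps",
    "layer_thickness",
)


def _metal_index(stack: LayerStack) -> int:
    for j, layer in enumerate(stack.layers[1:-1], start=1):
        if complex(layer.eps).real < 0:
            return j
    raise ConfigurationError("stack has no metal film (Re eps < 0)")


def _apply_params(stack: LayerStack, params: dict) -> LayerStack:
    layers = list(stack.layers)
    if any(k.startswith("metal") for k in params):
        j = _metal_index(stack)
        metal = layers[j]
        eps = complex(metal.eps)
        eps = complex(
            params.get("metal_eps_real", eps.real),
            params.get("metal_eps_imag", eps.imag),
        )
        layers[j] = replace(
            metal,
            eps=eps,
            thickness_nm=params.get("metal_thickness", metal.thickness_nm),
        )
    if "bulk_eps" in params:
        layers[-1] = replace(layers[-1], eps=params["bulk_eps"])
    if "layer_eps" in params or "layer_thickness" in params:
        idx = [j for j, l in enumerate(layers) if l.interfacial]
        if not idx:
            raise ConfigurationError("stack has no interfacial layer to free")
        j = idx[0]
        layers[j] = replace(
            layers[j],
            eps=params.get("layer_eps", layers[j].eps),
            thickness_nm=params.get(
                "layer_thickness", layers[j].thickness_nm
            ),
        )
    return LayerStack(tuple(layers), stack.wavelength_nm)


def fit_full_curve(
    scan: AngleScan,
    stack: LayerStack,
    free_parameters: dict[str, tuple[float, float]],
    window: tuple[float, float] | None = None,
) -> InterfacialFit:
    """Bounded least-squares fit of up to three stack parameters.

    ``free_parameters`` maps parameter names (see module source for the
    recognized set) to (lower, upper) bounds.  The mid-point of each
    bound pair seeds the optimizer, so identical inputs give identical
    fits.  Jointly freeing ``layer_eps`` and ``layer_thickness`` raises
    :class:`IdentifiabilityError` (the two only enter through their
    product for nanometric layers); other degeneracies are detected from
    the Jacobian conditioning and flagged in ``details``.
    """
    names = list(free_parameters)
    for name in names:
        if name not in _FREE_PARAMS:
            raise ConfigurationError(f"unknown free parameter {name!r}")
    if len(names) > 3:
        raise ConfigurationError("at most 3 simultaneously free parameters")
    if "layer_eps" in names and "layer_thickness" in names:
        raise IdentifiabilityError(
            "layer permittivity and thickness cannot be decoupled from a "
            "single angle scan"
        )
    sub = scan if window is None else scan.restricted(*window)

    def model_refl(values: np.ndarray) -> np.ndarray:
        params = dict(zip(names, values))
        return reflectivity_tm(_apply_params(stack, params), sub.angles_deg)

    base_residual = float(
        np.sqrt(np.mean((model_refl(np.empty(0)) - sub.reflectivity) ** 2))
    ) if not names else None

    bulk0 = complex(stack.bulk.eps).real
    layer = next((l for l in stack.layers if l.interfacial), None)
    if not names:
        return InterfacialFit(
            eps_bulk=bulk0,
            eps_interf=complex(layer.eps).real if layer else bulk0,
            assumed_thickness_nm=layer.thickness_nm if layer else 1.0,
            residual=base_residual,
            converged=True,
            mode="full_curve",
            window=(float(sub.angles_deg[0]), float(sub.angles_deg[-1])),
            details={"free": []},
        )

    lower = np.array([free_parameters[n][0] for n in names], dtype=float)
    upper = np.array([free_parameters[n][1] for n in names], dtype=float)
    x0 = 0.5 * (lower + upper)

    def residuals(values: np.ndarray) -> np.ndarray:
        return model_refl(values) - sub.reflectivity

    res = least_squares(
        residuals, x0, bounds=(lower, upper), xtol=1e-12, ftol=1e-12
    )
    if not res.success:
        raise FitNonConvergedError("full-curve fit failed to converge")

    jac = res.jac
    _, sing, _ = np.linalg.svd(jac, full_matrices=False)
    cond = float(sing[0] / sing[-1]) if sing[-1] > 0 else np.inf
    dof = max(sub.reflectivity.size - len(names), 1)
    sigma2 = float(2 * res.cost / dof)
    try:
        cov = sigma2 * np.linalg.pinv(jac.T @ jac)
    except np.linalg.LinAlgError:  # pragma: no cover
        cov = np.full((len(names), len(names)), np.nan)

    fitted = dict(zip(names, map(float, res.x)))
    final = _apply_params(stack, fitted)
    final_layer = next((l for l in final.layers if l.interfacial), None)
    return InterfacialFit(
        eps_bulk=complex(final.bulk.eps).real,
        eps_interf=(
            complex(final_layer.eps).real
            if final_layer
            else complex(final.bulk.eps).real
        ),
        assumed_thickness_nm=(
            final_layer.thickness_nm if final_layer else 1.0
        ),
        residual=float(np.sqrt(np.mean(res.fun**2))),
        converged=True,
        mode="full_curve",
        window=(float(sub.angles_deg[0]), float(sub.angles_deg[-1])),
        details={
            "free": names,
            "fitted": fitted,
            "covariance": cov.tolist(),
            "jacobian_condition": cond,
            "ill_conditioned": cond > 1e8,
        },
    )
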