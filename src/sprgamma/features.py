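"""Characteristic-angle extraction from SPR angle scans.

Two features carry the physics: the total-internal-reflection edge
``theta_TIR`` (depends only on the bulk liquid's refractive index) and
the plasmon-coupling minimum ``theta_SPR`` (additionally sensitive to
any nanoscale layer at the metal-liquid interface).  Comparing the two
between a solution and an index-matched reference isolates the
interfacial layer.

The edge is operationally defined as the maximum of the first derivative
of reflectivity with respect to angle, refined by a local quadratic fit
so the resolution is finer than the grid spacing.  The minimum is the
interior sample minimum refined by quadratic interpolation through its
neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FeatureNotFoundError
from .optics import AngleScan

__all__ = [
    "ScanFeatures",
    "DEFAULT_TIR_WINDOW",
    "DEFAULT_SPR_WINDOW",
    "find_tir_edge",
    "find_spr_minimum",
    "extract_features",
    "calibrate_prism",
]

#: Default angular search window for the TIR edge, degrees.
DEFAULT_TIR_WINDOW = (48.0, 52.0)
#: Default angular search window for the SPR minimum, degrees.
DEFAULT_SPR_WINDOW = (60.0, 66.0)


@dataclass(frozen=True)
class ScanFeatures:
    theta_tir: float
    theta_spr: float
    theta_tir_uncertainty: float = 0.0
    theta_spr_uncertainty: float = 0.0

    def __post_init__(self) -> None:
        if self.theta_tir_uncertainty < 0 or self.theta_spr_uncertainty < 0:
            raise ValueError("uncertainties must be non-negative")


def _parabola_vertex(x: np.ndarray, y: np.ndarray) -> float:
    """Vertex abscissa of the least-squares parabola through (x, y)."""
    x0 = x.mean()
    coeffs = np.polyfit(x - x0, y, 2)
    a, b = coeffs[0], coeffs[1]
    if a == 0.0:
        return float(x0)
    return float(x0 - b / (2.0 * a))


def find_tir_edge(
    scan: AngleScan,
    window: tuple[float, float] = DEFAULT_TIR_WINDOW,
    refine_points: int = 3,
    min_slope: float = 0.05,
) -> float:
    """Angle of the reflectivity edge (max positive slope) in ``window``.

    The edge is located in two steps: a Savitzky-Golay-smoothed
    derivative finds the neighbourhood of the maximum slope robustly
    against reflectivity noise, then the raw finite-difference
    derivative is re-maximized within +-2 samples and refined by a
    local quadratic fit, giving sub-grid resolution on clean data.
    Raises :class:`FeatureNotFoundError` when no positive-slope edge
    lies in the interior of the window.
    """
    from scipy.signal import savgol_filter

    sub = scan.restricted(*window)
    n = sub.angles_deg.size
    if n < 5:
        raise FeatureNotFoundError(
            f"TIR window {window} spans fewer than 5 scan points"
        )
    step = float(np.median(np.diff(sub.angles_deg)))
    sg_window = min(11, n if n % 2 == 1 else n - 1)
    smooth_deriv = savgol_filter(
        sub.reflectivity, sg_window, polyorder=2, deriv=1, delta=step
    )
    i0 = int(np.argmax(smooth_deriv))
    if smooth_deriv[i0] < min_slope:
        # a genuine TIR edge is steep; a slowly varying curve (e.g. no
        # index contrast, hence no critical angle) is not an edge
        raise FeatureNotFoundError(
            f"steepest slope {smooth_deriv[i0]:.3g}/deg below the edge "
            f"threshold {min_slope:g}/deg"
        )
    deriv = np.gradient(sub.reflectivity, sub.angles_deg)
    lo0, hi0 = max(1, i0 - 2), min(n - 1, i0 + 3)
    i = lo0 + int(np.argmax(deriv[lo0:hi0]))
    if deriv[i] <= 0.0:
        raise FeatureNotFoundError("no positive-slope edge in the TIR window")
    if i == 0 or i == n - 1:
        raise FeatureNotFoundError("TIR edge lies at the window boundary")
    half = max(1, refine_points // 2)
    lo, hi = max(0, i - half), min(n, i + half + 1)
    vertex = _parabola_vertex(sub.angles_deg[lo:hi], deriv[lo:hi])
    # a vertex outside the refinement neighbourhood means the quadratic
    # model is inapplicable; fall back to the sample maximum
    if not sub.angles_deg[lo] <= vertex <= sub.angles_deg[hi - 1]:
        vertex = float(sub.angles_deg[i])
    return vertex


def find_spr_minimum(
    scan: AngleScan,
    window: tuple[float, float] = DEFAULT_SPR_WINDOW,
    fit_halfwidth: float = 1.5,
    max_iter: int = 20,
) -> float:
    """Angle of the reflectivity minimum in ``window``.

    The plasmon dip is broad and flat near its bottom, so a quadratic is
    fitted by least squares to the raw reflectivity over
    ``+-fit_halfwidth`` degrees and the fit window is re-centred on the
    fitted vertex until self-consistent.  The fixed point is independent
    of where the initial (smoothed-argmin) guess lands, which makes the
    estimator stable under reflectivity noise while remaining exact on
    polynomial dips.  Ties in the discrete minimum resolve to the
    smallest angle.  Raises :class:`FeatureNotFoundError` when the
    minimum sits on the window boundary (no local minimum inside).
    """
    from scipy.signal import savgol_filter

    sub = scan.restricted(*window)
    a, r = sub.angles_deg, sub.reflectivity
    n = a.size
    if n < 3:
        raise FeatureNotFoundError(
            f"SPR window {window} spans fewer than 3 scan points"
        )
    if n >= 5:
        sg_window = min(31, n if n % 2 == 1 else n - 1)
        smooth = savgol_filter(r, sg_window, polyorder=2)
    else:
        smooth = r
    i = int(np.argmin(smooth))  # argmin takes the first of ties
    if i == 0 or i == n - 1:
        raise FeatureNotFoundError(
            "reflectivity minimum lies at the SPR window boundary"
        )
    center = float(a[i])
    vertex = center
    for _ in range(max_iter):
        mask = (a >= center - fit_halfwidth) & (a <= center + fit_halfwidth)
        x, y = a[mask], r[mask]
        if x.size < 5:
            return float(a[i])
        x0 = x.mean()
        coeffs = np.polyfit(x - x0, y, 2)
        if coeffs[0] <= 0:  # no upward curvature: fall back to the sample
            return float(a[i])
        vertex = float(np.clip(x0 - coeffs[1] / (2 * coeffs[0]), a[0], a[-1]))
        if abs(vertex - center) < 1e-9:
            break
        center = vertex
    return vertex


def extract_features(
    scan: AngleScan,
    tir_window: tuple[float, float] = DEFAULT_TIR_WINDOW,
    spr_window: tuple[float, float] = DEFAULT_SPR_WINDOW,
) -> ScanFeatures:
    """Both characteristic angles with grid-spacing-based uncertainties."""
    theta_tir = find_tir_edge(scan, tir_window)
    theta_spr = find_spr_minimum(scan, spr_window)
    step = float(np.median(np.diff(scan.angles_deg)))
    return ScanFeatures(
        theta_tir=theta_tir,
        theta_spr=theta_spr,
        theta_tir_uncertainty=step / 2.0,
        theta_spr_uncertainty=step / 2.0,
    )


def calibrate_prism(
    reference_scan: AngleScan,
    eps_bulk_known: float,
    window: tuple[float, float] = DEFAULT_TIR_WINDOW,
) -> float:
    """Effective prism permittivity from a reference liquid of known eps.

    Inverts the critical-angle relation:
    ``eps_prism = eps_bulk_known / sin^2(theta_TIR)``, with theta_TIR
    extracted from the reference scan.  This maps instrument angles onto
    internal angles with a single chip-level parameter.
    """
    theta_tir = find_tir_edge(reference_scan, window)
    return float(eps_bulk_known / np.sin(np.radians(theta_tir)) ** 2)
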