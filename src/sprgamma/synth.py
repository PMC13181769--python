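"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here: Kretschmann
chips with chip-to-chip parameter spread, noisy angle-scan pairs sharing
an exactly index-matched bulk, and wall-enriched solution-film density
profiles (analytic or realized as seeded particle positions).  Every
generator is a pure function of its parameters and seed, and records
the generating truth in the output metadata so recovery tests can close
the loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import presets
from .errors import ConfigurationError, DomainError
from .optics import AngleScan, LayerStack, OpticalLayer, simulate_scan
from .profiles import DensityProfile, ParticleFrame, SPECIES_MASSES

__all__ = [
    "SyntheticTruth",
    "make_chip",
    "synth_scan_pair",
    "FilmSpec",
    "synth_profile",
    "enriched_film_spec",
    "matched_particle_counts",
    "realize_particles",
    "FILM_FAMILY",
]

#: (n_solute, n_solvent, film width nm) for the reference film family —
#: 250 g/kg solutions whose width grows with the molecule count.
FILM_FAMILY = (
    (15, 250, 2.55),
    (30, 500, 4.65),
    (60, 1000, 8.80),
    (90, 1500, 12.95),
)

#: Default periodic cross-section of the film box, nm^2 (2.05 x 2.05).
DEFAULT_AREA_NM2 = 2.05 * 2.05


@dataclass(frozen=True)
class SyntheticTruth:
    """Generating parameters recorded alongside every synthetic output."""

    parameters: dict
    seed: int | None
    noise_sigma: float = 0.0

    def as_metadata(self) -> dict:
        return {
            "truth": dict(self.parameters),
            "seed": self.seed,
            "noise_sigma": self.noise_sigma,
        }


def make_chip(
    seed: int | None = None,
    surface: str = "gold",
    metal_thickness_range: tuple[float, float] = (46.0, 50.0),
    ps_thickness_range: tuple[float, float] = (20.0, 30.0),
    metal_eps_jitter: float = 0.02,
    eps_bulk: float = 1.8489,
) -> LayerStack:
    """A randomized sensor chip emulating chip-to-chip variation.

    The metal-film thickness is drawn uniformly from
    ``metal_thickness_range`` and its permittivity jittered by a
    relative ``metal_eps_jitter``; polystyrene-coated chips additionally
    draw the coat thickness.  ``seed=None`` returns the calibrated
    reference chip unchanged.
    """
    if seed is None:
        return presets.default_chip(surface=surface, eps_bulk=eps_bulk)
    rng = np.random.default_rng(seed)
    d_metal = rng.uniform(*metal_thickness_range)
    eps0 = presets.EPS_GOLD_DEFAULT
    eps_metal = complex(
        eps0.real * (1.0 + metal_eps_jitter * rng.standard_normal()),
        abs(eps0.imag * (1.0 + metal_eps_jitter * rng.standard_normal())),
    )
    ps_t = rng.uniform(*ps_thickness_range)
    return presets.default_chip(
        surface=surface,
        eps_bulk=eps_bulk,
        metal_thickness_nm=d_metal,
        eps_metal=eps_metal,
        ps_thickness_nm=ps_t,
    )


def synth_scan_pair(
    chip: LayerStack,
    eps_bulk: float,
    eps_interf: float,
    t_nm: float = 1.0,
    noise_sigma: float = 0.002,
    angle_grid=None,
    seed: int | None = 0,
) -> tuple[AngleScan, AngleScan]:
    """(sample, index-matched reference) scans from one chip.

    Both scans share ``eps_bulk`` exactly — perfect index matching; only
    the sample carries the interfacial layer.  Additive Gaussian
    reflectivity noise is applied independently to each, the result is
    clipped to [0, 1] and the clip rate recorded in the metadata.
    """
    if not (eps_interf >= eps_bulk >= 1.0):
        raise DomainError("need eps_interf >= eps_bulk >= 1")
    if angle_grid is None:
        angle_grid = np.arange(45.0, 70.0, 0.01)
    bare = chip.without_interfacial_layer().with_bulk(eps_bulk)
    layered = bare.with_interfacial_layer(eps_interf, t_nm)
    truth = SyntheticTruth(
        parameters={
            "eps_bulk": eps_bulk,
            "eps_interf": eps_interf,
            "t_nm": t_nm,
        },
        seed=seed,
        noise_sigma=noise_sigma,
    )
    rng = np.random.default_rng(seed)
    out = []
    for stack, label in ((layered, "sample"), (bare, "reference")):
        scan = simulate_scan(stack, angle_grid)
        refl = scan.reflectivity
        if noise_sigma > 0:
            refl = refl + noise_sigma * rng.standard_normal(refl.shape)
        clipped = np.clip(refl, 0.0, 1.0)
        clip_rate = float(np.mean(clipped != refl))
        meta = scan.metadata | truth.as_metadata() | {
            "sample": label,
            "clip_rate": clip_rate,
        }
        out.append(AngleScan(scan.angles_deg, clipped, meta))
    return out[0], out[1]


# --- density profiles ---------------------------------------------------


@dataclass(frozen=True)
class FilmSpec:
    """Analytic description of a wall-bounded solution film.

    The solute density is ``bulk + sum of Gaussian peaks`` multiplied by
    a smooth film-edge cutoff; the solvent is depleted one-for-one where
    the solute is enriched and decays to zero at the film-vacuum edge.
    The edge sigmoid is positioned so the solvent density crosses the
    0.1 g/cm^3 film-width criterion exactly at ``film_width_nm``.
    """

    film_width_nm: float
    peaks: tuple = ()  # (center_nm, sigma_nm, amplitude_g_cm3)
    bulk_solute: float = 0.216
    bulk_solvent: float = 0.90
    area_nm2: float = DEFAULT_AREA_NM2
    edge_sharpness_nm: float = 0.05
    edge_threshold: float = 0.1

    def __post_init__(self) -> None:
        if not self.film_width_nm > 0:
            raise DomainError("film width must be positive")
        for c, w, a in self.peaks:
            if a < 0 or w <= 0:
                raise DomainError("peak amplitude/width must be positive")
            if not 0.0 <= c <= self.film_width_nm:
                raise DomainError(
                    f"peak at {c} nm lies outside the {self.film_width_nm} nm film"
                )

    def _edge(self, z: np.ndarray) -> np.ndarray:
        s = self.edge_sharpness_nm
        # place the sigmoid so bulk_solvent * edge(film_width) == threshold
        ratio = self.bulk_solvent / self.edge_threshold - 1.0
        if ratio <= 0:
            raise DomainError("edge threshold must be below the solvent bulk")
        z0 = self.film_width_nm - s * np.log(ratio)
        return 1.0 / (1.0 + np.exp((z - z0) / s))

    def solute_density(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        rho = np.full_like(z, self.bulk_solute)
        for c, w, a in self.peaks:
            rho = rho + a * np.exp(-0.5 * ((z - c) / w) ** 2)
        return np.clip(rho * self._edge(z), 0.0, None)

    def solvent_density(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        enrich = self.solute_density(z) - self.bulk_solute * self._edge(z)
        rho = self.bulk_solvent * self._edge(z) - enrich
        return np.clip(rho, 0.0, None)


def synth_profile(
    spec: FilmSpec,
    bin_width_nm: float = 0.05,
    z_max_nm: float | None = None,
) -> DensityProfile:
    """Exact binned profile of an analytic film (bin-center evaluation)."""
    if z_max_nm is None:
        z_max_nm = spec.film_width_nm + 1.5
    n_bins = int(np.ceil(z_max_nm / bin_width_nm))
    edges = np.arange(n_bins + 1) * bin_width_nm
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(
        edges,
        {
            "solute": spec.solute_density(centers),
            "solvent": spec.solvent_density(centers),
        },
        spec.area_nm2,
    )


def enriched_film_spec(
    film_width_nm: float = 12.95,
    interfacial_average_target: float | None = 1.0,
    bulk_solute: float = 0.216,
    bulk_solvent: float = 0.90,
) -> FilmSpec:
    """Near-wall-enriched film preset.

    Two strong sub-nanometre solute peaks (0.35 and 0.70 nm from the
    wall) plus a weaker peak at 1.2 nm, over a solute-depleted solvent.
    When ``interfacial_average_target`` is given, the peak amplitudes
    are scaled so the solute density averaged over the first nanometre
    equals it exactly (default 1.0 g/cm^3).
    """
    base_peaks = [(0.35, 0.12, 1.5), (0.70, 0.12, 1.1), (1.20, 0.15, 0.35)]
    spec = FilmSpec(
        film_width_nm=film_width_nm,
        peaks=tuple(base_peaks),
        bulk_solute=bulk_solute,
        bulk_solvent=bulk_solvent,
    )
    if interfacial_average_target is None:
        return spec
    z = np.linspace(0.0, 1.0, 2001)
    with_peaks = np.trapezoid(spec.solute_density(z), z)
    flat = FilmSpec(
        film_width_nm=film_width_nm,
        bulk_solute=bulk_solute,
        bulk_solvent=bulk_solvent,
    )
    without = np.trapezoid(flat.solute_density(z), z)
    if with_peaks <= without:
        raise ConfigurationError("peaks contribute no interfacial mass")
    scale = (interfacial_average_target - without) / (with_peaks - without)
    if scale < 0:
        raise DomainError("target below the bulk-only interfacial average")
    peaks = tuple((c, w, a * scale) for c, w, a in base_peaks)
    return FilmSpec(
        film_width_nm=film_width_nm,
        peaks=peaks,
        bulk_solute=bulk_solute,
        bulk_solvent=bulk_solvent,
    )


def matched_particle_counts(
    spec: FilmSpec, z_max_nm: float | None = None
) -> tuple[int, int]:
    """Per-frame molecule counts whose binned density matches the
    analytic profile in absolute units (mass integral / molecular mass)."""
    from scipy.constants import Avogadro

    if z_max_nm is None:
        z_max_nm = spec.film_width_nm + 1.5
    zg = np.linspace(0.0, z_max_nm, 4001)
    counts = []
    for name, density in (
        ("solute", spec.solute_density),
        ("solvent", spec.solvent_density),
    ):
        integral = np.trapezoid(density(zg), zg)  # g/cm^3 * nm
        mass_g = integral * spec.area_nm2 * 1e-21
        counts.append(int(round(mass_g * Avogadro / SPECIES_MASSES[name])))
    return counts[0], counts[1]


def realize_particles(
    spec: FilmSpec,
    n_solute: int | None = None,
    n_solvent: int | None = None,
    n_frames: int = 1,
    seed: int | None = 0,
    z_max_nm: float | None = None,
) -> list[ParticleFrame]:
    """Seeded particle realization of an analytic film.

    z positions are drawn per species by inverse-CDF sampling of the
    analytic density; the cross-section is implicit (densities are
    one-dimensional).  Counts are per frame; when omitted they are
    derived from the analytic mass via :func:`matched_particle_counts`
    so the realized density matches the target in absolute units.
    """
    if z_max_nm is None:
        z_max_nm = spec.film_width_nm + 1.5
    if n_solute is None or n_solvent is None:
        auto = matched_particle_counts(spec, z_max_nm)
        n_solute = auto[0] if n_solute is None else n_solute
        n_solvent = auto[1] if n_solvent is None else n_solvent
    rng = np.random.default_rng(seed)
    zg = np.linspace(0.0, z_max_nm, 4001)
    frames = []
    cdfs = {}
    for name, density in (
        ("solute", spec.solute_density),
        ("solvent", spec.solvent_density),
    ):
        pdf = density(zg)
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1]) * np.diff(zg))])
        if cdf[-1] <= 0:
            raise ConfigurationError(f"{name} density integrates to zero")
        cdfs[name] = cdf / cdf[-1]
    for i in range(n_frames):
        zs, labels = [], []
        for name, n in (("solute", n_solute), ("solvent", n_solvent)):
            u = rng.random(n)
            zs.append(np.interp(u, cdfs[name], zg))
            labels.extend([name] * n)
        frames.append(
            ParticleFrame(
                np.concatenate(zs),
                np.asarray(labels),
                spec.area_nm2,
                frame_index=i,
            )
        )
    return frames
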