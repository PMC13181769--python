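"""Analysis of species-resolved density profiles of a solution film.

The module post-processes MD-style data for a thin film of aqueous
solution bounded by a structureless wall on one side (z = 0) and vacuum
on the other: histogram particle positions into fixed-width bins
(default 0.05 nm), locate the film-vacuum edge from the solvent density,
average species densities over a near-wall window, and integrate the
solute's surface excess against its bulk plateau.

Raw engine trajectories are not parsed here; inputs are either
per-frame particle tables (:class:`ParticleFrame`) or pre-binned
profiles (:class:`DensityProfile`), including LAMMPS-style
chunk-averaged text via :func:`read_lammps_chunks`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.constants import Avogadro

from .errors import ConfigurationError, DomainError, FormatError

__all__ = [
    "SPECIES_MASSES",
    "ParticleFrame",
    "DensityProfile",
    "FilmWidthResult",
    "bin_density_profile",
    "film_width",
    "interfacial_average",
    "profile_surface_excess",
    "read_profile_text",
    "write_profile_text",
    "read_lammps_chunks",
]

#: Default molecular masses (g/mol) by species role.
SPECIES_MASSES = {"solute": 75.07, "solvent": 18.015}

#: nm^3 -> cm^3
_NM3_TO_CM3 = 1e-21


@dataclass
class ParticleFrame:
    """Per-molecule wall distances for one trajectory frame.

    ``z_nm`` holds distances from the wall (center-of-mass convention),
    ``species`` the matching labels ("solute" / "solvent"), ``area_nm2``
    the periodic cross-section of the simulation box.
    """

    z_nm: np.ndarray
    species: np.ndarray
    area_nm2: float
    frame_index: int = 0
    masses: dict = field(default_factory=lambda: dict(SPECIES_MASSES))

    def __post_init__(self) -> None:
        self.z_nm = np.asarray(self.z_nm, dtype=float)
        self.species = np.asarray(self.species)
        if self.z_nm.shape != self.species.shape:
            raise ConfigurationError("z and species arrays differ in length")
        if np.any(self.z_nm < 0):
            raise DomainError("wall distances must be non-negative")
        if not self.area_nm2 > 0:
            raise DomainError("cross-sectional area must be positive")


@dataclass
class DensityProfile:
    """Species-resolved mass densities on a uniform z grid."""

    bin_edges_nm: np.ndarray
    densities: dict  # species -> g/cm^3 per bin
    area_nm2: float
    n_frames: int = 1

    def __post_init__(self) -> None:
        self.bin_edges_nm = np.asarray(self.bin_edges_nm, dtype=float)
        widths = np.diff(self.bin_edges_nm)
        if widths.size == 0 or not np.allclose(widths, widths[0]):
            raise ConfigurationError("bins must be uniform")
        self.densities = {
            k: np.asarray(v, dtype=float) for k, v in self.densities.items()
        }
        for name, rho in self.densities.items():
            if rho.size != widths.size:
                raise ConfigurationError(f"{name}: density/bin size mismatch")
            if np.any(rho < -1e-12):
                raise DomainError(f"{name}: negative density")

    @property
    def bin_width_nm(self) -> float:
        return float(self.bin_edges_nm[1] - self.bin_edges_nm[0])

    @property
    def bin_centers_nm(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_nm[:-1] + self.bin_edges_nm[1:])

    @property
    def extent_nm(self) -> float:
        return float(self.bin_edges_nm[-1])

    def total_mass_g(self, species: str) -> float:
        """Mass of one species implied by the profile (bin-sum identity)."""
        bin_vol_cm3 = self.area_nm2 * self.bin_width_nm * _NM3_TO_CM3
        return float(self.densities[species].sum() * bin_vol_cm3)


@dataclass(frozen=True)
class FilmWidthResult:
    width_nm: float
    flagged: bool = False

    def __float__(self) -> float:
        return self.width_nm


def bin_density_profile(
    frames: Sequence[ParticleFrame],
    bin_width_nm: float = 0.05,
    z_max_nm: float | None = None,
) -> DensityProfile:
    """Frame-averaged mass-density histogram in g/cm^3.

    Each species' counts are weighted by its molecular mass / Avogadro
    and divided by the bin volume (area x bin width).
    """
    if not frames:
        raise ConfigurationError("no frames supplied")
    if not bin_width_nm > 0:
        raise DomainError("bin width must be positive")
    area = frames[0].area_nm2
    if any(abs(f.area_nm2 - area) > 1e-9 * area for f in frames):
        raise ConfigurationError("frames have inconsistent areas")
    if z_max_nm is None:
        z_max_nm = max(float(f.z_nm.max()) for f in frames if f.z_nm.size)
    n_bins = max(1, int(np.ceil(z_max_nm / bin_width_nm - 1e-9)))
    edges = np.arange(n_bins + 1) * bin_width_nm
    species_names = sorted(
        {str(s) for f in frames for s in np.unique(f.species)}
    )
    bin_vol_cm3 = area * bin_width_nm * _NM3_TO_CM3
    densities = {}
    for name in species_names:
        acc = np.zeros(n_bins)
        mass = None
        for f in frames:
            mass = f.masses.get(name, SPECIES_MASSES.get(name))
            if mass is None:
                raise ConfigurationError(f"no molecular mass for {name!r}")
            z = f.z_nm[f.species == name]
            counts, _ = np.histogram(z, bins=edges)
            acc += counts
        acc /= len(frames)
        densities[name] = acc * (mass / Avogadro) / bin_vol_cm3
    return DensityProfile(edges, densities, area, n_frames=len(frames))


def film_width(
    profile: DensityProfile,
    solvent_threshold: float = 0.1,
    solvent: str = "solvent",
) -> FilmWidthResult:
    """Film extent from the solvent-density criterion.

    The film edge is the distance at which the solvent density first
    falls below ``solvent_threshold`` (default 0.1 g/cm^3), scanning
    outward from the last bin that still exceeds half the bulk solvent
    density (the guard rejects near-wall depletion dips).  The crossing
    is linearly interpolated between bin centers.  If the solvent never
    drops below the threshold the full profile extent is returned with
    ``flagged=True``.
    """
    rho = profile.densities[solvent]
    z = profile.bin_centers_nm
    wet = rho > solvent_threshold
    if not np.any(wet):
        # no solvent above threshold anywhere: zero-width film; flag the
        # degenerate case where there *is* solvent but the threshold
        # exceeds its bulk level
        return FilmWidthResult(0.0, flagged=bool(np.any(rho > 0)))
    bulk = float(np.percentile(rho[wet], 75))
    above = np.nonzero(rho > 0.5 * bulk)[0]
    start = above[-1]
    below = np.nonzero(rho[start:] < solvent_threshold)[0]
    if below.size == 0:
        return FilmWidthResult(profile.extent_nm, flagged=True)
    j = start + below[0]  # first bin below threshold, j > start
    z0, z1 = z[j - 1], z[j]
    r0, r1 = rho[j - 1], rho[j]
    width = z0 + (r0 - solvent_threshold) / (r0 - r1) * (z1 - z0)
    return FilmWidthResult(float(width), flagged=False)


def _window_overlap(profile: DensityProfile, window: tuple[float, float]):
    lo, hi = window
    if not (0.0 <= lo < hi):
        raise DomainError(f"invalid window {window}")
    if hi > profile.extent_nm + 1e-9:
        raise DomainError(
            f"window {window} extends past the profile ({profile.extent_nm} nm)"
        )
    left = np.clip(profile.bin_edges_nm[:-1], lo, hi)
    right = np.clip(profile.bin_edges_nm[1:], lo, hi)
    return right - left  # overlap length of each bin with the window


def interfacial_average(
    profile: DensityProfile,
    species: str = "solute",
    window: tuple[float, float] = (0.0, 1.0),
) -> float:
    """Volume-weighted mean density of one species over a z window.

    Partial bins are weighted by their overlap with the window.
    """
    overlap = _window_overlap(profile, window)
    rho = profile.densities[species]
    return float((rho * overlap).sum() / overlap.sum())


def profile_surface_excess(
    profile: DensityProfile,
    species: str = "solute",
    bulk_region: tuple[float, float] = (2.0, 4.0),
) -> float:
    """Surface excess of a species against its bulk plateau, ng/cm^2.

    ``integral_0^z1 (rho(z) - rho_bulk) dz`` with ``rho_bulk`` the mean
    over ``bulk_region = (z1, z2)``; the integral runs from the wall to
    the start of the bulk region.
    """
    z1, z2 = bulk_region
    rho_bulk = interfacial_average(profile, species, (z1, z2))
    overlap = _window_overlap(profile, (0.0, z1)) if z1 > 0 else None
    if overlap is None:
        return 0.0
    rho = profile.densities[species]
    integral = float(((rho - rho_bulk) * overlap).sum())  # g/cm^3 * nm
    return integral * 1e-7 * 1e9  # nm -> cm, g -> ng


# --- plain-text profile I/O --------------------------------------------


def write_profile_text(profile: DensityProfile, path) -> None:
    """Write a profile as '#'-commented text: z_nm, then one density
    column per species (alphabetical)."""
    names = sorted(profile.densities)
    with open(path, "w") as fh:
        fh.write(f"# area_nm2: {profile.area_nm2!r}\n")
        fh.write(f"# bin_width_nm: {profile.bin_width_nm!r}\n")
        fh.write(f"# n_frames: {profile.n_frames}\n")
        fh.write("# columns: z_nm " + " ".join(f"rho_{n}" for n in names) + "\n")
        for i, z in enumerate(profile.bin_centers_nm):
            row = " ".join(f"{profile.densities[n][i]:.10g}" for n in names)
            fh.write(f"{z:.6f} {row}\n")


def read_profile_text(path) -> DensityProfile:
    """Read the format written by :func:`write_profile_text`."""
    header: dict = {}
    names: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("columns:"):
                    cols = body.split(":", 1)[1].split()
                    names = [c[4:] for c in cols if c.startswith("rho_")]
                elif ":" in body:
                    key, val = body.split(":", 1)
                    header[key.strip()] = val.strip()
                continue
            try:
                rows.append([float(v) for v in line.split()])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparseable row") from exc
    if not rows or not names:
        raise FormatError(f"{path}: no data rows or column header")
    data = np.asarray(rows)
    centers = data[:, 0]
    try:
        area = float(header["area_nm2"])
        bw = float(header["bin_width_nm"])
        n_frames = int(header.get("n_frames", 1))
    except KeyError as exc:
        raise FormatError(f"{path}: missing header field {exc}") from exc
    edges = np.concatenate([centers - bw / 2, [centers[-1] + bw / 2]])
    densities = {n: data[:, j + 1] for j, n in enumerate(names)}
    return DensityProfile(edges, densities, area, n_frames=n_frames)


def read_lammps_chunks(
    path,
    area_nm2: float,
    column_map: dict | None = None,
    species_masses: dict | None = None,
    coords_in_angstrom: bool = False,
    number_density: bool = True,
) -> DensityProfile:
    """Read LAMMPS ``fix ave/chunk`` text output into a profile.

    ``column_map`` maps "z" and species names to 0-based column indices
    in the chunk rows (default ``{"z": 1, "solute": 3, "solvent": 4}``).
    With ``number_density=True`` the species columns hold molecules per
    nm^3 (or per A^3 with ``coords_in_angstrom``) and are converted to
    g/cm^3 via ``species_masses``; otherwise they are taken as g/cm^3
    already.  Multiple averaging blocks in one file are averaged.
    """
    column_map = dict(column_map or {"z": 1, "solute": 3, "solvent": 4})
    masses = dict(SPECIES_MASSES)
    masses.update(species_masses or {})
    zcol = column_map.pop("z")
    blocks: list[np.ndarray] = []
    current: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) <= max([zcol, *column_map.values()]):
                if current:
                    blocks.append(np.asarray(current))
                    current = []
                continue  # block header: timestep, n_chunks, ...
            current.append([float(v) for v in parts])
    if current:
        blocks.append(np.asarray(current))
    if not blocks:
        raise FormatError(f"{path}: no chunk rows found")
    shape = blocks[0].shape
    if any(b.shape != shape for b in blocks):
        raise FormatError(f"{path}: averaging blocks differ in shape")
    data = np.mean(blocks, axis=0)
    z = data[:, zcol]
    scale = 0.1 if coords_in_angstrom else 1.0
    centers = z * scale
    bw = float(np.median(np.diff(centers)))
    edges = np.concatenate([centers - bw / 2, [centers[-1] + bw / 2]])
    densities = {}
    for name, col in column_map.items():
        vals = data[:, col]
        if number_density:
            per_nm3 = vals / scale**3 if coords_in_angstrom else vals
            densities[name] = per_nm3 * masses[name] / Avogadro / _NM3_TO_CM3
        else:
            densities[name] = vals
    return DensityProfile(edges, densities, area_nm2, n_frames=len(blocks))
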