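"""Density-profile binning, film width, and surface-excess integrals."""

import numpy as np
import pytest
from scipy.constants import Avogadro

from sprgamma.errors import ConfigurationError, DomainError
from sprgamma.profiles import (
    DensityProfile,
    ParticleFrame,
    bin_density_profile,
    film_width,
    interfacial_average,
    profile_surface_excess,
    read_lammps_chunks,
    read_profile_text,
    write_profile_text,
)
from sprgamma.synth import (
    FILM_FAMILY,
    FilmSpec,
    enriched_film_spec,
    realize_particles,
    synth_profile,
)

AREA = 2.05 * 2.05


def flat_profile(rho_solute, rho_solvent, extent=5.0, bw=0.05):
    edges = np.arange(0, extent + bw / 2, bw)
    n = edges.size - 1
    return DensityProfile(
        edges,
        {
            "solute": np.full(n, rho_solute),
            "solvent": np.full(n, rho_solvent),
        },
        AREA,
    )


class TestBinning:
    def test_uniform_slab_closed_form(self):
        """N solvent molecules uniform in [0, L]: every interior bin holds
        the analytic density M N / (A L N_Avogadro)."""
        rng = np.random.default_rng(0)
        length, n = 8.0, 200_000
        frame = ParticleFrame(
            rng.uniform(0, length, n), np.array(["solvent"] * n), AREA
        )
        profile = bin_density_profile([frame], z_max_nm=length)
        expected = 18.015 * n / (AREA * length * 1e-21) / Avogadro
        interior = profile.densities["solvent"][1:-1]
        # binomial counting error: ~n_bin +- sqrt(n_bin) per bin, 5 sigma
        n_bin = n / 160
        tol = 5 * expected / np.sqrt(n_bin)
        np.testing.assert_allclose(interior, expected, atol=tol)
        assert interior.mean() == pytest.approx(expected, rel=0.01)

    def test_mass_conservation_exact(self):
        rng = np.random.default_rng(1)
        z = rng.uniform(0, 6.0, 500)
        species = np.where(rng.random(500) < 0.3, "solute", "solvent")
        frame = ParticleFrame(z, species, AREA)
        profile = bin_density_profile([frame], z_max_nm=6.0)
        for name, mass in (("solute", 75.07), ("solvent", 18.015)):
            n = int((species == name).sum())
            expected = n * mass / Avogadro
            assert profile.total_mass_g(name) == pytest.approx(
                expected, rel=1e-12
            )

    def test_sampled_particles_match_generator(self):
        """Inverse-CDF realizations reproduce the analytic target profile
        within multinomial counting error in every bin."""
        from sprgamma.profiles import SPECIES_MASSES

        spec = enriched_film_spec(film_width_nm=8.80)
        n_frames = 40
        frames = realize_particles(
            spec, 600, 10_000, n_frames=n_frames, seed=9
        )
        profile = bin_density_profile(frames, z_max_nm=10.3)
        z = profile.bin_centers_nm
        bin_vol_cm3 = profile.area_nm2 * profile.bin_width_nm * 1e-21
        for name, target_fn, n_total in (
            ("solute", spec.solute_density, 600),
            ("solvent", spec.solvent_density, 10_000),
        ):
            # bin probabilities from a fine per-bin quadrature of the
            # analytic density (center values misstate curved bins)
            fine = np.linspace(0, profile.extent_nm, 20 * z.size + 1)
            pdf = target_fn(fine)
            cum = np.concatenate(
                [[0.0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1]) * np.diff(fine))]
            )
            bin_mass = np.diff(np.interp(profile.bin_edges_nm, fine, cum))
            expected_counts = bin_mass / bin_mass.sum() * n_total * n_frames
            got_counts = (
                profile.densities[name]
                * bin_vol_cm3
                / (SPECIES_MASSES[name] / Avogadro)
                * n_frames
            )
            # 6-sigma multinomial band per bin (200+ bins tested)
            tol = 6.0 * np.sqrt(expected_counts + 1.0)
            assert np.all(np.abs(got_counts - expected_counts) <= tol)

    def test_errors(self):
        with pytest.raises(ConfigurationError):
            bin_density_profile([])
        f1 = ParticleFrame(np.array([1.0]), np.array(["solvent"]), 4.0)
        f2 = ParticleFrame(np.array([1.0]), np.array(["solvent"]), 5.0)
        with pytest.raises(ConfigurationError):
            bin_density_profile([f1, f2])


class TestFilmWidth:
    def test_reference_film_edge(self):
        profile = synth_profile(enriched_film_spec(film_width_nm=8.80))
        result = film_width(profile)
        assert not result.flagged
        assert result.width_nm == pytest.approx(8.80, abs=0.05)

    def test_no_solvent_zero_width(self):
        profile = flat_profile(0.2, 0.0)
        assert film_width(profile).width_nm == 0.0

    def test_threshold_above_bulk_flagged(self):
        profile = flat_profile(0.2, 0.9)
        result = film_width(profile, solvent_threshold=1.5)
        assert result.width_nm == 0.0 and result.flagged

    def test_never_below_threshold_returns_extent_flagged(self):
        profile = flat_profile(0.2, 0.9)
        result = film_width(profile)
        assert result.flagged and result.width_nm == profile.extent_nm

    def test_monotone_in_solvent_count(self):
        """Recovered width grows with the molecule count across the
        reference film family."""
        widths = []
        for n_solute, n_solvent, width in FILM_FAMILY:
            spec = enriched_film_spec(film_width_nm=width)
            frames = realize_particles(
                spec, n_solute, n_solvent, n_frames=100, seed=n_solvent
            )
            profile = bin_density_profile(frames, z_max_nm=width + 1.5)
            widths.append(film_width(profile).width_nm)
        assert np.all(np.diff(widths) > 0)


class TestInterfacialAverage:
    def test_flat_profile_any_window(self):
        profile = flat_profile(0.4, 0.7)
        for window in ((0.0, 1.0), (0.3, 2.7), (1.0, 1.05)):
            assert interfacial_average(profile, "solute", window) == pytest.approx(
                0.4, rel=1e-12
            )

    def test_single_bin_identity(self):
        profile = synth_profile(enriched_film_spec(film_width_nm=4.65))
        j = 10
        window = (
            float(profile.bin_edges_nm[j]),
            float(profile.bin_edges_nm[j + 1]),
        )
        assert interfacial_average(profile, "solute", window) == pytest.approx(
            profile.densities["solute"][j], rel=1e-12
        )

    def test_partial_bin_weighting(self):
        profile = flat_profile(0.4, 0.7)
        # window split across bins with different weights still flat
        assert interfacial_average(profile, "solvent", (0.02, 0.08)) == (
            pytest.approx(0.7, rel=1e-12)
        )

    def test_window_outside_extent(self):
        profile = flat_profile(0.4, 0.7, extent=2.0)
        with pytest.raises(DomainError):
            interfacial_average(profile, "solute", (1.0, 3.0))

    def test_refinement_consistency(self):
        spec = enriched_film_spec(film_width_nm=12.95)
        coarse = interfacial_average(synth_profile(spec, bin_width_nm=0.05))
        fine = interfacial_average(synth_profile(spec, bin_width_nm=0.025))
        assert abs(coarse - fine) < 0.01


class TestSurfaceExcess:
    def test_flat_profile_zero(self):
        profile = flat_profile(0.4, 0.7)
        assert profile_surface_excess(profile, "solute", (2.0, 4.0)) == (
            pytest.approx(0.0, abs=1e-12)
        )

    def test_rectangular_excess_closed_form(self):
        edges = np.arange(0, 6.0 + 0.025, 0.05)
        n = edges.size - 1
        solute = np.full(n, 0.2)
        solute[:20] += 0.5  # 1 nm wide, +0.5 g/cm^3 step
        profile = DensityProfile(
            edges, {"solute": solute, "solvent": np.full(n, 0.7)}, AREA
        )
        expected = 0.5 * 1.0 * 100.0  # delta_rho * width -> ng/cm^2
        assert profile_surface_excess(profile, "solute", (2.0, 5.0)) == (
            pytest.approx(expected, rel=1e-12)
        )

    def test_against_quadrature_oracle(self):
        """Bin-sum integral equals an independent trapezoid quadrature of
        the piecewise-constant density to 1e-10."""
        profile = synth_profile(enriched_film_spec(film_width_nm=12.95))
        z1, z2 = 3.0, 6.0
        got = profile_surface_excess(profile, "solute", (z1, z2))
        # oracle: trapezoid quadrature of the piecewise-constant density,
        # with each bin represented by its two edge abscissae so the
        # step discontinuities carry zero width
        rho = profile.densities["solute"]
        edges = profile.bin_edges_nm
        overlap = np.clip(edges[1:], z1, z2) - np.clip(edges[:-1], z1, z2)
        rho_bulk = float((rho * overlap).sum() / overlap.sum())
        n_in = int(round(z1 / profile.bin_width_nm))
        zz = np.repeat(edges[: n_in + 1], 2)[1:-1]
        vv = np.repeat(rho[:n_in] - rho_bulk, 2)
        oracle_ng = np.trapezoid(vv, zz) * 100.0
        assert got == pytest.approx(oracle_ng, abs=1e-10)

    def test_invariant_to_bulk_region_choice(self):
        profile = synth_profile(enriched_film_spec(film_width_nm=12.95))
        values = [
            profile_surface_excess(profile, "solute", region)
            for region in ((3.0, 5.0), (4.0, 6.0), (5.0, 7.0))
        ]
        spread = (max(values) - min(values)) / np.mean(values)
        assert spread < 0.02

    def test_bulk_region_outside_film(self):
        profile = flat_profile(0.4, 0.7, extent=3.0)
        with pytest.raises(DomainError):
            profile_surface_excess(profile, "solute", (2.5, 4.0))


class TestProfileIO:
    def test_text_round_trip(self, tmp_path):
        profile = synth_profile(enriched_film_spec(film_width_nm=4.65))
        path = tmp_path / "profile.txt"
        write_profile_text(profile, path)
        back = read_profile_text(path)
        np.testing.assert_allclose(
            back.bin_edges_nm, profile.bin_edges_nm, atol=1e-9
        )
        for name in profile.densities:
            np.testing.assert_allclose(
                back.densities[name], profile.densities[name], atol=1e-9
            )
        assert back.area_nm2 == pytest.approx(profile.area_nm2)

    def test_lammps_chunk_reader(self, tmp_path):
        path = tmp_path / "chunks.txt"
        rho_n = {"solute": 1.73, "solvent": 30.0}  # molecules / nm^3
        lines = [
            "# Chunk-averaged data for fix profile",
            "# Timestep Number-of-chunks Total-count",
            "1000 4 400",
        ]
        for i in range(4):
            z = 0.025 + 0.05 * i
            lines.append(
                f"  {i + 1} {z:.3f} 100 {rho_n['solute']} {rho_n['solvent']}"
            )
        path.write_text("\n".join(lines) + "\n")
        profile = read_lammps_chunks(path, area_nm2=AREA)
        assert profile.bin_width_nm == pytest.approx(0.05)
        expected_solute = rho_n["solute"] * 75.07 / Avogadro / 1e-21
        assert profile.densities["solute"][0] == pytest.approx(
            expected_solute, rel=1e-9
        )
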