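"""Clausius-Mossotti composition chain and excess-mass arithmetic."""

import numpy as np
import pytest
from scipy.interpolate import PchipInterpolator

from sprgamma.errors import CalibrationError, DomainError
from sprgamma.thermo import (
    EPS_WATER,
    RHO_GLYCINE_CRYSTAL,
    RHO_WATER,
    calibrate_refractions,
    cm_fraction,
    convert_gamma_units,
    default_calibration,
    density_of_solution,
    eps_to_massfraction,
    gamma_excess,
    load_property_table,
    mass_to_number_density,
)


class TestCmFraction:
    @pytest.mark.parametrize(
        "eps, expected",
        [(1.0, 0.0), (2.1070, 1.1070 / 4.1070), (1e9, 1.0)],
    )
    def test_values(self, eps, expected):
        assert cm_fraction(eps) == pytest.approx(expected, abs=1e-6)

    def test_strictly_increasing(self):
        eps = np.linspace(1.0, 3.0, 200)
        assert np.all(np.diff(cm_fraction(eps)) > 0)

    def test_domain_error(self):
        with pytest.raises(DomainError):
            cm_fraction(-0.5)


class TestDensityModel:
    def test_endpoints(self):
        assert density_of_solution(0.0) == pytest.approx(RHO_WATER, abs=1e-5)
        assert density_of_solution(1.0) == pytest.approx(
            RHO_GLYCINE_CRYSTAL, abs=1e-6
        )

    def test_interpolates_table_exactly(self):
        table = load_property_table()
        for _, row in table.iterrows():
            assert density_of_solution(row["x_gly"]) == pytest.approx(
                row["rho_g_cm3"], abs=1e-12
            )

    def test_monotone_over_full_range(self):
        x = np.linspace(0.0, 1.0, 501)
        rho = np.array([density_of_solution(v) for v in x])
        assert np.all(np.diff(rho) > 0)

    def test_domain_errors(self):
        for bad in (-0.1, 1.1):
            with pytest.raises(DomainError):
                density_of_solution(bad)


class TestRefractionCalibration:
    def test_water_point_closed_form(self):
        calib = calibrate_refractions(
            (1.7770, 0.9977), [(1.85, 0.15, 1.06)]
        )
        assert calib.r_water == pytest.approx(0.2062, abs=1e-4)

    def test_round_trip_recovers_generating_refraction(self):
        r_water = cm_fraction(EPS_WATER) / RHO_WATER
        r_gly = 0.2185
        x, rho = 0.15, 1.060
        f = rho * (x * r_gly + (1 - x) * r_water)
        eps = (1 + 2 * f) / (1 - f)
        calib = calibrate_refractions(
            (EPS_WATER, RHO_WATER), [(eps, x, rho)]
        )
        assert calib.r_gly == pytest.approx(r_gly, abs=1e-6)

    def test_duplicate_points_idempotent(self):
        point = (1.85003, 0.150, 1.06136)
        single = calibrate_refractions((EPS_WATER, RHO_WATER), [point])
        double = calibrate_refractions((EPS_WATER, RHO_WATER), [point, point])
        assert single.r_gly == pytest.approx(double.r_gly, rel=1e-12)

    def test_degenerate_points_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate_refractions((EPS_WATER, RHO_WATER), [(1.7770, 0.0, RHO_WATER)])

    def test_default_reproduces_its_own_table(self):
        calib = default_calibration()
        table = load_property_table()
        for _, row in table.iterrows():
            f = calib.cm_forward(row["x_gly"], row["rho_g_cm3"])
            eps = (1 + 2 * f) / (1 - f)
            assert eps == pytest.approx(row["eps"], abs=1e-4)


def grid_search_oracle(table):
    """Independent brute-force inverse of the composition chain.

    Rebuilds the density model (pchip + apparent-specific-volume
    extension) and the forward Clausius-Mossotti map on a 1e-6 mass
    fraction grid, then inverts by lookup on the monotone forward curve.
    """
    x_tab = table["x_gly"].to_numpy()
    rho_tab = table["rho_g_cm3"].to_numpy()
    interp = PchipInterpolator(x_tab, rho_tab)
    x_max, rho_max = x_tab[-1], rho_tab[-1]
    v_w = 1.0 / rho_tab[0]
    v_app_max = (1.0 / rho_max - (1.0 - x_max) * v_w) / x_max
    v_cr = 1.0 / RHO_GLYCINE_CRYSTAL

    x = np.arange(0.0, 1.0 + 1e-6, 1e-6)
    rho = np.where(
        x <= x_max,
        interp(np.clip(x, 0, x_max)),
        1.0
        / (
            (1.0 - x) * v_w
            + x * (v_app_max + (x - x_max) / (1.0 - x_max) * (v_cr - v_app_max))
        ),
    )
    r_w = cm_fraction(EPS_WATER) / RHO_WATER
    # r_gly by the same least-squares reduction the calibration defines,
    # recomputed here from the raw table rows
    rows = table.iloc[1:]
    a = (rows["rho_g_cm3"] * rows["x_gly"]).to_numpy()
    b = (
        cm_fraction(rows["eps"].to_numpy())
        - rows["rho_g_cm3"].to_numpy() * (1 - rows["x_gly"].to_numpy()) * r_w
    )
    r_g = float(a @ b / (a @ a))
    forward = rho * (x * r_g + (1.0 - x) * r_w)  # monotone in x

    def invert(eps):
        j = np.searchsorted(forward, cm_fraction(eps))
        j = min(max(j, 1), x.size - 1)
        return x[j] if abs(forward[j] - cm_fraction(eps)) < abs(
            forward[j - 1] - cm_fraction(eps)
        ) else x[j - 1]

    return invert


class TestEpsToMassFraction:
    def test_pure_solvent(self):
        comp = eps_to_massfraction(EPS_WATER)
        assert comp.x_gly == 0.0

    def test_below_solvent_flagged(self):
        comp = eps_to_massfraction(1.70)
        assert comp.x_gly == 0.0 and comp.below_solvent

    def test_calibration_points_self_consistent(self):
        table = load_property_table()
        for _, row in table.iloc[1:].iterrows():
            comp = eps_to_massfraction(row["eps"])
            assert comp.x_gly == pytest.approx(row["x_gly"], abs=1e-4)

    def test_against_grid_search_oracle(self):
        """Root-finder inversion agrees with the 1e-6-step brute-force
        grid search for 100 random permittivities."""
        oracle = grid_search_oracle(load_property_table())
        rng = np.random.default_rng(3)
        for eps in rng.uniform(1.80, 2.30, 100):
            x_impl = eps_to_massfraction(eps).x_gly
            assert abs(x_impl - oracle(eps)) <= 1.5e-6

    def test_frozen_oracle_value_for_reference_permittivity(self):
        # grid-search oracle value for eps = 2.0717, frozen
        assert eps_to_massfraction(2.0717).x_gly == pytest.approx(
            0.506339, abs=1e-4
        )

    def test_forward_backward_round_trip(self):
        calib = default_calibration()
        for x in np.linspace(0.0, 0.7, 15):
            f = calib.cm_forward(x, density_of_solution(x))
            eps = (1 + 2 * f) / (1 - f)
            assert eps_to_massfraction(eps, calib).x_gly == pytest.approx(
                x, abs=1e-8
            )

    def test_strictly_increasing(self):
        eps = np.linspace(1.80, 2.40, 50)
        x = [eps_to_massfraction(e).x_gly for e in eps]
        assert np.all(np.diff(x) > 0)


class TestGammaExcess:
    def test_no_contrast_no_excess(self):
        assert gamma_excess(1.8489, 1.8489, 1.0).gamma_ng_cm2 == pytest.approx(
            0.0, abs=1e-9
        )

    def test_reference_permittivity_pair_lands_in_band(self):
        gamma = gamma_excess(2.0717, 1.8489, 1.0).gamma_ng_cm2
        assert 40.0 <= gamma <= 60.0

    def test_sign_follows_permittivity_contrast(self):
        assert gamma_excess(1.90, 1.8489, 1.0).gamma_ng_cm2 > 0
        assert gamma_excess(1.8100, 1.8489, 1.0).gamma_ng_cm2 < 0

    def test_monotone_in_interfacial_permittivity(self):
        gammas = [
            gamma_excess(e, 1.8489, 1.0).gamma_ng_cm2
            for e in np.linspace(1.85, 2.3, 10)
        ]
        assert np.all(np.diff(gammas) > 0)

    def test_thickness_error(self):
        with pytest.raises(DomainError):
            gamma_excess(2.0, 1.85, 0.0)


class TestNumberDensities:
    @pytest.mark.parametrize(
        "rho, expected",
        [(1.6, 12.8), (0.0, 0.0), (0.5, 4.0)],
    )
    def test_conversion(self, rho, expected):
        assert mass_to_number_density(rho) == pytest.approx(expected, abs=0.05)

    def test_bulk_solution_benchmark(self):
        """250 g glycine per kg water (x = 0.2) holds ~1.7 glycine
        molecules per nm^3."""
        x = 250.0 / 1250.0
        rho_gly = density_of_solution(x) * x
        assert mass_to_number_density(rho_gly) == pytest.approx(1.7, abs=0.05)

    def test_bad_molar_mass(self):
        with pytest.raises(DomainError):
            mass_to_number_density(1.0, molar_mass=0.0)


@pytest.mark.parametrize(
    "gamma, expected",
    [(50.0, 5e-13), (0.0, 0.0), (1e14, 1.0)],
)
def test_gamma_unit_conversion(gamma, expected):
    assert convert_gamma_units(gamma) == pytest.approx(expected, rel=1e-12)
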