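import math

import numpy as np
import pytest
from scipy.integrate import quad

from filmsem import (
    AU,
    NI,
    SIN,
    BeamSpec,
    DomainError,
    Element,
    FilmStack,
    Layer,
    Material,
    elastic_cross_section,
    elastic_mfp,
    mean_ionization_potential,
    stopping_power,
)
from filmsem.materials import (
    AVOGADRO,
    GOLD,
    NITROGEN,
    SILICON,
    browning_cross_section,
    screening_parameter,
)


class TestMeanIonizationPotential:
    def test_low_z_branch(self):
        assert mean_ionization_potential(7) == pytest.approx(0.0805, rel=1e-12)

    def test_high_z_matches_hand_evaluation(self):
        expected = (9.76 * 79 + 58.5 * 79 ** (-0.19)) * 1e-3
        assert mean_ionization_potential(79) == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_z(self):
        js = [mean_ionization_potential(z) for z in range(1, 93)]
        assert all(b > a for a, b in zip(js, js[1:]))

    @pytest.mark.parametrize("bad", [0, -3, 2.5])
    def test_rejects_invalid_z(self, bad):
        with pytest.raises(DomainError):
            mean_ionization_potential(bad)


class TestElasticCrossSection:
    def test_decreasing_in_energy(self):
        energies = np.linspace(1.0, 10.0, 30)
        sigma = elastic_cross_section(79, energies)
        assert np.all(np.diff(sigma) < 0)

    def test_matches_quadrature_of_differential_form(self):
        # The angular density is proportional to 1/(1 - cos + 2 alpha)^2;
        # the normalization that integrates to the closed-form total is 4K
        # with K the prefactor of the total cross-section formula.
        Z, E = 79, 4.0
        alpha = screening_parameter(Z, E)
        K = 5.21e-21 * (Z / E) ** 2 * ((E + 511.0) / (E + 1024.0)) ** 2
        integrand = lambda c: 2.0 * math.pi * 4.0 * K / (1.0 - c + 2.0 * alpha) ** 2
        total, err = quad(integrand, -1.0, 1.0, epsrel=1e-10)
        assert elastic_cross_section(Z, E) == pytest.approx(total, rel=1e-6)

    def test_vanishes_in_large_screening_limit(self):
        # the screening factor 4pi/(alpha(1+alpha)) -> 0 as alpha -> inf,
        # so a hypothetical fully screened atom stops scattering
        factor = lambda a: 4 * math.pi / (a * (1 + a))
        assert factor(1e3) < factor(1.0)
        assert factor(1e9) < 1e-16
        # and the strongly screened regime (low E, high Z) has a smaller
        # cross-section than the weakly screened one at the same prefactor
        sigma = lambda e: elastic_cross_section(79, e) * e ** 2
        assert sigma(0.051) < sigma(10.0)

    def test_rejects_energy_below_floor(self):
        with pytest.raises(DomainError):
            elastic_cross_section(79, 0.04)


class TestBrowningCrossSection:
    def test_positive_over_grid(self):
        for z in (6, 14, 28, 79):
            sigma = browning_cross_section(z, np.array([0.1, 1.0, 4.0, 30.0]))
            assert np.all(sigma > 0)

    def test_smaller_than_rutherford_for_gold_at_few_kev(self):
        # the raison d'etre of the Mott fit: heavy elements at low energy
        assert browning_cross_section(79, 4.0) < elastic_cross_section(79, 4.0)


class TestElasticMfp:
    def test_density_scaling(self):
        dense = Material("Au2", 2 * AU.density, ((GOLD, 1.0),))
        assert elastic_mfp(dense, 4.0) == pytest.approx(
            elastic_mfp(AU, 4.0) / 2.0, rel=1e-12
        )

    def test_single_element_closed_form(self):
        sigma = elastic_cross_section(79, 4.0)
        expected = GOLD.atomic_mass / (AVOGADRO * AU.density * sigma) * 1e7
        assert elastic_mfp(AU, 4.0) == pytest.approx(expected, rel=1e-12)

    def test_compound_additivity(self):
        inv = 0.0
        for elem, w in SIN.composition:
            n_i = AVOGADRO * SIN.density * w / elem.atomic_mass
            inv += n_i * elastic_cross_section(elem.Z, 4.0) * 1e-7
        assert elastic_mfp(SIN, 4.0) == pytest.approx(1.0 / inv, rel=1e-12)


class TestStoppingPower:
    @pytest.mark.parametrize("material", [AU, NI, SIN])
    @pytest.mark.parametrize("energy", [0.1, 0.5, 1.0, 4.0, 10.0])
    def test_positive(self, material, energy):
        assert stopping_power(material, energy) > 0

    def test_gold_matches_hand_evaluation(self):
        J = (9.76 * 79 + 58.5 * 79 ** (-0.19)) * 1e-3
        k = 0.731 + 0.0688 * math.log10(79)
        expected = (
            7.85e4
            * (19.3 / 4.0)
            * (79 / 196.96657)
            * math.log(1.166 * (4.0 + k * J) / J)
            * 1e-7
        )
        assert stopping_power(AU, 4.0) == pytest.approx(expected, rel=1e-12)

    def test_e_times_s_varies_only_logarithmically(self):
        ratio = (8.0 * stopping_power(AU, 8.0)) / (4.0 * stopping_power(AU, 4.0))
        assert 1.0 < ratio < 1.5

    @pytest.mark.parametrize("energy", [0.05, 31.0, -1.0])
    def test_rejects_out_of_range_energy(self, energy):
        with pytest.raises(DomainError):
            stopping_power(AU, energy)


class TestDataModel:
    def test_weight_fractions_must_sum_to_one(self):
        with pytest.raises(DomainError):
            Material("bad", 1.0, ((SILICON, 0.6), (NITROGEN, 0.3)))

    def test_weight_fraction_bounds(self):
        with pytest.raises(DomainError):
            Material("bad", 1.0, ((SILICON, 1.2), (NITROGEN, -0.2)))

    def test_element_sanity(self):
        with pytest.raises(DomainError):
            Element("X", 10, 5.0)  # atomic mass implausibly low for Z

    def test_stack_total_thickness(self):
        stack = FilmStack((Layer(SIN, 50.0), Layer(NI, 15.0), Layer(AU, 10.0)))
        assert stack.total_thickness == pytest.approx(75.0)
        assert list(stack.boundaries()) == [50.0, 65.0, 75.0]

    def test_beam_voltage_range(self):
        with pytest.raises(DomainError):
            BeamSpec(voltage=45.0)

    def test_builtin_densities(self):
        assert (SIN.density, NI.density, AU.density) == (3.12, 8.9, 19.3)
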