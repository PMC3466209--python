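import math

import numpy as np
import pytest
from scipy.integrate import quad

import filmsem.transport as transport_mod
from filmsem import (
    AU,
    SIN,
    BeamSpec,
    DomainError,
    ElectronState,
    FilmStack,
    Layer,
    TransportConfig,
    half_intensity_width,
    run_transport,
    step_electron,
    transmission_curve,
)
from filmsem.transport import (
    rotate_direction,
    sample_free_path,
    sample_polar_angle,
)


class TestSampleFreePath:
    def test_boundary_values(self):
        assert sample_free_path(5.0, 1.0) == 0.0
        assert sample_free_path(5.0, math.exp(-1.0)) == pytest.approx(5.0, rel=1e-12)

    def test_mean_matches_mfp(self):
        rng = np.random.default_rng(3)
        u = 1.0 - rng.random(1_000_000)
        s = sample_free_path(7.5, u)
        assert s.mean() == pytest.approx(7.5, rel=5e-3)

    @pytest.mark.parametrize("u", [0.0, -0.1, 1.1])
    def test_rejects_bad_variate(self, u):
        with pytest.raises(DomainError):
            sample_free_path(5.0, u)


class TestSamplePolarAngle:
    def test_limits(self):
        assert sample_polar_angle(0.01, 0.0) == 1.0
        assert sample_polar_angle(0.01, 1.0) == pytest.approx(-1.0)

    def test_mean_matches_quadrature(self):
        alpha = 0.02
        norm = 1.0 / (2.0 * alpha * (1.0 + alpha))  # integral of the density kernel
        density = lambda c: 1.0 / (1.0 - c + 2.0 * alpha) ** 2 / norm
        expected, _ = quad(lambda c: c * density(c), -1.0, 1.0, epsrel=1e-10)
        rng = np.random.default_rng(5)
        sampled = sample_polar_angle(alpha, rng.random(1_000_000))
        assert sampled.mean() == pytest.approx(expected, rel=5e-3)


class TestRotateDirection:
    def test_zero_polar_angle_is_identity(self):
        d = np.array([0.0, 0.6, 0.8])
        out = rotate_direction(d, 0.0, 1.3)
        assert np.allclose(out, d, atol=1e-12)

    def test_norm_preserved(self):
        rng = np.random.default_rng(11)
        d = rng.normal(size=(200, 3))
        d /= np.linalg.norm(d, axis=1)[:, None]
        out = rotate_direction(d, rng.uniform(0, np.pi, 200), rng.uniform(0, 2 * np.pi, 200))
        assert np.allclose(np.linalg.norm(out, axis=1), 1.0, atol=1e-12)

    def test_against_rotation_matrix_oracle(self):
        # Rotating by theta must land on the cone of angle theta around the
        # old direction; with the same frame convention the full vector is
        # cos(t) d + sin(t) (cos(p) u + sin(p) v).
        rng = np.random.default_rng(13)
        for _ in range(100):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            theta = rng.uniform(0, np.pi)
            phi = rng.uniform(0, 2 * np.pi)
            out = rotate_direction(d, theta, phi)
            helper = np.array([1.0, 0.0, 0.0]) if abs(d[2]) > 0.99999 else np.array([0.0, 0.0, 1.0])
            u = np.cross(helper, d)
            u /= np.linalg.norm(u)
            v = np.cross(d, u)
            expected = (
                math.cos(theta) * d
                + math.sin(theta) * (math.cos(phi) * u + math.sin(phi) * v)
            )
            assert np.abs(out - expected).max() < 1e-9

    def test_rejects_zero_direction(self):
        with pytest.raises(DomainError):
            rotate_direction(np.zeros(3), 0.1, 0.1)


class TestStepElectron:
    def _state(self, energy=2.0):
        return ElectronState(
            position=np.array([0.0, 0.0, 1.0]),
            direction=np.array([0.0, 0.0, 1.0]),
            energy=energy,
        )

    def test_energy_never_increases(self):
        stack = FilmStack((Layer(SIN, 50.0), Layer(AU, 10.0)))
        rng = np.random.default_rng(17)
        state = self._state()
        while state.status == "in-flight":
            before = state.energy
            state = step_electron(state, stack, rng)
            assert state.energy <= before + 1e-15

    def test_straight_line_when_physics_disabled(self, monkeypatch):
        monkeypatch.setattr(
            transport_mod, "partial_inverse_mfps", lambda m, e, model=None: np.array([[1e-12]])
        )
        monkeypatch.setattr(transport_mod, "stopping_power", lambda m, e: 0.0)
        stack = FilmStack((Layer(SIN, 1e6),))
        state = self._state(energy=4.0)
        state.direction = np.array([0.6, 0.0, 0.8])
        start = state.position.copy()
        state = step_electron(state, stack, np.random.default_rng(1))
        moved = state.position - start
        assert np.allclose(moved / np.linalg.norm(moved), [0.6, 0.0, 0.8], atol=1e-12)
        assert state.energy == 4.0

    def test_trajectory_energy_bookkeeping_closes(self):
        stack = FilmStack((Layer(SIN, 50.0), Layer(AU, 10.0)))
        for seed in range(5):
            rng = np.random.default_rng(seed)
            state = self._state(energy=2.0)
            while state.status == "in-flight":
                state = step_electron(state, stack, rng)
            assert state.deposited + state.energy == pytest.approx(2.0, abs=1e-9)


class TestRunTransport:
    def test_near_empty_film_transmits_everything(self):
        stack = FilmStack((Layer(SIN, 1e-3),))
        s = run_transport(stack, BeamSpec(voltage=4.0), TransportConfig(n_electrons=2000, rng_seed=1))
        assert s.fraction_transmitted > 0.99

    def test_thick_gold_blocks_everything(self):
        stack = FilmStack((Layer(AU, 1000.0),))
        s = run_transport(stack, BeamSpec(voltage=4.0), TransportConfig(n_electrons=2000, rng_seed=1))
        assert s.n_transmitted == 0

    def test_fates_partition(self, run_4kv_small):
        s = run_4kv_small
        assert s.n_transmitted + s.n_backscattered + s.n_absorbed == s.n_electrons
        assert (
            s.fraction_transmitted + s.fraction_backscattered + s.fraction_absorbed
            == pytest.approx(1.0, abs=1e-12)
        )
        assert s.exit_radial_histogram.sum() == s.n_transmitted
        assert s.exit_lateral_profile.sum() == s.n_transmitted

    def test_seed_determinism_bit_identical(self, film_stack_50):
        beam = BeamSpec(voltage=4.0)
        cfg = TransportConfig(n_electrons=5000, rng_seed=99)
        a = run_transport(film_stack_50, beam, cfg)
        b = run_transport(film_stack_50, beam, cfg)
        assert a.n_transmitted == b.n_transmitted
        assert a.n_backscattered == b.n_backscattered
        assert np.array_equal(a.exit_x, b.exit_x)
        assert np.array_equal(a.exit_radial_histogram, b.exit_radial_histogram)

    def test_transmission_decreases_with_thickness(self):
        beam = BeamSpec(voltage=4.0)
        fractions = []
        for t, seed in ((50.0, 1), (60.0, 1), (80.0, 1)):
            stack = FilmStack((Layer(SIN, t), Layer(AU, 10.0)))
            s = run_transport(stack, beam, TransportConfig(n_electrons=20_000, rng_seed=seed))
            fractions.append(s.fraction_transmitted)
        sigma = math.sqrt(0.5 * 0.5 / 20_000)
        assert fractions[0] > fractions[1] - 3 * sigma
        assert fractions[1] > fractions[2] - 3 * sigma
        assert fractions[0] > fractions[2]

    def test_seed_to_seed_scatter_is_binomial(self, film_stack_50):
        beam = BeamSpec(voltage=4.0)
        fr = [
            run_transport(
                film_stack_50, beam, TransportConfig(n_electrons=20_000, rng_seed=s)
            ).fraction_transmitted
            for s in (1, 2)
        ]
        p = np.mean(fr)
        sigma = math.sqrt(p * (1 - p) / 20_000)
        assert abs(fr[0] - fr[1]) < 4 * math.sqrt(2) * sigma

    def test_vectorized_energy_bookkeeping(self, film_stack_50):
        s = run_transport(
            film_stack_50,
            BeamSpec(voltage=4.0),
            TransportConfig(n_electrons=5000, rng_seed=21, track_deposition=True),
        )
        total = s.deposited_energy + s.exit_kinetic_energy
        assert np.abs(total - 4.0).max() < 1e-9

    def test_rejects_empty_stack(self):
        with pytest.raises(DomainError):
            FilmStack(())


class TestHalfIntensityWidth:
    def test_single_bin_spike(self):
        assert half_intensity_width([0, 0, 10, 0, 0], 2.0) <= 2.0

    def test_gaussian_profile_fwhm(self):
        x = np.arange(-100, 101) * 1.0
        profile = np.exp(-(x ** 2) / (2 * 10.0 ** 2))
        assert half_intensity_width(profile, 1.0) == pytest.approx(23.548, rel=0.02)

    def test_rejects_empty_profile(self):
        with pytest.raises(DomainError):
            half_intensity_width([0.0, 0.0], 1.0)


class TestTransmissionCurve:
    def test_deterministic_and_monotone_on_film(self, film_stack_50):
        beam = BeamSpec()
        cfg = TransportConfig(n_electrons=10_000, rng_seed=5)
        a = transmission_curve(film_stack_50, [3.0, 4.0, 5.0], beam, cfg)
        b = transmission_curve(film_stack_50, [3.0, 4.0, 5.0], beam, cfg)
        assert a.equals(b)
        assert a["fraction_transmitted"].is_monotonic_increasing
        assert ((a["fraction_transmitted"] >= 0) & (a["fraction_transmitted"] <= 1)).all()

    def test_empty_film_transmits_at_all_voltages(self):
        stack = FilmStack((Layer(SIN, 1e-3),))
        table = transmission_curve(
            stack, [3.0, 4.0], BeamSpec(), TransportConfig(n_electrons=1000, rng_seed=2)
        )
        assert (table["fraction_transmitted"] > 0.99).all()
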