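"""Gaussian conditioning, epistemic value and belief pushforwards."""

import math

import numpy as np
import pytest

from epiexplore.geometry import (
    AffineMap,
    Frame,
    GeometryConfig,
    ProjectiveMap,
    embed_plane,
    transition_map,
)
from epiexplore.inference import (
    GaussianBelief,
    PushforwardScheme,
    SensorModel,
    ball_sensor_epistemic_value,
    condition_on_observation,
    epistemic_value,
    joint_covariance,
    pearl_update_unobserved,
    pushforward,
)
from epiexplore.fixtures import (
    FixtureSpec,
    grid_bayes_oracle,
    make_belief,
    mc_mutual_information_oracle,
    random_planar_transition,
)


def random_spd_belief(rng, d=2, scale=0.01):
    a = rng.standard_normal((d, d))
    return GaussianBelief(rng.standard_normal(d), scale * (a @ a.T + d * np.eye(d)))


class TestGaussianBelief:
    def test_rejects_asymmetric_covariance(self):
        with pytest.raises(ValueError):
            GaussianBelief([0, 0], [[1.0, 0.5], [0.1, 1.0]])

    def test_rejects_indefinite_covariance(self):
        with pytest.raises(ValueError):
            GaussianBelief([0, 0], [[1.0, 0.0], [0.0, -1.0]])

    def test_rejects_bad_dimension(self):
        with pytest.raises(ValueError):
            GaussianBelief([0.0], [[1.0]])


class TestJointCovariance:
    def test_paper_blocks(self):
        belief = GaussianBelief.isotropic([0, 1], 0.01)
        joint = joint_covariance(belief, SensorModel(0.1))
        expected = np.block(
            [
                [0.01 * np.eye(2), 0.01 * np.eye(2)],
                [0.01 * np.eye(2), 0.02 * np.eye(2)],
            ]
        )
        assert np.allclose(joint, expected)

    def test_large_epsilon_dominates_observation_block(self):
        belief = GaussianBelief.isotropic([0, 1], 0.01)
        joint = joint_covariance(belief, SensorModel(100.0))
        assert np.allclose(joint[2:, 2:], 1e4 * np.eye(2), rtol=1e-5)

    def test_joint_is_spd_for_random_priors(self, rng):
        for _ in range(10):
            belief = random_spd_belief(rng)
            joint = joint_covariance(belief, SensorModel(0.3))
            assert np.linalg.eigvalsh(joint).min() > 0


class TestConditioning:
    def test_centred_observation_keeps_mean_shrinks_cov(self, rng):
        belief = random_spd_belief(rng)
        post = condition_on_observation(belief, SensorModel(0.2), belief.mean)
        assert np.allclose(post.mean, belief.mean)
        # Loewner order: prior - posterior is PSD
        assert np.linalg.eigvalsh(belief.cov - post.cov).min() > -1e-12

    def test_scalar_conjugate_formula(self):
        belief = GaussianBelief.isotropic([0, 1], 0.01)
        post = condition_on_observation(belief, SensorModel(0.1), [0, 1])
        assert np.allclose(post.cov, 0.005 * np.eye(2), atol=1e-15)

    def test_matches_grid_bayes_oracle(self, rng):
        for _ in range(5):
            belief = random_spd_belief(rng)
            y = belief.mean + 0.1 * rng.standard_normal(2)
            post = condition_on_observation(belief, SensorModel(0.15), y)
            mean, cov = grid_bayes_oracle(belief, 0.15, y)
            assert np.abs(post.mean - mean).max() < 1e-3 * max(
                1.0, np.abs(mean).max()
            )
            assert np.abs(post.cov - cov).max() < 1e-3 * np.abs(cov).max()


class TestEpistemicValue:
    def test_closed_form_ln2(self):
        belief = GaussianBelief.isotropic([0, 1], 0.01)
        assert epistemic_value(belief, SensorModel(0.1)) == pytest.approx(
            math.log(2), abs=1e-12
        )

    def test_equals_det_ratio_definition(self, rng):
        for _ in range(10):
            belief = random_spd_belief(rng)
            sensor = SensorModel(rng.uniform(0.05, 1.0))
            joint = joint_covariance(belief, sensor)
            syy = belief.cov + sensor.epsilon**2 * np.eye(2)
            direct = 0.5 * math.log(
                np.linalg.det(belief.cov)
                * np.linalg.det(syy)
                / np.linalg.det(joint)
            )
            assert epistemic_value(belief, sensor) == pytest.approx(
                direct, abs=1e-9
            )

    def test_decreases_with_epsilon(self, rng):
        belief = random_spd_belief(rng)
        values = [
            epistemic_value(belief, SensorModel(e))
            for e in (0.05, 0.1, 0.3, 1.0, 10.0)
        ]
        assert all(a > b for a, b in zip(values, values[1:]))
        assert values[-1] < 1e-3  # uninformative sensor limit

    def test_matches_monte_carlo_oracle(self):
        belief = GaussianBelief.isotropic([0.0, 1.0], 0.01)
        mc = mc_mutual_information_oracle(belief, 0.1, n=100_000, seed=3)
        assert abs(mc - epistemic_value(belief, SensorModel(0.1))) < 0.02


class TestPushforward:
    def test_identity_map_is_exact(self, rng):
        belief = random_spd_belief(rng)
        for scheme in (
            PushforwardScheme("closed_form_rigid"),
            PushforwardScheme("quadrature"),
        ):
            pushed = pushforward(belief, AffineMap.identity(), scheme)
            assert np.allclose(pushed.mean, belief.mean, atol=1e-12)
            assert np.allclose(pushed.cov, belief.cov, atol=1e-12)

    def test_rigid_rotation_closed_form(self, rng):
        belief = random_spd_belief(rng)
        c, s = 0.0, 1.0  # 90 degrees about the plane normal
        rot3 = np.array([[c, 0, -s], [0, 1, 0], [s, 0, c]], dtype=float)
        mapping = AffineMap(rot3, np.zeros(3))
        pushed = pushforward(
            belief, mapping, PushforwardScheme("closed_form_rigid")
        )
        rot2 = np.array([[c, -s], [s, c]])
        assert np.allclose(pushed.mean, rot2 @ belief.mean)
        assert np.allclose(
            np.sort(np.linalg.eigvalsh(pushed.cov)),
            np.sort(np.linalg.eigvalsh(belief.cov)),
        )

    def test_closed_form_rejects_projective(self, rng):
        belief = random_spd_belief(rng)
        with pytest.raises(TypeError):
            pushforward(
                belief,
                ProjectiveMap.identity(),
                PushforwardScheme("closed_form_rigid"),
            )

    def test_quadrature_matches_monte_carlo(self, rng):
        for i in range(5):
            geo = GeometryConfig.projective(rng.uniform(0.3, 1.0))
            psi, _, _ = random_planar_transition(rng, geo)
            belief = GaussianBelief.isotropic([0.0, rng.uniform(0.3, 0.6)], 0.01)
            quad = pushforward(belief, psi, PushforwardScheme("quadrature"))
            mc = pushforward(
                belief,
                psi,
                PushforwardScheme("monte_carlo", n_samples=100_000, seed=i),
            )
            assert np.abs(quad.mean - mc.mean).max() < 1e-3
            assert np.abs(quad.cov - mc.cov).max() < 1e-3

    def test_monte_carlo_bit_reproducible(self, rng):
        geo = GeometryConfig.projective(0.6)
        psi, _, _ = random_planar_transition(rng, geo)
        belief = GaussianBelief.isotropic([0.0, 0.4], 0.01)
        scheme = PushforwardScheme("monte_carlo", n_samples=5_000, seed=42)
        a = pushforward(belief, psi, scheme)
        b = pushforward(belief, psi, scheme)
        assert np.array_equal(a.mean, b.mean)
        assert np.array_equal(a.cov, b.cov)

    def test_euclidean_invariance_of_epistemic_value(self, rng):
        """Rigid frame changes leave the epistemic value unchanged."""
        sensor = SensorModel(0.1)
        for _ in range(10):
            belief = random_spd_belief(rng)
            psi, _, _ = random_planar_transition(rng, GeometryConfig.euclidean())
            pushed = pushforward(
                belief, psi, PushforwardScheme("closed_form_rigid")
            )
            assert epistemic_value(pushed, sensor) == pytest.approx(
                epistemic_value(belief, sensor), abs=1e-9
            )

    def test_projective_magnification_orders_by_depth(self):
        """A forward step is worth more the closer the object already is."""
        geo = GeometryConfig.projective(1.0)
        sensor = SensorModel(0.1)
        step = np.array([0.0, 0.1])
        values = []
        for depth in (2.0, 1.0, 0.5, 0.3):
            pos = np.array([0.0, 0.0])
            obj = np.array([0.0, depth])
            f0 = Frame.facing(embed_plane(pos), embed_plane(obj))
            f1 = Frame.facing(embed_plane(pos + step), embed_plane(obj))
            psi = transition_map(f0, f1, geo)
            belief = GaussianBelief.isotropic(
                [0.0, depth / (1.0 + depth)], 0.01
            )
            pushed = pushforward(belief, psi, PushforwardScheme("quadrature"))
            values.append(epistemic_value(pushed, sensor))
        assert all(a < b for a, b in zip(values, values[1:]))


class TestPearlUpdate:
    def test_identity_and_zero_contribution(self, rng):
        belief = random_spd_belief(rng)
        updated, contribution = pearl_update_unobserved(belief)
        assert updated is belief
        assert contribution == 0.0

    def test_idempotent(self, rng):
        belief = random_spd_belief(rng)
        once, _ = pearl_update_unobserved(belief)
        twice, _ = pearl_update_unobserved(once)
        assert twice is belief


class TestBallSensorOracle:
    @staticmethod
    def _grid(n, spacing):
        axis = spacing * (np.arange(n) - (n - 1) / 2)
        g = np.meshgrid(axis, axis, axis, indexing="ij")
        return np.column_stack([a.ravel() for a in g])

    def test_point_mass_value_is_zero(self):
        """Q(B_y) is 0 or 1 for a delta prior, so the entropy term vanishes."""
        pts = self._grid(9, 0.02)
        w = np.zeros(len(pts))
        w[len(pts) // 2] = 1.0
        assert ball_sensor_epistemic_value(pts, w, 0.02, 0.08) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_rigid_translation_invariance(self):
        pts = self._grid(13, 0.02)
        rng = np.random.default_rng(5)
        w = np.zeros(len(pts))
        core = np.flatnonzero(np.linalg.norm(pts, axis=1) < 0.05)
        w[core] = rng.random(core.size)
        w /= w.sum()
        value = ball_sensor_epistemic_value(pts, w, 0.02, 0.08)
        shifted = ball_sensor_epistemic_value(
            pts + np.array([0.3, -0.1, 0.2]), w, 0.02, 0.08
        )
        assert shifted == pytest.approx(value, rel=1e-12)

    def test_magnifying_support_increases_value(self):
        """Enlarging the belief relative to the sensor ball is informative.

        An expanded uniform prior leaves more to learn from a ball-sized
        observation, so the epistemic value grows with the support radius —
        the mechanism by which approach (which magnifies the internal image
        of the believed region) is preferred.
        """
        pts = self._grid(15, 0.02)
        values = []
        for radius in (0.05, 0.08, 0.12):
            mask = np.linalg.norm(pts, axis=1) <= radius
            w = mask / mask.sum()
            values.append(ball_sensor_epistemic_value(pts, w, 0.02, 0.08))
        assert values[0] < values[1] < values[2]

    def test_coarse_grid_warns(self):
        pts = self._grid(5, 0.1)
        w = np.full(len(pts), 1.0 / len(pts))
        with pytest.warns(RuntimeWarning, match="spacing"):
            ball_sensor_epistemic_value(pts, w, 0.1, 0.2)

    def test_rejects_unnormalized_weights(self):
        pts = self._grid(3, 0.02)
        with pytest.raises(ValueError):
            ball_sensor_epistemic_value(pts, np.ones(len(pts)), 0.02, 0.1)


class TestFixtureBeliefs:
    def test_random_spd_preset_is_deterministic_and_spd(self):
        spec = FixtureSpec(seed=9, belief="random_spd")
        a = make_belief(spec)
        b = make_belief(spec)
        assert np.array_equal(a.cov, b.cov)
        assert np.linalg.eigvalsh(a.cov).min() > 0
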