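"""Deformation simulator: affine/elastic sampling, composition, regimes."""
import numpy as np
import pytest

from hybridreg.grids import DisplacementField, Volume
from hybridreg.simulator import (
    AffineParams,
    AffineRanges,
    ElasticSpec,
    Regime,
    SimulatorConfig,
    affine_to_field,
    compose_fields,
    sample_affine,
    sample_deformation,
    sample_elastic,
)
from hybridreg.transform import warp_volume


class TestSampleAffine:
    def test_degenerate_intervals_give_identity(self, rng):
        p = sample_affine(AffineRanges.identity(), rng, ndim=3)
        assert p.rotation == (0, 0, 0)
        assert p.scale == (1, 1, 1)
        assert p.translation == (0, 0, 0)

    def test_monte_carlo_rotation_mean(self):
        rng = np.random.default_rng(3)
        draws = [
            sample_affine(AffineRanges(rotation_deg=(-10, 10)), rng, ndim=2).rotation[0]
            for _ in range(1000)
        ]
        assert abs(np.mean(draws)) < 1.0

    def test_rng_contract(self):
        rng = np.random.default_rng(5)
        a = sample_affine(AffineRanges(), rng, ndim=3)
        b = sample_affine(AffineRanges(), rng, ndim=3)
        assert a != b
        rng2 = np.random.default_rng(5)
        c = sample_affine(AffineRanges(), rng2, ndim=3)
        assert a == c

    def test_inverted_interval_rejected(self):
        with pytest.raises(ValueError):
            AffineRanges(rotation_deg=(10, -10))


class TestAffineToField:
    def test_identity_gives_zero_field(self):
        p = AffineParams.identity(3)
        f = affine_to_field(p, (5, 5, 5), (1, 1, 1))
        np.testing.assert_array_equal(f.vectors, 0)

    def test_pure_translation_closed_form(self):
        p = AffineParams.identity(3)
        p = AffineParams(p.rotation, p.scale, p.shear, (3.0, 0.0, 0.0), p.center)
        f = affine_to_field(p, (4, 4, 4), (1, 1, 1))
        np.testing.assert_allclose(f.vectors[..., 0], 3.0)
        np.testing.assert_allclose(f.vectors[..., 1:], 0.0)

    def test_rotation_matches_matrix_oracle(self):
        center = (2.0, 2.0, 2.0)
        p = AffineParams((0.0, 0.0, 90.0), (1, 1, 1), (0, 0, 0), (0, 0, 0), center)
        f = affine_to_field(p, (5, 5, 5), (1, 1, 1))
        R = p.matrix()
        for idx in np.ndindex(5, 5, 5):
            x = np.array(idx, dtype=float)
            expect = R @ (x - center) + center - x
            np.testing.assert_allclose(f.vectors[idx], expect, atol=1e-9)

    def test_2d_rotation_90deg(self):
        p = AffineParams((90.0,), (1, 1), (0.0,), (0, 0), (1.0, 1.0))
        f = affine_to_field(p, (3, 3), (1, 1))
        # voxel (0,0) about centre (1,1): R90 @ (-1,-1) = (1,-1) -> target (2,0)
        np.testing.assert_allclose(f.vectors[0, 0], [2.0, 0.0], atol=1e-12)


class TestSampleElastic:
    def test_zero_max_displacement(self, rng):
        spec = ElasticSpec(max_displacement=0.0)
        f = sample_elastic(spec, (16, 16), (1, 1), rng)
        np.testing.assert_array_equal(f.vectors, 0)

    def test_magnitude_cap_is_exact(self, rng):
        spec = ElasticSpec(control_spacings=[4, 8], max_displacement=5.0)
        for _ in range(5):
            f = sample_elastic(spec, (20, 20), (0.5, 2.0), rng)
            peak = f.magnitude_mm().max()
            assert peak <= 5.0 + 1e-6
            assert peak == pytest.approx(5.0, rel=1e-9)

    def test_smoothness_monte_carlo(self):
        # max finite-difference gradient stays near a reference draw's level
        rng = np.random.default_rng(0)
        spec = ElasticSpec(control_spacings=[4], max_displacement=5.0, smoothness_sigma=2.0)

        def max_grad(f):
            g = 0.0
            for k in range(2):
                for ax in range(2):
                    g = max(g, np.abs(np.diff(f.vectors[..., k], axis=ax)).max())
            return g

        ref = max_grad(sample_elastic(spec, (32, 32), (1, 1), rng))
        grads = [max_grad(sample_elastic(spec, (32, 32), (1, 1), rng)) for _ in range(20)]
        assert 0.5 * ref <= np.mean(grads) <= 1.5 * ref

    def test_negative_max_displacement_rejected(self):
        with pytest.raises(ValueError):
            ElasticSpec(max_displacement=-1.0)


class TestComposeFields:
    def test_zero_is_identity_element(self, rng):
        f = DisplacementField(rng.standard_normal((6, 6, 2)), (1, 1))
        zero = DisplacementField.zeros((6, 6), (1, 1))
        np.testing.assert_allclose(compose_fields(zero, f).vectors, f.vectors)
        np.testing.assert_allclose(compose_fields(f, zero).vectors, f.vectors)

    def test_constant_translations_add(self):
        t1 = DisplacementField(np.broadcast_to([1.0, 2.0], (8, 8, 2)).copy(), (1, 1))
        t2 = DisplacementField(np.broadcast_to([0.5, -1.0], (8, 8, 2)).copy(), (1, 1))
        out = compose_fields(t1, t2)
        interior = out.vectors[2:-2, 2:-2]
        np.testing.assert_allclose(interior, np.broadcast_to([1.5, 1.0], interior.shape))

    def test_composition_consistent_with_sequential_warping(self, rng):
        # smooth image on an 8^3 grid: linear ramp plus a low-curvature
        # cosine, so the double-interpolation error stays below the tolerance
        idx = np.meshgrid(*[np.arange(8)] * 3, indexing="ij")
        img = sum(0.1 * g + 0.1 * np.cos(2 * np.pi * g / 64.0) for g in idx)
        v = Volume(img, (1, 1, 1))
        outer = DisplacementField(rng.uniform(-0.5, 0.5, (8, 8, 8, 3)), (1, 1, 1))
        inner = DisplacementField(rng.uniform(-0.5, 0.5, (8, 8, 8, 3)), (1, 1, 1))
        seq = warp_volume(warp_volume(v, outer, "linear"), inner, "linear")
        once = warp_volume(v, compose_fields(outer, inner), "linear")
        # compare away from the border: edge clamping inside the sequential
        # route's intermediate image reaches one voxel into the grid
        core = (slice(2, -2),) * 3
        np.testing.assert_allclose(once.values[core], seq.values[core], atol=1e-3)

    def test_shape_mismatch_rejected(self):
        a = DisplacementField.zeros((4, 4), (1, 1))
        b = DisplacementField.zeros((6, 6), (1, 1))
        with pytest.raises(ValueError):
            compose_fields(a, b)


class TestSampleDeformation:
    def test_zero_fraction_always_small(self, rng):
        cfg = SimulatorConfig(large_fraction=0.0)
        labels = {
            sample_deformation(cfg, (8, 8), (1, 1), rng)[1] for _ in range(20)
        }
        assert labels == {"small"}

    def test_magnitude_bound_with_identity_affine(self, rng):
        regime = Regime(
            affine=AffineRanges.identity(),
            elastic=ElasticSpec(max_displacement=15.0),
        )
        cfg = SimulatorConfig(small=regime, large=regime, large_fraction=1.0)
        for _ in range(5):
            f, label = sample_deformation(cfg, (16, 16), (1, 1), rng)
            assert label == "large"
            assert f.magnitude_mm().max() <= 15.0 + 1e-6

    def test_zero_magnitude_config_gives_zero_field(self, rng):
        regime = Regime(
            affine=AffineRanges.identity(), elastic=ElasticSpec(max_displacement=0.0)
        )
        cfg = SimulatorConfig(small=regime, large=regime, large_fraction=0.0)
        f, _ = sample_deformation(cfg, (12, 12), (1, 1), rng)
        np.testing.assert_array_equal(f.vectors, 0)

    def test_large_regime_frequency_in_binomial_band(self):
        rng = np.random.default_rng(11)
        cfg = SimulatorConfig(large_fraction=0.2)
        n_large = sum(
            sample_deformation(cfg, (8, 8), (1, 1), rng)[1] == "large"
            for _ in range(400)
        )
        # central 99% binomial interval for n=400, p=0.2
        assert 52 <= n_large <= 109

    def test_determinism(self):
        cfg = SimulatorConfig()
        f1, l1 = sample_deformation(cfg, (12, 12), (1, 1), np.random.default_rng(9))
        f2, l2 = sample_deformation(cfg, (12, 12), (1, 1), np.random.default_rng(9))
        assert l1 == l2
        np.testing.assert_array_equal(f1.vectors, f2.vectors)
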