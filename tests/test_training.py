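"""Hybrid-supervised training loop: pair construction, bookkeeping, descent."""
import dataclasses

import numpy as np
import pytest
from scipy import stats

from hybridreg.evaluation import evaluate_cases, make_eval_cases
from hybridreg.experiments import build_split, preprocess_subject
from hybridreg.losses import LossWeights
from hybridreg.network import NetworkSpec, build_network, predict_field
from hybridreg.phantoms import desk_spec_2d, generate_cohort
from hybridreg.simulator import (
    AffineRanges,
    ElasticSpec,
    Regime,
    SimulatorConfig,
    desk_simulator,
)
from hybridreg.training import (
    TrainConfig,
    augment_noise,
    make_supervised_pair,
    sample_selfsup_pair,
    train,
    validate,
)


def zero_sim():
    regime = Regime(
        affine=AffineRanges.identity(), elastic=ElasticSpec(max_displacement=0.0)
    )
    return SimulatorConfig(small=regime, large=regime, large_fraction=0.0)


@pytest.fixture(scope="module")
def cohort2d():
    return [preprocess_subject(s) for s in generate_cohort(desk_spec_2d(), 4, 0)]


@pytest.fixture(scope="module")
def tiny_net():
    return NetworkSpec(levels=2, base_channels=4, dilation_rates=[1], dims=2)


def small_cfg(**overrides):
    base = dict(
        steps=5,
        learning_rate=1e-3,
        seed=0,
        simulator=desk_simulator(),
        val_every=1000,
    )
    base.update(overrides)
    return TrainConfig(**base)


class TestMakeSupervisedPair:
    def test_zero_magnitude_simulator_is_identity_supervision(self, cohort2d, rng):
        M = cohort2d[0].volume
        I0, Fg0 = make_supervised_pair(M, zero_sim(), rng)
        np.testing.assert_array_equal(Fg0.vectors, 0)
        np.testing.assert_allclose(I0.values, M.values, atol=1e-7)

    def test_reproducible_under_fixed_rng(self, cohort2d):
        M = cohort2d[0].volume
        a = make_supervised_pair(M, desk_simulator(), np.random.default_rng(4))
        b = make_supervised_pair(M, desk_simulator(), np.random.default_rng(4))
        np.testing.assert_array_equal(a[1].vectors, b[1].vectors)
        np.testing.assert_array_equal(a[0].values, b[0].values)

    def test_landmarks_map_to_counterpart_features(self, cohort2d, rng):
        # fixed-point inversion oracle: the moving-image landmark q_m should
        # correspond to the reference-space point q_r with q_r + u(q_r) = q_m
        from hybridreg.transform import sample_field_at_points

        subj = cohort2d[0]
        M = subj.volume
        I0, Fg0 = make_supervised_pair(M, desk_simulator(), rng)
        sp = np.array(M.spacing)
        for q_m in subj.landmarks.points_mm:
            q_r = q_m.copy()
            for _ in range(50):
                u, _ = sample_field_at_points(Fg0, q_r[None])
                q_r = q_m - u[0]
            u, inb = sample_field_at_points(Fg0, q_r[None])
            if not inb[0]:
                continue
            assert np.linalg.norm((q_r + u[0]) - q_m) <= np.max(sp)


class TestSampleSelfsupPair:
    def test_cohort_of_two_always_distinct(self, cohort2d, rng):
        pair_pool = cohort2d[:2]
        for _ in range(10):
            m, i1 = sample_selfsup_pair(pair_pool, rng)
            assert m is not i1

    def test_needs_two_subjects(self, cohort2d, rng):
        with pytest.raises(ValueError):
            sample_selfsup_pair(cohort2d[:1], rng)

    def test_ordered_pair_frequencies_uniform(self, cohort2d):
        rng = np.random.default_rng(0)
        vols = [s.volume for s in cohort2d]
        ids = {id(v.values): i for i, v in enumerate(vols)}
        counts = {}
        n = 1000
        for _ in range(n):
            m, i1 = sample_selfsup_pair(vols, rng)
            key = (ids[id(m.values)], ids[id(i1.values)])
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 12
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 1 / 12)
        assert all(lo <= c <= hi for c in counts.values())

    def test_reproducible_sequence(self, cohort2d):
        vols = [s.volume for s in cohort2d]
        seq1 = [sample_selfsup_pair(vols, np.random.default_rng(9)) for _ in range(1)]
        seq2 = [sample_selfsup_pair(vols, np.random.default_rng(9)) for _ in range(1)]
        assert seq1[0][0] is seq2[0][0] and seq1[0][1] is seq2[0][1]


class TestAugmentNoise:
    def test_zero_sd_is_identity(self, cohort2d, rng):
        v = cohort2d[0].volume
        assert augment_noise(v, 0.0, rng) is v

    def test_sample_sd_in_chi_square_band(self):
        from hybridreg.grids import Volume

        v = Volume(np.zeros((64, 64)), (1, 1), intensity_domain="zscored")
        out = augment_noise(v, 0.05, np.random.default_rng(2))
        assert 0.045 <= out.values.std() <= 0.055

    def test_reproducible(self, cohort2d):
        v = cohort2d[0].volume
        a = augment_noise(v, 0.1, np.random.default_rng(5))
        b = augment_noise(v, 0.1, np.random.default_rng(5))
        np.testing.assert_array_equal(a.values, b.values)


class TestTrainLoop:
    def test_history_bookkeeping_reconstructs_total(self, cohort2d, tiny_net):
        model = build_network(tiny_net, 0)
        cfg = small_cfg(steps=1)
        _, hist = train(model, cohort2d, cfg)
        row = hist.iloc[0]
        wts = cfg.weights
        expect = wts.alpha * row.L_F + wts.beta * row.L_M0 + wts.gamma * row.L_M1
        assert row.total == pytest.approx(expect, abs=1e-6)

    def test_field_only_near_identity_start_stays_bounded(self, cohort2d, tiny_net):
        model = build_network(tiny_net, 0)
        cfg = small_cfg(
            steps=5, weights=LossWeights(alpha=1.0, beta=0.0, gamma=0.0),
            simulator=zero_sim(),
        )
        _, hist = train(model, cohort2d, cfg)
        assert hist.L_F.iloc[0] < 0.1  # near-identity init, zero gold field
        assert hist.L_F.max() < 1.0

    def test_overfit_fixed_pair_decreases_field_loss(self, cohort2d, tiny_net):
        # beta = gamma = 0 and a frozen supervised pair: 200 steps of Adam
        # must strictly reduce L_F
        from hybridreg import autodiff as ad
        from hybridreg.losses import ad_field_loss

        model = build_network(tiny_net, 1)
        M = cohort2d[0].volume
        I0, Fg0 = make_supervised_pair(
            M, desk_simulator(), np.random.default_rng(0)
        )
        opt = ad.Adam(model.parameters(), lr=1e-3)
        losses = []
        for _ in range(200):
            out = model.forward(
                M.values.astype(np.float32), I0.values.astype(np.float32)
            )
            loss = ad_field_loss(out, Fg0)
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        assert losses[-1] < 0.5 * losses[0]

    def test_seed_determinism_of_history(self, cohort2d, tiny_net):
        h = []
        for _ in range(2):
            model = build_network(tiny_net, 0)
            _, hist = train(model, cohort2d, small_cfg(steps=4))
            h.append(hist)
        assert h[0].equals(h[1])

    def test_non_finite_loss_aborts_with_diagnostic(self, cohort2d, tiny_net):
        model = build_network(tiny_net, 0)
        model.params["head.w"].data[:] = np.inf
        with pytest.raises(FloatingPointError, match="L_F"):
            train(model, cohort2d, small_cfg(steps=1))


@pytest.fixture(scope="module")
def val_cases(cohort2d):
    return make_eval_cases(cohort2d[:2], desk_simulator(), seed=3, n_cases=2)


class TestValidate:

    def test_oracle_predictor_scores_perfectly(self, val_cases):
        report = evaluate_cases(
            lambda m, r: next(
                c.gold_field for c in val_cases if c.moving is m
            ),
            val_cases,
        )
        assert report.aggregates["epe_mm"][0] <= 1e-6
        assert report.aggregates["dice"][0] >= 0.99

    def test_identity_model_equals_unregistered_baseline(self, val_cases):
        from hybridreg.evaluation import identity_predictor

        report = evaluate_cases(identity_predictor, val_cases)
        for case, epe in zip(val_cases, report.per_case.epe_mm):
            gold = np.linalg.norm(case.landmarks.gold_vectors_mm, axis=1).mean()
            assert epe == pytest.approx(gold, abs=1e-9)

    def test_repeated_validation_is_deterministic(self, val_cases, tiny_net):
        model = build_network(tiny_net, 0)
        m1 = validate(model, val_cases)
        m2 = validate(model, val_cases)
        assert m1 == m2

    def test_empty_validation_set_rejected(self, tiny_net):
        with pytest.raises(ValueError):
            validate(build_network(tiny_net, 0), [])
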