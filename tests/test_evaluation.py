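"""Evaluation metrics: landmark EPE, NMI, Dice, paired t-test, cohort reports."""
import numpy as np
import pytest

from hybridreg.evaluation import (
    EvalReport,
    compare_methods,
    dice,
    evaluate_cases,
    evaluate_cohort,
    identity_predictor,
    landmark_epe,
    make_eval_cases,
    nmi,
    paired_ttest,
)
from hybridreg.experiments import preprocess_subject
from hybridreg.grids import DisplacementField, LabelMask, LandmarkSet, Volume
from hybridreg.phantoms import desk_spec_2d, generate_cohort
from hybridreg.simulator import desk_simulator


class TestLandmarkEpe:
    def test_generating_field_scores_zero(self, rng):
        f = DisplacementField(rng.standard_normal((8, 8, 8, 3)), (1, 1, 2))
        from hybridreg.transform import sample_field_at_points

        pts = rng.uniform(2, 5, (6, 3)) * np.array(f.spacing)
        gold, _ = sample_field_at_points(f, pts)
        lms = LandmarkSet([f"p{i}" for i in range(6)], pts, gold_vectors_mm=gold)
        _, mean = landmark_epe(f, lms)
        assert mean <= 1e-6

    def test_zero_field_single_gold_vector(self):
        f = DisplacementField.zeros((8, 8, 8), (0.36, 0.36, 2.0))
        lms = LandmarkSet(
            ["a"], [[1.0, 1.0, 2.0]], gold_vectors_mm=[[0.36, 0.0, 2.0]]
        )
        _, mean = landmark_epe(f, lms)
        assert mean == pytest.approx(np.sqrt(0.36**2 + 2**2), abs=1e-6)
        assert mean == pytest.approx(2.0321, abs=1e-3)

    def test_matches_per_point_loop_oracle(self, rng):
        from hybridreg.transform import sample_field_at_points

        f = DisplacementField(rng.standard_normal((8, 8, 8, 3)), (1, 1, 1))
        pts = rng.uniform(1, 6, (5, 3))
        gold = rng.standard_normal((5, 3))
        lms = LandmarkSet([f"p{i}" for i in range(5)], pts, gold_vectors_mm=gold)
        per_point, mean = landmark_epe(f, lms)
        pred, _ = sample_field_at_points(f, pts)
        expect = [np.linalg.norm(p - g) for p, g in zip(pred, gold)]
        np.testing.assert_allclose(per_point, expect, atol=1e-10)
        assert mean == pytest.approx(np.mean(expect), abs=1e-10)

    def test_missing_gold_vectors_rejected(self):
        f = DisplacementField.zeros((4, 4), (1, 1))
        lms = LandmarkSet(["a"], [[1.0, 1.0]])
        with pytest.raises(ValueError):
            landmark_epe(f, lms)

    def test_out_of_extent_point_excluded_and_flagged(self):
        f = DisplacementField.zeros((4, 4), (1, 1))
        lms = LandmarkSet(
            ["in", "out"], [[1.0, 1.0], [40.0, 1.0]],
            gold_vectors_mm=[[0.0, 0.0], [0.0, 0.0]],
        )
        per_point, mean = landmark_epe(f, lms)
        assert np.isnan(per_point[1]) and not np.isnan(per_point[0])
        assert mean == pytest.approx(0.0)


class TestNmi:
    def test_self_information_is_one(self, rng):
        v = Volume(rng.standard_normal((12, 12)), (1, 1))
        assert nmi(v, v) == pytest.approx(1.0, abs=1e-9)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(0)
        a = Volume(rng.random((32, 32, 32)), (1, 1, 1))
        b = Volume(rng.random((32, 32, 32)), (1, 1, 1))
        assert nmi(a, b, bins=32) < 0.05

    def test_symmetry(self, rng):
        a = Volume(rng.standard_normal((10, 10)), (1, 1))
        b = Volume(rng.standard_normal((10, 10)), (1, 1))
        assert nmi(a, b) == pytest.approx(nmi(b, a), abs=1e-12)

    def test_constant_image_rejected(self):
        a = Volume(np.zeros((6, 6)), (1, 1))
        b = Volume(np.arange(36.0).reshape(6, 6), (1, 1))
        with pytest.raises(ValueError):
            nmi(a, b)

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(5):
            a = Volume(rng.standard_normal((10, 10)), (1, 1))
            b = Volume(0.5 * a.values + rng.standard_normal((10, 10)), (1, 1))
            assert 0.0 <= nmi(a, b) <= 1.0


class TestDice:
    def mask(self, arr):
        return LabelMask(np.asarray(arr, dtype=np.uint8), (1, 1))

    def test_identical_masks(self):
        m = self.mask(np.eye(6, dtype=int))
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), dtype=int)
        b = np.zeros((4, 4), dtype=int)
        a[0], b[2] = 1, 1
        assert dice(self.mask(a), self.mask(b)) == 0.0

    def test_half_overlap_closed_form(self):
        a = np.zeros((4, 4), dtype=int)
        b = np.zeros((4, 4), dtype=int)
        a[0:2] = 1  # 8 voxels
        b[1:3] = 1  # 8 voxels, overlap 4
        assert dice(self.mask(a), self.mask(b)) == 0.5

    def test_both_empty_rejected(self):
        z = self.mask(np.zeros((3, 3), dtype=int))
        with pytest.raises(ValueError):
            dice(z, z)


class TestPairedTtest:
    def test_closed_form_example(self):
        t, p, df = paired_ttest([2.0, 3.0, 4.0], [1.0, 1.0, 1.0])
        assert t == pytest.approx(2 / (1 / np.sqrt(3)), abs=1e-4)
        assert t == pytest.approx(3.4641, abs=1e-4)
        assert df == 2
        assert p == pytest.approx(0.0742, abs=1e-4)

    def test_constant_difference_rejected(self):
        with pytest.raises(ValueError):
            paired_ttest([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])

    def test_antisymmetry(self, rng):
        x = rng.standard_normal(8)
        y = rng.standard_normal(8)
        t1, p1, _ = paired_ttest(x, y)
        t2, p2, _ = paired_ttest(y, x)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)


@pytest.fixture(scope="module")
def test_subjects():
    return [preprocess_subject(s) for s in generate_cohort(desk_spec_2d(), 3, 5)]


class TestEvaluateCohort:
    def test_oracle_fields_upper_bound(self, test_subjects):
        cases = make_eval_cases(test_subjects, desk_simulator(), seed=0, n_cases=4)
        golds = {c.case_id: c.gold_field for c in cases}
        by_case = iter([golds[c.case_id] for c in cases])
        report = evaluate_cases(lambda m, r: next(by_case), cases)
        assert report.aggregates["epe_mm"][0] <= 1e-6
        assert report.aggregates["dice"][0] >= 0.99

    def test_identity_fields_match_direct_baseline(self, test_subjects):
        report = evaluate_cohort(
            identity_predictor, test_subjects, pairing_seed=1, sim=desk_simulator()
        )
        cases = make_eval_cases(test_subjects, desk_simulator(), seed=1)
        for case, row_epe in zip(cases, report.per_case.epe_mm):
            gold = np.linalg.norm(case.landmarks.gold_vectors_mm, axis=1).mean()
            assert row_epe == pytest.approx(gold, abs=1e-9)

    def test_same_seed_identical_reports_except_runtime(self, test_subjects):
        r1 = evaluate_cohort(identity_predictor, test_subjects, 7, desk_simulator())
        r2 = evaluate_cohort(identity_predictor, test_subjects, 7, desk_simulator())
        cols = [c for c in r1.per_case.columns if c != "runtime_s"]
        assert r1.per_case[cols].equals(r2.per_case[cols])

    def test_aggregates_recompute_from_rows(self, test_subjects):
        report = evaluate_cohort(identity_predictor, test_subjects, 3, desk_simulator())
        agg = report.aggregates
        assert agg["epe_mm"][0] == pytest.approx(report.per_case.epe_mm.mean())
        assert agg["epe_mm"][1] == pytest.approx(report.per_case.epe_mm.std(ddof=1))

    def test_method_comparison_paired_t(self, test_subjects):
        ident = evaluate_cohort(identity_predictor, test_subjects, 2, desk_simulator())
        cases = make_eval_cases(test_subjects, desk_simulator(), seed=2)
        golds = iter([c.gold_field for c in cases])
        oracle = evaluate_cases(lambda m, r: next(golds), cases)
        t, p, df = compare_methods(ident, oracle, "epe_mm")
        assert df == len(cases) - 1
        assert t > 0  # identity EPE strictly larger than the oracle's
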