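"""Registration quality metrics and cohort-level evaluation reports.

Metrics follow the standard battery for deformable registration studies:
sparse-landmark endpoint error (EPE, mm), normalized mutual information
(NMI, joint-histogram estimator, bounded in [0, 1]), Dice overlap of a
transported territory label, and a two-sided paired t-test for method
comparisons. Cohort evaluation draws simulated (reference, moving) pairs
from held-out test subjects, so gold sparse vectors come exactly from the
generating field sampled at the landmarks.
"""
from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .grids import DisplacementField, LabelMask, LandmarkSet, Volume
from .phantoms import Subject
from .simulator import SimulatorConfig, sample_deformation_parts
from .transform import sample_field_at_points, warp_mask, warp_volume

__all__ = [
    "landmark_epe",
    "nmi",
    "dice",
    "paired_ttest",
    "EvalReport",
    "evaluate_cohort",
    "identity_predictor",
    "make_eval_cases",
    "EvalCase",
]

Predictor = Callable[[Volume, Volume], DisplacementField]


def landmark_epe(
    pred_field: DisplacementField, landmarks: LandmarkSet
) -> Tuple[np.ndarray, float]:
    """Endpoint error (mm) at each gold-annotated landmark, plus the mean.

    The predicted sparse vector at point ``q`` is the multilinear sample of
    the predicted field converted to mm; EPE is its Euclidean distance from
    the gold vector. Out-of-extent points are excluded from the mean and
    reported as NaN in the per-point array.
    """
    if landmarks.gold_vectors_mm is None:
        raise ValueError("landmarks carry no gold displacement vectors")
    pred_mm, in_bounds = sample_field_at_points(pred_field, landmarks.points_mm)
    err = np.linalg.norm(pred_mm - landmarks.gold_vectors_mm, axis=1)
    err = np.where(in_bounds, err, np.nan)
    if not in_bounds.any():
        raise ValueError("all landmarks fall outside the field extent")
    return err, float(np.nanmean(err))


def nmi(a: Volume, b: Volume, bins: int = 32) -> float:
    """Normalized mutual information 2*I(A;B)/(H(A)+H(B)) in [0, 1].

    The joint histogram uses ``bins`` equal-width bins per image over each
    image's own [min, max] range; 0*log(0) counts as 0.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    x = np.asarray(a.values, dtype=float).ravel()
    y = np.asarray(b.values, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("images must share a shape")
    if x.min() == x.max() or y.min() == y.max():
        raise ValueError("NMI is undefined for a constant image")
    joint, _, _ = np.histogram2d(x, y, bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)

    def entropy(q):
        q = q[q > 0]
        return float(-(q * np.log(q)).sum())

    hx, hy, hxy = entropy(px), entropy(py), entropy(p.ravel())
    mi = hx + hy - hxy
    return float(2.0 * mi / (hx + hy))


def dice(a: LabelMask, b: LabelMask) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) of two binary masks."""
    if a.shape != b.shape:
        raise ValueError("masks must share a shape")
    na, nb = int(a.values.sum()), int(b.values.sum())
    if na == 0 and nb == 0:
        raise ValueError("Dice is undefined for two empty masks")
    inter = int((a.values & b.values).sum())
    return 2.0 * inter / (na + nb)


def paired_ttest(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float, int]:
    """Two-sided paired t-test on d = x - y; returns (t, p, df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two equal-length samples with n >= 2")
    d = x - y
    if d.std(ddof=1) == 0:
        raise ValueError("zero-variance differences; paired t is undefined")
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue), len(x) - 1


# -- cohort evaluation -------------------------------------------------------


@dataclass
class EvalCase:
    """One simulated test pair with exact gold supervision."""

    case_id: str
    moving: Volume
    reference: Volume
    gold_field: DisplacementField
    landmarks: LandmarkSet  # gold vectors sampled from gold_field
    moving_territory: LabelMask
    reference_territory: LabelMask
    affine_field: Optional[DisplacementField] = None  # smooth part, for ceilings


def make_eval_cases(
    subjects: Sequence[Subject],
    sim: SimulatorConfig,
    seed: int,
    n_cases: Optional[int] = None,
) -> List[EvalCase]:
    """Build simulated (reference, moving) pairs from test subjects.

    For each case a subject is drawn, a gold field is sampled, and the
    reference image/territory are the subject warped by that field. Gold
    sparse vectors are the field sampled at the subject's landmarks.
    """
    if not subjects:
        raise ValueError("no test subjects given")
    rng = np.random.default_rng([int(seed), 101])
    n_cases = n_cases or len(subjects)
    cases = []
    for i in range(n_cases):
        subj = subjects[int(rng.integers(len(subjects)))]
        f, _, f_aff, _ = sample_deformation_parts(
            sim, subj.volume.shape, subj.volume.spacing, rng
        )
        reference = warp_volume(subj.volume, f, "linear")
        ref_terr = warp_mask(subj.territory_mask, f)
        gold_mm, _ = sample_field_at_points(f, subj.landmarks.points_mm)
        lms = LandmarkSet(
            list(subj.landmarks.names), subj.landmarks.points_mm, gold_vectors_mm=gold_mm
        )
        cases.append(
            EvalCase(
                case_id=f"case{i:03d}",
                moving=subj.volume,
                reference=reference,
                gold_field=f,
                landmarks=lms,
                moving_territory=subj.territory_mask,
                reference_territory=ref_terr,
                affine_field=f_aff,
            )
        )
    return cases


@dataclass
class EvalReport:
    """Per-case metric rows plus aggregates that recompute from the rows."""

    per_case: pd.DataFrame
    comparisons: Dict[str, Tuple[float, float, int]] = field(default_factory=dict)

    METRICS = ("epe_mm", "nmi", "dice", "runtime_s")

    @property
    def aggregates(self) -> Dict[str, Tuple[float, float]]:
        out = {}
        for m in self.METRICS:
            col = self.per_case[m].dropna()
            out[m] = (float(col.mean()), float(col.std(ddof=1)) if len(col) > 1 else 0.0)
        return out

    def to_csv(self, path):
        self.per_case.to_csv(path, index=False)

    def format_table(self) -> str:
        agg = self.aggregates
        lines = ["metric        mean ± sd"]
        for m in self.METRICS:
            mean, sd = agg[m]
            lines.append(f"{m:<12s}  {mean:.4f} ± {sd:.4f}")
        return "\n".join(lines)


def identity_predictor(moving: Volume, reference: Volume) -> DisplacementField:
    """Zero-field baseline (no registration)."""
    return DisplacementField.zeros(moving.shape, moving.spacing)


def evaluate_cases(predictor: Predictor, cases: Sequence[EvalCase]) -> EvalReport:
    """Run a predictor over prepared cases and collect metrics."""
    rows = []
    for case in cases:
        row = dict(case_id=case.case_id, epe_mm=np.nan, nmi=np.nan, dice=np.nan,
                   runtime_s=np.nan, error="")
        try:
            t0 = time.perf_counter()
            f = predictor(case.moving, case.reference)
            row["runtime_s"] = time.perf_counter() - t0
            _, row["epe_mm"] = landmark_epe(f, case.landmarks)
            warped = warp_volume(case.moving, f, "linear")
            row["nmi"] = nmi(warped, case.reference)
            row["dice"] = dice(warp_mask(case.moving_territory, f), case.reference_territory)
        except Exception as exc:  # record failed rows rather than aborting
            row["error"] = str(exc)
        rows.append(row)
    return EvalReport(per_case=pd.DataFrame(rows))


def evaluate_cohort(
    predictor: Predictor,
    test_subjects: Sequence[Subject],
    pairing_seed: int,
    sim: Optional[SimulatorConfig] = None,
    n_cases: Optional[int] = None,
) -> EvalReport:
    """Evaluate a predictor on simulated pairs drawn from test subjects."""
    cases = make_eval_cases(test_subjects, sim or SimulatorConfig(), pairing_seed, n_cases)
    return evaluate_cases(predictor, cases)


def compare_methods(a: EvalReport, b: EvalReport, metric: str) -> Tuple[float, float, int]:
    """Paired t-test between two reports' per-case values of one metric."""
    return paired_ttest(a.per_case[metric].to_numpy(), b.per_case[metric].to_numpy())
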