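"""End-to-end experiment assembly: cohorts, preprocessing, training, reports.

This is the orchestration layer used by the command-line interface and by
reproduction scripts: it turns a :class:`~hybridreg.io.RunConfig` (or the
desk-scale defaults) into trained models and evaluation reports.

The desk-scale study: a 2-D phantom cohort split 8/2/4 (train/val/test,
mirroring the ratio of the clinical 57/14/30 split), 64x64 grids at 1x1 mm,
intersubject variation 0.3, the default simulator regimes, and the default
dilated U-Net trained for 2000 hybrid-loss steps. Problem sizes are chosen
so the whole study runs in a few minutes on one CPU core.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .evaluation import (
    EvalCase,
    EvalReport,
    evaluate_cases,
    identity_predictor,
    make_eval_cases,
)
from .grids import DisplacementField, Volume
from .network import NetworkSpec, RegistrationModel, build_network, predict_field
from .phantoms import PhantomSpec, Subject, desk_spec_2d, generate_cohort
from .preprocess import pad_to_multiple, strip_skull, zscore
from .simulator import SimulatorConfig, desk_simulator
from .training import TrainConfig, train

__all__ = [
    "preprocess_subject",
    "build_split",
    "register_pair",
    "model_predictor",
    "ExperimentResult",
    "desk_train_config",
    "run_desk_experiment",
]


def preprocess_subject(subj: Subject) -> Subject:
    """Skull-strip and z-score a phantom subject, keeping labels/landmarks."""
    stripped, mask = strip_skull(subj.volume)
    normalized = zscore(stripped, mask)
    return Subject(normalized, subj.territory_mask, subj.brain_mask, subj.landmarks)


def build_split(
    spec: PhantomSpec, n_train: int, n_val: int, n_test: int, seed: int
) -> Tuple[List[Subject], List[Subject], List[Subject]]:
    """Generate and preprocess a train/val/test cohort from one phantom family."""
    cohort = [preprocess_subject(s) for s in generate_cohort(spec, n_train + n_val + n_test, seed)]
    return (
        cohort[:n_train],
        cohort[n_train : n_train + n_val],
        cohort[n_train + n_val :],
    )


def register_pair(
    model: RegistrationModel, moving: Volume, reference: Volume
) -> DisplacementField:
    """Predict the displacement field for one pair, padding to the network's
    divisor and cropping the field back to the input grid."""
    div = model.spec.divisor
    if all(n % div == 0 for n in moving.shape):
        return predict_field(model, moving, reference)
    m_pad, rec = pad_to_multiple(moving, div)
    r_pad, _ = pad_to_multiple(reference, div)
    f = predict_field(model, m_pad, r_pad)
    cropped = f.vectors[tuple(slice(0, n) for n in moving.shape)]
    return DisplacementField(cropped, moving.spacing)


def model_predictor(model: RegistrationModel):
    return lambda moving, reference: register_pair(model, moving, reference)


@dataclass
class ExperimentResult:
    model: RegistrationModel
    history: pd.DataFrame
    report_registered: EvalReport
    report_identity: EvalReport
    report_affine_oracle: EvalReport
    test_cases: List[EvalCase]
    summary: Dict[str, float]


def case_field_predictor(cases: Sequence[EvalCase], attr: str = "gold_field"):
    """Predictor that replays a stored per-case field (oracle baselines)."""
    fields = iter([getattr(c, attr) for c in cases])
    return lambda moving, reference: next(fields)


def desk_train_config(seed: int, steps: int = 2000, **overrides) -> TrainConfig:
    cfg = TrainConfig(steps=steps, seed=seed, learning_rate=2e-3, val_every=100)
    return dataclasses.replace(cfg, **overrides) if overrides else cfg


def _summarize(
    registered: EvalReport, identity: EvalReport, affine_oracle: EvalReport
) -> Dict[str, float]:
    reg, ident = registered.aggregates, identity.aggregates
    oracle = affine_oracle.aggregates
    summary = {
        "epe_mm_registered": reg["epe_mm"][0],
        "epe_mm_registered_sd": reg["epe_mm"][1],
        "epe_mm_identity": ident["epe_mm"][0],
        "nmi_registered": reg["nmi"][0],
        "nmi_identity": ident["nmi"][0],
        "dice_registered": reg["dice"][0],
        "dice_unregistered": ident["dice"][0],
        "epe_mm_affine_oracle": oracle["epe_mm"][0],
        "dice_affine_oracle": oracle["dice"][0],
    }
    if summary["epe_mm_identity"] > 0:
        summary["epe_reduction_percent"] = 100.0 * (
            1.0 - summary["epe_mm_registered"] / summary["epe_mm_identity"]
        )
    return summary


def run_desk_experiment(
    seed: int,
    steps: int = 2000,
    n_train: int = 8,
    n_val: int = 2,
    n_test: int = 4,
    n_test_cases: int = 8,
    phantom_spec: Optional[PhantomSpec] = None,
    network_spec: Optional[NetworkSpec] = None,
    train_cfg: Optional[TrainConfig] = None,
    sim: Optional[SimulatorConfig] = None,
) -> ExperimentResult:
    """Train and evaluate the desk-scale 2-D study end to end.

    Returns reports for the trained model and for the identity (zero-field)
    baseline on the same held-out simulated test pairs.
    """
    spec = phantom_spec or desk_spec_2d()
    sim = sim or desk_simulator()
    net = network_spec or NetworkSpec(dims=spec.ndim)
    cfg = train_cfg or desk_train_config(seed, steps)
    cfg = dataclasses.replace(cfg, simulator=sim, seed=cfg.seed)

    train_s, val_s, test_s = build_split(spec, n_train, n_val, n_test, seed)
    val_cases = make_eval_cases(val_s, sim, seed=seed + 1, n_cases=2 * len(val_s))
    test_cases = make_eval_cases(test_s, sim, seed=seed + 2, n_cases=n_test_cases)

    model = build_network(net, seed)
    model, history = train(model, train_s, cfg, val_cases=val_cases)

    report_registered = evaluate_cases(model_predictor(model), test_cases)
    report_identity = evaluate_cases(identity_predictor, test_cases)
    report_affine = evaluate_cases(
        case_field_predictor(test_cases, "affine_field"), test_cases
    )
    return ExperimentResult(
        model=model,
        history=history,
        report_registered=report_registered,
        report_identity=report_identity,
        report_affine_oracle=report_affine,
        test_cases=test_cases,
        summary=_summarize(report_registered, report_identity, report_affine),
    )
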