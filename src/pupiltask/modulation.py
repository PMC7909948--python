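"""Modulation-index decomposition of state effects on evoked firing.

The modulation index between two conditions is the difference in mean evoked
rate normalized by the sum, MI = (r_a - r_b)/(r_a + r_b), with rates averaged
over the 0.75 s stimulus windows of the presentations in each condition.
Condition pairs: active/passive (AP), large/small pupil (LS, median split),
and pre/post-behavior passive blocks (P1P2).  MI is computed from model
predictions (rectified at zero), and the component uniquely attributable to
one state variable is the full-model MI minus the MI of the partial model in
which that variable was shuffled:

    MI_AP task-unique  = MI_AP full - MI_AP pupil-only
    MI_LS pupil-unique = MI_LS full - MI_LS task-only
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .session import ReferenceResponseSet
from .statemodel import (
    DEFAULT_CONSTANTS,
    SigmoidConstants,
    evaluate_unit,
    subset_presentations,
)


def compute_mi(rate_a: float, rate_b: float) -> float:
    """(a - b) / (a + b) for non-negative mean rates; 0 when both are zero."""
    if rate_a < 0 or rate_b < 0:
        raise ValueError("MI requires non-negative rates (rectify predictions upstream)")
    s = rate_a + rate_b
    if s == 0:
        return 0.0
    return float((rate_a - rate_b) / s)


def presentation_means(pred_flat: np.ndarray, nb: int) -> np.ndarray:
    """Mean rectified rate per presentation from a flat prediction."""
    pred = np.maximum(np.asarray(pred_flat, dtype=float), 0.0)
    return pred.reshape(-1, nb).mean(axis=1)


@dataclass
class ModulationResult:
    """MI values for one unit and condition pair, per model variant."""

    pair: str                 # 'AP', 'LS' or 'P1P2'
    mi_full: float
    mi_task_only: float       # block-only model for the P1P2 pair
    mi_pupil_only: float
    mi_task_unique: float     # block-unique for the P1P2 pair
    mi_pupil_unique: float
    valid: bool = True
    reason: str = ""


def _condition_mi(pred_flat: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray,
                  nb: int) -> float:
    means = presentation_means(pred_flat, nb)
    if not mask_a.any() or not mask_b.any():
        return float("nan")
    return compute_mi(float(means[mask_a].mean()), float(means[mask_b].mean()))


def mi_decomposition(predictions: dict, mask_a: np.ndarray, mask_b: np.ndarray,
                     nb: int, pair: str = "AP") -> ModulationResult:
    """Compute MI per model variant and the unique components by subtraction.

    ``predictions`` maps model variants ('full', 'task_only', 'pupil_only') to
    flat predictions over identical bins; ``mask_a``/``mask_b`` select the
    presentations of conditions alpha and beta.
    """
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if not mask_a.any() or not mask_b.any():
        return ModulationResult(pair=pair, mi_full=np.nan, mi_task_only=np.nan,
                                mi_pupil_only=np.nan, mi_task_unique=np.nan,
                                mi_pupil_unique=np.nan, valid=False,
                                reason="empty condition class")
    mi = {k: _condition_mi(v, mask_a, mask_b, nb) for k, v in predictions.items()}
    return ModulationResult(
        pair=pair,
        mi_full=mi["full"],
        mi_task_only=mi["task_only"],
        mi_pupil_only=mi["pupil_only"],
        mi_task_unique=mi["full"] - mi["pupil_only"],
        mi_pupil_unique=mi["full"] - mi["task_only"],
    )


def sign_normalized_reduction(mi_only: np.ndarray, mi_unique: np.ndarray
                              ) -> tuple[np.ndarray, float]:
    """Sign-normalize paired MI values per unit and measure the mean reduction.

    Each unit's (only, unique) pair is multiplied by the sign of its mean
    (zero means count as +1), so population magnitude comparisons are
    direction-agnostic.  Returns the normalized (n, 2) array and the percent
    reduction 1 - mean(unique_norm)/mean(only_norm).
    """
    mi_only = np.asarray(mi_only, dtype=float)
    mi_unique = np.asarray(mi_unique, dtype=float)
    if mi_only.shape != mi_unique.shape:
        raise ValueError("paired vectors must share a shape")
    pair_mean = (mi_only + mi_unique) / 2.0
    sign = np.where(pair_mean < 0, -1.0, 1.0)
    norm = np.column_stack([mi_only * sign, mi_unique * sign])
    mean_only = norm[:, 0].mean()
    if mean_only == 0:
        return norm, 0.0
    reduction = float(1.0 - norm[:, 1].mean() / mean_only)
    return norm, reduction


def unit_modulation(refset: ReferenceResponseSet, unit: int = 0, seed: int = 0,
                    n_folds: int = 20,
                    constants: SigmoidConstants = DEFAULT_CONSTANTS,
                    evaluation=None) -> dict:
    """AP and LS modulation results for one unit from its fitted model variants.

    Pass a precomputed :class:`ModelEvaluation` via ``evaluation`` to reuse
    fits; otherwise the four model variants are fit here.
    """
    from .session import label_pupil_trials

    ev = evaluation or evaluate_unit(refset, unit=unit, seed=seed, n_folds=n_folds,
                                     constants=constants)
    preds = {k: ev.fits[k].pred for k in ("full", "task_only", "pupil_only")}
    active = refset.b == 1
    labels = label_pupil_trials(refset)
    large = labels == "large"
    out = {
        "AP": mi_decomposition(preds, active, ~active, refset.nb, pair="AP"),
        "LS": mi_decomposition(preds, large, ~large, refset.nb, pair="LS"),
    }
    return out


def p1p2_analysis(refset: ReferenceResponseSet, unit: int = 0, seed: int = 0,
                  n_folds: int = 20,
                  constants: SigmoidConstants = DEFAULT_CONSTANTS) -> ModulationResult:
    """Persistence analysis: P1-vs-P2 block identity as a state variable.

    The state model is refit on passive presentations only, with the binary
    regressor replaced by a P2 indicator alongside pupil.  MI_P1P2 block-only
    comes from the block-only model (pupil shuffled); block-unique is the
    full-model MI minus the pupil-only MI.  Sessions without both a pre- and
    post-behavior passive block are skipped with a reason.
    """
    passive = np.isin(refset.block_ord, ["P1", "P2"])
    if not (refset.block_ord == "P1").any() or not (refset.block_ord == "P2").any():
        return ModulationResult(pair="P1P2", mi_full=np.nan, mi_task_only=np.nan,
                                mi_pupil_only=np.nan, mi_task_unique=np.nan,
                                mi_pupil_unique=np.nan, valid=False,
                                reason="missing P1 or P2 block")
    sub = subset_presentations(refset, passive)
    b_block = (sub.block_ord == "P2").astype(float)
    ev = evaluate_unit(sub, unit=unit, seed=seed, n_folds=n_folds,
                       constants=constants, b_override=b_block)
    preds = {k: ev.fits[k].pred for k in ("full", "task_only", "pupil_only")}
    res = mi_decomposition(preds, b_block == 1, b_block == 0, sub.nb, pair="P1P2")
    return res
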