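"""Metrics, cross-validation splits and stratified reporting.

IoU = TP/(TP+FP+FN) and Dice = 2TP/(2TP+FP+FN) are computed per image, in
crop space (against the cropped ground truth) and in original space (after
size restoration).  Clips whose detection failed score 0 in both metrics.
Mean IoU / mean Dice are plain arithmetic means over all images, including
those zeros.  Splitting follows the study protocol: a seeded shuffle is
partitioned into three near-equal test blocks (2:1 train:test per fold);
one-fifth of each fold's remaining data is validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import crop
from .inference import CSCResult

__all__ = ["iou", "dice", "classify_axis", "make_folds", "FoldSplit",
           "EvalRecord", "evaluate_results", "summarize"]


def _counts(pred: np.ndarray, truth: np.ndarray) -> tuple[int, int, int]:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    p = pred != 0
    t = truth != 0
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    return tp, fp, fn


def iou(pred: np.ndarray, truth: np.ndarray) -> float:
    """Intersection over union; both-empty masks score 1 by convention."""
    tp, fp, fn = _counts(pred, truth)
    denom = tp + fp + fn
    return 1.0 if denom == 0 else tp / denom


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice coefficient 2TP/(2TP+FP+FN); both-empty masks score 1."""
    tp, fp, fn = _counts(pred, truth)
    denom = 2 * tp + fp + fn
    return 1.0 if denom == 0 else 2 * tp / denom


def classify_axis(angle_deg: float) -> str:
    """'apical' when the septum axis is within 30 deg of vertical.

    Angles are axial: they are folded modulo 180, so 170 deg is 10 deg from
    vertical on the other side and counts as apical.
    """
    a = float(angle_deg) % 180.0
    return "apical" if min(a, 180.0 - a) <= 30.0 else "non-apical"


@dataclass(frozen=True)
class FoldSplit:
    fold_index: int
    train_ids: tuple
    val_ids: tuple
    test_ids: tuple


def make_folds(ids: list, seed: int, groups: list | None = None) -> list[FoldSplit]:
    """Three-fold cross-validation splits with the 2:1 / one-fifth rules.

    The seeded shuffle is split into three near-equal test blocks; for each
    fold the remaining two-thirds are train+validation, with one-fifth of
    them (floor) held out as validation.  Every id appears in exactly one
    fold's test set.

    When ``groups`` is given (one label per id, e.g. the source video), the
    shuffle and all partition boundaries respect groups, so ids sharing a
    group never straddle train/validation/test of one fold.
    """
    ids = list(ids)
    if len(ids) < 3:
        raise ValueError(f"need at least 3 ids, got {len(ids)}")
    rng = np.random.default_rng(seed)
    if groups is None:
        units = [[k] for k in rng.permutation(len(ids))]
    else:
        if len(groups) != len(ids):
            raise ValueError("groups must parallel ids")
        seen: dict = {}
        for k, g in enumerate(groups):
            seen.setdefault(g, []).append(k)
        keys = list(seen)
        units = [seen[keys[j]] for j in rng.permutation(len(keys))]
    blocks = np.array_split(np.arange(len(units)), 3)
    folds = []
    for i in range(3):
        test = [k for u in blocks[i] for k in units[u]]
        rest_units = [units[u] for j in range(3) if j != i for u in blocks[j]]
        n_rest = sum(len(u) for u in rest_units)
        n_val = n_rest // 5
        val: list[int] = []
        ui = 0
        while len(val) < n_val and ui < len(rest_units):
            val.extend(rest_units[ui])
            ui += 1
        train = [k for u in rest_units[ui:] for k in u]
        folds.append(FoldSplit(
            fold_index=i,
            train_ids=tuple(ids[k] for k in train),
            val_ids=tuple(ids[k] for k in val),
            test_ids=tuple(ids[k] for k in test)))
    return folds


@dataclass(frozen=True)
class EvalRecord:
    clip_id: str
    space: str            # 'crop' | 'original'
    iou: float
    dice: float
    detected: bool
    axis_group: str       # 'apical' | 'non-apical'
    phase_group: str      # 'systole' | 'diastole'


def evaluate_results(results: list[CSCResult], truths: list[np.ndarray],
                     labels: list[dict], spaces: tuple[str, ...] = ("crop", "original"),
                     ) -> pd.DataFrame:
    """Score each result against its ground truth in the requested spaces.

    ``labels`` carry ``axis_angle_deg`` and ``phase`` per clip.  Crop-space
    truth is the ground truth cropped with the clip's own crop record
    (nearest-neighbor).  Failed detections score IoU = Dice = 0 everywhere.
    """
    if not (len(results) == len(truths) == len(labels)):
        raise ValueError("results, truths and labels must be parallel lists")
    records = []
    for res, truth, lab in zip(results, truths, labels):
        groups = dict(axis_group=classify_axis(lab["axis_angle_deg"]),
                      phase_group=lab["phase"])
        for space in spaces:
            if not res.detected:
                score_i = score_d = 0.0
            elif space == "crop":
                truth_crop = crop(truth, res.crop_record, mask=True)
                score_i = iou(res.binary_crop, truth_crop)
                score_d = dice(res.binary_crop, truth_crop)
            elif space == "original":
                score_i = iou(res.binary_original, truth)
                score_d = dice(res.binary_original, truth)
            else:
                raise ValueError(f"unknown space {space!r}")
            records.append(EvalRecord(clip_id=res.clip_id, space=space,
                                      iou=score_i, dice=score_d,
                                      detected=res.detected, **groups))
    return pd.DataFrame([r.__dict__ for r in records])


def summarize(df: pd.DataFrame, by: list[str] | None = None) -> pd.DataFrame:
    """mIoU / mDice per space (and optional extra grouping columns).

    Means are over all images, failures included as zeros.
    """
    keys = ["space"] + (by or [])
    out = (df.groupby(keys, as_index=False)
             .agg(miou=("iou", "mean"), mdice=("dice", "mean"),
                  n=("iou", "size"), n_failed=("detected", lambda s: int((~s).sum()))))
    return out
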