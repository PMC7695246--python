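"""Module-ablation benchmark on a fixed phantom dataset.

Trains and evaluates the module combinations {U-net}, {U-net + crop},
{U-net + crop + ED} and {U-net + crop + ED + backbone} under one budget and
reports crop-space and original-space mIoU/mDice per combination, averaged
over training seeds (the phantom dataset itself is fixed).  This is a
scaled-down directional twin of the clinical module-ablation study: what is
asserted is the ordering (cropping dominates; calibration refines), not the
clinical magnitudes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import CSCConfig, CSCModel
from .evaluation import summarize
from .phantom import derive_seed, make_clips

__all__ = ["ABLATION_COMBOS", "combo_config", "run_benchmark"]

ABLATION_COMBOS = ("unet", "unet+crop", "unet+crop+ed", "unet+crop+ed+backbone")


def combo_config(combo: str, **overrides) -> CSCConfig:
    """Desk-scale configuration for one named module combination."""
    if combo not in ABLATION_COMBOS:
        raise ValueError(f"unknown combination {combo!r}; choose from {ABLATION_COMBOS}")
    parts = set(combo.split("+"))
    return CSCConfig.desk(use_crop="crop" in parts, use_ed="ed" in parts,
                          use_backbone="backbone" in parts, **overrides)


def run_benchmark(n_train: int = 120, n_test: int = 60, seeds: tuple[int, ...] = (0, 1, 2),
                  combos: tuple[str, ...] = ABLATION_COMBOS, *,
                  data_seed: int = 2024, epochs_phase1: int = 10,
                  epochs_phase2: int = 30, detector_jitter: float = 0.1,
                  progress: bool = False,
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the ablation benchmark and return (summary table, per-image records).

    The summary has one row per (combo, space) with seed-averaged mIoU/mDice
    and their SD across seeds; the records table keeps every per-image score
    with combo/seed/stratification columns for downstream analysis.
    """
    train_clips = make_clips(n_train, data_seed)
    test_clips = make_clips(n_test, derive_seed(data_seed, 2))
    frames, records = [], []
    for combo in combos:
        cfg = combo_config(combo, epochs_phase1=epochs_phase1,
                           epochs_phase2=epochs_phase2,
                           detector_jitter=detector_jitter)
        for seed in seeds:
            if progress:
                print(f"[ablation] {combo}, seed {seed}")
            res = CSCModel(train_clips, cfg).fit(seed=seed)
            df = res.evaluate(test_clips, seed=derive_seed(seed, 77))
            df.insert(0, "combo", combo)
            df.insert(1, "seed", seed)
            records.append(df)
            s = summarize(df)
            s.insert(0, "combo", combo)
            s.insert(1, "seed", seed)
            frames.append(s)
    per_seed = pd.concat(frames, ignore_index=True)
    summary = (per_seed.groupby(["combo", "space"], as_index=False)
               .agg(miou=("miou", "mean"), miou_sd=("miou", "std"),
                    mdice=("mdice", "mean"), mdice_sd=("mdice", "std"),
                    n_failed=("n_failed", "mean")))
    return summary, pd.concat(records, ignore_index=True)
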