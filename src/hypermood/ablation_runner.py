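"""Metadata-subset ablation and model comparison over CV folds.

Runs a grid of (model kind x metadata subset x fold) cells, each cell being
one training + evaluation on a speaker-independent fold, writes one JSON
report per cell, and aggregates them into ablation-table-shaped summaries
(mean +/- SD of per-speaker rho and MAE over folds). Cells with existing
outputs are skipped unless forced, so interrupted grids resume; per-cell
seeds derive from (base seed, cell key) so results are order-independent.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np

from .experiments import build_arrays, prediction_table
from .evaluation import evaluate_predictions
from .hyperadapter_core import EncoderConfig
from .metadata_encoding import fit_normalizer, subset_dimension
from .training import TrainConfig, build_model, make_splits, train

_FRAME_KINDS = ("finetune", "hyperformer")


@dataclass
class ExperimentGrid:
    models: tuple = ("ffnn", "ffnn-pers")
    subsets: tuple = ("all",)
    folds: tuple = (0, 1, 2, 3, 4)
    out_dir: str | Path = "ablation_out"
    base_seed: int = 0
    max_epochs: int | None = None  # None: model-kind default
    encoder: dict = field(default_factory=dict)  # EncoderConfig overrides

    def cells(self):
        return list(product(self.models, self.subsets, self.folds))

    def cell_path(self, model: str, subset: str, fold: int) -> Path:
        return Path(self.out_dir) / model / subset / f"fold{fold}" / "report.json"


def cell_seed(base_seed: int, key: tuple) -> int:
    digest = hashlib.blake2b("|".join(map(str, (base_seed,) + key)).encode(),
                             digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2 ** 31)


def _run_cell(model_kind, subset, fold_idx, dataset, splits, grid):
    split = splits[fold_idx]
    subj_map = dataset.subject_map()
    stats = fit_normalizer([subj_map[s] for s in split.train], subset)
    use_frames = model_kind in _FRAME_KINDS
    folds = {part: build_arrays(dataset, getattr(split, part), stats, subset,
                                use_frames=use_frames)
             for part in ("train", "val", "test")}
    seed = cell_seed(grid.base_seed, (model_kind, subset, fold_idx))
    enc_cfg = None
    if use_frames:
        enc_cfg = EncoderConfig(input_dim=len(dataset.feature_names),
                                seed=seed, **grid.encoder)
    model = build_model(model_kind, input_width=len(dataset.feature_names),
                        meta_width=subset_dimension(subset),
                        enc_cfg=enc_cfg, seed=seed)
    overrides = {"seed": seed}
    if grid.max_epochs is not None:
        overrides["max_epochs"] = grid.max_epochs
    ckpt = train(model, folds, TrainConfig.for_model(model_kind, **overrides))
    ckpt_path = grid.cell_path(model_kind, subset, fold_idx).parent / "checkpoint.npz"
    ckpt_path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(ckpt_path, **{
        f"{g}/{k}": arr for g, grp in ckpt.params.items()
        for k, arr in grp.items()})
    table = prediction_table(model, folds["test"], fold=fold_idx)
    report = evaluate_predictions(table, dataset.subjects)
    return {
        "model": model_kind, "subset": subset, "fold": fold_idx,
        "seed": seed, "val_score": ckpt.val_score, "best_epoch": ckpt.epoch,
        "report": report.to_json_dict(),
    }


def run_grid(grid: ExperimentGrid, dataset, force: bool = False) -> dict:
    """Execute every grid cell (resumable) and aggregate per (model, subset).

    Failing cells are recorded under 'failures' and the run continues.
    """
    splits = make_splits(dataset.subjects, k=max(5, max(grid.folds) + 1),
                         seed=grid.base_seed)
    cell_results, failures = [], []
    for model_kind, subset, fold_idx in grid.cells():
        path = grid.cell_path(model_kind, subset, fold_idx)
        if path.exists() and not force:
            cell_results.append(json.loads(path.read_text()))
            continue
        try:
            result = _run_cell(model_kind, subset, fold_idx, dataset, splits, grid)
        except Exception as exc:  # noqa: BLE001 - partial failure is recorded
            failures.append({"model": model_kind, "subset": subset,
                             "fold": fold_idx, "error": repr(exc)})
            continue
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(result, indent=1))
        cell_results.append(result)

    rows = {}
    for res in cell_results:
        key = (res["model"], res["subset"])
        rows.setdefault(key, []).append(res)
    summary = []
    for (model_kind, subset), cells in sorted(rows.items()):
        rhos = [c["report"]["mean_rho"] for c in cells]
        maes = [c["report"]["mae"] for c in cells]
        summary.append({
            "model": model_kind, "subset": subset, "n_folds": len(cells),
            "mean_rho": float(np.mean(rhos)), "sd_rho": float(np.std(rhos)),
            "mae": float(np.mean(maes)), "sd_mae": float(np.std(maes)),
        })
    out = {"cells": cell_results, "summary": summary, "failures": failures}
    summary_path = Path(grid.out_dir) / "summary.json"
    summary_path.parent.mkdir(parents=True, exist_ok=True)
    summary_path.write_text(json.dumps(out, indent=1))
    return out
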