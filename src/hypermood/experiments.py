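"""End-to-end study-protocol experiments on synthetic cohorts.

These functions wire the generator, metadata encoding, models, training and
evaluation together at desk scale: a small transformer encoder, a reduced
recording schedule (one recording per content type per session), and three
speaker-independent CV folds per seed whose metrics are averaged. They are
what the acceptance script and the heavier tests run.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .evaluation import (evaluate_predictions, gini_report, winners_losers)
from .hyperadapter_core import EncoderConfig, hyperformer_forward
from .metadata_encoding import encode_matrix, fit_normalizer, subset_dimension
from .synth_cohort import CohortConfig, generate_cohort
from .synth_ema import (FeatureModel, MoodConfig, ScheduleConfig,
                        estimate_feature_mood_coupling, generate_dataset)
from .training import Model, TrainConfig, build_model, make_splits, predict_rows, train

DESK_ENCODER = dict(n_layers=2, hidden=16, n_heads=2, ff_mult=2,
                    adapter_dim=4, subject_dim=8, embed_dim=4, hi_hidden=16)


def _derive_seed(seed: int, label: str) -> int:
    import hashlib
    digest = hashlib.blake2b(f"{seed}|{label}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2 ** 31)


# ---------------------------------------------------------------------------
# array preparation


def build_arrays(dataset, subject_ids, stats, subset: str = "all",
                 use_frames: bool = False) -> dict:
    """Training arrays for the recordings of the given subjects: targets y,
    per-row metadata matrix m, functional features x and/or frame tensors."""
    rec = dataset.recordings
    mask = rec["subject_id"].isin(set(subject_ids)).to_numpy()
    rows = rec.loc[mask]
    subj_map = dataset.subject_map()
    subjects = sorted(set(rows["subject_id"]))
    m_by_subject = dict(zip(subjects, encode_matrix(
        [subj_map[s] for s in subjects], subset, stats)))
    out = {
        "y": rows["mood"].to_numpy(dtype=float),
        "m": np.stack([m_by_subject[s] for s in rows["subject_id"]]),
        "x": rows[list(dataset.feature_names)].to_numpy(dtype=float),
        "subject_id": rows["subject_id"].to_numpy(),
        "content": rows["content"].to_numpy(),
        "session_idx": rows["session_idx"].to_numpy(),
    }
    if use_frames:
        if dataset.frames is None:
            raise ValueError("dataset was generated without frames")
        out["frames"] = dataset.frames[mask]
    return out


def prediction_table(model: Model, data: dict, fold: int = 0) -> pd.DataFrame:
    pred = predict_rows(model, data)
    return pd.DataFrame({
        "subject_id": data["subject_id"],
        "session_idx": data["session_idx"],
        "content": data["content"],
        "y_true": data["y"],
        "y_pred": pred,
        "fold": fold,
    })


# ---------------------------------------------------------------------------
# protocol arithmetic


def schedule_arithmetic() -> dict:
    """Recording-schedule maxima implied by the default EMA protocol, counted
    from actually generated schedules (no missingness)."""
    from .synth_ema import build_schedule

    cfg = ScheduleConfig(missingness_by_group={})
    cohort = generate_cohort(CohortConfig(seed=0))
    sessions_total = recordings_total = 0
    one_subject = None
    for s in cohort:
        sessions, recordings = build_schedule(s, cfg)
        if one_subject is None:
            one_subject = (len(sessions), len(recordings))
        sessions_total += len(sessions)
        recordings_total += len(recordings)
    return {
        "n_subjects": len(cohort),
        "sessions_per_subject": one_subject[0],
        "recordings_per_subject": one_subject[1],
        "cohort_sessions": sessions_total,
        "cohort_recordings": recordings_total,
    }


# ---------------------------------------------------------------------------
# identity at initialization


def identity_at_init_deviation(seed: int = 0, n_pairs: int = 100) -> float:
    """Max |personalized - frozen baseline| prediction over random
    (subject, frames) pairs with zero-initialized generator output layers."""
    from .baselines import finetune_encoder_forward

    rng = np.random.default_rng(seed)
    cfg = EncoderConfig(input_dim=6, n_layers=2, hidden=16, n_heads=2,
                        adapter_dim=4, subject_dim=4, embed_dim=4, seed=seed)
    model = build_model("hyperformer", meta_width=9, enc_cfg=cfg, seed=seed)
    worst = 0.0
    for _ in range(n_pairs):
        frames = rng.normal(size=(5, cfg.input_dim))
        m = rng.normal(size=9)
        y0 = finetune_encoder_forward(frames, model.groups["backbone"], cfg).data
        y1 = hyperformer_forward(frames, m, model.groups["backbone"],
                                 model.groups["hypernet"], cfg).data
        worst = max(worst, float(abs(y1 - y0)))
    return worst


# ---------------------------------------------------------------------------
# personalization benchmark (hyperformer vs fine-tuned encoder)


def _benchmark_dataset(seed: int, n_per_group: int, n_frames: int):
    cohort = generate_cohort(CohortConfig(
        n_control=n_per_group, n_subclinical=n_per_group,
        n_patients=n_per_group, seed=_derive_seed(seed, "cohort")))
    schedule = ScheduleConfig(recordings_per_content=1,
                              seed=_derive_seed(seed, "schedule"))
    fm = replace(FeatureModel(), n_frames=n_frames)
    dataset = generate_dataset(
        cohort, schedule_cfg=schedule, feature_model=fm,
        seed=_derive_seed(seed, "ema"), with_frames=True)
    return cohort, dataset


def _mean_or_none(values):
    vals = [v for v in values if v is not None]
    return float(np.mean(vals)) if vals else None


def run_personalization_trial(seed: int, n_per_group: int = 30,
                              subset: str = "all", n_frames: int = 6,
                              n_folds: int = 3, batch_size: int = 64,
                              ft_epochs: int = 6, hy_epochs: int = 14,
                              learning_rate: float = 1e-3,
                              hy_learning_rate: float = 2e-3) -> dict:
    """One seed of the personalization experiment.

    Per CV fold: train the fine-tuned encoder baseline, then the hyperformer
    on top of its frozen weights, evaluate both on the fold's test speakers;
    metrics are averaged over `n_folds` folds as in the study protocol.
    """
    cohort, dataset = _benchmark_dataset(seed, n_per_group, n_frames)
    splits = make_splits(cohort, k=5, seed=_derive_seed(seed, "split"))
    subj_map = dataset.subject_map()
    group_of = {s.subject_id: s.group for s in cohort}
    enc_cfg = EncoderConfig(input_dim=len(dataset.feature_names),
                            seed=_derive_seed(seed, "enc"), **DESK_ENCODER)

    def _gini(rhos: dict, group: str | None = None) -> float | None:
        vals = [v for s, v in rhos.items()
                if group is None or group_of[s] == group]
        if len(vals) < 2:
            return None
        rep = gini_report(vals)
        return rep["gini"] if rep.get("gini") is not None else rep.get("gini_clipped")

    per_fold = {k: [] for k in (
        "rho_finetune", "rho_hyperformer", "mae_finetune", "mae_hyperformer",
        "gini_finetune", "gini_hyperformer",
        "gini_patients_finetune", "gini_patients_hyperformer")}
    winners = losers = unchanged = 0
    content_rho = {c: [] for c in ("question", "answer", "positive_thought")}

    for fold_i in range(n_folds):
        split = splits[(seed + fold_i) % len(splits)]
        stats = fit_normalizer([subj_map[s] for s in split.train], subset)
        folds = {
            part: build_arrays(dataset, getattr(split, part), stats, subset,
                               use_frames=True)
            for part in ("train", "val", "test")
        }
        finetune = build_model("finetune", enc_cfg=enc_cfg,
                               seed=_derive_seed(seed, f"finetune{fold_i}"))
        ckpt_ft = train(finetune, folds, TrainConfig.for_model(
            "finetune", max_epochs=ft_epochs, batch_size=batch_size,
            learning_rate=learning_rate, weight_decay=0.01,
            seed=_derive_seed(seed, f"ft-train{fold_i}")))
        hyper = build_model(
            "hyperformer", meta_width=subset_dimension(subset),
            enc_cfg=enc_cfg, seed=_derive_seed(seed, f"hyper{fold_i}"),
            backbone_state=ckpt_ft.params["backbone"])
        train(hyper, folds, TrainConfig.for_model(
            "hyperformer", max_epochs=hy_epochs, batch_size=batch_size,
            learning_rate=hy_learning_rate, warmup_fraction=0.3,
            weight_decay=0.01, seed=_derive_seed(seed, f"hy-train{fold_i}")))

        report_ft = evaluate_predictions(
            prediction_table(finetune, folds["test"], fold=fold_i), cohort)
        report_hy = evaluate_predictions(
            prediction_table(hyper, folds["test"], fold=fold_i), cohort)

        per_fold["rho_finetune"].append(report_ft.mean_rho)
        per_fold["rho_hyperformer"].append(report_hy.mean_rho)
        per_fold["mae_finetune"].append(report_ft.mae)
        per_fold["mae_hyperformer"].append(report_hy.mae)
        per_fold["gini_finetune"].append(_gini(report_ft.speaker_rho))
        per_fold["gini_hyperformer"].append(_gini(report_hy.speaker_rho))
        per_fold["gini_patients_finetune"].append(
            _gini(report_ft.speaker_rho, "patient"))
        per_fold["gini_patients_hyperformer"].append(
            _gini(report_hy.speaker_rho, "patient"))
        for c, v in report_hy.content_rho.items():
            content_rho[c].append(v)

        common = sorted(set(report_ft.speaker_rho) & set(report_hy.speaker_rho))
        fairness = winners_losers(
            {s: report_ft.speaker_rho[s] for s in common},
            {s: report_hy.speaker_rho[s] for s in common})
        winners += fairness.winners
        losers += fairness.losers
        unchanged += fairness.unchanged

    out = {k: _mean_or_none(v) for k, v in per_fold.items()}
    out.update({
        "seed": seed,
        "n_folds": n_folds,
        "content_rho_hyperformer": {c: _mean_or_none(v)
                                    for c, v in content_rho.items()},
        "fairness": {"winners": winners, "losers": losers,
                     "unchanged": unchanged},
    })
    return out


def personalization_benchmark(seed: int = 0, n_seeds: int = 5, **kwargs) -> dict:
    """The criterion experiment over several seeds, with aggregate tallies."""
    trials = [run_personalization_trial(_derive_seed(seed, f"trial{i}"), **kwargs)
              for i in range(n_seeds)]
    wins = sum(t["rho_hyperformer"] > t["rho_finetune"] for t in trials)
    gini_wins = sum(
        t["gini_hyperformer"] is not None and t["gini_finetune"] is not None
        and t["gini_hyperformer"] <= t["gini_finetune"] for t in trials)
    total_winners = sum(t["fairness"]["winners"] for t in trials)
    total_losers = sum(t["fairness"]["losers"] for t in trials)
    total_unchanged = sum(t["fairness"]["unchanged"] for t in trials)
    content = {}
    for c in ("question", "answer", "positive_thought"):
        vals = [t["content_rho_hyperformer"].get(c) for t in trials]
        vals = [v for v in vals if v is not None]
        content[c] = float(np.mean(vals)) if vals else None
    return {
        "trials": trials,
        "n_seeds": n_seeds,
        "rho_wins": int(wins),
        "gini_wins": int(gini_wins),
        "mean_rho_finetune": float(np.mean([t["rho_finetune"] for t in trials])),
        "mean_rho_hyperformer": float(np.mean([t["rho_hyperformer"] for t in trials])),
        "mean_mae_finetune": float(np.mean([t["mae_finetune"] for t in trials])),
        "mean_mae_hyperformer": float(np.mean([t["mae_hyperformer"] for t in trials])),
        "winner_fraction": total_winners / max(
            total_winners + total_losers + total_unchanged, 1),
        "content_rho": content,
    }


# ---------------------------------------------------------------------------
# level-shift pathology (additive-metadata FFNN)


def level_shift_experiment(seed: int = 0, n_per_group: int = 30,
                           subset: str = "all", max_epochs: int = 60) -> dict:
    """Regime where metadata predicts only each subject's mean mood (feature
    coupling and trait loadings disabled, so the voice stream is pure noise):
    the additive-metadata FFNN should reduce global MAE versus the plain FFNN
    while mean per-speaker rho barely moves."""
    cohort = generate_cohort(CohortConfig(
        n_control=n_per_group, n_subclinical=n_per_group,
        n_patients=n_per_group, seed=_derive_seed(seed, "ls-cohort")))
    zero = {n: 0.0 for n in FeatureModel().feature_names}
    fm = replace(FeatureModel(), coupling_strength=dict(zero),
                 trait_loading=dict(zero))
    dataset = generate_dataset(
        cohort, schedule_cfg=ScheduleConfig(
            recordings_per_content=1, seed=_derive_seed(seed, "ls-sched")),
        feature_model=fm, seed=_derive_seed(seed, "ls-ema"))

    split = make_splits(cohort, k=5, seed=_derive_seed(seed, "ls-split"))[0]
    subj_map = dataset.subject_map()
    stats = fit_normalizer([subj_map[s] for s in split.train], subset)
    folds = {part: build_arrays(dataset, getattr(split, part), stats, subset)
             for part in ("train", "val", "test")}

    results = {}
    for kind in ("ffnn", "ffnn-pers"):
        model = build_model(
            kind, input_width=len(dataset.feature_names),
            meta_width=subset_dimension(subset), ffnn_hidden=30,
            seed=_derive_seed(seed, f"ls-{kind}"))
        cfg = TrainConfig.for_model(kind, max_epochs=max_epochs, batch_size=32,
                                    seed=_derive_seed(seed, f"ls-{kind}-train"))
        train(model, folds, cfg)
        table = prediction_table(model, folds["test"])
        results[kind] = evaluate_predictions(table, cohort,
                                             undefined_as_zero=True)
    return {
        "mae_baseline": results["ffnn"].mae,
        "mae_personalized": results["ffnn-pers"].mae,
        "rho_baseline": results["ffnn"].mean_rho,
        "rho_personalized": results["ffnn-pers"].mean_rho,
        "rho_change": results["ffnn-pers"].mean_rho - results["ffnn"].mean_rho,
    }


# ---------------------------------------------------------------------------
# generator parameter recovery


def coupling_recovery(seed: int = 0, n_subjects: int = 50) -> dict:
    """Recover the within-speaker feature-mood coupling on an
    answer-content-only, no-attenuation dataset; compare each pooled slope to
    the analytically implied standardized slope within 3 SE."""
    per_group = n_subjects // 3
    cohort = generate_cohort(CohortConfig(
        n_control=per_group, n_subclinical=per_group,
        n_patients=n_subjects - 2 * per_group, seed=_derive_seed(seed, "cr-cohort")))
    fm = replace(FeatureModel(), severity_attenuation=1.0, style_gain=0.0)
    schedule = ScheduleConfig(recordings_per_content=3,
                              content_types=("answer",),
                              missingness_by_group={},
                              seed=_derive_seed(seed, "cr-sched"))
    dataset = generate_dataset(cohort, schedule_cfg=schedule, feature_model=fm,
                               seed=_derive_seed(seed, "cr-ema"))
    table, excluded = estimate_feature_mood_coupling(dataset)

    base = FeatureModel()
    rows = {}
    for name in dataset.feature_names:
        beta = base.coupling_signs[name] * base.coupling_strength[name]
        expected = beta / np.sqrt(beta ** 2 + base.noise_sd ** 2)
        est = table.loc[name]
        rows[name] = {
            "expected": float(expected),
            "estimated": float(est["slope"]),
            "se": float(est["se"]),
            "within_3se": bool(abs(est["slope"] - expected) <= 3 * est["se"]),
        }
    return {"features": rows, "n_excluded": len(excluded),
            "max_abs_z": max(abs(r["estimated"] - r["expected"]) / r["se"]
                             for r in rows.values())}
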