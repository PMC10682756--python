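"""Individual-level evaluation: per-speaker rank correlations, global MAE,
prediction-questionnaire correlations, and fairness summaries.

The reporting conventions follow the study protocol: MAE pools all
predictions of a fold, Spearman's rho is computed for each speaker
independently and then averaged over speakers, every metric is computed per
fold and then summarized as mean +/- SD over folds, and fairness is the Gini
index over speaker-level rho together with winner/loser counts under a
baseline -> personalized model switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .synth_cohort import questionnaire_summaries

#: |rho_base| below this floor switches percent change to absolute change
PERCENT_CHANGE_FLOOR = 0.01


# ---------------------------------------------------------------------------
# correlation primitives


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("spearman_rho needs two equal-length vectors, n >= 2")
    rx, ry = rankdata(x), rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("rank variance is zero; correlation undefined")
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    return float(np.clip(np.mean(rx * ry), -1.0, 1.0))


def _safe_rho(x, y):
    try:
        return spearman_rho(x, y)
    except ValueError:
        return None


# ---------------------------------------------------------------------------
# per-speaker and global metrics


@dataclass
class EvalReport:
    mean_rho: float
    rho_by_fold: dict
    speaker_rho: dict  # subject_id -> rho (evaluable speakers only)
    excluded: list  # (subject_id, reason)
    mae: float
    mae_by_fold: dict
    group_rho: dict = field(default_factory=dict)
    content_rho: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "mean_rho": self.mean_rho,
            "rho_by_fold": self.rho_by_fold,
            "speaker_rho": self.speaker_rho,
            "excluded": [list(e) for e in self.excluded],
            "mae": self.mae,
            "mae_by_fold": self.mae_by_fold,
            "group_rho": self.group_rho,
            "content_rho": self.content_rho,
        }


def _require_pred_table(pred_table: pd.DataFrame):
    required = {"subject_id", "y_true", "y_pred"}
    missing = required - set(pred_table.columns)
    if missing:
        raise ValueError(f"prediction table misses columns {sorted(missing)}")
    if "fold" not in pred_table.columns:
        pred_table = pred_table.assign(fold=0)
    return pred_table


def per_speaker_rho(pred_table: pd.DataFrame, undefined_as_zero: bool = False):
    """Speaker-level Spearman's rho, averaged per fold.

    Speakers with undefined rho (constant truths or constant predictions)
    are excluded from the mean and listed -- unless `undefined_as_zero`
    assigns them 0 instead. Returns (speaker_rho, excluded, rho_by_fold).
    """
    pred_table = _require_pred_table(pred_table)
    speaker_rho, excluded = {}, []
    speaker_fold = {}
    for sid, grp in pred_table.groupby("subject_id", sort=True):
        rho = _safe_rho(grp["y_true"].to_numpy(), grp["y_pred"].to_numpy()) \
            if len(grp) >= 2 else None
        if rho is None:
            if undefined_as_zero:
                rho = 0.0
            else:
                excluded.append((sid, "undefined_rho"))
                continue
        speaker_rho[sid] = rho
        speaker_fold[sid] = int(grp["fold"].iloc[0])
    rho_by_fold = {}
    for fold in sorted(set(speaker_fold.values())):
        vals = [r for s, r in speaker_rho.items() if speaker_fold[s] == fold]
        if vals:
            rho_by_fold[fold] = float(np.mean(vals))
    if not speaker_rho:
        raise ValueError("per-speaker rho undefined for every speaker")
    return speaker_rho, excluded, rho_by_fold


def global_mae(pred_table: pd.DataFrame):
    """MAE over all rows of each fold; returns (mae_by_fold, mean, sd)."""
    pred_table = _require_pred_table(pred_table)
    if len(pred_table) == 0:
        raise ValueError("empty prediction table")
    mae_by_fold = {
        int(fold): float(np.mean(np.abs(grp["y_true"] - grp["y_pred"])))
        for fold, grp in pred_table.groupby("fold")
    }
    vals = np.array(list(mae_by_fold.values()))
    return mae_by_fold, float(vals.mean()), float(vals.std())


def evaluate_predictions(pred_table: pd.DataFrame, subjects: list | None = None,
                         undefined_as_zero: bool = False) -> EvalReport:
    """Full report: mean-of-per-speaker rho (per fold, then averaged), MAE,
    and group/content breakdowns on row subsets."""
    pred_table = _require_pred_table(pred_table)
    speaker_rho, excluded, rho_by_fold = per_speaker_rho(
        pred_table, undefined_as_zero=undefined_as_zero)
    mae_by_fold, mae_mean, _ = global_mae(pred_table)
    report = EvalReport(
        mean_rho=float(np.mean(list(rho_by_fold.values()))),
        rho_by_fold=rho_by_fold, speaker_rho=speaker_rho, excluded=excluded,
        mae=mae_mean, mae_by_fold=mae_by_fold,
    )
    if subjects is not None:
        group_of = {s.subject_id: s.group for s in subjects}
        for group in sorted(set(group_of.values())):
            ids = [sid for sid in speaker_rho if group_of.get(sid) == group]
            if ids:
                report.group_rho[group] = float(
                    np.mean([speaker_rho[sid] for sid in ids]))
    if "content" in pred_table.columns:
        for content, grp in pred_table.groupby("content"):
            try:
                rho, _, by_fold = per_speaker_rho(
                    grp, undefined_as_zero=undefined_as_zero)
            except ValueError:
                continue
            report.content_rho[content] = float(
                np.mean(list(by_fold.values())))
    return report


def metadata_correlations(pred_table: pd.DataFrame, subjects: list) -> pd.DataFrame:
    """Global Spearman of predictions vs questionnaire totals and ground
    truth, per fold (each recording row paired with its subject's total)."""
    pred_table = _require_pred_table(pred_table)
    totals = {s.subject_id: questionnaire_summaries(s) for s in subjects}
    missing = set(pred_table["subject_id"]) - set(totals)
    if missing:
        raise ValueError(f"missing questionnaire totals for {sorted(missing)[:5]}")
    rows = []
    for fold, grp in pred_table.groupby("fold"):
        pred = grp["y_pred"].to_numpy()
        row = {"fold": int(fold)}
        for instr in ("phq9", "hrsd", "sek"):
            ref = np.array([totals[sid][instr] for sid in grp["subject_id"]])
            rho = _safe_rho(pred, ref)
            row[instr] = np.nan if rho is None else rho
        gt = _safe_rho(pred, grp["y_true"].to_numpy())
        row["ground_truth"] = np.nan if gt is None else gt
        rows.append(row)
    return pd.DataFrame(rows).set_index("fold")


# ---------------------------------------------------------------------------
# fairness


def gini_index(values, clip_negative: bool = False) -> float:
    """Gini inequality index G = sum_ij |v_i - v_j| / (2 n^2 vbar).

    The raw formula requires a positive mean; with `clip_negative` the values
    are first clipped at zero (mathematical hygiene when per-speaker rho can
    be negative).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("gini_index needs at least 2 values")
    if clip_negative:
        v = np.clip(v, 0.0, None)
    vbar = v.mean()
    if vbar <= 0:
        raise ValueError(
            "mean <= 0: standard Gini formula undefined; use clip_negative=True")
    # O(n log n) equivalent of the pairwise double sum
    vs = np.sort(v)
    i = np.arange(1, v.size + 1)
    return float((2 * np.sum(i * vs) / (v.size * np.sum(vs))) - (v.size + 1) / v.size)


def gini_report(values) -> dict:
    """Raw-formula Gini plus the clip-at-zero variant when negatives occur."""
    v = np.asarray(values, dtype=float)
    out = {}
    try:
        out["gini"] = gini_index(v)
    except ValueError as exc:
        out["gini"] = None
        out["gini_error"] = str(exc)
    if (v < 0).any():
        out["gini_clipped"] = gini_index(v, clip_negative=True)
    return out


@dataclass
class FairnessReport:
    winners: int
    losers: int
    unchanged: int
    mean_winner_pct: float | None
    mean_loser_pct: float | None
    absolute_fallback_speakers: list

    def to_json_dict(self) -> dict:
        return {
            "winners": self.winners, "losers": self.losers,
            "unchanged": self.unchanged,
            "mean_winner_pct": self.mean_winner_pct,
            "mean_loser_pct": self.mean_loser_pct,
            "absolute_fallback_speakers": list(self.absolute_fallback_speakers),
        }


def winners_losers(rho_baseline: dict, rho_personalized: dict) -> FairnessReport:
    """Count speakers improved/worsened by personalization, with mean percent
    change per camp; |rho_base| < PERCENT_CHANGE_FLOOR falls back to absolute
    change (flagged)."""
    if set(rho_baseline) != set(rho_personalized):
        raise ValueError("winners_losers requires aligned speaker sets")
    winners, losers, unchanged = [], [], 0
    fallback = []
    for sid in sorted(rho_baseline):
        base, pers = rho_baseline[sid], rho_personalized[sid]
        delta = pers - base
        if abs(base) < PERCENT_CHANGE_FLOOR:
            change = delta * 100.0  # absolute change reported on a % scale
            fallback.append(sid)
        else:
            change = delta / abs(base) * 100.0
        if delta > 0:
            winners.append(change)
        elif delta < 0:
            losers.append(change)
        else:
            unchanged += 1
    return FairnessReport(
        winners=len(winners), losers=len(losers), unchanged=unchanged,
        mean_winner_pct=float(np.mean(winners)) if winners else None,
        mean_loser_pct=float(np.mean(losers)) if losers else None,
        absolute_fallback_speakers=fallback,
    )
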