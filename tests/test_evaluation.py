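"""Per-speaker correlation, MAE, fairness metrics and their oracles."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hypermood.evaluation import (evaluate_predictions, gini_index,
                                  gini_report, global_mae,
                                  metadata_correlations, per_speaker_rho,
                                  spearman_rho, winners_losers)
from hypermood.synth_cohort import questionnaire_summaries


def brute_force_ranks(x):
    """Average ranks computed by explicit enumeration."""
    x = np.asarray(x, dtype=float)
    ranks = np.empty(len(x))
    for i, v in enumerate(x):
        less = np.sum(x < v)
        equal = np.sum(x == v)
        ranks[i] = less + (equal + 1) / 2.0
    return ranks


def oracle_spearman(x, y):
    rx, ry = brute_force_ranks(x), brute_force_ranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def oracle_gini(v):
    v = np.asarray(v, dtype=float)
    n = len(v)
    return float(np.abs(v[:, None] - v[None, :]).sum() / (2 * n * n * v.mean()))


def test_spearman_trivial_cases(rng):
    x = rng.normal(size=20)
    assert spearman_rho(x, x) == pytest.approx(1.0)
    assert spearman_rho(x, -x) == pytest.approx(-1.0)


def test_spearman_tie_handling_matches_rank_oracle():
    x = np.array([1.0, 2.0, 2.0, 4.0])
    y = np.array([10.0, 20.0, 30.0, 40.0])
    assert spearman_rho(x, y) == pytest.approx(oracle_spearman(x, y), abs=1e-12)


def test_spearman_matches_oracle_on_random_instances(rng):
    for _ in range(100):
        n = int(rng.integers(3, 40))
        x = rng.integers(0, 6, size=n).astype(float)  # plenty of ties
        y = rng.normal(size=n)
        if np.all(x == x[0]):
            continue
        assert spearman_rho(x, y) == pytest.approx(oracle_spearman(x, y),
                                                   abs=1e-10)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.lists(st.integers(-50, 50), min_size=3, max_size=25, unique=True),
       st.sampled_from([np.exp, np.tanh, lambda v: v ** 3]))
def test_spearman_invariant_to_strictly_monotone_transforms(xs, f):
    x = np.array(xs, dtype=float)
    y = np.arange(len(x), dtype=float)
    assert spearman_rho(f(x / 50.0), y) == pytest.approx(
        spearman_rho(x, y), abs=1e-10)


def test_spearman_rejects_degenerate_input():
    with pytest.raises(ValueError):
        spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        spearman_rho([1.0], [2.0])


def _table(rows):
    return pd.DataFrame(rows, columns=["subject_id", "y_true", "y_pred", "fold",
                                       "content"][:len(rows[0])])


def test_perfect_predictions_give_unit_mean_rho():
    rows = [(f"s{i}", t, t, 0) for i in range(4) for t in (1.0, 2.0, 5.0)]
    rho, excluded, by_fold = per_speaker_rho(_table(rows))
    assert excluded == []
    assert by_fold[0] == pytest.approx(1.0)


def test_one_perfect_one_reversed_speaker_average_to_zero():
    rows = ([("a", t, t, 0) for t in (1.0, 2.0, 3.0)]
            + [("b", t, -t, 0) for t in (1.0, 2.0, 3.0)])
    _, _, by_fold = per_speaker_rho(_table(rows))
    assert by_fold[0] == pytest.approx(0.0)


def test_random_predictions_center_on_zero(rng):
    rows = []
    for i in range(50):
        truths = rng.integers(0, 11, size=42).astype(float)
        preds = rng.normal(size=42)
        rows += [(f"s{i:02d}", t, p, 0) for t, p in zip(truths, preds)]
    _, _, by_fold = per_speaker_rho(_table(rows))
    se = (1 / np.sqrt(41)) / np.sqrt(50)
    assert abs(by_fold[0]) < 3 * se + 1e-9


def test_constant_speakers_are_excluded_and_listed():
    rows = ([("a", t, t, 0) for t in (1.0, 2.0, 3.0)]
            + [("b", 5.0, p, 0) for p in (1.0, 2.0, 3.0)])
    rho, excluded, by_fold = per_speaker_rho(_table(rows))
    assert ("b", "undefined_rho") in excluded
    assert set(rho) == {"a"}
    rho0, excluded0, _ = per_speaker_rho(_table(rows), undefined_as_zero=True)
    assert rho0["b"] == 0.0 and excluded0 == []


def test_all_speakers_undefined_raises():
    rows = [("a", 5.0, p, 0) for p in (1.0, 2.0, 3.0)]
    with pytest.raises(ValueError):
        per_speaker_rho(_table(rows))


def test_mean_rho_invariant_to_row_duplication():
    rows = ([("a", t, p, 0) for t, p in [(1, 2), (2, 1), (3, 3), (4, 5)]]
            + [("b", t, p, 0) for t, p in [(1, 1), (2, 3), (3, 2), (5, 4)]])
    base = per_speaker_rho(_table(rows))[2][0]
    dup = rows + [("a", t, p, 0) for t, p in [(1, 2), (2, 1), (3, 3), (4, 5)]] * 3
    assert per_speaker_rho(_table(dup))[2][0] == pytest.approx(base)


def test_global_mae_trivial_and_bruteforce(rng):
    rows = [("a", 0.0, 5.0, 0), ("a", 10.0, 5.0, 0)]
    _, mean, _ = global_mae(_table(rows))
    assert mean == pytest.approx(5.0)
    rows = [(f"s{i%3}", float(t), float(p), int(i % 2))
            for i, (t, p) in enumerate(rng.normal(size=(100, 2)))]
    by_fold, _, _ = global_mae(_table(rows))
    df = _table(rows)
    for fold, grp in df.groupby("fold"):
        want = float(np.mean(np.abs(grp["y_true"] - grp["y_pred"])))
        assert by_fold[fold] == pytest.approx(want, abs=1e-12)
    perfect = [("a", 1.0, 1.0, 0), ("b", 2.0, 2.0, 0)]
    assert global_mae(_table(perfect))[1] == 0.0


def test_metadata_correlations_broadcast_and_null(default_cohort, rng):
    subjects = default_cohort[:30]
    rows = []
    for s in subjects:
        total = questionnaire_summaries(s)["phq9"]
        for k in range(5):
            rows.append({"subject_id": s.subject_id, "y_true": float(k),
                         "y_pred": float(total), "fold": 0})
    table = metadata_correlations(pd.DataFrame(rows), subjects)
    assert table.loc[0, "phq9"] == pytest.approx(1.0)
    for row in rows:
        row["y_pred"] = float(rng.normal())
    null = metadata_correlations(pd.DataFrame(rows), subjects)
    assert abs(null.loc[0, "phq9"]) < 0.25


def test_metadata_correlations_require_totals(small_cohort):
    rows = pd.DataFrame([{"subject_id": "ghost", "y_true": 1.0,
                          "y_pred": 2.0, "fold": 0}])
    with pytest.raises(ValueError):
        metadata_correlations(rows, small_cohort)


def test_gini_trivial_cases():
    assert gini_index([3.0, 3.0, 3.0]) == pytest.approx(0.0)
    assert gini_index([0.0, 1.0]) == pytest.approx(0.5)


def test_gini_matches_bruteforce_double_sum(rng):
    for _ in range(100):
        v = rng.uniform(0.01, 5.0, size=int(rng.integers(2, 30)))
        assert gini_index(v) == pytest.approx(oracle_gini(v), abs=1e-10)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.lists(st.floats(0.05, 10.0), min_size=2, max_size=20),
       st.floats(0.1, 9.0))
def test_gini_scale_invariant_translation_variant(vs, c):
    v = np.array(vs)
    assert gini_index(c * v) == pytest.approx(gini_index(v), abs=1e-9)
    if gini_index(v) > 1e-6:
        assert gini_index(v + c) < gini_index(v)


def test_gini_refuses_nonpositive_mean_but_clip_variant_works():
    with pytest.raises(ValueError):
        gini_index([-1.0, -2.0, 0.5])
    rep = gini_report([-1.0, -2.0, 0.5])
    assert rep["gini"] is None
    assert rep["gini_clipped"] == pytest.approx(gini_index([0.0, 0.0, 0.5]))


def test_winners_losers_cases():
    base = {"a": 0.2, "b": 0.4, "c": 0.5}
    same = winners_losers(base, dict(base))
    assert (same.winners, same.losers, same.unchanged) == (0, 0, 3)
    up = winners_losers(base, {k: v + 0.1 for k, v in base.items()})
    assert (up.winners, up.losers) == (3, 0)
    assert up.mean_winner_pct == pytest.approx(np.mean([50.0, 25.0, 20.0]))
    mixed = winners_losers({"a": 0.2, "b": 0.4, "c": 0.5},
                           {"a": 0.4, "b": 0.2, "c": 0.5})
    assert (mixed.winners, mixed.losers, mixed.unchanged) == (1, 1, 1)
    assert mixed.mean_winner_pct == pytest.approx(100.0)
    assert mixed.mean_loser_pct == pytest.approx(-50.0)


def test_winners_losers_small_baseline_falls_back_to_absolute():
    rep = winners_losers({"a": 0.001}, {"a": 0.101})
    assert rep.absolute_fallback_speakers == ["a"]
    assert rep.mean_winner_pct == pytest.approx(10.0)


def test_winners_losers_misaligned_sets_rejected():
    with pytest.raises(ValueError):
        winners_losers({"a": 0.1}, {"b": 0.1})


def test_report_is_reproducible(small_cohort, rng):
    rows = []
    for s in small_cohort[:6]:
        for k in range(6):
            rows.append({"subject_id": s.subject_id, "y_true": float(k % 4),
                         "y_pred": float(rng.normal()), "fold": k % 2,
                         "content": ("answer", "question")[k % 2]})
    table = pd.DataFrame(rows)
    a = json.dumps(evaluate_predictions(table, small_cohort).to_json_dict())
    b = json.dumps(evaluate_predictions(table.copy(), small_cohort).to_json_dict())
    assert a == b


def test_group_and_content_breakdowns(small_cohort, rng):
    rows = []
    for s in small_cohort:
        for k in range(8):
            rows.append({"subject_id": s.subject_id, "y_true": float(k),
                         "y_pred": float(k) + rng.normal() * 0.1, "fold": 0,
                         "content": ("answer", "question")[k % 2]})
    report = evaluate_predictions(pd.DataFrame(rows), small_cohort)
    assert set(report.group_rho) == {"control", "subclinical", "patient"}
    assert set(report.content_rho) == {"answer", "question"}
    assert report.mean_rho > 0.8
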