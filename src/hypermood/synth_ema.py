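"""Synthetic longitudinal EMA: schedules, mood ratings and acoustic features.

The generator emulates a 2-week ecological momentary assessment in which
participants record speech three times a day (morning, noon, evening). Each
session comprises three content types -- reading a mood-related *question*,
the free *answer*, and a spontaneous *positive_thought* -- with a fixed number
of repetitions each, followed by a 0-10 depressed-mood self-rating.

Structure built into the simulator:

* mood is a clamped, rounded AR(1) process around a subject-level mean that is
  an affine function of the shared severity latent, so group mood marginals
  order control < subclinical < patient and mood correlates with
  questionnaire totals;
* acoustic-like functional features couple to within-subject standardized
  mood with fixed signs (lower F0, more/longer pauses, slower speech when more
  depressed), strongest for answer content and weakest for read questions;
* subjects whose PHQ-9 total is above the cohort median express mood more
  weakly in their voice (per-feature attenuation of the coupling);
* subjects split along a psychomotor expression subtype (retarded vs
  agitated): the sign of the timing/fluency couplings is subject-specific
  and reflected in the clinician-rated HRSD psychomotor items;
* trait-level voice differences: feature intercepts load on severity, so
  between-subject feature levels carry diagnostic but no mood-change signal;
* whole sessions go missing with a group-dependent Bernoulli rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .synth_cohort import SubjectProfile, _subject_rng, questionnaire_summaries

CONTENT_TYPES = ("question", "answer", "positive_thought")
SLOTS = ("morning", "noon", "evening")

DEFAULT_FEATURES = (
    "f0_mean", "hnr", "jitter", "shimmer",
    "nsyll", "npause", "duration", "speech_rate",
)

# Missing-session rates: printed per-group missing counts over per-group maxima
# (169/1974, 200/2016, 233/2016).
DEFAULT_MISSINGNESS = {
    "control": 169 / 1974,
    "subclinical": 200 / 2016,
    "patient": 233 / 2016,
}


@dataclass
class ScheduleConfig:
    n_days: int = 14
    slots_per_day: int = 3
    recordings_per_content: int = 3
    content_types: tuple = CONTENT_TYPES
    missingness_by_group: dict = field(
        default_factory=lambda: dict(DEFAULT_MISSINGNESS)
    )
    seed: int = 0


@dataclass
class MoodConfig:
    """Mood = clamp(round(mu_S + AR(1) + noise), 0, 10) with
    mu_S = base + gain * severity_S + N(0, subject_sd)."""

    base: float = 2.8
    gain: float = 1.4
    subject_sd: float = 1.0  # idiosyncratic scale use (per-subject offset)
    phi: float = 0.5  # AR(1) persistence
    innovation_sd: float = 0.9
    noise_sd: float = 0.6


def _per_feature(value, names) -> np.ndarray:
    """Accept a scalar or a {feature: value} mapping; return an array."""
    if np.isscalar(value):
        return np.full(len(names), float(value))
    return np.array([float(value[n]) for n in names])


@dataclass
class FeatureModel:
    feature_names: tuple = DEFAULT_FEATURES
    #: direction of the within-subject mood coupling per feature
    coupling_signs: dict = field(default_factory=lambda: {
        "f0_mean": -1, "hnr": -1, "jitter": +1, "shimmer": +1,
        "nsyll": +1, "npause": +1, "duration": +1, "speech_rate": -1,
    })
    #: magnitude of the coupling (feature-SD units per within-subject mood SD)
    coupling_strength: dict = field(default_factory=lambda: {
        "f0_mean": 0.8, "hnr": 0.1, "jitter": 0.1, "shimmer": 0.1,
        "nsyll": 0.6, "npause": 0.6, "duration": 0.7, "speech_rate": 0.6,
    })
    #: per-content coupling multiplier; read questions retain some F0 coupling
    #: but almost no duration/rate coupling
    content_gain: dict = field(default_factory=lambda: {
        "answer": 1.0,
        "positive_thought": 0.6,
        "question": {
            "f0_mean": 0.5, "hnr": 0.1, "jitter": 0.1, "shimmer": 0.1,
            "nsyll": 0.1, "npause": 0.1, "duration": 0.1, "speech_rate": 0.1,
        },
    })
    #: coupling multiplier for subjects with PHQ-9 total above the cohort
    #: median (scalar or per-feature); 1.0 disables the interaction
    severity_attenuation: object = field(default_factory=lambda: {
        "f0_mean": 0.7, "hnr": 0.6, "jitter": 0.6, "shimmer": 0.6,
        "nsyll": 0.5, "npause": 0.5, "duration": 0.5, "speech_rate": 0.5,
    })
    #: trait-level loading of feature intercepts on the severity latent
    trait_loading: dict = field(default_factory=lambda: {
        "f0_mean": -0.3, "hnr": -0.8, "jitter": 0.7, "shimmer": 0.7,
        "nsyll": 0.1, "npause": 0.2, "duration": 0.2, "speech_rate": -0.2,
    })
    #: psychomotor expression subtype: "timing" features (fluency / rate)
    #: carry a *signed* per-subject multiplier
    #:     (1 - style_gain) + style_gain * psychomotor_S,
    #: so retarded expressors (psychomotor +1) slow down when depressed while
    #: agitated expressors (-1) speed up -- a pooled model averages the
    #: timing couplings toward zero, while the subtype is decodable from the
    #: HRSD psychomotor items. "source" features (pitch / voice quality) are
    #: unaffected. style_gain=0 disables the axis (every multiplier 1).
    style_channels: dict = field(default_factory=lambda: {
        "f0_mean": "source", "hnr": "source", "jitter": "source",
        "shimmer": "source", "nsyll": "timing", "npause": "timing",
        "duration": "timing", "speech_rate": "timing",
    })
    style_gain: float = 1.0
    intercept_sd: float = 0.5  # idiosyncratic per-subject intercept scale
    noise_sd: float = 1.0  # per-recording feature noise
    n_frames: int = 10  # sequence mode: frames per recording
    frame_noise_sd: float = 0.5
    #: set by generate_dataset; PHQ totals above this trigger attenuation
    phq_median: float | None = None

    def validate(self) -> None:
        names = self.feature_names
        q = _per_feature(self.content_gain["question"], names)
        p = _per_feature(self.content_gain["positive_thought"], names)
        a = _per_feature(self.content_gain["answer"], names)
        if not ((a >= p).all() and (p >= q).all()):
            raise ValueError("content gains must order answer >= positive_thought >= question")


@dataclass
class EmaDataset:
    """Long-format EMA bundle: one recordings row per speech sample."""

    subjects: list
    sessions: pd.DataFrame  # subject_id, day, slot, session_idx, missing, mood
    recordings: pd.DataFrame  # keys + mood + one column per feature
    feature_names: tuple
    frames: np.ndarray | None = None  # (n_recordings, T, F), aligned to rows

    def subject_map(self) -> dict:
        return {s.subject_id: s for s in self.subjects}

    def save(self, ema_path, frames_path=None) -> None:
        path = str(ema_path)
        if path.endswith(".parquet"):
            self.recordings.to_parquet(path, index=False)
        else:
            self.recordings.to_csv(path, index=False)
        if frames_path is not None and self.frames is not None:
            np.savez_compressed(frames_path, frames=self.frames)


# ---------------------------------------------------------------------------
# schedule


def build_schedule(subject: SubjectProfile, cfg: ScheduleConfig):
    """Session grid plus recording skeletons for one subject.

    Whole sessions are dropped independently with the subject's group
    missingness rate; recordings are only materialized for kept sessions.
    """
    rng = _subject_rng(cfg.seed, subject.subject_id, "schedule")
    p_miss = cfg.missingness_by_group.get(subject.group, 0.0)

    sess_rows, rec_rows = [], []
    idx = 0
    for day in range(1, cfg.n_days + 1):
        for slot_i in range(cfg.slots_per_day):
            slot = SLOTS[slot_i] if slot_i < len(SLOTS) else f"slot{slot_i}"
            missing = bool(rng.random() < p_miss)
            sess_rows.append({
                "subject_id": subject.subject_id, "day": day, "slot": slot,
                "session_idx": idx, "missing": missing,
            })
            if not missing:
                for content in cfg.content_types:
                    for rep in range(1, cfg.recordings_per_content + 1):
                        rec_rows.append({
                            "subject_id": subject.subject_id, "day": day,
                            "slot": slot, "session_idx": idx,
                            "content": content, "repetition": rep,
                        })
            idx += 1

    sessions = pd.DataFrame(sess_rows)
    recordings = pd.DataFrame(
        rec_rows,
        columns=["subject_id", "day", "slot", "session_idx", "content", "repetition"],
    )
    return sessions, recordings


# ---------------------------------------------------------------------------
# mood


def sample_mood(subject: SubjectProfile, sessions: pd.DataFrame,
                mood_cfg: MoodConfig, seed: int = 0) -> pd.DataFrame:
    """Fill integer 0-10 moods for non-missing sessions (NaN where missing)."""
    rng = _subject_rng(seed, subject.subject_id, "mood")
    n = len(sessions)
    mu = (mood_cfg.base + mood_cfg.gain * subject.severity
          + rng.normal(0.0, mood_cfg.subject_sd))

    ar = np.zeros(n)
    stat_sd = mood_cfg.innovation_sd / max(np.sqrt(1 - mood_cfg.phi ** 2), 1e-12)
    if n > 0:
        ar[0] = rng.normal(0.0, stat_sd)
        innov = rng.normal(0.0, mood_cfg.innovation_sd, size=n)
        for t in range(1, n):
            ar[t] = mood_cfg.phi * ar[t - 1] + innov[t]
    eps = rng.normal(0.0, mood_cfg.noise_sd, size=n)

    mood = np.clip(np.rint(mu + ar + eps), 0, 10)
    out = sessions.copy()
    out["mood"] = np.where(out["missing"].to_numpy(), np.nan, mood)
    return out


# ---------------------------------------------------------------------------
# features


def _style_multipliers(subject: SubjectProfile, fm: FeatureModel) -> np.ndarray:
    """Per-feature coupling multiplier from the subject's psychomotor
    expression subtype; source features are unaffected."""
    timing = (1.0 - fm.style_gain) + fm.style_gain * subject.psychomotor
    return np.array([
        1.0 if fm.style_channels.get(n) == "source" else timing
        for n in fm.feature_names
    ])


def _effective_coupling(fm: FeatureModel, content: str, attenuated: bool,
                        style_mult=1.0) -> np.ndarray:
    names = fm.feature_names
    signs = _per_feature(fm.coupling_signs, names)
    beta = _per_feature(fm.coupling_strength, names)
    gain = _per_feature(fm.content_gain[content], names)
    atten = _per_feature(fm.severity_attenuation, names) if attenuated else 1.0
    return signs * beta * gain * atten * style_mult


def sample_features(recordings: pd.DataFrame, sessions: pd.DataFrame,
                    subject: SubjectProfile, fm: FeatureModel,
                    seed: int = 0, with_frames: bool = False):
    """Feature vectors for one subject's recordings.

    feature = trait_k * severity_S + intercept_{S,k}
              + sign_k * strength_k * content_gain * attenuation * z(mood)
              + noise,
    where z(mood) is the subject's within-person standardized mood. Frames
    mode additionally emits T noisy copies per recording so that mean pooling
    recovers the functional vector in expectation.
    """
    fm.validate()
    names = fm.feature_names
    F = len(names)
    rng = _subject_rng(seed, subject.subject_id, "features")

    mood_by_idx = sessions.set_index("session_idx")["mood"]
    mood = mood_by_idx.loc[recordings["session_idx"]].to_numpy(dtype=float)
    if np.isnan(mood).any():
        raise ValueError("recordings of missing sessions carry no mood")

    obs = sessions.loc[~sessions["missing"], "mood"].to_numpy(dtype=float)
    sd = obs.std()
    z_all = (mood_by_idx - obs.mean()) / sd if sd > 0 else mood_by_idx * 0.0
    z = z_all.loc[recordings["session_idx"]].to_numpy(dtype=float)

    attenuated = False
    if fm.phq_median is not None:
        attenuated = questionnaire_summaries(subject)["phq9"] > fm.phq_median

    trait = _per_feature(fm.trait_loading, names)
    intercept = trait * subject.severity + rng.normal(0, fm.intercept_sd, size=F)
    style_mult = _style_multipliers(subject, fm)

    n = len(recordings)
    values = np.empty((n, F))
    for content in set(recordings["content"]):
        mask = (recordings["content"] == content).to_numpy()
        coupling = _effective_coupling(fm, content, attenuated, style_mult)
        values[mask] = intercept + z[mask, None] * coupling[None, :]
    values += rng.normal(0, fm.noise_sd, size=(n, F))

    out = recordings.copy()
    out["mood"] = mood
    for k, name in enumerate(names):
        out[name] = values[:, k]

    frames = None
    if with_frames:
        frames = values[:, None, :] + rng.normal(
            0, fm.frame_noise_sd, size=(n, fm.n_frames, F)
        )
    return out, frames


# ---------------------------------------------------------------------------
# full dataset


def generate_dataset(subjects: list, schedule_cfg: ScheduleConfig | None = None,
                     mood_cfg: MoodConfig | None = None,
                     feature_model: FeatureModel | None = None,
                     seed: int = 0, with_frames: bool = False) -> EmaDataset:
    """Schedules, moods and features for a whole cohort."""
    schedule_cfg = schedule_cfg or ScheduleConfig(seed=seed)
    mood_cfg = mood_cfg or MoodConfig()
    feature_model = feature_model or FeatureModel()

    if feature_model.phq_median is None and subjects:
        med = float(np.median([questionnaire_summaries(s)["phq9"] for s in subjects]))
        feature_model = replace(feature_model, phq_median=med)

    sess_frames, rec_frames, frame_blocks = [], [], []
    for s in subjects:
        sessions, recordings = build_schedule(s, schedule_cfg)
        sessions = sample_mood(s, sessions, mood_cfg, seed=seed)
        if len(recordings):
            recordings, frames = sample_features(
                recordings, sessions, s, feature_model,
                seed=seed, with_frames=with_frames,
            )
            if with_frames:
                frame_blocks.append(frames)
        sess_frames.append(sessions)
        rec_frames.append(recordings)

    sessions = pd.concat(sess_frames, ignore_index=True)
    recordings = pd.concat(rec_frames, ignore_index=True)
    frames = np.concatenate(frame_blocks, axis=0) if frame_blocks else None
    return EmaDataset(
        subjects=list(subjects), sessions=sessions, recordings=recordings,
        feature_names=tuple(feature_model.feature_names), frames=frames,
    )


# ---------------------------------------------------------------------------
# coupling estimator


def estimate_feature_mood_coupling(dataset: EmaDataset, min_sessions: int = 3):
    """Pooled within-speaker slope of each feature on mood.

    Both mood and features are z-scored within speaker, all rows are pooled,
    and the ordinary least-squares slope (cov/var from first principles) is
    returned with a normal-approximation 95% CI. Speakers with zero mood
    variance (or fewer than `min_sessions` rated sessions) contribute nothing
    and are reported separately.
    """
    rec = dataset.recordings
    names = dataset.feature_names
    excluded = []
    zm_parts, zf_parts = [], []
    for sid, grp in rec.groupby("subject_id", sort=True):
        n_sess = grp["session_idx"].nunique()
        mood = grp["mood"].to_numpy(dtype=float)
        if n_sess < min_sessions:
            excluded.append((sid, "too_few_sessions"))
            continue
        if mood.std() == 0:
            excluded.append((sid, "zero_mood_variance"))
            continue
        zm = (mood - mood.mean()) / mood.std()
        feats = grp[list(names)].to_numpy(dtype=float)
        mu, sd = feats.mean(axis=0), feats.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        zf = (feats - mu) / sd
        zm_parts.append(zm)
        zf_parts.append(zf)

    if len(zm_parts) < 2:
        raise ValueError("need at least 2 evaluable speakers")

    zm = np.concatenate(zm_parts)
    zf = np.concatenate(zf_parts, axis=0)
    n = len(zm)
    var_m = np.mean((zm - zm.mean()) ** 2)
    rows = []
    for k, name in enumerate(names):
        x = zf[:, k]
        cov = np.mean((zm - zm.mean()) * (x - x.mean()))
        slope = cov / var_m
        resid = (x - x.mean()) - slope * (zm - zm.mean())
        se = np.sqrt(np.sum(resid ** 2) / max(n - 2, 1) / (n * var_m))
        rows.append({
            "feature": name, "slope": slope, "se": se,
            "ci_low": slope - 1.96 * se, "ci_high": slope + 1.96 * se, "n": n,
        })
    return pd.DataFrame(rows).set_index("feature"), excluded
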