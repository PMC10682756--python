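"""Synthetic study cohort: three clinical groups with questionnaire metadata.

Emulates a longitudinal depressed-mood monitoring study: participants are
screened into healthy control (PHQ-9 total <= 4), subclinical (PHQ-9 > 4,
no MDD diagnosis) and patient (MDD) groups. Each subject carries demographics,
medication flags and item-level scores of five instruments (HRSD-24, PHQ-9,
BDI, SEK-27, TIPI). A single latent severity scalar per subject drives the
location of all depression instruments (and, with reversed sign, the
emotion-regulation items), so instrument totals are mutually correlated the
way they are clinically.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("control", "subclinical", "patient")

#: instrument -> (number of items, maximum item score)
INSTRUMENTS = {
    "hrsd": (24, 4),
    "phq9": (9, 3),
    "bdi": (21, 3),
    "sek": (27, 4),
    "tipi": (10, 6),
}

# Latent severity (standard-normal scale within group) -> per-item mean, via
# item_mean = base + slope * severity, clipped to the item range. SEK measures
# regulation skill, so its slope is sign-flipped via `sek_sign`.
_ITEM_BASE = {"hrsd": 1.1, "phq9": 0.85, "bdi": 0.8, "sek": 2.0, "tipi": 3.0}
_ITEM_SLOPE = {"hrsd": 0.55, "phq9": 0.45, "bdi": 0.42, "sek": 0.55, "tipi": 0.25}
_ITEM_SD = {"hrsd": 0.9, "phq9": 0.7, "bdi": 0.7, "sek": 0.9, "tipi": 1.6}

#: group -> mean of the latent severity scalar
SEVERITY_MEANS = {"control": -1.5, "subclinical": -0.1, "patient": 1.0}
SEVERITY_SD = 0.5


@dataclass
class CohortConfig:
    """Cohort composition and sampling parameters.

    Defaults reproduce the study composition: 47 controls, 48 subclinical,
    48 patients, ages 18-63, gender marginals approximately 48 m / 95 f /
    1 diverse.
    """

    n_control: int = 47
    n_subclinical: int = 48
    n_patients: int = 48
    age_range: tuple = (18, 63)
    gender_probs: tuple = (0.335, 0.658, 0.007)  # (m, f, diverse)
    questionnaire_means_by_group: dict = field(default_factory=dict)
    severity_sd: float = SEVERITY_SD
    sek_sign: float = -1.0  # higher SEK = better regulation (lower severity)
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_control, self.n_subclinical, self.n_patients) < 0:
            raise ValueError("group counts must be >= 0")
        p = np.asarray(self.gender_probs, dtype=float)
        if p.shape != (3,) or (p < 0).any() or not np.isclose(p.sum(), 1.0):
            raise ValueError("gender_probs must be a 3-vector of probabilities summing to 1")


@dataclass
class SubjectProfile:
    subject_id: str
    group: str
    age: int
    gender: str  # 'm' | 'f' | 'diverse'
    school_degree: int  # ordinal 0-3
    professional_degree: int  # ordinal 0-3
    full_time_job: int  # binary
    med_voice: int  # binary
    med_mood: int  # binary
    hrsd_items: np.ndarray  # 24 ints in 0-4
    phq9_items: np.ndarray  # 9 ints in 0-3
    bdi_items: np.ndarray  # 21 ints in 0-3
    sek_items: np.ndarray  # 27 ints in 0-4
    tipi_items: np.ndarray  # 10 ints in 0-6
    severity: float = 0.0  # simulator latent; never part of metadata encoding
    #: psychomotor expression subtype in (-1, 1): +1 retarded (slower speech,
    #: more pauses when depressed), -1 agitated (the reverse). Reflected in
    #: the clinician-rated retardation/agitation items of the HRSD.
    psychomotor: float = 0.0


def _subject_rng(seed: int, subject_id: str, label: str = "cohort") -> np.random.Generator:
    """Independent substream per (seed, subject_id): adding subjects to a
    cohort never perturbs existing ones."""
    digest = hashlib.blake2b(
        f"{label}|{subject_id}".encode(), digest_size=8
    ).digest()
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, int.from_bytes(digest, "big")])
    )


def _sample_items(rng, n_items, max_score, mean, sd):
    raw = np.rint(rng.normal(mean, sd, size=n_items))
    return np.clip(raw, 0, max_score).astype(int)


# HRSD-24 psychomotor items (1-based: 8 retardation, 9 agitation)
HRSD_RETARDATION_ITEM = 7
HRSD_AGITATION_ITEM = 8
_PSYCHOMOTOR_ITEM_SHIFT = 1.4


def _sample_instrument(rng, name, severity, cfg: CohortConfig,
                       psychomotor: float = 0.0):
    n_items, max_score = INSTRUMENTS[name]
    slope = _ITEM_SLOPE[name] * (cfg.sek_sign if name == "sek" else 1.0)
    mean = _ITEM_BASE[name] + slope * severity
    override = cfg.questionnaire_means_by_group.get(name)
    if override is not None:
        mean = override
    means = np.full(n_items, float(np.clip(mean, 0.0, max_score)))
    if name == "hrsd":
        means[HRSD_RETARDATION_ITEM] += _PSYCHOMOTOR_ITEM_SHIFT * psychomotor
        means[HRSD_AGITATION_ITEM] -= _PSYCHOMOTOR_ITEM_SHIFT * psychomotor
        means = np.clip(means, 0.0, max_score)
    return _sample_items(rng, n_items, max_score, means, _ITEM_SD[name])


def _sample_subject(subject_id: str, group: str, cfg: CohortConfig) -> SubjectProfile:
    rng = _subject_rng(cfg.seed, subject_id)
    severity = float(rng.normal(SEVERITY_MEANS[group], cfg.severity_sd))
    psychomotor = float(np.tanh(1.2 * rng.normal()))

    lo, hi = cfg.age_range
    age = int(np.clip(np.rint(rng.normal(32.7, 11.0)), lo, hi))
    gender = ("m", "f", "diverse")[rng.choice(3, p=np.asarray(cfg.gender_probs, float))]
    school = int(rng.choice(4, p=[0.05, 0.2, 0.3, 0.45]))
    professional = int(rng.choice(4, p=[0.1, 0.25, 0.35, 0.3]))
    full_time = int(rng.random() < 0.55)
    # medication more prevalent with clinical severity
    p_med = {"control": 0.02, "subclinical": 0.1, "patient": 0.45}[group]
    med_mood = int(rng.random() < p_med)
    med_voice = int(rng.random() < 0.05)

    # Screening constraint on PHQ-9 totals: rejection-resample items.
    for _ in range(1000):
        phq = _sample_instrument(rng, "phq9", severity, cfg)
        total = int(phq.sum())
        if (group == "control" and total <= 4) or (group != "control" and total > 4):
            break
    else:  # pragma: no cover - forced fallback for pathological configs
        phq = (
            np.zeros(9, dtype=int)
            if group == "control"
            else np.full(9, 1, dtype=int)
        )

    return SubjectProfile(
        subject_id=subject_id,
        group=group,
        age=age,
        gender=gender,
        school_degree=school,
        professional_degree=professional,
        full_time_job=full_time,
        med_voice=med_voice,
        med_mood=med_mood,
        hrsd_items=_sample_instrument(rng, "hrsd", severity, cfg,
                                      psychomotor=psychomotor),
        phq9_items=phq,
        bdi_items=_sample_instrument(rng, "bdi", severity, cfg),
        sek_items=_sample_instrument(rng, "sek", severity, cfg),
        tipi_items=_sample_instrument(rng, "tipi", severity, cfg),
        severity=severity,
        psychomotor=psychomotor,
    )


def generate_cohort(cfg: CohortConfig) -> list:
    """Sample the full cohort; group sizes are exact and per-group PHQ
    screening constraints hold for every subject. Deterministic per seed."""
    cfg.validate()
    subjects = []
    idx = 0
    for group, n in zip(GROUPS, (cfg.n_control, cfg.n_subclinical, cfg.n_patients)):
        for _ in range(n):
            subjects.append(_sample_subject(f"sub-{idx:03d}", group, cfg))
            idx += 1
    return subjects


def questionnaire_summaries(subject: SubjectProfile) -> dict:
    """Instrument total scores (item sums)."""
    return {
        "hrsd": int(np.sum(subject.hrsd_items)),
        "phq9": int(np.sum(subject.phq9_items)),
        "bdi": int(np.sum(subject.bdi_items)),
        "sek": int(np.sum(subject.sek_items)),
        "tipi": int(np.sum(subject.tipi_items)),
    }


def cohort_frame(subjects: list) -> pd.DataFrame:
    """One row per subject; item columns named like ``phq9_01``..``phq9_09``."""
    rows = []
    for s in subjects:
        row = {
            "subject_id": s.subject_id,
            "group": s.group,
            "age": s.age,
            "gender": s.gender,
            "school_degree": s.school_degree,
            "professional_degree": s.professional_degree,
            "full_time_job": s.full_time_job,
            "med_voice": s.med_voice,
            "med_mood": s.med_mood,
            "severity": s.severity,
            "psychomotor": s.psychomotor,
        }
        for name in INSTRUMENTS:
            items = getattr(s, f"{name}_items")
            for i, v in enumerate(items, start=1):
                row[f"{name}_{i:02d}"] = int(v)
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_from_frame(df: pd.DataFrame) -> list:
    """Rebuild SubjectProfiles from a subjects table (inverse of
    cohort_frame); missing metadata columns raise rather than impute."""
    subjects = []
    for _, row in df.iterrows():
        kwargs = {}
        for name, (n_items, _) in INSTRUMENTS.items():
            cols = [f"{name}_{i:02d}" for i in range(1, n_items + 1)]
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise ValueError(f"subjects table misses item columns {missing[:3]}")
            kwargs[f"{name}_items"] = row[cols].to_numpy(dtype=int)
        subjects.append(SubjectProfile(
            subject_id=str(row["subject_id"]), group=str(row["group"]),
            age=int(row["age"]), gender=str(row["gender"]),
            school_degree=int(row["school_degree"]),
            professional_degree=int(row["professional_degree"]),
            full_time_job=int(row["full_time_job"]),
            med_voice=int(row["med_voice"]), med_mood=int(row["med_mood"]),
            severity=float(row.get("severity", 0.0)),
            psychomotor=float(row.get("psychomotor", 0.0)),
            **kwargs,
        ))
    return subjects


def save_cohort(subjects: list, path) -> None:
    df = cohort_frame(subjects)
    path = str(path)
    if path.endswith(".parquet"):
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)
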