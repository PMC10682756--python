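"""Subject metadata -> conditioning vector m_S for a chosen metadata subset.

Questionnaires are encoded item-level (each item one continuous, z-scored
entry), age is continuous z-scored, degrees are ordinals scaled to [0, 1],
employment and medication flags are binary, gender is a 3-way one-hot
(m / f / diverse). Normalization statistics are fitted on training-fold
subjects only and applied unchanged to validation/test subjects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .synth_cohort import INSTRUMENTS, SubjectProfile, questionnaire_summaries

#: fields in each named subset; "depression_tests" is PHQ-9 u HRSD u BDI
SUBSETS = {
    "phq9": ("phq9",),
    "hrsd": ("hrsd",),
    "bdi": ("bdi",),
    "depression_tests": ("phq9", "hrsd", "bdi"),
    "sek": ("sek",),
    "personality": ("tipi",),
    "demographics_medication": ("demographics",),
    "all": ("demographics", "phq9", "hrsd", "bdi", "sek", "tipi"),
}

_DEMO_CONTINUOUS = ("age",)
_DEMO_ORDINAL = ("school_degree", "professional_degree")
_DEMO_BINARY = ("full_time_job", "med_voice", "med_mood")
_GENDERS = ("m", "f", "diverse")

#: width of the demographics + medication block:
#: age(1) + gender one-hot(3) + 2 ordinals + 3 binaries
DEMOGRAPHICS_DIM = 1 + len(_GENDERS) + len(_DEMO_ORDINAL) + len(_DEMO_BINARY)


@dataclass
class SubsetSpec:
    name: str
    blocks: tuple = ()

    def __post_init__(self):
        if self.name not in SUBSETS:
            raise KeyError(f"unknown metadata subset {self.name!r}; "
                           f"choose one of {sorted(SUBSETS)}")
        if not self.blocks:
            self.blocks = SUBSETS[self.name]


def subset_dimension(subset) -> int:
    spec = subset if isinstance(subset, SubsetSpec) else SubsetSpec(subset)
    dim = 0
    for block in spec.blocks:
        dim += DEMOGRAPHICS_DIM if block == "demographics" else INSTRUMENTS[block][0]
    return dim


def _raw_vector(subject: SubjectProfile, spec: SubsetSpec,
                include_totals: bool = False):
    """Unnormalized encoding plus per-entry kind labels.

    kind 'c' entries get z-scored by NormalizationStats; 'p' (pass-through:
    one-hots, scaled ordinals, binaries) do not.
    """
    vals, kinds, names = [], [], []
    for block in spec.blocks:
        if block == "demographics":
            vals.append(float(subject.age)); kinds.append("c"); names.append("age")
            onehot = [1.0 if subject.gender == g else 0.0 for g in _GENDERS]
            vals += onehot; kinds += ["p"] * 3
            names += [f"gender_{g}" for g in _GENDERS]
            for f in _DEMO_ORDINAL:
                vals.append(getattr(subject, f) / 3.0); kinds.append("p"); names.append(f)
            for f in _DEMO_BINARY:
                vals.append(float(getattr(subject, f))); kinds.append("p"); names.append(f)
        else:
            items = getattr(subject, f"{block}_items")
            n_items = INSTRUMENTS[block][0]
            if len(items) != n_items:
                raise ValueError(f"{block} expects {n_items} items, got {len(items)}")
            vals += [float(v) for v in items]
            kinds += ["c"] * n_items
            names += [f"{block}_{i:02d}" for i in range(1, n_items + 1)]
            if include_totals:
                vals.append(float(questionnaire_summaries(subject)[block]))
                kinds.append("c"); names.append(f"{block}_total")
    return np.asarray(vals), kinds, names


@dataclass
class NormalizationStats:
    subset: str
    mean: np.ndarray
    scale: np.ndarray
    names: list
    include_totals: bool = False

    def to_json(self) -> str:
        return json.dumps({
            "subset": self.subset,
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "names": list(self.names),
            "include_totals": self.include_totals,
        })

    @classmethod
    def from_json(cls, s: str) -> "NormalizationStats":
        d = json.loads(s)
        return cls(d["subset"], np.asarray(d["mean"]), np.asarray(d["scale"]),
                   d["names"], d.get("include_totals", False))


@dataclass
class MetadataVector:
    values: np.ndarray
    field_map: dict
    subset: SubsetSpec


def fit_normalizer(train_subjects: list, subset,
                   include_totals: bool = False) -> NormalizationStats:
    """Per-field mean/scale on training-fold subjects only.

    Constant fields keep scale 1 so normalization never divides by ~0;
    pass-through fields (one-hots, ordinals, binaries) get mean 0 / scale 1.
    """
    if len(train_subjects) == 0:
        raise ValueError("cannot fit normalizer on an empty training set")
    spec = subset if isinstance(subset, SubsetSpec) else SubsetSpec(subset)
    mat, kinds, names = [], None, None
    for s in train_subjects:
        v, kinds, names = _raw_vector(s, spec, include_totals)
        mat.append(v)
    mat = np.stack(mat)
    mean = mat.mean(axis=0)
    scale = mat.std(axis=0)
    scale = np.where(scale > 1e-9, scale, 1.0)
    passthrough = np.array([k == "p" for k in kinds])
    mean[passthrough] = 0.0
    scale[passthrough] = 1.0
    return NormalizationStats(spec.name, mean, scale, names, include_totals)


def encode(subject: SubjectProfile, subset,
           stats: NormalizationStats) -> MetadataVector:
    """Deterministic conditioning vector m_S under the given train-fold stats."""
    spec = subset if isinstance(subset, SubsetSpec) else SubsetSpec(subset)
    if stats.subset != spec.name:
        raise ValueError(f"stats fitted for subset {stats.subset!r}, "
                         f"requested {spec.name!r}")
    v, _, names = _raw_vector(subject, spec, stats.include_totals)
    if len(v) != len(stats.mean):
        raise ValueError("stats/subset dimension mismatch")
    field_map = {n: i for i, n in enumerate(names)}
    return MetadataVector((v - stats.mean) / stats.scale, field_map, spec)


def encode_matrix(subjects: list, subset, stats: NormalizationStats) -> np.ndarray:
    return np.stack([encode(s, subset, stats).values for s in subjects])
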