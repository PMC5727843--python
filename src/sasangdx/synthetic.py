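"""Seeded synthetic multi-modal cohorts with programmed class structure.

The generator emulates the statistical shape of the clinical data the
diagnostic pipeline was designed for — three unbalanced constitutional
types, block-correlated (multicollinear) continuous features with
type-dependent mean shifts, age- and sex-dependent drift, per-modality
missingness, plus raw landmark sets and pitch tracks so the feature
extractors are exercised end to end.  It makes no claim of anatomical
or phonetic realism; its purpose is controlled, reproducible inputs
with known ground truth.

Defaults mirror the study conditions the pipeline targets: class
proportions 0.40/0.27/0.33 (TE/SE/SY), 35% male, ages 15-79 with a
decade mix weighted toward older adults, 10 informative of 60 features
per continuous modality at a 1.5-SD extreme-class gap, within-block
correlation 0.7.  All randomness derives from one master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from sasangdx.grammar import LandmarkSet
from sasangdx.preprocess import Cohort
from sasangdx.questionnaire import Codebook
from sasangdx.voice import AudioFrame, PitchTrack


@dataclass(frozen=True)
class ModalityConfig:
    """Programmed structure of one continuous feature block."""

    n_features: int = 60
    n_informative: int = 10
    effect_size: float = 1.5   # extreme-class mean gap, in noise-SD units
    block_corr: float = 0.7    # equicorrelation within feature blocks
    block_size: int = 4
    noise_sd: float = 1.0
    age_slope_sd: float = 0.3  # per-feature age drift scale
    sex_shift_sd: float = 0.2  # per-feature sex offset scale
    missing_rate: float = 0.0


@dataclass(frozen=True)
class QuestionnaireConfig:
    n_questions: int = 15
    min_categories: int = 2
    max_categories: int = 5
    n_informative: int = 8
    tilt: float = 1.0          # class-dependent logit scale
    missing_rate: float = 0.0


@dataclass(frozen=True)
class CohortConfig:
    n: int = 2000
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"TE": 0.40, "SE": 0.27, "SY": 0.33})
    male_fraction: float = 0.35
    decade_weights: Mapping[int, float] = field(
        default_factory=lambda: {10: 0.05, 20: 0.12, 30: 0.17,
                                 40: 0.21, 50: 0.22, 60: 0.23})
    face: ModalityConfig = field(default_factory=lambda: ModalityConfig(missing_rate=0.10))
    body: ModalityConfig = field(default_factory=lambda: ModalityConfig(
        n_features=40, missing_rate=0.05))
    voice: ModalityConfig = field(default_factory=lambda: ModalityConfig(
        n_features=21, missing_rate=0.10))
    questionnaire: QuestionnaireConfig = field(
        default_factory=lambda: QuestionnaireConfig(missing_rate=0.05))
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if abs(sum(self.decade_weights.values()) - 1.0) > 1e-9:
            raise ValueError("decade weights must sum to 1")
        for m in (self.face, self.body, self.voice):
            if m.effect_size < 0:
                raise ValueError("effect sizes must be nonnegative")


def _rngs(seed: int, n: int) -> List[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s))
            for s in np.random.SeedSequence(seed).spawn(n)]


def _class_offsets(rng: np.random.Generator, n_features: int,
                   n_informative: int, effect: float,
                   block_size: int) -> np.ndarray:
    """Per-feature class mean shifts.

    Informative features (the first ``n_informative``) get a random
    assignment of (-e/2, 0, +e/2) to the three types, shared within
    each correlated block: a block models one anatomical region, which
    shifts as a unit with constitution, so correlation between its
    members cannot be exploited to cancel the shared noise.
    """
    out = np.zeros((3, n_features))
    base = np.array([-0.5, 0.0, 0.5])
    for start in range(0, min(n_informative, n_features), block_size):
        pattern = effect * rng.permutation(base)
        stop = min(start + block_size, n_informative, n_features)
        out[:, start:stop] = pattern[:, None]
    return out


def _continuous_block(
    rng: np.random.Generator,
    cfg: ModalityConfig,
    y: np.ndarray,           # class index 0/1/2
    z_age: np.ndarray,       # standardized age
    is_female: np.ndarray,
) -> np.ndarray:
    n = y.size
    p = cfg.n_features
    offsets = _class_offsets(rng, p, cfg.n_informative, cfg.effect_size,
                             cfg.block_size)
    rho = cfg.block_corr
    x = np.empty((n, p))
    for start in range(0, p, cfg.block_size):
        stop = min(start + cfg.block_size, p)
        shared = rng.standard_normal(n)
        eps = rng.standard_normal((n, stop - start))
        x[:, start:stop] = (np.sqrt(rho) * shared[:, None]
                            + np.sqrt(1 - rho) * eps)
    x *= cfg.noise_sd
    x += offsets[y]
    x += z_age[:, None] * rng.normal(0, cfg.age_slope_sd, p)
    x += is_female[:, None] * rng.normal(0, cfg.sex_shift_sd, p)
    return x


def _make_codebook(rng: np.random.Generator, cfg: QuestionnaireConfig) -> Codebook:
    qs = []
    for q in range(cfg.n_questions):
        k = int(rng.integers(cfg.min_categories, cfg.max_categories + 1))
        qs.append((f"Q{q + 1:02d}", tuple(str(c + 1) for c in range(k))))
    return Codebook(tuple(qs))


def _questionnaire_block(
    rng: np.random.Generator,
    cfg: QuestionnaireConfig,
    codebook: Codebook,
    y: np.ndarray,
) -> pd.DataFrame:
    n = y.size
    data = {}
    for qi, (qid, cats) in enumerate(codebook.questions):
        k = len(cats)
        base = rng.normal(0, 0.5, k)
        logits = np.tile(base, (3, 1))
        if qi < cfg.n_informative:
            logits = logits + cfg.tilt * rng.standard_normal((3, k))
        probs = np.exp(logits - logits.max(axis=1, keepdims=True))
        probs /= probs.sum(axis=1, keepdims=True)
        u = rng.random(n)
        cum = probs.cumsum(axis=1)
        data[qid] = (u[:, None] < cum[y]).argmax(axis=1) + 1
    return pd.DataFrame(data)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a cohort at feature level: metadata, three continuous
    blocks (face/body/voice) and a questionnaire response block, with
    per-modality missingness.  Deterministic in ``config.seed``; the
    synthetic codebook is attached as ``cohort.codebook``."""
    (rng_meta, rng_face, rng_body, rng_voice,
     rng_q, rng_miss) = _rngs(config.seed, 6)
    n = config.n
    classes = list(config.class_proportions)
    probs = np.array([config.class_proportions[c] for c in classes])
    y = rng_meta.choice(len(classes), size=n, p=probs)
    labels = np.array(classes)[y]
    sex = np.where(rng_meta.random(n) < config.male_fraction, "M", "F")
    decades = np.array(list(config.decade_weights))
    dw = np.array([config.decade_weights[d] for d in decades])
    dec = decades[rng_meta.choice(decades.size, size=n, p=dw)]
    lo = np.maximum(dec, 15)                      # cohort minimum age
    ages = lo + rng_meta.random(n) * (dec + 10 - lo)
    ids = pd.Index([f"S{i:05d}" for i in range(n)], name="subject_id")
    meta = pd.DataFrame({"sex": sex, "age": ages, "sc_type": labels}, index=ids)

    z_age = (ages - 42.0) / 15.0
    is_f = (sex == "F").astype(float)
    blocks: Dict[str, pd.DataFrame] = {}
    for name, cfg, rng in (("face", config.face, rng_face),
                           ("body", config.body, rng_body),
                           ("voice", config.voice, rng_voice)):
        x = _continuous_block(rng, cfg, y, z_age, is_f)
        cols = [f"{name}_{k:03d}" for k in range(cfg.n_features)]
        blocks[name] = pd.DataFrame(x, index=ids, columns=cols)
    codebook = _make_codebook(rng_q, config.questionnaire)
    qblock = _questionnaire_block(rng_q, config.questionnaire, codebook, y)
    qblock.index = ids
    blocks["questionnaire"] = qblock

    for name, rate in (("face", config.face.missing_rate),
                       ("body", config.body.missing_rate),
                       ("voice", config.voice.missing_rate),
                       ("questionnaire", config.questionnaire.missing_rate)):
        if rate > 0:
            keep = rng_miss.random(n) >= rate
            blocks[name] = blocks[name].loc[ids[keep]]

    return Cohort(meta=meta, blocks=blocks, codebook=codebook)


# ---------------------------------------------------------------------------
# raw landmark generation

# A synthetic canonical face covering every landmark id the shipped
# facial feature vocabulary references.  Coordinates are pixels in a
# nominal 200x260 image (x rightward, y downward); the geometry is
# plausible but invented for fixtures, with no degenerate point triples
# among the spec'd angles.
TEMPLATE_FRONTAL: Dict[int, Tuple[float, float]] = {
    47: (100, 40),    # hairline
    10: (100, 80),    # brow midline
    52: (100, 110),   # nasion
    81: (100, 160),   # subnasale
    80: (100, 185),   # mouth midline
    50: (100, 245),   # chin bottom
    21: (88, 78), 121: (112, 78),    # inner brow pair
    33: (38, 75), 133: (162, 75),    # temple pair
    53: (35, 100), 153: (165, 100),  # upper face width pair
    43: (30, 140), 143: (170, 140),  # cheek width pair
    94: (45, 195), 194: (155, 195),  # jaw pair
    17: (75, 88), 26: (75, 98),      # left eye top/bottom
    18: (60, 93), 25: (90, 93),      # left eye corners
    117: (125, 88), 126: (125, 98),  # right eye top/bottom
    118: (140, 93), 125: (110, 93),  # right eye corners
    36: (82, 158), 136: (118, 158),  # nose wings
}

TEMPLATE_PROFILE: Dict[int, Tuple[float, float]] = {
    6: (120, 40),     # hairline
    71: (112, 48), 72: (104, 62), 73: (98, 76),  # forehead contour
    7: (105, 60),     # forehead midpoint
    77: (125, 58),    # upper forehead reference
    9: (95, 85),      # brow ridge
    10: (96, 90),     # brow base
    12: (92, 105),    # nasion
    13: (90, 120), 84: (85, 135),    # nose bridge points
    14: (70, 150),    # nose tip
    87: (80, 158), 88: (88, 162),    # nostril points
    41: (75, 155),    # columella base
    21: (85, 165),    # subnasale
    22: (88, 185),    # upper lip
    25: (90, 200),    # lower lip
    32: (95, 225),    # chin point
    33: (110, 240),   # chin-neck junction
    36: (160, 110),   # tragus
    44: (150, 180),   # jaw corner
    53: (155, 95),    # upper ear reference
}


def template_face(subject_id: str = "template") -> LandmarkSet:
    """The canonical synthetic landmark set."""
    from sasangdx.geometry import Point2D

    return LandmarkSet(
        subject_id=subject_id,
        frontal={k: Point2D(*v) for k, v in TEMPLATE_FRONTAL.items()},
        profile={k: Point2D(*v) for k, v in TEMPLATE_PROFILE.items()},
    )


DEFAULT_WIDTH_FACTORS = {"TE": 1.05, "SE": 0.97, "SY": 1.00}


def generate_landmarks(
    labels: Sequence[str],
    seed: int = 0,
    width_factors: Mapping[str, float] = None,
    noise_sd: float = 1.0,
    subject_ids: Optional[Sequence[str]] = None,
) -> Dict[str, LandmarkSet]:
    """Per-subject landmark sets: the template deformed by a class-
    dependent frontal width factor (about the facial midline x = 100)
    plus isotropic coordinate noise.  ``noise_sd = 0`` with unit width
    factors reproduces the template exactly."""
    from sasangdx.geometry import Point2D

    if width_factors is None:
        width_factors = DEFAULT_WIDTH_FACTORS
    labels = list(labels)
    if subject_ids is None:
        subject_ids = [f"S{i:05d}" for i in range(len(labels))]
    rng = np.random.default_rng(seed)
    out = {}
    for sid, lab in zip(subject_ids, labels):
        f = width_factors.get(lab, 1.0)
        frontal = {}
        for pid, (x, y) in TEMPLATE_FRONTAL.items():
            nx = 100 + f * (x - 100) + rng.normal(0, noise_sd)
            ny = y + rng.normal(0, noise_sd)
            frontal[pid] = Point2D(nx, ny)
        profile = {pid: Point2D(x + rng.normal(0, noise_sd),
                                y + rng.normal(0, noise_sd))
                   for pid, (x, y) in TEMPLATE_PROFILE.items()}
        out[sid] = LandmarkSet(subject_id=sid, frontal=frontal, profile=profile)
    return out


# ---------------------------------------------------------------------------
# raw voice generation

DEFAULT_F0_OFFSETS = {"TE": -10.0, "SE": 10.0, "SY": 0.0}


def generate_voice(
    labels: Sequence[str],
    seed: int = 0,
    base_f0: float = 150.0,
    f0_offsets: Mapping[str, float] = None,
    f0_frame_sd: float = 6.0,
    n_frames: int = 100,
    hop_s: float = 0.01,
    with_frames: bool = False,
    hnr_db: float = 20.0,
    sample_rate: float = 44100.0,
    frame_samples: int = 2048,
    subject_ids: Optional[Sequence[str]] = None,
) -> Dict[str, dict]:
    """Per-subject pitch tracks (class-dependent mean pitch) and,
    optionally, harmonic-plus-noise audio frames at a programmed HNR.

    The SE-TE mean pitch gap under the defaults is 20 Hz.  Returns a
    mapping subject id -> {"track", "f0", optionally "frames"}.
    """
    if f0_offsets is None:
        f0_offsets = DEFAULT_F0_OFFSETS
    labels = list(labels)
    if subject_ids is None:
        subject_ids = [f"S{i:05d}" for i in range(len(labels))]
    rng = np.random.default_rng(seed)
    times = np.arange(n_frames) * hop_s
    out = {}
    for sid, lab in zip(subject_ids, labels):
        f0_mean = base_f0 + f0_offsets.get(lab, 0.0) + rng.normal(0, 2.0)
        f0 = f0_mean + rng.normal(0, f0_frame_sd, n_frames)
        f0 = np.maximum(f0, 50.0)
        track = PitchTrack(times=times, f0=f0, voiced=np.ones(n_frames, dtype=bool))
        entry = {"track": track, "f0": float(f0_mean)}
        if with_frames:
            t = np.arange(frame_samples) / sample_rate
            harm = sum((0.8 ** h) * np.sin(2 * np.pi * (h + 1) * f0_mean * t
                                           + rng.uniform(0, 2 * np.pi))
                       for h in range(5))
            p_h = float(np.mean(harm ** 2))
            noise_sd = np.sqrt(p_h / 10 ** (hnr_db / 10.0))
            frame = AudioFrame(harm + rng.normal(0, noise_sd, frame_samples),
                               sample_rate)
            entry["frames"] = [frame]
        out[sid] = entry
    return out
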