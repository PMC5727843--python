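"""Readers, writers and configuration for the pipeline's artifacts.

Formats: CSV for landmark tables, pitch tracks, cohort blocks and
per-subject results; JSON for fitted model bundles and run manifests;
YAML for pipeline configuration and questionnaire codebooks.  Numeric
CSV fields are written with Python's shortest round-trip float
representation, so write-then-read reproduces values bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from sasangdx.geometry import Point2D
from sasangdx.grammar import LandmarkSet
from sasangdx.integration import IntegrationModel
from sasangdx.lasso import LinearFit
from sasangdx.modality import ModalityModel
from sasangdx.pipeline import PipelineResult, SexResult
from sasangdx.preprocess import AgeNormalizer, Cohort
from sasangdx.questionnaire import Codebook, ScoreModels
from sasangdx.voice import PitchTrack


class SchemaError(ValueError):
    """An input file does not match the expected schema."""


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


# ---------------------------------------------------------------------------
# landmarks

def write_landmarks(landmarks: Mapping[str, LandmarkSet], path) -> None:
    rows = []
    for sid, lm in landmarks.items():
        for view, table in (("frontal", lm.frontal), ("profile", lm.profile)):
            for pid, pt in sorted(table.items()):
                rows.append((sid, view, pid, repr(float(pt.x)), repr(float(pt.y))))
    pd.DataFrame(rows, columns=["subject_id", "view", "point_id", "x", "y"]) \
        .to_csv(path, index=False)


def read_landmarks(path) -> Dict[str, LandmarkSet]:
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    _require_columns(df, ["subject_id", "view", "point_id", "x", "y"], "landmark file")
    bad = set(df["view"]) - {"frontal", "profile"}
    if bad:
        raise SchemaError(f"landmark file: unknown view(s) {sorted(bad)}")
    out = {}
    for sid, g in df.groupby("subject_id", sort=False):
        views = {"frontal": {}, "profile": {}}
        for _, r in g.iterrows():
            views[r["view"]][int(r["point_id"])] = Point2D(float(r["x"]), float(r["y"]))
        out[sid] = LandmarkSet(subject_id=sid, frontal=views["frontal"],
                               profile=views["profile"])
    return out


# ---------------------------------------------------------------------------
# pitch tracks

def write_pitch_track(track: PitchTrack, path) -> None:
    pd.DataFrame({
        "time_s": [repr(float(v)) for v in track.times],
        "f0_hz": [repr(float(v)) for v in track.f0],
        "voiced": track.voiced.astype(int),
    }).to_csv(path, index=False)


def read_pitch_track(path) -> PitchTrack:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["time_s", "f0_hz", "voiced"], "pitch track")
    return PitchTrack(times=df["time_s"].to_numpy(dtype=float),
                      f0=df["f0_hz"].to_numpy(dtype=float),
                      voiced=df["voiced"].to_numpy(dtype=bool))


def read_wav_frames(path, frame_samples: int = 2048) -> list:
    """Read a mono WAV file into consecutive analysis frames (44.1 kHz
    reference; integer PCM is scaled to [-1, 1])."""
    from scipy.io import wavfile

    from sasangdx.voice import AudioFrame

    sr, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim != 1:
        raise SchemaError("expected mono WAV input")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / np.iinfo(data.dtype).max
    else:
        data = data.astype(float)
    n = data.size // frame_samples
    return [AudioFrame(data[i * frame_samples:(i + 1) * frame_samples], float(sr))
            for i in range(n)]


# ---------------------------------------------------------------------------
# cohorts

def save_cohort(cohort: Cohort, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    cohort.meta.to_csv(d / "meta.csv")
    for name, block in cohort.blocks.items():
        block.to_csv(d / f"block_{name}.csv")
    if cohort.codebook is not None:
        cohort.codebook.to_yaml(d / "codebook.yaml")


def load_cohort(directory) -> Cohort:
    d = Path(directory)
    meta_path = d / "meta.csv"
    if not meta_path.exists():
        raise SchemaError(f"cohort directory {d}: meta.csv not found")
    meta = pd.read_csv(meta_path, index_col=0, float_precision="round_trip")
    _require_columns(meta, ["sex", "age", "sc_type"], "cohort metadata")
    blocks = {}
    for p in sorted(d.glob("block_*.csv")):
        blocks[p.stem[len("block_"):]] = pd.read_csv(p, index_col=0,
                                                     float_precision="round_trip")
    codebook = None
    if (d / "codebook.yaml").exists():
        codebook = Codebook.from_yaml(d / "codebook.yaml")
    return Cohort(meta=meta, blocks=blocks, codebook=codebook)


# ---------------------------------------------------------------------------
# models

def _normalizer_to_dict(nz: AgeNormalizer) -> dict:
    return {"age_grid": nz.age_grid.tolist(), "means": nz.means.tolist(),
            "sds": nz.sds.tolist(), "half_width": nz.half_width,
            "min_count": nz.min_count}


def _normalizer_from_dict(d: dict) -> AgeNormalizer:
    return AgeNormalizer(age_grid=np.asarray(d["age_grid"], dtype=float),
                         means=np.asarray(d["means"], dtype=float),
                         sds=np.asarray(d["sds"], dtype=float),
                         half_width=int(d["half_width"]),
                         min_count=int(d["min_count"]))


def sex_result_to_dict(r: SexResult) -> dict:
    return {
        "sex": r.sex,
        "models": {m: mm.to_dict() for m, mm in r.models.items()},
        "integration": r.integration.to_dict(),
        "normalizers": {m: {c: _normalizer_to_dict(nz) for c, nz in d.items()}
                        for m, d in r.normalizers.items()},
        "score_models": None if r.score_models is None else {
            "fits": {t: f.to_dict() for t, f in r.score_models.fits.items()},
            "column_names": list(r.score_models.column_names),
            "kept": np.asarray(r.score_models.kept, dtype=bool).tolist(),
        },
        "q_fits": None if r.q_fits is None else
        {t: f.to_dict() for t, f in r.q_fits.items()},
    }


def sex_result_from_dict(d: dict) -> SexResult:
    sm = None
    if d.get("score_models"):
        sm = ScoreModels(
            fits={t: LinearFit.from_dict(f) for t, f in d["score_models"]["fits"].items()},
            column_names=list(d["score_models"]["column_names"]),
            kept=np.asarray(d["score_models"]["kept"], dtype=bool))
    empty = pd.DataFrame()
    return SexResult(
        sex=d["sex"],
        models={m: ModalityModel.from_dict(mm) for m, mm in d["models"].items()},
        integration=IntegrationModel.from_dict(d["integration"]),
        diag_train=empty, diag_test=empty,
        labels_train=pd.Series(dtype=object), labels_test=pd.Series(dtype=object),
        pi_test={},
        normalizers={m: {c: _normalizer_from_dict(nz) for c, nz in dd.items()}
                     for m, dd in d.get("normalizers", {}).items()},
        score_models=sm,
        q_fits=None if d.get("q_fits") is None else
        {t: LinearFit.from_dict(f) for t, f in d["q_fits"].items()},
    )


def save_models(result: PipelineResult, path) -> None:
    """Serialize every fitted model of a pipeline run to one JSON file."""
    payload = {
        "seed": result.seed,
        "tau": result.tau,
        "by_sex": {s: sex_result_to_dict(r) for s, r in result.by_sex.items()},
    }
    Path(path).write_text(json.dumps(payload))


def load_models(path) -> PipelineResult:
    d = json.loads(Path(path).read_text())
    return PipelineResult(
        by_sex={s: sex_result_from_dict(r) for s, r in d["by_sex"].items()},
        seed=int(d["seed"]), tau=float(d["tau"]))


# ---------------------------------------------------------------------------
# results

def save_results(diag: pd.DataFrame, path) -> None:
    out = diag.copy()
    for c in ("tscore_te", "tscore_se", "tscore_sy", "margin"):
        out[c] = out[c].map(lambda v: repr(float(v)))
    out.to_csv(path)


def load_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    _require_columns(df, ["tscore_te", "tscore_se", "tscore_sy",
                          "predicted", "margin", "typical"], "results file")
    return df


# ---------------------------------------------------------------------------
# configuration and manifest

@dataclass
class PipelineConfig:
    """Validated run configuration; unknown keys are rejected on load."""

    seed: int = 0
    train_fraction: float = 0.7
    tau: float = 0.1
    folds: int = 10
    age_half_width: int = 5
    age_min_count: int = 30
    literal_weighted_sum: bool = False  # no stacking intercepts
    all_pi_inputs: bool = False         # 12 regressors per type

    def __post_init__(self):
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.tau < 0:
            raise ValueError("tau must be nonnegative")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def write_manifest(path, config: PipelineConfig, exclusion_counts: dict,
                   split_sizes: dict, extra: Optional[dict] = None) -> None:
    """Run manifest: config snapshot, seeds, bookkeeping counts."""
    import sasangdx

    payload = {
        "package_version": sasangdx.__version__,
        "config": dataclasses.asdict(config),
        "exclusion_counts": exclusion_counts,
        "split_sizes": split_sizes,
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2))
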