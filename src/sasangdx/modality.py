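"""Per-modality one-vs-rest component models.

Each of the four diagnostic components (face, body, questionnaire,
voice) gets three class-weighted L1 fits — one per constitutional type
— of the type indicator on the modality's age-normalized features.
The per-type linear predictors form the modality's probability block
pi_ij; they are uncalibrated scores (the CV criterion is MSE on the
indicator), which is immaterial for the downstream argmax because the
stacking stage absorbs affine scale.  A softmax view exists for
reporting only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from sasangdx.lasso import SC_TYPES, LinearFit, class_weights, fit_cv_lasso


@dataclass
class ModalityModel:
    """Three one-vs-rest fits over one modality's feature block."""

    modality: str
    feature_names: List[str]
    fits: Dict[str, LinearFit]  # SC type -> fit
    seed: int = 0

    def __post_init__(self):
        missing = [t for t in SC_TYPES if t not in self.fits]
        if missing:
            raise ValueError(f"missing per-type fits: {missing}")
        p = len(self.feature_names)
        for t, f in self.fits.items():
            if f.coef.size != p:
                raise ValueError(
                    f"{self.modality}/{t}: coefficient length {f.coef.size} != {p} features")

    def sparsity(self) -> Dict[str, int]:
        return {t: self.fits[t].n_active() for t in SC_TYPES}

    def to_dict(self) -> dict:
        return {
            "modality": self.modality,
            "feature_names": list(self.feature_names),
            "seed": int(self.seed),
            "fits": {t: f.to_dict() for t, f in self.fits.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModalityModel":
        return cls(modality=d["modality"], feature_names=list(d["feature_names"]),
                   fits={t: LinearFit.from_dict(f) for t, f in d["fits"].items()},
                   seed=int(d.get("seed", 0)))


def _as_matrix(features) -> tuple:
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float), list(features.columns), features.index
    X = np.asarray(features, dtype=float)
    return X, [f"x{i}" for i in range(X.shape[1])], pd.RangeIndex(X.shape[0])


def fit_modality_model(
    features,
    labels: Sequence[str],
    weights=None,
    modality: str = "modality",
    seed: int = 0,
    folds: int = 10,
) -> ModalityModel:
    """Fit the three one-vs-rest L1 models for one modality.

    The penalty of each type's model is chosen independently by
    stratified 10-fold CV on weighted MSE.  ``weights`` defaults to the
    prevalence-equalizing class weights.
    """
    X, names, _ = _as_matrix(features)
    if X.shape[1] == 0:
        raise ValueError(f"empty feature block for modality {modality!r}")
    labels = np.asarray(labels)
    if X.shape[0] != labels.size:
        raise ValueError("features and labels disagree on subject count")
    if weights is None:
        weights = class_weights(labels)
    fits = {}
    for k, t in enumerate(SC_TYPES):
        y = (labels == t).astype(float)
        fit, _ = fit_cv_lasso(X, y, weights, folds=folds, seed=seed + k,
                              stratify_on=labels)
        fits[t] = fit
    return ModalityModel(modality=modality, feature_names=names, fits=fits, seed=seed)


def predict_pi(model: ModalityModel, features) -> pd.DataFrame:
    """Probability block pi_ij for one modality: raw linear predictors,
    one column per SC type in (TE, SE, SY) order."""
    X, names, index = _as_matrix(features)
    if X.shape[1] != len(model.feature_names):
        raise ValueError(
            f"feature count {X.shape[1]} != model's {len(model.feature_names)}")
    cols = {t: model.fits[t].predict(X) for t in SC_TYPES}
    return pd.DataFrame(cols, index=index, columns=list(SC_TYPES))


def softmax_view(pi: pd.DataFrame) -> pd.DataFrame:
    """Simplex-renormalized view of a probability block (reporting only;
    never fed into integration)."""
    z = pi.to_numpy(dtype=float)
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return pd.DataFrame(e / e.sum(axis=1, keepdims=True),
                        index=pi.index, columns=pi.columns)


def modality_accuracy(model: ModalityModel, features, labels: Sequence[str]) -> float:
    """Within-modality argmax accuracy, as a fraction."""
    pi = predict_pi(model, features)
    pred = pi.to_numpy().argmax(axis=1)
    truth = np.array([SC_TYPES.index(t) for t in labels])
    return float(np.mean(pred == truth))
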