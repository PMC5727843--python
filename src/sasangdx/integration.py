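"""Stacked integration of the four modality probability blocks.

For each constitutional type j the integrated score is

    TSCORE_ij = b_j + sum_r w_jr * (pi_ij)_r,      r over the four
                                                   modalities,

with the weights w_jr fitted by the same class-weighted L1-with-CV
machinery as the component models, taking each modality's type-j score
as a regressor.  The predicted type is the argmax of the three TSCOREs
(ties broken in fixed TE < SE < SY order); the typicality margin is
the top score minus the runner-up, and subjects below a margin cutoff
tau are flagged atypical.

An intercept b_j is included by default because the component scores
are uncalibrated with arbitrary offsets; ``intercept=False`` recovers
the literal weighted-sum form.  The historical fixed-weight variant —
one weight per modality, shared across types — is available through
``tscore_fixed`` with user-supplied weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from sasangdx.lasso import SC_TYPES, LinearFit, class_weights, fit_cv_lasso
from sasangdx.preprocess import MODALITIES

DEFAULT_TAU = 0.1


@dataclass
class IntegrationModel:
    """Per-type stacking weights w_jr (+ intercepts) over the four
    modality blocks."""

    modalities: Tuple[str, ...]
    fits: Dict[str, LinearFit]  # SC type -> fit over the per-type pi columns
    all_inputs: bool = False    # True: each type sees all 12 pi columns
    tau: float = DEFAULT_TAU
    seed: int = 0

    def weights(self) -> pd.DataFrame:
        """The w_jr matrix (rows = SC types, columns = modalities).

        Only defined in per-type-input mode, where type j's regressors
        are exactly the four type-j columns."""
        if self.all_inputs:
            raise ValueError("w_jr matrix is defined only in per-type-input mode")
        return pd.DataFrame({m: [self.fits[t].coef[i] for t in SC_TYPES]
                             for i, m in enumerate(self.modalities)},
                            index=list(SC_TYPES))

    def intercepts(self) -> pd.Series:
        return pd.Series({t: self.fits[t].intercept for t in SC_TYPES})

    def to_dict(self) -> dict:
        return {
            "modalities": list(self.modalities),
            "all_inputs": bool(self.all_inputs),
            "tau": float(self.tau),
            "seed": int(self.seed),
            "fits": {t: f.to_dict() for t, f in self.fits.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IntegrationModel":
        return cls(modalities=tuple(d["modalities"]),
                   fits={t: LinearFit.from_dict(f) for t, f in d["fits"].items()},
                   all_inputs=bool(d.get("all_inputs", False)),
                   tau=float(d.get("tau", DEFAULT_TAU)),
                   seed=int(d.get("seed", 0)))


def _check_aligned(blocks: Mapping[str, pd.DataFrame]) -> pd.Index:
    indexes = [b.index for b in blocks.values()]
    first = indexes[0]
    for ix in indexes[1:]:
        if not first.equals(ix):
            raise ValueError("probability blocks are not row-aligned on "
                             "common samples")
    return first


def _design(blocks: Mapping[str, pd.DataFrame], modalities, sc_type: str,
            all_inputs: bool) -> np.ndarray:
    if all_inputs:
        cols = [blocks[m][t].to_numpy(dtype=float)
                for m in modalities for t in SC_TYPES]
    else:
        cols = [blocks[m][sc_type].to_numpy(dtype=float) for m in modalities]
    return np.column_stack(cols)


def fit_integration(
    blocks: Mapping[str, pd.DataFrame],
    labels: Sequence[str],
    weights=None,
    modalities: Sequence[str] = MODALITIES,
    all_inputs: bool = False,
    intercept: bool = True,
    tau: float = DEFAULT_TAU,
    seed: int = 0,
    folds: int = 10,
) -> IntegrationModel:
    """Fit the per-type stacking weights on row-aligned blocks."""
    modalities = tuple(modalities)
    index = _check_aligned({m: blocks[m] for m in modalities})
    labels = np.asarray(labels)
    if labels.size != len(index):
        raise ValueError("labels and blocks disagree on subject count")
    if len(set(labels)) < 2:
        raise ValueError("need at least 2 classes to fit the integration model")
    if weights is None:
        weights = class_weights(labels)
    fits = {}
    for k, t in enumerate(SC_TYPES):
        X = _design(blocks, modalities, t, all_inputs)
        y = (labels == t).astype(float)
        fit, _ = fit_cv_lasso(X, y, weights, folds=folds, seed=seed + k,
                              stratify_on=labels)
        if not intercept:
            fit.intercept = 0.0
        fits[t] = fit
    return IntegrationModel(modalities=modalities, fits=fits,
                            all_inputs=all_inputs, tau=tau, seed=seed)


def tscores(model: IntegrationModel, blocks: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """TSCORE_ij for every subject, columns in (TE, SE, SY) order."""
    index = _check_aligned({m: blocks[m] for m in model.modalities})
    out = {}
    for t in SC_TYPES:
        X = _design(blocks, model.modalities, t, model.all_inputs)
        out[t] = model.fits[t].predict(X)
    return pd.DataFrame(out, index=index, columns=list(SC_TYPES))


def tscore(pi_row: Mapping[str, Mapping[str, float]], model: IntegrationModel) -> Tuple[float, float, float]:
    """TSCORE triple for a single subject given its 4x3 pi values
    (mapping modality -> {TE/SE/SY: value})."""
    for m in model.modalities:
        if m not in pi_row:
            raise ValueError(f"missing modality {m!r}; integration requires "
                             "common samples")
    blocks = {m: pd.DataFrame([pi_row[m]], columns=list(SC_TYPES))
              for m in model.modalities}
    row = tscores(model, blocks).iloc[0]
    return float(row["TE"]), float(row["SE"]), float(row["SY"])


def tscore_fixed(blocks: Mapping[str, pd.DataFrame],
                 w: Mapping[str, float]) -> pd.DataFrame:
    """Historical variant: one fixed, user-supplied weight per modality
    shared by all types; TSCORE_ij = sum_r w_r * (pi_ij)_r."""
    index = _check_aligned(dict(blocks))
    total = sum(float(w[m]) * blocks[m].to_numpy(dtype=float) for m in blocks)
    return pd.DataFrame(total, index=index, columns=list(SC_TYPES))


def classify(scores) -> str:
    """Argmax type of a TSCORE triple; ties resolve to the earlier type
    in (TE, SE, SY) order."""
    a = np.asarray(scores, dtype=float)
    if a.shape != (3,):
        raise ValueError("expected exactly 3 scores")
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite TSCORE")
    return SC_TYPES[int(np.argmax(a))]


def margin(scores) -> float:
    """Typicality margin: top TSCORE minus the runner-up (>= 0)."""
    a = np.sort(np.asarray(scores, dtype=float))
    return float(a[-1] - a[-2])


def diagnose(
    model: IntegrationModel,
    blocks: Mapping[str, pd.DataFrame],
    tau: Optional[float] = None,
) -> pd.DataFrame:
    """Per-subject diagnosis table: the three TSCOREs, predicted type,
    typicality margin and typical flag at cutoff ``tau``."""
    tau = model.tau if tau is None else tau
    ts = tscores(model, blocks)
    a = ts.to_numpy(dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite TSCOREs")
    order = np.sort(a, axis=1)
    marg = order[:, -1] - order[:, -2]
    pred = [SC_TYPES[i] for i in a.argmax(axis=1)]
    return pd.DataFrame({
        "tscore_te": a[:, 0], "tscore_se": a[:, 1], "tscore_sy": a[:, 2],
        "predicted": pred, "margin": marg, "typical": marg >= tau,
    }, index=ts.index)


def typicality_filter(results: pd.DataFrame, tau: float) -> pd.DataFrame:
    """Subjects whose margin meets the cutoff; tau = 0 retains all."""
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    return results[results["margin"] >= tau]


def sweep_cutoff(
    results: pd.DataFrame,
    true_labels: pd.Series,
    taus: Sequence[float],
) -> pd.DataFrame:
    """Retained fraction and retained-subset accuracy along a tau grid."""
    rows = []
    for t in taus:
        kept = typicality_filter(results, t)
        frac = len(kept) / len(results) if len(results) else float("nan")
        acc = (float(np.mean(kept["predicted"].to_numpy()
                             == true_labels.loc[kept.index].to_numpy()))
               if len(kept) else float("nan"))
        rows.append({"tau": t, "retained_fraction": frac, "accuracy": acc})
    return pd.DataFrame(rows)
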