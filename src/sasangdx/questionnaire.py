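"""Questionnaire block: one-hot expansion and per-type continuous scores.

Multiple-choice responses are expanded to binary indicators (one per
question x category; unanswered questions become all-zero blocks, not
imputed).  A class-weighted L1 model per constitutional type reduces
the high-dimensional indicator matrix to one continuous score per type
(the model's linear predictor); the questionnaire component model is
then an ordinary weighted least-squares fit on those three scores,
since three well-conditioned regressors need no shrinkage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from sasangdx.lasso import SC_TYPES, LinearFit, class_weights, fit_cv_lasso, lasso_fit

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Codebook:
    """Ordered questions with their ordered response categories."""

    questions: Tuple[Tuple[str, Tuple[str, ...]], ...]  # (id, categories)

    def __post_init__(self):
        ids = [q for q, _ in self.questions]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate question ids in codebook")
        for q, cats in self.questions:
            if len(cats) < 2:
                raise ValueError(f"question {q!r} has fewer than 2 categories")

    @property
    def question_ids(self) -> List[str]:
        return [q for q, _ in self.questions]

    def n_categories(self, qid: str) -> int:
        for q, cats in self.questions:
            if q == qid:
                return len(cats)
        raise KeyError(qid)

    @property
    def width(self) -> int:
        return sum(len(cats) for _, cats in self.questions)

    def column_names(self) -> List[str]:
        return [f"{q}={c}" for q, cats in self.questions for c in cats]

    @classmethod
    def from_dict(cls, d: Mapping[str, Sequence[str]]) -> "Codebook":
        return cls(tuple((q, tuple(str(c) for c in cats)) for q, cats in d.items()))

    @classmethod
    def from_yaml(cls, path) -> "Codebook":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({q: list(cats) for q, cats in self.questions}, fh,
                           sort_keys=False)


def binarize(responses: Mapping[str, Optional[int]], codebook: Codebook) -> np.ndarray:
    """One-hot expand one subject's answers (1-based category indices).

    Unanswered questions (absent id, None or NaN) yield all-zero
    blocks; an out-of-range category or unknown question id is an
    error.
    """
    known = set(codebook.question_ids)
    for qid in responses:
        if qid not in known:
            raise KeyError(f"unknown question id {qid!r}")
    out = np.zeros(codebook.width, dtype=float)
    offset = 0
    for qid, cats in codebook.questions:
        ans = responses.get(qid)
        if ans is not None and not (isinstance(ans, float) and np.isnan(ans)):
            ans = int(ans)
            if not (1 <= ans <= len(cats)):
                raise ValueError(
                    f"category {ans} out of range 1..{len(cats)} for question {qid!r}")
            out[offset + ans - 1] = 1.0
        offset += len(cats)
    return out


def binarize_table(responses: pd.DataFrame, codebook: Codebook) -> pd.DataFrame:
    """One-hot expand a subjects x questions table of 1-based category
    indices (NaN = unanswered)."""
    rows = [binarize(responses.loc[i].to_dict(), codebook)
            for i in responses.index]
    return pd.DataFrame(np.vstack(rows) if rows else
                        np.empty((0, codebook.width)),
                        index=responses.index, columns=codebook.column_names())


@dataclass
class ScoreModels:
    """Per-type sparse linear maps from binary indicators to the three
    continuous questionnaire scores."""

    fits: Dict[str, LinearFit]
    column_names: List[str]
    kept: np.ndarray  # boolean mask of non-constant indicator columns

    def scores(self, binary: pd.DataFrame) -> pd.DataFrame:
        X = binary.to_numpy(dtype=float)[:, self.kept]
        return pd.DataFrame({t: self.fits[t].predict(X) for t in SC_TYPES},
                            index=binary.index, columns=list(SC_TYPES))


def fit_score_models(
    binary: pd.DataFrame,
    labels: Sequence[str],
    weights=None,
    seed: int = 0,
    folds: int = 10,
) -> ScoreModels:
    """L1 score models reducing indicators to per-type continuous scores.

    Constant indicator columns carry no information under any penalty
    and are dropped with a log entry before fitting.
    """
    labels = np.asarray(labels)
    if len(set(labels)) < 2:
        raise ValueError("need at least 2 classes to fit score models")
    if weights is None:
        weights = class_weights(labels)
    X = binary.to_numpy(dtype=float)
    kept = X.std(axis=0) > 0
    dropped = [c for c, k in zip(binary.columns, kept) if not k]
    if dropped:
        log.info("dropping %d constant indicator column(s): %s",
                 len(dropped), dropped[:5])
    Xk = X[:, kept]
    fits = {}
    for k, t in enumerate(SC_TYPES):
        y = (labels == t).astype(float)
        fit, _ = fit_cv_lasso(Xk, y, weights, folds=folds, seed=seed + k,
                              stratify_on=labels)
        fits[t] = fit
    return ScoreModels(fits=fits, column_names=list(binary.columns), kept=kept)


def questionnaire_component(
    scores: pd.DataFrame,
    labels: Sequence[str],
    weights=None,
    strict: bool = True,
) -> Dict[str, LinearFit]:
    """Weighted OLS of each type indicator on the 3 continuous scores.

    No penalty: the design is 3-dimensional.  A score column that is
    exactly constant (an intercept-only upstream model) contributes
    nothing and is tolerated — with all columns constant the fits
    predict the weighted class mass.  Non-constant but collinear
    columns signal a degenerate L1 path and raise by default;
    ``strict=False`` downgrades that to a warning and takes the
    minimum-norm solution (useful in automated simulations where a
    signal-free cohort legitimately degenerates).
    """
    labels = np.asarray(labels)
    X = scores.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite questionnaire scores")
    if weights is None:
        weights = class_weights(labels)
    w = np.asarray(weights, dtype=float)
    centered = X - (w[:, None] * X).sum(axis=0) / w.sum()
    varying = centered.std(axis=0) > 0
    if varying.any():
        C = np.sqrt(w)[:, None] * centered[:, varying]
        if np.linalg.matrix_rank(C) < int(varying.sum()):
            msg = ("rank-deficient score matrix; inspect the L1 score-model "
                   "path (collinear per-type scores)")
            if strict:
                raise ValueError(msg)
            log.warning("%s -- using the minimum-norm fit", msg)
    fits = {}
    for t in SC_TYPES:
        y = (labels == t).astype(float)
        fits[t] = lasso_fit(X, y, w, lam=0.0, standardize=False)
    return fits


def questionnaire_pi(fits: Dict[str, LinearFit], scores: pd.DataFrame) -> pd.DataFrame:
    """The questionnaire probability block from the OLS component fits."""
    return pd.DataFrame({t: fits[t].predict(scores.to_numpy(dtype=float))
                         for t in SC_TYPES},
                        index=scores.index, columns=list(SC_TYPES))
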