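"""End-to-end orchestration of the integrated diagnostic pipeline.

Stages, per sex (male and female run as separate pipelines, mirroring
the sex-stratified reporting of this model family):

1. exclusions (TY label, under-age, extraction errors);
2. restriction to common samples (all four modality blocks present);
3. stratified 7:3 train/test split (type x age-decade strata);
4. age normalization of the continuous blocks, fitted on training
   subjects only;
5. questionnaire one-hot expansion and L1 score models -> 3 continuous
   scores -> weighted OLS component;
6. class-weighted one-vs-rest L1 component models for face, body and
   voice with CV-chosen penalties;
7. stacked integration of the four probability blocks;
8. argmax diagnosis with typicality margins, and confusion summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from sasangdx.evaluation import ConfusionSummary, confusion
from sasangdx.integration import (
    DEFAULT_TAU,
    IntegrationModel,
    diagnose,
    fit_integration,
    typicality_filter,
)
from sasangdx.lasso import SC_TYPES, class_weights
from sasangdx.modality import ModalityModel, fit_modality_model, predict_pi
from sasangdx.preprocess import (
    Cohort,
    apply_exclusions,
    common_samples,
    normalize_block,
    stratified_split,
)
from sasangdx.questionnaire import (
    binarize_table,
    fit_score_models,
    questionnaire_component,
    questionnaire_pi,
)

log = logging.getLogger(__name__)

CONTINUOUS_MODALITIES = ("face", "body", "voice")


@dataclass
class SexResult:
    """Fitted models and diagnoses for one sex's pipeline."""

    sex: str
    models: Dict[str, ModalityModel]
    integration: IntegrationModel
    diag_train: pd.DataFrame
    diag_test: pd.DataFrame
    labels_train: pd.Series
    labels_test: pd.Series
    pi_test: Dict[str, pd.DataFrame]
    normalizers: Dict[str, dict] = field(default_factory=dict)
    score_models: Optional[object] = None
    q_fits: Optional[dict] = None

    def test_confusion(self) -> ConfusionSummary:
        return confusion(self.labels_test.to_numpy(),
                         self.diag_test["predicted"].to_numpy(),
                         sex=self.sex, subset="test")

    def train_confusion(self) -> ConfusionSummary:
        return confusion(self.labels_train.to_numpy(),
                         self.diag_train["predicted"].to_numpy(),
                         sex=self.sex, subset="train")


@dataclass
class PipelineResult:
    by_sex: Dict[str, SexResult]
    seed: int
    tau: float

    def _pairs(self, subset: str = "test"):
        for r in self.by_sex.values():
            diag = r.diag_test if subset == "test" else r.diag_train
            labels = r.labels_test if subset == "test" else r.labels_train
            yield diag, labels

    def integrated_accuracy(self, subset: str = "test") -> float:
        """Pooled held-out argmax accuracy (fraction)."""
        correct = total = 0
        for diag, labels in self._pairs(subset):
            correct += int((diag["predicted"].to_numpy()
                            == labels.to_numpy()).sum())
            total += len(diag)
        return correct / total if total else float("nan")

    def modality_accuracy(self, modality: str, subset: str = "test") -> float:
        """Pooled held-out accuracy of one modality's argmax alone."""
        correct = total = 0
        for r in self.by_sex.values():
            pi = r.pi_test[modality]
            labels = r.labels_test
            pred = pi.to_numpy().argmax(axis=1)
            truth = np.array([SC_TYPES.index(t) for t in labels])
            correct += int((pred == truth).sum())
            total += len(labels)
        return correct / total if total else float("nan")

    def cutoff_accuracy(self, tau: Optional[float] = None,
                        subset: str = "test") -> Tuple[float, float]:
        """(retained fraction, accuracy on the typical subset)."""
        tau = self.tau if tau is None else tau
        correct = kept = total = 0
        for diag, labels in self._pairs(subset):
            sub = typicality_filter(diag, tau)
            correct += int((sub["predicted"].to_numpy()
                            == labels.loc[sub.index].to_numpy()).sum())
            kept += len(sub)
            total += len(diag)
        return (kept / total if total else float("nan"),
                correct / kept if kept else float("nan"))


def _questionnaire_pi_blocks(cohort, train_ids, all_ids, weights, seed, folds):
    responses = cohort.blocks["questionnaire"]
    binary = binarize_table(responses, cohort.codebook)
    labels_train = cohort.meta.loc[train_ids, "sc_type"].to_numpy()
    sm = fit_score_models(binary.loc[train_ids], labels_train, weights,
                          seed=seed, folds=folds)
    scores = sm.scores(binary.loc[all_ids])
    q_fits = questionnaire_component(scores.loc[train_ids], labels_train, weights,
                                     strict=False)
    return questionnaire_pi(q_fits, scores), sm, q_fits


def run_pipeline(
    cohort: Cohort,
    seed: int = 0,
    tau: float = DEFAULT_TAU,
    train_fraction: float = 0.7,
    folds: int = 10,
    skip_exclusions: bool = False,
) -> PipelineResult:
    """Run the full diagnostic pipeline on a cohort, per sex."""
    if not skip_exclusions:
        cohort = apply_exclusions(cohort)
    cohort = common_samples(cohort)
    by_sex: Dict[str, SexResult] = {}
    for sex in ("M", "F"):
        ids = cohort.meta.index[cohort.meta["sex"] == sex]
        if len(ids) == 0:
            continue
        sub = cohort.subset(ids)
        train, test = stratified_split(sub, train_fraction, seed=seed)
        train_ids, test_ids = train.meta.index, test.meta.index
        all_ids = train_ids.append(test_ids)
        labels_train = sub.meta.loc[train_ids, "sc_type"]
        labels_test = sub.meta.loc[test_ids, "sc_type"]
        weights = class_weights(labels_train.to_numpy())

        pi_blocks_all: Dict[str, pd.DataFrame] = {}
        models: Dict[str, ModalityModel] = {}
        normalizers: Dict[str, dict] = {}
        ages = sub.meta["age"]
        for m in CONTINUOUS_MODALITIES:
            block = sub.blocks[m].loc[all_ids]
            normed, nzs = normalize_block(block, ages, fit_ids=train_ids)
            normalizers[m] = nzs
            model = fit_modality_model(normed.loc[train_ids],
                                       labels_train.to_numpy(), weights,
                                       modality=m, seed=seed, folds=folds)
            models[m] = model
            pi_blocks_all[m] = predict_pi(model, normed)
        qpi, score_models, q_fits = _questionnaire_pi_blocks(
            sub, train_ids, all_ids, weights, seed, folds)
        pi_blocks_all["questionnaire"] = qpi

        pi_train = {m: b.loc[train_ids] for m, b in pi_blocks_all.items()}
        pi_test = {m: b.loc[test_ids] for m, b in pi_blocks_all.items()}
        integ = fit_integration(pi_train, labels_train.to_numpy(), weights,
                                tau=tau, seed=seed, folds=folds)
        by_sex[sex] = SexResult(
            sex=sex,
            models=models,
            integration=integ,
            diag_train=diagnose(integ, pi_train),
            diag_test=diagnose(integ, pi_test),
            labels_train=labels_train,
            labels_test=labels_test,
            pi_test=pi_test,
            normalizers=normalizers,
            score_models=score_models,
            q_fits=q_fits,
        )
    if not by_sex:
        raise ValueError("cohort has no subjects after preprocessing")
    return PipelineResult(by_sex=by_sex, seed=seed, tau=tau)


def apply_sex_models(result: SexResult, cohort: Cohort,
                     tau: Optional[float] = None) -> pd.DataFrame:
    """Diagnose new subjects of one sex with an already-fitted pipeline
    (stored age normalizers, component models and integration weights).
    The cohort must provide all four modality blocks for every subject."""
    from sasangdx.preprocess import apply_age_normalizer

    ids = cohort.meta.index
    ages = cohort.meta.loc[ids, "age"]
    pi_blocks: Dict[str, pd.DataFrame] = {}
    for m in CONTINUOUS_MODALITIES:
        block = cohort.blocks[m].loc[ids]
        cols = {}
        for col in block.columns:
            nz = result.normalizers[m][col]
            cols[col] = apply_age_normalizer(nz, block[col].to_numpy(dtype=float),
                                             ages.to_numpy(dtype=float))
        pi_blocks[m] = predict_pi(result.models[m],
                                  pd.DataFrame(cols, index=ids))
    binary = binarize_table(cohort.blocks["questionnaire"].loc[ids],
                            cohort.codebook)
    scores = result.score_models.scores(binary)
    pi_blocks["questionnaire"] = questionnaire_pi(result.q_fits, scores)
    return diagnose(result.integration, pi_blocks, tau=tau)
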