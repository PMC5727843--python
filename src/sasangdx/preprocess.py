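"""Cohort assembly: exclusions, age normalization, intersection, split.

The cohort is a metadata table (sex, age, expert constitutional label)
plus one feature block per modality; a subject may lack any block.
Candidate features show age trends, so each feature is normalized to a
moving z-score against same-sex subjects of similar age before
modeling.  The integrated model is fit on the "common samples" —
subjects carrying all four blocks — split 7:3 into train and test
within sex x type x age-decade strata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MODALITIES = ("face", "body", "questionnaire", "voice")
MIN_AGE = 15
AGE_WINDOW_HALF_WIDTH = 5
AGE_WINDOW_MIN_COUNT = 30
AGE_SD_FLOOR = 1e-8


@dataclass
class Cohort:
    """Subjects with metadata and per-modality feature blocks.

    ``meta`` is indexed by subject id with columns ``sex`` (M/F),
    ``age`` (years), ``sc_type`` (TE/SE/SY/TY) and optional boolean
    ``error_<modality>`` extraction-error flags.  Each block is a
    DataFrame indexed by the subject ids that carry that modality.
    """

    meta: pd.DataFrame
    blocks: Dict[str, pd.DataFrame] = field(default_factory=dict)
    exclusion_counts: Dict[str, int] = field(default_factory=dict)
    codebook: Optional[object] = None  # questionnaire Codebook, when present

    def __post_init__(self):
        if self.meta.index.has_duplicates:
            raise ValueError("duplicate subject ids in cohort metadata")
        for name, block in self.blocks.items():
            extra = block.index.difference(self.meta.index)
            if len(extra):
                raise ValueError(
                    f"block {name!r} has subjects absent from metadata: "
                    f"{list(extra[:5])}")

    @property
    def n(self) -> int:
        return len(self.meta)

    @property
    def subject_ids(self) -> pd.Index:
        return self.meta.index

    def labels(self) -> pd.Series:
        return self.meta["sc_type"]

    def subset(self, ids) -> "Cohort":
        ids = pd.Index(ids, name=self.meta.index.name)
        return Cohort(
            meta=self.meta.loc[ids],
            blocks={m: b.loc[b.index.intersection(ids)]
                    for m, b in self.blocks.items()},
            codebook=self.codebook,
        )

    def has_modality(self, modality: str) -> pd.Series:
        present = self.meta.index.isin(self.blocks.get(modality, pd.DataFrame()).index)
        return pd.Series(present, index=self.meta.index)


def apply_exclusions(cohort: Cohort, min_age: int = MIN_AGE) -> Cohort:
    """Drop TY-labelled subjects and those below ``min_age`` years
    (strictly; a subject exactly at the boundary is kept), and remove
    extraction-error-flagged rows from the affected modality blocks.
    Exclusion counts are logged and recorded on the result."""
    meta = cohort.meta
    is_ty = meta["sc_type"] == "TY"
    too_young = meta["age"] < min_age
    keep = ~(is_ty | too_young)
    counts = {"TY constitution": int(is_ty.sum()),
              "below minimum age": int(too_young.sum())}
    blocks = {}
    for m, block in cohort.blocks.items():
        flag_col = f"error_{m}"
        kept_ids = meta.index[keep]
        if flag_col in meta.columns:
            errs = meta.index[meta[flag_col].fillna(False).astype(bool)]
            counts[f"extraction errors ({m})"] = int(
                block.index.isin(errs).sum())
            kept_ids = kept_ids.difference(errs)
        blocks[m] = block.loc[block.index.intersection(kept_ids)]
    out = Cohort(meta=meta.loc[keep].copy(), blocks=blocks,
                 codebook=cohort.codebook)
    out.exclusion_counts = counts
    for reason, c in counts.items():
        log.info("excluded %d subject-records: %s", c, reason)
    if out.n == 0:
        log.warning("cohort is empty after exclusions")
    return out


def common_samples(cohort: Cohort, modalities: Sequence[str] = MODALITIES) -> Cohort:
    """Restrict to subjects carrying every modality block."""
    ids = cohort.meta.index
    for m in modalities:
        block = cohort.blocks.get(m)
        if block is None:
            ids = ids[:0]
            break
        ids = ids.intersection(block.index)
    if len(ids) == 0:
        log.warning("no subjects have all modality blocks")
    else:
        by_sex = cohort.meta.loc[ids, "sex"].value_counts().to_dict()
        log.info("common samples: %d (%s)", len(ids), by_sex)
    return cohort.subset(ids)


# ---------------------------------------------------------------------------
# age normalization

@dataclass
class AgeNormalizer:
    """Moving mean/SD of one feature over an integer age grid.

    At each grid age the window is all training subjects within
    ``half_width`` years, widened symmetrically until at least
    ``min_count`` subjects fall inside (or the window covers everyone).
    The moving mean is a local linear estimate (value regressed on age
    within the window, evaluated at the grid age), which avoids the
    boundary bias of a plain window average; the moving SD is the
    within-window residual SD, floored at a small epsilon so
    degenerate windows stay finite."""

    age_grid: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    half_width: int = AGE_WINDOW_HALF_WIDTH
    min_count: int = AGE_WINDOW_MIN_COUNT

    def lookup(self, ages) -> Tuple[np.ndarray, np.ndarray]:
        ages = np.clip(np.asarray(ages, dtype=float),
                       self.age_grid[0], self.age_grid[-1])
        idx = np.searchsorted(self.age_grid, np.round(ages))
        idx = np.clip(idx, 0, self.age_grid.size - 1)
        return self.means[idx], self.sds[idx]


def fit_age_normalizer(
    values,
    ages,
    half_width: int = AGE_WINDOW_HALF_WIDTH,
    min_count: int = AGE_WINDOW_MIN_COUNT,
    sd_floor: float = AGE_SD_FLOOR,
) -> AgeNormalizer:
    """Fit the moving mean/SD of one feature against age."""
    v = np.asarray(values, dtype=float)
    a = np.asarray(ages, dtype=float)
    if v.shape != a.shape or v.size == 0:
        raise ValueError("values and ages must be equal-length and nonempty")
    lo, hi = int(np.floor(a.min())), int(np.ceil(a.max()))
    grid = np.arange(lo, hi + 1, dtype=float)
    means = np.empty(grid.size)
    sds = np.empty(grid.size)
    floored = 0
    for i, g in enumerate(grid):
        h = half_width
        while True:
            sel = np.abs(a - g) <= h
            if sel.sum() >= min(min_count, v.size):
                break
            h += 1
        aw, vw = a[sel], v[sel]
        if np.ptp(aw) > 0:
            slope, icept = np.polyfit(aw - g, vw, 1)
            means[i] = icept
            sd = float(np.std(vw - (icept + slope * (aw - g))))
        else:
            means[i] = vw.mean()
            sd = float(vw.std())
        if sd < sd_floor:
            sd = sd_floor
            floored += 1
        sds[i] = sd
    if floored:
        log.warning("SD floor hit at %d of %d grid ages", floored, grid.size)
    return AgeNormalizer(age_grid=grid, means=means, sds=sds,
                         half_width=half_width, min_count=min_count)


def apply_age_normalizer(normalizer: AgeNormalizer, values, ages) -> np.ndarray:
    """Moving z-score: (x - mean(age)) / sd(age)."""
    m, s = normalizer.lookup(ages)
    return (np.asarray(values, dtype=float) - m) / s


def normalize_block(
    block: pd.DataFrame,
    ages: pd.Series,
    fit_ids: Optional[pd.Index] = None,
    **kwargs,
) -> Tuple[pd.DataFrame, Dict[str, AgeNormalizer]]:
    """Age-normalize every column of a block, fitting the moving
    statistics on ``fit_ids`` only (training subjects) and applying to
    all rows."""
    fit_ids = block.index if fit_ids is None else block.index.intersection(fit_ids)
    out = {}
    normalizers = {}
    a_fit = ages.loc[fit_ids].to_numpy(dtype=float)
    a_all = ages.loc[block.index].to_numpy(dtype=float)
    for col in block.columns:
        nz = fit_age_normalizer(block.loc[fit_ids, col].to_numpy(dtype=float),
                                a_fit, **kwargs)
        out[col] = apply_age_normalizer(nz, block[col].to_numpy(dtype=float), a_all)
        normalizers[col] = nz
    return pd.DataFrame(out, index=block.index), normalizers


# ---------------------------------------------------------------------------
# stratified split

def age_decade(ages) -> np.ndarray:
    """Decade bins 10s..60s+ (ages 60 and above pool together)."""
    d = (np.asarray(ages, dtype=float) // 10).astype(int) * 10
    return np.minimum(d, 60)


def stratified_split(
    cohort: Cohort,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> Tuple[Cohort, Cohort]:
    """Random 7:3 partition within sex x type x age-decade strata.

    Per-stratum train counts are floor(f*n) plus largest-remainder
    correction so the overall train count is round(f*N); singleton
    strata go to train.  The same seed reproduces the split exactly.
    """
    if cohort.n == 0:
        raise ValueError("cannot split an empty cohort")
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must be in (0, 1)")
    meta = cohort.meta
    strata = list(zip(meta["sex"], meta["sc_type"], age_decade(meta["age"])))
    keys = sorted(set(strata))
    rng = np.random.default_rng(seed)
    sizes = {k: strata.count(k) for k in keys}
    base = {k: int(np.floor(train_fraction * n)) for k, n in sizes.items()}
    remainders = {k: train_fraction * sizes[k] - base[k] for k in keys}
    target = int(round(train_fraction * cohort.n))
    extra = target - sum(base.values())
    for k in sorted(keys, key=lambda k: (-remainders[k], k))[:max(extra, 0)]:
        base[k] += 1
    train_ids: List = []
    test_ids: List = []
    strata_arr = np.array([keys.index(s) for s in strata])
    for ki, k in enumerate(keys):
        members = meta.index[strata_arr == ki].to_numpy()
        n_train = base[k]
        if sizes[k] == 1 and n_train == 0:
            n_train = 1
            log.info("singleton stratum %s assigned to train", k)
        perm = rng.permutation(len(members))
        train_ids.extend(members[perm[:n_train]])
        test_ids.extend(members[perm[n_train:]])
    return cohort.subset(train_ids), cohort.subset(test_ids)
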