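"""Sex-stratified confusion matrices, sensitivity and accuracy.

Percentages are rounded half-up to one decimal, matching the reporting
convention of the published results for this model family; the shipped
``reference_confusions.json`` holds those published 3x3 count matrices
and printed percentages as a regression fixture for this arithmetic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from sasangdx.lasso import SC_TYPES

log = logging.getLogger(__name__)


def round_half_up_pct(numerator: int, denominator: int) -> float:
    """numerator/denominator as a percent, half-up at one decimal,
    computed in exact decimal arithmetic."""
    q = (Decimal(int(numerator)) * 100 / Decimal(int(denominator)))
    return float(q.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class ConfusionSummary:
    """3x3 count matrix, rows = true type, columns = predicted type."""

    counts: pd.DataFrame
    sex: Optional[str] = None
    subset: Optional[str] = None

    def __post_init__(self):
        c = self.counts
        if list(c.index) != list(SC_TYPES) or list(c.columns) != list(SC_TYPES):
            raise ValueError("confusion matrix must be indexed TE/SE/SY both ways")
        if (c.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @classmethod
    def from_matrix(cls, matrix, sex=None, subset=None) -> "ConfusionSummary":
        m = np.asarray(matrix, dtype=int)
        return cls(pd.DataFrame(m, index=list(SC_TYPES), columns=list(SC_TYPES)),
                   sex=sex, subset=subset)


def confusion(true_labels: Sequence[str], predicted: Sequence[str],
              sex=None, subset=None) -> ConfusionSummary:
    """Count matrix by (true, predicted) over the three types."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted)
    if t.size != p.size:
        raise ValueError("label vectors differ in length")
    bad = set(t) | set(p)
    bad -= set(SC_TYPES)
    if bad:
        raise ValueError(f"labels outside {SC_TYPES}: {sorted(bad)}")
    if t.size == 0:
        log.warning("empty label vectors; confusion matrix is all zero")
    m = np.zeros((3, 3), dtype=int)
    for a, b in zip(t, p):
        m[SC_TYPES.index(a), SC_TYPES.index(b)] += 1
    return ConfusionSummary.from_matrix(m, sex=sex, subset=subset)


def sensitivity(conf: ConfusionSummary, sc_type: str) -> float:
    """Per-class recall in percent (1 decimal, half-up)."""
    if sc_type not in SC_TYPES:
        raise ValueError(f"unknown SC type {sc_type!r}")
    row = int(conf.row_totals[sc_type])
    if row == 0:
        log.warning("sensitivity of %s undefined: empty true-class row", sc_type)
        return float("nan")
    return round_half_up_pct(int(conf.counts.at[sc_type, sc_type]), row)


def accuracy(conf: ConfusionSummary) -> float:
    """Trace over grand total in percent (1 decimal, half-up)."""
    total = conf.grand_total
    if total == 0:
        log.warning("accuracy undefined: empty confusion matrix")
        return float("nan")
    return round_half_up_pct(int(np.trace(conf.counts.to_numpy())), total)


def format_report(conf: ConfusionSummary) -> str:
    """Plain-text report in the conventional layout: predicted columns,
    true rows, per-class sensitivity and overall accuracy."""
    lines = []
    tag = " / ".join(s for s in (conf.sex, conf.subset) if s)
    if tag:
        lines.append(tag)
    header = f"{'True/Pred':>10}" + "".join(f"{t:>8}" for t in SC_TYPES)
    lines.append(header + f"{'Total':>8}{'Sens.':>8}")
    for t in SC_TYPES:
        row = conf.counts.loc[t]
        sens = sensitivity(conf, t)
        sens_s = f"{sens:.1f}%" if sens == sens else "--"
        lines.append(f"{t:>10}" + "".join(f"{int(row[c]):>8}" for c in SC_TYPES)
                     + f"{int(conf.row_totals[t]):>8}{sens_s:>8}")
    lines.append(f"{'Total':>10}" + "".join(
        f"{int(conf.col_totals[c]):>8}" for c in SC_TYPES)
        + f"{conf.grand_total:>8}")
    acc = accuracy(conf)
    lines.append(f"Accuracy: {acc:.1f}%" if acc == acc else "Accuracy: --")
    return "\n".join(lines)


def reference_results() -> dict:
    """The shipped published count matrices and printed percentages."""
    text = resources.files("sasangdx.data").joinpath(
        "reference_confusions.json").read_text()
    return json.loads(text)


def evaluate_reference_matrix(entry: dict) -> dict:
    """Recompute sensitivities and accuracy from a fixture entry's raw
    counts (never from its printed values)."""
    conf = ConfusionSummary.from_matrix(entry["matrix"])
    return {
        "sensitivity": {t: sensitivity(conf, t) for t in SC_TYPES},
        "accuracy": accuracy(conf),
    }
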