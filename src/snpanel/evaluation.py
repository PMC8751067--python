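"""Variety-level EDV evaluation: confusion counts, PR/RC/F1, union-set
enumeration and the identity-score threshold sweep.

The unit of evaluation is the variety (EDV vs non-EDV), matching how panel
reductions are judged operationally: ground-truth labels come from the full
marker set at a reference threshold, predictions from a reduced marker union
at each swept threshold.  Undefined metrics (zero denominators) are reported
as NaN, never coerced to 0, so the best-cell search is not distorted.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedValueError, ValidationError
from .identity import EDVPartition, WindowSpec, is_matrix
from .panel import GenotypePanel
from .selection import SimplifiedSet

DEFAULT_THRESHOLDS = (0.955, 0.965, 0.975, 0.985, 0.995)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(predicted: dict, truth: dict) -> ConfusionCounts:
    """2x2 counts over varieties, EDV = positive class.

    Both mappings must cover the same variety ids.
    """
    if set(predicted) != set(truth):
        raise ValidationError("predicted and truth label different variety sets")
    tp = fp = fn = tn = 0
    for v, p in predicted.items():
        t = truth[v]
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, fn, tn)


def precision(c: ConfusionCounts) -> float:
    """PR = TP / (TP + FP); NaN when no variety was predicted EDV."""
    return c.tp / (c.tp + c.fp) if (c.tp + c.fp) else math.nan


def recall(c: ConfusionCounts) -> float:
    """RC = TP / (TP + FN); NaN when no variety is truly EDV."""
    return c.tp / (c.tp + c.fn) if (c.tp + c.fn) else math.nan


def f1(pr: float, rc: float) -> float:
    """Harmonic mean 2*PR*RC/(PR+RC); NaN when undefined."""
    if math.isnan(pr) or math.isnan(rc) or (pr + rc) == 0:
        return math.nan
    return 2.0 * pr * rc / (pr + rc)


def enumerate_unions(
    sets: Sequence[SimplifiedSet], c_min: int = 1, c_max: int = 4
) -> list:
    """All unions of *c_min*..*c_max* of the given simplified sets.

    Returns ``(composition, marker_ids)`` pairs where composition is the
    tuple of run indices into *sets*.  Disjoint inputs make the union size
    the sum of the member sizes.
    """
    if c_max > len(sets):
        raise ValidationError("c_max exceeds the number of sets")
    out = []
    for c in range(c_min, c_max + 1):
        for comp in itertools.combinations(range(len(sets)), c):
            union: List[str] = []
            seen = set()
            for i in comp:
                for m in sets[i].marker_ids:
                    if m not in seen:
                        seen.add(m)
                        union.append(m)
            out.append((comp, union))
    return out


def _truth_labels(truth: EDVPartition, variety_ids: Sequence[str]) -> dict:
    edv = truth.edv_ids
    return {v: v in edv for v in variety_ids}


def _labels_from_matrix(values: np.ndarray, ids: Sequence[str], thr: float) -> dict:
    """EDV label per variety: best off-diagonal IS >= thr."""
    off = values.copy()
    np.fill_diagonal(off, -np.inf)
    best = np.nanmax(np.where(np.isnan(off), -np.inf, off), axis=1)
    return {v: bool(best[i] >= thr) for i, v in enumerate(ids)}


def sweep(
    train: GenotypePanel,
    truth: EDVPartition,
    unions: Sequence,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    spec: WindowSpec = WindowSpec(),
) -> pd.DataFrame:
    """PR/RC/F1 for every (union composition x IS threshold) cell.

    *unions* is the output of :func:`enumerate_unions`.  For each union the
    pairwise IS matrix is computed once and thresholded repeatedly.
    """
    truth_lab = _truth_labels(truth, train.variety_ids)
    rows = []
    for comp, markers in unions:
        mat = is_matrix(train, spec, marker_subset=markers)
        for thr in thresholds:
            pred = _labels_from_matrix(mat.values, mat.variety_ids, thr)
            c = confusion(pred, truth_lab)
            pr, rc = precision(c), recall(c)
            rows.append(
                {
                    "composition": "+".join(str(i) for i in comp),
                    "union_size": len(markers),
                    "threshold": thr,
                    "tp": c.tp,
                    "fp": c.fp,
                    "fn": c.fn,
                    "tn": c.tn,
                    "pr": pr,
                    "rc": rc,
                    "f1": f1(pr, rc),
                }
            )
    return pd.DataFrame(rows)


def pick_best(grid: pd.DataFrame):
    """Cell with the highest F1; ties broken by smaller union size, then
    lower threshold.  Returns the winning grid row (a Series)."""
    defined = grid.dropna(subset=["f1"])
    if defined.empty:
        raise UndefinedValueError("no grid cell has a defined F1")
    ordered = defined.sort_values(
        ["f1", "union_size", "threshold"], ascending=[False, True, True],
        kind="stable",
    )
    return ordered.iloc[0]
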