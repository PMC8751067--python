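"""Windowed identity scores (IS) and EDV calling.

The identity score between two varieties accumulates, over SNPs where both
calls are present, the per-site agreement ``1 - |Ds_a - Ds_b|`` where the
allele distance ``Ds`` of a genotype to the reference is 0 (hom-ref), 0.5
(het) or 1 (hom-alt).  Per-window scores divide by the number of jointly
called SNPs in a 20-kb window; genome-wide the default *pooled* aggregation
divides the total accumulated score by the total number of jointly called
SNPs (the SNP-count-weighted window mean), while *window_mean* averages the
per-window scores unweighted.

Varieties whose genome-wide IS reaches a threshold (0.975 by default) are
treated as essentially derived varieties (EDVs) of each other; EDV groups are
the connected components of the thresholded IS graph, and one representative
per group is retained for distinct-variety analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components as _cc
from sklearn.base import BaseEstimator, ClassifierMixin

from .errors import UndefinedValueError, ValidationError
from .panel import MISSING, GenotypePanel

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 20_000
DEFAULT_EDV_THRESHOLD = 0.975


@dataclass(frozen=True)
class WindowSpec:
    """How markers are windowed and aggregated genome-wide."""

    window_bp: int = DEFAULT_WINDOW_BP
    aggregation: str = "pooled"  # "pooled" | "window_mean"

    def __post_init__(self):
        if self.window_bp <= 0:
            raise ValidationError("window_bp must be positive")
        if self.aggregation not in ("pooled", "window_mean"):
            raise ValidationError(f"unknown aggregation: {self.aggregation}")


@dataclass
class PairwiseIS:
    """Symmetric matrix of genome-wide identity scores in [0, 1]."""

    variety_ids: list
    values: np.ndarray

    def get(self, a: str, b: str) -> float:
        ia, ib = self.variety_ids.index(a), self.variety_ids.index(b)
        return float(self.values[ia, ib])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.variety_ids, columns=self.variety_ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "PairwiseIS":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise ValidationError("IS matrix row/column variety ids disagree")
        return cls([str(v) for v in df.index], df.to_numpy(dtype=float))


@dataclass
class EDVPartition:
    """Connected components of the IS >= threshold graph with representatives."""

    components: list  # list[list[str]]
    representatives: list  # one variety id per component
    threshold: float

    @property
    def edv_ids(self) -> set:
        """Varieties belonging to a multi-member component."""
        return {v for comp in self.components if len(comp) > 1 for v in comp}

    def component_of(self, variety_id: str) -> list:
        for comp in self.components:
            if variety_id in comp:
                return comp
        raise ValidationError(f"unknown variety id: {variety_id}")


def allele_distance(code: int) -> float:
    """Distance of a genotype to the reference allele: 0, 0.5 or 1.

    Hom-ref scores 0, het 0.5, hom-alt 1.  A missing code raises so the
    caller decides the skip policy explicitly.
    """
    if code == MISSING:
        raise UndefinedValueError("allele distance undefined for a missing call")
    if code not in (0, 1, 2):
        raise ValidationError(f"invalid genotype code: {code}")
    return code / 2.0


def window_is(codes_a, codes_b) -> float:
    """IS for one window: mean of 1 - |Ds_a - Ds_b| over jointly called SNPs."""
    a = np.asarray(codes_a, dtype=float)
    b = np.asarray(codes_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("window vectors have different lengths")
    joint = (a != MISSING) & (b != MISSING)
    if not joint.any():
        raise UndefinedValueError("no jointly called SNP in window")
    return float(np.mean(1.0 - np.abs(a[joint] - b[joint]) / 2.0))


def _window_ids(panel: GenotypePanel, window_bp: int) -> np.ndarray:
    """Integer window label per marker: chromosomes tiled half-open from bp 1."""
    chrom_codes, _ = panel.markers["chromosome"].factorize()
    within = (panel.markers["position"].to_numpy() - 1) // window_bp
    return chrom_codes.astype(np.int64) * (within.max() + 1 if len(within) else 1) + within


def genome_is(
    panel: GenotypePanel,
    variety_a: str,
    variety_b: str,
    spec: WindowSpec = WindowSpec(),
    marker_subset: Optional[Iterable[str]] = None,
) -> float:
    """Genome-wide IS between two varieties of one panel."""
    cols = (
        panel.marker_indices(marker_subset)
        if marker_subset is not None
        else np.arange(panel.n_markers)
    )
    ia, ib = panel.variety_index(variety_a), panel.variety_index(variety_b)
    a = panel.codes[ia, cols].astype(float)
    b = panel.codes[ib, cols].astype(float)
    joint = (a != MISSING) & (b != MISSING)
    if not joint.any():
        raise UndefinedValueError(
            f"no jointly called SNP between {variety_a} and {variety_b}"
        )
    if spec.aggregation == "pooled":
        return float(np.mean(1.0 - np.abs(a[joint] - b[joint]) / 2.0))
    wid = _window_ids(panel, spec.window_bp)[cols]
    scores = []
    for w in np.unique(wid):
        sel = (wid == w) & joint
        if sel.any():
            scores.append(np.mean(1.0 - np.abs(a[sel] - b[sel]) / 2.0))
    return float(np.mean(scores))


def _pooled_is_dense(codes_a: np.ndarray, codes_b: np.ndarray) -> np.ndarray:
    """Pooled IS between every row of *codes_a* and every row of *codes_b*.

    Uses one-hot indicator products so missing calls drop out pairwise:
    score = jointly_called - n_opposite_hom - 0.5 * n_one_het, divided by
    jointly_called.  Entries with no jointly called SNP are NaN.
    """
    def indicators(c):
        return (
            (c == 0).astype(np.float32),
            (c == 1).astype(np.float32),
            (c == 2).astype(np.float32),
            (c != MISSING).astype(np.float32),
        )

    a0, a1, a2, ac = indicators(codes_a)
    b0, b1, b2, bc = indicators(codes_b)
    joint = ac @ bc.T
    opposite = a0 @ b2.T + a2 @ b0.T
    half = a1 @ (b0 + b2).T + (a0 + a2) @ b1.T
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (joint - opposite - 0.5 * half) / joint
    out[joint == 0] = np.nan
    return out


def is_matrix(
    panel: GenotypePanel,
    spec: WindowSpec = WindowSpec(),
    marker_subset: Optional[Iterable[str]] = None,
) -> PairwiseIS:
    """All-pairs genome-wide IS; symmetric with unit diagonal.

    Pairs with no jointly called SNP are flagged NaN rather than raising.
    """
    if panel.n_varieties < 2:
        raise ValidationError("is_matrix needs at least 2 varieties")
    cols = (
        panel.marker_indices(marker_subset)
        if marker_subset is not None
        else np.arange(panel.n_markers)
    )
    codes = panel.codes[:, cols]
    if spec.aggregation == "pooled":
        vals = _pooled_is_dense(codes, codes).astype(float)
    else:
        n = panel.n_varieties
        vals = np.ones((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                try:
                    v = genome_is(
                        panel,
                        panel.variety_ids[i],
                        panel.variety_ids[j],
                        spec,
                        marker_subset,
                    )
                except UndefinedValueError:
                    v = np.nan
                vals[i, j] = vals[j, i] = v
    np.fill_diagonal(vals, 1.0)
    vals = (vals + vals.T) / 2.0  # enforce exact symmetry against float noise
    return PairwiseIS(list(panel.variety_ids), vals)


def edv_components(
    is_values: PairwiseIS, threshold: float = DEFAULT_EDV_THRESHOLD, seed: int = 0
) -> EDVPartition:
    """Group varieties whose IS reaches *threshold* (inclusive) into EDV
    components and retain one seeded-random representative per component."""
    if not 0 < threshold <= 1:
        raise ValidationError("threshold must be in (0, 1]")
    vals = np.nan_to_num(is_values.values, nan=-1.0)
    adj = csr_matrix(vals >= threshold)
    n_comp, labels = _cc(adj, directed=False)
    rng = np.random.default_rng(seed)
    components, representatives = [], []
    for c in range(n_comp):
        members = [is_values.variety_ids[i] for i in np.flatnonzero(labels == c)]
        components.append(members)
        representatives.append(members[rng.integers(len(members))])
    return EDVPartition(components, representatives, threshold)


def cross_is(
    train: GenotypePanel,
    test: GenotypePanel,
    marker_subset: Optional[Iterable[str]] = None,
    spec: WindowSpec = WindowSpec(),
) -> np.ndarray:
    """Pooled IS between every test variety (rows) and every train variety.

    Computed over the marker-id intersection of the two panels (restricted to
    *marker_subset* if given); a shortfall is logged, an empty intersection is
    an error.  window_mean aggregation is not supported across panels.
    """
    if spec.aggregation != "pooled":
        raise ValidationError("cross-panel IS supports pooled aggregation only")
    train_ids = set(train.marker_ids)
    test_ids = set(test.marker_ids)
    wanted = set(marker_subset) if marker_subset is not None else train_ids
    shared = sorted(wanted & train_ids & test_ids)
    if not shared:
        raise ValidationError("no shared markers between train and test panels")
    if marker_subset is not None and len(shared) < len(wanted):
        logger.warning(
            "marker subset: only %d of %d markers present in both panels",
            len(shared), len(wanted),
        )
    a = test.codes[:, test.marker_indices(shared)]
    b = train.codes[:, train.marker_indices(shared)]
    return _pooled_is_dense(a, b).astype(float)


def label_test_varieties(
    train: GenotypePanel,
    test: GenotypePanel,
    marker_subset: Optional[Iterable[str]] = None,
    threshold: float = DEFAULT_EDV_THRESHOLD,
    spec: WindowSpec = WindowSpec(),
) -> dict:
    """EDV label per test variety: True iff its best IS against any train
    variety reaches *threshold*."""
    xs = cross_is(train, test, marker_subset, spec)
    best = np.nanmax(xs, axis=1)
    return {v: bool(best[i] >= threshold) for i, v in enumerate(test.variety_ids)}


class EDVClassifier(ClassifierMixin, BaseEstimator):
    """Similarity-threshold EDV caller with a scikit-learn fit/predict surface.

    ``fit(X)`` memorises the reference (training) genotype matrix;
    ``predict(X)`` labels each query variety True (EDV) iff its pooled
    genome-wide identity score against the closest reference variety is at
    least *threshold*.

    Parameters
    ----------
    threshold : float, default 0.975
        Genome-wide IS threshold for the EDV call (inclusive).
    """

    def __init__(self, threshold: float = DEFAULT_EDV_THRESHOLD):
        self.threshold = threshold

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.int8)
        if X.ndim != 2:
            raise ValidationError("X must be a 2-D genotype code matrix")
        if not np.isin(X, [-1, 0, 1, 2]).all():
            raise ValidationError("genotype codes must be in {-1,0,1,2}")
        self.reference_codes_ = X
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        """Best identity score of each query row against the reference set."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "reference_codes_")
        X = np.asarray(X, dtype=np.int8)
        if X.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"expected {self.n_features_in_} markers, got {X.shape[1]}"
            )
        return np.nanmax(_pooled_is_dense(X, self.reference_codes_), axis=1)

    def predict(self, X) -> np.ndarray:
        return self.decision_function(X) >= self.threshold
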