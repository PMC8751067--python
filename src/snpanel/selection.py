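"""Conditional Random Selection (CRS) of minimal distinguishing SNP sets.

CRS builds a small marker set that gives every variety a *specific
haplotype* — a genotype vector over the selected markers shared by no other
variety — in two stages:

Stage 1 (preliminary screening)
    In each round draw several random k-subsets (k = 3 by default) from the
    not-yet-selected candidates, score each by how many varieties newly gain
    a specific haplotype when the subset is appended, append the best subset
    and repeat until every variety is resolved.

Stage 2 (redundancy deletion)
    Shield one selected marker at a time in seeded random order; if the rest
    still distinguish all varieties the marker is redundant and dropped.
    Whole passes repeat until a pass drops nothing, so the output is
    irreducible: removing any single marker breaks distinguishability.

Repeated runs with previously selected markers excluded yield disjoint
"simplified SNP combinations" whose unions form the operational panels.
Baselines: RS draws markers uniformly at random; HPS draws uniformly among
markers with PIC strictly above a floor (0.4 by default).

Selection requires complete genotypes (no missing calls): a wildcard
interpretation of missing data would silently change the distinguishability
relation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

from .errors import (
    IndistinguishableVarietiesError,
    UndefinedValueError,
    ValidationError,
)
from .identity import EDVPartition
from .panel import MISSING, GenotypePanel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionConfig:
    """Tunables of one CRS run."""

    k_per_round: int = 3
    trials_per_round: int = 10
    seed: int = 0
    prune_passes_max: Optional[int] = None  # None = iterate to a fixed point
    edv_polymorphic_filter: bool = False

    def __post_init__(self):
        if self.k_per_round < 1:
            raise ValidationError("k_per_round must be >= 1")
        if self.trials_per_round < 1:
            raise ValidationError("trials_per_round must be >= 1")


@dataclass
class SimplifiedSet:
    """An ordered, duplicate-free marker set produced by one selection run."""

    marker_ids: list
    method: str = "CRS"  # CRS | RS | HPS
    run_index: int = 0
    seed: Optional[int] = None

    def __post_init__(self):
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValidationError("SimplifiedSet contains duplicate marker ids")

    @property
    def size(self) -> int:
        return len(self.marker_ids)


# ---------------------------------------------------------------------------
# distinguishability primitives
# ---------------------------------------------------------------------------

def _group_inverse(codes: np.ndarray) -> np.ndarray:
    """Group label per row; identical rows share a label."""
    if codes.shape[1] == 0:
        return np.zeros(codes.shape[0], dtype=np.int64)
    _, inv = np.unique(codes, axis=0, return_inverse=True)
    return inv.astype(np.int64)


def _n_groups(codes: np.ndarray) -> int:
    if codes.shape[1] == 0:
        return 1 if codes.shape[0] else 0
    return np.unique(codes, axis=0).shape[0]


def haplotype_groups(panel: GenotypePanel, selected: Iterable[str]) -> list:
    """Partition varieties by their genotype vector over *selected* markers.

    An empty selection yields a single group of all varieties.
    """
    idx = panel.marker_indices(selected)
    inv = _group_inverse(panel.codes[:, idx])
    groups: dict = {}
    for i, g in enumerate(inv):
        groups.setdefault(int(g), []).append(panel.variety_ids[i])
    return [groups[g] for g in sorted(groups)]


def distinguishes_all(panel: GenotypePanel, selected: Iterable[str]) -> bool:
    """True iff every variety has a specific haplotype over *selected*."""
    idx = panel.marker_indices(selected)
    return _n_groups(panel.codes[:, idx]) == panel.n_varieties


def _require_complete(codes: np.ndarray) -> None:
    if (codes == MISSING).any():
        raise ValidationError(
            "selection requires complete genotypes; impute or drop missing calls"
        )


def _residual_groups(codes: np.ndarray, ids: Sequence[str]) -> list:
    inv = _group_inverse(codes)
    groups: dict = {}
    for i, g in enumerate(inv):
        groups.setdefault(int(g), []).append(ids[i])
    return [g for g in groups.values() if len(g) > 1]


# ---------------------------------------------------------------------------
# CRS stages (array internals + panel wrappers)
# ---------------------------------------------------------------------------

def _stage1_indices(
    codes: np.ndarray,
    cand: np.ndarray,
    k: int,
    trials: int,
    rng: np.random.Generator,
    ids: Sequence[str],
) -> List[int]:
    n = codes.shape[0]
    if _n_groups(codes[:, cand]) < n:
        raise IndistinguishableVarietiesError(_residual_groups(codes[:, cand], ids))
    remaining = list(cand)
    selected: List[int] = []
    group = np.zeros(n, dtype=np.int64)
    n_single = 1 if n == 1 else 0
    while n_single < n:
        if not remaining:  # unreachable given the feasibility check; guard anyway
            raise IndistinguishableVarietiesError(
                _residual_groups(codes[:, selected], ids)
            )
        kk = min(k, len(remaining))
        best_subset, best_score, best_group = None, -1, None
        for _ in range(trials):
            pick = rng.choice(len(remaining), size=kk, replace=False)
            cols = [remaining[p] for p in pick]
            # combine current groups with the trial columns into new keys
            key = group.copy()
            for c in cols:
                key = key * 3 + codes[:, c]
            _, inv, counts = np.unique(key, return_inverse=True, return_counts=True)
            score = int((counts == 1).sum())
            if score > best_score:  # strict: ties fall to the earliest draw
                best_subset, best_score, best_group = cols, score, inv.astype(np.int64)
        selected.extend(best_subset)
        for c in best_subset:
            remaining.remove(c)
        group = best_group
        n_single = best_score
    return selected


def _stage2_indices(
    codes: np.ndarray,
    selected: Sequence[int],
    rng: np.random.Generator,
    max_passes: Optional[int] = None,
) -> List[int]:
    sel = list(selected)
    n = codes.shape[0]
    passes = 0
    while True:
        order = [sel[int(j)] for j in rng.permutation(len(sel))]
        dropped = False
        for marker in order:
            if len(sel) <= 1:
                break
            rest = [c for c in sel if c != marker]
            if _n_groups(codes[:, rest]) == n:
                sel = rest
                dropped = True
        passes += 1
        if not dropped:
            break  # fixed point: no single marker is removable
        if max_passes is not None and passes >= max_passes:
            break
    return sel


def stage1_screen(
    panel: GenotypePanel,
    candidates: Sequence[str],
    config: SelectionConfig = SelectionConfig(),
) -> list:
    """Stage 1: iterative best-of-`trials_per_round` random k-subset screening.

    Returns marker ids (in selection order) that distinguish all varieties.
    """
    if not candidates:
        raise ValidationError("candidate list is empty")
    cand = panel.marker_indices(candidates)
    _require_complete(panel.codes[:, cand])
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    sel = _stage1_indices(
        panel.codes, cand, config.k_per_round, config.trials_per_round, rng,
        panel.variety_ids,
    )
    return [panel.markers["id"].iat[i] for i in sel]


def stage2_prune(
    panel: GenotypePanel, selected: Sequence[str], seed: int = 0
) -> SimplifiedSet:
    """Stage 2: drop redundant markers until the set is irreducible."""
    idx = list(panel.marker_indices(selected))
    _require_complete(panel.codes[:, idx])
    if _n_groups(panel.codes[:, idx]) != panel.n_varieties:
        raise ValidationError("stage2_prune input does not distinguish all varieties")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    keep = _stage2_indices(panel.codes, idx, rng)
    return SimplifiedSet(
        [panel.markers["id"].iat[i] for i in sorted(keep)], method="CRS", seed=seed
    )


def run_crs(
    panel: GenotypePanel,
    candidates: Optional[Sequence[str]] = None,
    config: SelectionConfig = SelectionConfig(),
    run_index: int = 0,
) -> SimplifiedSet:
    """One full CRS run: stage 1 screening then stage 2 redundancy deletion."""
    if candidates is None:
        candidates = panel.marker_ids
    screened = stage1_screen(panel, candidates, config)
    pruned = stage2_prune(panel, screened, seed=config.seed)
    return SimplifiedSet(pruned.marker_ids, "CRS", run_index, config.seed)


def run_crs_multi(
    panel: GenotypePanel,
    candidates: Optional[Sequence[str]] = None,
    n_runs: int = 5,
    config: SelectionConfig = SelectionConfig(),
) -> List[SimplifiedSet]:
    """Repeated CRS runs with earlier selections excluded, so the returned
    simplified sets are pairwise disjoint.  Stops early (with a warning) when
    the residual candidate pool can no longer distinguish all varieties."""
    if candidates is None:
        candidates = panel.marker_ids
    pool = list(candidates)
    out: List[SimplifiedSet] = []
    for r in range(n_runs):
        if not pool and r > 0:
            logger.warning(
                "candidate pool exhausted after %d disjoint sets (%d requested)",
                r, n_runs,
            )
            break
        if r == 0:
            run_cfg = config  # a single run is exactly run_crs
        else:
            run_cfg = SelectionConfig(
                k_per_round=config.k_per_round,
                trials_per_round=config.trials_per_round,
                seed=int(
                    np.random.SeedSequence([config.seed, 100 + r]).generate_state(1)[0]
                    % (2**31)
                ),
                prune_passes_max=config.prune_passes_max,
                edv_polymorphic_filter=config.edv_polymorphic_filter,
            )
        try:
            s = run_crs(panel, pool, run_cfg, run_index=r)
        except IndistinguishableVarietiesError:
            if r == 0:
                raise
            logger.warning(
                "candidate pool exhausted after %d disjoint sets (%d requested)",
                r, n_runs,
            )
            break
        out.append(s)
        chosen = set(s.marker_ids)
        pool = [m for m in pool if m not in chosen]
    return out


def edv_polymorphic_candidates(
    panel: GenotypePanel, partition: EDVPartition
) -> list:
    """Markers polymorphic within at least one multi-member EDV component.

    With no multi-member component the filter is vacuous: the full marker
    list is returned with a warning.
    """
    multi = [c for c in partition.components if len(c) > 1]
    if not multi:
        logger.warning("no multi-member EDV component; candidate filter is vacuous")
        return panel.marker_ids
    keep = np.zeros(panel.n_markers, dtype=bool)
    for comp in multi:
        rows = panel.codes[[panel.variety_index(v) for v in comp]]
        keep |= (rows != rows[0]).any(axis=0)
    return [m for m, k in zip(panel.marker_ids, keep) if k]


# ---------------------------------------------------------------------------
# baselines and the exhaustive oracle
# ---------------------------------------------------------------------------

def select_rs(candidates: Sequence[str], n: int, seed: int = 0) -> SimplifiedSet:
    """Random Selection baseline: uniform seeded draw without replacement."""
    if n > len(candidates):
        raise ValidationError(f"cannot draw {n} markers from {len(candidates)}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    pick = rng.choice(len(candidates), size=n, replace=False)
    return SimplifiedSet([candidates[i] for i in pick], "RS", seed=seed)


def select_hps(
    candidates: Sequence[str],
    stats,
    n: int,
    pic_min: float = 0.4,
    seed: int = 0,
) -> SimplifiedSet:
    """High-PIC Selection baseline: uniform draw among markers with PIC
    strictly above *pic_min* ("more than 0.4")."""
    pic_by_id = dict(zip(stats["id"], stats["pic"]))
    eligible = [m for m in candidates if pic_by_id.get(m, np.nan) > pic_min]
    if len(eligible) < n:
        raise ValidationError(
            f"only {len(eligible)} markers have PIC > {pic_min}, need {n}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    pick = rng.choice(len(eligible), size=n, replace=False)
    return SimplifiedSet([eligible[i] for i in pick], "HPS", seed=seed)


def brute_force_min_set(
    panel: GenotypePanel, candidates: Optional[Sequence[str]] = None
) -> list:
    """Minimum-cardinality distinguishing subset by exhaustive enumeration.

    Test oracle only; candidate counts beyond ~20 are intractable.
    """
    if candidates is None:
        candidates = panel.marker_ids
    cand = panel.marker_indices(candidates)
    ids = [panel.markers["id"].iat[i] for i in cand]
    if _n_groups(panel.codes[:, cand]) < panel.n_varieties:
        raise IndistinguishableVarietiesError(
            _residual_groups(panel.codes[:, cand], panel.variety_ids)
        )
    for size in range(1, len(cand) + 1):
        for comb in itertools.combinations(range(len(cand)), size):
            if _n_groups(panel.codes[:, cand[list(comb)]]) == panel.n_varieties:
                return [ids[i] for i in comb]
    raise AssertionError("unreachable: full candidate set distinguishes")


# ---------------------------------------------------------------------------
# scikit-learn estimators
# ---------------------------------------------------------------------------

class _BaseMarkerSelector(SelectorMixin, BaseEstimator):
    """Shared plumbing: X is an (n_varieties, n_markers) genotype code matrix."""

    def _validate_codes(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.int8)
        if X.ndim != 2:
            raise ValidationError("X must be a 2-D genotype code matrix")
        if not np.isin(X, [-1, 0, 1, 2]).all():
            raise ValidationError("genotype codes must be in {-1,0,1,2}")
        self.n_features_in_ = X.shape[1]
        return X

    def _get_support_mask(self):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "support_")
        return self.support_


class CRSSelector(_BaseMarkerSelector):
    """Conditional-Random-Selection marker selector (scikit-learn API).

    ``fit(X)`` runs *n_runs* disjoint CRS selections on the genotype matrix
    (rows = varieties, columns = markers, codes 0/1/2) and exposes the union
    of the simplified sets as the selected features; the individual runs are
    available in ``sets_`` for union-composition analyses.

    Parameters
    ----------
    k_per_round : int, default 3
        Markers drawn per stage-1 subset.
    trials_per_round : int, default 10
        Random subsets scored per round; the best is kept.
    n_runs : int, default 5
        Disjoint simplified sets to produce.
    random_state : int, default 0
        Seed for every random draw; identical inputs and seed give identical
        output.

    Attributes
    ----------
    sets_ : list of list of int
        Column indices of each simplified set, pairwise disjoint; each set
        distinguishes all rows and is irreducible.
    support_ : ndarray of bool
        Union of all simplified sets.
    """

    def __init__(
        self,
        k_per_round: int = 3,
        trials_per_round: int = 10,
        n_runs: int = 5,
        random_state: int = 0,
    ):
        self.k_per_round = k_per_round
        self.trials_per_round = trials_per_round
        self.n_runs = n_runs
        self.random_state = random_state

    def fit(self, X, y=None):
        X = self._validate_codes(X)
        _require_complete(X)
        pool = np.arange(X.shape[1])
        self.sets_ = []
        for r in range(self.n_runs):
            children = np.random.SeedSequence([self.random_state, 100 + r]).spawn(2)
            rng1 = np.random.default_rng(children[0])
            rng2 = np.random.default_rng(children[1])
            try:
                s1 = _stage1_indices(
                    X, pool, self.k_per_round, self.trials_per_round, rng1,
                    [str(i) for i in range(X.shape[0])],
                )
            except IndistinguishableVarietiesError:
                if r == 0:
                    raise
                logger.warning("candidate pool exhausted after %d sets", r)
                break
            s2 = sorted(_stage2_indices(X, s1, rng2))
            self.sets_.append(s2)
            pool = np.array([c for c in pool if c not in set(s2)])
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        for s in self.sets_:
            self.support_[s] = True
        return self


class RandomSelector(_BaseMarkerSelector):
    """RS baseline: *n_markers* columns drawn uniformly without replacement."""

    def __init__(self, n_markers: int = 100, random_state: int = 0):
        self.n_markers = n_markers
        self.random_state = random_state

    def fit(self, X, y=None):
        X = self._validate_codes(X)
        if self.n_markers > X.shape[1]:
            raise ValidationError("n_markers exceeds the number of columns")
        rng = np.random.default_rng(np.random.SeedSequence([self.random_state, 3]))
        pick = rng.choice(X.shape[1], size=self.n_markers, replace=False)
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[pick] = True
        return self


class HighPICSelector(_BaseMarkerSelector):
    """HPS baseline: uniform draw among columns with PIC strictly > pic_min."""

    def __init__(self, n_markers: int = 100, pic_min: float = 0.4, random_state: int = 0):
        self.n_markers = n_markers
        self.pic_min = pic_min
        self.random_state = random_state

    def fit(self, X, y=None):
        from .stats import pic as _pic

        X = self._validate_codes(X)
        pics = np.array([_pic(X[:, j]) for j in range(X.shape[1])])
        eligible = np.flatnonzero(pics > self.pic_min)
        if eligible.size < self.n_markers:
            raise ValidationError(
                f"only {eligible.size} markers have PIC > {self.pic_min}, "
                f"need {self.n_markers}"
            )
        rng = np.random.default_rng(np.random.SeedSequence([self.random_state, 4]))
        pick = eligible[rng.choice(eligible.size, size=self.n_markers, replace=False)]
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[pick] = True
        return self
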