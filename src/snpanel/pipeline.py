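"""End-to-end workflow: full-panel EDV truth, disjoint CRS runs, union
enumeration and the threshold sweep that picks the operational panel.

This is the composition the individual modules are designed for:

1. pairwise IS over the full marker set at the reference threshold defines
   the EDV partition (the ground truth for the reduced panel);
2. one representative per EDV component is retained, giving the
   distinct-variety panel that CRS must discriminate;
3. repeated disjoint CRS runs produce the simplified SNP combinations;
4. unions of 1..4 of those sets are swept over a grid of IS thresholds and
   scored (PR/RC/F1) against the full-panel truth;
5. the best (union, threshold) cell is the operational fingerprint panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .evaluation import DEFAULT_THRESHOLDS, enumerate_unions, pick_best, sweep
from .identity import (
    DEFAULT_EDV_THRESHOLD,
    EDVPartition,
    WindowSpec,
    edv_components,
    is_matrix,
)
from .panel import GenotypePanel
from .selection import (
    SelectionConfig,
    SimplifiedSet,
    edv_polymorphic_candidates,
    run_crs_multi,
)


@dataclass
class StudyResult:
    """Everything produced by one full fingerprinting study."""

    partition: EDVPartition
    distinct_panel: GenotypePanel
    sets: list
    grid: pd.DataFrame
    best: pd.Series

    @property
    def best_markers(self) -> list:
        comp = [int(i) for i in str(self.best["composition"]).split("+")]
        seen, out = set(), []
        for i in comp:
            for m in self.sets[i].marker_ids:
                if m not in seen:
                    seen.add(m)
                    out.append(m)
        return out


def run_study(
    panel: GenotypePanel,
    reference_threshold: float = DEFAULT_EDV_THRESHOLD,
    n_runs: int = 5,
    config: SelectionConfig = SelectionConfig(),
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    c_min: int = 1,
    c_max: int = 4,
    spec: WindowSpec = WindowSpec(),
) -> StudyResult:
    """Run the full study on one training panel (see module docstring)."""
    full = is_matrix(panel, spec)
    partition = edv_components(full, reference_threshold, seed=config.seed)
    distinct = panel.subset_varieties(sorted(partition.representatives))
    if config.edv_polymorphic_filter:
        candidates = edv_polymorphic_candidates(panel, partition)
    else:
        candidates = panel.marker_ids
    sets = run_crs_multi(distinct, candidates, n_runs=n_runs, config=config)
    unions = enumerate_unions(sets, c_min, min(c_max, len(sets)))
    grid = sweep(panel, partition, unions, thresholds, spec)
    return StudyResult(partition, distinct, sets, grid, pick_best(grid))
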