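"""Per-marker polymorphism statistics.

PIC here is the genotype-class diversity ``1 - sum(f_i^2)`` where ``f_i`` are
the frequencies of the observed genotype classes (hom-ref / het / hom-alt)
among called cells.  For three classes its maximum is 2/3, reached at a
uniform spectrum; it is 0 iff the marker is monomorphic among called cells.
Missing cells are excluded from every denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedValueError
from .panel import MISSING, GenotypePanel


@dataclass(frozen=True)
class GenotypeFrequencySpectrum:
    """Genotype-class frequencies of one marker, missing excluded."""

    frequencies: dict
    n_called: int


def genotype_frequencies(column) -> GenotypeFrequencySpectrum:
    """Frequency of each observed genotype class in a marker column."""
    col = np.asarray(column)
    called = col[col != MISSING]
    if called.size == 0:
        return GenotypeFrequencySpectrum({}, 0)
    vals, counts = np.unique(called, return_counts=True)
    freqs = {int(v): c / called.size for v, c in zip(vals, counts)}
    return GenotypeFrequencySpectrum(freqs, int(called.size))


def pic(column) -> float:
    """Polymorphic information content, ``1 - sum(f_i^2)`` over genotype classes."""
    spec = genotype_frequencies(column)
    if spec.n_called == 0:
        raise UndefinedValueError("pic undefined: all calls missing")
    return 1.0 - sum(f * f for f in spec.frequencies.values())


def maf(column) -> float:
    """Minor allele frequency; code 1 contributes one alt allele, code 2 two."""
    col = np.asarray(column)
    called = col[col != MISSING]
    if called.size == 0:
        raise UndefinedValueError("maf undefined: all calls missing")
    p = called.sum() / (2 * called.size)
    return float(min(p, 1.0 - p))


def missing_rate(column) -> float:
    col = np.asarray(column)
    return float((col == MISSING).mean())


def stats_table(panel: GenotypePanel) -> pd.DataFrame:
    """Per-marker table: id, chromosome, position, pic, maf, missing_rate.

    Markers with no called cells get NaN statistics rather than an error so a
    full-panel report never aborts.
    """
    rows = []
    for j in range(panel.n_markers):
        col = panel.codes[:, j]
        try:
            p, m = pic(col), maf(col)
        except UndefinedValueError:
            p, m = np.nan, np.nan
        rows.append(
            {
                "id": panel.markers["id"].iat[j],
                "chromosome": panel.markers["chromosome"].iat[j],
                "position": panel.markers["position"].iat[j],
                "pic": p,
                "maf": m,
                "missing_rate": missing_rate(col),
            }
        )
    return pd.DataFrame(rows)
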