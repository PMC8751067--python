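"""Synthetic genotype panels with known derivation (EDV) structure.

The generator emulates a large inbred crop panel of the kind used for
variety fingerprinting: mostly homozygous bi-allelic SNPs spread over 12
chromosomes, founder varieties organised in small *families* of related
breeding lines, and derived varieties created by copying a parent and
mutating a small fraction ``q`` of sites.

Two constructions keep ground truth exact on fully homozygous panels:

* a mutated site is flipped to the *opposite* homozygote, so each mutation
  costs exactly one unit of identity and the pooled parent-child IS equals
  ``1 - realized_mutated_fraction``;
* within-family divergence is enforced to stay strictly below the EDV
  threshold (realized pairwise difference >= ``min_family_difference``), and
  each derived line strictly above it (realized mutated fraction <
  ``max_derived_difference``), so full-panel EDV calling at the reference
  threshold recovers the generative labels deterministically.

Family relatedness (pairwise genome IS ~ 0.90-0.97) is on by default: real
breeding panels are dense with related-but-distinct varieties just below the
EDV threshold, and both the size of CRS-selected sets and the behaviour of
reduced panels under threshold sweeps hinge on that relatedness continuum.
``family_size=1`` gives fully independent founders (background IS ~ 0.6),
the setting used for closed-form checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .errors import ValidationError
from .identity import DEFAULT_EDV_THRESHOLD
from .panel import GenotypePanel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic panel generator.

    Defaults are the package's standard study conditions: 100 founders in
    families of 4, 10,000 SNPs on 12 chromosomes, fully inbred genotypes,
    20 derived lines at mutation fraction 0.01.
    """

    n_founders: int = 100
    n_snps: int = 10_000
    n_chromosomes: int = 12
    chrom_length_bp: int = 2_000_000
    maf_low: float = 0.05
    maf_high: float = 0.5
    het_rate: float = 0.0
    family_size: int = 4
    family_divergence_low: float = 0.014
    family_divergence_high: float = 0.035
    min_family_difference: float = 0.028
    n_derived: int = 20
    mutation_fraction: float = 0.01
    max_derived_difference: float = 0.025
    mutate_to_het: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.mutation_fraction <= 1:
            raise ValidationError("mutation_fraction must be in [0, 1]")
        if self.maf_low > self.maf_high:
            raise ValidationError("maf_low must be <= maf_high")
        if self.n_founders < 2 or self.n_snps < 1:
            raise ValidationError("need n_founders >= 2 and n_snps >= 1")
        if self.family_size < 1:
            raise ValidationError("family_size must be >= 1")


@dataclass
class TruthLabels:
    """Generative ground truth: who derives from whom."""

    table: pd.DataFrame  # variety_id, parent_id, is_derived, n_mutated

    def parent_of(self, variety_id: str) -> Optional[str]:
        row = self.table.loc[self.table["variety_id"] == variety_id]
        if row.empty:
            raise ValidationError(f"unknown variety id: {variety_id}")
        p = row["parent_id"].iat[0]
        return None if pd.isna(p) else str(p)

    def edv_labels(self) -> dict:
        """True for every variety inside a derivation group (a derived line
        or a parent of one), False for unrelated-to-derivation varieties."""
        parents = set(self.table["parent_id"].dropna())
        out = {}
        for _, r in self.table.iterrows():
            out[r["variety_id"]] = bool(r["is_derived"]) or r["variety_id"] in parents
        return out


def _marker_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    chroms = rng.integers(1, config.n_chromosomes + 1, size=config.n_snps)
    pos = rng.integers(1, config.chrom_length_bp + 1, size=config.n_snps)
    # unique (chromosome, position) pairs; redraw collisions
    seen = set(zip(chroms.tolist(), pos.tolist()))
    while len(seen) < config.n_snps:
        c = int(rng.integers(1, config.n_chromosomes + 1))
        p = int(rng.integers(1, config.chrom_length_bp + 1))
        seen.add((c, p))
    pairs = sorted(seen)[: config.n_snps]
    df = pd.DataFrame(
        {
            "chromosome": [f"chr{c:02d}" for c, _ in pairs],
            "position": [p for _, p in pairs],
        }
    )
    df["id"] = [f"snp{i:06d}" for i in range(config.n_snps)]
    df["ref"] = "A"
    df["alt"] = "T"
    df["coding"] = False
    return df[["id", "chromosome", "position", "ref", "alt", "coding"]]


def _flip_hom(row: np.ndarray, cols, rng: np.random.Generator) -> None:
    """Flip the genotypes of one variety row at *cols* to the opposite
    homozygote in place (hets go to a random homozygote)."""
    cur = row[cols]
    new = np.where(cur == 0, 2, np.where(cur == 2, 0, rng.choice([0, 2], size=cur.shape)))
    row[cols] = new.astype(np.int8)


def simulate_founders(config: SimulationConfig) -> GenotypePanel:
    """Draw the founder panel (families of related inbred lines)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 10]))
    markers = _marker_table(config, rng)
    freqs = rng.uniform(config.maf_low, config.maf_high, size=config.n_snps)

    n_families = int(np.ceil(config.n_founders / config.family_size))
    codes = np.empty((config.n_founders, config.n_snps), dtype=np.int8)
    member = 0
    for _fam in range(n_families):
        ancestor = np.where(rng.random(config.n_snps) < freqs, 2, 0).astype(np.int8)
        het = rng.random(config.n_snps) < config.het_rate
        ancestor[het] = 1
        fam_members = min(config.family_size, config.n_founders - member)
        fam_rows = range(member, member + fam_members)
        for i in fam_rows:
            codes[i] = ancestor
            if config.family_size > 1:
                d = rng.uniform(
                    config.family_divergence_low, config.family_divergence_high
                )
                sites = rng.random(config.n_snps) < d
                _flip_hom(codes[i], np.flatnonzero(sites), rng)
        member += fam_members

    if config.family_size > 1:
        _enforce_family_margin(codes, config, rng)

    ids = [f"F{i:04d}" for i in range(config.n_founders)]
    return GenotypePanel(ids, markers, codes)


def _enforce_family_margin(
    codes: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> None:
    """Guarantee every within-family pair differs at >= min_family_difference
    of sites, so no founder pair crosses the EDV threshold genome-wide."""
    need = int(np.ceil(config.min_family_difference * config.n_snps))
    n_families = int(np.ceil(config.n_founders / config.family_size))
    for _pass in range(20):
        fixed_any = False
        member = 0
        for _fam in range(n_families):
            fam_members = min(config.family_size, config.n_founders - member)
            rows = list(range(member, member + fam_members))
            member += fam_members
            for a in range(len(rows)):
                for b in range(a + 1, len(rows)):
                    i, j = rows[a], rows[b]
                    diff = codes[i] != codes[j]
                    short = need - int(diff.sum())
                    if short > 0:
                        agree = np.flatnonzero(~diff)
                        extra = rng.choice(agree, size=short, replace=False)
                        _flip_hom(codes[j], extra, rng)
                        fixed_any = True
        if not fixed_any:
            return
    raise AssertionError("family divergence margin did not stabilise")


def derive_edvs(
    panel: GenotypePanel, config: SimulationConfig
) -> Tuple[GenotypePanel, TruthLabels]:
    """Append derived varieties: parent copies mutated at fraction ``q``.

    Mutated sites flip to the opposite homozygote (or to het when
    ``mutate_to_het``), so on fully homozygous panels the pooled parent-child
    IS is exactly ``1 - realized_mutated_fraction``.  A draw whose realized
    fraction reaches ``max_derived_difference`` is resampled so derived lines
    stay strictly inside the EDV threshold.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    q = config.mutation_fraction
    parents = rng.integers(0, panel.n_varieties, size=config.n_derived)
    rows, truth_rows = [], []
    # the inside-the-threshold margin only applies in the EDV regime;
    # deliberately large q (distant relatives) is passed through unchecked
    enforce = 0 < q < config.max_derived_difference
    max_sites = int(config.max_derived_difference * panel.n_markers)
    for d, pi in enumerate(parents):
        for _try in range(100):
            sites = np.flatnonzero(rng.random(panel.n_markers) < q)
            if not enforce or len(sites) < max_sites or max_sites == 0:
                break
        else:
            raise AssertionError("could not draw a derived line inside the margin")
        child = panel.codes[pi].copy()
        if config.mutate_to_het:
            child[sites] = 1
        else:
            _flip_hom(child, sites, rng)
        pid = panel.variety_ids[pi]
        cid = f"D{d:04d}_{pid}"
        rows.append(child)
        truth_rows.append(
            {
                "variety_id": cid,
                "parent_id": pid,
                "is_derived": True,
                "n_mutated": int(len(sites)),
            }
        )
    founder_rows = [
        {"variety_id": v, "parent_id": None, "is_derived": False, "n_mutated": 0}
        for v in panel.variety_ids
    ]
    truth = TruthLabels(pd.DataFrame(founder_rows + truth_rows))
    all_codes = np.vstack([panel.codes] + [r[np.newaxis, :] for r in rows]) if rows else panel.codes
    all_ids = panel.variety_ids + [r["variety_id"] for r in truth_rows]
    return GenotypePanel(all_ids, panel.markers, all_codes), truth


def simulate_panel(config: SimulationConfig) -> Tuple[GenotypePanel, TruthLabels]:
    """Founders plus derived lines in one call."""
    founders = simulate_founders(config)
    return derive_edvs(founders, config)


def make_panel_split(
    panel: GenotypePanel,
    labels: TruthLabels,
    config: SimulationConfig,
    fraction_internal: float = 0.5,
    n_test: int = 20,
    seed: int = 0,
) -> Tuple[GenotypePanel, GenotypePanel, dict]:
    """Build a train panel and a test panel with known EDV truth.

    *Internal* test varieties are fresh derived lines of randomly chosen
    train varieties (their parent stays in train, so they are truly EDV);
    *external* test varieties are fresh founders, optionally with their own
    derived lines, unrelated to anything in train (truly non-EDV).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 12]))
    n_internal = int(round(fraction_internal * n_test))
    n_external = n_test - n_internal
    q = config.mutation_fraction

    test_rows, test_ids, truth = [], [], {}
    for t in range(n_internal):
        pi = int(rng.integers(0, panel.n_varieties))
        sites = np.flatnonzero(rng.random(panel.n_markers) < q)
        child = panel.codes[pi].copy()
        _flip_hom(child, sites, rng)
        tid = f"T{t:04d}_int"
        test_rows.append(child)
        test_ids.append(tid)
        truth[tid] = True

    if n_external:
        ext_cfg = replace(
            config,
            n_founders=max(2, n_external),
            n_derived=0,
            seed=int(rng.integers(0, 2**31)),
        )
        ext = simulate_founders(ext_cfg)
        # fresh founders use fresh allele draws on the same marker map length
        for t in range(n_external):
            tid = f"T{t:04d}_ext"
            test_rows.append(ext.codes[t])
            test_ids.append(tid)
            truth[tid] = False

    test_panel = GenotypePanel(test_ids, panel.markers, np.vstack(test_rows))
    return panel, test_panel, truth


def fig3_like_fixture() -> GenotypePanel:
    """Deterministic 7-variety x 7-SNP binary-coded panel for worked examples.

    Markers snp1-snp3 carry a 3-bit code unique to each variety (so an
    irreducible resolving subset of size 3 exists, and 3 is the exhaustive
    minimum since two binary markers give at most 4 haplotypes); snp4/snp5
    duplicate snp1/snp2, snp6 is monomorphic and snp7 is a function of
    snp1/snp2 — so many random triples resolve only a strict subset of
    varieties.
    """
    bits = np.array([[(v >> b) & 1 for b in (2, 1, 0)] for v in range(7)])
    c1, c2, c3 = bits[:, 0], bits[:, 1], bits[:, 2]
    cols = [c1, c2, c3, c1, c2, np.zeros(7, dtype=int), (c1 ^ c2)]
    codes = (np.column_stack(cols) * 2).astype(np.int8)
    markers = pd.DataFrame(
        {
            "id": [f"snp{i+1}" for i in range(7)],
            "chromosome": "chr01",
            "position": [100 * (i + 1) for i in range(7)],
            "ref": "A",
            "alt": "T",
            "coding": False,
        }
    )
    return GenotypePanel([f"V{i+1}" for i in range(7)], markers, codes)
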