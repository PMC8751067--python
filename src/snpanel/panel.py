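"""Genotype panels: domain types and I/O.

A :class:`GenotypePanel` is the universal input of the package: a varieties ×
markers matrix of diploid genotype codes with per-marker metadata.  Codes are

====  ==========================
code  meaning
====  ==========================
0     homozygous reference
1     heterozygous
2     homozygous alternate
-1    missing call
====  ==========================

Markers are kept sorted by (chromosome, position, id); all coordinates are
1-based and inclusive (VCF/GFF convention).  BED input is converted from its
0-based half-open convention on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyPanelError, FormatError, UndefinedValueError, ValidationError

logger = logging.getLogger(__name__)

MISSING = -1
VALID_CODES = frozenset({-1, 0, 1, 2})

#: columns of the marker metadata table, in canonical order
MARKER_COLUMNS = ["id", "chromosome", "position", "ref", "alt", "coding"]


@dataclass(frozen=True)
class Marker:
    """A single bi-allelic SNP marker."""

    id: str
    chromosome: str
    position: int
    ref: str = "A"
    alt: str = "T"
    coding: bool = False

    def __post_init__(self):
        if self.position < 1:
            raise ValidationError(f"marker {self.id}: position must be >= 1")
        if self.ref == self.alt:
            raise ValidationError(f"marker {self.id}: ref and alt alleles are equal")


@dataclass(frozen=True)
class RegionSet:
    """Genomic intervals, 1-based inclusive on both ends."""

    intervals: tuple

    def __post_init__(self):
        for chrom, start, end in self.intervals:
            if start > end:
                raise ValidationError(f"region {chrom}:{start}-{end}: start > end")

    @classmethod
    def from_list(cls, intervals: Iterable) -> "RegionSet":
        return cls(tuple((str(c), int(s), int(e)) for c, s, e in intervals))


class GenotypePanel:
    """Varieties × markers matrix of genotype codes with marker metadata.

    Parameters
    ----------
    variety_ids
        Unique variety names, one per matrix row.
    markers
        DataFrame with columns ``id, chromosome, position, ref, alt, coding``
        (or a sequence of :class:`Marker`), one per matrix column.
    codes
        Integer matrix with values in ``{-1, 0, 1, 2}``.

    Markers are re-sorted by (chromosome, position, id) at construction and
    the code columns reordered to match, so panel layout is deterministic
    regardless of input order.
    """

    def __init__(self, variety_ids: Sequence[str], markers, codes):
        self.variety_ids = [str(v) for v in variety_ids]
        if len(set(self.variety_ids)) != len(self.variety_ids):
            dup = sorted({v for v in self.variety_ids if self.variety_ids.count(v) > 1})
            raise ValidationError(f"duplicate variety ids: {dup}")

        if isinstance(markers, pd.DataFrame):
            mdf = markers.copy()
        else:
            mdf = pd.DataFrame(
                [
                    {
                        "id": m.id,
                        "chromosome": m.chromosome,
                        "position": m.position,
                        "ref": m.ref,
                        "alt": m.alt,
                        "coding": m.coding,
                    }
                    for m in markers
                ],
                columns=MARKER_COLUMNS,
            )
        for col, default in (("ref", "A"), ("alt", "T"), ("coding", False)):
            if col not in mdf.columns:
                mdf[col] = default
        mdf = mdf[MARKER_COLUMNS].reset_index(drop=True)
        mdf["id"] = mdf["id"].astype(str)
        mdf["chromosome"] = mdf["chromosome"].astype(str)
        mdf["position"] = mdf["position"].astype(np.int64)
        mdf["coding"] = mdf["coding"].astype(bool)
        if mdf["id"].duplicated().any():
            dup = sorted(mdf.loc[mdf["id"].duplicated(), "id"].unique())
            raise ValidationError(f"duplicate marker ids: {dup}")
        if (mdf["position"] < 1).any():
            raise ValidationError("marker positions must be >= 1")

        codes = np.asarray(codes, dtype=np.int8)
        if codes.ndim != 2 or codes.shape != (len(self.variety_ids), len(mdf)):
            raise ValidationError(
                f"codes shape {codes.shape} does not match "
                f"({len(self.variety_ids)} varieties, {len(mdf)} markers)"
            )
        bad = ~np.isin(codes, [-1, 0, 1, 2])
        if bad.any():
            raise ValidationError(
                f"{int(bad.sum())} genotype codes outside {{-1,0,1,2}}"
            )

        order = mdf.sort_values(["chromosome", "position", "id"], kind="stable").index
        self.markers = mdf.loc[order].reset_index(drop=True)
        self.codes = np.ascontiguousarray(codes[:, np.asarray(order)])
        self._marker_index = {m: i for i, m in enumerate(self.markers["id"])}
        self._variety_index = {v: i for i, v in enumerate(self.variety_ids)}

    # -- basic accessors ---------------------------------------------------

    @property
    def n_varieties(self) -> int:
        return len(self.variety_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def shape(self):
        return self.codes.shape

    @property
    def marker_ids(self) -> list:
        return list(self.markers["id"])

    def marker_indices(self, marker_ids: Iterable[str]) -> np.ndarray:
        """Column indices for the given marker ids (panel order preserved)."""
        idx = []
        for m in marker_ids:
            if m not in self._marker_index:
                raise ValidationError(f"unknown marker id: {m}")
            idx.append(self._marker_index[m])
        return np.array(sorted(idx), dtype=np.intp)

    def variety_index(self, variety_id: str) -> int:
        if variety_id not in self._variety_index:
            raise ValidationError(f"unknown variety id: {variety_id}")
        return self._variety_index[variety_id]

    def subset_markers(self, marker_ids: Iterable[str]) -> "GenotypePanel":
        idx = self.marker_indices(marker_ids)
        return GenotypePanel(
            self.variety_ids, self.markers.iloc[idx], self.codes[:, idx]
        )

    def subset_varieties(self, variety_ids: Iterable[str]) -> "GenotypePanel":
        idx = [self.variety_index(v) for v in variety_ids]
        return GenotypePanel(
            [self.variety_ids[i] for i in idx], self.markers, self.codes[idx]
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenotypePanel)
            and self.variety_ids == other.variety_ids
            and self.markers.equals(other.markers)
            and np.array_equal(self.codes, other.codes)
        )

    def __repr__(self) -> str:
        return f"GenotypePanel({self.n_varieties} varieties x {self.n_markers} markers)"


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(path) -> GenotypePanel:
    """Read a diploid VCF into a panel.

    Only the GT field is consumed; GT 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2,
    ./. -> -1.  Multi-allelic records are skipped with a warning because the
    downstream statistics are defined for bi-allelic SNPs only.
    """
    import cyvcf2

    path = str(path)
    try:
        vcf = cyvcf2.VCF(path)
    except OSError as exc:  # pragma: no cover - cyvcf2 raises on bad paths
        raise FormatError(f"cannot read VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    rows, meta = [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(var.gt_types)
        codes = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        rows.append(codes.astype(np.int8))
        mid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        meta.append(
            {
                "id": mid,
                "chromosome": var.CHROM,
                "position": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0],
                "coding": False,
            }
        )
    vcf.close()
    if n_skipped:
        logger.warning("skipped %d non-bi-allelic VCF records in %s", n_skipped, path)
    if not meta:
        raise EmptyPanelError(f"no bi-allelic SNP records in {path}")
    codes = np.column_stack(rows)
    return GenotypePanel(samples, pd.DataFrame(meta), codes)


_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(panel: GenotypePanel, path) -> None:
    """Write a panel as a minimal VCF 4.2 text file (GT only)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(panel.markers["chromosome"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.variety_ids)
            + "\n"
        )
        for j, m in panel.markers.iterrows():
            gts = "\t".join(_GT_STRING[int(c)] for c in panel.codes[:, j])
            fh.write(
                f"{m['chromosome']}\t{m['position']}\t{m['id']}\t{m['ref']}\t"
                f"{m['alt']}\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# TSV matrix I/O
# ---------------------------------------------------------------------------

def read_matrix_tsv(path, markers_path) -> GenotypePanel:
    """Read a genotype matrix TSV plus its marker-metadata sidecar TSV.

    The matrix has a ``variety_id`` first column and one column per marker id;
    cells are 0/1/2 or NA.  The sidecar has columns
    ``id, chromosome, position, ref, alt[, coding]``.
    """
    path, markers_path = str(path), str(markers_path)
    try:
        mat = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if mat.columns[0] != "variety_id":
        raise FormatError(f"{path}: first column must be 'variety_id'")
    variety_ids = mat["variety_id"].tolist()
    if len(set(variety_ids)) != len(variety_ids):
        raise ValidationError(f"{path}: duplicate variety ids")
    body = mat.drop(columns="variety_id")
    codes = np.full(body.shape, MISSING, dtype=np.int8)
    for j, col in enumerate(body.columns):
        vals = body[col]
        called = vals.notna() & (vals != "NA")
        try:
            codes[called.to_numpy(), j] = vals[called].astype(int).to_numpy()
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer genotype in column {col}") from exc
    meta = pd.read_csv(markers_path, sep="\t", dtype={"id": str, "chromosome": str})
    if "coding" not in meta.columns:
        meta["coding"] = False
    missing_ids = [m for m in body.columns if m not in set(meta["id"])]
    if missing_ids:
        raise FormatError(f"{markers_path}: no metadata for markers {missing_ids[:5]}")
    meta = meta.set_index("id").loc[list(body.columns)].reset_index()
    return GenotypePanel(variety_ids, meta, codes)


def write_matrix_tsv(panel: GenotypePanel, path, markers_path) -> None:
    """Write a panel as matrix + marker-metadata TSVs (round-trips exactly)."""
    body = pd.DataFrame(
        np.where(panel.codes == MISSING, "NA", panel.codes.astype(str)),
        columns=panel.marker_ids,
    )
    body.insert(0, "variety_id", panel.variety_ids)
    body.to_csv(path, sep="\t", index=False)
    panel.markers.to_csv(markers_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------

def read_regions(path, fmt: str | None = None, gff_feature: str = "CDS") -> RegionSet:
    """Read intervals from a BED or GFF3 file.

    BED (0-based half-open) is converted to 1-based inclusive.  For GFF3 only
    rows whose feature type equals *gff_feature* are used.  The format is
    inferred from the suffix when *fmt* is None.
    """
    path = Path(path)
    if fmt is None:
        fmt = "gff" if path.suffix.lower() in {".gff", ".gff3"} else "bed"
    intervals = []
    if fmt == "bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1, 2])
        for chrom, start, end in df.itertuples(index=False):
            intervals.append((str(chrom), int(start) + 1, int(end)))
    elif fmt == "gff":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            usecols=[0, 2, 3, 4], names=["chrom", "feature", "start", "end"],
        )
        df = df[df["feature"] == gff_feature]
        for chrom, _feat, start, end in df.itertuples(index=False):
            intervals.append((str(chrom), int(start), int(end)))
    else:
        raise ValidationError(f"unknown region format: {fmt}")
    return RegionSet.from_list(intervals)


def extract_coding_snps(panel: GenotypePanel, regions: RegionSet) -> GenotypePanel:
    """Subset the panel to markers inside any region (cSNP extraction).

    Both marker positions and region bounds are 1-based inclusive.  Variety
    rows are unchanged; surviving marker codes are copied verbatim.
    """
    by_chrom: dict = {}
    for chrom, start, end in regions.intervals:
        by_chrom.setdefault(chrom, []).append((start, end))
    keep = np.zeros(panel.n_markers, dtype=bool)
    for chrom, ivals in by_chrom.items():
        mask = (panel.markers["chromosome"] == chrom).to_numpy()
        if not mask.any():
            continue
        pos = panel.markers["position"].to_numpy()[mask]
        # merge overlapping intervals, then locate positions by binary search
        ivals = sorted(ivals)
        merged = [list(ivals[0])]
        for s, e in ivals[1:]:
            if s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        starts = np.array([s for s, _ in merged])
        ends = np.array([e for _, e in merged])
        which = np.searchsorted(starts, pos, side="right") - 1
        inside = (which >= 0) & (pos <= ends[np.clip(which, 0, None)])
        keep[np.flatnonzero(mask)] = inside
    if not keep.any():
        logger.warning("extract_coding_snps: no markers fall inside the regions")
    mdf = panel.markers.iloc[keep].copy()
    mdf["coding"] = True
    return GenotypePanel(panel.variety_ids, mdf, panel.codes[:, keep])


def filter_markers(
    panel: GenotypePanel, max_missing: float = 0.2, min_maf: float = 0.01
) -> GenotypePanel:
    """QC filter: keep markers with missing fraction <= *max_missing* and
    minor allele frequency >= *min_maf* (missing cells excluded from counts).
    """
    if not 0 <= max_missing <= 1:
        raise ValidationError("max_missing must be in [0, 1]")
    if not 0 <= min_maf <= 0.5:
        raise ValidationError("min_maf must be in [0, 0.5]")
    from .stats import maf as _maf

    codes = panel.codes
    miss = (codes == MISSING).mean(axis=0)
    mafs = np.empty(panel.n_markers)
    for j in range(panel.n_markers):
        try:
            mafs[j] = _maf(codes[:, j])
        except UndefinedValueError:
            mafs[j] = np.nan
    keep = (miss <= max_missing) & ~np.isnan(mafs) & (mafs >= min_maf)
    if not keep.any():
        logger.warning("filter_markers removed every marker")
    return GenotypePanel(panel.variety_ids, panel.markers.iloc[keep], codes[:, keep])
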