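"""Per-fragment read counts: assignment, the retab dialect, masks, QC.

Aligned 4C-Seq reads are reduced to one integer per 3C fragment — the
number of reads whose 5'-most aligned base falls in that fragment.  The
resulting :class:`CountTable` carries, besides the counts, an ``included``
flag per fragment: the analysis set.  It starts as the mappability flag of
the fragment database and is narrowed by masking (e.g. removing the
viewpoint-proximal zone) or by restriction to a region of interest.
Excluded fragments take no part in either the observed windows or the
permutation shuffle pool, but their rows (and counts) are preserved in the
on-disk "retab" table.

The retab dialect is tab-delimited text with columns
``chrom  start  end  index  mappable  count``, 0-based half-open
coordinates, and ``#`` comment lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam

from .fragment_map import ChromFragments, FragmentMap

__all__ = [
    "AlignedRead",
    "CountTable",
    "MaskRegion",
    "BarcodeDupStats",
    "RetabParseError",
    "assign_reads",
    "read_sam",
    "read_retab",
    "write_retab",
    "read_bed_regions",
    "apply_mask",
    "region_restrict",
    "barcode_duplication_stats",
]


@dataclass(frozen=True)
class AlignedRead:
    """A mapped read reduced to the fields fragment assignment needs."""

    chrom: str
    pos5: int  # 5'-most aligned base, 0-based
    strand: str  # '+' or '-'
    mapq: int = 255
    barcode_pair: Optional[Tuple[str, str]] = None

    def __post_init__(self) -> None:
        if self.pos5 < 0:
            raise ValueError("pos5 must be >= 0")
        if self.mapq < 0:
            raise ValueError("mapq must be >= 0")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class MaskRegion:
    """A genomic interval to mask out (or restrict to), 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"mask region requires start < end, got {self}")


class RetabParseError(ValueError):
    """Malformed retab input; the message names the offending line."""


@dataclass
class CountTable:
    """Per-fragment read counts aligned to a :class:`FragmentMap`.

    ``included`` marks the analysis set (mappable and not masked).  When the
    table was built by :func:`assign_reads`, assigned + unassigned reads
    equal the number of input reads.
    """

    fmap: FragmentMap
    counts: Dict[str, np.ndarray]
    included: Dict[str, np.ndarray]
    replicate: str = "rep1"
    allele: Optional[str] = None
    unassigned_reads: int = 0

    @classmethod
    def zeros(cls, fmap: FragmentMap, replicate: str = "rep1",
              allele: Optional[str] = None) -> "CountTable":
        counts = {c: np.zeros(cf.n, dtype=np.int64) for c, cf in fmap.chroms.items()}
        included = {c: cf.mappable.copy() for c, cf in fmap.chroms.items()}
        return cls(fmap, counts, included, replicate, allele)

    def total_reads(self, chrom: Optional[str] = None) -> int:
        if chrom is not None:
            return int(self.counts[chrom].sum())
        return int(sum(v.sum() for v in self.counts.values()))

    def analysis_counts(self, chrom: str) -> Tuple[np.ndarray, np.ndarray]:
        """Counts of included fragments and their indices in the full map."""
        idx = np.flatnonzero(self.included[chrom])
        return self.counts[chrom][idx], idx

    def copy(self) -> "CountTable":
        return CountTable(
            self.fmap,
            {c: v.copy() for c, v in self.counts.items()},
            {c: v.copy() for c, v in self.included.items()},
            self.replicate, self.allele, self.unassigned_reads,
        )


def read_sam(path: str | Path, barcode_tag: str = "BC") -> Iterator[AlignedRead]:
    """Yield :class:`AlignedRead` from a SAM file.

    ``pos5`` is the reference start for forward-strand alignments and the
    last aligned base for reverse-strand alignments.  If ``barcode_tag`` is
    present and its value contains ``-``, it is split into a (left, right)
    barcode pair.
    """
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.reference_name is None:
                continue
            if aln.is_reverse:
                pos5, strand = aln.reference_end - 1, "-"
            else:
                pos5, strand = aln.reference_start, "+"
            barcode = None
            if aln.has_tag(barcode_tag):
                raw = str(aln.get_tag(barcode_tag))
                left, sep, right = raw.partition("-")
                barcode = (left, right) if sep else (raw, "")
            yield AlignedRead(aln.reference_name, pos5, strand, aln.mapping_quality, barcode)


def _locate(cf: ChromFragments, pos: int) -> int:
    """Index of the fragment containing ``pos``, or -1."""
    i = int(np.searchsorted(cf.starts, pos, side="right")) - 1
    if i < 0 or pos >= cf.ends[i]:
        return -1
    return i


def assign_reads(
    reads: Iterable[AlignedRead],
    fmap: FragmentMap,
    mode: str = "containment",
    boundary_tolerance: int = 4,
    min_mapq: int = 1,
    replicate: str = "rep1",
    allele: Optional[str] = None,
    collapse_barcode_duplicates: bool = False,
) -> CountTable:
    """Count reads per fragment.

    ``containment`` mode assigns a read to the fragment whose interval
    contains its ``pos5``.  ``boundary`` mode additionally requires the read
    to start within ``boundary_tolerance`` bases of the fragment boundary on
    the side matching its strand (5' boundary for '+', 3' boundary for '-'),
    since genuine 4C reads begin at a restriction-site junction.  Reads
    below ``min_mapq``, on unknown chromosomes, or failing the boundary test
    are tallied as unassigned.

    ``collapse_barcode_duplicates`` counts identical (fragment,
    barcode-pair) reads once — repeated amplification of a single ligation
    junction yields identical random barcodes on both read ends; the extra
    copies are tallied as unassigned.  Reads without a barcode pair are
    never collapsed.
    """
    if mode not in ("containment", "boundary"):
        raise ValueError(f"unknown assignment mode {mode!r}")
    if not fmap.chroms:
        raise ValueError("empty fragment map")
    table = CountTable.zeros(fmap, replicate=replicate, allele=allele)
    n_in = 0
    unassigned = 0
    seen: set = set()
    for read in reads:
        n_in += 1
        cf = fmap.chroms.get(read.chrom)
        if cf is None or read.mapq < min_mapq:
            unassigned += 1
            continue
        i = _locate(cf, read.pos5)
        if i < 0:
            unassigned += 1
            continue
        if mode == "boundary":
            if read.strand == "+":
                dist = read.pos5 - int(cf.starts[i])
            else:
                dist = int(cf.ends[i]) - 1 - read.pos5
            if dist > boundary_tolerance:
                unassigned += 1
                continue
        if collapse_barcode_duplicates and read.barcode_pair is not None:
            key = (read.chrom, i, read.barcode_pair)
            if key in seen:
                unassigned += 1
                continue
            seen.add(key)
        table.counts[read.chrom][i] += 1
    table.unassigned_reads = unassigned
    assert table.total_reads() + unassigned == n_in
    return table


def write_retab(table: CountTable, path: str | Path) -> None:
    """Write a CountTable in the retab dialect (all fragments, masked or not)."""
    with open(path, "w") as fh:
        fh.write("# fourc retab; coordinates 0-based half-open\n")
        fh.write("# columns: chrom\tstart\tend\tindex\tmappable\tcount\n")
        fh.write(f"# replicate={table.replicate}\n")
        if table.allele is not None:
            fh.write(f"# allele={table.allele}\n")
        fh.write(f"# unassigned_reads={table.unassigned_reads}\n")
        for chrom, cf in table.fmap.chroms.items():
            counts = table.counts[chrom]
            for i in range(cf.n):
                fh.write(
                    f"{chrom}\t{cf.starts[i]}\t{cf.ends[i]}\t{i}\t"
                    f"{int(cf.mappable[i])}\t{counts[i]}\n"
                )


def read_retab(path: str | Path) -> CountTable:
    """Read a retab file into a CountTable (reconstructing its FragmentMap).

    Malformed lines, negative counts and out-of-order fragments raise
    :class:`RetabParseError` naming the line number.
    """
    replicate, allele, unassigned = "rep1", None, 0
    per_chrom: Dict[str, List[Tuple[int, int, int, int, int]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("replicate="):
                    replicate = body.split("=", 1)[1]
                elif body.startswith("allele="):
                    allele = body.split("=", 1)[1]
                elif body.startswith("unassigned_reads="):
                    unassigned = int(body.split("=", 1)[1])
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise RetabParseError(
                    f"{path}: line {lineno}: expected 6 tab-separated columns, got {len(parts)}"
                )
            chrom = parts[0]
            try:
                start, end, index, mp, count = (int(p) for p in parts[1:])
            except ValueError:
                raise RetabParseError(
                    f"{path}: line {lineno}: non-integer field in {parts[1:]!r}"
                ) from None
            if count < 0:
                raise RetabParseError(f"{path}: line {lineno}: negative count {count}")
            if start >= end:
                raise RetabParseError(f"{path}: line {lineno}: start >= end")
            if mp not in (0, 1):
                raise RetabParseError(f"{path}: line {lineno}: mappable flag must be 0/1")
            rows = per_chrom.setdefault(chrom, [])
            if rows:
                prev_start, prev_end, prev_index = rows[-1][0], rows[-1][1], rows[-1][2]
                if index != prev_index + 1 or start != prev_end:
                    raise RetabParseError(
                        f"{path}: line {lineno}: fragments out of order or non-tiling"
                    )
            elif index != 0 or start != 0:
                raise RetabParseError(
                    f"{path}: line {lineno}: chromosome must start at fragment 0, position 0"
                )
            rows.append((start, end, index, mp, count))
    if not per_chrom:
        raise RetabParseError(f"{path}: no fragment rows found")
    fmap = FragmentMap()
    counts: Dict[str, np.ndarray] = {}
    for chrom, rows in per_chrom.items():
        arr = np.asarray(rows, dtype=np.int64)
        mappable = arr[:, 3].astype(bool)
        fmap.chroms[chrom] = ChromFragments(
            arr[:, 0], arr[:, 1], mappable, mappable.copy(), mappable.copy()
        )
        counts[chrom] = arr[:, 4].copy()
    fmap.validate()
    included = {c: cf.mappable.copy() for c, cf in fmap.chroms.items()}
    return CountTable(fmap, counts, included, replicate, allele, unassigned)


def read_bed_regions(path: str | Path) -> List[MaskRegion]:
    """Read mask/restriction regions from the first three BED columns."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, usecols=[0, 1, 2],
        names=["chrom", "start", "end"], dtype={"chrom": str},
    )
    return [MaskRegion(r.chrom, int(r.start), int(r.end)) for r in df.itertuples()]


def _overlap_flags(cf: ChromFragments, regions: Sequence[MaskRegion], chrom: str) -> np.ndarray:
    flags = np.zeros(cf.n, dtype=bool)
    for reg in regions:
        if reg.chrom != chrom:
            continue
        flags |= (cf.starts < reg.end) & (cf.ends > reg.start)
    return flags


def apply_mask(
    table: CountTable, masks: Sequence[MaskRegion], keep_inside: bool = False
) -> CountTable:
    """Narrow the analysis set by whole-fragment overlap with ``masks``.

    ``keep_inside=False`` (mask-out) excludes every fragment overlapping any
    region; ``keep_inside=True`` (region restriction) retains only
    overlapping fragments.  Counts are untouched — excluded fragments simply
    leave both the observed windows and the shuffle pool.
    """
    out = table.copy()
    for chrom, cf in table.fmap.chroms.items():
        overlap = _overlap_flags(cf, masks, chrom)
        if keep_inside:
            out.included[chrom] &= overlap
        else:
            out.included[chrom] &= ~overlap
    return out


def region_restrict(table: CountTable, regions: Sequence[MaskRegion]) -> CountTable:
    """Restrict the analysis set to fragments overlapping ``regions``."""
    return apply_mask(table, regions, keep_inside=True)


@dataclass
class BarcodeDupStats:
    """Per-fragment PCR-duplication signal from random barcode pairs.

    ``fraction`` maps chromosome -> array with, for every fragment carrying
    at least one barcoded read, the fraction of its reads whose (left,
    right) barcode pair is shared with another read on the same fragment
    (NaN where no barcoded read landed).  Repeated amplification of a single
    ligation junction shows up as fractions near 1.
    """

    fraction: Dict[str, np.ndarray]
    n_reads_without_barcode: int = 0


def barcode_duplication_stats(
    reads: Iterable[AlignedRead], fmap: FragmentMap
) -> BarcodeDupStats:
    """Compute the duplicated-barcode fraction per fragment.

    Reads lacking a barcode pair are excluded and counted in
    ``n_reads_without_barcode``.
    """
    pairs: Dict[Tuple[str, int], Dict[Tuple[str, str], int]] = {}
    missing = 0
    for read in reads:
        if read.barcode_pair is None:
            missing += 1
            continue
        cf = fmap.chroms.get(read.chrom)
        if cf is None:
            continue
        i = _locate(cf, read.pos5)
        if i < 0:
            continue
        frag = pairs.setdefault((read.chrom, i), {})
        frag[read.barcode_pair] = frag.get(read.barcode_pair, 0) + 1
    fraction = {
        c: np.full(cf.n, np.nan) for c, cf in fmap.chroms.items()
    }
    for (chrom, i), tally in pairs.items():
        total = sum(tally.values())
        dup = sum(n for n in tally.values() if n >= 2)
        fraction[chrom][i] = dup / total
    return BarcodeDupStats(fraction, missing)
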