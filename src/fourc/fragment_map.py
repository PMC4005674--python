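"""Restriction-fragment database construction and 4C mappability annotation.

A 4C-Seq experiment resolves chromosomal contacts at the level of 3C
fragments: the intervals between consecutive cut sites of the primary
restriction enzyme used to build the 3C template. This module digests
genome sequences in silico into a chromosome-tiling :class:`FragmentMap`
and flags each fragment's ends as capturable or not under a concrete 4C
library design (secondary trimming enzyme, primer length, size selection).
Fragments that cannot produce a sequenceable, alignable amplicon — e.g.
"blind" fragments lacking an internal secondary-enzyme site — are marked
unmappable and excluded from all downstream statistics, so that the
permutation null model is built over the fragments a read could actually
have landed on.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, NamedTuple, Optional

import numpy as np
from pyfaidx import Fasta

__all__ = [
    "IUPAC_CODES",
    "EnzymeSpec",
    "LibraryDesign",
    "Fragment",
    "ChromFragments",
    "FragmentMap",
    "digest",
    "build_fragment_map",
    "annotate_mappability",
    "read_genome",
    "write_fragments_tsv",
    "read_fragments_tsv",
]

#: IUPAC nucleotide codes and the concrete bases each one matches.  An ``N``
#: in a *recognition site* matches any base; an ``N`` in the *genome* matches
#: nothing (unplaced sequence must not create phantom cut sites).
IUPAC_CODES: Dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class EnzymeConfigError(ValueError):
    """Raised for an invalid restriction-enzyme specification."""


def _reverse_complement(site: str) -> str:
    return site.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction enzyme: IUPAC recognition site plus cut offset.

    ``cut_offset`` is the distance in bases from the start of the recognition
    match to the cut position on the given strand; e.g. HindIII (A^AGCTT) is
    ``EnzymeSpec("HindIII", "AAGCTT", 1)`` and NlaIII (CATG^) is
    ``EnzymeSpec("NlaIII", "CATG", 4)``.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        site = self.recognition.upper()
        object.__setattr__(self, "recognition", site)
        if len(site) < 4:
            raise EnzymeConfigError(
                f"{self.name}: recognition site must be >= 4 bases, got {site!r}"
            )
        bad = set(site) - set(IUPAC_CODES)
        if bad:
            raise EnzymeConfigError(
                f"{self.name}: invalid IUPAC code(s) {sorted(bad)} in {site!r}"
            )
        if not 0 <= self.cut_offset <= len(site):
            raise EnzymeConfigError(
                f"{self.name}: cut_offset {self.cut_offset} outside [0, {len(site)}]"
            )

    @property
    def is_palindromic(self) -> bool:
        return self.recognition == _reverse_complement(self.recognition)


@dataclass(frozen=True)
class LibraryDesign:
    """The 4C library parameters that govern fragment mappability.

    ``primer_length`` is the effective constant added to a fragment-end
    amplicon (primer plus any adapter bases); ``size_min``/``size_max`` are
    the size-selection bounds applied to the sequencing library;
    ``min_map_length`` is the shortest captured stretch that can still be
    aligned uniquely.
    """

    primary_enzyme: EnzymeSpec
    secondary_enzyme: EnzymeSpec
    read_length: int
    primer_length: int
    size_min: int
    size_max: int
    linearization_enzyme: Optional[EnzymeSpec] = None
    min_map_length: int = 20

    def __post_init__(self) -> None:
        if not (0 < self.size_min <= self.size_max):
            raise ValueError("require 0 < size_min <= size_max")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if self.primer_length < 0:
            raise ValueError("primer_length must be >= 0")
        if self.min_map_length <= 0:
            raise ValueError("min_map_length must be positive")


class Fragment(NamedTuple):
    """One 3C fragment with its mappability flags."""

    chrom: str
    start: int
    end: int
    index: int
    mappable: bool
    end5_capturable: bool
    end3_capturable: bool


@dataclass
class ChromFragments:
    """Column-oriented fragments of a single chromosome."""

    starts: np.ndarray
    ends: np.ndarray
    mappable: np.ndarray
    end5: np.ndarray
    end3: np.ndarray
    has_linearization_site: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.mappable = np.asarray(self.mappable, dtype=bool)
        self.end5 = np.asarray(self.end5, dtype=bool)
        self.end3 = np.asarray(self.end3, dtype=bool)

    @property
    def n(self) -> int:
        return self.starts.size

    @property
    def length(self) -> int:
        return int(self.ends[-1]) if self.n else 0


@dataclass
class FragmentMap:
    """Ordered, chromosome-tiling 3C fragment database.

    Fragments on each chromosome tile it exactly: ``fragment[i].end ==
    fragment[i+1].start``, the first start is 0 and the last end is the
    chromosome length. ``validate()`` asserts this invariant.
    """

    chroms: Dict[str, ChromFragments] = field(default_factory=dict)

    def validate(self) -> None:
        for name, cf in self.chroms.items():
            if cf.n == 0:
                raise ValueError(f"{name}: no fragments")
            if cf.starts[0] != 0:
                raise ValueError(f"{name}: first fragment does not start at 0")
            if np.any(cf.starts >= cf.ends):
                raise ValueError(f"{name}: zero/negative-length fragment")
            if np.any(cf.ends[:-1] != cf.starts[1:]):
                raise ValueError(f"{name}: fragments do not tile the chromosome")
            # mappable implies at least one capturable end
            if np.any(cf.mappable & ~(cf.end5 | cf.end3)):
                raise ValueError(f"{name}: mappable fragment with no capturable end")

    def fragments(self, chrom: str) -> Iterator[Fragment]:
        cf = self.chroms[chrom]
        for i in range(cf.n):
            yield Fragment(
                chrom, int(cf.starts[i]), int(cf.ends[i]), i,
                bool(cf.mappable[i]), bool(cf.end5[i]), bool(cf.end3[i]),
            )

    def n_fragments(self, chrom: Optional[str] = None) -> int:
        if chrom is not None:
            return self.chroms[chrom].n
        return sum(cf.n for cf in self.chroms.values())

    def chrom_length(self, chrom: str) -> int:
        return self.chroms[chrom].length


def _site_regex(site: str) -> re.Pattern:
    # lookahead so overlapping matches are all reported
    body = "".join(f"[{IUPAC_CODES[c]}]" for c in site)
    return re.compile(f"(?=({body}))")


def digest(sequence: str, enzyme: EnzymeSpec) -> List[int]:
    """Return the ordered cut positions of ``enzyme`` in ``sequence``.

    Each cut position is ``match_start + cut_offset``.  Palindromic sites are
    matched on the given strand only (equivalent to both strands); a
    non-palindromic site is additionally matched via its reverse complement,
    with the cut offset mapped back to reference coordinates.  ``N`` bases in
    the sequence never match.
    """
    seq = sequence.upper()
    site = enzyme.recognition
    positions = {m.start() + enzyme.cut_offset for m in _site_regex(site).finditer(seq)}
    if not enzyme.is_palindromic:
        rc = _reverse_complement(site)
        # a bottom-strand site at p cuts the reference at p + len - offset
        shift = len(site) - enzyme.cut_offset
        positions.update(m.start() + shift for m in _site_regex(rc).finditer(seq))
    return sorted(positions)


def build_fragment_map(
    genome: Mapping[str, str], primary_enzyme: EnzymeSpec
) -> FragmentMap:
    """Digest ``genome`` with the primary (3C) enzyme into a FragmentMap.

    Fragments are the intervals between consecutive cut positions, plus the
    leading and trailing intervals; empty intervals (cuts at 0, at the
    chromosome end, or coincident cuts) are suppressed.  Mappability flags
    are initialised to True and refined by :func:`annotate_mappability`.
    """
    if not genome:
        raise ValueError("empty genome: no chromosomes to digest")
    fmap = FragmentMap()
    for name in genome.keys():  # dict and pyfaidx.Fasta both expose keys()
        seq = str(genome[name])
        if len(seq) == 0:
            raise ValueError(f"chromosome {name!r} has zero length")
        cuts = digest(seq, primary_enzyme)
        bounds = np.unique(np.concatenate([[0], cuts, [len(seq)]]).astype(np.int64))
        starts, ends = bounds[:-1], bounds[1:]
        keep = starts < ends
        starts, ends = starts[keep], ends[keep]
        n = starts.size
        fmap.chroms[name] = ChromFragments(
            starts, ends,
            np.ones(n, dtype=bool), np.ones(n, dtype=bool), np.ones(n, dtype=bool),
        )
    fmap.validate()
    return fmap


def annotate_mappability(
    fmap: FragmentMap, genome: Mapping[str, str], design: LibraryDesign
) -> FragmentMap:
    """Flag each fragment end as capturable under ``design``.

    For each fragment end, let ``d`` be the distance from that primary-site
    boundary to the nearest secondary-enzyme cut strictly inside the
    fragment.  The end is capturable iff such a cut exists, ``d >=
    min_map_length`` and ``size_min <= d + primer_length <= size_max``.
    A fragment is mappable iff either end is capturable; blind fragments
    (no internal secondary cut) and fragments shorter than
    ``min_map_length`` are unmappable.  Returns a new FragmentMap; the input
    is not modified.
    """
    out = FragmentMap()
    for name, cf in fmap.chroms.items():
        seq = str(genome[name])
        sec = np.asarray(digest(seq, design.secondary_enzyme), dtype=np.int64)
        lin = None
        if design.linearization_enzyme is not None:
            lin = np.asarray(
                digest(seq, design.linearization_enzyme), dtype=np.int64
            )
        n = cf.n
        end5 = np.zeros(n, dtype=bool)
        end3 = np.zeros(n, dtype=bool)
        has_lin = np.zeros(n, dtype=bool) if lin is not None else None
        for i in range(n):
            s, e = int(cf.starts[i]), int(cf.ends[i])
            if e - s < design.min_map_length:
                continue
            lo = np.searchsorted(sec, s, side="right")
            hi = np.searchsorted(sec, e, side="left")
            # cuts strictly inside (s, e)
            internal = sec[lo:hi]
            internal = internal[internal > s]
            if internal.size:
                d5 = int(internal[0]) - s
                d3 = e - int(internal[-1])
                end5[i] = _end_capturable(d5, design)
                end3[i] = _end_capturable(d3, design)
            if has_lin is not None:
                jlo = np.searchsorted(lin, s, side="right")
                jhi = np.searchsorted(lin, e, side="left")
                has_lin[i] = jhi > jlo
        mappable = end5 | end3
        out.chroms[name] = ChromFragments(
            cf.starts.copy(), cf.ends.copy(), mappable, end5, end3, has_lin
        )
    out.validate()
    return out


def _end_capturable(d: int, design: LibraryDesign) -> bool:
    if d < design.min_map_length:
        return False
    amplicon = d + design.primer_length
    return design.size_min <= amplicon <= design.size_max


def read_genome(path: str | Path) -> Mapping[str, str]:
    """Open a (multi-)FASTA file; record IDs are chromosome names verbatim."""
    return Fasta(str(path), as_raw=True, sequence_always_upper=True)


def write_fragments_tsv(fmap: FragmentMap, path: str | Path, header_note: str = "") -> None:
    """Write the fragment database as tab-delimited text (the retab template).

    Columns: chrom, start, end, index, mappable(0/1), end5(0/1), end3(0/1);
    coordinates 0-based half-open; '#' lines are comments.
    """
    with open(path, "w") as fh:
        fh.write("# fourc fragment database; coordinates 0-based half-open\n")
        fh.write("# columns: chrom\tstart\tend\tindex\tmappable\tend5\tend3\n")
        if header_note:
            fh.write(f"# {header_note}\n")
        for chrom, cf in fmap.chroms.items():
            for i in range(cf.n):
                fh.write(
                    f"{chrom}\t{cf.starts[i]}\t{cf.ends[i]}\t{i}\t"
                    f"{int(cf.mappable[i])}\t{int(cf.end5[i])}\t{int(cf.end3[i])}\n"
                )


def read_fragments_tsv(path: str | Path) -> FragmentMap:
    """Read a fragment database written by :func:`write_fragments_tsv`."""
    rows: Dict[str, List[tuple]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 7:
                raise ValueError(f"{path}: line {lineno}: expected 7 columns, got {len(parts)}")
            try:
                chrom = parts[0]
                start, end, index = int(parts[1]), int(parts[2]), int(parts[3])
                mp, e5, e3 = int(parts[4]), int(parts[5]), int(parts[6])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            rows.setdefault(chrom, []).append((start, end, index, mp, e5, e3))
    fmap = FragmentMap()
    for chrom, rec in rows.items():
        rec.sort(key=lambda r: r[2])
        arr = np.asarray(rec, dtype=np.int64)
        fmap.chroms[chrom] = ChromFragments(
            arr[:, 0], arr[:, 1],
            arr[:, 3].astype(bool), arr[:, 4].astype(bool), arr[:, 5].astype(bool),
        )
    fmap.validate()
    return fmap
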