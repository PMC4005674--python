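"""Merging significant windows into interactions and prioritizing them.

Runs of contiguous significant windows are merged into one interaction,
then zero-read fragments are trimmed from both ends of the merged span.
Each member window is graded by how much its significance depends on its
single most abundant fragment:

* **Broad** (category 1) — still significant with the top fragment's reads
  removed entirely.  A genuine, frequent contact spreads reads over the
  neighboring fragments (the chromatin fiber around the contact point is
  also captured), so Broad calls are the ones most likely to replicate.
* **Intermediate** (category 2) — significant when the top fragment is
  replaced by the average of its in-window neighbors.
* **Narrow** (category 3) — significant only with all reads included; the
  signature of a single-fragment spike (and of every call at window size
  1, which has no neighbors to fall back on).

An interaction takes the broadest (numerically smallest) category among
its member windows, and replicate intersections retain the broadest
category seen for each shared fragment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .count_table import CountTable
from .fragment_map import FragmentMap
from .sigcall import WindowVector

__all__ = [
    "Category",
    "Interaction",
    "IntersectionResult",
    "categorize_window",
    "categorize_interaction",
    "merge_significant_windows",
    "call_interactions",
    "interactions_to_callset",
    "intersect_replicates",
    "write_interactions_bed",
    "read_interactions_bed",
    "write_bedgraph",
]


class Category(IntEnum):
    """Interaction priority; Broad (1) outranks Narrow (3)."""

    BROAD = 1
    INTERMEDIATE = 2
    NARROW = 3

    @property
    def label(self) -> str:
        return self.name.capitalize()

    @classmethod
    def from_label(cls, label: str) -> "Category":
        return cls[label.upper()]


def categorize_window(counts: Sequence[int], threshold: int) -> Category:
    """Grade one significant window by its dependence on the top fragment.

    ``counts`` are the window's per-fragment reads (length W); the window
    must already be significant (sum >= threshold).  Ties for the most
    abundant fragment resolve to the leftmost position — the Broad test is
    tie-invariant, only the Intermediate neighbor set can differ.  The
    neighbor replacement value is the real-valued mean of the 1 or 2
    in-window flanking fragments (0 if W = 1).
    """
    counts = np.asarray(counts, dtype=np.int64)
    S = int(counts.sum())
    if S < threshold:
        raise ValueError(
            f"window sum {S} below threshold {threshold}: window is not significant"
        )
    m_pos = int(np.argmax(counts))  # leftmost maximum
    m = int(counts[m_pos])
    if S - m >= threshold:
        return Category.BROAD
    neighbors = [counts[i] for i in (m_pos - 1, m_pos + 1) if 0 <= i < counts.size]
    replacement = float(np.mean(neighbors)) if neighbors else 0.0
    if S - m + replacement >= threshold:
        return Category.INTERMEDIATE
    return Category.NARROW


def categorize_interaction(categories: Iterable[Category]) -> Category:
    """The broadest (minimum-valued) designation among member windows."""
    cats = list(categories)
    if not cats:
        raise ValueError("interaction must contain at least one window")
    return Category(min(cats))


@dataclass
class Interaction:
    """A maximal run of merged significant windows, end-trimmed.

    ``frag_ordinals`` are mappable-fragment ordinals (contiguous);
    ``frag_index`` the corresponding positions in the chromosome's full
    fragment list; the genomic span runs from the start of the first
    retained fragment to the end of the last (0-based half-open).
    """

    chrom: str
    start: int
    end: int
    frag_ordinals: Tuple[int, int]  # inclusive range after trimming
    frag_index: np.ndarray
    windows: Tuple[int, int]  # inclusive range of member window indices
    total_reads: int
    category: Category
    threshold: int

    @property
    def n_windows(self) -> int:
        return self.windows[1] - self.windows[0] + 1


def _consecutive_runs(indices: np.ndarray) -> List[Tuple[int, int]]:
    if indices.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(indices) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [indices.size - 1]])
    return [(int(indices[a]), int(indices[b])) for a, b in zip(starts, ends)]


def merge_significant_windows(
    sig_windows: np.ndarray,
    observed: WindowVector,
    counts: np.ndarray,
    fmap: FragmentMap,
    chrom: str,
    threshold: int,
) -> List[Interaction]:
    """Merge contiguous significant windows into end-trimmed interactions.

    Two significant windows merge iff their fragment ranges overlap or abut,
    i.e. their window indices are consecutive.  Each interaction's fragment
    range is the union of its member windows' ranges; fragments without
    reads are then stripped from the 5' and 3' ends (interior zeros are
    kept).  ``counts`` are the analysis-set counts the windows were built
    from; ``observed.frag_index`` maps them into the full fragment list.
    """
    sig_windows = np.asarray(sig_windows, dtype=np.int64)
    if observed.frag_index is None:
        raise ValueError("observed WindowVector lacks frag_index mapping")
    W = observed.window
    cf = fmap.chroms[chrom]
    out: List[Interaction] = []
    for w_first, w_last in _consecutive_runs(np.sort(sig_windows)):
        a, b = w_first, w_last + W - 1  # mappable-ordinal range
        # trim zero-count fragments from both ends
        while a <= b and counts[a] == 0:
            a += 1
        while b >= a and counts[b] == 0:
            b -= 1
        if a > b:  # cannot happen for a significant window with T >= 1
            continue
        member_cats = [
            categorize_window(counts[w: w + W], threshold)
            for w in range(w_first, w_last + 1)
        ]
        fidx = observed.frag_index[a: b + 1]
        out.append(
            Interaction(
                chrom=chrom,
                start=int(cf.starts[fidx[0]]),
                end=int(cf.ends[fidx[-1]]),
                frag_ordinals=(a, b),
                frag_index=np.asarray(fidx),
                windows=(w_first, w_last),
                total_reads=int(counts[a: b + 1].sum()),
                category=categorize_interaction(member_cats),
                threshold=threshold,
            )
        )
    return out


def call_interactions(
    table: CountTable,
    chrom: str,
    observed: WindowVector,
    threshold: int,
) -> List[Interaction]:
    """Convenience: significant windows -> merged, categorized interactions."""
    from .sigcall import call_windows

    counts, _ = table.analysis_counts(chrom)
    sig = call_windows(observed, threshold)
    return merge_significant_windows(sig, observed, counts, table.fmap, chrom, threshold)


def interactions_to_callset(
    interactions: Iterable[Interaction], fmap: FragmentMap
) -> Dict[Tuple[str, int, int], Category]:
    """Per-fragment call set: (chrom, start, end) -> interaction category.

    Fragments shared by two interactions (impossible for maximal merges on
    one chromosome, but possible across runs) keep the broadest category.
    """
    calls: Dict[Tuple[str, int, int], Category] = {}
    for itx in interactions:
        cf = fmap.chroms[itx.chrom]
        for i in itx.frag_index:
            key = (itx.chrom, int(cf.starts[i]), int(cf.ends[i]))
            prev = calls.get(key)
            calls[key] = itx.category if prev is None else Category(min(prev, itx.category))
    return calls


@dataclass
class IntersectionResult:
    """Replicate intersection with broadest-category retention."""

    shared: Dict[Tuple[str, int, int], Category]
    per_replicate_categories: Dict[Tuple[str, int, int], List[Category]]
    unique: List[Dict[Tuple[str, int, int], Category]]
    pairwise_overlap: np.ndarray  # [i, j] = |set_i & set_j|


def intersect_replicates(
    callsets: Sequence[Mapping[Tuple[str, int, int], Category]],
) -> IntersectionResult:
    """Fragments called in every replicate, keeping the broadest category.

    Requires >= 2 replicate call sets on a shared fragment map (keys are
    exact fragment coordinates).  Also reports per-replicate unique
    fragments and the pairwise overlap count matrix.
    """
    if len(callsets) < 2:
        raise ValueError("replicate intersection requires at least 2 call sets")
    keysets = [set(cs) for cs in callsets]
    shared_keys = set.intersection(*keysets)
    shared = {
        k: Category(min(cs[k] for cs in callsets)) for k in sorted(shared_keys)
    }
    per_rep = {k: [Category(cs[k]) for cs in callsets] for k in sorted(shared_keys)}
    union_others = [
        set.union(*(keysets[j] for j in range(len(keysets)) if j != i))
        for i in range(len(keysets))
    ]
    unique = [
        {k: Category(callsets[i][k]) for k in sorted(keysets[i] - union_others[i])}
        for i in range(len(callsets))
    ]
    n = len(callsets)
    pairwise = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(n):
            pairwise[i, j] = len(keysets[i] & keysets[j])
    return IntersectionResult(shared, per_rep, unique, pairwise)


def write_interactions_bed(
    interactions: Sequence[Interaction], path: str | Path, header_note: str = ""
) -> None:
    """Write interactions as BED6+3 (0-based half-open).

    Extra columns: category number, member window count, threshold used.
    The score column is the read total capped at 1000 (BED convention).
    """
    with open(path, "w") as fh:
        fh.write("# fourc interactions; BED6+3; coordinates 0-based half-open\n")
        fh.write("# extra columns: category_number\tn_windows\tthreshold\n")
        if header_note:
            fh.write(f"# {header_note}\n")
        for n, itx in enumerate(interactions, start=1):
            fh.write(
                f"{itx.chrom}\t{itx.start}\t{itx.end}\t"
                f"INT{n}:{itx.category.label}\t{min(1000, itx.total_reads)}\t.\t"
                f"{int(itx.category)}\t{itx.n_windows}\t{itx.threshold}\n"
            )


def read_interactions_bed(path: str | Path) -> List[Tuple[str, int, int, Category]]:
    """Read back the (chrom, start, end, category) columns of a BED6+3 file."""
    out: List[Tuple[str, int, int, Category]] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            cat = Category(int(parts[6]))
            out.append((parts[0], int(parts[1]), int(parts[2]), cat))
    return out


def write_bedgraph(table: CountTable, path: str | Path, name: str = "fourc counts") -> None:
    """Emit per-fragment counts as bedGraph for genome-browser display."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{name}"\n')
        for chrom, cf in table.fmap.chroms.items():
            counts = table.counts[chrom]
            for i in range(cf.n):
                if counts[i]:
                    fh.write(f"{chrom}\t{cf.starts[i]}\t{cf.ends[i]}\t{counts[i]}\n")
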