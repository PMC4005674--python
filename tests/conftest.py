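"""Shared fixtures: toy fragment maps and count tables built in memory."""

from __future__ import annotations

import numpy as np
import pytest

from fourc.count_table import CountTable
from fourc.fragment_map import ChromFragments, FragmentMap


def uniform_fragment_map(
    n: int, length: int = 100, chrom: str = "chr1", mappable=None
) -> FragmentMap:
    """A tiling map of ``n`` equal-length fragments."""
    starts = np.arange(n, dtype=np.int64) * length
    ends = starts + length
    if mappable is None:
        mappable = np.ones(n, dtype=bool)
    else:
        mappable = np.asarray(mappable, dtype=bool)
    fmap = FragmentMap(
        {chrom: ChromFragments(starts, ends, mappable, mappable.copy(), mappable.copy())}
    )
    fmap.validate()
    return fmap


def table_from_counts(counts, chrom: str = "chr1", mappable=None, **kw) -> CountTable:
    """CountTable over a uniform map with the given per-fragment counts."""
    counts = np.asarray(counts, dtype=np.int64)
    fmap = uniform_fragment_map(counts.size, chrom=chrom, mappable=mappable)
    table = CountTable.zeros(fmap, **kw)
    table.counts[chrom] = counts.copy()
    return table


@pytest.fixture
def toy_map() -> FragmentMap:
    """Fragments [0,3), [3,11), [11,18) on one chromosome."""
    starts = np.array([0, 3, 11])
    ends = np.array([3, 11, 18])
    m = np.ones(3, dtype=bool)
    fmap = FragmentMap({"chr1": ChromFragments(starts, ends, m, m.copy(), m.copy())})
    fmap.validate()
    return fmap


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20140220)
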