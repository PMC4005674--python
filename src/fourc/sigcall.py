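"""Permutation-based significance thresholds for 4C window counts.

The null hypothesis is exchangeability: absent specific contacts, the
reads on a chromosome could equally well have landed on any mappable
fragment.  For a window size ``W`` (in fragments) the observed per-window
sums are compared against sums from shuffled counts.  Each permutation
``p`` yields a cutoff ``X_p``, the smallest reads-per-window value whose
empirical false discovery rate

    FDR(c) = |{shuffled window sums >= c}| / |{observed window sums >= c}|

falls below the user's target ``alpha`` (0 when the denominator is 0).
The final per-chromosome threshold ``T`` is an order statistic of the
``X_p`` distribution — the smallest cutoff within the top ``k`` percent —
so a single extreme permutation cannot drag the threshold around, unlike
a comparator mode that averages the shuffled tail counts over all
permutations before solving for one cutoff (``pooled_mean``).

All randomness flows through per-(seed, chromosome, permutation) RNG
streams, so results are bit-reproducible and independent of the order in
which chromosomes are processed.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .count_table import CountTable, MaskRegion, apply_mask

__all__ = [
    "ThresholdConfig",
    "WindowVector",
    "ThresholdResult",
    "window_sums",
    "shuffle_counts",
    "fdr_cutoff",
    "compute_threshold",
    "call_windows",
    "permutation_rng",
]


@dataclass(frozen=True)
class ThresholdConfig:
    """Parameters of the threshold engine.

    ``window`` is in fragments; ``fdr_target`` is the desired empirical FDR
    per permutation; ``top_percentile`` selects the slice of the X
    distribution the final threshold is drawn from (5 -> the smallest X
    among the top 5%).  At least 1000 permutations are recommended for
    stable thresholds; smaller values are fine for exploration.
    """

    window: int = 5
    fdr_target: float = 0.01
    n_permutations: int = 1000
    top_percentile: float = 5.0
    mode: str = "percentile"  # or "pooled_mean"
    shuffle_unit: str = "vector"  # or "read"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1 fragment")
        if not 0.0 < self.fdr_target < 1.0:
            raise ValueError("fdr_target must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0.0 < self.top_percentile <= 100.0:
            raise ValueError("top_percentile must be in (0, 100]")
        if self.mode not in ("percentile", "pooled_mean"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if self.shuffle_unit not in ("vector", "read"):
            raise ValueError(f"unknown shuffle unit {self.shuffle_unit!r}")


@dataclass
class WindowVector:
    """Sliding-window sums over the mappable-fragment counts of one chromosome.

    Window ``i`` covers mappable ordinals ``i .. i+W-1``; ``frag_index``
    (optional) maps mappable ordinals back to positions in the full
    fragment list of the chromosome.
    """

    sums: np.ndarray
    window: int
    frag_index: Optional[np.ndarray] = None

    @property
    def n_windows(self) -> int:
        return self.sums.size

    def window_range(self, i: int) -> Tuple[int, int]:
        """(first, last) mappable-fragment ordinal covered by window ``i``."""
        return i, i + self.window - 1


def window_sums(
    counts: np.ndarray, window: int, frag_index: Optional[np.ndarray] = None
) -> WindowVector:
    """Sum each run of ``window`` consecutive mappable-fragment counts.

    ``counts`` must already be restricted to the analysis set (mappable,
    unmasked) — windows slide over that sequence with step 1.  If fewer
    than ``window`` fragments are available the vector is empty (with a
    warning).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    counts = np.asarray(counts, dtype=np.int64)
    if counts.size < window:
        warnings.warn(
            f"window of {window} fragments exceeds the {counts.size} available; "
            "no windows formed",
            stacklevel=2,
        )
        return WindowVector(np.empty(0, dtype=np.int64), window, frag_index)
    cs = np.concatenate([[0], np.cumsum(counts)])
    return WindowVector(cs[window:] - cs[:-window], window, frag_index)


def shuffle_counts(counts: np.ndarray, rng: np.random.Generator,
                   unit: str = "vector") -> np.ndarray:
    """Randomize counts across fragments under the exchangeable null.

    ``vector`` (default): a uniformly random permutation of the count
    vector — the multiset of per-fragment counts is preserved exactly,
    which keeps the spiky, overdispersed marginal of real 4C data.
    ``read``: each of the ``sum(counts)`` reads is re-placed independently
    and uniformly on a fragment (sum preserved, multiset not).
    """
    counts = np.asarray(counts, dtype=np.int64)
    if unit == "vector":
        return rng.permutation(counts)
    if unit == "read":
        total = int(counts.sum())
        return np.bincount(
            rng.integers(0, counts.size, size=total), minlength=counts.size
        ).astype(np.int64)
    raise ValueError(f"unknown shuffle unit {unit!r}")


def _tail_count(sorted_vals: np.ndarray, c) -> np.ndarray:
    """|{v >= c}| for sorted ``sorted_vals``; ``c`` may be an array."""
    return sorted_vals.size - np.searchsorted(sorted_vals, c, side="left")


def _candidate_cutoffs(*vecs: np.ndarray) -> np.ndarray:
    """Cutoffs where the empirical FDR can change: 1 and v+1 for observed values.

    Between consecutive attained values both tail counts are constant, so
    the minimal cutoff satisfying FDR < alpha is always of this form.
    """
    vals = np.unique(np.concatenate([np.asarray(v, dtype=np.int64) for v in vecs]))
    cands = np.unique(np.concatenate([[1], vals + 1]))
    return cands[cands >= 1]


def fdr_cutoff(observed, shuffled, alpha: float) -> int:
    """Smallest integer cutoff whose empirical FDR is below ``alpha``.

    FDR(c) = |shuffled >= c| / |observed >= c|, taken as 0 when no observed
    window reaches c.  A valid cutoff always exists (at one past the
    largest shuffled sum the numerator is 0); the result is an integer
    >= 1.  Empty inputs yield the vacuous cutoff 1 with a warning.
    """
    observed = np.sort(np.asarray(observed, dtype=np.int64))
    shuffled = np.sort(np.asarray(shuffled, dtype=np.int64))
    if observed.size == 0 or shuffled.size == 0:
        warnings.warn("empty window vector: vacuous cutoff X = 1", stacklevel=2)
        return 1
    cands = _candidate_cutoffs(observed, shuffled)
    obs_tail = _tail_count(observed, cands)
    shuf_tail = _tail_count(shuffled, cands)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(obs_tail > 0, shuf_tail / np.maximum(obs_tail, 1), 0.0)
    ok = fdr < alpha
    # guaranteed non-empty: the last candidate exceeds max(shuffled)
    return int(cands[np.argmax(ok)])


def permutation_rng(seed: int, chrom: str, permutation: int) -> np.random.Generator:
    """Deterministic RNG stream for (seed, chromosome, permutation index).

    Streams are independent of the order in which chromosomes or
    permutations are evaluated, so runs are reproducible and
    parallelizable.
    """
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(chrom.encode()), permutation])
    )


@dataclass
class ThresholdResult:
    """Per-chromosome threshold and the X distribution behind it."""

    chrom: str
    threshold: int
    x_distribution: np.ndarray
    config: ThresholdConfig
    n_mappable: int
    total_reads: int
    max_observed_window: int
    n_windows: int

    def summary(self) -> Dict[str, object]:
        xs = np.sort(self.x_distribution)
        return {
            "chrom": self.chrom,
            "threshold": int(self.threshold),
            "mode": self.config.mode,
            "fdr": self.config.fdr_target,
            "window": self.config.window,
            "permutations": self.config.n_permutations,
            "top_percentile": self.config.top_percentile,
            "seed": self.config.seed,
            "shuffle_unit": self.config.shuffle_unit,
            "n_mappable_fragments": self.n_mappable,
            "total_reads": self.total_reads,
            "max_observed_window": self.max_observed_window,
            "x_min": int(xs[0]),
            "x_median": float(np.median(xs)),
            "x_max": int(xs[-1]),
        }


def percentile_rank(n_permutations: int, top_percentile: float) -> int:
    """1-based ascending rank of the smallest X inside the top k percent."""
    r = n_permutations - math.floor(n_permutations * top_percentile / 100.0) + 1
    return min(max(r, 1), n_permutations)


def compute_threshold(
    table: CountTable,
    chrom: str,
    config: ThresholdConfig,
    masks: Optional[Sequence[MaskRegion]] = None,
    keep_inside: bool = False,
) -> ThresholdResult:
    """Derive the significance threshold ``T`` for one chromosome.

    Masks (if given) are applied first; counts are then restricted to the
    analysis set.  In ``percentile`` mode each of the P permutations yields
    an ``X_p`` (shuffle -> window sums -> :func:`fdr_cutoff`) and ``T`` is
    the smallest X within the top ``top_percentile`` percent of the sorted
    distribution.  In ``pooled_mean`` mode the shuffled tail counts are
    averaged over permutations first and a single cutoff solved for — the
    comparator strategy, more sensitive to extreme permutations.
    """
    if masks:
        table = apply_mask(table, masks, keep_inside=keep_inside)
    counts, frag_index = table.analysis_counts(chrom)
    if counts.size == 0:
        raise ValueError(
            f"chromosome {chrom!r}: no mappable fragments remain after masking"
        )
    observed = window_sums(counts, config.window, frag_index)
    P = config.n_permutations
    xs = np.empty(P, dtype=np.int64)
    obs_sorted = np.sort(observed.sums)
    shuffled_all: List[np.ndarray] = []
    for p in range(P):
        rng = permutation_rng(config.seed, chrom, p)
        perm = shuffle_counts(counts, rng, unit=config.shuffle_unit)
        shuf = window_sums(perm, config.window)
        xs[p] = fdr_cutoff(observed.sums, shuf.sums, config.fdr_target)
        if config.mode == "pooled_mean":
            shuffled_all.append(shuf.sums)
    if config.mode == "percentile":
        xs_sorted = np.sort(xs)
        T = int(xs_sorted[percentile_rank(P, config.top_percentile) - 1])
    else:
        pooled = np.sort(np.concatenate(shuffled_all)) if shuffled_all else np.empty(0, np.int64)
        if obs_sorted.size == 0 or pooled.size == 0:
            T = 1
        else:
            cands = _candidate_cutoffs(obs_sorted, pooled)
            obs_tail = _tail_count(obs_sorted, cands)
            mean_shuf_tail = _tail_count(pooled, cands) / P
            with np.errstate(divide="ignore", invalid="ignore"):
                fdr = np.where(obs_tail > 0, mean_shuf_tail / np.maximum(obs_tail, 1), 0.0)
            T = int(cands[np.argmax(fdr < config.fdr_target)])
    return ThresholdResult(
        chrom=chrom,
        threshold=max(T, 1),
        x_distribution=xs,
        config=config,
        n_mappable=int(counts.size),
        total_reads=int(counts.sum()),
        max_observed_window=int(obs_sorted[-1]) if obs_sorted.size else 0,
        n_windows=int(observed.n_windows),
    )


def call_windows(observed: WindowVector, threshold: int) -> np.ndarray:
    """Indices of significant windows: sum >= threshold (inclusive).

    Inclusive because the threshold is defined as the minimum number of
    reads a window needs to be significant.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    return np.flatnonzero(observed.sums >= threshold)
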