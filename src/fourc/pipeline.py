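"""End-to-end runs with atomic, reproducible artifacts.

Each ``run_*`` function performs one pipeline stage (digest, counts,
call, intersect, simulate), logging to standard error and writing its
outputs atomically (temp file + rename) so an interrupted run never
leaves a truncated artifact.  Every artifact header echoes the
configuration and seed that produced it; a rerun with an identical
configuration produces byte-identical files.
"""

from __future__ import annotations

import json
import logging
import os
import sys
import tempfile
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import __version__
from .count_table import (
    CountTable,
    MaskRegion,
    apply_mask,
    assign_reads,
    read_bed_regions,
    read_retab,
    read_sam,
    write_retab,
)
from .fragment_map import (
    EnzymeSpec,
    LibraryDesign,
    annotate_mappability,
    build_fragment_map,
    read_fragments_tsv,
    read_genome,
    write_fragments_tsv,
)
from .peaks import (
    Category,
    Interaction,
    call_interactions,
    interactions_to_callset,
    intersect_replicates,
    read_interactions_bed,
    write_bedgraph,
    write_interactions_bed,
)
from .sigcall import ThresholdConfig, call_windows, compute_threshold, window_sums
from .simdata import PlantedPeak, SimConfig, simulate_dataset

logger = logging.getLogger("fourc")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

__all__ = [
    "atomic_write_text",
    "parse_region",
    "run_digest",
    "run_counts",
    "run_call",
    "run_intersect",
    "run_simulate",
]


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write ``text`` to ``path`` atomically (temp file in same dir + rename)."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or Path("."), prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _atomic(path: Path, writer) -> None:
    """Run ``writer(tmp_path)`` then rename the result into place."""
    fd, tmp = tempfile.mkstemp(dir=path.parent or Path("."), prefix=path.name, suffix=".tmp")
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_config_file(path: str | Path) -> Dict[str, str]:
    """Read a plain-text ``key=value`` configuration file.

    Blank lines and '#' comments are ignored.  Values are returned as
    strings; the CLI applies them as defaults, with explicit flags winning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    out: Dict[str, str] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}: line {lineno}: expected key=value, got {line!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def parse_region(text: str) -> MaskRegion:
    """Parse ``chrom:start-end`` (0-based half-open) into a MaskRegion."""
    try:
        chrom, span = text.rsplit(":", 1)
        start, end = (int(x.replace(",", "")) for x in span.split("-"))
    except ValueError:
        raise ValueError(f"cannot parse region {text!r}; expected chrom:start-end") from None
    return MaskRegion(chrom, start, end)


def run_digest(
    genome_path: str | Path,
    design: LibraryDesign,
    out_path: str | Path,
) -> None:
    """Digest a genome FASTA and write the annotated fragment database."""
    genome_path = Path(genome_path)
    if not genome_path.exists():
        raise FileNotFoundError(f"genome FASTA not found: {genome_path}")
    genome = read_genome(genome_path)
    fmap = build_fragment_map(genome, design.primary_enzyme)
    fmap = annotate_mappability(fmap, genome, design)
    note = (
        f"primary={design.primary_enzyme.recognition}/{design.primary_enzyme.cut_offset} "
        f"secondary={design.secondary_enzyme.recognition}/{design.secondary_enzyme.cut_offset} "
        f"read_length={design.read_length} primer_length={design.primer_length} "
        f"size={design.size_min}-{design.size_max} min_map_length={design.min_map_length}"
    )
    _atomic(Path(out_path), lambda tmp: write_fragments_tsv(fmap, tmp, header_note=note))
    n_map = sum(int(cf.mappable.sum()) for cf in fmap.chroms.values())
    logger.info(
        "digest: %d fragments (%d mappable) -> %s", fmap.n_fragments(), n_map, out_path
    )


def run_counts(
    sam_path: str | Path,
    frags_path: str | Path,
    out_path: str | Path,
    mode: str = "containment",
    boundary_tolerance: int = 4,
    min_mapq: int = 1,
    replicate: str = "rep1",
    collapse_barcode_duplicates: bool = False,
) -> None:
    """Assign SAM alignments to fragments and write a retab count table."""
    for p in (sam_path, frags_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"input not found: {p}")
    fmap = read_fragments_tsv(frags_path)
    table = assign_reads(
        read_sam(sam_path), fmap, mode=mode,
        boundary_tolerance=boundary_tolerance, min_mapq=min_mapq, replicate=replicate,
        collapse_barcode_duplicates=collapse_barcode_duplicates,
    )
    _atomic(Path(out_path), lambda tmp: write_retab(table, tmp))
    logger.info(
        "counts: %d assigned, %d unassigned -> %s",
        table.total_reads(), table.unassigned_reads, out_path,
    )


def run_call(
    retab_path: str | Path,
    config: ThresholdConfig,
    out_prefix: str | Path,
    masks: Optional[Sequence[MaskRegion]] = None,
    region: Optional[MaskRegion] = None,
    emit_bedgraph: bool = False,
) -> Dict[str, dict]:
    """Thresholds + interactions for every chromosome of a retab table.

    Writes ``<prefix>.thresholds.json`` and ``<prefix>.interactions.bed``
    (and optionally ``<prefix>.bedgraph``); returns the per-chromosome
    threshold summaries.  ``masks`` excludes regions; ``region`` restricts
    the analysis to one span (mutually exclusive with masks).
    """
    retab_path = Path(retab_path)
    if not retab_path.exists():
        raise FileNotFoundError(f"retab file not found: {retab_path}")
    if masks and region:
        raise ValueError("masks and region restriction are mutually exclusive")
    table = read_retab(retab_path)
    if masks:
        table = apply_mask(table, masks, keep_inside=False)
    elif region:
        table = apply_mask(table, [region], keep_inside=True)
    summaries: Dict[str, dict] = {}
    interactions: List[Interaction] = []
    for chrom in table.fmap.chroms:
        counts, frag_index = table.analysis_counts(chrom)
        if counts.size == 0 or counts.size < config.window:
            logger.warning("call: %s has too few analysis fragments; skipped", chrom)
            continue
        res = compute_threshold(table, chrom, config)
        observed = window_sums(counts, config.window, frag_index)
        chrom_itx = call_interactions(table, chrom, observed, res.threshold)
        interactions.extend(chrom_itx)
        summaries[chrom] = res.summary()
        logger.info(
            "call: %s threshold=%d interactions=%d (seed=%d)",
            chrom, res.threshold, len(chrom_itx), config.seed,
        )
    prefix = str(out_prefix)
    payload = {
        "tool": f"fourc {__version__}",
        "config": {
            "window": config.window,
            "fdr": config.fdr_target,
            "permutations": config.n_permutations,
            "top_percentile": config.top_percentile,
            "mode": config.mode,
            "shuffle_unit": config.shuffle_unit,
            "seed": config.seed,
            "input": retab_path.name,
            "masks": [[m.chrom, m.start, m.end] for m in (masks or [])],
            "region": [region.chrom, region.start, region.end] if region else None,
        },
        "chromosomes": summaries,
        "interactions_per_category": {
            cat.label: sum(1 for i in interactions if i.category == cat)
            for cat in Category
        },
    }
    atomic_write_text(
        prefix + ".thresholds.json",
        json.dumps(payload, indent=2, sort_keys=True) + "\n",
    )
    note = (
        f"seed={config.seed} window={config.window} fdr={config.fdr_target} "
        f"permutations={config.n_permutations} top_percentile={config.top_percentile} "
        f"mode={config.mode}"
    )
    _atomic(
        Path(prefix + ".interactions.bed"),
        lambda tmp: write_interactions_bed(interactions, tmp, header_note=note),
    )
    if emit_bedgraph:
        _atomic(Path(prefix + ".bedgraph"), lambda tmp: write_bedgraph(table, tmp))
    return summaries


def run_intersect(
    bed_paths: Sequence[str | Path],
    out_path: str | Path,
    frags_path: Optional[str | Path] = None,
) -> None:
    """Intersect replicate interaction BEDs, retaining the broadest category.

    With ``frags_path`` (the shared fragment database) each interaction span
    is expanded onto its member mappable fragments first, so replicates are
    compared at fragment resolution — congruent coordinates even when merged
    spans differ.  Without it, spans are intersected as exact intervals.
    Output columns: chrom, start, end, retained category label, and the
    per-replicate category labels.
    """
    for p in bed_paths:
        if not Path(p).exists():
            raise FileNotFoundError(f"interaction BED not found: {p}")
    fmap = None
    if frags_path is not None:
        if not Path(frags_path).exists():
            raise FileNotFoundError(f"fragment database not found: {frags_path}")
        fmap = read_fragments_tsv(frags_path)
    callsets = []
    for p in bed_paths:
        calls: Dict[Tuple[str, int, int], Category] = {}
        for c, s, e, cat in read_interactions_bed(p):
            if fmap is None:
                key = (c, s, e)
                calls[key] = min(calls.get(key, cat), cat)
                continue
            cf = fmap.chroms[c]
            lo = int(np.searchsorted(cf.ends, s, side="right"))
            hi = int(np.searchsorted(cf.starts, e, side="left"))
            for i in range(lo, hi):
                if not cf.mappable[i]:
                    continue
                key = (c, int(cf.starts[i]), int(cf.ends[i]))
                calls[key] = min(calls.get(key, cat), cat)
        callsets.append(calls)
    result = intersect_replicates(callsets)
    lines = ["# fourc replicate intersection; coordinates 0-based half-open",
             "# columns: chrom\tstart\tend\tcategory_retained\tper_replicate"]
    for key in sorted(result.shared):
        reps = ",".join(c.label for c in result.per_replicate_categories[key])
        lines.append(f"{key[0]}\t{key[1]}\t{key[2]}\t{result.shared[key].label}\t{reps}")
    atomic_write_text(out_path, "\n".join(lines) + "\n")
    logger.info(
        "intersect: %d shared intervals across %d replicates -> %s",
        len(result.shared), len(bed_paths), out_path,
    )


def run_simulate(
    config: SimConfig,
    out_frags: str | Path,
    out_retab: str | Path,
) -> None:
    """Generate a synthetic fragment map + count table and write both."""
    fmap, table = simulate_dataset(config)
    note = (
        f"simulated seed={config.seed} n_fragments={config.n_fragments} "
        f"mu={config.mu} dispersion={config.dispersion}"
    )
    _atomic(Path(out_frags), lambda tmp: write_fragments_tsv(fmap, tmp, header_note=note))
    _atomic(Path(out_retab), lambda tmp: write_retab(table, tmp))
    logger.info(
        "simulate: %d fragments, %d reads (seed=%d) -> %s, %s",
        config.n_fragments, table.total_reads(), config.seed, out_frags, out_retab,
    )
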