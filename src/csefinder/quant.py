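"""Exon read counting, FPKM normalization, and percentile ranks.

Counting follows htseq union semantics with ``-a 0 -s no --nonunique all``:
every alignment record is kept regardless of mapping quality, strand is
ignored, and a read overlapping k exons (e.g. a junction-spanning read)
increments all k.  Each alignment of a multi-mapped read counts.

FPKM uses the read length in place of the exon length for exons shorter
than the read, which prevents junction double-counting from inflating
short exons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree
from scipy.stats import rankdata

from .models import GeneModelSet

log = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    """Integer exon x sample counts plus per-sample library sizes."""

    values: pd.DataFrame  # exon_id x sample_id, int
    library_sizes: pd.Series  # per sample

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.library_sizes < 0).any():
            raise ValueError("library sizes must be non-negative")


def _exon_trees(models: GeneModelSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for exon in models.exons.values():
        trees.setdefault(exon.chrom, IntervalTree()).addi(exon.start, exon.end, exon.exon_id)
    return trees


def count_sample(
    path: str | Path,
    models: GeneModelSet,
    min_overlap_bp: int = 1,
    library_mode: str = "exonic",
) -> tuple[pd.Series, int]:
    """Count one sample's SAM file.

    Returns (per-exon counts, library size).  ``library_mode='exonic'``
    counts alignments overlapping >=1 exon (the quantity the counter
    sees); ``'mapped'`` counts all mapped alignment records.
    """
    trees = _exon_trees(models)
    exon_ids = sorted(models.exons)
    counts = {e: 0 for e in exon_ids}
    n_mapped = 0
    n_exonic = 0
    n_skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            try:
                if rec.is_unmapped:
                    continue
                blocks = rec.get_blocks()
            except (ValueError, AttributeError):
                n_skipped += 1
                continue
            n_mapped += 1
            tree = trees.get(rec.reference_name)
            if tree is None:
                continue
            hit: set[str] = set()
            for start, end in blocks:
                for iv in tree.overlap(start, end):
                    if min(end, iv.end) - max(start, iv.begin) >= min_overlap_bp:
                        hit.add(iv.data)
            if hit:
                n_exonic += 1
                for e in hit:
                    counts[e] += 1
    if n_skipped:
        log.warning("skipped %d malformed records (%d counted)", n_skipped, n_mapped)
    library = n_exonic if library_mode == "exonic" else n_mapped
    return pd.Series(counts, name="count").loc[exon_ids], library


def count_reads(
    alignments: Mapping[str, str | Path] | str | Path,
    models: GeneModelSet,
    min_overlap_bp: int = 1,
    library_mode: str = "exonic",
) -> CountMatrix:
    """Count alignments for one or many samples into a CountMatrix."""
    if isinstance(alignments, (str, Path)):
        alignments = {"sample": alignments}
    cols = {}
    libs = {}
    for sample, path in alignments.items():
        cols[sample], libs[sample] = count_sample(
            path, models, min_overlap_bp=min_overlap_bp, library_mode=library_mode
        )
    values = pd.DataFrame(cols)
    values.index.name = "exon_id"
    return CountMatrix(values=values, library_sizes=pd.Series(libs))


def fpkm(
    counts: CountMatrix,
    exon_lengths: pd.Series,
    read_length: int,
) -> pd.DataFrame:
    """FPKM with the short-exon rule.

    FPKM(e, s) = count * 1e9 / (max(exon_length, read_length) * library_size).
    A zero-count cell is 0 regardless of lengths; a zero library size with
    nonzero counts is an error.
    """
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    missing = counts.values.index.difference(exon_lengths.index)
    if len(missing):
        raise ValueError(f"missing exon lengths for {list(missing)[:5]}")
    lengths = exon_lengths.loc[counts.values.index].astype(float)
    if (lengths <= 0).any():
        raise ValueError("exon lengths must be positive")
    eff = np.maximum(lengths.values, float(read_length))

    out = np.zeros(counts.values.shape, dtype=float)
    for j, sample in enumerate(counts.values.columns):
        lib = float(counts.library_sizes[sample])
        col = counts.values.iloc[:, j].to_numpy(dtype=float)
        if lib == 0:
            if (col > 0).any():
                raise ValueError(f"sample {sample}: zero library size with nonzero counts")
            continue
        out[:, j] = col * 1e9 / (eff * lib)
    return pd.DataFrame(out, index=counts.values.index, columns=counts.values.columns)


def percentile_ranks(
    expr: pd.DataFrame,
    sample_subset: list[str] | None = None,
) -> pd.DataFrame:
    """Per-exon mid-rank percentiles, (rank - 0.5) / N, over a sample subset.

    Ties share the mid-rank; every row's mean is exactly 0.5 and all
    values lie strictly inside (0, 1).
    """
    sub = expr if sample_subset is None else expr[list(sample_subset)]
    n = sub.shape[1]
    if n < 2:
        raise ValueError("percentile ranks need >= 2 samples")
    ranks = rankdata(sub.to_numpy(), axis=1, method="average")
    return pd.DataFrame((ranks - 0.5) / n, index=sub.index, columns=sub.columns)
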