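"""AS-exon versus gene-level classification and the splice-variant check.

A target gene is an AS (alternatively spliced) target when some annotated
transcript carries < 40% of the gene's CSE exonic length (so the CSE
signal is isoform-restricted) and at least one CSE exon shows cassette
behavior (present in >= 1 and absent from >= 1 transcript).  Otherwise
specificity reflects whole-gene over-expression.  When a gene has several
AS exons the most differential one (highest composite Z) represents it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

from .models import GeneModelSet

AS_COVERAGE_THRESHOLD = 0.40


def transcript_cse_coverage(
    gene_id: str,
    cse_exons: list[str],
    models: GeneModelSet,
) -> dict[str, float]:
    """Fraction of each transcript's exonic length covered by CSE exons."""
    gene_exons = {e.exon_id for e in models.exons_of_gene(gene_id)}
    bad = set(cse_exons) - gene_exons
    if bad:
        raise ValueError(f"CSE exons not in gene {gene_id}: {sorted(bad)}")
    cse = set(cse_exons)
    out = {}
    for tx, exon_ids in sorted(models.transcripts_of_gene(gene_id).items()):
        total = sum(models.exons[e].length for e in exon_ids)
        covered = sum(models.exons[e].length for e in exon_ids if e in cse)
        out[tx] = covered / total if total else 0.0
    return out


def classify_target(
    gene_id: str,
    cse_exons: list[str],
    models: GeneModelSet,
    coverage_threshold: float = AS_COVERAGE_THRESHOLD,
) -> tuple[str, dict[str, float]]:
    """Return ('AS' | 'gene_level', per-transcript coverages).

    AS requires both a transcript with coverage strictly below the
    threshold and a differentially included (cassette) CSE exon.
    """
    coverages = transcript_cse_coverage(gene_id, sorted(set(cse_exons)), models)
    low_cov = any(c < coverage_threshold for c in coverages.values())
    cassette = set(models.cassette_exons(gene_id))
    has_cassette_cse = bool(cassette & set(cse_exons))
    return ("AS" if (low_cov and has_cassette_cse) else "gene_level"), coverages


def pick_top_as(
    gene_id: str,
    as_exons: list[str],
    composites: pd.Series,
    models: GeneModelSet,
) -> str:
    """The AS exon with maximal composite Z; ties break to the lower
    genomic start coordinate."""
    if not as_exons:
        raise ValueError("no AS exons to choose from")
    return min(as_exons, key=lambda e: (-float(composites[e]), models.exons[e].start))


def near_splice_variants(
    variants: pd.DataFrame,
    exon_id: str,
    models: GeneModelSet,
    window: int = 10,
) -> set[str]:
    """Samples with a variant within +/-window bp (inclusive) of either
    exon boundary; positions are 1-based."""
    exon = models.exons[exon_id]
    if len(variants) == 0:
        return set()
    boundaries = (exon.start + 1, exon.end)
    sub = variants[variants["chrom"] == exon.chrom]
    near = sub[
        (abs(sub["pos"] - boundaries[0]) <= window) | (abs(sub["pos"] - boundaries[1]) <= window)
    ]
    return set(near["sample_id"])


def splice_variant_test(
    carriers: set[str],
    expr_row: pd.Series,
    samples: pd.DataFrame,
    min_group: int = 2,
) -> dict:
    """One-sided Welch t-test: do carriers express the AS exon higher?

    Restricted to tumor samples with median-or-higher expression of the
    exon.  Returns p-value and group means, or an 'insufficient' result
    when either group has fewer than ``min_group`` eligible samples.
    """
    tumor_cols = [s for s in samples.index[samples["cohort"] == "tumor"] if s in expr_row.index]
    vals = expr_row[tumor_cols]
    eligible = vals[vals >= vals.median()].index
    car = [s for s in eligible if s in carriers]
    non = [s for s in eligible if s not in carriers]
    if len(car) < min_group or len(non) < min_group:
        return {"status": "insufficient", "n_carriers": len(car), "n_noncarriers": len(non)}
    res = ttest_ind(expr_row[car], expr_row[non], equal_var=False, alternative="greater")
    return {
        "status": "ok",
        "p": float(res.pvalue),
        "carrier_mean": float(np.mean(expr_row[car])),
        "noncarrier_mean": float(np.mean(expr_row[non])),
        "n_carriers": len(car),
        "n_noncarriers": len(non),
    }


def classify_all(
    kept: pd.DataFrame,
    models: GeneModelSet,
    variants: pd.DataFrame | None = None,
    expr: pd.DataFrame | None = None,
    samples: pd.DataFrame | None = None,
    window: int = 10,
) -> pd.DataFrame:
    """Classify every gene in a surviving-candidate table.

    ``kept`` needs columns exon_id, gene_id, composite_z.  Returns one
    row per gene: class, chosen exon (AS only), minimal transcript
    coverage, and the splice-variant p-value when variants are supplied.
    """
    rows = []
    for gene_id, sub in kept.groupby("gene_id"):
        exons = sorted(set(sub["exon_id"]))
        comp = sub.groupby("exon_id")["composite_z"].max()
        cls, coverages = classify_target(gene_id, exons, models)
        chosen = None
        variant_p = None
        if cls == "AS":
            cassette = set(models.cassette_exons(gene_id))
            as_exons = sorted(cassette & set(exons))
            chosen = pick_top_as(gene_id, as_exons, comp, models)
            if variants is not None and expr is not None and samples is not None:
                carriers = near_splice_variants(variants, chosen, models, window=window)
                res = splice_variant_test(carriers, expr.loc[chosen], samples)
                variant_p = res.get("p")
        rows.append({
            "gene_id": gene_id,
            "target_class": cls,
            "chosen_exon": chosen,
            "coverage_min": min(coverages.values()),
            "n_cse_exons": len(exons),
            "variant_p": variant_p,
        })
    return pd.DataFrame(
        rows,
        columns=["gene_id", "target_class", "chosen_exon", "coverage_min",
                 "n_cse_exons", "variant_p"],
    ).sort_values("gene_id").reset_index(drop=True)
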