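"""CSE candidacy thresholds and surfaceome/matrisome/blacklist filters.

A candidate exon must have composite Z > z* (default 1), above-median
expression in at least one tumor type of its compartment, and at most
``max_normals`` (default 5) normal tissues expressed above the median.
"Above median" is evaluated in per-exon percentile-rank space: a group is
flagged when the median rank of its samples strictly exceeds 0.5.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .models import AnnotationSet, GeneModelSet

log = logging.getLogger(__name__)


def above_median_flags(
    ranks: pd.DataFrame,
    samples: pd.DataFrame,
    groups: list[str] | None = None,
) -> pd.DataFrame:
    """Per-exon boolean flags, one column per group: median rank > 0.5."""
    if groups is None:
        groups = sorted(samples.loc[ranks.columns.intersection(samples.index), "group"].unique())
    flags = {}
    for g in groups:
        cols = [s for s in samples.index[samples["group"] == g] if s in ranks.columns]
        if not cols:
            raise KeyError(f"group {g!r} has no samples in the rank matrix")
        flags[g] = np.median(ranks[cols].to_numpy(), axis=1) > 0.5
    return pd.DataFrame(flags, index=ranks.index)


def select_cse(
    composites: pd.DataFrame,
    flags: pd.DataFrame,
    samples: pd.DataFrame,
    models: GeneModelSet,
    z_star: float = 1.0,
    max_normals: int = 5,
) -> pd.DataFrame:
    """Apply the three candidacy rules for one compartment.

    Returns a table (exon_id, gene_id, compartment, composite_z,
    supporting_groups, n_normals_above) of surviving exons.
    """
    tumor_groups = sorted(
        set(samples.loc[samples["cohort"] == "tumor", "group"]) & set(flags.columns)
    )
    tissues = sorted(
        set(samples.loc[samples["cohort"] == "normal", "group"]) & set(flags.columns)
    )
    comp = composites.set_index("exon_id")
    gene_of = models.exon_gene_map()

    rows = []
    for exon_id in comp.index:
        cz = comp.at[exon_id, "composite_z"]
        if not cz > z_star:
            continue
        supp = [g for g in tumor_groups if flags.at[exon_id, g]]
        if not supp:
            continue
        n_norm = int(sum(bool(flags.at[exon_id, t]) for t in tissues))
        if n_norm > max_normals:
            continue
        rows.append({
            "exon_id": exon_id,
            "gene_id": gene_of[exon_id],
            "compartment": comp.at[exon_id, "compartment"],
            "composite_z": float(cz),
            "supporting_groups": ",".join(supp),
            "n_normals_above": n_norm,
        })
    return pd.DataFrame(
        rows,
        columns=["exon_id", "gene_id", "compartment", "composite_z",
                 "supporting_groups", "n_normals_above"],
    )


def filter_surfaceome_matrisome(
    candidates: pd.DataFrame,
    annotations: AnnotationSet,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep exons of surfaceome/matrisome genes; hard-drop blacklisted genes.

    Returns (kept table with a ``localization`` column, dropped table with
    a ``drop_reason`` column).  Genes absent from every annotation table
    are dropped as "unannotated".
    """
    kept_rows = []
    dropped_rows = []
    blacklisted = annotations.blacklisted
    for _, row in candidates.iterrows():
        gene = row["gene_id"]
        if gene in blacklisted:
            cats = sorted(c for c, gs in annotations.blacklist.items() if gene in gs)
            dropped_rows.append({**row, "drop_reason": f"blacklist:{','.join(cats)}"})
            continue
        loc = annotations.localization(gene)
        if loc is None:
            dropped_rows.append({**row, "drop_reason": "unannotated"})
            log.info("gene %s not in surfaceome/matrisome annotations", gene)
            continue
        kept_rows.append({**row, "localization": loc})
    kept = pd.DataFrame(kept_rows, columns=list(candidates.columns) + ["localization"])
    dropped = pd.DataFrame(dropped_rows, columns=list(candidates.columns) + ["drop_reason"])
    return kept, dropped
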