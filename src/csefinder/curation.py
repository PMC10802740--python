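"""Curation checks on candidate exons.

Four checks: cross-resource validation of tumor expression, tumor
proteomics verification, removal of brain candidates with high normal
brain expression, and the exon-position (3') bias check against the
normal cohort.  Each check is a pure function of its declared inputs and
returns an evidence value alongside the verdict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .models import GeneModelSet

PASS, FAIL, NA = "pass", "fail", "not_applicable"


@dataclass
class CheckResult:
    status: str  # pass | fail | not_applicable
    evidence: object = None

    @property
    def ok(self) -> bool:
        return self.status != FAIL


def cross_resource_check(
    exon_id: str,
    supporting_groups: list[str],
    ranks: pd.DataFrame,
    samples: pd.DataFrame,
) -> CheckResult:
    """Every data source profiling a supporting tumor type must agree.

    For each supporting type with >=2 sources, the exon must be
    above-median (median rank > 0.5) within every source's samples of
    that type.  Single-source types pass vacuously.
    """
    evidence = {}
    ok = True
    for g in supporting_groups:
        g_samples = samples[(samples["group"] == g) & (samples.index.isin(ranks.columns))]
        sources = sorted(g_samples["data_source"].unique())
        if len(sources) < 2:
            continue
        for src in sources:
            cols = list(g_samples.index[g_samples["data_source"] == src])
            med = float(np.median(ranks.loc[exon_id, cols]))
            evidence[f"{g}/{src}"] = round(med, 4)
            if not med > 0.5:
                ok = False
    if not evidence:
        return CheckResult(NA, evidence)
    return CheckResult(PASS if ok else FAIL, evidence)


def tumor_proteomics_verify(
    gene_id: str,
    proteomics: pd.DataFrame,
    min_psm: int = 1,
) -> CheckResult:
    """Require >= min_psm peptide-spectral matches within the gene (tumor panel)."""
    sub = proteomics[(proteomics["panel"] == "tumor") & (proteomics["gene_id"] == gene_id)]
    total = int(sub["psm"].sum()) if len(sub) else 0
    if len(sub) == 0:
        return CheckResult(FAIL, {"psm": 0, "note": "no-coverage"})
    return CheckResult(PASS if total >= min_psm else FAIL, {"psm": total})


def brain_normal_filter(
    exon_id: str,
    ranks: pd.DataFrame,
    samples: pd.DataFrame,
    is_brain_candidate: bool,
    brain_tissue: str = "Brain",
    high_rank: float = 0.75,
) -> CheckResult:
    """Remove brain-compartment candidates highly expressed in normal brain.

    "High" is a median percentile rank at or above the 3rd quartile
    (>= 0.75) among the compartment's samples.
    """
    if not is_brain_candidate:
        return CheckResult(NA)
    cols = [s for s in samples.index[samples["group"] == brain_tissue] if s in ranks.columns]
    if not cols:
        return CheckResult(NA, {"note": "no normal-brain samples"})
    med = float(np.median(ranks.loc[exon_id, cols]))
    return CheckResult(FAIL if med >= high_rank else PASS, {"brain_median_rank": round(med, 4)})


def exon_position_bias(
    gene_id: str,
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    models: GeneModelSet,
    alpha: float = 0.01,
) -> CheckResult:
    """Detect 3'-coverage bias: Pearson correlation of mean normal
    expression with the exon's transcription-direction index.

    Removes the gene iff p < alpha and r > 0 (positional inflation toward
    the 3' end).  Genes with < 3 exons, or with constant normal means,
    are not applicable.
    """
    recs = models.exons_of_gene(gene_id)
    if len(recs) < 3:
        return CheckResult(NA, {"note": "<3 exons"})
    normal_cols = [s for s in samples.index[samples["cohort"] == "normal"] if s in expr.columns]
    means = np.array([float(expr.loc[r.exon_id, normal_cols].mean()) for r in recs])
    idx = np.array([r.index_in_gene for r in recs], dtype=float)
    if np.allclose(means, means[0]):
        return CheckResult(PASS, {"r": 0.0, "p": 1.0, "note": "constant means"})
    r, p = pearsonr(idx, means)
    remove = (p < alpha) and (r > 0)
    return CheckResult(FAIL if remove else PASS, {"r": round(float(r), 4), "p": float(p)})


def run_curation(
    candidates: pd.DataFrame,
    expr: pd.DataFrame,
    ranks_by_compartment: dict[str, pd.DataFrame],
    samples: pd.DataFrame,
    models: GeneModelSet,
    proteomics: pd.DataFrame,
    min_psm: int = 1,
    bias_alpha: float = 0.01,
    brain_q: float = 0.75,
    bias_scope: str = "brain",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply all curation checks to a candidate table.

    Returns (kept candidates, QC report with one row per exon x check).
    The bias check applies to brain-compartment candidates by default
    (``bias_scope='all'`` extends it to every candidate).
    """
    report_rows = []
    keep_mask = []
    bias_cache: dict[str, CheckResult] = {}
    psm_cache: dict[str, CheckResult] = {}

    for _, row in candidates.iterrows():
        exon_id, gene_id, comp = row["exon_id"], row["gene_id"], row["compartment"]
        ranks = ranks_by_compartment[comp]
        supporting = row["supporting_groups"].split(",") if row["supporting_groups"] else []
        checks: dict[str, CheckResult] = {}

        checks["cross_resource"] = cross_resource_check(exon_id, supporting, ranks, samples)
        if gene_id not in psm_cache:
            psm_cache[gene_id] = tumor_proteomics_verify(gene_id, proteomics, min_psm=min_psm)
        checks["tumor_proteomics"] = psm_cache[gene_id]
        checks["brain_normal"] = brain_normal_filter(
            exon_id, ranks, samples, is_brain_candidate=(comp == "brain"), high_rank=brain_q
        )
        if bias_scope == "all" or comp == "brain":
            if gene_id not in bias_cache:
                bias_cache[gene_id] = exon_position_bias(
                    gene_id, expr, samples, models, alpha=bias_alpha
                )
            checks["exon_position_bias"] = bias_cache[gene_id]
        else:
            checks["exon_position_bias"] = CheckResult(NA, {"note": "out of scope"})

        keep = all(c.ok for c in checks.values())
        keep_mask.append(keep)
        for name, res in checks.items():
            report_rows.append({
                "exon_id": exon_id,
                "gene_id": gene_id,
                "compartment": comp,
                "check": name,
                "status": res.status,
                "evidence": repr(res.evidence),
                "final_keep": keep,
            })

    report = pd.DataFrame(
        report_rows,
        columns=["exon_id", "gene_id", "compartment", "check", "status", "evidence", "final_keep"],
    )
    kept = candidates.loc[keep_mask].reset_index(drop=True) if len(candidates) else candidates
    return kept, report
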