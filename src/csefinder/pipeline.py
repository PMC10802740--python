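"""End-to-end orchestration: rank → differential → select → annotate →
curate → classify → tier → score/export, with a stage ledger and
deterministic reruns.

The pipeline operates on an in-memory :class:`PipelineData` bundle that
can be produced by the synthetic generator or loaded from files; the CLI
is a thin wrapper.  Classification runs before tiering because the
bone-marrow check applies only to gene-level targets.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as classify_mod
from . import curation, scoring, selection, tiering
from .diffexp import compartment_samples, run_differential
from .models import AnnotationSet, GeneModelSet, GroundTruth
from .quant import percentile_ranks
from .rng import subseed
from .synthetic import (
    CohortConfig,
    GeneModelConfig,
    generate_annotations,
    generate_cohort,
    generate_gene_models,
    generate_proteomics,
    generate_variants,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """All thresholds, defaulting to the published constants."""

    z_star: float = 1.0
    max_normals: int = 5
    coverage: float = 0.40
    bias_alpha: float = 0.01
    fpkm_floor: float = 1.0
    rank_high: float = 0.75
    window: int = 10
    min_psm: int = 1
    bias_scope: str = "brain"
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.coverage <= 1):
            raise ValueError("coverage threshold must be in (0, 1]")
        if self.max_normals < 0 or self.window < 0 or self.min_psm < 0:
            raise ValueError("max_normals, window, min_psm must be non-negative")
        if not (0 < self.bias_alpha < 1) or not (0 < self.rank_high < 1):
            raise ValueError("bias_alpha and rank_high must be in (0, 1)")


@dataclass
class PipelineData:
    models: GeneModelSet
    expr: pd.DataFrame  # exon x sample FPKM
    samples: pd.DataFrame
    annotations: AnnotationSet
    proteomics: pd.DataFrame
    calibration: pd.DataFrame  # gene_id, bm_expressed
    variants: pd.DataFrame | None = None
    truth: GroundTruth | None = None


@dataclass
class StageLedger:
    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, n_in: int, n_out: int, drops: dict[str, int] | None = None) -> None:
        drops = drops or {}
        if n_in - n_out != sum(drops.values()):
            drops = dict(drops)
            drops["other"] = n_in - n_out - sum(drops.values())
        self.stages.append({"stage": stage, "n_in": int(n_in), "n_out": int(n_out),
                            "drops": {k: int(v) for k, v in drops.items()}})

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.stages, indent=1) + "\n")


@dataclass
class PipelineResult:
    targets: pd.DataFrame  # one row per surviving gene target
    cse_exons: pd.DataFrame  # surviving exon-level table
    candidates: pd.DataFrame
    qc_report: pd.DataFrame
    pairs: pd.DataFrame
    composites: pd.DataFrame
    scores: pd.DataFrame
    type_table: pd.DataFrame
    ledger: StageLedger
    npsm_cutoff: float
    npsm_cutoff_fallback: bool


def simulate_scenario(
    seed: int = 0,
    model_config: GeneModelConfig | None = None,
    cohort_config: CohortConfig | None = None,
    carrier_fraction: float = 0.1,
) -> PipelineData:
    """Generate the default synthetic study: gene models, cohort with
    planted targets and confounders, annotations, proteomics, variants,
    and bone-marrow calibration genes."""
    models = generate_gene_models(model_config, seed=seed)
    expr, samples, truth = generate_cohort(models, cohort_config, seed=seed)
    annotations, _ = generate_annotations(models, truth, seed=seed)
    proteomics = generate_proteomics(models, truth, seed=seed)
    variants, _ = generate_variants(models, truth, samples, seed=seed,
                                    carrier_fraction=carrier_fraction)
    bm_pos = set(truth.bm_expressed_genes)
    calibration = pd.DataFrame({
        "gene_id": sorted(truth.null_genes),
        "bm_expressed": [1 if g in bm_pos else 0 for g in sorted(truth.null_genes)],
    })
    return PipelineData(
        models=models, expr=expr, samples=samples, annotations=annotations,
        proteomics=proteomics, calibration=calibration, variants=variants, truth=truth,
    )


def _gene_bm_expression(data: PipelineData) -> pd.Series:
    """Gene-level bone-marrow expression: median over bone-marrow samples
    of the mean FPKM across the gene's exons."""
    bm_cols = [s for s in data.samples.index
               if data.samples.at[s, "group"] == "Bone_Marrow" and s in data.expr.columns]
    if not bm_cols:
        return pd.Series(dtype=float)
    out = {}
    for gid in sorted(data.models.genes):
        exon_ids = [e.exon_id for e in data.models.exons_of_gene(gid)]
        out[gid] = float(data.expr.loc[exon_ids, bm_cols].mean(axis=0).median())
    return pd.Series(out)


def run_pipeline(
    data: PipelineData,
    params: PipelineParams | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute every stage; optionally write the full output bundle."""
    params = params or PipelineParams()
    params.validate()
    ledger = StageLedger()
    compartments = sorted(
        data.samples.loc[data.samples["cohort"] == "tumor", "compartment"].unique()
    )
    n_exons = len(data.expr)

    # stage 1-2: ranks and differential statistics per compartment
    ranks_by_comp: dict[str, pd.DataFrame] = {}
    all_pairs, all_comps, all_cands = [], [], []
    for comp in compartments:
        cols = compartment_samples(data.samples, comp)
        ranks = percentile_ranks(data.expr, cols)
        ranks_by_comp[comp] = ranks
        pairs, comps = run_differential(data.expr, data.samples, comp, ranks=ranks)
        all_pairs.append(pairs)
        all_comps.append(comps)
        flags = selection.above_median_flags(ranks, data.samples)
        cands = selection.select_cse(
            comps, flags, data.samples, data.models,
            z_star=params.z_star, max_normals=params.max_normals,
        )
        all_cands.append(cands)
    pairs = pd.concat(all_pairs, ignore_index=True)
    composites = pd.concat(all_comps, ignore_index=True)
    candidates = pd.concat(all_cands, ignore_index=True).sort_values(
        ["exon_id", "compartment"]).reset_index(drop=True)
    ledger.record("select_cse", n_exons * len(compartments), len(candidates),
                  {"below_threshold": n_exons * len(compartments) - len(candidates)})

    # stage 3: surfaceome/matrisome intersection and blacklist
    annotated, dropped = selection.filter_surfaceome_matrisome(candidates, data.annotations)
    drop_counts = dropped["drop_reason"].str.split(":").str[0].value_counts().to_dict() \
        if len(dropped) else {}
    ledger.record("annotation_filter", len(candidates), len(annotated), drop_counts)

    # stage 4: curation QC
    kept, qc_report = curation.run_curation(
        annotated, data.expr, ranks_by_comp, data.samples, data.models, data.proteomics,
        min_psm=params.min_psm, bias_alpha=params.bias_alpha,
        brain_q=params.rank_high, bias_scope=params.bias_scope,
    )
    failed_checks = (
        qc_report[(~qc_report["final_keep"]) & (qc_report["status"] == "fail")]
        .groupby("exon_id")["check"].first().value_counts().to_dict()
    ) if len(qc_report) else {}
    ledger.record("curation_qc", len(annotated), len(kept), failed_checks)

    # stage 5: AS vs gene-level classification (per gene)
    classified = classify_mod.classify_all(
        kept, data.models, variants=data.variants, expr=data.expr,
        samples=data.samples, window=params.window,
    )
    ledger.record("classification", kept["gene_id"].nunique(), len(classified))

    # stage 6: tiering
    bm_expr = _gene_bm_expression(data)
    bm_classifier = None
    try:
        bm_classifier = tiering.fit_bm_classifier(data.calibration, bm_expr)
    except ValueError as exc:
        log.warning("bone-marrow classifier unavailable: %s", exc)
    normal_npsm = tiering.add_npsm(data.proteomics[data.proteomics["panel"] == "normal"])
    try:
        cutoff, fallback = tiering.bimodal_cutoff(
            normal_npsm["npsm"].to_numpy(), random_state=subseed(params.seed, "gmm")
        )
    except ValueError:
        cutoff, fallback = 0.0, True

    gene_info = classified.set_index("gene_id")
    tier_rows = []
    for gid in sorted(gene_info.index):
        sub = kept[kept["gene_id"] == gid]
        is_gene_level = gene_info.at[gid, "target_class"] == "gene_level"
        checks: dict[str, curation.CheckResult] = {}
        paired_evidence: dict[str, object] = {}
        paired_status = curation.NA
        for _, row in sub.iterrows():
            res = tiering.paired_normal_check(
                row["exon_id"], row["supporting_groups"].split(","),
                ranks_by_comp[row["compartment"]], data.samples,
                high_rank=params.rank_high,
            )
            if res.status == curation.FAIL:
                paired_status = curation.FAIL
            elif res.status == curation.PASS and paired_status != curation.FAIL:
                paired_status = curation.PASS
            if isinstance(res.evidence, dict):
                paired_evidence.update(res.evidence)
        checks["paired_normal"] = curation.CheckResult(paired_status, paired_evidence)
        if bm_classifier is not None:
            checks["bone_marrow"] = tiering.bm_low_expression(
                gid, bm_expr, bm_classifier, is_gene_level=is_gene_level
            )
        checks["gtex_proteomics"] = tiering.protein_abundance_flag(gid, normal_npsm, cutoff)
        t = tiering.assign_tier(gid, checks)
        tier_rows.append({
            "gene_id": gid, "tier": t.tier,
            "failed_checks": ",".join(t.failed_checks),
            "evidence": json.dumps(t.evidence, sort_keys=True, default=str),
        })
    tiers = pd.DataFrame(tier_rows, columns=["gene_id", "tier", "failed_checks", "evidence"])
    ledger.record("tiering", len(classified), len(tiers))

    # stage 7: scoring and target table
    targets = classified.merge(tiers, on="gene_id", how="left")
    loc = kept.groupby("gene_id")["localization"].first() if len(kept) else pd.Series(dtype=object)
    comp_of = kept.groupby("gene_id")["compartment"].apply(
        lambda s: ",".join(sorted(set(s)))) if len(kept) else pd.Series(dtype=object)
    top_exon = (
        kept.sort_values(["composite_z", "exon_id"], ascending=[False, True])
        .groupby("gene_id")["exon_id"].first()
    ) if len(kept) else pd.Series(dtype=object)
    targets["localization"] = targets["gene_id"].map(loc)
    targets["compartments"] = targets["gene_id"].map(comp_of)
    targets["oncofetal"] = targets["gene_id"].isin(data.annotations.oncofetal)
    targets["chosen_exon"] = targets.apply(
        lambda r: r["chosen_exon"] if pd.notna(r["chosen_exon"]) else top_exon.get(r["gene_id"]),
        axis=1,
    )
    targets = targets.sort_values("gene_id").reset_index(drop=True)

    scored_exons = sorted(set(kept["exon_id"])) if len(kept) else []
    scores, type_table = scoring.score_exons(
        scored_exons, data.expr, data.samples, floor=params.fpkm_floor
    )
    ledger.record("scoring", len(targets), len(targets))

    result = PipelineResult(
        targets=targets, cse_exons=kept, candidates=candidates, qc_report=qc_report,
        pairs=pairs, composites=composites, scores=scores, type_table=type_table,
        ledger=ledger, npsm_cutoff=cutoff, npsm_cutoff_fallback=fallback,
    )
    if out_dir is not None:
        write_results(result, data, params, out_dir, ranks_by_comp)
    return result


def write_results(
    result: PipelineResult,
    data: PipelineData,
    params: PipelineParams,
    out_dir: str | Path,
    ranks_by_comp: dict[str, pd.DataFrame],
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = {"sep": "\t", "index": False, "float_format": "%.6g"}
    result.targets.to_csv(out / "targets.tsv", **fmt)
    result.cse_exons.to_csv(out / "cse_exons.tsv", **fmt)
    result.candidates.to_csv(out / "candidates.tsv", **fmt)
    result.qc_report.to_csv(out / "qc_report.tsv", **fmt)
    result.composites.to_csv(out / "composites.tsv", **fmt)
    result.pairs.to_csv(out / "pairwise_stats.tsv", **fmt)
    result.ledger.to_json(out / "ledger.json")
    fingerprint = scoring.fingerprint(dataclasses.asdict(params))
    scoring.export_portal(
        result.targets, result.scores, result.type_table, ranks_by_comp,
        data.samples, data.models, out / "portal", config_fingerprint=fingerprint,
    )


# --------------------------------------------------------------------------
# Recovery evaluation against planted truth
# --------------------------------------------------------------------------

def evaluate_recovery(result: PipelineResult, truth: GroundTruth) -> dict:
    """Sensitivity/precision of planted-target recovery plus confounder
    demotion and AS classification accuracy."""
    final_genes = set(result.targets["gene_id"])
    planted = truth.planted_genes
    tp = planted & final_genes
    sensitivity = len(tp) / len(planted) if planted else float("nan")
    precision = len(tp) / len(final_genes) if final_genes else float("nan")

    cls = result.targets.set_index("gene_id")
    as_ok = 0
    for gene, exon in truth.planted_as:
        if gene in cls.index and cls.at[gene, "target_class"] == "AS" \
                and cls.at[gene, "chosen_exon"] == exon:
            as_ok += 1
    gl_recovered = [g for g in truth.planted_gene_level if g in cls.index]
    gl_ok = sum(1 for g in gl_recovered if cls.at[g, "target_class"] == "gene_level")

    expected_check = {
        "high_in_paired_normal": "paired_normal",
        "high_in_bone_marrow": "bone_marrow",
        "high_normal_protein": "gtex_proteomics",
    }
    conf_total = conf_ok = 0
    for flag, check in expected_check.items():
        for g in truth.confounders.get(flag, []):
            conf_total += 1
            if g in cls.index and cls.at[g, "tier"] == 2 \
                    and check in str(cls.at[g, "failed_checks"]).split(","):
                conf_ok += 1
    bias_genes = truth.confounders.get("three_prime_biased", [])
    bias_removed = sum(1 for g in bias_genes if g not in final_genes)

    false_genes = final_genes - planted
    return {
        "sensitivity": sensitivity,
        "precision": precision,
        "n_planted": len(planted),
        "n_recovered": len(tp),
        "n_false": len(false_genes),
        "as_correct": as_ok,
        "as_total": len(truth.planted_as),
        "gene_level_correct": gl_ok,
        "gene_level_recovered": len(gl_recovered),
        "confounders_demoted": conf_ok,
        "confounders_total": conf_total,
        "bias_genes_removed": bias_removed,
        "bias_genes_total": len(bias_genes),
    }


# --------------------------------------------------------------------------
# File-based configuration (CLI)
# --------------------------------------------------------------------------

REQUIRED_SAMPLE_COLUMNS = ("sample_id", "group", "cohort", "compartment", "data_source")


def validate_inputs(config: dict) -> list[str]:
    """Schema checks on a file-based run configuration; errors are
    collected, not fail-fast."""
    errors: list[str] = []
    paths = config.get("paths", {})
    for key in ("gene_models", "expression", "samples", "annotations", "proteomics", "calibration"):
        p = paths.get(key)
        if not p:
            errors.append(f"missing path: {key}")
        elif not Path(p).exists():
            errors.append(f"path does not exist: {key}={p}")
    if errors:
        return errors
    samples = pd.read_csv(paths["samples"], sep="\t")
    for col in REQUIRED_SAMPLE_COLUMNS:
        if col not in samples.columns:
            errors.append(f"sample table missing column: {col}")
    if "sample_id" in samples.columns and samples["sample_id"].duplicated().any():
        dups = samples.loc[samples["sample_id"].duplicated(), "sample_id"].tolist()
        errors.append(f"duplicated sample ids: {dups[:5]}")
    expr = pd.read_csv(paths["expression"], sep="\t", index_col="exon_id", nrows=1)
    if "sample_id" in samples.columns:
        expr_cols = set(expr.columns)
        table_ids = set(samples["sample_id"])
        if expr_cols != table_ids:
            missing = sorted(expr_cols ^ table_ids)
            errors.append(f"sample table does not cover expression columns exactly: {missing[:5]}")
    return errors


def load_bundle(config: dict) -> PipelineData:
    paths = config["paths"]
    models = GeneModelSet.from_gtf(paths["gene_models"])
    expr = pd.read_csv(paths["expression"], sep="\t", index_col="exon_id")
    samples = pd.read_csv(paths["samples"], sep="\t", index_col="sample_id")
    samples.insert(0, "sample_id", samples.index)
    annotations = AnnotationSet.from_gmt(paths["annotations"])
    proteomics = pd.read_csv(paths["proteomics"], sep="\t")
    calibration = pd.read_csv(paths["calibration"], sep="\t")
    variants = None
    if paths.get("variants") and Path(paths["variants"]).exists():
        variants = pd.read_csv(paths["variants"], sep="\t")
    truth = None
    if paths.get("ground_truth") and Path(paths["ground_truth"]).exists():
        truth = GroundTruth.from_json(paths["ground_truth"])
    return PipelineData(models=models, expr=expr, samples=samples, annotations=annotations,
                        proteomics=proteomics, calibration=calibration,
                        variants=variants, truth=truth)


def write_bundle(data: PipelineData, out_dir: str | Path) -> dict:
    """Write a simulated study to disk and return a run config dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data.models.to_gtf(out / "gene_models.gtf")
    data.expr.to_csv(out / "expression.tsv", sep="\t", float_format="%.6g")
    data.samples.to_csv(out / "samples.tsv", sep="\t", index=False)
    data.annotations.to_gmt(out / "annotations.gmt")
    data.proteomics.to_csv(out / "proteomics.tsv", sep="\t", index=False)
    data.calibration.to_csv(out / "calibration.tsv", sep="\t", index=False)
    if data.variants is not None:
        data.variants.to_csv(out / "variants.tsv", sep="\t", index=False)
    if data.truth is not None:
        data.truth.to_json(out / "ground_truth.json")
    config = {"paths": {
        "gene_models": str(out / "gene_models.gtf"),
        "expression": str(out / "expression.tsv"),
        "samples": str(out / "samples.tsv"),
        "annotations": str(out / "annotations.gmt"),
        "proteomics": str(out / "proteomics.tsv"),
        "calibration": str(out / "calibration.tsv"),
        "variants": str(out / "variants.tsv"),
        "ground_truth": str(out / "ground_truth.json"),
    }}
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return config
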