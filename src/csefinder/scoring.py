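"""Quartile binned scores, tumor/normal averages, prevalence, and the
portal-ready export bundle.

Per exon, samples with >= 1 FPKM are binned 0-3 by the quartiles of the
exon's above-floor values across all samples (right-closed intervals;
strictly above Q3 is bin 3); sub-floor samples are bin 0.  Per-type
means are averaged, unweighted, across tumor types and across normal
tissue types to give the tumor and normal scores.  Prevalence is the
fraction of a type's samples in the top bin.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd


def quartile_breaks(values, floor: float = 1.0) -> tuple[float, float, float] | None:
    """Q1/Q2/Q3 of the values at or above the FPKM floor (linear
    interpolation); None when nothing reaches the floor."""
    vals = np.asarray(values, dtype=float)
    vals = vals[vals >= floor]
    if vals.size == 0:
        return None
    q1, q2, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
    return float(q1), float(q2), float(q3)


def binned_scores(values, breaks=None, floor: float = 1.0) -> np.ndarray:
    """Per-sample bins in {0,1,2,3} for one exon row."""
    vals = np.asarray(values, dtype=float)
    if breaks is None:
        breaks = quartile_breaks(vals, floor=floor)
    if breaks is None:
        return np.zeros(vals.size, dtype=int)
    q1, q2, q3 = breaks
    bins = np.zeros(vals.size, dtype=int)
    above = vals >= floor
    bins[above & (vals > q1)] = 1
    bins[above & (vals > q2)] = 2
    bins[above & (vals > q3)] = 3
    return bins


def binned_scores_median_variant(values, samples: pd.DataFrame, floor: float = 1.0) -> dict[str, int]:
    """Per-type bin of the type's median value (alternative reading of the
    binned score; kept behind this explicit entry point)."""
    vals = pd.Series(np.asarray(values, dtype=float), index=samples.index)
    breaks = quartile_breaks(vals.to_numpy(), floor=floor)
    out = {}
    for g, sub in samples.groupby("group"):
        med = float(vals[sub.index].median())
        out[g] = int(binned_scores(np.array([med]), breaks=breaks, floor=floor)[0])
    return out


def type_scores(
    bins: np.ndarray,
    samples: pd.DataFrame,
) -> tuple[pd.Series, float, float]:
    """(per-type mean bins, tumor_score, normal_score).

    Scores are unweighted means of per-type means, so duplicating every
    sample of a type leaves them unchanged.
    """
    s = pd.Series(bins, index=samples.index, dtype=float)
    means = {}
    for g, sub in samples.groupby("group"):
        if len(sub) == 0:
            continue
        means[g] = float(s[sub.index].mean())
    per_type = pd.Series(means)
    tumor_types = sorted(samples.loc[samples["cohort"] == "tumor", "group"].unique())
    normal_types = sorted(samples.loc[samples["cohort"] == "normal", "group"].unique())
    tumor_score = float(per_type[tumor_types].mean()) if tumor_types else 0.0
    normal_score = float(per_type[normal_types].mean()) if normal_types else 0.0
    return per_type, tumor_score, normal_score


def prevalence(bins: np.ndarray, samples: pd.DataFrame) -> pd.Series:
    """Per-type fraction of samples in the 4th-quartile bin (bin 3)."""
    s = pd.Series(bins, index=samples.index)
    out = {}
    for g, sub in samples.groupby("group"):
        out[g] = float((s[sub.index] == 3).mean()) if len(sub) else 0.0
    return pd.Series(out)


def score_exons(
    exon_ids: list[str],
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    floor: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score a list of exons.

    Returns (summary with tumor_score/normal_score per exon,
    long table of per-type mean bin and prevalence).
    """
    cols = [s for s in samples.index if s in expr.columns]
    sub_samples = samples.loc[cols]
    summary_rows = []
    type_rows = []
    for exon_id in exon_ids:
        bins = binned_scores(expr.loc[exon_id, cols].to_numpy(), floor=floor)
        per_type, t_score, n_score = type_scores(bins, sub_samples)
        prev = prevalence(bins, sub_samples)
        summary_rows.append({
            "exon_id": exon_id, "tumor_score": t_score, "normal_score": n_score,
        })
        for g in per_type.index:
            type_rows.append({
                "exon_id": exon_id, "group": g,
                "mean_bin": per_type[g], "prevalence": prev[g],
            })
    return (
        pd.DataFrame(summary_rows, columns=["exon_id", "tumor_score", "normal_score"]),
        pd.DataFrame(type_rows, columns=["exon_id", "group", "mean_bin", "prevalence"]),
    )


def export_portal(
    targets: pd.DataFrame,
    scores: pd.DataFrame,
    type_table: pd.DataFrame,
    ranks_by_compartment: dict[str, pd.DataFrame],
    samples: pd.DataFrame,
    models,
    outdir: str | Path,
    config_fingerprint: str = "",
    version: str = "0.1.0",
) -> dict[str, str]:
    """Write the portal bundle: scatter, table view, heatmap, gene view,
    and a manifest.  All files are TSV/JSON with deterministic ordering."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}

    scatter = targets.merge(scores, left_on="chosen_exon", right_on="exon_id", how="left") \
        if "chosen_exon" in targets.columns else targets
    scatter_path = outdir / "scatter.tsv"
    scatter.to_csv(scatter_path, sep="\t", index=False, float_format="%.6g")
    files["scatter"] = str(scatter_path)

    table_path = outdir / "table_view.tsv"
    type_table.sort_values(["exon_id", "group"]).to_csv(
        table_path, sep="\t", index=False, float_format="%.6g"
    )
    files["table_view"] = str(table_path)

    heat_rows = []
    for comp in sorted(ranks_by_compartment):
        ranks = ranks_by_compartment[comp]
        groups = sorted(samples.loc[samples.index.isin(ranks.columns), "group"].unique())
        mean_rank = pd.DataFrame({
            g: ranks[[s for s in samples.index[samples["group"] == g] if s in ranks.columns]].mean(axis=1)
            for g in groups
        })
        mean_rank.insert(0, "compartment", comp)
        heat_rows.append(mean_rank.reset_index())
    heat_path = outdir / "heatmap.tsv"
    pd.concat(heat_rows, ignore_index=True).to_csv(
        heat_path, sep="\t", index=False, float_format="%.6g"
    )
    files["heatmap"] = str(heat_path)

    gene_view = {}
    for _, row in targets.iterrows():
        gid = row["gene_id"]
        gene_view[gid] = {
            "target_class": row.get("target_class"),
            "tier": int(row["tier"]) if "tier" in row and pd.notna(row["tier"]) else None,
            "localization": row.get("localization"),
            "chosen_exon": row.get("chosen_exon"),
            "exons": [
                {
                    "exon_id": e.exon_id, "chrom": e.chrom,
                    "start": e.start + 1, "end": e.end,
                    "index_in_gene": e.index_in_gene,
                }
                for e in models.exons_of_gene(gid)
            ],
        }
    gene_path = outdir / "gene_view.json"
    gene_path.write_text(json.dumps(gene_view, indent=1, sort_keys=True) + "\n")
    files["gene_view"] = str(gene_path)

    manifest = {
        "pipeline_version": version,
        "config_fingerprint": config_fingerprint,
        "files": {k: Path(v).name for k, v in sorted(files.items())},
        "n_targets": int(len(targets)),
    }
    man_path = outdir / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    files["manifest"] = str(man_path)
    return files


def fingerprint(obj) -> str:
    """Stable short hash of a JSON-serializable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
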