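"""Synthetic study generator with planted ground truth.

Emulates the structure of a pan-pediatric-tumor exon screen: multi-group
tumor cohorts in two compartments (solid, brain) profiled by several data
sources, ~30 normal tissue types (including bone marrow and the five
tumor-paired tissues), exon-level FPKM with planted gene-level
over-expression and planted tumor-restricted alternatively spliced (AS)
exons, confounder genes for every tiering check, an optional 3'-coverage
bias for the normal cohort, bimodal normal-tissue proteomics, aligned
reads (SAM) for the counter, and splice-site-proximal variants.

Background expression is log-normal per exon on top of a hard
detection floor: each gene carries an expressed/silent pattern across
tumor groups and normal tissues, and silent means exactly 0 FPKM.  The
zero floor is what gives the "above-median" rank convention its meaning:
tissues where an exon is silent tie at a mid-rank just below 0.5, so only
tissues that actually express the exon can be flagged above-median.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .models import AnnotationSet, ExonRecord, Gene, GeneModelSet, GroundTruth
from .rng import substream


class ConfigurationError(ValueError):
    pass


# Five tumor types with a developmental paired normal tissue.
PAIR_MAP: dict[str, str] = {
    "ACT": "Adrenal",
    "WLM": "Kidney",
    "RHB": "Muscle",
    "RB": "Nerve",
    "Mel": "Skin",
}

DEFAULT_NORMAL_TISSUES: tuple[str, ...] = (
    "Adrenal", "Kidney", "Muscle", "Nerve", "Skin", "Brain", "Bone_Marrow",
    "Heart", "Liver", "Lung", "Pancreas", "Spleen", "Stomach", "Colon",
    "Small_Intestine", "Esophagus", "Thyroid", "Pituitary", "Breast",
    "Ovary", "Testis", "Prostate", "Uterus", "Bladder", "Adipose",
    "Artery", "Blood", "Salivary_Gland", "Thymus", "Lymph_Node",
)

REQUIRED_TISSUES: tuple[str, ...] = ("Bone_Marrow",) + tuple(PAIR_MAP.values())


@dataclass(frozen=True)
class TumorGroup:
    name: str
    compartment: str  # "solid" | "brain"
    sources: tuple[str, ...] = ("PCGP",)
    n: int = 15


def default_tumor_groups() -> tuple[TumorGroup, ...]:
    return (
        TumorGroup("ACT", "solid", ("PCGP",)),
        TumorGroup("WLM", "solid", ("PCGP", "TARGET")),
        TumorGroup("RHB", "solid", ("PCGP",)),
        TumorGroup("RB", "solid", ("PCGP",)),
        TumorGroup("Mel", "solid", ("ClinGen",)),
        TumorGroup("OS", "solid", ("ClinGen", "TARGET")),
        TumorGroup("HGG", "brain", ("PCGP", "ClinGen")),
        TumorGroup("MB", "brain", ("PCGP",)),
    )


@dataclass
class GeneModelConfig:
    n_genes: int = 200
    exons_per_gene: tuple[int, int] = (4, 10)
    exon_length: tuple[int, int] = (120, 480)
    intron_length: tuple[int, int] = (200, 800)
    multi_transcript_fraction: float = 0.3
    n_chroms: int = 4

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        for name in ("exons_per_gene", "exon_length", "intron_length"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ConfigurationError(f"invalid range for {name}: ({lo}, {hi})")
        if self.exons_per_gene[0] < 2:
            raise ConfigurationError("exons per gene must be >= 2")
        if not 0.0 <= self.multi_transcript_fraction <= 1.0:
            raise ConfigurationError("multi_transcript_fraction must be in [0,1]")


@dataclass
class CohortConfig:
    tumor_groups: tuple[TumorGroup, ...] = field(default_factory=default_tumor_groups)
    normal_tissues: tuple[str, ...] = DEFAULT_NORMAL_TISSUES
    n_per_tissue: int = 30
    n_planted_gene_level: int = 20
    n_planted_as: int = 5
    effect_fold: float = 8.0
    noise_sd: float = 0.3
    base_log_mean: float = math.log(8.0)
    gene_sd: float = 0.6
    exon_sd: float = 0.2
    group_sd: float = 0.3
    p_tumor_expressed: float = 0.7
    p_normal_expressed: float = 0.4
    p_normal_expressed_as_gene: float = 0.85
    with_confounders: bool = True
    bias_slope: float = 0.4  # 3'-bias multiplier: 1 + slope * (index_in_gene - 1)
    bias_gene_min_exons: int = 10  # positional signal needs enough exons to detect

    def validate(self) -> None:
        if any(g.n <= 0 for g in self.tumor_groups) or self.n_per_tissue <= 0:
            raise ConfigurationError("group sizes must be positive")
        missing = set(REQUIRED_TISSUES) - set(self.normal_tissues)
        if missing:
            raise ConfigurationError(f"missing required normal tissues: {sorted(missing)}")
        if self.with_confounders and "ACT" not in {g.name for g in self.tumor_groups}:
            raise ConfigurationError("paired-normal confounder requires an ACT tumor group")
        if self.effect_fold <= 0:
            raise ConfigurationError("effect_fold must be positive")


# --------------------------------------------------------------------------
# Gene models
# --------------------------------------------------------------------------

def generate_gene_models(config: GeneModelConfig | None = None, seed: int = 0) -> GeneModelSet:
    """Build a deterministic set of gene models.

    A fraction of genes gets a second transcript that skips one internal
    exon (a cassette exon) — the substrate for planted AS targets.
    """
    config = config or GeneModelConfig()
    config.validate()
    rng = substream(seed, "gene_models")

    genes: dict[str, Gene] = {}
    transcripts: dict[str, list[str]] = {}
    tx_gene: dict[str, str] = {}
    exons: dict[str, ExonRecord] = {}
    cursors = {f"chr{i + 1}": 10_000 for i in range(config.n_chroms)}

    for gi in range(config.n_genes):
        gid = f"G{gi + 1:04d}"
        chrom = f"chr{gi % config.n_chroms + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        multi = n_ex >= 3 and rng.random() < config.multi_transcript_fraction

        pos = cursors[chrom]
        recs: list[ExonRecord] = []  # genomic order
        for k in range(n_ex):
            length = int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
            idx = k + 1 if strand == "+" else n_ex - k  # transcription-direction index
            recs.append(ExonRecord(f"{gid}:E{idx:02d}", gid, chrom, pos, pos + length, idx))
            pos += length + int(rng.integers(config.intron_length[0], config.intron_length[1] + 1))
        cursors[chrom] = pos + 5_000

        for rec in recs:
            exons[rec.exon_id] = rec
        genes[gid] = Gene(gid, chrom, strand)

        tx_order = sorted(recs, key=lambda r: r.index_in_gene)
        t1 = f"{gid}.t1"
        transcripts[t1] = [r.exon_id for r in tx_order]
        tx_gene[t1] = gid
        if multi:
            # skip one internal exon (never the first or last in transcription order)
            skip = int(rng.integers(1, n_ex - 1))
            t2 = f"{gid}.t2"
            transcripts[t2] = [r.exon_id for j, r in enumerate(tx_order) if j != skip]
            tx_gene[t2] = gid

    models = GeneModelSet(genes=genes, transcripts=transcripts, tx_gene=tx_gene, exons=exons)
    models.validate()
    return models


# --------------------------------------------------------------------------
# Cohort expression
# --------------------------------------------------------------------------

def _sample_table(config: CohortConfig) -> pd.DataFrame:
    rows = []
    for grp in config.tumor_groups:
        for i in range(grp.n):
            rows.append({
                "sample_id": f"{grp.name}_T{i + 1:02d}",
                "group": grp.name,
                "cohort": "tumor",
                "compartment": grp.compartment,
                "data_source": grp.sources[i % len(grp.sources)],
            })
    for tis in config.normal_tissues:
        for i in range(config.n_per_tissue):
            rows.append({
                "sample_id": f"{tis}_N{i + 1:02d}",
                "group": tis,
                "cohort": "normal",
                "compartment": "normal",
                "data_source": "GTEx",
            })
    return pd.DataFrame(rows).set_index("sample_id", drop=False)


def generate_cohort(
    models: GeneModelSet,
    config: CohortConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Exon x sample FPKM matrix, sample table, and planted ground truth."""
    config = config or CohortConfig()
    config.validate()
    samples = _sample_table(config)
    rng_roles = substream(seed, "cohort", "roles")
    rng_expr = substream(seed, "cohort", "expr")

    gene_ids = sorted(models.genes)
    single_tx = [g for g in gene_ids if len(models.transcripts_of_gene(g)) == 1]
    cassette = [g for g in gene_ids if models.cassette_exons(g)]
    rng_roles.shuffle(single_tx)
    rng_roles.shuffle(cassette)

    n_extra = 1 if config.with_confounders else 0
    if len(cassette) < config.n_planted_as or len(single_tx) < config.n_planted_gene_level + n_extra:
        raise ConfigurationError("not enough genes for the requested planted targets")

    planted_as_genes = cassette[: config.n_planted_as]
    planted_gene = single_tx[: config.n_planted_gene_level]
    bias_gene = None
    if config.with_confounders:
        # the 3'-bias confounder goes into a long gene: the positional
        # Pearson check has no power on short genes
        pool = single_tx[config.n_planted_gene_level:]
        long_genes = [g for g in pool if len(models.exons_of_gene(g)) >= config.bias_gene_min_exons]
        bias_gene = long_genes[0] if long_genes else max(
            pool, key=lambda g: len(models.exons_of_gene(g))
        )

    confounders: dict[str, list[str]] = {
        "high_in_paired_normal": [],
        "high_in_bone_marrow": [],
        "high_normal_protein": [],
        "three_prime_biased": [],
    }
    if config.with_confounders and config.n_planted_gene_level >= 3:
        confounders["high_in_paired_normal"] = [planted_gene[0]]
        confounders["high_in_bone_marrow"] = [planted_gene[1]]
        confounders["high_normal_protein"] = [planted_gene[2]]
        confounders["three_prime_biased"] = [bias_gene]

    planted_as: list[tuple[str, str]] = []
    for g in planted_as_genes:
        cass = models.cassette_exons(g)
        planted_as.append((g, cass[int(rng_roles.integers(0, len(cass)))]))

    planted_set = set(planted_gene) | set(planted_as_genes) | ({bias_gene} if bias_gene else set())
    null_genes = [g for g in gene_ids if g not in planted_set]

    groups_by_comp: dict[str, list[str]] = {"solid": [], "brain": []}
    for grp in config.tumor_groups:
        groups_by_comp[grp.compartment].append(grp.name)

    def pick_designated(force_group: str | None = None, force_comp: str | None = None) -> list[str]:
        comp = force_comp or ("solid" if rng_roles.random() < 0.7 else "brain")
        pool = groups_by_comp[comp]
        k = int(rng_roles.integers(2, min(3, len(pool)) + 1))
        chosen = list(rng_roles.choice(pool, size=min(k, len(pool)), replace=False))
        if force_group and force_group not in chosen:
            chosen[0] = force_group
        return sorted(chosen)

    designated: dict[str, list[str]] = {}
    expressed_tumor: dict[str, set[str]] = {}
    expressed_normal: dict[str, set[str]] = {}
    tissues = list(config.normal_tissues)
    tumor_names = [g.name for g in config.tumor_groups]

    for g in gene_ids:
        if g in set(planted_gene):
            if g in confounders["high_in_paired_normal"]:
                designated[g] = pick_designated(force_group="ACT", force_comp="solid")
                expressed_normal[g] = {"Adrenal"}
            elif g in confounders["high_in_bone_marrow"]:
                designated[g] = pick_designated()
                expressed_normal[g] = {"Bone_Marrow"}
            else:
                designated[g] = pick_designated()
                expressed_normal[g] = set()
            expressed_tumor[g] = set(designated[g])
        elif g == bias_gene:
            designated[g] = sorted(groups_by_comp["brain"])
            expressed_tumor[g] = set(designated[g])
            pool = [t for t in tissues if t != "Brain"]
            expressed_normal[g] = set(rng_roles.choice(pool, size=2, replace=False))
        elif g in set(planted_as_genes):
            designated[g] = pick_designated()
            expressed_tumor[g] = set(tumor_names)  # gene backbone broadly expressed
            expressed_normal[g] = {
                t for t in tissues if rng_roles.random() < config.p_normal_expressed_as_gene
            }
        else:
            expressed_tumor[g] = {
                t for t in tumor_names if rng_roles.random() < config.p_tumor_expressed
            }
            expressed_normal[g] = {
                t for t in tissues if rng_roles.random() < config.p_normal_expressed
            }

    as_exon_of = {g: e for g, e in planted_as}
    log_fold = math.log(config.effect_fold)

    exon_order: list[ExonRecord] = []
    for g in gene_ids:
        exon_order.extend(models.exons_of_gene(g))
    exon_ids = [e.exon_id for e in exon_order]
    row_of = {e: i for i, e in enumerate(exon_ids)}
    sample_ids = list(samples.index)
    col_of = {s: j for j, s in enumerate(sample_ids)}
    values = np.zeros((len(exon_ids), len(sample_ids)))

    group_cols: dict[str, list[int]] = {
        name: [col_of[s] for s in samples.index[samples["group"] == name]]
        for name in tumor_names + tissues
    }

    for g in gene_ids:
        recs = models.exons_of_gene(g)
        n_ex = len(recs)
        mu_g = config.base_log_mean + rng_expr.normal(0.0, config.gene_sd)
        exon_off = rng_expr.normal(0.0, config.exon_sd, size=n_ex)
        rows = np.array([row_of[r.exon_id] for r in recs])
        idx = np.array([r.index_in_gene for r in recs], dtype=float)
        as_row = row_of[as_exon_of[g]] if g in as_exon_of else None
        biased = g in confounders["three_prime_biased"]

        for name in tumor_names + tissues:
            cols = group_cols[name]
            is_tumor = name in set(tumor_names)
            on = name in (expressed_tumor[g] if is_tumor else expressed_normal[g])
            grp_off = rng_expr.normal(0.0, config.group_sd)
            noise = rng_expr.normal(0.0, config.noise_sd, size=(n_ex, len(cols)))
            if not on:
                continue
            eff = log_fold if (is_tumor and name in designated.get(g, [])) else 0.0
            vals = np.exp(mu_g + exon_off[:, None] + grp_off + eff + noise)
            if biased and not is_tumor:
                vals *= (1.0 + config.bias_slope * (idx[:, None] - 1.0))
            values[np.ix_(rows, cols)] = vals

        # tumor-restricted AS exon: silent everywhere except designated groups
        if as_row is not None:
            values[as_row, :] = 0.0
            k = list(rows).index(as_row)
            for name in designated[g]:
                cols = group_cols[name]
                noise = rng_expr.normal(0.0, config.noise_sd, size=len(cols))
                values[as_row, cols] = np.exp(mu_g + exon_off[k] + log_fold + noise)

    expr = pd.DataFrame(values, index=pd.Index(exon_ids, name="exon_id"), columns=sample_ids)

    truth = GroundTruth(
        planted_gene_level=sorted(planted_gene),
        planted_as=sorted(planted_as),
        null_genes=sorted(null_genes),
        confounders=confounders,
        designated_groups={g: designated[g] for g in sorted(designated)},
        effect_fold=config.effect_fold,
        bm_expressed_genes=sorted(
            g for g in null_genes if "Bone_Marrow" in expressed_normal[g]
        ),
    )
    truth.validate(models)
    return expr, samples, truth


# --------------------------------------------------------------------------
# Annotations
# --------------------------------------------------------------------------

def generate_annotations(
    models: GeneModelSet,
    truth: GroundTruth,
    seed: int = 0,
    frac_null_surfaceome: float = 0.25,
    frac_null_matrisome: float = 0.15,
    frac_null_blacklist: float = 0.05,
) -> tuple[AnnotationSet, dict]:
    """Gene-set annotations consistent with the planted truth.

    All planted targets land in the surfaceome and/or matrisome; blacklist
    categories draw from null genes only.
    """
    rng = substream(seed, "annotations")
    planted = sorted(truth.planted_genes | {g for gs in truth.confounders.values() for g in gs})
    nulls = sorted(truth.null_genes)

    def frac_sample(pool: list[str], frac: float) -> set[str]:
        k = int(round(frac * len(pool)))
        if k == 0:
            return set()
        return set(rng.choice(pool, size=k, replace=False))

    surfaceome = set(planted) | frac_sample(nulls, frac_null_surfaceome)
    matrisome = frac_sample(planted, 0.5) | frac_sample(nulls, frac_null_matrisome)
    blacklist = {
        cat: frac_sample(nulls, frac_null_blacklist)
        for cat in ("tumor_suppressor", "transcription_factor", "chromatin_regulator")
    }
    ann = AnnotationSet(
        surfaceome=surfaceome,
        matrisome=matrisome,
        blacklist=blacklist,
        oncofetal=frac_sample(planted, 0.2),
        transmembrane=frac_sample(sorted(surfaceome), 0.6),
    )
    report = {
        "planted_in_surfaceome_or_matrisome": all(
            g in surfaceome or g in matrisome for g in planted
        ),
        "blacklist_disjoint_from_planted": not (ann.blacklisted & set(planted)),
        "n_surfaceome": len(surfaceome),
        "n_matrisome": len(matrisome),
        "n_blacklisted": len(ann.blacklisted),
    }
    return ann, report


# --------------------------------------------------------------------------
# Proteomics
# --------------------------------------------------------------------------

def sample_log_npsm(
    n: int,
    rng: np.random.Generator,
    mean_low: float = -2.0,
    mean_high: float = 0.0,
    sigma: float = 0.3,
    weight_high: float = 0.5,
) -> np.ndarray:
    """Draw log10 nPSM values from a 2-component Gaussian mixture."""
    comp = rng.random(n) < weight_high
    return np.where(comp, rng.normal(mean_high, sigma, n), rng.normal(mean_low, sigma, n))


def generate_proteomics(
    models: GeneModelSet,
    truth: GroundTruth,
    seed: int = 0,
    tumor_psm_lambda: float = 2.0,
    p_null_tumor_covered: float = 0.5,
    mean_low: float = -2.0,
    mean_high: float = 0.0,
    sigma: float = 0.3,
    p_null_protein_high: float = 0.15,
) -> pd.DataFrame:
    """PSM tables for the tumor and normal panels.

    Every planted target receives >=1 tumor PSM per exon.  The normal
    panel draws log10 nPSM from a 2-component mixture; genes flagged
    high-normal-protein (and a background fraction of null genes, which
    gives the mixture its upper mode) come from the upper component.
    Updates ``truth.normal_protein_high`` in place.
    """
    rng = substream(seed, "proteomics")
    planted = truth.planted_genes | {g for gs in truth.confounders.values() for g in gs}
    flagged = set(truth.confounders.get("high_normal_protein", []))
    high = set(flagged)
    rows = []
    for g in sorted(models.genes):
        recs = models.exons_of_gene(g)
        covered = g in planted or rng.random() < p_null_tumor_covered
        if g in truth.null_genes and rng.random() < p_null_protein_high:
            high.add(g)
        for rec in recs:
            aa_len = max(rec.length // 3, 10)
            if covered:
                psm = int(rng.poisson(tumor_psm_lambda)) + (1 if g in planted else 0)
                if psm > 0:
                    rows.append((g, rec.exon_id, psm, aa_len, "tumor"))
            mean = mean_high if g in high else mean_low
            log_npsm = rng.normal(mean, sigma)
            n_psm = int(round(10.0 ** log_npsm * aa_len))
            rows.append((g, rec.exon_id, n_psm, aa_len, "normal"))
    truth.normal_protein_high = sorted(high)
    return pd.DataFrame(rows, columns=["gene_id", "exon_id", "psm", "aa_length", "panel"])


# --------------------------------------------------------------------------
# Alignments (SAM)
# --------------------------------------------------------------------------

@dataclass
class AlignmentConfig:
    reads_per_exon: int = 3
    junction_reads_per_pair: int = 1
    n_multimap_groups: int = 5
    n_intergenic: int = 10
    read_length: int = 100


def generate_alignments(
    models: GeneModelSet,
    config: AlignmentConfig | None = None,
    seed: int = 0,
    out_path: str | Path | None = None,
) -> tuple[str, dict]:
    """Emit SAM alignment records with per-exon truth counts.

    Read classes: fully-intra-exonic, junction-spanning (counted for both
    flanking exons), multi-mapped groups (every alignment counts, MAPQ 0),
    and intergenic reads (counted nowhere).
    """
    config = config or AlignmentConfig()
    rng = substream(seed, "alignments")
    rl = config.read_length

    chrom_len: dict[str, int] = {}
    for e in models.exons.values():
        chrom_len[e.chrom] = max(chrom_len.get(e.chrom, 0), e.end + 10_000)

    truth_counts: dict[str, int] = {e: 0 for e in models.exons}
    records: list[tuple[str, int, str]] = []  # (chrom, pos0, sam line tail fields)
    qid = 0

    def emit(chrom: str, pos0: int, cigar: str, qname: str, flag: int = 0, mapq: int = 60) -> None:
        records.append(
            (chrom, pos0,
             f"{qname}\t{flag}\t{chrom}\t{pos0 + 1}\t{mapq}\t{cigar}\t*\t0\t0\t*\t*")
        )

    all_exons = sorted(models.exons.values(), key=lambda e: (e.chrom, e.start))
    for exon in all_exons:
        for _ in range(config.reads_per_exon):
            qid += 1
            if exon.length >= rl:
                start = exon.start + int(rng.integers(0, exon.length - rl + 1))
                emit(exon.chrom, start, f"{rl}M", f"r{qid:06d}")
            else:
                emit(exon.chrom, exon.start, f"{exon.length}M", f"r{qid:06d}")
            truth_counts[exon.exon_id] += 1

    for tx in sorted(models.transcripts):
        recs = sorted((models.exons[e] for e in models.transcripts[tx]), key=lambda r: r.start)
        for a, b in zip(recs, recs[1:]):
            for _ in range(config.junction_reads_per_pair):
                qid += 1
                m1 = min(rl // 2, a.length)
                m2 = min(rl - m1, b.length)
                gap = b.start - a.end
                emit(a.chrom, a.end - m1, f"{m1}M{gap}N{m2}M", f"r{qid:06d}")
                truth_counts[a.exon_id] += 1
                truth_counts[b.exon_id] += 1

    exon_list = list(all_exons)
    for _ in range(config.n_multimap_groups):
        qid += 1
        pair = rng.choice(len(exon_list), size=2, replace=False)
        for j, k in enumerate(pair):
            exon = exon_list[k]
            start = exon.start + int(rng.integers(0, max(exon.length - rl, 0) + 1))
            span = min(rl, exon.length)
            emit(exon.chrom, start, f"{span}M", f"m{qid:06d}", flag=0 if j == 0 else 256, mapq=0)
            truth_counts[exon.exon_id] += 1

    # intergenic: drop reads into introns, never touching an exon
    genes = sorted(models.genes)
    for _ in range(config.n_intergenic):
        qid += 1
        g = genes[int(rng.integers(0, len(genes)))]
        recs = sorted(models.exons_of_gene(g), key=lambda r: r.start)
        if len(recs) < 2:
            continue
        a, b = recs[0], recs[1]
        lo, hi = a.end + 5, b.start - rl - 5
        if hi <= lo:
            continue
        emit(a.chrom, int(rng.integers(lo, hi)), f"{rl}M", f"i{qid:06d}")

    header = ["@HD\tVN:1.6\tSO:coordinate"]
    for chrom in sorted(chrom_len):
        header.append(f"@SQ\tSN:{chrom}\tLN:{chrom_len[chrom]}")
    records.sort(key=lambda r: (r[0], r[1]))
    sam = "\n".join(header + [r[2] for r in records]) + "\n"
    if out_path is not None:
        Path(out_path).write_text(sam)

    n_exonic = sum(
        1 for r in records if not r[2].startswith("i")
    )
    truth = {"exon_counts": truth_counts, "n_exonic_alignments": n_exonic}
    return sam, truth


# --------------------------------------------------------------------------
# Variants
# --------------------------------------------------------------------------

def generate_variants(
    models: GeneModelSet,
    truth: GroundTruth,
    samples: pd.DataFrame,
    seed: int = 0,
    carrier_fraction: float = 0.1,
    window: int = 10,
) -> tuple[pd.DataFrame, dict[tuple[str, str], list[str]]]:
    """Place variants within +/-``window`` bp of planted AS exon boundaries.

    A ``carrier_fraction`` of the tumor samples in each AS gene's
    designated groups carry one variant each.  Returns the variant table
    (1-based positions) and the carrier map for coupling tests.
    """
    rng = substream(seed, "variants")
    rows = []
    carriers: dict[tuple[str, str], list[str]] = {}
    for gene, exon_id in sorted(truth.planted_as):
        exon = models.exons[exon_id]
        pool = [
            s for s in samples.index
            if samples.at[s, "cohort"] == "tumor"
            and samples.at[s, "group"] in truth.designated_groups.get(gene, [])
        ]
        k = int(round(carrier_fraction * len(pool)))
        chosen = sorted(rng.choice(pool, size=k, replace=False)) if k else []
        carriers[(gene, exon_id)] = list(chosen)
        boundaries = [exon.start + 1, exon.end]  # 1-based acceptor/donor positions
        for s in chosen:
            b = boundaries[int(rng.integers(0, 2))]
            pos = b + int(rng.integers(-window, window + 1))
            rows.append((s, exon.chrom, pos, gene))
    df = pd.DataFrame(rows, columns=["sample_id", "chrom", "pos", "gene_id"])
    return df, carriers


def couple_expression(
    expr: pd.DataFrame,
    carriers: dict[tuple[str, str], list[str]],
    delta: float,
) -> pd.DataFrame:
    """Shift carriers' AS-exon expression up by exp(delta) (positive control)."""
    out = expr.copy()
    for (gene, exon_id), carrier_samples in carriers.items():
        if carrier_samples:
            out.loc[exon_id, carrier_samples] = out.loc[exon_id, carrier_samples] * math.exp(delta)
    return out
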