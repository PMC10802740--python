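# Methods

This note documents the statistical model behind `csefinder`, the design
choices made where the procedure was genuinely open, what the synthetic
study conditions emulate, and the known limitations.

## The screen

The pipeline searches exon-level RNA-seq for *cancer-specific exons*
(CSEs): exons highly expressed in tumors but restricted in normal
tissues. A CSE can reflect over-expression of the whole gene or
tumor-restricted inclusion of an alternatively spliced (AS) cassette
exon; the latter matters for immunotherapy because an AS epitope can be
targetable even when the host gene is broadly expressed. Stages:

1. **Quantification.** Reads are counted per exon with union semantics:
   no mapping-quality filter, strand ignored, every alignment of a
   multi-mapped read counted, and a junction-spanning read counted for
   *both* flanking exons. Counts are converted to FPKM with a
   short-exon guard: the effective length is `max(exon_length,
   read_length)`, so junction double-counting cannot inflate exons
   shorter than a read.
2. **Differential statistics.** For each (tumor type, normal tissue)
   pair the Mann–Whitney statistic `U = Σᵢⱼ S(xᵢ, yⱼ)` (S = 1 / ½ / 0
   for y < x / y = x / y > x) is converted to
   `z = (U − n₁n₂/2) / √(n₁n₂(n₁+n₂+1)/12)` (no tie correction; a
   corrected variant exists for sensitivity analysis). Pairs are
   combined per exon by a weighted Stouffer sum
   `Z* = Σ wᵢzᵢ / √(Σ wᵢ²)` with `wᵢ` the median percentile-rank
   differential between the two groups. Solid and brain compartments
   are analyzed separately.
3. **Selection.** An exon is a candidate iff `Z* > 1`, at least one
   tumor type is above-median (median percentile rank > 0.5), and at
   most 5 normal tissues are above-median.
4. **Annotation.** Only genes in the surfaceome or matrisome survive;
   genes in any blacklist category (tumor suppressors, transcription
   factors, chromatin regulators, …) are hard-dropped.
5. **Curation.** Cross-resource agreement for tumor types profiled by
   several data sources; ≥1 tumor-panel PSM in proteomics; removal of
   brain candidates with normal-brain median rank ≥ 0.75; removal of
   genes whose mean normal expression correlates with exon index
   (Pearson p < 0.01 and r > 0 — 3′ coverage bias).
6. **Classification.** A gene is an AS target iff some transcript
   carries < 40% of the gene's CSE exonic length *and* a CSE exon shows
   cassette behavior; otherwise gene-level. Among several AS exons the
   one with the highest composite represents the gene (ties break to
   the lower genomic coordinate). AS targets get a splice-variant
   association check: one-sided Welch t-test of carriers (variant
   within ±10 bp of an exon boundary) versus non-carriers, restricted
   to tumors at or above median expression.
7. **Tiering.** Tier 1 requires passing all applicable checks: paired
   normal tissue not high (ACT/Adrenal, WLM/Kidney, RHB/Muscle,
   RB/Nerve, Mel/Skin; median rank < 0.75), low bone-marrow expression
   for gene-level targets (logistic model, below), and normal-proteome
   nPSM below the bimodal cutoff. Any failure — or missing evidence —
   demotes to Tier 2; the fail-safe never promotes.
8. **Scoring/export.** Per exon, samples ≥ 1 FPKM are binned 0–3 by the
   exon's own quartiles of above-floor values (right-closed intervals);
   sub-floor samples are bin 0. Per-type bin means are averaged,
   unweighted, over tumor types and over normal tissues to give the
   tumor and normal scores; prevalence is a type's fraction of bin-3
   samples. Portal exports: scatter, table view, heatmap of mean
   percentile ranks, gene view, and a manifest with a config hash.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `z_star` | 1 | composite threshold (strict >) |
| `max_normals` | 5 | normal tissues allowed above median |
| `coverage` | 0.40 | transcript CSE-coverage bound for AS (strict <) |
| `bias_alpha` | 0.01 | Pearson p for the 3′-bias removal |
| `rank_high` | 0.75 | "high expression" rank convention (≥, one constant reused by the brain filter and paired-tissue check) |
| `fpkm_floor` | 1 FPKM | binned-score detection floor |
| `window` | 10 bp | splice-site variant window (inclusive) |
| `min_psm` | 1 | tumor-proteomics verification threshold |

All are config keys; nothing is hard-coded.

## Interpretation choices

- **Percentile-rank population.** Ranks are computed once per
  compartment over the tumor groups of that compartment plus all
  normal samples, and reused for weights, above-median flags, heatmaps
  and prevalence — one coherent convention. Mid-ranks are
  `(rank − 0.5)/N`, so every row means exactly 0.5 and ties share a
  rank; a per-pair ranking mode exists behind `per_pair_ranks`.
- **Composite denominator.** `√(Σw²)` — the normalization that makes
  the composite unit-variance under the null for *fixed* weights.
  Weights may be negative and are not clamped.
- **Null behavior of the composite.** The weight and z are computed
  from the same samples and co-vary, so each pair contributes a
  positively biased product; with k ≈ 180 pairs the null composite mean
  is large (~9 under an everything-identical null) and the `Z* > 1`
  gate alone excludes almost nothing. This is a property of the
  statistic as defined, not an implementation artifact. The screen's
  specificity comes from the above-median and ≤5-normal-tissue filters:
  on no-signal cohorts the full cascade passes ~0% of exons, and the
  composite-rate is stable across seeds. Note also that the composite
  is *even* under jointly negating (z, w) — exchanging tumor and normal
  labels negates z and w individually but leaves the composite
  unchanged; the oddness holds in the z vector for fixed weights.
- **Binned score.** Implemented per sample (bin each sample, then
  per-type means), which defines prevalence naturally; a
  median-per-type variant (`binned_scores_median_variant`) is provided.
  Quartile breaks are per exon over all samples, keeping tumor and
  normal scores on one scale.
- **Bimodal nPSM cutoff.** A 2-component Gaussian mixture is fit to
  log10 nPSM (EM, k-means init, 5 restarts, seeded); the cutoff is the
  equal-posterior point between the means. Degeneracy is judged by
  Ashman's D < 2 (an EM fit of a unimodal sample yields means ~1.6
  component-sd apart, D ≈ 1.7; the target mixture gives D ≈ 6.8); the
  fallback is the median, flagged.
- **Bone-marrow model.** Logistic regression of expressed-status on
  `log2(median BM expression + 1)` over user-supplied calibration
  genes, with an L2 penalty so fully separated calibration sets stay
  well-posed; AS targets are exempt because bone-marrow data is
  gene-level. Missing genes fail safe to Tier 2.
- **Stage order.** Classification runs before tiering because the
  bone-marrow exemption needs the AS/gene-level class.
- **Exon index.** `index_in_gene` is strand-aware (1 = 5′-most exon in
  transcription direction), used both for the 3′-bias check and gene
  views.
- **FPKM denominator.** The library size is the number of alignments
  overlapping ≥1 exon (what the counter sees); `library_mode="mapped"`
  switches to all mapped records.

## The synthetic study

The generator emulates the structure of a pan-pediatric screen: 8
tumor types (6 solid incl. the five paired types, 2 brain), several
data sources per type, 15 samples/type; 30 normal tissues × 30 samples
including Bone_Marrow, Brain and the five paired tissues. Background
expression is log-normal per exon (gene sd 0.6, exon sd 0.2, group sd
0.3, sample noise sd 0.3 on the natural-log scale) on top of a hard
detection floor: each gene is expressed in a random subset of tumor
types (p = 0.7) and normal tissues (p = 0.4) and exactly 0 elsewhere.
The zero floor is what gives the rank conventions their meaning —
silent tissues tie at a mid-rank just below 0.5, so only expressing
tissues can be flagged above-median; with a fully continuous background
about half of all tissues would exceed any exon's global median
regardless of signal, and the ≤5-tissue filter would reject everything.

Planted signal: 20 gene-level targets (single-transcript genes, all
exons raised 8-fold in 2–3 designated tumor types, silent in normals),
5 AS targets (broadly expressed genes whose cassette exon is expressed
*only* in designated tumor types), and one confounder per tiering
check — a paired-normal confounder also expressed in Adrenal with ACT
support, a bone-marrow confounder expressed in Bone_Marrow, a
normal-proteomics confounder drawn from the upper nPSM mixture
component, and a brain-compartment 3′-bias confounder whose normal
expression is multiplied by `1 + 0.4·(index − 1)`. The bias confounder
is planted in a gene with ≥ 10 exons: a power analysis of the Pearson
p < 0.01 rule under the generator's noise shows the check has
essentially no power below ~8 exons, so the discrimination experiment
uses long genes (10–14 exons) by design. The proteomics normal panel
draws log10 nPSM from a mixture with means −2 and 0 (σ = 0.3); ~15% of
null genes occupy the upper component so the mixture is genuinely
bimodal. Variants are placed within ±10 bp of planted AS exon
boundaries for a configurable carrier fraction, with an optional
expression coupling for positive controls.

What the generator does **not** emulate: read errors, isoform-level
abundance mixtures, batch effects within a data source,
partially-expressed ("leaky") tissues, novel unannotated isoforms, and
correlated gene modules. Passing tests therefore demonstrate that the
machinery implements the screen correctly and recovers planted
structure under realistic noise — not that the thresholds are optimal
for any particular real cohort.

## Problem sizes

The default study is 200 genes (~1,400 exons) × 1,020 samples and runs
in a few seconds; null calibration uses 32-gene cohorts (≥200 exons)
over 20 seeds; cutoff recovery uses 50 mixtures of n = 2,000; the bias
discrimination study uses 15 long genes × 20 seeds. These sizes give
stable rank statistics while keeping a full acceptance run under a
minute.

## Limitations

- The composite's null distribution is not standard normal (see above);
  the `Z* > 1` threshold is meaningful only jointly with the rank
  filters, exactly as in the published procedure.
- Tie handling uses mid-ranks throughout; σ_U carries no tie correction
  by default, matching the printed formula.
- AS discovery is restricted to annotated cassette behavior; novel
  isoforms are out of scope.
- The bone-marrow model is only as good as its calibration genes; with
  fewer than 10 per class the check is skipped (never promoting).
- The 3′-bias check cannot detect bias in short genes (< ~8 exons);
  such genes pass unexamined.
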