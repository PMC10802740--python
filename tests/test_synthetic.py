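"""The generator is deterministic, self-consistent, and plants what it claims."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from csefinder.models import GeneModelSet
from csefinder.synthetic import (
    AlignmentConfig,
    CohortConfig,
    ConfigurationError,
    GeneModelConfig,
    couple_expression,
    generate_alignments,
    generate_annotations,
    generate_cohort,
    generate_gene_models,
    generate_proteomics,
    generate_variants,
    sample_log_npsm,
)


class TestGeneModels:
    def test_deterministic_gtf(self, tmp_path):
        cfg = GeneModelConfig(n_genes=50)
        for name in ("a.gtf", "b.gtf"):
            generate_gene_models(cfg, seed=1).to_gtf(tmp_path / name)
        assert (tmp_path / "a.gtf").read_bytes() == (tmp_path / "b.gtf").read_bytes()

    def test_gtf_round_trip(self, models30, tmp_path):
        path = tmp_path / "m.gtf"
        models30.to_gtf(path)
        back = GeneModelSet.from_gtf(path)
        assert set(back.exons) == set(models30.exons)
        assert back.transcripts == models30.transcripts
        for eid, rec in models30.exons.items():
            assert (back.exons[eid].start, back.exons[eid].end) == (rec.start, rec.end)

    def test_single_transcript_covers_all_exons(self):
        cfg = GeneModelConfig(n_genes=10, exons_per_gene=(5, 5), multi_transcript_fraction=0.0)
        models = generate_gene_models(cfg, seed=2)
        for gid in models.genes:
            txs = models.transcripts_of_gene(gid)
            assert len(txs) == 1
            (exon_ids,) = txs.values()
            assert set(exon_ids) == {e.exon_id for e in models.exons_of_gene(gid)}

    def test_cassette_exon_differential_inclusion(self, models30):
        multi = [g for g in models30.genes if len(models30.transcripts_of_gene(g)) > 1]
        assert multi, "fixture should contain multi-transcript genes"
        for g in multi:
            for exon in models30.cassette_exons(g):
                present = [exon in ex for ex in models30.transcripts_of_gene(g).values()]
                assert any(present) and not all(present)

    def test_index_in_gene_strand_aware(self, models30):
        for gid, gene in models30.genes.items():
            recs = sorted(models30.exons_of_gene(gid), key=lambda e: e.start)
            idx = [e.index_in_gene for e in recs]
            assert idx == (sorted(idx) if gene.strand == "+" else sorted(idx, reverse=True))
            assert min(idx) == 1

    @pytest.mark.parametrize("bad", [
        GeneModelConfig(n_genes=0),
        GeneModelConfig(exon_length=(500, 100)),
        GeneModelConfig(exons_per_gene=(1, 3)),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            generate_gene_models(bad, seed=0)


class TestCohort:
    def test_missing_required_tissue_rejected(self, models30):
        cfg = CohortConfig(normal_tissues=("Adrenal", "Kidney"))
        with pytest.raises(ConfigurationError):
            generate_cohort(models30, cfg, seed=0)

    def test_nonpositive_group_size_rejected(self, models30):
        cfg = CohortConfig(n_per_tissue=0)
        with pytest.raises(ConfigurationError):
            generate_cohort(models30, cfg, seed=0)

    def test_deterministic(self, models30):
        cfg = CohortConfig(n_planted_gene_level=4, n_planted_as=2)
        e1, s1, t1 = generate_cohort(models30, cfg, seed=9)
        e2, s2, t2 = generate_cohort(models30, cfg, seed=9)
        pd.testing.assert_frame_equal(e1, e2)
        assert t1.planted_as == t2.planted_as

    def test_planted_sets_consistent(self, small_scenario):
        truth, models = small_scenario.truth, small_scenario.models
        truth.validate(models)
        assert not (truth.planted_genes & set(truth.null_genes))
        for gene, exon in truth.planted_as:
            assert exon in models.cassette_exons(gene)

    def test_planted_gene_dominates_normals(self, small_scenario):
        """Planted tumor medians exceed every normal-tissue median."""
        expr, samples, truth = (
            small_scenario.expr, small_scenario.samples, small_scenario.truth,
        )
        clean = [g for g in truth.planted_gene_level
                 if all(g not in v for v in truth.confounders.values())]
        for g in clean:
            exon = small_scenario.models.exons_of_gene(g)[0].exon_id
            grp = truth.designated_groups[g][0]
            t_med = expr.loc[exon, samples.index[samples["group"] == grp]].median()
            for tis in samples.loc[samples["cohort"] == "normal", "group"].unique():
                n_med = expr.loc[exon, samples.index[samples["group"] == tis]].median()
                assert t_med > n_med

    def test_planted_fold_monte_carlo(self, models30):
        """With fold 8 and sigma 0.3, the planted tumor median beats all
        normal medians in >=95% of replicates."""
        wins = trials = 0
        for seed in range(100):
            cfg = CohortConfig(n_planted_gene_level=3, n_planted_as=1,
                               with_confounders=False, effect_fold=8.0, noise_sd=0.3)
            expr, samples, truth = generate_cohort(models30, cfg, seed=seed)
            g = truth.planted_gene_level[0]
            exon = models30.exons_of_gene(g)[0].exon_id
            grp = truth.designated_groups[g][0]
            t_med = expr.loc[exon, samples.index[samples["group"] == grp]].median()
            n_meds = [
                expr.loc[exon, samples.index[samples["group"] == tis]].median()
                for tis in samples.loc[samples["cohort"] == "normal", "group"].unique()
            ]
            trials += 1
            wins += t_med > max(n_meds)
        assert wins / trials >= 0.95

    def test_three_prime_bias_monotone(self, models30):
        cfg = CohortConfig(n_planted_gene_level=3, n_planted_as=1)
        expr, samples, truth = generate_cohort(models30, cfg, seed=4)
        (bias_gene,) = truth.confounders["three_prime_biased"]
        recs = models30.exons_of_gene(bias_gene)
        normal_cols = samples.index[samples["cohort"] == "normal"]
        means = [expr.loc[r.exon_id, normal_cols].mean() for r in recs]
        r, _ = pearsonr([r.index_in_gene for r in recs], means)
        assert r > 0

    def test_as_exon_silent_outside_designated_groups(self, small_scenario):
        expr, samples, truth = (
            small_scenario.expr, small_scenario.samples, small_scenario.truth,
        )
        for gene, exon in truth.planted_as:
            on = set(truth.designated_groups[gene])
            off_cols = [s for s in samples.index if samples.at[s, "group"] not in on]
            on_cols = [s for s in samples.index if samples.at[s, "group"] in on]
            assert (expr.loc[exon, off_cols] == 0).all()
            assert (expr.loc[exon, on_cols] > 0).all()


class TestAnnotations:
    def test_planted_always_annotated_and_never_blacklisted(self, small_scenario):
        ann, models, truth = (
            small_scenario.annotations, small_scenario.models, small_scenario.truth,
        )
        for g in truth.planted_genes:
            assert g in ann.surfaceome | ann.matrisome
        assert not (ann.blacklisted & truth.planted_genes)

    def test_empty_blacklist_config(self, models30):
        cfg = CohortConfig(n_planted_gene_level=3, n_planted_as=1)
        _, _, truth = generate_cohort(models30, cfg, seed=4)
        ann, report = generate_annotations(models30, truth, seed=4, frac_null_blacklist=0.0)
        assert not ann.blacklisted
        assert report["blacklist_disjoint_from_planted"]


class TestProteomics:
    def test_planted_targets_have_tumor_psm(self, small_scenario):
        prot, truth = small_scenario.proteomics, small_scenario.truth
        tumor = prot[prot["panel"] == "tumor"]
        for g in truth.planted_genes:
            assert tumor.loc[tumor["gene_id"] == g, "psm"].sum() >= 1

    def test_flagged_gene_npsm_higher(self, small_scenario):
        prot, truth = small_scenario.proteomics, small_scenario.truth
        normal = prot[prot["panel"] == "normal"].copy()
        normal["npsm"] = normal["psm"] / normal["aa_length"]
        high = set(truth.normal_protein_high)
        mean_high = normal.loc[normal["gene_id"].isin(high), "npsm"].mean()
        mean_low = normal.loc[~normal["gene_id"].isin(high), "npsm"].mean()
        assert mean_high > mean_low

    def test_mixture_dip_between_modes(self):
        rng = np.random.default_rng(0)
        vals = sample_log_npsm(2000, rng, mean_low=-2.0, mean_high=0.0, sigma=0.3)
        hist, edges = np.histogram(vals, bins=40)
        centers = (edges[:-1] + edges[1:]) / 2
        mid = hist[(centers > -1.3) & (centers < -0.7)].min()
        lo_mode = hist[(centers > -2.2) & (centers < -1.8)].max()
        hi_mode = hist[(centers > -0.2) & (centers < 0.2)].max()
        assert mid < lo_mode / 2 and mid < hi_mode / 2


class TestAlignments:
    def test_deterministic(self, models30):
        sam1, _ = generate_alignments(models30, seed=3)
        sam2, _ = generate_alignments(models30, seed=3)
        assert sam1 == sam2

    def test_empty_config_valid_sam(self, models30):
        cfg = AlignmentConfig(reads_per_exon=0, junction_reads_per_pair=0,
                              n_multimap_groups=0, n_intergenic=0)
        sam, truth = generate_alignments(models30, cfg, seed=0)
        body = [l for l in sam.splitlines() if not l.startswith("@")]
        assert body == []
        assert sum(truth["exon_counts"].values()) == 0
        assert any(l.startswith("@SQ") for l in sam.splitlines())

    def test_junction_reads_span_two_exons(self, models30):
        sam, truth = generate_alignments(
            models30,
            AlignmentConfig(reads_per_exon=0, junction_reads_per_pair=1,
                            n_multimap_groups=0, n_intergenic=0),
            seed=0,
        )
        body = [l for l in sam.splitlines() if not l.startswith("@")]
        assert all("N" in l.split("\t")[5] for l in body)
        n_junction = len(body)
        assert sum(truth["exon_counts"].values()) == 2 * n_junction


class TestVariants:
    def test_positions_within_window(self, small_scenario):
        variants, carriers = generate_variants(
            small_scenario.models, small_scenario.truth, small_scenario.samples,
            seed=1, carrier_fraction=0.3, window=10,
        )
        for _, row in variants.iterrows():
            exon = next(
                small_scenario.models.exons[e] for g, e in small_scenario.truth.planted_as
                if g == row["gene_id"]
            )
            d = min(abs(row["pos"] - (exon.start + 1)), abs(row["pos"] - exon.end))
            assert d <= 10

    def test_zero_carrier_fraction_empty(self, small_scenario):
        variants, carriers = generate_variants(
            small_scenario.models, small_scenario.truth, small_scenario.samples,
            seed=1, carrier_fraction=0.0,
        )
        assert len(variants) == 0
        assert all(len(v) == 0 for v in carriers.values())

    def test_coupling_raises_carrier_expression(self, small_scenario):
        variants, carriers = generate_variants(
            small_scenario.models, small_scenario.truth, small_scenario.samples,
            seed=1, carrier_fraction=0.3,
        )
        coupled = couple_expression(small_scenario.expr, carriers, delta=1.0)
        for (gene, exon), samp in carriers.items():
            if samp:
                assert (
                    coupled.loc[exon, samp].to_numpy()
                    > small_scenario.expr.loc[exon, samp].to_numpy()
                ).all()
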