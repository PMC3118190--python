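import math

import numpy as np
import pandas as pd
import pytest

import embryotx as e
from embryotx import synthetic as syn


SMALL = dict(chrom_names=("chr1",), chrom_lengths=(16_000_000,), n_genes=30)


class TestGenerateAnnotation:
    def test_deterministic_under_seed(self, tmp_path):
        spec = e.GenomeSpec(**SMALL, seed=5)
        p1, p2 = tmp_path / "a1.bed", tmp_path / "a2.bed"
        e.write_annotation(e.generate_annotation(spec), str(p1), "bed12")
        e.write_annotation(e.generate_annotation(spec), str(p2), "bed12")
        assert p1.read_bytes() == p2.read_bytes()

    def test_single_exon_genes_have_no_introns(self):
        spec = e.GenomeSpec(**SMALL, exons_per_gene=(1, 1), seed=2)
        for g in e.generate_annotation(spec):
            assert len(g.exons) == 1 and g.introns == []

    def test_geometric_validity(self, small_genome):
        aset = small_genome["annotation"]
        lengths = dict(zip(small_genome["spec"].chrom_names, small_genome["spec"].chrom_lengths))
        for chrom, genes in aset.by_chrom().items():
            prev_end = 0
            for g in genes:
                assert g.span.start >= prev_end  # gene spans do not overlap
                assert g.span.end <= lengths[chrom]
                for a, b in zip(g.exons, g.exons[1:]):
                    assert a.end <= b.start  # exons disjoint and sorted
                prev_end = g.span.end

    def test_intron_lengths_match_truncated_normal_moments(self):
        """Sampled intron lengths agree with closed-form truncated-normal moments."""
        spec = e.GenomeSpec()
        rng = np.random.default_rng(0)
        draws = syn._trunc_normal(rng, spec.mu_intron, spec.sd_intron, spec.intron_floor, 10_000)
        mean, sd = syn.truncated_normal_moments(spec.mu_intron, spec.sd_intron, spec.intron_floor)
        se_mean = sd / math.sqrt(len(draws))
        assert abs(draws.mean() - mean) < 3 * se_mean
        # sd of the sample sd is approx sd/sqrt(2n) for near-normal data; use a loose 5x band
        assert abs(draws.std(ddof=1) - sd) < 5 * sd / math.sqrt(2 * len(draws))

    def test_overflow_names_chromosome(self):
        spec = e.GenomeSpec(chrom_names=("tiny",), chrom_lengths=(30_000,), n_genes=5, seed=1)
        with pytest.raises(ValueError, match="tiny"):
            e.generate_annotation(spec)


class TestMakeTruth:
    def test_labels_partition_genes(self, small_genome):
        truth, aset = small_genome["truth"], small_genome["annotation"]
        assert set(truth.trend_labels) == set(aset.gene_ids())
        n = sum(len(truth.genes_with_trend(t)) for t in ("increasing", "decreasing", "steady"))
        assert n == len(aset)

    def test_planted_regions_clear_of_genes(self, small_genome):
        for pr in small_genome["truth"].planted_novel:
            d = e.distance_to_nearest_gene(pr.interval, small_genome["annotation"])
            assert d >= 20_000


class TestGenerateReads:
    def test_deterministic_under_seed(self, small_genome):
        aset, truth = small_genome["annotation"], small_genome["truth"]
        r1, l1 = e.generate_reads(aset, truth, seed=33, background_reads=50)
        r2, l2 = e.generate_reads(aset, truth, seed=33, background_reads=50)
        assert l1 == l2
        for s in r1:
            pd.testing.assert_frame_equal(r1[s], r2[s])

    def test_zero_mean_gene_gets_no_reads(self, small_genome):
        aset = small_genome["annotation"]
        truth = small_genome["truth"]
        gid = aset.gene_ids()[0]
        means = truth.stage_means.copy()
        means.loc[gid] = 0.0
        silent = syn.TruthTable(
            trend_labels=truth.trend_labels,
            stage_means=means,
            planted_novel=[],
        )
        reads, _ = e.generate_reads(aset, silent, seed=4, background_reads=0)
        gene = next(g for g in aset if g.gene_id == gid)
        for df in reads.values():
            span = gene.span
            hit = df[(df.chrom == gene.chrom) & (df.start < span.end) & (df.end > span.start)]
            assert hit.empty

    def test_planted_counts_exact(self, small_genome):
        """A planted region receives exactly its stated clean reads on its strand."""
        aset, truth = small_genome["annotation"], small_genome["truth"]
        reads, _ = e.generate_reads(aset, truth, seed=5, background_reads=0)
        for stage, df in reads.items():
            for pr in truth.planted_novel:
                iv = pr.interval
                inside = df[
                    (df.chrom == iv.chrom)
                    & (df.strand == iv.strand)
                    & (df.start >= iv.start)
                    & (df.end <= iv.end)
                ]
                assert len(inside) == pr.counts.get(stage, 0)
                if len(inside):
                    assert (inside.n_hits == 1).all() and (inside.score >= 24).all()

    def test_poisson_limit_matches_mean(self):
        """With dispersion -> infinity the per-gene count is Poisson around the truth mean."""
        iv = e.GenomicInterval
        gene = e.GeneModel("g1", "chr1", "+", [iv("chr1", 1000, 2000, "+")])
        aset = e.AnnotationSet(genes=[gene])
        mean = 40.0
        truth = syn.TruthTable(
            trend_labels={"g1": "steady"},
            stage_means=pd.DataFrame(
                {s: [mean] for s in syn.STAGES}, index=pd.Index(["g1"], name="gene_id")
            ),
            planted_novel=[],
            ambiguous_fraction=0.0,
            lowscore_fraction=0.0,
        )
        counts = []
        for rep in range(50):
            reads, _ = e.generate_reads(aset, truth, seed=1000 + rep, background_reads=0, dispersion=None)
            counts.extend(len(df) for df in reads.values())  # 4 stages per replicate
        counts = np.asarray(counts)  # 200 Poisson draws
        se = math.sqrt(mean / len(counts))
        assert abs(counts.mean() - mean) < 3 * se

    def test_requires_four_stages(self, small_genome):
        aset, truth = small_genome["annotation"], small_genome["truth"]
        with pytest.raises(ValueError, match="four-stage"):
            e.generate_reads(aset, truth, stages=("a", "b"), seed=1)


class TestGenerateCtTable:
    def test_fewer_than_two_controls_fails(self):
        with pytest.raises(ValueError, match="control"):
            e.generate_ct_table(
                assays=["c1", "t1"], controls=["c1"], truth_rq={"t1": {s: 1.0 for s in syn.STAGES}}
            )

    def test_flat_truth_gives_equal_dct(self):
        table = e.generate_ct_table(
            assays=["c1", "c2", "t1"],
            controls=["c1", "c2"],
            truth_rq={"t1": {s: 1.0 for s in syn.STAGES}},
            noise_sd=0.0,
            seed=3,
        )
        dct = e.delta_ct(table)
        assert dct.groupby("assay")["dct"].nunique().eq(1).all()

    def test_rq2_gives_ddct_minus_one(self):
        rqs = {s: 1.0 for s in syn.STAGES}
        rqs[syn.STAGES[2]] = 2.0
        table = e.generate_ct_table(
            assays=["c1", "c2", "t1"], controls=["c1", "c2"], truth_rq={"t1": rqs}, seed=4
        )
        rq = e.ddct_rq(e.delta_ct(table), table.reference_stage)
        row = rq.table[(rq.table.stage == syn.STAGES[2]) & (rq.table.assay == "t1")]
        assert row["ddct"].iloc[0] == pytest.approx(-1.0, abs=1e-12)

    def test_noisy_recovery_within_3se(self):
        """With Ct noise, the mean recovered RQ over replicates stays near truth."""
        truth_rq = {"t1": dict(zip(syn.STAGES, (1.0, 2.0, 4.0, 8.0)))}
        recovered = []
        for rep in range(50):
            table = e.generate_ct_table(
                assays=["c1", "c2", "t1"],
                controls=["c1", "c2"],
                truth_rq=truth_rq,
                noise_sd=0.1,
                n_replicates=1,
                seed=500 + rep,
            )
            rq = e.ddct_rq(e.delta_ct(table), table.reference_stage)
            recovered.append(rq.table.set_index("stage").loc[syn.STAGES[3], "rq"])
        recovered = np.asarray(recovered)
        se = recovered.std(ddof=1) / math.sqrt(len(recovered))
        assert abs(recovered.mean() - 8.0) < 3 * se + 0.2  # small lognormal bias allowance
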