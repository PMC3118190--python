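import math

import numpy as np
import pytest

import embryotx as e
from embryotx.novel import LengthDensityModel, NovelRegionCallConfig, Seqfrag
from embryotx.annotation import GenomicInterval as IV
from conftest import make_read, reads_frame


def _overlap_components(intervals):
    """Brute-force union-find over pairwise strict overlaps (the oracle)."""
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = intervals[i], intervals[j]
            if a[0] == b[0] and a[3] == b[3] and a[1] < b[2] and b[1] < a[2]:
                parent[find(i)] = find(j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(intervals[i])
    return list(comps.values())


class TestBuildSeqfrags:
    def test_two_overlapping_reads_merge(self):
        reads = reads_frame([make_read("chr1", 100, 150), make_read("chr1", 140, 190)])
        (sf,) = e.build_seqfrags(reads)
        assert (sf.interval.start, sf.interval.end, sf.read_count) == (100, 190, 2)

    def test_abutting_reads_stay_singletons(self):
        reads = reads_frame([make_read("chr1", 100, 150), make_read("chr1", 150, 200)])
        assert e.build_seqfrags(reads) == []

    def test_opposite_strands_do_not_merge(self):
        reads = reads_frame([make_read("chr1", 100, 150, "+"), make_read("chr1", 120, 170, "-")])
        assert e.build_seqfrags(reads) == []

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(21)
        rows = []
        for i in range(200):
            chrom = f"chr{rng.integers(1, 3)}"
            start = int(rng.integers(0, 3000))
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append(make_read(chrom, start, start + 50, strand, name=f"r{i}"))
        frags = e.build_seqfrags(reads_frame(rows))
        ivs = [(r["chrom"], r["start"], r["end"], r["strand"]) for r in rows]
        oracle = {
            (c[0][0], min(x[1] for x in c), max(x[2] for x in c), c[0][3], len(c))
            for c in _overlap_components(ivs)
            if len(c) >= 2
        }
        ours = {
            (f.interval.chrom, f.interval.start, f.interval.end, f.strand, f.read_count)
            for f in frags
        }
        assert ours == oracle

    def test_output_nonoverlapping_per_strand(self):
        rng = np.random.default_rng(22)
        rows = [
            make_read("chr1", int(s), int(s) + 50, "+", name=f"r{i}")
            for i, s in enumerate(rng.integers(0, 2000, size=120))
        ]
        frags = sorted(e.build_seqfrags(reads_frame(rows)), key=lambda f: f.interval.start)
        for a, b in zip(frags, frags[1:]):
            assert a.interval.end <= b.interval.start


class TestFilterCandidates:
    def _aset(self):
        return e.AnnotationSet(genes=[e.GeneModel("g", "chr1", "+", [IV("chr1", 0, 10_000, "+")])])

    @pytest.mark.parametrize(
        "count, start, kept",
        [
            (6, 30_000, True),    # both boundaries: > 5 reads, exactly 20 kb away
            (5, 60_000, False),   # support threshold is strict
            (10, 29_999, False),  # 19,999 bp < 20 kb
        ],
    )
    def test_boundaries(self, count, start, kept):
        sf = Seqfrag(IV("chr1", start, start + 500, "+"), count)
        out = e.filter_candidates([sf], self._aset())
        assert (len(out) == 1) is kept

    def test_union_of_annotation_sets(self):
        other = e.AnnotationSet(genes=[e.GeneModel("h", "chr1", "-", [IV("chr1", 45_000, 46_000, "-")])])
        sf = Seqfrag(IV("chr1", 30_000, 30_500, "+"), 10)
        assert e.filter_candidates([sf], self._aset()) != []
        assert e.filter_candidates([sf], [self._aset(), other]) == []


class TestDecisionBoundary:
    def test_study_parameters_give_17_6(self):
        assert e.decision_boundary(LengthDensityModel(2.8, 5.6, 97.0, 164.0)) == pytest.approx(
            17.6, abs=0.05
        )

    def test_equal_sds_midpoint(self):
        assert e.decision_boundary(LengthDensityModel(4.0, 3.0, 10.0, 3.0)) == pytest.approx(7.0)

    def test_matches_grid_scan_oracle(self):
        model = LengthDensityModel(1.0, 2.0, 50.0, 80.0)
        x = e.decision_boundary(model)

        def log_ratio(v):
            return (
                -((v - model.mu_intron) ** 2) / (2 * model.sd_intron**2)
                - math.log(model.sd_intron)
                + ((v - model.mu_intergenic) ** 2) / (2 * model.sd_intergenic**2)
                + math.log(model.sd_intergenic)
            )

        grid = np.arange(model.mu_intron, model.mu_intergenic, 1e-4)
        signs = np.sign([log_ratio(v) for v in grid])
        crossing = grid[np.nonzero(np.diff(signs))[0][0]]
        assert x == pytest.approx(crossing, abs=2e-4)

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            LengthDensityModel(mu_intron=100.0, sd_intron=1.0, mu_intergenic=50.0, sd_intergenic=1.0)


class TestGroupRegions:
    def _cands(self, gaps):
        pos, out = 0, []
        for i, gap in enumerate([0] + gaps):
            pos += gap
            out.append(Seqfrag(IV("chr1", pos, pos + 1000, "+"), 10))
            pos += 1000
        return out

    def test_gap_below_boundary_merges(self):
        regions = e.group_regions(self._cands([17_599]), boundary_kb=17.6)
        assert len(regions) == 1 and regions[0].read_count == 20

    def test_gap_at_boundary_splits(self):
        regions = e.group_regions(self._cands([17_600]), boundary_kb=17.6)
        assert len(regions) == 2

    def test_matches_single_linkage_oracle(self):
        rng = np.random.default_rng(31)
        starts = np.cumsum(rng.integers(500, 40_000, size=40))
        cands = [Seqfrag(IV("chr1", int(s), int(s) + 300, "+"), 7) for s in starts]
        x_kb = 17.6
        regions = e.group_regions(cands, x_kb)
        # oracle: 1-D single linkage at threshold on inter-candidate gaps
        blocks, cur = [], [cands[0]]
        for prev, nxt in zip(cands, cands[1:]):
            gap = nxt.interval.start - prev.interval.end
            if gap < x_kb * 1000:
                cur.append(nxt)
            else:
                blocks.append(cur)
                cur = [nxt]
        blocks.append(cur)
        assert [len(r.members) for r in regions] == [len(b) for b in blocks]

    def test_idempotent(self):
        cands = self._cands([5_000, 40_000, 2_000])
        once = e.group_regions(cands, 17.6)
        frags_again = [Seqfrag(r.interval, max(r.read_count, 2)) for r in once]
        twice = e.group_regions(frags_again, 17.6)
        assert [(r.interval.start, r.interval.end) for r in once] == [
            (r.interval.start, r.interval.end) for r in twice
        ]


class TestRegionStagePresence:
    def _region(self, start, end, strand="+"):
        return e.TranscribedRegion(IV("chr1", start, end, strand), [Seqfrag(IV("chr1", start, end, strand), 6)])

    def test_identical_calls_all_stages(self):
        calls = {s: [self._region(100, 500)] for s in ["a", "b", "c", "d"]}
        presence, part = e.region_stage_presence(calls)
        assert part.pattern_counts["1111"] == 1 and part.universe_size == 1

    def test_single_stage_exclusive(self):
        calls = {"a": [self._region(100, 500)], "b": [], "c": [], "d": []}
        _, part = e.region_stage_presence(calls)
        assert part.pattern_counts["1000"] == 1

    def test_matches_transitive_closure_oracle(self):
        rng = np.random.default_rng(41)
        stages = ["a", "b", "c", "d"]
        calls = {s: [] for s in stages}
        pool = []
        for i in range(60):
            start = int(rng.integers(0, 5000))
            end = start + int(rng.integers(100, 800))
            strand = "+" if rng.random() < 0.5 else "-"
            stage = stages[int(rng.integers(0, 4))]
            calls[stage].append(self._region(start, end, strand))
            pool.append(("chr1", start, end, strand, stage))
        _, part = e.region_stage_presence(calls)
        comps = _overlap_components([(c, s, t, st_) for c, s, t, st_, _ in pool])
        # map back stages per component via matching intervals
        patterns = {}
        for comp in comps:
            members = {(c, s, t, st_) for c, s, t, st_ in comp}
            present = {
                stage
                for c, s, t, st_, stage in pool
                if (c, s, t, st_) in members
            }
            pat = "".join("1" if s in present else "0" for s in stages)
            patterns[pat] = patterns.get(pat, 0) + 1
        for pat, count in patterns.items():
            assert part.pattern_counts[pat] == count
        assert part.universe_size == len(comps)


class TestEndToEndCaller:
    def test_pipeline_on_synthetic_stage(self, small_genome):
        aset, truth = small_genome["annotation"], small_genome["truth"]
        stage = list(small_genome["reads"])[0]
        kept = e.filter_reads(small_genome["reads"][stage]).reads
        regions = e.call_novel_regions(kept, aset)
        for pr in truth.planted_novel:
            if pr.counts.get(stage, 0) > 5:
                assert any(r.interval.overlaps(pr.interval) for r in regions)
            if pr.counts.get(stage, 0) <= 5:
                assert not any(r.interval.overlaps(pr.interval) for r in regions)
        for r in regions:
            assert e.distance_to_nearest_gene(r.interval, aset) >= 20_000

    def test_config_validation(self):
        with pytest.raises(ValueError):
            NovelRegionCallConfig(min_reads=0)
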