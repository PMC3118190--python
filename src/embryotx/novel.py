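"""Detection of putative novel transcribed regions from mapped reads.

The caller works in four steps:

1. *Seqfrags*: same-strand reads with overlapping coordinates (>= 1 bp,
   chained transitively) are merged; clusters of >= 2 reads become seqfrags.
2. *Candidate filter*: seqfrags with more than 5 reads lying at least 20 kb
   from any known gene (across all provided annotation sets) are putative
   novel transcribed regions.
3. *Grouping*: consecutive same-strand candidates separated by an
   intron-like gap are merged into one transcribed region.  A gap is
   intron-like when it is shorter than the decision boundary x* at which the
   normal intron-length density N(2.8, 5.6) kb equals the intergenic-length
   density N(97, 164) kb; with those genome-wide estimates x* = 17.6 kb.
4. *Cross-stage identity*: regions from different stages overlapping >= 1 bp
   on the same strand are the same entity; the resulting presence matrix
   feeds the stage-sharing Venn analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .annotation import AnnotationSet, GenomicInterval, distance_to_nearest_gene
from .stages import VennPartition, venn_partition

__all__ = [
    "Seqfrag",
    "LengthDensityModel",
    "NovelRegionCallConfig",
    "TranscribedRegion",
    "build_seqfrags",
    "filter_candidates",
    "decision_boundary",
    "group_regions",
    "call_novel_regions",
    "region_stage_presence",
]


@dataclass(frozen=True)
class Seqfrag:
    """A maximal cluster of >= 2 same-strand overlapping reads."""

    interval: GenomicInterval
    read_count: int

    def __post_init__(self) -> None:
        if self.read_count < 2:
            raise ValueError("a seqfrag contains at least two reads")

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass(frozen=True)
class LengthDensityModel:
    """Normal length densities for intron and intergenic gaps, in kb."""

    mu_intron: float = 2.8
    sd_intron: float = 5.6
    mu_intergenic: float = 97.0
    sd_intergenic: float = 164.0

    def __post_init__(self) -> None:
        if self.sd_intron <= 0 or self.sd_intergenic <= 0:
            raise ValueError("standard deviations must be > 0")
        if not self.mu_intron < self.mu_intergenic:
            raise ValueError("require mu_intron < mu_intergenic")


@dataclass(frozen=True)
class NovelRegionCallConfig:
    """Support and distance thresholds for candidate calling.

    ``min_reads`` is strictly-greater ("more than 5 reads"); the distance
    filter is inclusive ("at least 20 kb").
    """

    min_reads: int = 5
    min_gene_distance: int = 20_000

    def __post_init__(self) -> None:
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")
        if self.min_gene_distance < 0:
            raise ValueError("min_gene_distance must be >= 0")


@dataclass
class TranscribedRegion:
    """One or more candidate seqfrags merged across intron-like gaps."""

    interval: GenomicInterval
    members: list[Seqfrag]

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def read_count(self) -> int:
        return sum(m.read_count for m in self.members)


def build_seqfrags(reads: pd.DataFrame) -> list[Seqfrag]:
    """Merge reads into seqfrags per chromosome and strand.

    Connected components of the strict-overlap graph (abutting half-open
    intervals do NOT overlap) are found by a sorted sweep; components with
    >= 2 reads become seqfrags spanning the union of their reads, singletons
    are discarded.
    """
    out: list[Seqfrag] = []
    for (chrom, strand), grp in reads.groupby(["chrom", "strand"], sort=True):
        ivs = grp[["start", "end"]].sort_values(["start", "end"]).to_numpy()
        comp_start = comp_end = None
        count = 0
        for start, end in ivs:
            if comp_start is None:
                comp_start, comp_end, count = start, end, 1
            elif start < comp_end:  # strict overlap chains the component
                comp_end = max(comp_end, end)
                count += 1
            else:
                if count >= 2:
                    out.append(
                        Seqfrag(GenomicInterval(chrom, int(comp_start), int(comp_end), strand), count)
                    )
                comp_start, comp_end, count = start, end, 1
        if comp_start is not None and count >= 2:
            out.append(Seqfrag(GenomicInterval(chrom, int(comp_start), int(comp_end), strand), count))
    return out


def filter_candidates(
    seqfrags: Iterable[Seqfrag],
    annotation_sets: AnnotationSet | Sequence[AnnotationSet],
    cfg: NovelRegionCallConfig | None = None,
) -> list[Seqfrag]:
    """Keep seqfrags with read_count > min_reads lying >= min_gene_distance
    from every gene in the union of the annotation sets."""
    cfg = cfg or NovelRegionCallConfig()
    if isinstance(annotation_sets, AnnotationSet):
        annotation_sets = [annotation_sets]
    kept = []
    for sf in seqfrags:
        if sf.read_count <= cfg.min_reads:
            continue
        d = distance_to_nearest_gene(sf.interval, annotation_sets)
        if d >= cfg.min_gene_distance:
            kept.append(sf)
    return kept


def decision_boundary(model: LengthDensityModel | None = None) -> float:
    """Gap length x* (kb) where the two normal length densities are equal.

    Equating log N(x; mu1, s1) = log N(x; mu2, s2) gives a quadratic in x;
    the root lying strictly between the two means is the boundary.  Gaps
    below x* are intron-like (merge), at or above intergenic (split).  With
    equal sds the quadratic degenerates to the midpoint of the means.
    """
    m = model or LengthDensityModel()
    mu1, s1, mu2, s2 = m.mu_intron, m.sd_intron, m.mu_intergenic, m.sd_intergenic
    a = 1.0 / s1**2 - 1.0 / s2**2
    b = -2.0 * (mu1 / s1**2 - mu2 / s2**2)
    c = mu1**2 / s1**2 - mu2**2 / s2**2 + 2.0 * math.log(s1 / s2)
    if abs(a) < 1e-300:  # equal variances: linear equation
        roots = [-c / b]
    else:
        disc = b * b - 4.0 * a * c
        if disc < 0:
            raise ValueError("no real root of the equal-density equation")
        sq = math.sqrt(disc)
        roots = [(-b - sq) / (2.0 * a), (-b + sq) / (2.0 * a)]
    between = [r for r in roots if mu1 < r < mu2]
    if not between:
        raise ValueError(
            f"no equal-density root between the means {mu1} and {mu2} (roots: {roots})"
        )
    x = between[0]
    # verify: densities equal to numerical precision at the root
    log_ratio = (
        -((x - mu1) ** 2) / (2 * s1**2)
        - math.log(s1)
        + ((x - mu2) ** 2) / (2 * s2**2)
        + math.log(s2)
    )
    assert abs(log_ratio) < 1e-9, f"equal-density residual {log_ratio}"
    return x


def group_regions(candidates: Iterable[Seqfrag], boundary_kb: float) -> list[TranscribedRegion]:
    """Merge consecutive same-strand candidates separated by intron-like gaps.

    Gaps strictly below ``boundary_kb`` (converted to bp) merge transitively;
    a gap at or above the boundary is intergenic and starts a new region.
    """
    boundary_bp = boundary_kb * 1000.0
    by_key: dict[tuple, list[Seqfrag]] = {}
    for sf in candidates:
        by_key.setdefault((sf.interval.chrom, sf.strand), []).append(sf)
    regions: list[TranscribedRegion] = []
    for (chrom, strand), frags in sorted(by_key.items()):
        frags.sort(key=lambda s: (s.interval.start, s.interval.end))
        block: list[Seqfrag] = [frags[0]]
        block_end = frags[0].interval.end
        for sf in frags[1:]:
            gap = sf.interval.start - block_end
            if gap < boundary_bp:
                block.append(sf)
                block_end = max(block_end, sf.interval.end)
            else:
                regions.append(_make_region(chrom, strand, block))
                block = [sf]
                block_end = sf.interval.end
        regions.append(_make_region(chrom, strand, block))
    return regions


def _make_region(chrom: str, strand: str, members: list[Seqfrag]) -> TranscribedRegion:
    start = min(m.interval.start for m in members)
    end = max(m.interval.end for m in members)
    return TranscribedRegion(GenomicInterval(chrom, start, end, strand), list(members))


def call_novel_regions(
    reads: pd.DataFrame,
    annotation_sets: AnnotationSet | Sequence[AnnotationSet],
    cfg: NovelRegionCallConfig | None = None,
    model: LengthDensityModel | None = None,
    boundary_kb: float | None = None,
) -> list[TranscribedRegion]:
    """Full caller for one stage: seqfrags -> support/distance filter -> grouping.

    The decision boundary is recomputed from the length-density model unless
    ``boundary_kb`` overrides it.
    """
    if boundary_kb is None:
        boundary_kb = decision_boundary(model)
    frags = build_seqfrags(reads)
    candidates = filter_candidates(frags, annotation_sets, cfg)
    return group_regions(candidates, boundary_kb)


# ---------------------------------------------------------------------------
# Cross-stage identity and the novel-region Venn
# ---------------------------------------------------------------------------


def region_stage_presence(
    stage_regions: dict[str, list[TranscribedRegion]],
) -> tuple[pd.DataFrame, VennPartition]:
    """Identify regions across stages and build the presence matrix.

    Regions from any stages overlapping >= 1 bp on the same strand belong to
    one entity (transitive closure).  Returns a boolean entities x stages
    frame (entity ids ``chrom:start-end(strand)`` of the merged span) and its
    Venn partition.
    """
    stages = list(stage_regions)
    pool: list[tuple[str, str, int, int, str]] = []  # chrom, strand, start, end, stage
    for stage, regions in stage_regions.items():
        for r in regions:
            pool.append((r.interval.chrom, r.strand, r.interval.start, r.interval.end, stage))
    # sweep per chrom/strand: overlapping intervals chain into one entity
    entities: list[dict] = []
    by_key: dict[tuple, list[tuple]] = {}
    for rec in pool:
        by_key.setdefault(rec[:2], []).append(rec)
    for (chrom, strand), recs in sorted(by_key.items()):
        recs.sort(key=lambda r: (r[2], r[3]))
        cur = None
        for _c, _s, start, end, stage in recs:
            if cur is not None and start < cur["end"]:
                cur["end"] = max(cur["end"], end)
                cur["stages"].add(stage)
            else:
                cur = {"chrom": chrom, "strand": strand, "start": start, "end": end, "stages": {stage}}
                entities.append(cur)
    rows = {}
    for e in entities:
        eid = f"{e['chrom']}:{e['start']}-{e['end']}({e['strand']})"
        rows[eid] = {s: (s in e["stages"]) for s in stages}
    presence = pd.DataFrame.from_dict(rows, orient="index", columns=stages, dtype=bool)
    if presence.empty:
        presence = pd.DataFrame(columns=stages, dtype=bool)
    return presence, venn_partition(presence)


def regions_to_bed6(regions: Iterable[TranscribedRegion], path: str) -> None:
    """Write regions as BED6 with the read count in the score column."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            fh.write(
                "\t".join(
                    [
                        r.interval.chrom,
                        str(r.interval.start),
                        str(r.interval.end),
                        f"region_{i + 1}",
                        str(r.read_count),
                        r.strand,
                    ]
                )
                + "\n"
            )
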