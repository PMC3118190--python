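"""Read filtering, exon-model counting, RPKM and the mapping summary.

Mapped reads arrive as a DataFrame in BED6-like form (``chrom, start, end,
name, score, strand``) plus an ``n_hits`` column giving the number of genomic
placements of the read.  Quantification proceeds: filter (unique placement,
alignment score >= 24 on the +1 match / -1 mismatch scale) -> count against
exon models (>= 1 bp exon overlap, strand-matched, multi-gene reads set
aside as ambiguous) -> RPKM = 1e9 * C / (N * L) -> detection at >= 2 reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import AnnotationSet, exon_model_length

__all__ = [
    "READ_COLUMNS",
    "ReadFilterConfig",
    "FilterResult",
    "CountResult",
    "ExpressionTable",
    "MappingSummary",
    "filter_reads",
    "count_reads",
    "rpkm",
    "detect",
    "quantify_stages",
    "mapping_summary",
    "read_bed6_reads",
    "write_bed6_reads",
]

READ_COLUMNS = ["chrom", "start", "end", "name", "score", "strand", "n_hits"]

DEFAULT_MIN_SCORE = 24
DEFAULT_DETECTION_CUTOFF = 2


@dataclass(frozen=True)
class ReadFilterConfig:
    """Alignment-quality filter: unique placement and minimum alignment score."""

    min_score: int = DEFAULT_MIN_SCORE
    unique_only: bool = True

    def __post_init__(self) -> None:
        if self.min_score < 0:
            raise ValueError("min_score must be >= 0")


@dataclass
class FilterResult:
    reads: pd.DataFrame
    n_input: int
    n_removed_multihit: int
    n_removed_lowscore: int

    @property
    def n_kept(self) -> int:
        return len(self.reads)


def filter_reads(reads: pd.DataFrame, cfg: ReadFilterConfig | None = None) -> FilterResult:
    """Keep uniquely placed reads with score >= ``cfg.min_score`` (boundary inclusive).

    A read failing both criteria is tallied under multi-hit; the two removal
    counts therefore sum to the number removed.
    """
    cfg = cfg or ReadFilterConfig()
    multi = (reads["n_hits"] > 1) if cfg.unique_only else pd.Series(False, index=reads.index)
    lowscore = reads["score"] < cfg.min_score
    kept = reads[~multi & ~lowscore].reset_index(drop=True)
    return FilterResult(
        reads=kept,
        n_input=len(reads),
        n_removed_multihit=int(multi.sum()),
        n_removed_lowscore=int((lowscore & ~multi).sum()),
    )


@dataclass
class CountResult:
    """Per-gene read counts plus the conservation tallies."""

    counts: pd.Series  # indexed by gene_id
    n_assigned: int
    n_ambiguous: int  # read overlapped exons of > 1 gene
    n_unassigned: int  # read overlapped no exon

    @property
    def n_total(self) -> int:
        return self.n_assigned + self.n_ambiguous + self.n_unassigned


def _exon_trees(annotation: AnnotationSet, stranded: bool) -> dict[tuple, IntervalTree]:
    trees: dict[tuple, IntervalTree] = {}
    for g in annotation:
        for ex in g.exons:
            key = (g.chrom, g.strand) if stranded else (g.chrom,)
            trees.setdefault(key, IntervalTree()).addi(ex.start, ex.end, g.gene_id)
    return trees


def count_reads(
    reads: pd.DataFrame, annotation: AnnotationSet, stranded: bool = True
) -> CountResult:
    """Count filtered reads against exon models.

    A read is assigned to a gene iff it overlaps >= 1 bp of any exon of that
    gene (on the same strand when ``stranded``).  Reads hitting exons of more
    than one gene are assigned to none and tallied as ambiguous; each read
    counts at most once.
    """
    trees = _exon_trees(annotation, stranded)
    counts = {g.gene_id: 0 for g in annotation}
    n_assigned = n_ambiguous = n_unassigned = 0
    cols = ["chrom", "start", "end", "strand"]
    for chrom, start, end, strand in reads[cols].itertuples(index=False):
        key = (chrom, strand) if stranded else (chrom,)
        tree = trees.get(key)
        hits = {iv.data for iv in tree.overlap(start, end)} if tree is not None else set()
        if len(hits) == 1:
            counts[next(iter(hits))] += 1
            n_assigned += 1
        elif len(hits) > 1:
            n_ambiguous += 1
        else:
            n_unassigned += 1
    return CountResult(
        counts=pd.Series(counts, name="count", dtype=int),
        n_assigned=n_assigned,
        n_ambiguous=n_ambiguous,
        n_unassigned=n_unassigned,
    )


def rpkm(C: float, L: int, N: int) -> float:
    """Reads per kilobase of exon model per million mapped reads: 1e9*C/(N*L)."""
    if L <= 0:
        raise ValueError("exon model length L must be > 0")
    if N <= 0:
        raise ValueError("library size N must be > 0")
    return 1e9 * C / (N * L)


def detect(counts: pd.DataFrame, cutoff: int = DEFAULT_DETECTION_CUTOFF) -> pd.DataFrame:
    """Detection flags: a gene is expressed in a stage iff its count >= cutoff.

    With the default cutoff of 2, genes with 0 or 1 read are not expressed.
    """
    return counts >= cutoff


@dataclass
class ExpressionTable:
    """Per-gene, per-stage counts, RPKM and detection flags.

    ``counts`` and ``rpkm`` are genes x stages DataFrames; ``library_sizes``
    holds the per-stage N used in the RPKM denominator; ``exon_lengths`` the
    per-gene exon-model L in bp.
    """

    counts: pd.DataFrame
    rpkm: pd.DataFrame
    detected: pd.DataFrame
    library_sizes: pd.Series
    exon_lengths: pd.Series
    cutoff: int = DEFAULT_DETECTION_CUTOFF
    count_results: dict[str, CountResult] = field(default_factory=dict)
    filter_results: dict[str, FilterResult] = field(default_factory=dict)

    @property
    def stages(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    def to_tsv(self, path: str) -> None:
        out = pd.concat(
            {"count": self.counts, "rpkm": self.rpkm, "detected": self.detected.astype(int)},
            axis=1,
        )
        out.columns = [f"{stage}_{kind}" for kind, stage in out.columns]
        out.insert(0, "exon_model_bp", self.exon_lengths)
        out.to_csv(path, sep="\t", index_label="gene_id")


def quantify_stages(
    stage_reads: dict[str, pd.DataFrame],
    annotation: AnnotationSet,
    filter_cfg: ReadFilterConfig | None = None,
    cutoff: int = DEFAULT_DETECTION_CUTOFF,
    stranded: bool = True,
    library_sizes: dict[str, int] | None = None,
) -> ExpressionTable:
    """Run filter -> count -> RPKM -> detect for each stage.

    ``library_sizes`` overrides the RPKM denominator N per stage; by default N
    is the number of reads that survive filtering (the reads entering
    counting), mirroring the use of uniquely mapped reads.
    """
    filter_cfg = filter_cfg or ReadFilterConfig()
    gene_ids = annotation.gene_ids()
    L = pd.Series({g.gene_id: exon_model_length(g) for g in annotation}, name="exon_model_bp")
    counts = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"), dtype=int)
    libs: dict[str, int] = {}
    count_results: dict[str, CountResult] = {}
    filter_results: dict[str, FilterResult] = {}
    for stage, reads in stage_reads.items():
        fres = filter_reads(reads, filter_cfg)
        cres = count_reads(fres.reads, annotation, stranded=stranded)
        # conservation: every filtered read lands in exactly one tally
        assert cres.n_total == fres.n_kept
        counts[stage] = cres.counts.reindex(gene_ids)
        libs[stage] = library_sizes[stage] if library_sizes else fres.n_kept
        count_results[stage] = cres
        filter_results[stage] = fres
    rpkm_df = pd.DataFrame(index=counts.index)
    for stage in counts.columns:
        N = libs[stage]
        if N <= 0:
            raise ValueError(f"stage {stage!r}: empty library after filtering")
        rpkm_df[stage] = 1e9 * counts[stage] / (N * L.reindex(counts.index))
    return ExpressionTable(
        counts=counts,
        rpkm=rpkm_df,
        detected=detect(counts, cutoff),
        library_sizes=pd.Series(libs, name="library_size"),
        exon_lengths=L.reindex(counts.index),
        cutoff=cutoff,
        count_results=count_results,
        filter_results=filter_results,
    )


# ---------------------------------------------------------------------------
# Mapping summary (whole-percent arithmetic of the sequencing run table)
# ---------------------------------------------------------------------------


@dataclass
class MappingSummary:
    """Per-stage read tallies and their whole-percent ratios."""

    table: pd.DataFrame  # rows: stages; columns: tallies and percentages

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index_label="stage")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def mapping_summary(tallies: dict[str, dict[str, int]]) -> MappingSummary:
    """Whole-percent mapping summary from per-stage read tallies.

    ``tallies`` maps stage -> dict with keys ``total``, ``mapped``,
    ``unique`` and optionally ``filtered``.  Percentages are rounded to the
    nearest whole percent: mapped/total and unique/mapped.
    """
    rows = {}
    for stage, t in tallies.items():
        total, mapped, unique = t["total"], t["mapped"], t["unique"]
        if not (0 <= unique <= mapped <= total):
            raise ValueError(
                f"stage {stage!r}: require 0 <= unique <= mapped <= total, "
                f"got unique={unique} mapped={mapped} total={total}"
            )
        rows[stage] = {
            "total_reads": total,
            "reads_mapped": mapped,
            "reads_filtered": t.get("filtered", 0),
            "reads_unique": unique,
            "pct_mapped": _round_half_up(100 * mapped / total) if total else 0,
            "pct_unique": _round_half_up(100 * unique / mapped) if mapped else 0,
        }
    return MappingSummary(table=pd.DataFrame.from_dict(rows, orient="index"))


# ---------------------------------------------------------------------------
# Read I/O: BED6 + hit-count sidecar
# ---------------------------------------------------------------------------


def write_bed6_reads(reads: pd.DataFrame, bed_path: str, hits_path: str | None = None) -> None:
    """Write reads as BED6 (score column = alignment score) plus an n_hits sidecar TSV."""
    reads[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        bed_path, sep="\t", header=False, index=False
    )
    if hits_path is not None:
        reads[["name", "n_hits"]].to_csv(hits_path, sep="\t", header=False, index=False)


def write_sam_reads(reads: pd.DataFrame, path: str, chrom_lengths: dict[str, int]) -> None:
    """Write reads as minimal unsorted SAM (flag 0/16 for strand, NH tag for hits).

    The alignment score goes in the MAPQ column capped at 254; sequence and
    quality are omitted ('*') since only coordinates enter the analysis.
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in chrom_lengths.items()],
    }
    tid = {c: i for i, c in enumerate(chrom_lengths)}
    with pysam.AlignmentFile(path, "w", header=header) as fh:
        for row in reads.itertuples(index=False):
            a = pysam.AlignedSegment(fh.header)
            a.query_name = row.name
            a.flag = 16 if row.strand == "-" else 0
            a.reference_id = tid[row.chrom]
            a.reference_start = int(row.start)
            a.mapping_quality = min(int(row.score), 254) if row.score >= 0 else 0
            a.cigarstring = f"{int(row.end) - int(row.start)}M"
            a.set_tag("NH", int(row.n_hits))
            fh.write(a)


def read_bed6_reads(bed_path: str, hits_path: str | None = None) -> pd.DataFrame:
    """Read BED6 reads; n_hits comes from the sidecar TSV (default 1)."""
    reads = pd.read_csv(
        bed_path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str},
    )
    if hits_path is not None:
        hits = pd.read_csv(hits_path, sep="\t", header=None, names=["name", "n_hits"], dtype={"name": str})
        reads = reads.merge(hits, on="name", how="left")
        reads["n_hits"] = reads["n_hits"].fillna(1).astype(int)
    else:
        reads["n_hits"] = 1
    return reads[READ_COLUMNS]
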