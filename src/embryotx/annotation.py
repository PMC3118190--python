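"""Genomic interval arithmetic and gene-annotation I/O.

All coordinates are 0-based, half-open ``[start, end)`` internally.  GTF
(1-based, inclusive) is converted at the file boundary and nowhere else.
A :class:`GeneModel` is the unit of quantification: the union of its exons
is the "exon model" whose length is the *L* in RPKM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "AnnotationSet",
    "exon_model_length",
    "distance_to_nearest_gene",
    "read_annotation",
    "write_annotation",
]

#: Sentinel distance returned when no gene exists on the query chromosome.
NO_GENE_DISTANCE = math.inf


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Strict >= 1 bp overlap; abutting half-open intervals do not overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """A known transcript: sorted, disjoint exons on one strand of one chromosome."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    accession: str = ""

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: no exons")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        prev_end = -1
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise ValueError(
                    f"gene {self.gene_id}: exon on {ex.chrom}, gene on {self.chrom}"
                )
            if ex.strand != self.strand:
                raise ValueError(f"gene {self.gene_id}: exon strand mismatch")
            if ex.start < prev_end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
            prev_end = ex.end

    @property
    def span(self) -> GenomicInterval:
        """First-exon start to last-exon end (the gene span used for distances)."""
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out


@dataclass
class AnnotationSet:
    """A named collection of gene models (e.g. source='ucsc' or 'ensembl')."""

    source: str = ""
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r} in set {self.source!r}")
            seen.add(g.gene_id)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def by_chrom(self) -> dict[str, list[GeneModel]]:
        out: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            out.setdefault(g.chrom, []).append(g)
        for lst in out.values():
            lst.sort(key=lambda g: g.span.start)
        return out

    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]


def exon_model_length(gene: GeneModel) -> int:
    """Total length in bp of the union of a gene's exons (the RPKM *L*).

    Exons are disjoint by construction, so the union length is the sum.
    """
    return sum(len(ex) for ex in gene.exons)


def distance_to_nearest_gene(
    iv: GenomicInterval, sets: AnnotationSet | Iterable[AnnotationSet]
) -> float:
    """Minimum gap in bp between ``iv`` and any gene span across annotation sets.

    Strand-agnostic; 0 when the interval overlaps or abuts a gene span.
    Returns ``math.inf`` when no gene lies on the interval's chromosome.
    """
    if isinstance(sets, AnnotationSet):
        sets = [sets]
    best = NO_GENE_DISTANCE
    for aset in sets:
        for g in aset:
            if g.chrom != iv.chrom:
                continue
            sp = g.span
            if iv.start >= sp.end:
                d = iv.start - sp.end
            elif sp.start >= iv.end:
                d = sp.start - iv.end
            else:
                d = 0
            if d < best:
                best = d
    return best


# ---------------------------------------------------------------------------
# BED12 / GTF I/O
# ---------------------------------------------------------------------------

_BED12_NFIELDS = 12


def _gene_to_bed12(gene: GeneModel) -> str:
    span = gene.span
    name = gene.gene_id if not gene.accession else f"{gene.gene_id}|{gene.accession}"
    sizes = ",".join(str(len(ex)) for ex in gene.exons) + ","
    starts = ",".join(str(ex.start - span.start) for ex in gene.exons) + ","
    fields = [
        gene.chrom,
        str(span.start),
        str(span.end),
        name,
        "0",
        gene.strand,
        str(span.start),
        str(span.end),
        "0",
        str(len(gene.exons)),
        sizes,
        starts,
    ]
    return "\t".join(fields)


def _bed12_to_gene(line: str, lineno: int) -> GeneModel:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < _BED12_NFIELDS:
        raise ValueError(f"line {lineno}: expected {_BED12_NFIELDS} BED12 fields, got {len(fields)}")
    chrom, start_s, end_s, name, _score, strand = fields[:6]
    if strand not in ("+", "-"):
        raise ValueError(f"line {lineno}: unknown strand {strand!r}")
    try:
        chrom_start = int(start_s)
        n_blocks = int(fields[9])
        sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
    except ValueError as exc:
        raise ValueError(f"line {lineno}: malformed BED12 numeric field: {exc}") from None
    if len(sizes) != n_blocks or len(offsets) != n_blocks:
        raise ValueError(f"line {lineno}: blockCount {n_blocks} does not match block lists")
    gene_id, _, accession = name.partition("|")
    exons = [
        GenomicInterval(chrom, chrom_start + off, chrom_start + off + size, strand)
        for off, size in zip(offsets, sizes)
    ]
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, exons=exons, accession=accession)


def _gene_to_gtf(gene: GeneModel) -> list[str]:
    tx = gene.accession or gene.gene_id
    attrs = f'gene_id "{gene.gene_id}"; transcript_id "{tx}";'
    return [
        "\t".join(
            [
                gene.chrom,
                "embryotx",
                "exon",
                str(ex.start + 1),  # GTF is 1-based inclusive
                str(ex.end),
                ".",
                gene.strand,
                ".",
                attrs,
            ]
        )
        for ex in gene.exons
    ]


def _parse_gtf_attrs(raw: str, lineno: int) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, val = chunk.partition(" ")
        out[key] = val.strip().strip('"')
    if "gene_id" not in out:
        raise ValueError(f"line {lineno}: GTF attributes missing gene_id")
    return out


def write_annotation(aset: AnnotationSet, path: str, format: str = "bed12") -> None:
    """Write an annotation set as BED12 or GTF (exon features only)."""
    with open(path, "w") as fh:
        if format == "bed12":
            for g in aset:
                fh.write(_gene_to_bed12(g) + "\n")
        elif format == "gtf":
            for g in aset:
                for line in _gene_to_gtf(g):
                    fh.write(line + "\n")
        else:
            raise ValueError(f"unknown annotation format {format!r}")


def read_annotation(path: str, format: str = "bed12", source: str = "") -> AnnotationSet:
    """Read BED12 or GTF into an :class:`AnnotationSet`.

    GTF coordinates (1-based inclusive) are converted to the internal 0-based
    half-open convention on input.  Malformed lines fail with their number.
    """
    genes: list[GeneModel] = []
    if format == "bed12":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                genes.append(_bed12_to_gene(line, lineno))
    elif format == "gtf":
        exons_by_gene: dict[str, dict] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) != 9:
                    raise ValueError(f"line {lineno}: expected 9 GTF fields, got {len(fields)}")
                chrom, _src, feature, start_s, end_s, _sc, strand, _fr, attrs_raw = fields
                if feature != "exon":
                    continue
                if strand not in ("+", "-"):
                    raise ValueError(f"line {lineno}: unknown strand {strand!r}")
                try:
                    start = int(start_s) - 1  # to 0-based half-open
                    end = int(end_s)
                except ValueError:
                    raise ValueError(f"line {lineno}: malformed GTF coordinates") from None
                attrs = _parse_gtf_attrs(attrs_raw, lineno)
                gid = attrs["gene_id"]
                rec = exons_by_gene.setdefault(
                    gid,
                    {
                        "chrom": chrom,
                        "strand": strand,
                        "exons": [],
                        "accession": attrs.get("transcript_id", ""),
                    },
                )
                rec["exons"].append(GenomicInterval(chrom, start, end, strand))
        for gid, rec in exons_by_gene.items():
            acc = rec["accession"] if rec["accession"] != gid else ""
            genes.append(
                GeneModel(
                    gene_id=gid,
                    chrom=rec["chrom"],
                    strand=rec["strand"],
                    exons=rec["exons"],
                    accession=acc,
                )
            )
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    return AnnotationSet(source=source, genes=genes)
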