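"""Synthetic genome, read and Ct-table generation with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
multi-chromosome genome whose intron lengths follow a truncated normal with
mean 2.8 kb (sd 5.6 kb) and whose intergenic gaps follow a truncated normal
with mean 97 kb (sd 164 kb); four developmental stages with per-gene
negative-binomial read counts around trend-shaped means (increasing,
decreasing or steady across stages); planted intergenic transcription for
the novel-region caller; and configurable fractions of multi-hit and
low-score reads to exercise alignment filtering.  Everything is
deterministic under the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation import AnnotationSet, GeneModel, GenomicInterval, distance_to_nearest_gene
from .quantify import READ_COLUMNS

__all__ = [
    "GenomeSpec",
    "PlantedRegion",
    "TruthTable",
    "generate_annotation",
    "make_truth",
    "generate_reads",
    "generate_ct_table",
    "truncated_normal_moments",
]

STAGES = ("1-cell", "16-cell", "512-cell", "50pct-epiboly")
TREND_PROFILES = {
    "increasing": (1.0, 3.0, 9.0, 27.0),
    "decreasing": (27.0, 9.0, 3.0, 1.0),
    "steady": (1.0, 1.0, 1.0, 1.0),
}


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of the synthetic genome layout.

    Length densities default to the genome-wide estimates used by the
    novel-region decision rule (intron 2.8/5.6 kb, intergenic 97/164 kb),
    truncated at floors so sampled lengths stay positive.
    """

    chrom_names: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 9))
    chrom_lengths: tuple[int, ...] = (24_000_000,) * 8
    n_genes: int = 600
    exons_per_gene: tuple[int, int] = (4, 8)
    exon_length: tuple[int, int] = (100, 300)
    mu_intron: float = 2800.0
    sd_intron: float = 5600.0
    mu_intergenic: float = 97_000.0
    sd_intergenic: float = 164_000.0
    intron_floor: int = 50
    intergenic_floor: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be > 0")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        lo, hi = self.exons_per_gene
        if not (1 <= lo <= hi):
            raise ValueError("exons_per_gene range invalid")
        lo, hi = self.exon_length
        if not (1 <= lo <= hi):
            raise ValueError("exon_length range invalid")
        for v in (self.mu_intron, self.sd_intron, self.mu_intergenic, self.sd_intergenic):
            if v <= 0:
                raise ValueError("length-density parameters must be > 0")


def _trunc_normal(rng: np.random.Generator, mu: float, sd: float, floor: float, size: int) -> np.ndarray:
    """Lower-truncated normal samples, rounded to integer bp."""
    a = (floor - mu) / sd
    draws = sps.truncnorm.rvs(a, np.inf, loc=mu, scale=sd, size=size, random_state=rng)
    return np.maximum(np.round(draws), floor).astype(int)


def truncated_normal_moments(mu: float, sd: float, floor: float) -> tuple[float, float]:
    """Mean and sd of a normal truncated below at ``floor`` (closed form)."""
    a = (floor - mu) / sd
    mean, var = sps.truncnorm.stats(a, np.inf, loc=mu, scale=sd, moments="mv")
    return float(mean), float(math.sqrt(var))


def generate_annotation(spec: GenomeSpec) -> AnnotationSet:
    """Lay genes left-to-right per chromosome with sampled gaps and introns.

    Successive-gene gaps come from the truncated intergenic density, intron
    lengths from the truncated intron density, exon lengths uniformly from
    the configured range.  Fails naming the chromosome when a gene would
    overflow it.
    """
    rng = np.random.default_rng(spec.seed)
    per_chrom = _split_counts(spec.n_genes, len(spec.chrom_names))
    genes: list[GeneModel] = []
    gi = 0
    for chrom, clen, n_here in zip(spec.chrom_names, spec.chrom_lengths, per_chrom):
        pos = 0
        for _ in range(n_here):
            gi += 1
            gap = int(_trunc_normal(rng, spec.mu_intergenic, spec.sd_intergenic, spec.intergenic_floor, 1)[0])
            n_ex = int(rng.integers(spec.exons_per_gene[0], spec.exons_per_gene[1] + 1))
            ex_lens = rng.integers(spec.exon_length[0], spec.exon_length[1] + 1, size=n_ex)
            in_lens = (
                _trunc_normal(rng, spec.mu_intron, spec.sd_intron, spec.intron_floor, n_ex - 1)
                if n_ex > 1
                else np.array([], dtype=int)
            )
            strand = "+" if rng.random() < 0.5 else "-"
            start = pos + gap
            exons = []
            cursor = start
            for j, el in enumerate(ex_lens):
                exons.append((cursor, cursor + int(el)))
                cursor += int(el)
                if j < n_ex - 1:
                    cursor += int(in_lens[j])
            end = exons[-1][1]
            if end > clen:
                raise ValueError(
                    f"chromosome {chrom}: gene g{gi:04d} would end at {end} > length {clen}"
                )
            genes.append(
                GeneModel(
                    gene_id=f"g{gi:04d}",
                    chrom=chrom,
                    strand=strand,
                    exons=[GenomicInterval(chrom, s, e, strand) for s, e in exons],
                    accession=f"NM_{900000 + gi}",
                )
            )
            pos = end
    return AnnotationSet(source="synthetic", genes=genes)


def _split_counts(n: int, k: int) -> list[int]:
    base, extra = divmod(n, k)
    return [base + (1 if i < extra else 0) for i in range(k)]


@dataclass(frozen=True)
class PlantedRegion:
    """A planted intergenic transcription site with per-stage read counts."""

    interval: GenomicInterval
    counts: dict[str, int]  # stage -> reads planted (0 = absent)

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass
class TruthTable:
    """Ground truth behind one synthetic data set."""

    trend_labels: dict[str, str]  # gene_id -> increasing|decreasing|steady
    stage_means: pd.DataFrame  # genes x stages expected mean read counts
    planted_novel: list[PlantedRegion]
    ambiguous_fraction: float = 0.10
    lowscore_fraction: float = 0.05

    def __post_init__(self) -> None:
        bad = set(self.trend_labels.values()) - set(TREND_PROFILES)
        if bad:
            raise ValueError(f"unknown trend label(s): {sorted(bad)}")
        if set(self.trend_labels) != set(self.stage_means.index):
            raise ValueError("trend labels must cover exactly the genes in stage_means")

    def genes_with_trend(self, trend: str) -> list[str]:
        return [g for g, t in self.trend_labels.items() if t == trend]

    def to_tsv(self, path: str) -> None:
        out = self.stage_means.copy()
        out.insert(0, "trend", pd.Series(self.trend_labels))
        out.to_csv(path, sep="\t", index_label="gene_id")


# default per-stage read counts for planted regions; "all" = every stage
DEFAULT_PLANTED_COUNTS: tuple[dict, ...] = (
    {"all": 8},
    {"all": 12},
    {"all": 20},
    {"all": 25},
    {"all": 6},   # boundary: "more than 5" is satisfied at 6
    {"all": 3},   # below support threshold: must never be called
    {"stage_index": 0, "count": 10},   # first-stage exclusive
    {"stage_index": 3, "count": 15},   # last-stage exclusive
)


def make_truth(
    annotation: AnnotationSet,
    stages: tuple[str, ...] = STAGES,
    seed: int = 0,
    increasing_fraction: float = 0.15,
    decreasing_fraction: float = 0.15,
    planted_counts: tuple[dict, ...] = DEFAULT_PLANTED_COUNTS,
    planted_width: int = 1000,
    clearance: int = 21_000,
    ambiguous_fraction: float = 0.10,
    lowscore_fraction: float = 0.05,
    chrom_lengths: dict[str, int] | None = None,
) -> TruthTable:
    """Assign trend labels, per-stage mean counts and planted novel regions.

    Regulated genes follow a geometric profile across stages (doubling per
    stage for increasing, halving for decreasing) around a lognormal base
    abundance; steady genes sit at a constant lognormal level.  Planted
    regions are centred in intergenic gaps wide enough to keep ``clearance``
    bp (> the 20 kb filter) from every gene span.
    """
    rng = np.random.default_rng(seed)
    gene_ids = annotation.gene_ids()
    n = len(gene_ids)
    order = rng.permutation(n)
    n_inc = int(round(increasing_fraction * n))
    n_dec = int(round(decreasing_fraction * n))
    labels: dict[str, str] = {}
    for idx, gpos in enumerate(order):
        gid = gene_ids[gpos]
        labels[gid] = "increasing" if idx < n_inc else "decreasing" if idx < n_inc + n_dec else "steady"

    if len(stages) != len(TREND_PROFILES["increasing"]):
        # profiles are defined over four stages; interpolate geometrically otherwise
        raise ValueError("trend profiles are defined for exactly four stages")
    means = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"), columns=list(stages), dtype=float)
    for gid in gene_ids:
        trend = labels[gid]
        if trend == "steady":
            base = float(rng.lognormal(mean=math.log(50.0), sigma=1.2))
        else:
            base = float(rng.lognormal(mean=math.log(50.0), sigma=0.6))
        means.loc[gid] = np.array(TREND_PROFILES[trend]) * base

    planted = _plant_regions(
        annotation, stages, rng, planted_counts, planted_width, clearance, chrom_lengths
    )
    truth = TruthTable(
        trend_labels=labels,
        stage_means=means,
        planted_novel=planted,
        ambiguous_fraction=ambiguous_fraction,
        lowscore_fraction=lowscore_fraction,
    )
    for pr in truth.planted_novel:  # planted-novel safety, asserted on every build
        assert distance_to_nearest_gene(pr.interval, annotation) >= 20_000
    return truth


def _plant_regions(
    annotation: AnnotationSet,
    stages: tuple[str, ...],
    rng: np.random.Generator,
    planted_counts: tuple[dict, ...],
    width: int,
    clearance: int,
    chrom_lengths: dict[str, int] | None,
) -> list[PlantedRegion]:
    # intergenic gaps between consecutive gene spans (chromosome ends excluded
    # unless lengths are provided)
    gaps: list[tuple[str, int, int]] = []
    for chrom, genes in annotation.by_chrom().items():
        spans = [g.span for g in genes]
        for a, b in zip(spans, spans[1:]):
            gaps.append((chrom, a.end, b.start))
        if chrom_lengths and spans:
            gaps.append((chrom, spans[-1].end, chrom_lengths[chrom]))
    need = 2 * clearance + width
    eligible = [g for g in gaps if g[2] - g[1] >= need]
    if len(eligible) < len(planted_counts):
        raise ValueError(
            f"only {len(eligible)} intergenic gaps can host a planted region; "
            f"{len(planted_counts)} requested"
        )
    picks = rng.choice(len(eligible), size=len(planted_counts), replace=False)
    out: list[PlantedRegion] = []
    for spec_dict, gap_i in zip(planted_counts, picks):
        chrom, lo, hi = eligible[int(gap_i)]
        mid = (lo + hi) // 2
        start = mid - width // 2
        strand = "+" if rng.random() < 0.5 else "-"
        if "all" in spec_dict:
            counts = {s: int(spec_dict["all"]) for s in stages}
        else:
            counts = {s: 0 for s in stages}
            counts[stages[spec_dict["stage_index"]]] = int(spec_dict["count"])
        out.append(PlantedRegion(GenomicInterval(chrom, start, start + width, strand), counts))
    return out


def generate_reads(
    annotation: AnnotationSet,
    truth: TruthTable,
    stages: tuple[str, ...] = STAGES,
    seed: int = 0,
    read_length: int = 50,
    dispersion: float | None = 10.0,
    background_reads: int = 500,
    require_four_stages: bool = True,
) -> tuple[dict[str, pd.DataFrame], dict[str, int]]:
    """Generate per-stage stranded reads around the truth means.

    Per gene and stage the read count is negative binomial around the truth
    mean (``dispersion=None`` gives the Poisson limit); reads of length
    ``read_length`` are placed uniformly within the gene's exon model on the
    gene strand.  Planted regions receive exactly their stated counts as
    clean unique high-score reads tiled with overlapping offsets.  The
    stated fractions of gene/background reads are emitted multi-hit or with
    alignment score below 24.  Returns the reads and per-stage library sizes.
    """
    if require_four_stages and len(stages) != 4:
        raise ValueError(
            f"the pipeline is four-stage by construction, got {len(stages)} stages "
            "(pass require_four_stages=False to override)"
        )
    rng = np.random.default_rng(seed)
    genes = {g.gene_id: g for g in annotation}
    chrom_sizes = _chrom_extents(annotation, truth)
    out: dict[str, pd.DataFrame] = {}
    lib: dict[str, int] = {}
    for stage in stages:
        rows: list[tuple] = []
        frames: list[pd.DataFrame] = []
        ridx = 0
        for gid, gene in genes.items():
            mean = float(truth.stage_means.loc[gid, stage]) if stage in truth.stage_means else 0.0
            count = _draw_count(rng, mean, dispersion)
            if count == 0:
                continue
            starts = _place_in_exon_model(rng, gene, read_length, count)
            scores, n_hits = _score_and_hits(rng, truth, read_length, count)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": gene.chrom,
                        "start": starts,
                        "end": starts + read_length,
                        "name": [f"{stage}_r{ridx + j}" for j in range(count)],
                        "score": scores,
                        "strand": gene.strand,
                        "n_hits": n_hits,
                    }
                )
            )
            ridx += count
        for pi, pr in enumerate(truth.planted_novel):
            c = pr.counts.get(stage, 0)
            step = 25  # < read_length so consecutive reads overlap and chain
            if c and pr.interval.start + step * (c - 1) + read_length > pr.interval.end:
                raise ValueError(f"planted region {pi} too narrow for {c} tiled reads")
            for j in range(c):
                ridx += 1
                start = pr.interval.start + step * j
                rows.append(
                    (
                        pr.interval.chrom,
                        start,
                        start + read_length,
                        f"{stage}_p{pi}_{j}",
                        int(rng.integers(30, 51)),
                        pr.strand,
                        1,
                    )
                )
        for _ in range(background_reads):
            ridx += 1
            chrom, clen = _pick_chrom(rng, chrom_sizes)
            start = int(rng.integers(0, max(clen - read_length, 1)))
            strand = "+" if rng.random() < 0.5 else "-"
            scores, n_hits = _score_and_hits(rng, truth, read_length, 1)
            rows.append(
                (chrom, start, start + read_length, f"{stage}_b{ridx}", int(scores[0]), strand, int(n_hits[0]))
            )
        df = pd.concat(
            frames + [pd.DataFrame(rows, columns=READ_COLUMNS)], ignore_index=True
        )[READ_COLUMNS]
        out[stage] = df
        lib[stage] = len(df)
    return out, lib


def _draw_count(rng: np.random.Generator, mean: float, dispersion: float | None) -> int:
    if mean <= 0:
        return 0
    if dispersion is None or not np.isfinite(dispersion):
        return int(rng.poisson(mean))
    r = float(dispersion)
    return int(rng.negative_binomial(r, r / (r + mean)))


def _place_in_exon_model(
    rng: np.random.Generator, gene: GeneModel, read_length: int, count: int
) -> np.ndarray:
    """Uniform read starts over the exon model (exon chosen by placeable width)."""
    weights = np.array([max(len(ex) - read_length + 1, 1) for ex in gene.exons], dtype=float)
    ei = rng.choice(len(gene.exons), size=count, p=weights / weights.sum())
    ex_starts = np.array([ex.start for ex in gene.exons])
    spans = np.array([max(len(ex) - read_length + 1, 1) for ex in gene.exons])
    offs = np.floor(rng.random(count) * spans[ei]).astype(int)
    return ex_starts[ei] + offs


def _score_and_hits(
    rng: np.random.Generator, truth: TruthTable, read_length: int, count: int
) -> tuple[np.ndarray, np.ndarray]:
    lowscore = rng.random(count) < truth.lowscore_fraction
    multi = rng.random(count) < truth.ambiguous_fraction
    scores = np.where(
        lowscore, rng.integers(10, 24, size=count), rng.integers(24, read_length + 1, size=count)
    )
    n_hits = np.where(multi, rng.integers(2, 6, size=count), 1)
    return scores.astype(int), n_hits.astype(int)


def _chrom_extents(annotation: AnnotationSet, truth: TruthTable) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for g in annotation:
        sizes[g.chrom] = max(sizes.get(g.chrom, 0), g.span.end + 50_000)
    for pr in truth.planted_novel:
        sizes[pr.interval.chrom] = max(sizes.get(pr.interval.chrom, 0), pr.interval.end + 50_000)
    return sizes


def _pick_chrom(rng: np.random.Generator, sizes: dict[str, int]) -> tuple[str, int]:
    names = sorted(sizes)
    lens = np.array([sizes[c] for c in names], dtype=float)
    i = int(rng.choice(len(names), p=lens / lens.sum()))
    return names[i], int(lens[i])


# ---------------------------------------------------------------------------
# Ct-table generation for ddCt validation
# ---------------------------------------------------------------------------


def generate_ct_table(
    assays: list[str],
    controls: list[str],
    truth_rq: dict[str, dict[str, float]],
    stages: tuple[str, ...] = STAGES,
    reference_stage: str | None = None,
    noise_sd: float = 0.0,
    n_replicates: int = 2,
    seed: int = 0,
    control_base_ct: tuple[float, ...] = (16.0, 18.0),
):
    """Construct Ct values whose exact ddCt analysis recovers ``truth_rq``.

    ``truth_rq[assay][stage]`` is the relative quantity versus the reference
    stage (internally normalized so the reference RQ is 1).  Target Ct at a
    stage is the assay's base Ct minus log2(RQ); controls sit at fixed base
    Cts.  With ``noise_sd=0`` the recovery is exact.  Requires >= 2 controls.
    """
    from .qpcr import CT_COLUMNS, CtTable  # local import to avoid a cycle

    if len(controls) < 2:
        raise ValueError(f"at least 2 control assays required, got {len(controls)}")
    if not set(controls) <= set(assays):
        raise ValueError("controls must be a subset of the assay list")
    reference_stage = reference_stage or stages[0]
    rng = np.random.default_rng(seed)
    targets = [a for a in assays if a not in controls]
    missing = set(targets) - set(truth_rq)
    if missing:
        raise ValueError(f"truth RQ missing for assay(s): {sorted(missing)}")
    base_ct = {a: float(rng.uniform(22.0, 30.0)) for a in targets}
    ctrl_ct = {c: control_base_ct[i % len(control_base_ct)] for i, c in enumerate(controls)}
    rows = []
    for stage in stages:
        for rep in range(1, n_replicates + 1):
            for c in controls:
                rows.append((stage, rep, c, ctrl_ct[c] + rng.normal(0, noise_sd) if noise_sd else ctrl_ct[c]))
            for a in targets:
                rq = truth_rq[a][stage] / truth_rq[a][reference_stage]
                ct = base_ct[a] - math.log2(rq)
                if noise_sd:
                    ct += rng.normal(0, noise_sd)
                rows.append((stage, rep, a, ct))
    df = pd.DataFrame(rows, columns=CT_COLUMNS)
    return CtTable(data=df, control_assays=list(controls), reference_stage=reference_stage)
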