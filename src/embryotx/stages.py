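"""Stage-sharing (Venn) analysis, abundance ranking and replicate correlation.

Detection flags over the four developmental stages partition the gene
universe into the 16 possible presence patterns; the same machinery serves
both known gene models and putative novel transcribed regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VennPartition",
    "RankTable",
    "ReplicateComparison",
    "venn_partition",
    "shared_exclusive",
    "rank_top",
    "top_k_set",
    "replicate_r2",
]


@dataclass
class VennPartition:
    """Partition of a universe of entities by their stage-presence pattern.

    Patterns are bit strings over the stage order, e.g. ``'1010'`` = present
    in stages 1 and 3 only.  All 16 patterns (for 4 stages) are reported;
    ``'0...0'`` is the undetected set.
    """

    stages: list[str]
    pattern_members: dict[str, list[str]]

    def __post_init__(self) -> None:
        n = len(self.stages)
        for p in [format(i, f"0{n}b") for i in range(2**n)]:
            self.pattern_members.setdefault(p, [])

    @property
    def pattern_counts(self) -> dict[str, int]:
        return {p: len(m) for p, m in sorted(self.pattern_members.items())}

    @property
    def undetected(self) -> list[str]:
        return self.pattern_members["0" * len(self.stages)]

    @property
    def n_undetected(self) -> int:
        return len(self.undetected)

    @property
    def n_detected(self) -> int:
        return self.universe_size - self.n_undetected

    @property
    def universe_size(self) -> int:
        return sum(len(m) for m in self.pattern_members.values())

    def per_stage_counts(self) -> dict[str, int]:
        """Entities present in each stage (summing all patterns with that bit set)."""
        out = {}
        for i, stage in enumerate(self.stages):
            out[stage] = sum(
                len(m) for p, m in self.pattern_members.items() if p[i] == "1"
            )
        return out

    def to_tsv(self, path: str) -> None:
        rows = [
            {"pattern": p, "count": len(m), "members": ",".join(sorted(m))}
            for p, m in sorted(self.pattern_members.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def venn_partition(detected: pd.DataFrame) -> VennPartition:
    """Assign every entity (row) to its presence pattern over the stage columns.

    ``detected`` is a boolean genes x stages frame.  The 2^n patterns
    partition the universe; the all-zero pattern is the undetected set.
    """
    stages = list(detected.columns)
    members: dict[str, list[str]] = {}
    flags = detected.to_numpy(dtype=bool)
    ids = list(detected.index)
    for gid, row in zip(ids, flags):
        pattern = "".join("1" if b else "0" for b in row)
        members.setdefault(pattern, []).append(gid)
    part = VennPartition(stages=stages, pattern_members=members)
    assert part.universe_size == len(detected)  # conservation, every run
    return part


def shared_exclusive(
    partition: VennPartition, stages: set[str] | list[str], mode: str = "exclusive"
) -> set[str]:
    """Entities detected in exactly (``exclusive``) or at least (``inclusive``)
    the named stages."""
    stages = set(stages)
    if not stages:
        raise ValueError("stage subset must be non-empty")
    unknown = stages - set(partition.stages)
    if unknown:
        raise ValueError(f"unknown stage label(s): {sorted(unknown)}")
    want = "".join("1" if s in stages else "0" for s in partition.stages)
    if mode == "exclusive":
        return set(partition.pattern_members[want])
    if mode == "inclusive":
        out: set[str] = set()
        for p, m in partition.pattern_members.items():
            if all(pb == "1" for pb, wb in zip(p, want) if wb == "1"):
                out.update(m)
        return out
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class RankTable:
    """Top-n genes of one stage ordered by decreasing RPKM."""

    stage: str
    table: pd.DataFrame  # columns: rank, gene_id, accession, rpkm
    truncated: bool = False  # n exceeded the number of detected genes

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _ranked_gene_order(rpkm: pd.Series) -> pd.Series:
    """Sort by RPKM descending, ties broken by gene_id lexicographically."""
    df = rpkm.rename("rpkm").rename_axis("gene_id").reset_index()
    df = df.sort_values(["rpkm", "gene_id"], ascending=[False, True], kind="mergesort")
    return df.set_index("gene_id")["rpkm"]


def rank_top(
    table,
    stage: str,
    n: int = 10,
    detected_only: bool = True,
    accessions: dict[str, str] | None = None,
) -> RankTable:
    """The n most abundant genes of a stage by RPKM.

    ``table`` is an ExpressionTable (or any object with ``rpkm`` and
    ``detected`` frames).  Ties are broken by gene_id lexicographic order.
    If fewer than n genes qualify, all are returned and the result flagged.
    """
    vals = table.rpkm[stage]
    if detected_only:
        vals = vals[table.detected[stage]]
    ranked = _ranked_gene_order(vals)
    truncated = n > len(ranked)
    top = ranked.head(n)
    acc = accessions or {}
    out = pd.DataFrame(
        {
            "rank": np.arange(1, len(top) + 1),
            "gene_id": top.index,
            "accession": [acc.get(g, "") for g in top.index],
            "rpkm": top.to_numpy(),
        }
    )
    return RankTable(stage=stage, table=out, truncated=truncated)


def top_k_set(table, stage: str, k: int = 4000, detected_only: bool = True) -> set[str]:
    """The k highest-RPKM genes of a stage (same tie rule as rank_top)."""
    if k == 0:
        return set()
    return set(rank_top(table, stage, n=k, detected_only=detected_only).table["gene_id"])


@dataclass
class ReplicateComparison:
    r2: float
    n: int
    transform: str
    inclusion: str


def replicate_r2(
    x: pd.Series,
    y: pd.Series,
    transform: str = "log2",
    inclusion: str = "either_detected",
    detected_x: pd.Series | None = None,
    detected_y: pd.Series | None = None,
) -> ReplicateComparison:
    """Squared Pearson correlation between two replicate RPKM vectors.

    Default: log2(RPKM+1) over genes detected in either replicate (detection
    defaults to RPKM > 0 when no flags are given).  ``inclusion='all'`` uses
    every gene; ``transform='linear'`` skips the log.
    """
    x, y = x.align(y, join="inner")
    if inclusion == "either_detected":
        dx = detected_x.reindex(x.index) if detected_x is not None else x > 0
        dy = detected_y.reindex(y.index) if detected_y is not None else y > 0
        mask = dx | dy
        x, y = x[mask], y[mask]
    elif inclusion != "all":
        raise ValueError(f"unknown inclusion rule {inclusion!r}")
    if len(x) < 3:
        raise ValueError(f"need >= 3 genes to correlate, got {len(x)}")
    if transform == "log2":
        xv, yv = np.log2(x.to_numpy() + 1.0), np.log2(y.to_numpy() + 1.0)
    elif transform == "linear":
        xv, yv = x.to_numpy(float), y.to_numpy(float)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    r = stats.pearsonr(xv, yv).statistic
    return ReplicateComparison(r2=float(r * r), n=len(xv), transform=transform, inclusion=inclusion)
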