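import pandas as pd
import pytest

import embryotx as e
from embryotx.quantify import READ_COLUMNS


def make_read(chrom, start, end, strand="+", score=40, n_hits=1, name=None):
    return {
        "chrom": chrom,
        "start": start,
        "end": end,
        "name": name or f"r_{chrom}_{start}_{end}_{strand}_{score}_{n_hits}",
        "score": score,
        "strand": strand,
        "n_hits": n_hits,
    }


def reads_frame(rows):
    if not rows:
        return pd.DataFrame(columns=READ_COLUMNS)
    return pd.DataFrame(rows)[READ_COLUMNS]


@pytest.fixture
def toy_annotation():
    """Five handmade genes on two chromosomes, both strands."""
    iv = e.GenomicInterval
    genes = [
        e.GeneModel("gA", "chr1", "+", [iv("chr1", 100, 300, "+"), iv("chr1", 500, 800, "+")], "NM_1"),
        e.GeneModel("gB", "chr1", "-", [iv("chr1", 2000, 2300, "-"), iv("chr1", 2600, 2900, "-")], "NM_2"),
        e.GeneModel("gC", "chr1", "+", [iv("chr1", 10_000, 10_400, "+")], "NM_3"),
        e.GeneModel("gD", "chr2", "+", [iv("chr2", 50, 150, "+"), iv("chr2", 250, 400, "+")], "NM_4"),
        e.GeneModel("gE", "chr2", "-", [iv("chr2", 5000, 5600, "-")], "NM_5"),
    ]
    return e.AnnotationSet(source="toy", genes=genes)


@pytest.fixture(scope="session")
def small_genome():
    """A small but fully featured synthetic data set for fast tests."""
    spec = e.GenomeSpec(
        chrom_names=("chr1", "chr2"),
        chrom_lengths=(18_000_000, 18_000_000),
        n_genes=60,
        seed=7,
    )
    annotation = e.generate_annotation(spec)
    truth = e.make_truth(annotation, seed=8)
    reads, lib = e.generate_reads(annotation, truth, seed=9, background_reads=100)
    return {"spec": spec, "annotation": annotation, "truth": truth, "reads": reads, "lib": lib}


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline at the generator defaults, shared by end-to-end tests."""
    spec = e.GenomeSpec(seed=101)
    annotation = e.generate_annotation(spec)
    truth = e.make_truth(annotation, seed=102)
    reads, lib = e.generate_reads(annotation, truth, seed=103)
    table = e.quantify_stages(reads, annotation)
    return {
        "spec": spec,
        "annotation": annotation,
        "truth": truth,
        "reads": reads,
        "lib": lib,
        "table": table,
    }
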