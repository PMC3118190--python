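"""GO term over-representation analysis.

Direct gene->term annotations are propagated up the is_a hierarchy
(annotating a gene to every ancestor of its direct terms), then each term is
tested for over-representation in a study set against a population by the
one-sided hypergeometric tail P(X >= k), with Bonferroni (default) or
Benjamini-Hochberg correction across the tested terms and significance
called at adjusted p < 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Ontology",
    "propagate_annotations",
    "hypergeom_enrichment",
    "enrichment_heatmap",
    "read_ontology_tsv",
    "read_annotations_tsv",
]

NAMESPACES = ("molecular_function", "biological_process", "cellular_component")


@dataclass
class Ontology:
    """A DAG of terms with child -> parent (is_a) edges.

    ``namespaces`` is optional; when present, edges must stay within a
    namespace (the three GO vocabularies are independent).
    """

    parents: dict[str, set[str]]
    namespaces: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # every referenced parent is a term
        for child, ps in list(self.parents.items()):
            for p in ps:
                self.parents.setdefault(p, set())
        self._check_acyclic()
        self._ancestors: dict[str, set[str]] = {}

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(t: str, stack: list[str]) -> None:
            if state.get(t) == 1:
                return
            if state.get(t) == 0:
                raise ValueError(f"cycle in ontology involving {t!r}")
            state[t] = 0
            for p in self.parents.get(t, ()):
                visit(p, stack + [t])
            state[t] = 1

        for t in self.parents:
            visit(t, [])

    def terms(self) -> set[str]:
        return set(self.parents)

    def ancestors(self, term: str) -> set[str]:
        """All ancestors of a term (excluding the term itself), memoized."""
        if term not in self.parents:
            raise KeyError(f"unknown term {term!r}")
        if term not in self._ancestors:
            acc: set[str] = set()
            for p in self.parents[term]:
                acc.add(p)
                acc |= self.ancestors(p)
            self._ancestors[term] = acc
        return self._ancestors[term]


def read_ontology_tsv(path: str) -> Ontology:
    """Read is_a edges from a 2-column TSV: child <tab> parent."""
    parents: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ValueError(f"line {lineno}: expected child<TAB>parent")
            child, parent = fields[0], fields[1]
            parents.setdefault(child, set()).add(parent)
    return Ontology(parents=parents)


def read_annotations_tsv(path: str) -> dict[str, set[str]]:
    """Read direct gene->term annotations from a 2-column TSV."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ValueError(f"line {lineno}: expected gene<TAB>term")
            out.setdefault(fields[0], set()).add(fields[1])
    return out


def propagate_annotations(
    direct: dict[str, set[str]], ontology: Ontology
) -> dict[str, set[str]]:
    """Annotate each gene to every ancestor of each of its direct terms."""
    out: dict[str, set[str]] = {}
    for gene, terms in direct.items():
        full: set[str] = set()
        for t in terms:
            if t not in ontology.parents:
                raise KeyError(f"gene {gene!r} annotated to unknown term {t!r}")
            full.add(t)
            full |= ontology.ancestors(t)
        out[gene] = full
    return out


def hypergeom_enrichment(
    study: set[str],
    population: set[str],
    annotations: dict[str, set[str]],
    threshold: float = 0.01,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per term.

    For a term annotating K of N population genes and k of the n study
    genes, p_raw = P(X >= k) under Hypergeometric(N, K, n).  Terms with
    K >= 1 are tested; correction is ``bonferroni`` (default), ``fdr_bh``
    or ``none``; significant iff p_adj < threshold.
    """
    if not study <= population:
        raise ValueError("study set must be a subset of the population")
    N, n = len(population), len(study)
    counts: dict[str, list[int]] = {}
    for gene in population:
        for t in annotations.get(gene, ()):
            rec = counts.setdefault(t, [0, 0])
            rec[0] += 1
            if gene in study:
                rec[1] += 1
    terms = sorted(counts)
    K = np.array([counts[t][0] for t in terms])
    k = np.array([counts[t][1] for t in terms])
    # P(X >= k) = sf(k-1)
    p_raw = stats.hypergeom.sf(k - 1, N, K, n) if terms else np.array([])
    m = len(terms)
    if correction == "bonferroni":
        p_adj = np.minimum(p_raw * m, 1.0)
    elif correction == "fdr_bh":
        p_adj = stats.false_discovery_control(p_raw, method="bh") if m else p_raw
    elif correction == "none":
        p_adj = p_raw.copy()
    else:
        raise ValueError(f"unknown correction {correction!r}")
    df = pd.DataFrame(
        {
            "term": terms,
            "k": k,
            "n": n,
            "K": K,
            "N": N,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "significant": p_adj < threshold,
        }
    )
    return df.sort_values(["p_adj", "term"], kind="mergesort").reset_index(drop=True)


def enrichment_heatmap(per_stage: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Stage x term matrix of -log10 adjusted p for significant terms.

    Terms significant in no stage are excluded; cells where a term is not
    significant in a stage carry NaN (the "absent category" sentinel).
    """
    sig_terms: set[str] = set()
    for df in per_stage.values():
        sig_terms |= set(df.loc[df["significant"], "term"])
    terms = sorted(sig_terms)
    mat = pd.DataFrame(np.nan, index=list(per_stage), columns=terms)
    for stage, df in per_stage.items():
        sig = df[df["significant"] & df["term"].isin(sig_terms)]
        for t, p in zip(sig["term"], sig["p_adj"]):
            mat.loc[stage, t] = -np.log10(max(p, 1e-300))
    return mat
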