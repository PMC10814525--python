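"""Unranked two-list term over-representation analysis.

Given a *target* gene list and a *background* gene list, each term's
over-representation is scored as

    enrichment = (b/n) / (B/N)

with ``b`` target genes carrying the term, ``n`` total target genes, ``B``
background genes carrying the term and ``N`` total background genes, and an
upper-tail hypergeometric p-value ``P[X >= b]`` with
``X ~ Hypergeometric(N, B, n)``.

No multiple-testing correction is applied: results are filtered at a raw
p-value threshold (default 5e-5), mirroring common two-list GO practice.
Redundant terms (identical target hit sets) are collapsed to the most
specific term (smallest ``B``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

__all__ = [
    "AnnotationMap",
    "read_annotation",
    "read_gaf",
    "hypergeom_upper_tail",
    "term_enrichment_test",
    "filter_terms",
    "dedup_terms",
    "write_term_results",
]

RESULT_COLUMNS = ("term", "name", "category", "b", "n", "B", "N", "enrichment", "p_value")


@dataclass
class AnnotationMap:
    """gene -> set of term ids, plus optional term metadata."""

    gene_terms: dict
    term_names: dict = field(default_factory=dict)
    term_categories: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_terms = {
            g: frozenset(ts) for g, ts in self.gene_terms.items() if ts
        }

    def terms(self) -> frozenset:
        out = set()
        for ts in self.gene_terms.values():
            out |= ts
        return frozenset(out)

    def genes_with(self, term: str, universe) -> frozenset:
        return frozenset(
            g for g in universe if term in self.gene_terms.get(g, ())
        )


def read_annotation(path, name_path=None) -> AnnotationMap:
    """Read a two-column (gene<TAB>term) annotation file.

    ``name_path`` may point to an optional term metadata table with columns
    term, name and (optionally) category.
    """
    gene_terms: dict = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"annotation line lacks two columns: {line!r}")
            gene, term = parts[0], parts[1]
            gene_terms.setdefault(gene, set()).add(term)
    names: dict = {}
    categories: dict = {}
    if name_path is not None:
        with open(name_path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                names[parts[0]] = parts[1] if len(parts) > 1 else parts[0]
                if len(parts) > 2:
                    categories[parts[0]] = parts[2]
    return AnnotationMap(gene_terms, names, categories)


def read_gaf(path) -> AnnotationMap:
    """Thin GAF adapter: gene symbol (column 3) -> GO id (column 5)."""
    gene_terms: dict = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith("!"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                continue
            gene_terms.setdefault(parts[2], set()).add(parts[4])
    return AnnotationMap(gene_terms)


def hypergeom_upper_tail(b: int, n: int, B: int, N: int) -> float:
    """P[X >= b] for X ~ Hypergeometric(N, B, n)."""
    return float(stats.hypergeom.sf(b - 1, N, B, n))


def term_enrichment_test(target, background, annotation: AnnotationMap) -> pd.DataFrame:
    """Score every annotated term against a target/background gene pair.

    Genes absent from the annotation still count towards ``n`` and ``N``
    but hit no term.  Only terms with ``B >= 1`` in the background are
    reported.  The returned frame carries a ``target_genes`` column (sorted
    tuple of target hits) used downstream for redundancy removal.
    """
    target = frozenset(target)
    background = frozenset(background)
    if not target <= background:
        extra = sorted(target - background)[:5]
        raise ValueError(f"target is not a subset of background (e.g. {extra})")
    n = len(target)
    N = len(background)
    if n == 0:
        raise ValueError("empty target list")
    term_bg: dict = {}
    term_tg: dict = {}
    for g in background:
        for t in annotation.gene_terms.get(g, ()):
            term_bg.setdefault(t, set()).add(g)
    for g in target:
        for t in annotation.gene_terms.get(g, ()):
            term_tg.setdefault(t, set()).add(g)
    rows = []
    for t in sorted(term_bg):
        B = len(term_bg[t])
        hits = sorted(term_tg.get(t, ()))
        b = len(hits)
        enrichment = (b / n) / (B / N)
        rows.append(
            {
                "term": t,
                "name": annotation.term_names.get(t, t),
                "category": annotation.term_categories.get(t, ""),
                "b": b,
                "n": n,
                "B": B,
                "N": N,
                "enrichment": enrichment,
                "p_value": hypergeom_upper_tail(b, n, B, N),
                "target_genes": tuple(hits),
            }
        )
    out = pd.DataFrame(rows, columns=list(RESULT_COLUMNS) + ["target_genes"])
    return out.sort_values(
        ["enrichment", "term"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def filter_terms(results: pd.DataFrame, alpha: float = 5e-5) -> pd.DataFrame:
    """Keep terms with p strictly below ``alpha``."""
    return results[results["p_value"] < alpha].reset_index(drop=True)


def dedup_terms(results: pd.DataFrame) -> pd.DataFrame:
    """Collapse terms whose target hit sets are identical.

    Within each group of identical hit sets the most specific term (smallest
    background count ``B``) wins; equal ``B`` falls back to the
    lexicographically smallest term id.
    """
    if results.empty:
        return results.copy()
    keep_rows = []
    for _, group in results.groupby("target_genes", sort=False):
        group = group.sort_values(["B", "term"], kind="mergesort")
        keep_rows.append(group.index[0])
    out = results.loc[sorted(keep_rows)]
    return out.sort_values(
        ["enrichment", "term"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def write_term_results(results: pd.DataFrame, path) -> None:
    """Write results as TSV sorted by enrichment descending."""
    cols = [c for c in RESULT_COLUMNS if c in results.columns]
    results[cols].to_csv(path, sep="\t", index=False)
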