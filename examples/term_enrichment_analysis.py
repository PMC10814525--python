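"""Two-list term enrichment of a hit list against all identified genes.

Builds a small annotation in which one term concentrates in the target
list, scores every term with (b/n)/(B/N) and the upper-tail hypergeometric
p-value, filters at p < 5e-5 and collapses redundant terms.
"""

from pchquant.term_enrichment import (
    AnnotationMap,
    dedup_terms,
    filter_terms,
    term_enrichment_test,
)

background = {f"gene{i}" for i in range(400)}
target = {f"gene{i}" for i in range(40)}

gene_terms = {}
for i in range(400):
    terms = set()
    if i < 30 or i % 40 == 0:  # chromatin term concentrated in the target
        terms.add("GO:0000792")
    if i % 3 == 0:  # broad metabolic term, near-proportional
        terms.add("GO:0008152")
    if terms:
        gene_terms[f"gene{i}"] = terms
annotation = AnnotationMap(
    gene_terms,
    term_names={"GO:0000792": "heterochromatin", "GO:0008152": "metabolic process"},
)

results = term_enrichment_test(target, background, annotation)
print(results[["term", "name", "b", "n", "B", "N", "enrichment", "p_value"]]
      .to_string(index=False))
kept = dedup_terms(filter_terms(results, alpha=5e-5))
print(f"\nterms passing p < 5e-5 after redundancy removal: {list(kept['term'])}")
# enrichment = (b/n)/(B/N): ~7.7x for the planted heterochromatin term,
# ~1x for the proportional metabolic term (p close to 1).
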