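"""Four-stage selection of pericentromeric-heterochromatin-enriched proteins.

The selection takes per-protein PCH/nuclei enrichment ratios for two
tissues (brain, liver) and proceeds through:

1. replicate intersection — keep proteins quantified in all biological
   replicates;
2. common enrichment — keep proteins with PCH/nuclei > 1 in *both* tissues;
3. percentile classification — the upper and lower 10% of the brain-PCH /
   liver-PCH log2 ratio distribution are called brain- or liver-upregulated;
4. reference-anchored cut-off — keep only proteins whose brain enrichment
   is at least that of a microscopy-validated boundary protein (ATRX), which
   therefore survives its own cut-off.

Enrichment records are plain :class:`pandas.DataFrame` rows indexed by
protein id with columns ``gene_name``, ``e_brain``, ``e_liver``,
``log2_brain_over_liver``, ``log10_intensity``, ``n_replicates_brain``,
``n_replicates_liver``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SelectionResult",
    "build_enrichment_records",
    "intersect_replicates",
    "common_enrichment_filter",
    "percentile_classify",
    "reference_cutoff",
    "select_hits",
    "assemble_dotplot_table",
]

RECORD_COLUMNS = (
    "gene_name",
    "e_brain",
    "e_liver",
    "log2_brain_over_liver",
    "log10_intensity",
    "n_replicates_brain",
    "n_replicates_liver",
)


@dataclass
class SelectionResult:
    """State of the selection pipeline after all four stages."""

    common_enriched: frozenset
    category: pd.Series  # protein_id -> {brain_up, liver_up, shared}
    validated: frozenset
    reference_threshold: float
    category_post_cutoff: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.validated <= self.common_enriched:
            raise ValueError("validated hits must be a subset of common_enriched")


def build_enrichment_records(
    e_brain: pd.DataFrame,
    e_liver: pd.DataFrame,
    brain_over_liver: pd.DataFrame,
    log10_intensity: pd.Series,
    gene_names: pd.Series,
) -> pd.DataFrame:
    """Assemble per-protein enrichment records from replicate summaries.

    ``e_brain``/``e_liver``/``brain_over_liver`` are outputs of
    :func:`pchquant.ms_quant.summarize_replicates` (columns ``summary``,
    ``n_replicates``, ``log2_sd``).
    """
    idx = e_brain.index.union(e_liver.index)
    rec = pd.DataFrame(index=idx)
    rec["gene_name"] = gene_names.reindex(idx)
    rec["e_brain"] = e_brain["summary"].reindex(idx)
    rec["e_liver"] = e_liver["summary"].reindex(idx)
    rec["log2_brain_over_liver"] = np.log2(
        brain_over_liver["summary"].reindex(idx)
    )
    rec["log10_intensity"] = log10_intensity.reindex(idx)
    rec["n_replicates_brain"] = (
        e_brain["n_replicates"].reindex(idx).fillna(0).astype(int)
    )
    rec["n_replicates_liver"] = (
        e_liver["n_replicates"].reindex(idx).fillna(0).astype(int)
    )
    rec.index.name = "protein_id"
    return rec


def intersect_replicates(replicate_sets, n_required: int = 3) -> frozenset:
    """Proteins present in at least ``n_required`` of the replicate sets.

    With ``n_required`` equal to the number of replicates this is the plain
    intersection (reproducible identification in every replicate); with
    ``n_required=1`` it degenerates to the union.
    """
    if n_required < 1:
        raise ValueError("n_required must be >= 1")
    sets = [frozenset(s) for s in replicate_sets]
    counts: dict = {}
    for s in sets:
        for p in s:
            counts[p] = counts.get(p, 0) + 1
    return frozenset(p for p, c in counts.items() if c >= n_required)


def common_enrichment_filter(records: pd.DataFrame) -> frozenset:
    """Proteins enriched in PCH over nuclei in *both* tissues (strict > 1)."""
    mask = (records["e_brain"] > 1.0) & (records["e_liver"] > 1.0)
    return frozenset(records.index[mask.fillna(False)])


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5))


def percentile_classify(records: pd.DataFrame, fraction: float = 0.10) -> pd.Series:
    """Label the tails of the brain/liver log2-ratio distribution.

    Proteins are sorted by ``log2_brain_over_liver`` descending (ties broken
    by protein id ascending); the top ``k = round(fraction * n)`` (half away
    from zero) become ``brain_up``, the bottom ``k`` ``liver_up``, the rest
    ``shared``.
    """
    n = len(records)
    if n < 10:
        raise ValueError(f"too few for percentile classification ({n} < 10)")
    k = _round_half_away(fraction * n)
    # sort on value descending with protein id (index) as deterministic tie-break
    order = records.assign(_pid=records.index.astype(str)).sort_values(
        by=["log2_brain_over_liver", "_pid"], ascending=[False, True], kind="mergesort"
    )
    cats = pd.Series("shared", index=order.index, name="category")
    if k > 0:
        cats.iloc[:k] = "brain_up"
        cats.iloc[-k:] = "liver_up"
    return cats.reindex(records.index)


def reference_cutoff(
    records: pd.DataFrame,
    reference_gene: str = "Atrx",
    tissue: str = "brain",
) -> tuple[frozenset, float]:
    """Validation-anchored cut-off on single-tissue enrichment.

    The threshold is the reference protein's PCH/nuclei enrichment in
    ``tissue``; proteins at or above it are retained (inclusive, so the
    boundary protein itself survives).  Returns ``(validated, threshold)``.
    """
    col = {"brain": "e_brain", "liver": "e_liver"}.get(tissue)
    if col is None:
        raise ValueError(f"unknown tissue {tissue!r}")
    hits = records.index[records["gene_name"] == reference_gene]
    hits = [p for p in hits if np.isfinite(records.at[p, col])]
    if not hits:
        raise ValueError(f"reference protein not quantified: {reference_gene!r}")
    ref_id = sorted(hits, key=str)[0]
    threshold = float(records.at[ref_id, col])
    mask = records[col] >= threshold
    return frozenset(records.index[mask.fillna(False)]), threshold


def select_hits(
    records: pd.DataFrame,
    reference_gene: str = "Atrx",
    fraction: float = 0.10,
    tissue: str = "brain",
) -> SelectionResult:
    """Run stages 2-4 of the selection on replicate-intersected records."""
    common = common_enrichment_filter(records)
    common_records = records.loc[sorted(common, key=str)]
    category = percentile_classify(common_records, fraction=fraction)
    validated_all, threshold = reference_cutoff(
        common_records, reference_gene=reference_gene, tissue=tissue
    )
    validated = frozenset(validated_all) & common
    post = None
    validated_records = records.loc[sorted(validated, key=str)]
    if len(validated_records) >= 10:
        post = percentile_classify(validated_records, fraction=fraction)
    return SelectionResult(
        common_enriched=frozenset(common),
        category=category,
        validated=validated,
        reference_threshold=threshold,
        category_post_cutoff=post,
    )


def assemble_dotplot_table(
    result: SelectionResult,
    records: pd.DataFrame,
    functional_class: pd.Series | None = None,
) -> pd.DataFrame:
    """Plot-ready table: one row per common-enriched protein.

    Columns: abundance coordinate (``log10_intensity``), tissue contrast
    (``log2_brain_over_liver``), tail category, validated flag and an
    optional functional class annotation.
    """
    idx = sorted(result.common_enriched, key=str)
    out = records.loc[idx, ["gene_name", "log10_intensity", "log2_brain_over_liver"]].copy()
    out["category"] = result.category.reindex(idx)
    out["validated"] = [p in result.validated for p in idx]
    if functional_class is not None:
        out["functional_class"] = functional_class.reindex(idx)
    out.index.name = "protein_id"
    return out
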