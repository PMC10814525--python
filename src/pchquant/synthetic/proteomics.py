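"""Simulated dimethyl-labelling proteinGroups tables with planted truth.

The generator emulates the statistical structure the downstream selection
assumes: every protein has a light-labelled abundance in each of four
samples (brain nuclei, brain PCH, liver nuclei, liver PCH), all mixed
against one pooled medium-heavy reference, so each sample's reported value
is an H/L ratio.  Planted protein classes:

``conserved_pch``
    enriched ``enrich_effect``-fold in PCH over nuclei in both tissues;
``brain_up`` / ``liver_up``
    PCH-enriched in both tissues and ``tissue_effect``-fold more abundant
    in the respective tissue;
``chromatin_background``
    general chromatin, PCH/nuclei fold exactly 1;
``contaminant_membrane`` / ``contaminant_rna``
    low-abundance co-purifying material whose PCH/nuclei fold is drawn
    log2-uniformly between 1 and the reference protein's fold — above the
    plain >1 filter but below the validation cut-off.

The reference protein (gene ``Atrx``) is planted as a ``conserved_pch``
protein at exactly ``reference_enrich``, the minimum fold of the enriched
classes, so the validation cut-off is exercised at its boundary.

Replicate measurements carry multiplicative log-normal noise
(``noise_sd_log2`` on the log2 scale); missingness has two channels —
whole-replicate dropout (``dropout_prob``) and per-cell low peptide
evidence (``low_count_fraction`` of quantified cells get a ratio count of
1, which the standard filter removes).  A quota of decoy rows flagged
``Reverse`` / ``Potential contaminant`` is appended.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..ms_quant import RatioTable

__all__ = ["CLASSES", "MsSimConfig", "simulate_protein_groups", "SAMPLES"]

CLASSES = (
    "conserved_pch",
    "brain_up",
    "liver_up",
    "chromatin_background",
    "contaminant_membrane",
    "contaminant_rna",
)

SAMPLES = ("brain_nuclei", "brain_pch", "liver_nuclei", "liver_pch")

REFERENCE_GENE = "Atrx"
REFERENCE_ID = "P_ATRX"

_PREFIX = {
    "conserved_pch": "CONS",
    "brain_up": "BRUP",
    "liver_up": "LVUP",
    "chromatin_background": "CHBG",
    "contaminant_membrane": "MEMC",
    "contaminant_rna": "RNAC",
}


@dataclass
class MsSimConfig:
    """Design of one simulated quantitative proteomics study."""

    n_per_class: int = 30
    classes: tuple = CLASSES
    enrich_effect: float = 4.0
    tissue_effect: float = 4.0
    noise_sd_log2: float = 0.2
    reference_enrich: float = 2.0
    intensity_range_log10: tuple = (6.0, 9.0)
    n_replicates: int = 3
    dropout_prob: float = 0.1
    low_count_fraction: float = 0.05
    decoy_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.enrich_effect <= 1:
            raise ValueError("enrich_effect must be > 1")
        if self.reference_enrich <= 1:
            raise ValueError("reference_enrich must be > 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0 <= self.dropout_prob < 1:
            raise ValueError("dropout_prob must be in [0, 1)")
        unknown = set(self.classes) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown classes: {sorted(unknown)}")


def _planted_truth(config: MsSimConfig, rng: np.random.Generator) -> pd.DataFrame:
    lo, hi = config.intensity_range_log10
    rows = []
    for cls in CLASSES:
        if cls not in config.classes:
            continue
        for i in range(config.n_per_class):
            pid = f"{_PREFIX[cls]}{i:04d}"
            gene = f"{_PREFIX[cls].capitalize()}{i}"
            contaminant = cls.startswith("contaminant")
            if contaminant:
                # low abundance: bottom third of the stated range
                log10_ab = rng.uniform(lo, lo + (hi - lo) / 3.0)
                fold_brain = 2.0 ** rng.uniform(0.0, np.log2(config.reference_enrich))
                fold_liver = 2.0 ** rng.uniform(0.0, np.log2(config.reference_enrich))
            else:
                log10_ab = rng.uniform(lo + (hi - lo) / 3.0, hi)
                if cls == "chromatin_background":
                    fold_brain = fold_liver = 1.0
                else:
                    fold_brain = fold_liver = config.enrich_effect
            tissue_fold = 1.0
            if cls == "brain_up":
                tissue_fold = config.tissue_effect
            elif cls == "liver_up":
                tissue_fold = 1.0 / config.tissue_effect
            rows.append(
                {
                    "protein_id": pid,
                    "gene_name": gene,
                    "class": cls,
                    "fold_brain": fold_brain,
                    "fold_liver": fold_liver,
                    "brain_over_liver": tissue_fold,
                    "abundance": 10.0 ** log10_ab,
                }
            )
    if not rows:
        raise ValueError("empty design")
    # reference protein: conserved class at the boundary fold
    ref_log10 = rng.uniform(lo + (hi - lo) / 3.0, hi)
    rows.append(
        {
            "protein_id": REFERENCE_ID,
            "gene_name": REFERENCE_GENE,
            "class": "conserved_pch",
            "fold_brain": config.reference_enrich,
            "fold_liver": config.reference_enrich,
            "brain_over_liver": 1.0,
            "abundance": 10.0 ** ref_log10,
        }
    )
    truth = pd.DataFrame(rows).set_index("protein_id")
    return truth


def _sample_abundance(truth: pd.DataFrame, sample: str) -> pd.Series:
    base = truth["abundance"]
    tissue_fold = truth["brain_over_liver"]
    if sample == "brain_nuclei":
        return base * np.sqrt(tissue_fold)
    if sample == "brain_pch":
        return base * np.sqrt(tissue_fold) * truth["fold_brain"]
    if sample == "liver_nuclei":
        return base / np.sqrt(tissue_fold)
    if sample == "liver_pch":
        return base / np.sqrt(tissue_fold) * truth["fold_liver"]
    raise ValueError(sample)


def simulate_protein_groups(config: MsSimConfig):
    """Simulate per-replicate proteinGroups tables and their planted truth.

    Returns ``(tables, truth)`` where ``tables`` maps replicate names
    (``rep1`` ...) to :class:`~pchquant.ms_quant.RatioTable` objects with
    the four samples as columns, and ``truth`` is a frame indexed by
    protein id with class labels and planted folds.  Identical config and
    seed give identical output.
    """
    rng = np.random.default_rng(config.seed)
    truth = _planted_truth(config, rng)
    n = len(truth)

    abundances = {s: _sample_abundance(truth, s) for s in SAMPLES}
    # pooled medium-heavy reference: equal mix of the four light samples
    pool = sum(abundances.values()) / len(SAMPLES)

    # whole-replicate dropout per (protein, replicate)
    dropped = rng.random((n, config.n_replicates)) < config.dropout_prob

    tables = {}
    for r in range(config.n_replicates):
        ratios = {}
        counts = {}
        intensities = {}
        for s in SAMPLES:
            noise = 2.0 ** rng.normal(0.0, config.noise_sd_log2, size=n)
            measured = abundances[s].to_numpy() * noise
            ratio = pool.to_numpy() / measured
            count = 2 + rng.poisson(5.0, size=n)
            low = rng.random(n) < config.low_count_fraction
            count[low] = 1
            missing = dropped[:, r]
            ratio = ratio.copy()
            ratio[missing] = np.nan
            count[missing] = 0
            intensity = measured.copy()
            intensity[missing] = 0.0
            ratios[s] = ratio
            counts[s] = count
            intensities[s] = intensity
        idx = truth.index.copy()
        table = RatioTable(
            ratios=pd.DataFrame(ratios, index=idx),
            counts=pd.DataFrame(counts, index=idx),
            intensities=pd.DataFrame(intensities, index=idx),
            gene_names=truth["gene_name"].copy(),
            is_reverse=pd.Series(False, index=idx, name="is_reverse"),
            is_contaminant=pd.Series(False, index=idx, name="is_contaminant"),
        )
        tables[f"rep{r + 1}"] = _append_decoys(table, config, rng)
    return tables, truth


def _append_decoys(
    table: RatioTable, config: MsSimConfig, rng: np.random.Generator
) -> RatioTable:
    """Append flagged Reverse / Potential-contaminant quota rows."""
    n_real = len(table)
    n_decoy = int(np.ceil(config.decoy_fraction * n_real))
    if n_decoy == 0:
        return table
    rows = []
    for kind in ("REV", "CON"):
        for i in range(n_decoy):
            rows.append((f"{kind}__D{i:04d}", kind))
    idx = pd.Index([r[0] for r in rows], name="protein_id")
    lo, hi = config.intensity_range_log10
    ratios = pd.DataFrame(
        2.0 ** rng.normal(0.0, 1.0, size=(len(rows), len(SAMPLES))),
        index=idx,
        columns=list(SAMPLES),
    )
    counts = pd.DataFrame(
        2 + rng.poisson(2.0, size=(len(rows), len(SAMPLES))),
        index=idx,
        columns=list(SAMPLES),
    )
    intensities = pd.DataFrame(
        10.0 ** rng.uniform(lo, hi, size=(len(rows), len(SAMPLES))),
        index=idx,
        columns=list(SAMPLES),
    )
    return RatioTable(
        ratios=pd.concat([table.ratios, ratios]),
        counts=pd.concat([table.counts, counts]),
        intensities=pd.concat([table.intensities, intensities]),
        gene_names=pd.concat(
            [table.gene_names, pd.Series([r[0] for r in rows], index=idx)]
        ),
        is_reverse=pd.concat(
            [table.is_reverse, pd.Series([r[1] == "REV" for r in rows], index=idx)]
        ),
        is_contaminant=pd.concat(
            [table.is_contaminant, pd.Series([r[1] == "CON" for r in rows], index=idx)]
        ),
    )
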