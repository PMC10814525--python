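"""End-to-end orchestration of the proteomics and imaging workflows.

``run_ms_pipeline`` chains the quantitative proteomics stages — filter,
mode-normalise, fraction ratios, replicate summary, replicate intersection,
common enrichment filter, percentile classification, reference cut-off and
(optionally) term enrichment — writing every intermediate as TSV plus a
JSON manifest with per-stage record counts and a config hash.

``run_image_pipeline`` segments nuclei and heterochromatin foci in every
supplied image, collects per-nucleus statistics and compares groups
(rank-sum test on accumulation; pooled t-test on particle densities when
particle detection is enabled).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import hit_selection, image_quant, ms_quant, term_enrichment

__all__ = [
    "PipelineStageError",
    "MsPipelineResult",
    "run_ms_pipeline",
    "ImageSet",
    "ImagePipelineResult",
    "run_image_pipeline",
]

DEFAULT_SAMPLES = {
    "brain_nuclei": "brain_nuclei",
    "brain_pch": "brain_pch",
    "liver_nuclei": "liver_nuclei",
    "liver_pch": "liver_pch",
}


class PipelineStageError(RuntimeError):
    """An error raised by a named pipeline stage."""

    def __init__(self, stage: str, error: Exception):
        super().__init__(f"stage {stage!r} failed: {error}")
        self.stage = stage
        self.error = error


@dataclass
class MsPipelineResult:
    records: pd.DataFrame
    selection: hit_selection.SelectionResult
    dotplot: pd.DataFrame
    terms: pd.DataFrame | None
    manifest: dict


def _config_hash(params: dict) -> str:
    payload = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()


def _stage(name):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(name, exc) from exc
            return False

    return _Ctx()


def run_ms_pipeline(
    tables: dict,
    out_dir=None,
    min_ratio_count: int = 2,
    n_required: int | None = None,
    reference_gene: str = "Atrx",
    percentile: float = 0.10,
    annotation: term_enrichment.AnnotationMap | None = None,
    alpha: float = 5e-5,
    samples: dict = DEFAULT_SAMPLES,
    seed: int | None = None,
) -> MsPipelineResult:
    """Run the full selection workflow on per-replicate ratio tables.

    ``tables`` maps replicate names to :class:`~pchquant.ms_quant.RatioTable`
    objects carrying the four tissue/fraction samples.  Stage errors are
    re-raised as :class:`PipelineStageError` naming the stage.
    """
    counts: dict = {"input": {r: len(t) for r, t in tables.items()}}
    replicate_names = sorted(tables)
    if n_required is None:
        n_required = len(replicate_names)

    with _stage("filter"):
        filtered = {
            r: ms_quant.filter_records(tables[r], min_ratio_count=min_ratio_count)
            for r in replicate_names
        }
        counts["filtered"] = {r: len(t) for r, t in filtered.items()}

    with _stage("normalize"):
        normalized = {r: ms_quant.normalize_to_mode(t) for r, t in filtered.items()}

    with _stage("fraction_ratio"):
        e_brain_reps, e_liver_reps, bl_reps = [], [], []
        presence_sets = []
        for r in replicate_names:
            t = normalized[r]
            e_b = ms_quant.fraction_ratio(t, samples["brain_nuclei"], samples["brain_pch"])
            e_l = ms_quant.fraction_ratio(t, samples["liver_nuclei"], samples["liver_pch"])
            bl = ms_quant.fraction_ratio(t, samples["liver_pch"], samples["brain_pch"])
            e_brain_reps.append(e_b)
            e_liver_reps.append(e_l)
            bl_reps.append(bl)
            presence_sets.append(
                set(e_b.index) & set(e_l.index) & set(bl.index)
            )

    with _stage("intersect_replicates"):
        present = hit_selection.intersect_replicates(presence_sets, n_required=n_required)
        counts["replicate_intersection"] = len(present)

    with _stage("summarize_replicates"):
        keep = sorted(present, key=str)
        e_brain = ms_quant.summarize_replicates(
            [s.reindex(keep) for s in e_brain_reps]
        )
        e_liver = ms_quant.summarize_replicates(
            [s.reindex(keep) for s in e_liver_reps]
        )
        brain_over_liver = ms_quant.summarize_replicates(
            [s.reindex(keep) for s in bl_reps]
        )
        pch_cols = [samples["brain_pch"], samples["liver_pch"]]
        intensity = pd.concat(
            [normalized[r].intensities[pch_cols] for r in replicate_names], axis=1
        ).mean(axis=1)
        log10_intensity = np.log10(intensity.replace(0, np.nan)).reindex(keep)
        gene_names = pd.concat(
            [normalized[r].gene_names for r in replicate_names]
        )
        gene_names = gene_names[~gene_names.index.duplicated()]
        records = hit_selection.build_enrichment_records(
            e_brain, e_liver, brain_over_liver, log10_intensity, gene_names
        )
        counts["summarized"] = len(records)

    with _stage("hit_selection"):
        selection = hit_selection.select_hits(
            records,
            reference_gene=reference_gene,
            fraction=percentile,
        )
        counts["common_enriched"] = len(selection.common_enriched)
        counts["validated"] = len(selection.validated)
        dotplot = hit_selection.assemble_dotplot_table(selection, records)

    terms = None
    if annotation is not None:
        with _stage("term_enrichment"):
            background = set(gene_names.dropna())
            target = set(
                records.loc[sorted(selection.validated, key=str), "gene_name"].dropna()
            )
            terms = term_enrichment.term_enrichment_test(target, background, annotation)
            terms = term_enrichment.dedup_terms(
                term_enrichment.filter_terms(terms, alpha=alpha)
            )
            counts["enriched_terms"] = len(terms)

    manifest = {
        "config_hash": _config_hash(
            {
                "min_ratio_count": min_ratio_count,
                "n_required": n_required,
                "reference_gene": reference_gene,
                "percentile": percentile,
                "alpha": alpha,
                "samples": samples,
                "replicates": replicate_names,
            }
        ),
        "seed": seed,
        "reference_threshold": selection.reference_threshold,
        "counts": counts,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        records.to_csv(out / "summary_records.tsv", sep="\t")
        common = records.loc[sorted(selection.common_enriched, key=str)].copy()
        common["category"] = selection.category.reindex(common.index)
        common.to_csv(out / "common_enriched.tsv", sep="\t")
        validated = records.loc[sorted(selection.validated, key=str)]
        validated.to_csv(out / "validated_hits.tsv", sep="\t")
        dotplot.to_csv(out / "dotplot.tsv", sep="\t")
        if terms is not None:
            term_enrichment.write_term_results(terms, out / "term_enrichment.tsv")
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    return MsPipelineResult(records, selection, dotplot, terms, manifest)


@dataclass
class ImageSet:
    """One field of view: a DNA channel plus named protein channels."""

    name: str
    group: str
    dna: image_quant.IntensityGrid
    channels: dict = field(default_factory=dict)


@dataclass
class ImagePipelineResult:
    stats: pd.DataFrame
    group_tests: pd.DataFrame
    densities: pd.DataFrame | None = None


def run_image_pipeline(
    image_sets,
    out_dir=None,
    k_sd: float = 1.5,
    min_focus_voxels: int = 2,
    min_nucleus_size: float | None = None,
    detect_particles: bool = False,
) -> ImagePipelineResult:
    """Segment, quantify and compare groups of images.

    Per image: nucleus segmentation on the DNA channel, in-nucleus focus
    segmentation, and per-(nucleus, channel) statistics.  For every protein
    channel and pair of groups the per-nucleus accumulations are compared
    with the two-sided rank-sum test; with ``detect_particles`` the
    per-image whole-nucleus particle densities are compared with the pooled
    t-test.
    """
    all_stats = []
    all_density = []
    for im in image_sets:
        with _stage(f"segment:{im.name}"):
            nuclei = image_quant.segment_nuclei(im.dna, min_size=min_nucleus_size)
            foci = image_quant.segment_pch_foci(
                im.dna, nuclei, k_sd=k_sd, min_voxels=min_focus_voxels
            )
        with _stage(f"quantify:{im.name}"):
            stats = image_quant.nucleus_statistics(im.channels, nuclei, foci)
            stats.insert(0, "image", im.name)
            stats.insert(1, "group", im.group)
            all_stats.append(stats)
        if detect_particles:
            with _stage(f"particles:{im.name}"):
                for name, grid in im.channels.items():
                    det = image_quant.detect_particles(grid, nuclei)
                    dens = image_quant.region_particle_density(det, nuclei, foci)
                    dens.insert(0, "image", im.name)
                    dens.insert(1, "group", im.group)
                    dens.insert(2, "channel", name)
                    all_density.append(dens)
    stats = pd.concat(all_stats, ignore_index=True) if all_stats else pd.DataFrame()
    densities = (
        pd.concat(all_density, ignore_index=True) if all_density else None
    )

    tests = []
    if len(stats):
        groups = sorted(stats["group"].unique())
        channels = sorted(stats["channel"].unique())
        for ch in channels:
            for i, ga in enumerate(groups):
                for gb in groups[i + 1:]:
                    sub = stats[stats["channel"] == ch]
                    va = sub.loc[sub["group"] == ga, "accumulation"].dropna()
                    vb = sub.loc[sub["group"] == gb, "accumulation"].dropna()
                    if len(va) and len(vb):
                        u, p = image_quant.wilcoxon_rank_test(va, vb)
                        tests.append(
                            {
                                "channel": ch,
                                "quantity": "accumulation",
                                "group_a": ga,
                                "group_b": gb,
                                "test": "wilcoxon_rank",
                                "statistic": u,
                                "p_value": p,
                                "n_a": len(va),
                                "n_b": len(vb),
                            }
                        )
        if densities is not None:
            for ch in sorted(densities["channel"].unique()):
                sub = densities[
                    (densities["channel"] == ch)
                    & (densities["kind"] == "whole_nucleus")
                ]
                groups_d = sorted(sub["group"].unique())
                for i, ga in enumerate(groups_d):
                    for gb in groups_d[i + 1:]:
                        va = sub.loc[sub["group"] == ga, "density"]
                        vb = sub.loc[sub["group"] == gb, "density"]
                        if len(va) >= 2 and len(vb) >= 2:
                            t, p = image_quant.students_t_test(va, vb)
                            tests.append(
                                {
                                    "channel": ch,
                                    "quantity": "whole_nucleus_density",
                                    "group_a": ga,
                                    "group_b": gb,
                                    "test": "students_t",
                                    "statistic": t,
                                    "p_value": p,
                                    "n_a": len(va),
                                    "n_b": len(vb),
                                }
                            )
    group_tests = pd.DataFrame(tests)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        export = stats.copy()
        if "foci_sizes" in export.columns:
            export["foci_sizes"] = export["foci_sizes"].map(
                lambda t: ";".join(repr(x) for x in t)
            )
        export.to_csv(out / "nucleus_stats.tsv", sep="\t", index=False)
        group_tests.to_csv(out / "group_tests.tsv", sep="\t", index=False)
        if densities is not None:
            densities.to_csv(out / "particle_densities.tsv", sep="\t", index=False)
        with open(out / "report.txt", "w", encoding="utf-8") as fh:
            fh.write(f"nuclei quantified: {stats['nucleus_id'].count()}\n")
            for _, row in group_tests.iterrows():
                fh.write(
                    f"{row['channel']} {row['quantity']} {row['group_a']} vs "
                    f"{row['group_b']}: {row['test']} statistic="
                    f"{row['statistic']:.4g} p={row['p_value']:.4g}\n"
                )

    return ImagePipelineResult(stats, group_tests, densities)
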