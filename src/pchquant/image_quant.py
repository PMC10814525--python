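"""Quantification of nuclei, heterochromatin foci and particle densities.

Operates on 2D images or 3D stacks (axis order ``(z, )y, x``; voxel
coordinates 0-based) with a physical voxel size per axis in µm, so every
reported size is in µm² (2D) or µm³ (3D).

Key quantities, per nucleus and channel:

* *heterochromatin accumulation* — mean intensity inside the PCH foci of a
  nucleus divided by the mean nucleoplasm intensity of the same nucleus,
  where the nucleoplasm excludes a 1-voxel dilation of the foci (guards the
  denominator against partial-volume halos);
* *fraction in PCH* — percentage of the nucleus's total fluorescence that
  falls inside its foci;
* *mean PCH size* — total foci volume divided by the number of foci.

Group comparisons use the exact rank-sum (Mann-Whitney) test for
accumulation-type quantities and the pooled-variance unpaired t-test for
particle densities.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

__all__ = [
    "IntensityGrid",
    "LabelMask",
    "segment_nuclei",
    "segment_pch_foci",
    "nucleus_statistics",
    "detect_particles",
    "region_particle_density",
    "wilcoxon_rank_test",
    "students_t_test",
    "crosslevel_summary",
]


@dataclass
class IntensityGrid:
    """A 2D/3D intensity image with physical voxel size (µm per axis)."""

    values: np.ndarray
    voxel_size: tuple
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim not in (2, 3):
            raise ValueError("grid must be 2D or 3D")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != self.values.ndim:
            raise ValueError("voxel_size must have one entry per axis")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")
        if min(self.values.shape) < 1:
            raise ValueError("all dimensions must be >= 1")

    @property
    def voxel_volume(self) -> float:
        """Physical size of one voxel (µm² in 2D, µm³ in 3D)."""
        return float(np.prod(self.voxel_size))


@dataclass
class LabelMask:
    """Integer-labelled segmentation congruent with an IntensityGrid."""

    labels: np.ndarray
    kind: str = "custom_region"
    voxel_size: tuple | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer")
        if self.voxel_size is not None:
            self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())

    def object_ids(self):
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i != 0]


def _full_connectivity(ndim: int) -> np.ndarray:
    return np.ones((3,) * ndim, dtype=int)


def segment_nuclei(
    dna: IntensityGrid,
    min_size: float | None = None,
    split_touching: bool = False,
) -> LabelMask:
    """Segment nuclei from a DNA counterstain channel.

    Global Otsu threshold, hole filling, removal of objects below a minimum
    physical size (default 10 µm² in 2D / 50 µm³ in 3D) and full-connectivity
    labelling.  ``split_touching`` additionally runs a distance-transform
    watershed to separate touching nuclei.  A constant image yields zero
    objects.
    """
    img = dna.values
    if np.ptp(img) == 0:
        return LabelMask(np.zeros(img.shape, dtype=np.int32), "nucleus", dna.voxel_size)
    if min_size is None:
        min_size = 10.0 if img.ndim == 2 else 50.0
    binary = img > threshold_otsu(img)
    binary = ndimage.binary_fill_holes(binary)
    structure = _full_connectivity(img.ndim)
    labels, _ = ndimage.label(binary, structure=structure)
    # drop objects below the physical minimum size
    vox = dna.voxel_volume
    counts = np.bincount(labels.ravel())
    small = np.flatnonzero(counts * vox < min_size)
    if small.size:
        binary[np.isin(labels, small[small > 0])] = False
    if split_touching:
        distance = ndimage.distance_transform_edt(binary, sampling=dna.voxel_size)
        peak_sep = max(1, int(round(1.0 / min(dna.voxel_size))))
        coords = peak_local_max(
            distance, min_distance=peak_sep, labels=binary, exclude_border=False
        )
        markers = np.zeros(img.shape, dtype=np.int32)
        for i, c in enumerate(coords, start=1):
            markers[tuple(c)] = i
        labels = watershed(-distance, markers, mask=binary)
    else:
        labels, _ = ndimage.label(binary, structure=structure)
    labels = _relabel_consecutive(labels)
    return LabelMask(labels.astype(np.int32), "nucleus", dna.voxel_size)


def _relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    ids = np.unique(labels)
    ids = ids[ids != 0]
    out = np.zeros_like(labels)
    for new, old in enumerate(np.sort(ids), start=1):
        out[labels == old] = new
    return out


def segment_pch_foci(
    dna: IntensityGrid,
    nuclei: LabelMask,
    k_sd: float = 1.5,
    min_voxels: int = 2,
) -> LabelMask:
    """Segment bright heterochromatin foci within each nucleus.

    Per nucleus, voxels brighter than ``mean + k_sd * sd`` of the
    in-nucleus DNA intensity form candidate foci; connected components with
    at least ``min_voxels`` voxels are kept and labelled globally uniquely.
    """
    img = dna.values
    if img.shape != nuclei.labels.shape:
        raise ValueError("nuclei mask must be congruent with the DNA grid")
    structure = _full_connectivity(img.ndim)
    out = np.zeros(img.shape, dtype=np.int32)
    next_label = 1
    for nid in nuclei.object_ids():
        region = nuclei.labels == nid
        vals = img[region]
        thr = vals.mean() + k_sd * vals.std()
        cand = region & (img > thr)
        labels, n = ndimage.label(cand, structure=structure)
        for fid in range(1, n + 1):
            voxels = labels == fid
            if int(voxels.sum()) >= min_voxels:
                out[voxels] = next_label
                next_label += 1
    return LabelMask(out, "focus", nuclei.voxel_size or dna.voxel_size)


def nucleus_statistics(
    channels,
    nuclei: LabelMask,
    foci: LabelMask,
    voxel_size: tuple | None = None,
) -> pd.DataFrame:
    """Per-(nucleus, channel) geometry and fluorescence statistics.

    ``channels`` maps channel name to :class:`IntensityGrid` (a single grid
    is accepted too).  Returns one row per nucleus and channel with nucleus
    and foci sizes (physical units), per-channel means and sums, the
    heterochromatin accumulation (mean PCH / mean nucleoplasm, missing if
    the nucleoplasm is empty or the nucleus has no foci) and the percentage
    of total fluorescence located in PCH.
    """
    if isinstance(channels, IntensityGrid):
        channels = {channels.channel_name or "channel": channels}
    first = next(iter(channels.values()))
    if voxel_size is None:
        voxel_size = nuclei.voxel_size or first.voxel_size
    vox = float(np.prod(voxel_size))
    structure = _full_connectivity(first.values.ndim)

    rows = []
    for nid in nuclei.object_ids():
        nuc_mask = nuclei.labels == nid
        nucleus_size = float(nuc_mask.sum()) * vox
        foci_ids = [
            int(f) for f in np.unique(foci.labels[nuc_mask]) if f != 0
        ]
        foci_sizes = [
            float((foci.labels == f).sum()) * vox for f in foci_ids
        ]
        pch_mask = nuc_mask & (foci.labels > 0)
        total_foci_volume = float(pch_mask.sum()) * vox
        foci_count = len(foci_ids)
        mean_pch_size = total_foci_volume / foci_count if foci_count else math.nan
        halo = ndimage.binary_dilation(pch_mask, structure=structure)
        nucleoplasm_mask = nuc_mask & ~halo
        for name, grid in channels.items():
            vals = grid.values
            mean_nucleus = float(vals[nuc_mask].mean())
            sum_nucleus = float(vals[nuc_mask].sum()) * vox
            if pch_mask.any():
                mean_pch = float(vals[pch_mask].mean())
                sum_pch = float(vals[pch_mask].sum()) * vox
            else:
                mean_pch, sum_pch = math.nan, 0.0
            if nucleoplasm_mask.any():
                mean_nucleoplasm = float(vals[nucleoplasm_mask].mean())
            else:
                mean_nucleoplasm = math.nan
            if pch_mask.any() and nucleoplasm_mask.any() and mean_nucleoplasm != 0:
                accumulation = mean_pch / mean_nucleoplasm
            else:
                accumulation = math.nan
            fraction_in_pch = (
                100.0 * sum_pch / sum_nucleus if sum_nucleus > 0 else math.nan
            )
            rows.append(
                {
                    "nucleus_id": nid,
                    "channel": name,
                    "nucleus_size": nucleus_size,
                    "foci_count": foci_count,
                    "foci_sizes": tuple(foci_sizes),
                    "total_foci_volume": total_foci_volume,
                    "mean_pch_size": mean_pch_size,
                    "mean_nucleus": mean_nucleus,
                    "mean_nucleoplasm": mean_nucleoplasm,
                    "mean_pch": mean_pch,
                    "sum_nucleus": sum_nucleus,
                    "sum_pch": sum_pch,
                    "accumulation": accumulation,
                    "fraction_in_pch": fraction_in_pch,
                }
            )
    return pd.DataFrame(rows)


def detect_particles(
    grid: IntensityGrid,
    region: LabelMask,
    sigma: float = 1.0,
    threshold_abs: float | None = None,
    min_distance: int = 3,
) -> pd.DataFrame:
    """Detect point-like particles (e.g. immunogold) inside labelled regions.

    Gaussian smoothing (``sigma`` in pixels) followed by local-maxima
    detection above an absolute intensity threshold with a minimum peak
    separation; peaks closer than ``min_distance`` merge into one detection.
    When ``threshold_abs`` is None an Otsu threshold of the smoothed image
    is used.  Returns a frame of voxel coordinates with the region label of
    each detection (detections outside any region are dropped).
    """
    if grid.values.shape != region.labels.shape:
        raise ValueError("region mask must be congruent with the grid")
    smoothed = ndimage.gaussian_filter(grid.values, sigma=sigma)
    if threshold_abs is None:
        if np.ptp(smoothed) == 0:
            return pd.DataFrame(columns=["region_label", "coords"])
        threshold_abs = float(threshold_otsu(smoothed))
    coords = peak_local_max(
        smoothed,
        min_distance=min_distance,
        threshold_abs=threshold_abs,
        exclude_border=False,
    )
    rows = []
    for c in coords:
        label = int(region.labels[tuple(c)])
        if label > 0:
            rows.append({"region_label": label, "coords": tuple(int(x) for x in c)})
    return pd.DataFrame(rows, columns=["region_label", "coords"])


def _mask_density(coords, mask: np.ndarray, vox: float, kind: str) -> dict:
    size = float(mask.sum()) * vox
    if size == 0:
        raise ValueError(f"zero-size region for kind {kind!r}")
    count = sum(1 for c in coords if mask[tuple(c)])
    return {
        "kind": kind,
        "particle_count": int(count),
        "region_size": size,
        "density": count / size,
    }


def region_particle_density(
    detections: pd.DataFrame,
    nuclei: LabelMask,
    foci: LabelMask,
    voxel_size: tuple | None = None,
) -> pd.DataFrame:
    """Particle densities in the three reference region kinds.

    ``pch`` — all heterochromatin foci regions; ``pch_in_nucleus`` — foci
    lying inside segmented nuclei; ``whole_nucleus`` — entire nuclei.
    Density is particle count per physical region size (µm⁻² / µm⁻³).
    """
    if voxel_size is None:
        voxel_size = nuclei.voxel_size or foci.voxel_size
    if voxel_size is None:
        raise ValueError("voxel_size required")
    vox = float(np.prod(voxel_size))
    coords = list(detections["coords"]) if len(detections) else []
    nuc = nuclei.labels > 0
    pch = foci.labels > 0
    rows = [
        _mask_density(coords, pch, vox, "pch"),
        _mask_density(coords, pch & nuc, vox, "pch_in_nucleus"),
        _mask_density(coords, nuc, vox, "whole_nucleus"),
    ]
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# group statistics


def wilcoxon_rank_test(group_a, group_b, exact_limit: int = 12):
    """Two-sided rank-sum (Mann-Whitney) test.

    For ``n_a + n_b <= exact_limit`` the p-value is computed by exhaustive
    enumeration of all group labelings of the observed values (midranks for
    ties), counting labelings whose rank sum deviates from its mean at
    least as much as the observed one.  Larger samples use the normal
    approximation with tie and continuity correction.  Returns
    ``(U, p_two_sided)`` with ``U`` the Mann-Whitney statistic of group a.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must contain at least one value")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    w_obs = float(ranks[:n_a].sum())
    u_obs = w_obs - n_a * (n_a + 1) / 2.0

    if n <= exact_limit:
        mu = n_a * (n + 1) / 2.0
        dev_obs = abs(w_obs - mu)
        total = 0
        extreme = 0
        for idx in itertools.combinations(range(n), n_a):
            total += 1
            w = float(ranks[list(idx)].sum())
            if abs(w - mu) >= dev_obs - 1e-9:
                extreme += 1
        return u_obs, extreme / total

    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def students_t_test(group_a, group_b):
    """Two-tailed unpaired Student's t-test (pooled variance).

    Returns ``(t, p)`` with ``n_a + n_b - 2`` degrees of freedom.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group must contain at least two values")
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def crosslevel_summary(records: pd.DataFrame, n_bins: int = 3) -> pd.DataFrame:
    """Expression-level cross table of accumulation and compartment size.

    Cells are binned into quantile bins (tertiles by default) of their total
    H1 and total MeCP2 signal; per (H1 bin, MeCP2 bin) the mean PCH
    accumulation of each protein and the mean PCH compartment size are
    reported.  Bins without cells appear with missing means.

    ``records`` needs columns ``h1_total``, ``mecp2_total``,
    ``h1_accumulation``, ``mecp2_accumulation``, ``mean_pch_size``.
    """

    def _qbin(series: pd.Series) -> pd.Series:
        if series.nunique() <= 1:
            return pd.Series(0, index=series.index)
        binned = pd.qcut(series, q=n_bins, labels=False, duplicates="drop")
        return binned.astype(int)

    h1_bin = _qbin(records["h1_total"])
    mecp2_bin = _qbin(records["mecp2_total"])
    grouped = records.assign(h1_bin=h1_bin, mecp2_bin=mecp2_bin).groupby(
        ["h1_bin", "mecp2_bin"]
    )
    agg = grouped.agg(
        h1_accumulation=("h1_accumulation", "mean"),
        mecp2_accumulation=("mecp2_accumulation", "mean"),
        mean_pch_size=("mean_pch_size", "mean"),
        n_cells=("h1_total", "size"),
    )
    full = pd.MultiIndex.from_product(
        [sorted(h1_bin.unique()), sorted(mecp2_bin.unique())],
        names=["h1_bin", "mecp2_bin"],
    )
    agg = agg.reindex(full)
    agg["n_cells"] = agg["n_cells"].fillna(0).astype(int)
    return agg
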