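"""Reading, filtering and normalisation of dimethyl-labelling ratio tables.

In a dimethyl-labelling experiment every individual sample is labelled
*light* (L) and mixed with a pooled medium-heavy reference (H), so the
search engine reports one H/L ratio per protein group and sample.  Because
the heavy reference is common to all samples, the quotient of two samples'
H/L ratios cancels the reference::

    (H/L_a) / (H/L_b) = (H/L_a) * (L_b/H) = L_b / L_a

i.e. the abundance of sample *b* relative to sample *a*.  This module reads
``proteinGroups``-style tab-separated tables, removes decoy/contaminant
rows, drops poorly supported ratios, centres each sample's ratio
distribution on its most frequent value, and performs the quotient algebra
above.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RatioTable",
    "read_protein_groups",
    "write_protein_groups",
    "filter_records",
    "estimate_log2_mode",
    "normalize_to_mode",
    "fraction_ratio",
    "summarize_replicates",
]

#: required non-sample columns of the proteinGroups dialect
_FIXED_COLUMNS = ("Protein IDs", "Gene names", "Reverse", "Potential contaminant")

_RATIO_PREFIX = "Ratio H/L "
_COUNT_PREFIX = "Ratio H/L count "
_INTENSITY_PREFIX = "Intensity "


@dataclass
class RatioTable:
    """One proteinGroups-style table held as aligned per-sample frames.

    All frames are indexed by protein group identifier; ``ratios`` holds the
    per-sample H/L ratios with ``NaN`` meaning *not quantified in that
    sample*.
    """

    ratios: pd.DataFrame
    counts: pd.DataFrame
    intensities: pd.DataFrame
    gene_names: pd.Series
    is_reverse: pd.Series
    is_contaminant: pd.Series
    normalized: bool = False

    def __post_init__(self) -> None:
        cols = list(self.ratios.columns)
        if len(set(cols)) != len(cols):
            raise ValueError("sample identifiers must be unique")
        for frame in (self.counts, self.intensities):
            if list(frame.columns) != cols or not frame.index.equals(self.ratios.index):
                raise ValueError("ratio/count/intensity frames must be aligned")

    @property
    def samples(self) -> list[str]:
        return list(self.ratios.columns)

    @property
    def protein_ids(self) -> pd.Index:
        return self.ratios.index

    def __len__(self) -> int:
        return len(self.ratios)

    def copy(self) -> "RatioTable":
        return RatioTable(
            ratios=self.ratios.copy(),
            counts=self.counts.copy(),
            intensities=self.intensities.copy(),
            gene_names=self.gene_names.copy(),
            is_reverse=self.is_reverse.copy(),
            is_contaminant=self.is_contaminant.copy(),
            normalized=self.normalized,
        )


def _parse_float(cell: str, column: str, row: int) -> float:
    if cell is None or cell == "" or cell.lower() == "nan":
        return math.nan
    try:
        return float(cell)
    except ValueError:
        raise ValueError(
            f"non-numeric value {cell!r} in column {column!r} at file row {row}"
        ) from None


def read_protein_groups(path) -> RatioTable:
    """Read a tab-delimited proteinGroups-style table.

    Samples are discovered from the ``Ratio H/L <sample>`` columns; each
    sample must also carry ``Ratio H/L count <sample>`` and
    ``Intensity <sample>`` columns.  ``+`` in the ``Reverse`` /
    ``Potential contaminant`` columns parses as True, blank as False.
    Empty ratio cells parse as missing.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _FIXED_COLUMNS:
        if col not in raw.columns:
            raise ValueError(f"missing column {col!r}")
    samples = [
        c[len(_RATIO_PREFIX):]
        for c in raw.columns
        if c.startswith(_RATIO_PREFIX) and not c.startswith(_COUNT_PREFIX)
    ]
    if not samples:
        raise ValueError("missing column: no 'Ratio H/L <sample>' columns found")
    for s in samples:
        for col in (_COUNT_PREFIX + s, _INTENSITY_PREFIX + s):
            if col not in raw.columns:
                raise ValueError(f"missing column {col!r}")

    index = pd.Index(raw["Protein IDs"], name="protein_id")
    ratios = {}
    counts = {}
    intensities = {}
    for s in samples:
        rcol, ccol, icol = _RATIO_PREFIX + s, _COUNT_PREFIX + s, _INTENSITY_PREFIX + s
        # file row numbers are 1-based and include the header line
        ratios[s] = [
            _parse_float(v, rcol, i + 2) for i, v in enumerate(raw[rcol])
        ]
        counts[s] = [
            int(_parse_float(v, ccol, i + 2)) if v != "" else 0
            for i, v in enumerate(raw[ccol])
        ]
        intensities[s] = [
            _parse_float(v, icol, i + 2) for i, v in enumerate(raw[icol])
        ]
    return RatioTable(
        ratios=pd.DataFrame(ratios, index=index),
        counts=pd.DataFrame(counts, index=index),
        intensities=pd.DataFrame(intensities, index=index).fillna(0.0),
        gene_names=pd.Series(list(raw["Gene names"]), index=index, name="gene_name"),
        is_reverse=pd.Series(
            [v == "+" for v in raw["Reverse"]], index=index, name="is_reverse"
        ),
        is_contaminant=pd.Series(
            [v == "+" for v in raw["Potential contaminant"]],
            index=index,
            name="is_contaminant",
        ),
    )


def _fmt(x: float) -> str:
    """Shortest exact decimal representation; empty string for missing."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    return repr(float(x))


def write_protein_groups(table: RatioTable, path) -> None:
    """Write ``table`` in the same dialect ``read_protein_groups`` accepts.

    Floats are written in shortest round-trip form so that
    ``read_protein_groups(write_protein_groups(t))`` reproduces ``t``
    bit-exactly.
    """
    buf = io.StringIO()
    samples = table.samples
    header = list(_FIXED_COLUMNS[:2])
    for s in samples:
        header += [_RATIO_PREFIX + s, _COUNT_PREFIX + s, _INTENSITY_PREFIX + s]
    header += list(_FIXED_COLUMNS[2:])
    buf.write("\t".join(header) + "\n")
    for pid in table.protein_ids:
        row = [str(pid), str(table.gene_names.loc[pid])]
        for s in samples:
            row.append(_fmt(table.ratios.at[pid, s]))
            row.append(str(int(table.counts.at[pid, s])))
            row.append(_fmt(table.intensities.at[pid, s]))
        row.append("+" if table.is_reverse.loc[pid] else "")
        row.append("+" if table.is_contaminant.loc[pid] else "")
        buf.write("\t".join(row) + "\n")
    data = buf.getvalue()
    if hasattr(path, "write"):
        path.write(data)
    else:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(data)


def filter_records(table: RatioTable, min_ratio_count: int = 2) -> RatioTable:
    """Remove decoy/contaminant rows and poorly supported ratios.

    Ratios supported by fewer than ``min_ratio_count`` peptide-level
    measurements in a sample are set to missing for that sample; rows left
    with no quantified sample are dropped.  Idempotent; output rows are a
    subset of input rows.
    """
    keep = ~(table.is_reverse | table.is_contaminant)
    ratios = table.ratios.loc[keep].copy()
    counts = table.counts.loc[keep]
    ratios[counts < min_ratio_count] = np.nan
    surviving = ratios.notna().any(axis=1)
    idx = ratios.index[surviving]
    return RatioTable(
        ratios=ratios.loc[idx],
        counts=counts.loc[idx].copy(),
        intensities=table.intensities.loc[idx].copy(),
        gene_names=table.gene_names.loc[idx].copy(),
        is_reverse=table.is_reverse.loc[idx].copy(),
        is_contaminant=table.is_contaminant.loc[idx].copy(),
        normalized=table.normalized,
    )


def estimate_log2_mode(log2_values) -> float:
    """Most frequent value of a sample of log2 ratios.

    Estimated as the argmax of a Gaussian kernel density (Silverman
    bandwidth) evaluated on a 512-point grid spanning the data.  The grid is
    shift-equivariant, so re-estimating on centred data returns exactly 0.
    """
    x = np.asarray(log2_values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("cannot estimate mode of an empty sample")
    if np.ptp(x) == 0:
        return float(x[0])
    kde = stats.gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), 512)
    return float(grid[int(np.argmax(kde(grid)))])


def normalize_to_mode(table: RatioTable, min_ratios: int = 10) -> RatioTable:
    """Divide each sample's ratios by that sample's most frequent ratio.

    After normalisation the estimated mode of every sample sits at ratio 1
    (0 on the log2 scale), centring unchanged proteins at 1.
    """
    out = table.copy()
    for s in out.samples:
        vals = out.ratios[s].dropna()
        if len(vals) < min_ratios:
            raise ValueError(
                f"too few ratios to estimate mode in sample {s!r} "
                f"({len(vals)} < {min_ratios})"
            )
        mode_log2 = estimate_log2_mode(np.log2(vals.to_numpy()))
        out.ratios[s] = out.ratios[s] / (2.0 ** mode_log2)
    out.normalized = True
    return out


def fraction_ratio(table: RatioTable, sample_a: str, sample_b: str) -> pd.Series:
    """Per-protein abundance of ``sample_b`` relative to ``sample_a``.

    Computed as ``ratio_hl(a) / ratio_hl(b) = L_b / L_a`` — both samples
    must share the pooled heavy reference.  Proteins missing in either
    sample are absent from the output.
    """
    for s in (sample_a, sample_b):
        if s not in table.ratios.columns:
            raise ValueError(f"unknown sample identifier {s!r}")
    values = table.ratios[sample_a] / table.ratios[sample_b]
    values = values.dropna()
    values.name = f"{sample_b}/{sample_a}"
    values.attrs["pair"] = (sample_a, sample_b)
    return values


def summarize_replicates(replicate_values) -> pd.DataFrame:
    """Combine per-replicate sample ratios into one summary per protein.

    Ratios are multiplicative, so the summary is the geometric mean of the
    replicate values; the per-protein replicate count and the standard
    deviation of the log2 values (ddof=1, NaN for singletons) are reported
    alongside.
    """
    series = [pd.Series(v).dropna() for v in replicate_values]
    if not series:
        return pd.DataFrame(columns=["summary", "n_replicates", "log2_sd"])
    log2 = pd.concat([np.log2(s) for s in series], axis=1)
    mean_log2 = log2.mean(axis=1, skipna=True)
    n = log2.notna().sum(axis=1)
    sd = log2.std(axis=1, ddof=1, skipna=True)
    out = pd.DataFrame(
        {"summary": 2.0 ** mean_log2, "n_replicates": n, "log2_sd": sd}
    )
    return out[out["n_replicates"] > 0]
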