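import numpy as np
import pandas as pd
import pytest

from pchquant.ms_quant import RatioTable
from pchquant.synthetic import ImageSimConfig, MsSimConfig, simulate_nucleus_image


@pytest.fixture
def small_table() -> RatioTable:
    """Hand-built three-protein table with one reverse and one contaminant row."""
    idx = pd.Index(["P1", "P2", "P3", "REV__P4", "CON__P5"], name="protein_id")
    samples = ["brain_nuclei", "brain_pch"]
    ratios = pd.DataFrame(
        {
            "brain_nuclei": [2.0, 1.0, np.nan, 1.0, 1.0],
            "brain_pch": [0.5, 1.0, 2.0, 1.0, 1.0],
        },
        index=idx,
    )
    counts = pd.DataFrame(
        {"brain_nuclei": [3, 2, 0, 5, 5], "brain_pch": [4, 1, 2, 5, 5]}, index=idx
    )
    intensities = pd.DataFrame(
        {
            "brain_nuclei": [1e6, 2e6, 0.0, 1e5, 1e5],
            "brain_pch": [4e6, 1e6, 3e6, 1e5, 1e5],
        },
        index=idx,
    )
    return RatioTable(
        ratios=ratios,
        counts=counts,
        intensities=intensities,
        gene_names=pd.Series(["GenA", "GenB", "GenC", "RevD", "ConE"], index=idx),
        is_reverse=pd.Series([False, False, False, True, False], index=idx),
        is_contaminant=pd.Series([False, False, False, False, True], index=idx),
    )


@pytest.fixture(scope="session")
def noise_free_ms():
    """Noise- and missingness-free simulated study (deterministic)."""
    from pchquant.synthetic import simulate_protein_groups

    config = MsSimConfig(
        noise_sd_log2=0.0, dropout_prob=0.0, low_count_fraction=0.0, seed=11
    )
    tables, truth = simulate_protein_groups(config)
    return config, tables, truth


@pytest.fixture(scope="session")
def noise_free_image():
    """Noise-free simulated field of five nuclei."""
    config = ImageSimConfig(
        grid_shape=(300, 300), voxel_size=(0.2, 0.2), n_nuclei=5, seed=5
    )
    return config, simulate_nucleus_image(config)


def match_truth_nuclei(truth_mask, seg_mask):
    """Map truth nucleus ids to segmented ids by maximal overlap."""
    mapping = {}
    for tid in truth_mask.object_ids():
        region = truth_mask.labels == tid
        labels, counts = np.unique(seg_mask.labels[region], return_counts=True)
        nonzero = labels != 0
        if nonzero.any():
            mapping[tid] = int(labels[nonzero][np.argmax(counts[nonzero])])
    return mapping
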