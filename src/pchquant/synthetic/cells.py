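"""Simulated cotransfected cell populations under a competition model.

Each cell expresses two chromatin proteins (linker histone H1 and MeCP2) at
independent random levels.  Both bind the same pericentromeric
heterochromatin compartment, so the planted accumulation of each protein at
the compartment falls with the *other* protein's expression::

    accumulation_A = base_A / (1 + k * level_B)

with ``k`` the competition (interaction) strength.  The mean compartment
size reflects MeCP2-driven focus fusion and H1-driven compaction::

    size = s0 * (1 + a * mecp2 - b * h1)       (clipped positive)

With ``k = 0`` the two proteins are independent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["simulate_cotransfection_population"]


def simulate_cotransfection_population(
    n_cells: int,
    h1_level_range: tuple = (0.5, 2.0),
    mecp2_level_range: tuple = (0.5, 2.0),
    interaction_strength: float = 1.0,
    seed: int = 0,
    base_accumulation: tuple = (3.0, 3.0),
    base_size: float = 2.0,
    size_mecp2_coef: float = 0.3,
    size_h1_coef: float = 0.3,
    noise_sd_log2: float = 0.0,
):
    """Generate per-cell records and the planted noise-free truth.

    Returns ``(records, truth)``; both are frames indexed by cell id with
    columns ``h1_total``, ``mecp2_total``, ``h1_accumulation``,
    ``mecp2_accumulation`` and ``mean_pch_size``; ``records`` adds
    multiplicative log-normal measurement noise (``noise_sd_log2``) to the
    truth.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    for name, rng_pair in (("h1_level_range", h1_level_range),
                           ("mecp2_level_range", mecp2_level_range)):
        lo, hi = rng_pair
        if lo <= 0 or hi <= 0 or hi < lo:
            raise ValueError(f"{name} must be positive with high >= low")

    rng = np.random.default_rng(seed)
    h1 = rng.uniform(*h1_level_range, size=n_cells)
    mecp2 = rng.uniform(*mecp2_level_range, size=n_cells)
    k = float(interaction_strength)
    base_h1, base_mecp2 = base_accumulation

    acc_h1 = base_h1 / (1.0 + k * mecp2)
    acc_mecp2 = base_mecp2 / (1.0 + k * h1)
    size = base_size * (1.0 + size_mecp2_coef * mecp2 - size_h1_coef * h1)
    size = np.clip(size, 0.05 * base_size, None)

    idx = pd.Index([f"cell{i:04d}" for i in range(n_cells)], name="cell_id")
    truth = pd.DataFrame(
        {
            "h1_total": h1,
            "mecp2_total": mecp2,
            "h1_accumulation": acc_h1,
            "mecp2_accumulation": acc_mecp2,
            "mean_pch_size": size,
        },
        index=idx,
    )
    records = truth.copy()
    if noise_sd_log2 > 0:
        for col in ("h1_accumulation", "mecp2_accumulation", "mean_pch_size"):
            records[col] = records[col] * 2.0 ** rng.normal(
                0.0, noise_sd_log2, size=n_cells
            )
    return records, truth
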