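"""Synthetic replicate-wise protein quantification tables for co-IP selection.

Emulates an n-replicate immunoprecipitation / label-free LC-MS/MS
comparison: spiked interactors satisfy every selection criterion (>= 3
peptides in each target-IP replicate, >= 10-fold enrichment, small adjusted
p), a configurable subset is additionally/solely "unique" (zero control
signal), and background proteins each violate at least one criterion.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["generate_protein_quant"]


def generate_protein_quant(
    n_proteins: int,
    n_replicates: int,
    spiked_interactors: set | None = None,
    unique_proteins: set | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """One row per protein with per-replicate peptide counts and control
    abundances, a fold change and an adjusted p-value.

    ``spiked_interactors`` and ``unique_proteins`` are sets of protein names
    (``P0001`` style); unlisted proteins are background and are guaranteed
    to fail at least one selection criterion.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    spiked = set(spiked_interactors or ())
    unique = set(unique_proteins or ())
    names = [f"P{i + 1:04d}" for i in range(n_proteins)]
    unknown = (spiked | unique) - set(names)
    if unknown:
        raise ValueError(f"spiked/unique proteins outside the table: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    rows = []
    for name in names:
        is_spiked = name in spiked
        is_unique = name in unique
        if is_spiked or is_unique:
            peptides = rng.integers(3, 12, size=n_replicates)
            ctrl = (
                np.zeros(n_replicates)
                if is_unique
                else np.round(rng.uniform(1e4, 1e5, size=n_replicates), 1)
            )
            fold = float(np.round(rng.uniform(10.0, 60.0), 2))
            padj = (
                float(np.round(rng.uniform(0.0005, 0.01), 6))
                if is_spiked
                else float(np.round(rng.uniform(0.1, 0.9), 6))
            )
        else:
            # background: break one criterion at random, keep control signal
            # nonzero so the uniqueness branch cannot rescue it
            peptides = rng.integers(3, 12, size=n_replicates)
            fold = float(np.round(rng.uniform(10.0, 40.0), 2))
            padj = float(np.round(rng.uniform(0.0005, 0.04), 6))
            breakage = rng.integers(3)
            if breakage == 0:
                peptides[rng.integers(n_replicates)] = rng.integers(0, 3)
            elif breakage == 1:
                fold = float(np.round(rng.uniform(0.2, 9.5), 2))
            else:
                padj = float(np.round(rng.uniform(0.06, 0.9), 6))
            ctrl = np.round(rng.uniform(1e4, 1e5, size=n_replicates), 1)
        row = {"protein": name, "fold_change": fold, "padj": padj}
        for r in range(n_replicates):
            row[f"pep_ip_{r + 1}"] = int(peptides[r])
            row[f"abund_ctrl_{r + 1}"] = float(ctrl[r])
        rows.append(row)
    return pd.DataFrame(rows)
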