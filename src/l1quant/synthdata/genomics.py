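"""Synthetic full-length LINE-1 locus annotations and count matrices.

The locus fixture emulates the structure of a curated full-length coding
LINE-1 annotation: >= 6 kb elements on a small set of chromosomes, an exact
family split (L1HS / L1PA2), a programmed intronic/intergenic partition
against generated gene bodies, and a scatter of unique-k-mer regions (the
mappability track surrogate).  Count matrices are negative-binomial with
per-sample library-size factors and per-locus aged/young fold changes, with
sample ages drawn to respect the young (<= 65 y) / aged (> 65 y) design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "L1FixtureSpec",
    "CountDesign",
    "generate_l1_fixture",
    "generate_count_matrix",
]

MIN_UID_LENGTH = 6000  # bp; full-length coding elements exceed 6 kb


@dataclass
class L1FixtureSpec:
    """Layout of a synthetic UID annotation fixture."""

    n_chromosomes: int = 2
    chromosome_length: int = 5_000_000
    n_uids: int = 146
    family_mix: dict = field(
        default_factory=lambda: {"L1HS": 111 / 146, "L1PA2": 35 / 146}
    )
    fraction_intronic: float = 68 / 146
    n_genes: int = 80
    unique_mer_region_density: float = 2.0  # regions per kb
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.family_mix.values()) - 1.0) > 1e-9:
            raise ValueError("family_mix fractions must sum to 1")
        if not 0 <= self.fraction_intronic <= 1:
            raise ValueError("fraction_intronic must lie in [0, 1]")
        if self.chromosome_length < MIN_UID_LENGTH * 2:
            raise ValueError("chromosomes too short to host UIDs")


def _largest_remainder(fractions: dict, total: int) -> dict:
    """Integer allocation matching fractions exactly in expectation."""
    keys = sorted(fractions)
    quotas = np.array([fractions[k] * total for k in keys])
    counts = np.floor(quotas).astype(int)
    for i in np.argsort(-(quotas - counts))[: total - counts.sum()]:
        counts[i] += 1
    return dict(zip(keys, counts))


def _place_nonoverlapping(
    rng, avoid: list, record: dict, chroms: list, chrom_len: int, length: int,
    within: tuple | None = None, max_retries: int = 1000,
):
    """Sample a (chrom, start) for an interval avoiding occupied layers.

    ``avoid`` is a list of occupancy dicts (chrom -> [(start, end), ...])
    the new interval must not intersect; the placement is recorded in
    ``record``.  ``within`` restricts placement to a (chrom, start, end)
    window (used to drop a UID inside a gene body).
    """
    for _ in range(max_retries):
        if within is not None:
            chrom, lo, hi = within
            if hi - lo < length + 2:
                raise ValueError("host window too short")
            start = int(rng.integers(lo + 1, hi - length))  # strictly inside
        else:
            chrom = chroms[rng.integers(len(chroms))]
            start = int(rng.integers(0, chrom_len - length))
        end = start + length
        clash = any(
            s < end and start < e
            for layer in avoid
            for s, e in layer.get(chrom, [])
        )
        if not clash:
            record.setdefault(chrom, []).append((start, end))
            return chrom, start, end
    raise RuntimeError("infeasible interval placement; enlarge the chromosomes")


def generate_l1_fixture(
    spec: L1FixtureSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (uids, genes, unique_mer_regions) interval tables.

    All intervals are 0-based half-open.  Families follow the requested mix
    exactly (largest-remainder allocation); ``fraction_intronic`` of the
    UIDs lie strictly inside gene bodies, the rest clear of any gene.
    Unique-k-mer regions are >= 50 bp intervals scattered at the requested
    per-kb density (they may overlap each other, as the real track does).
    """
    rng = np.random.default_rng(spec.seed)
    chroms = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]
    gene_occ: dict = {}
    uid_occ: dict = {}

    gene_rows = []
    for g in range(spec.n_genes):
        length = int(rng.integers(20_000, 80_000))
        chrom, start, end = _place_nonoverlapping(
            rng, [gene_occ], gene_occ, chroms, spec.chromosome_length, length
        )
        gene_rows.append(
            {"chrom": chrom, "start": start, "end": end,
             "strand": "+" if rng.random() < 0.5 else "-",
             "gene_id": f"GENE{g + 1:04d}"}
        )
    genes = pd.DataFrame(gene_rows)

    n_intronic = int(round(spec.fraction_intronic * spec.n_uids))
    family_counts = _largest_remainder(spec.family_mix, spec.n_uids)
    families = [f for fam, n in sorted(family_counts.items()) for f in [fam] * n]
    families = list(rng.permutation(families))

    uid_rows = []
    for i in range(spec.n_uids):
        length = int(rng.integers(MIN_UID_LENGTH, MIN_UID_LENGTH + 2001))
        if i < n_intronic:
            placed = None
            for _host_try in range(100):  # retry across host genes
                host = genes.iloc[int(rng.integers(len(genes)))]
                if host["end"] - host["start"] < length + 2:
                    continue
                try:
                    placed = _place_nonoverlapping(
                        rng, [uid_occ], uid_occ, chroms,
                        spec.chromosome_length, length,
                        within=(host["chrom"], host["start"], host["end"]),
                        max_retries=20,
                    )
                    break
                except RuntimeError:
                    continue
            if placed is None:
                raise RuntimeError(
                    "cannot host all intronic UIDs; add or lengthen genes"
                )
            chrom, start, end = placed
        else:
            chrom, start, end = _place_nonoverlapping(
                rng, [gene_occ, uid_occ], uid_occ, chroms,
                spec.chromosome_length, length,
            )
        uid_rows.append(
            {"chrom": chrom, "start": start, "end": end,
             "name": f"UID-{i + 1}", "score": 0,
             "strand": "+" if rng.random() < 0.5 else "-",
             "uid": i + 1, "family": families[i]}
        )
    uids = pd.DataFrame(uid_rows).sort_values(["chrom", "start"]).reset_index(drop=True)

    n_mers = int(round(
        spec.unique_mer_region_density * spec.n_chromosomes
        * spec.chromosome_length / 1000
    ))
    mer_len = 50 + rng.integers(0, 101, size=n_mers)
    mer_chrom = rng.integers(0, spec.n_chromosomes, size=n_mers)
    mer_start = rng.integers(0, spec.chromosome_length - 200, size=n_mers)
    mers = (
        pd.DataFrame(
            {"chrom": [chroms[c] for c in mer_chrom],
             "start": mer_start, "end": mer_start + mer_len}
        )
        .sort_values(["chrom", "start"])
        .reset_index(drop=True)
    )
    return uids, genes, mers


@dataclass
class CountDesign:
    """Design of a synthetic UID x sample count matrix.

    ``baseline_mean`` and ``fold_change`` are scalars or per-UID arrays;
    ``library_size_factors`` is a per-sample array (default all ones).
    ``fold_change`` multiplies the expected count in aged samples only.
    """

    n_young: int = 6
    n_aged: int = 35
    baseline_mean: float | np.ndarray = 100.0
    dispersion: float = 0.1
    library_size_factors: np.ndarray | None = None
    fold_change: float | np.ndarray = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_young < 2 or self.n_aged < 2:
            raise ValueError("need at least 2 samples per group")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.library_size_factors is not None and np.any(
            np.asarray(self.library_size_factors) <= 0
        ):
            raise ValueError("size factors must be positive")


def generate_count_matrix(
    uid_names: list, design: CountDesign
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial counts for UIDs under a young/aged design.

    Counts for UID i in sample j are NB with mean
    ``baseline_i * size_factor_j * fold_i^[j is aged]`` and variance
    ``mu + dispersion * mu^2``.  Returns (counts, metadata); metadata rows
    carry a sampled donor age consistent with the group label (young
    uniform in 38-65, aged in 66-97).
    """
    rng = np.random.default_rng(design.seed)
    n_uids = len(uid_names)
    n = design.n_young + design.n_aged
    baseline = np.broadcast_to(
        np.asarray(design.baseline_mean, dtype=float), (n_uids,)
    ).copy()
    fold = np.broadcast_to(np.asarray(design.fold_change, dtype=float), (n_uids,)).copy()
    sf = (
        np.ones(n)
        if design.library_size_factors is None
        else np.asarray(design.library_size_factors, dtype=float)
    )
    if sf.shape != (n,):
        raise ValueError("library_size_factors must have one entry per sample")
    aged = np.zeros(n, dtype=bool)
    aged[design.n_young :] = True

    mu = baseline[:, None] * sf[None, :] * np.where(aged[None, :], fold[:, None], 1.0)
    if not np.all(np.isfinite(mu)) or np.any(mu < 0):
        raise ValueError("non-finite or negative expected counts")

    r = 1.0 / design.dispersion
    counts = np.zeros(mu.shape, dtype=np.int64)
    positive = mu > 0
    p = r / (r + mu[positive])
    counts[positive] = rng.negative_binomial(r, p)

    samples = [f"S{j + 1:02d}" for j in range(n)]
    ages = np.concatenate(
        [rng.integers(38, 66, size=design.n_young), rng.integers(66, 98, size=design.n_aged)]
    )
    counts_df = pd.DataFrame(counts, index=list(uid_names), columns=samples)
    metadata = pd.DataFrame(
        {"sample": samples, "age": ages,
         "group": np.where(aged, "aged", "young")}
    ).set_index("sample")
    return counts_df, metadata
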