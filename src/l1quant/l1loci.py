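"""Locus-resolved quantification and QC of full-length coding LINE-1 loci.

The human reference genome carries 146 full-length (>6 kb) LINE-1 copies
with intact ORF1 and ORF2, each tagged with a unique identifier (UID).
Because unique-read quantification of such young, highly similar repeats is
fragile, every UID carries quality annotations: a mappability score (number
of unique-50mer genomic regions overlapping the locus by at least 45 bp),
its genic context (intronic within a host gene vs intergenic), and its
subfamily (L1HS / L1PA2).  Count tables over UIDs are then filtered,
normalized by median-of-ratios size factors, and compared between young
(age <= 65 y) and aged (> 65 y) donors with rank-based statistics.

Intervals are 0-based half-open throughout; UID tables are pandas frames
with at least ``uid``, ``chrom``, ``start``, ``end``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from . import stats as l1stats

__all__ = [
    "classify_uid_context",
    "mappability_score",
    "summarize_uid_annotation",
    "filter_low_counts",
    "size_factors",
    "size_factors_and_normalize",
    "differential_uid_expression",
    "global_uid_trend",
    "regulator_correlation",
    "group_from_age",
]

YOUNG_MAX_AGE = 65  # inclusive upper bound of the 'young' group, years


def group_from_age(ages) -> pd.Series:
    """Age-group labels: 'young' for age <= 65 years, else 'aged'."""
    ages = pd.Series(ages)
    return pd.Series(
        np.where(ages <= YOUNG_MAX_AGE, "young", "aged"), index=ages.index
    )


def _check_intervals(df: pd.DataFrame, what: str) -> None:
    if (df["end"] - df["start"] < 0).any():
        raise ValueError(f"negative-length interval in {what}")


def _trees(df: pd.DataFrame) -> dict:
    trees: dict = {}
    for row in df.itertuples(index=True):
        if row.end > row.start:  # zero-length intervals carry no overlap
            trees.setdefault(row.chrom, IntervalTree()).addi(
                row.start, row.end, row.Index
            )
    return trees


def classify_uid_context(uids: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Classify each UID as intronic (inside a gene body) or intergenic.

    Any overlap of at least 1 bp with a gene body makes a UID intronic; if
    several genes overlap, the host is the gene with the longest overlap
    (ties broken by gene_id for determinism).  No exon model is consulted:
    the partition is the binary genic/intergenic one.
    """
    _check_intervals(uids, "uids")
    _check_intervals(genes, "genes")
    trees = _trees(genes)
    contexts, hosts = [], []
    for row in uids.itertuples(index=False):
        hits = trees.get(row.chrom, IntervalTree()).overlap(row.start, row.end)
        best = None
        for hit in hits:
            gene = genes.loc[hit.data]
            ov = min(row.end, gene["end"]) - max(row.start, gene["start"])
            key = (-ov, str(gene["gene_id"]))
            if best is None or key < best[0]:
                best = (key, gene["gene_id"])
        if best is None:
            contexts.append("intergenic")
            hosts.append(None)
        else:
            contexts.append("intronic")
            hosts.append(best[1])
    out = uids.copy()
    out["context"] = contexts
    out["host_gene"] = hosts
    return out


def mappability_score(
    uids: pd.DataFrame, unique_mer_regions: pd.DataFrame, min_overlap: int = 45
) -> pd.Series:
    """Number of unique-k-mer regions overlapping each UID by >= ``min_overlap`` bp.

    The score proxies how much of a locus is reachable by uniquely mapping
    short reads; the overlap bound is inclusive.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    _check_intervals(uids, "uids")
    _check_intervals(unique_mer_regions, "unique_mer_regions")
    trees = _trees(unique_mer_regions)
    scores = []
    for row in uids.itertuples(index=False):
        hits = trees.get(row.chrom, IntervalTree()).overlap(row.start, row.end)
        n = 0
        for hit in hits:
            if min(row.end, hit.end) - max(row.start, hit.begin) >= min_overlap:
                n += 1
        scores.append(n)
    return pd.Series(scores, index=uids.index, name="mappability_score")


def summarize_uid_annotation(uid_records: pd.DataFrame) -> pd.DataFrame:
    """Family and genic-context composition of a UID annotation set.

    Returns one row per (kind, category) with counts and percentages to two
    decimals, e.g. 111 L1HS of 146 -> 76.03 %.
    """
    if len(uid_records) == 0:
        raise ValueError("empty UID record set")
    total = len(uid_records)
    rows = []
    for kind, column in (("family", "family"), ("context", "context")):
        if column not in uid_records.columns:
            continue
        for category, count in uid_records[column].value_counts().items():
            rows.append(
                {
                    "kind": kind,
                    "category": category,
                    "count": int(count),
                    "percent": round(100.0 * count / total, 2),
                }
            )
    return pd.DataFrame(rows)


def filter_low_counts(
    counts: pd.DataFrame,
    min_reads: int = 3,
    min_individuals: int = 6,
    strict: bool = True,
) -> tuple[pd.DataFrame, list]:
    """Keep rows expressed above a count threshold in enough samples.

    A row survives when its count exceeds ``min_reads`` (strictly when
    ``strict``, else >=) in at least ``min_individuals`` samples.  The
    default (> 3 reads in >= 6 individuals, the size of the smaller age
    group) is the UID rule; the gene-level variant is ``min_reads=10,
    strict=False``.  Returns the surviving matrix and the dropped row ids.
    """
    if min_individuals > counts.shape[1]:
        raise ValueError("min_individuals exceeds the number of samples")
    hits = (counts > min_reads) if strict else (counts >= min_reads)
    keep = hits.sum(axis=1) >= min_individuals
    dropped = counts.index[~keep].tolist()
    return counts.loc[keep], dropped


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (the DESeq convention).

    The reference is the per-row geometric mean over rows with no zero
    count; each sample's factor is the median across those rows of its
    count over the reference.
    """
    mat = counts.to_numpy(dtype=float)
    zero_free = (mat > 0).all(axis=1)
    if not zero_free.any():
        raise ValueError(
            "no zero-free rows; supply a fuller matrix or use a pseudo-reference"
        )
    logs = np.log(mat[zero_free])
    ref = logs.mean(axis=1, keepdims=True)  # log geometric mean
    factors = np.exp(np.median(logs - ref, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def size_factors_and_normalize(
    counts: pd.DataFrame, full_matrix: pd.DataFrame | None = None
) -> tuple[pd.Series, pd.DataFrame]:
    """Size factors and the normalized count matrix.

    When ``full_matrix`` is given (e.g. genes + repeats), factors are
    estimated on it and applied to ``counts`` (e.g. the UID submatrix) —
    locus counts are too sparse to anchor the factors themselves.
    """
    factors = size_factors(full_matrix if full_matrix is not None else counts)
    factors = factors.loc[counts.columns]
    return factors, counts / factors


def differential_uid_expression(
    normalized: pd.DataFrame, groups: pd.Series, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Per-locus differential expression between the two age groups.

    Each UID is tested with a two-sided Mann-Whitney on its normalized
    counts; effect size is log2 of the ratio of group means (aged/young)
    with a pseudocount; p-values are Benjamini-Hochberg adjusted across
    loci.  Constant rows get p = 1 by convention (logged via warning).
    """
    groups = pd.Series(groups).loc[normalized.columns]
    for g in ("young", "aged"):
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} needs at least 2 samples")
    young = normalized.loc[:, (groups == "young").to_numpy()]
    aged = normalized.loc[:, (groups == "aged").to_numpy()]

    rows = []
    n_constant = 0
    for uid in normalized.index:
        yv = young.loc[uid].to_numpy(dtype=float)
        av = aged.loc[uid].to_numpy(dtype=float)
        if np.ptp(np.concatenate([yv, av])) == 0:
            n_constant += 1
            stat, p = np.nan, 1.0
        else:
            res = l1stats.mann_whitney(yv, av)
            stat, p = res.statistic, res.p
        my, ma = yv.mean(), av.mean()
        rows.append(
            {
                "uid": uid,
                "mean_young": my,
                "mean_aged": ma,
                "log2fc": np.log2((ma + pseudocount) / (my + pseudocount)),
                "statistic": stat,
                "p": p,
            }
        )
    if n_constant:
        warnings.warn(f"{n_constant} constant row(s); p = 1 by convention")
    out = pd.DataFrame(rows).set_index("uid")
    out["padj"] = l1stats.fdr_adjust(out["p"].to_numpy(), method="BH")
    return out


def global_uid_trend(normalized: pd.DataFrame, groups: pd.Series) -> dict:
    """Brain-wide style global trend over all loci.

    (i) Per-UID group means are paired across the locus axis and tested with
    the Wilcoxon matched signed-rank test (is expression globally shifted?).
    (ii) Per-sample sums over all UIDs are compared between groups with a
    two-sided Mann-Whitney (does total LINE-1 output differ?).
    """
    if normalized.shape[0] < 6:
        raise ValueError("paired test needs at least 6 loci")
    groups = pd.Series(groups).loc[normalized.columns]
    young = normalized.loc[:, (groups == "young").to_numpy()]
    aged = normalized.loc[:, (groups == "aged").to_numpy()]
    paired = l1stats.wilcoxon_signed_rank(
        aged.mean(axis=1).to_numpy() - young.mean(axis=1).to_numpy()
    )
    sums = l1stats.mann_whitney(
        young.sum(axis=0).to_numpy(), aged.sum(axis=0).to_numpy()
    )
    return {"paired_means": paired, "per_sample_sums": sums}


def regulator_correlation(
    expression: pd.DataFrame,
    te_rows: list,
    regulator_rows: list,
    min_reads: float = 3.0,
    min_individuals: int = 6,
) -> tuple[pd.DataFrame, pd.DataFrame, list]:
    """Spearman correlation of TE entities with candidate regulators.

    Rows failing the expression threshold (> ``min_reads`` normalized reads
    in > ``min_individuals`` samples) are excluded and listed.  Returns
    (rho, p, excluded); constant vectors yield NaN entries.
    """
    if expression.shape[1] < 4:
        raise ValueError("need at least 4 samples for rank correlation")
    wanted = list(te_rows) + list(regulator_rows)
    missing = [r for r in wanted if r not in expression.index]
    if missing:
        raise KeyError(f"rows absent from expression matrix: {missing}")
    passing = (expression.loc[wanted] > min_reads).sum(axis=1) > min_individuals
    excluded = passing.index[~passing].tolist()
    te_keep = [r for r in te_rows if r not in excluded]
    reg_keep = [r for r in regulator_rows if r not in excluded]

    from scipy.stats import spearmanr

    rho = pd.DataFrame(index=te_keep, columns=reg_keep, dtype=float)
    pmat = pd.DataFrame(index=te_keep, columns=reg_keep, dtype=float)
    for te in te_keep:
        x = expression.loc[te].to_numpy(dtype=float)
        for reg in reg_keep:
            y = expression.loc[reg].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue  # undefined; left as NaN
            r, p = spearmanr(x, y)
            rho.loc[te, reg] = r
            pmat.loc[te, reg] = p
    return rho, pmat, excluded
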