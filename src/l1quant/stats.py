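"""Statistical procedures used across the imaging and genomics arms.

Rank-based two-group tests, the matched signed-rank test, two-sample KS,
Pearson chi-square on count tables, FDR control (Benjamini-Hochberg and the
two-stage Benjamini-Krieger-Yekutieli sharpening), nested group comparisons
for cells-within-animals designs, post-hoc power for two independent samples,
the hypergeometric representation-factor (set overrepresentation) test, and
the co-IP interactor selection rule.

Small-sample inputs take an exact enumeration path (no asymptotic
approximation) wherever the exact null is tractable; ``TestResult.exact``
records which path was used.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "mann_whitney",
    "wilcoxon_signed_rank",
    "ks_two_sample",
    "chi_square_counts",
    "fdr_adjust",
    "nested_group_comparison",
    "posthoc_power_two_sample",
    "representation_factor_test",
    "select_interactors",
]

#: exact-path size limits
_MW_EXACT_MAX_N = 10
_WILCOXON_EXACT_MAX_N = 12


@dataclass
class TestResult:
    """Outcome of a hypothesis test.

    Attributes
    ----------
    method : name of the test performed.
    statistic : the test statistic (U, W, D, chi2, F, ... depending on method).
    p : p-value in [0, 1].
    n : per-group sample sizes.
    exact : True when the null distribution was enumerated exactly.
    extra : method-specific additions (df, effect size, ...).
    """

    method: str
    statistic: float
    p: float
    n: tuple
    exact: bool = False
    extra: dict = field(default_factory=dict)


def _as_1d(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if a.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")
    return a


def mann_whitney(x, y, alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney U test between two independent samples.

    The exact null distribution is enumerated when both samples have at most
    10 observations and no ties are present; otherwise the tie-corrected
    normal approximation (with continuity correction) is used.  Two identical
    samples report p = 1 by convention.
    """
    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    exact = (
        x.size <= _MW_EXACT_MAX_N
        and y.size <= _MW_EXACT_MAX_N
        and np.unique(np.concatenate([x, y])).size == x.size + y.size
    )
    res = sps.mannwhitneyu(
        x, y, alternative=alternative, method="exact" if exact else "asymptotic"
    )
    p = float(res.pvalue)
    # dead-centre U (e.g. identical multisets): report p = 1 rather than the
    # continuity-corrected value just below it
    if alternative == "two-sided" and res.statistic == x.size * y.size / 2.0:
        p = 1.0
    return TestResult(
        method="mann-whitney",
        statistic=float(res.statistic),
        p=min(p, 1.0),
        n=(x.size, y.size),
        exact=exact,
    )


def wilcoxon_signed_rank(diffs, alternative: str = "two-sided") -> TestResult:
    """Wilcoxon matched signed-rank test on paired differences.

    Zero differences are dropped (Pratt's alternative is not offered; the
    drop-zeros convention matches mainstream statistics software).  The exact
    distribution is enumerated for up to 12 nonzero differences without tied
    magnitudes; larger or tied inputs use the tie-corrected normal
    approximation.
    """
    d = _as_1d(diffs, "diffs")
    nonzero = d[d != 0]
    if nonzero.size == 0:
        warnings.warn("all paired differences are zero; p = 1 by convention")
        return TestResult("wilcoxon-signed-rank", 0.0, 1.0, (0,), exact=True)
    exact = (
        nonzero.size <= _WILCOXON_EXACT_MAX_N
        and np.unique(np.abs(nonzero)).size == nonzero.size
    )
    res = sps.wilcoxon(
        nonzero,
        alternative=alternative,
        method="exact" if exact else "approx",
        correction=False,
    )
    p = float(res.pvalue)
    m = nonzero.size
    if alternative == "two-sided" and res.statistic == m * (m + 1) / 4.0:
        p = 1.0  # perfectly symmetric rank sum
    return TestResult(
        method="wilcoxon-signed-rank",
        statistic=float(res.statistic),
        p=min(p, 1.0),
        n=(m,),
        exact=exact,
        extra={"n_zero_dropped": int(d.size - m)},
    )


def ks_two_sample(x, y) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test (D = sup |ECDF_x - ECDF_y|)."""
    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    res = sps.ks_2samp(x, y, method="auto")
    return TestResult(
        method="ks-two-sample",
        statistic=float(res.statistic),
        p=float(res.pvalue),
        n=(x.size, y.size),
        exact=x.size * y.size <= 10000,
    )


def chi_square_counts(table) -> TestResult:
    """Pearson chi-square test of independence on a contingency table.

    No Yates continuity correction is applied (the cell-count comparisons it
    backs are well above the small-expected-count regime; a zero marginal is
    rejected outright).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table entries must be nonnegative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    chi2, p, dof, _ = sps.chi2_contingency(t, correction=False)
    return TestResult(
        method="chi-square",
        statistic=float(chi2),
        p=float(p),
        n=(int(t.sum()),),
        exact=False,
        extra={"df": int(dof)},
    )


def fdr_adjust(pvalues, method: str = "BH") -> np.ndarray:
    """Adjust p-values for multiple testing.

    ``BH`` is the Benjamini-Hochberg step-up with cumulative minimum;
    ``BKY`` is the two-stage sharpened ("adaptive") linear step-up of
    Benjamini, Krieger & Yekutieli.  Output order matches the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"BH": "fdr_bh", "BKY": "fdr_tsbky"}.get(method.upper())
    if key is None:
        raise ValueError(f"unknown FDR method {method!r}; use 'BH' or 'BKY'")
    _, adj, _, _ = multipletests(p.ravel(), alpha=0.05, method=key)
    return adj.reshape(p.shape)


def nested_group_comparison(groups: dict) -> TestResult:
    """Nested comparison of conditions with animals as the experimental unit.

    Parameters
    ----------
    groups : mapping ``condition -> list of per-animal arrays`` of cell-level
        values (cells nested in animals nested in condition).

    For a balanced design (equal animals per condition, equal cells per
    animal) the classical two-level nested ANOVA is computed:
    ``F = MS(condition) / MS(animal within condition)``.  Unbalanced designs
    fall back to a one-way ANOVA on animal means (flagged in ``extra``);
    for balanced data the two are algebraically identical.
    """
    conditions = list(groups)
    if len(conditions) < 2:
        raise ValueError("need at least two conditions")
    animals = {c: [np.asarray(a, dtype=float).ravel() for a in groups[c]] for c in conditions}
    for c in conditions:
        if len(animals[c]) < 2:
            raise ValueError(f"condition {c!r} has fewer than 2 animals")
    n_animals = [len(animals[c]) for c in conditions]
    cell_counts = [a.size for c in conditions for a in animals[c]]
    balanced = len(set(n_animals)) == 1 and len(set(cell_counts)) == 1

    if balanced:
        a = len(conditions)
        b = n_animals[0]
        n = cell_counts[0]
        data = np.stack(
            [np.stack(animals[c]) for c in conditions]
        )  # (a, b, n)
        grand = data.mean()
        cond_means = data.mean(axis=(1, 2))
        animal_means = data.mean(axis=2)
        ss_cond = b * n * np.sum((cond_means - grand) ** 2)
        ss_animal = n * np.sum((animal_means - cond_means[:, None]) ** 2)
        df_cond = a - 1
        df_animal = a * (b - 1)
        ms_cond = ss_cond / df_cond
        ms_animal = ss_animal / df_animal
        if ms_animal == 0:
            f_stat, p = (0.0, 1.0) if ms_cond == 0 else (np.inf, 0.0)
        else:
            f_stat = ms_cond / ms_animal
            p = float(sps.f.sf(f_stat, df_cond, df_animal))
        return TestResult(
            method="nested-anova",
            statistic=float(f_stat),
            p=p,
            n=tuple(n_animals),
            exact=False,
            extra={"df": (df_cond, df_animal), "fallback_animal_means": False},
        )

    # unbalanced: one-way ANOVA on animal means
    means = [[a.mean() for a in animals[c]] for c in conditions]
    f_stat, p = sps.f_oneway(*means)
    return TestResult(
        method="nested-anova",
        statistic=float(f_stat),
        p=float(p),
        n=tuple(n_animals),
        exact=False,
        extra={
            "df": (len(conditions) - 1, sum(n_animals) - len(conditions)),
            "fallback_animal_means": True,
        },
    )


def posthoc_power_two_sample(
    mean1: float,
    mean2: float,
    sd1: float,
    sd2: float,
    n1: int,
    n2: int,
    alpha: float = 0.05,
) -> float:
    """Post-hoc power of the two-sided two-sample t test (continuous endpoint).

    Uses the noncentral-t distribution with a pooled standard deviation; the
    convention of the clinical post-hoc power calculators.  Zero effect
    returns exactly ``alpha`` (the two-sided size of the test).
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    df = n1 + n2 - 2
    sp = math.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df)
    ncp = abs(mean1 - mean2) / (sp * math.sqrt(1.0 / n1 + 1.0 / n2))
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    if ncp == 0:
        return alpha
    power = sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp)
    return float(power)


def representation_factor_test(k: int, n1: int, n2: int, universe: int) -> TestResult:
    """Overrepresentation of the overlap of two sets drawn from a universe.

    Representation factor RF = k * N / (n1 * n2): observed overlap over the
    overlap expected under independence.  The p-value is the upper-tail
    hypergeometric probability P(X >= k).
    """
    if not (0 <= k <= min(n1, n2) <= universe):
        raise ValueError("need 0 <= k <= min(n1, n2) <= universe")
    if n1 > universe or n2 > universe:
        raise ValueError("set sizes exceed the universe")
    if k < n1 + n2 - universe:
        raise ValueError("impossible overlap: k < n1 + n2 - N")
    if n1 == 0 or n2 == 0:
        raise ValueError("empty set has undefined representation factor")
    rf = k * universe / (n1 * n2)
    p = float(sps.hypergeom.sf(k - 1, universe, n1, n2))
    return TestResult(
        method="representation-factor",
        statistic=float(rf),
        p=p,
        n=(k, n1, n2, universe),
        exact=True,
    )


def select_interactors(
    quant: pd.DataFrame,
    n_peptides_min: int = 3,
    fold_min: float = 10.0,
    padj_max: float = 0.05,
) -> pd.DataFrame:
    """Select significantly enriched and unique proteins from a co-IP table.

    Expects one row per protein with columns ``protein``, per-replicate
    target-IP peptide counts ``pep_ip_<r>``, per-replicate control abundances
    ``abund_ctrl_<r>``, ``fold_change`` and ``padj``.

    A protein is *enriched* when it has at least ``n_peptides_min`` peptides
    in every target-IP replicate AND at least ``fold_min`` enrichment AND an
    adjusted p-value at most ``padj_max``.  A protein is *unique* when it has
    at least ``n_peptides_min`` peptides in every target-IP replicate and no
    detection in any control replicate (enrichment statistics are then
    undefined and not required).  Returns the input with ``selected`` and
    ``reason`` columns.
    """
    pep_cols = sorted(c for c in quant.columns if c.startswith("pep_ip_"))
    ctrl_cols = sorted(c for c in quant.columns if c.startswith("abund_ctrl_"))
    if not pep_cols or not ctrl_cols:
        raise ValueError("missing per-replicate pep_ip_*/abund_ctrl_* columns")
    for col in ("fold_change", "padj"):
        if col not in quant.columns:
            raise ValueError(f"missing column {col!r}")

    out = quant.copy()
    pep_ok = (out[pep_cols] >= n_peptides_min).all(axis=1)
    unique = pep_ok & (out[ctrl_cols] == 0).all(axis=1)
    enriched = pep_ok & (out["fold_change"] >= fold_min) & (out["padj"] <= padj_max)
    out["selected"] = enriched | unique
    reason = np.full(len(out), "rejected", dtype=object)
    reason[enriched.to_numpy()] = "enriched"
    reason[unique.to_numpy()] = "unique"  # uniqueness takes precedence in the report
    reason[(enriched & unique).to_numpy()] = "enriched+unique"
    out["reason"] = reason
    return out
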