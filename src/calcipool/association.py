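"""Group comparisons: per-variant 2x2 tests, Bonferroni policy, gene burden.

Each variant contributes a 2x2 haplotype table

    [[a, b], [c, d]] = [[minor_low, major_low], [minor_high, major_high]],

tested with an uncorrected Pearson chi-square (1 df) or, when any expected
cell is small or a policy override demands it, a two-sided Fisher exact test
(minimum-likelihood convention: sum over tables whose point probability does
not exceed the observed one). Multiple testing follows the Bonferroni
policy — a threshold alpha/n on unadjusted p-values, not p-value inflation.

The gene-level burden test aggregates the minor-haplotype counts of rare
variants (pooled frequency below a threshold, default 2%) per gene and per
group and applies the Fisher exact test to the aggregate table — the design
that asks whether carriers of *any* rare variant in the gene are enriched in
one phenotype tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_EXPECTED = 5.0
DEFAULT_RARE_THRESHOLD = 0.02


def _as_table(table) -> np.ndarray:
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr < 0).any():
        raise ValueError("table entries must be non-negative")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("table entries must be integers")
        arr = arr.astype(np.int64)
    return arr


def chi_square_2x2(table) -> float:
    """Uncorrected Pearson chi-square p-value (1 df) for a 2x2 table.

    Raises on a zero margin (the statistic is undefined there); use
    :func:`fisher_exact_2x2` for sparse tables.
    """
    arr = _as_table(table)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero margin: chi-square undefined, use fisher_exact_2x2")
    return float(stats.chi2_contingency(arr, correction=False)[1])


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value (minimum-likelihood method)."""
    arr = _as_table(table)
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def expected_cells(table) -> np.ndarray:
    arr = _as_table(table)
    n = arr.sum()
    if n == 0:
        return np.zeros((2, 2))
    return np.outer(arr.sum(axis=1), arr.sum(axis=0)) / n


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    return alpha / n_tests


@dataclass(frozen=True)
class TestPolicy:
    """How per-variant tests are chosen and judged.

    ``force_fisher`` lists variant keys always routed to the exact test
    regardless of expected cell counts (used to mirror published analyses
    that applied the exact test to designated variants).
    """

    alpha: float = DEFAULT_ALPHA
    min_expected: float = DEFAULT_MIN_EXPECTED
    force_fisher: frozenset = field(default_factory=frozenset)


@dataclass
class AssociationResult:
    key: str
    table: tuple[tuple[int, int], tuple[int, int]]
    test: str  # chi_square | fisher_exact | monomorphic
    p_value: float
    monomorphic: bool = False
    n_tests: int | None = None
    bonferroni_alpha: float | None = None
    significant: bool | None = None

    def judge(self, n_tests: int, alpha: float = DEFAULT_ALPHA) -> "AssociationResult":
        self.n_tests = n_tests
        self.bonferroni_alpha = bonferroni_threshold(alpha, n_tests)
        self.significant = self.p_value < self.bonferroni_alpha
        return self


def test_variant(
    key: str,
    a_low: int,
    n_low: int,
    a_high: int,
    n_high: int,
    policy: TestPolicy = TestPolicy(),
) -> AssociationResult:
    """2x2 haplotype-count test for one variant.

    The table is [[a_low, n_low - a_low], [a_high, n_high - a_high]]. The
    exact test is used when the policy forces it or any expected cell falls
    below ``policy.min_expected``; otherwise Pearson chi-square.
    """
    if n_low <= 0 or n_high <= 0:
        raise ValueError("group haplotype denominators must be positive")
    table = ((int(a_low), int(n_low - a_low)), (int(a_high), int(n_high - a_high)))
    if a_low + a_high == 0:
        return AssociationResult(key, table, "monomorphic", 1.0, monomorphic=True)
    arr = np.asarray(table)
    use_fisher = key in policy.force_fisher or (
        expected_cells(arr).min() < policy.min_expected
    )
    if not use_fisher and ((arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any()):
        use_fisher = True  # degenerate margin: chi-square undefined
    if use_fisher:
        return AssociationResult(key, table, "fisher_exact", fisher_exact_2x2(arr))
    return AssociationResult(key, table, "chi_square", chi_square_2x2(arr))


def associate_all(
    calls: pd.DataFrame,
    policy: TestPolicy = TestPolicy(),
    n_tests: int | None = None,
) -> pd.DataFrame:
    """Per-variant tests over a call table with group counts.

    Requires columns site_id, a_low, n_low, a_high, n_high. ``n_tests``
    defaults to the number of variants tested; the Bonferroni flag compares
    each unadjusted p against alpha / n_tests.
    """
    results = [
        test_variant(
            row.site_id, row.a_low, row.n_low, row.a_high, row.n_high, policy
        )
        for row in calls.itertuples(index=False)
    ]
    n = n_tests if n_tests is not None else len(results)
    out = []
    for res in results:
        res.judge(n, policy.alpha)
        (a, b), (c, d) = res.table
        out.append(
            {
                "site_id": res.key,
                "a_low": a, "n_low": a + b, "a_high": c, "n_high": c + d,
                "freq_low": a / (a + b),
                "freq_high": c / (c + d),
                "test": res.test,
                "p_value": res.p_value,
                "n_tests": res.n_tests,
                "bonferroni_alpha": res.bonferroni_alpha,
                "significant": res.significant,
            }
        )
    return pd.DataFrame(out)


@dataclass
class GeneBurdenResult:
    gene: str
    n_variants: int
    rare_low: int
    n_low: int
    rare_high: int
    n_high: int
    p_value: float


def gene_burden(
    calls: pd.DataFrame,
    rare_threshold: float = DEFAULT_RARE_THRESHOLD,
    unit: str = "alleles",
) -> pd.DataFrame:
    """Rare-variant burden per gene: aggregate counts and Fisher exact test.

    ``calls`` must carry gene, a_low, n_low, a_high, n_high and the pooled
    frequency ``af`` (computed here if absent). Variants with overall
    frequency below ``rare_threshold`` contribute; each variant's minor
    alleles count once. ``unit="carriers"`` counts carrying pools instead of
    alleles (requires an ``occurrence_pools``-style breakdown per group and
    is an approximation in pooled data). Genes with no rare variants are
    omitted with a log note.
    """
    df = calls.copy()
    if "af" not in df.columns:
        df["af"] = (df["a_low"] + df["a_high"]) / (df["n_low"] + df["n_high"])
    if unit not in ("alleles", "carriers"):
        raise ValueError("unit must be 'alleles' or 'carriers'")
    rare = df.loc[df["af"] < rare_threshold]
    results = []
    for gene, sub in rare.groupby("gene", sort=True):
        if unit == "alleles":
            a = int(sub["a_low"].sum())
            c = int(sub["a_high"].sum())
        else:
            a = int((sub["a_low"] > 0).sum())
            c = int((sub["a_high"] > 0).sum())
        # denominators: the widest per-site denominator seen for the gene
        # (sites share the same pools; per-site no-calls only shrink it)
        n_low = int(sub["n_low"].max())
        n_high = int(sub["n_high"].max())
        p = fisher_exact_2x2([[a, n_low - a], [c, n_high - c]])
        results.append(
            GeneBurdenResult(gene, len(sub), a, n_low, c, n_high, p)
        )
    dropped = set(df["gene"].unique()) - {r.gene for r in results}
    if dropped:
        logger.info("genes with no rare variants omitted: %s", sorted(dropped))
    return pd.DataFrame(
        [
            {
                "gene": r.gene, "n_variants": r.n_variants,
                "rare_low": r.rare_low, "n_low": r.n_low,
                "rare_high": r.rare_high, "n_high": r.n_high,
                "p_value": r.p_value,
            }
            for r in results
        ]
    )


@dataclass
class GroupSummary:
    table: pd.DataFrame
    stone_table: tuple[tuple[int, int], tuple[int, int]]
    stone_p: float


def group_summary(
    individuals: pd.DataFrame, low: pd.Index, high: pd.Index
) -> GroupSummary:
    """Phenotype summary by group x stone-former status plus the 2x2 test.

    Means +/- SD of urinary calcium (and age/BMI when present) per cell, and
    an uncorrected chi-square on the stone-former-by-group table.
    """
    traits = [c for c in ("urinary_ca", "age", "bmi") if c in individuals.columns]
    rows = []
    for group, idx in (("low", low), ("high", high)):
        sub = individuals.loc[idx]
        for stone, cell in sub.groupby("stone_former"):
            label = "stone_former" if stone else "non_stone_former"
            if len(cell) < 2:
                logger.warning("%s/%s has <2 members; SD undefined", group, label)
            row = {"group": group, "status": label, "n": len(cell)}
            for t in traits:
                row[f"{t}_mean"] = cell[t].mean()
                row[f"{t}_sd"] = cell[t].std(ddof=1) if len(cell) > 1 else np.nan
            rows.append(row)
    low_sub = individuals.loc[low, "stone_former"]
    high_sub = individuals.loc[high, "stone_former"]
    table = (
        (int(low_sub.sum()), int((~low_sub).sum())),
        (int(high_sub.sum()), int((~high_sub).sum())),
    )
    arr = np.asarray(table)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        p = 1.0 if (arr[0] == arr[1]).all() else fisher_exact_2x2(arr)
    elif (arr[0] == arr[1]).all():
        p = 1.0
    else:
        p = chi_square_2x2(arr)
    return GroupSummary(pd.DataFrame(rows), table, p)
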