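"""Pooled variant calling: per-pool minor-haplotype count MLE and site calls.

A pool of N diploid individuals contributes 2N haplotypes. If k of them carry
the minor allele and reads miscall with symmetric per-base rate eps, the
expected alt-read fraction is

    p(k) = (k/2N) (1 - eps) + (1 - k/2N) eps/3,

and the alt-read count is Binomial(depth, p(k)). The per-pool estimate
``k_hat`` is the exact maximizer of this likelihood over the discrete grid
k = 0..2N (ties broken toward smaller k); no approximation is involved.
A site is *called* when at least one pool's log-likelihood ratio of its best
k against k = 0 exceeds a threshold. Pools below a minimum depth are no-call
at that site and drop out of both the numerator and the haplotype
denominator, so per-site denominators reflect the pools that actually
contributed data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import Cohort, PoolManifest, TruthTable

NO_CALL = -1

DEFAULT_MIN_DEPTH = 20
DEFAULT_LR_THRESHOLD = 10.0
DEFAULT_ERROR_RATE = 0.005


def pool_count_loglik(
    alt_reads: int, depth: int, haploid_size: int, error_rate: float
) -> np.ndarray:
    """Log-likelihood of every haplotype count k = 0..2N given the pileup."""
    if not 0 <= alt_reads <= depth:
        raise ValueError("alt_reads must satisfy 0 <= alt_reads <= depth")
    if not 0.0 < error_rate < 0.1:
        raise ValueError("error_rate must be in (0, 0.1)")
    k = np.arange(haploid_size + 1)
    f = k / haploid_size
    p = f * (1.0 - error_rate) + (1.0 - f) * error_rate / 3.0
    return stats.binom.logpmf(alt_reads, depth, p)


def estimate_pool_count(
    alt_reads: int, depth: int, haploid_size: int, error_rate: float
) -> tuple[int, np.ndarray | None]:
    """MLE of the pool's minor-haplotype count.

    Returns ``(k_hat, logliks)``. Zero depth carries no information: the
    no-call sentinel (-1, None) is returned and the caller excludes the pool
    from group sums.
    """
    if depth == 0:
        return NO_CALL, None
    ll = pool_count_loglik(alt_reads, depth, haploid_size, error_rate)
    # np.argmax returns the first maximizer -> ties break toward smaller k
    return int(np.argmax(ll)), ll


@dataclass
class CallSet:
    """Called sites plus the per-pool estimates behind them.

    ``calls``: one row per called site with group minor counts (a_low,
    a_high), contributing-pool denominators (n_low, n_high), the fixed
    manifest denominators (n_low_total, n_high_total), the pooled frequency,
    the best log-likelihood ratio, and the two occurrence metrics the
    recurrence filter can use (total estimated alleles / carrying pools).

    ``pool_estimates``: long table (site_id, pool_id, k_hat, llr, no_call)
    over every site x pool with adequate depth.
    """

    calls: pd.DataFrame
    pool_estimates: pd.DataFrame


def call_sites(
    counts: pd.DataFrame,
    manifest: PoolManifest,
    min_depth: int = DEFAULT_MIN_DEPTH,
    lr_threshold: float = DEFAULT_LR_THRESHOLD,
    error_rate: float = DEFAULT_ERROR_RATE,
) -> CallSet:
    """Estimate pool counts for every site and keep the supported ones.

    ``counts`` is the long pileup table (site_id, gene, chrom, pos, ref,
    alt, pool_id, depth, alt_reads). All pools referenced must exist in the
    manifest. Pools with depth < ``min_depth`` are no-call for that site.
    """
    pool_ids = {p.pool_id for p in manifest.pools}
    unknown = set(counts["pool_id"]) - pool_ids
    if unknown:
        raise ValueError(f"counts reference pools not in manifest: {sorted(unknown)[:3]}")

    df = counts.copy()
    group = {p.pool_id: p.group for p in manifest.pools}
    hap = {p.pool_id: p.haploid_size for p in manifest.pools}
    df["group"] = df["pool_id"].map(group)
    df["haploid_size"] = df["pool_id"].map(hap)
    df["no_call"] = df["depth"] < min_depth

    ok = df.loc[~df["no_call"]]
    if ok.empty:
        warnings.warn("no pools pass min_depth at any site; empty call set")
        empty = df.iloc[0:0]
        return CallSet(calls=empty, pool_estimates=empty)

    # vectorized likelihood over the k grid, masking k beyond each pool's 2N
    alt = ok["alt_reads"].to_numpy()
    depth = ok["depth"].to_numpy()
    two_n = ok["haploid_size"].to_numpy()
    kmax = int(two_n.max())
    kgrid = np.arange(kmax + 1)[None, :]
    valid = kgrid <= two_n[:, None]
    f = np.where(valid, kgrid / two_n[:, None], 0.0)
    p = f * (1.0 - error_rate) + (1.0 - f) * error_rate / 3.0
    ll = stats.binom.logpmf(alt[:, None], depth[:, None], p)
    ll = np.where(valid, ll, -np.inf)
    k_hat = ll.argmax(axis=1)  # first max -> smaller k on ties
    llr = ll[np.arange(len(ll)), k_hat] - ll[:, 0]

    est = ok[["site_id", "pool_id", "group", "haploid_size"]].copy()
    est["k_hat"] = k_hat
    est["llr"] = llr
    est["no_call"] = False

    per_site = est.groupby("site_id", sort=False)
    max_llr = per_site["llr"].max()
    called_ids = max_llr.index[max_llr > lr_threshold]
    if len(called_ids) == 0:
        warnings.warn("no site exceeded the calling threshold; empty call set")

    low = est["group"] == "low"
    agg = est.assign(
        a_low=np.where(low, est["k_hat"], 0),
        a_high=np.where(~low, est["k_hat"], 0),
        n_low=np.where(low, est["haploid_size"], 0),
        n_high=np.where(~low, est["haploid_size"], 0),
        pools_carrying=(est["k_hat"] > 0).astype(int),
    )
    sums = agg.groupby("site_id", sort=False)[
        ["a_low", "a_high", "n_low", "n_high", "pools_carrying"]
    ].sum()

    meta = df[["site_id", "gene", "chrom", "pos", "ref", "alt"]].drop_duplicates("site_id")
    calls = meta.set_index("site_id").join(sums, how="inner")
    calls["max_llr"] = max_llr
    calls = calls.loc[calls.index.isin(called_ids)].reset_index()
    denom = calls["n_low"] + calls["n_high"]
    calls["af"] = (calls["a_low"] + calls["a_high"]) / denom.where(denom > 0, np.nan)
    calls["occurrence_alleles"] = calls["a_low"] + calls["a_high"]
    calls = calls.rename(columns={"pools_carrying": "occurrence_pools"})
    calls["n_low_total"] = manifest.haploid_total("low")
    calls["n_high_total"] = manifest.haploid_total("high")
    order = [
        "site_id", "gene", "chrom", "pos", "ref", "alt",
        "a_low", "n_low", "a_high", "n_high", "af", "max_llr",
        "occurrence_alleles", "occurrence_pools", "n_low_total", "n_high_total",
    ]
    return CallSet(calls=calls[order], pool_estimates=est.reset_index(drop=True))


def concordance(
    callset: CallSet, truth: TruthTable, manifest: PoolManifest, cohort: Cohort
) -> tuple[float, float]:
    """Completeness and accuracy of a call set against ground truth.

    The truth table plays the role of an external gold-standard variant
    panel assumed error-free (so artifact sites are not in the panel).
    Completeness: fraction of panel sites segregating among the pooled
    individuals (at least one minor haplotype) that were called. Accuracy:
    fraction of per-pool count estimates within +/-1 of truth, over called
    sites present in the panel and pools with adequate depth.
    """
    truth_k = truth.pool_counts(manifest, cohort)
    totals = truth_k.groupby("site_id")["k"].sum()
    fp_ids = set(truth.sites.loc[truth.sites["is_fp"], "site_id"])
    true_sites = {s for s, t in totals.items() if t > 0 and s not in fp_ids}
    called = set(callset.calls["site_id"])
    if not called & set(totals.index):
        warnings.warn("call set and truth share no sites")
        return 0.0, 0.0
    completeness = len(called & true_sites) / len(true_sites) if true_sites else 0.0

    panel_called = (called - fp_ids) & set(totals.index)
    est = callset.pool_estimates.loc[
        callset.pool_estimates["site_id"].isin(panel_called)
    ]
    merged = est.merge(truth_k, on=["site_id", "pool_id"], how="left")
    if merged.empty:
        return float(completeness), 0.0
    accuracy = float(((merged["k_hat"] - merged["k"]).abs() <= 1).mean())
    return float(completeness), accuracy


# ---------------------------------------------------------------------------
# VCF output
# ---------------------------------------------------------------------------

def write_vcf(callset: CallSet, manifest: PoolManifest, path: str | Path) -> None:
    """Write calls as VCF 4.2 with per-pool estimated haplotype counts.

    INFO carries group allele counts/denominators and the pooled frequency;
    each pool appears as a sample column with a single ``KH`` field (the
    estimated minor-haplotype count, ``.`` when the pool was no-call).
    """
    calls = callset.calls.sort_values(["chrom", "pos"], kind="mergesort")
    pools = [p.pool_id for p in manifest.pools]
    khat = callset.pool_estimates.pivot_table(
        index="site_id", columns="pool_id", values="k_hat", aggfunc="first"
    )
    lines = [
        "##fileformat=VCFv4.2",
        "##source=calcipool",
        '##INFO=<ID=AC_LOW,Number=1,Type=Integer,Description="Minor-haplotype count, low group">',
        '##INFO=<ID=AN_LOW,Number=1,Type=Integer,Description="Haplotype denominator, low group">',
        '##INFO=<ID=AC_HIGH,Number=1,Type=Integer,Description="Minor-haplotype count, high group">',
        '##INFO=<ID=AN_HIGH,Number=1,Type=Integer,Description="Haplotype denominator, high group">',
        '##INFO=<ID=AF,Number=1,Type=Float,Description="Pooled minor-allele frequency">',
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Candidate gene">',
        '##FORMAT=<ID=KH,Number=1,Type=Integer,Description="Estimated minor-haplotype count in pool">',
    ]
    for chrom in pd.unique(calls["chrom"]):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(pools)
    )
    for row in calls.itertuples(index=False):
        info = (
            f"AC_LOW={row.a_low};AN_LOW={row.n_low};AC_HIGH={row.a_high};"
            f"AN_HIGH={row.n_high};AF={row.af:.6g};GENE={row.gene}"
        )
        sample_fields = []
        for pool_id in pools:
            val = None
            if row.site_id in khat.index and pool_id in khat.columns:
                val = khat.loc[row.site_id, pool_id]
            sample_fields.append("." if val is None or pd.isna(val) else str(int(val)))
        lines.append(
            f"{row.chrom}\t{row.pos}\t{row.site_id}\t{row.ref}\t{row.alt}\t.\tPASS\t"
            f"{info}\tKH\t" + "\t".join(sample_fields)
        )
    Path(path).write_text("\n".join(lines) + "\n")
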