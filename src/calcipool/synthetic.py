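"""Synthetic pooled-resequencing study generator with known ground truth.

Emulates an extreme-phenotype pooled resequencing design for a quantitative
urine phenotype (24-hour urinary calcium excretion, mg/day):

1. a diploid cohort with per-site minor-allele dosages, a Gaussian phenotype
   with optional additive genetic effects, and a logistic stone-former link;
2. selection of the bottom/top phenotype tails;
3. assignment of each tail into sequencing pools of 15 or 20 individuals
   (30 or 40 haplotypes), ranked-adjacent, with optional whole-pool attrition
   emulating capture/coverage failure;
4. per-pool, per-site pileup counts: depth ~ Poisson, alt reads ~ Binomial
   with a symmetric per-base miscall rate.

Sites come in three kinds mirroring what a real call set contains:

* ``known``  — common SNPs present in one or more mock databases;
* ``novel``  — rare true variants absent from the databases, alt alleles
  drawn with a transition bias (Ti/Tv ~ 3);
* ``fp``     — artifact sites with zero true carriers whose alt allele is
  uniform over the three non-reference bases (expected Ti/Tv 0.5) and whose
  reads arise from a site-specific, systematically elevated miscall rate
  shared across pools, so that artifacts both enter the call set and recur —
  the behaviour the downstream recurrence filter exists to exploit.

The simulation is at pileup-count level: no reads, no alignment. Everything
downstream consumes per-site counts, so nothing is lost at this resolution.
All randomness flows from ``SimConfig.seed`` (or an explicit Generator).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotate import BASES, GeneModel, GenePanel, classify_substitution, complement

ALLOWED_POOL_SIZES = (15, 20)

#: candidate-gene names for the synthetic panel: calcium-handling genes a
#: nephrolithiasis panel would target (tight-junction claudins, the
#: calcium-sensing receptor, TRPV channels, solute carriers, ...).
PANEL_GENE_NAMES = (
    "ACO1", "CASR", "ACLY", "CLDN2", "CLDN8", "CLDN10", "CLDN14", "CLDN16",
    "CLDN19", "CLCN5", "CLCNKA", "CLCNKB", "FGF23", "GCM2", "KL", "NHERF1",
    "NHERF2", "SLC12A1", "PDZK1", "PIK3C2G", "PTH", "PTH1R", "KCNJ1",
    "SLC12A3", "SLC13A2", "SLC13A3", "SLC25A1", "SLC26A1", "SLC26A2",
    "SLC26A6", "SLC34A1", "SLC34A3", "SLC4A1", "SLC4A2", "SLC4A3", "TRPV5",
    "TRPV6", "UMOD", "VDR", "WNK4",
)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic generator.

    Defaults describe a cohort of 4,800 with 10% tails (480 individuals per
    phenotype group), 26 pools per group (8x15 + 18x20), ~35% whole-pool
    attrition, 500x mean pool depth, a 0.5% per-base miscall rate, and a site
    panel of 429 known SNPs, 259 rare novel variants and 884 artifact sites
    across 40 genes.
    """

    n_individuals: int = 4800
    sex_ratio: float = 0.5  # fraction female
    baseline_ca_mean: float = 200.0  # mg/day
    baseline_ca_sd: float = 60.0  # mg/day
    #: (site_id, per-minor-allele shift in mg/day)
    causal_effects: tuple[tuple[str, float], ...] = (("known_0000", -25.0),)
    causal_af: float | None = 0.025  # population MAF forced at causal sites
    stone_former_link: float = 0.0023  # log-odds per mg/day urinary Ca
    stone_former_rate: float = 0.55  # stone-former probability at the Ca mean
    extreme_fraction: float = 0.10  # per tail
    pool_sizes: tuple[int, ...] = (15,) * 8 + (20,) * 18  # per group
    mean_depth: float = 500.0  # reads/site/pool
    error_rate: float = 0.005  # per-base miscall probability
    n_true_sites: int = 259
    n_fp_sites: int = 884
    n_known_sites: int = 429
    titv_tp: float = 3.0  # transition/transversion ratio of true variants
    af_known: tuple[float, float] = (0.02, 0.5)  # uniform MAF range
    af_novel: tuple[float, float] = (3e-5, 1.5e-3)  # log-uniform MAF range
    #: site-specific artifact miscall rate range (uniform); see module docs
    fp_error_range: tuple[float, float] = (0.005, 0.04)
    #: marginal membership probability of a known site in each mock database
    db_membership: tuple[float, float, float] = (0.9, 0.6, 0.5)
    pool_attrition: float = 18.0 / 52.0  # fraction of pools dropped
    n_genes: int = 40
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if not 0.0 < self.extreme_fraction < 0.5:
            raise ValueError("extreme_fraction must be in (0, 0.5)")
        bad = set(self.pool_sizes) - set(ALLOWED_POOL_SIZES)
        if bad:
            raise ValueError(f"pool sizes must be in {ALLOWED_POOL_SIZES}, got {sorted(bad)}")
        if not 0.0 <= self.error_rate < 0.1:
            raise ValueError("error_rate must be in [0, 0.1)")
        if self.error_rate == 0.0 and self.n_fp_sites > 0:
            raise ValueError(
                "error_rate = 0 with n_fp_sites > 0: no mechanism produces artifacts"
            )
        if self.titv_tp <= 0.5:
            raise ValueError("titv_tp must exceed the pure-error ratio 0.5")
        if min(self.n_true_sites, self.n_fp_sites, self.n_known_sites) < 0:
            raise ValueError("site counts must be non-negative")
        if not 0.0 <= self.pool_attrition < 1.0:
            raise ValueError("pool_attrition must be in [0, 1)")

    @property
    def n_sites(self) -> int:
        return self.n_known_sites + self.n_true_sites + self.n_fp_sites

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """Simulated individuals plus their genotype matrix.

    ``individuals`` carries one row per person (id, sex, cohort, urinary_ca,
    age, bmi, stone_former); ``genotypes`` is an (n_individuals, n_sites)
    int8 matrix of minor-allele dosages in {0, 1, 2}, columns ordered as
    ``site_ids``.
    """

    individuals: pd.DataFrame
    genotypes: np.ndarray
    site_ids: pd.Index

    def dosages(self, site_id: str) -> np.ndarray:
        return self.genotypes[:, self.site_ids.get_loc(site_id)]


@dataclass
class TruthTable:
    """Ground truth for every simulated site.

    ``sites`` columns: site_id, gene, chrom, pos, ref, alt, af, kind
    (known/novel/fp), is_fp, dbsnp/g1000/esp flags, is_causal, fp_error_rate.
    Per-pool true minor-haplotype counts are derived on demand from a pool
    manifest via :meth:`pool_counts`.
    """

    sites: pd.DataFrame

    def pool_counts(self, manifest: "PoolManifest", cohort: Cohort) -> pd.DataFrame:
        """Long table (site_id, pool_id, k) of true per-pool haplotype counts."""
        rows = []
        site_ids = self.sites["site_id"].to_numpy()
        for pool in manifest.pools:
            idx = cohort.individuals.index.get_indexer(pool.members)
            k = cohort.genotypes[idx, :].sum(axis=0)
            rows.append(pd.DataFrame({"site_id": site_ids, "pool_id": pool.pool_id, "k": k}))
        out = pd.concat(rows, ignore_index=True)
        is_fp = self.sites.set_index("site_id")["is_fp"]
        out.loc[out["site_id"].map(is_fp).to_numpy(), "k"] = 0
        return out

    def write(self, path: str | Path) -> None:
        self.sites.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "TruthTable":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass(frozen=True)
class Pool:
    pool_id: str
    group: str  # "low" | "high"
    members: tuple[str, ...]

    def __post_init__(self):
        if len(self.members) not in ALLOWED_POOL_SIZES:
            raise ValueError(f"pool {self.pool_id}: size {len(self.members)} not in {ALLOWED_POOL_SIZES}")
        if self.group not in ("low", "high"):
            raise ValueError(f"pool {self.pool_id}: group must be low/high")

    @property
    def haploid_size(self) -> int:
        return 2 * len(self.members)


@dataclass
class PoolManifest:
    pools: list[Pool] = field(default_factory=list)

    def __post_init__(self):
        seen: set[str] = set()
        for p in self.pools:
            overlap = seen.intersection(p.members)
            if overlap:
                raise ValueError(f"pools are not disjoint: {sorted(overlap)[:3]} ...")
            seen.update(p.members)

    def by_group(self, group: str) -> list[Pool]:
        return [p for p in self.pools if p.group == group]

    def haploid_total(self, group: str) -> int:
        return sum(p.haploid_size for p in self.by_group(group))

    def pool(self, pool_id: str) -> Pool:
        for p in self.pools:
            if p.pool_id == pool_id:
                return p
        raise KeyError(pool_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pool_id": [p.pool_id for p in self.pools],
                "group": [p.group for p in self.pools],
                "member_ids": [",".join(p.members) for p in self.pools],
                "haploid_size": [p.haploid_size for p in self.pools],
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "PoolManifest":
        df = pd.read_csv(path, sep="\t", dtype=str)
        pools = [
            Pool(row.pool_id, row.group, tuple(row.member_ids.split(",")))
            for row in df.itertuples(index=False)
        ]
        return cls(pools)


# ---------------------------------------------------------------------------
# Gene panel and site synthesis
# ---------------------------------------------------------------------------

def synthesize_panel(n_genes: int, rng: np.random.Generator) -> GenePanel:
    """Random single-exon CDS models for the candidate-gene panel.

    Each gene gets an ATG-initiated CDS of 120-280 codons ending in a stop,
    placed on its own chromosome slot; roughly a quarter are minus-strand so
    strand handling is exercised end to end.
    """
    panel = GenePanel()
    names = list(PANEL_GENE_NAMES)
    while len(names) < n_genes:
        names.append(f"GENE{len(names):02d}")
    base_arr = np.array(list("ACGT"))
    stops = {"TAA", "TAG", "TGA"}
    for i in range(n_genes):
        n_codons = int(rng.integers(120, 281))
        body = []
        for _ in range(n_codons - 2):
            codon = "".join(rng.choice(base_arr, size=3))
            while codon in stops:
                codon = "".join(rng.choice(base_arr, size=3))
            body.append(codon)
        stop = ("TAA", "TAG", "TGA")[int(rng.integers(3))]
        cds = "ATG" + "".join(body) + stop
        chrom = f"chr{(i % 22) + 1}"
        start = 10_000 + (i // 22) * 2_000_000 + int(rng.integers(0, 500_000))
        strand = "-" if rng.random() < 0.25 else "+"
        panel.add(GeneModel(names[i], chrom, strand, cds, ((start, start + len(cds)),)))
    return panel


def _draw_alt(ref: str, kind: str, titv_tp: float, rng: np.random.Generator) -> str:
    """Alt allele for a site: transition-biased for real variants, uniform
    over the three non-reference bases for artifacts."""
    transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}
    if kind == "fp":
        choices = [b for b in BASES if b != ref]
        return choices[int(rng.integers(3))]
    if rng.random() < titv_tp / (1.0 + titv_tp):
        return transitions[ref]
    tvs = [b for b in BASES if b != ref and b != transitions[ref]]
    return tvs[int(rng.integers(2))]


def synthesize_sites(
    config: SimConfig, panel: GenePanel, rng: np.random.Generator
) -> pd.DataFrame:
    """Place known/novel/artifact sites on the panel and draw their truth.

    Sites are dealt round-robin across genes at distinct CDS positions.
    Known sites get common minor-allele frequencies and database flags drawn
    at the configured marginal rates (with dbSNP membership forced when all
    three draws miss, so that "known" stays consistent); novel sites get
    rare log-uniform frequencies; artifact sites get frequency zero and a
    site-specific elevated miscall rate.
    """
    kinds = (
        ["known"] * config.n_known_sites
        + ["novel"] * config.n_true_sites
        + ["fp"] * config.n_fp_sites
    )
    genes = list(panel)
    used: dict[str, set[int]] = {g.name: set() for g in genes}
    counters = {"known": 0, "novel": 0, "fp": 0}
    rows = []
    for i, kind in enumerate(kinds):
        gene = genes[i % len(genes)]
        cds_len = len(gene.cds)
        cds_pos = int(rng.integers(1, cds_len + 1))
        while cds_pos in used[gene.name]:
            cds_pos = int(rng.integers(1, cds_len + 1))
        used[gene.name].add(cds_pos)
        start, end = gene.exons[0]
        if gene.strand == "+":
            pos = start + cds_pos  # 1-based genomic
        else:
            pos = end - cds_pos + 1
        ref = gene.genomic_ref_base(pos)
        alt = _draw_alt(ref, kind, config.titv_tp, rng)
        if kind == "known":
            af = float(rng.uniform(*config.af_known))
        elif kind == "novel":
            lo, hi = config.af_novel
            af = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            af = 0.0
        fp_rate = float(rng.uniform(*config.fp_error_range)) if kind == "fp" else 0.0
        if kind == "known":
            flags = tuple(rng.random() < p for p in config.db_membership)
            if not any(flags):
                flags = (True, flags[1], flags[2])
        else:
            flags = (False, False, False)
        site_id = f"{kind}_{counters[kind]:04d}"
        counters[kind] += 1
        rows.append(
            {
                "site_id": site_id,
                "gene": gene.name,
                "chrom": gene.chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "kind": kind,
                "af": af,
                "is_fp": kind == "fp",
                "dbsnp": flags[0],
                "g1000": flags[1],
                "esp": flags[2],
                "is_causal": False,
                "fp_error_rate": fp_rate,
            }
        )
    sites = pd.DataFrame(rows)
    for site_id, _ in config.causal_effects:
        if site_id not in set(sites["site_id"]):
            raise ValueError(f"causal site {site_id!r} not in the site list")
        sites.loc[sites["site_id"] == site_id, "is_causal"] = True
        if config.causal_af is not None:
            sites.loc[sites["site_id"] == site_id, "af"] = config.causal_af
    return sites


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[Cohort, TruthTable, GenePanel]:
    """Simulate individuals, genotypes and phenotypes with full ground truth.

    Genotypes are Hardy-Weinberg draws Binomial(2, AF) per site; urinary
    calcium is baseline Gaussian plus additive causal-allele effects
    (resampled at the rare non-positive draws to keep mg/day positive);
    stone-former status follows a logistic link on urinary calcium.
    Deterministic under a fixed ``config.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    panel = synthesize_panel(config.n_genes, rng)
    sites = synthesize_sites(config, panel, rng)
    n = config.n_individuals
    afs = sites["af"].to_numpy()
    genotypes = rng.binomial(2, afs[None, :], size=(n, len(afs))).astype(np.int8)

    ca = rng.normal(config.baseline_ca_mean, config.baseline_ca_sd, size=n)
    for _ in range(20):  # resample the (rare) non-positive draws
        bad = ca <= 0
        if not bad.any():
            break
        ca[bad] = rng.normal(config.baseline_ca_mean, config.baseline_ca_sd, size=int(bad.sum()))
    ca = np.maximum(ca, 1.0)
    site_index = pd.Index(sites["site_id"])
    for site_id, effect in config.causal_effects:
        ca = ca + effect * genotypes[:, site_index.get_loc(site_id)]
    ca = np.maximum(ca, 1.0)

    logit_p = _logit(config.stone_former_rate) + config.stone_former_link * (
        ca - config.baseline_ca_mean
    )
    stone = rng.random(n) < 1.0 / (1.0 + np.exp(-logit_p))
    female = rng.random(n) < config.sex_ratio
    # three source cohorts: two all-female, one all-male
    cohort_label = np.where(
        female, np.where(rng.random(n) < 0.5, "cohortF1", "cohortF2"), "cohortM1"
    )
    age = np.clip(rng.normal(61, 9, size=n), 30, 90).round(1)
    bmi = np.clip(rng.normal(27, 5, size=n), 16, 55).round(1)

    ids = pd.Index([f"ind{i:05d}" for i in range(n)], name="id")
    individuals = pd.DataFrame(
        {
            "sex": np.where(female, "F", "M"),
            "cohort": cohort_label,
            "urinary_ca": ca.round(1),
            "age": age,
            "bmi": bmi,
            "stone_former": stone,
        },
        index=ids,
    )
    return Cohort(individuals, genotypes, site_index), TruthTable(sites), panel


def select_extremes(
    individuals: pd.DataFrame, extreme_fraction: float
) -> tuple[pd.Index, pd.Index]:
    """Bottom/top phenotype tails, each of size floor(fraction * n).

    Ranking is by urinary calcium with ties broken by individual id
    ascending, so the split is reproducible. Returned indexes are ordered by
    increasing urinary calcium within each group.
    """
    if not 0.0 < extreme_fraction < 0.5:
        raise ValueError("extreme_fraction must be in (0, 0.5)")
    n_tail = int(len(individuals) * extreme_fraction)
    if n_tail == 0:
        raise ValueError("extreme_fraction yields an empty group")
    ranked = individuals.sort_values(
        ["urinary_ca"], kind="mergesort"
    )  # mergesort is stable; index is already id-ascending
    low = ranked.index[:n_tail]
    high = ranked.index[-n_tail:]
    return low, high


def build_pools(
    members_ranked: Sequence[str],
    pool_sizes: Sequence[int],
    group: str,
    start_index: int = 0,
) -> list[Pool]:
    """Assign phenotype-rank-adjacent members to pools of 15 or 20.

    ``members_ranked`` must already be ordered by urinary calcium; pools take
    consecutive blocks so each pool spans a narrow phenotype range.
    """
    if sum(pool_sizes) != len(members_ranked):
        raise ValueError(
            f"pool sizes sum to {sum(pool_sizes)} but group has {len(members_ranked)} members"
        )
    pools = []
    cursor = 0
    for j, size in enumerate(pool_sizes):
        members = tuple(members_ranked[cursor : cursor + size])
        pools.append(Pool(f"{group}_{start_index + j:02d}", group, members))
        cursor += size
    return pools


def make_manifest(
    low: pd.Index,
    high: pd.Index,
    config: SimConfig,
    rng: np.random.Generator,
) -> PoolManifest:
    """Pool both groups and apply whole-pool attrition.

    Attrition drops round(pool_attrition * n_pools) pools uniformly at
    random, emulating capture or coverage failure of entire pools.
    """
    pools = build_pools(list(low), config.pool_sizes, "low") + build_pools(
        list(high), config.pool_sizes, "high"
    )
    n_drop = int(round(config.pool_attrition * len(pools)))
    if n_drop:
        drop = set(rng.choice(len(pools), size=n_drop, replace=False).tolist())
        pools = [p for i, p in enumerate(pools) if i not in drop]
    return PoolManifest(pools)


# ---------------------------------------------------------------------------
# Pileup simulation
# ---------------------------------------------------------------------------

def simulate_pileups(
    manifest: PoolManifest,
    truth: TruthTable,
    cohort: Cohort,
    config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-pool per-site read counts.

    depth ~ Poisson(mean_depth); alt reads ~ Binomial(depth, p) with
    p = f(1-eps) + (1-f) * eps/3 for real sites (f the true minor-haplotype
    fraction, eps the symmetric miscall rate) and p = the site's systematic
    miscall rate for artifact sites (all of it on the one recorded alt base).
    """
    if config.error_rate == 0 and truth.sites["is_fp"].any():
        raise ValueError(
            "error_rate = 0 with artifact sites present: no mechanism produces them"
        )
    missing = [
        m
        for p in manifest.pools
        for m in p.members
        if m not in cohort.individuals.index
    ]
    if missing:
        raise ValueError(f"pool members without genotypes: {missing[:3]} ...")
    sites = truth.sites
    n_sites = len(sites)
    eps = config.error_rate
    is_fp = sites["is_fp"].to_numpy()
    fp_rate = sites["fp_error_rate"].to_numpy()
    frames = []
    for pool in manifest.pools:
        idx = cohort.individuals.index.get_indexer(pool.members)
        k = cohort.genotypes[idx, :].sum(axis=0).astype(np.int64)
        k[is_fp] = 0
        f = k / pool.haploid_size
        p = f * (1 - eps) + (1 - f) * eps / 3.0
        p = np.where(is_fp, fp_rate, p)
        depth = rng.poisson(config.mean_depth, size=n_sites)
        alt = rng.binomial(depth, p)
        frames.append(
            pd.DataFrame(
                {
                    "site_id": sites["site_id"].to_numpy(),
                    "gene": sites["gene"].to_numpy(),
                    "chrom": sites["chrom"].to_numpy(),
                    "pos": sites["pos"].to_numpy(),
                    "ref": sites["ref"].to_numpy(),
                    "alt": sites["alt"].to_numpy(),
                    "pool_id": pool.pool_id,
                    "depth": depth,
                    "alt_reads": alt,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_databases(truth: TruthTable, out_dir: str | Path) -> dict[str, Path]:
    """Write the three mock database key files (headerless 4-column TSV)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("dbsnp", "g1000", "esp"):
        subset = truth.sites.loc[
            truth.sites[name], ["chrom", "pos", "ref", "alt"]
        ]
        path = out_dir / f"{name}.tsv"
        subset.to_csv(path, sep="\t", index=False, header=False)
        paths[name] = path
    return paths


# ---------------------------------------------------------------------------
# Count-level null and burden simulations (for calibration studies)
# ---------------------------------------------------------------------------

def simulate_null_variant_counts(
    n_variants: int,
    rng: np.random.Generator,
    n_low: int = 710,
    n_high: int = 520,
    af_range: tuple[float, float] = (0.05, 0.45),
) -> pd.DataFrame:
    """Group haplotype counts for variants with no group-frequency difference.

    Each variant gets one population frequency and independent binomial
    minor-allele counts in both groups — the null of the per-variant 2x2
    test. Frequencies default to the common range where the chi-square
    approximation is exact enough to calibrate against.
    """
    af = rng.uniform(*af_range, size=n_variants)
    return pd.DataFrame(
        {
            "af_pop": af,
            "a_low": rng.binomial(n_low, af),
            "n_low": n_low,
            "a_high": rng.binomial(n_high, af),
            "n_high": n_high,
        }
    )


def simulate_burden_counts(
    rng: np.random.Generator,
    n_genes: int = 40,
    variants_per_gene: int = 6,
    af_range: tuple[float, float] = (3e-5, 1.5e-3),
    n_low: int = 710,
    n_high: int = 520,
    spike_gene: str | None = None,
    spike_alleles: int = 0,
) -> pd.DataFrame:
    """Per-variant rare-allele counts for a gene panel under the null,
    optionally spiking extra carriers of one additional rare variant into
    the low group of one gene.

    Frequencies are log-uniform on ``af_range`` (the generator's default
    rare spectrum: observed variants are mostly singletons). Output columns
    match what :func:`calcipool.association.gene_burden` consumes.
    """
    lo, hi = af_range
    rows = []
    for g in range(n_genes):
        gene = f"GENE{g:02d}"
        af = np.exp(rng.uniform(np.log(lo), np.log(hi), size=variants_per_gene))
        a = rng.binomial(n_low, af)
        c = rng.binomial(n_high, af)
        for v in range(variants_per_gene):
            rows.append((gene, f"{gene}_v{v}", int(a[v]), n_low, int(c[v]), n_high))
        if spike_gene == gene and spike_alleles > 0:
            rows.append((gene, f"{gene}_spike", spike_alleles, n_low, 0, n_high))
    df = pd.DataFrame(
        rows, columns=["gene", "site_id", "a_low", "n_low", "a_high", "n_high"]
    )
    df["af"] = (df["a_low"] + df["a_high"]) / (df["n_low"] + df["n_high"])
    return df
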