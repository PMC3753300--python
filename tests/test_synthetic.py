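"""Generator behaviour: phenotype model, extremes, pooling, pileups."""

import numpy as np
import pandas as pd
import pytest

import calcipool as cp
from calcipool.synthetic import _draw_alt


def small_config(**kwargs) -> cp.SimConfig:
    base = dict(
        n_individuals=1200,
        pool_sizes=(15, 15, 20, 20, 20, 15, 15),  # 120 per group
        n_known_sites=30,
        n_true_sites=30,
        n_fp_sites=30,
        pool_attrition=0.0,
        causal_effects=(),
        seed=11,
    )
    base.update(kwargs)
    return cp.SimConfig(**base)


class TestSimulateCohort:
    def test_null_model_has_no_genotype_phenotype_correlation(self):
        cfg = small_config(n_individuals=2000, causal_effects=())
        cohort, truth, _ = cp.simulate_cohort(cfg)
        ca = cohort.individuals["urinary_ca"].to_numpy()
        common = truth.sites.loc[truth.sites["kind"] == "known", "site_id"]
        for site_id in common.iloc[:10]:
            g = cohort.dosages(site_id)
            if g.std() == 0:
                continue
            r = np.corrcoef(g, ca)[0, 1]
            assert abs(r) < 0.1

    def test_causal_effect_recovered_by_least_squares(self):
        # one causal allele shifting the phenotype +40 mg/day at MAF 0.2:
        # the OLS slope of phenotype on dosage must recover it
        cfg = small_config(
            n_individuals=5000,
            causal_effects=(("known_0000", 40.0),),
            causal_af=0.2,
            seed=3,
        )
        cohort, _, _ = cp.simulate_cohort(cfg)
        g = cohort.dosages("known_0000").astype(float)
        y = cohort.individuals["urinary_ca"].to_numpy()
        x = g - g.mean()
        slope = (x * y).sum() / (x * x).sum()
        resid = y - y.mean() - slope * x
        se = np.sqrt(resid.var(ddof=2) / (x * x).sum())
        assert slope == pytest.approx(40.0, abs=3 * se)

    def test_same_seed_reproduces_everything(self):
        cfg = small_config()
        c1, t1, _ = cp.simulate_cohort(cfg)
        c2, t2, _ = cp.simulate_cohort(cfg)
        pd.testing.assert_frame_equal(c1.individuals, c2.individuals)
        np.testing.assert_array_equal(c1.genotypes, c2.genotypes)
        pd.testing.assert_frame_equal(t1.sites, t2.sites)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            small_config(n_individuals=0)
        with pytest.raises(ValueError):
            small_config(pool_sizes=(10, 15))
        with pytest.raises(ValueError):
            small_config(extreme_fraction=0.6)
        with pytest.raises(ValueError):
            small_config(error_rate=0.0)  # artifacts present but no mechanism
        with pytest.raises(ValueError):
            cp.simulate_cohort(small_config(causal_effects=(("nope", 1.0),)))

    def test_phenotypes_positive_and_dosages_valid(self):
        cohort, _, _ = cp.simulate_cohort(small_config())
        assert (cohort.individuals["urinary_ca"] > 0).all()
        assert set(np.unique(cohort.genotypes)) <= {0, 1, 2}

    def test_stone_former_enrichment_in_high_tail(self):
        # positive calcium -> stone-former link: the high tail must carry
        # more stone formers in nearly every replicate
        hits = 0
        for seed in range(100):
            cfg = small_config(
                n_known_sites=5, n_true_sites=0, n_fp_sites=0,
                error_rate=0.005, seed=seed,
            )
            cohort, _, _ = cp.simulate_cohort(cfg)
            low, high = cp.select_extremes(cohort.individuals, cfg.extreme_fraction)
            f_low = cohort.individuals.loc[low, "stone_former"].mean()
            f_high = cohort.individuals.loc[high, "stone_former"].mean()
            hits += f_high > f_low
        assert hits >= 95


class TestSelectExtremes:
    def test_tail_sizes_match_study_split(self):
        # 9600 individuals at 5% per tail -> 480/480, the published design
        df = pd.DataFrame(
            {"urinary_ca": np.random.default_rng(0).normal(200, 60, 9600)},
            index=pd.Index([f"ind{i:05d}" for i in range(9600)], name="id"),
        )
        low, high = cp.select_extremes(df, 0.05)
        assert len(low) == len(high) == 480

    def test_simple_values(self):
        df = pd.DataFrame(
            {"urinary_ca": [1.0, 2, 3, 4, 5, 6, 7, 8, 9, 10]},
            index=pd.Index([f"i{k}" for k in range(10)], name="id"),
        )
        low, high = cp.select_extremes(df, 0.2)
        assert list(low) == ["i0", "i1"]
        assert list(high) == ["i8", "i9"]
        assert df.loc[low, "urinary_ca"].max() < df.loc[high, "urinary_ca"].min()

    def test_ties_broken_by_id_ascending(self):
        df = pd.DataFrame(
            {"urinary_ca": [5.0] * 6},
            index=pd.Index(["a", "b", "c", "d", "e", "f"], name="id"),
        )
        low, high = cp.select_extremes(df, 1 / 3)
        assert list(low) == ["a", "b"]
        assert list(high) == ["e", "f"]

    def test_empty_tail_rejected(self):
        df = pd.DataFrame(
            {"urinary_ca": [1.0, 2.0, 3.0]}, index=pd.Index(["a", "b", "c"], name="id")
        )
        with pytest.raises(ValueError):
            cp.select_extremes(df, 0.1)


class TestBuildPools:
    def test_cohort_row_of_study_layout(self):
        # 120 individuals in 4x15 + 3x20 -> 7 pools
        members = [f"m{i}" for i in range(120)]
        pools = cp.build_pools(members, (15, 15, 15, 15, 20, 20, 20), "low")
        assert len(pools) == 7
        assert sum(p.haploid_size for p in pools) == 240

    def test_355_survivors_give_710_haplotypes(self):
        members = [f"m{i}" for i in range(355)]
        pools = cp.build_pools(members, (15,) * 5 + (20,) * 14, "low")
        assert sum(p.haploid_size for p in pools) == 710

    def test_single_pool_haploid_size(self):
        pools = cp.build_pools([f"m{i}" for i in range(15)], (15,), "high")
        assert pools[0].haploid_size == 30

    def test_ranked_adjacency(self):
        members = [f"m{i}" for i in range(35)]
        pools = cp.build_pools(members, (15, 20), "low")
        assert pools[0].members == tuple(members[:15])
        assert pools[1].members == tuple(members[15:])

    def test_errors(self):
        members = [f"m{i}" for i in range(30)]
        with pytest.raises(ValueError):
            cp.build_pools(members, (15, 16), "low")  # bad size (and sum)
        with pytest.raises(ValueError):
            cp.build_pools(members, (15,), "low")  # sum mismatch

    def test_manifest_disjointness_enforced(self):
        p1 = cp.Pool("a", "low", tuple(f"m{i}" for i in range(15)))
        p2 = cp.Pool("b", "low", tuple(f"m{i}" for i in range(10, 25)))
        with pytest.raises(ValueError):
            cp.PoolManifest([p1, p2])

    def test_haploid_accounting_under_attrition(self, default_run):
        manifest = default_run.manifest
        for group, idx in (("low", default_run.low), ("high", default_run.high)):
            members = [m for p in manifest.by_group(group) for m in p.members]
            assert manifest.haploid_total(group) == 2 * len(members)
            assert set(members) <= set(idx)


class TestSimulatePileups:
    def test_artifact_alt_bases_have_error_titv(self):
        # uniform choice over the three non-reference bases: 4 of the 12
        # ordered substitution classes are transitions -> Ti/Tv -> 0.5
        rng = np.random.default_rng(5)
        refs = rng.choice(list("ACGT"), size=12_000)
        pairs = pd.DataFrame(
            {"ref": refs, "alt": [_draw_alt(r, "fp", 3.0, rng) for r in refs]}
        )
        ratio = cp.titv_ratio(pairs).titv_obs
        assert ratio == pytest.approx(0.5, abs=0.03)

    def test_true_variant_alt_bases_match_target_titv(self):
        rng = np.random.default_rng(6)
        refs = rng.choice(list("ACGT"), size=10_000)
        pairs = pd.DataFrame(
            {"ref": refs, "alt": [_draw_alt(r, "novel", 3.0, rng) for r in refs]}
        )
        assert cp.titv_ratio(pairs).titv_obs == pytest.approx(3.0, abs=0.1)

    def test_no_carriers_no_errors_no_alt_reads(self):
        cfg = small_config(
            n_fp_sites=0, error_rate=0.0,
            af_known=(0.0, 0.0), af_novel=(1e-12, 1.1e-12), causal_effects=(),
        )
        rng = np.random.default_rng(cfg.seed)
        cohort, truth, _ = cp.simulate_cohort(cfg, rng)
        cohort.genotypes[:] = 0
        low, high = cp.select_extremes(cohort.individuals, cfg.extreme_fraction)
        manifest = cp.make_manifest(low, high, cfg, rng)
        counts = cp.simulate_pileups(manifest, truth, cohort, cfg, rng)
        assert (counts["alt_reads"] == 0).all()

    def test_every_site_appears_once_per_pool(self, default_run):
        counts, truth = default_run.counts, default_run.truth
        per_pool = counts.groupby("pool_id")["site_id"].nunique()
        assert (per_pool == len(truth.sites)).all()
        per_site = counts.groupby("site_id")["pool_id"].nunique()
        assert (per_site == len(default_run.manifest.pools)).all()

    def test_true_counts_bounded_by_haploid_size(self, default_run):
        truth_k = default_run.truth.pool_counts(
            default_run.manifest, default_run.cohort
        )
        hap = {p.pool_id: p.haploid_size for p in default_run.manifest.pools}
        assert (truth_k["k"] <= truth_k["pool_id"].map(hap)).all()
        fp_ids = set(
            default_run.truth.sites.loc[default_run.truth.sites["is_fp"], "site_id"]
        )
        assert (truth_k.loc[truth_k["site_id"].isin(fp_ids), "k"] == 0).all()

    def test_pool_members_must_have_genotypes(self):
        cfg = small_config()
        rng = np.random.default_rng(cfg.seed)
        cohort, truth, _ = cp.simulate_cohort(cfg, rng)
        stranger = cp.Pool("x", "low", tuple(f"ghost{i}" for i in range(15)))
        manifest = cp.PoolManifest([stranger])
        with pytest.raises(ValueError, match="genotypes"):
            cp.simulate_pileups(manifest, truth, cohort, cfg, rng)


class TestManifestRoundTrip:
    def test_tsv_round_trip(self, default_run, tmp_path):
        path = tmp_path / "manifest.tsv"
        default_run.manifest.write(path)
        back = cp.PoolManifest.read(path)
        assert back.to_frame().equals(default_run.manifest.to_frame())
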