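"""Shared fixtures: one full default-configuration pipeline run per session."""

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

import calcipool as cp


@dataclass
class PipelineRun:
    config: cp.SimConfig
    cohort: cp.Cohort
    truth: cp.TruthTable
    panel: cp.GenePanel
    low: pd.Index
    high: pd.Index
    manifest: cp.PoolManifest
    counts: pd.DataFrame
    callset: cp.CallSet
    annotated: pd.DataFrame  # calls merged with annotations
    qc_result: cp.QcResult


def run_pipeline(config: cp.SimConfig) -> PipelineRun:
    rng = np.random.default_rng(config.seed)
    cohort, truth, panel = cp.simulate_cohort(config, rng)
    low, high = cp.select_extremes(cohort.individuals, config.extreme_fraction)
    manifest = cp.make_manifest(low, high, config, rng)
    counts = cp.simulate_pileups(manifest, truth, cohort, config, rng)
    callset = cp.call_sites(counts, manifest, error_rate=config.error_rate)
    databases = {
        name: set(
            zip(
                truth.sites.loc[truth.sites[name], "chrom"],
                truth.sites.loc[truth.sites[name], "pos"],
                truth.sites.loc[truth.sites[name], "ref"],
                truth.sites.loc[truth.sites[name], "alt"],
            )
        )
        for name in ("dbsnp", "g1000", "esp")
    }
    annotations = cp.annotate_calls(callset.calls, panel, databases)
    annotated = callset.calls.merge(annotations.drop(columns=["gene"]), on="site_id")
    qc_result = cp.apply_qc(annotated)
    return PipelineRun(
        config, cohort, truth, panel, low, high, manifest, counts, callset,
        annotated, qc_result,
    )


@pytest.fixture(scope="session")
def default_run() -> PipelineRun:
    """The default study configuration, simulated and analysed once."""
    return run_pipeline(cp.SimConfig(seed=0))


@pytest.fixture(scope="session")
def spiked_burden_wins() -> tuple[int, int]:
    """Rank-first count for a gene spiked with 10 extra rare-allele
    carriers in the low group, over 1000 burden replicates at the default
    singleton-dominated rare spectrum. Computed once per session."""
    rng = np.random.default_rng(109)
    reps, wins = 1000, 0
    for _ in range(reps):
        counts = cp.simulate_burden_counts(
            rng, spike_gene="GENE00", spike_alleles=10
        )
        burden = cp.gene_burden(counts)
        wins += burden.loc[burden["p_value"].idxmin(), "gene"] == "GENE00"
    return wins, reps
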