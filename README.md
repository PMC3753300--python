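# calcipool

Analysis pipeline for **pooled extreme-phenotype resequencing** of candidate
genes, built around the study design used to search for rare variants
influencing 24-hour urinary calcium excretion (the dominant risk factor for
calcium kidney stones): individuals from the tails of the phenotype
distribution are pooled (15 or 20 per pool), target-captured and deeply
sequenced, and only aggregate per-pool allele fractions are observed.

The package provides, as reusable library modules and a CLI:

* **`synthetic`** — a study generator: cohort with genotypes and a Gaussian
  phenotype, logistic stone-former link, tail selection, rank-adjacent
  pooling with whole-pool attrition, and per-pool pileup counts with known
  ground truth (known SNPs, rare novel variants, recurrent artifact sites);
* **`caller`** — per-pool minor-haplotype count estimation by exact
  discrete maximum likelihood and site calling by likelihood ratio;
* **`annotate`** — transition/transversion class, database membership
  (known vs novel), and coding consequence with HGVS-style names;
* **`qc`** — the recurrence filter for novel calls and the Ti/Tv mixture
  diagnostic;
* **`association`** — per-variant 2×2 haplotype tests with a Bonferroni
  policy, gene-level rare-variant burden tests, and group phenotype
  summaries.

## The model in brief

**Pool counts.** A pool of N individuals carries 2N haplotypes. With k
minor haplotypes and symmetric per-base miscall rate ε, the alt-read count
at a site is

    alt ~ Binomial(depth, p(k)),   p(k) = (k/2N)(1−ε) + (1−k/2N)·ε/3,

and k̂ = argmax_k over the discrete grid k ∈ {0,…,2N} (ties toward smaller
k). A site is called when some pool's log-likelihood ratio of k̂ against
k = 0 exceeds a threshold (default 10 nats); pools below 20× depth are
no-call and drop out of numerator and haplotype denominator alike.

**Artifact filtering.** Real SNVs are transition-biased (Ti/Tv ≈ 2.8–3.3);
uniform errors hit 4 of 12 substitution classes, Ti/Tv = 0.5. For a call
set with observed ratio Ti/Tv_obs the estimated true-positive share is

    %TP = (Ti/Tv_obs − Ti/Tv_FP) / (Ti/Tv_TP − Ti/Tv_FP).

Acting on the complementary observation that genuine novel variants are
rare, novel calls observed more than 3 times (total estimated haplotype
count) are excluded; the Ti/Tv of the retained set verifies the cleanup.

**Association.** Each variant contributes a haplotype table
[[a, n_low−a], [c, n_high−c]] tested by uncorrected Pearson chi-square, or
Fisher's exact test (two-sided, minimum-likelihood convention) when any
expected cell is below 5 or a policy override demands it; significance is
judged against α/n_tests. The gene burden test aggregates minor alleles of
variants with pooled frequency < 2% per gene and group and applies the
exact test to the aggregate.

## Worked example

Run the whole pipeline on the default synthetic study (4,800 individuals,
10% tails, 26 pools per group with ~35% attrition, 429 known + 259 novel +
884 artifact sites, 500× pool depth):

```bash
calcipool all --seed 0 --out run/
```

which ends with (abridged):

```
SNVs total: 1314
  known (in any database): 429 [Ti 322 / Tv 107 (Ti/Tv 3.01); %TP 89.6-100.0]
  novel, recurrence-excluded: 802 [Ti 259 / Tv 543 (Ti/Tv 0.48); %TP 0.0-0.0]
  novel, retained: 83 [Ti 68 / Tv 15 (Ti/Tv 4.53); %TP 100.0-100.0]

Top associations:
   site_id    gene       test  freq_low  freq_high  p_value  significant
known_0000    ACO1 chi_square  0.037736   0.007246 0.000195        False
known_0350 SLC34A1 chi_square  0.239623   0.328986 0.000652        False
...
```

Reading the ledger: 1,314 sites entered the call set; the 429 database
SNPs show the transition bias of real variation (Ti/Tv 3.01), the 802
recurrence-excluded novel calls sit at the pure-error ratio (0.48), and
the 83 retained novel calls are clean again (4.53) — the filter removed
the artifacts, not the signal. The top association is the simulated causal
variant (`known_0000`: 3.8% of low-group vs 0.7% of high-group
haplotypes, p = 2×10⁻⁴), which — like the corresponding real-study
signal — does not survive a Bonferroni threshold of 0.05/512 ≈ 1×10⁻⁴.
Per-stage artifacts (`calls.vcf`, `ledger.tsv`, `association.tsv`,
`burden.tsv`, JSON run manifests with input hashes and the seed) land in
`run/`.

The same stages are available as library calls; see the module docstrings
and `tests/conftest.py` for a compact end-to-end example.

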