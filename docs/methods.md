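# Methods

## Study design being modelled

The pipeline targets a pooled extreme-phenotype resequencing design for a
positive quantitative trait (24-hour urinary calcium excretion, mg/day).
Individuals from the bottom and top tails of the trait distribution are
assigned — in phenotype-rank order — to pools of 15 or 20, each pool is
captured and sequenced as one library, and only per-pool, per-site read
counts are observed. The analysis asks two questions: do individual
variants differ in haplotype frequency between the tails, and do genes
carry different aggregate burdens of rare alleles?

## Synthetic study generator

`synthetic.SimConfig` holds every design parameter. The defaults describe
the study conditions end to end; a scientist changing them is changing the
experiment, not tuning the software.

| parameter | default | meaning |
|---|---|---|
| `n_individuals` | 4800 | cohort size before tail selection |
| `extreme_fraction` | 0.10 | per-tail fraction → 480 individuals/group |
| `baseline_ca_mean`, `baseline_ca_sd` | 200, 60 mg/day | Gaussian trait (truncated > 0); tail means ≈ 95/305 mg/day |
| `causal_effects` | one −25 mg/day allele at MAF 0.025 | additive genetic effect; carriers are enriched ~4:1 in the low tail |
| `stone_former_link` | 0.0023 log-odds per mg/day | logistic link; ≈51% vs 63% stone formers in low/high tails |
| `pool_sizes` | 8×15 + 18×20 per group | 26 pools/group, 960 haplotypes/group before attrition |
| `pool_attrition` | 18/52 | whole pools dropped at random (capture/coverage failure) |
| `mean_depth` | 500 reads/site/pool | Poisson per-site depth |
| `error_rate` | 0.005 | symmetric per-base miscall probability |
| `n_known_sites` / `n_true_sites` / `n_fp_sites` | 429 / 259 / 884 | site panel composition |
| `af_known` | U(0.02, 0.5) | database-SNP frequency spectrum |
| `af_novel` | log-U(3×10⁻⁵, 1.5×10⁻³) | rare-variant spectrum: observed novels are mostly singletons |
| `titv_tp` | 3.0 | transition bias of real variants |
| `fp_error_range` | U(0.005, 0.04) | site-specific artifact miscall rate |

Choices worth explaining:

* **Artifact model.** Artifact sites have zero true carriers. Their alt
  base is uniform over the three non-reference bases, which fixes the
  expected Ti/Tv of the artifact class at 4/8 = 0.5 by counting
  substitution classes. Their reads are generated with a *site-specific*
  miscall rate, shared across pools and concentrated on that one alt base,
  emulating sequence-context-specific systematic error. This is the
  mechanism that makes artifacts (a) cross the calling threshold and (b)
  recur across pools — precisely the behaviour the recurrence filter
  exploits. Independent uniform errors at rate ε/3 per alternative base
  would essentially never be called at 500× and could never look like a
  recurrent "novel variant", leaving the filter nothing to do.
* **Rare-variant spectrum.** The novel-site frequency range is set so that
  a variant segregating in the population is seen 0–3 times among the
  ~1,200 sequenced haplotypes; observed novel variants are then mostly
  singletons, the regime this design actually operates in. Many latent
  novel sites are consequently never observed in a given cohort draw —
  also realistic.
* **Phenotype model.** Gaussian baseline plus additive allele effects plus
  a logistic stone-former link is the simplest generative model that
  produces the group structure the pipeline consumes (tail means, a
  recoverable per-allele effect, stone-former enrichment in the high
  tail). Ties at the tail cut are broken by individual id so a seed fully
  determines the split.
* **Pooling.** Members are assigned to pools in consecutive phenotype-rank
  blocks (pools span narrow trait ranges, as when samples are ranked
  before pooling). Attrition drops whole pools; per-amplicon dropout is
  not modelled.
* **Resolution.** Simulation is at pileup-count level (no reads, no
  FASTQ/BAM): every downstream computation consumes per-site counts, so
  read-level detail would add cost without information.

What the generator does **not** emulate — and hence what green tests do
not certify on real data: context-dependent coverage (GC, amplicon
effects), correlated errors between nearby sites, index hopping or sample
contamination between pools, linkage between sites (sites are drawn
independently), population structure, and real allele-frequency spectra
beyond the two stylised classes above.

## Pool calling

The minor-haplotype count of a pool is estimated by exhaustive likelihood
scan over k ∈ {0..2N} under alt ~ Binomial(depth, (k/2N)(1−ε) +
(1−k/2N)ε/3), ε taken from configuration (default 0.005), ties toward
smaller k. The scan *is* the estimator — no approximation sits between
the model and the argmax, and a property test keeps it that way against an
independent plain-Python scan. At 500× and 2N = 30 the estimate is within
±1 haplotype of truth in ≥95% of pools; exact recovery needs depth where
adjacent counts are several binomial SEs apart (~4.7 SEs at 20,000×).

Sites are called when any pool's log-likelihood ratio of k̂ against k = 0
exceeds `lr_threshold` (default 10 nats, at which real variants with one
carrier in a pool are called reliably while artifact calling is governed
by each site's systematic error rate). Pools under `min_depth` (default
20×, the design's coverage floor) are no-call: they leave the site's
haplotype denominator rather than imputing zero, so per-site denominators
are sums over contributing pools. The manifest-wide denominators are also
reported per call (`n_low_total`/`n_high_total`) since published tables
often use the fixed global denominator.

Concordance against the truth table treats it as an external
gold-standard variant panel assumed error-free: completeness is the
fraction of segregating panel sites called; accuracy is the rate of
per-pool count estimates within ±1, over called panel sites (artifact
sites are not in the panel — a panel comparison cannot score them).

## Annotation

Transition vs transversion is a two-set membership test (A↔G, C↔T).
Database membership is exact on (chrom, pos, ref, alt) — allele-aware
matching, stricter than position-only. Coding consequence translates the
affected codon with the standard genetic code; gene models carry the
coding-strand CDS with 0-based half-open exon blocks (converted at the
boundary; all public coordinates are 1-based), and minus-strand calls are
complemented into CDS space, so a variant annotates identically from
either strand representation. Names follow HGVS style (`c.11C>T`,
`p.Thr4Met`, `p.=` for silent, `Ter` for stop gain).

## QC filtering

Novel calls (absent from every database) with occurrence > 3 are
excluded. Occurrence defaults to the total estimated minor-haplotype
count Σk̂ across pools — in pooled data the natural multiplicity, since
per-individual genotypes do not exist; the number of carrying pools is
available as an alternative metric. The ledger enforces
`total = known + excluded + retained` by construction.

The %TP mixture estimate `(obs − fp)/(tp − fp)` is reported at both ends
of the assumed true-variant ratio interval [2.8, 3.3] and is a diagnostic
only; it never alters the retained set. Algebraically, because a pooled
Ti/Tv is the transversion-weighted mean of the component ratios, the
formula returns exactly the fraction of transversions contributed by the
true class — the tests assert this identity on deterministic counts.
Out-of-range values are returned flagged, not clamped (in summaries they
are clamped *and* flagged); a set with no transversions has an undefined
ratio, reported as such rather than as infinity.

## Association testing

Per-variant tables are tested by uncorrected Pearson chi-square (the
convention that reproduces the published per-variant values; a continuity
correction does not). Fisher's exact test (two-sided,
minimum-likelihood convention — the prevailing definition in scientific
software) is used when any expected cell is below 5, when a margin is
degenerate, or when a `TestPolicy.force_fisher` override designates the
variant (mirroring published analyses that applied the exact test to
specific variants regardless of expected counts). Monomorphic variants
report p = 1 with a flag. Bonferroni is applied as a threshold α/n on
unadjusted p-values.

The burden test aggregates minor-allele counts of variants with pooled
frequency < 2% per gene (allele-count burden; each variant counts its
alleles once) and applies the exact test to the aggregate table, using
the widest per-site denominator seen in the gene. Carrier-unit
aggregation is available as a switch but is approximate in pooled data.
Genes without rare variants are omitted with a log note.

Calibration, measured by the suite: the per-variant test rejects at the
nominal 5% under the null for common variants (where the chi-square route
applies). The burden test, being exact on discrete aggregates, is
*conservative* at the default singleton-dominated spectrum (rejection
well below nominal — asserted as never anti-conservative) and reaches the
nominal rate when aggregate counts are large enough for discreteness to
wash out; power is checked by spiking 10 extra rare-allele carriers into
one gene's low group, which tops the gene ranking in ~82% of replicates.

## Numerical and degenerate-input choices

* Likelihoods use `scipy.stats.binom.logpmf`; invalid k beyond a pool's
  2N are masked at −∞ in the vectorised path.
* Zero depth → no-call sentinel, never k̂ = 0.
* ε = 0 is accepted by the generator only when no artifact sites are
  requested (errors are the only mechanism that produces them); the
  caller requires ε ∈ (0, 0.1).
* Chi-square on a zero margin raises with a pointer to the exact test.
* Ledger conservation violations raise at construction.
* Every stage draws from a single `numpy` Generator seeded by the config,
  so a (config, seed) pair reproduces every artifact byte for byte.

## Problem sizes

The default study (4,800 individuals, 1,572 sites, 52→34 pools) simulates
and analyses in a few seconds; the test suite's Monte-Carlo studies use
1,000–2,500 replicates per calibration question, chosen so sampling error
is small against the asserted bounds.

## Known limitations

Single-transcript, SNV-only annotation (no splice/UTR effects, no
indels, no multi-allelic sites); error rate is configured, not estimated
from data; no covariate adjustment or trend tests across the full
phenotype distribution; burden testing is count-based (no
dispersion/kernel tests); the simulator's independence assumptions listed
above.
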