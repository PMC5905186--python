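# Methods

## Model

`cavedate` implements an isolation-with-migration model for a pair of
populations observed through pooled sequencing, with four distinctive
ingredients: unequal generation times handled on a common one-year clock, a
laboratory-drift observation layer, classification of sites into joint
polymorphism classes rather than a full joint site-frequency spectrum, and
dating by a summary-statistic goodness-of-fit profile rather than a
likelihood.

### Site classes

A biallelic site polarized with an outgroup falls into one of eight classes
according to whether each population is fixed (ancestral or derived) or
polymorphic, and whether polymorphism is shared or involves different allele
pairs (divergent polymorphism, class 8). "Fixed" means minor allele
frequency ≤ `maf_min` (default 0.05): pooled allele frequencies are noisy,
so a strictly-zero criterion would misclassify sites with trace
contamination or sequencing error, and the same threshold is used
symmetrically when the site is called polymorphic. Class 8 requires three
segregating alleles overall; it is essentially absent from data (one site in
the reference dataset) and structurally impossible under the infinite-sites
simulator, so all frequency vectors are over classes 1–7.

Exchanging the two populations permutes the classes as (1 2)(3 5)(4 6) and
fixes 7 and 8; this symmetry is exploited as a correctness property
throughout the tests.

### Retention filters

Sites pass four rules, applied in a fixed order with each discard attributed
to the first failing rule: depth ≥ `min_depth` in both pools (inclusive, so
a site at exactly 100 reads is kept); contig e-value < `max_evalue`; no
other surviving SNP within `min_isolation_bp` on either side (both members
of a close pair drop; computed among depth/e-value survivors, which makes
the filter idempotent); and a MAF rule that discards sites whose variation
is entirely sub-threshold, i.e. both populations are called fixed for the
same major allele. Sub-threshold variation in one population while the
other is genuinely polymorphic does not discard the site — that population
is simply called fixed, mirroring the calling threshold.

### Forward simulation

All loci are unlinked, neutral and biallelic. Drift is binomial: the
derived-allele count of the next generation is Binomial(2N, p). Mutation
follows the infinite-sites convention: a Poisson(2Nu) number of *new* loci
appears each generation at frequency 1/(2N), where `u` is the probability
of a new SNP arising per haploid genome per generation. With the default
u = 0.02, a population of 10,000 gains on average 400 loci per generation
at 5 × 10⁻⁵ and a population of 1250 gains 50 at 4 × 10⁻⁴.

The ancestral population is equilibrated by running 10 · `n_anc`
generations (several multiples of the ~2N-generation relaxation time of the
site-frequency spectrum); a two-halves comparison of the tail of the
segregating-site count flags non-stationarity. At equilibrium the
segregating-locus count fluctuates around the neutral expectation
4Nu·Σ_{i<2N} 1/i, which is verified in the tests at reduced scale.

After the split both populations inherit the ancestral frequency vector and
change instantaneously to their own sizes at their first reproduction.
Time advances in integer years: the surface population reproduces in years
divisible by `g_sf` (default 2), the cave population in years divisible by
`g_cf` (default 5). Each year, before any reproduction, a migration pulse
occurs with probability `mig_prob_per_year`; a pulse is deterministic
admixture `p_cave ← (1 − m)·p_cave + m·p_surface` with `m = mig_frac`
(stochasticity enters through the next drift step; migrant sampling noise
is second-order at the default m = 0.01). Cave-to-surface migration is
taken as negligible. A locus leaves the system only when it is absent from
both populations or fixed in both (counted as a shared substitution);
loci fixed in one population but not the other — the dating signal — are
retained indefinitely.

### Observation layer

Every `checkpoint_years` (default 100, a common multiple of both generation
times: 50 surface and 20 cave generations), each wild population is sampled
virtually: `2·lab_n_fish` allele copies are drawn binomially, then
`lab_gens` Wright–Fisher generations at size `lab_ne` with no mutation
emulate the drift accumulated in laboratory stocks between establishment
and sequencing (defaults 10 fish, 10 generations, Ne 10). With defaults
this compounds to a frequency variance of p(1−p)(1 − (19/20)¹¹) per locus.
Lab vectors are classified with the same `maf_min` as the data, so a
singleton among 20 allele copies counts as fixed, matching the MAF > 5%
calling rule. Checkpoints are recorded at years 0, 100, 200, …; sampling
is independent at each checkpoint and does not perturb the wild
populations.

### Goodness-of-fit dating

At each checkpoint the simulated class-frequency 7-vector is compared to
the observed one by

    score = Σ_c (sim_c − obs_c)² / max(obs_c, 1e-6),

and the reported age is the earliest checkpoint attaining the minimal score
(ties resolve to the youngest dating). The chi-square-type weighting keeps
rare classes informative; the distance is isolated behind `gof_score` /
the `score_fn` parameter so Euclidean or Hellinger alternatives can be
swapped, and on the default configuration all three place the minimum in
the same 20,000–30,000-year valley — the argmin, not the absolute score
value, is the meaningful quantity, and score values are not comparable
across distances.

The observation layer can be treated two ways. With ``lab_stats="sample"``
the simulator draws one virtual lab stock per checkpoint, reproducing the
noisy observation process (this is what the trajectory CLI emits). For
dating, `DivergenceDater` defaults to ``lab_stats="expected"``: for each
locus the full distribution of the final lab state is computed exactly —
the initial Binomial(2·`lab_n_fish`, p) sample propagated through the
lab-drift transition matrix raised to `lab_gens` — and expected class
counts are accumulated, with surface and cave samples independent given
the wild frequencies. This integrates the observation noise out of the
score profile (a Rao–Blackwellization: identical expectation, strictly
smaller variance), leaving only the wild drift process stochastic; the
two routes are cross-checked against each other in the tests. Fixed/
polymorphic calls compare the minor-allele frequency to `maf_min` with a
1e-9 tolerance so that boundary states (e.g. one copy among twenty) are
called symmetrically for ancestral and derived alleles regardless of
floating-point rounding.

Two numerical caveats are deliberate. First, the ε-guard makes the weight
degenerate when an *observed* class frequency is exactly zero: any
simulated occupancy of that class is then penalized by a factor ~10⁶.
Real datasets populate all seven classes, but small synthetic truth sets
(a few hundred classified loci) may not; in that case use more loci or a
different `score_fn`. Second, the per-checkpoint score is a Monte-Carlo
estimate whose noise is governed by the number of classified loci, which
scales with `u` — the expected class frequencies themselves are invariant
to `u` (verified in the tests), making the mutation rate purely an
accuracy/runtime knob. Around the optimum the score valley is flat, so even
with the exact observation layer the single-run argmin varies by roughly
±15% with the realized wild drift. `DivergenceDater(replicates=R)`
therefore averages R independent score profiles age-wise before taking the
argmin; the acceptance script uses R = 8 and additionally smooths the mean
profile with a centered ±500-year moving average (`smoothed_best_age`)
before locating the minimum, and reports the median of per-replicate
argmins as a companion statistic.

### Parameter defaults

| parameter | default | meaning |
|---|---|---|
| `n_anc`, `n_sf`, `n_cf` | 10000, 10000, 1250 | diploid effective sizes |
| `g_sf`, `g_cf` | 2, 5 yr | generation times |
| `u` | 0.02 | new-SNP probability per haploid genome per generation |
| `mig_prob_per_year` | 0.001 | surface→cave pulse probability |
| `mig_frac` | 0.01 | fraction of cave gene pool replaced per pulse |
| `lab_n_fish`, `lab_ne`, `lab_gens` | 10, 10, 10 | lab observation model |
| `checkpoint_years` | 100 | evaluation interval |
| `maf_min` | 0.05 | polymorphism-calling threshold |
| `min_depth`, `max_evalue`, `min_isolation_bp` | 100, 1e-5, 50 | site filters |

The defaults are the configuration reported to fit the Pachón/Texas data.
One published description of that configuration is internally inconsistent
(a figure legend lists cave size 625 and migrant fraction 0.1% where the
accompanying text, used here, says 1250 and 1%; the text also quantifies
the pulse as "12 fish", i.e. 0.96% of 1250, which we round to 1%).

## Synthetic data

`make_site_table` draws class labels from a specified multinomial and
materializes allele counts consistent with each class: fixed populations
carry only one allele; polymorphic populations draw their MAF uniformly on
(`maf_min`, 0.5], since only class membership, not the within-class
frequency, enters any downstream statistic. Depths are lognormal with a
heavy tail (clipped at `min_depth` for passing sites), the outgroup always
carries the ancestral allele, and disjoint subsets of sites are constructed
to violate exactly one retention rule each (shallow depth in one pool,
pairs 30 bp apart, all-sub-threshold variation, bad contig e-value). What
it does **not** emulate: read-level error, reference bias, mis-polarization
(outgroup homoplasy), annotation error, or linkage between nearby SNPs.
Passing tests therefore validate the classification/filter logic and the
estimator plumbing, not robustness to those real-data artefacts.

`make_truth_observed` runs the forward model itself to a known age and
returns the checkpoint statistics with the generating parameters, enabling
parameter-recovery tests (median recovered age within 25% of truth at
reduced scale). `make_quartet` builds four-taxon alignments on a known
topology with no homoplasy, so every informative site supports the
generating topology by construction.

## Quartet support

A column is informative iff it shows exactly two states, each in exactly
two taxa; columns with gaps or ambiguity codes in any taxon are skipped
(standard parsimony practice — the source analyses do not state a
convention). Topologies are reported as canonical taxon-name partitions
("a,b|c,d"), so results are independent of record order. A gene with no
informative sites or a tied maximum is unresolved and congruent with
nothing.

## Problem sizes and numerical choices

Tests run the full configuration with eight replicates to 40,000 years
(the same procedure the acceptance script uses) and everything else at
reduced scale (ancestral sizes 400–2000), keeping the suite around a
quarter of an hour; the acceptance script itself takes about thirteen
minutes single-core. The
simulator tracks ~8–12 × 10³ loci at the default scale in two float64
vectors; memory is negligible. All randomness flows from a single
`numpy.random.Generator` per simulator, seeded explicitly; runs are
bit-reproducible given (parameters, seed), and multi-replicate/sweep seeds
are spawned from the master seed via `SeedSequence`, independent of
execution order.

## Known limitations

- Free recombination and neutrality are assumed for every locus;
  background selection or hitchhiking in the transcriptome data would bias
  the class frequencies in ways the model cannot absorb.
- The ascertainment of the observed dataset (depth filters on pooled reads)
  is not modelled inside the simulator; the lab-drift + MAF observation
  layer is its proxy.
- The dating profile is a point summary; no credible interval is attached
  (the score is not a likelihood). The score-profile valley is intrinsically
  flat over roughly ±20% around the optimum at the default mutation rate.
- The divergent-polymorphism class is informative about tri-allelic sites
  only in the observed-data path; the simulator's infinite-sites assumption
  excludes it by construction.
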