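# Methods

`plethotime` implements a temporal population-genomic analysis of serially
collected specimens: museum-era samples (formalin-fixed liver), mid-century
frozen blood, and modern tissue from the same localities, genotyped at
multi-locus biallelic SNPs. Because real archival datasets are large and
access-controlled, the package pairs every analysis stage with a synthetic
data generator that carries known demographic truth, so the whole pipeline
is exercisable — and testable — with no external data.

## The forward model

Each locus (default length 710 bp) carries a set of independent biallelic
sites. Standing variation is initialised from the neutral site-frequency
spectrum: a segregating site's derived-allele count i in {1..2N−1} is drawn
with probability proportional to 1/i. Derived counts then follow binomial
Wright–Fisher updates each generation with the epoch's diploid size N, so a
scenario is just a piecewise-constant N trajectory plus a list of sampling
epochs. At each sampling epoch, diploid genotypes are drawn binomially from
the current allele frequency (Hardy–Weinberg); sites that have fixed or
been lost by a later epoch are retained and may be invariant there.

New variation enters as infinite-sites mutation influx: per locus and
generation, Poisson(2NμL) new sites appear at count 1. This term is what
lets an expanding population *gain* diversity — pure drift on standing
frequencies can only lose heterozygosity in expectation, so without influx
the expansion signature (π↑, θ_W↑, D↓) would be unreachable in principle.
At the default per-site rate of μ = 5.97e−9 per generation (a mean
vertebrate-style rate appropriate for the study organism) the influx is
negligible over the ~20 generations separating the 1960s from today, which
is realistic and is why the *preset* scenarios rescale μ (below).

Calendar time maps onto generations at 3 years per generation. This is a
configuration choice, not a measured quantity, for a small terrestrial
salamander; nothing downstream depends on it except labels.

Random-number discipline: a master seed spawns one substream per locus and,
in the artifact layer, one per sample, so a given locus or sample replays
identically regardless of how many others are simulated. Identical seeds
produce byte-identical VCF output.

### Scenario presets

The presets are desk-scale caricatures of three demographic histories,
sampled at generations 30 / 60 / 100 with 20 / 15 / 20 diploids (the uneven
sizes mirror typical collection series). μ is rescaled to 1e−5 so that
mutation–drift signatures are measurable at these population sizes — the
standard forward-simulation rescaling that preserves the products Nμ and
N·generations at a fraction of the cost.

* **stable** — N = 150 throughout, with standing variation initialised at
  the mutation–drift equilibrium level (27 segregating sites per locus,
  matching 4NμL·a_{2N−1}), so expected diversity is flat through time.
* **expansion** — N = 50 until generation 31 (just after the first
  sampling epoch), then N = 1000. Mutation influx at the large size adds
  rare variants: π and θ_W rise, Tajima's D falls.
* **bottleneck** — N = 1000 crashing 40-fold to N = 25 just after the
  second epoch. Diversity drops and the surviving sites sit at
  intermediate frequencies, pushing D up at the final epoch. The crash is
  placed late deliberately: a crash deep in the past drives survivors all
  the way to fixation, at which point D relaxes again and the signature
  inverts — a real limitation of endpoint-based trend calls.

## The artifact layer

Archival DNA corrupts genotype calls, not reads, at the point where this
pipeline begins (the VCF), so artifacts are modelled as call-level
operations:

| knob | default | emulates |
|---|---|---|
| depth, historic liver | N(19.2, 16.7), truncated at 1 | formalin-fixed voucher coverage |
| depth, frozen blood | N(37.7, 25.8) | capillary-tube blood coverage |
| depth, modern liver | N(54.0, 33.6) | fresh-tissue coverage |
| `missing_rate` | 0.05 | failed genotype calls |
| `dropout_rate` | 0.10 | allelic dropout: a true heterozygote read as one of its homozygotes (uniformly chosen) — the documented homozygous bias of degraded samples |
| `damage_rate_CT` / `damage_rate_GA` | 0.008 / 0.006 | deamination-style miscalls; each C (resp. G) allele copy at a C/T (G/A) site flips with this probability |

AD fields are a binomial split of the drawn depth by the observed genotype;
QUAL is 60 unless a `qual_error_fraction` of sites is demoted to 10 to
exercise the quality filter. The depth means/SDs and damage rates are the
kind of values mapDamage-style QC reports for formalin-era collections;
`missing_rate` and `dropout_rate` have no canonical published value and are
set to plausible defaults, stated here once and not tuned.

What the generator does **not** emulate: read-level errors and their
correlation structure, linkage within loci (sites are independent; the
one-SNP-per-locus thinning makes downstream statistics insensitive to
this), reference bias, contamination, and batch effects between library
preparations. Passing tests therefore certify the statistics and the
pipeline plumbing under a clean generative model, not robustness to every
failure mode of real archival data.

## The filter chain

Filters run in a fixed order; the published description of such chains
rarely states one, and site-level frequencies must be computed after
genotype-level masking for internal consistency:

1. **Indel proximity** — SNPs within 3 bp (|Δpos| ≤ 3) of an indel are
   removed; indels ≤ 5 bp apart form clusters whose members all project
   the same exclusion window.
2. **QUAL ≥ 30** (missing QUAL passes, with no evidence against it).
3. **Biallelic SNPs only** — multiallelic records and indels drop here.
4. **Genotype masks** — calls with DP < 5 are set missing; heterozygous
   calls with allele balance outside the open interval (0.25, 0.75) are
   set missing (balance is undefined for homozygotes). A VCF without AD
   makes the balance mask a no-op, flagged on the report.
5. **Site filters**, computed from the masked calls: minor allele count
   ≥ 3, minor allele frequency > 0.015 (both enforced — they are not
   redundant at small n), and ≥ 50% of individuals called.

The chain is idempotent, and the report balances exactly
(sites_in − Σremoved = sites_out). Depth downsampling to a 24× target mean
operates on DP (binomial thinning) and AD (hypergeometric subsampling)
rather than on reads, consistent with the VCF-level scope; samples at or
below the target are untouched. Boundary conventions: length/GC bounds of
the probe-design utility are inclusive; BED intervals are 0-based
half-open against 1-based VCF POS.

## Statistics

* **π** per site is the unbiased pairwise estimator
  n_minor(n − n_minor)/C(n, 2) over called chromosomes (diploid calls
  contribute two chromosomes, half-calls one). On a SNP matrix the
  population mean runs over all usable sites, with sites monomorphic
  within the population contributing zero.
* **Watterson's θ** per site is S/(a₁L) with a₁ = Σ_{i<n} 1/i, computed in
  150 bp windows tiling each locus (step = window size; the last, partial
  window is used at its true length). The window's chromosome count is
  the mean over its sites, rounded to the nearest integer for the
  constants — per-site variation in call rate is folded into that mean.
* **Tajima's D** uses the standard 1989 constants on the window sum of
  pairwise differences; undefined (NaN) when S = 0 or fewer than 4
  chromosomes.
* **Weir–Cockerham Fst** computes the 1984 variance components a, b, c
  per site from diploid calls (the h̄ term needs genotypes); both the
  mean of per-site ratios and the ratio of summed components are
  reported. The per-site mean is the default summary because the outlier
  scan operates site-wise. Negative per-site estimates are kept (they
  carry the estimator's near-zero behaviour); sites with a+b+c = 0 are
  excluded from summaries.

## Temporal inference

Uneven sample sizes are handled by permutation subsampling: for each
subsample size from 3 up to N, the statistic is recomputed on 20 draws
without replacement, each draw from a named substream (seed, size,
replicate). Screening rules: |mean D across permutations| > 1.5 flags a
departure from neutrality; CV of θ_W replicates > 1.0 flags significant
variability. One-way ANOVA with Tukey HSD runs per species × site stratum
on permutation replicates taken at a common subsample size one below the
smallest group — at full size the replicates coincide and the test
degenerates. The replicate values are pseudo-replicated by construction;
this is a property of the procedure being reproduced and is inherited, not
corrected.

Trend classification compares the last time point against the first:
(π↑, θ↑, D↓) → expansion; (π↓, θ↓, D↑) or (π↓, θ↑, D↑) → contraction; all
flat → stable; anything else → mixed. "Flat" means |relative change| ≤ 2%
(absolute for D, which crosses zero). The 2% default is tighter than
sampling noise at the preset sizes, so the stable preset mostly classifies
"mixed" rather than "stable"; the tolerance is configurable, and this
behaviour is the honest answer for endpoint rules on noisy series.

## Selection scan

The neutral baseline is the per-site W–C Fst distribution over non-coding
(flanking) SNPs under a user-supplied grouping — the grouping is a
required argument everywhere because it is a study-design decision, not a
package default. Candidates are flagged as outliers when their Fst
strictly exceeds mean + 2·SD (sample SD, n−1); under a normal null this
flags the expected 2.3% tail. Baselines under 30 informative sites carry a
low-power warning. Polymorphism summaries pool each species over all time
points and localities: "fixed" means monomorphic within the species across
everything; unique/missing alleles are judged against the all-species
allele union; percent heterozygosity is the mean per-site heterozygote
fraction over the species' polymorphic sites — one reasonable reading of
an ambiguous quantity, stated here explicitly. "Large frequency change
through time" is reported descriptively with a configurable |Δf| cutoff
(default 0.25).

## Numerical and degenerate-input choices

Empty filter output is a valid result (empty matrix plus a balanced
report), not an error. An all-missing population yields NaN diversity with
a warning. ANOVA with zero within-group variance and unequal means reports
p ≈ 0 flagged as degenerate. Identical permutation replicates give exactly
zero SD (no floating-point residue). Ne = θ/(4μ) conversions are not
performed; θ_W needs no mutation rate, and μ enters only the simulator.

## Problem sizes

The test-suite and acceptance-script simulations use 40–100 loci of 710 bp
with 14–27 segregating sites per locus and 55 samples across three epochs
(and a 141 × 2229 matrix for the missingness recovery check). These sizes
give the calibration checks ~500 windows and the recovery checks 25
replicate datasets per scenario, which is where their quoted rates are
measured; they are the package's chosen desk-scale study conditions.

## Known limitations

* Endpoint-based trend calls ignore the middle time point except through
  the monotonicity of the rule's inputs; non-monotone histories (crash
  then rebound) classify as mixed by design.
* The simulator's independence of sites within a locus makes window-level
  variances optimistic relative to linked data.
* The artifact model is call-level; biases that act through read mapping
  (reference bias, contamination) are out of scope.
* The stable preset needs a looser flat tolerance than the default 2% to
  classify as "stable" at desk-scale sample sizes.
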