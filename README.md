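# plethotime

Temporal population genomics of serially collected specimens.

Natural-history collections hold time series of the same populations:
formalin-fixed vouchers from the 1960s–70s, frozen blood from the
1980s–90s, fresh tissue from today. Genotyping those series at reduced-
representation SNP panels can, in principle, reveal whether reported field
declines left a genetic footprint — falling nucleotide diversity, a
rare-allele deficit, shifting allele frequencies at immune loci. In
practice the signal is entangled with archival-DNA artifacts: coverage
disparities between tissue preparations, allelic dropout (a homozygous
bias in degraded samples), deamination-style miscalls, and aggressive
filtering. `plethotime` is a tested pipeline for exactly this setting,
aimed at researchers analysing museum-genomics SNP data or planning such
studies.

## What it computes

Given a VCF (GT:DP:AD), a BED of coding intervals per locus, and a sample
metadata table (species, site, time period, year, tissue):

* **Filter chain** — indel-proximity pruning, QUAL ≥ 30, biallelic SNPs,
  genotype masking (DP ≥ 5; heterozygote allele balance in (0.25, 0.75)),
  then MAC ≥ 3, MAF > 0.015 and ≥ 50% presence, in that order, with exact
  removal accounting; one-random-SNP-per-locus thinning; coding/non-coding
  partitioning; depth downsampling to a target mean.
* **Diversity statistics**, from scratch — per-site nucleotide diversity
  π = n_minor(n − n_minor)/C(n, 2); observed and expected heterozygosity;
  private alleles; Watterson's θ_W = S/(a₁L) and Tajima's D
  (D = (π − S/a₁)/√(e₁S + e₂S(S−1))) in 150 bp windows; per-site
  Weir–Cockerham Fst from the variance components a, b, c.
* **Temporal inference** — permutation subsampling across uneven sample
  sizes (sizes 3..N, 20 replicates each), |D| > 1.5 neutrality flags,
  CV > 1 variability flags, one-way ANOVA + Tukey HSD across time
  periods, covariate regressions, and a trend classifier:
  (π↑, θ↑, D↓) → expansion; (π↓, θ↓, D↑) or (π↓, θ↑, D↑) → contraction.
* **Selection scan** — neutral Fst baseline from non-coding SNPs,
  candidate-locus outliers beyond mean + 2·SD, allele-frequency
  trajectories through time, and per-species polymorphism/fixation
  summaries.
* **Synthetic data** — a forward Wright–Fisher simulator (neutral-SFS
  standing variation, infinite-sites mutation influx, serial sampling)
  with an archival-artifact layer (tissue-specific coverage, missingness,
  dropout, C>T/G>A damage), emitting VCF + BED + metadata with known
  demographic truth. Presets: `stable`, `expansion`, `bottleneck`.

See `docs/methods.md` for the model, estimators, and design choices.

## Worked example

Simulate a population that crashes 40-fold between the second and third
collection periods, apply archival artifacts and the filter chain, and ask
whether the statistics see it:

```bash
plethotime simulate --scenario bottleneck --n-loci 60 --seed 20260928 --out sim
plethotime all --vcf sim.vcf --bed sim.coding.bed --meta sim.meta.tsv --seed 7 --out run/
```

Equivalently, the numbered drivers under `analysis/` run the same stages
on all three scenario presets (`01_simulate_datasets.py` …
`05_immune_scan.py`), writing tables under `results/`. The diversity stage
prints, for the bottleneck dataset:

```
time_period  n_samples      pi   h_obs   h_exp  theta_w  tajimas_d
1960s-1970s         20 0.18655 0.16572 0.18039  0.00220    0.16696
1980s-1990s         15 0.19699 0.17374 0.18919  0.00242    0.09093
      2010s         20 0.18297 0.16062 0.17768  0.00183    0.50534
```

π here is per variant site of the SNP matrix and θ_W per base pair, so
their scales differ. Between the pre-crash epochs and the 2010s, π and
θ_W fall while Tajima's D jumps (0.17 → 0.51): the crash removed rare
alleles faster than pairwise diversity, the classic contraction
signature, despite ~16% missing data and a dropout-biased heterozygote
deficit. The scan stage reports a non-coding baseline Fst of
mean = 0.147 (SD = 0.192) across time periods and flags 1 of 20 candidate
sites beyond the mean + 2·SD threshold. A single realisation can still
miss: the trend classifier recovers the bottleneck in ≥ 90% of replicate
datasets, not all of them, and the drivers print whichever call their
seed produced.

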