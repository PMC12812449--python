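"""Synthetic serially-sampled genotype datasets with archival-DNA artifacts.

A forward Wright-Fisher simulator on per-site allele frequencies generates
multi-locus biallelic SNP data sampled at three time points, with known
demographic truth (stable / expansion / bottleneck scenarios).  An artifact
layer then emulates what historical-specimen DNA does to genotype calls:
tissue-dependent coverage (formalin-fixed liver, frozen blood, modern liver),
missingness, allelic dropout (the documented homozygous bias of degraded
samples), and deamination-style C>T / G>A miscalls.  The result is emitted as
VCF + BED + metadata so the whole downstream pipeline is exercisable with no
external data.

Model
-----
* Standing variation: each locus starts with a fixed number of segregating
  sites whose derived-allele count i in {1..2N-1} is drawn from the neutral
  site-frequency spectrum (P(i) proportional to 1/i).
* Drift: derived counts follow binomial Wright-Fisher updates each
  generation with the current epoch's 2N.
* Mutation: new sites enter at count 1 at rate 2*N*mu*L per locus per
  generation (infinite-sites influx).  At the default per-site rate of
  5.97e-9 this is negligible over the study's time depth; the scenario
  presets use a rescaled rate so that desk-scale simulations show the
  mutation-drift signatures the classifier looks for.
* Sampling: at each sampling epoch, diploid genotypes are drawn binomially
  from the current frequency (Hardy-Weinberg); sites fixed or lost by a
  later epoch are retained and may be invariant there.

Sites within a locus are independent (no linkage); the one-SNP-per-locus
thinning step downstream makes the statistics insensitive to this.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix, METADATA_COLUMNS, matrix_from_gt012

BASES = np.array(["A", "C", "G", "T"])

#: default per-tissue depth (mean, sd) in x coverage
DEFAULT_DEPTH = {
    "historic_liver": (19.2, 16.7),
    "frozen_blood": (37.7, 25.8),
    "modern_liver": (54.0, 33.6),
}

#: epoch label -> (time-period string, representative collection year)
EPOCH_METADATA = {
    "T1": ("1960s-1970s", 1972),
    "T2": ("1980s-1990s", 1988),
    "T3": ("2010s", 2018),
}

#: epoch label -> tissue preparation used at that time point
EPOCH_TISSUE = {
    "T1": "historic_liver",
    "T2": "frozen_blood",
    "T3": "modern_liver",
}

#: calendar years per generation used to map decades onto generations.
#: Generation time is a configuration choice of this package, not a
#: measured quantity; 3 years is a plausible value for a small terrestrial
#: salamander.
YEARS_PER_GENERATION = 3.0


@dataclass
class DemographicScenario:
    """Parameters of the forward simulation."""

    n_loci: int
    sites_per_locus: int
    epoch_sizes: list[tuple[int, int]]          # (start_generation, diploid N)
    sampling_epochs: list[tuple[int, str, int]]  # (generation, label, n_samples)
    locus_length_bp: int = 710
    mutation_rate_mu: float = 5.97e-9            # per site per generation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("need at least one locus")
        if self.locus_length_bp < 1:
            raise ValueError("locus length must be positive")
        if not 0 <= self.sites_per_locus <= self.locus_length_bp:
            raise ValueError("sites_per_locus must be in [0, locus_length_bp]")
        if self.mutation_rate_mu < 0:
            raise ValueError("mutation rate must be non-negative")
        starts = [g for g, _ in self.epoch_sizes]
        if not starts or starts[0] != 0:
            raise ValueError("first epoch must start at generation 0")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("epoch boundaries must be strictly increasing")
        if any(n < 2 for _, n in self.epoch_sizes):
            raise ValueError("all population sizes must be >= 2")
        labels = [lab for _, lab, _ in self.sampling_epochs]
        if len(set(labels)) != len(labels):
            raise ValueError("sampling labels must be unique")
        gens = [g for g, _, _ in self.sampling_epochs]
        if any(g < 0 for g in gens):
            raise ValueError("sampling generations must be non-negative")
        if sorted(gens) != gens:
            raise ValueError("sampling epochs must be in increasing order")

    @property
    def span(self) -> int:
        """Last simulated generation (the final sampling epoch)."""
        return self.sampling_epochs[-1][0]

    def size_at(self, generation: int) -> int:
        """Diploid N in force at the given generation."""
        n = self.epoch_sizes[0][1]
        for start, size in self.epoch_sizes:
            if generation >= start:
                n = size
        return n


@dataclass
class ArtifactModel:
    """Archival-DNA artifact parameters applied at the genotype-call level.

    Depth defaults reflect the coverage disparity between modern liver,
    historic frozen blood and formalin-fixed historic liver; damage rates
    reflect mapDamage-style deamination misincorporation estimates for
    formalin-fixed tissue.
    """

    depth: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DEPTH)
    )
    missing_rate: float = 0.05
    dropout_rate: float = 0.10
    damage_rate_CT: float = 0.008
    damage_rate_GA: float = 0.006
    qual: float = 60.0
    qual_error_fraction: float = 0.0   # fraction of sites given low QUAL (10)

    def __post_init__(self) -> None:
        for rate in (
            self.missing_rate,
            self.dropout_rate,
            self.damage_rate_CT,
            self.damage_rate_GA,
            self.qual_error_fraction,
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("artifact probabilities must be in [0, 1]")
        for tissue, (m, s) in self.depth.items():
            if m <= 0 or s < 0:
                raise ValueError(f"invalid depth parameters for {tissue}")


@dataclass
class TruthRecord:
    """Ground truth emitted by the simulator, before artifacts."""

    scenario: DemographicScenario
    sites: pd.DataFrame                 # locus, pos, ref, alt
    freqs: np.ndarray                   # (n_sites, n_epochs) derived frequency
    genotypes: np.ndarray               # (n_sites, n_samples) 0/1/2 dosage
    samples: list[str]
    sample_epoch: list[str]             # epoch label per sample

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def epoch_labels(self) -> list[str]:
        return [lab for _, lab, _ in self.scenario.sampling_epochs]


# --------------------------------------------------------------------------
# neutral SFS initialisation
# --------------------------------------------------------------------------
def neutral_sfs_counts(n_sites: int, two_n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw derived-allele counts i in {1..2N-1} with P(i) proportional to 1/i."""
    i = np.arange(1, two_n)
    w = 1.0 / i
    return rng.choice(i, size=n_sites, p=w / w.sum())


# --------------------------------------------------------------------------
# forward simulation
# --------------------------------------------------------------------------
def simulate_temporal_population(scenario: DemographicScenario) -> TruthRecord:
    """Run the forward model and sample diploid genotypes at each epoch.

    Per-locus random substreams are spawned from the master seed so a given
    locus reproduces identically regardless of ``n_loci``.
    """
    epochs = scenario.sampling_epochs
    n_epochs = len(epochs)
    master = np.random.SeedSequence(scenario.seed)
    locus_seeds = master.spawn(scenario.n_loci)

    all_rows = []
    freq_blocks: list[np.ndarray] = []
    geno_blocks: list[np.ndarray] = []
    samples: list[str] = []
    sample_epoch: list[str] = []
    for gen, label, n_samp in epochs:
        samples.extend(f"{label}_s{j:03d}" for j in range(n_samp))
        sample_epoch.extend([label] * n_samp)

    for li in range(scenario.n_loci):
        rng = np.random.default_rng(locus_seeds[li])
        locus = f"locus{li:04d}"
        L = scenario.locus_length_bp
        two_n0 = 2 * scenario.size_at(0)

        counts = neutral_sfs_counts(scenario.sites_per_locus, two_n0, rng).astype(
            np.int64
        )
        positions = rng.choice(L, size=min(scenario.sites_per_locus, L), replace=False) + 1
        positions = positions.astype(np.int64)
        born = np.zeros(counts.shape, dtype=np.int64)
        occupied = set(positions.tolist())

        # recorded at each sampling epoch, aligned with `counts` order
        epoch_freq = np.zeros((len(counts), n_epochs))
        epoch_geno: list[np.ndarray] = [None] * n_epochs  # type: ignore[list-item]

        def record_epoch(k: int, counts, two_n, epoch_freq, epoch_geno):
            gen_k, label_k, n_samp = epochs[k]
            p = counts / two_n
            epoch_freq[:, k] = p
            g = rng.binomial(2, p[:, None], size=(len(counts), n_samp)).astype(np.int8)
            epoch_geno[k] = g
            return epoch_freq, epoch_geno

        next_epoch = 0
        two_n_prev = two_n0
        for gen in range(0, scenario.span + 1):
            two_n = 2 * scenario.size_at(gen)
            if gen > 0:
                # Wright-Fisher update into the current generation's size
                p = counts / two_n_prev
                counts = rng.binomial(two_n, p)
                # infinite-sites mutation influx at count 1
                lam = two_n * scenario.mutation_rate_mu * L
                n_new = rng.poisson(lam) if lam > 0 else 0
                if n_new:
                    free = [x for x in range(1, L + 1) if x not in occupied]
                    n_new = min(n_new, len(free))
                    if n_new:
                        new_pos = rng.choice(len(free), size=n_new, replace=False)
                        new_pos = np.array([free[j] for j in new_pos], dtype=np.int64)
                        occupied.update(new_pos.tolist())
                        counts = np.concatenate([counts, np.ones(n_new, dtype=np.int64)])
                        positions = np.concatenate([positions, new_pos])
                        born = np.concatenate(
                            [born, np.full(n_new, gen, dtype=np.int64)]
                        )
                        epoch_freq = np.concatenate(
                            [epoch_freq, np.zeros((n_new, n_epochs))]
                        )
                        for k in range(next_epoch):
                            epoch_geno[k] = np.concatenate(
                                [
                                    epoch_geno[k],
                                    np.zeros((n_new, epochs[k][2]), dtype=np.int8),
                                ]
                            )
            two_n_prev = two_n
            while next_epoch < n_epochs and epochs[next_epoch][0] == gen:
                epoch_freq, epoch_geno = record_epoch(
                    next_epoch, counts, two_n, epoch_freq, epoch_geno
                )
                next_epoch += 1
            # prune extinct sites that were never seen segregating at an epoch
            if len(counts):
                seen = (epoch_freq[:, :next_epoch] > 0).any(axis=1) if next_epoch else (
                    np.zeros(len(counts), dtype=bool)
                )
                dead = (counts == 0) & ~seen
                if dead.any():
                    keep = ~dead
                    occupied -= set(positions[dead].tolist())
                    counts = counts[keep]
                    positions = positions[keep]
                    born = born[keep]
                    epoch_freq = epoch_freq[keep]
                    for k in range(next_epoch):
                        epoch_geno[k] = epoch_geno[k][keep]

        # retain sites segregating or fixed-derived at some sampling epoch
        keep = (epoch_freq > 0).any(axis=1)
        counts_kept = int(keep.sum())
        if counts_kept == 0:
            continue
        order = np.argsort(positions[keep])
        idx = np.flatnonzero(keep)[order]
        refs = BASES[rng.integers(0, 4, size=counts_kept)]
        alt_off = rng.integers(1, 4, size=counts_kept)
        alts = BASES[(np.searchsorted(BASES, refs) + alt_off) % 4]
        all_rows.append(
            pd.DataFrame(
                {
                    "locus": locus,
                    "pos": positions[idx],
                    "ref": refs,
                    "alt": alts,
                }
            )
        )
        freq_blocks.append(np.asarray(epoch_freq)[idx])
        geno_blocks.append(
            np.concatenate([epoch_geno[k][idx] for k in range(n_epochs)], axis=1)
        )

    if not all_rows:
        warnings.warn("no site was polymorphic or fixed-derived at any sampling epoch")
        return TruthRecord(
            scenario=scenario,
            sites=pd.DataFrame(columns=["locus", "pos", "ref", "alt"]),
            freqs=np.zeros((0, n_epochs)),
            genotypes=np.zeros((0, len(samples)), dtype=np.int8),
            samples=samples,
            sample_epoch=sample_epoch,
        )
    sites = pd.concat(all_rows, ignore_index=True)
    return TruthRecord(
        scenario=scenario,
        sites=sites,
        freqs=np.concatenate(freq_blocks),
        genotypes=np.concatenate(geno_blocks),
        samples=samples,
        sample_epoch=sample_epoch,
    )


# --------------------------------------------------------------------------
# artifact layer
# --------------------------------------------------------------------------
def default_tissue_assignment(truth: TruthRecord) -> dict[str, str]:
    """Map each sample to the tissue preparation of its time point."""
    return {
        s: EPOCH_TISSUE[e] for s, e in zip(truth.samples, truth.sample_epoch)
    }


def apply_archival_artifacts(
    truth: TruthRecord,
    model: ArtifactModel,
    tissue_assignment: dict[str, str],
    seed: int | None = None,
) -> GenotypeMatrix:
    """Overlay coverage, missingness, dropout and damage on true genotypes.

    Each sample draws from its own substream of the artifact seed, so adding
    samples does not perturb existing ones.  Damage acts as allele-state
    flips on sites whose ref/alt pair is C/T (each C copy miscalled T with
    ``damage_rate_CT``) or G/A (G miscalled A with ``damage_rate_GA``).
    """
    missing_t = {s for s in truth.samples if s not in tissue_assignment}
    if missing_t:
        raise ValueError(f"tissue assignment missing for samples: {sorted(missing_t)}")
    unknown = {t for t in tissue_assignment.values() if t not in model.depth}
    if unknown:
        raise ValueError(f"unknown tissue class: {sorted(unknown)}")

    if seed is None:
        seed = truth.scenario.seed
    master = np.random.SeedSequence([int(seed), 0xA27])
    sample_seeds = master.spawn(len(truth.samples) + 1)
    site_rng = np.random.default_rng(sample_seeds[-1])

    n_sites = truth.n_sites
    n_samples = len(truth.samples)
    gt = truth.genotypes.astype(np.int8).copy()
    dp = np.zeros((n_sites, n_samples), dtype=np.int32)
    ad = np.full((n_sites, n_samples, 2), -1, dtype=np.int32)

    ref = truth.sites["ref"].to_numpy()
    alt = truth.sites["alt"].to_numpy()
    pair = np.char.add(ref.astype(str), alt.astype(str))
    ct_site = np.isin(pair, ["CT", "TC"])   # the C allele can read as T
    ga_site = np.isin(pair, ["GA", "AG"])   # the G allele can read as A
    # index (0=ref, 1=alt) of the damage-source allele at damage-prone sites
    ct_src = np.where(ref == "C", 0, 1)
    ga_src = np.where(ref == "G", 0, 1)

    for j, sample in enumerate(truth.samples):
        rng = np.random.default_rng(sample_seeds[j])
        mean, sd = model.depth[tissue_assignment[sample]]
        # normal truncated at 1: coverage exists for every emitted call;
        # unusable coverage manifests downstream via the DP >= 5 mask
        depth = np.maximum(
            np.rint(rng.normal(mean, sd, size=n_sites)).astype(np.int32), 1
        )
        g = gt[:, j]

        # allelic dropout: true het observed as one of its homozygotes
        het = g == 1
        drop = het & (rng.random(n_sites) < model.dropout_rate)
        g = np.where(drop, np.where(rng.random(n_sites) < 0.5, 0, 2), g)

        # damage miscalls per allele copy (source allele -> sink allele)
        for prone, src in ((ct_site, ct_src), (ga_site, ga_src)):
            rate = model.damage_rate_CT if prone is ct_site else model.damage_rate_GA
            if rate <= 0 or not prone.any():
                continue
            src_copies = np.where(src == 0, 2 - g, g)  # copies of source allele
            flips = rng.binomial(src_copies, rate) * prone.astype(int)
            # flipping a source copy moves dosage toward the sink allele
            delta = np.where(src == 0, flips, -flips)
            g = np.clip(g + delta, 0, 2).astype(np.int8)

        # missingness: explicit per-genotype uncall rate
        miss = rng.random(n_sites) < model.missing_rate
        g = np.where(miss, -1, g)

        # AD: binomial split of depth by observed genotype
        ad_alt = np.where(
            g == 1, rng.binomial(np.maximum(depth, 0), 0.5), np.where(g == 2, depth, 0)
        )
        ad[:, j, 0] = np.where(g >= 0, depth - ad_alt, -1)
        ad[:, j, 1] = np.where(g >= 0, ad_alt, -1)
        dp[:, j] = np.where(g >= 0, depth, 0)
        gt[:, j] = g

    qual = np.full(n_sites, float(model.qual))
    if model.qual_error_fraction > 0:
        low = site_rng.random(n_sites) < model.qual_error_fraction
        qual[low] = 10.0

    sites = truth.sites.copy()
    sites["qual"] = qual
    return matrix_from_gt012(truth.samples, sites, gt, dp=dp, ad=ad)


# --------------------------------------------------------------------------
# dataset emission
# --------------------------------------------------------------------------
def build_metadata(
    truth: TruthRecord,
    tissue_assignment: dict[str, str] | None = None,
    species: str = "species_A",
    site: str = "site_1",
) -> pd.DataFrame:
    """Sample metadata table (sample, species, site, time_period, year, tissue)."""
    if tissue_assignment is None:
        tissue_assignment = default_tissue_assignment(truth)
    rows = []
    for s, e in zip(truth.samples, truth.sample_epoch):
        period, year = EPOCH_METADATA.get(e, (e, 0))
        rows.append(
            {
                "sample": s,
                "species": species,
                "site": site,
                "time_period": period,
                "year": year,
                "tissue": tissue_assignment[s],
            }
        )
    return pd.DataFrame(rows, columns=METADATA_COLUMNS)


def central_coding_bed(
    locus_lengths: dict[str, int], coding_span_bp: int
) -> pd.DataFrame:
    """BED3 (0-based half-open) marking a centered coding span per locus."""
    rows = []
    for locus, length in locus_lengths.items():
        span = min(coding_span_bp, length)
        start = (length - span) // 2
        rows.append({"chrom": locus, "start": start, "end": start + span})
    return pd.DataFrame(rows)


def emit_dataset(
    matrix: GenotypeMatrix,
    meta: pd.DataFrame,
    out_prefix,
    locus_lengths: dict[str, int],
    coding_span_bp: int = 400,
) -> dict[str, str]:
    """Write VCF + BED + metadata TSV for a simulated dataset.

    Returns the paths written.  A write-then-read round trip through
    :func:`plethotime.variants.read_vcf` reproduces the matrix exactly.
    """
    from .variants import write_vcf  # local import to avoid a cycle

    if matrix.n_sites == 0:
        raise ValueError("refusing to emit an empty matrix")
    out_prefix = str(out_prefix)
    vcf_path = out_prefix + ".vcf"
    bed_path = out_prefix + ".coding.bed"
    meta_path = out_prefix + ".meta.tsv"
    write_vcf(matrix, vcf_path, contig_lengths=locus_lengths)
    bed = central_coding_bed(locus_lengths, coding_span_bp)
    bed.to_csv(bed_path, sep="\t", header=False, index=False)
    meta.to_csv(meta_path, sep="\t", index=False, columns=METADATA_COLUMNS)
    return {"vcf": vcf_path, "bed": bed_path, "meta": meta_path}


# --------------------------------------------------------------------------
# scenario presets
# --------------------------------------------------------------------------
#: Desk-scale demographic presets used throughout the analysis scripts and
#: recovery tests.  Three sampling epochs mirror the three collection
#: periods; the mutation rate is rescaled (standard forward-simulation
#: rescaling) so that mutation-drift signatures are measurable over ~100
#: generations at population sizes in the tens to thousands.
PRESET_MU = 1.0e-5
PRESET_SAMPLING = [(30, "T1", 20), (60, "T2", 15), (100, "T3", 20)]


def preset_scenario(
    name: str,
    n_loci: int = 80,
    sites_per_locus: int | None = None,
    seed: int = 0,
) -> DemographicScenario:
    """Named demographic scenario: ``stable``, ``expansion`` or ``bottleneck``.

    * stable: constant N = 150 with standing variation initialised at the
      mutation-drift equilibrium level (27 segregating sites per locus,
      matching 4*N*mu*L*a_{2N-1}), so diversity holds flat through time.
    * expansion: N = 50 until generation 31 (just after the first sampling
      epoch), then N = 1000 — rising diversity, excess rare variants.
    * bottleneck: N = 1000 crashing 40-fold to N = 25 just after the
      second sampling epoch — diversity loss and, at the final epoch, the
      intermediate-frequency excess (rising Tajima's D) of a recent crash.
    """
    if name == "stable":
        epoch_sizes = [(0, 150)]
        default_sites = 27
    elif name == "expansion":
        epoch_sizes = [(0, 50), (31, 1000)]
        default_sites = 14
    elif name == "bottleneck":
        epoch_sizes = [(0, 1000), (61, 25)]
        default_sites = 14
    else:
        raise ValueError(f"unknown scenario preset: {name!r}")
    return DemographicScenario(
        n_loci=n_loci,
        sites_per_locus=sites_per_locus if sites_per_locus is not None else default_sites,
        epoch_sizes=epoch_sizes,
        sampling_epochs=list(PRESET_SAMPLING),
        mutation_rate_mu=PRESET_MU,
        seed=seed,
    )
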