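"""Population-genetic diversity statistics.

From-scratch implementations of the estimators the temporal analysis rests
on: per-site nucleotide diversity (pi), observed/expected heterozygosity,
private alleles, windowed Watterson's theta and Tajima's D, and the
Weir & Cockerham (1984) Fst variance-components estimator.

Conventions
-----------
* Chromosome counting is haploid: a diploid call contributes two called
  chromosomes, a half-call one.
* pi on a SNP matrix is variant-sites-only by default; sites monomorphic
  within the focal population contribute 0 to the mean (they are part of
  the site set), matching how per-population pi is computed on a shared
  SNP matrix.
* Windows tile each locus independently; Tajima's D is NaN when S = 0 or
  fewer than 4 chromosomes are called.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix

__all__ = [
    "DiversityEstimate",
    "WindowStats",
    "FstResult",
    "site_pi",
    "allele_counts",
    "mean_pi",
    "heterozygosity",
    "private_alleles",
    "watterson_theta",
    "harmonic_a1",
    "tajimas_d",
    "sliding_windows",
    "weir_cockerham_fst",
]


# --------------------------------------------------------------------------
# result containers
# --------------------------------------------------------------------------
@dataclass
class DiversityEstimate:
    """Per-population diversity summary."""

    population: str
    pi: float
    h_obs: float
    h_exp: float
    n_private: int | None
    n_sites_used: int


@dataclass
class WindowStats:
    """Per-window segregating sites and SFS-based estimators."""

    locus: str
    start: int          # 1-based inclusive position of the window start
    end: int            # 1-based inclusive position of the window end
    length: int         # true window length in bp (last window may be partial)
    n_sites: int        # variant-matrix sites falling in the window
    S: int              # sites segregating in the focal samples
    n_chrom: float      # mean called chromosomes over the window's sites
    pi_total: float     # sum over sites of mean pairwise differences
    theta_w: float      # per-site Watterson's theta
    tajimas_d: float    # NaN when undefined


@dataclass
class FstResult:
    """Weir-Cockerham Fst over a site set."""

    groups: list[str]
    per_site: np.ndarray          # theta-hat per site, NaN where undefined
    a: np.ndarray                 # among-population variance component
    b: np.ndarray                 # among-individual component
    c: np.ndarray                 # within-individual component
    mean_of_ratios: float         # mean of per-site theta-hat (default summary)
    ratio_of_means: float         # sum(a) / sum(a+b+c)
    n_sites_used: int


# --------------------------------------------------------------------------
# elementary site statistics
# --------------------------------------------------------------------------
def site_pi(n_minor: int, n_total: int) -> float:
    """Unbiased per-site nucleotide diversity for a biallelic site.

    Equals the proportion of chromosome pairs carrying distinct alleles
    among all C(n, 2) pairs: ``n_minor * (n - n_minor) / C(n, 2)``, i.e.
    the ``n/(n-1) * 2p(1-p)`` estimator.

    Returns NaN when fewer than two chromosomes are called.
    """
    n = int(n_total)
    if n < 2:
        return float("nan")
    k = int(n_minor)
    return k * (n - k) / (n * (n - 1) / 2.0)


def allele_counts(matrix: GenotypeMatrix, sample_mask: np.ndarray | None = None):
    """Per-site (alt copies, called chromosomes) for the masked samples."""
    alt = matrix.alt_copies
    tot = matrix.called_copies
    if sample_mask is not None:
        alt = alt[:, sample_mask]
        tot = tot[:, sample_mask]
    return alt.sum(axis=1), tot.sum(axis=1)


def _site_pi_vector(alt: np.ndarray, tot: np.ndarray) -> np.ndarray:
    pi = np.full(alt.shape, np.nan, dtype=float)
    ok = tot >= 2
    t = tot[ok].astype(float)
    a = alt[ok].astype(float)
    pi[ok] = a * (t - a) / (t * (t - 1) / 2.0)
    return pi


def mean_pi(
    matrix: GenotypeMatrix,
    sample_mask: np.ndarray | None = None,
    include_invariant: bool = False,
    population: str = "",
) -> DiversityEstimate:
    """Mean per-site pi for a population slice of a SNP matrix.

    Sites with fewer than two called chromosomes in the slice are skipped.
    With ``include_invariant=False`` (SNP-matrix convention) the average
    runs over all usable matrix sites, invariant-in-population sites
    contributing 0; ``include_invariant=True`` behaves identically on a
    SNP-only matrix but also admits invariant rows retained by the
    simulator, for per-bp diversity work.
    """
    alt, tot = allele_counts(matrix, sample_mask)
    pi = _site_pi_vector(alt, tot)
    usable = ~np.isnan(pi)
    if not include_invariant:
        # on a SNP matrix every row is a variant site; nothing extra to drop
        pass
    if not usable.any():
        warnings.warn("no site with >=2 called chromosomes; pi undefined")
        h_obs, h_exp = heterozygosity(matrix, sample_mask)
        return DiversityEstimate(population, float("nan"), h_obs, h_exp, None, 0)
    h_obs, h_exp = heterozygosity(matrix, sample_mask)
    return DiversityEstimate(
        population=population,
        pi=float(np.nanmean(pi)),
        h_obs=h_obs,
        h_exp=h_exp,
        n_private=None,
        n_sites_used=int(usable.sum()),
    )


def heterozygosity(
    matrix: GenotypeMatrix, sample_mask: np.ndarray | None = None
) -> tuple[float, float]:
    """Observed and expected heterozygosity over sites.

    h_obs: per site, the fraction of called diploid genotypes that are
    heterozygous, averaged over sites with at least one called genotype.
    h_exp: per site 2p(1-p) from called allele copies, averaged over sites
    with at least two called chromosomes.
    """
    het = matrix.is_het
    both = matrix.called_copies == 2
    alt = matrix.alt_copies
    tot = matrix.called_copies
    if sample_mask is not None:
        het = het[:, sample_mask]
        both = both[:, sample_mask]
        alt = alt[:, sample_mask]
        tot = tot[:, sample_mask]
    n_dip = both.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        hobs_site = np.where(n_dip > 0, het.sum(axis=1) / np.maximum(n_dip, 1), np.nan)
    tot_s = tot.sum(axis=1).astype(float)
    alt_s = alt.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot_s >= 2, alt_s / np.maximum(tot_s, 1), np.nan)
    hexp_site = 2.0 * p * (1.0 - p)
    h_obs = float(np.nanmean(hobs_site)) if np.isfinite(hobs_site).any() else float("nan")
    h_exp = float(np.nanmean(hexp_site)) if np.isfinite(hexp_site).any() else float("nan")
    return h_obs, h_exp


def private_alleles(
    matrix: GenotypeMatrix, populations: dict[str, np.ndarray]
) -> dict[str, int]:
    """Count alleles observed in exactly one population.

    ``populations`` maps label -> boolean sample mask; masks must be
    disjoint.  Both REF and ALT alleles are eligible.
    """
    masks = list(populations.items())
    overlap = np.zeros(matrix.n_samples, dtype=int)
    for _, m in masks:
        overlap += m.astype(int)
    if (overlap > 1).any():
        raise ValueError("population masks overlap")
    # presence[p, site, allele] for allele in {ref, alt}
    presence = np.zeros((len(masks), matrix.n_sites, 2), dtype=bool)
    for i, (_, m) in enumerate(masks):
        alt = matrix.alt_copies[:, m].sum(axis=1)
        tot = matrix.called_copies[:, m].sum(axis=1)
        presence[i, :, 0] = (tot - alt) > 0
        presence[i, :, 1] = alt > 0
    n_pops_with = presence.sum(axis=0)
    out = {}
    for i, (label, _) in enumerate(masks):
        out[label] = int((presence[i] & (n_pops_with == 1)).sum())
    return out


# --------------------------------------------------------------------------
# SFS-based estimators
# --------------------------------------------------------------------------
def harmonic_a1(n_chrom: int) -> float:
    """a1 = sum_{i=1}^{n-1} 1/i (Watterson's denominator)."""
    n = int(n_chrom)
    if n < 2:
        raise ValueError("need at least 2 chromosomes")
    return float(np.sum(1.0 / np.arange(1, n)))


def watterson_theta(S: int, n_chrom: int, window_length: float) -> float:
    """Per-site Watterson's theta: S / (a1 * L)."""
    if window_length <= 0:
        raise ValueError("window length must be positive")
    if S == 0:
        return 0.0
    return S / (harmonic_a1(n_chrom) * window_length)


def _tajima_constants(n: int) -> tuple[float, float, float]:
    """(a1, e1, e2) from Tajima (1989) for sample size n chromosomes."""
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def tajimas_d(S: int, pi_total: float, n_chrom: int) -> float:
    """Tajima's D from segregating sites and summed pairwise differences.

    ``pi_total`` is the window *sum* of mean pairwise differences (not
    per-site).  Returns NaN when S = 0 or fewer than 4 chromosomes.
    """
    n = int(n_chrom)
    if S < 1 or n < 4:
        return float("nan")
    a1, e1, e2 = _tajima_constants(n)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return float("nan")
    return (pi_total - S / a1) / np.sqrt(var)


def sliding_windows(
    matrix: GenotypeMatrix,
    sample_mask: np.ndarray | None = None,
    size: int = 150,
    step: int | None = None,
    locus_lengths: dict[str, int] | None = None,
) -> list[WindowStats]:
    """Tile each locus with windows and compute S, theta_W and D per window.

    The last window of a locus may be partial and is used with its true
    length.  ``locus_lengths`` supplies locus lengths; when absent the
    maximum observed position per locus is used.  ``step`` defaults to
    ``size`` (non-overlapping tiling).
    """
    if step is None:
        step = size
    if step <= 0 or size <= 0:
        raise ValueError("size and step must be positive")
    alt, tot = allele_counts(matrix, sample_mask)
    pi = _site_pi_vector(alt, tot)
    loci = matrix.sites["locus"].to_numpy()
    pos = matrix.sites["pos"].to_numpy()
    out: list[WindowStats] = []
    for locus in pd.unique(loci):
        in_locus = loci == locus
        lpos = pos[in_locus]
        lalt, ltot, lpi = alt[in_locus], tot[in_locus], pi[in_locus]
        length = (
            int(locus_lengths[locus]) if locus_lengths else int(lpos.max())
        )
        start = 1
        while start <= length:
            end = min(start + size - 1, length)
            wlen = end - start + 1
            sel = (lpos >= start) & (lpos <= end)
            walt, wtot, wpi = lalt[sel], ltot[sel], lpi[sel]
            seg = (walt > 0) & (walt < wtot) & (wtot >= 2)
            S = int(seg.sum())
            usable = wtot >= 2
            n_chrom = float(wtot[usable].mean()) if usable.any() else 0.0
            pi_total = float(np.nansum(wpi))
            n_round = int(round(n_chrom))
            theta = (
                watterson_theta(S, n_round, wlen) if (S > 0 and n_round >= 2) else 0.0
            )
            d = tajimas_d(S, pi_total, n_round) if n_round >= 4 else float("nan")
            out.append(
                WindowStats(
                    locus=str(locus),
                    start=start,
                    end=end,
                    length=wlen,
                    n_sites=int(sel.sum()),
                    S=S,
                    n_chrom=n_chrom,
                    pi_total=pi_total,
                    theta_w=theta,
                    tajimas_d=d,
                )
            )
            if end == length:
                break
            start += step
    return out


def windows_to_frame(windows: list[WindowStats]) -> pd.DataFrame:
    return pd.DataFrame([vars(w) for w in windows])


# --------------------------------------------------------------------------
# Weir-Cockerham Fst
# --------------------------------------------------------------------------
def weir_cockerham_fst(
    matrix: GenotypeMatrix, populations: dict[str, np.ndarray]
) -> FstResult:
    """Per-site Weir & Cockerham (1984) theta-hat and two summary means.

    Variance components a (among populations), b (among individuals within
    populations) and c (within individuals) are computed per site from
    population sample sizes, allele frequencies and observed heterozygote
    fractions; theta-hat = a / (a + b + c).  Sites where fewer than two
    populations have called genotypes, or where a + b + c = 0, are excluded
    from the summary means.

    Only full diploid calls enter the computation (the estimator's h-bar
    term needs genotypes, not chromosomes).
    """
    labels = list(populations)
    if len(labels) < 2:
        raise ValueError("need at least two populations")
    r_max = len(labels)
    n_sites = matrix.n_sites

    # per pop per site: n_i (diploid individuals called), p_i, h_i
    n_i = np.zeros((r_max, n_sites), dtype=float)
    p_i = np.zeros((r_max, n_sites), dtype=float)
    h_i = np.zeros((r_max, n_sites), dtype=float)
    for k, label in enumerate(labels):
        m = populations[label]
        both = matrix.called_copies[:, m] == 2
        alt = np.where(both, matrix.alt_copies[:, m], 0)
        het = matrix.is_het[:, m] & both
        n = both.sum(axis=1).astype(float)
        n_i[k] = n
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[k] = np.where(n > 0, alt.sum(axis=1) / (2.0 * np.maximum(n, 1)), np.nan)
            h_i[k] = np.where(n > 0, het.sum(axis=1) / np.maximum(n, 1), np.nan)

    present = n_i > 0
    r = present.sum(axis=0).astype(float)

    a = np.full(n_sites, np.nan)
    b = np.full(n_sites, np.nan)
    c = np.full(n_sites, np.nan)
    ok = r >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        nsum = np.where(present, n_i, 0.0).sum(axis=0)
        nbar = nsum / r
        n2sum = np.where(present, n_i**2, 0.0).sum(axis=0)
        nc = (nsum - n2sum / nsum) / (r - 1)
        pbar = np.where(present, n_i * np.nan_to_num(p_i), 0.0).sum(axis=0) / nsum
        s2 = np.where(
            present, n_i * (np.nan_to_num(p_i) - pbar) ** 2, 0.0
        ).sum(axis=0) / ((r - 1) * nbar)
        hbar = np.where(present, n_i * np.nan_to_num(h_i), 0.0).sum(axis=0) / nsum

        pq = pbar * (1.0 - pbar)
        term = pq - (r - 1) / r * s2
        a_v = (nbar / nc) * (s2 - (term - hbar / 4.0) / (nbar - 1.0))
        b_v = (nbar / (nbar - 1.0)) * (term - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c_v = hbar / 2.0

    # nbar must exceed 1 for the b component denominator
    ok = ok & (nbar > 1) & np.isfinite(a_v) & np.isfinite(b_v) & np.isfinite(c_v)
    a[ok], b[ok], c[ok] = a_v[ok], b_v[ok], c_v[ok]

    denom = a + b + c
    defined = ok & (denom != 0)
    theta = np.full(n_sites, np.nan)
    theta[defined] = a[defined] / denom[defined]

    if defined.any():
        mean_ratio = float(np.mean(theta[defined]))
        ratio_mean = float(np.sum(a[defined]) / np.sum(denom[defined]))
    else:
        mean_ratio = ratio_mean = float("nan")
    return FstResult(
        groups=labels,
        per_site=theta,
        a=a,
        b=b,
        c=c,
        mean_of_ratios=mean_ratio,
        ratio_of_means=ratio_mean,
        n_sites_used=int(defined.sum()),
    )
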