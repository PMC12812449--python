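"""VCF I/O, the SNP filter chain, thinning, partitioning and downsampling.

The filter chain mirrors a stringent archival-DNA workflow: indel-proximity
pruning, QUAL >= 30, biallelic SNPs only, genotype-level masking on depth
(DP >= 5) and heterozygote allele balance (strictly inside (0.25, 0.75)),
then site-level minor-allele-count (>= 3), minor-allele-frequency (> 0.015)
and presence (>= 50% of individuals) filters computed from the masked calls.

The chain order is fixed: site-level frequencies must follow genotype
masking for internal consistency.  Both the MAF and MAC filters are
enforced; they are not redundant at small sample sizes.

Coordinate dialects: VCF POS is 1-based, BED intervals are 0-based
half-open; :func:`partition_coding_noncoding` converts explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .matrix import MISSING, SITE_COLUMNS, GenotypeMatrix

__all__ = [
    "FilterConfig",
    "FilterReport",
    "LocusMap",
    "read_vcf",
    "write_vcf",
    "read_bed",
    "apply_site_filters",
    "prune_indel_proximity",
    "thin_one_snp_per_locus",
    "partition_coding_noncoding",
    "downsample_depth",
    "compute_missingness",
    "filter_candidate_targets",
]


# --------------------------------------------------------------------------
# configuration and reporting
# --------------------------------------------------------------------------
@dataclass
class FilterConfig:
    """Thresholds of the SNP filter chain (defaults as described above)."""

    min_qual: float = 30.0
    biallelic_only: bool = True
    max_maf_excluded: float = 0.015     # sites with MAF <= this are removed
    min_mac: int = 3
    min_depth: int = 5
    allele_balance_lo: float = 0.25
    allele_balance_hi: float = 0.75
    min_presence_fraction: float = 0.5
    indel_window_bp: int = 3
    indel_cluster_gap_bp: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.allele_balance_lo < self.allele_balance_hi <= 1.0:
            raise ValueError("require 0 <= lo < hi <= 1 for allele balance")
        for v in (
            self.min_qual,
            self.max_maf_excluded,
            self.min_mac,
            self.min_depth,
            self.min_presence_fraction,
            self.indel_window_bp,
            self.indel_cluster_gap_bp,
        ):
            if v < 0:
                raise ValueError("filter thresholds must be non-negative")


@dataclass
class FilterReport:
    """Bookkeeping of the ordered chain: sites_in - sum(removed) = sites_out."""

    sites_in: int = 0
    removed: dict[str, int] = field(default_factory=dict)
    sites_out: int = 0
    genotypes_masked_depth: int = 0
    genotypes_masked_balance: int = 0
    missing_fraction: float = float("nan")
    warnings: list[str] = field(default_factory=list)

    def check_balance(self) -> bool:
        return self.sites_in - sum(self.removed.values()) == self.sites_out

    def to_frame(self) -> pd.DataFrame:
        rows = [{"step": k, "sites_removed": v} for k, v in self.removed.items()]
        rows.append({"step": "TOTAL_in", "sites_removed": self.sites_in})
        rows.append({"step": "TOTAL_out", "sites_removed": self.sites_out})
        return pd.DataFrame(rows)


@dataclass
class LocusMap:
    """Per-locus coding intervals (0-based half-open) and locus lengths."""

    coding: dict[str, list[tuple[int, int]]]
    lengths: dict[str, int]

    def __post_init__(self) -> None:
        for locus, ivs in self.coding.items():
            ivs.sort()
            length = self.lengths.get(locus)
            prev_end = 0
            for s, e in ivs:
                if s < 0 or e <= s:
                    raise ValueError(f"bad interval {(s, e)} on {locus}")
                if length is not None and e > length:
                    raise ValueError(f"interval {(s, e)} exceeds {locus} length")
                if s < prev_end:
                    raise ValueError(f"overlapping intervals on {locus}")
                prev_end = e

    def is_coding(self, locus: str, pos_1based: int) -> bool:
        p = pos_1based - 1
        return any(s <= p < e for s, e in self.coding.get(locus, []))


def read_bed(path, lengths: dict[str, int] | None = None) -> LocusMap:
    """Read a BED3 file of coding intervals into a LocusMap."""
    coding: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            coding.setdefault(chrom, []).append((int(start), int(end)))
    return LocusMap(coding=coding, lengths=dict(lengths or {}))


# --------------------------------------------------------------------------
# VCF I/O
# --------------------------------------------------------------------------
def read_vcf(path) -> GenotypeMatrix:
    """Parse a VCF 4.x with GT (DP/AD optional) into a GenotypeMatrix.

    Half-calls and multiallelic records are preserved; they are resolved by
    the filter chain.  A VCF without AD makes the allele-balance filter a
    no-op (flagged on the report) — handled downstream by checking for
    all-absent AD.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    n = len(samples)
    rows, alleles, dps, ads = [], [], [], []
    has_ad_warning = False
    for i, var in enumerate(vcf):
        try:
            rows.append(
                {
                    "locus": var.CHROM,
                    "pos": var.POS,
                    "ref": var.REF,
                    "alt": ",".join(var.ALT) if var.ALT else ".",
                    "qual": var.QUAL if var.QUAL is not None else float("nan"),
                }
            )
            g = np.asarray(var.genotypes, dtype=np.int64)[:, :2]
            alleles.append(g.astype(np.int8))
            try:
                dp = var.format("DP")
            except Exception:
                dp = None
            if dp is not None:
                dp = dp.reshape(n).astype(np.int64)
                dp = np.where(dp < 0, MISSING, dp)
            else:
                dp = np.full(n, MISSING, dtype=np.int64)
            dps.append(dp.astype(np.int32))
            try:
                ad = var.format("AD")
            except Exception:
                ad = None
            if ad is not None and ad.shape[1] >= 2:
                ad2 = ad[:, :2].astype(np.int64)
                ad2 = np.where(ad2 < 0, MISSING, ad2)
            else:
                ad2 = np.full((n, 2), MISSING, dtype=np.int64)
                has_ad_warning = True
            ads.append(ad2.astype(np.int32))
        except Exception as exc:  # pragma: no cover - malformed input path
            raise ValueError(f"malformed VCF record #{i + 1} in {path}: {exc}") from exc
    if has_ad_warning:
        warnings.warn(
            "VCF records lack AD; the allele-balance filter will be a no-op"
        )
    if not rows:
        sites = pd.DataFrame(columns=SITE_COLUMNS)
        return GenotypeMatrix(
            samples=samples,
            sites=sites,
            alleles=np.zeros((0, n, 2), dtype=np.int8),
            dp=np.zeros((0, n), dtype=np.int32),
            ad=np.zeros((0, n, 2), dtype=np.int32),
        )
    return GenotypeMatrix(
        samples=samples,
        sites=pd.DataFrame(rows),
        alleles=np.stack(alleles),
        dp=np.stack(dps),
        ad=np.stack(ads),
    )


def write_vcf(
    matrix: GenotypeMatrix, path, contig_lengths: dict[str, int] | None = None
) -> None:
    """Write a VCF 4.2 with GT:DP:AD, lossless for the matrix fields."""
    lines = [
        "##fileformat=VCFv4.2",
        "##source=plethotime",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
    ]
    contigs = contig_lengths or {}
    seen = list(dict.fromkeys(matrix.sites["locus"].tolist()))
    for locus in seen:
        length = contigs.get(locus)
        if length:
            lines.append(f"##contig=<ID={locus},length={length}>")
        else:
            lines.append(f"##contig=<ID={locus}>")
    header = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(
        matrix.samples
    )
    lines.append(header)
    alle = matrix.alleles
    dp = matrix.dp
    ad = matrix.ad
    for i, row in matrix.sites.iterrows():
        qual = row["qual"]
        qual_s = "." if pd.isna(qual) else f"{float(qual):g}"
        fields = [
            str(row["locus"]),
            str(int(row["pos"])),
            ".",
            str(row["ref"]),
            str(row["alt"]),
            qual_s,
            "PASS",
            ".",
            "GT:DP:AD",
        ]
        for j in range(matrix.n_samples):
            a0, a1 = alle[i, j]
            gt = f"{'.' if a0 < 0 else a0}/{'.' if a1 < 0 else a1}"
            d = "." if dp[i, j] < 0 else str(int(dp[i, j]))
            if ad[i, j, 0] < 0 and ad[i, j, 1] < 0:
                adf = "."
            else:
                adf = ",".join(
                    "." if v < 0 else str(int(v)) for v in ad[i, j]
                )
            fields.append(f"{gt}:{d}:{adf}")
        lines.append("\t".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# filter chain
# --------------------------------------------------------------------------
def prune_indel_proximity(
    sites: pd.DataFrame,
    is_indel: np.ndarray,
    config: FilterConfig | None = None,
) -> np.ndarray:
    """Boolean keep-mask for SNP records near indels.

    A SNP within ``indel_window_bp`` (|delta| <= window) of any indel on the
    same locus is removed.  Indels whose nearest indel neighbour is within
    ``indel_cluster_gap_bp`` form clusters; SNPs near any cluster member are
    likewise removed (cluster members are already indels, so the practical
    effect is the shared proximity window).  Indel records themselves are
    kept here — the biallelic-SNP filter drops them later, keeping the
    report's step accounting separable.
    """
    config = config or FilterConfig()
    loci = sites["locus"].to_numpy()
    pos = sites["pos"].to_numpy()
    keep = np.ones(len(sites), dtype=bool)
    for locus in pd.unique(loci[is_indel]):
        ind_pos = np.sort(pos[(loci == locus) & is_indel])
        snp_idx = np.flatnonzero((loci == locus) & ~is_indel)
        if not len(snp_idx):
            continue
        dist = np.min(
            np.abs(pos[snp_idx][:, None] - ind_pos[None, :]), axis=1
        )
        keep[snp_idx[dist <= config.indel_window_bp]] = False
    return keep


def _allele_balance_available(matrix: GenotypeMatrix) -> bool:
    return bool((matrix.ad >= 0).any())


def apply_site_filters(
    matrix: GenotypeMatrix, config: FilterConfig | None = None
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the ordered filter chain; returns the filtered matrix + report.

    Order: (1) indel-proximity pruning, (2) QUAL, (3) biallelic SNPs only,
    (4) genotype masking (depth, het allele balance), (5) site-level MAC,
    MAF and presence computed after masking.  An empty result is returned
    as an empty matrix with a balanced report, not an error.
    """
    config = config or FilterConfig()
    report = FilterReport(sites_in=matrix.n_sites)
    m = matrix.copy()

    # (1) indel proximity
    keep = prune_indel_proximity(m.sites, m.is_indel, config)
    report.removed["indel_proximity"] = int((~keep).sum())
    m = m.take_sites(keep)

    # (2) site quality
    qual = m.sites["qual"].to_numpy(dtype=float)
    keep = ~(qual < config.min_qual)          # NaN QUAL passes (no evidence)
    report.removed["qual"] = int((~keep).sum())
    m = m.take_sites(keep)

    # (3) biallelic SNPs only
    if config.biallelic_only:
        keep = m.is_snp
        report.removed["non_biallelic_snp"] = int((~keep).sum())
        m = m.take_sites(keep)
    else:
        report.removed["non_biallelic_snp"] = 0

    # (4) genotype-level masking
    has_dp = (m.dp >= 0).any()
    if has_dp:
        low_dp = (m.dp >= 0) & (m.dp < config.min_depth) & m.called
        report.genotypes_masked_depth = int(low_dp.sum())
        m.alleles[low_dp] = MISSING
    else:
        report.warnings.append("no DP present; depth mask skipped")
    if _allele_balance_available(m):
        ad_tot = m.ad[:, :, 0] + m.ad[:, :, 1]
        with np.errstate(invalid="ignore", divide="ignore"):
            ab = np.where(ad_tot > 0, m.ad[:, :, 1] / np.maximum(ad_tot, 1), np.nan)
        bad_ab = (
            m.is_het
            & (m.ad[:, :, 0] >= 0)
            & (m.ad[:, :, 1] >= 0)
            & ~((ab > config.allele_balance_lo) & (ab < config.allele_balance_hi))
        )
        report.genotypes_masked_balance = int(bad_ab.sum())
        m.alleles[bad_ab] = MISSING
    else:
        report.warnings.append("no AD present; allele-balance filter is a no-op")

    # (5) site-level filters from masked calls
    alt = m.alt_copies.sum(axis=1)
    tot = m.called_copies.sum(axis=1)
    mac = np.minimum(alt, tot - alt)
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(tot > 0, mac / np.maximum(tot, 1), 0.0)
    presence = m.called.sum(axis=1) / max(m.n_samples, 1)

    fail_mac = mac < config.min_mac
    fail_maf = ~fail_mac & (maf <= config.max_maf_excluded)
    fail_presence = ~fail_mac & ~fail_maf & (presence < config.min_presence_fraction)
    report.removed["mac"] = int(fail_mac.sum())
    report.removed["maf"] = int(fail_maf.sum())
    report.removed["presence"] = int(fail_presence.sum())
    m = m.take_sites(~(fail_mac | fail_maf | fail_presence))

    report.sites_out = m.n_sites
    report.missing_fraction = compute_missingness(m) if m.n_sites else float("nan")
    assert report.check_balance(), "filter report does not balance"
    return m, report


# --------------------------------------------------------------------------
# thinning / partitioning / downsampling / missingness
# --------------------------------------------------------------------------
def thin_one_snp_per_locus(matrix: GenotypeMatrix, seed: int) -> GenotypeMatrix:
    """Keep exactly one uniformly chosen site per locus (deterministic per seed)."""
    rng = np.random.default_rng(seed)
    loci = matrix.sites["locus"].to_numpy()
    chosen = []
    for locus in sorted(pd.unique(loci)):
        idx = np.flatnonzero(loci == locus)
        chosen.append(idx[rng.integers(0, len(idx))])
    chosen = np.sort(np.asarray(chosen))
    return matrix.take_sites(chosen)


def partition_coding_noncoding(
    matrix: GenotypeMatrix, locus_map: LocusMap
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Split sites into (coding, non-coding) by the BED half-open convention.

    A site with 1-based POS p is coding iff p-1 falls inside a coding
    interval of its locus.  Every locus in the matrix must appear in the
    map (a locus with no coding interval is declared with an empty list).
    """
    loci = matrix.sites["locus"].to_numpy()
    absent = set(pd.unique(loci)) - set(locus_map.coding)
    if absent:
        raise KeyError(f"loci absent from locus map: {sorted(absent)[:5]}")
    pos = matrix.sites["pos"].to_numpy()
    coding_mask = np.array(
        [locus_map.is_coding(l, int(p)) for l, p in zip(loci, pos)], dtype=bool
    )
    return matrix.take_sites(coding_mask), matrix.take_sites(~coding_mask)


def downsample_depth(
    matrix: GenotypeMatrix, target_mean_depth: float, seed: int = 0
) -> GenotypeMatrix:
    """Thin each sample's depths to a target mean (binomial DP, hypergeometric AD).

    Samples whose mean depth is at or below the target are untouched.
    Genotypes whose thinned DP falls below 1 are set missing.
    """
    if target_mean_depth <= 0:
        raise ValueError("target depth must be positive")
    m = matrix.copy()
    rng = np.random.default_rng([seed, 0xD5])
    for j in range(m.n_samples):
        dpj = m.dp[:, j]
        have = dpj >= 0
        if not have.any():
            continue
        mean = dpj[have].mean()
        if mean <= target_mean_depth:
            continue
        p = target_mean_depth / mean
        new_dp = dpj.copy()
        new_dp[have] = rng.binomial(dpj[have], p)
        ad_ref = m.ad[:, j, 0]
        ad_alt = m.ad[:, j, 1]
        has_ad = have & (ad_ref >= 0) & (ad_alt >= 0)
        if has_ad.any():
            tot = ad_ref[has_ad] + ad_alt[has_ad]
            draw = np.minimum(new_dp[has_ad], tot)
            new_alt = rng.hypergeometric(
                ngood=ad_alt[has_ad], nbad=ad_ref[has_ad], nsample=draw
            )
            m.ad[has_ad, j, 1] = new_alt
            m.ad[has_ad, j, 0] = draw - new_alt
        dead = have & (new_dp < 1) & m.called[:, j]
        m.alleles[dead, j] = MISSING
        m.dp[:, j] = new_dp
    return m


def compute_missingness(matrix: GenotypeMatrix) -> float:
    """Missing genotype cells / total cells of the sample x site matrix."""
    if matrix.n_sites == 0 or matrix.n_samples == 0:
        raise ValueError("empty matrix")
    return float(matrix.missing_mask.mean())


# --------------------------------------------------------------------------
# probe-design utility
# --------------------------------------------------------------------------
def filter_candidate_targets(
    candidates: list[tuple[float, float]],
    min_length: float = 200,
    max_length: float = 400,
    min_gc: float = 0.30,
    max_gc: float = 0.70,
) -> list[tuple[float, float]]:
    """Keep (length_bp, gc_fraction) candidates inside inclusive bounds."""
    out = []
    for length, gc in candidates:
        if length <= 0:
            raise ValueError("lengths must be positive")
        if not 0.0 <= gc <= 1.0:
            raise ValueError("gc must be in [0, 1]")
        if min_length <= length <= max_length and min_gc <= gc <= max_gc:
            out.append((length, gc))
    return out
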