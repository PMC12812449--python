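"""Immune-locus selection scan: Fst outliers, trajectories, polymorphism.

Candidate (e.g. immune-related) SNPs are tested against a neutral baseline
built from non-coding SNPs: per-site Weir-Cockerham Fst is computed for
both sets under the same grouping, and a candidate is an outlier when its
Fst strictly exceeds baseline mean + 2 SD.  Allele-frequency trajectories
through time and per-species polymorphism/fixation summaries round out the
scan.

The grouping over which Fst is computed (species, localities, or time
points) is a required argument of every entry point — it is a study design
choice, not a package default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import weir_cockerham_fst
from .matrix import GenotypeMatrix

__all__ = [
    "OutlierReport",
    "PolymorphismSummary",
    "neutral_baseline",
    "fst_outliers",
    "fst_elevation_percent",
    "allele_trajectories",
    "polymorphism_summary",
    "polymorphism_table",
]

#: fewest baseline sites considered adequately powered
MIN_BASELINE_SITES = 30


@dataclass
class OutlierReport:
    baseline_mean: float
    baseline_sd: float
    threshold: float                      # mean + 2*SD
    site_fst: pd.DataFrame                # locus, pos, fst, outlier
    n_baseline_sites: int
    low_power: bool
    candidate_mean: float
    elevation_percent: float              # 100*(candidate - baseline)/baseline

    @property
    def n_outliers(self) -> int:
        return int(self.site_fst["outlier"].sum())


@dataclass
class PolymorphismSummary:
    """Pooled per-species allele-variation summary for candidate loci."""

    species: str
    sample_size: int
    total_snps: int
    polymorphic_snps: int
    percent_polymorphic: float            # 100*poly/total, 1 decimal
    per_locus_polymorphic: dict[str, int]
    percent_heterozygosity: float
    fixed_snps: int
    unique_alleles: int
    missing_alleles: int


# --------------------------------------------------------------------------
# neutral baseline and outliers
# --------------------------------------------------------------------------
def neutral_baseline(
    noncoding: GenotypeMatrix, populations: dict[str, np.ndarray]
) -> tuple[float, float]:
    """(mean, sample SD) of per-site W-C Fst over non-coding sites.

    Requires at least two informative sites; below ``MIN_BASELINE_SITES``
    defined sites a low-power warning is raised.
    """
    res = weir_cockerham_fst(noncoding, populations)
    vals = res.per_site[np.isfinite(res.per_site)]
    if len(vals) < 2:
        raise ValueError(
            f"insufficient baseline: {len(vals)} informative site(s), need >= 2"
        )
    if len(vals) < MIN_BASELINE_SITES:
        warnings.warn(
            f"baseline built from only {len(vals)} sites (<{MIN_BASELINE_SITES}); "
            "outlier threshold has low power"
        )
    return float(vals.mean()), float(vals.std(ddof=1))


def fst_outliers(
    candidates: GenotypeMatrix | pd.DataFrame,
    baseline: tuple[float, float],
    populations: dict[str, np.ndarray] | None = None,
    n_baseline_sites: int = MIN_BASELINE_SITES,
) -> OutlierReport:
    """Flag candidate sites with Fst strictly above baseline mean + 2 SD.

    ``candidates`` is either a genotype matrix (per-site Fst computed under
    ``populations``) or a ready-made frame with columns locus/pos/fst.
    """
    mean, sd = baseline
    threshold = mean + 2.0 * sd
    if isinstance(candidates, GenotypeMatrix):
        if populations is None:
            raise ValueError("populations required when candidates is a matrix")
        res = weir_cockerham_fst(candidates, populations)
        frame = candidates.sites[["locus", "pos"]].copy()
        frame["fst"] = res.per_site
    else:
        frame = candidates.copy()
    frame = frame[np.isfinite(frame["fst"].to_numpy())].reset_index(drop=True)
    frame["outlier"] = frame["fst"] > threshold
    cand_mean = float(frame["fst"].mean()) if len(frame) else float("nan")
    return OutlierReport(
        baseline_mean=mean,
        baseline_sd=sd,
        threshold=threshold,
        site_fst=frame,
        n_baseline_sites=n_baseline_sites,
        low_power=n_baseline_sites < MIN_BASELINE_SITES,
        candidate_mean=cand_mean,
        elevation_percent=fst_elevation_percent(mean, cand_mean),
    )


def fst_elevation_percent(baseline_mean: float, candidate_mean: float) -> float:
    """Percent elevation of candidate mean Fst over the neutral baseline."""
    if baseline_mean == 0:
        return float("nan")
    return 100.0 * (candidate_mean - baseline_mean) / baseline_mean


# --------------------------------------------------------------------------
# trajectories
# --------------------------------------------------------------------------
def allele_trajectories(
    matrix: GenotypeMatrix,
    meta: pd.DataFrame,
    group_columns: tuple[str, ...] = ("species", "site"),
    period_column: str = "time_period",
) -> pd.DataFrame:
    """Alternate-allele frequency per site x group x time period.

    Periods with zero called genotypes in a group are marked absent
    (``freq`` NaN, ``absent`` True) — absent is not zero.
    """
    meta = meta.set_index("sample").loc[matrix.samples].reset_index()
    periods = sorted(meta[period_column].unique())
    rows = []
    for group_key, sub in meta.groupby(list(group_columns), sort=True):
        if not isinstance(group_key, tuple):
            group_key = (group_key,)
        for period in periods:
            names = sub.loc[sub[period_column] == period, "sample"].tolist()
            mask = matrix.sample_mask(names)
            alt = matrix.alt_copies[:, mask].sum(axis=1)
            tot = matrix.called_copies[:, mask].sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                freq = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
            for i in range(matrix.n_sites):
                rows.append(
                    {
                        **dict(zip(group_columns, group_key)),
                        period_column: period,
                        "locus": matrix.sites["locus"].iat[i],
                        "pos": int(matrix.sites["pos"].iat[i]),
                        "freq": float(freq[i]) if tot[i] > 0 else float("nan"),
                        "absent": bool(tot[i] == 0),
                    }
                )
    return pd.DataFrame(rows)


def max_frequency_change(trajectories: pd.DataFrame) -> pd.DataFrame:
    """Largest |delta f| across time periods per site x group.

    Descriptive reconstruction of "large changes through time": sites are
    usually screened with a configurable cutoff (default 0.25) downstream.
    """
    def span(g):
        f = g["freq"].dropna()
        return f.max() - f.min() if len(f) >= 2 else np.nan

    keys = [c for c in trajectories.columns if c not in
            ("time_period", "freq", "absent", "locus", "pos")]
    out = (
        trajectories.groupby(keys + ["locus", "pos"], sort=True)
        .apply(span, include_groups=False)
        .rename("max_delta_freq")
        .reset_index()
    )
    return out


# --------------------------------------------------------------------------
# polymorphism summaries
# --------------------------------------------------------------------------
def percent_polymorphic(polymorphic: int, total: int) -> float:
    """100 * polymorphic / total, rounded to one decimal."""
    if total <= 0:
        raise ValueError("total must be positive")
    if polymorphic > total:
        raise ValueError("polymorphic cannot exceed total")
    return round(100.0 * polymorphic / total, 1)


def polymorphism_summary(
    matrix: GenotypeMatrix,
    meta: pd.DataFrame,
    locus_of_site: pd.Series | None = None,
    species_column: str = "species",
) -> list[PolymorphismSummary]:
    """Per-species pooled allele-variation summary over candidate SNPs.

    Pooling runs over all time points and sites ("fixed" means monomorphic
    within the species across everything).  Total SNPs are candidate sites
    with at least one called genotype in the species; unique/missing
    alleles are judged against the all-species allele union.
    """
    meta = meta.set_index("sample").loc[matrix.samples].reset_index()
    if locus_of_site is None:
        locus_of_site = matrix.sites["locus"]
    locus_of_site = pd.Series(np.asarray(locus_of_site))

    species_list = sorted(meta[species_column].unique())
    presence = {}
    for sp in species_list:
        mask = matrix.sample_mask(meta.loc[meta[species_column] == sp, "sample"])
        alt = matrix.alt_copies[:, mask].sum(axis=1)
        tot = matrix.called_copies[:, mask].sum(axis=1)
        presence[sp] = np.stack([(tot - alt) > 0, alt > 0], axis=1)  # ref, alt seen
    union = np.zeros((matrix.n_sites, 2), dtype=bool)
    n_species_with = np.zeros((matrix.n_sites, 2), dtype=int)
    for sp in species_list:
        union |= presence[sp]
        n_species_with += presence[sp].astype(int)

    out = []
    for sp in species_list:
        mask = matrix.sample_mask(meta.loc[meta[species_column] == sp, "sample"])
        pres = presence[sp]
        observed = pres.any(axis=1)
        poly = pres.all(axis=1)
        total = int(observed.sum())
        n_poly = int(poly.sum())
        per_locus = (
            pd.Series(locus_of_site[poly]).value_counts().sort_index().to_dict()
        )
        het = matrix.is_het[:, mask]
        both = matrix.called_copies[:, mask] == 2
        with np.errstate(invalid="ignore", divide="ignore"):
            het_frac = np.where(
                both.sum(axis=1) > 0,
                het.sum(axis=1) / np.maximum(both.sum(axis=1), 1),
                np.nan,
            )
        pct_het = (
            float(np.nanmean(het_frac[poly]) * 100.0) if n_poly else float("nan")
        )
        unique = int((pres & (n_species_with == 1)).sum())
        missing = int((union & ~pres).sum())
        out.append(
            PolymorphismSummary(
                species=sp,
                sample_size=int(mask.sum()),
                total_snps=total,
                polymorphic_snps=n_poly,
                percent_polymorphic=percent_polymorphic(n_poly, total)
                if total
                else float("nan"),
                per_locus_polymorphic={str(k): int(v) for k, v in per_locus.items()},
                percent_heterozygosity=pct_het,
                fixed_snps=total - n_poly,
                unique_alleles=unique,
                missing_alleles=missing,
            )
        )
    return out


def polymorphism_table(summaries: list[PolymorphismSummary]) -> pd.DataFrame:
    """Flatten summaries into a table (one row per species)."""
    loci = sorted({l for s in summaries for l in s.per_locus_polymorphic})
    rows = []
    for s in summaries:
        row = {
            "species": s.species,
            "sample_size": s.sample_size,
            "total_snps": s.total_snps,
            "polymorphic_snps": s.polymorphic_snps,
            "percent_polymorphic": s.percent_polymorphic,
            "percent_heterozygosity": s.percent_heterozygosity,
            "fixed_snps": s.fixed_snps,
            "unique_alleles": s.unique_alleles,
            "missing_alleles": s.missing_alleles,
        }
        for l in loci:
            row[l] = s.per_locus_polymorphic.get(l, 0)
        rows.append(row)
    return pd.DataFrame(rows)
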