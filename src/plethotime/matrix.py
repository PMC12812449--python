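"""Core genotype containers.

The substrate of every statistic in this package is a samples x biallelic-sites
genotype matrix with per-call depth (DP) and allele-depth (AD) annotations, as
parsed from a VCF, plus a sample metadata table mapping each specimen to its
species, collection site, time period, collection year, and tissue preparation.

Genotypes are stored as allele-index pairs so half-calls and multiallelic
records survive until the filter chain resolves them.  Helper accessors expose
the diploid 0/1/2 coding and per-chromosome allele counts that the statistics
modules consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

SITE_COLUMNS = ["locus", "pos", "ref", "alt", "qual"]

METADATA_COLUMNS = ["sample", "species", "site", "time_period", "year", "tissue"]


@dataclass
class GenotypeMatrix:
    """Samples x sites genotype matrix with depth/quality annotations.

    Parameters
    ----------
    samples
        Sample identifiers, in column order.
    sites
        One row per site with columns ``locus`` (str), ``pos`` (1-based int),
        ``ref``, ``alt`` (comma-joined if multiallelic) and ``qual``.
    alleles
        ``(n_sites, n_samples, 2)`` int8 array of allele indices
        (0 = REF, 1.. = ALT order), ``-1`` for an uncalled allele copy.
    dp
        ``(n_sites, n_samples)`` int32 read depth, ``-1`` where absent.
    ad
        ``(n_sites, n_samples, 2)`` int32 ref/alt allele depths, ``-1`` where
        absent.  Only the first ALT is tracked; multiallelic records carry
        ``-1`` and are dropped by the biallelic filter before AD is used.
    """

    samples: list[str]
    sites: pd.DataFrame
    alleles: np.ndarray
    dp: np.ndarray
    ad: np.ndarray

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        n_sites, n_samples = len(self.sites), len(self.samples)
        if self.alleles.shape != (n_sites, n_samples, 2):
            raise ValueError(
                f"alleles shape {self.alleles.shape} != {(n_sites, n_samples, 2)}"
            )
        if self.dp.shape != (n_sites, n_samples):
            raise ValueError("dp shape mismatch")
        if self.ad.shape != (n_sites, n_samples, 2):
            raise ValueError("ad shape mismatch")
        dup = self.sites.duplicated(subset=["locus", "pos"])
        if dup.any():
            raise ValueError("duplicate locus/pos site records")

    # ------------------------------------------------------------------ shape
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    # ------------------------------------------------------------- accessors
    @property
    def called(self) -> np.ndarray:
        """Boolean (sites, samples): at least one allele copy called."""
        return (self.alleles >= 0).any(axis=2)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (sites, samples): genotype entirely uncalled."""
        return ~self.called

    @property
    def called_copies(self) -> np.ndarray:
        """Int (sites, samples): number of called allele copies (0, 1 or 2)."""
        return (self.alleles >= 0).sum(axis=2).astype(np.int32)

    @property
    def alt_copies(self) -> np.ndarray:
        """Int (sites, samples): called copies equal to the first ALT."""
        return (self.alleles == 1).sum(axis=2).astype(np.int32)

    @property
    def is_het(self) -> np.ndarray:
        """Boolean (sites, samples): both copies called and unequal."""
        both = (self.alleles >= 0).all(axis=2)
        return both & (self.alleles[:, :, 0] != self.alleles[:, :, 1])

    @property
    def gt012(self) -> np.ndarray:
        """Diploid genotype codes: 0/1/2 alt-allele dosage, -1 otherwise.

        Half-calls and genotypes carrying an allele index > 1 code as -1;
        use :attr:`alt_copies`/:attr:`called_copies` for chromosome-level
        counting that retains half-calls.
        """
        out = np.full((self.n_sites, self.n_samples), MISSING, dtype=np.int8)
        both = (self.alleles >= 0).all(axis=2) & (self.alleles <= 1).all(axis=2)
        dosage = self.alleles.clip(min=0).sum(axis=2)
        out[both] = dosage[both].astype(np.int8)
        return out

    # ----------------------------------------------------------- site typing
    @property
    def is_snp(self) -> np.ndarray:
        """Biallelic single-nucleotide sites."""
        bases = {"A", "C", "G", "T"}
        ref = self.sites["ref"].to_numpy()
        alt = self.sites["alt"].to_numpy()
        out = np.zeros(self.n_sites, dtype=bool)
        for i, (r, a) in enumerate(zip(ref, alt)):
            alts = str(a).split(",")
            out[i] = (
                len(alts) == 1
                and str(r) in bases
                and alts[0] in bases
                and str(r) != alts[0]
            )
        return out

    @property
    def is_indel(self) -> np.ndarray:
        """Sites where REF or any ALT is not a single base."""
        ref = self.sites["ref"].to_numpy()
        alt = self.sites["alt"].to_numpy()
        out = np.zeros(self.n_sites, dtype=bool)
        for i, (r, a) in enumerate(zip(ref, alt)):
            alts = str(a).split(",")
            out[i] = len(str(r)) != 1 or any(len(x) != 1 for x in alts)
        return out

    # ------------------------------------------------------------ subsetting
    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=self.sites.iloc[index],
            alleles=self.alleles[index],
            dp=self.dp[index],
            ad=self.ad[index],
        )

    def take_samples(self, which) -> "GenotypeMatrix":
        """Subset by sample names or integer/boolean index."""
        arr = np.asarray(which)
        if arr.dtype.kind in "US":
            lookup = {s: i for i, s in enumerate(self.samples)}
            idx = np.array([lookup[s] for s in which], dtype=int)
        elif arr.dtype == bool:
            idx = np.flatnonzero(arr)
        else:
            idx = arr.astype(int)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            sites=self.sites,
            alleles=self.alleles[:, idx],
            dp=self.dp[:, idx],
            ad=self.ad[:, idx],
        )

    def sample_mask(self, names) -> np.ndarray:
        """Boolean mask over columns for the given sample names."""
        wanted = set(names)
        return np.array([s in wanted for s in self.samples], dtype=bool)

    # --------------------------------------------------------------- algebra
    def concat_sites(self, other: "GenotypeMatrix") -> "GenotypeMatrix":
        if list(other.samples) != list(self.samples):
            raise ValueError("sample sets differ")
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=pd.concat([self.sites, other.sites], ignore_index=True),
            alleles=np.concatenate([self.alleles, other.alleles]),
            dp=np.concatenate([self.dp, other.dp]),
            ad=np.concatenate([self.ad, other.ad]),
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=self.sites.copy(),
            alleles=self.alleles.copy(),
            dp=self.dp.copy(),
            ad=self.ad.copy(),
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            list(self.samples) == list(other.samples)
            and self.sites[SITE_COLUMNS].equals(other.sites[SITE_COLUMNS])
            and np.array_equal(self.alleles, other.alleles)
            and np.array_equal(self.dp, other.dp)
            and np.array_equal(self.ad, other.ad)
        )


def matrix_from_gt012(
    samples: list[str],
    sites: pd.DataFrame,
    gt: np.ndarray,
    dp: np.ndarray | None = None,
    ad: np.ndarray | None = None,
) -> GenotypeMatrix:
    """Build a biallelic matrix from 0/1/2/-1 genotype codes.

    Convenience constructor used by the simulator and test fixtures.
    """
    gt = np.asarray(gt)
    n_sites, n_samples = gt.shape
    alleles = np.zeros((n_sites, n_samples, 2), dtype=np.int8)
    alleles[gt == 1, 1] = 1
    alleles[gt == 2] = 1
    alleles[gt == MISSING] = MISSING
    if dp is None:
        dp = np.full((n_sites, n_samples), MISSING, dtype=np.int32)
    if ad is None:
        ad = np.full((n_sites, n_samples, 2), MISSING, dtype=np.int32)
    return GenotypeMatrix(
        samples=list(samples),
        sites=sites,
        alleles=alleles,
        dp=np.asarray(dp, dtype=np.int32),
        ad=np.asarray(ad, dtype=np.int32),
    )


def load_metadata(path) -> pd.DataFrame:
    """Read the tab-separated sample metadata table."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample": str})
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False, columns=METADATA_COLUMNS)


def population_labels(meta: pd.DataFrame, columns=("species", "site", "time_period")) -> pd.Series:
    """Compose per-sample population labels from metadata columns."""
    parts = [meta[c].astype(str) for c in columns]
    out = parts[0]
    for p in parts[1:]:
        out = out + "|" + p
    out.index = meta["sample"].to_numpy()
    return out
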