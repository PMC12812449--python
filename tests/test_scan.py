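"""Fst outlier scan, trajectories and polymorphism summaries."""

import numpy as np
import pandas as pd
import pytest

from plethotime.matrix import matrix_from_gt012
from plethotime.scan import (
    allele_trajectories,
    fst_elevation_percent,
    fst_outliers,
    neutral_baseline,
    percent_polymorphic,
    polymorphism_summary,
    polymorphism_table,
)

from _oracles import wc_fst_matrix
from conftest import make_matrix, make_sites, random_gt


def _meta(samples, species, periods, site="S1"):
    return pd.DataFrame(
        {
            "sample": samples,
            "species": species,
            "site": site,
            "time_period": periods,
            "year": 2000,
            "tissue": "modern_liver",
        }
    )


# --------------------------------------------------------------------------
# baseline
# --------------------------------------------------------------------------
def test_baseline_of_constant_fst_sites_has_zero_sd():
    # two populations fixed for alternate alleles at every site -> Fst 1
    gt = np.concatenate(
        [np.zeros((40, 8), dtype=np.int8), np.full((40, 8), 2, dtype=np.int8)], axis=1
    )
    m = make_matrix(gt)
    pops = {"a": np.arange(16) < 8, "b": np.arange(16) >= 8}
    mean, sd = neutral_baseline(m, pops)
    assert mean == pytest.approx(1.0)
    assert sd == pytest.approx(0.0)


def test_baseline_requires_informative_sites_and_warns_when_few():
    gt = np.zeros((1, 8), dtype=np.int8)   # monomorphic: no informative site
    m = make_matrix(gt)
    pops = {"a": np.arange(8) < 4, "b": np.arange(8) >= 4}
    with pytest.raises(ValueError, match="insufficient baseline"):
        neutral_baseline(m, pops)
    gt = random_gt(np.random.default_rng(0), 5, 8)
    with pytest.warns(UserWarning, match="low power"):
        neutral_baseline(make_matrix(gt), pops)


def test_baseline_matches_brute_force_oracle_on_two_demes():
    rng = np.random.default_rng(8)
    p1 = rng.uniform(0.1, 0.9, size=120)
    p2 = np.clip(p1 + rng.normal(0, 0.25, size=120), 0.02, 0.98)
    gt = np.concatenate(
        [
            rng.binomial(2, p1[:, None], size=(120, 12)),
            rng.binomial(2, p2[:, None], size=(120, 12)),
        ],
        axis=1,
    ).astype(np.int8)
    m = make_matrix(gt)
    pops = {"a": np.arange(24) < 12, "b": np.arange(24) >= 12}
    mean, sd = neutral_baseline(m, pops)
    oracle = wc_fst_matrix({"a": gt[:, :12], "b": gt[:, 12:]})
    oracle = oracle[np.isfinite(oracle)]
    assert mean == pytest.approx(float(oracle.mean()), abs=1e-10)
    assert sd == pytest.approx(float(oracle.std(ddof=1)), abs=1e-10)


# --------------------------------------------------------------------------
# outliers
# --------------------------------------------------------------------------
def test_outlier_threshold_is_strict_two_sd():
    frame = pd.DataFrame(
        {"locus": "L", "pos": [1, 2, 3], "fst": [0.55, 0.50, 0.49]}
    )
    report = fst_outliers(frame, baseline=(0.3, 0.1))
    assert report.threshold == pytest.approx(0.5)
    assert report.site_fst["outlier"].tolist() == [True, False, False]


def test_null_outlier_rate_matches_normal_tail():
    rng = np.random.default_rng(17)
    n = 10_000
    baseline_sites = rng.normal(0.3, 0.08, size=n)
    baseline = (float(baseline_sites.mean()), float(baseline_sites.std(ddof=1)))
    candidates = pd.DataFrame(
        {"locus": "L", "pos": np.arange(n), "fst": rng.normal(0.3, 0.08, size=n)}
    )
    report = fst_outliers(candidates, baseline)
    rate = report.n_outliers / n
    expected = 0.02275
    se = np.sqrt(expected * (1 - expected) / n)
    assert abs(rate - expected) <= 3 * se


def test_elevation_percent_matches_reported_rounding():
    assert round(fst_elevation_percent(0.345, 0.462)) == 34


# --------------------------------------------------------------------------
# trajectories
# --------------------------------------------------------------------------
def test_trajectories_distinguish_absent_from_zero():
    samples = [f"s{j}" for j in range(6)]
    gt = np.array([[1, 1, 1, -1, -1, 0]], dtype=np.int8)
    m = matrix_from_gt012(samples, make_sites(1), gt)
    meta = _meta(samples, ["sp"] * 6, ["T1", "T1", "T1", "T2", "T2", "T3"])
    traj = allele_trajectories(m, meta, group_columns=("species",))
    t1 = traj[traj.time_period == "T1"].iloc[0]
    t2 = traj[traj.time_period == "T2"].iloc[0]
    t3 = traj[traj.time_period == "T3"].iloc[0]
    assert t1.freq == pytest.approx(0.5)      # all het group
    assert t2.absent and np.isnan(t2.freq)    # fully missing: absent, not 0
    assert not t3.absent and t3.freq == 0.0


def test_trajectories_invariant_to_allele_relabelling():
    rng = np.random.default_rng(5)
    samples = [f"s{j}" for j in range(8)]
    gt = random_gt(rng, 10, 8)
    meta = _meta(samples, ["sp"] * 8, ["T1"] * 4 + ["T2"] * 4)
    m = matrix_from_gt012(samples, make_sites(10), gt)
    swapped = matrix_from_gt012(samples, make_sites(10), 2 - gt)
    a = allele_trajectories(m, meta, group_columns=("species",))
    b = allele_trajectories(swapped, meta, group_columns=("species",))
    assert np.allclose(a["freq"], 1.0 - b["freq"], equal_nan=True)


# --------------------------------------------------------------------------
# polymorphism summaries
# --------------------------------------------------------------------------
def test_percent_polymorphic_reported_values():
    assert percent_polymorphic(6, 37) == 16.2
    assert percent_polymorphic(24, 49) == 49.0
    assert percent_polymorphic(5, 32) == 15.6
    with pytest.raises(ValueError):
        percent_polymorphic(5, 0)


def _candidate_fixture():
    """Two species over three loci with controlled polymorphism."""
    rng = np.random.default_rng(2)
    samples = [f"a{j}" for j in range(6)] + [f"b{j}" for j in range(6)]
    sites = pd.concat(
        [
            make_sites(4, locus="CXCR4"),
            make_sites(3, locus="ILF2"),
            make_sites(2, locus="ILF3"),
        ],
        ignore_index=True,
    )
    gt = np.zeros((9, 12), dtype=np.int8)
    # species A polymorphic at sites 0,1 (CXCR4) and 4 (ILF2)
    gt[0, :3] = 1
    gt[1, 1:3] = 1
    gt[4, 0] = 2
    # species B polymorphic at site 8 (ILF3); site 8 alt absent in A
    gt[8, 6:9] = 1
    # site 2 observed in B only (A all missing) and monomorphic alt
    gt[2, :6] = -1
    gt[2, 6:] = 2
    m = matrix_from_gt012(samples, sites, gt)
    meta = _meta(samples, ["A"] * 6 + ["B"] * 6, ["T1"] * 12)
    return m, meta


def test_polymorphism_summary_counts_and_per_locus_consistency():
    m, meta = _candidate_fixture()
    summaries = {s.species: s for s in polymorphism_summary(m, meta)}
    a, b = summaries["A"], summaries["B"]
    assert a.total_snps == 8            # site 2 unobserved in A
    assert a.polymorphic_snps == 3
    assert a.percent_polymorphic == percent_polymorphic(3, 8)
    assert a.per_locus_polymorphic == {"CXCR4": 2, "ILF2": 1}
    assert sum(a.per_locus_polymorphic.values()) == a.polymorphic_snps
    assert a.fixed_snps == 5
    assert b.total_snps == 9
    assert b.per_locus_polymorphic == {"ILF3": 1}
    # allele bookkeeping: site-2 alt + site-8 alt seen only in B; A holds no
    # allele B lacks except via shared sites
    assert b.unique_alleles >= 2
    assert a.missing_alleles >= 2


def test_single_species_alleles_all_unique_none_missing():
    rng = np.random.default_rng(4)
    samples = [f"s{j}" for j in range(5)]
    gt = random_gt(rng, 12, 5)
    m = matrix_from_gt012(samples, make_sites(12), gt)
    meta = _meta(samples, ["only"] * 5, ["T1"] * 5)
    (summary,) = polymorphism_summary(m, meta)
    observed_alleles = int(
        sum(
            ((gt[i][gt[i] >= 0].sum() < 2 * (gt[i] >= 0).sum()) and 1 or 0)
            + ((gt[i][gt[i] >= 0].sum() > 0) and 1 or 0)
            for i in range(12)
        )
    )
    assert summary.unique_alleles == observed_alleles
    assert summary.missing_alleles == 0
    table = polymorphism_table([summary])
    assert table.loc[0, "species"] == "only"
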