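"""Diversity statistics against brute-force and textbook oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plethotime.diversity import (
    harmonic_a1,
    heterozygosity,
    mean_pi,
    private_alleles,
    site_pi,
    sliding_windows,
    tajimas_d,
    watterson_theta,
    weir_cockerham_fst,
)

from _oracles import (
    pi_brute_force,
    private_allele_sets,
    tajimas_d_textbook,
    wc_fst_matrix,
)
from conftest import make_matrix, random_gt


# --------------------------------------------------------------------------
# site pi
# --------------------------------------------------------------------------
@pytest.mark.parametrize(
    "minor,total,expected",
    [
        (0, 10, 0.0),                  # monomorphic
        (3, 8, 15 / 28),               # 3*5 unequal pairs of C(8,2)
        (1, 2, 1.0),                   # the single pair differs
    ],
)
def test_site_pi_examples(minor, total, expected):
    assert site_pi(minor, total) == pytest.approx(expected, abs=1e-12)


def test_site_pi_undefined_below_two_chromosomes():
    assert np.isnan(site_pi(0, 1))


@given(
    total=st.integers(min_value=2, max_value=12),
    data=st.data(),
)
@settings(max_examples=100, derandomize=True)
def test_site_pi_equals_exhaustive_pairwise_differences(total, data):
    minor = data.draw(st.integers(min_value=0, max_value=total))
    chroms = [1] * minor + [0] * (total - minor)
    assert site_pi(minor, total) == pytest.approx(
        pi_brute_force(chroms), abs=1e-12
    )


def test_mean_pi_averages_variant_sites():
    # site 0: one alt copy of 4 chromosomes -> pi = 1*3 / C(4,2) = 0.5
    # site 1: monomorphic -> 0; mean = 0.25
    gt = np.array(
        [
            [1, 0],   # alt count 1 of 4 chroms -> pi = 1*3/6 = 0.5
            [0, 0],   # monomorphic -> 0
        ],
        dtype=np.int8,
    )
    m = make_matrix(gt)
    est = mean_pi(m)
    assert est.pi == pytest.approx(0.25)
    assert est.n_sites_used == 2


def test_mean_pi_all_missing_population_is_nan():
    m = make_matrix(np.full((3, 4), -1, dtype=np.int8))
    with pytest.warns(UserWarning):
        est = mean_pi(m)
    assert np.isnan(est.pi)


# --------------------------------------------------------------------------
# heterozygosity
# --------------------------------------------------------------------------
def test_heterozygosity_all_homozygous():
    m = make_matrix(np.array([[0, 2, 0, 2]], dtype=np.int8))
    h_obs, h_exp = heterozygosity(m)
    assert h_obs == 0.0
    assert h_exp == pytest.approx(0.5)  # p = 0.5 across chromosomes


def test_heterozygosity_all_het_site():
    m = make_matrix(np.ones((1, 4), dtype=np.int8))
    h_obs, h_exp = heterozygosity(m)
    assert h_obs == 1.0
    assert h_exp == pytest.approx(0.5)


def test_heterozygosity_matches_hwe_simulation():
    rng = np.random.default_rng(7)
    gt = rng.binomial(2, 0.3, size=(200, 500)).astype(np.int8)
    m = make_matrix(gt)
    h_obs, h_exp = heterozygosity(m)
    # E = 2*0.3*0.7 = 0.42; SE of the mean over 200x500 draws is tiny
    assert h_obs == pytest.approx(0.42, abs=0.01)
    assert h_exp == pytest.approx(0.42, abs=0.01)


# --------------------------------------------------------------------------
# private alleles
# --------------------------------------------------------------------------
def test_private_alleles_trivial_membership():
    # site 0: alt only in A; site 1: alt in both A and B
    gt = np.array(
        [
            [1, 1, 0, 0],
            [1, 1, 1, 1],
        ],
        dtype=np.int8,
    )
    m = make_matrix(gt)
    pops = {
        "A": np.array([True, True, False, False]),
        "B": np.array([False, False, True, True]),
    }
    counts = private_alleles(m, pops)
    assert counts["A"] == 1          # the site-0 alt allele
    assert counts["B"] == 0


def test_private_alleles_agree_with_membership_set_oracle():
    rng = np.random.default_rng(3)
    gt = random_gt(rng, 40, 18, p_missing=0.1)
    m = make_matrix(gt)
    masks = {
        "A": np.zeros(18, dtype=bool),
        "B": np.zeros(18, dtype=bool),
        "C": np.zeros(18, dtype=bool),
    }
    masks["A"][:6] = True
    masks["B"][6:12] = True
    masks["C"][12:] = True
    expected = private_allele_sets(
        {k: gt[:, v] for k, v in masks.items()}
    )
    assert private_alleles(m, masks) == expected


# --------------------------------------------------------------------------
# Watterson's theta and Tajima's D
# --------------------------------------------------------------------------
def test_watterson_examples():
    assert watterson_theta(0, 8, 150) == 0.0
    a1 = sum(1.0 / i for i in range(1, 8))
    assert watterson_theta(3, 8, 150) == pytest.approx(3 / (a1 * 150))
    assert watterson_theta(1, 2, 1) == 1.0


def test_tajimas_d_zero_when_pi_equals_watterson():
    S, n = 7, 12
    assert tajimas_d(S, S / harmonic_a1(n), n) == pytest.approx(0.0, abs=1e-12)


def test_tajimas_d_undefined_cases():
    assert np.isnan(tajimas_d(0, 0.0, 10))
    assert np.isnan(tajimas_d(3, 1.0, 3))


def test_tajimas_d_matches_textbook_oracle():
    rng = np.random.default_rng(5)
    assert tajimas_d(5, 4.0, 10) == pytest.approx(
        tajimas_d_textbook(5, 4.0, 10), abs=1e-12
    )
    for _ in range(100):
        n = int(rng.integers(4, 60))
        S = int(rng.integers(1, 40))
        pi_total = float(rng.uniform(0, 2 * S))
        assert tajimas_d(S, pi_total, n) == pytest.approx(
            tajimas_d_textbook(S, pi_total, n), abs=1e-10
        )


# --------------------------------------------------------------------------
# windows
# --------------------------------------------------------------------------
def test_windows_tile_a_710bp_locus_into_five():
    rng = np.random.default_rng(1)
    gt = random_gt(rng, 30, 10)
    m = make_matrix(gt)
    m.sites["pos"] = np.linspace(5, 700, 30).astype(int)
    wins = sliding_windows(m, size=150, locus_lengths={"locusA": 710})
    assert len(wins) == 5
    assert [w.length for w in wins] == [150, 150, 150, 150, 110]
    # per-window S sums to locus S at step == size
    alt = m.alt_copies.sum(axis=1)
    tot = m.called_copies.sum(axis=1)
    locus_S = int(((alt > 0) & (alt < tot)).sum())
    assert sum(w.S for w in wins) == locus_S


def test_empty_window_has_zero_theta_and_nan_d():
    gt = np.array([[1, 0, 1]], dtype=np.int8)
    m = make_matrix(gt)
    m.sites["pos"] = [10]
    wins = sliding_windows(m, size=150, locus_lengths={"locusA": 300})
    assert wins[1].S == 0
    assert wins[1].theta_w == 0.0
    assert np.isnan(wins[1].tajimas_d)


# --------------------------------------------------------------------------
# Weir-Cockerham Fst
# --------------------------------------------------------------------------
def _two_pop_masks(n1, n2):
    m1 = np.zeros(n1 + n2, dtype=bool)
    m1[:n1] = True
    return {"p1": m1, "p2": ~m1}


def test_fst_complete_differentiation_is_one():
    gt = np.concatenate(
        [np.zeros((5, 10), dtype=np.int8), np.full((5, 10), 2, dtype=np.int8)],
        axis=1,
    )
    m = make_matrix(gt)
    res = weir_cockerham_fst(m, _two_pop_masks(10, 10))
    assert np.allclose(res.per_site, 1.0)
    assert res.mean_of_ratios == pytest.approx(1.0)


def test_fst_identical_populations_near_zero():
    rng = np.random.default_rng(21)
    means = []
    for _ in range(20):
        p = rng.uniform(0.2, 0.8, size=50)
        gt = rng.binomial(2, p[:, None], size=(50, 40)).astype(np.int8)
        res = weir_cockerham_fst(make_matrix(gt), _two_pop_masks(20, 20))
        means.append(res.mean_of_ratios)
    assert abs(np.mean(means)) <= 0.05


def test_fst_matches_variance_components_oracle():
    rng = np.random.default_rng(9)
    for _ in range(100):
        n1, n2 = rng.integers(4, 12, size=2)
        p1, p2 = rng.uniform(0.1, 0.9, size=2)
        gt = np.concatenate(
            [
                rng.binomial(2, p1, size=(12, n1)),
                rng.binomial(2, p2, size=(12, n2)),
            ],
            axis=1,
        ).astype(np.int8)
        gt[rng.random(gt.shape) < 0.05] = -1
        m = make_matrix(gt)
        masks = _two_pop_masks(n1, n2)
        res = weir_cockerham_fst(m, masks)
        oracle = wc_fst_matrix({k: gt[:, v] for k, v in masks.items()})
        both = np.isfinite(res.per_site) & np.isfinite(oracle)
        assert np.isfinite(res.per_site).tolist() == np.isfinite(oracle).tolist()
        assert np.allclose(res.per_site[both], oracle[both], atol=1e-10)
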