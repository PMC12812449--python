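"""VCF round trips and the SNP filter chain."""

import numpy as np
import pandas as pd
import pytest

from plethotime.matrix import matrix_from_gt012
from plethotime.variants import (
    FilterConfig,
    LocusMap,
    apply_site_filters,
    compute_missingness,
    downsample_depth,
    filter_candidate_targets,
    partition_coding_noncoding,
    prune_indel_proximity,
    read_bed,
    read_vcf,
    thin_one_snp_per_locus,
    write_vcf,
)

from conftest import make_matrix, make_sites, random_gt


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------
def test_round_trip_identity_on_simulated_output(small_dataset, tmp_path):
    m = small_dataset["matrix"]
    again = read_vcf(small_dataset["vcf"])
    assert m.equals(again)
    write_vcf(again, tmp_path / "again.vcf", contig_lengths=small_dataset["lengths"])
    assert (
        open(small_dataset["vcf"]).read() == open(tmp_path / "again.vcf").read()
    )


def test_hand_written_vcf_dimensions_and_ad_warning(tmp_path):
    text = "\n".join(
        [
            "##fileformat=VCFv4.2",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb",
            "chr1\t5\t.\tA\tG\t50\tPASS\t.\tGT\t0/1\t1/1",
            "chr1\t9\t.\tC\tT\t50\tPASS\t.\tGT\t0/0\t./.",
            "chr2\t3\t.\tG\tA,C\t50\tPASS\t.\tGT\t1/2\t0/1",
        ]
    )
    path = tmp_path / "hand.vcf"
    path.write_text(text + "\n")
    with pytest.warns(UserWarning, match="allele-balance"):
        m = read_vcf(path)
    assert (m.n_sites, m.n_samples) == (3, 2)
    assert m.missing_mask[1, 1]
    # multiallelic record preserved until filtering
    assert m.sites.loc[2, "alt"] == "A,C"
    filtered, report = apply_site_filters(m, FilterConfig(min_mac=0, max_maf_excluded=0.0))
    assert report.removed["non_biallelic_snp"] == 1
    assert "allele-balance" in " ".join(report.warnings)


# --------------------------------------------------------------------------
# indel proximity
# --------------------------------------------------------------------------
def test_indel_proximity_boundaries():
    sites = pd.DataFrame(
        {
            "locus": "L",
            "pos": [100, 103, 200, 204, 50, 52, 54],
            "ref": ["A", "AT", "A", "ATT", "AC", "G", "CT"],
            "alt": ["G", "A", "G", "A", "A", "A", "C"],
            "qual": 60.0,
        }
    )
    is_indel = np.array([False, True, False, True, True, False, True])
    keep = prune_indel_proximity(sites, is_indel)
    assert not keep[0]      # |100-103| = 3 -> removed
    assert keep[2]          # |200-204| = 4 -> kept
    assert not keep[5]      # SNP at 52 inside the 50/54 indel cluster


# --------------------------------------------------------------------------
# filter chain
# --------------------------------------------------------------------------
def test_mac_filter_beats_maf_at_the_boundary():
    # 2 minor copies among 100 called: MAF 0.02 > 0.015 but MAC 2 < 3
    gt = np.zeros((1, 50), dtype=np.int8)
    gt[0, 0] = 1
    gt[0, 1] = 1
    m = make_matrix(gt)
    _, report = apply_site_filters(m)
    assert report.removed["mac"] == 1
    assert report.sites_out == 0


def test_allele_balance_masks_het_and_can_drop_site():
    gt = np.array([[1, 1, 0, -1]], dtype=np.int8)
    dp = np.full((1, 4), 20, dtype=np.int32)
    ad = np.zeros((1, 4, 2), dtype=np.int32)
    ad[0, 0] = (2, 8)    # balance 0.8 -> outside (0.25, 0.75): masked
    ad[0, 1] = (10, 10)  # balanced het: kept
    ad[0, 2] = (20, 0)
    ad[0, 3] = (-1, -1)
    m = matrix_from_gt012(["a", "b", "c", "d"], make_sites(1), gt, dp=dp, ad=ad)
    config = FilterConfig(min_mac=0, max_maf_excluded=0.0, min_presence_fraction=0.75)
    filtered, report = apply_site_filters(m, config)
    assert report.genotypes_masked_balance == 1
    # presence after masking: 2 of 4 called < 0.75 -> site removed
    assert report.removed["presence"] == 1
    assert filtered.n_sites == 0


def test_all_passing_matrix_is_untouched():
    rng = np.random.default_rng(0)
    gt = random_gt(rng, 20, 30)
    dp = np.full((20, 30), 30, dtype=np.int32)
    ad = np.zeros((20, 30, 2), dtype=np.int32)
    alt = np.where(gt == 1, 15, np.where(gt == 2, 30, 0))
    ad[:, :, 1] = alt
    ad[:, :, 0] = 30 - alt
    m = matrix_from_gt012([f"s{j}" for j in range(30)], make_sites(20), gt, dp=dp, ad=ad)
    filtered, report = apply_site_filters(m)
    assert all(v == 0 for v in report.removed.values())
    assert filtered.equals(m)


def test_filter_chain_is_idempotent(small_dataset):
    m = read_vcf(small_dataset["vcf"])
    once, r1 = apply_site_filters(m)
    twice, r2 = apply_site_filters(once)
    assert once.equals(twice)
    assert r1.check_balance() and r2.check_balance()


def test_low_qual_sites_removed(small_truth):
    from plethotime.simulate import ArtifactModel, apply_archival_artifacts, default_tissue_assignment

    model = ArtifactModel(qual_error_fraction=0.3)
    m = apply_archival_artifacts(small_truth, model, default_tissue_assignment(small_truth))
    _, report = apply_site_filters(m)
    assert report.removed["qual"] > 0
    assert report.removed["qual"] == int((m.sites["qual"] < 30).sum())


# --------------------------------------------------------------------------
# thinning
# --------------------------------------------------------------------------
def test_thinning_keeps_one_site_per_locus_and_depends_on_seed():
    rng = np.random.default_rng(1)
    frames = []
    gts = []
    for i in range(100):
        s = make_sites(5, locus=f"L{i:03d}")
        frames.append(s)
        gts.append(random_gt(rng, 5, 8))
    sites = pd.concat(frames, ignore_index=True)
    m = matrix_from_gt012([f"s{j}" for j in range(8)], sites, np.concatenate(gts))
    t1 = thin_one_snp_per_locus(m, seed=1)
    t2 = thin_one_snp_per_locus(m, seed=2)
    assert t1.n_sites == t2.n_sites == 100
    assert t1.sites["locus"].is_unique and t2.sites["locus"].is_unique
    assert not t1.sites["pos"].equals(t2.sites["pos"])
    # determinism per seed
    assert thin_one_snp_per_locus(m, seed=1).sites["pos"].equals(t1.sites["pos"])


def test_thinning_choice_is_uniform_over_sites():
    gt = random_gt(np.random.default_rng(0), 5, 6)
    m = matrix_from_gt012([f"s{j}" for j in range(6)], make_sites(5), gt)
    picks = np.zeros(5)
    n_seeds = 2000
    for seed in range(n_seeds):
        pos = thin_one_snp_per_locus(m, seed).sites["pos"].iloc[0]
        picks[pos - 1] += 1
    expected = n_seeds / 5
    se = np.sqrt(n_seeds * 0.2 * 0.8)
    assert np.all(np.abs(picks - expected) <= 3 * se)


# --------------------------------------------------------------------------
# partitioning
# --------------------------------------------------------------------------
def test_partition_respects_bed_half_open_convention():
    gt = random_gt(np.random.default_rng(2), 4, 6)
    m = matrix_from_gt012([f"s{j}" for j in range(6)], make_sites(4), gt)
    m.sites["pos"] = [155, 156, 555, 556]
    lm = LocusMap(coding={"locusA": [(155, 555)]}, lengths={"locusA": 710})
    coding, noncoding = partition_coding_noncoding(m, lm)
    assert coding.sites["pos"].tolist() == [156, 555]
    assert noncoding.sites["pos"].tolist() == [155, 556]
    merged = pd.concat([coding.sites, noncoding.sites])
    assert sorted(merged["pos"]) == [155, 156, 555, 556]


def test_partition_with_no_coding_interval_is_all_noncoding():
    gt = random_gt(np.random.default_rng(3), 3, 4)
    m = matrix_from_gt012([f"s{j}" for j in range(4)], make_sites(3), gt)
    lm = LocusMap(coding={"locusA": []}, lengths={})
    coding, noncoding = partition_coding_noncoding(m, lm)
    assert coding.n_sites == 0 and noncoding.n_sites == 3
    with pytest.raises(KeyError):
        partition_coding_noncoding(m, LocusMap(coding={"other": []}, lengths={}))


def test_bed_round_trip(tmp_path):
    from plethotime.simulate import central_coding_bed

    bed = central_coding_bed({"L1": 710, "L2": 300}, coding_span_bp=400)
    assert bed.loc[bed.chrom == "L1", ["start", "end"]].values.tolist() == [[155, 555]]
    path = tmp_path / "c.bed"
    bed.to_csv(path, sep="\t", header=False, index=False)
    lm = read_bed(path, {"L1": 710, "L2": 300})
    assert lm.coding["L1"] == [(155, 555)]
    assert not lm.is_coding("L1", 155)   # POS 155 -> 0-based 154 -> flank
    assert lm.is_coding("L1", 156)


# --------------------------------------------------------------------------
# downsampling and missingness
# --------------------------------------------------------------------------
def test_downsampling_halves_a_deep_sample():
    rng = np.random.default_rng(4)
    n_sites = 1000
    gt = random_gt(rng, n_sites, 2)
    dp = np.full((n_sites, 2), 48, dtype=np.int32)
    dp[:, 1] = 10                       # below target: untouched
    ad = np.zeros((n_sites, 2, 2), dtype=np.int32)
    alt = np.where(gt == 1, 24, np.where(gt == 2, dp, 0))
    ad[:, :, 1] = alt
    ad[:, :, 0] = dp - alt
    m = matrix_from_gt012(["deep", "shallow"], make_sites(n_sites), gt, dp=dp, ad=ad)
    ds = downsample_depth(m, 24.0, seed=0)
    assert abs(ds.dp[:, 0].mean() - 24.0) < 1.0
    assert np.array_equal(ds.dp[:, 1], m.dp[:, 1])
    assert np.array_equal(ds.ad[:, 1], m.ad[:, 1])
    # AD still sums to DP where drawn
    tot = ds.ad[:, 0, 0] + ds.ad[:, 0, 1]
    assert np.all(tot <= ds.dp[:, 0])
    with pytest.raises(ValueError):
        downsample_depth(m, 0)


@pytest.mark.parametrize(
    "gt,expected",
    [
        (np.zeros((2, 2), dtype=np.int8), 0.0),
        (np.array([[0, -1], [1, 2]], dtype=np.int8), 0.25),
    ],
)
def test_missingness_small_examples(gt, expected):
    assert compute_missingness(make_matrix(gt)) == expected


def test_missingness_recovers_injected_rate_at_study_scale():
    rng = np.random.default_rng(6)
    n_sites, n_samples, rate = 2229, 141, 0.157
    gt = rng.binomial(2, 0.5, size=(n_sites, n_samples)).astype(np.int8)
    gt[rng.random(gt.shape) < rate] = -1
    m = matrix_from_gt012(
        [f"s{j}" for j in range(n_samples)], make_sites(n_sites), gt
    )
    est = compute_missingness(m)
    se = np.sqrt(rate * (1 - rate) / (n_sites * n_samples))
    assert abs(est - rate) <= 3 * se


# --------------------------------------------------------------------------
# probe candidate filter
# --------------------------------------------------------------------------
def test_candidate_target_bounds_inclusive():
    kept = filter_candidate_targets(
        [(300, 0.50), (150, 0.50), (300, 0.80), (200, 0.30), (400, 0.70), (401, 0.5)]
    )
    assert kept == [(300, 0.50), (200, 0.30), (400, 0.70)]
    with pytest.raises(ValueError):
        filter_candidate_targets([(0, 0.5)])
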