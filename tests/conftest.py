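import numpy as np
import pandas as pd
import pytest

from plethotime.matrix import matrix_from_gt012
from plethotime.simulate import (
    ArtifactModel,
    apply_archival_artifacts,
    build_metadata,
    default_tissue_assignment,
    emit_dataset,
    preset_scenario,
    simulate_temporal_population,
)


def make_sites(n, locus="locusA", ref="A", alt="G", qual=60.0, start_pos=1):
    return pd.DataFrame(
        {
            "locus": locus,
            "pos": np.arange(start_pos, start_pos + n),
            "ref": ref,
            "alt": alt,
            "qual": qual,
        }
    )


def make_matrix(gt, **site_kw):
    """Biallelic matrix from a (sites x samples) 0/1/2/-1 array."""
    gt = np.asarray(gt, dtype=np.int8)
    samples = [f"s{j}" for j in range(gt.shape[1])]
    return matrix_from_gt012(samples, make_sites(gt.shape[0], **site_kw), gt)


def random_gt(rng, n_sites, n_samples, p_missing=0.0):
    """Random HWE-ish genotypes with site frequencies from U(0.05, 0.95)."""
    p = rng.uniform(0.05, 0.95, size=n_sites)
    gt = rng.binomial(2, p[:, None], size=(n_sites, n_samples)).astype(np.int8)
    if p_missing:
        gt[rng.random(gt.shape) < p_missing] = -1
    return gt


@pytest.fixture(scope="session")
def small_truth():
    scenario = preset_scenario("stable", n_loci=12, seed=11)
    return simulate_temporal_population(scenario)


@pytest.fixture(scope="session")
def small_dataset(small_truth, tmp_path_factory):
    """Emitted VCF/BED/metadata for a small artifact-laden dataset."""
    tissues = default_tissue_assignment(small_truth)
    matrix = apply_archival_artifacts(small_truth, ArtifactModel(), tissues)
    meta = build_metadata(small_truth, tissues)
    lengths = {
        l: small_truth.scenario.locus_length_bp
        for l in matrix.sites["locus"].unique()
    }
    out = tmp_path_factory.mktemp("dataset")
    paths = emit_dataset(matrix, meta, out / "sim", lengths)
    return {
        "truth": small_truth,
        "matrix": matrix,
        "meta": meta,
        "lengths": lengths,
        **paths,
    }
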