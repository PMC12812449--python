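#!/usr/bin/env python
"""Immune-locus style selection scan on the bottleneck dataset.

Treats the first three loci as candidate (immune-related) loci, builds the
neutral Fst baseline from non-coding flanking SNPs with time periods as the
contrast groups, flags outliers beyond mean + 2 SD, and summarises
polymorphism and allele-frequency trajectories.
"""

import json
from pathlib import Path

import pandas as pd

from plethotime.matrix import load_metadata
from plethotime.scan import (
    allele_trajectories,
    fst_outliers,
    neutral_baseline,
    polymorphism_summary,
    polymorphism_table,
)
from plethotime.variants import partition_coding_noncoding, read_bed, read_vcf

ROOT = Path(__file__).resolve().parents[1] / "results"
N_CANDIDATES = 3


def main() -> None:
    datasets = json.loads((ROOT / "data" / "datasets.json").read_text())
    info = datasets["bottleneck"]
    out = ROOT / "scan"
    out.mkdir(parents=True, exist_ok=True)

    matrix = read_vcf(ROOT / "filtered" / "bottleneck.filtered.vcf")
    meta = load_metadata(info["meta"])
    locus_map = read_bed(info["bed"])
    coding, noncoding = partition_coding_noncoding(matrix, locus_map)

    pops = {}
    for period in sorted(meta["time_period"].unique()):
        names = meta.loc[meta["time_period"] == period, "sample"]
        pops[period] = matrix.sample_mask(names)

    baseline = neutral_baseline(noncoding, pops)
    candidate_loci = sorted(matrix.sites["locus"].unique())[:N_CANDIDATES]
    cand = matrix.take_sites(matrix.sites["locus"].isin(candidate_loci).to_numpy())
    report = fst_outliers(cand, baseline, populations=pops,
                          n_baseline_sites=noncoding.n_sites)
    report.site_fst.to_csv(out / "outliers.tsv", sep="\t", index=False)

    summaries = polymorphism_summary(cand, meta)
    polymorphism_table(summaries).to_csv(out / "polymorphism.tsv", sep="\t", index=False)
    traj = allele_trajectories(cand, meta, group_columns=("species",))
    traj.to_csv(out / "trajectories.tsv", sep="\t", index=False)

    print(
        f"baseline Fst (non-coding, {noncoding.n_sites} sites): "
        f"mean={report.baseline_mean:.3f} sd={report.baseline_sd:.3f}"
    )
    print(
        f"candidate loci {candidate_loci}: mean Fst={report.candidate_mean:.3f} "
        f"({report.elevation_percent:+.0f}% vs baseline), "
        f"{report.n_outliers}/{len(report.site_fst)} outlier site(s) "
        f"beyond {report.threshold:.3f}"
    )
    for s in summaries:
        print(
            f"{s.species}: {s.polymorphic_snps}/{s.total_snps} polymorphic "
            f"({s.percent_polymorphic}%), per-locus {s.per_locus_polymorphic}"
        )


if __name__ == "__main__":
    main()
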