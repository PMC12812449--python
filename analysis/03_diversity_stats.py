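#!/usr/bin/env python
"""Per-time-period diversity statistics for each filtered dataset.

Computes nucleotide diversity, observed/expected heterozygosity and
windowed Watterson's theta / Tajima's D per collection period, writing one
table per dataset under results/diversity/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from plethotime.diversity import mean_pi, sliding_windows
from plethotime.matrix import load_metadata
from plethotime.variants import read_vcf

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    datasets = json.loads((ROOT / "data" / "datasets.json").read_text())
    out = ROOT / "diversity"
    out.mkdir(parents=True, exist_ok=True)
    for name, info in datasets.items():
        matrix = read_vcf(ROOT / "filtered" / f"{name}.filtered.vcf")
        meta = load_metadata(info["meta"])
        lengths = {l: 710 for l in matrix.sites["locus"].unique()}
        rows = []
        for period in sorted(meta["time_period"].unique()):
            names = meta.loc[meta["time_period"] == period, "sample"]
            mask = matrix.sample_mask(names)
            est = mean_pi(matrix, mask)
            wins = sliding_windows(matrix, mask, locus_lengths=lengths)
            d = np.array([w.tajimas_d for w in wins], dtype=float)
            rows.append(
                {
                    "time_period": period,
                    "n_samples": int(mask.sum()),
                    "pi": est.pi,
                    "h_obs": est.h_obs,
                    "h_exp": est.h_exp,
                    "theta_w": float(np.nanmean([w.theta_w for w in wins])),
                    "tajimas_d": float(np.nanmean(d[np.isfinite(d)])),
                }
            )
        table = pd.DataFrame(rows)
        table.to_csv(out / f"{name}.diversity.tsv", sep="\t", index=False)
        print(f"== {name}")
        print(table.to_string(index=False, float_format=lambda v: f"{v:.5f}"))


if __name__ == "__main__":
    main()
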