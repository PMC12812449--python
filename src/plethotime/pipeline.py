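"""End-to-end driver: simulate -> filter -> diversity -> temporal -> scan.

``run_pipeline`` wires the stages over the six canonical dataset tags
({all_reads, downsampled} x {all_sites, coding, noncoding}), writes TSV
tables plus a JSON manifest of seeds and per-stage counts, and is fully
deterministic for a fixed configuration.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diversity import mean_pi, sliding_windows, windows_to_frame
from .matrix import GenotypeMatrix, load_metadata, population_labels
from .scan import fst_outliers, neutral_baseline, polymorphism_table, polymorphism_summary
from .temporal import anova_time_periods, classify_trend, permute_subsample  # noqa: F401
from .variants import (
    FilterConfig,
    LocusMap,
    apply_site_filters,
    compute_missingness,
    downsample_depth,
    partition_coding_noncoding,
    read_bed,
    read_vcf,
    thin_one_snp_per_locus,
)

log = logging.getLogger("plethotime")

READ_TAGS = ("all_reads", "downsampled")
SITE_TAGS = ("all_sites", "coding", "noncoding")
DATASET_TAGS = tuple(f"{r}.{s}" for r in READ_TAGS for s in SITE_TAGS)


@dataclass
class RunConfig:
    """Configuration of a pipeline run."""

    vcf: str
    bed: str
    meta: str
    out_dir: str
    group_columns: tuple[str, ...] = ("species", "site", "time_period")
    fst_group_columns: tuple[str, ...] = ("species", "site")
    period_column: str = "time_period"
    seed: int = 0
    thin_seed: int | None = None
    reps: int = 20
    n_min: int = 3
    target_depth: float = 24.0
    window_size: int = 150
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    candidate_loci: tuple[str, ...] = ()
    run_permutations: bool = True
    figures: bool = False
    locus_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.thin_seed is None:
            self.thin_seed = self.seed


def _population_masks(matrix: GenotypeMatrix, meta: pd.DataFrame, columns):
    labels = population_labels(meta, columns=columns)
    labels = labels.loc[[s for s in matrix.samples]]
    masks = {}
    for lab in sorted(labels.unique()):
        names = labels.index[labels == lab]
        masks[lab] = matrix.sample_mask(names)
    return masks


def _pi_stat(matrix: GenotypeMatrix, mask: np.ndarray) -> float:
    return mean_pi(matrix, mask).pi


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage for each dataset tag; returns the manifest dict."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thin_seed": config.thin_seed,
        "datasets": {},
    }

    meta = load_metadata(config.meta)
    raw = read_vcf(config.vcf)
    locus_map = read_bed(config.bed, config.locus_lengths)
    log.info("loaded %d sites x %d samples", raw.n_sites, raw.n_samples)

    # all-reads and downsampled branches share the filter chain
    branches: dict[str, GenotypeMatrix] = {}
    for read_tag in READ_TAGS:
        m = raw if read_tag == "all_reads" else downsample_depth(
            raw, config.target_depth, seed=config.seed
        )
        filtered, report = apply_site_filters(m, config.filter_config)
        report_frame = report.to_frame()
        report_frame.to_csv(out / f"filter_report.{read_tag}.tsv", sep="\t", index=False)
        (out / f"filter_report.{read_tag}.json").write_text(
            json.dumps(
                {
                    "sites_in": report.sites_in,
                    "removed": report.removed,
                    "sites_out": report.sites_out,
                    "missing_fraction": report.missing_fraction,
                    "warnings": report.warnings,
                },
                indent=2,
            )
        )
        branches[read_tag] = filtered
        manifest["datasets"][read_tag] = {
            "sites_in": report.sites_in,
            "sites_out": report.sites_out,
            "missing_fraction": report.missing_fraction,
        }

    results: dict[str, dict] = {}
    for read_tag, filtered in branches.items():
        partitions = {"all_sites": filtered}
        if filtered.n_sites:
            coding, noncoding = partition_coding_noncoding(filtered, locus_map)
            partitions["coding"] = coding
            partitions["noncoding"] = noncoding
        else:  # pragma: no cover - degenerate input
            partitions["coding"] = filtered
            partitions["noncoding"] = filtered
        for site_tag, matrix in partitions.items():
            tag = f"{read_tag}.{site_tag}"
            stage = _analyse_dataset(matrix, meta, config, tag, out)
            results[tag] = stage
            manifest["datasets"][tag] = stage["counts"]

    # scan runs once, on the all-reads branch, against its non-coding baseline
    if config.candidate_loci:
        scan_info = _run_scan(branches["all_reads"], meta, locus_map, config, out)
        manifest["scan"] = scan_info

    manifest["runtime_s"] = round(time.time() - t0, 2)
    manifest["dataset_tags"] = list(DATASET_TAGS)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _analyse_dataset(
    matrix: GenotypeMatrix, meta: pd.DataFrame, config: RunConfig, tag: str, out: Path
) -> dict:
    counts = {"n_sites": matrix.n_sites, "n_samples": matrix.n_samples}
    if matrix.n_sites == 0:
        return {"counts": counts, "diversity": pd.DataFrame(), "trends": []}

    thinned = thin_one_snp_per_locus(matrix, config.thin_seed)
    counts["n_sites_thinned"] = thinned.n_sites
    counts["missing_fraction"] = compute_missingness(matrix)

    pop_masks = _population_masks(matrix, meta, config.group_columns)
    rows = []
    window_rows = []
    for label, mask in pop_masks.items():
        est = mean_pi(matrix, mask, population=label)
        wins = sliding_windows(
            matrix, mask, size=config.window_size,
            locus_lengths=config.locus_lengths or None,
        )
        d_vals = np.array([w.tajimas_d for w in wins], dtype=float)
        theta_vals = np.array([w.theta_w for w in wins], dtype=float)
        rows.append(
            {
                "population": label,
                "n_samples": int(mask.sum()),
                "pi": est.pi,
                "h_obs": est.h_obs,
                "h_exp": est.h_exp,
                "theta_w": float(np.nanmean(theta_vals)) if len(wins) else np.nan,
                "tajimas_d": float(np.nanmean(d_vals)) if np.isfinite(d_vals).any() else np.nan,
                "n_windows": len(wins),
            }
        )
        wf = windows_to_frame(wins)
        wf.insert(0, "population", label)
        window_rows.append(wf)
    diversity = pd.DataFrame(rows)
    diversity.to_csv(out / f"diversity.{tag}.tsv", sep="\t", index=False)
    if window_rows:
        pd.concat(window_rows, ignore_index=True).to_csv(
            out / f"windows.{tag}.tsv", sep="\t", index=False
        )

    # temporal: permutation + ANOVA per species x site stratum; trend calls
    trends = []
    anova_rows = []
    perm_rows = []
    strata_cols = [c for c in config.group_columns if c != config.period_column]
    meta_idx = meta.set_index("sample").loc[matrix.samples].reset_index()
    for stratum, sub in meta_idx.groupby(strata_cols, sort=True):
        if not isinstance(stratum, tuple):
            stratum = (stratum,)
        periods = sorted(sub[config.period_column].unique())
        if len(periods) < 2:
            continue
        series = {"pi": [], "theta": [], "d": []}
        perm_groups = {}
        # ANOVA compares permutation replicates at one common subsample
        # size: one below the smallest group, so every group retains
        # genuine permutation spread (at n_sub = N replicates coincide).
        sizes = [
            (sub[config.period_column] == p).sum() for p in periods
        ]
        n_common = max(config.n_min, int(min(sizes)) - 1)
        for period in periods:
            names = sub.loc[sub[config.period_column] == period, "sample"].tolist()
            mask = matrix.sample_mask(names)
            est = mean_pi(matrix, mask)
            wins = sliding_windows(
                matrix, mask, size=config.window_size,
                locus_lengths=config.locus_lengths or None,
            )
            d_vals = np.array([w.tajimas_d for w in wins], dtype=float)
            series["pi"].append(est.pi)
            series["theta"].append(
                float(np.nanmean([w.theta_w for w in wins])) if wins else np.nan
            )
            series["d"].append(
                float(np.nanmean(d_vals)) if np.isfinite(d_vals).any() else np.nan
            )
            if config.run_permutations and len(names) >= config.n_min:
                perms = permute_subsample(
                    matrix,
                    names,
                    _pi_stat,
                    n_min=config.n_min,
                    reps=config.reps,
                    seed=config.seed,
                    population=f"{'|'.join(map(str, stratum))}|{period}",
                )
                for p in perms:
                    perm_rows.append(
                        {
                            "population": p.population,
                            "n_sub": p.n_sub,
                            "median": p.median,
                            "mean": p.mean,
                            "sd": p.sd,
                            "cv": p.cv,
                        }
                    )
                if len(names) > n_common:
                    perm_groups[period] = perms[n_common - config.n_min].values
        label = "|".join(map(str, stratum))
        call = classify_trend(
            series["pi"], series["theta"], series["d"], population=label
        )
        trends.append(call)
        if len(perm_groups) >= 2 and all(len(v) >= 2 for v in perm_groups.values()):
            res = anova_time_periods(perm_groups)
            for _, r in res.tukey.iterrows():
                anova_rows.append(
                    {
                        "stratum": label,
                        "F": res.F,
                        "p": res.p,
                        "group1": r["group1"],
                        "group2": r["group2"],
                        "difference": r["difference"],
                        "p_adj": r["p_adj"],
                    }
                )
    pd.DataFrame(
        [
            {
                "population": t.population,
                "pi": t.direction_pi,
                "theta": t.direction_theta,
                "d": t.direction_d,
                "classification": t.classification,
            }
            for t in trends
        ]
    ).to_csv(out / f"trends.{tag}.tsv", sep="\t", index=False)
    if anova_rows:
        pd.DataFrame(anova_rows).to_csv(
            out / f"anova_tukey.{tag}.tsv", sep="\t", index=False
        )
    if perm_rows:
        pd.DataFrame(perm_rows).to_csv(
            out / f"permutations.{tag}.tsv", sep="\t", index=False
        )
    if config.figures and perm_rows:
        _plot_permutation_boxes(pd.DataFrame(perm_rows), tag, out)
    return {"counts": counts, "diversity": diversity, "trends": trends}


def _plot_permutation_boxes(perm: pd.DataFrame, tag: str, out: Path) -> None:
    """Box-plot-style figure of permutation medians per population (optional)."""
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:  # pragma: no cover - plotting is optional
        log.warning("matplotlib unavailable; skipping figures")
        return
    fig, ax = plt.subplots(figsize=(8, 4))
    groups = list(perm.groupby("population"))
    ax.boxplot(
        [g["median"].to_numpy() for _, g in groups],
        tick_labels=[str(k) for k, _ in groups],
    )
    ax.set_ylabel("median pi across subsample sizes")
    ax.set_title(tag)
    plt.setp(ax.get_xticklabels(), rotation=30, ha="right", fontsize=7)
    fig.tight_layout()
    fig.savefig(out / f"permutations.{tag}.png", dpi=120)
    plt.close(fig)


def neutral_calibration(
    seed: int,
    n_loci: int = 100,
    n_samples: int = 20,
    N: int = 1000,
    sites_per_locus: int = 14,
) -> dict:
    """Estimator calibration on a neutral constant-N sample.

    Samples one epoch directly from the stationary neutral SFS (constant
    N, negligible mutation influx over zero elapsed generations) and
    summarises the window statistics: under neutrality the mean Tajima's D
    should sit near 0 and Watterson's theta should equal pi in expectation
    (paired over windows).
    """
    from .simulate import DemographicScenario, simulate_temporal_population
    from .matrix import matrix_from_gt012

    scenario = DemographicScenario(
        n_loci=n_loci,
        sites_per_locus=sites_per_locus,
        epoch_sizes=[(0, N)],
        sampling_epochs=[(0, "T1", n_samples)],
        seed=seed,
    )
    truth = simulate_temporal_population(scenario)
    sites = truth.sites.copy()
    sites["qual"] = 60.0
    matrix = matrix_from_gt012(truth.samples, sites, truth.genotypes)
    lengths = {
        l: scenario.locus_length_bp for l in matrix.sites["locus"].unique()
    }
    wins = sliding_windows(matrix, locus_lengths=lengths)
    d = np.array([w.tajimas_d for w in wins], dtype=float)
    theta = np.array([w.theta_w for w in wins], dtype=float)
    pi_per_site = np.array([w.pi_total / w.length for w in wins], dtype=float)
    diff = theta - pi_per_site
    d_ok = d[np.isfinite(d)]
    return {
        "n_windows": len(wins),
        "mean_d": float(d_ok.mean()) if len(d_ok) else float("nan"),
        "mean_theta": float(theta.mean()),
        "mean_pi": float(pi_per_site.mean()),
        "theta_minus_pi": float(diff.mean()),
        "theta_minus_pi_se": float(diff.std(ddof=1) / np.sqrt(len(diff))),
    }


def classify_synthetic_scenario(
    name: str,
    seed: int,
    n_loci: int = 60,
    artifacts: bool = True,
    apply_filters: bool = True,
    rel_tol: float = 0.02,
):
    """Simulate a preset scenario and classify its demographic trend.

    End-to-end parameter-recovery path: forward simulation, archival
    artifact layer (at the default tissue depth/dropout/damage rates),
    the SNP filter chain, then per-epoch pi / Watterson's theta /
    Tajima's D and the trend rule.  Returns the TrendCall.
    """
    from .simulate import (
        ArtifactModel,
        apply_archival_artifacts,
        default_tissue_assignment,
        preset_scenario,
        simulate_temporal_population,
    )
    from .matrix import matrix_from_gt012

    scenario = preset_scenario(name, n_loci=n_loci, seed=seed)
    truth = simulate_temporal_population(scenario)
    if artifacts:
        matrix = apply_archival_artifacts(
            truth, ArtifactModel(), default_tissue_assignment(truth)
        )
    else:
        sites = truth.sites.copy()
        sites["qual"] = 60.0
        matrix = matrix_from_gt012(truth.samples, sites, truth.genotypes)
    if apply_filters:
        matrix, _ = apply_site_filters(matrix, FilterConfig())
    lengths = {
        l: scenario.locus_length_bp for l in matrix.sites["locus"].unique()
    }
    pi_s, th_s, d_s = [], [], []
    epoch_labels = [lab for _, lab, _ in scenario.sampling_epochs]
    for label in epoch_labels:
        mask = np.array([e == label for e in truth.sample_epoch])
        mask = matrix.sample_mask(
            [s for s, keep in zip(truth.samples, mask) if keep]
        )
        pi_s.append(mean_pi(matrix, mask).pi)
        wins = sliding_windows(matrix, mask, locus_lengths=lengths)
        d_vals = np.array([w.tajimas_d for w in wins], dtype=float)
        th_s.append(float(np.nanmean([w.theta_w for w in wins])))
        d_s.append(
            float(np.nanmean(d_vals)) if np.isfinite(d_vals).any() else float("nan")
        )
    return classify_trend(pi_s, th_s, d_s, rel_tol=rel_tol, population=name)


def _run_scan(
    filtered: GenotypeMatrix,
    meta: pd.DataFrame,
    locus_map: LocusMap,
    config: RunConfig,
    out: Path,
) -> dict:
    coding, noncoding = partition_coding_noncoding(filtered, locus_map)
    cand_mask = filtered.sites["locus"].isin(config.candidate_loci).to_numpy()
    candidates = filtered.take_sites(cand_mask)
    pops = _population_masks(filtered, meta, config.fst_group_columns)
    baseline = neutral_baseline(noncoding, pops)
    report = fst_outliers(
        candidates, baseline, populations=pops, n_baseline_sites=noncoding.n_sites
    )
    report.site_fst.to_csv(out / "scan_outliers.tsv", sep="\t", index=False)
    summaries = polymorphism_summary(candidates, meta)
    polymorphism_table(summaries).to_csv(
        out / "scan_polymorphism.tsv", sep="\t", index=False
    )
    return {
        "baseline_mean": report.baseline_mean,
        "baseline_sd": report.baseline_sd,
        "candidate_mean": report.candidate_mean,
        "elevation_percent": report.elevation_percent,
        "n_outliers": report.n_outliers,
        "n_candidate_sites": int(cand_mask.sum()),
    }
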