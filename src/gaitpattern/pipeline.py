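"""End-to-end orchestration: ingest or simulate trials, assemble and
standardize the feature matrix, cluster, classify, run the symmetry and
statistics battery, and write CSV outputs plus a plain-text report.

Every randomized stage takes its seed from the config, so a rerun with the
same config produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classification import (
    condition_comparisons_across,
    condition_comparisons_within,
    pairwise_subject_comparisons,
    within_table,
)
from .clustering import kmeans_cluster, loading_rates, merge_tree, select_k
from .errors import ConfigurationError, ParameterError
from .symmetry_stats import (
    compare_running_speed,
    friedman,
    kruskal_wallis,
    mann_whitney_effect,
    pairwise_mann_whitney,
    symmetry_table,
)
from .synthetic_data import SynthConfig, drop_trials, generate_cohort
from .waveform_prep import (
    ANGLES,
    build_feature_matrix,
    read_trials,
    standardize,
    write_trials,
)


@dataclass
class AnalysisConfig:
    """Everything one run needs; serializes to/from YAML losslessly."""

    input_path: str | None = None  # CSV trials; None -> simulate
    synth: dict = field(default_factory=dict)  # SynthConfig overrides
    drop_fraction: float = 0.0
    n_time: int = 201
    sd_mode: str = "block"
    k_min: int = 2
    k_max: int = 40
    restarts: int = 25
    seed: int = 0
    svm_c: float = 1.0
    alpha: float = 0.05
    symmetry_angles: list[str] | None = None  # None -> all nine
    linkage_rule: str = "ward"
    run_pairwise_subjects: bool = True
    reference_condition: str = "Neutral"

    def __post_init__(self) -> None:
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ConfigurationError("need 2 <= k_min <= k_max")
        if self.symmetry_angles:
            bad = [a for a in self.symmetry_angles if a not in ANGLES]
            if bad:
                raise ConfigurationError(f"unknown symmetry angle(s): {bad}")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class AnalysisReport:
    """Key numbers of one run; every entry is also written to a stage file."""

    config_digest: str
    seed: int
    n_rows: int
    n_cols: int
    best_k: int
    silhouette_by_k: dict[int, float]
    loading_summaries: dict[str, dict]
    pairwise_n: int
    pairwise_significant: int
    across_rates: dict[str, float]
    across_significant: dict[str, bool]
    within_mean_rates: dict[str, float]
    within_significant_subjects: dict[str, int]
    symmetry_medians: dict[str, float]
    kruskal_statistic: float
    kruskal_p: float
    version: str = __version__


def _load_trials(config: AnalysisConfig):
    if config.input_path is not None:
        path = Path(config.input_path)
        if not path.exists():
            raise ParameterError(f"input path does not exist: {path}")
        return read_trials(path)
    synth = SynthConfig(**{"seed": config.seed, **config.synth})
    trials, _ = generate_cohort(synth)
    if config.drop_fraction > 0:
        trials = drop_trials(trials, config.drop_fraction, seed=config.seed + 1)
    return trials


def run_full_analysis(config: AnalysisConfig, outdir: str | Path) -> AnalysisReport:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"gaitpattern {__version__}", f"config digest {config.digest()}",
                 f"seed {config.seed}"]

    # --- stage 1: trials -------------------------------------------------
    trials = _load_trials(config)
    write_trials(trials, out / "trials.csv")
    log_lines.append(f"trials: {len(trials)} rows, {len(trials.subjects)} subjects, "
                     f"{len(trials.conditions)} conditions")

    # --- stage 2: feature matrix ----------------------------------------
    fm = build_feature_matrix(trials, n_time=config.n_time)
    fm_std, params = standardize(fm, mode=config.sd_mode)
    pd.DataFrame(
        {"angle": params.angle_names, "block_sd": (params.block_sds if config.sd_mode == "block"
                                                   else np.full(len(params.angle_names), np.nan))}
    ).to_csv(out / "normalization_block_sds.csv", index=False)
    log_lines.append(f"feature matrix: {fm.n_rows} x {fm.n_cols} ({config.sd_mode} SD mode)")

    # --- stage 3: clustering --------------------------------------------
    k_max = min(config.k_max, fm.n_rows - 1)
    best_k, scores = select_k(
        fm_std, range(config.k_min, k_max + 1), seed=config.seed, restarts=config.restarts
    )
    pd.DataFrame(
        {"k": list(scores), "mean_silhouette": [scores[k] for k in scores]}
    ).to_csv(out / "silhouette_scan.csv", index=False)
    cluster = kmeans_cluster(fm_std, best_k, seed=config.seed, restarts=config.restarts)
    assign = fm.row_labels.copy()
    assign["cluster"] = cluster.assignments
    assign["silhouette"] = cluster.silhouette_per_row
    assign.to_csv(out / "cluster_assignments.csv", index=False)
    tree = merge_tree(fm_std, linkage_rule=config.linkage_rule)
    (out / "dendrogram.nwk").write_text(tree.to_newick() + "\n")
    loading_summaries = {}
    for grouping in ("subject", "condition", "subject_condition_side"):
        table = loading_rates(cluster.assignments, fm.row_labels, grouping)
        table.rates.to_csv(out / f"loading_rates_{grouping}.csv")
        loading_summaries[grouping] = table.summary
    log_lines.append(f"clustering: best_k={best_k} "
                     f"(mean silhouette {scores[best_k]:.4f}, "
                     f"scanned k={config.k_min}..{k_max}, restarts={config.restarts})")

    # --- stage 4: classification ----------------------------------------
    ref = config.reference_condition
    pairwise_n = pairwise_sig = 0
    if config.run_pairwise_subjects:
        pairwise = pairwise_subject_comparisons(fm_std, C=config.svm_c, alpha=config.alpha)
        pd.DataFrame(
            [
                (r.group_a, r.group_b, r.n_trials, r.n_correct, r.r_class,
                 r.critical_count, r.significant)
                for r in pairwise
            ],
            columns=["subject_a", "subject_b", "n_trials", "n_correct", "r_class",
                     "critical_count", "significant"],
        ).to_csv(out / "pairwise_subjects.csv", index=False)
        pairwise_n = len(pairwise)
        pairwise_sig = sum(r.significant for r in pairwise)
        log_lines.append(f"subject pairs: {pairwise_sig}/{pairwise_n} significant")
    across = condition_comparisons_across(fm_std, reference=ref, C=config.svm_c,
                                          alpha=config.alpha)
    pd.DataFrame(
        [(r.group_b, r.n_trials, r.n_correct, r.r_class, r.critical_count, r.significant)
         for r in across],
        columns=["condition", "n_trials", "n_correct", "r_class", "critical_count",
                 "significant"],
    ).to_csv(out / "condition_across.csv", index=False)
    within = condition_comparisons_within(fm_std, reference=ref, C=config.svm_c,
                                          alpha=config.alpha)
    rates_tbl, flags_tbl, mean_rates = within_table(within)
    rates_tbl.to_csv(out / "condition_within_rates.csv")
    flags_tbl.to_csv(out / "condition_within_significant.csv")
    across_rates = {r.group_b: r.r_class for r in across}
    across_sig = {r.group_b: r.significant for r in across}
    within_sig_counts = (
        within.groupby("comparison")["significant"].sum().astype(int).to_dict()
    )
    log_lines.append("across-subject condition rates: "
                     + ", ".join(f"{c}={v:.3f}" for c, v in across_rates.items()))
    log_lines.append("within-subject mean rates: "
                     + ", ".join(f"{c}={v:.3f}" for c, v in mean_rates.items()))

    # --- stage 5: symmetry + statistics ---------------------------------
    angles = tuple(config.symmetry_angles) if config.symmetry_angles else ANGLES
    sym = symmetry_table(trials, n_time=config.n_time, angles=angles)
    sym.values.to_csv(out / "symmetry_table.csv")
    groups = [sym.values[c].dropna().to_numpy() for c in sym.values.columns]
    kw = kruskal_wallis(groups)
    posthoc = pairwise_mann_whitney(sym.values, alpha=config.alpha)
    posthoc.to_csv(out / "symmetry_posthoc.csv", index=False)
    stats_lines = [
        "symmetry medians: "
        + ", ".join(f"{c}={m:.4f}" for c, m in sym.medians.items()),
        f"kruskal_wallis: H={kw.statistic:.4f} df={kw.df} N={kw.n} p={kw.p:.4f}",
    ]
    if sym.sex:
        for sex_label in ("F", "M"):
            sub = sym.by_sex(sex_label)
            if len(sub.dropna()) >= 2:
                fr = friedman(sub)
                stats_lines.append(
                    f"friedman[{sex_label}]: X2={fr.statistic:.4f} df={fr.df} "
                    f"n={fr.n} p={fr.p:.4f}"
                )
        for c in sym.values.columns:
            f_vals = sym.by_sex("F")[c].dropna()
            m_vals = sym.by_sex("M")[c].dropna()
            if len(f_vals) and len(m_vals):
                mw = mann_whitney_effect(f_vals, m_vals)
                stats_lines.append(
                    f"mann_whitney[{c}] F vs M: U={mw.statistic:.1f} p={mw.p:.4f} "
                    f"r={mw.effect_size_r:.3f} ({mw.effect})"
                )
    if trials.speed:
        speed_df = pd.DataFrame(
            [(k[0], k[1], v) for k, v in trials.speed.items()],
            columns=["subject", "condition", "speed"],
        )
        speed_res = compare_running_speed(speed_df, alpha=config.alpha)
        speed_res["posthoc"].to_csv(out / "running_speed_posthoc.csv", index=False)
        an = speed_res["anova"]
        stats_lines.append(
            f"running_speed anova: F={an.statistic:.4f} df={an.df} p={an.p:.4f}"
        )
    (out / "statistics_report.txt").write_text("\n".join(stats_lines) + "\n")

    report = AnalysisReport(
        config_digest=config.digest(),
        seed=config.seed,
        n_rows=fm.n_rows,
        n_cols=fm.n_cols,
        best_k=best_k,
        silhouette_by_k={int(k): float(v) for k, v in scores.items()},
        loading_summaries=loading_summaries,
        pairwise_n=pairwise_n,
        pairwise_significant=pairwise_sig,
        across_rates={k: float(v) for k, v in across_rates.items()},
        across_significant=across_sig,
        within_mean_rates={k: float(v) for k, v in mean_rates.items()},
        within_significant_subjects=within_sig_counts,
        symmetry_medians={c: float(m) for c, m in sym.medians.items()},
        kruskal_statistic=kw.statistic,
        kruskal_p=kw.p,
    )
    (out / "report.json").write_text(
        json.dumps(dataclasses.asdict(report), indent=2, sort_keys=True) + "\n"
    )
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return report


def make_fixtures(outdir: str | Path, seed: int = 2015) -> Path:
    """Write a small deterministic cohort (4 subjects x 4 conditions x
    3 trials x 2 sides = 96 trials) plus its expected symmetry table."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = SynthConfig(n_subjects=4, n_conditions=4, n_trials=3, n_time=41, seed=seed)
    trials, _ = generate_cohort(cfg)
    write_trials(trials, out / "trials.csv")
    sym = symmetry_table(trials, n_time=cfg.n_time)
    sym.values.to_csv(out / "expected_symmetry.csv")
    (out / "fixture_config.yaml").write_text(
        yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=True)
    )
    return out
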