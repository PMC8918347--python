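"""Manifest-driven batch pipelines for both assays.

A run is described by a :class:`RunConfig` (usually loaded from YAML): a
manifest CSV listing trajectory files with their group labels, the assay
protocol / geometry parameters, the gap policy, the statistical design and
the seed. Outputs are tidy CSV tables plus a JSON-lines log that records
the config hash, seed, exclusion thresholds and per-file failures, so a
run is reproducible and auditable.

Preference runs apply the two-pass exclusion rule: first the mean swim
speed of every fish is computed and averaged per genotype group within
each age group, then 0.6 x the smallest group mean is applied as the
inclusion threshold in the scoring pass.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, ShoalkitError
from .preference import AssayProtocol, exclusion_threshold, score_assay
from .shoaling import mixed_shoal_control, shoal_metrics
from .stats import ComparisonDesign, GroupSample, compare_groups, comparison_table
from .trajectory import fill_gaps, mean_swim_speed, read_trajectories

SHOAL_METRIC_COLUMNS = ["nnd_mm", "iid_mm", "fnd_mm",
                        "cumulative_distance_mm", "variance_explained_2"]


@dataclass
class RunConfig:
    """Configuration of one batch run."""

    assay: str  # "preference" | "shoaling"
    manifest: Path
    out_dir: Path
    protocol: AssayProtocol = field(default_factory=AssayProtocol)
    gap_max_frames: int = 5
    exclusion_basis: str = "test"
    adjust: str = "benjamini_hochberg"
    designs: list[ComparisonDesign] = field(default_factory=list)
    posthoc_alpha: float | None = 0.05
    seed: int = 0
    make_figures: bool = False

    def __post_init__(self) -> None:
        if self.assay not in ("preference", "shoaling"):
            raise ConfigurationError(f"unknown assay {self.assay!r}")
        self.manifest = Path(self.manifest)
        self.out_dir = Path(self.out_dir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        protocol = AssayProtocol(**raw.pop("protocol", {}))
        designs = [ComparisonDesign(compare=d["compare"],
                                    within=tuple(d.get("within", ())),
                                    name=d.get("name"))
                   for d in raw.pop("designs", [])]
        return cls(protocol=protocol, designs=designs, **raw)

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class RunLog:
    """JSON-lines structured log for one pipeline run."""

    def __init__(self, path: Path):
        self.path = path
        self.records: list[dict] = []

    def event(self, kind: str, **payload) -> None:
        self.records.append({"t": time.time(), "event": kind, **payload})

    def write(self) -> None:
        with self.path.open("w") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec, default=str) + "\n")


@dataclass
class PipelineOutcome:
    results: pd.DataFrame
    stats: pd.DataFrame
    n_failed: int
    out_dir: Path


def _default_designs(assay: str) -> list[ComparisonDesign]:
    if assay == "preference":
        return [
            ComparisonDesign(compare="age_wpf", within=("genotype", "rearing")),
            ComparisonDesign(compare="genotype", within=("age_wpf", "rearing")),
            ComparisonDesign(compare="rearing", within=("genotype", "age_wpf")),
        ]
    return [ComparisonDesign(compare="genotype", within=("age_wpf",))]


def run_preference_pipeline(cfg: RunConfig) -> PipelineOutcome:
    """Batch-score a preference cohort and compare groups.

    Manifest columns: ``path, genotype, age_wpf, rearing`` (rearing
    optional, defaults to "social"). Returns the per-fish result table and
    the statistics table; both are also written to ``out_dir``.
    """
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    log = RunLog(cfg.out_dir / "run.log.jsonl")
    log.event("start", assay=cfg.assay, config_hash=cfg.config_hash(), seed=cfg.seed)
    manifest = pd.read_csv(cfg.manifest)
    for col in ("path", "genotype", "age_wpf"):
        if col not in manifest.columns:
            raise ConfigurationError(f"manifest lacks column {col!r}")
    if "rearing" not in manifest.columns:
        manifest["rearing"] = "social"

    # pass 1: load everything and measure speeds
    loaded = []
    n_failed = 0
    for _, row in manifest.iterrows():
        try:
            ts = read_trajectories(row["path"])
            ts = fill_gaps(ts, cfg.gap_max_frames)
            hab_w = cfg.protocol.habituation_window(ts.frame_rate_hz)
            test_w = cfg.protocol.test_window(ts.frame_rate_hz)
            speeds = {"test": mean_swim_speed(ts, ts.fish_ids[0], test_w),
                      "habituation": mean_swim_speed(ts, ts.fish_ids[0], hab_w)}
            speeds["min"] = min(speeds.values())
            loaded.append((row, ts, speeds[cfg.exclusion_basis]))
        except (ShoalkitError, OSError) as exc:
            n_failed += 1
            log.event("file_failed", path=str(row["path"]), error=str(exc))
    if not loaded:
        raise ConfigurationError("no manifest rows could be processed")

    # pass 2: per-age-group thresholds, then scoring
    meta = pd.DataFrame([{"genotype": r["genotype"], "age_wpf": r["age_wpf"],
                          "speed": s} for r, _, s in loaded])
    thresholds = {}
    for age, sub in meta.groupby("age_wpf"):
        group_means = sub.groupby("genotype")["speed"].mean()
        thresholds[age] = exclusion_threshold(group_means.to_list())
        log.event("threshold", age_wpf=age, threshold_mm_s=thresholds[age],
                  group_means=group_means.to_dict())

    records = []
    for row, ts, _ in loaded:
        res = score_assay(ts, cfg.protocol, threshold=thresholds[row["age_wpf"]],
                          exclusion_basis=cfg.exclusion_basis)
        records.append({
            "fish_id": ts.source_id, "genotype": row["genotype"],
            "age_wpf": row["age_wpf"], "rearing": row["rearing"],
            "percent_social": res.percent_time_social,
            "mean_speed_test": res.mean_speed_test,
            "mean_speed_habituation": res.mean_speed_habituation,
            "included": res.included,
            "threshold_mm_s": res.threshold_applied,
        })
    results = pd.DataFrame(records)
    excl = results.groupby(["age_wpf", "genotype"])["included"].agg(["size", "sum"])
    for (age, gt), r in excl.iterrows():
        log.event("exclusion_count", age_wpf=age, genotype=gt,
                  n_total=int(r["size"]), n_included=int(r["sum"]))

    included = results[results["included"]]
    samples = []
    for (gt, age, rearing), sub in included.groupby(["genotype", "age_wpf", "rearing"]):
        if len(sub) == 0:
            continue
        samples.append(GroupSample({"genotype": gt, "age_wpf": age, "rearing": rearing},
                                   sub["percent_social"].to_numpy()))
    empty = results.groupby(["genotype", "age_wpf", "rearing"])["included"].sum()
    for key, n_inc in empty.items():
        if n_inc == 0:
            log.event("empty_group", group=list(map(str, key)))
    designs = cfg.designs or _default_designs("preference")
    if len(samples) >= 2:
        stats = comparison_table(compare_groups(samples, designs, adjust=cfg.adjust,
                                                posthoc_alpha=cfg.posthoc_alpha))
    else:
        log.event("stats_skipped", reason="fewer than 2 non-empty groups")
        stats = pd.DataFrame(columns=["family", "stratum", "group_a", "group_b",
                                      "statistic", "p_raw", "p_adj", "stars"])

    results.to_csv(cfg.out_dir / "preference_results.csv", index=False)
    stats.to_csv(cfg.out_dir / "stats.csv", index=False)
    log.event("done", n_fish=len(results), n_failed=n_failed,
              n_included=int(results["included"].sum()))
    log.write()
    if cfg.make_figures:
        _strip_plot(included, "percent_social", cfg.out_dir / "figures")
    return PipelineOutcome(results, stats, n_failed, cfg.out_dir)


def run_shoaling_pipeline(cfg: RunConfig, control_recordings: int = 0) -> PipelineOutcome:
    """Batch-compute shoal metrics and compare groups per metric.

    Manifest columns: ``path, genotype`` plus optional ``age_wpf``. One
    metrics row per shoal. If ``control_recordings >= 2``, a mixed-movie
    control curve over the first that many recordings is also written.
    """
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    log = RunLog(cfg.out_dir / "run.log.jsonl")
    log.event("start", assay=cfg.assay, config_hash=cfg.config_hash(), seed=cfg.seed)
    manifest = pd.read_csv(cfg.manifest)
    for col in ("path", "genotype"):
        if col not in manifest.columns:
            raise ConfigurationError(f"manifest lacks column {col!r}")
    if "age_wpf" not in manifest.columns:
        manifest["age_wpf"] = 0

    records = []
    kept_ts = []
    n_failed = 0
    for _, row in manifest.iterrows():
        try:
            ts = read_trajectories(row["path"])
            ts = fill_gaps(ts, cfg.gap_max_frames)
            m = shoal_metrics(ts)
            records.append({"shoal_id": ts.source_id, "genotype": row["genotype"],
                            "age_wpf": row["age_wpf"],
                            **{c: getattr(m, c) for c in SHOAL_METRIC_COLUMNS},
                            "n_fish": m.n_fish, "frames_used": m.frames_used})
            kept_ts.append(ts)
        except (ShoalkitError, OSError) as exc:
            n_failed += 1
            log.event("file_failed", path=str(row["path"]), error=str(exc))
    if not records:
        raise ConfigurationError("no manifest rows could be processed")
    results = pd.DataFrame(records)

    designs = cfg.designs or _default_designs("shoaling")
    stats_frames = []
    for metric in SHOAL_METRIC_COLUMNS:
        samples = [GroupSample({"genotype": gt, "age_wpf": age},
                               sub[metric].to_numpy())
                   for (gt, age), sub in results.groupby(["genotype", "age_wpf"])]
        if len(samples) < 2:
            continue
        tab = comparison_table(compare_groups(samples, designs, adjust=cfg.adjust,
                                              posthoc_alpha=cfg.posthoc_alpha))
        tab.insert(0, "metric", metric)
        stats_frames.append(tab)
    stats = pd.concat(stats_frames, ignore_index=True) if stats_frames else pd.DataFrame()

    results.to_csv(cfg.out_dir / "shoal_metrics.csv", index=False)
    stats.to_csv(cfg.out_dir / "stats.csv", index=False)
    if control_recordings >= 2 and len(kept_ts) >= control_recordings:
        n_total = min(r.n_fish for r in kept_ts[:control_recordings])
        curve = mixed_shoal_control(kept_ts[:control_recordings],
                                    n_total=n_total, seed=cfg.seed)
        curve.to_csv(cfg.out_dir / "mixed_control.csv", index=False)
        log.event("mixed_control", n_recordings=control_recordings, n_total=n_total)
    log.event("done", n_shoals=len(results), n_failed=n_failed)
    log.write()
    if cfg.make_figures:
        _strip_plot(results, "variance_explained_2", cfg.out_dir / "figures")
    return PipelineOutcome(results, stats, n_failed, cfg.out_dir)


def _strip_plot(df: pd.DataFrame, value: str, out_dir: Path) -> None:
    """Best-effort per-group strip plot; failures never abort a run."""
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        out_dir.mkdir(parents=True, exist_ok=True)
        groups = list(df.groupby(["genotype", "age_wpf"]))
        fig, ax = plt.subplots(figsize=(1.2 + 0.9 * len(groups), 3.2))
        rng = np.random.default_rng(0)
        for i, (key, sub) in enumerate(groups):
            x = i + rng.uniform(-0.12, 0.12, len(sub))
            ax.plot(x, sub[value], "o", ms=4, alpha=0.7)
        ax.set_xticks(range(len(groups)))
        ax.set_xticklabels(["/".join(map(str, k)) for k, _ in groups],
                           rotation=30, ha="right", fontsize=7)
        ax.set_ylabel(value)
        fig.tight_layout()
        fig.savefig(out_dir / f"{value}.png", dpi=120)
        plt.close(fig)
    except Exception:  # plotting is outside the determinism contract
        pass
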