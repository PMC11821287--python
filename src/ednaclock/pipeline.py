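"""End-to-end orchestration: bedMethyl summaries -> aging sites -> fitted
clocks -> importance reports, driven by one declarative config.

Every stage's input/output counts are logged and written to the run
directory, so the count identity

    candidates = retained_after_coverage + dropped_by_coverage
    retained_after_coverage = aging + non_differential

(plus the separately counted reconciliation conflicts) is auditable for
every run.  The config is serialized into the output directory for
provenance, and runs are idempotent given the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clock as clock_mod
from . import qc as qc_mod
from .errors import ConfigError, DataError
from .io import SUBMODELS, read_bedmethyl, read_genbank_features, read_sam_cigars
from .sites import (
    ClockDesignMatrix,
    ReconciledSite,
    annotate_genes,
    build_design_matrix,
    detect_aging_sites,
    filter_complete_coverage,
    reconcile_modtypes,
)

logger = logging.getLogger(__name__)

DEFAULT_DATASETS = ("full", "modC", "modA")


@dataclass
class RunConfig:
    bedmethyl_dir: str
    genbank: str
    out_dir: str
    ages: list[float]
    sample_ids: list[str] | None = None  # default: dph<age> per age
    datasets: tuple[str, ...] = DEFAULT_DATASETS
    min_coverage: int = 1
    alpha_step: float = 0.01
    fold_options: list[int] | None = None
    n_bootstrap: int = 10
    seed: int = 0
    pooling: str = "pooled"
    qc_sam: str | None = None
    collapse_strand: bool = False

    @property
    def samples(self) -> list[tuple[str, float]]:
        ids = self.sample_ids or [f"dph{a:g}" for a in self.ages]
        return list(zip(ids, [float(a) for a in self.ages]))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"{path}: cannot read config: {exc}") from exc
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys: {sorted(unknown)}")
        try:
            cfg = cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.ages or sorted(set(self.ages)) != sorted(self.ages):
            raise ConfigError("ages must be a non-empty list without duplicates")
        if not Path(self.bedmethyl_dir).is_dir():
            raise ConfigError(f"bedmethyl_dir not found: {self.bedmethyl_dir}")
        if not Path(self.genbank).is_file():
            raise ConfigError(f"genbank file not found: {self.genbank}")
        if self.sample_ids is not None and len(self.sample_ids) != len(self.ages):
            raise ConfigError("sample_ids and ages must have equal length")
        for ds in self.datasets:
            if ds not in ("full", "modC", "modA"):
                raise ConfigError(f"unknown dataset variant {ds!r}")
        if not 0 < self.alpha_step <= 1:
            raise ConfigError("alpha_step must be in (0, 1]")
        if self.n_bootstrap < 1:
            raise ConfigError("n_bootstrap must be >= 1")
        if self.min_coverage < 1:
            raise ConfigError("min_coverage must be >= 1")
        if self.qc_sam is not None and not Path(self.qc_sam).is_file():
            raise ConfigError(f"qc_sam file not found: {self.qc_sam}")

    def alpha_grid(self) -> np.ndarray:
        n = int(round(1.0 / self.alpha_step))
        return np.round(np.linspace(0.0, 1.0, n + 1), 6)


@dataclass
class RunCounts:
    candidates: int = 0
    conflicts_dropped: int = 0
    retained_after_coverage: int = 0
    dropped_by_coverage: int = 0
    aging: int = 0
    non_differential: int = 0


@dataclass
class RunResult:
    out_dir: Path
    counts: RunCounts
    aging_sites: list[ReconciledSite]
    clocks: dict[str, clock_mod.FittedClock]
    summaries: dict[str, clock_mod.SelectionSummary]
    paths: dict[str, Path] = field(default_factory=dict)


# sites.tsv serialization ---------------------------------------------------


def sites_to_tsv(sites: list[ReconciledSite], path) -> None:
    """One row per site: key, modification type, gene, the two mean
    features, and the per-age level/coverage/reliability vectors."""
    if not sites:
        raise DataError("no sites to write")
    ages = sites[0].ages
    rows = []
    for s in sites:
        row = {
            "site_key": f"{s.contig}:{s.position}:{s.strand}",
            "contig": s.contig,
            "position": s.position,
            "strand": s.strand,
            "mod_type": s.mod_type,
            "gene": s.gene if s.gene is not None else "NA",
            "mean_coverage": s.mean_coverage,
            "mean_reliability": s.mean_reliability,
        }
        for a, lv, cv, rl in zip(ages, s.levels, s.coverage, s.reliability):
            row[f"level_{a:g}"] = lv
            row[f"cov_{a:g}"] = cv
            row[f"rel_{a:g}"] = rl
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def sites_from_tsv(path) -> list[ReconciledSite]:
    df = pd.read_csv(path, sep="\t")
    level_cols = [c for c in df.columns if c.startswith("level_")]
    ages = tuple(float(c.split("_", 1)[1]) for c in level_cols)
    sites = []
    for _, row in df.iterrows():
        sites.append(
            ReconciledSite(
                contig=str(row["contig"]),
                position=int(row["position"]),
                strand=str(row["strand"]),
                mod_type=str(row["mod_type"]),
                ages=ages,
                levels=tuple(float(row[f"level_{a:g}"]) for a in ages),
                coverage=tuple(int(row[f"cov_{a:g}"]) for a in ages),
                reliability=tuple(float(row[f"rel_{a:g}"]) for a in ages),
                gene=str(row["gene"]),
            )
        )
    return sites


# Stage drivers -------------------------------------------------------------


def run_sites_stage(config: RunConfig) -> tuple[list[ReconciledSite], RunCounts]:
    """Ingest bedMethyl summaries, reconcile, filter, detect and annotate."""
    bed_dir = Path(config.bedmethyl_dir)
    records = []
    for sample_id, _age in config.samples:
        for submodel in SUBMODELS:
            path = bed_dir / f"{sample_id}_{submodel}.bed"
            if not path.is_file():
                raise DataError(f"missing bedMethyl file: {path}")
            records.extend(read_bedmethyl(path, sample_id, submodel))
    recon = reconcile_modtypes(
        records, config.samples, collapse_strand=config.collapse_strand
    )
    covered = filter_complete_coverage(recon.sites, min_coverage=config.min_coverage)
    aging = detect_aging_sites(covered)
    intervals = read_genbank_features(config.genbank)
    aging = annotate_genes(aging, intervals)
    counts = RunCounts(
        candidates=len(recon.sites),
        conflicts_dropped=recon.n_conflicts_dropped,
        retained_after_coverage=len(covered),
        dropped_by_coverage=len(recon.sites) - len(covered),
        aging=len(aging),
        non_differential=len(covered) - len(aging),
    )
    logger.info(
        "sites: %d candidates (+%d conflicts dropped) -> %d fully covered "
        "-> %d aging",
        counts.candidates, counts.conflicts_dropped,
        counts.retained_after_coverage, counts.aging,
    )
    return aging, counts


def run_all(config: RunConfig) -> RunResult:
    """Execute sites -> fit (per dataset variant) -> importance, plus QC if
    alignments are given.  Aborts with the stage name on any stage error."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    # provenance copy of the config
    cfg_path = out_dir / "run_config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(
            {k: getattr(config, k) for k in config.__dataclass_fields__},
            fh, sort_keys=True,
        )
    paths["config"] = cfg_path

    try:
        aging, counts = run_sites_stage(config)
    except DataError as exc:
        raise DataError(f"stage sites: {exc}") from exc
    if not aging:
        raise DataError("stage sites: no aging sites detected")
    sites_path = out_dir / "sites.tsv"
    sites_to_tsv(aging, sites_path)
    paths["sites"] = sites_path

    clocks: dict[str, clock_mod.FittedClock] = {}
    summaries: dict[str, clock_mod.SelectionSummary] = {}
    summary_frames = []
    for ds in config.datasets:
        try:
            design: ClockDesignMatrix = build_design_matrix(aging, dataset=ds)
            summary = clock_mod.grid_search(
                design,
                alpha_grid=config.alpha_grid(),
                fold_options=config.fold_options,
                n_bootstrap=config.n_bootstrap,
                base_seed=config.seed,
                dataset=ds,
                pooling=config.pooling,
            )
        except DataError as exc:
            raise DataError(f"stage fit[{ds}]: {exc}") from exc
        clocks[ds] = summary.best_clock
        summaries[ds] = summary
        clock_path = out_dir / f"clock_{ds}.json"
        clock_mod.write_clock(summary.best_clock, clock_path)
        paths[f"clock_{ds}"] = clock_path
        summary_frames.append(summary.scheme_optima)
        try:
            importance = clock_mod.gene_importance(summary.best_clock)
        except DataError as exc:
            raise DataError(f"stage importance[{ds}]: {exc}") from exc
        imp_path = out_dir / f"importance_{ds}.tsv"
        importance.to_csv(imp_path, sep="\t", index=False)
        paths[f"importance_{ds}"] = imp_path

    summary_path = out_dir / "summary.tsv"
    pd.concat(summary_frames, ignore_index=True).to_csv(
        summary_path, sep="\t", index=False
    )
    paths["summary"] = summary_path

    if config.qc_sam is not None:
        try:
            cigars = read_sam_cigars(config.qc_sam)
            stats = [qc_mod.alignment_stats(c) for c in cigars]
            qc_df = pd.DataFrame([s.__dict__ for s in stats])
            summary_row = qc_mod.summarize_identity(stats, "all")
            qc_df.loc[len(qc_df)] = {
                "read_id": "MEDIAN",
                "matches": -1, "mismatches": -1, "insertions": -1, "deletions": -1,
                "accuracy": summary_row.median_accuracy,
                "identity": summary_row.median_identity,
            }
        except DataError as exc:
            raise DataError(f"stage qc: {exc}") from exc
        qc_path = out_dir / "qc.tsv"
        qc_df.to_csv(qc_path, sep="\t", index=False)
        paths["qc"] = qc_path

    log_path = out_dir / "run_counts.json"
    with open(log_path, "w") as fh:
        json.dump(counts.__dict__, fh, indent=1)
        fh.write("\n")
    paths["counts"] = log_path
    return RunResult(
        out_dir=out_dir,
        counts=counts,
        aging_sites=aging,
        clocks=clocks,
        summaries=summaries,
        paths=paths,
    )
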