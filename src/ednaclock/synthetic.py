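"""Synthetic methylation datasets with planted ground truth.

The generator emulates the statistical structure the analysis assumes for
a mitogenome-scale eDNA experiment: six larval ages (10-24 days
post-hatch), a few hundred sites on a ~16.6 kb circular reference, read
coverage near 3x (1 + Poisson draws), per-site reliability scores, and the
observed methylation-trajectory families:

* **spike** sites — fully methylated (level 100) at exactly one age and 0
  elsewhere, with the single methylated stage biased toward the youngest
  age (the dominant pattern in the real aging sites);
* **ramp** sites — level = a + b * age with slope b in a stated range
  (default 3-6 percentage points per day);
* **constant** sites — one fixed level at every age (non-differential);
* **incomplete** sites — coverage 0 at one or more ages, so they drop out
  of the complete-coverage filter;
* **conflict** sites — emitted as 5mC by the 5mC submodel and 5hmC by the
  CpG submodel, the contradiction the reconciliation step must drop.

Noise on emitted levels is additive Gaussian (sd in percentage points),
clipped to [0, 100] — a generator assumption, since real calling noise is
not characterized.  Everything is reproducible from the config seed.

The miniature annotation uses real mitochondrial gene names (ND1, COX1,
tRNA-Trp, ...) with synthetic coordinates, including the ATP8/ATP6 and
ND4L/ND4 overlaps typical of vertebrate mitogenomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .io import MethylSiteRecord, write_bedmethyl

DEFAULT_AGES = (10.0, 12.0, 14.0, 17.0, 19.0, 24.0)
DEFAULT_LENGTH = 16_600

#: (name, feature kind, 1-based start, 1-based end) — synthetic coordinates,
#: gene names and overlap structure modeled on a fish mitogenome.
DEFAULT_GENE_MAP: tuple[tuple[str, str, int, int], ...] = (
    ("tRNA-Phe", "tRNA", 1, 68),
    ("12S-rRNA", "rRNA", 69, 1090),
    ("tRNA-Val", "tRNA", 1091, 1162),
    ("16S-rRNA", "rRNA", 1163, 2850),
    ("tRNA-Leu1", "tRNA", 2851, 2924),
    ("ND1", "CDS", 2925, 3899),
    ("tRNA-Ile", "tRNA", 3910, 3979),
    ("tRNA-Gln", "tRNA", 3981, 4051),
    ("tRNA-Met", "tRNA", 4052, 4120),
    ("ND2", "CDS", 4121, 5166),
    ("tRNA-Trp", "tRNA", 5167, 5238),
    ("COX1", "CDS", 5470, 7020),
    ("tRNA-Asp", "tRNA", 7095, 7165),
    ("COX2", "CDS", 7180, 7870),
    ("ATP8", "CDS", 7946, 8113),
    ("ATP6", "CDS", 8104, 8786),  # overlaps ATP8 (shorter feature wins)
    ("COX3", "CDS", 8787, 9571),
    ("ND3", "CDS", 9643, 9991),
    ("ND4L", "CDS", 9992, 10288),
    ("ND4", "CDS", 10282, 11662),  # overlaps ND4L
    ("tRNA-His", "tRNA", 11663, 11731),
    ("ND5", "CDS", 11906, 13744),
    ("ND6", "CDS", 13741, 14262),
    ("CYTB", "CDS", 14336, 15476),
    ("tRNA-Thr", "tRNA", 15477, 15548),
    ("D-loop", "D-loop", 15700, 16500),
)

#: Modification-type mixture for planted sites, skewed toward 6mA with 5mC
#: dominating the cytosine fraction, as on the mitogenomic aging sites.
DEFAULT_MOD_MIXTURE = {"5mC": 0.35, "5hmC": 0.03, "other_modC": 0.07, "6mA": 0.55}


@dataclass
class SyntheticConfig:
    """Study conditions for one generated dataset."""

    ages: tuple[float, ...] = DEFAULT_AGES
    contig: str = "MT"
    length: int = DEFAULT_LENGTH
    gene_map: tuple[tuple[str, str, int, int], ...] = DEFAULT_GENE_MAP
    n_spike_sites: int = 5
    n_ramp_sites: int = 5
    n_constant_sites: int = 90
    n_incomplete_sites: int = 10
    n_conflict_sites: int = 6
    noise_sd: float = 0.0  # percentage points on methylation levels
    coverage_extra_mean: float = 2.0  # coverage = 1 + Poisson(this)
    reliability_range: tuple[float, float] = (0.8, 1.0)
    mod_mixture: dict = field(default_factory=lambda: dict(DEFAULT_MOD_MIXTURE))
    ramp_slope_range: tuple[float, float] = (3.0, 6.0)
    spike_first_age_weight: float = 0.5  # P(spike lands on the youngest age)
    seed: int = 0

    def __post_init__(self):
        if list(self.ages) != sorted(set(self.ages)):
            raise ValueError("ages must be strictly increasing")
        for name in (
            "n_spike_sites", "n_ramp_sites", "n_constant_sites",
            "n_incomplete_sites", "n_conflict_sites",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_sites(self) -> int:
        return (
            self.n_spike_sites
            + self.n_ramp_sites
            + self.n_constant_sites
            + self.n_incomplete_sites
            + self.n_conflict_sites
        )

    @property
    def samples(self) -> list[tuple[str, float]]:
        return [(f"dph{age:g}", age) for age in self.ages]


@dataclass
class GeneratedDataset:
    """Paths of the emitted files plus the planted truth table."""

    out_dir: Path
    bedmethyl_paths: dict[tuple[str, str], Path]  # (sample_id, submodel) -> path
    annotation_path: Path
    truth_path: Path
    truth: pd.DataFrame
    samples: list[tuple[str, float]]
    config: SyntheticConfig


def _true_levels(cls, config: SyntheticConfig, rng) -> np.ndarray:
    ages = np.asarray(config.ages)
    if cls == "spike":
        if rng.random() < config.spike_first_age_weight:
            idx = 0
        else:
            idx = int(rng.integers(0, len(ages)))
        levels = np.zeros(len(ages))
        levels[idx] = 100.0
        return levels
    if cls == "ramp":
        lo, hi = config.ramp_slope_range
        b = rng.uniform(lo, hi)
        a = rng.uniform(-b * ages[0], 100.0 - b * ages[-1])
        return a + b * ages
    # constant, incomplete and conflict sites carry one fixed level
    return np.full(len(ages), rng.uniform(5.0, 95.0))


def write_annotation(config: SyntheticConfig, path) -> None:
    """Write the miniature annotation as a GenBank flat file.

    Synthetic reference: the sequence is a placeholder (all ``A``); only
    the feature table and declared length matter downstream.
    """
    record = SeqRecord(
        Seq("A" * config.length),
        id="SYNMITO1",
        name="SYNMITO1",
        description="synthetic mitogenome-like reference (placeholder sequence)",
        annotations={"molecule_type": "DNA", "topology": "circular"},
    )
    for name, kind, start, end in config.gene_map:
        record.features.append(
            SeqFeature(
                FeatureLocation(start - 1, end),
                type=kind,
                qualifiers={"gene": [name]},
            )
        )
    SeqIO.write(record, str(path), "genbank")


def generate_dataset(config: SyntheticConfig, out_dir) -> GeneratedDataset:
    """Emit bedMethyl files (one per sample x submodel), a GenBank-style
    annotation, and the planted truth table."""
    if config.n_sites > config.length:
        raise ValueError(
            f"{config.n_sites} sites requested on a {config.length} bp reference"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    ages = list(config.ages)
    n_ages = len(ages)

    positions = np.sort(rng.choice(config.length, size=config.n_sites, replace=False) + 1)
    classes = (
        ["spike"] * config.n_spike_sites
        + ["ramp"] * config.n_ramp_sites
        + ["constant"] * config.n_constant_sites
        + ["incomplete"] * config.n_incomplete_sites
        + ["conflict"] * config.n_conflict_sites
    )
    rng.shuffle(classes)

    mod_names = sorted(config.mod_mixture)
    mod_probs = np.array([config.mod_mixture[m] for m in mod_names], dtype=float)
    mod_probs = mod_probs / mod_probs.sum()

    rows_by_file: dict[tuple[str, str], list[MethylSiteRecord]] = {}
    truth_rows = []
    for pos, cls in zip(positions, classes):
        pos = int(pos)
        mod_type = (
            "conflict"
            if cls == "conflict"
            else str(rng.choice(mod_names, p=mod_probs))
        )
        true = _true_levels(cls, config, rng)
        noise = (
            rng.normal(0.0, config.noise_sd, size=n_ages)
            if config.noise_sd > 0
            else np.zeros(n_ages)
        )
        emitted = np.clip(true + noise, 0.0, 100.0).round(2)
        coverage = 1 + rng.poisson(config.coverage_extra_mean, size=n_ages)
        if cls == "incomplete":
            n_missing = int(rng.integers(1, n_ages))
            missing = rng.choice(n_ages, size=n_missing, replace=False)
            coverage[missing] = 0
        scores = (rng.uniform(*config.reliability_range, size=n_ages) * 1000).astype(int)

        for ai, (sample_id, _age) in enumerate(config.samples):
            cov = int(coverage[ai])
            level = float(emitted[ai]) if cov > 0 else 0.0
            score = int(scores[ai])

            def emit(submodel: str, code: str, percent: float):
                rec = MethylSiteRecord(
                    contig=config.contig,
                    start=pos - 1,
                    end=pos,
                    mod_code=code,
                    strand="+",
                    score=score,
                    coverage=cov,
                    percent_modified=percent,
                    sample_id=sample_id,
                    submodel=submodel,
                )
                rows_by_file.setdefault((sample_id, submodel), []).append(rec)

            if mod_type == "6mA":
                emit("6mA", "a", level)
            elif mod_type == "5mC":
                emit("5mC", "m", level)
                emit("5mCG_5hmCG", "m", level)
            elif mod_type == "5hmC":
                emit("5mCG_5hmCG", "h", level)
                emit("5mC", "m", 0.0)
            elif mod_type == "other_modC":
                emit("5mC", "C", level)
            else:  # conflict: contradictory characterizations
                emit("5mC", "m", level)
                emit("5mCG_5hmCG", "h", level)

        truth_rows.append(
            {
                "contig": config.contig,
                "position": pos,
                "strand": "+",
                "planted_class": cls,
                "mod_type": mod_type,
                **{f"level_{a:g}": float(t) for a, t in zip(ages, true)},
                **{f"coverage_{a:g}": int(c) for a, c in zip(ages, coverage)},
            }
        )

    bedmethyl_paths: dict[tuple[str, str], Path] = {}
    for sample_id, _age in config.samples:
        for submodel in ("5mC", "5mCG_5hmCG", "6mA"):
            path = out_dir / f"{sample_id}_{submodel}.bed"
            write_bedmethyl(rows_by_file.get((sample_id, submodel), []), path)
            bedmethyl_paths[(sample_id, submodel)] = path

    annotation_path = out_dir / "annotation.gb"
    write_annotation(config, annotation_path)

    truth = pd.DataFrame(truth_rows)
    truth_path = out_dir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    return GeneratedDataset(
        out_dir=out_dir,
        bedmethyl_paths=bedmethyl_paths,
        annotation_path=annotation_path,
        truth_path=truth_path,
        truth=truth,
        samples=config.samples,
        config=config,
    )


def generate_alignments(
    n_reads: int,
    read_length: int,
    mismatch_prob: float,
    indel_prob: float,
    seed: int,
    out_path,
) -> pd.DataFrame:
    """Write a SAM file of synthetic alignments with per-base mismatch and
    indel draws; returns the per-read truth (operation counts)."""
    if not (0 <= mismatch_prob < 1 and 0 <= indel_prob < 1):
        raise ValueError("probabilities must be in [0, 1)")
    rng = np.random.default_rng(seed)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": "synthetic_ref", "LN": max(read_length * 3, 1000)}],
    }
    truth_rows = []
    with pysam.AlignmentFile(str(out_path), "w", header=header) as fh:
        for i in range(n_reads):
            draws = rng.random(read_length)
            events = np.where(draws < indel_prob, 3, 0)  # 3: indel slot
            aligned = events == 0
            mism = rng.random(read_length) < mismatch_prob
            events[aligned & mism] = 1  # X
            # indel slots alternate between insertion and deletion
            indel_slots = np.flatnonzero(events == 3)
            for j, slot in enumerate(indel_slots):
                events[slot] = 2 if j % 2 else 4  # 2: D, 4: I
            op_of = {0: "=", 1: "X", 2: "D", 4: "I"}
            cigar = []
            for ev in events:
                op = op_of[int(ev)]
                if cigar and cigar[-1][0] == op:
                    cigar[-1][1] += 1
                else:
                    cigar.append([op, 1])
            cigarstring = "".join(f"{c}{o}" for o, c in cigar)
            qlen = int(np.sum((events == 0) | (events == 1) | (events == 4)))
            aln = pysam.AlignedSegment()
            aln.query_name = f"read{i}"
            aln.flag = 0
            aln.reference_id = 0
            aln.reference_start = 0
            aln.mapping_quality = 60
            aln.cigarstring = cigarstring
            aln.query_sequence = "A" * qlen
            counts = {
                "=": int(np.sum(events == 0)),
                "X": int(np.sum(events == 1)),
                "D": int(np.sum(events == 2)),
                "I": int(np.sum(events == 4)),
            }
            aln.set_tag("NM", counts["X"] + counts["I"] + counts["D"])
            fh.write(aln)
            truth_rows.append({"read_id": f"read{i}", **counts})
    return pd.DataFrame(truth_rows)


def planted_preset(seed: int = 0) -> SyntheticConfig:
    """Noise-free planted-trajectory benchmark: 5 spike + 5 ramp aging
    sites among 90 constant, 10 incompletely covered and 6 conflicting
    sites — the exact-recovery fixture."""
    return SyntheticConfig(
        n_spike_sites=5,
        n_ramp_sites=5,
        n_constant_sites=90,
        n_incomplete_sites=10,
        n_conflict_sites=6,
        noise_sd=0.0,
        seed=seed,
    )


def linear_signal_preset(seed: int = 0) -> SyntheticConfig:
    """Parameter-recovery benchmark: 6 ages, 20 ramp (signal) sites and
    480 nuisance sites (spikes at one random age plus constants), noise sd
    5 percentage points."""
    return SyntheticConfig(
        n_spike_sites=240,
        n_ramp_sites=20,
        n_constant_sites=240,
        n_incomplete_sites=0,
        n_conflict_sites=0,
        noise_sd=5.0,
        spike_first_age_weight=0.0,  # nuisance spikes land on any age
        seed=seed,
    )
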