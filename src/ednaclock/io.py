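"""Readers and writers for the external formats the pipeline touches.

bedMethyl summaries (as written by modbam2bed), GenBank feature tables of a
reference mitogenome, SAM alignments (CIGAR extraction for QC), and JSON
serialization of fitted clocks.

Coordinate conventions: bedMethyl is 0-based half-open (BED); GenBank is
1-based inclusive.  Every internal position is normalized to a 1-based
single-base position at ingestion (``MethylSiteRecord.position``), because
the gene-annotation join downstream is 1-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pysam
from Bio import SeqIO

from .errors import BedMethylParseError, GenBankFormatError

logger = logging.getLogger(__name__)

#: Accepted single-letter modified-base codes (bedMethyl column 4).
MOD_CODES = {
    "m": "5mC",
    "h": "5hmC",
    "C": "modC",  # ambiguous modified cytosine
    "a": "6mA",
}

#: The three modification-calling submodels whose summaries we consume.
SUBMODELS = ("5mC", "5mCG_5hmCG", "6mA")


@dataclass(frozen=True)
class MethylSiteRecord:
    """One summarized genomic position from one sample and one submodel.

    ``score`` is the raw bedMethyl score in [0, 1000]; ``reliability``
    exposes it as a fraction in [0, 1] (proportion of reads whose
    modification call was unambiguous at this site).
    """

    contig: str
    start: int  # 0-based
    end: int
    mod_code: str
    strand: str
    score: int
    coverage: int
    percent_modified: float
    sample_id: str
    submodel: str

    def __post_init__(self):
        if not 0.0 <= self.percent_modified <= 100.0:
            raise BedMethylParseError(
                f"percent modified {self.percent_modified} outside [0, 100]"
            )
        if not 0 <= self.score <= 1000:
            raise BedMethylParseError(f"score {self.score} outside [0, 1000]")
        if self.coverage < 0:
            raise BedMethylParseError(f"negative coverage {self.coverage}")
        if self.end != self.start + 1:
            raise BedMethylParseError(
                f"expected single-base interval, got [{self.start}, {self.end})"
            )

    @property
    def position(self) -> int:
        """1-based single-base position."""
        return self.start + 1

    @property
    def reliability(self) -> float:
        return self.score / 1000.0


@dataclass(frozen=True)
class GeneInterval:
    """A 1-based inclusive interval of the reference, labeled with a gene
    (or ``NC<k>`` for non-annotated, "non-coding" gaps)."""

    name: str
    start: int
    end: int
    feature_kind: str  # CDS | tRNA | rRNA | D-loop | NC

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class CigarOps:
    """Per-read CIGAR operation counts plus the NM tag when present."""

    read_id: str
    ops: dict[str, int] = field(default_factory=dict)
    nm: int | None = None

    def get(self, op: str) -> int:
        return self.ops.get(op, 0)


def read_bedmethyl(path, sample_id: str, submodel: str) -> list[MethylSiteRecord]:
    """Parse a bedMethyl file into records.

    Expects tab-separated rows with at least 11 columns (BED9 + valid
    coverage + percent modified).  Rows with coverage 0 are retained; they
    are filtered downstream by the coverage-completeness step.
    """
    if not sample_id or not submodel:
        raise ValueError("sample_id and submodel must be non-empty")
    records: list[MethylSiteRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise BedMethylParseError(
                    f"{path}: line {lineno}: expected >= 11 tab-separated "
                    f"columns, got {len(fields)}"
                )
            mod_code = fields[3]
            if mod_code not in MOD_CODES:
                raise BedMethylParseError(
                    f"{path}: line {lineno}: unknown modification code "
                    f"{mod_code!r}; accepted codes: {sorted(MOD_CODES)}"
                )
            try:
                record = MethylSiteRecord(
                    contig=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    mod_code=mod_code,
                    strand=fields[5],
                    score=int(fields[4]),
                    coverage=int(fields[9]),
                    percent_modified=float(fields[10]),
                    sample_id=sample_id,
                    submodel=submodel,
                )
            except ValueError as exc:
                raise BedMethylParseError(
                    f"{path}: line {lineno}: {exc}"
                ) from exc
            records.append(record)
    return records


def write_bedmethyl(records, path) -> None:
    """Serialize records as bedMethyl; numeric columns survive a read/write
    round trip exactly (percent is written with 2 decimals, the precision
    the summaries carry)."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.contig,
                        str(r.start),
                        str(r.end),
                        r.mod_code,
                        str(r.score),
                        r.strand,
                        str(r.start),
                        str(r.end),
                        "0,0,0",
                        str(r.coverage),
                        f"{r.percent_modified:.2f}",
                    ]
                )
                + "\n"
            )


# GenBank feature extraction ------------------------------------------------

_KIND_PRECEDENCE = {"CDS": 0, "tRNA": 1, "rRNA": 2, "D-loop": 3}


def _feature_name(feature) -> str:
    for key in ("gene", "product", "locus_tag"):
        if key in feature.qualifiers:
            return str(feature.qualifiers[key][0])
    return feature.type


def read_genbank_features(path) -> list[GeneInterval]:
    """Extract CDS/tRNA/rRNA/D-loop intervals from a GenBank flat file and
    tile the remainder with ``NC<k>`` gaps so every position of the declared
    sequence receives exactly one label.

    Overlaps are resolved with precedence CDS > tRNA > rRNA > D-loop;
    within equal kinds the shorter feature wins.  Origin-spanning compound
    features are split into one interval per part, sharing the name.
    """
    try:
        record = SeqIO.read(path, "genbank")
    except Exception as exc:
        raise GenBankFormatError(f"{path}: not a parseable GenBank file: {exc}") from exc
    length = len(record.seq)
    if length == 0:
        raise GenBankFormatError(f"{path}: zero-length sequence")

    # Collect (kind, name, parts) for the feature kinds we annotate with.
    annotated = []
    for feature in record.features:
        if feature.type not in _KIND_PRECEDENCE:
            continue
        parts = [(int(p.start) + 1, int(p.end)) for p in feature.location.parts]
        annotated.append((feature.type, _feature_name(feature), parts))

    # Paint positions lowest precedence first and, within a kind, longest
    # first, so the highest-precedence / shortest feature ends up on top.
    def total_len(parts):
        return sum(e - s + 1 for s, e in parts)

    annotated.sort(
        key=lambda t: (-_KIND_PRECEDENCE[t[0]], -total_len(t[2]))
    )
    labels: list[tuple[str, str] | None] = [None] * (length + 1)  # 1-based
    for kind, name, parts in annotated:
        for s, e in parts:
            if s < 1 or e > length:
                raise GenBankFormatError(
                    f"{path}: feature {name} [{s}, {e}] outside sequence 1..{length}"
                )
            for pos in range(s, e + 1):
                labels[pos] = (name, kind)

    # Run-length encode into intervals, numbering NC gaps left to right.
    intervals: list[GeneInterval] = []
    nc_counter = 0
    pos = 1
    while pos <= length:
        label = labels[pos]
        run_end = pos
        while run_end + 1 <= length and labels[run_end + 1] == label:
            run_end += 1
        if label is None:
            nc_counter += 1
            intervals.append(GeneInterval(f"NC{nc_counter}", pos, run_end, "NC"))
        else:
            intervals.append(GeneInterval(label[0], pos, run_end, label[1]))
        pos = run_end + 1
    return intervals


# SAM / CIGAR extraction ----------------------------------------------------

_CIGAR_OPS = "MIDNSHP=X"


def read_sam_cigars(path, include_secondary: bool = False) -> list[CigarOps]:
    """Extract per-read CIGAR operation counts from a SAM/BAM file.

    Unmapped records and records without a CIGAR are skipped (counted in a
    warning); secondary and supplementary alignments are excluded unless
    ``include_secondary`` is set.
    """
    out: list[CigarOps] = []
    n_skipped = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                n_skipped += 1
                continue
            if not include_secondary and (aln.is_secondary or aln.is_supplementary):
                n_skipped += 1
                continue
            if aln.cigartuples is None:
                n_skipped += 1
                continue
            ops: dict[str, int] = {}
            for code, count in aln.cigartuples:
                op = _CIGAR_OPS[code]
                ops[op] = ops.get(op, 0) + count
            nm = aln.get_tag("NM") if aln.has_tag("NM") else None
            out.append(CigarOps(read_id=aln.query_name, ops=ops, nm=nm))
    if n_skipped:
        logger.warning(
            "%s: skipped %d unmapped/secondary/CIGAR-less records", path, n_skipped
        )
    return out


# Clock serialization (thin wrappers; schema lives with FittedClock) --------


def write_clock(clock, path) -> None:
    """Serialize a fitted clock to JSON (lossless round trip)."""
    from .clock import write_clock as _write

    _write(clock, path)


def read_clock(path):
    """Load a fitted clock from JSON, checking the embedded version tag."""
    from .clock import read_clock as _read

    return _read(path)
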