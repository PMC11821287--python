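"""Mapping-quality metrics from CIGAR operation counts.

Two read-level metrics common in long-read sequencing:

* **read accuracy** — matches / alignment length, where the alignment
  length includes mismatches and gap bases (insertions + deletions);
* **read identity** — matches / aligned bases, gaps excluded.

Identity >= accuracy always, with equality exactly when the alignment has
no indels.  Soft/hard clips and reference skips (N) are excluded from both
denominators.  When a CIGAR uses M (alignment match) instead of =/X, the
mismatch count is recovered from the NM tag (NM minus inserted and deleted
bases); when both =/X and NM are present, =/X wins.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass

from .errors import DataError
from .io import CigarOps


@dataclass(frozen=True)
class AlignmentStats:
    read_id: str
    matches: int
    mismatches: int
    insertions: int
    deletions: int
    accuracy: float
    identity: float


@dataclass(frozen=True)
class IdentitySummary:
    sample_id: str
    n_reads: int
    median_accuracy: float
    median_identity: float
    median_error_rate: float  # 1 - median identity
    accuracies: tuple[float, ...]
    identities: tuple[float, ...]


def _match_mismatch(ops: CigarOps) -> tuple[int, int]:
    eq, x = ops.get("="), ops.get("X")
    ins, dele = ops.get("I"), ops.get("D")
    if eq or x:
        return eq, x
    m = ops.get("M")
    if m:
        if ops.nm is None:
            raise DataError(
                f"read {ops.read_id}: M-only CIGAR without NM tag — "
                "matches indeterminable"
            )
        mismatches = ops.nm - ins - dele
        if mismatches < 0 or mismatches > m:
            raise DataError(
                f"read {ops.read_id}: NM tag ({ops.nm}) inconsistent with "
                f"CIGAR (M={m}, I={ins}, D={dele})"
            )
        return m - mismatches, mismatches
    raise DataError(f"read {ops.read_id}: no aligned bases in CIGAR")


def alignment_stats(ops: CigarOps) -> AlignmentStats:
    matches, mismatches = _match_mismatch(ops)
    ins, dele = ops.get("I"), ops.get("D")
    aligned = matches + mismatches
    if aligned == 0 and ins == 0 and dele == 0:
        raise DataError(f"read {ops.read_id}: empty alignment")
    alen = aligned + ins + dele
    return AlignmentStats(
        read_id=ops.read_id,
        matches=matches,
        mismatches=mismatches,
        insertions=ins,
        deletions=dele,
        accuracy=matches / alen,
        identity=matches / aligned if aligned else 0.0,
    )


def read_accuracy(ops: CigarOps) -> float:
    """Matches over the alignment length (gaps count in the denominator)."""
    return alignment_stats(ops).accuracy


def read_identity(ops: CigarOps) -> float:
    """Matches over aligned bases (gaps excluded from the denominator)."""
    return alignment_stats(ops).identity


def summarize_identity(stats: list[AlignmentStats], sample_id: str) -> IdentitySummary:
    """Per-sample medians of accuracy and identity, plus the median
    basecalling-error proxy ``1 - median identity``.  The raw per-read
    values are carried along for density plots."""
    if not stats:
        raise DataError(f"sample {sample_id}: no reads to summarize")
    accuracies = tuple(s.accuracy for s in stats)
    identities = tuple(s.identity for s in stats)
    med_id = statistics.median(identities)
    return IdentitySummary(
        sample_id=sample_id,
        n_reads=len(stats),
        median_accuracy=statistics.median(accuracies),
        median_identity=med_id,
        median_error_rate=1.0 - med_id,
        accuracies=accuracies,
        identities=identities,
    )
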