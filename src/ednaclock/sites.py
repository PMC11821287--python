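"""From per-submodel methylation records to the clock design matrix.

The stages, in pipeline order:

1. ``reconcile_modtypes`` — merge records from the three calling submodels
   (5mC; 5mCG_5hmCG, i.e. CpG-context 5mC/5hmC; 6mA) into one canonical
   modification type per site.  A cytosine site called 5mC by the 5mC
   submodel *and* 5hmC by the CpG submodel is contradictory and dropped
   (counted).  Modified cytosines characterized as neither 5mC nor 5hmC
   become "other_modC".
2. ``filter_complete_coverage`` — keep sites covered at every age of
   interest (differential methylation is undefined otherwise).
3. ``detect_aging_sites`` — keep sites whose methylation-level vector is
   not constant across ages ("at least one unequal methylation level",
   evaluated literally on the parsed 2-decimal percentages, no test).
4. ``annotate_genes`` / ``build_design_matrix`` — attach gene labels and
   assemble the samples x sites matrix with the four per-site features
   (gene, modification type, mean coverage, mean reliability).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import DataError
from .io import GeneInterval, MethylSiteRecord

MOD_TYPES = ("5mC", "5hmC", "other_modC", "6mA")

#: Dataset variants for clock fitting (aliases accepted).
DATASET_MODTYPES = {
    "full": frozenset(MOD_TYPES),
    "modC": frozenset({"5mC", "5hmC", "other_modC"}),
    "modC_only": frozenset({"5mC", "5hmC", "other_modC"}),
    "modA": frozenset({"6mA"}),
    "modA_only": frozenset({"6mA"}),
}

# Preferred (submodel, code) source of the level vector for "other modC"
# sites, i.e. modified cytosines characterized as neither 5mC nor 5hmC.
_OTHER_MODC_PRECEDENCE = (
    ("5mC", "C"),
    ("5mCG_5hmCG", "C"),
    ("5mCG_5hmCG", "m"),
    ("5mC", "m"),
    ("5mCG_5hmCG", "h"),
)


@dataclass(frozen=True)
class ReconciledSite:
    """A genomic position with a single canonical modification type and
    per-age methylation summaries (vectors share the ordered age index)."""

    contig: str
    position: int  # 1-based
    strand: str
    mod_type: str
    ages: tuple[float, ...]
    levels: tuple[float, ...]  # % modified per age
    coverage: tuple[int, ...]
    reliability: tuple[float, ...]  # score/1000 per age; nan where absent
    gene: str | None = None

    @property
    def site_key(self) -> tuple[str, int, str]:
        return (self.contig, self.position, self.strand)

    @property
    def mean_coverage(self) -> float:
        return float(np.mean(self.coverage))

    @property
    def mean_reliability(self) -> float:
        return float(np.nanmean(np.asarray(self.reliability, dtype=float)))


@dataclass
class ReconcileResult:
    sites: list[ReconciledSite]
    n_conflicts_dropped: int


def reconcile_modtypes(
    records: list[MethylSiteRecord],
    samples: list[tuple[str, float]],
    collapse_strand: bool = False,
) -> ReconcileResult:
    """Assign each site one canonical modification type across submodels.

    ``samples`` is the ordered list of ``(sample_id, age_dph)`` pairs that
    defines the age index of every per-site vector.  Sites on + and - at
    the same position are distinct unless ``collapse_strand`` is set
    (mirrors the per-strand vs. aggregate summary modes).
    """
    if not samples:
        raise ValueError("samples must be non-empty")
    sample_ids = [s for s, _ in samples]
    ages = tuple(float(a) for _, a in samples)
    wanted = set(sample_ids)

    grouped: dict[tuple, dict[tuple, dict[str, MethylSiteRecord]]] = {}
    for rec in records:
        if rec.sample_id not in wanted:
            continue
        strand = "." if collapse_strand else rec.strand
        key = (rec.contig, rec.position, strand)
        grouped.setdefault(key, {}).setdefault(
            (rec.submodel, rec.mod_code), {}
        )[rec.sample_id] = rec

    sites: list[ReconciledSite] = []
    n_conflicts = 0
    for key in sorted(grouped):
        by_source = grouped[key]
        has_adenine = any(code == "a" for _, code in by_source)
        has_cytosine = any(code in ("m", "h", "C") for _, code in by_source)
        if has_adenine and has_cytosine:
            raise DataError(
                f"site {key}: both adenine and cytosine modification codes"
            )

        def labeled(submodel: str, code: str) -> bool:
            recs = by_source.get((submodel, code), {})
            return any(r.percent_modified > 0 for r in recs.values())

        if has_adenine:
            mod_type, source = "6mA", ("6mA", "a")
        else:
            is_m = labeled("5mC", "m")
            is_h = labeled("5mCG_5hmCG", "h")
            if is_m and is_h:
                n_conflicts += 1
                continue
            if is_m:
                mod_type, source = "5mC", ("5mC", "m")
            elif is_h:
                mod_type, source = "5hmC", ("5mCG_5hmCG", "h")
            else:
                mod_type = "other_modC"
                source = next(
                    (s for s in _OTHER_MODC_PRECEDENCE if s in by_source),
                    sorted(by_source)[0],
                )

        per_sample = by_source.get(source, {})
        levels, coverage, reliability = [], [], []
        for sid in sample_ids:
            rec = per_sample.get(sid)
            if rec is None:
                levels.append(0.0)
                coverage.append(0)
                reliability.append(float("nan"))
            else:
                levels.append(rec.percent_modified)
                coverage.append(rec.coverage)
                reliability.append(rec.reliability)
        sites.append(
            ReconciledSite(
                contig=key[0],
                position=key[1],
                strand=key[2],
                mod_type=mod_type,
                ages=ages,
                levels=tuple(levels),
                coverage=tuple(coverage),
                reliability=tuple(reliability),
            )
        )
    return ReconcileResult(sites=sites, n_conflicts_dropped=n_conflicts)


def filter_complete_coverage(
    sites: list[ReconciledSite], min_coverage: int = 1
) -> list[ReconciledSite]:
    """Keep sites covered at >= ``min_coverage`` reads at every age."""
    return [s for s in sites if all(c >= min_coverage for c in s.coverage)]


def detect_aging_sites(sites: list[ReconciledSite]) -> list[ReconciledSite]:
    """Keep differentially methylated sites: at least one unequal
    methylation level across ages (literal inequality at the parsed
    2-decimal precision, no statistical test)."""
    out = []
    for s in sites:
        rounded = {round(v, 2) for v in s.levels}
        if len(rounded) > 1:
            out.append(s)
    return out


def annotate_genes(
    sites: list[ReconciledSite], intervals: list[GeneInterval]
) -> list[ReconciledSite]:
    """Label each site with the gene interval containing its position.

    ``intervals`` must partition [1, L]; a site outside that range is a
    data error.
    """
    ordered = sorted(intervals, key=lambda iv: iv.start)
    starts = [iv.start for iv in ordered]
    length = max(iv.end for iv in ordered)
    out = []
    for s in sites:
        if not 1 <= s.position <= length:
            raise DataError(
                f"site {s.site_key}: position outside reference [1, {length}]"
            )
        idx = bisect.bisect_right(starts, s.position) - 1
        iv = ordered[idx]
        if not iv.start <= s.position <= iv.end:
            raise DataError(
                f"site {s.site_key}: no interval covers position {s.position}"
            )
        out.append(replace(s, gene=iv.name))
    return out


def aging_site_density(
    sites: list[ReconciledSite], intervals: list[GeneInterval]
) -> pd.DataFrame:
    """Aging sites per gene relative to gene length (density report)."""
    counts: dict[str, int] = {}
    for s in sites:
        if s.gene is None:
            raise ValueError("sites must be annotated before density report")
        counts[s.gene] = counts.get(s.gene, 0) + 1
    rows = []
    for iv in intervals:
        n = counts.get(iv.name, 0)
        rows.append(
            {
                "gene": iv.name,
                "feature_kind": iv.feature_kind,
                "gene_length": iv.length,
                "n_aging_sites": n,
                "density": n / iv.length,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ClockDesignMatrix:
    """Samples x aging-sites methylation matrix with site metadata.

    Rows follow the ordered ages (the response ``y``); columns follow the
    stable lexicographic site order (contig, position, strand, mod_type)
    recorded in ``metadata``.
    """

    ages: np.ndarray  # (n_samples,)
    X: np.ndarray  # (n_samples, n_sites), methylation %
    metadata: pd.DataFrame  # one row per column of X

    @property
    def n_sites(self) -> int:
        return self.X.shape[1]

    @property
    def site_keys(self) -> list[str]:
        return list(self.metadata["site_key"])


def site_key_str(site: ReconciledSite) -> str:
    return f"{site.contig}:{site.position}:{site.strand}"


def build_design_matrix(
    sites: list[ReconciledSite], dataset: str = "full"
) -> ClockDesignMatrix:
    """Assemble the design matrix for one dataset variant.

    ``dataset`` is ``full`` (all modification types), ``modC`` (5mC, 5hmC,
    other modC) or ``modA`` (6mA only).
    """
    if dataset not in DATASET_MODTYPES:
        raise ValueError(
            f"unknown dataset {dataset!r}; expected one of "
            f"{sorted(set(DATASET_MODTYPES))}"
        )
    allowed = DATASET_MODTYPES[dataset]
    kept = [s for s in sites if s.mod_type in allowed]
    if not kept:
        raise DataError(f"no aging sites left for dataset variant {dataset!r}")
    ages_sets = {s.ages for s in kept}
    if len(ages_sets) != 1:
        raise DataError("sites disagree on the age index")
    kept.sort(key=lambda s: (s.contig, s.position, s.strand, s.mod_type))
    X = np.array([s.levels for s in kept], dtype=float).T
    ages = np.array(kept[0].ages, dtype=float)
    metadata = pd.DataFrame(
        {
            "site_key": [site_key_str(s) for s in kept],
            "contig": [s.contig for s in kept],
            "position": [s.position for s in kept],
            "strand": [s.strand for s in kept],
            "mod_type": [s.mod_type for s in kept],
            "gene": [s.gene if s.gene is not None else "NA" for s in kept],
            "mean_coverage": [s.mean_coverage for s in kept],
            "mean_reliability": [s.mean_reliability for s in kept],
        }
    )
    return ClockDesignMatrix(ages=ages, X=X, metadata=metadata)
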