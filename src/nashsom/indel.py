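"""Post-prediction somatic indel filtering.

Candidate indels arrive as precomputed per-candidate summaries (coverage,
support-read statistics); this module applies the six filter criteria plus
a known-variant-sites exclusion.  A candidate FAILS a criterion when:

1. ``coverage``    — total coverage at the site < 30x;
2. ``map_qual``    — mean mapping quality of indel-supporting reads < 30;
3. ``mismatches``  — mean mismatches per supporting read >= 2;
4. ``base_qual``   — mean base quality of supporting reads < 20;
5. ``end_offset``  — median offset of the indel from the nearer read end
   within 10 bp (<= 10 fails);
6. ``strand_bias`` — the smaller of the forward/reverse supporting-read
   fractions < 20%;
plus ``known_site`` when the exact (chrom, pos, ref, alt) appears in the
known-sites list (the stand-in for a germline variant database).

Boundary semantics are literal: coverage 29 fails and 30 passes; exactly 2
mean mismatches fails; median offset exactly 10 fails; strand fraction
exactly 0.20 passes.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .io import IntegrityError, VariantRecord

__all__ = ["IndelParams", "IndelCandidate", "IndelVerdict", "INDEL_CRITERIA",
           "filter_indel", "filter_indels", "candidates_from_frame",
           "verdicts_to_records", "INDEL_FILTER_DESCRIPTIONS"]

logger = logging.getLogger(__name__)

INDEL_CRITERIA = ("coverage", "map_qual", "mismatches", "base_qual",
                  "end_offset", "strand_bias")

INDEL_FILTER_DESCRIPTIONS = {
    "coverage": "Total coverage at the site < 30x",
    "map_qual": "Mean mapping quality of indel-supporting reads < 30",
    "mismatches": "Mean mismatches per indel-supporting read >= 2",
    "base_qual": "Mean base quality of indel-supporting reads < 20",
    "end_offset": "Median indel offset within 10bp of read ends",
    "strand_bias": "Forward- or reverse-aligned supporting fraction < 20%",
    "known_site": "Locus present in the known-variant-sites list",
}


@dataclass
class IndelParams:
    min_coverage: int = 30
    min_mapq: float = 30.0
    max_mismatches: float = 2.0       # >= this many mean mismatches fails
    min_baseq: float = 20.0
    end_offset_max: int = 10          # median offset <= this fails
    min_strand_frac: float = 0.20


@dataclass(frozen=True)
class IndelCandidate:
    """Summary statistics of one candidate indel in one tumor sample."""

    sample: str
    chrom: str
    pos: int                 # anchor base before the event, 1-based
    ref: str
    alt: str
    total_coverage: int
    n_support: int
    avg_mapq_support: float
    avg_mismatches_support: float
    avg_baseq_support: float
    median_end_offset: float
    frac_forward_support: float
    frac_reverse_support: float

    def __post_init__(self) -> None:
        if self.total_coverage < 0 or self.n_support < 0:
            raise ValueError("counts must be non-negative")
        if self.n_support > 0:
            total = self.frac_forward_support + self.frac_reverse_support
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"strand fractions must sum to 1, got {total} at "
                    f"{self.chrom}:{self.pos}")


@dataclass
class IndelVerdict:
    candidate: IndelCandidate
    verdicts: dict[str, bool] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(self.verdicts.values())

    @property
    def failed_criteria(self) -> list[str]:
        order = (*INDEL_CRITERIA, "known_site")
        return [c for c in order if not self.verdicts.get(c, True)]

    @property
    def filter_status(self) -> str:
        return "PASS" if self.passed else ";".join(self.failed_criteria)


def filter_indel(candidate: IndelCandidate,
                 params: IndelParams | None = None,
                 known_sites: set[tuple[str, int, str, str]] | None = None
                 ) -> IndelVerdict:
    """Apply all six criteria plus known-sites exclusion to one candidate."""
    params = params or IndelParams()
    known_sites = known_sites or set()
    c = candidate
    if c.n_support == 0:
        raise ValueError(f"candidate at {c.chrom}:{c.pos} has no supporting reads")
    verdicts = {
        "coverage": c.total_coverage >= params.min_coverage,
        "map_qual": c.avg_mapq_support >= params.min_mapq,
        "mismatches": c.avg_mismatches_support < params.max_mismatches,
        "base_qual": c.avg_baseq_support >= params.min_baseq,
        "end_offset": c.median_end_offset > params.end_offset_max,
        "strand_bias": min(c.frac_forward_support,
                           c.frac_reverse_support) >= params.min_strand_frac,
        "known_site": (c.chrom, c.pos, c.ref, c.alt) not in known_sites,
    }
    return IndelVerdict(c, verdicts)


def candidates_from_frame(df: pd.DataFrame) -> list[IndelCandidate]:
    """Parse a candidates table (the candidates TSV layout) into objects."""
    fields = ["sample", "chrom", "pos", "ref", "alt", "total_coverage",
              "n_support", "avg_mapq_support", "avg_mismatches_support",
              "avg_baseq_support", "median_end_offset",
              "frac_forward_support", "frac_reverse_support"]
    missing = set(fields) - set(df.columns)
    if missing:
        raise ValueError(f"candidates table missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(IndelCandidate(
            sample=str(row["sample"]), chrom=str(row["chrom"]), pos=int(row["pos"]),
            ref=str(row["ref"]), alt=str(row["alt"]),
            total_coverage=int(row["total_coverage"]),
            n_support=int(row["n_support"]),
            avg_mapq_support=float(row["avg_mapq_support"]),
            avg_mismatches_support=float(row["avg_mismatches_support"]),
            avg_baseq_support=float(row["avg_baseq_support"]),
            median_end_offset=float(row["median_end_offset"]),
            frac_forward_support=float(row["frac_forward_support"]),
            frac_reverse_support=float(row["frac_reverse_support"])))
    return out


def filter_indels(candidates: Iterable[IndelCandidate],
                  params: IndelParams | None = None,
                  known_sites: set[tuple[str, int, str, str]] | None = None
                  ) -> list[IndelVerdict]:
    """Batch filtering: sorted verdicts plus a per-criterion failure tally.

    Candidates duplicated on (sample, chrom, pos, ref, alt) raise
    :class:`IntegrityError`; input order does not affect the output.
    """
    cands = sorted(candidates, key=lambda c: (c.chrom, c.pos, c.sample, c.alt))
    keys = [(c.sample, c.chrom, c.pos, c.ref, c.alt) for c in cands]
    if len(keys) != len(set(keys)):
        dup = next(k for k in keys if keys.count(k) > 1)
        raise IntegrityError(f"duplicate indel candidate {dup}")
    verdicts = [filter_indel(c, params, known_sites) for c in cands]
    tally: Counter[str] = Counter()
    for v in verdicts:
        for crit in v.failed_criteria:
            tally[crit] += 1
    logger.info("filter_indels: %d candidates, %d PASS; failures per criterion: %s",
                len(verdicts), sum(v.passed for v in verdicts), dict(tally))
    return verdicts


def verdicts_to_records(verdicts: Sequence[IndelVerdict]) -> list[VariantRecord]:
    records = []
    for v in verdicts:
        c = v.candidate
        ann = {"SAMPLE": c.sample, "COV": c.total_coverage, "NSUP": c.n_support}
        records.append(VariantRecord(c.chrom, c.pos, c.ref, c.alt, c.sample,
                                     v.filter_status, ann))
    return records
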