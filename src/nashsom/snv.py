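"""Tumor/normal somatic SNV calling as a seven-stage filter cascade.

A candidate site passes only if every stage passes; every stage is always
evaluated (no short-circuiting) so each call carries a complete filter
profile:

1. ``allele_freq`` — tumor alt fraction above 15% and normal alt fraction
   at most 2%, both over high-quality (Q > 10) reads;
2. ``tn_fisher`` — Fisher's exact test on (alt, ref) x (tumor, normal),
   one-sided for alt enrichment in tumor, p < 0.05;
3. ``coverage`` — high-quality depth of at least 10 reads in both samples;
4. ``seq_error`` — binomial tail test against a sequencing-error rate of
   f = 0.1, pass when p > 0.01 (lower-tail orientation: see
   :mod:`nashsom.stats`);
5. ``baseq_rank`` — Wilcoxon rank-sum of alt vs ref base qualities in the
   tumor, one-sided for *lower* alt quality, pass when p > 0.01;
6. ``repeat_align`` — Fisher test for alt enrichment among repeat-aligned
   (multi-mapping) reads, pass when p > 0.01;
7. ``end_bias`` — Fisher test for alt enrichment within 10 bases of either
   read end, pass when p > 0.01.

Thresholds are strict or inclusive exactly as stated: ">15%" strict,
"no more than 2%" inclusive, ">=10x" inclusive, "p > 0.01" strict.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import stats
from .io import PairedSite, SitePileup, VariantRecord

__all__ = ["SnvParams", "SnvCall", "STAGES", "select_alt_allele",
           "apply_cascade", "call_snvs", "calls_to_records", "FILTER_DESCRIPTIONS"]

logger = logging.getLogger(__name__)

#: Cascade stages in evaluation order.
STAGES = ("allele_freq", "tn_fisher", "coverage", "seq_error",
          "baseq_rank", "repeat_align", "end_bias")

FILTER_DESCRIPTIONS = {
    "allele_freq": "Tumor alt fraction <= 15% or normal alt fraction > 2% (high-quality reads)",
    "tn_fisher": "Tumor-vs-normal Fisher exact test not significant (p >= 0.05)",
    "coverage": "High-quality (Q>10) coverage below 10x in tumor or normal",
    "seq_error": "Alt support consistent with sequencing error (binomial tail p <= 0.01 at f=0.1)",
    "baseq_rank": "Alt base qualities lower than ref (Wilcoxon p <= 0.01)",
    "repeat_align": "Alt alleles enriched in repeat-aligned reads (Fisher p <= 0.01)",
    "end_bias": "Alt alleles enriched within 10bp of read ends (Fisher p <= 0.01)",
}


@dataclass
class SnvParams:
    """Thresholds of the cascade; defaults are the published values."""

    tumor_af_min: float = 0.15
    normal_af_max: float = 0.02
    tn_fisher_alpha: float = 0.05
    hq_base_quality: int = 10        # reads with Q > this are "high quality"
    hq_coverage_min: int = 10
    error_rate_f: float = 0.1
    screen_alpha: float = 0.01       # shared by stages 4-7
    end_window: int = 10
    #: orientation of the sequencing-error binomial screen
    binom_orientation: str = "lower"
    #: sidedness of the tumor-vs-normal Fisher test
    tn_fisher_alternative: str = "greater"

    def __post_init__(self) -> None:
        for p in (self.tumor_af_min, self.normal_af_max, self.tn_fisher_alpha,
                  self.error_rate_f, self.screen_alpha):
            if not 0.0 < p < 1.0:
                raise ValueError(f"probability parameter out of (0, 1): {p}")
        if self.hq_coverage_min < 1:
            raise ValueError("hq_coverage_min must be at least 1")
        if self.end_window < 0:
            raise ValueError("end_window must be non-negative")


@dataclass
class SnvCall:
    """One candidate SNV with its complete per-stage filter profile."""

    pair_id: str
    sample: str
    chrom: str
    pos: int
    ref: str
    alt: str
    tumor_alt: int
    tumor_depth: int        # high-quality depth
    normal_alt: int
    normal_depth: int
    tests: dict[str, stats.TestResult] = field(default_factory=dict)
    verdicts: dict[str, bool] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(self.verdicts.values())

    @property
    def failed_stages(self) -> list[str]:
        return [s for s in STAGES if not self.verdicts.get(s, True)]

    @property
    def filter_status(self) -> str:
        return "PASS" if self.passed else ";".join(self.failed_stages)


def _hq_mask(pileup: SitePileup, min_q: int) -> np.ndarray:
    return pileup.base_quality > min_q


def select_alt_allele(tumor: SitePileup, params: SnvParams | None = None) -> str | None:
    """Most frequent non-reference base among high-quality tumor reads.

    Ties break to the lexicographically smallest base; returns None when no
    non-reference base is observed at high quality.
    """
    params = params or SnvParams()
    hq = _hq_mask(tumor, params.hq_base_quality)
    bases = tumor.bases[hq]
    counts = Counter(b for b in bases if b != tumor.ref)
    if not counts:
        return None
    best = max(counts.values())
    return min(b for b, c in counts.items() if c == best)


def apply_cascade(site: PairedSite, params: SnvParams | None = None) -> SnvCall | None:
    """Evaluate all seven filter stages at one paired site.

    Returns None (a no-call) when the tumor shows no high-quality
    non-reference base.  All stage p-values are recorded even after an
    early failure.
    """
    params = params or SnvParams()
    tumor, normal = site.tumor, site.normal
    alt = select_alt_allele(tumor, params)
    if alt is None:
        return None

    t_hq = _hq_mask(tumor, params.hq_base_quality)
    n_hq = _hq_mask(normal, params.hq_base_quality)
    t_depth = int(t_hq.sum())
    n_depth = int(n_hq.sum())
    t_alt = int(((tumor.bases == alt) & t_hq).sum())
    t_ref = int(((tumor.bases == tumor.ref) & t_hq).sum())
    n_alt = int(((normal.bases == alt) & n_hq).sum())
    n_ref = int(((normal.bases == normal.ref) & n_hq).sum())

    tests: dict[str, stats.TestResult] = {}
    verdicts: dict[str, bool] = {}

    taf = t_alt / t_depth if t_depth else 0.0
    naf = n_alt / n_depth if n_depth else 0.0
    verdicts["allele_freq"] = (taf > params.tumor_af_min) and (naf <= params.normal_af_max)

    tests["tn_fisher"] = stats.fisher_exact(
        t_alt, t_ref, n_alt, n_ref, alternative=params.tn_fisher_alternative)
    verdicts["tn_fisher"] = tests["tn_fisher"].p_value < params.tn_fisher_alpha

    verdicts["coverage"] = (t_depth >= params.hq_coverage_min
                            and n_depth >= params.hq_coverage_min)

    tests["seq_error"] = stats.binom_cdf_test(
        t_alt, t_depth, params.error_rate_f, orientation=params.binom_orientation)
    verdicts["seq_error"] = tests["seq_error"].p_value > params.screen_alpha

    # stages 5-7 look at tumor reads only, in the direction that indicates
    # an artifact, so "p > alpha" reads "no significant artifact signal"
    alt_mask = tumor.bases == alt
    ref_mask = tumor.bases == tumor.ref
    alt_q = tumor.base_quality[alt_mask]
    ref_q = tumor.base_quality[ref_mask]
    if alt_q.size and ref_q.size:
        tests["baseq_rank"] = stats.wilcoxon_rank_sum(alt_q, ref_q, alternative="less")
        verdicts["baseq_rank"] = tests["baseq_rank"].p_value > params.screen_alpha
    else:
        verdicts["baseq_rank"] = True

    rep = tumor.repeat_flag
    tests["repeat_align"] = stats.fisher_exact(
        int((alt_mask & rep).sum()), int((alt_mask & ~rep).sum()),
        int((ref_mask & rep).sum()), int((ref_mask & ~rep).sum()),
        alternative="greater")
    verdicts["repeat_align"] = tests["repeat_align"].p_value > params.screen_alpha

    near_end = np.minimum(tumor.dist_5prime, tumor.dist_3prime) < params.end_window
    tests["end_bias"] = stats.fisher_exact(
        int((alt_mask & near_end).sum()), int((alt_mask & ~near_end).sum()),
        int((ref_mask & near_end).sum()), int((ref_mask & ~near_end).sum()),
        alternative="greater")
    verdicts["end_bias"] = tests["end_bias"].p_value > params.screen_alpha

    return SnvCall(pair_id=site.pair_id, sample=tumor.sample,
                   chrom=site.chrom, pos=site.pos, ref=site.ref, alt=alt,
                   tumor_alt=t_alt, tumor_depth=t_depth,
                   normal_alt=n_alt, normal_depth=n_depth,
                   tests=tests, verdicts=verdicts)


def call_snvs(sites: Iterable[PairedSite],
              params: SnvParams | None = None) -> list[SnvCall]:
    """Apply the cascade across a (chrom, pos)-sorted stream of paired sites.

    Emits one call per site with a selectable alt allele and logs a summary
    of how many candidates each stage rejected.
    """
    params = params or SnvParams()
    calls: list[SnvCall] = []
    last: tuple[str, int] | None = None
    fail_tally: Counter[str] = Counter()
    n_sites = 0
    for site in sites:
        key = (site.chrom, site.pos)
        if last is not None and key < last:
            raise ValueError(f"input not sorted by (chrom, pos) at {key}")
        last = key
        n_sites += 1
        call = apply_cascade(site, params)
        if call is None:
            continue
        calls.append(call)
        for s in call.failed_stages:
            fail_tally[s] += 1
    n_pass = sum(c.passed for c in calls)
    logger.info("call_snvs: %d sites, %d candidates, %d PASS; failures per stage: %s",
                n_sites, len(calls), n_pass,
                {s: fail_tally.get(s, 0) for s in STAGES})
    return calls


def calls_to_records(calls: Sequence[SnvCall]) -> list[VariantRecord]:
    """Convert calls to VCF-bound variant records with full annotations."""
    records = []
    for c in calls:
        ann = {
            "SAMPLE": c.sample,
            "TDP": c.tumor_depth, "TAD": c.tumor_alt,
            "NDP": c.normal_depth, "NAD": c.normal_alt,
            "TAF": c.tumor_alt / c.tumor_depth if c.tumor_depth else 0.0,
            "NAF": c.normal_alt / c.normal_depth if c.normal_depth else 0.0,
        }
        key_map = {"tn_fisher": "P_TNF", "seq_error": "P_ERR",
                   "baseq_rank": "P_BQ", "repeat_align": "P_REP",
                   "end_bias": "P_END"}
        for stage, info_key in key_map.items():
            if stage in c.tests:
                ann[info_key] = c.tests[stage].p_value
        records.append(VariantRecord(c.chrom, c.pos, c.ref, c.alt, c.sample,
                                     c.filter_status, ann))
    return records
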