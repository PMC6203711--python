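"""Hypergeometric gene-set over-representation with BH adjustment.

A query gene list (differentially expressed genes, or one sample's mutated
genes) is tested against every set of a GMT collection within a fixed gene
universe ("all mouse genes" in the original design).  Significance requires
*both* an adjusted p below ``alpha`` and a minimum number of overlapping
genes — at least 4 for expression queries and at least 3 for mutation
queries.  The BH family is all sets in the collection, including those with
zero overlap.

For mutation queries, :func:`per_sample_mutation_enrichment` applies the
multi-sample aggregation rule: a pathway is reported when it is
significantly enriched (>= 3 genes involved, adjusted p < 0.05) in at
least ``min_samples`` tumors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats

__all__ = ["EnrichmentResult", "enrich", "per_sample_mutation_enrichment",
           "results_to_frame"]

logger = logging.getLogger(__name__)

Collection = Mapping[str, tuple[str, Sequence[str]]]


@dataclass
class EnrichmentResult:
    set_id: str
    overlap_genes: list[str]
    set_size: int             # after intersection with the universe
    query_size: int
    universe_size: int
    p_value: float
    adjusted_p: float
    significant: bool

    @property
    def overlap(self) -> int:
        return len(self.overlap_genes)


def enrich(query: Iterable[str], collection: Collection,
           universe: Iterable[str], min_genes: int = 4,
           alpha: float = 0.05) -> list[EnrichmentResult]:
    """Over-representation of a query list in every set of a collection.

    Sets are intersected with the universe before testing; query genes
    outside the universe are dropped with a log warning.  BH adjustment
    runs across all tested sets; ``significant`` requires adjusted p <
    ``alpha`` AND overlap >= ``min_genes``.  Results are ordered by set id,
    so the outcome is independent of collection iteration order.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty gene universe")
    query_set = set(query)
    outside = query_set - universe_set
    if outside:
        logger.warning("dropping %d query genes outside the universe: %s",
                       len(outside), sorted(outside)[:5])
        query_set &= universe_set
    n = len(query_set)
    N = len(universe_set)

    set_ids = sorted(collection)
    raw, overlaps, sizes = [], [], []
    for sid in set_ids:
        members = set(collection[sid][1]) & universe_set
        hit = sorted(query_set & members)
        overlaps.append(hit)
        sizes.append(len(members))
        raw.append(stats.hypergeom_overrep(len(hit), len(members), n, N).p_value)
    adjusted = stats.bh_adjust(raw)
    results = []
    for sid, hit, K, p, ap in zip(set_ids, overlaps, sizes, raw, adjusted):
        results.append(EnrichmentResult(
            set_id=sid, overlap_genes=hit, set_size=K, query_size=n,
            universe_size=N, p_value=float(p), adjusted_p=float(ap),
            significant=bool(ap < alpha and len(hit) >= min_genes)))
    return results


def per_sample_mutation_enrichment(per_sample_genes: Mapping[str, Iterable[str]],
                                   collection: Collection,
                                   universe: Iterable[str],
                                   min_samples: int = 3,
                                   min_genes: int = 3,
                                   alpha: float = 0.05) -> pd.DataFrame:
    """Pathways recurrently enriched across tumors.

    Runs :func:`enrich` per sample with the mutation-query gene floor
    (``min_genes=3`` by default) and reports, per pathway, the per-sample
    significance flags, the number of significant samples, and whether the
    pathway meets the >= ``min_samples`` aggregation rule.
    """
    universe = list(universe)
    samples = sorted(per_sample_genes)
    flags: dict[str, dict[str, bool]] = {}
    for sample in samples:
        results = enrich(per_sample_genes[sample], collection, universe,
                         min_genes=min_genes, alpha=alpha)
        for r in results:
            flags.setdefault(r.set_id, {})[sample] = r.significant
    rows = []
    for sid in sorted(flags):
        per_sample = [bool(flags[sid].get(s, False)) for s in samples]
        n_sig = int(np.sum(per_sample))
        rows.append({"set_id": sid, **dict(zip(samples, per_sample)),
                     "n_significant_samples": n_sig,
                     "reported": n_sig >= min_samples})
    return pd.DataFrame(rows).set_index("set_id") if rows else pd.DataFrame(
        columns=["n_significant_samples", "reported"])


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "set_id": r.set_id, "overlap": r.overlap, "set_size": r.set_size,
        "query_size": r.query_size, "universe_size": r.universe_size,
        "p_value": r.p_value, "adjusted_p": r.adjusted_p,
        "significant": r.significant,
        "overlap_genes": ",".join(r.overlap_genes),
    } for r in results]).set_index("set_id") if results else pd.DataFrame()
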