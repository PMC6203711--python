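"""Annotated mutation records, recurrence matrices and cohort statistics.

Turns PASS somatic variants into per-sample mutation records with coding
consequences, builds the gene x sample recurrence matrix, and computes the
cohort-level quantities used to contrast tumor groups: per-gene mutation
frequencies, per-sample mutation burden with a Welch t-test, cross-cohort
frequency comparison by chi-square, gene-list overlap and ortholog mapping.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import stats
from .io import GeneModel, VariantRecord

__all__ = [
    "MutationRecord", "RecurrenceMatrix",
    "classify_substitution", "annotate_variant", "annotate_all",
    "build_recurrence", "mutation_frequency", "mutated_gene_counts",
    "burden_compare", "burden_compare_from_stats",
    "gene_overlap", "map_orthologs", "frequency_compare", "round_half_up",
]

#: Consequences that alter the protein product; recurrence and burden use
#: these by default.
NONSYNONYMOUS = frozenset({"missense", "stopgain", "stoploss", "frameshift",
                           "inframe_indel"})

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation in one sample, annotated with its consequence."""

    sample: str
    gene: str | None
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: str

    @property
    def nonsynonymous(self) -> bool:
        return self.consequence in NONSYNONYMOUS


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, as printed percentages are."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Consequence classification
# ---------------------------------------------------------------------------

def coding_sequence(genome: Mapping[str, str], model: GeneModel) -> str:
    """Spliced CDS on the coding strand (reverse-complemented for minus genes)."""
    chunks = [genome[model.chrom][s - 1:e] for s, e in sorted(model.cds_blocks)]
    seq = "".join(chunks)
    return seq if model.strand == "+" else _revcomp(seq)


def _coding_offset(model: GeneModel, pos: int) -> int:
    """0-based offset of a genomic position within the coding sequence."""
    blocks = sorted(model.cds_blocks)
    total = sum(e - s + 1 for s, e in blocks)
    off = 0
    for s, e in blocks:
        if s <= pos <= e:
            fwd = off + (pos - s)
            return fwd if model.strand == "+" else total - 1 - fwd
        off += e - s + 1
    raise ValueError(f"position {pos} not in CDS of {model.gene_id}")


def classify_substitution(genome: Mapping[str, str], models: Sequence[GeneModel],
                          chrom: str, pos: int, alt: str) -> tuple[str | None, str]:
    """Gene assignment and coding consequence of a single-base substitution.

    A site inside a gene's CDS is classified by translating the reference
    and mutated codon on the coding strand (the substituted base is
    complemented for minus-strand genes).  Sites outside every CDS are
    ``noncoding``, with the containing gene's id if the site falls inside a
    gene span, else no gene.
    """
    chrom_seq = genome.get(chrom)
    if chrom_seq is None:
        raise ValueError(f"unknown chromosome {chrom!r}")
    if not 1 <= pos <= len(chrom_seq):
        raise ValueError(f"position {chrom}:{pos} beyond chromosome end")
    for m in models:
        if m.contains_cds(chrom, pos):
            cds = coding_sequence(genome, m)
            off = _coding_offset(m, pos)
            ci, within = divmod(off, 3)
            codon = cds[3 * ci:3 * ci + 3]
            alt_coding = alt if m.strand == "+" else alt.translate(_COMPLEMENT)
            mutated = codon[:within] + alt_coding + codon[within + 1:]
            ref_aa = str(Seq(codon).translate())
            alt_aa = str(Seq(mutated).translate())
            if ref_aa == alt_aa:
                return m.gene_id, "synonymous"
            if alt_aa == "*":
                return m.gene_id, "stopgain"
            if ref_aa == "*":
                return m.gene_id, "stoploss"
            return m.gene_id, "missense"
    for m in models:
        if m.chrom == chrom and m.start <= pos <= m.end:
            return m.gene_id, "noncoding"
    return None, "noncoding"


def annotate_variant(variant: VariantRecord, models: Sequence[GeneModel],
                     genome: Mapping[str, str]) -> MutationRecord:
    """Annotate one variant with gene and consequence.

    SNVs are classified at codon level.  Indels inside a CDS are classified
    by the length difference (``frameshift`` when not a multiple of three,
    ``inframe_indel`` otherwise); both count as non-synonymous.
    """
    if len(variant.ref) == 1 and len(variant.alt) == 1:
        gene, csq = classify_substitution(genome, models, variant.chrom,
                                          variant.pos, variant.alt)
    else:
        gene, csq = None, "noncoding"
        for m in models:
            if m.contains_cds(variant.chrom, variant.pos):
                gene = m.gene_id
                shift = abs(len(variant.ref) - len(variant.alt)) % 3
                csq = "frameshift" if shift else "inframe_indel"
                break
        else:
            for m in models:
                if m.chrom == variant.chrom and m.start <= variant.pos <= m.end:
                    gene = m.gene_id
                    break
    return MutationRecord(variant.sample, gene, variant.chrom, variant.pos,
                          variant.ref, variant.alt, csq)


def annotate_all(variants: Iterable[VariantRecord], models: Sequence[GeneModel],
                 genome: Mapping[str, str]) -> list[MutationRecord]:
    return [annotate_variant(v, models, genome) for v in variants]


# ---------------------------------------------------------------------------
# Recurrence and cohort statistics
# ---------------------------------------------------------------------------

@dataclass
class RecurrenceMatrix:
    """Binary gene x sample mutation indicators with per-sample group labels."""

    indicators: pd.DataFrame            # genes x samples, values in {0, 1}
    groups: dict[str, str]              # sample -> group label

    def samples_in(self, group: str | None = None) -> list[str]:
        if group is None:
            return list(self.indicators.columns)
        return [s for s in self.indicators.columns if self.groups.get(s) == group]

    def recurrent_genes(self, min_samples: int = 2,
                        group: str | None = None) -> list[str]:
        cols = self.samples_in(group)
        sums = self.indicators[cols].sum(axis=1)
        return sorted(sums.index[sums >= min_samples])


def build_recurrence(records: Iterable[MutationRecord],
                     samples: Sequence[str] | None = None,
                     groups: Mapping[str, str] | None = None,
                     nonsynonymous_only: bool = True) -> RecurrenceMatrix:
    """Binary indicator matrix: 1 iff the gene carries a qualifying record
    in the sample.  Duplicate records for a (gene, sample) still give 1."""
    recs = [r for r in records
            if r.gene is not None and (r.nonsynonymous or not nonsynonymous_only)]
    sample_ids = sorted(set(samples or []) | {r.sample for r in recs})
    gene_ids = sorted({r.gene for r in recs})
    mat = pd.DataFrame(0, index=gene_ids, columns=sample_ids, dtype=int)
    for r in recs:
        mat.loc[r.gene, r.sample] = 1
    return RecurrenceMatrix(mat, dict(groups or {}))


def mutation_frequency(gene: str, matrix: RecurrenceMatrix,
                       group: str | None = None) -> dict:
    """Fraction and one-decimal percentage of group samples mutated in a gene."""
    if gene not in matrix.indicators.index:
        raise KeyError(f"gene {gene!r} not in recurrence matrix")
    cols = matrix.samples_in(group)
    if not cols:
        raise ValueError(f"no samples in group {group!r}")
    k = int(matrix.indicators.loc[gene, cols].sum())
    n = len(cols)
    frac = k / n
    return {"gene": gene, "mutated": k, "total": n, "fraction": frac,
            "percent": round_half_up(100.0 * frac, 1)}


def mutated_gene_counts(records: Iterable[MutationRecord],
                        nonsynonymous_only: bool = True,
                        per_call: bool = False) -> pd.Series:
    """Mutation burden per sample.

    By default counts distinct mutated genes per sample (the deduplicated
    reading of "mutated gene numbers"); ``per_call=True`` counts every
    qualifying variant call instead.
    """
    tally: dict[str, set | int] = {}
    for r in records:
        if nonsynonymous_only and not r.nonsynonymous:
            continue
        if r.gene is None:
            continue
        if per_call:
            tally[r.sample] = tally.get(r.sample, 0) + 1
        else:
            tally.setdefault(r.sample, set()).add(r.gene)
    counts = {s: (v if per_call else len(v)) for s, v in tally.items()}
    return pd.Series(counts, dtype=int).sort_index()


def burden_compare(counts_by_group: Mapping[str, Sequence[float]]) -> dict:
    """Group means +- SD, fold ratio and Welch t-test of per-sample burdens.

    The fold is larger mean over smaller mean, rounded half-up to one
    decimal.  Exactly two groups are required, each with >= 2 samples.
    """
    if len(counts_by_group) != 2:
        raise ValueError("burden comparison needs exactly two groups")
    (g1, c1), (g2, c2) = sorted(counts_by_group.items())
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    if c1.size < 2 or c2.size < 2:
        raise ValueError("each group needs at least 2 samples")
    m1, m2 = float(c1.mean()), float(c2.mean())
    s1 = float(c1.std(ddof=1))
    s2 = float(c2.std(ddof=1))
    test = stats.t_test(c1, c2, equal_var=False)
    lo, hi = sorted([m1, m2])
    fold = round_half_up(hi / lo, 1) if lo > 0 else float("inf")
    return {"groups": (g1, g2), "means": (m1, m2), "sds": (s1, s2),
            "fold": fold, "test": test}


def burden_compare_from_stats(mean1: float, sd1: float, n1: int,
                              mean2: float, sd2: float, n2: int) -> dict:
    """Burden comparison from printed summary statistics (Welch t-test)."""
    test = stats.t_test_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=False)
    lo, hi = sorted([mean1, mean2])
    fold = round_half_up(hi / lo, 1) if lo > 0 else float("inf")
    return {"means": (mean1, mean2), "sds": (sd1, sd2), "fold": fold, "test": test}


def gene_overlap(genes_a: Iterable[str], genes_b: Iterable[str]) -> int:
    """Size of the intersection of two gene lists."""
    return len(set(genes_a) & set(genes_b))


def map_orthologs(genes: Sequence[str], mapping: Mapping[str, str]) -> list[str]:
    """Map symbols through a many-to-one ortholog table.

    Unmapped symbols are dropped; the output preserves input order and is
    deduplicated (two sources collapsing onto one target yield one entry).
    """
    out: list[str] = []
    seen: set[str] = set()
    for g in genes:
        target = mapping.get(g)
        if target is not None and target not in seen:
            seen.add(target)
            out.append(target)
    return out


def frequency_compare(k1: int, n1: int, k2: int, n2: int,
                      continuity: bool = False) -> stats.TestResult:
    """Chi-square comparison of mutation frequencies k1/n1 vs k2/n2."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("cohort sizes must be positive")
    if k1 > n1 or k2 > n2:
        raise ValueError("mutated count exceeds cohort size")
    return stats.chi_square_2x2(k1, n1 - k1, k2, n2 - k2, continuity=continuity)
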