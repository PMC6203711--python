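"""Readers and writers for every on-disk format the pipeline touches.

All genomic coordinates are 1-based inclusive throughout (pileups, gene
models, VCF).  Formats are plain text: FASTA genomes, tab-separated pileups
and gene models, VCF v4.2 variant output, GMT gene sets, TSV matrices.
Readers validate eagerly and raise with enough context (line numbers, cell
coordinates) to locate the offending input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "PileupParseError", "PairingError", "IntegrityError",
    "PILEUP_COLUMNS", "SitePileup", "PairedSite", "GeneModel", "VariantRecord",
    "read_fasta", "write_fasta",
    "read_gene_models", "write_gene_models",
    "read_pair_manifest", "write_pair_manifest",
    "read_pileups", "write_pileups",
    "write_vcf", "read_vcf",
    "read_gmt", "write_gmt",
    "read_matrix", "write_matrix",
    "read_ortholog_map", "read_known_sites", "write_known_sites",
]


class PileupParseError(ValueError):
    """A pileup row could not be parsed or failed validation."""


class PairingError(ValueError):
    """Tumor/normal pairing could not be established for a site."""


class IntegrityError(ValueError):
    """Duplicate or internally inconsistent records in an input or output."""


VALID_BASES = frozenset("ACGT")

#: Column order of the read-observation (pileup) TSV: one row per read
#: overlapping a site in one sample.
PILEUP_COLUMNS = [
    "sample", "chrom", "pos", "ref", "base", "base_quality",
    "mapping_quality", "repeat_flag", "dist_5prime", "dist_3prime", "strand",
]


@dataclass
class SitePileup:
    """Read observations at one genomic site for one sample."""

    sample: str
    chrom: str
    pos: int
    ref: str
    bases: np.ndarray          # per-read called base
    base_quality: np.ndarray   # phred
    mapping_quality: np.ndarray
    repeat_flag: np.ndarray    # bool: read aligns ambiguously (multi-mapping)
    dist_5prime: np.ndarray    # bases from the 5' end of the read
    dist_3prime: np.ndarray
    strand: np.ndarray

    @property
    def depth(self) -> int:
        return int(self.bases.size)


@dataclass
class PairedSite:
    """Tumor and matched-normal pileups at the same locus."""

    pair_id: str
    chrom: str
    pos: int
    ref: str
    tumor: SitePileup
    normal: SitePileup


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand and CDS blocks, 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str                      # "+" or "-"
    cds_blocks: tuple[tuple[int, int], ...]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_blocks)

    def contains_cds(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and any(s <= pos <= e for s, e in self.cds_blocks)


@dataclass
class VariantRecord:
    """A candidate variant with filter status and annotations, VCF-bound.

    ``filter_status`` is ``"PASS"`` or a semicolon-joined list of failing
    filter names.  ``annotations`` maps INFO keys to values (depths, alt
    counts, per-filter p-values, gene, consequence).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    sample: str
    filter_status: str
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical at {self.chrom}:{self.pos}")
        if not self.filter_status:
            raise ValueError("filter_status must be non-empty")


# ---------------------------------------------------------------------------
# FASTA and gene models
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def write_gene_models(models: Iterable[GeneModel], path) -> None:
    rows = []
    for m in models:
        blocks = ",".join(f"{s}-{e}" for s, e in m.cds_blocks)
        rows.append((m.chrom, m.start, m.end, m.strand, m.gene_id, blocks))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "gene_id", "cds_blocks"])
    df.to_csv(path, sep="\t", index=False)


def read_gene_models(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
    models = []
    seen = set()
    for _, row in df.iterrows():
        if row["gene_id"] in seen:
            raise IntegrityError(f"duplicate gene_id {row['gene_id']!r}")
        seen.add(row["gene_id"])
        blocks = tuple(
            tuple(int(x) for x in blk.split("-")) for blk in str(row["cds_blocks"]).split(",")
        )
        models.append(GeneModel(row["gene_id"], row["chrom"], int(row["start"]),
                                int(row["end"]), row["strand"], blocks))
    return models


# ---------------------------------------------------------------------------
# Pileups
# ---------------------------------------------------------------------------

def write_pair_manifest(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, sep="\t", index=False)


def read_pair_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"pair_id", "tumor_sample", "normal_sample"}
    missing = required - set(df.columns)
    if missing:
        raise PileupParseError(f"pair manifest missing columns: {sorted(missing)}")
    if df["pair_id"].duplicated().any():
        raise IntegrityError("duplicate pair_id in manifest")
    return df


def write_pileups(rows: pd.DataFrame, path) -> None:
    rows.to_csv(path, sep="\t", index=False, columns=PILEUP_COLUMNS)


def _site_pileup_from_frame(g: pd.DataFrame) -> SitePileup:
    first = g.iloc[0]
    return SitePileup(
        sample=first["sample"], chrom=first["chrom"], pos=int(first["pos"]),
        ref=first["ref"],
        bases=g["base"].to_numpy(dtype="U1"),
        base_quality=g["base_quality"].to_numpy(dtype=int),
        mapping_quality=g["mapping_quality"].to_numpy(dtype=int),
        repeat_flag=g["repeat_flag"].to_numpy(dtype=int).astype(bool),
        dist_5prime=g["dist_5prime"].to_numpy(dtype=int),
        dist_3prime=g["dist_3prime"].to_numpy(dtype=int),
        strand=g["strand"].to_numpy(dtype="U1"),
    )


def read_pileups(path, pairs: pd.DataFrame) -> list[PairedSite]:
    """Load a pileup TSV and pair tumor with matched normal per site.

    Rows are grouped by (chrom, pos, sample); tumor and normal pileups are
    matched through the pair manifest.  Invalid bases (anything outside
    A/C/G/T) or negative qualities raise :class:`PileupParseError` naming
    the offending line; a site observed in only one member of a pair raises
    :class:`PairingError`.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str,
                                            "ref": str, "base": str, "strand": str})
    missing = set(PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise PileupParseError(f"pileup file missing columns: {sorted(missing)}")
    # +2: one for the header line, one for 0- vs 1-based indexing
    bad_base = ~df["base"].isin(VALID_BASES) | ~df["ref"].isin(VALID_BASES)
    if bad_base.any():
        line = int(df.index[bad_base][0]) + 2
        raise PileupParseError(
            f"invalid base {df.loc[bad_base, 'base'].iloc[0]!r} at line {line}")
    neg_q = (df["base_quality"] < 0) | (df["mapping_quality"] < 0)
    if neg_q.any():
        line = int(df.index[neg_q][0]) + 2
        raise PileupParseError(f"negative quality at line {line}")

    role: dict[str, tuple[str, str]] = {}
    for _, p in pairs.iterrows():
        role[p["tumor_sample"]] = (p["pair_id"], "tumor")
        role[p["normal_sample"]] = (p["pair_id"], "normal")
    unknown = set(df["sample"]) - set(role)
    if unknown:
        raise PairingError(f"samples absent from pair manifest: {sorted(unknown)}")

    df["pair_id"] = df["sample"].map(lambda s: role[s][0])
    df["role"] = df["sample"].map(lambda s: role[s][1])

    sites: list[PairedSite] = []
    for (chrom, pos, pair_id), g in df.groupby(["chrom", "pos", "pair_id"], sort=True):
        halves = {r: sub for r, sub in g.groupby("role")}
        if "tumor" not in halves or "normal" not in halves:
            present = ", ".join(sorted(halves))
            raise PairingError(
                f"site {chrom}:{pos} pair {pair_id}: only {present} reads present")
        tumor = _site_pileup_from_frame(halves["tumor"])
        normal = _site_pileup_from_frame(halves["normal"])
        if tumor.ref != normal.ref:
            raise IntegrityError(f"ref mismatch at {chrom}:{pos} pair {pair_id}")
        sites.append(PairedSite(pair_id, str(chrom), int(pos), tumor.ref, tumor, normal))
    return sites


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

# INFO key registry: (Number, Type, Description).  Unregistered keys are
# emitted as Type=String.
_INFO_FIELDS: dict[str, tuple[str, str, str]] = {
    "SAMPLE": ("1", "String", "Tumor sample in which the variant was called"),
    "TDP": ("1", "Integer", "High-quality tumor depth"),
    "TAD": ("1", "Integer", "High-quality tumor alt-supporting reads"),
    "NDP": ("1", "Integer", "High-quality normal depth"),
    "NAD": ("1", "Integer", "High-quality normal alt-supporting reads"),
    "TAF": ("1", "Float", "Tumor alt-allele fraction over high-quality reads"),
    "NAF": ("1", "Float", "Normal alt-allele fraction over high-quality reads"),
    "GENE": ("1", "String", "Containing gene (CDS overlap)"),
    "CSQ": ("1", "String", "Predicted coding consequence"),
    "P_TNF": ("1", "Float", "Tumor-vs-normal Fisher exact p-value"),
    "P_ERR": ("1", "Float", "Sequencing-error binomial tail p-value"),
    "P_BQ": ("1", "Float", "Alt-vs-ref base-quality Wilcoxon p-value"),
    "P_REP": ("1", "Float", "Repeat-alignment Fisher exact p-value"),
    "P_END": ("1", "Float", "Read-end enrichment Fisher exact p-value"),
    "COV": ("1", "Integer", "Total coverage at the indel site"),
    "NSUP": ("1", "Integer", "Consensus indel-supporting reads"),
}


def _fmt_info_value(v) -> str:
    if isinstance(v, bool):
        return str(int(v))
    if isinstance(v, float) or isinstance(v, np.floating):
        return f"{float(v):.4g}"
    return str(v)


def write_vcf(records: list[VariantRecord], path,
              filter_descriptions: Mapping[str, str] | None = None) -> None:
    """Serialize variant records to a VCF v4.2 file.

    The header defines every FILTER name used by any record (plus any
    extras supplied in ``filter_descriptions``) and every INFO key before
    use.  Records are sorted by (chrom, pos, sample, alt); exact duplicates
    of that key raise :class:`IntegrityError`.
    """
    filter_descriptions = dict(filter_descriptions or {})
    keys = [(r.chrom, r.pos, r.sample, r.alt) for r in records]
    if len(keys) != len(set(keys)):
        raise IntegrityError("duplicate (chrom, pos, sample, alt) in VCF records")
    ordered = sorted(records, key=lambda r: (r.chrom, r.pos, r.sample, r.alt))

    used_filters: list[str] = []
    used_info: list[str] = []
    for r in ordered:
        for name in r.filter_status.split(";"):
            if name != "PASS" and name not in used_filters:
                used_filters.append(name)
        for k in r.annotations:
            if k not in used_info:
                used_info.append(k)
    for name in filter_descriptions:
        if name not in used_filters:
            used_filters.append(name)

    lines = ["##fileformat=VCFv4.2"]
    for chrom in sorted({r.chrom for r in ordered}):
        lines.append(f"##contig=<ID={chrom}>")
    for name in used_filters:
        desc = filter_descriptions.get(name, f"Failed filter {name}")
        lines.append(f'##FILTER=<ID={name},Description="{desc}">')
    for k in used_info:
        number, typ, desc = _INFO_FIELDS.get(k, ("1", "String", f"Annotation {k}"))
        lines.append(f'##INFO=<ID={k},Number={number},Type={typ},Description="{desc}">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for r in ordered:
        info = ";".join(f"{k}={_fmt_info_value(v)}" for k, v in r.annotations.items()) or "."
        lines.append(
            f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t{r.filter_status}\t{info}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path) -> list[VariantRecord]:
    """Parse a VCF written by :func:`write_vcf` back into records (pysam)."""
    import pysam

    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            filters = list(rec.filter.keys()) or ["PASS"]
            ann = {}
            for k, v in rec.info.items():
                if isinstance(v, tuple) and len(v) == 1:
                    v = v[0]
                ann[k] = v
            out.append(VariantRecord(
                chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=rec.alts[0],
                sample=str(ann.get("SAMPLE", "")),
                filter_status=";".join(filters), annotations=ann))
    return out


# ---------------------------------------------------------------------------
# Gene sets, matrices, maps, known sites
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, tuple[str, list[str]]]:
    """GMT gene-set collection: set id -> (description, member genes)."""
    collection: dict[str, tuple[str, list[str]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise PileupParseError(f"GMT line {lineno}: fewer than 3 fields")
        set_id, desc, genes = parts[0], parts[1], parts[2:]
        if set_id in collection:
            raise IntegrityError(f"duplicate gene-set id {set_id!r}")
        if len(genes) != len(set(genes)):
            raise IntegrityError(f"duplicate gene within set {set_id!r}")
        collection[set_id] = (desc, genes)
    return collection


def write_gmt(collection: Mapping[str, tuple[str, list[str]]], path) -> None:
    lines = [
        "\t".join([set_id, desc, *genes]) for set_id, (desc, genes) in collection.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_matrix(path) -> pd.DataFrame:
    """Gene x sample numeric matrix from TSV (gene ids in the first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise IntegrityError(f"duplicate gene row {dup!r}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            gene = df.index[bad | df[col].isna()][0]
            raise PileupParseError(
                f"non-numeric or missing cell at gene {gene!r}, sample {col!r}")
        df[col] = coerced
    return df.astype(float)


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_ortholog_map(path) -> dict[str, str]:
    """Many-to-one source->target symbol map from a two-column TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise PileupParseError("ortholog map needs two columns")
    src, dst = df.columns[:2]
    if df[src].duplicated().any():
        dup = df.loc[df[src].duplicated(), src].iloc[0]
        raise IntegrityError(f"source symbol {dup!r} mapped more than once")
    return dict(zip(df[src], df[dst]))


def read_known_sites(path) -> set[tuple[str, int, str, str]]:
    """Known-variant loci as exact (chrom, pos, ref, alt) tuples."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    out = set()
    for _, row in df.iterrows():
        key = (row["chrom"], int(row["pos"]), row["ref"], row["alt"])
        if key in out:
            raise IntegrityError(f"duplicate known site {key}")
        out.add(key)
    return out


def write_known_sites(sites: Iterable[tuple[str, int, str, str]], path) -> None:
    df = pd.DataFrame(sorted(sites), columns=["chrom", "pos", "ref", "alt"])
    df.to_csv(path, sep="\t", index=False)
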