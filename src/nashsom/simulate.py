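"""Synthetic paired tumor/normal data with known ground truth.

Generates every input the pipeline consumes while emulating the statistical
structure of a paired tumor/normal exome study on a desk-scale toy genome:

* a random genome with non-overlapping gene models whose CDS begin with ATG
  and contain no internal stop codon;
* per-read pileups for tumor and matched normal at planted somatic,
  germline, artifact and background loci — somatic alt reads follow
  ``Binomial(depth, VAF)`` in tumor only (up to a small contamination leak
  into the normal), germline sites sit near VAF 0.5 in both samples, and
  three artifact classes reproduce the failure modes the filter cascade is
  designed to reject (read-end clustering, repeat-aligned support,
  low-quality alt bases);
* group-structured expression matrices with planted fold changes, in both
  two-group and paired tumor/normal designs;
* GMT gene-set collections with planted enriched pathways.

Reads are 100 bases long; site offsets within a read are uniform except at
end-biased artifact sites, where alt reads land within 10 bases of a read
terminus.  All randomness flows from ``SimConfig.seed`` through per-output
substreams, so an identical (seed, config) pair reproduces every output
byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GeneModel
from .landscape import classify_substitution

__all__ = [
    "SimConfig", "ExpressionSimConfig", "PathwaySimConfig", "TruthTable",
    "make_genome", "simulate_paired_pileups", "simulate_expression",
    "make_gene_sets", "make_indel_candidates",
]

ARTIFACT_CLASSES = ("end_biased", "repeat_biased", "low_quality_alt")

_STOP_CODONS = ("TAA", "TAG", "TGA")
_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# substream ids so each generator draws from an independent stream of the
# configured seed
_STREAM_GENOME = 1
_STREAM_PILEUP = 2
_STREAM_EXPR = 3
_STREAM_SETS = 4
_STREAM_INDEL = 5


@dataclass
class ExpressionSimConfig:
    """Expression-arm settings.

    ``log2_effect_size`` defaults to log2(2.5), i.e. planted genes change
    2.5-fold between groups; ``noise_sd`` is the per-observation Gaussian
    noise on the log2 scale.  The paired design emulates the human
    tumor/adjacent-normal validation arm (17 pairs).
    """

    n_genes: int = 1000
    n_de_genes: int = 50
    log2_effect_size: float = math.log2(2.5)
    noise_sd: float = 0.25
    baseline_sd: float = 0.5
    n_pairs: int = 17
    pair_baseline_sd: float = 0.5


@dataclass
class PathwaySimConfig:
    n_sets: int = 20
    set_size: int = 20
    planted_enriched: int = 3
    #: fraction of a planted set drawn from the "hot" gene list
    hot_fraction: float = 0.6


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults mirror the murine cohort structure (5 NASH vs 3 steatosis
    tumor/normal pairs), exome-typical depth (Poisson mean 80 per sample),
    clonal somatic variants at VAF 0.3, and a small tumor-in-normal
    contamination (0.5% of tumor alt reads leaking into the adjacent-tissue
    normal).  Background loci (500 per sample) carry only sequencing error
    so that specificity is measurable.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 100_000
    n_genes: int = 50
    n_samples_per_group: dict[str, int] = field(
        default_factory=lambda: {"NASH": 5, "steatosis": 3})
    depth_mean_tumor: float = 80.0
    depth_mean_normal: float | None = None     # None: same as tumor
    base_error_rate: float = 0.001
    somatic_vaf: float = 0.3
    n_somatic_per_sample: int = 20
    n_germline: int = 20
    artifact_counts: dict[str, int] = field(
        default_factory=lambda: {c: 6 for c in ARTIFACT_CLASSES})
    normal_contamination: float = 0.005
    n_background: int = 500
    read_length: int = 100
    expression: ExpressionSimConfig = field(default_factory=ExpressionSimConfig)
    pathways: PathwaySimConfig = field(default_factory=PathwaySimConfig)

    def __post_init__(self) -> None:
        counts = [self.n_chromosomes, self.chrom_length, self.n_genes,
                  self.n_somatic_per_sample, self.n_germline, self.n_background,
                  self.read_length, *self.artifact_counts.values(),
                  *self.n_samples_per_group.values()]
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be non-negative")
        for p in (self.base_error_rate, self.normal_contamination):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0, 1]: {p}")
        if not 0.0 < self.somatic_vaf <= 1.0:
            raise ValueError("somatic_vaf must be in (0, 1]")
        if self.somatic_vaf <= self.base_error_rate:
            raise ValueError("somatic_vaf must exceed base_error_rate")
        unknown = set(self.artifact_counts) - set(ARTIFACT_CLASSES)
        if unknown:
            raise ValueError(f"unknown artifact classes: {sorted(unknown)}")

    @property
    def normal_depth(self) -> float:
        return self.depth_mean_normal if self.depth_mean_normal is not None \
            else self.depth_mean_tumor


_TRUTH_VARIANT_COLUMNS = ["sample", "chrom", "pos", "ref", "alt", "vaf",
                          "gene", "consequence"]
_TRUTH_ARTIFACT_COLUMNS = ["sample", "chrom", "pos", "ref", "alt", "artifact_class"]


@dataclass
class TruthTable:
    """Planted events: the ground truth recovered analyses are scored against."""

    somatic: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=_TRUTH_VARIANT_COLUMNS))
    germline: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=_TRUTH_VARIANT_COLUMNS))
    artifacts: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=_TRUTH_ARTIFACT_COLUMNS))
    de_genes: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene", "direction", "log2fc"]))
    enriched_pathways: list[str] = field(default_factory=list)

    def validate_disjoint(self) -> None:
        """No locus may appear in more than one truth category per sample."""
        seen: set[tuple[str, str, int]] = set()
        for df in (self.somatic, self.germline, self.artifacts):
            for _, row in df.iterrows():
                key = (row["sample"], row["chrom"], int(row["pos"]))
                if key in seen:
                    raise ValueError(f"locus {key} in more than one truth category")
                seen.add(key)


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Genome and gene models
# ---------------------------------------------------------------------------

def _random_coding_sequence(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + ``n_codons`` random non-stop codons + one stop codon."""
    codons = []
    while len(codons) < n_codons:
        c = "".join(rng.choice(_BASES, size=3))
        if c not in _STOP_CODONS:
            codons.append(c)
    return "ATG" + "".join(codons) + _STOP_CODONS[rng.integers(0, 3)]


def make_genome(config: SimConfig,
                rng: np.random.Generator | None = None
                ) -> tuple[dict[str, str], list[GeneModel]]:
    """Random chromosomes plus non-overlapping gene models.

    Each gene's coding sequence (ATG start, no internal stop, length a
    multiple of three) is written into the chromosome on the chosen strand;
    roughly half the genes are split into two CDS blocks by an intron.
    Raises if the requested genes do not fit into the genome.
    """
    if config.chrom_length < 1000:
        raise ValueError("chrom_length must be at least 1000")
    if config.n_genes < 1:
        raise ValueError("n_genes must be at least 1")
    rng = rng or np.random.default_rng([config.seed, _STREAM_GENOME])

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chroms = {name: list(rng.choice(_BASES, size=config.chrom_length))
              for name in chrom_names}

    models: list[GeneModel] = []
    cursor = {name: 200 for name in chrom_names}
    ci = 0
    for gi in range(config.n_genes):
        n_codons = int(rng.integers(60, 121))
        code = _random_coding_sequence(rng, n_codons)
        split = bool(rng.random() < 0.5) and len(code) >= 60
        intron = int(rng.integers(20, 101)) if split else 0
        span = len(code) + intron
        placed = False
        for _ in range(config.n_chromosomes):
            name = chrom_names[ci % config.n_chromosomes]
            if cursor[name] + span < config.chrom_length - 200:
                start = cursor[name]
                cursor[name] = start + span + int(rng.integers(100, 301))
                placed = True
                break
            ci += 1
        if not placed:
            raise ValueError(
                f"genome too small: gene {gi + 1}/{config.n_genes} does not fit")
        strand = "+" if rng.random() < 0.5 else "-"
        if split:
            cut = 3 * int(rng.integers(5, len(code) // 3 - 4))
            b1 = (start, start + cut - 1)
            b2 = (start + cut + intron, start + span - 1)
            blocks = (b1, b2)
        else:
            blocks = ((start, start + len(code) - 1),)
        genomic = code if strand == "+" else _revcomp(code)
        seq = chroms[name]
        i = 0
        for s, e in blocks:
            length = e - s + 1
            seq[s - 1:e] = genomic[i:i + length]
            i += length
        models.append(GeneModel(f"g{gi + 1:03d}", name, blocks[0][0],
                                blocks[-1][1], strand, blocks))
        ci += 1
    genome = {name: "".join(seq) for name, seq in chroms.items()}
    return genome, models


# ---------------------------------------------------------------------------
# Paired pileups
# ---------------------------------------------------------------------------

def _read_block(rng: np.random.Generator, n: int, ref: str, alt: str | None,
                n_alt: int, artifact: str | None, read_length: int) -> dict:
    """Per-read observation arrays for one sample at one site.

    The first ``n_alt`` reads carry the alt base; artifact classes reshape
    the alt reads' offsets, repeat flags or base qualities.
    """
    bases = np.full(n, ref, dtype="U1")
    if n_alt:
        bases[:n_alt] = alt
    qual = np.clip(np.rint(rng.normal(35.0, 4.0, n)), 2, 40).astype(int)
    repeat = rng.random(n) < 0.05
    off = rng.integers(0, read_length, n)
    if n_alt and artifact == "end_biased":
        # every alt read within 10 bases of the 5' or 3' terminus
        near = rng.integers(0, 10, n_alt)
        use_3p = rng.random(n_alt) < 0.5
        off[:n_alt] = np.where(use_3p, read_length - 1 - near, near)
    if n_alt and artifact == "repeat_biased":
        repeat[:n_alt] = True
    if n_alt and artifact == "low_quality_alt":
        # low but still above the Q>10 high-quality cut, so only the
        # base-quality rank test sees the signal
        qual[:n_alt] = np.clip(np.rint(rng.normal(14.0, 2.0, n_alt)), 11, 20).astype(int)
    return {
        "base": bases,
        "base_quality": qual,
        "mapping_quality": np.where(repeat, rng.integers(0, 30, n), 60).astype(int),
        "repeat_flag": repeat.astype(int),
        "dist_5prime": off.astype(int),
        "dist_3prime": (read_length - 1 - off).astype(int),
        "strand": np.where(rng.random(n) < 0.5, "+", "-"),
    }


def _background_block(rng: np.random.Generator, n: int, ref: str,
                      error_rate: float, read_length: int) -> dict:
    block = _read_block(rng, n, ref, None, 0, None, read_length)
    n_err = rng.binomial(n, error_rate)
    if n_err:
        others = [b for b in "ACGT" if b != ref]
        block["base"][:n_err] = rng.choice(others, size=n_err)
    return block


def _draw_depth(rng: np.random.Generator, mean: float, require_reads: bool) -> int:
    d = int(rng.poisson(mean))
    while require_reads and d == 0:
        d = int(rng.poisson(mean))
    return d


def simulate_paired_pileups(genome: Mapping[str, str], models: Sequence[GeneModel],
                            config: SimConfig,
                            rng: np.random.Generator | None = None
                            ) -> tuple[pd.DataFrame, pd.DataFrame, TruthTable]:
    """Per-read tumor/normal pileups at truth and background loci.

    Returns the pileup row table (one row per read observation), the
    tumor/normal pair manifest, and the :class:`TruthTable` of planted
    events.  Somatic and germline loci are planted inside CDS so that their
    gene and coding consequence are defined; artifact and background loci
    fall anywhere in the genome.
    """
    rng = rng or np.random.default_rng([config.seed, _STREAM_PILEUP])

    cds_positions: list[tuple[str, int]] = []
    for m in models:
        for s, e in m.cds_blocks:
            cds_positions.extend((m.chrom, p) for p in range(s, e + 1))
    chrom_names = sorted(genome)

    pairs_rows = []
    blocks: list[dict] = []
    meta_rows: list[dict] = []
    somatic_rows, germline_rows, artifact_rows = [], [], []

    def _emit(sample: str, chrom: str, pos: int, ref: str, alt: str | None,
              depth_mean: float, alt_fraction: float, artifact: str | None,
              is_truth: bool, background: bool) -> None:
        depth = _draw_depth(rng, depth_mean, require_reads=is_truth)
        if depth == 0:
            return
        if background:
            block = _background_block(rng, depth, ref, config.base_error_rate,
                                      config.read_length)
        else:
            n_alt = rng.binomial(depth, alt_fraction) if alt_fraction > 0 else 0
            block = _read_block(rng, depth, ref, alt, n_alt, artifact,
                                config.read_length)
        blocks.append(block)
        meta_rows.append({"sample": sample, "chrom": chrom, "pos": pos,
                          "ref": ref, "n": depth})

    for group in sorted(config.n_samples_per_group):
        for i in range(config.n_samples_per_group[group]):
            pair_id = f"{group}{i + 1}"
            t_sample, n_sample = f"{pair_id}_T", f"{pair_id}_N"
            pairs_rows.append({"pair_id": pair_id, "tumor_sample": t_sample,
                               "normal_sample": n_sample, "group": group})
            used: set[tuple[str, int]] = set()

            def _pick_cds() -> tuple[str, int]:
                while True:
                    chrom, pos = cds_positions[rng.integers(0, len(cds_positions))]
                    if (chrom, pos) not in used:
                        used.add((chrom, pos))
                        return chrom, pos

            def _pick_any() -> tuple[str, int]:
                while True:
                    chrom = chrom_names[rng.integers(0, len(chrom_names))]
                    pos = int(rng.integers(1, len(genome[chrom]) + 1))
                    if (chrom, pos) not in used:
                        used.add((chrom, pos))
                        return chrom, pos

            def _alt_for(ref: str) -> str:
                others = [b for b in "ACGT" if b != ref]
                return others[rng.integers(0, 3)]

            for _ in range(config.n_somatic_per_sample):
                chrom, pos = _pick_cds()
                ref = genome[chrom][pos - 1]
                alt = _alt_for(ref)
                gene, csq = classify_substitution(genome, models, chrom, pos, alt)
                somatic_rows.append({"sample": t_sample, "chrom": chrom, "pos": pos,
                                     "ref": ref, "alt": alt, "vaf": config.somatic_vaf,
                                     "gene": gene, "consequence": csq})
                _emit(t_sample, chrom, pos, ref, alt, config.depth_mean_tumor,
                      config.somatic_vaf, None, True, False)
                _emit(n_sample, chrom, pos, ref, alt, config.normal_depth,
                      config.somatic_vaf * config.normal_contamination,
                      None, True, False)

            for _ in range(config.n_germline):
                chrom, pos = _pick_cds()
                ref = genome[chrom][pos - 1]
                alt = _alt_for(ref)
                gene, csq = classify_substitution(genome, models, chrom, pos, alt)
                germline_rows.append({"sample": t_sample, "chrom": chrom, "pos": pos,
                                      "ref": ref, "alt": alt, "vaf": 0.5,
                                      "gene": gene, "consequence": csq})
                _emit(t_sample, chrom, pos, ref, alt, config.depth_mean_tumor,
                      0.5, None, True, False)
                _emit(n_sample, chrom, pos, ref, alt, config.normal_depth,
                      0.5, None, True, False)

            for cls in ARTIFACT_CLASSES:
                for _ in range(config.artifact_counts.get(cls, 0)):
                    chrom, pos = _pick_any()
                    ref = genome[chrom][pos - 1]
                    alt = _alt_for(ref)
                    artifact_rows.append({"sample": t_sample, "chrom": chrom,
                                          "pos": pos, "ref": ref, "alt": alt,
                                          "artifact_class": cls})
                    _emit(t_sample, chrom, pos, ref, alt, config.depth_mean_tumor,
                          config.somatic_vaf, cls, True, False)
                    _emit(n_sample, chrom, pos, ref, alt, config.normal_depth,
                          0.0, None, True, False)

            for _ in range(config.n_background):
                chrom, pos = _pick_any()
                ref = genome[chrom][pos - 1]
                _emit(t_sample, chrom, pos, ref, None, config.depth_mean_tumor,
                      0.0, None, False, True)
                _emit(n_sample, chrom, pos, ref, None, config.normal_depth,
                      0.0, None, False, True)

    n_reads = [m["n"] for m in meta_rows]
    pileups = pd.DataFrame({
        "sample": np.repeat([m["sample"] for m in meta_rows], n_reads),
        "chrom": np.repeat([m["chrom"] for m in meta_rows], n_reads),
        "pos": np.repeat([m["pos"] for m in meta_rows], n_reads),
        "ref": np.repeat([m["ref"] for m in meta_rows], n_reads),
        "base": np.concatenate([b["base"] for b in blocks]),
        "base_quality": np.concatenate([b["base_quality"] for b in blocks]),
        "mapping_quality": np.concatenate([b["mapping_quality"] for b in blocks]),
        "repeat_flag": np.concatenate([b["repeat_flag"] for b in blocks]),
        "dist_5prime": np.concatenate([b["dist_5prime"] for b in blocks]),
        "dist_3prime": np.concatenate([b["dist_3prime"] for b in blocks]),
        "strand": np.concatenate([b["strand"] for b in blocks]),
    })
    pairs = pd.DataFrame(pairs_rows)
    truth = TruthTable(
        somatic=pd.DataFrame(somatic_rows, columns=_TRUTH_VARIANT_COLUMNS),
        germline=pd.DataFrame(germline_rows, columns=_TRUTH_VARIANT_COLUMNS),
        artifacts=pd.DataFrame(artifact_rows, columns=_TRUTH_ARTIFACT_COLUMNS),
    )
    truth.validate_disjoint()
    return pileups, pairs, truth


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(config: SimConfig, paired: bool = False,
                        rng: np.random.Generator | None = None
                        ) -> tuple[pd.DataFrame, dict, pd.DataFrame]:
    """Gene x sample log2 expression matrix with planted fold changes.

    Two-group mode (default): samples follow ``config.n_samples_per_group``
    and planted genes differ between the two groups by
    ``log2_effect_size`` (sign per planted direction, "up" meaning higher
    in the alphabetically first group).  Returns (matrix, sample->group
    labels, truth frame).

    Paired mode: ``n_pairs`` tumor/normal pairs with a per-pair baseline
    shift; planted genes are shifted in the tumor member.  Returns
    (matrix, tumor->normal pairing, truth frame).
    """
    ex = config.expression
    if ex.noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = rng or np.random.default_rng([config.seed, _STREAM_EXPR])
    genes = [f"eg{i + 1:04d}" for i in range(ex.n_genes)]
    de_idx = np.sort(rng.choice(ex.n_genes, size=ex.n_de_genes, replace=False))
    directions = np.where(rng.random(ex.n_de_genes) < 0.5, "up", "down")
    effect = np.zeros(ex.n_genes)
    effect[de_idx] = np.where(directions == "up", ex.log2_effect_size,
                              -ex.log2_effect_size)
    baseline = rng.normal(0.0, ex.baseline_sd, ex.n_genes)
    truth = pd.DataFrame({
        "gene": [genes[i] for i in de_idx],
        "direction": directions,
        "log2fc": effect[de_idx],
    })

    if paired:
        if ex.n_pairs < 2:
            raise ValueError("paired design needs at least 2 pairs")
        cols, data = [], []
        pairing: dict[str, str] = {}
        for k in range(ex.n_pairs):
            shift = rng.normal(0.0, ex.pair_baseline_sd, ex.n_genes)
            normal = baseline + shift + rng.normal(0.0, ex.noise_sd, ex.n_genes)
            tumor = baseline + shift + effect + rng.normal(0.0, ex.noise_sd, ex.n_genes)
            t_name, n_name = f"P{k + 1:02d}_T", f"P{k + 1:02d}_N"
            cols += [t_name, n_name]
            data += [tumor, normal]
            pairing[t_name] = n_name
        mat = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
        return mat, pairing, truth

    group_names = sorted(config.n_samples_per_group)
    if len(group_names) != 2:
        raise ValueError("two-group design needs exactly two group labels")
    if any(n < 2 for n in config.n_samples_per_group.values()):
        raise ValueError("need at least 2 samples per group")
    cols, data, groups = [], [], {}
    for gi, gname in enumerate(group_names):
        for i in range(config.n_samples_per_group[gname]):
            name = f"{gname}{i + 1}"
            cols.append(name)
            groups[name] = gname
            vals = baseline + rng.normal(0.0, ex.noise_sd, ex.n_genes)
            if gi == 0:   # effect applied to the first group
                vals = vals + effect
            data.append(vals)
    mat = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    return mat, groups, truth


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

def make_gene_sets(config: SimConfig, universe: Sequence[str],
                   hot_genes: Sequence[str] = (),
                   rng: np.random.Generator | None = None
                   ) -> tuple[dict[str, tuple[str, list[str]]], list[str]]:
    """GMT-style collection with planted enriched pathways.

    Planted sets draw ``hot_fraction`` of their members from ``hot_genes``
    (differentially expressed or mutation-scheduled genes); non-planted
    sets are drawn from the universe excluding hot genes, so by
    construction every planted set overlaps the hot list at least as much
    as any non-planted set.
    """
    pw = config.pathways
    if pw.set_size > len(universe):
        raise ValueError("set_size exceeds the gene universe")
    rng = rng or np.random.default_rng([config.seed, _STREAM_SETS])
    universe = list(universe)
    hot = [g for g in hot_genes if g in set(universe)]
    cold = [g for g in universe if g not in set(hot)]
    if len(cold) < pw.set_size:
        raise ValueError("universe minus hot genes too small for set_size")

    collection: dict[str, tuple[str, list[str]]] = {}
    planted: list[str] = []
    for si in range(pw.n_sets):
        set_id = f"pw{si + 1:03d}"
        if si < pw.planted_enriched and hot:
            n_hot = min(int(round(pw.hot_fraction * pw.set_size)), len(hot))
            members = list(rng.choice(hot, size=n_hot, replace=False))
            pool = [g for g in cold if g not in members]
            members += list(rng.choice(pool, size=pw.set_size - n_hot, replace=False))
            planted.append(set_id)
            desc = "planted_enriched"
        else:
            members = list(rng.choice(cold, size=pw.set_size, replace=False))
            desc = "background"
        collection[set_id] = (desc, sorted(members))
    return collection, planted


# ---------------------------------------------------------------------------
# Indel candidates
# ---------------------------------------------------------------------------

_INDEL_COLUMNS = ["sample", "chrom", "pos", "ref", "alt", "total_coverage",
                  "n_support", "avg_mapq_support", "avg_mismatches_support",
                  "avg_baseq_support", "median_end_offset",
                  "frac_forward_support", "frac_reverse_support",
                  "planted_fail"]


def make_indel_candidates(config: SimConfig, n_clean: int = 10,
                          plant_failures: bool = True,
                          rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Candidate somatic indel summaries with planted filter failures.

    Emits ``n_clean`` candidates passing every filter criterion plus, when
    ``plant_failures`` is set, one candidate violating exactly one
    criterion each; the ``planted_fail`` column names the violated
    criterion ("" for clean candidates).
    """
    rng = rng or np.random.default_rng([config.seed, _STREAM_INDEL])
    rows = []
    pos = 1000

    def _clean(sample: str) -> dict:
        nonlocal pos
        pos += int(rng.integers(500, 2000))
        ins = rng.random() < 0.5
        anchor = str(rng.choice(_BASES))
        extra = "".join(rng.choice(_BASES, size=int(rng.integers(1, 4))))
        ref, alt = (anchor, anchor + extra) if ins else (anchor + extra, anchor)
        f_fwd = float(rng.uniform(0.3, 0.7))
        return {"sample": sample, "chrom": "chr1", "pos": pos, "ref": ref,
                "alt": alt, "total_coverage": int(rng.integers(40, 120)),
                "n_support": int(rng.integers(8, 30)),
                "avg_mapq_support": float(rng.uniform(40, 60)),
                "avg_mismatches_support": float(rng.uniform(0.0, 1.5)),
                "avg_baseq_support": float(rng.uniform(25, 38)),
                "median_end_offset": int(rng.integers(15, 45)),
                "frac_forward_support": f_fwd,
                "frac_reverse_support": 1.0 - f_fwd,
                "planted_fail": ""}

    samples = [f"{g}{i + 1}_T" for g in sorted(config.n_samples_per_group)
               for i in range(config.n_samples_per_group[g])] or ["s1_T"]
    for i in range(n_clean):
        rows.append(_clean(samples[i % len(samples)]))
    if plant_failures:
        spoil = {
            "coverage": {"total_coverage": 25},
            "map_qual": {"avg_mapq_support": 22.0},
            "mismatches": {"avg_mismatches_support": 2.5},
            "base_qual": {"avg_baseq_support": 15.0},
            "end_offset": {"median_end_offset": 6},
            "strand_bias": {"frac_forward_support": 0.1,
                            "frac_reverse_support": 0.9},
        }
        for crit, overrides in spoil.items():
            row = _clean(samples[0])
            row.update(overrides)
            row["planted_fail"] = crit
            rows.append(row)
    return pd.DataFrame(rows, columns=_INDEL_COLUMNS)
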