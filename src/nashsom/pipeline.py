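"""End-to-end orchestration: simulate -> call -> filter -> landscape -> DE ->
enrichment, with a run manifest and a truth-vs-recovered report.

Every stage writes its inputs and outputs to disk in the plain-text formats
of :mod:`nashsom.io`, and downstream stages re-read those files, so a run
also exercises every serialization round trip.  The report juxtaposes
recovered results against the planted truth: SNV sensitivity and
specificity, per-artifact-class rejection with the matching filter flag,
germline leakage, recurrent-gene recall, DE recall and false-positive rate,
enrichment recall, and the cohort statistics (burden fold with Welch t,
chi-square frequency comparison).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd

from . import enrichment as enr
from . import expression as de
from . import indel as indel_mod
from . import io, landscape, simulate, snv

__all__ = ["run_all"]

logger = logging.getLogger(__name__)

_ARTIFACT_STAGE = {"end_biased": "end_bias", "repeat_biased": "repeat_align",
                   "low_quality_alt": "baseq_rank"}


def _json_default(o):
    if dataclasses.is_dataclass(o) and not isinstance(o, type):
        return dataclasses.asdict(o)
    if isinstance(o, (pd.Series,)):
        return o.to_dict()
    return str(o)


def _snv_truth_metrics(calls, truth: simulate.TruthTable) -> dict:
    by_key = {(c.sample, c.chrom, c.pos): c for c in calls}

    som = truth.somatic
    n_som = len(som)
    hits = 0
    for _, ev in som.iterrows():
        c = by_key.get((ev["sample"], ev["chrom"], int(ev["pos"])))
        if c is not None and c.passed and c.alt == ev["alt"]:
            hits += 1
    germ_pass = 0
    for _, ev in truth.germline.iterrows():
        c = by_key.get((ev["sample"], ev["chrom"], int(ev["pos"])))
        if c is not None and c.passed:
            germ_pass += 1
    per_class: dict[str, dict] = {}
    for cls, stage in _ARTIFACT_STAGE.items():
        sub = truth.artifacts[truth.artifacts["artifact_class"] == cls]
        rejected = flagged = 0
        for _, ev in sub.iterrows():
            c = by_key.get((ev["sample"], ev["chrom"], int(ev["pos"])))
            if c is None or not c.passed:
                rejected += 1
                if c is not None and stage in c.failed_stages:
                    flagged += 1
        n = len(sub)
        per_class[cls] = {
            "n": n, "rejected": rejected, "flagged": flagged,
            "rejected_frac": rejected / n if n else float("nan"),
            "flagged_frac": flagged / n if n else float("nan"),
        }
    truth_keys = set()
    for df in (truth.somatic, truth.germline, truth.artifacts):
        truth_keys |= {(r["sample"], r["chrom"], int(r["pos"])) for _, r in df.iterrows()}
    background_pass = sum(1 for k, c in by_key.items()
                          if c.passed and k not in truth_keys)
    return {
        "n_somatic_planted": n_som,
        "somatic_sensitivity": hits / n_som if n_som else float("nan"),
        "germline_pass": germ_pass,
        "background_pass": background_pass,
        "artifact_classes": per_class,
    }


def run_all(config: simulate.SimConfig, outdir,
            snv_params: snv.SnvParams | None = None,
            indel_params: indel_mod.IndelParams | None = None) -> dict:
    """Run every pipeline stage on synthetic data; returns the manifest.

    Writes all intermediates plus ``manifest.json`` and ``report.json``
    under ``outdir``.  Any stage failure propagates with intermediates
    preserved on disk.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    snv_params = snv_params or snv.SnvParams()
    indel_params = indel_params or indel_mod.IndelParams()
    paths: dict[str, str] = {}
    counts: dict[str, int] = {}

    def _p(name: str) -> Path:
        paths[name] = str(out / name)
        return out / name

    stage = "simulate_genome"
    try:
        genome, models = simulate.make_genome(config)
        io.write_fasta(genome, _p("genome.fa"))
        io.write_gene_models(models, _p("gene_models.tsv"))
        counts["genes"] = len(models)

        stage = "simulate_pileups"
        pileups, pairs, truth = simulate.simulate_paired_pileups(genome, models, config)
        io.write_pileups(pileups, _p("pileups.tsv"))
        io.write_pair_manifest(pairs, _p("pairs.tsv"))
        truth.somatic.to_csv(_p("truth_somatic.tsv"), sep="\t", index=False)
        truth.germline.to_csv(_p("truth_germline.tsv"), sep="\t", index=False)
        truth.artifacts.to_csv(_p("truth_artifacts.tsv"), sep="\t", index=False)
        counts["pileup_rows"] = len(pileups)
        counts["somatic_planted"] = len(truth.somatic)

        stage = "call_snvs"
        sites = io.read_pileups(out / "pileups.tsv", io.read_pair_manifest(out / "pairs.tsv"))
        calls = snv.call_snvs(sites, snv_params)
        io.write_vcf(snv.calls_to_records(calls), _p("snvs.vcf"),
                     snv.FILTER_DESCRIPTIONS)
        counts["snv_candidates"] = len(calls)
        counts["snv_pass"] = sum(c.passed for c in calls)

        stage = "filter_indels"
        cand_frame = simulate.make_indel_candidates(config)
        cand_frame.to_csv(_p("indel_candidates.tsv"), sep="\t", index=False)
        io.write_known_sites(
            {(r["chrom"], int(r["pos"]), r["ref"], r["alt"])
             for _, r in truth.germline.iterrows()}, _p("known_sites.tsv"))
        known = io.read_known_sites(out / "known_sites.tsv")
        candidates = indel_mod.candidates_from_frame(
            pd.read_csv(out / "indel_candidates.tsv", sep="\t", keep_default_na=False))
        verdicts = indel_mod.filter_indels(candidates, indel_params, known)
        io.write_vcf(indel_mod.verdicts_to_records(verdicts), _p("indels.vcf"),
                     indel_mod.INDEL_FILTER_DESCRIPTIONS)
        counts["indel_candidates"] = len(verdicts)
        counts["indel_pass"] = sum(v.passed for v in verdicts)

        stage = "mutation_landscape"
        pass_records = [r for r in io.read_vcf(out / "snvs.vcf")
                        if r.filter_status == "PASS"]
        mut_records = landscape.annotate_all(pass_records, models, genome)
        groups_by_tumor = {row["tumor_sample"]: row["group"]
                           for _, row in pairs.iterrows()}
        rec = landscape.build_recurrence(
            mut_records, samples=list(groups_by_tumor), groups=groups_by_tumor)
        rec.indicators.to_csv(_p("recurrence.tsv"), sep="\t", index_label="gene")
        group_names = sorted(config.n_samples_per_group)
        recurrent = rec.recurrent_genes(min_samples=2, group=group_names[0])
        burden_counts = landscape.mutated_gene_counts(mut_records)
        by_group = {
            g: [int(burden_counts.get(s, 0)) for s in rec.samples_in(g)]
            for g in group_names
        }
        burden = (landscape.burden_compare(by_group)
                  if all(len(v) >= 2 for v in by_group.values()) else None)
        chi = None
        if recurrent:
            top = max(recurrent,
                      key=lambda g: rec.indicators.loc[g, rec.samples_in(group_names[0])].sum())
            k1 = int(rec.indicators.loc[top, rec.samples_in(group_names[0])].sum())
            k2 = int(rec.indicators.loc[top, rec.samples_in(group_names[1])].sum()) \
                if top in rec.indicators.index else 0
            n1 = len(rec.samples_in(group_names[0]))
            n2 = len(rec.samples_in(group_names[1]))
            try:
                chi = {"gene": top, "k1": k1, "n1": n1, "k2": k2, "n2": n2,
                       "test": landscape.frequency_compare(k1, n1, k2, n2)}
            except ValueError:
                chi = None
        counts["recurrent_genes"] = len(recurrent)

        # recurrent-gene recall: planted non-synonymous somatic genes hit in
        # >=2 samples of the first group, recovered in the recurrent list
        som = truth.somatic
        som_ns = som[som["consequence"].isin(landscape.NONSYNONYMOUS)]
        first_group_samples = {f"{group_names[0]}{i + 1}_T"
                               for i in range(config.n_samples_per_group[group_names[0]])}
        in_group = som_ns[som_ns["sample"].isin(first_group_samples)]
        planted_rec = {g for g, sub in in_group.groupby("gene")
                       if sub["sample"].nunique() >= 2}
        rec_recall = (len(planted_rec & set(recurrent)) / len(planted_rec)
                      if planted_rec else float("nan"))

        stage = "expression_de"
        matrix, expr_groups, de_truth = simulate.simulate_expression(config)
        io.write_matrix(matrix, _p("expression.tsv"))
        matrix = io.read_matrix(out / "expression.tsv")
        up, down, de_table = de.de_genes(matrix, expr_groups)
        de_table.to_csv(_p("de_results.tsv"), sep="\t", index_label="gene")
        recovered = set(up) | set(down)
        de_genes_truth = set(de_truth["gene"])
        de_recall = (len(recovered & de_genes_truth) / len(de_genes_truth)
                     if de_genes_truth else float("nan"))
        nulls = set(matrix.index) - de_genes_truth
        de_fpr = len(recovered & nulls) / len(nulls) if nulls else float("nan")
        counts["de_up"], counts["de_down"] = len(up), len(down)

        stage = "enrichment"
        collection, planted_sets = simulate.make_gene_sets(
            config, list(matrix.index), hot_genes=sorted(de_genes_truth))
        io.write_gmt(collection, _p("gene_sets.gmt"))
        results = enr.enrich(sorted(recovered), io.read_gmt(out / "gene_sets.gmt"),
                             list(matrix.index), min_genes=4)
        enr.results_to_frame(results).to_csv(_p("enrichment.tsv"), sep="\t")
        sig = {r.set_id for r in results if r.significant}
        enr_recall = (len(sig & set(planted_sets)) / len(planted_sets)
                      if planted_sets else float("nan"))

        per_sample_genes = {
            s: sorted({r.gene for r in mut_records
                       if r.sample == s and r.gene and r.nonsynonymous})
            for s in sorted(first_group_samples)}
        # pathway sizes are tuned to the expression universe; rescale for
        # the (much smaller) genome gene universe of the mutation arm
        gene_universe = [m.gene_id for m in models]
        mut_set_size = max(3, min(config.pathways.set_size, len(gene_universe) // 4))
        mut_cfg = dataclasses.replace(
            config, pathways=dataclasses.replace(config.pathways,
                                                 set_size=mut_set_size))
        hot_mut = sorted(set(som_ns["gene"].dropna()))[:len(gene_universe) - mut_set_size]
        mut_collection, mut_planted = simulate.make_gene_sets(
            mut_cfg, gene_universe, hot_genes=hot_mut)
        mut_report = enr.per_sample_mutation_enrichment(
            per_sample_genes, mut_collection, gene_universe,
            min_samples=3, min_genes=3)
        mut_report.to_csv(_p("mutation_enrichment.tsv"), sep="\t")
    except Exception:
        logger.exception("pipeline stage %r failed; intermediates kept in %s",
                         stage, out)
        raise

    report = {
        "snv": _snv_truth_metrics(calls, truth),
        "recurrent_gene_recall": rec_recall,
        "burden": None if burden is None else {
            "groups": burden["groups"], "means": burden["means"],
            "sds": burden["sds"], "fold": burden["fold"],
            "welch_t": burden["test"].statistic, "welch_p": burden["test"].p_value,
        },
        "frequency_chi_square": None if chi is None else {
            "gene": chi["gene"], "k1": chi["k1"], "n1": chi["n1"],
            "k2": chi["k2"], "n2": chi["n2"],
            "statistic": chi["test"].statistic, "p": chi["test"].p_value,
        },
        "expression": {"de_recall": de_recall, "de_fpr": de_fpr,
                       "n_up": len(up), "n_down": len(down)},
        "enrichment": {"recall": enr_recall, "planted": planted_sets,
                       "significant": sorted(sig),
                       "mutation_pathways_reported":
                           sorted(mut_report.index[mut_report["reported"]])
                           if len(mut_report) else []},
    }
    manifest = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "snv_params": dataclasses.asdict(snv_params),
        "indel_params": dataclasses.asdict(indel_params),
        "paths": paths,
        "counts": counts,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=_json_default))
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=_json_default))
    manifest["report"] = report
    return manifest
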