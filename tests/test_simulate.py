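"""Simulator tests: determinism, construction invariants, calibration."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from nashsom import simulate
from nashsom.landscape import coding_sequence


def small_config(**kw):
    defaults = dict(seed=5, n_chromosomes=1, chrom_length=50_000, n_genes=20,
                    n_samples_per_group={"NASH": 2, "steatosis": 2},
                    n_somatic_per_sample=10, n_germline=5, n_background=30,
                    artifact_counts={"end_biased": 2, "repeat_biased": 2,
                                     "low_quality_alt": 2})
    defaults.update(kw)
    return simulate.SimConfig(**defaults)


class TestConfig:
    def test_vaf_below_error_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate.SimConfig(somatic_vaf=0.001, base_error_rate=0.01)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            simulate.SimConfig(n_somatic_per_sample=-1)

    def test_normal_depth_defaults_to_tumor(self):
        assert simulate.SimConfig(depth_mean_tumor=55).normal_depth == 55


class TestGenome:
    def test_deterministic_by_seed(self):
        g1, m1 = simulate.make_genome(small_config())
        g2, m2 = simulate.make_genome(small_config())
        assert g1 == g2
        assert m1 == m2

    def test_different_seed_differs(self):
        g1, _ = simulate.make_genome(small_config(seed=5))
        g2, _ = simulate.make_genome(small_config(seed=6))
        assert g1 != g2

    def test_gene_models_construction_invariants(self):
        config = small_config(n_genes=10)
        genome, models = simulate.make_genome(config)
        assert len(models) == 10
        spans = sorted((m.chrom, m.start, m.end) for m in models)
        for (c1, s1, e1), (c2, s2, e2) in zip(spans, spans[1:]):
            assert c1 != c2 or e1 < s2        # non-overlapping
        for m in models:
            assert m.cds_length % 3 == 0
            cds = coding_sequence(genome, m)
            assert cds.startswith("ATG")
            protein = str(Seq(cds).translate())
            assert "*" not in protein[:-1]     # no internal stop codon

    def test_infeasible_sizing_raises(self):
        with pytest.raises(ValueError, match="fit|small"):
            simulate.make_genome(small_config(chrom_length=1000, n_genes=50))


@pytest.fixture(scope="module")
def sim():
    config = small_config()
    genome, models = simulate.make_genome(config)
    pileups, pairs, truth = simulate.simulate_paired_pileups(genome, models, config)
    return config, genome, models, pileups, pairs, truth


class TestPileups:
    def test_truth_counts_conserved(self, sim):
        config, _, _, _, pairs, truth = sim
        n_samples = sum(config.n_samples_per_group.values())
        assert len(truth.somatic) == n_samples * config.n_somatic_per_sample
        assert len(truth.germline) == n_samples * config.n_germline
        per_class = truth.artifacts.groupby("artifact_class").size()
        for cls, count in config.artifact_counts.items():
            assert per_class[cls] == n_samples * count

    def test_every_truth_locus_present_in_pileups(self, sim):
        _, _, _, pileups, _, truth = sim
        emitted = set(zip(pileups["sample"], pileups["chrom"], pileups["pos"]))
        for df in (truth.somatic, truth.germline, truth.artifacts):
            for _, ev in df.iterrows():
                assert (ev["sample"], ev["chrom"], ev["pos"]) in emitted

    def test_truth_categories_disjoint(self, sim):
        *_, truth = sim
        truth.validate_disjoint()   # raises on violation

    def test_deterministic_by_seed(self, sim):
        config, genome, models, pileups, pairs, truth = sim
        p2, _, t2 = simulate.simulate_paired_pileups(genome, models, config)
        pd.testing.assert_frame_equal(pileups, p2)
        pd.testing.assert_frame_equal(truth.somatic, t2.somatic)

    def test_pooled_somatic_alt_fraction_matches_vaf(self):
        # binomial sampling check pooled over >=100 planted loci
        config = small_config(n_somatic_per_sample=30, n_germline=0,
                              n_background=0, somatic_vaf=0.3,
                              artifact_counts={})
        genome, models = simulate.make_genome(config)
        pileups, _, truth = simulate.simulate_paired_pileups(genome, models, config)
        assert len(truth.somatic) >= 100
        tumor = pileups[pileups["sample"].str.endswith("_T")]
        keys = set(zip(truth.somatic["sample"], truth.somatic["chrom"],
                       truth.somatic["pos"]))
        at_truth = tumor[[k in keys for k in
                          zip(tumor["sample"], tumor["chrom"], tumor["pos"])]]
        n = len(at_truth)
        alt_frac = float((at_truth["base"] != at_truth["ref"]).mean())
        se = np.sqrt(0.3 * 0.7 / n)
        assert abs(alt_frac - 0.3) < 3 * se

    def test_germline_alt_fraction_above_normal_gate_threshold(self):
        # at depth 80 and VAF 0.5 virtually every germline locus shows >2%
        # alt in both tumor and normal, so the allele-frequency gate catches it
        config = small_config(n_somatic_per_sample=0, n_germline=25,
                              n_background=0, artifact_counts={},
                              depth_mean_tumor=80.0)
        genome, models = simulate.make_genome(config)
        pileups, _, truth = simulate.simulate_paired_pileups(genome, models, config)
        frac_ok = []
        for (sample, chrom, pos), g in pileups.groupby(["sample", "chrom", "pos"]):
            frac_ok.append(float((g["base"] != g["ref"]).mean()) > 0.02)
        assert np.mean(frac_ok) >= 0.99

    def test_end_biased_artifacts_sit_near_read_ends(self, sim):
        _, _, _, pileups, _, truth = sim
        ends = truth.artifacts[truth.artifacts["artifact_class"] == "end_biased"]
        for _, ev in ends.iterrows():
            g = pileups[(pileups["sample"] == ev["sample"]) &
                        (pileups["chrom"] == ev["chrom"]) &
                        (pileups["pos"] == ev["pos"])]
            alt = g[g["base"] == ev["alt"]]
            if len(alt):
                assert (np.minimum(alt["dist_5prime"], alt["dist_3prime"]) < 10).all()


class TestExpression:
    def test_null_effect_means_no_true_difference(self):
        config = small_config()
        config.expression.log2_effect_size = 0.0
        _, _, truth = simulate.simulate_expression(config)
        assert (truth["log2fc"] == 0).all()

    def test_deterministic(self):
        config = small_config()
        m1, g1, t1 = simulate.simulate_expression(config)
        m2, g2, t2 = simulate.simulate_expression(config)
        pd.testing.assert_frame_equal(m1, m2)
        assert g1 == g2

    def test_planted_effect_recovered_in_group_means(self):
        # Monte-Carlo mean of the planted group difference over 50 seeds
        diffs = []
        effect = None
        for seed in range(50):
            config = small_config(seed=seed)
            config.expression.n_genes = 100
            config.expression.n_de_genes = 10
            effect = config.expression.log2_effect_size
            mat, groups, truth = simulate.simulate_expression(config)
            g1 = [s for s, g in groups.items() if g == "NASH"]
            g2 = [s for s, g in groups.items() if g == "steatosis"]
            up = truth.loc[truth["direction"] == "up", "gene"]
            if len(up):
                d = (mat.loc[up, g1].mean(axis=1) - mat.loc[up, g2].mean(axis=1))
                diffs.extend(d.tolist())
        diffs = np.asarray(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean() - effect) < 3 * se

    def test_invalid_noise_rejected(self):
        config = small_config()
        config.expression.noise_sd = 0.0
        with pytest.raises(ValueError):
            simulate.simulate_expression(config)

    def test_paired_design_structure(self):
        config = small_config()
        config.expression.n_pairs = 6
        mat, pairing, truth = simulate.simulate_expression(config, paired=True)
        assert len(pairing) == 6
        assert set(mat.columns) == set(pairing) | set(pairing.values())


class TestGeneSets:
    def test_collection_shape_and_distinctness(self):
        config = small_config()
        config.pathways.n_sets, config.pathways.set_size = 10, 5
        universe = [f"x{i}" for i in range(200)]
        coll, planted = simulate.make_gene_sets(config, universe, universe[:20])
        assert len(coll) == 10
        for _, (_, genes) in coll.items():
            assert len(genes) == 5 and len(set(genes)) == 5
            assert set(genes) <= set(universe)
        assert len(planted) == config.pathways.planted_enriched

    def test_planted_sets_dominate_hot_overlap(self):
        config = small_config()
        universe = [f"x{i}" for i in range(200)]
        hot = universe[:30]
        coll, planted = simulate.make_gene_sets(config, universe, hot)
        overlaps = {sid: len(set(genes) & set(hot))
                    for sid, (_, genes) in coll.items()}
        worst_planted = min(overlaps[p] for p in planted)
        best_other = max((v for s, v in overlaps.items() if s not in planted),
                         default=0)
        assert worst_planted >= best_other

    def test_oversized_sets_rejected(self):
        config = small_config()
        config.pathways.set_size = 10
        with pytest.raises(ValueError):
            simulate.make_gene_sets(config, ["a", "b", "c"], [])


class TestIndelCandidates:
    def test_one_planted_failure_per_criterion(self):
        df = simulate.make_indel_candidates(small_config())
        planted = df[df["planted_fail"] != ""]
        assert sorted(planted["planted_fail"]) == sorted(
            ["coverage", "map_qual", "mismatches", "base_qual",
             "end_offset", "strand_bias"])
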