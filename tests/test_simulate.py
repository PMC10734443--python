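"""The synthetic-data generators: layout guarantees, determinism, and
the statistical marginals the downstream stages rely on."""
from __future__ import annotations

import numpy as np
import pytest

import redoxreg as rr
from redoxreg.simulate import PlantedCluster, SimulationConfig, gen_annotation, gen_counts


def gaps_of(annotation):
    genes = list(annotation)
    return [b.start - a.end - 1 for a, b in zip(genes, genes[1:])]


class TestAnnotation:
    def test_planted_cluster_gaps_straddle_threshold(self):
        cfg = SimulationConfig(
            n_genes=10,
            planted_clusters=(PlantedCluster(3, "+", -4.0),),
            gap_small_range=(50, 100),
            seed=3,
        )
        annotation, truth = gen_annotation(cfg)
        members = truth.cluster_members[0]
        assert len(members) == 3
        strands = {annotation[m].strand for m in members}
        assert strands == {"+"}
        genes = list(annotation)
        idx = [i for i, g in enumerate(genes) if g.gene_id in members]
        assert idx == list(range(idx[0], idx[0] + 3)), "cluster members must be consecutive"
        internal = [genes[i + 1].start - genes[i].end - 1 for i in idx[:-1]]
        assert all(50 <= gap <= 100 for gap in internal)
        # flanking gaps break the chain
        if idx[0] > 0:
            assert genes[idx[0]].start - genes[idx[0] - 1].end - 1 >= 250
        if idx[-1] < len(genes) - 1:
            assert genes[idx[-1] + 1].start - genes[idx[-1]].end - 1 >= 250

    def test_without_clusters_all_gaps_break_chains(self):
        annotation, _ = gen_annotation(SimulationConfig(n_genes=30, seed=4))
        assert all(gap >= 250 for gap in gaps_of(annotation))

    def test_no_overlaps_and_sorted(self):
        cfg = SimulationConfig(
            n_genes=100, planted_clusters=(PlantedCluster(4, "-", 8.0),), seed=5
        )
        annotation, _ = gen_annotation(cfg)
        assert all(gap >= 0 for gap in gaps_of(annotation))
        assert annotation.same_strand_overlaps == []

    def test_determinism(self):
        cfg = SimulationConfig(n_genes=50, planted_clusters=(PlantedCluster(3, "+", -2.0),), seed=9)
        a1, t1 = gen_annotation(cfg)
        a2, t2 = gen_annotation(cfg)
        assert [(g.gene_id, g.start, g.end, g.strand) for g in a1] == [
            (g.gene_id, g.start, g.end, g.strand) for g in a2
        ]
        assert t1.true_fc == t2.true_fc

    def test_contig_too_short(self):
        with pytest.raises(ValueError, match="contig too short"):
            gen_annotation(SimulationConfig(n_genes=100, contig_length=5000, seed=0))

    def test_planted_clusters_satisfy_tc_predicate(self):
        """Planted-truth soundness: every planted cluster passes the TC
        caller's own predicate and is recovered verbatim from perfect
        candidate input."""
        import pandas as pd

        cfg = SimulationConfig(
            n_genes=60,
            planted_clusters=(
                PlantedCluster(3, "+", -4.0),
                PlantedCluster(5, "-", 16.0),
                PlantedCluster(2, "+", 2.0),
            ),
            seed=11,
        )
        annotation, truth = gen_annotation(cfg)
        planted_genes = [g for g, c in truth.cluster_of.items()]
        candidates = pd.DataFrame(
            {
                "fc": [truth.true_fc[g] for g in planted_genes],
                "direction": ["down" if truth.true_fc[g] < 0 else "up" for g in planted_genes],
            },
            index=pd.Index(planted_genes, name="gene_id"),
        )
        tcs, isolated = rr.call_tcs(candidates, annotation)
        assert isolated == []
        assert {t.members for t in tcs} == {tuple(v) for v in truth.cluster_members.values()}


class TestCounts:
    def test_null_ratio_near_one(self):
        cfg = SimulationConfig(
            n_genes=300,
            nb_dispersion=0.0,
            mean_expression_range=(2000.0, 5000.0),
            library_factor_range=(1.0, 1.0),
            n_replicates=6,
            seed=21,
        )
        annotation, truth = gen_annotation(cfg)
        m = gen_counts(annotation, truth, cfg)
        wt = m.counts[m.samples_of("wt")].mean(axis=1)
        mut = m.counts[m.samples_of("mut")].mean(axis=1)
        ratio = (mut / wt).to_numpy()
        assert np.allclose(ratio, 1.0, atol=0.05)

    def test_planted_fc_minus4_recovered(self):
        """Empirical mutant/wt mean ratio matches the analytic NB mean
        ratio 1/4 for 200 genes planted at signed fc -4."""
        cfg = SimulationConfig(
            n_genes=200,
            planted_isolated=(-4.0,) * 200,
            contig_length=10_000_000,
            nb_dispersion=0.001,
            mean_expression_range=(2000.0, 5000.0),
            library_factor_range=(1.0, 1.0),
            n_replicates=6,
            seed=22,
        )
        annotation, truth = gen_annotation(cfg)
        m = gen_counts(annotation, truth, cfg)
        wt = m.counts[m.samples_of("wt")].mean(axis=1).to_numpy()
        mut = m.counts[m.samples_of("mut")].mean(axis=1).to_numpy()
        est_fc = -(wt / mut)  # signed convention for downregulation
        assert abs(est_fc.mean() - (-4.0)) < 0.1

    def test_nb_marginal_variance(self):
        """Across 5,000 genes the replicate variance tracks the NB law
        var = mu + d*mu^2 within 10%."""
        cfg = SimulationConfig(
            n_genes=5000,
            contig_length=60_000_000,
            nb_dispersion=0.1,
            n_replicates=10,
            library_factor_range=(1.0, 1.0),
            seed=23,
        )
        annotation, truth = gen_annotation(cfg)
        m = gen_counts(annotation, truth, cfg)
        wt = m.counts[m.samples_of("wt")].to_numpy(dtype=float)
        mu = wt.mean(axis=1)
        var = wt.var(axis=1, ddof=1)
        expected = mu + cfg.nb_dispersion * mu**2
        assert abs(np.mean(var / expected) - 1.0) < 0.1

    def test_determinism(self):
        cfg = SimulationConfig(n_genes=40, seed=24)
        annotation, truth = gen_annotation(cfg)
        m1 = gen_counts(annotation, truth, cfg)
        m2 = gen_counts(annotation, truth, cfg)
        assert m1.counts.equals(m2.counts)


class TestVariantsAndGrowth:
    def test_planted_unique_calls_survive_screen(self):
        cfg = SimulationConfig(n_unique_variants=2, n_decoy_variants=3, seed=31)
        wt, mut, truth = rr.gen_variants(cfg)
        unique = rr.unique_to_mutant(rr.filter_variants(mut), rr.filter_variants(wt))
        assert {v.key for v in unique} == set(truth.unique_variant_keys)
        assert len(unique) == 2

    def test_no_planted_unique(self):
        cfg = SimulationConfig(n_unique_variants=0, n_decoy_variants=2, seed=32)
        wt, mut, _ = rr.gen_variants(cfg)
        assert rr.unique_to_mutant(rr.filter_variants(mut), rr.filter_variants(wt)) == []

    def test_variant_determinism(self):
        cfg = SimulationConfig(seed=33)
        assert rr.gen_variants(cfg)[1] == rr.gen_variants(cfg)[1]

    def test_growth_noise_free_delta_pmp(self):
        from redoxreg.phenotype import endpoint_delta_pmp

        cfg = SimulationConfig(pigment_effect=0.5, growth_noise_sd=0.0, seed=34)
        dpmp = endpoint_delta_pmp(rr.gen_growth(cfg), "O1")
        assert dpmp[("wt", "C3")] == pytest.approx(0.5)
        assert dpmp[("wt", "O1")] == 0.0
        assert dpmp[("mut", "C3")] == pytest.approx(0.0)

    def test_growth_zero_pigment_effect(self):
        from redoxreg.phenotype import endpoint_delta_pmp

        cfg = SimulationConfig(pigment_effect=0.0, growth_noise_sd=0.0, seed=35)
        assert all(v == pytest.approx(0.0) for v in endpoint_delta_pmp(rr.gen_growth(cfg), "O1").values())

    def test_growth_determinism(self):
        cfg = SimulationConfig(seed=36)
        g1, g2 = rr.gen_growth(cfg), rr.gen_growth(cfg)
        assert all(np.array_equal(a.od880, b.od880) for a, b in zip(g1, g2))
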