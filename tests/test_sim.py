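"""The synthetic-data generator: determinism, planted-truth
bookkeeping, marginal NB calibration and fixture emitters."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crossregen import (
    SimConfig,
    emit_genesets,
    emit_orthomap,
    emit_targets,
    filter_low_expression,
    paired_de,
    simulate_paired_cohort,
    simulate_timecourse,
    tmm_factors,
)
from crossregen.sim import MirnaBlock, _nb_counts


class TestConfigValidation:
    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            SimConfig(frac_de=1.5)

    def test_bad_counts(self):
        with pytest.raises(ValueError):
            SimConfig(n_injured_per_tp=0)

    def test_unsorted_timepoints(self):
        with pytest.raises(ValueError):
            SimConfig(timepoints=(4, 1, 7))


class TestDeterminism:
    def test_timecourse_bitwise_identical(self):
        cfg = SimConfig(seed=9, n_genes=300)
        a, _ = simulate_timecourse(cfg)
        b, _ = simulate_timecourse(cfg)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_cohort_bitwise_identical(self):
        cfg = SimConfig(seed=9, n_genes=300, n_pairs=4)
        a, am, at = simulate_paired_cohort(cfg)
        b, bm, bt = simulate_paired_cohort(cfg)
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_frame_equal(am.counts, bm.counts)
        assert at.tumor_lfc == bt.tumor_lfc

    def test_different_seeds_differ(self):
        a, _ = simulate_timecourse(SimConfig(seed=1, n_genes=200))
        b, _ = simulate_timecourse(SimConfig(seed=2, n_genes=200))
        assert not a.counts.equals(b.counts)


class TestTimecourseTruth:
    def test_null_case_no_planted_genes(self):
        cfg = SimConfig(seed=0, n_genes=300, frac_de=0.0)
        cm, truth = simulate_timecourse(cfg)
        assert all(a is None for a in truth.archetype.values())
        inj = cm.meta.index[cm.meta["condition"] == "injured"]
        hea = cm.meta.index[cm.meta["condition"] == "healthy"]
        # shared baseline: per-gene CPM means agree between groups
        c = cm.counts / cm.counts.sum(axis=0) * 1e6
        ratio = (c[inj].mean(axis=1) + 1) / (c[hea].mean(axis=1) + 1)
        assert np.median(np.abs(np.log2(ratio))) < 0.25

    def test_archetype_bookkeeping(self):
        cfg = SimConfig(seed=4, n_genes=2000, frac_de=0.25)
        _, truth = simulate_timecourse(cfg)
        assigned = [a for a in truth.archetype.values() if a is not None]
        assert len(assigned) == 500
        counts = pd.Series(assigned).value_counts()
        assert counts.sum() == 500 and counts.min() >= 90

    def test_peak_effect_magnitude_monte_carlo(self):
        """A planted gene peaking at ~4 dpi with effect 2 shows an
        injured/healthy mean ratio within 2x of 2^2 at 50 replicates."""
        cfg = SimConfig(seed=12, n_genes=400, frac_de=0.25, effect_size=2.0,
                        amp_jitter=0.0, n_injured_per_tp=50, n_healthy=50,
                        timepoints=(1, 4, 7))
        cm, truth = simulate_timecourse(cfg)
        c = cm.counts / cm.counts.sum(axis=0) * 1e6
        inj4 = cm.meta.index[(cm.meta["condition"] == "injured")
                             & (cm.meta["timepoint"] == 4.0)]
        hea = cm.meta.index[cm.meta["condition"] == "healthy"]
        # archetype 4 (sharp up, peak 5.5d) is near its max at 4 dpi
        from crossregen.sim import DEFAULT_ARCHETYPES
        expected = 2.0 ** (2.0 * DEFAULT_ARCHETYPES[4](np.array([4.0]))[0])
        genes = [g for g, a in truth.archetype.items() if a == 4]
        ratios = (c.loc[genes, inj4].mean(axis=1) / c.loc[genes, hea].mean(axis=1))
        med = float(np.median(ratios))
        assert expected / 2 <= med <= expected * 2

    def test_sham_effect_gone_by_30dpi(self):
        cfg = SimConfig(seed=5, n_genes=400, frac_de=0.5, sham_scale=0.5)
        cm, truth = simulate_timecourse(cfg)
        c = cm.counts / cm.counts.sum(axis=0) * 1e6
        hea = cm.meta.index[cm.meta["condition"] == "healthy"]
        planted = [g for g, a in truth.archetype.items() if a is not None]
        for t in (45.0, 120.0):
            sham = cm.meta.index[(cm.meta["condition"] == "sham")
                                 & (cm.meta["timepoint"] == t)]
            ratio = c.loc[planted, sham].mean(axis=1) / c.loc[planted, hea].mean(axis=1)
            assert np.median(np.abs(np.log2(ratio))) < 0.3


class TestNBMarginals:
    def test_variance_matches_parameterization(self):
        rng = np.random.default_rng(0)
        mu = np.full(5000, 200.0)
        for phi in (0.0, 0.05, 0.3):
            draws = _nb_counts(rng, mu, np.full_like(mu, phi))
            target = 200 + phi * 200**2
            assert np.var(draws) == pytest.approx(target, rel=0.12)

    def test_poisson_at_zero_dispersion(self):
        rng = np.random.default_rng(1)
        draws = _nb_counts(rng, np.full(200, 50.0), np.zeros(200))
        assert draws.min() >= 0


class TestCohort:
    def test_needs_three_pairs(self):
        with pytest.raises(ValueError):
            simulate_paired_cohort(SimConfig(n_pairs=2))

    def test_zero_slope_targets_uncorrelated(self):
        cfg = SimConfig(seed=6, n_genes=500, n_pairs=15,
                        mirna_block=MirnaBlock(slope=0.0, up_lfc=0.0))
        cm, cm_mi, truth = simulate_paired_cohort(cfg)
        c = np.log2(cm.counts / cm.counts.sum(axis=0) * 1e6 + 1)
        cmi = np.log2(cm_mi.counts / cm_mi.counts.sum(axis=0) * 1e6 + 1)
        rhos = []
        for m, targets in truth.mirna_targets.items():
            for g in targets:
                rhos.append(stats.pearsonr(cmi.loc[m], c.loc[g])[0])
        assert abs(np.mean(rhos)) < 0.2

    def test_negative_slope_targets_anticorrelated(self):
        cfg = SimConfig(seed=6, n_genes=500, n_pairs=15)
        cm, cm_mi, truth = simulate_paired_cohort(cfg)
        c = np.log2(cm.counts / cm.counts.sum(axis=0) * 1e6 + 1)
        cmi = np.log2(cm_mi.counts / cm_mi.counts.sum(axis=0) * 1e6 + 1)
        rhos = [stats.pearsonr(cmi.loc[m], c.loc[g])[0]
                for m, tg in truth.mirna_targets.items() for g in tg]
        assert np.median(rhos) < -0.5

    def test_paired_beats_unpaired_with_patient_effects(self):
        """The paired design recovers more planted genes than an
        unpaired two-sample test on the same data."""
        from crossregen import call_degs, log_cpm

        cfg = SimConfig(seed=8, n_genes=1500, n_pairs=10, frac_de=0.1,
                        effect_size=1.2, patient_sd=1.2)
        cm, _, truth = simulate_paired_cohort(cfg)
        cm = filter_low_expression(cm)
        fac = tmm_factors(cm)
        de = call_degs(paired_de(cm, fac), fdr_cut=0.05, relax_fdr=None)
        paired_hits = set(de.genes_called("up")) | set(de.genes_called("down"))

        expr = log_cpm(cm, fac)
        tum = cm.meta.index[cm.meta["condition"] == "tumor"]
        nor = cm.meta.index[cm.meta["condition"] == "normal"]
        t, p = stats.ttest_ind(expr[tum], expr[nor], axis=1, equal_var=False)
        from crossregen import bh_fdr

        unpaired_hits = set(expr.index[(bh_fdr(p) < 0.05)
                                       & (np.abs(expr[tum].mean(1) - expr[nor].mean(1)) > 1)])
        planted = {g for g, l in truth.tumor_lfc.items()
                   if l != 0 and g in set(cm.genes)}
        recall_paired = len(paired_hits & planted) / len(planted)
        recall_unpaired = len(unpaired_hits & planted) / len(planted)
        assert recall_paired > recall_unpaired


class TestEmitters:
    def test_orthomap_bijective_without_one2many(self):
        cfg = SimConfig(seed=0, n_genes=100, one2many_frac=0.0)
        omap = emit_orthomap(cfg)
        assert len(omap.pairs) == 100
        assert omap.pairs["gene_a"].is_unique and omap.pairs["gene_b"].is_unique

    def test_orthomap_has_one_to_many(self):
        cfg = SimConfig(seed=0, n_genes=200, one2many_frac=0.3)
        omap = emit_orthomap(cfg)
        assert omap.pairs["gene_a"].duplicated().any()

    def test_genesets_planted_directions_recorded(self):
        cfg = SimConfig(seed=2, n_genes=800, n_pairs=5)
        _, _, truth = simulate_paired_cohort(cfg)
        coll = emit_genesets(cfg, truth)
        ups = [n for n, d in truth.set_direction.items() if d == "up"]
        assert len(ups) == cfg.geneset_block.planted_per_direction
        for name in ups:
            members = coll.sets[name]
            frac_up = np.mean([truth.tumor_lfc[g] > 0 for g in members])
            assert frac_up >= 0.7

    def test_set_size_exceeding_universe_rejected(self):
        cfg = SimConfig(seed=2, n_genes=800, n_pairs=5)
        _, _, truth = simulate_paired_cohort(cfg)
        from dataclasses import replace

        cfg2 = replace(cfg, geneset_block=type(cfg.geneset_block)(set_size=10))
        with pytest.raises(ValueError):
            emit_genesets(cfg2, truth, genes=[f"hsg{i:05d}" for i in range(5)])

    def test_targets_planted_pass_filter_decoys_split(self):
        cfg = SimConfig(seed=3, n_genes=600, n_pairs=5)
        _, _, truth = simulate_paired_cohort(cfg)
        table = emit_targets(cfg, truth)
        planted = {(m, g) for m, tg in truth.mirna_targets.items() for g in tg}
        sub = table.set_index(["mirna_id", "gene_id"])
        for pair in planted:
            assert sub.loc[pair, "context_score"] < -0.2
        assert (table["context_score"] >= -0.2).any()

    def test_decoy_only_table_yields_no_valid_interactions(self):
        """Under the null (no planted coupling), the screen validates
        nothing in >= 95% of seeds."""
        from crossregen import correlate_pairs, log_cpm

        bad = 0
        for seed in range(10):
            cfg = SimConfig(seed=seed, n_genes=400, n_pairs=10, frac_de=0.0,
                            mirna_block=MirnaBlock(slope=0.0, up_lfc=0.0,
                                                   n_decoy_predicted=150))
            cm, cm_mi, truth = simulate_paired_cohort(cfg)
            truth.mirna_targets = {}  # decoys only
            table = emit_targets(cfg, truth)
            fac = tmm_factors(cm)
            fac_mi = tmm_factors(cm_mi)
            from crossregen import filter_targets

            cand = filter_targets(table)
            res = correlate_pairs(log_cpm(cm, fac), log_cpm(cm_mi, fac_mi), cand)
            if len(res) and res["valid"].any():
                bad += 1
        assert bad <= 1
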