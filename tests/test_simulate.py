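import numpy as np
import pytest
from scipy import stats

from mircontext import Assay, Platform
from mircontext.seed import find_seed_sites
from mircontext.simulate import (
    SimConfig,
    generate_genome,
    generate_mixed_study,
    generate_small_rnas,
    generate_study,
    plant_sites,
    simulate_experiment,
    simulate_read_positions,
)


class TestSimConfig:
    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="n_genes"):
            SimConfig(n_genes=5)

    def test_negative_effect_rejected(self):
        with pytest.raises(ValueError, match="knockdown"):
            SimConfig(knockdown_per_site=-0.1)

    def test_probability_bounds(self):
        with pytest.raises(ValueError, match="gc_content"):
            SimConfig(gc_content=1.4)


class TestGenerateGenome:
    def test_deterministic_under_seed(self):
        cfg = SimConfig(n_genes=50, seed=42)
        a = generate_genome(cfg)
        b = generate_genome(cfg)
        assert [g.utr_seq for g in a] == [g.utr_seq for g in b]
        assert [g.expr_score for g in a] == [g.expr_score for g in b]
        assert [g.promoter_seq for g in a] == [g.promoter_seq for g in b]

    def test_degenerate_conservation_prior(self):
        cfg = SimConfig(n_genes=20, seed=0, cons_rate_alpha=1e8, cons_rate_beta=1e-8)
        genes = generate_genome(cfg)
        for g in genes:
            assert np.asarray(g.cons_track).mean() > 0.999

    def test_zero_inflation_within_binomial_bounds(self):
        cfg = SimConfig(n_genes=10_000, seed=3, expr_zero_frac=0.2)
        genes = generate_genome(cfg)
        n_zero = sum(1 for g in genes if g.expr_score == 0)
        lo, hi = stats.binom.ppf([0.005, 0.995], 10_000, 0.2)
        assert lo <= n_zero <= hi

    def test_label_expression_coupling(self):
        cfg = SimConfig(n_genes=4000, seed=5)
        genes = generate_genome(cfg)
        hk = [g.expr_score for g in genes if g.is_housekeeping]
        dev = [g.expr_score for g in genes if g.is_developmental]
        rest = [g.expr_score for g in genes if not g.is_housekeeping]
        assert np.median(hk) > np.median(rest)
        assert np.median(dev) < np.median(hk)

    def test_cpg_rich_promoters_enriched_in_hk(self):
        from mircontext.features import cpg_class

        cfg = SimConfig(n_genes=800, seed=6)
        genes = generate_genome(cfg)
        hk_high = np.mean(
            [cpg_class(g.promoter_seq) == "high" for g in genes if g.is_housekeeping]
        )
        non_high = np.mean(
            [cpg_class(g.promoter_seq) == "high" for g in genes if not g.is_housekeeping]
        )
        assert hk_high > non_high


class TestPlantSites:
    def test_round_trip_exact_counts(self):
        cfg = SimConfig(n_genes=300, seed=9)
        rng = cfg.rng()
        genes = generate_genome(cfg, rng)
        rnas = generate_small_rnas(rng, 5, prefix="r")
        planted, truth = plant_sites(genes, rnas, cfg, rng)
        assert not truth.skipped_genes
        for g in planted:
            for r in rnas:
                assert len(find_seed_sites(r, g.utr_seq)) == truth.n_sites(
                    g.gene_id, r.rna_id
                )

    def test_zero_rate_no_targets(self):
        cfg = SimConfig(n_genes=30, seed=1, site_rate_per_kb=0.0,
                        endo_site_rate_per_kb=0.0)
        rng = cfg.rng()
        genes = generate_genome(cfg, rng)
        rnas = generate_small_rnas(rng, 3, prefix="r")
        _, truth = plant_sites(genes, rnas, cfg, rng)
        assert all(n == 0 for n in truth.site_counts.values())

    def test_longer_utrs_receive_more_sites(self):
        cfg = SimConfig(n_genes=2000, seed=2, site_rate_per_kb=1.0)
        rng = cfg.rng()
        genes = generate_genome(cfg, rng)
        rnas = generate_small_rnas(rng, 1, prefix="r")
        planted, truth = plant_sites(genes, rnas, cfg, rng)
        lengths = np.array([g.utr_length for g in planted])
        counts = np.array([truth.n_sites(g.gene_id, "r-1") for g in planted])
        r, p = stats.pearsonr(lengths, counts)
        assert r > 0.3 and p < 1e-10


class TestSimulateExperiment:
    def _planted(self, seed=4, **kw):
        cfg = SimConfig(n_genes=200, seed=seed, **kw)
        rng = cfg.rng()
        genes = generate_genome(cfg, rng)
        endo = generate_small_rnas(rng, 3, prefix="endo")
        exo = generate_small_rnas(rng, 1, prefix="exo", avoid=endo)
        genes, truth = plant_sites(genes, endo + exo, cfg, rng)
        truth.endo_rna_ids = [r.rna_id for r in endo]
        return cfg, rng, genes, exo, truth

    def test_noiseless_closed_form(self):
        cfg, rng, genes, exo, truth = self._planted(
            noise_sd=0.0, competition_shift=0.0, dilution_strength=0.0,
            knockdown_per_site=0.2,
        )
        exp = simulate_experiment(
            genes, exo, truth, Platform.MICROARRAY, Assay.TRANSFECTION, cfg, rng
        )
        s = exp.samples[0]
        for g in genes:
            n = truth.n_sites(g.gene_id, exo[0].rna_id)
            assert s.log_ratios[g.gene_id] == pytest.approx(-0.2 * n, abs=1e-12)

    def test_competition_shifts_endo_targets_up(self):
        cfg, rng, genes, exo, truth = self._planted(
            seed=8, competition_shift=0.3, noise_sd=0.05,
            endo_site_rate_per_kb=0.3,
        )
        exp = simulate_experiment(
            genes, exo, truth, Platform.MICROARRAY, Assay.TRANSFECTION, cfg, rng
        )
        s = exp.samples[0]
        nt_plus = [
            s.log_ratios[g.gene_id] for g in genes
            if truth.n_sites(g.gene_id, exo[0].rna_id) == 0
            and truth.n_endo_sites(g.gene_id) > 0
        ]
        nt_minus = [
            s.log_ratios[g.gene_id] for g in genes
            if truth.n_sites(g.gene_id, exo[0].rna_id) == 0
            and truth.n_endo_sites(g.gene_id) == 0
        ]
        assert np.mean(nt_plus) > np.mean(nt_minus) + 0.2

    def test_inhibition_flips_exogenous_effect(self):
        cfg, rng, genes, exo, truth = self._planted(
            noise_sd=0.0, competition_shift=0.0, knockdown_per_site=0.2
        )
        exp = simulate_experiment(
            genes, exo, truth, Platform.MICROARRAY, Assay.INHIBITION, cfg, cfg.rng()
        )
        s = exp.samples[0]
        targets = [g for g in genes if truth.n_sites(g.gene_id, exo[0].rna_id) > 0]
        assert all(s.log_ratios[g.gene_id] > 0 for g in targets)

    def test_proteomics_dropout_expression_dependent(self):
        cfg, rng, genes, exo, truth = self._planted(
            seed=12, proteomics_detect_midpoint=0.5
        )
        exp = simulate_experiment(
            genes, exo, truth, Platform.PROTEOMICS, Assay.TRANSFECTION, cfg, rng
        )
        s = exp.samples[0]
        detected = set(s.log_ratios)
        expr = np.array([g.expr_score for g in genes])
        in_top = [g.gene_id in detected for g, e in zip(genes, expr)
                  if e > np.median(expr)]
        in_bot = [g.gene_id in detected for g, e in zip(genes, expr)
                  if e <= np.median(expr)]
        assert np.mean(in_top) > np.mean(in_bot)

    def test_microarray_emits_detection_pvalues(self):
        cfg, rng, genes, exo, truth = self._planted(seed=13)
        exp = simulate_experiment(
            genes, exo, truth, Platform.MICROARRAY, Assay.TRANSFECTION, cfg, rng
        )
        s = exp.samples[0]
        assert set(s.detection_pvalues) == set(s.log_ratios)
        ps = np.array(list(s.detection_pvalues.values()))
        assert ((ps >= 0) & (ps <= 1)).all()


class TestStudies:
    def test_full_determinism(self):
        a = generate_study(SimConfig(n_genes=60, seed=77), n_samples=2)
        b = generate_study(SimConfig(n_genes=60, seed=77), n_samples=2)
        assert [g.utr_seq for g in a.genes] == [g.utr_seq for g in b.genes]
        for sa, sb in zip(a.experiment.samples, b.experiment.samples):
            assert sa.log_ratios == sb.log_ratios

    def test_mixed_study_design(self):
        st_ = generate_mixed_study(
            SimConfig(n_genes=60, seed=5),
            design=((Platform.MICROARRAY, Assay.TRANSFECTION, 2),
                    (Platform.PROTEOMICS, Assay.TRANSFECTION, 1)),
        )
        assert len(st_.experiments) == 2
        assert len(st_.experiments[0].samples) == 2
        assert st_.experiments[1].platform == Platform.PROTEOMICS

    def test_assignments_match_truth(self):
        st_ = generate_study(SimConfig(n_genes=50, seed=21), n_samples=2)
        asg = st_.assignments()
        for s in st_.experiment.samples:
            for g in st_.genes:
                ta = asg[s.sample_id][g.gene_id]
                assert ta.n_sites == st_.truth.n_sites(
                    g.gene_id, s.small_rna.rna_id
                )

    def test_read_positions_enriched_at_endo_targets(self):
        st_ = generate_study(SimConfig(n_genes=150, seed=30), n_samples=1)
        positions = simulate_read_positions(st_.genes, st_.truth, st_.config.rng())
        from mircontext.clip import call_binding_map

        calls = call_binding_map(positions, [g.gene_id for g in st_.genes])
        endo = [g.gene_id for g in st_.genes if st_.truth.n_endo_sites(g.gene_id) > 0]
        non = [g.gene_id for g in st_.genes if st_.truth.n_endo_sites(g.gene_id) == 0]
        assert np.mean([calls[g].bound for g in endo]) > np.mean(
            [calls[g].bound for g in non]
        )
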