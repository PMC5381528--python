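import numpy as np
import pytest

from ascoedit.io_formats import parse_mpileup, read_gene_models
from ascoedit.simulate import (
    SimulationConfig,
    generate_genes,
    models_to_fasta,
    models_to_tsv,
    plant_editing,
    simulate_sample,
)

SMALL = SimulationConfig(
    n_genes=6, n_specific_sites=4, n_stop_loss_sites=1,
    n_background_sites=12, n_reference_errors=1,
)


class TestGenerateGenes:
    def test_fixed_seed_is_byte_identical(self):
        m1, _ = generate_genes(SMALL, seed=1)
        m2, _ = generate_genes(SMALL, seed=1)
        assert models_to_fasta(m1) == models_to_fasta(m2)

    def test_different_seed_differs(self):
        m1, _ = generate_genes(SMALL, seed=1)
        m2, _ = generate_genes(SMALL, seed=2)
        assert models_to_fasta(m1) != models_to_fasta(m2)

    def test_zero_genes(self):
        cfg = SimulationConfig(n_genes=0, n_specific_sites=0, n_stop_loss_sites=0,
                               n_background_sites=0, n_reference_errors=0)
        models, _ = generate_genes(cfg, seed=1)
        assert models == []

    def test_models_pass_io_validation(self, tmp_path):
        cfg = SimulationConfig(n_genes=100)
        models, _ = generate_genes(cfg, seed=3)
        (tmp_path / "genes.tsv").write_text(models_to_tsv(models))
        (tmp_path / "genes.fa").write_text(models_to_fasta(models))
        from ascoedit.io_formats import read_fasta

        back = read_gene_models(tmp_path / "genes.tsv", read_fasta(tmp_path / "genes.fa"))
        assert len(back) == 100
        assert all(m.complete for m in back)

    def test_cds_starts_atg_ends_stop(self):
        models, _ = generate_genes(SMALL, seed=4)
        for m in models:
            cds = m.spliced_cds
            assert cds.startswith("ATG")
            assert cds[-3:] in ("TAA", "TAG", "TGA")
            # internal codons are never stops
            internal = [cds[i : i + 3] for i in range(3, len(cds) - 3, 3)]
            assert not set(internal) & {"TAA", "TAG", "TGA"}
            # downstream sequence exists for read-through
            assert m.segments[-1].kind == "three_utr"

    def test_noncoding_genes_flagged(self):
        cfg = SimulationConfig(n_genes=3, n_noncoding_genes=2, n_specific_sites=0,
                               n_stop_loss_sites=0, n_background_sites=0,
                               n_reference_errors=0)
        models, _ = generate_genes(cfg, seed=5)
        assert sum(m.noncoding for m in models) == 2


class TestPlantEditing:
    def test_specific_sites_zero_elsewhere(self):
        models, layouts = generate_genes(SMALL, seed=6)
        truth = plant_editing(models, layouts, SMALL, seed=6)
        specific = truth.specific_sites(SMALL.focal_condition)
        assert len(specific) == 4
        for s in specific:
            assert s.fractions["veg"] == 0.0 and s.fractions["sex"] == 0.0
            assert s.fractions["proto"] >= SMALL.specific_fraction_range[0]

    def test_stop_loss_sites_on_annotated_stops(self):
        models, layouts = generate_genes(SMALL, seed=6)
        truth = plant_editing(models, layouts, SMALL, seed=6)
        stop_sites = [s for s in truth.sites if s.category == "stop_loss"]
        assert len(stop_sites) == 1
        by_id = {m.gene_id: m for m in models}
        for s in stop_sites:
            m = by_id[s.gene_id]
            last_cds = m.cds_segments[-1]
            assert last_cds.end - 2 <= s.position <= last_cds.end
            assert m.base_at(s.position) == "A"

    def test_planted_ag_sites_sit_on_a(self):
        models, layouts = generate_genes(SMALL, seed=7)
        truth = plant_editing(models, layouts, SMALL, seed=7)
        by_id = {m.gene_id: m for m in models}
        for s in truth.sites:
            assert by_id[s.gene_id].base_at(s.position) == s.ref_base
            if s.alt_base == "G" and s.ref_base == "A":
                assert by_id[s.gene_id].base_at(s.position) == "A"

    def test_truth_disjoint_from_reference_errors(self):
        models, layouts = generate_genes(SMALL, seed=8)
        truth = plant_editing(models, layouts, SMALL, seed=8)
        site_pos = {(s.gene_id, s.position) for s in truth.sites}
        err_pos = {(e.gene_id, e.position) for e in truth.reference_errors}
        assert site_pos.isdisjoint(err_pos)

    def test_planted_categories_agree_with_classifier(self):
        """Cross-module oracle: generator bookkeeping vs the classifier."""
        from ascoedit.consequences import classify_site
        from ascoedit.detection import VariantSite

        cfg = SimulationConfig(n_genes=30, n_specific_sites=20, n_stop_loss_sites=5,
                               n_background_sites=0, n_reference_errors=0)
        models, layouts = generate_genes(cfg, seed=9)
        truth = plant_editing(models, layouts, cfg, seed=9)
        by_id = {m.gene_id: m for m in models}
        for s in truth.sites:
            site = VariantSite(s.gene_id, s.position, s.ref_base, s.alt_base, 50, 25)
            cons = classify_site(site, by_id[s.gene_id])
            assert cons.region == s.region
            if s.category is not None:
                assert cons.category == s.category


class TestSimulateSample:
    def test_error_free_sample_is_pure_reference(self):
        cfg = SimulationConfig(n_genes=3, error_rate=0.0, n_specific_sites=0,
                               n_stop_loss_sites=0, n_background_sites=0,
                               n_reference_errors=0, decorate_reads=False)
        models, layouts = generate_genes(cfg, seed=10)
        truth = plant_editing(models, layouts, cfg, seed=10)
        text = simulate_sample(models, truth, "veg", 1, cfg, seed=10)
        for col in parse_mpileup(text):
            assert col.counts[col.ref_base] == col.depth

    def test_full_editing_fraction_yields_pure_alt(self):
        cfg = SimulationConfig(n_genes=3, error_rate=0.0, n_specific_sites=2,
                               n_stop_loss_sites=0, n_background_sites=0,
                               n_reference_errors=0,
                               specific_fraction_range=(1.0, 1.0))
        models, layouts = generate_genes(cfg, seed=11)
        truth = plant_editing(models, layouts, cfg, seed=11)
        text = simulate_sample(models, truth, cfg.focal_condition, 1, cfg, seed=11)
        cols = {(c.gene_id, c.position): c for c in parse_mpileup(text)}
        for s in truth.sites:
            col = cols[(s.gene_id, s.position)]
            if col.depth >= 5:
                assert col.counts["G"] == col.depth

    def test_sample_determinism_and_replicate_divergence(self):
        cfg = SimulationConfig(n_genes=2, n_specific_sites=1, n_stop_loss_sites=0,
                               n_background_sites=4, n_reference_errors=0)
        models, layouts = generate_genes(cfg, seed=12)
        truth = plant_editing(models, layouts, cfg, seed=12)
        a = simulate_sample(models, truth, "veg", 1, cfg, seed=12)
        b = simulate_sample(models, truth, "veg", 1, cfg, seed=12)
        c = simulate_sample(models, truth, "veg", 2, cfg, seed=12)
        assert a == b and a != c

    def test_editing_fraction_recovered_on_average(self):
        cfg = SimulationConfig(
            n_genes=20, n_specific_sites=40, n_stop_loss_sites=0,
            n_background_sites=0, n_reference_errors=0, error_rate=0.0,
            specific_fraction_range=(0.5, 0.5), mean_coverage=50.0,
        )
        models, layouts = generate_genes(cfg, seed=13)
        truth = plant_editing(models, layouts, cfg, seed=13)
        text = simulate_sample(models, truth, cfg.focal_condition, 1, cfg, seed=13)
        cols = {(c.gene_id, c.position): c for c in parse_mpileup(text)}
        fracs = []
        for s in truth.sites:
            col = cols[(s.gene_id, s.position)]
            if col.depth:
                fracs.append(col.counts["G"] / col.depth)
        mean = np.mean(fracs)
        se = 0.5 / np.sqrt(sum(c.depth for c in cols.values() if c.depth) / len(cols))
        assert mean == pytest.approx(0.5, abs=0.05)

    def test_reference_error_near_fixed_in_every_sample(self):
        cfg = SimulationConfig(n_genes=4, n_specific_sites=0, n_stop_loss_sites=0,
                               n_background_sites=0, n_reference_errors=2)
        models, layouts = generate_genes(cfg, seed=14)
        truth = plant_editing(models, layouts, cfg, seed=14)
        for cond in cfg.conditions:
            text = simulate_sample(models, truth, cond, 1, cfg, seed=14)
            cols = {(c.gene_id, c.position): c for c in parse_mpileup(text)}
            for e in truth.reference_errors:
                col = cols[(e.gene_id, e.position)]
                if col.depth >= 5:
                    assert col.counts[e.alt_base] / col.depth >= 0.9
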