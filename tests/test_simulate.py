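"""Synthetic-data generators: codon evolution, hit tables, genome fixtures."""

import numpy as np
import pytest

from hgtscreen.fourdtv import fourdtv
from hgtscreen.io import ValidationError
from hgtscreen.simulate import (
    SimulationConfig,
    contaminant_nt_divergence,
    evolve_codon_pair,
    expected_bitscore,
    k80_probabilities,
    make_truth,
    random_cds,
    simulate_genome,
    simulate_hit_table,
    taxon_divergences,
)


class TestConfig:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(n_native_genes=-1)
        with pytest.raises(ValidationError):
            SimulationConfig(kappa=0.0)
        with pytest.raises(ValidationError):
            SimulationConfig(divergence_donor=-0.1)


class TestEvolveCodonPair:
    def test_zero_divergence_returns_identical_pair(self):
        cds = random_cds(np.random.default_rng(0), 200)
        pair = evolve_codon_pair(cds, 0.0, 2.0, seed=1)
        assert pair.seq_a == pair.seq_b == cds

    def test_pure_transitions_give_zero_fourdtv(self):
        cds = random_cds(np.random.default_rng(0), 2000, fourfold_only=True)
        pair = evolve_codon_pair(cds, 1.0, 1e9, seed=2)
        assert pair.seq_a != pair.seq_b  # transitions did happen
        assert fourdtv(pair).value == 0.0

    def test_amino_acid_positions_untouched(self):
        cds = random_cds(np.random.default_rng(3), 300)
        pair = evolve_codon_pair(cds, 2.0, 2.0, seed=4)
        for i in range(0, len(cds), 3):
            assert pair.seq_b[i : i + 2] == cds[i : i + 2]

    def test_non_multiple_of_three_rejected(self):
        with pytest.raises(ValidationError, match="multiple of 3"):
            evolve_codon_pair("GGTA", 0.1, 2.0, seed=0)

    def test_internal_stop_rejected(self):
        with pytest.raises(ValidationError, match="stop"):
            evolve_codon_pair("GGTTAAGGT", 0.1, 2.0, seed=0)

    def test_deterministic_under_fixed_seed(self):
        cds = random_cds(np.random.default_rng(5), 300)
        assert (
            evolve_codon_pair(cds, 0.5, 2.0, seed=9).seq_b
            == evolve_codon_pair(cds, 0.5, 2.0, seed=9).seq_b
        )

    def test_substitution_probabilities_sum_to_one(self):
        for d in (0.0, 0.1, 1.0, 5.0):
            p_same, p_ts, p_tv = k80_probabilities(d, 2.0)
            assert p_same + p_ts + 2 * p_tv == pytest.approx(1.0)
            assert min(p_same, p_ts, p_tv) >= 0.0

    def test_mean_fourdtv_monotone_in_divergence(self):
        grid = [0.05, 0.2, 0.5, 1.0, 2.5]
        means = []
        for d in grid:
            vals = []
            for seed in range(10):
                rng = np.random.default_rng([seed, 77])
                cds = random_cds(rng, 400, fourfold_only=True)
                vals.append(fourdtv(evolve_codon_pair(cds, d, 2.0, rng=rng)).value)
            means.append(np.mean(vals))
        assert all(m1 <= m2 for m1, m2 in zip(means, means[1:]))


class TestTruth:
    def test_origin_labels_partition_the_gene_set(self):
        config = SimulationConfig(seed=2)
        truth = make_truth(config)
        assert len(truth.origins) == 150
        assert len(truth.genes_of("native")) == 100
        assert len(truth.genes_of("hgt")) == 20
        assert len(truth.genes_of("contaminant")) == 30

    def test_families_cover_all_transferred_genes(self):
        truth = make_truth(SimulationConfig(seed=4))
        in_families = [g for fam in truth.hgt_families for g in fam]
        assert sorted(in_families) == truth.genes_of("hgt")
        assert all(len(f) >= 2 for f in truth.hgt_families)


class TestHitTable:
    def test_byte_identical_under_same_seed(self, tmp_path):
        from hgtscreen.io import write_hit_table

        config = SimulationConfig(seed=8)
        truth = make_truth(config)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_hit_table(simulate_hit_table(truth, config)[0], p1)
        write_hit_table(simulate_hit_table(truth, config)[0], p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_native_genes_have_no_donor_hit(self, default_dataset):
        natives = set(default_dataset.truth.genes_of("native"))
        donor_queries = {
            h.query_id for h in default_dataset.protein_hits
            if h.subject_taxon == "Donor_bacterium"
        }
        assert not (natives & donor_queries)

    def test_hgt_index_matches_generator_closed_form(self):
        """At zero noise the index equals the analytic difference of the two
        deterministic best coverage-weighted scores."""
        from collections import defaultdict

        from hgtscreen.hgt_index import call_genes
        from hgtscreen.simulate import _aln_length_aa

        config = SimulationConfig(seed=6, bitscore_noise_sd=0.0)
        truth = make_truth(config)
        hits, _ = simulate_hit_table(truth, config)
        by_gene = defaultdict(list)
        for h in hits:
            by_gene[h.query_id].append(h)
        calls = {c.gene_id: c for c in call_genes(hits, {g: config.n_codons for g in truth.origins})}
        L = config.n_codons

        def weighted(d):
            return expected_bitscore(d, config) * min(1.0, _aln_length_aa(d, config) / L)

        for gene in truth.genes_of("hgt"):
            dvg = taxon_divergences("hgt", config)
            # RAMVA is the excluded sister lineage; DONOR vs DROME remain
            expected_h = weighted(dvg["DONOR"]) - weighted(dvg["DROME"])
            assert calls[gene].h_index == pytest.approx(expected_h, abs=0.2)


class TestGenome:
    def test_contaminants_single_exon_and_hosts_multi_exon(self, default_dataset):
        origins = default_dataset.truth.origins
        for gene in default_dataset.genome.genes:
            if origins[gene.gene_id] == "contaminant":
                assert gene.n_exons == 1
            else:
                assert 2 <= gene.n_exons <= 8

    def test_planted_signature_ranges_match_alignment(self, default_dataset):
        aln = default_dataset.genome.clade_alignment
        focal_rows = [r for r, c in zip(aln.rows, aln.clades) if c == "bilateria"]
        other_rows = [r for r, c in zip(aln.rows, aln.clades) if c != "bilateria"]
        assert default_dataset.truth.signature_blocks
        for start, end, kind in default_dataset.truth.signature_blocks:
            if kind == "insertion":
                assert all("-" not in r[start:end] for r in focal_rows)
                assert all(set(r[start:end]) == {"-"} for r in other_rows)
            else:
                assert all(set(r[start:end]) == {"-"} for r in focal_rows)
                assert all("-" not in r[start:end] for r in other_rows)

    def test_contaminant_identity_at_least_configured_floor(self, default_dataset):
        config = default_dataset.config
        origins = default_dataset.truth.origins
        for h in default_dataset.genome.nt_hits:
            if origins[h.query_id] == "contaminant":
                assert h.pct_identity >= config.contaminant_identity

    def test_contaminant_scaffolds_outside_native_depth_fence(self):
        """With a 5x depth offset the contaminant contigs always fall outside
        the interquartile fence of host-scaffold depths."""
        for seed in range(20):
            config = SimulationConfig(seed=seed)
            truth = make_truth(config)
            genome = simulate_genome(truth, config)
            native_depths = [d.mean_depth for d in genome.depths if d.scaffold_id.startswith("scf")]
            q1, q3 = np.percentile(native_depths, [25, 75])
            fence_hi = q3 + 1.5 * (q3 - q1)
            for d in genome.depths:
                if d.scaffold_id.startswith("ctg"):
                    assert d.mean_depth > fence_hi

    def test_divergence_structure_for_unknown_origin_rejected(self):
        with pytest.raises(ValueError):
            taxon_divergences("weird", SimulationConfig())

    def test_contaminant_divergence_inverts_identity_map(self):
        config = SimulationConfig(contaminant_identity=97.0)
        d = contaminant_nt_divergence(config)
        assert 100.0 * np.exp(-2.5 * d) == pytest.approx(97.0)
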