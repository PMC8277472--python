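"""HGT index: coverage weighting, classification and the paralogy check."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hgtscreen.hgt_index import (
    Verdict,
    classify_hgt,
    hgt_index_for_gene,
    paralogy_check,
    weighted_bitscore,
)
from hgtscreen.io import HitRecord, TaxonGroup, ValidationError


def _hit(q="g1", s="x", bits=100.0, aln=100, group=TaxonGroup.METAZOAN, taxon="tax"):
    return HitRecord(
        query_id=q, subject_id=s, pct_identity=90.0, aln_length=aln,
        bitscore=bits, subject_taxon=taxon, taxon_group=group,
    )


class TestWeightedBitscore:
    @pytest.mark.parametrize(
        "bits,aln,qlen,expected",
        [
            (200.0, 150, 300, 100.0),  # half coverage halves the score
            (100.0, 350, 300, 100.0),  # coverage clamped at 1
            (150.0, 300, 300, 150.0),  # full-length hit keeps its raw score
        ],
    )
    def test_coverage_weighting(self, bits, aln, qlen, expected):
        assert weighted_bitscore(_hit(bits=bits, aln=aln), qlen) == expected

    def test_never_exceeds_raw_bitscore(self):
        for aln in (1, 50, 299, 300, 1000):
            assert weighted_bitscore(_hit(bits=77.0, aln=aln), 300) <= 77.0

    def test_nonpositive_query_length_rejected(self):
        with pytest.raises(ValueError):
            weighted_bitscore(_hit(), 0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        bits=st.floats(0.0, 1e4),
        aln_short=st.integers(1, 500),
        aln_long=st.integers(1, 500),
        qlen=st.integers(1, 500),
    )
    def test_weight_monotone_in_alignment_length_and_bounded(self, bits, aln_short, aln_long, qlen):
        lo, hi = sorted((aln_short, aln_long))
        w_lo = weighted_bitscore(_hit(bits=bits, aln=lo), qlen)
        w_hi = weighted_bitscore(_hit(bits=bits, aln=hi), qlen)
        assert w_lo <= w_hi <= bits


class TestHgtIndexForGene:
    def test_difference_of_group_maxima(self):
        hits = [
            _hit(s="nm", bits=180.0, aln=300, group=TaxonGroup.NON_METAZOAN),
            _hit(s="m", bits=120.0, aln=300, group=TaxonGroup.METAZOAN),
        ]
        h, best_nm, best_m = hgt_index_for_gene(hits, 300)
        assert h == 60.0
        assert best_nm == ("nm", 180.0) and best_m == ("m", 120.0)

    def test_empty_nonmetazoan_group_contributes_zero(self):
        hits = [_hit(s="m", bits=120.0, aln=300, group=TaxonGroup.METAZOAN)]
        h, best_nm, _ = hgt_index_for_gene(hits, 300)
        assert h == -120.0 and best_nm is None

    def test_only_excluded_hits_is_undefined(self):
        hits = [_hit(s="e", bits=500.0, group=TaxonGroup.EXCLUDED)]
        h, best_nm, best_m = hgt_index_for_gene(hits, 300)
        assert h is None and best_nm is None and best_m is None

    def test_exclusion_by_taxon_name(self):
        hits = [
            _hit(s="nm", bits=180.0, aln=300, group=TaxonGroup.NON_METAZOAN),
            _hit(s="sister", bits=500.0, aln=300, taxon="SisterLineage"),
        ]
        h, _, _ = hgt_index_for_gene(hits, 300, exclusion={"SisterLineage"})
        assert h == 180.0

    def test_mixed_query_ids_rejected(self):
        with pytest.raises(ValidationError, match="multiple queries"):
            hgt_index_for_gene([_hit(q="g1"), _hit(q="g2")], 300)

    def test_translation_invariance_at_full_coverage(self):
        base = [
            _hit(s="nm", bits=180.0, aln=300, group=TaxonGroup.NON_METAZOAN),
            _hit(s="m", bits=120.0, aln=300, group=TaxonGroup.METAZOAN),
        ]
        shifted = [
            _hit(s="nm", bits=180.0 + 37.0, aln=300, group=TaxonGroup.NON_METAZOAN),
            _hit(s="m", bits=120.0 + 37.0, aln=300, group=TaxonGroup.METAZOAN),
        ]
        h0, _, _ = hgt_index_for_gene(base, 300)
        h1, _, _ = hgt_index_for_gene(shifted, 300)
        assert h1 == pytest.approx(h0)


class TestClassify:
    @pytest.mark.parametrize(
        "h,verdict",
        [
            (60.0, Verdict.PUTATIVE_HGT),
            (30.0, Verdict.PUTATIVE_HGT),  # threshold is inclusive
            (0.0, Verdict.NATIVE),
            (None, Verdict.AMBIGUOUS),
        ],
    )
    def test_threshold_rule(self, h, verdict):
        assert classify_hgt(h, threshold=30.0) is verdict


class TestWeightingRegression:
    def test_short_spurious_hit_flips_to_native_when_weighted(self):
        """A 10%-coverage non-metazoan fragment with huge bit-score density
        crosses the threshold unweighted but not with coverage weighting."""
        qlen = 300
        hits = [
            _hit(s="frag", bits=120.0, aln=30, group=TaxonGroup.NON_METAZOAN),
            _hit(s="m", bits=80.0, aln=300, group=TaxonGroup.METAZOAN),
        ]
        unweighted, _, _ = hgt_index_for_gene(hits, qlen, weight_fn=lambda a, q: 1.0)
        weighted, _, _ = hgt_index_for_gene(hits, qlen)
        assert classify_hgt(unweighted, 30.0) is Verdict.PUTATIVE_HGT
        assert classify_hgt(weighted, 30.0) is Verdict.NATIVE


class TestParalogyCheck:
    def test_mutually_closer_family_passes(self):
        within = [
            _hit(q=a, s=b, bits=bits)
            for a, b, bits in [
                ("p1", "p2", 500), ("p2", "p1", 500), ("p1", "p3", 480),
                ("p3", "p1", 480), ("p2", "p3", 470), ("p3", "p2", 470),
            ]
        ]
        cross = [_hit(q=p, s="foreign", bits=300) for p in ("p1", "p2", "p3")]
        assert paralogy_check({"p1", "p2", "p3"}, within, cross) is True

    def test_foreign_best_hit_fails(self):
        within = [_hit(q="p1", s="p2", bits=500), _hit(q="p2", s="p1", bits=500)]
        cross = [_hit(q="p1", s="foreign", bits=520), _hit(q="p2", s="foreign", bits=100)]
        assert paralogy_check({"p1", "p2"}, within, cross) is False

    def test_missing_candidate_rejected(self):
        within = [_hit(q="p1", s="p2", bits=500), _hit(q="p2", s="p1", bits=500)]
        with pytest.raises(ValidationError, match="missing"):
            paralogy_check({"p1", "p2"}, within, [])

    def test_planted_families_recovered_across_seeds(self):
        """Transferred genes are generated as post-transfer duplicates, so
        mutual similarity should beat any cross-species hit."""
        from hgtscreen.simulate import (
            SimulationConfig,
            make_truth,
            simulate_hit_table,
            simulate_within_genome_hits,
        )

        ok = total = 0
        for seed in range(20):
            config = SimulationConfig(seed=seed)
            truth = make_truth(config)
            hits, _ = simulate_hit_table(truth, config)
            within = simulate_within_genome_hits(truth, config)
            for family in truth.hgt_families:
                total += 1
                ok += paralogy_check(family, within, hits)
        assert ok / total >= 0.95
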