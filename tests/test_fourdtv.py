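"""4DTv statistic, RBH pairing and CI membership, checked against an
independent brute-force oracle that re-derives degeneracy from the genetic
code table."""

import numpy as np
import pytest
from Bio.Data import CodonTable
from hypothesis import given, settings
from hypothesis import strategies as st

from hgtscreen.fourdtv import (
    CodonPairAlignment,
    FourDTvResult,
    ci_membership_test,
    fourdtv,
    fourfold_sites,
    one_to_one_pairs,
)
from hgtscreen.io import HitRecord, TaxonGroup, ValidationError

# ---------------------------------------------------------------------------
# oracle: enumerate every codon column, degeneracy from Bio.Data.CodonTable


def _fourfold_prefixes_from_code() -> set:
    table = CodonTable.unambiguous_dna_by_id[1].forward_table
    prefixes = set()
    for a in "ACGT":
        for b in "ACGT":
            aas = {table.get(a + b + c) for c in "ACGT"}
            if None not in aas and len(aas) == 1:
                prefixes.add(a + b)
    return prefixes


def oracle_fourdtv(seq_a: str, seq_b: str) -> tuple[int, int]:
    prefixes = _fourfold_prefixes_from_code()
    n_sites = n_tv = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if "-" in ca or "-" in cb:
            continue
        if ca[:2] != cb[:2] or ca[:2] not in prefixes:
            continue
        n_sites += 1
        purine = {"A": 1, "G": 1, "C": 0, "T": 0}
        if purine[ca[2]] != purine[cb[2]]:
            n_tv += 1
    return n_sites, n_tv


def _random_pair(rng: np.random.Generator, n_codons: int) -> CodonPairAlignment:
    codons = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"] + ["---"] * 4
    a = "".join(codons[i] for i in rng.integers(0, len(codons), n_codons))
    b = "".join(codons[i] for i in rng.integers(0, len(codons), n_codons))
    return CodonPairAlignment(a, b)


class TestFourfoldSites:
    @pytest.mark.parametrize(
        "codon_a,codon_b,counted",
        [
            ("GGT", "GGA", True),  # GG- prefix is fourfold (Gly)
            ("GGT", "GAT", False),  # prefix differs between the sequences
            ("AAA", "AAG", False),  # AA- prefix is twofold (Lys/Asn)
            ("---", "GGA", False),  # gapped codon excluded
        ],
    )
    def test_site_selection_rules(self, codon_a, codon_b, counted):
        pair = CodonPairAlignment(codon_a, codon_b)
        assert (fourfold_sites(pair) == [0]) is counted


class TestFourDTv:
    def test_identical_sequences_give_zero(self):
        seq = "GGTCTACGGACT"
        assert fourdtv(CodonPairAlignment(seq, seq)).value == 0.0

    def test_single_transversion_codon(self):
        r = fourdtv(CodonPairAlignment("GGT", "GGA"))
        assert (r.n_sites, r.n_transversions, r.value) == (1, 1, 1.0)

    def test_worked_example_two_thirds(self):
        # codons: GGT/GGA (transversion), CTA/CTT (transversion),
        # CGG/CGG (identical site), AAA/AAA (twofold, excluded)
        r = fourdtv(CodonPairAlignment("GGTCTACGGAAA", "GGACTTCGGAAA"))
        assert (r.n_sites, r.n_transversions) == (3, 2)
        assert r.value == pytest.approx(2 / 3)

    def test_transition_counts_denominator_only(self):
        r = fourdtv(CodonPairAlignment("GGA", "GGG"))  # A<->G transition
        assert (r.n_sites, r.n_transversions) == (1, 0)

    def test_no_sites_gives_undefined_value(self):
        r = fourdtv(CodonPairAlignment("AAA", "AAA"))
        assert r.n_sites == 0 and r.value is None

    def test_matches_brute_force_oracle_on_random_pairs(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            pair = _random_pair(rng, 300)
            r = fourdtv(pair)
            assert (r.n_sites, r.n_transversions) == oracle_fourdtv(pair.seq_a, pair.seq_b)

    def test_symmetric_in_its_arguments(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            pair = _random_pair(rng, 120)
            fwd = fourdtv(pair)
            rev = fourdtv(CodonPairAlignment(pair.seq_b, pair.seq_a))
            assert (fwd.n_sites, fwd.n_transversions) == (rev.n_sites, rev.n_transversions)

    def test_result_invariants_enforced(self):
        with pytest.raises(ValidationError):
            FourDTvResult(n_sites=2, n_transversions=3)

    _codon = st.sampled_from(
        [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"] + ["---"]
    )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(_codon, min_size=1, max_size=60), st.lists(_codon, min_size=1, max_size=60))
    def test_bounds_and_symmetry_hold_for_arbitrary_pairs(self, codons_a, codons_b):
        n = min(len(codons_a), len(codons_b))
        pair = CodonPairAlignment("".join(codons_a[:n]), "".join(codons_b[:n]))
        r = fourdtv(pair)
        assert 0 <= r.n_transversions <= r.n_sites <= n
        if r.value is not None:
            assert 0.0 <= r.value <= 1.0
        rev = fourdtv(CodonPairAlignment(pair.seq_b, pair.seq_a))
        assert (r.n_sites, r.n_transversions) == (rev.n_sites, rev.n_transversions)


class TestAlignmentValidation:
    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValidationError, match="length"):
            CodonPairAlignment("GGTAAA", "GGT")

    def test_frame_breaking_gap_rejected(self):
        with pytest.raises(ValidationError, match="whole-codon"):
            CodonPairAlignment("G-TAAA", "GGTAAA")

    def test_non_multiple_of_three_rejected(self):
        with pytest.raises(ValidationError, match="multiple of 3"):
            CodonPairAlignment("GGTA", "GGTA")


def _hit(q, s, bits):
    return HitRecord(
        query_id=q, subject_id=s, pct_identity=90.0, aln_length=100,
        bitscore=bits, subject_taxon="x", taxon_group=TaxonGroup.METAZOAN,
    )


class TestOneToOnePairs:
    def test_clean_mutual_bests(self):
        ab = [_hit("a1", "b1", 500), _hit("a1", "b2", 100),
              _hit("a2", "b2", 450), _hit("a2", "b1", 90)]
        ba = [_hit("b1", "a1", 500), _hit("b2", "a2", 450)]
        assert one_to_one_pairs(ab, ba) == [("a1", "b1"), ("a2", "b2")]

    def test_tie_for_top_score_disqualifies(self):
        ab = [_hit("a1", "b1", 500), _hit("a1", "b2", 500)]
        ba = [_hit("b1", "a1", 500), _hit("b2", "a1", 500)]
        assert one_to_one_pairs(ab, ba) == []

    def test_non_reciprocal_best_excluded(self):
        ab = [_hit("a1", "b1", 500)]
        ba = [_hit("b1", "a2", 600), _hit("b1", "a1", 500)]
        assert one_to_one_pairs(ab, ba) == []

    def test_recovers_planted_orthologues_at_zero_noise(self):
        from hgtscreen.simulate import SimulationConfig, simulate_dataset

        config = SimulationConfig(seed=3, bitscore_noise_sd=0.0)
        ds = simulate_dataset(config)
        pairs = one_to_one_pairs(ds.genome.ortho_hits_ab, ds.genome.ortho_hits_ba)
        planted = sorted((g, r) for g, r, _ in ds.truth.orthologue_pairs)
        assert pairs == planted


class TestCIMembership:
    @staticmethod
    def _results(values):
        return [FourDTvResult(100, round(v * 100)) for v in values]

    def test_median_inside_and_extreme_outside(self):
        background = self._results(np.linspace(0.05, 0.25, 50))
        median = FourDTvResult(100, 15)
        high = FourDTvResult(100, 90)
        inside, outside = ci_membership_test([median, high], background, alpha=0.05)
        assert inside == "inside" and outside == "outside"

    def test_small_background_rejected(self):
        background = self._results([0.1] * 19)
        with pytest.raises(ValidationError, match="background too small"):
            ci_membership_test([], background)

    def test_undefined_candidate_reported_as_none(self):
        background = self._results(np.linspace(0.05, 0.25, 30))
        (v,) = ci_membership_test([FourDTvResult(0, 0)], background)
        assert v is None

    def test_bad_alpha_rejected(self):
        with pytest.raises(ValueError):
            ci_membership_test([], self._results([0.1] * 30), alpha=0.7)
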