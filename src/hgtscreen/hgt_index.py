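"""Alignment-length-weighted HGT index and classification of transferred genes.

The HGT (alien) index of a gene contrasts its best similarity score against
non-metazoan databases with its best score against metazoan ones; a large
positive difference suggests horizontal acquisition.  Raw bit scores are
first down-weighted by query coverage, ``min(1, aln_length/query_length)``,
so that short high-scoring fragments cannot dominate — the weighting that
controls false positives from partial matches.  Hits to taxa in an explicit
exclusion set (the query's own lineage, so that only transfers postdating
the split from that lineage are called) are removed before taking maxima.
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

from .io import HitRecord, TaxonGroup, ValidationError

#: default classification threshold in bits
DEFAULT_THRESHOLD = 30.0

WeightFn = Callable[[int, int], float]


def coverage_weight(aln_length: int, query_length: int) -> float:
    """Multiplicative coverage weight, clamped at 1."""
    return min(1.0, aln_length / query_length)


class Verdict(str, enum.Enum):
    PUTATIVE_HGT = "putative_hgt"
    NATIVE = "native"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class HGTCall:
    """Per-gene index value, best hits per taxon group, and verdict."""

    gene_id: str
    h_index: float | None
    best_nonmetazoan: tuple[str, float] | None
    best_metazoan: tuple[str, float] | None
    verdict: Verdict


def weighted_bitscore(
    hit: HitRecord, query_length: int, weight_fn: WeightFn = coverage_weight
) -> float:
    """Bit score down-weighted by query coverage.

    Monotone non-decreasing in ``aln_length`` for fixed bit score and never
    exceeds the raw bit score.
    """
    if query_length <= 0:
        raise ValueError(f"query_length must be >= 1, got {query_length}")
    return hit.bitscore * weight_fn(hit.aln_length, query_length)


def hgt_index_for_gene(
    hits: Sequence[HitRecord],
    query_length: int,
    exclusion: frozenset[str] | set[str] = frozenset(),
    weight_fn: WeightFn = coverage_weight,
) -> tuple[float | None, tuple[str, float] | None, tuple[str, float] | None]:
    """HGT index for one gene from its taxon-labelled hits.

    h = max weighted bit score over non-metazoan hits minus the max over
    metazoan hits, after removing hits whose taxon is excluded.  An empty
    group contributes a max of 0; when both groups are empty h is undefined
    (None).
    """
    queries = {h.query_id for h in hits}
    if len(queries) > 1:
        raise ValidationError(f"hits span multiple queries: {sorted(queries)}")
    best: dict[TaxonGroup, tuple[str, float]] = {}
    for hit in hits:
        if hit.taxon_group is None:
            raise ValidationError(f"hit {hit.subject_id} lacks a taxon group")
        if hit.taxon_group is TaxonGroup.EXCLUDED or hit.subject_taxon in exclusion:
            continue
        w = weighted_bitscore(hit, query_length, weight_fn)
        cur = best.get(hit.taxon_group)
        if cur is None or w > cur[1]:
            best[hit.taxon_group] = (hit.subject_id, w)
    best_nm = best.get(TaxonGroup.NON_METAZOAN)
    best_m = best.get(TaxonGroup.METAZOAN)
    if best_nm is None and best_m is None:
        return None, None, None
    h = (best_nm[1] if best_nm else 0.0) - (best_m[1] if best_m else 0.0)
    return h, best_nm, best_m


def classify_hgt(h_index: float | None, threshold: float = DEFAULT_THRESHOLD) -> Verdict:
    """putative_hgt iff h is defined and >= threshold; ambiguous when undefined."""
    if h_index is None:
        return Verdict.AMBIGUOUS
    return Verdict.PUTATIVE_HGT if h_index >= threshold else Verdict.NATIVE


def call_genes(
    hits: Iterable[HitRecord],
    query_lengths: Mapping[str, int],
    exclusion: frozenset[str] | set[str] = frozenset(),
    threshold: float = DEFAULT_THRESHOLD,
    weight_fn: WeightFn = coverage_weight,
) -> list[HGTCall]:
    """Compute HGT calls for every query present in ``query_lengths``.

    Queries without any usable hit are called ambiguous.
    """
    by_gene: dict[str, list[HitRecord]] = defaultdict(list)
    for h in hits:
        by_gene[h.query_id].append(h)
    calls = []
    for gene_id in sorted(query_lengths):
        h, best_nm, best_m = hgt_index_for_gene(
            by_gene.get(gene_id, []), query_lengths[gene_id], exclusion, weight_fn
        )
        calls.append(
            HGTCall(
                gene_id=gene_id,
                h_index=h,
                best_nonmetazoan=best_nm,
                best_metazoan=best_m,
                verdict=classify_hgt(h, threshold),
            )
        )
    return calls


def paralogy_check(
    candidate_ids: Iterable[str],
    within_genome_hits: Iterable[HitRecord],
    cross_species_hits: Iterable[HitRecord],
) -> bool:
    """Single-acquisition test for a family of co-transferred paralogues.

    True iff every candidate's best non-self within-genome bit score among
    the candidate set strictly exceeds its best cross-species bit score —
    the pattern expected when one transfer was followed by in-genome
    duplications.
    """
    candidates = set(candidate_ids)
    if len(candidates) < 2:
        raise ValueError("paralogy_check needs >= 2 candidates")
    best_within: dict[str, float] = {}
    for h in within_genome_hits:
        if (
            h.query_id in candidates
            and h.subject_id in candidates
            and h.subject_id != h.query_id
        ):
            if h.bitscore > best_within.get(h.query_id, float("-inf")):
                best_within[h.query_id] = h.bitscore
    best_cross: dict[str, float] = {}
    for h in cross_species_hits:
        if h.query_id in candidates:
            if h.bitscore > best_cross.get(h.query_id, float("-inf")):
                best_cross[h.query_id] = h.bitscore
    for c in sorted(candidates):
        if c not in best_within:
            raise ValidationError(f"candidate {c} missing from within-genome hits")
        if c not in best_cross:
            raise ValidationError(f"candidate {c} missing from cross-species hits")
        if not best_within[c] > best_cross[c]:
            return False
    return True
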