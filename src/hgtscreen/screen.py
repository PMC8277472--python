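"""Multi-criterion screen separating genuine in-genome homologues from
contaminant-derived sequences.

Four lines of evidence are combined.  Two are hard criteria: a genuine
animal gene should be split into multiple coding exons (prokaryotic
contaminants lack spliceosomal introns) and should show nucleotide identity
below a ceiling (default 80%) to any non-metazoan homologue (a near-identical
nucleotide match indicates contamination rather than an ancient transfer).
Two are supporting criteria: the gene's scaffold should have a read depth
consistent with the rest of the assembly, and the gene should sit inside a
conserved synteny block anchored by reciprocal-best-hit orthologues of its
neighbours in a reference genome.
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import GeneModel, GeneOrder, HitRecord, ScaffoldDepth, ValidationError


class ScreenVerdict(str, enum.Enum):
    INTRINSIC = "intrinsic"
    SUSPECT_CONTAMINANT = "suspect_contaminant"
    INSUFFICIENT_EVIDENCE = "insufficient_evidence"


@dataclass
class ScreenEvidence:
    gene_id: str
    multi_exon: bool
    identity_ok: bool
    max_nonmetazoan_identity: float | None
    depth_ok: bool | None
    depth_ratio: float | None
    synteny_ok: bool | None
    n_synteny_anchors: int
    verdict: ScreenVerdict | None = None


def exon_filter(gene: GeneModel) -> bool:
    """True iff the gene is split into at least two coding exons."""
    if gene.n_exons < 1:
        raise ValidationError(f"gene {gene.gene_id} has no exons")
    return gene.n_exons >= 2


def identity_ceiling_filter(
    gene_id: str,
    nt_hits: Iterable[HitRecord],
    min_aln: int = 100,
    ceiling: float = 80.0,
) -> tuple[bool, float | None]:
    """Nucleotide-identity ceiling against non-metazoan homologues.

    Considering only this gene's hits with ``aln_length >= min_aln``, passes
    iff the maximum percent identity is strictly below ``ceiling``, or no
    qualifying hit exists (vacuously true).  Returns (ok, max_identity).
    """
    if not 0 < ceiling <= 100:
        raise ValueError(f"ceiling {ceiling} outside (0, 100]")
    if min_aln < 1:
        raise ValueError(f"min_aln {min_aln} < 1")
    best: float | None = None
    for h in nt_hits:
        if h.query_id != gene_id or h.aln_length < min_aln:
            continue
        if best is None or h.pct_identity > best:
            best = h.pct_identity
    if best is None:
        return True, None
    return best < ceiling, best


def length_weighted_median_depth(depths: Sequence[ScaffoldDepth]) -> float:
    """Median scaffold depth weighted by scaffold length."""
    if not depths:
        raise ValidationError("empty depth table")
    arr = sorted(depths, key=lambda d: d.mean_depth)
    lengths = np.array([d.length for d in arr], dtype=float)
    cum = np.cumsum(lengths)
    idx = int(np.searchsorted(cum, cum[-1] / 2.0))
    return arr[idx].mean_depth


def depth_filter(
    scaffold: ScaffoldDepth,
    genome_depths: Sequence[ScaffoldDepth],
    lo: float = 0.5,
    hi: float = 2.0,
) -> tuple[bool, float]:
    """Is the scaffold's read depth consistent with the assembly at large?

    The ratio to the length-weighted median depth must fall inside
    [lo, hi]; contaminant contigs typically sit far outside (their source
    organism is over- or under-represented in the read pool).
    """
    median = length_weighted_median_depth(genome_depths)
    if median == 0:
        raise ValidationError("length-weighted median depth is zero")
    ratio = scaffold.mean_depth / median
    return lo <= ratio <= hi, ratio


def synteny_filter(
    gene_id: str,
    focal_order: GeneOrder,
    reference_order: GeneOrder,
    rbh_pairs: Iterable[tuple[str, str]],
    window: int = 5,
    min_anchors: int = 2,
) -> tuple[bool, int]:
    """Is the gene inside a conserved synteny block?

    Takes up to ``window`` genes on each side of the candidate on its own
    scaffold and maps them through reciprocal-best-hit pairs.  Passes iff at
    least ``min_anchors`` of these neighbours have partners that lie on a
    single reference scaffold within a window of equal size around each
    other (local rearrangement tolerated — strict collinearity is not
    required).  Returns (ok, n_anchors).
    """
    focal_pos: tuple[str, int] | None = None
    for sid, genes in focal_order.items():
        if gene_id in genes:
            focal_pos = (sid, genes.index(gene_id))
            break
    if focal_pos is None:
        raise ValidationError(f"gene {gene_id} absent from focal gene order")
    sid, idx = focal_pos
    genes = focal_order[sid]
    neighbours = genes[max(0, idx - window) : idx] + genes[idx + 1 : idx + 1 + window]
    rbh = dict(rbh_pairs)
    ref_pos: dict[str, int] = {}
    for rsid, rgenes in reference_order.items():
        for p, g in enumerate(rgenes):
            ref_pos[g] = p
    ref_scaffold_of = {
        g: rsid for rsid, rgenes in reference_order.items() for g in rgenes
    }
    # partner positions grouped by reference scaffold
    by_scaffold: dict[str, list[int]] = defaultdict(list)
    for n in neighbours:
        partner = rbh.get(n)
        if partner is not None and partner in ref_pos:
            by_scaffold[ref_scaffold_of[partner]].append(ref_pos[partner])
    n_anchors = 0
    for positions in by_scaffold.values():
        positions.sort()
        # largest cluster of partners within a 2*window span
        best_here = 0
        j = 0
        for i in range(len(positions)):
            while positions[i] - positions[j] > 2 * window:
                j += 1
            best_here = max(best_here, i - j + 1)
        n_anchors = max(n_anchors, best_here)
    return n_anchors >= min_anchors, n_anchors


def aggregate_verdict(evidence: ScreenEvidence, required_supporting: int = 1) -> ScreenVerdict:
    """Combine the four criteria into one verdict.

    Multi-exon structure and the identity ceiling are hard criteria: failing
    either marks the gene a suspect contaminant.  When both hold, the gene
    is intrinsic iff at least ``required_supporting`` of the available
    supporting criteria (depth, synteny) also hold; otherwise the evidence
    is insufficient.
    """
    if not (evidence.multi_exon and evidence.identity_ok):
        return ScreenVerdict.SUSPECT_CONTAMINANT
    supporting = [v for v in (evidence.depth_ok, evidence.synteny_ok) if v is not None]
    if sum(supporting) >= required_supporting:
        return ScreenVerdict.INTRINSIC
    return ScreenVerdict.INSUFFICIENT_EVIDENCE


def screen_genes(
    genes: Sequence[GeneModel],
    nt_hits: Iterable[HitRecord],
    depths: Sequence[ScaffoldDepth],
    focal_order: GeneOrder | None = None,
    reference_order: GeneOrder | None = None,
    rbh_pairs: Iterable[tuple[str, str]] | None = None,
    min_aln: int = 100,
    ceiling: float = 80.0,
    depth_lo: float = 0.5,
    depth_hi: float = 2.0,
    window: int = 5,
    min_anchors: int = 2,
    required_supporting: int = 1,
) -> list[ScreenEvidence]:
    """Run the full screen over a gene set; deterministic and order-independent.

    Synteny evidence is computed only when the gene-order and RBH inputs are
    all provided; otherwise ``synteny_ok`` is None and the quorum counts the
    depth criterion alone.
    """
    hits_by_gene: dict[str, list[HitRecord]] = defaultdict(list)
    for h in nt_hits:
        hits_by_gene[h.query_id].append(h)
    depth_by_scaffold = {d.scaffold_id: d for d in depths}
    rbh_list = list(rbh_pairs) if rbh_pairs is not None else None
    have_synteny = (
        focal_order is not None and reference_order is not None and rbh_list is not None
    )
    out: list[ScreenEvidence] = []
    for gene in sorted(genes, key=lambda g: g.gene_id):
        multi = exon_filter(gene)
        identity_ok, max_ident = identity_ceiling_filter(
            gene.gene_id, hits_by_gene.get(gene.gene_id, []), min_aln, ceiling
        )
        depth_ok: bool | None = None
        ratio: float | None = None
        if gene.scaffold_id in depth_by_scaffold:
            depth_ok, ratio = depth_filter(
                depth_by_scaffold[gene.scaffold_id], depths, depth_lo, depth_hi
            )
        syn_ok: bool | None = None
        n_anchors = 0
        if have_synteny:
            syn_ok, n_anchors = synteny_filter(
                gene.gene_id, focal_order, reference_order, rbh_list, window, min_anchors
            )
        ev = ScreenEvidence(
            gene_id=gene.gene_id,
            multi_exon=multi,
            identity_ok=identity_ok,
            max_nonmetazoan_identity=max_ident,
            depth_ok=depth_ok,
            depth_ratio=ratio,
            synteny_ok=syn_ok,
            n_synteny_anchors=n_anchors,
        )
        ev.verdict = aggregate_verdict(ev, required_supporting)
        out.append(ev)
    return out
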