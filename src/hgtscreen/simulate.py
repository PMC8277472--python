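"""Seeded generators emulating every input the pipeline consumes.

The generators plant a known ground truth — native genes, horizontally
transferred gene families, contaminant genes, orthologue pairs with known
divergence, and clade-diagnostic indel blocks — so that every downstream
stage can be tested end-to-end without external data.

Statistical structure emulated:

* similarity bit scores decrease linearly with divergence to each database
  taxon (transferred genes are closest to a non-metazoan donor clade,
  native genes to metazoans), with Gaussian noise;
* codon pairs evolve under a two-parameter (Kimura-type) substitution
  process applied only at third positions of fourfold-degenerate codons, so
  the amino acid sequence is untouched and 4DTv behaves as a neutral
  divergence proxy;
* contaminant genes are single-exon, near-identical at the nucleotide level
  to a donor sequence, and sit on dedicated scaffolds with aberrant read
  depth;
* conserved gene-order blocks are shared with a reference genome around
  native genes;
* the clade-labelled protein alignment carries planted focal-clade indel
  blocks at recorded columns.

All randomness flows through numpy's PCG64 ``default_rng`` seeded from the
configuration, so identical configurations give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fourdtv import FOURFOLD_PREFIXES, CodonPairAlignment
from .io import (
    CladeLabelledAlignment,
    GeneModel,
    GeneOrder,
    HitRecord,
    ScaffoldDepth,
    TaxonEntry,
    TaxonGroup,
    TaxonMap,
    ValidationError,
)

# ---------------------------------------------------------------------------
# configuration and ground truth


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study conditions.

    Divergences are in expected substitutions per site; bit-score parameters
    are bits per alignment column; depths are fold-coverage.
    """

    seed: int = 0
    n_native_genes: int = 100
    n_hgt_genes: int = 20
    n_contaminant_genes: int = 30
    divergence_native: float = 0.1
    divergence_donor: float = 0.15
    distant_divergence: float = 1.5
    within_family_divergence: float = 0.05
    ortho_divergence: float = 0.2
    bitscore_intercept: float = 2.0  # bits per column at zero divergence
    bitscore_slope: float = 1.0  # bits per column per unit divergence
    bitscore_noise_sd: float = 5.0
    kappa: float = 2.0
    depth_native_mean: float = 60.0
    depth_native_sd: float = 6.0
    depth_contaminant_mean: float = 300.0
    depth_contaminant_sd: float = 30.0
    contaminant_identity: float = 97.0
    n_codons: int = 300
    genes_per_scaffold: int = 10
    hgt_family_size: int = 3
    p_de_native: float = 0.3
    p_de_hgt: float = 0.5

    def __post_init__(self) -> None:
        if min(self.n_native_genes, self.n_hgt_genes, self.n_contaminant_genes) < 0:
            raise ValidationError("gene counts must be >= 0")
        for name in (
            "divergence_native",
            "divergence_donor",
            "distant_divergence",
            "within_family_divergence",
            "ortho_divergence",
            "kappa",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.bitscore_noise_sd < 0 or self.bitscore_slope <= 0:
            raise ValidationError("bad bit-score parameters")
        if not 0 < self.contaminant_identity <= 100:
            raise ValidationError("contaminant_identity outside (0, 100]")


@dataclass
class GroundTruth:
    """Planted labels the simulators guarantee and tests recover."""

    origins: dict[str, str]  # gene_id -> native | hgt | contaminant
    hgt_families: list[list[str]] = field(default_factory=list)
    orthologue_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    signature_blocks: list[tuple[int, int, str]] = field(default_factory=list)

    def genes_of(self, origin: str) -> list[str]:
        return sorted(g for g, o in self.origins.items() if o == origin)


# stream keys separating the RNG used by each generator
_STREAM_TRUTH, _STREAM_HITS, _STREAM_GENOME, _STREAM_EVOLVE = 11, 13, 17, 19


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([config_seed, stream])


# ---------------------------------------------------------------------------
# codon-pair evolution

_STOPS = {"TAA", "TAG", "TGA"}
_CODONS_NO_STOP = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]
_FOURFOLD_CODONS = [p + c for p in sorted(FOURFOLD_PREFIXES) for c in "ACGT"]
_TRANSITION = {ord("A"): ord("G"), ord("G"): ord("A"), ord("C"): ord("T"), ord("T"): ord("C")}
_TRANSVERSIONS = {
    ord("A"): (ord("C"), ord("T")),
    ord("G"): (ord("C"), ord("T")),
    ord("C"): (ord("A"), ord("G")),
    ord("T"): (ord("A"), ord("G")),
}


def random_cds(rng: np.random.Generator, n_codons: int, fourfold_only: bool = False) -> str:
    """A random stop-free CDS; optionally all codons fourfold-degenerate."""
    pool = _FOURFOLD_CODONS if fourfold_only else _CODONS_NO_STOP
    idx = rng.integers(0, len(pool), size=n_codons)
    return "".join(pool[i] for i in idx)


def k80_probabilities(divergence: float, kappa: float) -> tuple[float, float, float]:
    """(p_same, p_transition, p_each_transversion) of a two-parameter process.

    The process is calibrated so the expected number of substitutions per
    site equals ``divergence`` with transition:transversion rate ratio
    ``kappa``.  At saturation each base is equally likely, so the total
    transversion probability tends to 1/2.
    """
    beta = divergence / (kappa + 2.0)
    alpha = kappa * beta
    e4 = math.exp(-4.0 * beta)
    e2 = math.exp(-2.0 * (alpha + beta))
    p_ts = 0.25 + 0.25 * e4 - 0.5 * e2
    p_tv_each = 0.25 - 0.25 * e4
    p_same = 1.0 - p_ts - 2.0 * p_tv_each
    return p_same, p_ts, p_tv_each


def evolve_codon_pair(
    cds: str,
    divergence: float,
    kappa: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> CodonPairAlignment:
    """Evolve a CDS into an aligned pair with substitutions only at fourfold
    third positions.

    The first sequence of the returned pair is the input; the second differs
    only at third positions of fourfold-degenerate codons, mutated under the
    two-parameter process at total expected divergence ``divergence``.  The
    amino acid sequence is therefore identical between the two.
    """
    cds = cds.upper()
    if len(cds) % 3:
        raise ValidationError(f"CDS length {len(cds)} not a multiple of 3")
    if divergence < 0:
        raise ValueError("divergence must be >= 0")
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    for i in range(0, len(cds) - 3, 3):
        if cds[i : i + 3] in _STOPS:
            raise ValidationError(f"internal stop codon at codon {i // 3}")
    if rng is None:
        rng = np.random.default_rng(seed)
    arr = np.frombuffer(cds.encode("ascii"), dtype=np.uint8).copy()
    codons = arr.reshape(-1, 3)
    prefix_ok = np.array(
        [chr(c[0]) + chr(c[1]) in FOURFOLD_PREFIXES for c in codons]
    )
    sites = np.flatnonzero(prefix_ok) * 3 + 2
    p_same, p_ts, p_tv = k80_probabilities(divergence, kappa)
    u = rng.random(sites.size)
    tv_choice = rng.random(sites.size) < 0.5  # which transversion target
    out = arr.copy()
    for k, pos in enumerate(sites):
        base = arr[pos]
        if u[k] < p_same:
            continue
        if u[k] < p_same + p_ts:
            out[pos] = _TRANSITION[base]
        else:
            t1, t2 = _TRANSVERSIONS[base]
            out[pos] = t1 if tv_choice[k] else t2
    return CodonPairAlignment(cds, out.tobytes().decode("ascii"))


# ---------------------------------------------------------------------------
# database taxa and divergence structure

#: (subject prefix, taxon name, group, excluded-lineage flag)
DB_TAXA: list[tuple[str, str, TaxonGroup, bool]] = [
    ("DROME", "Drosophila_melanogaster", TaxonGroup.METAZOAN, False),
    ("DAPPU", "Daphnia_pulex", TaxonGroup.METAZOAN, False),
    ("RAMVA", "Ramazzottius_varieornatus", TaxonGroup.METAZOAN, True),
    ("DONOR", "Donor_bacterium", TaxonGroup.NON_METAZOAN, False),
    ("ECOLI", "Escherichia_coli", TaxonGroup.NON_METAZOAN, False),
    ("ASPFU", "Aspergillus_nidulans", TaxonGroup.NON_METAZOAN, False),
]

#: exponential decay constants mapping divergence to percent identity
IDENTITY_DECAY_AA = 0.75
IDENTITY_DECAY_NT = 2.5


def contaminant_nt_divergence(config: SimulationConfig) -> float:
    """Divergence at which nucleotide identity equals contaminant_identity."""
    return -math.log(config.contaminant_identity / 100.0) / IDENTITY_DECAY_NT


def taxon_divergences(origin: str, config: SimulationConfig) -> dict[str, float]:
    """True divergence from a gene of the given origin to each database taxon.

    Native genes are closest to metazoans (including the excluded sister
    lineage) and far from everything non-metazoan; transferred and
    contaminant genes are closest to the donor clade.  Absent entries mean
    no detectable hit.
    """
    if origin == "native":
        return {
            "DROME": config.divergence_native,
            "DAPPU": config.divergence_native * 1.2,
            "RAMVA": config.divergence_native * 0.8,
            "ASPFU": config.distant_divergence,
        }
    if origin == "hgt":
        # the excluded lineage shares the transfer, hence its small distance:
        # without the exclusion the index would see a strong "metazoan" hit
        return {
            "DONOR": config.divergence_donor,
            "ECOLI": config.divergence_donor + 0.65,
            "RAMVA": config.divergence_donor * 1.2,
            "DROME": config.distant_divergence,
        }
    if origin == "contaminant":
        return {
            "DONOR": contaminant_nt_divergence(config),
            "ECOLI": 0.7,
        }
    raise ValueError(f"unknown origin {origin!r}")


def expected_bitscore(divergence: float, config: SimulationConfig) -> float:
    """Noise-free bit score of a full-length hit at the given divergence."""
    return max(
        0.0,
        config.n_codons
        * (config.bitscore_intercept - config.bitscore_slope * divergence),
    )


def _aln_length_aa(divergence: float, config: SimulationConfig) -> int:
    return max(30, round(config.n_codons * (1.0 - 0.25 * min(divergence, 1.6))))


def _pct_identity(divergence: float, decay: float) -> float:
    return float(np.clip(100.0 * math.exp(-decay * divergence), 1.0, 100.0))


def _evalue(bitscore: float) -> float:
    return max(1e-180, 10.0 ** (-bitscore / 10.0))


def make_taxon_map() -> TaxonMap:
    entries = {
        prefix: TaxonEntry(name, group, exclude)
        for prefix, name, group, exclude in DB_TAXA
    }
    entries["SYNREF"] = TaxonEntry("Synteny_reference", TaxonGroup.METAZOAN, False)
    entries["ITA"] = TaxonEntry("Sister_strain", TaxonGroup.METAZOAN, False)
    # focal-genome gene ids (g0001, ...) appear as subjects in the
    # within-genome and reciprocal cross-species tables
    entries["g"] = TaxonEntry("Focal_species", TaxonGroup.METAZOAN, False)
    return TaxonMap(entries)


def make_truth(config: SimulationConfig) -> GroundTruth:
    """Assign origins to gene ids with a seeded shuffle and group the
    transferred genes into co-duplicated families."""
    rng = _rng(config.seed, _STREAM_TRUTH)
    n = config.n_native_genes + config.n_hgt_genes + config.n_contaminant_genes
    labels = (
        ["native"] * config.n_native_genes
        + ["hgt"] * config.n_hgt_genes
        + ["contaminant"] * config.n_contaminant_genes
    )
    rng.shuffle(labels)
    origins = {f"g{i + 1:04d}": labels[i] for i in range(n)}
    truth = GroundTruth(origins=origins)
    hgt_genes = truth.genes_of("hgt")
    fs = max(2, config.hgt_family_size)
    families = [hgt_genes[i : i + fs] for i in range(0, len(hgt_genes), fs)]
    # a trailing singleton cannot form a family; merge it into the previous one
    if len(families) >= 2 and len(families[-1]) < 2:
        families[-2].extend(families.pop())
    truth.hgt_families = [f for f in families if len(f) >= 2]
    return truth


# ---------------------------------------------------------------------------
# hit tables


def simulate_hit_table(
    truth: GroundTruth, config: SimulationConfig
) -> tuple[list[HitRecord], TaxonMap]:
    """Protein-similarity hits of every gene against the taxon-labelled db.

    For each gene and taxon, bitscore = max(0, L*(s0 - slope*d) + eps) with
    eps ~ Normal(0, noise_sd), where d is the true divergence to that taxon;
    alignment length and percent identity are drawn consistently with d.
    Deterministic for fixed (truth, config).
    """
    rng = _rng(config.seed, _STREAM_HITS)
    taxon_map = make_taxon_map()
    taxa = {prefix: (name, group, exclude) for prefix, name, group, exclude in DB_TAXA}
    records: list[HitRecord] = []
    for gene_id in sorted(truth.origins):
        origin = truth.origins[gene_id]
        for prefix, d in sorted(taxon_divergences(origin, config).items()):
            eps = rng.normal(0.0, config.bitscore_noise_sd) if config.bitscore_noise_sd else 0.0
            score = max(0.0, expected_bitscore(d, config) + eps)
            if score <= 0.0:
                continue
            aln = _aln_length_aa(d, config)
            name, group, exclude = taxa[prefix]
            records.append(
                HitRecord(
                    query_id=gene_id,
                    subject_id=f"{prefix}_{gene_id}",
                    pct_identity=round(_pct_identity(d, IDENTITY_DECAY_AA), 2),
                    aln_length=aln,
                    bitscore=round(score, 1),
                    evalue=_evalue(score),
                    subject_taxon=name,
                    taxon_group=TaxonGroup.EXCLUDED if exclude else group,
                    qend=aln,
                    send=aln,
                )
            )
    return records, taxon_map


def simulate_within_genome_hits(
    truth: GroundTruth, config: SimulationConfig
) -> list[HitRecord]:
    """Mutual within-genome hits among each planted transferred family.

    Family members were duplicated after the transfer, so their mutual bit
    scores exceed any cross-species score.
    """
    rng = _rng(config.seed, _STREAM_HITS + 100)
    records: list[HitRecord] = []
    L = config.n_codons
    for family in truth.hgt_families:
        for q in family:
            for s in family:
                if q == s:
                    continue
                eps = rng.normal(0.0, config.bitscore_noise_sd) if config.bitscore_noise_sd else 0.0
                score = max(0.0, expected_bitscore(config.within_family_divergence, config) + eps)
                records.append(
                    HitRecord(
                        query_id=q,
                        subject_id=s,
                        pct_identity=round(
                            _pct_identity(config.within_family_divergence, IDENTITY_DECAY_AA), 2
                        ),
                        aln_length=L,
                        bitscore=round(score, 1),
                        evalue=_evalue(score),
                        subject_taxon="self",
                        taxon_group=TaxonGroup.METAZOAN,
                        qend=L,
                        send=L,
                    )
                )
    return records


# ---------------------------------------------------------------------------
# genome fixture


@dataclass
class GenomeFixture:
    genes: list[GeneModel]
    depths: list[ScaffoldDepth]
    nt_hits: list[HitRecord]
    focal_order: GeneOrder
    reference_order: GeneOrder
    synteny_hits_ab: list[HitRecord]
    synteny_hits_ba: list[HitRecord]
    ortho_pairs: dict[str, CodonPairAlignment]
    ortho_hits_ab: list[HitRecord]
    ortho_hits_ba: list[HitRecord]
    clade_alignment: CladeLabelledAlignment
    candidate_rows: dict[str, str]  # alignment row id -> gene id
    de_flags: dict[str, bool]


def _split_exons(
    rng: np.random.Generator, cds_len: int, n_exons: int
) -> list[int]:
    """Partition a CDS length into n_exons positive pieces."""
    if n_exons == 1:
        return [cds_len]
    cuts = np.sort(rng.choice(np.arange(1, cds_len), size=n_exons - 1, replace=False))
    pieces = np.diff(np.concatenate([[0], cuts, [cds_len]]))
    return [int(p) for p in pieces]


def _cross_hit(q: str, s: str, score: float, L: int, pident: float = 95.0) -> HitRecord:
    return HitRecord(
        query_id=q,
        subject_id=s,
        pct_identity=pident,
        aln_length=L,
        bitscore=round(score, 1),
        evalue=_evalue(score),
        subject_taxon="cross_species",
        taxon_group=TaxonGroup.METAZOAN,
        qend=L,
        send=L,
    )


def simulate_genome(truth: GroundTruth, config: SimulationConfig) -> GenomeFixture:
    """Gene models, depths, nucleotide hits, synteny and orthology fixtures,
    and the clade-labelled alignment, with planted contaminants and indels.

    Fills ``truth.orthologue_pairs`` and ``truth.signature_blocks``.
    """
    rng = _rng(config.seed, _STREAM_GENOME)
    L_nt = config.n_codons * 3
    host_genes = sorted(
        g for g, o in truth.origins.items() if o in ("native", "hgt")
    )
    contaminants = truth.genes_of("contaminant")

    genes: list[GeneModel] = []
    depths: list[ScaffoldDepth] = []
    focal_order: GeneOrder = {}

    # --- host scaffolds: native and transferred genes, multi-exon
    cds_of: dict[str, str] = {}
    for chunk_start in range(0, len(host_genes), config.genes_per_scaffold):
        chunk = host_genes[chunk_start : chunk_start + config.genes_per_scaffold]
        sid = f"scf{chunk_start // config.genes_per_scaffold + 1:03d}"
        focal_order[sid] = list(chunk)
        pos = 0
        for gid in chunk:
            cds = random_cds(rng, config.n_codons)
            cds_of[gid] = cds
            n_exons = int(rng.integers(2, 9))
            pieces = _split_exons(rng, L_nt, n_exons)
            pos += int(rng.integers(200, 2000))
            exons = []
            for piece in pieces:
                exons.append((pos, pos + piece))
                pos += piece + int(rng.integers(80, 400))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    gene_id=gid,
                    scaffold_id=sid,
                    strand=strand,
                    exons=exons,
                    cds_sequence=cds,
                )
            )
        scaffold_len = pos + int(rng.integers(500, 2000))
        depth = max(1.0, rng.normal(config.depth_native_mean, config.depth_native_sd))
        depths.append(ScaffoldDepth(sid, round(depth, 3), scaffold_len))

    # --- contaminant contigs: single-exon genes on aberrant-depth scaffolds
    for k, gid in enumerate(contaminants):
        sid = f"ctg{k + 1:03d}"
        cds = random_cds(rng, config.n_codons)
        cds_of[gid] = cds
        start = int(rng.integers(200, 1500))
        genes.append(
            GeneModel(
                gene_id=gid,
                scaffold_id=sid,
                strand="+",
                exons=[(start, start + L_nt)],
                cds_sequence=cds,
            )
        )
        focal_order[sid] = [gid]
        depth = max(
            1.0, rng.normal(config.depth_contaminant_mean, config.depth_contaminant_sd)
        )
        depths.append(
            ScaffoldDepth(sid, round(depth, 3), start + L_nt + int(rng.integers(200, 1500)))
        )

    # --- nucleotide hits vs the non-metazoan database
    nt_hits: list[HitRecord] = []
    d_cont = contaminant_nt_divergence(config)
    for gid in sorted(truth.origins):
        origin = truth.origins[gid]
        if origin == "hgt":
            pident = _pct_identity(config.divergence_donor, IDENTITY_DECAY_NT)
            aln = round(L_nt * 0.8)
        elif origin == "contaminant":
            pident = min(100.0, config.contaminant_identity + float(rng.uniform(0.0, 1.5)))
            aln = round(L_nt * 0.95)
        else:
            continue  # native genes: no detectable non-metazoan nucleotide hit
        score = 2.0 * aln * pident / 100.0
        nt_hits.append(
            HitRecord(
                query_id=gid,
                subject_id=f"DONOR_nt_{gid}",
                pct_identity=round(pident, 2),
                aln_length=aln,
                bitscore=round(score, 1),
                evalue=_evalue(score),
                subject_taxon="Donor_bacterium",
                taxon_group=TaxonGroup.NON_METAZOAN,
                qend=aln,
                send=aln,
            )
        )

    # --- synteny reference: conserved gene order around native genes only
    reference_order: GeneOrder = {}
    synteny_hits_ab: list[HitRecord] = []
    synteny_hits_ba: list[HitRecord] = []
    syn_partner: dict[str, str] = {}
    for sid, ordered in sorted(focal_order.items()):
        if sid.startswith("ctg"):
            continue
        rsid = "r" + sid
        ref_genes = []
        for gid in ordered:
            if truth.origins[gid] != "native":
                continue  # transferred genes have no counterpart in the reference
            ref_id = f"SYNREF_{gid}"
            ref_genes.append(ref_id)
            syn_partner[gid] = ref_id
        if ref_genes:
            reference_order[rsid] = ref_genes
    for i, (gid, ref_id) in enumerate(sorted(syn_partner.items())):
        score = 400.0 + (i % 7)
        synteny_hits_ab.append(_cross_hit(gid, ref_id, score, config.n_codons))
        synteny_hits_ba.append(_cross_hit(ref_id, gid, score, config.n_codons))

    # --- close-strain orthologues for the 4DTv background
    ortho_pairs: dict[str, CodonPairAlignment] = {}
    ortho_hits_ab: list[HitRecord] = []
    ortho_hits_ba: list[HitRecord] = []
    evolve_rng = _rng(config.seed, _STREAM_EVOLVE)
    top = expected_bitscore(config.within_family_divergence, config)
    for i, gid in enumerate(host_genes):
        pair = evolve_codon_pair(
            cds_of[gid], config.ortho_divergence, config.kappa, rng=evolve_rng
        )
        ortho_pairs[gid] = pair
        ref_id = f"ITA_{gid}"
        truth.orthologue_pairs.append((gid, ref_id, config.ortho_divergence))
        noise = (
            float(rng.normal(0.0, config.bitscore_noise_sd))
            if config.bitscore_noise_sd
            else 0.0
        )
        score = max(0.0, top + noise)
        ortho_hits_ab.append(_cross_hit(gid, ref_id, score, config.n_codons))
        ortho_hits_ba.append(_cross_hit(ref_id, gid, score, config.n_codons))
        # a weaker decoy hit to the next gene's orthologue, for realism
        nxt = host_genes[(i + 1) % len(host_genes)]
        decoy = max(0.0, score - 0.5 * top)
        if decoy > 0:
            ortho_hits_ab.append(
                _cross_hit(gid, f"ITA_{nxt}", decoy, config.n_codons, pident=60.0)
            )

    # --- clade-labelled alignment with planted diagnostic indel blocks
    aln, candidate_rows, blocks = _simulate_clade_alignment(truth, config, rng)
    truth.signature_blocks = blocks

    # --- differential-expression flags
    de_flags: dict[str, bool] = {}
    for gid in sorted(truth.origins):
        origin = truth.origins[gid]
        if origin == "hgt":
            p = config.p_de_hgt
        elif origin == "native":
            p = config.p_de_native
        else:
            p = 0.0
        de_flags[gid] = bool(rng.random() < p)

    return GenomeFixture(
        genes=genes,
        depths=depths,
        nt_hits=nt_hits,
        focal_order=focal_order,
        reference_order=reference_order,
        synteny_hits_ab=synteny_hits_ab,
        synteny_hits_ba=synteny_hits_ba,
        ortho_pairs=ortho_pairs,
        ortho_hits_ab=ortho_hits_ab,
        ortho_hits_ba=ortho_hits_ba,
        clade_alignment=aln,
        candidate_rows=candidate_rows,
        de_flags=de_flags,
    )


_AA = "ACDEFGHIKLMNPQRSTVWY"


def _simulate_clade_alignment(
    truth: GroundTruth, config: SimulationConfig, rng: np.random.Generator
) -> tuple[CladeLabelledAlignment, dict[str, str], list[tuple[int, int, str]]]:
    """A 120-column protein alignment with three planted indel blocks
    diagnostic for the bilaterian clade, plus donor-derived candidate rows
    (named after transferred genes) lacking every signature."""
    n_cols = 120
    rows_spec = (
        [(f"bilat{i:02d}", "bilateria") for i in range(1, 7)]
        + [(f"cnid{i:02d}", "cnidaria") for i in range(1, 4)]
        + [(f"fungi{i:02d}", "fungi") for i in range(1, 4)]
        + [(f"bact{i:02d}", "bacteria") for i in range(1, 4)]
    )
    hgt_genes = truth.genes_of("hgt")
    candidate_rows: dict[str, str] = {}
    for gid in hgt_genes[:2]:
        row_id = f"cand_{gid}"
        rows_spec.append((row_id, "candidate"))
        candidate_rows[row_id] = gid
    ids = [r[0] for r in rows_spec]
    clades = [r[1] for r in rows_spec]
    mat = np.array(
        [[_AA[i] for i in rng.integers(0, len(_AA), size=n_cols)] for _ in ids],
        dtype="<U1",
    )
    # planted blocks: two bilaterian-specific insertions and one deletion
    starts = [
        int(rng.integers(10, 22)),
        int(rng.integers(45, 57)),
        int(rng.integers(85, 97)),
    ]
    widths = [5, 3, 4]
    kinds = ["insertion", "insertion", "deletion"]
    blocks: list[tuple[int, int, str]] = []
    focal = [c == "bilateria" for c in clades]
    for start, width, kind in zip(starts, widths, kinds):
        end = start + width
        for r in range(len(ids)):
            is_focal = focal[r]
            if kind == "insertion":
                gap = not is_focal
            else:
                gap = is_focal
            if gap:
                mat[r, start:end] = "-"
        blocks.append((start, end, kind))
    rows = ["".join(mat[r]) for r in range(len(ids))]
    aln = CladeLabelledAlignment(ids=ids, clades=clades, rows=rows)
    return aln, candidate_rows, blocks


# ---------------------------------------------------------------------------
# one-call dataset


@dataclass
class SimulatedDataset:
    """Everything the pipeline consumes, plus the planted truth.

    The same container is used for file-backed (real-data) inputs, in which
    case ``truth`` carries origin "unknown" for every gene.
    """

    config: SimulationConfig
    truth: GroundTruth
    taxon_map: TaxonMap
    protein_hits: list[HitRecord]
    within_genome_hits: list[HitRecord]
    genome: GenomeFixture
    query_lengths: dict[str, int]


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate the full fixture set for one configuration."""
    truth = make_truth(config)
    protein_hits, taxon_map = simulate_hit_table(truth, config)
    within = simulate_within_genome_hits(truth, config)
    genome = simulate_genome(truth, config)
    return SimulatedDataset(
        config=config,
        truth=truth,
        taxon_map=taxon_map,
        protein_hits=protein_hits,
        within_genome_hits=within,
        genome=genome,
        query_lengths={g: config.n_codons for g in truth.origins},
    )


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> None:
    """Write the full fixture set as plain-text files (FASTA/GFF3/TSV)."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    from . import io as _io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    g = dataset.genome
    write_truth(dataset.truth, outdir / "truth.tsv")
    _io.write_taxon_map(dataset.taxon_map, outdir / "taxa.tsv")
    _io.write_hit_table(dataset.protein_hits, outdir / "hits.tsv")
    _io.write_hit_table(dataset.within_genome_hits, outdir / "within_hits.tsv")
    _io.write_gene_models(g.genes, outdir / "genes.gff3", outdir / "cds.fasta")
    _io.write_depth_table(g.depths, outdir / "depths.tsv")
    _io.write_hit_table(g.nt_hits, outdir / "nt_hits.tsv")
    _io.write_gene_order(g.focal_order, outdir / "order_focal.tsv")
    _io.write_gene_order(g.reference_order, outdir / "order_reference.tsv")
    _io.write_hit_table(g.synteny_hits_ab, outdir / "synteny_hits_ab.tsv")
    _io.write_hit_table(g.synteny_hits_ba, outdir / "synteny_hits_ba.tsv")
    _io.write_hit_table(g.ortho_hits_ab, outdir / "ortho_hits_ab.tsv")
    _io.write_hit_table(g.ortho_hits_ba, outdir / "ortho_hits_ba.tsv")
    for suffix, attr in (("a", "seq_a"), ("b", "seq_b")):
        records = [
            SeqRecord(Seq(getattr(pair, attr)), id=gid, description="")
            for gid, pair in sorted(g.ortho_pairs.items())
        ]
        SeqIO.write(records, str(outdir / f"ortho_{suffix}.fasta"), "fasta")
    _io.write_clade_alignment(
        g.clade_alignment, outdir / "msa.fasta", outdir / "msa_labels.tsv"
    )
    with open(outdir / "candidates.tsv", "w") as fh:
        fh.write("row_id\tgene_id\n")
        for row_id, gid in sorted(g.candidate_rows.items()):
            fh.write(f"{row_id}\t{gid}\n")
    _io.write_de_table(g.de_flags, outdir / "de.tsv")
    with open(outdir / "qlens.tsv", "w") as fh:
        fh.write("gene_id\tlength\n")
        for gid in sorted(dataset.query_lengths):
            fh.write(f"{gid}\t{dataset.query_lengths[gid]}\n")
    _io.write_config(dataclasses_asdict(dataset.config), outdir / "config.yaml")


def dataclasses_asdict(config: SimulationConfig) -> dict:
    import dataclasses

    return dataclasses.asdict(config)


def load_dataset(indir: str | Path) -> SimulatedDataset:
    """Load a fixture set written by :func:`write_dataset` (or assembled by
    hand in the same layout) back into the pipeline's input container."""
    from Bio import SeqIO

    from . import io as _io

    indir = Path(indir)
    config = SimulationConfig(**_io.load_config(indir / "config.yaml"))
    truth_path = indir / "truth.tsv"
    taxon_map = _io.read_taxon_map(indir / "taxa.tsv")
    genes = _io.read_gene_models(indir / "genes.gff3", indir / "cds.fasta")
    if truth_path.exists():
        truth = read_truth(truth_path)
    else:
        truth = GroundTruth(origins={g.gene_id: "unknown" for g in genes})
    seqs_a = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(indir / "ortho_a.fasta"), "fasta")}
    seqs_b = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(indir / "ortho_b.fasta"), "fasta")}
    if set(seqs_a) != set(seqs_b):
        raise ValidationError("ortho_a and ortho_b FASTA ids differ")
    ortho_pairs = {
        gid: CodonPairAlignment(seqs_a[gid], seqs_b[gid]) for gid in sorted(seqs_a)
    }
    candidate_rows: dict[str, str] = {}
    with open(indir / "candidates.tsv") as fh:
        fh.readline()
        for line in fh:
            line = line.rstrip("\n")
            if line:
                row_id, gid = line.split("\t")
                candidate_rows[row_id] = gid
    query_lengths: dict[str, int] = {}
    with open(indir / "qlens.tsv") as fh:
        fh.readline()
        for line in fh:
            line = line.rstrip("\n")
            if line:
                gid, length = line.split("\t")
                query_lengths[gid] = int(length)
    genome = GenomeFixture(
        genes=genes,
        depths=_io.read_depth_table(indir / "depths.tsv"),
        nt_hits=_io.read_hit_table(indir / "nt_hits.tsv", taxon_map),
        focal_order=_io.read_gene_order(indir / "order_focal.tsv"),
        reference_order=_io.read_gene_order(indir / "order_reference.tsv"),
        synteny_hits_ab=_io.read_hit_table(indir / "synteny_hits_ab.tsv", taxon_map),
        synteny_hits_ba=_io.read_hit_table(indir / "synteny_hits_ba.tsv", taxon_map),
        ortho_pairs=ortho_pairs,
        ortho_hits_ab=_io.read_hit_table(indir / "ortho_hits_ab.tsv", taxon_map),
        ortho_hits_ba=_io.read_hit_table(indir / "ortho_hits_ba.tsv", taxon_map),
        clade_alignment=_io.read_clade_alignment(
            indir / "msa.fasta", indir / "msa_labels.tsv"
        ),
        candidate_rows=candidate_rows,
        de_flags=_io.read_de_table(indir / "de.tsv"),
    )
    return SimulatedDataset(
        config=config,
        truth=truth,
        taxon_map=taxon_map,
        protein_hits=_io.read_hit_table(indir / "hits.tsv", taxon_map),
        within_genome_hits=_io.read_hit_table(indir / "within_hits.tsv", taxon_map),
        genome=genome,
        query_lengths=query_lengths,
    )


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\torigin\n")
        for gid in sorted(truth.origins):
            fh.write(f"{gid}\t{truth.origins[gid]}\n")


def read_truth(path: str | Path) -> GroundTruth:
    origins: dict[str, str] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            gid, origin = line.split("\t")
            origins[gid] = origin
    return GroundTruth(origins=origins)
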