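"""Readers and writers for the external formats the pipeline touches.

All coordinates are 0-based half-open internally and 1-based closed at GFF3
boundaries.  Every reader validates its input strictly: malformed rows raise
:class:`ParseError` with a line number, inconsistent records raise
:class:`ValidationError`.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class ParseError(ValueError):
    """A file could not be parsed; the message carries the line number."""


class ValidationError(ValueError):
    """A parsed record violates a domain invariant."""


class TaxonGroup(str, enum.Enum):
    METAZOAN = "metazoan"
    NON_METAZOAN = "non_metazoan"
    EXCLUDED = "excluded"


@dataclass(frozen=True)
class HitRecord:
    """One similarity hit (12-column tabular dialect) joined to a taxon group."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    bitscore: float
    evalue: float = 0.0
    subject_taxon: str = ""
    taxon_group: TaxonGroup | None = None
    mismatch: int = 0
    gapopen: int = 0
    qstart: int = 1
    qend: int = 1
    sstart: int = 1
    send: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValidationError(
                f"pct_identity {self.pct_identity} outside [0, 100] "
                f"for hit {self.query_id} vs {self.subject_id}"
            )
        if self.aln_length < 1:
            raise ValidationError(
                f"aln_length {self.aln_length} < 1 for hit "
                f"{self.query_id} vs {self.subject_id}"
            )
        if self.bitscore < 0:
            raise ValidationError(f"negative bitscore for {self.query_id}")
        if self.evalue < 0:
            raise ValidationError(f"negative evalue for {self.query_id}")


@dataclass(frozen=True)
class TaxonEntry:
    taxon_name: str
    group: TaxonGroup
    exclude: bool = False


class TaxonMap:
    """Maps subject ids to (taxon, metazoan/non-metazoan, exclude).

    Resolution is exact-match first, then longest-prefix match, so the map
    supports both per-sequence entries and accession-prefixed databases.
    Unresolvable subjects are an error.
    """

    def __init__(self, entries: Mapping[str, TaxonEntry]):
        self._entries = dict(entries)
        # prefixes sorted longest-first for deterministic longest-prefix match
        self._prefixes = sorted(self._entries, key=len, reverse=True)

    def resolve(self, subject_id: str) -> TaxonEntry:
        entry = self._entries.get(subject_id)
        if entry is not None:
            return entry
        for prefix in self._prefixes:
            if subject_id.startswith(prefix):
                return self._entries[prefix]
        raise ValidationError(f"subject {subject_id!r} not resolvable in taxon map")

    def group_of(self, subject_id: str) -> TaxonGroup:
        entry = self.resolve(subject_id)
        return TaxonGroup.EXCLUDED if entry.exclude else entry.group

    def items(self):
        return self._entries.items()

    def __len__(self) -> int:
        return len(self._entries)


@dataclass
class GeneModel:
    """A gene with ordered coding exons and its spliced, oriented CDS.

    ``exons`` are 0-based half-open genomic intervals, sorted by genomic
    start and non-overlapping; ``cds_sequence`` is already spliced and
    oriented 5'->3' regardless of strand.
    """

    gene_id: str
    scaffold_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds_sequence: str
    complete: bool = True

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"bad strand {self.strand!r} for {self.gene_id}")
        prev_end = -1
        for start, end in self.exons:
            if start < 0 or end <= start:
                raise ValidationError(
                    f"bad exon interval ({start}, {end}) in {self.gene_id}"
                )
            if start < prev_end:
                raise ValidationError(f"overlapping/unsorted exons in {self.gene_id}")
            prev_end = end
        exon_total = sum(end - start for start, end in self.exons)
        if self.cds_sequence and exon_total != len(self.cds_sequence):
            raise ValidationError(
                f"CDS length {len(self.cds_sequence)} != exon total {exon_total} "
                f"for {self.gene_id}"
            )
        if self.complete and self.cds_sequence and len(self.cds_sequence) % 3:
            raise ValidationError(
                f"complete CDS of {self.gene_id} not a multiple of 3"
            )

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass(frozen=True)
class ScaffoldDepth:
    scaffold_id: str
    mean_depth: float
    length: int

    def __post_init__(self) -> None:
        import math

        if not math.isfinite(self.mean_depth) or self.mean_depth < 0:
            raise ValidationError(
                f"bad depth {self.mean_depth} for {self.scaffold_id}"
            )
        if self.length <= 0:
            raise ValidationError(f"bad length {self.length} for {self.scaffold_id}")


@dataclass
class CladeLabelledAlignment:
    """A protein multiple alignment whose rows carry clade labels."""

    ids: list[str]
    clades: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if not (len(self.ids) == len(self.clades) == len(self.rows)):
            raise ValidationError("ids, clades and rows must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("duplicate sequence ids in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValidationError(f"ragged alignment: row lengths {sorted(lengths)}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]


# ---------------------------------------------------------------------------
# hit tables (12-column tabular dialect)

_HIT_COLUMNS = 12


def read_hit_table(path: str | Path, taxon_map: TaxonMap) -> list[HitRecord]:
    """Read a tab-separated 12-column similarity hit table.

    Columns: qid, sid, pident, length, mismatch, gapopen, qstart, qend,
    sstart, send, evalue, bitscore.  Extra columns are ignored with a
    warning.  Every subject must resolve in ``taxon_map``; excluded taxa are
    retained but flagged with ``TaxonGroup.EXCLUDED``.
    """
    records: list[HitRecord] = []
    warned_extra = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < _HIT_COLUMNS:
                raise ParseError(
                    f"{path}:{lineno}: expected {_HIT_COLUMNS} columns, "
                    f"got {len(fields)}"
                )
            if len(fields) > _HIT_COLUMNS and not warned_extra:
                warnings.warn(
                    f"{path}: extra columns beyond {_HIT_COLUMNS} ignored",
                    stacklevel=2,
                )
                warned_extra = True
            try:
                pident = float(fields[2])
                length = int(fields[3])
                mismatch = int(fields[4])
                gapopen = int(fields[5])
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            entry = taxon_map.resolve(fields[1])
            try:
                rec = HitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pct_identity=pident,
                    aln_length=length,
                    bitscore=bitscore,
                    evalue=evalue,
                    subject_taxon=entry.taxon_name,
                    taxon_group=TaxonGroup.EXCLUDED if entry.exclude else entry.group,
                    mismatch=mismatch,
                    gapopen=gapopen,
                    qstart=qstart,
                    qend=qend,
                    sstart=sstart,
                    send=send,
                )
            except ValidationError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_hit_table(records: Iterable[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.query_id,
                        r.subject_id,
                        f"{r.pct_identity:.2f}",
                        str(r.aln_length),
                        str(r.mismatch),
                        str(r.gapopen),
                        str(r.qstart),
                        str(r.qend),
                        str(r.sstart),
                        str(r.send),
                        f"{r.evalue:.3g}",
                        f"{r.bitscore:.1f}",
                    ]
                )
                + "\n"
            )


def read_taxon_map(path: str | Path) -> TaxonMap:
    """TSV: subject_id_or_prefix, taxon_name, group, exclude(0/1)."""
    entries: dict[str, TaxonEntry] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            key, name, group, exclude = fields
            if key in entries:
                raise ParseError(f"{path}:{lineno}: duplicate key {key!r}")
            if group not in ("metazoan", "non_metazoan"):
                raise ParseError(f"{path}:{lineno}: bad group {group!r}")
            if exclude not in ("0", "1"):
                raise ParseError(f"{path}:{lineno}: bad exclude flag {exclude!r}")
            entries[key] = TaxonEntry(name, TaxonGroup(group), exclude == "1")
    return TaxonMap(entries)


def write_taxon_map(taxon_map: TaxonMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for key, entry in sorted(taxon_map.items()):
            fh.write(
                f"{key}\t{entry.taxon_name}\t{entry.group.value}\t"
                f"{int(entry.exclude)}\n"
            )


# ---------------------------------------------------------------------------
# gene models (GFF3 + CDS FASTA)


def read_gene_models(path_gff: str | Path, path_cds_fasta: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 plus a CDS FASTA keyed by transcript id.

    Expects gene -> mRNA -> CDS features.  When a gene has several mRNAs the
    one with the longest summed CDS is used.  Coordinates are converted from
    1-based closed (GFF3) to 0-based half-open.
    """
    cds_seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path_cds_fasta), "fasta")}
    db = gffutils.create_db(
        str(path_gff),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        best: tuple[int, str, list] | None = None
        for mrna in db.children(gene, featuretype="mRNA", order_by="start"):
            cds_feats = list(db.children(mrna, featuretype="CDS", order_by="start"))
            total = sum(f.end - f.start + 1 for f in cds_feats)
            if best is None or total > best[0]:
                best = (total, mrna.id, cds_feats)
        if best is None:
            raise ValidationError(f"gene {gene.id} has no mRNA/CDS features")
        total, mrna_id, cds_feats = best
        if mrna_id not in cds_seqs:
            raise ValidationError(f"transcript {mrna_id} missing from CDS FASTA")
        seq = cds_seqs[mrna_id]
        if len(seq) != total:
            raise ValidationError(
                f"CDS length {len(seq)} != exon total {total} for {mrna_id}"
            )
        exons = [(f.start - 1, f.end) for f in cds_feats]
        genes.append(
            GeneModel(
                gene_id=gene.id,
                scaffold_id=gene.seqid,
                strand=gene.strand,
                exons=exons,
                cds_sequence=seq,
                complete=len(seq) % 3 == 0,
            )
        )
    return genes


def write_gene_models(
    genes: Sequence[GeneModel], path_gff: str | Path, path_cds_fasta: str | Path
) -> None:
    """Write gene models as GFF3 (gene/mRNA/CDS) plus a CDS FASTA.

    The transcript id is ``<gene_id>.t1``; the inverse of
    :func:`read_gene_models` on single-transcript genes.
    """
    with open(path_gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            start = min(s for s, _ in g.exons) + 1
            end = max(e for _, e in g.exons)
            tid = f"{g.gene_id}.t1"
            fh.write(
                f"{g.scaffold_id}\thgtscreen\tgene\t{start}\t{end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            fh.write(
                f"{g.scaffold_id}\thgtscreen\tmRNA\t{start}\t{end}\t.\t"
                f"{g.strand}\t.\tID={tid};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons):
                fh.write(
                    f"{g.scaffold_id}\thgtscreen\tCDS\t{s + 1}\t{e}\t.\t"
                    f"{g.strand}\t0\tID={tid}.cds{i};Parent={tid}\n"
                )
    records = [
        SeqRecord(Seq(g.cds_sequence), id=f"{g.gene_id}.t1", description="")
        for g in genes
    ]
    SeqIO.write(records, str(path_cds_fasta), "fasta")


# ---------------------------------------------------------------------------
# depth, DE flags, gene order, clade alignment


def read_depth_table(path: str | Path) -> list[ScaffoldDepth]:
    """TSV with header: scaffold_id, mean_depth, length; one row per scaffold."""
    out: list[ScaffoldDepth] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["scaffold_id", "mean_depth", "length"]:
            raise ParseError(f"{path}:1: unexpected depth-table header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns")
            sid = fields[0]
            if sid in seen:
                raise ParseError(f"{path}:{lineno}: duplicate scaffold {sid!r}")
            seen.add(sid)
            try:
                out.append(ScaffoldDepth(sid, float(fields[1]), int(fields[2])))
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_depth_table(depths: Iterable[ScaffoldDepth], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("scaffold_id\tmean_depth\tlength\n")
        for d in depths:
            fh.write(f"{d.scaffold_id}\t{d.mean_depth:.3f}\t{d.length}\n")


def read_de_table(path: str | Path) -> dict[str, bool]:
    """TSV with header gene_id, de_flag; flags must be 0 or 1."""
    flags: dict[str, bool] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["gene_id", "de_flag"]:
            raise ParseError(f"{path}:1: unexpected DE-table header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            gid, flag = fields
            if gid in flags:
                raise ParseError(f"{path}:{lineno}: duplicate gene {gid!r}")
            if flag not in ("0", "1"):
                raise ParseError(
                    f"{path}:{lineno}: DE flag must be 0 or 1, got {flag!r}"
                )
            flags[gid] = flag == "1"
    return flags


def write_de_table(flags: Mapping[str, bool], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tde_flag\n")
        for gid in sorted(flags):
            fh.write(f"{gid}\t{int(flags[gid])}\n")


GeneOrder = dict[str, list[str]]
"""Per-scaffold ordered gene ids."""


def read_gene_order(path: str | Path) -> GeneOrder:
    """TSV with header: scaffold_id, position, gene_id (position 0-based)."""
    order: GeneOrder = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["scaffold_id", "position", "gene_id"]:
            raise ParseError(f"{path}:1: unexpected gene-order header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns")
            sid, pos, gid = fields
            lst = order.setdefault(sid, [])
            if int(pos) != len(lst):
                raise ParseError(
                    f"{path}:{lineno}: positions on {sid} must be consecutive from 0"
                )
            lst.append(gid)
    return order


def write_gene_order(order: GeneOrder, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("scaffold_id\tposition\tgene_id\n")
        for sid in sorted(order):
            for pos, gid in enumerate(order[sid]):
                fh.write(f"{sid}\t{pos}\t{gid}\n")


def read_clade_alignment(path_fasta: str | Path, path_labels: str | Path) -> CladeLabelledAlignment:
    """Aligned FASTA plus a TSV (header: seq_id, clade) of clade labels."""
    labels: dict[str, str] = {}
    with open(path_labels) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["seq_id", "clade"]:
            raise ParseError(f"{path_labels}:1: unexpected labels header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path_labels}:{lineno}: expected 2 columns")
            if fields[0] in labels:
                raise ParseError(f"{path_labels}:{lineno}: duplicate id {fields[0]!r}")
            labels[fields[0]] = fields[1]
    ids, clades, rows = [], [], []
    for rec in SeqIO.parse(str(path_fasta), "fasta"):
        if rec.id not in labels:
            raise ValidationError(f"sequence {rec.id} has no clade label")
        ids.append(rec.id)
        clades.append(labels[rec.id])
        rows.append(str(rec.seq).upper())
    return CladeLabelledAlignment(ids=ids, clades=clades, rows=rows)


def write_clade_alignment(
    aln: CladeLabelledAlignment, path_fasta: str | Path, path_labels: str | Path
) -> None:
    records = [
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(aln.ids, aln.rows)
    ]
    SeqIO.write(records, str(path_fasta), "fasta")
    with open(path_labels, "w") as fh:
        fh.write("seq_id\tclade\n")
        for sid, clade in zip(aln.ids, aln.clades):
            fh.write(f"{sid}\t{clade}\n")


def load_config(path: str | Path) -> dict:
    """Load a flat key-value configuration file (YAML)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: configuration must be a mapping")
    return cfg


def write_config(cfg: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)
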