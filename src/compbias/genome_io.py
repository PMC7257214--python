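"""Reading genomes and gene models; strand-correct CDS extraction.

Coordinates follow the GFF3 convention (1-based, inclusive) at every I/O
boundary; slicing converts to Python half-open indexing in exactly one place
(:func:`extract_cds`) to avoid off-by-one drift.
"""

from __future__ import annotations

import logging
import re
import urllib.parse
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

# IUPAC nucleotide alphabet (upper case; validated on read)
IUPAC_NT = set("ACGTNRYSWKMBDHV")

_STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class GenomeSequence:
    """A named nucleotide sequence (scaffold, contig or chromosome)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be nonempty")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass
class GeneModel:
    """Strand-aware exon structure of one coding transcript.

    ``exons`` are 1-based inclusive ``(start, end)`` intervals in genomic
    order (sorted by start, non-overlapping). ``phase`` holds the GFF3 phase
    per exon where known; splicing trusts the intervals, not the phase.
    """

    gene_id: str
    scaffold_id: str
    strand: str
    exons: list[tuple[int, int]]
    phase: list[int | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        self.exons = sorted(self.exons)
        prev_end = 0
        for start, end in self.exons:
            if end < start:
                raise ValueError(f"{self.gene_id}: exon end {end} < start {start}")
            if start < 1:
                raise ValueError(f"{self.gene_id}: exon start {start} < 1")
            if start <= prev_end:
                raise ValueError(f"{self.gene_id}: overlapping exons")
            prev_end = end

    @property
    def cds_length(self) -> int:
        return sum(end - start + 1 for start, end in self.exons)


@dataclass
class CdsSequence:
    """A spliced coding sequence with a completeness flag.

    ``complete`` means: starts with ATG, ends with a stop codon, length is a
    multiple of three, and there is no internal stop.
    """

    gene_id: str
    seq: str
    complete: bool = False

    def __len__(self) -> int:
        return len(self.seq)

    @classmethod
    def from_seq(cls, gene_id: str, seq: str) -> "CdsSequence":
        return cls(gene_id=gene_id, seq=seq, complete=_is_complete(seq))


def _is_complete(seq: str) -> bool:
    if len(seq) < 6 or len(seq) % 3 != 0:
        return False
    if not seq.startswith("ATG") or seq[-3:] not in _STOP_CODONS:
        return False
    for i in range(3, len(seq) - 3, 3):
        if seq[i : i + 3] in _STOP_CODONS:
            return False
    return True


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a FASTA file into a list of :class:`GenomeSequence`.

    Residues are upper-cased and validated against the IUPAC nucleotide
    alphabet; invalid characters are rejected with their 1-based offset.
    Duplicate ids and empty files are errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty or not FASTA")
    out: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        bad = next((i for i, ch in enumerate(residues) if ch not in IUPAC_NT), None)
        if bad is not None:
            raise ValueError(
                f"{path}: sequence {rec.id!r} has non-IUPAC character "
                f"{residues[bad]!r} at offset {bad + 1}"
            )
        out.append(GenomeSequence(id=rec.id, residues=residues))
    return out


def write_fasta(seqs: Iterable[GenomeSequence | CdsSequence], path: str | Path, width: int = 60) -> None:
    """Write sequences to FASTA, wrapping lines at ``width`` columns."""
    with open(path, "w") as fh:
        for s in seqs:
            name = s.id if isinstance(s, GenomeSequence) else s.gene_id
            seq = s.residues if isinstance(s, GenomeSequence) else s.seq
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _parse_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attr.strip().split(";"):
        if not part:
            continue
        key, _, value = part.partition("=")
        out[key.strip()] = urllib.parse.unquote(value.strip())
    return out


def read_gff_cds(path: str | Path) -> list[GeneModel]:
    """Group GFF3 CDS features by Parent into :class:`GeneModel` objects.

    Only CDS lines are consulted; each distinct Parent becomes one model.
    Mixed strands within one parent, or end < start, are rejected. Phase is
    recorded but not used for splicing.
    """
    per_parent: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                continue
            seqid, _source, ftype, start, end, _score, strand, phase, attrs = fields[:9]
            if ftype != "CDS":
                continue
            start_i, end_i = int(start), int(end)
            if end_i < start_i:
                raise ValueError(f"{path}:{lineno}: CDS end {end_i} < start {start_i}")
            attr = _parse_attributes(attrs)
            parent = attr.get("Parent") or attr.get("ID")
            if parent is None:
                raise ValueError(f"{path}:{lineno}: CDS line without Parent or ID")
            rec = per_parent.get(parent)
            if rec is None:
                rec = {"scaffold": seqid, "strand": strand, "exons": [], "phase": []}
                per_parent[parent] = rec
                order.append(parent)
            if rec["strand"] != strand:
                raise ValueError(f"{path}: mixed strands for parent {parent!r}")
            if rec["scaffold"] != seqid:
                raise ValueError(f"{path}: parent {parent!r} spans scaffolds")
            rec["exons"].append((start_i, end_i))
            rec["phase"].append(int(phase) if phase in {"0", "1", "2"} else None)
    models = []
    for parent in order:
        rec = per_parent[parent]
        exon_order = sorted(range(len(rec["exons"])), key=lambda i: rec["exons"][i])
        models.append(
            GeneModel(
                gene_id=parent,
                scaffold_id=rec["scaffold"],
                strand=rec["strand"],
                exons=[rec["exons"][i] for i in exon_order],
                phase=[rec["phase"][i] for i in exon_order],
            )
        )
    return models


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving IUPAC ambiguity codes."""
    return str(Seq(seq).reverse_complement())


def extract_cds(genome: GenomeSequence, model: GeneModel) -> CdsSequence:
    """Splice a gene model out of its scaffold, 5'→3' in transcript orientation.

    Exons are concatenated in genomic order; minus-strand models are
    reverse-complemented after concatenation. The completeness flag (ATG
    start, terminal stop, no internal stop, length % 3 == 0) is set on the
    returned :class:`CdsSequence`.
    """
    if model.scaffold_id != genome.id:
        raise ValueError(f"{model.gene_id}: model is on {model.scaffold_id!r}, not {genome.id!r}")
    n = len(genome.residues)
    parts = []
    for start, end in model.exons:
        if end > n:
            raise ValueError(f"{model.gene_id}: exon [{start},{end}] out of bounds (scaffold length {n})")
        parts.append(genome.residues[start - 1 : end])
    seq = "".join(parts)
    if model.strand == "-":
        seq = reverse_complement(seq)
    if model.phase and model.phase[0] not in (None, 0):
        logger.info("%s: first-exon phase %s recorded but splicing trusts intervals", model.gene_id, model.phase[0])
    return CdsSequence.from_seq(model.gene_id, seq)


def longest_per_gene(models: list[GeneModel], gene_of: dict[str, str] | None = None) -> list[GeneModel]:
    """Keep one transcript per gene: the longest CDS, ties by id.

    ``gene_of`` maps transcript id -> gene id; without it, transcript ids of
    the form ``gene.N`` or ``gene-RX`` are collapsed on the stem.
    """
    def stem(tid: str) -> str:
        if gene_of is not None:
            return gene_of.get(tid, tid)
        return re.sub(r"[.-][A-Za-z0-9]+$", "", tid)

    best: dict[str, GeneModel] = {}
    for m in models:
        g = stem(m.gene_id)
        cur = best.get(g)
        if cur is None or (m.cds_length, cur.gene_id) > (cur.cds_length, m.gene_id):
            best[g] = m
    return sorted(best.values(), key=lambda m: m.gene_id)
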