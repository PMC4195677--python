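"""Core domain types, coordinate conventions and FASTA/GFF3 I/O.

All intervals are 0-based half-open on the forward strand internally.
GFF3 input/output converts to and from the 1-based inclusive convention of
that format.  CDS exons of a transcript are stored sorted ascending in
forward-strand coordinates regardless of strand; for a '-' strand gene the
spliced coding sequence is obtained by reverse-complementing the descending
concatenation (see :func:`extract_cds`).

The terminal stop codon is part of the CDS interval but is *not* counted in
the protein length: a coding-complete CDS of L nucleotides translates to
exactly L/3 - 1 amino acids.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = set("ACGTN")
GST_CLASSES = ("Delta", "Epsilon", "Omega", "Theta", "Sigma", "Zeta")
CLASS_LETTERS = {"Delta": "D", "Epsilon": "E", "Omega": "O",
                 "Theta": "T", "Sigma": "S", "Zeta": "Z"}

#: first three letters of each of the 12 sequenced species' epithets,
#: used by the unified GST nomenclature ("D" + code + "GST" + class + number).
SPECIES_CODES = {
    "melanogaster": "mel", "simulans": "sim", "sechellia": "sec",
    "yakuba": "yak", "erecta": "ere", "ananassae": "ana",
    "pseudoobscura": "pse", "persimilis": "per", "willistoni": "wil",
    "virilis": "vir", "mojavensis": "moj", "grimshawi": "gri",
}

_STOP_CODONS = set(standard_dna_table.stop_codons)
_FORWARD_TABLE = dict(standard_dna_table.forward_table)


class GenomeError(ValueError):
    """Raised for malformed sequences, annotations or coordinates."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Genome:
    """A set of scaffolds for one species.

    Sequences are case-normalized to upper and restricted to {A,C,G,T,N}.
    """

    species_tag: str
    scaffolds: dict[str, str]

    def __post_init__(self) -> None:
        norm: dict[str, str] = {}
        for sid, seq in self.scaffolds.items():
            if not seq:
                raise GenomeError(f"scaffold {sid!r} is empty")
            seq = seq.upper()
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise GenomeError(
                    f"scaffold {sid!r} contains illegal characters {sorted(bad)}")
            norm[sid] = seq
        self.scaffolds = norm

    def __getitem__(self, scaffold_id: str) -> str:
        return self.scaffolds[scaffold_id]


@dataclass
class TranscriptModel:
    """An exon-chain CDS annotation (coding part only, stop codon included)."""

    transcript_id: str
    cds_exons: list[tuple[int, int]]
    isoform_tag: str | None = None

    def __post_init__(self) -> None:
        exons = [(int(a), int(b)) for a, b in self.cds_exons]
        if not exons:
            raise GenomeError(f"{self.transcript_id}: no CDS exons")
        exons.sort()
        for (a, b) in exons:
            if b <= a:
                raise GenomeError(f"{self.transcript_id}: empty exon [{a},{b})")
        for (_, b1), (a2, _) in zip(exons, exons[1:]):
            if a2 < b1:
                raise GenomeError(f"{self.transcript_id}: overlapping exons")
        self.cds_exons = exons

    @property
    def cds_length(self) -> int:
        return sum(b - a for a, b in self.cds_exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.cds_exons[0][0], self.cds_exons[-1][1]


@dataclass
class GeneModel:
    gene_id: str
    scaffold_id: str
    strand: str
    transcripts: list[TranscriptModel]
    ortholog_label: str | None = None
    class_label: str = "unknown"

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise GenomeError(f"{self.gene_id}: bad strand {self.strand!r}")
        if not self.transcripts:
            raise GenomeError(f"{self.gene_id}: needs at least one transcript")
        if self.class_label not in GST_CLASSES + ("unknown",):
            raise GenomeError(f"{self.gene_id}: bad class {self.class_label!r}")

    @property
    def span(self) -> tuple[int, int]:
        return (min(t.span[0] for t in self.transcripts),
                max(t.span[1] for t in self.transcripts))

    def validate_against(self, genome: Genome) -> None:
        if self.scaffold_id not in genome.scaffolds:
            raise GenomeError(f"{self.gene_id}: unknown scaffold {self.scaffold_id}")
        length = len(genome[self.scaffold_id])
        for t in self.transcripts:
            for a, b in t.cds_exons:
                if a < 0 or b > length:
                    raise GenomeError(
                        f"{self.gene_id}/{t.transcript_id}: exon [{a},{b}) outside "
                        f"scaffold of length {length}")


@dataclass
class ProteinRecord:
    protein_id: str
    sequence: str

    @property
    def length_aa(self) -> int:
        return len(self.sequence)


@dataclass
class TranslationResult:
    """Protein plus the event flags the curation stages consume."""

    protein: str                      # may contain '*' at internal stops
    length_aa: int                    # excludes a terminal stop
    premature_stops: list[int] = field(default_factory=list)   # codon indices
    ambiguous_codons: list[int] = field(default_factory=list)  # codon indices
    has_terminal_stop: bool = False
    trimmed_nt: int = 0               # trailing nt dropped when len % 3 != 0

    @property
    def coding_complete(self) -> bool:
        return (self.has_terminal_stop and not self.premature_stops
                and self.trimmed_nt == 0)

    @property
    def stop_free(self) -> bool:
        return not self.premature_stops


# ---------------------------------------------------------------------------
# sequence operations
# ---------------------------------------------------------------------------

def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def extract_cds(genome: Genome, gene: GeneModel,
                transcript: TranscriptModel | None = None) -> str:
    """Spliced coding sequence of ``transcript`` in 5'->3' transcript order."""
    t = transcript or gene.transcripts[0]
    scaffold = genome[gene.scaffold_id]
    for a, b in t.cds_exons:
        if a < 0 or b > len(scaffold):
            raise GenomeError(f"{t.transcript_id}: exon [{a},{b}) out of bounds")
    forward = "".join(scaffold[a:b] for a, b in t.cds_exons)
    if gene.strand == "-":
        return reverse_complement(forward)
    return forward


def translate_cds(dna: str, partial: bool = False) -> TranslationResult:
    """Translate with the standard genetic code.

    Codons containing N give 'X' (flagged); internal stops are kept as '*'
    and flagged; a terminal stop is excluded from ``length_aa``.  A length
    not divisible by 3 is an error unless ``partial=True``, in which case the
    trailing remainder is dropped and recorded.
    """
    dna = dna.upper()
    rem = len(dna) % 3
    if rem:
        if not partial:
            raise GenomeError(f"CDS length {len(dna)} not divisible by 3")
        dna = dna[: len(dna) - rem]
    aas: list[str] = []
    premature: list[int] = []
    ambiguous: list[int] = []
    n_codons = len(dna) // 3
    for i in range(n_codons):
        codon = dna[3 * i: 3 * i + 3]
        if "N" in codon:
            aas.append("X")
            ambiguous.append(i)
        elif codon in _STOP_CODONS:
            aas.append("*")
        else:
            aas.append(_FORWARD_TABLE[codon])
    has_terminal = bool(aas) and aas[-1] == "*" and rem == 0
    if has_terminal:
        aas = aas[:-1]
    premature = [i for i, a in enumerate(aas) if a == "*"]
    protein = "".join(aas)
    return TranslationResult(protein=protein, length_aa=len(protein),
                             premature_stops=premature,
                             ambiguous_codons=[i for i in ambiguous
                                               if i < len(protein)],
                             has_terminal_stop=has_terminal, trimmed_nt=rem)


def build_gst_name(species_name: str, class_letter: str, number: int) -> str:
    """Unified GST name, e.g. ("simulans", "T", 4) -> "DsimGSTT4"."""
    species_name = species_name.lower()
    if species_name not in SPECIES_CODES:
        raise GenomeError(f"unknown species {species_name!r}")
    if class_letter not in set(CLASS_LETTERS.values()):
        raise GenomeError(f"unknown GST class letter {class_letter!r}")
    if number <= 0:
        raise GenomeError("GST number must be positive")
    return f"D{SPECIES_CODES[species_name]}GST{class_letter}{number}"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Records keyed by the first whitespace-delimited header token, in order."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise GenomeError(f"duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq)
        if not seq:
            raise GenomeError(f"empty FASTA record {rec.id!r}")
        records[rec.id] = seq
    if not records:
        raise GenomeError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Mapping[str, str], path: str | Path,
                width: int = 60) -> None:
    recs = [SeqRecord(Seq(seq), id=rid, description="")
            for rid, seq in records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_genome(path: str | Path, species_tag: str) -> Genome:
    return Genome(species_tag, {k: v for k, v in read_fasta(path).items()})


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path, genome: Genome | None = None) -> list[GeneModel]:
    """Parse a gene -> mRNA -> CDS GFF3 hierarchy into :class:`GeneModel`\\ s."""
    db = gffutils.create_db(str(path), ":memory:", keep_order=True,
                            merge_strategy="create_unique")
    mrna_ids = {f.id for f in db.features_of_type("mRNA")}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent", [])
        if not parents or not set(parents) & mrna_ids:
            raise GenomeError(f"CDS at {cds.seqid}:{cds.start} has no mRNA parent")
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        transcripts = []
        for mrna in db.children(gene, featuretype="mRNA", order_by="start"):
            exons = []
            strands = {mrna.strand}
            for cds in db.children(mrna, featuretype="CDS", order_by="start"):
                exons.append((cds.start - 1, cds.end))
                strands.add(cds.strand)
            if len(strands) != 1:
                raise GenomeError(f"{mrna.id}: mixed strands within transcript")
            if not exons:
                continue
            attrs = mrna.attributes
            tag = attrs["isoform_tag"][0] if "isoform_tag" in attrs else None
            transcripts.append(TranscriptModel(mrna.id, exons, isoform_tag=tag))
        attrs = gene.attributes
        label = attrs["ortholog_label"][0] if "ortholog_label" in attrs else None
        klass = attrs["class_label"][0] if "class_label" in attrs else "unknown"
        model = GeneModel(gene.id, gene.seqid, gene.strand, transcripts,
                          ortholog_label=label, class_label=klass)
        if genome is not None:
            model.validate_against(genome)
        models.append(model)
    return models


def _attr_str(pairs: list[tuple[str, str]]) -> str:
    return ";".join(f"{k}={v}" for k, v in pairs if v is not None)


def write_gff3(models: Iterable[GeneModel], path: str | Path,
               source: str = "gstcurate",
               extra_gene_attrs: Mapping[str, Mapping[str, str]] | None = None,
               ) -> None:
    """Write models as GFF3 (1-based inclusive), the inverse of read_gff3."""
    extra_gene_attrs = extra_gene_attrs or {}
    lines = ["##gff-version 3"]
    for gene in models:
        a, b = gene.span
        attrs: list[tuple[str, str]] = [("ID", gene.gene_id)]
        if gene.ortholog_label:
            attrs.append(("ortholog_label", gene.ortholog_label))
        if gene.class_label != "unknown":
            attrs.append(("class_label", gene.class_label))
        for k, v in extra_gene_attrs.get(gene.gene_id, {}).items():
            attrs.append((k, v))
        lines.append("\t".join([gene.scaffold_id, source, "gene", str(a + 1),
                                str(b), ".", gene.strand, ".", _attr_str(attrs)]))
        for t in gene.transcripts:
            ta, tb = t.span
            tattrs = [("ID", t.transcript_id), ("Parent", gene.gene_id)]
            if t.isoform_tag:
                tattrs.append(("isoform_tag", t.isoform_tag))
            lines.append("\t".join([gene.scaffold_id, source, "mRNA",
                                    str(ta + 1), str(tb), ".", gene.strand, ".",
                                    _attr_str(tattrs)]))
            # phase: number of nt to skip to reach the next codon start,
            # accumulated in translation (5'->3') order
            exons = t.cds_exons if gene.strand == "+" else t.cds_exons[::-1]
            phases = []
            cum = 0
            for (ea, eb) in exons:
                phases.append((3 - cum % 3) % 3)
                cum += eb - ea
            if gene.strand == "-":
                exons, phases = exons[::-1], phases[::-1]
            for k, ((ea, eb), ph) in enumerate(zip(exons, phases)):
                cattrs = [("ID", f"{t.transcript_id}.cds{k}"),
                          ("Parent", t.transcript_id)]
                lines.append("\t".join([gene.scaffold_id, source, "CDS",
                                        str(ea + 1), str(eb), ".", gene.strand,
                                        str(ph), _attr_str(cattrs)]))
    Path(path).write_text("\n".join(lines) + "\n")


def find_n_runs(seq: str, min_run: int = 5) -> list[tuple[int, int]]:
    """Maximal runs of >= min_run consecutive N characters."""
    return [(m.start(), m.end())
            for m in re.finditer("N{%d,}" % min_run, seq.upper())]
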