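"""Synthetic genomes with a GST-like clustered gene family plus ground truth.

The generator emulates the study design: a template species carries a
six-class family (Delta, Epsilon, Omega, Theta, Sigma, Zeta) laid out in
tandem clusters, one scaffold per class, with coding sequences of 600-800 bp
(the usual GST gene length), 1-6 exons, GT..AG introns, a planted catalytic
anchor motif, and four alternatively spliced genes following the conserved
patterns (alternative first exons for D11/Z2/T3-like genes, alternative
terminal exons for the O2-like gene).  Target species are produced by
JC-symmetric per-site substitution under purifying selection (no nonsense
changes, start/stop/splice dinucleotides frozen), after which annotation
defects and genome rearrangements are injected one at a time, each recorded
in a ground-truth ledger naming the curation category it should provoke.

Every output is a pure function of (spec, seed): one RNG stream consumed in
a fixed order.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .curation import CatalyticAnchor
from .genome import (GeneModel, Genome, GenomeError, TranscriptModel,
                     reverse_complement, translate_cds)
from .splice import IsoformTemplate, TemplateExon, TemplateIsoform
from .synteny import GeneMap, MapEntry

_AA20 = "ARNDCQEGHILKMFPSTWYV"
_STOPS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"

from Bio.Data.CodonTable import standard_dna_table as _tbl

_BACK: dict[str, list[str]] = {}
for _codon, _aa in sorted(_tbl.forward_table.items()):
    _BACK.setdefault(_aa, []).append(_codon)

CLASS_ORDER = ("Delta", "Epsilon", "Omega", "Theta", "Sigma", "Zeta")
_LETTER = {"Delta": "D", "Epsilon": "E", "Omega": "O", "Theta": "T",
           "Sigma": "S", "Zeta": "Z"}

DEFECT_KINDS = ("START_SHIFT_UP", "START_SHIFT_DOWN", "EXONIFY_INTRON",
                "INTRONIFY_EXON", "DELETE_NT", "INSERT_NT", "PREMATURE_STOP",
                "N_RUN", "TRUNCATE")

EXPECTED_CATEGORY = {
    "START_SHIFT_UP": "ANNOTATION_ERROR",
    "START_SHIFT_DOWN": "ANNOTATION_ERROR",
    "EXONIFY_INTRON": "ANNOTATION_ERROR",
    "INTRONIFY_EXON": "ANNOTATION_ERROR",
    "DELETE_NT": "AMBIGUOUS_INDEL",
    "INSERT_NT": "AMBIGUOUS_INDEL",
    "PREMATURE_STOP": "PSEUDOGENE",
    "N_RUN": "SEQUENCING_ERROR",
    "TRUNCATE": "PSEUDOGENE",
}


@dataclass
class FamilySpec:
    genes_per_cluster: tuple[int, ...] = (11, 14, 4, 4, 1, 2)  # D,E,O,T,S,Z
    exon_count_range: tuple[int, int] = (1, 6)
    cds_len_range: tuple[int, int] = (600, 800)    # incl. terminal stop, bp
    intron_len_range: tuple[int, int] = (50, 120)
    spacer_range: tuple[int, int] = (200, 500)
    utr5_len: int = 60
    utr3_len: int = 80
    anchor_offset: int = 8          # catalytic Ser-His-Ala-Ile planted here
    spliced: dict = field(default_factory=lambda: {
        "GSTD11": ("alt_first", 2),
        "GSTZ2": ("alt_first", 3),
        "GSTT3": ("alt_first", 2),
        "GSTO2": ("alt_last", 2),
    })
    seed: int = 0

    def __post_init__(self):
        for lo, hi in (self.exon_count_range, self.cds_len_range,
                       self.intron_len_range, self.spacer_range):
            if lo <= 0 or hi < lo:
                raise GenomeError("spec ranges must be positive and ordered")


@dataclass
class FamilyBundle:
    species_tag: str
    genome: Genome
    models: list[GeneModel]
    proteins: dict[str, str]                 # ortholog label -> protein
    anchors: dict[str, CatalyticAnchor]
    isoform_templates: dict[str, IsoformTemplate]
    spec: FamilySpec | None = None

    def model_by_label(self, label: str) -> GeneModel:
        for m in self.models:
            if m.ortholog_label == label:
                return m
        raise KeyError(label)

    def gene_map(self) -> GeneMap:
        return GeneMap(self.species_tag,
                       [MapEntry(m.ortholog_label or m.gene_id, m.scaffold_id,
                                 m.span[0], m.strand) for m in self.models])


@dataclass
class GroundTruthRecord:
    gene_id: str
    kind: str
    expected_category: str
    params: dict = field(default_factory=dict)
    inverse: dict = field(default_factory=dict)


@dataclass
class RearrangementRecord:
    kind: str
    labels: list[str]
    params: dict = field(default_factory=dict)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, n))


def _random_protein(rng: np.random.Generator, n_aa: int,
                    anchor_offset: int | None = None) -> str:
    aas = ["M"] + [_AA20[i] for i in rng.integers(0, 20, n_aa - 1)]
    if anchor_offset is not None and anchor_offset + 4 <= n_aa:
        aas[anchor_offset:anchor_offset + 4] = list("SHAI")
    return "".join(aas)


def back_translate(rng: np.random.Generator, protein: str,
                   stop: bool = True) -> str:
    codons = [_BACK[a][rng.integers(0, len(_BACK[a]))] for a in protein]
    if stop:
        codons.append(_STOPS[rng.integers(0, 3)])
    return "".join(codons)


def _stop_free_filler(rng: np.random.Generator, n_codons: int,
                      forbid_atg: bool = True) -> str:
    out = []
    while len(out) < n_codons:
        c = _random_dna(rng, 3)
        if c in _STOPS or (forbid_atg and c == "ATG"):
            continue
        out.append(c)
    return "".join(out)


def _intron(rng: np.random.Generator, length: int) -> str:
    if length < 6:
        raise GenomeError("intron too short")
    return "GT" + _random_dna(rng, length - 4) + "AG"


def _split_exons(rng: np.random.Generator, cds_len: int, n_exons: int,
                 min_exon: int = 30) -> list[int]:
    """Exon lengths summing to cds_len, each >= min_exon."""
    if n_exons == 1:
        return [cds_len]
    for _ in range(200):
        cuts = sorted(rng.integers(min_exon, cds_len - min_exon + 1,
                                   n_exons - 1))
        lens = np.diff([0] + list(cuts) + [cds_len])
        if (lens >= min_exon).all():
            return [int(x) for x in lens]
    # fall back to even split
    base = cds_len // n_exons
    lens = [base] * n_exons
    lens[-1] += cds_len - base * n_exons
    return lens


# ---------------------------------------------------------------------------
# template family generation
# ---------------------------------------------------------------------------

def _build_plain_gene(rng, spec: FamilySpec):
    """Returns (region, local exon intervals, protein)."""
    lo, hi = spec.cds_len_range
    aa_total = int(rng.integers(lo // 3, hi // 3 + 1))   # codons incl. stop
    cds_len = 3 * aa_total
    protein = _random_protein(rng, aa_total - 1, spec.anchor_offset)
    cds = back_translate(rng, protein)
    n_exons = int(rng.integers(spec.exon_count_range[0],
                               spec.exon_count_range[1] + 1))
    lens = _split_exons(rng, cds_len, n_exons)
    parts = []
    exons = []
    pos = 0
    consumed = 0
    for k, el in enumerate(lens):
        exons.append((pos, pos + el))
        parts.append(cds[consumed:consumed + el])
        consumed += el
        pos += el
        if k < n_exons - 1:
            ilen = int(rng.integers(*spec.intron_len_range))
            parts.append(_intron(rng, ilen))
            pos += ilen
    return "".join(parts), exons, protein


def _build_spliced_gene(rng, spec: FamilySpec, pattern: str, k: int):
    """Returns (region, per-isoform local exon chains, isoform template parts).

    alt_first: k isoforms with distinct first exons, shared tail exons.
    alt_last: shared head, two alternative terminal exons.
    """
    utr5 = _random_dna(rng, spec.utr5_len)
    utr3 = _random_dna(rng, spec.utr3_len)
    region_parts = [utr5]
    pos = len(utr5)
    isoform_exons: list[list[tuple[int, int]]] = []
    isoform_info = []
    if pattern == "alt_first":
        heads = []
        for i in range(k):
            h_aa = int(rng.integers(20, 36))
            heads.append(_random_protein(rng, h_aa, spec.anchor_offset))
        tail_aa = int(rng.integers(150, 181))
        tail_prot = "".join(_AA20[i] for i in rng.integers(0, 20, tail_aa))
        tail_cds = back_translate(rng, tail_prot, stop=True)
        head_spans = []
        for i, hp in enumerate(heads):
            hcds = back_translate(rng, hp, stop=False)
            region_parts.append(hcds)
            head_spans.append((pos, pos + len(hcds)))
            pos += len(hcds)
            ilen = int(rng.integers(max(spec.intron_len_range[0], 45),
                                    spec.intron_len_range[1] + 1))
            region_parts.append(_intron(rng, ilen))
            pos += ilen
        n_shared = 2
        lens = _split_exons(rng, len(tail_cds), n_shared)
        shared_spans = []
        consumed = 0
        for k2, el in enumerate(lens):
            region_parts.append(tail_cds[consumed:consumed + el])
            shared_spans.append((pos, pos + el))
            consumed += el
            pos += el
            if k2 < n_shared - 1:
                ilen = int(rng.integers(max(spec.intron_len_range[0], 45),
                                        spec.intron_len_range[1] + 1))
                region_parts.append(_intron(rng, ilen))
                pos += ilen
        region_parts.append(utr3)
        region_so_far = "".join(region_parts)
        for i in range(k):
            chain = [head_spans[i]] + shared_spans
            isoform_exons.append(chain)
            roles = ["unique"] + ["shared"] * n_shared
            # each variant's 5'UTR is the flank directly upstream of its
            # own first exon (for later variants that is intron sequence
            # of the earlier ones, as in the curated structures)
            u5 = region_so_far[max(0, head_spans[i][0] - spec.utr5_len):
                               head_spans[i][0]]
            isoform_info.append((chr(ord("A") + i), roles, u5, utr3))
    elif pattern == "alt_last":
        head_aa = int(rng.integers(120, 151))
        head_prot = _random_protein(rng, head_aa, spec.anchor_offset)
        head_cds = back_translate(rng, head_prot, stop=False)
        region_parts.append(head_cds)
        head_span = (pos, pos + len(head_cds))
        pos += len(head_cds)
        tails = []
        for i in range(2):
            ilen = int(rng.integers(max(spec.intron_len_range[0], 45),
                                    spec.intron_len_range[1] + 1))
            region_parts.append(_intron(rng, ilen))
            pos += ilen
            t_aa = int(rng.integers(55, 86))
            t_prot = "".join(_AA20[j] for j in rng.integers(0, 20, t_aa))
            t_cds = back_translate(rng, t_prot, stop=True)
            region_parts.append(t_cds)
            tails.append((pos, pos + len(t_cds)))
            pos += len(t_cds)
        region_parts.append(utr3)
        region_so_far = "".join(region_parts)
        for i in range(2):
            isoform_exons.append([head_span, tails[i]])
            u3 = region_so_far[tails[i][1]: tails[i][1] + spec.utr3_len]
            isoform_info.append((chr(ord("A") + i), ["shared", "unique"],
                                 utr5, u3))
    else:
        raise GenomeError(f"unknown splice pattern {pattern!r}")
    region = "".join(region_parts)
    return region, isoform_exons, isoform_info


def generate_family(spec: FamilySpec,
                    species_tag: str = "Dmel") -> FamilyBundle:
    """Template genome + models + proteins + anchors + isoform templates."""
    rng = np.random.default_rng(spec.seed)
    scaffolds: dict[str, str] = {}
    models: list[GeneModel] = []
    proteins: dict[str, str] = {}
    anchors: dict[str, CatalyticAnchor] = {}
    iso_templates: dict[str, IsoformTemplate] = {}
    for ci, klass in enumerate(CLASS_ORDER):
        if ci >= len(spec.genes_per_cluster):
            break
        n_genes = spec.genes_per_cluster[ci]
        letter = _LETTER[klass]
        scaffold_id = f"scaffold_{letter}"
        parts: list[str] = []
        pos = 0
        for gi in range(1, n_genes + 1):
            label = f"GST{letter}{gi}"
            spacer = _random_dna(rng, int(rng.integers(*spec.spacer_range)))
            parts.append(spacer)
            pos += len(spacer)
            gene_id = f"{species_tag}_{label}"
            if label in spec.spliced:
                pattern, k = spec.spliced[label]
                region, chains, info = _build_spliced_gene(
                    rng, spec, pattern, k)
                transcripts = []
                iso_list = []
                for chain, (tag, roles, utr5, utr3) in zip(chains, info):
                    g_exons = [(pos + a, pos + b) for a, b in chain]
                    transcripts.append(TranscriptModel(
                        f"{gene_id}.{tag}", g_exons, isoform_tag=tag))
                    exseqs = [TemplateExon(region[a:b], role)
                              for (a, b), role in zip(chain, roles)]
                    iso_list.append(TemplateIsoform(tag, exseqs,
                                                    utr5=utr5, utr3=utr3))
                model = GeneModel(gene_id, scaffold_id, "+", transcripts,
                                  ortholog_label=label, class_label=klass)
                iso_templates[label] = IsoformTemplate(label, iso_list)
                prot = iso_list[0].protein
            else:
                region, exons, prot = _build_plain_gene(rng, spec)
                strand = "+" if rng.random() < 0.5 else "-"
                if strand == "-":
                    L = len(region)
                    region = reverse_complement(region)
                    exons = sorted((L - b, L - a) for a, b in exons)
                g_exons = [(pos + a, pos + b) for a, b in exons]
                model = GeneModel(gene_id, scaffold_id, strand,
                                  [TranscriptModel(f"{gene_id}.t1", g_exons)],
                                  ortholog_label=label, class_label=klass)
            parts.append(region)
            pos += len(region)
            models.append(model)
            proteins[label] = prot
            anchors[label] = CatalyticAnchor(
                label, tuple(range(spec.anchor_offset,
                                   min(spec.anchor_offset + 4, len(prot)))))
        parts.append(_random_dna(rng, int(rng.integers(*spec.spacer_range))))
        scaffolds[scaffold_id] = "".join(parts)
    genome = Genome(species_tag, scaffolds)
    for m in models:
        m.validate_against(genome)
    return FamilyBundle(species_tag, genome, models, proteins, anchors,
                        iso_templates, spec)


# ---------------------------------------------------------------------------
# divergence
# ---------------------------------------------------------------------------

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _cds_positions(gene: GeneModel, t: TranscriptModel) -> list[int]:
    """Genomic positions of the CDS in 5'->3' translation order."""
    pos = [p for a, b in t.cds_exons for p in range(a, b)]
    return pos[::-1] if gene.strand == "-" else pos


def evolve_target(template: FamilyBundle, sub_rate: float, seed: int,
                  species_tag: str = "Dsim") -> FamilyBundle:
    """JC-symmetric substitutions at ``sub_rate`` under purifying selection.

    Sites whose substitution would create an in-frame stop codon within an
    annotated CDS are left unchanged, as are start/stop codons and the
    GT..AG intron dinucleotides; annotation coordinates carry over.
    """
    if not 0 <= sub_rate < 0.5:
        raise GenomeError("substitution rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    new_scaffolds: dict[str, str] = {}
    # maps per scaffold: position -> (codon positions in 5'->3' order, strand)
    codon_map: dict[str, dict[int, tuple[tuple[int, int, int], str]]] = {}
    protected: dict[str, set[int]] = {}
    for m in template.models:
        cm = codon_map.setdefault(m.scaffold_id, {})
        prot = protected.setdefault(m.scaffold_id, set())
        for t in m.transcripts:
            pos = _cds_positions(m, t)
            prot.update(pos[:3])
            prot.update(pos[-3:])
            for c in range(len(pos) // 3):
                trip = tuple(pos[3 * c: 3 * c + 3])
                for p in trip:
                    cm[p] = (trip, m.strand)
            exons = t.cds_exons
            for (_, b1), (a2, _) in zip(exons, exons[1:]):
                prot.update(range(b1, b1 + 2))       # donor (oriented GT/AC)
                prot.update(range(a2 - 2, a2))       # acceptor
    for sid in sorted(template.genome.scaffolds):
        seq = list(template.genome.scaffolds[sid])
        cm = codon_map.get(sid, {})
        prot = protected.get(sid, set())
        hits = np.nonzero(rng.random(len(seq)) < sub_rate)[0]
        choices = rng.integers(0, 3, len(hits))
        for idx, ch in zip(hits, choices):
            idx = int(idx)
            if idx in prot:
                continue
            old = seq[idx]
            if old == "N":
                continue
            alt = [b for b in _BASES if b != old][int(ch)]
            if idx in cm:
                trip, strand = cm[idx]
                bases = [alt if p == idx else seq[p] for p in trip]
                codon = "".join(bases)
                if strand == "-":
                    codon = "".join(_COMP[b] for b in codon)
                if codon in _STOPS:
                    continue
            seq[idx] = alt
        new_scaffolds[sid] = "".join(seq)
    models = copy.deepcopy(template.models)
    for m in models:
        m.gene_id = m.gene_id.replace(template.species_tag, species_tag, 1)
        for t in m.transcripts:
            t.transcript_id = t.transcript_id.replace(
                template.species_tag, species_tag, 1)
    genome = Genome(species_tag, new_scaffolds)
    return FamilyBundle(species_tag, genome, models,
                        dict(template.proteins), dict(template.anchors),
                        dict(template.isoform_templates), template.spec)


# ---------------------------------------------------------------------------
# oriented editing helpers
# ---------------------------------------------------------------------------

class _Editor:
    """Edit one gene's scaffold in gene-oriented coordinates."""

    def __init__(self, bundle: FamilyBundle, gene: GeneModel):
        self.bundle = bundle
        self.gene = gene
        self.t = gene.transcripts[0]
        self.scaffold = bundle.genome.scaffolds[gene.scaffold_id]
        self.L = len(self.scaffold)

    @property
    def locus(self) -> str:
        s = self.scaffold
        return reverse_complement(s) if self.gene.strand == "-" else s

    @property
    def exons(self) -> list[tuple[int, int]]:
        if self.gene.strand == "+":
            return list(self.t.cds_exons)
        return sorted((self.L - b, self.L - a) for a, b in self.t.cds_exons)

    def set_exons(self, oriented: Sequence[tuple[int, int]]) -> None:
        if self.gene.strand == "+":
            new = sorted((int(a), int(b)) for a, b in oriented)
        else:
            new = sorted((self.L - b, self.L - a) for a, b in oriented)
        self.t.cds_exons = new

    def write(self, a: int, b: int, seq: str) -> None:
        """Replace oriented [a, b) with same-length oriented sequence."""
        if len(seq) != b - a:
            raise GenomeError("replacement length mismatch")
        if self.gene.strand == "+":
            g0, g1, frag = a, b, seq
        else:
            g0, g1, frag = self.L - b, self.L - a, reverse_complement(seq)
        s = self.bundle.genome.scaffolds[self.gene.scaffold_id]
        self.bundle.genome.scaffolds[self.gene.scaffold_id] = (
            s[:g0] + frag + s[g1:])
        self.scaffold = self.bundle.genome.scaffolds[self.gene.scaffold_id]

    def cds_index_to_oriented(self, idx: int) -> int:
        run = 0
        for a, b in self.exons:
            if idx < run + (b - a):
                return a + (idx - run)
            run += b - a
        raise GenomeError("CDS index out of range")


def _shift_scaffold_coords(bundle: FamilyBundle, scaffold_id: str,
                           genomic_pos: int, delta: int) -> None:
    for m in bundle.models:
        if m.scaffold_id != scaffold_id:
            continue
        for t in m.transcripts:
            t.cds_exons = [(a + delta if a > genomic_pos else a,
                            b + delta if b > genomic_pos else b)
                           for a, b in t.cds_exons]


# ---------------------------------------------------------------------------
# defect injection
# ---------------------------------------------------------------------------

def inject_error(bundle: FamilyBundle, gene_id: str, kind: str,
                 rng: np.random.Generator,
                 params: dict | None = None) -> GroundTruthRecord:
    """Apply one annotation/sequence defect; mutates ``bundle`` in place."""
    if kind not in DEFECT_KINDS:
        raise GenomeError(f"unknown defect kind {kind!r}")
    gene = next(m for m in bundle.models if m.gene_id == gene_id)
    ed = _Editor(bundle, gene)
    exons = ed.exons
    cds_len = sum(b - a for a, b in exons)
    p = dict(params or {})
    inverse: dict = {}

    if kind == "START_SHIFT_UP":
        # annotation truncated: true start lies n nt upstream of new start
        e0 = exons[0]
        max_n = min(150, e0[1] - e0[0] - 45)
        if max_n < 45:
            raise GenomeError(f"{gene_id}: first exon too short for shift")
        n = p.get("n") or 3 * int(rng.integers(15, max_n // 3 + 1))
        ed.set_exons([(e0[0] + n, e0[1])] + exons[1:])
        p["n"], p["direction"] = n, "upstream"
        inverse["restore_start"] = e0[0]
    elif kind == "START_SHIFT_DOWN":
        # annotation extended upstream over a planted stop-free ATG segment
        e0 = exons[0]
        n = p.get("n") or 3 * int(rng.integers(13, 31))
        if e0[0] - n < 10:
            raise GenomeError(f"{gene_id}: no room upstream")
        filler = "ATG" + _stop_free_filler(rng, n // 3 - 1)
        inverse["overwritten"] = ed.locus[e0[0] - n:e0[0]]
        ed.write(e0[0] - n, e0[0], filler)
        exons = ed.exons
        ed.set_exons([(e0[0] - n, e0[1])] + exons[1:])
        p["n"], p["direction"] = n, "downstream"
        inverse["restore_start"] = e0[0]
    elif kind == "EXONIFY_INTRON":
        if len(exons) < 2:
            raise GenomeError(f"{gene_id}: no intron to exonify")
        introns = [(i, exons[i][1], exons[i + 1][0])
                   for i in range(len(exons) - 1)]
        introns = [iv for iv in introns if iv[2] - iv[1] >= 62]
        if not introns:
            raise GenomeError(f"{gene_id}: introns too short")
        i, ia, ib = introns[int(rng.integers(0, len(introns)))]
        max_fake = min(60, ((ib - ia - 20) // 3) * 3)
        fake = p.get("length") or 3 * int(rng.integers(10, max_fake // 3 + 1))
        u = ia + 8 + int(rng.integers(0, ib - ia - fake - 16 + 1))
        new = exons[:i + 1] + [(u, u + fake)] + exons[i + 1:]
        ed.set_exons(new)
        p.update(intron_index=i, start=u, length=fake)
        inverse["drop_exon_index"] = i + 1
    elif kind == "INTRONIFY_EXON":
        wide = [(i, a, b) for i, (a, b) in enumerate(exons) if b - a >= 110]
        if not wide:
            raise GenomeError(f"{gene_id}: exons too short to intronify")
        i, a, b = wide[int(rng.integers(0, len(wide)))]
        f = int(rng.integers(40, min(80, b - a - 50) + 1))
        u = a + 25 + int(rng.integers(0, (b - 25 - f) - (a + 25) + 1))
        new = exons[:i] + [(a, u), (u + f, b)] + exons[i + 1:]
        ed.set_exons(new)
        p.update(exon_index=i, start=u, length=f)
        inverse["merge_exon_index"] = i
    elif kind in ("DELETE_NT", "INSERT_NT"):
        widths = [(i, a, b) for i, (a, b) in enumerate(exons) if b - a >= 60]
        i, a, b = widths[int(rng.integers(0, len(widths)))] if widths else \
            (0, *exons[0])
        opos = a + 20 + int(rng.integers(0, max(1, (b - 20) - (a + 20))))
        gpos = opos if gene.strand == "+" else ed.L - 1 - opos
        sid = gene.scaffold_id
        s = bundle.genome.scaffolds[sid]
        if kind == "DELETE_NT":
            inverse["base"] = s[gpos]
            inverse["genomic_pos"] = gpos
            bundle.genome.scaffolds[sid] = s[:gpos] + s[gpos + 1:]
            _shift_scaffold_coords(bundle, sid, gpos, -1)
        else:
            base = _BASES[int(rng.integers(0, 4))]
            bundle.genome.scaffolds[sid] = s[:gpos] + base + s[gpos:]
            _shift_scaffold_coords(bundle, sid, gpos, +1)
            inverse["genomic_pos"] = gpos
            inverse["base"] = base
        p.update(oriented_pos=opos)
    elif kind == "PREMATURE_STOP":
        n_codons = cds_len // 3
        j = p.get("codon") or int(rng.integers(int(0.15 * n_codons),
                                               int(0.50 * n_codons)))
        positions = [ed.cds_index_to_oriented(3 * j + k) for k in range(3)]
        old = "".join(ed.locus[q] for q in positions)
        for q, base in zip(positions, "TAA"):
            ed.write(q, q + 1, base)
        p["codon"] = j
        inverse["positions"] = positions
        inverse["bases"] = old
    elif kind == "N_RUN":
        nlen = p.get("length") or int(rng.integers(15, 41))
        wide = [(a, b) for a, b in exons if b - a >= nlen + 20]
        if not wide:
            raise GenomeError(f"{gene_id}: exons too short for N run")
        a, b = wide[int(rng.integers(0, len(wide)))]
        u = a + 10 + int(rng.integers(0, (b - 10 - nlen) - (a + 10) + 1))
        inverse["overwritten"] = ed.locus[u:u + nlen]
        inverse["start"] = u
        ed.write(u, u + nlen, "N" * nlen)
        p.update(start=u, length=nlen)
    elif kind == "TRUNCATE":
        frac = p.get("frac", 0.45)
        keep = 3 * int(frac * cds_len / 3)
        new_exons = []
        run = 0
        cut = None
        for a, b in exons:
            if run + (b - a) <= keep:
                new_exons.append((a, b))
                run += b - a
            else:
                cut = a + (keep - run)
                if cut > a:
                    new_exons.append((a, cut))
                break
        end = exons[-1][1]
        if cut is None or cut >= end:
            raise GenomeError(f"{gene_id}: truncation cut failed")
        junk = _random_dna(rng, end - cut)
        inverse["overwritten"] = ed.locus[cut:end]
        inverse["start"] = cut
        ed.write(cut, end, junk)
        ed.set_exons(new_exons)
        p["frac"] = frac
    return GroundTruthRecord(gene_id=gene_id, kind=kind,
                             expected_category=EXPECTED_CATEGORY[kind],
                             params=p, inverse=inverse)


def undo_error(bundle: FamilyBundle, record: GroundTruthRecord) -> None:
    """Apply the ledger's inverse edit (round-trip testing support)."""
    gene = next(m for m in bundle.models if m.gene_id == record.gene_id)
    ed = _Editor(bundle, gene)
    inv = record.inverse
    kind = record.kind
    if kind == "START_SHIFT_UP":
        exons = ed.exons
        ed.set_exons([(inv["restore_start"], exons[0][1])] + exons[1:])
    elif kind == "START_SHIFT_DOWN":
        exons = ed.exons
        s = inv["restore_start"]
        ed.write(exons[0][0], s, inv["overwritten"])
        ed.set_exons([(s, exons[0][1])] + exons[1:])
    elif kind == "EXONIFY_INTRON":
        exons = ed.exons
        del exons[inv["drop_exon_index"]]
        ed.set_exons(exons)
    elif kind == "INTRONIFY_EXON":
        exons = ed.exons
        i = inv["merge_exon_index"]
        exons[i] = (exons[i][0], exons[i + 1][1])
        del exons[i + 1]
        ed.set_exons(exons)
    elif kind == "DELETE_NT":
        sid = gene.scaffold_id
        s = bundle.genome.scaffolds[sid]
        g = inv["genomic_pos"]
        bundle.genome.scaffolds[sid] = s[:g] + inv["base"] + s[g:]
        _shift_scaffold_coords(bundle, sid, g, +1)
    elif kind == "INSERT_NT":
        sid = gene.scaffold_id
        s = bundle.genome.scaffolds[sid]
        g = inv["genomic_pos"]
        bundle.genome.scaffolds[sid] = s[:g] + s[g + 1:]
        _shift_scaffold_coords(bundle, sid, g, -1)
    elif kind == "PREMATURE_STOP":
        for q, base in zip(inv["positions"], inv["bases"]):
            ed.write(q, q + 1, base)
    elif kind in ("N_RUN", "TRUNCATE"):
        u = inv["start"]
        ed.write(u, u + len(inv["overwritten"]), inv["overwritten"])
        if kind == "TRUNCATE":
            raise GenomeError("TRUNCATE annotation inverse not recorded")


# ---------------------------------------------------------------------------
# rearrangement injection (on gene maps)
# ---------------------------------------------------------------------------

def inject_rearrangement(gmap: GeneMap, kind: str,
                         rng: np.random.Generator,
                         params: dict | None = None
                         ) -> tuple[GeneMap, RearrangementRecord]:
    """INVERT_BLOCK / TRANSPOSE_GENE / DISPERSE_CLUSTER on an ordered map."""
    p = dict(params or {})
    entries = list(gmap.entries)
    n = len(entries)
    if kind == "INVERT_BLOCK":
        i = p.get("i", int(rng.integers(0, n - 1)))
        j = p.get("j", min(n, i + 2 + int(rng.integers(0, 3))))
        block = entries[i:j]
        flipped = [MapEntry(e.label, e.scaffold_id, 0,
                            "-" if e.strand == "+" else "+")
                   for e in reversed(block)]
        entries[i:j] = flipped
        labels = [e.label for e in block]
        p.update(i=i, j=j)
    elif kind == "TRANSPOSE_GENE":
        i = p.get("i", int(rng.integers(0, n)))
        moved = entries.pop(i)
        j = p.get("to")
        if j is None:
            j = int(rng.integers(0, n - 1))
            while abs(j - i) < 2:
                j = int(rng.integers(0, n - 1))
        entries.insert(j, moved)
        labels = [moved.label]
        p.update(i=i, to=j)
    elif kind == "DISPERSE_CLUSTER":
        at = p.get("at", n // 2)
        labels = [e.label for e in entries[at:]]
        entries = entries[:at] + [
            MapEntry(e.label, e.scaffold_id + "_frag", 0, e.strand)
            for e in entries[at:]]
        p.update(at=at)
    else:
        raise GenomeError(f"unknown rearrangement kind {kind!r}")
    rebuilt = [MapEntry(e.label, e.scaffold_id, 1000 * (k + 1), e.strand)
               for k, e in enumerate(entries)]
    return (GeneMap(gmap.species_tag, rebuilt),
            RearrangementRecord(kind, labels, p))


# ---------------------------------------------------------------------------
# defect panels
# ---------------------------------------------------------------------------

def _compatible(kind: str, gene: GeneModel) -> bool:
    t = gene.transcripts[0]
    exons = t.cds_exons
    if kind == "EXONIFY_INTRON":
        return len(exons) >= 2 and any(
            b2 - a1 >= 62 for (_, a1), (b2, _) in
            [((0, e1[1]), (e2[0], 0)) for e1, e2 in zip(exons, exons[1:])])
    if kind == "INTRONIFY_EXON":
        return any(b - a >= 110 for a, b in exons)
    if kind == "START_SHIFT_UP":
        first = exons[0] if gene.strand == "+" else exons[-1]
        return first[1] - first[0] >= 90
    if kind == "N_RUN":
        return any(b - a >= 61 for a, b in exons)
    return True


def build_defect_panel(n_genes: int = 200, sub_rate: float = 0.05,
                       seed: int = 0
                       ) -> tuple[FamilyBundle, FamilyBundle,
                                  list[GroundTruthRecord]]:
    """Template + diverged target with one injected defect per gene."""
    per = n_genes // 6
    clusters = [per] * 6
    for i in range(n_genes - 6 * per):
        clusters[i] += 1
    spec = FamilySpec(genes_per_cluster=tuple(clusters), spliced={},
                      seed=seed)
    template = generate_family(spec)
    target = evolve_target(template, sub_rate, seed + 1)
    rng = np.random.default_rng(seed + 2)
    ledger: list[GroundTruthRecord] = []
    ki = 0
    for gene in target.models:
        for attempt in range(len(DEFECT_KINDS)):
            kind = DEFECT_KINDS[(ki + attempt) % len(DEFECT_KINDS)]
            if not _compatible(kind, gene):
                continue
            try:
                rec = inject_error(target, gene.gene_id, kind, rng)
            except GenomeError:
                continue
            ledger.append(rec)
            ki += attempt + 1
            break
        else:
            raise GenomeError(f"no compatible defect for {gene.gene_id}")
    return template, target, ledger


def ledger_to_json(ledger: Sequence[GroundTruthRecord],
                   path: str | Path) -> None:
    Path(path).write_text(json.dumps([asdict(r) for r in ledger], indent=1))


# ---------------------------------------------------------------------------
# worked-example loci (the curated cases with printed sizes)
# ---------------------------------------------------------------------------

def make_start_rescue_case(annotated_len: int, shift: int, direction: str,
                           seed: int = 0
                           ) -> tuple[str, list[tuple[int, int]], str]:
    """Single-exon locus whose true ATG lies ``shift`` nt away.

    direction 'upstream': annotated CDS of ``annotated_len`` nt whose true
    start is ``shift`` nt upstream (in-frame, contiguous coding).
    direction 'downstream': annotated CDS of ``annotated_len`` nt whose
    correct start is the ATG ``shift`` nt into the annotation.
    Returns (locus, annotated exons, template protein).
    """
    rng = np.random.default_rng(seed)
    if direction == "upstream":
        true_len = annotated_len + shift
    elif direction == "downstream":
        true_len = annotated_len - shift
    else:
        raise GenomeError("direction must be 'upstream' or 'downstream'")
    if true_len % 3 or annotated_len % 3 or shift % 3:
        raise GenomeError("lengths and shift must be codon multiples")
    protein = _random_protein(rng, true_len // 3 - 1, anchor_offset=8)
    cds = back_translate(rng, protein)
    off = 360
    if direction == "upstream":
        locus = (_random_dna(rng, off) + cds + _random_dna(rng, 120))
        exons = [(off + shift, off + true_len)]
    else:
        prefix = "ATG" + _stop_free_filler(rng, shift // 3 - 1)
        locus = (_random_dna(rng, off) + prefix + cds
                 + _random_dna(rng, 120))
        exons = [(off, off + annotated_len)]
    return locus, exons, protein


def make_exon_reassignment_case(true_len: int = 714, seed: int = 0,
                                fake_lens: tuple[int, int] = (45, 30)
                                ) -> tuple[str, list[tuple[int, int]], str]:
    """Six-exon annotation whose exons 2-3 are really intron sequence.

    The true gene has 4 coding exons; two in-frame, stop-free fake exons are
    annotated inside intron 1.  Dropping both restores a ``true_len`` nt CDS.
    Returns (locus, annotated exons, template protein).
    """
    rng = np.random.default_rng(seed)
    if true_len % 3:
        raise GenomeError("true_len must be a codon multiple")
    protein = _random_protein(rng, true_len // 3 - 1, anchor_offset=8)
    cds = back_translate(rng, protein)
    lens = _split_exons(rng, true_len, 4)
    off = 250
    parts = [_random_dna(rng, off)]
    pos = off
    exon_coords = []
    consumed = 0
    # exon 1, then a long intron hosting the two fake exons
    e1 = lens[0]
    parts.append(cds[:e1]); exon_coords.append((pos, pos + e1))
    pos += e1; consumed += e1
    fake_total = sum(fake_lens)
    pad = 30
    intron_len = fake_total + 4 * pad
    intron = list(_intron(rng, intron_len))
    # plant stop-free fake exon sequence (in frame of the upstream CDS)
    fakes = []
    at = pad
    for fl in fake_lens:
        frag = _stop_free_filler(rng, fl // 3, forbid_atg=False)
        intron[at:at + fl] = list(frag)
        fakes.append((pos + at, pos + at + fl))
        at += fl + pad
    parts.append("".join(intron))
    pos += intron_len
    exon_coords.extend(fakes)
    for k, el in enumerate(lens[1:]):
        parts.append(cds[consumed:consumed + el])
        exon_coords.append((pos, pos + el))
        consumed += el
        pos += el
        if k < 2:
            ilen = 70
            parts.append(_intron(rng, ilen))
            pos += ilen
    parts.append(_random_dna(rng, 150))
    return "".join(parts), exon_coords, protein


def make_intron_start_case(true_len: int = 663, bogus_first_exon: int = 534,
                           hidden_head: int = 15, seed: int = 0
                           ) -> tuple[str, list[tuple[int, int]], str]:
    """Two-exon annotation whose real gene is one exon starting in 'intron 1'.

    The true single-exon CDS of ``true_len`` nt starts ``hidden_head`` nt
    before the annotated second exon (its ATG and first codons lie in the
    annotated intron); the annotated first exon is upstream junk.
    Returns (locus, annotated exons, template protein).
    """
    rng = np.random.default_rng(seed)
    if true_len % 3 or hidden_head % 3 or bogus_first_exon % 3:
        raise GenomeError("lengths must be codon multiples")
    protein = _random_protein(rng, true_len // 3 - 1, anchor_offset=8)
    cds = back_translate(rng, protein)
    off = 200
    junk_exon_len = bogus_first_exon
    intron_gap = 80                 # junk between bogus exon and true ATG
    locus = (_random_dna(rng, off)
             + _random_dna(rng, junk_exon_len)
             + _random_dna(rng, intron_gap)
             + cds
             + _random_dna(rng, 150))
    e1 = (off, off + junk_exon_len)
    true_start = off + junk_exon_len + intron_gap
    e2 = (true_start + hidden_head, true_start + true_len)
    return locus, [e1, e2], protein


def make_readthrough_case(true_len: int = 678, tail: int = 45, seed: int = 0
                          ) -> tuple[str, list[tuple[int, int]], str]:
    """Annotation missing the last ``tail`` nt (incl. stop) of the CDS.

    The stop codon sits ``tail`` nt into the annotated 'intron'; extending
    the terminal exon reads through to it.
    """
    rng = np.random.default_rng(seed)
    protein = _random_protein(rng, true_len // 3 - 1, anchor_offset=8)
    cds = back_translate(rng, protein)
    lens = _split_exons(rng, true_len, 2)
    if lens[1] <= tail + 30:
        lens = [true_len - (tail + 60), tail + 60]
    off = 200
    i1 = _intron(rng, 80)
    locus = (_random_dna(rng, off) + cds[:lens[0]] + i1 + cds[lens[0]:]
             + _random_dna(rng, 150))
    e1 = (off, off + lens[0])
    s2 = off + lens[0] + len(i1)
    e2 = (s2, s2 + lens[1] - tail)
    return locus, [e1, e2], protein
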