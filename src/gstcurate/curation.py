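"""Template-guided correction and classification of target gene models.

Each target gene is compared against its reference-species ortholog
("template") protein and passed through a staged repair procedure:

1. N-run detection: unresolved sequencing (runs of N) overlapping the
   projected CDS takes precedence — the verdict is SEQUENCING_ERROR and the
   best corrected model is still reported.
2. Start-site rescue: in-frame ATG codons upstream (contiguous, stop-free)
   and downstream (within the first coding exon) of the annotated start are
   enumerated and rescored against the template.
3. Exon reassignment: a bounded exhaustive search over structural edits
   (drop exon -> intron, merge adjacent exons reading through the intron,
   extend the terminal exon to the next in-frame stop).
4. Frameshift-indel detection: single-nucleotide virtual insertions or
   deletions proposed from the frameshift-aware codon alignment; if at most
   ``k_max`` such edits restore the reading frame the verdict is
   AMBIGUOUS_INDEL (the low-coverage genomes cannot distinguish sequencing
   error from real indel mutation, so no guess is encoded).
5. Pseudogene check: a gene whose best restorable stop-free ORF stays below
   ``length_frac`` of the template length, or whose catalytic anchor region
   is unalignable, is called PSEUDOGENE.

All candidate models are ranked by global alignment *score* against the
template (end gaps priced, so truncations lose to full-length rescues);
identities reported in verdicts are template-coverage identities
(matches / template length).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import align
from .align import CURATION, codon_align, global_align
from .genome import (GeneModel, Genome, GenomeError, TranscriptModel,
                     find_n_runs, reverse_complement, translate_cds,
                     write_gff3)

CATEGORIES = ("ORTHOLOG_OK", "ANNOTATION_ERROR", "SEQUENCING_ERROR",
              "AMBIGUOUS_INDEL", "PSEUDOGENE")
SUBTYPES = ("START_UPSTREAM", "START_DOWNSTREAM", "EXON_IS_INTRON",
            "INTRON_IS_EXON", "READTHROUGH_STOP", "NT_INSERTION",
            "NT_DELETION", "N_RUN", "TRUNCATION", "PREMATURE_STOP",
            "MOTIF_LOSS", "none")

_EPS = 1e-9


@dataclass
class CurationConfig:
    k_max: int = 2               # max virtual single-nt edits
    max_edits: int = 2           # max structural edits
    length_frac: float = 0.70    # pseudogene truncation threshold
    rescue_window: int = 300     # nt searched upstream of the annotated start
    identity_floor: float = 0.40  # orthology floor (coverage identity)
    min_n_run: int = 5
    length_band: float = 0.05    # |len/template - 1| accepted as full length
    extension_scan: int = 600    # nt scanned for a read-through stop


@dataclass
class CatalyticAnchor:
    """Residue indices of the conserved catalytic region on the template."""

    template_id: str
    positions: tuple[int, ...]

    def validate(self, template_protein: str) -> None:
        for p in self.positions:
            if not 0 <= p < len(template_protein):
                raise GenomeError(
                    f"anchor position {p} outside template {self.template_id}")


@dataclass
class VirtualEdit:
    kind: str       # NT_INSERTION / NT_DELETION
    position: int   # position in the oriented spliced CDS
    base: str = ""


@dataclass
class CurationVerdict:
    gene_id: str
    category: str
    subtype: str
    identity_before: float            # percent, matches / template length
    identity_after: float
    corrected_model: TranscriptModel | None = None
    edits: list[VirtualEdit] = field(default_factory=list)
    structural_edits: list[str] = field(default_factory=list)
    n_runs: list[tuple[int, int]] = field(default_factory=list)
    notes: str = ""

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise GenomeError(f"bad category {self.category}")
        if self.subtype not in SUBTYPES:
            raise GenomeError(f"bad subtype {self.subtype}")


# ---------------------------------------------------------------------------
# oriented view: all stage logic works on the 5'->3' strand of the gene
# ---------------------------------------------------------------------------

@dataclass
class _Oriented:
    locus: str                        # whole scaffold, gene-oriented
    exons: list[tuple[int, int]]      # ascending in oriented coordinates
    strand: str
    scaffold_len: int

    def to_genomic(self, exons: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
        if self.strand == "+":
            return [tuple(e) for e in exons]
        L = self.scaffold_len
        return sorted((L - b, L - a) for a, b in exons)


def _orient(genome: Genome, gene: GeneModel,
            transcript: TranscriptModel | None = None) -> _Oriented:
    t = transcript or gene.transcripts[0]
    scaffold = genome[gene.scaffold_id]
    L = len(scaffold)
    if gene.strand == "+":
        return _Oriented(scaffold, list(t.cds_exons), "+", L)
    locus = reverse_complement(scaffold)
    exons = sorted((L - b, L - a) for a, b in t.cds_exons)
    return _Oriented(locus, exons, "-", L)


def _spliced(locus: str, exons: Sequence[tuple[int, int]]) -> str:
    return "".join(locus[a:b] for a, b in exons)


@dataclass
class _Eval:
    protein: str
    n_match: int
    score: float
    stop_free: bool
    length_aa: int

    def coverage_identity(self, template: str) -> float:
        return self.n_match / len(template)


def _evaluate(locus: str, exons: Sequence[tuple[int, int]],
              template: str) -> _Eval:
    cds = _spliced(locus, exons)
    tr = translate_cds(cds, partial=True)
    prot = tr.protein.replace("*", "X")
    if not prot:
        return _Eval("", 0, float("-inf"), False, 0)
    aln = global_align(prot, template, CURATION)
    return _Eval(tr.protein, aln.n_match, aln.score, tr.stop_free, tr.length_aa)


def _full_length(ev: _Eval, template: str, cfg: CurationConfig) -> bool:
    return abs(ev.length_aa / len(template) - 1.0) <= cfg.length_band


def _accept_gain(new: _Eval, old: _Eval) -> bool:
    """Match accounting for a candidate correction.

    Residues a correction *adds* must align to the template well above
    chance (>= 40% matches), so junk read-through is rejected; residues it
    *removes* may only take away chance-level matches (<= 25%), so dropping
    a spurious exon survives the couple of matches the junk contributed.
    """
    added = new.length_aa - old.length_aa
    gain = new.n_match - old.n_match
    if added > 0:
        return gain >= max(1, 0.4 * added)
    return gain >= -max(2.0, 0.25 * (-added))


# ---------------------------------------------------------------------------
# stage operations (public, usable on oriented fixtures)
# ---------------------------------------------------------------------------

@dataclass
class RescueCandidate:
    exons: list[tuple[int, int]]
    shift: int            # nt; >0 means the start moved
    direction: str        # 'upstream' / 'downstream' / 'annotated'
    score: float
    identity: float       # coverage identity vs template
    evaluation: _Eval


def rescue_start_site(locus: str, exons: Sequence[tuple[int, int]],
                      template_protein: str,
                      window_nt: int = 300,
                      cfg: CurationConfig | None = None
                      ) -> list[RescueCandidate]:
    """Enumerate and rank alternative in-frame ATG start sites.

    Upstream candidates must be contiguous genomic sequence free of in-frame
    stop codons between the candidate ATG and the annotated start; downstream
    candidates lie within the first coding exon.  Ranked by alignment score
    (desc), then |shift| (asc), then upstream before downstream.
    """
    cfg = cfg or CurationConfig()
    exons = sorted(tuple(e) for e in exons)
    s = exons[0][0]
    cands: list[RescueCandidate] = []

    def add(new_exons, shift, direction):
        ev = _evaluate(locus, new_exons, template_protein)
        cands.append(RescueCandidate(list(new_exons), shift, direction, ev.score,
                                     ev.coverage_identity(template_protein), ev))

    add(exons, 0, "annotated")
    # upstream: extend exon 1 into contiguous genomic sequence
    for shift in range(3, window_nt + 1, 3):
        p = s - shift
        if p < 0:
            break
        if locus[p:p + 3] != "ATG":
            continue
        segment = locus[p:s]
        tr = translate_cds(segment, partial=True)
        if not tr.stop_free:
            continue
        add([(p, exons[0][1])] + exons[1:], shift, "upstream")
    # downstream: later in-frame ATGs within the first coding exon
    first_len = exons[0][1] - exons[0][0]
    for shift in range(3, first_len - 2, 3):
        p = s + shift
        if locus[p:p + 3] == "ATG":
            add([(p, exons[0][1])] + exons[1:], shift, "downstream")
    order = {"annotated": 0, "upstream": 1, "downstream": 2}
    cands.sort(key=lambda c: (-c.score, abs(c.shift), order[c.direction]))
    return cands


@dataclass
class ReassignResult:
    exons: list[tuple[int, int]]
    edits: list[str]            # e.g. ['drop_exon:1', 'drop_exon:2']
    score: float
    identity: float
    evaluation: _Eval
    nt_changed: int


def _apply_structural(locus: str, exons: list[tuple[int, int]],
                      moves: Sequence[tuple], scan: int
                      ) -> tuple[list[tuple[int, int]], int] | None:
    """Apply a structural edit set; returns (exons, nt changed) or None."""
    work = [list(e) for e in exons]
    changed = 0
    drops = sorted((m[1] for m in moves if m[0] == "drop"), reverse=True)
    merges = sorted((m[1] for m in moves if m[0] == "merge"), reverse=True)
    extend = any(m[0] == "extend" for m in moves)
    if len(drops) >= len(work):
        return None
    for i in merges:
        if i + 1 >= len(work):
            return None
        changed += work[i + 1][0] - work[i][1]
        work[i][1] = work[i + 1][1]
        del work[i + 1]
    for i in drops:
        if i >= len(work) or len(work) == 1:
            return None
        changed += work[i][1] - work[i][0]
        del work[i]
    if extend:
        # read the terminal exon on through the annotated intron/intergenic
        # sequence until the next in-frame stop codon
        a, b = work[-1]
        cds_len = sum(e[1] - e[0] for e in work)
        found = None
        limit = min(len(locus), b + scan)
        p = b - (cds_len % 3)   # first in-frame codon boundary at/before b
        while p + 3 <= limit:
            if p + 3 > b and locus[p:p + 3] in {"TAA", "TAG", "TGA"}:
                found = p + 3
                break
            p += 3
        if found is None or found <= b:
            return None
        changed += found - b
        work[-1][1] = found
    out = [tuple(e) for e in work]
    if any(b <= a for a, b in out):
        return None
    for (_, b1), (a2, _) in zip(out, out[1:]):
        if a2 < b1:
            return None
    return out, changed


def reassign_exons(locus: str, exons: Sequence[tuple[int, int]],
                   template_protein: str, max_edits: int = 2,
                   cfg: CurationConfig | None = None
                   ) -> ReassignResult | None:
    """Bounded exhaustive search over structural edit sets.

    Returns the best strictly-improving edit set (by alignment score; ties
    to fewest edits then smallest nt changed), or None when no structural
    edit yields a stop-free coding model better than the annotation.
    """
    cfg = cfg or CurationConfig()
    exons = sorted(tuple(e) for e in exons)
    base = _evaluate(locus, exons, template_protein)
    n = len(exons)
    moves: list[tuple] = [("drop", i) for i in range(n) if n > 1]
    moves += [("merge", i) for i in range(n - 1)]
    moves.append(("extend",))
    best: ReassignResult | None = None
    for k in range(1, max_edits + 1):
        for combo in itertools.combinations(moves, k):
            applied = _apply_structural(locus, list(exons), combo,
                                        cfg.extension_scan)
            if applied is None:
                continue
            new_exons, changed = applied
            cds_len = sum(b - a for a, b in new_exons)
            if cds_len < 3 or cds_len % 3 != 0:
                continue
            ev = _evaluate(locus, new_exons, template_protein)
            if not ev.stop_free:
                continue
            if ev.score <= base.score + _EPS or not _accept_gain(ev, base):
                continue
            labels = [":".join(str(x) for x in m) for m in combo]
            cand = ReassignResult(new_exons, labels, ev.score,
                                  ev.coverage_identity(template_protein),
                                  ev, changed)
            key = (-cand.score, len(cand.edits), cand.nt_changed)
            if best is None or key < (-best.score, len(best.edits),
                                      best.nt_changed):
                best = cand
    return best


def detect_sequence_gaps(locus: str, exons: Sequence[tuple[int, int]],
                         min_run: int = 5
                         ) -> list[tuple[int, int, bool]]:
    """N-runs within the gene span; third field flags CDS overlap."""
    exons = sorted(tuple(e) for e in exons)
    span = (exons[0][0], exons[-1][1])
    out = []
    for a, b in find_n_runs(locus[span[0]:span[1]], min_run):
        a, b = a + span[0], b + span[0]
        overlaps = any(a < eb and b > ea for ea, eb in exons)
        out.append((a, b, overlaps))
    return out


@dataclass
class IndelResult:
    edits: list[VirtualEdit]
    corrected_cds: str
    identity_before: float
    identity_after: float
    n_match_after: int
    score_after: float
    n_frameshifts: int
    correctable: bool


def _best_insertion(codon2: str, target_aa: str) -> tuple[int, str]:
    """Best (offset, base) completing a 2-nt codon toward the template residue."""
    best = (0, "A", -1e9)
    for off in range(3):
        for base in "ACGT":
            codon = codon2[:off] + base + codon2[off:]
            aa = translate_cds(codon, partial=True).protein or "X"
            s = align._MAT[align._IDX[aa], align._IDX.get(target_aa, align._IDX["X"])]
            if aa == "*":
                s -= 10
            if s > best[2]:
                best = (off, base, s)
    return best[0], best[1]


def _best_deletion(codon4: str, target_aa: str) -> int:
    best = (0, -1e9)
    for off in range(4):
        codon = codon4[:off] + codon4[off + 1:]
        aa = translate_cds(codon, partial=True).protein or "X"
        s = align._MAT[align._IDX[aa], align._IDX.get(target_aa, align._IDX["X"])]
        if aa == "*":
            s -= 10
        if s > best[1]:
            best = (off, s)
    return best[0]


def detect_frameshift_indels(cds: str, template_protein: str, k_max: int = 2
                             ) -> IndelResult:
    """Propose <= k_max virtual single-nt edits restoring the reading frame.

    The edited ("virtual") CDS is re-translated and rescored; the paper's
    convention of assuming the template base at the edited position is
    followed by choosing the base that best restores the template residue.
    """
    ca = codon_align(cds, template_protein)
    fs = ca.frameshifts
    tr0 = translate_cds(cds, partial=True)
    prot0 = tr0.protein.replace("*", "X")
    id_before = (align.template_coverage_identity(prot0, template_protein)
                 if prot0 else 0.0)
    n_fs = sum(abs(e.detail["shift"]) for e in fs)
    if not fs or n_fs > k_max:
        return IndelResult([], cds, id_before, id_before, 0, float("-inf"),
                           len(fs), False)
    # residue each event is paired with: approximate by codon index
    edits: list[VirtualEdit] = []
    work = cds
    for ev in sorted(fs, key=lambda e: -e.dna_position):
        p = ev.dna_position
        j = min(p // 3, len(template_protein) - 1)
        target = template_protein[j]
        if ev.kind == "FRAMESHIFT_DEL":
            if ev.detail["shift"] == -1:
                off, base = _best_insertion(work[p:p + 2], target)
                work = work[:p + off] + base + work[p + off:]
                edits.append(VirtualEdit("NT_INSERTION", p + off, base))
            else:
                work = work[:p] + "NN" + work[p:]
                edits.append(VirtualEdit("NT_INSERTION", p, "NN"))
        else:
            if ev.detail["shift"] == 1:
                off = _best_deletion(work[p:p + 4], target)
                edits.append(VirtualEdit("NT_DELETION", p + off,
                                         work[p + off]))
                work = work[:p + off] + work[p + off + 1:]
            else:
                edits.append(VirtualEdit("NT_DELETION", p, work[p:p + 2]))
                work = work[:p] + work[p + 2:]
    tr1 = translate_cds(work, partial=True)
    prot1 = tr1.protein.replace("*", "X")
    if not prot1:
        return IndelResult([], cds, id_before, id_before, 0, float("-inf"),
                           len(fs), False)
    aln = global_align(prot1, template_protein, CURATION)
    id_after = aln.n_match / len(template_protein)
    edits.reverse()
    return IndelResult(edits, work, id_before, id_after, aln.n_match,
                       aln.score, len(fs), True)


@dataclass
class PseudogeneCall:
    is_pseudogene: bool
    reasons: list[str]
    orf_fraction: float


def pseudogene_check(best_protein: str, template_protein: str,
                     anchors: CatalyticAnchor | None = None,
                     length_frac: float = 0.70) -> PseudogeneCall:
    """PSEUDOGENE iff the restorable stop-free ORF stays below
    ``length_frac`` of the template length, or a catalytic anchor falls in
    a deleted/unaligned region of the best model.

    The restorable ORF is measured from the model's start to its first
    internal stop (a premature stop truncates the product even though
    downstream sequence may still align)."""
    stop_at = best_protein.find("*")
    longest = len(best_protein) if stop_at < 0 else stop_at
    frac = longest / len(template_protein)
    reasons = []
    if frac < length_frac:
        reasons.append("TRUNCATION" if "*" not in best_protein
                       else "PREMATURE_STOP")
    if anchors and best_protein:
        aln = global_align(best_protein.replace("*", "X") or "X",
                           template_protein, CURATION)
        # template position -> aligned target symbol
        tpos = -1
        lost = False
        for x, y in zip(aln.aligned_a, aln.aligned_b):
            if y != "-":
                tpos += 1
                if tpos in anchors.positions and x == "-":
                    lost = True
        if lost:
            reasons.append("MOTIF_LOSS")
    return PseudogeneCall(bool(reasons), reasons, frac)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def curate_gene(genome: Genome, gene: GeneModel, template_protein: str,
                anchors: CatalyticAnchor | None = None,
                cfg: CurationConfig | None = None) -> CurationVerdict:
    """Run the staged decision procedure for one gene against its template."""
    cfg = cfg or CurationConfig()
    if not template_protein:
        raise GenomeError(f"{gene.gene_id}: template protein missing")
    ori = _orient(genome, gene)
    locus, exons = ori.locus, ori.exons
    t_id = gene.transcripts[0].transcript_id

    ev0 = _evaluate(locus, exons, template_protein)
    id_before = 100.0 * ev0.coverage_identity(template_protein)
    gaps = detect_sequence_gaps(locus, exons, cfg.min_n_run)
    cds_gaps = [g for g in gaps if g[2]]

    best_exons = [tuple(e) for e in exons]
    best_ev = ev0
    applied: list[tuple[str, str]] = []   # (stage, subtype)
    structural_labels: list[str] = []

    for _ in range(2):
        progressed = False
        cands = rescue_start_site(locus, best_exons, template_protein,
                                  cfg.rescue_window, cfg)
        top = cands[0]
        if (top.shift != 0 and top.score > best_ev.score + _EPS
                and top.evaluation.stop_free
                and _accept_gain(top.evaluation, best_ev)):
            best_exons, best_ev = top.exons, top.evaluation
            applied.append(("start", "START_UPSTREAM"
                            if top.direction == "upstream"
                            else "START_DOWNSTREAM"))
            progressed = True
        res = reassign_exons(locus, best_exons, template_protein,
                             cfg.max_edits, cfg)
        if res is not None and _accept_gain(res.evaluation, best_ev):
            kinds = {m.split(":")[0] for m in res.edits}
            if "drop" in kinds:
                sub = "EXON_IS_INTRON"
            elif "merge" in kinds:
                sub = "INTRON_IS_EXON"
            else:
                sub = "READTHROUGH_STOP"
            best_exons, best_ev = res.exons, res.evaluation
            applied.append(("structural", sub))
            structural_labels.extend(res.edits)
            progressed = True
        if not progressed:
            break

    # frameshift-indel routes: on the annotated model (an indel the
    # annotation hid may masquerade as a structural problem) and on the
    # structurally repaired model; the higher-scoring route wins
    indel = detect_frameshift_indels(_spliced(locus, best_exons),
                                     template_protein, cfg.k_max)
    if applied:
        indel_annot = detect_frameshift_indels(_spliced(locus, exons),
                                               template_protein, cfg.k_max)
        if (indel_annot.correctable and indel_annot.edits
                and (not indel.correctable or not indel.edits
                     or indel_annot.score_after > indel.score_after)):
            if indel_annot.score_after > best_ev.score + _EPS:
                # the pure-indel route beats every structural repair:
                # revert to the annotated exon chain
                indel = indel_annot
                best_exons = [tuple(e) for e in exons]
                best_ev = ev0
                applied = []
                structural_labels = []
    indel_applied = (indel.correctable and bool(indel.edits)
                     and indel.n_match_after >= best_ev.n_match
                     and indel.score_after > best_ev.score + _EPS)

    if indel_applied:
        final_match = indel.n_match_after
        final_prot = translate_cds(indel.corrected_cds, partial=True).protein
        final_len = len(final_prot)
        final_stop_free = "*" not in final_prot
    else:
        final_match = best_ev.n_match
        final_prot = best_ev.protein
        final_len = best_ev.length_aa
        final_stop_free = best_ev.stop_free
    id_after = 100.0 * final_match / len(template_protein)

    corrected = None
    if applied or indel_applied:
        corrected = TranscriptModel(f"{t_id}.curated",
                                    ori.to_genomic(best_exons))

    full = abs(final_len / len(template_protein) - 1.0) <= cfg.length_band
    healthy = (final_stop_free and full
               and final_match / len(template_protein) >= cfg.identity_floor)

    def verdict(category, subtype, notes=""):
        return CurationVerdict(
            gene_id=gene.gene_id, category=category, subtype=subtype,
            identity_before=round(id_before, 2),
            identity_after=round(max(id_after, id_before), 2),
            corrected_model=corrected,
            edits=indel.edits if indel_applied else [],
            structural_edits=structural_labels,
            n_runs=[(a, b) for a, b, _ in gaps], notes=notes)

    if cds_gaps:
        return verdict("SEQUENCING_ERROR", "N_RUN",
                       notes="CDS overlaps unresolved sequence; re-sequencing "
                             "needed")
    if indel_applied and healthy:
        sub = indel.edits[0].kind
        return verdict("AMBIGUOUS_INDEL", sub,
                       notes="sequencing error vs real indel undecidable "
                             "without coverage data")
    if applied and healthy:
        return verdict("ANNOTATION_ERROR", applied[0][1])
    if healthy and not applied and not indel_applied:
        return verdict("ORTHOLOG_OK", "none")
    pc = pseudogene_check(final_prot, template_protein, anchors,
                          cfg.length_frac)
    if pc.is_pseudogene:
        return verdict("PSEUDOGENE", pc.reasons[0],
                       notes=f"longest ORF {100 * pc.orf_fraction:.0f}% of "
                             f"template")
    if applied:
        return verdict("ANNOTATION_ERROR", applied[0][1])
    return verdict("ORTHOLOG_OK", "none", notes="below full-length band but "
                                                "no restorable defect found")


def curate_panel(genome: Genome, genes: Iterable[GeneModel],
                 templates: dict[str, str],
                 anchors: dict[str, CatalyticAnchor] | None = None,
                 cfg: CurationConfig | None = None) -> list[CurationVerdict]:
    anchors = anchors or {}
    out = []
    for gene in genes:
        label = gene.ortholog_label or gene.gene_id
        out.append(curate_gene(genome, gene, templates[label],
                               anchors.get(label), cfg))
    return out


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def verdicts_to_frame(verdicts: Sequence[CurationVerdict]) -> pd.DataFrame:
    rows = []
    for v in verdicts:
        rows.append({
            "gene_id": v.gene_id,
            "category": v.category,
            "subtype": v.subtype,
            "identity_before": v.identity_before,
            "identity_after": v.identity_after,
            "edits": ";".join(f"{e.kind}@{e.position}{e.base}" for e in v.edits),
            "structural_edits": ";".join(v.structural_edits),
            "corrected_exons": (";".join(f"{a}-{b}" for a, b in
                                         v.corrected_model.cds_exons)
                                if v.corrected_model else ""),
            "notes": v.notes,
        })
    return pd.DataFrame(rows)


def write_reports(verdicts: Sequence[CurationVerdict],
                  genes: Sequence[GeneModel], out_dir: str | Path) -> None:
    """TSV + JSON verdict reports and corrected models as GFF3."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = verdicts_to_frame(verdicts)
    df.to_csv(out_dir / "curation.tsv", sep="\t", index=False)
    payload = []
    for v in verdicts:
        d = {k: val for k, val in asdict(v).items() if k != "corrected_model"}
        d["corrected_exons"] = (v.corrected_model.cds_exons
                                if v.corrected_model else None)
        payload.append(d)
    (out_dir / "curation.json").write_text(json.dumps(payload, indent=1))
    by_id = {v.gene_id: v for v in verdicts}
    fixed = []
    attrs = {}
    for g in genes:
        v = by_id.get(g.gene_id)
        if v is None:
            continue
        model = g
        if v.corrected_model is not None:
            model = GeneModel(g.gene_id, g.scaffold_id, g.strand,
                              [v.corrected_model],
                              ortholog_label=g.ortholog_label,
                              class_label=g.class_label)
        fixed.append(model)
        attrs[g.gene_id] = {"curation_status": f"{v.category}:{v.subtype}"}
    write_gff3(fixed, out_dir / "curated_models.gff3",
               extra_gene_attrs=attrs)
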