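"""Projection of template alternative-splicing structures onto target loci.

A template gene's isoforms (exon chains with shared/unique roles plus UTR
intervals) are anchored on an orthologous target locus exon by exon via
semi-global (infix) alignment.  An isoform is *supported* when every exon
anchors above the identity floor, inferred introns are long enough, splice
boundaries are canonical GT..AG (non-canonical boundaries demote support to
"weak" rather than rejecting — two diverged nucleotides should not imply
isoform loss), and the spliced ORF is free of internal stops.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import edlib
import pandas as pd

from .align import CURATION, global_align, nucleotide_identity
from .genome import GenomeError, translate_cds


@dataclass
class SpliceConfig:
    min_intron: int = 40
    anchor_floor: float = 0.60     # nucleotide identity for an exon anchor
    utr_conserved_floor: float = 0.55
    require_canonical: bool = False


@dataclass
class TemplateExon:
    seq: str
    role: str = "shared"           # 'shared' or 'unique'


@dataclass
class TemplateIsoform:
    tag: str
    exons: list[TemplateExon]
    utr5: str | None = None
    utr3: str | None = None

    @property
    def cds(self) -> str:
        return "".join(e.seq for e in self.exons)

    @property
    def protein(self) -> str:
        return translate_cds(self.cds).protein


@dataclass
class IsoformTemplate:
    gene_id: str
    isoforms: list[TemplateIsoform]

    def __post_init__(self):
        if not self.isoforms:
            raise GenomeError(f"{self.gene_id}: no isoforms")


@dataclass
class IsoformSupport:
    tag: str
    supported: bool
    weak: bool
    provisional: bool
    exon_spans: list[tuple[int, int]]
    exon_identities: list[float]
    cds_identity: float | None      # percent, nucleotide, spliced CDS
    protein_identity: float | None  # percent, vs template isoform protein
    utr5_identity: float | None     # percent
    utr3_identity: float | None
    utr5_conserved: bool | None
    utr3_conserved: bool | None
    reasons: list[str] = field(default_factory=list)


@dataclass
class ProjectionResult:
    gene_id: str
    isoforms: list[IsoformSupport]

    def supported_tags(self) -> list[str]:
        return [i.tag for i in self.isoforms if i.supported]


def _anchor(query: str, locus: str) -> tuple[int, int, float] | None:
    """Best infix placement of query in locus: (start, end, identity)."""
    res = edlib.align(query, locus, mode="HW", task="locations")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    # co-optimal placements can trade an end substitution for an end gap,
    # shifting the span; prefer the span whose length matches the query,
    # then snap to the best exact-length window so splice-site windows are
    # not displaced by one base
    start, end_inc = min(res["locations"],
                         key=lambda se: (abs((se[1] + 1 - se[0]) - len(query)),
                                         se[0]))
    end = end_inc + 1
    L = len(query)
    if end - start == L:
        return start, end, 1.0 - res["editDistance"] / L
    snapped = None
    for s0 in sorted({start, end - L}):
        if s0 < 0 or s0 + L > len(locus):
            continue
        d = edlib.align(query, locus[s0:s0 + L], mode="NW")["editDistance"]
        ident = 1.0 - d / L
        if snapped is None or ident > snapped[2]:
            snapped = (s0, s0 + L, ident)
    if snapped is not None:
        return snapped
    return start, end, 1.0 - res["editDistance"] / max(L, end - start)


def _refine_window(query: str, locus: str, span: tuple[int, int],
                   identity: float, first: bool, last: bool
                   ) -> tuple[int, int, float]:
    """Nudge an anchored exon window (+-2 nt) toward canonical boundaries.

    Infix alignment can tie between windows one base apart; among windows
    of near-equal identity, prefer the one whose flanks read AG..[exon]..GT
    (acceptor before a non-first exon, donor after a non-last exon).
    """
    L = len(query)
    best = None
    for delta in (-2, -1, 0, 1, 2):
        s = span[0] + delta
        e = s + L
        if s < 0 or e > len(locus):
            continue
        if delta == 0:
            ident = identity
        else:
            d = edlib.align(query, locus[s:e], mode="NW")["editDistance"]
            ident = 1.0 - d / L
        if ident < identity - 0.02:
            continue
        canon = 0
        if not first and locus[s - 2:s] == "AG":
            canon += 1
        if not last and locus[e:e + 2] == "GT":
            canon += 1
        key = (canon, round(ident, 6), -abs(delta))
        if best is None or key > best[0]:
            best = (key, s, e, ident)
    if best is None:
        return span[0], span[1], identity
    return best[1], best[2], best[3]


def utr_identity(template_utr: str, locus: str, anchor: int,
                 side: str) -> float:
    """Percent identity of a UTR against the flank at ``anchor``.

    ``side='5'`` compares the region immediately upstream of the anchor
    (the first coding base), ``side='3'`` immediately downstream of the last
    coding base.
    """
    if anchor is None:
        raise GenomeError("anchor absent")
    L = len(template_utr)
    if side == "5":
        flank = locus[max(0, anchor - L):anchor]
    else:
        flank = locus[anchor:anchor + L]
    if not flank:
        return 0.0
    return 100.0 * nucleotide_identity(template_utr, flank)


def project_isoforms(template: IsoformTemplate, locus: str,
                     cfg: SpliceConfig | None = None) -> ProjectionResult:
    """Anchor each template isoform's exon chain on the target locus."""
    cfg = cfg or SpliceConfig()
    locus = locus.upper()
    supports: list[IsoformSupport] = []
    any_anchor = False
    for iso in template.isoforms:
        spans: list[tuple[int, int]] = []
        idents: list[float] = []
        reasons: list[str] = []
        for k, exon in enumerate(iso.exons):
            hit = _anchor(exon.seq, locus)
            if hit is None or hit[2] < cfg.anchor_floor:
                reasons.append(f"exon{k}_unanchored")
                spans.append((-1, -1))
                idents.append(0.0 if hit is None else hit[2])
                continue
            any_anchor = True
            s, e, ident = _refine_window(exon.seq, locus, hit[:2], hit[2],
                                         first=(k == 0),
                                         last=(k == len(iso.exons) - 1))
            spans.append((s, e))
            idents.append(ident)
        ok = all(s != (-1, -1) for s in spans)
        weak = False
        if ok:
            for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
                if a2 <= b1:
                    ok = False
                    reasons.append("exon_order_violated")
                    break
                intron = a2 - b1
                if intron < cfg.min_intron:
                    ok = False
                    reasons.append(f"intron_too_short:{intron}")
                    break
                donor, acceptor = locus[b1:b1 + 2], locus[a2 - 2:a2]
                if donor != "GT" or acceptor != "AG":
                    if cfg.require_canonical:
                        ok = False
                        reasons.append("non_canonical_boundary")
                        break
                    weak = True
                    reasons.append(f"non_canonical:{donor}..{acceptor}")
        cds_identity = protein_identity = None
        if ok:
            spliced = "".join(locus[a:b] for a, b in spans)
            tr = translate_cds(spliced, partial=True)
            if not tr.stop_free:
                ok = False
                reasons.append("internal_stop")
            else:
                cds_identity = round(
                    100.0 * nucleotide_identity(spliced, iso.cds), 2)
                aln = global_align(tr.protein.replace("*", "X") or "X",
                                   iso.protein, CURATION)
                protein_identity = round(100.0 * aln.identity_fraction, 2)
        u5 = u3 = None
        u5c = u3c = None
        if ok:
            if iso.utr5:
                u5 = round(utr_identity(iso.utr5, locus, spans[0][0], "5"), 2)
                u5c = u5 >= 100 * cfg.utr_conserved_floor
            if iso.utr3:
                u3 = round(utr_identity(iso.utr3, locus, spans[-1][1], "3"), 2)
                u3c = u3 >= 100 * cfg.utr_conserved_floor
        supports.append(IsoformSupport(
            tag=iso.tag, supported=ok, weak=weak, provisional=False,
            exon_spans=spans, exon_identities=[round(x, 4) for x in idents],
            cds_identity=cds_identity, protein_identity=protein_identity,
            utr5_identity=u5, utr3_identity=u3,
            utr5_conserved=u5c, utr3_conserved=u3c, reasons=reasons))
    if not any_anchor:
        for s in supports:
            s.reasons.append("no_locus")
    # a supported isoform whose CDS spans equal another supported isoform's
    # is distinguishable only by UTR -> provisional (5'UTR-variant situation)
    seen: dict[tuple, str] = {}
    for s in supports:
        if not s.supported:
            continue
        key = tuple(s.exon_spans)
        if key in seen:
            s.provisional = True
        else:
            seen[key] = s.tag
    return ProjectionResult(template.gene_id, supports)


def projection_to_frame(results: Sequence[ProjectionResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for s in r.isoforms:
            rows.append({"gene_id": r.gene_id, "isoform": s.tag,
                         "supported": s.supported, "weak": s.weak,
                         "provisional": s.provisional,
                         "cds_identity": s.cds_identity,
                         "protein_identity": s.protein_identity,
                         "utr5_identity": s.utr5_identity,
                         "utr3_identity": s.utr3_identity,
                         "reasons": ";".join(s.reasons)})
    return pd.DataFrame(rows)
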