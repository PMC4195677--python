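"""Ordered stranded gene maps and micro-rearrangement calls.

Gene order is compared between a reference and a target species through a
signed permutation: shared single-copy ortholog labels are numbered 1..n in
reference order and emitted in target order with a sign recording strand
agreement.  Breakpoint distance (non-conserved signed adjacencies, end caps
included) operationalizes the qualitative notion of gene-order "shuffling";
inversion calls are exact on signed blocks, transposition calls are an
explicitly greedy heuristic (not minimal-DCJ).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .genome import GeneModel


class SyntenyError(ValueError):
    pass


@dataclass(frozen=True)
class MapEntry:
    label: str
    scaffold_id: str
    start: int
    strand: str


@dataclass
class GeneMap:
    species_tag: str
    entries: list[MapEntry] = field(default_factory=list)

    def __post_init__(self):
        self.entries = sorted(self.entries,
                              key=lambda e: (e.scaffold_id, e.start))

    def labels(self) -> list[str]:
        return [e.label for e in self.entries]


def gene_map_from_models(species_tag: str,
                         models: Iterable[GeneModel]) -> GeneMap:
    entries = [MapEntry(g.ortholog_label or g.gene_id, g.scaffold_id,
                        g.span[0], g.strand) for g in models]
    return GeneMap(species_tag, entries)


def read_gene_map(path: str | Path, species_tag: str) -> GeneMap:
    """BED-like TSV: scaffold, start, end, label, score, strand."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["scaffold", "start", "end", "label", "score",
                            "strand"])
    entries = [MapEntry(r.label, r.scaffold, int(r.start), r.strand)
               for r in df.itertuples()]
    return GeneMap(species_tag, entries)


def write_gene_map(gmap: GeneMap, path: str | Path) -> None:
    rows = [(e.scaffold_id, e.start, e.start + 1, e.label, 0, e.strand)
            for e in gmap.entries]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


@dataclass
class RearrangementEvent:
    kind: str                  # INVERSION / TRANSPOSITION / SCAFFOLD_SPLIT / DUPLICATION
    labels: list[str]
    breakpoints: tuple[int, ...] = ()


@dataclass
class SignedPermutation:
    values: list[int]                  # +-1..n in target order
    ref_labels: list[str]              # label for each magnitude (1-based)
    scaffold_bounds: list[int]         # indices where a new target scaffold starts
    excluded_duplicates: list[str] = field(default_factory=list)
    unshared: list[str] = field(default_factory=list)

    def label_of(self, magnitude: int) -> str:
        return self.ref_labels[magnitude - 1]


def build_signed_permutation(ref: GeneMap, target: GeneMap
                             ) -> SignedPermutation:
    """Signed permutation of target gene order relative to the reference.

    Only labels single-copy in both maps enter the permutation; multi-copy
    labels are excluded and reported as DUPLICATION candidates.
    """
    def counts(gmap):
        c: dict[str, int] = {}
        for e in gmap.entries:
            c[e.label] = c.get(e.label, 0) + 1
        return c

    cr, ct = counts(ref), counts(target)
    shared = [l for l in cr if l in ct]
    dups = sorted(l for l in set(cr) | set(ct)
                  if max(cr.get(l, 0), ct.get(l, 0)) > 1)
    single = {l for l in shared if cr[l] == 1 and ct[l] == 1}
    if len(single) < 2:
        raise SyntenyError("fewer than 2 shared single-copy labels")
    unshared = sorted((set(cr) ^ set(ct)) - set(dups))
    ref_entries = [e for e in ref.entries if e.label in single]
    rank = {e.label: i + 1 for i, e in enumerate(ref_entries)}
    ref_strand = {e.label: e.strand for e in ref_entries}
    values: list[int] = []
    bounds: list[int] = []
    last_scaffold = None
    for e in target.entries:
        if e.label not in single:
            continue
        if e.scaffold_id != last_scaffold:
            bounds.append(len(values))
            last_scaffold = e.scaffold_id
        sign = 1 if e.strand == ref_strand[e.label] else -1
        values.append(sign * rank[e.label])
    return SignedPermutation(values, [e.label for e in ref_entries], bounds,
                             excluded_duplicates=dups, unshared=unshared)


def breakpoint_distance(perm: Sequence[int], caps: bool = True) -> int:
    """Signed adjacencies not conserved.

    With ``caps`` (default) the sequence is framed by 0 and n+1, which makes
    the distance zero exactly for the identity.  ``caps=False`` counts
    interior adjacencies only; that count is invariant under reading the
    whole sequence from the opposite strand (reversal with sign flip),
    a symmetry the capped count does not have.
    """
    vals = list(perm)
    n = len(vals)
    if sorted(abs(v) for v in vals) != list(range(1, n + 1)):
        raise SyntenyError("not a signed permutation of 1..n")
    ext = [0] + vals + [n + 1] if caps else vals
    return sum(1 for a, b in zip(ext, ext[1:]) if b - a != 1)


def detect_inversions(perm: Sequence[int]) -> list[RearrangementEvent]:
    """Maximal negative runs with consecutive descending magnitudes.

    Returned blocks are disjoint and cover every negative element; a lone
    negative element is a single-gene inversion.
    """
    vals = list(perm)
    events: list[RearrangementEvent] = []
    i = 0
    while i < len(vals):
        if vals[i] >= 0:
            i += 1
            continue
        j = i
        while (j + 1 < len(vals) and vals[j + 1] < 0
               and abs(vals[j + 1]) == abs(vals[j]) - 1):
            j += 1
        block = vals[i:j + 1]
        events.append(RearrangementEvent(
            "INVERSION", [str(abs(v)) for v in block], (i, j + 1)))
        i = j + 1
    return events


def _compact(vals: Sequence[int]) -> list[int]:
    order = sorted(range(len(vals)), key=lambda k: abs(vals[k]))
    new_mag = [0] * len(vals)
    for rank, k in enumerate(order, start=1):
        new_mag[k] = rank
    return [new_mag[k] * (1 if vals[k] > 0 else -1)
            for k in range(len(vals))]


def _candidate_blocks(vals: Sequence[int]) -> list[tuple[int, int]]:
    """Contiguous runs of consecutive ascending positive values, and singles."""
    blocks = []
    i = 0
    while i < len(vals):
        j = i
        while (j + 1 < len(vals) and vals[j] > 0 and vals[j + 1] > 0
               and vals[j + 1] == vals[j] + 1):
            j += 1
        blocks.append((i, j + 1))
        if j > i:
            blocks.append((i, i + 1))  # also consider the leading single
        i = j + 1
    return blocks


def detect_transpositions(perm: Sequence[int]) -> list[RearrangementEvent]:
    """Greedy transposition calling.

    A block whose removal lowers the breakpoint distance by >= 2 (i.e. it
    re-inserts contiguously at its reference position) is called a
    TRANSPOSITION; applied iteratively until no block qualifies.  Heuristic:
    not guaranteed minimal.
    """
    vals = list(perm)
    breakpoint_distance(vals)  # validates
    events: list[RearrangementEvent] = []
    guard = 0
    while guard < 50:
        guard += 1
        base = breakpoint_distance(_compact(vals))
        if base == 0:
            break
        best = None
        for (i, j) in _candidate_blocks(vals):
            if j - i >= len(vals):
                continue
            rest = vals[:i] + vals[j:]
            drop = base - breakpoint_distance(_compact(rest))
            if drop >= 2:
                key = (-drop, j - i, i)
                if best is None or key < best[0]:
                    best = (key, i, j)
        if best is None:
            break
        _, i, j = best
        moved = vals[i:j]
        events.append(RearrangementEvent(
            "TRANSPOSITION", [str(abs(v)) for v in moved], (i, j)))
        rest = vals[:i] + vals[j:]
        # re-insert at the reference position to continue the search
        mags = sorted(abs(v) for v in moved)
        insert_at = 0
        for k, v in enumerate(rest):
            if abs(v) < mags[0]:
                insert_at = k + 1
        vals = rest[:insert_at] + moved + rest[insert_at:]
    return events


def compare_maps(ref: GeneMap, target: GeneMap) -> dict:
    """Full comparison: permutation, distance and event calls."""
    perm = build_signed_permutation(ref, target)
    events: list[RearrangementEvent] = []
    for d in perm.excluded_duplicates:
        events.append(RearrangementEvent("DUPLICATION", [d]))
    # scaffold splits: a reference run split across >1 target scaffolds
    if len(perm.scaffold_bounds) > 1:
        for b in perm.scaffold_bounds[1:]:
            events.append(RearrangementEvent(
                "SCAFFOLD_SPLIT",
                [perm.label_of(abs(perm.values[b - 1])),
                 perm.label_of(abs(perm.values[b]))], (b,)))
    inv = detect_inversions(perm.values)
    # undo called inversions before hunting transpositions, so an inverted
    # block is not re-called as an order move
    undone = list(perm.values)
    for e in inv:
        i, j = e.breakpoints
        undone[i:j] = [-v for v in reversed(undone[i:j])]
    trans = detect_transpositions(undone)
    for e in inv + trans:
        e.labels = [perm.label_of(int(m)) for m in e.labels]
    events.extend(inv + trans)
    return {"permutation": perm,
            "breakpoint_distance": breakpoint_distance(perm.values),
            "events": events}


def events_to_frame(events: Sequence[RearrangementEvent]) -> pd.DataFrame:
    return pd.DataFrame([{"kind": e.kind, "labels": ";".join(e.labels),
                          "breakpoints": ";".join(map(str, e.breakpoints))}
                         for e in events])
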