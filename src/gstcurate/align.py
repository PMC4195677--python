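"""Pairwise global alignment, identity metrics, a frameshift-aware
codon-vs-protein dynamic program, and Jukes-Cantor distances.

Two scoring presets are provided:

``CURATION``
    BLOSUM62 with affine gaps (open 11, extend 1) — the standard sensitive
    setting used for ortholog comparison during curation.
``PAPER_TREE``
    BLOSUM62 with a linear per-column gap penalty of 1 — the unusual but
    explicit setting used for distance-tree construction.

Traceback ties are always broken deterministically, preferring
diagonal > up > left, so outputs are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import edlib
import numpy as np
from Bio.Align import substitution_matrices

from .genome import translate_cds

_BLOSUM = substitution_matrices.load("BLOSUM62")
_ALPHA = str(_BLOSUM.alphabet)  # 'ARNDCQEGHILKMFPSTWYVBZX*'
_IDX = {c: i for i, c in enumerate(_ALPHA)}
_MAT = np.asarray(_BLOSUM, dtype=np.float64)

_NEG = -1.0e30
_TOL = 1e-6


class AlignError(ValueError):
    pass


@dataclass(frozen=True)
class ScoringScheme:
    matrix_name: str = "BLOSUM62"
    mode: str = "affine"          # 'linear' or 'affine'
    gap_open: float = 11.0        # linear mode: per-gap-column penalty
    gap_extend: float = 1.0

    def __post_init__(self):
        if self.mode not in {"linear", "affine"}:
            raise AlignError(f"unknown gap mode {self.mode!r}")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise AlignError("gap penalties must be >= 0")


CURATION = ScoringScheme(mode="affine", gap_open=11.0, gap_extend=1.0)
PAPER_TREE = ScoringScheme(mode="linear", gap_open=1.0, gap_extend=1.0)


@dataclass
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    n_match: int
    n_mutual: int

    @property
    def identity_fraction(self) -> float:
        if self.n_mutual == 0:
            raise AlignError("no mutually aligned columns")
        return self.n_match / self.n_mutual


def _encode(seq: str, what: str) -> np.ndarray:
    try:
        return np.fromiter((_IDX[c] for c in seq), dtype=np.intp, count=len(seq))
    except KeyError as e:
        raise AlignError(f"symbol {e.args[0]!r} in {what} not in BLOSUM62 alphabet")


def _counts(aligned_a: str, aligned_b: str) -> tuple[int, int]:
    n_match = n_mutual = 0
    for x, y in zip(aligned_a, aligned_b):
        if x != "-" and y != "-":
            n_mutual += 1
            if x == y:
                n_match += 1
    return n_match, n_mutual


# ---------------------------------------------------------------------------
# Needleman-Wunsch, linear gaps
# ---------------------------------------------------------------------------

def _nw_linear(a: str, b: str, S: np.ndarray, g: float):
    n, m = len(a), len(b)
    js = np.arange(m + 1, dtype=np.float64)
    H = np.empty((n + 1, m + 1))
    H[0] = -g * js
    for i in range(1, n + 1):
        T = np.empty(m + 1)
        T[0] = -g * i
        T[1:] = np.maximum(H[i - 1, :-1] + S[i - 1], H[i - 1, 1:] - g)
        H[i] = np.maximum.accumulate(T + g * js) - g * js
    # traceback, diagonal > up > left
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if (i > 0 and j > 0
                and math.isclose(H[i, j], H[i - 1, j - 1] + S[i - 1, j - 1],
                                 abs_tol=_TOL)):
            out_a.append(a[i - 1]); out_b.append(b[j - 1]); i -= 1; j -= 1
        elif i > 0 and math.isclose(H[i, j], H[i - 1, j] - g, abs_tol=_TOL):
            out_a.append(a[i - 1]); out_b.append("-"); i -= 1
        else:
            out_a.append("-"); out_b.append(b[j - 1]); j -= 1
    return H[n, m], "".join(reversed(out_a)), "".join(reversed(out_b))


# ---------------------------------------------------------------------------
# Needleman-Wunsch, affine gaps (Gotoh)
# ---------------------------------------------------------------------------

def _nw_affine(a: str, b: str, S: np.ndarray, open_: float, ext: float):
    n, m = len(a), len(b)
    js = np.arange(m + 1, dtype=np.float64)
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)   # gap in b (consumes a, 'up')
    Y = np.full((n + 1, m + 1), _NEG)   # gap in a (consumes b, 'left')
    M[0, 0] = 0.0
    Y[0, 1:] = -(open_ + (js[1:] - 1) * ext)
    for i in range(1, n + 1):
        X[i, 0] = -(open_ + (i - 1) * ext)
        X[i, 1:] = np.maximum(M[i - 1, 1:] - open_, X[i - 1, 1:] - ext)
        prev = np.maximum(np.maximum(M[i - 1, :-1], X[i - 1, :-1]), Y[i - 1, :-1])
        M[i, 1:] = prev + S[i - 1]
        A = np.maximum(M[i], X[i])
        c = np.maximum.accumulate(A[:-1] + js[:-1] * ext)
        Y[i, 1:] = c - open_ - (js[1:] - 1) * ext
    # traceback; state preference M (diag) > X (up) > Y (left)
    i, j = n, m
    state = max(((M[n, m], 0), (X[n, m], 1), (Y[n, m], 2)),
                key=lambda t: (t[0] - _TOL * t[1]))[1]
    score = (M[n, m], X[n, m], Y[n, m])[state]
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == 0:
            out_a.append(a[i - 1]); out_b.append(b[j - 1])
            target = M[i, j] - S[i - 1, j - 1]
            i -= 1; j -= 1
            if math.isclose(M[i, j], target, abs_tol=_TOL):
                state = 0
            elif math.isclose(X[i, j], target, abs_tol=_TOL):
                state = 1
            else:
                state = 2
        elif state == 1:
            out_a.append(a[i - 1]); out_b.append("-")
            val = X[i, j]
            i -= 1
            state = 0 if math.isclose(M[i, j] - open_, val, abs_tol=_TOL) else 1
        else:
            out_a.append("-"); out_b.append(b[j - 1])
            val = Y[i, j]
            j -= 1
            if math.isclose(M[i, j] - open_, val, abs_tol=_TOL):
                state = 0
            elif math.isclose(X[i, j] - open_, val, abs_tol=_TOL):
                state = 1
            else:
                state = 2
    return score, "".join(reversed(out_a)), "".join(reversed(out_b))


def global_align(a: str, b: str,
                 scheme: ScoringScheme = CURATION) -> AlignmentResult:
    """Optimal global protein alignment under ``scheme``.

    The traceback is deterministic (ties: diagonal > up > left) and
    canonical under operand order: swapping a and b mirrors the alignment,
    so score and identity are exactly symmetric.
    """
    if not a or not b:
        raise AlignError("empty input sequence")
    if b < a:
        sw = global_align(b, a, scheme)
        return AlignmentResult(sw.aligned_b, sw.aligned_a, sw.score,
                               sw.n_match, sw.n_mutual)
    ea, eb = _encode(a, "sequence a"), _encode(b, "sequence b")
    S = _MAT[np.ix_(ea, eb)]
    if scheme.mode == "linear":
        score, aa, ab = _nw_linear(a, b, S, scheme.gap_open)
    else:
        score, aa, ab = _nw_affine(a, b, S, scheme.gap_open, scheme.gap_extend)
    n_match, n_mutual = _counts(aa, ab)
    return AlignmentResult(aa, ab, float(score), n_match, n_mutual)


def percent_identity(aln: AlignmentResult) -> float:
    """100 * matches / mutually aligned columns."""
    return 100.0 * aln.identity_fraction


def template_coverage_identity(target: str, template: str,
                               scheme: ScoringScheme = CURATION) -> float:
    """Matches as a fraction of the template length (coverage-weighted), 0-1."""
    if not target:
        return 0.0
    aln = global_align(target, template, scheme)
    return aln.n_match / len(template)


def nucleotide_identity(a: str, b: str) -> float:
    """Global (NW) nucleotide identity via edit distance, as a fraction.

    Defined as 1 - d/max(|a|,|b|); exact for substitution-only divergence.
    """
    if not a or not b:
        raise AlignError("empty input sequence")
    d = edlib.align(a, b, mode="NW")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


# ---------------------------------------------------------------------------
# codon-aware DNA vs template-protein alignment with frameshift states
# ---------------------------------------------------------------------------

@dataclass
class CodonEvent:
    kind: str            # FRAMESHIFT_INS / FRAMESHIFT_DEL / PREMATURE_STOP / CODON_GAP
    dna_position: int    # 0-based position in the input DNA
    detail: dict = field(default_factory=dict)


@dataclass
class CodonAlignment:
    events: list[CodonEvent]
    raw_identity: float        # frame-0 translation vs template, mutual columns
    corrected_identity: float  # translation along the chosen path vs template
    score: float
    path_protein: str          # residues emitted along the path ('X' at shifts)

    @property
    def frameshifts(self) -> list[CodonEvent]:
        return [e for e in self.events if e.kind.startswith("FRAMESHIFT")]


def _codon_aas(dna: str) -> np.ndarray:
    """Encoded amino acid of the codon starting at every position (or -1)."""
    n = len(dna)
    enc = np.full(n, -1, dtype=np.intp)
    for p in range(n - 2):
        codon = dna[p:p + 3]
        if "N" in codon:
            enc[p] = _IDX["X"]
        elif codon in {"TAA", "TAG", "TGA"}:
            enc[p] = _IDX["*"]
        else:
            enc[p] = _IDX[translate_cds(codon, partial=True).protein or "X"]
    return enc


# transition table: (d_nt, d_template, uses_codon_at, penalty_kind)
# preference order = listing order (codon match first, left-gap last)
_CA_MATCH, _CA_GDNA, _CA_D1, _CA_I1, _CA_D2, _CA_I2, _CA_GTPL = range(7)


def codon_align(dna: str, template_protein: str,
                scheme: ScoringScheme = CURATION,
                frameshift_penalty: float | None = None,
                codon_gap: float | None = None) -> CodonAlignment:
    """Align a coding DNA sequence to a template protein, allowing +-1/+-2
    nucleotide frameshifts at a penalty.

    The DP state is (nucleotides consumed, template residues consumed); one
    template residue may be paired with 3 nt (codon), 2 or 1 nt (1- or 2-nt
    deletion in the DNA) or 4 or 5 nt (1- or 2-nt insertion).  Whole-codon
    gaps on either side use a linear per-codon penalty.
    """
    dna = dna.upper()
    if len(dna) < 3:
        raise AlignError("DNA shorter than one codon")
    if not template_protein:
        raise AlignError("empty template protein")
    fp = float(frameshift_penalty if frameshift_penalty is not None
               else 2 * scheme.gap_open)
    fp2 = 1.5 * fp
    g = float(codon_gap if codon_gap is not None
              else scheme.gap_open + scheme.gap_extend)
    n, m = len(dna), len(template_protein)
    et = _encode(template_protein, "template")
    aas = _codon_aas(dna)
    # score of codon starting at p vs template residue j: Srow[p][j]
    js = np.arange(m + 1, dtype=np.float64)
    C = np.full((n + 1, m + 1), _NEG)
    choice = np.full((n + 1, m + 1), -1, dtype=np.int8)
    left = np.zeros((n + 1, m + 1), dtype=bool)
    stop_pen = 0.0  # BLOSUM62 already prices '*' vs residues at -4
    for i in range(0, n + 1):
        cand = np.full((7, m + 1), _NEG)
        if i == 0:
            cand[_CA_MATCH, 0] = 0.0  # origin
        if i >= 3:
            s = _MAT[aas[i - 3], et] - (stop_pen if _ALPHA[aas[i - 3]] == "*" else 0)
            cand[_CA_MATCH, 1:] = C[i - 3, :-1] + s
            cand[_CA_GDNA, :] = C[i - 3, :] - g
        if i >= 2:
            cand[_CA_D1, 1:] = C[i - 2, :-1] - fp
        if i >= 4:
            cand[_CA_I1, 1:] = C[i - 4, :-1] + _MAT[aas[i - 3], et] - fp
        if i >= 1:
            cand[_CA_D2, 1:] = C[i - 1, :-1] - fp2
        if i >= 5:
            cand[_CA_I2, 1:] = C[i - 5, :-1] + _MAT[aas[i - 3], et] - fp2
        best = np.argmax(cand, axis=0)           # first max = preference order
        T = cand[best, np.arange(m + 1)]
        row = np.maximum.accumulate(T + js * g) - js * g
        C[i] = row
        choice[i] = best
        left[i] = row > T + _TOL
    score = C[n, m]
    # traceback
    events: list[CodonEvent] = []
    path_dna_aa: list[str] = []
    path_tpl_aa: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if left[i, j]:
            events.append(CodonEvent("CODON_GAP", i, {"side": "template"}))
            j -= 1
            continue
        ch = choice[i, j]
        if ch == _CA_MATCH:
            if i == 0 and j == 0:
                break
            aa = _ALPHA[aas[i - 3]]
            if aa == "*" and i < n:
                events.append(CodonEvent("PREMATURE_STOP", i - 3,
                                         {"codon_index": (i - 3) // 3}))
            path_dna_aa.append(aa)
            path_tpl_aa.append(template_protein[j - 1])
            i -= 3; j -= 1
        elif ch == _CA_GDNA:
            aa = _ALPHA[aas[i - 3]]
            if aa == "*" and i < n:
                events.append(CodonEvent("PREMATURE_STOP", i - 3,
                                         {"codon_index": (i - 3) // 3}))
            events.append(CodonEvent("CODON_GAP", i - 3, {"side": "dna"}))
            i -= 3
        elif ch == _CA_D1:
            events.append(CodonEvent("FRAMESHIFT_DEL", i - 2, {"shift": -1}))
            path_dna_aa.append("X"); path_tpl_aa.append(template_protein[j - 1])
            i -= 2; j -= 1
        elif ch == _CA_I1:
            events.append(CodonEvent("FRAMESHIFT_INS", i - 4, {"shift": +1}))
            path_dna_aa.append(_ALPHA[aas[i - 3]])
            path_tpl_aa.append(template_protein[j - 1])
            i -= 4; j -= 1
        elif ch == _CA_D2:
            events.append(CodonEvent("FRAMESHIFT_DEL", i - 1, {"shift": -2}))
            path_dna_aa.append("X"); path_tpl_aa.append(template_protein[j - 1])
            i -= 1; j -= 1
        elif ch == _CA_I2:
            events.append(CodonEvent("FRAMESHIFT_INS", i - 5, {"shift": +2}))
            path_dna_aa.append(_ALPHA[aas[i - 3]])
            path_tpl_aa.append(template_protein[j - 1])
            i -= 5; j -= 1
        else:  # pragma: no cover - DP always leaves a valid move
            raise AlignError("codon alignment traceback failed")
    events.reverse()
    path_dna_aa.reverse()
    path_tpl_aa.reverse()
    mutual = len(path_dna_aa)
    matches = sum(1 for x, y in zip(path_dna_aa, path_tpl_aa) if x == y)
    corrected = matches / mutual if mutual else 0.0
    raw_tr = translate_cds(dna, partial=True)
    prot = raw_tr.protein.replace("*", "X") or "X"
    raw_aln = global_align(prot, template_protein, scheme)
    raw = raw_aln.identity_fraction if raw_aln.n_mutual else 0.0
    # drop the terminal-stop codon gap artifact from the event list
    events = [e for e in events
              if not (e.kind == "CODON_GAP" and e.detail.get("side") == "dna"
                      and e.dna_position >= n - 3)]
    return CodonAlignment(events=events, raw_identity=raw,
                          corrected_identity=corrected, score=float(score),
                          path_protein="".join(path_dna_aa))


# ---------------------------------------------------------------------------
# Jukes-Cantor
# ---------------------------------------------------------------------------

def jukes_cantor(p: float, k: int = 20) -> float:
    """JC distance d = -((k-1)/k) ln(1 - k p / (k-1)) for a k-letter alphabet."""
    if k < 2:
        raise AlignError("alphabet size must be >= 2")
    bound = (k - 1) / k
    if p < 0:
        raise AlignError("mismatch fraction must be >= 0")
    if p >= bound:
        raise AlignError(
            f"mismatch fraction {p:.4f} at or beyond JC saturation {bound:.4f}")
    if p == 0:
        return 0.0
    return -bound * math.log(1.0 - p / bound)
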