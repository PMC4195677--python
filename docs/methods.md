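# Methods

## The curation model

The package assumes the comparative setting of a reference species with
trusted gene models and target species whose annotations were produced by
automatic predictors over assemblies of varying coverage. Orthology between
a target locus and a template gene is given (candidate assignment is the
caller's job; homology search is out of scope). Curation is then a search
over *small* perturbations of the annotated model — the defect classes seen
in practice are all local: a start codon a few dozen codons away, one or two
exons mis-assigned around an intron, a single-nucleotide indel, a run of
`N`, or genuine pseudogenization.

All candidate models are compared by the global alignment **score** of their
translation against the template (BLOSUM62, affine gap open 11 / extend 1 —
the "curation" preset). Score is used for ranking rather than
percent identity because identity over mutually aligned columns is blind to
coverage: a truncated model can match a template at 95% over half its
length, and only end-gap-priced scores prefer the full-length rescue over
the truncation. Verdicts nevertheless report identities, defined as
template-coverage identity (matches / template length, as a percent), which
makes the invariant `identity_after ≥ identity_before` structural: a
correction is only accepted if it does not lose matches.

Two further match-accounting gates keep the search honest:

* residues a candidate **adds** must match the template at ≥40% — random
  read-through sequence matches at ~6% and is rejected, which is what keeps
  a truncated pseudogene from being "repaired" by extension into junk;
* residues a candidate **removes** may only take away ≤25% matches — the
  couple of chance matches inside a spurious exon do not protect it.

### Stage order and precedence

N-runs overlapping the projected CDS always win (`SEQUENCING_ERROR`), since
no inference about the true sequence is possible; the best corrected model
is still attached. Start rescue and structural reassignment then iterate
(at most twice — a wrong start and a wrong exon can co-occur, as in the
annotated-intron start cases). Frameshift detection runs both on the
repaired model and on the *original* annotation, and the higher-scoring
route wins: an indel the annotation disguised as an intron looks like a
structural problem, and conversely a structural repair that merely deletes
the frameshifted exon must lose to the single-nucleotide virtual edit that
restores the whole protein. A gene is `ORTHOLOG_OK` only if it is
internal-stop-free, within ±5% of template length, and above the 40%
identity floor with no repair applied; otherwise the pseudogene test is
consulted before falling back.

### The frameshift-aware codon alignment

`codon_align` is a dynamic program over (nucleotides consumed, template
residues consumed). A template residue may consume 3 nt (codon match,
scored by BLOSUM62 on the translated codon, with stop codons priced by the
matrix's `*` column), 2 or 1 nt (1- or 2-nt deletion in the DNA), or 4 or
5 nt (1- or 2-nt insertion); whole-codon gaps on either side carry a linear
per-codon penalty (gap open + extend = 12). The frameshift penalty defaults
to 2× gap open (22, 1.5× that for 2-nt shifts) so frameshifts are rarer
than codon gaps. The traceback emits frameshift events with DNA positions
(accurate to within one codon — within a run of residues compatible with
both frames the exact base is unidentifiable in principle) and premature
stop events with codon indices. Virtual edits then insert or delete the
base that best restores the template residue at the shift (deterministic
tie-break: smallest offset, alphabetical base), mirroring the practice of
assuming the reference base at an ambiguous position.

### Pseudogene criterion

The restorable ORF is measured from the model start to the first internal
stop; a gene is a pseudogene when that fraction falls below
`length_frac = 0.70` of the template. The published pseudogene calls range
from roughly a quarter to three quarters of template length while every
repaired gene reaches ≥95%, so any threshold in the gap works; 0.70 is the
configurable default. Independently, loss of the catalytic anchor — the
conserved active-site residue block, planted as Ser-His-Ala-Ile at residues
8–11 in the synthetic templates — from the aligned region yields
`MOTIF_LOSS` even at full length.

## Alignment and tree construction

`global_align` is a Needleman–Wunsch/Gotoh implementation (numpy row
recurrences, cumulative-maximum trick for the in-row gap chain) with a
deterministic traceback (ties: diagonal > up > left) that is canonical
under operand order, so scores and identities are exactly symmetric. Two
presets exist because the study's tree settings are unusual but explicit:
`CURATION` (affine 11/1) for ortholog comparison and `PAPER_TREE` (linear
per-column gap penalty of 1) for distances. Under the cheap linear gap,
strongly negative mismatches (below −2) are optimally replaced by double
gaps; distance computations inherit this property of the prescribed
scoring, which slightly deflates the mismatch fraction for harsh
substitutions.

Distances are Jukes–Cantor-corrected mismatch fractions over mutually
aligned columns, d = −((k−1)/k)·ln(1 − kp/(k−1)). The correction's alphabet
size is a parameter (default k = 20 for proteins, 4 for nucleotides), since
distance tools differ on which variant they apply to protein alignments.
Saturated pairs (p ≥ (k−1)/k) raise an error naming the pair.
Neighbor joining follows Saitou–Nei with the Q criterion; ties are broken
on the lexicographically smallest leaf-label pair, negative branch lengths
are clamped to zero and counted, and the unrooted tree keeps one central
trifurcation. On additive matrices the output reproduces the generating
topology and path lengths exactly (machine precision); this is tested
against 100 random 6–10-leaf trees and cross-checked against scikit-bio's
implementation. Newick output rounds branch lengths to 6 significant
digits; the in-memory tree retains full precision.

## Splice projection

Template isoform structures are projected exon by exon: each exon sequence
is placed on the target locus by infix (semi-global) alignment via edlib,
snapped to an exact-length window when co-optimal placements trade end
substitutions for end gaps, and nudged ±2 nt toward canonical `AG`…exon…`GT`
flanks when windows of near-equal identity tie — the boundary refinement a
human curator applies. An isoform is *supported* when all exons anchor at
≥60% nucleotide identity, inferred introns are ≥40 nt, boundaries are
GT..AG (non-canonical boundaries demote to "weak" rather than reject: two
diverged bases should not imply isoform loss), and the spliced ORF has no
internal stop. Reported per isoform: nucleotide CDS identity (which tracks
the substitution rate), protein identity (which degrades roughly three
times faster), and 5′/3′ UTR identities against the anchored flanks, with a
conservation flag at 55%. Isoforms with identical projected CDS spans but
distinct UTR anchors are flagged `provisional` (the 5′UTR-only variant
situation).

## Gene order and micro-rearrangements

Gene maps are ordered, stranded lists of ortholog labels per scaffold.
Labels single-copy in both species form a signed permutation (sign =
strand agreement); multi-copy labels are excluded and surfaced as
`DUPLICATION` events, since a 1–1 order mapping is undefined for them.
Breakpoint distance counts non-conserved signed adjacencies; with the
default end caps it is zero exactly for the identity, while the cap-free
interior count (exposed as `caps=False`) is invariant under reading the
sequence from the opposite strand — the two conventions cannot be combined
in one number. Inversions are exact calls: maximal uniformly negative runs
with consecutive descending magnitudes. Transposition calling is an
explicitly greedy heuristic (remove a block; if the breakpoint distance
drops by ≥2 and the block re-inserts contiguously, call it and iterate) —
not a minimal-DCJ solver; adjacent swaps are inherently ambiguous as to
which gene moved, which bounds recovery below 100% by construction.
Reference-contiguous runs split across target scaffolds are
`SCAFFOLD_SPLIT` events, never inversions across scaffolds, because
fragmented assemblies would otherwise fabricate rearrangements.

## The synthetic data generator

`generate_family` emulates the study system: six classes on six scaffolds,
default cluster sizes (11, 14, 4, 4, 1, 2) matching the reference species'
gene counts, coding sequences of 600–800 bp (terminal stop included), 1–6
exons with GT..AG introns of 50–120 nt, intergenic spacers of 200–500 nt,
random strand per gene, a catalytic anchor motif at fixed residue
positions, and four alternatively spliced genes with the family's two
observed patterns (alternative first exons for the D11/Z2/T3 analogues —
three variants for Z2 — and alternative terminal exons for the O2
analogue, each variant with its own UTR flank). Every output is a pure
function of the spec and one integer seed, consumed in a fixed order.

`evolve_target` applies per-site Jukes–Cantor-symmetric substitutions at a
stated rate, with purifying selection: hits that would create an in-frame
stop inside an annotated CDS, alter a start ATG or terminal stop, or touch
an intron's GT/AG dinucleotides are skipped. Without this, nonsense
mutations at 5% divergence would scramble the expected category of a
defect-free ortholog and make ground truth meaningless; the cost is a
realized substitution rate a few percent below nominal (asserted within
binomial bounds in the tests). There is no background indel mutation —
indels exist only as injected defects, keeping the ledger unambiguous.

`inject_error` applies exactly one defect per call and records kind,
parameters, the inverse edit, and the curation category it should provoke:
start shifts (annotation truncated, expecting upstream rescue, or extended
over a planted stop-free upstream segment, expecting downstream rescue),
fake exons inside introns, fake introns inside exons, single-nucleotide
genomic deletions/insertions (with coordinate shifts propagated to every
model on the scaffold), premature stops at 15–50% of the CDS, N-runs of
15–40 nt inside exons, and truncation to 45% with the removed tail
scrambled. The defect panel used by the recovery benchmark cycles the nine
kinds over 200 genes at 5% divergence.

### What the synthetic benchmarks do and do not show

The generator's sequences are i.i.d. random codons: they lack codon-usage
bias, repeats, paralog cross-similarity within a cluster, real splice-site
motifs beyond GT..AG, and indel polymorphism. Category recovery of ~100%
on this panel therefore demonstrates the *logic* of the decision procedure
under realistic divergence and defect geometry — not performance on real
fly assemblies, where near-identical tandem paralogs and repeat content
would make ortholog assignment (out of scope here) the harder problem.
Divergence is substitution-only by design; the frameshift detector is
exercised by injected indels, not background ones.

## Problem sizes and defaults

| parameter | default | note |
|---|---|---|
| rescue window | 300 nt | largest published start shift is 255 nt |
| `k_max` virtual edits | 2 | every published indel case needs 1 |
| `max_edits` structural | 2 | worst case: two exons dropped |
| `length_frac` | 0.70 | pseudogene truncation threshold |
| length band for "full length" | ±5% | no background indels ⇒ tight |
| identity floor | 40% (coverage) | orthology left to caller above it |
| N-run minimum | 5 | |
| frameshift penalty | 2× gap open | 1.5× more for 2-nt shifts |
| anchor identity floor (splice) | 60% nt | deepest comparisons still anchor |
| min intron | 40 nt | |
| JC alphabet k | 20 protein / 4 nt | |

The recovery benchmark runs 200 genes (≈34 per class) at 0% and 5%
divergence; the tree benchmarks use 100 random 6–10-leaf additive
matrices; rearrangement recovery uses 50 injected events on 12–15-gene
maps. These sizes make the full suite complete in a few minutes on one
core while keeping every estimate's sampling error far from the
acceptance margins.

## Known limitations

* Frameshift positions are reported to within one codon; the exact base is
  unidentifiable inside frame-compatible runs.
* Transposition calling is greedy and undercounts nested arrangements.
* `AMBIGUOUS_INDEL` vs `SEQUENCING_ERROR` is decided purely by the presence
  of N-runs; coverage metadata, if available, is not consumed.
* UTR handling scores given intervals only; UTR boundary discovery and
  novel-isoform discovery are out of scope.
* The unusual linear gap penalty of 1 in the tree preset makes harsh
  mismatches alignable as double gaps; this is a property of the prescribed
  scoring, retained deliberately.
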