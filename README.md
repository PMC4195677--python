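# gstcurate

Template-guided curation of a clustered multi-gene family across related
genomes, modeled on the cytosolic glutathione-transferase (GST) superfamily
of *Drosophila*: 36+ genes in six classes (Delta, Epsilon, Omega, Theta,
Sigma, Zeta) laid out in tandem clusters, typically 600–800 bp of coding
sequence per gene.

Automated gene predictions in newly sequenced relatives of a well-annotated
reference species are frequently wrong in stereotyped ways: misplaced ATG
start sites, intron sequence annotated as exons (and vice versa), single
nucleotide indels from low-coverage sequencing that shatter the reading
frame, runs of `N` where sequencing never finished, and genuinely decayed
pseudogenes. `gstcurate` reproduces, as tested code, the manual comparative
procedure used to fix such models: every target gene is scored against its
reference-species ortholog ("template") protein and pushed through a staged
repair-and-classify pipeline. It also projects the template's
alternative-splicing structures onto target loci, calls micro-rearrangements
of gene order (inversions, transpositions, cluster dispersal) from signed
permutations, and builds Jukes–Cantor neighbor-joining trees of the curated
proteins.

## What the pipeline computes

For each target gene with template protein *T*:

1. **Sequencing gaps** — maximal runs of ≥5 `N` intersecting the projected
   CDS ⇒ verdict `SEQUENCING_ERROR` (the best corrected model is still
   reported; the gene "needs to be re-sequenced").
2. **Start-site rescue** — in-frame ATGs up to 300 nt upstream (contiguous,
   stop-free) and downstream within exon 1, each candidate re-scored by
   global alignment (BLOSUM62, affine 11/1) against *T*.
3. **Exon reassignment** — bounded exhaustive search over ≤2 structural
   edits: drop exon → intron, merge adjacent exons (read through the
   intron), extend the terminal exon to the next in-frame stop.
4. **Frameshift indels** — a frameshift-aware dynamic program aligns the
   coding DNA directly to *T*, allowing ±1/±2-nt shifts at a penalty; ≤2
   single-nucleotide virtual edits that restore the frame give
   `AMBIGUOUS_INDEL` (sequencing error vs. real indel is left undecided, as
   it must be for low-coverage assemblies).
5. **Pseudogene check** — a gene whose restorable stop-free ORF stays below
   70% of the template length, or whose catalytic anchor region
   (the conserved Ser/Tyr active-site block, e.g. Ser-His-Ala-Ile) is
   unalignable, is a `PSEUDOGENE`; otherwise `ANNOTATION_ERROR` (if a
   structural fix was needed) or `ORTHOLOG_OK`.

Trees use the distance construction the study prescribes: pairwise global
alignments scored by BLOSUM62 with a linear gap penalty of 1, mismatch
fraction *p* over mutually aligned columns, and the Jukes–Cantor correction
d = −((k−1)/k)·ln(1 − kp/(k−1)) with k = 20 for proteins, followed by
Saitou–Nei neighbor joining (exact on additive matrices, deterministic
tie-breaks, negative branches clamped to 0).

Because no data accompany the original curation, a first-class synthetic
generator (`gstcurate.simulate`) builds template genomes with the family's
cluster layout, evolves targets by Jukes–Cantor-symmetric substitution under
purifying selection, injects every defect class above plus gene-order
rearrangements, and records each injection in a ground-truth ledger, so the
whole pipeline is testable end to end.

## Worked example

The most drastic start-site case in the curated family: a gene annotated at
489 bp (too short to encode a viable GST) whose true ATG lies 255 nt
upstream, in frame and contiguous with the annotated exon.

```python
from gstcurate.simulate import make_start_rescue_case
from gstcurate.curation import rescue_start_site
from gstcurate.genome import translate_cds

locus, exons, template = make_start_rescue_case(489, 255, "upstream", seed=2)
top = rescue_start_site(locus, exons, template, window_nt=300)[0]
cds = "".join(locus[a:b] for a, b in top.exons)
tr = translate_cds(cds)
print(f"shift={top.shift} nt {top.direction}; corrected CDS {len(cds)} bp -> "
      f"{tr.length_aa} aa; identity {100*top.identity:.0f}%")
```

prints

```
shift=255 nt upstream; corrected CDS 744 bp -> 247 aa; identity 100%
```

i.e. the rescue finds the upstream ATG, the corrected CDS is
489 + 255 = 744 bp, and — with the terminal stop inside the CDS but not the
protein — it encodes 744/3 − 1 = 247 amino acids.

The same from the command line, on a full synthetic study:

```sh
$ gstcurate simulate --seed 1 --divergence 0.05 --n-defects 6 --out demo
INFO gstcurate: wrote target Dtgt1 at 5% divergence (6 defects)
$ gstcurate curate --template demo/template --target demo/Dtgt1 --out demo/reports
INFO gstcurate: Dtgt1: {'ANNOTATION_ERROR': 4, 'ORTHOLOG_OK': 30, 'AMBIGUOUS_INDEL': 2}
```

`demo/reports/Dtgt1/curation.tsv` then holds one verdict per gene
(category, subtype, template-coverage identity before/after, proposed
edits, corrected coordinates), e.g.

```
gene_id      category          subtype         identity_before  identity_after
Dtgt1_GSTD1  ANNOTATION_ERROR  START_UPSTREAM  77.87            87.75
Dtgt1_GSTD2  ORTHOLOG_OK       none            90.45            90.45
```

`gstcurate run-all --seed 1 --out run/` drives the whole study (simulate →
curate → splice → synteny → trees) and writes curation TSV/JSON/GFF3,
splice-support tables, rearrangement-event tables, per-class newick trees
and a run manifest.

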