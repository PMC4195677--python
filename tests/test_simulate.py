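"""The synthetic family generator, divergence model and defect injection."""

import numpy as np
import pytest

from gstcurate.genome import extract_cds, translate_cds
from gstcurate.simulate import (DEFECT_KINDS, EXPECTED_CATEGORY, FamilySpec,
                                build_defect_panel, evolve_target,
                                generate_family, inject_error,
                                inject_rearrangement)
from gstcurate.synteny import build_signed_permutation, detect_inversions


def test_generation_is_deterministic():
    spec = FamilySpec(genes_per_cluster=(3, 3, 2, 2, 1, 2), seed=4)
    a = generate_family(spec)
    b = generate_family(spec)
    assert a.genome.scaffolds == b.genome.scaffolds
    assert [m.gene_id for m in a.models] == [m.gene_id for m in b.models]
    assert a.proteins == b.proteins


def test_generated_cds_lengths_and_translation(plain_family):
    for m in plain_family.models:
        cds = extract_cds(plain_family.genome, m)
        assert 600 <= len(cds) <= 800 and len(cds) % 3 == 0
        tr = translate_cds(cds)
        assert tr.coding_complete
        assert tr.protein == plain_family.proteins[m.ortholog_label]


def test_planted_anchor_motif(plain_family):
    for label, anchor in plain_family.anchors.items():
        prot = plain_family.proteins[label]
        motif = "".join(prot[p] for p in anchor.positions)
        assert motif == "SHAI"


def test_spliced_genes_share_tail_exons(small_family):
    for label, tpl in small_family.isoform_templates.items():
        gene = small_family.model_by_label(label)
        assert len(gene.transcripts) == len(tpl.isoforms) >= 2
        for t in gene.transcripts:
            cds = extract_cds(small_family.genome, gene, t)
            assert translate_cds(cds).coding_complete
        shared = [{e.seq for e in iso.exons if e.role == "shared"}
                  for iso in tpl.isoforms]
        assert all(s == shared[0] for s in shared[1:])


def test_evolve_zero_rate_is_identity(plain_family):
    target = evolve_target(plain_family, 0.0, seed=5)
    assert target.genome.scaffolds == plain_family.genome.scaffolds


def test_evolve_realized_rate_within_binomial_bound(plain_family):
    rate = 0.05
    target = evolve_target(plain_family, rate, seed=5)
    diffs = total = 0
    for sid, seq in plain_family.genome.scaffolds.items():
        mut = target.genome[sid]
        diffs += sum(1 for a, b in zip(seq, mut) if a != b)
        total += len(seq)
    # purifying selection skips some hits, so the realized rate is slightly
    # below nominal; it must stay within 3 sd of the nominal binomial
    sd = (rate * (1 - rate) / total) ** 0.5
    assert rate - 5 * sd < diffs / total <= rate
    assert diffs / total > 0.8 * rate


def test_evolve_never_creates_internal_stops(plain_family):
    target = evolve_target(plain_family, 0.2, seed=11)
    for m in target.models:
        tr = translate_cds(extract_cds(target.genome, m))
        assert tr.coding_complete, m.gene_id


def test_protein_identity_decreases_with_rate(plain_family):
    from gstcurate.align import CURATION, global_align
    means = []
    for rate in (0.0, 0.05, 0.10, 0.20):
        target = evolve_target(plain_family, rate, seed=3)
        idents = []
        for m in target.models:
            prot = translate_cds(extract_cds(target.genome, m)).protein
            tpl = plain_family.proteins[m.ortholog_label]
            idents.append(global_align(prot, tpl, CURATION).identity_fraction)
        means.append(float(np.mean(idents)))
    assert means[0] == 1.0
    assert means == sorted(means, reverse=True)


@pytest.mark.parametrize("kind", DEFECT_KINDS)
def test_inject_each_defect_records_expected_category(kind, plain_family,
                                                      rng):
    target = evolve_target(plain_family, 0.0, seed=2)
    for gene in target.models:
        try:
            rec = inject_error(target, gene.gene_id, kind, rng)
        except Exception:
            continue
        assert rec.kind == kind
        assert rec.expected_category == EXPECTED_CATEGORY[kind]
        return
    pytest.fail(f"no gene compatible with {kind}")


def test_delete_nt_shifts_downstream_gene_coordinates(plain_family, rng):
    target = evolve_target(plain_family, 0.0, seed=2)
    first = target.models[0]
    sid = first.scaffold_id
    same_scaffold = [m for m in target.models if m.scaffold_id == sid]
    before = {m.gene_id: [t.cds_exons[:] for t in m.transcripts]
              for m in same_scaffold}
    rec = inject_error(target, first.gene_id, "DELETE_NT", rng)
    gpos = rec.inverse["genomic_pos"]
    for m in same_scaffold[1:]:
        for t_old, t_new in zip(before[m.gene_id],
                                [t.cds_exons for t in m.transcripts]):
            for (a0, b0), (a1, b1) in zip(t_old, t_new):
                assert a1 == (a0 - 1 if a0 > gpos else a0)
                assert b1 == (b0 - 1 if b0 > gpos else b0)


def test_panel_has_one_defect_per_gene_and_balanced_kinds():
    template, target, ledger = build_defect_panel(n_genes=30, sub_rate=0.05,
                                                  seed=1)
    assert len(ledger) == len(target.models) == 30
    assert len({r.gene_id for r in ledger}) == 30
    kinds = {r.kind for r in ledger}
    assert len(kinds) >= 7     # nearly all defect classes represented


def test_invert_block_gives_forced_permutation(plain_family, rng):
    ref = plain_family.gene_map()
    # restrict to one scaffold for a clean single-cluster check
    tgt, rec = inject_rearrangement(ref, "INVERT_BLOCK", rng,
                                    {"i": 1, "j": 4})
    perm = build_signed_permutation(ref, tgt)
    evs = detect_inversions(perm.values)
    called = [{perm.label_of(int(m)) for m in e.labels} for e in evs]
    assert {"GSTD2", "GSTD3", "GSTD4"} in called


def test_transpose_roundtrip_detection(plain_family, rng):
    from gstcurate.synteny import detect_transpositions
    ref = plain_family.gene_map()
    # move the first Delta gene three positions down (within its cluster);
    # a distance >= 2 makes the moved gene unambiguous
    tgt, rec = inject_rearrangement(ref, "TRANSPOSE_GENE", rng,
                                    {"i": 0, "to": 3})
    perm = build_signed_permutation(ref, tgt)
    evs = detect_transpositions(perm.values)
    called = [{perm.label_of(int(m)) for m in e.labels} for e in evs]
    assert set(rec.labels) in called
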