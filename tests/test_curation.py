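"""The staged template-guided curation procedure."""

import numpy as np
import pytest

from gstcurate.curation import (CatalyticAnchor,
                                curate_gene, curate_panel,
                                detect_frameshift_indels,
                                detect_sequence_gaps, pseudogene_check,
                                reassign_exons, rescue_start_site,
                                verdicts_to_frame, write_reports)
from gstcurate.genome import (GeneModel, Genome, TranscriptModel,
                              translate_cds)
from gstcurate.simulate import (back_translate, build_defect_panel,
                                evolve_target, inject_error,
                                make_exon_reassignment_case,
                                make_intron_start_case,
                                make_readthrough_case,
                                make_start_rescue_case, undo_error,
                                _random_protein)


def _as_gene(locus, exons, strand="+", gene_id="g1"):
    genome = Genome("Dtst", {"s": locus})
    gene = GeneModel(gene_id, "s", strand,
                     [TranscriptModel(f"{gene_id}.t1", exons)],
                     ortholog_label="X")
    return genome, gene


# ---------------------------------------------------------------------------
# start-site rescue
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("annotated,shift,direction,want_aa", [
    (603, 48, "upstream", 216),     # 651 nt corrected CDS
    (603, 33, "upstream", 211),     # 636 nt
    (489, 255, "upstream", 247),    # 744 nt
    (723, 54, "downstream", 222),   # 669 nt
])
def test_rescue_recovers_true_start(annotated, shift, direction, want_aa):
    locus, exons, tpl = make_start_rescue_case(annotated, shift, direction,
                                               seed=11)
    top = rescue_start_site(locus, exons, tpl, 300)[0]
    assert top.shift == shift and top.direction == direction
    cds = "".join(locus[a:b] for a, b in top.exons)
    tr = translate_cds(cds)
    assert tr.coding_complete and tr.length_aa == want_aa


def test_rescue_keeps_perfect_annotated_start():
    locus, exons, tpl = make_start_rescue_case(603, 48, "upstream", seed=1)
    true_exons = [(exons[0][0] - 48, exons[0][1])]
    top = rescue_start_site(locus, true_exons, tpl, 300)[0]
    assert top.shift == 0 and top.direction == "annotated"


def test_rescue_without_atg_flags_unrescued():
    rng = np.random.default_rng(5)
    prot = _random_protein(rng, 100)
    cds = back_translate(rng, prot)
    locus = "C" * 300 + cds[3:]  # start codon removed, no upstream ATG
    cands = rescue_start_site(locus, [(300, 300 + len(cds) - 3)], prot, 300)
    assert all(c.direction == "annotated" or c.shift > 0 for c in cands)


# ---------------------------------------------------------------------------
# exon reassignment
# ---------------------------------------------------------------------------

def test_reassign_drops_intronic_exons_714():
    locus, exons, tpl = make_exon_reassignment_case(714, seed=5)
    assert len(exons) == 6
    res = reassign_exons(locus, exons, tpl, max_edits=2)
    assert res is not None
    assert sorted(res.edits) == ["drop:1", "drop:2"]
    cds = "".join(locus[a:b] for a, b in res.exons)
    tr = translate_cds(cds)
    assert len(cds) == 714 and tr.length_aa == 237 and tr.coding_complete


def test_reassign_terminal_extension_recovers_hidden_stop():
    locus, exons, tpl = make_readthrough_case(678, tail=45, seed=3)
    res = reassign_exons(locus, exons, tpl, max_edits=2)
    assert res is not None and "extend" in ";".join(res.edits)
    assert sum(b - a for a, b in res.exons) == 678


def test_reassign_leaves_correct_model_alone():
    locus, exons, tpl = make_exon_reassignment_case(714, seed=5)
    good = [exons[0]] + exons[3:]
    assert reassign_exons(locus, good, tpl, max_edits=2) is None


# ---------------------------------------------------------------------------
# sequence gaps
# ---------------------------------------------------------------------------

def test_detect_sequence_gaps():
    rng = np.random.default_rng(2)
    prot = _random_protein(rng, 150)
    cds = back_translate(rng, prot)
    locus = "ACGT" * 50 + cds + "ACGT" * 50
    exons = [(200, 200 + len(cds))]
    assert detect_sequence_gaps(locus, exons) == []
    mut = locus[:300] + "N" * 30 + locus[330:]
    gaps = detect_sequence_gaps(mut, exons)
    assert gaps == [(300, 330, True)]


def test_intronic_n_run_flagged_non_overlapping():
    rng = np.random.default_rng(3)
    head = back_translate(rng, _random_protein(rng, 50), stop=False)
    tail = back_translate(rng, "K" * 49)
    intron = "GT" + "N" * 40 + "C" * 20 + "AG"
    locus = "ACGT" * 25 + head + intron + tail + "ACGT" * 25
    a = 100
    exons = [(a, a + len(head)),
             (a + len(head) + len(intron),
              a + len(head) + len(intron) + len(tail))]
    gaps = detect_sequence_gaps(locus, exons)
    assert len(gaps) == 1 and gaps[0][2] is False


# ---------------------------------------------------------------------------
# frameshift indels
# ---------------------------------------------------------------------------

def test_single_deletion_yields_one_virtual_insertion(rng):
    prot = _random_protein(rng, 150)
    cds = back_translate(rng, prot)
    p = 210
    mut = cds[:p] + cds[p + 1:]
    res = detect_frameshift_indels(mut, prot, k_max=2)
    assert res.correctable and len(res.edits) == 1
    e = res.edits[0]
    assert e.kind == "NT_INSERTION" and abs(e.position - p) <= 4
    assert res.identity_after > res.identity_before


def test_clean_gene_has_no_edits(rng):
    prot = _random_protein(rng, 120)
    cds = back_translate(rng, prot)
    res = detect_frameshift_indels(cds, prot, k_max=2)
    assert res.edits == [] and res.n_frameshifts == 0


def test_two_indels_with_kmax1_not_correctable(rng):
    prot = _random_protein(rng, 150)
    cds = back_translate(rng, prot)
    mut = cds[:100] + cds[101:300] + cds[301:]
    res = detect_frameshift_indels(mut, prot, k_max=1)
    assert not res.correctable and res.n_frameshifts >= 2


# ---------------------------------------------------------------------------
# pseudogene check
# ---------------------------------------------------------------------------

def test_truncated_half_length_is_pseudogene(rng):
    template = _random_protein(rng, 215)
    model = template[:108]  # mirrors a 108 aa model vs a 215 aa template
    call = pseudogene_check(model, template)
    assert call.is_pseudogene and "TRUNCATION" in call.reasons
    assert call.orf_fraction == pytest.approx(108 / 215)


def test_full_length_with_anchors_is_not_pseudogene(rng):
    template = _random_protein(rng, 215, anchor_offset=8)
    anchors = CatalyticAnchor("X", (8, 9, 10, 11))
    call = pseudogene_check(template, template, anchors)
    assert not call.is_pseudogene


def test_anchor_deletion_is_motif_loss(rng):
    template = _random_protein(rng, 215, anchor_offset=8)
    model = template[:5] + template[20:]   # catalytic region deleted
    anchors = CatalyticAnchor("X", (8, 9, 10, 11))
    call = pseudogene_check(model, template, anchors)
    assert call.is_pseudogene and "MOTIF_LOSS" in call.reasons


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def test_curate_clean_gene_is_ortholog_ok(rng):
    prot = _random_protein(rng, 200)
    cds = back_translate(rng, prot)
    locus = "ACGT" * 60 + cds + "ACGT" * 60
    genome, gene = _as_gene(locus, [(240, 240 + len(cds))])
    v = curate_gene(genome, gene, prot)
    assert v.category == "ORTHOLOG_OK" and v.subtype == "none"
    assert v.identity_before == 100.0 and v.corrected_model is None


def test_curate_intron_start_gene_recovers_663nt_single_exon():
    locus, exons, tpl = make_intron_start_case(663, seed=2)
    genome, gene = _as_gene(locus, exons)
    v = curate_gene(genome, gene, tpl)
    assert v.category == "ANNOTATION_ERROR"
    assert v.corrected_model.cds_length == 663
    cds = "".join(locus[a:b] for a, b in v.corrected_model.cds_exons)
    assert translate_cds(cds).length_aa == 220


def test_sequencing_error_takes_precedence_over_frameshift(rng):
    """A gene with both an N run and an indel reports SEQUENCING_ERROR."""
    prot = _random_protein(rng, 200)
    cds = back_translate(rng, prot)
    mut = cds[:150] + cds[151:]                    # frameshift deletion
    mut = mut[:300] + "N" * 25 + mut[325:]         # N run in the CDS
    locus = "ACGT" * 60 + mut + "ACGT" * 60
    genome, gene = _as_gene(locus, [(240, 240 + len(mut))])
    v = curate_gene(genome, gene, prot)
    assert v.category == "SEQUENCING_ERROR" and v.subtype == "N_RUN"
    assert v.n_runs


def test_verdict_identity_never_decreases_on_small_panel():
    template, target, ledger = build_defect_panel(n_genes=24, sub_rate=0.05,
                                                  seed=41)
    verdicts = curate_panel(target.genome, target.models, template.proteins,
                            template.anchors)
    for v in verdicts:
        assert v.identity_after >= v.identity_before
        # precedence is a total order: exactly one category per gene
        assert v.category in ("ORTHOLOG_OK", "ANNOTATION_ERROR",
                              "SEQUENCING_ERROR", "AMBIGUOUS_INDEL",
                              "PSEUDOGENE")


def test_undo_injected_indel_restores_ortholog_ok():
    """Applying the ledger's inverse edit and re-curating gives a clean call."""
    template, target, ledger = build_defect_panel(n_genes=12, sub_rate=0.05,
                                                  seed=7)
    recs = [r for r in ledger if r.kind in ("DELETE_NT", "INSERT_NT")]
    assert recs
    for rec in recs:
        undo_error(target, rec)
    genes = [m for m in target.models
             if m.gene_id in {r.gene_id for r in recs}]
    verdicts = curate_panel(target.genome, genes, template.proteins,
                            template.anchors)
    for v in verdicts:
        assert v.category == "ORTHOLOG_OK", (v.gene_id, v.category)


def test_zero_divergence_defect_free_panel_is_all_ok(plain_family):
    target = evolve_target(plain_family, 0.0, seed=3)
    verdicts = curate_panel(target.genome, target.models,
                            plain_family.proteins, plain_family.anchors)
    assert all(v.category == "ORTHOLOG_OK" for v in verdicts)
    assert all(v.identity_before == 100.0 for v in verdicts)


def test_reports_round_trip(tmp_path, plain_family):
    target = evolve_target(plain_family, 0.02, seed=3)
    rng = np.random.default_rng(0)
    inject_error(target, target.models[0].gene_id, "N_RUN", rng)
    verdicts = curate_panel(target.genome, target.models,
                            plain_family.proteins, plain_family.anchors)
    df = verdicts_to_frame(verdicts)
    assert set(df.columns) >= {"gene_id", "category", "subtype",
                               "identity_before", "identity_after"}
    write_reports(verdicts, target.models, tmp_path)
    assert (tmp_path / "curation.tsv").exists()
    assert (tmp_path / "curation.json").exists()
    gff = (tmp_path / "curated_models.gff3").read_text()
    assert "curation_status" in gff
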