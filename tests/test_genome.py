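"""Domain types, coordinate conventions, sequence extraction and I/O."""

import pytest
from hypothesis import given, settings, strategies as st

from gstcurate.genome import (GeneModel, Genome, GenomeError, TranscriptModel,
                              build_gst_name, extract_cds, find_n_runs,
                              read_fasta, read_gff3, reverse_complement,
                              translate_cds, write_fasta, write_gff3)

dna = st.text(alphabet="ACGT", min_size=1)


def test_genome_normalizes_case_and_validates():
    g = Genome("Dmel", {"s1": "acgtn"})
    assert g["s1"] == "ACGTN"
    with pytest.raises(GenomeError):
        Genome("Dmel", {"s1": ""})
    with pytest.raises(GenomeError):
        Genome("Dmel", {"s1": "ACGU"})


def test_transcript_invariants():
    t = TranscriptModel("t", [(9, 18), (0, 6)])
    assert t.cds_exons == [(0, 6), (9, 18)]
    assert t.cds_length == 15
    with pytest.raises(GenomeError):
        TranscriptModel("t", [(0, 6), (5, 9)])  # overlap
    with pytest.raises(GenomeError):
        TranscriptModel("t", [])


def test_extract_cds_forward_and_reverse():
    g = Genome("x", {"s": "ATGAAACCC"})
    plus = GeneModel("g1", "s", "+", [TranscriptModel("t1", [(0, 6)])])
    assert extract_cds(g, plus) == "ATGAAA"
    g2 = Genome("x", {"s": "TTTCATCCC"})
    minus = GeneModel("g2", "s", "-", [TranscriptModel("t2", [(0, 6)])])
    assert extract_cds(g2, minus) == "ATGAAA"


def test_extract_cds_multi_exon_matches_slice_oracle(rng):
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
    g = Genome("x", {"s": seq})
    exons = [(10, 40), (60, 101), (150, 200)]
    t = TranscriptModel("t", exons)
    plus = GeneModel("g", "s", "+", [t])
    oracle = "".join(seq[a:b] for a, b in exons)
    assert extract_cds(g, plus) == oracle
    minus = GeneModel("g", "s", "-", [t])
    assert extract_cds(g, minus) == reverse_complement(oracle)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(dna.filter(lambda s: len(s) >= 20))
def test_extract_strand_symmetry(seq):
    """extract(+) of S equals revcomp of extract(-) of revcomp(S)."""
    exons = [(2, 8), (12, min(18, len(seq)))]
    if exons[1][1] <= exons[1][0]:
        exons = exons[:1]
    t = TranscriptModel("t", exons)
    fwd = extract_cds(Genome("x", {"s": seq}), GeneModel("g", "s", "+", [t]))
    L = len(seq)
    rc_exons = sorted((L - b, L - a) for a, b in exons)
    rev = extract_cds(Genome("x", {"s": reverse_complement(seq)}),
                      GeneModel("g", "s", "-",
                                [TranscriptModel("t", rc_exons)]))
    assert fwd == rev


def test_translate_basics():
    tr = translate_cds("ATGAAATAA")
    assert tr.protein == "MK" and tr.length_aa == 2
    assert tr.coding_complete and not tr.premature_stops
    tr = translate_cds("ATGTAAAAATAA")  # internal stop at codon 1
    assert tr.premature_stops == [1] and not tr.coding_complete
    tr = translate_cds("ATGANATAA")
    assert tr.protein == "MX" and tr.ambiguous_codons == [1]
    with pytest.raises(GenomeError):
        translate_cds("ATGA")
    assert translate_cds("ATGA", partial=True).trimmed_nt == 1


def test_translate_length_law_744nt_gives_247aa(rng):
    """A coding-complete CDS of L nt yields exactly L/3 - 1 residues."""
    from gstcurate.simulate import back_translate, _random_protein
    for L in (744, 669, 651, 636, 663, 714):
        prot = _random_protein(rng, L // 3 - 1)
        cds = back_translate(rng, prot)
        assert len(cds) == L
        tr = translate_cds(cds)
        assert tr.length_aa == L // 3 - 1 and tr.coding_complete


def test_translate_matches_codon_table_oracle(rng):
    from Bio.Seq import Seq
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 900))
    tr = translate_cds(seq)
    oracle = str(Seq(seq).translate())
    expect = oracle[:-1] if oracle.endswith("*") else oracle
    assert tr.protein == expect
    assert tr.premature_stops == [i for i, c in enumerate(expect)
                                  if c == "*"]


@pytest.mark.parametrize("species,letter,num,expected", [
    ("simulans", "T", 4, "DsimGSTT4"),
    ("melanogaster", "D", 1, "DmelGSTD1"),
    ("virilis", "Z", 1, "DvirGSTZ1"),
    ("Erecta", "E", 6, "DereGSTE6"),
])
def test_build_gst_name(species, letter, num, expected):
    assert build_gst_name(species, letter, num) == expected


def test_build_gst_name_rejects_bad_input():
    with pytest.raises(GenomeError):
        build_gst_name("sapiens", "D", 1)
    with pytest.raises(GenomeError):
        build_gst_name("virilis", "Q", 1)
    with pytest.raises(GenomeError):
        build_gst_name("virilis", "D", 0)


def test_fasta_round_trip(tmp_path):
    recs = {"s1": "ACGT" * 40, "s2": "A" * 61}
    write_fasta(recs, tmp_path / "a.fasta")
    assert read_fasta(tmp_path / "a.fasta") == recs
    write_fasta(read_fasta(tmp_path / "a.fasta"), tmp_path / "b.fasta")
    assert (tmp_path / "a.fasta").read_bytes() == \
        (tmp_path / "b.fasta").read_bytes()


def test_fasta_errors(tmp_path):
    (tmp_path / "dup.fasta").write_text(">a\nACGT\n>a\nACGT\n")
    with pytest.raises(GenomeError):
        read_fasta(tmp_path / "dup.fasta")


def test_gff3_coordinate_convention(tmp_path):
    (tmp_path / "g.fasta").write_text(">s\n" + "A" * 60 + "\n")
    (tmp_path / "m.gff3").write_text("\n".join([
        "##gff-version 3",
        "s\tx\tgene\t10\t18\t.\t+\t.\tID=g1",
        "s\tx\tmRNA\t10\t18\t.\t+\t.\tID=t1;Parent=g1",
        "s\tx\tCDS\t10\t18\t.\t+\t0\tID=c1;Parent=t1",
    ]) + "\n")
    models = read_gff3(tmp_path / "m.gff3")
    assert models[0].transcripts[0].cds_exons == [(9, 18)]


def test_gff3_two_mrnas_and_round_trip(tmp_path, plain_family):
    write_gff3(plain_family.models, tmp_path / "m.gff3")
    models2 = read_gff3(tmp_path / "m.gff3", plain_family.genome)
    by_id = {m.gene_id: m for m in plain_family.models}
    for m in models2:
        orig = by_id[m.gene_id]
        assert m.strand == orig.strand
        assert [t.cds_exons for t in m.transcripts] == \
            [t.cds_exons for t in orig.transcripts]
    write_gff3(models2, tmp_path / "m2.gff3")
    assert (tmp_path / "m.gff3").read_bytes() == \
        (tmp_path / "m2.gff3").read_bytes()


def test_gff3_error_on_parentless_cds(tmp_path):
    (tmp_path / "bad.gff3").write_text("\n".join([
        "##gff-version 3",
        "s\tx\tgene\t1\t9\t.\t+\t.\tID=g1",
        "s\tx\tCDS\t1\t9\t.\t+\t0\tID=c1",
    ]) + "\n")
    with pytest.raises(GenomeError):
        read_gff3(tmp_path / "bad.gff3")


def test_find_n_runs():
    assert find_n_runs("ACGT") == []
    assert find_n_runs("AC" + "N" * 30 + "GT") == [(2, 32)]
    assert find_n_runs("ANNNNA", min_run=5) == []
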