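"""Signed-permutation gene-order comparison and rearrangement calling."""

import pytest

from gstcurate.synteny import (GeneMap, MapEntry, SyntenyError,
                               breakpoint_distance, build_signed_permutation,
                               compare_maps, detect_inversions,
                               detect_transpositions, gene_map_from_models,
                               read_gene_map, write_gene_map)
from gstcurate.simulate import inject_rearrangement


def _map(species, labels, strands=None, scaffold="s1"):
    strands = strands or ["+"] * len(labels)
    return GeneMap(species, [MapEntry(l, scaffold, 100 * (i + 1), st)
                             for i, (l, st) in enumerate(zip(labels, strands))])


def test_identical_maps_give_identity_permutation():
    ref = _map("A", list("abcde"))
    perm = build_signed_permutation(ref, _map("B", list("abcde")))
    assert perm.values == [1, 2, 3, 4, 5]
    assert breakpoint_distance(perm.values) == 0


def test_inverted_block_permutation_forced():
    ref = _map("A", list("abcde"))
    tgt = _map("B", ["a", "d", "c", "b", "e"],
               ["+", "-", "-", "-", "+"])
    perm = build_signed_permutation(ref, tgt)
    assert perm.values == [1, -4, -3, -2, 5]
    assert breakpoint_distance(perm.values) == 2


def test_permutation_matches_label_lookup_oracle(rng):
    labels = [f"g{i}" for i in range(12)]
    ref = _map("A", labels)
    for _ in range(25):
        order = list(rng.permutation(12))
        strands = ["+" if rng.random() < 0.5 else "-" for _ in range(12)]
        tgt = _map("B", [labels[i] for i in order], strands)
        perm = build_signed_permutation(ref, tgt)
        oracle = [(i + 1) * (1 if s == "+" else -1)
                  for i, s in zip(order, strands)]
        assert perm.values == oracle


def test_duplicated_labels_excluded_and_reported():
    ref = _map("A", ["a", "b", "c", "b"])
    tgt = _map("B", ["a", "b", "c"])
    perm = build_signed_permutation(ref, tgt)
    assert perm.excluded_duplicates == ["b"]
    assert perm.values == [1, 2]


def test_fewer_than_two_shared_labels_is_error():
    with pytest.raises(SyntenyError):
        build_signed_permutation(_map("A", ["a", "b"]), _map("B", ["a", "c"]))


def test_breakpoint_distance_zero_iff_identity(rng):
    for _ in range(50):
        n = int(rng.integers(2, 10))
        vals = [int(v) * int(rng.choice([-1, 1]))
                for v in rng.permutation(n) + 1]
        bd = breakpoint_distance(vals)
        assert (bd == 0) == (vals == list(range(1, n + 1)))


def test_breakpoint_interior_count_reversal_symmetric(rng):
    """Reading the sequence from the other strand preserves the interior count."""
    for _ in range(50):
        n = int(rng.integers(2, 10))
        vals = [int(v) * int(rng.choice([-1, 1]))
                for v in rng.permutation(n) + 1]
        rev = [-v for v in reversed(vals)]
        assert breakpoint_distance(vals, caps=False) == \
            breakpoint_distance(rev, caps=False)


def test_breakpoint_rejects_non_permutation():
    with pytest.raises(SyntenyError):
        breakpoint_distance([1, 1, 2])


def test_inversion_detection_examples():
    assert detect_inversions([1, 2, 3]) == []
    evs = detect_inversions([1, -4, -3, -2, 5])
    assert len(evs) == 1 and evs[0].labels == ["4", "3", "2"]
    # single-gene inversion
    evs = detect_inversions([1, -2, 3])
    assert len(evs) == 1 and evs[0].labels == ["2"]


def test_inversion_blocks_disjoint_cover_all_negatives(rng):
    for _ in range(50):
        n = int(rng.integers(3, 12))
        vals = [int(v) * int(rng.choice([-1, 1]))
                for v in rng.permutation(n) + 1]
        evs = detect_inversions(vals)
        covered = []
        for e in evs:
            i, j = e.breakpoints
            covered.extend(range(i, j))
        negatives = [k for k, v in enumerate(vals) if v < 0]
        assert sorted(covered) == sorted(set(covered))
        assert set(negatives) <= set(covered)


def test_fifty_injected_inversions_recovered_exactly(rng):
    """Each injected single-block inversion is called with exact extent."""
    n = 12
    for trial in range(50):
        i = int(rng.integers(0, n - 1))
        j = int(rng.integers(i + 1, min(n, i + 5) + 1))
        vals = list(range(1, n + 1))
        vals[i:j] = [-v for v in reversed(vals[i:j])]
        evs = detect_inversions(vals)
        assert len(evs) == 1
        assert evs[0].breakpoints == (i, j)
        assert evs[0].labels == [str(abs(v)) for v in vals[i:j]]


def test_transposition_example_and_identity():
    evs = detect_transpositions([1, 3, 4, 2, 5])
    assert len(evs) == 1 and evs[0].labels == ["2"]
    assert detect_transpositions([1, 2, 3, 4]) == []


def test_injected_transpositions_recovered_90pct(rng):
    n = 12
    hits = 0
    trials = 50
    for _ in range(trials):
        i = int(rng.integers(0, n))
        j = int(rng.integers(0, n - 1))
        while abs(j - i) < 2:
            j = int(rng.integers(0, n - 1))
        vals = list(range(1, n + 1))
        moved = vals.pop(i)
        vals.insert(j, moved)
        evs = detect_transpositions(vals)
        if any(e.labels == [str(moved)] for e in evs):
            hits += 1
    assert hits >= 0.9 * trials


def test_inversion_undo_monotone_breakpoints(rng):
    """Undoing called inversions never increases the breakpoint distance."""
    n = 10
    for _ in range(20):
        vals = list(range(1, n + 1))
        for _ in range(2):
            i = int(rng.integers(0, n - 1))
            j = int(rng.integers(i + 1, n + 1))
            vals[i:j] = [-v for v in reversed(vals[i:j])]
        bd = breakpoint_distance(vals)
        for e in detect_inversions(vals):
            i, j = e.breakpoints
            vals[i:j] = [-v for v in reversed(vals[i:j])]
            bd_new = breakpoint_distance(vals)
            assert bd_new <= bd
            bd = bd_new


def test_compare_maps_calls_injected_events(plain_family, rng):
    ref = plain_family.gene_map()
    # block chosen inside the first cluster (one scaffold)
    tgt, rec_inv = inject_rearrangement(ref, "INVERT_BLOCK", rng,
                                        {"i": 1, "j": 3})
    cmp = compare_maps(ref, tgt)
    inv = [e for e in cmp["events"] if e.kind == "INVERSION"]
    assert len(inv) == 1 and set(inv[0].labels) == set(rec_inv.labels)
    tgt2, rec_tr = inject_rearrangement(ref, "TRANSPOSE_GENE", rng,
                                        {"i": 1, "to": 7})
    cmp2 = compare_maps(ref, tgt2)
    tr = [e for e in cmp2["events"] if e.kind == "TRANSPOSITION"]
    assert any(set(e.labels) == set(rec_tr.labels) for e in tr)


def test_dispersed_cluster_reports_scaffold_split(plain_family, rng):
    ref = plain_family.gene_map()
    tgt, rec = inject_rearrangement(ref, "DISPERSE_CLUSTER", rng, {"at": 8})
    cmp = compare_maps(ref, tgt)
    assert any(e.kind == "SCAFFOLD_SPLIT" for e in cmp["events"])


def test_gene_map_io(tmp_path, plain_family):
    gmap = gene_map_from_models("Dmel", plain_family.models)
    write_gene_map(gmap, tmp_path / "map.tsv")
    back = read_gene_map(tmp_path / "map.tsv", "Dmel")
    assert [e.label for e in back.entries] == [e.label for e in gmap.entries]
    assert [e.strand for e in back.entries] == [e.strand for e in gmap.entries]
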