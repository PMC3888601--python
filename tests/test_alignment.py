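import itertools

import pytest
from hypothesis import given, settings, strategies as st

from paranno.alignment import (
    ConsensusTrack,
    DuplicateMemberError,
    RaggedAlignmentError,
    ScoreFileError,
    UnknownMemberError,
    build_residue_map,
    consensus_from_alternatives,
    make_alignment,
    read_alignment,
    read_score_file,
    round_half_up,
    write_alignment,
)


def test_read_alignment_fasta_and_clustal_equivalent(tmp_path):
    fa = tmp_path / "a.fasta"
    fa.write_text(">s1\nAR-K\n>s2\nARGK\n")
    cl = tmp_path / "a.aln"
    cl.write_text(
        "CLUSTAL W (1.82) multiple sequence alignment\n\n"
        "s1   AR-K\ns2   ARGK\n"
    )
    a1 = read_alignment(fa)
    a2 = read_alignment(cl)
    assert a1.n_columns == 4
    assert a1 == a2


def test_read_alignment_errors(tmp_path):
    ragged = tmp_path / "r.fasta"
    ragged.write_text(">s1\nARK\n>s2\nARGK\n")
    with pytest.raises(RaggedAlignmentError):
        read_alignment(ragged)
    with pytest.raises(DuplicateMemberError):
        make_alignment(["s1", "s1"], ["AR", "AR"])
    empty = tmp_path / "e.fasta"
    empty.write_text("")
    with pytest.raises(Exception):
        read_alignment(empty)


def test_alignment_normalises_case_and_dots():
    a = make_alignment(["s1", "s2"], ["ar.k", "ARGK"])
    assert a.rows[0] == "AR-K"
    assert a.sequence("s1") == "ARK"


def test_write_read_round_trip(tmp_path, toy_alignment):
    p = tmp_path / "out.fasta"
    write_alignment(toy_alignment, p)
    assert read_alignment(p) == toy_alignment


def test_residue_map_gap_handling():
    a = make_alignment(["s1", "s2"], ["A-K", "ARK"])
    m = build_residue_map(a, "s1", "s2")
    assert m.forward == {1: 1, 2: 3}  # s1's K is its residue 2
    back = build_residue_map(a, "s2", "s1")
    assert back.get(2) is None  # R faces the gap
    assert m.invert().forward == back.forward


def test_residue_map_identity_and_unknown_member(toy_alignment):
    ident = make_alignment(["a", "b"], ["ARNDC", "ARNDC"])
    m = build_residue_map(ident, "a", "b")
    assert m.forward == {i: i for i in range(1, 6)}
    with pytest.raises(UnknownMemberError):
        build_residue_map(ident, "a", "zz")


def test_residue_map_round_trip_is_identity(toy_alignment):
    fwd = build_residue_map(toy_alignment, "PX", "QRY")
    back = build_residue_map(toy_alignment, "QRY", "PX")
    for src, dst in fwd.forward.items():
        assert back.get(dst) == src


def test_consensus_identical_alternatives_score_nine(toy_alignment):
    """Self-consensus is 9 at every residue with a non-gap partner and 0 at
    residues aligned only to gaps (PX's K at column 10)."""
    track = consensus_from_alternatives(toy_alignment, [toy_alignment])
    assert all(v == 9 for v in track.scores["QRY"])
    assert all(v == 9 for v in track.scores["PY"])
    assert track.scores["PX"] == (9, 9, 9, 9, 9, 9, 9, 9, 0, 9)


def test_consensus_zero_when_no_pair_reproduced():
    primary = make_alignment(["a", "b"], ["WK--", "--WK"])
    # primary aligns nothing; use a fully-paired primary and a disjoint alt
    primary = make_alignment(["a", "b"], ["WK", "WK"])
    alt = make_alignment(["a", "b"], ["WK--", "--WK"])
    track = consensus_from_alternatives(primary, [alt])
    assert all(v == 0 for v in track.scores["a"])


def test_consensus_hand_enumerated_partial_agreement():
    """Residue a1 has partners {(b,1),(c,1)}; one alternative keeps both,
    the other keeps only (b,1): score = round_half_up(9*(1+0.5)/2) = 7."""
    primary = make_alignment(["a", "b", "c"], ["WK", "WK", "WK"])
    alt_full = primary
    alt_half = make_alignment(["a", "b", "c"], ["WK-", "WK-", "-WK"])
    track = consensus_from_alternatives(primary, [alt_full, alt_half])
    assert track.score("a", 1) == 7


def test_consensus_permutation_invariant():
    primary = make_alignment(["a", "b", "c"], ["WKY", "WKY", "WKY"])
    alts = [
        make_alignment(["a", "b", "c"], ["WKY-", "WKY-", "-WKY"]),
        make_alignment(["a", "b", "c"], ["-WKY", "WKY-", "WKY-"]),
        primary,
    ]
    tracks = [
        consensus_from_alternatives(primary, list(perm))
        for perm in itertools.permutations(alts)
    ]
    assert all(t == tracks[0] for t in tracks)


def test_consensus_rejects_mismatched_members():
    primary = make_alignment(["a", "b"], ["WK", "WK"])
    with pytest.raises(Exception):
        consensus_from_alternatives(primary, [make_alignment(["a", "x"], ["WK", "WK"])])
    with pytest.raises(Exception):
        consensus_from_alternatives(primary, [make_alignment(["a", "b"], ["WY", "WK"])])


@settings(derandomize=True, max_examples=50)
@given(st.integers(min_value=0, max_value=8))
def test_score_file_round_trip_values(tmp_path_factory, base):
    from paranno.alignment import write_score_file

    aln = make_alignment(["a", "b"], ["ARK", "ARK"])
    track = ConsensusTrack({"a": (base, base + 1, 9), "b": (0, base, 1)})
    p = tmp_path_factory.mktemp("scores") / "s.txt"
    write_score_file(track, p)
    assert read_score_file(p, aln) == track


def test_score_file_gapped_dialect(tmp_path):
    aln = make_alignment(["a", "b"], ["AR-K", "ARGK"])
    p = tmp_path / "s.txt"
    p.write_text(">a\n99-9\n>b\n9819\n")
    track = read_score_file(p, aln)
    assert track.scores["a"] == (9, 9, 9)
    assert track.scores["b"] == (9, 8, 1, 9)


def test_score_file_ungapped_dialect(tmp_path):
    aln = make_alignment(["a", "b"], ["AR-K", "ARGK"])
    p = tmp_path / "s.txt"
    p.write_text(">a\n981\n>b\n9819\n")
    assert read_score_file(p, aln).scores["a"] == (9, 8, 1)


def test_score_file_errors(tmp_path):
    aln = make_alignment(["a", "b"], ["ARK", "ARK"])
    long = tmp_path / "long.txt"
    long.write_text(">a\n9999\n>b\n999\n")
    with pytest.raises(ScoreFileError):
        read_score_file(long, aln)
    bad = tmp_path / "bad.txt"
    bad.write_text(">a\n9x9\n>b\n999\n")
    with pytest.raises(ScoreFileError):
        read_score_file(bad, aln)
    with pytest.raises(ValueError):
        ConsensusTrack({"a": (10,)})


def test_round_half_up():
    assert round_half_up(80.5) == 81
    assert round_half_up(6.125) == 6
    assert round_half_up(4.375, 1) == 4.4
    assert round_half_up(1.515, 2) == 1.52
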