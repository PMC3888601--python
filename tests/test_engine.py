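import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

from paranno.alignment import ConsensusTrack, build_residue_map, make_alignment
from paranno.engine import (
    AnnotationTable,
    QualityTier,
    annotate_all_residues,
    annotate_query_variant,
    classify_quality,
    map_paralogue_variant,
    reciprocal,
)
from paranno.variants import PositionError, ProteinVariant, parse_protein_hgvs


@pytest.mark.parametrize(
    "conserved,consensus,n,tier",
    [
        (True, 9, 1, QualityTier.HIGH),
        (True, 4, 1, QualityTier.HIGH),
        (True, 3, 2, QualityTier.MEDIUM),  # 3 is not > 3
        (True, 0, 1, QualityTier.MEDIUM),
        (False, 9, 1, QualityTier.MEDIUM),
        (False, 2, 2, QualityTier.MEDIUM),
        (False, 2, 1, QualityTier.LOW),
        (False, 3, 1, QualityTier.LOW),
    ],
)
def test_classify_quality(conserved, consensus, n, tier):
    assert classify_quality(conserved, consensus, n) is tier


def test_classify_quality_validates_inputs():
    with pytest.raises(ValueError):
        classify_quality(True, 10, 1)
    with pytest.raises(ValueError):
        classify_quality(True, -1, 1)
    with pytest.raises(ValueError):
        classify_quality(True, 5, 0)


@settings(derandomize=True, max_examples=300)
@given(
    conserved=st.booleans(),
    consensus=st.integers(min_value=0, max_value=8),
    n=st.integers(min_value=1, max_value=4),
)
def test_classify_quality_is_monotone(conserved, consensus, n):
    """Upgrading conservation or consensus never lowers the tier."""
    base = classify_quality(conserved, consensus, n)
    assert classify_quality(True, consensus, n) >= base
    assert classify_quality(conserved, consensus + 1, n) >= base
    assert classify_quality(conserved, consensus, n + 1) >= base


def test_map_paralogue_variant_through_toy(toy_bundle):
    b = toy_bundle
    rmap = build_residue_map(b.alignment, "PX", "QRY")
    q = b.protein("QRY")
    m = map_paralogue_variant(
        ProteinVariant("PX", "D", 3, "W"), rmap, b.track, q, b.alignment
    )
    assert (m.query_position, m.query_ref_aa, m.conserved, m.consensus) == (4, "D", True, 9)
    # variant opposite a gap in the query row
    assert map_paralogue_variant(
        ProteinVariant("PX", "K", 9, "M"), rmap, b.track, q, b.alignment
    ) is None
    with pytest.raises(PositionError):
        map_paralogue_variant(
            ProteinVariant("PX", "K", 99, "M"), rmap, b.track, q, b.alignment
        )


def test_annotate_all_residues_toy_oracle(toy_bundle):
    """Hand-enumerated: 3 paralogue variants, 1 at a gap -> 2 annotations on
    2 residues, both HIGH (conserved, consensus 9)."""
    table = annotate_all_residues(toy_bundle)
    assert len(table.annotations) == 2
    assert table.annotated_positions == {2, 4}
    assert table.n_unmapped == 1
    assert all(a.tier is QualityTier.HIGH for a in table.annotations)
    assert dict(table.mapped_variant_counts) == {"PX": 1, "PY": 1}


def test_annotate_query_variant(toy_bundle):
    hits = annotate_query_variant(parse_protein_hgvs("p.D4W", "QRY"), toy_bundle)
    assert len(hits) == 1
    assert hits[0].paralogue_variant.hgvs == "p.D3W"
    # residue with no mapped paralogue variant
    assert annotate_query_variant(parse_protein_hgvs("p.C5A", "QRY"), toy_bundle) == []
    with pytest.raises(Exception):
        annotate_query_variant(parse_protein_hgvs("p.A99V", "QRY"), toy_bundle)


def test_own_gene_evidence_is_not_an_annotation(toy_bundle):
    """QRY's own known variant at residue 1 must not annotate QRY."""
    table = annotate_all_residues(toy_bundle)
    assert 1 not in table.annotated_positions


def test_low_tier_never_in_table(toy_bundle):
    # force a low-quality context: non-conserved, low consensus, single variant
    aln = make_alignment(["QRY", "PX"], ["AK", "GK"])
    track = ConsensusTrack({"QRY": (2, 2), "PX": (2, 2)})
    b = dataclasses.replace(
        toy_bundle,
        alignment=aln,
        track=track,
        proteins={m: dataclasses.replace(toy_bundle.protein("QRY"),
                                         gene_symbol=m, protein_length=2,
                                         sequence=aln.sequence(m))
                  for m in ("QRY", "PX")},
        evidence_by_gene={"PX": toy_bundle.evidence_by_gene["PX"][:0] + [
            dataclasses.replace(toy_bundle.evidence_by_gene["PX"][0],
                                variant=ProteinVariant("PX", "G", 1, "R"))
        ]},
    )
    table = annotate_all_residues(b)
    assert table.annotations == []
    with pytest.raises(ValueError):
        AnnotationTable("QRY", [dataclasses.replace(
            annotate_all_residues(toy_bundle).annotations[0],
            tier=QualityTier.LOW)])


def test_multiplicity_upgrades_to_medium():
    """Two non-conserved low-consensus variants at one residue are MEDIUM."""
    aln = make_alignment(["QRY", "PX", "PY"], ["AKW", "GKW", "SKW"])
    track = ConsensusTrack({m: (1, 1, 1) for m in ("QRY", "PX", "PY")})
    from paranno.engine import FamilyBundle
    from paranno.status import Assertion, EvidenceRecord
    from paranno.variants import GeneProtein

    b = FamilyBundle(
        query="QRY",
        proteins={m: GeneProtein(m, 3, sequence=aln.sequence(m))
                  for m in aln.member_ids},
        alignment=aln,
        track=track,
        evidence_by_gene={
            "PX": [EvidenceRecord(ProteinVariant("PX", "G", 1, "R"),
                                  Assertion.PATHOGENIC_REPORT)],
            "PY": [EvidenceRecord(ProteinVariant("PY", "S", 1, "R"),
                                  Assertion.PATHOGENIC_REPORT)],
        },
    )
    table = annotate_all_residues(b)
    assert len(table.annotations) == 2
    assert {a.tier for a in table.annotations} == {QualityTier.MEDIUM}


def test_annotations_sorted_and_consistent(scn_fixture):
    table = annotate_all_residues(scn_fixture.bundle)
    keys = [a.sort_key() for a in table.annotations]
    assert keys == sorted(keys)
    # stored (conserved, consensus) fields re-derive from alignment and track
    aln = scn_fixture.bundle.alignment
    track = scn_fixture.bundle.track
    for a in table.annotations:
        qaa = aln.sequence(a.query_gene)[a.query_position - 1]
        assert a.query_ref_aa == qaa
        assert a.conserved == (qaa == a.paralogue_variant.ref_aa)
        assert a.consensus == track.score(a.query_gene, a.query_position)
        assert a.tier is not QualityTier.LOW


def test_reciprocal_inverts_mapped_pairs(toy_bundle):
    rec = reciprocal(toy_bundle, "PX")
    back = annotate_all_residues(rec)
    # oracle: invert the forward QRY->PX residue map; every QRY-sourced
    # annotation of PX must land exactly where the inverted map says
    fwd_map = build_residue_map(toy_bundle.alignment, "QRY", "PX")
    qry_pairs = {(a.paralogue_variant.position, a.query_position)
                 for a in back.annotations if a.paralogue_gene == "QRY"}
    assert qry_pairs  # QRY's own evidence does annotate the new query
    for qry_pos, px_pos in qry_pairs:
        assert fwd_map.get(qry_pos) == px_pos
    # reciprocal of reciprocal restores the original bundle
    assert reciprocal(rec, "QRY") == toy_bundle
    with pytest.raises(Exception):
        reciprocal(toy_bundle, "NOPE")


def test_reciprocal_annotates_former_query_evidence(toy_bundle):
    rec = reciprocal(toy_bundle, "PY")
    table = annotate_all_residues(rec)
    # QRY's pathogenic A1V and PX's D3W both land on PY (gap-free columns)
    sources = {(a.paralogue_gene, a.paralogue_variant.hgvs) for a in table.annotations}
    assert ("QRY", "p.A1V") in sources
    assert ("PX", "p.D3W") in sources
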