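import pytest

from paranno.alignment import ConsensusTrack, make_alignment
from paranno.engine import FamilyBundle
from paranno.status import Assertion, EvidenceRecord
from paranno.variants import GeneProtein, ProteinVariant


@pytest.fixture
def toy_alignment():
    """Three members, 11 columns; QRY has a gap at column 10.

    QRY  A R N D C E Q G H - I
    PX   A R - D C E Q G H K I
    PY   A R N D C E Q G H - I
    """
    return make_alignment(
        ["QRY", "PX", "PY"],
        ["ARNDCEQGH-I", "AR-DCEQGHKI", "ARNDCEQGH-I"],
    )


@pytest.fixture
def toy_bundle(toy_alignment):
    """Toy family: 3 paralogue disease variants, one opposite a query gap.

    Hand-enumerated outcome: PX D3W -> QRY position 4 (conserved, HIGH),
    PY R2Q -> QRY position 2 (conserved, HIGH), PX K9M faces the QRY gap
    and is unmapped: 2 annotations on 2 residues.
    """
    aln = toy_alignment
    track = ConsensusTrack(
        {m: tuple([9] * len(aln.sequence(m))) for m in aln.member_ids}
    )
    proteins = {
        m: GeneProtein(m, len(aln.sequence(m)), sequence=aln.sequence(m))
        for m in aln.member_ids
    }
    evidence = {
        "PX": [
            EvidenceRecord(ProteinVariant("PX", "D", 3, "W"),
                           Assertion.PATHOGENIC_REPORT, disease="toyopathy"),
            EvidenceRecord(ProteinVariant("PX", "K", 9, "M"),
                           Assertion.PATHOGENIC_REPORT, disease="toyopathy"),
        ],
        "PY": [
            EvidenceRecord(ProteinVariant("PY", "R", 2, "Q"),
                           Assertion.PATHOGENIC_REPORT, disease="toyodystrophy"),
        ],
        "QRY": [
            EvidenceRecord(ProteinVariant("QRY", "A", 1, "V"),
                           Assertion.PATHOGENIC_REPORT),
        ],
    }
    return FamilyBundle(
        query="QRY",
        proteins=proteins,
        alignment=aln,
        track=track,
        evidence_by_gene=evidence,
    )


@pytest.fixture(scope="session")
def ryr_fixture():
    from paranno.fixtures import load_paper_fixture

    return load_paper_fixture("RYR")


@pytest.fixture(scope="session")
def scn_fixture():
    from paranno.fixtures import load_paper_fixture

    return load_paper_fixture("SCN")
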