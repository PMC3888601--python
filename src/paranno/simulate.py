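"""Synthetic paralogue-family generator for end-to-end recovery testing.

The simulator emulates the signal the annotation-transfer method exploits: a
set of variation-intolerant residues shared by the whole family (never
substituted during divergence), on which disease-causing variants are
planted, while benign variants fall elsewhere.  It does NOT emulate indels,
phylogenetic tree structure or realistic substitution matrices — alternative
alignments differ from the primary only by local column perturbations at a
configurable noise rate, which is the knob that degrades the consensus
score.  Recovery metrics therefore measure the pipeline's bookkeeping and
quality filtering, not alignment accuracy on real proteins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .alignment import ConsensusTrack, FamilyAlignment, consensus_from_alternatives, make_alignment
from .engine import AnnotationTable, FamilyBundle
from .status import Assertion, EvidenceRecord
from .variants import AA_ALPHABET, GeneProtein, ProteinVariant

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimParams:
    """Study conditions for one simulated family.

    Defaults describe a small but non-trivial family: four members of 200
    residues, 10% divergence per member, 12 shared intolerant residues
    carrying 3 planted disease variants per member, 3 benign variants per
    member elsewhere, and a 5% column-perturbation rate in each of 3
    alternative alignments.
    """

    n_members: int = 4
    protein_length: int = 200
    substitution_rate: float = 0.1
    n_intolerant_residues: int = 12
    n_pathogenic_variants_per_member: int = 3
    n_benign_variants_per_member: int = 3
    alignment_noise: float = 0.05
    n_alternatives: int = 3
    mislabel_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for r, label in (
            (self.substitution_rate, "substitution_rate"),
            (self.alignment_noise, "alignment_noise"),
            (self.mislabel_fraction, "mislabel_fraction"),
        ):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{label} {r} outside [0, 1]")
        if self.n_members < 2:
            raise ValueError("need at least 2 family members")
        if self.n_intolerant_residues > self.protein_length:
            raise ValueError("more intolerant residues than residues")
        if self.n_pathogenic_variants_per_member > self.n_intolerant_residues:
            raise ValueError("more planted pathogenic variants than intolerant residues")
        if (self.n_benign_variants_per_member
                > self.protein_length - self.n_intolerant_residues):
            raise ValueError("more planted benign variants than tolerant residues")


@dataclass
class GroundTruth:
    """What the simulator planted, for scoring recovery."""

    intolerant: set[int]
    pathogenic_by_member: dict[str, list[ProteinVariant]]
    benign_by_member: dict[str, list[ProteinVariant]]
    mislabelled_by_member: dict[str, list[ProteinVariant]] = field(default_factory=dict)


def _mutate(seq: list[str], rate: float, protected: set[int], rng) -> list[str]:
    out = list(seq)
    for i in range(len(out)):
        if (i + 1) in protected:
            continue
        if rng.random() < rate:
            choices = [a for a in AA_ALPHABET if a != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return out


def _perturbed_alternative(
    primary_rows: dict[str, str], query: str, intolerant: set[int],
    noise: float, rng,
) -> FamilyAlignment:
    """A gapped variant of the identity alignment with local column shifts.

    At each perturbed position c (both c and c+1 tolerant), one non-query
    member's residues at columns c, c+1 are shifted one column right, via a
    gap at c and a member-specific insertion column after c+1.  Ungapped
    sequences are unchanged.
    """
    members = list(primary_rows)
    length = len(next(iter(primary_rows.values())))
    candidates = [
        c for c in range(1, length)  # 1-based c, uses c and c+1
        if c not in intolerant and (c + 1) not in intolerant
    ]
    chosen = sorted(c for c in candidates if rng.random() < noise)
    # drop overlapping perturbations (c and c+1 windows must not touch)
    pruned, last = [], -10
    for c in chosen:
        if c > last + 1:
            pruned.append(c)
            last = c
    others = [m for m in members if m != query] or members
    events = [(c, others[rng.integers(len(others))]) for c in pruned]

    out = {m: [] for m in members}
    pos = 0
    event_at = {c: m for c, m in events}
    while pos < length:
        c = pos + 1
        if c in event_at:
            target = event_at[c]
            x1 = {m: primary_rows[m][pos] for m in members}
            x2 = {m: primary_rows[m][pos + 1] for m in members}
            for m in members:
                if m == target:
                    out[m].extend(["-", x1[m], x2[m]])
                else:
                    out[m].extend([x1[m], x2[m], "-"])
            pos += 2
        else:
            for m in members:
                out[m].append(primary_rows[m][pos])
            pos += 1
    return make_alignment(members, ["".join(out[m]) for m in members])


def simulate_family(params: SimParams) -> tuple[FamilyBundle, GroundTruth]:
    """Simulate a paralogue family; deterministic under ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    L = params.protein_length
    members = [f"P{i + 1}" for i in range(params.n_members)]
    query = members[0]

    ancestor = [AA_ALPHABET[i] for i in rng.integers(len(AA_ALPHABET), size=L)]
    intolerant = set(
        int(p) + 1 for p in rng.choice(L, size=params.n_intolerant_residues, replace=False)
    )
    sequences = {
        m: _mutate(ancestor, params.substitution_rate, intolerant, rng) for m in members
    }

    truth = GroundTruth(intolerant=intolerant, pathogenic_by_member={},
                        benign_by_member={}, mislabelled_by_member={})
    evidence: dict[str, list[EvidenceRecord]] = {m: [] for m in members}
    intol_sorted = sorted(intolerant)
    tolerant_sorted = [p for p in range(1, L + 1) if p not in intolerant]
    for m in members:
        seq = sequences[m]

        def plant(pool: Sequence[int], k: int) -> list[ProteinVariant]:
            picks = rng.choice(len(pool), size=k, replace=False)
            out = []
            for idx in sorted(int(i) for i in picks):
                pos = pool[idx]
                ref = seq[pos - 1]
                alts = [a for a in AA_ALPHABET if a != ref]
                out.append(ProteinVariant(m, ref, pos, alts[rng.integers(len(alts))]))
            return out

        path = plant(intol_sorted, params.n_pathogenic_variants_per_member)
        benign = plant(tolerant_sorted, params.n_benign_variants_per_member)
        truth.pathogenic_by_member[m] = path
        truth.benign_by_member[m] = benign
        mislabelled = [
            v for v in benign if rng.random() < params.mislabel_fraction
        ]
        truth.mislabelled_by_member[m] = mislabelled
        for v in path + mislabelled:
            evidence[m].append(
                EvidenceRecord(v, Assertion.PATHOGENIC_REPORT, source="simulated")
            )
        for v in benign:
            if v not in mislabelled:
                evidence[m].append(
                    EvidenceRecord(v, Assertion.BENIGN_REPORT, source="simulated")
                )

    primary_rows = {m: "".join(sequences[m]) for m in members}
    primary = make_alignment(members, [primary_rows[m] for m in members])
    alternatives = [
        _perturbed_alternative(primary_rows, query, intolerant,
                               params.alignment_noise, rng)
        for _ in range(params.n_alternatives)
    ]
    track = consensus_from_alternatives(primary, alternatives)

    proteins = {m: GeneProtein(m, L, sequence=primary_rows[m]) for m in members}
    bundle = FamilyBundle(
        query=query,
        proteins=proteins,
        alignment=primary,
        track=track,
        evidence_by_gene=evidence,
        consensus_is_recomputed=True,
    )
    logger.info(
        "simulated family: %d members, length %d, %d intolerant residues",
        params.n_members, L, params.n_intolerant_residues,
    )
    return bundle, truth


@dataclass(frozen=True)
class RecoveryMetrics:
    """PPV/sensitivity of annotated residues against the planted truth."""

    ppv: Optional[float]  # percent; None when nothing was annotated
    sensitivity: float  # percent of intolerant residues annotated
    n_annotated: int
    n_intolerant: int


def recovery_metrics(
    truth: GroundTruth, table: AnnotationTable, status=None
) -> RecoveryMetrics:
    """Score annotated residues against the planted intolerant set.

    ``status`` (a StatusTable) is accepted for interface symmetry and only
    length-checked; the metrics need just the annotation table and truth.
    """
    if status is not None and truth.intolerant and max(truth.intolerant) > status.protein_length:
        raise ValueError("truth positions exceed status table length")
    annotated = table.annotated_positions
    hits = annotated & truth.intolerant
    ppv = 100.0 * len(hits) / len(annotated) if annotated else None
    sensitivity = (
        100.0 * len(hits) / len(truth.intolerant) if truth.intolerant else 0.0
    )
    return RecoveryMetrics(ppv, sensitivity, len(annotated), len(truth.intolerant))
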