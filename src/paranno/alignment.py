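"""Family multiple alignments, consensus scores and residue-to-residue maps.

A family alignment holds one gapped row per member (gap character ``-``).
Two residues of different members correspond when they occupy the same
alignment column; residue maps derived this way are partial (gap-opposite
residues are unmapped), injective and symmetric.

The per-residue consensus score (0-9) measures agreement between alternative
alignments of the same sequences.  When a score file is supplied it is
authoritative; otherwise the package computes its own partner-reproduction
score: for each residue, the fraction of its primary-alignment partners
reproduced by each alternative, averaged over alternatives and scaled to 0-9
(rounded half-up).  A residue aligned only to gaps scores 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import AlignIO

logger = logging.getLogger(__name__)

GAP = "-"


class AlignmentError(ValueError):
    pass


class RaggedAlignmentError(AlignmentError):
    pass


class DuplicateMemberError(AlignmentError):
    pass


class EmptyAlignmentError(AlignmentError):
    pass


class UnknownMemberError(KeyError):
    pass


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (0.5 -> 1), as printed reports expect."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FamilyAlignment:
    """A multiple alignment of a paralogue family (equal-length gapped rows)."""

    member_ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        if len(self.member_ids) < 2:
            raise EmptyAlignmentError("an alignment needs at least 2 rows")
        if len(set(self.member_ids)) != len(self.member_ids):
            dupes = sorted({m for m in self.member_ids if self.member_ids.count(m) > 1})
            raise DuplicateMemberError(f"duplicate member ids: {dupes}")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise RaggedAlignmentError(f"rows have unequal lengths: {sorted(lengths)}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def row(self, member: str) -> str:
        try:
            return self.rows[self.member_ids.index(member)]
        except ValueError:
            raise UnknownMemberError(member) from None

    def sequence(self, member: str) -> str:
        """Ungapped sequence of a member."""
        return self.row(member).replace(GAP, "")

    def column_positions(self, member: str) -> list[Optional[int]]:
        """Per column: the member's 1-based residue index, or None at gaps."""
        out: list[Optional[int]] = []
        pos = 0
        for ch in self.row(member):
            if ch == GAP:
                out.append(None)
            else:
                pos += 1
                out.append(pos)
        return out

    def residue_columns(self, member: str) -> list[int]:
        """Per residue (1-based, index 0 unused): its column index (0-based)."""
        cols = [-1]
        for i, ch in enumerate(self.row(member)):
            if ch != GAP:
                cols.append(i)
        return cols


def _clean_row(seq: str) -> str:
    return seq.upper().replace(".", GAP)


def make_alignment(member_ids: Sequence[str], rows: Sequence[str]) -> FamilyAlignment:
    """Build a validated FamilyAlignment, normalising case and gap characters."""
    return FamilyAlignment(tuple(member_ids), tuple(_clean_row(r) for r in rows))


def _sniff_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "clustal" if line.upper().startswith("CLUSTAL") else "fasta"
    raise EmptyAlignmentError(f"{path}: empty file")


def read_alignment(path, fmt: Optional[str] = None) -> FamilyAlignment:
    """Read an aligned-FASTA or Clustal family alignment.

    ``fmt`` is "fasta" or "clustal"; when omitted it is sniffed from the
    first non-blank line.
    """
    path = Path(path)
    fmt = fmt or _sniff_format(path)
    try:
        msa = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        # Biopython raises plain ValueError for ragged fasta records
        if "length" in str(exc).lower():
            raise RaggedAlignmentError(f"{path}: {exc}") from exc
        raise AlignmentError(f"{path}: {exc}") from exc
    ids = [rec.id for rec in msa]
    rows = [str(rec.seq) for rec in msa]
    aln = make_alignment(ids, rows)
    logger.info("read %d rows x %d columns from %s", len(ids), aln.n_columns, path)
    return aln


def write_alignment(aln: FamilyAlignment, path) -> None:
    """Write as aligned FASTA (one record per member)."""
    with open(path, "w") as fh:
        for member, row in zip(aln.member_ids, aln.rows):
            fh.write(f">{member}\n{row}\n")


@dataclass(frozen=True)
class ResidueMap:
    """Partial 1-based position map between two family members."""

    source: str
    target: str
    forward: Mapping[int, int]

    def __post_init__(self):
        values = list(self.forward.values())
        if len(set(values)) != len(values):
            raise AlignmentError("residue map is not injective")

    def get(self, source_position: int) -> Optional[int]:
        return self.forward.get(source_position)

    def invert(self) -> "ResidueMap":
        return ResidueMap(self.target, self.source,
                          {v: k for k, v in self.forward.items()})

    def __len__(self) -> int:
        return len(self.forward)


def build_residue_map(aln: FamilyAlignment, src: str, dst: str) -> ResidueMap:
    """Map src residue positions onto dst positions via shared columns.

    Columns where either member has a gap contribute no pair.
    """
    src_pos = aln.column_positions(src)
    dst_pos = aln.column_positions(dst)
    forward = {s: d for s, d in zip(src_pos, dst_pos) if s is not None and d is not None}
    return ResidueMap(src, dst, forward)


@dataclass(frozen=True)
class ConsensusTrack:
    """Per member, one integer score in [0, 9] per ungapped residue."""

    scores: Mapping[str, tuple[int, ...]]

    def __post_init__(self):
        for member, vals in self.scores.items():
            bad = [v for v in vals if not 0 <= v <= 9]
            if bad:
                raise ValueError(f"{member}: consensus scores outside [0, 9]: {bad[:5]}")

    def score(self, member: str, position: int) -> int:
        try:
            vals = self.scores[member]
        except KeyError:
            raise UnknownMemberError(member) from None
        if not 1 <= position <= len(vals):
            raise AlignmentError(
                f"{member}: no residue {position} (length {len(vals)})"
            )
        return vals[position - 1]


def _partner_sets(aln: FamilyAlignment) -> dict[str, list[set]]:
    """For each member, per residue (0-based list), the set of
    (other_member, other_residue_position) partners in this alignment."""
    positions = {m: aln.column_positions(m) for m in aln.member_ids}
    partners: dict[str, list[set]] = {
        m: [set() for _ in range(len(aln.sequence(m)))] for m in aln.member_ids
    }
    for col in range(aln.n_columns):
        occupied = [(m, positions[m][col]) for m in aln.member_ids
                    if positions[m][col] is not None]
        for m, p in occupied:
            partners[m][p - 1].update((om, op) for om, op in occupied if om != m)
    return partners


def _check_same_family(primary: FamilyAlignment, other: FamilyAlignment) -> None:
    if set(primary.member_ids) != set(other.member_ids):
        raise AlignmentError("alternative alignment has different members")
    for m in primary.member_ids:
        if primary.sequence(m) != other.sequence(m):
            raise AlignmentError(f"{m}: ungapped sequence differs between alignments")


def consensus_from_alternatives(
    primary: FamilyAlignment, alternatives: Sequence[FamilyAlignment]
) -> ConsensusTrack:
    """Partner-reproduction consensus score on the 0-9 scale.

    For residue r with primary partner set P: each alternative contributes
    |P reproduced| / |P|; the score is round_half_up(9 * mean).  Residues
    with no primary partner (aligned only to gaps) score 0.
    """
    if not alternatives:
        raise AlignmentError("at least one alternative alignment is required")
    for alt in alternatives:
        _check_same_family(primary, alt)
    prim = _partner_sets(primary)
    alts = [_partner_sets(a) for a in alternatives]
    scores = {}
    for m in primary.member_ids:
        vals = []
        for r0, P in enumerate(prim[m]):
            if not P:
                vals.append(0)
                continue
            frac = sum(len(P & a[m][r0]) / len(P) for a in alts) / len(alts)
            vals.append(int(round_half_up(9 * frac)))
        scores[m] = tuple(vals)
    return ConsensusTrack(scores)


class ScoreFileError(ValueError):
    pass


def read_score_file(path, aln: FamilyAlignment) -> ConsensusTrack:
    """Read a per-residue score track in the score_ascii-style dialect.

    The file is FASTA-shaped: ``>member`` headers followed by digit strings
    (0-9) either aligned to the member's gapped row (gaps allowed, skipped)
    or ungapped with one digit per residue.
    """
    path = Path(path)
    blocks: dict[str, str] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                blocks[name] = ""
            elif name is not None:
                blocks[name] += line
    if not blocks:
        raise ScoreFileError(f"{path}: no score records")
    scores = {}
    for member, digits in blocks.items():
        seq_len = len(aln.sequence(member))  # raises UnknownMemberError
        row = aln.row(member)
        if len(digits) == len(row):
            # gapped form: digits line up with the gapped row
            pairs = [(d, c) for d, c in zip(digits, row) if c != GAP]
            if any(d == GAP for d, _ in pairs):
                raise ScoreFileError(f"{path}: {member}: gap in score over a residue")
            digits = "".join(d for d, _ in pairs)
        else:
            digits = digits.replace(GAP, "")
        if len(digits) != seq_len:
            raise ScoreFileError(
                f"{path}: {member}: {len(digits)} scores for {seq_len} residues"
            )
        if not digits.isdigit():
            bad = sorted(set(digits) - set("0123456789"))
            raise ScoreFileError(f"{path}: {member}: non-digit score characters {bad}")
        scores[member] = tuple(int(d) for d in digits)
    logger.info("read scores for %d members from %s", len(scores), path)
    return ConsensusTrack(scores)


def write_score_file(track: ConsensusTrack, path) -> None:
    """Write a ConsensusTrack in the ungapped digit-string dialect."""
    with open(path, "w") as fh:
        for member, vals in track.scores.items():
            fh.write(f">{member}\n{''.join(str(v) for v in vals)}\n")
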