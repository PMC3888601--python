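"""Domain types for genes, proteins and missense variants, with HGVS parsing.

Protein coordinates are 1-based throughout; only single-residue missense
substitutions are modelled.  Nonsense and synonymous changes are rejected at
parse time with distinct error kinds so that bulk evidence loading can count
and log skipped rows instead of aborting.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

AA_THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}

_STOP_TOKENS = {"X", "*", "Ter", "TER", "Stop"}


class VariantError(ValueError):
    """Base class for variant parsing/validation failures."""

    kind = "variant"


class HgvsSyntaxError(VariantError):
    """The string is not a simple substitution in HGVS-like syntax."""

    kind = "syntax"


class NonsenseVariantError(VariantError):
    """The alternate allele is a stop codon (nonsense, not missense)."""

    kind = "nonsense"


class SynonymousVariantError(VariantError):
    """Reference and alternate residues are identical."""

    kind = "synonymous"


class SequenceMismatchError(VariantError):
    """Stated reference residue disagrees with the protein sequence."""

    kind = "ref_mismatch"


class PositionError(VariantError):
    """Variant position lies outside the protein."""

    kind = "position"


@dataclass(frozen=True)
class GeneProtein:
    """One protein isoform of a gene, with optional full sequence."""

    gene_symbol: str
    protein_length: int
    sequence: Optional[str] = None
    transcript_ids: tuple = ()

    def __post_init__(self):
        if self.protein_length < 1:
            raise ValueError(f"{self.gene_symbol}: protein_length must be >= 1")
        if self.sequence is not None and len(self.sequence) != self.protein_length:
            raise ValueError(
                f"{self.gene_symbol}: sequence length {len(self.sequence)} "
                f"!= protein_length {self.protein_length}"
            )

    def residue(self, position: int) -> str:
        """1-based residue lookup; requires a sequence."""
        if self.sequence is None:
            raise ValueError(f"{self.gene_symbol} has no sequence")
        if not 1 <= position <= self.protein_length:
            raise PositionError(
                f"position {position} outside {self.gene_symbol} "
                f"(length {self.protein_length})"
            )
        return self.sequence[position - 1]


@dataclass(frozen=True, order=True)
class ProteinVariant:
    """A single missense substitution: ref residue, 1-based position, alt."""

    gene_symbol: str
    ref_aa: str
    position: int
    alt_aa: str

    def __post_init__(self):
        for aa, label in ((self.ref_aa, "ref"), (self.alt_aa, "alt")):
            if aa not in AA_ALPHABET:
                raise VariantError(f"{label} residue {aa!r} is not a standard amino acid")
        if self.position < 1:
            raise PositionError(f"position {self.position} must be >= 1")
        if self.ref_aa == self.alt_aa:
            raise SynonymousVariantError(
                f"p.{self.ref_aa}{self.position}{self.alt_aa} is synonymous"
            )

    @property
    def hgvs(self) -> str:
        return f"p.{self.ref_aa}{self.position}{self.alt_aa}"

    def __str__(self) -> str:
        return f"{self.gene_symbol}:{self.hgvs}" if self.gene_symbol else self.hgvs


@dataclass(frozen=True)
class CdsVariant:
    """A coding-DNA substitution, carried as provenance only."""

    gene_symbol: str
    cds_position: int
    ref_base: str
    alt_base: str

    def __post_init__(self):
        if self.cds_position < 1:
            raise PositionError(f"cds position {self.cds_position} must be >= 1")
        for b, label in ((self.ref_base, "ref"), (self.alt_base, "alt")):
            if b not in "ACGT":
                raise VariantError(f"{label} base {b!r} is not one of ACGT")
        if self.ref_base == self.alt_base:
            raise SynonymousVariantError(
                f"c.{self.cds_position}{self.ref_base}>{self.alt_base}: ref == alt"
            )

    @property
    def hgvs(self) -> str:
        return f"c.{self.cds_position}{self.ref_base}>{self.alt_base}"


_AA_TOKEN = r"(?:[A-Z\*]|[A-Z][a-z]{2})"
_PROTEIN_RE = re.compile(rf"^(?:p\.)?({_AA_TOKEN})(\d+)({_AA_TOKEN})$")
_CDS_RE = re.compile(r"^(?:c\.)?(\d+)([ACGT])>([ACGT])$")
_REJECT_RE = re.compile(r"(fs|del|ins|dup|ext|=)", re.IGNORECASE)


def _normalize_aa(token: str, *, what: str) -> str:
    """Normalise a 1- or 3-letter residue token to a 1-letter code.

    Stop tokens return "*" so the caller can raise the nonsense error kind.
    """
    if token in _STOP_TOKENS:
        return "*"
    if len(token) == 3:
        if token not in AA_THREE_TO_ONE:
            raise HgvsSyntaxError(f"unknown 3-letter residue code {token!r}")
        return AA_THREE_TO_ONE[token]
    if token not in AA_ALPHABET:
        raise HgvsSyntaxError(f"unknown residue code {token!r} in {what}")
    return token


def parse_protein_hgvs(s: str, gene_symbol: str = "") -> ProteinVariant:
    """Parse a protein-level HGVS substitution such as ``p.R176Q``.

    Accepts 1- or 3-letter amino-acid codes (``p.Gly357Ser``); the leading
    ``p.`` is optional.  Nonsense (stop alt), synonymous (ref == alt) and
    non-substitution syntax (frameshift, indel, ...) each raise a distinct
    :class:`VariantError` subclass.
    """
    s = s.strip()
    if _REJECT_RE.search(s):
        raise HgvsSyntaxError(f"{s!r} is not a simple substitution")
    m = _PROTEIN_RE.match(s)
    if not m:
        raise HgvsSyntaxError(f"cannot parse protein HGVS {s!r}")
    ref = _normalize_aa(m.group(1), what=s)
    alt = _normalize_aa(m.group(3), what=s)
    if ref == "*":
        raise HgvsSyntaxError(f"{s!r}: reference residue is a stop")
    if alt == "*":
        raise NonsenseVariantError(f"{s!r} is a nonsense variant, not missense")
    if ref == alt:
        raise SynonymousVariantError(f"{s!r} is synonymous")
    return ProteinVariant(gene_symbol, ref, int(m.group(2)), alt)


def parse_cds_hgvs(s: str, gene_symbol: str = "") -> CdsVariant:
    """Parse a cDNA substitution such as ``c.527G>A``."""
    s = s.strip()
    m = _CDS_RE.match(s)
    if not m:
        raise HgvsSyntaxError(f"cannot parse cDNA HGVS {s!r}")
    return CdsVariant(gene_symbol, int(m.group(1)), m.group(2), m.group(3))


def format_protein_hgvs(v: ProteinVariant) -> str:
    """Canonical 1-letter HGVS string for a variant (inverse of parsing)."""
    return v.hgvs


def validate_against_sequence(v: ProteinVariant, p: GeneProtein) -> ProteinVariant:
    """Check that the variant's reference residue matches the protein sequence.

    Returns the variant unchanged if ``sequence[v.position]`` (1-based) equals
    ``v.ref_aa``; raises :class:`PositionError` or
    :class:`SequenceMismatchError` otherwise.
    """
    found = p.residue(v.position)
    if found != v.ref_aa:
        raise SequenceMismatchError(
            f"{p.gene_symbol} position {v.position}: variant states "
            f"{v.ref_aa}, sequence has {found}"
        )
    return v


@dataclass
class SkippedRow:
    """Record of an evidence row rejected during bulk parsing."""

    gene: str
    raw: str
    kind: str
    message: str


def parse_variant_rows(
    rows: Sequence[tuple[str, str]],
) -> tuple[list[ProteinVariant], list[SkippedRow]]:
    """Parse (gene, protein_hgvs) pairs, collecting rejects instead of raising."""
    parsed: list[ProteinVariant] = []
    skipped: list[SkippedRow] = []
    for gene, hgvs in rows:
        try:
            parsed.append(parse_protein_hgvs(hgvs, gene))
        except VariantError as exc:
            skipped.append(SkippedRow(gene, hgvs, exc.kind, str(exc)))
    return parsed, skipped
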