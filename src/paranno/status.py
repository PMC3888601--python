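"""Per-residue mutation status from collated clinical and population evidence.

Each residue of the query protein is classified as PATHOGENIC, BENIGN,
UNCERTAIN or UNANNOTATED:

* pathogenic — one or more missense variants reported disease-causing;
* benign — reported benign, or population frequency incompatible with a
  rare Mendelian disease (MAF >= 0.01 in any population with more than one
  observation in total);
* uncertain — conflicting benign and pathogenic reports at the residue
  (same or different variants), or only weak records (dbSNP entries without
  usable frequency, frequency records failing the benign rule);
* unannotated — no known missense variant.
"""

from __future__ import annotations

import enum
import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .variants import (
    GeneProtein,
    PositionError,
    ProteinVariant,
    SkippedRow,
    VariantError,
    parse_protein_hgvs,
)

logger = logging.getLogger(__name__)

BENIGN_MAF_THRESHOLD = 0.01
BENIGN_MIN_OBSERVATIONS = 2  # "more than one observation"


class Assertion(str, enum.Enum):
    PATHOGENIC_REPORT = "PATHOGENIC_REPORT"
    BENIGN_REPORT = "BENIGN_REPORT"
    DBSNP_NO_FREQ = "DBSNP_NO_FREQ"


class ResidueStatus(str, enum.Enum):
    PATHOGENIC = "PATHOGENIC"
    BENIGN = "BENIGN"
    UNCERTAIN = "UNCERTAIN"
    UNANNOTATED = "UNANNOTATED"


STATUS_ORDER = (
    ResidueStatus.PATHOGENIC,
    ResidueStatus.BENIGN,
    ResidueStatus.UNCERTAIN,
    ResidueStatus.UNANNOTATED,
)


@dataclass(frozen=True)
class EvidenceRecord:
    """One literature/database report about one variant."""

    variant: ProteinVariant
    assertion: Assertion
    source: str = ""
    pmid: str = ""
    disease: str = ""


@dataclass(frozen=True)
class FrequencyRecord:
    """One population-frequency observation of one variant."""

    variant: ProteinVariant
    population: str
    maf: float
    observations: int

    def __post_init__(self):
        if not 0.0 <= self.maf <= 1.0:
            raise ValueError(f"MAF {self.maf} outside [0, 1]")
        if self.observations < 0:
            raise ValueError("observations must be >= 0")


def is_population_benign(freqs: Sequence[FrequencyRecord]) -> bool:
    """Benign-by-frequency rule for one variant.

    True iff some population reaches MAF >= 0.01 and the variant has been
    observed more than once in total across datasets.
    """
    if not freqs:
        return False
    variants = {f.variant for f in freqs}
    if len(variants) > 1:
        raise ValueError(f"frequency records span several variants: {variants}")
    total_obs = sum(f.observations for f in freqs)
    return total_obs >= BENIGN_MIN_OBSERVATIONS and any(
        f.maf >= BENIGN_MAF_THRESHOLD for f in freqs
    )


def classify_residue(
    evidence: Sequence[EvidenceRecord],
    freqs: Sequence[FrequencyRecord] = (),
) -> ResidueStatus:
    """Classify one residue from all records whose variants hit it.

    Conflict dominates: any residue with both pathogenic and benign support
    is UNCERTAIN, regardless of how many reports are on each side.
    """
    positions = {r.variant.position for r in evidence} | {f.variant.position for f in freqs}
    if len(positions) > 1:
        raise ValueError(f"records span several positions: {sorted(positions)}")
    if not evidence and not freqs:
        return ResidueStatus.UNANNOTATED

    pathogenic = any(r.assertion is Assertion.PATHOGENIC_REPORT for r in evidence)
    benign = any(r.assertion is Assertion.BENIGN_REPORT for r in evidence)
    by_variant: dict[ProteinVariant, list[FrequencyRecord]] = defaultdict(list)
    for f in freqs:
        by_variant[f.variant].append(f)
    benign = benign or any(is_population_benign(group) for group in by_variant.values())

    if pathogenic and benign:
        return ResidueStatus.UNCERTAIN
    if pathogenic:
        return ResidueStatus.PATHOGENIC
    if benign:
        return ResidueStatus.BENIGN
    # only weak records: dbSNP without frequency, or sub-threshold frequencies
    return ResidueStatus.UNCERTAIN


@dataclass
class StatusTable:
    """Residue statuses for one protein, positions 1..protein_length."""

    gene: str
    statuses: tuple[ResidueStatus, ...]

    @property
    def protein_length(self) -> int:
        return len(self.statuses)

    def status(self, position: int) -> ResidueStatus:
        if not 1 <= position <= self.protein_length:
            raise PositionError(f"position {position} outside {self.gene}")
        return self.statuses[position - 1]

    def counts(self) -> dict[ResidueStatus, int]:
        c = {s: 0 for s in STATUS_ORDER}
        for s in self.statuses:
            c[s] += 1
        return c

    def count_vector(self) -> tuple[int, int, int, int]:
        """(pathogenic, benign, uncertain, unannotated) — sums to length."""
        c = self.counts()
        return tuple(c[s] for s in STATUS_ORDER)

    def positions_with(self, status: ResidueStatus) -> set[int]:
        return {i + 1 for i, s in enumerate(self.statuses) if s is status}


def build_status_table(
    gene: GeneProtein,
    evidence: Iterable[EvidenceRecord],
    freqs: Iterable[FrequencyRecord] = (),
) -> StatusTable:
    """Classify every residue of a protein from collated evidence."""
    ev_by_pos: dict[int, list[EvidenceRecord]] = defaultdict(list)
    fr_by_pos: dict[int, list[FrequencyRecord]] = defaultdict(list)
    for r in evidence:
        if r.variant.position > gene.protein_length:
            raise PositionError(
                f"{gene.gene_symbol} {r.variant.hgvs}: position beyond protein "
                f"length {gene.protein_length}"
            )
        ev_by_pos[r.variant.position].append(r)
    for f in freqs:
        if f.variant.position > gene.protein_length:
            raise PositionError(
                f"{gene.gene_symbol} {f.variant.hgvs}: position beyond protein "
                f"length {gene.protein_length}"
            )
        fr_by_pos[f.variant.position].append(f)
    statuses = tuple(
        classify_residue(ev_by_pos.get(p, ()), fr_by_pos.get(p, ()))
        for p in range(1, gene.protein_length + 1)
    )
    return StatusTable(gene.gene_symbol, statuses)


# --- tabular IO ------------------------------------------------------------

def read_evidence_table(path) -> tuple[list[EvidenceRecord], list[SkippedRow]]:
    """Read a status-evidence TSV (gene, protein_hgvs, assertion, source, pmid).

    Rows whose HGVS fails missense parsing are skipped and returned, not fatal.
    Unknown columns are preserved by ignoring them; '#' lines are comments.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    records: list[EvidenceRecord] = []
    skipped: list[SkippedRow] = []
    for _, row in df.iterrows():
        try:
            v = parse_protein_hgvs(row["protein_hgvs"], row["gene"])
            records.append(
                EvidenceRecord(
                    v,
                    Assertion(row["assertion"]),
                    source=row.get("source", ""),
                    pmid=row.get("pmid", ""),
                    disease=row.get("disease", ""),
                )
            )
        except VariantError as exc:
            skipped.append(SkippedRow(row["gene"], row["protein_hgvs"], exc.kind, str(exc)))
    if skipped:
        logger.warning("%s: skipped %d non-missense rows", path, len(skipped))
    logger.info("%s: %d evidence records", path, len(records))
    return records, skipped


def read_frequency_table(path) -> tuple[list[FrequencyRecord], list[SkippedRow]]:
    """Read a frequency TSV (gene, protein_hgvs, population, maf, observations)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    records: list[FrequencyRecord] = []
    skipped: list[SkippedRow] = []
    for _, row in df.iterrows():
        try:
            v = parse_protein_hgvs(row["protein_hgvs"], row["gene"])
            records.append(
                FrequencyRecord(
                    v, row["population"], float(row["maf"]), int(row["observations"])
                )
            )
        except VariantError as exc:
            skipped.append(SkippedRow(row["gene"], row["protein_hgvs"], exc.kind, str(exc)))
    logger.info("%s: %d frequency records", path, len(records))
    return records, skipped
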