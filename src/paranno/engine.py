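"""The paralogue-annotation engine.

A *family bundle* holds everything needed to annotate one query gene: the
family alignment, a per-residue consensus track, per-gene disease-variant
evidence, the query gene's own status evidence, and optional region
definitions.  Annotation maps every paralogue residue carrying a
disease-causing missense variant onto the alignment-equivalent query
residue and grades the transfer:

* HIGH    — reference residue conserved between the two proteins AND
            alignment consensus score > 3;
* MEDIUM  — conserved OR consensus > 3 OR more than one paralogue variant
            mapping to the same query residue;
* LOW     — none of these; excluded from all tables and statistics.

Annotation is reciprocal: swapping the query role re-uses the same
alignment and evidence to annotate any other family member.
"""

from __future__ import annotations

import enum
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

from .alignment import (
    ConsensusTrack,
    FamilyAlignment,
    ResidueMap,
    UnknownMemberError,
    build_residue_map,
    consensus_from_alternatives,
    read_alignment,
    read_score_file,
)
from .status import EvidenceRecord, FrequencyRecord, StatusTable, Assertion
from .stats import RegionSet
from .variants import (
    GeneProtein,
    PositionError,
    ProteinVariant,
    SkippedRow,
    VariantError,
    parse_protein_hgvs,
    validate_against_sequence,
)

logger = logging.getLogger(__name__)


class QualityTier(enum.IntEnum):
    """Mapping quality; higher is better, LOW is discarded."""

    LOW = 0
    MEDIUM = 1
    HIGH = 2


def classify_quality(conserved: bool, consensus: int, n_variants_at_query_residue: int) -> QualityTier:
    """Grade one paralogue-to-query mapping.

    ``n_variants_at_query_residue`` counts distinct paralogue variants
    (across all paralogues) mapping to the same query residue.
    """
    if not 0 <= consensus <= 9:
        raise ValueError(f"consensus score {consensus} outside [0, 9]")
    if n_variants_at_query_residue < 1:
        raise ValueError("a mapped residue has at least one variant")
    if conserved and consensus > 3:
        return QualityTier.HIGH
    if conserved or consensus > 3 or n_variants_at_query_residue > 1:
        return QualityTier.MEDIUM
    return QualityTier.LOW


@dataclass(frozen=True)
class ParalogueAnnotation:
    """One paralogue disease variant mapped onto one query residue."""

    query_gene: str
    query_position: int
    query_ref_aa: str
    paralogue_gene: str
    paralogue_variant: ProteinVariant
    disease: str
    pmid: str
    consensus: int
    conserved: bool
    tier: QualityTier

    def sort_key(self):
        return (
            -int(self.tier),
            -self.consensus,
            self.paralogue_gene,
            self.query_position,
            self.paralogue_variant.hgvs,
        )


@dataclass(frozen=True)
class MappedVariant:
    """Intermediate result of mapping one paralogue variant (pre-tier)."""

    query_position: int
    query_ref_aa: str
    conserved: bool
    consensus: int


@dataclass
class AnnotationTable:
    """All retained (tier >= MEDIUM) annotations for one query gene."""

    query_gene: str
    annotations: list[ParalogueAnnotation]
    n_unmapped: int = 0
    mapped_variant_counts: Counter = field(default_factory=Counter)

    def __post_init__(self):
        seen = set()
        for a in self.annotations:
            if a.tier is QualityTier.LOW:
                raise ValueError("LOW-tier annotation in an AnnotationTable")
            key = (a.paralogue_gene, a.paralogue_variant, a.query_position)
            if key in seen:
                raise ValueError(f"duplicate annotation {key}")
            seen.add(key)

    @property
    def annotated_positions(self) -> set[int]:
        """Residue-level view: query positions with >= 1 retained annotation."""
        return {a.query_position for a in self.annotations}

    def at_position(self, position: int) -> list[ParalogueAnnotation]:
        return [a for a in self.annotations if a.query_position == position]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "query_gene": a.query_gene,
                    "query_position": a.query_position,
                    "query_ref_aa": a.query_ref_aa,
                    "paralogue_gene": a.paralogue_gene,
                    "paralogue_variant": a.paralogue_variant.hgvs,
                    "disease": a.disease,
                    "pmid": a.pmid,
                    "consensus": a.consensus,
                    "conserved": a.conserved,
                    "tier": a.tier.name,
                }
                for a in self.annotations
            ],
            columns=[
                "query_gene", "query_position", "query_ref_aa", "paralogue_gene",
                "paralogue_variant", "disease", "pmid", "consensus", "conserved",
                "tier",
            ],
        )


@dataclass
class FamilyBundle:
    """A paralogue family ready for annotation of one query member."""

    query: str
    proteins: dict[str, GeneProtein]
    alignment: FamilyAlignment
    track: ConsensusTrack
    evidence_by_gene: dict[str, list[EvidenceRecord]]
    frequency_by_gene: dict[str, list[FrequencyRecord]] = field(default_factory=dict)
    regions: Optional[RegionSet] = None
    recorded: Optional[dict] = None
    skipped: list[SkippedRow] = field(default_factory=list)
    validate_query_sequence: bool = True
    consensus_is_recomputed: bool = False

    def __post_init__(self):
        if self.query not in self.alignment.member_ids:
            raise UnknownMemberError(self.query)

    def protein(self, gene: str) -> GeneProtein:
        if gene not in self.proteins:
            raise UnknownMemberError(gene)
        return self.proteins[gene]

    def pathogenic_evidence(self, gene: str) -> list[EvidenceRecord]:
        return [
            r
            for r in self.evidence_by_gene.get(gene, [])
            if r.assertion is Assertion.PATHOGENIC_REPORT
        ]

    def paralogues(self) -> list[str]:
        return [m for m in self.alignment.member_ids if m != self.query]


def map_paralogue_variant(
    pv: ProteinVariant,
    rmap: ResidueMap,
    track: ConsensusTrack,
    query: GeneProtein,
    alignment: FamilyAlignment,
) -> Optional[MappedVariant]:
    """Map one paralogue variant onto the query; None when it faces a gap.

    Conservation compares the paralogue variant's reference residue with the
    query residue taken from the alignment row (the two proteins' reference
    amino acids).  The consensus score is the track value at the *query*
    residue.
    """
    paralogue_seq = alignment.sequence(rmap.source)
    if pv.position > len(paralogue_seq):
        raise PositionError(
            f"{pv} exceeds {rmap.source} length {len(paralogue_seq)}"
        )
    if paralogue_seq[pv.position - 1] != pv.ref_aa:
        logger.warning(
            "%s: alignment row has %s at %d, evidence states %s",
            rmap.source, paralogue_seq[pv.position - 1], pv.position, pv.ref_aa,
        )
    qpos = rmap.get(pv.position)
    if qpos is None:
        return None
    query_aa = alignment.sequence(rmap.target)[qpos - 1]
    return MappedVariant(
        query_position=qpos,
        query_ref_aa=query_aa,
        conserved=(query_aa == pv.ref_aa),
        consensus=track.score(rmap.target, qpos),
    )


def annotate_all_residues(bundle: FamilyBundle, query: Optional[str] = None) -> AnnotationTable:
    """Attempt every paralogue disease variant; keep tier >= MEDIUM.

    Emits both the variant-level view (one row per paralogue variant /
    query residue pair, duplicates collapsed) and, via
    ``AnnotationTable.annotated_positions``, the residue-level view.
    """
    query = query or bundle.query
    qprot = bundle.protein(query)
    aln = bundle.alignment
    candidates: list[tuple[EvidenceRecord, MappedVariant, str]] = []
    n_unmapped = 0
    mapped_variant_counts: Counter = Counter()
    for paralogue in aln.member_ids:
        if paralogue == query:
            continue  # own-gene evidence feeds residue status, not annotation
        records = bundle.pathogenic_evidence(paralogue)
        if not records:
            continue
        rmap = build_residue_map(aln, paralogue, query)
        seen_variants = set()
        for rec in records:
            if rec.variant in seen_variants:
                continue  # identical variant reported via several cDNA changes
            seen_variants.add(rec.variant)
            mapped = map_paralogue_variant(rec.variant, rmap, bundle.track, qprot, aln)
            if mapped is None:
                n_unmapped += 1
                continue
            mapped_variant_counts[paralogue] += 1
            candidates.append((rec, mapped, paralogue))
    # multiplicity: distinct paralogue variants per query residue, gap-filtered,
    # before tier filtering
    per_residue: dict[int, set] = defaultdict(set)
    for rec, mapped, paralogue in candidates:
        per_residue[mapped.query_position].add((paralogue, rec.variant))
    annotations = []
    for rec, mapped, paralogue in candidates:
        n_here = len(per_residue[mapped.query_position])
        tier = classify_quality(mapped.conserved, mapped.consensus, n_here)
        if tier is QualityTier.LOW:
            continue
        annotations.append(
            ParalogueAnnotation(
                query_gene=query,
                query_position=mapped.query_position,
                query_ref_aa=mapped.query_ref_aa,
                paralogue_gene=paralogue,
                paralogue_variant=rec.variant,
                disease=rec.disease,
                pmid=rec.pmid,
                consensus=mapped.consensus,
                conserved=mapped.conserved,
                tier=tier,
            )
        )
    annotations.sort(key=ParalogueAnnotation.sort_key)
    logger.info(
        "%s: %d annotations on %d residues (%d paralogue variants unmapped)",
        query, len(annotations), len({a.query_position for a in annotations}),
        n_unmapped,
    )
    return AnnotationTable(query, annotations, n_unmapped, mapped_variant_counts)


def annotate_query_variant(
    qv: ProteinVariant, bundle: FamilyBundle
) -> list[ParalogueAnnotation]:
    """All retained annotations at one query variant's residue.

    An empty list means "no paralogue annotation" — which does not imply the
    variant is benign, only that no equivalent paralogue residue has a known
    disease variant.
    """
    qprot = bundle.protein(bundle.query)
    if bundle.validate_query_sequence and qprot.sequence is not None:
        validate_against_sequence(qv, qprot)
    elif not 1 <= qv.position <= qprot.protein_length:
        raise PositionError(
            f"{qv.hgvs}: position outside {bundle.query} "
            f"(length {qprot.protein_length})"
        )
    table = annotate_all_residues(bundle)
    return table.at_position(qv.position)


def reciprocal(bundle: FamilyBundle, new_query: str) -> FamilyBundle:
    """Swap annotation roles: the former query's evidence now annotates
    ``new_query``.  Alignment, consensus and evidence are unchanged."""
    if new_query not in bundle.alignment.member_ids:
        raise UnknownMemberError(new_query)
    return replace(bundle, query=new_query)


# --- bundle IO --------------------------------------------------------------

def write_annotation_report(table: AnnotationTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_paralogue_evidence(path) -> tuple[dict[str, list[EvidenceRecord]], list[SkippedRow]]:
    """Read a paralogue disease-variant TSV into per-gene evidence.

    Expected columns: gene, protein_hgvs, disease, pmid (extra columns such
    as cds_hgvs are preserved as provenance and otherwise ignored).  Rows
    that are not simple missense substitutions (nonsense, synonymous,
    frameshift) are skipped and logged, not fatal.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    by_gene: dict[str, list[EvidenceRecord]] = defaultdict(list)
    skipped: list[SkippedRow] = []
    for _, row in df.iterrows():
        gene = row["gene"]
        try:
            v = parse_protein_hgvs(row["protein_hgvs"], gene)
        except VariantError as exc:
            skipped.append(SkippedRow(gene, row["protein_hgvs"], exc.kind, str(exc)))
            continue
        by_gene[gene].append(
            EvidenceRecord(
                v,
                Assertion.PATHOGENIC_REPORT,
                source=row.get("source", ""),
                pmid=row.get("pmid", ""),
                disease=row.get("disease", ""),
            )
        )
    if skipped:
        logger.warning(
            "%s: skipped %d non-missense rows (%s)",
            path, len(skipped), ", ".join(f"{s.gene} {s.raw}" for s in skipped),
        )
    return dict(by_gene), skipped


def load_bundle(config_path) -> FamilyBundle:
    """Load a family bundle from a YAML config.

    Paths inside the config are resolved relative to the config file.  Keys:

    query, members ({gene: {length, sequence?}}), alignment,
    score_file?, alternative_alignments?, paralogue_evidence,
    status_evidence?, frequency_table?, regions?, recorded?,
    validate_query_sequence?
    """
    from .status import read_evidence_table, read_frequency_table
    from .stats import read_region_table

    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    base = config_path.parent

    def _p(key):
        return base / cfg[key]

    aln = read_alignment(_p("alignment"))
    proteins = {}
    for gene, spec in cfg["members"].items():
        seq = aln.sequence(gene) if gene in aln.member_ids else spec.get("sequence")
        proteins[gene] = GeneProtein(
            gene, int(spec["length"]), sequence=seq,
            transcript_ids=tuple(spec.get("transcripts", ())),
        )
        if seq is not None and len(seq) != int(spec["length"]):
            raise ValueError(
                f"{gene}: alignment sequence length {len(seq)} != declared "
                f"length {spec['length']}"
            )

    consensus_is_recomputed = False
    if cfg.get("score_file"):
        track = read_score_file(_p("score_file"), aln)
    elif cfg.get("alternative_alignments"):
        alts = [read_alignment(base / p) for p in cfg["alternative_alignments"]]
        track = consensus_from_alternatives(aln, alts)
        consensus_is_recomputed = True
    else:
        raise ValueError(
            f"{config_path}: need score_file or alternative_alignments"
        )

    evidence_by_gene, skipped = read_paralogue_evidence(_p("paralogue_evidence"))
    frequency_by_gene: dict[str, list[FrequencyRecord]] = defaultdict(list)
    if cfg.get("status_evidence"):
        records, sk = read_evidence_table(_p("status_evidence"))
        skipped.extend(sk)
        for r in records:
            evidence_by_gene.setdefault(r.variant.gene_symbol, []).append(r)
    if cfg.get("frequency_table"):
        freqs, sk = read_frequency_table(_p("frequency_table"))
        skipped.extend(sk)
        for f in freqs:
            frequency_by_gene[f.variant.gene_symbol].append(f)

    regions = None
    if cfg.get("regions"):
        lengths = {g: p.protein_length for g, p in proteins.items()}
        region_sets = read_region_table(_p("regions"), lengths)
        regions = region_sets.get(cfg["query"])

    return FamilyBundle(
        query=cfg["query"],
        proteins=proteins,
        alignment=aln,
        track=track,
        evidence_by_gene=dict(evidence_by_gene),
        frequency_by_gene=dict(frequency_by_gene),
        regions=regions,
        recorded=cfg.get("recorded"),
        skipped=skipped,
        validate_query_sequence=bool(cfg.get("validate_query_sequence", True)),
        consensus_is_recomputed=consensus_is_recomputed,
    )
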