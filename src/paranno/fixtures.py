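"""Packaged arrhythmia-gene fixtures: RYR (RYR2/RYR1/RYR3) and SCN (SCN5A
plus its 19 sodium/calcium-channel paralogues).

What is real printed data and what is synthetic scaffolding:

* Real: the per-variant annotation rows (query variant, paralogue variant,
  disease, consensus score), the paralogue family composition, the region
  coordinates, and the recorded full-protein summary vectors (status counts,
  observed annotation counts, per-domain annotation counts).
* Synthetic: the family alignments.  The original full-length T-Coffee
  alignments are not published, so each fixture builds an *anchored
  scaffold* alignment at load time — filler sequences in which every printed
  (query position, paralogue position, reference residue) pair is anchored
  into a shared alignment column, plus a score track carrying the printed
  consensus at each anchored query residue (a neutral mid-scale 5
  elsewhere).  The scaffold reproduces exactly the printed mappings and
  nothing else; query sequence validation is disabled for fixture bundles
  because residues between anchors are filler, not the real protein.
* Synthetic: the full status-evidence table.  The complete benign/pathogenic
  evidence set is proprietary, so the fixture plants deterministic synthetic
  evidence records whose per-residue classification reproduces the recorded
  status-count vectors exactly (positions arbitrary).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .alignment import (
    ConsensusTrack,
    FamilyAlignment,
    make_alignment,
    write_alignment,
    write_score_file,
)
from .engine import FamilyBundle, read_paralogue_evidence
from .status import Assertion, EvidenceRecord, FrequencyRecord
from .stats import RegionSet, read_region_table
from .variants import (
    GeneProtein,
    ProteinVariant,
    SkippedRow,
    VariantError,
    parse_protein_hgvs,
)

logger = logging.getLogger(__name__)

FIXTURE_NAMES = ("RYR", "SCN")
FILLER_AA = "A"
DEFAULT_SCORE = 5
_STATUS_EVIDENCE_SEED = 20131017  # fixed: fixture content, not a tunable


def _data_path(name: str):
    return resources.files("paranno.data").joinpath(name)


def _read_tsv(name: str) -> pd.DataFrame:
    with resources.as_file(_data_path(name)) as p:
        return pd.read_csv(p, sep="\t", comment="#", dtype=str).fillna("")


def family_metadata() -> dict:
    with resources.as_file(_data_path("families.yaml")) as p:
        with open(p) as fh:
            return yaml.safe_load(fh)


# --- anchored scaffold alignment -------------------------------------------

@dataclass(frozen=True)
class Anchor:
    """One printed correspondence: query position <-> member position."""

    query_position: int
    member_position: int
    member_aa: str


def build_anchored_alignment(
    query: str,
    query_length: int,
    query_residues: dict[int, str],
    members: Sequence[tuple[str, int, Sequence[Anchor]]],
    filler: str = FILLER_AA,
) -> FamilyAlignment:
    """Build a scaffold MSA in which each anchor pair shares a column.

    Columns are keyed by query position; member residues between anchors are
    laid left-aligned into the corresponding query columns, and any surplus
    (member segment longer than the query segment) goes into member-specific
    insertion columns placed just before the next anchor, where every other
    row has a gap.  Anchors must be strictly increasing in both coordinates.
    """
    # column keys: (qpos, 1) for the query backbone, (qnext, 0, member, j)
    # for member insertions ordered before their following backbone column
    backbone = [(q, 1, "", 0) for q in range(1, query_length + 1)]
    member_cells: dict[str, dict[tuple, str]] = {}
    insertion_keys: list[tuple] = []

    for member, length, anchors in members:
        anchors = sorted(anchors, key=lambda a: a.query_position)
        cells: dict[tuple, str] = {}
        prev_q, prev_p = 0, 0
        bounds = [(a.query_position, a.member_position, a.member_aa) for a in anchors]
        bounds.append((query_length + 1, length + 1, None))
        for qb, pb, aa in bounds:
            if qb <= prev_q or pb <= prev_p:
                raise ValueError(
                    f"{member}: anchors not strictly increasing near "
                    f"query {qb} / member {pb}"
                )
            nq, np_ = qb - prev_q - 1, pb - prev_p - 1
            k = min(nq, np_)
            for j in range(1, k + 1):
                cells[(prev_q + j, 1, "", 0)] = filler
            for j in range(k + 1, np_ + 1):  # surplus -> insertion columns
                key = (qb, 0, member, j - k)
                cells[key] = filler
                insertion_keys.append(key)
            if aa is not None:
                cells[(qb, 1, "", 0)] = aa
            prev_q, prev_p = qb, pb
        member_cells[member] = cells

    columns = sorted(backbone + insertion_keys)
    rows = []
    ids = [query] + [m for m, _, _ in members]
    qrow = {
        (q, 1, "", 0): query_residues.get(q, filler) for q in range(1, query_length + 1)
    }
    rows.append("".join(qrow.get(c, "-") for c in columns))
    for member, _, _ in members:
        cells = member_cells[member]
        rows.append("".join(cells.get(c, "-") for c in columns))
    return make_alignment(ids, rows)


# --- fixture assembly -------------------------------------------------------

@dataclass
class PaperFixture:
    """One packaged family fixture, ready for annotation and statistics."""

    name: str
    bundle: FamilyBundle
    novel_variants: pd.DataFrame
    recorded: dict
    cohort: dict
    paralogue_summary: Optional[pd.DataFrame] = None
    skipped: list[SkippedRow] = field(default_factory=list)

    @property
    def query(self) -> str:
        return self.bundle.query


def _synthetic_status_evidence(
    gene: str,
    scaffold: str,
    status_counts: Sequence[int],
) -> tuple[list[EvidenceRecord], list[FrequencyRecord]]:
    """Plant deterministic synthetic evidence reproducing a recorded
    (pathogenic, benign, uncertain, unannotated) residue-count vector.

    Positions are arbitrary (seeded draw); variant reference residues are
    taken from the scaffold so sequence validation stays consistent.
    """
    n_path, n_ben, n_unc, _ = (int(c) for c in status_counts)
    length = len(scaffold)
    rng = np.random.default_rng(_STATUS_EVIDENCE_SEED)
    picks = rng.choice(length, size=n_path + n_ben + n_unc, replace=False) + 1
    path_pos = sorted(int(p) for p in picks[:n_path])
    ben_pos = sorted(int(p) for p in picks[n_path:n_path + n_ben])
    unc_pos = sorted(int(p) for p in picks[n_path + n_ben:])

    def _variant(pos: int) -> ProteinVariant:
        ref = scaffold[pos - 1]
        alt = "V" if ref != "V" else "L"
        return ProteinVariant(gene, ref, pos, alt)

    evidence: list[EvidenceRecord] = []
    freqs: list[FrequencyRecord] = []
    for pos in path_pos:
        evidence.append(
            EvidenceRecord(_variant(pos), Assertion.PATHOGENIC_REPORT,
                           source="synthetic_fixture")
        )
    for i, pos in enumerate(ben_pos):
        if i % 2 == 0:
            evidence.append(
                EvidenceRecord(_variant(pos), Assertion.BENIGN_REPORT,
                               source="synthetic_fixture")
            )
        else:  # benign via the population-frequency rule
            freqs.append(FrequencyRecord(_variant(pos), "ALL", 0.02, 10))
    for pos in unc_pos:
        evidence.append(
            EvidenceRecord(_variant(pos), Assertion.DBSNP_NO_FREQ,
                           source="synthetic_fixture")
        )
    return evidence, freqs


def _fixture_anchors(
    df: pd.DataFrame,
) -> tuple[dict[int, str], dict[str, list[Anchor]], dict[int, int], list[SkippedRow]]:
    """Anchors, query residues and consensus scores from a novel-variant table."""
    query_residues: dict[int, str] = {}
    anchors: dict[str, list[Anchor]] = {}
    consensus: dict[int, int] = {}
    skipped: list[SkippedRow] = []
    seen: dict[tuple, Anchor] = {}
    for row in df.itertuples():
        qv = parse_protein_hgvs(row.query_hgvs, row.query_gene)
        query_residues[qv.position] = qv.ref_aa
        consensus[qv.position] = int(row.consensus)
        try:
            pv = parse_protein_hgvs(row.protein_hgvs, row.gene)
        except VariantError as exc:
            skipped.append(SkippedRow(row.gene, row.protein_hgvs, exc.kind, str(exc)))
            continue
        key = (row.gene, qv.position, pv.position)
        if key not in seen:
            a = Anchor(qv.position, pv.position, pv.ref_aa)
            seen[key] = a
            anchors.setdefault(row.gene, []).append(a)
    return query_residues, anchors, consensus, skipped


def load_paper_fixture(name: str) -> PaperFixture:
    """Load a packaged fixture ("RYR" or "SCN") as an in-memory bundle."""
    name = name.upper()
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    meta = family_metadata()[name]
    query = meta["query"]
    df = _read_tsv(meta["novel_variants"])

    query_residues, anchors, consensus, _ = _fixture_anchors(df)
    member_specs = [
        (gene, int(spec["length"]), anchors.get(gene, []))
        for gene, spec in meta["members"].items()
        if gene != query
    ]
    qlen = int(meta["members"][query]["length"])
    aln = build_anchored_alignment(query, qlen, query_residues, member_specs)

    scores = {}
    for member in aln.member_ids:
        n = len(aln.sequence(member))
        vals = [DEFAULT_SCORE] * n
        if member == query:
            for pos, sc in consensus.items():
                vals[pos - 1] = sc
        scores[member] = tuple(vals)
    track = ConsensusTrack(scores)

    proteins = {
        gene: GeneProtein(
            gene,
            int(spec["length"]),
            sequence=aln.sequence(gene),
            transcript_ids=tuple(spec.get("transcripts", ())),
        )
        for gene, spec in meta["members"].items()
    }

    # paralogue disease evidence: the printed rows, with non-missense rows
    # (nonsense/synonymous) skipped and logged
    evidence_rows = df.rename(columns={"pmid": "pmid"})[
        ["gene", "protein_hgvs", "disease", "pmid"]
    ]
    by_gene: dict[str, list[EvidenceRecord]] = {}
    skipped: list[SkippedRow] = []
    for row in evidence_rows.itertuples():
        try:
            v = parse_protein_hgvs(row.protein_hgvs, row.gene)
        except VariantError as exc:
            skipped.append(SkippedRow(row.gene, row.protein_hgvs, exc.kind, str(exc)))
            continue
        by_gene.setdefault(row.gene, []).append(
            EvidenceRecord(v, Assertion.PATHOGENIC_REPORT,
                           source="printed_table", pmid=row.pmid,
                           disease=row.disease)
        )
    if skipped:
        logger.warning(
            "fixture %s: skipped %d non-missense paralogue rows (%s)",
            name, len(skipped),
            ", ".join(f"{s.gene} {s.raw} [{s.kind}]" for s in skipped),
        )

    # synthetic status evidence for the query, matching recorded counts
    recorded = meta["recorded"]
    ev, freqs = _synthetic_status_evidence(
        query, aln.sequence(query), recorded["status_counts"]
    )
    by_gene.setdefault(query, []).extend(ev)

    with resources.as_file(_data_path(meta["regions"])) as p:
        regions = read_region_table(p, {query: qlen})[query]

    bundle = FamilyBundle(
        query=query,
        proteins=proteins,
        alignment=aln,
        track=track,
        evidence_by_gene=by_gene,
        frequency_by_gene={query: freqs},
        regions=regions,
        recorded=recorded,
        skipped=skipped,
        validate_query_sequence=False,  # scaffold is synthetic between anchors
    )
    summary = _read_tsv(meta["paralogue_summary"]) if "paralogue_summary" in meta else None
    return PaperFixture(
        name=name,
        bundle=bundle,
        novel_variants=df,
        recorded=recorded,
        cohort=meta.get("cohort", {}),
        paralogue_summary=summary,
        skipped=skipped,
    )


def materialize(fixture: PaperFixture, outdir) -> Path:
    """Write a fixture as an on-disk bundle (the formats the CLI consumes).

    Returns the path of the bundle YAML.  The alignment/score/status files
    written here are the synthetic scaffold components and are named
    accordingly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    b = fixture.bundle
    write_alignment(b.alignment, outdir / "alignment_synthetic_scaffold.fasta")
    write_score_file(b.track, outdir / "scores_synthetic_scaffold.txt")

    meta = family_metadata()[fixture.name]
    ev_rows, st_rows, fr_rows = [], [], []
    for gene, records in b.evidence_by_gene.items():
        for r in records:
            if r.source == "printed_table":
                ev_rows.append(
                    {"gene": gene, "protein_hgvs": r.variant.hgvs,
                     "disease": r.disease, "pmid": r.pmid}
                )
            else:
                st_rows.append(
                    {"gene": gene, "protein_hgvs": r.variant.hgvs,
                     "assertion": r.assertion.value, "source": r.source,
                     "pmid": r.pmid}
                )
    # re-emit the printed-but-rejected rows so a reload skips (and logs) them too
    for s in fixture.skipped:
        ev_rows.append({"gene": s.gene, "protein_hgvs": s.raw, "disease": "",
                        "pmid": ""})
    for gene, freqs in b.frequency_by_gene.items():
        for f in freqs:
            fr_rows.append(
                {"gene": gene, "protein_hgvs": f.variant.hgvs,
                 "population": f.population, "maf": f.maf,
                 "observations": f.observations}
            )
    pd.DataFrame(ev_rows).to_csv(outdir / "paralogue_evidence.tsv", sep="\t", index=False)
    pd.DataFrame(st_rows).to_csv(
        outdir / "status_evidence_synthetic.tsv", sep="\t", index=False
    )
    pd.DataFrame(fr_rows).to_csv(
        outdir / "frequency_synthetic.tsv", sep="\t", index=False
    )
    with resources.as_file(_data_path(meta["regions"])) as p:
        (outdir / "regions.tsv").write_text(p.read_text())
    fixture.novel_variants.to_csv(outdir / "novel_variants.tsv", sep="\t", index=False)

    cfg = {
        "query": b.query,
        "members": {
            g: {"length": p.protein_length, "transcripts": list(p.transcript_ids)}
            for g, p in b.proteins.items()
        },
        "alignment": "alignment_synthetic_scaffold.fasta",
        "score_file": "scores_synthetic_scaffold.txt",
        "paralogue_evidence": "paralogue_evidence.tsv",
        "status_evidence": "status_evidence_synthetic.tsv",
        "frequency_table": "frequency_synthetic.tsv",
        "regions": "regions.tsv",
        "recorded": fixture.recorded,
        "validate_query_sequence": False,
    }
    yaml_path = outdir / "bundle.yaml"
    with open(yaml_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    logger.info("materialized fixture %s into %s", fixture.name, outdir)
    return yaml_path
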