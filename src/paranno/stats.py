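"""Protein regions and summary statistics for paralogue annotation.

Covers region (hotspot / transmembrane-domain) membership, observed vs
expected annotated-residue counts under a random-placement null, enrichment
factors, positive predictive value (PPV), region enrichment and a 2x2
Fisher's exact test.

Two enrichment conventions are emitted everywhere: ``paper_compat`` divides
the observed count by the *rounded* expected count (the convention printed
in the original reports, e.g. 35/8 = 4.4), while the unrounded variant
divides by the exact expectation.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from scipy import stats as sps

from .alignment import round_half_up
from .status import STATUS_ORDER, ResidueStatus
from .variants import PositionError

logger = logging.getLogger(__name__)

OUTSIDE = "outside"


@dataclass(frozen=True)
class Region:
    label: str
    start: int
    end: int
    group: str

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class RegionSet:
    """Non-overlapping labelled regions of one protein, grouped for stats.

    ``group`` is a free-form group name (e.g. "hotspots", "transmembrane");
    residues covered by no region belong to the implicit "outside" group.
    """

    gene: str
    regions: tuple[Region, ...]
    protein_length: int

    def __post_init__(self):
        labels = [r.label for r in self.regions]
        if len(set(labels)) != len(labels):
            raise ValueError(f"{self.gene}: duplicate region labels")
        covered: set[int] = set()
        for r in self.regions:
            if not 1 <= r.start <= r.end <= self.protein_length:
                raise ValueError(
                    f"{self.gene} {r.label}: range {r.start}-{r.end} outside "
                    f"protein of length {self.protein_length}"
                )
            span = set(range(r.start, r.end + 1))
            if covered & span:
                raise ValueError(f"{self.gene} {r.label}: regions overlap")
            covered |= span

    def region_of(self, position: int) -> Optional[Region]:
        if not 1 <= position <= self.protein_length:
            raise PositionError(
                f"position {position} outside {self.gene} (length {self.protein_length})"
            )
        for r in self.regions:
            if r.start <= position <= r.end:
                return r
        return None

    def group_of(self, position: int) -> str:
        r = self.region_of(position)
        return r.group if r is not None else OUTSIDE

    def group_spans(self) -> dict[str, int]:
        """Residue span of each group, including the implicit outside group."""
        spans: dict[str, int] = {}
        for r in self.regions:
            spans[r.group] = spans.get(r.group, 0) + r.span
        rest = self.protein_length - sum(spans.values())
        if rest:
            spans[OUTSIDE] = spans.get(OUTSIDE, 0) + rest
        return spans


def region_of(position: int, rs: RegionSet) -> str:
    """Label of the region containing a position, or "OUTSIDE"."""
    r = rs.region_of(position)
    return r.label if r is not None else "OUTSIDE"


def read_region_table(path, protein_length: Mapping[str, int] | int) -> dict[str, RegionSet]:
    """Read a region TSV (gene, label, start, end, group) into RegionSets.

    ``protein_length`` is either one integer (single-gene file) or a mapping
    gene -> length.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    out = {}
    for gene, sub in df.groupby("gene"):
        length = protein_length if isinstance(protein_length, int) else protein_length[gene]
        regions = tuple(
            Region(str(r.label), int(r.start), int(r.end), str(r.group))
            for r in sub.itertuples()
        )
        out[gene] = RegionSet(gene, regions, length)
    logger.info("%s: regions for %d gene(s)", path, len(out))
    return out


# --- observed/expected and enrichment --------------------------------------

def expected_by_status(
    total_annotated: int,
    status_counts: Sequence[int],
    protein_length: int,
) -> tuple[tuple[float, ...], tuple[int, ...]]:
    """Expected annotated residues per status class under random placement.

    ``status_counts`` is the (pathogenic, benign, uncertain, unannotated)
    vector; it must sum to ``protein_length``.  Returns the exact
    expectations (which sum to ``total_annotated``) and their half-up
    roundings as printed in reports.
    """
    if protein_length <= 0:
        raise ValueError("protein_length must be positive")
    if sum(status_counts) != protein_length:
        raise ValueError(
            f"status counts sum to {sum(status_counts)}, not protein length "
            f"{protein_length}"
        )
    exact = tuple(total_annotated * c / protein_length for c in status_counts)
    rounded = tuple(int(round_half_up(e)) for e in exact)
    return exact, rounded


def enrichment_vs_expected(observed: int, expected: float, *, ndigits: int = 1) -> Optional[float]:
    """Fold enrichment of observed over expected, half-up rounded.

    Returns None ("N/A") when the expectation is zero.
    """
    if expected == 0:
        return None
    return round_half_up(observed / expected, ndigits)


def ppv(pathogenic_observed: int, benign_observed: int, *, ndigits: int = 1) -> Optional[float]:
    """Positive predictive value in percent over classifiable residues.

    Residues of uncertain or unannotated status carry no truth label and are
    excluded.  Returns None when there is nothing to classify.
    """
    total = pathogenic_observed + benign_observed
    if total == 0:
        return None
    return round_half_up(100.0 * pathogenic_observed / total, ndigits)


@dataclass(frozen=True)
class GroupEnrichment:
    group: str
    annotations: int
    observed_fraction: float
    span: int
    length_fraction: float
    factor: Optional[float]  # rounded to 2 decimals; None when undefined


def region_enrichment_from_counts(
    group_counts: Mapping[str, int],
    rs: RegionSet,
    *,
    total: Optional[int] = None,
) -> dict[str, GroupEnrichment]:
    """Per-group enrichment from annotation counts per group.

    factor = (annotations in group / total annotations)
           / (group residue span / protein length).
    """
    spans = rs.group_spans()
    unknown = set(group_counts) - set(spans)
    if unknown:
        raise ValueError(f"counts for unknown groups: {sorted(unknown)}")
    total = sum(group_counts.values()) if total is None else total
    out = {}
    for group, span in spans.items():
        n = group_counts.get(group, 0)
        lf = span / rs.protein_length
        if total == 0:
            of, factor = 0.0, None
        else:
            of = n / total
            factor = round_half_up(of / lf, 2)
        out[group] = GroupEnrichment(group, n, of, span, lf, factor)
    return out


def region_enrichment(
    annotated_positions: Iterable[int], rs: RegionSet
) -> dict[str, GroupEnrichment]:
    """Per-group enrichment of annotated positions (multiset) over the
    length-fraction null."""
    counts = Counter(rs.group_of(p) for p in annotated_positions)
    return region_enrichment_from_counts(counts, rs, total=sum(counts.values()))


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact p for a 2x2 table.

    Two-sided by the conventional rule: sum of the probabilities of all
    tables with the observed margins whose probability does not exceed the
    observed table's.
    """
    (a, b), (c, d) = table
    cells = [a, b, c, d]
    if any(x < 0 for x in cells):
        raise ValueError(f"negative cell in contingency table: {cells}")
    if any(int(x) != x for x in cells):
        raise ValueError("contingency table cells must be integers")
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


# --- assembled report -------------------------------------------------------

@dataclass
class StatsReport:
    """Observed vs expected annotation counts, enrichments, PPV, regions."""

    gene: str
    protein_length: int
    total_annotated: int
    status_counts: tuple[int, int, int, int]
    observed: tuple[int, int, int, int]
    expected_exact: tuple[float, ...]
    expected_rounded: tuple[int, ...]
    enrichment_paper_compat: tuple[Optional[float], ...]
    enrichment_unrounded: tuple[Optional[float], ...]
    ppv_percent: Optional[float]
    region_enrichments: dict[str, GroupEnrichment] = field(default_factory=dict)
    fisher_p: Optional[float] = None
    consensus_is_recomputed: bool = False  # flag: stand-in score, not T-Coffee's
    from_recorded: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, status in enumerate(STATUS_ORDER):
            rows.append(
                {
                    "gene": self.gene,
                    "status": status.value,
                    "known_residues": self.status_counts[i],
                    "observed": self.observed[i],
                    "expected": self.expected_rounded[i],
                    "expected_exact": round(self.expected_exact[i], 3),
                    "enrichment": self.enrichment_paper_compat[i],
                    "enrichment_unrounded": self.enrichment_unrounded[i],
                }
            )
        return pd.DataFrame(rows)

    def region_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene": self.gene,
                "group": g.group,
                "annotations": g.annotations,
                "observed_fraction": round(g.observed_fraction, 4),
                "span": g.span,
                "length_fraction": round(g.length_fraction, 4),
                "enrichment": g.factor,
            }
            for g in self.region_enrichments.values()
        ]
        return pd.DataFrame(rows)

    def render_text(self) -> str:
        lines = [f"# Annotation statistics for {self.gene}",
                 f"protein length: {self.protein_length}",
                 f"annotated residues: {self.total_annotated}"]
        if self.from_recorded:
            lines.append("(observed/annotated counts are recorded summary "
                         "vectors, not recomputed from evidence)")
        if self.consensus_is_recomputed:
            lines.append("(consensus scores are the package's "
                         "partner-reproduction stand-in, not T-Coffee's)")
        for i, status in enumerate(STATUS_ORDER):
            enr = self.enrichment_paper_compat[i]
            enr_s = "N/A" if enr is None else f"{enr:.1f}"
            lines.append(
                f"{status.value.lower():12s} known {self.status_counts[i]:5d}  "
                f"observed {self.observed[i]:4d}  expected {self.expected_rounded[i]:4d}"
                f"  enrichment {enr_s}"
            )
        ppv_s = "N/A" if self.ppv_percent is None else f"{self.ppv_percent:.1f}"
        lines.append(f"PPV: {ppv_s}%")
        for g in self.region_enrichments.values():
            f_s = "N/A" if g.factor is None else f"{g.factor:.2f}"
            lines.append(
                f"region group {g.group:15s} annotations {g.annotations:4d} "
                f"span {g.span:5d}  enrichment {f_s}"
            )
        if self.fisher_p is not None:
            lines.append(f"Fisher exact p: {self.fisher_p:.2e}")
        return "\n".join(lines) + "\n"


def build_stats_report(
    gene: str,
    protein_length: int,
    status_counts: Sequence[int],
    observed: Sequence[int],
    *,
    regions: Optional[RegionSet] = None,
    region_counts: Optional[Mapping[str, int]] = None,
    annotated_positions: Optional[Iterable[int]] = None,
    fisher_table: Optional[Sequence[Sequence[int]]] = None,
    consensus_is_recomputed: bool = False,
    from_recorded: bool = False,
) -> StatsReport:
    """Assemble the full statistics report from count vectors.

    ``observed`` is the annotated-residue count per status class; region
    enrichment is computed from ``region_counts`` (per group) or from
    ``annotated_positions`` when given.
    """
    status_counts = tuple(int(c) for c in status_counts)
    observed = tuple(int(c) for c in observed)
    total = sum(observed)
    exact, rounded = expected_by_status(total, status_counts, protein_length)
    enr_pc = tuple(enrichment_vs_expected(o, e) for o, e in zip(observed, rounded))
    enr_ur = tuple(enrichment_vs_expected(o, e) for o, e in zip(observed, exact))
    report = StatsReport(
        gene=gene,
        protein_length=protein_length,
        total_annotated=total,
        status_counts=status_counts,
        observed=observed,
        expected_exact=exact,
        expected_rounded=rounded,
        enrichment_paper_compat=enr_pc,
        enrichment_unrounded=enr_ur,
        ppv_percent=ppv(observed[0], observed[1]),
        consensus_is_recomputed=consensus_is_recomputed,
        from_recorded=from_recorded,
    )
    if regions is not None:
        if region_counts is not None:
            report.region_enrichments = region_enrichment_from_counts(
                region_counts, rs=regions
            )
        elif annotated_positions is not None:
            report.region_enrichments = region_enrichment(annotated_positions, regions)
    if fisher_table is not None:
        report.fisher_p = fisher_exact(fisher_table)
    return report
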