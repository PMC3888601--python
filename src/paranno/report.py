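"""Bundle-level statistics assembly.

Connects the annotation engine, residue-status classification and the
summary statistics: given a family bundle, compute (or take from recorded
summary vectors, for the packaged fixtures) the per-status observed
annotation counts, expected counts under random placement, enrichments, PPV
and region enrichment.
"""

from __future__ import annotations

import logging
from typing import Optional

from .engine import AnnotationTable, FamilyBundle, annotate_all_residues
from .stats import StatsReport, build_stats_report
from .status import STATUS_ORDER, StatusTable, build_status_table

logger = logging.getLogger(__name__)


def bundle_status_table(bundle: FamilyBundle) -> StatusTable:
    """Residue statuses of the query gene from its own collated evidence."""
    gene = bundle.protein(bundle.query)
    return build_status_table(
        gene,
        bundle.evidence_by_gene.get(bundle.query, []),
        bundle.frequency_by_gene.get(bundle.query, []),
    )


def bundle_statistics(
    bundle: FamilyBundle,
    *,
    use_recorded: Optional[bool] = None,
    annotation_table: Optional[AnnotationTable] = None,
) -> StatsReport:
    """Full statistics report for a bundle's query gene.

    When the bundle carries recorded summary vectors (the packaged fixtures;
    the underlying full evidence set is not redistributable) those are used
    unless ``use_recorded=False``; otherwise everything is recomputed from
    the bundle's evidence and alignment.
    """
    qprot = bundle.protein(bundle.query)
    if use_recorded is None:
        use_recorded = bundle.recorded is not None
    if use_recorded:
        if not bundle.recorded:
            raise ValueError("bundle has no recorded summary vectors")
        rec = bundle.recorded
        return build_stats_report(
            bundle.query,
            qprot.protein_length,
            rec["status_counts"],
            rec["observed"],
            regions=bundle.regions,
            region_counts=rec.get("region_counts"),
            consensus_is_recomputed=bundle.consensus_is_recomputed,
            from_recorded=True,
        )
    status = bundle_status_table(bundle)
    table = annotation_table or annotate_all_residues(bundle)
    counts = status.count_vector()
    observed = tuple(
        len(table.annotated_positions & status.positions_with(s))
        for s in STATUS_ORDER
    )
    return build_stats_report(
        bundle.query,
        qprot.protein_length,
        counts,
        observed,
        regions=bundle.regions,
        annotated_positions=table.annotated_positions,
        consensus_is_recomputed=bundle.consensus_is_recomputed,
        from_recorded=False,
    )
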