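"""Region fold-change profiling and biological-process aggregation.

Used to characterise named chromosomal regions — typically the three
photosynthesis gene clusters (PGCs) of the organism — in terms of the
fold changes of the genes they contain, and to break the affected set
down by a curated gene -> biological-process map. The category map is a
user-supplied table, not an automated functional annotation.
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .models import AffectedSet, GenomeAnnotation, RegionDefinition, TranscriptionalCluster, percentage

UNKNOWN_CATEGORY = "Unknown"


def genes_in_region(region: RegionDefinition, annotation: GenomeAnnotation) -> list[str]:
    """Gene ids in the region, in genomic order.

    Membership is an explicit gene list when the region carries one,
    otherwise any gene whose interval overlaps the region by >= 1 bp.
    """
    if region.genes is not None:
        for g in region.genes:
            if g not in annotation:
                raise KeyError(f"region {region.name}: gene {g!r} not in annotation")
        return sorted(region.genes, key=lambda g: annotation[g].start)
    return [
        g.gene_id
        for g in annotation
        if g.contig == region.contig and g.start <= region.end and g.end >= region.start
    ]


def profile_region(
    region: RegionDefinition,
    de: pd.DataFrame,
    affected: AffectedSet,
    tcs: list[TranscriptionalCluster],
    annotation: GenomeAnnotation,
) -> dict:
    """Fold-change profile of one region.

    Averages are taken over *affected* genes only: unaffected genes sit
    near fc = +/-1 and would dilute the signal of interest. The profile
    reports per-gene fcs in genomic order, the average signed fc (NaN
    when no gene is affected), per-strand averages, the max-|fc| gene,
    the TCs lying fully inside the region, and the count of affected
    genes in the region that belong to no reported TC (transcriptional
    fragmentation).
    """
    members = genes_in_region(region, annotation)
    fc = de["fc"]
    per_gene = [
        {
            "gene_id": g,
            "strand": annotation[g].strand,
            "fc": float(fc.get(g, np.nan)),
            "affected": g in affected.reasons,
        }
        for g in members
    ]
    aff = [r for r in per_gene if r["affected"]]

    def mean_fc(rows: list[dict]) -> float:
        return float(np.mean([r["fc"] for r in rows])) if rows else math.nan

    member_set = set(members)
    inside = [
        tc
        for tc in tcs
        if tc.contig == region.contig and set(tc.members) <= member_set
        and any(m in affected.reasons for m in tc.members)
    ]
    in_tc = {m for tc in inside for m in tc.members}
    max_gene = max(aff, key=lambda r: abs(r["fc"]), default=None)
    return {
        "region": region.name,
        "n_genes": len(members),
        "n_affected": len(aff),
        "per_gene": per_gene,
        "avg_fc_affected": mean_fc(aff),
        "avg_fc_by_strand": {s: mean_fc([r for r in aff if r["strand"] == s]) for s in ("+", "-")},
        "max_abs_fc_gene": None if max_gene is None else max_gene["gene_id"],
        "max_abs_fc": math.nan if max_gene is None else max_gene["fc"],
        "n_tcs_inside": len(inside),
        "tcs_inside": [tc.tc_id for tc in inside],
        "n_isolated_affected": sum(1 for r in aff if r["gene_id"] not in in_tc),
    }


def categorize_affected(
    affected: AffectedSet,
    category_map: dict[str, str],
    de: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Break the affected set down by biological-process category.

    Genes absent from the map fall into ``Unknown``. Returns a DataFrame
    (category, n, pct, n_up, n_down) sorted by count descending, then by
    category name for stable ties. Percentages are of the total affected
    set, integer-rounded, so they sum to 100 up to rounding.
    """
    rows: dict[str, dict] = {}
    for g in affected.gene_ids:
        cat = category_map.get(g, UNKNOWN_CATEGORY)
        r = rows.setdefault(cat, {"category": cat, "n": 0, "n_up": 0, "n_down": 0})
        r["n"] += 1
        r["n_up" if affected.directions[g] == "up" else "n_down"] += 1
    total = affected.n_affected
    out = pd.DataFrame(rows.values(), columns=["category", "n", "n_up", "n_down"])
    if out.empty:
        out["pct"] = pd.Series(dtype=int)
        return out
    out["pct"] = [percentage(n, total) for n in out["n"]]
    out = out.sort_values(["n", "category"], ascending=[False, True], kind="stable")
    return out.reset_index(drop=True)[["category", "n", "pct", "n_up", "n_down"]]
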