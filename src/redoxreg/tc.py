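"""Transcriptional-cluster (TC) calling and the affected-gene set.

The core bespoke procedure: candidate genes pass |fc| >= 2 (inclusive)
and raw p < 0.05 (strict); within each (contig, strand) candidates in
genomic order are chained into TCs when consecutive intergenic gaps are
below the threshold (default 250 bp) and regulation directions agree;
maximal chains of >= 2 genes are TCs, singletons are "isolated". The
final affected set keeps BH-significant candidates plus candidates
rescued by membership in a TC that contains at least one BH-significant
gene.

A TC is a weaker claim than an operon: co-strand genes transcribed in a
coordinated way under the conditions studied, with no assertion of a
shared polycistronic mRNA. The gap is measured between consecutive
*candidate* genes; an intervening non-candidate gene on the same strand
does not by itself break a chain — only the resulting distance does.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .models import (
    AffectedSet,
    GenomeAnnotation,
    TranscriptionalCluster,
    percentage,
)

DEFAULT_FC_THRESHOLD = 2.0
DEFAULT_RAW_P_THRESHOLD = 0.05
DEFAULT_BH_THRESHOLD = 0.05
DEFAULT_MAX_GAP_BP = 250


def select_candidates(
    de: pd.DataFrame,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    raw_p_threshold: float = DEFAULT_RAW_P_THRESHOLD,
) -> pd.DataFrame:
    """Candidate DE genes: |fc| >= fc_threshold AND raw p < raw_p_threshold.

    The fc threshold is inclusive and the p threshold strict, mirroring
    the reporting convention the pipeline reproduces. Returns the DE rows
    of the candidates with an added ``direction`` column.
    """
    keep = (de["fc"].abs() >= fc_threshold) & (de["pvalue"] < raw_p_threshold)
    out = de.loc[keep].copy()
    out["direction"] = np.where(out["fc"] < 0, "down", "up")
    return out


def intergenic_gap(prev_end: int, next_start: int) -> int:
    """Gap in bp between two 1-based inclusive intervals (adjacent -> 0)."""
    return next_start - prev_end - 1


def call_tcs(
    candidates: pd.DataFrame,
    annotation: GenomeAnnotation,
    max_gap: int = DEFAULT_MAX_GAP_BP,
) -> tuple[list[TranscriptionalCluster], list[str]]:
    """Chain candidates into transcriptional clusters.

    Within each (contig, strand), candidates sorted by start join the
    current chain iff the gap to the previous candidate is < ``max_gap``
    and the regulation direction matches; chains of >= 2 genes become
    TCs, chains of 1 are reported as isolated. Greedy left-to-right
    chaining yields exactly the maximal valid runs, so the result is
    order-independent.
    """
    for gene_id in candidates.index:
        if gene_id not in annotation:
            raise KeyError(f"candidate gene {gene_id!r} not present in annotation")

    rows = []
    for gene_id in candidates.index:
        g = annotation[gene_id]
        rows.append((g.contig, g.strand, g.start, g.end, gene_id))
    rows.sort()

    tcs: list[TranscriptionalCluster] = []
    isolated: list[str] = []

    def close(chain: list[tuple[str, str, int, int, str]]) -> None:
        if len(chain) == 1:
            isolated.append(chain[0][4])
            return
        members = tuple(r[4] for r in chain)
        fcs = candidates.loc[list(members), "fc"].to_numpy(dtype=float)
        gaps = [intergenic_gap(chain[i][3], chain[i + 1][2]) for i in range(len(chain) - 1)]
        tcs.append(
            TranscriptionalCluster(
                tc_id=f"TC{len(tcs) + 1:03d}",
                members=members,
                contig=chain[0][0],
                strand=chain[0][1],
                direction=str(candidates.loc[members[0], "direction"]),
                avg_fc=float(fcs.mean()),
                span=(chain[0][2], chain[-1][3]),
                max_internal_gap=max(gaps),
            )
        )

    chain: list[tuple[str, str, int, int, str]] = []
    for row in rows:
        if chain:
            prev = chain[-1]
            same_group = row[0] == prev[0] and row[1] == prev[1]
            gap_ok = same_group and intergenic_gap(prev[3], row[2]) < max_gap
            dir_ok = (
                candidates.loc[row[4], "direction"] == candidates.loc[prev[4], "direction"]
            )
            if not (gap_ok and dir_ok):
                close(chain)
                chain = []
        chain.append(row)
    if chain:
        close(chain)
    return tcs, isolated


def apply_rescue(
    de: pd.DataFrame,
    candidates: pd.DataFrame,
    tcs: list[TranscriptionalCluster],
    bh_threshold: float = DEFAULT_BH_THRESHOLD,
) -> AffectedSet:
    """Build the affected set: BH-significant candidates plus TC rescues.

    A candidate failing BH at ``bh_threshold`` is still included when it
    belongs to a TC with at least one BH-significant member; its reason
    is recorded as ``tc_rescued``. TCs with no significant member
    contribute nothing. Rescued genes necessarily already pass the raw
    filters, since TCs are built from the candidate set.
    """
    padj = de["padj"]
    significant = {
        g for g in candidates.index if np.isfinite(padj.get(g, np.nan)) and padj[g] < bh_threshold
    }
    affected = AffectedSet()
    in_reported_tc: dict[str, str] = {}
    for tc in tcs:
        if any(m in significant for m in tc.members):
            for m in tc.members:
                in_reported_tc[m] = tc.tc_id

    for g in candidates.index:
        if g in significant:
            affected.reasons[g] = "bh_significant"
        elif g in in_reported_tc:
            affected.reasons[g] = "tc_rescued"
        else:
            continue
        affected.directions[g] = str(candidates.loc[g, "direction"])
        if g in in_reported_tc:
            affected.tc_of[g] = in_reported_tc[g]
    return affected


def summarize_counts(
    n_affected: int,
    n_down: int,
    n_up: int,
    n_in_tc: int,
    n_tcs: int = 0,
    n_rescued: int = 0,
) -> dict:
    """Headline counts and integer percentages (ties away from zero)."""
    return {
        "n_affected": n_affected,
        "n_down": n_down,
        "n_up": n_up,
        "pct_down": percentage(n_down, n_affected),
        "pct_up": percentage(n_up, n_affected),
        "n_tcs": n_tcs,
        "n_genes_in_tcs": n_in_tc,
        "pct_in_tcs": percentage(n_in_tc, n_affected),
        "n_rescued": n_rescued,
    }


def summarize_affected(
    affected: AffectedSet,
    tcs: list[TranscriptionalCluster],
    de: pd.DataFrame | None = None,
    n_largest: int = 5,
) -> dict:
    """Summary record of the affected set: counts, percentages, and the
    largest reported TCs with their average signed fold change."""
    reported = [tc for tc in tcs if any(m in affected.reasons for m in tc.members)]
    summary = summarize_counts(
        affected.n_affected,
        affected.n_down,
        affected.n_up,
        affected.n_in_tc,
        n_tcs=len(reported),
        n_rescued=affected.n_rescued,
    )
    largest = sorted(reported, key=lambda tc: (-tc.size, tc.tc_id))[:n_largest]
    summary["largest_tcs"] = [
        {"tc_id": tc.tc_id, "size": tc.size, "avg_fc": round(tc.avg_fc, 3), "direction": tc.direction}
        for tc in largest
    ]
    return summary
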