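"""Core domain types shared across the pipeline.

Coordinates are 1-based inclusive throughout (GFF3 convention); the
intergenic gap between two genes on the same contig is
``next.start - prev.end - 1``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

STRANDS = ("+", "-")


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene: the coordinate substrate of TC calling."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in STRANDS:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class GenomeAnnotation:
    """Ordered collection of genes, sorted by (contig, start).

    Same-strand overlaps are tolerated with a warning on construction
    (annotations in the wild contain them) but the synthetic generator
    never produces them.
    """

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: list[GeneModel] = sorted(genes, key=lambda g: (g.contig, g.start, g.end))
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene ids in annotation")
        self._by_id: dict[str, GeneModel] = {g.gene_id: g for g in self.genes}
        self.same_strand_overlaps: list[tuple[str, str]] = []
        last: dict[tuple[str, str], GeneModel] = {}
        for g in self.genes:
            key = (g.contig, g.strand)
            prev = last.get(key)
            if prev is not None and g.start <= prev.end:
                self.same_strand_overlaps.append((prev.gene_id, g.gene_id))
            last[key] = g
        if self.same_strand_overlaps:
            import warnings

            warnings.warn(
                f"annotation contains {len(self.same_strand_overlaps)} same-strand overlap(s)",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __getitem__(self, gene_id: str) -> GeneModel:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not present in annotation") from None

    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]


class CountMatrix:
    """Per-gene read counts for exactly two conditions with replicates.

    ``counts`` is a genes x samples integer DataFrame; ``conditions`` maps
    each sample id to its condition label.
    """

    def __init__(self, counts: pd.DataFrame, conditions: Mapping[str, str]):
        if counts.index.has_duplicates:
            raise ValueError("duplicate gene ids in count matrix")
        if (counts.values < 0).any():
            raise ValueError("counts must be nonnegative")
        missing = [s for s in counts.columns if s not in conditions]
        if missing:
            raise ValueError(f"samples without condition label: {missing}")
        self.counts = counts.astype(np.int64)
        self.conditions = {s: conditions[s] for s in counts.columns}
        labels = sorted(set(self.conditions.values()))
        if len(labels) != 2:
            raise ValueError(f"exactly two conditions required, got {labels}")
        self.condition_labels = tuple(labels)

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    def samples_of(self, condition: str) -> list[str]:
        return [s for s, c in self.conditions.items() if c == condition]

    def require_replicates(self, minimum: int = 2) -> None:
        for label in self.condition_labels:
            n = len(self.samples_of(label))
            if n < minimum:
                raise ValueError(f"condition {label!r} has {n} replicate(s); >= {minimum} required")


def fc_from_lfc(lfc: float) -> float:
    """Signed fold change from a log2 fold change.

    fc = 2**lfc for lfc >= 0 and -2**(-lfc) for lfc < 0, so a 23-fold
    drop is reported as -23 and the null is +1; |fc| >= 1 always.
    """
    lfc = float(lfc)
    return 2.0 ** lfc if lfc >= 0 else -(2.0 ** (-lfc))


def lfc_from_fc(fc: float) -> float:
    """Inverse of :func:`fc_from_lfc`; requires |fc| >= 1."""
    fc = float(fc)
    if abs(fc) < 1:
        raise ValueError(f"signed fold change must have magnitude >= 1, got {fc}")
    return math.log2(fc) if fc > 0 else -math.log2(-fc)


@dataclass(frozen=True)
class TranscriptionalCluster:
    """A maximal run of >= 2 co-strand candidate genes with gaps below the
    threshold and concordant regulation direction."""

    tc_id: str
    members: tuple[str, ...]
    contig: str
    strand: str
    direction: str  # "up" | "down"
    avg_fc: float
    span: tuple[int, int]
    max_internal_gap: int

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a transcriptional cluster needs >= 2 members")
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class AffectedSet:
    """Final affected-gene set with per-gene inclusion reason.

    ``reasons`` maps gene id -> 'bh_significant' | 'tc_rescued';
    ``directions`` maps gene id -> 'up' | 'down'; ``tc_of`` maps gene id
    -> tc_id for members of a reported TC (absent for isolated genes).
    """

    reasons: dict[str, str] = field(default_factory=dict)
    directions: dict[str, str] = field(default_factory=dict)
    tc_of: dict[str, str] = field(default_factory=dict)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.reasons)

    @property
    def n_affected(self) -> int:
        return len(self.reasons)

    @property
    def n_down(self) -> int:
        return sum(1 for g in self.reasons if self.directions[g] == "down")

    @property
    def n_up(self) -> int:
        return sum(1 for g in self.reasons if self.directions[g] == "up")

    @property
    def n_in_tc(self) -> int:
        return sum(1 for g in self.reasons if g in self.tc_of)

    @property
    def n_tcs(self) -> int:
        return len({self.tc_of[g] for g in self.reasons if g in self.tc_of})

    @property
    def n_rescued(self) -> int:
        return sum(1 for r in self.reasons.values() if r == "tc_rescued")


@dataclass(frozen=True)
class VariantRecord:
    """One variant call; identity is (contig, position, ref, alt)."""

    contig: str
    position: int
    ref: str
    alt: str
    coverage: int
    frequency: float

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError("alt-allele frequency must be in [0, 1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.position, self.ref, self.alt)


@dataclass(frozen=True)
class TruncationReport:
    """Predicted consequence of a CDS edit on the encoded protein."""

    original_length_aa: int
    mutant_length_aa: int
    percent_reduction: float
    stop_position_nt: int | None  # 1-based first nt of the new stop in the mutant CDS
    homopolymer_ambiguous: bool
    no_stop: bool = False


@dataclass
class GrowthSeries:
    """Time-indexed OD660/OD880 readings for one culture replicate."""

    condition: str
    strain: str
    replicate: str
    time_h: np.ndarray
    od660: np.ndarray
    od880: np.ndarray

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.od660 = np.asarray(self.od660, dtype=float)
        self.od880 = np.asarray(self.od880, dtype=float)
        if not (len(self.time_h) == len(self.od660) == len(self.od880)):
            raise ValueError("time, od660 and od880 must have equal length")
        if len(self.time_h) and (np.diff(self.time_h) <= 0).any():
            raise ValueError("time points must be strictly increasing")
        if (self.od660 < 0).any() or (self.od880 < 0).any():
            raise ValueError("optical densities must be >= 0")


@dataclass(frozen=True)
class RegionDefinition:
    """A named genomic interval (e.g. one photosynthesis gene cluster),
    optionally overridden by an explicit gene-id list."""

    name: str
    contig: str
    start: int
    end: int
    genes: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region {self.name}: start > end")


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero (83.5 -> 84,
    -83.5 -> -84); matches how percentages are reported."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def percentage(part: float, whole: float) -> int:
    """Integer percentage of ``part`` in ``whole`` (ties away from zero);
    0 when the denominator is 0."""
    if whole == 0:
        return 0
    return round_half_away(100.0 * part / whole)
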