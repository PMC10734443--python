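"""Synthetic data with planted truth.

Every downstream stage (differential expression, transcriptional-cluster
calling, region profiling, pigmentation metrics, variant screening) is
exercised on data generated here, so the whole pipeline is testable
without any external download. Each generator is deterministic under the
configured seed, and the planted truth it returns is the ground truth the
tests score against.

The chromosome is treated as linear: no wraparound gap between the last
and the first gene.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .models import CountMatrix, GeneModel, GenomeAnnotation, GrowthSeries, VariantRecord

_DISPERSION_POISSON_LIMIT = 1e-12


@dataclass(frozen=True)
class PlantedCluster:
    """A block of co-strand genes planted with a shared signed fold change.

    ``fc`` follows the signed convention (|fc| >= 1); its sign is the
    regulation direction of every member.
    """

    size: int
    strand: str
    fc: float

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("planted clusters need size >= 2")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if abs(self.fc) < 1:
            raise ValueError("planted signed fold change must have magnitude >= 1")

    @property
    def direction(self) -> str:
        return "down" if self.fc < 0 else "up"


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study.

    Gap ranges are validated against ``tc_gap_bp``: every intra-cluster gap
    must be callable (< threshold) and every other gap must break a chain
    (>= threshold), so planted clusters are transcriptional clusters by
    construction.
    """

    n_genes: int = 200
    contig: str = "chr1"
    contig_length: int = 2_000_000
    gene_length_range: tuple[int, int] = (300, 1500)
    gap_small_range: tuple[int, int] = (20, 200)
    gap_large_range: tuple[int, int] = (300, 2000)
    tc_gap_bp: int = 250
    planted_clusters: tuple[PlantedCluster, ...] = ()
    planted_isolated: tuple[float, ...] = ()
    n_replicates: int = 3
    nb_dispersion: float = 0.05
    mean_expression_range: tuple[float, float] = (50.0, 1000.0)
    library_factor_range: tuple[float, float] = (0.7, 1.4)
    # baseline-mean override for the first member of the first planted
    # cluster: a deliberately weakly expressed gene whose raw evidence
    # passes the candidate filters but whose BH-adjusted p tends to fail,
    # exercising the TC rescue rule
    weak_member_mean: float | None = None
    # variant-screen knobs
    n_background_variants: int = 5
    n_unique_variants: int = 2
    n_decoy_variants: int = 3
    # growth-curve knobs
    growth_conditions: tuple[tuple[str, bool], ...] = (("O1", False), ("C3", True))
    growth_replicates: int = 3
    growth_times_h: tuple[float, ...] = tuple(float(t) for t in range(0, 52, 4))
    logistic_k: float = 1.2
    logistic_rate: float = 0.25
    logistic_midpoint_h: float = 12.0
    basal_pmp: float = 1.0
    pigment_effect: float = 0.5
    growth_noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        lo, hi = self.mean_expression_range
        if lo <= 0 or hi < lo:
            raise ValueError("mean_expression_range must be positive and ordered")
        if max(self.gap_small_range) >= self.tc_gap_bp:
            raise ValueError("gap_small_range values must be < tc_gap_bp")
        if min(self.gap_large_range) < self.tc_gap_bp:
            raise ValueError("gap_large_range values must be >= tc_gap_bp")
        planted = sum(c.size for c in self.planted_clusters) + len(self.planted_isolated)
        if planted > self.n_genes:
            raise ValueError("planted cluster sizes sum to more than n_genes")
        for fc in self.planted_isolated:
            if abs(fc) < 1:
                raise ValueError("planted signed fold changes must have magnitude >= 1")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class PlantedTruth:
    """Ground truth of one simulation: what the pipeline should recover."""

    true_fc: dict[str, float] = field(default_factory=dict)
    cluster_of: dict[str, int] = field(default_factory=dict)
    cluster_members: dict[int, tuple[str, ...]] = field(default_factory=dict)
    cluster_fc: dict[int, float] = field(default_factory=dict)
    isolated_genes: tuple[str, ...] = ()
    unique_variant_keys: frozenset = frozenset()
    pigment_effect: float = 0.0
    basal_pmp: float = 1.0


def _draw_gap(rng: np.random.Generator, gap_range: tuple[int, int]) -> int:
    return int(rng.integers(gap_range[0], gap_range[1] + 1))


def gen_annotation(config: SimulationConfig) -> tuple[GenomeAnnotation, PlantedTruth]:
    """Lay genes along a linear contig with controlled intergenic gaps.

    Planted cluster members are consecutive in genomic order, share the
    cluster strand and are separated by gaps drawn from
    ``gap_small_range``; all other consecutive gaps come from
    ``gap_large_range``, so cluster boundaries never merge. Genes never
    overlap (which trivially guarantees no same-strand overlap).
    """
    rng = np.random.default_rng(config.seed)
    n_background = config.n_genes - sum(c.size for c in config.planted_clusters) - len(
        config.planted_isolated
    )

    # blocks: ("cluster", idx) | ("isolated", idx) | ("bg", None), shuffled
    blocks: list[tuple[str, int | None]] = (
        [("cluster", i) for i in range(len(config.planted_clusters))]
        + [("isolated", i) for i in range(len(config.planted_isolated))]
        + [("bg", None)] * n_background
    )
    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]

    genes: list[GeneModel] = []
    truth = PlantedTruth()
    cursor = 1 + _draw_gap(rng, config.gap_large_range)
    gidx = 0
    isolated: list[str] = []

    def place(strand: str) -> GeneModel:
        nonlocal cursor, gidx
        gidx += 1
        length = int(rng.integers(*config.gene_length_range))
        gene = GeneModel(f"gene_{gidx:05d}", config.contig, cursor, cursor + length - 1, strand)
        cursor = gene.end + 1
        return gene

    for kind, idx in blocks:
        if kind == "cluster":
            cl = config.planted_clusters[idx]  # type: ignore[index]
            for j in range(cl.size):
                g = place(cl.strand)
                genes.append(g)
                truth.true_fc[g.gene_id] = cl.fc
                truth.cluster_of[g.gene_id] = idx  # type: ignore[assignment]
                if j < cl.size - 1:
                    cursor += _draw_gap(rng, config.gap_small_range)
            truth.cluster_members[idx] = tuple(  # type: ignore[index]
                g for g, c in truth.cluster_of.items() if c == idx
            )
            truth.cluster_fc[idx] = cl.fc  # type: ignore[index]
        elif kind == "isolated":
            g = place(str(rng.choice(["+", "-"])))
            genes.append(g)
            truth.true_fc[g.gene_id] = config.planted_isolated[idx]  # type: ignore[index]
            isolated.append(g.gene_id)
        else:
            g = place(str(rng.choice(["+", "-"])))
            genes.append(g)
            truth.true_fc[g.gene_id] = 1.0
        cursor += _draw_gap(rng, config.gap_large_range)

    truth.isolated_genes = tuple(isolated)
    last_end = genes[-1].end
    if last_end > config.contig_length:
        raise ValueError(
            f"contig too short: layout needs {last_end} bp but contig_length is "
            f"{config.contig_length}"
        )
    return GenomeAnnotation(genes), truth


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean mu, var mu + d*mu^2); exact Poisson when d ~ 0."""
    mu = np.asarray(mu, dtype=float)
    if dispersion <= _DISPERSION_POISSON_LIMIT:
        return rng.poisson(mu)
    n = 1.0 / dispersion
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def _ratio_from_fc(fc: float) -> float:
    """Mutant/wild-type mean ratio implied by a signed fold change."""
    return fc if fc >= 1 else 1.0 / abs(fc)


def gen_counts(
    annotation: GenomeAnnotation, truth: PlantedTruth, config: SimulationConfig
) -> CountMatrix:
    """Negative-binomial counts with the planted condition effect.

    Gene baseline means are log-uniform over ``mean_expression_range``;
    the mutant-condition mean is the baseline times the ratio implied by
    the planted signed fold change; per-sample library factors (log-uniform
    over ``library_factor_range``) exercise normalization downstream.
    """
    rng = np.random.default_rng(config.seed + 1)
    gene_ids = annotation.gene_ids()
    lo, hi = config.mean_expression_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), len(gene_ids)))
    if config.weak_member_mean is not None and 0 in truth.cluster_members:
        weak_gene = truth.cluster_members[0][0]
        base[gene_ids.index(weak_gene)] = config.weak_member_mean
    ratio = np.array([_ratio_from_fc(truth.true_fc.get(g, 1.0)) for g in gene_ids])

    n = config.n_replicates
    samples = [f"wt_{i + 1}" for i in range(n)] + [f"mut_{i + 1}" for i in range(n)]
    conditions = {s: ("wt" if s.startswith("wt") else "mut") for s in samples}
    flo, fhi = config.library_factor_range
    lib = np.exp(rng.uniform(np.log(flo), np.log(fhi), len(samples)))

    cols = {}
    for j, s in enumerate(samples):
        mu = base * (ratio if conditions[s] == "mut" else 1.0) * lib[j]
        cols[s] = _nb_sample(rng, mu, config.nb_dispersion)
    counts = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    return CountMatrix(counts, conditions)


def gen_variants(
    config: SimulationConfig,
) -> tuple[list[VariantRecord], list[VariantRecord], PlantedTruth]:
    """Variant tables for wild type and mutant with planted unique calls.

    Both tables share ``n_background_variants`` calls that pass the
    coverage/frequency filters; the mutant table additionally carries
    ``n_unique_variants`` passing calls (the planted strain differences)
    and ``n_decoy_variants`` unique calls designed to fail either the
    coverage (< 10) or the frequency (<= 60%) filter.
    """
    rng = np.random.default_rng(config.seed + 2)
    bases = np.array(list("ACGT"))

    def rand_snv(position: int, coverage: int, freq: float) -> VariantRecord:
        ref, alt = rng.choice(bases, size=2, replace=False)
        return VariantRecord(config.contig, position, str(ref), str(alt), coverage, round(freq, 3))

    total = config.n_background_variants + config.n_unique_variants + config.n_decoy_variants
    positions = np.sort(
        rng.choice(np.arange(1, config.contig_length + 1), size=total, replace=False)
    )
    pos_iter = iter(int(p) for p in positions)

    background = [
        rand_snv(next(pos_iter), int(rng.integers(20, 120)), rng.uniform(0.75, 1.0))
        for _ in range(config.n_background_variants)
    ]
    unique = [
        rand_snv(next(pos_iter), int(rng.integers(20, 120)), rng.uniform(0.75, 1.0))
        for _ in range(config.n_unique_variants)
    ]
    decoys = []
    for k in range(config.n_decoy_variants):
        if k % 2 == 0:  # fails coverage
            decoys.append(rand_snv(next(pos_iter), int(rng.integers(1, 10)), rng.uniform(0.75, 1.0)))
        else:  # fails frequency (strictly > 60% is required to pass)
            decoys.append(rand_snv(next(pos_iter), int(rng.integers(20, 120)), rng.uniform(0.05, 0.60)))

    wildtype = sorted(background, key=lambda v: v.position)
    mutant = sorted(background + unique + decoys, key=lambda v: v.position)
    truth = PlantedTruth(unique_variant_keys=frozenset(v.key for v in unique))
    return wildtype, mutant, truth


def gen_growth(config: SimulationConfig) -> list[GrowthSeries]:
    """Logistic growth plus a condition-dependent pigment signal.

    OD660 follows a logistic curve; OD880 = OD660 * (basal PMP +
    pigment_effect * 1[pigmented condition and wild-type strain]) plus
    Gaussian measurement noise. The mutant strain never pigments,
    mirroring the unpigmented phenotype under study. ``growth_noise_sd = 0``
    is the exact noise-free mode used by the recovery tests.
    """
    rng = np.random.default_rng(config.seed + 3)
    t = np.asarray(config.growth_times_h, dtype=float)
    series: list[GrowthSeries] = []
    for strain in ("wt", "mut"):
        for condition, pigmented in config.growth_conditions:
            for rep in range(1, config.growth_replicates + 1):
                od660 = config.logistic_k / (
                    1.0 + np.exp(-config.logistic_rate * (t - config.logistic_midpoint_h))
                )
                pmp = config.basal_pmp + (
                    config.pigment_effect if (pigmented and strain == "wt") else 0.0
                )
                od880 = od660 * pmp
                if config.growth_noise_sd > 0:
                    od660 = np.clip(od660 + rng.normal(0, config.growth_noise_sd, t.size), 0, None)
                    od880 = np.clip(od880 + rng.normal(0, config.growth_noise_sd, t.size), 0, None)
                series.append(GrowthSeries(condition, strain, f"r{rep}", t, od660, od880))
    return series
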