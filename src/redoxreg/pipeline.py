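"""End-to-end orchestration: simulate (optional) -> DE -> TC calling ->
region/category summaries -> phenotype metrics -> variant screen.

Each stage reads/writes the plain-text formats in :mod:`redoxreg.io`;
the run ends with a JSON manifest carrying input hashes, parameters and
headline counts, so identical configs (and seeds) yield identical
manifests.
"""
from __future__ import annotations

import hashlib
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import diffexpr, io, phenotype, regions as regions_mod, simulate as sim, tc, variants as var_mod
from .simulate import SimulationConfig


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    outdir: Path
    simulation: SimulationConfig | None = None
    gff: Path | None = None
    counts: Path | None = None
    conditions: Path | None = None
    regions: Path | None = None
    categories: Path | None = None
    growth: Path | None = None
    variants_wt: Path | None = None
    variants_mut: Path | None = None
    fc_threshold: float = tc.DEFAULT_FC_THRESHOLD
    raw_p_threshold: float = tc.DEFAULT_RAW_P_THRESHOLD
    bh_threshold: float = tc.DEFAULT_BH_THRESHOLD
    max_gap: int = tc.DEFAULT_MAX_GAP_BP
    min_coverage: int = 10
    min_frequency: float = 0.60
    control_condition: str = "O1"
    pathlength_factor: float = 1.0
    force: bool = False

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        for name in ("fc_threshold", "raw_p_threshold", "bh_threshold", "max_gap",
                     "min_coverage", "min_frequency", "pathlength_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _log(msg: str) -> None:
    print(f"[redoxreg] {msg}", file=sys.stderr)


def run_all(config: PipelineConfig) -> dict:
    """Run every configured stage; returns (and writes) the manifest."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not config.force:
        raise FileExistsError(f"{manifest_path} exists; pass force=True/--force to overwrite")

    manifest: dict = {"stages": [], "inputs": {}, "parameters": {
        "fc_threshold": config.fc_threshold,
        "raw_p_threshold": config.raw_p_threshold,
        "bh_threshold": config.bh_threshold,
        "max_gap": config.max_gap,
        "min_coverage": config.min_coverage,
        "min_frequency": config.min_frequency,
        "control_condition": config.control_condition,
        "pathlength_factor": config.pathlength_factor,
    }}

    def stage(name: str):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as exc:  # noqa: BLE001 — stage-named rethrow
                raise StageError(name, exc) from exc
            dt = time.perf_counter() - t0
            _log(f"stage {name} done in {dt:.2f} s")
            manifest["stages"].append(name)

        return deco

    gff_path, counts_path, cond_path = config.gff, config.counts, config.conditions
    growth_path = config.growth
    vwt_path, vmut_path = config.variants_wt, config.variants_mut

    if config.simulation is not None:
        @stage("simulate")
        def _():
            nonlocal gff_path, counts_path, cond_path, growth_path, vwt_path, vmut_path
            cfg = config.simulation
            annotation, truth = sim.gen_annotation(cfg)
            matrix = sim.gen_counts(annotation, truth, cfg)
            wt_vars, mut_vars, var_truth = sim.gen_variants(cfg)
            growth = sim.gen_growth(cfg)
            gff_path = out / "annotation.gff3"
            counts_path = out / "counts.tsv"
            cond_path = out / "conditions.csv"
            growth_path = out / "growth.csv"
            vwt_path = out / "variants_wt.vcf"
            vmut_path = out / "variants_mut.vcf"
            io.write_gff3(annotation, gff_path)
            io.write_counts_tsv(matrix, counts_path)
            io.write_conditions_csv(matrix, cond_path)
            io.write_growth_csv(growth, growth_path)
            contigs = {cfg.contig: cfg.contig_length}
            io.write_vcf(wt_vars, vwt_path, contigs)
            io.write_vcf(mut_vars, vmut_path, contigs)
            io.write_json(
                {
                    "true_fc": truth.true_fc,
                    "cluster_members": {str(k): list(v) for k, v in truth.cluster_members.items()},
                    "unique_variant_keys": sorted(map(list, var_truth.unique_variant_keys)),
                },
                out / "truth.json",
            )

    for p in (gff_path, counts_path, cond_path):
        if p is None:
            raise StageError("de", FileNotFoundError("annotation/counts/conditions not configured"))
        if not Path(p).exists():
            raise StageError("de", FileNotFoundError(str(p)))
        manifest["inputs"][Path(p).name] = _sha256(Path(p))

    state: dict = {}

    @stage("de")
    def _():
        matrix = io.read_counts_tsv(counts_path, cond_path)
        de = diffexpr.run_de(matrix)
        io.write_de_tsv(de, out / "de_results.tsv")
        state["de"] = de

    @stage("tc")
    def _():
        annotation = io.read_gff3(gff_path)
        de = state["de"]
        candidates = tc.select_candidates(de, config.fc_threshold, config.raw_p_threshold)
        tcs, isolated = tc.call_tcs(candidates, annotation, config.max_gap)
        affected = tc.apply_rescue(de, candidates, tcs, config.bh_threshold)
        summary = tc.summarize_affected(affected, tcs, de)
        io.write_tc_tsv(tcs, out / "tcs.tsv")
        io.write_json(summary, out / "tc_summary.json")
        aff_rows = [
            {"gene_id": g, "reason": affected.reasons[g], "direction": affected.directions[g],
             "tc_id": affected.tc_of.get(g, "")}
            for g in affected.gene_ids
        ]
        import pandas as pd

        pd.DataFrame(aff_rows).to_csv(out / "affected_genes.tsv", sep="\t", index=False)
        state.update(annotation=annotation, candidates=candidates, tcs=tcs,
                     isolated=isolated, affected=affected, summary=summary)
        manifest["summary"] = {k: v for k, v in summary.items() if k != "largest_tcs"}

    if config.regions is not None:
        @stage("regions")
        def _():
            region_defs = io.read_regions_tsv(config.regions)
            profiles = [
                regions_mod.profile_region(r, state["de"], state["affected"], state["tcs"],
                                           state["annotation"])
                for r in region_defs
            ]
            io.write_json({p["region"]: {k: v for k, v in p.items() if k != "per_gene"}
                           for p in profiles}, out / "region_profiles.json")

    if config.categories is not None:
        @stage("categories")
        def _():
            cat_map = io.read_category_tsv(config.categories)
            breakdown = regions_mod.categorize_affected(state["affected"], cat_map, state["de"])
            breakdown.to_csv(out / "category_breakdown.tsv", sep="\t", index=False)

    if growth_path is not None:
        @stage("phenotype")
        def _():
            series = io.read_growth_csv(growth_path)
            table = phenotype.endpoint_table(series, config.pathlength_factor)
            dpmp = phenotype.endpoint_delta_pmp(series, config.control_condition,
                                                config.pathlength_factor)
            io.write_json(
                {
                    "endpoints": table,
                    "delta_pmp": {f"{s}:{c}": v for (s, c), v in dpmp.items()},
                },
                out / "phenotype.json",
            )

    if vwt_path is not None and vmut_path is not None:
        @stage("variants")
        def _():
            wt = var_mod.filter_variants(io.read_vcf(vwt_path), config.min_coverage,
                                         config.min_frequency)
            mut = var_mod.filter_variants(io.read_vcf(vmut_path), config.min_coverage,
                                          config.min_frequency)
            unique = var_mod.unique_to_mutant(mut, wt)
            io.write_variants_tsv(unique, out / "mutant_unique_variants.tsv")
            manifest.setdefault("summary", {})["n_unique_variants"] = len(unique)

    io.write_json(manifest, manifest_path)
    return manifest
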