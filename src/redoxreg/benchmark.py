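"""Reference synthetic benchmarks used by the test suite and the
reproduction script.

Two canonical datasets:

* **recovery** — 2,000 genes on a 20 Mbp contig with 40 planted
  transcriptional clusters, ten per signed fold change in
  {-83, -23, -4, +4}, 6+6 replicates, dispersion 0.01, baseline means
  log-uniform on [200, 2000]. The first member of the first (fc = -4)
  cluster is planted at baseline mean 3.5 so its raw evidence passes the
  candidate filters while its BH-adjusted p tends to fail — the
  textbook case for the TC rescue rule.
* **null** — 2,000 genes, no planted effects, 3+3 replicates at the
  generator's default dispersion; used to measure the Wald test's
  type-I error at the pipeline's working replicate number.
"""
from __future__ import annotations

import numpy as np

from . import diffexpr, simulate as sim, tc
from .simulate import PlantedCluster, SimulationConfig

RECOVERY_FCS = (-4.0, 4.0, -23.0, -83.0)


def recovery_config(seed: int = 1) -> SimulationConfig:
    clusters = tuple(
        PlantedCluster(3 + (k % 3), "+" if k % 2 else "-", fc)
        for fc in RECOVERY_FCS
        for k in range(10)
    )
    return SimulationConfig(
        n_genes=2000,
        contig_length=20_000_000,
        planted_clusters=clusters,
        n_replicates=6,
        nb_dispersion=0.01,
        mean_expression_range=(200.0, 2000.0),
        weak_member_mean=3.5,
        seed=seed,
    )


def run_recovery(seed: int = 1) -> dict:
    """Run the full DE -> TC -> rescue pipeline on the recovery benchmark
    and score it against the planted truth.

    Returns cluster-level precision/recall (a planted cluster counts as
    recovered only when a called TC matches its members exactly), the
    mean estimated signed fc and its relative error per planted group,
    and how many planted genes the rescue rule saved.
    """
    cfg = recovery_config(seed)
    annotation, truth = sim.gen_annotation(cfg)
    matrix = sim.gen_counts(annotation, truth, cfg)
    de = diffexpr.run_de(matrix)
    candidates = tc.select_candidates(de)
    tcs, _ = tc.call_tcs(candidates, annotation)
    affected = tc.apply_rescue(de, candidates, tcs)

    called = {t.members for t in tcs}
    planted = {tuple(v) for v in truth.cluster_members.values()}
    tp = len(called & planted)
    fc_recovery = {}
    for fc in RECOVERY_FCS:
        genes = [g for g, v in truth.true_fc.items() if v == fc]
        est = float(de.loc[genes, "fc"].mean())
        fc_recovery[fc] = {"estimate": est, "rel_error": abs(est - fc) / abs(fc)}
    rescued_planted = [
        g for g, r in affected.reasons.items() if r == "tc_rescued" and g in truth.cluster_of
    ]
    return {
        "precision": tp / len(called) if called else 0.0,
        "recall": tp / len(planted),
        "fc_recovery": fc_recovery,
        "n_rescued": affected.n_rescued,
        "n_rescued_planted": len(rescued_planted),
        "summary": tc.summarize_affected(affected, tcs, de),
    }


def null_config(seed: int = 0) -> SimulationConfig:
    return SimulationConfig(n_genes=2000, contig_length=20_000_000, n_replicates=3, seed=seed)


def type_i_error(seed: int = 0) -> float:
    """Fraction of raw Wald p values below 0.05 on the null benchmark."""
    cfg = null_config(seed)
    annotation, truth = sim.gen_annotation(cfg)
    matrix = sim.gen_counts(annotation, truth, cfg)
    de = diffexpr.run_de(matrix)
    p = de.loc[de["tested"], "pvalue"].to_numpy()
    return float(np.mean(p < 0.05))
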