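"""Fold-change profile of a named genomic region (a photosynthesis gene
cluster, say) and a biological-process breakdown of the affected set.
"""
import redoxreg as rr
from redoxreg.models import RegionDefinition

cfg = rr.SimulationConfig(
    n_genes=120,
    planted_clusters=(rr.PlantedCluster(4, "+", -23.0), rr.PlantedCluster(3, "-", 4.0)),
    n_replicates=4,
    seed=7,
)
annotation, truth = rr.gen_annotation(cfg)
de = rr.run_de(rr.gen_counts(annotation, truth, cfg))
candidates = rr.select_candidates(de)
tcs, _ = rr.call_tcs(candidates, annotation)
affected = rr.apply_rescue(de, candidates, tcs)

# a region spanning the first planted cluster plus some flanking genes
members = truth.cluster_members[0]
span = (annotation[members[0]].start - 5000, annotation[members[-1]].end + 5000)
region = RegionDefinition("PGC-like", cfg.contig, max(1, span[0]), span[1])
profile = rr.profile_region(region, de, affected, tcs, annotation)
print(f"region {profile['region']}: {profile['n_genes']} genes, "
      f"{profile['n_affected']} affected, avg fc {profile['avg_fc_affected']:+.1f}, "
      f"{profile['n_tcs_inside']} TC(s) fully inside, "
      f"{profile['n_isolated_affected']} isolated affected gene(s)")
print(f"strongest response: {profile['max_abs_fc_gene']} at fc {profile['max_abs_fc']:+.1f}")

category_map = {g: "PSA" for g in members}  # curated map: planted cluster = photosystem genes
breakdown = rr.categorize_affected(affected, category_map, de)
print(breakdown.to_string(index=False))
# Unmapped affected genes land in 'Unknown'; percentages are of the whole
# affected set and sum to 100 up to rounding.
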