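"""Variant screen: coverage/frequency filtering, mutant-unique calls,
and the protein consequence of a single-G deletion in a 7-G run.
"""
import redoxreg as rr
from redoxreg.variants import orf_protein_length, predict_frameshift

cfg = rr.SimulationConfig(n_unique_variants=2, n_decoy_variants=3, seed=12)
wt, mut, truth = rr.gen_variants(cfg)
kept_mut = rr.filter_variants(mut, min_coverage=10, min_frequency=0.60)
kept_wt = rr.filter_variants(wt, min_coverage=10, min_frequency=0.60)
unique = rr.unique_to_mutant(kept_mut, kept_wt)
print(f"mutant table {len(mut)} calls -> {len(kept_mut)} pass filters -> "
      f"{len(unique)} unique to the mutant (planted: {len(truth.unique_variant_keys)})")
# Decoy calls with coverage < 10 or frequency <= 60% are screened out;
# only the planted strain differences survive the set difference.

# a synthetic CDS carrying a 7-G homopolymer run: deleting any one G
# gives the same frameshifted protein
cds = "ATG" + "GCTCTGAAAGTCGAA" * 7 + "GGGGGGG" + "TC" + "GCTCTGAAAGTCGAA" * 3 + "TAA"
assert len(cds) % 3 == 0
run_start = cds.index("GGGGGGG") + 1
report = predict_frameshift(cds, (run_start + 3, "G", ""))  # delete the 4th G
print(f"CDS {len(cds)} nt encodes {report.original_length_aa} aa "
      f"(orf_protein_length check: {orf_protein_length(len(cds))})")
print(f"after the 1-bp deletion: {report.mutant_length_aa} aa, "
      f"{report.percent_reduction:.0f}% shorter, new stop at nt {report.stop_position_nt}, "
      f"homopolymer-ambiguous={report.homopolymer_ambiguous}")
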