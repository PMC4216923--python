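"""Cross-generation retention of DMPs and sample clustering.

Checks how many of a tenth-generation plant's DMPs stay significant
(same direction) in its selfed offspring — the generator inherits each
epimutation with probability 0.76, so the printed fraction should land
near that — then clusters all samples on CG-DMP methylation levels.
"""

from maepi import (MethylationCallPolicy, SimulationConfig, call_dmps,
                   cluster_samples, remove_parental_dmps, retention_analysis,
                   simulate_bisulfite_counts, simulate_pedigree, site_universe)

cfg = SimulationConfig(seed=3, chromosome_lengths=(150_000, 150_000))
truth, _ = simulate_pedigree(cfg)
records, _ = simulate_bisulfite_counts(truth, cfg)
parental = [s.sample_id for s in truth.bisulfite_samples if s.role == "parental"]
derived = [s.sample_id for s in truth.bisulfite_samples if s.role == "derived"]
policy = MethylationCallPolicy()

_, analyzable = site_universe(records, parental, derived, policy)
mask, _ = remove_parental_dmps(records, parental, policy, analyzable)
dmps = call_dmps(records, parental, derived, policy, mask)

for carrier, offspring in (("G10-C1", "G11-C1"), ("G10-S1", "G11-S1")):
    kept, lost, frac = retention_analysis(dmps, records, parental, carrier,
                                          offspring, policy, mask)
    print(f"{carrier} -> {offspring}: {kept} retained, {lost} lost "
          f"({frac:.1%} retained; generator truth 76%)")

cg = dmps[dmps["context"] == "CG"]
_, labels, newick = cluster_samples(records, cg["site_idx"].unique(),
                                    parental + derived, n_sites=20_000, seed=0)
print("\naverage-linkage dendrogram on CG-DMP methylation levels:")
print(newick)
print("(saline G10 samples should sit furthest from the G1 parents)")
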