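"""Simulate a tetraploid admixed genome and write its observations to disk.

Builds a genome whose four haplotypes are mosaics of European-like (E) and
Asian-like (A) founder segments, ~10 meioses old, then emits the three
files a real strain would contribute: a VCF with genotypes and read
counts, a HapCUT2-style fragment file of long-read observations, and a
strain->population table.
"""

import os

from polyadmix.ioformats import write_fragments, write_population_table, write_vcf
from polyadmix.simdata import (
    SimConfig,
    simulate_admixed_polyploid,
    simulate_founders,
    simulate_observations,
)

out = "scratch/example01"
os.makedirs(out, exist_ok=True)

cfg = SimConfig(seed=1, ploidy=4, n_meioses=10)
pools = simulate_founders(cfg)
truth = simulate_admixed_polyploid(pools, cfg)
matrix, counts, fragments = simulate_observations(truth, cfg, strain="ale_sim")

write_vcf(matrix, f"{out}/ale_sim.vcf", counts)
write_fragments(fragments, f"{out}/ale_sim.frag")
write_population_table(matrix.pop, f"{out}/pops.tsv")

print(f"sites simulated:        {len(truth.sites)}")
print(f"diagnostic E/A sites:   {len(pools.diagnostic_idx)}")
print(f"ghost-private sites:    {len(pools.ghost_private_idx)}")
print(f"ancestry crossovers:    {truth.n_crossovers()}")
print(f"LOH tracts applied:     {len(truth.loh_tracts)}")
print(f"long-read fragments:    {len(fragments)}")
print(f"het fraction of calls:  {(matrix.calls == 1).mean():.3f}")
print()
print("Crossovers accumulate at n_meioses per Morgan (0.34 cM/kb), so the")
print("count above reflects the simulated admixture age; the high het")
print("fraction is the signature of a polyploid carrying two ancestries.")
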