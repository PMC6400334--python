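"""Phase long-read fragments into a variable number of haplotypes.

Simulates a tetraploid at ~35x fragment coverage with 2% allele error,
runs the three-round greedy merger, and reports the diagnostics used to
judge a phasing: how many haplotypes cover each site on average, and the
fragment error rate implied by read-vs-haplotype mismatches.
"""

from polyadmix.phaser import estimate_error_rate, haplotype_count_profile, phase
from polyadmix.simdata import (
    SimConfig,
    simulate_admixed_polyploid,
    simulate_founders,
    simulate_observations,
)

cfg = SimConfig(
    seed=3, n_chrom=1, chrom_length=200_000, n_sites_per_chrom=400,
    ploidy=4, fragment_count=500, fragment_length_mean=15_000,
    fragment_error_rate=0.02, loh_tract_rate=0.0,
)
pools = simulate_founders(cfg)
truth = simulate_admixed_polyploid(pools, cfg)
_, _, fragments = simulate_observations(truth, cfg)

hapset = phase(fragments, pools.sites)
counts, mean_count = haplotype_count_profile(hapset)
rate = estimate_error_rate(fragments, hapset)

print(f"fragments phased:          {len(fragments)}")
print(f"haplotypes assembled:      {len(hapset)}")
print(f"mean haplotypes per site:  {mean_count:.2f}")
print(f"estimated error rate:      {100 * rate:.2f}%")
print()
print("A tetraploid should phase to about four haplotypes per covered site;")
print("the error-rate estimate recovers the simulated 2% per-allele error,")
print("the same diagnostic used to validate phasing of real PacBio reads.")
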