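"""Date admixture from the decay of ancestry covariance with distance.

Same-ancestry alleles at linked sites stay correlated after admixture;
each meiosis erodes the correlation at a rate set by the genetic map.
Fitting amplitude * exp(-x/D) to the binned covariance and converting the
decay scale D with t = 1/(D_kb * 0.0034) dates the admixture in meiotic
equivalents (0.34 cM/kb map).
"""

from polyadmix.ancestry import paint
from polyadmix.lddecay import ancestry_covariance, fit_decay, meiotic_equivalents
from polyadmix.simdata import (
    SimConfig,
    simulate_admixed_polyploid,
    simulate_founders,
    truth_haplotype_set,
    truth_panel,
)

cfg0 = SimConfig(
    seed=11, n_chrom=2, chrom_length=500_000, n_sites_per_chrom=1000,
    frac_diagnostic=0.5, diagnostic_leak=0.0, admixture_fraction=0.5,
    fragment_count=0, loh_tract_rate=0.0,
)
pools = simulate_founders(cfg0)
panel = truth_panel(pools)

for n_meioses in (10, 50):
    painted = []
    for g in range(5):  # several genomes sharpen the covariance curve
        cfg = cfg0.with_(n_meioses=n_meioses, seed=100 * n_meioses + g)
        truth = simulate_admixed_polyploid(pools, cfg)
        painted += paint(truth_haplotype_set(truth, id_prefix=f"g{g}"), panel)
    fit = fit_decay(ancestry_covariance(painted, pools.sites))
    print(
        f"true age {n_meioses:>2} meioses: decay scale "
        f"{fit.decay_scale_bp / 1000:.1f} kb -> estimated "
        f"{fit.meiotic_equivalents:.1f} meiotic equivalents"
    )

print(f"a 30-kb decay corresponds to {meiotic_equivalents(30.0):.1f} meioses")
print()
print("Older admixture leaves shorter ancestry blocks, hence a shorter")
print("decay scale and a larger meiotic-equivalent estimate.")
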