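# Methods

This note documents the models and procedures implemented in `polyadmix`,
the assumptions behind them, the defaults and why, and what the synthetic
data generator does and does not emulate.

## The scientific setting

The package targets genomes that are (i) polyploid — three or four
chromosome copies, so standard diploid phasing and genotype models do not
apply; (ii) admixed — each haplotype is a mosaic of segments from two
diverged source populations (called E, European-like, and A, Asian-like
throughout); and (iii) clonally propagated, so mitotic gene conversion and
recombination cause loss of heterozygosity (LOH) but meiosis is rare.
Brewing yeasts are the motivating case.  The analyses answer: how many
genome copies does a strain carry, what are its haplotypes, which ancestry
does each segment derive from, how long ago did the admixture happen, and
what fraction of the genome comes from each source.

## Variable-ploidy phasing

Fragments (per-read allele observations at het SNPs) are merged into
clusters in rounds.  A candidate pair is eligible when it shares at least
`min_overlap = 4` sites; in round 1 the overlap must be mismatch-free, in
rounds 2–3 at least `min_match_frac = 0.80` of shared sites must agree.
Eligible merges execute globally best-score-first with
`score = matches − 5 × mismatches`, re-scoring after every merge.
Consensus at a conflicting site is the allele with majority read support.
Output haplotypes covering fewer than `min_overlap` sites are dropped as
residual fragments too short to merge.

Decisions the criteria above do not fix, made here for determinism:

* merge order is globally best-first via a priority queue (a per-read
  iteration order would make the result depend on input order);
* ties in score break by more matches, then longer combined extent, then
  lowest cluster ids; consensus ties resolve toward the cluster with more
  supporting reads;
* rounds 2–3 allow read-to-haplotype joins as well as
  haplotype-to-haplotype merges (all clusters compete equally);
* reads are canonically sorted (extent start, length descending, read id)
  before clustering, so the output is invariant to file order.

The fragment error rate is estimated as the total of each read's minimum
mismatch count against any overlapping haplotype, divided by the alleles
compared; reads overlapping no haplotype are excluded and logged.

Known behaviour: the greedy heuristic is not an optimizer.  On small
noiseless instances it reaches the exhaustive-partition optimum in ≥ 90%
of cases (tested against a brute-force oracle); at realistic depth and 2%
allele error it occasionally produces a chimeric merge where two true
haplotypes agree over ≥ 80% of a window (admixed haplotypes genuinely
share founder segments), which inflates the haplotype count above the
ploidy and the apparent switch rate.  The regression tests pin nominal
behaviour at fixed seeds; users should treat per-region haplotype counts
above the expected ploidy as a warning sign, as with the real-data
control.

## Ploidy from allele balance

At a het site with c alternative copies among N, alt reads are
approximately Binomial(depth, c/N).  Each ploidy class is scored as a
fixed-weight binomial mixture over its allele-balance modes — {1/2},
{1/3, 2/3}, {1/4, 1/2, 3/4} with equal component weights — and the
maximum-likelihood class returned.  Weights are fixed, not estimated, to
keep the classifier deterministic and parameter-free; the extra modes of
the richer classes are automatically penalised by their 1/k weight when
the data are concentrated at 1/2.

Defaults: sites need depth ≥ 10 (`min_depth`); alt fractions outside
(0.05, 0.95) at het-called sites are excluded as genotype miscalls; a full
2/3/4 call needs ≥ 500 usable het sites (`min_het`).  With 50–499 sites a
non-diploid best fit is reported as `polyploid-unresolved` (enough signal
to reject diploidy, not enough to separate 3n from 4n) and a diploid best
fit as diploid; below 50 sites the call is `unknown`.  The 500/50 cutoffs
are this package's own operational choices, exposed as parameters.

Aneuploidy: per-chromosome median depth over the median of chromosome
medians; flagged when the ratio deviates from 1 by more than 0.20
(default), which separates a 4-in-3n chromosome (ratio 1.33) from Poisson
noise at ≥ 20× while staying conservative.  At least two chromosomes are
required, and with few chromosomes the median baseline itself absorbs part
of a large deviation — interpret flags on < 4 chromosomes cautiously.

## Ancestry panels, painting, switches

Population allele frequencies count homozygous calls fully and
heterozygous calls half: `freq = (2·homAlt + het) / (2·called)`, excluding
strains with more than 1% assigned admixture.  Half-calls and
low-genotype-quality calls are treated as missing by the VCF reader.
Diagnostic sites require frequency ≥ 0.99 in one source and ≤ 0.01 in the
other; group-private alleles require ≥ 0.25 in the owning group and
< 0.01 in every other population (either allele may be the private one).

Painting codes each covered diagnostic site E or A by allele match;
private-allele sites are flagged but never enter E/A purity.  A haplotype
is E-pure or A-pure when more than 95% (default purity) of its coded sites
agree, mixed otherwise, unclassified with zero coded sites.  Switch
counting collapses the code sequence into runs, discards runs failing the
filter (< `min_sites` sites, or spanning < `min_span_bp` where span is
last-minus-first position + 1), merges same-type flanks, and reports
surviving runs − 1.  Because codes are binary, a dropped run's flanks
always share a type, and the filters are monotone, so a single
drop-then-merge pass suffices and stronger filters can only reduce counts.

Genome fractions on pure haplotypes are measured over classified haplotype
extents (not a full reference), each haplotype weighted by its own extent;
overlapping haplotypes of one strain each count their own bp.  Copy
numbers of A-typed and private alleles are averaged over sites covered by
exactly four phased haplotypes with both alleles present.

## Admixture-LD dating

Ancestry codes (E = 0, A = 1) are mean-centered per site across the
haplotypes covering it; invariant sites are excluded.  Products of
centered codes for within-haplotype site pairs at 1–50 kb are binned every
100 bp, and `a·exp(−x/D)` is fit by least squares weighted by per-bin pair
counts.  A fit is flagged non-converged when the scale runs to its bound
(no measurable decay in the window, e.g. unrecombined genomes).

Map units: the package uses a uniform yeast map of **0.34 cM/kb** (the
genome-wide average, ≈ 4,400 cM over 12 Mb).  Under that map the ancestry
covariance after t meioses decays as `exp(−t · x_kb · 0.0034)`, so the
fitted scale converts as `t = 1/(D_kb × 0.0034)` — 30 kb ↦ 9.8 meioses,
6.3 kb ↦ 46.7.  The same constant written as "kb/cM" appears in parts of
the literature; the form adopted here is the one under which the simulator
(junctions at t per Morgan) and the dating conversion are mutually
consistent, which the recovery tests verify directly.  The "50% drop"
distance D·ln 2 is also reported.

The estimator assumes a single admixture pulse, a uniform map, and no
interference; repeated back-crossing or map heterogeneity would bias t.

## f4 statistics and clocks

`f4(A,B;C,D)` is the mean over complete-case sites of
`(p_A−p_B)(p_C−p_D)`; no frequency imputation is attempted.  Standard
errors come from a delete-one jackknife over consecutive blocks of 500
polymorphic SNPs in genome order, the final partial block merged into its
predecessor: `se² = ((B−1)/B)·Σ(θ₋ᵢ − mean)²`.  Note that Z scores are
t-like with B−1 degrees of freedom: with fewer than ~10 blocks the |Z|>3
criterion is anticonservative, which the calibration test sizes around.

The admixture proportion is `α = f4(R1,R2;test,S_E) / f4(R1,R2;S_A,S_E)`,
both terms evaluated on the common complete-case site set; a single strain
can serve as `test` through its genotype dosage (0, ½, 1).  α is reported
raw (it may fall slightly outside [0,1]) and flagged when the
denominator's |Z| < 3.

Clock operations are pure arithmetic: divergence percent =
100 × private-allele count / sites surveyed; years = (d/100)/(μ·g) with
defaults μ = 5×10⁻¹⁰ per base per generation and g = 150 generations/year;
expected mitotic events per cell division scale published per-locus rates
(conversion 1.3×10⁻⁶ per division with 16.6 kb median tracts;
recombination 7×10⁻⁶ per 120 kb) to a 48-Mb tetraploid genome.  Replicate
genotype discordance is mismatches over sites called in both strains.

## The synthetic-data generator

What it emulates, with defaults chosen to mirror the study conditions the
inferences assume:

* **Founders.** Four pools of 20 haplotypes: E and A fixed for opposite
  alleles at a configurable fraction of diagnostic sites (default 30%,
  residual leak 0.5%); a ghost population carrying private alleles at 50%
  frequency at 5% of sites and resembling E at diagnostic sites with
  affinity 0.8; an outgroup at the ancestral 50:50 state.  The outgroup
  and the ghost's E-affinity exist so that four-population tests have a
  usable reference pair; three pools alone cannot anchor an f4-ratio.
* **Admixture.** Single pulse, then t = `n_meioses` rounds of random
  mating approximated by the standard Markov ancestry process: junctions
  Poisson at t per Morgan on a uniform 0.34 cM/kb map (no interference),
  segment ancestries iid Bernoulli(`admixture_fraction`, default 0.4).
  This reproduces the exponential ancestry-LD decay the dating method
  fits; it does not represent repeated back-crossing pedigrees.
* **Polyploidy.** N independent admixed haplotypes drawn per genome
  (auto-polyploid union) — the simplest mechanism consistent with the
  observations the pipeline uses; allo- vs auto-polyploid origins are not
  distinguished.
* **LOH.** Per-haplotype tract initiations Poisson along the chromosome
  (default 5×10⁻⁷ per bp), exponential lengths with 16.6 kb mean, donor
  haplotype's alleles and ancestry copied over the acceptor.
* **Observations.** Short reads: per-site depth Poisson (default 20×),
  alt count Binomial(depth, copies/ploidy), call het iff both alleles
  seen — no base-error model, so genotype noise is allele dropout only.
  Long reads: uniformly placed fragments with exponential bp lengths
  (default 20 kb) from a uniformly chosen haplotype, each observed allele
  flipped with probability 0.02.

Everything derives from one integer seed (fixed seed ⇒ byte-identical
output).  Default genome size is 2 × 500 kb with 1,000 SNPs per
chromosome — enough sites for stable panels, LD curves and jackknife
blocks while keeping the full test suite and the acceptance script in the
tens of seconds; parameter-recovery experiments state their own sizes.

Passing tests on this generator show the inference machinery is correct
under its assumptions; they do not certify behaviour under real-data
complications the generator omits: reference bias and mapping artifacts,
indels and multiallelic sites, base-calling error in short reads,
non-uniform recombination maps, population structure within founder pools,
and interspecies hybrids.

## Numerical and degenerate-input conventions

* Genotypes: 0/1/2/−1 codes; coordinates 1-based externally (VCF), 0-based
  site indices internally; het 0/1 ≡ 1/0 and phased separators ignored.
* Frequencies at sites with no called strain are NaN and propagate to
  complete-case exclusion everywhere downstream.
* Zero-overlap score is (0, 0, 0); empty fragment sets phase to empty
  haplotype sets; empty haplotype sets have undefined (NaN) mean counts.
* The decay fit requires ≥ 10 non-empty bins; initial scale from a
  log-linear fit of positive bins, bounds amplitude > 0,
  1 bp ≤ D ≤ 10 × window.
* Aneuploidy and jackknife both refuse inputs too small to resample
  (< 2 chromosomes, < 2 blocks).

## Limitations

* The phaser is greedy; no likelihood or MEC optimality is claimed, and
  chimeric merges occur at low depth or high error (see above).
* The ploidy classifier assumes the binomial read model and equal
  component weights; strong reference bias or contamination would violate
  both.  It cannot see ploidy without heterozygosity.
* LD dating assumes one pulse and a uniform map; the f4-ratio assumes the
  references are unadmixed with the sources.
* Four-fold degenerate site identification is out of scope: divergence
  operations take counts and a site total as inputs.
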