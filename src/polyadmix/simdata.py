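"""Synthetic polyploid admixed genomes and their sequencing observations.

The generator emulates the structure that admixture inference assumes:

* two founder populations (``E`` European-like, ``A`` Asian-like) carrying
  nearly fixed diagnostic differences,
* a third "ghost" population contributing group-private alleles,
* an ancestral outgroup pool (for four-population tests),
* single-pulse admixture aged by a number of meiotic equivalents on a
  uniform genetic map (0.34 cM/kb, the yeast genome-wide average),
* triploid/tetraploid genome formation as a union of independently drawn
  admixed haplotypes,
* mitotic loss-of-heterozygosity (LOH) tracts with exponential lengths,
* noisy observations: Poisson short-read depth with binomial allele
  sampling, and long-read fragments with a per-allele error rate.

All randomness flows from ``SimConfig.seed``: a fixed seed gives
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

from .ioformats import Fragment, FragmentSet, GenotypeMatrix, Site, SiteReadCounts

ANC_E, ANC_A, ANC_G = 0, 1, 2  # ancestry codes: European-like, Asian-like, ghost
ANCESTRY_LETTER = {ANC_E: "E", ANC_A: "A", ANC_G: "G"}


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Parameters of the synthetic admixed-polyploid genome generator.

    Defaults describe the regime the downstream inferences are built for:
    a few hundred kb of genome at yeast-like SNP density, admixture ~10
    meioses old at 0.34 cM/kb, tetraploid genomes, ~2% long-read allele
    error and 20x short-read depth.
    """

    n_chrom: int = 2
    chrom_length: int = 500_000  # bp
    n_sites_per_chrom: int = 1000
    n_founders_per_pop: int = 20  # haplotypes per founder pool
    frac_diagnostic: float = 0.30  # nearly fixed E/A differences
    frac_ghost_private: float = 0.05  # ghost-private allele sites
    diagnostic_leak: float = 0.005  # residual minor-allele freq at diagnostic sites
    ghost_private_freq: float = 0.5  # ghost-pool frequency of private alleles
    ghost_europe_affinity: float = 0.8  # P(ghost matches E allele at diagnostic site)
    n_meioses: int = 10  # admixture age in meiotic equivalents
    cm_per_kb: float = 0.34  # genetic map density
    admixture_fraction: float = 0.4  # genome fraction of Asian-like ancestry
    ploidy: int = 4
    ghost_lineage_frac: float = 0.5  # fraction of haplotypes carrying ghost alleles
    ghost_on_pure: bool = False  # place ghost alleles on unrecombined backbones
    loh_tract_rate: float = 5e-7  # tract initiations per bp per haplotype
    loh_tract_length_mean: float = 16_600.0  # bp, exponential
    fragment_count: int = 2000
    fragment_length_mean: float = 20_000.0  # bp, exponential
    fragment_error_rate: float = 0.02
    short_read_depth_mean: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "frac_diagnostic",
            "frac_ghost_private",
            "diagnostic_leak",
            "ghost_private_freq",
            "ghost_europe_affinity",
            "admixture_fraction",
            "ghost_lineage_frac",
            "fragment_error_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.frac_diagnostic + self.frac_ghost_private > 1.0:
            raise ConfigError("frac_diagnostic + frac_ghost_private exceeds 1")
        if self.chrom_length <= 0 or self.fragment_length_mean <= 0:
            raise ConfigError("lengths must be positive")
        if self.loh_tract_length_mean <= 0:
            raise ConfigError("loh_tract_length_mean must be positive")
        if self.ploidy not in (2, 3, 4):
            raise ConfigError(f"ploidy must be 2, 3 or 4, got {self.ploidy}")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        """Load a config from a YAML key-value file (unknown keys rejected)."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a mapping of config keys")
        valid = {f.name for f in fields(cls)}
        unknown = set(raw) - valid
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)


@dataclass
class FounderPools:
    """Founder haplotype pools per population plus site annotations.

    ``pools[name]`` is an (n_founders, n_sites) 0/1 array; ``sites`` is the
    global sorted site list; ``site_class`` codes each site 0=shared,
    1=diagnostic, 2=ghost-private; ``diag_e_allele`` gives, at diagnostic
    sites, the allele (0/1) that is European-typed.
    """

    sites: list[Site]
    pools: dict[str, np.ndarray]
    site_class: np.ndarray
    diag_e_allele: np.ndarray

    @property
    def diagnostic_idx(self) -> np.ndarray:
        return np.flatnonzero(self.site_class == 1)

    @property
    def ghost_private_idx(self) -> np.ndarray:
        return np.flatnonzero(self.site_class == 2)


@dataclass
class LohTract:
    chrom: int
    donor: int
    acceptor: int
    start: int  # bp, inclusive
    end: int  # bp, exclusive


@dataclass
class TruthGenome:
    """Simulator truth: per-chromosome haplotypes with per-site ancestry.

    ``haplotypes[c]`` is (ploidy, n_sites_c) of 0/1 alleles; ``ancestry[c]``
    parallel codes in {0=E, 1=A, 2=G}; ``crossovers[c]`` the per-haplotype
    lists of recombination breakpoints (bp) drawn by the ancestry process;
    ``loh_tracts`` the applied LOH events.
    """

    sites: list[Site]
    chrom_site_idx: list[np.ndarray]  # global site indices per chromosome
    haplotypes: list[np.ndarray]
    ancestry: list[np.ndarray]
    crossovers: list[list[np.ndarray]]
    loh_tracts: list[LohTract] = field(default_factory=list)

    @property
    def ploidy(self) -> int:
        return self.haplotypes[0].shape[0]

    def n_crossovers(self) -> int:
        return sum(len(x) for per_chrom in self.crossovers for x in per_chrom)

    def ancestry_switches(self) -> int:
        """True E<->A switch count between consecutive diagnostic-codeable sites."""
        n = 0
        for anc in self.ancestry:
            for h in anc:
                ea = h[h != ANC_G]
                n += int(np.sum(ea[1:] != ea[:-1]))
        return n


def _site_list(cfg: SimConfig, rng: np.random.Generator) -> tuple[list[Site], list[np.ndarray]]:
    sites: list[Site] = []
    chrom_idx: list[np.ndarray] = []
    offset = 0
    for c in range(cfg.n_chrom):
        pos = np.sort(
            rng.choice(np.arange(1, cfg.chrom_length + 1), size=cfg.n_sites_per_chrom, replace=False)
        )
        name = f"chr{c + 1:02d}"
        ref, alt = "A", "T"
        sites.extend(Site(name, int(p), ref, alt) for p in pos)
        chrom_idx.append(np.arange(offset, offset + len(pos)))
        offset += len(pos)
    return sites, chrom_idx


def simulate_founders(cfg: SimConfig) -> FounderPools:
    """Draw founder haplotype pools for E, A, ghost and outgroup populations.

    Diagnostic sites are fixed (up to ``diagnostic_leak``) for opposite
    alleles in E and A; ghost-private sites carry the alternative allele only
    in the ghost pool, at ``ghost_private_freq``; the remaining sites share
    polymorphism at a common random frequency across all pools.  The
    outgroup sits at the ancestral 50:50 state at diagnostic sites, which is
    what four-population tests need of a reference unrelated to either
    source.
    """
    rng = np.random.default_rng(cfg.seed)
    sites, _ = _site_list(cfg, rng)
    n_sites = len(sites)
    site_class = np.zeros(n_sites, dtype=np.int8)
    n_diag = int(round(cfg.frac_diagnostic * n_sites))
    n_ghost = int(round(cfg.frac_ghost_private * n_sites))
    special = rng.choice(n_sites, size=n_diag + n_ghost, replace=False)
    site_class[special[:n_diag]] = 1
    site_class[special[n_diag:]] = 2

    # which allele is European-typed at each diagnostic site (random polarity)
    diag_e_allele = np.full(n_sites, -1, dtype=np.int8)
    diag = site_class == 1
    diag_e_allele[diag] = rng.integers(0, 2, size=n_diag)

    base_freq = rng.uniform(0.05, 0.95, size=n_sites)  # shared polymorphism
    nf = cfg.n_founders_per_pop
    pools: dict[str, np.ndarray] = {}
    for name in ("E", "A", "ghost", "outgroup"):
        p = np.empty(n_sites)
        p[:] = base_freq
        if name == "E":
            p[diag] = np.where(diag_e_allele[diag] == 1, 1 - cfg.diagnostic_leak, cfg.diagnostic_leak)
        elif name == "A":
            p[diag] = np.where(diag_e_allele[diag] == 1, cfg.diagnostic_leak, 1 - cfg.diagnostic_leak)
        elif name == "ghost":
            e_freq = np.where(diag_e_allele[diag] == 1, 1.0, 0.0)
            a_freq = 1.0 - e_freq
            aff = cfg.ghost_europe_affinity
            p[diag] = aff * e_freq + (1 - aff) * a_freq
        else:  # outgroup: ancestral state at diagnostic sites
            p[diag] = 0.5
        gp = site_class == 2
        p[gp] = cfg.ghost_private_freq if name == "ghost" else 0.0
        pools[name] = (rng.random((nf, n_sites)) < p).astype(np.int8)
    return FounderPools(sites, pools, site_class, diag_e_allele)


def _ancestry_process(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One chromosome's ancestry mosaic after ``n_meioses`` meioses.

    Junctions accumulate as a Poisson process at ``n_meioses`` per Morgan;
    the ancestry of each inter-junction segment is an independent draw from
    the pulse proportions.  This is the standard Markov approximation to
    ancestry in a randomly mating admixed population and yields admixture-LD
    covariance decaying as exp(-t * d) with d in Morgans.
    Returns (breakpoints in bp, per-segment ancestry codes E/A).
    """
    morgans = cfg.chrom_length / 1000.0 * cfg.cm_per_kb / 100.0
    n_bp = rng.poisson(cfg.n_meioses * morgans)
    breaks = np.sort(rng.uniform(0, cfg.chrom_length, size=n_bp))
    seg_anc = (rng.random(n_bp + 1) < cfg.admixture_fraction).astype(np.int8)  # 1 = A
    return breaks, seg_anc


def simulate_admixed_polyploid(pools: FounderPools, cfg: SimConfig) -> TruthGenome:
    """Build a polyploid genome of independently drawn admixed haplotypes.

    Each of the ``ploidy`` haplotypes is an ancestry mosaic (E/A segments)
    filled with alleles copied from one E and one A founder; a configurable
    subset of haplotypes additionally carries ghost-private alleles (coded
    G at those sites).  LOH tracts then overwrite acceptor haplotypes with
    donor alleles and ancestry.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    sites = pools.sites
    n_sites = len(sites)
    chrom_names = list(dict.fromkeys(s.chrom for s in sites))
    pos = np.array([s.pos for s in sites])
    chrom_of = np.array([chrom_names.index(s.chrom) for s in sites])
    chrom_site_idx = [np.flatnonzero(chrom_of == c) for c in range(len(chrom_names))]

    nf = cfg.n_founders_per_pop
    ghost_carrier = rng.random(cfg.ploidy) < cfg.ghost_lineage_frac

    haplotypes, ancestry, crossovers = [], [], []
    for c, idx in enumerate(chrom_site_idx):
        cpos = pos[idx]
        hap = np.zeros((cfg.ploidy, len(idx)), dtype=np.int8)
        anc = np.zeros((cfg.ploidy, len(idx)), dtype=np.int8)
        xovers = []
        for h in range(cfg.ploidy):
            e_founder = pools.pools["E"][rng.integers(nf)][idx]
            a_founder = pools.pools["A"][rng.integers(nf)][idx]
            if cfg.ghost_on_pure and ghost_carrier[h]:
                breaks = np.empty(0)
                site_anc = np.zeros(len(idx), dtype=np.int8)  # pure E backbone
            else:
                breaks, seg_anc = _ancestry_process(cfg, rng)
                site_anc = seg_anc[np.searchsorted(breaks, cpos)]
            hap[h] = np.where(site_anc == ANC_A, a_founder, e_founder)
            anc[h] = site_anc
            xovers.append(breaks)
            if ghost_carrier[h]:
                gp = np.isin(idx, pools.ghost_private_idx)
                planted = gp & (rng.random(len(idx)) < cfg.ghost_private_freq)
                hap[h, planted] = 1
                anc[h, planted] = ANC_G
        haplotypes.append(hap)
        ancestry.append(anc)
        crossovers.append(xovers)

    # mitotic LOH: donor tract copied over acceptor haplotype
    tracts: list[LohTract] = []
    if cfg.loh_tract_rate > 0 and cfg.ploidy >= 2:
        for c, idx in enumerate(chrom_site_idx):
            cpos = pos[idx]
            for acceptor in range(cfg.ploidy):
                n_tracts = rng.poisson(cfg.loh_tract_rate * cfg.chrom_length)
                for _ in range(n_tracts):
                    donor = int(rng.choice([d for d in range(cfg.ploidy) if d != acceptor]))
                    start = float(rng.uniform(0, cfg.chrom_length))
                    length = float(rng.exponential(cfg.loh_tract_length_mean))
                    end = min(start + length, cfg.chrom_length)
                    inside = (cpos >= start) & (cpos < end)
                    haplotypes[c][acceptor, inside] = haplotypes[c][donor, inside]
                    ancestry[c][acceptor, inside] = ancestry[c][donor, inside]
                    tracts.append(LohTract(c, donor, acceptor, int(start), int(end)))

    return TruthGenome(sites, chrom_site_idx, haplotypes, ancestry, crossovers, tracts)


def simulate_observations(
    truth: TruthGenome, cfg: SimConfig, strain: str = "sim1", seed: int | None = None
) -> tuple[GenotypeMatrix, SiteReadCounts, FragmentSet]:
    """Observe a TruthGenome: short-read genotypes/counts and long-read fragments.

    Short reads: per-site depth ~ Poisson(mean); alt reads ~ Binomial(depth,
    c/N) for c alt copies among N haplotypes; the call is het iff both
    alleles were observed.  Fragments: exponential bp lengths starting at
    uniform positions on a uniformly chosen haplotype; each observed allele
    is flipped with ``fragment_error_rate``.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed if seed is None else seed, 2])
    )
    n_sites = len(truth.sites)
    ploidy = truth.ploidy
    alt_copies = np.concatenate([h.sum(axis=0) for h in truth.haplotypes])
    order = np.concatenate(truth.chrom_site_idx)
    copies = np.empty(n_sites, dtype=np.int64)
    copies[order] = alt_copies

    depth = rng.poisson(cfg.short_read_depth_mean, size=n_sites)
    alt = rng.binomial(depth, copies / ploidy)
    ref = depth - alt
    calls = np.full(n_sites, -1, dtype=np.int8)
    calls[(ref > 0) & (alt == 0)] = 0
    calls[(ref > 0) & (alt > 0)] = 1
    calls[(ref == 0) & (alt > 0)] = 2

    matrix = GenotypeMatrix(truth.sites, [strain], calls[None, :], pop={strain: "sim"})
    counts = SiteReadCounts(ref[None, :], alt[None, :])

    pos = np.array([s.pos for s in truth.sites])
    fragments: list[Fragment] = []
    n_chrom = len(truth.chrom_site_idx)
    for r in range(cfg.fragment_count):
        c = int(rng.integers(n_chrom))
        h = int(rng.integers(ploidy))
        start = rng.uniform(0, cfg.chrom_length)
        length = rng.exponential(cfg.fragment_length_mean)
        idx = truth.chrom_site_idx[c]
        cpos = pos[idx]
        inside = np.flatnonzero((cpos >= start) & (cpos < start + length))
        if len(inside) < 2:
            continue
        alleles = truth.haplotypes[c][h, inside].copy()
        flips = rng.random(len(inside)) < cfg.fragment_error_rate
        alleles[flips] ^= 1
        fragments.append(
            Fragment(f"read{r:06d}_c{c}h{h}", idx[inside], alleles)
        )
    return matrix, counts, FragmentSet(fragments)


def simulate_cohort(
    cfg: SimConfig,
    n_strains_per_pop: dict[str, int],
    alpha: float | None = None,
) -> GenotypeMatrix:
    """Diploid genotype matrix of strains drawn from the founder pools.

    ``n_strains_per_pop`` maps pool names (E/A/ghost/outgroup) to strain
    counts; strains are formed by pairing two independent haplotypes
    resampled from the pool's allele frequencies.  When ``alpha`` is given,
    an extra population ``admixed`` of mosaic strains with exact Asian-like
    site fraction ``alpha`` is appended (one strain per entry of
    ``n_strains_per_pop.get('admixed', 0)``).
    """
    pools = simulate_founders(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    n_sites = len(pools.sites)
    strains: list[str] = []
    rows: list[np.ndarray] = []
    pop: dict[str, str] = {}
    for name, n in n_strains_per_pop.items():
        if name == "admixed":
            continue
        freq = pools.pools[name].mean(axis=0)
        for k in range(n):
            g = (rng.random(n_sites) < freq).astype(np.int8) + (
                rng.random(n_sites) < freq
            ).astype(np.int8)
            sname = f"{name}_{k:03d}"
            strains.append(sname)
            rows.append(g)
            pop[sname] = name
    for k in range(n_strains_per_pop.get("admixed", 0)):
        if alpha is None:
            raise ConfigError("alpha required when requesting admixed strains")
        g = np.zeros(n_sites, dtype=np.int8)
        for _ in range(2):  # two haplotypes per diploid mosaic
            e = pools.pools["E"][rng.integers(cfg.n_founders_per_pop)]
            a = pools.pools["A"][rng.integers(cfg.n_founders_per_pop)]
            n_asian = int(round(alpha * n_sites))
            take_a = np.zeros(n_sites, dtype=bool)
            take_a[rng.choice(n_sites, size=n_asian, replace=False)] = True
            g += np.where(take_a, a, e).astype(np.int8)
        sname = f"admixed_{k:03d}"
        strains.append(sname)
        rows.append(g)
        pop[sname] = "admixed"
    calls = np.stack(rows) if rows else np.zeros((0, n_sites), dtype=np.int8)
    return GenotypeMatrix(pools.sites, strains, calls, pop=pop)


def truth_panel(pools: FounderPools):
    """AncestryPanel straight from generator truth (diagnostic + ghost sites)."""
    from .ancestry import AncestryPanel

    diagnostic = {
        int(j): (int(pools.diag_e_allele[j]), int(1 - pools.diag_e_allele[j]))
        for j in pools.diagnostic_idx
    }
    private = {int(j): (1, "ghost") for j in pools.ghost_private_idx}
    return AncestryPanel(diagnostic, private)


def truth_haplotype_set(truth: TruthGenome, id_prefix: str = ""):
    """Expose the simulator's true haplotypes as a fully covered HaplotypeSet.

    One haplotype per (chromosome, copy); useful for noiseless painting,
    switch-count and LD tests where phasing itself is not under study.
    """
    from .phaser import Haplotype, HaplotypeSet

    haps = []
    for c, idx in enumerate(truth.chrom_site_idx):
        for h in range(truth.ploidy):
            alleles = {int(j): int(a) for j, a in zip(idx, truth.haplotypes[c][h])}
            haps.append(
                Haplotype(
                    id=f"{id_prefix}c{c}h{h}",
                    alleles=alleles,
                    support={j: 1 for j in alleles},
                )
            )
    return HaplotypeSet(haps, truth.sites)


def truth_diagnostic_switches(truth: TruthGenome, pools: FounderPools) -> int:
    """True E<->A switch count between consecutive diagnostic sites, summed
    over haplotypes (the painting-visible subset of ancestry junctions)."""
    diag = set(int(j) for j in pools.diagnostic_idx)
    n = 0
    for c, idx in enumerate(truth.chrom_site_idx):
        keep = np.array([int(j) in diag for j in idx])
        for h in range(truth.ploidy):
            codes = truth.ancestry[c][h][keep]
            codes = codes[codes != ANC_G]
            n += int(np.sum(codes[1:] != codes[:-1]))
    return n
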