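"""Four-population statistics, block-jackknife errors, admixture proportions,
molecular-clock divergence dating and mitotic-event expectations.

f4(A, B; C, D) is the mean over SNPs of (pA - pB)(pC - pD): zero under a
tree ((A,B),(C,D)) without gene flow, systematically nonzero under
admixture.  Standard errors come from a delete-one block jackknife over
consecutive SNP blocks (robust to linkage).  The f4-ratio
f4(R1, R2; test, S1) / f4(R1, R2; S2, S1) estimates the fraction of the
test genome derived from source S2.  The clock and mitotic-event
operations are exact arithmetic on published rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ancestry import population_allele_freq
from .ioformats import MISSING, GenotypeMatrix


@dataclass
class F4Result:
    value: float
    se: float
    z: float
    n_blocks: int
    block_size: int
    n_sites: int


@dataclass
class AdmixtureProportion:
    name: str
    alpha: float
    numerator: F4Result
    denominator: F4Result
    weak_denominator: bool  # |denominator Z| < 3


@dataclass
class ClockEstimate:
    divergence_percent: float
    mutation_rate: float
    generations_per_year: float
    years: float


def f4(
    freq_a: np.ndarray,
    freq_b: np.ndarray,
    freq_c: np.ndarray,
    freq_d: np.ndarray,
) -> float:
    """f4 = mean over complete-case sites of (pA - pB)(pC - pD)."""
    prods, _ = _f4_products(freq_a, freq_b, freq_c, freq_d)
    if len(prods) == 0:
        raise ValueError("no site with frequencies in all four populations")
    return float(prods.mean())


def _f4_products(fa, fb, fc, fd) -> tuple[np.ndarray, np.ndarray]:
    fa, fb, fc, fd = (np.asarray(f, dtype=float) for f in (fa, fb, fc, fd))
    ok = np.isfinite(fa) & np.isfinite(fb) & np.isfinite(fc) & np.isfinite(fd)
    return ((fa - fb) * (fc - fd))[ok], np.flatnonzero(ok)


def f4_from_matrix(
    matrix: GenotypeMatrix,
    pops: tuple[str, str, str, str],
    max_admixture: float = 0.01,
) -> float:
    freqs = [population_allele_freq(matrix, p, max_admixture) for p in pops]
    return f4(*freqs)


def block_jackknife(values: np.ndarray, block_id: np.ndarray) -> tuple[float, float, int]:
    """Delete-one-block jackknife mean and standard error of a per-site statistic.

    Returns ``(estimate, se, n_blocks)`` where estimate is the all-site mean
    and se^2 = ((B-1)/B) * sum((theta_-i - mean(theta_-i))^2).
    """
    values = np.asarray(values, dtype=float)
    blocks = np.unique(block_id)
    n_blocks = len(blocks)
    if n_blocks < 2:
        raise ValueError("need >= 2 blocks for a jackknife")
    total = values.sum()
    n = len(values)
    theta = np.empty(n_blocks)
    for i, b in enumerate(blocks):
        inb = block_id == b
        theta[i] = (total - values[inb].sum()) / (n - inb.sum())
    se = float(np.sqrt((n_blocks - 1) / n_blocks * np.sum((theta - theta.mean()) ** 2)))
    return float(total / n), se, n_blocks


def make_blocks(n_sites: int, block_size: int = 500) -> np.ndarray:
    """Consecutive genome-order blocks; a final partial block is merged into
    the previous one."""
    if n_sites < 2 * block_size:
        raise ValueError(f"need >= {2 * block_size} sites for 2 blocks")
    block = np.arange(n_sites) // block_size
    last = block[-1]
    if np.sum(block == last) < block_size:
        block[block == last] = last - 1
    return block


def f4_jackknife(
    matrix: GenotypeMatrix,
    pops: tuple[str, str, str, str] | tuple[list[str], ...],
    block_size: int = 500,
    max_admixture: float = 0.01,
) -> F4Result:
    """f4 with a delete-one 500-SNP block jackknife standard error and Z score."""
    freqs = [population_allele_freq(matrix, p, max_admixture) for p in pops]
    prods, site_idx = _f4_products(*freqs)
    block = make_blocks(len(prods), block_size)
    value, se, n_blocks = block_jackknife(prods, block)
    z = value / se if se > 0 else float("nan")
    return F4Result(value, se, z, n_blocks, block_size, len(prods))


def strain_frequency(matrix: GenotypeMatrix, strain: str) -> np.ndarray:
    """A single strain's genotype dosage (0, 0.5, 1) as a one-sample frequency."""
    i = matrix.strain_index(strain)
    calls = matrix.calls[i].astype(float)
    calls[matrix.calls[i] == MISSING] = np.nan
    return calls / 2.0

def f4_admixture_proportion(
    matrix: GenotypeMatrix,
    ref_pops: tuple[str, str],
    source_pops: tuple[str, str],
    test: str | list[str],
    block_size: int = 500,
    max_admixture: float = 0.01,
    test_is_strain: bool = False,
) -> AdmixtureProportion:
    """alpha = f4(R1, R2; test, S2) / f4(R1, R2; S1, S2).

    ``source_pops = (S1, S2)`` orders the sources so that alpha is the
    fraction of the test genome derived from S1 (the Asia-like source when
    S2 is the Europe-like source).  ``test_is_strain`` treats ``test`` as a
    single strain whose genotype dosage serves as its frequency.  alpha is
    reported raw (it may fall slightly outside [0, 1]); the result is
    flagged when the denominator's |Z| < 3.
    """
    r1, r2 = (population_allele_freq(matrix, p, max_admixture) for p in ref_pops)
    s1, s2 = (population_allele_freq(matrix, p, max_admixture) for p in source_pops)
    if test_is_strain:
        ft = strain_frequency(matrix, test)
        name = test
    else:
        ft = population_allele_freq(matrix, test, max_admixture)
        name = str(test)

    num_prods, num_idx = _f4_products(r1, r2, ft, s2)
    den_prods, den_idx = _f4_products(r1, r2, s1, s2)
    # evaluate both on the common complete-case site set
    common = np.intersect1d(num_idx, den_idx)
    sel_n = np.isin(num_idx, common)
    sel_d = np.isin(den_idx, common)
    num_prods, den_prods = num_prods[sel_n], den_prods[sel_d]
    if len(num_prods) == 0:
        raise ValueError("no shared complete-case sites")
    block = make_blocks(len(num_prods), block_size)
    num_v, num_se, nb = block_jackknife(num_prods, block)
    den_v, den_se, _ = block_jackknife(den_prods, block)
    if abs(den_v) < 1e-12:
        raise ZeroDivisionError("f4 denominator numerically zero")
    num = F4Result(num_v, num_se, num_v / num_se if num_se > 0 else float("nan"), nb, block_size, len(num_prods))
    den = F4Result(den_v, den_se, den_v / den_se if den_se > 0 else float("nan"), nb, block_size, len(den_prods))
    return AdmixtureProportion(
        name=name,
        alpha=num_v / den_v,
        numerator=num,
        denominator=den,
        weak_denominator=not (abs(den.z) >= 3),
    )


# ---------------------------------------------------------------------------
# clock arithmetic
# ---------------------------------------------------------------------------


def lineage_divergence(private_allele_count: int, n_sites_surveyed: int) -> float:
    """Lineage divergence in percent: 100 x private alleles / sites surveyed."""
    if n_sites_surveyed <= 0:
        raise ValueError("n_sites_surveyed must be positive")
    if private_allele_count < 0:
        raise ValueError("allele count must be non-negative")
    return 100.0 * private_allele_count / n_sites_surveyed


def divergence_time(
    divergence_percent: float,
    mutation_rate: float = 5e-10,
    generations_per_year: float = 150.0,
) -> ClockEstimate:
    """Mutation-clock dating: years = (d/100) / (mu x generations/year)."""
    if divergence_percent <= 0 or mutation_rate <= 0 or generations_per_year <= 0:
        raise ValueError("all clock inputs must be positive")
    years = (divergence_percent / 100.0) / (mutation_rate * generations_per_year)
    return ClockEstimate(divergence_percent, mutation_rate, generations_per_year, years)


def expected_mitotic_events(
    genome_kb: float = 48_000.0,
    conversion_rate_per_division: float = 1.3e-6,
    track_kb: float = 16.6,
    recombination_rate: float = 7e-6,
    recombination_window_kb: float = 120.0,
) -> tuple[float, float]:
    """Expected mitotic gene conversions and recombinations per cell division.

    Published per-locus rates are scaled to genome size: conversions =
    rate x genome/track-length; recombinations = rate x genome/window.
    Defaults describe a ~48-Mb tetraploid yeast genome.
    """
    if min(genome_kb, conversion_rate_per_division, track_kb, recombination_rate, recombination_window_kb) <= 0:
        raise ValueError("all inputs must be positive")
    conversions = conversion_rate_per_division * genome_kb / track_kb
    recombinations = recombination_rate * genome_kb / recombination_window_kb
    return conversions, recombinations


def genotype_discordance(calls_a: np.ndarray, calls_b: np.ndarray) -> float:
    """Genotype discordance between replicate strains: mismatches / shared calls."""
    a = np.asarray(calls_a)
    b = np.asarray(calls_b)
    if a.shape != b.shape:
        raise ValueError("call vectors must be aligned")
    shared = (a != MISSING) & (b != MISSING)
    n = int(shared.sum())
    if n == 0:
        raise ValueError("no sites called in both strains")
    return float(np.sum(a[shared] != b[shared]) / n)
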