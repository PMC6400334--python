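"""Ploidy calling from allele balance and aneuploidy flagging from coverage.

At a heterozygous site, the fraction of reads carrying the alternative
allele concentrates near 1/2 in a diploid, near {1/3, 2/3} in a triploid
and near {1/4, 1/2, 3/4} in a tetraploid.  The caller scores each class as
a fixed-weight binomial mixture over the observed (alt, depth) pairs and
returns the maximum-likelihood class — a reproducible replacement for
eyeballing allele-balance histograms.  Whole-chromosome aneuploidy is
flagged from per-chromosome median depth relative to the genome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import binom

from .ioformats import HET, GenotypeMatrix, SiteReadCounts

#: mixture components (alt-fraction modes) per ploidy class, equal weights
PLOIDY_COMPONENTS: dict[int, tuple[float, ...]] = {
    2: (1 / 2,),
    3: (1 / 3, 2 / 3),
    4: (1 / 4, 1 / 2, 3 / 4),
}

DIPLOID, TRIPLOID, TETRAPLOID = 2, 3, 4
POLYPLOID_UNRESOLVED = "polyploid-unresolved"
UNKNOWN = "unknown"

#: alt fractions outside this open interval at het-called sites are treated
#: as genotype miscalls and excluded
ERROR_FLOOR = 0.05

#: below this many usable het sites no call of any kind is attempted
MIN_HET_ANY_CALL = 50


@dataclass
class PloidyCall:
    strain: str
    ploidy: int | str  # 2, 3, 4, "polyploid-unresolved" or "unknown"
    n_het_used: int
    mean_depth: float
    log_likelihood: dict[int, float]  # per-class total log-likelihood


def _class_loglik(alt: np.ndarray, depth: np.ndarray, modes: tuple[float, ...]) -> float:
    per_comp = np.stack([binom.logpmf(alt, depth, p) for p in modes])
    return float(np.sum(logsumexp(per_comp, axis=0) - np.log(len(modes))))


def call_ploidy(
    ref: np.ndarray,
    alt: np.ndarray,
    het_mask: np.ndarray,
    strain: str = "",
    min_depth: int = 10,
    min_het: int = 500,
) -> PloidyCall:
    """Call ploidy for one strain from ref/alt read counts at het sites.

    ``ref``/``alt`` are per-site counts, ``het_mask`` marks heterozygous
    calls.  Sites with depth < ``min_depth`` or alt fraction outside
    (0.05, 0.95) are excluded.  With >= ``min_het`` usable sites the
    maximum-likelihood class among {2, 3, 4} is returned; with fewer (but
    >= 50) the call is diploid only if the diploid model wins, otherwise
    ``polyploid-unresolved``; below that, ``unknown``.
    """
    ref = np.asarray(ref, dtype=float)
    alt = np.asarray(alt, dtype=float)
    depth = ref + alt
    usable = het_mask & (ref >= 0) & (alt >= 0) & (depth >= min_depth)
    frac = np.divide(alt, depth, out=np.zeros_like(depth), where=depth > 0)
    usable &= (frac > ERROR_FLOOR) & (frac < 1 - ERROR_FLOOR)
    a, d = alt[usable].astype(int), depth[usable].astype(int)
    n_het = len(a)
    mean_depth = float(d.mean()) if n_het else 0.0

    if n_het < MIN_HET_ANY_CALL:
        return PloidyCall(strain, UNKNOWN, n_het, mean_depth, {})

    loglik = {k: _class_loglik(a, d, modes) for k, modes in PLOIDY_COMPONENTS.items()}
    best = max(loglik, key=lambda k: (loglik[k], -k))
    if n_het >= min_het:
        return PloidyCall(strain, best, n_het, mean_depth, loglik)
    # sub-threshold: enough signal to reject diploidy but not to resolve 3 vs 4
    if best == DIPLOID:
        return PloidyCall(strain, DIPLOID, n_het, mean_depth, loglik)
    return PloidyCall(strain, POLYPLOID_UNRESOLVED, n_het, mean_depth, loglik)


def call_ploidy_for_strain(
    matrix: GenotypeMatrix,
    counts: SiteReadCounts,
    strain: str,
    min_depth: int = 10,
    min_het: int = 500,
) -> PloidyCall:
    """Convenience wrapper: call ploidy for a named strain in a cohort."""
    i = matrix.strain_index(strain)
    het = matrix.calls[i] == HET
    return call_ploidy(
        counts.ref[i], counts.alt[i], het, strain=strain, min_depth=min_depth, min_het=min_het
    )


def detect_aneuploidy(
    depth: np.ndarray,
    chroms: np.ndarray,
    threshold: float = 0.20,
) -> list[tuple[str, float]]:
    """Flag chromosomes whose median depth deviates from the genome baseline.

    The baseline is the median of per-chromosome median depths; a
    chromosome is flagged when its ratio to the baseline deviates from 1 by
    more than ``threshold``.  Returns ``[(chrom, ratio), ...]`` for flagged
    chromosomes; raises on a single-chromosome input (not assessable).
    """
    depth = np.asarray(depth, dtype=float)
    chroms = np.asarray(chroms)
    names = list(dict.fromkeys(chroms.tolist()))
    if len(names) < 2:
        raise ValueError("aneuploidy requires >= 2 chromosomes")
    medians = {c: float(np.median(depth[(chroms == c) & (depth >= 0)])) for c in names}
    baseline = float(np.median(list(medians.values())))
    if baseline <= 0:
        raise ValueError("non-positive baseline depth")
    flagged = []
    for c in names:
        ratio = medians[c] / baseline
        if abs(ratio - 1.0) > threshold:
            flagged.append((c, ratio))
    return flagged
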