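"""Admixture-LD decay: ancestry covariance vs distance, exponential fit,
and conversion of the decay scale to meiotic equivalents.

Admixture creates an association between same-ancestry alleles at linked
sites that recombination erodes each meiosis; after t meioses the
covariance of ancestry indicators at map distance d Morgans is
proportional to exp(-t*d).  On a uniform genetic map of 0.34 cM/kb the
fitted physical decay scale D (kb) therefore dates the admixture at
t = 1 / (D * 0.0034) meiotic equivalents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .ancestry import CODE_A, PaintedHaplotype


@dataclass
class DecayCurve:
    """Binned mean ancestry covariance vs pair distance."""

    bin_mid: np.ndarray  # bp, ascending
    mean_cov: np.ndarray
    n_pairs: np.ndarray

    def nonempty(self) -> "DecayCurve":
        keep = self.n_pairs > 0
        return DecayCurve(self.bin_mid[keep], self.mean_cov[keep], self.n_pairs[keep])


@dataclass
class DecayFit:
    amplitude: float
    decay_scale_bp: float  # D in cov(x) = amplitude * exp(-x / D)
    half_distance_bp: float  # D * ln 2
    meiotic_equivalents: float
    converged: bool


def ancestry_covariance(
    painted: list[PaintedHaplotype],
    sites,
    max_dist: int = 50_000,
    bin_width: int = 100,
    min_dist: int = 1_000,
) -> DecayCurve:
    """Mean covariance of ancestry codes between site pairs, binned by distance.

    Codes are 0 (E) / 1 (A); each site is mean-centered across the
    haplotypes covering it and invariant sites are excluded.  Only pairs of
    sites on the same haplotype (and chromosome) at min_dist..max_dist bp
    contribute — the within-haplotype restriction is what makes this
    admixture LD rather than population LD.
    """
    if min_dist >= max_dist:
        raise ValueError("min_dist must be < max_dist")
    # per-site mean across covering haplotypes
    sums: dict[int, float] = {}
    ns: dict[int, int] = {}
    for p in painted:
        for j, c in zip(p.site_idx, p.codes):
            x = 1.0 if c == CODE_A else 0.0
            sums[int(j)] = sums.get(int(j), 0.0) + x
            ns[int(j)] = ns.get(int(j), 0) + 1
    mean = {j: sums[j] / ns[j] for j in sums}
    variant = {j for j, m in mean.items() if 0.0 < m < 1.0}

    n_bins = int(np.ceil((max_dist - min_dist) / bin_width))
    cov_sum = np.zeros(n_bins)
    n_pairs = np.zeros(n_bins, dtype=np.int64)
    for p in painted:
        keep = [k for k, j in enumerate(p.site_idx) if int(j) in variant]
        if len(keep) < 2:
            continue
        idx = p.site_idx[keep]
        pos = np.array([sites[int(j)].pos for j in idx], dtype=np.int64)
        centered = np.array(
            [
                (1.0 if p.codes[k] == CODE_A else 0.0) - mean[int(p.site_idx[k])]
                for k in keep
            ]
        )
        # same chromosome guaranteed by haplotype extent; pair within window
        d = pos[None, :] - pos[:, None]
        iu, ju = np.triu_indices(len(pos), k=1)
        dist = d[iu, ju]
        ok = (dist >= min_dist) & (dist < max_dist)
        if not ok.any():
            continue
        b = ((dist[ok] - min_dist) // bin_width).astype(np.int64)
        prod = centered[iu[ok]] * centered[ju[ok]]
        np.add.at(cov_sum, b, prod)
        np.add.at(n_pairs, b, 1)
    with np.errstate(invalid="ignore"):
        mean_cov = np.where(n_pairs > 0, cov_sum / np.maximum(n_pairs, 1), np.nan)
    mids = min_dist + (np.arange(n_bins) + 0.5) * bin_width
    return DecayCurve(mids, mean_cov, n_pairs)


def fit_decay(curve: DecayCurve, cm_per_kb: float = 0.34) -> DecayFit:
    """Weighted least-squares fit of amplitude * exp(-x/D) to a decay curve.

    Bins are weighted by pair count.  A fit is flagged non-converged when
    the optimizer fails, the amplitude is non-positive, or the fitted scale
    runs beyond 10x the curve's span (no measurable decay in the window).
    """
    c = curve.nonempty()
    if len(c.bin_mid) < 10:
        raise ValueError("need >= 10 non-empty bins to fit")
    x, y, w = c.bin_mid, c.mean_cov, c.n_pairs.astype(float)
    span = float(x[-1])
    upper_d = 10.0 * span
    if np.allclose(y, 0.0):
        return DecayFit(0.0, float("inf"), float("inf"), 0.0, converged=False)
    a0 = max(float(y[0]), 1e-6)
    # crude initial scale from the log-linear trend of positive bins
    pos = y > 0
    if pos.sum() >= 2:
        slope = np.polyfit(x[pos], np.log(y[pos]), 1, w=np.sqrt(w[pos]))[0]
        d0 = -1.0 / slope if slope < 0 else span
    else:
        d0 = span
    d0 = float(np.clip(d0, 1.0, upper_d))
    try:
        popt, _ = curve_fit(
            lambda xx, a, d: a * np.exp(-xx / d),
            x,
            y,
            p0=(a0, d0),
            sigma=1.0 / np.sqrt(w),
            bounds=((1e-12, 1.0), (np.inf, upper_d)),
            maxfev=10_000,
        )
        a, d = float(popt[0]), float(popt[1])
        converged = a > 0 and d < 0.99 * upper_d
    except RuntimeError:
        a, d, converged = a0, upper_d, False
    return DecayFit(
        amplitude=a,
        decay_scale_bp=d,
        half_distance_bp=d * np.log(2),
        meiotic_equivalents=meiotic_equivalents(d / 1000.0, cm_per_kb),
        converged=converged,
    )


def meiotic_equivalents(decay_distance_kb: float, cm_per_kb: float = 0.34) -> float:
    """Meiotic equivalents since admixture from the LD decay distance.

    On a uniform map of ``cm_per_kb`` centimorgans per kb, the admixture-LD
    covariance after t meioses decays as exp(-t * x_kb * cm_per_kb / 100),
    so a fitted decay distance D (kb) gives t = 1 / (D * cm_per_kb / 100);
    at the default map, a 30-kb decay distance dates to 9.8 meioses.
    """
    if decay_distance_kb <= 0:
        raise ValueError("decay distance must be positive")
    if cm_per_kb <= 0:
        raise ValueError("map density must be positive")
    return 1.0 / (decay_distance_kb * cm_per_kb / 100.0)
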