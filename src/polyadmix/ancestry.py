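"""Ancestry-diagnostic panels, haplotype painting and switch counting.

A *diagnostic* site is nearly fixed for opposite alleles in two source
populations (>= 99% vs <= 1% by default); a *group-private* allele is
common in one group (>= 25%) but essentially absent (< 1%) from every
other population.  Phased haplotypes are painted E (European-like) or A
(Asian-like) at diagnostic sites they cover, classified pure or mixed at a
purity threshold, and their E<->A switches counted under run-length
filters that suppress single-site artifacts (sequencing error) and short
tracts (mitotic gene conversion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ioformats import HET, HOM_ALT, MISSING, GenotypeMatrix
from .phaser import HaplotypeSet

CODE_E, CODE_A = "E", "A"


@dataclass
class AncestryPanel:
    """Diagnostic sites (siteIndex -> alleles typed Pop1/Pop2) and private alleles.

    ``diagnostic[j] = (e_allele, a_allele)``; ``private[j] = (allele, group)``.
    A site appears in at most one of the two maps.
    """

    diagnostic: dict[int, tuple[int, int]] = field(default_factory=dict)
    private: dict[int, tuple[int, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.diagnostic) & set(self.private)
        if overlap:
            raise ValueError(f"sites in both panels: {sorted(overlap)[:5]}")


@dataclass
class PaintedHaplotype:
    """Ancestry codes of one haplotype at the diagnostic sites it covers."""

    hap_id: str
    site_idx: np.ndarray  # covered diagnostic sites, ascending
    codes: list[str]  # "E"/"A", parallel to site_idx
    private_idx: np.ndarray  # covered sites carrying a private allele
    classification: str  # "E-pure" | "A-pure" | "mixed" | "unclassified"
    extent_bp: tuple[int, int]  # genomic extent (chrom implied by sites)
    chrom: str


@dataclass
class SwitchReport:
    """Switch counts per haplotype and in total, under one run filter."""

    per_haplotype: dict[str, int]
    total: int


def population_allele_freq(
    matrix: GenotypeMatrix,
    group: str | list[str],
    max_admixture: float = 0.01,
) -> np.ndarray:
    """Per-site alternative-allele frequency of a population.

    freq = (2 x homAlt + het) / (2 x called), counting homozygous calls
    fully and heterozygous calls half; strains with admixture above
    ``max_admixture`` are excluded first.  Sites with no called strain are
    nan.
    """
    if isinstance(group, str):
        strains = matrix.strains_in(group, max_admixture)
    else:
        strains = [
            s for s in group if matrix.admixture.get(s, 0.0) <= max_admixture
        ]
    if not strains:
        raise ValueError(f"no strains in group {group!r} after admixture filter")
    rows = [matrix.strain_index(s) for s in strains]
    calls = matrix.calls[rows]
    called = calls != MISSING
    n_called = called.sum(axis=0)
    num = 2 * (calls == HOM_ALT).sum(axis=0) + (calls == HET).sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.where(n_called > 0, num / (2.0 * n_called), np.nan)
    return freq


def select_diagnostic_sites(
    freq_pop1: np.ndarray,
    freq_pop2: np.ndarray,
    hi: float = 0.99,
    lo: float = 0.01,
) -> dict[int, tuple[int, int]]:
    """Sites nearly fixed for opposite alleles in the two source populations.

    Selected iff (f1 >= hi and f2 <= lo) or (f1 <= lo and f2 >= hi); the
    returned map gives (Pop1-typed allele, Pop2-typed allele) per site.
    """
    f1 = np.asarray(freq_pop1, dtype=float)
    f2 = np.asarray(freq_pop2, dtype=float)
    out: dict[int, tuple[int, int]] = {}
    ok = np.isfinite(f1) & np.isfinite(f2)
    alt_is_e = ok & (f1 >= hi) & (f2 <= lo)
    ref_is_e = ok & (f1 <= lo) & (f2 >= hi)
    for j in np.flatnonzero(alt_is_e):
        out[int(j)] = (1, 0)
    for j in np.flatnonzero(ref_is_e):
        out[int(j)] = (0, 1)
    return dict(sorted(out.items()))


def select_group_private_alleles(
    group_freqs: dict[str, np.ndarray],
    other_freqs: dict[str, np.ndarray],
    min_in: float = 0.25,
    max_out: float = 0.01,
) -> dict[int, tuple[int, str]]:
    """Alleles common in one focal group but absent from every other population.

    ``group_freqs`` are the candidate owner groups, ``other_freqs`` all
    remaining populations.  An allele (alt if freq >= min_in, ref if
    1-freq >= min_in) is private to a group iff its frequency is < max_out
    in every other population.  Earlier-listed groups win a (rare) tie.
    """
    if len(group_freqs) + len(other_freqs) < 2:
        raise ValueError("need at least two populations")
    out: dict[int, tuple[int, str]] = {}
    others = list(other_freqs.values())
    for gname, gfreq in group_freqs.items():
        rest = others + [f for n, f in group_freqs.items() if n != gname]
        for allele in (1, 0):
            f_in = gfreq if allele == 1 else 1.0 - gfreq
            ok = np.isfinite(f_in) & (f_in >= min_in)
            for f_other in rest:
                f_o = f_other if allele == 1 else 1.0 - f_other
                ok &= np.isfinite(f_o) & (f_o < max_out)
            for j in np.flatnonzero(ok):
                out.setdefault(int(j), (allele, gname))
    return dict(sorted(out.items()))


def build_panel(diagnostic: dict[int, tuple[int, int]], private: dict[int, tuple[int, str]]) -> AncestryPanel:
    """Combine the two site sets, dropping private entries at diagnostic sites."""
    private = {j: v for j, v in private.items() if j not in diagnostic}
    return AncestryPanel(diagnostic, private)


def paint(
    hapset: HaplotypeSet,
    panel: AncestryPanel,
    purity: float = 0.95,
) -> list[PaintedHaplotype]:
    """Paint each haplotype E/A at covered diagnostic sites and classify it.

    A haplotype is E-pure (A-pure) when more than ``purity`` of its coded
    sites are E (A); otherwise mixed; with zero coded sites, unclassified.
    Private-allele sites are flagged but never contribute to purity.
    """
    sites = hapset.sites
    painted = []
    for h in hapset.haplotypes:
        idx, codes = [], []
        priv = []
        for j, allele in h.alleles.items():
            d = panel.diagnostic.get(j)
            if d is not None:
                idx.append(j)
                codes.append(CODE_E if allele == d[0] else CODE_A)
            p = panel.private.get(j)
            if p is not None and allele == p[0]:
                priv.append(j)
        order = np.argsort(idx) if idx else []
        idx_arr = np.array(idx, dtype=np.int64)[order] if idx else np.empty(0, dtype=np.int64)
        codes = [codes[i] for i in order] if idx else []
        if not idx:
            cls = "unclassified"
        else:
            fe = codes.count(CODE_E) / len(codes)
            if fe > purity:
                cls = "E-pure"
            elif 1 - fe > purity:
                cls = "A-pure"
            else:
                cls = "mixed"
        lo, hi = h.extent
        painted.append(
            PaintedHaplotype(
                hap_id=h.id,
                site_idx=idx_arr,
                codes=codes,
                private_idx=np.array(sorted(priv), dtype=np.int64),
                classification=cls,
                extent_bp=(sites[lo].pos, sites[hi].pos),
                chrom=sites[lo].chrom,
            )
        )
    return painted


def _runs(codes: list[str], positions: np.ndarray) -> list[tuple[str, int, int, int]]:
    """Collapse a code sequence into (code, n_sites, start_bp, end_bp) runs."""
    runs = []
    i = 0
    while i < len(codes):
        j = i
        while j + 1 < len(codes) and codes[j + 1] == codes[i]:
            j += 1
        runs.append((codes[i], j - i + 1, int(positions[i]), int(positions[j])))
        i = j + 1
    return runs


def count_switches(
    painted: list[PaintedHaplotype],
    sites,
    min_sites: int = 1,
    min_span_bp: int | None = None,
) -> SwitchReport:
    """Count E<->A switches per haplotype after filtering short runs.

    The code sequence is collapsed into runs; runs with fewer than
    ``min_sites`` sites (or spanning less than ``min_span_bp``, when given)
    are discarded and their same-type flanks merged; switches = surviving
    runs - 1 (0 when fewer than 2 survive).
    """
    per_hap: dict[str, int] = {}
    for p in painted:
        pos = np.array([sites[j].pos for j in p.site_idx])
        runs = _runs(p.codes, pos)
        if min_span_bp is not None:
            runs = [r for r in runs if (r[3] - r[2] + 1) >= min_span_bp]
        else:
            runs = [r for r in runs if r[1] >= min_sites]
        # merge adjacent survivors of the same type
        merged = 0
        last = None
        for code, *_ in runs:
            if code != last:
                merged += 1
                last = code
        per_hap[p.hap_id] = max(merged - 1, 0)
    return SwitchReport(per_hap, sum(per_hap.values()))


def pure_fraction(painted: list[PaintedHaplotype]) -> float:
    """Fraction of classified haplotype bp lying on E-pure or A-pure haplotypes.

    Each classified haplotype contributes its extent in bp; overlapping
    haplotypes each count their own extent (per-haplotype weighting).
    """
    pure = total = 0.0
    for p in painted:
        if p.classification == "unclassified":
            continue
        span = p.extent_bp[1] - p.extent_bp[0] + 1
        total += span
        if p.classification in ("E-pure", "A-pure"):
            pure += span
    if total == 0:
        raise ValueError("no classified haplotype coverage")
    return pure / total


def allele_copy_counts(
    hapset: HaplotypeSet,
    panel: AncestryPanel,
) -> tuple[float, float]:
    """Mean copy number of Asian-typed and group-private alleles at 4-haplotype sites.

    Only sites covered by exactly four phased haplotypes and heterozygous
    among them (both alleles present) qualify.  Returns
    ``(mean_a_copies, mean_private_copies)``; a mean is nan when no site
    qualifies for that panel.
    """
    counts = hapset.per_site_count()
    a_copies: list[int] = []
    p_copies: list[int] = []
    for j, n in counts.items():
        if n != 4:
            continue
        alleles = [h.alleles[j] for h in hapset.haplotypes if j in h.alleles]
        if len(set(alleles)) < 2:
            continue  # homozygous among phased haplotypes
        d = panel.diagnostic.get(j)
        if d is not None:
            a_copies.append(sum(1 for a in alleles if a == d[1]))
        p = panel.private.get(j)
        if p is not None:
            p_copies.append(sum(1 for a in alleles if a == p[0]))
    mean_a = float(np.mean(a_copies)) if a_copies else float("nan")
    mean_p = float(np.mean(p_copies)) if p_copies else float("nan")
    return mean_a, mean_p
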