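"""Ploidy-agnostic haplotype phasing by iterative greedy fragment merging.

Long-read allele observations (fragments) are merged into a *variable*
number of haplotypes — no assumption or cap on ploidy.  Merging proceeds in
rounds: in round one, fragments are joined only when their overlap is
mismatch-free; in later rounds, clusters are merged whenever they overlap
by at least ``min_overlap`` sites and agree at ``min_match_frac`` of them.
Candidate joins are taken globally best-score first, where
``score = matches - mismatch_penalty * mismatches``, and the merged
consensus at a conflicting site is the allele with majority read support.

The same machinery yields the two diagnostics used to sanity-check a run:
the fragment error rate (minimum read-vs-haplotype mismatches) and the mean
number of haplotypes covering phased sites.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import numpy as np

from .ioformats import FragmentSet, Site

logger = logging.getLogger(__name__)


@dataclass
class MergeParams:
    """Merge thresholds: overlap >= 4 matching SNPs, >= 80% matching, score
    = matches - 5 x mismatches, three rounds (round 1 mismatch-free)."""

    min_overlap: int = 4
    min_match_frac: float = 0.80
    mismatch_penalty: float = 5.0
    rounds: int = 3

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if not 0 < self.min_match_frac <= 1:
            raise ValueError("min_match_frac must be in (0, 1]")


@dataclass
class Haplotype:
    """A phased haplotype: sparse site->allele map with per-site read support."""

    id: str
    alleles: dict[int, int]
    support: dict[int, int]
    read_ids: list[str] = field(default_factory=list)

    @property
    def extent(self) -> tuple[int, int]:
        if not self.alleles:
            return (-1, -1)
        return (min(self.alleles), max(self.alleles))

    def n_sites(self) -> int:
        return len(self.alleles)


@dataclass
class HaplotypeSet:
    """Phased haplotypes over a shared site list."""

    haplotypes: list[Haplotype]
    sites: list[Site]

    def __len__(self) -> int:
        return len(self.haplotypes)

    def per_site_count(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for h in self.haplotypes:
            for j in h.alleles:
                counts[j] = counts.get(j, 0) + 1
        return counts


def score_overlap(a: dict[int, int], b: dict[int, int], mismatch_penalty: float = 5.0):
    """Matches, mismatches and score over the sites keyed in both vectors."""
    if len(b) < len(a):
        a, b = b, a
    matches = mismatches = 0
    for j, allele in a.items():
        other = b.get(j)
        if other is None:
            continue
        if other == allele:
            matches += 1
        else:
            mismatches += 1
    return matches, mismatches, matches - mismatch_penalty * mismatches


class _Cluster:
    """Mutable merge unit: consensus alleles plus per-site 0/1 read support."""

    __slots__ = ("cid", "alleles", "n0", "n1", "read_ids", "n_reads", "version", "alive")

    def __init__(self, cid: int, alleles: dict[int, int], read_id: str):
        self.cid = cid
        self.alleles = dict(alleles)
        self.n0 = {j: 1 for j, a in alleles.items() if a == 0}
        self.n1 = {j: 1 for j, a in alleles.items() if a == 1}
        self.read_ids = [read_id]
        self.n_reads = 1
        self.version = 0
        self.alive = True

    def extent(self) -> tuple[int, int]:
        return (min(self.alleles), max(self.alleles))

    def absorb(self, other: "_Cluster") -> None:
        """Merge ``other`` into this cluster; consensus = majority support,
        ties resolved toward the cluster with more supporting reads."""
        bigger_is_self = (self.n_reads, -self.cid) >= (other.n_reads, -other.cid)
        for j in set(other.n0) | set(other.n1):
            z = self.n0.get(j, 0) + other.n0.get(j, 0)
            o = self.n1.get(j, 0) + other.n1.get(j, 0)
            if z:
                self.n0[j] = z
            if o:
                self.n1[j] = o
            if z > o:
                self.alleles[j] = 0
            elif o > z:
                self.alleles[j] = 1
            else:  # tie: keep the higher-support cluster's call
                keeper = self if bigger_is_self else other
                self.alleles[j] = keeper.alleles.get(j, other.alleles.get(j, self.alleles.get(j, 0)))
        self.read_ids.extend(other.read_ids)
        self.n_reads += other.n_reads
        self.version += 1
        other.alive = False


def _eligible(a: _Cluster, b: _Cluster, params: MergeParams, zero_mismatch: bool):
    m, mm, score = score_overlap(a.alleles, b.alleles, params.mismatch_penalty)
    if m + mm < params.min_overlap:
        return None
    if zero_mismatch:
        if mm != 0:
            return None
    elif m / (m + mm) < params.min_match_frac:
        return None
    # ordering: score desc, then matches desc, combined extent desc, ids asc
    lo = min(a.extent()[0], b.extent()[0])
    hi = max(a.extent()[1], b.extent()[1])
    return (-score, -m, -(hi - lo), min(a.cid, b.cid), max(a.cid, b.cid))


def _merge_round(clusters: list[_Cluster], params: MergeParams, zero_mismatch: bool) -> None:
    """One round of globally best-first merging until no eligible pair remains."""
    alive = [c for c in clusters if c.alive]
    # index clusters by covered site for candidate generation
    by_site: dict[int, list[_Cluster]] = {}
    for c in alive:
        for j in c.alleles:
            by_site.setdefault(j, []).append(c)

    def candidates(c: _Cluster):
        seen = set()
        for j in c.alleles:
            for other in by_site.get(j, ()):  # shares >= 1 site
                if other is not c and other.alive and other.cid not in seen:
                    seen.add(other.cid)
                    yield other

    heap: list[tuple] = []

    def push_pairs(c: _Cluster):
        for other in candidates(c):
            key = _eligible(c, other, params, zero_mismatch)
            if key is not None:
                heapq.heappush(heap, key + (c.cid, c.version, other.cid, other.version))

    by_id = {c.cid: c for c in alive}
    for c in alive:
        for other in candidates(c):
            if other.cid > c.cid:
                key = _eligible(c, other, params, zero_mismatch)
                if key is not None:
                    heapq.heappush(heap, key + (c.cid, c.version, other.cid, other.version))

    while heap:
        entry = heapq.heappop(heap)
        cid_a, ver_a, cid_b, ver_b = entry[-4:]
        a, b = by_id.get(cid_a), by_id.get(cid_b)
        if a is None or b is None or not a.alive or not b.alive:
            continue
        if a.version != ver_a or b.version != ver_b:
            continue  # stale entry
        if _eligible(a, b, params, zero_mismatch) is None:
            continue
        a.absorb(b)
        del by_id[b.cid]
        for j in b.alleles:
            lst = by_site.get(j)
            if lst is not None and b in lst:
                lst.remove(b)
        for j in a.alleles:
            lst = by_site.setdefault(j, [])
            if a not in lst:
                lst.append(a)
        push_pairs(a)


def phase(
    fragments: FragmentSet,
    sites: list[Site],
    params: MergeParams | None = None,
    min_output_sites: int | None = None,
) -> HaplotypeSet:
    """Assemble fragments into a variable number of phased haplotypes.

    Fragments are sorted canonically (extent start, length descending, read
    id) so the result is independent of input file order.  Output drops
    haplotypes covering fewer than ``min_output_sites`` sites (default:
    ``params.min_overlap``, i.e. residual fragments too short to merge).
    """
    params = params or MergeParams()
    if min_output_sites is None:
        min_output_sites = params.min_overlap
    frags = sorted(
        fragments,
        key=lambda f: (int(f.site_idx[0]), -len(f.site_idx), f.read_id),
    )
    clusters = [
        _Cluster(i, dict(zip(map(int, f.site_idx), map(int, f.alleles))), f.read_id)
        for i, f in enumerate(frags)
    ]
    if not clusters:
        return HaplotypeSet([], sites)

    for rnd in range(params.rounds):
        _merge_round(clusters, params, zero_mismatch=(rnd == 0))

    haps = []
    k = 0
    for c in clusters:
        if not c.alive or len(c.alleles) < min_output_sites:
            continue
        support = {
            j: c.n0.get(j, 0) + c.n1.get(j, 0) for j in c.alleles
        }
        haps.append(
            Haplotype(
                id=str(k),
                alleles=dict(sorted(c.alleles.items())),
                support=support,
                read_ids=sorted(c.read_ids),
            )
        )
        k += 1
    return HaplotypeSet(haps, sites)


def estimate_error_rate(fragments: FragmentSet, hapset: HaplotypeSet) -> float:
    """Fragment error rate: minimum read-vs-haplotype mismatches.

    For each read, the minimum mismatch count against any haplotype over
    their shared sites; the rate is total minimum mismatches divided by the
    total alleles compared (at each read's best haplotype).  Reads that
    overlap no haplotype are excluded (logged).
    """
    if not hapset.haplotypes:
        raise ValueError("empty haplotype set")
    total_mm = 0
    total_alleles = 0
    n_orphans = 0
    for frag in fragments:
        obs = dict(zip(map(int, frag.site_idx), map(int, frag.alleles)))
        best = None
        for h in hapset.haplotypes:
            m, mm, _ = score_overlap(obs, h.alleles)
            if m + mm == 0:
                continue
            cand = (mm, -(m + mm))
            if best is None or cand < best:
                best = cand
        if best is None:
            n_orphans += 1
            continue
        total_mm += best[0]
        total_alleles += -best[1]
    if n_orphans:
        logger.info("%d reads overlapped no haplotype; excluded", n_orphans)
    if total_alleles == 0:
        raise ValueError("no read overlaps any haplotype")
    return total_mm / total_alleles


def haplotype_count_profile(hapset: HaplotypeSet) -> tuple[dict[int, int], float]:
    """Per-site haplotype counts and their mean over phased sites.

    Returns ``(counts, mean)`` where ``counts[j]`` is the number of
    haplotypes covering site ``j``; the mean is over sites covered by at
    least one haplotype (nan for an empty set).
    """
    counts = hapset.per_site_count()
    if not counts:
        return counts, float("nan")
    return counts, float(np.mean(list(counts.values())))


def total_mismatches(hapset_or_clusters: HaplotypeSet, fragments: FragmentSet) -> int:
    """Total within-cluster read-vs-consensus mismatches of a phasing.

    Each read is compared to the haplotype that absorbed it; unplaced reads
    contribute zero.  Used to compare the greedy result against exhaustive
    partition oracles.
    """
    owner: dict[str, Haplotype] = {}
    for h in hapset_or_clusters.haplotypes:
        for rid in h.read_ids:
            owner[rid] = h
    total = 0
    for frag in fragments:
        h = owner.get(frag.read_id)
        if h is None:
            continue
        obs = dict(zip(map(int, frag.site_idx), map(int, frag.alleles)))
        _, mm, _ = score_overlap(obs, h.alleles)
        total += mm
    return total


def exhaustive_min_mismatches(fragments: FragmentSet, max_groups: int = 4) -> int:
    """Exact minimum total mismatches over all read partitions (brute force).

    Enumerates every partition of the reads into at most ``max_groups``
    groups (restricted-growth strings) and scores each by summing, per
    group and site, the minority read count — the mismatch count against a
    majority consensus.  Exponential in the number of reads; intended as a
    reference optimum for instances of a dozen reads or fewer.
    """
    reads = list(fragments)
    n = len(reads)
    if n == 0:
        return 0
    if n > 14:
        raise ValueError("exhaustive search is limited to <= 14 reads")
    sites = sorted({int(j) for f in reads for j in f.site_idx})
    col = {j: k for k, j in enumerate(sites)}
    obs0 = np.zeros((n, len(sites)), dtype=np.int32)
    obs1 = np.zeros((n, len(sites)), dtype=np.int32)
    for i, f in enumerate(reads):
        for j, a in zip(f.site_idx, f.alleles):
            (obs1 if a else obs0)[i, col[int(j)]] = 1

    best = [np.inf]
    assign = np.zeros(n, dtype=np.int64)

    def rec(i: int, n_used: int) -> None:
        if i == n:
            cost = 0
            for g in range(n_used):
                ing = assign[:i] == g
                cost += int(np.minimum(obs0[ing].sum(0), obs1[ing].sum(0)).sum())
            best[0] = min(best[0], cost)
            return
        for g in range(min(n_used + 1, max_groups)):
            assign[i] = g
            rec(i + 1, max(n_used, g + 1))

    rec(0, 0)
    return int(best[0])
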