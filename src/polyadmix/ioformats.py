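"""Readers and writers for the formats the pipeline touches.

Biallelic SNP genotypes travel as VCF (GT plus AD read counts), long-read
allele observations as HapCUT2-style fragment files, and phased/painted
haplotypes and strain->population assignments as TSV tables.  External
coordinates are 1-based (VCF convention); all in-memory site references are
0-based indices into a sorted site list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: genotype codes used throughout
HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True, order=True)
class Site:
    """A biallelic SNP: chromosome, 1-based position, ref and alt alleles."""

    chrom: str
    pos: int
    ref: str = "A"
    alt: str = "T"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")


@dataclass
class GenotypeMatrix:
    """Strains x biallelic SNPs with optional population assignments.

    ``calls[i, j]`` holds the genotype of strain ``i`` at site ``j`` coded
    0=homRef, 1=het, 2=homAlt, -1=missing.  ``pop`` maps strain name to a
    population label; ``admixture`` maps strain name to an assigned-ancestry
    admixture fraction (strains above a cutoff are excluded from population
    allele frequencies).
    """

    sites: list[Site]
    strains: list[str]
    calls: np.ndarray
    pop: dict[str, str] = field(default_factory=dict)
    admixture: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.strains), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.strains)} strains x {len(self.sites)} sites"
            )
        if any(b <= a for a, b in zip(self.sites, self.sites[1:])):
            raise ValueError("sites must be strictly sorted by (chrom, pos)")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    def strain_index(self, name: str) -> int:
        return self.strains.index(name)

    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    def chroms(self) -> np.ndarray:
        return np.array([s.chrom for s in self.sites])

    def strains_in(self, population: str, max_admixture: float = 1.0) -> list[str]:
        """Strains assigned to ``population`` with admixture <= cutoff."""
        out = []
        for s in self.strains:
            if self.pop.get(s) != population:
                continue
            if self.admixture.get(s, 0.0) > max_admixture:
                continue
            out.append(s)
        return out


@dataclass
class SiteReadCounts:
    """Per-strain, per-site ref/alt read counts (from VCF AD); -1 = missing."""

    ref: np.ndarray
    alt: np.ndarray

    def __post_init__(self) -> None:
        self.ref = np.asarray(self.ref, dtype=np.int32)
        self.alt = np.asarray(self.alt, dtype=np.int32)
        if self.ref.shape != self.alt.shape:
            raise ValueError("ref and alt count arrays must have equal shape")

    def depth(self) -> np.ndarray:
        d = self.ref + self.alt
        d[(self.ref < 0) | (self.alt < 0)] = -1
        return d


@dataclass
class Fragment:
    """One read's allele observations: parallel arrays of site index and allele."""

    read_id: str
    site_idx: np.ndarray
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.site_idx = np.asarray(self.site_idx, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.site_idx.shape != self.alleles.shape:
            raise ValueError("site_idx and alleles must be parallel")
        if len(self.site_idx) > 1 and np.any(np.diff(self.site_idx) <= 0):
            raise ValueError(f"site indices not strictly increasing in {self.read_id}")


@dataclass
class FragmentSet:
    """Sparse long-read allele observations over a shared site list."""

    fragments: list[Fragment]

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self):
        return iter(self.fragments)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_SNP_ALLELES = frozenset("ACGT")


def read_vcf(path: str, min_base_quality: int = 0) -> tuple[GenotypeMatrix, SiteReadCounts]:
    """Read biallelic SNP genotypes and AD read counts from a VCF 4.x file.

    Multiallelic records and non-SNP records are skipped (counted in the
    log).  Het codes 0/1 and 1/0 are equivalent; phased separators are
    accepted but phase is ignored.  Where AD is absent, counts are -1.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:  # malformed header
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc

    strains = list(vcf.samples)
    sites: list[Site] = []
    calls_rows, ref_rows, alt_rows = [], [], []
    n_skipped = 0
    for rec in vcf:
        if (
            len(rec.ALT) != 1
            or len(rec.REF) != 1
            or rec.REF not in _SNP_ALLELES
            or len(rec.ALT[0]) != 1
            or rec.ALT[0] not in _SNP_ALLELES
        ):
            n_skipped += 1
            continue
        gts = rec.gt_types  # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        if gts is None:
            raise FormatError(f"VCF {path} has no GT field")
        row = np.asarray(gts, dtype=np.int8)
        row[row == 3] = MISSING
        sites.append(Site(rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        calls_rows.append(row)
        try:
            ad = rec.format("AD")
        except KeyError:  # AD absent from header
            ad = None
        if ad is None:
            ref_rows.append(np.full(len(strains), -1, dtype=np.int32))
            alt_rows.append(np.full(len(strains), -1, dtype=np.int32))
        else:
            ad = np.asarray(ad, dtype=np.int32)
            ref_rows.append(np.where(ad[:, 0] < 0, -1, ad[:, 0]))
            alt_rows.append(np.where(ad[:, 1] < 0, -1, ad[:, 1]))
    if n_skipped:
        logger.info("skipped %d multiallelic/non-SNP records in %s", n_skipped, path)
    if not sites:
        calls = np.zeros((len(strains), 0), dtype=np.int8)
        counts = SiteReadCounts(np.zeros((len(strains), 0)), np.zeros((len(strains), 0)))
        return GenotypeMatrix(sites, strains, calls), counts

    # enforce (chrom, pos) order even for unsorted inputs
    keys = sorted(range(len(sites)), key=lambda i: (sites[i].chrom, sites[i].pos))
    sites = [sites[i] for i in keys]
    calls = np.stack([calls_rows[i] for i in keys], axis=1)
    ref = np.stack([ref_rows[i] for i in keys], axis=1)
    alt = np.stack([alt_rows[i] for i in keys], axis=1)
    return GenotypeMatrix(sites, strains, calls), SiteReadCounts(ref, alt)


_GT_STR = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(
    matrix: GenotypeMatrix,
    path: str,
    counts: SiteReadCounts | None = None,
) -> None:
    """Write a minimal VCF 4.2 file with GT (and AD when counts given)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(s.chrom for s in matrix.sites):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if counts is not None:
            fh.write(
                '##FORMAT=<ID=AD,Number=R,Type=Integer,'
                'Description="Allelic depths">\n'
            )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.strains)
            + "\n"
        )
        fmt = "GT:AD" if counts is not None else "GT"
        for j, site in enumerate(matrix.sites):
            fields = [site.chrom, str(site.pos), ".", site.ref, site.alt, ".", ".", ".", fmt]
            for i in range(matrix.n_strains):
                cell = _GT_STR[int(matrix.calls[i, j])]
                if counts is not None:
                    r, a = int(counts.ref[i, j]), int(counts.alt[i, j])
                    ad = "." if r < 0 or a < 0 else f"{r},{a}"
                    cell = f"{cell}:{ad}"
                fields.append(cell)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# HapCUT2 fragment files
# ---------------------------------------------------------------------------


def read_fragments(
    path: str, sites: list[Site], min_base_quality: int = 10
) -> FragmentSet:
    """Parse a HapCUT2 fragment file against a site list.

    Each line is ``nblocks readId (offset alleles)... qualities`` where
    offsets are 1-based indices into the phased-site list and qualities are
    phred+33 characters, one per observed allele.  Alleles with base quality
    below ``min_base_quality`` are dropped; reads left covering fewer than
    two sites are discarded.
    """
    fragments: list[Fragment] = []
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\r\n").strip()
            if not line:
                continue
            n_lines += 1
            tok = line.split()
            try:
                n_blocks = int(tok[0])
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}:{lineno}: bad block count") from exc
            read_id = tok[1]
            expected = 2 + 2 * n_blocks + 1
            if len(tok) != expected:
                raise FormatError(
                    f"{path}:{lineno}: expected {expected} fields for "
                    f"{n_blocks} blocks, got {len(tok)}"
                )
            quals = tok[-1]
            idx: list[int] = []
            alleles: list[int] = []
            for b in range(n_blocks):
                start = int(tok[2 + 2 * b])
                allele_str = tok[3 + 2 * b]
                if set(allele_str) - {"0", "1"}:
                    raise FormatError(
                        f"{path}:{lineno}: allele characters must be 0/1, "
                        f"got {allele_str!r}"
                    )
                for k, ch in enumerate(allele_str):
                    idx.append(start - 1 + k)
                    alleles.append(int(ch))
            if len(quals) != len(idx):
                raise FormatError(
                    f"{path}:{lineno}: {len(idx)} alleles but {len(quals)} qualities"
                )
            if idx and (min(idx) < 0 or max(idx) >= len(sites)):
                raise IndexError(
                    f"{path}:{lineno}: SNP index outside site list (n={len(sites)})"
                )
            keep = [
                (i, a)
                for i, a, q in zip(idx, alleles, quals)
                if ord(q) - 33 >= min_base_quality
            ]
            if len(keep) < 2:
                continue
            keep.sort()
            fragments.append(
                Fragment(
                    read_id,
                    np.array([i for i, _ in keep]),
                    np.array([a for _, a in keep]),
                )
            )
    if n_lines == 0:
        logger.warning("fragment file %s is empty", path)
    return FragmentSet(fragments)


def write_fragments(fragset: FragmentSet, path: str, quality_char: str = "I") -> None:
    """Write fragments in the HapCUT2 dialect (single quality for all alleles)."""
    with open(path, "w") as fh:
        for frag in fragset:
            blocks: list[tuple[int, str]] = []
            start = prev = None
            cur = ""
            for i, a in zip(frag.site_idx, frag.alleles):
                if prev is not None and i == prev + 1:
                    cur += str(int(a))
                else:
                    if cur:
                        blocks.append((start, cur))
                    start, cur = int(i), str(int(a))
                prev = int(i)
            if cur:
                blocks.append((start, cur))
            parts = [str(len(blocks)), frag.read_id]
            for s, alle in blocks:
                parts += [str(s + 1), alle]
            parts.append(quality_char * len(frag.site_idx))
            fh.write(" ".join(parts) + "\n")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------


def write_haplotypes(hapset, path: str, painted=None) -> None:
    """Write a HaplotypeSet as TSV: chrom, pos, one 0/1/. column per haplotype.

    When ``painted`` (a list of PaintedHaplotype aligned with the set's
    haplotypes) is given, one ancestry-code column (E/A/.) per haplotype is
    appended.
    """
    sites = hapset.sites
    haps = hapset.haplotypes
    cols = ["chrom", "pos"] + [f"hap{h.id}" for h in haps]
    code_maps = None
    if painted is not None:
        cols += [f"anc{h.id}" for h in haps]
        code_maps = [dict(zip(p.site_idx, p.codes)) for p in painted]
    covered = sorted({int(i) for h in haps for i in h.alleles})
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for j in covered:
            row = [sites[j].chrom, str(sites[j].pos)]
            for h in haps:
                row.append(str(h.alleles[j]) if j in h.alleles else ".")
            if code_maps is not None:
                for cm in code_maps:
                    row.append(cm.get(j, "."))
            fh.write("\t".join(row) + "\n")


def read_haplotypes(path: str, sites: list[Site]):
    """Read a haplotype TSV back into a HaplotypeSet over ``sites``."""
    from .phaser import Haplotype, HaplotypeSet

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    pos_index = {(s.chrom, s.pos): j for j, s in enumerate(sites)}
    hap_cols = [c for c in df.columns if c.startswith("hap")]
    haps = []
    for c in hap_cols:
        alleles = {}
        for _, row in df.iterrows():
            v = str(row[c])
            if v in ("0", "1"):
                alleles[pos_index[(row["chrom"], int(row["pos"]))]] = int(v)
        haps.append(Haplotype(id=c[3:], alleles=alleles, support={k: 1 for k in alleles}))
    return HaplotypeSet([h for h in haps if h.alleles], sites)


def read_population_table(path: str) -> tuple[dict[str, str], dict[str, float]]:
    """Read strain->population TSV (columns strain, population[, ancestry_fraction])."""
    df = pd.read_csv(path, sep="\t", dtype={"strain": str, "population": str})
    if "strain" not in df.columns or "population" not in df.columns:
        raise FormatError(f"{path}: need columns strain, population")
    pop = dict(zip(df["strain"], df["population"]))
    adm = {}
    if "ancestry_fraction" in df.columns:
        adm = {
            s: 1.0 - float(f)
            for s, f in zip(df["strain"], df["ancestry_fraction"])
            if np.isfinite(f)
        }
    return pop, adm


def write_population_table(
    pop: dict[str, str], path: str, admixture: dict[str, float] | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write("strain\tpopulation\tancestry_fraction\n")
        for strain, p in pop.items():
            frac = 1.0 - (admixture or {}).get(strain, 0.0)
            fh.write(f"{strain}\t{p}\t{frac:.6g}\n")
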