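import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyadmix.ancestry import (
    AncestryPanel,
    PaintedHaplotype,
    allele_copy_counts,
    build_panel,
    count_switches,
    paint,
    population_allele_freq,
    pure_fraction,
    select_diagnostic_sites,
    select_group_private_alleles,
)
from polyadmix.ioformats import GenotypeMatrix, Site
from polyadmix.phaser import Haplotype, HaplotypeSet
from polyadmix.simdata import (
    simulate_admixed_polyploid,
    simulate_cohort,
    truth_diagnostic_switches,
    truth_haplotype_set,
    truth_panel,
)


def _matrix(calls, pops=None, admix=None):
    calls = np.asarray(calls, dtype=np.int8)
    sites = [Site("chr01", 10 * (j + 1)) for j in range(calls.shape[1])]
    strains = [f"s{i}" for i in range(calls.shape[0])]
    pop = {s: (pops or {}).get(s, "P") for s in strains}
    return GenotypeMatrix(sites, strains, calls, pop=pop, admixture=admix or {})


class TestPopulationAlleleFreq:
    def test_all_hom_alt_gives_one(self):
        m = _matrix([[2], [2], [2], [2]])
        assert population_allele_freq(m, "P")[0] == 1.0

    def test_homozygotes_count_fully_heterozygotes_half(self):
        m = _matrix([[0], [0], [1], [1]])
        assert population_allele_freq(m, "P")[0] == pytest.approx(0.25)

    def test_all_missing_is_nan(self):
        m = _matrix([[-1], [-1]])
        assert np.isnan(population_allele_freq(m, "P")[0])

    def test_missing_excluded_from_denominator(self):
        m = _matrix([[2], [-1], [0], [-1]])
        assert population_allele_freq(m, "P")[0] == pytest.approx(0.5)

    def test_admixed_strains_excluded(self):
        m = _matrix([[2], [0]], admix={"s1": 0.10})
        assert population_allele_freq(m, "P", max_admixture=0.01)[0] == 1.0

    def test_empty_group_raises(self):
        m = _matrix([[0]])
        with pytest.raises(ValueError):
            population_allele_freq(m, "missing-pop")


class TestDiagnosticSites:
    def test_fixed_difference_selected_with_allele_typing(self):
        sel = select_diagnostic_sites(np.array([1.0]), np.array([0.0]))
        assert sel == {0: (1, 0)}
        sel = select_diagnostic_sites(np.array([0.0]), np.array([1.0]))
        assert sel == {0: (0, 1)}

    def test_near_threshold_rejected(self):
        assert select_diagnostic_sites(np.array([0.98]), np.array([0.0])) == {}

    def test_nan_frequencies_never_selected(self):
        assert select_diagnostic_sites(np.array([np.nan]), np.array([0.0])) == {}

    def test_recovers_generator_diagnostic_set_exactly(self, small_cfg):
        cfg = small_cfg.with_(diagnostic_leak=0.0)
        m = simulate_cohort(cfg, {"E": 12, "A": 12})
        from polyadmix.simdata import simulate_founders

        pools = simulate_founders(cfg)
        f_e = population_allele_freq(m, "E")
        f_a = population_allele_freq(m, "A")
        sel = select_diagnostic_sites(f_e, f_a)
        assert sorted(sel) == sorted(int(j) for j in pools.diagnostic_idx)


class TestGroupPrivateAlleles:
    def test_common_in_group_absent_elsewhere_selected(self):
        sel = select_group_private_alleles(
            {"Ale 1": np.array([0.30])}, {"Clinical": np.array([0.0])}
        )
        assert sel == {0: (1, "Ale 1")}

    def test_low_presence_elsewhere_rejects(self):
        sel = select_group_private_alleles(
            {"Ale 1": np.array([0.30])}, {"Clinical": np.array([0.02])}
        )
        assert sel == {}

    def test_reference_allele_can_be_private(self):
        sel = select_group_private_alleles(
            {"g": np.array([0.5])}, {"o": np.array([0.999])}
        )
        assert sel == {0: (0, "g")}

    def test_recovers_planted_ghost_alleles(self, small_cfg):
        from polyadmix.simdata import simulate_founders

        pools = simulate_founders(small_cfg)
        m = simulate_cohort(small_cfg, {"E": 15, "A": 15, "ghost": 15})
        freqs = {p: population_allele_freq(m, p) for p in ("E", "A", "ghost")}
        sel = select_group_private_alleles(
            {"ghost": freqs["ghost"]}, {"E": freqs["E"], "A": freqs["A"]}
        )
        planted = set(int(j) for j in pools.ghost_private_idx)
        found = {j for j, (a, g) in sel.items() if a == 1 and j in planted}
        assert len(found) / len(planted) >= 0.95


def _toy_hapset(allele_rows, start=0):
    sites = [Site("chr01", 1000 * (j + 1)) for j in range(len(allele_rows[0]))]
    haps = [
        Haplotype(str(i), {j + start: int(a) for j, a in enumerate(row)}, {})
        for i, row in enumerate(allele_rows)
    ]
    return HaplotypeSet(haps, sites)


class TestPaint:
    def test_all_european_alleles_is_pure_at_any_purity(self):
        hs = _toy_hapset([[1, 1, 1, 1]])
        panel = AncestryPanel({j: (1, 0) for j in range(4)}, {})
        (p,) = paint(hs, panel, purity=1.0 - 1e-9)
        assert p.codes == ["E"] * 4 and p.classification == "E-pure"

    def test_purity_threshold_splits_pure_and_mixed(self):
        codes = [1] * 96 + [0] * 4
        hs = _toy_hapset([codes])
        panel = AncestryPanel({j: (1, 0) for j in range(100)}, {})
        (p95,) = paint(hs, panel, purity=0.95)
        (p97,) = paint(hs, panel, purity=0.97)
        assert p95.classification == "E-pure"
        assert p97.classification == "mixed"

    def test_haplotype_without_panel_sites_is_unclassified(self):
        hs = _toy_hapset([[0, 1]])
        panel = AncestryPanel({5: (1, 0)}, {})
        (p,) = paint(hs, panel)
        assert p.classification == "unclassified" and len(p.site_idx) == 0

    def test_codes_only_at_covered_diagnostic_sites(self):
        hs = _toy_hapset([[0, 1, 0]])
        panel = AncestryPanel({0: (1, 0), 2: (0, 1)}, {1: (1, "g")})
        (p,) = paint(hs, panel)
        assert list(p.site_idx) == [0, 2]
        # site 0: allele 0 differs from E-typed allele 1 -> A;
        # site 2: allele 0 equals E-typed allele 0 -> E
        assert p.codes == ["A", "E"]
        assert list(p.private_idx) == [1]


class TestCountSwitches:
    def _painted(self, codes, positions=None):
        n = len(codes)
        positions = positions or [1000 * (j + 1) for j in range(n)]
        sites = [Site("chr01", p) for p in positions]
        p = PaintedHaplotype(
            "h", np.arange(n), list(codes), np.empty(0, dtype=np.int64),
            "mixed", (positions[0], positions[-1]), "chr01",
        )
        return [p], sites

    def test_single_boundary_counts_one_switch(self):
        painted, sites = self._painted("EEEAAA")
        assert count_switches(painted, sites, min_sites=1).total == 1

    def test_short_run_filtered_and_flanks_merged(self):
        painted, sites = self._painted("EEEEEAEEEEE")
        assert count_switches(painted, sites, min_sites=1).total == 2
        assert count_switches(painted, sites, min_sites=5).total == 0

    def test_span_filter_drops_narrow_runs(self):
        # middle A run spans 3 kb < 4 kb
        painted, sites = self._painted(
            "EEAAEE", positions=[1000, 2000, 3000, 6000, 10_000, 11_000]
        )
        assert count_switches(painted, sites, min_span_bp=4000).total == 0
        assert count_switches(painted, sites, min_sites=1).total == 2

    @given(st.text(alphabet="EA", min_size=0, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_filters_only_reduce_switch_counts(self, codes):
        if not codes:
            return
        painted, sites = self._painted(codes)
        c1 = count_switches(painted, sites, min_sites=1).total
        c5 = count_switches(painted, sites, min_sites=5).total
        c4kb = count_switches(painted, sites, min_span_bp=4000).total
        assert c5 <= c1 and c4kb <= c1

    def test_noiseless_painting_matches_generator_truth(self, small_cfg):
        """With no leak and no observation noise, switches seen by painting
        equal the generator's diagnostic-site ancestry switches exactly."""
        from polyadmix.simdata import simulate_founders

        cfg = small_cfg.with_(diagnostic_leak=0.0, n_meioses=20)
        pools = simulate_founders(cfg)
        truth = simulate_admixed_polyploid(pools, cfg)
        painted = paint(truth_haplotype_set(truth), truth_panel(pools))
        got = count_switches(painted, pools.sites, min_sites=1).total
        assert got == truth_diagnostic_switches(truth, pools)


class TestPureFraction:
    def _painted_with(self, classes, spans):
        return [
            PaintedHaplotype(
                str(i), np.empty(0, dtype=np.int64), [], np.empty(0, dtype=np.int64),
                cls, span, "chr01",
            )
            for i, (cls, span) in enumerate(zip(classes, spans))
        ]

    def test_all_pure_is_one(self):
        p = self._painted_with(["E-pure", "A-pure"], [(1, 100), (1, 100)])
        assert pure_fraction(p) == 1.0

    def test_equal_extents_half_pure(self):
        p = self._painted_with(["E-pure", "mixed"], [(1, 100), (1, 100)])
        assert pure_fraction(p) == 0.5

    def test_unclassified_excluded_from_denominator(self):
        p = self._painted_with(["E-pure", "unclassified"], [(1, 100), (1, 100)])
        assert pure_fraction(p) == 1.0

    def test_no_classified_coverage_raises(self):
        p = self._painted_with(["unclassified"], [(1, 100)])
        with pytest.raises(ValueError):
            pure_fraction(p)

    def test_unrecombined_genome_is_fully_pure(self, small_cfg):
        from polyadmix.simdata import simulate_founders

        cfg = small_cfg.with_(n_meioses=0, diagnostic_leak=0.0, frac_ghost_private=0.0)
        pools = simulate_founders(cfg)
        truth = simulate_admixed_polyploid(pools, cfg)
        painted = paint(truth_haplotype_set(truth), truth_panel(pools))
        assert pure_fraction(painted) == 1.0


class TestAlleleCopyCounts:
    def test_two_asian_copies_at_every_site(self):
        hs = _toy_hapset([[1, 1], [1, 1], [0, 0], [0, 0]])
        panel = AncestryPanel({0: (1, 0), 1: (1, 0)}, {})
        mean_a, _ = allele_copy_counts(hs, panel)
        assert mean_a == 2.0  # allele 0 is Asian-typed here

    def test_private_allele_on_single_haplotype(self):
        hs = _toy_hapset([[1, 1], [0, 0], [0, 0], [0, 0]])
        panel = AncestryPanel({}, {0: (1, "g"), 1: (1, "g")})
        _, mean_p = allele_copy_counts(hs, panel)
        assert mean_p == 1.0

    def test_sites_without_four_haplotypes_excluded(self):
        hs = _toy_hapset([[1, 1], [1, 1], [0, 0]])
        panel = AncestryPanel({0: (1, 0), 1: (1, 0)}, {})
        mean_a, mean_p = allele_copy_counts(hs, panel)
        assert np.isnan(mean_a) and np.isnan(mean_p)


def test_panel_construction_rejects_overlap_and_build_panel_resolves_it():
    with pytest.raises(ValueError):
        AncestryPanel({0: (1, 0)}, {0: (1, "g")})
    p = build_panel({0: (1, 0)}, {0: (1, "g"), 1: (0, "g")})
    assert 0 in p.diagnostic and 0 not in p.private and 1 in p.private
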