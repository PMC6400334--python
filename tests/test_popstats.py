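import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from polyadmix import popstats as ps
from polyadmix.simdata import (
    SimConfig,
    simulate_admixed_polyploid,
    simulate_cohort,
    simulate_founders,
    simulate_observations,
)

freq_arrays = arrays(
    dtype=float,
    shape=st.integers(2, 30),
    elements=st.floats(0.0, 1.0, allow_nan=False),
)


class TestF4:
    def test_identical_first_pair_gives_zero(self):
        p = np.array([0.1, 0.5, 0.9])
        assert ps.f4(p, p, np.array([1.0, 0, 1]), np.array([0.0, 1, 0])) == 0.0

    def test_single_fixed_site(self):
        one, zero = np.array([1.0]), np.array([0.0])
        assert ps.f4(one, zero, one, zero) == 1.0

    def test_sites_missing_in_any_population_dropped(self):
        a = np.array([1.0, np.nan])
        b = np.array([0.0, 0.5])
        assert ps.f4(a, b, a, b) == 1.0

    def test_no_shared_sites_raises(self):
        with pytest.raises(ValueError):
            ps.f4(np.array([np.nan]), np.array([0.5]), np.array([0.5]), np.array([0.5]))

    @given(a=freq_arrays, seed=st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_antisymmetry_identities(self, a, seed):
        rng = np.random.default_rng(seed)
        b, c, d = (rng.random(len(a)) for _ in range(3))
        v = ps.f4(a, b, c, d)
        assert ps.f4(b, a, c, d) == pytest.approx(-v, abs=1e-12)
        assert ps.f4(a, b, d, c) == pytest.approx(-v, abs=1e-12)
        assert ps.f4(a, a, c, d) == 0.0


class TestBlockJackknife:
    def test_two_block_arithmetic(self):
        # leave-one-out means 0.1 and 0.3 -> se = 0.1
        values = np.concatenate([np.full(500, 0.3), np.full(500, 0.1)])
        block = np.repeat([0, 1], 500)
        est, se, nb = ps.block_jackknife(values, block)
        assert est == pytest.approx(0.2)
        assert se == pytest.approx(0.1)
        assert nb == 2

    def test_identical_blocks_give_zero_se(self):
        values = np.tile(np.linspace(0, 1, 500), 4)
        block = np.repeat(np.arange(4), 500)
        _, se, _ = ps.block_jackknife(values, block)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_single_block_rejected(self):
        with pytest.raises(ValueError):
            ps.block_jackknife(np.ones(500), np.zeros(500))

    def test_partial_final_block_merged(self):
        block = ps.make_blocks(1499, 500)
        # 2 blocks: 500 + 999
        assert np.sum(block == 1) == 999
        assert len(np.unique(block)) == 2

    def test_null_f4_z_scores_are_calibrated(self):
        """Without admixture or diagnostic structure all pools are exchangeable,
        so |Z| should rarely exceed 3."""
        n_extreme = 0
        reps = 40
        for seed in range(reps):
            # enough sites for ~10 jackknife blocks, else Z is heavy-tailed
            cfg = SimConfig(
                seed=7000 + seed, n_chrom=2, chrom_length=400_000,
                n_sites_per_chrom=2500, frac_diagnostic=0.0,
                frac_ghost_private=0.0, fragment_count=0, loh_tract_rate=0.0,
            )
            m = simulate_cohort(cfg, {"E": 10, "A": 10, "ghost": 10, "outgroup": 10})
            res = ps.f4_jackknife(m, ("E", "A", "ghost", "outgroup"))
            if abs(res.z) >= 3:
                n_extreme += 1
        assert n_extreme / reps <= 0.05

    def test_admixture_produces_significant_f4(self):
        cfg = SimConfig(
            seed=77, n_chrom=2, chrom_length=400_000, n_sites_per_chrom=1000,
            fragment_count=0, loh_tract_rate=0.0,
        )
        m = simulate_cohort(cfg, {"E": 15, "A": 15, "ghost": 12, "outgroup": 12,
                                  "admixed": 4}, alpha=0.4)
        res = ps.f4_jackknife(m, ("ghost", "outgroup", "admixed", "E"))
        assert abs(res.z) > 3


class TestAdmixtureProportion:
    def _cohort(self, seed=5, alpha=0.4, n_adm=1):
        cfg = SimConfig(
            seed=seed, n_chrom=2, chrom_length=400_000, n_sites_per_chrom=1000,
            fragment_count=0, loh_tract_rate=0.0,
        )
        return simulate_cohort(
            cfg, {"E": 20, "A": 20, "ghost": 15, "outgroup": 15, "admixed": n_adm},
            alpha=alpha,
        )

    def test_pure_asian_population_gives_alpha_one(self):
        m = self._cohort()
        r = ps.f4_admixture_proportion(m, ("ghost", "outgroup"), ("A", "E"), "A")
        assert r.alpha == pytest.approx(1.0)

    def test_pure_european_population_gives_alpha_zero(self):
        m = self._cohort()
        r = ps.f4_admixture_proportion(m, ("ghost", "outgroup"), ("A", "E"), "E")
        assert r.alpha == pytest.approx(0.0)

    def test_per_strain_alpha_recovers_simulated_mixture(self):
        est = []
        for seed in range(5):
            m = self._cohort(seed=200 + seed)
            r = ps.f4_admixture_proportion(
                m, ("ghost", "outgroup"), ("A", "E"), "admixed_000",
                test_is_strain=True,
            )
            assert not r.weak_denominator
            est.append(r.alpha)
        assert np.mean(est) == pytest.approx(0.40, abs=0.03)


class TestClockArithmetic:
    @pytest.mark.parametrize(
        "count, expected_pct",
        [(1586, 0.153), (1040, 0.100), (899, 0.087), (716, 0.069)],
    )
    def test_divergence_from_private_allele_counts(self, count, expected_pct):
        pct = ps.lineage_divergence(count, 1_036_317)
        assert round(pct, 3) == expected_pct

    def test_zero_count_gives_zero_percent(self):
        assert ps.lineage_divergence(0, 100) == 0.0

    def test_zero_sites_rejected(self):
        with pytest.raises(ValueError):
            ps.lineage_divergence(10, 0)

    def test_clock_dates_divergence(self):
        est = ps.divergence_time(0.153)
        assert est.years == pytest.approx(2.04e4, rel=1e-3)
        est = ps.divergence_time(0.069)
        assert est.years == pytest.approx(9.2e3, rel=1e-3)

    def test_doubling_mutation_rate_halves_years(self):
        a = ps.divergence_time(0.1, mutation_rate=5e-10)
        b = ps.divergence_time(0.1, mutation_rate=1e-9)
        assert a.years == pytest.approx(2 * b.years)

    def test_expected_mitotic_events_match_published_rates(self):
        conv, rec = ps.expected_mitotic_events()
        assert round(conv, 4) == 0.0038
        assert round(rec, 4) == 0.0028

    def test_mitotic_expectations_scale_linearly_with_genome(self):
        c1, r1 = ps.expected_mitotic_events(genome_kb=48_000)
        c2, r2 = ps.expected_mitotic_events(genome_kb=96_000)
        assert (c2, r2) == (pytest.approx(2 * c1), pytest.approx(2 * r1))


class TestGenotypeDiscordance:
    def test_identical_calls_give_zero(self):
        calls = np.array([0, 1, 2, -1, 1])
        assert ps.genotype_discordance(calls, calls.copy()) == 0.0

    def test_one_in_a_thousand(self):
        a = np.zeros(1000, dtype=np.int8)
        b = a.copy()
        b[0] = 1
        assert ps.genotype_discordance(a, b) == pytest.approx(1e-3)

    def test_missing_sites_excluded(self):
        a = np.array([0, -1, 2])
        b = np.array([0, 2, -1])
        assert ps.genotype_discordance(a, b) == 0.0

    def test_no_shared_calls_rejected(self):
        with pytest.raises(ValueError):
            ps.genotype_discordance(np.array([-1]), np.array([0]))

    def test_replicate_observations_match_noise_model(self, small_cfg, small_pools):
        """Observing the same genome twice at 30x should disagree at the rate
        implied by Poisson allele dropout at heterozygous sites."""
        cfg = small_cfg.with_(short_read_depth_mean=30.0, fragment_count=0)
        truth = simulate_admixed_polyploid(small_pools, cfg)
        m1, _, _ = simulate_observations(truth, cfg, seed=901)
        m2, _, _ = simulate_observations(truth, cfg, seed=902)
        rate = ps.genotype_discordance(m1.calls[0], m2.calls[0])

        # analytic expectation: per-site call distribution from Poisson-thinned
        # allele counts; two independent observations disagree with
        # probability 1 - sum_g P(g)^2 (conditioned on both being called)
        lam = 30.0
        copies = np.concatenate([h.sum(axis=0) for h in truth.haplotypes])
        exp_disc = []
        for c in copies:
            f = c / truth.ploidy
            p_no_alt = np.exp(-lam * f)
            p_no_ref = np.exp(-lam * (1 - f))
            p = np.array(
                [
                    (1 - p_no_ref) * p_no_alt,  # homRef call
                    (1 - p_no_ref) * (1 - p_no_alt),  # het call
                    p_no_ref * (1 - p_no_alt),  # homAlt call
                ]
            )
            called = p.sum()
            p /= called
            exp_disc.append(1 - np.sum(p**2))
        expected = float(np.mean(exp_disc))
        n = len(copies)
        sd = np.sqrt(expected * (1 - expected) / n)
        assert abs(rate - expected) < 3 * sd + 1e-4
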