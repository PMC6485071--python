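"""Balding-Nichols generator, clean-split pair coalescent, binned hazards."""

import numpy as np
import pytest

from diffscan.fst import pair_summaries, pairwise_fst
from diffscan.io import MISSING
from diffscan.synthetic import (
    BNConfig,
    SpikeConfig,
    SplitConfig,
    block_copy_variants,
    rates_from_times,
    simulate_genotypes,
    simulate_pair_coalescence,
)


class TestGenotypeSimulation:
    def test_determinism(self):
        cfg = BNConfig(3, 10, 500, F=0.1, missing_rate=0.1,
                       spike=SpikeConfig(5, "G2", 0.3), seed=7)
        a, ta = simulate_genotypes(cfg)
        b, tb = simulate_genotypes(cfg)
        assert np.array_equal(a.dosages, b.dosages)
        assert ta.equals(tb)

    def test_values_and_truth_table(self):
        cfg = BNConfig(2, 8, 300, F=0.1, missing_rate=0.2,
                       spike=SpikeConfig(12, "G1", 0.9), seed=1)
        gm, truth = simulate_genotypes(cfg)
        assert set(np.unique(gm.dosages)) <= {-1, 0, 1, 2}
        assert len(truth) == 12  # exactly n_spiked rows
        assert (truth["spiked_focal_freq"] <= 1.0).all()  # clamped
        assert (truth["spiked_focal_freq"] >= truth["base_focal_freq"]).all()
        assert truth["site_index"].is_unique

    def test_vanishing_f_removes_differentiation(self):
        # F -> 0: group frequencies collapse onto the ancestral frequency
        cfg = BNConfig(2, 500, 50, F=1e-6, seed=3,
                       ancestral_freq_range=(0.3, 0.7))
        gm, _ = simulate_genotypes(cfg)
        idx = gm.group_indices()
        f1 = gm.dosages[:, idx["G1"]].mean(axis=1) / 2
        f2 = gm.dosages[:, idx["G2"]].mean(axis=1) / 2
        # binomial sampling error with 1000 alleles: sd ~ 0.016
        assert np.abs(f1 - f2).max() < 0.08

    def test_missing_rate_applied(self):
        cfg = BNConfig(2, 50, 2000, F=0.1, missing_rate=0.15, seed=9)
        gm, _ = simulate_genotypes(cfg)
        frac = (gm.dosages == MISSING).mean()
        assert frac == pytest.approx(0.15, abs=0.01)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"F": 1.0},
            {"F": 0.0},
            {"missing_rate": 1.0},
            {"ancestral_freq_range": (0.0, 0.9)},
            {"spike": SpikeConfig(600, "G1", 0.4)},
        ],
    )
    def test_degenerate_configs_rejected(self, kwargs):
        base = dict(n_groups=2, samples_per_group=5, n_sites=500, seed=0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            BNConfig(**base)

    def test_mean_fst_increases_with_configured_f(self):
        means = []
        for F in (0.01, 0.05, 0.1, 0.2):
            cfg = BNConfig(2, 25, 20_000, F=F, seed=11)
            gm, _ = simulate_genotypes(cfg)
            summ = pair_summaries(pairwise_fst(gm))
            means.append(summ.loc[0, "mean_fst"])
        assert all(a < b for a, b in zip(means, means[1:]))


class TestPairCoalescence:
    def test_no_split_is_single_exponential(self):
        cfg = SplitConfig(T_split=0, N_deme=10_000, N_anc=10_000, n_pairs=50_000,
                          time_bins=[0, 1e5], seed=2)
        s = simulate_pair_coalescence(cfg)
        for arr in (s.within1, s.within2, s.cross):
            assert arr.mean() == pytest.approx(20_000, rel=0.02)

    def test_cross_mean_is_shifted_exponential(self):
        cfg = SplitConfig(T_split=5000, N_deme=2000, N_anc=8000, n_pairs=50_000,
                          time_bins=[0, 1e5], seed=4)
        s = simulate_pair_coalescence(cfg)
        assert s.cross.min() >= 5000  # no cross coalescence before the split
        assert s.cross.mean() == pytest.approx(5000 + 16_000, rel=0.02)

    def test_matches_msprime_split_model(self):
        """Independent coalescent oracle: msprime under the same demography."""
        import msprime

        T, N, Na = 3000, 10_000, 10_000
        demo = msprime.Demography()
        # haploid lineages (ploidy=1) coalesce at rate 1/size, so a diploid
        # deme of N corresponds to size 2N
        demo.add_population(name="d1", initial_size=2 * N)
        demo.add_population(name="d2", initial_size=2 * N)
        demo.add_population(name="anc", initial_size=2 * Na)
        demo.add_population_split(time=T, derived=["d1", "d2"], ancestral="anc")
        reps = msprime.sim_ancestry(
            samples={"d1": 1, "d2": 1}, demography=demo, ploidy=1,
            num_replicates=3000, random_seed=77,
        )
        ms_times = np.array([ts.first().time(ts.first().root) for ts in reps])

        cfg = SplitConfig(T_split=T, N_deme=N, N_anc=Na, n_pairs=50_000,
                          time_bins=[0, 1e6], seed=5)
        ours = simulate_pair_coalescence(cfg).cross
        # mean of T + Exp(2 Na): sd of the msprime mean ~ 2e4/sqrt(3000) ~ 365
        assert ours.mean() == pytest.approx(ms_times.mean(), abs=1500)


class TestRatesFromTimes:
    def test_single_bin_definition(self):
        times = np.array([1.0, 2.0, 3.0])
        h, counts, expo = rates_from_times(times, [0, 10])
        assert counts[0] == 3
        assert expo[0] == pytest.approx(6.0)  # each pair exposed until it coalesces
        assert h[0] == pytest.approx(0.5)

    def test_constant_size_flat_hazard(self):
        cfg = SplitConfig(T_split=0, N_deme=5000, N_anc=5000, n_pairs=200_000,
                          time_bins=[0, 1e5], seed=6)
        s = simulate_pair_coalescence(cfg)
        edges = np.array([0, 2000, 5000, 10_000, 20_000, 40_000])
        h, _, _ = rates_from_times(s.within1, edges)
        np.testing.assert_allclose(h, 1 / 10_000, rtol=0.05)

    def test_brute_force_recount(self, rng):
        times = rng.exponential(50, size=100)
        edges = np.array([0.0, 20.0, 60.0, 150.0, 400.0])
        h, counts, expo = rates_from_times(times, edges)
        for i, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
            c = sum(1 for t in times if a <= t < b)
            e = sum(max(0.0, min(t, b) - a) for t in times)
            assert counts[i] == c
            assert expo[i] == pytest.approx(e, rel=1e-9)
            if e > 0:
                assert h[i] == pytest.approx(c / e, rel=1e-9)

    def test_zero_exposure_flagged(self):
        h, _, expo = rates_from_times(np.array([1.0]), [0, 5, 10])
        assert expo[1] == 0 and np.isnan(h[1])

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            rates_from_times(np.array([]), [0, 1])


class TestBlockCopy:
    def test_perfect_copy_has_unit_r2(self, small_bn):
        from diffscan.ld import genotype_r2

        gm2 = block_copy_variants(small_bn, 10, n_copies=2, flip_prob=0.0, seed=1)
        assert gm2.n_sites == small_bn.n_sites + 2
        src_pos = small_bn.pos[10]
        i = int(np.flatnonzero(gm2.pos == src_pos)[0])
        j = int(np.flatnonzero(gm2.pos == src_pos + 100)[0])
        assert genotype_r2(gm2.dosages[i], gm2.dosages[j]) == pytest.approx(1.0)

    def test_flip_noise_degrades_r2(self, small_bn):
        from diffscan.ld import genotype_r2

        gm2 = block_copy_variants(small_bn, 10, n_copies=1, flip_prob=0.4, seed=1)
        src_pos = small_bn.pos[10]
        i = int(np.flatnonzero(gm2.pos == src_pos)[0])
        j = int(np.flatnonzero(gm2.pos == src_pos + 100)[0])
        r2 = genotype_r2(gm2.dosages[i], gm2.dosages[j])
        assert r2 < 0.9
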