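import numpy as np
import pytest
from scipy.integrate import quad

from hetexcess import (
    SfsModel,
    SimConfig,
    expected_pi_reduction,
    excess_with_bootstrap,
    generate_dataset,
    partition_blocks,
    read_vcf_table,
    sample_population_frequencies,
    sfs_density,
    site_pi,
    theoretical_delta,
)


class TestExpectedPiReduction:
    @pytest.mark.parametrize("gamma", [0.0, -0.3, -1.0, -2.0, -5.0, -10.0, -48.0, 2.0, 25.0])
    def test_closed_form_matches_adaptive_quadrature(self, gamma):
        num = quad(lambda q: 2 * q * (1 - q) * sfs_density(q, gamma), 0, 1, limit=200)[0]
        den = quad(lambda q: 2 * q * (1 - q) * sfs_density(q, 0.0), 0, 1, limit=200)[0]
        assert expected_pi_reduction(gamma) == pytest.approx(num / den, rel=1e-8)

    def test_neutral_limit_and_known_value(self):
        assert expected_pi_reduction(0.0) == 1.0
        # numerical integration of the stated integral gives ~0.200 at gamma=-10
        assert expected_pi_reduction(-10.0) == pytest.approx(0.200, abs=0.001)

    def test_strictly_decreasing_in_selection_strength(self):
        grid = -np.geomspace(0.01, 300, 60)
        vals = [expected_pi_reduction(g) for g in grid]
        assert all(a > b for a, b in zip(vals, vals[1:])) or all(
            a < b for a, b in zip(vals, vals[1:])
        )
        # deleterious direction: heavier selection, less diversity
        assert expected_pi_reduction(-5) < expected_pi_reduction(-1) < 1.0

    def test_extreme_gamma_stays_finite(self):
        assert 0 < expected_pi_reduction(-5000.0) < 0.001
        with pytest.raises(ValueError):
            expected_pi_reduction(float("nan"))


class TestTheoreticalDelta:
    def test_no_selection_or_equal_sizes_give_zero(self):
        assert theoretical_delta(60_000, 10_000, 0.0) == 0.0
        with pytest.raises(ValueError):
            theoretical_delta(10_000, 10_000, 1e-5)

    def test_composition_of_reduction_oracle(self):
        s = 10.0 / (4.0 * 60_000)  # gamma_L = -10, gamma_S = -2 at ratio 5
        d = theoretical_delta(60_000, 12_000, s)
        expected = 1.0 - expected_pi_reduction(-10.0) / expected_pi_reduction(-2.0)
        assert d == pytest.approx(expected, rel=1e-12)

    def test_increases_with_ne_contrast(self):
        s = 5.0 / (4.0 * 60_000)
        d_big = theoretical_delta(60_000, 10_000, s)  # ratio 6
        d_small = theoretical_delta(60_000, 25_000, s)  # ratio 2.4
        assert d_big > d_small > 0


class TestFrequencySampler:
    def test_same_seed_identical_draws(self):
        model = SfsModel(gamma=-3.0, theta_site=0.01, ne=5000)
        a = sample_population_frequencies(model, 1e5, np.random.default_rng(42))
        b = sample_population_frequencies(model, 1e5, np.random.default_rng(42))
        assert np.array_equal(a, b)

    def test_neutral_site_count_matches_poisson_mean(self):
        from hetexcess.synthetic_data import sfs_mass

        model = SfsModel(gamma=0.0, theta_site=0.01, ne=5000)
        lam = model.theta_site * 2e5 * sfs_mass(0.0, 5000)
        k = len(sample_population_frequencies(model, 2e5, np.random.default_rng(7)))
        assert abs(k - lam) < 3 * np.sqrt(lam)

    def test_strong_selection_shifts_frequencies_down(self):
        rng = np.random.default_rng(3)
        neutral = sample_population_frequencies(
            SfsModel(gamma=0.0, theta_site=0.01, ne=5000), 3e5, rng
        )
        selected = sample_population_frequencies(
            SfsModel(gamma=-50.0, theta_site=0.01, ne=5000), 3e5, rng
        )
        se = np.sqrt(
            neutral.var() / len(neutral) + selected.var() / len(selected)
        )
        assert selected.mean() < neutral.mean() - 3 * se

    def test_sample_pi_ratio_tracks_reduction_oracle(self):
        """pi at selected sites over pi at neutral sites ~ r(gamma)."""
        rng = np.random.default_rng(17)
        theta, ne, n = 0.02, 10_000, 20
        L_sel, L_neu = 1e5, 3e5
        neutral = sample_population_frequencies(
            SfsModel(0.0, theta, ne), L_neu, rng
        )
        j = rng.binomial(n, neutral)
        pi_neu = site_pi(j, np.full(len(j), n)).sum() / L_neu
        for gamma in (-1.0, -5.0):
            freqs = sample_population_frequencies(
                SfsModel(gamma, theta, ne), L_sel, rng
            )
            j = rng.binomial(n, freqs)
            pi_sel = site_pi(j, np.full(len(j), n)).sum() / L_sel
            assert pi_sel / pi_neu == pytest.approx(
                expected_pi_reduction(gamma), rel=0.1
            )


def _wf_mean_pi(ne, s, mu, L, gens, burn, seed):
    """Slow forward Wright-Fisher oracle: infinite sites, genic selection."""
    rng = np.random.default_rng(seed)
    N = 2 * ne
    counts = np.empty(0, dtype=np.int64)
    total, kept = 0.0, 0
    for g in range(burn + gens):
        q = counts / N
        q_sel = q * (1 - s) / (1 - q * s)
        counts = rng.binomial(N, q_sel)
        k = rng.poisson(N * mu * L)
        counts = np.concatenate(
            [counts[(counts > 0) & (counts < N)], np.ones(k, dtype=np.int64)]
        )
        if g >= burn:
            q = counts / N
            total += (2 * q * (1 - q)).sum() / L
            kept += 1
    return total / kept


class TestForwardWrightFisherCrossCheck:
    def test_diffusion_sfs_matches_forward_simulation_at_tiny_ne(self):
        """Independent route: a forward WF simulation at Ne=200 reproduces the
        equilibrium diversities the diffusion SFS predicts."""
        ne, mu, L = 200, 2.5e-5, 3000
        theta = 4 * ne * mu
        pi_neutral = _wf_mean_pi(ne, 0.0, mu, L, gens=6000, burn=3000, seed=1)
        assert pi_neutral == pytest.approx(theta, rel=0.10)
        s = 5e-3  # gamma = -4
        pi_sel = _wf_mean_pi(ne, s, mu, L, gens=6000, burn=3000, seed=2)
        expected = theta * expected_pi_reduction(-4.0 * ne * s)
        assert pi_sel == pytest.approx(expected, rel=0.10)


class TestGenerateDataset:
    def test_truth_bookkeeping_matches_config(self, tiny_sim_config):
        ds = generate_dataset(tiny_sim_config)
        cfg = tiny_sim_config
        assert ds.truth["theoretical_delta"] == pytest.approx(
            theoretical_delta(cfg.ne_large, cfg.ne_small, cfg.s), rel=1e-12
        )
        assert ds.truth["theta"]["large"] == pytest.approx(4 * cfg.ne_large * cfg.mu)

    def test_neutral_truth_recovers_zero_delta(self):
        cfg = SimConfig(
            s=0.0,
            n_chrom=4,
            genes_per_chrom=5,
            gene_spacing=100_000,
            intergenic_length=10_000,
            intron_length=5_000,
            seed=21,
        )
        ds = generate_dataset(cfg)
        blocks = partition_blocks(ds.variants, ds.class_map)
        est = excess_with_bootstrap(blocks, "large", "small", B=300, seed=21)
        assert abs(est.delta) < 3 * est.se_delta

    def test_sample_pi_matches_theta_per_class(self, tiny_sim_config):
        from hetexcess import class_pi

        ds = generate_dataset(tiny_sim_config)
        for pop in ("large", "small"):
            theta = tiny_sim_config.theta(pop)
            est = class_pi(
                ds.variants, "intron", ds.class_map.totals["intron"], pop
            )
            assert est.pi == pytest.approx(theta, rel=0.25)
            nonsyn = class_pi(
                ds.variants, "nonsynonymous", ds.class_map.totals["nonsynonymous"], pop
            )
            assert nonsyn.pi < est.pi  # purifying selection lowers diversity

    def test_infinite_sites_regime_enforced(self):
        with pytest.raises(ValueError, match="infinite-sites"):
            SimConfig(mu=1e-5)

    def test_written_files_round_trip(self, tiny_sim_config, tmp_path):
        ds = generate_dataset(tiny_sim_config)
        paths = ds.write(str(tmp_path))
        back = read_vcf_table(paths["vcf"], ds.populations)
        assert len(back) == len(ds.variants)
        for col in ("pos", "j_large", "n_large", "j_small", "n_small"):
            assert (
                back[col].to_numpy() == ds.variants[col].to_numpy()
            ).all()
        import json

        truth = json.load(open(paths["truth"]))
        assert truth["theoretical_delta"] == pytest.approx(
            ds.truth["theoretical_delta"]
        )

    def test_same_seed_reproduces_dataset(self, tiny_sim_config):
        a = generate_dataset(tiny_sim_config)
        b = generate_dataset(tiny_sim_config)
        assert a.variants.equals(b.variants)
        assert a.genes["expression"].equals(b.genes["expression"])
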