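import numpy as np
import pytest

from hybridzone import (
    SimulationConfig,
    em_allele_frequencies,
    simulate_ancient_hybrid,
    simulate_contemporary_zone,
    simulate_gbs_likelihoods,
    simulate_parental_frequencies,
    simulate_study,
    simulate_topology_windows,
)
from hybridzone.synthetic import TruthSet

from conftest import one_pop_map


class TestParentalFrequencies:
    def test_no_divergence_limit(self):
        cfg = SimulationConfig(
            parental_divergence=5e-4, n_loci_per_chromosome=500,
            n_chromosomes=20, seed=1,
        )
        _, truth = simulate_parental_frequencies(cfg)
        assert np.mean(np.abs(truth.p0 - truth.p1)) < 0.02

    def test_high_divergence_matches_mixture_oracle(self):
        """Monte-Carlo oracle of the Balding-Nichols mixture at F = 0.9:
        pi ~ U(0.05, 0.95), p ~ Beta(pi*s, (1-pi)*s) with s = (1-F)/F,
        independently per parent. The generator's AIM fraction must match
        the oracle's within Monte-Carlo error."""
        rng = np.random.default_rng(1234)
        n_mc = 200_000
        s = (1 - 0.9) / 0.9
        pi = rng.uniform(0.05, 0.95, size=n_mc)
        pa = rng.beta(np.maximum(pi * s, 1e-3), np.maximum((1 - pi) * s, 1e-3))
        pb = rng.beta(np.maximum(pi * s, 1e-3), np.maximum((1 - pi) * s, 1e-3))
        oracle = np.mean(np.abs(pa - pb) >= 0.3)

        cfg = SimulationConfig(
            parental_divergence=0.9, n_loci_per_chromosome=500,
            n_chromosomes=20, seed=2,
        )
        _, truth = simulate_parental_frequencies(cfg)
        frac = np.mean(np.abs(truth.p0 - truth.p1) >= 0.3)
        se = np.sqrt(oracle * (1 - oracle) / 10_000)
        assert abs(frac - oracle) < 4 * se

    def test_aim_fraction_monotone_in_divergence(self):
        fracs = []
        for f in (0.05, 0.3, 0.7):
            cfg = SimulationConfig(
                parental_divergence=f, n_loci_per_chromosome=400,
                n_chromosomes=10, seed=3,
            )
            _, truth = simulate_parental_frequencies(cfg)
            fracs.append(np.mean(np.abs(truth.p0 - truth.p1) >= 0.3))
        assert fracs[0] < fracs[1] < fracs[2]

    def test_identical_seeds_identical_tables(self):
        for _ in range(2):
            cfg = SimulationConfig(seed=9)
            _, truth = simulate_parental_frequencies(cfg)
        _, truth2 = simulate_parental_frequencies(SimulationConfig(seed=9))
        np.testing.assert_array_equal(truth.p0, truth2.p0)
        np.testing.assert_array_equal(truth.p1, truth2.p1)


class TestAncientHybrid:
    def _diagnostic_truth(self, cfg):
        _, truth = simulate_parental_frequencies(cfg)
        truth.p0 = np.zeros(len(truth.loci))
        truth.p1 = np.ones(len(truth.loci))
        return truth

    def test_pure_parent1_profile(self):
        cfg = SimulationConfig(
            n_loci_per_chromosome=50, n_chromosomes=2, n_individuals=10, seed=4
        )
        truth = self._diagnostic_truth(cfg)
        q = np.ones(len(truth.loci))
        g, truth = simulate_ancient_hybrid(cfg, truth, q_profile=q)
        assert (g == 2).all()

    def test_mean_ancestry_run_length_matches_block_length(self):
        """Completed runs of constant ancestry within a haplotype should
        average the configured block length (geometric run-length oracle)."""
        cfg = SimulationConfig(
            n_loci_per_chromosome=1000, n_chromosomes=1, n_individuals=30,
            block_length=50, seed=5,
        )
        truth = self._diagnostic_truth(cfg)
        _, truth = simulate_ancient_hybrid(
            cfg, truth, q_profile=np.full(1000, 0.5)
        )
        anc = truth.ancestry_haplotypes["ancient"]  # (L, n, 2)
        runs = []
        for j in range(anc.shape[1]):
            for c in range(2):
                chain = anc[:, j, c]
                change = np.flatnonzero(np.diff(chain) != 0)
                lengths = np.diff(np.concatenate([[-1], change, [len(chain) - 1]]))
                if len(lengths) > 2:
                    runs.extend(lengths[1:-1])  # completed runs only
        runs = np.asarray(runs, dtype=float)
        se = runs.std(ddof=1) / np.sqrt(len(runs))
        assert abs(runs.mean() - 50.0) < 3 * se + 1.0

    def test_realized_ancestry_tracks_target_profile(self):
        cfg = SimulationConfig(
            n_loci_per_chromosome=400, n_chromosomes=1, n_individuals=60,
            block_length=10, seed=6,
        )
        truth = self._diagnostic_truth(cfg)
        target = 0.7
        g, truth = simulate_ancient_hybrid(
            cfg, truth, q_profile=np.full(400, target)
        )
        q_hat = g.mean(axis=1) / 2.0  # diagnostic loci: allele == ancestry
        se = np.sqrt(target * (1 - target) / (2 * 60))
        frac_within = np.mean(np.abs(q_hat - target) <= 3 * se)
        assert frac_within >= 0.9


class TestContemporaryZone:
    def _setup(self, seed, n_loci=300, n_ind=80, **kw):
        cfg = SimulationConfig(
            n_loci_per_chromosome=n_loci, n_chromosomes=1,
            n_individuals=n_ind, seed=seed, **kw,
        )
        _, truth = simulate_parental_frequencies(cfg)
        truth.p0 = np.zeros(n_loci)
        truth.p1 = np.ones(n_loci)
        return cfg, truth

    def test_neutral_clines_track_hybrid_index(self):
        cfg, truth = self._setup(seed=7)
        n_loci = 300
        g, truth = simulate_contemporary_zone(
            cfg, truth, alpha=np.zeros(n_loci), beta=np.zeros(n_loci)
        )
        realized = g.mean(axis=0) / 2.0
        se = np.sqrt(np.maximum(truth.h["zone"] * (1 - truth.h["zone"]), 1e-4) / (2 * n_loci))
        assert np.mean(np.abs(realized - truth.h["zone"]) <= 4 * se + 0.01) >= 0.9

    def test_u_shaped_hybrid_index_distribution(self):
        cfg, truth = self._setup(seed=8, n_ind=400)
        _, truth = simulate_contemporary_zone(
            cfg, truth, alpha=np.zeros(300), beta=np.zeros(300)
        )
        h = truth.h["zone"]
        # Beta(0.5, 0.5): heavy tails, mean 1/2, variance 1/8
        assert np.mean((h < 0.1) | (h > 0.9)) > np.mean((h > 0.4) & (h < 0.6))
        assert h.mean() == pytest.approx(0.5, abs=3 * np.sqrt(0.125 / 400))

    def test_positive_beta_steepens_transition(self):
        """Slope of realized ancestry on h near h = 0.5 approaches the
        analytic cline slope 1 + beta."""
        cfg, truth = self._setup(seed=9, n_ind=600)
        beta = np.full(300, 2.0)
        g, truth = simulate_contemporary_zone(
            cfg, truth, alpha=np.zeros(300), beta=beta
        )
        h = truth.h["zone"]
        realized = g.mean(axis=0) / 2.0
        mid = (h > 0.3) & (h < 0.7)
        assert mid.sum() > 30
        slope = np.polyfit(h[mid], realized[mid], 1)[0]
        assert slope > 1.5


class TestGbsLikelihoods:
    def test_infinite_depth_degenerates_to_truth(self, tiny_sim_config):
        rng = np.random.default_rng(0)
        g = np.array([[0, 1, 2]])
        loci = SimulationConfig(
            n_loci_per_chromosome=1, n_chromosomes=1
        ).locus_map()
        gl = simulate_gbs_likelihoods(g, loci, ["a", "b", "c"], 2000.0, 0.0, rng)
        assert gl.gl[0].argmax(axis=1).tolist() == [0, 1, 2]
        assert gl.gl[0, 0, 0] > 0.999

    def test_near_zero_depth_is_mostly_missing(self):
        rng = np.random.default_rng(1)
        g = np.ones((200, 20), dtype=int)
        loci = SimulationConfig(
            n_loci_per_chromosome=200, n_chromosomes=1
        ).locus_map()
        gl = simulate_gbs_likelihoods(g, loci, [f"i{k}" for k in range(20)], 0.01, 0.01, rng)
        assert gl.is_missing().mean() >= 0.985

    def test_em_recovers_parental_frequencies_from_gbs(self):
        """Parameter-recovery oracle: EM at depth 8, n = 50 should sit within
        RMSE 0.03 of the generating frequencies for AIM-like loci."""
        cfg = SimulationConfig(
            n_loci_per_chromosome=300, n_chromosomes=1, n_individuals=50,
            parental_divergence=0.8, seed=10,
        )
        _, truth = simulate_parental_frequencies(cfg)
        rng = cfg.rng("test_gbs")
        g = rng.binomial(2, truth.p0[:, None], size=(300, 50))
        gl = simulate_gbs_likelihoods(
            g, truth.loci, [f"i{k}" for k in range(50)], 8.0, 0.005, rng
        )
        freqs = em_allele_frequencies(gl, one_pop_map(gl.individuals))
        rmse = np.sqrt(np.mean((freqs.freq["pop1"] - truth.p0) ** 2))
        assert rmse < 0.03


class TestTopologyWindows:
    def test_zero_switch_probability_one_label_per_chromosome(self):
        cfg = SimulationConfig(
            topology_switch_prob=0.0, n_chromosomes=6,
            n_windows_per_chromosome=5, window_snps=30, seed=11,
        )
        _, windows, truth = simulate_topology_windows(cfg)
        for chrom in windows["chromosome"].unique():
            sel = (windows["chromosome"] == chrom).to_numpy()
            assert len(set(truth.topology_labels[sel])) == 1

    def test_zero_noise_gives_perfect_recovery(self):
        from hybridzone import assign_window_topologies

        cfg = SimulationConfig(
            topology_noise=0.0, n_chromosomes=5, n_windows_per_chromosome=6,
            window_snps=40, seed=12,
        )
        mats, windows, truth = simulate_topology_windows(cfg)
        table = assign_window_topologies(mats, windows)
        assert (table.labels == truth.topology_labels).all()

    def test_label_autocorrelation_exceeds_frequency_baseline(self):
        cfg = SimulationConfig(
            topology_switch_prob=0.2, n_chromosomes=40,
            n_windows_per_chromosome=12, window_snps=5, seed=13,
        )
        _, windows, truth = simulate_topology_windows(cfg)
        labels = truth.topology_labels
        same = []
        for chrom in windows["chromosome"].unique():
            lab = labels[(windows["chromosome"] == chrom).to_numpy()]
            same.extend(lab[1:] == lab[:-1])
        lag1 = np.mean(same)
        baseline = np.sum(
            (np.bincount(labels) / len(labels)) ** 2
        )  # chance agreement from label frequencies
        assert lag1 > baseline + 0.1


def test_study_generation_is_deterministic_and_bounded():
    cfg = SimulationConfig(
        n_loci_per_chromosome=20, n_chromosomes=3, n_individuals=8,
        window_snps=20, n_windows_per_chromosome=2, seed=14,
    )
    a = simulate_study(cfg)
    b = simulate_study(cfg)
    np.testing.assert_array_equal(a.gl.gl, b.gl.gl)
    np.testing.assert_array_equal(a.truth.topology_labels, b.truth.topology_labels)
    assert ((a.truth.p0 >= 0) & (a.truth.p0 <= 1)).all()
    for pop_q in a.truth.q.values():
        assert ((pop_q >= 0) & (pop_q <= 1)).all()
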