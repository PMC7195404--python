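import numpy as np
import pandas as pd
import pytest

from hybridzone import (
    SimulationConfig,
    TOPOLOGIES,
    assign_window_topologies,
    fd_statistic,
    fd_window_set_test,
    infer_window_topology,
    read_newick_topology,
    simulate_topology_windows,
    split_windows,
    topology_class_test,
    topology_newick,
    topology_size_correlation,
)
from hybridzone.core_io import LocusMap
from hybridzone.enrichment import proportion_size_correlation
from hybridzone.phylo import (
    WindowTopologyTable,
    _path_matrix,
    topology_id_from_cherries,
)

TAXA = ["A", "B", "C", "D", "E"]


def _loci(counts: dict[str, int]) -> LocusMap:
    rows = []
    for chrom, n in counts.items():
        for k in range(n):
            rows.append(
                {
                    "locus_id": f"{chrom}_{k}",
                    "chromosome": chrom,
                    "position": (k + 1) * 10,
                    "is_Z": chrom == "Z",
                }
            )
    return LocusMap(pd.DataFrame(rows))


class TestEnumeration:
    def test_exactly_fifteen_unrooted_trees(self):
        assert len(TOPOLOGIES) == 15
        assert len({tuple(t) for t in TOPOLOGIES}) == 15

    def test_newick_round_trip_for_every_id(self):
        for tid in range(1, 16):
            nwk = topology_newick(tid, TAXA)
            assert read_newick_topology(nwk, TAXA) == tid

    def test_rooted_newick_resolves_to_same_unrooted_id(self):
        # ((A,B),(C,D),E) rooted on the E branch
        assert read_newick_topology("(((A,B),(C,D)),E);", TAXA) == (
            topology_id_from_cherries((0, 1), (2, 3))
        )


class TestSplitWindows:
    def test_remainder_dropped(self):
        loci = _loci({"chr1": 2500})
        win = split_windows(loci, 1000)
        assert len(win) == 2
        assert list(win["stop"] - win["start"]) == [1000, 1000]

    def test_exact_fit_single_window(self):
        win = split_windows(_loci({"chr1": 1000}), 1000)
        assert len(win) == 1

    def test_windows_never_span_chromosomes(self):
        loci = _loci({"chr1": 1500, "chr2": 1200})
        win = split_windows(loci, 1000)
        assert len(win) == 2
        for _, row in win.iterrows():
            chroms = loci.table["chromosome"].iloc[row["start"] : row["stop"]]
            assert chroms.nunique() == 1

    def test_short_chromosome_yields_no_windows(self):
        win = split_windows(_loci({"chr1": 50, "chr2": 300}), 100)
        assert set(win["chromosome"]) == {"chr2"}


def _synapomorphy_matrix(cherry1, cherry2, n_per=20):
    sites = []
    for cherry in (cherry1, cherry2):
        for _ in range(n_per):
            row = np.zeros(5)
            row[list(cherry)] = 1.0
            sites.append(row)
    return np.asarray(sites)


class TestInferTopology:
    def test_clean_synapomorphies_recovered_with_minimal_length(self):
        mat = _synapomorphy_matrix((0, 1), (2, 3))
        tid, score, tie = infer_window_topology(mat, method="parsimony")
        assert tid == topology_id_from_cherries((0, 1), (2, 3))
        assert score == mat.shape[0]  # one change per site, no excess
        assert not tie

    def test_me_ls_exact_fit_on_additive_distances(self):
        """Singleton + cherry sites make the hamming distances exactly
        additive on the generating tree, so its least-squares fit has RSS 0."""
        sites = []
        for taxon, count in enumerate([3, 5, 2, 4, 6]):  # terminal branches
            for _ in range(count):
                row = np.zeros(5)
                row[taxon] = 1.0
                sites.append(row)
        mat = np.vstack([np.asarray(sites), _synapomorphy_matrix((0, 2), (1, 4), 8)])
        tid, score, tie = infer_window_topology(mat, method="me_ls")
        assert tid == topology_id_from_cherries((0, 2), (1, 4))
        assert score == pytest.approx(0.0, abs=1e-18)

    def test_invariant_window_is_flagged_uninformative_tie(self):
        tid, score, tie = infer_window_topology(np.zeros((50, 5)))
        assert tie
        assert tid == 1  # tie broken by lowest canonical id
        assert score == 0

    def test_heterozygous_calls_enter_as_ambiguity(self):
        # a 0.5 call is compatible with either allele: no extra length
        mat = _synapomorphy_matrix((0, 1), (2, 3), 10)
        mat[::3, 4] = 0.5
        tid, score, _ = infer_window_topology(mat)
        assert tid == topology_id_from_cherries((0, 1), (2, 3))
        assert score == mat.shape[0]

    def test_recovery_under_conflicting_sites(self):
        cfg = SimulationConfig(
            n_chromosomes=5,
            n_windows_per_chromosome=10,
            window_snps=120,
            topology_noise=0.10,
            topology_labels=(1, 8, 15),
            topology_weights=(0.4, 0.4, 0.2),
            seed=77,
        )
        mats, windows, truth = simulate_topology_windows(cfg)
        table = assign_window_topologies(mats, windows)
        agree = (table.labels == truth.topology_labels).mean()
        assert agree >= 0.9

    def test_path_matrix_rank_supports_identifiable_fit(self):
        a = _path_matrix(TOPOLOGIES[0])
        assert a.shape == (10, 7)
        assert np.linalg.matrix_rank(a) == 7


class TestClassTests:
    def _table(self, labels, chroms=None):
        n = len(labels)
        return WindowTopologyTable(
            pd.DataFrame(
                {
                    "window_id": range(n),
                    "chromosome": chroms if chroms is not None else ["chr1"] * n,
                    "start": np.arange(n) * 10,
                    "stop": (np.arange(n) + 1) * 10,
                    "topology_id": labels,
                    "score": 0.0,
                    "tie": False,
                }
            )
        )

    def test_whole_genome_class_has_xfold_one(self):
        rng = np.random.default_rng(41)
        table = self._table(rng.integers(1, 4, size=80))
        res = topology_class_test(table, 1, np.ones(80, dtype=bool), n_perm=400, seed=1)
        assert res.x_fold == pytest.approx(1.0, abs=1e-12)

    def test_planted_excess_detected(self):
        labels = np.ones(100, dtype=int)
        labels[:70] = 2
        class_mask = np.zeros(100, dtype=bool)
        class_mask[70:] = True  # the class holds every topology-1 window
        res = topology_class_test(table=self._table(labels), target_topology=1,
                                  class_mask=class_mask, n_perm=1_000, seed=2)
        assert res.x_fold > 2
        assert res.p_one_sided <= 0.005

    def test_planted_deficit_mirrored_tail(self):
        labels = np.ones(100, dtype=int)
        labels[:30] = 2
        class_mask = np.zeros(100, dtype=bool)
        class_mask[:30] = True  # class contains only topology-2 windows
        res = topology_class_test(
            self._table(labels), 1, class_mask, n_perm=1_000, seed=3,
            direction="deficit",
        )
        assert res.x_fold < 0.5
        assert res.p_one_sided <= 0.005

    def test_absent_topology_is_an_error(self):
        table = self._table(np.ones(10, dtype=int))
        with pytest.raises(ValueError, match="absent"):
            topology_class_test(table, 9, np.ones(10, dtype=bool))


class TestFd:
    def test_complete_sharing_limit_is_one(self):
        n = 20
        res = fd_statistic(
            np.zeros(n), np.full(n, 0.5), np.full(n, 0.5), np.zeros(n)
        )
        assert res.fd == pytest.approx(1.0)

    def test_no_shared_derived_alleles_is_zero(self):
        n = 20
        res = fd_statistic(np.zeros(n), np.zeros(n), np.full(n, 0.6), np.zeros(n))
        assert res.fd == pytest.approx(0.0)

    def test_four_site_hand_table(self):
        p1 = np.array([0.0, 0.2, 0.1, 0.0])
        p2 = np.array([0.5, 0.8, 0.3, 0.9])
        p3 = np.array([0.6, 0.9, 0.4, 0.8])
        po = np.array([0.0, 0.1, 0.0, 0.2])
        num = den = 0.0
        for k in range(4):  # brute-force per-site evaluation
            abba = (1 - p1[k]) * p2[k] * p3[k] * (1 - po[k])
            baba = p1[k] * (1 - p2[k]) * p3[k] * (1 - po[k])
            num += abba - baba
            pd_ = max(p2[k], p3[k])
            den += (1 - p1[k]) * pd_ * pd_ * (1 - po[k]) - p1[k] * (1 - pd_) * pd_ * (
                1 - po[k]
            )
        res = fd_statistic(p1, p2, p3, po)
        assert res.fd == pytest.approx(num / den, abs=1e-12)

    def test_zero_denominator_flagged(self):
        n = 5
        res = fd_statistic(np.zeros(n), np.zeros(n), np.zeros(n), np.zeros(n))
        assert res.undefined and np.isnan(res.fd)

    def test_missing_sites_skipped(self):
        p1 = np.array([0.0, np.nan, 0.0])
        res = fd_statistic(p1, np.full(3, 0.5), np.full(3, 0.5), np.zeros(3))
        assert res.n_sites == 2


class TestFdWindowSet:
    def test_full_set_equals_null_mean(self):
        rng = np.random.default_rng(51)
        fd = rng.uniform(0.1, 0.5, size=40)
        res = fd_window_set_test(fd, np.ones(40, dtype=bool), n_draws=300, seed=4)
        assert res.observed == pytest.approx(res.null_mean, abs=1e-12)
        assert 0.2 < res.p_one_sided

    def test_planted_low_fd_candidates_significant(self):
        rng = np.random.default_rng(52)
        fd = rng.normal(0.3, 0.02, size=120)
        mask = np.zeros(120, dtype=bool)
        mask[:15] = True
        fd[:15] = 0.0
        res = fd_window_set_test(fd, mask, n_draws=1_000, seed=5)
        assert res.p_one_sided <= 0.005

    def test_undefined_windows_excluded_from_pool(self):
        fd = np.array([0.1, 0.2, np.nan, 0.3, 0.4, 0.5])
        mask = np.array([True, True, False, False, False, False])
        res = fd_window_set_test(fd, mask, n_draws=200, seed=6)
        assert res.observed == pytest.approx(0.15)


def test_topology_size_correlation_delegates():
    props = [0.1, 0.4, 0.2, 0.6, 0.3]
    sizes = [10, 40, 25, 55, 30]
    assert topology_size_correlation(props, sizes) == proportion_size_correlation(
        props, sizes
    )
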