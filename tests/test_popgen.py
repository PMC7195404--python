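import numpy as np
import pandas as pd
import pytest

from hybridzone import (
    build_ibd_table,
    designate_aims,
    fit_ibd_model,
    fst_pair,
    haversine_km,
    polarized_ld,
)
from hybridzone.allele_freq import AlleleFrequencyTable

from conftest import gl_matrix_from_genotypes, one_pop_map


def _freq_table(loci, **pops):
    return AlleleFrequencyTable(loci, {k: np.asarray(v, float) for k, v in pops.items()})


class TestFst:
    def _loci_table(self, n):
        return gl_matrix_from_genotypes(np.zeros((n, 2), dtype=int)).loci

    def test_fixed_differences_give_one(self):
        loci = self._loci_table(5)
        freqs = _freq_table(loci, a=np.zeros(5), b=np.ones(5))
        assert fst_pair(freqs, "a", "b").fst == pytest.approx(1.0)

    def test_identical_frequencies_give_zero(self):
        loci = self._loci_table(5)
        p = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        freqs = _freq_table(loci, a=p, b=p)
        assert fst_pair(freqs, "a", "b").fst == pytest.approx(0.0)

    def test_two_locus_hand_computation(self):
        """Locus 1 with p = (0.2, 0.8), locus 2 with p = (0.5, 0.5):
        H_S = (0.32, 0.5), H_T = (0.5, 0.5), so
        F_ST = mean(H_T - H_S) / mean(H_T) = 0.09 / 0.5 = 0.18."""
        loci = self._loci_table(2)
        freqs = _freq_table(loci, a=[0.2, 0.5], b=[0.8, 0.5])
        res = fst_pair(freqs, "a", "b")
        assert res.fst == pytest.approx(0.18, abs=1e-12)

    def test_allele_label_swap_invariance(self):
        loci = self._loci_table(4)
        pa = np.array([0.1, 0.4, 0.6, 0.9])
        pb = np.array([0.3, 0.2, 0.8, 0.5])
        f1 = fst_pair(_freq_table(loci, a=pa, b=pb), "a", "b").fst
        f2 = fst_pair(_freq_table(loci, a=1 - pa, b=1 - pb), "a", "b").fst
        assert f1 == pytest.approx(f2, abs=1e-12)

    def test_monomorphic_pair_flagged_undefined(self):
        loci = self._loci_table(3)
        freqs = _freq_table(loci, a=np.zeros(3), b=np.zeros(3))
        assert fst_pair(freqs, "a", "b").undefined


class TestPolarizedLd:
    def _mixture_gl(self, rng, n_each=30, n_loci=24):
        """Half pure parent-0, half pure parent-1 individuals."""
        g0 = rng.binomial(2, 0.05, size=(n_loci, n_each))
        g1 = rng.binomial(2, 0.95, size=(n_loci, n_each))
        return gl_matrix_from_genotypes(np.concatenate([g0, g1], axis=1))

    def test_admixture_mixture_shows_positive_coupling_ld(self):
        rng = np.random.default_rng(17)
        gl = self._mixture_gl(rng)
        pop = one_pop_map(gl.individuals)
        freqs = _freq_table(
            gl.loci, p0=np.full(24, 0.05), p1=np.full(24, 0.95)
        )
        aims = designate_aims(freqs, ["p0"], ["p1"], 0.3)
        ld = polarized_ld(gl, pop, aims, "pop1", parental_freqs=freqs)
        assert ld.mean_r > 0.5

    def test_single_panmictic_population_near_zero(self):
        rng = np.random.default_rng(18)
        gl = gl_matrix_from_genotypes(rng.binomial(2, 0.5, size=(24, 60)))
        pop = one_pop_map(gl.individuals)
        freqs = _freq_table(gl.loci, p0=np.full(24, 0.1), p1=np.full(24, 0.9))
        aims = designate_aims(freqs, ["p0"], ["p1"], 0.3)
        ld = polarized_ld(gl, pop, aims, "pop1", parental_freqs=freqs)
        assert abs(ld.mean_r) < 0.05

    def test_flipping_one_locus_polarization_negates_its_r(self):
        rng = np.random.default_rng(19)
        gl = self._mixture_gl(rng)
        pop = one_pop_map(gl.individuals)
        p0 = np.full(24, 0.05)
        p1 = np.full(24, 0.95)
        freqs = _freq_table(gl.loci, p0=p0, p1=p1)
        aims = designate_aims(freqs, ["p0"], ["p1"], 0.3)
        ld = polarized_ld(gl, pop, aims, "pop1", parental_freqs=freqs)
        p0f, p1f = p0.copy(), p1.copy()
        p0f[3], p1f[3] = 0.95, 0.05  # reverse which parent carries the allele
        freqs_f = _freq_table(gl.loci, p0=p0f, p1=p1f)
        aims_f = designate_aims(freqs_f, ["p0"], ["p1"], 0.3)
        ld_f = polarized_ld(gl, pop, aims_f, "pop1", parental_freqs=freqs_f)
        off_diag = np.arange(24) != 3
        np.testing.assert_allclose(
            ld_f.r[3, off_diag], -ld.r[3, off_diag], atol=1e-10
        )

    def test_small_population_requires_override(self):
        rng = np.random.default_rng(20)
        gl = gl_matrix_from_genotypes(rng.binomial(2, 0.5, size=(10, 5)))
        pop = one_pop_map(gl.individuals)
        freqs = _freq_table(gl.loci, p0=np.zeros(10), p1=np.ones(10))
        aims = designate_aims(freqs, ["p0"], ["p1"], 0.3)
        with pytest.raises(ValueError, match="20 required"):
            polarized_ld(gl, pop, aims, "pop1", parental_freqs=freqs)

    def test_matrix_symmetry_and_bounds(self):
        rng = np.random.default_rng(21)
        gl = self._mixture_gl(rng, n_each=20, n_loci=12)
        pop = one_pop_map(gl.individuals)
        freqs = _freq_table(gl.loci, p0=np.full(12, 0.05), p1=np.full(12, 0.95))
        aims = designate_aims(freqs, ["p0"], ["p1"], 0.3)
        r = polarized_ld(gl, pop, aims, "pop1", parental_freqs=freqs).r
        np.testing.assert_allclose(r, r.T, atol=1e-12)
        finite = np.isfinite(r)
        assert (np.abs(r[finite]) <= 1 + 1e-9).all()


def test_haversine_equator_degree():
    # one degree of longitude on the equator is ~111.19 km
    assert haversine_km(0, 0, 0, 1) == pytest.approx(111.19, abs=0.5)


def _simulate_ibd(rng, n_pops=10, b0=-2.0, b1=0.5, b2=1.0, sd_u=0.3, sd_e=0.2):
    rows = []
    u = rng.normal(0, sd_u, size=n_pops)
    coords = rng.uniform([40, -115], [46, -105], size=(n_pops, 2))
    taxon = (np.arange(n_pops) % 2).astype(int)
    for i in range(n_pops):
        for j in range(i + 1, n_pops):
            dist = haversine_km(*coords[i], *coords[j])
            x1 = np.log(max(dist, 1e-3))
            x2 = int(taxon[i] != taxon[j])
            y = b0 + b1 * x1 + b2 * x2 + u[i] + u[j] + rng.normal(0, sd_e)
            rows.append(
                {
                    "pop_i": f"p{i}",
                    "pop_j": f"p{j}",
                    "logit_fst": y,
                    "log_distance": x1,
                    "taxon_distance": x2,
                }
            )
    return pd.DataFrame(rows)


FAST_IBD = dict(n_chains=2, n_iter=1_500, burn_in=500, thin=5)


class TestIbdModel:
    def test_coefficient_recovery_coverage(self):
        """95% CIs should cover the generating coefficients in most replicate
        fits of data simulated from the model itself."""
        rng = np.random.default_rng(23)
        covered = total = 0
        for rep in range(10):
            table = _simulate_ibd(rng)
            fit = fit_ibd_model(table, seed=rep, models=("full",), **FAST_IBD)["full"]
            coef = fit.coefficients.set_index("term")
            for term, truth in (("log_distance", 0.5), ("taxon_distance", 1.0)):
                total += 1
                covered += int(
                    coef.at[term, "ci_low"] <= truth <= coef.at[term, "ci_high"]
                )
        assert covered / total >= 0.8

    def test_dic_prefers_generating_model_structure(self):
        """With no taxon effect in the truth, the geography-only model should
        beat the taxon-only model by DIC in most replicates."""
        rng = np.random.default_rng(29)
        wins = 0
        n_rep = 6
        for rep in range(n_rep):
            table = _simulate_ibd(rng, b2=0.0)
            fits = fit_ibd_model(
                table, seed=100 + rep, models=("geo_only", "taxon_only"), **FAST_IBD
            )
            wins += int(fits["geo_only"].dic < fits["taxon_only"].dic)
        assert wins > n_rep / 2

    def test_degenerate_constant_response_rejected(self):
        table = _simulate_ibd(np.random.default_rng(31))
        table["logit_fst"] = 1.0
        with pytest.raises(ValueError, match="identifiable"):
            fit_ibd_model(table, **FAST_IBD)

    def test_too_few_populations_rejected(self):
        table = _simulate_ibd(np.random.default_rng(33), n_pops=3)
        with pytest.raises(ValueError, match=">= 4 populations"):
            fit_ibd_model(table, **FAST_IBD)


def test_build_ibd_table_distances_and_taxon():
    from hybridzone.popgen import FstResult

    coords = pd.DataFrame(
        {
            "population": ["a", "b"],
            "lat": [0.0, 0.0],
            "lon": [0.0, 1.0],
            "taxon": ["t1", "t2"],
        }
    )
    res = FstResult("a", "b", 10, 0.4, 0.3, 0.25)
    table = build_ibd_table([res], coords)
    assert table["taxon_distance"].iloc[0] == 1
    assert table["log_distance"].iloc[0] == pytest.approx(np.log(111.19), abs=0.01)
    assert table["logit_fst"].iloc[0] == pytest.approx(np.log(0.25 / 0.75))
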