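"""Polarized linkage disequilibrium, F_ST, and isolation-by-distance.

LD here is the Pearson correlation between genotypes at pairs of
ancestry-informative markers, with alleles polarized so that positive
correlations mean coupling associations (alleles from the same parental
taxon travel together, the signature of ongoing admixture) and negative
correlations mean repulsion associations.

F_ST for a population pair is the ratio of averages

    F_ST = mean_l(H_T - H_S) / mean_l(H_T)

with H_S the mean within-population expected heterozygosity and H_T the
expected heterozygosity at the mean allele frequency.

The isolation-by-distance model regresses logit(F_ST) for every population
pair on log great-circle distance and a same/different-taxon indicator,
with a random effect per population entering every pair it belongs to --
the Clarke-style mixed model for correlated pairwise observations. It is
fit by Gibbs sampling with conjugate updates, and candidate models (full,
geography-only, taxon-only) are compared by DIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .allele_freq import AimSet, AlleleFrequencyTable, em_allele_frequencies
from .core_io import GenotypeLikelihoodMatrix, PopulationMap

__all__ = [
    "LdMatrix",
    "FstResult",
    "IbdModelFit",
    "polarized_ld",
    "fst_pair",
    "haversine_km",
    "build_ibd_table",
    "fit_ibd_model",
]

MIN_LD_INDIVIDUALS = 20  # inclusion rule for per-population LD


@dataclass
class LdMatrix:
    population: str
    locus_ids: np.ndarray
    r: np.ndarray  # (L, L), nan where undefined

    @property
    def mean_r(self) -> float:
        iu = np.triu_indices(self.r.shape[0], k=1)
        vals = self.r[iu]
        return float(np.nanmean(vals))


@dataclass
class FstResult:
    population_a: str
    population_b: str
    n_loci: int
    sum_ht: float
    sum_hs: float
    fst: float
    undefined: bool = False

    @property
    def logit_fst(self) -> float:
        clipped = min(max(self.fst, 1e-6), 1 - 1e-6)
        return float(np.log(clipped / (1 - clipped)))


def polarized_ld(
    gl: GenotypeLikelihoodMatrix,
    pop: PopulationMap,
    aims: AimSet,
    population: str,
    parental_freqs: AlleleFrequencyTable | None = None,
    min_individuals: int = MIN_LD_INDIVIDUALS,
    allow_small: bool = False,
) -> LdMatrix:
    """Pairwise polarized Pearson LD among AIMs within one population.

    Genotypes are posterior-mean allele counts from the GL triples under a
    Hardy-Weinberg prior at the population's own EM frequency; missing
    (flat) triples are excluded pairwise. Each AIM is recoded so the counted
    allele is the one more common in parent 1, so admixture LD shows up as
    positive r.
    """
    members = [i for i in pop.individuals(population=population) if i in gl.individuals]
    if len(members) < min_individuals and not allow_small:
        raise ValueError(
            f"population {population!r} has {len(members)} individuals; "
            f"{min_individuals} required (set allow_small=True to override)"
        )
    sub = gl.subset_individuals(members).subset_loci(aims.member_mask)
    own = em_allele_frequencies(sub, pop, populations=[population])
    p_own = own.freq[population]

    hw = np.stack([(1 - p_own) ** 2, 2 * p_own * (1 - p_own), p_own**2], axis=1)
    post = sub.gl * hw[:, None, :]
    post /= post.sum(axis=2, keepdims=True)
    dosage = (post * np.arange(3)).sum(axis=2)  # (L, n)

    if parental_freqs is None:
        raise ValueError("parental_freqs required to polarize alleles")
    p0 = parental_freqs.mean_over(aims.parent0_populations)[aims.member_mask]
    p1 = parental_freqs.mean_over(aims.parent1_populations)[aims.member_mask]
    flip = (p1 - p0) < 0
    dosage[flip] = 2.0 - dosage[flip]

    dosage = dosage.T  # (n, L)
    missing = sub.is_missing().T
    dosage = np.where(missing, np.nan, dosage)
    r = _pairwise_complete_corr(dosage)
    return LdMatrix(population, aims.member_ids, r)


def _pairwise_complete_corr(x: np.ndarray) -> np.ndarray:
    """Pearson correlation with pairwise deletion of missing (nan) entries."""
    m = ~np.isnan(x)
    x0 = np.where(m, x, 0.0)
    mf = m.astype(float)
    n = mf.T @ mf
    sx = x0.T @ mf
    sy = sx.T
    sxy = x0.T @ x0
    sxx = (x0**2).T @ mf
    syy = sxx.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        var_x = n * sxx - sx**2
        var_y = n * syy - sy**2
        r = cov / np.sqrt(var_x * var_y)
    r[(n < 2) | ~np.isfinite(r)] = np.nan
    return r


def fst_pair(
    freqs: AlleleFrequencyTable,
    population_a: str,
    population_b: str,
    locus_mask: np.ndarray | None = None,
    ht_method: str = "mean_freq",
) -> FstResult:
    """F_ST between two populations as a ratio of heterozygosity averages.

    ``ht_method='mean_freq'`` (default) computes H_T at the unweighted mean
    of the two frequencies; ``'weighted'`` weights by effective sample
    sizes when available.
    """
    pa = freqs.freq[population_a]
    pb = freqs.freq[population_b]
    if locus_mask is not None:
        pa, pb = pa[locus_mask], pb[locus_mask]
    if ht_method == "mean_freq":
        pbar = (pa + pb) / 2.0
    elif ht_method == "weighted":
        na = freqs.n_effective[population_a]
        nb = freqs.n_effective[population_b]
        if locus_mask is not None:
            na, nb = na[locus_mask], nb[locus_mask]
        w = np.maximum(na + nb, 1)
        pbar = (na * pa + nb * pb) / w
    else:
        raise ValueError(f"unknown ht_method {ht_method!r}")
    hs = (2 * pa * (1 - pa) + 2 * pb * (1 - pb)) / 2.0
    ht = 2 * pbar * (1 - pbar)
    sum_ht = float(ht.mean())
    sum_hs = float(hs.mean())
    if sum_ht == 0:
        return FstResult(
            population_a, population_b, len(pa), 0.0, 0.0, np.nan, undefined=True
        )
    return FstResult(
        population_a,
        population_b,
        len(pa),
        sum_ht,
        sum_hs,
        (sum_ht - sum_hs) / sum_ht,
    )


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km between decimal-degree coordinates."""
    r_earth = 6371.0088
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2) ** 2
    return float(2 * r_earth * np.arcsin(np.sqrt(a)))


def build_ibd_table(
    fst_results: list[FstResult],
    coordinates: pd.DataFrame,
) -> pd.DataFrame:
    """Pairwise regression table from F_ST results and a coordinates table.

    ``coordinates`` needs columns population, lat, lon, taxon. Output has
    one row per pair: logit F_ST, log km distance, taxon distance (0 same /
    1 different), and the two population ids.
    """
    coords = coordinates.set_index("population")
    rows = []
    for res in fst_results:
        a, b = res.population_a, res.population_b
        dist = haversine_km(
            coords.at[a, "lat"], coords.at[a, "lon"],
            coords.at[b, "lat"], coords.at[b, "lon"],
        )
        rows.append(
            {
                "pop_i": a,
                "pop_j": b,
                "logit_fst": res.logit_fst,
                "log_distance": np.log(max(dist, 1e-3)),
                "taxon_distance": int(
                    coords.at[a, "taxon"] != coords.at[b, "taxon"]
                ),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class IbdModelFit:
    model: str  # full | geo_only | taxon_only
    coefficients: pd.DataFrame  # mean/sd/CI per fixed effect
    sd_population: float
    sd_residual: float
    dic: float
    mean_deviance: float
    p_d: float
    rhat: dict[str, float] = field(default_factory=dict)
    flagged_nonmixing: bool = False


_MODEL_COVARIATES = {
    "full": ["log_distance", "taxon_distance"],
    "geo_only": ["log_distance"],
    "taxon_only": ["taxon_distance"],
}


def fit_ibd_model(
    table: pd.DataFrame,
    n_chains: int = 3,
    n_iter: int = 10_000,
    burn_in: int = 2_000,
    thin: int = 5,
    seed: int = 0,
    models: tuple[str, ...] = ("full", "geo_only", "taxon_only"),
) -> dict[str, IbdModelFit]:
    """Fit the pairwise mixed models by Gibbs sampling; compare by DIC.

    y_ij = b0 + b1 log_distance + b2 taxon + u_i + u_j + e_ij, with
    Normal(0, tau=0.001) priors on coefficients and Gamma(1, 0.01) priors on
    the population-effect and residual precisions. DIC = mean deviance +
    p_D with p_D = mean deviance - deviance at the posterior means.
    """
    pops = sorted(set(table["pop_i"]) | set(table["pop_j"]))
    if len(pops) < 4:
        raise ValueError("need >= 4 populations for the pairwise mixed model")
    y = table["logit_fst"].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("response has zero variance: model not identifiable")
    pop_index = {p: k for k, p in enumerate(pops)}
    z = np.zeros((len(table), len(pops)))
    for row_k, (i, j) in enumerate(zip(table["pop_i"], table["pop_j"])):
        z[row_k, pop_index[i]] = 1.0
        z[row_k, pop_index[j]] = 1.0

    fits: dict[str, IbdModelFit] = {}
    for model in models:
        covs = _MODEL_COVARIATES[model]
        x = np.column_stack(
            [np.ones(len(table))] + [table[c].to_numpy(dtype=float) for c in covs]
        )
        fits[model] = _gibbs_ibd(
            y, x, z, ["intercept"] + covs, model,
            n_chains, n_iter, burn_in, thin, seed,
        )
    return fits


def _gibbs_ibd(
    y, x, z, names, model, n_chains, n_iter, burn_in, thin, seed
) -> IbdModelFit:
    n, p = x.shape
    n_pop = z.shape[1]
    prior_prec_b = 0.001
    gamma_shape, gamma_rate = 1.0, 0.01
    xtx = x.T @ x
    ztz = z.T @ z

    b_draws, u_draws, te_draws, tu_draws, dev_draws = [], [], [], [], []
    chain_sizes = []
    for chain in range(n_chains):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 15_485_863, chain]))
        b = np.zeros(p)
        u = np.zeros(n_pop)
        tau_e, tau_u = 1.0, 1.0
        kept = 0
        for it in range(n_iter):
            # fixed effects
            prec = tau_e * xtx + prior_prec_b * np.eye(p)
            mean = np.linalg.solve(prec, tau_e * x.T @ (y - z @ u))
            b = mean + np.linalg.solve(
                np.linalg.cholesky(prec).T, rng.standard_normal(p)
            )
            # population random effects (joint draw)
            prec_u = tau_e * ztz + tau_u * np.eye(n_pop)
            mean_u = np.linalg.solve(prec_u, tau_e * z.T @ (y - x @ b))
            u = mean_u + np.linalg.solve(
                np.linalg.cholesky(prec_u).T, rng.standard_normal(n_pop)
            )
            # precisions
            resid = y - x @ b - z @ u
            tau_e = rng.gamma(
                gamma_shape + n / 2.0, 1.0 / (gamma_rate + 0.5 * resid @ resid)
            )
            tau_u = rng.gamma(
                gamma_shape + n_pop / 2.0, 1.0 / (gamma_rate + 0.5 * u @ u)
            )
            if it >= burn_in and (it - burn_in) % thin == 0:
                b_draws.append(b.copy())
                u_draws.append(u.copy())
                te_draws.append(tau_e)
                tu_draws.append(tau_u)
                dev_draws.append(_deviance(y, x @ b + z @ u, tau_e))
                kept += 1
        chain_sizes.append(kept)

    b_arr = np.asarray(b_draws)
    u_arr = np.asarray(u_draws)
    te_arr = np.asarray(te_draws)
    tu_arr = np.asarray(tu_draws)
    dev_arr = np.asarray(dev_draws)

    mean_dev = float(dev_arr.mean())
    dev_at_means = _deviance(
        y, x @ b_arr.mean(axis=0) + z @ u_arr.mean(axis=0), float(te_arr.mean())
    )
    p_d = mean_dev - dev_at_means
    dic = mean_dev + p_d

    coef = pd.DataFrame(
        {
            "term": names,
            "mean": b_arr.mean(axis=0),
            "sd": b_arr.std(axis=0, ddof=1),
            "ci_low": np.quantile(b_arr, 0.025, axis=0),
            "ci_high": np.quantile(b_arr, 0.975, axis=0),
        }
    )
    rhat = {
        name: _scalar_rhat(b_arr[:, k], n_chains) for k, name in enumerate(names)
    }
    return IbdModelFit(
        model=model,
        coefficients=coef,
        sd_population=float(1.0 / np.sqrt(tu_arr.mean())),
        sd_residual=float(1.0 / np.sqrt(te_arr.mean())),
        dic=float(dic),
        mean_deviance=mean_dev,
        p_d=float(p_d),
        rhat=rhat,
        flagged_nonmixing=any(v > 1.1 for v in rhat.values()),
    )


def _deviance(y: np.ndarray, mu: np.ndarray, tau_e: float) -> float:
    n = len(y)
    return float(
        -2.0
        * (
            0.5 * n * (np.log(tau_e) - np.log(2 * np.pi))
            - 0.5 * tau_e * np.sum((y - mu) ** 2)
        )
    )


def _scalar_rhat(draws: np.ndarray, n_chains: int) -> float:
    per = len(draws) // n_chains
    half = per // 2
    if half < 2:
        return float("nan")
    segs = []
    for c in range(n_chains):
        chain = draws[c * per : (c + 1) * per]
        segs.append(chain[:half])
        segs.append(chain[half : 2 * half])
    arr = np.asarray(segs)
    w = arr.var(axis=1, ddof=1).mean()
    b = half * arr.mean(axis=1).var(ddof=1)
    var_hat = (half - 1) / half * w + b / half
    return float(np.sqrt(var_hat / max(w, 1e-300)))
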