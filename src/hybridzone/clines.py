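"""Hybrid-index estimation and Bayesian genomic clines.

A genomic cline describes, for one locus, the probability that an allele
copy carried by a hybrid derives from parental taxon 1 as a function of the
individual's genome-wide hybrid index h. The cline function used here is

    phi(h; alpha, beta) = h + 2 h (1 - h) (alpha + beta (2h - 1)),

truncated to [0, 1]. alpha shifts the cline center (positive alpha raises
the probability of parent-1 ancestry at every intermediate h); beta changes
the rate of transition along the admixture gradient (positive beta steepens
the cline). phi(0) = 0 and phi(1) = 1 for any parameter values: pure
parentals are never reassigned.

Estimation is two-stage: hybrid indexes are first estimated per individual
by bounded maximum likelihood, then per-locus (alpha, beta) are sampled by
a Metropolis-within-Gibbs MCMC with independent normal priors, holding h
fixed. Loci are conditionally independent given h, so the sampler is
vectorized across loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .allele_freq import AimSet, AlleleFrequencyTable
from .core_io import GenotypeLikelihoodMatrix

__all__ = [
    "ClineMcmcConfig",
    "HybridIndexEstimate",
    "ClineParameterEstimate",
    "cline_function",
    "estimate_hybrid_index",
    "fit_genomic_clines",
    "classify_credible",
]


def cline_function(
    h: float | np.ndarray, alpha: float | np.ndarray, beta: float | np.ndarray
) -> float | np.ndarray:
    """Probability of parent-1 ancestry for an allele copy at hybrid index h."""
    h_arr = np.asarray(h, dtype=float)
    if np.any((h_arr < 0) | (h_arr > 1)):
        raise ValueError("hybrid index outside [0, 1]")
    phi = h_arr + 2.0 * h_arr * (1.0 - h_arr) * (
        np.asarray(alpha) + np.asarray(beta) * (2.0 * h_arr - 1.0)
    )
    phi = np.clip(phi, 0.0, 1.0)
    return float(phi) if np.isscalar(h) and phi.ndim == 0 else phi


@dataclass
class HybridIndexEstimate:
    individuals: list[str]
    h: np.ndarray
    loglik: np.ndarray
    uninformative: np.ndarray  # all-missing individuals, pinned at h = 0.5

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual_id": self.individuals,
                "h_hat": self.h,
                "loglik": self.loglik,
                "uninformative": self.uninformative,
            }
        )


@dataclass
class ClineMcmcConfig:
    """Sampler settings for the genomic-cline MCMC."""

    n_chains: int = 5
    n_iter: int = 25_000
    burn_in: int = 5_000
    thin: int = 5
    prior_sd_alpha: float = 1.0
    prior_sd_beta: float = 1.0
    proposal_scale: float = 0.3
    adapt_during_burnin: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_chains, self.n_iter, self.thin) < 1 or self.burn_in < 0:
            raise ValueError("MCMC settings must be positive")
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")


@dataclass
class ClineParameterEstimate:
    """Posterior summaries of (alpha, beta) per AIM with credible-deviation flags."""

    locus_ids: np.ndarray
    summary: pd.DataFrame  # per locus: mean/median/CI for alpha and beta
    rhat: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def directional_parent1(self) -> np.ndarray:
        return (self.summary["alpha_ci_low"] > 0).to_numpy()

    @property
    def directional_parent0(self) -> np.ndarray:
        return (self.summary["alpha_ci_high"] < 0).to_numpy()

    @property
    def restricted(self) -> np.ndarray:
        return (self.summary["beta_ci_low"] > 0).to_numpy()


def estimate_hybrid_index(
    gl_hybrids: GenotypeLikelihoodMatrix,
    parental_freqs: AlleleFrequencyTable,
    aims: AimSet,
    tol: float = 1e-6,
) -> HybridIndexEstimate:
    """Maximum-likelihood hybrid index per individual.

    At hybrid index h the counted-allele probability at locus l is
    pi_l = h p1_l + (1-h) p0_l and the genotype is Binomial(2, pi_l),
    observed through the genotype-likelihood triple. Each individual's h is
    found by bounded scalar optimization on [0, 1].
    """
    if aims.n_members < 10:
        import warnings

        warnings.warn(
            f"only {aims.n_members} AIMs; hybrid indexes will be noisy",
            stacklevel=2,
        )
    mask = aims.member_mask
    p0 = parental_freqs.mean_over(aims.parent0_populations)[mask]
    p1 = parental_freqs.mean_over(aims.parent1_populations)[mask]
    gl = gl_hybrids.gl[mask]  # (L, n, 3)
    missing_all = gl_hybrids.is_missing()[mask].all(axis=0)

    h_out = np.empty(gl.shape[1])
    ll_out = np.empty(gl.shape[1])
    for j in range(gl.shape[1]):
        if missing_all[j]:
            h_out[j] = 0.5
            ll_out[j] = _h_loglik(0.5, gl[:, j, :], p0, p1)
            continue
        res = minimize_scalar(
            lambda h: -_h_loglik(h, gl[:, j, :], p0, p1),
            bounds=(0.0, 1.0),
            method="bounded",
            options={"xatol": tol},
        )
        h_out[j] = res.x
        ll_out[j] = -res.fun
    return HybridIndexEstimate(
        list(gl_hybrids.individuals), h_out, ll_out, missing_all
    )


def _h_loglik(h: float, gl: np.ndarray, p0: np.ndarray, p1: np.ndarray) -> float:
    pi = h * p1 + (1.0 - h) * p0
    geno = np.stack([(1 - pi) ** 2, 2 * pi * (1 - pi), pi**2], axis=1)
    return float(np.log((gl * geno).sum(axis=1)).sum())


def fit_genomic_clines(
    gl_hybrids: GenotypeLikelihoodMatrix,
    hybrid_index: HybridIndexEstimate,
    parental_freqs: AlleleFrequencyTable,
    aims: AimSet,
    cfg: ClineMcmcConfig | None = None,
) -> ClineParameterEstimate:
    """Sample per-AIM (alpha, beta) by Metropolis-within-Gibbs MCMC.

    Likelihood: each allele copy of hybrid i at AIM l is parent-1-derived
    with probability phi(h_i; alpha_l, beta_l); given origin the counted
    allele occurs with the parental frequency, so the counted-allele
    probability is a_il = phi p1_l + (1 - phi) p0_l and the genotype is
    Binomial(2, a_il) observed through the GL triple. Priors are independent
    Normal(0, prior_sd) on alpha and beta. alpha and beta are updated in
    alternating random-walk Metropolis steps, vectorized over loci; chains
    are pooled after burn-in and thinning. Split-R-hat is reported per locus
    and poorly mixing loci (R-hat > 1.1) are flagged, never dropped.
    """
    cfg = cfg or ClineMcmcConfig()
    mask = aims.member_mask
    p0 = parental_freqs.mean_over(aims.parent0_populations)[mask]
    p1 = parental_freqs.mean_over(aims.parent1_populations)[mask]
    gl = gl_hybrids.gl[mask]  # (L, n, 3)
    h = np.asarray(hybrid_index.h, dtype=float)
    if len(np.unique(np.round(h, 12))) < 2:
        raise ValueError("need at least two hybrids with distinct hybrid indexes")
    # canonical polarity: with parent roles swapped (p0 <-> p1, h -> 1 - h)
    # the likelihood depends on alpha only through its sign, so running in a
    # fixed orientation and negating alpha afterwards makes the label-swap
    # symmetry exact under the same seed
    mirrored = float(p1.sum()) < float(p0.sum())
    if mirrored:
        p0, p1 = p1, p0
        h = 1.0 - h
    L, n, _ = gl.shape

    keep = [
        s
        for chain in range(cfg.n_chains)
        for s in _run_chain(gl, h, p0, p1, cfg, chain_id=chain)
    ]
    alpha_draws = np.stack([s[0] for s in keep])  # (n_kept_total, L)
    beta_draws = np.stack([s[1] for s in keep])
    if mirrored:
        alpha_draws = -alpha_draws

    n_kept_per_chain = len(keep) // cfg.n_chains
    rhat_alpha = _split_rhat(alpha_draws, cfg.n_chains, n_kept_per_chain)
    rhat_beta = _split_rhat(beta_draws, cfg.n_chains, n_kept_per_chain)

    summary = pd.DataFrame(
        {
            "locus_id": aims.member_ids,
            "alpha_mean": alpha_draws.mean(axis=0),
            "alpha_median": np.median(alpha_draws, axis=0),
            "alpha_ci_low": np.quantile(alpha_draws, 0.025, axis=0),
            "alpha_ci_high": np.quantile(alpha_draws, 0.975, axis=0),
            "beta_mean": beta_draws.mean(axis=0),
            "beta_median": np.median(beta_draws, axis=0),
            "beta_ci_low": np.quantile(beta_draws, 0.025, axis=0),
            "beta_ci_high": np.quantile(beta_draws, 0.975, axis=0),
        }
    )
    rhat = pd.DataFrame(
        {
            "locus_id": aims.member_ids,
            "rhat_alpha": rhat_alpha,
            "rhat_beta": rhat_beta,
            "flagged_nonmixing": (rhat_alpha > 1.1) | (rhat_beta > 1.1),
        }
    )
    return ClineParameterEstimate(aims.member_ids, summary, rhat)


def _cline_loglik(
    alpha: np.ndarray,
    beta: np.ndarray,
    gl: np.ndarray,
    h: np.ndarray,
    p0: np.ndarray,
    p1: np.ndarray,
) -> np.ndarray:
    """Log-likelihood per locus. alpha/beta: (L,); gl: (L, n, 3); h: (n,)."""
    hh = h[None, :]
    phi = hh + 2.0 * hh * (1.0 - hh) * (
        alpha[:, None] + beta[:, None] * (2.0 * hh - 1.0)
    )
    phi = np.clip(phi, 0.0, 1.0)
    a = phi * p1[:, None] + (1.0 - phi) * p0[:, None]  # (L, n)
    lik = (
        gl[:, :, 0] * (1 - a) ** 2
        + gl[:, :, 1] * 2 * a * (1 - a)
        + gl[:, :, 2] * a**2
    )
    return np.log(np.maximum(lik, 1e-300)).sum(axis=1)


def _run_chain(gl, h, p0, p1, cfg: ClineMcmcConfig, chain_id: int):
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 7_919, chain_id])
    )
    L = gl.shape[0]
    alpha = rng.normal(0.0, 0.1, size=L)
    beta = rng.normal(0.0, 0.1, size=L)
    scale_a = np.full(L, cfg.proposal_scale)
    scale_b = np.full(L, cfg.proposal_scale)
    ll = _cline_loglik(alpha, beta, gl, h, p0, p1)
    lp = _normal_lp(alpha, cfg.prior_sd_alpha) + _normal_lp(beta, cfg.prior_sd_beta)
    kept = []
    acc_a = np.zeros(L)
    acc_b = np.zeros(L)
    adapt_window = 200
    for it in range(cfg.n_iter):
        # alpha step
        prop = alpha + rng.normal(0.0, scale_a, size=L)
        ll_p = _cline_loglik(prop, beta, gl, h, p0, p1)
        lp_p = _normal_lp(prop, cfg.prior_sd_alpha) + _normal_lp(
            beta, cfg.prior_sd_beta
        )
        accept = np.log(rng.random(L)) < (ll_p + lp_p) - (ll + lp)
        alpha = np.where(accept, prop, alpha)
        ll = np.where(accept, ll_p, ll)
        lp = np.where(accept, lp_p, lp)
        acc_a += accept
        # beta step
        prop = beta + rng.normal(0.0, scale_b, size=L)
        ll_p = _cline_loglik(alpha, prop, gl, h, p0, p1)
        lp_p = _normal_lp(alpha, cfg.prior_sd_alpha) + _normal_lp(
            prop, cfg.prior_sd_beta
        )
        accept = np.log(rng.random(L)) < (ll_p + lp_p) - (ll + lp)
        beta = np.where(accept, prop, beta)
        ll = np.where(accept, ll_p, ll)
        lp = np.where(accept, lp_p, lp)
        acc_b += accept

        if (
            cfg.adapt_during_burnin
            and it < cfg.burn_in
            and (it + 1) % adapt_window == 0
        ):
            # steer acceptance into the 20-40% band during burn-in only
            rate_a = acc_a / adapt_window
            rate_b = acc_b / adapt_window
            scale_a *= np.where(rate_a < 0.20, 0.7, np.where(rate_a > 0.40, 1.4, 1.0))
            scale_b *= np.where(rate_b < 0.20, 0.7, np.where(rate_b > 0.40, 1.4, 1.0))
            acc_a[:] = 0.0
            acc_b[:] = 0.0
        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            kept.append((alpha.copy(), beta.copy()))
    return kept


def _normal_lp(x: np.ndarray, sd: float) -> np.ndarray:
    return -0.5 * (x / sd) ** 2


def _split_rhat(draws: np.ndarray, n_chains: int, n_per_chain: int) -> np.ndarray:
    """Split-R-hat per locus from pooled draws of shape (chains*kept, L)."""
    L = draws.shape[1]
    half = n_per_chain // 2
    if half < 2:
        return np.full(L, np.nan)
    segments = []
    for c in range(n_chains):
        chain = draws[c * n_per_chain : (c + 1) * n_per_chain]
        segments.append(chain[:half])
        segments.append(chain[half : 2 * half])
    arr = np.stack(segments)  # (2*chains, half, L)
    m, n_ = arr.shape[0], arr.shape[1]
    means = arr.mean(axis=1)
    variances = arr.var(axis=1, ddof=1)
    w = variances.mean(axis=0)
    b = n_ * means.var(axis=0, ddof=1)
    var_hat = (n_ - 1) / n_ * w + b / n_
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.sqrt(var_hat / np.maximum(w, 1e-300))


def classify_credible(est: ClineParameterEstimate) -> pd.DataFrame:
    """Credible-deviation classes from the 95% equal-tail intervals.

    directional_parent1: CI(alpha) entirely above 0; directional_parent0:
    entirely below 0; restricted: CI(beta) entirely above 0.
    """
    table = pd.DataFrame(
        {
            "locus_id": est.locus_ids,
            "directional_parent1": est.directional_parent1,
            "directional_parent0": est.directional_parent0,
            "restricted": est.restricted,
        }
    )
    table.attrs["counts"] = {
        "directional_parent1": int(est.directional_parent1.sum()),
        "directional_parent0": int(est.directional_parent0.sum()),
        "restricted": int(est.restricted.sum()),
        "n_loci": len(est.locus_ids),
    }
    return table
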