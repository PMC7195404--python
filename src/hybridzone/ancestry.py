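"""Locus-specific ancestry frequencies in old hybrid populations.

The model targets populations where genome stabilization is under way:
individuals share similar genome-wide admixture proportions but the
frequency q_l of parent-1-derived allele copies varies along the genome,
with strong autocorrelation between neighboring loci.

Data model, per allele copy c of individual i at AIM l:

    z_ilc ~ Bernoulli(q_l)                        (latent parental origin)
    allele | z = 1 ~ Bernoulli(p1_l),  z = 0 ~ Bernoulli(p0_l)
    genotype observed through the GL triple.

Prior: q_l ~ Beta(nu * mu_l, nu * (1 - mu_l)) where mu_l is the mean of the
current q over a w-locus window centered on l (truncated at chromosome
ends). This window-mean beta prior is a conjugate realization of a
correlated beta process: it shares information between neighbors like a
hidden Markov model would while letting q drift along the chromosome.
Gibbs sampling alternates the latent origin counts z | q (exact,
marginalizing genotypes over the GL triples) and q | z (beta update with
mu_l held fixed within the sweep).

Females are hemizygous on the Z chromosome and contribute a single allele
copy there when sex is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .allele_freq import AimSet, AlleleFrequencyTable
from .core_io import GenotypeLikelihoodMatrix, PopulationMap, Sex

__all__ = [
    "AncestryModelConfig",
    "AncestryFrequencyTrack",
    "fit_ancestry_frequencies",
    "summarize_fixation",
]


@dataclass
class AncestryModelConfig:
    window: int = 3  # loci; odd
    nu: float = 10.0  # beta-prior precision of the smoothing window
    n_iter: int = 10_000
    burn_in: int = 5_000
    thin: int = 10
    seed: int = 0
    male_only: bool = False

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 1")
        if self.nu <= 0:
            raise ValueError("nu must be positive")
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")


@dataclass
class AncestryFrequencyTrack:
    """Posterior ancestry frequencies per population and AIM locus."""

    aims: AimSet
    q_mean: dict[str, np.ndarray] = field(default_factory=dict)
    q_sd: dict[str, np.ndarray] = field(default_factory=dict)
    mean_copies: dict[str, np.ndarray] = field(default_factory=dict)
    unidentifiable: np.ndarray | None = None

    def populations(self) -> list[str]:
        return list(self.q_mean)

    def mean_track(self) -> np.ndarray:
        """Posterior mean q averaged across populations (per AIM)."""
        return np.mean([self.q_mean[p] for p in self.q_mean], axis=0)

    def to_frame(self) -> pd.DataFrame:
        ids = self.aims.member_ids
        frames = []
        for pop in self.q_mean:
            frames.append(
                pd.DataFrame(
                    {
                        "population": pop,
                        "locus_id": ids,
                        "q_hat": self.q_mean[pop],
                        "q_sd": self.q_sd[pop],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def fit_ancestry_frequencies(
    gl_hybrids: GenotypeLikelihoodMatrix,
    parental_freqs: AlleleFrequencyTable,
    aims: AimSet,
    pop: PopulationMap,
    populations: list[str] | None = None,
    cfg: AncestryModelConfig | None = None,
) -> AncestryFrequencyTrack:
    """Fit the correlated beta-process ancestry model per hybrid population."""
    cfg = cfg or AncestryModelConfig()
    if populations is None:
        populations = pop.populations(role="hybrid")
    mask = aims.member_mask
    p0 = parental_freqs.mean_over(aims.parent0_populations)[mask]
    p1 = parental_freqs.mean_over(aims.parent1_populations)[mask]
    # canonical polarity: run the sampler with the higher-total-frequency
    # pool as parent 1 and mirror q afterwards, so that swapping the parent
    # roles maps q_hat -> 1 - q_hat exactly under the same seed
    mirrored = float(p1.sum()) < float(p0.sum())
    if mirrored:
        p0, p1 = p1, p0
    unident = np.isclose(p0, p1)
    aim_loci = aims.member_locus_map()
    is_z = aim_loci.is_Z
    chrom_slices = list(aim_loci.chromosome_slices().values())

    ind_index = {ind: j for j, ind in enumerate(gl_hybrids.individuals)}
    sex_of = dict(zip(pop.table["individual_id"], pop.table["sex"]))
    track = AncestryFrequencyTrack(aims=aims, unidentifiable=unident)
    for k, population in enumerate(populations):
        members = pop.individuals(
            population=population,
            sex=Sex.MALE if cfg.male_only else None,
        )
        members = [m for m in members if m in ind_index]
        if len(members) < 2:
            raise ValueError(
                f"population {population!r}: need >= 2 individuals with data"
            )
        cols = [ind_index[m] for m in members]
        gl = gl_hybrids.gl[mask][:, cols, :]  # (L, n, 3)
        female = np.array([sex_of.get(m) == Sex.FEMALE.value for m in members])
        # ploidy per (locus, individual): 1 for females on the Z
        ploidy = np.where(is_z[:, None] & female[None, :], 1, 2)
        q_mean, q_sd, z_mean = _gibbs_population(
            gl, p0, p1, ploidy, chrom_slices, cfg, stream=k
        )
        if mirrored:
            q_mean = 1.0 - q_mean
            z_mean = 1.0 - z_mean
        track.q_mean[population] = q_mean
        track.q_sd[population] = q_sd
        track.mean_copies[population] = z_mean
    return track


def _origin_likelihoods(p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    """M[l, k, g] = P(genotype g | k parent-1 copies of 2) per locus."""
    L = p0.shape[0]
    M = np.empty((L, 3, 3))
    for k in range(3):
        pa = [p0, p0] if k == 0 else ([p0, p1] if k == 1 else [p1, p1])
        M[:, k, 0] = (1 - pa[0]) * (1 - pa[1])
        M[:, k, 1] = pa[0] * (1 - pa[1]) + (1 - pa[0]) * pa[1]
        M[:, k, 2] = pa[0] * pa[1]
    return M


def _origin_likelihoods_haploid(p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    """M1[l, k, g] for a single copy; the copy's allele shows as g in {0, 2}."""
    L = p0.shape[0]
    M = np.zeros((L, 2, 3))
    M[:, 0, 0] = 1 - p0
    M[:, 0, 2] = p0
    M[:, 1, 0] = 1 - p1
    M[:, 1, 2] = p1
    return M


def _window_mean(q: np.ndarray, chrom_slices: list[slice], w: int) -> np.ndarray:
    """Mean of q over the w-locus window centered at each locus, per chromosome."""
    mu = np.empty_like(q)
    kernel = np.ones(w)
    for sl in chrom_slices:
        seg = q[sl]
        if w == 1 or len(seg) == 1:
            mu[sl] = seg
            continue
        sums = np.convolve(seg, kernel, mode="same")
        counts = np.convolve(np.ones_like(seg), kernel, mode="same")
        mu[sl] = sums / counts
    return mu


def _gibbs_population(
    gl: np.ndarray,
    p0: np.ndarray,
    p1: np.ndarray,
    ploidy: np.ndarray,
    chrom_slices: list[slice],
    cfg: AncestryModelConfig,
    stream: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 104_729, stream]))
    L, n, _ = gl.shape
    diploid = ploidy == 2

    # Precompute S[l, i, k] = sum_g GL[l,i,g] P(g | k parent-1 copies);
    # this is the only place the genotype likelihoods enter the sweep.
    M2 = _origin_likelihoods(p0, p1)  # (L, 3, 3)
    M1 = _origin_likelihoods_haploid(p0, p1)  # (L, 2, 3)
    S = np.zeros((L, n, 3))
    S2 = np.einsum("lig,lkg->lik", gl, M2)
    S1 = np.einsum("lig,lkg->lik", gl, M1)
    S[diploid] = S2[diploid]
    hap = ~diploid
    S[:, :, :2][hap] = S1[hap]
    binom2 = np.array([1.0, 2.0, 1.0])

    q = np.full(L, 0.5)
    keep_sum = np.zeros(L)
    keep_sq = np.zeros(L)
    z_sum = np.zeros(L)
    n_kept = 0
    k_values = np.arange(3)
    for it in range(cfg.n_iter):
        # z | q: posterior over number of parent-1 copies per (locus, ind)
        ql = q[:, None]
        w2 = binom2[None, None, :] * ql[:, :, None] ** k_values * (
            1 - ql[:, :, None]
        ) ** (2 - k_values)
        w1 = np.zeros_like(w2)
        w1[:, :, 0] = 1 - ql
        w1[:, :, 1] = ql
        wk = np.where(diploid[:, :, None], w2, w1) * S
        wk_sum = wk.sum(axis=2, keepdims=True)
        probs = wk / np.maximum(wk_sum, 1e-300)
        u = rng.random((L, n))
        cum = np.cumsum(probs, axis=2)
        k_draw = (u[:, :, None] > cum).sum(axis=2)
        # q | z with the window-mean beta prior (mu fixed within the sweep)
        n1 = k_draw.sum(axis=1).astype(float)
        n_tot = ploidy.sum(axis=1).astype(float)
        mu = np.clip(_window_mean(q, chrom_slices, cfg.window), 1e-6, 1 - 1e-6)
        q = rng.beta(cfg.nu * mu + n1, cfg.nu * (1 - mu) + (n_tot - n1))
        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            keep_sum += q
            keep_sq += q**2
            z_sum += n1 / n_tot
            n_kept += 1
    q_mean = keep_sum / n_kept
    q_var = np.maximum(keep_sq / n_kept - q_mean**2, 0.0)
    return q_mean, np.sqrt(q_var), z_sum / n_kept


def summarize_fixation(
    track: AncestryFrequencyTrack, threshold: float = 0.95
) -> pd.DataFrame:
    """Fractions of loci fixed or nearly fixed for either ancestry.

    A locus counts as parent-1-fixed when q_hat >= threshold (inclusive) and
    parent-0-fixed when q_hat <= 1 - threshold. Reported overall, per
    chromosome, and for Z vs autosomes, per population.
    """
    aim_loci = track.aims.member_locus_map()
    chroms = aim_loci.table["chromosome"].to_numpy()
    is_z = aim_loci.is_Z
    rows = []
    for pop in track.populations():
        q = track.q_mean[pop]

        def _frac(sel: np.ndarray, scope: str, pop=pop, q=q) -> dict:
            qq = q[sel]
            return {
                "population": pop,
                "scope": scope,
                "n_loci": int(sel.sum()),
                "frac_parent1_fixed": float(np.mean(qq >= threshold))
                if len(qq)
                else np.nan,
                "frac_parent0_fixed": float(np.mean(qq <= 1 - threshold))
                if len(qq)
                else np.nan,
            }

        rows.append(_frac(np.ones(len(q), dtype=bool), "all"))
        rows.append(_frac(is_z, "Z"))
        rows.append(_frac(~is_z, "autosomes"))
        for chrom in dict.fromkeys(chroms):
            rows.append(_frac(chroms == chrom, f"chrom:{chrom}"))
    return pd.DataFrame(rows)
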