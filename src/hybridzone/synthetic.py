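"""Synthetic data with the statistical structure the analyses assume.

The generator emulates a two-species butterfly system observed through
low-coverage GBS genotype likelihoods:

* two divergent parental gene pools (Balding-Nichols-style frequencies);
* ancient hybrid populations whose ancestry is laid down in autocorrelated
  blocks, some stabilized near fixation, with the Z chromosome biased
  toward parent 1;
* a contemporary hybrid zone whose individuals span the full admixture
  gradient, with locus-specific genomic-cline deviations (alpha, beta);
* genotype likelihoods from Poisson read depth with sequencing error;
* five-taxon genome windows whose topology labels are autocorrelated along
  chromosomes.

Every draw flows from the config seed, and every generated quantity is
mirrored in a :class:`TruthSet` for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .allele_freq import AlleleFrequencyTable
from .core_io import GenotypeLikelihoodMatrix, LocusMap, PopulationMap
from .phylo import TOPOLOGIES

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "simulate_parental_frequencies",
    "simulate_ancient_hybrid",
    "simulate_contemporary_zone",
    "simulate_gbs_likelihoods",
    "simulate_topology_windows",
    "simulate_study",
    "StudyData",
]


@dataclass
class SimulationConfig:
    """Knobs of the generative model, with study-like defaults.

    Defaults describe the system the analyses target: 23 chromosomes with
    one Z, GBS coverage averaging a few reads per site, a U-shaped
    hybrid-index distribution in the contemporary zone, and blockwise
    ancestry in the ancient hybrids.
    """

    n_loci_per_chromosome: int = 50
    n_chromosomes: int = 23  # last one is the Z
    parental_divergence: float = 0.4  # Balding-Nichols F between parents
    n_individuals: int = 48  # per population
    mean_depth: float = 4.0  # reads per site per individual
    error_rate: float = 0.01
    hybrid_beta_a: float = 0.5  # U-shaped hybrid-index distribution
    hybrid_beta_b: float = 0.5
    block_length: float = 20.0  # mean ancestry-block length, in loci
    ancient_mean_ancestry: float = 0.65  # parent-1 share in ancient hybrids
    ancient_fixed_fraction: float = 0.15  # segments pushed to q >= 0.95
    z_ancestry_bias: float = 0.2  # added parent-1 ancestry on the Z
    frac_alpha_loci: float = 0.05
    alpha_effect: float = 1.5
    frac_beta_loci: float = 0.05
    beta_effect: float = 2.0
    window_snps: int = 200
    n_windows_per_chromosome: int = 6
    topology_labels: tuple[int, ...] = (1, 2, 3)
    topology_weights: tuple[float, ...] = (0.5, 0.3, 0.2)
    topology_switch_prob: float = 0.2
    topology_noise: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        rates = [
            self.parental_divergence,
            self.error_rate,
            self.ancient_fixed_fraction,
            self.frac_alpha_loci,
            self.frac_beta_loci,
            self.topology_switch_prob,
            self.topology_noise,
        ]
        if any(not 0 <= r <= 1 for r in rates):
            raise ValueError("rates and fractions must lie in [0, 1]")
        if not 0 < self.parental_divergence < 1:
            raise ValueError("parental_divergence must be in (0, 1)")
        if self.block_length < 1:
            raise ValueError("block_length must be >= 1")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if min(self.hybrid_beta_a, self.hybrid_beta_b) <= 0:
            raise ValueError("hybrid-index Beta parameters must be positive")
        if len(self.topology_labels) < 2:
            raise ValueError("need >= 2 topology labels")
        if len(self.topology_labels) != len(self.topology_weights):
            raise ValueError("one weight per topology label")

    def rng(self, stage: str) -> np.random.Generator:
        import hashlib

        tag = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
        return np.random.default_rng(np.random.SeedSequence([self.seed, tag]))

    def locus_map(self) -> LocusMap:
        rng = self.rng("locus_map")
        rows = []
        for c in range(self.n_chromosomes):
            name = "Z" if c == self.n_chromosomes - 1 else f"chr{c + 1}"
            gaps = rng.integers(200, 2000, size=self.n_loci_per_chromosome)
            positions = np.cumsum(gaps)
            for k, pos in enumerate(positions):
                rows.append(
                    {
                        "locus_id": f"{name}:{pos}",
                        "chromosome": name,
                        "position": int(pos),
                        "is_Z": name == "Z",
                    }
                )
        return LocusMap(pd.DataFrame(rows))


@dataclass
class TruthSet:
    """Ground truth mirrored out of the generator for recovery tests."""

    loci: LocusMap | None = None
    p0: np.ndarray | None = None
    p1: np.ndarray | None = None
    h: dict[str, np.ndarray] = field(default_factory=dict)
    alpha: np.ndarray | None = None
    beta: np.ndarray | None = None
    q: dict[str, np.ndarray] = field(default_factory=dict)
    ancestry_haplotypes: dict[str, np.ndarray] = field(default_factory=dict)
    topology_labels: np.ndarray | None = None


def simulate_parental_frequencies(
    cfg: SimulationConfig, truth: TruthSet | None = None
) -> tuple[AlleleFrequencyTable, TruthSet]:
    """Draw parental allele frequencies from a Balding-Nichols-style model.

    Each locus has a common ancestral frequency pi ~ Uniform(0.05, 0.95);
    each parent's frequency is Beta(pi (1-F)/F, (1-pi)(1-F)/F) with F the
    parental divergence, so the expected fraction of loci with
    |p0 - p1| >= 0.3 grows monotonically with F.
    """
    truth = truth or TruthSet()
    rng = cfg.rng("parental_frequencies")
    loci = truth.loci or cfg.locus_map()
    n = len(loci)
    pi = rng.uniform(0.05, 0.95, size=n)
    f = cfg.parental_divergence
    shape = (1.0 - f) / f
    p0 = rng.beta(np.maximum(pi * shape, 1e-3), np.maximum((1 - pi) * shape, 1e-3))
    p1 = rng.beta(np.maximum(pi * shape, 1e-3), np.maximum((1 - pi) * shape, 1e-3))
    truth.loci = loci
    truth.p0 = p0
    truth.p1 = p1
    table = AlleleFrequencyTable(loci, {"parent0_true": p0, "parent1_true": p1})
    return table, truth


def _ancestry_profile(cfg: SimulationConfig, loci: LocusMap, rng) -> np.ndarray:
    """Target per-locus ancestry frequency q_l, blockwise along chromosomes."""
    q = np.empty(len(loci))
    kappa = 2.0
    for chrom, sl in loci.chromosome_slices().items():
        n = sl.stop - sl.start
        mean = cfg.ancient_mean_ancestry + (
            cfg.z_ancestry_bias if chrom == "Z" else 0.0
        )
        mean = min(mean, 0.98)
        pos = 0
        seg = np.empty(n)
        while pos < n:
            length = int(rng.geometric(1.0 / max(cfg.block_length, 1.0)))
            if rng.random() < cfg.ancient_fixed_fraction:
                val = rng.uniform(0.95, 1.0)
            else:
                val = rng.beta(mean * kappa, (1 - mean) * kappa)
            seg[pos : pos + length] = val
            pos += length
        q[sl] = seg
    return q


def simulate_ancient_hybrid(
    cfg: SimulationConfig,
    truth: TruthSet,
    population: str = "ancient",
    q_profile: np.ndarray | None = None,
) -> tuple[np.ndarray, TruthSet]:
    """Genotypes for one ancient hybrid population with blockwise ancestry.

    Each of the two haplotypes per individual carries a two-state ancestry
    chain along each chromosome whose local stationary frequency is the
    target profile q_l and whose switch rate matches a mean ancestry-block
    length of ``cfg.block_length`` loci; alleles are then drawn from the
    parental frequency of the copy's origin. Returns the (n_loci,
    n_individuals) genotype matrix; the haplotype ancestry states and the
    target profile land in the truth set.
    """
    if truth.p0 is None or truth.loci is None:
        raise ValueError("simulate_parental_frequencies must run first")
    rng = cfg.rng(f"ancient_hybrid:{population}")
    loci = truth.loci
    q = q_profile if q_profile is not None else _ancestry_profile(cfg, loci, rng)
    n_loci, n_ind = len(loci), cfg.n_individuals
    # mean run length equals block_length at q = 0.5 under this scaling
    l_eff = max(cfg.block_length / 2.0, 0.5)
    anc = np.empty((n_loci, n_ind, 2), dtype=np.int8)
    for chrom, sl in loci.chromosome_slices().items():
        qc = q[sl]
        n = sl.stop - sl.start
        state = (rng.random((n_ind, 2)) < qc[0]).astype(np.int8)
        anc[sl.start] = state
        for k in range(1, n):
            to1 = np.minimum(qc[k] / l_eff, 1.0)
            to0 = np.minimum((1.0 - qc[k]) / l_eff, 1.0)
            u = rng.random((n_ind, 2))
            state = np.where(state == 1, (u >= to0), (u < to1)).astype(np.int8)
            anc[sl.start + k] = state
    p_by_origin = np.where(
        anc == 1, truth.p1[:, None, None], truth.p0[:, None, None]
    )
    alleles = (rng.random(anc.shape) < p_by_origin).astype(np.int8)
    genotypes = alleles.sum(axis=2)
    truth.q[population] = q
    truth.ancestry_haplotypes[population] = anc
    return genotypes, truth


def _draw_effects(cfg: SimulationConfig, rng, n_loci: int) -> tuple[np.ndarray, np.ndarray]:
    alpha = np.zeros(n_loci)
    beta = np.zeros(n_loci)
    n_a = int(round(cfg.frac_alpha_loci * n_loci))
    n_b = int(round(cfg.frac_beta_loci * n_loci))
    if n_a:
        idx = rng.choice(n_loci, size=n_a, replace=False)
        alpha[idx] = rng.choice([-1.0, 1.0], size=n_a) * cfg.alpha_effect
    if n_b:
        idx = rng.choice(n_loci, size=n_b, replace=False)
        beta[idx] = cfg.beta_effect
    return alpha, beta


def simulate_contemporary_zone(
    cfg: SimulationConfig,
    truth: TruthSet,
    population: str = "zone",
    alpha: np.ndarray | None = None,
    beta: np.ndarray | None = None,
) -> tuple[np.ndarray, TruthSet]:
    """Genotypes for a contemporary hybrid zone with genomic-cline deviations.

    Hybrid indexes are Beta(a, b); each allele copy at locus l is
    parent-1-derived with probability phi(h_i; alpha_l, beta_l) and the
    allele is then drawn from that parent's frequency. alpha/beta default to
    sparse nonzero effects controlled by the config fractions.
    """
    if truth.p0 is None or truth.loci is None:
        raise ValueError("simulate_parental_frequencies must run first")
    from .clines import cline_function

    rng = cfg.rng(f"zone:{population}")
    n_loci, n_ind = len(truth.loci), cfg.n_individuals
    if alpha is None or beta is None:
        a_draw, b_draw = _draw_effects(cfg, rng, n_loci)
        alpha = a_draw if alpha is None else alpha
        beta = b_draw if beta is None else beta
    h = rng.beta(cfg.hybrid_beta_a, cfg.hybrid_beta_b, size=n_ind)
    phi = cline_function(
        np.broadcast_to(h[None, :], (n_loci, n_ind)),
        alpha[:, None],
        beta[:, None],
    )
    origin = rng.random((n_loci, n_ind, 2)) < phi[:, :, None]
    p_by_origin = np.where(
        origin, truth.p1[:, None, None], truth.p0[:, None, None]
    )
    alleles = (rng.random(origin.shape) < p_by_origin).astype(np.int8)
    genotypes = alleles.sum(axis=2)
    truth.h[population] = h
    truth.alpha = alpha
    truth.beta = beta
    return genotypes, truth


def simulate_parental_genotypes(
    cfg: SimulationConfig, truth: TruthSet, parent: int, rng=None
) -> np.ndarray:
    """Hardy-Weinberg genotypes for a pure parental population."""
    if truth.p0 is None:
        raise ValueError("simulate_parental_frequencies must run first")
    rng = rng or cfg.rng(f"parental_genotypes:{parent}")
    p = truth.p1 if parent == 1 else truth.p0
    return rng.binomial(2, p[:, None], size=(len(p), cfg.n_individuals)).astype(
        np.int8
    )


def simulate_gbs_likelihoods(
    genotypes: np.ndarray,
    loci: LocusMap,
    individuals: list[str],
    mean_depth: float,
    error_rate: float,
    rng: np.random.Generator,
) -> GenotypeLikelihoodMatrix:
    """GBS-like genotype likelihoods from Poisson coverage and read error.

    Per site and individual, the read count is Poisson(mean_depth); each
    read shows the counted allele with probability g/2 adjusted by the
    error rate. The GL triple holds the binomial read likelihoods under
    each candidate genotype; sites with zero reads get a flat (missing)
    triple.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    g = np.asarray(genotypes)
    depth = rng.poisson(mean_depth, size=g.shape)
    p_read = np.select(
        [g == 0, g == 1, g == 2], [error_rate, 0.5, 1.0 - error_rate]
    )
    y = rng.binomial(depth, p_read)
    p_candidates = np.array([error_rate, 0.5, 1.0 - error_rate])
    # log space guards against underflow at high depth
    from scipy.special import xlogy

    loggl = np.empty((*g.shape, 3))
    for cand in range(3):
        pc = p_candidates[cand]
        loggl[..., cand] = xlogy(y, pc) + xlogy(depth - y, 1.0 - pc)
    loggl -= loggl.max(axis=-1, keepdims=True)
    gl = np.exp(loggl)
    gl[depth == 0] = 1.0 / 3.0
    return GenotypeLikelihoodMatrix(loci, list(individuals), gl)


def simulate_topology_windows(
    cfg: SimulationConfig, truth: TruthSet | None = None
) -> tuple[list[np.ndarray], pd.DataFrame, TruthSet]:
    """Five-taxon SNP matrices for genome windows with autocorrelated labels.

    Window labels follow a Markov chain along each chromosome: with
    probability ``topology_switch_prob`` the label is redrawn from the
    mixing weights, otherwise it carries over. Within a window, each site
    supports one of the label topology's two internal splits (the taxa of
    one cherry carry the derived allele) or, with probability
    ``topology_noise``, a random conflicting split.
    """
    truth = truth or TruthSet()
    rng = cfg.rng("topology_windows")
    labels_pool = np.asarray(cfg.topology_labels)
    weights = np.asarray(cfg.topology_weights, dtype=float)
    weights = weights / weights.sum()
    rows, labels, matrices = [], [], []
    wid = 0
    all_pairs = [(i, j) for i in range(5) for j in range(i + 1, 5)]
    for c in range(cfg.n_chromosomes):
        chrom = "Z" if c == cfg.n_chromosomes - 1 else f"chr{c + 1}"
        label = rng.choice(labels_pool, p=weights)
        for w in range(cfg.n_windows_per_chromosome):
            if w > 0 and rng.random() < cfg.topology_switch_prob:
                label = rng.choice(labels_pool, p=weights)
            (ch1, ch2) = TOPOLOGIES[int(label) - 1]
            mat = np.zeros((cfg.window_snps, 5))
            for s in range(cfg.window_snps):
                if rng.random() < cfg.topology_noise:
                    pair = all_pairs[rng.integers(len(all_pairs))]
                else:
                    pair = ch1 if rng.random() < 0.5 else ch2
                mat[s, list(pair)] = 1.0
            rows.append(
                {
                    "window_id": wid,
                    "chromosome": chrom,
                    "start": wid * cfg.window_snps,
                    "stop": (wid + 1) * cfg.window_snps,
                }
            )
            labels.append(int(label))
            matrices.append(mat)
            wid += 1
    windows = pd.DataFrame(rows)
    truth.topology_labels = np.asarray(labels)
    return matrices, windows, truth


# ---------------------------------------------------------------------------
# Full-study preset


@dataclass
class StudyData:
    """Everything the pipeline consumes, generated in one call."""

    config: SimulationConfig
    truth: TruthSet
    gl: GenotypeLikelihoodMatrix
    populations: PopulationMap
    window_matrices: list[np.ndarray]
    windows: pd.DataFrame


def simulate_study(
    cfg: SimulationConfig,
    n_parent0_pops: int = 2,
    n_parent1_pops: int = 1,
    n_ancient_pops: int = 2,
    n_zone_pops: int = 1,
) -> StudyData:
    """Generate the full study design: parental references, ancient hybrid
    populations, a contemporary hybrid zone, GBS likelihoods for everyone,
    and five-taxon topology windows."""
    table, truth = simulate_parental_frequencies(cfg)
    del table
    blocks: list[np.ndarray] = []
    ind_rows = []
    rng_gl = cfg.rng("study_gl")

    def _add(pop_name: str, role: str, genotypes: np.ndarray) -> None:
        ids = [f"{pop_name}_{k:03d}" for k in range(genotypes.shape[1])]
        for i in ids:
            ind_rows.append(
                {
                    "individual_id": i,
                    "population_id": pop_name,
                    "role": role,
                    "sex": "male",
                }
            )
        blocks.append(genotypes)

    for k in range(n_parent0_pops):
        _add(
            f"p0_{k}",
            "parent0",
            simulate_parental_genotypes(
                cfg, truth, 0, rng=cfg.rng(f"parental_genotypes:0:{k}")
            ),
        )
    for k in range(n_parent1_pops):
        _add(
            f"p1_{k}",
            "parent1",
            simulate_parental_genotypes(
                cfg, truth, 1, rng=cfg.rng(f"parental_genotypes:1:{k}")
            ),
        )
    for k in range(n_ancient_pops):
        g, truth = simulate_ancient_hybrid(cfg, truth, population=f"ancient_{k}")
        _add(f"ancient_{k}", "hybrid", g)
    for k in range(n_zone_pops):
        g, truth = simulate_contemporary_zone(cfg, truth, population=f"zone_{k}")
        _add(f"zone_{k}", "hybrid", g)

    genotypes = np.concatenate(blocks, axis=1)
    individuals = [r["individual_id"] for r in ind_rows]
    gl = simulate_gbs_likelihoods(
        genotypes, truth.loci, individuals, cfg.mean_depth, cfg.error_rate, rng_gl
    )
    matrices, windows, truth = simulate_topology_windows(cfg, truth)
    return StudyData(
        config=cfg,
        truth=truth,
        gl=gl,
        populations=PopulationMap(pd.DataFrame(ind_rows)),
        window_matrices=matrices,
        windows=windows,
    )
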