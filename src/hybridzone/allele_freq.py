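"""EM estimation of population allele frequencies from genotype likelihoods,
and designation of ancestry-informative markers (AIMs).

The estimator maximizes the marginal likelihood of the genotype-likelihood
data under Hardy-Weinberg genotype proportions, iterating

    p  <-  (1 / 2n) * sum_i E[g_i | GL_i, HW(p)]

until the largest per-locus change falls below a tolerance. Flat (missing)
triples contribute their prior expectation 2p and therefore do not move the
estimate; loci where every individual is missing stay at the symmetric
initialization p = 0.5 and are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_io import GenotypeLikelihoodMatrix, LocusMap, PopulationMap

__all__ = [
    "AlleleFrequencyTable",
    "AimSet",
    "em_allele_frequencies",
    "designate_aims",
    "expected_heterozygosity",
]


@dataclass
class AlleleFrequencyTable:
    """Allele frequencies of the counted allele, per population and locus.

    ``freq`` maps population id -> array of length n_loci; ``n_effective``
    maps population id -> per-locus count of individuals with informative
    (non-flat) genotype likelihoods.
    """

    loci: LocusMap
    freq: dict[str, np.ndarray]
    n_effective: dict[str, np.ndarray] = field(default_factory=dict)
    flags: dict[str, np.ndarray] = field(default_factory=dict)

    def populations(self) -> list[str]:
        return list(self.freq)

    def mean_over(self, populations: Iterable[str]) -> np.ndarray:
        """Unweighted mean frequency across the listed populations."""
        pops = list(populations)
        return np.mean([self.freq[p] for p in pops], axis=0)

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for pop, p in self.freq.items():
            frames.append(
                pd.DataFrame(
                    {
                        "population": pop,
                        "locus_id": self.loci.locus_ids,
                        "p_hat": p,
                        "n_effective": self.n_effective.get(
                            pop, np.full(len(p), np.nan)
                        ),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


@dataclass
class AimSet:
    """Loci whose parental allele-frequency difference meets a threshold."""

    loci: LocusMap
    threshold: float
    parent0_populations: list[str]
    parent1_populations: list[str]
    diff: np.ndarray  # |p1_bar - p0_bar| per locus of the full map
    member_mask: np.ndarray

    def __post_init__(self) -> None:
        expected = self.diff >= self.threshold
        if not np.array_equal(expected, self.member_mask):
            raise ValueError("member_mask inconsistent with threshold rule")

    @property
    def n_members(self) -> int:
        return int(self.member_mask.sum())

    @property
    def member_ids(self) -> np.ndarray:
        return self.loci.locus_ids[self.member_mask]

    def member_locus_map(self) -> LocusMap:
        return LocusMap(self.loci.table[self.member_mask])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus_id": self.loci.locus_ids,
                "parental_diff": self.diff,
                "is_aim": self.member_mask,
            }
        )


def em_allele_frequencies(
    gl: GenotypeLikelihoodMatrix,
    pop: PopulationMap,
    tol: float = 0.001,
    max_iter: int = 20,
    populations: Sequence[str] | None = None,
) -> AlleleFrequencyTable:
    """Estimate per-population allele frequencies by EM.

    Runs the EM update independently per population (and, vectorized, per
    locus) from the symmetric start p = 0.5, stopping when
    ``max |delta p| < tol`` or after ``max_iter`` sweeps. The observed-data
    log-likelihood is monotone non-decreasing across sweeps, a property the
    test suite asserts.
    """
    if populations is None:
        populations = pop.populations()
    ind_index = {ind: j for j, ind in enumerate(gl.individuals)}
    missing = gl.is_missing()
    freq: dict[str, np.ndarray] = {}
    n_eff: dict[str, np.ndarray] = {}
    flags: dict[str, np.ndarray] = {}
    for population in populations:
        members = [
            i for i in pop.individuals(population=population) if i in ind_index
        ]
        if not members:
            raise ValueError(f"population {population!r} has no individuals with data")
        cols = [ind_index[i] for i in members]
        sub = gl.gl[:, cols, :]  # (L, n, 3)
        informative = ~missing[:, cols]
        p, _ = _em_single(sub, tol=tol, max_iter=max_iter)
        freq[population] = p
        n_eff[population] = informative.sum(axis=1)
        flags[population] = n_eff[population] == 0
    return AlleleFrequencyTable(gl.loci, freq, n_eff, flags)


def _em_single(
    gl: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, list[np.ndarray]]:
    """EM for one population. gl: (L, n, 3). Returns (p, loglik history)."""
    L, n, _ = gl.shape
    p = np.full(L, 0.5)
    g = np.arange(3)
    history: list[np.ndarray] = []
    for _ in range(max_iter):
        # HW genotype prior at current p
        hw = np.stack(
            [(1 - p) ** 2, 2 * p * (1 - p), p**2], axis=1
        )  # (L, 3)
        post_unnorm = gl * hw[:, None, :]  # (L, n, 3)
        norm = post_unnorm.sum(axis=2)  # (L, n)
        history.append(np.log(norm).sum(axis=1))
        post = post_unnorm / norm[:, :, None]
        e_g = (post * g).sum(axis=2)  # (L, n)
        p_new = e_g.mean(axis=1) / 2.0
        delta = np.max(np.abs(p_new - p)) if L else 0.0
        p = p_new
        if delta < tol:
            break
    return p, history


def marginal_loglik(gl: np.ndarray, p: float | np.ndarray) -> np.ndarray:
    """Observed-data log-likelihood of p for GL array (L, n, 3) or (n, 3)."""
    arr = np.asarray(gl, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    p = np.atleast_1d(np.asarray(p, dtype=float))
    hw = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2], axis=1)
    return np.log((arr * hw[:, None, :]).sum(axis=2)).sum(axis=1)


def designate_aims(
    freqs: AlleleFrequencyTable,
    parent0: Sequence[str],
    parent1: Sequence[str],
    threshold: float = 0.3,
) -> AimSet:
    """Select loci with parental mean-frequency difference >= threshold.

    Parental means are unweighted across the listed populations; the
    threshold is inclusive.
    """
    for p in list(parent0) + list(parent1):
        if p not in freqs.freq:
            raise ValueError(f"population {p!r} absent from frequency table")
    p0 = freqs.mean_over(parent0)
    p1 = freqs.mean_over(parent1)
    diff = np.abs(p1 - p0)
    mask = diff >= threshold
    if not mask.any():
        import warnings

        warnings.warn("no loci pass the AIM threshold", stacklevel=2)
    return AimSet(
        loci=freqs.loci,
        threshold=threshold,
        parent0_populations=list(parent0),
        parent1_populations=list(parent1),
        diff=diff,
        member_mask=mask,
    )


def expected_heterozygosity(p: float | np.ndarray) -> float | np.ndarray:
    """Hardy-Weinberg expected heterozygosity 2p(1-p)."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("allele frequency outside [0, 1]")
    out = 2.0 * arr * (1.0 - arr)
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out
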