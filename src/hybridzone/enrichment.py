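"""Permutation (randomization) machinery for x-fold enrichment tests.

x-fold enrichment is the observed count of a pattern divided by the mean
count under a permutation null in which set membership is relabeled
uniformly at random across loci. One-sided P-values use the add-one
permutation estimator (1 + #{null >= observed}) / (n_perm + 1), so a P of
exactly zero is never reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("hybridzone")

__all__ = [
    "EnrichmentResult",
    "LocusSet",
    "topq_set",
    "overlap_randomization_test",
    "category_enrichment_test",
    "proportion_size_correlation",
    "consistency_suite",
]


@dataclass
class EnrichmentResult:
    observed: float
    null_mean: float
    null_sd: float
    null_quantiles: dict[str, float]
    x_fold: float
    p_one_sided: float
    n_perm: int
    direction: str  # "excess" or "deficit"

    def as_dict(self) -> dict:
        return {
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "x_fold": self.x_fold,
            "p_one_sided": self.p_one_sided,
            "n_perm": self.n_perm,
            "direction": self.direction,
        }


@dataclass
class LocusSet:
    """A top/bottom quantile of loci under some per-locus score."""

    member_index: np.ndarray  # integer indices into the N scored loci
    score_name: str
    quantile: float
    direction: str  # "top" or "bottom"
    n_total: int

    def __len__(self) -> int:
        return len(self.member_index)

    def mask(self) -> np.ndarray:
        m = np.zeros(self.n_total, dtype=bool)
        m[self.member_index] = True
        return m


def topq_set(
    scores: np.ndarray,
    q: float,
    direction: str = "top",
    score_name: str = "score",
) -> LocusSet:
    """Select the floor(q*N) loci with the most extreme scores.

    Ranking is by score with ties broken by locus order (stable sort); a
    tie crossing the cutoff is logged rather than resolved by value.
    """
    scores = np.asarray(scores, dtype=float)
    if not 0 < q <= 1:
        raise ValueError("quantile must be in (0, 1]")
    if direction not in ("top", "bottom"):
        raise ValueError("direction must be 'top' or 'bottom'")
    if np.all(scores == scores[0]):
        raise ValueError("all scores equal: top-quantile set undefined")
    n = len(scores)
    size = max(int(np.floor(q * n)), 1)
    key = -scores if direction == "top" else scores
    order = np.argsort(key, kind="stable")
    chosen = order[:size]
    if size < n and scores[order[size - 1]] == scores[order[size]]:
        logger.info(
            "tie at the %s-%g cutoff (score %g); broken by locus order",
            direction,
            q,
            scores[order[size]],
        )
    return LocusSet(np.sort(chosen), score_name, q, direction, n)


def _result(
    observed: float,
    null: np.ndarray,
    direction: str,
) -> EnrichmentResult:
    n_perm = len(null)
    null_mean = float(null.mean())
    if direction == "excess":
        p = (1 + int((null >= observed).sum())) / (n_perm + 1)
    else:
        p = (1 + int((null <= observed).sum())) / (n_perm + 1)
    if null_mean == 0:
        raise ValueError("null mean is zero: x-fold undefined")
    return EnrichmentResult(
        observed=float(observed),
        null_mean=null_mean,
        null_sd=float(null.std(ddof=1)) if n_perm > 1 else 0.0,
        null_quantiles={
            "q025": float(np.quantile(null, 0.025)),
            "q500": float(np.quantile(null, 0.5)),
            "q975": float(np.quantile(null, 0.975)),
        },
        x_fold=float(observed) / null_mean,
        p_one_sided=p,
        n_perm=n_perm,
        direction=direction,
    )


def overlap_randomization_test(
    set_a: LocusSet,
    set_b: LocusSet,
    n_loci: int,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
    direction: str = "excess",
) -> EnrichmentResult:
    """x-fold enrichment of the overlap between two locus sets.

    The observed statistic is |A intersect B|; each permutation relabels
    set A's membership uniformly at random over the N loci while B stays
    fixed, which matches permuting one parameter's values across loci.
    """
    if set_a.n_total != n_loci or set_b.n_total != n_loci:
        raise ValueError("sets must be defined over the same N loci")
    if n_perm < 100:
        import warnings

        warnings.warn("n_perm < 100 gives an unstable null", stacklevel=2)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    mask_b = set_b.mask()
    observed = int(np.intersect1d(set_a.member_index, set_b.member_index).size)
    null = _null_counts(rng, mask_b, len(set_a), n_perm)
    return _result(observed, null, direction)


def _null_counts(
    rng: np.random.Generator, membership: np.ndarray, size: int, n_perm: int
) -> np.ndarray:
    """Counts of category members in uniformly relabeled sets of a given size.

    Each permutation draws a uniform random subset of ``size`` loci (by
    ranking i.i.d. uniforms, i.e., a random permutation truncated to the set
    size) and counts how many fall in the fixed category. Chunked to bound
    memory.
    """
    n = len(membership)
    null = np.empty(n_perm)
    chunk = max(1, int(2_000_000 // max(n, 1)))
    done = 0
    member_f = membership.astype(float)
    while done < n_perm:
        m = min(chunk, n_perm - done)
        u = rng.random((m, n))
        idx = np.argpartition(u, size - 1, axis=1)[:, :size]
        null[done : done + m] = member_f[idx].sum(axis=1)
        done += m
    return null


def category_enrichment_test(
    locus_set: LocusSet,
    membership: np.ndarray,
    n_perm: int = 1_000,
    seed: int | np.random.Generator = 0,
    direction: str = "excess",
) -> EnrichmentResult:
    """x-fold enrichment of a locus set within a boolean category.

    Category membership (e.g., Z-linked, or within 1 kb of a gene) is fixed;
    the focal set is relabeled uniformly across all loci each permutation.
    ``direction='deficit'`` tests under-representation with the lower tail.
    """
    membership = np.asarray(membership, dtype=bool)
    if len(membership) != locus_set.n_total:
        raise ValueError("membership must cover all N loci")
    if not membership.any():
        raise ValueError("membership all false: null mean 0, x-fold undefined")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    observed = int(membership[locus_set.member_index].sum())
    null = _null_counts(rng, membership, len(locus_set), n_perm)
    return _result(observed, null, direction)


def proportion_size_correlation(
    proportions: Sequence[float],
    sizes_bp: Sequence[float],
    exclude: np.ndarray | None = None,
) -> tuple[float, float]:
    """Pearson correlation between a per-chromosome proportion and size.

    Returns (r, two-sided P) from the t transform with n - 2 degrees of
    freedom. ``exclude`` masks chromosomes out (e.g., the Z) for the
    autosome-only re-run.
    """
    x = np.asarray(sizes_bp, dtype=float)
    y = np.asarray(proportions, dtype=float)
    if exclude is not None:
        keep = ~np.asarray(exclude, dtype=bool)
        x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 chromosomes")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# The nine-comparison consistency grid

_COMPARISONS: list[tuple[str, str, str]] = [
    # (name, cline score, ancestry score)
    ("high_alpha__high_parent1", "alpha_top", "q_parent1"),
    ("high_alpha__high_parent0", "alpha_top", "q_parent0"),
    ("low_alpha__high_parent1", "alpha_bottom", "q_parent1"),
    ("low_alpha__high_parent0", "alpha_bottom", "q_parent0"),
    ("high_beta__high_parent1", "beta_top", "q_parent1"),
    ("high_beta__high_parent0", "beta_top", "q_parent0"),
    ("high_alpha__extreme", "alpha_top", "q_extreme"),
    ("low_alpha__extreme", "alpha_bottom", "q_extreme"),
    ("high_beta__extreme", "beta_top", "q_extreme"),
]


def consistency_suite(
    cline_summary: pd.DataFrame,
    ancestry_q: np.ndarray,
    is_z: np.ndarray,
    quantiles: Sequence[float] = (0.10, 0.09, 0.08, 0.07, 0.06, 0.05, 0.04, 0.03, 0.02, 0.01),
    scopes: Sequence[str] = ("all", "autosomes", "Z"),
    n_perm: int = 10_000,
    seed: int = 0,
    scope_rule: str = "within_scope",
) -> pd.DataFrame:
    """Cross-tabulate cline deviations against ancestry extremes.

    Runs the overlap randomization test for nine comparisons between
    contemporary-zone cline scores (high alpha, low alpha, high beta) and
    ancient-hybrid ancestry frequencies (high parent-1, high parent-0, and
    extreme = near fixation for either), at each quantile and chromosome
    scope. ``cline_summary`` must align row-wise with ``ancestry_q`` and
    ``is_z`` on the same AIM set.

    scope_rule='within_scope' rebuilds the top-quantile sets inside the
    scope before permuting within it; 'global_sets_scoped_null' scores the
    genome-wide sets against a scope-restricted null.
    """
    if scope_rule not in ("within_scope", "global_sets_scoped_null"):
        raise ValueError(f"unknown scope_rule {scope_rule!r}")
    alpha = cline_summary["alpha_mean"].to_numpy()
    beta = cline_summary["beta_mean"].to_numpy()
    q = np.asarray(ancestry_q, dtype=float)
    is_z = np.asarray(is_z, dtype=bool)
    if not (len(alpha) == len(q) == len(is_z)):
        raise ValueError("inputs must align on the same AIM set")
    scores_a = {"alpha_top": (alpha, "top"), "alpha_bottom": (alpha, "bottom"),
                "beta_top": (beta, "top")}
    scores_b = {
        "q_parent1": (q, "top"),
        "q_parent0": (1 - q, "top"),
        "q_extreme": (np.maximum(q, 1 - q), "top"),
    }
    rng = np.random.default_rng(seed)
    rows = []
    for scope in scopes:
        if scope == "all":
            sel = np.ones(len(q), dtype=bool)
        elif scope == "autosomes":
            sel = ~is_z
        elif scope == "Z":
            sel = is_z
        else:
            raise ValueError(f"unknown scope {scope!r}")
        global_idx = np.flatnonzero(sel)
        for quantile in quantiles:
            for name, key_a, key_b in _COMPARISONS:
                sa_score, sa_dir = scores_a[key_a]
                sb_score, sb_dir = scores_b[key_b]
                try:
                    if scope_rule == "within_scope":
                        set_a = topq_set(sa_score[sel], quantile, sa_dir, key_a)
                        set_b = topq_set(sb_score[sel], quantile, sb_dir, key_b)
                        n_scope = int(sel.sum())
                    else:
                        ga = topq_set(sa_score, quantile, sa_dir, key_a)
                        gb = topq_set(sb_score, quantile, sb_dir, key_b)
                        pos = {g: i for i, g in enumerate(global_idx)}
                        ia = np.array(
                            [pos[i] for i in ga.member_index if i in pos], dtype=int
                        )
                        ib = np.array(
                            [pos[i] for i in gb.member_index if i in pos], dtype=int
                        )
                        if len(ia) == 0 or len(ib) == 0:
                            raise ValueError("empty scoped set")
                        n_scope = len(global_idx)
                        set_a = LocusSet(ia, key_a, quantile, sa_dir, n_scope)
                        set_b = LocusSet(ib, key_b, quantile, sb_dir, n_scope)
                    res = overlap_randomization_test(
                        set_a, set_b, n_scope, n_perm=n_perm, seed=rng
                    )
                except ValueError as exc:
                    logger.info(
                        "skipping %s q=%g scope=%s: %s", name, quantile, scope, exc
                    )
                    continue
                rows.append(
                    {
                        "comparison": name,
                        "quantile": quantile,
                        "scope": scope,
                        "n_scope": n_scope,
                        "set_size": len(set_a),
                        **res.as_dict(),
                        "significant": res.p_one_sided <= 0.05,
                    }
                )
    return pd.DataFrame(rows)
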