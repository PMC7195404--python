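"""Window-based phylogenomics for five lineages.

The genome is cut into nonoverlapping windows of a fixed number of SNPs and
each window is assigned one of the 15 possible unrooted binary topologies
for five taxa. For five taxa exhaustive scoring of all 15 topologies is
exact and fast, so no heuristic tree search is needed: the default scorer
is Fitch parsimony (heterozygous calls enter as ambiguity sets), with an
ordinary-least-squares minimum-evolution alternative fit to pairwise
distances. Downstream, topology counts per chromosome class are tested by
permutation, and ABBA-BABA f_d admixture proportions quantify introgression
per linkage group or for candidate window sets.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .core_io import LocusMap
from .enrichment import EnrichmentResult, LocusSet, _null_counts, _result
from .enrichment import proportion_size_correlation as _prop_size_corr

logger = logging.getLogger("hybridzone")

__all__ = [
    "TOPOLOGIES",
    "topology_newick",
    "WindowTopologyTable",
    "FdResult",
    "split_windows",
    "infer_window_topology",
    "assign_window_topologies",
    "topology_class_test",
    "fd_statistic",
    "fd_window_set_test",
    "topology_size_correlation",
    "read_newick_topology",
]


def _enumerate_topologies() -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """All 15 unrooted binary 5-taxon shapes as unordered disjoint cherry pairs."""
    pairs = list(itertools.combinations(range(5), 2))
    out = []
    for a, b in itertools.combinations(pairs, 2):
        if not set(a) & set(b):
            out.append((a, b))
    assert len(out) == 15
    return out


#: Canonical topology enumeration: ids 1..15 index this list (id - 1).
TOPOLOGIES: list[tuple[tuple[int, int], tuple[int, int]]] = _enumerate_topologies()


def topology_newick(topology_id: int, taxa: list[str]) -> str:
    """Newick string for a canonical topology id with the given taxon names."""
    (a, b), (c, d) = TOPOLOGIES[topology_id - 1]
    e = (set(range(5)) - {a, b, c, d}).pop()
    return (
        f"(({taxa[a]},{taxa[b]}),({taxa[c]},{taxa[d]}),{taxa[e]});"
    )


def topology_id_from_cherries(
    cherry1: tuple[int, int], cherry2: tuple[int, int]
) -> int:
    key = tuple(sorted([tuple(sorted(cherry1)), tuple(sorted(cherry2))]))
    for k, (a, b) in enumerate(TOPOLOGIES):
        if (a, b) == key:
            return k + 1
    raise ValueError(f"not a valid cherry pair: {cherry1}, {cherry2}")


@dataclass
class WindowTopologyTable:
    """Per-window inferred topology over the canonical 15-tree enumeration."""

    table: pd.DataFrame  # window_id, chromosome, start, stop, topology_id, score, tie

    @property
    def labels(self) -> np.ndarray:
        return self.table["topology_id"].to_numpy()

    def counts(self) -> pd.Series:
        return self.table["topology_id"].value_counts().sort_index()

    def proportion_by_chromosome(self, topology_id: int) -> pd.Series:
        by = self.table.groupby("chromosome", sort=False)["topology_id"]
        return by.apply(lambda s: float(np.mean(s == topology_id)))


def split_windows(loci: LocusMap, window_snps: int = 1000) -> pd.DataFrame:
    """Nonoverlapping windows of exactly ``window_snps`` loci per chromosome.

    Returns a frame with global 0-based half-open index ranges into the
    locus order. The trailing remainder on each chromosome (fewer than
    ``window_snps`` loci) is dropped and logged; windows never span
    chromosome boundaries.
    """
    if window_snps < 2:
        raise ValueError("window_snps must be >= 2")
    rows = []
    wid = 0
    for chrom, sl in loci.chromosome_slices().items():
        n = sl.stop - sl.start
        n_windows, remainder = divmod(n, window_snps)
        if n_windows == 0:
            logger.info("chromosome %s has %d < %d loci: no windows", chrom, n, window_snps)
        elif remainder:
            logger.info("chromosome %s: dropping %d trailing loci", chrom, remainder)
        for w in range(n_windows):
            start = sl.start + w * window_snps
            rows.append(
                {
                    "window_id": wid,
                    "chromosome": chrom,
                    "start": start,
                    "stop": start + window_snps,
                }
            )
            wid += 1
    return pd.DataFrame(rows, columns=["window_id", "chromosome", "start", "stop"])


# ---------------------------------------------------------------------------
# Topology scoring

_MASKS = {0.0: 1, 0.5: 3, 1.0: 2}  # allele calls -> Fitch state sets


def _site_masks(matrix: np.ndarray) -> np.ndarray:
    """Map a (sites, 5) matrix of 0/0.5/1 calls (nan = missing) to bitmasks."""
    masks = np.full(matrix.shape, 3, dtype=np.int8)
    masks[matrix == 0.0] = 1
    masks[matrix == 1.0] = 2
    return masks


def _fitch_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    inter = x & y
    cost = (inter == 0).astype(np.int64)
    state = np.where(inter > 0, inter, x | y)
    return state, cost


def _parsimony_scores(masks: np.ndarray) -> np.ndarray:
    """Total Fitch length per topology; masks shape (sites, 5)."""
    scores = np.empty(15, dtype=np.int64)
    for k, ((a, b), (c, d)) in enumerate(TOPOLOGIES):
        e = (set(range(5)) - {a, b, c, d}).pop()
        n1, c1 = _fitch_pair(masks[:, a], masks[:, b])
        n2, c2 = _fitch_pair(masks[:, c], masks[:, d])
        n3, c3 = _fitch_pair(n1, n2)
        _, c4 = _fitch_pair(n3, masks[:, e])
        scores[k] = (c1 + c2 + c3 + c4).sum()
    return scores


def _path_matrix(topology: tuple[tuple[int, int], tuple[int, int]]) -> np.ndarray:
    """Pair-path incidence over the 7 branches of a 5-taxon unrooted tree.

    Branch order: 5 terminal branches (taxon 0..4), internal branch of
    cherry 1, internal branch of cherry 2.
    """
    (a, b), (c, d) = topology
    rows = []
    for i, j in itertools.combinations(range(5), 2):
        row = np.zeros(7)
        row[i] = row[j] = 1.0
        # path crosses a cherry's internal branch when exactly one endpoint
        # is inside that cherry
        for br, cherry in ((5, {a, b}), (6, {c, d})):
            if len({i, j} & cherry) == 1:
                row[br] = 1.0
        rows.append(row)
    return np.asarray(rows)


def _distance_vector(matrix: np.ndarray) -> np.ndarray:
    """Mean absolute call difference per taxon pair, skipping missing sites."""
    d = np.empty(10)
    for k, (i, j) in enumerate(itertools.combinations(range(5), 2)):
        xi, xj = matrix[:, i], matrix[:, j]
        ok = ~(np.isnan(xi) | np.isnan(xj))
        d[k] = np.abs(xi[ok] - xj[ok]).mean() if ok.any() else 0.0
    return d


def _me_ls_scores(matrix: np.ndarray) -> np.ndarray:
    """Residual sum of squares of nonnegative OLS branch lengths per topology."""
    d = _distance_vector(matrix)
    scores = np.empty(15)
    for k, topo in enumerate(TOPOLOGIES):
        a_mat = _path_matrix(topo)
        _, rnorm = nnls(a_mat, d)
        scores[k] = rnorm**2
    return scores


def infer_window_topology(
    matrix: np.ndarray, method: str = "parsimony"
) -> tuple[int, float, bool]:
    """Best-scoring unrooted topology for one window.

    ``matrix`` is (sites, 5) with within-taxon allele frequencies coded
    0 / 0.5 / 1 (nan for missing). All 15 topologies are scored; the argmin
    wins, with ties flagged and broken by the lowest canonical id. A window
    with no variation ties across all topologies and is flagged
    uninformative.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] != 5:
        raise ValueError("matrix must be (sites, 5)")
    if method == "parsimony":
        scores = _parsimony_scores(_site_masks(matrix)).astype(float)
    elif method == "me_ls":
        scores = _me_ls_scores(matrix)
    else:
        raise ValueError(f"unknown method {method!r}")
    best = int(np.argmin(scores))
    tie = bool(np.sum(np.isclose(scores, scores[best], atol=1e-12)) > 1)
    return best + 1, float(scores[best]), tie


def assign_window_topologies(
    matrices: "list[np.ndarray]",
    windows: pd.DataFrame,
    method: str = "parsimony",
) -> WindowTopologyTable:
    """Score every window and return the labeled window table."""
    if len(matrices) != len(windows):
        raise ValueError("one SNP matrix per window required")
    ids, scores, ties = [], [], []
    for m in matrices:
        tid, score, tie = infer_window_topology(m, method=method)
        ids.append(tid)
        scores.append(score)
        ties.append(tie)
    out = windows.copy()
    out["topology_id"] = ids
    out["score"] = scores
    out["tie"] = ties
    return WindowTopologyTable(out)


def topology_class_test(
    table: WindowTopologyTable,
    target_topology: int,
    class_mask: np.ndarray,
    n_perm: int = 1_000,
    seed: int | np.random.Generator = 0,
    direction: str = "excess",
) -> EnrichmentResult:
    """Excess/deficit of a topology within a window class, by permutation.

    The observed statistic is the count of the target topology among class
    windows; the null permutes topology labels across all windows (which is
    equivalent to relabeling the class uniformly at random).
    """
    labels = table.labels
    class_mask = np.asarray(class_mask, dtype=bool)
    if len(class_mask) != len(labels):
        raise ValueError("class mask must cover all windows")
    if not class_mask.any():
        raise ValueError("empty window class")
    membership = labels == target_topology
    if not membership.any():
        raise ValueError(f"topology {target_topology} absent genome-wide")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    observed = int(membership[class_mask].sum())
    null = _null_counts(rng, membership, int(class_mask.sum()), n_perm)
    return _result(observed, null, direction)


# ---------------------------------------------------------------------------
# f_d admixture proportions


@dataclass
class FdResult:
    scope: str
    n_sites: int
    sum_abba: float
    sum_baba: float
    s_num: float
    s_den: float
    fd: float
    undefined: bool
    roles: tuple[str, str, str, str]  # names of P1, P2, P3, O


def fd_statistic(
    p1: np.ndarray,
    p2: np.ndarray,
    p3: np.ndarray,
    p_out: np.ndarray,
    roles: tuple[str, str, str, str] = ("P1", "P2", "P3", "O"),
    scope: str = "all",
) -> FdResult:
    """ABBA-BABA f_d admixture proportion over a locus set.

    Per site, with derived-allele frequencies in populations P1, P2, P3 and
    outgroup O:

        ABBA = (1 - p1) p2 p3 (1 - pO),   BABA = p1 (1 - p2) p3 (1 - pO)

    The numerator is sum(ABBA - BABA). The denominator recomputes the same
    sum after substituting the donor frequency pD = max(p2, p3) for both p2
    and p3 -- the expectation under complete introgression from the donor.
    Sites with missing data in any taxon are skipped.
    """
    arrs = [np.asarray(a, dtype=float) for a in (p1, p2, p3, p_out)]
    ok = ~np.any([np.isnan(a) for a in arrs], axis=0)
    a1, a2, a3, ao = (a[ok] for a in arrs)
    abba = (1 - a1) * a2 * a3 * (1 - ao)
    baba = a1 * (1 - a2) * a3 * (1 - ao)
    s_num = float((abba - baba).sum())
    pd_donor = np.maximum(a2, a3)
    abba_d = (1 - a1) * pd_donor * pd_donor * (1 - ao)
    baba_d = a1 * (1 - pd_donor) * pd_donor * (1 - ao)
    s_den = float((abba_d - baba_d).sum())
    undefined = s_den == 0.0
    return FdResult(
        scope=scope,
        n_sites=int(ok.sum()),
        sum_abba=float(abba.sum()),
        sum_baba=float(baba.sum()),
        s_num=s_num,
        s_den=s_den,
        fd=np.nan if undefined else s_num / s_den,
        undefined=undefined,
        roles=roles,
    )


def fd_window_set_test(
    fd_per_window: np.ndarray,
    candidate_mask: np.ndarray,
    n_draws: int = 1_000,
    seed: int | np.random.Generator = 0,
) -> EnrichmentResult:
    """Is mean f_d over candidate windows lower than over random window sets?

    The observed statistic is the mean f_d across the k candidate windows;
    the null repeatedly draws k windows at random. Windows with undefined
    f_d are excluded from the sampling pool (a draw hitting one is resampled
    by construction) and logged. One-sided P targets reduced admixture
    (lower tail).
    """
    fd = np.asarray(fd_per_window, dtype=float)
    candidate_mask = np.asarray(candidate_mask, dtype=bool)
    defined = ~np.isnan(fd)
    n_undef = int((~defined).sum())
    if n_undef:
        logger.info("excluding %d windows with undefined f_d from the null pool", n_undef)
    pool = fd[defined]
    k = int((candidate_mask & defined).sum())
    if k == 0:
        raise ValueError("no candidate windows with defined f_d")
    if k > len(pool):
        raise ValueError("candidate set larger than the window pool")
    observed = float(fd[candidate_mask & defined].mean())
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    null = np.empty(n_draws)
    for t in range(n_draws):
        take = rng.choice(len(pool), size=k, replace=False)
        null[t] = pool[take].mean()
    res = _result(observed, null, "deficit")
    return res


def topology_size_correlation(
    proportions, sizes_bp, exclude=None
) -> tuple[float, float]:
    """Pearson correlation between per-chromosome topology proportion and size."""
    return _prop_size_corr(proportions, sizes_bp, exclude=exclude)


def read_newick_topology(newick: str, taxa: list[str]) -> int:
    """Canonical topology id of an externally supplied 5-taxon Newick tree.

    Ignores branch lengths and rooting; the tree must contain exactly the
    five taxon names given (their order defines the canonical indexing).
    """
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    index = {t: i for i, t in enumerate(taxa)}
    labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if labels != set(taxa):
        raise ValueError("tree must contain exactly the five given taxa")
    all_ids = set(range(5))
    cherries: set[tuple[int, int]] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        below = {
            index[leaf.taxon.label] for leaf in node.leaf_iter()
        }
        if len(below) == 2:
            cherries.add(tuple(sorted(below)))  # type: ignore[arg-type]
        elif len(below) == 3:
            cherries.add(tuple(sorted(all_ids - below)))  # type: ignore[arg-type]
    for c1, c2 in itertools.combinations(sorted(cherries), 2):
        if not set(c1) & set(c2):
            return topology_id_from_cherries(c1, c2)
    raise ValueError("could not resolve two disjoint splits from the tree")
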