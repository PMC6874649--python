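"""Community-phylogenetic structure of priority plant sets.

Tests whether a set of selected plant species is more closely related than
expected by chance: the standardized effect sizes of the mean pairwise
phylogenetic distance (MPD) and the mean nearest-taxon distance (MNTD)
against null sets drawn from the species pool, optionally weighted by plant
abundance.  Following the reporting convention adopted here, negative
standardized scores (negative NRI / negative NTI) indicate phylogenetic
clustering; the classic Webb indices (NRI = -SES(MPD), NTI = -SES(MNTD))
are also emitted.

Also provides between-community mean phylogenetic distance (comdist) and a
rank-based ANOSIM permutation test for group structure in a distance
matrix.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from scipy.stats import norm, rankdata

from .network import NetworkInputError

__all__ = [
    "load_tree",
    "cophenetic_distances",
    "PhyloStructResult",
    "null_draws",
    "sample_stat",
    "ses_phylo",
    "comdist",
    "comdist_matrix",
    "anosim",
]


class DegenerateNullError(ValueError):
    """The null distribution has zero variance (e.g. sample == pool)."""


def load_tree(source: str, *, is_path: bool = True) -> dendropy.Tree:
    """Load a rooted Newick tree with branch lengths."""
    kwargs = {"path": source} if is_path else {"data": source}
    return dendropy.Tree.get(schema="newick", preserve_underscores=True, **kwargs)


def cophenetic_distances(
    tree: dendropy.Tree, *, allow_missing_lengths: bool = False
) -> pd.DataFrame:
    """Patristic (sum of branch lengths) leaf-to-leaf distance matrix.

    Missing branch lengths are an error unless ``allow_missing_lengths``
    substitutes unit lengths explicitly.
    """
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise NetworkInputError("duplicate leaf labels in tree")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            if allow_missing_lengths:
                edge.length = 1.0
            else:
                raise NetworkInputError(
                    "tree has missing branch lengths "
                    "(pass allow_missing_lengths=True for unit branches)"
                )
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    mat = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[a], taxa[labels[j]])
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# SES of MPD / MNTD
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhyloStructResult:
    """Standardized effect size of a phylogenetic distance statistic.

    ``ses`` = (observed - null mean) / null sd; negative values indicate
    clustering.  ``nri_nti`` is the classic Webb index (-ses).  Both a
    one-sample z-test p (one-tailed toward clustering, and two-tailed) and
    the distribution-free rank p are reported.
    """

    stat: str
    observed: float
    null_mean: float
    null_sd: float
    ses: float
    nri_nti: float
    p_z_one_tailed: float
    p_z_two_tailed: float
    p_rank: float
    n_null: int

    def to_row(self) -> dict:
        return {
            "stat": self.stat,
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "ses": self.ses,
            "nri_nti": self.nri_nti,
            "p_z_one_tailed": self.p_z_one_tailed,
            "p_z_two_tailed": self.p_z_two_tailed,
            "p_rank": self.p_rank,
            "n_null": self.n_null,
        }


def _as_matrix(dist, pool: list[str]) -> np.ndarray:
    if isinstance(dist, pd.DataFrame):
        missing = set(pool) - set(dist.index)
        if missing:
            raise NetworkInputError(f"species missing from distance matrix: {sorted(missing)}")
        return dist.loc[pool, pool].to_numpy(dtype=float)
    return np.asarray(dist, dtype=float)


def sample_stat(d: np.ndarray, idx: np.ndarray, stat: str) -> np.ndarray:
    """MPD or MNTD for one index vector or a batch of them.

    ``idx`` has shape (k,) or (n_draws, k); returns a scalar array per draw.
    """
    idx = np.atleast_2d(idx)
    sub = d[idx[:, :, None], idx[:, None, :]]
    k = idx.shape[1]
    if stat == "MPD":
        out = (sub.sum(axis=(1, 2))) / (k * (k - 1))
    elif stat == "MNTD":
        sub = sub + np.where(np.eye(k, dtype=bool), np.inf, 0.0)
        out = sub.min(axis=2).mean(axis=1)
    else:
        raise NetworkInputError("stat must be 'MPD' or 'MNTD'")
    return out


def null_draws(
    n_pool: int,
    k: int,
    n_null: int,
    weights: np.ndarray | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Index sets of ``n_null`` random k-subsets of the pool without
    replacement, probability proportional to ``weights``.

    Weighted draws use exponential sort keys (Efraimidis-Spirakis), which is
    distributionally identical to sequential draw-remove-renormalize
    sampling; this matters because alternative weighted-without-replacement
    schemes change the null distribution.
    """
    rng = np.random.default_rng(seed)
    if weights is None:
        keys = rng.random((n_null, n_pool))
    else:
        weights = np.asarray(weights, dtype=float)
        if np.any(weights < 0) or weights.sum() <= 0:
            raise NetworkInputError("weights must be nonnegative with positive sum")
        if np.count_nonzero(weights) < k:
            raise NetworkInputError("fewer positively-weighted species than sample size")
        with np.errstate(divide="ignore"):
            keys = rng.exponential(size=(n_null, n_pool)) / weights
    return np.argpartition(keys, k - 1, axis=1)[:, :k]


def _exhaustive_draws(n_pool: int, k: int, limit: int = 200_000) -> np.ndarray:
    if math.comb(n_pool, k) > limit:
        raise NetworkInputError("pool too large for exhaustive null enumeration")
    return np.array(list(itertools.combinations(range(n_pool), k)))


def ses_phylo(
    sample,
    pool,
    dist,
    stat: str = "MPD",
    weights=None,
    n_null: int = 10_000,
    seed: int = 0,
    method: str = "sample",
    null_values: np.ndarray | None = None,
) -> PhyloStructResult:
    """Standardized effect size of MPD or MNTD against random pool subsets.

    Parameters
    ----------
    sample
        Selected species (>= 2, a strict subset of ``pool``).
    pool
        Candidate species list; ``dist`` must cover it.
    weights
        Optional per-pool-species abundances for weighted nulls (uniform if
        absent).
    method
        ``'sample'`` draws ``n_null`` subsets; ``'exhaustive'`` enumerates
        every k-subset (uniform weights only).
    null_values
        Precomputed null statistic values (e.g. to share one null
        distribution across many observed samples from the same pool).
    """
    pool = list(pool)
    sample = list(dict.fromkeys(sample))
    if len(sample) < 2:
        raise NetworkInputError("sample must contain at least 2 species")
    if not set(sample) <= set(pool):
        raise NetworkInputError("sample must be a subset of the pool")
    if len(sample) == len(pool):
        raise DegenerateNullError("sample equals pool: null distribution has sd 0")
    d = _as_matrix(dist, pool)
    pos = {s: i for i, s in enumerate(pool)}
    obs_idx = np.array([pos[s] for s in sample])
    observed = float(sample_stat(d, obs_idx, stat)[0])

    if null_values is None:
        k = len(sample)
        if method == "exhaustive":
            if weights is not None:
                raise NetworkInputError("exhaustive nulls require uniform weights")
            draws = _exhaustive_draws(len(pool), k)
        elif method == "sample":
            w = None if weights is None else _align_weights(weights, pool)
            draws = null_draws(len(pool), k, n_null, weights=w, seed=seed)
        else:
            raise NetworkInputError("method must be 'sample' or 'exhaustive'")
        null_values = sample_stat(d, draws, stat)
    null_values = np.asarray(null_values, dtype=float)

    null_mean = float(null_values.mean())
    null_sd = float(null_values.std(ddof=0))
    if null_sd < 1e-12:
        raise DegenerateNullError("null distribution has sd 0")
    ses = (observed - null_mean) / null_sd
    r = int(np.sum(null_values <= observed + 1e-12))
    return PhyloStructResult(
        stat=stat,
        observed=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        ses=float(ses),
        nri_nti=float(-ses),
        p_z_one_tailed=float(norm.cdf(ses)),
        p_z_two_tailed=float(2 * norm.sf(abs(ses))),
        p_rank=(r + 1) / (len(null_values) + 1),
        n_null=len(null_values),
    )


def _align_weights(weights, pool: list[str]) -> np.ndarray:
    if isinstance(weights, (pd.Series, dict)):
        series = pd.Series(weights)
        missing = set(pool) - set(series.index)
        if missing:
            raise NetworkInputError(f"weights missing for species: {sorted(missing)}")
        return series.loc[pool].to_numpy(dtype=float)
    w = np.asarray(weights, dtype=float)
    if len(w) != len(pool):
        raise NetworkInputError("weights must cover the pool")
    return w


# ---------------------------------------------------------------------------
# Between-community distance and ANOSIM
# ---------------------------------------------------------------------------

def comdist(comm_a, comm_b, dist) -> float:
    """Mean phylogenetic distance between two communities.

    Averages over the full cross-product of species pairs (a in A, b in B),
    including identical species (distance 0), so a community against itself
    is not in general 0.
    """
    a = list(comm_a)
    b = list(comm_b)
    if not a or not b:
        raise NetworkInputError("communities must be nonempty")
    labels = list(dict.fromkeys(a + b))
    d = _as_matrix(dist, labels)
    pos = {s: i for i, s in enumerate(labels)}
    ia = np.array([pos[s] for s in a])
    ib = np.array([pos[s] for s in b])
    return float(d[np.ix_(ia, ib)].mean())


def comdist_matrix(communities: dict, dist) -> pd.DataFrame:
    """Pairwise comdist between named communities (e.g. networks)."""
    names = list(communities)
    mat = np.zeros((len(names), len(names)))
    for i, a in enumerate(names):
        for j in range(i, len(names)):
            v = comdist(communities[a], communities[names[j]], dist)
            mat[i, j] = mat[j, i] = v
    return pd.DataFrame(mat, index=names, columns=names)


def anosim(
    dist, groups, n_perm: int = 999, seed: int = 0
) -> tuple[float, float]:
    """Analysis of similarities on a distance matrix.

    R = (mean rank of between-group distances - mean rank of within-group
    distances) / (N(N-1)/4), with tied distances given average ranks.
    The p-value is the permutation rank (r+1)/(n_perm+1) of the observed R
    under random relabelling.  Requires >= 2 groups of >= 2 members.
    """
    if isinstance(dist, pd.DataFrame):
        labels = list(dist.index)
        mat = dist.to_numpy(dtype=float)
        groups = pd.Series(groups)
        if set(labels) <= set(groups.index) and not isinstance(groups.index, pd.RangeIndex):
            g = groups.loc[labels].to_numpy()
        else:
            g = groups.to_numpy()
    else:
        mat = np.asarray(dist, dtype=float)
        g = np.asarray(list(groups))
    n = mat.shape[0]
    if len(g) != n:
        raise NetworkInputError("groups must match the distance matrix size")
    uniq, counts = np.unique(g, return_counts=True)
    if len(uniq) < 2:
        raise NetworkInputError("ANOSIM needs at least 2 groups")
    if counts.min() < 2:
        raise NetworkInputError("every group must have at least 2 members")
    condensed = squareform(mat, checks=False)
    ranks = rankdata(condensed)  # average ranks for ties
    iu, ju = np.triu_indices(n, k=1)
    denom = n * (n - 1) / 4.0

    def r_stat(labels_vec: np.ndarray) -> float:
        within = labels_vec[iu] == labels_vec[ju]
        return float((ranks[~within].mean() - ranks[within].mean()) / denom)

    r_obs = r_stat(g)
    rng = np.random.default_rng(seed)
    count = sum(
        r_stat(rng.permutation(g)) >= r_obs - 1e-12 for _ in range(n_perm)
    )
    return r_obs, (count + 1) / (n_perm + 1)
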