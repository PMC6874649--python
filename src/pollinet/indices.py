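"""Species-level prioritization metrics and network-level structure indices.

Species-level metrics (per plant):

* normalised degree (ND) — partner bee species / total bee species;
* interaction strength (ST) — sum over partner bees of that bee's dependency
  on the plant (its fraction of visits made to the plant), so plant
  strengths sum to the number of bee species;
* closeness (CC) and betweenness (BC) centrality on the unweighted one-mode
  plant projection (two plants adjacent iff they share at least one bee);
* functional complementarity (FC) — leave-one-out contribution to the total
  branch length of a UPGMA dendrogram on Euclidean distances between plant
  visit profiles, i.e. how much visitor-assemblage distinctiveness the plant
  adds.

Network-level indices: number of links, interaction diversity (exponential
Shannon entropy of the interaction frequency distribution), standardized
Kullback-Leibler specialization d' (per species) and H2' (whole network),
the Mueller shared-visitor index (potential for apparent facilitation), and
robustness to random bee extinctions.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .network import DegenerateNetworkError, NetworkInputError, VisitMatrix

__all__ = [
    "species_metrics",
    "plant_projection",
    "functional_complementarity_total",
    "d_prime",
    "h2_prime",
    "shannon_entropy",
    "network_summary",
    "NetworkSummary",
    "muller_pac",
    "robustness",
]


# ---------------------------------------------------------------------------
# Species-level metrics
# ---------------------------------------------------------------------------

def plant_projection(net: VisitMatrix) -> nx.Graph:
    """Unweighted one-mode projection: plants adjacent iff they share a bee."""
    inc = net.incidence
    shared = inc @ inc.T
    g = nx.Graph()
    g.add_nodes_from(net.plant_labels)
    for i, j in zip(*np.nonzero(np.triu(shared, k=1))):
        g.add_edge(net.plant_labels[i], net.plant_labels[j])
    return g


def functional_complementarity_total(counts: np.ndarray) -> float:
    """Total branch length of the UPGMA dendrogram over plant visit rows.

    Computed as the sum of the merge heights of average-linkage clustering
    on Euclidean distances; zero for fewer than two plants.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape[0] < 2:
        return 0.0
    z = linkage(pdist(counts, metric="euclidean"), method="average")
    return float(z[:, 2].sum())


def species_metrics(net: VisitMatrix) -> pd.DataFrame:
    """Per-plant prioritization metric table.

    Returns a DataFrame indexed by plant label with columns
    ``normalized_degree``, ``strength``, ``closeness``, ``betweenness``,
    ``functional_complementarity``, ``total_visits``.

    For a single-plant network the projection-based and leave-one-out
    metrics are reported as 0 with a warning.
    """
    net.validate()
    counts = net.counts.astype(float)
    p, b = net.n_plants, net.n_bees

    nd = (counts > 0).sum(axis=1) / b
    dependencies = counts / counts.sum(axis=0, keepdims=True)
    st = dependencies.sum(axis=1)

    if p == 1:
        warnings.warn("single-plant network: centrality and FC reported as 0")
        cc = np.zeros(1)
        bc = np.zeros(1)
        fc = np.zeros(1)
    else:
        g = plant_projection(net)
        cc_d = nx.closeness_centrality(g)  # Wasserman-Faust component scaling
        bc_d = nx.betweenness_centrality(g, normalized=True)
        cc = np.array([cc_d[pl] for pl in net.plant_labels])
        bc = np.array([bc_d[pl] for pl in net.plant_labels])
        fc_all = functional_complementarity_total(counts)
        fc = np.array(
            [
                fc_all - functional_complementarity_total(np.delete(counts, i, axis=0))
                for i in range(p)
            ]
        )
        # total branch length is not strictly monotone under point removal;
        # the per-species contribution is floored at 0 to keep FC >= 0
        fc = np.maximum(fc, 0.0)

    return pd.DataFrame(
        {
            "normalized_degree": nd,
            "strength": st,
            "closeness": cc,
            "betweenness": bc,
            "functional_complementarity": fc,
            "total_visits": net.plant_totals,
        },
        index=list(net.plant_labels),
    )


# ---------------------------------------------------------------------------
# Kullback-Leibler specialization: d' and H2'
# ---------------------------------------------------------------------------

def _kl(p: np.ndarray, q: np.ndarray) -> float:
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def _d_max_allocation(total: int, q: np.ndarray, caps: np.ndarray) -> np.ndarray:
    """Most-specialized feasible allocation: fill partners in order of
    increasing availability q, each capped at its marginal total."""
    order = np.argsort(q, kind="stable")
    x = np.zeros_like(caps)
    remaining = total
    for i in order:
        take = min(remaining, caps[i])
        x[i] = take
        remaining -= take
        if remaining == 0:
            break
    return x


def _d_min_allocation(total: int, q: np.ndarray) -> np.ndarray:
    """Least-specialized integer allocation.

    Minimizes sum (x_i/A) log(x_i/(A q_i)) over integer allocations summing
    to ``total``.  The objective is separable and convex in each x_i, so
    adding one visit at a time where the marginal increase is smallest
    yields the exact integer optimum.
    """
    n = len(q)
    x = np.zeros(n, dtype=np.int64)
    a = float(total)

    def marginal(xi: int, qi: float) -> float:
        g1 = (xi + 1) / a * math.log((xi + 1) / (a * qi))
        g0 = 0.0 if xi == 0 else xi / a * math.log(xi / (a * qi))
        return g1 - g0

    deltas = np.array([marginal(0, qi) for qi in q])
    for _ in range(total):
        i = int(np.argmin(deltas))
        x[i] += 1
        deltas[i] = marginal(int(x[i]), q[i])
    return x


def d_prime(net: VisitMatrix, side: str = "bees") -> pd.Series:
    """Standardized Kullback-Leibler specialization d' per species.

    For a species j with visit vector a_.j, d = sum_i p'_ij ln(p'_ij / q_i)
    where p' is the species' resource-use distribution and q the partners'
    marginal share of all visits.  d is rescaled to [0, 1] by its discrete
    minimum and maximum given the marginal totals: the maximum fills the
    rarest partners first (each capped at its marginal total); the minimum
    distributes visits as proportionally to q as integer constraints allow
    (exact separable-convex greedy).  Values are clipped to [0, 1].
    """
    net.validate()
    if side == "bees":
        counts = net.counts
    elif side == "plants":
        counts = net.counts.T
    else:
        raise NetworkInputError("side must be 'bees' or 'plants'")
    total = counts.sum()
    q = counts.sum(axis=1) / total  # partner marginal shares
    caps = counts.sum(axis=1)
    out = {}
    labels = net.bee_labels if side == "bees" else net.plant_labels
    for j, label in enumerate(labels):
        col = counts[:, j]
        a = int(col.sum())
        if a == 0:
            raise DegenerateNetworkError(f"species {label!r} has zero visits")
        d_obs = _kl(col / a, q)
        x_max = _d_max_allocation(a, q, caps)
        d_max = _kl(x_max / a, q)
        x_min = _d_min_allocation(a, q)
        d_min = _kl(x_min / a, q)
        if d_max - d_min < 1e-12:
            out[label] = 0.0
        else:
            out[label] = float(np.clip((d_obs - d_min) / (d_max - d_min), 0.0, 1.0))
    return pd.Series(out, name=f"d_prime_{side}")


def shannon_entropy(counts: np.ndarray) -> float:
    """Shannon entropy of the interaction frequency distribution (nats)."""
    p = np.asarray(counts, dtype=float).ravel()
    p = p[p > 0] / p.sum()
    return float(-np.sum(p * np.log(p)))


def _h2_min_table(row_tot: np.ndarray, col_tot: np.ndarray) -> np.ndarray:
    """Greedy marginal-packing heuristic for the most specialized table:
    repeatedly pair the largest remaining row and column marginal."""
    r = row_tot.astype(np.int64).copy()
    c = col_tot.astype(np.int64).copy()
    table = np.zeros((len(r), len(c)), dtype=np.int64)
    while r.sum() > 0:
        i = int(np.argmax(r))
        j = int(np.argmax(c))
        m = min(r[i], c[j])
        table[i, j] += m
        r[i] -= m
        c[j] -= m
    return table


def h2_prime(net: VisitMatrix) -> float:
    """Network-level specialization H2' in [0, 1].

    H2' = (H2_max - H2) / (H2_max - H2_min) where H2 is the Shannon entropy
    of the observed interaction frequencies, H2_max the entropy of the
    independence (outer-product-of-marginals) table — the maximum-entropy
    table with the observed marginals — and H2_min the entropy of a greedy
    marginal-packing table.  0 means interactions follow partner
    availability; 1 means perfect reciprocal specialization.
    """
    net.validate()
    if net.n_plants < 2 or net.n_bees < 2:
        raise DegenerateNetworkError("H2' needs at least 2 plants and 2 bees")
    total = net.grand_total
    h2 = shannon_entropy(net.counts)
    r = net.plant_totals / total
    c = net.bee_totals / total
    h2_max = shannon_entropy(np.outer(r, c))
    h2_min = shannon_entropy(_h2_min_table(net.plant_totals, net.bee_totals))
    if h2_max - h2_min < 1e-12:
        return 0.0
    return float(np.clip((h2_max - h2) / (h2_max - h2_min), 0.0, 1.0))


# ---------------------------------------------------------------------------
# Mueller shared-visitor index
# ---------------------------------------------------------------------------

def muller_pac(
    net: VisitMatrix, include_self: bool = False
) -> tuple[pd.DataFrame, pd.Series]:
    """Mueller shared-flower-visitor index (potential apparent facilitation).

    ``PAC[target i, acting k]`` is the expected contribution of acting plant
    k to the diet of target plant i's visitors:
    ``sum_j (a_ij / A_i.) * (a_kj / A_.j)``.  Each target row sums to 1.

    The per-plant acting score sums a plant's PAC column over all *other*
    targets (self-pairs excluded by default; ``include_self=True`` adds the
    diagonal).
    Returns ``(pac, acting_scores)``.
    """
    net.validate()
    counts = net.counts.astype(float)
    use = counts / counts.sum(axis=1, keepdims=True)  # target's visit shares
    dep = counts / counts.sum(axis=0, keepdims=True)  # bee dependencies
    pac = use @ dep.T  # targets x acting
    labels = list(net.plant_labels)
    pac_df = pd.DataFrame(pac, index=labels, columns=labels)
    acting = pac.sum(axis=0)
    if not include_self:
        acting = acting - np.diag(pac)
    return pac_df, pd.Series(acting, index=labels, name="muller_acting_score")


# ---------------------------------------------------------------------------
# Robustness to random bee extinction
# ---------------------------------------------------------------------------

def _area_from_death_positions(death: np.ndarray, n_bees: int) -> np.ndarray:
    """Trapezoidal area under the plant-survival curve for each removal order.

    ``death[r, p]`` is the removal step (1-based) at which plant p loses its
    last bee in order r; the curve runs through (0, 1) and (1, 0).
    """
    n_orders, n_plants = death.shape
    # y[r, m] = proportion of plants alive after m removals, m = 0..n_bees
    steps = np.arange(n_bees + 1)
    alive = (death[:, None, :] > steps[None, :, None]).mean(axis=2)
    return np.trapezoid(alive, dx=1.0 / n_bees, axis=1)


def robustness(
    net: VisitMatrix,
    n_iter: int = 1000,
    seed: int = 0,
    method: str = "monte_carlo",
) -> float:
    """Robustness to random extinction of bees (higher trophic level).

    Bees are removed uniformly at random one at a time; a plant goes
    secondarily extinct when its last visiting bee is removed.  Robustness
    is the mean (over removal orders) area under the curve of the proportion
    of surviving plants against the proportion of bees removed, with
    endpoints (0, 1) and (1, 0).  ``method='exact'`` enumerates all removal
    orders (guarded to <= 8 bees).
    """
    net.validate()
    if n_iter < 1:
        raise NetworkInputError("n_iter must be >= 1")
    inc = net.incidence
    b = net.n_bees
    if method == "exact":
        if b > 8:
            raise NetworkInputError("exact enumeration limited to <= 8 bees")
        orders = np.array(list(itertools.permutations(range(b))))
    elif method == "monte_carlo":
        rng = np.random.default_rng(seed)
        orders = np.argsort(rng.random((n_iter, b)), axis=1)
    else:
        raise NetworkInputError("method must be 'monte_carlo' or 'exact'")
    # position (1-based) of each bee in each removal order
    pos = np.empty_like(orders)
    np.put_along_axis(pos, orders, np.arange(1, b + 1)[None, :].repeat(len(orders), 0), axis=1)
    death = np.array([pos[:, inc[p]].max(axis=1) for p in range(net.n_plants)]).T
    return float(_area_from_death_positions(death, b).mean())


# ---------------------------------------------------------------------------
# Network summary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkSummary:
    """Network-level structure and function indices."""

    network_id: str
    n_links: int
    interaction_diversity: float
    h2_prime: float  # NaN for degenerate (single plant / single bee) networks
    d_prime_bees: pd.Series
    mean_d_prime_bees: float
    muller_scores: pd.Series
    robustness: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "network_id": [self.network_id],
                "n_links": [self.n_links],
                "interaction_diversity": [self.interaction_diversity],
                "h2_prime": [self.h2_prime],
                "mean_d_prime_bees": [self.mean_d_prime_bees],
                "robustness": [self.robustness],
            }
        )


def network_summary(
    net: VisitMatrix,
    *,
    robustness_iter: int | None = None,
    seed: int = 0,
) -> NetworkSummary:
    """Compute the network-level index bundle.

    ``interaction_diversity`` is exp(Shannon entropy) of the interaction
    frequency distribution, bounded above by the number of links.
    Robustness is computed only when ``robustness_iter`` is given.
    """
    net.validate()
    diversity = math.exp(shannon_entropy(net.counts))
    try:
        h2 = h2_prime(net)
    except DegenerateNetworkError:
        h2 = float("nan")
    dpb = d_prime(net, side="bees")
    _, acting = muller_pac(net)
    rob = (
        robustness(net, n_iter=robustness_iter, seed=seed)
        if robustness_iter
        else None
    )
    return NetworkSummary(
        network_id=net.network_id,
        n_links=net.n_links,
        interaction_diversity=diversity,
        h2_prime=h2,
        d_prime_bees=dpb,
        mean_d_prime_bees=float(dpb.mean()),
        muller_scores=acting,
        robustness=rob,
    )
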