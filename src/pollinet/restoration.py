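"""Simulated bee-community recovery under plant-selection strategies.

A restoration simulation rebuilds a community "from scratch" by adding
plant species in multiples of two (the default step) following a ranking,
until a coverage target is met for one of two criteria:

* ``bee_richness`` — fraction of the original bee species receiving at
  least one visit from the selected plants;
* ``bee_visitation`` — fraction of the original visits retained.

Rankings come from the species-level metric table (ND, ST, CC, BC, FC), a
random baseline (exact hypergeometric expectation or Monte Carlo), a
genetic algorithm over fixed-cardinality plant sets, or an exhaustive
minimum-set search used as a testing oracle.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import indices
from .network import NetworkInputError, VisitMatrix, subnetwork

__all__ = [
    "CRITERIA",
    "METRIC_STRATEGIES",
    "RestorationResult",
    "GAParams",
    "coverage",
    "rank_plants",
    "simulate_greedy",
    "random_baseline",
    "ga_select",
    "ga_max_coverage",
    "brute_force_min_set",
    "threshold_sweep",
    "run_strategy",
]

CRITERIA = ("bee_richness", "bee_visitation")

#: strategy name -> column of the species-metric table
METRIC_STRATEGIES = {
    "ND": "normalized_degree",
    "ST": "strength",
    "CC": "closeness",
    "BC": "betweenness",
    "FC": "functional_complementarity",
}


class SizeLimitError(ValueError):
    """Exhaustive search refused: too many plants."""


@dataclass(frozen=True)
class RestorationResult:
    """Outcome of one network x strategy x criterion x threshold simulation."""

    network_id: str
    strategy: str
    criterion: str
    threshold: float
    selection: tuple[str, ...]
    trajectory: tuple[tuple[int, float], ...]
    n_required: int
    proportion_required: float
    seed: int | None = None

    def to_row(self) -> dict:
        return {
            "network_id": self.network_id,
            "strategy": self.strategy,
            "criterion": self.criterion,
            "threshold": self.threshold,
            "n_required": self.n_required,
            "proportion_required": self.proportion_required,
            "selection": ";".join(self.selection),
            "seed": self.seed,
        }


def _check_criterion(criterion: str) -> None:
    if criterion not in CRITERIA:
        raise NetworkInputError(f"criterion must be one of {CRITERIA}")


def _check_threshold(threshold: float) -> None:
    if not (0 < threshold <= 1):
        raise NetworkInputError("threshold must be in (0, 1]")


def coverage(net: VisitMatrix, plant_set: Iterable[str], criterion: str) -> float:
    """Fraction of the restoration target recovered by ``plant_set``."""
    _check_criterion(criterion)
    wanted = set(plant_set)
    unknown = wanted - set(net.plant_labels)
    if unknown:
        raise NetworkInputError(f"unknown plant labels: {sorted(unknown)}")
    if not wanted:
        return 0.0
    rows = np.array([p in wanted for p in net.plant_labels])
    if criterion == "bee_richness":
        covered = (net.counts[rows].sum(axis=0) > 0).sum()
        return float(covered / net.n_bees)
    return float(net.counts[rows].sum() / net.grand_total)


def rank_plants(metrics: pd.DataFrame, metric: str) -> list[str]:
    """Deterministic ranking: metric descending, ties by total visits
    descending, then label lexicographic."""
    column = METRIC_STRATEGIES.get(metric, metric)
    if column not in metrics.columns:
        raise NetworkInputError(f"unknown metric {metric!r}")
    df = metrics.copy()
    df["_label"] = df.index.astype(str)
    df = df.sort_values(
        by=[column, "total_visits", "_label"],
        ascending=[False, False, True],
        kind="stable",
    )
    return list(df.index)


def _size_grid(n_plants: int, step: int) -> list[int]:
    if step < 1:
        raise NetworkInputError("step must be >= 1")
    sizes = list(range(step, n_plants + 1, step))
    if not sizes or sizes[-1] != n_plants:
        sizes.append(n_plants)
    return sizes


def simulate_greedy(
    net: VisitMatrix,
    ranking: Sequence[str],
    criterion: str,
    threshold: float,
    step: int = 2,
    strategy: str = "ranked",
) -> RestorationResult:
    """Add plants in ranking order at the given step until the target is met."""
    _check_criterion(criterion)
    _check_threshold(threshold)
    if sorted(ranking) != sorted(net.plant_labels):
        raise NetworkInputError("ranking must be a permutation of the plant labels")
    trajectory: list[tuple[int, float]] = []
    n_required = None
    for k in _size_grid(net.n_plants, step):
        cov = coverage(net, ranking[:k], criterion)
        trajectory.append((k, cov))
        if cov >= threshold - 1e-12:
            n_required = k
            break
    if n_required is None:  # full set always reaches coverage 1 >= threshold
        raise NetworkInputError("threshold unreachable even with the full plant set")
    return RestorationResult(
        network_id=net.network_id,
        strategy=strategy,
        criterion=criterion,
        threshold=threshold,
        selection=tuple(ranking[:n_required]),
        trajectory=tuple(trajectory),
        n_required=n_required,
        proportion_required=n_required / net.n_plants,
    )


# ---------------------------------------------------------------------------
# Random baseline
# ---------------------------------------------------------------------------

def _expected_richness_exact(net: VisitMatrix, k: int) -> float:
    """E[richness coverage of a uniform k-subset]: for each bee with P_b
    host plants, P(covered) = 1 - C(P - P_b, k)/C(P, k)."""
    p = net.n_plants
    denom = math.comb(p, k)
    hosts = (net.counts > 0).sum(axis=0)
    probs = [1.0 - math.comb(p - int(pb), k) / denom if p - int(pb) >= k else 1.0
             for pb in hosts]
    return float(np.mean(probs))


def random_baseline(
    net: VisitMatrix,
    criterion: str,
    threshold: float,
    n_sims: int = 1000,
    seed: int = 0,
    mode: str = "exact",
    step: int = 2,
) -> RestorationResult:
    """Mean coverage of uniform random plant subsets per evaluated size.

    ``mode='exact'`` uses closed forms (hypergeometric accumulation for
    richness; E[visitation at k] = k/P by symmetry) and is deterministic;
    ``mode='monte_carlo'`` averages ``n_sims`` uniform subsets per size.
    ``n_required`` is the smallest evaluated size whose *mean* coverage
    meets the threshold.  The result carries no witness selection.
    """
    _check_criterion(criterion)
    _check_threshold(threshold)
    p = net.n_plants
    rng = np.random.default_rng(seed)
    trajectory: list[tuple[int, float]] = []
    n_required = None
    for k in _size_grid(p, step):
        if mode == "exact":
            mean_cov = (
                _expected_richness_exact(net, k)
                if criterion == "bee_richness"
                else k / p
            )
        elif mode == "monte_carlo":
            if n_sims < 1:
                raise NetworkInputError("n_sims must be >= 1 for monte_carlo")
            idx = np.argpartition(rng.random((n_sims, p)), k - 1, axis=1)[:, :k]
            if criterion == "bee_richness":
                inc = net.incidence
                covered = inc[idx].any(axis=1).sum(axis=1)
                mean_cov = float(covered.mean() / net.n_bees)
            else:
                totals = net.plant_totals
                mean_cov = float(totals[idx].sum(axis=1).mean() / net.grand_total)
        else:
            raise NetworkInputError("mode must be 'exact' or 'monte_carlo'")
        trajectory.append((k, mean_cov))
        if n_required is None and mean_cov >= threshold - 1e-12:
            n_required = k
            break
    if n_required is None:
        n_required = p
    return RestorationResult(
        network_id=net.network_id,
        strategy="random",
        criterion=criterion,
        threshold=threshold,
        selection=(),
        trajectory=tuple(trajectory),
        n_required=n_required,
        proportion_required=n_required / p,
        seed=seed if mode == "monte_carlo" else None,
    )


# ---------------------------------------------------------------------------
# Genetic algorithm
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GAParams:
    """Hyperparameters for the fixed-cardinality set-selection GA.

    Defaults are sized for reliable convergence on networks of up to ~100
    plants; every field is overridable.  ``patience`` stops a run early when
    the best fitness has not improved for that many generations.
    """

    population: int = 100
    generations: int = 200
    tournament: int = 3
    crossover_rate: float = 0.9
    mutation_rate: float = 0.02
    elitism: int = 1
    patience: int = 30

    def __post_init__(self) -> None:
        if self.population < 2 or self.generations < 1 or self.tournament < 1:
            raise NetworkInputError("invalid GA parameters")
        if not (0 <= self.crossover_rate <= 1 and 0 <= self.mutation_rate <= 1):
            raise NetworkInputError("GA rates must be in [0, 1]")


def _fitness(pop: np.ndarray, net: VisitMatrix, criterion: str) -> np.ndarray:
    if criterion == "bee_richness":
        covered = (pop @ net.incidence) > 0
        return covered.sum(axis=1) / net.n_bees
    return (pop @ net.plant_totals) / net.grand_total


def _repair(mask: np.ndarray, k: int, rng: np.random.Generator) -> None:
    """In-place cardinality repair by random swaps."""
    ones = np.flatnonzero(mask)
    if len(ones) > k:
        drop = rng.choice(ones, size=len(ones) - k, replace=False)
        mask[drop] = False
    elif len(ones) < k:
        zeros = np.flatnonzero(~mask)
        add = rng.choice(zeros, size=k - len(ones), replace=False)
        mask[add] = True


def ga_max_coverage(
    net: VisitMatrix,
    criterion: str,
    k: int,
    params: GAParams | None = None,
    seed: int = 0,
) -> tuple[tuple[str, ...], float]:
    """Evolve fixed-cardinality plant sets maximizing coverage.

    Chromosomes are k-of-P bit vectors; tournament selection, one-point
    cardinality-preserving crossover (repair by random swap), per-bit swap
    mutation, elitism.  Deterministic given the seed.  Returns the best
    plant set and its coverage.
    """
    _check_criterion(criterion)
    params = params or GAParams()
    p = net.n_plants
    if not (1 <= k <= p):
        raise NetworkInputError("k must be in [1, n_plants]")
    rng = np.random.default_rng(seed)
    n = params.population
    pop = np.zeros((n, p), dtype=bool)
    for i in range(n):
        pop[i, rng.choice(p, size=k, replace=False)] = True
    fit = _fitness(pop, net, criterion)
    best_i = int(np.argmax(fit))
    best_mask, best_fit = pop[best_i].copy(), float(fit[best_i])
    stall = 0
    for _ in range(params.generations):
        # tournament selection of parents
        contenders = rng.integers(0, n, size=(n, params.tournament))
        parents = contenders[np.arange(n), np.argmax(fit[contenders], axis=1)]
        children = pop[parents].copy()
        # one-point crossover on consecutive pairs
        for a in range(0, n - 1, 2):
            if rng.random() < params.crossover_rate:
                c = rng.integers(1, p)
                children[a, c:], children[a + 1, c:] = (
                    children[a + 1, c:].copy(),
                    children[a, c:].copy(),
                )
        for child in children:
            _repair(child, k, rng)
            # per-bit swap mutation on set bits
            ones = np.flatnonzero(child)
            swaps = ones[rng.random(k) < params.mutation_rate]
            if len(swaps):
                zeros = np.flatnonzero(~child)
                repl = rng.choice(zeros, size=len(swaps), replace=False)
                child[swaps] = False
                child[repl] = True
        # elitism: reinsert current best
        children[: params.elitism] = best_mask
        pop = children
        fit = _fitness(pop, net, criterion)
        gen_best = int(np.argmax(fit))
        if fit[gen_best] > best_fit + 1e-12:
            best_mask, best_fit = pop[gen_best].copy(), float(fit[gen_best])
            stall = 0
        else:
            stall += 1
            if stall >= params.patience:
                break
    selection = tuple(
        sorted(
            (net.plant_labels[i] for i in np.flatnonzero(best_mask)),
            key=lambda lab: -net.plant_totals[net.plant_labels.index(lab)],
        )
    )
    return selection, best_fit


def ga_select(
    net: VisitMatrix,
    criterion: str,
    threshold: float,
    ga_params: GAParams | None = None,
    seed: int = 0,
    step: int = 2,
) -> RestorationResult:
    """Smallest plant set (on the step grid) found by the GA that meets the
    coverage target."""
    _check_threshold(threshold)
    ga_params = ga_params or GAParams()
    trajectory: list[tuple[int, float]] = []
    seeds = np.random.SeedSequence(seed).generate_state(len(_size_grid(net.n_plants, step)))
    for k, k_seed in zip(_size_grid(net.n_plants, step), seeds):
        selection, fit = ga_max_coverage(
            net, criterion, k, params=ga_params, seed=int(k_seed % (2**31))
        )
        trajectory.append((k, fit))
        if fit >= threshold - 1e-12:
            return RestorationResult(
                network_id=net.network_id,
                strategy="GA",
                criterion=criterion,
                threshold=threshold,
                selection=selection,
                trajectory=tuple(trajectory),
                n_required=k,
                proportion_required=k / net.n_plants,
                seed=seed,
            )
    # full plant set has coverage 1 and is always on the grid
    raise NetworkInputError("threshold unreachable even with the full plant set")


# ---------------------------------------------------------------------------
# Exhaustive oracle
# ---------------------------------------------------------------------------

def brute_force_min_set(
    net: VisitMatrix, criterion: str, threshold: float
) -> RestorationResult:
    """Exact minimum-cardinality plant set meeting the coverage target.

    For the (additive) visitation criterion, taking plants in descending
    total-visit order is provably optimal at every cardinality; for
    richness the search enumerates subsets (guarded to <= 20 plants).
    ``threshold=0`` yields the empty set.
    """
    _check_criterion(criterion)
    if threshold < 0 or threshold > 1:
        raise NetworkInputError("threshold must be in [0, 1]")
    p = net.n_plants
    if threshold <= 0:
        return RestorationResult(
            net.network_id, "brute_force", criterion, threshold,
            (), ((0, 0.0),), 0, 0.0,
        )
    if criterion == "bee_visitation":
        totals = net.plant_totals
        order = np.lexsort((list(net.plant_labels), -totals))
        cum = np.cumsum(totals[order]) / net.grand_total
        n_req = int(np.argmax(cum >= threshold - 1e-12)) + 1
        sel = tuple(net.plant_labels[i] for i in order[:n_req])
        return RestorationResult(
            net.network_id, "brute_force", criterion, threshold,
            sel, ((n_req, float(cum[n_req - 1])),), n_req, n_req / p,
        )
    if p > 20:
        raise SizeLimitError("exhaustive search limited to <= 20 plants")
    masks = [
        int.from_bytes(np.packbits(net.incidence[i]).tobytes(), "big")
        for i in range(p)
    ]
    needed = threshold * net.n_bees - 1e-9
    for n_req in range(1, p + 1):
        best = None
        for combo in itertools.combinations(range(p), n_req):
            acc = 0
            for i in combo:
                acc |= masks[i]
            if acc.bit_count() >= needed:
                best = combo
                break
        if best is not None:
            sel = tuple(net.plant_labels[i] for i in best)
            cov = coverage(net, sel, criterion)
            return RestorationResult(
                net.network_id, "brute_force", criterion, threshold,
                sel, ((n_req, cov),), n_req, n_req / p,
            )
    raise NetworkInputError("threshold unreachable even with the full plant set")


# ---------------------------------------------------------------------------
# Strategy dispatch and threshold sweep
# ---------------------------------------------------------------------------

def run_strategy(
    net: VisitMatrix,
    strategy: str,
    criterion: str,
    threshold: float,
    *,
    step: int = 2,
    seed: int = 0,
    metrics: pd.DataFrame | None = None,
    ga_params: GAParams | None = None,
    n_sims: int = 1000,
    random_mode: str = "exact",
) -> RestorationResult:
    """Run one named selection strategy (metric ranking, ``random`` or ``GA``)."""
    if strategy in METRIC_STRATEGIES:
        if metrics is None:
            metrics = indices.species_metrics(net)
        ranking = rank_plants(metrics, strategy)
        return simulate_greedy(net, ranking, criterion, threshold, step=step,
                               strategy=strategy)
    if strategy == "random":
        return random_baseline(net, criterion, threshold, n_sims=n_sims,
                               seed=seed, mode=random_mode, step=step)
    if strategy == "GA":
        return ga_select(net, criterion, threshold, ga_params=ga_params,
                         seed=seed, step=step)
    if strategy == "brute_force":
        return brute_force_min_set(net, criterion, threshold)
    raise NetworkInputError(f"unknown strategy {strategy!r}")


def threshold_sweep(
    net: VisitMatrix,
    strategy: str,
    criterion: str,
    thresholds: Sequence[float] = tuple(np.round(np.arange(0.1, 0.91, 0.1), 2)),
    *,
    step: int = 2,
    seed: int = 0,
    robustness_iter: int = 200,
    metrics: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Coverage-target sweep: plants required and restored-network robustness.

    For each threshold, runs the strategy, induces the restored subnetwork
    from its selection (a uniform random set of the required size for the
    ``random`` strategy) and measures robustness to random bee extinction.
    """
    if list(thresholds) != sorted(thresholds) or not all(0 < t < 1 for t in thresholds):
        raise NetworkInputError("thresholds must be ascending values in (0, 1)")
    if metrics is None and strategy in METRIC_STRATEGIES:
        metrics = indices.species_metrics(net)
    rng = np.random.default_rng(seed)
    rows = []
    for t in thresholds:
        res = run_strategy(net, strategy, criterion, t, step=step, seed=seed,
                           metrics=metrics)
        selection = res.selection
        if not selection:  # random baseline: draw a witness set of that size
            selection = tuple(
                rng.choice(net.plant_labels, size=res.n_required, replace=False)
            )
        sub = subnetwork(net, selection)
        rob = indices.robustness(sub, n_iter=robustness_iter, seed=seed)
        rows.append(
            {
                "network_id": net.network_id,
                "strategy": strategy,
                "criterion": criterion,
                "threshold": t,
                "n_required": res.n_required,
                "proportion_required": res.proportion_required,
                "robustness": rob,
            }
        )
    return pd.DataFrame(rows)
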