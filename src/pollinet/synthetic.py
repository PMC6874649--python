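"""Synthetic visitation networks, family-structured phylogenies and
trait-conservation scenarios.

The generator emulates the statistical structure of tropical plant-bee
visitation surveys: right-skewed visit distributions dominated by a few
supergeneralist bees (lognormal abundance weights), sparse matrices with a
generalist core (a neutral abundance-product term), an optional
partner-specific affinity term controlling specialization, plant families
of unequal size on an ultrametric phylogeny, and an optional
phylogenetically conserved plant-generalism trait (Brownian motion on the
tree blended with white noise).

Visits are allocated multinomially so the configured total is exact, which
keeps visitation-coverage denominators deterministic.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .network import (
    DegenerateNetworkError,
    NetworkInputError,
    VisitMatrix,
    drop_empty,
    write_network,
)
from . import phylo

__all__ = [
    "SyntheticConfig",
    "gen_network",
    "gen_tree",
    "gen_conserved_scenario",
    "write_toy24",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the network generator.

    ``plant_abundance_sigma`` / ``bee_abundance_sigma`` are lognormal shape
    parameters of the abundance weights (sigma >= 1 gives the heavy-tailed,
    supergeneralist-dominated regime typical of these surveys);
    ``specialization`` (theta in [0, 1]) mixes the neutral abundance-product
    interaction rates with a sparse partner-specific affinity matrix;
    ``phylo_signal`` (lambda in [0, 1]) blends a Brownian trait on the
    phylogeny with white noise when generating conserved-generalism
    scenarios.
    """

    n_plants: int = 30
    n_bees: int = 40
    total_visits: int = 2000
    plant_abundance_sigma: float = 1.2
    bee_abundance_sigma: float = 1.2
    specialization: float = 0.3
    n_families: int = 8
    phylo_signal: float = 0.0
    seed: int = 0
    network_id: str = "synthetic"
    biome: str = "unspecified"
    affinity_kind: str = "sparse"  # or "one_to_one"

    def __post_init__(self) -> None:
        if min(self.n_plants, self.n_bees, self.total_visits, self.n_families) < 1:
            raise NetworkInputError("counts must be positive")
        if not (0 <= self.specialization <= 1 and 0 <= self.phylo_signal <= 1):
            raise NetworkInputError("specialization and phylo_signal must be in [0, 1]")
        if min(self.plant_abundance_sigma, self.bee_abundance_sigma) < 0:
            raise NetworkInputError("sigmas must be nonnegative")


def _affinity(cfg: SyntheticConfig, n_p: int, n_b: int,
              bee_w: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    aff = np.zeros((n_p, n_b))
    if cfg.affinity_kind == "one_to_one":
        for j in range(n_b):
            aff[j % n_p, j] = bee_w[j]
    elif cfg.affinity_kind == "sparse":
        for j in range(n_b):
            n_pref = int(rng.integers(1, 4))
            plants = rng.choice(n_p, size=min(n_pref, n_p), replace=False)
            aff[plants, j] = rng.exponential(size=len(plants)) * bee_w[j]
    else:
        raise NetworkInputError("affinity_kind must be 'sparse' or 'one_to_one'")
    return aff


def gen_network(
    cfg: SyntheticConfig,
    *,
    plant_weights: np.ndarray | None = None,
    bee_weights: np.ndarray | None = None,
    plant_labels: list[str] | None = None,
    bee_labels: list[str] | None = None,
) -> VisitMatrix:
    """Generate one visitation network; deterministic given ``cfg.seed``.

    Explicit weights/labels override the lognormal draws (used by the
    conserved-generalism scenario and the fixture writer).  Empty rows or
    columns after multinomial allocation are dropped; a configuration that
    empties the network is retried with up to 10 derived seeds.
    """
    seq = np.random.SeedSequence(cfg.seed)
    n_p = len(plant_labels) if plant_labels is not None else cfg.n_plants
    n_b = len(bee_labels) if bee_labels is not None else cfg.n_bees
    last_err: Exception | None = None
    for child in seq.spawn(10):
        rng = np.random.default_rng(child)
        pw = (
            np.asarray(plant_weights, dtype=float)
            if plant_weights is not None
            else rng.lognormal(0.0, cfg.plant_abundance_sigma, size=n_p)
        )
        bw = (
            np.asarray(bee_weights, dtype=float)
            if bee_weights is not None
            else rng.lognormal(0.0, cfg.bee_abundance_sigma, size=n_b)
        )
        neutral = np.outer(pw, bw)
        neutral /= neutral.sum()
        theta = cfg.specialization
        if theta > 0:
            aff = _affinity(cfg, n_p, n_b, bw, rng)
            aff /= aff.sum()
            rates = (1 - theta) * neutral + theta * aff
        else:
            rates = neutral
        counts = rng.multinomial(cfg.total_visits, rates.ravel()).reshape(n_p, n_b)
        plants = tuple(plant_labels) if plant_labels else tuple(
            f"plant_{i+1:03d}" for i in range(n_p)
        )
        bees = tuple(bee_labels) if bee_labels else tuple(
            f"bee_{j+1:03d}" for j in range(n_b)
        )
        net = VisitMatrix(plants, bees, counts, network_id=cfg.network_id,
                          biome=cfg.biome)
        try:
            return drop_empty(net)
        except DegenerateNetworkError as err:
            last_err = err
    raise DegenerateNetworkError(
        f"configuration produced an empty network in 10 attempts: {last_err}"
    )


# ---------------------------------------------------------------------------
# Phylogenies
# ---------------------------------------------------------------------------

def _random_ultrametric(labels: list[str], rng: np.random.Generator,
                        height: float) -> str:
    """Newick fragment of a random ultrametric tree over ``labels``.

    Random sequential pair-merging (Yule-distributed topology) with
    exponential waiting times rescaled so the root sits at ``height``.
    """
    if len(labels) == 1:
        return f"{labels[0]}:0"  # caller adds the stem
    clusters: list[tuple[str, float]] = [(lab, 0.0) for lab in labels]
    times = np.cumsum(rng.exponential(size=len(labels) - 1))
    times = times / times[-1] * height
    for t in times:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        (na, ha), (nb, hb) = clusters[i], clusters[j]
        merged = (f"({na}:{t - ha:.10g},{nb}:{t - hb:.10g})", float(t))
        clusters = [c for idx, c in enumerate(clusters) if idx not in (i, j)]
        clusters.append(merged)
    return clusters[0][0]


def gen_tree(
    n_families: int,
    species_per_family: int,
    seed: int = 0,
    *,
    family_height: float = 0.3,
    total_height: float = 1.0,
) -> tuple[dendropy.Tree, dict[str, str]]:
    """Ultrametric plant phylogeny with family structure.

    Families are subtrees of depth ``family_height`` grafted onto a stem
    tree whose internal nodes lie between ``(family_height + total_height)/2``
    and ``total_height``, so within-family distances are always smaller than
    between-family distances.  Returns the tree and a leaf -> family map.
    """
    if n_families < 1 or species_per_family < 1:
        raise NetworkInputError("sizes must be positive")
    rng = np.random.default_rng(seed)
    family_map: dict[str, str] = {}
    fam_fragments: list[str] = []
    for f in range(n_families):
        fam = f"Fam{f+1:02d}"
        leaves = [f"{fam}_sp{s+1:02d}" for s in range(species_per_family)]
        for leaf in leaves:
            family_map[leaf] = fam
        frag = _random_ultrametric(leaves, rng, family_height)
        if species_per_family == 1:
            frag = leaves[0]  # bare leaf; stem added at the family level
        fam_fragments.append(frag)
    if n_families == 1:
        newick = f"({fam_fragments[0]}:{total_height - family_height:.10g});"
    else:
        lo = (family_height + total_height) / 2
        clusters = [(frag, family_height if species_per_family > 1 else 0.0)
                    for frag in fam_fragments]
        times = np.cumsum(rng.exponential(size=n_families - 1))
        times = lo + times / times[-1] * (total_height - lo)
        for t in times:
            i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
            (na, ha), (nb, hb) = clusters[i], clusters[j]
            merged = (f"({na}:{t - ha:.10g},{nb}:{t - hb:.10g})", float(t))
            clusters = [c for idx, c in enumerate(clusters) if idx not in (i, j)]
            clusters.append(merged)
        newick = clusters[0][0] + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    return tree, family_map


def gen_conserved_scenario(
    tree: dendropy.Tree,
    lam: float,
    cfg: SyntheticConfig,
) -> tuple[VisitMatrix, pd.Series]:
    """Network whose plant generalism is phylogenetically conserved.

    A log-abundance trait is simulated as Brownian motion on the tree
    (covariance = shared root-to-tip path length) and blended with white
    noise: trait = sqrt(lambda) * brownian + sqrt(1 - lambda) * noise, both
    standardized, so lambda = 1 is pure Brownian and lambda = 0 pure noise.
    This is a controllable signal knob, not an estimate of any empirical
    branch-length transformation.  The trait is exponentiated (scaled by
    ``plant_abundance_sigma``) into plant abundance weights.  Returns the
    generated network and the trait vector.
    """
    if not (0 <= lam <= 1):
        raise NetworkInputError("lambda must be in [0, 1]")
    dist = phylo.cophenetic_distances(tree)
    leaves = list(dist.index)
    d = dist.to_numpy()
    depth = d.max() / 2.0
    cov = depth - d / 2.0 + 1e-9 * np.eye(len(leaves))
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    chol = np.linalg.cholesky(cov)
    brown = chol @ rng.standard_normal(len(leaves))
    noise = rng.standard_normal(len(leaves))

    def standardize(x: np.ndarray) -> np.ndarray:
        return (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)

    trait = np.sqrt(lam) * standardize(brown) + np.sqrt(1 - lam) * standardize(noise)
    weights = np.exp(cfg.plant_abundance_sigma * trait)
    net = gen_network(cfg, plant_weights=weights, plant_labels=leaves)
    return net, pd.Series(trait, index=leaves, name="log_abundance_trait")


# ---------------------------------------------------------------------------
# Reproducible demo fixture
# ---------------------------------------------------------------------------

def write_toy24(outdir, seed: int = 0, n_networks: int = 6) -> dict:
    """Write a small reproducible demo dataset ("toy24").

    ``n_networks`` networks over a shared 40-species plant pool (10 families
    of 4) on an ultrametric tree, split between two biome labels whose plant
    communities are drawn from different family blocks; a global bee pool
    with a flagged non-native honeybee present in every network.  Emits
    matrix CSVs, the Newick tree, a family map, species metadata and
    per-network metadata; returns the written paths.
    """
    outdir = str(outdir)
    os.makedirs(os.path.join(outdir, "networks"), exist_ok=True)
    rng = np.random.default_rng(seed)
    tree, family_map = gen_tree(10, 4, seed=seed)
    pool = list(family_map)
    bees = ["Apis_mellifera"] + [f"bee_{j:02d}" for j in range(1, 20)]

    meta_rows = []
    net_paths = []
    for i in range(n_networks):
        biome = "forest" if i < n_networks // 2 else "savannah"
        # biome-specific family preference: forest favours Fam01-05
        fam_idx = np.array([int(family_map[p][3:]) for p in pool])
        pref = np.where(fam_idx <= 5, 4.0, 1.0) if biome == "forest" else np.where(
            fam_idx <= 5, 1.0, 4.0
        )
        pref = pref / pref.sum()
        plants = list(rng.choice(pool, size=15, replace=False, p=pref))
        bee_subset = ["Apis_mellifera"] + list(
            rng.choice(bees[1:], size=11, replace=False)
        )
        bw = rng.lognormal(0.0, 1.0, size=len(bee_subset))
        bw[0] *= 8.0  # supergeneralist honeybee
        cfg = SyntheticConfig(
            total_visits=400,
            plant_abundance_sigma=1.2,
            specialization=0.3,
            seed=int(rng.integers(2**31)),
            network_id=f"net{i+1:02d}",
            biome=biome,
        )
        net = gen_network(cfg, plant_labels=plants, bee_labels=bee_subset,
                          bee_weights=bw)
        path = os.path.join(outdir, "networks", f"{net.network_id}.csv")
        write_network(net, path)
        net_paths.append(path)
        meta_rows.append({"network_id": net.network_id, "biome": biome})

    tree_path = os.path.join(outdir, "tree.nwk")
    tree.write(path=tree_path, schema="newick", suppress_rooting=True,
               unquoted_underscores=True)
    fam_path = os.path.join(outdir, "family_map.csv")
    pd.DataFrame(
        {"plant": list(family_map), "family": list(family_map.values())}
    ).to_csv(fam_path, index=False)
    meta_path = os.path.join(outdir, "metadata.csv")
    pd.DataFrame(meta_rows).to_csv(meta_path, index=False)
    species_path = os.path.join(outdir, "species_meta.csv")
    rows = [{"species": p, "role": "plant", "family": family_map[p], "flags": ""}
            for p in pool]
    rows += [
        {
            "species": b,
            "role": "bee",
            "family": "",
            "flags": "non_native_honeybee" if b == "Apis_mellifera" else "",
        }
        for b in bees
    ]
    pd.DataFrame(rows).to_csv(species_path, index=False)
    return {
        "networks": net_paths,
        "tree": tree_path,
        "family_map": fam_path,
        "metadata": meta_path,
        "species_meta": species_path,
    }
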