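"""Quantitative bipartite visitation networks: data model, I/O, validation, filtering.

The central object is :class:`VisitMatrix`, a plants x bees matrix of
nonnegative integer visit counts.  Visitation data are visit *tallies*, so
fractional values in input files are rejected rather than rounded.  Label
order is the file's first-appearance order and is preserved through every
operation, so seeded stochastic procedures downstream are reproducible.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BIOMES = ("forest", "savannah", "unspecified")

#: metadata flag marking a non-native honeybee (e.g. Apis mellifera)
HONEYBEE_FLAG = "non_native_honeybee"


class NetworkInputError(ValueError):
    """Malformed input: negative/non-integer counts, duplicate or unknown labels."""


class DegenerateNetworkError(ValueError):
    """An operation produced a network with no plants or no bees."""


@dataclass(frozen=True, eq=False)
class VisitMatrix:
    """A quantitative plant-bee visitation network.

    Parameters
    ----------
    plant_labels, bee_labels
        Ordered unique species labels for each level.  Plants and bees live
        in disjoint namespaces.
    counts
        plants x bees matrix of nonnegative integer visit counts.
    network_id
        Identifier used in output tables.
    biome
        One of ``forest``, ``savannah``, ``unspecified``.
    """

    plant_labels: tuple[str, ...]
    bee_labels: tuple[str, ...]
    counts: np.ndarray
    network_id: str = ""
    biome: str = "unspecified"

    def __post_init__(self) -> None:
        plants = tuple(str(p) for p in self.plant_labels)
        bees = tuple(str(b) for b in self.bee_labels)
        object.__setattr__(self, "plant_labels", plants)
        object.__setattr__(self, "bee_labels", bees)
        if len(set(plants)) != len(plants):
            raise NetworkInputError("duplicate plant labels")
        if len(set(bees)) != len(bees):
            raise NetworkInputError("duplicate bee labels")
        if set(plants) & set(bees):
            raise NetworkInputError(
                "plant and bee labels must be disjoint namespaces: "
                f"{sorted(set(plants) & set(bees))}"
            )
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape != (len(plants), len(bees)):
            raise NetworkInputError(
                f"counts shape {arr.shape} does not match labels "
                f"({len(plants)} plants, {len(bees)} bees)"
            )
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr)) or np.any(np.mod(arr, 1) != 0):
                raise NetworkInputError("visit counts must be integers (tallies)")
        arr = arr.astype(np.int64)
        if np.any(arr < 0):
            raise NetworkInputError("visit counts must be nonnegative")
        arr.setflags(write=False)
        object.__setattr__(self, "counts", arr)
        if self.biome not in BIOMES:
            raise NetworkInputError(f"biome must be one of {BIOMES}")

    # -- basic geometry -------------------------------------------------
    @property
    def n_plants(self) -> int:
        return len(self.plant_labels)

    @property
    def n_bees(self) -> int:
        return len(self.bee_labels)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    @property
    def plant_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def bee_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def incidence(self) -> np.ndarray:
        """Boolean plants x bees interaction (link) matrix."""
        return self.counts > 0

    @property
    def n_links(self) -> int:
        return int(np.count_nonzero(self.counts))

    def plant_index(self, label: str) -> int:
        try:
            return self.plant_labels.index(label)
        except ValueError:
            raise NetworkInputError(f"unknown plant label: {label!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.plant_labels), columns=list(self.bee_labels)
        )

    def validate(self) -> "VisitMatrix":
        """Assert the post-load invariant: every species has at least one visit."""
        if self.n_plants == 0 or self.n_bees == 0:
            raise DegenerateNetworkError("network has no plants or no bees")
        if np.any(self.plant_totals == 0) or np.any(self.bee_totals == 0):
            raise NetworkInputError(
                "network contains species with zero visits; apply drop_empty first"
            )
        return self

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VisitMatrix):
            return NotImplemented
        return (
            self.plant_labels == other.plant_labels
            and self.bee_labels == other.bee_labels
            and np.array_equal(self.counts, other.counts)
            and self.network_id == other.network_id
            and self.biome == other.biome
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"VisitMatrix(id={self.network_id!r}, {self.n_plants} plants x "
            f"{self.n_bees} bees, {self.grand_total} visits, biome={self.biome})"
        )


@dataclass(frozen=True)
class SpeciesMeta:
    """Per-species metadata: trophic role, family, and flags."""

    species_label: str
    role: str  # "plant" | "bee"
    family: str | None = None
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.role not in ("plant", "bee"):
            raise NetworkInputError(f"role must be 'plant' or 'bee', got {self.role!r}")
        object.__setattr__(self, "flags", frozenset(self.flags))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_network(
    path,
    format: str = "matrix_csv",
    *,
    network_id: str | None = None,
    biome: str = "unspecified",
    clean: bool = True,
) -> VisitMatrix:
    """Read a visitation network from disk.

    ``matrix_csv`` files carry bee labels in the header row and plant labels
    in the first column.  ``edge_list`` files carry columns
    ``plant,bee,visits`` (comma- or tab-delimited, autodetected from the
    header); duplicate rows for the same (plant, bee) pair are summed.

    All-zero species are dropped by default (``clean=True``); the source data
    format does not guarantee their absence.
    """
    path = str(path)
    if network_id is None:
        import os

        network_id = os.path.splitext(os.path.basename(path))[0]
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    delim = _sniff_delimiter(header)

    if format == "matrix_csv":
        bee_labels = [c.strip() for c in next(csv.reader([header], delimiter=delim))][1:]
        if len(set(bee_labels)) != len(bee_labels):
            raise NetworkInputError("duplicate bee label in matrix_csv header")
        df = pd.read_csv(path, sep=delim, index_col=0, dtype=str)
        if df.index.duplicated().any():
            raise NetworkInputError("duplicate plant label in matrix_csv")
        try:
            vals = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise NetworkInputError(f"non-numeric count in {path}: {exc}") from exc
        net = VisitMatrix(
            tuple(df.index.astype(str)), tuple(bee_labels), vals,
            network_id=network_id, biome=biome,
        )
    elif format == "edge_list":
        df = pd.read_csv(path, sep=delim)
        required = {"plant", "bee", "visits"}
        if not required.issubset(df.columns):
            raise NetworkInputError(
                f"edge list must have columns {sorted(required)}, got {list(df.columns)}"
            )
        visits = pd.to_numeric(df["visits"], errors="coerce")
        if visits.isna().any():
            raise NetworkInputError("non-numeric visit count in edge list")
        if (visits < 0).any():
            raise NetworkInputError("negative visit count in edge list")
        plants = list(dict.fromkeys(df["plant"].astype(str)))
        bees = list(dict.fromkeys(df["bee"].astype(str)))
        counts = np.zeros((len(plants), len(bees)))
        pi = {p: i for i, p in enumerate(plants)}
        bi = {b: j for j, b in enumerate(bees)}
        for p, b, v in zip(df["plant"].astype(str), df["bee"].astype(str), visits):
            counts[pi[p], bi[b]] += v
        net = VisitMatrix(tuple(plants), tuple(bees), counts,
                          network_id=network_id, biome=biome)
    else:
        raise NetworkInputError(f"unknown format {format!r}")

    return drop_empty(net) if clean else net


def write_network(net: VisitMatrix, path, format: str = "matrix_csv") -> None:
    """Write a network in one of the two supported text formats."""
    path = str(path)
    if format == "matrix_csv":
        net.to_frame().to_csv(path)
    elif format == "edge_list":
        rows = [
            {"plant": p, "bee": b, "visits": int(net.counts[i, j])}
            for i, p in enumerate(net.plant_labels)
            for j, b in enumerate(net.bee_labels)
            if net.counts[i, j] > 0
        ]
        pd.DataFrame(rows, columns=["plant", "bee", "visits"]).to_csv(path, index=False)
    else:
        raise NetworkInputError(f"unknown format {format!r}")


def read_species_meta(path) -> list[SpeciesMeta]:
    """Read species metadata CSV with header ``species,role,family,flags``.

    ``flags`` is a ``;``-separated list and may be empty; ``family`` may be
    empty for bees.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    if not {"species", "role"}.issubset(df.columns):
        raise NetworkInputError("species metadata needs columns species,role[,family,flags]")
    metas = []
    for _, row in df.iterrows():
        flags = frozenset(f for f in str(row.get("flags", "")).split(";") if f)
        family = str(row.get("family", "")) or None
        metas.append(
            SpeciesMeta(str(row["species"]), str(row["role"]), family, flags)
        )
    return metas


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def drop_empty(net: VisitMatrix) -> VisitMatrix:
    """Remove all-zero rows and columns, iterating to a fixed point.

    Raises :class:`DegenerateNetworkError` if nothing remains on either level.
    """
    counts = net.counts
    plants = list(net.plant_labels)
    bees = list(net.bee_labels)
    removed: list[str] = []
    while True:
        row_ok = counts.sum(axis=1) > 0
        col_ok = counts.sum(axis=0) > 0
        if row_ok.all() and col_ok.all():
            break
        removed += [p for p, ok in zip(plants, row_ok) if not ok]
        removed += [b for b, ok in zip(bees, col_ok) if not ok]
        counts = counts[np.ix_(row_ok, col_ok)]
        plants = [p for p, ok in zip(plants, row_ok) if ok]
        bees = [b for b, ok in zip(bees, col_ok) if ok]
        if not plants or not bees:
            raise DegenerateNetworkError(
                f"network {net.network_id!r} is empty after removing zero-visit species"
            )
    if removed:
        logger.info("drop_empty(%s): removed %s", net.network_id, removed)
    return VisitMatrix(tuple(plants), tuple(bees), counts,
                       network_id=net.network_id, biome=net.biome)


def exclude_honeybee(net: VisitMatrix, meta: Iterable[SpeciesMeta]) -> VisitMatrix:
    """Remove flagged non-native honeybee columns and the plant rows they
    exclusively supported.

    All other counts are unchanged.  Raises
    :class:`DegenerateNetworkError` if the exclusion empties the network.
    """
    flagged = {
        m.species_label
        for m in meta
        if m.role == "bee" and HONEYBEE_FLAG in m.flags
    }
    keep_cols = [b not in flagged for b in net.bee_labels]
    if all(keep_cols):
        return net
    if not any(keep_cols):
        raise DegenerateNetworkError("all bees are flagged as non-native honeybees")
    counts = net.counts[:, np.array(keep_cols)]
    bees = tuple(b for b, k in zip(net.bee_labels, keep_cols) if k)
    keep_rows = counts.sum(axis=1) > 0
    dropped = [p for p, k in zip(net.plant_labels, keep_rows) if not k]
    if dropped:
        logger.info("exclude_honeybee(%s): dropped exclusively honeybee-visited "
                    "plants %s", net.network_id, dropped)
    if not keep_rows.any():
        raise DegenerateNetworkError("honeybee exclusion removed every plant")
    plants = tuple(p for p, k in zip(net.plant_labels, keep_rows) if k)
    return VisitMatrix(plants, bees, counts[keep_rows], network_id=net.network_id,
                       biome=net.biome)


def subnetwork(net: VisitMatrix, plant_set: Iterable[str]) -> VisitMatrix:
    """Induced subnetwork on a plant subset (restored community).

    Rows are restricted to ``plant_set`` (kept in the parent network's
    order); bee columns left with zero visits are removed; counts are
    otherwise unchanged.
    """
    wanted = set(plant_set)
    if not wanted:
        raise NetworkInputError("plant_set must be nonempty")
    unknown = wanted - set(net.plant_labels)
    if unknown:
        raise NetworkInputError(f"unknown plant labels: {sorted(unknown)}")
    keep_rows = [p in wanted for p in net.plant_labels]
    counts = net.counts[np.array(keep_rows)]
    keep_cols = counts.sum(axis=0) > 0
    return VisitMatrix(
        tuple(p for p, k in zip(net.plant_labels, keep_rows) if k),
        tuple(b for b, k in zip(net.bee_labels, keep_cols) if k),
        counts[:, keep_cols],
        network_id=net.network_id,
        biome=net.biome,
    )
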