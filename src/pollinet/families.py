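"""Plant families selected more or less often than expected by chance.

For each network, the expected number of selected species from a family is
its share of the network's plants times the selection size (kept
fractional).  Across networks, the per-family differences
``observed - expected`` are pooled and tested with a one-sample z-test
(normal reference, sample sd with n-1); a family absent from a network
contributes no difference there, since it could not have been selected.
Families with at least ``min_occurrence`` summed species occurrences across
networks are flagged ``common``.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .network import NetworkInputError, VisitMatrix

__all__ = ["family_expectation", "family_enrichment", "read_family_map"]


def read_family_map(path) -> dict[str, str]:
    """Read a plant->family CSV with header ``plant,family``."""
    df = pd.read_csv(path, dtype=str)
    if not {"plant", "family"}.issubset(df.columns):
        raise NetworkInputError("family map needs columns plant,family")
    return dict(zip(df["plant"], df["family"]))


def family_expectation(
    net: VisitMatrix,
    selection: Iterable[str],
    family_map: Mapping[str, str],
) -> pd.DataFrame:
    """Observed and expected selected-species counts per family in one network.

    ``expected_f = (plants in family f / total plants) * |selection|``; e.g.
    a family holding 25% of a network's plants is expected to contribute 3
    of 12 selected species.  Expected counts are kept fractional.
    """
    selection = set(selection)
    unknown = selection - set(net.plant_labels)
    if unknown:
        raise NetworkInputError(f"selection contains unknown plants: {sorted(unknown)}")
    unmapped = [p for p in net.plant_labels if p not in family_map]
    if unmapped:
        raise NetworkInputError(f"plants without family mapping: {unmapped}")
    fams = pd.Series({p: family_map[p] for p in net.plant_labels}, name="family")
    n_plants = net.n_plants
    n_sel = len(selection)
    rows = []
    for family, members in fams.groupby(fams):
        plants = set(members.index)
        rows.append(
            {
                "network_id": net.network_id,
                "family": family,
                "n_plants": len(plants),
                "observed": len(plants & selection),
                "expected": len(plants) / n_plants * n_sel,
            }
        )
    return pd.DataFrame(rows)


def family_enrichment(
    per_network_tables: Sequence[pd.DataFrame],
    min_occurrence: int = 10,
) -> pd.DataFrame:
    """Cross-network family enrichment from per-network expectation tables.

    For each family with >= 2 networks and varying differences, reports the
    mean difference, its one-sample z-score ``mean(d) / (sd(d)/sqrt(n))``,
    a two-tailed normal p, and a 95% CI; otherwise the family is flagged
    not evaluable.  Output mirrors the reporting convention of strong
    (p < 0.05) and marginal (p < 0.10) selection, with sign giving the
    direction.
    """
    if len(per_network_tables) < 2:
        raise NetworkInputError("need tables from at least 2 networks")
    pooled = pd.concat(per_network_tables, ignore_index=True)
    rows = []
    for family, grp in pooled.groupby("family"):
        diffs = (grp["observed"] - grp["expected"]).to_numpy(dtype=float)
        n = len(diffs)
        n_occ = int(grp["n_plants"].sum())
        row = {
            "family": family,
            "n_networks": n,
            "n_occurrences": n_occ,
            "common": n_occ >= min_occurrence,
            "mean_diff": float(diffs.mean()),
            "sd_diff": float(diffs.std(ddof=1)) if n > 1 else np.nan,
            "observed_total": int(grp["observed"].sum()),
            "expected_total": float(grp["expected"].sum()),
        }
        sd = row["sd_diff"]
        if n >= 2 and sd == 0 and row["mean_diff"] == 0:
            # observed matches expectation exactly in every network
            row.update(
                evaluable=True, diff_z=0.0, p=1.0, ci_low=0.0, ci_high=0.0,
                direction="", significance="ns",
            )
        elif n < 2 or not np.isfinite(sd) or sd == 0:
            row.update(
                evaluable=False, diff_z=np.nan, p=np.nan,
                ci_low=np.nan, ci_high=np.nan, direction="",
                significance="not_evaluable",
            )
        else:
            se = sd / math.sqrt(n)
            z = row["mean_diff"] / se
            p = float(2 * norm.sf(abs(z)))
            ci = 1.959963984540054 * se
            direction = "+" if row["mean_diff"] > 0 else "-"
            if p < 0.05:
                sig = "strong"
            elif p < 0.10:
                sig = "marginal"
            else:
                sig = "ns"
            row.update(
                evaluable=True, diff_z=float(z), p=p,
                ci_low=row["mean_diff"] - ci, ci_high=row["mean_diff"] + ci,
                direction=direction, significance=sig,
            )
        rows.append(row)
    out = pd.DataFrame(rows).sort_values("family").reset_index(drop=True)
    return out
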