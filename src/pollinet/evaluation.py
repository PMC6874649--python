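"""Size-standardized comparison of restored networks built under the two
restoration criteria, including the proxy pollination-function measure.

Because the bee-richness target typically needs the fewest plants, the two
selections are compared at equal size: the visitation selection is
truncated, in its ranking order, to the richness selection's size (if it is
already shorter, both are truncated to the shorter length).  The proxy
pollination function ``mi_fraction`` is the summed Mueller acting score of
the selected plants divided by the summed acting scores of all plants,
with scores always taken from the *full* network's shared-visitor matrix —
a plant's contribution to other plants' visitor diets is a property of the
intact community.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from . import indices
from .network import DegenerateNetworkError, NetworkInputError, VisitMatrix, subnetwork

__all__ = ["evaluate_restored", "evaluate_selection"]


def evaluate_selection(
    net: VisitMatrix,
    selection: Sequence[str],
    criterion: str,
    acting_scores: pd.Series | None = None,
) -> dict:
    """Structure/function metrics of the subnetwork induced by ``selection``.

    Proportions (bee species, visits, links) use full-network denominators;
    ``mi_fraction`` uses full-network Mueller acting scores.
    """
    if not len(selection):
        raise NetworkInputError("selection must be nonempty")
    if acting_scores is None:
        _, acting_scores = indices.muller_pac(net)
    sub = subnetwork(net, selection)
    diversity = math.exp(indices.shannon_entropy(sub.counts))
    try:
        h2 = indices.h2_prime(sub)
    except DegenerateNetworkError:
        warnings.warn(f"{net.network_id}: restored network too small for H2'")
        h2 = float("nan")
    dpb = indices.d_prime(sub, side="bees")
    total_acting = float(acting_scores.sum())
    mi_fraction = (
        float(acting_scores.loc[list(selection)].sum() / total_acting)
        if total_acting > 0
        else float("nan")
    )
    return {
        "network_id": net.network_id,
        "criterion": criterion,
        "n_plants": sub.n_plants,
        "prop_bee_species": sub.n_bees / net.n_bees,
        "prop_visits": sub.grand_total / net.grand_total,
        "prop_links": sub.n_links / net.n_links,
        "interaction_diversity": diversity,
        "mean_d_prime_bees": float(dpb.mean()),
        "h2_prime": h2,
        "mi_fraction": mi_fraction,
    }


def evaluate_restored(
    net: VisitMatrix,
    selection_richness: Sequence[str],
    selection_visitation: Sequence[str],
) -> pd.DataFrame:
    """Evaluate the two criteria's restored networks at equal plant number.

    Returns a two-row tidy DataFrame (one per criterion) ready for the
    mixed-model comparisons done downstream of this package.
    """
    if not len(selection_richness) or not len(selection_visitation):
        raise NetworkInputError("both selections must be nonempty")
    n_std = min(len(selection_richness), len(selection_visitation))
    sel_rich = list(selection_richness)[:n_std]
    sel_vis = list(selection_visitation)[:n_std]
    _, acting = indices.muller_pac(net)
    rows = [
        evaluate_selection(net, sel_rich, "bee_richness", acting_scores=acting),
        evaluate_selection(net, sel_vis, "bee_visitation", acting_scores=acting),
    ]
    return pd.DataFrame(rows)
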