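"""Latent-space projections and region-level weight summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import WeightPair
from .data import TwoViewDataset

__all__ = [
    "LatentScores",
    "project_latent",
    "rank_regions",
    "display_flips",
    "UNLABELED",
]

#: reserved bucket for features without a region label
UNLABELED = "unlabeled"


@dataclass
class LatentScores:
    """Per-sample scores on the estimated latent space.

    Column h of ``xi`` is ``X @ u_h`` and column h of ``omega`` is
    ``Y @ v_h``, in effect order.
    """

    xi: np.ndarray
    omega: np.ndarray
    effect_labels: list[str]
    sample_ids: list[str] | None = None


def project_latent(data: TwoViewDataset, pairs: list[WeightPair]) -> LatentScores:
    """Project both views onto a sequence of weight-vector pairs."""
    if not pairs:
        raise ValueError("project_latent needs at least one weight pair")
    for pair in pairs:
        if pair.u.size != data.p or pair.v.size != data.q:
            raise ValueError(
                f"weight pair for effect {pair.effect_index} does not match the "
                f"dataset dimensions (p={data.p}, q={data.q})"
            )
    xi = np.column_stack([data.X @ pair.u for pair in pairs])
    omega = np.column_stack([data.Y @ pair.v for pair in pairs])
    labels = [f"effect_{pair.effect_index}" for pair in pairs]
    return LatentScores(xi=xi, omega=omega, effect_labels=labels, sample_ids=data.sample_ids)


def display_flips(scores: LatentScores) -> np.ndarray:
    """Per-effect signs (+1/-1) that orient every effect consistently with
    the first for presentation.

    The sign of each weight pair is arbitrary, which can make plots of
    successive effects point in opposite directions. This returns, for each
    effect, the sign that makes its X-view scores correlate non-negatively
    with the first effect's. Purely presentational: stored weights are
    never mutated.
    """
    ref = scores.xi[:, 0] - scores.xi[:, 0].mean()
    flips = np.ones(scores.xi.shape[1])
    for j in range(1, scores.xi.shape[1]):
        col = scores.xi[:, j] - scores.xi[:, j].mean()
        if float(ref @ col) < 0.0:
            flips[j] = -1.0
    return flips


def rank_regions(u: np.ndarray, labels) -> pd.DataFrame:
    """Summarise a weight vector by labelled regions (e.g. atlas parcels).

    For every region label, reports the mean of |u| over *all* features
    carrying that label (zeros included, so large regions with few selected
    features rank low) and the number of nonzero-weight features in the
    region. Features without a label (None or empty string) are collected
    under the reserved ``"unlabeled"`` bucket. Rows are sorted by
    descending mean absolute weight.
    """
    u = np.asarray(u, dtype=float).ravel()
    labels = list(labels)
    if len(labels) != u.size:
        raise ValueError("labels length must equal the weight vector length")
    labels = [UNLABELED if (lab is None or str(lab) == "") else str(lab) for lab in labels]
    df = pd.DataFrame({"region": labels, "abs_weight": np.abs(u), "nonzero": u != 0.0})
    out = (
        df.groupby("region", sort=False)
        .agg(n_voxels_found=("nonzero", "sum"), mean_abs_weight=("abs_weight", "mean"))
        .reset_index()
    )
    out["n_voxels_found"] = out["n_voxels_found"].astype(int)
    out = out.sort_values(
        "mean_abs_weight", ascending=False, kind="stable", ignore_index=True
    )
    return out
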