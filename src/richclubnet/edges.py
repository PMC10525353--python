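"""Rich-club / feeder / local edge classification and strengths.

Every existing edge falls in exactly one class: *rich* if both endpoints are
rich-club nodes, *feeder* if exactly one is, *local* if neither is.  The
per-class connectivity strength of a subject is the sum of that class's edge
weights, so the three class strengths partition the connectome's total
weight.  Region-specific strengths sum a rich-club node's class edges per
hemisphere and average the left/right values; for the rich class an edge
between two rich regions contributes to both regions' totals (including the
inter-hemispheric edge between a region's own left and right nodes).

Raw strengths are converted to z-scores against a reference group
(cognitively unimpaired by convention) for visualization and comparability.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import CohortTable, NodeAtlas, WeightedConnectome

__all__ = [
    "EdgeClassification",
    "EdgeClassStrengths",
    "ZScoredValues",
    "classify_edges",
    "class_strengths",
    "region_class_strength",
    "zscore_vs_reference",
]

CLASS_LABELS = ("rich", "feeder", "local")


@dataclasses.dataclass(frozen=True)
class EdgeClassification:
    """Class label per existing (upper-triangle) edge."""

    edge_i: np.ndarray
    edge_j: np.ndarray
    labels: np.ndarray  # values in CLASS_LABELS

    def counts(self) -> dict[str, int]:
        return {lab: int(np.sum(self.labels == lab)) for lab in CLASS_LABELS}


@dataclasses.dataclass(frozen=True)
class EdgeClassStrengths:
    subject_id: str
    rich_strength: float
    feeder_strength: float
    local_strength: float
    region_strengths: dict[tuple[str, str], float]  # (region, class) -> value

    def as_dict(self) -> dict[str, float]:
        return {
            "rich": self.rich_strength,
            "feeder": self.feeder_strength,
            "local": self.local_strength,
        }


@dataclasses.dataclass(frozen=True)
class ZScoredValues:
    variable: str
    reference_group: str
    reference_mean: float
    reference_sd: float
    z: pd.Series  # indexed by subject_id


def classify_edges(c: WeightedConnectome, atlas: NodeAtlas) -> EdgeClassification:
    """Label every existing edge rich / feeder / local by its endpoints."""
    if c.n_nodes != atlas.n_nodes:
        raise ValueError(
            f"connectome has {c.n_nodes} nodes but atlas has {atlas.n_nodes}"
        )
    flags = atlas.rich_club_flags
    iu, ju, _ = c.edge_list()
    n_rich_ends = flags[iu].astype(int) + flags[ju].astype(int)
    labels = np.array(CLASS_LABELS)[2 - n_rich_ends]
    return EdgeClassification(edge_i=iu, edge_j=ju, labels=labels)


def class_strengths(
    c: WeightedConnectome,
    cls: EdgeClassification,
    atlas: NodeAtlas | None = None,
) -> EdgeClassStrengths:
    """Per-class sums of edge weights (+ region-specific values if an atlas
    is given); the three class strengths sum to the connectome's total
    weight."""
    w = c.weights[cls.edge_i, cls.edge_j]
    sums = {lab: float(w[cls.labels == lab].sum()) for lab in CLASS_LABELS}
    region_strengths: dict[tuple[str, str], float] = {}
    if atlas is not None:
        for region in atlas.rich_club_regions:
            for lab in ("rich", "feeder"):
                region_strengths[(region, lab)] = region_class_strength(
                    c, atlas, region, lab
                )
    return EdgeClassStrengths(
        subject_id=c.subject_id,
        rich_strength=sums["rich"],
        feeder_strength=sums["feeder"],
        local_strength=sums["local"],
        region_strengths=region_strengths,
    )


def region_class_strength(
    c: WeightedConnectome,
    atlas: NodeAtlas,
    region: str,
    cls_label: str,
) -> float:
    """Hemisphere-averaged strength of one rich-club region's class edges.

    For each hemisphere node of ``region``, sum the weights of its edges of
    the requested class; return the mean of the two hemisphere values.
    """
    if cls_label not in ("rich", "feeder"):
        raise ValueError(f"cls_label must be 'rich' or 'feeder', got {cls_label!r}")
    if region not in atlas.rich_club_regions:
        raise ValueError(f"{region!r} is not a rich-club region in this atlas")
    flags = atlas.rich_club_flags
    left, right = atlas.region_pair(region)
    vals = []
    for node in (left, right):
        nbr_w = c.weights[node]
        nbrs = np.flatnonzero(nbr_w > 0)
        if cls_label == "rich":
            keep = nbrs[flags[nbrs]]
        else:
            keep = nbrs[~flags[nbrs]]
        vals.append(float(nbr_w[keep].sum()))
    return float(np.mean(vals))


def zscore_vs_reference(
    values: pd.Series,
    cohort: CohortTable | pd.DataFrame,
    reference_group: str = "CU",
    variable: str = "value",
) -> ZScoredValues:
    """Z-score per-subject values against a reference group's mean and SD.

    ``values`` is indexed by subject_id.  All subjects (reference and
    non-reference) are standardized with the reference group's mean and
    sample SD (n−1 denominator), so reference members have mean 0, SD 1 by
    construction.
    """
    table = cohort.table if isinstance(cohort, CohortTable) else cohort
    ref_ids = table.loc[table["group"] == reference_group, "subject_id"]
    ref_vals = values.loc[values.index.intersection(ref_ids)].dropna()
    if len(ref_vals) < 2:
        raise ValueError(
            f"reference group {reference_group!r} has fewer than 2 finite values"
        )
    mu = float(ref_vals.mean())
    sd = float(ref_vals.std(ddof=1))
    if sd == 0:
        raise ValueError(f"reference group {reference_group!r} has zero SD")
    return ZScoredValues(
        variable=variable,
        reference_group=reference_group,
        reference_mean=mu,
        reference_sd=sd,
        z=(values - mu) / sd,
    )
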