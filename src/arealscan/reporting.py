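"""Choropleth-ready classification and GeoJSON export of scan results."""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np

from .regions import StudyArea
from .scan.common import Cluster

__all__ = ["jenks_breaks", "classify", "export_geojson"]


def jenks_breaks(values: Sequence[float], k: int) -> list[float]:
    """Natural-breaks classification into k classes (Fisher's exact DP).

    Finds the partition of the sorted values into k contiguous classes
    minimising the total within-class sum of squared deviations, and
    returns the k-1 break points (the upper value of each class but the
    last).  Deterministic and invariant to input order.
    """
    vals = np.sort(np.asarray(values, dtype=float))
    n = len(vals)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(np.unique(vals)) < k:
        raise ValueError("need at least k distinct values")
    # prefix sums give O(1) within-class SSD
    cs = np.concatenate([[0.0], np.cumsum(vals)])
    cs2 = np.concatenate([[0.0], np.cumsum(vals**2)])

    def ssd(i: int, j: int) -> float:  # class = vals[i:j]
        m = j - i
        s = cs[j] - cs[i]
        return (cs2[j] - cs2[i]) - s * s / m

    INF = float("inf")
    cost = np.full((k + 1, n + 1), INF)
    split = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, arg = INF, c - 1
            for i in range(c - 1, j):
                v = cost[c - 1, i] + ssd(i, j)
                if v < best:
                    best, arg = v, i
            cost[c, j] = best
            split[c, j] = arg
    breaks = []
    j = n
    for c in range(k, 1, -1):
        i = split[c, j]
        breaks.append(float(vals[i - 1]))  # upper value of the class below
        j = i
    return breaks[::-1]


def classify(values: Sequence[float], breaks: Sequence[float]) -> np.ndarray:
    """Class index (0-based) of each value given ascending break points."""
    return np.searchsorted(np.asarray(breaks, dtype=float), np.asarray(values, dtype=float), side="left")


def export_geojson(
    area: StudyArea,
    clusters: Sequence[Cluster] = (),
    path=None,
    n_classes: int | None = None,
) -> dict:
    """Build (and optionally write) a GeoJSON FeatureCollection report.

    Each region becomes a feature tagged with its counts, prevalence, any
    cluster membership (rank, risk ratios, p-value) and, when
    ``n_classes`` is given, a natural-breaks class index of prevalence.
    Polygon geometry is used when the study area carries it; otherwise
    point features at the centroids are emitted.
    """
    rank_of: dict[str, Cluster] = {}
    for cl in clusters:
        for rid in cl.members:
            rank_of[rid] = cl

    prevalence = area.cases / area.populations
    class_idx = None
    breaks: list[float] | None = None
    if n_classes is not None:
        breaks = jenks_breaks(prevalence, n_classes)
        class_idx = classify(prevalence, breaks)

    features = []
    for i, r in enumerate(area.regions):
        if area.geometry is not None:
            geom = area.geometry[i]
        else:
            geom = {"type": "Point", "coordinates": [r.x, r.y]}
        props = {
            "id": r.id,
            "name": r.name,
            "x": r.x,
            "y": r.y,
            "population": r.population,
            "cases": r.cases,
            "prevalence": float(prevalence[i]),
            **{k: float(v) for k, v in r.covariates.items()},
        }
        cl = rank_of.get(r.id)
        props["cluster_rank"] = cl.rank if cl else None
        if cl is not None:
            props["cluster_rr_io"] = cl.rr_io
            props["cluster_oe"] = cl.oe
            props["cluster_p_value"] = cl.p_value
        if class_idx is not None:
            props["prevalence_class"] = int(class_idx[i])
        features.append({"type": "Feature", "geometry": geom, "properties": props})
    fc = {"type": "FeatureCollection", "features": features}
    if breaks is not None:
        fc["properties"] = {"prevalence_breaks": breaks}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(fc, fh)
    return fc
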