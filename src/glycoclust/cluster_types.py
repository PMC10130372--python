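"""Cluster typing: partition clustered tissue into marker-exclusive and
dual cluster types, and score per-specimen cluster-type heterogeneity.

Typing is pixelwise on the two cluster masks (called at the same tau), so
the partition identity area(A_only) + area(dual) = area(A) holds exactly
by construction. A specimen is "heterogeneous" when two or more of the
three types (A-only, B-only, dual) are present after dichotomization.
"""

from __future__ import annotations

import numpy as np

from .types import (
    TYPE_A_ONLY,
    TYPE_B_ONLY,
    TYPE_DUAL,
    ClusterMask,
    ClusterTypeMap,
    TissueMask,
    TypeQuantities,
)

__all__ = ["type_map", "count_cluster_types", "quantify_types", "TYPE_NAMES"]

TYPE_NAMES = ("A_only", "B_only", "dual")


def type_map(clust_a: ClusterMask, clust_b: ClusterMask, tissue: TissueMask) -> ClusterTypeMap:
    """Pixelwise cluster-type partition of two cluster masks.

    dual = A ∧ B, A_only = A ∧ ¬B, B_only = B ∧ ¬A; type-area fractions
    are normalised to the tissue area. Both masks must come from the same
    concentration threshold tau.
    """
    if clust_a.mask.shape != clust_b.mask.shape or clust_a.mask.shape != tissue.shape:
        raise ValueError("cluster masks and tissue mask must share one shape")
    if clust_a.tau != clust_b.tau:
        raise ValueError("cluster masks must be called at the same tau")
    a = np.asarray(clust_a.mask, dtype=bool)
    b = np.asarray(clust_b.mask, dtype=bool)
    labels = np.zeros(a.shape, dtype=np.uint8)
    labels[a & ~b] = TYPE_A_ONLY
    labels[b & ~a] = TYPE_B_ONLY
    labels[a & b] = TYPE_DUAL
    area = tissue.tissue_area
    fractions = {
        "A_only": float((labels == TYPE_A_ONLY).sum()) / area if area else 0.0,
        "B_only": float((labels == TYPE_B_ONLY).sum()) / area if area else 0.0,
        "dual": float((labels == TYPE_DUAL).sum()) / area if area else 0.0,
    }
    return ClusterTypeMap(labels=labels, fractions=fractions)


def count_cluster_types(indicators: dict) -> tuple[int, bool]:
    """Number of cluster types present (0–3) and the heterogeneity flag.

    ``indicators`` maps each of "A_only", "B_only", "dual" to 0/1 after
    dichotomization; the specimen is heterogeneous when at least two
    types co-occur.
    """
    vals = [indicators[name] for name in TYPE_NAMES]
    if any(v not in (0, 1, True, False) for v in vals):
        raise ValueError("indicators must be binary")
    n = int(sum(int(v) for v in vals))
    return n, n >= 2


def quantify_types(tmap: ClusterTypeMap, indicators: dict) -> TypeQuantities:
    """Bundle a specimen's type fractions with its cohort-dichotomized
    indicators and type count."""
    n, _ = count_cluster_types(indicators)
    return TypeQuantities(
        fractions=dict(tmap.fractions),
        indicators={k: int(indicators[k]) for k in TYPE_NAMES},
        n_types=n,
    )
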