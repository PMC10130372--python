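"""Region-of-interest comparison of cluster heterogeneity against a
pathology annotation.

The tissue is tiled into non-overlapping square ROIs (~3 mm in the
original workflow, three times the spatial-concentration window), each ROI
is classified by how many cluster types it contains, and the overlap of
heterogeneous vs homogeneous ROIs with a cancer annotation mask is
summarised. The exhaustive grid removes user selection of ROI locations;
manually chosen ROI rectangles can be supplied instead to mirror a
pathologist-driven layout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import TYPE_A_ONLY, TYPE_B_ONLY, TYPE_DUAL, ClusterTypeMap, TissueMask

__all__ = ["Roi", "OverlapSummary", "tile_rois", "classify_roi", "overlap_summary"]


@dataclass
class Roi:
    """Square tile: half-open pixel bounds [row0, row1) × [col0, col1)."""

    row0: int
    col0: int
    row1: int
    col1: int
    tissue_px: int = 0
    n_types_present: int = -1  # -1 until classified

    @property
    def heterogeneous(self) -> bool:
        return self.n_types_present >= 2

    @property
    def area_px(self) -> int:
        return (self.row1 - self.row0) * (self.col1 - self.col0)


@dataclass
class OverlapSummary:
    n_het: int
    n_het_overlapping_cancer: int
    n_homo: int
    n_homo_overlapping_cancer: int

    @property
    def het_overlap_fraction(self) -> float:
        return self.n_het_overlapping_cancer / self.n_het if self.n_het else float("nan")

    @property
    def homo_overlap_fraction(self) -> float:
        return self.n_homo_overlapping_cancer / self.n_homo if self.n_homo else float("nan")


def tile_rois(tissue: TissueMask, roi_px: int, min_tissue_fraction: float = 0.25) -> list[Roi]:
    """Non-overlapping grid of square ROIs, keeping tiles whose tissue
    coverage is at least ``min_tissue_fraction``."""
    if roi_px < 8:
        raise ValueError("ROI must span at least 8 px; use a coarser grid or finer pixels")
    h, w = tissue.shape
    rois = []
    for r0 in range(0, h - roi_px + 1, roi_px):
        for c0 in range(0, w - roi_px + 1, roi_px):
            sub = tissue.mask[r0 : r0 + roi_px, c0 : c0 + roi_px]
            tpx = int(sub.sum())
            if tpx >= min_tissue_fraction * roi_px * roi_px:
                rois.append(Roi(row0=r0, col0=c0, row1=r0 + roi_px, col1=c0 + roi_px, tissue_px=tpx))
    return rois


def classify_roi(types: ClusterTypeMap, roi: Roi, min_type_px: int | None = None) -> Roi:
    """Fill ``n_types_present``: a type counts as present when its pixel
    count inside the ROI reaches ``min_type_px`` (default 0.1% of the ROI
    area — a floor that keeps single stray pixels from minting spurious
    heterogeneity)."""
    if min_type_px is None:
        min_type_px = max(1, int(round(0.001 * roi.area_px)))
    sub = types.labels[roi.row0 : roi.row1, roi.col0 : roi.col1]
    n = sum(int((sub == code).sum()) >= min_type_px for code in (TYPE_A_ONLY, TYPE_B_ONLY, TYPE_DUAL))
    roi.n_types_present = n
    return roi


def overlap_summary(
    rois: list[Roi],
    cancer: np.ndarray,
    tissue: TissueMask,
    min_overlap_fraction: float = 0.05,
) -> OverlapSummary:
    """Summarise cancer-annotation overlap per heterogeneity group.

    An ROI "overlaps cancer" when at least ``min_overlap_fraction`` of its
    tissue pixels fall inside the annotation. ROIs with fewer than two
    types present (including type-free ROIs) form the homogeneous group,
    so the two groups partition the ROI list; the summary does not depend
    on list order.
    """
    cancer = np.asarray(cancer, dtype=bool)
    if cancer.shape != tissue.shape:
        raise ValueError("annotation mask shape differs from tissue")
    n_het = n_het_c = n_homo = n_homo_c = 0
    for roi in rois:
        if roi.n_types_present < 0:
            raise ValueError("ROI not classified; call classify_roi first")
        sub_t = tissue.mask[roi.row0 : roi.row1, roi.col0 : roi.col1]
        sub_c = cancer[roi.row0 : roi.row1, roi.col0 : roi.col1]
        tpx = int(sub_t.sum())
        overlap = (int((sub_t & sub_c).sum()) >= min_overlap_fraction * tpx) if tpx else False
        if roi.heterogeneous:
            n_het += 1
            n_het_c += overlap
        else:
            n_homo += 1
            n_homo_c += overlap
    return OverlapSummary(
        n_het=n_het,
        n_het_overlapping_cancer=n_het_c,
        n_homo=n_homo,
        n_homo_overlapping_cancer=n_homo_c,
    )
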