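"""Core containers shared across the image-analysis stages.

All images are 2-D numpy grids. Physical scale is carried as ``pixel_size``
in micrometres per pixel so that window sizes, cluster rates and ROI sizes
can be stated in millimetres and converted once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ChannelImage",
    "TissueMask",
    "SignalMap",
    "IntensityMetrics",
    "ConcentrationMap",
    "ClusterMask",
    "ClusterProfile",
    "ClusterTypeMap",
    "TypeQuantities",
    "EmptyTissueError",
]

#: canonical channel labels; "other" admits arbitrary markers
CHANNEL_LABELS = ("nuclear", "CA19-9", "STRA", "other")


class EmptyTissueError(ValueError):
    """Raised when no tissue can be located in a slide (e.g. an all-zero
    nuclear image), so that downstream tissue-normalised metrics are
    undefined."""


@dataclass
class ChannelImage:
    """A single fluorescence channel: nonnegative intensity grid plus the
    channel label and physical pixel size (µm/px)."""

    pixels: np.ndarray
    channel: str = "other"
    pixel_size: float = 20.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("channel image must be a 2-D grid")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("channel intensities must be finite")
        if self.pixels.size and self.pixels.min() < 0:
            raise ValueError("channel intensities must be nonnegative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive (µm/px)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def mm_to_px(self, mm: float) -> float:
        """Convert a length in millimetres to pixels at this resolution."""
        return mm * 1000.0 / self.pixel_size


@dataclass
class TissueMask:
    """Binary support of tissue-containing pixels; every fraction reported
    by the pipeline is normalised to ``tissue_area``."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("tissue mask must be 2-D")

    @property
    def tissue_area(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def fraction_of_frame(self) -> float:
        return self.tissue_area / self.mask.size


@dataclass
class SignalMap:
    """Per-pixel signal call for one channel, with the threshold that
    produced it and the fraction of tissue pixels called signal."""

    mask: np.ndarray
    threshold: float
    signal_fraction: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not 0.0 <= self.signal_fraction <= 1.0:
            raise ValueError("signal_fraction must lie in [0, 1]")


@dataclass
class IntensityMetrics:
    """Alternative intensity-based quantifications of one channel.

    ``mean_above_threshold`` is the mean intensity over called signal
    pixels (0 by convention when the signal map is empty, so cohort tables
    never contain missing cells). ``top_decile_mean`` is the mean of the
    brightest tenth of tissue pixels (the pixels at/above the 90th
    percentile, nearest-rank convention)."""

    mean_above_threshold: float
    top_decile_mean: float


@dataclass
class ConcentrationMap:
    """Moving-box spatial concentration: per pixel, the fraction of the
    centred ``window_w`` × ``window_w`` box occupied by signal
    (zero-padded outside the frame)."""

    values: np.ndarray
    window_w: int
    window_mm: float = float("nan")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.window_w < 3 or self.window_w % 2 == 0:
            raise ValueError("window_w must be odd and >= 3")


@dataclass
class ClusterMask:
    """Tissue pixels whose spatial concentration clears a threshold tau,
    with the connected-region count and clustered tissue-area fraction."""

    mask: np.ndarray
    tau: float
    regions: int
    clustered_area_fraction: float


@dataclass
class ClusterProfile:
    """Ladder of cluster calls over increasing tau; ``cluster_amount`` is
    the clustered-area fraction at the configured primary tau."""

    taus: list[float]
    regions: list[int]
    clustered_area_fractions: list[float]
    primary_tau: float
    cluster_amount: float
    primary_regions: int

    def as_rows(self) -> list[tuple[float, int, float]]:
        return list(zip(self.taus, self.regions, self.clustered_area_fractions))


#: integer codes used in ClusterTypeMap.labels
TYPE_NONE, TYPE_A_ONLY, TYPE_B_ONLY, TYPE_DUAL = 0, 1, 2, 3


@dataclass
class ClusterTypeMap:
    """Pixelwise partition of clustered tissue into marker-exclusive and
    dual cluster types (0 none, 1 A-only, 2 B-only, 3 dual)."""

    labels: np.ndarray
    fractions: dict = field(default_factory=dict)  # {"A_only","B_only","dual"} over tissue

    def area(self, code: int) -> int:
        return int((self.labels == code).sum())


@dataclass
class TypeQuantities:
    """Per-specimen cluster-type quantities after cohort dichotomization."""

    fractions: dict
    indicators: dict
    n_types: int

    def __post_init__(self) -> None:
        if self.n_types != sum(int(v) for v in self.indicators.values()):
            raise ValueError("n_types must equal the sum of the indicators")

    @property
    def heterogeneous(self) -> bool:
        return self.n_types >= 2
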