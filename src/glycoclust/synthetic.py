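"""Synthetic specimens and cohorts with the statistical structure the
analysis assumes.

Each specimen is a tissue region inside a frame carrying three channels: a
nuclear stain (cellularity), and two glycan marker channels whose signal
ranges from uniform speckle to strongly clustered. Marker signal follows a
Neyman–Scott cluster process — Poisson parent points on the tissue with
Gaussian-dispersed offspring pixels — which is the simplest stationary
process producing both punctate (small ``offspring_sd``) and broad (large
``offspring_sd``) clusters. "Dual" clusters arise by sharing parent
locations between the two channels (``dual_overlap`` is the shared
fraction), so duality is a property of cluster locations, not of pixelwise
intensity correlation. Foreground and background intensities are
lognormal, zero outside tissue.

Recurrence times follow an exponential proportional-hazards model whose
covariate is the constructed cluster-type heterogeneity (hazard =
``hazard_baseline × exp(beta · 1{n_types ≥ 2})``), censored at a fixed
horizon — the minimal outcome model under which the cohort-level χ² and
ρ² analyses have signal to recover.

All randomness flows from one integer seed through per-specimen
counter-based streams (`numpy` SeedSequence spawn keys), so a specimen's
draws do not depend on the cohort size or on whether images are rendered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import label as cc_label

from .types import ChannelImage, SignalMap, TissueMask

__all__ = [
    "ChannelParams",
    "SimulationParams",
    "SyntheticSpecimen",
    "CohortBundle",
    "TissueGenerationError",
    "make_tissue_mask",
    "simulate_channel",
    "simulate_specimen",
    "simulate_outcome_table",
    "simulate_cohort",
    "PROFILES",
]

#: specimen construction profiles and the cluster types each one seeds
PROFILES = ("none", "A", "B", "AB", "AB_dual")


class TissueGenerationError(RuntimeError):
    """Raised when no threshold yields a tissue mask at the requested
    fraction (e.g. extreme target with too little smoothness)."""


@dataclass
class ChannelParams:
    """Neyman–Scott parameters for one marker channel."""

    parent_rate: float = 0.8  # cluster parents per mm² of tissue
    offspring_per_parent: int = 600
    offspring_sd: float = 150.0  # µm
    uniform_noise_rate: float = 50.0  # stray signal px per mm² of tissue

    def validate(self) -> None:
        if self.parent_rate < 0 or self.uniform_noise_rate < 0:
            raise ValueError("rates must be nonnegative")
        if self.offspring_per_parent < 0 or self.offspring_sd < 0:
            raise ValueError("offspring parameters must be nonnegative")


@dataclass
class SimulationParams:
    """Study conditions for a synthetic cohort.

    The frame is 256 × 256 px at 20 µm/px (a 5.1 mm field — a desk-scale
    stand-in for slide scans, with window sizes still stated in mm), half
    of it tissue. Marker defaults put ~10 clusters of ~150 µm dispersion
    on the tissue so that cluster cores clear a 1-mm moving-box
    concentration of 0.10. Background intensity is lognormal(4.0, 0.3)
    and foreground lognormal(6.5, 0.4) (≈ 12× brighter at the median).
    The outcome model uses a 0.2 events/year baseline hazard, log hazard
    ratio ln 4 for heterogeneous specimens and a 3-year censoring horizon.
    """

    image_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 20.0  # µm/px
    tissue_smoothness: float = 12.0  # px
    tissue_fraction: float = 0.5
    marker_a: ChannelParams = field(default_factory=ChannelParams)
    marker_b: ChannelParams = field(default_factory=ChannelParams)
    dual_overlap: float = 0.5
    fg_mu: float = 6.5
    fg_sigma: float = 0.4
    bg_mu: float = 4.0
    bg_sigma: float = 0.3
    nuclear_density: float = 0.3
    cancer_region_fraction: float = 0.3
    hazard_baseline: float = 0.2  # events per year
    log_hazard_ratio: float = math.log(4.0)
    censoring_horizon: float = 3.0  # years
    n_specimens: int = 21
    seed: int = 0
    #: probabilities of the construction profiles in PROFILES order
    profile_probs: tuple[float, ...] = (0.15, 0.15, 0.15, 0.20, 0.35)
    #: restrict cluster parents to the cancer annotation region
    seed_clusters_in_cancer: bool = False

    def validate(self) -> None:
        h, w = self.image_shape
        if h < 64 or w < 64:
            raise ValueError("image_shape must be at least 64 × 64")
        if not 0.0 <= self.dual_overlap <= 1.0:
            raise ValueError("dual_overlap must lie in [0, 1]")
        if self.fg_mu <= self.bg_mu:
            raise ValueError("foreground lognormal median must exceed background")
        if not 0.0 < self.tissue_fraction < 1.0:
            raise ValueError("tissue_fraction must lie in (0, 1)")
        if not 0.0 <= self.nuclear_density <= 1.0:
            raise ValueError("nuclear_density must lie in [0, 1]")
        if self.hazard_baseline < 0 or self.censoring_horizon <= 0:
            raise ValueError("hazard parameters must be positive")
        if abs(sum(self.profile_probs) - 1.0) > 1e-9 or len(self.profile_probs) != len(PROFILES):
            raise ValueError("profile_probs must be a distribution over the profiles")
        self.marker_a.validate()
        self.marker_b.validate()

    @property
    def px_area_mm2(self) -> float:
        return (self.pixel_size / 1000.0) ** 2


@dataclass
class SyntheticSpecimen:
    specimen_id: str
    tissue: TissueMask
    cancer_annotation: np.ndarray  # binary, subset of tissue
    channels: dict  # {"nuclear", "marker_a", "marker_b"} -> ChannelImage
    truth_signal: dict  # {"marker_a", "marker_b"} -> SignalMap
    truth_parents: dict  # {"marker_a", "marker_b"} -> (n, 2) float px coords
    heterogeneity_truth: int
    profile: str

    def __post_init__(self) -> None:
        shape = self.tissue.shape
        for name, ch in self.channels.items():
            if ch.shape != shape:
                raise ValueError(f"channel {name} shape differs from tissue")
        for name, sig in self.truth_signal.items():
            if np.any(sig.mask & ~self.tissue.mask):
                raise ValueError(f"truth signal {name} escapes the tissue mask")
        if np.any(self.cancer_annotation & ~self.tissue.mask):
            raise ValueError("cancer annotation escapes the tissue mask")


@dataclass
class CohortBundle:
    specimens: list
    outcomes: pd.DataFrame  # specimen_id, time, event, het_truth, profile

    def __post_init__(self) -> None:
        if len(self.specimens) != len(self.outcomes):
            raise ValueError("one outcome row required per specimen")
        if (self.outcomes["time"] <= 0).any():
            raise ValueError("event times must be positive")
        if not self.outcomes["event"].isin([0, 1]).all():
            raise ValueError("event flags must be 0/1")


def _stream(seed: int, *key: int) -> np.random.Generator:
    """Counter-based child stream: independent of how many other streams
    have been drawn from."""
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=tuple(int(k) for k in key)))


# ---------------------------------------------------------------------------
# tissue and annotation masks


def _mask_from_field(fld: np.ndarray, raw_fraction: float) -> np.ndarray:
    thr = np.quantile(fld, 1.0 - raw_fraction)
    raw = fld >= thr
    lab = cc_label(raw, connectivity=2)
    if lab.max() == 0:
        return np.zeros_like(raw)
    largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
    return ndi.binary_fill_holes(lab == largest)


def make_tissue_mask(
    shape: tuple[int, int], smoothness: float, target_fraction: float, seed: int
) -> TissueMask:
    """Single connected tissue region occupying ``target_fraction`` of the
    frame within ±5 percentage points.

    A smoothed Gaussian random field is thresholded, the largest connected
    component kept and its holes filled; the threshold quantile is found
    by bisection. Deterministic for a fixed seed.
    """
    if not 0.0 < target_fraction < 1.0:
        raise ValueError("target_fraction must lie in (0, 1)")
    rng = _stream(seed, 0)
    white = rng.standard_normal(shape)
    h, w = shape
    # a broad radial bump around a random interior point anchors one
    # dominant blob (a slide carries one section), which keeps the
    # largest-component fraction near-continuous in the threshold
    ci = rng.uniform(0.35 * h, 0.65 * h)
    cj = rng.uniform(0.35 * w, 0.65 * w)
    ii, jj = np.mgrid[0:h, 0:w]
    radius = 0.45 * min(h, w)
    bump = np.exp(-((ii - ci) ** 2 + (jj - cj) ** 2) / (2 * radius**2))
    best_mask, best_err = None, np.inf
    # keeping only the largest component can still make the achieved
    # fraction non-monotone in the threshold, so bisection falls back to a
    # dense threshold scan, then to re-filtering the same noise at larger
    # smoothness (fewer, bigger blobs)
    for sigma_scale in (1.0, 1.5, 2.25):
        smooth = ndi.gaussian_filter(white, sigma=smoothness * sigma_scale)
        sd = smooth.std() or 1.0
        fld = smooth / sd + 1.5 * bump
        lo, hi = 0.005, 0.995
        for _ in range(30):
            q = 0.5 * (lo + hi)
            mask = _mask_from_field(fld, q)
            frac = mask.mean()
            err = abs(frac - target_fraction)
            if err < best_err:
                best_mask, best_err = mask, err
            if err <= 0.02:
                break
            if frac < target_fraction:
                lo = q
            else:
                hi = q
        if best_err > 0.02:
            for q in np.linspace(0.05, 0.95, 91):
                mask = _mask_from_field(fld, q)
                err = abs(mask.mean() - target_fraction)
                if err < best_err:
                    best_mask, best_err = mask, err
        if best_err <= 0.02:
            break
    if best_err > 0.02 and best_mask is not None and best_mask.any():
        # final trim: grow or shrink the best candidate one morphological
        # step at a time (a step moves the fraction by ~1 perimeter)
        adjust = best_mask
        for _ in range(200):
            frac = adjust.mean()
            if abs(frac - target_fraction) <= 0.02:
                break
            if frac < target_fraction:
                adjust = ndi.binary_dilation(adjust)
            else:
                eroded = ndi.binary_erosion(adjust)
                if not eroded.any():
                    break
                lab = cc_label(eroded, connectivity=2)
                adjust = lab == (np.argmax(np.bincount(lab.ravel())[1:]) + 1)
            err = abs(adjust.mean() - target_fraction)
            if err < best_err:
                best_mask, best_err = adjust, err
    if best_err > 0.05 or best_mask is None or not best_mask.any():
        raise TissueGenerationError(
            f"no threshold reached tissue fraction {target_fraction:.2f} "
            f"(best deviation {best_err:.3f}; try more smoothness or a milder target)"
        )
    return TissueMask(mask=best_mask)


def _annotation_mask(tissue: TissueMask, fraction: float, smoothness: float, rng) -> np.ndarray:
    """Compact connected sub-region covering ``fraction`` of the tissue
    (a single dominant lesion: the largest smoothed-field patch, grown
    within the tissue to the target size)."""
    if fraction <= 0:
        return np.zeros(tissue.shape, dtype=bool)
    target_px = fraction * tissue.tissue_area
    fld = ndi.gaussian_filter(rng.standard_normal(tissue.shape), sigma=2.0 * smoothness)
    vals = fld[tissue.mask]
    thr = np.quantile(vals, 1.0 - min(fraction, 1.0))
    raw = tissue.mask & (fld >= thr)
    lab = cc_label(raw, connectivity=2)
    if lab.max() == 0:
        return raw
    mask = lab == (np.argmax(np.bincount(lab.ravel())[1:]) + 1)
    for _ in range(300):
        n = mask.sum()
        if n >= target_px:
            break
        grown = ndi.binary_dilation(mask) & tissue.mask
        if grown.sum() == n:
            break
        mask = grown
    return mask


# ---------------------------------------------------------------------------
# marker channels


def _sample_points(mask: np.ndarray, n: int, rng) -> np.ndarray:
    """Uniform continuous positions over the true pixels of ``mask``."""
    coords = np.argwhere(mask)
    if n == 0 or coords.size == 0:
        return np.empty((0, 2), dtype=float)
    pick = coords[rng.integers(0, len(coords), size=n)]
    return pick + rng.uniform(-0.5, 0.5, size=pick.shape)


def simulate_channel(
    tissue: TissueMask,
    params: ChannelParams,
    pixel_size: float,
    *,
    fg: tuple[float, float] = (6.5, 0.4),
    bg: tuple[float, float] = (4.0, 0.3),
    shared_parents: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    label: str = "other",
    parent_support: np.ndarray | None = None,
) -> tuple[ChannelImage, SignalMap, np.ndarray]:
    """Render one marker channel on a tissue mask.

    Parent points are the union of ``shared_parents`` and fresh Poisson
    draws at ``parent_rate`` per mm² of tissue; offspring signal pixels
    are Gaussian-dispersed around the parents (``offspring_sd`` µm) and
    clipped to tissue; stray signal pixels are added at
    ``uniform_noise_rate`` per mm². Foreground pixels draw lognormal
    ``fg`` intensities, tissue background lognormal ``bg``, and the frame
    outside tissue is zero. Returns the channel image, the ground-truth
    signal map (threshold recorded as NaN) and the parent list.
    """
    if tissue.tissue_area == 0:
        raise ValueError("tissue mask is empty")
    params.validate()
    if rng is None:
        rng = _stream(0 if seed is None else seed, 1)
    support = tissue.mask if parent_support is None else (parent_support & tissue.mask)
    area_mm2 = tissue.tissue_area * (pixel_size / 1000.0) ** 2

    n_new = rng.poisson(params.parent_rate * area_mm2)
    parents = _sample_points(support, int(n_new), rng)
    if shared_parents is not None and len(shared_parents):
        parents = np.vstack([np.asarray(shared_parents, dtype=float), parents]) if parents.size else np.asarray(shared_parents, dtype=float)

    h, w = tissue.shape
    truth = np.zeros((h, w), dtype=bool)
    if len(parents) and params.offspring_per_parent > 0:
        sd_px = params.offspring_sd / pixel_size
        pts = np.repeat(parents, params.offspring_per_parent, axis=0)
        if sd_px > 0:
            pts = pts + rng.normal(0.0, sd_px, size=pts.shape)
        ij = np.rint(pts).astype(int)
        ok = (ij[:, 0] >= 0) & (ij[:, 0] < h) & (ij[:, 1] >= 0) & (ij[:, 1] < w)
        ij = ij[ok]
        ok_t = tissue.mask[ij[:, 0], ij[:, 1]]
        ij = ij[ok_t]
        truth[ij[:, 0], ij[:, 1]] = True

    n_noise = rng.poisson(params.uniform_noise_rate * area_mm2)
    if n_noise:
        noise_pts = np.rint(_sample_points(tissue.mask, int(n_noise), rng)).astype(int)
        noise_pts = noise_pts[
            (noise_pts[:, 0] >= 0) & (noise_pts[:, 0] < h) & (noise_pts[:, 1] >= 0) & (noise_pts[:, 1] < w)
        ]
        keep = tissue.mask[noise_pts[:, 0], noise_pts[:, 1]]
        noise_pts = noise_pts[keep]
        truth[noise_pts[:, 0], noise_pts[:, 1]] = True

    img = np.zeros((h, w), dtype=float)
    n_tissue = tissue.tissue_area
    img[tissue.mask] = rng.lognormal(bg[0], bg[1], size=n_tissue)
    n_sig = int(truth.sum())
    if n_sig:
        img[truth] = rng.lognormal(fg[0], fg[1], size=n_sig)

    frac = n_sig / n_tissue
    channel = ChannelImage(pixels=img, channel=label, pixel_size=pixel_size)
    sig = SignalMap(mask=truth, threshold=float("nan"), signal_fraction=frac)
    return channel, sig, parents


# ---------------------------------------------------------------------------
# specimens and cohorts


def _profile_heterogeneity(profile: str, dual_overlap: float) -> int:
    return {
        "none": 0,
        "A": 1,
        "B": 1,
        "AB": 2,
        "AB_dual": 3 if dual_overlap > 0 else 2,
    }[profile]


def simulate_specimen(
    params: SimulationParams, index: int = 0, profile: str | None = None
) -> SyntheticSpecimen:
    """Build one specimen; ``index`` selects its counter-based streams.

    If ``profile`` is None it is drawn from ``profile_probs`` (the same
    draw :func:`simulate_outcome_table` makes, so rendered specimens match
    the outcome table row for row).
    """
    params.validate()
    if profile is None:
        profile = PROFILES[_stream(params.seed, index, 0).choice(len(PROFILES), p=params.profile_probs)]
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}")

    tissue = make_tissue_mask(
        params.image_shape,
        params.tissue_smoothness,
        params.tissue_fraction,
        seed=(params.seed * 1000003 + index) % (2**31),
    )
    rng_cancer = _stream(params.seed, index, 1)
    cancer = _annotation_mask(tissue, params.cancer_region_fraction, params.tissue_smoothness, rng_cancer)

    parent_support = cancer if params.seed_clusters_in_cancer else None
    fg = (params.fg_mu, params.fg_sigma)
    bg = (params.bg_mu, params.bg_sigma)

    # shared parents create the dual cluster type
    rng_shared = _stream(params.seed, index, 2)
    area_mm2 = tissue.tissue_area * params.px_area_mm2
    shared = np.empty((0, 2))
    rate_a = params.marker_a.parent_rate if profile in ("A", "AB", "AB_dual") else 0.0
    rate_b = params.marker_b.parent_rate if profile in ("B", "AB", "AB_dual") else 0.0
    if profile == "AB_dual" and params.dual_overlap > 0:
        shared_rate = params.dual_overlap * min(rate_a, rate_b)
        n_shared = rng_shared.poisson(shared_rate * area_mm2)
        shared_support = tissue.mask if parent_support is None else (parent_support & tissue.mask)
        shared = _sample_points(shared_support, int(n_shared), rng_shared)
        rate_a -= shared_rate
        rate_b -= shared_rate

    chan_a, truth_a, parents_a = simulate_channel(
        tissue,
        replace(params.marker_a, parent_rate=max(rate_a, 0.0)),
        params.pixel_size,
        fg=fg,
        bg=bg,
        shared_parents=shared,
        rng=_stream(params.seed, index, 3),
        label="CA19-9",
        parent_support=parent_support,
    )
    chan_b, truth_b, parents_b = simulate_channel(
        tissue,
        replace(params.marker_b, parent_rate=max(rate_b, 0.0)),
        params.pixel_size,
        fg=fg,
        bg=bg,
        shared_parents=shared,
        rng=_stream(params.seed, index, 4),
        label="STRA",
        parent_support=parent_support,
    )

    # nuclear channel: iid per-pixel nuclear occupancy at nuclear_density
    rng_nuc = _stream(params.seed, index, 5)
    h, w = tissue.shape
    nuc_truth = np.zeros((h, w), dtype=bool)
    nuc_truth[tissue.mask] = rng_nuc.random(tissue.tissue_area) < params.nuclear_density
    nuc_img = np.zeros((h, w), dtype=float)
    nuc_img[tissue.mask] = rng_nuc.lognormal(bg[0], bg[1], size=tissue.tissue_area)
    if nuc_truth.any():
        nuc_img[nuc_truth] = rng_nuc.lognormal(fg[0], fg[1], size=int(nuc_truth.sum()))
    nuclear = ChannelImage(pixels=nuc_img, channel="nuclear", pixel_size=params.pixel_size)

    return SyntheticSpecimen(
        specimen_id=f"S{index:03d}",
        tissue=tissue,
        cancer_annotation=cancer,
        channels={"nuclear": nuclear, "marker_a": chan_a, "marker_b": chan_b},
        truth_signal={"marker_a": truth_a, "marker_b": truth_b},
        truth_parents={"marker_a": parents_a, "marker_b": parents_b},
        heterogeneity_truth=_profile_heterogeneity(profile, params.dual_overlap),
        profile=profile,
    )


def simulate_outcome_table(params: SimulationParams) -> pd.DataFrame:
    """Profiles, heterogeneity truth and recurrence outcomes for a cohort,
    without rendering images.

    Uses the same per-specimen streams as :func:`simulate_cohort`, so the
    outcome rows are identical whether or not images are generated —
    which keeps large replicate simulations of the cohort statistics
    cheap.
    """
    params.validate()
    rows = []
    for i in range(params.n_specimens):
        profile = PROFILES[_stream(params.seed, i, 0).choice(len(PROFILES), p=params.profile_probs)]
        het = _profile_heterogeneity(profile, params.dual_overlap)
        rng_out = _stream(params.seed, i, 9)
        hazard = params.hazard_baseline * math.exp(params.log_hazard_ratio * (het >= 2))
        draw = rng_out.exponential(1.0 / hazard) if hazard > 0 else math.inf
        if draw < params.censoring_horizon:
            time, event = draw, 1
        else:
            time, event = params.censoring_horizon, 0
        rows.append(
            {"specimen_id": f"S{i:03d}", "time": float(time), "event": int(event), "het_truth": het, "profile": profile}
        )
    return pd.DataFrame(rows)


def simulate_cohort(params: SimulationParams) -> CohortBundle:
    """Full cohort: rendered specimens plus the outcome table.

    Each specimen's heterogeneity is fixed by construction (which cluster
    types were seeded) and its recurrence time drawn from the exponential
    proportional-hazards model, censored at the horizon. Fully
    reproducible from ``params.seed``.
    """
    if params.n_specimens < 2:
        raise ValueError("a cohort requires at least 2 specimens")
    outcomes = simulate_outcome_table(params)
    specimens = [
        simulate_specimen(params, index=i, profile=outcomes["profile"].iat[i])
        for i in range(params.n_specimens)
    ]
    return CohortBundle(specimens=specimens, outcomes=outcomes)
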