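"""Per-specimen and cohort orchestration.

``quantify_specimen`` composes the per-specimen stages — tissue support,
automatic thresholding, moving-box concentration, cluster calling and
cluster typing — into one quantification row. ``run_specimen`` /
``run_cohort`` are the file-based entry points behind the CLI: they read
channel images and the cohort table, write maps and tables under the
output directory, and compute the cohort statistics (ROC dichotomization
of the cluster-type fractions, the heterogeneity χ², median-split
Kaplan–Meier / log-rank, and Cox + ρ² per quantification). Everything is
deterministic for fixed inputs and configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .cluster_types import TYPE_NAMES, count_cluster_types, type_map
from .detect import auto_threshold, cellularity, intensity_metrics, signal_map, tissue_mask_from_nuclear
from .spatial import box_concentration, call_clusters, cluster_profile, window_px_from_mm
from .stats import (
    cox_fit,
    heterogeneity_table,
    log_rank,
    median_split,
    roc_cutoff,
    rho2_xoq,
)
from .types import ChannelImage, TissueMask

__all__ = [
    "SignalConfig",
    "SpatialConfig",
    "RoiConfig",
    "StatsConfig",
    "RunConfig",
    "SpecimenQuant",
    "CohortResult",
    "quantify_specimen",
    "run_specimen",
    "run_cohort",
    "cohort_statistics",
]

CHANNEL_FILES = {"nuclear": "nuclear.tif", "marker_a": "marker_a.tif", "marker_b": "marker_b.tif"}


@dataclass
class SignalConfig:
    k: float = 6.0  # robust-background multiplier for the threshold m + k·s
    top_decile: str = "mean_top_decile"
    closing_um: float = 25.0
    min_object_px: int | None = None


@dataclass
class SpatialConfig:
    window_mm: float = 1.0
    tau_ladder: tuple[float, ...] = (0.02, 0.05, 0.10, 0.20, 0.40)
    primary_tau: float = 0.10
    connectivity: int = 2


@dataclass
class RoiConfig:
    roi_mm: float = 3.0
    min_tissue_fraction: float = 0.25
    min_type_px: int | None = None
    min_overlap_fraction: float = 0.05


@dataclass
class StatsConfig:
    rho2_variant: str = "events"


@dataclass
class RunConfig:
    images_dir: str = "."
    cohort_csv: str = "cohort.csv"
    output_dir: str = "out"
    pixel_size: float = 20.0  # µm/px, used when images carry no scale
    seed: int = 0
    signal: SignalConfig = field(default_factory=SignalConfig)
    spatial: SpatialConfig = field(default_factory=SpatialConfig)
    roi: RoiConfig = field(default_factory=RoiConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = gio.load_yaml(path) or {}
        kwargs = {}
        for key, sub in (("signal", SignalConfig), ("spatial", SpatialConfig), ("roi", RoiConfig), ("stats", StatsConfig)):
            if key in raw:
                section = dict(raw.pop(key))
                if "tau_ladder" in section:
                    section["tau_ladder"] = tuple(section["tau_ladder"])
                kwargs[key] = sub(**section)
        kwargs.update(raw)
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        gio.save_params_yaml(path, self)


@dataclass
class SpecimenQuant:
    """One specimen's quantification row (cluster-type indicators are
    filled at the cohort stage, where the ROC cutoffs live)."""

    specimen_id: str
    a_signal_fraction: float
    b_signal_fraction: float
    a_mean_above_threshold: float
    b_mean_above_threshold: float
    a_top_decile_mean: float
    b_top_decile_mean: float
    a_cluster_amount: float
    b_cluster_amount: float
    a_cluster_regions: int
    b_cluster_regions: int
    A_only_frac: float
    B_only_frac: float
    dual_frac: float
    cellularity: float

    def as_row(self) -> dict:
        return dict(self.__dict__)


def _cluster_stage(channel: ChannelImage, tissue: TissueMask, cfg: SpatialConfig, sig):
    w = window_px_from_mm(cfg.window_mm, channel.pixel_size)
    max_w = min(tissue.shape)
    if w > max_w:  # small frames: largest odd window that fits
        w = max_w if max_w % 2 == 1 else max_w - 1
    conc = box_concentration(sig, w, window_mm=cfg.window_mm)
    prof = cluster_profile(conc, list(cfg.tau_ladder), tissue, primary_tau=cfg.primary_tau, connectivity=cfg.connectivity)
    clust = call_clusters(conc, cfg.primary_tau, tissue, connectivity=cfg.connectivity)
    return conc, prof, clust


def quantify_specimen(
    specimen_id: str,
    channels: dict,
    signal_cfg: SignalConfig | None = None,
    spatial_cfg: SpatialConfig | None = None,
    tissue: TissueMask | None = None,
) -> tuple[SpecimenQuant, dict]:
    """Run detection → concentration → clustering → typing on one
    specimen.

    ``channels`` must contain "nuclear", "marker_a" and "marker_b"
    ChannelImages. Returns the quantification row and the intermediate
    maps (tissue, per-channel SignalMap / ConcentrationMap / ClusterMask /
    ClusterProfile, and the ClusterTypeMap).
    """
    signal_cfg = signal_cfg or SignalConfig()
    spatial_cfg = spatial_cfg or SpatialConfig()
    for name in CHANNEL_FILES:
        if name not in channels:
            raise KeyError(f"missing channel: {name}")
    nuclear = channels["nuclear"]
    if tissue is None:
        tissue = tissue_mask_from_nuclear(
            nuclear, min_object_px=signal_cfg.min_object_px, closing_um=signal_cfg.closing_um, k=signal_cfg.k
        )

    maps: dict = {"tissue": tissue}
    per_channel = {}
    for key in ("marker_a", "marker_b"):
        ch = channels[key]
        thr = auto_threshold(ch, tissue, k=signal_cfg.k)
        sig = signal_map(ch, tissue, thr)
        metrics = intensity_metrics(ch, tissue, sig, top_decile=signal_cfg.top_decile)
        conc, prof, clust = _cluster_stage(ch, tissue, spatial_cfg, sig)
        per_channel[key] = (sig, metrics, conc, prof, clust)
        maps[key] = {"signal": sig, "concentration": conc, "profile": prof, "clusters": clust}

    cell = cellularity(nuclear, tissue, k=signal_cfg.k)
    tmap = type_map(per_channel["marker_a"][4], per_channel["marker_b"][4], tissue)
    maps["types"] = tmap

    (sig_a, met_a, _, prof_a, _), (sig_b, met_b, _, prof_b, _) = per_channel["marker_a"], per_channel["marker_b"]
    quant = SpecimenQuant(
        specimen_id=specimen_id,
        a_signal_fraction=sig_a.signal_fraction,
        b_signal_fraction=sig_b.signal_fraction,
        a_mean_above_threshold=met_a.mean_above_threshold,
        b_mean_above_threshold=met_b.mean_above_threshold,
        a_top_decile_mean=met_a.top_decile_mean,
        b_top_decile_mean=met_b.top_decile_mean,
        a_cluster_amount=prof_a.cluster_amount,
        b_cluster_amount=prof_b.cluster_amount,
        a_cluster_regions=prof_a.primary_regions,
        b_cluster_regions=prof_b.primary_regions,
        A_only_frac=tmap.fractions["A_only"],
        B_only_frac=tmap.fractions["B_only"],
        dual_frac=tmap.fractions["dual"],
        cellularity=cell,
    )
    return quant, maps


def _load_channels(config: RunConfig, specimen_id: str) -> dict:
    base = Path(config.images_dir) / specimen_id
    channels = {}
    for name, fname in CHANNEL_FILES.items():
        path = base / fname
        if not path.exists():
            raise FileNotFoundError(f"specimen {specimen_id}: missing channel image {path} (channel '{name}')")
        label = {"nuclear": "nuclear", "marker_a": "CA19-9", "marker_b": "STRA"}[name]
        channels[name] = gio.load_channel(path, channel=label, pixel_size=config.pixel_size)
    return channels


def run_specimen(config: RunConfig, specimen_id: str, write: bool = True) -> SpecimenQuant:
    """File-based per-specimen run: load channels, quantify, write maps
    and the quantification row under ``output_dir/<specimen_id>``."""
    channels = _load_channels(config, specimen_id)
    quant, maps = quantify_specimen(specimen_id, channels, config.signal, config.spatial)
    if write:
        outdir = Path(config.output_dir) / specimen_id
        outdir.mkdir(parents=True, exist_ok=True)
        gio.save_mask(outdir / "tissue.png", maps["tissue"].mask)
        for key, tag in (("marker_a", "a"), ("marker_b", "b")):
            gio.save_mask(outdir / f"signal_{tag}.png", maps[key]["signal"].mask)
            gio.save_float_map(outdir / f"concentration_{tag}.tif", maps[key]["concentration"].values)
            gio.save_mask(outdir / f"clusters_{tag}.png", maps[key]["clusters"].mask)
        gio.iio.imwrite(str(outdir / "cluster_types.png"), maps["types"].labels)
        pd.DataFrame([quant.as_row()]).to_csv(outdir / "quantification.csv", index=False)
    return quant


@dataclass
class CohortResult:
    quant: pd.DataFrame  # per-specimen quantifications + indicators + n_types
    cutoffs: dict  # ROC cutoff per cluster-type fraction
    het_chi2: object  # ChiSquareResult
    survival: pd.DataFrame  # per-quantification log-rank and Cox/ρ² rows
    excluded: list  # specimen ids excluded for unknown outcome


#: quantification columns carried into the survival analyses
SURVIVAL_QUANTS = (
    "a_signal_fraction",
    "b_signal_fraction",
    "a_cluster_amount",
    "b_cluster_amount",
    "A_only_frac",
    "B_only_frac",
    "dual_frac",
    "cellularity",
    "n_types",
)

_TYPE_FRAC_COLS = {"A_only": "A_only_frac", "B_only": "B_only_frac", "dual": "dual_frac"}


def cohort_statistics(quant: pd.DataFrame, outcomes: pd.DataFrame, stats_cfg: StatsConfig | None = None) -> CohortResult:
    """Cohort-level statistics on per-specimen quantifications.

    Joins quantifications to outcomes (specimens without a known outcome
    are excluded and reported), derives ROC cutoffs for the three
    cluster-type fractions against recurrence, scores each specimen's
    number of cluster types and heterogeneity, tests heterogeneity ×
    recurrence by χ², and fits median-split log-rank plus Cox/ρ² models
    per quantification.
    """
    stats_cfg = stats_cfg or StatsConfig()
    df = quant.merge(outcomes[["specimen_id", "time", "event"]], on="specimen_id", how="left")
    excluded = df.loc[df["time"].isna() | df["event"].isna(), "specimen_id"].tolist()
    df = df.dropna(subset=["time", "event"]).reset_index(drop=True)
    if len(df) < 2:
        raise ValueError("at least 2 specimens with known outcome are required")
    events = df["event"].astype(int).values

    cutoffs = {}
    for type_name, col in _TYPE_FRAC_COLS.items():
        try:
            roc = roc_cutoff(df[col].values, events)
        except ValueError as exc:
            raise ValueError(f"ROC dichotomization failed for {col}: {exc}") from exc
        cutoffs[type_name] = roc.cutoff
        df[f"ind_{type_name}"] = (df[col].values >= roc.cutoff).astype(int)

    counts = []
    for _, row in df.iterrows():
        n, _het = count_cluster_types({t: row[f"ind_{t}"] for t in TYPE_NAMES})
        counts.append(n)
    df["n_types"] = counts
    df["heterogeneous"] = df["n_types"] >= 2

    het_chi2 = heterogeneity_table(df["heterogeneous"].values, events)

    rows = []
    times = df["time"].values
    for col in SURVIVAL_QUANTS:
        vals = df[col].values.astype(float)
        row: dict = {"quantification": col}
        high = median_split(vals)
        if high.any() and (~high).any():
            lr = log_rank((times[~high], events[~high]), (times[high], events[high]))
            row["logrank_stat"], row["logrank_p"] = lr.statistic, lr.p
        else:
            row["logrank_stat"] = row["logrank_p"] = float("nan")
        try:
            fit = cox_fit(times, events, vals)
            rho2 = (
                fit.rho2_xoq
                if stats_cfg.rho2_variant == "events"
                else rho2_xoq(fit.lr_stat, fit.n_events, variant="n", n_total=len(df))
            )
            row.update(
                cox_beta=fit.beta_hat, cox_se=fit.se, lr_stat=fit.lr_stat, rho2_xoq=rho2, separation=fit.separation
            )
        except ValueError:
            row.update(cox_beta=float("nan"), cox_se=float("nan"), lr_stat=float("nan"), rho2_xoq=float("nan"), separation=False)
        rows.append(row)

    survival = pd.DataFrame(rows)
    return CohortResult(quant=df, cutoffs=cutoffs, het_chi2=het_chi2, survival=survival, excluded=excluded)


def run_cohort(config: RunConfig) -> CohortResult:
    """File-based cohort run: quantify every specimen listed in the
    cohort CSV, then compute and write the cohort statistics.

    Per-specimen rows are written before the statistics, so a statistics
    failure (e.g. single-class ROC) leaves the partial outputs in place.
    """
    outcomes = pd.read_csv(config.cohort_csv, dtype={"specimen_id": str})
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    quants = [run_specimen(config, sid).as_row() for sid in outcomes["specimen_id"]]
    quant = pd.DataFrame(quants)
    quant.to_csv(outdir / "cohort_quantifications.csv", index=False)

    result = cohort_statistics(quant, outcomes, config.stats)
    result.quant.to_csv(outdir / "cohort_quantifications.csv", index=False)
    result.survival.to_csv(outdir / "cohort_survival_stats.csv", index=False)
    config.to_yaml(outdir / "config_echo.yaml")
    with open(outdir / "report.txt", "w") as fh:
        fh.write(_report_text(result))
    return result


def _report_text(result: CohortResult) -> str:
    lines = ["cohort statistics report", "=" * 30, ""]
    if result.excluded:
        lines.append("excluded (unknown outcome): " + ", ".join(result.excluded))
    lines.append("ROC cutoffs (cluster-type fractions vs recurrence):")
    for name in TYPE_NAMES:
        lines.append(f"  {name}: {result.cutoffs[name]:.6g}")
    t = result.het_chi2.table
    lines += [
        "",
        "heterogeneity (>= 2 cluster types) x recurrence:",
        f"  table [[{t[0,0]},{t[0,1]}],[{t[1,0]},{t[1,1]}]]",
        f"  chi2 = {result.het_chi2.statistic:.4f}, p = {result.het_chi2.p:.4g}",
        "",
        "survival models per quantification:",
        result.survival.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        "",
    ]
    return "\n".join(lines)
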