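"""ROI definition, transmural HA quantification and consensus-range QC.

The septal ROI — bounded by the two RV-insertion landmarks and spanning
the full wall thickness — is the reference region for summary statistics.
Helix-angle transmurality (HAT) is the linear slope of the transmural HA
profile (deg per % wall depth, or deg/mm), and the HA range is its
endo-to-epi span.  E2A mobility is the difference in median absolute
sheetlet angle between systole and diastole.  Summaries are checked
against published consensus normal ranges per sequence type and cardiac
phase, with a hard ceiling at the diffusivity of free water at body
temperature (3e-3 mm^2/s): any diffusion measure above it indicates
corruption, whatever the sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, Polygon

from .dwi_io import LVContours

__all__ = [
    "SummaryMetrics",
    "TransmuralProfile",
    "HATResult",
    "QCFlag",
    "NORMAL_RANGES",
    "FREE_WATER_CEILING",
    "septal_roi",
    "segment_partition",
    "transmural_profile",
    "ha_transmurality",
    "e2a_mobility",
    "summarize_roi",
    "normal_range_qc",
]

#: diffusivity of free water at 37 C, mm^2/s — hard QC ceiling
FREE_WATER_CEILING = 3e-3

#: guard against statistically meaningless regions
MIN_ROI_VOXELS = 50

# Consensus approximate normal values per metric/sequence/phase:
# (mean, sd, typical_range).  typical_range=None -> QC falls back to
# mean +/- 2 SD.  Diffusivities in mm^2/s, angles in degrees, HAT in
# deg per % wall depth.  Read-only data asset.
NORMAL_RANGES: dict[tuple[str, str, str], tuple[float, float | None, tuple | None]] = {
    ("md", "STEAM", "any"): (1.03e-3, 0.11e-3, (0.8e-3, 1.2e-3)),
    ("fa", "STEAM", "systole"): (0.47, 0.04, (0.43, 0.51)),
    ("fa", "STEAM", "diastole"): (0.58, 0.04, (0.54, 0.62)),
    ("e2a", "STEAM", "diastole"): (13.0, 6.0, (7.0, 20.0)),
    ("e2a", "STEAM", "end_systole"): (62.0, 5.0, (51.0, 67.0)),
    ("md", "MCSE", "systole"): (1.45e-3, 0.23e-3, (1.22e-3, 1.68e-3)),
    ("fa", "MCSE", "systole"): (0.36, 0.04, (0.22, 0.58)),
    ("e2a", "MCSE", "mid_systole"): (38.0, 8.0, (34.0, 47.0)),
    ("ha_range", "any", "any"): (102.5, None, (95.0, 110.0)),
    ("hat", "any", "any"): (-1.0, 0.06, None),
    ("e2a_mobility", "any", "any"): (45.0, None, (39.0, 50.0)),
}


@dataclass
class TransmuralProfile:
    bin_centers: np.ndarray     # nominal bin centres, % depth
    bin_depth: np.ndarray       # mean voxel depth per populated bin
    bin_ha: np.ndarray          # circular-aware, unwrapped per-bin HA (deg)
    counts: np.ndarray
    empty_bins: np.ndarray      # indices of unpopulated bins


@dataclass
class HATResult:
    slope_deg_per_pct: float
    slope_deg_per_mm: float
    intercept_deg: float
    ha_range: float             # endo-to-epi span, deg


@dataclass
class SummaryMetrics:
    """Per-ROI summary statistics for one acquisition/phase."""

    md_mean: float = np.nan
    md_median: float = np.nan
    md_sd: float = np.nan
    fa_mean: float = np.nan
    fa_median: float = np.nan
    fa_sd: float = np.nan
    mode_mean: float = np.nan
    mode_median: float = np.nan
    e2a_median: float = np.nan
    ha_range: float = np.nan
    hat_deg_per_pct: float = np.nan
    hat_deg_per_mm: float = np.nan
    e2a_mobility: float | None = None
    n_voxels: int = 0
    extras: dict = field(default_factory=dict)


@dataclass
class QCFlag:
    metric: str
    value: float
    status: str                 # "in_range" | "out_of_range" | "hard_flag"
    rule: str                   # which reference rule fired
    reference: tuple | None


def _polar_angles(points: np.ndarray, center: np.ndarray) -> np.ndarray:
    d = points - center
    return np.degrees(np.arctan2(d[..., 1], d[..., 0]))


def septal_roi(
    contours: LVContours,
    mask: np.ndarray,
    pixel_spacing: float,
    min_voxels: int = MIN_ROI_VOXELS,
) -> np.ndarray:
    """Septal ROI: myocardial voxels between the RV-insertion angles.

    The ROI spans the minor arc between the two insertion landmarks about
    the LV centroid (full transmural extent), with any delineated
    trabeculation region excluded.  Raises when landmarks are missing or
    the ROI is too small to summarize.
    """
    if contours.rv_insertion is None:
        raise ValueError("septal ROI requires the two RV-insertion landmarks")
    center = contours.centroid()
    th1, th2 = _polar_angles(contours.rv_insertion, center)
    rows, cols = mask.shape
    xs = np.arange(rows) * pixel_spacing
    xx, yy = np.meshgrid(xs, np.arange(cols) * pixel_spacing, indexing="ij")
    theta = np.degrees(np.arctan2(yy - center[1], xx - center[0]))
    # membership in the minor arc from th1 to th2
    span = (th2 - th1) % 360.0
    if span > 180.0:
        th1, th2 = th2, th1
        span = 360.0 - span
    rel = (theta - th1) % 360.0
    roi = mask & (rel <= span)
    if contours.trabeculation is not None:
        poly = Polygon(contours.trabeculation)
        flat = np.column_stack([xx[roi], yy[roi]])
        inside = np.array([poly.contains(Point(*p)) for p in flat])
        idx = np.flatnonzero(roi.ravel())
        roi_flat = roi.ravel().copy()
        roi_flat[idx[inside]] = False
        roi = roi_flat.reshape(mask.shape)
    if roi.sum() < min_voxels:
        raise ValueError(
            f"septal ROI has {int(roi.sum())} voxels (< {min_voxels}); "
            "very small ROIs should be avoided"
        )
    return roi


def segment_partition(contours: LVContours, mask: np.ndarray, pixel_spacing: float) -> np.ndarray:
    """Six equal-angle segments referenced to the anterior RV insertion.

    Returns an integer label map (1..6 inside the mask, 0 outside);
    segment 1 starts at the first landmark and labels advance
    counter-clockwise.
    """
    if contours.rv_insertion is None:
        raise ValueError("segment partition requires RV-insertion landmarks")
    center = contours.centroid()
    th0 = _polar_angles(contours.rv_insertion[0], center)
    rows, cols = mask.shape
    xs = np.arange(rows) * pixel_spacing
    xx, yy = np.meshgrid(xs, np.arange(cols) * pixel_spacing, indexing="ij")
    theta = np.degrees(np.arctan2(yy - center[1], xx - center[0]))
    rel = (theta - th0) % 360.0
    labels = (rel // 60.0).astype(int) + 1
    labels[~mask] = 0
    return labels


def _circular_mean_axial(deg: np.ndarray) -> float:
    """Mean of axial angles (period 180 deg) via the doubled-angle trick."""
    rad2 = np.radians(2.0 * deg)
    return float(np.degrees(np.arctan2(np.sin(rad2).mean(), np.cos(rad2).mean())) / 2.0)


def transmural_profile(
    ha_map: np.ndarray,
    depth: np.ndarray,
    roi: np.ndarray,
    n_bins: int = 10,
    min_populated: int = 5,
) -> TransmuralProfile:
    """Bin HA by transmural depth with circular-aware averaging.

    Per-bin HA is the axial (mod-180) circular mean; the endo->epi bin
    sequence is then unwrapped so profiles crossing the +/-90 deg wrap
    stay continuous (no spurious 180 deg jumps).
    """
    sel = roi & np.isfinite(ha_map) & np.isfinite(depth)
    d = depth[sel]
    h = ha_map[sel]
    edges = np.linspace(0.0, 100.0, n_bins + 1)
    idx = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    centers, means, depths, counts, empty = [], [], [], [], []
    for k in range(n_bins):
        in_bin = idx == k
        if not in_bin.any():
            empty.append(k)
            continue
        centers.append(0.5 * (edges[k] + edges[k + 1]))
        depths.append(float(d[in_bin].mean()))
        means.append(_circular_mean_axial(h[in_bin]))
        counts.append(int(in_bin.sum()))
    if len(means) < min_populated:
        raise ValueError(
            f"only {len(means)} populated depth bins (< {min_populated})"
        )
    # unwrap endo->epi on the 180-deg axial period
    means = np.array(means)
    for k in range(1, means.size):
        while means[k] - means[k - 1] > 90.0:
            means[k] -= 180.0
        while means[k] - means[k - 1] < -90.0:
            means[k] += 180.0
    return TransmuralProfile(
        bin_centers=np.array(centers),
        bin_depth=np.array(depths),
        bin_ha=means,
        counts=np.array(counts),
        empty_bins=np.array(empty, dtype=int),
    )


def ha_transmurality(profile: TransmuralProfile, mean_wall_thickness: float) -> HATResult:
    """Helix-angle transmurality: OLS slope of HA vs transmural depth.

    The slope is reported both per % wall depth and per mm
    (``slope_mm = slope_pct * 100 / wall thickness``).  The HA range is
    the span over the per-bin means together with the fitted line
    evaluated at 0% and 100% depth — bin means alone systematically
    understate the wall-surface values by half a bin width at each side.
    """
    if profile.bin_ha.size < 3:
        raise ValueError("HAT requires at least three populated bins")
    x = profile.bin_depth
    y = profile.bin_ha
    slope, intercept = np.polyfit(x, y, 1)
    endpoints = np.array([intercept, intercept + 100.0 * slope])
    values = np.concatenate([y, endpoints])
    return HATResult(
        slope_deg_per_pct=float(slope),
        slope_deg_per_mm=float(slope * 100.0 / mean_wall_thickness),
        intercept_deg=float(intercept),
        ha_range=float(values.max() - values.min()),
    )


def e2a_mobility(e2a_systole_median: float, e2a_diastole_median: float):
    """Sheetlet mobility: median absolute systolic minus diastolic E2A (deg).

    Normally sheetlets re-orient radially in systole so mobility is
    positive; a negative value (diastolic > systolic) is reported as-is
    with a reduced-mobility flag for the caller.
    """
    mobility = float(e2a_systole_median - e2a_diastole_median)
    return mobility, mobility < 0


def summarize_roi(
    md: np.ndarray,
    fa: np.ndarray,
    mode: np.ndarray,
    angle_maps,
    frames,
    roi: np.ndarray,
    n_bins: int = 10,
) -> SummaryMetrics:
    """Summary statistics (MD/FA/mode/E2A/HAT/HA-range) over one ROI."""
    sel = roi & np.isfinite(md)
    n = int(sel.sum())
    if n < MIN_ROI_VOXELS:
        raise ValueError(f"ROI too small to summarize ({n} voxels)")
    profile = transmural_profile(angle_maps.ha, frames.depth, roi, n_bins=n_bins)
    hat = ha_transmurality(profile, float(frames.wall_thickness[sel].mean()))
    e2a_sel = roi & np.isfinite(angle_maps.e2a)
    return SummaryMetrics(
        md_mean=float(md[sel].mean()),
        md_median=float(np.median(md[sel])),
        md_sd=float(md[sel].std()),
        fa_mean=float(np.nanmean(fa[sel])),
        fa_median=float(np.nanmedian(fa[sel])),
        fa_sd=float(np.nanstd(fa[sel])),
        mode_mean=float(np.nanmean(mode[sel])),
        mode_median=float(np.nanmedian(mode[sel])),
        e2a_median=float(np.median(np.abs(angle_maps.e2a[e2a_sel]))),
        ha_range=hat.ha_range,
        hat_deg_per_pct=hat.slope_deg_per_pct,
        hat_deg_per_mm=hat.slope_deg_per_mm,
        n_voxels=n,
    )


_METRIC_FIELDS = {
    "md": "md_mean",
    "fa": "fa_mean",
    "e2a": "e2a_median",
    "ha_range": "ha_range",
    "hat": "hat_deg_per_pct",
    "e2a_mobility": "e2a_mobility",
}


def _lookup(metric: str, sequence_kind: str, phase: str):
    for seq in (sequence_kind, "any"):
        for ph in (phase, "any"):
            key = (metric, seq, ph)
            if key in NORMAL_RANGES:
                return key, NORMAL_RANGES[key]
    return None, None


def normal_range_qc(
    summary: SummaryMetrics,
    sequence_kind: str,
    phase: str,
) -> list[QCFlag]:
    """Flag each summary metric against the matching consensus normal row.

    STEAM and MCSE references are never mixed; a metric with no row for
    the given sequence/phase is skipped.  Where a typical range is
    printed it is used directly, otherwise mean +/- 2 SD; the fired rule
    is recorded on each flag.  Any diffusion measure above the free-water
    ceiling is hard-flagged regardless of range.
    """
    if sequence_kind not in ("STEAM", "MCSE"):
        raise ValueError("sequence_kind must be 'STEAM' or 'MCSE'")
    flags: list[QCFlag] = []
    for metric, attr in _METRIC_FIELDS.items():
        value = getattr(summary, attr)
        if value is None or not np.isfinite(value):
            continue
        if metric == "md" and value > FREE_WATER_CEILING:
            flags.append(QCFlag(
                metric="md", value=value, status="hard_flag",
                rule=f"exceeds free-water diffusivity ceiling {FREE_WATER_CEILING:g} mm^2/s",
                reference=None,
            ))
            continue
        key, row = _lookup(metric, sequence_kind, phase)
        if row is None:
            continue
        mean, sd, typical = row
        if typical is not None:
            lo, hi = typical
            rule = f"typical range {key}"
        else:
            lo, hi = mean - 2 * sd, mean + 2 * sd
            rule = f"mean±2SD {key}"
        status = "in_range" if lo <= value <= hi else "out_of_range"
        flags.append(QCFlag(metric=metric, value=float(value), status=status,
                            rule=rule, reference=(lo, hi)))
    return flags


def reporting_manifest(metadata: dict) -> dict[str, object]:
    """Acquisition-parameter reporting manifest.

    Lists the consensus-recommended reporting fields with the value found
    in the acquisition metadata or a "missing" marker.
    """
    recommended = [
        "sequence", "b_values", "n_directions", "n_repetitions",
        "TE_ms", "TR", "TM_ms", "trigger_delay_ms", "delta_ms",
        "big_delta_ms", "gradient_amplitude_mT_m", "matrix_size",
        "FOV_mm", "slice_thickness_mm", "cardiac_phase",
        "respiratory_strategy", "registration", "outlier_rejection",
        "fit_method", "roi_definition",
    ]
    return {k: metadata.get(k, "missing") for k in recommended}
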