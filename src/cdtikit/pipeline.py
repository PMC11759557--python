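"""End-to-end convenience pipeline: stack + table + contours -> maps + summary.

Mirrors the consensus postprocessing workflow: inspect and reject
corrupted frames, rigid-register, fit the tensor on the overdetermined
system, eigendecompose, derive scalar and angle maps in the local cardiac
frame, and summarize over the septal ROI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cardiac_geometry import AngleMaps, LocalFrameField, angle_maps, build_local_frames
from .diffusion_model import GradientTable
from .dwi_io import DwiStack, LVContours
from .metrics_report import SummaryMetrics, septal_roi, summarize_roi
from .preprocess import QCReport, attenuation_check, detect_corrupted_frames, rigid_register
from .tensor_fit import (
    EigenSystem,
    TensorField,
    compute_fa,
    compute_md,
    compute_mode,
    eigendecompose,
    fit_tensor,
)

__all__ = ["PipelineResult", "run_pipeline", "myocardial_mask"]


def myocardial_mask(contours: LVContours, grid_shape, pixel_spacing: float) -> np.ndarray:
    """Voxel-centre myocardial mask: inside epi, outside endo."""
    from matplotlib.path import Path as MplPath

    rows, cols = grid_shape
    xs = np.arange(rows) * pixel_spacing
    xx, yy = np.meshgrid(xs, np.arange(cols) * pixel_spacing, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    inside_epi = MplPath(contours.epi).contains_points(pts)
    inside_endo = MplPath(contours.endo).contains_points(pts)
    return (inside_epi & ~inside_endo).reshape(grid_shape)


@dataclass
class PipelineResult:
    qc: QCReport
    tensor_field: TensorField
    eigensystem: EigenSystem
    md: np.ndarray
    fa: np.ndarray
    mode: np.ndarray
    angles: AngleMaps
    frames: LocalFrameField
    mask: np.ndarray
    septal: np.ndarray | None
    summary: SummaryMetrics | None

    def maps(self) -> dict[str, np.ndarray]:
        return {"md": self.md, "fa": self.fa, "mode": self.mode,
                "ha": self.angles.ha, "ta": self.angles.ta, "e2a": self.angles.e2a}


def run_pipeline(
    stack: DwiStack,
    table: GradientTable,
    contours: LVContours,
    mask: np.ndarray | None = None,
    reject_outliers: bool = True,
    register: bool = True,
    weighted_fit: bool = False,
    rr_correction: bool = True,
    summarize: bool = True,
) -> PipelineResult:
    """Run the full postprocessing chain on one short-axis acquisition."""
    grid = stack.grid_shape
    if mask is None:
        mask = myocardial_mask(contours, grid, stack.pixel_spacing)
    qc = QCReport()
    qc.attenuation = attenuation_check(stack, table, mask)

    data = stack.data
    keep = np.ones(len(table), bool)
    if reject_outliers:
        outliers = detect_corrupted_frames(stack, table, mask)
        qc.outliers = outliers
        keep = outliers.keep
    if register:
        data, reg = rigid_register(stack, reference_frame=int(np.flatnonzero(keep)[0]))
        qc.registration = reg

    sub_table = GradientTable(
        directions=table.directions[keep],
        b_values=table.b_values[keep],
        rr_intervals=None if table.rr_intervals is None else table.rr_intervals[keep],
        sequence_kind=table.sequence_kind,
        steam_timing=table.steam_timing,
        acquisition_metadata=table.acquisition_metadata,
    )
    field = fit_tensor(data[keep], sub_table, mask,
                       weighted=weighted_fit, rr_correction=rr_correction)
    eig = eigendecompose(field)
    md = np.where(mask, compute_md(eig), np.nan)
    fa = np.where(mask, compute_fa(eig), np.nan)
    mode = np.where(mask, compute_mode(eig), np.nan)
    frames = build_local_frames(contours, grid, stack.pixel_spacing, mask=mask)
    angles = angle_maps(eig, frames, mask)

    septal = None
    summary = None
    if contours.rv_insertion is not None:
        septal = septal_roi(contours, mask, stack.pixel_spacing)
        if summarize:
            summary = summarize_roi(md, fa, mode, angles, frames, septal)
    return PipelineResult(
        qc=qc, tensor_field=field, eigensystem=eig, md=md, fa=fa, mode=mode,
        angles=angles, frames=frames, mask=mask, septal=septal, summary=summary,
    )
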