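"""Readers/writers for the formats the pipeline touches.

NIfTI-1 image stacks (via nibabel), FSL-dialect gradient files (see
:mod:`cdtikit.diffusion_model`), a plain-text LV contour format, and map
rendering with the consensus colour conventions (cyclic scale for helix
angle, sequential for MD/FA/E2A, labelled colour bars everywhere).

Geometry conventions used across the package: 0-based voxel indices,
row-major arrays, world coordinates in mm from the NIfTI affine with the
voxel-centre of index (0, 0) at the affine origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import nibabel as nib
import numpy as np
from shapely.geometry import LinearRing, Point, Polygon

from .diffusion_model import GradientTable, read_bval_bvec, write_bval_bvec

__all__ = [
    "DwiStack",
    "LVContours",
    "read_dwi",
    "write_dwi",
    "read_contours",
    "write_contours",
    "write_maps",
    "render_map",
    "COLOR_SPECS",
]


@dataclass
class DwiStack:
    """Multi-frame short-axis diffusion-weighted image stack.

    ``data`` is (frames, rows, cols) in signal units; ``frame_map`` maps
    each frame to its (b-value, direction index, repeat index) triple so
    that repeats of the same encoding are never silently averaged.
    """

    data: np.ndarray
    pixel_spacing: float
    slice_thickness: float
    affine: np.ndarray | None = None
    frame_map: list[tuple[float, int, int]] = field(default_factory=list)
    sequence_kind: str = "STEAM"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 3:
            raise ValueError("DwiStack.data must be (frames, rows, cols)")
        if self.pixel_spacing <= 0 or self.slice_thickness <= 0:
            raise ValueError("pixel spacing and slice thickness must be positive")
        if np.any(self.data < 0):
            raise ValueError("signal must be non-negative (magnitude images)")
        if self.affine is None:
            self.affine = np.diag(
                [self.pixel_spacing, self.pixel_spacing, self.slice_thickness, 1.0]
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]


def build_frame_map(table: GradientTable) -> list[tuple[float, int, int]]:
    """Group identical (b, direction) pairs into repeat-indexed entries."""
    seen: list[tuple[float, np.ndarray]] = []
    counts: dict[int, int] = {}
    out = []
    for b, g in zip(table.b_values, table.directions):
        idx = None
        for i, (b0, g0) in enumerate(seen):
            if abs(b - b0) < 1e-6 and abs(abs(g @ g0) - 1.0) < 1e-9:
                idx = i
                break
        if idx is None:
            idx = len(seen)
            seen.append((float(b), g))
        rep = counts.get(idx, 0)
        counts[idx] = rep + 1
        out.append((float(b), idx, rep))
    return out


def read_dwi(nifti_path, bval_path, bvec_path, **table_kwargs):
    """Load a DWI stack plus its gradient table.

    Returns ``(DwiStack, GradientTable)``; frame counts are cross-checked
    and the frame map is built by grouping identical encodings.
    """
    img = nib.load(str(nifti_path))
    arr = np.asarray(img.dataobj, dtype=float)
    if arr.ndim == 4:
        if arr.shape[2] != 1:
            raise ValueError("expected a single-slice short-axis stack")
        data = np.moveaxis(arr[:, :, 0, :], -1, 0)
    elif arr.ndim == 3:
        data = np.moveaxis(arr, -1, 0)
    else:
        raise ValueError("unsupported NIfTI dimensionality")
    table = read_bval_bvec(bval_path, bvec_path, **table_kwargs)
    if len(table) != data.shape[0]:
        raise ValueError(
            f"gradient table has {len(table)} frames but image has {data.shape[0]}"
        )
    zooms = img.header.get_zooms()
    stack = DwiStack(
        data=data,
        pixel_spacing=float(zooms[0]),
        slice_thickness=float(zooms[2]) if len(zooms) > 2 else 8.0,
        affine=np.array(img.affine),
        frame_map=build_frame_map(table),
        sequence_kind=table.sequence_kind,
    )
    return stack, table


def write_dwi(stack: DwiStack, table: GradientTable, nifti_path, bval_path, bvec_path):
    """Write stack + gradient table (NIfTI as rows x cols x 1 x frames)."""
    arr = np.moveaxis(stack.data, 0, -1)[:, :, None, :]
    img = nib.Nifti1Image(arr, stack.affine)
    img.header.set_zooms(
        (stack.pixel_spacing, stack.pixel_spacing, stack.slice_thickness, 1.0)
    )
    nib.save(img, str(nifti_path))
    write_bval_bvec(table, bval_path, bvec_path)


# -- LV contours ---------------------------------------------------------------


@dataclass
class LVContours:
    """Endo/epi contours in mm with optional RV-insertion landmarks.

    Polygons are vertex lists (closed implicitly); winding is normalized
    counter-clockwise on construction.  Exactly zero or two RV-insertion
    landmarks are allowed; trabeculation regions, if delineated, are an
    exclusion polygon.
    """

    endo: np.ndarray
    epi: np.ndarray
    rv_insertion: np.ndarray | None = None
    trabeculation: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.endo = self._normalize_ring(np.asarray(self.endo, float), "endo")
        self.epi = self._normalize_ring(np.asarray(self.epi, float), "epi")
        if not Polygon(self.epi).contains(Polygon(self.endo)):
            raise ValueError("endocardial contour must lie strictly inside epicardial")
        if self.rv_insertion is not None:
            self.rv_insertion = np.atleast_2d(np.asarray(self.rv_insertion, float))
            if self.rv_insertion.shape != (2, 2):
                raise ValueError("exactly two RV-insertion landmarks are required")
        if self.trabeculation is not None:
            self.trabeculation = np.asarray(self.trabeculation, float)

    @staticmethod
    def _normalize_ring(pts: np.ndarray, name: str) -> np.ndarray:
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise ValueError(f"{name} contour must be an (N>=3, 2) point list in mm")
        ring = LinearRing(pts)
        if not ring.is_simple:
            raise ValueError(f"{name} contour is self-intersecting")
        if not ring.is_ccw:
            pts = pts[::-1]
        return pts

    def centroid(self) -> np.ndarray:
        c = Polygon(self.endo).centroid
        return np.array([c.x, c.y])

    def contains(self, xy) -> bool:
        return Polygon(self.epi).contains(Point(*xy))


_SECTIONS = ("endo", "epi", "rv_insertion", "trabeculation")


def write_contours(contours: LVContours, path) -> None:
    """Write the named-section plain-text contour format (mm, '[name]' headers)."""
    lines = ["# cdtikit contours v1 — coordinates in mm, one 'x y' pair per line"]
    for name in _SECTIONS:
        pts = getattr(contours, name)
        if pts is None:
            continue
        lines.append(f"[{name}]")
        lines.extend(f"{x:.9f} {y:.9f}" for x, y in np.atleast_2d(pts))
    Path(path).write_text("\n".join(lines) + "\n")


def read_contours(path) -> LVContours:
    """Read and validate a contour file (see :func:`write_contours`)."""
    sections: dict[str, list[list[float]]] = {}
    current: str | None = None
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1]
            sections[current] = []
            continue
        if current is None:
            raise ValueError(f"point before any section header in {path}")
        sections[current].append([float(v) for v in line.split()])
    for required in ("endo", "epi"):
        if required not in sections:
            raise ValueError(f"contour file missing [{required}] section")
    def arr(name):
        return np.array(sections[name]) if name in sections and sections[name] else None
    return LVContours(
        endo=np.array(sections["endo"]),
        epi=np.array(sections["epi"]),
        rv_insertion=arr("rv_insertion"),
        trabeculation=arr("trabeculation"),
    )


# -- map output ----------------------------------------------------------------

#: Per-map colour conventions: (colormap, vmin, vmax, display scale, unit label).
#: HA uses a cyclic map wrapping at +/-90 deg; diffusivities are displayed in
#: 1e-3 mm^2/s to match how normal values are quoted.
COLOR_SPECS = {
    "ha": ("twilight_shifted", -90.0, 90.0, 1.0, "deg"),
    "ta": ("coolwarm", -90.0, 90.0, 1.0, "deg"),
    "e2a": ("magma", 0.0, 90.0, 1.0, "deg"),
    "md": ("viridis", 0.0, 3.0, 1e3, "1e-3 mm^2/s"),
    "fa": ("viridis", 0.0, 1.0, 1.0, ""),
    "mode": ("coolwarm", -1.0, 1.0, 1.0, ""),
}


def render_map(values: np.ndarray, kind: str, path=None, title: str | None = None):
    """Render one scalar map with its labelled colour bar.

    NaN voxels (outside the myocardial mask) render transparent.  Returns
    the matplotlib figure; saves a PNG when ``path`` is given.
    """
    cmap_name, vmin, vmax, scale, unit = COLOR_SPECS.get(
        kind, ("viridis", None, None, 1.0, "")
    )
    cmap = plt.get_cmap(cmap_name).copy()
    cmap.set_bad((0, 0, 0, 0))
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(values * scale, cmap=cmap, vmin=vmin, vmax=vmax,
                   origin="lower", interpolation="nearest")
    label = kind.upper() + (f" [{unit}]" if unit else "")
    fig.colorbar(im, ax=ax, label=label)
    ax.set_title(title or kind.upper())
    ax.set_axis_off()
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def write_maps(maps: dict[str, np.ndarray], out_dir, affine=None, render: bool = True):
    """Write each scalar map as NIfTI (and a rendered PNG with colour bar)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4) if affine is None else affine
    written = {}
    for name, values in maps.items():
        nii = out_dir / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(values, float)[:, :, None], affine), str(nii))
        written[name] = nii
        if render:
            render_map(values, name, path=out_dir / f"{name}.png")
    return written
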