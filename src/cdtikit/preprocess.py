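"""Data inspection, corrupted-frame rejection and rigid registration.

The pipeline's first stages: a bulk attenuation sanity check (the mean
septal signal should drop by roughly 30-50% between the low- and high-b
images, scaling as exp(-bD)), automated rejection of frames with profound
artifactual signal loss, and translation-only rigid registration — the
minimum motion correction required before any pixel-wise model fitting.

The rejection statistic is deliberately simple and deterministic: each
frame's masked mean signal is compared against the robust centre
(median / MAD) of its b-shell.  No consensus exists on a superior
data-curating approach, so an explainable rule is preferred.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .diffusion_model import GradientTable, design_matrix

__all__ = [
    "AttenuationResult",
    "OutlierResult",
    "RegistrationResult",
    "QCReport",
    "attenuation_check",
    "detect_corrupted_frames",
    "rigid_register",
]

#: accepted band for the low->high b signal reduction (fraction)
DEFAULT_ATTENUATION_BAND = (0.30, 0.50)
#: frames whose masked mean falls below this fraction of the shell median
#: are rejected outright (profound signal dropout)
DROPOUT_FRACTION = 0.7


@dataclass
class AttenuationResult:
    ratio: float            # mean high-b / mean low-b masked signal
    reduction: float        # 1 - ratio
    passed: bool
    band: tuple[float, float]


@dataclass
class OutlierResult:
    scores: np.ndarray      # per-frame robust z-scores (NaN where shell too small)
    rejected: np.ndarray    # indices of rejected frames
    keep: np.ndarray        # boolean keep mask over frames


@dataclass
class RegistrationResult:
    shifts: np.ndarray          # applied per-frame (drow, dcol) in pixels
    boundary_flagged: np.ndarray  # frames whose optimum hit the search bound


@dataclass
class QCReport:
    """Aggregated QC outcome for one acquisition."""

    attenuation: AttenuationResult | None = None
    outliers: OutlierResult | None = None
    registration: RegistrationResult | None = None
    notes: list[str] = field(default_factory=list)

    def to_text(self) -> str:
        lines = ["# cdtikit QC report"]
        if self.attenuation is not None:
            a = self.attenuation
            lines.append(
                f"attenuation_reduction: {a.reduction:.4f} "
                f"(band {a.band[0]:.2f}-{a.band[1]:.2f}) "
                f"=> {'PASS' if a.passed else 'FAIL'}"
            )
        if self.outliers is not None:
            lines.append(f"rejected_frames: {list(map(int, self.outliers.rejected))}")
            lines.append(
                "frame_scores: "
                + " ".join(f"{s:.2f}" if np.isfinite(s) else "na"
                           for s in self.outliers.scores)
            )
        if self.registration is not None:
            r = self.registration
            lines.append("registration_shifts_px: "
                         + " ".join(f"({dr:+.2f},{dc:+.2f})" for dr, dc in r.shifts))
            if r.boundary_flagged.any():
                lines.append(
                    "boundary_flagged_frames: "
                    f"{list(np.flatnonzero(r.boundary_flagged))}"
                )
        lines.extend(f"note: {n}" for n in self.notes)
        return "\n".join(lines) + "\n"


def attenuation_check(
    stack,
    table: GradientTable,
    mask: np.ndarray,
    band: tuple[float, float] = DEFAULT_ATTENUATION_BAND,
) -> AttenuationResult:
    """Check that high-b images are attenuated into the accepted band.

    ratio = mean masked signal over all high-b frames / mean over low-b
    frames; the reduction ``1 - ratio`` should land in ``band``
    (default 30-50%): below it there is too little diffusion contrast,
    above it too little SNR in the high-b images.
    """
    data = stack if isinstance(stack, np.ndarray) else np.asarray(stack.data, float)
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("attenuation check requires a non-empty mask")
    low, high = table.low_b_frames(), table.high_b_frames()
    if low.size == 0 or high.size == 0:
        raise ValueError("need frames at both a low and a high b-value")
    if np.isclose(table.b_values[low].mean(), table.b_values[high].mean()):
        raise ValueError("low and high b-values coincide")
    mean_low = float(data[low][:, mask].mean())
    mean_high = float(data[high][:, mask].mean())
    ratio = mean_high / mean_low
    reduction = 1.0 - ratio
    passed = band[0] <= reduction <= band[1]
    return AttenuationResult(ratio=ratio, reduction=reduction, passed=passed, band=band)


def detect_corrupted_frames(
    stack,
    table: GradientTable,
    mask: np.ndarray,
    z_threshold: float = 3.0,
) -> OutlierResult:
    """Flag frames with abnormally low masked mean signal.

    Frames are grouped into b-shells (low/high); each frame's masked mean
    is scored against its shell's median in MAD units.  A frame is
    rejected when its score falls below ``-z_threshold`` or its mean
    falls below 70% of the shell median.  Rejection never proceeds if the
    survivors could not support a tensor fit (six non-collinear high-b
    directions plus one low-b reference) — that raises instead.
    """
    data = stack if isinstance(stack, np.ndarray) else np.asarray(stack.data, float)
    mask = np.asarray(mask, bool)
    if data.shape[0] < 3:
        raise ValueError("too few frames to form an outlier reference")
    means = data[:, mask].mean(axis=1)
    scores = np.full(data.shape[0], np.nan)
    reject = np.zeros(data.shape[0], bool)
    for shell in (table.low_b_frames(), table.high_b_frames()):
        if shell.size == 0:
            continue
        med = np.median(means[shell])
        if shell.size >= 3:
            mad = np.median(np.abs(means[shell] - med))
            sigma = 1.4826 * mad
            scores[shell] = (means[shell] - med) / max(sigma, 1e-9 * max(med, 1.0))
            reject[shell] |= scores[shell] < -z_threshold
        reject[shell] |= means[shell] < DROPOUT_FRACTION * med
    rejected = np.flatnonzero(reject)
    keep = ~reject
    surviving = GradientTable(
        directions=table.directions[keep],
        b_values=table.b_values[keep],
        sequence_kind=table.sequence_kind,
    )
    try:
        surviving.validate_for_tensor_fit()
    except ValueError as err:
        raise ValueError(
            "outlier rejection would leave too few frames for tensor fitting "
            f"({err}); inspect the acquisition instead of rejecting"
        ) from err
    return OutlierResult(scores=scores, rejected=rejected, keep=keep)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized cross-correlation of two equal-shape images."""
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float((a * b).sum() / denom) if denom > 0 else 0.0


def _shift_int(img: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Integer-pixel shift with zero fill (exact, no interpolation)."""
    out = np.zeros_like(img)
    r0, r1 = max(dr, 0), img.shape[0] + min(dr, 0)
    c0, c1 = max(dc, 0), img.shape[1] + min(dc, 0)
    out[r0:r1, c0:c1] = img[r0 - dr : r1 - dr, c0 - dc : c1 - dc]
    return out


def rigid_register(
    stack,
    reference_frame: int = 0,
    window: int = 10,
    subpixel: bool = False,
):
    """Translation-only registration of every frame to a reference frame.

    Each frame is shifted to maximize normalized cross-correlation with
    the reference over an integer search window of +/-``window`` pixels,
    with optional parabolic subpixel refinement.  Frames whose optimum
    lands on the window boundary are flagged and left unshifted rather
    than silently moved to the edge of the search space.

    Returns ``(registered stack data, RegistrationResult)``.
    """
    data = stack if isinstance(stack, np.ndarray) else np.asarray(stack.data, float)
    n = data.shape[0]
    if not 0 <= reference_frame < n:
        raise ValueError("reference frame index out of range")
    ref = data[reference_frame]
    offsets = np.arange(-window, window + 1)
    out = data.copy()
    shifts = np.zeros((n, 2))
    flagged = np.zeros(n, bool)
    for f in range(n):
        if f == reference_frame:
            continue
        ncc = np.empty((offsets.size, offsets.size))
        for i, dr in enumerate(offsets):
            for j, dc in enumerate(offsets):
                ncc[i, j] = _ncc(ref, _shift_int(data[f], dr, dc))
        i, j = np.unravel_index(np.argmax(ncc), ncc.shape)
        if i in (0, offsets.size - 1) or j in (0, offsets.size - 1):
            flagged[f] = True
            warnings.warn(
                f"frame {f}: registration optimum on the +/-{window} px search "
                "boundary; shift not applied", stacklevel=2,
            )
            continue
        dr, dc = float(offsets[i]), float(offsets[j])
        if subpixel:
            dr += _parabolic_offset(ncc[i - 1, j], ncc[i, j], ncc[i + 1, j])
            dc += _parabolic_offset(ncc[i, j - 1], ncc[i, j], ncc[i, j + 1])
            out[f] = ndimage.shift(data[f], (dr, dc), order=1, mode="constant")
        else:
            out[f] = _shift_int(data[f], int(dr), int(dc))
        shifts[f] = (dr, dc)
    return out, RegistrationResult(shifts=shifts, boundary_flagged=flagged)


def _parabolic_offset(y_minus: float, y0: float, y_plus: float) -> float:
    denom = y_minus - 2.0 * y0 + y_plus
    if denom >= 0:  # not a local maximum; keep the integer optimum
        return 0.0
    return float(np.clip(0.5 * (y_minus - y_plus) / denom, -0.5, 0.5))
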