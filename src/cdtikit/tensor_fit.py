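"""Overdetermined log-linear diffusion tensor estimation and invariants.

Per voxel the model ``log S_i = log S_ref + row_i . vec(D)`` is solved by
least squares over every surviving frame (repeats are kept as separate
observations, never averaged).  The intercept log S_ref is estimated, not
pinned to a measured frame, because stimulated-echo protocols have no true
b=0 image — the low-b frame is simply another observation at its actual b.
For STEAM tables carrying per-frame RR intervals, each frame's b-value is
re-evaluated at that frame's diffusion time before the design is built.

Rotation-invariant scalars follow the standard definitions: MD is the
eigenvalue mean, FA the normalized eigenvalue dispersion in [0, 1], and
tensor mode the normalized determinant of the deviatoric tensor in
[-1, +1] (stick = +1, disk = -1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diffusion_model import GradientTable, design_matrix

__all__ = [
    "TensorField",
    "EigenSystem",
    "fit_tensor",
    "eigendecompose",
    "compute_md",
    "compute_fa",
    "compute_mode",
    "adc_from_pair",
    "mean_adc",
    "tensor_from_vec",
]

_VEC_IDX = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]


def tensor_from_vec(vec: np.ndarray) -> np.ndarray:
    """(..., 6) ``(Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)`` -> symmetric (..., 3, 3)."""
    vec = np.asarray(vec, float)
    out = np.zeros(vec.shape[:-1] + (3, 3))
    for k, (i, j) in enumerate(_VEC_IDX):
        out[..., i, j] = vec[..., k]
        out[..., j, i] = vec[..., k]
    return out


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensor plus fit diagnostics.

    ``tensors`` is (rows, cols, 3, 3) in mm^2/s, defined only where
    ``mask`` is set.  ``residual_norm`` is the per-voxel log-domain
    residual 2-norm; ``condition_number`` that of the shared design.
    """

    tensors: np.ndarray
    mask: np.ndarray
    residual_norm: np.ndarray
    condition_number: float
    negative_eigenvalue: np.ndarray | None = None


@dataclass
class EigenSystem:
    """Ordered eigensystem of a tensor field.

    ``eigenvalues`` (..., 3) sorted descending (lambda1 >= lambda2 >=
    lambda3); e1/e2/e3 unit eigenvectors, sign-normalized to a
    right-handed triple.  Negative lambda3 is flagged, never clamped.
    """

    eigenvalues: np.ndarray
    e1: np.ndarray
    e2: np.ndarray
    e3: np.ndarray
    negative_flag: np.ndarray


def fit_tensor(
    stack,
    table: GradientTable,
    mask: np.ndarray,
    weighted: bool = False,
    rr_correction: bool = True,
) -> TensorField:
    """Fit the diffusion tensor voxel-wise by (weighted) linear least squares.

    Parameters
    ----------
    stack : DwiStack or (frames, rows, cols) ndarray
        Signal stack; only voxels inside ``mask`` are fitted.
    table : GradientTable
        Must provide >= 6 non-collinear high-b directions and a low-b frame.
    weighted : bool
        Weight observations by signal^2 (first-order variance correction
        for the log transform).  Default is ordinary least squares.
    rr_correction : bool
        Re-evaluate per-frame STEAM b-values at each frame's RR interval
        when the table carries them.
    """
    data = stack if isinstance(stack, np.ndarray) else np.asarray(stack.data, float)
    if data.shape[0] != len(table):
        raise ValueError("frame count of stack and gradient table disagree")
    table.validate_for_tensor_fit()
    mask = np.asarray(mask, bool)

    b_eff = table.effective_bvalues(rr_correction=rr_correction)
    rows = design_matrix(table.directions, b_eff)
    design = np.column_stack([np.ones(len(table)), rows])  # intercept + 6
    if np.linalg.matrix_rank(design) < 7:
        raise ValueError("design rank < 7: directions/b-values cannot determine "
                         "the 6 tensor components plus intercept")
    cond = float(np.linalg.cond(design))

    signals = data[:, mask]  # (frames, nvox)
    if np.any(signals <= 0):
        # log of non-positive signal undefined; floor at a tiny positive value
        signals = np.clip(signals, 1e-12, None)
    logs = np.log(signals)

    if not weighted:
        coeffs, *_ = np.linalg.lstsq(design, logs, rcond=None)
    else:
        nvox = logs.shape[1]
        coeffs = np.empty((7, nvox))
        for j in range(nvox):
            w = signals[:, j] ** 2
            aw = design * w[:, None]
            coeffs[:, j] = np.linalg.solve(design.T @ aw, aw.T @ logs[:, j])

    resid = np.linalg.norm(design @ coeffs - logs, axis=0)
    grid = mask.shape
    tensors = np.zeros(grid + (3, 3))
    tensors[mask] = tensor_from_vec(coeffs[1:].T)
    residual_norm = np.full(grid, np.nan)
    residual_norm[mask] = resid
    return TensorField(
        tensors=tensors,
        mask=mask,
        residual_norm=residual_norm,
        condition_number=cond,
    )


def eigendecompose(field) -> EigenSystem:
    """Eigendecompose a tensor field (descending eigenvalues, RH triple).

    Accepts a :class:`TensorField` or a raw (..., 3, 3) symmetric array.
    Negative third eigenvalues are flagged in ``negative_flag`` and the
    values reported unchanged.
    """
    tensors = field.tensors if isinstance(field, TensorField) else np.asarray(field, float)
    if not np.all(np.isfinite(tensors)):
        if isinstance(field, TensorField):
            bad = ~np.all(np.isfinite(tensors), axis=(-2, -1))
            if np.any(bad & field.mask):
                raise ValueError("non-finite tensor entries inside the mask")
            tensors = np.where(np.isfinite(tensors), tensors, 0.0)
        else:
            raise ValueError("non-finite tensor entries")
    w, v = np.linalg.eigh(tensors)           # ascending
    w = w[..., ::-1]
    v = v[..., ::-1]
    # right-handed sign normalization: flip e3 where det < 0
    det = np.linalg.det(v)
    v[..., 2] = v[..., 2] * np.where(det < 0, -1.0, 1.0)[..., None]
    eig = EigenSystem(
        eigenvalues=w,
        e1=v[..., 0],
        e2=v[..., 1],
        e3=v[..., 2],
        negative_flag=w[..., 2] < 0,
    )
    if isinstance(field, TensorField):
        field.negative_eigenvalue = eig.negative_flag & field.mask
    return eig


def _eigvals(x) -> np.ndarray:
    if isinstance(x, EigenSystem):
        return x.eigenvalues
    return np.asarray(x, float)


def compute_md(eigensystem) -> np.ndarray:
    """Mean diffusivity: average of the three eigenvalues (mm^2/s)."""
    return _eigvals(eigensystem).mean(axis=-1)


def compute_fa(eigensystem) -> np.ndarray:
    """Fractional anisotropy in [0, 1]; NaN where the tensor is all-zero."""
    lam = _eigvals(eigensystem)
    md = lam.mean(axis=-1, keepdims=True)
    num = np.linalg.norm(lam - md, axis=-1)
    den = np.linalg.norm(lam, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    return np.where(den > 0, fa, np.nan)


def compute_mode(eigensystem) -> np.ndarray:
    """Tensor mode in [-1, +1]: stick-like +1, disk-like -1.

    ``mode = 3*sqrt(6) * det(A~) / ||A~||^3`` with the deviatoric tensor
    ``A~ = D - MD*I``.  Isotropic input is degenerate; 0 is returned there
    by convention.
    """
    lam = _eigvals(eigensystem)
    md = lam.mean(axis=-1, keepdims=True)
    dev = lam - md
    norm = np.linalg.norm(dev, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mode = 3.0 * np.sqrt(6.0) * np.prod(dev, axis=-1) / norm**3
    return np.where(norm > 0, np.clip(mode, -1.0, 1.0), 0.0)


def adc_from_pair(s_low, s_high, b_low: float, b_high: float):
    """Apparent diffusion coefficient along one direction from a signal pair.

    ``ADC = ln(s_low / s_high) / (b_high - b_low)``; negative values
    (signal increase with b — a noise/artifact indicator) are returned
    as-is for the caller to flag.
    """
    s_low = np.asarray(s_low, float)
    s_high = np.asarray(s_high, float)
    if b_high <= b_low:
        raise ValueError("b_high must exceed b_low")
    if np.any(s_low <= 0) or np.any(s_high <= 0):
        raise ValueError("signals must be strictly positive to form an ADC")
    return np.log(s_low / s_high) / (b_high - b_low)


def mean_adc(adcs):
    """Mean ADC over three mutually orthogonal encoding directions.

    Equals MD exactly for mono-exponential tensor data (trace identity).
    """
    adcs = np.asarray(adcs, float)
    if adcs.shape[-1] != 3:
        raise ValueError("mean ADC is defined over exactly three orthogonal ADCs")
    return adcs.mean(axis=-1)
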