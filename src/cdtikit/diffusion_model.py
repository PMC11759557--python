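"""Closed-form diffusion signal and b-value mathematics.

The mono-exponential forward model ``S = S0 * exp(-b * D)`` and the
stimulated-echo (STEAM) b-value ``b = gamma^2 delta^2 G^2 (Delta - delta/3)``
are shared by the synthetic phantom (forward simulation) and the tensor
fitter (inverse problem).  Unit policy: b-values in s*mm^-2, diffusivities
in mm^2*s^-1 internally; gradient timing in ms and amplitude in mT/m, as
quoted on scanner consoles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "GAMMA_PROTON",
    "SteamTiming",
    "GradientTable",
    "attenuate",
    "steam_bvalue",
    "gradient_amplitude_for_b",
    "builtin_directions",
    "design_row",
    "design_matrix",
    "read_bval_bvec",
    "write_bval_bvec",
]

#: Proton gyromagnetic ratio, rad s^-1 T^-1.
GAMMA_PROTON = 2.6752e8

# Fixed encoding direction sets.  The 6-direction scheme is the classic
# dual-gradient set; the 12-direction scheme is a spherical-Fibonacci
# hemisphere sampling, frozen here so that phantoms and protocols are
# reproducible run to run.  Both yield a full-rank (6) tensor design.
_SQ2 = 1.0 / np.sqrt(2.0)
_DIRECTIONS_6 = np.array(
    [
        [_SQ2, _SQ2, 0.0],
        [_SQ2, 0.0, _SQ2],
        [0.0, _SQ2, _SQ2],
        [_SQ2, -_SQ2, 0.0],
        [_SQ2, 0.0, -_SQ2],
        [0.0, _SQ2, -_SQ2],
    ]
)
_DIRECTIONS_12 = np.array(
    [
        [0.99913157, 0.00000000, 0.04166667],
        [-0.73158550, 0.67019225, 0.12500000],
        [0.08550742, -0.97431294, 0.20833333],
        [0.58198395, 0.75909501, 0.29166667],
        [-0.91285383, -0.16147099, 0.37500000],
        [0.74991315, -0.47703336, 0.45833333],
        [-0.21822166, 0.81177369, 0.54166667],
        [-0.35979543, -0.69276421, 0.62500000],
        [0.66304633, 0.24214346, 0.70833333],
        [-0.56473193, 0.23311313, 0.79166667],
        [0.20519356, -0.43848672, 0.87500000],
        [0.08549112, 0.27255915, 0.95833333],
    ]
)
# literals are stored to 8 decimals; restore exact unit norm
_DIRECTIONS_12 /= np.linalg.norm(_DIRECTIONS_12, axis=1, keepdims=True)


@dataclass(frozen=True)
class SteamTiming:
    """Timing/amplitude of the monopolar STEAM diffusion experiment.

    Parameters
    ----------
    delta : float
        Encoding-gradient duration, ms.
    big_delta : float
        Time between the paired gradients (one cardiac cycle for STEAM), ms.
    amplitude : float
        Gradient amplitude, mT/m.
    gamma : float
        Gyromagnetic ratio, rad s^-1 T^-1.  Defaults to the proton value.
    """

    delta: float
    big_delta: float
    amplitude: float
    gamma: float = GAMMA_PROTON

    def __post_init__(self) -> None:
        for name in ("delta", "big_delta", "gamma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"SteamTiming.{name} must be strictly positive")
        if self.amplitude < 0:
            raise ValueError("gradient amplitude cannot be negative")
        if self.delta >= self.big_delta:
            raise ValueError("encoding duration delta must be shorter than big_delta")


def attenuate(s0, b, d):
    """Mono-exponential diffusion attenuation ``S = S0 * exp(-b * d)``.

    Parameters
    ----------
    s0 : array_like
        Non-diffusion-weighted signal (arbitrary units), >= 0.
    b : array_like
        Diffusion weighting, s mm^-2, >= 0.
    d : array_like
        Apparent diffusivity along the encoding direction, mm^2 s^-1, >= 0.
    """
    s0, b, d = np.asarray(s0, float), np.asarray(b, float), np.asarray(d, float)
    if np.any(s0 < 0) or np.any(b < 0) or np.any(d < 0):
        raise ValueError("attenuate requires s0, b and d to be non-negative")
    return s0 * np.exp(-b * d)


def steam_bvalue(timing: SteamTiming) -> float:
    """b-value of the monopolar STEAM experiment, in s mm^-2.

    Evaluates ``gamma^2 delta^2 G^2 (Delta - delta/3)`` in SI units and
    converts to s mm^-2.  Does not apply to moment-compensated (M1/M2)
    spin-echo waveforms, whose b-values must be taken as given.
    """
    delta = timing.delta * 1e-3          # s
    big_delta = timing.big_delta * 1e-3  # s
    g = timing.amplitude * 1e-3          # T/m
    b_si = timing.gamma**2 * delta**2 * g**2 * (big_delta - delta / 3.0)
    return b_si * 1e-6  # s/m^2 -> s/mm^2


def gradient_amplitude_for_b(
    b: float, delta: float, big_delta: float, gamma: float = GAMMA_PROTON
) -> float:
    """Gradient amplitude (mT/m) that yields ``b`` at the given timing.

    Inverse of :func:`steam_bvalue`; useful when building a protocol from
    a nominal b-value.
    """
    if b < 0:
        raise ValueError("b must be non-negative")
    if b == 0:
        return 0.0
    d_s, dd_s = delta * 1e-3, big_delta * 1e-3
    g_si = np.sqrt(b * 1e6 / (gamma**2 * d_s**2 * (dd_s - d_s / 3.0)))
    return float(g_si * 1e3)


def builtin_directions(n: int) -> np.ndarray:
    """Fixed diffusion-encoding direction sets.

    ``n=3`` returns the orthonormal laboratory triad (for mean-ADC style
    acquisitions); ``n=6`` and ``n=12`` return documented non-collinear
    sets whose 6-column tensor design has full rank.  Tensor work requires
    at least six non-collinear directions plus a reference image, so other
    counts are rejected.
    """
    if n == 3:
        return np.eye(3)
    if n == 6:
        return _DIRECTIONS_6.copy()
    if n == 12:
        return _DIRECTIONS_12.copy()
    raise ValueError(
        f"unsupported direction count {n}; choose 3, 6 or 12 "
        "(tensor fitting needs >= 6 non-collinear directions)"
    )


def design_row(direction, b: float) -> np.ndarray:
    """Row of the log-linear tensor design for one frame.

    Returns ``-b * (gx^2, gy^2, gz^2, 2 gx gy, 2 gx gz, 2 gy gz)`` so that
    ``row @ vec(D) = -b * g^T D g`` with
    ``vec(D) = (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)``.
    """
    g = np.asarray(direction, float)
    if abs(np.linalg.norm(g) - 1.0) > 1e-9:
        raise ValueError("design_row requires a unit direction vector")
    gx, gy, gz = g
    return -b * np.array(
        [gx * gx, gy * gy, gz * gz, 2 * gx * gy, 2 * gx * gz, 2 * gy * gz]
    )


def design_matrix(directions, b_values) -> np.ndarray:
    """Stacked :func:`design_row` for a whole gradient table (frames x 6)."""
    directions = np.atleast_2d(np.asarray(directions, float))
    b_values = np.asarray(b_values, float)
    return np.stack([design_row(g, b) for g, b in zip(directions, b_values)])


@dataclass
class GradientTable:
    """Per-frame diffusion encoding: directions, b-values and timing metadata.

    Attributes
    ----------
    directions : (N, 3) ndarray
        Unit encoding directions (the direction of a b=0 frame is
        conventional but must still be a unit vector).
    b_values : (N,) ndarray
        Nominal per-frame diffusion weighting, s mm^-2.
    rr_intervals : (N,) ndarray, optional
        Per-frame RR interval, ms.  For STEAM the diffusion time spans one
        cardiac cycle, so RR variability changes the realized b-value; when
        present (together with ``steam_timing``) :meth:`effective_bvalues`
        rescales each frame's b accordingly.
    sequence_kind : {"STEAM", "MCSE"}
    steam_timing : SteamTiming, optional
        Nominal timing used for the RR correction.
    acquisition_metadata : dict
        Free-form acquisition fields (TE/TR/TM/trigger delay, gradient
        specs); stored and reported, never computed on.
    """

    directions: np.ndarray
    b_values: np.ndarray
    rr_intervals: np.ndarray | None = None
    sequence_kind: str = "STEAM"
    steam_timing: SteamTiming | None = None
    acquisition_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.directions = np.atleast_2d(np.asarray(self.directions, float))
        self.b_values = np.atleast_1d(np.asarray(self.b_values, float))
        if self.directions.shape != (self.b_values.size, 3):
            raise ValueError("directions and b_values lengths disagree")
        norms = np.linalg.norm(self.directions, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("every encoding direction must have unit norm")
        if np.any(self.b_values < 0):
            raise ValueError("b-values must be non-negative")
        if self.rr_intervals is not None:
            self.rr_intervals = np.atleast_1d(np.asarray(self.rr_intervals, float))
            if self.rr_intervals.size != self.b_values.size:
                raise ValueError("rr_intervals length must match frame count")
        if self.sequence_kind not in ("STEAM", "MCSE"):
            raise ValueError("sequence_kind must be 'STEAM' or 'MCSE'")

    def __len__(self) -> int:
        return self.b_values.size

    # -- b-shell bookkeeping -------------------------------------------------

    @property
    def b_max(self) -> float:
        return float(self.b_values.max())

    def low_b_frames(self) -> np.ndarray:
        """Indices of reference (low-b) frames: b below half the maximum."""
        return np.flatnonzero(self.b_values < 0.5 * self.b_max)

    def high_b_frames(self) -> np.ndarray:
        return np.flatnonzero(self.b_values >= 0.5 * self.b_max)

    def validate_for_tensor_fit(self) -> None:
        """Require >= 6 non-collinear high-b directions plus a low-b frame."""
        low, high = self.low_b_frames(), self.high_b_frames()
        if low.size < 1:
            raise ValueError("tensor fitting needs at least one low-b reference frame")
        hidir = self.directions[high]
        # collapse antipodal / repeated directions before counting
        uniq: list[np.ndarray] = []
        for g in hidir:
            if not any(abs(abs(g @ u) - 1.0) < 1e-9 for u in uniq):
                uniq.append(g)
        if len(uniq) < 6:
            raise ValueError(
                f"only {len(uniq)} unique high-b directions; tensor fitting "
                "requires a minimum of six non-collinear directions"
            )
        if np.linalg.matrix_rank(design_matrix(np.array(uniq), np.ones(len(uniq)))) < 6:
            raise ValueError("high-b directions are collinear/degenerate (design rank < 6)")

    # -- STEAM per-frame b correction ----------------------------------------

    def effective_bvalues(self, rr_correction: bool = True) -> np.ndarray:
        """Per-frame b-values, RR-corrected for STEAM when possible.

        Each frame's b is re-evaluated with the diffusion time set to that
        frame's RR interval: ``b_i = b_nom * (RR_i - delta/3) / (Delta - delta/3)``,
        which is the STEAM b-value formula at the per-frame diffusion time
        and the gradient amplitude implied by the nominal b.
        """
        b = self.b_values.astype(float).copy()
        if (
            not rr_correction
            or self.sequence_kind != "STEAM"
            or self.rr_intervals is None
            or self.steam_timing is None
        ):
            return b
        t = self.steam_timing
        scale = (self.rr_intervals - t.delta / 3.0) / (t.big_delta - t.delta / 3.0)
        if np.any(scale <= 0):
            raise ValueError("RR interval shorter than delta/3; timing inconsistent")
        return b * scale


# -- FSL-dialect gradient files ----------------------------------------------

def read_bval_bvec(bval_path, bvec_path, **kwargs) -> GradientTable:
    """Read FSL-dialect .bval (one row) and .bvec (three rows: x, y, z)."""
    bval_path, bvec_path = Path(bval_path), Path(bvec_path)
    b = np.loadtxt(bval_path, ndmin=1)
    vec = np.loadtxt(bvec_path, ndmin=2)
    if vec.shape[0] != 3:
        raise ValueError(".bvec must contain exactly three rows (x, y, z)")
    if vec.shape[1] != b.size:
        raise ValueError(".bval and .bvec frame counts disagree")
    directions = vec.T
    # b=0 frames are conventionally written with zero vectors; re-normalize
    norms = np.linalg.norm(directions, axis=1)
    zero = norms < 1e-12
    directions[zero] = [1.0, 0.0, 0.0]
    norms[zero] = 1.0
    directions /= norms[:, None]
    return GradientTable(directions=directions, b_values=b, **kwargs)


def write_bval_bvec(table: GradientTable, bval_path, bvec_path) -> None:
    """Write the table in FSL dialect; round-trips to printed precision."""
    np.savetxt(bval_path, table.b_values[None, :], fmt="%.6g")
    np.savetxt(bvec_path, table.directions.T, fmt="%.9f")
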