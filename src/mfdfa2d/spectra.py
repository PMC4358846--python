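"""Scaling exponents and singularity spectra derived from F_q(s).

The generalized Hurst exponent h(q) is the slope of ln F_q(s) on ln s.
From it follow the mass exponent tau(q) = q h(q) - 2 (support dimension
D_f = 2 for a surface), the generalized dimensions D_q = tau(q)/(q - 1)
with the information dimension D_1 estimated separately from a box-mass
entropy regression, and the Legendre pair alpha(q) = tau'(q),
f(alpha) = q alpha - tau(q) whose width Delta alpha and asymmetry
Delta f summarize texture heterogeneity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_surfaces import FEATURE_NAMES, GraySurface
from .mfdfa_core import (
    CORNERS,
    FluctuationTable,
    QGrid,
    ScaleGrid,
    compute_fluctuation_table,
)

__all__ = [
    "HurstSpectrum",
    "MultifractalSpectrum",
    "estimate_hq",
    "tau_from_h",
    "dq_from_tau",
    "estimate_D1",
    "legendre_spectrum",
    "spectrum_widths",
    "multifractal_spectrum",
    "extract_features",
]

#: Support (fractal) dimension of the image plane.
SUPPORT_DIM = 2.0


@dataclass
class HurstSpectrum:
    """Per-q slope h(q), intercept and goodness of fit of the scaling law."""

    q_values: np.ndarray
    h: np.ndarray
    intercept: np.ndarray
    r_squared: np.ndarray


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and r^2 of an ordinary least-squares line."""
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.dot(resid, resid))
    ss_tot = float(np.dot(y - y.mean(), y - y.mean()))
    r2 = 1.0 if ss_tot == 0.0 else max(0.0, 1.0 - ss_res / ss_tot)
    return float(slope), float(intercept), r2


def estimate_hq(table: FluctuationTable) -> HurstSpectrum:
    """h(q) by regressing ln F_q(s) on ln s over the full scale grid.

    All scales in the grid are used (no subrange tuning); r^2 is reported
    per q so scaling breaks can be detected by the caller.
    """
    if len(table.scale_grid) < 4:
        raise ValueError("need at least 4 scales to estimate h(q)")
    x = np.log(np.asarray(table.scale_grid.scales, dtype=float))
    qs = np.asarray(table.q_grid.q_values)
    h = np.empty(qs.size)
    c = np.empty(qs.size)
    r2 = np.empty(qs.size)
    for k in range(qs.size):
        h[k], c[k], r2[k] = _ols_line(x, np.log(table.F[k]))
    return HurstSpectrum(qs, h, c, r2)


def tau_from_h(h_spec: HurstSpectrum) -> np.ndarray:
    """Mass exponent tau(q) = q h(q) - 2; tau(0) = -2 regardless of h."""
    return h_spec.q_values * h_spec.h - SUPPORT_DIM


def dq_from_tau(
    tau: np.ndarray, q_values: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Generalized dimensions D_q = tau(q)/(q - 1) on the q != 1 support.

    Returns (q_support, D_q).  q = 1 is excluded: the information
    dimension is not a ratio of this form; use :func:`estimate_D1`.
    """
    q = np.asarray(q_values, dtype=float)
    mask = np.abs(q - 1.0) > 1e-12
    return q[mask], np.asarray(tau)[mask] / (q[mask] - 1.0)


def dq_at(tau: np.ndarray, q_values: np.ndarray, q: float) -> float:
    """D_q at a single grid point; q = 1 raises (use estimate_D1)."""
    if abs(q - 1.0) <= 1e-12:
        raise ValueError("D_1 is not tau(q)/(q-1); use estimate_D1 instead")
    qs = np.asarray(q_values, dtype=float)
    i = int(np.argmin(np.abs(qs - q)))
    if abs(qs[i] - q) > 1e-12:
        raise KeyError(f"q = {q} not on the grid")
    return float(np.asarray(tau)[i] / (q - 1.0))


def estimate_D1(
    surface: GraySurface | np.ndarray,
    scale_grid: ScaleGrid | None = None,
) -> float:
    """Information dimension from the box-mass entropy regression.

    Per scale s the surface mass in each s x s box of the top-left tiling,
    normalized by the total mass, gives probabilities P_{m,n}; D_1 is the
    slope of sum P ln P against ln s.  Empty boxes contribute 0 (the
    p ln p -> 0 limit).  Requires nonnegative values with positive total.
    """
    values = surface.values if isinstance(surface, GraySurface) else np.asarray(surface, float)
    M, N = values.shape
    if scale_grid is None:
        scale_grid = ScaleGrid.default_for(M, N)
    scale_grid.validate_for(M, N)
    if np.any(values < 0):
        raise ValueError("box-mass entropy needs nonnegative surface values")
    total = values.sum()
    if total <= 0:
        raise ValueError("surface has zero total mass")
    entropies = []
    for s in scale_grid:
        Ms, Ns = M // s, N // s
        sub = values[: Ms * s, : Ns * s]
        P = sub.reshape(Ms, s, Ns, s).sum(axis=(1, 3)) / total
        pos = P[P > 0]
        entropies.append(float(np.sum(pos * np.log(pos))))
    x = np.log(np.asarray(scale_grid.scales, dtype=float))
    slope, _, _ = _ols_line(x, np.asarray(entropies))
    return slope


def legendre_spectrum(
    tau: np.ndarray, q_values: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hoelder exponents alpha = tau'(q) and spectrum f(alpha) = q alpha - tau.

    alpha is a central finite difference of tau on the (possibly
    non-uniform) q grid; the one-sided endpoint estimates are discarded,
    so only interior q points are returned as (q_interior, alpha, f).
    A non-monotone alpha (spectrum folding from estimation noise) is
    reported as a warning and the values are kept.
    """
    q = np.asarray(q_values, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if q.size < 3:
        raise ValueError("need at least 3 q points for the Legendre transform")
    alpha = np.gradient(tau, q)[1:-1]
    q_in = q[1:-1]
    f = q_in * alpha - tau[1:-1]
    if np.any(np.diff(alpha) > 1e-9):
        warnings.warn(
            "alpha(q) is not non-increasing: the singularity spectrum folds, "
            "likely from estimation noise at extreme q",
            stacklevel=2,
        )
    return q_in, alpha, f


def spectrum_widths(
    alpha: np.ndarray, f: np.ndarray, q_values: np.ndarray
) -> tuple[float, float, float, float]:
    """(alpha_max, alpha_min, delta_alpha, delta_f) over the q support.

    delta_f = f(alpha_max) - f(alpha_min), evaluated at the q's achieving
    the alpha extrema; exact ties are broken toward the smallest |q|
    (the best-estimated part of the spectrum).
    """
    alpha = np.asarray(alpha, float)
    f = np.asarray(f, float)
    q = np.asarray(q_values, float)

    def _pick(candidates: np.ndarray) -> int:
        return int(candidates[np.argmin(np.abs(q[candidates]))])

    i_max = _pick(np.flatnonzero(alpha == alpha.max()))
    i_min = _pick(np.flatnonzero(alpha == alpha.min()))
    a_max, a_min = float(alpha[i_max]), float(alpha[i_min])
    return a_max, a_min, a_max - a_min, float(f[i_max] - f[i_min])


@dataclass
class MultifractalSpectrum:
    """All derived spectra of one surface, on a shared q grid."""

    q_values: np.ndarray
    h: np.ndarray
    r_squared: np.ndarray
    tau: np.ndarray
    q_dq: np.ndarray       # q support of D_q (q != 1)
    Dq: np.ndarray
    D2: float
    q_interior: np.ndarray
    alpha: np.ndarray
    f_alpha: np.ndarray
    alpha_max: float
    alpha_min: float
    delta_alpha: float
    delta_f: float

    def h_at(self, q: float) -> float:
        qs = self.q_values
        i = int(np.argmin(np.abs(qs - q)))
        if abs(qs[i] - q) > 1e-12:
            raise KeyError(f"q = {q} not on the grid")
        return float(self.h[i])


def multifractal_spectrum(table: FluctuationTable) -> MultifractalSpectrum:
    """h(q), tau(q), D_q, alpha, f(alpha) and widths from one F_q(s) table."""
    hs = estimate_hq(table)
    tau = tau_from_h(hs)
    q_dq, Dq = dq_from_tau(tau, hs.q_values)
    D2 = dq_at(tau, hs.q_values, 2.0)
    q_in, alpha, f = legendre_spectrum(tau, hs.q_values)
    a_max, a_min, d_alpha, d_f = spectrum_widths(alpha, f, q_in)
    return MultifractalSpectrum(
        hs.q_values, hs.h, hs.r_squared, tau, q_dq, Dq, D2,
        q_in, alpha, f, a_max, a_min, d_alpha, d_f,
    )


def extract_features(
    surface: GraySurface | np.ndarray,
    scale_grid: ScaleGrid | None = None,
    q_grid: QGrid | None = None,
    corners: Sequence[str] = CORNERS,
) -> np.ndarray:
    """The 12-parameter texture feature vector of one surface.

    Order (see :data:`mfdfa2d.io_surfaces.FEATURE_NAMES`): h(-3), h(-2),
    h(-1), h(1), h(2), h(3), alpha_max, alpha_min, delta_alpha, delta_f,
    D_1, D_2.  Deterministic composition of the full pipeline.
    """
    values = surface.values if isinstance(surface, GraySurface) else np.asarray(surface, float)
    if scale_grid is None:
        scale_grid = ScaleGrid.default_for(*values.shape)
    table = compute_fluctuation_table(values, scale_grid, q_grid, corners)
    spec = multifractal_spectrum(table)
    D1 = estimate_D1(values, scale_grid)
    vec = np.array(
        [
            spec.h_at(-3), spec.h_at(-2), spec.h_at(-1),
            spec.h_at(1), spec.h_at(2), spec.h_at(3),
            spec.alpha_max, spec.alpha_min, spec.delta_alpha, spec.delta_f,
            D1, spec.D2,
        ]
    )
    if not np.isfinite(vec).all():
        bad = [FEATURE_NAMES[i] for i in np.flatnonzero(~np.isfinite(vec))]
        raise ValueError(f"non-finite feature(s) {bad}")
    return vec
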