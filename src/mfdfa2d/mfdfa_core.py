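"""Core of the two-dimensional multifractal detrended fluctuation analysis.

The surface is partitioned into non-overlapping s x s segments starting
from each of the four corners; each segment is integrated (double
cumulative sum), a least-squares plane is removed, and the RMS residual
gives the local fluctuation F(m, n, s).  Pooling the segment fluctuations
through a generalized mean of order q yields the q-th order fluctuation
function F_q(s), whose power-law scaling in s carries the multifractal
structure of the texture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp

from .io_surfaces import GraySurface

__all__ = [
    "CORNERS",
    "ScaleGrid",
    "QGrid",
    "FluctuationTable",
    "DegenerateSurfaceError",
    "partition_indices",
    "cumulative_sum",
    "detrend_plane",
    "local_fluctuation",
    "segment_fluctuations",
    "fluctuation_function",
    "compute_fluctuation_table",
]

#: Order in which corner tilings are pooled.
CORNERS = ("TL", "TR", "BL", "BR")

#: |q| below this is treated as q = 0 (geometric-mean limit).
Q0_TOL = 1e-9

#: Feature q's that must be present on any usable q grid.
_REQUIRED_Q = (-3.0, -2.0, -1.0, 1.0, 2.0, 3.0)


class DegenerateSurfaceError(ValueError):
    """A segment has exactly zero fluctuation while q <= 0 is requested.

    A zero fluctuation (perfectly planar integrated segment, e.g. a flat
    image region) makes the q <= 0 generalized mean undefined.  Add a tiny
    positive dither to the surface or crop the flat region.
    """


def _max_scale(M: int, N: int) -> int:
    return min(M, N) // 4


def _check_scale(M: int, N: int, s: int) -> None:
    smax = _max_scale(M, N)
    if not 6 <= s <= smax:
        raise ValueError(
            f"scale s={s} outside the valid range 6 ... min(M, N)/4 = {smax} "
            f"for a {M}x{N} surface"
        )


@dataclass(frozen=True)
class ScaleGrid:
    """Strictly increasing integer scales s with 6 <= s <= min(M, N)/4."""

    scales: tuple[int, ...]

    def __post_init__(self) -> None:
        s = tuple(int(v) for v in self.scales)
        if len(s) < 4:
            raise ValueError("at least 4 scales are required for the log-log regression")
        if any(b <= a for a, b in zip(s, s[1:])):
            raise ValueError("scales must be strictly increasing")
        if s[0] < 6:
            raise ValueError("smallest scale must be >= 6")
        object.__setattr__(self, "scales", s)

    def __iter__(self):
        return iter(self.scales)

    def __len__(self) -> int:
        return len(self.scales)

    def validate_for(self, M: int, N: int) -> None:
        if self.scales[-1] > _max_scale(M, N):
            raise ValueError(
                f"largest scale {self.scales[-1]} exceeds min(M, N)/4 = "
                f"{_max_scale(M, N)} for a {M}x{N} surface"
            )

    @classmethod
    def default_for(cls, M: int, N: int, n_scales: int = 20) -> "ScaleGrid":
        """About ``n_scales`` geometrically spaced integers in 6 ... min(M, N)/4.

        Geometric spacing gives roughly uniform leverage in log s for the
        regression; duplicates from rounding are removed.
        """
        smax = _max_scale(M, N)
        if smax < 9:
            raise ValueError(
                f"surface {M}x{N} too small for a default scale grid "
                f"(needs min(M, N) >= 36)"
            )
        raw = np.geomspace(6, smax, n_scales)
        scales = tuple(sorted(set(int(round(v)) for v in raw)))
        return cls(scales)


@dataclass(frozen=True)
class QGrid:
    """Increasing grid of moment orders q covering [-15, 15].

    Must contain the six integer q's used as features (+-1, +-2, +-3) and
    the endpoints +-15; a value with |q| < 1e-9 is routed to the q = 0
    (geometric mean) branch.
    """

    q_values: tuple[float, ...]

    def __post_init__(self) -> None:
        q = tuple(float(v) for v in self.q_values)
        if any(b <= a for a, b in zip(q, q[1:])):
            raise ValueError("q values must be strictly increasing")
        present = set(q)
        for need in (*_REQUIRED_Q, -15.0, 15.0):
            if need not in present:
                raise ValueError(f"q grid must contain q = {need}")
        object.__setattr__(self, "q_values", q)

    def __iter__(self):
        return iter(self.q_values)

    def __len__(self) -> int:
        return len(self.q_values)

    def index_of(self, q: float) -> int:
        arr = np.asarray(self.q_values)
        i = int(np.argmin(np.abs(arr - q)))
        if abs(arr[i] - q) > 1e-12:
            raise KeyError(f"q = {q} not on the grid")
        return i

    @property
    def has_negative(self) -> bool:
        return self.q_values[0] <= Q0_TOL

    @classmethod
    def default(cls) -> "QGrid":
        """Integers -15 ... 15 plus +-0.5 for derivative resolution near 0."""
        q = sorted(set(range(-15, 16)) | {-0.5, 0.5})
        return cls(tuple(float(v) for v in q))


def partition_indices(M: int, N: int, s: int, corner: str = "TL") -> list[tuple[int, int]]:
    """Origins (r, t) of the M_s x N_s segments tiled from one corner.

    M_s = floor(M/s), N_s = floor(N/s); with corner TL the segment (m, n)
    starts at ((m-1)s, (n-1)s) in 0-based indices, and the untiled margin
    lies at the bottom/right.  The other corners mirror the tiling so the
    margin falls on the opposite side.
    """
    _check_scale(M, N, s)
    if corner not in CORNERS:
        raise ValueError(f"corner must be one of {CORNERS}, got {corner!r}")
    Ms, Ns = M // s, N // s
    rows = np.arange(Ms) * s
    cols = np.arange(Ns) * s
    if corner in ("BL", "BR"):
        rows = rows + (M - Ms * s)
    if corner in ("TR", "BR"):
        cols = cols + (N - Ns * s)
    return [(int(r), int(t)) for r in rows for t in cols]


def cumulative_sum(segment: np.ndarray) -> np.ndarray:
    """Double cumulative sum G(i, j) = sum_{k1<=i} sum_{k2<=j} X(k1, k2)."""
    seg = np.asarray(segment, dtype=float)
    if seg.ndim != 2 or seg.shape[0] != seg.shape[1]:
        raise ValueError(f"segment must be square, got shape {seg.shape}")
    return np.cumsum(np.cumsum(seg, axis=0), axis=1)


def _plane_design(s: int) -> np.ndarray:
    """Design matrix [i, j, 1] over the s x s grid, 1-based coordinates."""
    i = np.arange(1, s + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    return np.column_stack([ii.ravel(), jj.ravel(), np.ones(s * s)])


def detrend_plane(profile: np.ndarray) -> tuple[tuple[float, float, float], np.ndarray]:
    """Least-squares plane fit a*i + b*j + c and its residual matrix.

    Grid coordinates are 1-based (i, j = 1 ... s).  Residuals sum to zero
    and are orthogonal to i and j over the grid.
    """
    G = np.asarray(profile, dtype=float)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ValueError(f"profile must be square, got shape {G.shape}")
    s = G.shape[0]
    if s < 2:
        raise ValueError("plane detrending needs s >= 2")
    A = _plane_design(s)
    coeffs, *_ = np.linalg.lstsq(A, G.ravel(), rcond=None)
    residuals = G - (A @ coeffs).reshape(s, s)
    a, b, c = (float(v) for v in coeffs)
    return (a, b, c), residuals


def local_fluctuation(residuals: np.ndarray) -> float:
    """Root mean square of the detrended segment residuals."""
    r = np.asarray(residuals, dtype=float)
    return float(np.sqrt(np.mean(r * r)))


def _segment_stack(values: np.ndarray, s: int, corners: Sequence[str]) -> np.ndarray:
    """All s x s segments from the requested corner tilings, stacked."""
    M, N = values.shape
    Ms, Ns = M // s, N // s
    blocks = []
    for corner in corners:
        r0 = (M - Ms * s) if corner in ("BL", "BR") else 0
        c0 = (N - Ns * s) if corner in ("TR", "BR") else 0
        sub = values[r0:r0 + Ms * s, c0:c0 + Ns * s]
        blocks.append(
            sub.reshape(Ms, s, Ns, s).transpose(0, 2, 1, 3).reshape(Ms * Ns, s, s)
        )
    return np.concatenate(blocks, axis=0)


def segment_fluctuations(
    surface: GraySurface | np.ndarray,
    s: int,
    corners: Sequence[str] = CORNERS,
) -> np.ndarray:
    """F(m, n, s) for every segment of every requested corner tiling.

    Vectorized composition of cumulative_sum -> detrend_plane ->
    local_fluctuation over the stacked segments.
    """
    values = surface.values if isinstance(surface, GraySurface) else np.asarray(surface, float)
    _check_scale(*values.shape, s)
    segs = _segment_stack(values, s, corners)
    G = np.cumsum(np.cumsum(segs, axis=1), axis=2)
    Gf = G.reshape(G.shape[0], -1)
    A = _plane_design(s)
    pinv = np.linalg.pinv(A)            # 3 x s^2
    fitted = (Gf @ pinv.T) @ A.T
    resid = Gf - fitted
    return np.sqrt(np.mean(resid * resid, axis=1))


def _generalized_means(F: np.ndarray, q_values: Iterable[float]) -> np.ndarray:
    """Order-q means of segment fluctuations, in log space for stability.

    For q != 0, exp((1/q) log mean(F^q)); for |q| < Q0_TOL the geometric
    mean (the q -> 0 limit).  Requires all F > 0 when any q <= 0.
    """
    F = np.asarray(F, dtype=float)
    qs = np.asarray(list(q_values), dtype=float)
    zero = np.flatnonzero(F == 0.0)
    if zero.size and np.any(qs <= Q0_TOL):
        raise DegenerateSurfaceError(
            f"segment(s) {zero[:5].tolist()} have zero fluctuation; "
            f"q <= 0 moments are undefined"
        )
    with np.errstate(divide="ignore"):
        logF = np.log(F)
    n = np.log(F.size)
    out = np.empty(qs.size)
    for k, q in enumerate(qs):
        if abs(q) < Q0_TOL:
            out[k] = np.exp(np.mean(logF))
        else:
            out[k] = np.exp((logsumexp(q * logF) - n) / q)
    return out


def fluctuation_function(
    surface: GraySurface | np.ndarray,
    s: int,
    q_grid: QGrid,
    corners: Sequence[str] = CORNERS,
) -> np.ndarray:
    """The q-th order fluctuation function F_q(s) for one scale.

    All segment fluctuations from the requested corner tilings are pooled
    into a single order-q mean (the 1/(M_s N_s) normalizer generalizes to
    one over the total segment count).  Non-decreasing in q.
    """
    F = segment_fluctuations(surface, s, corners)
    return _generalized_means(F, q_grid)


@dataclass
class FluctuationTable:
    """F_q(s) on a (q, s) grid, with per-scale pooled segment counts."""

    F: np.ndarray                       # (n_q, n_s), all > 0
    n_segments: tuple[int, ...]         # per scale, summed over corners
    scale_grid: ScaleGrid
    q_grid: QGrid
    corners: tuple[str, ...] = field(default=CORNERS)

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if self.F.shape != (len(self.q_grid), len(self.scale_grid)):
            raise ValueError(
                f"F must be ({len(self.q_grid)}, {len(self.scale_grid)}), "
                f"got {self.F.shape}"
            )


def compute_fluctuation_table(
    surface: GraySurface | np.ndarray,
    scale_grid: ScaleGrid | None = None,
    q_grid: QGrid | None = None,
    corners: Sequence[str] = CORNERS,
) -> FluctuationTable:
    """Fill F_q(s) for every (q, s) pair; deterministic for fixed input."""
    values = surface.values if isinstance(surface, GraySurface) else np.asarray(surface, float)
    M, N = values.shape
    if scale_grid is None:
        scale_grid = ScaleGrid.default_for(M, N)
    scale_grid.validate_for(M, N)
    if q_grid is None:
        q_grid = QGrid.default()
    cols = []
    counts = []
    for s in scale_grid:
        F = segment_fluctuations(values, s, corners)
        counts.append(int(F.size))
        try:
            cols.append(_generalized_means(F, q_grid))
        except DegenerateSurfaceError as exc:
            raise DegenerateSurfaceError(f"at scale s={s}: {exc}") from exc
    return FluctuationTable(
        np.column_stack(cols), tuple(counts), scale_grid, q_grid, tuple(corners)
    )
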