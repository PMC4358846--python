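"""Synthetic surfaces and datasets with known multifractal ground truth.

Two generators anchor the test pyramid: an isotropic fractional-Brownian
surface (monofractal; every h(q) should recover the prescribed Hurst
exponent H) and a 2x2 multiplicative cascade (exactly multifractal; its
partition-function exponent has the closed form
tau_meas(q) = -log2(sum_i p_i^q)).  A box-counting estimator provides an
independent route to tau_meas, and a species-dataset builder turns
cascade families into labelled grayscale datasets — or directly into
feature tables — with controllable inter-class separation, standing in
for a multi-species leaf-scan study.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io_surfaces import FEATURE_NAMES, FeatureTable, GraySurface

__all__ = [
    "CascadeSpec",
    "FbmSpec",
    "fbm_surface",
    "cascade_surface",
    "cascade_tau_analytic",
    "cascade_alpha_f_analytic",
    "box_counting_tau",
    "cascade_to_gray",
    "default_species_weights",
    "make_species_surfaces",
    "make_feature_dataset",
]

LN2 = np.log(2.0)


@dataclass(frozen=True)
class CascadeSpec:
    """2x2 multiplicative cascade: weights p1..p4 >= 0 summing to 1.

    The surface side is 2**depth; with ``shuffle`` the placement of the
    four weights is re-randomized per subdivided cell (per seed), which
    keeps tau(q) exact while varying the realization.
    """

    weights: tuple[float, float, float, float]
    depth: int
    seed: int = 0
    shuffle: bool = False

    def __post_init__(self) -> None:
        w = tuple(float(v) for v in self.weights)
        if len(w) != 4 or any(v < 0 for v in w):
            raise ValueError("weights must be 4 nonnegative reals")
        if abs(sum(w) - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1, got {sum(w)}")
        if self.depth < 5:
            raise ValueError("depth must be >= 5 (surface side 2**depth >= 32)")
        object.__setattr__(self, "weights", w)

    @property
    def side(self) -> int:
        return 2 ** self.depth


@dataclass(frozen=True)
class FbmSpec:
    """Isotropic fractional-Brownian-type surface with Hurst exponent H."""

    H: float
    size: tuple[int, int] = (256, 256)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.H < 1.0:
            raise ValueError(f"H must be in (0, 1), got {self.H}")


def _fbm_profile(H: float, n_rows: int, n_cols: int, seed: int) -> np.ndarray:
    """Isotropic fBm-type surface B by spectral synthesis.

    White Gaussian noise is filtered with the radial power spectrum
    |k|^-(2H+2), folded over the first Fourier aliases so the small-scale
    scaling stays correct on the discrete grid; the DC mode is zeroed.
    """
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((n_rows, n_cols))
    kx = np.fft.fftfreq(n_rows)[:, None]
    ky = np.fft.fftfreq(n_cols)[None, :]
    power = np.zeros((n_rows, n_cols))
    for mx in (-1, 0, 1):
        for my in (-1, 0, 1):
            k = np.hypot(kx + mx, ky + my)
            with np.errstate(divide="ignore"):
                power += np.where(k > 0, k ** (-(2.0 * H + 2.0)), 0.0)
    amp = np.sqrt(power)
    amp[0, 0] = 0.0
    return np.fft.ifft2(np.fft.fft2(white) * amp).real


def fbm_surface(spec: FbmSpec) -> np.ndarray:
    """Monofractal test field with generalized Hurst exponent H.

    An isotropic fractional-Brownian surface B with power spectrum
    proportional to |k|^-(2H+2) is synthesized spectrally, and its
    discrete double-increment field is returned, normalized to unit
    variance and zero mean.  The analysis pipeline's per-segment double
    cumulative sum re-integrates this field back into (a local copy of)
    B, so the estimated h(q) recovers H at every q.  Deterministic per
    seed.
    """
    rows, cols = spec.size
    B = _fbm_profile(spec.H, rows + 1, cols + 1, spec.seed)
    field = np.diff(np.diff(B, axis=0), axis=1)[:rows, :cols]
    field -= field.mean()
    sd = field.std()
    return field / sd if sd > 0 else field


def cascade_surface(spec: CascadeSpec) -> np.ndarray:
    """Multiplicative cascade measure on a 2**depth square grid; sum = 1."""
    rng = np.random.default_rng(spec.seed)
    w = np.asarray(spec.weights)
    m = np.ones((1, 1))
    for _ in range(spec.depth):
        side = m.shape[0]
        if spec.shuffle:
            tiles = rng.permuted(np.tile(w, (side * side, 1)), axis=1)
        else:
            tiles = np.tile(w, (side * side, 1))
        blocks = tiles.reshape(side, side, 2, 2)
        expanded = m[:, :, None, None] * blocks
        m = expanded.transpose(0, 2, 1, 3).reshape(2 * side, 2 * side)
    return m


def _positive_weights(weights: Sequence[float], q: float) -> np.ndarray:
    p = np.asarray(weights, dtype=float)
    if np.any(p == 0):
        if q <= 0:
            raise ValueError("zero weights make q <= 0 moments undefined")
        p = p[p > 0]
    return p


def cascade_tau_analytic(weights: Sequence[float], q: float) -> float:
    """Closed-form partition-function exponent tau_meas(q) = -log2(sum p_i^q).

    At q = 0 this is -log2(4) = -2, the support dimension of the plane;
    equal weights give the monofractal line tau_meas(q) = 2(q - 1).
    """
    p = _positive_weights(weights, q)
    return float(-np.log2(np.sum(p ** q)))


def cascade_alpha_f_analytic(weights: Sequence[float], q: float) -> tuple[float, float]:
    """Exact Legendre pair (alpha(q), f(alpha)) of the cascade exponent.

    alpha = tau'(q) = -sum(p^q ln p) / (ln 2 sum(p^q)); f = q alpha - tau.
    """
    p = _positive_weights(weights, q)
    pq = p ** q
    alpha = float(-np.sum(pq * np.log(p)) / (LN2 * np.sum(pq)))
    f = q * alpha - cascade_tau_analytic(weights, q)
    return alpha, float(f)


def box_counting_tau(
    measure: np.ndarray, q_values: Sequence[float]
) -> np.ndarray:
    """Partition-function exponents of a measure on a dyadic grid.

    For dyadic box sizes the box masses P are summed to Z(q) = sum P^q and
    tau_meas(q) is the slope of ln Z versus ln eps (eps = box size over
    side).  Boxes with zero mass are excluded for q <= 0 (their moments
    diverge).  Independent of the detrended-fluctuation route, hence
    usable as a cross-check.
    """
    m = np.asarray(measure, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("measure must be a square matrix")
    side = m.shape[0]
    L = int(np.log2(side))
    if 2 ** L != side:
        raise ValueError(f"side must be a power of 2, got {side}")
    if np.any(m < 0):
        raise ValueError("measure must be nonnegative")
    total = m.sum()
    if total <= 0:
        raise ValueError("measure has zero total mass")
    m = m / total
    # box masses at every dyadic level: level k has boxes of 2**k pixels
    levels = list(range(0, L))          # eps from 1/side to 1/2
    log_eps = []
    logZ = {float(q): [] for q in q_values}
    P = m.copy()
    for k in levels:
        if k > 0:
            n = P.shape[0] // 2
            P = P.reshape(n, 2, n, 2).sum(axis=(1, 3))
        log_eps.append(np.log(2.0 ** k / side))
        flat = P.ravel()
        pos = flat[flat > 0]
        for q in logZ:
            vals = pos if q <= 0 else flat[flat > 0]
            logZ[q].append(np.log(np.sum(vals ** q)))
    x = np.asarray(log_eps)
    out = np.empty(len(q_values))
    for i, q in enumerate(q_values):
        y = np.asarray(logZ[float(q)])
        out[i] = np.polyfit(x, y, 1)[0]
    return out


def cascade_to_gray(
    measure: np.ndarray,
    rng: Optional[np.random.Generator] = None,
    dither: float = 1e-6,
    mode: str = "linear",
) -> np.ndarray:
    """Map a cascade measure to a 0-255 gray surface.

    ``mode='linear'`` (default) min-max scales the mass itself, so the
    gray surface keeps the spiky multiplicative structure whose cumulative
    sum is the multifractal distribution function — this is what makes the
    detrended-fluctuation features discriminate between weight vectors.
    ``mode='log'`` scales the log of the mass instead, giving a smooth
    additive field (visually texture-like, but its h(q) saturates near the
    detrending limit and carries little weight information).  A tiny
    positive dither (``dither`` x U(0,1) gray levels) guarantees no
    segment is exactly flat, which would break the q <= 0 moments.
    """
    m = np.asarray(measure, dtype=float)
    if np.any(m <= 0):
        raise ValueError("measure must be strictly positive (use nonzero weights)")
    if mode == "linear":
        g = m / m.max() * 255.0
    elif mode == "log":
        g = np.log(m)
        lo, hi = g.min(), g.max()
        g = np.zeros_like(g) if hi == lo else (g - lo) / (hi - lo) * 255.0
    else:
        raise ValueError("mode must be 'linear' or 'log'")
    rng = rng or np.random.default_rng(0)
    return g + dither * rng.random(g.shape)


def default_species_weights(n_species: int) -> list[tuple[float, float, float, float]]:
    """Distinct cascade weight vectors with graded heterogeneity.

    The dominant weight p1 ranges over 0.30 ... 0.70 and the remaining
    mass is split equally, so species differ in spectrum width and Hurst
    level while each stays exactly multifractal.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    out = []
    for p1 in np.linspace(0.30, 0.70, n_species):
        rest = (1.0 - p1) / 3.0
        out.append((float(p1), rest, rest, rest))
    return out


def make_species_surfaces(
    n_species: int = 5,
    n_per_species: int = 30,
    base_specs: Optional[Sequence[CascadeSpec]] = None,
    depth: int = 7,
    noise_sd: float = 2.0,
    seed: int = 0,
) -> list[GraySurface]:
    """Labelled multi-species surface dataset from cascade families.

    Each species is one cascade weight vector; samples within a species
    differ by the shuffled weight placement (per-sample seed) and by
    additive Gaussian gray-level noise of SD ``noise_sd`` (in gray
    levels).  Deterministic per seed.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    if base_specs is None:
        base_specs = [
            CascadeSpec(w, depth=depth, shuffle=True)
            for w in default_species_weights(n_species)
        ]
    if len(base_specs) != n_species:
        raise ValueError("base_specs length must equal n_species")
    root = np.random.default_rng(np.random.SeedSequence([int(seed), 2 ** 20]))
    surfaces: list[GraySurface] = []
    for k, base in enumerate(base_specs):
        name = f"S{k + 1:02d}"
        for i in range(n_per_species):
            sample_seed = int(root.integers(2**31 - 1))
            spec = CascadeSpec(base.weights, base.depth, seed=sample_seed,
                               shuffle=base.shuffle)
            m = cascade_surface(spec)
            rng = np.random.default_rng(sample_seed + 1)
            g = cascade_to_gray(m, rng)
            if noise_sd > 0:
                # clip at black and re-dither so gray levels stay
                # nonnegative with no exactly flat region
                g = np.maximum(g + rng.normal(0.0, noise_sd, g.shape), 0.0)
                g += 1e-6 * rng.random(g.shape)
            surfaces.append(
                GraySurface(g, source_id=f"{name}_{i:03d}", species=name)
            )
    return surfaces


def make_feature_dataset(
    n_species: int = 5,
    n_per_species: int = 30,
    shifted_features: Sequence[str] = ("h_m3", "alpha_min", "delta_alpha"),
    feature_shift: float = 2.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    species_centers: Optional[np.ndarray] = None,
) -> FeatureTable:
    """Synthetic 12-feature table with controllable species separation.

    Within a species every feature is Gaussian with SD ``noise_sd``.
    Species means are 0 except for ``shifted_features``, whose per-species
    offsets are drawn N(0, (feature_shift * noise_sd)^2) — a between- to
    within-species spread ratio of ``feature_shift``.  Passing explicit
    ``species_centers`` (n_species x 12) overrides the random offsets,
    which is how planted similarity structure is constructed.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2 ** 21]))
    n_feat = len(FEATURE_NAMES)
    if species_centers is None:
        centers = np.zeros((n_species, n_feat))
        for name in shifted_features:
            j = FEATURE_NAMES.index(name)
            centers[:, j] = rng.normal(0.0, feature_shift * noise_sd, n_species)
    else:
        centers = np.asarray(species_centers, dtype=float)
        if centers.shape != (n_species, n_feat):
            raise ValueError(f"species_centers must be ({n_species}, {n_feat})")
    ids, species, rows = [], [], []
    for k in range(n_species):
        name = f"S{k + 1:02d}"
        samples = centers[k] + rng.normal(0.0, noise_sd, (n_per_species, n_feat))
        for i in range(n_per_species):
            ids.append(f"{name}_{i:03d}")
            species.append(name)
            rows.append(samples[i])
    return FeatureTable(ids, species, np.asarray(rows))
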