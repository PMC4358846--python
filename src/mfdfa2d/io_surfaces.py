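"""Reading image surfaces and feature tables.

A grayscale image is treated as a surface: the pixel grid supplies the
two spatial coordinates and the gray level supplies the height.  This
module converts raster images (PNG/TIFF/JPEG) or dense numeric matrices
(CSV) into :class:`GraySurface`, and reads/writes the per-sample feature
tables produced by :func:`mfdfa2d.spectra.extract_features`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MIN_SIDE",
    "FEATURE_NAMES",
    "GraySurface",
    "FeatureTable",
    "load_surface",
    "surface_from_array",
    "to_gray",
    "write_feature_table",
    "read_feature_table",
    "FeatureTableFormatError",
]

#: Minimum side length so that the default scale range 6 ... min(M, N)/4
#: is non-empty.
MIN_SIDE = 24

#: Canonical order of the 12 texture features: six generalized Hurst
#: exponents h(q) at q = -3..-1, 1..3 and six spectrum summaries.
FEATURE_NAMES = (
    "h_m3", "h_m2", "h_m1", "h_p1", "h_p2", "h_p3",
    "alpha_max", "alpha_min", "delta_alpha", "delta_f", "D1", "D2",
)

#: BT.601 luma weights for RGB -> gray conversion.
_LUMA601 = np.array([0.299, 0.587, 0.114])


class FeatureTableFormatError(ValueError):
    """Raised when a feature-table file does not match the expected layout."""


@dataclass
class GraySurface:
    """An M x N matrix of gray levels standing for the image surface X(i, j).

    ``values[i, j]`` is the gray level of image row ``i`` (top to bottom)
    and column ``j`` (left to right); values are dimensionless, nominally
    in 0-255 but any finite reals are accepted.
    """

    values: np.ndarray
    source_id: str = ""
    species: Optional[str] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError(f"surface must be a 2-D matrix, got shape {v.shape}")
        if v.shape[0] < MIN_SIDE or v.shape[1] < MIN_SIDE:
            raise ValueError(
                f"surface is {v.shape[0]}x{v.shape[1]}; both sides must be "
                f">= {MIN_SIDE} so that the scale range 6 ... min(M, N)/4 "
                f"is non-empty"
            )
        if not np.isfinite(v).all():
            raise ValueError("surface contains non-finite values")
        self.values = v

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def to_gray(rgb: np.ndarray, gray_method: str = "luma601") -> np.ndarray:
    """Reduce an (M, N, 3) or (M, N, 4) color array to a gray matrix.

    ``luma601`` uses the ITU-R BT.601 weights (0.299, 0.587, 0.114);
    ``mean`` averages the three channels.  An alpha channel is ignored.
    """
    a = np.asarray(rgb, dtype=float)
    if a.ndim == 2:
        return a
    if a.ndim != 3 or a.shape[2] not in (1, 3, 4):
        raise ValueError(f"cannot interpret array of shape {a.shape} as an image")
    if a.shape[2] == 1:
        return a[:, :, 0]
    rgb3 = a[:, :, :3]
    if gray_method == "luma601":
        return rgb3 @ _LUMA601
    if gray_method == "mean":
        return rgb3.mean(axis=2)
    raise ValueError(f"unknown gray_method {gray_method!r}; use 'luma601' or 'mean'")


def surface_from_array(
    values: np.ndarray,
    source_id: str = "",
    species: Optional[str] = None,
    gray_method: str = "luma601",
) -> GraySurface:
    """Wrap an in-memory array (2-D gray or 3-D color) as a GraySurface."""
    return GraySurface(to_gray(values, gray_method), source_id=source_id, species=species)


def load_surface(path: str | os.PathLike, gray_method: str = "luma601") -> GraySurface:
    """Read a raster image or a dense CSV matrix as a :class:`GraySurface`.

    Color images are reduced to gray per ``gray_method``; the whole image
    is used as-is (no cropping, background removal or segmentation).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    source_id = os.path.splitext(os.path.basename(path))[0]
    if path.lower().endswith((".csv", ".txt")):
        try:
            values = np.loadtxt(path, delimiter=",", dtype=float, ndmin=2)
        except Exception as exc:  # noqa: BLE001 - report as I/O failure
            raise IOError(f"could not parse {path} as a dense CSV matrix: {exc}") from exc
    else:
        from PIL import Image, UnidentifiedImageError

        try:
            with Image.open(path) as img:
                values = np.asarray(img, dtype=float)
        except UnidentifiedImageError as exc:
            raise IOError(f"could not decode {path} as a raster image: {exc}") from exc
        values = to_gray(values, gray_method)
    return GraySurface(values, source_id=source_id)


@dataclass
class FeatureTable:
    """Per-sample 12-feature vectors with species labels."""

    sample_ids: list[str]
    species: list[str]
    values: np.ndarray  # (n_samples, 12), columns ordered as FEATURE_NAMES
    feature_names: tuple[str, ...] = field(default=FEATURE_NAMES)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if len(self.species) != n:
            raise ValueError("sample_ids and species must have equal length")
        if self.values.shape != (n, len(self.feature_names)):
            raise ValueError(
                f"values must be ({n}, {len(self.feature_names)}), "
                f"got {self.values.shape}"
            )

    def __len__(self) -> int:
        return len(self.sample_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.species == other.species
            and self.feature_names == other.feature_names
            and np.array_equal(self.values, other.values)
        )

    @property
    def species_set(self) -> list[str]:
        """Distinct species labels, in order of first appearance."""
        return list(dict.fromkeys(self.species))

    def feature(self, name: str) -> np.ndarray:
        """Column of a single feature by name."""
        try:
            idx = self.feature_names.index(name)
        except ValueError:
            raise KeyError(
                f"unknown feature {name!r}; expected one of {self.feature_names}"
            ) from None
        return self.values[:, idx]

    def columns(self, names: Sequence[str]) -> np.ndarray:
        """(n_samples, len(names)) matrix of the requested features."""
        return np.column_stack([self.feature(n) for n in names])

    def subset_species(self, keep: Sequence[str]) -> "FeatureTable":
        keep_set = set(keep)
        mask = [sp in keep_set for sp in self.species]
        idx = np.flatnonzero(mask)
        return FeatureTable(
            [self.sample_ids[i] for i in idx],
            [self.species[i] for i in idx],
            self.values[idx],
            self.feature_names,
        )

    def subset_rows(self, idx: Sequence[int]) -> "FeatureTable":
        idx = list(idx)
        return FeatureTable(
            [self.sample_ids[i] for i in idx],
            [self.species[i] for i in idx],
            self.values[np.asarray(idx, dtype=int)],
            self.feature_names,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.feature_names))
        df.insert(0, "species", self.species)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureTable":
        expected = ["sample_id", "species", *FEATURE_NAMES]
        missing = [c for c in expected if c not in df.columns]
        if missing:
            raise FeatureTableFormatError(
                f"missing column(s) {missing}; expected header {expected}"
            )
        return cls(
            [str(s) for s in df["sample_id"]],
            [str(s) for s in df["species"]],
            df[list(FEATURE_NAMES)].to_numpy(dtype=float),
        )


def write_feature_table(table: FeatureTable, path: str | os.PathLike) -> None:
    """Write a feature table as comma-delimited text with a header row."""
    if len(table) == 0:
        raise ValueError("refusing to write an empty feature table")
    bad = np.flatnonzero(~np.isfinite(table.values).all(axis=1))
    if bad.size:
        raise ValueError(
            f"non-finite feature value(s) for sample id(s) "
            f"{[table.sample_ids[i] for i in bad]}"
        )
    table.to_frame().to_csv(path, index=False)


def read_feature_table(path: str | os.PathLike) -> FeatureTable:
    """Read a feature table written by :func:`write_feature_table`."""
    df = pd.read_csv(
        path, dtype={"sample_id": str, "species": str}, float_precision="round_trip"
    )
    return FeatureTable.from_frame(df)
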