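"""Variance-ratio feature selection.

For each texture feature the ratio I0 = sigma_bet / sigma_in compares the
spread of per-species mean values (inter-species variability) with the
average within-species standard deviation.  Features with large I0
separate species well relative to their own noise; the top-k by I0 are
selected as classifier inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_surfaces import FeatureTable

__all__ = ["SeparabilityReport", "compute_separability", "select_top_features"]


@dataclass
class SeparabilityReport:
    """Per-feature sigma_in, sigma_bet and I0, plus the I0 ranking."""

    feature_names: tuple[str, ...]
    sigma_in: np.ndarray
    sigma_bet: np.ndarray
    i0: np.ndarray
    ranking: tuple[str, ...]    # all features, I0 descending

    def selected(self, k: int = 3) -> tuple[str, ...]:
        return self.ranking[:k]

    def to_frame(self) -> pd.DataFrame:
        """Three rows (sigma_bet, sigma_in, I0) by 12 feature columns."""
        return pd.DataFrame(
            [self.sigma_bet, self.sigma_in, self.i0],
            index=["sigma_bet", "sigma_in", "I0"],
            columns=list(self.feature_names),
        )


def compute_separability(table: FeatureTable, ddof: int = 1) -> SeparabilityReport:
    """sigma_in, sigma_bet and I0 for every feature of a labelled table.

    Per feature, sigma_in(i) is the standard deviation over species i's
    samples and sigma_in their unweighted mean across species; sigma_bet
    is the standard deviation of the per-species mean values (unweighted,
    matching a balanced design).  The sample (n-1) standard deviation is
    the default; pass ``ddof=0`` for the population convention.

    A feature with zero within-species spread gets I0 = +inf with a
    warning (degenerate but maximally separating if the means differ).
    """
    species = table.species_set
    if len(species) < 2:
        raise ValueError("separability needs at least 2 species")
    groups = []
    for sp in species:
        idx = [i for i, s in enumerate(table.species) if s == sp]
        if len(idx) < 2:
            raise ValueError(f"species {sp!r} has fewer than 2 samples")
        groups.append(table.values[idx])

    within = np.array([g.std(axis=0, ddof=ddof) for g in groups])   # (C, 12)
    means = np.array([g.mean(axis=0) for g in groups])              # (C, 12)
    sigma_in = within.mean(axis=0)
    sigma_bet = means.std(axis=0, ddof=ddof)

    with np.errstate(divide="ignore", invalid="ignore"):
        i0 = np.where(sigma_in > 0, sigma_bet / sigma_in, np.inf)
    if np.any(sigma_in == 0):
        degenerate = [table.feature_names[i] for i in np.flatnonzero(sigma_in == 0)]
        warnings.warn(
            f"zero within-species variance for feature(s) {degenerate}; "
            f"I0 reported as +inf",
            stacklevel=2,
        )

    # I0 descending; exact ties broken by canonical feature order.
    order = sorted(range(len(table.feature_names)), key=lambda i: (-i0[i], i))
    ranking = tuple(table.feature_names[i] for i in order)
    return SeparabilityReport(table.feature_names, sigma_in, sigma_bet, i0, ranking)


def select_top_features(report: SeparabilityReport, k: int = 3) -> list[str]:
    """The k features with largest I0 (ties: canonical feature order)."""
    if not 1 <= k <= len(report.feature_names):
        raise ValueError(f"k must be in 1 ... {len(report.feature_names)}")
    return list(report.ranking[:k])
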