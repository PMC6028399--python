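"""Richness-constrained null models for functional diversity change.

Observed FD change can simply track TD change.  To isolate the functional
signal, occupancy probabilities are reshuffled across the species of each
assemblage independently within every year — the multiset of psi values, and
hence TD, is exactly preserved — and the FD-vs-year slope is refitted on each
replicate.  The observed slope's rank within the replicate distribution gives
a two-sided significance convention: p > 0.975 means observed FD change is
significantly higher than expected given TD change, p < 0.025 significantly
lower.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .functional import FunctionalDendrogram, functional_diversity
from .trends import fit_trend


def reshuffle_psi(psi_vector, rng) -> np.ndarray:
    """Permute occupancy values across species labels (TD-preserving)."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    psi = np.asarray(psi_vector, dtype=float)
    return rng.permutation(psi)


@dataclass
class NullDistribution:
    """Observed FD slope, its null replicates, and the rank p value."""

    observed_slope: float
    null_slopes: np.ndarray
    p_value: float

    @property
    def significantly_higher(self) -> bool:
        return self.p_value > 0.975

    @property
    def significantly_lower(self) -> bool:
        return self.p_value < 0.025


def rank_p_value(observed: float, null_samples) -> float:
    """p = (#{null < obs} + 0.5 #{null == obs}) / n."""
    null = np.asarray(null_samples, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    return float(((null < observed).sum() + 0.5 * (null == observed).sum()) / null.size)


def null_fd_slope_distribution(
    tree: FunctionalDendrogram,
    psi_series: dict,
    n_reps: int = 100,
    seed=0,
    ar_order: int = 1,
) -> NullDistribution:
    """TD-constrained null distribution of the FD-vs-year slope for one cell.

    ``psi_series`` maps year -> psi vector aligned with ``tree.leaf_names``.
    Each replicate independently permutes each year's psi values across
    species, recomputes the per-year FD, and refits the FD slope with the
    same trend machinery as the observed series.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    years = sorted(psi_series)
    if len(years) < 3:
        raise ValueError("need at least 3 years to fit an FD slope")
    mat = {t: np.asarray(psi_series[t], dtype=float) for t in years}

    def fd_slope(panel):
        tab = pd.DataFrame(
            {"cell": 0, "year": years, "value": [functional_diversity(tree, panel[t]) for t in years]}
        )
        return fit_trend(tab, ar_order=ar_order).slope

    observed = fd_slope(mat)
    rng = np.random.default_rng(seed)
    null_slopes = np.empty(n_reps)
    for r in range(n_reps):
        shuffled = {t: reshuffle_psi(mat[t], rng) for t in years}
        null_slopes[r] = fd_slope(shuffled)
    return NullDistribution(
        observed_slope=observed,
        null_slopes=null_slopes,
        p_value=rank_p_value(observed, null_slopes),
    )
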