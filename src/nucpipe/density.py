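"""Shared Gaussian kernel density estimation on explicit grids.

Density plots in this pipeline are never left to a plotting library: the
curve, its grid and its bandwidth are data. Estimates use Gaussian kernels
with a Silverman-type bandwidth by default and are renormalised to unit
area on their evaluation grid (trapezoid rule), so curve comparisons such
as overlap integrals are well posed.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import gaussian_kde

__all__ = ["kde_bandwidth", "kde_on_grid", "shared_grid"]

_PAD_BANDWIDTHS = 3.0


def _make_kde(values: np.ndarray, bandwidth_rule) -> gaussian_kde:
    return gaussian_kde(values, bw_method=bandwidth_rule)


def kde_bandwidth(values, bandwidth_rule="silverman") -> float:
    """Kernel standard deviation implied by the bandwidth rule (data units)."""
    values = np.asarray(values, dtype=float)
    kde = _make_kde(values, bandwidth_rule)
    return float(kde.factor * values.std(ddof=1))


def shared_grid(samples, bandwidth_rule="silverman", grid_points: int = 512) -> np.ndarray:
    """Evaluation grid spanning all samples, padded by 3 bandwidths.

    The pad uses the largest of the per-sample bandwidths so that no
    curve's mass is clipped by the grid.
    """
    samples = [np.asarray(s, dtype=float) for s in samples]
    h = max(kde_bandwidth(s, bandwidth_rule) for s in samples)
    lo = min(s.min() for s in samples) - _PAD_BANDWIDTHS * h
    hi = max(s.max() for s in samples) + _PAD_BANDWIDTHS * h
    return np.linspace(lo, hi, grid_points)


def kde_on_grid(values, grid: np.ndarray, bandwidth_rule="silverman") -> np.ndarray:
    """Unit-area Gaussian KDE of ``values`` evaluated on ``grid``.

    Raises ``ValueError`` for degenerate (fewer than two distinct values)
    input, for which a density is meaningless.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2 or np.unique(values).size < 2:
        raise ValueError(
            "density estimation needs >= 2 distinct values; for constant or "
            "near-constant data use threshold-based calling instead"
        )
    kde = _make_kde(values, bandwidth_rule)
    f = kde(grid)
    area = np.trapezoid(f, grid)
    if area <= 0:
        raise ValueError("density integrates to zero on the supplied grid")
    return f / area
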