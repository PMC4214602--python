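"""Base-weighted rescaling of per-base series into fixed bin counts.

Shared by the metagene, tRNA-heatmap and duplex-stability modules.  A
segment of length L is divided into n equal-width bins (fractional base
boundaries allowed); each bin's value is the base-weighted mean of the
per-base series over the bin, computed from a cumulative sum so that the
width-weighted mean of the bins equals the plain mean of the series.
NaN bases (missing values) are excluded from both numerator and weight.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rescale_bins", "fixed_bins", "per_base_from_windows"]


def rescale_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Base-weighted mean of ``values`` over ``n_bins`` equal-width bins."""
    values = np.asarray(values, dtype=float)
    L = len(values)
    if L == 0 or n_bins < 1:
        raise ValueError("need a non-empty series and n_bins >= 1")
    valid = ~np.isnan(values)
    filled = np.where(valid, values, 0.0)
    csum = np.concatenate(([0.0], np.cumsum(filled)))
    wsum = np.concatenate(([0.0], np.cumsum(valid.astype(float))))
    edges = np.linspace(0.0, L, n_bins + 1)
    grid = np.arange(L + 1, dtype=float)
    c_at = np.interp(edges, grid, csum)
    w_at = np.interp(edges, grid, wsum)
    num = np.diff(c_at)
    den = np.diff(w_at)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def fixed_bins(values: np.ndarray, bin_size: int) -> np.ndarray:
    """Mean of ``values`` over consecutive fixed-size bins (tail < bin_size
    averaged over its actual length)."""
    values = np.asarray(values, dtype=float)
    n_bins = -(-len(values) // bin_size)
    out = np.empty(n_bins)
    for i in range(n_bins):
        chunk = values[i * bin_size : (i + 1) * bin_size]
        valid = ~np.isnan(chunk)
        out[i] = chunk[valid].mean() if valid.any() else np.nan
    return out


def per_base_from_windows(
    window_values: np.ndarray, window_size: int, start: int, end: int
) -> np.ndarray:
    """Expand fixed-window values to per-base resolution over [start, end).

    Bases outside the windowed range (negative coordinates or beyond the
    last window) come back as NaN.
    """
    window_values = np.asarray(window_values, dtype=float)
    pos = np.arange(start, end)
    idx = pos // window_size
    out = np.full(len(pos), np.nan)
    ok = (pos >= 0) & (idx < len(window_values))
    out[ok] = window_values[idx[ok]]
    return out
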