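"""Concavity-based peak detection shared by the FLD and contact-curve stages.

Peaks are defined as the curve maximum within each maximal run of negative
discrete second difference of the (lightly smoothed) curve.  This is the
criterion used throughout the package for calling nucleosome-contact peaks
on probability curves and contact-enrichment peaks on fragment-length
ratio curves.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["rolling_mean", "bool_runs", "find_concave_peaks"]


def rolling_mean(values, window: int) -> np.ndarray:
    """Centered rolling mean with window shrinkage at the boundaries.

    ``window <= 1`` returns the input unchanged (as float).  Edge bins are
    averaged over however much of the window fits, so the output has the
    same length as the input and no NaN padding.
    """
    values = np.asarray(values, dtype=float)
    if window <= 1:
        return values.copy()
    return (
        pd.Series(values)
        .rolling(int(window), center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def bool_runs(mask) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean vector as (start, stop) inclusive."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]]).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1) - 1
    return list(zip(starts.tolist(), stops.tolist()))


def find_concave_peaks(
    x,
    y,
    smooth_window: int = 15,
    height_floor: float | str | None = "median",
    min_separation: int | str | None = "auto",
) -> tuple[np.ndarray, np.ndarray]:
    """Call peaks where the second difference of the smoothed curve is negative.

    Parameters
    ----------
    x, y
        Curve coordinates and values; ``x`` must be strictly increasing and
        regularly spaced (unit spacing is assumed for the second difference).
    smooth_window
        Width of the centered rolling mean applied before differencing.
    height_floor
        Minimum smoothed height a candidate peak must exceed.  ``"median"``
        (default) uses the median of the positive part of the smoothed
        curve — on curves that are positive everywhere this is the plain
        median, while on curves with exactly-zero tails it keeps the floor
        positive so that isolated stray counts cannot pass; ``None``
        disables the floor; a float is used as-is.
    min_separation
        Candidate peaks closer than this (in x units) are merged, keeping
        the higher one: two maxima within the smoothing scale are not
        resolvable, they are one noise-split peak.  ``"auto"`` (default)
        uses twice the smoothing window; ``None`` disables merging.

    Returns
    -------
    positions, heights
        Peak x-positions and smoothed curve values at those positions, in
        ascending x order.  Empty arrays if the curve has no concave runs.
    """
    x = np.asarray(x)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("curve too short for second-difference peak calling")
    ys = rolling_mean(y, smooth_window)
    # d2[i] is the second difference centered on curve index i+1; its sign is
    # taken after local averaging at the same scale, otherwise sampling noise
    # on broad peaks fragments one concave region into many short runs
    d2 = rolling_mean(np.diff(ys, 2), smooth_window)
    if height_floor == "median":
        positive = ys[ys > 0]
        floor = float(np.median(positive)) if positive.size else -np.inf
    elif height_floor is None:
        floor = -np.inf
    else:
        floor = float(height_floor)
    positions, heights = [], []
    for start, stop in bool_runs(d2 < 0):
        lo, hi = start + 1, stop + 2  # curve-index slice of the concave run
        k = lo + int(np.argmax(ys[lo:hi]))
        # window shrinkage fabricates curvature at the boundaries, so the
        # outermost smooth_window positions cannot host a peak
        if k < smooth_window or k >= x.size - smooth_window:
            continue
        if ys[k] > floor:
            positions.append(x[k])
            heights.append(ys[k])
    positions = np.asarray(positions)
    heights = np.asarray(heights)
    if min_separation == "auto":
        min_separation = 2 * smooth_window
    if min_separation and positions.size > 1:
        positions, heights = _merge_close(positions, heights, min_separation)
    return positions, heights


def _merge_close(positions, heights, min_separation):
    """Greedily drop the lower of any two peaks closer than min_separation."""
    order = np.argsort(heights)[::-1]  # strongest first
    kept: list[int] = []
    for i in order:
        if all(abs(positions[i] - positions[j]) >= min_separation for j in kept):
            kept.append(i)
    kept.sort()
    return positions[kept], heights[kept]
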