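"""Fragment-length-distribution (FLD) processing for RICC-seq-style data.

The chain implemented here turns raw single-stranded fragment tables or
insert-size histograms into normalized, comparable curves:

1. region subsetting (span-overlap rule) and histogramming,
2. spike-in depth scaling (REF_b / D_i within a biological replicate),
3. exponential length-bias fitting from a spike-in ladder and correction,
4. interpolation onto a common grid, rolling-mean smoothing, and
   normalization to the mononucleosome signal at 180 nt,
5. the cell / irradiated-gDNA ratio that enhances contact-peak contrast,
6. replicate aggregation with Student-t confidence intervals and
   per-position Welch tests with a minimum-run significance filter.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .peaks import bool_runs, find_concave_peaks, rolling_mean

__all__ = [
    "DEFAULT_GRID",
    "FragmentLengthHistogram",
    "BiasModel",
    "CorrectedCurve",
    "ComparisonResult",
    "histogram_from_fragments",
    "spikein_scale",
    "fit_length_bias",
    "correct_normalize",
    "gdna_ratio",
    "aggregate_condition",
    "compare_conditions",
    "significant_runs",
    "call_fld_peaks",
    "align_by_mono_falloff",
]

#: Common analysis grid, 55-450 nt inclusive at 1 nt spacing.
DEFAULT_GRID = np.arange(55, 451)

SOURCES = ("cell", "gdna", "spikein_pre", "spikein_post")


@dataclass
class FragmentLengthHistogram:
    """Integer fragment-length histogram with sample provenance.

    ``counts`` maps positive integer lengths (nt) to nonnegative real
    counts; it is stored as a pandas Series with a strictly increasing
    integer index.
    """

    counts: pd.Series
    sample_id: str = ""
    condition: str = ""
    biological_replicate: str = ""
    technical_replicate: str = ""
    source: str = "cell"
    subset: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        s = pd.Series(self.counts).astype(float)
        idx = np.asarray(s.index)
        if len(s) == 0:
            raise ValueError("empty histogram")
        if not np.issubdtype(idx.dtype, np.integer):
            if not np.allclose(idx, np.round(idx)):
                raise ValueError("histogram lengths must be integers")
            s.index = idx = np.round(idx).astype(int)
        if (idx <= 0).any():
            raise ValueError("histogram lengths must be positive")
        if np.any(np.diff(idx) <= 0):
            raise ValueError("histogram lengths must be strictly increasing")
        if (s.values < 0).any():
            raise ValueError("histogram counts must be nonnegative")
        if s.sum() <= 0:
            raise ValueError("histogram total count must be positive")
        if self.source not in SOURCES:
            raise ValueError(f"source must be one of {SOURCES}")
        self.counts = s

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def scaled(self, factor: float) -> "FragmentLengthHistogram":
        """Return a copy with counts multiplied by ``factor``."""
        return dataclasses.replace(self, counts=self.counts * float(factor))

    def dense(self) -> pd.Series:
        """Counts re-indexed onto every integer length in the support."""
        lo, hi = int(self.counts.index.min()), int(self.counts.index.max())
        return self.counts.reindex(range(lo, hi + 1), fill_value=0.0)


@dataclass(frozen=True)
class BiasModel:
    """Exponential length-capture bias ``a * exp(k * (L - fit_min))``.

    Fitted to the log post/pre spike-in ratio at lengths >= ``fit_min``
    (default 300 nt) and extrapolated back over the full grid.  Correction
    divides a histogram by the model value at each length.
    """

    amplitude: float
    rate: float
    fit_min: int = 300
    fit_max: int | None = None

    def __post_init__(self):
        if not (self.amplitude > 0 and np.isfinite(self.amplitude)):
            raise ValueError("amplitude must be positive and finite")
        if not np.isfinite(self.rate):
            raise ValueError("rate must be finite")

    def value(self, lengths) -> np.ndarray:
        L = np.asarray(lengths, dtype=float)
        v = self.amplitude * np.exp(self.rate * (L - self.fit_min))
        if not np.all(np.isfinite(v) & (v > 0)):
            raise ValueError("bias model is not finite and positive on the grid")
        return v

    @classmethod
    def identity(cls) -> "BiasModel":
        return cls(amplitude=1.0, rate=0.0)


@dataclass
class CorrectedCurve:
    """Bias-corrected, normalized FLD values on a fixed length grid."""

    grid: np.ndarray
    values: np.ndarray
    n_replicates: int = 1
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None
    sample_id: str = ""
    condition: str = ""
    source: str = "cell"
    subset: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape != self.values.shape:
            raise ValueError("grid and values must have equal length")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")


@dataclass
class ComparisonResult:
    """Per-position two-condition comparison (B / A) with significance runs."""

    grid: np.ndarray
    mean_ratio: np.ndarray
    p_values: np.ndarray
    significant_runs: list[tuple[int, int]]
    alpha: float
    min_run: int


# ---------------------------------------------------------------------------
# histogramming and subsetting


def _region_trees(regions: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in regions.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            zip(grp["start"].astype(int), grp["end"].astype(int))
        )
    return trees


def span_overlap_mask(fragments: pd.DataFrame, regions: pd.DataFrame) -> np.ndarray:
    """True where a fragment's [start, end) span overlaps >= 1 bp of a region.

    Coordinates are 0-based half-open on both sides, so a fragment abutting
    a region (fragment end == region start) does not overlap.
    """
    trees = _region_trees(regions)
    chroms = fragments["chrom"].to_numpy()
    starts = fragments["start"].to_numpy()
    ends = fragments["end"].to_numpy()
    keep = np.zeros(len(fragments), dtype=bool)
    for i, (c, s, e) in enumerate(zip(chroms, starts, ends)):
        tree = trees.get(c)
        if tree is not None and tree.overlaps(int(s), int(e)):
            keep[i] = True
    return keep


def histogram_from_fragments(
    fragments: pd.DataFrame,
    regions: pd.DataFrame | None = None,
    subset: str | None = None,
    **meta,
) -> FragmentLengthHistogram:
    """Tabulate fragment lengths, optionally restricted to a region set.

    A fragment is counted iff its full [start, end) span overlaps at least
    1 bp of any region (the span-overlap rule used for paired-fragment
    intersection); without regions every fragment is counted.
    """
    for col in ("chrom", "start", "end"):
        if col not in fragments.columns:
            raise ValueError(f"fragment table missing column {col!r}")
    starts = fragments["start"].to_numpy()
    ends = fragments["end"].to_numpy()
    if np.any(ends <= starts):
        raise ValueError("fragment end must be greater than start")
    if regions is not None:
        fragments = fragments.loc[span_overlap_mask(fragments, regions)]
    lengths = (fragments["end"] - fragments["start"]).astype(int)
    counts = lengths.value_counts().sort_index().astype(float)
    return FragmentLengthHistogram(counts=counts, subset=subset, **meta)


# ---------------------------------------------------------------------------
# spike-in scaling


def spikein_scale(
    histograms: Sequence[FragmentLengthHistogram],
    spikein_histograms: Sequence[FragmentLengthHistogram],
):
    """Depth-scale technical replicates of one biological replicate.

    Each sample's counts are multiplied by REF_b / D_i where D_i is that
    sample's spike-in read depth and REF_b is the mean spike-in depth over
    all technical replicates in the group.  After scaling, every spike-in
    total equals REF_b, which makes the operation idempotent.

    Returns ``(scaled_histograms, scaled_spikeins, factors, ref_depth)``.
    """
    if len(histograms) == 0 or len(histograms) != len(spikein_histograms):
        raise ValueError("need one spike-in histogram per sample histogram")
    depths = np.array([h.total for h in spikein_histograms], dtype=float)
    if np.any(depths <= 0):
        raise ValueError("spike-in depth D_i must be positive for every sample")
    ref = float(depths.mean())
    factors = ref / depths
    scaled = [h.scaled(f) for h, f in zip(histograms, factors)]
    scaled_spike = [h.scaled(f) for h, f in zip(spikein_histograms, factors)]
    return scaled, scaled_spike, factors, ref


# ---------------------------------------------------------------------------
# length-bias fit and correction


def fit_length_bias(
    post: FragmentLengthHistogram,
    pre: FragmentLengthHistogram,
    fit_min: int = 300,
    fit_max: int | None = None,
    min_count: float = 5.0,
) -> BiasModel:
    """Fit the exponential length bias from a spike-in ladder pair.

    Ordinary least squares of log(post/pre) against length, restricted to
    lengths >= ``fit_min`` (default 300 nt) where both histograms are
    positive; the fitted exponential is extrapolated back over the full
    length range when used as a correction.

    Sampled positions with fewer than ``min_count`` post-sequencing reads
    are excluded along with zero bins: conditioning a log-ratio regression
    on near-empty bins being nonzero biases the slope toward zero (the
    empty bins that would have pulled it down are unrepresentable), so the
    fit only uses bins where the log of the count is stable.
    """
    joined = pd.concat(
        {"post": post.counts, "pre": pre.counts}, axis=1, join="inner"
    ).dropna()
    L = joined.index.to_numpy(dtype=float)
    usable = (joined["post"].to_numpy() >= min_count) & (
        joined["pre"].to_numpy() > 0
    )
    usable &= L >= fit_min
    if fit_max is not None:
        usable &= L <= fit_max
    if usable.sum() < 10:
        raise ValueError(
            f"only {int(usable.sum())} usable fit positions at >= {fit_min} nt "
            "(need >= 10)"
        )
    x = L[usable] - fit_min
    y = np.log(joined["post"].to_numpy()[usable] / joined["pre"].to_numpy()[usable])
    slope, intercept = np.polyfit(x, y, 1)
    return BiasModel(
        amplitude=float(np.exp(intercept)),
        rate=float(slope),
        fit_min=int(fit_min),
        fit_max=int(fit_max) if fit_max is not None else int(L[usable].max()),
    )


def correct_normalize(
    hist: FragmentLengthHistogram,
    bias: BiasModel | None = None,
    grid: np.ndarray | None = None,
    smooth_window: int = 10,
    norm_at: int = 180,
    norm_mode: str = "at",
) -> CorrectedCurve:
    """Bias-correct, regrid, smooth and normalize one histogram.

    Counts are divided by the bias-model value at each length, linearly
    interpolated onto ``grid`` (default 55-450 nt; lengths missing from the
    histogram count as zero), smoothed with a centered rolling mean of
    width ``smooth_window`` (default 10 nt, shrinking at the edges), and
    divided by the smoothed value at ``norm_at`` (default 180 nt) so the
    output is exactly 1 there.  ``norm_mode="peak"`` divides instead by the
    smoothed maximum within 25 nt of ``norm_at``.
    """
    if grid is None:
        grid = DEFAULT_GRID
    grid = np.asarray(grid)
    dense = hist.dense()
    lengths = dense.index.to_numpy(dtype=float)
    vals = dense.to_numpy(dtype=float)
    if bias is not None:
        vals = vals / bias.value(lengths)
    on_grid = np.interp(grid, lengths, vals, left=0.0, right=0.0)
    smoothed = rolling_mean(on_grid, smooth_window)
    if norm_mode == "at":
        at = np.flatnonzero(grid == norm_at)
        if at.size == 0:
            raise ValueError(f"norm_at={norm_at} is not on the grid")
        denom = smoothed[at[0]]
    elif norm_mode == "peak":
        near = np.abs(grid - norm_at) <= 25
        if not near.any():
            raise ValueError(f"no grid positions within 25 nt of {norm_at}")
        denom = smoothed[near].max()
    else:
        raise ValueError("norm_mode must be 'at' or 'peak'")
    if denom == 0:
        raise ValueError(f"normalization value at {norm_at} nt is zero")
    meta = dict(hist.metadata)
    meta.update(
        smooth_window=smooth_window,
        norm_at=norm_at,
        norm_mode=norm_mode,
        bias_amplitude=None if bias is None else bias.amplitude,
        bias_rate=None if bias is None else bias.rate,
    )
    return CorrectedCurve(
        grid=grid,
        values=smoothed / denom,
        sample_id=hist.sample_id,
        condition=hist.condition,
        source=hist.source,
        subset=hist.subset,
        metadata=meta,
    )


def gdna_ratio(
    cell: CorrectedCurve,
    gdna: CorrectedCurve,
    pseudocount: float | None = None,
) -> CorrectedCurve:
    """Cell / irradiated-gDNA ratio of two corrected curves.

    The gDNA control captures the uncorrelated-break background, so the
    ratio enhances contact-peak contrast.  A pseudocount (default 1e-6 of
    the larger curve maximum) keeps zero bins finite; because the default
    pseudocount scales with the inputs, the ratio is exactly invariant to
    any common positive rescaling of both curves.
    """
    if cell.grid.shape != gdna.grid.shape or np.any(cell.grid != gdna.grid):
        raise ValueError("cell and gDNA curves must share the same grid")
    eps = (
        float(pseudocount)
        if pseudocount is not None
        else 1e-6 * max(cell.values.max(), gdna.values.max())
    )
    return CorrectedCurve(
        grid=cell.grid,
        values=(cell.values + eps) / (gdna.values + eps),
        sample_id=cell.sample_id,
        condition=cell.condition,
        source="cell",
        subset=cell.subset,
        metadata={
            "ratio_of": (cell.sample_id, gdna.sample_id),
            "pseudocount": eps,
        },
    )


# ---------------------------------------------------------------------------
# replicate aggregation and condition comparison


def _stack(curves: Sequence[CorrectedCurve]) -> tuple[np.ndarray, np.ndarray]:
    grid = curves[0].grid
    for c in curves[1:]:
        if c.grid.shape != grid.shape or np.any(c.grid != grid):
            raise ValueError("curves must share the same grid")
    return grid, np.vstack([c.values for c in curves])


def aggregate_condition(curves: Sequence[CorrectedCurve]) -> CorrectedCurve:
    """Pointwise replicate mean with a 95% Student-t confidence interval.

    The interval is mean +/- t_{0.975, n-1} * SD / sqrt(n).  With a single
    replicate the CI is undefined and left as None.
    """
    if len(curves) == 0:
        raise ValueError("need at least one curve")
    grid, mat = _stack(curves)
    n = mat.shape[0]
    mean = mat.mean(axis=0)
    if n >= 2:
        half = stats.t.ppf(0.975, n - 1) * mat.std(axis=0, ddof=1) / np.sqrt(n)
        lo, hi = mean - half, mean + half
    else:
        lo = hi = None
    return CorrectedCurve(
        grid=grid,
        values=mean,
        n_replicates=n,
        ci_lower=lo,
        ci_upper=hi,
        condition=curves[0].condition,
        source=curves[0].source,
        subset=curves[0].subset,
        metadata={"aggregated_from": [c.sample_id for c in curves]},
    )


def significant_runs(
    p_values, alpha: float = 0.05, min_run: int = 5, grid=None
) -> list[tuple[int, int]]:
    """Maximal contiguous stretches with p < alpha of length >= min_run.

    Returned as (start, end) inclusive in grid coordinates (or indices when
    ``grid`` is None).  Non-finite p-values never count as significant.
    """
    p = np.asarray(p_values, dtype=float)
    sig = np.isfinite(p) & (p < alpha)
    runs = []
    for start, stop in bool_runs(sig):
        if stop - start + 1 >= min_run:
            if grid is None:
                runs.append((start, stop))
            else:
                runs.append((int(grid[start]), int(grid[stop])))
    return runs


def compare_conditions(
    cond_a: Sequence[CorrectedCurve],
    cond_b: Sequence[CorrectedCurve],
    alpha: float = 0.05,
    min_run: int = 5,
) -> ComparisonResult:
    """Per-position Welch test between two conditions' replicate curves.

    Runs a two-sided Welch (unequal-variance) t-test across replicates at
    every grid position, reports the pointwise mean ratio B / A, and calls
    significant runs: maximal contiguous stretches with p < ``alpha`` of
    length >= ``min_run`` positions.  Positions where both conditions have
    zero variance yield NaN p-values and never enter a run.
    """
    if len(cond_a) < 2 or len(cond_b) < 2:
        raise ValueError("need >= 2 replicate curves per condition")
    grid, mat_a = _stack(cond_a)
    grid_b, mat_b = _stack(cond_b)
    if grid.shape != grid_b.shape or np.any(grid != grid_b):
        raise ValueError("conditions must share the same grid")
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # the normalization anchor has zero variance in every condition by
        # construction; its p-value is NaN and excluded from run calling
        warnings.filterwarnings("ignore", message="Precision loss occurred")
        result = stats.ttest_ind(mat_b, mat_a, axis=0, equal_var=False)
        ratio = mat_b.mean(axis=0) / mat_a.mean(axis=0)
    p = np.asarray(result.pvalue, dtype=float)
    return ComparisonResult(
        grid=grid,
        mean_ratio=ratio,
        p_values=p,
        significant_runs=significant_runs(p, alpha, min_run, grid=grid),
        alpha=alpha,
        min_run=min_run,
    )


# ---------------------------------------------------------------------------
# FLD peak calls and spike-in diagnostics


def call_fld_peaks(
    curve: CorrectedCurve,
    smooth_window: int = 15,
    height_floor: float | str | None = "median",
) -> tuple[np.ndarray, np.ndarray]:
    """Second-difference peak calls on a corrected (typically ratio) curve."""
    return find_concave_peaks(
        curve.grid, curve.values, smooth_window=smooth_window, height_floor=height_floor
    )


def align_by_mono_falloff(
    reference: FragmentLengthHistogram,
    other: FragmentLengthHistogram,
    smooth_window: int = 5,
    max_peak_length: int = 250,
) -> int:
    """Shift (nt) aligning two ladders by the mononucleosome falloff.

    The falloff is the right-side half-maximum position of the tallest
    smoothed peak below ``max_peak_length`` nt.  Used only for pre/post
    spike-in diagnostics; returns the shift to add to ``other`` lengths.
    """

    def falloff(h: FragmentLengthHistogram) -> int:
        dense = h.dense()
        y = rolling_mean(dense.to_numpy(), smooth_window)
        x = dense.index.to_numpy()
        below = x < max_peak_length
        if not below.any():
            raise ValueError("no histogram support below the peak-search limit")
        k = int(np.argmax(y[below]))
        half = y[below][k] / 2.0
        right = np.flatnonzero((x > x[below][k]) & (y <= half))
        return int(x[right[0]]) if right.size else int(x[-1])

    return falloff(reference) - falloff(other)
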