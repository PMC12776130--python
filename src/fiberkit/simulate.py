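"""Synthetic data generators emulating sub-kilobase chromatin assays.

These generators produce every input class the analysis pipeline consumes,
with the statistical structure the downstream stages assume:

* RICC-seq-like single-stranded fragment tables whose length distribution
  is a Gaussian mixture of contact peaks (default quartet at 78, 180, 270
  and 360 nt) over a uniform random-break background, thinned by an
  exponential length-capture bias exp(-k*L).
* An MNase-ladder spike-in with an exactly known pre-sequencing
  distribution and a sampled, bias-thinned post-sequencing counterpart.
* Irradiated-gDNA controls (background-only fragment sets).
* Micro-C-like cis ligation pairs whose distances form a comb of Gaussian
  peaks at integer multiples of a configurable nucleosome repeat length
  (NRL), with power-law step decay, optional odd-step zig-zag modulation,
  and orientation-dependent distance offsets.
* Labeled epigenetic-state interval sets with state-specific generator
  overrides, and paired compartment-score / reference bin tracks.

Every generator is deterministic given its configuration and seed.  The
peaks are phenomenological mixture components; no 3D fiber geometry or
radical-diffusion physics is modeled, and no sequencing reads (FASTQ) are
simulated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fld import FragmentLengthHistogram

__all__ = [
    "FldSimConfig",
    "SpikeSimConfig",
    "MicrocSimConfig",
    "StateSpec",
    "StateRegionConfig",
    "simulate_ricc_fragments",
    "simulate_gdna_fragments",
    "simulate_spikein",
    "simulate_microc_pairs",
    "microc_step_weights",
    "simulate_state_regions",
    "simulate_cscore_tracks",
]

_DEFAULT_CHROM_SIZES = {"chrS1": 20_000_000}

PAIRS_COLUMNS = ["read_id", "chrom1", "pos1", "chrom2", "pos2", "strand1", "strand2"]


def _as_tuple(x, n=None, name=""):
    t = tuple(float(v) for v in (x if np.iterable(x) else [x] * (n or 1)))
    if n is not None and len(t) != n:
        raise ValueError(f"{name} must have length {n}")
    return t


@dataclass(frozen=True)
class FldSimConfig:
    """Mixture model for correlated-cleavage fragment lengths.

    ``peak_weights`` plus ``background_fraction`` must sum to 1; the
    background is uniform over ``background_range`` (the length law of
    uncorrelated random breaks is not otherwise constrained, so a
    maximally uninformative model is used).  ``bias_rate`` is the per-nt
    exponential thinning rate k >= 0; ``depth`` counts fragments drawn
    before thinning.
    """

    peak_centers: tuple = (78.0, 180.0, 270.0, 360.0)
    peak_widths: tuple = (12.0, 12.0, 12.0, 12.0)
    peak_weights: tuple = (0.125, 0.125, 0.125, 0.125)
    background_fraction: float = 0.5
    background_range: tuple = (50, 700)
    bias_rate: float = 0.005
    depth: int = 200_000
    chrom_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_CHROM_SIZES)
    )
    seed: int = 0

    def __post_init__(self):
        k = len(self.peak_centers)
        object.__setattr__(self, "peak_centers", _as_tuple(self.peak_centers, k))
        object.__setattr__(self, "peak_widths", _as_tuple(self.peak_widths, k, "peak_widths"))
        object.__setattr__(self, "peak_weights", _as_tuple(self.peak_weights, k, "peak_weights"))
        if any(w < 0 for w in self.peak_weights) or self.background_fraction < 0:
            raise ValueError("weights must be nonnegative")
        total = sum(self.peak_weights) + self.background_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError("peak_weights + background_fraction must sum to 1")
        lo, hi = self.background_range
        if not (0 < lo < hi):
            raise ValueError("background_range must satisfy 0 < min < max")
        if self.bias_rate < 0:
            raise ValueError("bias_rate must be >= 0")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not self.chrom_sizes:
            raise ValueError("chrom_sizes must be non-empty")

    def replace(self, **kw) -> "FldSimConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class SpikeSimConfig:
    """MNase ladder spike-in: evenly spaced rungs with Gaussian widths.

    The ladder repeat defaults to 154 nt (a typical fission-yeast NRL) and
    rung mixture weights are equal.
    """

    ladder_repeat: float = 154.0
    n_rungs: int = 6
    rung_widths: tuple = (15.0,)
    depth: int = 1_000_000
    bias_rate: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if self.n_rungs < 2:
            raise ValueError("n_rungs must be >= 2")
        if self.ladder_repeat <= 0:
            raise ValueError("ladder_repeat must be positive")
        widths = self.rung_widths
        if not np.iterable(widths):
            widths = (widths,)
        if len(widths) == 1:
            widths = tuple(widths) * self.n_rungs
        object.__setattr__(
            self, "rung_widths", _as_tuple(widths, self.n_rungs, "rung_widths")
        )
        if self.depth <= 0 or self.bias_rate < 0:
            raise ValueError("depth must be positive and bias_rate >= 0")

    @property
    def rung_centers(self) -> np.ndarray:
        return self.ladder_repeat * np.arange(1, self.n_rungs + 1)

    def replace(self, **kw) -> "SpikeSimConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class MicrocSimConfig:
    """Comb model for cis ligation-pair distances.

    Latent dyad distances are drawn from sum_n w_n * N(n * nrl, sigma^2)
    truncated to [min_distance, max_distance], with step weights
    w_n proportional to n^(-gamma) * (1 + A * [n odd, n >= 3]).  Ligation
    orientation is then assigned (default equal thirds) and the measured
    distance is shifted by +orientation_shift for inward and
    -orientation_shift for outward pairs, reflecting that read positions
    fall at nucleosome entry/exit points.
    """

    nrl: float = 186.0
    peak_width: float = 12.0
    n_peaks: int = 8
    decay_exponent: float = 1.2
    zigzag_amplitude: float = 0.0
    orientation_shift: float = 147.0
    orientation_fractions: tuple = (1 / 3, 1 / 3, 1 / 3)  # tandem, inward, outward
    min_distance: int = 50
    max_distance: int = 1500
    depth: int = 500_000
    chrom_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_CHROM_SIZES)
    )
    seed: int = 0

    def __post_init__(self):
        if self.nrl <= 0 or self.peak_width <= 0:
            raise ValueError("nrl and peak_width must be positive")
        if self.n_peaks < 1:
            raise ValueError("n_peaks must be >= 1")
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be > 0")
        if self.zigzag_amplitude < 0:
            raise ValueError("zigzag_amplitude must be >= 0")
        if not (0 < self.min_distance < self.max_distance):
            raise ValueError("need 0 < min_distance < max_distance")
        fr = _as_tuple(self.orientation_fractions, 3, "orientation_fractions")
        if any(f < 0 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("orientation_fractions must be nonnegative and sum to 1")
        object.__setattr__(self, "orientation_fractions", fr)
        if self.depth <= 0:
            raise ValueError("depth must be positive")

    def replace(self, **kw) -> "MicrocSimConfig":
        return dataclasses.replace(self, **kw)


def microc_step_weights(cfg: MicrocSimConfig) -> np.ndarray:
    """Normalized step weights w_n for n = 1..n_peaks."""
    n = np.arange(1, cfg.n_peaks + 1, dtype=float)
    odd_boost = 1.0 + cfg.zigzag_amplitude * ((n % 2 == 1) & (n >= 3))
    w = n ** (-cfg.decay_exponent) * odd_boost
    return w / w.sum()


# ---------------------------------------------------------------------------
# fragment generators


def _draw_fld_lengths(rng: np.random.Generator, cfg: FldSimConfig) -> np.ndarray:
    """Mixture lengths (int nt) after exponential thinning."""
    k = len(cfg.peak_centers)
    probs = list(cfg.peak_weights) + [cfg.background_fraction]
    comp = rng.choice(k + 1, size=cfg.depth, p=probs)
    lengths = np.empty(cfg.depth, dtype=float)
    for i, (c, w) in enumerate(zip(cfg.peak_centers, cfg.peak_widths)):
        m = comp == i
        lengths[m] = rng.normal(c, w, int(m.sum()))
    bg = comp == k
    lo, hi = cfg.background_range
    lengths[bg] = rng.integers(int(lo), int(hi), size=int(bg.sum()), endpoint=True)
    # reject nonpositive Gaussian draws by resampling
    bad = lengths < 1
    while bad.any():
        for i, (c, w) in enumerate(zip(cfg.peak_centers, cfg.peak_widths)):
            m = bad & (comp == i)
            lengths[m] = rng.normal(c, w, int(m.sum()))
        bad = lengths < 1
    lengths = np.rint(lengths).astype(np.int64)
    if cfg.bias_rate > 0:
        keep = rng.random(cfg.depth) < np.exp(-cfg.bias_rate * lengths)
        lengths = lengths[keep]
    return lengths


def _place_uniform(
    rng: np.random.Generator, lengths: np.ndarray, chrom_sizes: Mapping[str, int]
) -> pd.DataFrame:
    chroms = np.array(list(chrom_sizes))
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=np.int64)
    if lengths.size and lengths.max() > sizes.min():
        raise ValueError("fragment longer than the smallest chromosome")
    ci = rng.choice(len(chroms), size=lengths.size, p=sizes / sizes.sum())
    start = np.floor(rng.random(lengths.size) * (sizes[ci] - lengths)).astype(np.int64)
    return pd.DataFrame(
        {
            "chrom": chroms[ci],
            "start": start,
            "end": start + lengths,
            "length": lengths,
        }
    )


def simulate_ricc_fragments(cfg: FldSimConfig) -> pd.DataFrame:
    """Correlated-cleavage fragment table (chrom, start, end, length).

    Lengths follow the configured Gaussian mixture plus uniform background,
    thinned with probability exp(-k * length); genomic placement is uniform
    over ``chrom_sizes``.  Deterministic per seed.
    """
    rng = np.random.default_rng(cfg.seed)
    lengths = _draw_fld_lengths(rng, cfg)
    return _place_uniform(rng, lengths, cfg.chrom_sizes)


def simulate_gdna_fragments(cfg: FldSimConfig) -> pd.DataFrame:
    """Background-only control emulating irradiated genomic DNA.

    Identical to :func:`simulate_ricc_fragments` with every contact-peak
    weight forced to zero (uncorrelated breaks only).
    """
    cfg = cfg.replace(
        peak_weights=(0.0,) * len(cfg.peak_weights), background_fraction=1.0
    )
    return simulate_ricc_fragments(cfg)


def simulate_spikein(cfg: SpikeSimConfig):
    """Spike-in ladder: exact pre-sequencing FLD and sampled, biased post-FLD.

    ``pre`` is the analytic ladder mixture evaluated per integer nt and
    scaled to ``depth`` (the pre-sequencing expectation); ``post`` is a
    sample of ``depth`` fragments thinned with probability exp(-k * L).
    Both share one seed.
    """
    rng = np.random.default_rng(cfg.seed)
    centers = cfg.rung_centers
    widths = np.asarray(cfg.rung_widths)
    grid = np.arange(1, int(centers[-1] + 5 * widths.max()) + 1)
    pmf = np.zeros(grid.size)
    for c, w in zip(centers, widths):
        pmf += np.exp(-0.5 * ((grid - c) / w) ** 2) / w
    pmf /= pmf.sum()
    pre = FragmentLengthHistogram(
        counts=pd.Series(cfg.depth * pmf, index=grid),
        sample_id="spikein_pre",
        source="spikein_pre",
        metadata={"seed": cfg.seed},
    )
    rung = rng.integers(0, cfg.n_rungs, size=cfg.depth)
    lengths = rng.normal(centers[rung], widths[rung])
    bad = lengths < 1
    while bad.any():
        lengths[bad] = rng.normal(centers[rung[bad]], widths[rung[bad]])
        bad = lengths < 1
    lengths = np.rint(lengths).astype(np.int64)
    if cfg.bias_rate > 0:
        keep = rng.random(cfg.depth) < np.exp(-cfg.bias_rate * lengths)
        lengths = lengths[keep]
    counts = np.bincount(
        np.clip(lengths, 1, grid[-1]), minlength=grid[-1] + 1
    )[1:].astype(float)
    post = FragmentLengthHistogram(
        counts=pd.Series(counts, index=grid),
        sample_id="spikein_post",
        source="spikein_post",
        metadata={"seed": cfg.seed},
    )
    return pre, post


# ---------------------------------------------------------------------------
# ligation-pair generator


def _draw_pair_geometry(rng: np.random.Generator, cfg: MicrocSimConfig, n: int):
    """Measured distances plus position-ordered strand pairs for n pairs."""
    centers = cfg.nrl * np.arange(1, cfg.n_peaks + 1)
    reachable = (centers > cfg.min_distance - 5 * cfg.peak_width) & (
        centers < cfg.max_distance + 5 * cfg.peak_width
    )
    if not reachable.any():
        raise ValueError(
            "distance truncation empties the support: no comb peak lies near "
            f"[{cfg.min_distance}, {cfg.max_distance}]"
        )
    # steps whose comb peak lies entirely outside the truncation window get
    # zero weight, otherwise rejection sampling would spin on them
    w = microc_step_weights(cfg)
    w = np.where(reachable, w, 0.0)
    w /= w.sum()
    step = rng.choice(cfg.n_peaks, size=n, p=w)
    d = rng.normal(centers[step], cfg.peak_width)
    # global truncation of the mixture: out-of-window draws are redrawn with
    # a fresh step too, so interior peak heights keep their w_n proportions
    out = (d < cfg.min_distance) | (d > cfg.max_distance)
    tries = 0
    while out.any():
        step[out] = rng.choice(cfg.n_peaks, size=int(out.sum()), p=w)
        d[out] = rng.normal(centers[step[out]], cfg.peak_width)
        out = (d < cfg.min_distance) | (d > cfg.max_distance)
        tries += 1
        if tries > 1000:
            raise ValueError("distance truncation rejects essentially all draws")
    orient = rng.choice(3, size=n, p=cfg.orientation_fractions)  # 0 tan, 1 in, 2 out
    measured = d + cfg.orientation_shift * (orient == 1) - cfg.orientation_shift * (
        orient == 2
    )
    measured = np.maximum(np.rint(measured).astype(np.int64), 1)
    # position-ordered strand convention: inward +/-, outward -/+, tandem same
    strand1 = np.where(orient == 2, "-", "+").astype(object)
    strand2 = np.where(orient == 1, "-", "+").astype(object)
    tandem = orient == 0
    minus_tandem = tandem & (rng.random(n) < 0.5)
    strand1[minus_tandem] = "-"
    strand2[minus_tandem] = "-"
    return measured, strand1, strand2


def simulate_microc_pairs(cfg: MicrocSimConfig) -> pd.DataFrame:
    """Cis ligation-pair table in 4DN column order, deterministic per seed.

    Columns: read_id, chrom1, pos1, chrom2, pos2, strand1, strand2 with
    pos1 <= pos2 and strands encoding the ligation orientation (inward
    +/-, outward -/+, tandem +/+ or -/-).
    """
    rng = np.random.default_rng(cfg.seed)
    measured, strand1, strand2 = _draw_pair_geometry(rng, cfg, cfg.depth)
    chroms = np.array(list(cfg.chrom_sizes))
    sizes = np.array([cfg.chrom_sizes[c] for c in chroms], dtype=np.int64)
    if measured.max() >= sizes.min():
        raise ValueError("pair distance exceeds the smallest chromosome")
    ci = rng.choice(len(chroms), size=cfg.depth, p=sizes / sizes.sum())
    pos1 = np.floor(rng.random(cfg.depth) * (sizes[ci] - measured)).astype(np.int64)
    return pd.DataFrame(
        {
            "read_id": [f"sim{i:08d}" for i in range(cfg.depth)],
            "chrom1": chroms[ci],
            "pos1": pos1,
            "chrom2": chroms[ci],
            "pos2": pos1 + measured,
            "strand1": strand1,
            "strand2": strand2,
        }
    )


# ---------------------------------------------------------------------------
# epigenetic-state regions


@dataclass(frozen=True)
class StateSpec:
    """One labeled epigenetic state with generator overrides."""

    label: str
    n_intervals: int = 20
    interval_length: int = 20_000
    fld: FldSimConfig | None = None
    microc: MicrocSimConfig | None = None

    def __post_init__(self):
        if self.n_intervals < 0 or self.interval_length <= 0:
            raise ValueError("invalid interval geometry")


@dataclass(frozen=True)
class StateRegionConfig:
    states: tuple = ()
    chrom_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_CHROM_SIZES)
    )
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "states", tuple(self.states))


def _place_intervals(
    rng: np.random.Generator,
    spec: StateSpec,
    chrom_sizes: Mapping[str, int],
) -> pd.DataFrame:
    chroms = np.array(list(chrom_sizes))
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=np.int64)
    if spec.interval_length > sizes.max():
        raise ValueError(f"interval length exceeds every chromosome ({spec.label})")
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    rows = []
    tries = 0
    while len(rows) < spec.n_intervals:
        tries += 1
        if tries > 200 * max(spec.n_intervals, 1):
            raise ValueError(
                f"cannot place {spec.n_intervals} non-overlapping intervals "
                f"for state {spec.label!r}"
            )
        i = rng.choice(len(chroms), p=sizes / sizes.sum())
        if sizes[i] < spec.interval_length:
            continue
        start = int(rng.integers(0, sizes[i] - spec.interval_length, endpoint=True))
        end = start + spec.interval_length
        if any(start < e and s < end for s, e in placed[chroms[i]]):
            continue
        placed[chroms[i]].append((start, end))
        rows.append((chroms[i], start, end, spec.label, 0, "."))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    ).sort_values(["chrom", "start"], ignore_index=True)


def _place_in_intervals(
    rng: np.random.Generator, lengths: np.ndarray, intervals: pd.DataFrame
) -> pd.DataFrame:
    """Place fragments of given lengths fully inside the given intervals."""
    iv_start = intervals["start"].to_numpy()
    iv_len = (intervals["end"] - intervals["start"]).to_numpy()
    chrom = np.empty(lengths.size, dtype=object)
    start = np.empty(lengths.size, dtype=np.int64)
    for j, L in enumerate(lengths):
        ok = np.flatnonzero(iv_len >= L)
        if ok.size == 0:
            raise ValueError("fragment longer than every state interval")
        weights = (iv_len[ok] - L + 1).astype(float)
        i = ok[rng.choice(ok.size, p=weights / weights.sum())]
        chrom[j] = intervals["chrom"].iloc[i]
        start[j] = iv_start[i] + rng.integers(0, iv_len[i] - L, endpoint=True)
    return pd.DataFrame(
        {"chrom": chrom, "start": start, "end": start + lengths, "length": lengths}
    )


def simulate_state_regions(cfg: StateRegionConfig):
    """Labeled interval sets plus per-state fragment and pair tables.

    Returns ``(regions, per_state)`` where ``regions`` is a BED6-style
    DataFrame (state label in the name field) and ``per_state`` maps each
    label to a dict with ``"fragments"`` and/or ``"pairs"`` tables drawn
    from that state's override configs and placed inside its intervals.
    """
    rng = np.random.default_rng(cfg.seed)
    all_regions = []
    per_state: dict[str, dict] = {}
    for spec in cfg.states:
        regions = _place_intervals(rng, spec, cfg.chrom_sizes)
        all_regions.append(regions)
        out: dict[str, pd.DataFrame] = {}
        if spec.fld is not None:
            frag_rng = np.random.default_rng(spec.fld.seed)
            lengths = _draw_fld_lengths(frag_rng, spec.fld)
            out["fragments"] = _place_in_intervals(frag_rng, lengths, regions)
        if spec.microc is not None:
            pair_rng = np.random.default_rng(spec.microc.seed)
            measured, s1, s2 = _draw_pair_geometry(pair_rng, spec.microc, spec.microc.depth)
            placed = _place_in_intervals(pair_rng, measured, regions)
            out["pairs"] = pd.DataFrame(
                {
                    "read_id": [f"{spec.label}_{i:08d}" for i in range(measured.size)],
                    "chrom1": placed["chrom"],
                    "pos1": placed["start"],
                    "chrom2": placed["chrom"],
                    "pos2": placed["end"],
                    "strand1": s1,
                    "strand2": s2,
                }
            )
        per_state[spec.label] = out
    regions = (
        pd.concat(all_regions, ignore_index=True)
        if all_regions
        else pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand"])
    )
    return regions, per_state


# ---------------------------------------------------------------------------
# compartment-score tracks


def simulate_cscore_tracks(
    n_bins: int,
    rho_target: float,
    seed: int,
    chroms: Sequence[str] = ("chr1",),
    bin_size: int = 100_000,
    signs: Mapping[str, int] | None = None,
    shifts: Mapping[str, np.ndarray] | None = None,
):
    """Paired compartment-score and reference tracks plus a shifted condition.

    Per chromosome the compartment score is built as
    ``sign * (rho_target * ref + sqrt(1 - rho_target^2) * noise)`` with
    standard-normal reference and noise, so |Spearman rho| with the
    reference is approximately ``rho_target`` and its sign is configurable
    per chromosome.  The second-condition track equals the first plus the
    configured per-bin shifts (default zero).

    Returns ``(cscore, reference, cscore_condition_b)`` as bedGraph-style
    DataFrames with columns chrom, start, end, value.
    """
    if n_bins < 10:
        raise ValueError("n_bins must be >= 10")
    if not -1.0 <= rho_target <= 1.0:
        raise ValueError("rho_target must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    starts = np.arange(n_bins, dtype=np.int64) * bin_size
    frames_c, frames_r, frames_b = [], [], []
    for chrom in chroms:
        ref = rng.standard_normal(n_bins)
        noise = rng.standard_normal(n_bins)
        sign = (signs or {}).get(chrom, 1)
        c = sign * (rho_target * ref + np.sqrt(1.0 - rho_target**2) * noise)
        shift = np.zeros(n_bins) if shifts is None else np.asarray(
            shifts.get(chrom, np.zeros(n_bins)), dtype=float
        )
        if shift.shape != (n_bins,):
            raise ValueError("per-chromosome shifts must have length n_bins")
        base = {"chrom": chrom, "start": starts, "end": starts + bin_size}
        frames_c.append(pd.DataFrame({**base, "value": c}))
        frames_r.append(pd.DataFrame({**base, "value": ref}))
        frames_b.append(pd.DataFrame({**base, "value": c + shift}))
    return (
        pd.concat(frames_c, ignore_index=True),
        pd.concat(frames_r, ignore_index=True),
        pd.concat(frames_b, ignore_index=True),
    )
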