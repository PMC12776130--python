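"""End-to-end analysis recipes built from the pipeline stages.

Each function runs one complete synthetic-to-result path at a scale a
workstation handles in seconds: quartet FLD peak recovery through the
full spike-in / bias-correction / gDNA-ratio chain, nucleosome repeat
length (NRL) recovery from contact curves, null calibration of the
per-position Welch comparison, and the zig-zag amplitude sweep.  The
acceptance script and the acceptance test suite both drive these.
"""

from __future__ import annotations

import numpy as np

from . import fld, microc
from .simulate import (
    FldSimConfig,
    MicrocSimConfig,
    SpikeSimConfig,
    simulate_gdna_fragments,
    simulate_microc_pairs,
    simulate_ricc_fragments,
    simulate_spikein,
)

__all__ = [
    "QUARTET_WINDOWS",
    "quartet_recovery",
    "nrl_recovery",
    "null_calibration",
    "zigzag_sweep",
]

#: Search windows (nt) for the four FLD contact peaks: sub-nucleosomal,
#: mononucleosome, and the two stacked-gyre peaks.
QUARTET_WINDOWS = {
    "sub_nucleosomal": (55, 120),
    "mononucleosome": (140, 220),
    "third": (230, 310),
    "fourth": (320, 420),
}


def _mean_bias(models: list[fld.BiasModel]) -> fld.BiasModel:
    """Average per-technical-replicate bias fits into one falloff profile."""
    return fld.BiasModel(
        amplitude=float(np.exp(np.mean([np.log(m.amplitude) for m in models]))),
        rate=float(np.mean([m.rate for m in models])),
        fit_min=models[0].fit_min,
        fit_max=models[0].fit_max,
    )


def quartet_recovery(
    seed: int,
    depth: int = 200_000,
    n_tech: int = 2,
    bias_rate: float = 0.005,
    spike_depth: int = 500_000,
) -> dict:
    """Recover the quartet FLD peak centers through the full pipeline.

    Simulates a fibroblast-like correlated-cleavage fragment set (Gaussian
    quartet at 78/180/270/360 nt over a 50% uniform background, exponential
    length bias) split over ``n_tech`` technical replicates, plus matched
    irradiated-gDNA controls and spike-in ladders; then runs spike-in
    scaling, bias fitting, correction/normalization, gDNA ratio, and
    second-derivative peak calling.

    Returns a dict with the called peak center in each quartet search
    window (NaN where no peak was called) plus the fitted bias rate.
    """
    seed = int(seed) % 2**31
    base = FldSimConfig(depth=max(depth // n_tech, 1), bias_rate=bias_rate)

    cell_hists, gdna_hists = [], []
    cell_spikes, gdna_spikes = [], []
    bias_fits = []
    for r in range(n_tech):
        cell_cfg = base.replace(seed=seed + r)
        gdna_cfg = base.replace(seed=seed + 100 + r)
        spike_cfg = SpikeSimConfig(
            depth=spike_depth, bias_rate=bias_rate, seed=seed + 200 + r
        )
        gdna_spike_cfg = spike_cfg.replace(seed=seed + 300 + r)

        cell_hists.append(
            fld.histogram_from_fragments(
                simulate_ricc_fragments(cell_cfg),
                sample_id=f"cell_t{r}", source="cell", technical_replicate=str(r),
            )
        )
        gdna_hists.append(
            fld.histogram_from_fragments(
                simulate_gdna_fragments(gdna_cfg),
                sample_id=f"gdna_t{r}", source="gdna", technical_replicate=str(r),
            )
        )
        pre, post = simulate_spikein(spike_cfg)
        cell_spikes.append(post)
        bias_fits.append(fld.fit_length_bias(post, pre))
        _, gdna_post = simulate_spikein(gdna_spike_cfg)
        gdna_spikes.append(gdna_post)

    cell_scaled, _, cell_factors, _ = fld.spikein_scale(cell_hists, cell_spikes)
    gdna_scaled, _, _, _ = fld.spikein_scale(gdna_hists, gdna_spikes)
    bias = _mean_bias(bias_fits)

    cell_curve = fld.aggregate_condition(
        [fld.correct_normalize(h, bias=bias) for h in cell_scaled]
    )
    gdna_curve = fld.aggregate_condition(
        [fld.correct_normalize(h, bias=bias) for h in gdna_scaled]
    )
    ratio = fld.gdna_ratio(cell_curve, gdna_curve)
    positions, heights = fld.call_fld_peaks(ratio)

    out = {"bias_rate_fit": bias.rate, "scaling_factors": list(map(float, cell_factors))}
    for name, (lo, hi) in QUARTET_WINDOWS.items():
        inside = (positions >= lo) & (positions <= hi)
        if inside.any():
            best = np.flatnonzero(inside)[np.argmax(heights[inside])]
            out[name] = float(positions[best])
        else:
            out[name] = float("nan")
    return out


def nrl_recovery(
    nrl: float,
    seed: int,
    depth: int = 500_000,
    peak_width: float = 12.0,
    decay_exponent: float = 1.2,
) -> dict:
    """Recover a nucleosome repeat length from synthetic ligation pairs.

    Simulates cis pairs from the comb model at the given repeat length
    with no zig-zag modulation, builds the tandem-orientation contact
    curve on 50-1500 bp, calls second-derivative peaks, and estimates the
    NRL as the mean successive peak spacing.
    """
    cfg = MicrocSimConfig(
        nrl=float(nrl),
        peak_width=peak_width,
        decay_exponent=decay_exponent,
        zigzag_amplitude=0.0,
        depth=depth,
        seed=int(seed) % 2**31,
    )
    pairs = simulate_microc_pairs(cfg)
    curve = microc.contact_curve(pairs, orientation="tandem")
    peaks = microc.call_contact_peaks(curve)
    return {
        "nrl": microc.estimate_nrl(peaks),
        "n_peaks": len(peaks),
        "n_tandem_pairs": curve.n_pairs,
    }


def null_calibration(
    seed: int,
    n_trials: int = 50,
    n_replicates: int = 4,
    depth: int = 100_000,
    alpha: float = 0.05,
    min_run: int = 5,
) -> dict:
    """Calibrate the Welch comparison stage under the null.

    Both conditions are drawn from one generator configuration, so every
    per-position test is a true null.  Replicate curves are built without
    smoothing (window 1): the rolling average would correlate neighboring
    per-bp p-values by construction, which is exactly what the minimum-run
    filter must not be confounded by when its false-call rate is measured.
    ``depth`` keeps per-bin counts large enough (dozens per position) for
    the Welch test's normality assumption to hold.  Reports the per-trial
    fraction of significant positions before run filtering and the number
    of runs >= ``min_run`` after filtering.
    """
    rng = np.random.default_rng(int(seed) % 2**31)
    base = FldSimConfig(depth=depth, bias_rate=0.0)
    fractions, run_counts = [], []
    for _ in range(n_trials):
        curves = []
        for _r in range(2 * n_replicates):
            cfg = base.replace(seed=int(rng.integers(0, 2**31)))
            hist = fld.histogram_from_fragments(simulate_ricc_fragments(cfg))
            curves.append(fld.correct_normalize(hist, smooth_window=1))
        result = fld.compare_conditions(
            curves[:n_replicates], curves[n_replicates:], alpha=alpha, min_run=min_run
        )
        finite = np.isfinite(result.p_values)
        fractions.append(float((result.p_values[finite] < alpha).mean()))
        run_counts.append(len(result.significant_runs))
    return {
        "fractions": np.array(fractions),
        "run_counts": np.array(run_counts),
        "alpha": alpha,
    }


def zigzag_sweep(
    seed: int,
    amplitudes=(0.0, 0.25, 0.5),
    depth: int = 500_000,
) -> dict:
    """Odd/even contact ratio as a function of the zig-zag amplitude.

    One tandem-orientation curve per amplitude, peaks called, and the
    decay-detrended odd/even ratio computed (1 for a smoothly decaying
    comb, rising with the odd-step enrichment).
    """
    out = {}
    for a in amplitudes:
        cfg = MicrocSimConfig(
            zigzag_amplitude=float(a), depth=depth, seed=int(seed) % 2**31
        )
        pairs = simulate_microc_pairs(cfg)
        summary = microc.summarize_zigzag(pairs, detrend=True)
        out[float(a)] = summary.odd_even_ratio
    return out
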