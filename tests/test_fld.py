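"""FLD processing chain: scaling, bias correction, normalization, statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import make_regions
from _oracles import brute_force_runs, brute_force_span_overlap

from fiberkit import fld
from fiberkit.simulate import FldSimConfig, SpikeSimConfig, simulate_ricc_fragments, simulate_spikein


def hist_from(counts: dict, **meta) -> fld.FragmentLengthHistogram:
    return fld.FragmentLengthHistogram(counts=pd.Series(counts).sort_index(), **meta)


# ---------------------------------------------------------------------------
# histogramming and subsetting


def frag_table(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def test_span_overlap_counting_rules():
    """Half-open span overlap: >= 1 bp counts, abutment does not."""
    frags = frag_table([("chr1", 100, 200)])
    assert fld.histogram_from_fragments(frags, make_regions([("chr1", 150, 300)])).total == 1
    with pytest.raises(ValueError):
        fld.histogram_from_fragments(frags, make_regions([("chr1", 200, 300)]))
    # abutting fragment is dropped -> empty histogram -> invariant violation
    frags2 = frag_table([("chr1", 100, 200), ("chr1", 250, 350)])
    h = fld.histogram_from_fragments(frags2, make_regions([("chr1", 200, 300)]))
    assert h.total == 1  # only the second fragment overlaps


def test_histogram_counts_overlapping_subset():
    rows = [("chr1", i * 1000, i * 1000 + 150) for i in range(10)]
    regions = make_regions([("chr1", 0, 3500)])  # covers fragments 0..3
    h = fld.histogram_from_fragments(frag_table(rows), regions)
    assert h.total == 4


def test_histogram_rejects_bad_intervals():
    with pytest.raises(ValueError):
        fld.histogram_from_fragments(frag_table([("chr1", 200, 200)]))


def test_span_overlap_equals_brute_force(rng):
    """Vectorized span overlap matches an explicit per-pair interval check."""
    n = 1000
    starts = rng.integers(0, 100_000, n)
    frags = pd.DataFrame(
        {
            "chrom": rng.choice(["chr1", "chr2"], n),
            "start": starts,
            "end": starts + rng.integers(1, 500, n),
        }
    )
    r_starts = rng.integers(0, 100_000, 40)
    regions = make_regions(
        [
            (c, int(s), int(s + w))
            for c, s, w in zip(
                rng.choice(["chr1", "chr2"], 40), r_starts, rng.integers(1, 2000, 40)
            )
        ]
    )
    np.testing.assert_array_equal(
        fld.span_overlap_mask(frags, regions), brute_force_span_overlap(frags, regions)
    )


def test_subsetting_conserves_totals_over_partition(rng):
    """Disjoint exhaustive region sets partition the histogram total."""
    n = 2000
    starts = rng.integers(0, 49_000, n)
    frags = pd.DataFrame(
        {"chrom": "chr1", "start": starts, "end": starts + rng.integers(1, 100, n)}
    )
    # half-open tiling of the whole placement range; fragments crossing a
    # boundary overlap two tiles, so count them once via their start tile
    edges = [0, 10_000, 25_000, 50_000]
    total = 0
    for lo, hi in zip(edges[:-1], edges[1:]):
        sub = frags[(frags["start"] >= lo) & (frags["start"] < hi)]
        if len(sub):
            total += fld.histogram_from_fragments(
                sub, make_regions([("chr1", lo, hi)])
            ).total
    assert total == fld.histogram_from_fragments(frags).total


# ---------------------------------------------------------------------------
# spike-in scaling


def spike_of_depth(d):
    return hist_from({100: d / 2, 200: d / 2}, source="spikein_post")


def test_spikein_scale_factor_arithmetic():
    hists = [hist_from({180: 10.0}) for _ in range(3)]
    spikes = [spike_of_depth(d) for d in (100, 200, 300)]
    scaled, scaled_spikes, factors, ref = fld.spikein_scale(hists, spikes)
    assert ref == 200
    np.testing.assert_allclose(factors, [2.0, 1.0, 2 / 3])
    for s in scaled_spikes:
        assert s.total == pytest.approx(200)


def test_spikein_scale_equal_depths_and_singleton():
    hists = [hist_from({180: 1.0}) for _ in range(2)]
    _, _, factors, _ = fld.spikein_scale(hists, [spike_of_depth(50)] * 2)
    np.testing.assert_allclose(factors, [1.0, 1.0])
    _, _, f1, ref = fld.spikein_scale(hists[:1], [spike_of_depth(77)])
    assert f1[0] == 1.0 and ref == 77


def test_spikein_scale_is_idempotent():
    hists = [hist_from({180: 10.0}) for _ in range(3)]
    spikes = [spike_of_depth(d) for d in (100, 200, 400)]
    scaled, scaled_spikes, _, _ = fld.spikein_scale(hists, spikes)
    again, _, factors2, _ = fld.spikein_scale(scaled, scaled_spikes)
    np.testing.assert_allclose(factors2, 1.0)
    for a, b in zip(scaled, again):
        pd.testing.assert_series_equal(a.counts, b.counts)


def test_spikein_scale_rejects_zero_depth_and_empty_group():
    # a zero-total spike-in cannot be built through the validated
    # constructor, so zero the counts afterwards to exercise the guard
    spike = spike_of_depth(10)
    spike.counts.iloc[:] = 0.0
    with pytest.raises(ValueError):
        fld.spikein_scale([hist_from({180: 1.0})], [spike])
    with pytest.raises(ValueError):
        fld.spikein_scale([], [])


# ---------------------------------------------------------------------------
# bias fit and correction


def ladder(scale=1000.0, rate=0.0):
    L = np.arange(100, 1001)
    base = np.exp(-0.5 * ((L[:, None] - np.array([154, 308, 462, 616, 770])) / 15) ** 2).sum(axis=1)
    return hist_from(dict(zip(L, scale * base * np.exp(rate * L))), source="spikein_pre")


def test_fit_length_bias_identity_and_exact_exponential():
    pre = ladder()
    assert abs(fld.fit_length_bias(pre, pre).rate) < 1e-9
    post = ladder(rate=-0.01)
    model = fld.fit_length_bias(post, pre)
    assert model.rate == pytest.approx(-0.01, abs=1e-9)


def test_fit_length_bias_monte_carlo():
    pre, post = simulate_spikein(SpikeSimConfig(depth=1_000_000, bias_rate=0.005, seed=41))
    assert fld.fit_length_bias(post, pre).rate == pytest.approx(-0.005, rel=0.10)


def test_fit_length_bias_needs_enough_positions():
    small = hist_from({300: 1.0, 301: 1.0, 302: 1.0})
    with pytest.raises(ValueError):
        fld.fit_length_bias(small, small)


def test_correct_normalize_identity_bias_window_one():
    """Identity bias and window 1 reduce to regridded renormalization."""
    h = hist_from({100: 2.0, 180: 8.0, 300: 4.0})
    curve = fld.correct_normalize(h, bias=fld.BiasModel.identity(), smooth_window=1)
    assert curve.values[curve.grid == 180][0] == 1.0
    assert curve.values[curve.grid == 100][0] == pytest.approx(2.0 / 8.0)
    assert curve.values[curve.grid == 300][0] == pytest.approx(4.0 / 8.0)


def test_correct_normalize_contract_at_180():
    cfg = FldSimConfig(depth=30_000, seed=43)
    h = fld.histogram_from_fragments(simulate_ricc_fragments(cfg))
    curve = fld.correct_normalize(h)
    assert curve.values[curve.grid == 180][0] == 1.0


def test_correct_normalize_errors_on_zero_norm():
    h = hist_from({100: 1.0})
    with pytest.raises(ValueError):
        fld.correct_normalize(h)


def test_bias_roundtrip_recovers_unbiased_curve():
    """Correcting with the true bias matches the analytic mixture.

    Agreement is asserted up to counting noise: per-bin deviations scaled
    by their expected standard error stay within 5 sigma everywhere, the
    median relative error is under 2%, and bins deep enough to resolve 5%
    (expected window counts >= 4000) agree within 5%.
    """
    cfg = FldSimConfig(depth=1_000_000, bias_rate=0.005, seed=47)
    h = fld.histogram_from_fragments(simulate_ricc_fragments(cfg))
    true_bias = fld.BiasModel(amplitude=float(np.exp(-0.005 * 300)), rate=-0.005)
    corrected = fld.correct_normalize(h, bias=true_bias)
    grid = corrected.grid.astype(float)
    pmf = np.zeros_like(grid)
    for w, c, s in zip(cfg.peak_weights, cfg.peak_centers, cfg.peak_widths):
        pmf += w * stats.norm.pdf(grid, c, s)
    lo, hi = cfg.background_range
    pmf += cfg.background_fraction / (hi - lo + 1)
    expected = pd.Series(pmf).rolling(10, center=True, min_periods=1).mean().to_numpy()
    expected /= expected[grid == 180][0]
    rel = corrected.values / expected - 1
    n_win = pd.Series(cfg.depth * pmf * np.exp(-0.005 * grid)).rolling(
        10, center=True, min_periods=1
    ).sum().to_numpy()
    assert np.abs(rel * np.sqrt(n_win)).max() < 5.0
    assert np.median(np.abs(rel)) < 0.02
    assert np.all(np.abs(rel[n_win >= 4000]) < 0.05)


# ---------------------------------------------------------------------------
# gDNA ratio


def flat_curve(values):
    grid = fld.DEFAULT_GRID
    return fld.CorrectedCurve(grid=grid, values=np.asarray(values, float))


def test_gdna_ratio_identity_and_degenerate_bins():
    c = flat_curve(np.linspace(0.5, 2.0, fld.DEFAULT_GRID.size))
    np.testing.assert_allclose(fld.gdna_ratio(c, c).values, 1.0)
    g = flat_curve(np.ones(fld.DEFAULT_GRID.size))
    g.values[10] = 0.0
    assert np.isfinite(fld.gdna_ratio(c, g).values).all()


def test_gdna_ratio_invariant_to_common_rescaling():
    rng = np.random.default_rng(0)
    a = flat_curve(rng.uniform(0, 2, fld.DEFAULT_GRID.size))
    b = flat_curve(rng.uniform(0, 2, fld.DEFAULT_GRID.size))
    r1 = fld.gdna_ratio(a, b).values
    a2 = flat_curve(a.values * 37.5)
    b2 = flat_curve(b.values * 37.5)
    np.testing.assert_allclose(fld.gdna_ratio(a2, b2).values, r1)


def test_gdna_ratio_grid_mismatch():
    a = flat_curve(np.ones(fld.DEFAULT_GRID.size))
    b = fld.CorrectedCurve(grid=np.arange(60, 456), values=np.ones(396))
    with pytest.raises(ValueError):
        fld.gdna_ratio(a, b)


def test_matched_cell_gdna_ratio_peaks_at_injected_centers():
    cfg = FldSimConfig(depth=400_000, bias_rate=0.0, seed=53)
    cell = fld.correct_normalize(
        fld.histogram_from_fragments(simulate_ricc_fragments(cfg))
    )
    from fiberkit.simulate import simulate_gdna_fragments

    gdna = fld.correct_normalize(
        fld.histogram_from_fragments(simulate_gdna_fragments(cfg.replace(seed=54)))
    )
    ratio = fld.gdna_ratio(cell, gdna)
    positions, heights = fld.call_fld_peaks(ratio)
    for center in cfg.peak_centers:
        assert np.min(np.abs(positions - center)) <= 4


# ---------------------------------------------------------------------------
# aggregation and comparison


def curves_from_rows(rows):
    grid = np.arange(55, 65)
    return [fld.CorrectedCurve(grid=grid, values=np.asarray(r, float)) for r in rows]


def test_aggregate_t_interval_closed_form():
    """n=3 values {1,2,3}: half-width t_{0.975,2}/sqrt(3) = 2.484."""
    curves = curves_from_rows([[v] * 10 for v in (1.0, 2.0, 3.0)])
    agg = fld.aggregate_condition(curves)
    assert agg.values[0] == pytest.approx(2.0)
    half = agg.ci_upper[0] - agg.values[0]
    assert half == pytest.approx(4.302652 / np.sqrt(3), abs=1e-4)


def test_aggregate_two_replicates_use_t_12_706():
    curves = curves_from_rows([[1.0] * 10, [2.0] * 10])
    agg = fld.aggregate_condition(curves)
    half = agg.ci_upper[0] - agg.values[0]
    sd = np.std([1.0, 2.0], ddof=1)
    assert half == pytest.approx(12.7062 * sd / np.sqrt(2), abs=1e-3)


def test_aggregate_identical_replicates_zero_width_and_singleton_flag():
    curves = curves_from_rows([[1.5] * 10] * 3)
    agg = fld.aggregate_condition(curves)
    np.testing.assert_allclose(agg.ci_upper, agg.ci_lower)
    single = fld.aggregate_condition(curves[:1])
    assert single.ci_lower is None and single.n_replicates == 1


def test_compare_conditions_requires_replicates():
    curves = curves_from_rows([[1.0] * 10, [1.1] * 10])
    with pytest.raises(ValueError):
        fld.compare_conditions(curves[:1], curves)


def test_compare_conditions_planted_signal_recovered():
    """A 30-nt 2-fold difference yields exactly one run covering it."""
    rng = np.random.default_rng(59)
    grid = fld.DEFAULT_GRID
    base = np.ones(grid.size)
    window = (grid >= 200) & (grid <= 229)

    def rep(factor):
        v = base.copy() * (1 + rng.normal(0, 0.005, grid.size))
        v[window] *= factor
        return fld.CorrectedCurve(grid=grid, values=v)

    result = fld.compare_conditions(
        [rep(1.0) for _ in range(4)], [rep(2.0) for _ in range(4)]
    )
    assert len(result.significant_runs) == 1
    start, end = result.significant_runs[0]
    covered = max(0, min(end, 229) - max(start, 200) + 1)
    assert covered >= 0.8 * 30
    assert np.all(result.mean_ratio[window] > 1.5)


def test_short_subalpha_stretch_filtered():
    """A 4-bp significant stretch is below min_run and reported as no run."""
    p = np.ones(50)
    p[10:14] = 1e-6
    assert fld.significant_runs(p, alpha=0.05, min_run=5) == []
    assert fld.significant_runs(p, alpha=0.05, min_run=4) == [(10, 13)]


@settings(max_examples=200, derandomize=True)
@given(
    p=st.lists(st.floats(0, 1), min_size=1, max_size=80),
    alpha=st.sampled_from([0.01, 0.05, 0.2]),
    min_run=st.integers(1, 6),
)
def test_run_calling_equals_brute_force_scan(p, alpha, min_run):
    p = np.asarray(p)
    assert fld.significant_runs(p, alpha, min_run) == brute_force_runs(p, alpha, min_run)


def test_align_by_mono_falloff_detects_shift():
    L = np.arange(50, 400)
    peak = np.exp(-0.5 * ((L - 180) / 15.0) ** 2) * 100 + 1
    a = hist_from(dict(zip(L, peak)), source="spikein_pre")
    b = hist_from(dict(zip(L + 20, peak)), source="spikein_post")
    assert fld.align_by_mono_falloff(a, b) == -20
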