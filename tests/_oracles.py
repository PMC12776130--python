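"""Independent brute-force reference implementations used by the tests.

Each oracle restates a pipeline definition from scratch with explicit
loops, deliberately sharing no code with the implementation it checks.
Windows passed to the peak oracle must be odd so that "centered mean"
is unambiguous.
"""

import numpy as np


def brute_force_runs(p, alpha, min_run):
    """Significant runs by linear scan: maximal stretches of p < alpha."""
    runs = []
    i, n = 0, len(p)
    while i < n:
        if np.isfinite(p[i]) and p[i] < alpha:
            j = i
            while j + 1 < n and np.isfinite(p[j + 1]) and p[j + 1] < alpha:
                j += 1
            if j - i + 1 >= min_run:
                runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def _centered_mean(y, window):
    half = window // 2
    out = np.empty(len(y))
    for i in range(len(y)):
        lo, hi = max(0, i - half), min(len(y), i + half + 1)
        out[i] = sum(y[lo:hi]) / (hi - lo)
    return out


def brute_force_peaks(x, y, smooth_window=15, min_separation=None):
    """Exhaustive concavity-maximum peak search.

    Smooth, take the second difference, average its sign signal at the
    same scale, enumerate every maximal negative run, take the smoothed
    curve maximum inside each, drop candidates at or below the median of
    the positive smoothed values, then greedily merge candidates closer
    than ``min_separation`` (defaults to twice the window) keeping the
    higher.
    """
    assert smooth_window % 2 == 1, "oracle requires an odd window"
    ys = _centered_mean(np.asarray(y, float), smooth_window)
    d2 = np.array([ys[i + 1] - 2 * ys[i] + ys[i - 1] for i in range(1, len(ys) - 1)])
    d2 = _centered_mean(d2, smooth_window)
    positive = [v for v in ys if v > 0]
    floor = np.median(positive) if positive else -np.inf
    cand = []
    i = 0
    while i < len(d2):
        if d2[i] < 0:
            j = i
            while j + 1 < len(d2) and d2[j + 1] < 0:
                j += 1
            seg = range(i + 1, j + 2)  # curve indices covered by the run
            k = max(seg, key=lambda idx: ys[idx])
            in_interior = smooth_window <= k < len(ys) - smooth_window
            if in_interior and ys[k] > floor:
                cand.append((x[k], ys[k]))
            i = j + 1
        else:
            i += 1
    if min_separation is None:
        min_separation = 2 * smooth_window
    kept = []
    for pos, h in sorted(cand, key=lambda c: -c[1]):
        if all(abs(pos - kp) >= min_separation for kp, _ in kept):
            kept.append((pos, h))
    kept.sort()
    return np.array([p for p, _ in kept]), np.array([h for _, h in kept])


def brute_force_span_overlap(fragments, regions):
    """Per-fragment overlap flags by checking every region explicitly."""
    keep = []
    for _, f in fragments.iterrows():
        hit = False
        for _, r in regions.iterrows():
            if (
                f["chrom"] == r["chrom"]
                and f["start"] < r["end"]
                and r["start"] < f["end"]
            ):
                hit = True
                break
        keep.append(hit)
    return np.array(keep)
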