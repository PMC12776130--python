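"""Compartment-score orientation and between-condition shift classification.

Per-bin compartment scores (c-scores) computed upstream from Hi-C contact
data have an arbitrary sign per chromosome.  Each chromosome is oriented
by Spearman correlation against a reference active-mark signal (such as
H3K36me3 ChIP) so that positive scores consistently denote the gene-dense
A compartment: negatively correlated chromosomes are sign-flipped and
chromosomes whose correlation is not significant (p >= 0.01) are excluded.
Between two oriented conditions, per-bin shifts with |delta c-score|
above a threshold (default 0.25) are classified as compartment changes
(B-to-A / A-to-B on sign change) or within-compartment shifts (A-shifted
when the score increases, B-shifted when it decreases).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SHIFT_LABELS",
    "OrientationReport",
    "orient_cscores",
    "classify_shifts",
]

SHIFT_LABELS = ("B_to_A", "A_to_B", "A_shifted", "B_shifted", "stable")

BIN_COLS = ["chrom", "start", "end"]


@dataclass
class OrientationReport:
    """Per-chromosome Spearman rho, p-value, and keep/flip/exclude decision."""

    table: pd.DataFrame  # columns chrom, rho, p_value, decision

    def decision(self, chrom: str) -> str:
        row = self.table.loc[self.table["chrom"] == chrom]
        if row.empty:
            raise KeyError(chrom)
        return str(row["decision"].iloc[0])


def _check_same_bins(a: pd.DataFrame, b: pd.DataFrame, what: str):
    a_bins = a[BIN_COLS].reset_index(drop=True)
    b_bins = b[BIN_COLS].reset_index(drop=True)
    if len(a_bins) != len(b_bins) or not a_bins.equals(b_bins):
        raise ValueError(f"{what} must share the same binning")


def orient_cscores(
    cscore: pd.DataFrame,
    reference: pd.DataFrame,
    p_cut: float = 0.01,
) -> tuple[pd.DataFrame, OrientationReport]:
    """Orient per-chromosome c-scores against a reference signal.

    Both tracks are bedGraph-style DataFrames (chrom, start, end, value)
    on identical bins.  Per chromosome, Spearman rank correlation (average
    ranks for ties; p from the large-sample t approximation with n-2 df)
    decides: exclude when p >= ``p_cut`` (or undefined), flip the sign
    when kept with rho < 0, keep otherwise.  Excluded chromosomes are
    dropped from the oriented track.
    """
    _check_same_bins(cscore, reference, "c-score and reference tracks")
    merged = cscore.rename(columns={"value": "c"}).copy()
    merged["ref"] = reference["value"].to_numpy()
    rows = []
    oriented_parts = []
    for chrom, grp in merged.groupby("chrom", sort=False):
        n = len(grp)
        if n < 5:
            raise ValueError(f"chromosome {chrom} has {n} bins (need >= 5)")
        rho, p = stats.spearmanr(grp["c"], grp["ref"])
        if not np.isfinite(rho) or not np.isfinite(p) or p >= p_cut:
            decision = "exclude"
        elif rho < 0:
            decision = "flip"
        else:
            decision = "keep"
        rows.append((chrom, rho, p, decision))
        if decision != "exclude":
            part = grp[BIN_COLS].copy()
            part["value"] = grp["c"].to_numpy() * (-1.0 if decision == "flip" else 1.0)
            oriented_parts.append(part)
    report = OrientationReport(
        pd.DataFrame(rows, columns=["chrom", "rho", "p_value", "decision"])
    )
    oriented = (
        pd.concat(oriented_parts, ignore_index=True)
        if oriented_parts
        else pd.DataFrame(columns=BIN_COLS + ["value"])
    )
    return oriented, report


def classify_shifts(
    a: pd.DataFrame,
    b: pd.DataFrame,
    threshold: float = 0.25,
) -> tuple[pd.DataFrame, dict]:
    """Classify per-bin compartment shifts between two oriented tracks.

    delta = c-score_B - c-score_A per shared bin.  |delta| <= threshold is
    ``stable``; otherwise a sign change negative -> nonnegative is
    ``B_to_A`` and nonnegative -> negative is ``A_to_B``; within the same
    sign an increase is ``A_shifted`` and a decrease ``B_shifted``
    (exactly-zero scores count as nonnegative).  Bins missing a value in
    either track are omitted from the output and counted in the report.

    Returns ``(calls, report)`` where ``calls`` has columns chrom, start,
    end, a, b, delta, label and ``report`` holds label counts plus the
    number of dropped bins.
    """
    merged = pd.merge(
        a.rename(columns={"value": "a"}),
        b.rename(columns={"value": "b"}),
        on=BIN_COLS,
        how="outer",
    )
    missing = merged["a"].isna() | merged["b"].isna()
    calls = merged.loc[~missing].copy()
    av = calls["a"].to_numpy(dtype=float)
    bv = calls["b"].to_numpy(dtype=float)
    delta = bv - av
    a_nonneg = av >= 0
    b_nonneg = bv >= 0
    label = np.where(
        np.abs(delta) <= threshold,
        "stable",
        np.where(
            ~a_nonneg & b_nonneg,
            "B_to_A",
            np.where(
                a_nonneg & ~b_nonneg,
                "A_to_B",
                np.where(delta > 0, "A_shifted", "B_shifted"),
            ),
        ),
    )
    calls["delta"] = delta
    calls["label"] = label
    report = {lab: int((label == lab).sum()) for lab in SHIFT_LABELS}
    report["missing_bins"] = int(missing.sum())
    report["threshold"] = float(threshold)
    return calls.reset_index(drop=True), report
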