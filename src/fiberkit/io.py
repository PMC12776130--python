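"""Readers and writers for the text formats the pipeline touches.

Histograms come in as two-column TSV (insert_size, count), optionally in
the HISTOGRAM dialect of Picard CollectInsertSizeMetrics logs; ligation
pairs use the 4DN ``.pairs`` text format; region sets are BED3+/BED6 or
ENCODE gappedPeak (coordinates plus optional name only); bin tracks are
bedGraph.  Writers emit files that their parsers round-trip losslessly,
and every writer accepts a metadata mapping recorded as ``#key=value``
header lines for provenance (seeds, parameters, parents).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fld import ComparisonResult, CorrectedCurve, FragmentLengthHistogram

__all__ = [
    "read_histogram",
    "write_histogram",
    "read_pairs",
    "write_pairs",
    "read_regions",
    "merge_regions",
    "write_regions",
    "read_bedgraph",
    "write_bedgraph",
    "read_fragments",
    "write_fragments",
    "write_curve",
    "read_curve",
    "write_comparison",
]

PAIRS_HEADER = "## pairs format v1.0"
PAIRS_COLUMNS = ["read_id", "chrom1", "pos1", "chrom2", "pos2", "strand1", "strand2"]

_HIST_META_FIELDS = (
    "sample_id",
    "condition",
    "biological_replicate",
    "technical_replicate",
    "source",
    "subset",
)


def _meta_lines(metadata: dict | None) -> list[str]:
    if not metadata:
        return []
    return [f"#{k}={v}" for k, v in metadata.items() if v is not None]


def _parse_meta(lines: list[str]) -> dict:
    meta = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if "=" in body:
            k, v = body.split("=", 1)
            meta[k.strip()] = v.strip()
    return meta


# ---------------------------------------------------------------------------
# fragment-length histograms (plain TSV and Picard HISTOGRAM dialect)


def read_histogram(path) -> FragmentLengthHistogram:
    """Parse a two-column (insert_size, count) histogram file.

    Accepts plain TSV with optional ``#key=value`` metadata lines, and
    Picard CollectInsertSizeMetrics logs: when a ``## HISTOGRAM`` section
    marker is present only the table that follows it is read, so METRICS
    CLASS preambles are skipped.  Errors on empty tables and on duplicate
    or non-monotone lengths.
    """
    text = Path(path).read_text()
    lines = text.splitlines()
    meta_lines = [ln for ln in lines if ln.startswith("#")]
    if any(ln.startswith("## HISTOGRAM") for ln in lines):
        start = next(i for i, ln in enumerate(lines) if ln.startswith("## HISTOGRAM"))
        table_lines = []
        for ln in lines[start + 1 :]:
            if not ln.strip():
                break
            table_lines.append(ln)
    else:
        table_lines = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
    rows = []
    for ln in table_lines:
        parts = ln.replace(",", "\t").split()
        if len(parts) < 2:
            continue
        try:
            rows.append((int(parts[0]), float(parts[1])))
        except ValueError:
            continue  # header row such as "insert_size  count"
    if not rows:
        raise ValueError(f"no histogram rows found in {path}")
    lengths = np.array([r[0] for r in rows])
    if np.any(np.diff(lengths) <= 0):
        raise ValueError("histogram lengths must be strictly increasing (no duplicates)")
    meta = _parse_meta(meta_lines)
    fields = {k: meta.pop(k) for k in list(meta) if k in _HIST_META_FIELDS}
    return FragmentLengthHistogram(
        counts=pd.Series([r[1] for r in rows], index=lengths),
        metadata=meta,
        **fields,
    )


def write_histogram(hist: FragmentLengthHistogram, path, metadata: dict | None = None):
    meta = dict(hist.metadata)
    for k in _HIST_META_FIELDS:
        v = getattr(hist, k)
        if v:
            meta[k] = v
    meta.update(metadata or {})
    lines = _meta_lines(meta)
    lines.append("insert_size\tcount")
    lines += [f"{int(L)}\t{c:.10g}" for L, c in hist.counts.items()]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# 4DN .pairs


def read_pairs(path, max_bad_fraction: float = 0.10) -> pd.DataFrame:
    """Parse a 4DN ``.pairs`` text file into a pair table.

    Header lines start with ``#``.  Malformed data lines (wrong column
    count, non-integer positions, strands outside {+,-}) are skipped and
    counted; more than ``max_bad_fraction`` of malformed lines is an
    error.  A header-only file yields an empty table.
    """
    rows, bad = [], 0
    with open(path) as fh:
        for ln in fh:
            ln = ln.rstrip("\n")
            if not ln or ln.startswith("#"):
                continue
            parts = ln.split("\t")
            if len(parts) < 7:
                bad += 1
                continue
            rid, c1, p1, c2, p2, s1, s2 = parts[:7]
            try:
                p1, p2 = int(p1), int(p2)
            except ValueError:
                bad += 1
                continue
            if s1 not in "+-" or s2 not in "+-" or p1 < 0 or p2 < 0:
                bad += 1
                continue
            rows.append((rid, c1, p1, c2, p2, s1, s2))
    total = len(rows) + bad
    if total > 0 and bad / total > max_bad_fraction:
        raise ValueError(f"{bad}/{total} malformed lines in {path}")
    return pd.DataFrame(rows, columns=PAIRS_COLUMNS)


def write_pairs(pairs: pd.DataFrame, path, metadata: dict | None = None,
                chrom_sizes: dict | None = None):
    lines = [PAIRS_HEADER]
    for chrom, size in (chrom_sizes or {}).items():
        lines.append(f"#chromsize: {chrom} {size}")
    lines += _meta_lines(metadata)
    lines.append("#columns: readID chrom1 pos1 chrom2 pos2 strand1 strand2")
    for row in pairs[PAIRS_COLUMNS].itertuples(index=False):
        lines.append("\t".join(str(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# region sets (BED / gappedPeak) and bedGraph tracks


def read_regions(path, merge: bool = False) -> pd.DataFrame:
    """Parse BED3+/BED6/gappedPeak intervals (0-based half-open).

    Only chrom/start/end and, when present, the name field (used as a
    state label) are retained; gappedPeak block columns are ignored.
    Overlapping intervals are merged only when ``merge=True``.
    """
    rows = []
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln or ln.startswith(("#", "track", "browser")):
                continue
            parts = ln.split()
            if len(parts) < 3:
                raise ValueError(f"region line has fewer than 3 columns: {ln!r}")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"region start >= end: {ln!r}")
            name = parts[3] if len(parts) > 3 else "."
            rows.append((chrom, start, end, name))
    regions = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    regions = regions.sort_values(["chrom", "start"], ignore_index=True)
    return merge_regions(regions) if merge else regions


def merge_regions(regions: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping or book-ended intervals per chromosome."""
    out = []
    for chrom, grp in regions.sort_values(["chrom", "start"]).groupby("chrom"):
        cur_s = cur_e = None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e, "."))
                cur_s, cur_e = s, e
        if cur_s is not None:
            out.append((chrom, cur_s, cur_e, "."))
    return pd.DataFrame(out, columns=["chrom", "start", "end", "name"])


def write_regions(regions: pd.DataFrame, path, metadata: dict | None = None):
    lines = _meta_lines(metadata)
    cols = [c for c in ("chrom", "start", "end", "name", "score", "strand") if c in regions]
    for row in regions[cols].itertuples(index=False):
        lines.append("\t".join(str(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
    )
    return df


def write_bedgraph(track: pd.DataFrame, path, metadata: dict | None = None):
    lines = _meta_lines(metadata)
    for row in track[["chrom", "start", "end", "value"]].itertuples(index=False):
        lines.append(f"{row.chrom}\t{int(row.start)}\t{int(row.end)}\t{row.value:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_fragments(path) -> pd.DataFrame:
    """BED3 + length column fragment table."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "length"],
    )
    return df


def write_fragments(fragments: pd.DataFrame, path, metadata: dict | None = None):
    lines = _meta_lines(metadata)
    for row in fragments[["chrom", "start", "end", "length"]].itertuples(index=False):
        lines.append(f"{row.chrom}\t{int(row.start)}\t{int(row.end)}\t{int(row.length)}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# corrected curves and comparisons (TSV + JSON sidecar)


def write_curve(curve: CorrectedCurve, path, sidecar: bool = True):
    """Curve as TSV (grid, value[, ci_lower, ci_upper]) + JSON metadata sidecar."""
    cols = {"grid": curve.grid, "value": curve.values}
    if curve.ci_lower is not None:
        cols["ci_lower"] = curve.ci_lower
        cols["ci_upper"] = curve.ci_upper
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
    if sidecar:
        meta = {
            "sample_id": curve.sample_id,
            "condition": curve.condition,
            "source": curve.source,
            "subset": curve.subset,
            "n_replicates": curve.n_replicates,
            **{k: _jsonable(v) for k, v in curve.metadata.items()},
        }
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2) + "\n")


def read_curve(path) -> CorrectedCurve:
    df = pd.read_csv(path, sep="\t")
    meta_path = Path(str(path) + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return CorrectedCurve(
        grid=df["grid"].to_numpy(),
        values=df["value"].to_numpy(),
        ci_lower=df["ci_lower"].to_numpy() if "ci_lower" in df else None,
        ci_upper=df["ci_upper"].to_numpy() if "ci_upper" in df else None,
        n_replicates=int(meta.pop("n_replicates", 1)),
        sample_id=meta.pop("sample_id", "") or "",
        condition=meta.pop("condition", "") or "",
        source=meta.pop("source", "cell") or "cell",
        subset=meta.pop("subset", None),
        metadata=meta,
    )


def write_comparison(result: ComparisonResult, path, sidecar: bool = True):
    in_run = np.zeros(result.grid.size, dtype=bool)
    for start, end in result.significant_runs:
        in_run |= (result.grid >= start) & (result.grid <= end)
    pd.DataFrame(
        {
            "grid": result.grid,
            "mean_ratio": result.mean_ratio,
            "p_value": result.p_values,
            "significant_run": in_run.astype(int),
        }
    ).to_csv(path, sep="\t", index=False)
    if sidecar:
        meta = {
            "alpha": result.alpha,
            "min_run": result.min_run,
            "significant_runs": [list(map(int, r)) for r in result.significant_runs],
        }
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2) + "\n")


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    if dataclasses.is_dataclass(v):
        return dataclasses.asdict(v)
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    return v
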