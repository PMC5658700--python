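"""Promoter positivity calls and the eight-state classification.

A promoter is *positive* for a chromatin mark (H3K27me3, RNAPII-S5p or
RNAPII-S7p) at a time point when (i) its 2-kb TSS window intersects a
region enriched for that mark and (ii) the read count in the window
clears a data-driven threshold: the 5th percentile of the counts of all
window-overlapping promoters for that (mark, time point) — a 5% tail
cut that trims spuriously overlapped promoters with negligible signal.

Two geometric exclusion filters then set ambiguous promoters to NA:

* *window overlap* — positive TSS windows of different genes for the
  same mark that overlap by more than 200 bp (10% of the window);
* *internal gene* — a positive gene whose body lies entirely inside
  another positive gene's body (the internal gene is removed).

The triple of mark statuses maps to one of eight promoter states
(``classify_state``); a gene that is NA for any mark at any time point
is dropped from the analysis set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import count_points, windows_overlap

logger = logging.getLogger(__name__)

__all__ = [
    "MARKS",
    "STATES",
    "MarkCall",
    "count_reads_in_window",
    "positivity_threshold",
    "call_positive",
    "apply_exclusion_filters",
    "classify_state",
    "classify_all",
    "classify_promoters",
]

MARKS = ("H3K27me3", "S5p", "S7p")

#: canonical time-point ordering of the differentiation course
TIMEPOINTS = ("ESC", "day1", "day3", "day16", "day30")

POSITIVE = "positive"
NEGATIVE = "negative"
NA = "NA"

#: truth table on (H3K27me3, S5p, S7p) positivity
_STATE_TABLE = {
    (True, True, False): "PRC_S5p",
    (True, True, True): "PRC_Active",
    (True, False, False): "PRC_Only",
    (True, False, True): "PRC_S7p",
    (False, True, True): "Active",
    (False, False, False): "Inactive",
    (False, True, False): "S5p_Only",
    (False, False, True): "S7p_Only",
}

STATES = (
    "Active",
    "Inactive",
    "PRC_Only",
    "PRC_S5p",
    "PRC_Active",
    "S5p_Only",
    "S7p_Only",
    "PRC_S7p",
)


@dataclass(frozen=True)
class MarkCall:
    gene: str
    mark: str
    timepoint: str
    status: str
    reads_in_window: float
    overlapped: bool


def count_reads_in_window(
    read_starts: dict[str, np.ndarray], chrom: str, start: int, end: int
) -> int:
    """Count read 5' start positions in ``[start, end)`` on ``chrom``.

    ``read_starts`` maps chromosome to a sorted position array.  An
    unknown chromosome yields 0 with a logged warning.
    """
    if chrom not in read_starts:
        logger.warning("unknown chromosome %r in read-count query; returning 0", chrom)
        return 0
    return count_points(read_starts[chrom], start, end)


def positivity_threshold(counts, q: float = 0.05) -> float:
    """The 5% tail-cut threshold: the ``q`` quantile (linear
    interpolation between order statistics) of the read counts of
    window-overlapping genes for one (mark, time point)."""
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("no overlapping genes for this mark/timepoint")
    return float(np.quantile(counts, q, method="linear"))


def call_positive(
    overlapped: np.ndarray,
    counts: np.ndarray,
    threshold: float,
    inclusive: bool = False,
) -> np.ndarray:
    """Vectorized two-condition positivity rule.

    Positive iff the window overlapped an enriched region and its count
    is above the threshold (strictly by default; set ``inclusive`` to
    count exact-threshold ties as positive).
    """
    counts = np.asarray(counts, dtype=float)
    passed = counts >= threshold if inclusive else counts > threshold
    return np.asarray(overlapped, dtype=bool) & passed


def apply_exclusion_filters(
    calls: pd.DataFrame,
    max_window_overlap: int = 200,
    overlap_policy: str = "both",
) -> pd.DataFrame:
    """Set ambiguous positive calls to NA for one (mark, time point).

    ``calls`` needs columns gene, chrom, win_start, win_end, body_start,
    body_end, status.  Both filters use snapshot semantics — NA sets are
    computed from the incoming positives and applied at once, in order
    (window overlap, then internal gene) — which makes the pass
    idempotent.

    ``overlap_policy``: ``"both"`` removes both genes of a
    >``max_window_overlap``-bp window-overlapping pair; ``"lower_count"``
    removes only the gene with the smaller read count (requires a
    ``count`` column).
    """
    if overlap_policy not in {"both", "lower_count"}:
        raise ValueError(f"unknown overlap_policy {overlap_policy!r}")
    out = calls.copy()

    # -- window-overlap filter (sorted sweep per chromosome) --
    pos = out[out["status"] == POSITIVE]
    na_genes: set = set()
    for _, sub in pos.groupby("chrom", sort=False):
        sub = sub.sort_values("win_start", kind="stable")
        starts = sub["win_start"].to_numpy()
        ends = sub["win_end"].to_numpy()
        genes = sub["gene"].to_numpy()
        cnts = sub["count"].to_numpy() if "count" in sub else None
        n = len(sub)
        for i in range(n):
            j = i + 1
            while j < n and starts[j] < ends[i]:
                ov = min(ends[i], ends[j]) - starts[j]
                if ov > max_window_overlap:
                    if overlap_policy == "both":
                        na_genes.add(genes[i])
                        na_genes.add(genes[j])
                    else:
                        loser = genes[i] if cnts[i] <= cnts[j] else genes[j]
                        na_genes.add(loser)
                j += 1
    out.loc[out["gene"].isin(na_genes), "status"] = NA

    # -- internal-gene filter (among genes still positive) --
    pos = out[out["status"] == POSITIVE]
    internal: set = set()
    for _, sub in pos.groupby("chrom", sort=False):
        sub = sub.sort_values(["body_start", "body_end"], kind="stable")
        bs = sub["body_start"].to_numpy()
        be = sub["body_end"].to_numpy()
        genes = sub["gene"].to_numpy()
        n = len(sub)
        # sorted by start: containers of i can only be at j <= i, and a
        # running max of body ends bounds the scan
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                if bs[j] <= bs[i] and be[i] <= be[j]:
                    internal.add(genes[i])
                    break
    out.loc[out["gene"].isin(internal), "status"] = NA
    return out


def classify_state(k27: str, s5p: str, s7p: str) -> str:
    """Map a (H3K27me3, S5p, S7p) status triple to a promoter state.

    Any NA status yields state NA.
    """
    triple = (k27, s5p, s7p)
    for s in triple:
        if s not in {POSITIVE, NEGATIVE, NA}:
            raise ValueError(f"invalid mark status {s!r}")
    if NA in triple:
        return NA
    return _STATE_TABLE[tuple(s == POSITIVE for s in triple)]


def classify_all(
    calls: pd.DataFrame, timepoints: tuple[str, ...]
) -> tuple[pd.DataFrame, list[str]]:
    """Assemble per-gene, per-time-point states and the analysis set.

    ``calls`` is long-format (gene, mark, timepoint, status) covering
    the 3 marks x all time points for every gene; missing combinations
    raise ``ValueError`` listing what is absent.  Returns the state
    table (gene, timepoint, k27, s5p, s7p, state) and the analysis set:
    genes with no NA for any mark at any time point.
    """
    genes = sorted(calls["gene"].unique())
    wide = calls.pivot_table(
        index=["gene", "timepoint"],
        columns="mark",
        values="status",
        aggfunc="first",
    )
    expected = pd.MultiIndex.from_product([genes, list(timepoints)], names=["gene", "timepoint"])
    missing = expected.difference(wide.index)
    missing_cols = [m for m in MARKS if m not in wide.columns]
    if len(missing) or missing_cols:
        raise ValueError(
            f"missing mark/timepoint combinations: rows={list(missing)[:10]} marks={missing_cols}"
        )
    wide = wide.reindex(expected)
    holes = wide[list(MARKS)].isna()
    if holes.to_numpy().any():
        where = wide.index[holes.any(axis=1)]
        raise ValueError(f"missing mark calls at: {list(where)[:10]}")
    out = wide.reset_index().rename(
        columns={"H3K27me3": "k27", "S5p": "s5p", "S7p": "s7p"}
    )
    out["state"] = [
        classify_state(k, f, s) for k, f, s in zip(out["k27"], out["s5p"], out["s7p"])
    ]
    # analysis set: no NA anywhere
    na_genes = set(out.loc[out["state"] == NA, "gene"])
    analysis_set = [g for g in genes if g not in na_genes]
    out["timepoint"] = pd.Categorical(out["timepoint"], categories=timepoints, ordered=True)
    out = out.sort_values(["gene", "timepoint"]).reset_index(drop=True)
    return out, analysis_set


def classify_promoters(
    gene_table: pd.DataFrame,
    regions: dict[tuple[str, str], pd.DataFrame],
    counts: pd.DataFrame,
    timepoints: tuple[str, ...],
    quantile: float = 0.05,
    inclusive: bool = False,
    max_window_overlap: int = 200,
    overlap_policy: str = "both",
) -> dict:
    """End-to-end classification for a cohort.

    Parameters
    ----------
    gene_table
        One row per (cluster, timepoint) with TSS windows and gene
        bodies (output of :func:`~promoterpoise.annotation.build_gene_table`).
    regions
        Mapping (mark, timepoint) -> BED-like frame (chrom/start/end) of
        enriched regions.
    counts
        Long-format (gene, mark, timepoint, count) TSS-window read
        counts for the selected isoforms.
    Returns
    -------
    dict with keys ``states`` (gene x timepoint state table),
    ``analysis_set``, ``calls`` (long-format statuses) and
    ``thresholds`` (mark, timepoint, threshold, n_overlapping).
    """
    for mark in MARKS:
        for tp in timepoints:
            if (mark, tp) not in regions:
                raise ValueError(f"missing enriched-region set for ({mark}, {tp})")

    call_rows = []
    thr_rows = []
    for tp in timepoints:
        gt = gene_table[gene_table["timepoint"] == tp]
        for mark in MARKS:
            reg = regions[(mark, tp)]
            cnt = counts[(counts["mark"] == mark) & (counts["timepoint"] == tp)]
            cmap = dict(zip(cnt["gene"], cnt["count"]))
            sub = gt.copy()
            sub["count"] = sub["cluster_id"].map(cmap).fillna(0.0)
            overlapped = np.zeros(len(sub), dtype=bool)
            for chrom, idx in sub.groupby("chrom", sort=False).groups.items():
                r = reg[reg["chrom"] == chrom]
                overlapped[sub.index.get_indexer(idx)] = windows_overlap(
                    sub.loc[idx, "tss_win_start"].to_numpy(),
                    sub.loc[idx, "tss_win_end"].to_numpy(),
                    r["start"].to_numpy(),
                    r["end"].to_numpy(),
                )
            ov_counts = sub["count"].to_numpy()[overlapped]
            threshold = positivity_threshold(ov_counts, quantile)
            positive = call_positive(overlapped, sub["count"].to_numpy(), threshold, inclusive)
            frame = pd.DataFrame(
                {
                    "gene": sub["cluster_id"].to_numpy(),
                    "chrom": sub["chrom"].to_numpy(),
                    "win_start": sub["tss_win_start"].to_numpy(),
                    "win_end": sub["tss_win_end"].to_numpy(),
                    "body_start": sub["tx_start"].to_numpy(),
                    "body_end": sub["tx_end"].to_numpy(),
                    "count": sub["count"].to_numpy(),
                    "overlapped": overlapped,
                    "status": np.where(positive, POSITIVE, NEGATIVE),
                }
            )
            frame = apply_exclusion_filters(frame, max_window_overlap, overlap_policy)
            frame["mark"] = mark
            frame["timepoint"] = tp
            call_rows.append(frame)
            thr_rows.append(
                {
                    "mark": mark,
                    "timepoint": tp,
                    "threshold": threshold,
                    "n_overlapping": int(overlapped.sum()),
                }
            )
    calls = pd.concat(call_rows, ignore_index=True)
    states, analysis_set = classify_all(
        calls[["gene", "mark", "timepoint", "status"]], timepoints
    )
    return {
        "states": states,
        "analysis_set": analysis_set,
        "calls": calls,
        "thresholds": pd.DataFrame(thr_rows),
    }
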