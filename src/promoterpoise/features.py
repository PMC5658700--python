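"""Promoter-level genomic features.

Covers the sequence- and methylation-level correlates of promoter
states: breadth of the H3K27me3 enriched region over the TSS window, GC
content, CpG-island coverage, metagene coverage profiles, and the DNA
methylation landscape — proximity clustering of hypomethylated regions
(HMRs) into DNA methylation valleys (DMVs, clustered hypomethylated
territory at least 5 kb long) and a three-way promoter methylation
class (DMV / hypomethylated / methylated).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .intervals import (
    GenomicInterval,
    covered_fraction,
    longest_overlapping_length,
    merge_intervals,
    windows_overlap,
)

__all__ = [
    "h3k27me3_breadth",
    "gc_fraction",
    "cgi_coverage",
    "metagene_profile",
    "cluster_hmrs",
    "define_dmvs",
    "promoter_methylation_class",
]


def h3k27me3_breadth(
    window: GenomicInterval, starts: np.ndarray, ends: np.ndarray
) -> int:
    """Length of the longest enriched region overlapping the TSS
    window; 0 when none overlaps (a pseudo-count of 1 is conventionally
    added before log plotting)."""
    return longest_overlapping_length(window, starts, ends)


def gc_fraction(sequence: str, exclude_n: bool = True) -> float:
    """(#G + #C) / denominator for a sequence over {A,C,G,T,N}.

    With ``exclude_n`` (default) N bases are dropped from the
    denominator; an all-N sequence yields NaN.  Empty input raises
    ``ValueError``.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"unexpected characters in sequence: {sorted(bad)}")
    gc = seq.count("G") + seq.count("C")
    denom = len(seq) - seq.count("N") if exclude_n else len(seq)
    if denom == 0:
        return float("nan")
    return gc / denom


def cgi_coverage(
    target: GenomicInterval, cgi_starts: np.ndarray, cgi_ends: np.ndarray
) -> float:
    """Fraction of ``target`` covered by CpG islands (merged first, so
    mutually overlapping islands are not double counted)."""
    return covered_fraction(target, cgi_starts, cgi_ends)


def metagene_profile(
    coverage: dict[str, np.ndarray],
    anchors: pd.DataFrame,
    flank: int = 5000,
    bin_size: int = 10,
) -> np.ndarray:
    """Mean coverage in non-overlapping bins across anchor-centered
    windows.

    ``coverage`` maps chromosome to a per-base coverage array;
    ``anchors`` has columns chrom, pos, strand.  Each anchor contributes
    the window ``[pos - flank, pos + flank)`` binned into
    ``2 * flank / bin_size`` bins; minus-strand windows are reversed so
    bins run 5' to 3'.  Bins extending past a chromosome end are dropped
    from that gene's contribution (the mean is over the genes covering
    each bin).
    """
    if (2 * flank) % bin_size:
        raise ValueError("2*flank must be a multiple of bin_size")
    n_bins = 2 * flank // bin_size
    total = np.zeros(n_bins)
    count = np.zeros(n_bins)
    for row in anchors.itertuples():
        cov = coverage.get(row.chrom)
        if cov is None:
            continue
        lo = int(row.pos) - flank
        hi = int(row.pos) + flank
        vals = np.full(2 * flank, np.nan)
        src_lo, src_hi = max(lo, 0), min(hi, len(cov))
        if src_lo < src_hi:
            vals[src_lo - lo : src_hi - lo] = cov[src_lo:src_hi]
        binned = vals.reshape(n_bins, bin_size)
        ok = ~np.isnan(binned).any(axis=1)
        bmean = np.where(ok, np.nan_to_num(binned).mean(axis=1), 0.0)
        if row.strand == "-":
            bmean = bmean[::-1]
            ok = ok[::-1]
        total += np.where(ok, bmean, 0.0)
        count += ok
    with np.errstate(invalid="ignore"):
        return np.where(count > 0, total / np.maximum(count, 1), np.nan)


def cluster_hmrs(hmrs: pd.DataFrame, max_gap: int = 1000) -> pd.DataFrame:
    """Proximity-cluster HMRs: transitively merge intervals separated
    by gaps <= ``max_gap`` bp, per chromosome.  Returns a sorted,
    disjoint BED-like frame with the number of source HMRs per merged
    interval."""
    rows = []
    for chrom, sub in hmrs.groupby("chrom", sort=True):
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        ms, me = merge_intervals(s, e, max_gap=max_gap)
        # count source intervals per merged interval
        order = np.argsort(s, kind="stable")
        s_sorted = s[order]
        starts_idx = np.searchsorted(s_sorted, ms, side="left")
        counts = np.diff(np.append(starts_idx, len(s_sorted)))
        for a, b, k in zip(ms, me, counts):
            rows.append({"chrom": chrom, "start": int(a), "end": int(b), "n_source_hmrs": int(k)})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_source_hmrs"])


def define_dmvs(merged: pd.DataFrame, min_length: int = 5000) -> pd.DataFrame:
    """Keep merged hypomethylated intervals at least ``min_length`` bp
    long (inclusive cutoff)."""
    keep = (merged["end"] - merged["start"]) >= min_length
    return merged[keep].reset_index(drop=True)


def promoter_methylation_class(
    window: GenomicInterval,
    dmvs: pd.DataFrame,
    hmrs: pd.DataFrame,
) -> str:
    """Classify a promoter window by its methylation context: ``DMV``
    if it overlaps a DMV, else ``hypomethylated`` if it overlaps any
    HMR, else ``methylated``."""
    for name, frame in (("DMV", dmvs), ("hypomethylated", hmrs)):
        sub = frame[frame["chrom"] == window.chrom]
        if len(sub):
            hit = windows_overlap(
                np.array([window.start]),
                np.array([window.end]),
                sub["start"].to_numpy(),
                sub["end"].to_numpy(),
            )[0]
            if hit:
                return name
    return "methylated"
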