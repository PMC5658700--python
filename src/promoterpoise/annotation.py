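"""Non-redundant gene list construction.

A gene *cluster* groups the transcript isoforms of one gene (UCSC
knownGene / knownIsoforms style).  This module filters clusters
(mitochondrial and ``*_random`` scaffolds out, RefSeq-linked only) and
selects one representative isoform per cluster per time point through a
four-step cascade:

1. highest RNAPII-S5p read count in the 2-kb TSS window,
2. among S5p ties, highest RNAPII-S2p read count in the 4-kb TES window
   (optional — skipped when no S2p data are supplied),
3. among remaining ties, the uniquely flagged canonical isoform,
4. otherwise a seeded random draw.

The TSS of a minus-strand transcript is its ``txEnd``; its TES is
``txStart``.  All windows are half-open and clamped at chromosome
position 0.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

__all__ = [
    "IsoformModel",
    "GeneCluster",
    "read_isoform_table",
    "filter_clusters",
    "tss_window",
    "tes_window",
    "select_isoform",
    "build_gene_table",
]

ISOFORM_COLUMNS = [
    "isoform_id",
    "cluster_id",
    "chrom",
    "strand",
    "txStart",
    "txEnd",
    "cdsStart",
    "cdsEnd",
    "refseq_flag",
    "canonical_flag",
]


@dataclass(frozen=True)
class IsoformModel:
    """One transcript model of a gene cluster."""

    isoform_id: str
    cluster_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    has_refseq: bool
    is_canonical: bool

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.tx_start >= self.tx_end:
            raise ValueError("txStart must be < txEnd")
        if self.cds_start > self.cds_end:
            raise ValueError("cdsStart must be <= cdsEnd")
        if self.coding_bases > 0 and not (
            self.tx_start <= self.cds_start and self.cds_end <= self.tx_end
        ):
            raise ValueError("CDS must lie within the transcript")

    @property
    def coding_bases(self) -> int:
        return self.cds_end - self.cds_start

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def tes(self) -> int:
        return self.tx_end if self.strand == "+" else self.tx_start

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.tx_start, self.tx_end, self.strand)


@dataclass
class GeneCluster:
    """A gene with its isoforms and the per-time-point selection record."""

    cluster_id: str
    isoforms: list[IsoformModel]
    selected: dict[str, str] = field(default_factory=dict)
    selection_step: dict[str, str] = field(default_factory=dict)

    def isoform_ids(self) -> list[str]:
        return [iso.isoform_id for iso in self.isoforms]


def read_isoform_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"isoform_id": str, "cluster_id": str})
    missing = [c for c in ISOFORM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"isoform table missing columns: {missing}")
    return df


def _is_decoy_chrom(chrom: str) -> bool:
    return chrom == "chrM" or chrom.endswith("_random")


def filter_clusters(raw: pd.DataFrame) -> list[GeneCluster]:
    """Apply the cluster-level filters and build :class:`GeneCluster`s.

    Removes clusters on chrM or ``*_random`` scaffolds and clusters with
    no RefSeq-linked isoform.  Malformed rows (missing chrom or cluster
    id) raise ``ValueError`` naming the offending row index.
    """
    bad = raw.index[
        raw["cluster_id"].isna()
        | (raw["cluster_id"].astype(str).str.len() == 0)
        | raw["chrom"].isna()
        | (raw["chrom"].astype(str).str.len() == 0)
    ]
    if len(bad):
        raise ValueError(f"malformed isoform rows (missing chrom/cluster id): {list(bad)}")

    clusters: list[GeneCluster] = []
    for cluster_id, sub in raw.groupby("cluster_id", sort=True):
        chroms = set(sub["chrom"].astype(str))
        if any(_is_decoy_chrom(c) for c in chroms):
            continue
        if not sub["refseq_flag"].astype(bool).any():
            continue
        isoforms = [
            IsoformModel(
                isoform_id=str(r.isoform_id),
                cluster_id=str(cluster_id),
                chrom=str(r.chrom),
                strand=str(r.strand),
                tx_start=int(r.txStart),
                tx_end=int(r.txEnd),
                cds_start=int(r.cdsStart),
                cds_end=int(r.cdsEnd),
                has_refseq=bool(r.refseq_flag),
                is_canonical=bool(r.canonical_flag),
            )
            for r in sub.itertuples()
        ]
        clusters.append(GeneCluster(str(cluster_id), isoforms))
    return clusters


def _centered_window(chrom: str, center: int, width: int, strand: str) -> GenomicInterval:
    if width <= 0 or width % 2:
        raise ValueError("window width must be positive and even")
    half = width // 2
    return GenomicInterval(chrom, max(0, center - half), center + half, strand)


def tss_window(isoform: IsoformModel, width: int = 2000) -> GenomicInterval:
    """The ``width``-bp window centered on the TSS, clamped at 0."""
    return _centered_window(isoform.chrom, isoform.tss, width, isoform.strand)


def tes_window(isoform: IsoformModel, width: int = 4000) -> GenomicInterval:
    """The ``width``-bp window centered on the TES, clamped at 0."""
    return _centered_window(isoform.chrom, isoform.tes, width, isoform.strand)


def _argmax_survivors(ids: list[str], counts: dict[str, float]) -> list[str]:
    vals = {i: counts[i] for i in ids}
    best = max(vals.values())
    return [i for i in ids if vals[i] == best]


def _seeded_choice(survivors: list[str], cluster_id: str, timepoint: str, seed: int) -> str:
    # order-invariant: sort lexicographically, then draw with an rng
    # derived from (seed, cluster, timepoint) so re-runs agree
    survivors = sorted(survivors)
    key = zlib.crc32(f"{cluster_id}\t{timepoint}".encode())
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), key]))
    return survivors[int(rng.integers(len(survivors)))]


def select_isoform(
    cluster: GeneCluster,
    s5p_tss_counts: dict[str, float],
    s2p_tes_counts: dict[str, float] | None = None,
    canonical_ids: set[str] | None = None,
    seed: int = 0,
    timepoint: str = "",
) -> tuple[str, str]:
    """Resolve one isoform for ``cluster`` and report the resolving step.

    Returns ``(isoform_id, step)`` with step in
    ``{single, s5p, s2p, canonical, random}``.  Counts must cover every
    isoform of the cluster when the corresponding signal is supplied.
    """
    ids = cluster.isoform_ids()
    if not ids:
        raise ValueError(f"cluster {cluster.cluster_id} has no isoforms")
    if len(ids) == 1:
        return ids[0], "single"

    survivors = _argmax_survivors(ids, s5p_tss_counts)
    if len(survivors) == 1:
        return survivors[0], "s5p"

    if s2p_tes_counts is not None:
        survivors = _argmax_survivors(survivors, s2p_tes_counts)
        if len(survivors) == 1:
            return survivors[0], "s2p"

    if canonical_ids is None:
        canonical_ids = {iso.isoform_id for iso in cluster.isoforms if iso.is_canonical}
    canon = [i for i in survivors if i in canonical_ids]
    if len(canon) == 1:
        return canon[0], "canonical"
    # 0 or >=2 canonical survivors: seeded random (among the canonical
    # ones when there are several, else among all survivors)
    pool = canon if len(canon) >= 2 else survivors
    return _seeded_choice(pool, cluster.cluster_id, timepoint, seed), "random"


def build_gene_table(
    clusters: list[GeneCluster],
    counts: pd.DataFrame,
    timepoints: tuple[str, ...],
    seed: int = 0,
    tss_width: int = 2000,
    tes_width: int = 4000,
) -> pd.DataFrame:
    """Select an isoform per cluster per time point and derive windows.

    ``counts`` is long-format (isoform_id, timepoint, mark, count) with
    mark ``S5p`` (TSS window) and optionally ``S2p`` (TES window).
    Returns one row per (cluster, timepoint).
    """
    counts = counts.copy()
    counts["isoform_id"] = counts["isoform_id"].astype(str)
    rows = []
    for cluster in clusters:
        by_iso = {iso.isoform_id: iso for iso in cluster.isoforms}
        for tp in timepoints:
            sub = counts[counts["timepoint"] == tp]
            s5p = dict(
                zip(sub[sub["mark"] == "S5p"]["isoform_id"], sub[sub["mark"] == "S5p"]["count"])
            )
            s2p_sub = sub[sub["mark"] == "S2p"]
            s2p = (
                dict(zip(s2p_sub["isoform_id"], s2p_sub["count"])) if len(s2p_sub) else None
            )
            s5p_cluster = {i: s5p.get(i, 0.0) for i in cluster.isoform_ids()}
            s2p_cluster = (
                {i: s2p.get(i, 0.0) for i in cluster.isoform_ids()} if s2p is not None else None
            )
            iso_id, step = select_isoform(
                cluster, s5p_cluster, s2p_cluster, seed=seed, timepoint=tp
            )
            cluster.selected[tp] = iso_id
            cluster.selection_step[tp] = step
            iso = by_iso[iso_id]
            tssw = tss_window(iso, tss_width)
            tesw = tes_window(iso, tes_width)
            rows.append(
                {
                    "cluster_id": cluster.cluster_id,
                    "timepoint": tp,
                    "selected_isoform": iso_id,
                    "selection_step": step,
                    "chrom": iso.chrom,
                    "strand": iso.strand,
                    "tx_start": iso.tx_start,
                    "tx_end": iso.tx_end,
                    "tss": iso.tss,
                    "tes": iso.tes,
                    "tss_win_start": tssw.start,
                    "tss_win_end": tssw.end,
                    "tes_win_start": tesw.start,
                    "tes_win_end": tesw.end,
                }
            )
    return pd.DataFrame(rows)
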