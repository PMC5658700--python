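"""Gene-set statistics: hypergeometric state enrichment, TF influence
rank aggregation, and a preranked gene-set enrichment statistic.

The preranked GSEA here is self-contained.  Given a list of N genes
ordered by a score (here, trans-differentiation influence: score =
max_rank - rank + 1, so highly influential TFs sit at the top) and a
gene set of size m, the running sum increments by |score|^p normalized
over set members at each hit and decrements by 1/(N-m) at each miss;
the enrichment score (ES) is the signed maximum deviation.  The null is
built by drawing random size-m gene sets (label permutations, the only
permutation scheme available for preranked input); NES divides ES by
the mean |null ES| of the same sign, and FDR follows the standard
pooled positive/negative-null procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EnrichmentResult",
    "hypergeom_state_enrichment",
    "average_influence_rank",
    "enrichment_score",
    "gsea_preranked",
    "match_homologs",
]


@dataclass(frozen=True)
class EnrichmentResult:
    universe_size: int
    set_size: int
    list_size: int
    overlap: int
    p_enrich: float
    p_deplete: float


def hypergeom_state_enrichment(
    list_genes, state_genes, universe
) -> EnrichmentResult:
    """One-sided hypergeometric enrichment and depletion p-values for
    the overlap between a gene list and a promoter-state set within a
    universe.

    ``p_enrich`` = P(X >= overlap), ``p_deplete`` = P(X <= overlap) for
    X ~ Hypergeometric(|universe|, |state|, |list|).
    """
    universe = set(universe)
    list_genes = set(list_genes)
    state_genes = set(state_genes)
    if not list_genes <= universe or not state_genes <= universe:
        raise ValueError("gene list and state set must be subsets of the universe")
    N, K, n = len(universe), len(state_genes), len(list_genes)
    k = len(list_genes & state_genes)
    dist = stats.hypergeom(N, K, n)
    return EnrichmentResult(
        universe_size=N,
        set_size=K,
        list_size=n,
        overlap=k,
        p_enrich=float(dist.sf(k - 1)),
        p_deplete=float(dist.cdf(k)),
    )


def average_influence_rank(per_conversion_ranks: dict[str, float]) -> float:
    """Mean of a TF's influence ranks over all conversions into a
    target cell type (lower = more influential)."""
    if not per_conversion_ranks:
        raise ValueError("no conversions supplied")
    return float(np.mean(list(per_conversion_ranks.values())))


def _es_from_steps(run: np.ndarray) -> np.ndarray:
    """Signed maximum deviation per row of a running-sum matrix."""
    idx = np.abs(run).argmax(axis=1)
    return run[np.arange(run.shape[0]), idx]


def _es_batch(weights: np.ndarray, hits: np.ndarray) -> np.ndarray:
    """ES for each row of a boolean membership matrix.

    ``weights`` = |score|^p in list order (length N); ``hits`` is
    (B, N).  Every row must have 0 < m < N members.
    """
    n = weights.shape[0]
    m = hits.sum(axis=1, keepdims=True)
    wh = np.where(hits, weights, 0.0)
    denom = wh.sum(axis=1, keepdims=True)
    # a set with all-zero weights degenerates to the unweighted statistic
    safe = np.where(denom > 0, denom, 1.0)
    p_hit = wh / safe
    p_miss = np.where(hits, 0.0, 1.0 / (n - m))
    run = np.cumsum(p_hit - p_miss, axis=1)
    return _es_from_steps(run)


def enrichment_score(
    scores: np.ndarray, membership: np.ndarray, weight_exponent: float = 1.0
) -> float:
    """ES of one gene set against a score-ordered list.

    ``scores`` must already be sorted in ranking order (most
    influential first); ``membership`` is the boolean set-indicator in
    the same order.
    """
    scores = np.asarray(scores, dtype=float)
    hits = np.asarray(membership, dtype=bool)
    if hits.shape != scores.shape:
        raise ValueError("membership and scores must align")
    m = int(hits.sum())
    if m == 0 or m >= scores.size:
        raise ValueError("gene set must be a non-empty proper subset of the list")
    w = np.abs(scores) ** weight_exponent
    return float(_es_batch(w, hits[None, :])[0])


def _normalize(es: np.ndarray, null: np.ndarray) -> np.ndarray:
    """NES: divide each ES by the mean |null ES| of the same sign
    (row-wise null)."""
    out = np.zeros_like(es, dtype=float)
    for i, e in enumerate(es):
        pool = null[i]
        same = pool[pool >= 0] if e >= 0 else pool[pool < 0]
        denom = np.abs(same).mean() if same.size else 0.0
        out[i] = e / denom if denom > 0 else 0.0
    return out


def gsea_preranked(
    ranked_genes,
    scores,
    gene_sets: dict[str, set],
    weight_exponent: float = 1.0,
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Preranked GSEA for one or more gene sets.

    Parameters
    ----------
    ranked_genes
        Gene identifiers ordered by decreasing score (ties should be
        pre-broken stably by identifier).
    scores
        The ranking scores aligned with ``ranked_genes``.
    gene_sets
        Mapping set name -> set of genes; each must be a non-empty
        proper subset of the list.
    Returns
    -------
    DataFrame with es, nes, fdr, direction (``high``/``low`` end of the
    ranking), set size, n_permutations and seed per gene set.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    genes = list(ranked_genes)
    n = len(genes)
    index = {g: i for i, g in enumerate(genes)}
    w = np.abs(np.asarray(scores, dtype=float)) ** weight_exponent
    names = sorted(gene_sets)

    hits = np.zeros((len(names), n), dtype=bool)
    for i, name in enumerate(names):
        members = gene_sets[name]
        if not members or not set(members) <= set(genes):
            raise ValueError(f"gene set {name!r} must be a non-empty subset of the list")
        if len(members) >= n:
            raise ValueError(f"gene set {name!r} is not a proper subset of the list")
        hits[i, [index[g] for g in members]] = True
    es = _es_batch(w, hits)

    rng = np.random.default_rng(seed)
    sizes = hits.sum(axis=1)
    null_by_size: dict[int, np.ndarray] = {}
    for m in np.unique(sizes):
        perm_hits = np.zeros((n_permutations, n), dtype=bool)
        for b in range(n_permutations):
            perm_hits[b, rng.choice(n, size=int(m), replace=False)] = True
        null_by_size[int(m)] = _es_batch(w, perm_hits)
    null = np.stack([null_by_size[int(m)] for m in sizes])

    nes = _normalize(es, null)
    null_nes = np.stack([_normalize_null_row(null[i]) for i in range(len(names))])

    pooled = null_nes.ravel()
    fdr = np.ones(len(names))
    for i, e in enumerate(nes):
        if e >= 0:
            a = (pooled >= e).sum()
            b = (pooled >= 0).sum()
            c = (nes >= e).sum()
            d = (nes >= 0).sum()
        else:
            a = (pooled <= e).sum()
            b = (pooled < 0).sum()
            c = (nes <= e).sum()
            d = (nes < 0).sum()
        num = a / b if b else 1.0
        den = c / d if d else 1.0
        fdr[i] = min(1.0, num / den) if den > 0 else 1.0

    return pd.DataFrame(
        {
            "gene_set": names,
            "set_size": sizes,
            "es": es,
            "nes": nes,
            "fdr": fdr,
            "direction": np.where(es >= 0, "high", "low"),
            "n_permutations": n_permutations,
            "seed": seed,
        }
    )


def _normalize_null_row(null_row: np.ndarray) -> np.ndarray:
    """Normalize a null ES sample against itself (same-sign means)."""
    pos = null_row[null_row >= 0]
    neg = null_row[null_row < 0]
    pos_mean = np.abs(pos).mean() if pos.size else 0.0
    neg_mean = np.abs(neg).mean() if neg.size else 0.0
    out = np.zeros_like(null_row)
    if pos_mean > 0:
        out[null_row >= 0] = null_row[null_row >= 0] / pos_mean
    if neg_mean > 0:
        out[null_row < 0] = null_row[null_row < 0] / neg_mean
    return out


def match_homologs(
    genes, homology_table: pd.DataFrame
) -> tuple[dict[str, str], dict[str, int]]:
    """Map gene names through a two-column homology table.

    ``homology_table`` has columns ``source`` and ``target``.  Only
    one-to-one matches are kept; genes with zero or more than one
    target are dropped and counted.  Returns (mapping, counts) with
    counts keyed ``matched``/``unmatched``/``ambiguous``.
    """
    grouped = homology_table.groupby("source")["target"].apply(lambda s: sorted(set(s)))
    mapping: dict[str, str] = {}
    counts = {"matched": 0, "unmatched": 0, "ambiguous": 0}
    for g in genes:
        targets = grouped.get(g, [])
        if len(targets) == 1:
            mapping[g] = targets[0]
            counts["matched"] += 1
        elif len(targets) == 0:
            counts["unmatched"] += 1
        else:
            counts["ambiguous"] += 1
    return mapping, counts
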