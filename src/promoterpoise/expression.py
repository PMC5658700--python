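"""Expression dynamics and knockout derepression.

Implements the expression side of the promoter-state analysis:

* per-gene z-score standardization of a TPM time course and selection
  of genes whose expression peaks in a single time point (z > 1.75 at
  exactly one time point, > 1 TPM somewhere);
* the log10(TPM + 1e-4) transform used for plotting/comparison;
* Polycomb-knockout derepression calls (fold change > 2 and knockout
  expression > 1 FPKM) and per-promoter-state upregulation fractions,
  with repressed-state genes already expressed in wild type (> 1 FPKM)
  excluded from numerator and denominator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "REPRESSED_STATES",
    "zscore_standardize",
    "select_peaking_genes",
    "log_tpm",
    "call_upregulated",
    "per_state_upregulation",
]

REPRESSED_STATES = frozenset({"PRC_S5p", "PRC_Only", "Inactive"})

#: floor for fold-change denominators (FPKM); keeps FC > 2 calls for
#: genes silent in wild type without dividing by zero
WT_EPSILON = 1e-6


def zscore_standardize(values, ddof: int = 1) -> tuple[np.ndarray, bool]:
    """Standardize one expression row across time points.

    Returns ``(z, degenerate)``; a constant row (sd = 0) yields all
    zeros with ``degenerate=True``.  Sample sd (``ddof=1``) by default.
    """
    x = np.asarray(values, dtype=float)
    sd = x.std(ddof=ddof)
    # relative floor: rows constant up to floating-point cancellation
    # are degenerate, not hugely-dispersed
    if sd <= 1e-12 * max(np.abs(x).max(), 1.0):
        return np.zeros_like(x), True
    return (x - x.mean()) / sd, False


def select_peaking_genes(
    matrix: pd.DataFrame,
    z_threshold: float = 1.75,
    expr_threshold: float = 1.0,
    ddof: int = 1,
) -> pd.DataFrame:
    """Genes whose standardized expression peaks in a single time point.

    ``matrix`` is genes x time points (TPM).  A gene is selected iff it
    exceeds ``expr_threshold`` TPM in >= 1 time point and its z-score
    exceeds ``z_threshold`` in exactly one time point (multi-peak genes
    are not single-time-point peaks).  Returns (gene, peak_timepoint,
    max_z) for the selected genes.
    """
    x = matrix.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=ddof, keepdims=True)
    floor = 1e-12 * np.maximum(np.abs(x).max(axis=1, keepdims=True), 1.0)
    ok = sd > floor
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(ok, (x - mean) / np.where(ok, sd, 1.0), 0.0)
    n_over = (z > z_threshold).sum(axis=1)
    expressed = (x > expr_threshold).any(axis=1)
    keep = expressed & (n_over == 1)
    peak_idx = z.argmax(axis=1)
    return pd.DataFrame(
        {
            "gene": matrix.index[keep],
            "peak_timepoint": matrix.columns.to_numpy()[peak_idx[keep]],
            "max_z": z[keep, peak_idx[keep]],
        }
    ).reset_index(drop=True)


def log_tpm(value, pseudocount: float = 1e-4):
    """log10(TPM + pseudocount); monotone, maps 0 to -4 at the default
    pseudocount.  Negative input raises ``ValueError``."""
    x = np.asarray(value, dtype=float)
    if (x < 0).any():
        raise ValueError("TPM values must be non-negative")
    out = np.log10(x + pseudocount)
    return float(out) if np.isscalar(value) else out


def call_upregulated(
    wt_expr,
    ko_expr,
    fc_threshold: float = 2.0,
    ko_expr_threshold: float = 1.0,
) -> np.ndarray:
    """Knockout derepression call: fold change (ko / max(wt, eps)) >
    ``fc_threshold`` and ko expression > ``ko_expr_threshold``."""
    wt = np.asarray(wt_expr, dtype=float)
    ko = np.asarray(ko_expr, dtype=float)
    if (wt < 0).any() or (ko < 0).any():
        raise ValueError("expression values must be non-negative")
    fc = ko / np.maximum(wt, WT_EPSILON)
    res = (fc > fc_threshold) & (ko > ko_expr_threshold)
    return bool(res) if res.ndim == 0 else res


def per_state_upregulation(
    states: pd.Series,
    upregulated: pd.Series,
    wt_expr: pd.Series,
    repressed_states: frozenset = REPRESSED_STATES,
    wt_threshold: float = 1.0,
) -> pd.DataFrame:
    """Fraction of upregulated genes per promoter state.

    All three series are indexed by gene; only genes present in
    ``states`` AND ``upregulated`` (the identifier-matched universe)
    are counted.  Genes in a repressed state whose wild-type expression
    exceeds ``wt_threshold`` are removed from both numerator and
    denominator.  Empty-denominator states get fraction NaN and
    ``defined=False``.
    """
    common = states.index.intersection(upregulated.index)
    st = states.loc[common]
    up = upregulated.loc[common].astype(bool)
    wt = wt_expr.reindex(common)
    excluded = st.isin(repressed_states) & (wt > wt_threshold)
    st, up = st[~excluded], up[~excluded]
    rows = []
    for state in sorted(st.unique()):
        in_state = st == state
        n = int(in_state.sum())
        k = int((in_state & up).sum())
        rows.append(
            {
                "state": state,
                "n_genes": n,
                "n_upregulated": k,
                "fraction": k / n if n else float("nan"),
                "defined": n > 0,
            }
        )
    return pd.DataFrame(rows)
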