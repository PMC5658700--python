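"""Temporal promoter-state trajectories.

Given the per-time-point promoter states of the analysis set, this
module partitions genes by their H3K27me3 (Polycomb) trajectory —
Maintained (positive at every time point), Lost (positive at the first
time point but not all), Acquired (negative at the first time point,
positive later), NeverPRC — and derives the finer groupings: timing and
transience of acquisition, and the fates of promoters that start in the
poised PRC/S5p state.

A gene that loses the mark and regains it later (without being positive
everywhere) counts as Lost: this is the unique reading under which
|Maintained| + |Lost| equals the count of first-time-point positives
and, with |Acquired|, the count of genes positive anywhere.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .state_classification import NA, STATES

__all__ = [
    "PRC_STATES",
    "k27_flags",
    "prc_dynamics",
    "prc_dynamics_table",
    "transient_acquisition",
    "prcs5p_fates",
    "always_state_genes",
    "transition_matrix",
]

#: states implying H3K27me3 positivity
PRC_STATES = frozenset({"PRC_Only", "PRC_S5p", "PRC_Active", "PRC_S7p"})

MAINTAINED = "Maintained"
LOST = "Lost"
ACQUIRED = "Acquired"
NEVER = "NeverPRC"


def k27_flags(states: tuple[str, ...]) -> tuple[bool, ...]:
    """H3K27me3 positivity flags implied by a state trajectory."""
    if any(s == NA for s in states):
        raise ValueError("trajectory contains NA states")
    return tuple(s in PRC_STATES for s in states)


def prc_dynamics(flags) -> str:
    """Classify one H3K27me3 positivity trajectory."""
    flags = tuple(bool(f) for f in flags)
    if all(flags):
        return MAINTAINED
    if flags[0]:
        return LOST
    if any(flags[1:]):
        return ACQUIRED
    return NEVER


def _state_matrix(states: pd.DataFrame, timepoints: tuple[str, ...]) -> pd.DataFrame:
    wide = states.pivot(index="gene", columns="timepoint", values="state")
    missing = [tp for tp in timepoints if tp not in wide.columns]
    if missing:
        raise ValueError(f"state table lacks time points: {missing}")
    return wide[list(timepoints)]


def prc_dynamics_table(
    states: pd.DataFrame, timepoints: tuple[str, ...]
) -> pd.DataFrame:
    """Per-gene dynamics group from a long-format state table.

    NA-state genes must already be excluded (the analysis set).
    """
    wide = _state_matrix(states, timepoints)
    if (wide == NA).to_numpy().any():
        raise ValueError("state table contains NA genes; restrict to the analysis set")
    flags = wide.isin(PRC_STATES)
    group = np.select(
        [
            flags.all(axis=1),
            flags.iloc[:, 0],
            flags.iloc[:, 1:].any(axis=1),
        ],
        [MAINTAINED, LOST, ACQUIRED],
        default=NEVER,
    )
    return pd.DataFrame({"gene": wide.index, "dynamics_group": group}).reset_index(drop=True)


def transient_acquisition(
    states: pd.DataFrame, timepoints: tuple[str, ...]
) -> pd.DataFrame:
    """Partition Acquired genes by first acquisition time point and
    whether the mark is later lost again (transient) or kept to the end
    (retained)."""
    wide = _state_matrix(states, timepoints)
    flags = wide.isin(PRC_STATES)
    dyn = prc_dynamics_table(states, timepoints).set_index("gene")["dynamics_group"]
    rows = []
    for gene in wide.index[dyn.reindex(wide.index) == ACQUIRED]:
        f = flags.loc[gene].to_numpy()
        first = int(np.argmax(f))
        transient = not f[-1]
        rows.append(
            {
                "gene": gene,
                "acquired_at": timepoints[first],
                "fate": "transient" if transient else "retained",
            }
        )
    return pd.DataFrame(rows, columns=["gene", "acquired_at", "fate"])


def prcs5p_fates(
    states: pd.DataFrame, timepoints: tuple[str, ...]
) -> pd.DataFrame:
    """Fates of promoters that are PRC/S5p at the first time point.

    Reports the final-time-point state (grouped into Active, PRC_Active,
    PRC_S5p, PRC_Only, Inactive or ``other``) and whether the gene is
    PRC/S5p at every time point (``always_prcs5p``).
    """
    wide = _state_matrix(states, timepoints)
    start = wide.iloc[:, 0]
    sub = wide[start == "PRC_S5p"]
    named = {"Active", "PRC_Active", "PRC_S5p", "PRC_Only", "Inactive"}
    final = sub.iloc[:, -1]
    fate = final.where(final.isin(named), "other")
    always = (sub == "PRC_S5p").all(axis=1)
    return pd.DataFrame(
        {"gene": sub.index, "final_state": fate.to_numpy(), "always_prcs5p": always.to_numpy()}
    ).reset_index(drop=True)


def always_state_genes(
    states: pd.DataFrame, timepoints: tuple[str, ...], state: str
) -> list[str]:
    """Genes holding ``state`` at every time point."""
    wide = _state_matrix(states, timepoints)
    mask = (wide == state).all(axis=1)
    return list(wide.index[mask])


def transition_matrix(
    states_a: pd.Series, states_b: pd.Series
) -> pd.DataFrame:
    """9x9 count matrix of state transitions between two time points.

    Both series are indexed by gene over the same universe; a mismatch
    raises ``ValueError``.  Rows are the source states, columns the
    destination; the grand total equals the universe size.
    """
    if set(states_a.index) != set(states_b.index):
        raise ValueError("gene universes differ between the two time points")
    labels = list(STATES) + [NA]
    mat = pd.crosstab(
        pd.Categorical(states_a, categories=labels),
        pd.Categorical(states_b.reindex(states_a.index), categories=labels),
        dropna=False,
    )
    mat.index = labels
    mat.columns = labels
    return mat
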