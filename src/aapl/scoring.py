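"""Interaction scoring by a topological-score (TopS) adaptation.

TopS, originally defined for AP-MS spectral counts, scores each cell of a
proteins x conditions abundance matrix by how much the observed value
exceeds its expectation under row/column independence:

    score(p, c) = v(p, c) * ln( v(p, c) / E(p, c) ),
    E(p, c)     = row_sum(p) * col_sum(c) / grand_total

with 0 * ln(0/E) defined as 0.  The score is positive exactly when the
observed value exceeds the expectation, negative when it falls short, and
scales linearly with the matrix (doubling all entries doubles every score).

Here the matrix entry combines the two protein-level oxidation readouts —
v(p, c) = oxidized spectral count x EPO by default — and the per-protein
interaction score is the TopS value read at the selected (optimal)
treatment condition; all other conditions shape the expectation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: How spectral counts and EPO combine into the score-matrix entry.
SCORING_MODES = ("spc_times_epo", "spc_only", "tops_times_epo")


class ScoringError(ValueError):
    pass


def build_score_matrix(
    profiles: pd.DataFrame, mode: str = "spc_times_epo"
) -> pd.DataFrame:
    """Proteins x conditions matrix of oxidation signal.

    Default entry: oxidized spectral count times EPO (undefined EPO counts
    as 0).  Rows that are zero across every condition carry no information
    for the log-odds transform and are dropped (logged).
    """
    if mode not in SCORING_MODES:
        raise ScoringError(f"unknown scoring mode {mode!r}")
    df = profiles.copy()
    epo = df["epo"].fillna(0.0)
    if mode == "spc_only":
        df["v"] = df["ox_spectral_count"].astype(float)
    else:
        df["v"] = df["ox_spectral_count"] * epo
    mat = df.pivot_table(index="protein_id", columns="condition", values="v", aggfunc="first")
    mat = mat.fillna(0.0).sort_index().sort_index(axis=1)
    nonzero = (mat > 0).any(axis=1)
    dropped = int((~nonzero).sum())
    if dropped:
        logger.info("dropped %d all-zero protein rows from the score matrix", dropped)
    mat = mat[nonzero]
    if mat.empty:
        raise ScoringError("score matrix empty after dropping all-zero rows")
    return mat


def tops(matrix: pd.DataFrame, rescale_total: float | None = None) -> pd.DataFrame:
    """TopS log-odds score for every cell of a non-negative matrix.

    ``rescale_total``, when given, first rescales the matrix to that grand
    total; because TopS scales linearly with the matrix, this makes scores
    comparable across datasets of different depth (off by default).
    """
    v = matrix.to_numpy(dtype=float)
    if (v < 0).any():
        raise ScoringError("score matrix entries must be non-negative")
    total = v.sum()
    if total <= 0:
        raise ScoringError("score matrix grand total is zero")
    if rescale_total is not None:
        v = v * (rescale_total / total)
        total = rescale_total
    expected = np.outer(v.sum(axis=1), v.sum(axis=0)) / total
    scores = np.zeros_like(v)
    pos = v > 0
    scores[pos] = v[pos] * np.log(v[pos] / expected[pos])
    return pd.DataFrame(scores, index=matrix.index, columns=matrix.columns)


def aapl_scores(tops_matrix: pd.DataFrame, selected_condition: str) -> pd.Series:
    """Per-protein AAPL score: the TopS value in the selected treatment condition."""
    if selected_condition not in tops_matrix.columns:
        raise ScoringError(
            f"selected condition {selected_condition!r} absent from the score matrix"
        )
    scores = tops_matrix[selected_condition].copy()
    scores.name = "aapl_score"
    return scores


def score_table(
    matrix: pd.DataFrame, tops_matrix: pd.DataFrame, selected_condition: str
) -> pd.DataFrame:
    """Long-form per-cell audit table: observed v, expectation, TopS score, AAPL flag."""
    total = matrix.to_numpy().sum()
    expected = pd.DataFrame(
        np.outer(matrix.sum(axis=1), matrix.sum(axis=0)) / total,
        index=matrix.index,
        columns=matrix.columns,
    )
    rows = []
    for mat, name in ((matrix, "v"), (expected, "expected"), (tops_matrix, "tops")):
        long = mat.stack().rename(name)
        rows.append(long)
    out = pd.concat(rows, axis=1).reset_index()
    out.columns = ["protein_id", "condition", "v", "expected", "tops"]
    out["is_selected_condition"] = out["condition"] == selected_condition
    return out.sort_values(["protein_id", "condition"], ignore_index=True)
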