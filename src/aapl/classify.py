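"""Interactor classification.

Two independent classifications are assigned to every scored (oxidized)
protein and then compared:

* AAPL level — from the proximity-labeling readout itself: L1 when the
  AAPL score exceeds 1; L2 when the score lies in (0, 1] and the EPO fold
  change versus controls exceeds 1.5; otherwise none.  The bait is not its
  own interactor and is excluded.
* STRING type — from prior knowledge: T1 for a direct bait edge with
  combined score above 0.7, T2 for a direct bait edge scoring in
  [0.4, 0.7], T3 for proteins without a qualifying direct bait edge but
  linked (score >= 0.4) to a T1/T2 protein, T4 for the remaining scored
  proteins.

Boundary conventions (the thresholds are quoted as "above", read strictly):
score exactly 1 is not L1; score exactly 0 is not L2; fold change exactly
1.5 is not L2; bait-edge score exactly 0.7 is T2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LEVELS = ("L1", "L2", "none")
STRING_TYPES = ("T1", "T2", "T3", "T4", "NA")


@dataclass(frozen=True)
class ClassificationThresholds:
    l1_score: float = 1.0
    l2_fc: float = 1.5
    string_high: float = 0.7
    string_low: float = 0.4


def classify_levels(
    scores: pd.Series,
    fold_changes: pd.Series,
    bait_id: str,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> pd.DataFrame:
    """Assign L1/L2/none per protein; the bait itself is excluded.

    ``scores`` and ``fold_changes`` are indexed by protein_id.  Proteins
    without a defined fold change cannot be L2.
    """
    if scores.index.has_duplicates or fold_changes.index.has_duplicates:
        raise ValueError("duplicate protein ids in scores or fold changes")
    df = pd.DataFrame({"aapl_score": scores})
    df = df.join(fold_changes.rename("epo_fc"), how="left")
    df = df[df.index != bait_id]
    fc = df["epo_fc"].fillna(-np.inf)  # missing FC can never clear the L2 clause
    is_l1 = df["aapl_score"] > thresholds.l1_score
    is_l2 = (
        ~is_l1
        & (df["aapl_score"] > 0)
        & (df["aapl_score"] <= thresholds.l1_score)
        & (fc > thresholds.l2_fc)
    )
    df["level"] = np.select([is_l1, is_l2], ["L1", "L2"], default="none")
    df.index.name = "protein_id"
    return df.reset_index()


def string_types(
    proteins: list[str] | pd.Index,
    bait_id: str,
    edges: pd.DataFrame,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> pd.Series:
    """STRING type T1–T4 per scored protein (the bait itself gets NA).

    The universe for T3 adjacency is the scored (oxidized) protein set: a
    protein is T3 when it lacks a qualifying direct bait edge but has an
    edge (combined score >= the 0.4 floor) to a protein typed T1 or T2.
    """
    proteins = list(proteins)
    usable = edges[edges["combined_score"] >= thresholds.string_low]
    bait_partner_score: dict[str, float] = {}
    adjacency: dict[str, set[str]] = {}
    for a, b, s in usable[["protein_a", "protein_b", "combined_score"]].itertuples(index=False):
        if a == bait_id:
            bait_partner_score[b] = max(s, bait_partner_score.get(b, 0.0))
        elif b == bait_id:
            bait_partner_score[a] = max(s, bait_partner_score.get(a, 0.0))
        else:
            adjacency.setdefault(a, set()).add(b)
            adjacency.setdefault(b, set()).add(a)

    types: dict[str, str] = {}
    direct12 = set()
    for pid in proteins:
        if pid == bait_id:
            types[pid] = "NA"
            continue
        s = bait_partner_score.get(pid)
        if s is not None and s > thresholds.string_high:
            types[pid] = "T1"
            direct12.add(pid)
        elif s is not None and thresholds.string_low <= s <= thresholds.string_high:
            types[pid] = "T2"
            direct12.add(pid)
    for pid in proteins:
        if pid in types:
            continue
        if adjacency.get(pid, set()) & direct12:
            types[pid] = "T3"
        else:
            types[pid] = "T4"
    return pd.Series({p: types[p] for p in proteins}, name="string_type")


def build_results(
    scores: pd.Series,
    profiles: pd.DataFrame,
    edges: pd.DataFrame,
    bait_id: str,
    selected_condition: str,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> pd.DataFrame:
    """Combined per-protein result table: score, FC, level, STRING type, site count."""
    sel = profiles[profiles["condition"] == selected_condition].set_index("protein_id")
    fold_changes = sel["epo_fc"]
    results = classify_levels(scores, fold_changes, bait_id, thresholds)
    types = string_types(list(results["protein_id"]), bait_id, edges, thresholds)
    results = results.merge(
        types.rename_axis("protein_id").reset_index(), on="protein_id"
    )
    results = results.merge(
        sel[["n_sites", "epo", "epo_norm"]].reset_index(), on="protein_id", how="left"
    )
    results["n_sites"] = results["n_sites"].fillna(0).astype("int64")
    return results.sort_values("protein_id", ignore_index=True)


#: Score bins used for the summary statistics, as (label, lower, upper]
SCORE_BINS = (
    ("score>1", 1.0, np.inf),
    ("0<score<=1", 0.0, 1.0),
    ("score<=0", -np.inf, 0.0),
)


def _bin_label(score: float) -> str:
    for label, lo, hi in SCORE_BINS:
        if lo < score <= hi:
            return label
    return SCORE_BINS[-1][0]


def mean_sites_by_score_bin(results: pd.DataFrame) -> dict[str, float]:
    """Mean oxidation-site count per AAPL-score bin; empty bins get NaN."""
    labels = results["aapl_score"].map(_bin_label)
    means = results.groupby(labels)["n_sites"].mean()
    return {label: float(means.get(label, np.nan)) for label, _, _ in SCORE_BINS}


def score_distribution_of_known_interactors(
    results: pd.DataFrame,
) -> dict[str, float] | None:
    """Fractions of T1∪T2 interactors falling in each AAPL-score bin (sums to 1).

    None when there are no T1/T2 proteins.
    """
    known = results[results["string_type"].isin(("T1", "T2"))]
    if known.empty:
        return None
    labels = known["aapl_score"].map(_bin_label)
    counts = labels.value_counts()
    n = len(known)
    return {label: float(counts.get(label, 0)) / n for label, _, _ in SCORE_BINS}


def cross_reactivity_report(
    results: pd.DataFrame, off_target_bait_id: str
) -> dict[str, object]:
    """How an unrelated antigen behaves under another antibody's labeling experiment.

    ``results`` comes from a run with a different bait; the report flags
    cross-reactivity when the off-target antigen would itself classify as
    an L1/L2 interactor there.
    """
    row = results[results["protein_id"] == off_target_bait_id]
    if row.empty:
        return {
            "protein_id": off_target_bait_id,
            "detected": False,
            "flagged": False,
            "level": "not detected",
            "aapl_score": float("nan"),
            "epo_fc": float("nan"),
        }
    r = row.iloc[0]
    return {
        "protein_id": off_target_bait_id,
        "detected": True,
        "flagged": r["level"] in ("L1", "L2"),
        "level": r["level"],
        "aapl_score": float(r["aapl_score"]),
        "epo_fc": float(r["epo_fc"]) if pd.notna(r["epo_fc"]) else float("nan"),
    }
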