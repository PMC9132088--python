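"""N-glycopeptide typing and glycosylation-dependent interaction comparisons.

Compositions (Hex, HexNAc, Fuc, NeuAc counts) are classified into five
N-glycan types:

* HM — high mannose: the unsubstituted Man_n core, HexNAc <= 2, Hex >= 4,
  no fucose or sialic acid;
* FS — fucosyl-sialylated: at least one fucose and one sialic acid
  (takes precedence over F and S);
* F  — fucosylated (no sialic acid);
* S  — sialylated (no fucose);
* CH — remaining neutral complex/hybrid glycans.

Per-protein summaries are intensity-weighted percentages by default
(a spectrum-count weighting is available).  The inhibitor comparison
contrasts a protein's extent of oxidation under the optimal labeling
condition against the same experiment run after glycosylation inhibitors
(kifunensine, blocking complex-glycan maturation; a sialyltransferase
inhibitor stripping sialic acids), flagging interactors whose oxidation —
hence apparent interaction — drops.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GLYCO_TYPES = ("CH", "F", "FS", "HM", "S")

#: Condition labels of the inhibitor experiment.
INHIBITOR_CONDITIONS = ("AAPL-ctrl", "AAPL-Kif", "AAPL-SI")


@dataclass(frozen=True)
class GlycanRules:
    """Decision thresholds for the high-mannose call (standard N-glycan nomenclature)."""

    hm_max_hexnac: int = 2
    hm_min_hex: int = 4


def classify_glycan(
    hex: int, hexnac: int, fuc: int, neuac: int, rules: GlycanRules = GlycanRules()
) -> str:
    """Type a single composition; total and deterministic over valid counts."""
    for name, count in (("hex", hex), ("hexnac", hexnac), ("fuc", fuc), ("neuac", neuac)):
        if count < 0:
            raise ValueError(f"negative {name} count")
    if hexnac <= rules.hm_max_hexnac and hex >= rules.hm_min_hex and fuc == 0 and neuac == 0:
        return "HM"
    if fuc >= 1 and neuac >= 1:
        return "FS"
    if fuc >= 1:
        return "F"
    if neuac >= 1:
        return "S"
    return "CH"


def classify_table(records: pd.DataFrame, rules: GlycanRules = GlycanRules()) -> pd.DataFrame:
    """Vectorized typing of a glycopeptide table; adds a ``glyco_type`` column."""
    df = records.copy()
    counts = df[["hex", "hexnac", "fuc", "neuac"]].to_numpy()
    if (counts < 0).any():
        raise ValueError("negative monosaccharide count")
    hexn, hexnac, fuc, neuac = counts.T
    is_hm = (hexnac <= rules.hm_max_hexnac) & (hexn >= rules.hm_min_hex) & (fuc == 0) & (neuac == 0)
    df["glyco_type"] = np.select(
        [is_hm, (fuc >= 1) & (neuac >= 1), fuc >= 1, neuac >= 1],
        ["HM", "FS", "F", "S"],
        default="CH",
    )
    return df


def glyco_summary(
    records: pd.DataFrame,
    protein_id: str,
    weight: str = "intensity",
    rules: GlycanRules = GlycanRules(),
) -> pd.DataFrame | None:
    """Per-type totals and percentages of one protein's glycosylation.

    ``weight`` is ``"intensity"`` (default) or ``"count"`` (each
    glycopeptide weighs 1).  Percentages sum to 100.  None when the protein
    has no records or zero total weight.
    """
    mine = records[records["protein_id"] == protein_id]
    if mine.empty:
        return None
    typed = classify_table(mine, rules)
    if weight == "count":
        typed = typed.assign(weight=1.0)
    elif weight == "intensity":
        typed = typed.assign(weight=typed["intensity"].astype(float))
    else:
        raise ValueError(f"unknown weighting {weight!r}")
    total = typed["weight"].sum()
    if total <= 0:
        return None
    per_type = typed.groupby("glyco_type")["weight"].sum()
    out = pd.DataFrame(
        {
            "glyco_type": GLYCO_TYPES,
            "total": [float(per_type.get(t, 0.0)) for t in GLYCO_TYPES],
        }
    )
    out["percent"] = out["total"] / total * 100.0
    out.insert(0, "protein_id", protein_id)
    return out


def dominant_glyco_type(summary: pd.DataFrame) -> str:
    """The glycan type carrying the largest share (ties break alphabetically)."""
    best = summary.sort_values(["percent", "glyco_type"], ascending=[False, True])
    return str(best.iloc[0]["glyco_type"])


def inhibitor_comparison(
    profiles: pd.DataFrame,
    interactors: list[str],
    glyco_records: pd.DataFrame,
    conditions: tuple[str, str, str] = INHIBITOR_CONDITIONS,
    delta: float = 0.2,
    rules: GlycanRules = GlycanRules(),
) -> pd.DataFrame:
    """EPO of glycosylated interactors under control vs inhibitor conditions.

    For each interactor: EPO in each of the three conditions, the ratio of
    each inhibitor condition to the control, a ``decreased`` flag per
    inhibitor (ratio < 1 - delta), and the protein's dominant glycan type.
    """
    ctrl_cond, *inhibitor_conds = conditions
    present = set(profiles["condition"])
    missing = [c for c in conditions if c not in present]
    if missing:
        raise ValueError(f"conditions absent from profiles: {missing}")
    epo = profiles.pivot_table(
        index="protein_id", columns="condition", values="epo", aggfunc="first"
    )
    rows = []
    for pid in sorted(interactors):
        if pid not in epo.index:
            continue
        summary = glyco_summary(glyco_records, pid, rules=rules)
        if summary is None:
            continue  # not glycosylated: outside this comparison
        row: dict[str, object] = {
            "protein_id": pid,
            "dominant_glyco_type": dominant_glyco_type(summary),
            f"epo_{ctrl_cond}": float(epo.loc[pid, ctrl_cond]),
        }
        ctrl_epo = float(epo.loc[pid, ctrl_cond])
        for cond in inhibitor_conds:
            value = float(epo.loc[pid, cond]) if pd.notna(epo.loc[pid, cond]) else np.nan
            ratio = value / ctrl_epo if ctrl_epo > 0 else np.nan
            row[f"epo_{cond}"] = value
            row[f"ratio_{cond}"] = ratio
            row[f"decreased_{cond}"] = bool(ratio < 1.0 - delta) if pd.notna(ratio) else False
        rows.append(row)
    return pd.DataFrame(rows)
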