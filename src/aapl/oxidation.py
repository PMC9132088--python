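"""Quantification of proximity-dependent oxidation.

Implements the two core footprinting quantities and everything derived from
them:

* site degree of oxidation — for one tryptic peptide, the ratio of the
  oxidized peptidoform intensity at a residue to the summed unmodified and
  modified peptidoform intensities;
* extent of protein oxidation (EPO) — per protein and condition, the ratio
  of summed oxidized peptide intensities to summed total peptide
  intensities;

plus cross-condition EPO normalization (to the condition with the largest
EPO), fold change versus control conditions, oxidation-site counts,
condition clustering for the optimization heatmap, one-sided significance
tests of treatment versus pooled controls with Benjamini–Hochberg
correction, and mapping of oxidation sites onto annotated protein regions.

Replicate handling: intensities are summed across replicates for the point
estimates; replicate-level EPOs are computed separately and feed only the
significance tests.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .records import UNMODIFIED
from .synthetic_data import ExperimentDesign

logger = logging.getLogger(__name__)

#: Floor for the control-mean EPO in fold-change denominators.
FC_EPSILON = 1e-4


class GroupingError(ValueError):
    """Measurements passed to a single-group operation span multiple groups."""


def _ox_positions(mod: pd.Series) -> pd.Series:
    """Oxidized 1-based positions for each row; <NA> for unmodified rows."""
    return pd.to_numeric(
        mod.where(mod != UNMODIFIED).str.removeprefix("ox:"), errors="coerce"
    ).astype("Int64")


def aggregate_replicates(measurements: pd.DataFrame) -> pd.DataFrame:
    """Sum intensity and spectral count across replicates of each peptidoform."""
    keys = ["protein_id", "peptide", "start", "end", "mod", "condition"]
    return measurements.groupby(keys, as_index=False)[["intensity", "spectral_count"]].sum()


def site_degree(peptide_measurements: pd.DataFrame) -> dict[int, float]:
    """Degree of oxidation per oxidized position for ONE peptide in ONE condition.

    degree(p) = I_ox(p) / (I_unmod + sum_q I_ox(q)).  Empty dict when the
    denominator is zero or no oxidized forms exist.  Rows must all share
    (protein, peptide, condition); replicates are summed here.
    """
    df = peptide_measurements
    for key in ("protein_id", "peptide", "condition"):
        if df[key].nunique() > 1:
            raise GroupingError(f"measurements span multiple values of {key}")
    total = float(df["intensity"].sum())
    if total <= 0:
        return {}
    ox = df[df["mod"] != UNMODIFIED]
    if ox.empty:
        return {}
    by_pos = ox.groupby(_ox_positions(ox["mod"]))["intensity"].sum()
    return {int(pos): float(i) / total for pos, i in by_pos.items() if i > 0}


def site_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-(protein, position, condition) oxidation degrees over the whole table.

    Degrees are computed per tryptic peptide after summing replicates; when
    several peptidoform groups (e.g. missed-cleavage variants) cover the
    same residue, the maximum degree is kept so each site has one value per
    condition.
    """
    agg = aggregate_replicates(measurements)
    pep_keys = ["protein_id", "peptide", "start", "end", "condition"]
    totals = agg.groupby(pep_keys)["intensity"].sum().rename("pep_total")
    ox = agg[agg["mod"] != UNMODIFIED].copy()
    if ox.empty:
        return pd.DataFrame(columns=["protein_id", "position", "condition", "degree"])
    ox["position"] = _ox_positions(ox["mod"]).astype("int64")
    ox = ox.join(totals, on=pep_keys)
    ox = ox[(ox["pep_total"] > 0) & (ox["intensity"] > 0)]
    ox["degree"] = ox["intensity"] / ox["pep_total"]
    out = (
        ox.groupby(["protein_id", "position", "condition"], as_index=False)["degree"].max()
    )
    return out.sort_values(["protein_id", "position", "condition"], ignore_index=True)


def protein_epo(protein_measurements: pd.DataFrame) -> float:
    """EPO for ONE protein in ONE condition; NaN sentinel when total intensity is 0."""
    df = protein_measurements
    for key in ("protein_id", "condition"):
        if df[key].nunique() > 1:
            raise GroupingError(f"measurements span multiple values of {key}")
    if df.empty:
        raise GroupingError("empty measurement set")
    total = float(df["intensity"].sum())
    if total <= 0:
        return float("nan")
    ox = float(df.loc[df["mod"] != UNMODIFIED, "intensity"].sum())
    return ox / total


def epo_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-(protein, condition) EPO, oxidized spectral count and site count.

    Replicates are summed before the ratio.  Proteins with zero total
    intensity in a condition get EPO = NaN (excluded downstream, logged).
    """
    agg = aggregate_replicates(measurements)
    is_ox = agg["mod"] != UNMODIFIED
    grp = agg.groupby(["protein_id", "condition"])
    out = grp.agg(total_intensity=("intensity", "sum")).reset_index()
    ox_part = (
        agg[is_ox]
        .groupby(["protein_id", "condition"])
        .agg(ox_intensity=("intensity", "sum"), ox_spectral_count=("spectral_count", "sum"))
        .reset_index()
    )
    out = out.merge(ox_part, on=["protein_id", "condition"], how="left")
    out[["ox_intensity", "ox_spectral_count"]] = out[
        ["ox_intensity", "ox_spectral_count"]
    ].fillna(0)
    out["ox_spectral_count"] = out["ox_spectral_count"].astype("int64")
    out["epo"] = np.where(
        out["total_intensity"] > 0, out["ox_intensity"] / out["total_intensity"], np.nan
    )
    n_undefined = int(out["epo"].isna().sum())
    if n_undefined:
        logger.info("EPO undefined (zero total intensity) for %d protein-conditions", n_undefined)

    sites = site_table(measurements)
    n_sites = (
        sites.groupby(["protein_id", "condition"])["position"].nunique().rename("n_sites")
    )
    out = out.join(n_sites, on=["protein_id", "condition"])
    out["n_sites"] = out["n_sites"].fillna(0).astype("int64")
    return out[
        ["protein_id", "condition", "epo", "n_sites", "ox_spectral_count", "total_intensity"]
    ].sort_values(["protein_id", "condition"], ignore_index=True)


def count_sites(measurements: pd.DataFrame, protein_id: str, condition: str) -> int:
    """Distinct oxidized positions with nonzero degree for one protein/condition."""
    sites = site_table(measurements)
    mask = (sites["protein_id"] == protein_id) & (sites["condition"] == condition)
    return int(sites.loc[mask, "position"].nunique())


def normalize_epo(profiles: pd.DataFrame) -> pd.DataFrame:
    """Add ``epo_norm``: each protein's EPO divided by its largest EPO across conditions.

    The maximum condition gets exactly 1; proteins with all-zero (or
    undefined) EPO get 0 everywhere.
    """
    out = profiles.copy()
    peak = out.groupby("protein_id")["epo"].transform("max")
    with np.errstate(invalid="ignore", divide="ignore"):
        out["epo_norm"] = np.where(peak > 0, out["epo"] / peak, 0.0)
    out["epo_norm"] = out["epo_norm"].fillna(0.0)
    return out


def epo_fold_change(
    profiles: pd.DataFrame,
    control_conditions: tuple[str, ...] | list[str],
    epsilon: float = FC_EPSILON,
) -> pd.DataFrame:
    """Add ``epo_fc``: treatment EPO over the mean control EPO (floored at ``epsilon``).

    ``fc_capped`` flags proteins whose control mean hit the floor.  Proteins
    without any defined control EPO get NaN (undefined fold change).
    Control rows carry NaN fold change by definition.
    """
    controls = set(control_conditions)
    out = profiles.copy()
    ctrl = out[out["condition"].isin(controls)]
    ctrl_mean = ctrl.groupby("protein_id")["epo"].mean().rename("ctrl_mean_epo")
    out = out.join(ctrl_mean, on="protein_id")
    denom = out["ctrl_mean_epo"].clip(lower=epsilon)
    is_treat = ~out["condition"].isin(controls)
    out["epo_fc"] = np.where(
        is_treat & out["ctrl_mean_epo"].notna(), out["epo"] / denom, np.nan
    )
    out["fc_capped"] = is_treat & out["ctrl_mean_epo"].notna() & (
        out["ctrl_mean_epo"] < epsilon
    )
    return out


def replicate_epo_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """EPO computed per (protein, condition, replicate) — input to the significance tests."""
    is_ox = measurements["mod"] != UNMODIFIED
    grp = measurements.groupby(["protein_id", "condition", "replicate"])
    out = grp.agg(total=("intensity", "sum")).reset_index()
    ox_part = (
        measurements[is_ox]
        .groupby(["protein_id", "condition", "replicate"])["intensity"]
        .sum()
        .rename("ox")
    )
    out = out.join(ox_part, on=["protein_id", "condition", "replicate"])
    out["ox"] = out["ox"].fillna(0.0)
    out["epo"] = np.where(out["total"] > 0, out["ox"] / out["total"], np.nan)
    return out[["protein_id", "condition", "replicate", "epo"]]


def test_epo_vs_controls(
    replicate_epos: pd.DataFrame,
    treatment_condition: str,
    control_conditions: tuple[str, ...] | list[str],
) -> pd.DataFrame:
    """One-sided Welch t-test of treatment replicate EPOs vs pooled control replicates.

    Returns one row per protein with ``p_value`` and Benjamini–Hochberg
    ``q_value`` (corrected across proteins).  Proteins with fewer than two
    replicate EPOs in either group, or with zero variance in both groups,
    get NaN sentinels and are excluded from the correction.
    """
    df = replicate_epos.dropna(subset=["epo"])
    treat = df[df["condition"] == treatment_condition]
    ctrl = df[df["condition"].isin(set(control_conditions))]
    t_g = {p: g["epo"].to_numpy() for p, g in treat.groupby("protein_id")}
    c_g = {p: g["epo"].to_numpy() for p, g in ctrl.groupby("protein_id")}
    proteins = sorted(set(t_g) | set(c_g))
    pvals = np.full(len(proteins), np.nan)
    for i, pid in enumerate(proteins):
        a = t_g.get(pid, np.empty(0))
        b = c_g.get(pid, np.empty(0))
        if len(a) < 2 or len(b) < 2:
            continue
        if np.var(a) == 0 and np.var(b) == 0:
            continue
        pvals[i] = stats.ttest_ind(a, b, equal_var=False, alternative="greater").pvalue
    qvals = np.full(len(proteins), np.nan)
    defined = ~np.isnan(pvals)
    if defined.any():
        qvals[defined] = stats.false_discovery_control(pvals[defined], method="bh")
    return pd.DataFrame(
        {
            "protein_id": proteins,
            "condition": treatment_condition,
            "p_value": pvals,
            "q_value": qvals,
        }
    )


def condition_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Conditions x proteins EPO matrix (undefined EPO -> 0), for the heatmap."""
    mat = profiles.pivot_table(
        index="condition", columns="protein_id", values="epo", aggfunc="first"
    )
    return mat.fillna(0.0).sort_index().sort_index(axis=1)


def condition_matrix_and_clustering(
    profiles: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str], np.ndarray]:
    """EPO matrix plus hierarchical clustering of conditions.

    Correlation distance with average linkage; conditions enter in sorted id
    order so equal-distance merges break ties deterministically.  Returns
    (matrix, leaf-ordered condition ids, linkage matrix).
    """
    mat = condition_matrix(profiles)
    if len(mat) < 2:
        raise ValueError("need at least 2 conditions to cluster")
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = pdist(mat.to_numpy(), metric="correlation")
    dist = np.nan_to_num(dist, nan=1.0)  # constant condition rows: treat as uncorrelated
    linkage = hierarchy.linkage(dist, method="average")
    order = hierarchy.leaves_list(linkage)
    leaf_order = [mat.index[i] for i in order]
    return mat, leaf_order, linkage


def correlation_distance_matrix(mat: pd.DataFrame) -> pd.DataFrame:
    """Condition-by-condition correlation distance matrix (1 - Pearson r)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = squareform(np.nan_to_num(pdist(mat.to_numpy(), metric="correlation"), nan=1.0))
    return pd.DataFrame(dist, index=mat.index, columns=mat.index)


def map_sites_to_regions(
    sites: pd.DataFrame, regions: pd.DataFrame | None
) -> pd.DataFrame:
    """Assign oxidation sites to all overlapping annotated regions.

    Sites covered by no region (or when no annotation is supplied) are
    reported under the region name ``"unassigned"``.  Returns per
    (protein, region, condition) site counts and degree sums.
    """
    if sites.empty:
        return pd.DataFrame(
            columns=["protein_id", "region_name", "condition", "n_sites", "degree_sum"]
        )
    rows = []
    assigned_idx: set[int] = set()
    if regions is not None and not regions.empty:
        merged = sites.reset_index().merge(regions, on="protein_id", how="inner")
        hit = merged[(merged["position"] >= merged["start"]) & (merged["position"] <= merged["end"])]
        assigned_idx = set(hit["index"])
        rows.append(hit[["protein_id", "region_name", "condition", "position", "degree"]])
    unassigned = sites.loc[~sites.index.isin(assigned_idx)].copy()
    if not unassigned.empty:
        unassigned["region_name"] = "unassigned"
        rows.append(unassigned[["protein_id", "region_name", "condition", "position", "degree"]])
    combined = pd.concat(rows, ignore_index=True)
    out = (
        combined.groupby(["protein_id", "region_name", "condition"])
        .agg(n_sites=("position", "nunique"), degree_sum=("degree", "sum"))
        .reset_index()
    )
    return out.sort_values(["protein_id", "region_name", "condition"], ignore_index=True)


def protein_profiles(
    measurements: pd.DataFrame, design: ExperimentDesign
) -> pd.DataFrame:
    """Full per-(protein, condition) oxidation profile table.

    Combines EPO, cross-condition normalization, fold change versus the
    design's controls, site counts, oxidized spectral counts, and the
    treatment-vs-control significance test for the design's selected
    condition.
    """
    profiles = epo_table(measurements)
    profiles = normalize_epo(profiles)
    profiles = epo_fold_change(profiles, design.control_conditions)
    tests = test_epo_vs_controls(
        replicate_epo_table(measurements),
        design.selected_condition,
        design.control_conditions,
    )
    profiles = profiles.merge(
        tests[["protein_id", "condition", "p_value", "q_value"]],
        on=["protein_id", "condition"],
        how="left",
    )
    return profiles
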