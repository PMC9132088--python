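"""Oxidation quantification: site degrees, EPO, normalization, tests, regions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from aapl import oxidation
from aapl.oxidation import (
    GroupingError,
    condition_matrix_and_clustering,
    correlation_distance_matrix,
    count_sites,
    epo_fold_change,
    epo_table,
    map_sites_to_regions,
    normalize_epo,
    protein_epo,
    site_degree,
    site_table,
)

# qualified access: a bare import of oxidation.test_epo_vs_controls would be
# collected by pytest as a test function
epo_vs_controls = oxidation.test_epo_vs_controls

from conftest import make_rows, random_peptide_table


def brute_force_epo(table):
    """Independent EPO oracle: explicit row-by-row summation."""
    ox = total = 0.0
    for row in table.itertuples(index=False):
        total += row.intensity
        if row.mod != "none":
            ox += row.intensity
    return float("nan") if total == 0 else ox / total


def brute_force_degrees(table):
    """Independent site-degree oracle: per-peptide explicit ratios."""
    out = {}
    groups = {}
    for row in table.itertuples(index=False):
        groups.setdefault((row.protein_id, row.peptide, row.start, row.end), []).append(row)
    for (pid, pep, start, end), rows in groups.items():
        denom = sum(r.intensity for r in rows)
        if denom <= 0:
            continue
        per_pos = {}
        for r in rows:  # rows of the same oxidized peptidoform are merged
            if r.mod != "none":
                pos = int(r.mod.split(":")[1])
                per_pos[pos] = per_pos.get(pos, 0.0) + r.intensity
        for pos, intensity in per_pos.items():
            if intensity > 0:
                key = (pid, pos)
                out[key] = max(out.get(key, 0.0), intensity / denom)
    return out


class TestSiteDegree:
    def test_hand_ratio(self):
        table = make_rows(
            [
                ("P1", "AAAAAAA", 40, 46, "none", "M5", 1, 8e6, 10),
                ("P1", "AAAAAAA", 40, 46, "ox:42", "M5", 1, 2e6, 3),
            ]
        )
        assert site_degree(table) == {42: pytest.approx(0.20)}

    def test_no_oxidized_rows_empty(self):
        table = make_rows([("P1", "AAAAAAA", 1, 7, "none", "M5", 1, 8e6, 10)])
        assert site_degree(table) == {}

    def test_fully_oxidized_boundary(self):
        table = make_rows(
            [
                ("P1", "AAAAAAA", 1, 7, "none", "M5", 1, 0.0, 0),
                ("P1", "AAAAAAA", 1, 7, "ox:3", "M5", 1, 5e5, 2),
            ]
        )
        assert site_degree(table) == {3: pytest.approx(1.0)}

    def test_mixed_peptides_rejected(self):
        table = make_rows(
            [
                ("P1", "AAAAAAA", 1, 7, "none", "M5", 1, 1.0, 1),
                ("P1", "CCCCCCC", 8, 14, "none", "M5", 1, 1.0, 1),
            ]
        )
        with pytest.raises(GroupingError):
            site_degree(table)


class TestProteinEpo:
    def test_hand_summation(self):
        table = make_rows(
            [
                ("P1", "AAAAAAA", 1, 7, "none", "M5", 1, 8e6, 10),
                ("P1", "AAAAAAA", 1, 7, "ox:3", "M5", 1, 2e6, 2),
                ("P1", "CCCCCCC", 8, 14, "none", "M5", 1, 1e7, 12),
            ]
        )
        assert protein_epo(table) == pytest.approx(0.10)

    def test_all_unmodified_zero(self):
        table = make_rows([("P1", "AAAAAAA", 1, 7, "none", "M5", 1, 1e6, 5)])
        assert protein_epo(table) == 0.0

    def test_all_oxidized_one(self):
        table = make_rows([("P1", "AAAAAAA", 1, 7, "ox:2", "M5", 1, 1e6, 5)])
        assert protein_epo(table) == 1.0

    def test_zero_total_intensity_sentinel(self):
        table = make_rows([("P1", "AAAAAAA", 1, 7, "none", "M5", 1, 0.0, 3)])
        assert np.isnan(protein_epo(table))

    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_oracle(self, seed):
        table = random_peptide_table(np.random.default_rng(seed))
        expected = brute_force_epo(table)
        profiles = epo_table(table)
        got = float(profiles.loc[0, "epo"])
        assert got == pytest.approx(expected, rel=1e-12)
        assert 0.0 <= got <= 1.0

    @given(seed=st.integers(0, 10_000))
    def test_epo_is_weighted_mean_of_peptide_fractions(self, seed):
        """EPO lies between the min and max per-peptide oxidized fractions."""
        table = random_peptide_table(np.random.default_rng(seed))
        fractions = [
            g.loc[g["mod"] != "none", "intensity"].sum() / g["intensity"].sum()
            for _, g in table.groupby("peptide")
            if g["intensity"].sum() > 0
        ]
        epo = float(epo_table(table).loc[0, "epo"])
        assert min(fractions) - 1e-12 <= epo <= max(fractions) + 1e-12


class TestNormalization:
    def test_hand_division(self):
        profiles = pd.DataFrame(
            {"protein_id": ["P1", "P1"], "condition": ["M5", "C1"], "epo": [0.2, 0.05]}
        )
        out = normalize_epo(profiles)
        assert out["epo_norm"].tolist() == pytest.approx([1.0, 0.25])

    def test_single_condition_is_one(self):
        out = normalize_epo(
            pd.DataFrame({"protein_id": ["P1"], "condition": ["M5"], "epo": [0.07]})
        )
        assert out["epo_norm"].tolist() == [1.0]

    def test_all_zero_protein_stays_zero(self):
        out = normalize_epo(
            pd.DataFrame({"protein_id": ["P1", "P1"], "condition": ["M5", "C1"], "epo": [0.0, 0.0]})
        )
        assert out["epo_norm"].tolist() == [0.0, 0.0]

    def test_max_is_one_whenever_any_positive(self, measurements):
        profiles = normalize_epo(epo_table(measurements))
        peak = profiles.groupby("protein_id")["epo_norm"].max()
        positive = profiles.groupby("protein_id")["epo"].max() > 0
        assert np.allclose(peak[positive], 1.0)
        assert profiles["epo_norm"].between(0, 1).all()


class TestFoldChange:
    def _profiles(self, treat, ctrl):
        return pd.DataFrame(
            {
                "protein_id": ["P1"] * 4,
                "condition": ["M5", "C1", "C2", "C3"],
                "epo": [treat, *ctrl],
            }
        )

    def test_hand_division(self):
        out = epo_fold_change(self._profiles(0.15, [0.05, 0.05, 0.05]), ["C1", "C2", "C3"])
        assert out.loc[out["condition"] == "M5", "epo_fc"].iloc[0] == pytest.approx(3.0)

    def test_equal_means_unity(self):
        out = epo_fold_change(self._profiles(0.05, [0.05, 0.05, 0.05]), ["C1", "C2", "C3"])
        assert out.loc[out["condition"] == "M5", "epo_fc"].iloc[0] == pytest.approx(1.0)

    def test_zero_controls_hit_floor_and_flag(self):
        out = epo_fold_change(self._profiles(0.1, [0.0, 0.0, 0.0]), ["C1", "C2", "C3"])
        row = out[out["condition"] == "M5"].iloc[0]
        assert row["epo_fc"] == pytest.approx(0.1 / 1e-4)
        assert bool(row["fc_capped"])

    def test_no_control_data_sentinel(self):
        profiles = pd.DataFrame({"protein_id": ["P1"], "condition": ["M5"], "epo": [0.1]})
        out = epo_fold_change(profiles, ["C1"])
        assert np.isnan(out["epo_fc"].iloc[0])


class TestSiteCounts:
    def test_distinct_positions(self):
        table = make_rows(
            [
                ("P1", "AAAAAAA", 1, 7, "none", "M5", 1, 1e6, 5),
                ("P1", "AAAAAAA", 1, 7, "ox:3", "M5", 1, 1e5, 1),
                ("P1", "AAAAAAA", 1, 7, "ox:3", "M5", 2, 2e5, 1),
                ("P1", "CCCCCCC", 50, 56, "none", "M5", 1, 1e6, 5),
                ("P1", "CCCCCCC", 50, 56, "ox:57", "M5", 1, 1e5, 1),
            ]
        )
        assert count_sites(table, "P1", "M5") == 2

    def test_no_oxidation_zero(self):
        table = make_rows([("P1", "AAAAAAA", 1, 7, "none", "M5", 1, 1e6, 5)])
        assert count_sites(table, "P1", "M5") == 0

    @given(seed=st.integers(0, 10_000))
    def test_matches_site_enumeration(self, seed):
        table = random_peptide_table(np.random.default_rng(seed))
        oracle = brute_force_degrees(table)
        got = site_table(table)
        got_map = {
            (r.protein_id, r.position): r.degree for r in got.itertuples(index=False)
        }
        assert set(got_map) == set(oracle)
        for key, degree in oracle.items():
            assert got_map[key] == pytest.approx(degree, rel=1e-12)
            assert 0.0 <= got_map[key] <= 1.0


class TestClustering:
    def test_identical_conditions_are_adjacent_at_zero_distance(self):
        profiles = pd.DataFrame(
            {
                "protein_id": ["P1", "P2", "P3"] * 3,
                "condition": ["A"] * 3 + ["B"] * 3 + ["Z"] * 3,
                "epo": [0.1, 0.2, 0.3, 0.1, 0.2, 0.3, 0.9, 0.1, 0.5],
            }
        )
        mat, order, _ = condition_matrix_and_clustering(profiles)
        dist = correlation_distance_matrix(mat)
        assert dist.loc["A", "B"] == pytest.approx(0.0, abs=1e-12)
        assert abs(order.index("A") - order.index("B")) == 1

    def test_anticorrelated_conditions_maximal_distance(self):
        mat = pd.DataFrame(
            [[0.1, 0.5, 0.9], [0.9, 0.5, 0.1]], index=["A", "B"], columns=["P1", "P2", "P3"]
        )
        dist = correlation_distance_matrix(mat)
        assert dist.loc["A", "B"] == pytest.approx(2.0)

    def test_average_linkage_matches_hand_agglomeration(self):
        """4 conditions with a fixed EPO matrix: scipy's tree equals the
        manual average-linkage agglomeration of the 4x4 distance matrix."""
        mat = pd.DataFrame(
            [
                [0.10, 0.20, 0.30, 0.40],
                [0.11, 0.21, 0.29, 0.41],
                [0.40, 0.10, 0.20, 0.05],
                [0.05, 0.50, 0.01, 0.30],
            ],
            index=["A", "B", "C", "D"],
            columns=["P1", "P2", "P3", "P4"],
        )
        profiles = mat.reset_index().melt(
            id_vars="index", var_name="protein_id", value_name="epo"
        ).rename(columns={"index": "condition"})
        _, order, linkage = condition_matrix_and_clustering(profiles)

        # manual agglomeration on the same distance matrix
        d = correlation_distance_matrix(mat)
        clusters = {i: [c] for i, c in enumerate(mat.index)}
        heights = []
        pair_dist = {
            frozenset((i, j)): d.iloc[i, j] for i in range(4) for j in range(i + 1, 4)
        }
        next_id = 4
        while len(clusters) > 1:
            best = min(
                (
                    (np.mean([d.loc[a, b] for a in clusters[i] for b in clusters[j]]), i, j)
                    for i in clusters
                    for j in clusters
                    if i < j
                ),
            )
            height, i, j = best
            heights.append(height)
            clusters[next_id] = clusters.pop(i) + clusters.pop(j)
            next_id += 1
        assert np.allclose(sorted(linkage[:, 2]), sorted(heights))
        assert set(order) == set(mat.index)


class TestSignificance:
    def test_single_replicate_sentinel(self):
        reps = pd.DataFrame(
            {
                "protein_id": ["P1"] * 4,
                "condition": ["M5", "C1", "C1", "C1"],
                "replicate": [1, 1, 2, 3],
                "epo": [0.5, 0.1, 0.12, 0.09],
            }
        )
        out = epo_vs_controls(reps, "M5", ["C1"])
        assert np.isnan(out["p_value"].iloc[0])

    def test_large_shift_highly_significant(self):
        rng = np.random.default_rng(0)
        rows = []
        for rep in range(1, 4):
            rows.append(("P1", "M5", rep, 0.5 + rng.normal(0, 0.01)))
        for cond in ("C1", "C2", "C3"):
            for rep in range(1, 4):
                rows.append(("P1", cond, rep, 0.1 + rng.normal(0, 0.01)))
        reps = pd.DataFrame(rows, columns=["protein_id", "condition", "replicate", "epo"])
        out = epo_vs_controls(reps, "M5", ["C1", "C2", "C3"])
        assert out["p_value"].iloc[0] < 0.001

    def test_null_p_values_approximately_uniform(self):
        """Treatment identical to controls: type-I error near the nominal level."""
        rng = np.random.default_rng(1)
        rows = []
        for pid in range(500):
            for cond in ("M5", "C1", "C2", "C3"):
                for rep in range(1, 4):
                    rows.append((f"P{pid}", cond, rep, rng.normal(0.1, 0.02)))
        reps = pd.DataFrame(rows, columns=["protein_id", "condition", "replicate", "epo"])
        out = epo_vs_controls(reps, "M5", ["C1", "C2", "C3"])
        frac = float((out["p_value"] < 0.05).mean())
        assert 0.02 <= frac <= 0.09


class TestRegionMapping:
    def _sites(self):
        return pd.DataFrame(
            {
                "protein_id": ["P1", "P1", "P1"],
                "position": [100, 60, 300],
                "condition": ["M5"] * 3,
                "degree": [0.2, 0.1, 0.3],
            }
        )

    def test_containment_and_unassigned(self):
        regions = pd.DataFrame(
            {"protein_id": ["P1"], "region_name": ["extracellular"], "start": [50], "end": [150]}
        )
        out = map_sites_to_regions(self._sites(), regions)
        extr = out[out["region_name"] == "extracellular"].iloc[0]
        assert extr["n_sites"] == 2
        assert extr["degree_sum"] == pytest.approx(0.3)
        unassigned = out[out["region_name"] == "unassigned"].iloc[0]
        assert unassigned["n_sites"] == 1

    def test_overlapping_regions_count_site_in_both(self):
        regions = pd.DataFrame(
            {
                "protein_id": ["P1", "P1"],
                "region_name": ["domain1", "domain2"],
                "start": [50, 90],
                "end": [120, 150],
            }
        )
        out = map_sites_to_regions(self._sites(), regions)
        by_region = out.set_index("region_name")["n_sites"]
        assert by_region["domain1"] == 2  # sites 60, 100
        assert by_region["domain2"] == 1  # site 100

    def test_no_annotations_all_unassigned(self):
        out = map_sites_to_regions(self._sites(), None)
        assert out["region_name"].unique().tolist() == ["unassigned"]
        assert out["n_sites"].sum() == 3
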