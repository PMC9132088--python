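"""Reference synthetic experiments and their recovery metrics.

These helpers run the complete pipeline on the package's reference
simulation conditions (200 proteins, 10 proximal partners at 8x proximity
enrichment, 3 replicates, half of the true partners present in the
known-interaction list) and measure how well the interactor calls recover
the simulated ground truth.  They back both the test suite and the
reproduction script.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import pandas as pd

from . import classify, oxidation, scoring
from .synthetic_data import (
    ExperimentDesign,
    GroundTruth,
    SimulationParams,
    assign_ground_truth,
    generate_proteome,
    simulate_experiment,
    simulate_string_edges,
)


@dataclass
class ExperimentRun:
    truth: GroundTruth
    design: ExperimentDesign
    measurements: pd.DataFrame
    profiles: pd.DataFrame
    scores: pd.Series
    results: pd.DataFrame
    edges: pd.DataFrame


def run_reference_experiment(
    seed: int,
    params: SimulationParams | None = None,
    design: ExperimentDesign | None = None,
    overlap_fraction: float = 0.5,
    truth: GroundTruth | None = None,
) -> ExperimentRun:
    """Simulate one labeling experiment and push it through the whole pipeline."""
    params = dataclasses.replace(params or SimulationParams(), seed=seed)
    design = design or ExperimentDesign()
    proteome = generate_proteome(params)
    if truth is None:
        truth = assign_ground_truth(proteome, params)
    measurements = simulate_experiment(proteome, truth, design, params)
    profiles = oxidation.protein_profiles(measurements, design)
    matrix = scoring.build_score_matrix(profiles)
    scores = scoring.aapl_scores(scoring.tops(matrix), design.selected_condition)
    edges = simulate_string_edges(truth, overlap_fraction, n_decoy_edges=100, seed=seed)
    results = classify.build_results(
        scores, profiles, edges, truth.bait_id, design.selected_condition
    )
    return ExperimentRun(truth, design, measurements, profiles, scores, results, edges)


def recovery_metrics(run: ExperimentRun) -> dict[str, float]:
    """Sensitivity / false-call rate of L1∪L2 calls and the score's rank AUC
    for truly proximal versus background proteins."""
    truth = run.truth
    classes = pd.Series(truth.proximity)
    merged = run.results.set_index("protein_id").join(classes.rename("class"), how="left")
    called = merged["level"].isin(["L1", "L2"])
    proximal = merged["class"] == "proximal"
    background = merged["class"] == "background"
    # denominators count all simulated proteins, including any that dropped
    # out of the score matrix (an uncalled protein either way)
    n_proximal_total = len(truth.members("proximal"))
    n_background_total = len(truth.members("background"))
    sensitivity = float(called[proximal].sum() / n_proximal_total)
    false_rate = float(called[background].sum() / n_background_total)

    pos = merged.loc[proximal, "aapl_score"].to_numpy()
    neg = merged.loc[background, "aapl_score"].to_numpy()
    if len(pos) and len(neg):
        greater = (pos[:, None] > neg[None, :]).sum() + 0.5 * (
            pos[:, None] == neg[None, :]
        ).sum()
        auc = float(greater / (len(pos) * len(neg)))
    else:
        auc = float("nan")
    return {"sensitivity": sensitivity, "false_call_rate": false_rate, "auc": auc}


def cross_reactivity_null(seed: int, params: SimulationParams | None = None) -> dict:
    """Two antibodies with disjoint proximity sets: how the first bait behaves
    in the second antibody's experiment (it should look like background)."""
    params = dataclasses.replace(params or SimulationParams(), seed=seed)
    proteome = generate_proteome(params)
    truth_a = assign_ground_truth(proteome, params)
    members_a = set(truth_a.members("proximal")) | {truth_a.bait_id}
    truth_b = assign_ground_truth(proteome, params, exclude=members_a, salt=7)
    run_b = run_reference_experiment(seed, params=params, truth=truth_b)
    return classify.cross_reactivity_report(run_b.results, truth_a.bait_id)


def null_calibration(seed: int, n_proteins: int = 1000) -> dict[str, float]:
    """Pure-null experiment (enrichment 1 everywhere): significance and score
    calibration across proteins."""
    params = SimulationParams(
        seed=seed, n_proteins=n_proteins, enrichment_bait=1.0, enrichment_proximal=1.0
    )
    design = ExperimentDesign()
    proteome = generate_proteome(params)
    truth = assign_ground_truth(proteome, params)
    measurements = simulate_experiment(proteome, truth, design, params)
    profiles = oxidation.protein_profiles(measurements, design)
    selected = profiles[profiles["condition"] == design.selected_condition]
    tested = selected.dropna(subset=["p_value"])
    matrix = scoring.build_score_matrix(profiles)
    scores = scoring.aapl_scores(scoring.tops(matrix), design.selected_condition)
    return {
        "n_tested": float(len(tested)),
        "frac_p_below_0.05": float((tested["p_value"] < 0.05).mean()),
        "frac_q_below_0.05": float((tested["q_value"] < 0.05).mean()),
        "frac_score_above_1": float((scores > 1).mean()),
    }
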