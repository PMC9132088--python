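"""Ground-truthed synthetic proximity-labeling experiments.

Emulates an antibody-directed oxidation experiment end to end: a small
proteome, tryptic digestion, proximity-dependent hydroxyl-radical oxidation
of the bait protein and its neighbors over a uniform background, replicate
intensity/spectral-count noise, control conditions without catalysis, and a
partially overlapping known-interaction edge list.  Everything is
deterministic given a seed, so the whole downstream pipeline can be tested
against known ground truth at desk scale.

The oxidation model: every residue r of a protein p carries a per-condition
mono-oxidation stoichiometry with expectation

    pi(r, p, c) = p_background * residue_weight(r) * enrichment(p, c)

where enrichment(p, c) > 1 only for the bait and its proximal partners and
only in treatment conditions; controls use multiplier 1 everywhere.  The
realized stoichiometry is drawn as Binomial(n_copies, pi) / n_copies so its
expectation is exactly pi while small peptide pools produce zero-oxidation
dropout.  The base peptide intensity is lognormal, split exactly between the
unmodified and oxidized peptidoforms by the realized stoichiometries, and
spectral counts are Poisson with mean proportional to intensity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import PEPTIDE_COLUMNS, UNMODIFIED, mod_token

logger = logging.getLogger(__name__)

#: Amino-acid frequencies used to draw synthetic protein sequences
#: (rounded human proteome composition).
RESIDUE_FREQUENCIES: dict[str, float] = {
    "A": 0.070, "R": 0.056, "N": 0.036, "D": 0.047, "C": 0.023,
    "Q": 0.048, "E": 0.071, "G": 0.066, "H": 0.026, "I": 0.043,
    "L": 0.100, "K": 0.057, "M": 0.021, "F": 0.037, "P": 0.063,
    "S": 0.083, "T": 0.054, "W": 0.011, "Y": 0.027, "V": 0.060,
}

#: Relative hydroxyl-radical susceptibility per residue.  Sulfur-containing
#: and aromatic side chains dominate; everything else gets a small nonzero
#: weight so backbone/aliphatic oxidation is represented but rare.
DEFAULT_RESIDUE_WEIGHTS: dict[str, float] = {
    "M": 5.0, "C": 3.0, "W": 3.0, "Y": 2.0, "F": 1.0, "H": 1.0,
    **{aa: 0.1 for aa in "ARNDQEGILKPSTV"},
}

PROXIMITY_CLASSES = ("bait", "proximal", "background")

#: Relative labeling efficiency of the default treatment conditions.  The
#: treatment series emulates an optimization of the probe chemistry: the
#: proximity enrichment only develops fully in the best condition (M5),
#: partially in the others, exactly like a condition screen where one
#: condition yields the highest extent of oxidation.  Conditions absent
#: from the map run at full efficiency.
DEFAULT_CONDITION_EFFICIENCY: dict[str, float] = {
    "M1": 0.25, "M2": 0.40, "M3": 0.30, "M4": 0.60, "M5": 1.00, "M6": 0.80,
}


class SimulationError(ValueError):
    """Invalid simulation parameters or inconsistent design/ground-truth inputs."""


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 30:
            raise ValueError(f"{self.protein_id}: sequence shorter than 30 residues")


@dataclass(frozen=True)
class GroundTruth:
    """Which proteins are near the antibody-bound bait, and how oxidizable that makes them."""

    bait_id: str
    proximity: dict[str, str]
    oxidation_enrichment: dict[str, float]

    def __post_init__(self) -> None:
        if self.bait_id not in self.proximity:
            raise ValueError("bait_id missing from proximity map")
        for pid, cls in self.proximity.items():
            if cls not in PROXIMITY_CLASSES:
                raise ValueError(f"{pid}: unknown proximity class {cls!r}")
            mult = self.oxidation_enrichment.get(pid)
            if mult is None:
                raise ValueError(f"{pid}: missing enrichment multiplier")
            if cls == "background" and mult != 1.0:
                raise ValueError(f"{pid}: background enrichment must be 1, got {mult}")
            if mult < 1.0:
                raise ValueError(f"{pid}: enrichment multiplier must be >= 1")
        bait_mult = self.oxidation_enrichment[self.bait_id]
        for pid, cls in self.proximity.items():
            if cls == "proximal" and self.oxidation_enrichment[pid] > bait_mult:
                raise ValueError("proximal enrichment exceeds bait enrichment")

    def members(self, cls: str) -> list[str]:
        return sorted(p for p, c in self.proximity.items() if c == cls)


@dataclass(frozen=True)
class ExperimentDesign:
    """Treatment/control condition layout of one labeling experiment."""

    treatment_conditions: tuple[str, ...] = ("M1", "M2", "M3", "M4", "M5", "M6")
    control_conditions: tuple[str, ...] = ("C1", "C2", "C3")
    selected_condition: str = "M5"
    replicates: int = 3

    def __post_init__(self) -> None:
        all_conditions = tuple(self.treatment_conditions) + tuple(self.control_conditions)
        if len(set(all_conditions)) != len(all_conditions):
            raise ValueError("condition ids must be unique across treatments and controls")
        if self.selected_condition not in self.treatment_conditions:
            raise ValueError(
                f"selected_condition {self.selected_condition!r} not a treatment condition"
            )
        if self.replicates < 2:
            raise ValueError("at least 2 replicates required")

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.treatment_conditions) + tuple(self.control_conditions)


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic experiment; defaults are the package's reference conditions."""

    n_proteins: int = 200
    n_proximal: int = 10
    p_background: float = 0.003
    enrichment_bait: float = 8.0
    enrichment_proximal: float = 8.0
    residue_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RESIDUE_WEIGHTS)
    )
    condition_efficiency: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_EFFICIENCY)
    )
    intensity_log_mean: float = 14.0
    intensity_log_sd: float = 1.0
    replicate_log_sd: float = 0.2
    spc_per_intensity: float = 1e-5
    missed_cleavages: int = 0
    n_copies: int = 50
    min_protein_length: int = 120
    max_protein_length: int = 360
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 2:
            raise SimulationError("n_proteins must be >= 2")
        if not 0 <= self.n_proximal < self.n_proteins:
            raise SimulationError("n_proximal must be in [0, n_proteins)")
        if not 0 <= self.p_background < 1:
            raise SimulationError("p_background must be in [0, 1)")
        if self.enrichment_bait < 1 or self.enrichment_proximal < 1:
            raise SimulationError("enrichment multipliers must be >= 1")
        if self.enrichment_proximal > self.enrichment_bait:
            raise SimulationError("proximal enrichment must not exceed bait enrichment")
        if min(self.residue_weights.values(), default=0.0) < 0:
            raise SimulationError("residue weights must be non-negative")
        wmax = max(self.residue_weights.values(), default=0.0)
        if self.p_background * wmax * self.enrichment_bait > 1:
            raise SimulationError(
                "p_background * max(residue_weights) * enrichment_bait exceeds 1; "
                "the per-residue oxidation probability would leave [0, 1]"
            )
        if self.missed_cleavages < 0 or self.n_copies < 1:
            raise SimulationError("counts must be positive")
        for cond, eff in self.condition_efficiency.items():
            if not 0.0 < eff <= 1.0:
                raise SimulationError(
                    f"condition_efficiency[{cond!r}] must lie in (0, 1], got {eff}"
                )
        if self.spc_per_intensity <= 0 or self.intensity_log_sd < 0:
            raise SimulationError("intensity/spectral-count parameters must be positive")
        if not 30 <= self.min_protein_length <= self.max_protein_length:
            raise SimulationError("protein length range invalid (min >= 30 required)")


def generate_proteome(params: SimulationParams) -> list[ProteinRecord]:
    """Draw ``n_proteins`` random sequences from the fixed residue frequency table."""
    rng = np.random.default_rng(params.seed)
    residues = np.array(list(RESIDUE_FREQUENCIES))
    probs = np.array(list(RESIDUE_FREQUENCIES.values()))
    probs = probs / probs.sum()
    width = len(str(params.n_proteins))
    proteome = []
    for i in range(params.n_proteins):
        length = int(
            rng.integers(params.min_protein_length, params.max_protein_length + 1)
        )
        seq = "".join(rng.choice(residues, size=length, p=probs))
        proteome.append(ProteinRecord(f"P{i + 1:0{width}d}", seq))
    return proteome


def assign_ground_truth(
    proteome: list[ProteinRecord],
    params: SimulationParams,
    exclude: set[str] | None = None,
    salt: int = 0,
) -> GroundTruth:
    """Pick a bait and ``n_proximal`` neighbors at random; everything else is background.

    ``exclude`` keeps the listed proteins out of the bait/proximal draw —
    use it with a nonzero ``salt`` to build a second antibody's ground
    truth with a proximity set disjoint from the first.
    """
    rng = np.random.default_rng(params.seed + 101 + salt)
    ids = [p.protein_id for p in proteome]
    eligible = [i for i, pid in enumerate(ids) if pid not in (exclude or set())]
    if len(eligible) < params.n_proximal + 1:
        raise SimulationError("not enough proteins left to draw a bait and proximal set")
    chosen = rng.choice(eligible, size=params.n_proximal + 1, replace=False)
    bait = ids[chosen[0]]
    proximal = {ids[i] for i in chosen[1:]}
    proximity = {}
    enrichment = {}
    for pid in ids:
        if pid == bait:
            proximity[pid] = "bait"
            enrichment[pid] = params.enrichment_bait
        elif pid in proximal:
            proximity[pid] = "proximal"
            enrichment[pid] = params.enrichment_proximal
        else:
            proximity[pid] = "background"
            enrichment[pid] = 1.0
    return GroundTruth(bait_id=bait, proximity=proximity, oxidation_enrichment=enrichment)


def digest_protein(
    record: ProteinRecord,
    missed_cleavages: int = 0,
    min_length: int = 6,
    max_length: int = 50,
) -> list[tuple[str, int, int]]:
    """In-silico tryptic digestion: cleave C-terminal to K/R except before P.

    Returns ``(peptide, start, end)`` with 1-based inclusive protein
    coordinates: all fully cleaved peptides plus products with up to
    ``missed_cleavages`` missed sites, filtered to the detectability window
    ``min_length``..``max_length``.
    """
    seq = record.sequence
    if not seq:
        raise ValueError("empty sequence")
    # fully cleaved fragment boundaries (0-based half-open)
    cut_after = [
        i for i in range(len(seq) - 1) if seq[i] in "KR" and seq[i + 1] != "P"
    ]
    bounds = [0] + [c + 1 for c in cut_after] + [len(seq)]
    fragments = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]
    peptides = []
    for i in range(len(fragments)):
        for mc in range(missed_cleavages + 1):
            if i + mc >= len(fragments):
                break
            lo = fragments[i][0]
            hi = fragments[i + mc][1]
            if min_length <= hi - lo <= max_length:
                peptides.append((seq[lo:hi], lo + 1, hi))
    return peptides


def _check_consistency(
    proteome: list[ProteinRecord], truth: GroundTruth, design: ExperimentDesign
) -> None:
    missing = [p.protein_id for p in proteome if p.protein_id not in truth.proximity]
    if missing:
        raise SimulationError(
            f"ground truth does not cover {len(missing)} proteins (e.g. {missing[0]})"
        )
    if truth.bait_id not in {p.protein_id for p in proteome}:
        raise SimulationError(f"bait {truth.bait_id!r} absent from proteome")


def simulate_experiment(
    proteome: list[ProteinRecord],
    truth: GroundTruth,
    design: ExperimentDesign,
    params: SimulationParams,
    enrichment_overrides: dict[str, dict[str, float]] | None = None,
) -> pd.DataFrame:
    """Simulate the full peptide quantification table of one labeling experiment.

    One unmodified row is emitted for every peptide x condition x replicate;
    whenever a residue's realized oxidation stoichiometry is nonzero, one row
    per oxidized peptidoform is added and the base intensity is split exactly
    between the forms (intensities are conserved).

    ``enrichment_overrides`` maps a treatment condition id to per-protein
    multipliers replacing the ground-truth enrichment in that condition —
    used to emulate perturbations (e.g. glycosylation inhibitors) that
    weaken specific interactions.
    """
    _check_consistency(proteome, truth, design)
    if enrichment_overrides:
        unknown = set(enrichment_overrides) - set(design.treatment_conditions)
        if unknown:
            raise SimulationError(f"override for non-treatment conditions: {sorted(unknown)}")
    rng = np.random.default_rng(params.seed + 202)
    weights = params.residue_weights
    conditions = list(design.conditions)
    n_cond = len(conditions)
    n_rep = design.replicates
    treatment = set(design.treatment_conditions)

    cols: dict[str, list] = {c: [] for c in PEPTIDE_COLUMNS}

    for record in proteome:
        pid = record.protein_id
        base_mult = truth.oxidation_enrichment[pid]
        # per-condition enrichment multiplier for this protein; the
        # labeling-efficiency profile scales the proximity-dependent excess
        # (mult - 1), never the background floor of 1
        enr = np.ones(n_cond)
        for j, cond in enumerate(conditions):
            if cond in treatment:
                if enrichment_overrides and cond in enrichment_overrides:
                    mult = enrichment_overrides[cond].get(pid, base_mult)
                else:
                    mult = base_mult
                eff = params.condition_efficiency.get(cond, 1.0)
                enr[j] = 1.0 + (mult - 1.0) * eff
        peptides = digest_protein(record, params.missed_cleavages)
        for pep, start, end in peptides:
            w = np.array([weights.get(aa, 0.0) for aa in pep])
            ox_idx = np.nonzero(w > 0)[0]
            # expected stoichiometry per oxidizable residue x condition
            pi = np.clip(params.p_background * np.outer(w[ox_idx], enr), 0.0, 1.0)
            # realized stoichiometry per residue x condition x replicate
            f = (
                rng.binomial(params.n_copies, pi[:, :, None], size=(len(ox_idx), n_cond, n_rep))
                / params.n_copies
            )
            total = f.sum(axis=0)
            over = total > 1.0
            if over.any():  # tiny peptide pools can over-commit; renormalize
                f[:, over] /= total[over]
                total = np.minimum(total, 1.0)
            log_base = rng.normal(params.intensity_log_mean, params.intensity_log_sd)
            base = np.exp(
                log_base + rng.normal(0.0, params.replicate_log_sd, size=(n_cond, n_rep))
            )
            unmod = base * (1.0 - total)
            spc_unmod = rng.poisson(params.spc_per_intensity * unmod)
            for j, cond in enumerate(conditions):
                for r in range(n_rep):
                    cols["protein_id"].append(pid)
                    cols["peptide"].append(pep)
                    cols["start"].append(start)
                    cols["end"].append(end)
                    cols["mod"].append(UNMODIFIED)
                    cols["condition"].append(cond)
                    cols["replicate"].append(r + 1)
                    cols["intensity"].append(unmod[j, r])
                    cols["spectral_count"].append(int(spc_unmod[j, r]))
            hit_res, hit_cond, hit_rep = np.nonzero(f > 0)
            if hit_res.size:
                ox_int = base[hit_cond, hit_rep] * f[hit_res, hit_cond, hit_rep]
                spc_ox = rng.poisson(params.spc_per_intensity * ox_int)
                for k in range(hit_res.size):
                    pos = start + int(ox_idx[hit_res[k]])
                    cols["protein_id"].append(pid)
                    cols["peptide"].append(pep)
                    cols["start"].append(start)
                    cols["end"].append(end)
                    cols["mod"].append(mod_token(pos))
                    cols["condition"].append(conditions[hit_cond[k]])
                    cols["replicate"].append(int(hit_rep[k]) + 1)
                    cols["intensity"].append(float(ox_int[k]))
                    cols["spectral_count"].append(int(spc_ox[k]))

    table = pd.DataFrame(cols)
    table["start"] = table["start"].astype("int64")
    table["end"] = table["end"].astype("int64")
    table["replicate"] = table["replicate"].astype("int64")
    table["spectral_count"] = table["spectral_count"].astype("int64")
    logger.info(
        "simulated %d rows (%d oxidized) for %d proteins",
        len(table),
        int((table["mod"] != UNMODIFIED).sum()),
        len(proteome),
    )
    return table


def simulate_string_edges(
    truth: GroundTruth,
    overlap_fraction: float = 0.5,
    n_decoy_edges: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Known-interaction edge list partially overlapping the true proximity set.

    ``round(overlap_fraction * n_proximal)`` proximal proteins get a direct
    bait edge (combined score uniform in [0.4, 1.0]); decoy edges connect
    random background pairs.  No self edges or duplicate pairs.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed + 303)
    proximal = truth.members("proximal")
    background = truth.members("background")
    n_bait_edges = round(overlap_fraction * len(proximal))
    linked = rng.choice(len(proximal), size=n_bait_edges, replace=False) if n_bait_edges else []
    rows = []
    seen = set()
    for i in sorted(int(x) for x in linked):
        pid = proximal[i]
        pair = tuple(sorted((truth.bait_id, pid)))
        seen.add(pair)
        rows.append((pair[0], pair[1], float(rng.uniform(0.4, 1.0))))
    attempts = 0
    while len(rows) < n_bait_edges + n_decoy_edges and attempts < 50 * n_decoy_edges:
        attempts += 1
        if len(background) < 2:
            break
        i, j = rng.choice(len(background), size=2, replace=False)
        pair = tuple(sorted((background[int(i)], background[int(j)])))
        if pair in seen:
            continue
        seen.add(pair)
        rows.append((pair[0], pair[1], float(rng.uniform(0.4, 1.0))))
    return pd.DataFrame(rows, columns=["protein_a", "protein_b", "combined_score"])


#: Representative N-glycan compositions (Hex, HexNAc, Fuc, NeuAc) per glycan type.
_GLYCAN_COMPOSITIONS = {
    "HM": [(5, 2, 0, 0), (6, 2, 0, 0), (9, 2, 0, 0)],
    "CH": [(5, 4, 0, 0), (4, 4, 0, 0)],
    "F": [(5, 4, 1, 0), (4, 4, 2, 0)],
    "S": [(5, 4, 0, 1), (5, 4, 0, 2)],
    "FS": [(5, 4, 1, 1), (5, 4, 1, 2)],
}


def simulate_glycopeptides(
    proteome: list[ProteinRecord],
    glyco_profiles: dict[str, dict[str, float]],
    n_sites: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic glycopeptide table for proteins with a given glycan-type intensity profile.

    ``glyco_profiles`` maps protein_id -> {glycan type -> relative intensity
    share}; each listed protein gets ``n_sites`` glycosites carrying
    compositions drawn from a canonical composition list for each type.
    """
    rng = np.random.default_rng(seed + 404)
    lengths = {p.protein_id: len(p.sequence) for p in proteome}
    rows = []
    for pid, profile in sorted(glyco_profiles.items()):
        if pid not in lengths:
            raise ValueError(f"{pid!r} absent from proteome")
        sites = sorted(
            int(s) + 1 for s in rng.choice(lengths[pid], size=n_sites, replace=False)
        )
        total = sum(profile.values())
        for site in sites:
            for gtype, share in sorted(profile.items()):
                if share <= 0:
                    continue
                comps = _GLYCAN_COMPOSITIONS[gtype]
                h, n, fu, s = comps[int(rng.integers(len(comps)))]
                intensity = 1e6 * (share / total) * float(rng.lognormal(0.0, 0.2))
                rows.append((pid, site, h, n, fu, s, intensity))
    return pd.DataFrame(
        rows,
        columns=["protein_id", "site", "hex", "hexnac", "fuc", "neuac", "intensity"],
    )


def ground_truth_table(truth: GroundTruth) -> pd.DataFrame:
    """Ground truth as a tidy table (protein_id, class, enrichment)."""
    rows = [
        (pid, truth.proximity[pid], truth.oxidation_enrichment[pid])
        for pid in sorted(truth.proximity)
    ]
    return pd.DataFrame(rows, columns=["protein_id", "class", "enrichment"])
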