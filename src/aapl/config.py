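"""Declarative pipeline configuration (YAML).

A config file is a nested mapping with sections ``design``, ``thresholds``,
``scoring``, ``simulation`` and ``inputs``; every field has a default, so
the minimal valid config is an empty file.  ``validate_config`` collects
all problems instead of failing on the first.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .classify import ClassificationThresholds
from .synthetic_data import ExperimentDesign, SimulationError, SimulationParams


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "aapl_results"
    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    thresholds: ClassificationThresholds = field(default_factory=ClassificationThresholds)
    scoring_mode: str = "spc_times_epo"
    rescale_total: float | None = None
    score_floor: float = 0.4
    string_overlap_fraction: float = 0.5
    n_decoy_edges: int = 100
    simulation: SimulationParams = field(default_factory=SimulationParams)
    peptide_table: str | None = None
    string_links: str | None = None
    fasta: str | None = None
    regions: str | None = None
    glyco_table: str | None = None
    bait_id: str | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["design"]["treatment_conditions"] = list(self.design.treatment_conditions)
        d["design"]["control_conditions"] = list(self.design.control_conditions)
        return d

    def dump(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _build(section: dict, cls, errors: list[str], label: str):
    try:
        return cls(**section)
    except (TypeError, ValueError, SimulationError) as exc:
        errors.append(f"{label}: {exc}")
        return None


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate; raises ValueError listing every problem found."""
    config, errors = validate_config(path)
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    assert config is not None
    return config


def validate_config(path: str | Path) -> tuple[PipelineConfig | None, list[str]]:
    """Parse a YAML config, fill defaults, and collect (not raise) validation errors.

    Returns ``(config, errors)``; config is None only when the document
    cannot be interpreted at all.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        return None, ["config root must be a mapping"]
    errors: list[str] = []
    known = {
        "seed", "out_dir", "design", "thresholds", "scoring_mode", "rescale_total",
        "score_floor", "string_overlap_fraction", "n_decoy_edges", "simulation",
        "peptide_table", "string_links", "fasta", "regions", "glyco_table", "bait_id",
    }
    for key in raw:
        if key not in known:
            errors.append(f"unknown config key {key!r}")

    design_raw = dict(raw.get("design") or {})
    for key in ("treatment_conditions", "control_conditions"):
        if key in design_raw:
            design_raw[key] = tuple(design_raw[key])
    design = _build(design_raw, ExperimentDesign, errors, "design")
    thresholds = _build(dict(raw.get("thresholds") or {}), ClassificationThresholds, errors, "thresholds")
    simulation = _build(dict(raw.get("simulation") or {}), SimulationParams, errors, "simulation")
    if thresholds is not None:
        for name in ("l1_score", "l2_fc", "string_high", "string_low"):
            if getattr(thresholds, name) <= 0:
                errors.append(f"thresholds.{name} must be positive")

    scalars = {
        k: raw[k]
        for k in (
            "seed", "out_dir", "scoring_mode", "rescale_total", "score_floor",
            "string_overlap_fraction", "n_decoy_edges", "peptide_table",
            "string_links", "fasta", "regions", "glyco_table", "bait_id",
        )
        if k in raw
    }
    if scalars.get("scoring_mode") not in (None, "spc_times_epo", "spc_only", "tops_times_epo"):
        errors.append(f"unknown scoring_mode {scalars['scoring_mode']!r}")
    for key in ("peptide_table", "string_links", "fasta", "regions", "glyco_table"):
        value = scalars.get(key)
        if value is not None and not Path(value).exists():
            errors.append(f"{key}: file not found: {value}")
    if errors or design is None or thresholds is None or simulation is None:
        return None, errors
    config = PipelineConfig(
        design=design, thresholds=thresholds, simulation=simulation, **scalars
    )
    return config, errors
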