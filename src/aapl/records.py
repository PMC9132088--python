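"""Core record types shared across the pipeline.

Tabular data moves through the pipeline as pandas DataFrames whose column
contracts are defined here; the dataclasses are the row-level views used at
API boundaries and for validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Canonical column order of the peptide quantification table.
PEPTIDE_COLUMNS = (
    "protein_id",
    "peptide",
    "start",
    "end",
    "mod",
    "condition",
    "replicate",
    "intensity",
    "spectral_count",
)

#: Modification token for the unmodified peptidoform.
UNMODIFIED = "none"


def mod_token(position: int) -> str:
    """Return the modification token for mono-oxidation at a 1-based protein position."""
    if position < 1:
        raise ValueError(f"oxidation position must be 1-based positive, got {position}")
    return f"ox:{position}"


def parse_mod(token: str) -> int | None:
    """Parse a mod token; return the oxidized 1-based position, or None if unmodified.

    Raises ValueError for malformed tokens (including ``ox:0``, which violates
    the 1-based coordinate convention).
    """
    if token == UNMODIFIED:
        return None
    if token.startswith("ox:"):
        try:
            pos = int(token[3:])
        except ValueError:
            raise ValueError(f"invalid mod token {token!r}") from None
        if pos < 1:
            raise ValueError(f"invalid mod token {token!r}: position must be >= 1")
        return pos
    raise ValueError(f"invalid mod token {token!r}")


@dataclass(frozen=True)
class PeptideMeasurement:
    """One quantified peptidoform observation — the pipeline's atomic input.

    Coordinates are 1-based inclusive residue positions within the protein.
    ``mod`` is either ``"none"`` or ``"ox:<p>"`` where ``p`` is the oxidized
    residue position in protein coordinates.
    """

    protein_id: str
    peptide: str
    start: int
    end: int
    mod: str
    condition: str
    replicate: int
    intensity: float
    spectral_count: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")
        if self.spectral_count < 0:
            raise ValueError("spectral_count must be non-negative")
        if self.replicate < 1:
            raise ValueError("replicate index is 1-based")
        pos = parse_mod(self.mod)
        if pos is not None and not (self.start <= pos <= self.end):
            raise ValueError(
                f"oxidized position {pos} outside peptide span [{self.start}, {self.end}]"
            )


@dataclass(frozen=True)
class StringEdge:
    """Undirected known-interaction edge with a combined confidence score in [0, 1]."""

    protein_a: str
    protein_b: str
    combined_score: float

    def __post_init__(self) -> None:
        if self.protein_a == self.protein_b:
            raise ValueError(f"self edge on {self.protein_a!r}")
        if not 0.0 <= self.combined_score <= 1.0:
            raise ValueError(f"combined_score {self.combined_score} outside [0, 1]")

    @property
    def pair(self) -> tuple[str, str]:
        """The unordered pair as a sorted tuple."""
        return tuple(sorted((self.protein_a, self.protein_b)))  # type: ignore[return-value]


@dataclass(frozen=True)
class RegionAnnotation:
    """A named region (domain, topological segment, ...) on a protein; 1-based inclusive."""

    protein_id: str
    region_name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class GlycopeptideRecord:
    """A site-specific glycopeptide observation with monosaccharide composition counts."""

    protein_id: str
    site: int
    hex: int
    hexnac: int
    fuc: int
    neuac: int
    intensity: float
    glyco_type: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        for name in ("hex", "hexnac", "fuc", "neuac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} count must be non-negative")
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")
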