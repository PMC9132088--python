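"""Readers and writers for every external format the pipeline touches.

The canonical table format is tab-separated text with a header row; comma
dialects are rejected rather than guessed, and unparseable rows are hard
errors — silent data loss is worse than failure.  All residue coordinates
are 1-based inclusive.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd
from Bio import SeqIO

from .records import PEPTIDE_COLUMNS, parse_mod
from .synthetic_data import ProteinRecord

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """Input file does not match the documented column contract."""


class TableParseError(ValueError):
    """A row of an input table violates the format's invariants."""


def _read_tsv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype="object")
    if len(df.columns) == 1 and "," in str(df.columns[0]):
        raise SchemaError(f"{path}: comma-separated input; the canonical format is TSV")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def read_peptide_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a peptide quantification table.

    Rows with intensity 0 and spectral count 0 carry no quantitative signal
    and are dropped (the count is logged).  Any malformed value is an error
    naming the 1-based data line.
    """
    df = _read_tsv(path, PEPTIDE_COLUMNS)
    df = df[list(PEPTIDE_COLUMNS)]
    try:
        df = df.astype(
            {
                "start": "int64",
                "end": "int64",
                "replicate": "int64",
                "intensity": "float64",
                "spectral_count": "int64",
            }
        )
    except (ValueError, TypeError) as exc:
        raise TableParseError(f"{path}: non-numeric value in a numeric column ({exc})") from exc

    for line0, row in enumerate(df.itertuples(index=False), start=1):
        try:
            pos = parse_mod(row.mod)
            if row.start > row.end:
                raise ValueError(f"start {row.start} > end {row.end}")
            if pos is not None and not (row.start <= pos <= row.end):
                raise ValueError(
                    f"oxidized position {pos} outside peptide span [{row.start}, {row.end}]"
                )
            if row.intensity < 0 or row.spectral_count < 0 or row.replicate < 1:
                raise ValueError("negative quantity")
        except ValueError as exc:
            raise TableParseError(f"{path}, line {line0}: {exc}") from None

    keep = (df["intensity"] > 0) | (df["spectral_count"] > 0)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("%s: dropped %d rows with zero intensity and zero spectral count", path, dropped)
    return df[keep].reset_index(drop=True)


def write_peptide_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table[list(PEPTIDE_COLUMNS)].to_csv(path, sep="\t", index=False)
    return path


def read_string_links(path: str | Path, score_floor: float = 0.4) -> pd.DataFrame:
    """Read a STRING-style links file into normalized undirected edges.

    Accepts either the native dialect (integer combined scores 0–1000,
    divided by 1000) or already-normalized reals in [0, 1]; the dialect is
    decided by the column dtype.  Duplicate unordered pairs collapse to the
    maximum score; edges below ``score_floor`` are dropped.
    """
    df = _read_tsv(path, ("combined_score",))
    if {"protein1", "protein2"}.issubset(df.columns):  # native STRING header
        df = df.rename(columns={"protein1": "protein_a", "protein2": "protein_b"})
    if not {"protein_a", "protein_b"}.issubset(df.columns):
        raise SchemaError(f"{path}: missing protein pair columns (protein1/protein2)")
    scores = pd.to_numeric(df["combined_score"], errors="coerce")
    if scores.isna().any():
        line = int(scores.index[scores.isna()][0]) + 1
        raise TableParseError(f"{path}, line {line}: non-numeric combined_score")
    if (scores < 0).any() or (scores > 1000).any():
        raise TableParseError(f"{path}: combined_score outside [0, 1000]")
    integral = (scores == scores.round()).all()
    if integral and (scores > 1).any():
        scores = scores / 1000.0
    elif (scores > 1).any():
        raise TableParseError(f"{path}: fractional scores must lie in [0, 1]")
    a = df["protein_a"].astype(str)
    b = df["protein_b"].astype(str)
    if (a == b).any():
        raise TableParseError(f"{path}: self edge present")
    lo = a.where(a < b, b)
    hi = b.where(a < b, a)
    edges = pd.DataFrame({"protein_a": lo, "protein_b": hi, "combined_score": scores})
    edges = (
        edges.groupby(["protein_a", "protein_b"], as_index=False)["combined_score"].max()
    )
    edges = edges[edges["combined_score"] >= score_floor].reset_index(drop=True)
    return edges


def write_string_links(edges: pd.DataFrame, path: str | Path) -> Path:
    """Write edges in the native STRING dialect (protein1/protein2, integer scores 0–1000)."""
    out = edges.rename(columns={"protein_a": "protein1", "protein_b": "protein2"}).copy()
    out["combined_score"] = (out["combined_score"] * 1000).round().astype("int64")
    out.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    return [
        ProteinRecord(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(proteome: list[ProteinRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in proteome:
            fh.write(f">{rec.protein_id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")
    return path


def read_region_table(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, ("protein_id", "region_name", "start", "end"))
    df = df.astype({"start": "int64", "end": "int64"})
    if (df["start"] > df["end"]).any():
        raise TableParseError(f"{path}: region with start > end")
    return df


def read_glyco_table(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(
        path, ("protein_id", "site", "hex", "hexnac", "fuc", "neuac", "intensity")
    )
    df = df.astype(
        {
            "site": "int64",
            "hex": "int64",
            "hexnac": "int64",
            "fuc": "int64",
            "neuac": "int64",
            "intensity": "float64",
        }
    )
    if (df[["hex", "hexnac", "fuc", "neuac"]] < 0).any().any():
        raise TableParseError(f"{path}: negative monosaccharide count")
    if (df["intensity"] < 0).any():
        raise TableParseError(f"{path}: negative intensity")
    return df


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write each named table as ``<name>.tsv`` under ``out_dir``; return the manifest.

    Deterministic: a re-run over identical tables produces byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for name in sorted(tables):
        path = out_dir / f"{name}.tsv"
        tables[name].to_csv(path, sep="\t", index=False)
        manifest.append(path)
        logger.info("wrote %s (%d rows)", path, len(tables[name]))
    return manifest


def write_graphml(graph: nx.Graph, path: str | Path) -> Path:
    nx.write_graphml(graph, str(path))
    return Path(path)


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))


def write_sif(graph: nx.Graph, path: str | Path) -> Path:
    """Cytoscape SIF: one ``a <style> b`` line per edge, nodes without edges listed bare."""
    path = Path(path)
    with open(path, "w") as fh:
        isolated = [n for n in sorted(graph.nodes) if graph.degree(n) == 0]
        for a, b, data in sorted(graph.edges(data=True)):
            fh.write(f"{a}\t{data.get('style', 'solid')}\t{b}\n")
        for n in isolated:
            fh.write(f"{n}\n")
    return path
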