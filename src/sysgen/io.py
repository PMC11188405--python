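"""Readers and writers for every tabular format the pipeline exchanges.

Conventions: genetic maps and most tables are TSV; genotypes are CSV with
the line id first; gene positions use BED (0-based half-open, converted to
a 1-based midpoint internally); networks export as SIF plus a weighted TSV
for Cytoscape. Thresholds and seeds are echoed into JSON sidecars so any
numeric output can be reproduced from its manifest.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .exprprep import ExpressionMatrix
from .genmap import GeneticMap, GenotypeMatrix

__all__ = [
    "read_genetic_map", "write_genetic_map",
    "read_genotypes", "write_genotypes",
    "read_expression", "write_expression",
    "read_positions_bed", "write_positions_bed",
    "read_traits", "write_traits",
    "write_edges_sif", "write_edges_tsv",
    "write_json_sidecar", "write_manifest",
]


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def read_genetic_map(path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["marker", "chrom", "cM", "bp"], path)
    return GeneticMap(df[["marker", "chrom", "cM", "bp"]])


def write_genetic_map(gmap: GeneticMap, path) -> None:
    gmap.table.to_csv(path, sep="\t", index=False)


def read_genotypes(path, gmap: GeneticMap) -> GenotypeMatrix:
    """CSV: first column line id, then one column per marker with {0,1,NA}.

    Codes other than 0/1/NA are reported with line id and marker name.
    """
    df = pd.read_csv(path, index_col=0)
    markers = gmap.markers
    if list(df.columns) != markers:
        raise ValueError(f"{path}: marker columns do not match the genetic map order")
    values = df.to_numpy(dtype=float)
    finite = np.isfinite(values)
    bad = finite & (values != 0) & (values != 1)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: invalid DH genotype code {values[i, j]!r} at "
            f"line {df.index[i]!r}, marker {markers[j]!r}")
    return GenotypeMatrix(values, list(df.index), gmap)


def write_genotypes(genotypes: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(genotypes.values, index=pd.Index(genotypes.line_ids, name="line"),
                      columns=genotypes.gmap.markers)
    df.to_csv(path, na_rep="NA")


def read_expression(path, positions_path=None) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "transcript":
        raise ValueError(f"{path}: first column must be 'transcript'")
    df = df.set_index("transcript")
    positions = None
    if positions_path is not None:
        positions = read_positions_bed(positions_path)
    return ExpressionMatrix(df, positions) if positions is not None \
        else ExpressionMatrix(df)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.values.rename_axis("transcript").to_csv(path, sep="\t")


def read_positions_bed(path) -> pd.DataFrame:
    """BED (chrom, start, end, transcript) -> 1-based midpoint per transcript."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "transcript"])
    if (df["end"] <= df["start"]).any():
        bad = df[df["end"] <= df["start"]].iloc[0]
        raise ValueError(f"{path}: empty/negative interval for {bad['transcript']!r}")
    mid = ((df["start"] + df["end"] - 1) // 2) + 1     # 0-based half-open -> 1-based
    return pd.DataFrame({"chrom": df["chrom"].to_numpy(), "bp": mid.to_numpy()},
                        index=pd.Index(df["transcript"], name="transcript"))


def write_positions_bed(positions: pd.DataFrame, path) -> None:
    """Midpoint table -> degenerate 1-bp BED intervals (0-based half-open)."""
    out = pd.DataFrame({
        "chrom": positions["chrom"],
        "start": positions["bp"] - 1,
        "end": positions["bp"],
        "transcript": positions.index,
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def read_traits(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: trait table has no trait columns")
    return df


def write_traits(traits: pd.DataFrame, path) -> None:
    traits.rename_axis("line").to_csv(path, sep="\t")


def write_edges_sif(edges: pd.DataFrame, path, relation: str = "cc") -> None:
    with open(path, "w") as fh:
        for _, row in edges.iterrows():
            fh.write(f"{row['node_a']}\t{relation}\t{row['node_b']}\n")


def write_edges_tsv(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def write_json_sidecar(payload: dict, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")
    Path(path).write_text(json.dumps(payload, indent=2, default=_default) + "\n")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path, stage: str, inputs: dict, params: dict, seed,
                   started: float) -> None:
    """Run manifest: input hashes, parameters, seed, wall time."""
    manifest = {
        "stage": stage,
        "inputs": {k: file_sha256(v) for k, v in inputs.items()
                   if v is not None and Path(v).exists()},
        "params": params,
        "seed": seed,
        "wall_time_s": round(time.time() - started, 3),
    }
    write_json_sidecar(manifest, path)
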