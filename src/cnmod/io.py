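"""Readers and writers for the pipeline's tab formats.

Formats: SEG-like segment tables (1-based inclusive on disk, converted to the
internal 0-based half-open convention), ploidy/purity tables, gene-by-sample
matrices, two-column edge lists and three-column SIF interaction files, BED
masks (read natively, already 0-based half-open), GMT gene-set collections,
survival tables, genome maps and ground-truth JSON.  Every writer's output is
re-readable by its paired reader; readers reject malformed input with errors
naming the file and line.

Floats are written with %.10g so that identical in-memory results produce
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .segments import GenomicInterval, SampleProfile, SegmentCall
from .synthetic import GroundTruth

__all__ = [
    "read_profiles", "write_profiles",
    "read_matrix", "write_matrix",
    "read_interactome", "write_interactome", "write_sif",
    "read_bed", "write_bed",
    "read_gmt", "write_gmt",
    "read_survival", "write_survival",
    "read_genome_map", "write_genome_map",
    "read_ground_truth", "write_ground_truth",
    "export_cytoscape",
]

FLOAT_FORMAT = "%.10g"

SEG_COLUMNS = ["sample", "chrom", "start", "end", "n_markers", "total_cn"]
PLOIDY_COLUMNS = ["sample", "ploidy", "aberrant_cell_fraction"]


def _err(path, lineno: int, msg: str) -> ValueError:
    return ValueError(f"{path}:{lineno}: {msg}")


def _read_tsv(path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(columns) - set(df.columns)
    if missing:
        raise _err(path, 1, f"missing columns {sorted(missing)}; found {list(df.columns)}")
    return df


def _as_number(path, df: pd.DataFrame, col: str, kind=float) -> pd.Series:
    try:
        return df[col].astype(kind)
    except (TypeError, ValueError):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        lineno = int(bad.idxmax()) + 2  # header is line 1
        raise _err(path, lineno, f"non-numeric value {df[col][bad.idxmax()]!r} in column {col!r}")


def write_profiles(profiles: list[SampleProfile], seg_path, ploidy_path) -> None:
    """Write profiles as a SEG-like table (1-based inclusive) plus a ploidy table."""
    rows = [
        {
            "sample": seg.sample_id,
            "chrom": seg.interval.chrom,
            "start": seg.interval.start + 1,  # 0-based half-open -> 1-based inclusive
            "end": seg.interval.end,
            "n_markers": seg.n_markers,
            "total_cn": seg.total_cn,
        }
        for p in profiles
        for seg in p.segments
    ]
    pd.DataFrame(rows, columns=SEG_COLUMNS).to_csv(
        seg_path, sep="\t", index=False, float_format=FLOAT_FORMAT
    )
    pd.DataFrame(
        [
            {"sample": p.sample_id, "ploidy": p.ploidy,
             "aberrant_cell_fraction": p.aberrant_cell_fraction}
            for p in profiles
        ],
        columns=PLOIDY_COLUMNS,
    ).to_csv(ploidy_path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_profiles(seg_path, ploidy_path) -> list[SampleProfile]:
    """Read a SEG-like table plus ploidy/purity table into sample profiles."""
    seg = _read_tsv(seg_path, SEG_COLUMNS)
    for col, kind in (("start", int), ("end", int), ("n_markers", int), ("total_cn", float)):
        seg[col] = _as_number(seg_path, seg, col, kind)
    plo = _read_tsv(ploidy_path, PLOIDY_COLUMNS)
    for col in ("ploidy", "aberrant_cell_fraction"):
        plo[col] = _as_number(ploidy_path, plo, col)
    if plo["sample"].duplicated().any():
        dup = plo.loc[plo["sample"].duplicated(), "sample"].iloc[0]
        raise _err(ploidy_path, 1, f"duplicate sample {dup!r}")

    meta = plo.set_index("sample")
    unknown = set(seg["sample"]) - set(meta.index)
    if unknown:
        raise _err(seg_path, 1, f"samples without ploidy record: {sorted(unknown)[:5]}")
    profiles = []
    for sample, rows in seg.groupby("sample", sort=True):
        segments = []
        for i, row in rows.iterrows():
            try:
                iv = GenomicInterval(
                    chrom=row["chrom"], start=int(row["start"]) - 1, end=int(row["end"])
                )
                segments.append(
                    SegmentCall(sample, iv, int(row["n_markers"]), float(row["total_cn"]))
                )
            except ValueError as exc:
                raise _err(seg_path, i + 2, str(exc)) from exc
        profiles.append(
            SampleProfile(
                sample_id=sample,
                ploidy=float(meta.loc[sample, "ploidy"]),
                aberrant_cell_fraction=float(meta.loc[sample, "aberrant_cell_fraction"]),
                segments=segments,
            )
        )
    return profiles


def write_matrix(df: pd.DataFrame, path, index_name: str = "gene") -> None:
    """Write a genes x samples matrix as TSV with a named index column."""
    out = df.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_matrix(path, index_name: str = "gene") -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name != index_name:
        raise _err(path, 1, f"expected index column {index_name!r}, found {df.index.name!r}")
    if df.index.has_duplicates:
        raise _err(path, 1, "duplicate row labels")
    return df


def write_interactome(graph: nx.Graph, path) -> None:
    """Write an undirected graph as a sorted two-column edge-list TSV."""
    edges = sorted(tuple(sorted(e)) for e in graph.edges())
    pd.DataFrame(edges, columns=["gene_a", "gene_b"]).to_csv(path, sep="\t", index=False)


def write_sif(graph: nx.Graph, path, relation: str = "interacts") -> None:
    """Write a Cytoscape SIF file (``a<TAB>interacts<TAB>b``)."""
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{a}\t{relation}\t{b}\n")


def read_interactome(path) -> nx.Graph:
    """Read an edge list (two-column TSV with header, or headerless SIF).

    Self-loops are rejected; duplicate edges collapse (simple graph).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0] in ("gene_a", "source", "node1"):
                continue  # header of a two-column edge list
            if len(parts) == 2:
                a, b = parts
            elif len(parts) == 3:
                a, _, b = parts  # SIF: source relation target
            else:
                raise _err(path, lineno, f"expected 2 or 3 tab-separated fields, got {len(parts)}")
            if not a or not b:
                raise _err(path, lineno, "empty gene id")
            if a == b:
                raise _err(path, lineno, f"self-loop on {a!r}")
            g.add_edge(a, b)
    return g


def write_bed(intervals: list[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in sorted(intervals):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_bed(path) -> list[GenomicInterval]:
    """Read a 3+ column BED file (0-based half-open, no conversion needed)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise _err(path, lineno, "BED needs at least 3 columns")
            try:
                out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise _err(path, lineno, str(exc)) from exc
    return out


def write_gmt(gene_sets: dict[str, set[str]], path, descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for term in sorted(gene_sets):
            genes = "\t".join(sorted(gene_sets[term]))
            fh.write(f"{term}\t{descriptions.get(term, 'na')}\t{genes}\n")


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT collection: term, description, then one gene per column."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise _err(path, lineno, "GMT needs term, description and >= 1 gene")
            if parts[0] in sets:
                raise _err(path, lineno, f"duplicate term {parts[0]!r}")
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_survival(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_survival(path) -> pd.DataFrame:
    df = _read_tsv(path, ["sample", "time", "event"])
    df["time"] = _as_number(path, df, "time")
    df["event"] = _as_number(path, df, "event", int)
    bad = ~df["event"].isin((0, 1))
    if bad.any():
        raise _err(path, int(bad.idxmax()) + 2, "event must be 0 or 1")
    bad = df["time"] <= 0
    if bad.any():
        raise _err(path, int(bad.idxmax()) + 2, "time must be > 0")
    return df


def write_genome_map(gm: pd.DataFrame, path) -> None:
    gm.to_csv(path, sep="\t", index=False)


def read_genome_map(path) -> pd.DataFrame:
    gm = _read_tsv(path, ["gene", "chrom", "start", "end"])
    gm["start"] = _as_number(path, gm, "start", int)
    gm["end"] = _as_number(path, gm, "end", int)
    bad = gm["start"] >= gm["end"]
    if bad.any():
        raise _err(path, int(bad.idxmax()) + 2, "start must be < end")
    if gm["gene"].duplicated().any():
        dup = gm.loc[gm["gene"].duplicated(), "gene"].iloc[0]
        raise _err(path, 1, f"duplicate gene {dup!r}")
    return gm


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "planted_module_membership": dict(sorted(truth.planted_module_membership.items())),
        "causal_genes": sorted(truth.causal_genes),
        "risk_genes": sorted(truth.risk_genes),
        "module_directions": {str(k): v for k, v in sorted(truth.module_directions.items())},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_ground_truth(path) -> GroundTruth:
    with open(path) as fh:
        payload = json.load(fh)
    return GroundTruth(
        planted_module_membership={
            k: int(v) for k, v in payload["planted_module_membership"].items()
        },
        causal_genes=set(payload["causal_genes"]),
        risk_genes=set(payload["risk_genes"]),
        module_directions={int(k): v for k, v in payload["module_directions"].items()},
    )


# Cytoscape colour/shape conventions of the emulated figures
_COLOURS = {"gain": "red", "loss": "green", "none": "gray"}
_SHAPES = {"driver": "circle", "linker": "diamond"}


def export_cytoscape(network, partition=None, outdir=".") -> dict[str, Path]:
    """Export a network as Cytoscape-loadable SIF + node/edge attribute tables.

    Node attributes: role (with its drawn shape), alteration (with the colour
    key: loss green, gain red, linker gray), sample frequency (node size),
    degree and, when a partition is given, module id.
    """
    graph = network.graph if isinstance(getattr(network, "graph", None), nx.Graph) else network
    if graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sif = outdir / "network.sif"
    write_sif(graph, sif)

    assignment = partition.assignment if partition is not None else {}
    rows = []
    for node in sorted(graph.nodes):
        data = graph.nodes[node]
        role = data.get("role", "driver")
        alteration = data.get("alteration", "none")
        rows.append(
            {
                "gene": node,
                "role": role,
                "shape": _SHAPES.get(role, "circle"),
                "alteration": alteration,
                "color": _COLOURS.get(alteration, "gray"),
                "sample_frequency": data.get("sample_frequency", 0.0),
                "degree": graph.degree(node),
                "module": assignment.get(node, -1),
            }
        )
    nodes_path = outdir / "node_attributes.tsv"
    pd.DataFrame(rows).to_csv(nodes_path, sep="\t", index=False, float_format=FLOAT_FORMAT)

    edges_path = outdir / "edges.tsv"
    pd.DataFrame(
        sorted(tuple(sorted(e)) for e in graph.edges()), columns=["gene_a", "gene_b"]
    ).to_csv(edges_path, sep="\t", index=False)
    return {"sif": sif, "nodes": nodes_path, "edges": edges_path}
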