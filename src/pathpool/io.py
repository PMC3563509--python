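"""Readers and writers for the pipeline's tab-delimited formats.

Formats: expression matrix (TSV, first column gene id, one column per
sample); group labels (2-column TSV sample -> group, no header); edge list
(4-column TSV with header ``pathway_id source target relation``); per-gene
p-value table (2-column TSV, no header); GMT membership.  All files are
UTF-8 with ``#`` comment lines.
"""

from __future__ import annotations

import hashlib
import json
import pathlib

import numpy as np
import pandas as pd

from .evidence import ExpressionDataset
from .pathway_model import PathwayGraph, read_edge_list, parse_kgml


def read_expression(expr_path, groups_path) -> ExpressionDataset:
    df = pd.read_csv(expr_path, sep="\t", comment="#", index_col=0)
    gdf = pd.read_csv(groups_path, sep="\t", comment="#", header=None,
                      names=["sample", "group"], dtype=str)
    labels = dict(zip(gdf["sample"], gdf["group"]))
    missing = [s for s in df.columns if s not in labels]
    if missing:
        raise ValueError(f"samples without group labels: {missing[:5]}")
    groups = np.array([labels[s] for s in df.columns])
    return ExpressionDataset(gene_ids=[str(g) for g in df.index],
                             values=df.to_numpy(dtype=float), groups=groups)


def write_expression(dataset: ExpressionDataset, expr_path, groups_path) -> None:
    samples = [f"s{i + 1:03d}" for i in range(len(dataset.groups))]
    df = pd.DataFrame(dataset.values, index=dataset.gene_ids, columns=samples)
    df.index.name = "gene"
    df.to_csv(expr_path, sep="\t", float_format="%.6g")
    with open(groups_path, "w") as fh:
        for s, g in zip(samples, dataset.groups):
            fh.write(f"{s}\t{g}\n")


def write_edge_list(pathways: list[PathwayGraph], path) -> None:
    with open(path, "w") as fh:
        fh.write("pathway_id\tsource\ttarget\trelation\n")
        for pw in pathways:
            for e in pw.edges:
                fh.write(f"{pw.pathway_id}\t{e.source}\t{e.target}\t{e.relation}\n")
            # isolated genes are carried as self-describing comment lines
            connected = {e.source for e in pw.edges} | {e.target for e in pw.edges}
            for g in sorted(pw.genes - connected):
                fh.write(f"# isolated\t{pw.pathway_id}\t{g}\n")


def read_pathways(path, relation_map=None) -> list[PathwayGraph]:
    """Load pathways from an edge-list TSV, a KGML file, or a directory of KGML files."""
    p = pathlib.Path(path)
    if p.is_dir():
        graphs = []
        for f in sorted(p.glob("*.xml")) or sorted(p.glob("*.kgml")):
            graphs.append(parse_kgml(f.read_bytes(), relation_map,
                                     source_name=str(f)))
        if not graphs:
            raise ValueError(f"no KGML files found in {p}")
        return graphs
    head = p.open("rb").read(200)
    if head.lstrip().startswith(b"<"):
        return [parse_kgml(p.read_bytes(), relation_map, source_name=str(p))]
    return read_edge_list(p, relation_map)


def read_relation_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["relation", "policy"], dtype=str)
    return dict(zip(df["relation"], df["policy"]))


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, config: dict, inputs: dict[str, str]) -> None:
    """JSON run manifest: full config plus input checksums, for reproducibility."""
    import pathpool
    manifest = {
        "pathpool_version": pathpool.__version__,
        "config": config,
        "input_sha256": {k: sha256_of(v) for k, v in inputs.items()
                         if v and pathlib.Path(v).is_file()},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
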