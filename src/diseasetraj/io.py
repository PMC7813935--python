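"""File-format contracts: claims, tensors, trees, networks, manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from .blocks import BlockTable
from .divclus import ClusterTree
from .states import StateMatrix
from .transitions import TransitionTensor, network_to_node_link

CLAIMS_DTYPES = {
    "patient_id": str,
    "sex": str,
    "age_group": str,
    "region": str,
    "half_year_index": "int64",
    "icd10_codes": str,
    "discharge": str,
}


def write_claims(claims: pd.DataFrame, path: str | Path) -> None:
    """CSV for plain text, Parquet for the columnar binary format."""
    path = Path(path)
    if path.suffix == ".parquet":
        claims.to_parquet(path, index=False)
    else:
        claims.to_csv(path, index=False)


def read_claims(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".parquet":
        df = pd.read_parquet(path)
    else:
        df = pd.read_csv(path, dtype=CLAIMS_DTYPES, keep_default_na=False)
    df["icd10_codes"] = df["icd10_codes"].fillna("")
    return df


def write_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def read_yaml(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def write_tree(tree: ClusterTree, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(tree.to_dict(), fh, indent=1)


def read_tree(path: str | Path) -> ClusterTree:
    with open(path, encoding="utf-8") as fh:
        return ClusterTree.from_dict(json.load(fh))


def write_states(states: StateMatrix, prefix: str | Path) -> list[Path]:
    prefix = Path(prefix)
    paths = []
    for name, frame in states.to_frames().items():
        p = prefix.parent / f"{prefix.name}_{name}.csv"
        frame.to_csv(p, index=False)
        paths.append(p)
    return paths


def read_states(prefix: str | Path, table: BlockTable) -> StateMatrix:
    prefix = Path(prefix)
    frames = {}
    for name in ("triplets", "demographics", "snapshots"):
        frames[name] = pd.read_csv(
            prefix.parent / f"{prefix.name}_{name}.csv",
            dtype={"patient_id": str, "sex": str, "region": str},
        )
    return StateMatrix.from_frames(frames, table)


def write_tensor(tensor: TransitionTensor, path: str | Path) -> None:
    tensor.to_frame().to_csv(path, index=False)


def read_tensor(path: str | Path, n_clusters: int) -> TransitionTensor:
    frame = pd.read_csv(path, dtype={"sex": str, "age_group": str})
    return TransitionTensor.from_frame(frame, n_clusters)


def write_network(g: nx.DiGraph, path_graphml: str | Path, path_json: str | Path) -> None:
    h = nx.DiGraph(**{k: v for k, v in g.graph.items() if v is not None})
    for n, d in g.nodes(data=True):
        h.add_node(n, **{k: v for k, v in d.items() if v is not None})
    for u, v, d in g.edges(data=True):
        h.add_edge(u, v, **d)
    nx.write_graphml(h, path_graphml)
    with open(path_json, "w", encoding="utf-8") as fh:
        json.dump(network_to_node_link(g), fh, indent=1)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
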