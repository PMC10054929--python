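"""File formats: SWC skeletons, pair/neuron tables, config and ground truth.

SWC is the standard 7-column dialect (id, type, x, y, z, radius, parent)
with '#' comments, 1-based node ids, parent -1 for roots (forests are
accepted), and type codes 2 = axon, 3 = dendrite.  Tables interchange as
CSV (inspection) and Parquet (canonical, via pyarrow).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import Skeleton

__all__ = ["read_swc", "write_swc", "split_compartments", "write_tables", "config_hash"]

SWC_TYPE_CODES = {"axon": 2, "dendrite": 3}
CODE_TO_COMPARTMENT = {2: "axon", 3: "dendrite"}


def read_swc(path) -> tuple[Skeleton, np.ndarray]:
    """Read an SWC file into one Skeleton plus per-vertex type codes.

    Returns (skeleton, type_codes); use :func:`split_compartments` to pull
    out the axonal and dendritic sub-skeletons.  Malformed rows raise with
    their line number.
    """
    vertices, types, parents, ids = [], [], [], {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 SWC columns, got {len(fields)}")
            try:
                nid = int(fields[0])
                code = int(fields[1])
                x, y, z = (float(v) for v in fields[2:5])
                parent = int(fields[6])
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: malformed SWC row ({err})") from None
            ids[nid] = len(vertices)
            vertices.append((x, y, z))
            types.append(code)
            parents.append(parent)
    edges = []
    for row, parent in enumerate(parents):
        if parent == -1:
            continue
        if parent not in ids:
            raise ValueError(f"{path}: node parent {parent} never defined")
        edges.append((ids[parent], row))
    name = Path(path).stem
    skel = Skeleton(np.asarray(vertices, dtype=float), np.asarray(edges, dtype=int).reshape(-1, 2),
                    compartment="mixed", neuron_id=name)
    return skel, np.asarray(types, dtype=int)


def write_swc(skel: Skeleton, path, type_codes: np.ndarray | None = None) -> None:
    """Write a Skeleton as SWC (radius 1.0; tree structure from the edges)."""
    if type_codes is None:
        code = SWC_TYPE_CODES.get(skel.compartment, 0)
        type_codes = np.full(skel.n_vertices, code, dtype=int)
    parent = np.full(skel.n_vertices, -1, dtype=int)
    # orient edges away from the lowest-index vertex of each component
    seen = np.zeros(skel.n_vertices, dtype=bool)
    adj: dict[int, list[int]] = {i: [] for i in range(skel.n_vertices)}
    for a, b in skel.edges:
        adj[a].append(b)
        adj[b].append(a)
    for root in range(skel.n_vertices):
        if seen[root]:
            continue
        stack = [root]
        seen[root] = True
        while stack:
            v = stack.pop()
            for w in adj[v]:
                if not seen[w]:
                    seen[w] = True
                    parent[w] = v
                    stack.append(w)
    with open(path, "w") as fh:
        fh.write(f"# SWC export, neuron {skel.neuron_id}\n")
        for i in range(skel.n_vertices):
            x, y, z = skel.vertices[i]
            par = parent[i] + 1 if parent[i] >= 0 else -1
            fh.write(f"{i + 1} {type_codes[i]} {x:.6f} {y:.6f} {z:.6f} 1.0 {par}\n")


def split_compartments(skel: Skeleton, type_codes: np.ndarray) -> dict[str, Skeleton]:
    """Axonal and dendritic sub-skeletons of a mixed SWC read.

    Edges whose endpoints straddle compartments are dropped (they connect
    the compartments at the soma).
    """
    out = {}
    for code, name in CODE_TO_COMPARTMENT.items():
        mask = type_codes == code
        if not mask.any():
            continue
        remap = -np.ones(skel.n_vertices, dtype=int)
        remap[mask] = np.arange(mask.sum())
        keep = mask[skel.edges[:, 0]] & mask[skel.edges[:, 1]] if skel.edges.size else np.zeros(0, bool)
        edges = remap[skel.edges[keep]] if skel.edges.size else skel.edges
        out[name] = Skeleton(skel.vertices[mask], edges, name, skel.neuron_id)
    return out


def config_hash(config) -> str:
    """Stable short hash of a configuration dataclass/dict."""
    if hasattr(config, "__dataclass_fields__"):
        from dataclasses import asdict

        payload = asdict(config)
    else:
        payload = dict(config)
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_tables(outdir, neurons: pd.DataFrame, pairs: pd.DataFrame, truth=None) -> None:
    """Write the neuron and pair tables as CSV + Parquet (ground truth as YAML)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in [("neurons", neurons), ("pairs", pairs)]:
        df.to_csv(outdir / f"{name}.csv", index=False)
        df.to_parquet(outdir / f"{name}.parquet", index=False)
    if truth is not None:
        with open(outdir / "ground_truth.yaml", "w") as fh:
            yaml.safe_dump(truth.to_dict(), fh, default_flow_style=False)
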