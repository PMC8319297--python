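"""Reading and writing the pipeline's plain-text interchange formats.

Tables are headered UTF-8 CSV; the area adjacency is a two-column
whitespace-delimited edge list with a header line; ground truth is JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from ebep.types import AreaGraph, PosteriorDraws, TruthRecord


def write_adjacency(graph: AreaGraph, path) -> None:
    lines = ["area_a area_b"]
    lines += [f"{a} {b}" for a, b in graph.edges]
    # isolated areas still need to appear; record them with a sentinel
    touched = {a for e in graph.edges for a in e}
    lines += [f"{a} ." for a in graph.area_ids if a not in touched]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_adjacency(path, region_of: Mapping[str, str] | None = None) -> AreaGraph:
    rows = Path(path).read_text(encoding="utf-8").strip().splitlines()[1:]
    edges, areas = [], []
    for line in rows:
        a, b = line.split()
        areas.append(a)
        if b != ".":
            areas.append(b)
            edges.append((a, b))
    ids = tuple(dict.fromkeys(areas))
    regions = dict(region_of) if region_of else {a: "r0" for a in ids}
    return AreaGraph(ids, tuple(edges), regions)


def write_regions(graph: AreaGraph, path) -> None:
    pd.DataFrame({"area_id": list(graph.area_ids),
                  "region": [graph.region_of[a] for a in graph.area_ids]}
                 ).to_csv(path, index=False)


def read_regions(path) -> dict[str, str]:
    df = pd.read_csv(path)
    return dict(zip(df["area_id"].astype(str), df["region"].astype(str)))


def write_draws_csv(draws: PosteriorDraws, path) -> None:
    draws.to_long_frame().to_csv(path, index=False)


def write_truth(truth: TruthRecord, path) -> None:
    truth.to_json(path)


def write_json(payload: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, default=str)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
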