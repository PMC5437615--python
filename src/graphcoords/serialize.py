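"""Graph-document JSON: a graph plus its partitions and build metadata.

Layout::

    {
      "blocks": [...], "edges": [...], "main_paths": {...},
      "source_maps": {...},
      "partitions": {"hierarchical": {...}, "sequential": {...}},
      "meta": {"mode": "trimmed", "alt_info": {...}}
    }
"""

from __future__ import annotations

import json
from typing import Optional

from .assembly import AltBuildInfo, GraphBuild
from .coordinates import RegionPathPartition
from .graph import SequenceGraph


def document_dict(graph: SequenceGraph, partitions=None, meta=None) -> dict:
    doc = graph.to_dict()
    if partitions:
        doc["partitions"] = {p.kind: p.to_dict() for p in partitions}
    if meta:
        doc["meta"] = meta
    return doc


def save_document(path: str, graph: SequenceGraph, partitions=None, meta=None):
    with open(path, "w") as fh:
        json.dump(document_dict(graph, partitions, meta), fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_document(path: str):
    """Returns ``(graph, {kind: partition}, meta_dict)``."""
    with open(path) as fh:
        doc = json.load(fh)
    graph = SequenceGraph.from_dict(doc)
    partitions = {
        kind: RegionPathPartition.from_dict(pdoc, graph)
        for kind, pdoc in doc.get("partitions", {}).items()
    }
    return graph, partitions, doc.get("meta", {})


def build_from_meta(graph: SequenceGraph, meta: dict) -> Optional[GraphBuild]:
    if "mode" not in meta:
        return None
    alt_info = {
        k: AltBuildInfo.from_dict(v) for k, v in meta.get("alt_info", {}).items()
    }
    return GraphBuild(graph, meta["mode"], alt_info)
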