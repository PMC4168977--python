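"""Serialization and reproducibility plumbing.

JSON is the lossless native cluster format (every per-cell field
round-trips bit-for-bit); Newick is offered for interchange with tree
tooling, with unit branch lengths (one generation per edge) and dead
cells tagged in the node label.  Every CLI results file is accompanied
by a run manifest recording the command, full configuration and master
seed needed to regenerate it.
"""

from __future__ import annotations

import dataclasses
import json
import sys
import time
from typing import Any

import dendropy
import yaml

from .cluster import NO_PARENT, Cluster
from .evolution import EvoConfig
from .popsim import SimConfig

__all__ = [
    "cluster_to_dict",
    "cluster_from_dict",
    "cluster_to_json",
    "cluster_from_json",
    "cluster_to_newick",
    "export_cluster",
    "config_to_yaml",
    "sim_config_from_yaml",
    "evo_config_from_yaml",
    "RunManifest",
    "write_manifest",
]


def cluster_to_dict(cluster: Cluster) -> dict[str, Any]:
    return {
        "founding_gen": cluster.founding_gen,
        "cells": [
            {
                "id": c.id,
                "parent": c.parent,
                "birth_gen": c.birth_gen,
                "last_repro_gen": c.last_repro_gen,
                "alive": c.alive,
                "shell": c.shell,
                "links_used": c.links_used,
            }
            for c in cluster.cells()
        ],
    }


def cluster_from_dict(data: dict[str, Any]) -> Cluster:
    cluster = Cluster(founding_gen=data["founding_gen"])
    for rec in sorted(data["cells"], key=lambda r: r["id"]):
        parent = NO_PARENT if rec["parent"] is None else rec["parent"]
        if parent != NO_PARENT and parent >= rec["id"]:
            raise ValueError("cells must be topologically ordered (parent id < id)")
        cid = cluster._add_cell(
            parent,
            rec["birth_gen"],
            alive=rec["alive"],
            shell=rec["shell"],
            last_repro=rec["last_repro_gen"],
        )
        if cid != rec["id"]:
            raise ValueError("cell ids must be dense 0..n-1")
    # overwrite the link counts so bud scars survive the round trip
    cluster._links_used = [rec["links_used"] for rec in sorted(data["cells"], key=lambda r: r["id"])]
    return cluster


def cluster_to_json(cluster: Cluster) -> str:
    return json.dumps(cluster_to_dict(cluster), indent=None, sort_keys=True)


def cluster_from_json(text: str) -> Cluster:
    return cluster_from_dict(json.loads(text))


def cluster_to_newick(cluster: Cluster) -> str:
    """Newick string with unit branch lengths; dead cells labeled ``|dead``."""
    nodes: list[dendropy.Node] = []
    for c in cluster.cells():
        node = dendropy.Node()
        node.label = f"c{c.id}" + ("" if c.alive else "_dead")
        if c.parent is not None:
            node.edge.length = 1
        nodes.append(node)
    for c in cluster.cells():
        if c.parent is not None:
            nodes[c.parent].add_child(nodes[c.id])
    tree = dendropy.Tree(seed_node=nodes[cluster.root_id])
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        suppress_leaf_node_labels=False,
    ).strip()


def export_cluster(cluster: Cluster, fmt: str) -> str:
    """Serialize a cluster to ``newick`` or (lossless) ``json`` text."""
    if fmt == "json":
        return cluster_to_json(cluster)
    if fmt == "newick":
        return cluster_to_newick(cluster)
    raise ValueError("format must be 'newick' or 'json'")


# -- configuration ---------------------------------------------------


def config_to_yaml(config: SimConfig | EvoConfig) -> str:
    data = dataclasses.asdict(config)
    if "mutation_range" in data:
        data["mutation_range"] = list(data["mutation_range"])
    return yaml.safe_dump(data, sort_keys=True)


def sim_config_from_yaml(text: str) -> SimConfig:
    data = yaml.safe_load(text) or {}
    return SimConfig(**data)


def evo_config_from_yaml(text: str) -> EvoConfig:
    data = yaml.safe_load(text) or {}
    if "mutation_range" in data:
        data["mutation_range"] = tuple(data["mutation_range"])
    return EvoConfig(**data)


# -- manifests --------------------------------------------------------


@dataclasses.dataclass
class RunManifest:
    """Provenance record written next to every CLI results file."""

    command: str
    config: dict[str, Any]
    seed: int | None
    outputs: list[str]
    package_version: str
    timestamp: str


def write_manifest(
    out_path: str,
    command: str,
    config: dict[str, Any],
    seed: int | None,
) -> str:
    from . import __version__

    manifest = RunManifest(
        command=command,
        config=config,
        seed=seed,
        outputs=[out_path],
        package_version=__version__,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    path = f"{out_path}.manifest.json"
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(manifest), fh, indent=2, sort_keys=True)
    return path
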