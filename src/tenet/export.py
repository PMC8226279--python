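"""Graph serialisation (GEXF/GraphML) and partition tables."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .ssn import Partition

__all__ = ["write_graph", "read_graph", "attach_partition",
           "write_partition_tsv", "read_partition_tsv"]

_FORMATS = ("gexf", "graphml")


def _resolve_format(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported graph format {fmt!r}; choose from {_FORMATS}")
    return fmt


def write_graph(net: nx.Graph, path: str | Path, fmt: str | None = None) -> None:
    """Serialise a network with all node/edge attributes preserved.

    GEXF is the default interchange with external layout/visualisation
    tools; GraphML is offered for everything else. Both round-trip through
    :func:`read_graph` losslessly (node set, edge set, weights, attributes).
    """
    path = Path(path)
    fmt = _resolve_format(path, fmt)
    if fmt == "gexf":
        nx.write_gexf(net, path)
    else:
        nx.write_graphml(net, path)


def read_graph(path: str | Path, fmt: str | None = None) -> nx.Graph:
    path = Path(path)
    fmt = _resolve_format(path, fmt)
    if fmt == "gexf":
        net = nx.read_gexf(path, node_type=str)
        # networkx stores its own bookkeeping ('label') on read; drop it so
        # a write->read->write cycle is stable
        for _, data in net.nodes(data=True):
            data.pop("label", None)
    else:
        net = nx.read_graphml(path, node_type=str)
    return net


def attach_partition(net: nx.Graph, partition: Partition,
                     attr: str = "cluster_id") -> None:
    """Record a partition as a node attribute (for export colouring)."""
    for node, cid in partition.mapping.items():
        net.nodes[node][attr] = int(cid)


def write_partition_tsv(partition: Partition, path: str | Path) -> None:
    rows = sorted(partition.mapping.items())
    df = pd.DataFrame(rows, columns=["node", "cluster_id"])
    df["method"] = partition.method
    df.to_csv(path, sep="\t", index=False)


def read_partition_tsv(path: str | Path) -> Partition:
    df = pd.read_csv(path, sep="\t", dtype={"node": str})
    method = str(df["method"].iloc[0]) if len(df) else "unknown"
    return Partition(mapping={r.node: int(r.cluster_id) for r in df.itertuples()},
                     method=method)
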