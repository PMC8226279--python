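"""End-to-end pipeline runner with a reproducibility manifest.

A run is described by a small YAML/dict config naming the input tables and
the clustering parameters; outputs (networks, partitions, statistics tables)
land in one run directory together with a manifest recording the config
hash, seeds and input digests. Statistics tables are byte-identical across
reruns with the same config and seeds.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from . import content_net as cn
from . import export, repeat_io, ssn

__all__ = ["run_pipeline", "load_config"]


def load_config(path: str | Path) -> dict:
    with Path(path).open() as fh:
        return yaml.safe_load(fh)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_pipeline(config: Mapping[str, Any] | str | Path,
                 outdir: str | Path) -> Path:
    """Execute build -> cluster -> stats -> export for the configured inputs.

    Config keys: ``inputs`` (paths: copies, optional hits, annotations),
    ``ssn`` (min_length, max_evalue, resolution, seed), ``bipartite``
    (metric, resolution, seed). Missing input files are enumerated before
    any computation starts.
    """
    if not isinstance(config, Mapping):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    inputs = {k: Path(v) for k, v in config.get("inputs", {}).items()}
    missing = [f"{k}: {v}" for k, v in inputs.items() if not v.exists()]
    if missing:
        raise FileNotFoundError("missing input files: " + "; ".join(missing))
    if "copies" not in inputs:
        raise ValueError("config must name an 'inputs: copies:' table")

    copies = repeat_io.read_copies_tsv(inputs["copies"])
    annotations = (repeat_io.read_annotations_tsv(inputs["annotations"])
                   if "annotations" in inputs else [])

    ssn_cfg = dict(config.get("ssn", {}))
    bip_cfg = dict(config.get("bipartite", {}))

    if "hits" in inputs:
        hits = repeat_io.read_hits_tsv(inputs["hits"])
        net = ssn.build_ssn(hits, copies,
                            min_copy_length=int(ssn_cfg.get("min_length", 0)),
                            max_evalue=ssn_cfg.get("max_evalue"))
        part = ssn.louvain_partition(net,
                                     resolution=float(ssn_cfg.get("resolution", 1.0)),
                                     seed=int(ssn_cfg.get("seed", 0)))
        export.attach_partition(net, part)
        export.write_graph(net, outdir / "ssn.gexf")
        export.write_partition_tsv(part, outdir / "ssn_partition.tsv")
        ssn.cluster_composition(net, part).to_csv(
            outdir / "ssn_clusters.tsv", sep="\t", index=False)

    if annotations:
        bnet = cn.build_content_network(copies, annotations,
                                        metric=bip_cfg.get("metric", "total_bp"))
        bpart = ssn.louvain_partition(bnet,
                                      resolution=float(bip_cfg.get("resolution", 1.0)),
                                      seed=int(bip_cfg.get("seed", 0)))
        export.attach_partition(bnet, bpart)
        export.write_graph(bnet, outdir / "bipartite.gexf")
        cn.genome_statistics(bnet).to_csv(outdir / "genome_stats.tsv", sep="\t")
    cn.family_summary(copies).to_csv(outdir / "family_summary.tsv",
                                     sep="\t", index=False)

    manifest = {
        "tool": "tenet",
        "version": __version__,
        "command": "run_pipeline",
        "config": dict(config),
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()).hexdigest(),
        "seeds": {"ssn": int(ssn_cfg.get("seed", 0)),
                  "bipartite": int(bip_cfg.get("seed", 0))},
        "input_sha256": {k: _sha256(v) for k, v in inputs.items()},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    with (outdir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return outdir
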