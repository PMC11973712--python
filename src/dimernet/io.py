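"""Serialization of networks, profiles and run configuration.

Networks travel as JSON documents with 1-based monomer indices (the
user-facing convention; everything in memory is 0-based):

    {"m": 3, "edges": [[1, 2], [2, 3], [3, 3]], "K": [...],
     "totals": [...], "input_indices": [1]}

Floats are written with Python's shortest round-trip repr, so a
save/load cycle is lossless.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from .network import ConcentrationProfile, DimerizationNetwork

__all__ = ["load_network", "save_network", "network_to_dict", "network_from_dict",
           "load_config", "write_manifest"]


class NetworkFileError(ValueError):
    """Malformed or invalid network document."""


def network_to_dict(
    network: DimerizationNetwork, profile: ConcentrationProfile | None = None
) -> dict:
    doc = {
        "m": network.m,
        "edges": [[i + 1, j + 1] for i, j in network.edges],
        "K": list(network.K),
    }
    if profile is not None:
        doc["totals"] = list(profile.totals)
        doc["input_indices"] = [i + 1 for i in profile.input_indices]
    return doc


def network_from_dict(doc: dict) -> tuple[DimerizationNetwork, ConcentrationProfile | None]:
    for field in ("m", "edges", "K"):
        if field not in doc:
            raise NetworkFileError(f"missing required field {field!r}")
    try:
        m = int(doc["m"])
        edges = tuple((int(i) - 1, int(j) - 1) for i, j in doc["edges"])
    except (TypeError, ValueError) as err:
        raise NetworkFileError(f"malformed field 'edges': {err}") from err
    kvals = doc["K"]
    if len(kvals) != len(edges):
        raise NetworkFileError("field 'K' must align with 'edges'")
    for k in kvals:
        if not (isinstance(k, (int, float)) and k > 0):
            raise NetworkFileError(f"field 'K' must contain positive numbers, got {k!r}")
    try:
        net = DimerizationNetwork(m, edges, tuple(float(k) for k in kvals))
    except ValueError as err:
        raise NetworkFileError(f"invalid network: {err}") from err
    profile = None
    if "totals" in doc:
        totals = doc["totals"]
        if len(totals) != m:
            raise NetworkFileError("field 'totals' must have one entry per monomer")
        inputs = tuple(int(i) - 1 for i in doc.get("input_indices", []))
        try:
            profile = ConcentrationProfile(tuple(float(t) for t in totals), inputs)
        except ValueError as err:
            raise NetworkFileError(f"invalid profile: {err}") from err
    return net, profile


def save_network(
    path, network: DimerizationNetwork, profile: ConcentrationProfile | None = None
) -> None:
    Path(path).write_text(json.dumps(network_to_dict(network, profile), indent=1))


def load_network(path) -> tuple[DimerizationNetwork, ConcentrationProfile | None]:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as err:
        raise NetworkFileError(f"not valid JSON: {err}") from err
    return network_from_dict(doc)


def load_config(path) -> dict:
    """YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def write_manifest(out_dir, command: str, config: dict, seed=None) -> Path:
    """Provenance manifest for a CLI run: config hash, seed, version."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "command": command,
        "config": config,
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "seed": seed,
        "version": __version__,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=str))
    return path
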