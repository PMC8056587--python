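"""Shared readers/writers and run manifests."""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .errors import ParameterError


def read_gene_list(path) -> list[str]:
    """Newline-delimited gene symbols; blanks and '#' comments ignored."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line.upper())
    if not genes:
        raise ParameterError(f"gene list {path} is empty")
    return genes


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(str(g) + "\n")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ParameterError(f"config {path} must be a YAML mapping")
    return cfg


def write_manifest(outdir, subcommand: str, params: dict) -> None:
    """Record the fully resolved run configuration (no wall-clock fields, so
    reruns with identical inputs produce byte-identical manifests)."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    doc = {
        "subcommand": subcommand,
        "version": __version__,
        "params": {k: _jsonable(v) for k, v in sorted(params.items())},
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


def _jsonable(v):
    if isinstance(v, Path):
        return str(v)
    if isinstance(v, tuple):
        return list(v)
    return v
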