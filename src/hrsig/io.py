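"""Dataset readers/writers and run configuration.

A cohort directory holds:

* ``phenotype.csv``   — id, diagnosis, age, motion, site, severity, carrier
* ``connectivity.npy``— float array (n_individuals, n_networks, n_units)
* ``meta.json``       — ids and array shape, for schema validation
* ``generator.yaml``  — the full generator config, when the cohort is synthetic

Round-trips are lossless; shape/id mismatches raise errors naming both counts.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synth import CohortDataset, GeneratorConfig

__all__ = ["read_cohort", "write_cohort", "read_config", "write_config"]


def write_cohort(dataset: CohortDataset, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    # %.17g guarantees float64 -> text -> float64 is the identity
    dataset.phenotype.to_csv(path / "phenotype.csv", index=False, float_format="%.17g")
    np.save(path / "connectivity.npy", dataset.connectivity)
    meta = {
        "ids": list(dataset.phenotype["id"]),
        "shape": list(dataset.connectivity.shape),
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    if dataset.config is not None:
        write_config(dataset.config, path / "generator.yaml")
    return path


def read_cohort(path: str | Path) -> CohortDataset:
    path = Path(path)
    phen_file = path / "phenotype.csv"
    conn_file = path / "connectivity.npy"
    for f in (phen_file, conn_file):
        if not f.exists():
            raise FileNotFoundError(f"cohort directory {path} is missing {f.name}")
    phenotype = pd.read_csv(phen_file, float_precision="round_trip")
    connectivity = np.load(conn_file)
    if len(phenotype) != connectivity.shape[0]:
        raise ValueError(
            f"phenotype has {len(phenotype)} rows but connectivity has "
            f"{connectivity.shape[0]} individuals"
        )
    meta_file = path / "meta.json"
    if meta_file.exists():
        meta = json.loads(meta_file.read_text())
        if meta.get("ids") != list(phenotype["id"]):
            raise ValueError("meta.json ids do not match phenotype.csv ids")
        if tuple(meta.get("shape", ())) != connectivity.shape:
            raise ValueError(
                f"meta.json shape {meta.get('shape')} does not match array shape "
                f"{list(connectivity.shape)}"
            )
    config = None
    cfg_file = path / "generator.yaml"
    if cfg_file.exists():
        config = read_config(cfg_file)
    if "carrier" in phenotype.columns:
        phenotype["carrier"] = phenotype["carrier"].astype(bool)
    return CohortDataset(connectivity=connectivity, phenotype=phenotype, config=config)


def write_config(config: GeneratorConfig, path: str | Path) -> Path:
    path = Path(path)
    d = dataclasses.asdict(config)
    d["signature_networks"] = list(d["signature_networks"])
    path.write_text(yaml.safe_dump(d, sort_keys=True))
    return path


def read_config(path: str | Path) -> GeneratorConfig:
    raw = yaml.safe_load(Path(path).read_text())
    valid = {f.name for f in dataclasses.fields(GeneratorConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(
            f"unknown config keys {sorted(unknown)}; valid keys are {sorted(valid)}"
        )
    if "signature_networks" in raw:
        raw["signature_networks"] = tuple(raw["signature_networks"])
    return GeneratorConfig(**raw)
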