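"""Packaged reference parameter sets and parameter-file IO.

Three named sets share the reference species counts (2500 tRNAs, 500
ribosomes, 100 transcripts of 300 codons, k_speed = 0.02) and the
calibrated rate constants, and differ in the preferred-tRNA fraction:
``baseline`` (0.5), ``ratio07`` (0.7), ``ratio09`` (0.9).  The stored
k_charge / k_bind_eff are the closed-form calibration of the symmetric
baseline to an 88% charged and 88% active fraction; see
:func:`twocodon.core_model.calibrate`.
"""

from __future__ import annotations

import importlib.resources
import json
from pathlib import Path

import yaml

from .core_model import ModelParams

__all__ = ["load_reference_params", "reference_names", "load_params", "save_params"]

_DATA = importlib.resources.files("twocodon") / "data" / "reference_params.yaml"


def _all_sets() -> dict:
    return yaml.safe_load(_DATA.read_text())


def reference_names() -> list[str]:
    return sorted(_all_sets())


def load_reference_params(name: str) -> ModelParams:
    """One of the packaged parameter sets: baseline | ratio07 | ratio09."""
    sets = _all_sets()
    if name not in sets:
        raise KeyError(
            f"unknown parameter set {name!r}; available: {sorted(sets)}"
        )
    return ModelParams.from_dict(sets[name])


def load_params(path: str | Path) -> ModelParams:
    """Read a ModelParams YAML/JSON file (field names as in the type)."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of ModelParams fields")
    return ModelParams.from_dict(data)


def save_params(params: ModelParams, path: str | Path) -> None:
    path = Path(path)
    d = params.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
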