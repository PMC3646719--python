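"""YAML run-configuration loading and saving.

A single YAML file carries the generator spec, the coding scheme, the
cohort settings and the bootstrap settings used by the command-line
interface.  Only scalar fields are exposed in YAML; array-valued
defaults (entry-age distribution, item distributions, true transition
coefficients) are taken from the package defaults unless overridden
programmatically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict

import numpy as np
import yaml

from .bootstrap import BootstrapConfig
from .synthetic import TruePopulationSpec

__all__ = ["load_population_spec", "save_population_spec", "load_bootstrap_config", "config_hash"]

_POP_SCALARS = (
    "n_subjects",
    "sex_ratio",
    "n_villages",
    "n_regions",
    "p_too_ill_given_severe",
    "aux_missing_prob",
    "age_cap",
    "seed",
)


def load_population_spec(path) -> TruePopulationSpec:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {k: raw[k] for k in _POP_SCALARS if k in raw}
    if "wave_years" in raw:
        kwargs["wave_years"] = tuple(raw["wave_years"])
    if "attrition_coefficients" in raw:
        kwargs["attrition_coefficients"] = tuple(raw["attrition_coefficients"])
    if "initial_state_distribution" in raw:
        kwargs["initial_state_distribution"] = {
            tuple(map(int, k.split("-"))): tuple(v)
            for k, v in raw["initial_state_distribution"].items()
        }
    spec = TruePopulationSpec(**kwargs)
    spec.validate()
    return spec


def save_population_spec(spec: TruePopulationSpec, path) -> None:
    data = {k: getattr(spec, k) for k in _POP_SCALARS}
    data["wave_years"] = list(spec.wave_years)
    data["attrition_coefficients"] = list(spec.attrition_coefficients)
    data["initial_state_distribution"] = {
        f"{lo}-{hi}": list(map(float, p))
        for (lo, hi), p in spec.initial_state_distribution.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def load_bootstrap_config(path) -> BootstrapConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = BootstrapConfig(**{k: raw[k] for k in raw if hasattr(BootstrapConfig, k)})
    cfg.validate()
    return cfg


def config_hash(obj) -> str:
    """Short stable hash of a config object for stamping outputs."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "__dict__"):
            return {k: v for k, v in vars(o).items() if not k.startswith("_")}
        return str(o)

    def fix_keys(o):
        if isinstance(o, dict):
            return {str(k): fix_keys(v) for k, v in o.items()}
        if isinstance(o, (list, tuple)):
            return [fix_keys(v) for v in o]
        return o

    try:
        payload = asdict(obj)
    except TypeError:
        payload = obj
    blob = json.dumps(fix_keys(payload), sort_keys=True, default=default).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
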