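"""Configuration loading and validation.

The whole model is parameterised by one YAML document (see
``data/default_config.yaml``): anthropometric formula constants, the
compartment table, the circulation topology, the injection protocol, the
HU calibration, solver settings and cohort defaults.  User files are deep
merged over the defaults; unknown top-level keys are rejected.
"""

from __future__ import annotations

import copy
import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigurationError

_KNOWN_SECTIONS = {
    "meta",
    "physiology",
    "compartments",
    "topology",
    "protocol",
    "calibration",
    "simulation",
    "metrics",
    "cohort",
}

_FRACTION_TOL = 1e-6


def load_default_config() -> dict:
    """Return a fresh copy of the packaged default configuration."""
    text = resources.files("bolusim.data").joinpath("default_config.yaml").read_text()
    cfg = yaml.safe_load(text)
    validate_config(cfg)
    return cfg


def load_config(path: str | Path | None = None) -> dict:
    """Load a config file merged over the packaged defaults.

    Parameters
    ----------
    path
        YAML file with any subset of the known sections; ``None`` returns the
        defaults unchanged.
    """
    cfg = load_default_config()
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, Mapping):
        raise ConfigurationError(f"config file {path} is not a mapping")
    cfg = deep_merge(cfg, user)
    validate_config(cfg)
    return cfg


def deep_merge(base: dict, override: Mapping) -> dict:
    """Recursively merge ``override`` into a copy of ``base``.

    Lists (e.g. the compartment table) are replaced wholesale, not merged.
    """
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, Mapping):
            out[key] = deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def validate_config(cfg: Mapping) -> None:
    """Check structural consistency; raise :class:`ConfigurationError`.

    Verifies that only known sections are present, that blood-volume
    fractions sum to 1 and systemic-branch flow fractions sum to 1 (each
    within 1e-6), and that every topology edge references a declared
    compartment.
    """
    unknown = set(cfg) - _KNOWN_SECTIONS
    if unknown:
        raise ConfigurationError(f"unknown config sections: {sorted(unknown)}")
    comps = cfg.get("compartments")
    if not comps:
        raise ConfigurationError("config has no compartments")
    names = [c["name"] for c in comps]
    if len(names) != len(set(names)):
        raise ConfigurationError("duplicate compartment names")

    bv_sum = sum(c["blood_volume_fraction"] for c in comps)
    if abs(bv_sum - 1.0) > _FRACTION_TOL:
        raise ConfigurationError(
            f"blood_volume_fraction entries sum to {bv_sum!r}, expected 1"
        )
    branch_sum = sum(
        c["flow_fraction"] for c in comps if c.get("systemic_branch", False)
    )
    if abs(branch_sum - 1.0) > _FRACTION_TOL:
        raise ConfigurationError(
            f"systemic_branch flow fractions sum to {branch_sum!r}, expected 1"
        )

    topo = cfg.get("topology", {})
    known = set(names)
    for edge in topo.get("edges", []):
        for end in ("source", "target"):
            if edge[end] not in known:
                raise ConfigurationError(
                    f"edge references unknown compartment {edge[end]!r}"
                )
    site = topo.get("injection_site")
    if site is not None and site not in known:
        raise ConfigurationError(f"unknown injection_site {site!r}")
    for tap in topo.get("output_taps", []):
        if tap not in known:
            raise ConfigurationError(f"unknown output tap {tap!r}")


def config_hash(cfg: Mapping) -> str:
    """Short provenance hash of a canonical JSON rendering of the config."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def apply_cerebral_flow_reduction(cfg: dict, factor: float) -> dict:
    """Return a config with cerebral blood flow scaled by ``factor`` in (0, 1].

    Emulates a proximal carotid stenosis: the carotid/cerebral/brain/jugular
    path carries ``factor`` times its reference flow and the deficit is
    rerouted through the descending aorta into the lower body, so cardiac
    output and per-node flow balance are preserved.
    """
    if not (0.0 < factor <= 1.0):
        raise ConfigurationError(f"flow reduction factor {factor} not in (0, 1]")
    out = copy.deepcopy(cfg)
    if factor == 1.0:
        return out
    comps = {c["name"]: c for c in out["compartments"]}
    base = comps["carotid_artery"]["flow_fraction"]
    delta = base * (1.0 - factor)

    for name in ("carotid_artery", "cerebral_artery", "brain", "jugular_vein"):
        comps[name]["flow_fraction"] *= factor
    comps["svc"]["flow_fraction"] -= delta
    for name in ("descending_aorta", "iliac_artery", "lower_body", "ivc"):
        comps[name]["flow_fraction"] += delta

    scaled_edges = {
        ("aortic_arch", "carotid_artery"),
        ("carotid_artery", "cerebral_artery"),
        ("cerebral_artery", "brain"),
        ("brain", "jugular_vein"),
        ("jugular_vein", "svc"),
    }
    bumped_edges = {
        ("aortic_arch", "descending_aorta"),
        ("descending_aorta", "iliac_artery"),
        ("iliac_artery", "lower_body"),
        ("lower_body", "ivc"),
        ("ivc", "right_atrium"),
    }
    shrunk_edges = {("svc", "right_atrium")}
    for edge in out["topology"]["edges"]:
        key = (edge["source"], edge["target"])
        if key in scaled_edges:
            edge["flow_fraction"] *= factor
        elif key in bumped_edges:
            edge["flow_fraction"] += delta
        elif key in shrunk_edges:
            edge["flow_fraction"] -= delta
    return out
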