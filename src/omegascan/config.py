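"""Pipeline configuration: defaults file, user overrides, validation."""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigurationError
from .scan import WindowSpec
from .simulate import SimulationConfig
from .genetics import SpeciesTree


def default_config() -> dict[str, Any]:
    text = importlib.resources.files("omegascan").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


# mappings that are data, not option groups: a user value replaces the
# default wholesale instead of merging key-by-key
_REPLACE_KEYS = {"category_sizes", "branch_multipliers", "chromosomes"}


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for key, value in override.items():
        if (
            key not in _REPLACE_KEYS
            and isinstance(value, Mapping)
            and isinstance(out.get(key), dict)
        ):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None, **overrides: Any) -> dict[str, Any]:
    """Defaults, overlaid with a user YAML file, overlaid with kwargs."""
    cfg = default_config()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(user, dict):
            raise ConfigurationError(f"config file {path} is not a mapping")
        cfg = _deep_merge(cfg, user)
    cfg = _deep_merge(cfg, {k: v for k, v in overrides.items() if v is not None})
    validate_config(cfg)
    return cfg


def validate_config(cfg: Mapping[str, Any]) -> None:
    """Check every numeric option against its module's preconditions."""
    try:
        window_spec(cfg)
    except ValueError as exc:
        raise ConfigurationError(f"invalid window spec: {exc}") from None
    bg = cfg["background"]
    if bg["radius_bp"] <= 0 or bg["ds_tolerance"] < 0:
        raise ConfigurationError("background radius_bp must be > 0 and ds_tolerance >= 0")
    if cfg["divergence"]["saturation_threshold"] <= 0:
        raise ConfigurationError("saturation_threshold must be > 0")
    if cfg["paired"]["window_on"] not in ("omega", "dS"):
        raise ConfigurationError("paired.window_on must be 'omega' or 'dS'")
    simulation_config(cfg)  # raises ConfigurationError on bad values


def window_spec(cfg: Mapping[str, Any]) -> WindowSpec:
    w = cfg["windows"]
    return WindowSpec(
        width=float(w["width"]),
        slide=float(w["slide"]),
        percentile=float(w["percentile"]),
        min_genes=int(w["min_genes"]),
    )


def simulation_config(cfg: Mapping[str, Any], seed: int | None = None) -> SimulationConfig:
    s = cfg["simulation"]
    tree = SpeciesTree.default(
        terminal_length=float(s["terminal_length"]),
        internal_length=float(s["internal_length"]),
        outgroup_length=float(s["outgroup_length"]),
    )
    return SimulationConfig(
        n_genes=int(s["n_genes"]),
        n_codons_range=(int(s["n_codons_min"]), int(s["n_codons_max"])),
        kappa=float(s["kappa"]),
        omega_distribution=("lognormal", (float(s["omega_median"]), float(s["omega_log_sd"]))),
        branch_multipliers={
            str(c): {str(b): float(m) for b, m in bm.items()}
            for c, bm in (s.get("branch_multipliers") or {}).items()
        },
        tree=tree,
        chromosomes=tuple((str(n), int(l)) for n, l in s["chromosomes"]),
        gene_spacing=float(s["gene_spacing"]),
        category_sizes={str(c): int(v) for c, v in (s.get("category_sizes") or {}).items()},
        rate_heterogeneity_shape=float(s["rate_heterogeneity_shape"]),
        saturation_fraction=float(s["saturation_fraction"]),
        saturation_scale=float(s["saturation_scale"]),
        seed=int(seed if seed is not None else cfg.get("seed", 0)),
    )
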