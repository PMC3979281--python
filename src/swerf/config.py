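"""YAML configuration loading.

A flat key-value file can override the convention parameters and the PSD
reader defaults, e.g.::

    inhalable_decay: 0.06
    respirable_median: 4.25
    respirable_gsd: 1.5
    psd.dialect: cumulative_passing
    psd.diameter_basis: spherical_equivalent
"""

from __future__ import annotations

from typing import Mapping, Optional

import yaml

from .conventions import ConventionParams
from .exceptions import ConfigurationError

__all__ = ["load_config", "convention_params_from_config"]

_CONVENTION_KEYS = ("inhalable_decay", "respirable_median", "respirable_gsd")
_PSD_KEYS = ("psd.dialect", "psd.diameter_basis", "psd.n_bins")


def load_config(path) -> dict:
    """Load a flat YAML config, rejecting unknown keys."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, Mapping):
        raise ConfigurationError("config file must contain a key-value mapping")
    unknown = set(data) - set(_CONVENTION_KEYS) - set(_PSD_KEYS)
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return dict(data)


def convention_params_from_config(
    config: Optional[Mapping] = None,
) -> ConventionParams:
    """Build ConventionParams from a config mapping, using defaults for
    absent keys."""
    config = config or {}
    kwargs = {k: float(config[k]) for k in _CONVENTION_KEYS if k in config}
    return ConventionParams(**kwargs)
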