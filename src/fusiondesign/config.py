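"""YAML run configuration: one structured file mirroring the CLI flags.

Example::

    input:
      carcass_path: carcass.csv
      flight_path: flights.csv
      species_group: geese
      delimiter: ","
      column_map:
        n_carcass: Sum_carcass
        interval_days: days
    simulation:
      scenario: base
      n_sims: 1000
      null_fraction: 0.5
      seed: 1
      n_obs_per_cell: 60
    evaluation:
      alpha: 0.05

CLI flags override config values; unset keys fall back to defaults.
"""

from __future__ import annotations

from pathlib import Path

import yaml

__all__ = ["load_config", "merged"]


def load_config(path) -> dict:
    if path is None:
        return {}
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping at top level")
    return data


def merged(config: dict, section: str, **cli_values) -> dict:
    """Section of the config overridden by any non-None CLI values."""
    out = dict(config.get(section, {}) or {})
    for key, value in cli_values.items():
        if value is not None:
            out[key] = value
    return out
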