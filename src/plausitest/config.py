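"""Configuration files for simulation scenarios (YAML or JSON).

A scenario file is a flat mapping validated strictly against the
:class:`~plausitest.simulate.ScenarioSpec` schema — unknown keys are
rejected before any computation.  The ``effect_prior`` entry is either a
named family (``{family: lognormal, params: [median, sigma_log]}`` or
``{family: point, params: [delta]}``) or explicit ``nodes``/``weights`` on
the log variance-ratio axis.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .errors import DomainError
from .simulate import ScenarioSpec

__all__ = ["load_scenario", "dump_scenario"]


def load_scenario(path: str | Path) -> ScenarioSpec:
    """Read and validate a scenario configuration from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise DomainError(f"scenario file {path} must contain a mapping at top level")
    return ScenarioSpec.from_dict(raw)


def dump_scenario(spec: ScenarioSpec, path: str | Path) -> None:
    """Write a scenario back to YAML (round-trips through load_scenario)."""
    Path(path).write_text(yaml.safe_dump(spec.to_dict(), sort_keys=True))
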