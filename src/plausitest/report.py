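"""Human- and machine-readable report bundles for the command-line tools.

Every report echoes all inputs, including defaulted ones, so that each
number it prints can be regenerated from the report alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

__all__ = ["ReportBundle"]


@dataclass
class ReportBundle:
    """Inputs, results and warnings of one command invocation."""

    title: str
    inputs: dict = field(default_factory=dict)
    results: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def render(self) -> str:
        lines = [self.title, "=" * len(self.title), "", "inputs:"]
        for k, v in self.inputs.items():
            lines.append(f"  {k}: {_fmt(v)}")
        lines.append("results:")
        for k, v in self.results.items():
            lines.append(f"  {k}: {_fmt(v)}")
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(
            {
                "title": self.title,
                "inputs": self.inputs,
                "results": self.results,
                "warnings": self.warnings,
            },
            indent=2,
            sort_keys=True,
            default=str,
        )


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)
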