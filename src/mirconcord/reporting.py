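"""Effect-size and run-level summary reporting."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path


@dataclass
class EffectReport:
    reference_mean: float
    alternative_mean: float
    percent_change: float
    rounded_percent: int


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def percent_change(reference_mean: float, alternative_mean: float) -> EffectReport:
    """Signed percent change of a group mean relative to a reference mean.

    percent = 100 * (alternative - reference) / reference, with the display
    value rounded half-away-from-zero to an integer percent.
    """
    if reference_mean == 0:
        raise ValueError("reference mean must be non-zero")
    pct = 100.0 * (alternative_mean - reference_mean) / reference_mean
    return EffectReport(reference_mean, alternative_mean, pct, _round_half_away(pct))


REQUIRED_KEYS = {
    "parameters": dict,
    "seed": (int, type(None)),
    "stages": dict,
    "warnings": list,
}


def run_summary(
    stages: dict | None = None,
    parameters: dict | None = None,
    seed: int | None = None,
    warnings: list | None = None,
) -> dict:
    """Machine-readable run report with a stable key order.

    ``stages`` maps a stage name to its count/metric dict (evaluated,
    significant, called, classified...).  The same inputs always produce an
    identical report, so two runs with one config and seed are comparable
    byte for byte.
    """
    report = {
        "parameters": dict(sorted((parameters or {}).items())),
        "seed": seed,
        "stages": {k: dict(sorted(v.items())) for k, v in sorted((stages or {}).items())},
        "warnings": list(warnings or []),
    }
    validate_summary(report)
    return report


def validate_summary(report: dict) -> None:
    """Structural check against the shipped run-summary schema."""
    schema = json.loads(
        resources.files("mirconcord").joinpath("schemas/run_summary.schema.json").read_text()
    )
    for key, spec in schema["properties"].items():
        if key in schema.get("required", []) and key not in report:
            raise ValueError(f"run summary missing key {key!r}")
    for key, typ in REQUIRED_KEYS.items():
        if not isinstance(report.get(key, None), typ):
            raise ValueError(f"run summary key {key!r} has wrong type")


def write_summary(report: dict, path: str | Path) -> None:
    validate_summary(report)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
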