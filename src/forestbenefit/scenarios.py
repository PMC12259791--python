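"""Management scenarios and intervention-level analytics.

Scenarios are declarative lever sets: harvest level as a share of landscape
net growth, rotation prolongation, set-aside share, fertilised area, slash and
stump extraction intensities and fast-growing-species planting.  Shipped YAML
fixtures cover business-as-usual, the reduced-harvest and intensified
variants, the high-intervention replications of earlier studies, and the
Swedish Forest Agency's recommended maximum intervention levels.

Intervention ratios (scenario level / recommended or reference level) are the
quantity used to judge how far a study's scenario design exceeds what the
agency considers an acceptable maximum potential.
"""

from __future__ import annotations

import decimal
from dataclasses import asdict, dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import NamedTuple

import yaml

__all__ = [
    "ManagementScenario",
    "RecommendedLevels",
    "InterventionRatio",
    "load_scenario",
    "scenario_to_dict",
    "save_scenario",
    "load_recommended_levels",
    "fixture_path",
    "list_fixtures",
    "intervention_ratio",
    "ratio_range",
    "LEVER_FIELDS",
]


@dataclass(frozen=True)
class ManagementScenario:
    """One management scenario's lever set.

    Units: ``harvest_target_fraction`` and ``set_aside_fraction`` are
    dimensionless shares; ``rotation_delta`` years; ``fertilized_area`` and
    ``contorta_area`` hectares per year; ``slash_extraction`` and
    ``stump_extraction`` tonnes dry matter per hectare (of total landscape
    area) per year.
    """

    name: str = "bau"
    harvest_target_fraction: float = 0.95
    rotation_delta: float = 0.0
    set_aside_fraction: float = 0.103
    fertilized_area: float = 2100.0
    slash_extraction: float = 0.078
    stump_extraction: float = 0.0
    contorta_area: float = 0.0
    substitution: dict | None = None   # optional RS / DF+share block

    def __post_init__(self) -> None:
        problems = []
        if not 0.0 <= self.harvest_target_fraction <= 1.2:
            problems.append("harvest_target_fraction must lie in [0, 1.2]")
        if not 0.0 <= self.set_aside_fraction <= 1.0:
            problems.append("set_aside_fraction must lie in [0, 1]")
        for name in ("fertilized_area", "slash_extraction", "stump_extraction",
                     "contorta_area"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be non-negative")
        if problems:
            raise ValueError("invalid scenario: " + "; ".join(problems))


@dataclass(frozen=True)
class RecommendedLevels:
    """Acceptable-maximum intervention levels (agency recommendations)."""

    set_aside_fraction: float = 0.309
    fertilized_area: float = 6300.0
    slash_extraction: float = 0.18
    stump_extraction: float = 0.013
    contorta_area: float = 1504.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be strictly positive")


#: levers compared between scenarios and recommendations
LEVER_FIELDS = ("set_aside_fraction", "fertilized_area", "slash_extraction",
                "stump_extraction", "contorta_area")

_SCENARIO_KEYS = {f.name for f in fields(ManagementScenario)}


def _fixture_dir():
    return resources.files("forestbenefit") / "fixtures"


def fixture_path(name: str) -> Path:
    """Path of a shipped scenario fixture (name without extension)."""
    p = _fixture_dir() / "scenarios" / f"{name}.yaml"
    return Path(str(p))


def list_fixtures() -> list[str]:
    """Names of all shipped scenario fixtures."""
    d = Path(str(_fixture_dir() / "scenarios"))
    return sorted(p.stem for p in d.glob("*.yaml"))


def load_scenario(config) -> ManagementScenario:
    """Load and validate a scenario from a YAML path, mapping, or fixture name.

    Unknown keys are rejected; invariant violations raise ``ValueError``
    naming the offending field.
    """
    if isinstance(config, ManagementScenario):
        return config
    if isinstance(config, (str, Path)):
        path = Path(config)
        if not path.exists() and isinstance(config, str) and "/" not in config:
            path = fixture_path(config)
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "name" not in data:
            data["name"] = path.stem
    elif isinstance(config, dict):
        data = dict(config)
    else:
        raise TypeError(f"cannot load a scenario from {type(config).__name__}")
    unknown = set(data) - _SCENARIO_KEYS
    if unknown:
        raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
    return ManagementScenario(**data)


def scenario_to_dict(scenario: ManagementScenario) -> dict:
    d = asdict(scenario)
    if d.get("substitution") is None:
        d.pop("substitution")
    return d


def save_scenario(scenario: ManagementScenario, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(scenario), fh, sort_keys=False)


def load_recommended_levels(path=None) -> RecommendedLevels:
    """Load the recommended maximum intervention levels registry."""
    p = Path(path) if path else Path(str(_fixture_dir() / "recommended_levels.yaml"))
    with open(p) as fh:
        data = yaml.safe_load(fh) or {}
    allowed = {f.name for f in fields(RecommendedLevels)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown recommended-level keys: {sorted(unknown)}")
    return RecommendedLevels(**data)


class InterventionRatio(NamedTuple):
    """A scenario-vs-reference intervention ratio."""

    lever: str
    factor: float      # rounded half-up to 1 decimal, for reporting
    exact: float


def _round_half_up(x: float, decimals: int = 1) -> float:
    q = decimal.Decimal(10) ** -decimals
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def intervention_ratio(scenario_level: float, reference_level: float,
                       lever: str = "") -> InterventionRatio:
    """Ratio of a scenario's intervention level to a reference level.

    The reported factor is rounded half-up to one decimal; the exact quotient
    is retained alongside.
    """
    if reference_level <= 0:
        raise ValueError("reference level must be strictly positive")
    exact = scenario_level / reference_level
    return InterventionRatio(lever, _round_half_up(exact), exact)


def ratio_range(scenario: ManagementScenario,
                recommendations: RecommendedLevels) -> tuple[float, float] | None:
    """(min, max) rounded ratio over levers exceeding their recommendation.

    Returns ``None`` when no lever exceeds its recommended level.
    """
    exceeding = [r.factor for r in iter_ratios(scenario, recommendations)
                 if r.exact > 1.0]
    if not exceeding:
        return None
    return min(exceeding), max(exceeding)


def iter_ratios(scenario: ManagementScenario,
                recommendations: RecommendedLevels) -> list[InterventionRatio]:
    """Intervention ratios for every lever the scenario actually uses."""
    out = []
    for lever in LEVER_FIELDS:
        level = getattr(scenario, lever)
        ref = getattr(recommendations, lever)
        if level > 0:
            out.append(intervention_ratio(level, ref, lever))
    return out
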