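"""Age/gender-stratified population distributions of model parameters.

The packaged default table holds, for each of 6 age decades x 2 genders,
the mean and SD of height, weight, heart rate, aortic distensibility,
total peripheral resistance and mean arterial pressure, compiled from
published population data. The cohort sampler draws independent
truncated Gaussians from it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

PARAMETERS = (
    "height",
    "weight",
    "heart_rate",
    "aortic_distensibility",
    "tpr",
    "map",
)
GENDERS = ("M", "F")


def default_population_path() -> Path:
    return Path(__file__).resolve().parent / "data" / "population_table.yaml"


@dataclass
class PopulationSpec:
    """Mean/SD of every sampled parameter per (age_group, gender) stratum."""

    age_groups: list[str]
    age_midpoints: dict[str, float]
    # strata[(age_group, gender)][parameter] -> (mean, sd)
    strata: dict[tuple[str, str], dict[str, tuple[float, float]]]
    floors: dict[str, float]

    def __post_init__(self) -> None:
        self.validate()

    @property
    def stratum_labels(self) -> list[tuple[str, str]]:
        """Fixed stratum order: age groups young to old, M before F."""
        return [(ag, g) for ag in self.age_groups for g in GENDERS]

    def validate(self) -> None:
        if len(self.age_groups) == 0:
            raise ValueError("no age groups")
        expected = set(self.stratum_labels)
        if set(self.strata) != expected:
            raise ValueError(
                f"strata mismatch: expected {len(expected)}, "
                f"got {len(self.strata)}"
            )
        for key, params in self.strata.items():
            for p in PARAMETERS:
                if p not in params:
                    raise ValueError(f"stratum {key}: missing parameter {p!r}")
                mean, sd = params[p]
                if sd < 0:
                    raise ValueError(f"stratum {key}, {p}: negative SD {sd}")
                if mean <= 0:
                    raise ValueError(f"stratum {key}, {p}: non-positive mean")
        for ag in self.age_groups:
            if ag not in self.age_midpoints:
                raise ValueError(f"no age midpoint for group {ag!r}")

    def mean_sd(
        self, age_group: str, gender: str, parameter: str
    ) -> tuple[float, float]:
        return self.strata[(age_group, gender)][parameter]


def load_population_spec(path: str | Path | None = None) -> PopulationSpec:
    """Load a population spec from YAML (packaged default when path is None)."""
    with open(path or default_population_path()) as fh:
        cfg = yaml.safe_load(fh)
    age_groups = list(cfg["age_groups"])
    strata: dict[tuple[str, str], dict[str, tuple[float, float]]] = {}
    for p, by_gender in cfg["parameters"].items():
        for g, by_age in by_gender.items():
            for ag, (mean, sd) in by_age.items():
                strata.setdefault((ag, g), {})[p] = (float(mean), float(sd))
    return PopulationSpec(
        age_groups=age_groups,
        age_midpoints={k: float(v) for k, v in cfg["age_midpoints"].items()},
        strata=strata,
        floors={k: float(v) for k, v in cfg.get("floors", {}).items()},
    )
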