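"""Run configuration: flat key-value files, validation, defaults, metadata.

The configuration is a flat text format, one ``key = value`` pair per line
(``#`` starts a comment), with one key per model parameter.  Unset keys take
the hematopoietic defaults (active stem pool of 100 cells dividing every 20
weeks, progenitor lifespan 20 weeks, maximal proliferation 1.5 + 0.2k per
week, maximal death rate 1.0 per week).
"""

from __future__ import annotations

import dataclasses
import datetime
from dataclasses import dataclass, field
from pathlib import Path

from ._version import __version__ as _version
from .branching import HomeostasisParams
from .moran import MoranParams
from .progenitor import DEFAULT_PROGENITOR_ADVANTAGE, ProgenitorParams

__all__ = ["SimConfig", "RunMetadata", "load_config", "save_config", "write_table"]


@dataclass(frozen=True)
class SimConfig:
    """Complete run configuration (stem + progenitor + experiment keys)."""

    model: str = "constant_N"          # constant_N | variable_N
    # stem compartment
    n_stem: int = 100                  # N (constant-size model)
    stem_cycle_weeks: float = 20.0     # tau
    stem_mutation_rate: float = 1e-5   # u per replication
    selection_s: float = 0.0           # stem-pool advantage of 2-mutation cells
    dediff_weight: float = 0.0         # d (constant-size model)
    dediff_scope: str = "two_mutation_only"
    carrying_capacity: float = 100.0   # K (variable-size model)
    asym_prob: float = 0.5             # q1
    reversion_strength: float = 3.0    # z
    dediff_rate: float = 0.0           # eta per 2-mutation progenitor per week
    exponential_intervals: bool = False
    # progenitor compartment
    max_age_weeks: float = 20.0        # A
    age_step_weeks: float = 0.05       # grid spacing = PDE time step
    birth_max: float = 1.5             # b_0 maximal proliferation
    progenitor_advantage: float = DEFAULT_PROGENITOR_ADVANTAGE
    death_max: float = 1.0
    birth_switch_age: float = 10.0     # a_b
    death_switch_age: float = 0.0      # a_d
    birth_steepness: float = 2.0       # m_b
    death_steepness: float = 2.0       # m_d
    progenitor_mutation_rate: float | None = None  # v; None -> same as u
    competition_mode: str = "none"
    progenitor_capacity: float = 1e4
    # experiment
    t_max_weeks: float = 1e5
    replicates: int = 1
    base_seed: int = 0
    record_stride: int = 10            # PDE steps between trajectory samples

    def __post_init__(self) -> None:
        if self.model not in ("constant_N", "variable_N"):
            raise ValueError("model: must be constant_N or variable_N")
        checks = [
            ("n_stem", self.n_stem >= 1),
            ("stem_cycle_weeks", self.stem_cycle_weeks > 0),
            ("stem_mutation_rate", 0 <= self.stem_mutation_rate <= 1),
            ("selection_s", self.selection_s > -1),
            ("dediff_weight", 0 <= self.dediff_weight <= 1),
            ("carrying_capacity", self.carrying_capacity >= 1),
            ("asym_prob", 0 <= self.asym_prob <= 1),
            ("reversion_strength", self.reversion_strength >= 0),
            ("dediff_rate", self.dediff_rate >= 0),
            ("t_max_weeks", self.t_max_weeks > 0),
            ("replicates", self.replicates >= 1),
            ("record_stride", self.record_stride >= 1),
            (
                "progenitor_mutation_rate",
                self.progenitor_mutation_rate is None
                or self.progenitor_mutation_rate >= 0,
            ),
        ]
        for key, ok in checks:
            if not ok:
                raise ValueError(f"{key}: value {getattr(self, key)!r} out of range")

    # -- derived parameter bundles -------------------------------------
    def progenitor_params(self) -> ProgenitorParams:
        v = self.progenitor_mutation_rate
        if v is None:
            v = self.stem_mutation_rate  # per week, numerically equal to u
        return ProgenitorParams.with_selection(
            self.progenitor_advantage,
            b_max=self.birth_max,
            max_age=self.max_age_weeks,
            age_step=self.age_step_weeks,
            death_max=self.death_max,
            birth_switch_age=self.birth_switch_age,
            death_switch_age=self.death_switch_age,
            birth_steepness=self.birth_steepness,
            death_steepness=self.death_steepness,
            mutation_rate=v,
            competition_mode=self.competition_mode,
            carrying_capacity=self.progenitor_capacity,
        )

    def moran_params(self) -> MoranParams:
        return MoranParams(
            N=self.n_stem,
            stem_mutation_rate=self.stem_mutation_rate,
            dediff_weight=self.dediff_weight,
            dediff_scope=self.dediff_scope,
            selection=self.selection_s,
            stem_cycle=self.stem_cycle_weeks,
            exponential_intervals=self.exponential_intervals,
        )

    def homeostasis_params(self) -> HomeostasisParams:
        return HomeostasisParams(
            carrying_capacity=self.carrying_capacity,
            asym_prob=self.asym_prob,
            reversion_strength=self.reversion_strength,
            stem_cycle=self.stem_cycle_weeks,
            stem_mutation_rate=self.stem_mutation_rate,
            dediff_rate=self.dediff_rate,
        )


_FIELDS = {f.name: f for f in dataclasses.fields(SimConfig)}


def _parse_value(key: str, raw: str):
    f = _FIELDS[key]
    raw = raw.strip()
    if "None" in str(f.type) and raw.lower() in ("none", ""):
        return None
    if f.type in ("bool",):
        if raw.lower() in ("true", "1", "yes"):
            return True
        if raw.lower() in ("false", "0", "no"):
            return False
        raise ValueError(f"{key}: cannot parse boolean from {raw!r}")
    if f.type == "int":
        return int(raw)
    if f.type in ("float", "float | None"):
        return float(raw)
    return raw


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> SimConfig:
    """Load a flat key-value config file; ``overrides`` (e.g. CLI flags) win.

    Unknown keys are rejected; all values are validated with the offending
    key named in the error.
    """
    values: dict = {}
    if path is not None:
        text = Path(path).read_text()
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected 'key = value', got {line!r}")
            key, raw = (part.strip() for part in line.split("=", 1))
            if key not in _FIELDS:
                raise ValueError(f"unknown configuration key {key!r}")
            values[key] = _parse_value(key, raw)
    if overrides:
        for key, val in overrides.items():
            if key not in _FIELDS:
                raise ValueError(f"unknown configuration key {key!r}")
            if val is not None:
                values[key] = val
    return SimConfig(**values)


def save_config(config: SimConfig, path: str | Path) -> None:
    """Write the full configuration as flat key-value text (round-trips)."""
    lines = []
    for f in dataclasses.fields(SimConfig):
        val = getattr(config, f.name)
        lines.append(f"{f.name} = {val if val is not None else 'none'}")
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class RunMetadata:
    """Provenance record accompanying every output table."""

    config: SimConfig
    base_seed: int
    replicate_seeds: list[int] = field(default_factory=list)
    created: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )
    version: str = _version

    def write(self, path: str | Path) -> None:
        lines = [f"# dediffsim {self.version}", f"# created {self.created}"]
        for f in dataclasses.fields(SimConfig):
            val = getattr(self.config, f.name)
            lines.append(f"{f.name} = {val if val is not None else 'none'}")
        lines.append(f"base_seed = {self.base_seed}")
        if self.replicate_seeds:
            lines.append(
                "replicate_seeds = " + ",".join(str(s) for s in self.replicate_seeds)
            )
        Path(path).write_text("\n".join(lines) + "\n")


def write_table(records, path: str | Path) -> None:
    """Write homogeneous records as CSV: header, stable column order,
    full float precision; byte-identical for identical inputs."""
    import pandas as pd

    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(list(records))
    df.to_csv(path, index=False)
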