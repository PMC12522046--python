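"""Sampling of reaction-condition text.

Condition text around a reaction arrow falls into five core roles — agent,
solvent, temperature, time, yield — plus "other" for auxiliary annotations
(pH ranges, R-group legends, atmosphere notes) that carry no role token in
serialized annotations.  Agents are drawn above the arrow; all other roles
are stacked below it.

Default vocabularies emulate common literature usage.  Names are chosen so
that none accidentally parses as SMILES (e.g. "CO" is excluded): only
SMILES-valued agent items enter the agent field of assembled reaction
SMILES, name-only agents remain textual metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rng import RNGStream
from .scheme import BBox, ConditionItem

# placeholder box; the layout engine assigns real geometry
_SENTINEL = BBox(0.0, 0.0, 1.0, 1.0)

DEFAULT_AGENTS = [
    "Pd/C", "H2", "NaBH4", "Et3N", "DMAP", "TsOH", "K2CO3",
    "AcOH", "PPh3", "CuI", "Pd(PPh3)4", "NaOH", "LiAlH4", "DIPEA",
]
DEFAULT_SOLVENTS = [
    "THF", "DMF", "DMSO", "MeOH", "EtOH", "toluene", "CH2Cl2",
    "MeCN", "dioxane", "Et2O", "H2O", "hexane",
]
DEFAULT_TEMPERATURE_FORMATS = ["{v} °C", "{v}°C", "rt", "reflux", "{v} K"]
DEFAULT_TIME_FORMATS = ["{v} h", "{v} min", "overnight"]
DEFAULT_YIELD_FORMATS = ["{v}%", "{v}% yield"]
DEFAULT_OTHER_TEXTS = [
    "pH 10–11", "N2 atmosphere", "2 steps", "dr > 20:1",
    "R = Me, Et", "0.1 M", "sealed tube", "argon",
]


@dataclass
class ConditionSpec:
    """What condition text can appear and how often."""

    agent_vocab: list[str] = field(default_factory=lambda: list(DEFAULT_AGENTS))
    solvent_vocab: list[str] = field(default_factory=lambda: list(DEFAULT_SOLVENTS))
    temperature_formats: list[str] = field(
        default_factory=lambda: list(DEFAULT_TEMPERATURE_FORMATS)
    )
    time_formats: list[str] = field(default_factory=lambda: list(DEFAULT_TIME_FORMATS))
    yield_formats: list[str] = field(default_factory=lambda: list(DEFAULT_YIELD_FORMATS))
    other_texts: list[str] = field(default_factory=lambda: list(DEFAULT_OTHER_TEXTS))
    temperature_range: tuple[int, int] = (-78, 200)
    time_range: tuple[int, int] = (1, 48)
    yield_range: tuple[float, float] = (50.0, 99.0)
    p_role_present: dict[str, float] = field(
        default_factory=lambda: {
            "agent": 0.7,
            "solvent": 0.7,
            "temperature": 0.6,
            "time": 0.5,
            "yield": 0.5,
        }
    )
    p_other: float = 0.1
    p_second_agent: float = 0.3

    def validate(self) -> None:
        vocabs = {
            "agent": self.agent_vocab,
            "solvent": self.solvent_vocab,
            "temperature": self.temperature_formats,
            "time": self.time_formats,
            "yield": self.yield_formats,
        }
        for role, p in self.p_role_present.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p_role_present[{role!r}]={p} outside [0,1]")
            if p > 0 and not vocabs.get(role):
                raise ValueError(f"role {role!r} has p>0 but an empty vocabulary")
        if not 0.0 <= self.p_other <= 1.0:
            raise ValueError(f"p_other={self.p_other} outside [0,1]")
        lo, hi = self.yield_range
        if lo > hi:
            raise ValueError("yield_range min > max")


def _realize(fmt: str, value) -> str:
    return fmt.replace("{v}", str(value)) if "{v}" in fmt else fmt


def sample_conditions(rng: RNGStream, spec: ConditionSpec) -> list[ConditionItem]:
    """Draw one arrow's worth of condition items (geometry assigned later)."""
    spec.validate()
    g = rng.generator()
    items: list[ConditionItem] = []
    p = spec.p_role_present

    if g.random() < p.get("agent", 0.0):
        n_agents = 1 + (1 if g.random() < spec.p_second_agent else 0)
        picks = g.choice(len(spec.agent_vocab), size=n_agents, replace=False)
        for i in picks:
            items.append(ConditionItem(spec.agent_vocab[int(i)], "agent", _SENTINEL))
    if g.random() < p.get("solvent", 0.0):
        items.append(
            ConditionItem(spec.solvent_vocab[int(g.integers(len(spec.solvent_vocab)))], "solvent", _SENTINEL)
        )
    if g.random() < p.get("temperature", 0.0):
        fmt = spec.temperature_formats[int(g.integers(len(spec.temperature_formats)))]
        v = int(g.integers(spec.temperature_range[0], spec.temperature_range[1] + 1))
        items.append(ConditionItem(_realize(fmt, v), "temperature", _SENTINEL))
    if g.random() < p.get("time", 0.0):
        fmt = spec.time_formats[int(g.integers(len(spec.time_formats)))]
        v = int(g.integers(spec.time_range[0], spec.time_range[1] + 1))
        items.append(ConditionItem(_realize(fmt, v), "time", _SENTINEL))
    if g.random() < p.get("yield", 0.0):
        fmt = spec.yield_formats[int(g.integers(len(spec.yield_formats)))]
        lo, hi = spec.yield_range
        v = int(round(float(g.uniform(lo, hi)))) if hi > lo else int(round(lo))
        items.append(ConditionItem(_realize(fmt, v), "yield", _SENTINEL))
    if spec.other_texts and g.random() < spec.p_other:
        items.append(
            ConditionItem(spec.other_texts[int(g.integers(len(spec.other_texts)))], "other", _SENTINEL)
        )
    return items
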