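"""Flat run configuration: presets, YAML round-trip, content hashing.

A ``RunConfig`` bundles everything a reproducible experiment needs —
pattern statistics, connectivity, integration constants, the short-term
memory boost and the serial-recall coupling strength — in one flat record
that serialises to YAML.  Presets name the dynamical regimes explored in
the accompanying examples.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import yaml

from .dynamics import CueSpec, SimConfig
from .network import BoostConfig

__all__ = ["RunConfig", "PRESETS", "make_preset", "load_config", "save_config"]


@dataclass
class RunConfig:
    """One experiment's worth of parameters, flat and serialisable."""

    # patterns / network
    p: int = 200
    N: int = 600
    c_m: int = 90
    S: int = 7
    a: float = 0.25
    # integration
    tau1: float = 0.01
    tau2: float = 0.2
    tau_A: float = 0.005
    tau_B: float = 100.0
    gamma_A: float = 0.5
    beta: float = 11.0
    U: float = 0.1
    w: float = 1.1
    dt: float | None = None
    max_updates: int = 100_000
    sample_every: int = 16
    cue_pattern: int = 0
    cue_strength: float = 1.0
    cue_duration: float = 0.1
    m_null: float = 0.1
    # short-term memory boost
    boost_model: str = "none"  # none, M1, M2, M3a, M3b
    boost_delta: float = 0.0
    stm_length: int = 0
    # serial recall
    lam: float = 0.0
    # provenance
    seed: int = 0
    preset: str = ""

    def sim_config(self) -> SimConfig:
        return SimConfig(
            tau1=self.tau1,
            tau2=self.tau2,
            tau_A=self.tau_A,
            tau_B=self.tau_B,
            gamma_A=self.gamma_A,
            beta=self.beta,
            U=self.U,
            w=self.w,
            dt=self.dt,
            max_updates=self.max_updates,
            sample_every=self.sample_every,
            cue=CueSpec(
                pattern=self.cue_pattern,
                strength=self.cue_strength,
                duration=self.cue_duration,
            ),
            m_null=self.m_null,
            seed=self.seed,
        )

    def boost_config(self, stm_list) -> BoostConfig:
        return BoostConfig(
            model=self.boost_model, delta=self.boost_delta, stm_list=tuple(stm_list)
        )

    def with_(self, **kw) -> "RunConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        return cls(**d)

    def content_hash(self) -> str:
        """Short digest of the canonical parameter set (for filenames and
        provenance records)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# Named dynamical regimes.  "free-recall" is the sweep default; the three
# inhibition presets differ in the fast/slow split gamma_A and the local
# feedback w; "serial" adds the weak heteroassociative bias that carries
# instructed order.
PRESETS: dict[str, dict] = {
    "free-recall": {"w": 1.1, "gamma_A": 0.5},
    "slow-inhibition": {"w": 0.4, "gamma_A": 0.0},
    "balanced-inhibition": {"w": 0.8, "gamma_A": 0.5},
    "fast-inhibition": {"w": 1.0, "gamma_A": 1.0},
    "serial": {
        "w": 1.0,
        "gamma_A": 0.5,
        "boost_model": "M2",
        "boost_delta": 0.1,
        "lam": 0.01,
        "p": 200,
    },
}


def make_preset(name: str, **overrides) -> RunConfig:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kw = dict(PRESETS[name])
    kw.update(overrides)
    kw["preset"] = name
    return RunConfig(**kw)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def load_config(path: str | Path) -> RunConfig:
    d = yaml.safe_load(Path(path).read_text())
    if not isinstance(d, dict):
        raise ValueError("config file must hold a mapping")
    return RunConfig.from_dict(d)
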