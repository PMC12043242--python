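"""YAML configuration profiles keyed by macrocycle size class.

Profiles bundle the annealing schedule, good-backbone criteria, energy
constants, and GA settings for the supported size classes ("7", "15",
"20", "24"), plus the desk-scale "toy" profile and "predict-small" for
sequence-only prediction.  The packaged defaults live in
``data/profiles.yaml``; a user file with the same layout can override any
subset of keys.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from importlib import resources
from pathlib import Path

import yaml

from .annealer import AnnealSchedule, GoodBackboneCriteria, LayerSpec
from .clustergen import GAConfig, population_schedule
from .energy import DEFAULT_PARAMS, EnergyParams

__all__ = ["load_profiles", "get_profile", "Profile", "config_hash"]


class Profile:
    """One named bundle of schedule + criteria + GA settings."""

    def __init__(self, name: str, raw: dict):
        self.name = name
        self.raw = raw

    @property
    def n(self) -> int:
        return int(self.raw.get("n", 7))

    def schedule(self) -> AnnealSchedule:
        s = self.raw.get("sa", {})
        layers = tuple(
            LayerSpec(d["name"], float(d["threshold"]), float(d["T0"]),
                      float(d["Tf"]))
            for d in s.get("layers", []))
        kwargs = dict(steps=int(s.get("steps", 5000)),
                      k_start=float(s.get("k_start", 40.0)),
                      k_end=float(s.get("k_end", 0.5)),
                      max_repeats=int(s.get("max_repeats", 3)))
        if layers:
            kwargs["layers"] = layers
        return AnnealSchedule(**kwargs)

    def criteria(self) -> GoodBackboneCriteria:
        c = self.raw.get("criteria", {})
        return GoodBackboneCriteria(
            max_cyclic_error=float(c.get("max_cyclic_error", 0.01)),
            max_rep_energy_per_res=float(c.get("max_rep_energy_per_res", 0.5)),
            min_strong_hbonds=c.get("min_strong_hbonds"),
        )

    def ga(self) -> GAConfig:
        g = dict(self.raw.get("ga", {}))
        sched = g.pop("population_profile", None)
        cfg = GAConfig(**{k: v for k, v in g.items()
                          if k in GAConfig.__dataclass_fields__})
        if sched is not None:
            cfg.n_ga = population_schedule(str(sched))
        cfg.sa_criteria = self.criteria()
        return cfg

    def energy_params(self) -> EnergyParams:
        e = self.raw.get("energy", {})
        if not e:
            return DEFAULT_PARAMS
        base = asdict(DEFAULT_PARAMS)
        base.update(e)
        for key in ("radius", "charge"):
            if isinstance(base[key], dict):
                base[key] = tuple(base[key].items())
            elif isinstance(base[key], list):
                base[key] = tuple(tuple(x) for x in base[key])
        return EnergyParams(**base)


def _packaged_profiles_path() -> Path:
    return Path(resources.files("cyclopep").joinpath("data", "profiles.yaml"))


def load_profiles(path=None) -> dict:
    """Load the profile table (packaged defaults unless ``path`` given)."""
    with open(path or _packaged_profiles_path()) as fh:
        raw = yaml.safe_load(fh)
    return {name: Profile(name, body) for name, body in raw.items()}


def get_profile(name: str, path=None) -> Profile:
    profiles = load_profiles(path)
    if name not in profiles:
        raise KeyError(f"unknown profile {name!r}; have {sorted(profiles)}")
    return profiles[name]


def config_hash(profile: Profile, seed: int) -> str:
    """Short digest of every config value in effect, for run logging."""
    payload = json.dumps({"name": profile.name, "raw": profile.raw,
                          "seed": seed}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
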