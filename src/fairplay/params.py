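"""Run configuration: model parameters, sweep specification, seeding.

A single simulation is fully described by a :class:`ModelParams` record and
an integer seed.  Factorial experiments are described by a
:class:`SweepSpec`, which enumerates the Cartesian product of its factor
lists and assigns every (configuration, replicate) pair a deterministic
seed, so a sweep can be re-run or resumed bit-for-bit.

Parameter symbols follow the field's standard usage: ``K`` population cap,
``G`` group cap, ``f``/``g`` fission/offspring-group sizes, ``j`` juvenile
stage length, ``alpha`` play bouts needed to learn fairness, ``P`` parental
investment, ``T`` reproductive threshold, ``r`` mutation rate, ``l``/``sd_l``
lifespan mean/SD, ``R``/``p`` foraging reward and success probability,
``c`` per-bout play mortality, ``d`` reproductive delay.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

__all__ = [
    "ModelParams",
    "SweepSpec",
    "ConfigError",
    "load_config",
    "dump_config",
    "load_sweep_spec",
    "enumerate_sweep",
    "derive_seed",
]

#: Maximum replicates per configuration supported by the seed scheme.
MAX_REPLICATES = 1024


class ConfigError(ValueError):
    """Invalid or unparsable run configuration."""


@dataclass(frozen=True)
class ModelParams:
    """Immutable parameter vector for one simulation run.

    Defaults are the model's reference condition: a population capped at
    K=1000 adults in at most G=50 groups, juvenile stage of 50 steps,
    foraging reward R=40 with success probability p=0.0875 (expected payoff
    pR=3.5 per step), parental investment P=0.5, reproductive threshold
    T=100 and delay d=15, and per-bout play mortality c=0.003.
    """

    # population / group structure
    K: int = 1000
    G: int = 50
    f: int = 40
    g: int = 20
    # life history
    j: int = 50
    alpha: int = 5
    l: int = 150
    sd_l: float = 25.0
    # reproduction
    P: float = 0.5
    T: float = 100.0
    d: int = 15
    r: float = 0.01
    # foraging
    R: float = 40.0
    p: float = 0.0875
    # play
    c: float = 0.003
    learn_fairness: bool = True
    # initial conditions
    F0: float = 0.05
    n_init_groups: int = 50
    n_init_per_group: int = 20
    init_resource_range: tuple[float, float] = (50.0, 150.0)
    init_age_range: tuple[int, int] = (50, 150)
    # run control
    tau: int = 25000
    burn_in: int = 10000

    @property
    def sd_R(self) -> float:
        """Foraging noise SD, fixed at 10% of the mean reward R."""
        return 0.1 * self.R

    @property
    def expected_payoff(self) -> float:
        """Per-step expected foraging intake pR (never stored, always derived)."""
        return self.p * self.R

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        err = lambda msg: (_ for _ in ()).throw(ConfigError(msg))
        for name in ("p", "c", "r", "P", "F0"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and 0.0 <= v <= 1.0):
                err(f"{name} must be a probability in [0, 1], got {v!r}")
        for name in ("K", "G", "f", "g", "j", "alpha", "l", "tau"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v > 0):
                err(f"{name} must be a positive integer, got {v!r}")
        for name in ("d", "burn_in"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v >= 0):
                err(f"{name} must be a non-negative integer, got {v!r}")
        if not (0 < self.g <= self.f <= self.K):
            err(f"need 0 < g <= f <= K, got g={self.g}, f={self.f}, K={self.K}")
        if not (self.T > 0 and math.isfinite(self.T)):
            err(f"T must be positive and finite, got {self.T!r}")
        if not (self.sd_l >= 0):
            err(f"sd_l must be non-negative, got {self.sd_l!r}")
        if not (isinstance(self.n_init_groups, int) and 0 < self.n_init_groups <= self.G):
            err(f"n_init_groups must be in 1..G, got {self.n_init_groups!r}")
        if not (isinstance(self.n_init_per_group, int) and self.n_init_per_group > 0):
            err(f"n_init_per_group must be positive, got {self.n_init_per_group!r}")
        if not (self.burn_in < self.tau):
            err(f"burn_in must be < tau, got burn_in={self.burn_in}, tau={self.tau}")
        lo, hi = self.init_resource_range
        if not (0 <= lo <= hi):
            err(f"init_resource_range must be 0 <= lo <= hi, got {self.init_resource_range!r}")
        alo, ahi = self.init_age_range
        if not (isinstance(alo, int) and isinstance(ahi, int) and alo <= ahi):
            err(f"init_age_range must be integer lo <= hi, got {self.init_age_range!r}")
        if alo < self.j:
            err(
                f"init_age_range minimum must be >= j so initial agents are "
                f"adults, got min {alo} < j={self.j}"
            )

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields changed (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["init_resource_range"] = list(d["init_resource_range"])
        d["init_age_range"] = list(d["init_age_range"])
        return d


_FIELD_NAMES = {f.name for f in dataclasses.fields(ModelParams)}
_INT_FIELDS = {
    f.name for f in dataclasses.fields(ModelParams) if f.type in ("int",)
}


def _coerce(name: str, value):
    if name == "init_resource_range":
        lo, hi = value
        return (float(lo), float(hi))
    if name == "init_age_range":
        lo, hi = value
        return (int(lo), int(hi))
    if name == "learn_fairness":
        if not isinstance(value, bool):
            raise ConfigError(f"learn_fairness must be a boolean, got {value!r}")
        return value
    if name in _INT_FIELDS:
        if isinstance(value, bool) or (isinstance(value, float) and not value.is_integer()):
            raise ConfigError(f"{name} must be an integer, got {value!r}")
        return int(value)
    if isinstance(value, bool):
        raise ConfigError(f"{name} must be a number, got {value!r}")
    return float(value)


def load_config(source: str | dict) -> ModelParams:
    """Build a validated :class:`ModelParams` from a flat JSON document.

    ``source`` is JSON text (or an already-parsed flat dict).  Omitted keys
    take the reference-condition defaults; unknown keys are rejected so a
    typo cannot silently fall back to a default.
    """
    if isinstance(source, str):
        try:
            doc = json.loads(source)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"config is not valid JSON: {exc}") from exc
    else:
        doc = dict(source)
    if not isinstance(doc, dict):
        raise ConfigError("config must be a flat JSON object")
    unknown = set(doc) - _FIELD_NAMES
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {}
    for name, value in doc.items():
        try:
            kwargs[name] = _coerce(name, value)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"bad value for {name!r}: {value!r}") from exc
    return ModelParams(**kwargs)


def dump_config(params: ModelParams) -> str:
    """Serialize to JSON; ``load_config(dump_config(p)) == p``."""
    return json.dumps(params.to_dict(), indent=2, sort_keys=True)


@dataclass(frozen=True)
class SweepSpec:
    """A factorial experiment: factor lists, replicates, and a base seed.

    Enumeration order is fixed and documented: investments (outermost),
    then payoff pairs, then delays, then costs, then replicates (innermost).
    """

    payoff_pairs: tuple[tuple[float, float], ...]  # (R, p)
    delays: tuple[int, ...]
    costs: tuple[float, ...]
    investments: tuple[float, ...] = (0.5,)
    replicates: int = 20
    base_seed: int = 0
    control: bool = False
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.payoff_pairs and self.delays and self.costs and self.investments):
            raise ConfigError("sweep factor lists must be non-empty")
        if not (1 <= self.replicates <= MAX_REPLICATES):
            raise ConfigError(
                f"replicates must be in 1..{MAX_REPLICATES}, got {self.replicates}"
            )
        object.__setattr__(self, "payoff_pairs",
                           tuple((float(R), float(p)) for R, p in self.payoff_pairs))
        object.__setattr__(self, "delays", tuple(int(d) for d in self.delays))
        object.__setattr__(self, "costs", tuple(float(c) for c in self.costs))
        object.__setattr__(self, "investments", tuple(float(P) for P in self.investments))

    @property
    def n_configs(self) -> int:
        return (len(self.investments) * len(self.payoff_pairs)
                * len(self.delays) * len(self.costs))

    @property
    def n_runs(self) -> int:
        return self.n_configs * self.replicates


def load_sweep_spec(source: str | dict) -> SweepSpec:
    """Parse a sweep-spec JSON document (factor arrays plus run controls)."""
    if isinstance(source, str):
        try:
            doc = json.loads(source)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"sweep spec is not valid JSON: {exc}") from exc
    else:
        doc = dict(source)
    known = {"payoff_pairs", "delays", "costs", "investments", "replicates",
             "base_seed", "control", "overrides"}
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"unknown sweep-spec keys: {sorted(unknown)}")
    kwargs = {k: doc[k] for k in known & set(doc)}
    if "payoff_pairs" in kwargs:
        kwargs["payoff_pairs"] = tuple(tuple(pair) for pair in kwargs["payoff_pairs"])
    for k in ("delays", "costs", "investments"):
        if k in kwargs:
            kwargs[k] = tuple(kwargs[k])
    return SweepSpec(**kwargs)


def derive_seed(base_seed: int, config_index: int, replicate: int) -> int:
    """Deterministic per-run seed, collision-free within one sweep.

    The (config, replicate) index pair is packed linearly with a stride of
    ``MAX_REPLICATES`` and offset by ``base_seed`` modulo 2**31.  Within one
    sweep the packed offsets occupy an interval shorter than the modulus, so
    the map is injective.  Statistical independence between nearby seeds is
    provided downstream: every seed passes through numpy's SeedSequence
    entropy mixing before it initializes a generator.
    """
    if config_index < 0 or replicate < 0 or base_seed < 0:
        raise ValueError("seed components must be non-negative")
    if replicate >= MAX_REPLICATES:
        raise ValueError(f"replicate index must be < {MAX_REPLICATES}")
    return (base_seed + config_index * MAX_REPLICATES + replicate) % (2 ** 31)


def enumerate_sweep(
    spec: SweepSpec,
) -> Iterator[tuple[ModelParams, int, int, int]]:
    """Yield ``(params, config_index, replicate, seed)`` for every run.

    The full Cartesian product investments x payoff_pairs x delays x costs,
    each repeated for ``spec.replicates`` replicates, in the documented
    stable order.  Re-running yields an identical sequence.
    """
    idx = 0
    base = dict(spec.overrides)
    if spec.control:
        base["learn_fairness"] = False
    for P in spec.investments:
        for R, p in spec.payoff_pairs:
            for d in spec.delays:
                for c in spec.costs:
                    params = _make_params(base, P=P, R=R, p=p, d=d, c=c)
                    for k in range(spec.replicates):
                        yield params, idx, k, derive_seed(spec.base_seed, idx, k)
                    idx += 1


def _make_params(overrides: dict, **factors) -> ModelParams:
    doc = {**overrides, **factors}
    unknown = set(doc) - _FIELD_NAMES
    if unknown:
        raise ConfigError(f"unknown override keys: {sorted(unknown)}")
    return ModelParams(**{k: _coerce(k, v) if k != "learn_fairness" else v
                          for k, v in doc.items()})
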