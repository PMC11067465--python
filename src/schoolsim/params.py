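"""Model parameters and configuration I/O.

The default parameter set describes a school of black neon tetra
(*Hyphessobrycon herbertaxelrodi*): a 2D self-propelled-particle model in
which each individual feels pairwise attraction--repulsion and alignment
forces from its Voronoi neighbors, a friction--propulsion force relaxing
its speed toward a preferred value, and anisotropic Gaussian white noise.
All forces are accelerations (units of mass m = 1).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Literal, Optional

import yaml

Variant = Literal["standard", "selective", "nearest_only",
                  "explicit_antialignment", "persistent_random"]

_VARIANTS = ("standard", "selective", "nearest_only",
             "explicit_antialignment", "persistent_random")


@dataclass
class PersistentRandomParams:
    """Parameters of the persistent-random-force variant.

    With probability rate ``rate`` per unit time an individual switches off
    its social interactions and instead feels a force of amplitude
    ``amplitude`` in a fixed, uniformly random direction for ``duration``
    seconds.  No canonical values exist for these; they must be supplied.
    """

    rate: float          # switching rate r, s^-1
    amplitude: float     # force amplitude A, cm/s^2
    duration: float      # persistence time tau_p, s

    def __post_init__(self) -> None:
        if self.rate < 0 or self.amplitude < 0 or self.duration < 0:
            raise ValueError("persistent-random parameters must be >= 0")


@dataclass
class ModelParams:
    """Parameters of the schooling model and its variants.

    Defaults are the calibrated values for the N = 39 tetra school.

    Attributes
    ----------
    k_rep : float
        Repulsive spring constant, s^-2 (active for d_ij <= d0).
    k_att : float
        Attractive spring constant, s^-2 (active for d_ij > d0).
    d0 : float
        Equilibrium inter-individual distance, cm.
    mu : float
        Alignment constant, s^-1.
    v0 : float
        Preferred speed, cm/s.
    tau_v : float
        Speed relaxation time, s.
    sigma_v : float
        Noise amplitude along the heading, cm/s^(3/2).
    sigma_phi : float
        Noise amplitude perpendicular to the heading, cm/s^(3/2).
    dt : float
        Integration time step, s.
    n_individuals : int
        Number of individuals.
    variant : str
        One of ``standard``, ``selective`` (interact only with faster
        Voronoi neighbors), ``nearest_only`` (testing aid),
        ``explicit_antialignment`` (alignment replaced by a tabulated
        field lookup) or ``persistent_random``.
    normalize_weights : bool
        If True (default) the 1/d_ij neighbor weights are normalized to
        sum to one per individual (weighted mean of pairwise forces);
        if False the raw 1/d_ij weighted sum is used.
    """

    k_rep: float = 12.5
    k_att: float = 5.0
    d0: float = 5.8
    mu: float = 1.5
    v0: float = 11.0
    tau_v: float = 1.6
    sigma_v: float = 6.4
    sigma_phi: float = 2.6
    dt: float = 0.02
    n_individuals: int = 39
    variant: Variant = "standard"
    normalize_weights: bool = True
    persistent: Optional[PersistentRandomParams] = None
    # Tabulated relative-velocity force field for explicit_antialignment;
    # any object with a __call__(points) -> forces signature works
    # (see schoolsim.forcemap.TabulatedField).
    antialign_field: Any = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("k_rep", "k_att", "mu", "v0", "tau_v",
                     "sigma_v", "sigma_phi"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.d0 <= 0:
            raise ValueError("d0 must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if self.variant not in _VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "persistent_random" and self.persistent is None:
            raise ValueError("persistent_random variant requires "
                             "PersistentRandomParams")
        if (self.variant == "explicit_antialignment"
                and self.antialign_field is None):
            raise ValueError("explicit_antialignment variant requires "
                             "a tabulated force field")

    def replace(self, **changes: Any) -> "ModelParams":
        return dataclasses.replace(self, **changes)

    # -- flat key-value config ------------------------------------------

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("k_rep", "k_att", "d0", "mu", "v0", "tau_v", "sigma_v",
              "sigma_phi", "dt", "variant", "normalize_weights", "seed")}
        d["n"] = self.n_individuals
        if self.persistent is not None:
            d.update(r=self.persistent.rate, A=self.persistent.amplitude,
                     tau_p=self.persistent.duration)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        d = dict(d)
        if "n" in d:
            d["n_individuals"] = int(d.pop("n"))
        if {"r", "A", "tau_p"} & set(d):
            d["persistent"] = PersistentRandomParams(
                rate=float(d.pop("r")), amplitude=float(d.pop("A")),
                duration=float(d.pop("tau_p")))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path: str) -> "ModelParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
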