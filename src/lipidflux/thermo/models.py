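"""Domain types for the lipid-site allosteric model."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from lipidflux.constants import DEFAULT_TEMPERATURE
from lipidflux.errors import DataError, ParameterError

#: Closed enumeration of lipid species in the model.
SPECIES: tuple[str, ...] = ("POPC", "POPE", "POPG")

#: Closed enumeration of channel conformations.
CONFORMATIONS: tuple[str, ...] = ("WT_CA", "ELIC5_CA")

#: Reference species used to anchor relative binding constants.
REFERENCE_SPECIES = "POPE"

#: Tolerance for thermodynamic-cycle closure of a free-energy table (kcal/mol).
CYCLE_TOLERANCE = 1e-6


def check_species(name: str) -> str:
    if name not in SPECIES:
        raise ParameterError(f"unknown lipid species {name!r}; expected one of {SPECIES}")
    return name


def check_conformation(name: str) -> str:
    if name not in CONFORMATIONS:
        raise ParameterError(
            f"unknown conformation {name!r}; expected one of {CONFORMATIONS}"
        )
    return name


@dataclass
class TransformFreeEnergies:
    """Lipid a -> b transformation free energies per local environment.

    An environment is either a bulk membrane composition label (e.g.
    ``"2:1:1"``) or a bound-lipid conformation label (``"WT_CA"``,
    ``"ELIC5_CA"``).  Antisymmetry dG(a->b) = -dG(b->a) is enforced: the
    reverse of a stored entry is available on lookup, and adding an entry
    that contradicts its stored reverse is an error.
    """

    entries: dict[tuple[str, str, str], tuple[float, float]] = field(default_factory=dict)

    def add(self, environment: str, a: str, b: str, dg: float, err: float = 0.0) -> None:
        check_species(a)
        check_species(b)
        if err < 0:
            raise ParameterError(f"error must be >= 0, got {err}")
        key = (environment, a, b)
        rkey = (environment, b, a)
        for k, expected in ((key, (dg, err)), (rkey, (-dg, err))):
            if k in self.entries:
                have = self.entries[k]
                if not (np.isclose(have[0], expected[0]) and np.isclose(have[1], expected[1])):
                    raise DataError(
                        f"conflicting entry for {k[0]} {k[1]}->{k[2]}: "
                        f"have {have[0]} +/- {have[1]}, new implies "
                        f"{expected[0]} +/- {expected[1]} (antisymmetry violated)"
                    )
        self.entries[key] = (float(dg), float(err))

    def get(self, environment: str, a: str, b: str) -> tuple[float, float]:
        """dG(a->b) with error; resolves the reverse entry by antisymmetry."""
        if a == b:
            return 0.0, 0.0
        if (environment, a, b) in self.entries:
            return self.entries[(environment, a, b)]
        if (environment, b, a) in self.entries:
            dg, err = self.entries[(environment, b, a)]
            return -dg, err
        raise DataError(f"no entry for environment {environment!r}, pair {a}->{b}")

    def environments(self) -> list[str]:
        return sorted({k[0] for k in self.entries})

    def check_cycle_closure(self, environment: str, tol: float = CYCLE_TOLERANCE) -> None:
        """If all three pairs are present, dG(a->b)+dG(b->c)+dG(c->a) ~ 0."""
        a, b, c = SPECIES
        try:
            ab = self.get(environment, a, b)[0]
            bc = self.get(environment, b, c)[0]
            ca = self.get(environment, c, a)[0]
        except DataError:
            return  # cycle not fully specified; nothing to check
        closure = ab + bc + ca
        if abs(closure) > tol:
            raise DataError(
                f"thermodynamic cycle for environment {environment!r} fails to "
                f"close: sum = {closure:.6g} kcal/mol (tol {tol})"
            )

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class RelativeAffinityMatrix:
    """Relative binding constants for one conformation.

    Internally stores one constant per species relative to the reference
    species, so every pairwise ratio K(a, b) = K_b / K_a is cycle-consistent
    by construction: K(a,b) * K(b,a) = 1 and K(a,b) * K(b,c) = K(a,c).
    """

    conformation: str
    k_by_species: dict[str, float]
    temperature: float = DEFAULT_TEMPERATURE
    bulk_reference: str = ""

    def __post_init__(self) -> None:
        check_conformation(self.conformation)
        for s in SPECIES:
            if s not in self.k_by_species:
                raise ParameterError(f"missing binding constant for species {s}")
            if self.k_by_species[s] <= 0:
                raise ParameterError(f"binding constant for {s} must be positive")

    def K(self, a: str, b: str) -> float:
        """Relative binding constant of species b vs species a."""
        check_species(a)
        check_species(b)
        return self.k_by_species[b] / self.k_by_species[a]


@dataclass
class Composition:
    """Ternary mole-fraction composition (POPC, POPE, POPG), summing to 1."""

    x_popc: float
    x_pope: float
    x_popg: float

    def __post_init__(self) -> None:
        xs = (self.x_popc, self.x_pope, self.x_popg)
        if any(x < 0 for x in xs):
            raise ParameterError(f"mole fractions must be >= 0, got {xs}")
        if abs(sum(xs) - 1.0) > 1e-12:
            raise ParameterError(f"mole fractions must sum to 1, got {sum(xs)!r}")

    def x(self, species: str) -> float:
        return {
            "POPC": self.x_popc,
            "POPE": self.x_pope,
            "POPG": self.x_popg,
        }[check_species(species)]

    @classmethod
    def on_pg_path(cls, x: float) -> "Composition":
        """Composition at coordinate x on the 2 POPC : 1 POPE : x POPG path."""
        if x < 0:
            raise ParameterError(f"path coordinate must be >= 0, got {x}")
        total = 3.0 + x
        return cls(x_popc=2.0 / total, x_pope=1.0 / total, x_popg=x / total)


@dataclass
class OccupancyResult:
    """Probability that the site is occupied by each species (sums to 1)."""

    p_occ: dict[str, float]

    def __post_init__(self) -> None:
        for s, p in self.p_occ.items():
            check_species(s)
            if not (-1e-12 <= p <= 1 + 1e-12):
                raise ParameterError(f"occupancy for {s} out of [0,1]: {p}")

    def __getitem__(self, species: str) -> float:
        return self.p_occ[check_species(species)]


@dataclass
class X50Result:
    """50%-POPG-occupancy point on the 2:1:x path."""

    mole_fraction: float  # normalized x_POPG = x / (3 + x)
    path_x: float  # raw path coordinate x
    conformation: str


@dataclass
class StabilityMap:
    """Delta log(p_ELIC5 / p_WT) over a barycentric grid of compositions."""

    x_popc: np.ndarray
    x_pope: np.ndarray
    x_popg: np.ndarray
    delta_log: np.ndarray  # natural log
    log_base: str = "e"

    def __len__(self) -> int:
        return len(self.delta_log)
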