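"""Genotype bookkeeping: genotype sets, inheritance cubes, RIDL fitness.

The inheritance cube maps every (mother genotype, father genotype) cross
to a distribution over offspring genotypes and carries per-genotype
fitness modifiers.  The genotype ordering of a cube is the canonical
state ordering used everywhere downstream (dynamics, optimization, I/O).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "GenotypeSet",
    "InheritanceCube",
    "mendelian_cube",
    "apply_ridl",
    "offspring_distribution",
    "validate_cube",
]

_ROW_TOL = 1e-12


@dataclass(frozen=True)
class GenotypeSet:
    """Ordered genotype labels partitioned into wild and modified subsets.

    ``allele_composition[i]`` maps allele name -> copy number for genotype
    ``labels[i]``; a genotype is *wild* iff it carries no transgene allele.
    """

    labels: tuple[str, ...]
    allele_composition: tuple[dict, ...]
    transgene_alleles: frozenset = frozenset({"R"})

    def __post_init__(self):
        if len(self.labels) != len(set(self.labels)):
            raise ConfigurationError("duplicate genotype labels")
        if len(self.allele_composition) != len(self.labels):
            raise ConfigurationError("allele_composition length mismatch")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown genotype {label!r}; known: {self.labels}") from None

    def carries_transgene(self, i: int) -> bool:
        comp = self.allele_composition[i]
        return any(comp.get(a, 0) > 0 for a in self.transgene_alleles)

    @property
    def wild_subset(self) -> tuple[int, ...]:
        return tuple(i for i in range(len(self)) if not self.carries_transgene(i))

    @property
    def modified_subset(self) -> tuple[int, ...]:
        return tuple(i for i in range(len(self)) if self.carries_transgene(i))


@dataclass(frozen=True)
class InheritanceCube:
    """Offspring distributions for every cross, plus genotype fitness.

    ``probs[f, m, o]`` is the probability that a mother of genotype ``f``
    and father of genotype ``m`` produce an offspring of genotype ``o``.

    Fitness modifiers (all indexed by genotype):

    - ``s_female`` / ``s_male``: egg-to-adult survival applied at
      emergence to newly eclosing females / males, in ``[0, 1]``;
    - ``eta``: male mating competitiveness weight, >= 0;
    - ``beta``: female fecundity factor, >= 0.
    """

    genotypes: GenotypeSet
    probs: np.ndarray
    s_female: np.ndarray = None
    s_male: np.ndarray = None
    eta: np.ndarray = None
    beta: np.ndarray = None
    ridl_penetrance: float = 0.0
    ridl_female_only: bool = False

    def __post_init__(self):
        G = len(self.genotypes)
        probs = np.asarray(self.probs, dtype=float)
        if probs.shape != (G, G, G):
            raise ConfigurationError(f"probs must have shape {(G, G, G)}, got {probs.shape}")
        object.__setattr__(self, "probs", probs)
        for name in ("s_female", "s_male", "eta", "beta"):
            v = getattr(self, name)
            v = np.ones(G) if v is None else np.asarray(v, dtype=float)
            if v.shape != (G,):
                raise ConfigurationError(f"{name} must have shape ({G},)")
            object.__setattr__(self, name, v)

    @property
    def s(self) -> np.ndarray:
        """Egg-to-adult survival per genotype (female channel)."""
        return self.s_female

    def to_dict(self) -> dict:
        return {
            "genotypes": list(self.genotypes.labels),
            "alleles": [dict(c) for c in self.genotypes.allele_composition],
            "transgene_alleles": sorted(self.genotypes.transgene_alleles),
            "probs": self.probs.tolist(),
            "s_female": self.s_female.tolist(),
            "s_male": self.s_male.tolist(),
            "eta": self.eta.tolist(),
            "beta": self.beta.tolist(),
            "ridl_penetrance": self.ridl_penetrance,
            "ridl_female_only": self.ridl_female_only,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InheritanceCube":
        gs = GenotypeSet(
            labels=tuple(d["genotypes"]),
            allele_composition=tuple(dict(c) for c in d["alleles"]),
            transgene_alleles=frozenset(d.get("transgene_alleles", ["R"])),
        )
        return cls(
            genotypes=gs,
            probs=np.asarray(d["probs"], dtype=float),
            s_female=np.asarray(d["s_female"], dtype=float),
            s_male=np.asarray(d["s_male"], dtype=float),
            eta=np.asarray(d["eta"], dtype=float),
            beta=np.asarray(d["beta"], dtype=float),
            ridl_penetrance=float(d.get("ridl_penetrance", 0.0)),
            ridl_female_only=bool(d.get("ridl_female_only", False)),
        )


def mendelian_cube(alleles: tuple[str, str] = ("W", "R")) -> InheritanceCube:
    """Single-locus Mendelian cube over genotypes {AA, BA, BB}.

    With the default alleles this yields labels ``("WW", "RW", "RR")``
    where ``R`` is the transgene.  All fitness modifiers start at 1.
    """
    if len(alleles) != 2 or len(set(alleles)) != 2:
        raise ConfigurationError("mendelian_cube requires exactly two distinct alleles")
    a, b = alleles
    labels = (a + a, b + a, b + b)
    comp = ({a: 2}, {a: 1, b: 1}, {b: 2})
    gs = GenotypeSet(labels=labels, allele_composition=comp, transgene_alleles=frozenset({b}))

    # gamete distribution per genotype: P(transmitting allele)
    gametes = []
    for c in comp:
        total = sum(c.values())
        gametes.append({al: n / total for al, n in c.items()})

    def genotype_of(al1: str, al2: str) -> int:
        key = {al1: 0, al2: 0}
        key[al1] += 1
        key[al2] += 1
        for i, c in enumerate(comp):
            if c == key:
                return i
        raise AssertionError

    G = len(labels)
    probs = np.zeros((G, G, G))
    for f, m in itertools.product(range(G), range(G)):
        for al_f, p_f in gametes[f].items():
            for al_m, p_m in gametes[m].items():
                probs[f, m, genotype_of(al_f, al_m)] += p_f * p_m
    return InheritanceCube(genotypes=gs, probs=probs)


def apply_ridl(
    cube: InheritanceCube, penetrance: float = 1.0, female_only: bool = False
) -> InheritanceCube:
    """Apply dominant-lethal fitness to every transgene-carrying genotype.

    Emerging adults of a carrier genotype survive with probability
    ``1 - penetrance`` (both sexes by default; only females when
    ``female_only`` — the fsRIDL variant).  Idempotent at fixed settings:
    survival is assigned, not multiplied.
    """
    if not 0.0 <= penetrance <= 1.0:
        raise ConfigurationError(f"penetrance must be in [0, 1], got {penetrance}")
    if not cube.genotypes.modified_subset:
        raise ConfigurationError("cube has no transgene-carrying genotype to act on")
    carrier = np.array(
        [cube.genotypes.carries_transgene(i) for i in range(len(cube.genotypes))]
    )
    s_female = np.where(carrier, 1.0 - penetrance, 1.0)
    s_male = cube.s_male.copy() if female_only else np.where(carrier, 1.0 - penetrance, 1.0)
    return replace(
        cube,
        s_female=s_female,
        s_male=s_male,
        ridl_penetrance=penetrance,
        ridl_female_only=female_only,
    )


def offspring_distribution(cube: InheritanceCube, g_f: str, g_m: str) -> dict:
    """Offspring genotype distribution for the (mother ``g_f``, father ``g_m``) cross."""
    f = cube.genotypes.index(g_f)
    m = cube.genotypes.index(g_m)
    row = cube.probs[f, m]
    return {lab: float(p) for lab, p in zip(cube.genotypes.labels, row) if p > 0.0}


def validate_cube(cube: InheritanceCube) -> list[str]:
    """Check normalization, non-negativity and fitness bounds.

    Returns a list of human-readable violations; empty means valid.
    """
    out = []
    labels = cube.genotypes.labels
    if np.any(cube.probs < 0):
        bad = np.argwhere(cube.probs < 0)
        for f, m, o in bad:
            out.append(
                f"negative probability for cross ({labels[f]}, {labels[m]}) -> {labels[o]}"
            )
    sums = cube.probs.sum(axis=2)
    for f, m in np.argwhere(np.abs(sums - 1.0) > _ROW_TOL):
        out.append(
            f"cross ({labels[f]}, {labels[m]}) offspring mass sums to {sums[f, m]!r}, not 1"
        )
    for name, v, lo, hi in (
        ("s_female", cube.s_female, 0.0, 1.0),
        ("s_male", cube.s_male, 0.0, 1.0),
        ("eta", cube.eta, 0.0, np.inf),
        ("beta", cube.beta, 0.0, np.inf),
    ):
        for (i,) in np.argwhere((v < lo) | (v > hi)):
            out.append(f"{name}[{labels[i]}] = {v[i]} outside [{lo}, {hi}]")
    return out
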