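"""Exact transmission genetics for the two-locus carp scale-pattern system.

The classical model of scale-pattern inheritance in common carp (*Cyprinus
carpio*) involves two unlinked loci with two alleles each.  The S locus (a
paralog of ``fgfr1a1``) controls the basic scale cover: at least one dominant
``S`` allele gives a fully scaled or linear fish, while ``ss`` homozygotes
lose most body scales ("scattered": the classical mirror plus the irregular
sub-type).  The N locus modifies that pattern: a single ``N`` allele on an
``ss`` background removes (nearly) all remaining scales ("nude"/"leather"),
``S_Nn`` gives the linear pattern, and ``NN`` homozygotes die before hatching
regardless of the S genotype.  A dihybrid ``SsNn x SsNn`` cross therefore
yields scaled 3/16, linear 6/16, scattered 1/16, nude 2/16 and a lethal 4/16
class.

All transmission probabilities here are exact :class:`fractions.Fraction`
values; floating point enters only at reporting boundaries.  Two variant
allele hypotheses are supported alongside the standard model:

* **weak-N** — the N mutation is viable when homozygous and ``NN`` fish are
  nude; no lethal class exists.  This reproduces the direction of the
  Hungarian nude x nude observations (no early loss, excess of nudes).
* **strong-s** — a third S-locus allele ``s*`` causing complete loss of
  function; ``s*s*`` homozygotes are nude-like without any N mutation, while
  ``ss*`` fish fall in the scattered class.  A nude-looking ``s*s*nn`` parent
  crossed to an ordinary mirror (``ssnn``) then produces 100% scattered
  offspring and zero nudes.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence


class Phenotype(str, enum.Enum):
    """Scale-pattern categories.

    ``SCATTERED`` is the model-level aggregate (the two-locus system predicts
    no finer split); ``IRREGULAR`` and ``MIRROR`` are the observation-level
    sub-types into which scattered fish are classified.  ``LETHAL`` labels
    the pre-hatching loss class and is never observed in live offspring.
    """

    SCALED = "scaled"
    LINEAR = "linear"
    SCATTERED = "scattered"
    IRREGULAR = "irregular"
    MIRROR = "mirror"
    NUDE = "nude"
    LETHAL = "lethal"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Categories that can be recorded on live fish.
OBSERVABLE_CATEGORIES = (
    Phenotype.SCALED,
    Phenotype.LINEAR,
    Phenotype.IRREGULAR,
    Phenotype.MIRROR,
    Phenotype.NUDE,
)

_S_ALLELES = ("S", "s", "s*")
_N_ALLELES = ("N", "n")
_S_ORDER = {a: i for i, a in enumerate(_S_ALLELES)}
_N_ORDER = {a: i for i, a in enumerate(_N_ALLELES)}


class NonviableParentError(ValueError):
    """Raised when a cross is requested from a genotype that cannot survive."""


@dataclass(frozen=True)
class Gamete:
    """One haploid allele combination (one allele per locus)."""

    s_allele: str
    n_allele: str

    def __post_init__(self) -> None:
        if self.s_allele not in _S_ALLELES:
            raise ValueError(f"unknown S-locus allele {self.s_allele!r}")
        if self.n_allele not in _N_ALLELES:
            raise ValueError(f"unknown N-locus allele {self.n_allele!r}")

    def __str__(self) -> str:
        return self.s_allele + self.n_allele

    @property
    def _key(self) -> tuple[int, int]:
        return (_S_ORDER[self.s_allele], _N_ORDER[self.n_allele])


@dataclass(frozen=True)
class Genotype:
    """Diploid two-locus genotype, canonically ordered (e.g. ``SsNn``).

    The S locus carries two alleles from {S, s, s*} (``s*`` only under the
    strong-s hypothesis) and the N locus two alleles from {N, n}.  Instances
    canonicalize allele order on construction so that equal genotypes compare
    and hash equal regardless of input order.
    """

    s_alleles: tuple[str, str]
    n_alleles: tuple[str, str]

    def __post_init__(self) -> None:
        for a in self.s_alleles:
            if a not in _S_ALLELES:
                raise ValueError(f"unknown S-locus allele {a!r}")
        for a in self.n_alleles:
            if a not in _N_ALLELES:
                raise ValueError(f"unknown N-locus allele {a!r}")
        object.__setattr__(
            self, "s_alleles", tuple(sorted(self.s_alleles, key=_S_ORDER.__getitem__))
        )
        object.__setattr__(
            self, "n_alleles", tuple(sorted(self.n_alleles, key=_N_ORDER.__getitem__))
        )

    @classmethod
    def from_string(cls, text: str) -> "Genotype":
        """Parse the field's genotype notation, e.g. ``"ssNn"`` or ``"ss*nn"``."""
        tokens: list[str] = []
        i = 0
        while i < len(text):
            c = text[i]
            if c in "Ss":
                if i + 1 < len(text) and text[i + 1] == "*":
                    if c == "S":
                        raise ValueError(f"invalid allele 'S*' in {text!r}")
                    tokens.append("s*")
                    i += 2
                else:
                    tokens.append(c)
                    i += 1
            elif c in "Nn":
                tokens.append(c)
                i += 1
            else:
                raise ValueError(f"unexpected character {c!r} in genotype {text!r}")
        if len(tokens) != 4:
            raise ValueError(f"genotype {text!r} must carry two alleles per locus")
        s_part, n_part = tokens[:2], tokens[2:]
        if any(t not in _S_ALLELES[:3] or t in _N_ALLELES for t in s_part):
            raise ValueError(f"first two alleles of {text!r} must be S-locus alleles")
        if any(t not in _N_ALLELES for t in n_part):
            raise ValueError(f"last two alleles of {text!r} must be N-locus alleles")
        return cls((s_part[0], s_part[1]), (n_part[0], n_part[1]))

    def __str__(self) -> str:
        return "".join(self.s_alleles) + "".join(self.n_alleles)

    @property
    def s_mutant_count(self) -> int:
        """Copies of loss-of-function alleles (s or s*) at the S locus (0-2)."""
        return sum(1 for a in self.s_alleles if a != "S")

    @property
    def n_mutant_count(self) -> int:
        """Copies of the N allele (0-2)."""
        return sum(1 for a in self.n_alleles if a == "N")

    @property
    def _key(self) -> tuple[int, int, int, int]:
        return (
            _S_ORDER[self.s_alleles[0]],
            _S_ORDER[self.s_alleles[1]],
            _N_ORDER[self.n_alleles[0]],
            _N_ORDER[self.n_alleles[1]],
        )


@dataclass(frozen=True)
class AlleleModel:
    """A hypothesis about the alleles segregating at the two loci.

    Parameters
    ----------
    NN_lethal
        Whether ``NN`` homozygotes die before hatching (standard model).
    NN_viable_phenotype
        Phenotype assigned to ``NN`` fish when viable (weak-N: nude).
    strong_s_enabled
        Whether the third S-locus allele ``s*`` is allowed; ``s*s*``
        homozygotes map to the nude category, ``ss*`` to scattered.
    scattered_split
        Observation-layer probability that a scattered fish presents as
        irregular rather than mirror.  The two-locus model itself makes no
        prediction for this split.
    """

    name: str = "standard"
    NN_lethal: bool = True
    NN_viable_phenotype: Phenotype | None = None
    strong_s_enabled: bool = False
    scattered_split: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.scattered_split <= 1.0:
            raise ValueError("scattered_split must lie in [0, 1]")
        if not self.NN_lethal and self.NN_viable_phenotype is None:
            raise ValueError("a viable-NN model must assign NN a phenotype")


STANDARD_MODEL = AlleleModel(name="standard")
WEAK_N_MODEL = AlleleModel(
    name="weak-N", NN_lethal=False, NN_viable_phenotype=Phenotype.NUDE
)
STRONG_S_MODEL = AlleleModel(name="strong-s", strong_s_enabled=True)

MODELS_BY_NAME = {
    "standard": STANDARD_MODEL,
    "weak-n": WEAK_N_MODEL,
    "weak-N": WEAK_N_MODEL,
    "strong-s": STRONG_S_MODEL,
}


def phenotype_of(genotype: Genotype, model: AlleleModel = STANDARD_MODEL) -> Phenotype:
    """Map a genotype to its phenotype category under ``model``.

    Standard model: any ``NN`` is lethal; ``S_nn`` scaled; ``S_Nn`` linear;
    ``ssnn`` scattered; ``ssNn`` nude.
    """
    if "s*" in genotype.s_alleles and not model.strong_s_enabled:
        raise ValueError(
            f"genotype {genotype} carries s* but model {model.name!r} does not "
            "enable the strong-s allele"
        )
    if genotype.n_mutant_count == 2:
        if model.NN_lethal:
            return Phenotype.LETHAL
        assert model.NN_viable_phenotype is not None
        return model.NN_viable_phenotype
    if genotype.s_alleles == ("s*", "s*"):
        return Phenotype.NUDE
    if "S" in genotype.s_alleles:
        return Phenotype.SCALED if genotype.n_mutant_count == 0 else Phenotype.LINEAR
    return Phenotype.SCATTERED if genotype.n_mutant_count == 0 else Phenotype.NUDE


def is_viable(genotype: Genotype, model: AlleleModel = STANDARD_MODEL) -> bool:
    return phenotype_of(genotype, model) is not Phenotype.LETHAL


def all_genotypes(model: AlleleModel = STANDARD_MODEL) -> list[Genotype]:
    """Every distinct genotype constructible under ``model``, canonical order."""
    s_alleles = _S_ALLELES if model.strong_s_enabled else _S_ALLELES[:2]
    out = []
    for s_pair in itertools.combinations_with_replacement(s_alleles, 2):
        for n_pair in itertools.combinations_with_replacement(_N_ALLELES, 2):
            out.append(Genotype(s_pair, n_pair))
    return sorted(out, key=lambda g: g._key)


def viable_genotypes(model: AlleleModel = STANDARD_MODEL) -> list[Genotype]:
    return [g for g in all_genotypes(model) if is_viable(g, model)]


def gamete_distribution(
    parent: Genotype, model: AlleleModel = STANDARD_MODEL
) -> dict[Gamete, Fraction]:
    """Exact gamete probabilities of a viable parent (independent assortment)."""
    if not is_viable(parent, model):
        raise NonviableParentError(
            f"parent genotype {parent} is not viable under the {model.name!r} model"
        )
    half = Fraction(1, 2)
    s_probs: dict[str, Fraction] = {}
    for a in parent.s_alleles:
        s_probs[a] = s_probs.get(a, Fraction(0)) + half
    n_probs: dict[str, Fraction] = {}
    for a in parent.n_alleles:
        n_probs[a] = n_probs.get(a, Fraction(0)) + half
    dist = {
        Gamete(sa, na): ps * pn
        for sa, ps in s_probs.items()
        for na, pn in n_probs.items()
    }
    return dict(sorted(dist.items(), key=lambda kv: kv[0]._key))


@dataclass(frozen=True)
class PhenotypeDistribution:
    """Normalized phenotype-category probabilities for one cross.

    ``includes_lethal`` distinguishes zygote-level distributions (the lethal
    class counted, as in the classical expectation tables) from
    survivor-level ones obtained through :meth:`condition_on_survival`.
    """

    probabilities: Mapping[Phenotype, Fraction]
    includes_lethal: bool

    def __post_init__(self) -> None:
        total = sum(self.probabilities.values())
        exact = all(isinstance(p, Fraction) for p in self.probabilities.values())
        if any(p < 0 for p in self.probabilities.values()):
            raise ValueError("probabilities must be non-negative")
        if exact:
            if total != 1:
                raise ValueError(f"probabilities must sum to 1, got {total}")
        elif abs(float(total) - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1, got {float(total)}")
        if not self.includes_lethal and self.prob(Phenotype.LETHAL) > 0:
            raise ValueError("survivor-level distribution carries lethal mass")
        object.__setattr__(self, "probabilities", dict(self.probabilities))

    def prob(self, category: Phenotype) -> Fraction:
        return self.probabilities.get(category, Fraction(0))

    def categories(self) -> list[Phenotype]:
        return list(self.probabilities)

    def condition_on_survival(self) -> "PhenotypeDistribution":
        """Remove the lethal class and renormalize.  Idempotent."""
        lethal = self.prob(Phenotype.LETHAL)
        if not self.includes_lethal:
            return self
        if lethal >= 1:
            raise ValueError("cannot condition on survival: all offspring lethal")
        rest = {
            c: p / (1 - lethal)
            for c, p in self.probabilities.items()
            if c is not Phenotype.LETHAL
        }
        return PhenotypeDistribution(rest, includes_lethal=False)

    def split_scattered(self, split: float) -> "PhenotypeDistribution":
        """Replace the aggregate scattered class by irregular/mirror.

        ``split`` is the probability that a scattered fish presents as
        irregular (observation-layer parameter).
        """
        if not 0.0 <= split <= 1.0:
            raise ValueError("split must lie in [0, 1]")
        sc = self.prob(Phenotype.SCATTERED)
        if sc == 0:
            return self
        frac = Fraction(split)
        probs = {
            c: p for c, p in self.probabilities.items() if c is not Phenotype.SCATTERED
        }
        irr = sc * frac
        mir = sc * (1 - frac)
        if irr > 0:
            probs[Phenotype.IRREGULAR] = probs.get(Phenotype.IRREGULAR, Fraction(0)) + irr
        if mir > 0:
            probs[Phenotype.MIRROR] = probs.get(Phenotype.MIRROR, Fraction(0)) + mir
        return PhenotypeDistribution(probs, includes_lethal=self.includes_lethal)

    def merge_scattered(self) -> "PhenotypeDistribution":
        """Pool irregular and mirror into the aggregate scattered class."""
        sc = (
            self.prob(Phenotype.SCATTERED)
            + self.prob(Phenotype.IRREGULAR)
            + self.prob(Phenotype.MIRROR)
        )
        probs = {
            c: p
            for c, p in self.probabilities.items()
            if c not in (Phenotype.SCATTERED, Phenotype.IRREGULAR, Phenotype.MIRROR)
        }
        if sc > 0:
            probs[Phenotype.SCATTERED] = sc
        return PhenotypeDistribution(probs, includes_lethal=self.includes_lethal)

    def as_percent(self) -> dict[Phenotype, float]:
        return {c: float(p) * 100.0 for c, p in self.probabilities.items()}


def offspring_genotype_distribution(
    p1: Genotype, p2: Genotype, model: AlleleModel = STANDARD_MODEL
) -> dict[Genotype, Fraction]:
    """Exact zygote genotype probabilities from two viable parents."""
    d1 = gamete_distribution(p1, model)
    d2 = gamete_distribution(p2, model)
    out: dict[Genotype, Fraction] = {}
    for (g1, q1), (g2, q2) in itertools.product(d1.items(), d2.items()):
        z = Genotype((g1.s_allele, g2.s_allele), (g1.n_allele, g2.n_allele))
        out[z] = out.get(z, Fraction(0)) + q1 * q2
    return dict(sorted(out.items(), key=lambda kv: kv[0]._key))


def cross_distribution(
    p1: Genotype, p2: Genotype, model: AlleleModel = STANDARD_MODEL
) -> PhenotypeDistribution:
    """Zygote-level phenotype distribution of a cross (lethal class included)."""
    probs: dict[Phenotype, Fraction] = {}
    for z, q in offspring_genotype_distribution(p1, p2, model).items():
        ph = phenotype_of(z, model)
        probs[ph] = probs.get(ph, Fraction(0)) + q
    return PhenotypeDistribution(probs, includes_lethal=True)


@dataclass(frozen=True)
class PunnettTable:
    """Gamete-by-gamete grid of offspring phenotypes for one cross."""

    gametes1: tuple[Gamete, ...]
    gametes2: tuple[Gamete, ...]
    gamete_probs1: Mapping[Gamete, Fraction]
    gamete_probs2: Mapping[Gamete, Fraction]
    cells: Mapping[tuple[Gamete, Gamete], Phenotype]

    def to_distribution(self) -> PhenotypeDistribution:
        """Aggregate the grid back into a phenotype distribution."""
        probs: dict[Phenotype, Fraction] = {}
        for (g1, g2), ph in self.cells.items():
            q = self.gamete_probs1[g1] * self.gamete_probs2[g2]
            probs[ph] = probs.get(ph, Fraction(0)) + q
        return PhenotypeDistribution(probs, includes_lethal=True)


def punnett_table(
    p1: Genotype, p2: Genotype, model: AlleleModel = STANDARD_MODEL
) -> PunnettTable:
    d1 = gamete_distribution(p1, model)
    d2 = gamete_distribution(p2, model)
    cells = {
        (g1, g2): phenotype_of(
            Genotype((g1.s_allele, g2.s_allele), (g1.n_allele, g2.n_allele)), model
        )
        for g1 in d1
        for g2 in d2
    }
    return PunnettTable(tuple(d1), tuple(d2), d1, d2, cells)


def genotypes_for_phenotype(
    phenotype: Phenotype, model: AlleleModel = STANDARD_MODEL
) -> list[Genotype]:
    """All viable genotypes presenting the given observable phenotype.

    Irregular and mirror map to the model-level scattered class; lethal is
    rejected because it is never observed in a live parent.
    """
    if phenotype is Phenotype.LETHAL:
        raise ValueError("lethal is not an observable parental phenotype")
    target = (
        Phenotype.SCATTERED
        if phenotype in (Phenotype.IRREGULAR, Phenotype.MIRROR)
        else phenotype
    )
    return [g for g in viable_genotypes(model) if phenotype_of(g, model) is target]


@dataclass(frozen=True)
class GenotypePairClass:
    """Parental genotype pairs sharing an identical offspring distribution."""

    pairs: tuple[tuple[Genotype, Genotype], ...]
    distribution: PhenotypeDistribution

    def label(self) -> str:
        return " | ".join(f"{a}x{b}" for a, b in self.pairs)


def expected_for_cross_type(
    phenotype1: Phenotype,
    phenotype2: Phenotype,
    model: AlleleModel = STANDARD_MODEL,
) -> list[GenotypePairClass]:
    """Enumerate genotype-pair equivalence classes for a phenotypic cross.

    Every viable genotype pair compatible with the two parental phenotypes is
    evaluated; pairs with identical zygote-level offspring distributions are
    grouped into classes (never silently collapsed).  Classes are returned in
    first-encountered enumeration order.
    """
    gs1 = genotypes_for_phenotype(phenotype1, model)
    gs2 = genotypes_for_phenotype(phenotype2, model)
    classes: dict[tuple, tuple[list, PhenotypeDistribution]] = {}
    for g1, g2 in itertools.product(gs1, gs2):
        dist = cross_distribution(g1, g2, model)
        key = tuple(sorted((c.value, p) for c, p in dist.probabilities.items()))
        if key not in classes:
            classes[key] = ([], dist)
        classes[key][0].append((g1, g2))
    return [
        GenotypePairClass(tuple(pairs), dist) for pairs, dist in classes.values()
    ]
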