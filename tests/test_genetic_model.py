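"""Exact transmission genetics: gametes, crosses, lethality, survivor views."""

import itertools
from collections import defaultdict
from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st

from carpscales.genetic_model import (
    Gamete,
    Genotype,
    NonviableParentError,
    Phenotype,
    PhenotypeDistribution,
    STANDARD_MODEL,
    STRONG_S_MODEL,
    WEAK_N_MODEL,
    cross_distribution,
    expected_for_cross_type,
    gamete_distribution,
    genotypes_for_phenotype,
    phenotype_of,
    punnett_table,
    viable_genotypes,
)

G = Genotype.from_string
F = Fraction


# ---------------------------------------------------------------------------
# independent brute-force oracle: enumerate the 16 equally likely parental
# allele picks and map each zygote through an explicit lookup table
# ---------------------------------------------------------------------------

_STANDARD_LOOKUP = {
    ("SS", "nn"): "scaled",
    ("Ss", "nn"): "scaled",
    ("ss", "nn"): "scattered",
    ("SS", "Nn"): "linear",
    ("Ss", "Nn"): "linear",
    ("ss", "Nn"): "nude",
    ("SS", "NN"): "lethal",
    ("Ss", "NN"): "lethal",
    ("ss", "NN"): "lethal",
}
_WEAK_N_LOOKUP = {
    k: ("nude" if k[1] == "NN" else v) for k, v in _STANDARD_LOOKUP.items()
}

_NINE = [
    (s, n) for s in ("SS", "Ss", "ss") for n in ("NN", "Nn", "nn")
]


def oracle_cross(p1: tuple, p2: tuple, lookup: dict) -> dict:
    out: dict = defaultdict(Fraction)
    q = F(1, 16)
    for a, b, c, d in itertools.product(p1[0], p1[1], p2[0], p2[1]):
        zygote = ("".join(sorted(a + c)), "".join(sorted(b + d)))
        out[lookup[zygote]] += q
    return dict(out)


def as_plain(dist: PhenotypeDistribution) -> dict:
    return {c.value: p for c, p in dist.probabilities.items() if p > 0}


# ---------------------------------------------------------------------------
# genotypes and gametes
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "text, canonical",
    [("SsNn", "SsNn"), ("sSnN", "SsNn"), ("ssNn", "ssNn"), ("s*snn", "ss*nn")],
)
def test_genotype_parsing_canonicalizes(text, canonical):
    assert str(G(text)) == canonical


@pytest.mark.parametrize("bad", ["SsN", "SsNnN", "XxNn", "S*sNn", "NnSs*x"])
def test_genotype_parsing_rejects_malformed(bad):
    with pytest.raises(ValueError):
        G(bad)


@pytest.mark.parametrize(
    "parent, expected",
    [
        ("SsNn", {"SN": F(1, 4), "Sn": F(1, 4), "sN": F(1, 4), "sn": F(1, 4)}),
        ("ssnn", {"sn": F(1)}),
        ("SSNn", {"SN": F(1, 2), "Sn": F(1, 2)}),
    ],
)
def test_gamete_distribution_independent_assortment(parent, expected):
    dist = gamete_distribution(G(parent))
    assert {str(g): p for g, p in dist.items()} == expected
    assert sum(dist.values()) == 1


def test_gamete_distribution_rejects_nonviable_parent():
    with pytest.raises(NonviableParentError, match="not viable"):
        gamete_distribution(G("SsNN"))


# ---------------------------------------------------------------------------
# phenotype mapping
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "genotype, phenotype",
    [
        ("SSnn", Phenotype.SCALED),
        ("Ssnn", Phenotype.SCALED),
        ("SSNn", Phenotype.LINEAR),
        ("SsNn", Phenotype.LINEAR),
        ("ssnn", Phenotype.SCATTERED),
        ("ssNn", Phenotype.NUDE),
        ("SsNN", Phenotype.LETHAL),
        ("ssNN", Phenotype.LETHAL),
        ("SSNN", Phenotype.LETHAL),
    ],
)
def test_phenotype_map_standard(genotype, phenotype):
    assert phenotype_of(G(genotype)) is phenotype


def test_phenotype_map_weak_n_makes_NN_viable_nude():
    for s in ("SS", "Ss", "ss"):
        assert phenotype_of(G(s + "NN"), WEAK_N_MODEL) is Phenotype.NUDE


def test_phenotype_map_strong_s():
    # one strong allele with an ordinary s keeps the scattered class;
    # two strong alleles give a nude-like fish without any N mutation
    assert phenotype_of(G("ss*nn"), STRONG_S_MODEL) is Phenotype.SCATTERED
    assert phenotype_of(G("s*s*nn"), STRONG_S_MODEL) is Phenotype.NUDE
    assert phenotype_of(G("Ss*nn"), STRONG_S_MODEL) is Phenotype.SCALED
    with pytest.raises(ValueError, match="strong-s"):
        phenotype_of(G("ss*nn"), STANDARD_MODEL)


# ---------------------------------------------------------------------------
# cross distributions
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "p1, p2, expected",
    [
        (
            "SsNn",
            "SsNn",
            {
                "scaled": F(3, 16),
                "linear": F(6, 16),
                "scattered": F(1, 16),
                "nude": F(2, 16),
                "lethal": F(4, 16),
            },
        ),
        ("ssnn", "ssnn", {"scattered": F(1)}),
        ("ssNn", "ssnn", {"scattered": F(1, 2), "nude": F(1, 2)}),
        (
            "ssNn",
            "ssNn",
            {"scattered": F(1, 4), "nude": F(1, 2), "lethal": F(1, 4)},
        ),
    ],
)
def test_cross_distribution_classical_expectations(p1, p2, expected):
    assert as_plain(cross_distribution(G(p1), G(p2))) == expected


def test_cross_distribution_rejects_nonviable_parent():
    with pytest.raises(NonviableParentError):
        cross_distribution(G("ssNN"), G("ssnn"))


def test_cross_distribution_matches_oracle_and_is_symmetric():
    """All ordered viable pairs agree exactly with 16-cell enumeration."""
    for model, lookup in [(STANDARD_MODEL, _STANDARD_LOOKUP), (WEAK_N_MODEL, _WEAK_N_LOOKUP)]:
        viable = [
            (s, n) for s, n in _NINE if lookup[(s, n)] != "lethal"
        ]
        n_pairs = 0
        for p1, p2 in itertools.product(viable, repeat=2):
            got = as_plain(
                cross_distribution(G(p1[0] + p1[1]), G(p2[0] + p2[1]), model)
            )
            assert got == oracle_cross(p1, p2, lookup)
            rev = as_plain(
                cross_distribution(G(p2[0] + p2[1]), G(p1[0] + p1[1]), model)
            )
            assert got == rev
            n_pairs += 1
        assert n_pairs == len(viable) ** 2
    # the viable-NN model exposes all 9x9 = 81 ordered pairs
    assert len([g for g in _NINE]) ** 2 == 81


def test_lethal_mass_is_quarter_iff_both_parents_carry_Nn():
    for g1, g2 in itertools.product(viable_genotypes(STANDARD_MODEL), repeat=2):
        lethal = cross_distribution(g1, g2).prob(Phenotype.LETHAL)
        if g1.n_mutant_count == 1 and g2.n_mutant_count == 1:
            assert lethal == F(1, 4)
        else:
            assert lethal == 0


# ---------------------------------------------------------------------------
# survivor conditioning
# ---------------------------------------------------------------------------


def test_condition_on_survival_renormalizes():
    dist = cross_distribution(G("ssNn"), G("ssNn"))
    surv = dist.condition_on_survival()
    assert as_plain(surv) == {"scattered": F(1, 3), "nude": F(2, 3)}
    assert not surv.includes_lethal


def test_condition_on_survival_idempotent_and_ratio_preserving():
    dist = cross_distribution(G("SsNn"), G("SsNn"))
    surv = dist.condition_on_survival()
    assert surv.condition_on_survival() is surv
    # ratios among non-lethal categories unchanged
    for a, b in itertools.combinations(
        [Phenotype.SCALED, Phenotype.LINEAR, Phenotype.NUDE], 2
    ):
        assert surv.prob(a) / surv.prob(b) == dist.prob(a) / dist.prob(b)


def test_condition_on_survival_without_lethal_mass_is_identity():
    dist = cross_distribution(G("ssNn"), G("ssnn"))
    assert as_plain(dist.condition_on_survival()) == as_plain(dist)


def test_condition_on_survival_rejects_all_lethal():
    dist = PhenotypeDistribution({Phenotype.LETHAL: F(1)}, includes_lethal=True)
    with pytest.raises(ValueError, match="lethal"):
        dist.condition_on_survival()


# ---------------------------------------------------------------------------
# Punnett tables
# ---------------------------------------------------------------------------


def test_punnett_table_dihybrid_matches_classical_grid():
    table = punnett_table(G("SsNn"), G("SsNn"))
    assert len(table.cells) == 16
    lethal_cells = [c for c in table.cells.values() if c is Phenotype.LETHAL]
    assert len(lethal_cells) == 4
    assert as_plain(table.to_distribution()) == as_plain(
        cross_distribution(G("SsNn"), G("SsNn"))
    )


def test_punnett_table_homozygous_parent_single_cell():
    table = punnett_table(G("ssnn"), G("ssnn"))
    assert len(table.cells) == 1
    assert list(table.cells.values()) == [Phenotype.SCATTERED]


def test_punnett_aggregation_equals_cross_distribution():
    table = punnett_table(G("SsNn"), G("ssNn"))
    assert as_plain(table.to_distribution()) == as_plain(
        cross_distribution(G("SsNn"), G("ssNn"))
    )


# ---------------------------------------------------------------------------
# phenotype-level cross enumeration
# ---------------------------------------------------------------------------


def test_linear_by_nude_enumerates_two_classes():
    classes = expected_for_cross_type(Phenotype.LINEAR, Phenotype.NUDE)
    dists = {cls.pairs[0]: as_plain(cls.distribution) for cls in classes}
    assert dists[(G("SSNn"), G("ssNn"))] == {
        "scaled": F(1, 4),
        "linear": F(1, 2),
        "lethal": F(1, 4),
    }
    assert dists[(G("SsNn"), G("ssNn"))] == {
        "scaled": F(1, 8),
        "linear": F(1, 4),
        "scattered": F(1, 8),
        "nude": F(1, 4),
        "lethal": F(1, 4),
    }
    assert len(classes) == 2


def test_mirror_by_irregular_is_single_scattered_class():
    classes = expected_for_cross_type(Phenotype.MIRROR, Phenotype.IRREGULAR)
    assert len(classes) == 1
    assert classes[0].pairs == ((G("ssnn"), G("ssnn")),)
    assert as_plain(classes[0].distribution) == {"scattered": F(1)}


def test_nude_by_nude_single_class_with_lethal_quarter():
    classes = expected_for_cross_type(Phenotype.NUDE, Phenotype.NUDE)
    assert len(classes) == 1
    assert as_plain(classes[0].distribution) == {
        "scattered": F(1, 4),
        "nude": F(1, 2),
        "lethal": F(1, 4),
    }


def test_scaled_parents_group_equivalent_pairs_without_collapsing():
    classes = expected_for_cross_type(Phenotype.SCALED, Phenotype.SCALED)
    by_size = sorted(len(cls.pairs) for cls in classes)
    assert by_size == [1, 3]  # SSxSS, SSxSs, SsxSS share one distribution


def test_lethal_parent_phenotype_rejected():
    with pytest.raises(ValueError, match="lethal"):
        expected_for_cross_type(Phenotype.LETHAL, Phenotype.NUDE)
    with pytest.raises(ValueError, match="lethal"):
        genotypes_for_phenotype(Phenotype.LETHAL)


# ---------------------------------------------------------------------------
# variant allele models
# ---------------------------------------------------------------------------


def test_weak_n_model_has_no_lethal_class_anywhere():
    for g1, g2 in itertools.product(viable_genotypes(WEAK_N_MODEL), repeat=2):
        assert cross_distribution(g1, g2, WEAK_N_MODEL).prob(Phenotype.LETHAL) == 0


def test_weak_n_nude_cross_gives_three_quarter_nudes():
    dist = cross_distribution(G("ssNn"), G("ssNn"), WEAK_N_MODEL)
    assert as_plain(dist) == {"nude": F(3, 4), "scattered": F(1, 4)}


def test_strong_s_mirror_cross_yields_zero_nudes():
    # a nude-looking s*s* fish crossed to an ordinary mirror: all offspring
    # carry one ordinary and one strong allele and stay in the scattered class
    dist = cross_distribution(G("s*s*nn"), G("ssnn"), STRONG_S_MODEL)
    assert as_plain(dist) == {"scattered": F(1)}


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------

_VIABLE_STANDARD = viable_genotypes(STANDARD_MODEL)


@given(
    st.sampled_from(_VIABLE_STANDARD),
    st.sampled_from(_VIABLE_STANDARD),
)
def test_cross_distribution_properties(g1, g2):
    dist = cross_distribution(g1, g2)
    assert sum(dist.probabilities.values()) == 1
    assert all(p >= 0 for p in dist.probabilities.values())
    assert dist.probabilities == cross_distribution(g2, g1).probabilities


@given(
    st.sampled_from(_VIABLE_STANDARD),
    st.sampled_from(_VIABLE_STANDARD),
    st.floats(min_value=0.0, max_value=1.0),
)
def test_split_then_merge_scattered_roundtrips(g1, g2, split):
    surv = cross_distribution(g1, g2).condition_on_survival()
    back = surv.split_scattered(split).merge_scattered()
    assert back.probabilities == surv.merge_scattered().probabilities
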