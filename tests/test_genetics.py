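"""Gamete rules, inheritance and allele-frequency accounting.

The panmictic one-generation oracles at the bottom pin the mechanistic
gamete rules to exact expectations over mating classes, computed by
exhaustive enumeration of (mother genotype, father genotype, gamete,
gamete) combinations.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from drivewave import genetics
from drivewave.genetics import (
    ChromosomeSystem,
    Genotype,
    Sex,
    drive_allele_frequency,
    gamete_distribution,
    offspring_genotype,
    sex_of,
)

G = Genotype.from_string


@pytest.mark.parametrize(
    "s, sex",
    [
        ("XX", Sex.FEMALE),
        ("XY", Sex.MALE),
        ("XYd", Sex.MALE),
        ("ZW", Sex.FEMALE),
        ("ZdW", Sex.FEMALE),
        ("ZZ", Sex.MALE),
        ("ZZd", Sex.MALE),
        ("ZdZd", Sex.MALE),
    ],
)
def test_sex_of(s, sex):
    assert sex_of(G(s)) is sex


@pytest.mark.parametrize("bad", ["YY", "WW", "YdYd", "XW", "ZY"])
def test_invalid_pairs_unconstructible(bad):
    with pytest.raises(ValueError):
        G(bad)


def test_shredder_gamete_distributions():
    assert gamete_distribution(G("XYd"), 1.0) == {"Yd": 1.0, "X": 0.0}
    d = gamete_distribution(G("XYd"), 0.5)
    assert d["Yd"] == pytest.approx(2 / 3)
    assert d["X"] == pytest.approx(1 / 3)
    assert gamete_distribution(G("ZdW"), 1.0)["Zd"] == 1.0
    # No W target in males: plain Mendelian transmission whatever c is.
    assert gamete_distribution(G("ZZd"), 0.7) == {"Z": 0.5, "Zd": 0.5}
    assert gamete_distribution(G("ZdZd"), 0.3) == {"Zd": 1.0}


@given(c=st.floats(0, 1))
@settings(deadline=None, max_examples=50)
def test_gamete_distributions_normalized(c):
    for s in ("XX", "XY", "XYd", "ZW", "ZdW", "ZZ", "ZZd", "ZdZd"):
        assert sum(gamete_distribution(G(s), c).values()) == pytest.approx(1.0)


def test_c_zero_is_mendelian():
    for s in ("XYd", "ZdW"):
        assert set(gamete_distribution(G(s), 0.0).values()) == {0.5}


def test_offspring_forced_crosses(rng):
    for _ in range(20):
        assert offspring_genotype(G("XX"), G("XYd"), 1.0, rng) == G("XYd")
        assert offspring_genotype(G("ZdW"), G("ZZ"), 1.0, rng) == G("ZZd")
    kids = {str(offspring_genotype(G("XX"), G("XY"), 0.5, rng)) for _ in range(200)}
    assert kids == {"XX", "XY"}


def test_offspring_pairing_errors(rng):
    with pytest.raises(ValueError):
        offspring_genotype(G("XX"), G("ZZ"), 1.0, rng)
    with pytest.raises(ValueError):
        offspring_genotype(G("XX"), G("XX"), 1.0, rng)


def test_drive_allele_frequency_counting():
    assert drive_allele_frequency([G("XX"), G("XY")]) == 0.0
    assert drive_allele_frequency([G("XYd")] * 10) == 1.0
    assert drive_allele_frequency([G("ZdW"), G("ZZ")]) == pytest.approx(1 / 3)
    assert drive_allele_frequency([]) is None
    assert drive_allele_frequency([G("XX"), G("XX")]) is None  # no Y-type chromosomes


def test_vectorized_codes_agree_with_scalar(rng):
    for system, strings in (
        (ChromosomeSystem.XY, ["XX", "XY", "XYd"]),
        (ChromosomeSystem.ZW, ["ZW", "ZdW", "ZZ", "ZZd", "ZdZd"]),
    ):
        codes = np.array([genetics.genotype_code(G(s)) for s in strings], dtype=np.int8)
        assert [genetics.code_to_string(c, system) for c in codes] == strings
        assert genetics.drive_frequency_from_codes(codes, system) == pytest.approx(
            drive_allele_frequency([G(s) for s in strings])
        )
        female = genetics.is_female_codes(codes, system)
        assert [sex_of(G(s)) is Sex.FEMALE for s in strings] == list(female)


def test_vectorized_offspring_match_scalar_distribution(rng):
    """Array offspring draws reproduce the scalar two-gamete composition."""
    n = 40_000
    mothers = np.full(n, genetics.ZW_CODES["ZdW"], dtype=np.int8)
    fathers = np.full(n, genetics.ZW_CODES["ZZd"], dtype=np.int8)
    kids = genetics.draw_offspring_codes(mothers, fathers, ChromosomeSystem.ZW, 0.5, rng)
    freq = {
        s: np.mean(kids == code) for s, code in genetics.ZW_CODES.items()
    }
    # mother: Zd 2/3, W 1/3; father: Z 1/2, Zd 1/2
    assert freq["ZdW"] == pytest.approx(1 / 3 * 1 / 2, abs=0.01)
    assert freq["ZW"] == pytest.approx(1 / 3 * 1 / 2, abs=0.01)
    assert freq["ZZd"] == pytest.approx(2 / 3 * 1 / 2, abs=0.01)
    assert freq["ZdZd"] == pytest.approx(2 / 3 * 1 / 2, abs=0.01)
    assert freq["ZZ"] == 0.0


# ---------------------------------------------------------------------------
# Panmictic one-generation oracles (exact expectations over mating classes)
# ---------------------------------------------------------------------------


def x_shredder_expected_next_q(q: float, c: float) -> float:
    """Male drive frequency after one panmictic generation, by enumeration."""
    fathers = [(G("XYd"), q), (G("XY"), 1 - q)]
    sons = drive_sons = 0.0
    for father, w in fathers:
        for gamete, p in gamete_distribution(father, c).items():
            if gamete in ("Y", "Yd"):
                sons += w * p
                drive_sons += w * p * (gamete == "Yd")
    return drive_sons / sons


def w_shredder_expected_next_q(q: float, c: float) -> float:
    """Zd frequency among offspring Z chromosomes, by enumeration.

    Population construction: carrier (ZdW) mothers at frequency q; male
    genotypes at random-union proportions for Z-chromosome frequency q.
    """
    mothers = [(G("ZdW"), q), (G("ZW"), 1 - q)]
    fathers = [
        (G("ZZ"), (1 - q) ** 2),
        (G("ZZd"), 2 * q * (1 - q)),
        (G("ZdZd"), q**2),
    ]
    zd = z_type = 0.0
    for (mother, wm), (father, wf) in itertools.product(mothers, fathers):
        for gm, pm in gamete_distribution(mother, c).items():
            for gf, pf in gamete_distribution(father, c).items():
                w = wm * wf * pm * pf
                for g in (gm, gf):
                    if g in ("Z", "Zd"):
                        z_type += w
                        zd += w * (g == "Zd")
    return zd / z_type


def expected_female_fraction(q: float, c: float, system: ChromosomeSystem) -> float:
    """Offspring female fraction under panmixia, by enumeration."""
    if system is ChromosomeSystem.XY:
        fathers = [(G("XYd"), q), (G("XY"), 1 - q)]
        return sum(
            w * p
            for father, w in fathers
            for gamete, p in gamete_distribution(father, c).items()
            if gamete == "X"
        )
    mothers = [(G("ZdW"), q), (G("ZW"), 1 - q)]
    return sum(
        w * p
        for mother, w in mothers
        for gamete, p in gamete_distribution(mother, c).items()
        if gamete == "W"
    )


@pytest.mark.parametrize("q", [0.01, 0.1, 0.5, 0.9, 0.99])
@pytest.mark.parametrize("c", [0.0, 0.25, 0.5, 0.75, 1.0])
def test_x_shredder_oracle_matches_recursion(q, c):
    """The mechanistic gamete rules reproduce q' = 2q/(2-c+cq) exactly."""
    expected = 2 * q / (2 - c + c * q)
    assert x_shredder_expected_next_q(q, c) == pytest.approx(expected, abs=1e-14)


@pytest.mark.parametrize("q", [0.01, 0.1, 0.5, 0.9, 0.99])
@pytest.mark.parametrize("c", [0.0, 0.25, 0.5, 0.75, 1.0])
def test_w_shredder_oracle_closed_form(q, c):
    """Enumeration over mating classes gives q' = 2q(3-c)/(6-3c+cq).

    This is the exact one-generation map for Zd frequency among Z-type
    chromosomes under renormalized shredding with random-union male
    genotypes; it fixes 0 and 1 and is neutral at c=0.
    """
    expected = 2 * q * (3 - c) / (6 - 3 * c + c * q)
    assert w_shredder_expected_next_q(q, c) == pytest.approx(expected, abs=1e-14)


@pytest.mark.parametrize("system", list(ChromosomeSystem))
@pytest.mark.parametrize("q, c", [(0.3, 0.5), (0.5, 1.0), (0.9, 0.25), (0.2, 0.0)])
def test_female_fraction_oracle(system, q, c):
    """Offspring female fraction equals (2-c-cq)/(4-2c) in both systems."""
    expected = (2 - c - c * q) / (4 - 2 * c)
    assert expected_female_fraction(q, c, system) == pytest.approx(expected, abs=1e-14)


def test_c_zero_neutrality():
    for q in (0.1, 0.5, 0.9):
        assert x_shredder_expected_next_q(q, 0.0) == pytest.approx(q, abs=1e-14)
        assert w_shredder_expected_next_q(q, 0.0) == pytest.approx(q, abs=1e-14)
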