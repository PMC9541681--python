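"""Sex-chromosome genotypes, shredder gamete rules and inheritance.

Two sex-determination systems are modelled.  In the XY system the drive
allele (Yd) rides on the Y chromosome and shreds X-bearing gametes in
carrier males; in the ZW system the drive (Zd) rides on the Z chromosome
and shreds W-bearing gametes in carrier females.  Shredding destroys the
targeted gametes with probability ``c`` and the surviving gametes are
renormalized, so carrier fecundity is unaffected: an XYd male transmits Yd
with probability ``1/(2-c)`` and X with probability ``(1-c)/(2-c)``, and a
ZdW female transmits Zd/W with the same probabilities.  At ``c = 1``
carriers transmit only the drive-bearing chromosome; at ``c = 0`` both
systems collapse to neutral Mendelian inheritance.

Genotypes are exposed both as small frozen objects (the scalar API) and as
int8 code arrays with vectorized offspring draws (used by the simulator).
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "ChromosomeSystem",
    "Sex",
    "Genotype",
    "sex_of",
    "gamete_distribution",
    "offspring_genotype",
    "drive_allele_frequency",
    "XY_CODES",
    "ZW_CODES",
    "genotype_code",
    "code_to_string",
    "is_female_codes",
    "is_carrier_codes",
    "drive_frequency_from_codes",
    "draw_offspring_codes",
]


class ChromosomeSystem(str, enum.Enum):
    XY = "XY"
    ZW = "ZW"


class Sex(str, enum.Enum):
    FEMALE = "FEMALE"
    MALE = "MALE"


_VALID = {
    ChromosomeSystem.XY: {("X", "X"), ("X", "Y"), ("X", "Yd")},
    ChromosomeSystem.ZW: {("Z", "Z"), ("Z", "Zd"), ("Zd", "Zd"), ("Z", "W"), ("Zd", "W")},
}

# W always sorts last so ("Z", "W") is the canonical order of a ZW pair.
_ORDER = {"X": 0, "Y": 1, "Yd": 2, "Z": 0, "Zd": 1, "W": 2}


@dataclasses.dataclass(frozen=True)
class Genotype:
    """An unordered sex-chromosome pair in one of the two systems.

    YY and WW pairs are unconstructible: a Y can only come from the father
    and a W only from the mother.
    """

    system: ChromosomeSystem
    chromosomes: tuple[str, str]

    def __post_init__(self) -> None:
        system = ChromosomeSystem(self.system)
        pair = tuple(sorted(self.chromosomes, key=_ORDER.__getitem__))
        object.__setattr__(self, "system", system)
        object.__setattr__(self, "chromosomes", pair)
        if pair not in _VALID[system]:
            raise ValueError(f"invalid {system.value} genotype: {self.chromosomes}")

    @classmethod
    def from_string(cls, s: str) -> "Genotype":
        """Parse short genotype strings such as ``"XYd"`` or ``"ZdW"``."""
        tokens: list[str] = []
        for ch in s:
            if ch == "d":
                if not tokens:
                    raise ValueError(f"cannot parse genotype {s!r}")
                tokens[-1] += "d"
            else:
                tokens.append(ch)
        if len(tokens) != 2:
            raise ValueError(f"cannot parse genotype {s!r}")
        system = ChromosomeSystem.XY if tokens[0][0] in "XY" else ChromosomeSystem.ZW
        return cls(system, (tokens[0], tokens[1]))

    def __str__(self) -> str:
        return "".join(self.chromosomes)

    @property
    def carries_drive(self) -> bool:
        return any(c in ("Yd", "Zd") for c in self.chromosomes)


def sex_of(genotype: Genotype) -> Sex:
    """XX and ZW-type pairs are female; XY-type and ZZ-type pairs are male."""
    if genotype.system is ChromosomeSystem.XY:
        return Sex.FEMALE if genotype.chromosomes == ("X", "X") else Sex.MALE
    return Sex.FEMALE if "W" in genotype.chromosomes else Sex.MALE


def gamete_distribution(genotype: Genotype, c: float) -> dict[str, float]:
    """Probability of each gamete chromosome produced by a genotype.

    Mendelian 1/2 : 1/2 everywhere except in an active shredder (an XYd
    male or a ZdW female), whose surviving gametes are renormalized:
    drive chromosome with probability ``1/(2-c)``, the shredding target
    with probability ``(1-c)/(2-c)``.
    """
    if not 0 <= c <= 1:
        raise ValueError(f"shredding efficiency must lie in [0, 1] (got {c})")
    a, b = genotype.chromosomes
    if a == b:
        return {a: 1.0}
    pair = set(genotype.chromosomes)
    if pair == {"X", "Yd"}:
        return {"Yd": 1.0 / (2.0 - c), "X": (1.0 - c) / (2.0 - c)}
    if pair == {"Zd", "W"}:
        return {"Zd": 1.0 / (2.0 - c), "W": (1.0 - c) / (2.0 - c)}
    return {a: 0.5, b: 0.5}


def offspring_genotype(
    mother: Genotype, father: Genotype, c: float, rng: np.random.Generator
) -> Genotype:
    """Sample one gamete from each parent and return the offspring pair."""
    if mother.system is not father.system:
        raise ValueError("parents must share a sex-determination system")
    if sex_of(mother) is not Sex.FEMALE or sex_of(father) is not Sex.MALE:
        raise ValueError("mother must be female and father male")

    def draw(g: Genotype) -> str:
        dist = gamete_distribution(g, c)
        names = list(dist)
        return names[rng.choice(len(names), p=[dist[n] for n in names])]

    return Genotype(mother.system, (draw(mother), draw(father)))


def drive_allele_frequency(genotypes: Iterable[Genotype]) -> float | None:
    """Drive allele frequency of a population of genotypes.

    XY system: Yd count over Y-type chromosomes (i.e. over males).
    ZW system: Zd count over Z-type chromosomes (one per female, two per
    male).  Returns ``None`` when the denominator is empty (no males /
    no Z chromosomes or an empty population) — an undefined frequency is
    distinct from frequency zero.
    """
    genotypes = list(genotypes)
    if not genotypes:
        return None
    num = den = 0
    for g in genotypes:
        for chrom in g.chromosomes:
            if chrom in ("Y", "Yd"):
                den += 1
                num += chrom == "Yd"
            elif chrom in ("Z", "Zd"):
                den += 1
                num += chrom == "Zd"
    if den == 0:
        return None
    return num / den


# ---------------------------------------------------------------------------
# Vectorized integer-coded representation used by the simulator.
# ---------------------------------------------------------------------------

XY_CODES: Mapping[str, int] = {"XX": 0, "XY": 1, "XYd": 2}
ZW_CODES: Mapping[str, int] = {"ZW": 0, "ZdW": 1, "ZZ": 2, "ZZd": 3, "ZdZd": 4}

_XY_STRINGS = {v: k for k, v in XY_CODES.items()}
_ZW_STRINGS = {v: k for k, v in ZW_CODES.items()}

_IS_FEMALE = {
    ChromosomeSystem.XY: np.array([True, False, False]),
    ChromosomeSystem.ZW: np.array([True, True, False, False, False]),
}
_IS_CARRIER = {
    ChromosomeSystem.XY: np.array([False, False, True]),
    ChromosomeSystem.ZW: np.array([False, True, False, True, True]),
}
# Drive and drive-capable chromosome counts per genotype code.
_DRIVE_COUNT = {
    ChromosomeSystem.XY: np.array([0, 0, 1]),
    ChromosomeSystem.ZW: np.array([0, 1, 0, 1, 2]),
}
_DENOM_COUNT = {
    ChromosomeSystem.XY: np.array([0, 1, 1]),  # Y-type chromosomes
    ChromosomeSystem.ZW: np.array([1, 1, 2, 2, 2]),  # Z-type chromosomes
}


def genotype_code(genotype: Genotype) -> int:
    table = XY_CODES if genotype.system is ChromosomeSystem.XY else ZW_CODES
    return table[str(genotype)]


def code_to_string(code: int, system: ChromosomeSystem) -> str:
    return (_XY_STRINGS if system is ChromosomeSystem.XY else _ZW_STRINGS)[int(code)]


def is_female_codes(codes: np.ndarray, system: ChromosomeSystem) -> np.ndarray:
    return _IS_FEMALE[system][codes]


def is_carrier_codes(codes: np.ndarray, system: ChromosomeSystem) -> np.ndarray:
    return _IS_CARRIER[system][codes]


def drive_frequency_from_codes(codes: np.ndarray, system: ChromosomeSystem) -> float | None:
    """Vectorized counterpart of :func:`drive_allele_frequency`."""
    if codes.size == 0:
        return None
    den = int(_DENOM_COUNT[system][codes].sum())
    if den == 0:
        return None
    return float(_DRIVE_COUNT[system][codes].sum()) / den


def draw_offspring_codes(
    mother_codes: np.ndarray,
    father_codes: np.ndarray,
    system: ChromosomeSystem,
    c: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized offspring genotypes, one per (mother, father) entry.

    Equivalent to composing two independent draws from each parent's
    gamete distribution, applied elementwise over aligned parent arrays.
    """
    n = mother_codes.size
    out = np.empty(n, dtype=np.int8)
    if n == 0:
        return out
    u_m = rng.random(n)
    u_f = rng.random(n)
    p_drive = 1.0 / (2.0 - c)  # active shredder's drive-gamete probability
    if system is ChromosomeSystem.XY:
        # Mothers are XX and always give an X; the father's gamete decides.
        xy, xyd = XY_CODES["XY"], XY_CODES["XYd"]
        out[:] = XY_CODES["XX"]
        plain = father_codes == xy
        out[plain & (u_f < 0.5)] = xy
        carrier = father_codes == xyd
        out[carrier & (u_f < p_drive)] = xyd
    else:
        # Mother gamete: W (daughter) or a Z-type chromosome (son).
        mother_gives_w = np.where(
            mother_codes == ZW_CODES["ZdW"], u_m >= p_drive, u_m >= 0.5
        )
        mother_z_is_drive = mother_codes == ZW_CODES["ZdW"]  # her Z is Zd
        # Father gamete: Zd from ZdZd always, from ZZd half the time.
        father_gives_drive = (father_codes == ZW_CODES["ZdZd"]) | (
            (father_codes == ZW_CODES["ZZd"]) & (u_f < 0.5)
        )
        daughters = np.where(father_gives_drive, ZW_CODES["ZdW"], ZW_CODES["ZW"])
        son_drive_count = mother_z_is_drive.astype(int) + father_gives_drive.astype(int)
        sons = np.array([ZW_CODES["ZZ"], ZW_CODES["ZZd"], ZW_CODES["ZdZd"]])[son_drive_count]
        out[:] = np.where(mother_gives_w, daughters, sons)
    return out
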