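"""Monoisotopic-mass arithmetic for small-molecule ion identification.

High-resolution electrospray mass spectrometry identifies metabolites by
comparing observed m/z values against theoretical values computed from an
elemental composition. This module provides exact monoisotopic mass and m/z
computation (with electron-mass correction, which matters at sub-ppm
accuracy), ppm-tolerance matching of observed peaks against candidate ions,
and the built-in NAD+ fragment series used to confirm the identity of the
dauer-exit-promoting food-signal component: the protonated precursor
[NAD+H]+ and its characteristic neutral-loss fragments (nicotinamide, water)
together with the ADP, dehydrated-adenosine and adenine cations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "MONOISOTOPIC_MASSES",
    "ELECTRON_MASS",
    "ElementalFormula",
    "IonSpec",
    "FragmentMatch",
    "monoisotopic_mass",
    "mz",
    "ppm_error",
    "match_fragments",
    "nad_fragment_series",
]

#: Monoisotopic masses (Da) of the most abundant isotope, IUPAC/CODATA values.
MONOISOTOPIC_MASSES: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
}

#: Electron rest mass in Da. At m/z 664 the correction is ~0.8 ppm, which is
#: material at Orbitrap-class mass accuracy.
ELECTRON_MASS: float = 0.00054857990907

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """An elemental composition (element -> nonnegative integer count).

    Supports addition and subtraction so that adduct and neutral-loss
    arithmetic ([M+H]+, loss of nicotinamide, loss of water ...) can be
    written directly on compositions. Subtraction that would drive any
    element count negative is rejected: a fragment cannot lose atoms the
    precursor does not contain.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for element, n in self.counts.items():
            if not isinstance(n, int) or isinstance(n, bool):
                raise TypeError(f"count for {element!r} must be an integer, got {n!r}")
            if n < 0:
                raise ValueError(f"negative count for element {element!r}: {n}")
            if n > 0:
                clean[element] = n
        object.__setattr__(self, "counts", clean)

    @classmethod
    def parse(cls, formula: str) -> "ElementalFormula":
        """Parse a Hill-style formula string such as ``"C21H28N7O14P2"``."""
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(formula):
            if not match.group(0):
                continue
            if match.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r} at {formula[pos:]!r}")
            pos = match.end()
            element = match.group(1)
            counts[element] = counts.get(element, 0) + int(match.group(2) or 1)
        if pos != len(formula):
            raise ValueError(f"cannot parse formula {formula!r} at {formula[pos:]!r}")
        return cls(counts)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for element, n in other.counts.items():
            merged[element] = merged.get(element, 0) + n
        return ElementalFormula(merged)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for element, n in other.counts.items():
            remaining = merged.get(element, 0) - n
            if remaining < 0:
                raise ValueError(
                    f"neutral loss removes more {element} than present "
                    f"({self} - {other})"
                )
            merged[element] = remaining
        return ElementalFormula(merged)

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical.
        elements = sorted(
            self.counts, key=lambda e: (e != "C", e != "H", e)
        )
        return "".join(
            f"{e}{self.counts[e]}" if self.counts[e] != 1 else e for e in elements
        )


@dataclass(frozen=True)
class IonSpec:
    """A gas-phase ion: the intact composition (protons included) plus charge."""

    formula: ElementalFormula
    charge: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("an ion must carry a nonzero charge for m/z computation")


@dataclass(frozen=True)
class FragmentMatch:
    """Pairing of an observed m/z with a candidate ion within tolerance."""

    observed_mz: float
    candidate: IonSpec | None
    theoretical_mz: float | None
    error_ppm: float | None

    @property
    def matched(self) -> bool:
        return self.candidate is not None


def monoisotopic_mass(formula: ElementalFormula | str) -> float:
    """Monoisotopic mass in Da: sum of count x most-abundant-isotope mass."""
    if isinstance(formula, str):
        formula = ElementalFormula.parse(formula)
    total = 0.0
    for element, n in formula.counts.items():
        try:
            total += n * MONOISOTOPIC_MASSES[element]
        except KeyError:
            raise ValueError(f"unknown element symbol: {element!r}") from None
    return total


def mz(ion: IonSpec) -> float:
    """m/z of an ion: (monoisotopic mass - charge x electron mass) / |charge|."""
    if ion.charge == 0:
        raise ValueError("charge must be nonzero")
    return (monoisotopic_mass(ion.formula) - ion.charge * ELECTRON_MASS) / abs(ion.charge)


def ppm_error(observed: float, theoretical: float) -> float:
    """Relative mass error in parts per million: 1e6 (obs - theo) / theo."""
    return 1e6 * (observed - theoretical) / theoretical


def match_fragments(
    observed: Sequence[float],
    candidates: Iterable[IonSpec],
    tol_ppm: float = 5.0,
) -> list[FragmentMatch]:
    """Match observed m/z values against candidate ions within a ppm window.

    Every (observed, candidate) pair within ``tol_ppm`` is reported; observed
    values with no candidate inside the window are reported as unmatched
    (``candidate is None``) so the caller can see unexplained peaks.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    theoretical = [(ion, mz(ion)) for ion in candidates]
    matches: list[FragmentMatch] = []
    for obs in observed:
        hit = False
        for ion, theo in theoretical:
            err = ppm_error(obs, theo)
            if abs(err) <= tol_ppm:
                matches.append(FragmentMatch(obs, ion, theo, err))
                hit = True
        if not hit:
            matches.append(FragmentMatch(obs, None, None, None))
    return matches


# Neutral molecules used in the NAD+ fragmentation arithmetic.
_PROTON = ElementalFormula({"H": 1})
_WATER = ElementalFormula.parse("H2O")
_NICOTINAMIDE = ElementalFormula.parse("C6H6N2O")
# Neutral NAD+ free acid; protonation gives the [NAD+H]+ precursor at m/z 664.
_NAD_FREE_ACID = ElementalFormula.parse("C21H27N7O14P2")
_ADP = ElementalFormula.parse("C10H15N5O10P2")
_ADENOSINE = ElementalFormula.parse("C10H13N5O4")
_ADENINE = ElementalFormula.parse("C5H5N5")


def nad_fragment_series() -> list[IonSpec]:
    """The built-in NAD+ candidate series: precursor plus five HCD fragments.

    All compositions are assembled by adduct/neutral-loss arithmetic from the
    NAD+ free acid: protonation, loss of nicotinamide, further loss of water,
    and the ADP / twice-dehydrated adenosine / adenine cations that arise from
    cleavage around the pyrophosphate and glycosidic bonds.
    """
    precursor = _NAD_FREE_ACID + _PROTON
    return [
        IonSpec(precursor, 1, "[NAD+H]+"),
        IonSpec(precursor - _NICOTINAMIDE, 1, "[NAD+H-nicotinamide]+"),
        IonSpec(precursor - _NICOTINAMIDE - _WATER, 1, "[NAD+H-nicotinamide-H2O]+"),
        IonSpec(_ADP + _PROTON, 1, "[ADP+H]+"),
        IonSpec(_ADENOSINE + _PROTON - _WATER - _WATER, 1, "[adenosine+H-2H2O]+"),
        IonSpec(_ADENINE + _PROTON, 1, "[adenine+H]+"),
    ]
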