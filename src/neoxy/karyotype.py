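"""Sex-chromosome complements, karyomorphs, and sex-determination hypotheses.

The mandarin vole (*Lasiopodomys mandarinus vinogradovi*) carries a complex
of neo-sex chromosomes built from two autosome-to-sex-chromosome
translocations.  Four elements participate:

============  =============  ===============  =========================
element       X euchromatin  autosomal block  description
============  =============  ===============  =========================
``neo-X1``    yes            A1               metacentric, X + MAG13 homolog
``neo-X2``    yes            A2               submetacentric, X + MAG17/19
``neo-X3``    no             A2               small acrocentric, MAG17/19
``neo-Y``     no             A1               small acrocentric, MAG13 homolog
============  =============  ===============  =========================

The neo-Y carries only X-homologous *repeats* (no functional X
euchromatin): chromosome sequencing shows synteny with the MAG13 block
alone, so dosage accounting counts it as zero X.

Four karyomorphs occur in nature: KI males (neo-X1/neo-X3/neo-X3/neo-Y,
2n=48) and three female forms — KII (neo-X1/neo-X2/neo-X3, 2n=47),
KIII (neo-X2/neo-X3/neo-Y, 2n=47) and KIV (neo-X1/neo-X1/neo-X3/neo-X3,
2n=48).  Under a standard "Y makes male" rule KIII animals would be male;
the XY-female hypothesis — encoded here as three alternative mechanisms —
assigns them a female phenotype, as in wood and collared lemmings.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

__all__ = [
    "Element",
    "Sex",
    "SexComplement",
    "Karyomorph",
    "Hypothesis",
    "ViabilityModel",
    "classify_karyomorph",
    "phenotype",
    "dosage",
    "viability_weight",
    "KARYOMORPH_COMPLEMENTS",
    "STANDARD_REGIME_COMPLEMENTS",
]


class Element(Enum):
    """One of the four chromosomes of the sex complex."""

    X1 = "neo-X1"
    X2 = "neo-X2"
    X3 = "neo-X3"
    Y = "neo-Y"

    @property
    def has_x_euchromatin(self) -> bool:
        return self in (Element.X1, Element.X2)

    @property
    def autosomal_block(self) -> str | None:
        """Translocated autosomal block: A1 (MAG13/MMU18 homolog) or A2
        (MAG17/19 homolog); the sort key of the canonical serialization."""
        if self in (Element.X1, Element.Y):
            return "A1"
        return "A2"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: canonical ordering for serialized complements: X1 < X2 < X3 < Y
_ORDER = {Element.X1: 0, Element.X2: 1, Element.X3: 2, Element.Y: 3}


class Sex(Enum):
    MALE = "male"
    FEMALE = "female"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class ComplementError(ValueError):
    """Raised for malformed sex-chromosome complements or parameters."""


@dataclass(frozen=True)
class SexComplement:
    """An (unordered) multiset of sex-complex chromosomes.

    Gametes, zygotes and somatic complements are all represented this way;
    the empty complement stands for a nullo ("0") gamete.  Copy numbers are
    capped at 2 and the total at 4 (a zygote formed from two balanced
    gametes of a 2n=47/48 animal can carry at most four sex elements).
    """

    elements: tuple[Element, ...]

    def __init__(self, elements: Iterable[Element] = ()):
        elems = tuple(sorted(elements, key=_ORDER.__getitem__))
        counts = Counter(elems)
        if any(v > 2 for v in counts.values()):
            raise ComplementError(
                f"copy number > 2 in complement {[e.value for e in elems]}"
            )
        if len(elems) > 4:
            raise ComplementError(f"more than 4 sex elements: {len(elems)}")
        object.__setattr__(self, "elements", elems)

    @classmethod
    def from_string(cls, text: str) -> "SexComplement":
        """Parse a slash-separated complement, e.g. ``"neo-X1/neo-X2/neo-X3"``.

        Accepts any element order and the short spellings ``X1``..``Y``.
        An empty string or ``"0"`` denotes the empty complement.
        """
        text = text.strip()
        if text in ("", "0"):
            return cls(())
        alias = {e.value: e for e in Element}
        alias.update({e.name: e for e in Element})
        alias.update({e.value.replace("neo-", ""): e for e in Element})
        members = []
        for token in text.split("/"):
            token = token.strip()
            if token == "0":
                continue
            if token not in alias:
                raise ComplementError(f"unknown sex chromosome {token!r}")
            members.append(alias[token])
        return cls(members)

    @property
    def counts(self) -> Mapping[Element, int]:
        return Counter(self.elements)

    def count(self, element: Element) -> int:
        return self.elements.count(element)

    def __contains__(self, element: Element) -> bool:
        return element in self.elements

    def __len__(self) -> int:
        return len(self.elements)

    def union(self, other: "SexComplement") -> "SexComplement":
        """Multiset union — the zygote formed by two gametes."""
        return SexComplement(self.elements + other.elements)

    def __add__(self, other: "SexComplement") -> "SexComplement":
        return self.union(other)

    def __str__(self) -> str:
        if not self.elements:
            return "0"
        return "/".join(e.value for e in self.elements)


def _c(*elems: Element) -> SexComplement:
    return SexComplement(elems)


class Karyomorph(Enum):
    """The karyomorphs observed among 205 karyotyped voles, plus UNLISTED."""

    KI = "KI"
    KII = "KII"
    KIII = "KIII"
    KIV = "KIV"
    UNLISTED = "UNLISTED"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: full complements, as resolved by chromosome painting (2n in parentheses)
KARYOMORPH_COMPLEMENTS: dict[Karyomorph, SexComplement] = {
    Karyomorph.KI: _c(Element.X1, Element.X3, Element.X3, Element.Y),    # 2n=48
    Karyomorph.KII: _c(Element.X1, Element.X2, Element.X3),              # 2n=47
    Karyomorph.KIII: _c(Element.X2, Element.X3, Element.Y),              # 2n=47
    Karyomorph.KIV: _c(Element.X1, Element.X1, Element.X3, Element.X3),  # 2n=48
}

DIPLOID_NUMBERS: dict[Karyomorph, int] = {
    Karyomorph.KI: 48,
    Karyomorph.KII: 47,
    Karyomorph.KIII: 47,
    Karyomorph.KIV: 48,
}

#: reduced complements used by the standard-hypothesis bookkeeping, which
#: treats the small acrocentrics as unidentifiable ("/0") and tracks only
#: the recognized sex chromosomes: KI = X1/Y, KII = X1/X2, KIII = X2/0,
#: KIV = X1/X1.
STANDARD_REGIME_COMPLEMENTS: dict[Karyomorph, SexComplement] = {
    Karyomorph.KI: _c(Element.X1, Element.Y),
    Karyomorph.KII: _c(Element.X1, Element.X2),
    Karyomorph.KIII: _c(Element.X2),
    Karyomorph.KIV: _c(Element.X1, Element.X1),
}

_CLASSIFY = {
    **{v: k for k, v in KARYOMORPH_COMPLEMENTS.items()},
    **{v: k for k, v in STANDARD_REGIME_COMPLEMENTS.items()},
}


def classify_karyomorph(complement: SexComplement) -> Karyomorph:
    """Map a complement to its karyomorph label.

    Both the fully resolved complements (painting nomenclature) and the
    reduced standard-regime forms are recognized; any other combination —
    including every lethal zygote class — is ``UNLISTED`` rather than an
    error, so the cross engine can enumerate unobserved zygotes.
    """
    if not isinstance(complement, SexComplement):
        raise ComplementError(f"not a SexComplement: {complement!r}")
    return _CLASSIFY.get(complement, Karyomorph.UNLISTED)


class Hypothesis(Enum):
    """Competing genotype-to-sex rules.

    STANDARD
        Presence of neo-Y is necessary and sufficient for testis
        development.
    MECH_A
        neo-X2 carries an epistatic locus (B) suppressing the dominant
        male trigger (A) on neo-Y: male iff Y present and X2 absent.
    MECH_B
        neo-X1 carries a locus (D) complementing the male trigger (C) on
        neo-Y: male iff both Y and X1 present (the wood-lemming-like
        deletion scenario; neo-X2 lacks the complementing locus).
    MECH_C
        The male trigger sits on neo-X1 itself, inactive in double dose
        and suppressed (or subject to nonrandom inactivation) when neo-X2
        is present: male iff exactly one neo-X1 copy and no neo-X2.
    """

    STANDARD = "standard"
    MECH_A = "mech_a"
    MECH_B = "mech_b"
    MECH_C = "mech_c"

    @property
    def xy_female(self) -> bool:
        """True for the three XY-female mechanisms."""
        return self is not Hypothesis.STANDARD

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def phenotype(complement: SexComplement, hypothesis: Hypothesis) -> Sex:
    """Phenotypic sex of a complement under a hypothesis.

    Total over all complements, including lethal ones (viability is a
    separate concern, see :func:`viability_weight`).
    """
    n_x1 = complement.count(Element.X1)
    has_x2 = Element.X2 in complement
    has_y = Element.Y in complement
    if hypothesis is Hypothesis.STANDARD:
        male = has_y
    elif hypothesis is Hypothesis.MECH_A:
        male = has_y and not has_x2
    elif hypothesis is Hypothesis.MECH_B:
        male = has_y and n_x1 >= 1
    elif hypothesis is Hypothesis.MECH_C:
        male = n_x1 == 1 and not has_x2
    else:  # pragma: no cover - exhaustive
        raise ValueError(hypothesis)
    return Sex.MALE if male else Sex.FEMALE


def dosage(complement: SexComplement) -> tuple[int, int, int]:
    """Copy numbers ``(nX, nA1, nA2)`` of X euchromatin and the two
    translocated autosomal blocks, summed over elements.

    KIII females are X-monosomic (nX = 1); KI males are disomic for the A1
    block (once on the neo-X1 q-arm, once as the neo-Y body).
    """
    n_x = sum(1 for e in complement.elements if e.has_x_euchromatin)
    n_a1 = sum(1 for e in complement.elements if e.autosomal_block == "A1")
    n_a2 = sum(1 for e in complement.elements if e.autosomal_block == "A2")
    return (n_x, n_a1, n_a2)


@dataclass(frozen=True)
class ViabilityModel:
    """Zygote viability weights under one regime.

    Under the XY-female regime the only lethal class is a zygote without
    any X euchromatin (operationally: neither neo-X1 nor neo-X2), the
    neo-Y/neo-Y combination being the canonical case.  Under the standard
    regime the lethal set is the one invoked to explain the missing
    karyomorphs: no-X zygotes, neo-X2/neo-Y males, and monosomic "/0"
    zygotes (neo-X1/0, neo-Y/0).

    ``v_x1x1`` is the relative viability of neo-X1/neo-X1 (double-X1)
    zygotes, in [0, 1]; 1 means fully viable.  Reduced values encode the
    "apparent lower viability" explanation for the rarity of KIV.
    """

    xy_female: bool = True
    v_x1x1: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.v_x1x1 <= 1.0:
            raise ComplementError(f"v_x1x1 must lie in [0, 1], got {self.v_x1x1}")

    @classmethod
    def for_hypothesis(
        cls, hypothesis: Hypothesis, v_x1x1: float = 1.0
    ) -> "ViabilityModel":
        return cls(xy_female=hypothesis.xy_female, v_x1x1=v_x1x1)

    def weight(self, complement: SexComplement) -> float:
        n_x1 = complement.count(Element.X1)
        has_x2 = Element.X2 in complement
        no_x = n_x1 == 0 and not has_x2
        if self.xy_female:
            if no_x:
                return 0.0
        else:
            if no_x:
                return 0.0
            if has_x2 and Element.Y in complement:
                return 0.0
            if len(complement) < 2:  # monosomic "/0" zygote
                return 0.0
        if n_x1 == 2:
            return self.v_x1x1
        return 1.0


def viability_weight(complement: SexComplement, model: ViabilityModel) -> float:
    """Relative viability in [0, 1] of a zygote complement; 0 = lethal."""
    return model.weight(complement)
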