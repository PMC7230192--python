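"""Gamete formation and dam x sire cross models.

In females the three (KII, KIII) or four (KIV) sex elements pair at
meiosis as a trivalent chain or two bivalents.  The model resolves every
trivalent by strictly alternate (balanced) segregation into exactly two
gamete classes — the unique rule that regenerates all four observed
offspring karyomorphs from a KI sire without invoking nondisjunction:

* KI male (X1-X3-X3-Y): gametes ``{X1, X3}`` and ``{Y, X3}``;
* KII female (X1-X2-X3 chain): ``{X1, X3}`` or ``{X2}``;
* KIII female (X3-X2-Y chain): ``{X2}`` or ``{X3, Y}``;
* KIV female (two bivalents): ``{X1, X3}`` only.

Transmission-ratio distortion is modeled at fertilization: the relative
success of neo-X1- vs neo-Y-bearing sperm is a weight pair conditioned on
the karyomorph of the fertilized female (the data suggest neo-Y sperm are
favored in KII dams and neo-X1 sperm in KIII/KIV dams).  Under the
STANDARD regime the small acrocentrics are unidentifiable and gametes
track only the recognized sex chromosomes, with the nullo class written
``0`` (as in neo-X1/0, neo-Y/0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import pandas as pd

from .karyotype import (
    Element,
    Hypothesis,
    Karyomorph,
    KARYOMORPH_COMPLEMENTS,
    STANDARD_REGIME_COMPLEMENTS,
    Sex,
    SexComplement,
    ViabilityModel,
    classify_karyomorph,
    phenotype,
)

__all__ = [
    "CrossParameters",
    "GameteDistribution",
    "OffspringDistribution",
    "UnsupportedCrossError",
    "gametes",
    "cross",
    "expected_sex_ratio",
    "nonviable_fraction",
    "daughter_karyomorph_distribution",
]

_PROB_TOL = 1e-12

DAM_KARYOMORPHS = (Karyomorph.KII, Karyomorph.KIII, Karyomorph.KIV)


class UnsupportedCrossError(ValueError):
    """Raised for karyomorphs or crosses outside the breeding design."""


def _default_weights() -> dict[Karyomorph, float]:
    return {k: 1.0 for k in DAM_KARYOMORPHS}


@dataclass(frozen=True)
class CrossParameters:
    """Segregation, sperm-selection and viability parameters.

    Attributes
    ----------
    w_x1, w_y:
        Relative fertilization success of neo-X1- and neo-Y-bearing sperm,
        per dam karyomorph (only the ratio ``w_y / w_x1`` is identifiable).
        Defaults of 1 : 1 mean no gamete selection.
    s_kii, s_kiii:
        Probability of the X1-bearing ({X1, X3}) gamete class in KII dam
        trivalent segregation, and of the X2-bearing ({X2}) class in KIII
        dams.  Default 0.5 (fair alternate resolution).
    v_x1x1:
        Relative viability of neo-X1/neo-X1 zygotes, passed to the
        :class:`~neoxy.karyotype.ViabilityModel`.
    """

    w_x1: Mapping[Karyomorph, float] = field(default_factory=_default_weights)
    w_y: Mapping[Karyomorph, float] = field(default_factory=_default_weights)
    s_kii: float = 0.5
    s_kiii: float = 0.5
    v_x1x1: float = 1.0

    def __post_init__(self) -> None:
        for name, mapping in (("w_x1", self.w_x1), ("w_y", self.w_y)):
            for k, w in mapping.items():
                if w < 0:
                    raise ValueError(f"{name}[{k}] must be >= 0, got {w}")
        for name, s in (("s_kii", self.s_kii), ("s_kiii", self.s_kiii)):
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {s}")
        if not 0.0 <= self.v_x1x1 <= 1.0:
            raise ValueError(f"v_x1x1 must lie in [0, 1], got {self.v_x1x1}")

    def viability_model(self, hypothesis: Hypothesis) -> ViabilityModel:
        return ViabilityModel.for_hypothesis(hypothesis, v_x1x1=self.v_x1x1)

    def with_updates(self, **kwargs) -> "CrossParameters":
        """Return a copy with scalar fields replaced and/or single sperm
        weights updated (keys ``wY_KII`` ... ``wY_KIV``)."""
        w_y = dict(self.w_y)
        scalars = {}
        for key, value in kwargs.items():
            if key.startswith("wY_"):
                w_y[Karyomorph(key[3:])] = float(value)
            else:
                scalars[key] = value
        return replace(self, w_y=w_y, **scalars)


@dataclass(frozen=True)
class GameteDistribution:
    """Discrete distribution over gamete complements."""

    entries: tuple[tuple[SexComplement, float], ...]

    def __post_init__(self) -> None:
        total = sum(p for _, p in self.entries)
        if any(p < 0 for _, p in self.entries):
            raise ValueError("negative gamete probability")
        if abs(total - 1.0) > _PROB_TOL:
            raise ValueError(f"gamete probabilities sum to {total}, not 1")

    def items(self) -> Iterable[tuple[SexComplement, float]]:
        return self.entries


def _g(*elems: Element) -> SexComplement:
    return SexComplement(elems)


def gametes(
    karyomorph: Karyomorph,
    sex: Sex,
    params: CrossParameters | None = None,
    hypothesis: Hypothesis = Hypothesis.MECH_A,
) -> GameteDistribution:
    """Balanced-segregation gamete distribution for one parent.

    Sperm-selection weights are *not* applied here — they act at
    fertilization, conditioned on the dam karyomorph (see :func:`cross`) —
    so KI male gametes are an unweighted 1/2 : 1/2.
    """
    params = params or CrossParameters()
    if karyomorph not in KARYOMORPH_COMPLEMENTS:
        raise UnsupportedCrossError(f"unsupported karyomorph: {karyomorph}")
    table = (
        STANDARD_REGIME_COMPLEMENTS
        if not hypothesis.xy_female
        else KARYOMORPH_COMPLEMENTS
    )
    expected_sex = phenotype(table[karyomorph], hypothesis)
    if sex is not expected_sex:
        raise UnsupportedCrossError(
            f"{karyomorph} is {expected_sex.value} under {hypothesis.value}, "
            f"not {sex.value}"
        )
    s2, s3 = params.s_kii, params.s_kiii
    if hypothesis.xy_female:
        rules = {
            Karyomorph.KI: [
                (_g(Element.X1, Element.X3), 0.5),
                (_g(Element.Y, Element.X3), 0.5),
            ],
            Karyomorph.KII: [
                (_g(Element.X1, Element.X3), s2),
                (_g(Element.X2), 1.0 - s2),
            ],
            Karyomorph.KIII: [
                (_g(Element.X2), s3),
                (_g(Element.X3, Element.Y), 1.0 - s3),
            ],
            Karyomorph.KIV: [(_g(Element.X1, Element.X3), 1.0)],
        }
    else:
        rules = {
            Karyomorph.KI: [(_g(Element.X1), 0.5), (_g(Element.Y), 0.5)],
            Karyomorph.KII: [(_g(Element.X1), s2), (_g(Element.X2), 1.0 - s2)],
            Karyomorph.KIII: [(_g(Element.X2), s3), (_g(), 1.0 - s3)],
            Karyomorph.KIV: [(_g(Element.X1), 1.0)],
        }
    entries = tuple((g, p) for g, p in rules[karyomorph] if p > 0.0)
    return GameteDistribution(entries)


@dataclass(frozen=True)
class OffspringDistribution:
    """Zygote classes of one cross, with raw and viability-renormalized
    probabilities.

    ``table`` columns: zygote (canonical string), karyomorph, sex, raw_p,
    viability, norm_p.  Raw probabilities sum to 1 over all zygotes;
    norm_p sums to 1 over classes with positive viability.
    """

    dam: Karyomorph
    sire: Karyomorph
    hypothesis: Hypothesis
    table: pd.DataFrame

    def male_fraction(self) -> float:
        """Proportion of males among (viability-weighted) live offspring."""
        male = self.table["sex"] == Sex.MALE.value
        return float(self.table.loc[male, "norm_p"].sum())

    def nonviable_fraction(self) -> float:
        """Raw-probability mass of fully lethal (weight 0) zygote classes."""
        lethal = self.table["viability"] == 0.0
        return float(self.table.loc[lethal, "raw_p"].sum())

    def daughter_distribution(self) -> dict[Karyomorph, float]:
        """Distribution of karyomorphs among live daughters."""
        fem = self.table[self.table["sex"] == Sex.FEMALE.value]
        total = fem["norm_p"].sum()
        if total <= 0:
            return {}
        out: dict[Karyomorph, float] = {}
        for _, row in fem.iterrows():
            if row["norm_p"] <= 0:
                continue
            k = Karyomorph(row["karyomorph"])
            out[k] = out.get(k, 0.0) + float(row["norm_p"]) / float(total)
        return out

    def class_probability(self, karyomorph: Karyomorph, sex: Sex) -> float:
        """Normalized probability of one live (karyomorph, sex) class."""
        sel = (self.table["karyomorph"] == karyomorph.value) & (
            self.table["sex"] == sex.value
        )
        return float(self.table.loc[sel, "norm_p"].sum())


def cross(
    dam: Karyomorph,
    sire: Karyomorph,
    hypothesis: Hypothesis = Hypothesis.MECH_A,
    params: CrossParameters | None = None,
) -> OffspringDistribution:
    """Offspring distribution of a dam x KI-sire cross.

    The product of the two gamete distributions, with the sire's X1- vs
    Y-sperm classes reweighted by ``(w_x1[dam], w_y[dam])`` at
    fertilization, then viability weighting and renormalization over live
    zygotes.  Each zygote is the multiset union of its gametes.
    """
    params = params or CrossParameters()
    if sire is not Karyomorph.KI:
        raise UnsupportedCrossError(
            f"only KI sires occur in nature; got {sire}"
        )
    if dam not in DAM_KARYOMORPHS:
        raise UnsupportedCrossError(f"dam must be KII, KIII or KIV; got {dam}")

    dam_g = gametes(dam, Sex.FEMALE, params, hypothesis)
    sire_g = gametes(sire, Sex.MALE, params, hypothesis)

    # fertilization-stage sperm selection, conditioned on the dam
    w_x1 = float(params.w_x1.get(dam, 1.0))
    w_y = float(params.w_y.get(dam, 1.0))
    weighted = []
    for g, p in sire_g.items():
        w = w_y if Element.Y in g else w_x1
        weighted.append((g, p * w))
    total_w = sum(p for _, p in weighted)
    if total_w <= 0:
        raise ValueError("all sperm classes have zero fertilization weight")
    sire_entries = [(g, p / total_w) for g, p in weighted]

    viability = params.viability_model(hypothesis)
    zygotes: dict[SexComplement, float] = {}
    for dg, dp in dam_g.items():
        for sg, sp in sire_entries:
            z = dg + sg
            zygotes[z] = zygotes.get(z, 0.0) + dp * sp

    rows = []
    for z, raw in sorted(zygotes.items(), key=lambda kv: str(kv[0])):
        v = viability.weight(z)
        rows.append(
            {
                "zygote": str(z),
                "karyomorph": classify_karyomorph(z).value,
                "sex": phenotype(z, hypothesis).value,
                "raw_p": raw,
                "viability": v,
            }
        )
    table = pd.DataFrame(rows)
    live = table["raw_p"] * table["viability"]
    norm = live.sum()
    table["norm_p"] = live / norm if norm > 0 else 0.0
    return OffspringDistribution(dam=dam, sire=sire, hypothesis=hypothesis, table=table)


def expected_sex_ratio(
    dam: Karyomorph,
    sire: Karyomorph = Karyomorph.KI,
    hypothesis: Hypothesis = Hypothesis.MECH_A,
    params: CrossParameters | None = None,
) -> float:
    """Expected proportion of sons among live offspring of a cross."""
    return cross(dam, sire, hypothesis, params).male_fraction()


def nonviable_fraction(
    dam: Karyomorph,
    sire: Karyomorph = Karyomorph.KI,
    hypothesis: Hypothesis = Hypothesis.MECH_A,
    params: CrossParameters | None = None,
) -> float:
    """Fraction of zygotes falling in lethal classes (viability weight 0)."""
    return cross(dam, sire, hypothesis, params).nonviable_fraction()


def daughter_karyomorph_distribution(
    dam: Karyomorph,
    sire: Karyomorph = Karyomorph.KI,
    hypothesis: Hypothesis = Hypothesis.MECH_A,
    params: CrossParameters | None = None,
) -> dict[Karyomorph, float]:
    """Karyomorph distribution among live daughters of a cross."""
    return cross(dam, sire, hypothesis, params).daughter_distribution()
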