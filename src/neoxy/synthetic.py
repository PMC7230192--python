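"""Synthetic breeding-colony data with the structure of the real design.

The emulated experiment: dams of karyomorphs KII/KIII/KIV, each crossed
to a KI sire, all surviving offspring sexed, and a fraction of each dam's
daughters karyotyped.  Defaults mirror the real colony: 17 KII, 18 KIII
and 3 KIV dams, a mean of 8.6 sexed offspring per dam (327 offspring from
38 dams), and about a third of daughters karyotyped (64 of ~196).

Per-dam offspring totals are negative binomial (configurable dispersion;
litter sizes are not printed per dam, so litters within a dam are pooled
and offspring are i.i.d. across a dam's progeny by default).  Offspring
genotype/sex classes are drawn from the cross model's live-offspring
distribution, so the generator is exact with respect to whatever
hypothesis and parameters it is handed — it is the parameter-recovery
engine for the inference tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .karyotype import Hypothesis, Karyomorph, Sex
from .meiosis import CrossParameters, DAM_KARYOMORPHS, cross
from .inference import CrossCounts, ProgenyCounts

__all__ = [
    "BreedingDesign",
    "simulate_breeding_experiment",
    "simulate_karyotyped_daughters",
]

_DAUGHTER_CLASSES = (Karyomorph.KII, Karyomorph.KIII, Karyomorph.KIV)


def _default_dams() -> dict[Karyomorph, int]:
    return {Karyomorph.KII: 17, Karyomorph.KIII: 18, Karyomorph.KIV: 3}


@dataclass(frozen=True)
class BreedingDesign:
    """Size and sampling structure of a simulated breeding experiment.

    ``mean_offspring`` is the expected number of sexed offspring per dam
    over the experiment; ``dispersion`` the negative-binomial size
    parameter (larger = closer to Poisson).  ``karyotype_fraction`` is
    the fraction of each dam's daughters karyotyped (simple random
    subsample without replacement).
    """

    n_dams: Mapping[Karyomorph, int] = field(default_factory=_default_dams)
    mean_offspring: float = 8.6
    dispersion: float = 20.0
    karyotype_fraction: float = 0.33
    seed: int | None = None

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.n_dams.values()):
            raise ValueError("n_dams must be >= 0")
        if self.mean_offspring < 0 or self.dispersion <= 0:
            raise ValueError("mean_offspring >= 0 and dispersion > 0 required")
        if not 0.0 <= self.karyotype_fraction <= 1.0:
            raise ValueError("karyotype_fraction must lie in [0, 1]")


def _negative_binomial(
    rng: np.random.Generator, mean: float, dispersion: float, size: int
) -> np.ndarray:
    if mean == 0:
        return np.zeros(size, dtype=int)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def simulate_breeding_experiment(
    design: BreedingDesign,
    hypothesis: Hypothesis = Hypothesis.MECH_A,
    params: CrossParameters | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ProgenyCounts, pd.DataFrame]:
    """Simulate one breeding experiment; fully reproducible from the seed.

    Returns the aggregated :class:`~neoxy.inference.ProgenyCounts` and a
    per-dam table (dam_id, dam_karyomorph, n_sons, per-karyomorph daughter
    and karyotyped-daughter counts).
    """
    params = params or CrossParameters()
    if rng is None:
        rng = np.random.default_rng(design.seed)
    rows = []
    for dam_k in DAM_KARYOMORPHS:
        n_dams = int(design.n_dams.get(dam_k, 0))
        if n_dams == 0:
            continue
        dist = cross(dam_k, Karyomorph.KI, hypothesis, params)
        live = dist.table[dist.table["norm_p"] > 0]
        class_keys = [
            (Karyomorph(r["karyomorph"]), Sex(r["sex"]))
            for _, r in live.iterrows()
        ]
        class_p = live["norm_p"].to_numpy(dtype=float)
        litters = _negative_binomial(
            rng, design.mean_offspring, design.dispersion, n_dams
        )
        for i, n_off in enumerate(litters):
            draws = (
                rng.multinomial(int(n_off), class_p)
                if n_off > 0
                else np.zeros(len(class_p), dtype=int)
            )
            sons = 0
            daughters = {k: 0 for k in _DAUGHTER_CLASSES}
            for (k, sex), c in zip(class_keys, draws):
                if sex is Sex.MALE:
                    sons += int(c)
                else:
                    daughters[k] = daughters.get(k, 0) + int(c)
            rows.append(
                {
                    "dam_id": f"{dam_k.value}-{i + 1:03d}",
                    "dam_karyomorph": dam_k.value,
                    "sire_karyomorph": Karyomorph.KI.value,
                    "n_sons": sons,
                    **{
                        f"daughters_{k.value}": daughters.get(k, 0)
                        for k in _DAUGHTER_CLASSES
                    },
                }
            )
    per_dam = pd.DataFrame(
        rows,
        columns=[
            "dam_id",
            "dam_karyomorph",
            "sire_karyomorph",
            "n_sons",
            *(f"daughters_{k.value}" for k in _DAUGHTER_CLASSES),
        ],
    )
    per_dam = _attach_karyotyped(per_dam, design.karyotype_fraction, rng)
    return aggregate_progeny_counts(per_dam), per_dam


def _attach_karyotyped(
    per_dam: pd.DataFrame, fraction: float, rng: np.random.Generator
) -> pd.DataFrame:
    per_dam = per_dam.copy()
    cols = [f"daughters_{k.value}" for k in _DAUGHTER_CLASSES]
    k_cols = {f"k_daughters_{k.value}": [] for k in _DAUGHTER_CLASSES}
    for _, row in per_dam.iterrows():
        pool = [int(row[c]) for c in cols]
        total = sum(pool)
        m = int(round(fraction * total))
        sample = (
            rng.multivariate_hypergeometric(pool, m)
            if m > 0
            else np.zeros(len(pool), dtype=int)
        )
        for (k, c) in zip(_DAUGHTER_CLASSES, sample):
            k_cols[f"k_daughters_{k.value}"].append(int(c))
    for name, values in k_cols.items():
        per_dam[name] = values
    return per_dam


def simulate_karyotyped_daughters(
    per_dam: pd.DataFrame, fraction: float, seed: int | None = None
) -> dict[Karyomorph, dict[Karyomorph, int]]:
    """Re-draw the karyotyped subsample of daughters from a per-dam table.

    Per dam, ``round(fraction * n_daughters)`` daughters are sampled
    without replacement; returns karyotyped counts per dam karyomorph.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    table = _attach_karyotyped(
        per_dam.drop(
            columns=[c for c in per_dam.columns if c.startswith("k_daughters_")]
        ),
        fraction,
        rng,
    )
    out: dict[Karyomorph, dict[Karyomorph, int]] = {}
    for dam_k, group in table.groupby("dam_karyomorph"):
        out[Karyomorph(dam_k)] = {
            k: int(group[f"k_daughters_{k.value}"].sum())
            for k in _DAUGHTER_CLASSES
        }
    return out


def aggregate_progeny_counts(per_dam: pd.DataFrame) -> ProgenyCounts:
    """Pool a per-dam table into :class:`~neoxy.inference.ProgenyCounts`."""
    crosses = {}
    for dam_k, group in per_dam.groupby("dam_karyomorph"):
        d_cols = [f"daughters_{k.value}" for k in _DAUGHTER_CLASSES]
        karyotyped = {
            k: int(group[f"k_daughters_{k.value}"].sum())
            for k in _DAUGHTER_CLASSES
            if f"k_daughters_{k.value}" in group
        }
        crosses[Karyomorph(dam_k)] = CrossCounts(
            n_dams=len(group),
            n_sons=int(group["n_sons"].sum()),
            n_daughters=int(group[d_cols].sum().sum()),
            karyotyped=karyotyped,
        )
    return ProgenyCounts(crosses=crosses)
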