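"""Forward-time dynamics of the karyomorph polymorphism.

Asks how a population segregating KI males and KII/KIII/KIV females can
maintain the observed frequencies (about 47% KII, 47% KIII, 6% KIV among
females).  Two modes share the same per-generation recursion built on the
cross model:

* deterministic — iterate the expectation map on female karyomorph
  frequencies exactly;
* stochastic — draw each dam's litter (Poisson) and offspring classes
  (multinomial) with an explicit seed, non-overlapping generations.

Dams mate KI sires (the only live male genotype under the XY-female
rules), mating success is equal across males, and a dam's realized
fecundity is proportional to her cross's viable-zygote fraction times an
optional per-karyomorph fecundity multiplier (KIV subfertility — none of
the observed KIV dams bred in the reproductive-success cohort — is
representable there).  Without any selection against double-X1 zygotes
the KIV fraction grows toward fixation, so the observed KIV rarity
requires ``v_x1x1 < 1`` or reduced KIV fecundity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .karyotype import Hypothesis, Karyomorph, Sex
from .meiosis import CrossParameters, DAM_KARYOMORPHS, cross

__all__ = [
    "PopulationState",
    "step_generation",
    "run_trajectory",
    "deterministic_equilibrium",
]


@dataclass(frozen=True)
class PopulationState:
    """Counts (stochastic) or frequencies (deterministic) per sex and
    karyomorph for one generation."""

    generation: int
    females: Mapping[Karyomorph, float]
    males: Mapping[Karyomorph, float]
    deterministic: bool = True
    extinct: bool = False

    def __post_init__(self) -> None:
        for pool in (self.females, self.males):
            if any(v < 0 for v in pool.values()):
                raise ValueError("negative count/frequency")

    @classmethod
    def from_female_frequencies(
        cls, freqs: Mapping[Karyomorph, float], generation: int = 0
    ) -> "PopulationState":
        total = sum(freqs.values())
        if total <= 0:
            return cls(generation, {}, {}, deterministic=True, extinct=True)
        return cls(
            generation,
            {k: v / total for k, v in freqs.items() if v > 0},
            {Karyomorph.KI: 1.0},
            deterministic=True,
        )

    def female_frequencies(self) -> dict[Karyomorph, float]:
        total = sum(self.females.values())
        if total <= 0:
            return {}
        return {k: v / total for k, v in self.females.items() if v > 0}

    @property
    def size(self) -> float:
        return sum(self.females.values()) + sum(self.males.values())


def _class_masses(
    hypothesis: Hypothesis,
    params: CrossParameters,
    fecundity: Mapping[Karyomorph, float],
) -> dict[Karyomorph, dict[tuple[Karyomorph, Sex], float]]:
    """Per dam karyomorph: viability-weighted raw class masses, scaled by
    fecundity, so that the total mass equals (relative) litter output."""
    out: dict[Karyomorph, dict[tuple[Karyomorph, Sex], float]] = {}
    for dam in DAM_KARYOMORPHS:
        dist = cross(dam, Karyomorph.KI, hypothesis, params)
        fec = float(fecundity.get(dam, 1.0))
        masses: dict[tuple[Karyomorph, Sex], float] = {}
        for _, row in dist.table.iterrows():
            mass = float(row["raw_p"]) * float(row["viability"]) * fec
            if mass <= 0:
                continue
            key = (Karyomorph(row["karyomorph"]), Sex(row["sex"]))
            masses[key] = masses.get(key, 0.0) + mass
        out[dam] = masses
    return out


def step_generation(
    state: PopulationState,
    hypothesis: Hypothesis = Hypothesis.MECH_A,
    params: CrossParameters | None = None,
    fecundity: Mapping[Karyomorph, float] | None = None,
    rng: np.random.Generator | None = None,
    offspring_per_dam: float = 8.6,
    max_population: int | None = None,
) -> PopulationState:
    """Advance one non-overlapping generation.

    Deterministic mode applies the expectation map exactly; stochastic
    mode draws Poisson litters and multinomial offspring classes from
    ``rng``.  An empty or single-sex population is returned unchanged with
    ``extinct=True`` rather than raising.
    """
    params = params or CrossParameters()
    fecundity = fecundity or {}
    if state.extinct:
        return state
    have_dams = any(v > 0 for v in state.females.values())
    have_sires = any(v > 0 for v in state.males.values())
    if not have_dams or not have_sires:
        return replace(state, extinct=True)

    masses = _class_masses(hypothesis, params, fecundity)

    if state.deterministic:
        pool: dict[tuple[Karyomorph, Sex], float] = {}
        total_f = sum(state.females.values())
        for dam, f in state.females.items():
            if f <= 0:
                continue
            if dam not in masses:
                raise ValueError(f"no cross model for dam karyomorph {dam}")
            for key, mass in masses[dam].items():
                pool[key] = pool.get(key, 0.0) + (f / total_f) * mass
        females = {k: v for (k, s), v in pool.items() if s is Sex.FEMALE}
        males = {k: v for (k, s), v in pool.items() if s is Sex.MALE}
        tot_f, tot_m = sum(females.values()), sum(males.values())
        return PopulationState(
            state.generation + 1,
            {k: v / tot_f for k, v in females.items()} if tot_f > 0 else {},
            {k: v / tot_m for k, v in males.items()} if tot_m > 0 else {},
            deterministic=True,
            extinct=(tot_f <= 0 or tot_m <= 0),
        )

    if rng is None:
        raise ValueError("stochastic mode requires an rng")
    counts: dict[tuple[Karyomorph, Sex], int] = {}
    for dam, n_dams in state.females.items():
        n_dams = int(n_dams)
        if n_dams <= 0:
            continue
        if dam not in masses:
            raise ValueError(f"no cross model for dam karyomorph {dam}")
        keys = sorted(masses[dam], key=lambda ks: (ks[0].value, ks[1].value))
        mass_vec = np.array([masses[dam][k] for k in keys])
        viable_mass = mass_vec.sum()
        if viable_mass <= 0:
            continue
        n_off = rng.poisson(n_dams * offspring_per_dam * viable_mass)
        if n_off == 0:
            continue
        draws = rng.multinomial(n_off, mass_vec / viable_mass)
        for key, c in zip(keys, draws):
            if c > 0:
                counts[key] = counts.get(key, 0) + int(c)
    if max_population is not None:
        total = sum(counts.values())
        if total > max_population:
            keys = sorted(counts, key=lambda ks: (ks[0].value, ks[1].value))
            kept = rng.multivariate_hypergeometric(
                [counts[k] for k in keys], max_population
            )
            counts = {k: int(c) for k, c in zip(keys, kept) if c > 0}
    females = {k: float(v) for (k, s), v in counts.items() if s is Sex.FEMALE}
    males = {k: float(v) for (k, s), v in counts.items() if s is Sex.MALE}
    return PopulationState(
        state.generation + 1,
        females,
        males,
        deterministic=False,
        extinct=(not females or not males),
    )


def run_trajectory(
    initial: PopulationState,
    n_generations: int,
    hypothesis: Hypothesis = Hypothesis.MECH_A,
    params: CrossParameters | None = None,
    fecundity: Mapping[Karyomorph, float] | None = None,
    seed: int | None = None,
    offspring_per_dam: float = 8.6,
    max_population: int | None = None,
) -> pd.DataFrame:
    """Iterate :func:`step_generation`; returns a long-format table with
    columns generation, sex, karyomorph, value.  A single integer seed
    fully determines a stochastic run."""
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    rng = None if initial.deterministic else np.random.default_rng(seed)
    rows = []
    state = initial
    hyp = hypothesis

    def record(s: PopulationState) -> None:
        for sex, pool in (("female", s.females), ("male", s.males)):
            for k, v in sorted(pool.items(), key=lambda kv: kv[0].value):
                rows.append(
                    {
                        "generation": s.generation,
                        "sex": sex,
                        "karyomorph": k.value,
                        "value": v,
                    }
                )

    record(state)
    for _ in range(n_generations):
        state = step_generation(
            state,
            hyp,
            params,
            fecundity,
            rng=rng,
            offspring_per_dam=offspring_per_dam,
            max_population=max_population,
        )
        if hyp.xy_female and not state.extinct:
            # no other viable male genotype is reachable under these rules
            assert set(state.males) <= {Karyomorph.KI}, state.males
        record(state)
        if state.extinct:
            break
    return pd.DataFrame(rows)


def deterministic_equilibrium(
    hypothesis: Hypothesis = Hypothesis.MECH_A,
    params: CrossParameters | None = None,
    fecundity: Mapping[Karyomorph, float] | None = None,
    initial: Mapping[Karyomorph, float] | None = None,
    tol: float = 1e-12,
    max_iter: int = 100_000,
) -> tuple[dict[Karyomorph, float], bool, int]:
    """Iterate the expectation map to a fixed point of the female
    karyomorph frequencies.

    Returns ``(frequencies, converged, n_iterations)``; non-convergence
    within ``max_iter`` is reported via the flag, never raised.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    params = params or CrossParameters()
    fecundity = fecundity or {}
    freqs = dict(
        initial
        or {Karyomorph.KII: 1 / 3, Karyomorph.KIII: 1 / 3, Karyomorph.KIV: 1 / 3}
    )
    total = sum(freqs.values())
    if total <= 0:
        return {}, True, 0
    # the class masses are fixed by the parameters; compute them once and
    # iterate the daughter map on a plain vector
    masses = _class_masses(hypothesis, params, fecundity)
    dams = sorted(masses, key=lambda k: k.value)
    daughter_mass = np.array(
        [
            [masses[d].get((k, Sex.FEMALE), 0.0) for d in dams]
            for k in dams
        ]
    )  # rows: daughter karyomorph, cols: dam karyomorph
    f = np.array([freqs.get(d, 0.0) / total for d in dams])
    for i in range(1, max_iter + 1):
        nxt = daughter_mass @ f
        s = nxt.sum()
        if s <= 0:
            return {}, True, i
        nxt = nxt / s
        delta = float(np.max(np.abs(nxt - f)))
        f = nxt
        if delta < tol:
            break
    out = {d: float(v) for d, v in zip(dams, f) if v > 0}
    return out, delta < tol, i
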