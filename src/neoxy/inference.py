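"""Multinomial likelihood for progeny counts and hypothesis comparison.

The breeding data per dam karyomorph are (i) a son count out of all sexed
offspring and (ii) karyomorph counts for a karyotyped subsample of the
daughters.  The likelihood factorizes these as independent conditional
pieces: a binomial for the sex ratio (probability from the cross model's
expected son fraction among live offspring) and a multinomial for the
karyotyped-daughter karyomorphs (probabilities from the cross model's
daughter distribution, conditional on being a karyotyped daughter).  Any
observed class with model probability zero drives the log-likelihood to
-inf — this is exactly how the standard hypothesis fails: it predicts
only KII daughters from KIII dams, yet KIII daughters are observed.

Fitting is by deterministic bounded grid refinement (log-spaced for the
sperm weights), with profile-likelihood intervals at the chi-square(1)
95% cutoff.  Hypotheses are ranked by AIC.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .karyotype import Hypothesis, Karyomorph
from .meiosis import CrossParameters, DAM_KARYOMORPHS, cross

__all__ = [
    "CrossCounts",
    "ProgenyCounts",
    "FitResult",
    "FREE_PARAMETERS",
    "cross_log_likelihood",
    "fit_parameters",
    "compare_hypotheses",
]

_DAUGHTER_CLASSES = (Karyomorph.KII, Karyomorph.KIII, Karyomorph.KIV)

#: free parameter names accepted by :func:`fit_parameters`, with bounds
#: and grid scale.  Sperm weights are searched log-spaced over [1e-3, 1e3].
FREE_PARAMETERS: dict[str, tuple[float, float, str]] = {
    "wY_KII": (1e-3, 1e3, "log"),
    "wY_KIII": (1e-3, 1e3, "log"),
    "wY_KIV": (1e-3, 1e3, "log"),
    "v_x1x1": (0.0, 1.0, "linear"),
    "s_kii": (0.0, 1.0, "linear"),
    "s_kiii": (0.0, 1.0, "linear"),
}


@dataclass(frozen=True)
class CrossCounts:
    """Observed progeny of all dams of one karyomorph (KI sires)."""

    n_dams: int
    n_sons: int
    n_daughters: int
    karyotyped: Mapping[Karyomorph, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("n_dams", "n_sons", "n_daughters"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(v < 0 for v in self.karyotyped.values()):
            raise ValueError("karyotyped counts must be >= 0")
        if sum(self.karyotyped.values()) > self.n_daughters:
            raise ValueError("karyotyped daughters exceed n_daughters")

    @property
    def n_offspring(self) -> int:
        return self.n_sons + self.n_daughters


@dataclass(frozen=True)
class ProgenyCounts:
    """Progeny counts keyed by dam karyomorph."""

    crosses: Mapping[Karyomorph, CrossCounts]

    def __post_init__(self) -> None:
        for k in self.crosses:
            if k not in DAM_KARYOMORPHS:
                raise ValueError(f"unsupported dam karyomorph {k}")

    @property
    def n_offspring(self) -> int:
        return sum(c.n_offspring for c in self.crosses.values())

    @property
    def n_sons(self) -> int:
        return sum(c.n_sons for c in self.crosses.values())


def cross_log_likelihood(
    counts: ProgenyCounts,
    hypothesis: Hypothesis,
    params: CrossParameters | None = None,
) -> float:
    """Log-likelihood of observed progeny counts under a cross model.

    Sum over dam karyomorphs of a binomial term for the son count and a
    multinomial term for the karyotyped-daughter karyomorphs.  Returns
    ``-inf`` when any observed class has model probability zero.
    """
    params = params or CrossParameters()
    total = 0.0
    for dam, obs in counts.crosses.items():
        dist = cross(dam, Karyomorph.KI, hypothesis, params)
        if obs.n_offspring > 0:
            p_male = dist.male_fraction()
            term = float(sps.binom.logpmf(obs.n_sons, obs.n_offspring, p_male))
            if not np.isfinite(term):
                return -math.inf
            total += term
        k_counts = [int(obs.karyotyped.get(k, 0)) for k in _DAUGHTER_CLASSES]
        m = sum(k_counts)
        if m > 0:
            ddist = dist.daughter_distribution()
            probs = np.array([ddist.get(k, 0.0) for k in _DAUGHTER_CLASSES])
            if any(c > 0 and p <= 0.0 for c, p in zip(k_counts, probs)):
                return -math.inf
            s = probs.sum()
            if s <= 0:
                return -math.inf
            term = float(
                sps.multinomial.logpmf(k_counts, n=m, p=probs / s)
            )
            if not np.isfinite(term):
                return -math.inf
            total += term
    return total


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of cross parameters."""

    hypothesis: Hypothesis
    estimates: dict[str, float]
    log_likelihood: float
    intervals: dict[str, tuple[float, float]]
    metadata: dict

    @property
    def params(self) -> CrossParameters:
        return CrossParameters().with_updates(**self.estimates)


def _grid(lo: float, hi: float, scale: str, n: int) -> np.ndarray:
    if scale == "log":
        return np.geomspace(lo, hi, n)
    return np.linspace(lo, hi, n)


def _objective(
    counts: ProgenyCounts,
    hypothesis: Hypothesis,
    base: CrossParameters,
    names: Sequence[str],
):
    def f(values: Sequence[float]) -> float:
        params = base.with_updates(**dict(zip(names, values)))
        return cross_log_likelihood(counts, hypothesis, params)

    return f


def _refine(
    f,
    bounds: Sequence[tuple[float, float, str]],
    n_points: int = 9,
    n_iter: int = 6,
) -> tuple[np.ndarray, float, int]:
    """Deterministic successive grid refinement over a box."""
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    scales = [b[2] for b in bounds]
    best_x = None
    best_v = -math.inf
    n_evals = 0
    for _ in range(n_iter):
        axes = [
            _grid(lo[i], hi[i], scales[i], n_points) for i in range(len(bounds))
        ]
        for point in itertools.product(*axes):
            v = f(point)
            n_evals += 1
            if v > best_v:
                best_v, best_x = v, np.array(point)
        if best_x is None:
            break
        # shrink each axis around the current optimum
        for i, scale in enumerate(scales):
            if scale == "log":
                span = (hi[i] / lo[i]) ** (1.0 / (n_points - 1))
                lo[i] = max(bounds[i][0], best_x[i] / span)
                hi[i] = min(bounds[i][1], best_x[i] * span)
            else:
                span = (hi[i] - lo[i]) / (n_points - 1)
                lo[i] = max(bounds[i][0], best_x[i] - span)
                hi[i] = min(bounds[i][1], best_x[i] + span)
    return best_x, best_v, n_evals


def fit_parameters(
    counts: ProgenyCounts,
    hypothesis: Hypothesis,
    free: Sequence[str] = ("wY_KII",),
    base: CrossParameters | None = None,
    n_points: int = 9,
    n_iter: int = 6,
    profile_points: int = 41,
) -> FitResult:
    """Maximize the cross log-likelihood over the named free parameters.

    Deterministic given the search settings.  A flat likelihood (all grid
    evaluations within 1e-9 of each other on the first pass) is reported
    in ``metadata['identifiable'] = False`` rather than raised.
    Profile-likelihood 95% intervals are computed per free parameter by
    re-optimizing the remaining ones on a coarse scan.
    """
    for name in free:
        if name not in FREE_PARAMETERS:
            raise ValueError(
                f"unknown free parameter {name!r}; "
                f"choose from {sorted(FREE_PARAMETERS)}"
            )
    base = base or CrossParameters()
    names = list(free)
    bounds = [FREE_PARAMETERS[n] for n in names]
    f = _objective(counts, hypothesis, base, names)

    # identifiability probe on the initial coarse grid
    probe = [
        f(point)
        for point in itertools.product(
            *[_grid(b[0], b[1], b[2], 5) for b in bounds]
        )
    ]
    finite = [v for v in probe if np.isfinite(v)]
    identifiable = bool(finite) and (max(finite) - min(finite) > 1e-9)

    best_x, best_v, n_evals = _refine(f, bounds, n_points, n_iter)
    if best_x is None:  # likelihood -inf everywhere (impossible observation)
        best_x = np.array([_grid(b[0], b[1], b[2], 3)[1] for b in bounds])
        best_v = f(best_x)
    estimates = dict(zip(names, (float(v) for v in best_x)))

    cutoff = best_v - sps.chi2.ppf(0.95, 1) / 2.0
    intervals: dict[str, tuple[float, float]] = {}
    for i, name in enumerate(names):
        lo_b, hi_b, scale = bounds[i]
        others = [n for j, n in enumerate(names) if j != i]
        other_bounds = [bounds[j] for j in range(len(names)) if j != i]

        def profile(value: float) -> float:
            if others:
                fixed = base.with_updates(**{name: float(value)})
                g = _objective(counts, hypothesis, fixed, others)
                _, prof_v, _ = _refine(g, other_bounds, n_points=7, n_iter=3)
                return prof_v
            return f([value])

        scan = sorted(
            set(map(float, _grid(lo_b, hi_b, scale, profile_points)))
            | {estimates[name]}
        )
        inside = [v for v in scan if profile(v) >= cutoff]
        if not inside:
            intervals[name] = (estimates[name], estimates[name])
            continue
        lo_edge, hi_edge = min(inside), max(inside)
        # sharpen each edge by bisection against the nearest excluded point
        for direction in ("low", "high"):
            if direction == "low":
                outside = [v for v in scan if v < lo_edge]
                a, b = (max(outside), lo_edge) if outside else (None, None)
            else:
                outside = [v for v in scan if v > hi_edge]
                a, b = (hi_edge, min(outside)) if outside else (None, None)
            if a is None:
                continue
            for _ in range(20):
                mid = (
                    math.sqrt(a * b)
                    if scale == "log" and a > 0
                    else 0.5 * (a + b)
                )
                if (profile(mid) >= cutoff) == (direction == "high"):
                    a = mid
                else:
                    b = mid
            if direction == "low":
                lo_edge = b
            else:
                hi_edge = a
        intervals[name] = (lo_edge, hi_edge)

    return FitResult(
        hypothesis=hypothesis,
        estimates=estimates,
        log_likelihood=float(best_v),
        intervals=intervals,
        metadata={
            "identifiable": identifiable,
            "n_evaluations": n_evals,
            "free": names,
            "optimizer": "grid_refinement",
            "n_points": n_points,
            "n_iter": n_iter,
        },
    )


def compare_hypotheses(
    counts: ProgenyCounts,
    hypotheses: Sequence[Hypothesis],
    params: Mapping[Hypothesis, CrossParameters] | None = None,
    n_free: Mapping[Hypothesis, int] | None = None,
) -> pd.DataFrame:
    """Rank hypotheses by AIC on the same progeny counts.

    ``params`` supplies per-hypothesis parameter values (defaults
    otherwise); ``n_free`` the number of fitted parameters used in the
    AIC penalty (0 for fixed defaults).  Hypotheses with -inf
    log-likelihood carry ``rejected = True`` ("rejected by impossible
    observation") and sort last.
    """
    if len(hypotheses) < 2:
        raise ValueError("need at least two hypotheses to compare")
    rows = []
    for h in hypotheses:
        p = (params or {}).get(h) or CrossParameters()
        k = int((n_free or {}).get(h, 0))
        logl = cross_log_likelihood(counts, h, p)
        aic = math.inf if not np.isfinite(logl) else 2 * k - 2 * logl
        rows.append(
            {
                "hypothesis": h.value,
                "log_likelihood": logl,
                "n_params": k,
                "aic": aic,
                "rejected": not np.isfinite(logl),
                "note": (
                    "rejected by impossible observation"
                    if not np.isfinite(logl)
                    else ""
                ),
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["rejected", "aic"], kind="stable"
    )
    return out.reset_index(drop=True)
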