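"""Discrete-generation dynamics of a CI-inducing *Wolbachia* strain and
mitochondrial haplotypes.

The model tracks four heritable cytotypes in an already singly infected host
population that a second, CI-inducing strain is invading:

====  =========================  ==========
code  Wolbachia infection        haplotype
====  =========================  ==========
A1    single (resident strain)   HT1
A2    single (resident strain)   HT2
B1    double (resident+invader)  HT1
B2    double (resident+invader)  HT2
====  =========================  ==========

CI is unidirectional: crosses of doubly infected males with singly infected
females lose a fraction ``l_CI`` of their eggs; all other crosses are fully
compatible.  Haplotypes are strictly maternally inherited.  The invading
strain is transmitted maternally with rate ``1 - mu`` and, optionally,
paternally (``tau``) or horizontally (``beta`` per generation, of which a
fraction ``alpha`` reaches the germline and becomes heritable).  Horizontal
acquisitions that do not reach the germline are *somatic*: PCR-detectable at
census but neither transmitted nor CI-active.  Somatic infections therefore
appear only in the "observed" (PCR-visible) frequencies, as an overlay
``beta * (1 - alpha) * x_Ah`` on top of the heritable double class of the
same haplotype.

Each generation applies, in order: horizontal acquisition, census (observed
overlay), random mating with CI mortality via the mating table, and
renormalisation by mean reproductive output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "CYTOTYPES",
    "ModelParams",
    "CytotypeState",
    "MatingTable",
    "Trajectory",
    "build_mating_table",
    "classic_ci_recursion",
    "step",
    "run_scenario",
    "mismatch_fraction",
    "peak_mismatch",
    "ZeroReproductionError",
]

#: Heritable cytotype labels: infection (A single, B double) x haplotype (1, 2).
CYTOTYPES = ("A1", "A2", "B1", "B2")

_UNIT_FIELDS = ("l_ci", "mu", "tau", "alpha", "beta")


class ZeroReproductionError(ValueError):
    """Raised when the population's mean reproductive output is zero."""


@dataclass(frozen=True)
class ModelParams:
    """All dynamical parameters of the invasion model.

    Parameters
    ----------
    l_ci
        CI level: fraction of eggs dying when a singly infected female mates
        a doubly infected male (0-1).
    mu
        Maternal transmission leakage of the invading strain; maternal
        transmission rate is ``1 - mu``.
    F_A, F_B
        Relative fecundities of singly / doubly infected females (> 0).
    tau
        Paternal transmission probability, applied to offspring that did not
        already inherit the invading strain maternally.
    alpha
        Probability that a horizontally acquired infection reaches the
        germline and becomes heritable.
    beta
        Per-generation horizontal acquisition probability for singly
        infected individuals.
    acquisition
        How the horizontal acquisition probability scales: ``"constant"``
        (the default; every singly infected individual acquires with
        probability ``beta`` regardless of prevalence) or ``"frequency"``
        (mass action: probability ``beta`` times the heritable
        double-infection frequency, i.e. acquisition from infected
        carriers).
    """

    l_ci: float
    mu: float = 0.0
    F_A: float = 1.0
    F_B: float = 1.0
    tau: float = 0.0
    alpha: float = 0.0
    beta: float = 0.0
    acquisition: str = "constant"

    def __post_init__(self) -> None:
        for name in _UNIT_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        for name in ("F_A", "F_B"):
            v = getattr(self, name)
            if not v > 0.0:
                raise ValueError(f"{name} must be > 0, got {v!r}")
        if self.acquisition not in ("constant", "frequency"):
            raise ValueError(f"unknown acquisition mode {self.acquisition!r}")

    def acquisition_rate(self, double_freq: float) -> float:
        """Per-generation horizontal acquisition probability of a singly
        infected individual, given the heritable double-infection frequency."""
        if self.acquisition == "constant":
            return self.beta
        return self.beta * double_freq

    # The three transmission scenarios of the quantitative analysis share
    # l_CI = 0.98, mu = 0, F_A = F_B = 1 and differ only in tau/alpha/beta.
    @classmethod
    def paternal_transmission(cls, l_ci: float = 0.98, tau: float = 0.3) -> "ModelParams":
        """Invasion with paternal leakage of the invading strain (tau = 0.3)."""
        return cls(l_ci=l_ci, tau=tau)

    @classmethod
    def heritable_horizontal(
        cls, l_ci: float = 0.98, beta: float = 0.015
    ) -> "ModelParams":
        """Horizontal acquisition that always reaches the germline
        (alpha = 1, beta = 0.015)."""
        return cls(l_ci=l_ci, alpha=1.0, beta=beta)

    @classmethod
    def somatic_horizontal(cls, l_ci: float = 0.98, beta: float = 0.3) -> "ModelParams":
        """Purely somatic horizontal acquisition (alpha = 0, beta = 0.3):
        PCR-visible but never transmitted."""
        return cls(l_ci=l_ci, alpha=0.0, beta=beta)


@dataclass(frozen=True)
class CytotypeState:
    """Frequencies of the four heritable cytotypes plus the observed
    (PCR-visible) frequencies of the double-infection classes.

    ``o_b1``/``o_b2`` add the somatic overlay ``beta*(1-alpha)*x_Ah`` to the
    heritable double class of the same haplotype; for states not produced by
    :func:`step`/:func:`run_scenario` they default to the heritable values.
    """

    x_a1: float
    x_a2: float
    x_b1: float
    x_b2: float
    o_b1: float | None = field(default=None, compare=False)
    o_b2: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        for v in (self.x_a1, self.x_a2, self.x_b1, self.x_b2):
            if not -1e-12 <= v <= 1.0 + 1e-12:
                raise ValueError(f"cytotype frequency outside [0, 1]: {v!r}")
        if abs(self.heritable_sum() - 1.0) > 1e-8:
            raise ValueError(
                f"heritable frequencies must sum to 1, got {self.heritable_sum()!r}"
            )

    # -- constructors -------------------------------------------------
    @classmethod
    def from_array(cls, x: Iterable[float]) -> "CytotypeState":
        a1, a2, b1, b2 = x
        return cls(float(a1), float(a2), float(b1), float(b2))

    @classmethod
    def founder(cls, p0: float = 0.01, founder_haplotype: str = "HT2") -> "CytotypeState":
        """A rare doubly infected founder entering a resident HT1 population.

        The default (``x_B2 = p0 = 0.01``, ``x_A1 = 1 - p0``) is an
        HT2-linked founder, the configuration behind all three named
        scenarios.
        """
        if founder_haplotype == "HT2":
            return cls(1.0 - p0, 0.0, 0.0, p0)
        if founder_haplotype == "HT1":
            return cls(1.0 - p0, 0.0, p0, 0.0)
        raise ValueError(f"unknown haplotype {founder_haplotype!r}")

    # -- accessors ----------------------------------------------------
    def as_array(self) -> np.ndarray:
        return np.array([self.x_a1, self.x_a2, self.x_b1, self.x_b2])

    def heritable_sum(self) -> float:
        return self.x_a1 + self.x_a2 + self.x_b1 + self.x_b2

    @property
    def double_freq(self) -> float:
        """Heritable double-infection frequency."""
        return self.x_b1 + self.x_b2

    @property
    def observed_b1(self) -> float:
        return self.x_b1 if self.o_b1 is None else self.o_b1

    @property
    def observed_b2(self) -> float:
        return self.x_b2 if self.o_b2 is None else self.o_b2

    @property
    def observed_double_freq(self) -> float:
        """PCR-visible double-infection frequency (somatic overlay included)."""
        return self.observed_b1 + self.observed_b2

    @property
    def ht1_freq(self) -> float:
        return self.x_a1 + self.x_b1

    def with_observed(self, params: ModelParams) -> "CytotypeState":
        """Attach the observed overlay for a census under ``params``."""
        somatic = params.acquisition_rate(self.double_freq) * (1.0 - params.alpha)
        return replace(
            self,
            o_b1=self.x_b1 + somatic * self.x_a1,
            o_b2=self.x_b2 + somatic * self.x_a2,
        )


@dataclass(frozen=True)
class MatingTable:
    """Relative reproductive output and offspring distribution per cross.

    ``rows`` maps (mother cytotype, father cytotype) to
    ``(weight, {offspring cytotype: probability})`` where weight is the
    mother's fecundity times CI survival.
    """

    rows: dict[tuple[str, str], tuple[float, dict[str, float]]]

    def __post_init__(self) -> None:
        for (m, f), (w, dist) in self.rows.items():
            if w < 0:
                raise ValueError(f"negative weight for cross {m} x {f}")
            if abs(sum(dist.values()) - 1.0) > 1e-12:
                raise ValueError(f"offspring distribution of {m} x {f} does not sum to 1")

    def weight(self, mother: str, father: str) -> float:
        return self.rows[(mother, father)][0]

    def offspring(self, mother: str, father: str) -> dict[str, float]:
        return self.rows[(mother, father)][1]


def build_mating_table(params: ModelParams) -> MatingTable:
    """Derive the mating table from the transmission rules.

    Rules: haplotype is strictly maternal; doubly infected (B) mothers
    transmit the invading strain with probability ``1 - mu``; crosses of A
    mothers with B fathers lose fraction ``l_ci`` of eggs and surviving
    offspring acquire the strain paternally with probability ``tau``;
    offspring of a B father that missed maternal transmission also gain it
    paternally with probability ``tau``; fecundity weights apply by mother.
    """
    l, mu, tau = params.l_ci, params.mu, params.tau
    rows: dict[tuple[str, str], tuple[float, dict[str, float]]] = {}
    for h, (a, b) in (("1", ("A1", "B1")), ("2", ("A2", "B2"))):
        for father in CYTOTYPES:
            father_double = father.startswith("B")
            # Singly infected mother of haplotype h.
            if father_double:
                rows[(a, father)] = (
                    params.F_A * (1.0 - l),
                    _dist({b: tau, a: 1.0 - tau}),
                )
            else:
                rows[(a, father)] = (params.F_A, {a: 1.0})
            # Doubly infected mother of haplotype h.
            p_double = (1.0 - mu) + (mu * tau if father_double else 0.0)
            rows[(b, father)] = (params.F_B, _dist({b: p_double, a: 1.0 - p_double}))
    return MatingTable(rows)


def _dist(d: dict[str, float]) -> dict[str, float]:
    return {k: v for k, v in d.items() if v > 0.0} or d


def classic_ci_recursion(p: float, l_ci: float, mu: float = 0.0, F: float = 1.0) -> float:
    """One generation of the single-strain CI invasion recursion.

    ``p`` is the infection frequency, ``F`` the fecundity of infected
    females relative to uninfected ones:

        p' = F p (1 - mu) / [F p + (1 - p)(1 - l_ci p)]

    This is the haplotype-free aggregation of :func:`step` with
    ``tau = beta = 0`` and ``F = F_B / F_A``, and serves as its oracle.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p!r}")
    denom = F * p + (1.0 - p) * (1.0 - l_ci * p)
    if denom <= 0.0:
        raise ZeroReproductionError("mean reproductive output is not positive")
    return F * p * (1.0 - mu) / denom


def step(
    state: CytotypeState,
    params: ModelParams,
    table: MatingTable | None = None,
) -> CytotypeState:
    """Advance the cytotype frequencies by one generation.

    Order of events: (1) horizontal acquisition (fraction ``beta`` of each
    single class acquires the strain, fraction ``alpha`` of acquirers joins
    the heritable double class of the same haplotype); (2) random mating of
    heritable types through the mating table; (3) renormalisation by mean
    reproductive output.  The returned state carries the observed overlay
    for its own census.
    """
    if abs(state.heritable_sum() - 1.0) > 1e-8:
        raise ValueError("input state is not normalized")
    if table is None:
        table = build_mating_table(params)

    conv = params.alpha * params.acquisition_rate(state.double_freq)
    freqs = {
        "A1": state.x_a1 * (1.0 - conv),
        "A2": state.x_a2 * (1.0 - conv),
        "B1": state.x_b1 + conv * state.x_a1,
        "B2": state.x_b2 + conv * state.x_a2,
    }

    out = dict.fromkeys(CYTOTYPES, 0.0)
    for (mother, father), (w, dist) in table.rows.items():
        contrib = freqs[mother] * freqs[father] * w
        if contrib == 0.0:
            continue
        for off, pr in dist.items():
            out[off] += contrib * pr
    total = sum(out.values())
    if total <= 0.0:
        raise ZeroReproductionError("mean reproductive output is zero")
    nxt = CytotypeState(*(out[c] / total for c in CYTOTYPES))
    return nxt.with_observed(params)


@dataclass(frozen=True)
class Trajectory:
    """Generation-indexed sequence of states under one parameter set."""

    states: tuple[CytotypeState, ...]
    params: ModelParams
    converged: bool

    def __post_init__(self) -> None:
        if len(self.states) < 1:
            raise ValueError("a trajectory holds at least one state")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def final(self) -> CytotypeState:
        return self.states[-1]

    def wcer2_frequencies(self, observed: bool = True) -> np.ndarray:
        """Per-generation frequency of the invading (double) infection."""
        if observed:
            return np.array([s.observed_double_freq for s in self.states])
        return np.array([s.double_freq for s in self.states])

    def mismatch_series(self, denominator: str = "all") -> np.ndarray:
        return np.array([mismatch_fraction(s, denominator) for s in self.states])

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for g, s in enumerate(self.states):
            rows.append(
                {
                    "generation": g,
                    "x_A1": s.x_a1,
                    "x_A2": s.x_a2,
                    "x_B1": s.x_b1,
                    "x_B2": s.x_b2,
                    "o_B1": s.observed_b1,
                    "o_B2": s.observed_b2,
                    "wCer2_freq": s.observed_double_freq,
                    "mismatch": mismatch_fraction(s, "all"),
                }
            )
        return pd.DataFrame(rows)


def run_scenario(
    initial: CytotypeState,
    params: ModelParams,
    max_gens: int = 10_000,
    tol: float = 1e-10,
) -> Trajectory:
    """Iterate :func:`step` until component-wise convergence or ``max_gens``.

    Convergence means every heritable component changed by less than
    ``tol`` between consecutive generations.
    """
    if max_gens < 1:
        raise ValueError("max_gens must be >= 1")
    table = build_mating_table(params)
    states = [initial.with_observed(params)]
    converged = False
    for _ in range(max_gens):
        nxt = step(states[-1], params, table)
        delta = np.max(np.abs(nxt.as_array() - states[-1].as_array()))
        states.append(nxt)
        if delta < tol:
            converged = True
            break
    return Trajectory(tuple(states), params, converged)


def mismatch_fraction(state: CytotypeState, denominator: str = "all") -> float:
    """Observed frequency of the mismatched class (double infection with the
    resident HT1 haplotype).

    ``denominator="all"`` divides by 1, ``"infected"`` by the observed
    double-infection frequency; NaN marks an undefined ratio (no infected
    individuals).
    """
    m = state.observed_b1
    if denominator == "all":
        return m
    if denominator == "infected":
        d = state.observed_double_freq
        return math.nan if d == 0.0 else m / d
    raise ValueError(f"unknown denominator {denominator!r}")


def peak_mismatch(traj: Trajectory, denominator: str = "all") -> tuple[int, float]:
    """Generation and value of the maximal mismatch fraction.

    Ties break to the earliest generation; NaN entries (undefined ratios)
    are ignored unless every entry is NaN.
    """
    series = traj.mismatch_series(denominator)
    if np.all(np.isnan(series)):
        return 0, math.nan
    gen = int(np.nanargmax(series))
    return gen, float(series[gen])
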