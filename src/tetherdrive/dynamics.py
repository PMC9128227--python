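"""Deterministic genotype-frequency dynamics of the drive system.

Discrete, non-overlapping generations; infinite-population expectation;
random mating; 1:1 sex ratio.  This is the expectation of the 12-day
discrete-generation cage design, and it is what defines the *introduction
threshold*: the unstable equilibrium release frequency above which a
confined toxin-antidote drive spreads and below which it declines.

Fitness follows the codominant multiplicative model: a drive homozygote has
relative fitness ``f_hom`` and a heterozygote ``sqrt(f_hom)`` (per-allele
multiplicative cost).  Disrupted *h* alleles are cost-free in heterozygotes
because the locus is haplosufficient.  The cost can act through female
fecundity, male mating success, offspring viability, or both sexes
multiplicatively -- at the cage level these are nearly interchangeable, which
is why cage data alone barely distinguish them.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genetics import (
    Diplotype,
    _dip_viable,
    all_diplotypes,
    DriveParams,
    Genotype,
    Haplotype,
    HomingAllele,
    HomingLocusRule,
    Sex,
    TareAllele,
    _parent_fertile,
    diplotype,
    drive_haplotype,
    viable_offspring,
    wild_haplotype,
)

__all__ = [
    "FitnessComponent",
    "FitnessModel",
    "PopulationState",
    "ReleaseEvent",
    "DeterministicTrajectory",
    "ThresholdResult",
    "EquilibriumResult",
    "PopulationExtinct",
    "next_generation",
    "iterate",
    "find_introduction_threshold",
    "find_equilibrium",
]

FreqMap = Dict[Diplotype, float]


class PopulationExtinct(Exception):
    """Raised when total viable, fertile reproductive output is zero."""


class FitnessComponent(enum.Enum):
    FEMALE_FECUNDITY = "female_fecundity"
    MALE_MATING = "male_mating"
    OFFSPRING_VIABILITY = "offspring_viability"
    BOTH_SEXES = "both_sexes"


@dataclass(frozen=True, slots=True)
class FitnessModel:
    """Codominant multiplicative fitness of drive alleles.

    ``f_hom`` is the fitness of a TARE-drive homozygote relative to wild-type
    1.0; heterozygotes get ``sqrt(f_hom)``.  ``f_hom_homing`` plays the same
    role for the homing element (default 1.0 = cost-free).  Costs at the two
    loci multiply.
    """

    f_hom: float = 1.0
    f_hom_homing: float = 1.0
    component: FitnessComponent = FitnessComponent.BOTH_SEXES

    def __post_init__(self) -> None:
        if self.f_hom <= 0 or self.f_hom_homing <= 0:
            raise ValueError("fitness values must be positive")

    def diplotype_fitness(self, dip: Diplotype) -> float:
        n_t = sum(h.tare is TareAllele.DRIVE for h in dip)
        n_h = sum(h.homing is HomingAllele.DRIVE for h in dip)
        w = 1.0
        if n_t:
            w *= self.f_hom ** (n_t / 2.0)
        if n_h:
            w *= self.f_hom_homing ** (n_h / 2.0)
        return w


@dataclass(frozen=True, slots=True)
class ReleaseEvent:
    """Mix ``genotype`` into the population at ``proportion`` of the
    post-release population, at the start of ``generation``."""

    generation: int
    genotype: Diplotype
    proportion: float

    def __post_init__(self) -> None:
        if not (0.0 < self.proportion < 1.0):
            raise ValueError("release proportion must be in (0, 1)")


@dataclass
class PopulationState:
    """Per-sex genotype frequencies at one generation.

    Autosomal inheritance keeps the sexes identical at birth; they are kept
    separately so that sex-specific release compositions remain expressible.
    """

    generation: int
    females: FreqMap
    males: FreqMap

    def __post_init__(self) -> None:
        for name, freq in (("females", self.females), ("males", self.males)):
            tot = sum(freq.values())
            if not math.isclose(tot, 1.0, abs_tol=1e-9):
                raise ValueError(f"{name} frequencies sum to {tot}, not 1")

    # -- constructors --------------------------------------------------------
    @classmethod
    def from_diplotype_freqs(cls, freq: FreqMap, generation: int = 0) -> "PopulationState":
        return cls(generation=generation, females=dict(freq), males=dict(freq))

    @classmethod
    def release_into_wild(
        cls,
        proportion: float,
        release: Diplotype,
        with_homing_locus: bool = False,
        generation: int = 0,
    ) -> "PopulationState":
        wild = diplotype(wild_haplotype(with_homing_locus), wild_haplotype(with_homing_locus))
        freq: FreqMap = {wild: 1.0 - proportion}
        freq[release] = freq.get(release, 0.0) + proportion
        return cls.from_diplotype_freqs(freq, generation)

    # -- summaries ------------------------------------------------------------
    def pooled(self) -> FreqMap:
        out: FreqMap = {}
        for freq in (self.females, self.males):
            for d, p in freq.items():
                out[d] = out.get(d, 0.0) + 0.5 * p
        return out

    def carrier_freq_tare(self) -> float:
        return sum(
            p
            for d, p in self.pooled().items()
            if any(h.tare is TareAllele.DRIVE for h in d)
        )

    def carrier_freq_homing(self) -> float:
        return sum(
            p
            for d, p in self.pooled().items()
            if any(h.homing is HomingAllele.DRIVE for h in d)
        )

    def allele_freq_tare_drive(self) -> float:
        return sum(
            p * sum(h.tare is TareAllele.DRIVE for h in d) / 2.0
            for d, p in self.pooled().items()
        )

    def allele_freq_homing_drive(self) -> float:
        return sum(
            p * sum(h.homing is HomingAllele.DRIVE for h in d) / 2.0
            for d, p in self.pooled().items()
        )

    def apply_release(self, release: ReleaseEvent) -> "PopulationState":
        q = release.proportion
        f = {d: p * (1 - q) for d, p in self.females.items()}
        m = {d: p * (1 - q) for d, p in self.males.items()}
        f[release.genotype] = f.get(release.genotype, 0.0) + q
        m[release.genotype] = m.get(release.genotype, 0.0) + q
        return PopulationState(self.generation, f, m)


# ---------------------------------------------------------------------------
# One-generation recursion (vectorised over the viable genotype space)


class GenotypeSpace:
    """Indexed viable genotype space with a precomputed offspring tensor.

    ``tensor[i, j, g]`` is the probability that a mother of diplotype ``i``
    and father ``j`` produce a *surviving* offspring of diplotype ``g``,
    unnormalised (its sum over ``g`` is the cross's survival weight).
    Sterile mothers have all-zero rows.  Built once per parameter set.
    """

    _cache: Dict[DriveParams, "GenotypeSpace"] = {}

    def __init__(self, params: DriveParams) -> None:
        self.params = params
        self.dips: List[Diplotype] = [
            d
            for d in all_diplotypes(with_homing_locus=params.homing_active)
            if _dip_viable(d, params)
        ]
        self.index: Dict[Diplotype, int] = {d: i for i, d in enumerate(self.dips)}
        n = len(self.dips)
        self.tensor = np.zeros((n, n, n))
        for i, mdip in enumerate(self.dips):
            if not _parent_fertile(mdip, Sex.FEMALE, params):
                continue
            for j, fdip in enumerate(self.dips):
                dist, weight = viable_offspring(mdip, fdip, params)
                for dip, p in dist:
                    self.tensor[i, j, self.index[dip]] = p * weight

    @classmethod
    def for_params(cls, params: DriveParams) -> "GenotypeSpace":
        sp = cls._cache.get(params)
        if sp is None:
            sp = cls(params)
            cls._cache[params] = sp
        return sp

    def vector(self, freq: FreqMap) -> np.ndarray:
        v = np.zeros(len(self.dips))
        for d, p in freq.items():
            try:
                v[self.index[d]] = p
            except KeyError:
                raise ValueError(f"nonviable or unknown diplotype in state: {d}")
        return v

    def fitness_vector(self, fitness: FitnessModel) -> np.ndarray:
        return np.array([fitness.diplotype_fitness(d) for d in self.dips])


def reproduce_vector(
    qf: np.ndarray,
    qm: np.ndarray,
    space: GenotypeSpace,
    fitness: FitnessModel,
) -> Tuple[np.ndarray, float]:
    """Vectorised expected-offspring step; see :func:`reproduce`."""
    comp = fitness.component
    w = space.fitness_vector(fitness)
    wm = w if comp in (FitnessComponent.FEMALE_FECUNDITY, FitnessComponent.BOTH_SEXES) else np.ones_like(w)
    wf = w if comp in (FitnessComponent.MALE_MATING, FitnessComponent.BOTH_SEXES) else np.ones_like(w)
    out = np.einsum("i,j,ijg->g", qf * wm, qm * wf, space.tensor)
    if comp is FitnessComponent.OFFSPRING_VIABILITY:
        out = out * w
    total = float(out.sum())
    if total <= 0.0:
        raise PopulationExtinct("no viable, fertile reproductive output")
    return out / total, total


def reproduce(
    state_females: FreqMap,
    state_males: FreqMap,
    params: DriveParams,
    fitness: FitnessModel,
) -> Tuple[FreqMap, float]:
    """Expected offspring diplotype frequencies and mean reproductive output.

    Parent pairs are weighted by the mating-relevant fitness components
    (fecundity weights mothers, mating success weights fathers, both-sexes
    weights each parent); sterile females contribute nothing; nonviable
    offspring are removed via the per-cross survival weight; the viability
    component multiplies each offspring genotype by its own fitness.  The
    returned scalar is the population's reproductive output relative to an
    all-wild-type population (1 minus this is the genetic load).
    """
    space = GenotypeSpace.for_params(params)
    out, total = reproduce_vector(
        space.vector(state_females), space.vector(state_males), space, fitness
    )
    freq = {d: float(p) for d, p in zip(space.dips, out) if p > 0.0}
    return freq, total


def next_generation(
    state: PopulationState, params: DriveParams, fitness: FitnessModel
) -> PopulationState:
    """Advance expected genotype frequencies by one discrete generation."""
    freq, _ = reproduce(state.females, state.males, params, fitness)
    return PopulationState(state.generation + 1, dict(freq), dict(freq))


# ---------------------------------------------------------------------------
# Multi-generation iteration


@dataclass
class DeterministicTrajectory:
    states: List[PopulationState]
    loads: List[float]  # genetic load of transition t -> t+1; len == len(states)-1
    extinct: bool = False

    def summary(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.states):
            rows.append(
                {
                    "generation": s.generation,
                    "carrier_freq_tare": s.carrier_freq_tare(),
                    "carrier_freq_homing": s.carrier_freq_homing(),
                    "allele_freq_tare_drive": s.allele_freq_tare_drive(),
                    "allele_freq_homing_drive": s.allele_freq_homing_drive(),
                    "genetic_load": self.loads[i] if i < len(self.loads) else float("nan"),
                }
            )
        return pd.DataFrame(rows)


def iterate(
    state: PopulationState,
    params: DriveParams,
    fitness: FitnessModel,
    n_gens: int,
    releases: Sequence[ReleaseEvent] = (),
) -> DeterministicTrajectory:
    """Iterate ``next_generation`` for ``n_gens`` generations.

    Returns the n_gens+1 states including the input, per-transition genetic
    loads (1 minus reproductive output relative to wild-type), and an
    ``extinct`` flag with a truncated trajectory if reproduction fails.
    """
    if n_gens < 0:
        raise ValueError("n_gens must be >= 0")
    by_gen: Dict[int, List[ReleaseEvent]] = {}
    for r in releases:
        by_gen.setdefault(r.generation, []).append(r)

    for r in by_gen.get(state.generation, []):
        state = state.apply_release(r)

    states = [state]
    loads: List[float] = []
    for _ in range(n_gens):
        try:
            freq, total = reproduce(state.females, state.males, params, fitness)
        except PopulationExtinct:
            return DeterministicTrajectory(states, loads, extinct=True)
        loads.append(1.0 - total)
        state = PopulationState(state.generation + 1, dict(freq), dict(freq))
        for r in by_gen.get(state.generation, []):
            state = state.apply_release(r)
        states.append(state)
    return DeterministicTrajectory(states, loads)


# ---------------------------------------------------------------------------
# Introduction threshold (unstable equilibrium) by bisection


@dataclass(frozen=True)
class ThresholdResult:
    """Unstable introduction-frequency equilibrium of a confined drive.

    ``threshold`` is the drive-carrier frequency at the unstable equilibrium
    -- the coordinate the cage experiments observe and report.  A release of
    drive homozygotes immediately produces heterozygote-rich generations, so
    the *release proportion* at the spread/decline boundary
    (``release_proportion``) is noticeably smaller than the carrier frequency
    the population then hovers at; both are returned.  ``bracketed`` is False
    when the dynamics were monotone (every release spreads, or none does) and
    0 or 1 is returned on both scales.
    """

    threshold: float  # carrier frequency at the unstable equilibrium
    release_proportion: float  # homozygote-release proportion at the boundary
    bracketed: bool

    def __float__(self) -> float:
        return self.threshold


def _tare_release_diplotype(params: DriveParams) -> Diplotype:
    with_hom = params.homing_active
    h = drive_haplotype(with_homing_locus=with_hom)
    return diplotype(h, h)


def _spreads(
    p: float,
    params: DriveParams,
    fitness: FitnessModel,
    horizon: int,
    release: Diplotype,
) -> bool:
    """Classify a release proportion as spreading or declining.

    Spreading: the carrier frequency reaches 0.99, or is still above its
    initial value and rising when the horizon is hit (slow logistic growth
    of a cost-free drive).  Declining: it collapses below a fifth of the
    initial value, or is falling at the horizon.
    """
    state = PopulationState.release_into_wild(
        p, release, with_homing_locus=params.homing_active
    )
    c0 = state.carrier_freq_tare()
    prev = c0
    c = c0
    rising = False
    for _ in range(horizon):
        try:
            state = next_generation(state, params, fitness)
        except PopulationExtinct:
            return False
        c = state.carrier_freq_tare()
        if c >= 0.99:
            return True
        if c < 0.2 * c0 or c < 1e-9:
            return False
        rising = c > prev
        prev = c
    return rising and c > c0


def find_introduction_threshold(
    params: DriveParams,
    fitness: FitnessModel,
    tol: float = 1e-4,
    horizon: int = 1000,
    release: Optional[Diplotype] = None,
) -> ThresholdResult:
    """Bisection for the unstable introduction-frequency equilibrium.

    The release genotype defaults to the TARE-drive homozygote.  A release
    proportion is classified as *spreading* when the carrier frequency reaches
    0.99 (or exceeds the initial frequency by 0.05 at the horizon) and as
    *declining* when it collapses below a fifth of its initial value.  Returns
    0 when every positive release spreads (cost-free drive) and 1, flagged,
    when none does.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if release is None:
        release = _tare_release_diplotype(params)

    lo, hi = tol, 1.0 - tol
    if _spreads(lo, params, fitness, horizon, release):
        return ThresholdResult(0.0, 0.0, bracketed=False)
    if not _spreads(hi, params, fitness, horizon, release):
        return ThresholdResult(1.0, 1.0, bracketed=False)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _spreads(mid, params, fitness, horizon, release):
            hi = mid
        else:
            lo = mid
    carrier = _saddle_carrier(lo, hi, params, fitness, horizon, release)
    return ThresholdResult(carrier, 0.5 * (lo + hi), bracketed=True)


def _saddle_carrier(
    lo: float,
    hi: float,
    params: DriveParams,
    fitness: FitnessModel,
    horizon: int,
    release: Diplotype,
) -> float:
    """Carrier frequency at the unstable equilibrium.

    Releases at the bisection midpoint hover near the saddle for many
    generations; the carrier frequency at the point of slowest motion along
    that trajectory is the equilibrium value.
    """
    state = PopulationState.release_into_wild(
        0.5 * (lo + hi), release, with_homing_locus=params.homing_active
    )
    c0 = state.carrier_freq_tare()
    prev = c0
    best_c = c0
    best_speed = float("inf")
    for _ in range(horizon):
        try:
            state = next_generation(state, params, fitness)
        except PopulationExtinct:
            break
        c = state.carrier_freq_tare()
        speed = abs(c - prev)
        if speed < best_speed:
            best_speed = speed
            best_c = c
        if c >= 0.99 or c < 0.2 * c0:
            break
        prev = c
    return best_c


# ---------------------------------------------------------------------------
# Long-run equilibrium of the homing element in a TARE-fixed background


@dataclass(frozen=True)
class EquilibriumResult:
    carrier_freq: float
    converged: bool
    generations: int


def find_equilibrium(
    params: DriveParams,
    fitness: FitnessModel,
    release_proportion: float,
    horizon: int = 400,
    tol: float = 1e-7,
) -> EquilibriumResult:
    """Long-run homing-drive carrier frequency in a TARE-fixed population.

    Releases TARE-homozygous individuals heterozygous for the homing element
    at ``release_proportion`` into a population fixed for the TARE drive,
    then iterates until the carrier frequency settles (|change| < tol over
    the last five generations) or the horizon is hit.
    """
    if not params.homing_active:
        raise ValueError("equilibrium analysis needs a configured homing locus")
    dd = drive_haplotype(with_homing_locus=True)
    dd_het = Haplotype(TareAllele.DRIVE, HomingAllele.DRIVE)
    background = diplotype(dd, dd)
    release = diplotype(dd, dd_het)
    freq: FreqMap = {background: 1.0 - release_proportion, release: release_proportion}
    state = PopulationState.from_diplotype_freqs(freq)

    recent: List[float] = [state.carrier_freq_homing()]
    for gen in range(1, horizon + 1):
        try:
            state = next_generation(state, params, fitness)
        except PopulationExtinct:
            return EquilibriumResult(recent[-1], converged=False, generations=gen)
        recent.append(state.carrier_freq_homing())
        if len(recent) >= 6:
            window = recent[-6:]
            if max(window) - min(window) < tol:
                return EquilibriumResult(recent[-1], converged=True, generations=gen)
    return EquilibriumResult(recent[-1], converged=False, generations=horizon)
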