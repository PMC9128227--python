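"""Finite-population cage simulator with effective-size drift.

Emulates the discrete-generation cage experiments: a large census population
(mean ~3,500 flies per generation) whose realized genotype-frequency changes
show far more variance than the census size alone would produce.  Drift is
therefore injected at an *effective* population size expressed as a fraction
of the census -- the same parameterisation the likelihood machinery estimates
-- using the average census of the two generations in a transition.

The per-transition contract (shared verbatim with the likelihood in
:mod:`tetherdrive.likelihood`):

1. expected offspring genotype frequencies from the deterministic recursion;
2. drift: ``round(ne_fraction * mean(census_t, census_t1))`` individuals are
   drawn multinomially and their empirical frequencies become the realized
   genotype frequencies;
3. observation: ``census_t1`` individuals are drawn multinomially from the
   realized frequencies and phenotyped (EGFP = at least one TARE drive
   allele, DsRed = at least one homing drive allele);
4. scheduled releases are mixed into the realized frequencies at their
   stated proportion of the post-release population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .dynamics import (
    FitnessModel,
    PopulationExtinct,
    ReleaseEvent,
    reproduce,
)
from .genetics import (
    Diplotype,
    DriveParams,
    HomingAllele,
    TareAllele,
    diplotype,
    drive_haplotype,
    wild_haplotype,
)

__all__ = [
    "CageConfig",
    "CageTrajectory",
    "PHENOTYPE_CLASSES",
    "phenotype_class",
    "simulate_cage",
    "summarize_replicates",
]

logger = logging.getLogger(__name__)

PHENOTYPE_CLASSES = ("egfp_only", "dsred_only", "both", "neither")


def phenotype_class(dip: Diplotype) -> str:
    """Fluorescence phenotype of a genotype (EGFP = TARE drive, DsRed = homing drive)."""
    egfp = any(h.tare is TareAllele.DRIVE for h in dip)
    dsred = any(h.homing is HomingAllele.DRIVE for h in dip)
    if egfp and dsred:
        return "both"
    if egfp:
        return "egfp_only"
    if dsred:
        return "dsred_only"
    return "neither"


@dataclass(frozen=True)
class CageConfig:
    """Configuration of one simulated cage.

    ``census_sizes`` is either a constant (every generation) or an explicit
    per-generation schedule of length ``n_generations + 1``.  ``ne_fraction``
    scales the census into the effective size used for drift.  ``releases``
    are mixed in at the start of their generation; a release at generation 0
    defines the starting composition on top of a wild-type background.
    """

    n_generations: int
    census_sizes: Union[int, Sequence[int]] = 3500
    ne_fraction: float = 0.036
    releases: Tuple[ReleaseEvent, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.ne_fraction <= 1.0):
            raise ValueError("ne_fraction must be in (0, 1]")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        sched = self.census_schedule()
        if any(c < 1 for c in sched):
            raise ValueError("census sizes must be >= 1")

    def census_schedule(self) -> List[int]:
        if isinstance(self.census_sizes, (int, np.integer)):
            return [int(self.census_sizes)] * (self.n_generations + 1)
        sched = [int(c) for c in self.census_sizes]
        if len(sched) != self.n_generations + 1:
            raise ValueError(
                f"census schedule has {len(sched)} entries; "
                f"need n_generations + 1 = {self.n_generations + 1}"
            )
        return sched


@dataclass
class CageTrajectory:
    """Observed phenotype counts per generation, plus the latent states.

    ``counts`` has columns generation, census, n_egfp_only, n_dsred_only,
    n_both, n_neither (phenotype counts always sum to the census).
    ``latent`` holds the realized genotype frequencies each generation --
    available to simulation studies, deliberately unused by the fitting code.
    ``suppressed`` flags a trajectory truncated by reproductive failure
    (no viable offspring or no fertile females).
    """

    counts: pd.DataFrame
    latent: List[Dict[Diplotype, float]] = field(default_factory=list)
    suppressed: bool = False

    def __len__(self) -> int:
        return len(self.counts)

    def carrier_freq(self, drive: str = "tare") -> np.ndarray:
        c = self.counts
        if drive == "tare":
            num = c["n_egfp_only"] + c["n_both"]
        elif drive == "homing":
            num = c["n_dsred_only"] + c["n_both"]
        else:
            raise ValueError("drive must be 'tare' or 'homing'")
        return (num / c["census"]).to_numpy()


def _mix_release(freq: Dict[Diplotype, float], rel: ReleaseEvent) -> Dict[Diplotype, float]:
    out = {d: p * (1.0 - rel.proportion) for d, p in freq.items()}
    out[rel.genotype] = out.get(rel.genotype, 0.0) + rel.proportion
    return out


def _observe(
    freq: Dict[Diplotype, float], census: int, rng: np.random.Generator
) -> Dict[str, int]:
    probs = {c: 0.0 for c in PHENOTYPE_CLASSES}
    for d, p in freq.items():
        probs[phenotype_class(d)] += p
    vec = np.array([probs[c] for c in PHENOTYPE_CLASSES])
    vec = vec / vec.sum()
    draw = rng.multinomial(census, vec)
    return dict(zip(PHENOTYPE_CLASSES, (int(x) for x in draw)))


def _drift(
    freq: Dict[Diplotype, float], ne: int, rng: np.random.Generator
) -> Dict[Diplotype, float]:
    dips = list(freq.keys())
    vec = np.array([freq[d] for d in dips])
    vec = vec / vec.sum()
    draw = rng.multinomial(ne, vec)
    total = draw.sum()
    return {d: k / total for d, k in zip(dips, draw) if k > 0}


def simulate_cage(
    params: DriveParams,
    fitness: FitnessModel,
    cage: CageConfig,
    keep_latent: bool = True,
) -> CageTrajectory:
    """Simulate one cage trajectory (same seed => bit-identical output)."""
    rng = np.random.default_rng(cage.seed)
    censuses = cage.census_schedule()
    by_gen: Dict[int, List[ReleaseEvent]] = {}
    for r in cage.releases:
        by_gen.setdefault(r.generation, []).append(r)

    wild = diplotype(
        wild_haplotype(params.homing_active), wild_haplotype(params.homing_active)
    )
    freq: Dict[Diplotype, float] = {wild: 1.0}
    for rel in by_gen.get(0, []):
        freq = _mix_release(freq, rel)

    rows = []
    latent: List[Dict[Diplotype, float]] = []
    suppressed = False

    obs = _observe(freq, censuses[0], rng)
    rows.append({"generation": 0, "census": censuses[0], **{f"n_{k}": v for k, v in obs.items()}})
    if keep_latent:
        latent.append(dict(freq))

    for t in range(cage.n_generations):
        try:
            expected, _ = reproduce(freq, freq, params, fitness)
        except PopulationExtinct:
            suppressed = True
            logger.info("cage seed=%s suppressed at transition %d", cage.seed, t)
            break
        ne = max(1, round(cage.ne_fraction * 0.5 * (censuses[t] + censuses[t + 1])))
        freq = _drift(expected, ne, rng)
        for rel in by_gen.get(t + 1, []):
            freq = _mix_release(freq, rel)
        obs = _observe(freq, censuses[t + 1], rng)
        rows.append(
            {
                "generation": t + 1,
                "census": censuses[t + 1],
                **{f"n_{k}": v for k, v in obs.items()},
            }
        )
        if keep_latent:
            latent.append(dict(freq))

    counts = pd.DataFrame(rows)
    return CageTrajectory(counts=counts, latent=latent, suppressed=suppressed)


def summarize_replicates(
    trajectories: Sequence[CageTrajectory], drive: str = "tare"
) -> pd.DataFrame:
    """Per-generation mean and 2.5/50/97.5% quantiles of carrier frequency.

    Ragged replicate lengths (e.g. suppressed cages) are truncated to the
    shortest trajectory; a ``truncated`` column flags when that happened.
    """
    if not trajectories:
        raise ValueError("need at least one trajectory")
    n = min(len(t) for t in trajectories)
    truncated = any(len(t) != n for t in trajectories)
    mat = np.stack([t.carrier_freq(drive)[:n] for t in trajectories])
    q = np.quantile(mat, [0.025, 0.5, 0.975], axis=0)
    return pd.DataFrame(
        {
            "generation": np.arange(n),
            "mean": mat.mean(axis=0),
            "q025": q[0],
            "median": q[1],
            "q975": q[2],
            "truncated": truncated,
        }
    )
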