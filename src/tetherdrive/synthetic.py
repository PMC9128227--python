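"""Synthetic dataset generation with known ground truth.

Real cross and cage data live in supplementary spreadsheets that a fresh
checkout does not have; these generators stand in for them.  Every dataset is
produced from a single seed, ships with a *truth record* (the exact
parameters that generated it), and round-trips losslessly through the
readers/writers in :mod:`tetherdrive.io`.

Cross data emulate vial-level scoring: each vial gets an egg count, a pupa
count thinned by the model-predicted relative survival, and phenotype counts
drawn around the predicted class probabilities with optional between-vial
overdispersion (Dirichlet-multinomial, interpolating binomial at dispersion
zero).

Cage data emulate the discrete-generation cage study: several cages released
with TARE homozygotes at different proportions (a threshold-straddling
design), optionally followed by a homing-element release once the TARE drive
has fixed.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cage import CageConfig, CageTrajectory, simulate_cage
from .crosses import CrossDesign, predict_cross, tare_het_female_x_wild
from .dynamics import FitnessComponent, FitnessModel, ReleaseEvent
from .genetics import (
    DriveParams,
    HomingAllele,
    Haplotype,
    TareAllele,
    diplotype,
    drive_haplotype,
    format_genotype,
)

__all__ = [
    "CrossSyntheticSpec",
    "CageSyntheticSpec",
    "gen_cross_dataset",
    "gen_cage_dataset",
    "default_cage_spec",
    "tethered_release_schedule",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Cross datasets


@dataclass(frozen=True)
class CrossSyntheticSpec:
    """Ground truth and sampling design of a synthetic cross dataset.

    ``dispersion`` is the between-vial overdispersion of the phenotype-class
    fractions: vial-level class probabilities are Dirichlet-distributed with
    concentration ``probs * (1 - dispersion) / dispersion``, so 0 means every
    vial draws from the exact predicted probabilities (plain multinomial) and
    values toward 1 mean heavy batch effects.
    """

    params: DriveParams
    design: Optional[CrossDesign] = None  # default: TARE/+ female x wild male
    n_vials: int = 20
    mean_eggs: float = 150.0
    dispersion: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vials < 0:
            raise ValueError("n_vials must be >= 0")
        if not (0.0 <= self.dispersion < 1.0):
            raise ValueError("dispersion must be in [0, 1)")
        if self.mean_eggs <= 0:
            raise ValueError("mean_eggs must be positive")


def gen_cross_dataset(spec: CrossSyntheticSpec) -> Tuple[pd.DataFrame, Dict]:
    """Generate a vial-level cross dataset plus its truth record.

    Returns a DataFrame in the cross CSV schema (vial_id, mother_genotype,
    father_genotype, n_egfp, n_dsred, n_both, n_neither, n_eggs, n_pupae) and
    a JSON-serializable dict of the generating parameters.  Zero vials yield
    an empty, correctly-typed frame.
    """
    rng = np.random.default_rng(spec.seed)
    design = spec.design or tare_het_female_x_wild()
    pred = predict_cross(design, spec.params)
    probs = np.array([pred.class_probs[c] for c in ("egfp_only", "dsred_only", "both", "neither")])

    rows = []
    for v in range(spec.n_vials):
        n_eggs = int(rng.poisson(spec.mean_eggs))
        n_pupae = int(rng.binomial(n_eggs, pred.relative_survival)) if n_eggs else 0
        if spec.dispersion > 0.0:
            conc = probs * (1.0 - spec.dispersion) / spec.dispersion
            # Dirichlet needs strictly positive concentrations; zero-probability
            # classes stay exactly zero.
            pos = conc > 0.0
            p = np.zeros_like(probs)
            p[pos] = rng.dirichlet(conc[pos])
        else:
            p = probs
        counts = rng.multinomial(n_pupae, p)
        rows.append(
            {
                "vial_id": v,
                "mother_genotype": format_genotype(design.mother),
                "father_genotype": format_genotype(design.father),
                "n_egfp": int(counts[0]),
                "n_dsred": int(counts[1]),
                "n_both": int(counts[2]),
                "n_neither": int(counts[3]),
                "n_eggs": n_eggs,
                "n_pupae": n_pupae,
            }
        )
    cols = [
        "vial_id",
        "mother_genotype",
        "father_genotype",
        "n_egfp",
        "n_dsred",
        "n_both",
        "n_neither",
        "n_eggs",
        "n_pupae",
    ]
    df = pd.DataFrame(rows, columns=cols)
    truth = {
        "kind": "cross",
        "seed": spec.seed,
        "n_vials": spec.n_vials,
        "mean_eggs": spec.mean_eggs,
        "dispersion": spec.dispersion,
        "params": _params_dict(spec.params),
        "mother_genotype": format_genotype(design.mother),
        "father_genotype": format_genotype(design.father),
        "predicted_class_probs": dict(pred.class_probs),
        "predicted_carrier_frac_tare": pred.carrier_frac_tare,
        "predicted_relative_survival": pred.relative_survival,
    }
    logger.info(
        "generated cross dataset: %d vials, seed %d, predicted carrier rate %.4f",
        spec.n_vials,
        spec.seed,
        pred.carrier_frac_tare,
    )
    return df, truth


# ---------------------------------------------------------------------------
# Cage datasets


@dataclass(frozen=True)
class CageSyntheticSpec:
    """Ground truth and design of a synthetic multi-cage dataset.

    ``release_proportions`` gives each cage its generation-0 TARE-homozygote
    release; ``homing_release`` optionally adds a homing-element release
    (proportion, generation) to every cage, as in the tethered cage study
    where the homing element entered at 6% or 33% after TARE fixation.
    """

    params: DriveParams
    fitness: FitnessModel
    release_proportions: Tuple[float, ...] = (0.71, 0.61, 0.25, 0.15)
    n_generations: int = 12
    census: int = 3500
    ne_fraction: float = 0.036
    homing_release: Optional[Tuple[float, int]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.release_proportions:
            raise ValueError("need at least one cage release proportion")
        for p in self.release_proportions:
            if not (0.0 < p < 1.0):
                raise ValueError("release proportions must be in (0, 1)")


def tethered_release_schedule(
    tare_proportion: float,
    homing_proportion: float,
    homing_generation: int,
) -> Tuple[ReleaseEvent, ...]:
    """Release schedule of a tethered cage: TARE homozygotes at generation 0,
    then TARE-homozygous homing heterozygotes at ``homing_generation``."""
    dd = drive_haplotype(with_homing_locus=True)
    dd_hom = Haplotype(TareAllele.DRIVE, HomingAllele.DRIVE)
    return (
        ReleaseEvent(0, diplotype(dd, dd), tare_proportion),
        ReleaseEvent(homing_generation, diplotype(dd, dd_hom), homing_proportion),
    )


def gen_cage_dataset(
    spec: CageSyntheticSpec,
) -> Tuple[List[CageTrajectory], Dict]:
    """Simulate one cage per release proportion; returns trajectories + truth.

    Cage ``i`` uses seed ``spec.seed * 1000 + i`` so replicate datasets with
    different top-level seeds never share streams.
    """
    with_hom = spec.params.homing_active
    dd = drive_haplotype(with_homing_locus=with_hom)
    release_dip = diplotype(dd, dd)
    trajectories: List[CageTrajectory] = []
    for i, prop in enumerate(spec.release_proportions):
        if spec.homing_release is not None:
            if not with_hom:
                raise ValueError(
                    "homing_release requires params with a configured homing locus"
                )
            releases = tethered_release_schedule(
                prop, spec.homing_release[0], spec.homing_release[1]
            )
        else:
            releases = (ReleaseEvent(0, release_dip, prop),)
        cfg = CageConfig(
            n_generations=spec.n_generations,
            census_sizes=spec.census,
            ne_fraction=spec.ne_fraction,
            releases=releases,
            seed=spec.seed * 1000 + i,
        )
        trajectories.append(simulate_cage(spec.params, spec.fitness, cfg))
    truth = {
        "kind": "cage",
        "seed": spec.seed,
        "release_proportions": list(spec.release_proportions),
        "n_generations": spec.n_generations,
        "census": spec.census,
        "ne_fraction": spec.ne_fraction,
        "homing_release": list(spec.homing_release) if spec.homing_release else None,
        "params": _params_dict(spec.params),
        "fitness": {
            "f_hom": spec.fitness.f_hom,
            "f_hom_homing": spec.fitness.f_hom_homing,
            "component": spec.fitness.component.value,
        },
    }
    logger.info(
        "generated cage dataset: %d cages x %d generations, seed %d",
        len(trajectories),
        spec.n_generations,
        spec.seed,
    )
    return trajectories, truth


def default_cage_spec(seed: int = 0) -> CageSyntheticSpec:
    """Experiment-scale defaults: measured cleavage rates, fitness 0.867 on both
    sexes, four cages straddling the introduction threshold, census 3,500,
    effective size 3.6% of census."""
    return CageSyntheticSpec(
        params=DriveParams.tare_only(0.888, 0.632),
        fitness=FitnessModel(f_hom=0.867, component=FitnessComponent.BOTH_SEXES),
        seed=seed,
    )


def _params_dict(params: DriveParams) -> Dict:
    d = asdict(params)
    d["homing_locus_rule"] = params.homing_locus_rule.value
    return d
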