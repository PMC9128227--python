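"""Cross predictions and cleavage-rate inference from inheritance bias.

The workhorse experimental readouts of a toxin-antidote drive are simple
crosses scored by fluorescence:

* drive-heterozygous **females** x wild-type males: maternal Cas9/gRNA
  deposition disrupts wild-type *h* alleles in the embryo, killing offspring
  that end up with two disrupted copies and inflating the drive-carrier
  fraction above the Mendelian 50%;
* drive-heterozygous **males** x wild-type females: no deposition, so
  inheritance is exactly Mendelian even though the male germline still
  produces disrupted alleles;
* heterozygote x heterozygote: disrupted alleles from both parents meet,
  adding a germline-rate signal on top of the embryo-rate signal.

The female-cross and het-x-het carrier fractions form a two-equation system
in (germline rate, embryo rate); :func:`estimate_cleavage_rates` inverts it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize

from .cage import PHENOTYPE_CLASSES, phenotype_class
from .genetics import (
    DriveParams,
    Genotype,
    Sex,
    TareAllele,
    diplotype,
    drive_haplotype,
    offspring_distribution,
    wild_haplotype,
)

__all__ = [
    "CrossDesign",
    "CrossPrediction",
    "CleavageEstimate",
    "RateEstimate",
    "predict_cross",
    "estimate_cleavage_rates",
    "rate_with_sem",
    "tare_het_female_x_wild",
    "tare_het_x_het",
    "tare_het_male_x_wild",
]


@dataclass(frozen=True)
class CrossDesign:
    """One mating design: a mother and a father genotype."""

    mother: Genotype
    father: Genotype

    def __post_init__(self) -> None:
        if self.mother.sex is not Sex.FEMALE or self.father.sex is not Sex.MALE:
            raise ValueError("CrossDesign needs a female mother and a male father")


def _tare_design(mother_het: bool, father_het: bool) -> CrossDesign:
    w = wild_haplotype()
    d = drive_haplotype()
    mdip = diplotype(d, w) if mother_het else diplotype(w, w)
    fdip = diplotype(d, w) if father_het else diplotype(w, w)
    return CrossDesign(Genotype(mdip, Sex.FEMALE), Genotype(fdip, Sex.MALE))


def tare_het_female_x_wild() -> CrossDesign:
    return _tare_design(True, False)


def tare_het_male_x_wild() -> CrossDesign:
    return _tare_design(False, True)


def tare_het_x_het() -> CrossDesign:
    return _tare_design(True, True)


@dataclass(frozen=True)
class CrossPrediction:
    """Phenotype-class probabilities among viable offspring and the
    relative egg-to-adult survival of the cross (viable zygote fraction)."""

    class_probs: Dict[str, float]
    carrier_frac_tare: float
    carrier_frac_homing: float
    relative_survival: float


def predict_cross(design: CrossDesign, params: DriveParams) -> CrossPrediction:
    """Exact phenotype-class probabilities of a cross.

    ``relative_survival`` is the fraction of zygotes surviving the viability
    rules -- the model's prediction for relative egg-to-pupa survival.  A
    sterile mother yields survival 0 and empty class probabilities.
    """
    dist = offspring_distribution(design.mother, design.father, params)
    probs = {c: 0.0 for c in PHENOTYPE_CLASSES}
    for g, p in dist.by_genotype.items():
        probs[phenotype_class(g.haplotypes)] += p
    return CrossPrediction(
        class_probs=probs,
        carrier_frac_tare=probs["egfp_only"] + probs["both"],
        carrier_frac_homing=probs["dsred_only"] + probs["both"],
        relative_survival=dist.viable_weight,
    )


# ---------------------------------------------------------------------------
# Inverting inheritance rates to cleavage rates


@dataclass(frozen=True)
class CleavageEstimate:
    c_germ: float
    c_embryo: float
    identifiable: bool
    residual: float
    message: str = ""


def _inheritance_pair(c_germ: float, c_embryo: float) -> Tuple[float, float]:
    params = DriveParams.tare_only(c_germ, c_embryo)
    inh_f = predict_cross(tare_het_female_x_wild(), params).carrier_frac_tare
    inh_hh = predict_cross(tare_het_x_het(), params).carrier_frac_tare
    return inh_f, inh_hh


def estimate_cleavage_rates(
    inh_F: float, inh_HH: float, tol: float = 1e-12
) -> CleavageEstimate:
    """Solve for (germline rate, embryo rate) from two observed carrier rates.

    ``inh_F`` is the drive-carrier fraction among viable progeny of
    drive/+ females x wild males; ``inh_HH`` the fraction from drive/+ x
    drive/+ crosses.  Model assumptions (as in the experimental analysis):
    equal germline cut rates in the two sexes, embryo cutting only in the
    progeny of females.  The solution satisfies the round-trip property
    ``predict_cross(estimate) == observed`` to ~1e-9.

    Mendelian inputs carry no cleavage signal: ``inh_F = 0.5`` forces the
    embryo rate to 0, and if additionally ``inh_HH = 0.75`` the germline
    rate is unidentifiable (flagged, NaN returned).
    """
    if not (0.0 < inh_F < 1.0 and 0.0 < inh_HH < 1.0):
        raise ValueError("inheritance rates must be in (0, 1)")

    if abs(inh_F - 0.5) < 1e-9 and abs(inh_HH - 0.75) < 1e-9:
        return CleavageEstimate(
            c_germ=float("nan"),
            c_embryo=0.0,
            identifiable=False,
            residual=0.0,
            message="Mendelian rates: embryo rate 0, germline rate unidentifiable",
        )

    def residuals(x: np.ndarray) -> np.ndarray:
        f, hh = _inheritance_pair(x[0], x[1])
        return np.array([f - inh_F, hh - inh_HH])

    best = None
    for start in ((0.8, 0.5), (0.5, 0.2), (0.2, 0.8), (0.95, 0.95), (0.05, 0.05)):
        sol = optimize.least_squares(
            residuals,
            x0=np.array(start),
            bounds=([0.0, 0.0], [1.0, 1.0]),
            xtol=3e-16,
            ftol=3e-16,
            gtol=1e-15,
        )
        cost = float(np.sqrt(2.0 * sol.cost))
        if best is None or cost < best[1]:
            best = (sol.x, cost)
        if cost < 1e-10:
            break

    x, resid = best
    ok = resid < 1e-6
    return CleavageEstimate(
        c_germ=float(x[0]),
        c_embryo=float(x[1]),
        identifiable=ok,
        residual=resid,
        message="" if ok else f"no solution in [0,1]^2; residual norm {resid:.3g}",
    )


# ---------------------------------------------------------------------------
# Pooled rates with between-vial standard errors


@dataclass(frozen=True)
class RateEstimate:
    rate: float
    sem: float  # NaN for a single vial
    n_vials: int
    n_total: int
    single_batch: bool


def rate_with_sem(
    counts: Sequence[int], totals: Sequence[int]
) -> RateEstimate:
    """Pooled rate and between-vial SEM.

    ``counts[i]`` successes out of ``totals[i]`` offspring in vial i.  The
    pooled rate is total successes over total offspring.  The SEM is the
    size-weighted standard error of the vial-level rates:

        sem = sqrt( sum_i w_i (p_i - p)^2 / ((M - 1) * sum_i w_i) )

    with w_i the vial sizes, p_i the vial rates, p the pooled rate and M the
    number of vials -- the weighted analogue of sd/sqrt(M).  Undefined
    (NaN, flagged) for a single vial.
    """
    counts = np.asarray(counts, dtype=float)
    totals = np.asarray(totals, dtype=float)
    if counts.shape != totals.shape or counts.ndim != 1 or len(counts) == 0:
        raise ValueError("counts and totals must be equal-length 1-D sequences")
    if np.any(counts < 0) or np.any(counts > totals):
        raise ValueError("counts must satisfy 0 <= count <= total per vial")
    if totals.sum() == 0:
        raise ValueError("no offspring in any vial; rate undefined")

    keep = totals > 0
    counts, totals = counts[keep], totals[keep]
    pooled = counts.sum() / totals.sum()
    m = len(totals)
    if m == 1:
        return RateEstimate(pooled, float("nan"), 1, int(totals.sum()), True)
    rates = counts / totals
    var_w = np.sum(totals * (rates - pooled) ** 2) / ((m - 1) * totals.sum())
    return RateEstimate(pooled, float(np.sqrt(var_w)), m, int(totals.sum()), False)


def carrier_rate_from_frame(
    df: pd.DataFrame, drive: str = "tare"
) -> RateEstimate:
    """Pooled carrier rate (+SEM) from a cross-observation table.

    Expects the cross CSV schema columns n_egfp, n_dsred, n_both, n_neither,
    one row per vial.
    """
    if drive == "tare":
        num = df["n_egfp"] + df["n_both"]
    elif drive == "homing":
        num = df["n_dsred"] + df["n_both"]
    else:
        raise ValueError("drive must be 'tare' or 'homing'")
    tot = df[["n_egfp", "n_dsred", "n_both", "n_neither"]].sum(axis=1)
    return rate_with_sem(num.to_numpy(), tot.to_numpy())
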