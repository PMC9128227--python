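"""Maximum-likelihood estimation of drive fitness and effective size.

Cage trajectories observe only fluorescence phenotypes, and their
generation-to-generation changes mix three things: the deterministic push of
the drive, selection against drive carriers, and genetic drift much stronger
than the census size suggests.  The likelihood treats each generation
transition as:

    expected genotype frequencies  (deterministic recursion at fitness f)
        -> multinomial drift of Ne = ne_fraction * mean(census_t, census_t1)
        -> multinomial census observation of the phenotype classes

exactly the contract the simulator in :mod:`tetherdrive.cage` uses, so that
simulating and fitting are internally consistent by construction.  Genotype
composition within a phenotype class is never observed; it is carried
forward from the model's running latent-state prediction, re-anchored to the
observed phenotype fractions each generation and initialized from the known
release genotypes.

Both parameters are estimated jointly by bounded derivative-free
maximization; 95% confidence intervals come from the profile likelihood
(chi-square with 1 df: 1.92 log-likelihood units).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln, logsumexp

from .cage import PHENOTYPE_CLASSES, CageTrajectory, phenotype_class
from .dynamics import (
    FitnessComponent,
    FitnessModel,
    GenotypeSpace,
    PopulationExtinct,
    ThresholdResult,
    find_introduction_threshold,
    reproduce,
    reproduce_vector,
)
from .genetics import (
    Diplotype,
    DriveParams,
    diplotype,
    drive_haplotype,
    wild_haplotype,
)

__all__ = [
    "LikelihoodFit",
    "ThresholdCI",
    "transition_loglik",
    "fit_fitness",
    "compare_components",
    "threshold_ci",
]

_CHI2_95_1DF = 1.92  # half the 95% chi-square quantile, 1 df
_EXACT_MAX_NE = 5000  # exact drift summation only for two-class transitions


# ---------------------------------------------------------------------------
# Single-transition likelihood


def _class_probs(freq: Dict[Diplotype, float]) -> np.ndarray:
    probs = {c: 0.0 for c in PHENOTYPE_CLASSES}
    for d, p in freq.items():
        probs[phenotype_class(d)] += p
    vec = np.array([probs[c] for c in PHENOTYPE_CLASSES])
    return vec / vec.sum()


@lru_cache(maxsize=64)
def _drift_support(ne: int) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Cached per-Ne arrays: y, log-binomial coefficient, log(y/ne), log(1-y/ne)."""
    y = np.arange(ne + 1, dtype=float)
    comb = gammaln(ne + 1.0) - gammaln(y + 1.0) - gammaln(ne - y + 1.0)
    with np.errstate(divide="ignore"):
        log_frac = np.log(y / ne)
        log_cfrac = np.log1p(-y / ne)
    return y, comb, log_frac, log_cfrac


def _compound_loglik_2class(n1: int, n_tot: int, pi: float, ne: int) -> float:
    """Exact log P(n1 successes of n_tot | drift of ne then observation)."""
    y, comb, log_frac, log_cfrac = _drift_support(ne)
    with np.errstate(divide="ignore", invalid="ignore"):
        drift = comb + y * math.log(pi) + (ne - y) * math.log1p(-pi)
        obs = n1 * log_frac + (n_tot - n1) * log_cfrac
    # 0 * log(0) at the support edges is a valid zero contribution
    if n1 == 0:
        obs[0] = 0.0
    if n1 == n_tot:
        obs[-1] = 0.0
    obs += (
        gammaln(n_tot + 1.0) - gammaln(n1 + 1.0) - gammaln(n_tot - n1 + 1.0)
    )
    terms = drift + obs
    m = np.max(terms)
    if not np.isfinite(m):
        terms = terms[np.isfinite(terms)]
        if terms.size == 0:
            return -np.inf
        m = np.max(terms)
    return float(m + math.log(np.sum(np.exp(terms - m))))


def _compound_loglik_normal(
    counts: np.ndarray, n_tot: int, pi: np.ndarray, ne: float
) -> float:
    """Multivariate-normal approximation to the drift+observation compound.

    Phenotype fractions f = counts / n_tot have mean pi and covariance
    (diag(pi) - pi pi^T) * (1/ne + (1 - 1/ne)/n_tot); the density of the
    count vector is the density of f divided by n_tot^(K-1).
    """
    k = len(pi)
    if k == 1:
        return 0.0
    scale = 1.0 / ne + (1.0 - 1.0 / ne) / n_tot
    cov = (np.diag(pi) - np.outer(pi, pi))[: k - 1, : k - 1] * scale
    cov = cov + np.eye(k - 1) * 1e-14
    f = counts[: k - 1] / n_tot
    dev = f - pi[: k - 1]
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        return -np.inf
    z = np.linalg.solve(chol, dev)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    ll = -0.5 * (z @ z + logdet + (k - 1) * math.log(2.0 * math.pi))
    return float(ll) - (k - 1) * math.log(n_tot)


def _phenotype_loglik(
    counts: np.ndarray, pi: np.ndarray, ne: float
) -> float:
    """Compound drift+observation log-likelihood of one phenotype count vector.

    Non-integer effective sizes are handled by linear interpolation between
    the two neighbouring integers so the likelihood is continuous in
    ``ne_fraction``.
    """
    n_tot = int(counts.sum())
    active = pi > 1e-15
    if np.any(counts[~active] > 0):
        return -np.inf  # observed a class the model says is impossible
    counts = counts[active]
    pi_a = pi[active] / pi[active].sum()
    k = len(pi_a)
    if k == 1:
        return 0.0

    def at_ne(ne_int: int) -> float:
        ne_int = max(1, ne_int)
        if k == 2 and ne_int <= _EXACT_MAX_NE:
            return _compound_loglik_2class(int(counts[0]), n_tot, pi_a[0], ne_int)
        return _compound_loglik_normal(counts, n_tot, pi_a, float(ne_int))

    lo = math.floor(ne)
    hi = math.ceil(ne)
    if lo == hi:
        return at_ne(lo)
    w = ne - lo
    return (1.0 - w) * at_ne(lo) + w * at_ne(hi)


def _anchor_latent(
    pred: Dict[Diplotype, float], obs_counts: np.ndarray
) -> Optional[Dict[Diplotype, float]]:
    """Re-anchor the latent genotype state to observed phenotype fractions.

    Within each phenotype class the genotype composition is taken from the
    model prediction; the class totals are replaced by the observed ones.
    Returns None when a class was observed that the prediction rules out.
    """
    total = obs_counts.sum()
    obs_frac = {c: obs_counts[i] / total for i, c in enumerate(PHENOTYPE_CLASSES)}
    pi = {c: 0.0 for c in PHENOTYPE_CLASSES}
    for d, p in pred.items():
        pi[phenotype_class(d)] += p
    out: Dict[Diplotype, float] = {}
    for d, p in pred.items():
        c = phenotype_class(d)
        if pi[c] <= 0.0:
            continue
        out[d] = p * obs_frac[c] / pi[c]
    for c in PHENOTYPE_CLASSES:
        if obs_frac[c] > 0.0 and pi[c] <= 1e-15:
            return None
    norm = sum(out.values())
    if norm <= 0.0:
        return None
    return {d: p / norm for d, p in out.items()}


def transition_loglik(
    counts_t: Dict[str, int],
    counts_t1: Dict[str, int],
    census_t: int,
    census_t1: int,
    params: DriveParams,
    fitness: FitnessModel,
    ne_fraction: float,
    latent: Optional[Dict[Diplotype, float]] = None,
    class_genotypes: Optional[Dict[str, Diplotype]] = None,
) -> float:
    """Log-likelihood of one generation transition.

    ``counts_t``/``counts_t1`` map phenotype classes to counts summing to the
    censuses.  The latent genotype composition at t is either supplied
    (``latent``, already scaled to the observed class fractions) or
    reconstructed from ``class_genotypes`` (class -> diplotype, e.g. the
    release genotypes at generation zero).  Impossible observations (a class
    the model assigns zero probability) yield -inf.
    """
    vec_t = np.array([counts_t.get(c, 0) for c in PHENOTYPE_CLASSES], dtype=float)
    vec_t1 = np.array([counts_t1.get(c, 0) for c in PHENOTYPE_CLASSES], dtype=float)
    if vec_t.sum() != census_t or vec_t1.sum() != census_t1:
        raise ValueError("phenotype counts must sum to the census")
    if latent is None:
        latent = _latent_from_classes(vec_t, class_genotypes, params)
    try:
        pred, _ = reproduce(latent, latent, params, fitness)
    except PopulationExtinct:
        return -np.inf
    pi = _class_probs(pred)
    ne = ne_fraction * 0.5 * (census_t + census_t1)
    return _phenotype_loglik(vec_t1, pi, ne)


def _default_class_genotypes(params: DriveParams) -> Dict[str, Diplotype]:
    with_hom = params.homing_active
    wild = diplotype(wild_haplotype(with_hom), wild_haplotype(with_hom))
    dd = diplotype(
        drive_haplotype(with_homing_locus=with_hom),
        drive_haplotype(with_homing_locus=with_hom),
    )
    return {"neither": wild, "egfp_only": dd}


def _latent_from_classes(
    vec: np.ndarray,
    class_genotypes: Optional[Dict[str, Diplotype]],
    params: DriveParams,
) -> Dict[Diplotype, float]:
    mapping = class_genotypes or _default_class_genotypes(params)
    total = vec.sum()
    out: Dict[Diplotype, float] = {}
    for i, c in enumerate(PHENOTYPE_CLASSES):
        if vec[i] == 0:
            continue
        if c not in mapping:
            raise ValueError(
                f"observed phenotype class {c!r} with no release genotype to seed "
                "the latent state"
            )
        d = mapping[c]
        out[d] = out.get(d, 0.0) + vec[i] / total
    return out


# ---------------------------------------------------------------------------
# Multi-cage likelihood


def _cage_matrix(traj: CageTrajectory) -> Tuple[np.ndarray, np.ndarray]:
    cols = [f"n_{c}" for c in PHENOTYPE_CLASSES]
    return traj.counts[cols].to_numpy(dtype=float), traj.counts["census"].to_numpy()


def _class_matrix(space: GenotypeSpace) -> np.ndarray:
    """(4, n) indicator matrix mapping genotype index to phenotype class."""
    mat = np.zeros((len(PHENOTYPE_CLASSES), len(space.dips)))
    for g, d in enumerate(space.dips):
        mat[PHENOTYPE_CLASSES.index(phenotype_class(d)), g] = 1.0
    return mat


def _cages_loglik(
    cages: Sequence[Tuple[np.ndarray, np.ndarray]],
    params: DriveParams,
    fitness: FitnessModel,
    ne_fraction: float,
    discard_first: int,
    class_genotypes: Optional[Dict[str, Diplotype]],
    per_transition: Optional[List[Tuple[int, int, float]]] = None,
) -> float:
    space = GenotypeSpace.for_params(params)
    cmat = _class_matrix(space)
    total = 0.0
    for ci, (mat, census) in enumerate(cages):
        q = space.vector(_latent_from_classes(mat[0], class_genotypes, params))
        for t in range(len(census) - 1):
            try:
                pred, _ = reproduce_vector(q, q, space, fitness)
            except PopulationExtinct:
                return -np.inf
            pred = pred / pred.sum()
            pi = cmat @ pred
            if t >= discard_first:
                ne = ne_fraction * 0.5 * (census[t] + census[t + 1])
                ll = _phenotype_loglik(mat[t + 1], pi, ne)
                if per_transition is not None:
                    per_transition.append((ci, t, ll))
                if not np.isfinite(ll):
                    return -np.inf
                total += ll
            # re-anchor latent genotype state to observed class fractions
            obs_frac = mat[t + 1] / mat[t + 1].sum()
            if np.any((obs_frac > 0.0) & (pi <= 1e-15)):
                return -np.inf
            with np.errstate(divide="ignore", invalid="ignore"):
                scale = np.where(pi > 0.0, obs_frac / pi, 0.0)
            q = pred * (cmat.T @ scale)
            norm = q.sum()
            if norm <= 0.0:
                return -np.inf
            q = q / norm
    return total


@dataclass
class LikelihoodFit:
    """Joint ML estimate of drive fitness and effective-size fraction."""

    f_hom: float
    component: FitnessComponent
    ne_fraction: float
    loglik: float
    ci_f_hom: Tuple[float, float]
    ci_ne_fraction: Tuple[float, float]
    per_transition: pd.DataFrame
    transitions_discarded: int
    converged: bool
    message: str = ""


_F_BOUNDS = (0.25, 1.6)
_LOG_NF_BOUNDS = (math.log(2e-4), 0.0)


def fit_fitness(
    trajectories: Sequence[CageTrajectory],
    params: DriveParams,
    component: FitnessComponent = FitnessComponent.BOTH_SEXES,
    discard_first: int = 2,
    class_genotypes: Optional[Dict[str, Diplotype]] = None,
    profile_ci: bool = True,
) -> LikelihoodFit:
    """Jointly maximize the cage likelihood over (f_hom, ne_fraction).

    A single estimate per parameter is produced from all cages combined.
    The first ``discard_first`` transitions of each cage are excluded from
    the likelihood (parental/inbreeding effects in fresh releases) but still
    propagate the latent genotype state.  95% CIs are profile-likelihood
    intervals (1.92 log-units).
    """
    if not trajectories:
        raise ValueError("need at least one trajectory")
    cages = [_cage_matrix(t) for t in trajectories]
    for mat, census in cages:
        if len(census) - 1 < discard_first + 1:
            raise ValueError(
                "every cage needs at least discard_first + 1 transitions"
            )

    def negll(x: np.ndarray) -> float:
        f, lognf = x
        if not (_F_BOUNDS[0] <= f <= _F_BOUNDS[1]) or not (
            _LOG_NF_BOUNDS[0] <= lognf <= _LOG_NF_BOUNDS[1]
        ):
            return 1e12
        fit = FitnessModel(f_hom=f, component=component)
        ll = _cages_loglik(
            cages, params, fit, math.exp(lognf), discard_first, class_genotypes
        )
        return -ll if np.isfinite(ll) else 1e12

    best = None
    for start in ((0.9, math.log(0.03)), (0.7, math.log(0.1)), (1.05, math.log(0.01))):
        res = optimize.minimize(
            negll,
            x0=np.array(start),
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 400},
        )
        if best is None or res.fun < best.fun:
            best = res

    f_hat, lognf_hat = best.x
    ll_max = -best.fun
    nf_hat = math.exp(lognf_hat)
    flat = not np.isfinite(ll_max) or ll_max <= -1e11

    # profile confidence intervals -----------------------------------------
    def prof_f(f: float) -> float:
        r = optimize.minimize_scalar(
            lambda lognf: negll(np.array([f, lognf])),
            bounds=_LOG_NF_BOUNDS,
            method="bounded",
            options={"xatol": 1e-3},
        )
        return -r.fun

    def prof_nf(lognf: float) -> float:
        r = optimize.minimize_scalar(
            lambda f: negll(np.array([f, lognf])),
            bounds=_F_BOUNDS,
            method="bounded",
            options={"xatol": 1e-4},
        )
        return -r.fun

    if profile_ci and not flat:
        ci_f = _profile_interval(prof_f, f_hat, ll_max, _F_BOUNDS, step=0.02)
        ci_nf_log = _profile_interval(
            prof_nf, lognf_hat, ll_max, _LOG_NF_BOUNDS, step=0.1
        )
        ci_nf = (math.exp(ci_nf_log[0]), math.exp(ci_nf_log[1]))
    else:
        ci_f = (float("nan"), float("nan"))
        ci_nf = (float("nan"), float("nan"))

    rows: List[Tuple[int, int, float]] = []
    fit_model = FitnessModel(f_hom=f_hat, component=component)
    _cages_loglik(
        cages, params, fit_model, nf_hat, discard_first, class_genotypes, rows
    )
    per_tr = pd.DataFrame(rows, columns=["cage", "transition", "loglik"])

    return LikelihoodFit(
        f_hom=float(f_hat),
        component=component,
        ne_fraction=float(nf_hat),
        loglik=float(ll_max),
        ci_f_hom=ci_f,
        ci_ne_fraction=ci_nf,
        per_transition=per_tr,
        transitions_discarded=discard_first * len(cages),
        converged=bool(best.success and not flat),
        message="" if best.success else best.message,
    )


def _profile_interval(
    prof: Callable[[float], float],
    x_hat: float,
    ll_max: float,
    bounds: Tuple[float, float],
    step: float,
) -> Tuple[float, float]:
    """Walk outward from the optimum, then bisect the 1.92-unit crossing."""
    target = ll_max - _CHI2_95_1DF

    def crossing(direction: int) -> float:
        x = x_hat
        prev = x
        for _ in range(200):
            x_next = x + direction * step
            if x_next <= bounds[0]:
                return bounds[0] if prof(bounds[0]) < target else bounds[0]
            if x_next >= bounds[1]:
                return bounds[1] if prof(bounds[1]) < target else bounds[1]
            if prof(x_next) < target:
                try:
                    return float(
                        optimize.brentq(
                            lambda z: prof(z) - target, min(prev, x_next), max(prev, x_next), xtol=1e-4
                        )
                    )
                except ValueError:
                    return x_next
            prev = x
            x = x_next
        return x

    return (crossing(-1), crossing(+1))


# ---------------------------------------------------------------------------
# Component comparison and threshold propagation


def compare_components(
    trajectories: Sequence[CageTrajectory],
    params: DriveParams,
    discard_first: int = 2,
    components: Sequence[FitnessComponent] = tuple(FitnessComponent),
    profile_ci: bool = False,
    class_genotypes: Optional[Dict[str, Diplotype]] = None,
) -> pd.DataFrame:
    """Fit every fitness component and tabulate fits with delta log-likelihood."""
    fits = {
        c: fit_fitness(
            trajectories,
            params,
            component=c,
            discard_first=discard_first,
            profile_ci=profile_ci,
            class_genotypes=class_genotypes,
        )
        for c in components
    }
    best = max(f.loglik for f in fits.values())
    rows = [
        {
            "component": c.value,
            "f_hom": f.f_hom,
            "ne_fraction": f.ne_fraction,
            "loglik": f.loglik,
            "delta_loglik": best - f.loglik,
        }
        for c, f in fits.items()
    ]
    df = pd.DataFrame(rows).sort_values("delta_loglik").reset_index(drop=True)
    df.attrs["fits"] = fits
    return df


@dataclass(frozen=True)
class ThresholdCI:
    lower: float
    point: float
    upper: float


def threshold_ci(
    fit: LikelihoodFit,
    params: DriveParams,
    tol: float = 1e-4,
    horizon: int = 1000,
) -> ThresholdCI:
    """Introduction-threshold point estimate and CI from a fitness fit.

    The threshold is monotone decreasing in fitness, so the upper fitness
    bound maps to the lower threshold bound and vice versa.  Thresholds are
    drive-carrier frequencies at the unstable equilibrium.
    """

    def thr(f: float) -> float:
        if not np.isfinite(f):
            return float("nan")
        fm = FitnessModel(f_hom=f, component=fit.component)
        return find_introduction_threshold(params, fm, tol=tol, horizon=horizon).threshold

    return ThresholdCI(
        lower=thr(fit.ci_f_hom[1]),
        point=thr(fit.f_hom),
        upper=thr(fit.ci_f_hom[0]),
    )
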