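"""Independent brute-force enumeration oracle for offspring distributions.

Deliberately written as a flat enumeration over every per-allele branch
(recombination choice, germline cut fates, embryo cut fates) rather than
reusing the package's factored gamete/embryo machinery, so that agreement
between the two is informative.
"""

from itertools import product
from typing import Dict, Tuple

from tetherdrive.genetics import (
    Diplotype,
    DriveParams,
    Haplotype,
    HomingAllele,
    HomingLocusRule,
    TareAllele,
    diplotype,
)

W, D, R = TareAllele.WILD, TareAllele.DRIVE, TareAllele.DISRUPTED
HW, HD, HR, HA = (
    HomingAllele.WILD,
    HomingAllele.DRIVE,
    HomingAllele.NONFUNCTIONAL_R,
    HomingAllele.ABSENT,
)


def _gametes(dip: Diplotype, female: bool, params: DriveParams) -> Dict[Haplotype, float]:
    h1, h2 = dip
    r = params.recomb_female if female else params.recomb_male
    raw = [
        ((h1.tare, h1.homing), (1 - r) / 2),
        ((h2.tare, h2.homing), (1 - r) / 2),
        ((h1.tare, h2.homing), r / 2),
        ((h2.tare, h1.homing), r / 2),
    ]
    has_cas9 = D in (h1.tare, h2.tare)
    has_homing = HD in (h1.homing, h2.homing)
    out: Dict[Haplotype, float] = {}
    for (t, m), p in raw:
        if p == 0:
            continue
        # branch over germline fates of this gamete's alleles
        t_branches = [(t, 1.0)]
        if t is W and has_cas9 and params.c_germ_tare > 0:
            t_branches = [(R, params.c_germ_tare), (W, 1 - params.c_germ_tare)]
        m_branches = [(m, 1.0)]
        if (
            m is HW
            and has_cas9
            and has_homing
            and params.homing_active
            and params.homing_germ_cut > 0
        ):
            cut, conv = params.homing_germ_cut, params.homing_conversion_frac
            m_branches = [
                (HD, cut * conv),
                (HR, cut * (1 - conv)),
                (HW, 1 - cut),
            ]
        for (tf, pt), (mf, pm) in product(t_branches, m_branches):
            q = p * pt * pm
            if q > 0:
                hap = Haplotype(tf, mf)
                out[hap] = out.get(hap, 0.0) + q
    return out


def _embryo_branches(hap: Haplotype, t_cut: float, m_cut: float):
    t_branches = [(hap.tare, 1.0)]
    if hap.tare is W and t_cut > 0:
        t_branches = [(R, t_cut), (W, 1 - t_cut)]
    m_branches = [(hap.homing, 1.0)]
    if hap.homing is HW and m_cut > 0:
        m_branches = [(HR, m_cut), (HW, 1 - m_cut)]
    for (t, pt), (m, pm) in product(t_branches, m_branches):
        if pt * pm > 0:
            yield Haplotype(t, m), pt * pm


def _viable(dip: Diplotype, params: DriveParams) -> bool:
    if dip[0].tare is R and dip[1].tare is R:
        return False
    if params.homing_locus_rule is HomingLocusRule.HAPLOLETHAL_RESCUE and HR in (
        dip[0].homing,
        dip[1].homing,
    ):
        return False
    return True


def oracle_offspring(
    mother: Diplotype, father: Diplotype, params: DriveParams
) -> Tuple[Dict[Diplotype, float], float]:
    """Viable-offspring distribution (probabilities summing to the survival
    weight) of one mother x father cross, by exhaustive enumeration."""
    mg = _gametes(mother, True, params)
    fg = _gametes(father, False, params)
    mother_cas9 = D in (mother[0].tare, mother[1].tare)
    mother_homing = HD in (mother[0].homing, mother[1].homing)
    t_cut = params.c_embryo_tare if mother_cas9 else 0.0
    m_cut = (
        params.c_embryo_homing
        if (mother_cas9 and mother_homing and params.homing_active)
        else 0.0
    )
    out: Dict[Diplotype, float] = {}
    weight = 0.0
    for (gm, pm), (gf, pf) in product(mg.items(), fg.items()):
        for (am, qa), (af, qb) in product(
            _embryo_branches(gm, t_cut, m_cut), _embryo_branches(gf, t_cut, m_cut)
        ):
            p = pm * pf * qa * qb
            dip = diplotype(am, af)
            if _viable(dip, params):
                out[dip] = out.get(dip, 0.0) + p
                weight += p
    return out, weight
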