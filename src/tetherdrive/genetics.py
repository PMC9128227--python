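"""Two-locus genetics of a tethered CRISPR gene-drive system.

The tethered architecture couples two elements in *Drosophila melanogaster*:

* a confined **TARE** (Toxin-Antidote Recessive Embryo) element inserted in an
  essential but haplosufficient gene (*hairy*).  The element carries Cas9, its
  gRNAs and a recoded rescue copy of the target.  Cas9 disrupts wild-type
  copies of the target in the germline of carriers and -- via maternally
  deposited Cas9/gRNA -- in the early embryos of carrier mothers.  Individuals
  inheriting two disrupted (unrescued) copies die, which raises the relative
  frequency of the drive among survivors.

* a **split homing** element at a second locus that lacks its own Cas9 and is
  therefore only active in individuals that also carry the TARE element.  Two
  variants are supported: a modification drive in a haplolethal gene
  (*RpL35A*; any unrescued disrupted copy is lethal) and a suppression drive
  in a haplosufficient female-fertility gene (*yellow-g*; females with no
  functional copy are sterile).

This module provides the allele/haplotype/genotype value types, the drive
parameterisation, and exact finite distributions for gamete formation, embryo
modification by maternal deposition, and viable offspring of a cross.
Functional resistance alleles (cut alleles repaired in-frame) are not
representable: with multiplexed gRNAs their formation is rare enough to be
negligible on experimental timescales.
"""

from __future__ import annotations

import enum
import functools
import itertools
import re
from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Tuple

__all__ = [
    "TareAllele",
    "HomingAllele",
    "Sex",
    "HomingLocusRule",
    "Haplotype",
    "Genotype",
    "Diplotype",
    "DriveParams",
    "OffspringDistribution",
    "diplotype",
    "wild_haplotype",
    "drive_haplotype",
    "gamete_distribution",
    "apply_embryo_cleavage",
    "is_viable",
    "is_fertile_female",
    "offspring_distribution",
    "viable_offspring",
    "parse_genotype",
    "format_genotype",
    "parse_diplotype",
    "format_diplotype",
    "all_diplotypes",
]


class TareAllele(enum.Enum):
    """Allele state at the toxin-antidote locus (*h*)."""

    WILD = "W"
    DRIVE = "D"  # Cas9 + gRNAs + recoded rescue
    DISRUPTED = "R"  # nonfunctional target copy; recessive lethal


class HomingAllele(enum.Enum):
    """Allele state at the homing locus (*RpL35A* or *yellow-g*)."""

    WILD = "W"
    DRIVE = "D"
    NONFUNCTIONAL_R = "R"  # out-of-frame repair product
    ABSENT = "-"  # locus not configured (single-locus TARE model)


class Sex(enum.Enum):
    FEMALE = "F"
    MALE = "M"


class HomingLocusRule(enum.Enum):
    """What the homing locus does to its carriers.

    ``NONE``: no homing locus in the model (all homing activity ignored).
    ``HAPLOLETHAL_RESCUE``: target is haplolethal; the drive allele rescues,
    a nonfunctional repair product kills its carrier.
    ``FEMALE_FERTILITY``: target is a haplosufficient female-fertility gene;
    females with no wild-type copy are sterile (drive provides no rescue).
    """

    NONE = "none"
    HAPLOLETHAL_RESCUE = "haplolethal_rescue"
    FEMALE_FERTILITY = "female_fertility"


@dataclass(frozen=True, slots=True)
class Haplotype:
    """Phased pair of allele states on one chromosome copy."""

    tare: TareAllele
    homing: HomingAllele = HomingAllele.ABSENT

    @property
    def sort_key(self) -> Tuple[str, str]:
        return (self.tare.value, self.homing.value)

    def __str__(self) -> str:
        return f"{self.tare.value}{self.homing.value}"


#: Unordered pair of haplotypes in canonical order (sex left unspecified).
Diplotype = Tuple[Haplotype, Haplotype]


def diplotype(h1: Haplotype, h2: Haplotype) -> Diplotype:
    """Canonically ordered haplotype pair; rejects mixed ABSENT configurations."""
    absent1 = h1.homing is HomingAllele.ABSENT
    absent2 = h2.homing is HomingAllele.ABSENT
    if absent1 != absent2:
        raise ValueError(
            "malformed genotype: ABSENT homing allele paired with a configured one"
        )
    return (h1, h2) if h1.sort_key <= h2.sort_key else (h2, h1)


def wild_haplotype(with_homing_locus: bool = False) -> Haplotype:
    hom = HomingAllele.WILD if with_homing_locus else HomingAllele.ABSENT
    return Haplotype(TareAllele.WILD, hom)


def drive_haplotype(
    with_homing_locus: bool = False, homing: HomingAllele | None = None
) -> Haplotype:
    """TARE-drive haplotype; homing allele defaults to wild-type if the locus exists."""
    if homing is None:
        homing = HomingAllele.WILD if with_homing_locus else HomingAllele.ABSENT
    return Haplotype(TareAllele.DRIVE, homing)


@dataclass(frozen=True, slots=True)
class Genotype:
    """Unordered, phased two-locus genotype plus sex."""

    haplotypes: Diplotype
    sex: Sex

    def __post_init__(self) -> None:
        object.__setattr__(self, "haplotypes", diplotype(*self.haplotypes))

    # -- allele accessors ---------------------------------------------------
    @property
    def tare_alleles(self) -> Tuple[TareAllele, TareAllele]:
        return (self.haplotypes[0].tare, self.haplotypes[1].tare)

    @property
    def homing_alleles(self) -> Tuple[HomingAllele, HomingAllele]:
        return (self.haplotypes[0].homing, self.haplotypes[1].homing)

    @property
    def has_tare_drive(self) -> bool:
        return TareAllele.DRIVE in self.tare_alleles

    @property
    def has_homing_drive(self) -> bool:
        return HomingAllele.DRIVE in self.homing_alleles

    @property
    def n_tare_drive(self) -> int:
        return sum(a is TareAllele.DRIVE for a in self.tare_alleles)

    @property
    def n_homing_drive(self) -> int:
        return sum(a is HomingAllele.DRIVE for a in self.homing_alleles)

    def __str__(self) -> str:
        return format_genotype(self)


# ---------------------------------------------------------------------------
# Drive parameters


@dataclass(frozen=True, slots=True)
class DriveParams:
    """Cut/conversion probabilities and locus rules of the drive system.

    All probabilities are per wild-type target allele and unitless in [0, 1].

    c_germ_tare
        Germline disruption probability of a wild-type *h* allele in a
        TARE-carrier parent (either sex).
    c_embryo_tare
        Embryo disruption probability of a wild-type *h* allele given a
        TARE-carrier mother (maternal Cas9/gRNA deposition); applies to every
        wild-type copy present after fertilisation.
    homing_germ_cut
        Total germline cut probability of a wild-type homing-locus allele.
        Requires Cas9, i.e. the parent must carry both the TARE drive and the
        homing drive (split-drive conditionality).
    homing_conversion_frac
        Fraction of germline cuts resolved by homology-directed repair into a
        drive copy; the remainder become nonfunctional repair products.
    c_embryo_homing
        Embryo cut probability of a wild-type homing allele given a mother
        carrying both elements; embryo cuts never convert (no homologous
        template at that stage), they always yield nonfunctional alleles.
    recomb_female / recomb_male
        Recombination probability between the two loci per meiosis.  Male
        *D. melanogaster* lack meiotic crossovers, hence recomb_male = 0.
    homing_locus_rule
        Viability/fertility rule of the homing locus (see HomingLocusRule).
    """

    c_germ_tare: float = 0.0
    c_embryo_tare: float = 0.0
    homing_germ_cut: float = 0.0
    homing_conversion_frac: float = 0.0
    c_embryo_homing: float = 0.0
    recomb_female: float = 0.5
    recomb_male: float = 0.0
    homing_locus_rule: HomingLocusRule = HomingLocusRule.NONE

    def __post_init__(self) -> None:
        for name in (
            "c_germ_tare",
            "c_embryo_tare",
            "homing_germ_cut",
            "homing_conversion_frac",
            "c_embryo_homing",
            "recomb_female",
            "recomb_male",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"DriveParams.{name} = {v!r} outside [0, 1]")

    @classmethod
    def tare_only(
        cls, c_germ_tare: float, c_embryo_tare: float, **kwargs
    ) -> "DriveParams":
        """Single-locus TARE configuration (no homing element)."""
        return cls(
            c_germ_tare=c_germ_tare,
            c_embryo_tare=c_embryo_tare,
            homing_locus_rule=HomingLocusRule.NONE,
            **kwargs,
        )

    @property
    def homing_active(self) -> bool:
        return self.homing_locus_rule is not HomingLocusRule.NONE


# ---------------------------------------------------------------------------
# Gamete formation


def _validate_parent(parent: Genotype, params: DriveParams) -> None:
    if not is_viable(parent, params):
        raise ValueError(f"parent genotype {parent} is not viable under these rules")


def gamete_distribution(
    parent: Genotype, params: DriveParams
) -> Dict[Haplotype, float]:
    """Exact gamete distribution of a viable parent.

    Steps, in order: (1) meiotic recombination between the loci at the
    sex-specific rate; (2) if the parent carries the TARE drive, each
    wild-type *h* allele is independently disrupted in the germline with
    ``c_germ_tare``; (3) if the parent carries both the TARE drive (Cas9
    source) and the homing drive, each wild-type homing allele is
    independently cut with ``homing_germ_cut`` and resolves to a drive copy
    with ``homing_conversion_frac``, else to a nonfunctional allele; (4) one
    haplotype is drawn uniformly.

    Germline cutting in a parent without the TARE drive never occurs, no
    matter the homing parameters: the homing element has no Cas9 of its own.
    """
    _validate_parent(parent, params)
    h1, h2 = parent.haplotypes
    r = params.recomb_female if parent.sex is Sex.FEMALE else params.recomb_male

    base: Dict[Haplotype, float] = defaultdict(float)
    base[Haplotype(h1.tare, h1.homing)] += (1.0 - r) / 2.0
    base[Haplotype(h2.tare, h2.homing)] += (1.0 - r) / 2.0
    base[Haplotype(h1.tare, h2.homing)] += r / 2.0
    base[Haplotype(h2.tare, h1.homing)] += r / 2.0

    tare_cut = params.c_germ_tare if parent.has_tare_drive else 0.0
    homing_cut = (
        params.homing_germ_cut
        if (parent.has_tare_drive and parent.has_homing_drive and params.homing_active)
        else 0.0
    )

    out: Dict[Haplotype, float] = defaultdict(float)
    for hap, p in base.items():
        if p == 0.0:
            continue
        for hap2, q in _germline_fates(hap, tare_cut, homing_cut, params):
            out[hap2] += p * q
    return dict(out)


def _germline_fates(
    hap: Haplotype, tare_cut: float, homing_cut: float, params: DriveParams
) -> Iterable[Tuple[Haplotype, float]]:
    tare_fates: List[Tuple[TareAllele, float]]
    if hap.tare is TareAllele.WILD and tare_cut > 0.0:
        tare_fates = [
            (TareAllele.DISRUPTED, tare_cut),
            (TareAllele.WILD, 1.0 - tare_cut),
        ]
    else:
        tare_fates = [(hap.tare, 1.0)]

    homing_fates: List[Tuple[HomingAllele, float]]
    if hap.homing is HomingAllele.WILD and homing_cut > 0.0:
        conv = params.homing_conversion_frac
        homing_fates = [
            (HomingAllele.DRIVE, homing_cut * conv),
            (HomingAllele.NONFUNCTIONAL_R, homing_cut * (1.0 - conv)),
            (HomingAllele.WILD, 1.0 - homing_cut),
        ]
    else:
        homing_fates = [(hap.homing, 1.0)]

    for (t, pt), (m, pm) in itertools.product(tare_fates, homing_fates):
        p = pt * pm
        if p > 0.0:
            yield Haplotype(t, m), p


# ---------------------------------------------------------------------------
# Embryo modification by maternal deposition


def _embryo_fates_hap(
    hap: Haplotype, tare_cut: float, homing_cut: float
) -> List[Tuple[Haplotype, float]]:
    tare_fates: List[Tuple[TareAllele, float]]
    if hap.tare is TareAllele.WILD and tare_cut > 0.0:
        tare_fates = [
            (TareAllele.DISRUPTED, tare_cut),
            (TareAllele.WILD, 1.0 - tare_cut),
        ]
    else:
        tare_fates = [(hap.tare, 1.0)]

    homing_fates: List[Tuple[HomingAllele, float]]
    if hap.homing is HomingAllele.WILD and homing_cut > 0.0:
        homing_fates = [
            (HomingAllele.NONFUNCTIONAL_R, homing_cut),
            (HomingAllele.WILD, 1.0 - homing_cut),
        ]
    else:
        homing_fates = [(hap.homing, 1.0)]

    out = []
    for (t, pt), (m, pm) in itertools.product(tare_fates, homing_fates):
        p = pt * pm
        if p > 0.0:
            out.append((Haplotype(t, m), p))
    return out


def _embryo_cut_rates(
    mother_has_tare: bool, mother_has_homing: bool, params: DriveParams
) -> Tuple[float, float]:
    tare_cut = params.c_embryo_tare if mother_has_tare else 0.0
    homing_cut = (
        params.c_embryo_homing
        if (mother_has_tare and mother_has_homing and params.homing_active)
        else 0.0
    )
    return tare_cut, homing_cut


def _embryo_outcomes(
    dip: Diplotype, tare_cut: float, homing_cut: float
) -> Iterable[Tuple[Diplotype, float]]:
    if tare_cut == 0.0 and homing_cut == 0.0:
        yield dip, 1.0
        return
    f1 = _embryo_fates_hap(dip[0], tare_cut, homing_cut)
    f2 = _embryo_fates_hap(dip[1], tare_cut, homing_cut)
    for (a, pa), (b, pb) in itertools.product(f1, f2):
        yield diplotype(a, b), pa * pb


def apply_embryo_cleavage(
    zygote: Genotype, mother: Genotype, params: DriveParams
) -> Dict[Genotype, float]:
    """Distribution of the zygote genotype after maternal-deposition cutting.

    If the mother carries the TARE drive, every wild-type *h* allele in the
    zygote -- whichever parent it came from -- is independently disrupted with
    ``c_embryo_tare``; if she additionally carries the homing drive, every
    wild-type homing allele is independently cut to a nonfunctional allele
    with ``c_embryo_homing``.  A TARE-less mother deposits no Cas9 and the
    zygote is returned unchanged.
    """
    tare_cut, homing_cut = _embryo_cut_rates(
        mother.has_tare_drive, mother.has_homing_drive, params
    )
    out: Dict[Genotype, float] = defaultdict(float)
    for dip, p in _embryo_outcomes(zygote.haplotypes, tare_cut, homing_cut):
        out[Genotype(dip, zygote.sex)] += p
    return dict(out)


# ---------------------------------------------------------------------------
# Viability / fertility


def _dip_viable(dip: Diplotype, params: DriveParams) -> bool:
    tare = (dip[0].tare, dip[1].tare)
    if tare[0] is TareAllele.DISRUPTED and tare[1] is TareAllele.DISRUPTED:
        return False
    if params.homing_locus_rule is HomingLocusRule.HAPLOLETHAL_RESCUE:
        if HomingAllele.NONFUNCTIONAL_R in (dip[0].homing, dip[1].homing):
            return False
    return True


def is_viable(g: Genotype, params: DriveParams) -> bool:
    """Recessive lethality at *h*; haplolethality at an unrescued homing target."""
    return _dip_viable(g.haplotypes, params)


def _dip_fertile_female(dip: Diplotype, params: DriveParams) -> bool:
    if params.homing_locus_rule is not HomingLocusRule.FEMALE_FERTILITY:
        return True
    alleles = (dip[0].homing, dip[1].homing)
    if HomingAllele.ABSENT in alleles:
        return True
    return HomingAllele.WILD in alleles


def is_fertile_female(g: Genotype, params: DriveParams) -> bool:
    """Fertility of a female under the suppression-drive rule.

    The suppression target is haplosufficient: one wild-type copy keeps the
    female fertile; both drive and nonfunctional alleles disrupt it and there
    is no rescue.  Only meaningful when ``homing_locus_rule`` is
    FEMALE_FERTILITY and ``g`` is female.
    """
    if params.homing_locus_rule is not HomingLocusRule.FEMALE_FERTILITY:
        raise ValueError("fertility rule queried without a female-fertility locus")
    if g.sex is not Sex.FEMALE:
        raise ValueError("is_fertile_female called on a male genotype")
    return _dip_fertile_female(g.haplotypes, params)


def _parent_fertile(dip: Diplotype, sex: Sex, params: DriveParams) -> bool:
    if sex is Sex.MALE:
        return True
    return _dip_fertile_female(dip, params)


# ---------------------------------------------------------------------------
# Offspring of a cross


@dataclass(frozen=True)
class OffspringDistribution:
    """Viable offspring of one mother x father cross.

    ``by_genotype`` is normalised over viable offspring with sexes assigned
    1:1; ``viable_weight`` is the fraction of zygotes that survive the
    viability rules (1.0 for a wild-type cross).  A sterile mother yields an
    empty distribution with weight 0.
    """

    by_genotype: Mapping[Genotype, float]
    viable_weight: float

    def by_diplotype(self) -> Dict[Diplotype, float]:
        out: Dict[Diplotype, float] = defaultdict(float)
        for g, p in self.by_genotype.items():
            out[g.haplotypes] += p
        return dict(out)


@functools.lru_cache(maxsize=None)
def _viable_offspring_cached(
    mdip: Diplotype, fdip: Diplotype, params: DriveParams
) -> Tuple[Tuple[Tuple[Diplotype, float], ...], float]:
    mother = Genotype(mdip, Sex.FEMALE)
    father = Genotype(fdip, Sex.MALE)
    gm = gamete_distribution(mother, params)
    gf = gamete_distribution(father, params)
    tare_cut, homing_cut = _embryo_cut_rates(
        mother.has_tare_drive, mother.has_homing_drive, params
    )

    acc: Dict[Diplotype, float] = defaultdict(float)
    for (hm, pm), (hf, pf) in itertools.product(gm.items(), gf.items()):
        pz = pm * pf
        for dip, pe in _embryo_outcomes(diplotype(hm, hf), tare_cut, homing_cut):
            acc[dip] += pz * pe

    viable = {d: p for d, p in acc.items() if _dip_viable(d, params)}
    weight = sum(viable.values())
    if weight > 0.0:
        viable = {d: p / weight for d, p in viable.items()}
    return tuple(sorted(viable.items(), key=lambda kv: (kv[0][0].sort_key, kv[0][1].sort_key))), weight


def viable_offspring(
    mdip: Diplotype, fdip: Diplotype, params: DriveParams
) -> Tuple[Tuple[Tuple[Diplotype, float], ...], float]:
    """Cached sexless core of :func:`offspring_distribution`.

    Returns the normalised viable diplotype distribution and the viable
    weight.  A sterile mother (suppression rule) yields ``((), 0.0)``.
    """
    if not _parent_fertile(mdip, Sex.FEMALE, params):
        return (), 0.0
    return _viable_offspring_cached(mdip, fdip, params)


def offspring_distribution(
    mother: Genotype, father: Genotype, params: DriveParams
) -> OffspringDistribution:
    """Distribution over viable offspring genotypes of one cross.

    Convolves the parental gamete distributions, applies maternal-deposition
    embryo cutting, removes nonviable genotypes, renormalises, and assigns
    sexes 1:1.  ``viable_weight`` is the survival fraction before
    renormalisation (relative egg-to-adult viability of the cross).
    """
    if mother.sex is not Sex.FEMALE or father.sex is not Sex.MALE:
        raise ValueError("offspring_distribution requires a female mother and male father")
    _validate_parent(mother, params)
    _validate_parent(father, params)
    dist, weight = viable_offspring(mother.haplotypes, father.haplotypes, params)
    by_genotype: Dict[Genotype, float] = {}
    for dip, p in dist:
        for sex in (Sex.FEMALE, Sex.MALE):
            g = Genotype(dip, sex)
            by_genotype[g] = by_genotype.get(g, 0.0) + 0.5 * p
    return OffspringDistribution(by_genotype=by_genotype, viable_weight=weight)


# ---------------------------------------------------------------------------
# Text syntax: "h:D/W;hom:W/W;sex:F" (hom segment optional => ABSENT)

_GENO_RE = re.compile(
    r"^h:(?P<t1>[WDR])/(?P<t2>[WDR])"
    r"(?:;hom:(?P<m1>[WDR-])/(?P<m2>[WDR-]))?"
    r"(?:;sex:(?P<sex>[FM]))?$"
)


def parse_diplotype(text: str) -> Diplotype:
    m = _GENO_RE.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse genotype string {text!r}")
    m1 = m.group("m1") or "-"
    m2 = m.group("m2") or "-"
    h1 = Haplotype(TareAllele(m.group("t1")), HomingAllele(m1))
    h2 = Haplotype(TareAllele(m.group("t2")), HomingAllele(m2))
    return diplotype(h1, h2)


def parse_genotype(text: str) -> Genotype:
    """Parse ``"h:D/W;hom:W/W;sex:F"``; the hom segment is optional (ABSENT)."""
    m = _GENO_RE.match(text.strip())
    if not m or not m.group("sex"):
        raise ValueError(f"cannot parse genotype string {text!r} (sex required)")
    return Genotype(parse_diplotype(text), Sex(m.group("sex")))


def format_diplotype(dip: Diplotype) -> str:
    s = f"h:{dip[0].tare.value}/{dip[1].tare.value}"
    if dip[0].homing is not HomingAllele.ABSENT:
        s += f";hom:{dip[0].homing.value}/{dip[1].homing.value}"
    return s


def format_genotype(g: Genotype) -> str:
    return format_diplotype(g.haplotypes) + f";sex:{g.sex.value}"


def all_diplotypes(with_homing_locus: bool) -> List[Diplotype]:
    """Every distinct diplotype of the configured allele space (viability not applied)."""
    if with_homing_locus:
        homs = [HomingAllele.WILD, HomingAllele.DRIVE, HomingAllele.NONFUNCTIONAL_R]
    else:
        homs = [HomingAllele.ABSENT]
    haps = [Haplotype(t, m) for t in TareAllele for m in homs]
    seen = set()
    out = []
    for h1, h2 in itertools.combinations_with_replacement(haps, 2):
        d = diplotype(h1, h2)
        if d not in seen:
            seen.add(d)
            out.append(d)
    return out
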