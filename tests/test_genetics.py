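import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tetherdrive.genetics import (
    DriveParams,
    Genotype,
    Haplotype,
    HomingAllele,
    HomingLocusRule,
    Sex,
    TareAllele,
    all_diplotypes,
    apply_embryo_cleavage,
    diplotype,
    drive_haplotype,
    format_diplotype,
    format_genotype,
    gamete_distribution,
    is_fertile_female,
    is_viable,
    offspring_distribution,
    parse_diplotype,
    parse_genotype,
    wild_haplotype,
)

from _oracle import oracle_offspring


def _geno(dip, sex=Sex.FEMALE):
    return Genotype(dip, sex)


class TestGametes:
    def test_wild_parent_is_mendelian(self, measured_params):
        g = _geno(diplotype(wild_haplotype(), wild_haplotype()))
        dist = gamete_distribution(g, measured_params)
        assert dist == {wild_haplotype(): pytest.approx(1.0)}

    def test_distribution_sums_to_one(self, tethered_params):
        for dip in all_diplotypes(with_homing_locus=True):
            for sex in (Sex.FEMALE, Sex.MALE):
                g = Genotype(dip, sex)
                if not is_viable(g, tethered_params):
                    continue
                dist = gamete_distribution(g, tethered_params)
                assert math.isclose(sum(dist.values()), 1.0, abs_tol=1e-12)
                assert all(p >= 0 for p in dist.values())

    def test_germline_disruption_rates(self, measured_params):
        het = _geno(diplotype(drive_haplotype(), wild_haplotype()))
        dist = gamete_distribution(het, measured_params)
        c = measured_params.c_germ_tare
        assert dist[drive_haplotype()] == pytest.approx(0.5)
        assert dist[wild_haplotype()] == pytest.approx(0.5 * (1 - c))
        disrupted = Haplotype(TareAllele.DISRUPTED, HomingAllele.ABSENT)
        assert dist[disrupted] == pytest.approx(0.5 * c)

    def test_no_cas9_without_tare_drive(self, tethered_params):
        # homing drive alone cannot cut: no Cas9 source
        hap = Haplotype(TareAllele.WILD, HomingAllele.DRIVE)
        wt = Haplotype(TareAllele.WILD, HomingAllele.WILD)
        g = _geno(diplotype(hap, wt))
        dist = gamete_distribution(g, tethered_params)
        assert set(dist) == {hap, wt}
        assert dist[hap] == pytest.approx(0.5)

    def test_males_have_no_crossovers(self, tethered_params):
        """With germline cutting switched off, a male's gametes keep the
        parental tare/homing linkage exactly (no meiotic crossovers); only
        homing conversion, not recombination, can create new pairings."""
        from dataclasses import replace

        no_cut = replace(
            tethered_params, c_germ_tare=0.0, homing_germ_cut=0.0
        )
        h1 = Haplotype(TareAllele.DRIVE, HomingAllele.WILD)
        h2 = Haplotype(TareAllele.WILD, HomingAllele.DRIVE)
        g = Genotype(diplotype(h1, h2), Sex.MALE)
        dist = gamete_distribution(g, no_cut)
        assert dist == {h1: pytest.approx(0.5), h2: pytest.approx(0.5)}
        # with cutting on, conversion (not crossover) may pair D with D
        full = gamete_distribution(g, tethered_params)
        converted = Haplotype(TareAllele.DRIVE, HomingAllele.DRIVE)
        assert full[converted] == pytest.approx(
            0.5 * tethered_params.homing_germ_cut
            * tethered_params.homing_conversion_frac
        )

    def test_females_recombine(self, tethered_params):
        h1 = Haplotype(TareAllele.DRIVE, HomingAllele.WILD)
        h2 = Haplotype(TareAllele.WILD, HomingAllele.DRIVE)
        g = Genotype(diplotype(h1, h2), Sex.FEMALE)
        dist = gamete_distribution(g, tethered_params)
        assert any(
            hap.tare is TareAllele.DRIVE and hap.homing is HomingAllele.DRIVE
            for hap in dist
        )


class TestEmbryoCleavage:
    def test_motherless_deposition_never_occurs(self, measured_params):
        zyg = _geno(diplotype(wild_haplotype(), wild_haplotype()))
        mother = _geno(diplotype(wild_haplotype(), wild_haplotype()))
        out = apply_embryo_cleavage(zyg, mother, measured_params)
        assert out == {zyg: pytest.approx(1.0)}

    def test_both_parental_alleles_are_cut(self, measured_params):
        # wild/wild zygote of a TARE-carrier mother: both copies at risk
        zyg = _geno(diplotype(wild_haplotype(), wild_haplotype()))
        mother = _geno(diplotype(drive_haplotype(), wild_haplotype()))
        out = apply_embryo_cleavage(zyg, mother, measured_params)
        ce = measured_params.c_embryo_tare
        rr = diplotype(
            Haplotype(TareAllele.DISRUPTED, HomingAllele.ABSENT),
            Haplotype(TareAllele.DISRUPTED, HomingAllele.ABSENT),
        )
        assert out[_geno(rr)] == pytest.approx(ce * ce)
        assert out[zyg] == pytest.approx((1 - ce) ** 2)

    def test_probabilities_sum_to_one(self, tethered_params):
        mother = _geno(
            diplotype(
                drive_haplotype(with_homing_locus=True, homing=HomingAllele.DRIVE),
                wild_haplotype(True),
            )
        )
        zyg = _geno(diplotype(wild_haplotype(True), wild_haplotype(True)))
        out = apply_embryo_cleavage(zyg, mother, tethered_params)
        assert math.isclose(sum(out.values()), 1.0, abs_tol=1e-12)


class TestViabilityFertility:
    def test_biallelic_disruption_is_lethal(self, measured_params):
        r = Haplotype(TareAllele.DISRUPTED, HomingAllele.ABSENT)
        assert not is_viable(_geno(diplotype(r, r)), measured_params)
        assert is_viable(_geno(diplotype(r, wild_haplotype())), measured_params)
        assert is_viable(_geno(diplotype(r, drive_haplotype())), measured_params)

    def test_haplolethal_unrescued_allele_is_dominant_lethal(self, tethered_params):
        bad = Haplotype(TareAllele.WILD, HomingAllele.NONFUNCTIONAL_R)
        ok = Haplotype(TareAllele.WILD, HomingAllele.WILD)
        assert not is_viable(_geno(diplotype(bad, ok)), tethered_params)
        assert is_viable(_geno(diplotype(ok, ok)), tethered_params)

    def test_female_fertility_rule(self):
        params = DriveParams(
            homing_germ_cut=0.5,
            homing_locus_rule=HomingLocusRule.FEMALE_FERTILITY,
        )
        drive = Haplotype(TareAllele.WILD, HomingAllele.DRIVE)
        wt = Haplotype(TareAllele.WILD, HomingAllele.WILD)
        nf = Haplotype(TareAllele.WILD, HomingAllele.NONFUNCTIONAL_R)
        assert is_fertile_female(_geno(diplotype(drive, wt)), params)
        assert not is_fertile_female(_geno(diplotype(drive, drive)), params)
        assert not is_fertile_female(_geno(diplotype(drive, nf)), params)
        # nonfunctional alleles are viable here (haplosufficient target)
        assert is_viable(_geno(diplotype(nf, nf)), params)


class TestOffspringDistribution:
    def test_het_female_cross_closed_form(self, measured_params):
        """Carrier fraction follows the closed-form solution of the
        one-locus recursion (germline cut c_g, embryo cut c_e both alleles)."""
        mother = _geno(diplotype(drive_haplotype(), wild_haplotype()))
        father = Genotype(diplotype(wild_haplotype(), wild_haplotype()), Sex.MALE)
        dist = offspring_distribution(mother, father, measured_params)
        cg, ce = measured_params.c_germ_tare, measured_params.c_embryo_tare
        viable = 0.5 + 0.5 * (1 - cg) * (1 - ce**2) + 0.5 * cg * (1 - ce)
        assert dist.viable_weight == pytest.approx(viable, abs=1e-12)
        carriers = sum(
            p for g, p in dist.by_genotype.items() if g.has_tare_drive
        )
        assert carriers / sum(dist.by_genotype.values()) == pytest.approx(
            0.5 / viable, abs=1e-12
        )

    def test_sterile_mother_yields_no_offspring(self):
        params = DriveParams(
            homing_germ_cut=0.5,
            homing_locus_rule=HomingLocusRule.FEMALE_FERTILITY,
        )
        drive = Haplotype(TareAllele.WILD, HomingAllele.DRIVE)
        mother = _geno(diplotype(drive, drive))
        father = Genotype(
            diplotype(wild_haplotype(True), wild_haplotype(True)), Sex.MALE
        )
        dist = offspring_distribution(mother, father, params)
        assert dist.viable_weight == 0.0
        assert dist.by_genotype == {}

    def test_matches_oracle_tare_only(self, measured_params):
        from tetherdrive.genetics import _dip_viable

        dips = [
            d
            for d in all_diplotypes(with_homing_locus=False)
            if _dip_viable(d, measured_params)
        ]
        for mdip in dips:
            for fdip in dips:
                got = offspring_distribution(
                    _geno(mdip), Genotype(fdip, Sex.MALE), measured_params
                )
                want, weight = oracle_offspring(mdip, fdip, measured_params)
                assert got.viable_weight == pytest.approx(weight, abs=1e-12)
                # by_genotype is normalized among survivors; the oracle's
                # probabilities sum to the survival weight
                by_dip = {}
                for g, p in got.by_genotype.items():
                    by_dip[g.haplotypes] = by_dip.get(g.haplotypes, 0.0) + p
                assert set(by_dip) == set(want)
                for dip in want:
                    assert by_dip[dip] == pytest.approx(
                        want[dip] / weight, abs=1e-12
                    )


class TestTextFormat:
    def test_roundtrip_all_diplotypes(self):
        for with_hom in (False, True):
            for dip in all_diplotypes(with_homing_locus=with_hom):
                assert parse_diplotype(format_diplotype(dip)) == dip

    def test_genotype_roundtrip(self):
        g = Genotype(diplotype(drive_haplotype(), wild_haplotype()), Sex.FEMALE)
        assert parse_genotype(format_genotype(g)) == g

    def test_malformed_strings_rejected(self):
        with pytest.raises(ValueError):
            parse_diplotype("h:X/W")
        with pytest.raises(ValueError):
            parse_genotype("h:D/W")  # sex required

    def test_mixed_absent_homing_rejected(self):
        with pytest.raises(ValueError):
            diplotype(
                Haplotype(TareAllele.WILD, HomingAllele.ABSENT),
                Haplotype(TareAllele.WILD, HomingAllele.WILD),
            )


class TestParamValidation:
    @given(st.floats(min_value=-10, max_value=10))
    @settings(max_examples=30, deadline=None)
    def test_probabilities_validated(self, v):
        if 0.0 <= v <= 1.0:
            DriveParams.tare_only(v, 0.5)
        else:
            with pytest.raises(ValueError):
                DriveParams.tare_only(v, 0.5)

    @given(
        st.floats(min_value=0, max_value=1),
        st.floats(min_value=0, max_value=1),
    )
    @settings(max_examples=25, deadline=None)
    def test_gamete_distribution_normalized_everywhere(self, cg, ce):
        params = DriveParams.tare_only(cg, ce)
        het = _geno(diplotype(drive_haplotype(), wild_haplotype()))
        dist = gamete_distribution(het, params)
        assert math.isclose(sum(dist.values()), 1.0, abs_tol=1e-12)
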