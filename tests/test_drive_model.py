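"""Closed-form sex-ratio expectations and the genotype/cross domain types."""

import pytest
from hypothesis import given, settings, strategies as st

from sazdscreen.drive_model import (
    CrossSpec,
    Cytoplasm,
    Genotype,
    MechanismParams,
    NEUTRAL_PARAMS,
    SuppressorSpec,
    XAllele,
    YChrom,
    daughter_genotype,
    expected_embryo_pf,
    expected_subadult_pf,
    line_genotypes,
    son_genotype,
)

survivals = st.floats(0.01, 1.0, allow_nan=False)


def sr_cross(**line_kwargs):
    dam, sire = line_genotypes("SR", driver=True, **line_kwargs)
    return CrossSpec(sire=sire, dam=dam, label="SRxSR")


class TestExpectations:
    def test_sperm_killing_sets_embryo_sex_ratio(self):
        # %F = 100 / (1 + s_Y): the driver removes Y-bearing sperm at syngamy
        pf = expected_embryo_pf(MechanismParams(s_Y=0.307), sr_cross())
        assert pf == pytest.approx(100.0 / 1.307, abs=1e-9)
        assert pf == pytest.approx(76.5, abs=0.02)

    def test_neutral_parameters_give_even_ratio(self):
        assert expected_embryo_pf(NEUTRAL_PARAMS, sr_cross()) == 50.0
        assert expected_subadult_pf(NEUTRAL_PARAMS, sr_cross()) == 50.0

    def test_unexpressed_driver_is_inert(self):
        p = MechanismParams(s_Y=0.5, penetrance=0.0)
        assert expected_embryo_pf(p, sr_cross()) == 50.0

    def test_sequential_sd_and_zygotic_drive_compose(self):
        # SD then paternal-effect son killing: %F = 100 / (1 + s_Y * s_son_post)
        p = MechanismParams(s_Y=0.307, s_son_post=0.625)
        pf = expected_subadult_pf(p, sr_cross())
        assert pf == pytest.approx(100.0 / (1.0 + 0.307 * 0.625), abs=1e-9)
        assert pf == pytest.approx(83.9, abs=0.02)

    def test_suppressor_y_silences_both_drive_components(self):
        # a Y that restores both sperm killing and the paternal effect
        sup = {"sec": SuppressorSpec(frozenset({"s_Y", "s_son_post"}), "sire")}
        p = MechanismParams(s_Y=0.307, s_son_post=0.625, suppressors=sup)
        dam, sire = line_genotypes("SR", driver=True)
        sec_sire = Genotype(
            x_alleles=sire.x_alleles,
            y=YChrom(origin="sec", suppressors=frozenset({"sec"})),
            autosome_dose_sr=1.0,
            cytoplasm=sire.cytoplasm,
        )
        assert expected_subadult_pf(p, CrossSpec(sec_sire, dam)) == pytest.approx(50.0)

    def test_partial_penetrance_pools_expressing_and_inert_sires(self):
        p = MechanismParams(s_Y=0.307, penetrance=0.5)
        pf = expected_embryo_pf(p, sr_cross())
        # pooled zygotes: half the sires produce 1:0.307 broods, half 1:1
        expected = 100 * (0.5 / 1.307 + 0.5 * 0.5)
        assert pf == pytest.approx(expected, abs=1e-9)

    def test_matrilineal_son_killing(self):
        # endosymbiont kills sons of infected dams only
        p = MechanismParams(sk_son_survival=0.3)
        sr_dam, sr_sire = line_genotypes("SR", driver=True, infected=True)
        even_dam, even_sire = line_genotypes("EVEN")
        infected_dam_cross = CrossSpec(even_sire, sr_dam)
        clean_dam_cross = CrossSpec(sr_sire, even_dam)
        assert expected_subadult_pf(p, infected_dam_cross) == pytest.approx(
            100.0 / 1.3, abs=1e-9
        )
        assert expected_subadult_pf(p, clean_dam_cross) == 50.0
        # son-killing acts after the embryo census
        assert expected_embryo_pf(p, infected_dam_cross) == 50.0

    def test_recessive_viability_needs_full_focal_autosome_dose(self):
        p = MechanismParams(v_male=0.5)
        sr_dam, sr_sire = line_genotypes("SR", driver=True)
        even_dam, _ = line_genotypes("EVEN")
        assert expected_subadult_pf(p, CrossSpec(sr_sire, sr_dam)) == pytest.approx(
            100.0 / 1.5
        )
        # outcrossed offspring are heterozygous for the focal background
        assert expected_subadult_pf(p, CrossSpec(sr_sire, even_dam)) == 50.0

    def test_y_linked_killer_follows_the_y(self):
        p = {"SR": MechanismParams(v_male=0.3, v_male_scope="y_linked"),
             "EVEN": NEUTRAL_PARAMS}
        sr_dam, sr_sire = line_genotypes("SR", driver=True)
        even_dam, even_sire = line_genotypes("EVEN")
        # sons of an SR sire carry Y_SR and die; sons of an EVEN sire do not
        assert expected_subadult_pf(p, CrossSpec(sr_sire, sr_dam)) == pytest.approx(
            100.0 / 1.3
        )
        assert expected_subadult_pf(p, CrossSpec(even_sire, sr_dam)) == 50.0

    def test_feminization_reclassifies_by_sexing_mode(self):
        p = MechanismParams(p_fem_y=0.4)
        dam, sire = line_genotypes("SR", driver=True, y_feminizer=True)
        cross = CrossSpec(sire, dam)
        pf_pheno = expected_embryo_pf(p, cross, sexing_mode="phenotype")
        pf_karyo = expected_embryo_pf(p, cross, sexing_mode="karyotype")
        assert pf_pheno == pytest.approx(100 * 0.7 / 1.0)
        assert pf_karyo == 50.0

    def test_asexual_daughters_add_female_share(self):
        p = MechanismParams(asex_fraction=0.2)
        dam, sire = line_genotypes("SR", driver=True, infected=True)
        assert expected_embryo_pf(p, CrossSpec(sire, dam)) == pytest.approx(
            100 * (0.2 + 0.8 * 0.5)
        )


class TestInvariantProperties:
    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(lo=survivals, hi=survivals)
    def test_expected_pf_monotone_in_each_survival(self, lo, hi):
        """Percent-female never decreases as any male-survival parameter drops."""
        lo, hi = min(lo, hi), max(lo, hi)
        infected = sr_cross(infected=True)
        for fieldname in ("s_Y", "s_son_embryo", "s_son_post", "v_male",
                          "sk_son_survival"):
            p_lo = MechanismParams(**{fieldname: lo})
            p_hi = MechanismParams(**{fieldname: hi})
            assert (
                expected_subadult_pf(p_lo, infected)
                >= expected_subadult_pf(p_hi, infected) - 1e-12
            )

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(a=survivals, b=survivals)
    def test_sd_and_zygotic_drive_operate_sequentially(self, a, b):
        """Subadult %F under (s_Y=a, s_son_post=b) equals embryo %F under s_Y=a*b."""
        cross = sr_cross()
        via_stages = expected_subadult_pf(MechanismParams(s_Y=a, s_son_post=b), cross)
        collapsed = expected_embryo_pf(MechanismParams(s_Y=a * b), cross)
        assert via_stages == pytest.approx(collapsed, abs=1e-12)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(a=survivals, e=survivals)
    def test_stages_agree_when_post_embryo_neutral(self, a, e):
        p = MechanismParams(s_Y=a, s_son_embryo=e)
        cross = sr_cross()
        assert expected_embryo_pf(p, cross) == pytest.approx(
            expected_subadult_pf(p, cross), abs=1e-12
        )

    def test_suppressor_application_is_idempotent(self):
        sup = {"nmy": SuppressorSpec(frozenset({"s_Y"}), "sire")}
        p = MechanismParams(s_Y=0.307, suppressors=sup)
        dam, _ = line_genotypes("SR", driver=True)
        once = Genotype(
            x_alleles=(XAllele(origin="SR", driver=True),),
            y=YChrom(origin="SR"),
            autosome_dose_sr=1.0,
            autosome_suppressors={"nmy": 1.0},
            cytoplasm=Cytoplasm("SR"),
        )
        # also carried on the X and the Y: still one suppression event
        twice = Genotype(
            x_alleles=(XAllele(origin="SR", driver=True,
                               suppressors=frozenset({"nmy"})),),
            y=YChrom(origin="SR", suppressors=frozenset({"nmy"})),
            autosome_dose_sr=1.0,
            autosome_suppressors={"nmy": 1.0},
            cytoplasm=Cytoplasm("SR"),
        )
        pf_once = expected_embryo_pf(p, CrossSpec(once, dam))
        pf_twice = expected_embryo_pf(p, CrossSpec(twice, dam))
        assert pf_once == pf_twice == 50.0


class TestDomainTypes:
    def test_parameters_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            MechanismParams(s_Y=1.2)
        with pytest.raises(ValueError):
            MechanismParams(asex_fraction=-0.1)

    def test_cross_requires_male_sire_and_female_dam(self):
        dam, sire = line_genotypes("SR")
        with pytest.raises(ValueError):
            CrossSpec(sire=dam, dam=sire)

    def test_sire_without_x_cannot_head_a_cross(self):
        bad = Genotype(x_alleles=(), y=YChrom("SR"))
        dam, _ = line_genotypes("SR")
        with pytest.raises(ValueError):
            CrossSpec(sire=bad, dam=dam)

    def test_f1_sons_take_x_from_dam_and_y_from_sire(self):
        sr_dam, _ = line_genotypes("SR", driver=True)
        _, even_sire = line_genotypes("EVEN")
        son = son_genotype(CrossSpec(even_sire, sr_dam))
        assert son.x_alleles[0].origin == "SR" and son.x_alleles[0].driver
        assert son.y.origin == "EVEN"
        assert son.autosome_dose_sr == pytest.approx(0.5)
        assert son.cytoplasm.origin == "SR"

    def test_compound_x_dam_reverses_sex_chromosome_transmission(self):
        _, paris_sire = line_genotypes("Paris", driver=True)
        cx_dam = Genotype(
            x_alleles=(XAllele("sim"), XAllele("sim")),
            y=YChrom("sim"),
            compound_x=True,
            cytoplasm=Cytoplasm("sim"),
        )
        assert cx_dam.is_female
        cross = CrossSpec(paris_sire, cx_dam)
        son = son_genotype(cross)
        assert son.x_alleles[0].origin == "Paris"  # X from the sire
        assert son.y.origin == "sim"               # Y from the dam
        daughter = daughter_genotype(cross)
        assert daughter.compound_x and daughter.y.origin == "Paris"
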