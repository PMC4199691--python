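"""Forward simulator: convergence to closed forms, reproducibility, designs."""

import numpy as np
import pytest

from sazdscreen.drive_model import (
    CrossSpec,
    MechanismParams,
    NEUTRAL_PARAMS,
    expected_embryo_pf,
    expected_subadult_pf,
    line_genotypes,
)
from sazdscreen.synthetic_data import (
    BroodCounts,
    SCREEN_CROSS_IDS,
    default_screen_design,
    screen_scenario,
    simulate_cross,
    simulate_recombination_assay,
    simulate_screen_dataset,
)


def pooled_pf(broods, stage="subadult"):
    if stage == "embryo":
        f = sum(b.n_embryo_female for b in broods)
        m = sum(b.n_embryo_male for b in broods)
    else:
        f = sum(b.n_subadult_female for b in broods)
        m = sum(b.n_subadult_male for b in broods)
    return 100.0 * f / (f + m)


@pytest.fixture
def sr_cross():
    dam, sire = line_genotypes("SR", driver=True)
    return CrossSpec(sire, dam, "SRxSR")


class TestSimulateCross:
    def test_pooled_ratios_converge_to_closed_forms(self, sr_cross):
        p = MechanismParams(s_Y=0.307, s_son_post=0.625)
        broods = simulate_cross(
            sr_cross, p, n_vials=12, eggs_per_vial=150, rho=0.0, rng_seed=42,
            census_embryo=True,
        )
        assert abs(pooled_pf(broods, "embryo") - expected_embryo_pf(p, sr_cross)) < 3.0
        assert abs(pooled_pf(broods, "subadult") - expected_subadult_pf(p, sr_cross)) < 3.0

    def test_neutral_cross_near_even(self, sr_cross):
        broods = simulate_cross(
            sr_cross, NEUTRAL_PARAMS, n_vials=20, eggs_per_vial=200, rho=0.0,
            rng_seed=0,
        )
        assert abs(pooled_pf(broods) - 50.0) < 2.0

    def test_matrilineal_transmission_of_son_killing(self):
        p = MechanismParams(sk_son_survival=0.3)
        sr_dam, sr_sire = line_genotypes("SR", driver=True, infected=True)
        even_dam, even_sire = line_genotypes("EVEN")
        infected = simulate_cross(
            CrossSpec(even_sire, sr_dam), p, 20, 300, 0.0, rng_seed=1
        )
        clean = simulate_cross(
            CrossSpec(sr_sire, even_dam), p, 20, 300, 0.0, rng_seed=1
        )
        assert pooled_pf(infected) > 70.0
        assert abs(pooled_pf(clean) - 50.0) < 2.0

    def test_identical_seeds_reproduce_counts(self, sr_cross):
        p = MechanismParams(s_Y=0.4, s_son_post=0.7, penetrance=0.8)
        a = simulate_cross(sr_cross, p, 10, 150, 0.05, rng_seed=123, census_embryo=True)
        b = simulate_cross(sr_cross, p, 10, 150, 0.05, rng_seed=123, census_embryo=True)
        assert a == b

    def test_counts_conserved_within_vial(self, sr_cross):
        p = MechanismParams(s_Y=0.5, s_son_embryo=0.8, s_son_post=0.6)
        broods = simulate_cross(
            sr_cross, p, 30, ("poisson", 120), 0.1, rng_seed=9,
            census_embryo=True, record_eggs=True, background_survival=0.85,
        )
        for b in broods:
            assert b.n_subadult_female + b.n_subadult_male <= b.n_eggs
            assert b.n_embryo_female + b.n_embryo_male <= b.n_eggs

    def test_overdispersion_inflates_vial_variance_not_mean(self, sr_cross):
        p = MechanismParams(s_Y=0.307, s_son_post=0.625)
        def vial_pfs(rho, seed):
            broods = simulate_cross(sr_cross, p, 200, 400, rho, rng_seed=seed)
            return np.array(
                [100 * b.n_subadult_female / (b.n_subadult_female + b.n_subadult_male)
                 for b in broods]
            )
        tight = vial_pfs(0.0, 5)
        loose = vial_pfs(0.25, 5)
        assert loose.var() > 2 * tight.var()
        truth = expected_subadult_pf(p, sr_cross)
        assert abs(tight.mean() - truth) < 1.5
        assert abs(loose.mean() - truth) < 3.0

    def test_invalid_inputs_rejected(self, sr_cross):
        with pytest.raises(ValueError):
            simulate_cross(sr_cross, NEUTRAL_PARAMS, 5, 100, rho=1.0)
        with pytest.raises(ValueError):
            simulate_cross(sr_cross, NEUTRAL_PARAMS, 5, 0, rho=0.0, rng_seed=1)

    def test_brood_counts_validate(self):
        with pytest.raises(ValueError):
            BroodCounts("c", "v", n_subadult_female=-1, n_subadult_male=2)
        with pytest.raises(ValueError):
            BroodCounts("c", "v", 100, 100, n_eggs=150)


class TestScreenDataset:
    def test_design_contains_the_seven_crosses(self):
        ps, pe, skw, ekw = screen_scenario("sa-zd")
        ds = simulate_screen_dataset(ps, pe, rng_seed=2, sr_line_kwargs=skw,
                                     even_line_kwargs=ekw)
        assert set(ds.design.cross_ids()) == set(SCREEN_CROSS_IDS)
        # embryo census only for the focal parental cross
        for cid in SCREEN_CROSS_IDS:
            has_embryo = any(
                b.n_embryo_female is not None for b in ds.broods_for(cid)
            )
            assert has_embryo == (cid == "P0_SR")

    def test_f1_sire_genotypes_follow_mendelian_transmission(self):
        sr_dam, sr_sire = line_genotypes("SR", driver=True)
        even_dam, even_sire = line_genotypes("EVEN")
        design = default_screen_design(sr_dam, sr_sire, even_dam, even_sire)
        by_id = {cd.cross_id: cd.cross for cd in design.crosses}
        s3a = by_id["step3a"].sire
        assert s3a.x_alleles[0].origin == "SR" and s3a.y.origin == "EVEN"
        s3c = by_id["step3c"].sire
        assert s3c.x_alleles[0].origin == "EVEN" and s3c.y.origin == "SR"
        # backcross dams are from the SR line for 3a/3c, EVEN for 3b
        assert by_id["step3a"].dam.cytoplasm.origin == "SR"
        assert by_id["step3b"].dam.cytoplasm.origin == "EVEN"

    def test_incomplete_design_rejected(self):
        sr_dam, sr_sire = line_genotypes("SR", driver=True)
        even_dam, even_sire = line_genotypes("EVEN")
        design = default_screen_design(sr_dam, sr_sire, even_dam, even_sire)
        partial = type(design)(crosses=design.crosses[:4], rho=design.rho)
        with pytest.raises(ValueError, match="step3"):
            simulate_screen_dataset(
                MechanismParams(s_Y=0.3), NEUTRAL_PARAMS, partial, rng_seed=1
            )

    def test_dataset_reproducible(self):
        ps, pe, skw, ekw = screen_scenario("sd-only")
        a = simulate_screen_dataset(ps, pe, rng_seed=11)
        b = simulate_screen_dataset(ps, pe, rng_seed=11)
        assert a.broods == b.broods


class TestRecombinationAssay:
    def test_complete_linkage_produces_no_driverless_sires(self):
        data = simulate_recombination_assay(0.0, penetrance=1.0, n_sires=354,
                                            rng_seed=1)
        assert all(s.true_drivers for s in data.sires)

    def test_null_class_fraction_is_half_the_recombination_fraction(self):
        data = simulate_recombination_assay(0.1, penetrance=1.0, n_sires=10_000,
                                            rng_seed=7)
        frac = sum(1 for s in data.sires if not s.true_drivers) / len(data.sires)
        assert frac == pytest.approx(0.05, abs=0.01)

    def test_incomplete_penetrance_creates_rescuable_false_negatives(self):
        data = simulate_recombination_assay(0.0, penetrance=0.9, n_sires=400,
                                            family_size_model=150, rng_seed=3)
        nonsig = [s for s in data.sires if s.grandson_families is not None]
        # ~10% of sires fail to express; all carry a driver
        assert 0.03 < len(nonsig) / 400 < 0.25
        assert all(s.true_drivers for s in nonsig)

    def test_followups_only_for_nonsignificant_sires(self):
        data = simulate_recombination_assay(0.2, penetrance=0.9, n_sires=500,
                                            rng_seed=13)
        from scipy.stats import binomtest
        for s in data.sires:
            sig = (
                s.n_total > 0
                and binomtest(s.n_female, s.n_total, 0.5, alternative="greater").pvalue
                < data.alpha
            )
            assert (s.grandson_families is None) == sig

    def test_invalid_recombination_fraction_rejected(self):
        with pytest.raises(ValueError):
            simulate_recombination_assay(0.6, rng_seed=1)
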