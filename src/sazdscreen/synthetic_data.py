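"""Seeded forward simulator for genetic-cross sex-ratio data.

Generates per-vial brood counts for arbitrary crosses and for the two
multi-generation designs the screen needs:

* the seven-cross process-of-elimination design (parental SR x SR with an
  embryo and a subadult census, an EVEN x EVEN control, both reciprocal F1
  crosses, and three backcrosses with F1 sires), and
* the two-driver recombination assay (G2 sires crossed to EVEN dams, with a
  grandson follow-up of sires whose primary family was not significantly
  female-biased).

Sampling model per vial: one sire, whose drive expression is drawn once
(incomplete penetrance); zygote sexes are binomial at the syngamy
female-share given by the closed forms in :mod:`sazdscreen.drive_model`;
embryo-stage and post-embryo male survivals are per-individual Bernoulli
deaths whose vial-level probabilities are beta-perturbed with intra-vial
correlation ``rho`` (``rho = 0`` is pure binomial sampling).  Daughters are
the survival reference; an optional sex-neutral background egg-to-subadult
survival makes hatch rates realistic without moving any percent-female
expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .drive_model import (
    CrossSpec,
    Genotype,
    MechanismParams,
    NEUTRAL_PARAMS,
    ParamsLike,
    SuppressorSpec,
    expression_states,
    line_genotypes,
    male_fate_components,
    son_genotype,
    syngamy_female_share,
)

__all__ = [
    "BroodCounts",
    "CrossDesign",
    "DesignSpec",
    "ScreenDataset",
    "SireFamily",
    "LinkageAssayData",
    "simulate_cross",
    "simulate_screen_dataset",
    "simulate_recombination_assay",
    "default_screen_design",
    "screen_scenario",
    "SCREEN_SCENARIOS",
    "SCREEN_CROSS_IDS",
]


@dataclass(frozen=True)
class BroodCounts:
    """Census counts for one vial (the unit of replication).

    Embryo counts are present only when the design requested an embryo
    census for the cross; ``n_eggs`` is recorded only for crosses used in
    hatch-rate (egg-to-subadult survival) assays.
    """

    cross_id: str
    vial_id: str
    n_subadult_female: int
    n_subadult_male: int
    n_eggs: Optional[int] = None
    n_embryo_female: Optional[int] = None
    n_embryo_male: Optional[int] = None

    def __post_init__(self):
        for name in ("n_subadult_female", "n_subadult_male", "n_eggs",
                     "n_embryo_female", "n_embryo_male"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if (self.n_embryo_female is None) != (self.n_embryo_male is None):
            raise ValueError("embryo counts must be both present or both absent")
        if self.n_eggs is not None:
            if self.n_subadult_female + self.n_subadult_male > self.n_eggs:
                raise ValueError("subadult total exceeds egg count")


FamilySizeModel = Union[int, tuple, Callable]


def _draw_family_size(model: FamilySizeModel, rng: np.random.Generator) -> int:
    if callable(model):
        return int(model(rng))
    if isinstance(model, tuple):
        kind, value = model
        if kind == "fixed":
            return int(value)
        if kind == "poisson":
            return int(rng.poisson(value))
        raise ValueError(f"unknown family-size model kind {kind!r}")
    return int(model)


def _beta_perturb(mean: float, rho: float, rng: np.random.Generator) -> float:
    """Draw a vial-level probability with the given mean and intra-class rho."""
    if rho <= 0.0 or mean <= 0.0 or mean >= 1.0:
        return mean
    scale = (1.0 - rho) / rho
    return float(rng.beta(mean * scale, (1.0 - mean) * scale))


def simulate_cross(
    cross: CrossSpec,
    params: ParamsLike,
    n_vials: int,
    eggs_per_vial: FamilySizeModel = 150,
    rho: float = 0.0,
    rng_seed: Union[int, np.random.Generator, None] = None,
    *,
    census_embryo: bool = False,
    record_eggs: bool = False,
    sexing_mode: str = "phenotype",
    background_survival: float = 1.0,
    cross_id: Optional[str] = None,
) -> list:
    """Simulate per-vial brood counts for one cross.

    One sire per vial; his drive expression is drawn once.  With ``rho = 0``
    and large totals the pooled stage-wise percent-female converges to
    :func:`~sazdscreen.drive_model.expected_embryo_pf` /
    :func:`~sazdscreen.drive_model.expected_subadult_pf`.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho must lie in [0, 1), got {rho}")
    if not 0.0 < background_survival <= 1.0:
        raise ValueError("background_survival must lie in (0, 1]")
    if n_vials < 1:
        raise ValueError("n_vials must be >= 1")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    cid = cross_id if cross_id is not None else (cross.label or "cross")

    states = expression_states(params, cross)
    pen_expressed = sum(w for w, e in states if e)
    # precompute fate components per expression state
    fates = {
        e: male_fate_components(params, cross, e) for _, e in states
    }
    shares = {e: syngamy_female_share(params, cross, e) for _, e in states}

    broods = []
    for i in range(n_vials):
        expressed = bool(rng.random() < pen_expressed)
        eggs = _draw_family_size(eggs_per_vial, rng)
        if eggs <= 0:
            raise ValueError("eggs per vial must be positive")
        phi = shares[expressed]
        nf_zyg = int(rng.binomial(eggs, phi))
        nm_zyg = eggs - nf_zyg

        comps = fates[expressed]
        probs = np.array([c[0] for c in comps])
        counts = rng.multinomial(nm_zyg, probs / probs.sum()) if nm_zyg else np.zeros(
            len(comps), dtype=int
        )

        bg = _beta_perturb(background_survival, rho, rng)
        emb_f = nf_zyg
        emb_m = 0
        sub_m = 0
        fem_survivors = 0  # phenotypic females of XY karyotype
        for (prob, s_e, s_post, p_fem), n_c in zip(comps, counts):
            if n_c == 0:
                continue
            n_fem = int(rng.binomial(n_c, p_fem)) if p_fem > 0 else 0
            n_plain = n_c - n_fem
            p_e = _beta_perturb(s_e, rho, rng)
            alive_fem_e = int(rng.binomial(n_fem, p_e)) if n_fem else 0
            alive_m_e = int(rng.binomial(n_plain, p_e)) if n_plain else 0
            if sexing_mode == "phenotype":
                emb_f += alive_fem_e
                emb_m += alive_m_e
            else:
                emb_m += alive_fem_e + alive_m_e
            p_p = _beta_perturb(s_post, rho, rng) * bg
            fem_survivors += int(rng.binomial(alive_fem_e, p_p)) if alive_fem_e else 0
            sub_m += int(rng.binomial(alive_m_e, p_p)) if alive_m_e else 0

        sub_f = int(rng.binomial(nf_zyg, bg)) if bg < 1.0 else nf_zyg
        if sexing_mode == "phenotype":
            sub_f += fem_survivors
        else:
            sub_m += fem_survivors
        broods.append(
            BroodCounts(
                cross_id=cid,
                vial_id=f"{cid}-v{i + 1}",
                n_eggs=eggs if record_eggs else None,
                n_embryo_female=emb_f if census_embryo else None,
                n_embryo_male=emb_m if census_embryo else None,
                n_subadult_female=sub_f,
                n_subadult_male=sub_m,
            )
        )
    return broods


# ---------------------------------------------------------------------------
# The seven-cross screen design
# ---------------------------------------------------------------------------

SCREEN_CROSS_IDS = (
    "P0_SR",     # SR x SR, embryo + subadult census (E and F)
    "P0_EVEN",   # EVEN x EVEN control
    "step2a",    # Sire_EVEN x Dam_SR
    "step2b",    # Sire_SR x Dam_EVEN
    "step3a",    # X_SR Y_EVEN F1 sires x SR dams
    "step3b",    # X_SR Y_EVEN F1 sires x EVEN dams
    "step3c",    # X_EVEN Y_SR F1 sires x SR dams
)


@dataclass(frozen=True)
class CrossDesign:
    cross_id: str
    cross: CrossSpec
    n_vials: int = 40
    eggs_per_vial: FamilySizeModel = 150
    census_embryo: bool = False
    record_eggs: bool = False

    def __post_init__(self):
        if self.n_vials < 1:
            raise ValueError("vial counts must be >= 1")


@dataclass(frozen=True)
class DesignSpec:
    """A multi-cross census design with shared overdispersion ``rho``."""

    crosses: tuple
    rho: float = 0.01
    background_survival: float = 0.9
    sexing_mode: str = "phenotype"

    def __post_init__(self):
        object.__setattr__(self, "crosses", tuple(self.crosses))
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must lie in [0, 1), got {self.rho}")

    def cross_ids(self) -> tuple:
        return tuple(cd.cross_id for cd in self.crosses)


@dataclass(frozen=True)
class ScreenDataset:
    """Simulated screen inputs: per-vial counts plus the generating design."""

    broods: tuple
    design: DesignSpec
    seed: Optional[int] = None

    def __post_init__(self):
        object.__setattr__(self, "broods", tuple(self.broods))

    def broods_for(self, cross_id: str) -> list:
        return [b for b in self.broods if b.cross_id == cross_id]


def default_screen_design(
    sr_dam: Genotype,
    sr_sire: Genotype,
    even_dam: Genotype,
    even_sire: Genotype,
    *,
    n_vials: int = 40,
    eggs_per_vial: FamilySizeModel = 150,
    rho: float = 0.01,
    background_survival: float = 0.9,
) -> DesignSpec:
    """The seven-cross design, with F1 sire genotypes derived Mendelianly.

    The F1 sire of steps 3a/3b carries the SR-line X and the EVEN-line Y
    (son of an EVEN sire x SR dam); the step-3c sire carries the EVEN X and
    SR Y (son of the reciprocal cross).  Y follows the sire's line, the F1
    son's X follows the dam.

    Defaults emulate the study scale: 40 single-sire vials per cross culled
    to ~150 eggs each gives roughly 5,000-6,000 subadults per cross, matching
    the reported per-cross sample sizes (4,307-7,013); embryos are sexed only
    in the SR x SR cross, which is also the hatch-rate assay cross.
    """
    p0_sr = CrossSpec(sire=sr_sire, dam=sr_dam, label="P0_SR")
    p0_even = CrossSpec(sire=even_sire, dam=even_dam, label="P0_EVEN")
    c2a = CrossSpec(sire=even_sire, dam=sr_dam, label="step2a")
    c2b = CrossSpec(sire=sr_sire, dam=even_dam, label="step2b")
    f1_xsr_yeven = son_genotype(c2a)   # X from SR dam, Y from EVEN sire
    f1_xeven_ysr = son_genotype(c2b)   # X from EVEN dam, Y from SR sire
    crosses = (
        CrossDesign("P0_SR", p0_sr, n_vials, eggs_per_vial,
                    census_embryo=True, record_eggs=True),
        CrossDesign("P0_EVEN", p0_even, n_vials, eggs_per_vial),
        CrossDesign("step2a", c2a, n_vials, eggs_per_vial),
        CrossDesign("step2b", c2b, n_vials, eggs_per_vial),
        CrossDesign("step3a", CrossSpec(f1_xsr_yeven, sr_dam, "step3a"),
                    n_vials, eggs_per_vial),
        CrossDesign("step3b", CrossSpec(f1_xsr_yeven, even_dam, "step3b"),
                    n_vials, eggs_per_vial),
        CrossDesign("step3c", CrossSpec(f1_xeven_ysr, sr_dam, "step3c"),
                    n_vials, eggs_per_vial),
    )
    return DesignSpec(crosses=crosses, rho=rho, background_survival=background_survival)


def simulate_screen_dataset(
    params_sr: MechanismParams,
    params_even: MechanismParams = NEUTRAL_PARAMS,
    design: Optional[DesignSpec] = None,
    rng_seed: Optional[int] = None,
    *,
    sr_line_kwargs: Optional[Mapping] = None,
    even_line_kwargs: Optional[Mapping] = None,
) -> ScreenDataset:
    """Simulate the full seven-cross screen input table.

    ``params_sr`` / ``params_even`` hold the mechanism parameters attached to
    elements of SR-line and EVEN-line origin respectively; F1 and backcross
    parental genotypes are derived by Mendelian transmission from the line
    genotypes.  ``*_line_kwargs`` are forwarded to
    :func:`~sazdscreen.drive_model.line_genotypes` (infection status,
    suppressor placement, feminizer flags).
    """
    if design is None:
        sr_dam, sr_sire = line_genotypes("SR", driver=True, **dict(sr_line_kwargs or {}))
        even_dam, even_sire = line_genotypes(
            "EVEN", driver=True, **dict(even_line_kwargs or {})
        )
        design = default_screen_design(sr_dam, sr_sire, even_dam, even_sire)
    missing = [cid for cid in SCREEN_CROSS_IDS if cid not in design.cross_ids()]
    if missing:
        raise ValueError(f"design is missing required screen crosses: {missing}")
    params = {"SR": params_sr, "EVEN": params_even}
    rng = np.random.default_rng(rng_seed)
    broods = []
    for cd in design.crosses:
        broods.extend(
            simulate_cross(
                cd.cross,
                params,
                cd.n_vials,
                cd.eggs_per_vial,
                design.rho,
                rng,
                census_embryo=cd.census_embryo,
                record_eggs=cd.record_eggs,
                sexing_mode=design.sexing_mode,
                background_survival=design.background_survival,
                cross_id=cd.cross_id,
            )
        )
    return ScreenDataset(broods=tuple(broods), design=design, seed=rng_seed)


# ---------------------------------------------------------------------------
# Ground-truth scenarios for the screen
# ---------------------------------------------------------------------------

def _sc_neutral():
    return NEUTRAL_PARAMS, NEUTRAL_PARAMS, {}, {}


def _sc_sa_zd():
    # SD + SA-ZD at the strengths inferred for the focal line
    return (
        MechanismParams(s_Y=0.307, s_son_post=0.625),
        NEUTRAL_PARAMS,
        {},
        {},
    )


def _sc_sd_only():
    return MechanismParams(s_Y=0.307), NEUTRAL_PARAMS, {}, {}


def _sc_sk():
    # maternally transmitted endosymbiont kills sons of infected dams
    return (
        MechanismParams(sk_son_survival=0.3),
        NEUTRAL_PARAMS,
        {"infected": True},
        {},
    )


def _sc_viability():
    # recessive autosomal male killer in the focal line background
    return MechanismParams(v_male=0.5), NEUTRAL_PARAMS, {}, {}


def _sc_y_killer():
    # Y-linked (or Y-epistatic) male killer riding on the focal line's Y
    return (
        MechanismParams(v_male=0.3, v_male_scope="y_linked"),
        NEUTRAL_PARAMS,
        {},
        {},
    )


def _sc_sa_zd_suppressed_even():
    # SA-ZD present, but the EVEN line is fixed for a dominant autosomal
    # suppressor that rescues sons from the paternal effect: the documented
    # false-negative mode of the screen.
    sup = {"even_rescue": SuppressorSpec(frozenset({"s_son_post"}), site="offspring")}
    return (
        MechanismParams(s_son_post=0.4, suppressors=sup),
        NEUTRAL_PARAMS,
        {},
        {"autosome_suppressors": {"even_rescue": 1.0}},
    )


SCREEN_SCENARIOS = {
    "neutral": _sc_neutral,
    "sa-zd": _sc_sa_zd,
    "sd-only": _sc_sd_only,
    "sk": _sc_sk,
    "viability": _sc_viability,
    "y-killer": _sc_y_killer,
    "sa-zd-suppressed-even": _sc_sa_zd_suppressed_even,
}


def screen_scenario(name: str) -> tuple:
    """(params_SR, params_EVEN, sr_line_kwargs, even_line_kwargs) for a named ground truth."""
    try:
        return SCREEN_SCENARIOS[name]()
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; choose from {sorted(SCREEN_SCENARIOS)}"
        ) from None


# ---------------------------------------------------------------------------
# Recombination assay
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SireFamily:
    """Primary family of one G2 sire, plus any grandson follow-up families.

    ``true_drivers`` is simulation ground truth ("SR", "Paris", both, or
    neither); ``grandson_families`` is a tuple of (n_female, n_male) pairs,
    present only for sires whose primary family was not significantly
    female-biased.
    """

    sire_id: str
    n_female: int
    n_male: int
    true_drivers: tuple = ()
    grandson_families: Optional[tuple] = None

    def __post_init__(self):
        if self.n_female < 0 or self.n_male < 0:
            raise ValueError("family counts must be >= 0")
        object.__setattr__(self, "true_drivers", tuple(self.true_drivers))
        if self.grandson_families is not None:
            object.__setattr__(
                self, "grandson_families", tuple(map(tuple, self.grandson_families))
            )

    @property
    def n_total(self) -> int:
        return self.n_female + self.n_male


@dataclass(frozen=True)
class LinkageAssayData:
    sires: tuple
    alpha: float = 0.05
    n_grandsons: int = 10
    seed: Optional[int] = None

    def __post_init__(self):
        object.__setattr__(self, "sires", tuple(self.sires))


def _family_significant(nf: int, n: int, alpha: float) -> bool:
    if n == 0:
        return False
    return stats.binomtest(nf, n, 0.5, alternative="greater").pvalue < alpha


def simulate_recombination_assay(
    r: float,
    penetrance: float = 0.9,
    n_sires: int = 400,
    dams_per_sire: int = 2,
    family_size_model: FamilySizeModel = 80,
    n_grandsons: int = 10,
    rng_seed: Optional[int] = None,
    *,
    s_y_sr: float = 0.307,
    s_y_paris: float = 0.218,
    alpha: float = 0.05,
    p_sterile: float = 0.0,
) -> LinkageAssayData:
    """Simulate the two-driver recombination test.

    G2 sires descend from dams heterozygous for two X-linked drivers in
    repulsion; with recombination fraction ``r`` a sire carries one driver
    with probability (1-r)/2 each, both with probability r/2, and neither
    with probability r/2.  Each sire's family sex ratio is drawn given his
    carrier status and (per-sire) drive expression; sires whose family is
    not significantly female-biased by a one-sided exact binomial test at
    ``alpha`` receive a grandson follow-up in which each of ``n_grandsons``
    grandsons carries the sire's X with probability 1/2.
    """
    if not 0.0 <= r <= 0.5:
        raise ValueError(f"recombination fraction must lie in [0, 0.5], got {r}")
    if n_sires < 1 or dams_per_sire < 1 or n_grandsons < 0:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(rng_seed)

    classes = [("SR",), ("Paris",), ("SR", "Paris"), ()]
    probs = [(1 - r) / 2, (1 - r) / 2, r / 2, r / 2]
    driver_s = {("SR",): s_y_sr, ("Paris",): s_y_paris,
                ("SR", "Paris"): s_y_sr * s_y_paris, (): 1.0}

    def family_counts(drivers: tuple) -> tuple:
        total = sum(
            _draw_family_size(family_size_model, rng) for _ in range(dams_per_sire)
        )
        expressed = bool(drivers) and rng.random() < penetrance
        s = driver_s[drivers] if expressed else 1.0
        pf = 1.0 / (1.0 + s)
        nf = int(rng.binomial(total, pf)) if total else 0
        return nf, total - nf

    sires = []
    class_draws = rng.choice(len(classes), size=n_sires, p=probs)
    for i, ci in enumerate(class_draws):
        drivers = classes[ci]
        if p_sterile > 0 and rng.random() < p_sterile:
            nf = nm = 0
        else:
            nf, nm = family_counts(drivers)
        grandsons = None
        if not _family_significant(nf, nf + nm, alpha):
            gf = []
            for _ in range(n_grandsons):
                carrier = bool(drivers) and rng.random() < 0.5
                gf.append(family_counts(drivers if carrier else ()))
            grandsons = tuple(gf)
        sires.append(
            SireFamily(
                sire_id=f"G2-{i + 1}",
                n_female=nf,
                n_male=nm,
                true_drivers=drivers,
                grandson_families=grandsons,
            )
        )
    return LinkageAssayData(
        sires=tuple(sires), alpha=alpha, n_grandsons=n_grandsons, seed=rng_seed
    )
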