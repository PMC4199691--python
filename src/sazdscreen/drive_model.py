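"""Genotypes, crosses, and closed-form sex-ratio expectations.

This module holds the quantitative model of every etiology a female-biased
brood sex ratio can have in an XY system:

* **SD** (X-linked segregation distortion / meiotic drive): a driver on the
  sire's X kills or incapacitates Y-bearing sperm, so the zygotic sex ratio
  is already biased at syngamy.  Parameterized by ``s_Y``, the survival /
  functionality of Y-bearing sperm relative to X-bearing sperm.
* **SA-ZD** (sexually antagonistic zygotic drive): a paternal effect of the
  sire's X that kills sons *after* fertilization.  Split into an
  embryo-stage component ``s_son_embryo`` (acting before embryos are sexed)
  and a post-embryo component ``s_son_post`` (embryo census to subadult).
* **SK** (endosymbiont son-killing): sons of infected dams die, with
  maternal transmission probability ``sk_transmission``.
* **Viability**: offspring-genotype-determined male viability ``v_male``,
  either recessive to the focal line's autosomal background or Y-linked.
* **Feminization** of XY zygotes by cytoplasmic, X-linked or Y-linked
  factors, and endosymbiont-induced **asexual** production of daughters.

The closed forms here are the oracle for the forward simulator in
:mod:`sazdscreen.synthetic_data`: with overdispersion 0 and large counts the
simulated stage-wise percent-female converges to these expectations.

Relative-survival convention: daughters are the reference class (survival 1),
so every mechanism parameter is the survival of the affected class *relative
to* its sisters.  A multiplicative composition of mechanisms on male
survival is assumed throughout; SD acts first (on sperm), then embryo-stage
mortality, then post-embryo mortality — so SD and SA-ZD compose as
``s_Y * s_son_post`` on the male path, acting sequentially on an already
diminished pool of male zygotes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

__all__ = [
    "SuppressorSpec",
    "MechanismParams",
    "NEUTRAL_PARAMS",
    "XAllele",
    "YChrom",
    "Cytoplasm",
    "Genotype",
    "CrossSpec",
    "line_genotypes",
    "son_genotype",
    "daughter_genotype",
    "expected_embryo_pf",
    "expected_subadult_pf",
]

#: mechanism parameters a suppressor is allowed to restore to neutrality
RESTORABLE_PARAMS = frozenset(
    {"s_Y", "s_son_embryo", "s_son_post", "v_male", "sk_son_survival"}
)

_SITES = ("sire", "offspring")


@dataclass(frozen=True)
class SuppressorSpec:
    """Scope of a named suppressor allele.

    ``restores`` names the mechanism parameters that are reset to their
    neutral value (1) when the suppressor is present; ``site`` says where it
    must be present to act — in the sire (e.g. an autosomal dominant
    suppressor of sperm killing, or a Y that silences the driver in the
    sire's germline) or in the affected offspring (e.g. a Y that rescues
    sons from endosymbiont killing).
    """

    restores: frozenset
    site: str = "sire"

    def __post_init__(self):
        restores = frozenset(self.restores)
        object.__setattr__(self, "restores", restores)
        if not restores <= RESTORABLE_PARAMS:
            raise ValueError(
                f"unknown restorable parameter(s): {sorted(restores - RESTORABLE_PARAMS)}"
            )
        if self.site not in _SITES:
            raise ValueError(f"suppressor site must be one of {_SITES}, got {self.site!r}")


def _check_unit(name: str, value: float, lo: float = 0.0, hi: float = 1.0) -> None:
    if not (lo <= value <= hi):
        raise ValueError(f"{name} must lie in [{lo}, {hi}], got {value}")


@dataclass(frozen=True)
class MechanismParams:
    """Quantitative switches for each sex-ratio-distorting etiology.

    All survivals are relative to sisters, in [0, 1]; 1 everywhere (with
    feminization/asexuality probabilities 0 and penetrance 1) is the neutral
    configuration under which every cross yields exactly 50 percent female.

    Parameters
    ----------
    s_Y
        Relative survival/functionality of Y-bearing sperm from a
        driver-carrying, drive-expressing sire (1 = no SD).
    s_son_embryo
        Paternal-effect relative survival of sons up to the stage at which
        embryos are sexed.
    s_son_post
        Paternal-effect relative survival of sons from the embryo census to
        the subadult census — the SA-ZD component.
    v_male
        Constitutive (offspring-genotype-determined) male relative
        viability, acting post-embryo.
    v_male_scope
        ``"autosome_recessive"``: ``v_male`` applies to sons whose autosomal
        complement derives entirely from the focal line (recessive male
        killer). ``"y_linked"``: applies to sons whose Y comes from the line
        these parameters describe.
    sk_son_survival
        Endosymbiont-induced relative survival of infected sons (post-embryo).
    sk_transmission
        Maternal transmission probability of the endosymbiont.
    p_fem_cyto, p_fem_x, p_fem_y
        Probabilities that an XY zygote develops as a phenotypic female
        under cytoplasmic (requires infection), X-linked or Y-linked
        feminization (require the feminizer flag on the relevant chromosome).
    asex_fraction
        Fraction of an infected dam's offspring produced asexually, all
        daughters.
    penetrance
        Probability that a driver-carrying sire expresses drive at all.
        Resolved once per sire: a sire either expresses fully or is inert.
    suppressors
        Registry mapping suppressor name -> :class:`SuppressorSpec`.
        Genotypes carry suppressor *names*; the registry defines their scope.
    """

    s_Y: float = 1.0
    s_son_embryo: float = 1.0
    s_son_post: float = 1.0
    v_male: float = 1.0
    v_male_scope: str = "autosome_recessive"
    sk_son_survival: float = 1.0
    sk_transmission: float = 1.0
    p_fem_cyto: float = 0.0
    p_fem_x: float = 0.0
    p_fem_y: float = 0.0
    asex_fraction: float = 0.0
    penetrance: float = 1.0
    suppressors: Mapping[str, SuppressorSpec] = field(default_factory=dict)

    def __post_init__(self):
        for name in (
            "s_Y",
            "s_son_embryo",
            "s_son_post",
            "v_male",
            "sk_son_survival",
            "sk_transmission",
            "p_fem_cyto",
            "p_fem_x",
            "p_fem_y",
            "asex_fraction",
            "penetrance",
        ):
            _check_unit(name, getattr(self, name))
        if self.v_male_scope not in ("autosome_recessive", "y_linked"):
            raise ValueError(f"invalid v_male_scope {self.v_male_scope!r}")
        object.__setattr__(self, "suppressors", dict(self.suppressors))

    @property
    def is_neutral(self) -> bool:
        return (
            self.s_Y == self.s_son_embryo == self.s_son_post == 1.0
            and self.v_male == self.sk_son_survival == 1.0
            and self.p_fem_cyto == self.p_fem_x == self.p_fem_y == 0.0
            and self.asex_fraction == 0.0
        )


NEUTRAL_PARAMS = MechanismParams()

# params may be a single MechanismParams (applied to every lineage origin) or
# a mapping origin-tag -> MechanismParams, as used by the screen simulator
# where the SR and EVEN lines carry distinct etiologies.
ParamsLike = Union[MechanismParams, Mapping[str, MechanismParams]]


def _resolve(params: ParamsLike, origin: str) -> MechanismParams:
    if isinstance(params, MechanismParams):
        return params
    return params.get(origin, NEUTRAL_PARAMS)


def _suppressor_registry(params: ParamsLike) -> Mapping[str, SuppressorSpec]:
    if isinstance(params, MechanismParams):
        return params.suppressors
    merged: dict = {}
    for p in params.values():
        merged.update(p.suppressors)
    return merged


# ---------------------------------------------------------------------------
# Genotypes and crosses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class XAllele:
    """One X chromosome: driver flag, line-of-origin tag, optional riders."""

    origin: str = "SR"
    driver: bool = False
    feminizer: bool = False
    suppressors: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "suppressors", frozenset(self.suppressors))


@dataclass(frozen=True)
class YChrom:
    origin: str = "SR"
    feminizer: bool = False
    suppressors: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "suppressors", frozenset(self.suppressors))


@dataclass(frozen=True)
class Cytoplasm:
    origin: str = "SR"
    infected: bool = False


@dataclass(frozen=True)
class Genotype:
    """X/Y/autosome/cytoplasm composition of an individual or line.

    ``autosome_dose_sr`` is the fraction of the autosomal complement derived
    from the focal (SR) line; for the crosses used it takes values in
    {0, 1/2, 3/4, 1}.  ``autosome_suppressors`` maps suppressor name to the
    gamete transmission probability of that allele (1 = fixed/homozygous,
    0.5 = heterozygous).

    A compound-X individual (``compound_x=True``) carries a joined double-X
    plus a Y and is phenotypically female; such dams transmit the double-X
    to daughters and their Y to sons, so sons take their X from the sire.
    """

    x_alleles: tuple = ()
    y: Optional[YChrom] = None
    compound_x: bool = False
    autosome_dose_sr: float = 0.0
    autosome_suppressors: Mapping[str, float] = field(default_factory=dict)
    cytoplasm: Cytoplasm = field(default_factory=Cytoplasm)

    def __post_init__(self):
        object.__setattr__(self, "x_alleles", tuple(self.x_alleles))
        object.__setattr__(self, "autosome_suppressors", dict(self.autosome_suppressors))
        _check_unit("autosome_dose_sr", self.autosome_dose_sr)
        for name, g in self.autosome_suppressors.items():
            _check_unit(f"autosome_suppressors[{name!r}]", g)
        if self.compound_x:
            if len(self.x_alleles) != 2 or self.y is None:
                raise ValueError("compound-X genotype must carry a double-X and a Y")

    @property
    def is_female(self) -> bool:
        if self.compound_x:
            return True
        return len(self.x_alleles) == 2 and self.y is None

    @property
    def is_male(self) -> bool:
        return not self.compound_x and len(self.x_alleles) == 1 and self.y is not None

    def driver_x(self) -> Optional[XAllele]:
        for x in self.x_alleles:
            if x.driver:
                return x
        return None

    def carried_suppressors(self) -> frozenset:
        """Names of all suppressors this individual carries anywhere."""
        names = set()
        for x in self.x_alleles:
            names |= x.suppressors
        if self.y is not None:
            names |= self.y.suppressors
        names |= {n for n, g in self.autosome_suppressors.items() if g > 0}
        return frozenset(names)


@dataclass(frozen=True)
class CrossSpec:
    """A single mating: phenotypically male sire x phenotypically female dam."""

    sire: Genotype
    dam: Genotype
    label: str = ""

    def __post_init__(self):
        if not self.sire.is_male:
            raise ValueError(f"cross {self.label!r}: sire is not phenotypically male")
        if not self.dam.is_female:
            raise ValueError(f"cross {self.label!r}: dam is not phenotypically female")
        if not self.sire.x_alleles:
            raise ValueError(f"cross {self.label!r}: sire carries no X")


def line_genotypes(
    origin: str,
    *,
    driver: bool = False,
    infected: bool = False,
    x_feminizer: bool = False,
    y_feminizer: bool = False,
    x_suppressors: Sequence[str] = (),
    y_suppressors: Sequence[str] = (),
    autosome_suppressors: Optional[Mapping[str, float]] = None,
) -> tuple:
    """Build the (dam, sire) genotypes of an inbred line.

    The line is homozygous: both dam X's are identical, autosomal suppressor
    alleles are fixed (gamete probability 1) unless stated otherwise, and
    ``autosome_dose_sr`` is 1 for the ``"SR"`` line and 0 otherwise.
    """
    x = XAllele(
        origin=origin,
        driver=driver,
        feminizer=x_feminizer,
        suppressors=frozenset(x_suppressors),
    )
    y = YChrom(origin=origin, feminizer=y_feminizer, suppressors=frozenset(y_suppressors))
    cyto = Cytoplasm(origin=origin, infected=infected)
    dose = 1.0 if origin == "SR" else 0.0
    asup = dict(autosome_suppressors or {})
    dam = Genotype(
        x_alleles=(x, x),
        autosome_dose_sr=dose,
        autosome_suppressors=asup,
        cytoplasm=cyto,
    )
    sire = Genotype(
        x_alleles=(x,),
        y=y,
        autosome_dose_sr=dose,
        autosome_suppressors=asup,
        cytoplasm=cyto,
    )
    return dam, sire


def _merged_autosomes(cross: CrossSpec) -> tuple:
    dose = (cross.sire.autosome_dose_sr + cross.dam.autosome_dose_sr) / 2.0
    sups: dict = {}
    for name in set(cross.sire.autosome_suppressors) | set(cross.dam.autosome_suppressors):
        gs = cross.sire.autosome_suppressors.get(name, 0.0)
        gd = cross.dam.autosome_suppressors.get(name, 0.0)
        # expected gamete frequency of the allele in the offspring
        sups[name] = (gs + gd) / 2.0
    return dose, sups


def son_genotype(cross: CrossSpec) -> Genotype:
    """Genotype of a son of this cross (dam assumed X-homozygous).

    With a standard dam, sons take an X from the dam and the Y from the
    sire; with a compound-X dam the transmission is reversed (X from sire,
    Y from dam).  Autosomal doses are expected values; the cytoplasm follows
    the dam.
    """
    dose, sups = _merged_autosomes(cross)
    if cross.dam.compound_x:
        x = cross.sire.x_alleles[0]
        y = cross.dam.y
    else:
        xs = set(cross.dam.x_alleles)
        if len(xs) > 1:
            raise ValueError("dam is X-heterozygous; son X is not deterministic")
        x = cross.dam.x_alleles[0]
        y = cross.sire.y
    return Genotype(
        x_alleles=(x,),
        y=y,
        autosome_dose_sr=dose,
        autosome_suppressors=sups,
        cytoplasm=cross.dam.cytoplasm,
    )


def daughter_genotype(cross: CrossSpec) -> Genotype:
    """Genotype of a daughter; compound-X dams pass the double-X plus the sire's Y."""
    dose, sups = _merged_autosomes(cross)
    if cross.dam.compound_x:
        return Genotype(
            x_alleles=cross.dam.x_alleles,
            y=cross.sire.y,
            compound_x=True,
            autosome_dose_sr=dose,
            autosome_suppressors=sups,
            cytoplasm=cross.dam.cytoplasm,
        )
    xs = set(cross.dam.x_alleles)
    if len(xs) > 1:
        raise ValueError("dam is X-heterozygous; daughter X is not deterministic")
    return Genotype(
        x_alleles=(cross.dam.x_alleles[0], cross.sire.x_alleles[0]),
        autosome_dose_sr=dose,
        autosome_suppressors=sups,
        cytoplasm=cross.dam.cytoplasm,
    )


# ---------------------------------------------------------------------------
# Closed-form expectations
# ---------------------------------------------------------------------------


def _sire_restored(params: ParamsLike, cross: CrossSpec) -> frozenset:
    """Parameters restored to neutrality by sire-site suppressors the sire carries."""
    registry = _suppressor_registry(params)
    restored = set()
    for name in cross.sire.carried_suppressors():
        spec = registry.get(name)
        if spec is not None and spec.site == "sire":
            restored |= spec.restores
    return frozenset(restored)


def _offspring_suppressor_probs(params: ParamsLike, cross: CrossSpec) -> dict:
    """Carrier probability per offspring-site suppressor for a son of this cross."""
    registry = _suppressor_registry(params)
    probs: dict = {}
    if cross.dam.compound_x:
        son_x_source = cross.sire.x_alleles
        son_y = cross.dam.y
    else:
        son_x_source = cross.dam.x_alleles
        son_y = cross.sire.y
    for name, spec in registry.items():
        if spec.site != "offspring":
            continue
        p_not = 1.0
        frac_x = sum(name in x.suppressors for x in son_x_source) / len(son_x_source)
        p_not *= 1.0 - frac_x
        if son_y is not None and name in son_y.suppressors:
            p_not = 0.0
        gs = cross.sire.autosome_suppressors.get(name, 0.0)
        gd = cross.dam.autosome_suppressors.get(name, 0.0)
        p_not *= (1.0 - gs) * (1.0 - gd)
        p = 1.0 - p_not
        if p > 0.0:
            probs[name] = p
    return probs


def syngamy_female_share(params: ParamsLike, cross: CrossSpec, expressed: bool) -> float:
    """P(zygote is female at syngamy), including asexual daughters.

    Sperm-killing (``s_Y``) biases the sexual zygote pool; an infected dam
    additionally contributes a fraction ``asex_fraction`` of asexually
    produced daughters.
    """
    drv = cross.sire.driver_x()
    s_y = 1.0
    if drv is not None and expressed:
        p = _resolve(params, drv.origin)
        if "s_Y" not in _sire_restored(params, cross):
            s_y = p.s_Y
    p_dam = _resolve(params, cross.dam.cytoplasm.origin)
    a = p_dam.asex_fraction if cross.dam.cytoplasm.infected else 0.0
    sexual_female = 0.5 / (0.5 + 0.5 * s_y)
    return a + (1.0 - a) * sexual_female


def male_fate_components(
    params: ParamsLike, cross: CrossSpec, expressed: bool
) -> list:
    """Fate classes for a male (XY) zygote of this cross.

    Returns a list of ``(prob, s_embryo, s_post, p_fem)`` tuples: with
    probability ``prob`` a son falls in a class whose survival to the embryo
    census is ``s_embryo``, whose survival from embryo census to subadult is
    ``s_post`` (paternal effect x viability x endosymbiont killing), and
    whose probability of developing as a phenotypic female is ``p_fem``.
    Classes enumerate offspring-site suppressor carriage and endosymbiont
    infection, which is why survivals and feminization can covary.
    """
    drv = cross.sire.driver_x()
    sire_restored = _sire_restored(params, cross)
    p_drv = _resolve(params, drv.origin) if drv is not None else NEUTRAL_PARAMS
    registry = _suppressor_registry(params)

    # son's sex chromosomes
    if cross.dam.compound_x:
        son_x_source = cross.sire.x_alleles
        son_y = cross.dam.y
    else:
        son_x_source = cross.dam.x_alleles
        son_y = cross.sire.y

    # constitutive viability
    dose = (cross.sire.autosome_dose_sr + cross.dam.autosome_dose_sr) / 2.0
    v = 1.0
    p_sr = _resolve(params, "SR")
    if p_sr.v_male < 1.0 and p_sr.v_male_scope == "autosome_recessive" and dose >= 1.0 - 1e-9:
        v *= p_sr.v_male
    if son_y is not None:
        p_yv = _resolve(params, son_y.origin)
        if p_yv.v_male < 1.0 and p_yv.v_male_scope == "y_linked":
            v *= p_yv.v_male

    # endosymbiont exposure
    p_dam = _resolve(params, cross.dam.cytoplasm.origin)
    t_inf = p_dam.sk_transmission if cross.dam.cytoplasm.infected else 0.0

    # feminization channels independent of infection
    frac_fem_x = sum(x.feminizer for x in son_x_source) / len(son_x_source)
    p_x_fem = frac_fem_x * _resolve(params, son_x_source[0].origin).p_fem_x
    p_y_fem = 0.0
    if son_y is not None and son_y.feminizer:
        p_y_fem = _resolve(params, son_y.origin).p_fem_y

    sup_probs = _offspring_suppressor_probs(params, cross)
    sup_names = sorted(sup_probs)

    components = []
    for carried in itertools.product(
        *([(True, False)] * len(sup_names)), (True, False)
    ):
        *carry_flags, infected = carried
        prob = t_inf if infected else 1.0 - t_inf
        restored = set(sire_restored)
        for name, flag in zip(sup_names, carry_flags):
            prob *= sup_probs[name] if flag else 1.0 - sup_probs[name]
            if flag:
                restored |= registry[name].restores
        if prob == 0.0:
            continue

        active = drv is not None and expressed
        s_e = p_drv.s_son_embryo if active and "s_son_embryo" not in restored else 1.0
        s_p = p_drv.s_son_post if active and "s_son_post" not in restored else 1.0
        v_eff = 1.0 if "v_male" in restored else v
        sk = 1.0
        if infected and "sk_son_survival" not in restored:
            sk = p_dam.sk_son_survival
        p_c_fem = p_dam.p_fem_cyto if infected else 0.0
        p_fem = 1.0 - (1.0 - p_c_fem) * (1.0 - p_x_fem) * (1.0 - p_y_fem)
        components.append((prob, s_e, s_p * v_eff * sk, p_fem))
    return components


def expression_states(params: ParamsLike, cross: CrossSpec) -> list:
    """(weight, expressed) pairs for the sire's drive-expression state."""
    drv = cross.sire.driver_x()
    if drv is None:
        return [(1.0, False)]
    pen = _resolve(params, drv.origin).penetrance
    states = []
    if pen > 0:
        states.append((pen, True))
    if pen < 1:
        states.append((1.0 - pen, False))
    return states


def _expected_pf(
    params: ParamsLike, cross: CrossSpec, stage: str, sexing_mode: str
) -> float:
    if sexing_mode not in ("phenotype", "karyotype"):
        raise ValueError(f"sexing_mode must be 'phenotype' or 'karyotype', got {sexing_mode!r}")
    f_total = 0.0
    m_total = 0.0
    for w, expressed in expression_states(params, cross):
        f_share = syngamy_female_share(params, cross, expressed)
        m_share = 1.0 - f_share
        f_w = f_share
        m_w = 0.0
        for prob, s_e, s_post, p_fem in male_fate_components(params, cross, expressed):
            surv = s_e if stage == "embryo" else s_e * s_post
            alive = m_share * prob * surv
            if sexing_mode == "phenotype":
                f_w += alive * p_fem
                m_w += alive * (1.0 - p_fem)
            else:
                m_w += alive
        f_total += w * f_w
        m_total += w * m_w
    return 100.0 * f_total / (f_total + m_total)


def expected_embryo_pf(
    params: ParamsLike, cross: CrossSpec, sexing_mode: str = "phenotype"
) -> float:
    """Exact expectation of percent-female among sexed embryos.

    The female share is 0.5 of sexual zygotes plus any asexual daughters;
    the male share is ``0.5 * s_Y * s_son_embryo`` with suppressors applied
    before survivals.  Feminized XY embryos count as female when sexing is
    phenotype-based and as male when karyotype-based.
    """
    return _expected_pf(params, cross, "embryo", sexing_mode)


def expected_subadult_pf(
    params: ParamsLike, cross: CrossSpec, sexing_mode: str = "phenotype"
) -> float:
    """Exact expectation of percent-female at the subadult census.

    Returns ``100 * f / (f + m)`` with
    ``m = 0.5 * s_Y * s_son_embryo * s_son_post * v_male * (SK term if the
    dam is infected)`` — the sequential composition of sperm killing and
    zygotic mortality on the male path.
    """
    return _expected_pf(params, cross, "subadult", sexing_mode)
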