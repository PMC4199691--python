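"""The six-step dichotomous decision key for diagnosing SA-ZD.

The key works by process of elimination over seven crosses between a
female-biased focal line (SR) and an even-sex-ratio control line (EVEN):

1. Compare embryo (E) and subadult (F) percent-female in SR x SR.  No
   significant rise means no post-embryonic male-specific mortality — the
   bias is attributable to sperm killing (SD) and/or asexual daughters.
   Otherwise compute the post-embryonic male survival and the percent-female
   it alone would predict.
2a. Sire_EVEN x Dam_SR: a strongly female-biased brood implicates maternal
   transmission (endosymbiont son-killing or cytoplasmic feminization).
2b. Sire_SR x Dam_EVEN: collapse toward 50 implicates recessive autosomal
   male killers exposed by outcrossing.
3a. X_SR Y_EVEN F1 sires x SR dams: collapse implicates son-killing
   suppressed by the EVEN Y.
3b. The same F1 sires on EVEN dams must stay near F, else the EVEN line
   hides a latent distorter.
3c. X_EVEN Y_SR F1 sires x SR dams: a strong bias implicates the SR Y
   (Y-linked or Y-epistatic killing, or sex-chromosome feminization).

Navigating every step rightward leaves paternal-effect son killing by the
sire's X — SA-ZD — as the only remaining explanation for the post-embryonic
component.  "Much greater" / "much less" comparisons require both
statistical significance (confidence-interval exclusion) and that most of
the maximum possible deviation is realized (fraction > ``tau``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .estimators import (
    ProportionEstimate,
    SexRatioEstimate,
    egg_to_subadult_survival,
    mortality_sufficiency,
    predicted_pf,
    sex_ratio_ci,
    survival_m_rel_f,
    survival_Y_rel_X,
)
from .synthetic_data import BroodCounts, SCREEN_CROSS_IDS

__all__ = [
    "Verdict",
    "ScreenConfig",
    "ScreenInputs",
    "StepRecord",
    "ScreenResult",
    "run_screen",
    "screen_inputs_from_broods",
]


class Verdict:
    """Terminal verdicts of the decision key."""

    SD_OR_CYTO_ASEX_ONLY = "SD-or-CYTO-ASEX-only"
    SK_OR_CYTO_FEM = "SK-or-CYTO-FEM"
    AUTOSOMAL_RECESSIVE_MALE_KILLING = "autosomal-recessive-male-killing"
    SK_SUPPRESSED_BY_Y_EVEN = "SK-suppressed-by-Y_EVEN"
    LATENT_EVEN_DISTORTER = "latent-EVEN-distorter"
    Y_SR_OR_EPISTATIC = "Y_SR-or-epistatic-male-killing-or-sex-chromosome-FEM"
    SA_ZD_PRESENT = "SA-ZD-present"
    INCOMPLETE = "incomplete"


@dataclass(frozen=True)
class ScreenConfig:
    """Decision thresholds for the key.

    ``tau`` is the fraction of the maximum possible deviation that must be
    realized for a ">>" or "<<" comparison to hold (a "most of the
    deviation" rule); ``alpha`` is carried by the estimates' intervals and
    recorded here for the report; ``sexing_mode`` notes whether embryo
    sexing was phenotype- or karyotype-based, which governs which
    feminization etiologies fold into which exits.
    """

    tau: float = 0.5
    alpha: float = 0.05
    sexing_mode: str = "phenotype"

    def __post_init__(self):
        if not 0.0 < self.tau < 1.0:
            raise ValueError(f"tau must lie in (0, 1), got {self.tau}")
        if not 0.0 < self.alpha < 0.5:
            raise ValueError(f"alpha must lie in (0, 0.5), got {self.alpha}")
        if self.sexing_mode not in ("phenotype", "karyotype"):
            raise ValueError(f"invalid sexing_mode {self.sexing_mode!r}")


@dataclass(frozen=True)
class ScreenInputs:
    """Per-cross percent-female estimates feeding the key.

    ``e`` and ``f`` (SR x SR embryos and subadults) are required; any absent
    later step terminates the screen with an ``incomplete`` verdict naming
    the missing cross.  ``total_survival`` optionally carries the
    egg-to-subadult hatch-rate estimate for the mortality-sufficiency check.
    """

    e: SexRatioEstimate
    f: SexRatioEstimate
    control: Optional[SexRatioEstimate] = None
    step2a: Optional[SexRatioEstimate] = None
    step2b: Optional[SexRatioEstimate] = None
    step3a: Optional[SexRatioEstimate] = None
    step3b: Optional[SexRatioEstimate] = None
    step3c: Optional[SexRatioEstimate] = None
    total_survival: Optional[ProportionEstimate] = None


@dataclass(frozen=True)
class StepRecord:
    step: str
    comparison: str
    numbers: dict
    outcome: str  # "left-exit" | "pass" | "missing"


@dataclass(frozen=True)
class ScreenResult:
    verdict: str
    has_sd_component: bool
    trail: tuple
    survival_m_rel_f: Optional[float] = None
    survival_y_rel_x: Optional[float] = None
    predicted_pf: Optional[float] = None
    mortality_verdict: Optional[str] = None
    config: ScreenConfig = field(default_factory=ScreenConfig)

    def __post_init__(self):
        object.__setattr__(self, "trail", tuple(self.trail))


def _sig_above(est: SexRatioEstimate, value: float) -> bool:
    return est.ci_low > value


def _much_greater_than_50(est: SexRatioEstimate, scale_top: float, tau: float) -> bool:
    """">> 50": significantly above 50 and most of the way to ``scale_top``."""
    if scale_top <= 50.0:
        return False
    frac = (est.pf - 50.0) / (scale_top - 50.0)
    return _sig_above(est, 50.0) and frac > tau


def _much_less_than_f(
    est: SexRatioEstimate, f: SexRatioEstimate, tau: float
) -> bool:
    """"<< F": significantly below F and most of the possible drop (F - 50) realized."""
    if f.pf <= 50.0:
        return False
    significant = est.ci_high < f.ci_low
    frac = (f.pf - est.pf) / (f.pf - 50.0)
    return significant and frac > tau


def run_screen(inputs: ScreenInputs, config: ScreenConfig = ScreenConfig()) -> ScreenResult:
    """Navigate the decision key over the supplied estimates.

    Steps are evaluated in the key's fixed order; the first leftward exit
    terminates the screen with the corresponding verdict.  The trail records
    every evaluated step exactly once with the numbers compared.
    ``has_sd_component`` is set iff the embryo interval excludes 50 from
    above — independent evidence that sperm killing contributes.
    """
    e, f = inputs.e, inputs.f
    trail = []
    has_sd = e.ci_low > 50.0

    def result(verdict, **kw):
        return ScreenResult(
            verdict=verdict, has_sd_component=has_sd, trail=tuple(trail),
            config=config, **kw,
        )

    s_yx = survival_Y_rel_X(e.pf) if 50.0 <= e.pf < 100.0 else None

    # Step 1: F significantly greater than E?
    step1_pass = f.ci_low > e.ci_high
    trail.append(
        StepRecord(
            step="1",
            comparison="F significantly > E (CI separation)",
            numbers={
                "E": e.pf, "E_ci": (e.ci_low, e.ci_high),
                "F": f.pf, "F_ci": (f.ci_low, f.ci_high),
            },
            outcome="pass" if step1_pass else "left-exit",
        )
    )
    if not step1_pass:
        return result(Verdict.SD_OR_CYTO_ASEX_ONLY, survival_y_rel_x=s_yx)

    s_mf = survival_m_rel_f(e.pf, f.pf)
    pred = predicted_pf(s_mf)
    derived = dict(survival_m_rel_f=s_mf, survival_y_rel_x=s_yx, predicted_pf=pred)

    mort = None
    if inputs.total_survival is not None:
        mort = mortality_sufficiency(f, inputs.total_survival.ci_low)
        derived["mortality_verdict"] = mort

    steps = (
        ("2a", inputs.step2a, "much-greater-50", pred, Verdict.SK_OR_CYTO_FEM),
        ("2b", inputs.step2b, "much-less-F", None, Verdict.AUTOSOMAL_RECESSIVE_MALE_KILLING),
        ("3a", inputs.step3a, "much-less-F", None, Verdict.SK_SUPPRESSED_BY_Y_EVEN),
        ("3b", inputs.step3b, "much-less-F", None, Verdict.LATENT_EVEN_DISTORTER),
        ("3c", inputs.step3c, "much-greater-50", f.pf, Verdict.Y_SR_OR_EPISTATIC),
    )
    for step_id, est, kind, scale_top, exit_verdict in steps:
        if est is None:
            trail.append(
                StepRecord(
                    step=step_id,
                    comparison="(estimate missing)",
                    numbers={"missing_cross": f"step{step_id}"},
                    outcome="missing",
                )
            )
            return result(Verdict.INCOMPLETE, **derived)
        if kind == "much-greater-50":
            hit = _much_greater_than_50(est, scale_top, config.tau)
            comparison = f">> 50 toward {scale_top:.1f} (tau={config.tau})"
            numbers = {
                "pf": est.pf, "ci": (est.ci_low, est.ci_high),
                "scale_top": scale_top,
                "deviation_fraction": (est.pf - 50.0) / (scale_top - 50.0)
                if scale_top > 50 else float("nan"),
            }
        else:
            hit = _much_less_than_f(est, f, config.tau)
            comparison = f"<< F={f.pf:.1f} (tau={config.tau})"
            numbers = {
                "pf": est.pf, "ci": (est.ci_low, est.ci_high), "F": f.pf,
                "deviation_fraction": (f.pf - est.pf) / (f.pf - 50.0)
                if f.pf > 50 else float("nan"),
            }
        trail.append(
            StepRecord(
                step=step_id,
                comparison=comparison,
                numbers=numbers,
                outcome="left-exit" if hit else "pass",
            )
        )
        if hit:
            return result(exit_verdict, **derived)

    return result(Verdict.SA_ZD_PRESENT, **derived)


def screen_inputs_from_broods(
    broods: Sequence[BroodCounts], alpha: float = 0.05
) -> ScreenInputs:
    """Build ScreenInputs from a brood table using the canonical cross ids.

    Expects the seven-cross schema of the screen design (``P0_SR`` with
    embryo and subadult censuses, ``P0_EVEN``, ``step2a`` ... ``step3c``);
    crosses absent from the table yield ``None`` estimates and an eventual
    ``incomplete`` verdict.  The egg-to-subadult survival estimate is taken
    from ``P0_SR`` vials with recorded egg counts, when present.
    """
    by_cross: dict = {}
    for b in broods:
        by_cross.setdefault(b.cross_id, []).append(b)

    def est(cross_id, stage="subadult"):
        group = by_cross.get(cross_id)
        if not group:
            return None
        try:
            return sex_ratio_ci(group, stage=stage, alpha=alpha)
        except ValueError:
            return None

    p0 = by_cross.get("P0_SR", [])
    e = est("P0_SR", "embryo")
    f = est("P0_SR", "subadult")
    if e is None or f is None:
        raise ValueError("P0_SR embryo and subadult censuses are required (E and F)")
    survival = None
    if any(b.n_eggs for b in p0):
        survival = egg_to_subadult_survival(p0, alpha=alpha)
    return ScreenInputs(
        e=e,
        f=f,
        control=est("P0_EVEN"),
        step2a=est("step2a"),
        step2b=est("step2b"),
        step3a=est("step3a"),
        step3b=est("step3b"),
        step3c=est("step3c"),
        total_survival=survival,
    )
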