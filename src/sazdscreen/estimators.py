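"""Closed-form survival estimators and interval procedures for brood counts.

The two survival estimators invert the stage-wise percent-female values of
the focal cross:

* ``survival_m_rel_f(E, F)`` — post-embryonic survival of males relative to
  their sisters, inferred from the rise in percent-female between the embryo
  census (E) and the subadult census (F):
  ``s = (100 E / F - E) / (100 - E)``.
* ``survival_Y_rel_X(E)`` — survival/functionality of Y-bearing relative to
  X-bearing sperm, inferred from the embryo census alone:
  ``s = (100 * 50 / E - 50) / 50``.

Both are exact inverses of the forward model ``%F = 100 / (1 + s)``.

Percent-female confidence intervals treat the vial as the unit of
replication and assume beta-binomial error terms: an intercept-only
beta-binomial model is fit by maximum likelihood across vials, with a
profile-likelihood interval on the mean; a single vial (or a fit with
negligible overdispersion) degenerates to the exact Clopper-Pearson
binomial interval.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, special, stats

from .synthetic_data import BroodCounts

__all__ = [
    "SexRatioEstimate",
    "ProportionEstimate",
    "RecombinationBound",
    "survival_m_rel_f",
    "survival_Y_rel_X",
    "predicted_pf",
    "max_pf_from_total_survival",
    "sex_ratio_ci",
    "egg_to_subadult_survival",
    "mortality_sufficiency",
    "recombination_upper_bound",
    "grandson_detection_prob",
]


# ---------------------------------------------------------------------------
# Closed-form survival estimators
# ---------------------------------------------------------------------------


def survival_m_rel_f(e_pf: float, f_pf: float) -> float:
    """Post-embryonic male survival relative to sisters from (E, F).

    ``(100*E/F - E) / (100 - E)``; the complementary "extra mortality" is
    ``100 * (1 - result)``.  If ``F < E`` (males apparently survived better
    than females) the estimate exceeds 1 and is clamped with a warning.
    """
    if not 0.0 < e_pf < 100.0:
        raise ValueError(f"E must lie in (0, 100), got {e_pf}")
    if not 0.0 < f_pf < 100.0:
        raise ValueError(f"F must lie in (0, 100), got {f_pf}")
    s = (100.0 * e_pf / f_pf - e_pf) / (100.0 - e_pf)
    if f_pf < e_pf:
        warnings.warn(
            "F < E: males survived better than females; survival clamped to 1",
            stacklevel=2,
        )
        return 1.0
    return s


def survival_Y_rel_X(e_pf: float) -> float:
    """Survival/functionality of Y-bearing relative to X-bearing sperm from E.

    ``(100 * 50 / E - 50) / 50``, valid for E in [50, 100): a female-biased
    embryo sex ratio attributed entirely to sperm killing.
    """
    if e_pf < 50.0:
        raise ValueError(
            f"E = {e_pf} < 50: drive against the X, outside the scope of this screen"
        )
    if e_pf >= 100.0:
        raise ValueError("E must be < 100")
    return (100.0 * 50.0 / e_pf - 50.0) / 50.0


def predicted_pf(survival: float) -> float:
    """Percent-female predicted from a male relative survival: ``100 / (1 + s)``."""
    if not 0.0 <= survival <= 1.0:
        raise ValueError(f"survival must lie in [0, 1], got {survival}")
    return 100.0 / (1.0 + survival)


def max_pf_from_total_survival(s_total: float) -> float:
    """Maximum subadult percent-female from a 50:50 zygotic ratio.

    If total egg-to-subadult survival is ``s_total`` and every death is
    male, the subadult percent-female is ``100 * 0.5 / s_total``; below
    total survival 0.5 all males can be dead and the cap is 100.
    """
    if s_total <= 0.0 or s_total > 1.0:
        raise ValueError(f"total survival must lie in (0, 1], got {s_total}")
    if s_total <= 0.5:
        return 100.0
    return 100.0 * 0.5 / s_total


def grandson_detection_prob(k: int) -> float:
    """P(>= 1 of k grandsons carries the driver | heterozygous mother) = 1 - (1/2)^k."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return 1.0 - 0.5 ** k


# ---------------------------------------------------------------------------
# Beta-binomial percent-female intervals
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SexRatioEstimate:
    """Percent-female point estimate with a confidence interval."""

    pf: float
    ci_low: float
    ci_high: float
    n: int
    n_vials: int
    method: str  # "beta-binomial" | "exact-binomial"
    alpha: float = 0.05
    rho_hat: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.ci_low <= self.pf <= self.ci_high <= 100.0):
            raise ValueError(
                f"interval ordering violated: {self.ci_low}, {self.pf}, {self.ci_high}"
            )


@dataclass(frozen=True)
class ProportionEstimate:
    """A generic overdispersed proportion (0-1 scale), e.g. egg-to-subadult survival."""

    p: float
    ci_low: float
    ci_high: float
    n: int
    n_vials: int
    method: str
    alpha: float = 0.05
    rho_hat: float = 0.0


_RHO_FLOOR = 1e-9
_RHO_DEGENERATE = 1e-6


def _betabinom_loglik(mu: float, rho: float, k: np.ndarray, n: np.ndarray,
                      lchoose: np.ndarray) -> float:
    if rho < _RHO_DEGENERATE:
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = lchoose + k * np.log(mu) + (n - k) * np.log1p(-mu)
        return float(np.sum(np.where(np.isfinite(ll), ll, -np.inf)))
    scale = (1.0 - rho) / rho
    a = mu * scale
    b = (1.0 - mu) * scale
    ll = lchoose + special.betaln(k + a, n - k + b) - special.betaln(a, b)
    return float(np.sum(ll))


def _fit_betabinom(k: np.ndarray, n: np.ndarray) -> tuple:
    """ML fit of an intercept-only beta-binomial; returns (mu, rho, loglik fn, ll_max)."""
    lchoose = special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1)

    def nll(x):
        mu, rho = x
        return -_betabinom_loglik(mu, rho, k, n, lchoose)

    mu0 = float(np.clip(k.sum() / n.sum(), 1e-4, 1 - 1e-4))
    best = None
    for rho0 in (1e-4, 0.02, 0.2):
        res = optimize.minimize(
            nll,
            x0=[mu0, rho0],
            method="L-BFGS-B",
            bounds=[(1e-6, 1 - 1e-6), (_RHO_FLOOR, 0.98)],
        )
        if best is None or res.fun < best.fun:
            best = res
    mu_hat, rho_hat = best.x

    def loglik(mu, rho):
        return _betabinom_loglik(mu, rho, k, n, lchoose)

    return float(mu_hat), float(rho_hat), loglik, -float(best.fun)


def _profile_ci(mu_hat: float, loglik, ll_max: float, alpha: float) -> tuple:
    """Profile-likelihood interval on the beta-binomial mean."""
    crit = stats.chi2.ppf(1.0 - alpha, df=1) / 2.0

    def prof(mu):
        res = optimize.minimize_scalar(
            lambda r: -loglik(mu, r), bounds=(_RHO_FLOOR, 0.98), method="bounded"
        )
        return -res.fun

    def g(mu):
        return ll_max - prof(mu) - crit

    lo_bracket, hi_bracket = 1e-6, 1 - 1e-6
    lo = lo_bracket if g(lo_bracket) <= 0 else optimize.brentq(
        g, lo_bracket, mu_hat, xtol=1e-6
    )
    hi = hi_bracket if g(hi_bracket) <= 0 else optimize.brentq(
        g, mu_hat, hi_bracket, xtol=1e-6
    )
    return float(lo), float(hi)


def _clopper_pearson(k: int, n: int, alpha: float) -> tuple:
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def _overdispersed_proportion(
    successes: Sequence[int], totals: Sequence[int], alpha: float
) -> tuple:
    """Returns (p_hat, lo, hi, method, rho_hat) on the proportion scale."""
    k = np.asarray(successes, dtype=float)
    n = np.asarray(totals, dtype=float)
    keep = n > 0
    k, n = k[keep], n[keep]
    if k.size == 0:
        raise ValueError("no vials with nonzero totals")
    k_tot, n_tot = int(k.sum()), int(n.sum())
    if n_tot == 0 or k_tot < 0:
        raise ValueError("all-zero counts")
    pooled = k_tot / n_tot
    if k.size == 1 or pooled in (0.0, 1.0):
        lo, hi = _clopper_pearson(k_tot, n_tot, alpha)
        return pooled, lo, hi, "exact-binomial", 0.0
    mu_hat, rho_hat, loglik, ll_max = _fit_betabinom(k, n)
    if rho_hat < _RHO_DEGENERATE:
        lo, hi = _clopper_pearson(k_tot, n_tot, alpha)
        return pooled, lo, hi, "exact-binomial", 0.0
    lo, hi = _profile_ci(mu_hat, loglik, ll_max, alpha)
    return mu_hat, lo, hi, "beta-binomial", rho_hat


def sex_ratio_ci(
    broods: Sequence[BroodCounts], stage: str = "subadult", alpha: float = 0.05
) -> SexRatioEstimate:
    """Percent-female estimate across vials with a beta-binomial interval.

    ``stage`` selects the embryo or subadult census.  Vials with zero total
    at the stage are dropped; a single vial (or negligible fitted
    overdispersion) yields the exact Clopper-Pearson interval on the pooled
    counts.
    """
    if stage == "embryo":
        pairs = [
            (b.n_embryo_female, b.n_embryo_female + b.n_embryo_male)
            for b in broods
            if b.n_embryo_female is not None
        ]
    elif stage == "subadult":
        pairs = [
            (b.n_subadult_female, b.n_subadult_female + b.n_subadult_male)
            for b in broods
        ]
    else:
        raise ValueError(f"stage must be 'embryo' or 'subadult', got {stage!r}")
    pairs = [(f, t) for f, t in pairs if t > 0]
    if not pairs:
        raise ValueError(f"no vials with nonzero {stage} totals")
    females, totals = zip(*pairs)
    p, lo, hi, method, rho_hat = _overdispersed_proportion(females, totals, alpha)
    return SexRatioEstimate(
        pf=100.0 * p,
        ci_low=100.0 * lo,
        ci_high=100.0 * hi,
        n=int(sum(totals)),
        n_vials=len(totals),
        method=method,
        alpha=alpha,
        rho_hat=rho_hat,
    )


def egg_to_subadult_survival(
    broods: Sequence[BroodCounts], alpha: float = 0.05
) -> ProportionEstimate:
    """Total egg-to-subadult survival (hatch-rate assay), per-vial beta-binomial."""
    pairs = [
        (b.n_subadult_female + b.n_subadult_male, b.n_eggs)
        for b in broods
        if b.n_eggs is not None and b.n_eggs > 0
    ]
    if not pairs:
        raise ValueError("no vials with recorded egg counts")
    survivors, eggs = zip(*pairs)
    p, lo, hi, method, rho_hat = _overdispersed_proportion(survivors, eggs, alpha)
    return ProportionEstimate(
        p=p, ci_low=lo, ci_high=hi, n=int(sum(eggs)), n_vials=len(eggs),
        method=method, alpha=alpha, rho_hat=rho_hat,
    )


def mortality_sufficiency(
    f_estimate: SexRatioEstimate, survival_lower: float
) -> str:
    """Can total mortality alone explain the subadult female bias?

    ``insufficient`` iff the lower confidence bound of F exceeds the maximum
    percent-female achievable from a 50:50 zygotic ratio when every death
    (bounded by the lower confidence limit of total egg-to-subadult
    survival) is male.  ``insufficient`` rules out "mortality alone" and
    implies a component acting before the zygote stage (e.g. SD).
    """
    cap = max_pf_from_total_survival(survival_lower)
    return "insufficient" if f_estimate.ci_low > cap else "sufficient"


# ---------------------------------------------------------------------------
# Recombination bound
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RecombinationBound:
    """Two-point map-distance estimate from the neither-driver sire class."""

    point_cM: float
    upper_cM: float
    n_informative: int
    n_null_class: int
    alpha: float
    detect_fraction: float
    unlinked: bool = False


def recombination_upper_bound(
    n_informative: int,
    n_null_class: int,
    alpha: float = 0.05,
    detect_fraction: float = 0.5,
) -> RecombinationBound:
    """Map-distance point estimate and one-sided exact upper bound.

    Recombinant X's appear in the neither-driver and both-driver sire
    classes, but only the neither-driver class is phenotypically detectable,
    so the null-class proportion estimates ``detect_fraction`` (default 1/2)
    of the recombination fraction.  The upper bound is the one-sided exact
    (Clopper-Pearson) upper limit on the null-class proportion at ``alpha``,
    divided by ``detect_fraction`` and expressed in centimorgans.  Estimates
    at or beyond 50 cM are capped and flagged unlinked.
    """
    if n_informative < 1:
        raise ValueError("need at least one informative sire")
    if not 0 <= n_null_class <= n_informative:
        raise ValueError("null-class count must lie in [0, n_informative]")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if not 0.0 < detect_fraction <= 1.0:
        raise ValueError("detect_fraction must lie in (0, 1]")
    point = 100.0 * (n_null_class / n_informative) / detect_fraction
    if n_null_class == n_informative:
        p_upper = 1.0
    else:
        p_upper = float(
            stats.beta.ppf(1.0 - alpha, n_null_class + 1, n_informative - n_null_class)
        )
    upper = 100.0 * p_upper / detect_fraction
    unlinked = point >= 50.0
    return RecombinationBound(
        point_cM=min(point, 50.0),
        upper_cM=min(upper, 50.0),
        n_informative=n_informative,
        n_null_class=n_null_class,
        alpha=alpha,
        detect_fraction=detect_fraction,
        unlinked=unlinked,
    )
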