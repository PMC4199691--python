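"""Two-driver recombination test: family classification and map-distance bound.

G2 sires descended from dams heterozygous for two X-linked drivers in
repulsion carry one driver, both, or neither; the neither-driver class (the
only phenotypically detectable recombinant class) estimates half the
recombination fraction.  Each sire's primary family is classified by a
one-sided exact binomial test for a female-biased sex ratio; sires that fail
(small families, incomplete penetrance) are rescued through a grandson
follow-up, since a truly heterozygous daughter transmits the driver to each
grandson with probability 1/2 and the chance of missing it in k grandsons is
only (1/2)^k.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from scipy import stats

from .estimators import RecombinationBound, recombination_upper_bound
from .synthetic_data import LinkageAssayData, SireFamily  # re-exported container types

__all__ = [
    "SireFamily",
    "LinkageAssayData",
    "SireCall",
    "LinkageAssayResult",
    "classify_families",
]


@dataclass(frozen=True)
class SireCall:
    sire_id: str
    informative: bool
    primary_significant: bool
    rescued: bool
    null_class: bool


@dataclass(frozen=True)
class LinkageAssayResult:
    """Outcome of the recombination assay over all informative sires."""

    n_informative: int
    n_null_class: int
    rescued_sires: tuple
    calls: tuple
    bound: RecombinationBound

    def __post_init__(self):
        object.__setattr__(self, "rescued_sires", tuple(self.rescued_sires))
        object.__setattr__(self, "calls", tuple(self.calls))
        n_primary_negative = sum(
            1 for c in self.calls if c.informative and not c.primary_significant
        )
        if self.n_null_class > n_primary_negative:
            raise ValueError("null-class count exceeds primary-negative count")


def _significant_female_bias(nf: int, n: int, alpha: float) -> bool:
    if n == 0:
        return False
    return stats.binomtest(nf, n, 0.5, alternative="greater").pvalue < alpha


def classify_families(
    data: LinkageAssayData,
    alpha: float = 0.05,
    *,
    min_grandson_offspring: int = 0,
    detect_fraction: float = 0.5,
) -> LinkageAssayResult:
    """Classify every sire and bound the map distance between the drivers.

    A sire is *informative* if his primary family produced offspring; a
    primary-negative sire is *rescued* iff at least one grandson family of
    at least ``min_grandson_offspring`` offspring is significantly
    female-biased by the same one-sided exact binomial test.  Unrescued
    primary-negative sires form the null (neither-driver) class, from which
    :func:`~sazdscreen.estimators.recombination_upper_bound` computes the
    point estimate and one-sided exact upper bound.
    """
    if not 0.0 < alpha < 0.5:
        raise ValueError(f"alpha must lie in (0, 0.5), got {alpha}")
    calls = []
    n_informative = 0
    n_null = 0
    rescued_ids = []
    for sire in data.sires:
        informative = sire.n_total > 0
        if not informative:
            calls.append(SireCall(sire.sire_id, False, False, False, False))
            continue
        n_informative += 1
        primary = _significant_female_bias(sire.n_female, sire.n_total, alpha)
        rescued = False
        null_class = False
        if not primary:
            families = [
                (nf, nm)
                for nf, nm in (sire.grandson_families or ())
                if nf + nm >= min_grandson_offspring
            ]
            # one rescue decision per sire: Bonferroni across his grandson
            # families, else ~40% of truly driver-free sires would be falsely
            # rescued at alpha=0.05 x 10 families
            g_alpha = alpha / max(1, len(families))
            rescued = any(
                _significant_female_bias(nf, nf + nm, g_alpha) for nf, nm in families
            )
            if rescued:
                rescued_ids.append(sire.sire_id)
            else:
                null_class = True
                n_null += 1
        calls.append(SireCall(sire.sire_id, True, primary, rescued, null_class))
    if n_informative == 0:
        raise ValueError("no informative sires (every family was empty)")
    bound = recombination_upper_bound(
        n_informative, n_null, alpha=alpha, detect_fraction=detect_fraction
    )
    return LinkageAssayResult(
        n_informative=n_informative,
        n_null_class=n_null,
        rescued_sires=tuple(rescued_ids),
        calls=tuple(calls),
        bound=bound,
    )
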