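"""Two-step MR mediation: biomarker screen and product-of-coefficients decomposition.

Step one screens a family of candidate mediators (biomarkers) by running
IVW-MR of the drug-target instruments on each biomarker, with a Bonferroni
family-wise threshold.  Step two decomposes the total exposure-to-outcome
effect ``b0`` into an indirect component through the mediator,
``b1 * b2`` (exposure-to-mediator times mediator-to-outcome), and a direct
component ``b0 - b1 * b2``, with first-order delta-method standard errors.
The three coefficient estimates are treated as independent, which is
appropriate for non-overlapping GWAS samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from scipy import stats

from drugmr.instruments import InstrumentSet
from drugmr.mr import MREstimate, ivw_mre
from drugmr.sumstats import NoSharedVariantsError, SummaryRecord, harmonize

logger = logging.getLogger(__name__)


def bonferroni(alpha_family: float, n_tests: int) -> float:
    """Family-wise threshold ``alpha_family / n_tests``."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not (0 < alpha_family < 1):
        raise ValueError("alpha_family must be in (0, 1)")
    return alpha_family / n_tests


@dataclass
class MediationResult:
    """Product-of-coefficients decomposition with delta-method SEs.

    ``proportion`` is the signed mediated proportion ``(b1*b2)/b0``; it is
    ``None`` when the total effect is zero.  ``se_proportion`` optionally
    includes the uncertainty of ``b0`` (default yes).
    """

    b0: float
    b1: float
    b2: float
    se0: float
    se1: float
    se2: float
    indirect: float
    se_indirect: float
    direct: float
    proportion: float | None
    se_proportion: float | None
    pval_indirect: float

    @property
    def abs_proportion(self) -> float | None:
        return None if self.proportion is None else abs(self.proportion)


def two_step_mediation(
    b0: float, se0: float, b1: float, se1: float, b2: float, se2: float,
    include_b0_uncertainty: bool = True,
) -> MediationResult:
    """Decompose the total effect ``b0`` into indirect ``b1*b2`` and direct parts.

    Delta-method variances (independent estimates, zero covariances):

    - ``var(indirect) = b2^2 se1^2 + b1^2 se2^2``
    - ``var(proportion) = (b2/b0)^2 se1^2 + (b1/b0)^2 se2^2
      + (b1 b2 / b0^2)^2 se0^2`` — the last term dropped when
      ``include_b0_uncertainty`` is false.

    The proportion variance is written in gradient form so zero component
    effects never cause a division by zero.
    """
    for name, se in (("se0", se0), ("se1", se1), ("se2", se2)):
        if not se > 0:
            raise ValueError(f"{name} must be > 0")
    indirect = b1 * b2
    se_indirect = math.sqrt(b2 * b2 * se1 * se1 + b1 * b1 * se2 * se2)
    direct = b0 - indirect
    if se_indirect > 0:
        pval_indirect = float(2.0 * stats.norm.sf(abs(indirect / se_indirect)))
    else:
        pval_indirect = 1.0
    if b0 == 0:
        proportion = None
        se_proportion = None
    else:
        proportion = indirect / b0
        var_p = (b2 / b0) ** 2 * se1**2 + (b1 / b0) ** 2 * se2**2
        if include_b0_uncertainty:
            var_p += (indirect / (b0 * b0)) ** 2 * se0**2
        se_proportion = math.sqrt(var_p)
    return MediationResult(
        b0=b0, b1=b1, b2=b2, se0=se0, se1=se1, se2=se2,
        indirect=indirect, se_indirect=se_indirect, direct=direct,
        proportion=proportion, se_proportion=se_proportion,
        pval_indirect=pval_indirect,
    )


@dataclass
class ScreenResult:
    """Per-biomarker IVW estimates against a Bonferroni family threshold.

    Direction bookkeeping follows the drug-perturbation convention: a
    biomarker is counted as *elevated* when its level rises per 1-unit
    exposure decrease (slope ``b < 0``) and *reduced* otherwise.
    """

    estimates: dict[str, MREstimate]
    bonferroni_alpha: float
    passed: dict[str, bool]
    failed_harmonization: list[str] = field(default_factory=list)
    family_size: int = 0

    @property
    def n_passed(self) -> int:
        return sum(self.passed.values())

    @property
    def n_elevated(self) -> int:
        return sum(1 for name, ok in self.passed.items() if ok and self.estimates[name].b < 0)

    @property
    def n_reduced(self) -> int:
        return sum(1 for name, ok in self.passed.items() if ok and self.estimates[name].b > 0)


def screen_biomarkers(
    instruments: InstrumentSet,
    biomarker_sumstats: Mapping[str, Sequence[SummaryRecord]],
    alpha_family: float = 0.05,
    family_size: int | None = None,
) -> ScreenResult:
    """IVW-MR of the instrument set against every biomarker in the family.

    The Bonferroni denominator is the configured family size (default: the
    number of biomarkers supplied), kept fixed regardless of harmonization
    failures so the threshold does not depend on data quirks.
    """
    n_family = family_size if family_size is not None else len(biomarker_sumstats)
    threshold = bonferroni(alpha_family, n_family)
    estimates: dict[str, MREstimate] = {}
    passed: dict[str, bool] = {}
    failed: list[str] = []
    for name, records in biomarker_sumstats.items():
        try:
            hset = harmonize(instruments.records, records)
            if len(hset) == 0:
                raise NoSharedVariantsError(name)
            est = ivw_mre(hset)
        except (NoSharedVariantsError, ValueError) as exc:
            logger.warning("biomarker %s: harmonization/estimation failed (%s)", name, exc)
            failed.append(name)
            continue
        estimates[name] = est
        passed[name] = est.pval < threshold
    return ScreenResult(
        estimates=estimates,
        bonferroni_alpha=threshold,
        passed=passed,
        failed_harmonization=failed,
        family_size=n_family,
    )
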