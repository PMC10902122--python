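"""Bayesian colocalization of two association signals in a genomic window.

Under the single-causal-variant assumption, the evidence that variant j is
causal for a trait is summarized by the Wakefield approximate Bayes factor
computed from the marginal estimate and its standard error:

    log ABF = 1/2 * [ log(1 - r) + r * z^2 ],   r = W / (V + W)

with ``V = se^2``, ``W`` the prior variance of a true effect and
``z = beta/se``.  Enumerating configurations with per-variant priors p1
(trait-1 only), p2 (trait-2 only) and p12 (shared) yields posterior
probabilities for five hypotheses: H0 (no association), H1/H2 (one trait
only), H3 (two distinct causal variants), H4 (one shared causal variant).
All accumulation happens in log space via log-sum-exp.

The conventional decision rules — PP.H4 > 0.8, and the conditional ratio
PP.H4 / (PP.H3 + PP.H4) > 0.75 given a causal variant exists for trait 2 —
are reported as flags, never enforced.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from drugmr.sumstats import GeneRegion, SummaryRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ColocPriors:
    """Per-variant prior probabilities of association configurations."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p12"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1)")
        if self.p12 > min(self.p1, self.p2):
            logger.warning("coloc priors: p12 (%.3g) exceeds min(p1, p2) — unusual configuration",
                           self.p12)


@dataclass(frozen=True)
class TraitSpec:
    """Trait type and prior effect scale for the ABF.

    ``prior_effect_sd`` is sqrt(W): defaults to 0.15 for quantitative
    traits (standardized effects) and 0.2 for case-control traits on the
    log-odds scale.
    """

    trait_type: str = "quantitative"
    prior_effect_sd: float | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "case_control"):
            raise ValueError("trait_type must be 'quantitative' or 'case_control'")
        if self.prior_effect_sd is None:
            object.__setattr__(
                self, "prior_effect_sd", 0.15 if self.trait_type == "quantitative" else 0.2
            )
        if not self.prior_effect_sd > 0:
            raise ValueError("prior_effect_sd must be > 0")


@dataclass
class ColocResult:
    """Posterior probabilities of the five colocalization hypotheses."""

    pp: dict[str, float]
    conditional_h4: float | None
    n_variants: int
    priors: ColocPriors
    log_abf_trait1: np.ndarray = field(repr=False, default=None)
    log_abf_trait2: np.ndarray = field(repr=False, default=None)
    variant_ids: list[str] = field(repr=False, default=None)

    @property
    def h4_flag(self) -> bool:
        """Conventional shared-causal-variant call: PP.H4 > 0.8."""
        return self.pp["H4"] > 0.8

    @property
    def conditional_h4_flag(self) -> bool:
        """Conditional colocalization call: PP.H4/(PP.H3+PP.H4) > 0.75."""
        return self.conditional_h4 is not None and self.conditional_h4 > 0.75

    def to_dict(self) -> dict:
        return {
            "pp": self.pp,
            "conditional_h4": self.conditional_h4,
            "n_variants": self.n_variants,
            "priors": {"p1": self.priors.p1, "p2": self.priors.p2, "p12": self.priors.p12},
            "h4_flag": self.h4_flag,
            "conditional_h4_flag": self.conditional_h4_flag,
        }


def log_abf(beta: float, se: float, prior_effect_sd: float) -> float:
    """Wakefield log approximate Bayes factor for one variant.

    ``prior_effect_sd = 0`` returns 0 (Bayes factor 1: the prior carries no
    effect, so the datum is uninformative).
    """
    if not se > 0:
        raise ValueError("se must be > 0")
    v = se * se
    w = prior_effect_sd * prior_effect_sd
    if w == 0:
        return 0.0
    r = w / (v + w)
    z = beta / se
    return 0.5 * (math.log1p(-r) + r * z * z)


def approx_se(n: float, eaf: float, trait_type: str, case_fraction: float | None = None) -> float:
    """Fallback standard error from sample size and allele frequency.

    For a standardized quantitative trait, ``var(beta_hat) ~ 1/(2 n p q)``;
    for a case-control trait on the log-odds scale the effective sample
    size is scaled by ``k(1-k)``.
    """
    if not (0 < eaf < 1) or n <= 0:
        raise ValueError("require n > 0 and eaf in (0, 1)")
    denom = 2.0 * n * eaf * (1.0 - eaf)
    if trait_type == "case_control":
        if case_fraction is None or not (0 < case_fraction < 1):
            raise ValueError("case_control fallback needs case_fraction in (0, 1)")
        denom *= case_fraction * (1.0 - case_fraction)
    return math.sqrt(1.0 / denom)


def _trait_log_abfs(records: Sequence[SummaryRecord], spec: TraitSpec) -> np.ndarray:
    out = np.empty(len(records))
    for i, r in enumerate(records):
        se = r.se
        if not se > 0:
            if r.n is None or r.eaf is None:
                raise ValueError(f"{r.variant_id}: se missing and no n/eaf fallback available")
            se = approx_se(r.n, r.eaf, spec.trait_type)
        out[i] = log_abf(r.beta, se, spec.prior_effect_sd)
    return out


def coloc_abf(
    trait1: Sequence[SummaryRecord],
    trait2: Sequence[SummaryRecord],
    spec1: TraitSpec | None = None,
    spec2: TraitSpec | None = None,
    priors: ColocPriors | None = None,
) -> ColocResult:
    """Enumerate the five colocalization hypotheses over shared variants.

    With per-variant log-ABFs ``l1_j``, ``l2_j`` and log-space sums
    ``S1 = lse(l1)``, ``S2 = lse(l2)``, ``S12 = lse(l1 + l2)``, the
    unnormalized hypothesis masses are ``{1, p1*S1, p2*S2,
    p1*p2*(S1*S2 - S12), p12*S12}`` (sums on the natural scale), which are
    normalized into posterior probabilities.
    """
    spec1 = spec1 or TraitSpec()
    spec2 = spec2 or TraitSpec()
    priors = priors or ColocPriors()

    by_id2 = {r.variant_id: r for r in trait2}
    pairs = [(r, by_id2[r.variant_id]) for r in trait1 if r.variant_id in by_id2]
    if not pairs:
        raise ValueError("no shared variants between the two traits")

    l1 = _trait_log_abfs([p[0] for p in pairs], spec1)
    l2 = _trait_log_abfs([p[1] for p in pairs], spec2)
    s1 = float(logsumexp(l1))
    s2 = float(logsumexp(l2))
    s12 = float(logsumexp(l1 + l2))

    log_p1 = math.log(priors.p1)
    log_p2 = math.log(priors.p2)
    log_p12 = math.log(priors.p12)

    # H3 mass: p1*p2*(exp(S1)*exp(S2) - exp(S12)); mathematically >= 0,
    # clamp to zero when floating point says otherwise (or when J = 1)
    d = s12 - (s1 + s2)
    if d >= 0:
        if d > 1e-9:
            logger.debug("coloc_abf: H3 mass numerically negative (d = %.3g), clamped to 0", d)
        log_h3 = -math.inf
    else:
        log_h3 = log_p1 + log_p2 + s1 + s2 + math.log1p(-math.exp(d))

    log_masses = np.array([
        0.0,
        log_p1 + s1,
        log_p2 + s2,
        log_h3,
        log_p12 + s12,
    ])
    log_total = float(logsumexp(log_masses))
    pp_arr = np.exp(log_masses - log_total)
    pp_arr /= pp_arr.sum()
    pp = {f"H{i}": float(pp_arr[i]) for i in range(5)}

    denom = pp["H3"] + pp["H4"]
    conditional_h4 = pp["H4"] / denom if denom > 0 else None

    return ColocResult(
        pp=pp,
        conditional_h4=conditional_h4,
        n_variants=len(pairs),
        priors=priors,
        log_abf_trait1=l1,
        log_abf_trait2=l2,
        variant_ids=[p[0].variant_id for p in pairs],
    )


def window_slice(
    sumstats: Sequence[SummaryRecord],
    region: GeneRegion,
    flank_kb: float,
) -> list[SummaryRecord]:
    """Records on the region's chromosome within the flanked span
    ``[start - flank_kb*1000, end + flank_kb*1000]``, bounds inclusive."""
    lo = region.start - flank_kb * 1000.0
    hi = region.end + flank_kb * 1000.0
    chrom = _norm(region.chrom)
    return [r for r in sumstats if _norm(r.chrom) == chrom and lo <= r.pos <= hi]


def _norm(chrom: str) -> str:
    c = str(chrom).lower()
    return c[3:] if c.startswith("chr") else c
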