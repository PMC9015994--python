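"""Biologically effective dose for protracted radionuclide exposure.

In the linear-quadratic model, the biological effect of an absorbed dose D
delivered with an exponentially decaying dose rate (effective decay
constant λ = ln2/T_eff) and mono-exponential sublethal-damage repair
(repair constant μ = ln2/T_repair) is summarised by

    BED = D · (1 + D/(α/β) · λ/(λ+μ)).

Slower delivery (smaller λ relative to μ) allows more repair during the
exposure and lowers the BED towards D.  Cycles separated by intervals long
compared with T_eff add their BEDs.  No default α/β or repair half-life is
shipped: these are tissue- and endpoint-specific and must be supplied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = ["LQParameters", "BEDResult", "bed_single", "bed_fractionated", "eqd2"]


@dataclass(frozen=True)
class LQParameters:
    """Linear-quadratic tissue parameters.

    ``alpha_beta_Gy`` is the dose at which linear and quadratic kill are
    equal (low for late-responding tissues such as kidney, higher for
    tumours); ``repair_halflife_h`` sets the sublethal-damage repair rate.
    """

    alpha_beta_Gy: float
    repair_halflife_h: float

    def __post_init__(self) -> None:
        if self.alpha_beta_Gy <= 0:
            raise ValueError("alpha/beta must be > 0")
        if self.repair_halflife_h <= 0:
            raise ValueError("repair half-life must be > 0")

    @property
    def mu_per_h(self) -> float:
        return math.log(2.0) / self.repair_halflife_h


@dataclass
class BEDResult:
    """BED value with the assumptions under which it is valid."""

    bed_Gy: float
    assumptions: list[str] = field(default_factory=list)

    def __float__(self) -> float:
        return self.bed_Gy


def bed_single(dose_Gy: float, effective_halflife_h: float, lq: LQParameters) -> float:
    """BED of one administration with mono-exponential washout."""
    if dose_Gy < 0:
        raise ValueError("dose must be >= 0")
    if effective_halflife_h <= 0:
        raise ValueError("effective half-life must be > 0")
    lam = math.log(2.0) / effective_halflife_h
    g = lam / (lam + lq.mu_per_h)
    return dose_Gy * (1.0 + dose_Gy / lq.alpha_beta_Gy * g)


def bed_fractionated(
    per_cycle: list[tuple[float, float]], lq: LQParameters
) -> BEDResult:
    """Sum of per-cycle BEDs for well-separated administrations.

    Each element is ``(dose_Gy, effective_halflife_h)``.  Valid when the
    inter-cycle interval is long compared with the effective half-life, so
    no unrepaired damage carries over between cycles; that assumption is
    recorded in the result.
    """
    if not per_cycle:
        raise ValueError("per_cycle must be non-empty")
    total = sum(bed_single(d, t_eff, lq) for d, t_eff in per_cycle)
    return BEDResult(
        total,
        assumptions=[
            "mono-exponential washout within each cycle",
            "inter-cycle interval >> effective half-life (no damage carry-over)",
        ],
    )


def eqd2(bed_Gy: float, alpha_beta_Gy: float) -> float:
    """Equieffective dose in 2 Gy fractions: EQD2 = BED / (1 + 2/(α/β))."""
    if bed_Gy < 0:
        raise ValueError("BED must be >= 0")
    if alpha_beta_Gy <= 0:
        raise ValueError("alpha/beta must be > 0")
    return bed_Gy / (1.0 + 2.0 / alpha_beta_Gy)
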