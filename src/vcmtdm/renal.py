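"""Creatinine-clearance estimation (Cockcroft-Gault) and derived renal covariates.

Vancomycin is cleared almost entirely by the kidney, so every dose plan in
this package starts from an estimate of creatinine clearance (CLcr).  The
Cockcroft-Gault formula overestimates CLcr in patients with low muscle mass
(low serum creatinine); Japanese TDM practice floors SCr at 0.6 mg/dL before
applying the formula.  Both the floored SCr and the *amount* added by the
floor are kept as covariates: the adjustment amount is a continuous marker of
how aggressively renal function was corrected, and it appears in the final
trough-correction model with a negative coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

__all__ = [
    "ScrAdjustment",
    "RenalCovariates",
    "adjust_scr",
    "cockcroft_gault",
    "renal_covariates",
]

#: Conventional serum-creatinine floor (mg/dL) applied before Cockcroft-Gault.
DEFAULT_SCR_FLOOR = 0.6


class ScrAdjustment(NamedTuple):
    scr_adjusted: float
    scr_adjusted_amount: float
    scr_was_adjusted: bool


@dataclass(frozen=True)
class RenalCovariates:
    """Renal covariates for one patient at one time point.

    ``bun_over_scr`` uses the raw SCr, ``bun_over_adjscr`` the floored SCr;
    both are ``None`` when BUN is missing.
    """

    clcr: float            # mL/min
    scr: float             # mg/dL, raw
    scr_adjusted: float    # mg/dL, after flooring
    scr_adjusted_amount: float
    scr_was_adjusted: bool
    bun_over_scr: float | None
    bun_over_adjscr: float | None


def adjust_scr(scr: float, floor: float = DEFAULT_SCR_FLOOR) -> ScrAdjustment:
    """Floor serum creatinine at ``floor`` mg/dL.

    Returns the floored value, the increment applied (``max(0, floor - scr)``)
    and whether any adjustment took place.  Idempotent.
    """
    if scr <= 0:
        raise ValueError(f"serum creatinine must be positive, got {scr}")
    adjusted = max(scr, floor)
    return ScrAdjustment(adjusted, adjusted - scr, adjusted > scr)


def cockcroft_gault(sex: str, age: float, weight: float, scr_adjusted: float) -> float:
    """Cockcroft-Gault creatinine clearance in mL/min.

    ``clcr = (140 - age) * weight / (72 * scr)``, times 0.85 for females.
    ``scr_adjusted`` should already have the floor applied (see
    :func:`adjust_scr`); this function does not floor.
    """
    if sex not in ("female", "male"):
        raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")
    if age >= 140:
        raise ValueError("Cockcroft-Gault is undefined for age >= 140 (non-positive numerator)")
    if weight <= 0:
        raise ValueError(f"weight must be positive, got {weight}")
    if scr_adjusted <= 0:
        raise ValueError(f"scr must be positive, got {scr_adjusted}")
    clcr = (140.0 - age) * weight / (72.0 * scr_adjusted)
    if sex == "female":
        clcr *= 0.85
    return clcr


def renal_covariates(record, at: str = "planning", floor: float = DEFAULT_SCR_FLOOR) -> RenalCovariates:
    """Compose SCr flooring and Cockcroft-Gault for one patient record.

    ``at='planning'`` uses the SCr measured when the initial dose was planned;
    ``at='trough'`` uses the SCr at trough sampling (CLcr is recomputed from
    the contemporaneous SCr whenever a trough is interpreted).  BUN ratios are
    ``None`` when BUN is missing rather than an error.
    """
    if at == "planning":
        scr = record.scr
    elif at == "trough":
        scr = record.scr_at_trough if record.scr_at_trough is not None else record.scr
    else:
        raise ValueError(f"at must be 'planning' or 'trough', got {at!r}")
    adj = adjust_scr(scr, floor=floor)
    clcr = cockcroft_gault(record.sex, record.age, record.weight, adj.scr_adjusted)
    bun = record.bun
    return RenalCovariates(
        clcr=clcr,
        scr=scr,
        scr_adjusted=adj.scr_adjusted,
        scr_adjusted_amount=adj.scr_adjusted_amount,
        scr_was_adjusted=adj.scr_was_adjusted,
        bun_over_scr=None if bun is None else bun / scr,
        bun_over_adjscr=None if bun is None else bun / adj.scr_adjusted,
    )
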