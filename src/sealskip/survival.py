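"""Maternal and pup survival.

Maternal survival follows a hockey-stick in body mass: certain death at or
below the critical mass x_crit, a linear rise to the maximum annual survival
s_max at x_cutoff, and mass independence above that.  Pup first-year survival
is a nondecreasing step function of weaning mass.
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import ModelParams

__all__ = ["SurvivalCurve", "maternal_survival", "pup_survival"]


@dataclass(frozen=True)
class SurvivalCurve:
    """Hockey-stick maternal survival curve."""

    x_crit: float
    x_cutoff: float
    s_max: float

    def __post_init__(self) -> None:
        if self.x_cutoff < self.x_crit:
            raise ValueError("x_cutoff must be >= x_crit")
        if not (0.0 <= self.s_max <= 1.0):
            raise ValueError("s_max must be a probability")

    @classmethod
    def from_params(cls, params: ModelParams) -> "SurvivalCurve":
        return cls(params.x_crit, params.x_cutoff, params.s_max)


def maternal_survival(x: float, curve: SurvivalCurve | ModelParams) -> float:
    """Annual survival probability of a female evaluated at body mass ``x``.

    At or below x_crit the female is dead (survival 0); at or above x_cutoff
    survival is the mass-independent maximum.  With x_cutoff == x_crit the
    curve degenerates to flat s_max for every mass above x_crit
    (mass-independent survival).
    """
    if isinstance(curve, ModelParams):
        curve = SurvivalCurve.from_params(curve)
    if x <= curve.x_crit:
        return 0.0
    if x >= curve.x_cutoff:
        return curve.s_max
    frac = (x - curve.x_crit) / (curve.x_cutoff - curve.x_crit)
    return curve.s_max * frac


def pup_survival(m_p: float, params: ModelParams) -> float:
    """Probability a pup weaned at mass ``m_p`` (kg) survives its first year."""
    if m_p < 0:
        raise ValueError("weaning mass must be nonnegative")
    prob = 0.0
    for bound, surv in params.pup_survival_bins:
        if m_p >= bound:
            prob = surv.mean
        else:
            break
    return min(max(prob, 0.0), 1.0)
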