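"""Mass budget of the female's annual cycle.

A year runs breed -> post-breeding foraging -> molt -> post-molt foraging,
and every loss and gain is mass-specific: each stage operates on the mass
that comes out of the previous stage.  The state dynamics are

    x(y+1) = x - p - r + f_b - m_l + f_m      (breeder)
    x(y+1) = x + f_b' - m_l + f_m             (non-breeder)

with p the pup's birth mass, r the lactation loss, f the foraging gains
(reduced by a fixed factor in a bad year), and m_l the molt loss.  A female
whose mass falls below the critical mass x_crit at any stage starves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import ModelParams

__all__ = [
    "AnnualTransition",
    "pup_birth_mass",
    "expected_pup_birth_mass",
    "breeding_loss",
    "foraging_gain",
    "molt_loss",
    "wean_mass",
    "initial_mass",
    "annual_transition",
]

# starvation stages that occur before the pup is weaned (lactation lasts ~3
# weeks; the molt and later stages happen months after weaning)
PRE_WEANING_STAGES = ("parturition", "lactation")


def pup_birth_mass(x: float, params: ModelParams, sex_draw: float) -> float:
    """Pup mass at parturition for a mother of arrival mass ``x`` (kg).

    Small mothers (< ``pup_sex_mass_threshold``) bear female pups (lower
    intercept); larger mothers bear male pups, which are heavier, with
    probability one half (``sex_draw`` <= 0.5 selects the male intercept).
    The saturating regression can go negative when extrapolated to very small
    mothers; the result is floored at 0 (pup production fails).
    """
    if x >= params.pup_sex_mass_threshold and sex_draw <= 0.5:
        intercept = params.pup_intercept_high.mean
    else:
        intercept = params.pup_intercept_low.mean
    p = intercept - params.pup_coef.mean * math.exp(-params.pup_rate.mean * x)
    return max(p, 0.0)


def expected_pup_birth_mass(x: float, params: ModelParams) -> float:
    """Sex-averaged pup birth mass: the deterministic surrogate used by the solver.

    Below the sex threshold only the female branch exists; above it the two
    intercepts are averaged with equal weight (pup sex is a fair coin there).
    """
    low = pup_birth_mass(x, params, sex_draw=1.0)
    if x < params.pup_sex_mass_threshold:
        return low
    high = pup_birth_mass(x, params, sex_draw=0.0)
    return 0.5 * (low + high)


def breeding_loss(m_i: float, params: ModelParams) -> float:
    """Mass lost to lactation (kg): daily loss times lactation length.

    ``m_i`` is the mother's postpartum mass (arrival mass minus pup).
    """
    r_d = params.lact_slope.mean * m_i + params.lact_intercept.mean
    return r_d * params.lact_days.mean


def foraging_gain(
    m_i: float,
    period: str,
    breeder: bool,
    bad_year: bool,
    params: ModelParams,
) -> float:
    """Mass gained (kg) on a foraging trip entered at mass ``m_i``.

    ``period`` is ``"postbreed"`` or ``"postmolt"``.  Non-breeders forage
    through the breeding season and so gain a larger fraction post-breeding;
    the breeder flag is irrelevant post-molt.  Bad years scale every gain by
    ``bad_year_factor``.
    """
    if period == "postbreed":
        frac = params.forage_breed.mean if breeder else params.forage_nonbreed.mean
    elif period == "postmolt":
        frac = params.forage_postmolt.mean
    else:
        raise ValueError(f"unknown foraging period: {period!r}")
    if bad_year:
        frac *= params.bad_year_factor
    return frac * m_i


def molt_loss(m_i: float, params: ModelParams) -> float:
    """Mass lost to the molt (kg): mass-dependent duration times daily loss."""
    d_m = params.molt_days_slope.mean * m_i + params.molt_days_intercept.mean
    return max(d_m, 0.0) * params.molt_daily_loss.mean


def wean_mass(m_i: float, params: ModelParams) -> float:
    """Pup mass at weaning (kg) given the mother's mass ``m_i`` at parturition.

    Nursing transfers mass directly from mother to pup; capped at the largest
    observed weaner size, floored at 0 (the regression can extrapolate
    negative under drawn coefficients at very small maternal mass).
    """
    m_p = params.wean_slope.mean * m_i + params.wean_intercept.mean
    return min(max(m_p, 0.0), params.pup_mass_cap)


def initial_mass(age: int, params: ModelParams, rng=None) -> float:
    """Body mass (kg) of a female recruiting at ``age``, clamped to the grid.

    With an rng, the regression coefficients are drawn from their error
    distributions; without one, point estimates are used.
    """
    slope = params.init_mass_slope
    intercept = params.init_mass_intercept
    if rng is not None:
        s = slope.draw(rng, 0.0)
        b = intercept.draw(rng)
    else:
        s, b = slope.mean, intercept.mean
    m = s * age + b
    return min(max(m, params.x_crit), params.x_max)


@dataclass(frozen=True)
class AnnualTransition:
    """Record of one female-year: every stage's mass delta plus outcomes."""

    start_mass: float
    breed: bool
    bad_year: bool
    pup_birth_mass: float | None   # p, kg (None if skipped)
    breeding_loss: float | None    # r, kg
    postbreed_gain: float
    molt_loss: float
    postmolt_gain: float
    end_mass: float                # clamped to x_max
    wean_mass: float | None        # m_p, kg (None if no pup weaned)
    died_of_starvation: bool
    starved_stage: str | None = None   # parturition | lactation | molt
    postpartum_mass: float | None = None
    nadir_mass: float | None = None    # mass after lactation (breeders) / arrival (non-breeders)

    def starved_before_weaning(self) -> bool:
        return self.starved_stage in PRE_WEANING_STAGES

    def to_row(self) -> dict:
        return {
            "start_mass": self.start_mass,
            "breed": self.breed,
            "bad_year": self.bad_year,
            "pup_birth_mass": self.pup_birth_mass,
            "breeding_loss": self.breeding_loss,
            "postbreed_gain": self.postbreed_gain,
            "molt_loss": self.molt_loss,
            "postmolt_gain": self.postmolt_gain,
            "end_mass": self.end_mass,
            "wean_mass": self.wean_mass,
            "died_of_starvation": self.died_of_starvation,
        }


def annual_transition(
    x: float,
    breed: bool,
    bad_year: bool,
    params: ModelParams,
    sex_draw: float | None = None,
) -> AnnualTransition:
    """Run one full annual cycle from arrival mass ``x``.

    Stages are applied in calendar order, each on the mass left by the one
    before.  ``sex_draw`` is the uniform variate deciding pup sex; ``None``
    uses the sex-averaged expected pup mass (the solver's deterministic mode).
    Starvation (any stage mass below ``x_crit``) is flagged but the remaining
    stage arithmetic is still recorded, so a trajectory row is always complete.
    """
    if not (params.x_crit <= x <= params.x_max):
        raise ValueError(
            f"arrival mass {x} outside [{params.x_crit}, {params.x_max}]"
        )
    starved_stage: str | None = None
    if breed:
        if sex_draw is None:
            p = expected_pup_birth_mass(x, params)
        else:
            p = pup_birth_mass(x, params, sex_draw)
        postpartum = x - p
        if postpartum < params.x_crit:
            starved_stage = "parturition"
        r = breeding_loss(postpartum, params)
        nadir = postpartum - r
        if starved_stage is None and nadir < params.x_crit:
            starved_stage = "lactation"
        m_p = wean_mass(postpartum, params) if starved_stage is None else None
        gain_b = foraging_gain(nadir, "postbreed", True, bad_year, params)
        pre_molt = nadir + gain_b
    else:
        p = None
        r = None
        m_p = None
        postpartum = None
        nadir = x
        gain_b = foraging_gain(x, "postbreed", False, bad_year, params)
        pre_molt = x + gain_b
    m_l = molt_loss(pre_molt, params)
    post_molt = pre_molt - m_l
    if starved_stage is None and post_molt < params.x_crit:
        starved_stage = "molt"
    gain_m = foraging_gain(post_molt, "postmolt", breed, bad_year, params)
    end = min(post_molt + gain_m, params.x_max)
    return AnnualTransition(
        start_mass=x,
        breed=breed,
        bad_year=bad_year,
        pup_birth_mass=p,
        breeding_loss=r,
        postbreed_gain=gain_b,
        molt_loss=m_l,
        postmolt_gain=gain_m,
        end_mass=end,
        wean_mass=m_p,
        died_of_starvation=starved_stage is not None,
        starved_stage=starved_stage,
        postpartum_mass=postpartum,
        nadir_mass=nadir,
    )
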