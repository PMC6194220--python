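"""Backward-iteration solver for the optimal breed/skip policy.

The expected number of surviving pups (in pup-mass-weighted currency) from age
y onward for a female of mass x is

    F(x, y) = max{ V_breed(x, y), V_skip(x, y) },    F(x, terminal_age) = 0

where breeding yields the current reward (1 - mu_p) * m_p plus the
survival-discounted continuation value at next year's mass, and skipping
yields only the (better-fed) continuation.  Environmental stochasticity
enters as a (1-a)/a mixture over good and bad foraging years; off-grid
continuation masses are handled by linear interpolation, which is equivalent
to a stochastic transition onto the two bracketing grid points.

The solver is deterministic: it uses point-estimate parameters and the
sex-averaged expected pup mass.  Parameter uncertainty belongs to the Monte
Carlo layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mass_dynamics import AnnualTransition, annual_transition
from .params import ModelParams
from .survival import maternal_survival, pup_survival

__all__ = [
    "StateGrid",
    "PolicySolution",
    "interpolate_F",
    "fitness_breed",
    "fitness_skip",
    "solve",
    "skip_region_summary",
]


@dataclass(frozen=True)
class StateGrid:
    """Discretized (body mass x age) state space."""

    masses: np.ndarray          # kg, x_crit .. x_max, uniform spacing
    ages: np.ndarray            # decision ages
    terminal_age: int

    @classmethod
    def from_params(cls, params: ModelParams) -> "StateGrid":
        n = int(round((params.x_max - params.x_crit) / params.mass_step)) + 1
        masses = params.x_crit + params.mass_step * np.arange(n)
        if abs(masses[-1] - params.x_max) > 1e-9:
            raise ValueError("mass grid does not end exactly at x_max")
        ages = np.arange(params.age_first, params.age_last + 1)
        return cls(masses=masses, ages=ages, terminal_age=params.terminal_age)

    @property
    def x_crit(self) -> float:
        return float(self.masses[0])

    @property
    def mass_step(self) -> float:
        return float(self.masses[1] - self.masses[0])

    def nearest_index(self, x: float) -> int:
        """Nearest grid-mass index; exact midpoints resolve to the lower mass."""
        return int(np.argmin(np.abs(self.masses - x)))


def interpolate_F(F_next: np.ndarray, x: float, grid: StateGrid) -> float:
    """Continuation value at (possibly off-grid) mass ``x``.

    Linear between bracketing grid masses; 0 at or below the critical mass
    (dead); flat at the top of the grid (masses are clamped to x_max).
    """
    if x <= grid.x_crit:
        return 0.0
    if x >= grid.masses[-1]:
        return float(F_next[-1])
    return float(np.interp(x, grid.masses, F_next))


def _branch_future(
    trans: AnnualTransition, F_next: np.ndarray, grid: StateGrid
) -> float:
    if trans.died_of_starvation:
        return 0.0
    return interpolate_F(F_next, trans.end_mass, grid)


def _mixture_future(
    good: AnnualTransition,
    bad: AnnualTransition,
    F_next: np.ndarray,
    params: ModelParams,
    grid: StateGrid,
) -> float:
    """Survival-discounted expected continuation over the good/bad-year mixture."""
    a = params.bad_year_prob
    fg = _branch_future(good, F_next, grid) if a < 1.0 else 0.0
    fb = _branch_future(bad, F_next, grid) if a > 0.0 else 0.0
    if params.survival_eval == "nadir":
        # the annual low point: post-lactation mass for breeders, arrival
        # mass for non-breeders (same in both environmental branches)
        s = maternal_survival(good.nadir_mass, params)
        return s * ((1.0 - a) * fg + a * fb)
    sg = maternal_survival(good.end_mass, params) if a < 1.0 else 0.0
    sb = maternal_survival(bad.end_mass, params) if a > 0.0 else 0.0
    return (1.0 - a) * sg * fg + a * sb * fb


def fitness_breed(
    x: float,
    F_next: np.ndarray,
    params: ModelParams,
    grid: StateGrid,
    _trans: tuple[AnnualTransition, AnnualTransition] | None = None,
) -> float:
    """Value of breeding this year at mass ``x`` (V1).

    Current reward is the pup's survival-weighted weaning mass; the
    continuation is the survival-discounted next-year value.  A female who
    starves during the breeding stage itself loses both pup and future.
    """
    if _trans is None:
        good = annual_transition(x, True, False, params, sex_draw=None)
        bad = annual_transition(x, True, True, params, sex_draw=None)
    else:
        good, bad = _trans
    if good.starved_before_weaning():
        return 0.0
    m_p = good.wean_mass
    reward = pup_survival(m_p, params) * m_p
    return reward + _mixture_future(good, bad, F_next, params, grid)


def fitness_skip(
    x: float,
    F_next: np.ndarray,
    params: ModelParams,
    grid: StateGrid,
    _trans: tuple[AnnualTransition, AnnualTransition] | None = None,
) -> float:
    """Value of skipping this year at mass ``x`` (V2): continuation only."""
    if _trans is None:
        good = annual_transition(x, False, False, params, sex_draw=None)
        bad = annual_transition(x, False, True, params, sex_draw=None)
    else:
        good, bad = _trans
    return _mixture_future(good, bad, F_next, params, grid)


@dataclass(frozen=True)
class PolicySolution:
    """Fitness surface and breed/skip decision matrix from backward iteration.

    ``F`` has one column per decision age plus a final all-zero terminal
    column; ``decision`` is True where breeding is optimal (ties go to breed).
    """

    grid: StateGrid
    F: np.ndarray               # (n_masses, n_ages + 1)
    decision: np.ndarray        # (n_masses, n_ages), bool, True = breed
    V1: np.ndarray
    V2: np.ndarray
    params: ModelParams

    def decision_at(self, x: float, age: int) -> bool:
        """Breed (True) or skip (False) for a female of mass ``x`` at ``age``.

        Decisions are categorical, so the mass is snapped to the nearest grid
        point (exact midpoints to the lower mass).
        """
        ages = self.grid.ages
        if not ages[0] <= age <= ages[-1]:
            raise ValueError(f"age {age} outside decision ages {ages[0]}..{ages[-1]}")
        j = int(age - ages[0])
        return bool(self.decision[self.grid.nearest_index(x), j])

    def fitness_frame(self) -> pd.DataFrame:
        cols = list(self.grid.ages) + [self.grid.terminal_age]
        return pd.DataFrame(self.F, index=self.grid.masses, columns=cols)

    def decision_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.where(self.decision, "breed", "skip"),
            index=self.grid.masses,
            columns=list(self.grid.ages),
        )

    def decision_map(self) -> str:
        """Compact text map (rows = ages, columns = mass grid; B/s)."""
        lines = []
        for j, age in enumerate(self.grid.ages):
            row = "".join("B" if d else "s" for d in self.decision[:, j])
            lines.append(f"age {age:2d} {row}")
        return "\n".join(lines)

    def save(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.fitness_frame().to_csv(out / "fitness.csv", index_label="mass_kg")
        self.decision_frame().to_csv(out / "decision.csv", index_label="mass_kg")
        (out / "decision_map.txt").write_text(self.decision_map() + "\n")


def _survival_vec(x: np.ndarray, params: ModelParams) -> np.ndarray:
    """Vectorized hockey-stick maternal survival over an array of masses."""
    xc, cut, s = params.x_crit, params.x_cutoff, params.s_max
    if cut == xc:
        return np.where(x > xc, s, 0.0)
    frac = np.clip((x - xc) / (cut - xc), 0.0, 1.0)
    return np.where(x > xc, s * frac, 0.0)


def solve(params: ModelParams, grid: StateGrid | None = None) -> PolicySolution:
    """Solve for the optimal breed/skip policy by backward iteration.

    Point-estimate (mean) parameters are used throughout; see the module
    docstring.  Transitions are age-independent, so the four per-mass annual
    transitions (breed/skip x good/bad year) are computed once, summarized
    into arrays, and the Bellman sweep runs vectorized over the mass axis.
    The per-cell values equal :func:`fitness_breed` / :func:`fitness_skip`.
    """
    if grid is None:
        grid = StateGrid.from_params(params)
    masses = grid.masses
    n_x = len(masses)
    n_y = len(grid.ages)
    a = params.bad_year_prob

    def summarize(breed: bool):
        good = [annual_transition(x, breed, False, params, None) for x in masses]
        bad = [annual_transition(x, breed, True, params, None) for x in masses]
        end_g = np.array([t.end_mass for t in good])
        end_b = np.array([t.end_mass for t in bad])
        ok_g = np.array([not t.died_of_starvation for t in good])
        ok_b = np.array([not t.died_of_starvation for t in bad])
        nadir = np.array([t.nadir_mass for t in good])
        return good, end_g, end_b, ok_g, ok_b, nadir

    bg, b_end_g, b_end_b, b_ok_g, b_ok_b, b_nadir = summarize(True)
    _, s_end_g, s_end_b, s_ok_g, s_ok_b, s_nadir = summarize(False)

    viable = np.array([not t.starved_before_weaning() for t in bg])
    reward = np.array(
        [
            pup_survival(t.wean_mass, params) * t.wean_mass if v else 0.0
            for t, v in zip(bg, viable)
        ]
    )

    nadir_mode = params.survival_eval == "nadir"
    if nadir_mode:
        sb = _survival_vec(b_nadir, params)
        sk = _survival_vec(s_nadir, params)
    else:
        sb_g = _survival_vec(b_end_g, params)
        sb_b = _survival_vec(b_end_b, params)
        sk_g = _survival_vec(s_end_g, params)
        sk_b = _survival_vec(s_end_b, params)

    F = np.zeros((n_x, n_y + 1))
    V1 = np.zeros((n_x, n_y))
    V2 = np.zeros((n_x, n_y))
    decision = np.zeros((n_x, n_y), dtype=bool)

    for j in range(n_y - 1, -1, -1):
        F_next = F[:, j + 1]
        fb_g = np.interp(b_end_g, masses, F_next) * b_ok_g
        fb_b = np.interp(b_end_b, masses, F_next) * b_ok_b
        fs_g = np.interp(s_end_g, masses, F_next) * s_ok_g
        fs_b = np.interp(s_end_b, masses, F_next) * s_ok_b
        if nadir_mode:
            v1 = reward + sb * ((1.0 - a) * fb_g + a * fb_b)
            v2 = sk * ((1.0 - a) * fs_g + a * fs_b)
        else:
            v1 = reward + (1.0 - a) * sb_g * fb_g + a * sb_b * fb_b
            v2 = (1.0 - a) * sk_g * fs_g + a * sk_b * fs_b
        v1 = np.where(viable, v1, 0.0)
        V1[:, j] = v1
        V2[:, j] = v2
        decision[:, j] = v1 >= v2          # tie resolves to breed
        F[:, j] = np.maximum(v1, v2)

    return PolicySolution(
        grid=grid, F=F, decision=decision, V1=V1, V2=V2, params=params
    )


def skip_region_summary(solution: PolicySolution) -> pd.DataFrame:
    """Contiguous skip intervals of the policy surface, one row per interval.

    Columns: age, mass_lo (first skipped grid mass), mass_hi (one grid step
    past the last skipped mass), n_cells.  Empty frame for an all-breed policy.
    """
    grid = solution.grid
    step = grid.mass_step
    rows = []
    for j, age in enumerate(grid.ages):
        skip = ~solution.decision[:, j]
        i = 0
        while i < len(skip):
            if skip[i]:
                start = i
                while i < len(skip) and skip[i]:
                    i += 1
                rows.append(
                    {
                        "age": int(age),
                        "mass_lo": float(grid.masses[start]),
                        "mass_hi": float(grid.masses[i - 1] + step),
                        "n_cells": i - start,
                    }
                )
            else:
                i += 1
    return pd.DataFrame(rows, columns=["age", "mass_lo", "mass_hi", "n_cells"])
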