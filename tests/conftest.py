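"""Shared fixtures and the independent brute-force policy oracle."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from sealskip.mass_dynamics import annual_transition
from sealskip.params import ModelParams
from sealskip.sdp import StateGrid
from sealskip.survival import maternal_survival, pup_survival


@pytest.fixture
def default_params() -> ModelParams:
    return ModelParams()


@pytest.fixture
def det_params() -> ModelParams:
    """Point-estimate model: every parameter sd zeroed."""
    return ModelParams().with_means()


@pytest.fixture
def toy_params() -> ModelParams:
    """A 4-mass x 3-age grid small enough for exhaustive policy enumeration."""
    return ModelParams(
        x_crit=140.0,
        x_max=980.0,
        mass_step=280.0,
        age_first=11,
        age_last=13,
        terminal_age=14,
        x_cutoff=300.0,
        s_max=0.8,
    )


def _interp_manual(masses: np.ndarray, col: np.ndarray, x: float) -> float:
    """Linear interpolation written independently of the solver."""
    if x <= masses[0]:
        return 0.0
    if x >= masses[-1]:
        return float(col[-1])
    k = int(np.searchsorted(masses, x, side="right")) - 1
    w = (x - masses[k]) / (masses[k + 1] - masses[k])
    return float((1 - w) * col[k] + w * col[k + 1])


def brute_force_optimum(params: ModelParams) -> np.ndarray:
    """Optimal fitness surface by exhaustive enumeration of every policy matrix.

    Linear interpolation of the continuation value is a stochastic transition
    onto the two bracketing grid points, so the grid model is a finite Markov
    decision process and the pointwise maximum of the values of all 2^(n_x*n_y)
    closed-loop policies equals the Bellman optimum.  Feasible only on tiny
    grids; serves as the independent oracle for the backward-iteration solver.
    """
    grid = StateGrid.from_params(params)
    masses = grid.masses
    n_x, n_y = len(masses), len(grid.ages)
    a = params.bad_year_prob

    reward = np.zeros(n_x)
    viable = np.zeros(n_x, dtype=bool)
    s_breed = np.zeros(n_x)
    s_skip = np.zeros(n_x)
    ends = {}  # (i, breed, bad) -> (end_mass, survived_starvation)
    for i, x in enumerate(masses):
        for breed in (True, False):
            for bad in (True, False):
                t = annual_transition(x, breed, bad, params, sex_draw=None)
                ends[(i, breed, bad)] = (t.end_mass, not t.died_of_starvation)
        tb = annual_transition(x, True, False, params, sex_draw=None)
        viable[i] = not tb.starved_before_weaning()
        if viable[i]:
            reward[i] = pup_survival(tb.wean_mass, params) * tb.wean_mass
        s_breed[i] = maternal_survival(tb.nadir_mass, params)
        s_skip[i] = maternal_survival(x, params)

    def policy_value(pol: np.ndarray) -> np.ndarray:
        V = np.zeros((n_x, n_y + 1))
        for j in range(n_y - 1, -1, -1):
            col = V[:, j + 1]
            for i in range(n_x):
                breed = pol[i, j]
                if breed and not viable[i]:
                    V[i, j] = 0.0
                    continue
                future = 0.0
                for bad, w in ((False, 1.0 - a), (True, a)):
                    if w == 0.0:
                        continue
                    end, ok = ends[(i, breed, bad)]
                    if ok:
                        future += w * _interp_manual(masses, col, end)
                s = s_breed[i] if breed else s_skip[i]
                V[i, j] = (reward[i] if breed else 0.0) + s * future
        return V

    best = np.full((n_x, n_y + 1), -np.inf)
    best[:, -1] = 0.0
    for bits in itertools.product((False, True), repeat=n_x * n_y):
        pol = np.array(bits).reshape(n_x, n_y)
        best = np.maximum(best, policy_value(pol))
    return best
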