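"""Forward Monte Carlo simulation of individual lifetimes.

Each simulated female recruits at the first breeding age with a regression-
drawn initial mass, then lives through at most ten annual cycles.  Every year
she (or her strategy) decides to breed or skip, experiences a Bernoulli bad
year, runs the annual mass budget, and survives to the next year with the
mass-dependent hockey-stick probability (starvation is certain death).  Pups
survive their first year with the weaning-mass step probability.

Parameter-estimation error propagates by drawing every uncertain parameter
once per individual (default) or once per year; cohorts of such lifetimes are
summarized and compared between strategies with Cohen's d.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mass_dynamics import annual_transition, initial_mass
from .params import ModelParams, draw_individual_params
from .sdp import PolicySolution, solve
from .survival import maternal_survival, pup_survival

__all__ = [
    "AlwaysBreed",
    "ALWAYS_BREED",
    "YearEntry",
    "LifeHistoryRecord",
    "SimulationSummary",
    "simulate_individual",
    "run_cohort",
    "cohens_d",
    "skip_count_distribution",
]


class AlwaysBreed:
    """Annual-breeding strategy: breed every year regardless of state."""

    def decision_at(self, x: float, age: int) -> bool:  # noqa: ARG002
        return True


ALWAYS_BREED = AlwaysBreed()


@dataclass(frozen=True)
class YearEntry:
    age: int
    start_mass: float
    breed: bool
    bad_year: bool
    pup_born: bool
    wean_mass: float | None
    pup_survived: bool
    end_mass: float
    mother_survived: bool


@dataclass
class LifeHistoryRecord:
    """One simulated female: her yearly trajectory and lifetime totals."""

    individual_id: int
    years: list[YearEntry] = field(default_factory=list)
    age_at_death: int = 0               # last age alive
    lifetime_reproductive_output: int = 0   # pups surviving to age 1
    n_attempts: int = 0
    n_skips: int = 0
    wean_masses: list[float] = field(default_factory=list)
    wean_masses_surviving: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(y) for y in self.years])


def simulate_individual(
    policy: PolicySolution | AlwaysBreed,
    params: ModelParams,
    rng: np.random.Generator | int,
    individual_id: int = 0,
) -> LifeHistoryRecord:
    """Simulate one female lifetime under ``policy`` with the given parameters.

    ``params`` is normally a per-individual draw (sd already collapsed); with
    ``params.draw_mode == "per_year"`` a fresh draw is taken at the start of
    every year instead.  Exactly four uniform variates are consumed per year
    (bad-year, pup-sex, pup-survival, maternal-survival), so two strategies
    run from the same seed see common random numbers.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    per_year = params.draw_mode == "per_year"
    p = draw_individual_params(params, rng) if per_year else params

    rec = LifeHistoryRecord(individual_id=individual_id)
    x = initial_mass(p.age_first, p, rng=None)  # coefficients already drawn
    a = p.bad_year_prob

    for age in range(p.age_first, p.age_last + 1):
        if per_year and age > p.age_first:
            p = draw_individual_params(params, rng)
        u_bad = rng.random()
        u_sex = rng.random()
        u_pup = rng.random()
        u_surv = rng.random()
        bad = u_bad < a
        breed = bool(policy.decision_at(x, age))
        trans = annual_transition(x, breed, bad, p, sex_draw=u_sex)

        pup_born = breed and not trans.starved_before_weaning()
        pup_survived = False
        if pup_born:
            rec.wean_masses.append(trans.wean_mass)
            pup_survived = u_pup < pup_survival(trans.wean_mass, p)
            if pup_survived:
                rec.wean_masses_surviving.append(trans.wean_mass)
                rec.lifetime_reproductive_output += 1
        rec.n_attempts += int(breed)
        rec.n_skips += int(not breed)

        if trans.died_of_starvation:
            alive = False
        else:
            eval_mass = (
                trans.nadir_mass if p.survival_eval == "nadir" else trans.end_mass
            )
            alive = u_surv < maternal_survival(eval_mass, p)
        rec.years.append(
            YearEntry(
                age=age,
                start_mass=x,
                breed=breed,
                bad_year=bad,
                pup_born=pup_born,
                wean_mass=trans.wean_mass if pup_born else None,
                pup_survived=pup_survived,
                end_mass=trans.end_mass,
                mother_survived=alive,
            )
        )
        rec.age_at_death = age
        if not alive:
            break
        x = trans.end_mass
    return rec


@dataclass
class SimulationSummary:
    """Per-cohort statistics with the full per-individual table retained."""

    label: str
    n: int
    table: pd.DataFrame                  # one row per individual
    wean_masses: np.ndarray              # pooled over all attempts
    wean_masses_surviving: np.ndarray    # pooled over surviving pups only
    records: list[LifeHistoryRecord] | None = None

    @property
    def lro(self) -> np.ndarray:
        return self.table["lro"].to_numpy()

    @property
    def longevity(self) -> np.ndarray:
        return self.table["longevity"].to_numpy()

    @property
    def attempts(self) -> np.ndarray:
        return self.table["attempts"].to_numpy()

    @property
    def skips(self) -> np.ndarray:
        return self.table["skips"].to_numpy()

    def mean_wean_mass(self, which: str = "surviving") -> float:
        """Mean pup weaning mass, pooled over pups surviving to age 1
        ("surviving", the reported statistic) or over all attempts ("all")."""
        arr = self.wean_masses if which == "all" else self.wean_masses_surviving
        if len(arr) == 0:
            return float("nan")
        return float(np.mean(arr))

    def describe(self) -> pd.DataFrame:
        stats = {}
        for name in ("lro", "longevity", "attempts", "skips"):
            v = self.table[name]
            stats[name] = {"mean": v.mean(), "sd": v.std(ddof=1) if self.n > 1 else np.nan}
        stats["wean_mass"] = {
            "mean": self.mean_wean_mass(),
            "sd": float(np.std(self.wean_masses, ddof=1))
            if len(self.wean_masses) > 1
            else np.nan,
        }
        return pd.DataFrame(stats).T


def run_cohort(
    strategy: str,
    params: ModelParams,
    n: int,
    seed: int | np.random.SeedSequence,
    policy: PolicySolution | None = None,
    label: str | None = None,
    keep_records: bool = False,
) -> SimulationSummary:
    """Simulate a cohort of ``n`` independent lifetimes.

    ``strategy`` is ``"optimal"`` or ``"annual"`` (breed every year).  With
    ``params.policy_mode == "per_individual"`` (default) each individual's
    policy is re-solved from her own parameter draw, mirroring a Monte Carlo
    in which the whole model — backward iteration included — is re-run per
    simulation; passing an explicit ``policy``, or ``policy_mode == "mean"``,
    uses one point-estimate policy for the whole cohort.  Each individual
    gets her own random stream via seed spawning, so two cohorts started
    from the same seed are paired by common random numbers.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    per_individual = False
    if strategy == "optimal":
        if policy is not None:
            strat = policy
        elif params.policy_mode == "per_individual":
            per_individual = True
            strat = None
        else:
            strat = solve(params)
    elif strategy == "annual":
        strat = ALWAYS_BREED
    else:
        raise ValueError(f"unknown strategy: {strategy!r}")

    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(int(seed))
    )
    children = ss.spawn(n)
    per_year = params.draw_mode == "per_year"

    rows = []
    wean_all: list[float] = []
    wean_surv: list[float] = []
    records: list[LifeHistoryRecord] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        p = params if per_year else draw_individual_params(params, rng)
        if per_individual:
            if per_year:
                # policy draw on a spawned side-stream so the simulation
                # stream stays aligned between strategies (common random numbers)
                policy_rng = np.random.default_rng(child.spawn(1)[0])
                strat_i = solve(draw_individual_params(params, policy_rng))
            else:
                strat_i = solve(p)  # her lifetime draw is also her policy
        else:
            strat_i = strat
        rec = simulate_individual(strat_i, p, rng, individual_id=i)
        rows.append(
            {
                "id": i,
                "lro": rec.lifetime_reproductive_output,
                "longevity": rec.age_at_death,
                "attempts": rec.n_attempts,
                "skips": rec.n_skips,
                "n_pups_weaned": len(rec.wean_masses),
            }
        )
        wean_all.extend(rec.wean_masses)
        wean_surv.extend(rec.wean_masses_surviving)
        if keep_records:
            records.append(rec)

    return SimulationSummary(
        label=label or strategy,
        n=n,
        table=pd.DataFrame(rows),
        wean_masses=np.asarray(wean_all),
        wean_masses_surviving=np.asarray(wean_surv),
        records=records if keep_records else None,
    )


def cohens_d(a, b) -> float:
    """Standardized mean difference (mean_a - mean_b) / pooled SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("Cohen's d needs at least 2 values per cohort")
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        raise ValueError("pooled standard deviation is zero; d undefined")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def skip_count_distribution(summary: SimulationSummary) -> pd.Series:
    """Histogram of skip counts per individual; values sum to the cohort size."""
    counts = summary.table["skips"].value_counts().sort_index()
    counts.name = "individuals"
    counts.index.name = "skips"
    return counts
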