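"""Scenario drivers for the model's computational experiments.

Four experiment families:

* ``sweep_x_cutoff`` — how the mass at which maximal survival is reached
  shapes the skip region of the optimal policy (policy surfaces only).
* ``sweep_s_max`` — sensitivity of the policy to the maximum annual survival
  under mass-independent survival (x_cutoff = x_crit).
* ``compare_strategies`` — lifetime benefit of the optimal policy over annual
  breeding (Cohen's d on lifetime reproductive output and longevity, attempt
  and weaning-mass means, skip histogram).
* ``compare_heterogeneity`` — good- vs poor-quality foraging classes, each
  under its own optimal policy.
* ``sweep_bad_year`` — paired per-individual benefit of the optimal policy as
  the frequency of environmentally bad years rises.

Each driver optionally writes a self-describing output directory (config
echo, seeds, CSV tables) sufficient to re-run bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .montecarlo import (
    SimulationSummary,
    cohens_d,
    run_cohort,
    skip_count_distribution,
)
from .params import ModelParams, apply_heterogeneity, save_config
from .sdp import PolicySolution, skip_region_summary, solve

__all__ = [
    "StrategyComparison",
    "HeterogeneityComparison",
    "sweep_x_cutoff",
    "sweep_s_max",
    "compare_strategies",
    "compare_heterogeneity",
    "sweep_bad_year",
    "EXPERIMENT_PRESETS",
]

# Published experiment settings, one preset per scenario family.
EXPERIMENT_PRESETS: dict[str, dict] = {
    "cutoff": {"x_cutoffs": [200.0, 300.0, 400.0, 500.0], "s_max": 0.912, "bad_year_prob": 0.0},
    "smax": {"s_max_values": [0.95, 0.85, 0.75, 0.65, 0.55, 0.45], "x_cutoff": 140.0, "bad_year_prob": 0.0},
    "strategies": {"x_cutoff": 200.0, "s_max": 0.912, "bad_year_prob": 0.0, "n": 1000},
    "heterogeneity": {"x_cutoff": 200.0, "s_max": 0.912, "bad_year_prob": 0.0, "n": 1000},
    "badyear": {"probs": [0.0, 0.2, 0.4, 0.6, 0.8, 1.0], "x_cutoff": 300.0, "s_max": 0.912, "n": 1000},
}


def _echo(out_dir: str | Path | None, params: ModelParams, meta: dict) -> Path | None:
    if out_dir is None:
        return None
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(params, out / "config.yaml")
    (out / "run.json").write_text(json.dumps(meta, indent=2, default=str))
    return out


def sweep_x_cutoff(
    params: ModelParams,
    cutoffs: Sequence[float] | None = None,
    out_dir: str | Path | None = None,
) -> dict[float, PolicySolution]:
    """Solve the policy for each survival-cutoff mass (good years only)."""
    if cutoffs is None:
        cutoffs = EXPERIMENT_PRESETS["cutoff"]["x_cutoffs"]
    base = params.replace(bad_year_prob=0.0)
    solutions: dict[float, PolicySolution] = {}
    out = _echo(out_dir, base, {"experiment": "cutoff", "cutoffs": list(cutoffs)})
    for c in cutoffs:
        sol = solve(base.replace(x_cutoff=float(c)))
        solutions[float(c)] = sol
        if out is not None:
            sub = out / f"xcutoff_{int(c)}"
            sol.save(sub)
            skip_region_summary(sol).to_csv(sub / "skip_regions.csv", index=False)
    return solutions


def sweep_s_max(
    params: ModelParams,
    values: Sequence[float] | None = None,
    out_dir: str | Path | None = None,
) -> dict[float, PolicySolution]:
    """Solve the policy for each maximum survival under mass-independent survival."""
    if values is None:
        values = EXPERIMENT_PRESETS["smax"]["s_max_values"]
    base = params.replace(bad_year_prob=0.0, x_cutoff=params.x_crit)
    solutions: dict[float, PolicySolution] = {}
    out = _echo(out_dir, base, {"experiment": "smax", "values": list(values)})
    for s in values:
        sol = solve(base.replace(s_max=float(s)))
        solutions[float(s)] = sol
        if out is not None:
            sub = out / f"smax_{s:.2f}"
            sol.save(sub)
            skip_region_summary(sol).to_csv(sub / "skip_regions.csv", index=False)
    return solutions


@dataclass
class StrategyComparison:
    optimal: SimulationSummary
    annual: SimulationSummary
    d_lro: float
    d_longevity: float
    skip_histogram: pd.Series
    policy: PolicySolution

    def summary_table(self) -> pd.DataFrame:
        rows = []
        for s in (self.optimal, self.annual):
            rows.append(
                {
                    "cohort": s.label,
                    "n": s.n,
                    "mean_lro": s.lro.mean(),
                    "sd_lro": s.lro.std(ddof=1),
                    "mean_longevity": s.longevity.mean(),
                    "mean_attempts": s.attempts.mean(),
                    "sd_attempts": s.attempts.std(ddof=1),
                    "mean_wean_mass": s.mean_wean_mass(),
                    "mean_skips": s.skips.mean(),
                }
            )
        return pd.DataFrame(rows)


def compare_strategies(
    params: ModelParams,
    n: int = 1000,
    seed: int = 0,
    paired: bool = False,
    out_dir: str | Path | None = None,
) -> StrategyComparison:
    """Optimal-policy vs annual-breeding cohorts under one scenario.

    With ``paired=False`` (default) the cohorts use independent random
    streams; ``paired=True`` reuses the same per-individual seeds for both
    strategies (common random numbers).
    """
    if n < 2:
        raise ValueError("need n >= 2 to compare cohorts")
    policy = solve(params)  # point-estimate policy, kept for reference/plots
    ss = np.random.SeedSequence(int(seed))
    if paired:
        seed_opt = seed_ann = ss
    else:
        seed_opt, seed_ann = ss.spawn(2)
    mean_mode = params.policy_mode == "mean"
    opt = run_cohort(
        "optimal", params, n, seed_opt,
        policy=policy if mean_mode else None, label="optimal",
    )
    ann = run_cohort("annual", params, n, seed_ann, label="annual")
    comp = StrategyComparison(
        optimal=opt,
        annual=ann,
        d_lro=cohens_d(opt.lro, ann.lro),
        d_longevity=cohens_d(opt.longevity, ann.longevity),
        skip_histogram=skip_count_distribution(opt),
        policy=policy,
    )
    out = _echo(out_dir, params, {"experiment": "strategies", "n": n, "seed": seed, "paired": paired})
    if out is not None:
        policy.save(out / "policy")
        opt.table.to_csv(out / "cohort_optimal.csv", index=False)
        ann.table.to_csv(out / "cohort_annual.csv", index=False)
        comp.summary_table().to_csv(out / "summary.csv", index=False)
        comp.skip_histogram.to_csv(out / "skip_histogram.csv")
    return comp


@dataclass
class HeterogeneityComparison:
    good: SimulationSummary
    poor: SimulationSummary
    d_skips_poor_minus_good: float
    d_lro_good_minus_poor: float
    policies: dict[str, PolicySolution]


def compare_heterogeneity(
    params: ModelParams,
    n: int = 1000,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> HeterogeneityComparison:
    """Good- vs poor-quality classes, each simulated under its own policy."""
    if n < 2:
        raise ValueError("need n >= 2 to compare cohorts")
    ss = np.random.SeedSequence(int(seed))
    seeds = dict(zip(("good", "poor"), ss.spawn(2)))
    summaries: dict[str, SimulationSummary] = {}
    policies: dict[str, PolicySolution] = {}
    for label in ("good", "poor"):
        p_cls = apply_heterogeneity(params, label)
        policies[label] = solve(p_cls)
        summaries[label] = run_cohort(
            "optimal", p_cls, n, seeds[label],
            policy=policies[label] if p_cls.policy_mode == "mean" else None,
            label=label,
        )
    comp = HeterogeneityComparison(
        good=summaries["good"],
        poor=summaries["poor"],
        d_skips_poor_minus_good=cohens_d(summaries["poor"].skips, summaries["good"].skips),
        d_lro_good_minus_poor=cohens_d(summaries["good"].lro, summaries["poor"].lro),
        policies=policies,
    )
    out = _echo(out_dir, params, {"experiment": "heterogeneity", "n": n, "seed": seed})
    if out is not None:
        for label in ("good", "poor"):
            policies[label].save(out / f"policy_{label}")
            summaries[label].table.to_csv(out / f"cohort_{label}.csv", index=False)
    return comp


def sweep_bad_year(
    params: ModelParams,
    probs: Sequence[float] | None = None,
    n: int = 1000,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> dict[float, np.ndarray]:
    """Per-pair lifetime-output benefit of the optimal policy for each bad-year frequency.

    For every bad-year probability ``a`` the policy is re-solved (the mixture
    enters the Bellman recursion), the two strategies are run on common random
    numbers, and the per-individual difference LRO(optimal) - LRO(annual) is
    returned.
    """
    if probs is None:
        probs = EXPERIMENT_PRESETS["badyear"]["probs"]
    results: dict[float, np.ndarray] = {}
    for a in probs:
        # stream keyed by (seed, a) so a repeated probability reproduces exactly
        stream = np.random.SeedSequence([int(seed), int(round(float(a) * 1e6))])
        pa = params.replace(bad_year_prob=float(a))
        opt = run_cohort(
            "optimal", pa, n, stream,
            policy=solve(pa) if pa.policy_mode == "mean" else None,
            label=f"optimal_a{a}",
        )
        ann = run_cohort("annual", pa, n, stream, label=f"annual_a{a}")
        results[float(a)] = opt.lro - ann.lro
    out = _echo(
        out_dir, params, {"experiment": "badyear", "probs": list(probs), "n": n, "seed": seed}
    )
    if out is not None:
        df = pd.DataFrame({f"a={a}": diffs for a, diffs in results.items()})
        df.to_csv(out / "lro_benefit.csv", index=False)
    return results
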