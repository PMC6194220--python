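"""Model parameters for the elephant-seal breeding model.

Every quantity in the energy-budget and survival equations lives here as an
:class:`UncertainParam` (point estimate plus standard error) or a plain scalar,
so that a single :class:`ModelParams` object is the complete specification of a
model run.  Scenario handling (survival regime, environmental bad-year
frequency, individual-quality class) and the per-individual stochastic
parameter draws used by the Monte Carlo layer are also implemented here.

Units are kg, days and annual probabilities throughout.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterator

import numpy as np
import yaml

__all__ = [
    "UncertainParam",
    "ModelParams",
    "HeterogeneityClass",
    "HETEROGENEITY_CLASSES",
    "ConfigError",
    "load_config",
    "save_config",
    "draw_individual_params",
    "apply_heterogeneity",
]


class ConfigError(ValueError):
    """Raised for malformed or inconsistent configuration input."""


@dataclass(frozen=True)
class UncertainParam:
    """A parameter with a point estimate (``mean``) and standard error (``sd``).

    ``sd`` propagates parameter-estimation uncertainty into the Monte Carlo
    simulations; the backward-iteration solver always uses ``mean``.
    """

    mean: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ConfigError(f"sd must be >= 0, got {self.sd}")

    def draw(
        self,
        rng: np.random.Generator,
        low: float = -np.inf,
        high: float = np.inf,
        max_tries: int = 1000,
    ) -> float:
        """One truncated-normal draw, by rejection so no mass piles up at bounds."""
        if self.sd == 0.0:
            return float(min(max(self.mean, low), high))
        for _ in range(max_tries):
            v = rng.normal(self.mean, self.sd)
            if low <= v <= high:
                return float(v)
        # pathological bounds; fall back to clipping
        return float(min(max(self.mean, low), high))


def _u(mean: float, sd: float) -> UncertainParam:
    return UncertainParam(mean, sd)


# Pup first-year survival as a step function of weaning mass: (lower bound kg,
# survival probability).  The two boundary bins (certain death / certain
# survival) carry no estimation error.
DEFAULT_PUP_SURVIVAL_BINS: tuple[tuple[float, UncertainParam], ...] = (
    (0.0, _u(0.0, 0.0)),
    (66.0, _u(0.14, 0.007)),
    (80.0, _u(0.50, 0.025)),
    (95.0, _u(0.67, 0.0335)),
    (140.0, _u(0.93, 0.0465)),
    (155.0, _u(1.0, 0.0)),
)


@dataclass(frozen=True)
class ModelParams:
    """Complete parameterization of the model.

    Defaults reproduce the published point estimates and the default
    Monte-Carlo scenario (x_cutoff = 200 kg, s_max = 0.912, no bad years).
    """

    # state grid
    x_crit: float = 140.0        # starvation mass, kg
    x_max: float = 1060.0        # maximum body mass, kg
    mass_step: float = 10.0      # grid resolution, kg
    age_first: int = 4
    age_last: int = 13
    terminal_age: int = 14

    # pup mass at parturition:  p = intercept - coef * exp(-rate * x)
    pup_intercept_low: UncertainParam = _u(47.8, 3.5)
    pup_intercept_high: UncertainParam = _u(52.6, 7.2)
    pup_coef: UncertainParam = _u(107.0, 49.0)
    pup_rate: UncertainParam = _u(0.0055, 0.002)
    pup_sex_mass_threshold: float = 380.0

    # lactation: daily loss r_d = slope * m_i + intercept, over lact_days
    lact_slope: UncertainParam = _u(0.013, 0.001)
    lact_intercept: UncertainParam = _u(2.48, 0.91)
    lact_days: UncertainParam = _u(22.1, 2.3)

    # foraging gains as fractions of the mass entering the trip
    forage_breed: UncertainParam = _u(0.367, 0.03)      # post-breeding, breeders
    forage_nonbreed: UncertainParam = _u(0.5, 0.03)     # post-breeding, non-breeders
    forage_postmolt: UncertainParam = _u(0.666, 0.03)   # post-molt, everyone
    bad_year_factor: float = 0.75                       # gain multiplier in a bad year

    # molt: days d_m = slope * m_i + intercept, at molt_daily_loss kg/day
    molt_days_slope: UncertainParam = _u(0.0396, 0.008)
    molt_days_intercept: UncertainParam = _u(1.92, 4.05)
    molt_daily_loss: UncertainParam = _u(4.58, 0.17)

    # pup outcome
    pup_survival_bins: tuple[tuple[float, UncertainParam], ...] = DEFAULT_PUP_SURVIVAL_BINS
    pup_mass_cap: float = 160.0
    wean_slope: UncertainParam = _u(0.171, 0.05)
    wean_intercept: UncertainParam = _u(31.457, 24.3)

    # maternal survival (hockey stick) and environment
    s_max: float = 0.912
    x_cutoff: float = 200.0
    bad_year_prob: float = 0.0

    # initial mass at recruitment: m_i = slope * age + intercept
    init_mass_slope: UncertainParam = _u(20.2, 2.3)
    init_mass_intercept: UncertainParam = _u(346.0, 26.2)

    # behavioural switches (see docs/methods.md)
    survival_eval: str = "nadir"          # "nadir" | "end_of_year"
    draw_mode: str = "per_year"           # "per_year" | "per_lifetime"
    policy_mode: str = "per_individual"   # "per_individual" | "mean"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.x_crit < self.x_max:
            raise ConfigError(f"x_crit ({self.x_crit}) must be < x_max ({self.x_max})")
        if not (self.x_crit <= self.x_cutoff <= self.x_max):
            raise ConfigError(
                f"x_cutoff ({self.x_cutoff}) must lie in [x_crit, x_max]"
            )
        if not (0.0 <= self.s_max <= 1.0):
            raise ConfigError(f"s_max must be a probability, got {self.s_max}")
        if not (0.0 <= self.bad_year_prob <= 1.0):
            raise ConfigError(f"bad_year_prob must be a probability, got {self.bad_year_prob}")
        if self.mass_step <= 0:
            raise ConfigError("mass_step must be positive")
        if not self.age_first <= self.age_last < self.terminal_age:
            raise ConfigError("require age_first <= age_last < terminal_age")
        if self.survival_eval not in ("nadir", "end_of_year"):
            raise ConfigError(f"unknown survival_eval: {self.survival_eval!r}")
        if self.draw_mode not in ("per_lifetime", "per_year"):
            raise ConfigError(f"unknown draw_mode: {self.draw_mode!r}")
        if self.policy_mode not in ("per_individual", "mean"):
            raise ConfigError(f"unknown policy_mode: {self.policy_mode!r}")
        bounds = [b for b, _ in self.pup_survival_bins]
        survs = [s.mean for _, s in self.pup_survival_bins]
        if sorted(bounds) != list(bounds) or len(set(bounds)) != len(bounds):
            raise ConfigError("pup_survival_bins mass bounds must be strictly increasing")
        if sorted(survs) != list(survs):
            raise ConfigError("pup survival must be nondecreasing with weaning mass")
        for _, s in self.pup_survival_bins:
            if not (0.0 <= s.mean <= 1.0):
                raise ConfigError("pup survival values must be probabilities")

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        out: dict = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, UncertainParam):
                out[f.name] = {"mean": v.mean, "sd": v.sd}
            elif f.name == "pup_survival_bins":
                out[f.name] = [[b, s.mean, s.sd] for b, s in v]
            else:
                out[f.name] = v
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParams":
        known = {f.name: f for f in fields(cls)}
        kwargs: dict = {}
        for key, raw in data.items():
            if key not in known:
                raise ConfigError(f"unknown configuration key: {key!r}")
            default = getattr(cls, key, None)
            if key == "pup_survival_bins":
                try:
                    kwargs[key] = tuple(
                        (float(b), _u(float(m), float(s))) for b, m, s in raw
                    )
                except (TypeError, ValueError) as exc:
                    raise ConfigError(f"malformed pup_survival_bins: {exc}") from exc
            elif isinstance(default, UncertainParam):
                if isinstance(raw, dict):
                    extra = set(raw) - {"mean", "sd"}
                    if extra:
                        raise ConfigError(f"unknown subkeys for {key!r}: {sorted(extra)}")
                    kwargs[key] = _u(float(raw["mean"]), float(raw.get("sd", default.sd)))
                elif isinstance(raw, (list, tuple)) and len(raw) == 2:
                    kwargs[key] = _u(float(raw[0]), float(raw[1]))
                elif isinstance(raw, (int, float)):
                    kwargs[key] = _u(float(raw), default.sd)
                else:
                    raise ConfigError(f"cannot parse value for {key!r}: {raw!r}")
            elif isinstance(default, (int, float)) and not isinstance(default, bool):
                try:
                    val = type(default)(raw)
                except (TypeError, ValueError) as exc:
                    raise ConfigError(f"cannot parse value for {key!r}: {raw!r}") from exc
                kwargs[key] = val
            else:
                kwargs[key] = raw
        return cls(**kwargs)

    def replace(self, **changes) -> "ModelParams":
        return dataclasses.replace(self, **changes)

    def with_means(self) -> "ModelParams":
        """Copy with every sd zeroed (deterministic point-estimate model)."""
        changes: dict = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, UncertainParam):
                changes[f.name] = _u(v.mean, 0.0)
            elif f.name == "pup_survival_bins":
                changes[f.name] = tuple((b, _u(s.mean, 0.0)) for b, s in v)
        return self.replace(**changes)


@dataclass(frozen=True)
class HeterogeneityClass:
    """Persistent individual-quality class, expressed as foraging-gain fractions.

    Quality classes split the plausible range of the foraging mass-gain
    fractions into an upper ("good") and lower ("poor") half; everything else
    about the model is shared.
    """

    label: str
    forage_breed: UncertainParam | None = None
    forage_nonbreed: UncertainParam | None = None
    forage_postmolt: UncertainParam | None = None


HETEROGENEITY_CLASSES: dict[str, HeterogeneityClass] = {
    "baseline": HeterogeneityClass("baseline"),
    "good": HeterogeneityClass(
        "good",
        forage_breed=_u(0.4, 0.015),
        forage_nonbreed=_u(0.55, 0.015),
        forage_postmolt=_u(0.7, 0.015),
    ),
    "poor": HeterogeneityClass(
        "poor",
        forage_breed=_u(0.33, 0.015),
        forage_nonbreed=_u(0.45, 0.015),
        forage_postmolt=_u(0.63, 0.015),
    ),
}


def apply_heterogeneity(
    params: ModelParams, cls: HeterogeneityClass | str
) -> ModelParams:
    """Return ``params`` with the foraging fractions of a quality class applied.

    Bad-year gains are always derived downstream as ``bad_year_factor`` times
    the (possibly overridden) good-year fraction, so the class only needs to
    restate the good-year fractions.
    """
    if isinstance(cls, str):
        try:
            cls = HETEROGENEITY_CLASSES[cls]
        except KeyError:
            raise ConfigError(
                f"unknown heterogeneity class: {cls!r} "
                f"(expected one of {sorted(HETEROGENEITY_CLASSES)})"
            ) from None
    changes = {}
    for name in ("forage_breed", "forage_nonbreed", "forage_postmolt"):
        override = getattr(cls, name)
        if override is not None:
            changes[name] = override
    return params.replace(**changes) if changes else params


def load_config(path: str | Path | None = None) -> ModelParams:
    """Build :class:`ModelParams` from a YAML file, or pure defaults if None.

    Unknown keys are rejected with a :class:`ConfigError` naming the key.
    """
    if path is None:
        return ModelParams()
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
    if data is None:
        return ModelParams()
    if not isinstance(data, dict):
        raise ConfigError(f"top level of {path} must be a mapping")
    return ModelParams.from_dict(data)


def save_config(params: ModelParams, path: str | Path) -> None:
    """Write a config echo (YAML for .yml/.yaml, else JSON) for provenance."""
    path = Path(path)
    data = params.to_dict()
    if path.suffix in (".yml", ".yaml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2))


# Fields drawn per individual, with their physical truncation bounds.
# Regression intercepts are unbounded (downstream formulas floor derived
# quantities where needed); rates, durations and fractions cannot go negative.
_DRAW_BOUNDS: dict[str, tuple[float, float]] = {
    "pup_intercept_low": (-np.inf, np.inf),
    "pup_intercept_high": (-np.inf, np.inf),
    "pup_coef": (-np.inf, np.inf),
    "pup_rate": (0.0, np.inf),
    "lact_slope": (0.0, np.inf),
    "lact_intercept": (-np.inf, np.inf),
    "lact_days": (0.0, np.inf),
    "forage_breed": (0.0, np.inf),
    "forage_nonbreed": (0.0, np.inf),
    "forage_postmolt": (0.0, np.inf),
    "molt_days_slope": (0.0, np.inf),
    "molt_days_intercept": (-np.inf, np.inf),
    "molt_daily_loss": (0.0, np.inf),
    "wean_slope": (0.0, np.inf),
    "wean_intercept": (-np.inf, np.inf),
    "init_mass_slope": (0.0, np.inf),
    "init_mass_intercept": (-np.inf, np.inf),
}


def draw_individual_params(
    params: ModelParams, rng: np.random.Generator | int
) -> ModelParams:
    """One stochastic realization of every uncertain parameter.

    Each :class:`UncertainParam` is replaced by a single truncated-normal draw
    (sd set to 0 in the result, so downstream code sees a deterministic
    parameter set).  Probabilities are truncated to [0, 1] and physically
    nonnegative quantities to [0, inf).  Deterministic for a given generator
    state or integer seed.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    changes: dict = {}
    for name, (low, high) in _DRAW_BOUNDS.items():
        up: UncertainParam = getattr(params, name)
        changes[name] = _u(up.draw(rng, low, high), 0.0)
    # bins are drawn jointly and re-drawn (rarely) if the step function would
    # lose monotonicity, keeping the survival-nondecreasing invariant intact
    for _ in range(100):
        drawn = [s.draw(rng, 0.0, 1.0) for _, s in params.pup_survival_bins]
        if all(a <= b for a, b in zip(drawn, drawn[1:])):
            break
    else:
        drawn = list(np.maximum.accumulate(drawn))
    changes["pup_survival_bins"] = tuple(
        (b, _u(v, 0.0)) for (b, _), v in zip(params.pup_survival_bins, drawn)
    )
    return params.replace(**changes)


def iter_uncertain_fields(params: ModelParams) -> Iterator[tuple[str, UncertainParam]]:
    for f in fields(params):
        v = getattr(params, f.name)
        if isinstance(v, UncertainParam):
            yield f.name, v
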