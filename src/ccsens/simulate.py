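"""Synthetic cohort generator.

Emulates the statistical structure of a strain-panel sensitization study:
~59 inbred strains (Collaborative Cross + founders), two treatment arms,
nine test days, strain / mouse / residual variance components, a
cumulative sensitization ramp across the five cocaine exposures, a
conditioned-activation shift on the day-12 saline challenge, an
expression shift on the day-19 post-withdrawal challenge, and additive
sex and site effects.

Generative model for the distance of mouse m (strain s) on day d::

    y_md = mu + a_s + b_s * k(d) + u_m + delta_d + drug(d) + sex + site + e_md

with a_s ~ N(0, var_strain), b_s ~ N(0, var_strain_slope),
u_m ~ N(0, var_mouse), e_md ~ N(0, var_resid), k(d) the 0-based cocaine
exposure index (0 off cocaine days and in the saline arm), and, in the
cocaine arm only::

    drug(d) = acute + cumulative_ramp(k)      on exposure days 3,5,7,9,11
    drug(12) = conditioned_effect             (saline challenge)
    drug(19) = acute + cumulative_ramp(5) + expression_effect

Distances are floored at zero after noise (truncation is counted in the
returned TrueParameters since it slightly biases moments at extreme
configurations). Everything is deterministic given the seed.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortTable, make_cohort
from .phenotypes import PHENOTYPE_DAYS, auc_weights, variable_day_set
from .protocol import SENSITIZATION_DAYS, TEST_DAYS

_N_DAYS = len(TEST_DAYS)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator (distances in cm)."""

    n_strains: int = 59
    mice_per_strain_per_arm: int = 8
    var_strain: float = 2.25e6          # between-strain baseline variance, cm^2
    var_strain_slope: float = 2.25e4    # strain-specific sensitization-slope variance
    var_mouse: float = 6.4e5            # per-mouse random-intercept variance
    var_resid: float = 1.0e6            # day-level residual variance
    grand_mean: float = 6000.0
    day_effects: tuple[float, ...] = (0.0, -500.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    cocaine_acute_effect: float = 4000.0
    #: per-exposure increments; cumulative sum gives the ramp at exposures 1..5
    ramp: tuple[float, ...] = (0.0, 800.0, 600.0, 400.0, 300.0)
    expression_effect: float = 0.0
    conditioned_effect: float = 1000.0
    sex_effect: float = 500.0           # additive F - M shift
    site_effect: float = 800.0          # additive JAX - UNC shift
    sex_ratio: float = 0.5              # fraction female within each strain x arm
    site_assignment: str = "JAX"        # "JAX", "UNC", or "split"
    body_weight_mean: float = 22.0      # grams at day 1
    body_weight_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("var_strain", "var_strain_slope", "var_mouse"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.var_resid <= 0:
            raise ConfigError("var_resid must be > 0")
        if len(self.ramp) != 5:
            raise ConfigError("ramp must have one increment per cocaine exposure (5)")
        if len(self.day_effects) != _N_DAYS:
            raise ConfigError(f"day_effects must have length {_N_DAYS}")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ConfigError("sex_ratio must be in [0, 1]")
        if self.site_assignment not in ("JAX", "UNC", "split"):
            raise ConfigError("site_assignment must be 'JAX', 'UNC' or 'split'")
        if self.n_strains < 1 or self.mice_per_strain_per_arm < 1:
            raise ConfigError("need at least one strain and one mouse per arm")
        self.ramp = tuple(float(x) for x in self.ramp)
        self.day_effects = tuple(float(x) for x in self.day_effects)

    def to_json(self, path: str | Path) -> None:
        payload = {"schema_version": "1.0", **asdict(self)}
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        payload = json.loads(Path(path).read_text())
        payload.pop("schema_version", None)
        payload["ramp"] = tuple(payload.get("ramp", ()))
        payload["day_effects"] = tuple(payload.get("day_effects", ()))
        return cls(**payload)


@dataclass
class TrueParameters:
    """Realized random effects and analytic expectations, kept for
    recovery tests against the fitted estimates."""

    strain_effects: dict[str, float]
    strain_slopes: dict[str, float]
    mouse_effects: dict[str, float]
    h2_expectation: dict[str, float]
    n_truncated: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _exposure_multiplier(day: int) -> float:
    """0-based exposure index k(d): 0,1,2,3,4 across days 3..11; 4 on day 19."""
    if day in SENSITIZATION_DAYS:
        return float(SENSITIZATION_DAYS.index(day))
    if day == 19:
        return 4.0
    return 0.0


def _drug_effect(config: SimulationConfig, day: int) -> float:
    ramp_cum = np.cumsum(config.ramp)
    if day in SENSITIZATION_DAYS:
        k = SENSITIZATION_DAYS.index(day)
        return config.cocaine_acute_effect + float(ramp_cum[k])
    if day == 12:
        return config.conditioned_effect
    if day == 19:
        return config.cocaine_acute_effect + float(ramp_cum[-1]) + config.expression_effect
    return 0.0


def _strain_names(n: int) -> list[str]:
    return [f"SIM{j:03d}" for j in range(1, n + 1)]


def simulate_cohort(config: SimulationConfig) -> tuple[CohortTable, TrueParameters]:
    """Draw one cohort (both treatment arms) under the generative model."""
    rng = np.random.default_rng(config.seed)
    strains = _strain_names(config.n_strains)
    a = rng.normal(0.0, np.sqrt(config.var_strain), size=config.n_strains)
    b = rng.normal(0.0, np.sqrt(config.var_strain_slope), size=config.n_strains)

    n_per_arm = config.mice_per_strain_per_arm
    n_f = int(round(config.sex_ratio * n_per_arm))

    day_effect = dict(zip(TEST_DAYS, config.day_effects))
    rows: list[dict] = []
    mouse_effects: dict[str, float] = {}
    n_trunc = 0
    for si, strain in enumerate(strains):
        for arm in ("cocaine", "saline"):
            for i in range(n_per_arm):
                mouse_id = f"{strain}-{arm[0].upper()}{i + 1:02d}"
                sex = "F" if i < n_f else "M"
                if config.site_assignment == "split":
                    site = "JAX" if i % 2 == 0 else "UNC"
                else:
                    site = config.site_assignment
                u = rng.normal(0.0, np.sqrt(config.var_mouse))
                mouse_effects[mouse_id] = u
                weight = max(rng.normal(config.body_weight_mean, config.body_weight_sd), 1.0)
                eps = rng.normal(0.0, np.sqrt(config.var_resid), size=_N_DAYS)
                for di, day in enumerate(TEST_DAYS):
                    mean = (
                        config.grand_mean
                        + a[si]
                        + u
                        + day_effect[day]
                        + (config.sex_effect if sex == "F" else 0.0)
                        + (config.site_effect if site == "JAX" else 0.0)
                    )
                    if arm == "cocaine":
                        mean += _drug_effect(config, day) + b[si] * _exposure_multiplier(day)
                    y = mean + eps[di]
                    if y < 0:
                        y = 0.0
                        n_trunc += 1
                    rows.append(
                        {
                            "mouse_id": mouse_id,
                            "strain": strain,
                            "sex": sex,
                            "site": site,
                            "treatment_group": arm,
                            "day": day,
                            "distance": y,
                            "body_weight": weight,
                        }
                    )

    table = make_cohort(pd.DataFrame(rows), source=f"simulated(seed={config.seed})")
    h2_exp = {}
    for variable in PHENOTYPE_DAYS:
        try:
            h2_exp[variable] = plugin_h2_expectation(config, variable)
        except ConfigError:
            pass
    truth = TrueParameters(
        strain_effects=dict(zip(strains, map(float, a))),
        strain_slopes=dict(zip(strains, map(float, b))),
        mouse_effects={k: float(v) for k, v in mouse_effects.items()},
        h2_expectation=h2_exp,
        n_truncated=n_trunc,
    )
    return table, truth


def _variable_coefficients(variable: str) -> np.ndarray:
    """Coefficients c_d over the nine test days so that the derived value
    equals sum_d c_d * D_d."""
    c = np.zeros(_N_DAYS)
    days = {day: i for i, day in enumerate(TEST_DAYS)}
    if variable == "auc":
        for w, day in zip(auc_weights("trapezoid"), SENSITIZATION_DAYS):
            c[days[day]] = w
        return c
    dset = sorted(variable_day_set(variable))
    if not dset:
        raise ConfigError(f"variable {variable!r} has no day-set definition")
    if len(dset) == 1:
        c[days[dset[0]]] = 1.0
    else:
        earlier, later = dset
        c[days[later]] = 1.0
        c[days[earlier]] = -1.0
    return c


def variable_variances(config: SimulationConfig, variable: str) -> tuple[float, float]:
    """Analytic (between-strain, within-strain) variance of a derived
    variable in the cocaine arm under the generative model."""
    c = _variable_coefficients(variable)
    s = float(c.sum())
    kappa = np.array([_exposure_multiplier(d) for d in TEST_DAYS])
    slope_coef = float(c @ kappa)
    between = s * s * config.var_strain + slope_coef * slope_coef * config.var_strain_slope
    within = s * s * config.var_mouse + float(c @ c) * config.var_resid
    r = config.sex_ratio
    within += s * s * config.sex_effect**2 * r * (1.0 - r)
    if config.site_assignment == "split":
        within += s * s * config.site_effect**2 * 0.25
    return between, within


def plugin_h2_expectation(config: SimulationConfig, variable: str) -> float:
    """Plug-in expectation of the mean-squares heritability estimator under
    balanced one-way sampling: (s2_B + s2_W / n) / (s2_B + s2_W)."""
    n = config.mice_per_strain_per_arm
    if not isinstance(n, (int, np.integer)):
        raise ConfigError("plug-in expectation requires a balanced design")
    between, within = variable_variances(config, variable)
    total = between + within
    if total <= 0:
        raise ConfigError("variable has zero variance under this configuration")
    return (between + within / n) / total


def default_config() -> SimulationConfig:
    """The versioned default configuration shipped with the package."""
    from importlib.resources import files

    path = files("ccsens.data").joinpath("default_config.json")
    payload = json.loads(path.read_text())
    payload.pop("schema_version", None)
    payload["ramp"] = tuple(payload["ramp"])
    payload["day_effects"] = tuple(payload["day_effects"])
    return SimulationConfig(**payload)
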