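"""Synthetic NMR-style time courses for testing the full analysis pipeline.

The generator emulates what the migration experiments actually measure:
species mole fractions derived from well-separated acetyl ^1H singlets,
sampled over roughly four weeks, under a buffer whose pH drifts from ~7.95
at dissolution toward 7.70-7.75 as acetic acid is released, with additive
integration noise on each fraction.

Defaults mirror the study conditions: 25 geometrically spaced sample times
from 1 h to 672 h (four weeks, denser early to catch the fast O3<->O2
equilibration), a linear pH drift 7.95 -> 7.75 over the four weeks, and
Gaussian noise of 0.005 absolute mole fraction (a plausible ^1H-integral
precision; synthetic, not a measured value).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .fitting import FitConfig, TimecourseDataset, fit_rate_constants
from .kinetics import (
    ConfigurationError,
    PhProfile,
    RateConstants,
    equilibrium_O2_fraction,
    normalize_model_kind,
    simulate_closed_form,
    species_for,
)

__all__ = [
    "PhDriftModel",
    "NoiseModel",
    "GeneratorConfig",
    "default_sample_times",
    "ph_drift_profile",
    "initial_state_for",
    "generate_dataset",
    "recovery_experiment",
]

START_PRESETS = ("from_1a", "from_1b", "ggm_default")

# Acetyl-bearing GGM units at t0: O2:O3 = 61:39 with no O6 signal initially;
# never-acetylated mannoses are invisible to acetyl-peak NMR and excluded.
GGM_DEFAULT_START = (0.39, 0.61, 0.0, 0.0)

DEFAULT_HORIZON_H = 672.0  # four weeks


@dataclass(frozen=True)
class PhDriftModel:
    """Parametric pH-versus-time model for the buffer.

    ``constant`` holds ph_start; ``linear`` interpolates ph_start -> ph_end
    over the horizon; ``exponential_approach`` relaxes from ph_start toward
    ph_end with the given timescale (hours).
    """

    kind: str = "linear"
    ph_start: float = 7.95
    ph_end: float = 7.75
    horizon: float = DEFAULT_HORIZON_H
    timescale: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "linear", "exponential_approach"):
            raise ConfigurationError(f"unknown pH drift kind {self.kind!r}")
        if not 0 <= self.ph_start <= 14:
            raise ConfigurationError(f"ph_start out of [0, 14]: {self.ph_start}")
        if self.kind != "constant":
            if not 0 <= self.ph_end <= self.ph_start:
                raise ConfigurationError(
                    "drift requires 0 <= ph_end <= ph_start, got "
                    f"({self.ph_start}, {self.ph_end})"
                )
        if self.horizon <= 0:
            raise ConfigurationError("horizon must be positive")
        if self.kind == "exponential_approach" and (
            self.timescale is None or self.timescale <= 0
        ):
            raise ConfigurationError("exponential_approach requires a positive timescale")


def ph_drift_profile(model: PhDriftModel, n_points: int = 50) -> PhProfile:
    """Sample a drift model on a uniform time grid into a pH profile."""
    if model.kind == "constant":
        return PhProfile.constant(model.ph_start)
    if n_points < 2:
        raise ConfigurationError("drift profiles need at least 2 points")
    times = np.linspace(0.0, model.horizon, n_points)
    if model.kind == "linear":
        ph = np.linspace(model.ph_start, model.ph_end, n_points)
    else:
        tau = float(model.timescale)
        if math.isinf(tau):
            ph = np.full(n_points, model.ph_start)
        else:
            ph = model.ph_end + (model.ph_start - model.ph_end) * np.exp(-times / tau)
    return PhProfile(times=times, ph=ph)


@dataclass(frozen=True)
class NoiseModel:
    """Additive measurement-noise model on the mole fractions."""

    kind: str = "gaussian"
    sigma: float = 0.005
    clip_to_simplex: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "gaussian"):
            raise ConfigurationError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ConfigurationError("noise sigma must be >= 0")


def default_sample_times(
    n_points: int = 25, first: float = 1.0, horizon: float = DEFAULT_HORIZON_H
) -> np.ndarray:
    """Geometric sampling grid, denser early to resolve the fast exchange."""
    return np.geomspace(first, horizon, n_points)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full description of one synthetic experiment."""

    model_kind: str = "trisaccharide"
    constants: RateConstants = field(
        default_factory=lambda: RateConstants(2.06e-3, 1.88, 1.01, 1.93e-3, 1.56e-3)
    )
    start: str | Sequence[float] = "from_1a"
    initial_hydrolyzed_fraction: float = 0.0
    sample_times: np.ndarray | None = None
    ph_model: PhDriftModel = field(default_factory=PhDriftModel)
    noise: NoiseModel = field(default_factory=NoiseModel)
    label: str = ""

    def __post_init__(self) -> None:
        kind = normalize_model_kind(self.model_kind)
        object.__setattr__(self, "model_kind", kind)
        if not 0 <= self.initial_hydrolyzed_fraction < 1:
            raise ConfigurationError("initial_hydrolyzed_fraction must lie in [0, 1)")
        times = (
            default_sample_times(horizon=self.ph_model.horizon)
            if self.sample_times is None
            else np.asarray(self.sample_times, dtype=float)
        )
        if np.any(times < 0) or np.any(times > self.ph_model.horizon + 1e-9):
            raise ConfigurationError("sample_times must lie in [0, ph_model.horizon]")
        object.__setattr__(self, "sample_times", times)


def initial_state_for(config: GeneratorConfig) -> np.ndarray:
    """Resolve the starting state vector of a generator configuration.

    Presets: ``from_1a`` and ``from_1b`` start pure in the respective
    compound; ``ggm_default`` starts at the 61:39 O2:O3 split with no O6
    signal.  A nonzero ``initial_hydrolyzed_fraction`` moves that fraction
    into the singly acetylated pair 1d/1e at the O2:O3 equilibrium split
    (trisaccharide) or into the deacetylated unit D (GGM), emulating the
    hydrolysis already seen at the first measurement point.
    """
    species = species_for(config.model_kind)
    h = config.initial_hydrolyzed_fraction
    if isinstance(config.start, str):
        if config.start not in START_PRESETS:
            raise ConfigurationError(
                f"unknown start preset {config.start!r}; expected one of {START_PRESETS}"
            )
        state = np.zeros(len(species))
        if config.start == "ggm_default":
            if config.model_kind != "ggm":
                raise ConfigurationError("ggm_default start requires the ggm model")
            state[:] = GGM_DEFAULT_START
            if h > 0:
                state *= 1.0 - h
                state[species.index("D")] = h
        else:
            if config.model_kind != "trisaccharide":
                raise ConfigurationError(
                    f"{config.start!r} start requires the trisaccharide model"
                )
            state[species.index(config.start.removeprefix("from_"))] = 1.0 - h
            if h > 0:
                f_o2 = equilibrium_O2_fraction(config.constants)
                state[species.index("1e")] += h * f_o2
                state[species.index("1d")] += h * (1.0 - f_o2)
        return state
    state = np.asarray(config.start, dtype=float)
    if state.shape != (len(species),):
        raise ConfigurationError(
            f"explicit start state must have length {len(species)} for {config.model_kind!r}"
        )
    return state


def generate_dataset(config: GeneratorConfig) -> TimecourseDataset:
    """Simulate the exact trajectory, then apply the configured noise.

    Deterministic given the noise seed.  Noisy fractions are always clipped
    to [0, 1]; with ``clip_to_simplex`` each row is additionally rescaled
    back to the (conserved) total of the clean trajectory.
    """
    profile = ph_drift_profile(config.ph_model)
    initial_state = initial_state_for(config)
    trajectory = simulate_closed_form(
        config.constants, initial_state, profile, config.sample_times, config.model_kind
    )
    clean = trajectory.states
    if config.noise.kind == "none" or config.noise.sigma == 0.0:
        observations = clean.copy()
    else:
        rng = np.random.default_rng(config.noise.seed)
        observations = np.clip(
            clean + rng.normal(0.0, config.noise.sigma, size=clean.shape), 0.0, 1.0
        )
        if config.noise.clip_to_simplex:
            totals = clean.sum(axis=1)
            row_sums = observations.sum(axis=1)
            nonzero = row_sums > 0
            observations[nonzero] *= (totals[nonzero] / row_sums[nonzero])[:, None]
            observations = np.clip(observations, 0.0, 1.0)

    label = config.label or (
        f"synthetic {config.model_kind} ({config.start if isinstance(config.start, str) else 'custom start'})"
    )
    return TimecourseDataset(
        model_kind=config.model_kind,
        sample_times=config.sample_times,
        observations=observations,
        observed_species=species_for(config.model_kind),
        ph_profile=profile,
        initial_state=initial_state,
        label=label,
    )


def recovery_experiment(
    config: GeneratorConfig | Sequence[GeneratorConfig],
    fit_config: FitConfig,
    n_replicates: int,
    seed: int = 0,
) -> dict:
    """Repeatedly generate noisy datasets, refit, and score parameter recovery.

    ``config`` may be a single generator configuration or a sequence; with a
    sequence, each replicate generates one dataset per configuration and fits
    them jointly (all configurations must share the same true constants).
    Reports, per free parameter: relative bias, relative RMSE, median
    absolute relative error, and coverage of the +-2 standard-error interval.
    Individual fit failures are recorded and counted, not fatal.
    """
    if n_replicates < 1:
        raise ConfigurationError("n_replicates must be >= 1")
    configs = [config] if isinstance(config, GeneratorConfig) else list(config)
    if not configs:
        raise ConfigurationError("at least one generator configuration is required")
    truth = configs[0].constants
    for other in configs[1:]:
        if other.constants != truth:
            raise ConfigurationError("joint recovery requires shared true constants")

    seed_seq = np.random.SeedSequence(seed)
    replicate_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(n_replicates)]

    free = fit_config.free_parameters
    estimates: dict[str, list[float]] = {name: [] for name in free}
    covered: dict[str, list[bool]] = {name: [] for name in free}
    failures: list[dict] = []
    replicate_records: list[dict] = []

    for rep, rep_seed in enumerate(replicate_seeds):
        datasets = []
        for k, cfg in enumerate(configs):
            noisy = replace(cfg, noise=replace(cfg.noise, seed=rep_seed + k))
            datasets.append(generate_dataset(noisy))
        try:
            result = fit_rate_constants(datasets, fit_config)
        except Exception as exc:  # noqa: BLE001 - failures are reported, not raised
            failures.append({"replicate": rep, "error": str(exc)})
            continue
        record = {"replicate": rep, "ssq": result.ssq, "estimates": result.estimates.as_dict()}
        for name in free:
            est = getattr(result.estimates, name)
            estimates[name].append(est)
            se = result.standard_errors.get(name)
            if se is not None:
                covered[name].append(abs(est - getattr(truth, name)) <= 2.0 * se)
        replicate_records.append(record)

    per_parameter = {}
    for name in free:
        true_value = getattr(truth, name)
        values = np.array(estimates[name])
        if values.size and true_value > 0:
            rel_err = (values - true_value) / true_value
            per_parameter[name] = {
                "true_value": true_value,
                "n_fits": int(values.size),
                "bias_rel": float(rel_err.mean()),
                "rmse_rel": float(np.sqrt(np.mean(rel_err**2))),
                "median_abs_rel_error": float(np.median(np.abs(rel_err))),
                "coverage_2se": float(np.mean(covered[name])) if covered[name] else None,
            }
        else:
            per_parameter[name] = {
                "true_value": true_value,
                "n_fits": int(values.size),
                "bias_rel": None,
                "rmse_rel": None,
                "median_abs_rel_error": None,
                "coverage_2se": None,
            }

    return {
        "n_replicates": n_replicates,
        "n_failed": len(failures),
        "failures": failures,
        "seed": seed,
        "truth": truth.as_dict(),
        "per_parameter": per_parameter,
        "replicates": replicate_records,
    }
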