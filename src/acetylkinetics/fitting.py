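"""ODE-constrained least-squares estimation of migration/hydrolysis constants.

The estimator minimises the unweighted sum of squared residuals

    SSQ = sum_t sum_i (c_model(i, t) - c_observed(i, t))^2

over one or more time-course datasets simulated from their own initial state
and pH log, with a simplex (Nelder-Mead) stage for robustness followed by a
Levenberg-Marquardt-style least-squares refinement.  Optimisation runs in
log10 parameter space because the constants span about three decades.
Standard errors come from the linearised covariance s^2 (J^T J)^-1 with J by
central finite differences of the simulated observations.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares, minimize

from .kinetics import (
    ConfigurationError,
    IntegrationError,
    PARAMETER_NAMES,
    PhProfile,
    RateConstants,
    normalize_model_kind,
    simulate,
    simulate_closed_form,
    species_for,
)

__all__ = [
    "TimecourseDataset",
    "FitConfig",
    "FitError",
    "FitResult",
    "ssq_objective",
    "fit_rate_constants",
    "linearized_standard_errors",
    "degree_of_explanation",
]


class FitError(ConfigurationError):
    """Raised when no optimisation start converges."""


@dataclass(frozen=True)
class TimecourseDataset:
    """Observed species fractions at sample times, with pH log and metadata.

    ``observations`` is a (time x observed species) array of mole fractions;
    missing values are NaN and are excluded from the objective.
    ``initial_state`` is the full-length state vector the simulation starts
    from (observed or assumed at t = 0).
    """

    model_kind: str
    sample_times: np.ndarray
    observations: np.ndarray
    observed_species: tuple[str, ...]
    ph_profile: PhProfile
    initial_state: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        kind = normalize_model_kind(self.model_kind)
        species = species_for(kind)
        observed = tuple(self.observed_species)
        unknown = [s for s in observed if s not in species]
        if unknown:
            raise ValueError(f"observed species {unknown} not in {kind!r} model {species}")
        times = np.asarray(self.sample_times, dtype=float)
        obs = np.asarray(self.observations, dtype=float)
        if times.ndim != 1:
            raise ValueError("sample_times must be 1-D")
        if np.any(np.diff(times) < 0):
            raise ValueError("sample_times must be non-decreasing")
        if obs.shape != (times.size, len(observed)):
            raise ValueError(
                f"observations shape {obs.shape} does not match "
                f"{times.size} times x {len(observed)} observed species"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            if np.any((obs < -1e-9) | (obs > 1 + 1e-9)):
                raise ValueError("observations must lie in [0, 1]")
            row_sums = np.nansum(obs, axis=1)
        # slack accommodates additive measurement noise across many species
        bad = np.nonzero(row_sums > 1 + 0.05)[0]
        if bad.size:
            raise ValueError(f"observation rows {bad.tolist()} sum to more than 1")
        c0 = np.asarray(self.initial_state, dtype=float)
        if c0.shape != (len(species),):
            raise ValueError(f"initial_state must have length {len(species)}")
        object.__setattr__(self, "model_kind", kind)
        object.__setattr__(self, "sample_times", times)
        object.__setattr__(self, "observations", obs)
        object.__setattr__(self, "observed_species", observed)
        object.__setattr__(self, "initial_state", c0)

    @property
    def n_observations(self) -> int:
        return int(np.sum(~np.isnan(self.observations)))


_DEFAULT_BOUNDS = (1e-8, 1e2)


@dataclass(frozen=True)
class FitConfig:
    """Which constants are free, how they start, and how to optimise them."""

    free_parameters: tuple[str, ...] = PARAMETER_NAMES
    locked_values: Mapping[str, float] = field(default_factory=dict)
    initial_guess: Mapping[str, float] = field(default_factory=dict)
    bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    optimizer_stages: tuple[str, ...] = ("simplex", "levenberg_marquardt")
    ftol: float = 1e-12
    xtol: float = 1e-10
    max_iterations: int = 2000
    multistart_count: int = 5
    seed: int = 0
    simulator: str = "closed_form"  # or "bdf"

    def __post_init__(self) -> None:
        free = tuple(self.free_parameters)
        locked = dict(self.locked_values)
        overlap = set(free) & set(locked)
        if overlap:
            raise ConfigurationError(f"parameters both free and locked: {sorted(overlap)}")
        covered = set(free) | set(locked)
        if covered != set(PARAMETER_NAMES):
            missing = set(PARAMETER_NAMES) - covered
            extra = covered - set(PARAMETER_NAMES)
            raise ConfigurationError(
                f"free + locked must cover exactly {PARAMETER_NAMES}; "
                f"missing {sorted(missing)}, unknown {sorted(extra)}"
            )
        if not free:
            raise ConfigurationError("at least one parameter must be free")
        for name, (lo, hi) in dict(self.bounds).items():
            if lo < 0 or hi <= lo:
                raise ConfigurationError(f"invalid bounds for {name}: ({lo}, {hi})")
        for stage in self.optimizer_stages:
            if stage not in ("simplex", "levenberg_marquardt"):
                raise ConfigurationError(f"unknown optimizer stage {stage!r}")
        if self.simulator not in ("closed_form", "bdf"):
            raise ConfigurationError(f"unknown simulator {self.simulator!r}")
        object.__setattr__(self, "free_parameters", free)
        object.__setattr__(self, "locked_values", locked)
        object.__setattr__(self, "initial_guess", dict(self.initial_guess))
        object.__setattr__(self, "bounds", dict(self.bounds))
        object.__setattr__(self, "optimizer_stages", tuple(self.optimizer_stages))

    def bounds_for(self, name: str) -> tuple[float, float]:
        return self.bounds.get(name, _DEFAULT_BOUNDS)

    def guess_for(self, name: str) -> float:
        if name in self.initial_guess:
            return float(self.initial_guess[name])
        lo, hi = self.bounds_for(name)
        return math.sqrt(max(lo, 1e-30) * hi)


@dataclass(frozen=True)
class FitResult:
    """Estimated constants with linearised uncertainties and diagnostics."""

    estimates: RateConstants
    standard_errors: dict[str, float | None]
    ssq: float
    degree_of_explanation: float
    n_observations: int
    converged: bool
    iterations: int
    stage_log: tuple[dict, ...]

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates.as_dict(),
            "standard_errors": self.standard_errors,
            "ssq": self.ssq,
            "degree_of_explanation": self.degree_of_explanation,
            "n_observations": self.n_observations,
            "converged": self.converged,
            "iterations": self.iterations,
            "stage_log": list(self.stage_log),
        }

    def to_json(self, **kwargs) -> str:
        def _default(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            raise TypeError(f"not JSON serialisable: {type(obj)}")

        return json.dumps(self.to_dict(), default=_default, **kwargs)


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------

def _predict_observations(
    constants: RateConstants, dataset: TimecourseDataset, simulator: str
) -> np.ndarray:
    sim = simulate_closed_form if simulator == "closed_form" else simulate
    try:
        trajectory = sim(
            constants,
            dataset.initial_state,
            dataset.ph_profile,
            dataset.sample_times,
            dataset.model_kind,
        )
    except IntegrationError as exc:
        raise IntegrationError(
            f"simulation failed for dataset {dataset.label!r}: {exc}"
        ) from exc
    species = species_for(dataset.model_kind)
    cols = [species.index(s) for s in dataset.observed_species]
    return trajectory.states[:, cols]


def _residual_vector(
    constants: RateConstants, datasets: Sequence[TimecourseDataset], simulator: str
) -> np.ndarray:
    parts = []
    for dataset in datasets:
        predicted = _predict_observations(constants, dataset, simulator)
        diff = predicted - dataset.observations
        parts.append(diff[~np.isnan(dataset.observations)])
    return np.concatenate(parts)


def ssq_objective(
    constants: RateConstants,
    datasets: Sequence[TimecourseDataset],
    simulator: str = "closed_form",
) -> float:
    """Unweighted sum of squared residuals over datasets, times and species."""
    if not datasets:
        raise ValueError("at least one dataset is required")
    residuals = _residual_vector(constants, datasets, simulator)
    return float(residuals @ residuals)


# ---------------------------------------------------------------------------
# Goodness of fit and uncertainties
# ---------------------------------------------------------------------------

def degree_of_explanation(
    ssq: float,
    datasets: Sequence[TimecourseDataset],
    per_species: bool = False,
) -> float:
    """R^2-style statistic, 100 * (1 - SSQ / total sum of squares), in percent.

    By default the total sum of squares centres on the grand mean over all
    observed values pooled across species and datasets; ``per_species=True``
    centres each species on its own pooled mean instead.  Returns NaN when
    the total variance is zero (undefined).
    """
    if per_species:
        groups: dict[tuple[str, str], list[np.ndarray]] = {}
        for dataset in datasets:
            for j, sp in enumerate(dataset.observed_species):
                col = dataset.observations[:, j]
                groups.setdefault((dataset.model_kind, sp), []).append(col[~np.isnan(col)])
        total = 0.0
        for cols in groups.values():
            values = np.concatenate(cols)
            if values.size:
                total += float(np.sum((values - values.mean()) ** 2))
    else:
        values = np.concatenate(
            [ds.observations[~np.isnan(ds.observations)] for ds in datasets]
        )
        total = float(np.sum((values - values.mean()) ** 2)) if values.size else 0.0
    if total == 0.0:
        return float("nan")
    return 100.0 * (1.0 - ssq / total)


def linearized_standard_errors(jacobian: np.ndarray, residuals: np.ndarray) -> np.ndarray:
    """Standard errors from the linearised covariance s^2 (J^T J)^-1.

    ``jacobian`` holds d(model)/d(parameter) columns at the optimum and
    ``residuals`` the model-minus-data vector.  The residual variance is
    estimated as SSQ / (n - p).  Parameters whose direction lies in the
    numerical null space of J are reported as NaN (not identifiable).
    """
    J = np.asarray(jacobian, dtype=float)
    r = np.asarray(residuals, dtype=float)
    n, p = J.shape
    dof = n - p
    s2 = float(r @ r) / dof if dof > 0 else 0.0
    U, sv, Vt = np.linalg.svd(J, full_matrices=False)
    tol = sv[0] * max(n, p) * np.finfo(float).eps if sv.size and sv[0] > 0 else 0.0
    rank = int(np.sum(sv > tol))
    errors = np.full(p, np.nan)
    if rank == p:
        inv_jtj = (Vt.T / sv**2) @ Vt
        errors = np.sqrt(np.clip(s2 * np.diag(inv_jtj), 0.0, None))
    else:
        warnings.warn(
            "sensitivity matrix is rank deficient; some parameters are not "
            "identifiable and their standard errors are undefined",
            stacklevel=2,
        )
        null_mass = np.sum(Vt[rank:] ** 2, axis=0)
        identifiable = null_mass < 1e-8
        if np.any(identifiable):
            inv_jtj = (Vt[:rank].T / sv[:rank] ** 2) @ Vt[:rank]
            se = np.sqrt(np.clip(s2 * np.diag(inv_jtj), 0.0, None))
            errors[identifiable] = se[identifiable]
    return errors


_LOG_STEP = 1e-4  # relative central-difference step in log10 space


def _sensitivity_jacobian(
    constants: RateConstants,
    free_names: Sequence[str],
    datasets: Sequence[TimecourseDataset],
    simulator: str,
) -> np.ndarray:
    columns = []
    for name in free_names:
        theta = getattr(constants, name)
        if theta <= 0:
            theta = 1e-12
        hi = theta * 10.0**_LOG_STEP
        lo = theta * 10.0**-_LOG_STEP
        m_hi = np.concatenate(
            [
                _predict_observations(constants.replace(**{name: hi}), ds, simulator)[
                    ~np.isnan(ds.observations)
                ]
                for ds in datasets
            ]
        )
        m_lo = np.concatenate(
            [
                _predict_observations(constants.replace(**{name: lo}), ds, simulator)[
                    ~np.isnan(ds.observations)
                ]
                for ds in datasets
            ]
        )
        columns.append((m_hi - m_lo) / (hi - lo))
    return np.column_stack(columns)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _make_constants(x_log: np.ndarray, free_names, locked: Mapping[str, float]) -> RateConstants:
    values = dict(locked)
    for name, xv in zip(free_names, x_log):
        values[name] = 10.0**xv
    return RateConstants.from_dict(values)


def fit_rate_constants(
    datasets: Sequence[TimecourseDataset],
    config: FitConfig | None = None,
) -> FitResult:
    """Estimate the free rate constants by staged nonlinear least squares.

    Runs the configured optimiser stages in order from each multistart point
    (the first start is the configured initial guess, further starts are
    multiplicative perturbations of it) and returns the best result.  Locked
    parameters are held bit-exactly at their locked values.
    """
    if not datasets:
        raise ValueError("at least one dataset is required")
    config = config or FitConfig()
    free_names = config.free_parameters
    locked = dict(config.locked_values)

    lb = np.array([math.log10(config.bounds_for(n)[0]) for n in free_names])
    ub = np.array([math.log10(config.bounds_for(n)[1]) for n in free_names])
    x0 = np.clip(
        np.array([math.log10(max(config.guess_for(n), 1e-30)) for n in free_names]), lb, ub
    )

    def residuals_of(x_log: np.ndarray) -> np.ndarray:
        return _residual_vector(
            _make_constants(x_log, free_names, locked), datasets, config.simulator
        )

    def ssq_of(x_log: np.ndarray) -> float:
        if np.any(x_log < lb - 1e-12) or np.any(x_log > ub + 1e-12):
            violation = float(
                np.sum(np.clip(lb - x_log, 0, None) + np.clip(x_log - ub, 0, None))
            )
            return 1e30 * (1.0 + violation)
        r = residuals_of(x_log)
        return float(r @ r)

    rng = np.random.default_rng(config.seed)
    stage_log: list[dict] = []
    best_x, best_ssq = x0.copy(), ssq_of(x0)
    total_evals = 0
    any_converged = False

    for start_index in range(max(1, config.multistart_count)):
        if start_index == 0:
            x = x0.copy()
        else:
            x = np.clip(x0 + np.log10(rng.uniform(0.5, 1.5, size=x0.size)), lb, ub)
        start_ssq = ssq_of(x)
        if start_ssq < best_ssq:
            best_x, best_ssq = x.copy(), start_ssq
        for stage in config.optimizer_stages:
            entry = {"start": start_index, "stage": stage, "ssq_before": ssq_of(x)}
            if stage == "simplex":
                res = minimize(
                    ssq_of,
                    x,
                    method="Nelder-Mead",
                    options={
                        "maxiter": config.max_iterations,
                        "fatol": config.ftol,
                        "xatol": config.xtol,
                    },
                )
                candidate, cand_ssq = res.x, float(res.fun)
                entry.update(nfev=int(res.nfev), success=bool(res.success))
            else:  # levenberg_marquardt refinement (trust-region LS with bounds)
                try:
                    res = least_squares(
                        residuals_of,
                        np.clip(x, lb, ub),
                        bounds=(lb, ub),
                        method="trf",
                        x_scale="jac",
                        ftol=config.ftol,
                        xtol=config.xtol,
                        max_nfev=config.max_iterations,
                    )
                    candidate, cand_ssq = res.x, float(2.0 * res.cost)
                    entry.update(nfev=int(res.nfev), success=bool(res.success))
                except (IntegrationError, np.linalg.LinAlgError) as exc:
                    entry.update(nfev=0, success=False, error=str(exc))
                    candidate, cand_ssq = x, ssq_of(x)
            # accepted step: never move uphill
            if cand_ssq <= entry["ssq_before"]:
                x = np.asarray(candidate, dtype=float)
            entry["ssq_after"] = min(cand_ssq, entry["ssq_before"])
            total_evals += entry.get("nfev", 0)
            any_converged = any_converged or entry.get("success", False)
            stage_log.append(entry)
        final_ssq = ssq_of(x)
        if final_ssq < best_ssq:
            best_x, best_ssq = x.copy(), final_ssq

    if not any_converged and not math.isfinite(best_ssq):
        raise FitError(f"no optimisation start converged; stage log: {stage_log}")

    estimates = _make_constants(best_x, free_names, locked)
    residuals = residuals_of(best_x)
    ssq = float(residuals @ residuals)
    n_obs = sum(ds.n_observations for ds in datasets)

    se_values = linearized_standard_errors(
        _sensitivity_jacobian(estimates, free_names, datasets, config.simulator),
        residuals,
    )
    standard_errors: dict[str, float | None] = {name: None for name in PARAMETER_NAMES}
    for name, se in zip(free_names, se_values):
        standard_errors[name] = float(se) if math.isfinite(se) else None

    return FitResult(
        estimates=estimates,
        standard_errors=standard_errors,
        ssq=ssq,
        degree_of_explanation=degree_of_explanation(ssq, datasets),
        n_observations=n_obs,
        converged=any_converged,
        iterations=total_evals,
        stage_log=tuple(stage_log),
    )
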