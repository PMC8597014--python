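"""Reaction networks for acetyl-group migration and hydrolysis on mannan backbones.

Two pseudo-first-order networks are implemented:

* a 7-species scheme for a doubly acetylated manno-trisaccharide, tracking
  every acetylation pattern from the fully acetylated starting compounds down
  to the deacetylated end product, and
* a 4-unit scheme for acetylated galactoglucomannan (GGM), tracking the
  per-unit acetylation state (O3-Ac, O2-Ac, O6-Ac, deacetylated).

Both networks are linear in the species vector.  Every rate carries the same
hydroxide-dependence correction ``10**(pH - 8)``, so rate constants are
reported "at pH 8" and a drifting pH only reparametrises time.  That makes the
system exactly solvable by a matrix exponential in transformed time, which is
used as the oracle for the stiff numerical integrator.

Species orderings are fixed everywhere:

* trisaccharide: ``1a, 1b, 1c, 1d, 1e, 1f, 1g`` where 1a carries O2-Ac+O3-Ac
  on the central unit, 1b O6-Ac (reducing end) + O3-Ac, 1c O6-Ac + O2-Ac,
  1d O3-Ac only, 1e O2-Ac only, 1f O6-Ac only and 1g is deacetylated;
* GGM: ``A, B, C, D`` = O3-acetylated, O2-acetylated, O6-acetylated and
  deacetylated mannose units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

__all__ = [
    "KineticsError",
    "ConfigurationError",
    "IntegrationError",
    "RateConstants",
    "PhProfile",
    "Trajectory",
    "PARAMETER_NAMES",
    "TRISACCHARIDE_SPECIES",
    "GGM_SPECIES",
    "MODEL_KINDS",
    "species_for",
    "constants_preset",
    "CONSTANT_PRESETS",
    "oh_correction_factor",
    "transformed_time",
    "build_rate_matrix",
    "species_rates",
    "simulate",
    "simulate_closed_form",
    "equilibrium_O2_fraction",
]


class KineticsError(Exception):
    """Base class for errors raised by this package."""


class ConfigurationError(KineticsError):
    """Invalid model, profile or option configuration."""


class IntegrationError(KineticsError):
    """The ODE solver failed to produce a trajectory."""


PARAMETER_NAMES: tuple[str, ...] = (
    "k_O2_O6",
    "k_O3_O2",
    "k_O2_O3",
    "k_prim_hydr",
    "k_sec_hydr",
)

TRISACCHARIDE_SPECIES: tuple[str, ...] = ("1a", "1b", "1c", "1d", "1e", "1f", "1g")
GGM_SPECIES: tuple[str, ...] = ("A", "B", "C", "D")

MODEL_KINDS: tuple[str, ...] = ("trisaccharide", "ggm")

_MODEL_ALIASES = {
    "trisaccharide": "trisaccharide",
    "tri": "trisaccharide",
    "ggm": "ggm",
}


def normalize_model_kind(model_kind: str) -> str:
    try:
        return _MODEL_ALIASES[str(model_kind).lower()]
    except KeyError:
        raise ConfigurationError(
            f"unknown model kind {model_kind!r}; expected one of {MODEL_KINDS}"
        ) from None


def species_for(model_kind: str) -> tuple[str, ...]:
    """Fixed species ordering of the given model."""
    kind = normalize_model_kind(model_kind)
    return TRISACCHARIDE_SPECIES if kind == "trisaccharide" else GGM_SPECIES


@dataclass(frozen=True)
class RateConstants:
    """The five tied pseudo-first-order rate constants (h^-1 at pH 8).

    ``k_O2_O6`` is the slow trans-glycosidic migration to the primary O6,
    ``k_O3_O2``/``k_O2_O3`` the fast intra-unit O3<->O2 exchange pair, and
    ``k_prim_hydr``/``k_sec_hydr`` the hydrolysis constants from the primary
    (O6) and secondary (O2/O3) positions.  The same five constants
    parameterise both network kinds.
    """

    k_O2_O6: float
    k_O3_O2: float
    k_O2_O3: float
    k_prim_hydr: float
    k_sec_hydr: float

    def __post_init__(self) -> None:
        for name in PARAMETER_NAMES:
            value = float(getattr(self, name))
            if not math.isfinite(value):
                raise ValueError(f"rate constant {name} must be finite, got {value!r}")
            if value < 0:
                raise ValueError(f"rate constant {name} must be >= 0, got {value!r}")
            object.__setattr__(self, name, value)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAMETER_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in PARAMETER_NAMES])

    @classmethod
    def from_dict(cls, values: Mapping[str, float]) -> "RateConstants":
        unknown = set(values) - set(PARAMETER_NAMES)
        if unknown:
            raise ValueError(f"unknown rate-constant names: {sorted(unknown)}")
        missing = set(PARAMETER_NAMES) - set(values)
        if missing:
            raise ValueError(f"missing rate-constant names: {sorted(missing)}")
        return cls(**{name: float(values[name]) for name in PARAMETER_NAMES})

    def replace(self, **updates: float) -> "RateConstants":
        merged = self.as_dict()
        merged.update(updates)
        return RateConstants.from_dict(merged)


# Published rate-constant sets (h^-1 at pH 8, 100 mM phosphate, 25 degC).
# "table1": trisaccharide model compounds; "table2-*": GGM at 2/10/20 mg/ml
# with k_O2_O3 locked at 1.00 h^-1.
CONSTANT_PRESETS: dict[str, RateConstants] = {
    "table1": RateConstants(
        k_O2_O6=2.06e-3,
        k_O3_O2=1.88,
        k_O2_O3=1.01,
        k_prim_hydr=1.93e-3,
        k_sec_hydr=1.56e-3,
    ),
    "table2-2mg": RateConstants(
        k_O2_O6=1.50e-3,
        k_O3_O2=1.60,
        k_O2_O3=1.00,
        k_prim_hydr=3.72e-3,
        k_sec_hydr=2.60e-4,
    ),
    "table2-10mg": RateConstants(
        k_O2_O6=8.41e-4,
        k_O3_O2=1.51,
        k_O2_O3=1.00,
        k_prim_hydr=2.35e-3,
        k_sec_hydr=1.16e-3,
    ),
    "table2-20mg": RateConstants(
        k_O2_O6=7.08e-4,
        k_O3_O2=1.56,
        k_O2_O3=1.00,
        k_prim_hydr=2.06e-3,
        k_sec_hydr=1.24e-3,
    ),
}


def constants_preset(name: str) -> RateConstants:
    """Look up a published rate-constant set by preset name."""
    try:
        return CONSTANT_PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown constants preset {name!r}; expected one of {sorted(CONSTANT_PRESETS)}"
        ) from None


# ---------------------------------------------------------------------------
# pH handling
# ---------------------------------------------------------------------------

def oh_correction_factor(ph: float, reference_ph: float = 8.0) -> float:
    """Hydroxide correction factor ``10**(ph - reference_ph)``.

    All reaction rates are proportional to [OH-]; dividing by the hydroxide
    concentration at the reference pH (default 8, i.e. [OH-] = 1e-6 M) makes
    the rate constants pH-independent quantities "at pH 8".  The factor is 1
    at the reference pH and strictly increasing in pH.
    """
    ph = float(ph)
    if not 0.0 <= ph <= 14.0:
        raise ValueError(f"pH must lie in [0, 14], got {ph}")
    return 10.0 ** (ph - reference_ph)


@dataclass(frozen=True)
class PhProfile:
    """Time-stamped pH measurements defining the hydroxide correction in time.

    pH is linearly interpolated between samples and held constant outside the
    sampled span.  ``reference_ph`` selects the pH at which the correction
    factor equals 1 (8.0 by default; set it to the starting pH to reference
    constants to the start of the experiment instead).
    """

    times: np.ndarray
    ph: np.ndarray
    reference_ph: float = 8.0

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        ph = np.asarray(self.ph, dtype=float)
        if times.ndim != 1 or ph.ndim != 1 or times.size != ph.size:
            raise ValueError("times and ph must be 1-D arrays of equal length")
        if times.size == 0:
            raise ConfigurationError("pH profile must contain at least one sample")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("pH profile times must be strictly increasing")
        if np.any((ph < 0) | (ph > 14)):
            raise ValueError("pH values must lie in [0, 14]")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "ph", ph)

    @classmethod
    def constant(cls, ph: float, reference_ph: float = 8.0) -> "PhProfile":
        return cls(times=np.array([0.0]), ph=np.array([float(ph)]), reference_ph=reference_ph)

    @classmethod
    def from_points(
        cls, points: Iterable[tuple[float, float]], reference_ph: float = 8.0
    ) -> "PhProfile":
        pts = list(points)
        return cls(
            times=np.array([p[0] for p in pts], dtype=float),
            ph=np.array([p[1] for p in pts], dtype=float),
            reference_ph=reference_ph,
        )

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])

    def ph_at(self, t) -> np.ndarray | float:
        """Linearly interpolated pH; held constant beyond the sampled span."""
        out = np.interp(np.asarray(t, dtype=float), self.times, self.ph)
        return float(out) if np.isscalar(t) or np.ndim(t) == 0 else out

    def factor_at(self, t) -> np.ndarray | float:
        return 10.0 ** (np.asarray(self.ph_at(t)) - self.reference_ph) if np.ndim(t) else oh_correction_factor(
            self.ph_at(t), self.reference_ph
        )


def _segment_integral(t0: float, t1: float, ph0: float, ph1: float, ref: float) -> float:
    """Exact integral of 10**(pH(s)-ref) over [t0, t1] with pH linear in s."""
    if t1 <= t0:
        return 0.0
    f0 = 10.0 ** (ph0 - ref)
    if abs(ph1 - ph0) < 1e-13:
        return f0 * (t1 - t0)
    f1 = 10.0 ** (ph1 - ref)
    return (f1 - f0) * (t1 - t0) / ((ph1 - ph0) * math.log(10.0))


def transformed_time(profile: PhProfile, t) -> np.ndarray | float:
    """Hydroxide-weighted time ``tau(t) = int_0^t 10**(pH(s) - ref) ds``.

    Because every rate in the network carries the same pH correction factor,
    the dynamics in tau are autonomous: c(t) = expm(K * tau(t)) c0.  The
    integral is evaluated exactly on the piecewise-linear pH interpolant.
    """
    scalar = np.isscalar(t) or np.ndim(t) == 0
    ts = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(ts < 0):
        raise ValueError("transformed time is defined for t >= 0")
    ref = profile.reference_ph
    out = np.empty_like(ts)
    for i, tv in enumerate(ts):
        # breakpoints: 0, interior profile knots, tv
        knots = profile.times[(profile.times > 0) & (profile.times < tv)]
        bps = np.concatenate(([0.0], knots, [tv]))
        phs = np.interp(bps, profile.times, profile.ph)
        out[i] = sum(
            _segment_integral(bps[j], bps[j + 1], phs[j], phs[j + 1], ref)
            for j in range(len(bps) - 1)
        )
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# Rate matrix and derivatives
# ---------------------------------------------------------------------------

# First-order transitions (source, target, constant name).  The doubly
# acetylated 1a loses either secondary acetyl, feeding both 1d and 1e at
# k_sec_hydr each — hence the factor 2 on its own loss term.
_TRI_TRANSITIONS: tuple[tuple[str, str, str], ...] = (
    ("1a", "1b", "k_O2_O6"),
    ("1a", "1d", "k_sec_hydr"),
    ("1a", "1e", "k_sec_hydr"),
    ("1b", "1c", "k_O3_O2"),
    ("1c", "1b", "k_O2_O3"),
    ("1d", "1e", "k_O3_O2"),
    ("1e", "1d", "k_O2_O3"),
    ("1b", "1d", "k_prim_hydr"),
    ("1c", "1e", "k_prim_hydr"),
    ("1f", "1g", "k_prim_hydr"),
    ("1b", "1f", "k_sec_hydr"),
    ("1c", "1f", "k_sec_hydr"),
    ("1d", "1g", "k_sec_hydr"),
    ("1e", "1g", "k_sec_hydr"),
    ("1e", "1f", "k_O2_O6"),
)

_GGM_TRANSITIONS: tuple[tuple[str, str, str], ...] = (
    ("A", "B", "k_O3_O2"),
    ("B", "A", "k_O2_O3"),
    ("B", "C", "k_O2_O6"),
    ("A", "D", "k_sec_hydr"),
    ("B", "D", "k_sec_hydr"),
    ("C", "D", "k_prim_hydr"),
)


def build_rate_matrix(constants: RateConstants, model_kind: str) -> np.ndarray:
    """Assemble the generator matrix K with d c/dt = factor(t) * K @ c.

    Off-diagonal entry K[j, i] is the total rate constant of the i -> j
    transition; each column sums to zero, so total mass is conserved.
    """
    kind = normalize_model_kind(model_kind)
    species = species_for(kind)
    transitions = _TRI_TRANSITIONS if kind == "trisaccharide" else _GGM_TRANSITIONS
    index = {name: i for i, name in enumerate(species)}
    K = np.zeros((len(species), len(species)))
    for source, target, kname in transitions:
        k = getattr(constants, kname)
        i, j = index[source], index[target]
        K[j, i] += k
        K[i, i] -= k
    return K


def species_rates(
    state: Sequence[float],
    constants: RateConstants,
    factor: float,
    model_kind: str,
) -> np.ndarray:
    """Time derivative of the species vector, ``factor * K @ state``."""
    kind = normalize_model_kind(model_kind)
    c = np.asarray(state, dtype=float)
    n = len(species_for(kind))
    if c.shape != (n,):
        raise ValueError(f"state for {kind!r} must have length {n}, got shape {c.shape}")
    if factor < 0:
        raise ValueError("correction factor must be >= 0")
    return factor * (build_rate_matrix(constants, kind) @ c)


# ---------------------------------------------------------------------------
# Forward simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Trajectory:
    """Simulated mole-fraction time course (times x species)."""

    times: np.ndarray
    states: np.ndarray
    model_kind: str
    species: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        kind = normalize_model_kind(self.model_kind)
        species = self.species or species_for(kind)
        times = np.asarray(self.times, dtype=float)
        states = np.asarray(self.states, dtype=float)
        if states.shape != (times.size, len(species)):
            raise ValueError(
                f"states shape {states.shape} does not match {times.size} times x {len(species)} species"
            )
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "model_kind", kind)
        object.__setattr__(self, "species", tuple(species))

    def to_dataframe(self):
        import pandas as pd

        frame = pd.DataFrame(self.states, columns=[f"c_{s}" for s in self.species])
        frame.insert(0, "time_h", self.times)
        return frame


def _validate_simulation_inputs(initial_state, times, model_kind):
    kind = normalize_model_kind(model_kind)
    species = species_for(kind)
    c0 = np.asarray(initial_state, dtype=float)
    if c0.shape != (len(species),):
        raise ValueError(
            f"initial state for {kind!r} must have length {len(species)}, got shape {c0.shape}"
        )
    if np.any(c0 < -1e-12) or np.any(c0 > 1 + 1e-9):
        raise ValueError("initial state components must lie in [0, 1]")
    ts = np.asarray(times, dtype=float)
    if ts.ndim != 1 or ts.size == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if np.any(np.diff(ts) < 0):
        raise ValueError("times must be non-decreasing")
    if ts[0] < 0:
        raise ValueError("times must be >= 0")
    return kind, c0, ts


def simulate(
    constants: RateConstants,
    initial_state: Sequence[float],
    profile: PhProfile,
    times: Sequence[float],
    model_kind: str,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the stiff linear system with a backward-differentiation method.

    The rate constants span roughly three orders of magnitude (fast O3<->O2
    exchange vs. slow hydrolysis), so a stiff multistep (BDF) integrator is
    the default.  Round-off negatives are clipped to zero on output only.
    """
    kind, c0, ts = _validate_simulation_inputs(initial_state, times, model_kind)
    K = build_rate_matrix(constants, kind)

    def rhs(t, c):
        return profile.factor_at(t) * (K @ c)

    def jac(t, c):
        return profile.factor_at(t) * K

    t_end = float(ts[-1])
    if t_end == 0.0:
        states = np.tile(c0, (ts.size, 1))
        return Trajectory(times=ts, states=states, model_kind=kind)
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        c0,
        method="BDF",
        t_eval=ts,
        jac=jac,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(
            f"BDF integration failed for {kind!r} over [0, {t_end}] h: {sol.message}"
        )
    states = np.clip(sol.y.T, 0.0, None)
    return Trajectory(times=ts, states=states, model_kind=kind)


def _propagators(K: np.ndarray, taus: np.ndarray, c0: np.ndarray) -> np.ndarray:
    """States expm(K*tau) @ c0 for each tau, via eigendecomposition when safe."""
    try:
        w, V = np.linalg.eig(K)
        Vinv = np.linalg.inv(V)
        if np.linalg.cond(V) < 1e10:
            a = Vinv @ c0
            out = np.real((V * np.exp(np.outer(taus, w))[:, None, :]) @ a[:, None]).squeeze(-1)
            # guard against a near-defective decomposition
            check = V @ np.diag(w) @ Vinv
            if np.allclose(check, K, atol=1e-10 * max(1.0, np.abs(K).max())):
                return out
    except np.linalg.LinAlgError:
        pass
    # fallback: incremental matrix exponentials over sorted tau increments
    order = np.argsort(taus, kind="stable")
    out = np.empty((taus.size, c0.size))
    current = c0.copy()
    prev = 0.0
    for idx in order:
        dt = taus[idx] - prev
        if dt != 0.0:
            current = expm(K * dt) @ current
            prev = taus[idx]
        out[idx] = current
    return out


def simulate_closed_form(
    constants: RateConstants,
    initial_state: Sequence[float],
    profile: PhProfile,
    times: Sequence[float],
    model_kind: str,
) -> Trajectory:
    """Exact trajectory ``c(t) = expm(K * tau(t)) @ c0``.

    tau is the hydroxide-weighted transformed time; the result is exact to
    matrix-exponential precision and serves as the oracle for :func:`simulate`.
    """
    kind, c0, ts = _validate_simulation_inputs(initial_state, times, model_kind)
    K = build_rate_matrix(constants, kind)
    taus = np.atleast_1d(np.asarray(transformed_time(profile, ts), dtype=float))
    states = _propagators(K, taus, c0)
    states[taus == 0.0] = c0  # exp(0) is exactly the identity
    states = np.clip(states, 0.0, None)
    return Trajectory(times=ts, states=states, model_kind=kind)


def equilibrium_O2_fraction(constants: RateConstants) -> float:
    """O2-acetylated fraction at the fast O3<->O2 migration quasi-equilibrium.

    The exchange pair is ~1000x faster than migration to O6 or hydrolysis, so
    species connected by it reach the ratio k_O3->O2 : k_O2->O3 long before
    any other process matters.  Returns k_O3_O2 / (k_O3_O2 + k_O2_O3).
    """
    total = constants.k_O3_O2 + constants.k_O2_O3
    if total <= 0:
        raise ValueError(
            "equilibrium undefined: both migration constants k_O3_O2 and k_O2_O3 are zero"
        )
    return constants.k_O3_O2 / total
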