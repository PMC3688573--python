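"""Reaction–diffusion model of habitat split for amphibians with aquatic larvae.

Habitat split is the human-induced disconnection between the aquatic habitat of
the larvae (a river or pond, placed at x = 0) and the terrestrial habitat of the
adults (a forest fragment occupying h <= x <= L).  Newly metamorphosed juveniles
leave the river and diffuse haphazardly through the inhospitable matrix [0, h]
with diffusivity D_J and mortality sigma_J; on reaching the fragment edge x = h
they become adults, which diffuse inside the fragment with diffusivity D_A and
mortality sigma_A.  The model is the pair of linear diffusion equations

    dJ/dt = D_J J_xx - sigma_J J      on 0 < x < h   (matrix, juveniles)
    dA/dt = D_A A_xx - sigma_A A      on h < x < L   (fragment, adults)

closed by four boundary conditions:

    x = h:  J = 0 (juveniles are absorbed by metamorphosis into adults) and the
            adult influx equals the juvenile efflux, -D_A A_x = -D_J J_x;
    x = L:  Robin condition D_A A_x + p A = 0 with edge permeability p
            (p = 0 reflecting/closed edge, p = inf fully absorbing edge);
    x = 0:  the juvenile flux entering the matrix equals the saturating,
            delayed recruitment  -D_J J_x|_0 = R n / (1 + R n / g)  evaluated
            at n = N_T(t - tau), where N_T = int_h^L A dx is the total number
            of adults in the fragment, R the per-adult recruitment rate, g the
            maximum juvenile production rate and tau the reproduction delay.

All density dependence lives in that single boundary condition, so stationary
profiles have an exact piecewise closed form (sinh decay in the matrix,
cosh/sinh combination in the fragment) and a transcritical extinction
threshold: a positive steady state exists iff R exceeds a critical recruitment
R_c(h) that grows as cosh(alpha h) with the split distance h
(alpha = sqrt(sigma_J / D_J)).  Inverting R = R_c(h) gives the critical split
distance h_c beyond which the population goes locally extinct.

The file is organised in the order the method runs:

  1. parameters, validation, config I/O, nondimensionalisation, sampling;
  2. exact stationary solution and derived scalars (R_c, N_T, profiles);
  3. critical split distance and figure-style parameter sweeps;
  4. an independent finite-difference boundary-value oracle;
  5. the time-dependent Crank–Nicolson simulator with the delayed boundary;
  6. preset catalog emulating the published figure regimes, CSV/plot output.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.linalg import solve_banded
from scipy.optimize import brentq

__all__ = [
    "ModelParams",
    "StationarySolution",
    "GridProfile",
    "Trajectory",
    "SweepResult",
    "Preset",
    "PRESETS",
    "ParameterError",
    "ConfigError",
    "NoViableSplitError",
    "ThresholdNotFoundError",
    "SimulationError",
    "validate_params",
    "decay_lengths",
    "nondimensionalize",
    "sample_params",
    "load_config",
    "save_config",
    "recruitment_flux",
    "critical_recruitment",
    "solve_stationary",
    "total_adults",
    "evaluate_profile",
    "critical_split_distance",
    "sweep_population_vs_split",
    "sweep_hc_vs_recruitment",
    "sweep_population_vs_fragment_size",
    "solve_stationary_fd",
    "compare_to_analytic",
    "simulate",
    "classify_persistence",
    "steady_state_error",
    "mass_balance",
    "run_preset",
]

logger = logging.getLogger("habitat_split")
logger.addHandler(logging.NullHandler())


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------

class ParameterError(ValueError):
    """A model parameter violates its invariant."""


class ConfigError(ValueError):
    """A configuration file could not be interpreted."""


class NoViableSplitError(ValueError):
    """Recruitment cannot sustain the population even at zero split distance."""


class ThresholdNotFoundError(RuntimeError):
    """The root search for a threshold failed to bracket a sign change."""


class SimulationError(RuntimeError):
    """The time-dependent integration failed (instability or negativity)."""


# ---------------------------------------------------------------------------
# 1. parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelParams:
    """Rate and landscape parameters of the habitat-split model.

    All quantities are in consistent model units of length and time (the
    package does not fix a physical unit system; see :func:`nondimensionalize`
    for the canonical rescaling x -> alpha*x, t -> sigma_A*t).

    Attributes
    ----------
    D_J, D_A : float
        Diffusion coefficients of juveniles (matrix) and adults (fragment),
        length^2 / time.
    sigma_J, sigma_A : float
        Mortality rates of juveniles and adults, 1 / time.
    R : float
        Recruitment rate: juveniles produced at the river per adult per unit
        time (1 / time).  Phenomenologically folds in fertility, larval
        survival and adult return-trip mortality.
    g : float
        Saturation parameter: maximum rate of juvenile production at the
        river (individuals / time), the model's only density-dependent term.
    tau : float
        Reproduction delay (time) between a change in the adult population and
        the corresponding change in juvenile influx.
    p : float
        Permeability of the fragment outer edge at x = L (length / time).
        0 means a closed/reflecting edge; ``float('inf')`` is the absorbing
        edge A(L) = 0 (every individual reaching the edge leaves the system).
    h : float
        Split distance: river-to-fragment distance (length).  h = 0 is the
        degenerate no-split case where the fragment touches the river.
    L : float
        Coordinate of the fragment outer edge (length); fragment size is
        s = L - h.
    """

    D_J: float = 1.0
    D_A: float = 1.0
    sigma_J: float = 1.0
    sigma_A: float = 0.1
    R: float = 0.5
    g: float = 1.0
    tau: float = 1.0
    p: float = 0.0
    h: float = 1.0
    L: float = 6.0

    @property
    def s(self) -> float:
        """Fragment size L - h."""
        return self.L - self.h

    @property
    def absorbing_edge(self) -> bool:
        """True when the outer edge is fully absorbing (p = inf, A(L) = 0)."""
        return math.isinf(self.p)

    def with_(self, **kw) -> "ModelParams":
        """Return a copy with the given fields replaced (and re-validated)."""
        return validate_params(replace(self, **kw))


PARAM_NAMES = tuple(f.name for f in fields(ModelParams))


def validate_params(params: ModelParams) -> ModelParams:
    """Check every parameter invariant; return ``params`` unchanged if valid.

    Raises :class:`ParameterError` naming the first violated invariant.
    """
    for name in ("D_J", "D_A", "sigma_J", "sigma_A", "g"):
        v = getattr(params, name)
        if not (np.isfinite(v) and v > 0):
            raise ParameterError(f"{name} must be a positive finite number, got {v!r}")
    for name in ("R", "tau"):
        v = getattr(params, name)
        if not (np.isfinite(v) and v >= 0):
            raise ParameterError(f"{name} must be a non-negative finite number, got {v!r}")
    if not (params.p >= 0):  # inf allowed
        raise ParameterError(f"p must be >= 0 (or inf for an absorbing edge), got {params.p!r}")
    if not (np.isfinite(params.h) and params.h >= 0):
        raise ParameterError(f"h must be a non-negative finite number, got {params.h!r}")
    if not np.isfinite(params.L):
        raise ParameterError(f"L must be finite, got {params.L!r}")
    if not params.h < params.L:
        raise ParameterError(f"h must be < L, got h={params.h!r}, L={params.L!r}")
    return params


def decay_lengths(params: ModelParams) -> tuple[float, float]:
    """Inverse decay lengths (alpha, beta) of the stationary profiles.

    alpha = sqrt(sigma_J / D_J) governs the exponential attenuation of the
    juvenile profile across the matrix; beta = sqrt(sigma_A / D_A) the decay
    of the adult profile away from the fragment edge at h.
    """
    validate_params(params)
    return (math.sqrt(params.sigma_J / params.D_J),
            math.sqrt(params.sigma_A / params.D_A))


def nondimensionalize(params: ModelParams) -> ModelParams:
    """Rescale to the canonical units x~ = alpha*x, t~ = sigma_A*t.

    In the rescaled parameters alpha~ = 1 and sigma_A~ = 1; thresholds map as
    R_c~ = R_c / sigma_A and h_c~ = alpha * h_c, while densities and the adult
    total N_T are rescaled by alpha.
    """
    validate_params(params)
    a, _ = decay_lengths(params)
    sA = params.sigma_A
    return ModelParams(
        D_J=params.sigma_J / sA,
        D_A=params.D_A * a * a / sA,
        sigma_J=params.sigma_J / sA,
        sigma_A=1.0,
        R=params.R / sA,
        g=params.g * a / sA,
        tau=params.tau * sA,
        p=params.p * a / sA if not math.isinf(params.p) else math.inf,
        h=a * params.h,
        L=a * params.L,
    )


def sample_params(rng: np.random.Generator, *, with_delay: bool = False) -> ModelParams:
    """Draw a random valid parameter set spanning the model's regimes.

    Diffusivities are log-uniform around 1, mortalities span matrix/fragment
    contrasts of up to ~60x, the edge permeability is closed, partial or
    absorbing with equal probability, and the split distance ranges from the
    degenerate h = 0 case to several juvenile decay lengths.  Used by the
    randomized equivalence suite and the validation scripts.
    """
    D_J = float(10 ** rng.uniform(-0.5, 0.5))
    D_A = float(10 ** rng.uniform(-0.5, 0.5))
    sigma_J = float(10 ** rng.uniform(math.log10(0.3), math.log10(3.0)))
    sigma_A = float(10 ** rng.uniform(math.log10(0.05), math.log10(1.0)))
    R = float(10 ** rng.uniform(math.log10(0.05), math.log10(3.0)))
    g = float(10 ** rng.uniform(math.log10(0.5), math.log10(2.0)))
    tau = float(rng.uniform(0.0, 2.0)) if with_delay else 0.0
    mode = rng.integers(3)
    p = 0.0 if mode == 0 else (float(10 ** rng.uniform(-1, 0.7)) if mode == 1 else math.inf)
    h = 0.0 if rng.random() < 0.1 else float(rng.uniform(0.2, 2.5))
    s = float(rng.uniform(0.5, 6.0))
    return validate_params(ModelParams(D_J=D_J, D_A=D_A, sigma_J=sigma_J,
                                       sigma_A=sigma_A, R=R, g=g, tau=tau,
                                       p=p, h=h, L=h + s))


# -- config I/O --------------------------------------------------------------

def load_config(path: str | Path) -> ModelParams:
    """Read a flat key: value YAML/JSON config into validated parameters.

    Keys are exactly the :class:`ModelParams` field names; any subset may be
    given (missing keys take the package defaults).  ``p`` accepts the literal
    string ``inf`` (or YAML ``.inf``) for the absorbing edge.  Unknown keys are
    rejected with a close-match suggestion.
    """
    import difflib

    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a flat key: value mapping")
    kw = {}
    for key, value in raw.items():
        if key not in PARAM_NAMES:
            close = difflib.get_close_matches(str(key), PARAM_NAMES, n=3, cutoff=0.4)
            hint = f" (did you mean: {', '.join(close)}?)" if close else ""
            raise ConfigError(f"unknown parameter {key!r}{hint}")
        kw[key] = _coerce_value(key, value)
    try:
        return validate_params(ModelParams(**kw))
    except ParameterError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def _coerce_value(key: str, value) -> float:
    if isinstance(value, str):
        v = value.strip().lower()
        if v in ("inf", ".inf", "infinity"):
            return math.inf
        try:
            return float(value)
        except ValueError:
            raise ConfigError(f"parameter {key!r}: cannot interpret {value!r} as a number")
    if isinstance(value, (int, float)):
        return float(value)
    raise ConfigError(f"parameter {key!r}: cannot interpret {value!r} as a number")


def save_config(params: ModelParams, path: str | Path) -> Path:
    """Write parameters as a flat YAML mapping (round-trips through load_config)."""
    path = Path(path)
    lines = []
    for name in PARAM_NAMES:
        v = getattr(params, name)
        lines.append(f"{name}: {'inf' if math.isinf(v) else repr(float(v))}")
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# 2. stationary solution (exact closed form)
# ---------------------------------------------------------------------------

def recruitment_flux(n: float, params: ModelParams) -> float:
    """Saturating recruitment flux at the river for an adult total ``n``.

    Monod (hyperbolic) form  R n / (1 + R n / g): slope R at n = 0 and
    supremum g, the maximum juvenile production rate.  This is the single
    place the saturation law is defined; every solver accepts an alternative
    ``flux`` callable with the same (n, params) signature.
    """
    Rn = params.R * n
    return Rn / (1.0 + Rn / params.g)


FluxFn = Callable[[float, ModelParams], float]


def _edge_reflection(params: ModelParams, beta: float) -> float:
    """Reflection coefficient r of the Robin edge: +1 closed, -1 absorbing."""
    if params.absorbing_edge:
        return -1.0
    Db = params.D_A * beta
    return (Db - params.p) / (Db + params.p)


def _adult_geometry(params: ModelParams, beta: float) -> float:
    """Adults sustained in the fragment per unit adult influx at x = h.

    For a closed edge this is 1/sigma_A (all influx is balanced by adult
    mortality); edge permeability reduces it by the leakage through x = L.
    Written with decaying exponentials only, so it is stable for any beta*s.
    """
    r = _edge_reflection(params, beta)
    e1 = math.exp(-beta * params.s)
    return ((1.0 - e1) * (1.0 + r * e1)) / ((1.0 - r * e1 * e1) * params.sigma_A)


def _attenuation(alpha: float, h: float) -> float:
    """cosh(alpha h): river flux per unit flux delivered at the fragment edge."""
    try:
        return math.cosh(alpha * h)
    except OverflowError:
        return math.inf


def critical_recruitment(params: ModelParams) -> float:
    """Threshold recruitment R_c: a positive steady state exists iff R > R_c.

    R_c = cosh(alpha h) / G where G is the adult geometry factor (adults
    sustained per unit influx at the fragment edge).  Linearizing the river
    flux condition, recruitment must replace the whole population: each adult
    must generate enough juveniles that, after exponential attenuation across
    the matrix (factor cosh(alpha h)), the surviving influx rebuilds the adult
    stock against mortality and edge leakage.  For a closed edge (p = 0) this
    reduces to R_c = sigma_A cosh(alpha h), independent of fragment size; at
    zero split distance R_c(0) = sigma_A exactly.  The ``R`` field of
    ``params`` is ignored.
    """
    validate_params(params)
    alpha, beta = decay_lengths(params)
    return _attenuation(alpha, params.h) / _adult_geometry(params, beta)


@dataclass(frozen=True)
class StationarySolution:
    """Exact stationary profile of the habitat-split model.

    The juvenile profile is J(x) = C sinh(alpha (h - x)) on [0, h] (so the
    metamorphosis boundary J(h) = 0 holds by construction); the adult profile
    is A(x) = E cosh(beta (x - h)) + F sinh(beta (x - h)) on [h, L].  The
    amplitude is fixed by the saturating river-flux condition; below threshold
    (``exists`` False) the null solution is returned with all coefficients 0.
    """

    params: ModelParams
    alpha: float
    beta: float
    exists: bool
    N_T: float          # total adults in the fragment, int_h^L A dx
    R_c: float          # existence threshold for the recruitment rate
    phi_river: float    # juvenile flux entering the matrix at x = 0
    phi_h: float        # juvenile efflux at x = h = adult influx
    C: float            # juvenile amplitude
    E: float            # adult cosh coefficient (= A(h))
    F: float            # adult sinh coefficient (= A'(h)/beta)
    r: float = field(repr=False, default=0.0)   # edge reflection coefficient

    # -- profile evaluation (vectorized, overflow-safe) ---------------------

    def juvenile_density(self, x) -> np.ndarray:
        """J(x) on [0, h]."""
        x = np.asarray(x, dtype=float)
        return self.C * np.sinh(self.alpha * (self.params.h - x))

    def juvenile_flux(self, x) -> np.ndarray:
        """-D_J dJ/dx, the rightward juvenile flux."""
        x = np.asarray(x, dtype=float)
        return (self.params.D_J * self.C * self.alpha
                * np.cosh(self.alpha * (self.params.h - x)))

    def adult_density(self, x) -> np.ndarray:
        """A(x) on [h, L]."""
        xi = np.asarray(x, dtype=float) - self.params.h
        b, s, r = self.beta, self.params.s, self.r
        denom = 1.0 - r * math.exp(-2.0 * b * s)
        amp = self.phi_h / (self.params.D_A * b)
        return amp * (np.exp(-b * xi) + r * np.exp(-b * (2 * s - xi))) / denom

    def adult_density_derivative(self, x) -> np.ndarray:
        """dA/dx on [h, L]."""
        xi = np.asarray(x, dtype=float) - self.params.h
        b, s, r = self.beta, self.params.s, self.r
        denom = 1.0 - r * math.exp(-2.0 * b * s)
        amp = self.phi_h / self.params.D_A
        return amp * (-np.exp(-b * xi) + r * np.exp(-b * (2 * s - xi))) / denom


def _solve_amplitude(gamma: float, params: ModelParams, flux: FluxFn | None) -> float:
    """Positive root of phi = flux(gamma * phi), or 0 below threshold.

    ``gamma`` is the number of adults sustained per unit river flux.  Under
    the default Monod law the root is closed form; for a user-supplied
    saturating flux a guarded bracketing solver (relative tolerance 1e-12)
    is used.
    """
    if gamma <= 0.0 or params.R <= 0.0:
        return 0.0
    if flux is None:
        Rg = params.R * gamma
        return params.g * (1.0 - 1.0 / Rg) if Rg > 1.0 else 0.0

    def f(phi: float) -> float:
        return phi - flux(gamma * phi, params)

    lo = 1e-14 * params.g
    if f(lo) >= 0.0:
        return 0.0
    hi = params.g
    for _ in range(64):
        if f(hi) > 0.0:
            break
        hi *= 2.0
    else:
        raise ThresholdNotFoundError(
            "amplitude equation failed to bracket: flux function does not saturate")
    return float(brentq(f, lo, hi, rtol=1e-12, xtol=1e-30 * params.g))


def solve_stationary(params: ModelParams, flux: FluxFn | None = None) -> StationarySolution:
    """Exact stationary solution (the null solution below threshold).

    The linear profiles are determined up to one amplitude by the interior
    equations, the metamorphosis boundary J(h) = 0, the flux matching at h and
    the Robin edge at L; the saturating river-flux condition then fixes the
    amplitude.  A positive solution exists iff R > R_c (transcritical
    threshold: N_T -> 0 continuously as R decreases to R_c).

    Parameters
    ----------
    params : ModelParams
    flux : callable, optional
        Alternative saturation law ``flux(n, params)``; defaults to the Monod
        form of :func:`recruitment_flux`.
    """
    validate_params(params)
    alpha, beta = decay_lengths(params)
    g_adult = _adult_geometry(params, beta)
    att = _attenuation(alpha, params.h)
    r = _edge_reflection(params, beta)
    R_c = att / g_adult
    gamma = g_adult / att if math.isfinite(att) else 0.0

    phi_river = _solve_amplitude(gamma, params, flux)
    if phi_river <= 0.0:
        return StationarySolution(params=params, alpha=alpha, beta=beta,
                                  exists=False, N_T=0.0, R_c=R_c,
                                  phi_river=0.0, phi_h=0.0, C=0.0,
                                  E=0.0, F=0.0, r=r)

    phi_h = phi_river / att
    C = phi_h / (params.D_J * alpha)
    N_T = g_adult * phi_h
    e2 = math.exp(-2.0 * beta * params.s)
    E = phi_h * (1.0 + r * e2) / (params.D_A * beta * (1.0 - r * e2))  # A(h)
    F = -phi_h / (params.D_A * beta)                                   # A'(h)/beta
    return StationarySolution(params=params, alpha=alpha, beta=beta,
                              exists=True, N_T=N_T, R_c=R_c,
                              phi_river=phi_river, phi_h=phi_h, C=C,
                              E=E, F=F, r=r)


def total_adults(sol: StationarySolution) -> float:
    """Total adult population N_T = int_h^L A(x) dx (closed-form antiderivative)."""
    return sol.N_T


@dataclass(frozen=True)
class GridProfile:
    """Juvenile and adult densities on an explicit spatial grid.

    ``x_juvenile`` spans [0, h] and ``x_adult`` spans [h, L]; both include
    their endpoints exactly, so the metamorphosis point h carries the pair
    (J(h) = 0, A(h)).
    """

    x_juvenile: np.ndarray
    J: np.ndarray
    x_adult: np.ndarray
    A: np.ndarray

    @property
    def x(self) -> np.ndarray:
        """Joint axis (juvenile then adult positions, h appearing twice)."""
        return np.concatenate([self.x_juvenile, self.x_adult])

    def total_adults(self) -> float:
        return float(np.trapezoid(self.A, self.x_adult)) if self.A.size else 0.0

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns (x, J, A); NaN outside each domain."""
        xj = pd.DataFrame({"x": self.x_juvenile, "J": self.J, "A": np.nan})
        xa = pd.DataFrame({"x": self.x_adult, "J": np.nan, "A": self.A})
        return pd.concat([xj, xa], ignore_index=True)


def evaluate_profile(sol: StationarySolution, x_grid: Sequence[float]) -> GridProfile:
    """Evaluate the stationary profile on explicit positions in [0, L].

    Positions <= h are reported as juvenile density, positions >= h as adult
    density (the joint axis used in profile plots); x = h carries both, with
    J(h) = 0 exactly.
    """
    x = np.sort(np.asarray(x_grid, dtype=float))
    p = sol.params
    if x.size and (x[0] < -1e-12 or x[-1] > p.L + 1e-12):
        raise ValueError(f"positions must lie in [0, L] = [0, {p.L}]")
    xj = x[x <= p.h]
    xa = x[x >= p.h]
    if not sol.exists:
        return GridProfile(xj, np.zeros_like(xj), xa, np.zeros_like(xa))
    return GridProfile(xj, sol.juvenile_density(xj), xa, sol.adult_density(xa))


# ---------------------------------------------------------------------------
# 3. thresholds and sweeps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SweepResult:
    """One curve of a figure-style parameter sweep.

    ``rows`` are (varied parameter value, output scalar) pairs sorted by the
    parameter value; ``output_name`` is ``"N_T"`` or ``"h_c"``.  When the sweep
    is grouped (one curve per value of a second parameter), ``group_name`` and
    ``group_value`` identify the curve.
    """

    varied_name: str
    rows: tuple[tuple[float, float], ...]
    output_name: str
    group_name: str | None = None
    group_value: float | None = None

    @property
    def values(self) -> np.ndarray:
        return np.array([v for v, _ in self.rows])

    @property
    def outputs(self) -> np.ndarray:
        return np.array([o for _, o in self.rows])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows, columns=[self.varied_name, self.output_name])
        if self.group_name is not None:
            df.insert(1, self.group_name, self.group_value)
        return df


def sweep_frame(sweeps: Iterable[SweepResult]) -> pd.DataFrame:
    """Stack several sweep curves into one long-format table."""
    return pd.concat([s.to_frame() for s in sweeps], ignore_index=True)


def critical_split_distance(params: ModelParams, *, hold: str = "size",
                            bracket_cap: float | None = None) -> float:
    """Critical split distance h_c: the root of R = R_c(h).

    Populations persist for h < h_c and go extinct for h > h_c.  As h varies
    the fragment either slides with fixed size s = L - h (``hold="size"``, the
    default, so split distance and fragment size act as independent axes) or
    keeps its outer edge fixed (``hold="edge"``).  The root is found by
    bracketed root-finding on R - R_c(h), which is monotone because the matrix
    attenuation cosh(alpha h) strictly increases with h; the bracket is grown
    geometrically up to ``bracket_cap`` (default 1000/alpha).

    Raises
    ------
    NoViableSplitError
        If R <= R_c(h=0): the population is not viable even with the fragment
        adjacent to the river, so no split distance admits persistence.
    ThresholdNotFoundError
        If no sign change is found below the bracket cap.
    """
    validate_params(params)
    if hold not in ("size", "edge"):
        raise ValueError("hold must be 'size' or 'edge'")
    alpha, _ = decay_lengths(params)
    s = params.s

    def r_c(h: float) -> float:
        if hold == "size":
            q = replace(params, h=h, L=h + s)
        else:
            q = replace(params, h=h)
        return critical_recruitment(q)

    f = lambda h: params.R - r_c(h)
    f0 = f(0.0)
    if f0 < 0.0:
        raise NoViableSplitError(
            f"no viable split distance: R = {params.R} < R_c(h=0) = {r_c(0.0)}")
    if f0 == 0.0:
        return 0.0  # limit point: minimum recruitment, fragment touching the river
    cap = bracket_cap if bracket_cap is not None else 1e3 / alpha
    if hold == "edge":
        cap = min(cap, params.L * (1.0 - 1e-12))
    hi = min(1.0 / alpha, cap)
    while f(hi) > 0.0:
        if hi >= cap:
            raise ThresholdNotFoundError(
                f"no finite threshold found below h = {cap}")
        hi = min(2.0 * hi, cap)
    return float(brentq(f, 0.0, hi, xtol=1e-10 / alpha, rtol=8.9e-16))


def _nt_at(params: ModelParams, h: float, *, hold: str = "size",
           s: float | None = None) -> float:
    size = params.s if s is None else s
    if hold == "size":
        q = replace(params, h=h, L=h + size)
    else:
        q = replace(params, h=h)
    return solve_stationary(validate_params(q)).N_T


def sweep_population_vs_split(params: ModelParams, h_values: Sequence[float],
                              sigma_J_values: Sequence[float] | None = None,
                              *, hold: str = "size") -> list[SweepResult]:
    """Adult population N_T versus split distance h, one curve per sigma_J.

    Each curve decreases strictly with h and meets the x-axis at its critical
    split distance; beyond h_c the extinct branch is recorded as exactly 0 so
    exported curves show the intercept.  The fragment slides with constant
    size by default (``hold``).
    """
    validate_params(params)
    groups = [None] if sigma_J_values is None else list(sigma_J_values)
    out = []
    for sj in groups:
        q = params if sj is None else replace(params, sigma_J=sj)
        rows = tuple((float(h), _nt_at(q, float(h), hold=hold))
                     for h in sorted(h_values))
        out.append(SweepResult("h", rows, "N_T",
                               None if sj is None else "sigma_J", sj))
    return out


def sweep_hc_vs_recruitment(params: ModelParams, R_values: Sequence[float],
                            D_J_values: Sequence[float] | None = None,
                            *, hold: str = "size") -> list[SweepResult]:
    """Critical split distance h_c versus recruitment R, one curve per D_J.

    h_c increases with R (higher reproductive success tolerates a wider
    matrix) and, at every R, with the juvenile diffusivity D_J (faster
    dispersal counterbalances matrix mortality).
    """
    validate_params(params)
    groups = [None] if D_J_values is None else list(D_J_values)
    out = []
    for dj in groups:
        q = params if dj is None else replace(params, D_J=dj)
        rows = tuple(
            (float(R), critical_split_distance(replace(q, R=float(R)), hold=hold))
            for R in sorted(R_values))
        out.append(SweepResult("R", rows, "h_c",
                               None if dj is None else "D_J", dj))
    return out


def sweep_population_vs_fragment_size(params: ModelParams,
                                      h_values: Sequence[float],
                                      s_values: Sequence[float]) -> list[SweepResult]:
    """N_T versus split distance, one curve per fragment size s (needs p > 0).

    With a permeable edge, smaller fragments leak more adults, so smaller s
    gives pointwise smaller populations and a shorter critical split
    distance.  For a closed edge (p = 0) the size effect vanishes and all
    curves coincide; a warning is emitted in that case.
    """
    validate_params(params)
    if params.p == 0.0:
        warnings.warn("fragment-size effect vanishes for p = 0: "
                      "all curves will coincide", stacklevel=2)
    out = []
    for s in s_values:
        rows = tuple((float(h), _nt_at(params, float(h), hold="size", s=float(s)))
                     for h in sorted(h_values))
        out.append(SweepResult("h", rows, "N_T", "s", float(s)))
    return out


# ---------------------------------------------------------------------------
# 4. finite-difference boundary-value oracle
# ---------------------------------------------------------------------------
#
# Independent brute-force stationary solver: second-order central differences
# on the two coupled stationary ODEs with ghost-point boundary rows, and an
# outer scalar solve of the saturating river-flux condition.  Because the
# interior problem is linear in the river flux, one unit-flux solve yields the
# discrete adults-per-unit-flux factor; the nonlinear flux condition is then a
# scalar root problem.  Validation-only: it never stands in for the closed
# form.

def _tridiag_solve(lower, diag, upper, rhs):
    n = len(diag)
    ab = np.zeros((3, n))
    ab[0, 1:] = upper[:-1]
    ab[1, :] = diag
    ab[2, :-1] = lower[1:]
    return solve_banded((1, 1), ab, rhs)


def _fd_unit_profiles(params: ModelParams, nJ: int, nA: int):
    """Solve both stationary FD systems for unit river flux.

    Returns (xJ, J_unit, xA, A_unit, gamma_d) where gamma_d is the discrete
    adults-per-unit-river-flux factor.  The juvenile block is skipped when
    h = 0 (the river flux feeds the adults directly).
    """
    p = params
    if p.h > 0:
        xJ = np.linspace(0.0, p.h, nJ + 1)
        dx = xJ[1] - xJ[0]
        c = p.D_J / dx**2
        n = nJ  # unknowns J_0..J_{nJ-1}; J_nJ = 0 (Dirichlet)
        lower = np.full(n, c)
        diag = np.full(n, -2.0 * c - p.sigma_J)
        upper = np.full(n, c)
        upper[0] = 2.0 * c          # ghost-point flux row at x = 0
        rhs = np.zeros(n)
        rhs[0] = -2.0 / dx          # unit influx source
        Ju = np.append(_tridiag_solve(lower, diag, upper, rhs), 0.0)
        # second-order one-sided efflux at h (J_nJ = 0)
        phi_h = p.D_J * (4.0 * Ju[-2] - Ju[-3]) / (2.0 * dx)
    else:
        xJ = np.array([0.0])
        Ju = np.array([0.0])
        phi_h = 1.0

    xA = np.linspace(p.h, p.L, nA + 1)
    dxa = xA[1] - xA[0]
    ca = p.D_A / dxa**2
    m = nA if p.absorbing_edge else nA + 1
    lower = np.full(m, ca)
    diag = np.full(m, -2.0 * ca - p.sigma_A)
    upper = np.full(m, ca)
    upper[0] = 2.0 * ca             # ghost-point influx row at x = h
    rhs = np.zeros(m)
    rhs[0] = -2.0 * phi_h / dxa
    if not p.absorbing_edge:
        lower[-1] = 2.0 * ca        # Robin ghost row at x = L
        diag[-1] = -2.0 * ca - 2.0 * p.p / dxa - p.sigma_A
    Au = _tridiag_solve(lower, diag, upper, rhs)
    if p.absorbing_edge:
        Au = np.append(Au, 0.0)
    gamma_d = float(np.trapezoid(Au, xA))
    return xJ, Ju, xA, Au, gamma_d


def _split_points(params: ModelParams, n_points: int) -> tuple[int, int]:
    if params.h == 0.0:
        return 0, max(4, n_points) + n_points % 2
    nJ = int(round(n_points * params.h / params.L))
    nJ = min(max(nJ, 4), n_points - 4)
    # even counts so a coarsened grid with exactly doubled spacing exists
    return nJ + nJ % 2, n_points - nJ + (n_points - nJ) % 2


def solve_stationary_fd(params: ModelParams, n_points: int = 1000,
                        flux: FluxFn | None = None) -> GridProfile:
    """Brute-force stationary profile by finite differences (validation oracle).

    ``n_points`` intervals are distributed over the two domains in proportion
    to their lengths, with h and L as exact grid nodes.  The discrete
    adults-per-unit-flux factor is Richardson-extrapolated from the working
    grid and a 2x-coarsened grid: near the transcritical threshold the
    stationary amplitude amplifies any error in that scalar by 1/(R/R_c - 1),
    so the extrapolation keeps the amplitude and the existence classification
    sharp while the profiles themselves remain second order.  The scalar
    river-flux condition is resolved to a residual below 1e-10 of the flux
    scale; below threshold the extinct profile is returned.
    """
    validate_params(params)
    if n_points < 100:
        raise ValueError("n_points must be >= 100")
    nJ, nA = _split_points(params, n_points)
    xJ, Ju, xA, Au, gamma_fine = _fd_unit_profiles(params, nJ, nA)
    *_, gamma_coarse = _fd_unit_profiles(params, nJ // 2, nA // 2)
    gamma_d = (4.0 * gamma_fine - gamma_coarse) / 3.0
    phi0 = _solve_amplitude(gamma_d, params, flux)
    if phi0 > 0.0:
        f = flux if flux is not None else recruitment_flux
        resid = abs(phi0 - f(gamma_d * phi0, params))
        if resid > 1e-10 * max(params.g, phi0):
            raise ThresholdNotFoundError(
                f"river-flux residual {resid:.3e} exceeds tolerance")
    return GridProfile(xJ, phi0 * Ju, xA, phi0 * Au)


def compare_to_analytic(params: ModelParams,
                        n_points: int = 2000) -> tuple[float, float, float]:
    """Relative discrepancies (Linf J, Linf A, N_T) between oracle and closed form.

    Profile discrepancies are normalized by the maximum of the analytic
    profile on each domain; all three are exactly 0 when both solvers agree
    the population is extinct.
    """
    fd = solve_stationary_fd(params, n_points)
    sol = solve_stationary(params)
    if sol.exists:
        ref_J = sol.juvenile_density(fd.x_juvenile) if params.h > 0 else \
            np.zeros_like(fd.x_juvenile)
        ref_A = sol.adult_density(fd.x_adult)
    else:
        ref_J = np.zeros_like(fd.x_juvenile)
        ref_A = np.zeros_like(fd.x_adult)
    scale_J = float(np.max(np.abs(ref_J))) if ref_J.size else 0.0
    scale_A = float(np.max(np.abs(ref_A))) if ref_A.size else 0.0
    err_J = float(np.max(np.abs(fd.J - ref_J)) / scale_J) if scale_J > 0 else \
        float(np.max(np.abs(fd.J), initial=0.0))
    err_A = float(np.max(np.abs(fd.A - ref_A)) / scale_A) if scale_A > 0 else \
        float(np.max(np.abs(fd.A), initial=0.0))
    nt_fd = fd.total_adults()
    err_N = abs(nt_fd - sol.N_T) / sol.N_T if sol.N_T > 0 else abs(nt_fd)
    return err_J, err_A, float(err_N)


# ---------------------------------------------------------------------------
# 5. time-dependent simulator (method of lines, delayed boundary)
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Output of the time-dependent simulation.

    ``times``/``N_T`` hold the full adult-total series at every step; the
    initial history over [-tau, 0] is kept in ``history_times``/``history_N_T``
    so the delayed-recruitment buffer always spans at least tau.  Spatial
    snapshots (including the final state) are stored sparsely in
    ``profiles`` as (time, GridProfile) pairs.
    """

    params: ModelParams
    times: np.ndarray
    N_T: np.ndarray
    history_times: np.ndarray
    history_N_T: np.ndarray
    profiles: list[tuple[float, GridProfile]]
    dt: float
    dx_juvenile: float
    dx_adult: float
    phi_river_final: float = 0.0
    phi_h_final: float = 0.0

    @property
    def final_profile(self) -> GridProfile:
        return self.profiles[-1][1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.times, "N_T": self.N_T})


def _theta_matrix(lower, diag, upper, dt, theta):
    """Banded operator I - theta*dt*T for du/dt = T u, T = tridiag(lower,diag,upper)."""
    n = len(diag)
    ab = np.zeros((3, n))
    ab[0, 1:] = -theta * dt * upper[:-1]
    ab[1, :] = 1.0 - theta * dt * diag
    ab[2, :-1] = -theta * dt * lower[1:]
    return ab


def _theta_rhs(lower, diag, upper, dt, theta, u):
    w = (1.0 - theta) * dt
    out = (1.0 + w * diag) * u
    out[:-1] += w * upper[:-1] * u[1:]
    out[1:] += w * lower[1:] * u[:-1]
    return out


def simulate(params: ModelParams, initial=None, history=None, *,
             t_end: float, dt: float, dx: float,
             flux: FluxFn | None = None, max_snapshots: int = 101) -> Trajectory:
    """Integrate the stage-structured system with the delayed river boundary.

    Method of lines with ghost-point boundary rows and Crank–Nicolson
    (theta = 1/2) stepping of both diffusion operators; the delayed river flux
    is read from the N_T history buffer at the step midpoint t + dt/2 - tau
    (linear interpolation, linear extrapolation for tau < dt/2), and the adult
    influx at h is the old/new average of the second-order one-sided juvenile
    efflux, keeping the scheme second order in dx and dt.

    Parameters
    ----------
    params : ModelParams
    initial : None, (callable, callable) or GridProfile
        Initial densities.  ``None`` starts from an empty matrix and a small
        uniform adult density (1% of the saturation stock g/sigma_A spread
        over the fragment); a pair of callables gives (J(x), A(x)); a
        GridProfile is interpolated onto the simulation grid.
    history : None, float or callable
        N_T on [-tau, 0].  ``None`` holds the t = 0 value constant; a float is
        a constant history; a callable is sampled on the step grid.
    t_end, dt, dx : float
        Horizon, time step and target grid spacing (h and L are always exact
        nodes, so the realized spacings may be slightly smaller).
    flux : callable, optional
        Alternative saturation law (defaults to the Monod form).
    max_snapshots : int
        Upper bound on the number of stored spatial snapshots.

    Raises
    ------
    SimulationError
        On non-finite values (naming dt/dx) or on negative densities beyond
        1e-12 of the running maximum (small negatives are clipped).
    """
    validate_params(params)
    if dt <= 0 or dx <= 0 or t_end <= 0:
        raise ValueError("t_end, dt and dx must be positive")
    p = params
    f = flux if flux is not None else recruitment_flux

    # grids: endpoints exact, spacing <= dx
    if p.h > 0:
        nJ = max(3, math.ceil(p.h / dx - 1e-12))
        xJ = np.linspace(0.0, p.h, nJ + 1)
        dxj = xJ[1] - xJ[0]
    else:
        nJ, xJ, dxj = 0, np.array([0.0]), float("nan")
    nA = max(2, math.ceil(p.s / dx - 1e-12))
    xA = np.linspace(p.h, p.L, nA + 1)
    dxa = xA[1] - xA[0]

    # initial condition
    if initial is None:
        J0 = np.zeros(nJ + 1) if nJ else np.array([0.0])
        A0 = np.full(nA + 1, 0.01 * p.g / (p.sigma_A * p.s))
    elif isinstance(initial, GridProfile):
        J0 = (np.interp(xJ, initial.x_juvenile, initial.J)
              if nJ and initial.x_juvenile.size > 1 else np.zeros(nJ + 1))
        A0 = np.interp(xA, initial.x_adult, initial.A)
    else:
        fJ, fA = initial
        J0 = fJ(xJ) * np.ones_like(xJ) if nJ else np.array([0.0])
        A0 = fA(xA) * np.ones_like(xA)
    J0 = np.asarray(J0, dtype=float).copy()
    A0 = np.asarray(A0, dtype=float).copy()
    if nJ:
        J0[-1] = 0.0  # metamorphosis boundary
    if p.absorbing_edge:
        A0[-1] = 0.0
    if (J0 < 0).any() or (A0 < 0).any():
        raise ValueError("initial densities must be non-negative")

    # Crank–Nicolson operators
    if nJ:
        cj = p.D_J / dxj**2
        lJ = np.full(nJ, cj)
        dJd = np.full(nJ, -2.0 * cj - p.sigma_J)
        uJ = np.full(nJ, cj)
        uJ[0] = 2.0 * cj
        abJ = {th: _theta_matrix(lJ, dJd, uJ, dt, th) for th in (0.5, 1.0)}
    ca = p.D_A / dxa**2
    mA = nA if p.absorbing_edge else nA + 1
    lA = np.full(mA, ca)
    dAd = np.full(mA, -2.0 * ca - p.sigma_A)
    uA = np.full(mA, ca)
    uA[0] = 2.0 * ca
    if not p.absorbing_edge:
        lA[-1] = 2.0 * ca
        dAd[-1] = -2.0 * ca - 2.0 * p.p / dxa - p.sigma_A
    abA = {th: _theta_matrix(lA, dAd, uA, dt, th) for th in (0.5, 1.0)}

    # history buffer on a uniform dt grid; index k <-> t = (k - n_hist) * dt
    n_steps = int(round(t_end / dt))
    n_hist = int(math.ceil(p.tau / dt - 1e-12)) if p.tau > 0 else 0
    nt0 = float(np.trapezoid(A0, xA))
    nt_all = np.empty(n_hist + n_steps + 1)
    if history is None:
        nt_all[:n_hist + 1] = nt0
    elif callable(history):
        th = (np.arange(n_hist + 1) - n_hist) * dt
        nt_all[:n_hist + 1] = [float(history(t)) for t in th]
        nt_all[n_hist] = nt0
    else:
        nt_all[:n_hist + 1] = float(history)
        nt_all[n_hist] = nt0

    def nt_lookup(t: float, k_now: int) -> float:
        """N_T at time t from the buffer (linear interp / extrapolation).

        The buffer is filled up to position k_now + n_hist (time k_now * dt);
        a query beyond that (only possible when tau < dt/2) is linearly
        extrapolated from the last two known values.
        """
        idx = t / dt + n_hist          # fractional position in nt_all
        filled = k_now + n_hist
        if idx <= 0:
            return nt_all[0]
        if idx >= filled:
            if filled == 0:
                return nt_all[0]
            a, b = nt_all[filled - 1], nt_all[filled]
            return b + (idx - filled) * (b - a)
        i = int(idx)
        w = idx - i
        return (1 - w) * nt_all[i] + w * nt_all[i + 1]

    def efflux(Jv: np.ndarray) -> float:
        return p.D_J * (4.0 * Jv[-2] - Jv[-3]) / (2.0 * dxj)

    save_every = max(1, n_steps // max(1, max_snapshots - 1))
    J, A = J0, A0
    times = np.arange(n_steps + 1) * dt
    profiles: list[tuple[float, GridProfile]] = [
        (0.0, GridProfile(xJ.copy(), J.copy(), xA.copy(), A.copy()))]
    phi0 = phi_h = 0.0
    max_seen = max(float(J.max(initial=0.0)), float(A.max()), 1e-300)

    for k in range(n_steps):
        t = k * dt
        # Rannacher startup: a few backward-Euler steps damp the ringing a
        # non-smooth initial state excites in Crank-Nicolson; a fixed number
        # of first-order steps leaves the global order at two
        th = 1.0 if k < 4 else 0.5
        # the buffer currently ends at step k (N_T known up to t)
        nt_delayed = nt_lookup(t + 0.5 * dt - p.tau, k)
        phi0 = max(0.0, f(max(nt_delayed, 0.0), p))
        if nJ:
            rhs = _theta_rhs(lJ, dJd, uJ, dt, th, J[:-1])
            rhs[0] += dt * 2.0 * phi0 / dxj
            phi_old = efflux(J)
            J_new = np.append(solve_banded((1, 1), abJ[th], rhs), 0.0)
            phi_h = 0.5 * (phi_old + efflux(J_new))
            J = J_new
        else:
            phi_h = phi0
        Au = A[:mA]
        rhs = _theta_rhs(lA, dAd, uA, dt, th, Au)
        rhs[0] += dt * 2.0 * phi_h / dxa
        A_new = solve_banded((1, 1), abA[th], rhs)
        A = np.append(A_new, 0.0) if p.absorbing_edge else A_new

        if not (np.all(np.isfinite(J)) and np.all(np.isfinite(A))):
            raise SimulationError(
                f"instability detected (non-finite values) at t = {t + dt:.6g}; "
                f"dt = {dt}, dx = {dx}")
        max_seen = max(max_seen, float(J.max(initial=0.0)), float(A.max()))
        worst = min(float(J.min(initial=0.0)), float(A.min()))
        if worst < 0.0:
            if worst < -1e-12 * max_seen:
                raise SimulationError(
                    f"negative density {worst:.3e} at t = {t + dt:.6g} exceeds "
                    f"1e-12 of the running maximum {max_seen:.3e}")
            J = np.clip(J, 0.0, None)
            A = np.clip(A, 0.0, None)

        nt_all[k + 1 + n_hist] = float(np.trapezoid(A, xA))
        if (k + 1) % save_every == 0 and (k + 1) != n_steps:
            profiles.append((times[k + 1],
                             GridProfile(xJ.copy(), J.copy(), xA.copy(), A.copy())))

    profiles.append((times[-1], GridProfile(xJ.copy(), J.copy(), xA.copy(), A.copy())))
    return Trajectory(params=p, times=times, N_T=nt_all[n_hist:].copy(),
                      history_times=(np.arange(n_hist + 1) - n_hist) * dt,
                      history_N_T=nt_all[:n_hist + 1].copy(),
                      profiles=profiles, dt=dt, dx_juvenile=dxj, dx_adult=dxa,
                      phi_river_final=phi0, phi_h_final=phi_h)


def classify_persistence(traj: Trajectory, epsilon: float = 1e-6,
                         window: float | None = None) -> str:
    """Classify a trajectory as ``"persist"``, ``"extinct"`` or ``"undecided"``.

    Over the final ``window`` (default 10/sigma_A): extinct if N_T stays below
    ``epsilon`` times the saturation stock g/sigma_A; persist if N_T holds
    within 1% of a constant positive level; otherwise undecided (e.g. a slow
    transient or a delay-induced oscillation).
    """
    p = traj.params
    if window is None:
        window = 10.0 / p.sigma_A
    t_end = traj.times[-1]
    if t_end < window:
        raise ValueError(f"trajectory ({t_end}) shorter than window ({window})")
    vals = traj.N_T[traj.times >= t_end - window]
    floor = epsilon * p.g / p.sigma_A
    if np.all(vals < floor):
        return "extinct"
    mean = float(vals.mean())
    if mean > floor and (vals.max() - vals.min()) <= 0.01 * mean:
        return "persist"
    return "undecided"


def steady_state_error(traj: Trajectory, sol: StationarySolution) -> float:
    """Relative L-infinity deviation of the final profile from the closed form.

    Normalized by the maximum of the analytic profile; 0 for an extinct
    trajectory compared with the extinct solution.
    """
    prof = traj.final_profile
    if sol.exists:
        ref_J = (sol.juvenile_density(prof.x_juvenile)
                 if traj.params.h > 0 else np.zeros_like(prof.x_juvenile))
        ref_A = sol.adult_density(prof.x_adult)
    else:
        ref_J = np.zeros_like(prof.x_juvenile)
        ref_A = np.zeros_like(prof.x_adult)
    scale = max(float(np.max(np.abs(ref_J), initial=0.0)),
                float(np.max(np.abs(ref_A), initial=0.0)))
    diff = max(float(np.max(np.abs(prof.J - ref_J), initial=0.0)),
               float(np.max(np.abs(prof.A - ref_A), initial=0.0)))
    return diff / scale if scale > 0 else diff


def mass_balance(traj: Trajectory) -> dict[str, float]:
    """Steady-state mass budgets of the final profile (diagnostic).

    Juvenile budget: river influx - matrix deaths - efflux at h, using the
    discretization-consistent efflux (so the residual measures convergence in
    time, not quadrature error).  Adult budget: influx at h - adult deaths -
    edge leakage.  Residuals are relative to the river influx.
    """
    p = traj.params
    prof = traj.final_profile
    phi0 = traj.phi_river_final
    out: dict[str, float] = {"river_influx": phi0}
    if p.h > 0 and prof.x_juvenile.size > 2:
        dxj = traj.dx_juvenile
        deaths_J = p.sigma_J * float(np.trapezoid(prof.J, prof.x_juvenile))
        efflux_consistent = p.D_J * prof.J[-2] / dxj  # telescoped discrete flux
        out["juvenile_deaths"] = deaths_J
        out["juvenile_efflux"] = efflux_consistent
        out["juvenile_residual"] = (phi0 - deaths_J - efflux_consistent) / phi0 \
            if phi0 > 0 else 0.0
    deaths_A = p.sigma_A * float(np.trapezoid(prof.A, prof.x_adult))
    leak = 0.0 if (p.p == 0.0 or p.absorbing_edge) else p.p * float(prof.A[-1])
    if p.absorbing_edge:
        dxa = traj.dx_adult
        leak = -p.D_A * (4.0 * prof.A[-2] - prof.A[-3]) / (2.0 * dxa) * -1.0
    phi_h = traj.phi_h_final
    out["adult_influx"] = phi_h
    out["adult_deaths"] = deaths_A
    out["edge_leakage"] = leak
    out["adult_residual"] = (phi_h - deaths_A - leak) / phi_h if phi_h > 0 else 0.0
    return out


# ---------------------------------------------------------------------------
# 6. presets and outputs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Preset:
    """A named parameter regime with a sweep specification.

    The catalog emulates the qualitative regimes of the published
    habitat-split figures (stationary profiles; population vs. split distance
    per matrix quality; threshold vs. recruitment per juvenile diffusivity;
    size effect with a permeable edge).  The numeric parameter values are
    package choices, not taken from any publication.
    """

    name: str
    params: ModelParams
    kind: str                 # "profile" | "split" | "recruitment" | "size"
    group_values: tuple[float, ...]
    note: str


_DEFAULTS = ModelParams()

PRESETS: dict[str, Preset] = {
    "fig2": Preset(
        "fig2", _DEFAULTS, "profile", (0.5, 1.0, 2.0),
        "Stationary profiles J(x), A(x) on the joint axis for three juvenile "
        "mortalities (matrix qualities); densities fall across the matrix and "
        "level off inside the fragment."),
    "fig3": Preset(
        "fig3", _DEFAULTS, "split", (0.5, 1.0, 2.0),
        "Adult population vs. split distance for three juvenile mortalities; "
        "each curve meets the x-axis at its critical split distance, larger "
        "sigma_J giving the shorter threshold."),
    "fig4": Preset(
        "fig4", _DEFAULTS.with_(R=0.5), "recruitment", (0.5, 1.0, 2.0),
        "Critical split distance vs. recruitment for three juvenile "
        "diffusivities; h_c grows with R and with D_J from the limit point "
        "(R = sigma_A, h_c = 0)."),
    "fig5": Preset(
        "fig5", _DEFAULTS.with_(p=1.0), "size", (1.0, 2.0, 5.0),
        "Adult population vs. split distance for three fragment sizes with a "
        "permeable edge (p = 1); smaller fragments leak more adults and go "
        "extinct at shorter split distances."),
}


def _preset_data(preset: Preset):
    p = preset.params
    if preset.kind == "profile":
        sweeps = []
        x = np.linspace(0.0, p.L, 601)
        frames = []
        for sj in preset.group_values:
            sol = solve_stationary(p.with_(sigma_J=sj))
            df = evaluate_profile(sol, x).to_frame()
            df.insert(1, "sigma_J", sj)
            frames.append(df)
        return pd.concat(frames, ignore_index=True), None
    if preset.kind == "split":
        h = np.linspace(0.0, 4.0, 81)
        sweeps = sweep_population_vs_split(p, h, preset.group_values)
    elif preset.kind == "recruitment":
        R = np.linspace(p.sigma_A * 1.05, 1.0, 40)
        sweeps = sweep_hc_vs_recruitment(p, R, preset.group_values)
    elif preset.kind == "size":
        h = np.linspace(0.0, 3.0, 61)
        sweeps = sweep_population_vs_fragment_size(p, h, preset.group_values)
    else:  # pragma: no cover
        raise ValueError(f"unknown preset kind {preset.kind!r}")
    return sweep_frame(sweeps), sweeps


def run_preset(name: str, outdir: str | Path = ".") -> dict[str, Path]:
    """Regenerate a preset's sweep as CSV and a figure-style plot (PNG).

    Deterministic given the preset; returns the written paths.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {', '.join(PRESETS)}")
    preset = PRESETS[name]
    logger.info("running preset %s with params %s", name, preset.params)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df, sweeps = _preset_data(preset)
    csv_path = outdir / f"{name}.csv"
    df.to_csv(csv_path, index=False)

    fig, ax = plt.subplots(figsize=(6, 4))
    if preset.kind == "profile":
        for sj, sub in df.groupby("sigma_J"):
            dens = sub["J"].fillna(0.0) + sub["A"].fillna(0.0)
            ax.plot(sub["x"], dens, label=f"$\\sigma_J$ = {sj}")
        ax.axvline(preset.params.h, color="0.6", ls=":")
        ax.set_xlabel("distance from river x")
        ax.set_ylabel("density (juveniles for x < h, adults for x > h)")
    else:
        labels = {"split": "$\\sigma_J$", "recruitment": "$D_J$", "size": "s"}
        for sw in sweeps:
            ax.plot(sw.values, sw.outputs,
                    label=f"{labels[preset.kind]} = {sw.group_value}")
        if preset.kind == "recruitment":
            ax.set_xlabel("recruitment R")
            ax.set_ylabel("critical split distance $h_c$")
        else:
            ax.set_xlabel("split distance h")
            ax.set_ylabel("adult population $N_T$")
    ax.legend()
    ax.set_title(preset.note[:60] + ("…" if len(preset.note) > 60 else ""))
    fig.tight_layout()
    png_path = outdir / f"{name}.png"
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
    return {"csv": csv_path, "png": png_path}
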