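"""Oscillator model zoo: right-hand sides, parameter tables and conversions.

Six model families are provided, spanning the range from conservative
mechanical oscillators to kinetic circadian clock models and the abstract
amplitude-phase (Poincare) oscillator with an explicit twist parameter:

``harmonic``
    Frictionless mass-spring oscillator; period ``2*pi*sqrt(m/k)`` is
    independent of amplitude (no twist).
``duffing``
    Mass-spring oscillator with a cubic restoring-force term ``-beta*x**3``.
    ``beta < 0`` gives a *soft* spring (period grows with amplitude,
    positive twist), ``beta > 0`` a *hard* spring (negative twist).
``goodwin``
    Three-variable delayed negative feedback loop (clock gene mRNA ``x``,
    protein ``y``, repressor ``z``) with linear degradation and Hill-type
    transcriptional repression.
``gonze``
    Goodwin variant with Michaelis-Menten (saturating) degradation of all
    three variables, which lowers the Hill exponent needed for
    self-sustained oscillations from ~9.5 to 4.
``almeida``
    Eight-variable protein-level model of the mammalian core clock
    (BMAL1, ROR, REV-ERB, DBP, E4BP4, CRY, PER and the PER:CRY complex)
    wired through E-box, D-box and RORE clock-controlled elements.
``poincare``
    Radial limit-cycle oscillator ``dr/dt = lam*r*(A - r)``,
    ``dphi/dt = omega + eps*(A - r)`` whose twist parameter ``eps`` makes
    the instantaneous phase velocity depend on the distance from the cycle.

All right-hand sides are pure functions written with numpy ufuncs so they
evaluate on single states as well as on batches of states (leading axes
broadcast), which the ensemble and scan modules exploit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "HarmonicSpec",
    "DuffingSpec",
    "GoodwinSpec",
    "GonzeSpec",
    "AlmeidaSpec",
    "PoincareSpec",
    "ZeitgeberSpec",
    "PulseSpec",
    "CouplingSpec",
    "MODEL_FAMILIES",
    "make_default_spec",
    "make_spec",
    "model_id_of",
    "param_names",
    "get_param",
    "with_params",
    "spec_to_dict",
    "spec_from_dict",
    "eval_rhs",
    "poincare_cartesian_rhs",
    "poincare_polar_rhs",
    "zeitgeber_value",
    "pulse_value",
    "default_initial_state",
    "family_rhs",
    "var_names",
]


def _require_positive(spec, names: Iterable[str]) -> None:
    for name in names:
        value = getattr(spec, name)
        if not np.all(np.asarray(value) > 0):
            raise ValueError(
                f"{type(spec).__name__}.{name} must be > 0, got {value!r}"
            )


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HarmonicSpec:
    """Frictionless mass-spring oscillator; state ``(x, v)`` in a.u."""

    m: float = 1.0
    k: float = 1.0

    model_id = "harmonic"

    def __post_init__(self):
        _require_positive(self, ("m", "k"))

    @property
    def period(self) -> float:
        """Closed-form period ``2*pi*sqrt(m/k)``."""
        return 2.0 * np.pi * np.sqrt(self.m / self.k)


@dataclass(frozen=True)
class DuffingSpec:
    """Undamped Duffing oscillator; ``beta = 0`` reduces to the harmonic case.

    The documented defaults ``m = k = 1`` and ``|beta| = 1`` are package
    conventions (the mechanical models are dimensionless); ``beta = +1``
    is the hard-spring default, use ``beta = -1`` for the soft spring.
    """

    m: float = 1.0
    k: float = 1.0
    beta: float = 1.0

    model_id = "duffing"

    def __post_init__(self):
        _require_positive(self, ("m", "k"))

    def energy(self, x, v):
        """Conserved energy per unit mass, ``v^2/2 + (k/m)x^2/2 + (beta/m)x^4/4``."""
        return 0.5 * np.asarray(v) ** 2 + 0.5 * (self.k / self.m) * np.asarray(x) ** 2 \
            + 0.25 * (self.beta / self.m) * np.asarray(x) ** 4


@dataclass(frozen=True)
class GoodwinSpec:
    """Goodwin oscillator with linear degradation.

    Defaults are the standard parameterisation with ``k4`` and ``n``
    adapted so that the default point sits inside the oscillatory region
    (the published degradation rates give weakly damped rhythms).
    Units: synthesis rates nM/h or 1/h, degradation rates 1/h, ``K1`` nM.
    """

    k1: float = 1.0
    k2: float = 0.2
    k3: float = 1.0
    k4: float = 0.15
    k5: float = 1.0
    k6: float = 0.1
    K1: float = 1.0
    n: float = 9.5

    model_id = "goodwin"

    def __post_init__(self):
        _require_positive(self, ("k1", "k2", "k3", "k4", "k5", "k6", "K1"))
        if self.n < 1:
            raise ValueError(f"Hill exponent n must be >= 1, got {self.n}")


@dataclass(frozen=True)
class GonzeSpec:
    """Gonze oscillator: Goodwin loop with Michaelis-Menten degradation."""

    k1: float = 0.7
    k2: float = 0.35
    k3: float = 0.7
    k4: float = 0.35
    k5: float = 0.7
    k6: float = 0.35
    K1: float = 1.0
    K2: float = 1.0
    K4: float = 1.0
    K6: float = 1.0
    n: float = 4.0

    model_id = "gonze"

    def __post_init__(self):
        _require_positive(
            self, ("k1", "k2", "k3", "k4", "k5", "k6", "K1", "K2", "K4", "K6")
        )
        if self.n < 1:
            raise ValueError(f"Hill exponent n must be >= 1, got {self.n}")


@dataclass(frozen=True)
class AlmeidaSpec:
    """Protein-level mammalian core clock model (8 variables, 18 parameters).

    Clock-controlled-element activities::

        Ebox = VE * BMAL1 / (kE + BMAL1 + kEr * BMAL1 * CRY)
        RORE = VR * ROR / (kR + ROR) * kRr^2 / (kRr^2 + REV^2)
        Dbox = VD * DBP / (kD + DBP) * kDr / (kDr + E4BP4)

    The R-box term appearing in the E4BP4 and CRY equations is the RORE
    activity (no separate element is defined).  ``gamma_PC`` is the
    PER:CRY association rate and ``gamma_CP`` the dissociation rate, as
    wired in the differential equations.  Time unit: hours; concentrations
    in a.u.
    """

    VR: float = 44.4
    kR: float = 3.54
    kRr: float = 80.1
    VE: float = 30.3
    kE: float = 214.0
    kEr: float = 1.24
    VD: float = 202.0
    kD: float = 5.32
    kDr: float = 94.7
    gamma_Ror: float = 2.55
    gamma_Rev: float = 0.241
    gamma_P: float = 0.844
    gamma_C: float = 2.34
    gamma_DB: float = 0.156
    gamma_E4: float = 0.295
    gamma_PC: float = 0.191
    gamma_CP: float = 0.141
    gamma_BP: float = 2.58

    model_id = "almeida"

    def __post_init__(self):
        _require_positive(self, (f.name for f in dataclasses.fields(self)))


@dataclass(frozen=True)
class PoincareSpec:
    """Amplitude-phase oscillator with twist.

    Parameters
    ----------
    A : float
        Limit-cycle amplitude (a.u.).
    lam : float
        Amplitude relaxation rate ``lambda`` (1/h); radial deviations from
        the cycle decay at rate ``lam * A``.
    tau : float
        Free-running period (h); the angular velocity ``omega = 2*pi/tau``
        is always derived, never stored.
    eps : float
        Twist parameter ``epsilon`` (1/h).  ``eps > 0``: trajectories
        outside the cycle (r > A) are decelerated (soft oscillator);
        ``eps < 0``: accelerated (hard oscillator).
    """

    A: float = 1.0
    lam: float = 0.05
    tau: float = 24.0
    eps: float = 0.0

    model_id = "poincare"

    def __post_init__(self):
        _require_positive(self, ("A", "lam", "tau"))

    @property
    def omega(self) -> float:
        return 2.0 * np.pi / self.tau


@dataclass(frozen=True)
class ZeitgeberSpec:
    """Sinusoidal zeitgeber ``Z(t) = FZ * cos(2*pi*t/T + pi/2)``."""

    FZ: float = 0.05
    T: float = 24.0

    def __post_init__(self):
        if self.FZ < 0:
            raise ValueError("zeitgeber strength FZ must be >= 0")
        if self.T <= 0:
            raise ValueError("zeitgeber period T must be > 0")


@dataclass(frozen=True)
class PulseSpec:
    """Square pulse: ``pert(t) = FP`` for ``t_start <= t <= t_start+duration``, else 0."""

    FP: float = 0.7
    t_start: float = 0.0
    duration: float = 1.0

    def __post_init__(self):
        if self.FP < 0:
            raise ValueError("pulse strength FP must be >= 0")
        if self.duration <= 0:
            raise ValueError("pulse duration must be > 0")

    @property
    def t_end(self) -> float:
        return self.t_start + self.duration


@dataclass(frozen=True)
class CouplingSpec:
    """Mean-field coupling ``M = (K/N) * sum_i x_i(t)``."""

    K: float = 0.1
    N: int = 2

    def __post_init__(self):
        if self.K < 0:
            raise ValueError("coupling strength K must be >= 0")
        if self.N < 1:
            raise ValueError("number of oscillators N must be >= 1")


MODEL_FAMILIES = {
    "harmonic": HarmonicSpec,
    "duffing": DuffingSpec,
    "goodwin": GoodwinSpec,
    "gonze": GonzeSpec,
    "almeida": AlmeidaSpec,
    "poincare": PoincareSpec,
}

_VAR_NAMES = {
    "harmonic": ("x", "v"),
    "duffing": ("x", "v"),
    "goodwin": ("x", "y", "z"),
    "gonze": ("x", "y", "z"),
    "almeida": ("BMAL1", "ROR", "REV", "DBP", "E4BP4", "CRY", "PER", "PERCRY"),
    "poincare": ("x", "y"),
}

_DEFAULT_X0 = {
    "harmonic": (1.0, 0.0),
    "duffing": (1.0, 0.0),
    "goodwin": (0.1, 0.1, 0.1),
    "gonze": (0.1, 0.1, 0.1),
    "almeida": (1.0,) * 8,
    "poincare": (1.0, 0.0),
}


def make_default_spec(model_id: str):
    """Return the spec for ``model_id`` with its documented default parameters."""
    try:
        cls = MODEL_FAMILIES[model_id]
    except KeyError:
        valid = ", ".join(sorted(MODEL_FAMILIES))
        raise ValueError(
            f"unknown model id {model_id!r}; valid choices: {valid}"
        ) from None
    return cls()


def make_spec(model_id: str, overrides: Mapping[str, float] | None = None):
    """Build a spec from its family id and a flat ``{param: value}`` override map."""
    spec = make_default_spec(model_id)
    if overrides:
        spec = with_params(spec, **overrides)
    return spec


def model_id_of(spec) -> str:
    try:
        return spec.model_id
    except AttributeError:
        raise TypeError(f"{spec!r} is not an oscillator spec") from None


def param_names(spec) -> tuple[str, ...]:
    return tuple(f.name for f in dataclasses.fields(spec))


def get_param(spec, name: str) -> float:
    if name not in param_names(spec):
        raise KeyError(
            f"{type(spec).__name__} has no parameter {name!r}; "
            f"available: {', '.join(param_names(spec))}"
        )
    return getattr(spec, name)


def with_params(spec, **overrides):
    """Return a copy of ``spec`` with the given parameters replaced."""
    unknown = set(overrides) - set(param_names(spec))
    if unknown:
        raise KeyError(
            f"unknown parameter(s) {sorted(unknown)} for {type(spec).__name__}; "
            f"available: {', '.join(param_names(spec))}"
        )
    return dataclasses.replace(spec, **overrides)


def spec_to_dict(spec) -> dict:
    """Serialise a spec to a plain dict (round-trips through JSON/YAML)."""
    return {"model": model_id_of(spec), "params": dataclasses.asdict(spec)}


def spec_from_dict(payload: Mapping) -> object:
    return make_spec(payload["model"], payload.get("params") or {})


def var_names(spec) -> tuple[str, ...]:
    return _VAR_NAMES[model_id_of(spec)]


def default_initial_state(spec) -> np.ndarray:
    return np.asarray(_DEFAULT_X0[model_id_of(spec)], dtype=float)


# ---------------------------------------------------------------------------
# Right-hand sides (batch-capable: state shape (..., dim))
# ---------------------------------------------------------------------------

def harmonic_rhs(state, p):
    x, v = state[..., 0], state[..., 1]
    return np.stack([v, -(p["k"] / p["m"]) * x], axis=-1)


def duffing_rhs(state, p):
    x, v = state[..., 0], state[..., 1]
    dv = -(p["k"] / p["m"]) * x - (p["beta"] / p["m"]) * x**3
    return np.stack([np.broadcast_to(v, np.shape(dv)), dv], axis=-1)


def goodwin_rhs(state, p):
    x, y, z = state[..., 0], state[..., 1], state[..., 2]
    K1n = p["K1"] ** p["n"]
    # |z|: keeps fractional Hill powers finite if a solver probes z < 0
    repression = K1n / (K1n + np.abs(z) ** p["n"])
    dx = p["k1"] * repression - p["k2"] * x
    dy = p["k3"] * x - p["k4"] * y
    dz = p["k5"] * y - p["k6"] * z
    return np.stack([dx, dy, dz], axis=-1)


def gonze_rhs(state, p):
    x, y, z = state[..., 0], state[..., 1], state[..., 2]
    K1n = p["K1"] ** p["n"]
    repression = K1n / (K1n + np.abs(z) ** p["n"])
    dx = p["k1"] * repression - p["k2"] * x / (p["K2"] + x)
    dy = p["k3"] * x - p["k4"] * y / (p["K4"] + y)
    dz = p["k5"] * y - p["k6"] * z / (p["K6"] + z)
    return np.stack([dx, dy, dz], axis=-1)


def almeida_rhs(state, p):
    B = state[..., 0]
    ROR = state[..., 1]
    REV = state[..., 2]
    DBP = state[..., 3]
    E4 = state[..., 4]
    CRY = state[..., 5]
    PER = state[..., 6]
    PC = state[..., 7]

    ebox = p["VE"] * B / (p["kE"] + B + p["kEr"] * B * CRY)
    rore = p["VR"] * ROR / (p["kR"] + ROR) * p["kRr"] ** 2 / (p["kRr"] ** 2 + REV**2)
    dbox = p["VD"] * DBP / (p["kD"] + DBP) * p["kDr"] / (p["kDr"] + E4)

    assoc = p["gamma_PC"] * PER * CRY      # PER:CRY complex formation
    dissoc = p["gamma_CP"] * PC            # complex dissociation
    export = p["gamma_BP"] * B * PC        # BMAL1-mediated removal

    dB = rore - export
    dROR = ebox + rore - p["gamma_Ror"] * ROR
    dREV = 2.0 * ebox + dbox - p["gamma_Rev"] * REV
    dDBP = ebox - p["gamma_DB"] * DBP
    dE4 = 2.0 * rore - p["gamma_E4"] * E4
    dCRY = ebox + 2.0 * rore - assoc + dissoc - p["gamma_C"] * CRY
    dPER = ebox + dbox - assoc + dissoc - p["gamma_P"] * PER
    dPC = assoc - dissoc - export
    return np.stack([dB, dROR, dREV, dDBP, dE4, dCRY, dPER, dPC], axis=-1)


def poincare_rhs(state, p, Z=0.0, M=0.0, P=0.0):
    """Cartesian twist oscillator; additive forcing acts on ``dx/dt`` only."""
    x, y = state[..., 0], state[..., 1]
    r = np.hypot(x, y)
    radial = p["lam"] * (p["A"] - r)
    angular = 2.0 * np.pi / p["tau"] + p["eps"] * (p["A"] - r)
    dx = x * radial - y * angular + Z + M + P
    dy = y * radial + x * angular
    return np.stack([dx, dy], axis=-1)


_FAMILY_RHS = {
    "harmonic": harmonic_rhs,
    "duffing": duffing_rhs,
    "goodwin": goodwin_rhs,
    "gonze": gonze_rhs,
    "almeida": almeida_rhs,
    "poincare": poincare_rhs,
}


def family_rhs(model_id: str):
    """Batch right-hand side ``f(state, params_dict, ...)`` for a model family."""
    return _FAMILY_RHS[model_id]


def _params_of(spec) -> dict:
    return {f.name: getattr(spec, f.name) for f in dataclasses.fields(spec)}


def zeitgeber_value(z: ZeitgeberSpec, t):
    """Evaluate ``Z(t) = FZ * cos(2*pi*t/T + pi/2)``."""
    return z.FZ * np.cos(2.0 * np.pi * np.asarray(t) / z.T + np.pi / 2.0)


def pulse_value(p: PulseSpec, t):
    """Evaluate the square pulse: ``FP`` inside the window, 0 outside."""
    t = np.asarray(t)
    return np.where((t >= p.t_start) & (t <= p.t_end), p.FP, 0.0)


def _forcing_value(forcing, t) -> float:
    if forcing is None:
        return 0.0
    if isinstance(forcing, ZeitgeberSpec):
        return float(zeitgeber_value(forcing, t))
    if isinstance(forcing, PulseSpec):
        return float(pulse_value(forcing, t))
    if isinstance(forcing, (int, float, np.floating)):
        return float(forcing)
    if isinstance(forcing, (list, tuple)):
        return sum(_forcing_value(f, t) for f in forcing)
    raise TypeError(f"unsupported forcing {forcing!r}")


def eval_rhs(spec, state, t: float = 0.0, forcing=None) -> np.ndarray:
    """Instantaneous derivatives for any model spec.

    ``state`` must match the model dimension (2 mechanical / Poincare
    Cartesian, 3 Goodwin/Gonze, 8 Almeida).  ``forcing`` (a
    :class:`ZeitgeberSpec`, :class:`PulseSpec`, plain number or a sequence
    of these, summed) is only legal for the Poincare model, where it enters
    the x equation additively.  Negative kinetic-model states are accepted
    as inputs but lie outside the invariant (non-negative) region.
    """
    mid = model_id_of(spec)
    state = np.asarray(state, dtype=float)
    dim = len(_VAR_NAMES[mid])
    if state.shape[-1] != dim:
        raise ValueError(
            f"state dimension {state.shape[-1]} does not match "
            f"{mid} model dimension {dim}"
        )
    if forcing is not None and mid != "poincare":
        raise ValueError("additive forcing is only defined for the poincare model")
    p = _params_of(spec)
    if mid == "poincare":
        return poincare_rhs(state, p, Z=_forcing_value(forcing, t))
    return _FAMILY_RHS[mid](state, p)


def poincare_cartesian_rhs(spec: PoincareSpec, xy, t: float = 0.0,
                           Z: float = 0.0, M: float = 0.0, P: float = 0.0) -> np.ndarray:
    """Cartesian right-hand side with explicit zeitgeber/mean-field/pulse terms."""
    xy = np.asarray(xy, dtype=float)
    return poincare_rhs(xy, _params_of(spec), Z=Z, M=M, P=P)


def poincare_polar_rhs(spec: PoincareSpec, rphi) -> np.ndarray:
    """Polar right-hand side ``(dr/dt, dphi/dt)`` of the twist oscillator."""
    rphi = np.asarray(rphi, dtype=float)
    r = rphi[..., 0]
    dr = spec.lam * r * (spec.A - r)
    dphi = spec.omega + spec.eps * (spec.A - r) * np.ones_like(r)
    return np.stack([dr, dphi], axis=-1)


def polar_to_cartesian(rphi) -> np.ndarray:
    rphi = np.asarray(rphi, dtype=float)
    r, phi = rphi[..., 0], rphi[..., 1]
    return np.stack([r * np.cos(phi), r * np.sin(phi)], axis=-1)


def cartesian_to_polar(xy) -> np.ndarray:
    xy = np.asarray(xy, dtype=float)
    x, y = xy[..., 0], xy[..., 1]
    return np.stack([np.hypot(x, y), np.arctan2(y, x)], axis=-1)


def batch_params(specs: Sequence) -> dict:
    """Stack the parameters of same-family specs into arrays for batch RHS use."""
    ids = {model_id_of(s) for s in specs}
    if len(ids) != 1:
        raise ValueError(f"specs must share one model family, got {sorted(ids)}")
    names = param_names(specs[0])
    return {name: np.array([getattr(s, name) for s in specs]) for name in names}
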