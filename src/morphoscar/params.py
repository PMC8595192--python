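"""Model parameters, literature-derived rate formulas, and validity checks.

All quantities are in the model's native units (cm, day, g, cells, N); there
is no unit-conversion layer.  Two parameters are never set directly: the
proliferation exponent ``q`` and the collagen secretion rate ``k_rho`` are
equilibrium requirements and are always derived from the other parameters
(see :func:`derive_q` and :func:`derive_k_rho`).

Parameters that vary spatially (in the heterogeneous Monte Carlo study) may
be NumPy arrays of nodal values; every formula here is written to broadcast.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Union

import numpy as np

__all__ = [
    "ParameterSet",
    "ValidationReport",
    "InvalidParameterError",
    "derive_q",
    "derive_k_rho",
    "decay_rate_from_half_life",
    "apoptosis_rate_from_lifespan",
    "differentiation_rate",
    "validate_parameters",
]

Scalarish = Union[float, np.ndarray]


class InvalidParameterError(ValueError):
    """A parameter value outside its physical/mathematical domain."""


def derive_q(delta_N: Scalarish, r_F: Scalarish, kappa_F: Scalarish,
             N_bar: Scalarish) -> Scalarish:
    """Proliferation exponent making the fibroblast kinetics vanish at equilibrium.

    Solving the fibroblast reaction term for a root at ``(N_bar, M=0, c=0)``
    gives::

        q = [log(delta_N) - log(r_F * (1 - kappa_F * N_bar))] / log(N_bar)

    For the default parameter set q is approximately -0.415 (negative:
    apoptosis is slower than unconstrained division).
    """
    delta_N, r_F, kappa_F, N_bar = map(np.asarray, (delta_N, r_F, kappa_F, N_bar))
    if np.any(delta_N <= 0) or np.any(r_F <= 0) or np.any(kappa_F <= 0) \
            or np.any(N_bar <= 0):
        raise InvalidParameterError("derive_q requires strictly positive arguments")
    if np.any(kappa_F * N_bar >= 1):
        raise InvalidParameterError(
            "kappa_F * N_bar must be < 1 (equilibrium below carrying capacity)")
    q = (np.log(delta_N) - np.log(r_F * (1.0 - kappa_F * N_bar))) / np.log(N_bar)
    return float(q) if q.ndim == 0 else q


def derive_k_rho(delta_rho: Scalarish, rho_bar: Scalarish) -> Scalarish:
    """Collagen secretion rate balancing degradation at equilibrium: ``delta_rho * rho_bar**2``."""
    delta_rho, rho_bar = np.asarray(delta_rho), np.asarray(rho_bar)
    if np.any(delta_rho < 0) or np.any(rho_bar < 0):
        raise InvalidParameterError("derive_k_rho requires non-negative arguments")
    k = delta_rho * rho_bar ** 2
    return float(k) if k.ndim == 0 else k


def decay_rate_from_half_life(half_life_minutes: float) -> float:
    """Convert a molecular half-life in minutes to a decay rate per day.

    A 2-minute half-life (typical for free TGF-beta / PDGF) gives ~499/day.
    """
    if half_life_minutes <= 0:
        raise InvalidParameterError("half-life must be positive")
    return float(np.log(2.0)) * (24.0 * 60.0) / half_life_minutes


def apoptosis_rate_from_lifespan(PD: float, DT_hours: float) -> float:
    """Fibroblast apoptosis rate from lifespan: ``ln(2) / (PD * DT/24)``.

    ``PD`` is the lifespan in population doublings and ``DT_hours`` the
    doubling time in hours; (PD=70, DT=20) -> 0.0119/day, (40, 18) -> 0.0231/day.
    """
    if PD <= 0 or DT_hours <= 0:
        raise InvalidParameterError("PD and DT must be positive")
    return float(np.log(2.0)) / (PD * DT_hours / 24.0)


def differentiation_rate(activated_fraction: float, days: float,
                         dose: float) -> float:
    """Linear-activation estimate of the differentiation rate k_F.

    A fraction ``activated_fraction`` of fibroblasts converting to
    myofibroblasts over ``days`` days under a sustained signaling dose
    ``dose`` (g/cm^3) gives ``(activated_fraction / days) / dose`` in
    cm^3/(g day).
    """
    if activated_fraction <= 0 or days <= 0 or dose <= 0:
        raise InvalidParameterError("all arguments must be positive")
    return (activated_fraction / days) / dose


# Fields that may legitimately be spatially heterogeneous nodal arrays.
HETEROGENEOUS_CAPABLE = (
    "E", "mu", "xi", "delta_N", "delta_M", "rho_bar", "N_bar", "delta_rho",
    "a_c_II", "zeta", "kappa_F", "r_F",
)


@dataclass
class ParameterSet:
    """All constants of the contraction model.

    Defaults are the literature mean values for a healthy adult (the second
    age group of the feasibility study).  ``q`` and ``k_rho`` are read-only
    properties recomputed on access so that perturbing their inputs (e.g. in
    a sensitivity sweep) keeps the equilibrium identities intact.
    """

    # -- signaling molecule kinetics
    D_c: Scalarish = 2.88e-3       # diffusion of signaling molecules, cm^2/day
    k_c: Scalarish = 3e-13         # max net secretion rate, g/(cells day)
    a_c_I: Scalarish = 1e-8        # half-max secretion concentration, g/cm^3
    eta_I: Scalarish = 2.0         # myo/fibro secretion ratio
    delta_c: Scalarish = 5e-4      # proteolytic breakdown rate, cm^6/(cells g day)
    eta_II: Scalarish = 0.45       # myo/fibro MMP-secretion ratio
    a_c_II: Scalarish = 2e8        # MMP-secretion inhibition constant, cm^3/g
    a_c_III: Scalarish = 1e-8      # half-max proliferation enhancement, g/cm^3
    # -- cell kinetics
    D_F: Scalarish = 1e-6          # (myo)fibroblast diffusion factor, cm^5/(cells day)
    chi_F: Scalarish = 2e-3        # chemotactic parameter, cm^5/(g day)
    r_F: Scalarish = 0.924         # cell division rate, cm^{3q}/(cells^q day)
    r_F_max: Scalarish = 2.0       # max division-rate enhancement factor
    kappa_F: Scalarish = 1e-6      # crowding factor, cm^3/cells
    k_F: Scalarish = 1.08e7        # differentiation rate, cm^3/(g day)
    delta_N: Scalarish = 0.02      # fibroblast apoptosis rate, /day
    delta_M: Scalarish = 0.06      # myofibroblast apoptosis rate, /day
    # -- collagen kinetics
    k_rho_max: Scalarish = 10.0    # max collagen-secretion enhancement factor
    a_c_IV: Scalarish = 1e-9       # half-max collagen enhancement, g/cm^3
    delta_rho: Scalarish = 6e-6    # collagen degradation rate, cm^6/(cells g day)
    # -- mechanics
    rho_t: Scalarish = 1.09        # total dermal tissue mass density, g/cm^3
    mu: Scalarish = 100.0          # viscosity, (N day)/cm^2
    E: Scalarish = 350.0           # Young's-modulus factor, N/((g cm)^{1/2})
    xi: Scalarish = 4.4e-2         # traction per cell per collagen, (N g)/(cells cm^2)
    R: Scalarish = 0.995           # body-force saturation constant, g/cm^3
    zeta: Scalarish = 4e2          # rate of morphoelastic change, cm^6/(cells g day)
    # -- equilibria and wound values
    N_bar: Scalarish = 1e4         # equilibrium fibroblast density, cells/cm^3
    N_tilde: Scalarish = 2e3       # wound fibroblast density, cells/cm^3
    M_bar: Scalarish = 0.0         # equilibrium myofibroblast density, cells/cm^3
    c_bar: Scalarish = 0.0         # equilibrium signaling concentration, g/cm^3
    c_tilde: Scalarish = 1e-8      # wound signaling concentration, g/cm^3
    rho_bar: Scalarish = 0.1125    # equilibrium collagen concentration, g/cm^3
    rho_tilde: Scalarish = 0.2 * 0.1125  # wound collagen concentration, g/cm^3
    # -- geometry
    L: float = 10.0                # half-length of computational domain, cm
    L_w: float = 3.6               # half-length of wound, cm
    s: float = 1.5                 # wound-edge transition width, cm
    # -- modeling switch: apply the wound profile to collagen too (a burn
    #    destroys dermal collagen); False restores the uniform rho_bar start.
    wounded_collagen: bool = True

    @property
    def q(self) -> Scalarish:
        """Proliferation exponent (always derived; see :func:`derive_q`)."""
        return derive_q(self.delta_N, self.r_F, self.kappa_F, self.N_bar)

    @property
    def k_rho(self) -> Scalarish:
        """Collagen secretion rate (always derived; see :func:`derive_k_rho`)."""
        return derive_k_rho(self.delta_rho, self.rho_bar)

    def replace(self, **changes) -> "ParameterSet":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["q"] = self.q
        d["k_rho"] = self.k_rho
        return d

    def is_heterogeneous(self) -> bool:
        return any(np.ndim(getattr(self, name)) > 0
                   for name in HETEROGENEOUS_CAPABLE)


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_parameters`.

    ``violations`` holds ``(constraint_name, left_value, right_value)``
    triples where the constraint ``left <= right`` (or as named) failed.
    """

    ok: bool = True
    violations: list = field(default_factory=list)

    def add(self, name: str, left: float, right: float) -> None:
        self.violations.append((name, float(left), float(right)))
        self.ok = False

    def to_dict(self) -> dict:
        return {
            "ok": self.ok,
            "violations": [
                {"constraint": n, "left": l, "right": r}
                for (n, l, r) in self.violations
            ],
        }


_POSITIVE_FIELDS = (
    "D_c", "k_c", "a_c_I", "eta_I", "delta_c", "eta_II", "a_c_II", "a_c_III",
    "D_F", "chi_F", "r_F", "r_F_max", "kappa_F", "k_F", "delta_N", "delta_M",
    "k_rho_max", "a_c_IV", "delta_rho", "rho_t", "mu", "E", "xi", "R", "zeta",
    "N_bar", "N_tilde", "rho_bar", "rho_tilde", "L", "L_w", "s",
)


def validate_parameters(p: ParameterSet) -> ValidationReport:
    """Check positivity, geometry, and the two linear-stability bounds.

    The stability constraints are ``k_c <= delta_c * rho_bar * a_c_I``
    (bounded net secretion of signaling molecules) and
    ``mu >= sqrt(rho_bar * E) / pi`` (viscous damping of the mechanical
    system).  For heterogeneous parameter fields the bounds are checked
    pointwise and the worst case is reported.
    """
    report = ValidationReport()
    for name in _POSITIVE_FIELDS:
        val = np.asarray(getattr(p, name))
        if np.any(val <= 0):
            report.add(f"{name} > 0", float(np.min(val)), 0.0)
    # wound signaling may be exactly zero (the unwounded control case)
    for name in ("M_bar", "c_bar", "c_tilde"):
        val = np.asarray(getattr(p, name))
        if np.any(val < 0):
            report.add(f"{name} >= 0", float(np.min(val)), 0.0)
    if not (p.s < p.L_w):
        report.add("s < L_w", p.s, p.L_w)
    if not (p.L_w < p.L):
        report.add("L_w < L", p.L_w, p.L)
    # stability: secretion of signaling molecules bounded by MMP clearance
    lhs = np.asarray(p.k_c, dtype=float)
    rhs = np.asarray(p.delta_c * p.rho_bar * p.a_c_I, dtype=float)
    if np.any(lhs > rhs):
        i = np.argmax(lhs - rhs)
        report.add("k_c <= delta_c*rho_bar*a_c_I",
                   float(np.ravel(np.broadcast_arrays(lhs, rhs)[0])[i]),
                   float(np.ravel(np.broadcast_arrays(lhs, rhs)[1])[i]))
    # stability: viscosity dominates the elastic wave speed
    mu = np.asarray(p.mu, dtype=float)
    bound = np.sqrt(np.asarray(p.rho_bar, dtype=float)
                    * np.asarray(p.E, dtype=float)) / np.pi
    if np.any(mu < bound):
        i = np.argmax(bound - mu)
        report.add("mu >= sqrt(rho_bar*E)/pi",
                   float(np.ravel(np.broadcast_arrays(mu, bound)[0])[i]),
                   float(np.ravel(np.broadcast_arrays(mu, bound)[1])[i]))
    return report
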