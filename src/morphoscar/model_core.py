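"""Continuous model: reaction kinetics, mechanics terms, initial profiles.

The model tracks six coupled fields on a one-dimensional dermal section:
signaling molecules ``c`` (lumped cytokines/growth factors), fibroblasts
``N``, myofibroblasts ``M``, collagen ``rho``, the displacement velocity
``v``, and the effective Eulerian strain ``eps`` (the elastically
recoverable part of the local strain).  The displacement ``u`` is carried
along for the contraction readout.  Matrix metalloproteinase (MMP) activity
is an instantaneous balance of its producers and inhibitor rather than an
explicit field.

All kinetics are defined on the non-negative orthant; the constant
equilibrium state (c=0, N=N_bar, M=0, rho=rho_bar, v=0, eps=0) is a
simultaneous root of every reaction term by construction of the derived
parameters q and k_rho.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .params import ParameterSet

logger = logging.getLogger(__name__)

__all__ = [
    "FieldState",
    "InitialProfileSpec",
    "initial_profile",
    "initialize_state",
    "mmp_activity",
    "reaction_c",
    "reaction_N",
    "reaction_M",
    "reaction_rho",
    "cell_traction",
    "strain_relaxation_rate",
    "clip_nonnegative",
]

FIELD_NAMES = ("c", "N", "M", "rho", "v", "eps")


@dataclass
class FieldState:
    """Nodal values of all unknowns on a (possibly moved) mesh at one time.

    ``x`` is strictly increasing; nodes are material points, so a node keeps
    its identity as the tissue contracts.
    """

    t: float
    x: np.ndarray
    c: np.ndarray
    N: np.ndarray
    M: np.ndarray
    rho: np.ndarray
    v: np.ndarray
    eps: np.ndarray
    u: np.ndarray

    def copy(self) -> "FieldState":
        return FieldState(self.t, *(getattr(self, f).copy()
                                    for f in ("x",) + FIELD_NAMES + ("u",)))

    def check(self) -> None:
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("mesh tangled: node coordinates not increasing")


@dataclass
class InitialProfileSpec:
    """Piecewise-sinusoidal wound profile: plateaus joined by half-sine ramps.

    ``healthy_value`` may be a nodal array (heterogeneous skin); the wound
    plateau is reached for |x| <= L_w - s and the healthy plateau for
    |x| >= L_w, with a monotone sine transition of width ``s`` on each edge.
    """

    healthy_value: float | np.ndarray
    wound_value: float | np.ndarray
    L_w: float
    s: float

    def __post_init__(self):
        if self.s > self.L_w:
            raise ValueError("transition width s must not exceed L_w")


def initial_profile(x: np.ndarray, spec: InitialProfileSpec) -> np.ndarray:
    """Evaluate the initial wound profile at coordinates ``x``.

    Continuous, symmetric in x, equal to the arithmetic mean of the two
    plateau values at the transition midpoint |x| = L_w - s/2.
    """
    ax = np.abs(np.asarray(x, dtype=float))
    h = np.asarray(spec.healthy_value, dtype=float)
    w = np.asarray(spec.wound_value, dtype=float)
    # ramp: 0 on the wound plateau, 1 on the healthy plateau
    ramp = 0.5 + 0.5 * np.sin(np.pi / spec.s * (ax - spec.L_w + spec.s / 2.0))
    ramp = np.where(ax >= spec.L_w, 1.0, np.where(ax <= spec.L_w - spec.s, 0.0, ramp))
    return w + (h - w) * ramp


def initialize_state(p: ParameterSet, x: np.ndarray) -> FieldState:
    """Build the wounded initial condition on mesh ``x``.

    N, c (and rho when ``p.wounded_collagen``) follow the sinusoidal wound
    profile; myofibroblasts, displacement, velocity, and strain start at
    zero.
    """
    x = np.asarray(x, dtype=float)
    nn = x.size

    def bcast(val):
        return np.broadcast_to(np.asarray(val, dtype=float), (nn,)).copy()

    N = initial_profile(x, InitialProfileSpec(p.N_bar, p.N_tilde, p.L_w, p.s))
    c = initial_profile(x, InitialProfileSpec(p.c_bar, p.c_tilde, p.L_w, p.s))
    if p.wounded_collagen:
        rho = initial_profile(
            x, InitialProfileSpec(p.rho_bar, p.rho_tilde, p.L_w, p.s))
    else:
        rho = bcast(p.rho_bar)
    zero = np.zeros(nn)
    return FieldState(t=0.0, x=x.copy(), c=bcast(c), N=bcast(N),
                      M=zero.copy(), rho=bcast(rho), v=zero.copy(),
                      eps=zero.copy(), u=zero.copy())


def clip_nonnegative(arr: np.ndarray, name: str = "field") -> np.ndarray:
    """Clip solver undershoots below zero, warning if the excursion is large.

    Kinetics are only defined on the non-negative orthant; mass lumping keeps
    undershoot rare and small, so anything beyond roundoff is logged.
    """
    low = arr.min() if arr.size else 0.0
    if low < 0:
        scale = np.abs(arr).max() or 1.0
        if low < -1e-9 * scale:
            logger.warning("clipping negative %s values (min %.3e)", name, low)
        return np.maximum(arr, 0.0)
    return arr


# --- reaction kinetics -----------------------------------------------------

def mmp_activity(N, M, c, rho, p: ParameterSet):
    """Instantaneous MMP balance g = [N + eta_II*M]*rho / (1 + a_c_II*c).

    Non-negative, linear in rho, and decreasing in c (the signaling
    molecules inhibit MMP secretion).
    """
    return (N + p.eta_II * M) * rho / (1.0 + p.a_c_II * c)


def reaction_c(c, N, M, rho, p: ParameterSet):
    """Net production of signaling molecules (secretion minus MMP breakdown)."""
    secretion = p.k_c * (c / (p.a_c_I + c)) * (N + p.eta_I * M)
    return secretion - p.delta_c * mmp_activity(N, M, c, rho, p) * c


def _power_1q(pop, q):
    """pop**(1+q) with pop=0 mapped to 0 (1+q > 0 for realistic q)."""
    scalar = np.ndim(pop) == 0 and np.ndim(q) == 0
    base, expo = np.broadcast_arrays(
        np.atleast_1d(np.asarray(pop, dtype=float)),
        np.atleast_1d(1.0 + np.asarray(q, dtype=float)))
    out = np.zeros(base.shape)
    pos = base > 0
    out[pos] = base[pos] ** expo[pos]
    return float(out[0]) if scalar else out


def reaction_N(N, M, c, p: ParameterSet):
    """Fibroblast kinetics: signaling-enhanced crowded logistic growth,
    differentiation loss, and apoptosis."""
    growth = (p.r_F * (1.0 + p.r_F_max * c / (p.a_c_III + c))
              * (1.0 - p.kappa_F * (N + M)) * _power_1q(N, p.q))
    return growth - p.k_F * c * N - p.delta_N * N


def reaction_M(N, M, c, p: ParameterSet):
    """Myofibroblast kinetics: signaling-gated growth, differentiation gain,
    and apoptosis.  Without signaling molecules there is no myofibroblast
    source."""
    growth = (p.r_F * ((1.0 + p.r_F_max) * c / (p.a_c_III + c))
              * (1.0 - p.kappa_F * (N + M)) * _power_1q(M, p.q))
    return growth + p.k_F * c * N - p.delta_M * M


def reaction_rho(N, M, c, rho, p: ParameterSet):
    """Collagen kinetics: cell secretion (signaling-enhanced) minus MMP-driven
    degradation."""
    secretion = (p.k_rho * (1.0 + p.k_rho_max * c / (p.a_c_IV + c))
                 * (N + p.eta_I * M))
    return secretion - p.delta_rho * mmp_activity(N, M, c, rho, p) * rho


# --- mechanics -------------------------------------------------------------

def cell_traction(M, rho, p: ParameterSet):
    """Myofibroblast pulling stress xi*M*rho/(R^2 + rho^2).

    For fixed M this is maximal at rho = R: sparse collagen gives the cells
    nothing to pull on, dense collagen resists deformation.
    """
    return p.xi * M * rho / (p.R ** 2 + rho ** 2)


def strain_relaxation_rate(N, M, c, eps, p: ParameterSet):
    """Morphoelastic source: -zeta * [N + eta_II*M]*c/(1 + a_c_II*c) * eps.

    Always opposite in sign to eps; this active decay of the effective
    strain is what converts transient contraction into permanent
    deformation.
    """
    return -p.zeta * (N + p.eta_II * M) * c / (1.0 + p.a_c_II * c) * eps
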