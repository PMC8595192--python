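"""Outcome curves and scalar summaries of a contraction simulation.

Two curves are tracked over the healing year:

* **relative surface area (RSA)** — the distance between the material
  points that started at the wound edges, as a percentage of the initial
  wound length.  Because the mesh moves with the material, the initial
  wound-edge nodes remain material points and the readout is exact node
  tracking ("surface area" of a 1D wound is its interval length);
* **total strain energy (SED)** — the integral of (1/2)*E*sqrt(rho)*eps^2
  over the whole domain, a proxy for the discomfort the patient
  experiences.  On a half-domain run the symmetric full-domain value is
  reported (the half-domain integral without the 1/2).

Five scalars summarize a run: the minimum RSA (maximum contraction), the
day it is reached, the RSA at day 365 (permanent contraction), the maximum
SED, and the day it is reached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fem import Trajectory
from .params import ParameterSet

__all__ = ["SummaryStatistics", "rsa_series", "sed_series", "summarize",
           "summarize_trajectory"]


@dataclass
class SummaryStatistics:
    """The five scalar outputs of one simulation."""

    RSA_min: float    # %
    RSA_day: int      # day index of minimum RSA (earliest if tied)
    RSA_365: float    # % at the end of the follow-up year
    SED_max: float    # model units (N/cm)
    SED_day: int      # day index of maximum SED (earliest if tied)

    def to_dict(self) -> dict:
        return {"RSA_min": self.RSA_min, "RSA_day": self.RSA_day,
                "RSA_365": self.RSA_365, "SED_max": self.SED_max,
                "SED_day": self.SED_day}


def rsa_series(traj: Trajectory, L_w: float = None) -> np.ndarray:
    """Relative surface area (%) at each stored time.

    Tracks the node(s) initially at the wound edge(s); RSA(0) = 100.
    """
    if traj.edge_index is None:
        raise ValueError("trajectory lacks a wound-edge marker node")
    length0 = traj.initial_wound_length
    if L_w is not None:
        expected = L_w if traj.edge_index_right is None else 2 * L_w
        if abs(length0 - expected) > 1e-9 * max(1.0, expected):
            raise ValueError("wound-edge marker does not match L_w")
    out = np.empty(len(traj.states))
    for k, st in enumerate(traj.states):
        if traj.edge_index_right is None:
            length = -st.x[traj.edge_index]
        else:
            length = st.x[traj.edge_index_right] - st.x[traj.edge_index]
        out[k] = 100.0 * length / length0
    return out


def _sed_at(state, E_nodal: np.ndarray, half_domain: bool) -> float:
    dens = E_nodal * np.sqrt(np.maximum(state.rho, 0.0)) * state.eps ** 2
    integral = np.trapezoid(dens, state.x)
    # full-domain form of the energy: (1/2) * integral over [-L, L]
    return integral if half_domain else 0.5 * integral


def sed_series(traj: Trajectory, p: ParameterSet = None) -> np.ndarray:
    """Total strain energy at each stored time (trapezoidal quadrature on
    the moving mesh)."""
    p = p or traj.params
    nn = traj.states[0].x.size
    E_nodal = np.broadcast_to(np.asarray(p.E, dtype=float), (nn,))
    half = traj.edge_index_right is None
    return np.asarray([_sed_at(st, E_nodal, half) for st in traj.states])


def summarize(rsa: np.ndarray, sed: np.ndarray, times: np.ndarray,
              horizon: float = 365.0) -> SummaryStatistics:
    """Reduce the two curves to the five scalar summaries.

    ``times`` must cover day 0 through ``horizon`` at (integer-)daily
    resolution; day indices use earliest-day tie-breaking.
    """
    rsa, sed, times = map(np.asarray, (rsa, sed, times))
    if not (len(rsa) == len(sed) == len(times)):
        raise ValueError("series lengths differ")
    if times[-1] < horizon - 1e-9:
        raise ValueError(
            f"series end at day {times[-1]:.1f}, before day {horizon:g}")
    i_min = int(np.argmin(rsa))
    i_max = int(np.argmax(sed))
    i_end = int(np.argmin(np.abs(times - horizon)))
    return SummaryStatistics(
        RSA_min=float(rsa[i_min]), RSA_day=int(round(times[i_min])),
        RSA_365=float(rsa[i_end]), SED_max=float(sed[i_max]),
        SED_day=int(round(times[i_max])))


def summarize_trajectory(traj: Trajectory,
                         horizon: float = None) -> SummaryStatistics:
    """Convenience wrapper: curves plus summary straight from a trajectory."""
    if horizon is None:
        horizon = traj.config.t_end
    return summarize(rsa_series(traj), sed_series(traj), traj.times,
                     horizon=horizon)
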