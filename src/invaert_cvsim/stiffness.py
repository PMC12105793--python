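"""Stiffness analysis of the linearized circulation model.

With the valve indicators frozen at the current state, the pressure dynamics
take the linear time-varying form ``dP/dt = A(t) P + b(t)``.  The spectrum of
A(t) along a converged periodic solution quantifies how widely separated the
fast (ventricular ejection) and slow (venous filling) timescales are: the
stiffness ratio

    SR(t) = max|Re(lambda)| / min|Re(lambda)|

uses the smallest-magnitude eigenvalue above a zero tolerance in the
denominator, since conserved combinations of pressures make one or more exact
zeros.  The reciprocal magnitudes 1/|Re(lambda)| are the intrinsic timescales,
which during ejection agree with resistor-capacitor constants at the
ventricular outflows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cvsim6 import (MMHG_TO_BARYE, CVSimError, ParameterSet, Trajectory,
                     system_matrix)

#: Default threshold below which an eigenvalue counts as numerically zero.
ZERO_TOL = 1e-14

#: Allowed relative imaginary part (w.r.t. the spectral radius) before the
#: spectrum is declared non-real.
IMAG_TOL = 1e-8


class StiffnessWarning(UserWarning):
    pass


@dataclass
class LinearizedSystem:
    """``dP/dt = A P + b`` at one instant; A in 1/s, b in Barye/s."""

    A: np.ndarray
    b: np.ndarray
    t: float


def linearize(t: float, P, params: ParameterSet) -> LinearizedSystem:
    """Assemble A(t), b(t) with valve indicators frozen at the state ``P``
    (Barye).  A collects every pressure-linear term, including the
    ``-dC/C`` diagonal contributions of the ventricles; b collects the
    ``Pth*dC/C`` transthoracic forcing."""
    A, b = system_matrix(t, P, params)
    return LinearizedSystem(A=A, b=b, t=t)


def sort_eigensystem(eigvals: np.ndarray, eigvecs: np.ndarray | None = None):
    """Order eigenvalues by |Re| descending; ties broken by signed real part
    descending (reproducible ordering)."""
    order = np.lexsort((-eigvals.real, -np.abs(eigvals.real)))
    if eigvecs is None:
        return eigvals[order]
    return eigvals[order], eigvecs[:, order]


def stiffness_ratio(eigenvalues, tol: float = ZERO_TOL) -> float:
    """SR = max|Re| / min|Re| over eigenvalues with |Re| above ``tol``.

    Zero (sub-tolerance) eigenvalues are excluded from the denominator; if
    every eigenvalue is below the tolerance the ratio is undefined and NaN is
    returned with a warning.
    """
    mags = np.abs(np.real(np.asarray(eigenvalues, dtype=complex)))
    nonzero = mags[mags > tol]
    if nonzero.size == 0:
        warnings.warn("all eigenvalues below tolerance: SR undefined",
                      StiffnessWarning)
        return float("nan")
    return float(nonzero.max() / nonzero.min())


def characteristic_timescales(eigenvalues, tol: float = ZERO_TOL) -> np.ndarray:
    """Intrinsic timescales tau_i = 1/|Re(lambda_i)| (s), zero eigenvalues
    excluded, returned in the input (magnitude-descending) order."""
    mags = np.abs(np.real(np.asarray(eigenvalues, dtype=complex)))
    return 1.0 / mags[mags > tol]


def rc_constants(params: ParameterSet) -> dict[str, float]:
    """Resistor-capacitor constants R*C_j*C_k/(C_j+C_k) (s) for each
    neighbouring compartment pair, keyed by the shared resistance.

    Ventricular capacitances enter with the phase in which the corresponding
    valve conducts: systolic value at the outflow valves, diastolic value at
    the inflow valves.
    """
    p = params

    def rc(r, cj, ck):
        return r * cj * ck / (cj + ck)

    return {
        "Rl_in": rc(p.Rl_in, p.Cpv, p.Cl_dia),    # mitral: pv -> lv filling
        "Rl_out": rc(p.Rl_out, p.Cl_sys, p.Ca),   # aortic: lv ejection
        "Ra": rc(p.Ra, p.Ca, p.Cv),               # systemic bed
        "Rr_in": rc(p.Rr_in, p.Cv, p.Cr_dia),     # tricuspid: rv filling
        "Rr_out": rc(p.Rr_out, p.Cr_sys, p.Cpa),  # pulmonary: rv ejection
        "Rpv": rc(p.Rpv, p.Cpa, p.Cpv),           # pulmonary bed
    }


@dataclass
class StiffnessProfile:
    """Eigenstructure of A(t) sampled along a trajectory window.

    ``eigenvalues[k]`` holds the six real eigenvalues at ``time_grid[k]``
    sorted by |Re| descending; ``eigenvectors[k]`` the matching unit
    eigenvector columns; ``SR[k]`` the stiffness ratio.
    """

    time_grid: np.ndarray           # (nt,)
    eigenvalues: np.ndarray         # (nt, 6) real
    eigenvectors: np.ndarray        # (nt, 6, 6)
    SR: np.ndarray                  # (nt,)
    tol: float = ZERO_TOL

    i_max: int = field(init=False)
    i_min: int = field(init=False)

    def __post_init__(self):
        self.i_max = int(np.nanargmax(self.SR))
        self.i_min = int(np.nanargmin(self.SR))

    @property
    def t_max_sr(self) -> float:
        """Instant of maximum stiffness ratio (s from simulation start)."""
        return float(self.time_grid[self.i_max])

    @property
    def t_min_sr(self) -> float:
        return float(self.time_grid[self.i_min])

    @property
    def eigenvalues_at_max_sr(self) -> np.ndarray:
        return self.eigenvalues[self.i_max]

    @property
    def eigenvalues_at_min_sr(self) -> np.ndarray:
        return self.eigenvalues[self.i_min]

    def to_frame(self):
        import pandas as pd

        data = {"t": self.time_grid}
        for i in range(6):
            data[f"lambda{i + 1}"] = self.eigenvalues[:, i]
        data["SR"] = self.SR
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def eigenvector_table(self, index: int):
        """Tidy |eigenvector| components at one sample (radar-plot data)."""
        import pandas as pd

        from .cvsim6 import STATE_NAMES

        rows = []
        for mode in range(6):
            for comp in range(6):
                rows.append({
                    "mode": mode + 1,
                    "eigenvalue": self.eigenvalues[index, mode],
                    "component": STATE_NAMES[comp],
                    "abs_value": abs(self.eigenvectors[index, comp, mode]),
                })
        return pd.DataFrame(rows)


def eigen_history(traj: Trajectory, params: ParameterSet | None = None,
                  window: tuple[float, float] | None = None,
                  tol: float = ZERO_TOL,
                  imag_tol: float = IMAG_TOL) -> StiffnessProfile:
    """Eigen-decompose A(t) at every trajectory sample inside ``window``
    (default: the last two cycles) and attach the SR series.

    A non-real eigenvalue with |Im| exceeding ``imag_tol`` times the spectral
    radius raises, rather than being silently truncated.
    """
    if params is None:
        params = traj.params
    if window is None:
        window = (traj.t[-1] - 2.0 * params.cycle_length, traj.t[-1])
    if traj.t[0] > window[0] + 1e-9 or traj.t[-1] < window[1] - 1e-9:
        raise CVSimError("trajectory does not cover the requested window")
    sel = (traj.t >= window[0] - 1e-12) & (traj.t <= window[1] + 1e-12)
    t = traj.t[sel]
    P = traj.pressures_barye[sel]
    nt = t.size
    vals = np.empty((nt, 6))
    vecs = np.empty((nt, 6, 6))
    sr = np.empty(nt)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", StiffnessWarning)
        for k in range(nt):
            A, _ = system_matrix(t[k], P[k], params)
            w, V = np.linalg.eig(A)
            radius = max(np.abs(w).max(), 1.0)
            if np.abs(w.imag).max() > imag_tol * radius:
                raise CVSimError(
                    f"non-real eigenvalue at t={t[k]:.4f}: {w}")
            w, V = sort_eigensystem(w, V)
            vals[k] = w.real
            vecs[k] = V.real
            sr[k] = stiffness_ratio(w, tol)
    return StiffnessProfile(time_grid=t, eigenvalues=vals, eigenvectors=vecs,
                            SR=sr, tol=tol)
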