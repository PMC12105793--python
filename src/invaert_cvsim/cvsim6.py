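"""CVSim-6: a six-compartment lumped-parameter model of the human circulation.

The closed loop consists of the left ventricle (l), systemic arteries (a),
systemic veins (v), right ventricle (r), pulmonary arteries (pa) and pulmonary
veins (pv).  Each compartment is a two-element Windkessel (capacitance C,
unstressed volume V0) connected to its neighbour through a resistance R; the
four heart valves are ideal diodes expressed with indicator functions.
Ventricular contraction is driven by prescribed time-varying capacitances
oscillating between a diastolic and a systolic value.

State variables are the six compartment pressures, integrated in CGS units
(Barye, ml, s) with mmHg at user-facing interfaces.  The forward map
``v -> y`` composes :func:`simulate` with :func:`extract_outputs`, producing
the 16 clinical targets (systolic/diastolic pressures and volumes, ejection
fraction, cardiac output, vascular resistances).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
from scipy.integrate import solve_ivp

try:  # numba accelerates the integrator callbacks ~30x; pure numpy works too
    from numba import njit as _njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba present in the target env
    HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap


MMHG_TO_BARYE = 1333.22  # 1 mmHg in Barye (dyn/cm^2); consistent with Ra's default

STATE_NAMES = ["Pl", "Pa", "Pv", "Pr", "Ppa", "Ppv"]
FLOW_NAMES = ["Ql_in", "Ql_out", "Qa", "Qr_in", "Qr_out", "Qpv"]

#: 23 input parameters, CGS units (pressures of the parameter vector in mmHg).
PARAM_NAMES = [
    "Hr", "Pth", "rsys",
    "Cl_dia", "Cl_sys", "Ca", "Cv", "Cr_dia", "Cr_sys", "Cpa", "Cpv",
    "Rl_in", "Rl_out", "Ra", "Rr_in", "Rr_out", "Rpv",
    "Vl0", "Va0", "Vv0", "Vr0", "Vpa0", "Vpv0",
]

#: The 16 clinical outputs, in their conventional order and units.
OUTPUT_NAMES = [
    "Hr", "Pa_sys", "Pa_dia", "Pr_sys", "Pr_dia", "Ppa_sys", "Ppa_dia",
    "Pr_edp", "Pw", "Pcvp", "Vl_sys", "Vl_dia", "LVEF", "CO", "SVR", "PVR",
]

#: Literature-based measurement standard deviation per output component
#: (bpm, mmHg..., ml, -, L/min, dyn.s/cm^5).
OUTPUT_STDS = np.array(
    [3.0, 1.5, 1.5, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 0.5,
     10.0, 20.0, 0.02, 0.2, 50.0, 5.0]
)

OUTPUT_UNITS = [
    "bpm", "mmHg", "mmHg", "mmHg", "mmHg", "mmHg", "mmHg", "mmHg", "mmHg",
    "mmHg", "ml", "ml", "-", "L/min", "dyn.s/cm^5", "dyn.s/cm^5",
]


class CVSimError(ValueError):
    """Invalid model input (parameters, configuration or preconditions)."""


@dataclass
class ParameterSet:
    """The 23 physiological inputs of the model.

    Units: Hr in bpm, Pth in mmHg, rsys dimensionless, capacitances in
    ml/Barye, resistances in Barye*s/ml, unstressed volumes in ml.
    """

    Hr: float
    Pth: float
    rsys: float
    Cl_dia: float
    Cl_sys: float
    Ca: float
    Cv: float
    Cr_dia: float
    Cr_sys: float
    Cpa: float
    Cpv: float
    Rl_in: float
    Rl_out: float
    Ra: float
    Rr_in: float
    Rr_out: float
    Rpv: float
    Vl0: float
    Va0: float
    Vv0: float
    Vr0: float
    Vpa0: float
    Vpv0: float

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        errs = []
        if not self.Hr > 0:
            errs.append(f"Hr must be positive, got {self.Hr}")
        if not 0.0 < self.rsys < 1.0:
            errs.append(f"rsys must lie in (0, 1), got {self.rsys}")
        for name in ("Cl_dia", "Cl_sys", "Ca", "Cv", "Cr_dia", "Cr_sys",
                     "Cpa", "Cpv"):
            if not getattr(self, name) > 0:
                errs.append(f"capacitance {name} must be positive")
        for name in ("Rl_in", "Rl_out", "Ra", "Rr_in", "Rr_out", "Rpv"):
            if not getattr(self, name) > 0:
                errs.append(f"resistance {name} must be positive")
        for name in ("Vl0", "Va0", "Vv0", "Vr0", "Vpa0", "Vpv0"):
            if getattr(self, name) < 0:
                errs.append(f"unstressed volume {name} must be non-negative")
        if self.Cl_sys >= self.Cl_dia:
            errs.append("Cl_sys must be smaller than Cl_dia")
        if self.Cr_sys >= self.Cr_dia:
            errs.append("Cr_sys must be smaller than Cr_dia")
        if errs:
            raise CVSimError("; ".join(errs))

    # -- conversions --------------------------------------------------------
    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "ParameterSet":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(PARAM_NAMES),):
            raise CVSimError(f"expected {len(PARAM_NAMES)} parameters, "
                             f"got shape {arr.shape}")
        return cls(**dict(zip(PARAM_NAMES, arr.tolist())))

    def to_dict(self) -> dict:
        return {n: getattr(self, n) for n in PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        missing = [n for n in PARAM_NAMES if n not in d]
        if missing:
            raise CVSimError(f"missing parameters: {missing}")
        unknown = [k for k in d if k not in PARAM_NAMES]
        if unknown:
            raise CVSimError(f"unknown parameters: {unknown}")
        return cls(**{n: float(d[n]) for n in PARAM_NAMES})

    # -- file I/O (JSON object or one-row CSV keyed by symbol) --------------
    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path) -> "ParameterSet":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(PARAM_NAMES)
            w.writerow([getattr(self, n) for n in PARAM_NAMES])

    @classmethod
    def from_csv(cls, path) -> "ParameterSet":
        with open(path) as fh:
            rows = list(csv.reader(fh))
        if len(rows) < 2:
            raise CVSimError(f"{path}: expected a header row and a value row")
        return cls.from_dict(dict(zip(rows[0], map(float, rows[1]))))

    def replace(self, **kw) -> "ParameterSet":
        return replace(self, **kw)

    @property
    def cycle_length(self) -> float:
        """Cardiac period Ttot = 60/Hr in seconds."""
        return 60.0 / self.Hr

    @property
    def total_unstressed_volume(self) -> float:
        return self.Vl0 + self.Va0 + self.Vv0 + self.Vr0 + self.Vpa0 + self.Vpv0


def default_parameters() -> ParameterSet:
    """Reference parameter set of the model (healthy adult at 72 bpm)."""
    return ParameterSet(
        Hr=72.0, Pth=-4.0, rsys=0.33,
        Cl_dia=7.50e-3, Cl_sys=3.00e-4, Ca=1.20e-3, Cv=7.50e-2,
        Cr_dia=1.50e-2, Cr_sys=9.00e-4, Cpa=3.23e-3, Cpv=6.30e-3,
        Rl_in=13.33, Rl_out=8.00, Ra=1333.22, Rr_in=66.66, Rr_out=4.00,
        Rpv=106.66,
        Vl0=15.0, Va0=715.0, Vv0=2500.0, Vr0=15.0, Vpa0=90.0, Vpv0=490.0,
    )


# ---------------------------------------------------------------------------
# Time-varying ventricular capacitances
# ---------------------------------------------------------------------------

def ventricular_capacitances(t, params: ParameterSet):
    """Left/right ventricular capacitance and analytic time derivative.

    Both ventricles contract in perfect synchrony: over one cardiac cycle of
    length Ttot = 60/Hr the capacitance starts at its diastolic value, falls
    to the systolic value at end systole ``t = rsys*Ttot`` along a raised
    cosine, and recovers to the diastolic value along a second raised cosine
    over diastole.  The waveform is C1-smooth and Ttot-periodic.

    Parameters
    ----------
    t : float or array
        Time in seconds (t >= 0).
    params : ParameterSet

    Returns
    -------
    (Cl, dCl, Cr, dCr) : capacitances in ml/Barye and their derivatives in
        ml/Barye/s, with the same shape as ``t``.
    """
    if not 0.0 < params.rsys < 1.0:
        raise CVSimError(f"rsys must lie in (0, 1), got {params.rsys}")
    t = np.asarray(t, dtype=float)
    ttot = 60.0 / params.Hr
    tsys = params.rsys * ttot
    tdia = ttot - tsys
    tau = np.mod(t, ttot)
    in_sys = tau < tsys

    def _wave(c_from, c_to):
        # raised cosine from c_from to c_to over each sub-phase
        x_s = np.pi * tau / tsys
        x_d = np.pi * (tau - tsys) / tdia
        c = np.where(
            in_sys,
            c_from + (c_to - c_from) * 0.5 * (1.0 - np.cos(x_s)),
            c_to + (c_from - c_to) * 0.5 * (1.0 - np.cos(x_d)),
        )
        dc = np.where(
            in_sys,
            (c_to - c_from) * 0.5 * np.pi / tsys * np.sin(x_s),
            (c_from - c_to) * 0.5 * np.pi / tdia * np.sin(x_d),
        )
        return c, dc

    cl, dcl = _wave(params.Cl_dia, params.Cl_sys)
    cr, dcr = _wave(params.Cr_dia, params.Cr_sys)
    if t.ndim == 0:
        return float(cl), float(dcl), float(cr), float(dcr)
    return cl, dcl, cr, dcr


# ---------------------------------------------------------------------------
# Flows, right-hand side and the (A, b) form of the ODEs
# ---------------------------------------------------------------------------

def valve_flows(P, t, params: ParameterSet) -> np.ndarray:
    """Inter-compartment flows [Ql_in, Ql_out, Qa, Qr_in, Qr_out, Qpv] (ml/s).

    ``P`` holds the six pressures in Barye (ordering ``STATE_NAMES``), either
    a single state (6,) or a batch (n, 6).  The four valved flows follow the
    diode law ``Q = max(dP, 0)/R`` (indicator on the pressure difference);
    the two unvalved flows (systemic and pulmonary resistances) are linear
    with either sign.
    """
    P = np.asarray(P, dtype=float)
    if not np.all(np.isfinite(P)):
        raise CVSimError("non-finite pressure passed to valve_flows")
    pl, pa, pv, pr, ppa, ppv = (P[..., i] for i in range(6))
    q = np.empty(P.shape, dtype=float)
    q[..., 0] = np.maximum(ppv - pl, 0.0) / params.Rl_in   # mitral
    q[..., 1] = np.maximum(pl - pa, 0.0) / params.Rl_out   # aortic
    q[..., 2] = (pa - pv) / params.Ra                      # systemic bed
    q[..., 3] = np.maximum(pv - pr, 0.0) / params.Rr_in    # tricuspid
    q[..., 4] = np.maximum(pr - ppa, 0.0) / params.Rr_out  # pulmonary valve
    q[..., 5] = (ppa - ppv) / params.Rpv                   # pulmonary bed
    return q


def rhs(t: float, P, params: ParameterSet) -> np.ndarray:
    """Time derivative of the six pressures (Barye/s) at state ``P`` (Barye).

    The ventricular equations carry the extra ``-(P - Pth)*dC/C`` term from
    the chain rule on the stored volume C(t)*(P - Pth); the four passive
    compartments are plain flow balances divided by a constant capacitance.
    """
    P = np.asarray(P, dtype=float)
    q = valve_flows(P, t, params)
    cl, dcl, cr, dcr = ventricular_capacitances(t, params)
    pth = params.Pth * MMHG_TO_BARYE
    dP = np.empty(6, dtype=float)
    dP[0] = (q[0] - q[1] - (P[0] - pth) * dcl) / cl
    dP[1] = (q[1] - q[2]) / params.Ca
    dP[2] = (q[2] - q[3]) / params.Cv
    dP[3] = (q[3] - q[4] - (P[3] - pth) * dcr) / cr
    dP[4] = (q[4] - q[5]) / params.Cpa
    dP[5] = (q[5] - q[0]) / params.Cpv
    return dP


def system_matrix(t: float, P, params: ParameterSet):
    """State matrix A(t) (1/s) and forcing b(t) (Barye/s) with valve
    indicators frozen at the state ``P`` (Barye), so that
    ``rhs(t, P) == A @ P + b`` at the linearization state.

    ``b`` collects the transthoracic-pressure contribution ``Pth*dC/C`` of
    the two ventricular equations; away from the ventricular rows it is zero.
    """
    P = np.asarray(P, dtype=float)
    pl, pa, pv, pr, ppa, ppv = P
    il = 1.0 if ppv > pl else 0.0    # mitral open
    ol = 1.0 if pl > pa else 0.0     # aortic open
    ir = 1.0 if pv > pr else 0.0     # tricuspid open
    orr = 1.0 if pr > ppa else 0.0   # pulmonary valve open
    cl, dcl, cr, dcr = ventricular_capacitances(t, params)
    pth = params.Pth * MMHG_TO_BARYE
    p = params
    A = np.zeros((6, 6))
    A[0, 0] = -(il / p.Rl_in + ol / p.Rl_out) / cl - dcl / cl
    A[0, 1] = ol / (p.Rl_out * cl)
    A[0, 5] = il / (p.Rl_in * cl)
    A[1, 0] = ol / (p.Rl_out * p.Ca)
    A[1, 1] = -(ol / p.Rl_out + 1.0 / p.Ra) / p.Ca
    A[1, 2] = 1.0 / (p.Ra * p.Ca)
    A[2, 1] = 1.0 / (p.Ra * p.Cv)
    A[2, 2] = -(1.0 / p.Ra + ir / p.Rr_in) / p.Cv
    A[2, 3] = ir / (p.Rr_in * p.Cv)
    A[3, 2] = ir / (p.Rr_in * cr)
    A[3, 3] = -(ir / p.Rr_in + orr / p.Rr_out) / cr - dcr / cr
    A[3, 4] = orr / (p.Rr_out * cr)
    A[4, 3] = orr / (p.Rr_out * p.Cpa)
    A[4, 4] = -(orr / p.Rr_out + 1.0 / p.Rpv) / p.Cpa
    A[4, 5] = 1.0 / (p.Rpv * p.Cpa)
    A[5, 4] = 1.0 / (p.Rpv * p.Cpv)
    A[5, 5] = -(1.0 / p.Rpv + il / p.Rl_in) / p.Cpv
    A[5, 0] = il / (p.Rl_in * p.Cpv)
    b = np.zeros(6)
    b[0] = pth * dcl / cl
    b[3] = pth * dcr / cr
    return A, b


# ---------------------------------------------------------------------------
# Compiled integrator kernels (same maths as rhs/system_matrix, scalar form)
# ---------------------------------------------------------------------------

@_njit(cache=False)
def _capacitance_kernel(t, hr, rsys, c_dia, c_sys):
    ttot = 60.0 / hr
    tsys = rsys * ttot
    tau = t % ttot
    if tau < tsys:
        x = np.pi * tau / tsys
        c = c_dia + (c_sys - c_dia) * 0.5 * (1.0 - np.cos(x))
        dc = (c_sys - c_dia) * 0.5 * np.pi / tsys * np.sin(x)
    else:
        x = np.pi * (tau - tsys) / (ttot - tsys)
        c = c_sys + (c_dia - c_sys) * 0.5 * (1.0 - np.cos(x))
        dc = (c_dia - c_sys) * 0.5 * np.pi / (ttot - tsys) * np.sin(x)
    return c, dc


@_njit(cache=False)
def _rhs_kernel(t, P, theta):
    hr, pth_mmhg, rsys = theta[0], theta[1], theta[2]
    cl_dia, cl_sys, ca, cv = theta[3], theta[4], theta[5], theta[6]
    cr_dia, cr_sys, cpa, cpv = theta[7], theta[8], theta[9], theta[10]
    rl_in, rl_out, ra = theta[11], theta[12], theta[13]
    rr_in, rr_out, rpv = theta[14], theta[15], theta[16]
    pth = pth_mmhg * MMHG_TO_BARYE
    pl, pa, pv, pr, ppa, ppv = P[0], P[1], P[2], P[3], P[4], P[5]
    cl, dcl = _capacitance_kernel(t, hr, rsys, cl_dia, cl_sys)
    cr, dcr = _capacitance_kernel(t, hr, rsys, cr_dia, cr_sys)
    ql_in = (ppv - pl) / rl_in if ppv > pl else 0.0
    ql_out = (pl - pa) / rl_out if pl > pa else 0.0
    qa = (pa - pv) / ra
    qr_in = (pv - pr) / rr_in if pv > pr else 0.0
    qr_out = (pr - ppa) / rr_out if pr > ppa else 0.0
    qpv = (ppa - ppv) / rpv
    out = np.empty(6)
    out[0] = (ql_in - ql_out - (pl - pth) * dcl) / cl
    out[1] = (ql_out - qa) / ca
    out[2] = (qa - qr_in) / cv
    out[3] = (qr_in - qr_out - (pr - pth) * dcr) / cr
    out[4] = (qr_out - qpv) / cpa
    out[5] = (qpv - ql_in) / cpv
    return out


@_njit(cache=False)
def _jac_kernel(t, P, theta):
    hr, rsys = theta[0], theta[2]
    cl_dia, cl_sys, ca, cv = theta[3], theta[4], theta[5], theta[6]
    cr_dia, cr_sys, cpa, cpv = theta[7], theta[8], theta[9], theta[10]
    rl_in, rl_out, ra = theta[11], theta[12], theta[13]
    rr_in, rr_out, rpv = theta[14], theta[15], theta[16]
    pl, pa, pv, pr, ppa, ppv = P[0], P[1], P[2], P[3], P[4], P[5]
    cl, dcl = _capacitance_kernel(t, hr, rsys, cl_dia, cl_sys)
    cr, dcr = _capacitance_kernel(t, hr, rsys, cr_dia, cr_sys)
    il = 1.0 if ppv > pl else 0.0
    ol = 1.0 if pl > pa else 0.0
    ir = 1.0 if pv > pr else 0.0
    orr = 1.0 if pr > ppa else 0.0
    A = np.zeros((6, 6))
    A[0, 0] = -(il / rl_in + ol / rl_out) / cl - dcl / cl
    A[0, 1] = ol / (rl_out * cl)
    A[0, 5] = il / (rl_in * cl)
    A[1, 0] = ol / (rl_out * ca)
    A[1, 1] = -(ol / rl_out + 1.0 / ra) / ca
    A[1, 2] = 1.0 / (ra * ca)
    A[2, 1] = 1.0 / (ra * cv)
    A[2, 2] = -(1.0 / ra + ir / rr_in) / cv
    A[2, 3] = ir / (rr_in * cv)
    A[3, 2] = ir / (rr_in * cr)
    A[3, 3] = -(ir / rr_in + orr / rr_out) / cr - dcr / cr
    A[3, 4] = orr / (rr_out * cr)
    A[4, 3] = orr / (rr_out * cpa)
    A[4, 4] = -(orr / rr_out + 1.0 / rpv) / cpa
    A[4, 5] = 1.0 / (rpv * cpa)
    A[5, 4] = 1.0 / (rpv * cpv)
    A[5, 5] = -(1.0 / rpv + il / rl_in) / cpv
    A[5, 0] = il / (rl_in * cpv)
    return A


# ---------------------------------------------------------------------------
# Initial conditions
# ---------------------------------------------------------------------------

def _reference_pressures(params: ParameterSet) -> np.ndarray:
    """Per-compartment reference pressure (Barye) for the volume relation
    V = C*(P - P_ref) + V0.

    The intrathoracic compartments (both ventricles and the pulmonary
    circulation) are referenced to the transthoracic pressure Pth; the
    extrathoracic systemic arteries and veins to atmospheric (zero).
    """
    pth = params.Pth * MMHG_TO_BARYE
    return np.array([pth, 0.0, 0.0, pth, pth, pth])


def initial_conditions(params: ParameterSet,
                       total_blood_volume: float = 5000.0) -> np.ndarray:
    """Initial pressures (Barye) from a mass-conserving linear system.

    At t = 0 (cycle start, ventricular capacitances at their diastolic
    values) the stressed blood volume ``TBV - sum(V0)`` is distributed so
    that every compartment carries the same transmural pressure:

        (P_i - P_ref,i) - (P_i+1 - P_ref,i+1) = 0      (5 rows)
        sum_i C_i * (P_i - P_ref,i) = TBV - sum(V0)    (conservation row)

    With zero stressed volume every pressure equals its reference pressure.
    """
    params.validate()
    v0 = params.total_unstressed_volume
    if total_blood_volume < v0:
        raise CVSimError(
            f"total blood volume {total_blood_volume} ml is below the total "
            f"unstressed volume {v0} ml")
    C = np.array([params.Cl_dia, params.Ca, params.Cv,
                  params.Cr_dia, params.Cpa, params.Cpv])
    ref = _reference_pressures(params)
    M = np.zeros((6, 6))
    rhs_vec = np.zeros(6)
    for i in range(5):
        M[i, i], M[i, i + 1] = 1.0, -1.0
        rhs_vec[i] = ref[i] - ref[i + 1]
    M[5] = C
    rhs_vec[5] = (total_blood_volume - v0) + C @ ref
    try:
        P0 = np.linalg.solve(M, rhs_vec)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate C
        raise CVSimError(
            f"singular initial-condition system for parameters "
            f"{params.to_dict()}") from exc
    return P0


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Numerical settings of a forward run.

    ``solver`` is ``"radau"`` (adaptive fifth-order implicit Runge-Kutta,
    the reference scheme for this stiff system), ``"lsoda"`` (adaptive
    stiff/non-stiff switching multistep method; ~10x faster at slightly
    lower accuracy, used for bulk dataset generation) or ``"rk4"``
    (explicit fixed-step classic Runge-Kutta with step ``output_dt``,
    provided for instability studies).  ``output_dt`` is also the uniform
    dense-output step used for extrema and trapezoidal time averages.

    ``burn_in_cycles`` equilibrates the state on the limit cycle before the
    reported window: the algebraic initial condition conserves mass but
    starts away from the periodic orbit, and the slow systemic-venous
    volume redistribution (~10 s time constant) would otherwise still be
    settling during the final cycles.  The burn-in runs a cheap adaptive
    integration, then restores exact stressed-volume conservation; 0
    disables it.
    """

    n_cycles: int = 12
    solver: str = "radau"
    rel_tol: float = 1e-8
    abs_tol: float = 1e-6      # Barye; pressures are O(1e5) Barye
    output_dt: float = 1e-3
    total_blood_volume: float = 5000.0
    burn_in_cycles: int = 24

    def validate(self) -> None:
        if self.n_cycles < 1:
            raise CVSimError(f"n_cycles must be >= 1, got {self.n_cycles}")
        if self.burn_in_cycles < 0:
            raise CVSimError("burn_in_cycles must be >= 0")
        if self.output_dt <= 0:
            raise CVSimError("output_dt must be positive")
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise CVSimError("solver tolerances must be positive")
        if self.solver not in ("radau", "lsoda", "rk4"):
            raise CVSimError(f"unknown solver {self.solver!r}")


@dataclass
class SimulationFailure:
    """Structured record of a failed integration (never an exception), so
    batch generation can log and skip bad parameter draws."""

    params: ParameterSet
    message: str
    t_reached: float = 0.0

    ok: bool = field(default=False, init=False, repr=False)


@dataclass
class Trajectory:
    """Time-resolved solution of one simulation.

    Pressures are stored in mmHg, flows in ml/s, capacitances in ml/Barye,
    volumes in ml.  ``total_stressed_volume`` is ``sum_i C_i (P_i - P_ref,i)``
    which the continuous dynamics conserve exactly.
    """

    t: np.ndarray                      # (nt,) s, uniform grid
    pressures: np.ndarray              # (nt, 6) mmHg, STATE_NAMES order
    flows: np.ndarray                  # (nt, 6) ml/s, FLOW_NAMES order
    Cl: np.ndarray                     # (nt,) ml/Barye
    Cr: np.ndarray
    dCl: np.ndarray                    # (nt,) ml/Barye/s
    dCr: np.ndarray
    volumes: np.ndarray                # (nt, 6) ml
    total_stressed_volume: np.ndarray  # (nt,) ml
    params: ParameterSet
    config: SimulationConfig

    ok: bool = field(default=True, init=False, repr=False)

    @property
    def pressures_barye(self) -> np.ndarray:
        return self.pressures * MMHG_TO_BARYE

    def cycle_window(self, first: int, last: int) -> np.ndarray:
        """Boolean mask selecting cycles ``first`` (0-based) to ``last``
        (exclusive)."""
        ttot = self.params.cycle_length
        return (self.t >= first * ttot - 1e-12) & (self.t <= last * ttot + 1e-12)

    def to_frame(self):
        """Tidy export: one row per sample, named columns."""
        import pandas as pd

        data = {"t": self.t}
        for i, n in enumerate(STATE_NAMES):
            data[n] = self.pressures[:, i]
        for i, n in enumerate(FLOW_NAMES):
            data[n] = self.flows[:, i]
        data["Cl"], data["Cr"] = self.Cl, self.Cr
        data["dCl"], data["dCr"] = self.dCl, self.dCr
        for i, n in enumerate(STATE_NAMES):
            data["V" + n[1:].lower()] = self.volumes[:, i]
        data["total_stressed_volume"] = self.total_stressed_volume
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("t", data=self.t)
            f.create_dataset("pressures", data=self.pressures)
            f.create_dataset("flows", data=self.flows)
            f.create_dataset("volumes", data=self.volumes)
            f.create_dataset("Cl", data=self.Cl)
            f.create_dataset("Cr", data=self.Cr)
            f.create_dataset("dCl", data=self.dCl)
            f.create_dataset("dCr", data=self.dCr)
            f.create_dataset("total_stressed_volume",
                             data=self.total_stressed_volume)
            f.attrs["params"] = json.dumps(self.params.to_dict())
            f.attrs["config"] = json.dumps(vars(self.config))

    @classmethod
    def from_hdf5(cls, path) -> "Trajectory":
        import h5py

        with h5py.File(path, "r") as f:
            params = ParameterSet.from_dict(json.loads(f.attrs["params"]))
            config = SimulationConfig(**json.loads(f.attrs["config"]))
            return cls(
                t=f["t"][:], pressures=f["pressures"][:], flows=f["flows"][:],
                Cl=f["Cl"][:], Cr=f["Cr"][:], dCl=f["dCl"][:], dCr=f["dCr"][:],
                volumes=f["volumes"][:],
                total_stressed_volume=f["total_stressed_volume"][:],
                params=params, config=config)


def _integrate_rk4(fun, t_grid, y0):
    """Classic fixed-step RK4 on the output grid (explicit; may go unstable
    on this stiff system -- that is the point of offering it)."""
    y = np.empty((t_grid.size, y0.size))
    y[0] = y0
    for k in range(t_grid.size - 1):
        t, h = t_grid[k], t_grid[k + 1] - t_grid[k]
        k1 = fun(t, y[k])
        k2 = fun(t + 0.5 * h, y[k] + 0.5 * h * k1)
        k3 = fun(t + 0.5 * h, y[k] + 0.5 * h * k2)
        k4 = fun(t + h, y[k] + h * k3)
        y[k + 1] = y[k] + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(y[k + 1])):
            return y[: k + 2], t_grid[: k + 2], False
    return y, t_grid, True


def simulate(params: ParameterSet, config: SimulationConfig | None = None):
    """Integrate the model for ``config.n_cycles`` cardiac cycles.

    Returns a :class:`Trajectory` on success or a :class:`SimulationFailure`
    if the integrator does not converge (checked via ``.ok``).  Invalid
    inputs raise :class:`CVSimError`.
    """
    if config is None:
        config = SimulationConfig()
    params.validate()
    config.validate()
    T = config.n_cycles * params.cycle_length
    n_out = int(round(T / config.output_dt))
    t_grid = np.linspace(0.0, T, n_out + 1)
    P0 = initial_conditions(params, config.total_blood_volume)
    theta = params.to_array()
    fun = lambda t, P: _rhs_kernel(t, P, theta)
    jac = lambda t, P: _jac_kernel(t, P, theta)

    if config.burn_in_cycles > 0:
        t_burn = config.burn_in_cycles * params.cycle_length
        pre = solve_ivp(fun, (0.0, t_burn), P0, method="LSODA",
                        rtol=1e-6, atol=1e-2, jac=jac, t_eval=[t_burn])
        if not pre.success or not np.all(np.isfinite(pre.y)):
            return SimulationFailure(
                params=params, message=f"burn-in failed: {pre.message}",
                t_reached=0.0)
        P0 = pre.y[:, -1]
        # the burn-in ends at a cycle boundary (diastolic capacitances);
        # shift pressures uniformly to restore exact mass conservation
        C = np.array([params.Cl_dia, params.Ca, params.Cv,
                      params.Cr_dia, params.Cpa, params.Cpv])
        ref = _reference_pressures(params)
        vs_target = config.total_blood_volume - params.total_unstressed_volume
        P0 = P0 + (vs_target - C @ (P0 - ref)) / C.sum()

    if config.solver in ("radau", "lsoda"):
        sol = solve_ivp(
            fun, (0.0, T), P0,
            method={"radau": "Radau", "lsoda": "LSODA"}[config.solver],
            t_eval=t_grid, rtol=config.rel_tol, atol=config.abs_tol,
            jac=jac,
        )
        if not sol.success or not np.all(np.isfinite(sol.y)):
            return SimulationFailure(
                params=params, message=sol.message,
                t_reached=float(sol.t[-1]) if sol.t.size else 0.0)
        t, P = sol.t, sol.y.T
    else:
        P, t, finite = _integrate_rk4(fun, t_grid, P0)
        if not finite:
            return SimulationFailure(
                params=params, message="explicit RK4 diverged (non-finite "
                "state); the system is stiff", t_reached=float(t[-1]))

    Q = valve_flows(P, t, params)
    cl, dcl, cr, dcr = ventricular_capacitances(t, params)
    V, total = _volumes_from_pressures(t, P, params)
    return Trajectory(
        t=t, pressures=P / MMHG_TO_BARYE, flows=Q,
        Cl=cl, Cr=cr, dCl=dcl, dCr=dcr,
        volumes=V, total_stressed_volume=total,
        params=params, config=config)


# ---------------------------------------------------------------------------
# Volumes and clinical outputs
# ---------------------------------------------------------------------------

def _volumes_from_pressures(t, P_barye, params: ParameterSet):
    cl, _, cr, _ = ventricular_capacitances(t, params)
    C = np.column_stack([
        cl,
        np.full(t.shape, params.Ca),
        np.full(t.shape, params.Cv),
        cr,
        np.full(t.shape, params.Cpa),
        np.full(t.shape, params.Cpv),
    ])
    ref = _reference_pressures(params)
    stressed = C * (P_barye - ref)
    v0 = np.array([params.Vl0, params.Va0, params.Vv0,
                   params.Vr0, params.Vpa0, params.Vpv0])
    return stressed + v0, stressed.sum(axis=1)


def compartment_volumes(traj: Trajectory, params: ParameterSet | None = None):
    """Compartment volumes V = C*(P - P_ref) + V0 (ml) and the total
    stressed volume series, recomputed from the trajectory pressures."""
    if params is None:
        params = traj.params
    return _volumes_from_pressures(traj.t, traj.pressures_barye, params)


@dataclass
class ClinicalOutputs:
    """The 16 clinical targets ``y`` with an optional missingness mask
    (True = observed).  Units per ``OUTPUT_UNITS``."""

    Hr: float
    Pa_sys: float
    Pa_dia: float
    Pr_sys: float
    Pr_dia: float
    Ppa_sys: float
    Ppa_dia: float
    Pr_edp: float
    Pw: float
    Pcvp: float
    Vl_sys: float
    Vl_dia: float
    LVEF: float
    CO: float
    SVR: float
    PVR: float
    mask: np.ndarray | None = None
    resistances_valid: bool = True

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in OUTPUT_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr, mask=None) -> "ClinicalOutputs":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (16,):
            raise CVSimError(f"expected 16 outputs, got shape {arr.shape}")
        return cls(**dict(zip(OUTPUT_NAMES, arr.tolist())), mask=mask)

    def to_dict(self) -> dict:
        return {n: getattr(self, n) for n in OUTPUT_NAMES}


def extract_outputs(traj: Trajectory, params: ParameterSet | None = None,
                    window: tuple[float, float] | None = None) -> ClinicalOutputs:
    """Clinical outputs from the periodic window Tp (default: final three
    cycles) of a trajectory.

    Extrema (systolic/diastolic pressures and ventricular volumes) are taken
    over Tp on the dense output grid; Pw, Pcvp, the mean pressures inside
    SVR/PVR and CO are trapezoidal time averages over Tp; Pr_edp is the right
    ventricular pressure at the last sample of Tp.  If CO <= 0 the vascular
    resistances are reported as NaN and flagged invalid.
    """
    if params is None:
        params = traj.params
    ttot = params.cycle_length
    if window is None:
        if traj.t[-1] < 3.0 * ttot - 1e-9:
            raise CVSimError("trajectory must cover at least 3 full cycles")
        window = (traj.t[-1] - 3.0 * ttot, traj.t[-1])
    sel = (traj.t >= window[0] - 1e-12) & (traj.t <= window[1] + 1e-12)
    t = traj.t[sel]
    P = traj.pressures[sel]
    V = traj.volumes[sel]
    qa = traj.flows[sel, 2]
    span = t[-1] - t[0]

    def tmean(x):
        return np.trapezoid(x, t) / span

    pw = tmean(P[:, 5])
    pcvp = tmean(P[:, 2])
    co_mls = tmean(qa)                      # ml/s
    co = co_mls * 60.0 / 1000.0             # L/min
    if co_mls > 0:
        svr = (tmean(P[:, 1]) - pcvp) * MMHG_TO_BARYE / co_mls
        pvr = (tmean(P[:, 4]) - pw) * MMHG_TO_BARYE / co_mls
        valid = True
    else:
        svr = pvr = float("nan")
        valid = False
    vl_sys, vl_dia = V[:, 0].min(), V[:, 0].max()
    return ClinicalOutputs(
        Hr=params.Hr,
        Pa_sys=P[:, 1].max(), Pa_dia=P[:, 1].min(),
        Pr_sys=P[:, 3].max(), Pr_dia=P[:, 3].min(),
        Ppa_sys=P[:, 4].max(), Ppa_dia=P[:, 4].min(),
        Pr_edp=P[-1, 3],
        Pw=pw, Pcvp=pcvp,
        Vl_sys=vl_sys, Vl_dia=vl_dia,
        LVEF=(vl_dia - vl_sys) / vl_dia,
        CO=co, SVR=svr, PVR=pvr,
        resistances_valid=valid,
    )


def forward_map(params: ParameterSet,
                config: SimulationConfig | None = None):
    """The full forward map v -> y: simulate then extract outputs.

    Returns ``(ClinicalOutputs, Trajectory)`` or a
    :class:`SimulationFailure`.
    """
    traj = simulate(params, config)
    if not traj.ok:
        return traj
    return extract_outputs(traj), traj
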