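"""Hemodynamic relations linking the mitral-regurgitation jet to left atrial pressure.

During systole the mitral-regurgitation (MR) jet velocity ``V`` (m/s) encodes
the instantaneous pressure difference between left ventricle (LV) and left
atrium through the simplified Bernoulli relation ``dP = 4 V**2`` (mmHg).  On
the descending branch of the continuous-wave Doppler spectrum the LV pressure
relaxes mono-exponentially (Weiss model)::

    P_LV(t) = P_ref * exp(-(t - t_ref) / tau)

above an approximately constant left atrial pressure (LAP).  Reading the
times ``t1, t2, t3`` at which the descending branch crosses 1, 2 and 3 m/s
therefore yields two interval equations in the two unknowns (LAP, tau)::

    tau * ln[(LAP + 36) / (LAP + 4)] = t1 - t3
    tau * ln[(LAP + 16) / (LAP + 4)] = t1 - t2

because ``4 V**2`` equals 4, 16 and 36 mmHg at 1, 2 and 3 m/s.  Dividing the
two eliminates tau; the resulting function of LAP is strictly increasing, so
the system has at most one non-negative root, found here by bisection.

The module also provides the sphygmomanometer estimate
``LAP_BP = P_systolic - 4 * V_peak**2``, which substitutes arterial systolic
pressure for LV systolic pressure (valid absent aortic/LVOT stenosis).

Units are fixed package-wide: seconds, m/s, mmHg.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from scipy.optimize import bisect

from .errors import ConvergenceError, InfeasibleGeometryError

__all__ = [
    "RATIO_MIN",
    "RATIO_SUP",
    "WeissDecay",
    "DescentTimes",
    "LapEstimate",
    "bernoulli_dp",
    "weiss_pressure",
    "tau_from_pressure_rate",
    "forward_descent_intervals",
    "descent_intervals_for_offsets",
    "solve_lap_eq",
    "lap_bp",
]

#: Bernoulli pressure offsets (mmHg) at the 1, 2, 3 m/s descent landmarks.
OFFSET_LOW = 4.0
OFFSET_MID = 16.0
OFFSET_HIGH = 36.0

#: Interval ratio (t1-t3)/(t1-t2) at LAP = 0: ln 9 / ln 4.
RATIO_MIN = math.log(9.0) / math.log(4.0)
#: Supremum of the interval ratio as LAP -> infinity: (36-4)/(16-4) = 8/3.
RATIO_SUP = 8.0 / 3.0


@dataclass(frozen=True)
class WeissDecay:
    """Mono-exponential LV pressure decay ``P(t) = p_ref * exp(-(t-t_ref)/tau)``.

    ``t_ref`` is the instant of peak pressure-fall rate (-dP/dt max), from
    which relaxation time is conventionally counted.
    """

    p_ref: float  # LV pressure at t_ref, mmHg
    tau: float  # relaxation time constant, s
    t_ref: float = 0.0  # reference time, s

    def __post_init__(self) -> None:
        if not (self.p_ref > 0):
            raise ValueError(f"p_ref must be positive, got {self.p_ref}")
        if not (self.tau > 0):
            raise ValueError(f"tau must be positive, got {self.tau}")


@dataclass(frozen=True)
class DescentTimes:
    """Descending-branch crossing times at 3, 2 and 1 m/s.

    Stored as absolute times; only the differences ``t1-t2`` and ``t1-t3``
    enter the equations, so the time origin is arbitrary.  Velocity falls
    with time, hence ``t3 < t2 < t1``.
    """

    t1: float  # time at 1 m/s, s
    t2: float  # time at 2 m/s, s
    t3: float  # time at 3 m/s, s

    def __post_init__(self) -> None:
        for name in ("t1", "t2", "t3"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if not (self.t3 < self.t2 < self.t1):
            raise ValueError(
                f"descent ordering violated: need t3 < t2 < t1, "
                f"got t3={self.t3}, t2={self.t2}, t1={self.t1}"
            )

    @property
    def d12(self) -> float:
        """Interval t1 - t2 (s)."""
        return self.t1 - self.t2

    @property
    def d13(self) -> float:
        """Interval t1 - t3 (s)."""
        return self.t1 - self.t3

    @property
    def ratio(self) -> float:
        """Interval ratio (t1-t3)/(t1-t2); feasible range [ln9/ln4, 8/3)."""
        return self.d13 / self.d12


@dataclass(frozen=True)
class LapEstimate:
    """A left-atrial-pressure estimate with provenance.

    ``method`` is "Eq" (interval-equation), "BP" (sphygmomanometer) or "C"
    (catheter reference).  ``tau`` is present only for the equation method.
    ``implausible`` flags a physiologically impossible value (e.g. negative
    LAP_BP), which is reported raw rather than clipped so that downstream
    comparison statistics see the actual number.
    """

    lap: float  # mmHg
    method: str
    tau: float | None = None  # s
    implausible: bool = False
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not math.isfinite(self.lap):
            raise ValueError("lap must be finite")
        if self.method not in ("Eq", "BP", "C"):
            raise ValueError(f"unknown method tag {self.method!r}")
        if self.tau is not None and not (self.tau > 0):
            raise ValueError("tau must be positive when present")


def bernoulli_dp(v: float) -> float:
    """Pressure drop across the regurgitant orifice: ``4 v**2`` (mmHg).

    Parameters
    ----------
    v : jet velocity, m/s (non-negative).
    """
    if v < 0:
        raise ValueError(f"velocity must be non-negative, got {v}")
    return 4.0 * v * v


def weiss_pressure(decay: WeissDecay, t: float) -> float:
    """LV pressure at time ``t`` under mono-exponential relaxation (mmHg)."""
    if t < decay.t_ref:
        raise ValueError(f"t={t} precedes reference time t_ref={decay.t_ref}")
    return decay.p_ref * math.exp(-(t - decay.t_ref) / decay.tau)


def tau_from_pressure_rate(p: float, dpdt: float) -> float:
    """Relaxation constant from an instantaneous pressure and its fall rate.

    For a Weiss decay, ``tau = P / (-dP/dt)`` at every instant.
    """
    if not (p > 0):
        raise ValueError(f"pressure must be positive, got {p}")
    if not (dpdt < 0):
        raise ValueError(f"dP/dt must be negative during relaxation, got {dpdt}")
    return p / (-dpdt)


def descent_intervals_for_offsets(
    lap: float, tau: float, off_low: float, off_mid: float, off_high: float
) -> tuple[float, float]:
    """Descent intervals for arbitrary Bernoulli offsets (mmHg).

    Generalisation of :func:`forward_descent_intervals` used to model
    eccentric-jet velocity underestimation, where a measured crossing of
    ``v*`` corresponds to a true pressure offset ``4 (v*/c)**2``.
    """
    if lap < 0:
        raise ValueError(f"lap must be non-negative, got {lap}")
    if not (tau > 0):
        raise ValueError(f"tau must be positive, got {tau}")
    d12 = tau * math.log((lap + off_mid) / (lap + off_low))
    d13 = tau * math.log((lap + off_high) / (lap + off_low))
    return d12, d13


def forward_descent_intervals(lap: float, tau: float) -> tuple[float, float]:
    """Forward model: descent intervals (t1-t2, t1-t3) for a given (LAP, tau).

    Returns
    -------
    (d12, d13) : intervals in seconds, with ``d13 > d12 > 0`` and ratio
    ``d13/d12`` strictly inside ``(ln9/ln4, 8/3)``.
    """
    return descent_intervals_for_offsets(lap, tau, OFFSET_LOW, OFFSET_MID, OFFSET_HIGH)


def _ratio_mismatch(lap: float, d12: float, d13: float) -> float:
    # h(L) = d12*ln[(L+36)/(L+4)] - d13*ln[(L+16)/(L+4)];
    # strictly increasing in L, negative at the root's left.
    return d12 * math.log((lap + OFFSET_HIGH) / (lap + OFFSET_LOW)) - d13 * math.log(
        (lap + OFFSET_MID) / (lap + OFFSET_LOW)
    )


def solve_lap_eq(
    times: DescentTimes,
    *,
    bracket_max: float = 200.0,
    xtol: float = 1e-8,
    maxiter: int = 200,
    ratio_tol: float = 1e-9,
) -> LapEstimate:
    """Solve the two-interval system for (LAP, tau) from descent timing.

    Feasibility is screened first through the interval ratio
    ``r = (t1-t3)/(t1-t2)``: the ratio map ``g(L)`` is strictly increasing
    with ``g(0) = ln9/ln4`` and ``g -> 8/3`` as ``L -> inf``, so a
    non-negative root exists iff ``r`` lies in ``[ln9/ln4, 8/3)`` and is then
    unique.  LAP is located by bisection (guaranteed convergence on a
    bracket); tau follows from the t1-t3 equation.

    Raises
    ------
    InfeasibleGeometryError
        if the ratio lies outside the feasible range.
    ConvergenceError
        if bisection fails within the iteration budget or the root cannot be
        bracketed below ``1e7`` mmHg.
    """
    d12, d13 = times.d12, times.d13
    r = d13 / d12
    if r < RATIO_MIN - ratio_tol or r >= RATIO_SUP - ratio_tol:
        raise InfeasibleGeometryError(
            f"interval ratio {r:.6f} outside feasible range "
            f"[{RATIO_MIN:.6f}, {RATIO_SUP:.6f}); no non-negative LAP solves the system"
        )
    if r <= RATIO_MIN + ratio_tol:
        # Boundary case: the root is LAP = 0 to within tolerance.
        tau = d13 / math.log(OFFSET_HIGH / OFFSET_LOW)
        return LapEstimate(
            lap=0.0,
            tau=tau,
            method="Eq",
            diagnostics={"ratio": r, "iterations": 0, "converged": True},
        )

    hi = bracket_max
    while _ratio_mismatch(hi, d12, d13) < 0.0:
        hi *= 2.0
        if hi > 1e7:
            raise ConvergenceError(
                f"could not bracket a LAP root below 1e7 mmHg (ratio {r:.6f})"
            )
    try:
        lap, res = bisect(
            _ratio_mismatch,
            0.0,
            hi,
            args=(d12, d13),
            xtol=xtol,
            maxiter=maxiter,
            full_output=True,
        )
    except RuntimeError as exc:  # scipy signals maxiter exhaustion this way
        raise ConvergenceError(str(exc)) from exc
    if not res.converged:
        raise ConvergenceError(f"bisection did not converge: {res.flag}")
    tau = d13 / math.log((lap + OFFSET_HIGH) / (lap + OFFSET_LOW))
    return LapEstimate(
        lap=float(lap),
        tau=float(tau),
        method="Eq",
        diagnostics={"ratio": r, "iterations": res.iterations, "converged": True},
    )


def lap_bp(p_systolic: float, v_peak: float) -> LapEstimate:
    """Sphygmomanometer LAP estimate: ``P_systolic - 4 * v_peak**2``.

    A negative result (peak gradient exceeding systolic pressure, typical of
    eccentric-jet velocity *over*-correction or measurement error) is
    returned as-is with ``implausible=True`` rather than clipped.
    """
    if not (p_systolic > 0):
        raise ValueError(f"p_systolic must be positive, got {p_systolic}")
    if not (v_peak > 0):
        raise ValueError(f"v_peak must be positive, got {v_peak}")
    lap = p_systolic - bernoulli_dp(v_peak)
    implausible = lap < 0
    if implausible:
        warnings.warn(
            f"LAP_BP = {lap:.2f} mmHg is negative (physiologically implausible); "
            "reported unclipped",
            stacklevel=2,
        )
    return LapEstimate(lap=float(lap), method="BP", implausible=implausible)
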