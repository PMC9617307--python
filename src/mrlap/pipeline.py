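"""End-to-end estimation: spectrogram in, LAP estimates out.

Per image the sequence is calibrate -> detect -> refine -> quality gate ->
descent times -> interval-equation solve, plus the sphygmomanometer estimate
when an arterial systolic pressure is supplied.  Non-calculable cases yield
a :class:`ResultRecord` carrying the skip reason instead of estimates; a
batch never crashes on a single bad case.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import hemo
from .envelope import (
    EnvelopeTrace,
    Spectrogram,
    ThresholdPolicy,
    assess_quality,
    detect_raw_edge,
    extract_descent_times,
    refine_edge_polynomial,
)
from .errors import (
    ConvergenceError,
    EmptySignalError,
    InfeasibleGeometryError,
    MrlapError,
    RefinementError,
    RuleViolationError,
)

__all__ = ["ResultRecord", "EstimateSettings", "estimate_from_spectrogram"]


@dataclass(frozen=True)
class EstimateSettings:
    """Tunables of the estimation pipeline (all have working defaults)."""

    threshold: ThresholdPolicy = ThresholdPolicy()
    refine_degree: int = 3
    refine_knot_spacing: float = 0.006
    refine_outlier_rule: float = 3.0
    monotone_tol: float = 0.15


@dataclass
class ResultRecord:
    """Per-case outcome: either estimates or a skip/error reason."""

    case_id: str
    t1: float | None = None
    t2: float | None = None
    t3: float | None = None
    lap_eq: float | None = None
    tau: float | None = None
    lap_bp: float | None = None
    peak_velocity: float | None = None
    calculable: bool = False
    lap_bp_implausible: bool = False
    skip_reason: str | None = None
    error: str | None = None

    def as_row(self) -> dict:
        return {
            "case_id": self.case_id,
            "t1": self.t1,
            "t2": self.t2,
            "t3": self.t3,
            "lap_eq": self.lap_eq,
            "tau": self.tau,
            "lap_bp": self.lap_bp,
            "peak_velocity": self.peak_velocity,
            "calculable": self.calculable,
            "lap_bp_implausible": self.lap_bp_implausible,
            "skip_reason": self.skip_reason,
            "error": self.error,
        }


def estimate_from_spectrogram(
    spec: Spectrogram,
    case_id: str = "case",
    *,
    p_systolic: float | None = None,
    settings: EstimateSettings | None = None,
) -> tuple[ResultRecord, EnvelopeTrace | None]:
    """Run the full pipeline on one calibrated spectrogram.

    Returns the result record together with the refined envelope (``None``
    when even coarse detection failed).  When ``p_systolic`` is given, the
    sphygmomanometer estimate ``LAP_BP = p_systolic - 4 v_peak^2`` is
    computed from the refined envelope's peak.
    """
    cfg = settings or EstimateSettings()
    rec = ResultRecord(case_id=case_id)
    try:
        raw = detect_raw_edge(spec, cfg.threshold)
        env = refine_edge_polynomial(
            raw,
            degree=cfg.refine_degree,
            outlier_rule=cfg.refine_outlier_rule,
            knot_spacing=cfg.refine_knot_spacing,
        )
    except (EmptySignalError, RefinementError) as exc:
        rec.error = f"{type(exc).__name__}: {exc}"
        return rec, None

    quality = assess_quality(env, monotone_tol=cfg.monotone_tol)
    rec.peak_velocity = quality.peak_velocity

    if p_systolic is not None and quality.peak_velocity > 0:
        bp = hemo.lap_bp(p_systolic, quality.peak_velocity)
        rec.lap_bp = bp.lap
        rec.lap_bp_implausible = bp.implausible

    try:
        times = extract_descent_times(env, quality)
        est = hemo.solve_lap_eq(times)
    except RuleViolationError as exc:
        rec.skip_reason = str(exc)
        return rec, env
    except (InfeasibleGeometryError, ConvergenceError) as exc:
        rec.skip_reason = f"{type(exc).__name__}: {exc}"
        return rec, env
    except MrlapError as exc:  # pragma: no cover - defensive
        rec.error = f"{type(exc).__name__}: {exc}"
        return rec, env

    rec.t1, rec.t2, rec.t3 = times.t1, times.t2, times.t3
    rec.lap_eq = est.lap
    rec.tau = est.tau
    rec.calculable = True
    return rec, env
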