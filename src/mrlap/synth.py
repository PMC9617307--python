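"""Ground-truthed synthetic MR spectrograms and cohort simulation.

Every downstream module is testable without clinical data: the generator
draws a patient's hemodynamic truth, builds the exact model envelope (systolic
LV pressure rise, then Weiss mono-exponential relaxation above a constant
LAP, mapped to jet velocity through the simplified Bernoulli relation),
renders it as a speckle-noised CW-Doppler-style intensity grid, and emulates
the reference readings (floating-catheter PAWP, radial-artery systolic
pressure) as noisy observations of the truth.

The default cohort mirrors the study conditions the method was evaluated
under: LAP 7-29 mmHg (mean 15.3, SD 4.9), radial systolic pressure roughly
96-119 mmHg, peak jet velocities near 4.2-5 m/s, and a case mix of
CABG/rheumatic patients (central jets), MVP with A2/P2 prolapse (central)
and MVP with P1/P3 prolapse, whose eccentric jets underestimate measured
velocity by a multiplicative factor ``c`` (cosine of the beam-jet angle).

All randomness flows from per-case child seeds derived from one master seed;
any case is regenerable from its seed record alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .envelope import EnvelopeTrace, Spectrogram
from .errors import ConfigError, InfeasiblePhysiologyError

__all__ = [
    "PatientTruth",
    "NoiseConfig",
    "CohortConfig",
    "SyntheticCase",
    "simulate_envelope",
    "render_spectrogram",
    "simulate_catheter",
    "simulate_case",
    "simulate_cohort",
]

GROUPS = ("CABG", "RHD", "MVP_A2P2", "MVP_P1P3")


@dataclass(frozen=True)
class PatientTruth:
    """Ground-truth hemodynamics of one synthetic patient."""

    lap_true: float  # left atrial pressure, mmHg
    tau: float  # LV relaxation constant, s
    p_systolic: float  # LV (= radial, absent stenosis) systolic pressure, mmHg
    v_peak: float  # true peak MR velocity, m/s
    eccentricity_factor: float = 1.0  # measured-velocity factor c in (0, 1]
    group: str = "CABG"
    rhythm: str = "sinus"

    def __post_init__(self) -> None:
        if not (self.lap_true > 0 and self.tau > 0 and self.v_peak > 0):
            raise ValueError("lap_true, tau and v_peak must be positive")
        if not (0 < self.eccentricity_factor <= 1):
            raise ValueError(f"eccentricity_factor must be in (0, 1], got {self.eccentricity_factor}")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.rhythm not in ("sinus", "AF"):
            raise ValueError(f"unknown rhythm {self.rhythm!r}")


@dataclass(frozen=True)
class NoiseConfig:
    """Rendering noise: multiplicative speckle (unit mean, given variance),
    additive background, and a soft-edge taper (pixels) emulating beam-spread
    blur centred on the true envelope edge."""

    speckle_var: float = 0.1
    background_sigma: float = 0.02
    soft_edge_px: float = 2.0

    @classmethod
    def none(cls) -> "NoiseConfig":
        """Noise-free, hard-edged rendering."""
        return cls(speckle_var=0.0, background_sigma=0.0, soft_edge_px=0.0)

    @classmethod
    def noiseless(cls) -> "NoiseConfig":
        """Stochastic noise off, but the deterministic beam-spread edge
        taper kept at its default width (the image-formation model is part
        of the renderer, not of the noise)."""
        return cls(speckle_var=0.0, background_sigma=0.0)


def simulate_envelope(
    truth: PatientTruth,
    dt: float,
    *,
    t_rise: float = 0.1,
    p_end_margin: float = 1.0,
) -> EnvelopeTrace:
    """Exact model envelope of one regurgitant beat, sampled every ``dt`` s.

    Ascending limb: LV pressure rises from LAP to systolic along a
    half-cosine over ``t_rise`` s (a shape choice for realistic rendering
    only — the estimation method uses nothing before the peak); velocity is
    ``sqrt(P_LV - LAP) / 2``, capped at ``v_peak``.  Descending limb: Weiss
    decay ``P_LV = p_systolic * exp(-(t - t_rise)/tau)`` continued until
    ``P_LV <= lap_true + p_end_margin``.  Measured velocities are multiplied
    by the eccentricity factor ``c``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if truth.p_systolic <= truth.lap_true + p_end_margin:
        raise InfeasiblePhysiologyError(
            f"p_systolic {truth.p_systolic} must exceed lap_true {truth.lap_true} "
            "for a regurgitant jet to exist"
        )
    t_down = truth.tau * math.log(truth.p_systolic / (truth.lap_true + p_end_margin))
    t = np.arange(0.0, t_rise + t_down, dt)
    p_lv = np.where(
        t <= t_rise,
        truth.lap_true
        + (truth.p_systolic - truth.lap_true) * 0.5 * (1 - np.cos(np.pi * np.minimum(t, t_rise) / t_rise)),
        truth.p_systolic * np.exp(-(t - t_rise) / truth.tau),
    )
    v = np.sqrt(np.maximum(p_lv - truth.lap_true, 0.0)) / 2.0
    v = np.minimum(v, truth.v_peak) * truth.eccentricity_factor
    return EnvelopeTrace(time=t, velocity=v, column_valid=np.ones(t.shape, dtype=bool))


def render_spectrogram(
    env: EnvelopeTrace,
    dv: float,
    noise: NoiseConfig | None = None,
    *,
    rng: np.random.Generator | int | None = None,
    base_intensity: float = 1.0,
    baseline_row: int = 3,
    top_margin: int = 5,
) -> Spectrogram:
    """Render an envelope as a CW-Doppler-style intensity grid.

    Pixels between the baseline and the envelope are filled at
    ``base_intensity``, multiplied by gamma-distributed speckle (unit mean,
    variance ``speckle_var``), with Gaussian background noise added
    everywhere and a linear soft-edge ramp of width ``soft_edge_px`` centred
    on the true edge.  Deterministic for a fixed ``rng`` seed.
    """
    if dv <= 0:
        raise ValueError("dv must be positive")
    cfg = noise if noise is not None else NoiseConfig()
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    n_cols = len(env)
    v_max = float(env.velocity.max())
    n_jet_rows = int(math.ceil(v_max / dv)) + top_margin + 1
    n_rows = baseline_row + n_jet_rows

    depth = np.arange(n_jet_rows, dtype=float)[:, None]  # rows below baseline
    edge = env.velocity[None, :] / dv  # edge depth per column, in rows
    w = cfg.soft_edge_px
    if w > 0:
        fill = np.clip((edge - depth) / w + 0.5, 0.0, 1.0)
    else:
        fill = (depth <= edge).astype(float)

    jet = base_intensity * fill
    if cfg.speckle_var > 0:
        shape = 1.0 / cfg.speckle_var
        jet = jet * gen.gamma(shape, 1.0 / shape, size=jet.shape)

    grid = np.zeros((n_rows, n_cols))
    grid[baseline_row:, :] = jet
    if cfg.background_sigma > 0:
        grid = grid + gen.normal(0.0, cfg.background_sigma, size=grid.shape)
    grid = np.clip(grid, 0.0, None)

    return Spectrogram(
        intensity=grid, dt=env.dt, dv=dv, baseline_row=baseline_row, jet_side="below"
    )


def simulate_catheter(
    truth: PatientTruth, sigma_c: float = 2.0, rng: np.random.Generator | int | None = None
) -> float:
    """Floating-catheter (PAWP) reading: unbiased Gaussian noise around LAP."""
    if sigma_c < 0:
        raise ValueError("sigma_c must be non-negative")
    if sigma_c == 0:
        return truth.lap_true
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    return float(truth.lap_true + gen.normal(0.0, sigma_c))


@dataclass(frozen=True)
class CohortConfig:
    """Sampling ranges and noise levels for a synthetic cohort.

    Defaults follow the clinical conditions the estimator targets; every
    hemodynamic parameter is drawn uniformly over its stated range: LAP on
    [7, 29] mmHg, radial systolic pressure on [96, 119] mmHg, tau on
    [0.03, 0.08] s; the true peak velocity is Bernoulli-consistent,
    ``sqrt(p_systolic - lap)/2``.  The group mix is 10/28 CABG+rheumatic,
    7/28 MVP A2/P2 (central jets) and 11/28 MVP P1/P3 (eccentric,
    c ~ U[0.85, 0.95]); atrial fibrillation in 12/28 of cases adds +/-10 %
    beat jitter to tau and the velocity cap.
    """

    n: int = 28
    group_mix: dict = field(
        default_factory=lambda: {
            "CABG": 7 / 28,
            "RHD": 3 / 28,
            "MVP_A2P2": 7 / 28,
            "MVP_P1P3": 11 / 28,
        }
    )
    lap_range: tuple[float, float] = (7.0, 29.0)
    tau_range: tuple[float, float] = (0.03, 0.08)
    p_systolic_range: tuple[float, float] = (96.0, 119.0)
    eccentricity_range: tuple[float, float] = (0.85, 0.95)
    af_fraction: float = 12 / 28
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    sigma_catheter: float = 2.0
    sigma_arterial: float = 3.0
    dt: float = 0.001
    dv: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigError(f"cohort size must be >= 1, got {self.n}")
        probs = list(self.group_mix.values())
        if any(p < 0 for p in probs):
            raise ConfigError("group proportions must be non-negative")
        if abs(sum(probs) - 1.0) > 1e-6:
            raise ConfigError(f"group proportions must sum to 1, got {sum(probs):.6f}")
        unknown = set(self.group_mix) - set(GROUPS)
        if unknown:
            raise ConfigError(f"unknown groups in mix: {sorted(unknown)}")
        if not (0 <= self.af_fraction <= 1):
            raise ConfigError("af_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticCase:
    """One fully specified synthetic patient: truth, exact envelope, rendered
    spectrogram, simulated reference readings, and the child seed from which
    the whole case can be regenerated."""

    case_id: str
    truth: PatientTruth
    envelope_true: EnvelopeTrace
    spectrogram: Spectrogram
    lap_catheter: float
    p_radial_measured: float
    seed: int


def simulate_case(cfg: CohortConfig, case_id: str, seed: int) -> SyntheticCase:
    """Generate one case deterministically from its child seed."""
    rng = np.random.default_rng(seed)
    groups = list(cfg.group_mix)
    probs = np.asarray(list(cfg.group_mix.values()), dtype=float)
    group = str(rng.choice(groups, p=probs / probs.sum()))

    lap = float(rng.uniform(*cfg.lap_range))
    tau = float(rng.uniform(*cfg.tau_range))
    p_sys = float(rng.uniform(*cfg.p_systolic_range))
    v_peak = math.sqrt(p_sys - lap) / 2.0
    c = float(rng.uniform(*cfg.eccentricity_range)) if group == "MVP_P1P3" else 1.0
    rhythm = "AF" if rng.random() < cfg.af_fraction else "sinus"
    if rhythm == "AF":
        # beat-to-beat variability: this beat's tau and velocity cap jittered
        tau *= float(rng.uniform(0.9, 1.1))
        v_peak *= float(rng.uniform(0.9, 1.1))

    truth = PatientTruth(
        lap_true=lap,
        tau=tau,
        p_systolic=p_sys,
        v_peak=v_peak,
        eccentricity_factor=c,
        group=group,
        rhythm=rhythm,
    )
    env = simulate_envelope(truth, cfg.dt)
    spec = render_spectrogram(env, cfg.dv, cfg.noise, rng=rng)
    lap_c = simulate_catheter(truth, cfg.sigma_catheter, rng=rng)
    p_radial = float(p_sys + rng.normal(0.0, cfg.sigma_arterial)) if cfg.sigma_arterial > 0 else p_sys
    return SyntheticCase(
        case_id=case_id,
        truth=truth,
        envelope_true=env,
        spectrogram=spec,
        lap_catheter=lap_c,
        p_radial_measured=p_radial,
        seed=int(seed),
    )


def simulate_cohort(cfg: CohortConfig) -> list[SyntheticCase]:
    """Generate ``cfg.n`` cases with per-case child seeds from the master seed."""
    master = np.random.default_rng(cfg.seed)
    seeds = master.integers(0, 2**31 - 1, size=cfg.n)
    width = max(3, len(str(cfg.n)))
    return [
        simulate_case(cfg, f"case_{i:0{width}d}", int(s)) for i, s in enumerate(seeds)
    ]


def with_seed(cfg: CohortConfig, seed: int) -> CohortConfig:
    """Copy of a cohort config with a different master seed."""
    return replace(cfg, seed=int(seed))
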