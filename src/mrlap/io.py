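"""File formats: spectrogram images, calibration sidecars, CSV tables, reports.

Images are 8/16-bit grayscale PNG or TIFF; intensities are rescaled to
[0, 1] on read.  Calibration sidecars are YAML key-value files with the keys
``dt_s``, ``dv_mps``, ``baseline_row``, ``jet_side``.  Tables are plain CSV
written with a fixed column order and 6-significant-digit floats so that
identical runs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .envelope import EnvelopeTrace, Spectrogram, calibrate_pixels
from .errors import ConfigError
from .synth import SyntheticCase

__all__ = [
    "read_calibration",
    "write_calibration",
    "read_spectrogram_image",
    "load_spectrogram",
    "write_spectrogram_png",
    "write_envelope_csv",
    "truth_table",
    "write_truth_table",
    "write_estimates_csv",
    "write_report_json",
]

FLOAT_FORMAT = "%.6g"

TRUTH_COLUMNS = [
    "case_id",
    "group",
    "rhythm",
    "lap_true",
    "tau",
    "p_systolic",
    "v_peak",
    "eccentricity_factor",
    "lap_catheter",
    "p_radial_measured",
    "seed",
]

ESTIMATE_COLUMNS = [
    "case_id",
    "t1",
    "t2",
    "t3",
    "lap_eq",
    "tau",
    "lap_bp",
    "peak_velocity",
    "calculable",
    "lap_bp_implausible",
    "skip_reason",
    "error",
]


def read_calibration(path: str | Path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"calibration file {path} is not a key-value mapping")
    missing = {"dt_s", "dv_mps", "baseline_row"} - set(raw)
    if missing:
        raise ConfigError(f"calibration file {path} missing keys: {sorted(missing)}")
    return {
        "dt": float(raw["dt_s"]),
        "dv": float(raw["dv_mps"]),
        "baseline_row": int(raw["baseline_row"]),
        "jet_side": str(raw.get("jet_side", "below")),
    }


def write_calibration(path: str | Path, spec: Spectrogram) -> None:
    payload = {
        "dt_s": float(spec.dt),
        "dv_mps": float(spec.dv),
        "baseline_row": int(spec.baseline_row),
        "jet_side": spec.jet_side,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def read_spectrogram_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF as a non-negative float grid scaled to [0, 1]."""
    raw = np.asarray(iio.imread(path))
    arr = raw.astype(float)
    if arr.ndim == 3:  # RGB(A) -> luminance
        arr = arr[..., :3].mean(axis=2)
    if np.issubdtype(raw.dtype, np.integer):
        arr = arr / np.iinfo(raw.dtype).max
    elif arr.max() > 1:
        arr = arr / arr.max()
    return arr


def load_spectrogram(image_path: str | Path, calib: dict) -> Spectrogram:
    grid = read_spectrogram_image(image_path)
    return calibrate_pixels(
        grid, calib["dt"], calib["dv"], calib["baseline_row"], calib.get("jet_side", "below")
    )


def write_spectrogram_png(path: str | Path, spec: Spectrogram) -> None:
    """Write the intensity grid as a 16-bit grayscale PNG (max-normalised)."""
    grid = spec.intensity
    top = grid.max()
    scaled = np.zeros_like(grid) if top == 0 else grid / top
    iio.imwrite(Path(path), (scaled * 65535).round().astype(np.uint16))


def write_envelope_csv(path: str | Path, env: EnvelopeTrace) -> None:
    df = pd.DataFrame(
        {
            "time_s": env.time,
            "velocity_mps": env.velocity,
            "column_valid": env.column_valid.astype(int),
        }
    )
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def truth_table(cases: list[SyntheticCase]) -> pd.DataFrame:
    rows = []
    for case in cases:
        t = case.truth
        rows.append(
            {
                "case_id": case.case_id,
                "group": t.group,
                "rhythm": t.rhythm,
                "lap_true": t.lap_true,
                "tau": t.tau,
                "p_systolic": t.p_systolic,
                "v_peak": t.v_peak,
                "eccentricity_factor": t.eccentricity_factor,
                "lap_catheter": case.lap_catheter,
                "p_radial_measured": case.p_radial_measured,
                "seed": case.seed,
            }
        )
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def write_truth_table(path: str | Path, cases: list[SyntheticCase]) -> None:
    truth_table(cases).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_estimates_csv(path: str | Path, records) -> None:
    rows = [r.as_row() for r in records]
    pd.DataFrame(rows, columns=ESTIMATE_COLUMNS).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


def write_report_json(path: str | Path, report: dict) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
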