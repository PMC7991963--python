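"""Configuration, validation, and CSV serialization for scenario runs."""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import pandas as pd
import yaml

from .geometry import ConicSurface, OpticalZone, RefractiveConstants
from .projection import DEFAULT_QUAD_ORDER
from .scenarios import ScenarioResult

__all__ = ["RunConfig", "load_config", "results_to_frame", "write_results", "CSV_COLUMNS"]

#: Fixed output column order for scenario CSV tables.
CSV_COLUMNS = [
    "D", "S", "R0", "Q0", "R1", "Q1", "dQ",
    "dz0", "dz2", "dz4", "dz6",
    "dg0", "dg2", "dg4", "dg6",
    "dSE_z", "dSE_g", "shift_z", "shift_g",
]

# display rounding: diopter columns to 2 decimals, everything else (um, mm, Q) to 4
_DIOPTER_COLUMNS = {"D", "dSE_z", "dSE_g", "shift_z", "shift_g"}


@dataclass(frozen=True)
class RunConfig:
    """Validated defaults for scenario runs.

    Parameters are the pre-operative apical radius ``r0`` (mm),
    asphericity ``q0``, zone diameter ``zone`` (mm), stromal index
    ``n_stroma``, Gauss-Legendre ``quad_order``, solver tolerance
    ``solver_tol`` (on Q1), and an optional output path.
    """

    r0: float = 7.8
    q0: float = 0.0
    zone: float = 6.0
    n_stroma: float = 1.376
    quad_order: int = DEFAULT_QUAD_ORDER
    solver_tol: float = 1e-8
    out: str | None = None

    def __post_init__(self) -> None:
        if not 5.0 <= self.r0 <= 12.0:
            raise ValueError(f"r0 must be within [5, 12] mm, got {self.r0}")
        if not 3.0 <= self.zone <= 9.0:
            raise ValueError(f"zone must be within [3, 9] mm, got {self.zone}")
        if not -3.0 <= self.q0 <= 1.0:
            raise ValueError(f"q0 must be within [-3, 1], got {self.q0}")
        if not 1.0 < self.n_stroma < 2.0:
            raise ValueError(f"n_stroma must be within (1, 2), got {self.n_stroma}")
        if self.quad_order < 8:
            raise ValueError("quad_order must be at least 8")
        if self.solver_tol <= 0:
            raise ValueError("solver_tol must be positive")

    @property
    def preop(self) -> ConicSurface:
        return ConicSurface(self.r0, self.q0)

    @property
    def optical_zone(self) -> OpticalZone:
        return OpticalZone(self.zone)

    @property
    def constants(self) -> RefractiveConstants:
        return RefractiveConstants(n_stroma=self.n_stroma)


def load_config(path) -> RunConfig:
    """Load a YAML key-value config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a key-value mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(
            f"unknown config keys {sorted(unknown)}; known keys are {sorted(known)}"
        )
    return RunConfig(**raw)


def _result_record(res: ScenarioResult) -> dict:
    d = res.delta
    return {
        "D": res.d, "S": res.zone.diameter_mm,
        "R0": res.r0, "Q0": res.q0, "R1": res.r1, "Q1": res.q1, "dQ": res.dq,
        "dz0": d.dz.c0, "dz2": d.dz.c2, "dz4": d.dz.c4, "dz6": d.dz.c6,
        "dg0": d.dg.g0, "dg2": d.dg.g2, "dg4": d.dg.g4, "dg6": d.dg.g6,
        "dSE_z": d.dse_zernike, "dSE_g": d.dse_ldhd,
        "shift_z": d.shift_zernike, "shift_g": d.shift_ldhd,
    }


def results_to_frame(rows: list[ScenarioResult]) -> pd.DataFrame:
    """Full-precision DataFrame with the fixed column order."""
    if not rows:
        raise ValueError("no scenario results to serialize")
    return pd.DataFrame([_result_record(r) for r in rows], columns=CSV_COLUMNS)


def write_results(rows: list[ScenarioResult], path, full_precision: bool = False) -> None:
    """Write scenario rows as CSV with deterministic formatting.

    Default display rounding is 2 decimals for diopter columns and 4
    decimals elsewhere; ``full_precision`` switches to repr-exact floats.
    """
    frame = results_to_frame(rows)
    if full_precision:
        text = frame.to_csv(index=False)
    else:
        formatted = frame.copy()
        for col in CSV_COLUMNS:
            decimals = 2 if col in _DIOPTER_COLUMNS else 4
            # round then format so output is byte-stable across runs
            formatted[col] = [f"{v:.{decimals}f}" for v in frame[col]]
        text = formatted.to_csv(index=False)
    Path(path).write_text(text)
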