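"""Tensile analysis of femur–ACL–tibia load–displacement curves.

Stiffness is the ordinary-least-squares slope of load versus displacement
restricted to a fixed extension window (0.45–0.5 mm, endpoints inclusive);
failure load is the peak force over the whole extension. Curves that peak at
the load-cell ceiling (50 N in the study) are flagged as censored rather than
dropped — the true failure load is only known to be at least the ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SchemaError, WindowError

__all__ = [
    "LoadDisplacementCurve",
    "MechanicsResult",
    "compute_stiffness",
    "compute_failure_load",
    "analyze_curve",
]

CENSOR_TOL_FRACTION = 0.001  # censored when peak is within 0.1 % of the ceiling


@dataclass
class LoadDisplacementCurve:
    displacement_mm: np.ndarray
    load_N: np.ndarray
    extension_rate_mm_s: float = 0.03
    load_cell_max_N: float = 50.0

    def __post_init__(self) -> None:
        self.displacement_mm = np.asarray(self.displacement_mm, dtype=float)
        self.load_N = np.asarray(self.load_N, dtype=float)
        if self.displacement_mm.size == 0:
            raise SchemaError("empty load-displacement curve")
        if self.displacement_mm.shape != self.load_N.shape:
            raise SchemaError("displacement and load lengths differ")
        if not (np.all(np.isfinite(self.displacement_mm))
                and np.all(np.isfinite(self.load_N))):
            raise SchemaError("non-finite values in curve")
        if np.any(np.diff(self.displacement_mm) <= 0):
            raise SchemaError("displacement must be strictly increasing")

    def __len__(self) -> int:
        return self.displacement_mm.size


@dataclass
class MechanicsResult:
    stiffness_N_per_mm: float
    failure_load_N: float
    window_mm: tuple[float, float]
    n_window_points: int
    censored: bool


def compute_stiffness(
    curve: LoadDisplacementCurve, window: tuple[float, float] = (0.45, 0.5)
) -> float:
    """OLS slope of load vs displacement inside the closed window (N/mm)."""
    lo, hi = window
    sel = (curve.displacement_mm >= lo) & (curve.displacement_mm <= hi)
    n = int(np.count_nonzero(sel))
    if n < 2:
        raise WindowError(
            f"only {n} samples in displacement window [{lo}, {hi}] mm (need >= 2)"
        )
    x = curve.displacement_mm[sel]
    y = curve.load_N[sel]
    xc = x - x.mean()
    return float(np.dot(xc, y - y.mean()) / np.dot(xc, xc))


def compute_failure_load(curve: LoadDisplacementCurve) -> tuple[float, bool]:
    """Peak force over the full extension, with a ceiling-censoring flag."""
    peak = float(curve.load_N.max())
    censored = peak >= curve.load_cell_max_N * (1.0 - CENSOR_TOL_FRACTION)
    return peak, censored


def analyze_curve(
    curve: LoadDisplacementCurve, window: tuple[float, float] = (0.45, 0.5)
) -> MechanicsResult:
    lo, hi = window
    sel = (curve.displacement_mm >= lo) & (curve.displacement_mm <= hi)
    stiffness = compute_stiffness(curve, window)
    peak, censored = compute_failure_load(curve)
    return MechanicsResult(
        stiffness_N_per_mm=stiffness,
        failure_load_N=peak,
        window_mm=(lo, hi),
        n_window_points=int(np.count_nonzero(sel)),
        censored=censored,
    )
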