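"""In-silico voltage calibration for gait cycling.

Before cycling, the stimulation intensity must be set so the mouse muscle's
normalized force (force / measured Fmax) matches the human muscle's
normalized force over the gait cycle.  The procedure mirrors the bench one:
start from the 0-20 V excitation range with a scale factor of 1; if the peak
normalized force misses the target by more than the tolerance, escalate to
the 0-80 V range and adjust the scale factor until the peak matches.  The
adjustment here is bracketing + bisection on the peak-force error, which the
monotone peak-vs-scale response guarantees to converge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .hill import HillParameters, VoltageExcitationMap, simulate_force
from .protocol import (DEFAULT_VOLTAGE_RANGE, ESCALATED_VOLTAGE_RANGE,
                       HumanGaitTrace, MuscleArchitecture, NormalizedTrace,
                       build_gait_cycle_command)

__all__ = ["CalibrationResult", "calibrate_voltage", "peak_normalized_force"]

#: Bisection bracket on the scale factor over the escalated 0-80 V range:
#: 4x the initial range ratio, spanning the 0-20 -> 0-80 V escalation.
SCALE_BRACKET = (0.0, 8.0)


@dataclass(frozen=True)
class CalibrationResult:
    scale_factor: float
    voltage_range: tuple[float, float]
    achieved_peak: float
    target_peak: float
    n_iterations: int
    converged: bool
    diagnostic: str = ""

    def __post_init__(self) -> None:
        if not self.voltage_range[0] < self.voltage_range[1]:
            raise ValueError("voltage_range must satisfy lo < hi")
        if self.scale_factor < 0 or self.achieved_peak < 0:
            raise ValueError("scale_factor and achieved_peak must be >= 0")


def peak_normalized_force(scale: float, voltage_range: tuple[float, float],
                          trace: HumanGaitTrace, arch: MuscleArchitecture,
                          muscle: HillParameters,
                          voltage_map: Callable[[np.ndarray], np.ndarray] | None = None,
                          sample_rate_hz: float = 222.0) -> float:
    """Simulate one gait cycle and return peak force / Fmax of the testbed."""
    cmd = build_gait_cycle_command(trace, arch, voltage_scale=scale,
                                   sample_rate_hz=sample_rate_hz,
                                   voltage_range=voltage_range)
    res = simulate_force(muscle, cmd, voltage_map)
    return float(res.force_mn.max() / muscle.fmax_mn)


def calibrate_voltage(target: NormalizedTrace, trace: HumanGaitTrace,
                      arch: MuscleArchitecture, muscle: HillParameters,
                      tolerance: float = 0.05, max_iter: int = 40,
                      voltage_map: Callable[[np.ndarray], np.ndarray] | None = None,
                      sample_rate_hz: float = 222.0) -> CalibrationResult:
    """Find the voltage scale factor matching the human normalized peak force.

    ``target`` is the human force trace normalized by the human model Fmax;
    the matching criterion is the peak normalized force over the cycle.
    Deterministic; an unattainable target returns ``converged=False`` with a
    diagnostic instead of raising.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    target_peak = float(np.max(target.value))
    if target_peak < 0 or target_peak > 1:
        raise ValueError("target peak must lie in [0, 1]")
    if voltage_map is None:
        voltage_map = VoltageExcitationMap()

    if target_peak == 0.0:
        return CalibrationResult(0.0, DEFAULT_VOLTAGE_RANGE, 0.0, 0.0, 0, True)

    def peak(scale: float, vrange: tuple[float, float]) -> float:
        return peak_normalized_force(scale, vrange, trace, arch, muscle,
                                     voltage_map, sample_rate_hz)

    # step 1: initial range 0-20 V, scale factor 1
    n_eval = 1
    p = peak(1.0, DEFAULT_VOLTAGE_RANGE)
    if abs(p - target_peak) <= tolerance:
        return CalibrationResult(1.0, DEFAULT_VOLTAGE_RANGE, p, target_peak,
                                 n_eval, True)

    # step 2: escalate to 0-80 V, bisect the scale factor on peak error
    lo, hi = SCALE_BRACKET
    n_eval += 1
    p_lo = peak(lo, ESCALATED_VOLTAGE_RANGE)
    if abs(p_lo - target_peak) <= tolerance:
        return CalibrationResult(lo, ESCALATED_VOLTAGE_RANGE, p_lo, target_peak,
                                 n_eval, True)
    n_eval += 1
    p_hi = peak(hi, ESCALATED_VOLTAGE_RANGE)
    if abs(p_hi - target_peak) <= tolerance:
        return CalibrationResult(hi, ESCALATED_VOLTAGE_RANGE, p_hi, target_peak,
                                 n_eval, True)
    if p_hi < target_peak:
        return CalibrationResult(hi, ESCALATED_VOLTAGE_RANGE, p_hi, target_peak,
                                 n_eval, False,
                                 diagnostic="target peak unattainable at maximum "
                                            f"voltage (best {p_hi:.3f} < "
                                            f"{target_peak:.3f})")
    if p_lo > target_peak:
        return CalibrationResult(lo, ESCALATED_VOLTAGE_RANGE, p_lo, target_peak,
                                 n_eval, False,
                                 diagnostic="passive response already exceeds the "
                                            "target peak at zero excitation")

    best = (lo, p_lo)
    while n_eval < max_iter:
        mid = 0.5 * (lo + hi)
        n_eval += 1
        p_mid = peak(mid, ESCALATED_VOLTAGE_RANGE)
        if abs(p_mid - target_peak) < abs(best[1] - target_peak):
            best = (mid, p_mid)
        if abs(p_mid - target_peak) <= tolerance:
            return CalibrationResult(mid, ESCALATED_VOLTAGE_RANGE, p_mid,
                                     target_peak, n_eval, True)
        if p_mid < target_peak:
            lo = mid
        else:
            hi = mid
    return CalibrationResult(best[0], ESCALATED_VOLTAGE_RANGE, best[1],
                             target_peak, n_eval, False,
                             diagnostic="max_iter reached before the peak error "
                                        "fell within tolerance")
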